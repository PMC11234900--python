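"""Delimited-text readers and writers for the pipeline's artifacts.

Formats (all plain text):

* sensor series — CSV with header ``timestamp,value``, ISO-8601 timestamps;
* daily yields — CSV with header ``date,value``; missing days are absent
  rows, never zeros;
* truth sidecar — YAML with the generating bump parameters, noise sd and seed
  of a synthetic dataset;
* fit directory — per-predictor surface coefficient matrices as CSV, basis
  descriptors and fit metadata (λ's, edf, rss, n, centering means) as YAML.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import BasisSystem
from .model import CoefficientSurface, VCFRMFit, VCFRMSpec
from .preprocess import CenteringInfo
from .simulate import Bump, NoiseModel, SimulatedDataset, TrueSurface


class FormatError(ValueError):
    """A malformed input row; the message names the offending line."""


def write_sensor_csv(series: pd.Series, path) -> None:
    df = pd.DataFrame(
        {"timestamp": series.index.strftime("%Y-%m-%dT%H:%M:%S"),
         "value": series.to_numpy()}
    )
    df.to_csv(path, index=False)


def read_sensor_csv(path) -> pd.Series:
    """Read a ``timestamp,value`` series, validating row by row.

    Malformed timestamps or values raise :class:`FormatError` naming the
    1-based file line number.
    """
    stamps, values = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["timestamp", "value"]:
            raise FormatError(f"{path}: line 1: expected header 'timestamp,value'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 fields")
            try:
                ts = pd.Timestamp(row[0])
                if pd.isna(ts):
                    raise ValueError
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: malformed timestamp {row[0]!r}"
                ) from None
            try:
                v = float(row[1])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: malformed value {row[1]!r}"
                ) from None
            stamps.append(ts)
            values.append(v)
    if not stamps:
        raise FormatError(f"{path}: no data rows")
    s = pd.Series(values, index=pd.DatetimeIndex(stamps), name="value")
    if not s.index.is_monotonic_increasing:
        raise FormatError(f"{path}: timestamps are not strictly increasing")
    return s


def write_yield_csv(series: pd.Series, path) -> None:
    df = pd.DataFrame(
        {"date": series.index.strftime("%Y-%m-%d"), "value": series.to_numpy()}
    )
    df.to_csv(path, index=False)


def read_yield_csv(path) -> pd.Series:
    dates, values = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["date", "value"]:
            raise FormatError(f"{path}: line 1: expected header 'date,value'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                d = pd.Timestamp(row[0])
                if pd.isna(d):
                    raise ValueError
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: malformed date {row[0]!r}"
                ) from None
            try:
                v = float(row[1])
            except (ValueError, IndexError):
                raise FormatError(
                    f"{path}: line {lineno}: malformed value"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: line {lineno}: negative yield {v}"
                )
            dates.append(d)
            values.append(v)
    if not dates:
        raise FormatError(f"{path}: no data rows")
    s = pd.Series(values, index=pd.DatetimeIndex(dates), name="yield")
    if not s.index.is_monotonic_increasing:
        raise FormatError(f"{path}: dates are not strictly increasing")
    return s


def write_truth_sidecar(ds: SimulatedDataset, path) -> None:
    doc = {
        "season_origin": str(ds.season_origin.date()),
        "lag_days": int(ds.lag_days),
        "noise": {"sd": float(ds.noise.sd), "seed": int(ds.noise.seed)},
        "surfaces": [
            {
                "predictor_index": t.predictor_index,
                "bumps": [
                    {
                        "center_s": b.center_s, "center_t": b.center_t,
                        "amplitude": b.amplitude,
                        "width_s": b.width_s, "width_t": b.width_t,
                    }
                    for b in t.bumps
                ],
            }
            for t in ds.truth
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_truth_sidecar(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    doc["truth"] = [
        TrueSurface(
            s["predictor_index"],
            tuple(Bump(**b) for b in s["bumps"]),
        )
        for s in doc.pop("surfaces")
    ]
    doc["noise"] = NoiseModel(**doc["noise"])
    return doc


def _basis_doc(b: BasisSystem) -> dict:
    return {
        "domain": [float(b.domain[0]), float(b.domain[1])],
        "n_basis": int(b.n_basis),
        "order": int(b.order),
    }


def _basis_from_doc(doc: dict) -> BasisSystem:
    return BasisSystem(
        domain=tuple(doc["domain"]), n_basis=doc["n_basis"], order=doc["order"]
    )


def write_fit_dir(fit: VCFRMFit, outdir) -> None:
    """Serialize a fitted model to a directory of delimited-text artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = fit.spec
    lam_s = np.atleast_1d(np.asarray(spec.lambda_s, dtype=float))
    lam_t = np.atleast_1d(np.asarray(spec.lambda_t, dtype=float))
    meta = {
        "model_kind": spec.model_kind,
        "intercept": bool(spec.intercept),
        "J": spec.J,
        "lambda_s": [float(v) for v in lam_s],
        "lambda_t": [float(v) for v in lam_t],
        "edf": float(fit.edf),
        "rss": float(fit.rss),
        "n": int(fit.n),
        "s_basis": _basis_doc(spec.s_basis),
        "t_basis": _basis_doc(spec.t_basis),
    }
    if fit.centering is not None:
        meta["y_mean"] = float(fit.centering.y_mean)
    (outdir / "fit.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    for j, surf in enumerate(fit.surfaces):
        np.savetxt(outdir / f"surface_{j}.csv", surf.B, delimiter=",")
    if spec.intercept:
        np.savetxt(
            outdir / "intercept.csv", fit.coef[spec.n_params :], delimiter=","
        )
    if fit.centering is not None:
        for j, curve in enumerate(fit.centering.x_mean_curves):
            np.savetxt(outdir / f"x_mean_{j}.csv", curve, delimiter=",")


def read_fit_dir(indir) -> VCFRMFit:
    indir = Path(indir)
    meta = yaml.safe_load((indir / "fit.yaml").read_text())
    s_basis = _basis_from_doc(meta["s_basis"])
    t_basis = _basis_from_doc(meta["t_basis"])
    lam_s = meta["lambda_s"]
    lam_t = meta["lambda_t"]
    spec = VCFRMSpec(
        J=meta["J"], s_basis=s_basis, t_basis=t_basis,
        lambda_s=lam_s[0] if len(lam_s) == 1 else np.array(lam_s),
        lambda_t=lam_t[0] if len(lam_t) == 1 else np.array(lam_t),
        model_kind=meta["model_kind"],
        intercept=bool(meta.get("intercept", False)),
    )
    surfaces, coefs = [], []
    for j in range(meta["J"]):
        B = np.loadtxt(indir / f"surface_{j}.csv", delimiter=",")
        B = B.reshape(spec.s_basis.n_basis, spec.t_basis.n_basis)
        surfaces.append(CoefficientSurface(j, B, spec.s_basis, spec.t_basis))
        coefs.append(B.ravel())
    if spec.intercept:
        a = np.loadtxt(indir / "intercept.csv", delimiter=",")
        coefs.append(np.atleast_1d(a))
    centering = None
    if "y_mean" in meta:
        curves = []
        for j in range(meta["J"]):
            p = indir / f"x_mean_{j}.csv"
            if p.exists():
                curves.append(np.loadtxt(p, delimiter=","))
        centering = CenteringInfo(y_mean=meta["y_mean"], x_mean_curves=curves)
    return VCFRMFit(
        spec=spec, surfaces=surfaces, coef=np.concatenate(coefs),
        edf=meta["edf"], rss=meta["rss"], n=meta["n"], centering=centering,
    )
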
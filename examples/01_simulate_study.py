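"""Generate a synthetic greenhouse study and look at what it contains.

The generator produces minute-cadence temperature and radiation streams, a
multi-season daily yield series driven through the model integral by known
coefficient surfaces, weekly facility holidays, and the noiseless signal for
reference.
"""

import numpy as np

from cropfda import make_synthetic_study

ds = make_synthetic_study(seed=7, cadence_minutes=10, n_years=2)

temp, rad = ds.env_raw
print(f"temperature: {len(temp):,} samples, "
      f"{temp.index[0]:%Y-%m-%d} .. {temp.index[-1]:%Y-%m-%d}, "
      f"mean {temp.mean():.1f} degC")
print(f"radiation:   {len(rad):,} samples, min {rad.min():.1f} (clipped at 0)")
print(f"yields:      {len(ds.yield_daily)} harvest days over "
      f"{(ds.yield_daily.index[-1] - ds.yield_daily.index[0]).days + 1} calendar days "
      f"(gaps are weekly holidays)")
print(f"yield noise sd: {ds.noise.sd:.2f} "
      f"(= 10% of the noiseless signal sd)")

# the generating truth is recorded: coefficient-surface value at its peak
b = ds.truth[0].bumps[0]
print(f"true temperature effect peaks at s={b.center_s:.0f} d before harvest, "
      f"t={b.center_t:.0f} d of season, amplitude {b.amplitude} yield units "
      f"per degC per day")
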
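"""End-to-end monthly-claims-style analysis on a synthetic series.

The fixture emulates a decade of monthly counts of disability-benefit
claimants (T=12, 120 observations, all counts >= 1).  Users with the real
claims series can load it with ``read_series_csv(path, T=12)`` and run the
same pipeline.  Pipeline: detect the period, estimate thresholds, compare
innovation families by AIC/BIC under conditional maximum likelihood, and
score hold-out forecasts.
"""

import numpy as np

from psetinar import aic_bic, cml_estimate, detect_period, three_step_estimate
from psetinar.forecasting import holdout_forecast_table, model_from_estimate
from psetinar.study import make_wcb_like_fixture

series = make_wcb_like_fixture(seed=0)
print(f"{series.x.size} monthly counts, min={series.x.min()}, max={series.x.max()}")
print("detected period:", detect_period(series.x))

three = three_step_estimate(series)
r_hat = three.r_mql.r_int
print("estimated thresholds:", r_hat)
for j, msgs in three.r_mql.flags.items():
    print(f"  month {j}: {msgs[0]}")

print("\ninnovation-family comparison (CML, 3 parameters per month):")
fits = {}
for family in ("poisson", "zero_truncated_poisson",
               "geometric", "zero_truncated_geometric"):
    fit = cml_estimate(series, r_hat, family=family)
    aic, bic = aic_bic(fit.loglik, n_params=3 * 12, n_obs=series.x.size)
    fits[family] = fit
    print(f"  {family:28s} loglik={fit.loglik:9.2f}  AIC={aic:7.2f}  BIC={bic:7.2f}")

best_family = min(
    fits, key=lambda f: aic_bic(fits[f].loglik, 36, series.x.size)[0]
)
print("best family by AIC:", best_family)

spec = model_from_estimate(fits[best_family], r_hat, best_family)
table = holdout_forecast_table(spec, series, horizons=(1, 2, 3, 12))
print("\nlast-year hold-out PRMSE (conditional expectation):")
print(table.to_string(index=False))
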
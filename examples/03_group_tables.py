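"""Two-group statistics from printed summaries and from raw samples.

Welch t-tests (unequal variances — the groups are 68 vs 24) with
pooled-SD Cohen's d, 95% mean confidence intervals, and the
covariate-adjusted sex effect with variance inflation factors.
"""

import numpy as np
import pandas as pd

from pedoperm import SummaryStats, mean_ci, pooled_cohens_d_from_summary, welch_t_from_summary
from pedoperm.cohortstats import adjusted_sex_effect

# group summaries (n, mean, SD) as they would appear in a cohort table
rows = {
    "age (y)": ((68, 34.5, 14.9), (24, 33.7, 14.4)),
    "step duration (s)": ((68, 0.49, 0.03), (24, 0.524, 0.048)),
    "cadence (steps/min)": ((68, 122.99, 7.56), (24, 115.60, 11.41)),
    "max force (N)": ((68, 652.2, 88.3), (24, 848.1, 105.0)),
}
print(f"{'parameter':<22}{'t':>8}{'p':>9}{'d':>8}   female 95% CI")
for name, (f, m) in rows.items():
    sf, sm = SummaryStats(*f), SummaryStats(*m)
    t, df, p = welch_t_from_summary(sf, sm)
    d = pooled_cohens_d_from_summary(sf, sm)
    lo, hi = mean_ci(sf)
    print(f"{name:<22}{t:>8.2f}{p:>9.3f}{d:>8.2f}   [{lo:.2f}, {hi:.2f}]")

# covariate-adjusted sex effect on a synthetic parameter
rng = np.random.default_rng(0)
n = 92
sex = np.array([1] * 68 + [0] * 24)  # female = 1, male = 0
table = pd.DataFrame({
    "sex": sex,
    "age": rng.normal(34, 14, n),
    "bmi": rng.normal(22, 3, n),
    "cadence": rng.normal(120, 9, n),
    "foot_angle": rng.normal(4, 4, n),
    "speed": rng.normal(1.4, 0.18, n),
})
table["contact_area"] = 150 - 18 * sex + 0.5 * table["bmi"] + rng.normal(0, 8, n)
res = adjusted_sex_effect(table, "contact_area")
print(f"\nadjusted sex effect on contact area: "
      f"coef {res.params['sex']:.1f} cm^2 (t = {res.tvalues['sex']:.2f}, "
      f"p = {res.pvalues['sex']:.4f}); all VIF < {res.vif.max():.2f}")

# A negative female coefficient close to the generating -18 cm^2 shows the
# sex effect survives adjustment for the five gait/anthropometric covariates.
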
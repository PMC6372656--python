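"""The sigma scale: Mahalanobis distances as chi-distribution percentiles.

Converts a few ICV-standardized climate distances to percentiles and back to
the sigma scale, showing the two anchor points of the method: 2σ is the 95th
percentile of the chi distribution and 4σ the 99.994th.
"""

import numpy as np

from climate_analogs import ICVModel, chi_percentile, sigma_dissimilarity

print("chi(1) percentile at D=2:", round(chi_percentile(2.0, 1)[0] * 100, 1), "%")
print("chi(1) percentile at D=4:", round(chi_percentile(4.0, 1)[0] * 100, 3), "%")

# a 12-variable ICV with moderate correlation between neighbouring variables
idx = np.arange(12)
cov = 0.4 ** np.abs(idx[:, None] - idx[None, :])
icv = ICVModel(mean=np.zeros(12), covariance=cov, retained_dims=12)

y = np.zeros(12)
for step in (0.1, 0.3, 0.6, 1.0, 2.0):
    x = np.full(12, step)  # a uniform shift of every climate variable
    d = sigma_dissimilarity(x, y, icv)
    print(
        f"shift {step:.1f} per variable -> D = {d.mahalanobis_d:5.2f}, "
        f"percentile = {d.percentile:8.6f}, sigma = {d.sigma:5.2f}"
    )

# Reading: sigma ≤ 2 means the two climates differ no more than ~95% of
# interannual fluctuations do — a representative analog; sigma > 4 means the
# match is worse than essentially any year-to-year excursion (a novel climate).
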
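"""Rank correlations between the HV index and the pressure gradient.

Computes the pooled Spearman correlation with its Fisher-z confidence
interval, the per-timepoint correlations, and the chi-squared test of
whether the per-timepoint coefficients share one population value.
"""

from hvindex import (SyntheticConfig, correlation_heterogeneity,
                     generate_cohort, spearman)

cohort = generate_cohort(SyntheticConfig(seed=1))
df = cohort.df

pooled = spearman(df["hv_index"], df["gradient_mmhg"], method="approx")
print(f"pooled rho = {pooled.rho:.3f} "
      f"(95% CI {pooled.ci_low:.3f}, {pooled.ci_high:.3f}; "
      f"p = {pooled.p:.2g}, n = {pooled.n})")

rhos, ns = [], []
for tp in cohort.timepoints():
    sub = df[df["timepoint"] == tp]
    r = spearman(sub["hv_index"], sub["gradient_mmhg"])  # exact p at n <= 10
    print(f"  {tp:7s} rho = {r.rho:6.3f}  p = {r.p:.3f}  n = {r.n}")
    rhos.append(r.rho)
    ns.append(r.n)

het = correlation_heterogeneity(rhos, ns)
print(f"equality of correlations: chi2 = {het.chi2:.3f}, df = {het.df}, "
      f"p = {het.p:.3f}")

# A non-significant chi-squared says the index tracks the gradient equally
# well at every stage of remodeling -- the property that makes it usable
# for longitudinal monitoring.
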
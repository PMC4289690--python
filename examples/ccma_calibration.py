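"""Calibrate the CCMA statistic and classify a few variants.

The compare-and-contrast statistic T_max is the largest of |T1|, |T2|,
|T1+T2|/sqrt(2) and |T1-T2|/sqrt(2), where T1 and T2 are the per-disease
meta-analysis z-scores of one variant.  Under the null both z-scores are
independent standard normals, so significance thresholds follow from the
null distribution of the max.
"""

from crosspheno import analytic_tail_p, calibrate, ccma_statistic, simulate_null

# thresholds at the conventional suggestive / genome-wide tail probabilities
thresholds, curve = calibrate([1e-5, 1e-8])
print(f"T_max threshold for p = 1e-5 (suggestive):  {thresholds[1e-5]:.3f}")
print(f"T_max threshold for p = 1e-8 (significant): {thresholds[1e-8]:.3f}")

# Monte-Carlo cross-check of the analytic tail at the suggestive threshold
null = simulate_null(2_000_000, seed=0)
t = thresholds[1e-5]
print(f"analytic tail at {t:.2f}: {analytic_tail_p(t):.3g}; "
      f"MC tail: {(null.draws > t).mean():.3g}")

# classification: the arg-max component names the effect pattern
for t1, t2 in [(5.5, 0.3), (0.2, -5.1), (4.1, 4.4), (3.9, -3.6)]:
    s = ccma_statistic(t1, t2)
    print(f"T1={t1:+.1f} T2={t2:+.1f} -> T_max={s.T_max:.2f} "
          f"category={s.category}")
# A variant is e.g. 'opposing' when the difference contrast dominates:
# the allele raises risk for one disease and lowers it for the other.
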
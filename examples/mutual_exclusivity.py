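"""How much mutual exclusivity do opposing loci explain?

Atopic dermatitis is reported ~25-fold rarer among psoriasis cases than in
the population.  Given loci with opposing allelic effects, the model
combines the two per-disease logistic risk models (conditionally
independent given genotype, marginal prevalences fixed at 10% and 2%) and
evaluates P(AD | PSO) by exact enumeration over genotypes.
"""

from crosspheno import (
    ExclusivityModel,
    Locus,
    conditional_prevalence,
    exclusivity_explained,
    observed_reduction,
)

# six opposing loci: risk allele for one disease protects against the other
loci = [Locus(freq=0.25, or_ad=0.55, or_pso=1.42),
        Locus(freq=0.40, or_ad=1.27, or_pso=0.88),
        Locus(freq=0.30, or_ad=0.70, or_pso=1.77),
        Locus(freq=0.20, or_ad=0.81, or_pso=1.12),
        Locus(freq=0.15, or_ad=0.60, or_pso=1.18),
        Locus(freq=0.10, or_ad=0.61, or_pso=1.18)]
model = ExclusivityModel(loci=loci, prevalence_ad=0.10,
                         prevalence_pso=0.02, fold_reduction=25)

cond = conditional_prevalence(model)
print(f"population P(AD)          = {model.prevalence_ad:.3f}")
print(f"genetic   P(AD | PSO)     = {cond:.3f}")
print(f"observed exclusivity      = {observed_reduction(model):.1f} "
      "percentage points (25-fold reduction: 10% -> 0.4%)")
print(f"share explained by loci   = "
      f"{exclusivity_explained(model, cond):.1f}%")
# The genetic model lowers AD prevalence among psoriasis cases by some
# percentage points; dividing by the observed 9.6-point drop gives the
# fraction of the epidemiological exclusivity these loci account for.
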
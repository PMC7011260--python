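"""Operating characteristics of the pipeline on synthetic catalogues.

Simulates case-control meta-analyses with known truth: null variants
should essentially never be flagged noteworthy at the low GWAS prior,
and the fixed-effect pooled OR should recover the generating effect.
"""

import math

import numpy as np

from metacred import cred_stats, synthetic_meta

# 200 null variants at GWAS-ish scale
spec = synthetic_meta.SimulationSpec(
    n_variants=200, fraction_true=0.0, studies_per_variant=5,
    cases_per_study=5000, controls_per_study=5000,
    study_type_label="gwas", seed=7)
sim = synthetic_meta.simulate_catalog(spec)
config = cred_stats.CredibilityConfig.for_study_type("gwas")
flagged = sum(cred_stats.evaluate_profile(rec, config).noteworthy_any(1e-6)
              for rec in sim.catalog)
print(f"null catalogue: {flagged}/{spec.n_variants} variants flagged "
      f"noteworthy at prior 1e-6")

# effect recovery at OR 1.5
rng = np.random.default_rng(7)
studies = [synthetic_meta.simulate_study(0.3, 1.5, 2000, 2000, rng)
           for _ in range(20)]
rec = synthetic_meta.pool_fixed_effect(studies, maf=0.3)
print(f"pooled OR over 20 studies of 2000/2000 at true OR 1.5: "
      f"{rec.odds_ratio:.4f} ({rec.ci_lower:.4f}-{rec.ci_upper:.4f})")
se = math.log(rec.ci_upper / rec.ci_lower) / (2 * cred_stats.normal_quantile(0.975))
effect = cred_stats.z_and_p(rec.odds_ratio, se)
print(f"pooled two-sided log10 P: {effect.log10_p:.1f} "
      f"(the P value itself underflows double precision)")

profile = cred_stats.evaluate_profile(rec, config)
print(f"BFDP at prior 1e-6: {profile.bfdp[1e-6].value:.3g} "
      f"-> noteworthy: {profile.noteworthy_any(1e-6)}")

print("\nA true OR of 1.5 at this scale is overwhelming evidence, while "
      "\nnull variants are (correctly) never promoted to noteworthiness.")
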
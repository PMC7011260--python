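"""Credibility statistics for a single pooled association estimate.

Takes one published-style result — OR 1.19 (95% CI 1.06-1.33), a
candidate-gene meta-analysis — reconstructs its effect-size uncertainty,
and evaluates FPRP (power at ORs 1.2 and 1.5) and BFDP at the medium and
low candidate-SNP priors.
"""

from metacred import cred_stats

or_, lo, hi = 1.19, 1.06, 1.33
se = cred_stats.se_from_ci(or_, lo, hi)
effect = cred_stats.z_and_p(or_, se)
print(f"OR {or_} ({lo}-{hi})  ->  SE(ln OR) = {se:.6f}, "
      f"Z = {effect.z:.4f}, two-sided P = {effect.p_two_sided:.5f}")

config = cred_stats.CredibilityConfig.for_study_type("observational")


class _Record:
    odds_ratio, ci_lower, ci_upper, ci_level, p_value = or_, lo, hi, 0.95, None


profile = cred_stats.evaluate_profile(_Record(), config)
for or1 in config.detection_ors:
    print(f"power to detect OR {or1}: {profile.power[or1]:.4f}")
for pi in config.priors:
    for or1 in config.detection_ors:
        value = profile.fprp[(pi, or1)]
        flag = " (noteworthy)" if profile.noteworthy_fprp(pi, or1) else ""
        print(f"FPRP at prior {pi:g}, OR {or1}: {value:.4f}{flag}")
    bf = profile.bfdp[pi]
    flag = " (noteworthy)" if profile.noteworthy_bfdp(pi) else ""
    print(f"BFDP at prior {pi:g}: {bf.value:.4f}{flag}")

print("\nAn FPRP below 0.2 (or BFDP below 0.8) marks the association as"
      "\nnoteworthy: unlikely to be a false positive at that prior belief.")
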
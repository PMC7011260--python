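# Methods

## Scope and data model

The package re-analyses catalogues of *pooled* association results: each
record is one meta-analytic estimate (variant, allele/genotype comparison,
OR with 95% CI, P value, study metadata), not primary study data. Six
published summary tables are bundled as TSV transcriptions with their
printed FPRP/BFDP/PAR cells carried verbatim in a `printed_stats` mapping;
cells the source printed as "–" (not computable) are stored as absent, so
downstream counting treats them as "no value" rather than zero.

Curation follows two rules. Deduplication keeps, per
(variant, comparison, study type, subtype, ethnicity) key, the most recent
meta-analysis, breaking year ties by total sample size; the key includes
subtype and ethnicity so subgroup rows coexist with overall rows.
Significance requires the study-type P threshold (0.05 observational,
5×10⁻⁸ GWAS, strict inequality) *and* a CI excluding the null. Because
published bounds are rounded to two decimals, a bound printed exactly as
1.00 counts as excluding 1 (`boundary_excludes=True`): intervals such as
1.03 (1.00–1.06) with P = 2.5×10⁻⁹ plainly excluded the null before
rounding, and a strict rule would wrongly drop them. The flag can be
turned off for unrounded inputs.

## Effect reconstruction and the credibility measures

`se = (ln U − ln L)/(2 z)` with the normal quantile computed for the
record's CI level (not hard-coded), `z = ln(OR)/se`, and the two-sided P
obtained through `log Φ̄`, so `log p` is finite far beyond double-precision
underflow of p itself.

FPRP is `p(1−π) / (p(1−π) + (1−β)π)`, evaluated from `log p` with
`logaddexp`. The power convention is configurable because the spreadsheet
lineage of the measure leaves it ambiguous:

* `fprp_alpha_mode="observed_p"` (default): power is the probability of
  exceeding the *observed* |z| under OR₁ — the convention recommended with
  the original proposal;
* `"fixed"`: power at the two-sided critical value for a fixed α (0.05).

Likewise the observed P may be reconstructed from the CI (default,
`p_source="ci"`) or taken from the printed P column. Only the exactly
degenerate case (p and power both underflowing to zero with no log
available) returns an explicit "undefined" value, mirroring the source
tables' "–" cells; an undefined FPRP is never noteworthy.

BFDP uses the normal approximate Bayes factor with prior variance
`W = (ln κ / z₀.₉₇₅)²`, κ = 1.5 by default. A single κ is used regardless
of the FPRP detection-OR grid, matching the one-BFDP-column-per-prior
layout of the source tables. The posterior null probability is formed as
`log_expit(log ABF + log PO)`, keeping `log BFDP` exact at |z| ≥ 50 (the
strongest bundled input, OR 0.90 (0.89–0.91), gives log₁₀ BFDP ≈ −70.4 at
π = 0.001, confirmed against a 60-digit evaluation of the same formula).

Protective estimates are handled through |z| with the same θ₁ = ln OR₁,
which is identical to inverting the OR and mirroring the CI; profiles are
therefore invariant under OR ↔ 1/OR.

Noteworthiness: FPRP < 0.2 or BFDP < 0.8 at the relevant prior. Priors
default to 0.05/0.001 (candidate-gene) and 0.001/10⁻⁶ (GWAS); power is
evaluated at OR₁ ∈ {1.2, 1.5}. All thresholds, priors and conventions are
fields of `CredibilityConfig`/`ReanalysisConfig`.

## Printed vs recomputed counting

Headline counts are reproduced in **printed** mode: thresholds applied to
the published cells themselves. **Recomputed** mode applies them to this
package's statistics. The two differ for borderline rows because the only
available inputs are ORs and CI bounds rounded to two decimals; with the
default conventions the recomputed observational-table cells match the
printed ones to a median absolute deviation of ≈0.006 (worst column
median ≈0.021, single worst cell ≈0.08), and `compare_to_printed` /
`deviation_summary` report the reconciliation per cell. The exact
spreadsheet conventions behind the published cells cannot be identified
uniquely from rounded inputs; the deviations are documented rather than
tuned away. Recomputed mode also yields well-defined (astronomically
small) FPRPs for the nine GWAS rows whose published cells were "–".

## Venice grading

Grades arrive either as a preformed string ("A + C + C") or from raw
inputs: amount of evidence graded on the minor-group count (A > 1000,
B 100–1000, C < 100), replication on I² (A < 25, B 25–50, C > 50), both
configurable since the grading literature's cut-offs are conventions; the
source assessment does not state whether amount was graded on minor-allele
count or total sample size, so the input is the caller's choice. Bias has
no computable rule here and is always supplied. Mapping: all A → high;
any C → low (decisive even alongside missing grades); any NA without C →
NA; otherwise intermediate.

## Attributable risk

Levin's allele-frequency form `f(OR−1)/(f(OR−1)+1)` was identified by
exact reproduction of all 36 published 10-decimal PAR cells from their
printed MAF and OR (max error < 5×10⁻¹¹ in percent units), including the
magnitude convention for protective alleles; the published allelic OR is
used as-is, with no odds-to-risk conversion. Both the signed and magnitude
values are retained. The published joint value (44.2094776354%) equals the
complement product Π(1−PARᵢ), not the conventional 1−Π(1−PARᵢ) (≈55.8%);
whether that was intended cannot be determined from the text, so both are
always reported, the product labelled "as published", and neither silently
corrected. The PAR set is selected at the low prior per study type with
power at OR 1.5 (FPRP < 0.2 or BFDP < 0.8); in printed mode a catalogue
that carries MAFs but no credibility columns (an already-curated PAR
table) is used whole. Magnitudes can exceed 1 for strongly protective
common alleles (f(1−OR) > ½); all bundled inputs are far from that regime.

## Synthetic catalogues

The generator emulates the pooled rows the pipeline consumes: per study,
control minor-allele counts are Binomial(2n, f) and case counts
Binomial(2n, f_case) with `f_case = OR·f/(1−f) / (1 + OR·f/(1−f))`;
per-study log ORs (Woolf SE, 0.5 continuity correction on zero cells) are
pooled by fixed-effect inverse variance. Defaults — 5 studies of
2000/2000 subjects, MAF uniform on (0.05, 0.5), true OR 1.5 for the
associated fraction — represent a mid-sized consortium meta-analysis; the
operating-characteristic checks use 5000/5000 per study ("GWAS scale")
and 20×2000/2000 for effect recovery. Everything is drawn from a single
`numpy` generator seeded by the spec, so catalogues are byte-identical
across runs.

Deliberately not modelled: between-study heterogeneity (random effects),
LD between variants, genotype-level models, covariates and selection
bias. Passing tests therefore show the *statistics* behave correctly on
idealised inputs, not that real catalogues are free of the biases the
Venice bias grade exists to flag.

## Numerical choices and limitations

* Quantiles come from `scipy.stats.norm`; nothing is hard-coded beyond
  documented defaults.
* Log-space FPRP/BFDP agree with naive direct evaluation to 1e-10
  relative for |z| ≤ 8 (tested), and remain finite and ordered to
  |z| = 50.
* Dedup ties beyond year and sample size keep the first-seen record and
  warn; empty post-filter catalogues produce a zero-row report with a
  warning, never an exception.
* Fixture ethnicity strings keep the printed study-count annotations
  (e.g. "Caucasian 22"), which keeps subgroup tables dedup-stable but
  means ethnicity-axis partitions split by those exact strings.
* The joint PAR combination assumes independent variants; no confidence
  intervals are attached to PAR (the sources provide none).
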
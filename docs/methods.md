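# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `sigcross`. It complements the API docstrings; nothing
here states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signature extraction

A DE table is a per-gene record (gene, log₂FC, p, FDR). The significance gate
is two-part and inclusive: up = {FDR ≤ fdr_max and log₂FC ≥ lfc_min}, down =
{FDR ≤ fdr_max and log₂FC ≤ −lfc_min}, defaults fdr_max = 0.1 and lfc_min = 1.
Tables read without an FDR column must pass through `add_fdr`
(Benjamini–Hochberg step-up, delegated to statsmodels) before thresholding:
keeping the adjustment an explicit, visible step avoids accidental double
adjustment and makes the multiplicity universe (the whole table) unambiguous.
BH was chosen because it is the default of the standard DE fitters whose
output the package consumes; the adjustment is a single exchangeable function.

Fold-change rankings and top-k selections break ties by gene identifier,
ascending lexicographic. This matters only on exactly tied values but makes
every ordering — and therefore every downstream area statistic and output
file — platform-independent.

## Ortholog mapping

Gene identifiers are case-sensitive strings and no case conversion is ever
applied implicitly; crossing species always requires an explicit ortholog map
(a helper can *construct* an uppercase-identity map, which is then visible
provenance). The default policy is `strict_one_to_one`: a gene participates
only when its mapping is unique in both directions. One-to-many orthologs
(e.g. several rodent paralogs against one human gene) are dropped and counted,
not expanded, because expansion double-counts genes in enrichment universes
and correlation vectors; `expand_all` is available where inflation is
acceptable. Paired vectors account exactly: candidates = kept + unmapped +
ambiguous + missing-in-B.

## Cumulative-overlap area and rank-sum test

With N reference genes ranked by fold change and a query of K genes present in
the reference, C(i) counts query members in the top i. The area statistic is
the discrete step sum

    area = (1/N) Σ_{i=1..N} (C(i)/K − i/N).

This definition was chosen over trapezoid or KS-style formulations because it
is a linear function of the member rank sum — area = 1/2 + (N+1)/(2N) −
(Σranks)/(NK) up to the step convention — which makes two properties exact:
reversing the ranking negates the area, and the area's sign always agrees
with the direction of the smaller one-sided rank-sum p. Query genes absent
from the reference universe are dropped and counted, never imputed.

The p-value is a Wilcoxon rank-sum comparison of member vs non-member ranks.
When min(K, N−K) ≤ 10 and N ≤ 30 the null distribution of the rank sum is
enumerated exactly by dynamic programming over subset sums (the two-sided p is
twice the smaller tail, capped at 1 — the distribution is symmetric because
reference ranks are untied by construction). Otherwise the continuity- and
tie-corrected normal approximation (scipy) is used; at N = 20, K = 5 the
one-sided approximation is within 0.01 of exact enumeration, the two-sided
within 0.02 (its error is mechanically twice the one-sided tail's). The
default sidedness is two-sided, with direction read from the area's sign —
conservative, since a one-sided choice would presuppose the result.

## Enrichment

Observed/expected enrichment uses the one-sided hypergeometric upper tail
P(X ≥ observed) with expected = n·K/N, BH-adjusted within each call's
collection; sets with no members in the universe are reported untestable and
excluded from the adjustment's m. The universe is a deliberate choice: default
is the query's source DE table (all measured genes), optionally intersected
with the reference experiment's genes (`intersect_reference`), and the policy
used is recorded in every output. Restricting to jointly measured genes keeps
the expected count honest when the platforms differ.

TF-target enrichment runs the same test per transcription factor on the up and
down signatures separately, adjusting within each direction, and reports a
signed display score: sign from whichever direction has the smaller adjusted
p, magnitude −log₁₀ of it, zero on ties (so swapping up and down exactly
negates every score). Regulation mode (activation/repression) in TF-target
files is parsed and carried through but does not enter the test.

Cell-state marker projection reports the median and interquartile range of the
bulk log₂FC of each state's markers plus a two-sided Mann–Whitney test against
non-marker genes, with a minimum-member gate (default 3) below which the state
is flagged untestable. Median/IQR + rank test were chosen as the
assumption-light summary of "where do this state's markers sit in the bulk
contrast"; this is a reconstruction of a qualitative readout, not a calibrated
estimator of cell-state abundance.

## Synthetic generator

The generator exists so that every statistic above can be validated against
known truth. Its model:

* **Programs.** Each program is a contiguous block of `size` genes (blocks may
  overlap by a configured fraction, membership effects add). Per program one
  effect δ ~ Normal(effect, effect_sd²) is drawn, signed by direction
  (`mixed` draws a per-gene sign). True per-gene effect β_g sums the programs
  containing g; non-members have β_g = 0 exactly.
* **Observation.** Observed log₂FC ~ Normal(β_g, τ²) with τ =
  residual_sd·√(2/n_replicates_per_group) — the standard error of a
  difference of two group means of per-replicate log2 expression. p-values
  are the two-sided normal tail of log₂FC/τ; FDR is BH. A z-model was chosen
  over a count model (negative binomial) because downstream statistics consume
  only (log₂FC, p, FDR), and the z-model gives closed-form oracles: under the
  defaults the p < 0.05 power of a member gene is Φ(z − 1.96) + Φ(−z − 1.96)
  with z = effect/τ, and the BH-gate recovery solves the fixed point
  k = m₀t + m₁·power(t), t = fdr_max·k/m. The tests hold the generator to
  both.
* **Pairs.** Shared programs have identical true effects in both species with
  independent observation noise. Non-shared programs exist in species A only:
  independently re-drawn effects on the same member genes would still
  correlate the species (the product of two draws centered on the same
  nonzero effect has nonzero mean), so absence is the only construction that
  makes "nothing shared" a genuine correlation null. Species-B symbols are
  the uppercase of species-A symbols; genes outside the map get a suffix so
  nothing pairs without the explicit map. The map covers an exact rounded
  fraction of genes (`ortholog_coverage`), with `one_to_many_fraction` of the
  mapped genes made ambiguous via a bogus extra partner.
* **Reference sets.** One set per program: each true member included with
  probability `sensitivity`, padded with round(sens·size·(1−prec)/prec)
  uniformly drawn non-members so the expected true-member fraction is
  `precision`; one size-matched decoy per program drawn from non-program
  genes.
* **Determinism.** All draws come from a single numpy Generator seeded by the
  config, in documented order (program effects, species-A noise, species-B
  noise, map construction, reference sets). Identical config + seed gives
  byte-identical written tables.

**Defaults** (the study conditions used throughout the tests and the
acceptance script): 2000 genes, one up-program of 100 genes with effect 2
(log₂ units), effect_sd 0, residual_sd 1, 4 replicates per group (τ ≈ 0.707),
ortholog coverage 0.9, no ambiguity, reference sensitivity and precision 0.8.
These describe a mid-sized two-group RNA-Seq contrast with a strong planted
pathway; the 36-comparison bank (21 sharing, 15 null) emulates ranking a
disease panel against one perturbation signature. Monte-Carlo sizes (100
seeded runs for recovery and calibration rates, 50 for the 5000-gene null
correlation) keep the full suite around a minute on one CPU while leaving
binomial standard errors on the reported rates below ~5 percentage points.

**What the generator does not emulate:** count-level noise and
mean-dispersion coupling, library-size and batch effects, correlated genes
outside planted programs, imperfect ortholog annotation beyond random
dropout/ambiguity, and single-cell sampling. Passing the recovery tests
therefore shows the statistics behave correctly under their stated model, not
that any particular biological comparison will reach the same rates.

## Degenerate inputs and numerical conventions

* Spearman correlation of a constant vector is undefined and returned as NaN,
  never silently 0; NaN correlations sort after all defined ones in rankings.
* Enrichment with K = 0 after universe restriction, or an empty query, yields
  an untestable result rather than an error or a fabricated p.
* Floats are written with 12 significant digits (`%.12g`); written tables
  round-trip numerically to that precision and are byte-identical across
  reruns. The output directory path is excluded from the config hash so runs
  into different locations compare equal.
* −log₁₀ scores floor p at 1e−300 to avoid infinities.

## Known limitations

* The pipeline consumes DE tables; it never fits the DE model, so shrinkage
  or dispersion artifacts in the input propagate untouched.
* `expand_all` mapping can double-count genes; it is provided for coverage
  studies, not for enrichment universes.
* The cumulative-overlap statistic is unweighted (every rank step counts
  equally); a weighted running-sum variant is out of scope.
* Reference-set precision is controlled in expectation, not exactly per draw.
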
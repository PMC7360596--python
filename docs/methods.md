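# Methods

This note documents the models, estimators, defaults and numerical choices
behind the package, and what the synthetic-data tests do and do not show.

## The inference chain

The scientific object is the age and evolutionary regime of a
non-recombining supergene (SB/Sb) relative to two reference events: the
speciation of the two socially polymorphic species and a deeply diverged,
externally dated outgroup split. All estimators work on one currency —
substitutions per site — so no absolute rate is ever needed except through
the single outgroup calibration.

1. **Homology filters.** Queries (assembly scaffolds or RAD reads) enter the
   analysis only with unique homology to the region. Genome mode: top hit in
   the region with E ≤ 10⁻⁴, and no second hit that is itself significant
   (E ≤ 10⁻⁴), has at least half the top hit's base matches, or at most half
   its mismatch percentage. RAD mode: top hit with ≤ 4 mismatches and any
   second hit with more than double the top hit's mismatches. All boundary
   comparisons are inclusive on the disqualifying side, matching the rules
   as stated; consequently a top hit with 0% mismatches (or 0 mismatches in
   RAD mode) is disqualified by any second hit at 0 — an intentional literal
   reading of a corner the rules leave open. Hit ranking ties break by
   (bitscore descending, subject id ascending) for determinism.

2. **Alignment QC.** Block length is counted in alignment columns including
   gap columns; blocks under 60 columns are dropped (strict inequality).
   Confidence masking sets columns scoring below 60 (strict) to `N` in all
   rows; scores are consumed from a sidecar table, never computed — the
   upstream alignment-confidence tool is outside this package's scope.
   Masking is idempotent and commutes with length filtering. Coverage
   summaries deduplicate overlapping reference intervals.

3. **Distances.** Substitutions are counted with *pairwise deletion* (a
   column is excluded only for pairs where either member has a gap or `N`),
   maximizing usable sites per pair. Counts are pooled across blocks per
   pair *before* the Jukes–Cantor correction `d = −(3/4)ln(1 − 4p/3)`,
   because the correction is nonlinear and pooling is the consistent
   estimator. Pairs with zero valid sites, or with p ≥ 0.75 (saturation),
   are flagged undefined — never silently zero. Storage is per site;
   reporting is per 1,000 sites, the literature's unit. Whether published
   per-1,000-site denominators excluded masked bases is not documented;
   here the denominator is always the unmasked, ungapped site count.

4. **Trees.** Neighbor joining (Saitou–Nei) serves as a desk-scale stand-in
   for a maximum-likelihood search. Negative branch estimates are clamped to
   zero with the deficit moved to the sibling branch of the join, preserving
   the joined pair's mutual distance; on additive matrices the tree
   reproduces every input distance to machine precision, which is the
   property the path-length analyses rely on. Outgroup rooting places the
   root at the *clock-balanced* point of the branch separating outgroup from
   ingroup: the position equalizing mean root-to-tip depth on the two sides
   (clamped to the branch). The position is unidentifiable from distances
   alone; the balanced choice recovers the true divergence node exactly
   under a clock, and in simulation the residual error from the accelerated
   Sb tips shifting the balance is well under 1% of the calibration depth.
   Tip-to-tip paths are invariant to the placement.

5. **Dating.**
   * λ̂ = mean(Sb root-to-tip paths)/mean(SB paths) below the SB/Sb
     divergence node. Its SD is first-order (delta-method) propagation of
     the two path-set SDs; how the published ±0.2 was derived is not stated,
     and the delta method is the simplest defensible choice. The
     significance test is a two-sided Wilcoxon rank-sum, enumerated exactly
     for group sizes ≤ 10 without ties (the study's 7v7 regime) and normal
     approximated otherwise.
   * R uses only SB paths (numerator: to the SB/Sb ancestor; denominator:
     to the ingroup–outgroup ancestor), so the Sb acceleration cancels by
     construction. Tree paths are used; a matrix-based variant would differ
     only through NJ's residual error, which is zero on additive input.
   * Age = R × calibration point. The CI multiplies tip-bootstrap quantiles
     of R (resampling SB tips, 2,000 replicates) by the matching calibration
     bounds — a conservative outer product rather than an
     independence-normality assumption. Calibration-only scaling of the
     published ratio gives a narrower interval than the published one,
     which indicates the authors combined sources of uncertainty in some
     such way; the bootstrap combination is one reasonable reading, not a
     claim about their method.
   * Ordering: with D_morph the SB–Sb distance within one species and
     D_species the SB–SB distance between species, t·r_B = D_morph/(1+λ)
     and s·r_B = D_species/2 order the two events without knowing r_B.
     When the underlying pairwise-distance sets are supplied the verdict is
     gated on a two-sided Wilcoxon comparison at α = 0.05 (returning
     "indistinguishable" when the sets do not separate); with only the two
     means, the verdict is the sign of s·r_B − t·r_B.

6. **Tajima's D.** Computed from the classic constants (a₁, a₂, b₁, b₂, c₁,
   c₂, e₁, e₂) with π the absolute mean pairwise difference per window and S
   the segregating-site count. D is undefined when S = 0, and also when the
   null variance vanishes (e.g. n = 3 with S = 1). Windows *tile* the
   chromosome (step = width): published "sliding window" scans of this kind
   follow the tooling convention of non-overlapping bins; the step is
   exposed for overlapping scans. Sites with any missing call are dropped
   listwise within their window. Depth filters: whole-genome mode keeps
   sites with at most one individual below 6 reads; RAD mode requires all
   individuals at ≥ 6. Significance maps D onto its theoretical support
   [Dmin, Dmax] (functions of n) and compares with the moment-matched beta
   distribution, two-sided at α = 0.05 — the published procedure's
   sidedness and α are unstated, so this choice is documented rather than
   inherited. n < 4 is flagged undefined (the approximation is unreliable).
   Multiple-testing correction across windows is deliberately off by
   default, matching per-window reporting; a Bonferroni option exists.

## The synthetic-data generator

The generator *defines* the validation conditions; its defaults are the
study's reported scale, chosen once:

| parameter | default | rationale |
|---|---|---|
| outgroup split | 25 MY | the external calibration, 95% CI 18–32 MY |
| speciation age | 1.26 MY | makes s·r_B ≈ 2.4 per 1,000 sites |
| supergene age | 1.1 MY | makes t·r_B ≈ 2.1 per 1,000 sites |
| base rate r_B | 1.9×10⁻³ /site/MY | SB depth ≈ 2.1/1,000 at 1.1 MY |
| λ (Sb multiplier) | 1.4 | the reported acceleration factor |
| group sizes | 7 SB + 7 Sb (dating); 4+4+4 (two-species) | the two sample designs |
| sequence length | 2×10⁵ sites (10⁶ for rate recovery) | ≫ 10× the resolved distances |
| native diversity π | 3×10⁻³ /site (2Nμ, N = 7.5×10⁴, μ = 2×10⁻⁸/gen) | reported native Sb diversity ≈ 3/1,000 |
| founder bottleneck | 1 founder + 5×10⁻⁵ private subs/site | introduced-Sb diversity ≈ 0.1/1,000 |
| RAD loci | 400 × 90 bp, Poisson(8) depth | reduced-representation regime |

Sequences evolve under strict JC69 — equal base frequencies, one rate, no
indels (gaps enter only via masking fixtures) — because that is the model
the distance correction assumes, keeping the oracle closed-form: the
expected mismatch fraction over a path d is (3/4)(1 − e^(−4d/3)). The rate
multiplier applies to every branch inside the Sb clade including its stem,
so mean true Sb/SB depths below the divergence node satisfy the ratio λ
exactly. Which of the two internal nodes is older decides the topology:
speciation-first nests the Sb clade inside the richteri subtree (the
reported arrangement); supergene-first nests the two SB groups together.

SNP tables are simulated as *independent* coalescent windows (free
recombination between 100-kb windows, none within), since within-region
recombination is out of scope but window-to-window independence is what
makes a per-window scan informative. The founder bottleneck is modeled as
founder resampling plus fresh private mutations, not a full demographic
simulation — sufficient to reproduce the single-clone signature (near-zero
inherited diversity, an excess of singletons, strongly negative D).

What passing tests therefore show: the estimators are unbiased and
well-calibrated *under the generating model* — JC69, clock-like SB
evolution, no gene flow, no recombination within the region, free
recombination between windows. They do not establish robustness to
alignment error, indels, rate heterogeneity across sites, selection, or
real demographic history; the published real-data values (e.g. a −1.51 mean
D over the supergene segment) are emulated in distribution, not reproduced
from the original genomes.

## Numerical and reproducibility choices

* One global seed expands into fixed per-stage child seeds
  (`SeedSequence(seed, spawn_key=(stage,))`); a fixed seed makes every
  output byte-identical, including pipeline TSVs.
* Internally all coordinates are 0-based half-open; every emitted text
  format (MAF-like blocks, BLAST tabular, VCF, confidence TSV) is 1-based
  fully closed, following each format's convention.
* NJ pair selection uses the row-major argmin of the Q matrix — a fixed,
  documented tie-break.
* The pipeline caches stages by checksums of their inputs and the resolved
  configuration; corrupted or edited intermediates trigger regeneration of
  the producing stage.
* Problem sizes in the test-suite and acceptance script (10⁵–10⁶ sites,
  20–50 replicates, 0.1–2 Mb chromosomes) are chosen so each recovery
  statistic has comfortable margin over its threshold while a full run
  stays desk-scale.

## Known limitations

* Confidence scores are per-column; a per-residue dialect exists in the
  wild and would need a small extension of the masking rule.
* The beta significance flag is an approximation; for very small n or S its
  calibration degrades (hence the n < 4 guard).
* The λ SD and the age-CI combination are the package's documented choices
  among several defensible ones (see above); both alternatives (bootstrap
  λ, calibration-only CI) are reachable through the API.
* No indel process, selection model, or within-region recombination in the
  generator; the ordering test assumes the decomposition
  D_morph = t·r_B(1+λ), i.e. rate constancy along each side since
  divergence.
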
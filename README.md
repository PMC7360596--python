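# supergene

Dating and population-genetic analysis of the fire-ant **social supergene** —
the SB/Sb haplotype pair on chromosome 16 of *Solenopsis* fire ants that
controls colony queen number and behaves like a young X/Y pair. The package
is aimed at molecular evolution researchers who want the full inference
chain behind a "how old is this non-recombining region?" analysis as tested,
reproducible code, exercised end to end on synthetic data with known truth.

## What it computes

Given multi-sample alignments of the non-recombining region, a group
assignment (which haplotypes are SB, Sb, outgroup) and an external
calibration, the pipeline produces:

* **Homology filtering** — BLAST-tabular and RAD-style hit tables are
  reduced to queries with unique homology to the region: top hit E ≤ 10⁻⁴
  (genome mode) or ≤ 4 mismatches (RAD mode), with competitive second hits
  rejected (second E ≤ 10⁻⁴, or ≥ half the top hit's base matches, or ≤ half
  its mismatch percentage; RAD: second hit within double the top hit's
  mismatches).
* **Alignment QC** — blocks shorter than 60 columns are dropped and columns
  with alignment-confidence scores below 60% are masked to `N`.
* **Jukes–Cantor distances** — substitutions are counted with pairwise
  deletion, pooled across blocks per pair, and corrected for multiple hits:
  `d = −(3/4)·ln(1 − (4/3)·p)`.
* **Phylogeny** — neighbor joining on the distance matrix, rooted with the
  outgroup (*S. fugax* in the study design); monophyly, MRCA and
  root-to-tip path queries.
* **Dating** — the acceleration factor λ = r_b/r_B from Sb vs SB root-to-tip
  paths (with an exact two-sided Wilcoxon rank-sum test); the depth ratio
  R = (mean SB path to the SB/Sb ancestor)/(mean SB path to the
  ingroup–outgroup ancestor), which is insensitive to the Sb acceleration;
  the supergene age `R × calibration` with a tip-bootstrap CI; and the
  ordering test `t·r_B = D_morph/(1+λ)` vs `s·r_B = D_species/2` that asks
  whether speciation or supergene formation came first.
* **Tajima's D** — per-100-kb-window D from the classic constants, with the
  study's read-depth filters and beta-distribution significance flags, plus
  segment summaries (mean D, counts of significantly negative windows).

The synthetic-data module generates every input the pipeline consumes —
JC69-evolved haplotypes on the SB/Sb/outgroup tree with an Sb rate
multiplier, RAD read stacks, SNP tables with a founder-bottlenecked
introduced-range Sb group, and toy hit tables — so every estimator can be
validated against known truth.

## Worked example

```python
from supergene import (pairwise_matrix, build_nj_tree)
from supergene.simulate import SimulationConfig, simulate_haplotypes
from supergene.dating import (CalibrationSpec, acceleration_factor,
                              relative_ratio, calibrated_age)

cfg = SimulationConfig(seq_length=1_000_000, n_blocks=1, seed=42)
blocks, truth = simulate_haplotypes(cfg)          # 7 SB + 7 Sb + outgroup
dm = pairwise_matrix(blocks)
rooted = build_nj_tree(dm).root_with_outgroup(["outgroup_1"])

sb = sorted(l for l, g in truth.groups.items() if g == "Sb")
sB = sorted(l for l, g in truth.groups.items() if g == "invicta_SB")
div = rooted.mrca(sb + sB)
lam, sd, p = acceleration_factor(rooted.path_lengths_from_node(div, sb),
                                 rooted.path_lengths_from_node(div, sB))
R, num, den = relative_ratio(rooted, sB, sb, ["outgroup_1"])
age, ci = calibrated_age(R, CalibrationSpec(25, 18, 32), (num, den), seed=42)
```

Output:

```
Sb monophyletic:      True
acceleration lambda:  1.40 +/- 0.02  (Wilcoxon p = 0.0006)
depth ratio R:        1:22.7
supergene age:        1.10 MYA  (95% CI 0.79-1.42)
```

The simulation's truth was λ = 1.4 and a supergene age of 1.1 MY against a
25 MY outgroup split: the chain recovers the acceleration factor, finds the
Sb clade monophyletic, and converts the ~1:23 depth ratio into an age of
about 1.1 MYA.

The same chain is available from the shell:

```bash
supergene all --outdir run --seed 42        # simulate + full pipeline
cat run/report.txt                          # lambda, R, age, ordering, D scan
```

Each stage writes plain-text TSVs into the output directory and reruns are
byte-identical under a fixed seed (stages are cached by input checksums).

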
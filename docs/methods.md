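# Methods

`cnvherd` implements a complete array-CGH copy-number workflow for multi-group
bovine cohorts: a synthetic experiment generator, least-squares segmentation of
log2-ratio profiles, CNV calling, CNVR aggregation, gene/QTL annotation,
indicator-value group statistics, ΔΔCt copy-number estimation from qPCR, and
fixed-effects trait association. This note records the models, the defaults
and why they were chosen, and what the synthetic data does and does not show.

## The measurement model

An aCGH experiment co-hybridises a test genome and a two-copy reference and
reports, per probe, `r = log2(test/reference)`. Under ideal hybridisation a
probe inside a region of copy number CN has expectation `log2(CN/2)`: 0 at two
copies, −1 at one copy, +0.585 at three, +1 at four. The synthetic generator
produces exactly this expectation at the probe midpoint plus independent
Gaussian noise per probe.

Choices and assumptions:

* **Noise is Gaussian.** Real probe noise has heavier tails and spatial/GC
  structure; the noise family of the original arrays is not published, so
  Gaussian is an explicit modelling assumption. Passing recovery tests on
  this generator demonstrates correctness of the pipeline's logic, not
  robustness to real-array artefacts.
* **CN=0 floor.** A homozygous deletion has `log2(0/2) = −∞`; real arrays
  saturate near background, so the expectation is floored at −3.0 log2 units.
* **Probe layout.** Probes of 60 bp (middle of the 50–75 bp design range) are
  placed with start-to-start gaps uniform on [0.5, 1.5] × the mean spacing
  (default 3,364 bp, the density of the 720k bovine design), giving a
  realised mean spacing within 5% of the request. The mitochondrial contig
  always carries exactly 5 evenly spaced probes.
* **Scaled genome.** The default genome is 5 autosomes of 10 Mb plus a 16 kb
  "M" contig (~15,000 probes at default spacing). This preserves
  multi-chromosome structure, per-chromosome segmentation, and the
  mitochondrial special case at desk-scale runtime; coordinates are not
  those of any real assembly.
* **Event structure.** Planted events are 0/1/3/4 copies organised as
  shared-by-all, group-shared, and private, mirroring the carrier-sharing
  structure of real CNVR catalogues. Events are rejection-sampled to be
  non-overlapping per sample; the first-placed event wins and later
  conflicting placements are retried elsewhere. Synthetic QTL intervals
  default to 20–300 kb: real QTL intervals span roughly 0.2–3 Mb, scaled
  down ~10× along with the chromosomes.

## Segmentation

The original analysis used a vendor's proprietary least-squares segmentation
whose objective and tuning are unpublished. `cnvherd` substitutes an exact,
testable procedure with the same modelling intent (piecewise-constant means):
minimise

    Σ_segments within-segment SSE + penalty × (number of segments)

over all contiguous partitions of a chromosome's probe-ordered values. The
optimum is found by dynamic programming with PELT-style candidate pruning,
which is exact because pooled SSE is superadditive under concatenation; the
usual case is far below the worst-case O(n²). Ties in the objective are
broken toward fewer segments, then earlier breakpoints, making results
deterministic. The DP is verified against exhaustive enumeration of all
2^(n−1) breakpoint patterns for n ≤ 12.

Each sample is median-centred before segmentation (the bulk of probes sit at
two copies, so the median tracks the two-copy baseline) — the minimal analog
of array-level normalisation.

**Penalty selection.** `choose_penalty` segments the profile at each penalty
of a candidate grid and keeps the penalty minimising
`n·log(SSE/n) + K·log(n)` (K = segment count), ties toward the larger
penalty. Because this criterion tracks deviance, it will adopt any overfit
candidate offered to it; the default grid is therefore floored at the
modified-BIC rate `3·σ̂²·log n` — the standard conservative default in
changepoint detection, above the `~2·σ̂²·log n` scale of the best spurious
split on pure noise — and extends upward by factors up to 4. The noise scale
σ̂ is estimated from the median absolute successive difference (robust to the
few differences straddling true breakpoints). On signal-free profiles this
yields a single segment ≥95% of the time; a 10-probe shift of one log2 unit
is located within ±1 probe.

## CNV calling and CNVR construction

A segment is a CNV when its mean log2 ratio is ≥ |0.5| (inclusive) and it
covers ≥ 5 consecutive probes; the state is gain or loss by sign. Adjacent
qualifying segments of the same state merge into one call (a least-squares
segmentation may split one true event; merging is conservative and does not
change carrier frequencies). Calls carry only gain/loss — the integer copy
number is deliberately not inferred from the magnitude.

CNVRs are connected components of the interval-overlap graph over calls
(transitive union); overlap means ≥1 shared base under 0-based half-open
coordinates, so bookended intervals do not merge. A CNVR is "both" when its
carriers include both gain and loss calls. Frequency uses the group size as
denominator, not the number of CNV carriers. Cross-group merging applies the
same closure to the groups' CNVR sets and records, per merged region, which
groups contributed (the Venn accounting). The construction is idempotent and
order-invariant, and is tested against a brute-force pairwise-overlap
closure.

## Annotation

A gene or QTL is "positive" for a CNVR when strictly more than 50% of the
**feature's** length is overlapped — the denominator is the feature, not the
CNVR, and the boundary is exclusive. Overlap arithmetic is verified against
per-base counting. Strand is ignored.

## Group structure

Carrier incidence forms a binary sample × CNVR matrix. Samples cluster by
average-linkage hierarchical agglomeration on Jaccard distance (two all-zero
profiles are at distance 0; an all-zero profile is at distance 1 from any
non-empty one — a documented convention, since Jaccard is undefined on empty
unions). Ordination (PCA/NMDS) is intentionally not implemented as a method.

Group-indicative CNVRs use the classic Dufrêne–Legendre IndVal on binary
presence: specificity `A_g` = (mean presence in g)/(Σ_g mean presence),
fidelity `B_g` = fraction of group-g samples carrying, statistic
`max_g sqrt(A_g·B_g)`, significance by permuting group labels with
`p = (1 + #{perm ≥ obs})/(n_perm + 1)`. An exact mode enumerates all label
orderings for small cohorts. The default α = 0.05 applies no multiplicity
correction (a Benjamini–Hochberg helper is provided, off by default).

A caveat worth knowing: on binary data the statistic for a column with k
carriers depends only on the maximum per-group carrier count, so its
permutation distribution has few atoms; exact ties with the observed value
are frequent, and the permutation p (which counts ties as exceedances, the
standard valid-test convention) is markedly conservative on balanced designs.
Attained significance levels well below the nominal α are expected, not a
bug.

## qPCR quantification

Replicate Cts are averaged per (sample, assay); ΔCt subtracts the internal
control gene, ΔΔCt subtracts the two-copy calibrator's ΔCt, and the relative
copy number is `2^−ΔΔCt` assuming perfect doubling per cycle (amplification
efficiency fixed at 2.0; efficiency correction is out of scope). Typing cuts
default to gain ≥ 1.4 and loss ≤ 0.6 — near the midpoints between the ideal
two-copy RCN of 1 and the three-copy (1.5) / one-copy (0.5) values, widened
for replicate noise; no published boundaries exist, so both are
configurable. Expression fold change is the identical arithmetic with an
expression normaliser on cDNA. Type-vs-type expression contrasts use
two-sided Welch t-tests; groups with fewer than 2 samples are skipped.

## Trait association

The trait model is additive fixed effects:

    Y_ijk = μ + F_i + G_j + B_k + E_ijk

(farm, CNV genotype, breed), fitted by OLS. Farm and breed are treated as
crossed; perfect confounding between factors is detected and rejected with
the aliased levels named, and single-level factors drop out of the formula.
Missing trait values are dropped listwise per trait.

The least-squares mean of a genotype level is the model prediction averaged
with equal weights over the grid of observed farm × breed levels; its SE
comes from the corresponding contrast and the coefficient covariance. With a
balanced design this equals the raw genotype mean (asserted in tests).
Pairwise genotype contrasts are t-tested on residual degrees of freedom, with
compact-letter display: levels sharing no letter differ at α (maximal
cliques of the not-significantly-different graph, enumerated exactly —
genotype level counts are tiny). No multiplicity correction by default,
matching the P < 0.05 superscript convention of association tables in this
field.

## Problem sizes and reproducibility

All generators and permutation tests are driven by explicit seeds; per-stage
seeds are derived from the master seed via `SeedSequence`, and a rerun of the
pipeline with the same configuration is byte-identical. Default analysis
sizes — 5 × 10 Mb genome, ~15k probes, 13 samples in 3 groups, 999
permutations, 100-replicate simulation studies for penalty selection and LSM
coverage — were chosen so a full run completes in seconds to a few minutes
on one CPU while keeping every statistical check well-powered.

## Known limitations

* No dye-swap, GC, wave, or spatial artefacts in the generator; no probe
  quality weights in segmentation.
* Segmentation equivalence with the vendor's algorithm cannot be asserted
  (its objective is unpublished); only the modelling intent is shared.
* CNVR boundaries inherit probe-resolution uncertainty; no boundary
  refinement or reciprocal-overlap CNVR definition is offered.
* The ΔΔCt chain assumes perfect efficiency and a clean two-copy calibrator.
* Farm/breed are modelled as crossed; nested designs surface as aliasing
  errors rather than being re-parameterised automatically.
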
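# Methods

## Model

A bulk tumor sample mixes tumor cells (fraction `π`, the purity) with normal
diploid cells (`1 − π`). On a segment with `nA` major and `nB` minor allele
copies, reads land on `2(1 − π) + π(nA + nB)` chromosome copies per locus in
expectation. A somatic mutation carried by `m` copies in a fraction `c` of
tumor cells is therefore read at frequency

    v_m(π, c) = m π c / [2(1 − π) + π (nA + nB)]        (clonal peak map)

The whole framework is this equation plus bookkeeping: peak prediction
(forward map), purity estimation from observed peaks (inverse map
`π(v) = 2v / [m + (2 − p) v]`, with `p = nA + nB`), first-order error
propagation in both directions, and its extension to two coexisting tumor
subclones.

Assumptions worth stating explicitly: the normal genome is diploid at every
autosomal locus (sex chromosomes are the user's responsibility via the input
segmentation); read counts are binomial at the locus level (no
over-dispersion is modelled — beta-binomial noise in real data widens peaks
but does not move them); mutation multiplicities on amplified segments are
in {1, 2} for simple states because those states are one evolutionary event
away from diploid.

## Multiplicity sets and karyotype taxonomy

Simple clonal states — 1:0 (LOH), 1:1, 2:0 (copy-neutral LOH), 2:1, 2:2
(genome doubling) — admit `m = 1` (1:0, 1:1) or `m ∈ {1, 2}` (amplified
states). Everything else is *complex* and is tested for every `m` from 1 to
max(nA, nB). Two-subclone segments are supported when both clone states are
simple (mirrored orientations such as 1:2 included); anything else is
reported unsupported rather than guessed at.

## Peak detection

Two detectors over the pooled VAFs of one karyotype:

* **KDE**: a Gaussian kernel estimate on a 0.001 grid with fixed bandwidth
  0.01 VAF. Local maxima below 1/20 of the tallest peak are discarded, and a
  prominence requirement at the same relative level merges sampling wiggles
  on one cluster. The effective bandwidth is floored at one VAF lattice step
  (1/median depth): below that, the estimate resolves the comb of individual
  count ratios `k/DP` rather than mutation clusters — a numerical degeneracy
  of low-coverage data, not signal.
* **Binomial mixture**: maximum-likelihood EM on the raw (NV, DP) counts for
  each component count `w ≤ 4`, selected by the integrated classification
  likelihood `ICL = −logL + Σ H(z) + ½ k log n` — the BIC further charged
  with the entropy of the posterior assignments, so overlapping components
  pay for their ambiguity. Initialisation is quantile spread plus five
  seeded random restarts; ties break toward fewer components. The ICL
  variant is our implementation choice; only the binomial likelihood and the
  `w < 5` cap are fixed by the method.

## Matching and scoring

The user's tolerance `ε` is stated in purity units. For each expected peak
the symmetric purity band `π ± ε` (total width `2ε`) is pushed through the
linearized peak map, giving the VAF half-width
`Δv = 2m(2ε) / [2(1 − π) + πp]²`; for a diploid pool at `π = 0.60`,
`ε = 0.025` this accepts data peaks in [27.5%, 32.5%] VAF, i.e. implied
purities in [55%, 65%]. The detected peak carries its own slack `σ`
(default 0.01 VAF — the image of a 2% purity slack under the diploid
conversion `∂v/∂π = ½`), absorbing peak-*detection* noise, which lives in
VAF space regardless of segment ploidy. A peak is matched when the two
intervals overlap.

Per karyotype, the verdict follows the peak with the most mutations
(counted in the 0.01-wide VAF bin of the matched peak; bins are
right-open, the last bin right-closed). Per sample, each karyotype gets a
weight proportional to its mutation count (split across its peaks), each
peak's signed offset is converted to purity units with the inverse-map
derivative, and their weighted sum is the sample score `λ`; the sample
passes when the mutation mass on matched peaks is at least that on
unmatched ones, and a failing sample reports `purity + λ` as the supported
purity. Comparing *score* mass instead is available
(`aggregate="score"`) but not default: perfectly matched peaks carry
near-zero score mass, so a single noisy small pool would fail an otherwise
perfect sample. A strict rule `|λ| ≤ ε` (`status_rule="score_threshold"`)
is also exposed; it is the natural criterion when `λ` itself is the object
of interest.

Matching strategies: `closest` (default) or `right_only`, which only
considers peaks right of the expectation — useful to hunt segments whose
breakpoints swallowed an undetected LOH region.

Complex and subclonal segments are matched with the raw `ε` as a VAF
tolerance (no purity conversion) using the KDE detector only, and produce
peak tables and matched fractions, not `λ` contributions.

## Subclonal evolution models

For two subclones `nA,1:nB,1` (fraction ρ₁) and `nA,2:nB,2` (ρ₂ = 1 − ρ₁),
peak positions depend on the evolutionary route. Events are single-allele
gains and losses of one copy plus whole-genome doubling (2:2 is one step
from 1:1; copy-neutral LOH via loss+gain has identical mutation
consequences to a one-step jump, so the minimal alphabet loses nothing).
Scenarios are enumerated as shortest paths in the allele-labelled copy-state
graph: branching (ancestor → clone1 | clone2) and linear in both directions
(ancestor → X → Y). Orientation variants that need more events than the
minimum for their topology are dropped; scenarios equivalent under a global
A↔B relabelling are reported once; genuinely mirrored amplifications (AAB |
ABB) stay distinct. A lost allele can never be regained, which is why e.g.
no linear chain runs from 2:0 to 2:1.

Mutation multiplicities come from replaying each path with explicit copy
genealogy (every concrete choice of which copy is duplicated or lost is
enumerated): a mutation at epoch `t` on copy `c` ends with multiplicity
equal to the number of surviving descendants of `c`. Shared mutations
(before the clones diverge) get pairs `(m₁, m₂)` and peak at

    v = (m₁ρ₁ + m₂ρ₂) π / [2(1 − π) + π(ρ₁p₁ + ρ₂p₂)]

private mutations of clone `i` use `m_i ρ_i` in the numerator. Pairs with a
zero component coincide with private peaks and are collapsed. Model
selection against data ranks models by their fraction of matched peaks;
ties among models with literally identical peak sets are reported as
`indistinguishable` (e.g. 1:1–1:0 linear vs branching), other ties as
`ambiguous`, and a best fraction below 50% as `none`.

## CCFs and multiplicity phasing

Inverting the peak map gives `c_m(π, v) = v[(nA + nB − 2)π + 2]/(mπ)`.
Per-mutation CCFs keep the binomial VAF noise — clonal mutations spread
*around* 1 and values are deliberately not clipped (a flag marks values
above 1.5 as likely artifacts). For amplified simple states the
multiplicity is phased by a two-component binomial mixture anchored at the
theoretical peaks `v₁, v₂`, with trials fixed at the median depth and
mixing weights from counting mutations inside each component's 1–99%
quantile range (mutations in both ranges go to the closer peak; mutations
in neither split proportionally). Posterior responsibilities give each
mutation an entropy `H(z)`; around the density crossing `H` spikes and
phasing from VAFs is impossible. The abstention range `[h₁, h₂]` brackets
the spike at the entropy level of a (0.9, 0.1) assignment — i.e. NA
wherever neither multiplicity reaches 90% posterior support. (Bracketing by
curvature shoulders of the profile was tried and rejected: the binomial
entropy spike has no side structure, so shoulder criteria collapse to
near-zero-width ranges and report essentially no uncertainty even at 30×
coverage and 50% purity, contradicting the method's intent.) The *rough*
alternative cuts at the mixture-weighted midpoint `o = v₁ + (v₂ − v₁)π₁`
and never abstains; outside `[h₁, h₂]` the two methods agree mutation by
mutation, so the entropy method is exactly the rough cut plus abstention.
CCF QC fails a karyotype when its NA fraction strictly exceeds 10%
(configurable); the rough method therefore always passes.

## Over-fragmentation test

Per chromosome arm (built-in length/centromere tables for GRCh38 and hg19;
segments spanning a centromere are split first), segments shorter than
`μ = 0.2` of the arm are *short* (boundary counts as long). Under the null
the short count among `k` segments is Binomial(k, μ); the one-tailed
p-value `P(X ≥ s)` is the exact upper tail, Bonferroni-controlled across
tested arms. Arms are tested only with ≥ 10 segments and a total absolute
ploidy jump ≥ 1 (both configurable and reported, since these gates are
empirical); same-state segments within 1 Mb are merged beforehand so caller
fragmentation noise does not inflate the test. Absolute differences are
used in the jump so gains and losses both count.

## Simulator

The generator reproduces the study conditions the QC is meant for: per
chromosome (real GRCh38 lengths), Poisson(6) breakpoints; per segment a
karyotype drawn from a categorical whose probabilities are Dirichlet with
concentrations 1, 1, 6, 2, 1 over {1:0, 2:0, 1:1, 2:1, 2:2} (the empirical
pan-cancer prevalence); per mutation a multiplicity uniform over the legal
set (unstated in the source design; it moves only relative peak heights,
never positions), depth Poisson(coverage), alt reads Binomial(depth, v_m).
Mutations with zero alt reads are dropped (a caller cannot report them);
stricter caller thresholds (`min_nv≈3`) can be emulated and visibly bias
low-coverage VAF modes toward the truncation point. The default mutation
rate of 2/Mb is a typical WGS burden. Optionally one two-subclone segment
is generated under a chosen evolution model with mutations placed at its
predicted peaks. Identical configs (including seed) give byte-identical
tables.

What the simulator does *not* model — over-dispersed counts, mapping
artifacts, germline leakage, purity varying along the genome, more than two
subclones — bounds what passing tests show: they validate the mathematics
and the detection/matching machinery under the stated noise model, not
robustness to every real-data pathology.

## Tolerance calibration

For a grid of (purity 0.15–0.9) × (coverage 20–120) cells and `ε` from 0.01
to 0.10, tumors are simulated at true purity `π` and QC-ed at input purity
`π + ε + φ`, `φ ~ U[0, 0.03]` — borderline inputs that exceed the tolerance
and must fail. QC runs in strict mode for this purpose (band factor 1, no
`σ` slack): the borderline design measures the tolerance band itself, and
any slack term would be what is being measured instead. The pass fraction
per cell is the false positive rate; a binomial GLM (logit) of FPR on `ε`
is inverted for the largest `ε` with predicted FPR under the target
(default 10%), capped to user bounds, and the per-cell values are
interpolated at the query point with a tensor Akima (non-smoothing
piecewise-cubic) interpolant — bilinear fallback on degenerate grids,
reported in the output. No extrapolation outside the training hull. A
frozen 5×5×10 grid with 10 replicates per point (seed 20260101, simulated
on 4-chromosome genomes at 2 mutations/Mb) ships with the package and
regenerates bit-identically from its stored parameters; denser grids can
be rebuilt with `build_fpr_grid`.

## Numerical conventions and scale choices

* Coordinates: 1-based, fully closed, for segments and mutations alike; a
  mutation at `pos == to` belongs to the segment. Overlapping segments are
  an input error, never silently resolved.
* VAF is always recomputed from NV/DP; counts are the source of truth.
* Acceptance band: the `2ε`-wide purity band is the convention that
  reproduces the published interval semantics; the strict single-`ε`
  propagation is used for FPR calibration (`band_factor=1`).
* Support bins: `[k/100, (k+1)/100)`, last bin right-closed.
* Minimum mutations: 20 per simple karyotype pool, 150 for complex and
  subclonal segments (pools below threshold are skipped and reported, not
  failed).
* Degenerate inputs: all-reference count vectors fit a single mixture
  component with a warning; an empty peak list matches nothing; a clonal
  fractional-CN input (mCNF = mCN1, CNF = CN1) yields no spurious subclone
  because every candidate ρ₁ is 0.
* Test and calibration problem sizes are scaled down (4–10 chromosomes,
  10–80 replicates per condition) from the full-genome, hundreds-of-
  thousands-of-tumors scale of the original study design; all seeds are
  fixed and every simulation is reproducible from its config.

## Known limitations

Two subclones at most; no liftover between genome builds; no read-level
simulation; the per-chromosome mode inherits the per-pool minimum mutation
counts and can be underpowered on quiet chromosomes; complex-CNA QC has no
evolutionary model (every multiplicity is tested as if clonal), so highly
rearranged genomes get a peak table rather than a verdict; CCF phasing
covers simple amplified states only, by design.
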
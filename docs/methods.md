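# Methods

## Scope and data model

`regfoot` covers the computational path of a mutagenesis-based MPRA study of
bacterial promoters: library design, ground-truth simulation, barcode
mapping and counting, footprint statistics, binding-site discovery,
cross-condition clustering and pulldown-enrichment scoring. All coordinates
live on a TSS-anchored axis −115..+45 (no position 0; +1 is the transcript
start), 160 bases total — the window in which most bacterial cis-regulation
occurs. Internally positions are 0-based, half-open; the axis labels are
used at every file interface because they match how promoter figures are
drawn.

## Library design

Each promoter window is mutated independently per position at rate 0.1
(default), substitutions only, uniform over the three non-wild-type bases;
1500 mutants plus one wild-type entry form a promoter's pool. These defaults
give each position ~150 mutant variants, enough mutational coverage to
estimate per-position effects. Pool size is therefore exactly
n\_promoters × (n\_variants + 1); a design of 119 promoters yields 178,619
entries. Promoters sharing a TSS are treated as independent entries (the
designer never deduplicates). Barcodes are uniform random 20-mers, globally
unique (collisions redrawn; a capacity error is raised when 4^L is
exhausted). Per-variant barcode multiplicities are drawn Poisson(m) clamped
at ≥1, where m is the configured median (13 and 28 are the magnitudes seen
in real libraries); at these values the Poisson median equals its integer
mean, so the realized median matches the configuration.

## Thermodynamic expression model

Expression of a variant is the equilibrium occupancy of the polymerase
site:

    p_bound = p·ω_eff / (1 + p·ω_eff + r)

* `p = w_rnap · exp(−E_rnap(s))`, with `E` the additive energy-matrix score
  of the variant sequence in k_BT (β ≡ 1). The dimensionless `weight`
  absorbs copy number, the non-specific genomic background and the
  reference binding energy — these are never separately identified, so the
  model does not represent them separately.
* Repressors act by competitive exclusion:
  `r = Σ a_j · w_j · exp(−E_j(s))` over active repressors.
* Activators stabilize the polymerase-bound state (simple activation):
  `ω_eff = 1 + Σ a_k · f_k · (ω_k − 1)` with occupancy
  `f_k = w_k e^{−E_k}/(1 + w_k e^{−E_k})` and cooperativity ω_k > 1.
* `a ∈ [0,1]` is a per-condition active fraction (the allosteric state of
  the factor in that environment); the RNAP site is always active.

Assumptions: additive (no-epistasis) energy matrices, equilibrium
occupancy ∝ transcription rate, no DNA looping and no kinetic effects.
Monotonicity holds by construction: p_bound strictly decreases in any
active repressor weight and increases in an active activator's ω.

## Synthetic data generator

The generator exists so every downstream stage can be scored against known
truth. Defaults emulate the study conditions of a real library: 1500
variants × 160 bp at 10 % mutation rate, ~3 barcodes per variant (the
medians 13/28 are available via configuration), two replicates per
condition, sequencing depths 10^5–10^6 per sample.

DNA counts are multinomial over barcodes with lognormal abundance jitter
(σ = 0.3) shared between DNA and RNA — mimicking clone-abundance variation
that cancels in the RNA/DNA ratio. RNA counts are multinomial with
probabilities ∝ abundance × p_bound. An optional Dirichlet overdispersion
knob adds the extra-multinomial noise real libraries show; it is off by
default so count noise is exactly multinomial.

The default planted architecture is an RNAP site at −40..−1, a
condition-specific activator at −75..−55, optionally a constitutive
repressor at −100..−85. Energy matrices take the wild type as consensus
with mismatch penalties Uniform(0.5, 1.5) k_BT (RNAP) and Uniform(2, 3)
k_BT (TFs); the activator sits at half occupancy with ω = 25 and the
repressor represses ~15-fold. These levels were fixed from the model, not
fitted: the finite library (1500 variants) sets a background-MI noise floor
proportional to the cross-variant expression variance, so the polymerase
site is kept in a moderate dynamic range while TF-site mutations still move
expression severalfold. What the generator does **not** emulate: PCR
jackpotting and amplification bias, barcode cross-talk, RNA degradation,
growth-rate selection during culturing, and epistasis — so passing
recovery tests demonstrates correctness of the analysis given the model,
not robustness to every artifact of real libraries.

## Barcode mapping

Read pairs are grouped by barcode; pairs with fewer than 3 total reads
(pre-consensus) are discarded. A per-position majority consensus of the
variant-side reads is assigned to a promoter by best wild-type match, then
to the nearest designed variant of that promoter by edit distance (edlib),
with a default cap of 20 edits (≈ expected mutations plus sequencing
errors). Consensi beyond the cap but well supported are retained as novel
variants, because synthesized pools genuinely contain synthesis errors.
Barcode counting is exact-match — no error correction, since random
20-mers at realistic depths essentially never collide within one edit.

## Footprints and expression shifts

The information footprint uses the 2×2 plug-in MI estimator (mutation
status × read class), each variant weighted by its DNA and RNA counts,
ψ = 0.5 pseudocount per cell. ψ bounds the estimator on sparse cells
without visibly biasing it at depths ≥ 10^4; it is configurable.
Positions with zero mutant mass get MI 0 and coverage 0. Replicates are
footprinted separately; a "combined" footprint is computed from summed
counts, never by averaging MI values. Expression shifts are mean
differences of log2(RNA/DNA) (library-normalized, same ψ) between variants
carrying a substitution and variants carrying the wild-type base; wild-type
cells are exactly 0 and uncovered cells NaN. Smoothing is a discrete
Gaussian with reflective boundaries (mass-conserving away from edges).

## Footprint classification

Three outcomes: `active_with_sites`, `emergent_tss_candidate`, `inactive`.

1. **Activity gate**: peak MI ≥ 2×10⁻³ bits. The threshold was calibrated
   on null (flat-expression) simulations across depths 10^4–10^6
   (`scripts/calibrate_thresholds.py`): null peaks stay below 5×10⁻⁴ bits
   at the shallowest depth while active footprints peak around 2–4×10⁻².
   A scale-free statistic cannot serve here — the coefficient of variation
   of a null footprint (≈1.4, chi-square-like noise) overlaps that of
   genuine site-block footprints (≈1.1–1.7) — so the gate is deliberately
   absolute and depth-calibrated.
2. **Spike vs block**: the footprint is smoothed (Gaussian, σ = 3 bases by
   default) and the CV recomputed. Smoothing destroys an isolated
   single-position spike but leaves a multi-base site block nearly
   untouched: a smoothed/raw CV ratio < 0.5 classifies the footprint as an
   emergent-TSS candidate, otherwise as active with sites. This decision is
   invariant to uniform rescaling of the footprint.

## Two-state HMM segmentation

Active footprints are segmented on log-transformed MI (floor 10⁻¹² before
the log) with a two-state Gaussian HMM: state 0 background, state 1 "site"
(the larger emission mean). Baum–Welch (hmmlearn) with emission means
initialized from the 25th/90th-percentile split, sticky transitions
(0.95/0.90 self-transition), tolerance 10⁻⁶, ≤500 iterations. Emission
variances are floored at 0.25 (log-MI units): binding sites of different
strength produce distinct MI plateaus, and without the floor the site state
collapses onto the strongest plateau and loses weaker sites. Degenerate
fits (state means closer than 5 % of the observation spread) fall back to
threshold segmentation at the 90th percentile, flagged as such. In the
pipeline the footprint is lightly smoothed (σ = 1.5) before segmentation,
which bridges single noisy positions inside sites. Posteriors come from
log-space forward–backward smoothing; decoding thresholds P(site) > 0.5,
merges gaps ≤ 2 bases and drops segments < 4 bases. Call signs come from
the coverage-weighted mean expression shift inside the interval (positive →
repressor-like, negative → activator-like, |mean| < 0.15 log2 units →
mixed). On the default planted suite this recovers sites at median Jaccard
≈ 0.7 with the condition-specific activator found only in its active
condition in ≈95 % of runs.

## Emergent transcription start sites

σ70 recognizes the −10 hexamer (consensus TATAAT) with positions 1, 2 and 6
dominating binding. A classified single-position spike is screened: for
each substitution with a strongly positive expression shift (> 1 log2 unit)
and each of the six hexamer frames covering the position, an event is
reported when positions 1/2/6 all match T, A, T after the mutation and did
not before. Frames truncated at the window edge are skipped. The −35
element and spacer are not modeled; the rule concerns only the −10
important triple. An exhaustive single-mutant × frame enumeration is kept
in the tests as the independent oracle.

## Replicate QC and condition clustering

Replicate agreement is the Pearson correlation of footprints across all 160
positions (concatenated across promoters for the global view). When a
condition's replicates correlate below a floor (default r = 0.3 — the
criterion by which an experiment earns a third replicate or exclusion), the
replicate that correlates worse with the ensemble of all experiments is
flagged; constant footprints are flagged degenerate.

Clustering is average-linkage on correlation distance 1 − r, per promoter
across its active conditions and globally on the condition×replicate ×
concatenated-positions matrix. Missing promoter×condition blocks are filled
with zeros — silence in a condition is signal, not missingness — with the
observation mask retained for a masking analysis. Flat clusters default to
a cut at 0.7 × the deepest merge: distinct regulatory programs still share
the polymerase-site signal (between-program r can be ≈ 0.7), so an absolute
correlation floor would lump them; the relative criterion separates
programs while keeping near-duplicates together. The clustering is
deterministic given the matrix (ties broken by row order) and invariant to
per-row affine rescaling.

## Pulldown enrichment

Per protein: log2((target + ψ)/(control + ψ)), ψ = half the smallest
nonzero abundance; the abundance percentile ranks the protein's target
abundance within the table. A call requires both log2 ratio ≥ 2 and
percentile ≥ 50 (both configurable); proteins clearing the ratio but not
the abundance floor are reported separately, since weakly abundant factors
are exactly the ones such assays fail to detect reliably. Enrichment is
deliberately a ratio + rank, not a statistical test: single
target-vs-control pulldowns carry no replicate variance to model. Scores
are antisymmetric under swapping the baits and rank-invariant under global
rescaling.

## Numerical and degenerate-input conventions

* All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; pipelines derive per-stage seeds from one run seed, and
  reruns are byte-identical.
* Zero-mutant-mass positions: MI 0, coverage 0. All-zero count tables and
  empty condition matrices raise.
* Mutation libraries at rate 0 are valid (all wild-type copies).
* Forward–backward runs entirely in log space; exact zeros in transition
  or initial probabilities are handled as −inf.
* Edit-distance alignment uses a distance cap for early termination;
  capped comparisons count as "beyond the cap".

## Problem sizes used in validation

The test-suite simulations use one promoter of 1500 variants (×160 bp) at
~3 barcodes per variant and depths 10^4–10^6, with 20–50 seeded replicates
for recovery/specificity statistics and a 2,000-protein proteome for
enrichment fixtures — sizes at which every statistic of interest is already
well resolved.

## Known limitations

* The two-state HMM models two MI levels; promoters with many sites of
  very different strengths can lose the weakest ones even with the
  variance floor.
* The activity threshold is calibrated for depths 10^4–10^6 and the 2×2
  plug-in estimator; other estimators or much shallower data need
  recalibration (script provided).
* The emergent-TSS rule is necessary-condition screening (the −10 triple
  only); it does not rank candidate promoters by predicted strength.
* The simulator's null model cannot certify behavior under artifacts it
  does not generate (jackpotting, barcode hopping, selection).
* Barcode mapping aligns consensus sequences per promoter; extremely
  similar promoters (near-identical windows) could be cross-assigned.
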
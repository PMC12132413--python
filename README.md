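# regfoot

Environment-dependent regulatory footprinting for massively parallel
reporter assays (MPRAs) in bacteria.

Bacterial promoters are regulated by transcription-factor binding sites
whose activity depends on the growth environment, and for most genes — even
in *E. coli* — those sites are unknown. A Reg-Seq-style experiment attacks
this at scale: every promoter window is randomly mutagenized, thousands of
barcoded variants are grown across many conditions, and DNA/RNA barcode
sequencing reads out each variant's expression. Positions that matter for
expression reveal themselves because mutations there shift the RNA/DNA
balance of the variants carrying them.

`regfoot` implements the computational side of that experiment end to end,
for analysts of MPRA data and for method development against simulated
ground truth:

- **Library design** — 160-bp TSS-anchored windows (−115..+45), mutated at
  0.1 per position, 1500 variants per promoter, unique randomized 20-bp
  barcodes.
- **Thermodynamic simulator** — planted regulatory architectures (an RNAP
  site plus activators/repressors with additive energy matrices, in units
  of k\_BT) drive an occupancy model of expression; DNA/RNA counts are
  drawn multinomially so every downstream stage can be validated against
  known truth.
- **Barcode pipeline** — barcode↔variant mapping from paired reads
  (pairs with fewer than 3 supporting reads are discarded; consensus
  sequences are aligned to the designed pool by edit distance, with
  well-supported synthesis errors kept as novel variants), exact-match
  barcode counting and per-variant aggregation.
- **Footprint statistics** — per-base information footprints and
  expression-shift matrices, with Gaussian smoothing.
- **Site discovery** — classification of footprints into three outcomes
  (active with sites / emergent-TSS candidate / inactive) by how the
  coefficient of variation changes upon smoothing; two-state Gaussian HMM
  segmentation of binding sites; the σ70 −10-element rule (consensus
  TATAAT, dominant positions 1, 2 and 6) for single mutations that create
  new transcription start sites.
- **Condition clustering** — replicate QC by Pearson correlation of
  footprints, and per-promoter/global hierarchical clustering (average
  linkage on 1 − r) of which environments a promoter perceives alike.
- **Pulldown enrichment** — log2 target/control scoring of DNA-affinity
  chromatography mass-spec abundance tables against a no-site control bait,
  with an abundance-percentile criterion.

## The statistics at the core

For each promoter position $i$, the **information footprint** is the mutual
information between mutation status and read class,

$$I_i = \sum_{m\in\{\mathrm{wt},\mathrm{mut}\}}\ \sum_{\mu\in\{\mathrm{DNA},\mathrm{RNA}\}} p(m,\mu)\,\log_2\frac{p(m,\mu)}{p(m)\,p(\mu)},$$

estimated from the 2×2 table of DNA/RNA counts of variants wild-type vs
mutated at $i$ (pseudocount ψ = 0.5 per cell). The **expression shift**
$\Delta(i,b)$ is the mean change in $\log_2$ expression
($\rho_v = \mathrm{RNA}_v/\mathrm{DNA}_v$, library-normalized) when base $b$
replaces the wild-type base at $i$; positive shifts inside a site mean
mutations *increase* expression (repressor-like), negative shifts mean
activator- or polymerase-like. Expression itself is modeled thermodynamically:

$$p_\mathrm{bound} = \frac{p\,\omega_\mathrm{eff}}{1 + p\,\omega_\mathrm{eff} + r},$$

with $p$ the polymerase Boltzmann weight, $r$ the summed weights of active
repressors (competitive exclusion) and $\omega_\mathrm{eff}$ the activator
stabilization factor. See `docs/methods.md` for assumptions and defaults.

## Worked example

The repository ships a demo configuration (3 synthetic promoters, 4 growth
conditions with an arabinose-specific activator, depth 10^5, 2 replicates):

```bash
regfoot run-all --config examples/demo_config.yaml --out demo_run
# pipeline complete: 13 artifacts in demo_run
```

`demo_run/site_calls.tsv` then contains rows such as

```
promoter_id  condition  replicate  start  end  start_label  end_label  mean_mi  sign            posterior
synp001      arabinose  1          41     61   -74          -55        0.0072   activator-like  0.970
synp001      arabinose  1          75     115  -40          -1         0.0078   activator-like  0.862
```

— the planted activator site (−75..−55) is called only in the arabinose
condition, alongside the constitutive polymerase site (−40..−1); `mean_mi`
is the mean mutual information (bits) inside the interval and `posterior`
the mean HMM site-state probability. In the other three conditions only the
polymerase site is called. `classification.tsv`, `footprints.tsv`,
`shifts.tsv`, `replicate_flags.tsv` and `global_clusters.tsv` carry the
remaining stages; `true_sites.tsv` holds the planted ground truth for
scoring.

Each stage is also exposed as its own subcommand (`design`, `simulate`,
`map`, `count`, `aggregate`, `footprint`, `discover`, `cluster`, `enrich`)
and as plain library functions.

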
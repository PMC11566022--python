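# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind `pislice`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Pairing geometry and the cleavage register

PIWI proteins slice their targets between the nucleotides paired to guide
positions g10 and g11 (standard Argonaute geometry), so the 5′ end of the
3′ cleavage product — the nucleotide bearing the 5′ monophosphate — pairs
g10.  `align_guide_at_site` therefore pairs guide position *k* (1-based
from the guide 5′ end) with transcript coordinate *p* + 10 − *k*
(0-based), *k* = 1…30.  Conventions:

* Sites clipped at transcript ends are evaluated with out-of-range
  positions unpaired, not rejected; positions beyond the guide's own
  length are likewise unpaired.  The guide used for pairing is the
  representative full-length member of a prefix group (the 25-nt prefix
  alone would only cover g1–g25).
* G·U wobble counts as a mismatch by default (`allow_wobble=True`
  reverses this).  The calling rules are defined on Watson–Crick pairs;
  wobble handling is exposed because the chemistry is genuinely open.
* The four abundance tiers (≥1 ppm / ≥20 nt in g2–g25; ≥5 ppm contiguous
  g3–g15; ≥10 ppm g3–g16; ≥50 ppm g4–g17) are evaluated independently
  and OR-combined.  All threshold comparisons in the package are
  inclusive, exactly as written.  Note the windows are nested: any site
  with contiguous g3–g16 pairing necessarily also satisfies the g3–g15
  rule; this nesting is intentional and kept as printed.

Duplex ΔG° annotation sums Watson–Crick nearest-neighbor stacking terms
(RNA/RNA parameters at 37 °C, Xia et al. 1998; 10 unique values bundled
as a 16-key dinucleotide table) over runs of consecutively paired guide
positions.  No initiation, terminal-AU or dangling-end terms are added:
the quantity is an annotation ordering duplexes by stability, never an
input to calling, and an empty pairing is defined as 0.

## Filters and classes

* Prefix groups are retained when ≥ 1 ppm in **every** control replicate;
  a guide is undetectable in a mutant when its **mean** mutant abundance
  is ≤ 0.1 ppm.
* Cleavage products require ≥ 0.1 ppm.  Genotype dependence supports two
  modes: `absent` (detected in control, < 0.1 ppm in every mutant
  replicate; a `strict_zero` option requires literally zero) and `fold8`
  (mean control / mean mutant ≥ 8, the mutant mean floored at a 0.01-ppm
  pseudocount — the division-by-zero convention is ours).  Presence uses
  any-replicate detection; magnitude uses means.
* High confidence = callable ∧ exclusive ∧ genotype-dependent.  Control
  targets are callable sites of non-focal, biogenesis-independent guides
  whose product is detected in both genotypes.
* Because control/mutant replicate pairing is arbitrary, target counts
  are reported as the median and IQR over all pairings (4 × 4 = 16 by
  default).
* Derepression classes are nested: any increase ⊃ significant increase
  (BH q < 0.01) ⊃ strong increase (additionally ≥ 1.5-fold).
  Translational-efficiency stage classes use ≥ 2-fold up and ≥ 1.5-fold
  down, boundaries inclusive.  The GRO-seq 1.25-fold split assigns the
  exact boundary to the ≤ 1.25 class.
* Unit conversions: molecules/cell = ppm × (piRNAs per cell, default
  10⁷) × 10⁻⁶; pM = molecules / (cell volume × N_A) × 10¹², with the
  default volume 1,800 µm³ (median primary spermatocyte).  Detectability
  is Poisson 1 − e^(−mean), with a negative-binomial option
  1 − (r/(r+mean))^r, r = 1/dispersion.

## The negative-binomial contrast

The differential test is a deliberately simple, fully specified stand-in
for a DESeq2-style analysis, so results are reproducible from this
package alone: median-of-ratios size factors; per-transcript
method-of-moments dispersion (variance model µ + αµ², floor 0.01,
pooled across the two groups); log2FC from normalized group means with a
0.5 pseudocount; delta-method Wald z with two-tailed normal p and BH
adjustment.  Divergence from shrinkage-based tools is expected: no
dispersion sharing across genes and no fold-change shrinkage.

**Normalization choice.**  When a sizeable fraction of transcripts is
derepressed in one genotype, the all-transcript median of ratios is
composition-biased (on the default synthetic study it under-estimates
target log2FC by ≈ 0.16).  The contrast therefore accepts
`size_factor_rows`: the pipeline anchors size factors on the spike-in
rows, whose molecule counts are constant across libraries by design.
Spike counts carry their own replicate noise, which leaves a small
random per-study normalization offset common to all transcripts
(≈ 0.08 log2 sd with nine spikes at the default dispersion); it averages
out across studies, which is why the acceptance script measures recovery
bias pooled over five independently generated studies.

## The synthetic world

The generator emulates the study design end to end: two genotypes
(control and a knockout of the two focal piRNA loci) × 4 replicates of
small-RNA, 5′-monophosphate (degradome), total RNA-seq (with nine
equimolar ERCC-style spike-ins), poly(A)+ RNA, ribosome-footprint and
GRO-seq (3 replicates, control) tables, plus UMI-flanked small-RNA FASTQ
with nine spike-in oligonucleotides.

* **Kinetics.**  Steady state is the first-order fixed point
  ss = k_tx/(k_dec + k_slice); the knockout removes k_slice only for
  targets planted by focal guides, so the planted fold-change is
  1 + k_slice/k_dec.  No transcriptional bursting, no delays.  Defaults:
  k_tx ∈ [5, 500] molecules/h, k_dec and k_slice ∈ [0.1, 1] h⁻¹
  (log-uniform) — chosen so steady states span ~10–5,000 molecules/cell
  and planted fold-changes span ~1.1–11×, a realistic dynamic range for
  spermatocyte transcripts.
* **piRNA abundance** is log-normal on the ppm scale (median 5 ppm,
  log-sd 1.2).  The real abundance distribution is only known to span
  roughly 0.01–10 nM, so the parameters are exposed in `SimConfig`.
  A guide chosen to plant a site is raised, if necessary, to 1.5–3× its
  tier's abundance threshold so the planted site is callable by
  construction.
* **Planted sites** are written into the transcript with exactly the
  requested tier's geometry: R1 plants 20 paired positions in g2–g25
  with contiguity deliberately broken (g12–g14 mismatched); R2/R3/R4
  plant only their contiguous window with the next window's extra
  position mismatched.  Mismatches are written as the guide base itself,
  which can never pair (nor wobble).  The generator re-scans every
  planted site and asserts its tier — the generator/verifier closure is
  enforced at build time and re-tested in the suite.
* **Degradome.**  A planted product's expected abundance is
  k_slice × ss (zero in the knockout for focal-guided sites); every
  transcript also sheds one generic decay species (∝ k_dec × ss, both
  genotypes), and ~2 background species per transcript are drawn around
  0.12 ppm (log-normal, sd 1.0) so the 0.1-ppm detection threshold is
  exercised rather than trivial.
* **Counts** are negative-binomial around depth-scaled proportions
  (dispersion 0.05 throughout, i.e. ~22% biological CV per replicate);
  GRO-seq reads are Poisson with expectation ∝ k_tx × gene-body kb.
  Read counts are proportional to molecules (not molecules × length) so
  that the spike-in regression through the origin recovers molecules per
  cell directly; TPM is computed per kb where lengths are supplied.
* **Small RNA.**  Reads ∝ molecules, with guides at ppm × 10 molecules
  per cell, nine spikes at 5,000 molecules each, and a bulk "other" bin
  filling the remainder of the 10⁷-molecule pool.  Knockout libraries
  carry zero reads for focal-locus guides and for the ~10% of non-focal
  guides flagged biogenesis-dependent (piRNAs whose production is
  initiated by focal-piRNA cleavage); the latter are excluded from the
  control-target universe.
* **Determinism.**  One `numpy` generator seeded from `SimConfig.seed`
  is consumed in a fixed order; identical configs give identical worlds
  and identical emitted files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error and adapter chemistry, genome
alignment and multi-mapping ambiguity (inputs arrive in transcript
coordinates; the `unambiguous` flag is plumbed but all simulated species
are unique), rRNA contamination, transcriptional bursting, 3′-end
trimming heterogeneity within a prefix group (each guide is a single
species), isoform structure, and any piRNA effect on translation
(deliberately absent, so the translation contrast has a true null).

## Problem sizes and statistical expectations

The default study uses 240 transcripts (0.9–2.1 kb), 8 loci × 25 guides,
60 planted focal targets and 36 control targets, RNA-seq depth 10⁶ and
degradome depth 2 × 10⁷ — sizes chosen so every pipeline stage, the
brute-force oracle comparison and the 20-simulation null calibration run
comfortably on a single CPU while keeping per-species counts deep enough
that detection thresholds, not sampling artifacts, drive the results.

Two consequences of the replicate dispersion are worth stating
explicitly.  With variance µ + αµ² (α = 0.05) and n = 4 replicates per
group, the delta-method standard error of a per-transcript log2
fold-change is √(2α/n)/ln 2 ≈ 0.23, so individual estimates scatter well
beyond ±0.25 even though their mean (the bias the acceptance script
measures) is ≈ 0; likewise single-guide ppm estimates have ~11–16%
standard error after averaging four replicates, so recovery is asserted
as unbiasedness plus a median deviation < 15%, not as a per-guide
guarantee.

## Numerical conventions and degenerate inputs

Ties for a prefix group's representative break to the lexicographically
smallest sequence.  Empty target or control sets in distribution tests
raise rather than return NaN.  Genes ≤ 500 bp are excluded from
polymerase density (the first 500 bp of every gene body are skipped to
avoid paused polymerase).  TE is undefined (and logged) for zero mRNA.
Reads shorter than 19 nt cannot contain an insert between two 9-nt UMIs
and are skipped with a logged count.  Exact-match (zero-mismatch)
assignment identifies spike-in reads.

## Limitations

The pipeline operates in transcript coordinates and delegates read
mapping entirely; rRNA filtering is reduced to an optional blocklist;
non-templated 3′ tailing is absorbed by prefix grouping rather than
modeled; the NB contrast is intentionally plain (no shrinkage, no
outlier handling); and the translation and transcription analyses take
gene-level tables as given (no P-site offsetting, no pausing-index
analysis).
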
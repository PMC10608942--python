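# Methods

## Scope and data model

`magquant` quantifies a microbial community from two count layers hanging
off one gene catalog: gene-level mapped-read counts (metagenome) and
metaprotein spectral counts (metaproteome). It deliberately begins *after*
the upstream tools — assembly, binning, gene prediction, read mapping,
database search — whose outputs are converted by the user into one
canonical TSV schema per input (tab-separated, header row, `NA`
sentinel). Parsing native featureCounts/CheckM/GTDB-Tk/Mascot formats is
out of scope.

Genes on contigs never assigned to a MAG are kept under the reserved
identifier `UNBINNED`, a first-class abundance category: all relative
abundances are fractions of the whole community, not of the binned part.

## Genomic quantification

**Annotation filter.** A KO/EC assignment is kept when alignment identity
≥ 30% *and* e-value ≤ 1e-10; the discard rule is stated with strict
"below"/"larger than" wording, so both boundaries stay on the keep side.
Filtering clears annotation fields only — genes keep their MAG membership
and read counts.

**MAG abundance.** Per sample, a MAG's abundance is the summed read count
on its genes over all mapped reads (×100); unmapped reads are excluded by
definition of the denominator. Summed read counts are the default mapping
signal; a `coverage` option (count/length sums) is provided because the
upstream mapping signal is tool-dependent and length bias cancels within
a MAG either way at the scales involved. Replicates are aggregated per
condition by the element-wise median and the column is then renormalized
to 100 — median first, so one outlier replicate cannot drag the column
total; renormalization second, so the output is always a proper
percentage profile.

**AGCN.** KO counts are divided by the KO's mean gene length, then scaled
per sample so the median over the USiCG reference equals 1. The packaged
reference is ten ribosomal-protein KOs (single copy in essentially all
prokaryotes); it is overridable by file. Only this inter-sample,
single-copy-gene scaling is implemented; learned intra-sample corrections
(per-KO regression models fitted on reference genome panels) require
trained weights and are out of scope. Samples in which every USiCG count
is zero have no copy-number scale and raise an error rather than
returning garbage.

## Proteomic quantification

Identifications sharing a peptide set are grouped into one metaprotein
(counts summed, gene set unioned); metaproteins whose gene set is not a
singleton are excluded before any normalization. The contractual order is
**group → exclude → normalize**: normalizing first would distribute the
fixed column total over rows that are later discarded, changing every
remaining value (asserted by a test).

Round 1 of total-count normalization scales each replicate column to a
fixed constant, default 78,119 spectra — a dataset-specific total kept as
a configurable default so independently normalized datasets remain
comparable. Round 2 applies the same scaling to the per-condition
replicate medians (gene level, and KO level after summing gene medians
per KO). Whether round 2 should reuse the round-1 constant is not
determined by the source material; the same constant is assumed and both
are configurable.

MAG proteomic abundance divides each MAG's summed spectra by its
completeness *fraction* (83% → /0.83), so a complete MAG is unadjusted
and an incomplete MAG is scaled up to compensate for its unassembled
genes. `UNBINNED` has no completeness estimate and is never adjusted. The
per-replicate percentage profiles are combined by median-then-renormalize
exactly as on the genomic side. Two useful invariants follow: pairwise
abundance ratios equal `(raw_i/c_i)/(raw_j/c_j)`, and scaling every
completeness by a common factor only shifts the UNBINNED share.

## Functional summaries

* **Fold changes**: `log2FC = log2((count_x + s)/(count_y + s))` with a
  positive offset `s` so zero counts stay finite; antisymmetric under
  pair swap by construction. The default s = 2 corresponds to the rounded
  30th percentile of KO-level spectral counts in the motivating dataset;
  `derive_offset` recomputes it from data using the linear-interpolation
  percentile and half-up rounding with a floor of 1. Neither the
  percentile convention nor the count universe (zeros in or out) is fixed
  by the source material, so both are explicit options (`universe ∈
  {all, nonzero}`), defaulting to linear interpolation over all counts.
* **Modules**: a KEGG module is an ordered list of blocks, each a set of
  alternative KO sets (`K1,K2 K3+K4`: two blocks, the second a two-KO
  complex). A block is satisfied when any alternative is fully present; a
  module is retained when at most one block is missing. The grammar
  covers exactly this logic; parenthesised subexpressions and
  minus-prefixed optional KOs are rejected with a clear error (documented
  limitation — modules using them must be pre-flattened). Module activity
  is the MAG's module-member spectra over its total spectra, 0 with a
  warning for a MAG with no spectra.
* **Key enzymes**: a packaged, user-editable table maps KOs to enzymes
  and anaerobic-digestion categories. AGCNs are summed over
  similar-function KOs and medianed over subunit KOs (a complex's copy
  number is not the sum of its subunit counts); spectral counts are
  always summed. Display filtering keeps enzymes reaching ≥ 10 spectra
  (inclusive) in at least one condition. Pathway presence is spectral
  count > 0 for at least one member KO — the most permissive reading,
  since no stricter threshold is specified.
* **HQ MAGs**: completeness > 50, contamination < 10, and > 0.5% relative
  abundance in either layer in at least one condition — all strict
  inequalities, following "above/below" wording. The category summary
  partitions 100% of each column into unbinned+low-quality, HQ below the
  abundance threshold, and HQ above it; quality and abundance splits use
  the same thresholds.
* **Metadata correlations**: plain Pearson r per (taxon, parameter), with
  per-condition metadata expanded to replicate samples via the condition
  map. Constant vectors give undefined r, reported as NaN with a warning
  — never coerced to 0.

## Synthetic communities

The generator emulates the study design the pipeline targets: 3
conditions × 3 replicates, log-normal MAG abundances (σ = 1.5 — strongly
uneven communities, as in digesters), a 20% unbinned fraction, an 11–18%
unmapped fraction, 200,000 mapped reads per metagenome sample. Read
counts are Poisson around abundance × gene length; spectral counts are
gamma–Poisson (negative binomial, variance μ + αμ², default α = 0.3;
α = 0 degenerates to exact Poisson) around abundance × a per-MAG activity
multiplier drawn log-uniformly from [0.5, 5]. One MAG defaults to a 20×
"hyperactive" multiplier, emulating methanogenic archaea whose proteomic
abundance far exceeds their genomic abundance; it is an ordinary
multiplier, not a special code path. Spectra default to 20,000 per
replicate — the analysis depends only on relative counts, so the total
merely sets the noise level.

Each genome carries the ten USiCG KOs exactly once, a planted two-copy
control KO (copy-number ground truth for AGCN checks), and 40 accessory
genes drawn from a 150-KO pool, of which 20% are unannotated and 5% carry
deliberately weak annotations that the 30%/1e-10 filter must remove.
Incompleteness withholds a uniform random gene subset matching the stated
completeness. All copies of a given KO share one gene length across
genomes (drawn once per KO, log-normal with median 900 bp): orthologues
have similar lengths in reality, and this choice makes length-normalized
KO counts recover copy number exactly in expectation instead of adding
MAG-lottery noise through independent per-copy lengths.

What the generator does **not** emulate: sequence-level artifacts
(chimeric contigs, mis-binning, multi-mapping reads), shared KOs causing
cross-MAG protein misassignment beyond the explicit non-unique
metaprotein fraction, compositional correlations between conditions, and
contamination's effect on counts (the contamination column is metadata
only). Passing tests therefore demonstrate the *arithmetic contracts* of
the pipeline and its statistical recovery under clean sampling noise, not
robustness to upstream artifacts in real data.

## Numerical conventions

* Abundance columns sum to 100 within 1e-9; round-1 spectral columns to
  the constant within 1e-6; the category summary within 0.01 (absorbs
  category rounding).
* Zero-signal degenerate inputs (a sample with no mapped reads, a column
  with no spectra, all-zero USiCGs, zero completeness) are hard errors
  naming the offender; an all-non-unique spectral table is a warning and
  an empty result, since downstream code can meaningfully continue.
* Determinism: one integer seed drives independent per-stage RNG streams
  (catalog, reads, spectra), so regenerating one layer never perturbs
  another; fixed seed gives bit-identical tables.
* Problem sizes in the test suite and acceptance script (communities of
  2–20 MAGs, 3,000–200,000 reads per sample) are chosen so ground-truth
  recovery is statistically comfortable at desk scale while the whole
  suite runs in seconds.

## Known limitations

* The module grammar rejects nested/optional KEGG expressions.
* AGCN lacks intra-sample (per-KO bias) correction.
* The proteomic layer assumes spectral counts are comparable across
  replicates after total-count scaling; no peptide-level normalization.
* `UNBINNED` aggregates all unbinned contigs as one pseudo-organism; its
  "abundance" is a bookkeeping share, not an organism's.
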
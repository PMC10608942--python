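# magquant

MAG-centric quantification of metagenome and metaproteome count data for
microbial communities, built around the anaerobic-digestion (biogas) use
case: three differently operated digesters sampled in triplicate, with
gene-level mapped-read counts on one side and metaprotein spectral counts
on the other.

`magquant` starts where the upstream tools stop — after assembly, binning,
gene prediction, read mapping and protein identification — and answers the
quantitative questions: *how abundant is each metagenome-assembled genome
(MAG), how active is it at the protein level, and which metabolic functions
does it actually express?*

## What it computes

**Genomic MAG abundance.** For sample *s* and MAG *m* with gene set
*G(m)*,

```
a_s(m) = 100 · Σ_{g∈G(m)} reads_s(g) / Σ_{g} reads_s(g)
```

Unmapped reads are excluded; genes on unbinned contigs form a first-class
`UNBINNED` row, so abundances are fractions of the whole community.
Replicates are combined per condition by the element-wise median, then the
column is renormalized to 100%.

**Proteomic MAG abundance with completeness adjustment.** Metaproteins
(protein groups sharing a peptide set) that map to exactly one gene are
kept; each sample is total-count normalized to a fixed constant (default
78,119 spectra). A MAG's raw spectral sum is divided by its completeness
fraction *c(m)* ∈ (0,1] so incomplete MAGs are not underrepresented:

```
p(m) ∝ Σ_{g∈G(m)} spectra(g) / c(m)
```

with `UNBINNED` never adjusted, then MAGs + UNBINNED are renormalized to
100% (median over replicates, as above).

**Average genomic copy number (AGCN).** KO-level read counts are length-
normalized and scaled per sample so the median over a universal
single-copy gene (USiCG) reference — ten ribosomal-protein KOs, packaged
— equals 1. AGCN(k) = 2 means KO *k* occurs, on average, twice per genome
in the community.

**Functional summaries.** KO-level log2 fold changes
`log2((count_x + s)/(count_y + s))` with a pseudo-count offset (default
s = 2, or derived as the rounded 30th percentile of the counts);
KEGG-module completeness per MAG (a module is retained when it is
complete or missing one block) and module activity (module spectra over
total MAG spectra); key-enzyme profiles of the anaerobic-digestion chain
(hydrolysis → acidogenesis → acetogenesis → methanogenesis) aggregating
subunit KOs by median AGCN and similar-function KOs by sum, spectra
always summed; high-quality MAG filtering (>50% completeness, <10%
contamination, >0.5% abundance in either layer); Table-style community
category summaries; and Pearson correlations of taxon abundances with
process metadata (temperature, OLR, HRT, feed composition).

**Synthetic communities.** Because the real inputs are terabyte-scale
sequencing and MS archives, `magquant.simulate` generates communities
with known ground truth — log-normal MAG abundances, Poisson read counts
proportional to abundance × gene length, negative-binomial spectral
counts modulated by per-MAG activity multipliers, incomplete MAGs,
non-unique metaproteins — so every stage is testable offline.

## Worked example

```python
from magquant import genomic, proteomic
from magquant.simulate import (CommunitySpec, generate_community,
                               simulate_read_counts, simulate_spectral_counts)

spec = CommunitySpec(n_mags=5, rng_seed=11)
catalog, mags, truth = generate_community(spec)
reads = simulate_read_counts(catalog, truth, spec)
spectra = simulate_spectral_counts(catalog, truth, spec)

catalog = genomic.filter_annotations(catalog)           # 30% identity, 1e-10
gen = genomic.mag_relative_abundance(reads, catalog, mags)
print(gen.round(2))
```

```
condition_id     D1     D2     D3
mag_id
MAG_001       17.31   2.91  19.69
MAG_002       20.18  21.35  26.61
MAG_003       19.55   8.96  12.30
MAG_004       11.71  33.15  12.49
MAG_005       11.29  13.65   8.88
UNBINNED      19.97  19.97  20.02
```

The recovered genomic profile tracks the true abundances (e.g. MAG_001
truth: 17.27 / 2.88 / 19.66%) and the unbinned fraction (20%). The
proteomic side tells a different story:

```python
gene_r1 = proteomic.total_count_normalize(proteomic.exclude_nonunique(spectra))
prot = proteomic.mag_proteomic_abundance(gene_r1, catalog, mags,
                                         reads.samples.condition_map)
print(prot.round(2))
```

```
condition_id     D1     D2     D3
mag_id
MAG_001       78.00  30.85  79.89
MAG_002        8.14  16.88   8.69
MAG_003        3.60   4.37   2.23
MAG_004        4.89  32.86   4.70
MAG_005        2.48   7.59   1.81
UNBINNED       2.89   7.46   2.69
```

MAG_001 carries a 20× activity multiplier (the generator's hyperactive
"methanogen archaeon"): ~17% of the genomes but ~78% of the expressed
protein — the genomically-rare-but-proteomically-dominant pattern typical
of methanogens in digesters.

## Command line

```
magquant simulate --spec spec.yaml --seed 3 --out fixtures/
magquant genomic  --catalog gene_catalog.tsv --counts read_counts.tsv \
                  --unmapped unmapped.tsv --mags mag_quality.tsv --out profile.tsv
magquant proteomic --spectra spectral_counts.tsv --catalog gene_catalog.tsv \
                   --mags mag_quality.tsv --unmapped unmapped.tsv \
                   --constant 78119 --out profile.tsv
magquant run --config demo.yaml          # simulate → genomic → proteomic → summarize
```

All inputs are UTF-8 TSVs with a header row and `NA` for missing values;
see the docstrings in `magquant.io` for the column schemas.

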
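"""Synthetic community generator.

Emulates the statistical structure of a MAG-centric multi-omics study of
a full-scale biogas plant — three differently operated digesters sampled
in triplicate — starting at the pipeline's true inputs: count tables.  No
sequences, reads or spectra are simulated.

What the generator produces:

* log-normally distributed true MAG abundances per condition, with an
  unbinned contig fraction carrying part of the community;
* gene-level mapped-read counts proportional to abundance × gene length
  with Poisson noise, plus a per-sample unmapped-read count whose
  fraction falls in a configurable range (default 11–18%);
* gene-level spectral counts proportional to abundance × a per-MAG
  activity multiplier, drawn from a negative binomial (over-dispersion is
  the norm in spectral counting); hyperactive members (e.g. methanogenic
  archaea with high proteomic but low genomic abundance) are plain large
  activity multipliers, not a special case;
* incomplete MAGs realised by withholding a random gene subset consistent
  with the stated completeness;
* a universal single-copy KO set carried exactly once per complete
  genome, plus optional planted multi-copy KOs, giving the copy-number
  ground truth for AGCN checks.

All copies of a given KO share one gene length across genomes
(orthologues have similar lengths), so length-normalized KO counts
recover genomic copy number exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genomic import default_usicg_set
from .model import (
    GENE_COLUMNS,
    UNBINNED,
    GeneCatalog,
    MagTable,
    ReadCountTable,
    SampleInfo,
    SpectralCountTable,
    ValidationError,
)


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community.

    Defaults mirror a three-digester, triplicate study design with
    200,000 mapped reads per metagenome sample and an 11–18% unmapped
    fraction.
    """

    n_mags: int = 20
    n_conditions: int = 3
    n_replicates: int = 3
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.5
    unbinned_fraction: float = 0.2
    unmapped_fraction_range: tuple[float, float] = (0.11, 0.18)
    mean_reads_per_sample: int = 200_000
    mean_spectra_per_sample: int = 20_000
    activity_multiplier_range: tuple[float, float] = (0.5, 5.0)
    n_hyperactive: int = 1
    hyperactive_multiplier: float = 20.0
    completeness_range: tuple[float, float] = (60.0, 100.0)
    genes_per_mag: int = 40
    n_unbinned_genes: int = 100
    ko_pool_size: int = 150
    frac_unannotated: float = 0.2
    frac_weak_annotation: float = 0.05
    planted_kos: Mapping[str, int] = field(
        default_factory=lambda: {"K_PLANTED_2COPY": 2}
    )
    nb_dispersion: float = 0.3
    nonunique_fraction: float = 0.1
    gene_length_median_bp: float = 900.0
    gene_length_sigma: float = 0.45
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mags < 1:
            raise ValidationError("n_mags must be at least 1")
        if self.n_conditions < 1 or self.n_replicates < 1:
            raise ValidationError("need at least one condition and one replicate")
        if not 0 <= self.unbinned_fraction < 1:
            raise ValidationError("unbinned_fraction must lie in [0, 1)")
        lo, hi = self.unmapped_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValidationError("unmapped_fraction_range must lie within [0, 1)")
        clo, chi = self.completeness_range
        if not (0 < clo <= chi <= 100):
            raise ValidationError("completeness_range must lie within (0, 100]")
        alo, ahi = self.activity_multiplier_range
        if not (0 < alo <= ahi):
            raise ValidationError("activity_multiplier_range must be positive")
        if self.mean_reads_per_sample < 1:
            raise ValidationError("mean_reads_per_sample must be positive")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be non-negative")
        if not 0 <= self.nonunique_fraction <= 1:
            raise ValidationError("nonunique_fraction must lie in [0, 1]")

    @property
    def conditions(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_conditions)]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{c}_r{r + 1}" for c in self.conditions for r in range(self.n_replicates)
        ]

    def condition_of_sample(self) -> pd.Series:
        return pd.Series(
            {s: s.split("_r")[0] for s in self.sample_ids}, name="condition_id"
        )


@dataclass
class GroundTruth:
    """True parameters behind a synthetic community."""

    abundance: pd.DataFrame  # (mag + UNBINNED) × condition, columns sum to 1
    activity: pd.Series  # per-MAG activity multiplier (UNBINNED = 1)
    completeness: pd.Series  # per-MAG completeness actually drawn (%)
    ko_copies: pd.Series  # KO → copies per complete genome (USiCGs + planted)


def _draw_abundances(spec: CommunitySpec, rng: np.random.Generator, mag_ids) -> pd.DataFrame:
    cols = {}
    for cond in spec.conditions:
        raw = rng.lognormal(
            spec.abundance_lognormal_mu, spec.abundance_lognormal_sigma, spec.n_mags
        )
        share = raw / raw.sum() * (1.0 - spec.unbinned_fraction)
        cols[cond] = np.append(share, spec.unbinned_fraction)
    return pd.DataFrame(cols, index=list(mag_ids) + [UNBINNED])


def generate_community(spec: CommunitySpec) -> tuple[GeneCatalog, MagTable, GroundTruth]:
    """Build a gene catalog, MAG quality table and ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    mag_ids = [f"MAG_{i + 1:03d}" for i in range(spec.n_mags)]

    usicg = sorted(default_usicg_set())
    pool = [f"K{90000 + i:05d}" for i in range(spec.ko_pool_size)]
    special = usicg + sorted(spec.planted_kos)
    # one length per KO, shared by every copy in every genome
    ko_lengths = pd.Series(
        np.round(
            rng.lognormal(np.log(spec.gene_length_median_bp), spec.gene_length_sigma, len(pool) + len(special))
        ).clip(min=100),
        index=special + pool,
    ).astype(int)

    abundance = _draw_abundances(spec, rng, mag_ids)
    activity = pd.Series(
        np.exp(
            rng.uniform(
                np.log(spec.activity_multiplier_range[0]),
                np.log(spec.activity_multiplier_range[1]),
                spec.n_mags,
            )
        ),
        index=mag_ids,
    )
    hyper = mag_ids[: min(spec.n_hyperactive, spec.n_mags)]
    activity.loc[hyper] = spec.hyperactive_multiplier
    activity[UNBINNED] = 1.0

    completeness = pd.Series(
        rng.uniform(*spec.completeness_range, spec.n_mags), index=mag_ids
    )

    rows: list[dict] = []
    genome_sizes = {}
    for mag in mag_ids:
        mag_rows: list[dict] = []
        core = usicg + [k for k, c in sorted(spec.planted_kos.items()) for _ in range(c)]
        accessory = list(rng.choice(pool, size=spec.genes_per_mag, replace=True))
        for j, ko in enumerate(core + accessory):
            unannot = j >= len(core) and rng.random() < spec.frac_unannotated
            weak = (not unannot) and j >= len(core) and rng.random() < spec.frac_weak_annotation
            if unannot:
                ko_id, ident, ev = np.nan, np.nan, np.nan
                length = int(np.round(rng.lognormal(np.log(spec.gene_length_median_bp), spec.gene_length_sigma)).clip(min=100))
            else:
                ko_id = ko
                length = int(ko_lengths[ko])
                if weak:
                    # fails the 30% / 1e-10 annotation filter
                    ident, ev = float(rng.uniform(5, 29)), 1e-5
                else:
                    ident, ev = float(rng.uniform(60, 100)), float(10 ** rng.uniform(-60, -12))
            mag_rows.append(
                {
                    "gene_id": f"{mag}_g{j + 1:04d}",
                    "contig_id": f"{mag}_c{j // 5 + 1:03d}",
                    "mag_id": mag,
                    "length_bp": length,
                    "ko_id": ko_id,
                    "ec_ids": (),
                    "annot_identity_pct": ident,
                    "annot_evalue": ev,
                }
            )
        genome_sizes[mag] = int(sum(r["length_bp"] for r in mag_rows))
        # withhold genes to realize the stated completeness
        n_drop = int(np.floor(len(mag_rows) * (1.0 - completeness[mag] / 100.0)))
        if n_drop:
            drop = set(rng.choice(len(mag_rows), size=n_drop, replace=False))
            mag_rows = [r for i, r in enumerate(mag_rows) if i not in drop]
        rows.extend(mag_rows)

    for j in range(spec.n_unbinned_genes):
        annotated = rng.random() < 0.5
        ko = str(rng.choice(pool)) if annotated else np.nan
        length = (
            int(ko_lengths[ko])
            if annotated
            else int(np.round(rng.lognormal(np.log(spec.gene_length_median_bp), spec.gene_length_sigma)).clip(min=100))
        )
        rows.append(
            {
                "gene_id": f"UNB_g{j + 1:04d}",
                "contig_id": f"UNB_c{j // 5 + 1:03d}",
                "mag_id": UNBINNED,
                "length_bp": length,
                "ko_id": ko,
                "ec_ids": (),
                "annot_identity_pct": float(rng.uniform(60, 100)) if annotated else np.nan,
                "annot_evalue": float(10 ** rng.uniform(-60, -12)) if annotated else np.nan,
            }
        )
    if spec.unbinned_fraction == 0:
        rows = [r for r in rows if r["mag_id"] != UNBINNED]

    genes = pd.DataFrame(rows).set_index("gene_id")
    catalog = GeneCatalog(genes[GENE_COLUMNS[1:]])

    mags = pd.DataFrame(
        {
            "completeness_pct": completeness.round(2),
            "contamination_pct": rng.uniform(0, 8, spec.n_mags).round(2),
            "taxonomy": [
                (
                    "d__Archaea;p__Halobacteriota;c__Methanosarcinia;o__Methanosarcinales;"
                    f"f__Methanosarcinaceae;g__Methanosarcina;s__synthetic_{m}"
                    if m in hyper
                    else "d__Bacteria;p__Bacillota;c__Clostridia;o__Oscillospirales;"
                    f"f__Ruminococcaceae;g__Synthetica;s__synthetic_{m}"
                )
                for m in mag_ids
            ],
            "genome_size_bp": pd.Series(genome_sizes),
        },
        index=pd.Index(mag_ids, name="mag_id"),
    )
    ko_copies = pd.Series(
        {**{k: 1 for k in usicg}, **dict(spec.planted_kos)}, name="copies"
    )
    truth = GroundTruth(abundance, activity, completeness, ko_copies)
    return catalog, MagTable(mags), truth


def _gene_weights(
    catalog: GeneCatalog, weight_of_mag: pd.Series, per_gene: pd.Series
) -> pd.Series:
    """Unnormalized per-gene expectation: MAG weight × per-gene share."""
    mag_of = catalog.genes["mag_id"]
    return mag_of.map(weight_of_mag).astype(float) * per_gene


def simulate_read_counts(
    catalog: GeneCatalog, truth: GroundTruth, spec: CommunitySpec
) -> ReadCountTable:
    """Gene × sample mapped-read counts with Poisson noise.

    A gene's expected count is ``reads × abundance(mag, condition) ×
    length / total cataloged length of the mag``, so a MAG's mapped-read
    share matches its true abundance.  The per-sample unmapped count is
    drawn so the unmapped fraction falls in the configured range.
    """
    rng = np.random.default_rng(_stage_seed(spec.rng_seed, 1))
    lengths = catalog.genes["length_bp"].astype(float)
    mag_of = catalog.genes["mag_id"]
    mag_len = lengths.groupby(mag_of).sum()
    frac_in_mag = lengths / mag_of.map(mag_len)

    cond_of = spec.condition_of_sample()
    counts = {}
    unmapped = {}
    for sample in spec.sample_ids:
        cond = cond_of[sample]
        abund = truth.abundance[cond].reindex(mag_of.unique(), fill_value=0.0)
        mu = spec.mean_reads_per_sample * _gene_weights(catalog, abund, frac_in_mag)
        counts[sample] = rng.poisson(mu.to_numpy())
        u = rng.uniform(*spec.unmapped_fraction_range)
        mapped = int(counts[sample].sum())
        unmapped[sample] = int(round(mapped * u / (1.0 - u)))
    df = pd.DataFrame(counts, index=catalog.gene_ids)
    samples = pd.DataFrame(
        {
            "condition_id": cond_of,
            "replicate": [int(s.split("_r")[1]) for s in spec.sample_ids],
            "unmapped_reads": pd.Series(unmapped),
        }
    )
    samples.index.name = "sample_id"
    return ReadCountTable(df, SampleInfo(samples))


def simulate_spectral_counts(
    catalog: GeneCatalog, truth: GroundTruth, spec: CommunitySpec
) -> SpectralCountTable:
    """Metaprotein × replicate spectral counts.

    A gene's expected spectral count is proportional to its MAG's
    abundance × activity multiplier, shared evenly over the MAG's
    cataloged genes, and drawn from a gamma–Poisson (negative binomial)
    mixture with dispersion ``nb_dispersion`` (variance μ + αμ²; α = 0
    degenerates to Poisson).  A configurable fraction of metaproteins is
    assigned non-uniquely to two genes, exercising the uniqueness
    exclusion downstream.
    """
    rng = np.random.default_rng(_stage_seed(spec.rng_seed, 2))
    mag_of = catalog.genes["mag_id"]
    genes_in_mag = mag_of.groupby(mag_of).size()
    per_gene = 1.0 / mag_of.map(genes_in_mag).astype(float)

    cond_of = spec.condition_of_sample()
    counts = {}
    for sample in spec.sample_ids:
        cond = cond_of[sample]
        weight = truth.abundance[cond] * truth.activity
        w = _gene_weights(catalog, weight, per_gene)
        mu = (spec.mean_spectra_per_sample * w / w.sum()).to_numpy()
        if spec.nb_dispersion > 0:
            lam = rng.gamma(1.0 / spec.nb_dispersion, mu * spec.nb_dispersion)
        else:
            lam = mu
        counts[sample] = rng.poisson(lam)
    gene_ids = list(catalog.gene_ids)
    df = pd.DataFrame(counts, index=pd.Index([f"MP_{g}" for g in gene_ids], name="metaprotein_id"))
    df = df.astype(float)

    gene_sets = {f"MP_{g}": frozenset({g}) for g in gene_ids}
    n_nonunique = int(np.floor(spec.nonunique_fraction * len(gene_ids)))
    if n_nonunique and len(gene_ids) > 1:
        chosen = rng.choice(len(gene_ids), size=n_nonunique, replace=False)
        for idx in chosen:
            partner = int(rng.integers(len(gene_ids) - 1))
            if partner >= idx:
                partner += 1
            g = gene_ids[idx]
            gene_sets[f"MP_{g}"] = frozenset({g, gene_ids[partner]})
    peptide_sets = {f"MP_{g}": f"pep_{g}" for g in gene_ids}
    return SpectralCountTable(df, gene_sets, peptide_sets)


def _stage_seed(seed: int, stage: int) -> int:
    """Independent per-stage streams from one user seed (kept below 2^31)."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31 - 1))


__all__ = [
    "CommunitySpec",
    "GroundTruth",
    "generate_community",
    "simulate_read_counts",
    "simulate_spectral_counts",
]
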
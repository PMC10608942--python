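"""Domain types shared by all pipeline stages.

The pipeline quantifies a microbial community from two count layers that
both hang off one gene catalog:

* metagenome — reads mapped onto predicted genes, aggregated to
  metagenome-assembled genomes (MAGs) and KEGG orthologies (KOs);
* metaproteome — MS/MS spectral counts assigned to genes via identified
  metaproteins.

Genes on contigs that were never binned into a MAG are kept as a
first-class abundance category under the reserved MAG identifier
:data:`UNBINNED`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved mag_id for genes on contigs not assigned to any MAG.
UNBINNED = "UNBINNED"


class ValidationError(ValueError):
    """Raised when an input table violates a schema invariant."""


# ---------------------------------------------------------------------------
# gene catalog / MAG quality
# ---------------------------------------------------------------------------

GENE_COLUMNS = [
    "gene_id",
    "contig_id",
    "mag_id",
    "length_bp",
    "ko_id",
    "ec_ids",
    "annot_identity_pct",
    "annot_evalue",
]


@dataclass
class GeneCatalog:
    """Gene → contig → MAG membership with optional functional annotation.

    ``genes`` is indexed by ``gene_id`` and carries the remaining
    :data:`GENE_COLUMNS`.  ``ko_id`` is NaN when the gene is unannotated
    (or its annotation was discarded); ``ec_ids`` is a tuple of EC number
    strings, possibly empty.
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        validate_gene_catalog(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def genes_of_mag(self, mag_id: str) -> pd.Index:
        return self.genes.index[self.genes["mag_id"] == mag_id]

    def mag_of_gene(self) -> pd.Series:
        """gene_id → mag_id mapping (UNBINNED included)."""
        return self.genes["mag_id"]

    def ko_of_gene(self) -> pd.Series:
        """gene_id → ko_id for annotated genes only."""
        ko = self.genes["ko_id"]
        return ko[ko.notna()]

    @property
    def mag_ids(self) -> list[str]:
        """MAG identifiers referenced by the catalog, UNBINNED excluded."""
        ids = self.genes["mag_id"].unique().tolist()
        return sorted(m for m in ids if m != UNBINNED)

    def kos_of_mag(self, mag_id: str) -> set[str]:
        sub = self.genes.loc[self.genes["mag_id"] == mag_id, "ko_id"]
        return set(sub.dropna())


def validate_gene_catalog(genes: pd.DataFrame) -> None:
    if genes.index.name != "gene_id":
        raise ValidationError("gene table must be indexed by gene_id")
    if len(genes) == 0:
        raise ValidationError("no records in gene catalog")
    dup = genes.index[genes.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate gene_id values: {', '.join(map(str, dup))}")
    bad_len = genes.index[genes["length_bp"] < 1].tolist()
    if bad_len:
        raise ValidationError(f"length_bp < 1 for genes: {', '.join(map(str, bad_len))}")
    ident = genes["annot_identity_pct"].dropna()
    if ((ident < 0) | (ident > 100)).any():
        raise ValidationError("annot_identity_pct outside [0, 100]")
    ev = genes["annot_evalue"].dropna()
    if (ev < 0).any():
        raise ValidationError("annot_evalue must be non-negative")


@dataclass
class MagTable:
    """Per-MAG quality estimates and taxonomy.

    ``mags`` is indexed by ``mag_id`` with columns ``completeness_pct``,
    ``contamination_pct``, ``taxonomy`` and (synthetic fixtures only)
    ``genome_size_bp``.
    """

    mags: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.mags
        if m.index.name != "mag_id":
            raise ValidationError("MAG table must be indexed by mag_id")
        dup = m.index[m.index.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate mag_id values: {', '.join(map(str, dup))}")
        if (m["completeness_pct"] <= 0).any() or (m["completeness_pct"] > 100).any():
            raise ValidationError("completeness_pct must lie in (0, 100]")
        if (m["contamination_pct"] < 0).any() or (m["contamination_pct"] >= 100).any():
            raise ValidationError("contamination_pct must lie in [0, 100)")

    def __len__(self) -> int:
        return len(self.mags)

    @property
    def mag_ids(self) -> pd.Index:
        return self.mags.index

    def completeness(self, mag_id: str) -> float:
        return float(self.mags.at[mag_id, "completeness_pct"])


def check_catalog_mags(catalog: GeneCatalog, mags: MagTable) -> None:
    """Every non-UNBINNED mag_id in the catalog must exist in the MAG table."""
    referenced = set(catalog.genes["mag_id"]) - {UNBINNED}
    unknown = sorted(referenced - set(mags.mag_ids))
    if unknown:
        raise ValidationError(f"unknown mag_id values in gene catalog: {', '.join(unknown)}")


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

@dataclass
class SampleInfo:
    """Per-sample metadata: condition (digester), replicate, unmapped reads.

    ``table`` is indexed by ``sample_id`` with columns ``condition_id``,
    ``replicate`` and ``unmapped_reads``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "sample_id":
            raise ValidationError("sample table must be indexed by sample_id")
        if t.index.duplicated().any():
            raise ValidationError("duplicate sample_id values")
        if (t["unmapped_reads"] < 0).any():
            raise ValidationError("unmapped_reads must be non-negative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def condition_map(self) -> pd.Series:
        """sample_id → condition_id."""
        return self.table["condition_id"]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.table["condition_id"]:
            if c not in seen:
                seen.append(c)
        return seen

    def unmapped(self, sample_id: str) -> int:
        return int(self.table.at[sample_id, "unmapped_reads"])


@dataclass
class ReadCountTable:
    """Mapped-read counts per gene and sample, plus sample metadata."""

    counts: pd.DataFrame  # gene_id × sample_id, non-negative integers
    samples: SampleInfo

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("read counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in set(self.samples.sample_ids)]
        if missing:
            raise ValidationError(
                f"samples missing from the condition map: {', '.join(map(str, missing))}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class SpectralCountTable:
    """Spectral counts per metaprotein and replicate sample.

    ``counts`` is indexed by ``metaprotein_id``; ``gene_sets`` maps each
    metaprotein to its (non-empty) set of candidate genes, and
    ``peptide_sets`` to the peptide-set identifier that defined the group.
    """

    counts: pd.DataFrame  # metaprotein_id × sample_id, non-negative reals
    gene_sets: Mapping[str, frozenset[str]]
    peptide_sets: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("spectral counts must be non-negative")
        for mp in self.counts.index:
            gs = self.gene_sets.get(mp)
            if not gs:
                raise ValidationError(f"metaprotein {mp} has an empty gene set")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def is_unique(self) -> pd.Series:
        """Per metaprotein: does its gene set contain exactly one gene?"""
        return pd.Series(
            {mp: len(self.gene_sets[mp]) == 1 for mp in self.counts.index},
            name="unique",
        )


# ---------------------------------------------------------------------------
# KEGG modules, key enzymes, process metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModuleDefinition:
    """A KEGG module as an ordered list of blocks.

    Each block is a tuple of alternative KO sets; the block is satisfied
    when any single alternative is fully present.  A plus-joined complex
    (K1+K2) is one alternative requiring both KOs.
    """

    module_id: str
    blocks: tuple[tuple[frozenset[str], ...], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError(f"module {self.module_id} has zero blocks")
        for block in self.blocks:
            if not block or any(len(alt) == 0 for alt in block):
                raise ValidationError(f"module {self.module_id} has an empty alternative")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def all_kos(self) -> frozenset[str]:
        return frozenset(k for block in self.blocks for alt in block for k in alt)


#: Anaerobic-digestion process-chain categories (after Sikora et al.).
AD_CATEGORIES = (
    "hydrolysis",
    "acidogenesis",
    "acetogenesis",
    "hydrogenotrophic_methanogenesis",
    "acetoclastic_methanogenesis",
    "methylotrophic_methanogenesis",
)

AGG_SUM = "sum_similar"
AGG_MEDIAN = "median_subunits"


@dataclass(frozen=True)
class KeyEnzymeGroup:
    """One biogas-process key enzyme and the KOs it aggregates.

    ``aggregation_mode`` controls how member-KO average genomic copy
    numbers are combined: ``sum_similar`` for KOs with similar function,
    ``median_subunits`` for KOs that are subunits of one complex.
    Spectral counts are always summed.
    """

    enzyme_label: str
    ko_ids: tuple[str, ...]
    aggregation_mode: str
    ad_category: str

    def __post_init__(self) -> None:
        if not self.ko_ids:
            raise ValidationError(f"key enzyme {self.enzyme_label} has no KOs")
        if self.aggregation_mode not in (AGG_SUM, AGG_MEDIAN):
            raise ValidationError(
                f"unknown aggregation mode {self.aggregation_mode!r} "
                f"for enzyme {self.enzyme_label}"
            )


@dataclass
class ProcessMetadata:
    """Numeric process parameters per condition (temperature, OLR, HRT, ...).

    ``table`` is indexed by ``condition_id``; every column is a numeric
    parameter shared by all conditions.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.name != "condition_id":
            raise ValidationError("process metadata must be indexed by condition_id")

    @property
    def parameters(self) -> pd.Index:
        return self.table.columns


__all__ = [
    "UNBINNED",
    "ValidationError",
    "GENE_COLUMNS",
    "GeneCatalog",
    "MagTable",
    "check_catalog_mags",
    "SampleInfo",
    "ReadCountTable",
    "SpectralCountTable",
    "ModuleDefinition",
    "KeyEnzymeGroup",
    "ProcessMetadata",
    "AD_CATEGORIES",
    "AGG_SUM",
    "AGG_MEDIAN",
]
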
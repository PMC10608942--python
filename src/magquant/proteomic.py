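"""Metaproteome-side quantification.

Protein identifications are grouped into metaproteins by shared peptide
set, metaproteins that cannot be assigned to exactly one gene are
excluded, and the remaining gene-level spectral counts undergo two rounds
of total-count normalization: round 1 scales every replicate column to a
common total (default 78,119 spectra, the dataset-specific constant of
the reference study, configurable), round 2 re-scales the per-condition
replicate medians.  MAG-level proteomic abundance divides each MAG's
summed spectra by its completeness fraction so incomplete MAGs are not
underrepresented, and renormalizes MAGs + unbinned to 100%.

The contractual operation order is group → exclude → normalize; the
normalization constant is redistributed over a different row universe if
non-unique metaproteins are removed afterwards, so the order matters.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    UNBINNED,
    GeneCatalog,
    MagTable,
    SpectralCountTable,
    ValidationError,
    check_catalog_mags,
)
from .genomic import median_then_renormalize

#: Default total-count normalization target (sum of spectral counts per sample).
NORMALIZATION_CONSTANT = 78_119.0


def group_metaproteins(identifications: pd.DataFrame) -> SpectralCountTable:
    """Group redundant protein identifications into metaproteins.

    ``identifications`` has columns ``protein_id``, ``peptide_set_id``,
    ``gene_id`` plus one numeric column per replicate sample.
    Identifications sharing a peptide set are homologous and merged into
    one metaprotein: spectral counts are summed and the gene set is the
    union (a multi-gene set marks the metaprotein as non-unique).
    """
    meta = ["protein_id", "peptide_set_id", "gene_id"]
    sample_cols = [c for c in identifications.columns if c not in meta]
    grouped = identifications.groupby("peptide_set_id", sort=False)
    counts = grouped[sample_cols].sum()
    gene_sets = {
        pep: frozenset(sub["gene_id"]) for pep, sub in grouped
    }
    counts.index = [f"MP_{pep}" for pep in counts.index]
    counts.index.name = "metaprotein_id"
    gene_sets = {f"MP_{pep}": gs for pep, gs in gene_sets.items()}
    peptide_sets = {mp: mp[3:] for mp in counts.index}
    return SpectralCountTable(counts.astype(float), gene_sets, peptide_sets)


def exclude_nonunique(table: SpectralCountTable) -> pd.DataFrame:
    """Drop metaproteins not uniquely assigned to one gene; re-key by gene.

    Returns a gene × sample spectral-count matrix.  If several unique
    metaproteins map to the same gene their counts are summed.  An
    all-non-unique input yields an empty matrix with a warning, not an
    error.
    """
    unique = table.is_unique()
    kept = table.counts.loc[unique[unique].index]
    if len(kept) == 0:
        warnings.warn("all metaproteins are non-unique; spectral table is empty")
        empty = table.counts.iloc[0:0].copy()
        empty.index = pd.Index([], name="gene_id")
        return empty
    gene_of = pd.Series({mp: next(iter(table.gene_sets[mp])) for mp in kept.index})
    out = kept.groupby(gene_of).sum()
    out.index.name = "gene_id"
    return out


def total_count_normalize(
    table: pd.DataFrame, constant: float = NORMALIZATION_CONSTANT
) -> pd.DataFrame:
    """Scale every sample column so its sum equals ``constant``."""
    if constant <= 0:
        raise ValidationError("normalization constant must be positive")
    sums = table.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ValidationError(
            f"zero total spectral count in sample(s): {', '.join(map(str, zero))}"
        )
    return table * (constant / sums)


def median_and_renormalize(
    gene_spectra: pd.DataFrame,
    condition_map: pd.Series,
    catalog: GeneCatalog | None = None,
    constant: float = NORMALIZATION_CONSTANT,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-condition gene- and KO-level matrices (round-2 normalization).

    Per condition the element-wise median across replicate columns is
    taken at gene level; the KO level sums gene medians per KO (requires
    ``catalog`` for the gene → KO map, returns ``None`` otherwise).  Each
    resulting column is total-count normalized again to ``constant``.
    """
    cond_of = condition_map.loc[gene_spectra.columns]
    gene_med = gene_spectra.T.groupby(cond_of, sort=False).median().T
    gene_out = total_count_normalize(gene_med, constant)
    ko_out = None
    if catalog is not None:
        ko_of = catalog.genes.loc[gene_med.index, "ko_id"]
        annotated = ko_of.notna()
        ko_med = gene_med.loc[annotated].groupby(ko_of[annotated]).sum()
        ko_med.index.name = "ko_id"
        ko_out = total_count_normalize(ko_med, constant)
    return gene_out, ko_out


def mag_proteomic_abundance(
    gene_spectra: pd.DataFrame,
    catalog: GeneCatalog,
    mags: MagTable,
    condition_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Completeness-adjusted MAG proteomic abundance (%), unbinned included.

    Per column: a MAG's raw signal is the sum of spectral counts of its
    genes; the raw sum is divided by the MAG's completeness fraction
    (83% → /0.83) so incomplete MAGs are not underrepresented.  The
    unbinned fraction has no completeness estimate and is never adjusted.
    Columns are renormalized so MAGs + UNBINNED sum to 100%.  When
    ``condition_map`` is given, columns are replicates: the per-MAG median
    across replicate percentages is taken per condition, then renormalized
    to 100%.
    """
    check_catalog_mags(catalog, mags)
    genes = gene_spectra.index
    unknown = genes.difference(catalog.gene_ids)
    if len(unknown):
        raise ValidationError(
            f"spectral genes absent from catalog: {', '.join(map(str, unknown[:5]))}"
        )
    mag_of = catalog.genes.loc[genes, "mag_id"]
    raw = gene_spectra.groupby(mag_of).sum()
    row_order = list(mags.mag_ids) + [UNBINNED]
    raw = raw.reindex(row_order, fill_value=0.0)
    comp = mags.mags["completeness_pct"].reindex(row_order)
    comp.loc[UNBINNED] = 100.0
    if (comp <= 0).any():
        bad = comp.index[comp <= 0].tolist()
        raise ValidationError(f"non-positive completeness for MAG(s): {', '.join(bad)}")
    adjusted = raw.div(comp / 100.0, axis=0)
    totals = adjusted.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValidationError(f"zero spectral signal in column(s): {', '.join(map(str, zero))}")
    pct = adjusted.div(totals, axis=1) * 100.0
    if condition_map is None:
        return pct
    return median_then_renormalize(pct, condition_map)


__all__ = [
    "NORMALIZATION_CONSTANT",
    "group_metaproteins",
    "exclude_nonunique",
    "total_count_normalize",
    "median_and_renormalize",
    "mag_proteomic_abundance",
]
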
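"""Metagenome-side quantification.

Annotation filtering, MAG relative abundance from gene-level read
mappings, KO-level count aggregation, and average genomic copy number
(AGCN) normalization against universal single-copy genes (USiCGs).

The AGCN of a genetic feature is the number of copies of that feature
found, on average, on a genome in the community.  It is obtained by
length-normalizing KO read counts and scaling each sample so that the
median length-normalized count over a USiCG reference set equals one —
USiCGs occur exactly once per prokaryotic genome, so their signal defines
"one copy per average genome".
"""

from __future__ import annotations

import importlib.resources
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    UNBINNED,
    GeneCatalog,
    MagTable,
    ReadCountTable,
    ValidationError,
    check_catalog_mags,
)

#: Annotation acceptance thresholds: keep if identity >= 30% AND e-value <= 1e-10.
MIN_IDENTITY_PCT = 30.0
MAX_EVALUE = 1e-10


def filter_annotations(
    catalog: GeneCatalog,
    min_identity_pct: float = MIN_IDENTITY_PCT,
    max_evalue: float = MAX_EVALUE,
) -> GeneCatalog:
    """Discard weak functional annotations, keeping the genes themselves.

    A gene's KO/EC assignment is dropped when its alignment identity is
    below ``min_identity_pct`` or its e-value exceeds ``max_evalue``
    (boundaries kept).  Membership and read counts are untouched: the gene
    still contributes to MAG abundance, just not to functional profiles.
    """
    genes = catalog.genes.copy()
    annotated = genes["ko_id"].notna() | genes["ec_ids"].map(bool)
    ident = genes["annot_identity_pct"]
    ev = genes["annot_evalue"]
    # missing identity/e-value on an annotated gene counts as failing
    keep = (ident >= min_identity_pct) & (ev <= max_evalue)
    discard = annotated & ~keep.fillna(False)
    genes.loc[discard, "ko_id"] = np.nan
    genes.loc[discard, "ec_ids"] = pd.Series([()] * int(discard.sum()), index=genes.index[discard], dtype=object)
    return GeneCatalog(genes)


def _per_sample_mag_signal(
    counts: ReadCountTable, catalog: GeneCatalog, signal: str
) -> pd.DataFrame:
    """MAG × sample matrix of the mapping signal (reads or coverage)."""
    genes = counts.counts.index
    missing = genes.difference(catalog.gene_ids)
    if len(missing):
        raise ValidationError(
            f"counted genes absent from catalog: {', '.join(map(str, missing[:5]))}"
        )
    mat = counts.counts
    if signal == "coverage":
        lengths = catalog.genes.loc[genes, "length_bp"].astype(float)
        mat = mat.div(lengths, axis=0)
    elif signal != "reads":
        raise ValueError(f"unknown abundance signal {signal!r}")
    mag_of = catalog.genes.loc[genes, "mag_id"]
    return mat.groupby(mag_of).sum()


def mag_relative_abundance(
    counts: ReadCountTable,
    catalog: GeneCatalog,
    mags: MagTable,
    signal: str = "reads",
    aggregate: bool = True,
) -> pd.DataFrame:
    """MAG relative abundance (%) per condition, unbinned included.

    Per sample, a MAG's abundance is the share of mapped reads falling on
    its genes among all mapped reads — unmapped reads are excluded, but
    genes on unbinned contigs contribute a first-class ``UNBINNED`` row,
    so abundances are fractions of the whole community rather than of the
    binned part only.  Replicates of a condition are combined by taking
    the per-MAG median and renormalizing the column to 100%.

    With ``aggregate=False`` the per-sample percentages are returned
    without replicate aggregation.
    """
    check_catalog_mags(catalog, mags)
    sig = _per_sample_mag_signal(counts, catalog, signal)
    totals = sig.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValidationError(f"zero mapped reads in sample(s): {', '.join(map(str, zero))}")
    # all MAGs in the table get a row even if no reads mapped to them
    row_order = list(mags.mag_ids)
    if UNBINNED in sig.index or UNBINNED not in row_order:
        row_order = row_order + [UNBINNED]
    pct = sig.reindex(row_order, fill_value=0.0).div(totals, axis=1) * 100.0
    if not aggregate:
        return pct
    return median_then_renormalize(pct, counts.samples.condition_map)


def median_then_renormalize(
    per_sample_pct: pd.DataFrame, condition_map: pd.Series, total: float = 100.0
) -> pd.DataFrame:
    """Per condition: element-wise median across replicates, then rescale
    each column so it sums to ``total``."""
    cond_of = condition_map.loc[per_sample_pct.columns]
    med = per_sample_pct.T.groupby(cond_of, sort=False).median().T
    sums = med.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0].tolist()
        raise ValidationError(f"zero total abundance in condition(s): {', '.join(map(str, bad))}")
    return med.div(sums, axis=1) * total


def ko_read_counts(counts: ReadCountTable, catalog: GeneCatalog) -> pd.DataFrame:
    """Sum gene read counts to KO level (KO × sample).

    Genes without a (retained) KO annotation contribute nothing; run
    :func:`filter_annotations` first.
    """
    ko_of = catalog.genes.loc[counts.counts.index, "ko_id"]
    annotated = ko_of.notna()
    return counts.counts.loc[annotated].groupby(ko_of[annotated]).sum().rename_axis("ko_id")


def default_usicg_set() -> frozenset[str]:
    """The packaged universal single-copy reference: ten ribosomal-protein
    KOs present exactly once per prokaryotic genome."""
    text = (
        importlib.resources.files("magquant").joinpath("data/usicg_kos.tsv").read_text()
    )
    kos = [
        line.split("\t")[0].strip()
        for line in text.splitlines()[1:]
        if line.strip() and not line.startswith("#")
    ]
    return frozenset(kos)


def agcn_normalize(
    ko_counts: pd.DataFrame,
    usicg_set: Iterable[str] | None = None,
    gene_lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Average genomic copy numbers from KO read counts (KO × sample).

    Per sample: divide each KO count by the KO's mean gene length, then
    divide by the median length-normalized count over the USiCG reference.
    After scaling, the median AGCN over the USiCGs present equals 1 by
    construction; a KO with AGCN 2 is carried, on average, in two copies
    per genome.

    ``gene_lengths`` maps ko_id → mean gene length in bp; if omitted, all
    KOs are treated as equal length (pure count ratios).
    """
    usicg = frozenset(usicg_set) if usicg_set is not None else default_usicg_set()
    norm = ko_counts.astype(float)
    if gene_lengths is not None:
        lens = gene_lengths.reindex(ko_counts.index)
        if lens.isna().any():
            missing = lens.index[lens.isna()].tolist()
            raise ValidationError(
                f"no gene length for KO(s): {', '.join(map(str, missing[:5]))}"
            )
        norm = norm.div(lens, axis=0)
    ref = norm.loc[norm.index.intersection(usicg)]
    if len(ref) == 0:
        raise ValidationError("no universal single-copy KO present in the count matrix")
    med = ref.median(axis=0)
    dead = med.index[med <= 0].tolist()
    if dead:
        raise ValidationError(
            f"all single-copy reference KOs are zero in sample(s): {', '.join(map(str, dead))}"
        )
    return norm.div(med, axis=1)


def mean_ko_gene_length(catalog: GeneCatalog) -> pd.Series:
    """ko_id → mean length (bp) of the genes carrying that KO."""
    genes = catalog.genes
    annotated = genes["ko_id"].notna()
    return genes.loc[annotated, "length_bp"].groupby(genes.loc[annotated, "ko_id"]).mean()


__all__ = [
    "MIN_IDENTITY_PCT",
    "MAX_EVALUE",
    "filter_annotations",
    "mag_relative_abundance",
    "median_then_renormalize",
    "ko_read_counts",
    "agcn_normalize",
    "default_usicg_set",
    "mean_ko_gene_length",
]
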
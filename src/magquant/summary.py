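"""Downstream functional summaries.

KO-level log2 fold changes with a pseudo-count offset, KEGG-module
completeness and activity per MAG, enzyme-level aggregation of copy
numbers and spectral counts, high-quality MAG filtering, community
category summaries, key-pathway presence matrices for the anaerobic
digestion (AD) process chain, and Pearson correlations of taxon
abundances with process metadata.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    AGG_MEDIAN,
    AGG_SUM,
    UNBINNED,
    GeneCatalog,
    KeyEnzymeGroup,
    MagTable,
    ModuleDefinition,
    ProcessMetadata,
    ValidationError,
)

#: Default pseudo-count offset for fold changes (30th percentile of the
#: KO-level spectral counts in the reference dataset, rounded).
DEFAULT_OFFSET = 2.0

#: Display threshold: an enzyme needs >= 10 spectra in at least one condition.
SPECTRAL_DISPLAY_MIN = 10.0


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def log2fc(countx, county, offset_s: float = DEFAULT_OFFSET):
    """log2((countx + s) / (county + s)); the offset keeps zero counts finite."""
    if offset_s <= 0:
        raise ValidationError("fold-change offset must be positive")
    return np.log2((np.asarray(countx, dtype=float) + offset_s) / (np.asarray(county, dtype=float) + offset_s))


@dataclass(frozen=True)
class FoldChangeRecord:
    ko_id: str
    condition_pair: tuple[str, str]
    countx: float
    county: float
    offset_s: float

    @property
    def log2fc(self) -> float:
        return float(log2fc(self.countx, self.county, self.offset_s))


def log2_fold_change(
    ko_matrix: pd.DataFrame,
    pair: tuple[str, str],
    offset_s: float = DEFAULT_OFFSET,
) -> list[FoldChangeRecord]:
    """Per-KO log2 fold change between two condition columns."""
    x, y = pair
    for c in pair:
        if c not in ko_matrix.columns:
            raise ValidationError(f"condition {c!r} not in matrix columns")
    return [
        FoldChangeRecord(ko, (x, y), float(ko_matrix.at[ko, x]), float(ko_matrix.at[ko, y]), offset_s)
        for ko in ko_matrix.index
    ]


def fold_change_table(
    ko_matrix: pd.DataFrame, pair: tuple[str, str], offset_s: float = DEFAULT_OFFSET
) -> pd.DataFrame:
    """Vectorized variant of :func:`log2_fold_change` (KO-indexed frame)."""
    x, y = pair
    out = pd.DataFrame(
        {
            "countx": ko_matrix[x].astype(float),
            "county": ko_matrix[y].astype(float),
        },
        index=ko_matrix.index,
    )
    out["offset_s"] = offset_s
    out["log2fc"] = log2fc(out["countx"].to_numpy(), out["county"].to_numpy(), offset_s)
    return out


def derive_offset(
    ko_matrix: pd.DataFrame, percentile: float = 30.0, universe: str = "all"
) -> float:
    """Offset from the data: the rounded 30th percentile of KO-level counts.

    Uses the linear-interpolation percentile definition and half-up
    rounding, with a floor of 1 so the offset never vanishes.  ``universe``
    selects whether zero counts participate (``all``) or not (``nonzero``).
    """
    values = ko_matrix.to_numpy(dtype=float).ravel()
    if universe == "nonzero":
        values = values[values > 0]
    elif universe != "all":
        raise ValidationError(f"unknown offset universe {universe!r}")
    if values.size == 0:
        raise ValidationError("empty count matrix")
    pct = float(np.percentile(values, percentile, method="linear"))
    rounded = float(np.floor(pct + 0.5))  # half-up
    if rounded < 1:
        warnings.warn(f"derived offset {rounded} clamped to 1")
        return 1.0
    return rounded


def max_pairwise_fold_change(row, offset_s: float = DEFAULT_OFFSET) -> float:
    """Max |log2FC| over all unordered condition pairs of one row."""
    vals = np.asarray(row, dtype=float)
    if vals.size < 2:
        raise ValidationError("need at least two conditions")
    return max(
        abs(float(log2fc(a, b, offset_s))) for a, b in itertools.combinations(vals, 2)
    )


# ---------------------------------------------------------------------------
# KEGG modules
# ---------------------------------------------------------------------------

@dataclass
class ModuleScore:
    """Completeness and (optionally) expression activity of one module in one MAG.

    A module is ``retained`` for downstream analysis when it is complete
    or missing at most one block.  ``activity`` holds, per condition, the
    fraction of the MAG's total spectral counts carried by proteins whose
    KO occurs in the module.
    """

    mag_id: str
    module_id: str
    blocks_total: int
    blocks_satisfied: int
    activity: pd.Series | None = None

    @property
    def completeness_pct(self) -> float:
        return 100.0 * self.blocks_satisfied / self.blocks_total

    @property
    def retained(self) -> bool:
        return self.blocks_satisfied >= self.blocks_total - 1


def block_satisfied(block: tuple[frozenset[str], ...], mag_kos: set[str]) -> bool:
    return any(alt <= mag_kos for alt in block)


def module_completeness(
    mag_kos: set[str], modules: list[ModuleDefinition], mag_id: str = ""
) -> list[ModuleScore]:
    """Score every module against a MAG's KO repertoire.

    A block is satisfied when any of its alternative KO sets is fully
    present in ``mag_kos``.
    """
    scores = []
    for mod in modules:
        satisfied = sum(block_satisfied(b, mag_kos) for b in mod.blocks)
        scores.append(ModuleScore(mag_id, mod.module_id, mod.n_blocks, satisfied))
    return scores


def module_activity(
    mag_id: str,
    module: ModuleDefinition,
    gene_spectra: pd.DataFrame,
    catalog: GeneCatalog,
) -> pd.Series:
    """Fraction of a MAG's spectra carried by the module, per condition.

    Numerator: spectral counts of the MAG's genes whose KO occurs in the
    module; denominator: all spectral counts originating from the MAG.
    Zero (with a warning) where the MAG expressed nothing at all.
    """
    genes = gene_spectra.index.intersection(catalog.genes.index[catalog.genes["mag_id"] == mag_id])
    sub = gene_spectra.loc[genes]
    total = sub.sum(axis=0)
    kos = catalog.genes.loc[genes, "ko_id"]
    in_module = kos.isin(module.all_kos)
    num = sub.loc[in_module[in_module].index].sum(axis=0)
    if (total <= 0).any():
        warnings.warn(f"MAG {mag_id} has zero spectral counts in some condition(s)")
    with np.errstate(invalid="ignore"):
        frac = (num / total).where(total > 0, 0.0)
    frac.name = module.module_id
    return frac


def score_modules(
    mag_id: str,
    catalog: GeneCatalog,
    modules: list[ModuleDefinition],
    gene_spectra: pd.DataFrame | None = None,
) -> list[ModuleScore]:
    """Completeness for all modules of one MAG; activity for retained ones."""
    mag_kos = catalog.kos_of_mag(mag_id)
    by_id = {m.module_id: m for m in modules}
    scores = module_completeness(mag_kos, modules, mag_id)
    if gene_spectra is not None:
        for sc in scores:
            if sc.retained:
                sc.activity = module_activity(mag_id, by_id[sc.module_id], gene_spectra, catalog)
    return scores


# ---------------------------------------------------------------------------
# enzyme-level aggregation
# ---------------------------------------------------------------------------

def enzyme_level_summary(
    agcn: pd.DataFrame,
    ko_spectra: pd.DataFrame,
    groups: list[KeyEnzymeGroup],
) -> pd.DataFrame:
    """Aggregate KO-level AGCNs and spectral counts to enzyme level.

    AGCNs of KOs with similar functionality are summed (``sum_similar``);
    where the KOs are individual subunits of one enzyme the median AGCN is
    taken (``median_subunits``).  Spectral counts are always summed.
    Missing KOs count as zero.  Columns come back as a two-level index
    ``(metric, condition)`` with metrics ``agcn`` and ``spectra``.
    """
    conditions = list(agcn.columns)
    if list(ko_spectra.columns) != conditions:
        raise ValidationError("AGCN and spectral matrices must share columns")
    rows = {}
    for g in groups:
        a = agcn.reindex(list(g.ko_ids), fill_value=0.0)
        s = ko_spectra.reindex(list(g.ko_ids), fill_value=0.0)
        if g.aggregation_mode == AGG_SUM:
            a_val = a.sum(axis=0)
        elif g.aggregation_mode == AGG_MEDIAN:
            a_val = a.median(axis=0)
        else:  # pragma: no cover - guarded by KeyEnzymeGroup
            raise ValidationError(f"unknown aggregation mode {g.aggregation_mode!r}")
        row = pd.concat({"agcn": a_val, "spectra": s.sum(axis=0)})
        rows[g.enzyme_label] = row
    out = pd.DataFrame(rows).T
    out.index.name = "enzyme_label"
    return out


def spectral_threshold_filter(
    table: pd.DataFrame, min_count: float = SPECTRAL_DISPLAY_MIN
) -> pd.DataFrame:
    """Keep rows whose spectral count reaches ``min_count`` (inclusive) in
    at least one condition.  Accepts plain matrices or the two-level
    output of :func:`enzyme_level_summary` (then only the ``spectra``
    block is thresholded)."""
    if len(table) == 0:
        return table
    if isinstance(table.columns, pd.MultiIndex):
        spectra = table["spectra"]
    else:
        spectra = table
    keep = spectra.max(axis=1) >= min_count
    return table.loc[keep]


# ---------------------------------------------------------------------------
# HQ MAGs and category summaries
# ---------------------------------------------------------------------------

def hq_mag_filter(
    mags: MagTable,
    genomic: pd.DataFrame,
    proteomic: pd.DataFrame,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    min_abundance: float = 0.5,
) -> MagTable:
    """High-quality MAGs: above 50% completeness, below 10% contamination
    and above 0.5% relative abundance in either omics layer (all strict).
    """
    for profile, name in ((genomic, "genomic"), (proteomic, "proteomic")):
        missing = mags.mag_ids.difference(profile.index)
        if len(missing):
            raise ValidationError(
                f"MAG(s) missing from {name} profile: {', '.join(map(str, missing[:5]))}"
            )
    m = mags.mags.sort_index()
    quality = (m["completeness_pct"] > min_completeness) & (
        m["contamination_pct"] < max_contamination
    )
    gmax = genomic.loc[m.index].max(axis=1)
    pmax = proteomic.loc[m.index].max(axis=1)
    abundant = (gmax > min_abundance) | (pmax > min_abundance)
    return MagTable(m.loc[quality & abundant])


CATEGORY_ROWS = ("unbinned_and_low_quality", "hq_below_threshold", "hq_above_threshold")


def summarize_categories(
    mags: MagTable,
    hq_quality_set: set[str] | None,
    genomic: pd.DataFrame,
    proteomic: pd.DataFrame,
    min_abundance: float = 0.5,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> pd.DataFrame:
    """Partition community abundance into three categories per condition.

    Rows: unbinned contigs plus low-quality MAGs; high-quality MAGs below
    the abundance threshold; high-quality MAGs above it.  Quality is
    completeness/contamination only; the abundance split uses the maximum
    relative abundance over conditions in either layer (strict ``>``).
    Columns are ``(layer, condition)`` and each sums to 100.
    """
    m = mags.mags
    if hq_quality_set is None:
        quality = (m["completeness_pct"] > min_completeness) & (
            m["contamination_pct"] < max_contamination
        )
        hq_quality_set = set(m.index[quality])
    hq = sorted(set(hq_quality_set) & set(m.index))
    gmax = genomic.reindex(hq).max(axis=1)
    pmax = proteomic.reindex(hq).max(axis=1)
    above = set(np.array(hq)[((gmax > min_abundance) | (pmax > min_abundance)).to_numpy()])
    below = set(hq) - above
    cols = {}
    for layer, profile in (("genomic", genomic), ("proteomic", proteomic)):
        low = profile.index.difference(list(above | below))  # UNBINNED + low quality
        for cond in profile.columns:
            cols[(layer, cond)] = pd.Series(
                {
                    CATEGORY_ROWS[0]: profile.loc[low, cond].sum(),
                    CATEGORY_ROWS[1]: profile.loc[sorted(below), cond].sum(),
                    CATEGORY_ROWS[2]: profile.loc[sorted(above), cond].sum(),
                }
            )
    out = pd.DataFrame(cols)
    out.index.name = "category"
    return out


# ---------------------------------------------------------------------------
# key-pathway presence
# ---------------------------------------------------------------------------

def key_pathway_presence(
    mag_id: str,
    groups: list[KeyEnzymeGroup],
    gene_spectra: pd.DataFrame,
    catalog: GeneCatalog,
) -> pd.DataFrame:
    """AD-category × condition presence matrix for one MAG.

    A category is marked present in a condition when at least one member
    KO of at least one of its key-enzyme groups carries a positive
    spectral count on that MAG's genes.
    """
    categories = []
    for g in groups:
        if g.ad_category not in categories:
            categories.append(g.ad_category)
    genes = gene_spectra.index.intersection(
        catalog.genes.index[catalog.genes["mag_id"] == mag_id]
    )
    sub = gene_spectra.loc[genes]
    kos = catalog.genes.loc[genes, "ko_id"]
    out = pd.DataFrame(False, index=pd.Index(categories, name="ad_category"), columns=gene_spectra.columns)
    for g in groups:
        member = kos.isin(g.ko_ids)
        if not member.any():
            continue
        expressed = sub.loc[member[member].index].sum(axis=0) > 0
        out.loc[g.ad_category] |= expressed
    return out


# ---------------------------------------------------------------------------
# metadata correlations
# ---------------------------------------------------------------------------

def metadata_correlations(
    taxa_abundances: pd.DataFrame,
    metadata: ProcessMetadata,
    condition_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson r of each taxon's abundance against each process parameter.

    ``taxa_abundances`` is taxon × sample; when samples are replicates,
    ``condition_map`` expands the per-condition metadata to the sample
    columns.  Correlations against a constant vector are undefined and
    reported as NaN (with a warning), never as 0.
    """
    meta = metadata.table
    if condition_map is not None:
        conds = condition_map.loc[taxa_abundances.columns]
        missing = set(conds) - set(meta.index)
        if missing:
            raise ValidationError(f"conditions missing from metadata: {', '.join(sorted(missing))}")
        meta = meta.loc[conds].set_axis(taxa_abundances.columns)
    elif not taxa_abundances.columns.equals(meta.index):
        raise ValidationError("taxa columns and metadata rows do not match")
    n = taxa_abundances.shape[1]
    if n < 3:
        raise ValidationError("need at least three paired observations")
    out = pd.DataFrame(index=taxa_abundances.index, columns=meta.columns, dtype=float)
    out.index.name = "taxon"
    for taxon in taxa_abundances.index:
        x = taxa_abundances.loc[taxon].to_numpy(dtype=float)
        for param in meta.columns:
            y = meta[param].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"constant vector for ({taxon}, {param}); correlation undefined")
                out.at[taxon, param] = np.nan
            else:
                out.at[taxon, param] = stats.pearsonr(x, y).statistic
    return out


__all__ = [
    "DEFAULT_OFFSET",
    "SPECTRAL_DISPLAY_MIN",
    "CATEGORY_ROWS",
    "FoldChangeRecord",
    "ModuleScore",
    "log2fc",
    "log2_fold_change",
    "fold_change_table",
    "derive_offset",
    "max_pairwise_fold_change",
    "module_completeness",
    "module_activity",
    "score_modules",
    "enzyme_level_summary",
    "spectral_threshold_filter",
    "hq_mag_filter",
    "summarize_categories",
    "key_pathway_presence",
    "metadata_correlations",
]
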
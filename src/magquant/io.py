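"""Readers and writers for the canonical TSV schemas.

Upstream tools (featureCounts, CheckM, GTDB-Tk, Mascot exports, ...) emit
heterogeneous formats; this package defines one tab-separated, UTF-8,
header-row schema per input with ``NA`` as the missing-value sentinel, and
users convert into it.  Readers validate invariants and fail with
actionable messages naming the offending rows.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    GENE_COLUMNS,
    GeneCatalog,
    KeyEnzymeGroup,
    MagTable,
    ModuleDefinition,
    ProcessMetadata,
    ReadCountTable,
    SampleInfo,
    SpectralCountTable,
    ValidationError,
)

NA = "NA"
_READ_KW = dict(sep="\t", na_values=[NA], keep_default_na=False, encoding="utf-8")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns: {', '.join(missing)}")


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, **_READ_KW)
    if len(df) == 0:
        raise ValidationError(f"{path}: no records")
    return df


# ---------------------------------------------------------------------------
# gene catalog
# ---------------------------------------------------------------------------

def read_gene_catalog(path) -> GeneCatalog:
    """Read ``gene_catalog.tsv``.

    Columns: ``gene_id  contig_id  mag_id  length_bp  ko_id  ec_ids
    annot_identity_pct  annot_evalue``.  ``ec_ids`` holds comma-separated
    EC numbers; annotation fields are ``NA`` when absent.
    """
    df = _read_tsv(path)
    _require_columns(df, GENE_COLUMNS, path)
    dup = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dup:
        rows = [str(i + 2) for i in df.index[df["gene_id"].duplicated(keep=False)]]
        raise ValidationError(
            f"{path}: duplicate gene_id {', '.join(map(str, dup))} (rows {', '.join(rows)})"
        )
    df = df.set_index("gene_id")
    df["length_bp"] = df["length_bp"].astype(int)
    df["ec_ids"] = df["ec_ids"].map(_split_ec)
    df["annot_identity_pct"] = pd.to_numeric(df["annot_identity_pct"])
    df["annot_evalue"] = pd.to_numeric(df["annot_evalue"])
    return GeneCatalog(df[GENE_COLUMNS[1:]])


def _split_ec(cell) -> tuple[str, ...]:
    if pd.isna(cell) or cell == "":
        return ()
    return tuple(tok.strip() for tok in str(cell).split(",") if tok.strip())


def _join_ec(ec: Iterable[str]) -> str:
    ec = tuple(ec)
    return ",".join(ec) if ec else NA


def write_gene_catalog(catalog: GeneCatalog, path) -> None:
    df = catalog.genes.copy()
    df["ec_ids"] = df["ec_ids"].map(_join_ec)
    df.to_csv(path, sep="\t", na_rep=NA)


# ---------------------------------------------------------------------------
# MAG quality
# ---------------------------------------------------------------------------

def read_mag_table(path) -> MagTable:
    """Read ``mag_quality.tsv`` (CheckM/GTDB-Tk-style, converted)."""
    df = _read_tsv(path)
    _require_columns(df, ["mag_id", "completeness_pct", "contamination_pct", "taxonomy"], path)
    df = df.set_index("mag_id")
    if "genome_size_bp" not in df.columns:
        df["genome_size_bp"] = np.nan
    return MagTable(df)


def write_mag_table(mags: MagTable, path) -> None:
    mags.mags.to_csv(path, sep="\t", na_rep=NA)


# ---------------------------------------------------------------------------
# read counts + sample metadata
# ---------------------------------------------------------------------------

def read_sample_info(path) -> SampleInfo:
    """Read ``unmapped.tsv``: sample_id, condition_id, replicate, unmapped_reads."""
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "condition_id", "replicate", "unmapped_reads"], path)
    df = df.set_index("sample_id")
    df["unmapped_reads"] = df["unmapped_reads"].astype(int)
    return SampleInfo(df)


def write_sample_info(samples: SampleInfo, path) -> None:
    samples.table.to_csv(path, sep="\t", na_rep=NA)


def read_read_counts(counts_path, samples_path) -> ReadCountTable:
    """Read ``read_counts.tsv`` (gene_id + one integer column per sample)."""
    df = _read_tsv(counts_path)
    _require_columns(df, ["gene_id"], counts_path)
    df = df.set_index("gene_id")
    df = df.astype(int)
    samples = read_sample_info(samples_path)
    return ReadCountTable(df, samples)


def write_read_counts(table: ReadCountTable, counts_path, samples_path=None) -> None:
    table.counts.to_csv(counts_path, sep="\t", na_rep=NA)
    if samples_path is not None:
        write_sample_info(table.samples, samples_path)


# ---------------------------------------------------------------------------
# spectral counts
# ---------------------------------------------------------------------------

def read_spectral_counts(path) -> SpectralCountTable:
    """Read ``spectral_counts.tsv``.

    Columns: ``metaprotein_id  peptide_set_id  gene_ids`` then one numeric
    column per replicate sample.  ``gene_ids`` is comma-separated.
    """
    df = _read_tsv(path)
    _require_columns(df, ["metaprotein_id", "peptide_set_id", "gene_ids"], path)
    df = df.set_index("metaprotein_id")
    gene_sets = {
        mp: frozenset(g.strip() for g in str(cell).split(",") if g.strip())
        for mp, cell in df["gene_ids"].items()
    }
    peptide_sets = df["peptide_set_id"].to_dict()
    counts = df.drop(columns=["peptide_set_id", "gene_ids"]).astype(float)
    return SpectralCountTable(counts, gene_sets, peptide_sets)


def write_spectral_counts(table: SpectralCountTable, path) -> None:
    df = table.counts.copy()
    df.insert(0, "gene_ids", [",".join(sorted(table.gene_sets[mp])) for mp in df.index])
    df.insert(0, "peptide_set_id", [table.peptide_sets.get(mp, mp) for mp in df.index])
    df.to_csv(path, sep="\t", na_rep=NA)


# ---------------------------------------------------------------------------
# KEGG module definitions
# ---------------------------------------------------------------------------

_KO_TOKEN = re.compile(r"^[A-Za-z0-9_.:-]+$")


def parse_module_expression(module_id: str, expression: str) -> ModuleDefinition:
    """Parse a block expression into a :class:`ModuleDefinition`.

    Grammar: blocks separated by whitespace, alternatives within a block by
    commas, complexes by plus signs (``K1+K2`` = one alternative needing
    both KOs).  Parentheses and minus-prefixed optional KOs are not part of
    the grammar and are rejected.
    """
    if any(ch in expression for ch in "()"):
        raise ValidationError(
            f"module {module_id}: parenthesised expressions are not supported"
        )
    if "-" in expression:
        raise ValidationError(
            f"module {module_id}: minus-prefixed optional KOs are not supported"
        )
    blocks: list[tuple[frozenset[str], ...]] = []
    for block_txt in expression.split():
        alts = []
        for alt_txt in block_txt.split(","):
            kos = frozenset(k for k in alt_txt.split("+") if k)
            if not kos or not all(_KO_TOKEN.match(k) for k in kos):
                raise ValidationError(
                    f"module {module_id}: malformed alternative {alt_txt!r}"
                )
            alts.append(kos)
        blocks.append(tuple(alts))
    return ModuleDefinition(module_id, tuple(blocks))


def read_module_definitions(path) -> list[ModuleDefinition]:
    """Read ``modules.tsv``: module_id TAB block expression, one per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    modules: list[ModuleDefinition] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[0] == "module_id":
                continue  # optional header
            parts = line.split("\t", 1)
            if len(parts) == 1:  # whitespace-delimited variant
                parts = line.split(None, 1)
            module_id = parts[0].strip()
            expression = parts[1] if len(parts) > 1 else ""
            try:
                modules.append(parse_module_expression(module_id, expression))
            except ValidationError as err:
                raise ValidationError(f"{path}, line {lineno}: {err}") from err
    if not modules:
        raise ValidationError(f"{path}: no records")
    return modules


# ---------------------------------------------------------------------------
# key enzymes and process metadata
# ---------------------------------------------------------------------------

def read_key_enzymes(path) -> list[KeyEnzymeGroup]:
    """Read ``key_enzymes.tsv``: enzyme_label, ko_ids, aggregation_mode, ad_category."""
    df = _read_tsv(path)
    _require_columns(df, ["enzyme_label", "ko_ids", "aggregation_mode", "ad_category"], path)
    groups = []
    for _, row in df.iterrows():
        kos = tuple(k.strip() for k in str(row["ko_ids"]).split(",") if k.strip())
        groups.append(
            KeyEnzymeGroup(
                enzyme_label=row["enzyme_label"],
                ko_ids=kos,
                aggregation_mode=row["aggregation_mode"],
                ad_category=row["ad_category"],
            )
        )
    return groups


def read_process_metadata(path) -> ProcessMetadata:
    """Read ``process_metadata.tsv``: condition_id + numeric parameter columns."""
    df = _read_tsv(path)
    _require_columns(df, ["condition_id"], path)
    df = df.set_index("condition_id")
    return ProcessMetadata(df.apply(pd.to_numeric))


# ---------------------------------------------------------------------------
# generic labelled matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a fully labelled numeric matrix as TSV (NaN → ``NA``)."""
    if matrix.index.name is None:
        matrix = matrix.rename_axis("id")
    matrix.to_csv(path, sep="\t", na_rep=NA)


def read_matrix(path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` (round-trip identity)."""
    df = _read_tsv(path)
    return df.set_index(df.columns[0])


__all__ = [
    "NA",
    "read_gene_catalog",
    "write_gene_catalog",
    "read_mag_table",
    "write_mag_table",
    "read_sample_info",
    "write_sample_info",
    "read_read_counts",
    "write_read_counts",
    "read_spectral_counts",
    "write_spectral_counts",
    "parse_module_expression",
    "read_module_definitions",
    "read_key_enzymes",
    "read_process_metadata",
    "write_matrix",
    "read_matrix",
]
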
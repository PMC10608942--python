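import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from magquant.model import (
    GENE_COLUMNS,
    UNBINNED,
    GeneCatalog,
    MagTable,
    ReadCountTable,
    SampleInfo,
    SpectralCountTable,
)


def make_catalog(rows):
    """rows: (gene_id, contig_id, mag_id, length_bp, ko_id, identity, evalue)."""
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "contig_id", "mag_id", "length_bp", "ko_id", "annot_identity_pct", "annot_evalue"],
    ).set_index("gene_id")
    df["ec_ids"] = [()] * len(df)
    return GeneCatalog(df[GENE_COLUMNS[1:]])


def make_mags(rows):
    """rows: (mag_id, completeness, contamination)."""
    df = pd.DataFrame(rows, columns=["mag_id", "completeness_pct", "contamination_pct"]).set_index("mag_id")
    df["taxonomy"] = "d__Bacteria"
    df["genome_size_bp"] = np.nan
    return MagTable(df)


def make_samples(rows):
    """rows: (sample_id, condition_id, replicate, unmapped)."""
    df = pd.DataFrame(rows, columns=["sample_id", "condition_id", "replicate", "unmapped_reads"]).set_index("sample_id")
    return SampleInfo(df)


@pytest.fixture
def toy_catalog():
    return make_catalog(
        [
            ("g1", "c1", "M1", 900, "K1", 95.0, 1e-30),
            ("g2", "c1", "M1", 600, "K2", 50.0, 1e-20),
            ("g3", "c2", "M2", 300, "K1", 80.0, 1e-15),
            ("g4", "c3", UNBINNED, 450, "K2", 70.0, 1e-12),
        ]
    )


@pytest.fixture
def toy_mags():
    return make_mags([("M1", 90.0, 2.0), ("M2", 100.0, 5.0)])


@pytest.fixture
def toy_reads(toy_catalog):
    counts = pd.DataFrame(
        {
            "D1_r1": [30, 20, 40, 10],
            "D1_r2": [28, 22, 38, 12],
            "D2_r1": [5, 5, 80, 10],
        },
        index=toy_catalog.gene_ids,
    )
    samples = make_samples(
        [("D1_r1", "D1", 1, 20), ("D1_r2", "D1", 2, 25), ("D2_r1", "D2", 1, 15)]
    )
    return ReadCountTable(counts, samples)


@pytest.fixture
def toy_spectra(toy_catalog):
    counts = pd.DataFrame(
        {
            "D1_r1": [10.0, 4.0, 6.0, 2.0],
            "D1_r2": [8.0, 6.0, 4.0, 2.0],
            "D2_r1": [1.0, 1.0, 17.0, 1.0],
        },
        index=pd.Index(["mp1", "mp2", "mp3", "mp4"], name="metaprotein_id"),
    )
    gene_sets = {
        "mp1": frozenset({"g1"}),
        "mp2": frozenset({"g2"}),
        "mp3": frozenset({"g3"}),
        "mp4": frozenset({"g4"}),
    }
    return SpectralCountTable(counts, gene_sets)
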
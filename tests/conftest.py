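from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dmscreen import synthetic_data as sd
from dmscreen.codons import AA_ALPHABET, CODON_INDEX
from dmscreen.read_processing import CodonCountTable, empty_count_frame


@pytest.fixture
def tiny_preset() -> sd.LibraryPreset:
    """A 6-codon gene for hand-checkable tests."""
    return sd.LibraryPreset(
        gene_id="tiny",
        L=6,
        wt_codons=("ATG", "AAA", "CTG", "GAT", "TTT", "GGC"),
        lambda_mut=1.0,
        n_clones=50,
    )


@pytest.fixture
def small_preset() -> sd.LibraryPreset:
    """A 30-codon gene, large enough for screen-level tests, still fast."""
    return sd.LibraryPreset(
        gene_id="small",
        L=30,
        wt_codons=sd._random_wt_codons(30, 30_001),
        lambda_mut=1.2,
        n_clones=400,
    )


def make_count_table(
    L: int, entries: dict[tuple[int, str], int], sample_id: str = "s", wt_codons=None
) -> CodonCountTable:
    """Build a CodonCountTable from sparse {(site, codon): count} entries."""
    if wt_codons is None:
        wt_codons = sd._random_wt_codons(L, 99)
    frame = empty_count_frame(L)
    for (site, codon), count in entries.items():
        frame.loc[site, codon] = count
    return CodonCountTable(sample_id=sample_id, counts=frame, wt_codons=tuple(wt_codons))


def make_aa_frame(rows: dict[int, dict[str, float]]) -> pd.DataFrame:
    """sites x 20 amino-acid DataFrame from sparse per-site dicts."""
    sites = sorted(rows)
    frame = pd.DataFrame(
        0.0, index=pd.Index(sites, name="site"), columns=list(AA_ALPHABET)
    )
    for site, vals in rows.items():
        for aa, v in vals.items():
            frame.loc[site, aa] = v
    return frame


@pytest.fixture
def aa_frame_factory():
    return make_aa_frame


@pytest.fixture
def count_table_factory():
    return make_count_table
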
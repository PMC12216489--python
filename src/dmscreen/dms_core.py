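"""Selection-screen statistics: reads-per-million normalization, amino-acid
aggregation, enrichment ratios, per-site amino-acid preferences and
wild-type-relative differential selection (log2), plus replicate aggregation.

Conventions
-----------
* RPM = count x 1e6 / sample total, over the whole position x codon table.
* Enrichment and differential selection use a symmetric pseudocount
  (default 0.5 RPM), which keeps every entry finite and makes diffsel exactly
  antisymmetric under swapping the selected and unselected samples.
* Stop codons are aggregated into a separate '*' column retained for QC and
  excluded from preferences and differential selection.
* Differential selection is computed at the amino-acid level after codon
  aggregation, mirroring per-residue heatmap reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import AA_ALPHABET, CODON_TO_AA, STOP_AA
from .read_processing import CodonCountTable

DEFAULT_PSEUDOCOUNT = 0.5  # in RPM units


@dataclass
class AATable:
    """Per-site amino-acid values (counts or RPM) with the stop column kept
    aside for QC."""

    sample_id: str
    values: pd.DataFrame  # sites x 20 amino acids
    stop: pd.Series  # per-site stop-codon totals
    wt_aa: tuple[str, ...]


def to_rpm(table: CodonCountTable) -> CodonCountTable:
    """Normalize a codon count table to reads per million (grand total 1e6)."""
    total = table.total
    if total <= 0:
        raise ValueError(f"sample {table.sample_id!r} has zero total counts (empty screen)")
    rpm = table.counts.astype(float) * (1e6 / total)
    return CodonCountTable(sample_id=table.sample_id, counts=rpm, wt_codons=table.wt_codons)


def aggregate_to_aa(table: CodonCountTable) -> AATable:
    """Sum synonymous codons per site into one column per amino acid."""
    codon_cols = list(table.counts.columns)
    aa_of = {c: CODON_TO_AA[c] for c in codon_cols}
    grouped = table.counts.T.groupby(lambda c: aa_of[c]).sum().T
    stop = grouped[STOP_AA] if STOP_AA in grouped else pd.Series(0.0, index=grouped.index)
    values = grouped.reindex(columns=list(AA_ALPHABET), fill_value=0)
    wt_aa = tuple(CODON_TO_AA[c] for c in table.wt_codons)
    return AATable(sample_id=table.sample_id, values=values, stop=stop, wt_aa=wt_aa)


def _check_shapes(sel: pd.DataFrame, unsel: pd.DataFrame) -> None:
    if sel.shape != unsel.shape or list(sel.columns) != list(unsel.columns):
        raise ValueError("selected and unselected tables must share shape and columns")


def enrichment(
    sel: pd.DataFrame, unsel: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-entry (sel + p) / (unsel + p) enrichment ratio on RPM tables."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    _check_shapes(sel, unsel)
    return (sel + pseudocount) / (unsel + pseudocount)


def preferences(enrichment_table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize enrichment ratios into per-site amino-acid preferences."""
    row_sums = enrichment_table.sum(axis=1)
    return enrichment_table.div(row_sums, axis=0)


def differential_selection(
    sel: pd.DataFrame,
    unsel: pd.DataFrame,
    wt_aa: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """log2 enrichment of each amino acid relative to the wild-type residue.

    entry(site, aa) = log2[((sel_aa+p)/(sel_wt+p)) / ((unsel_aa+p)/(unsel_wt+p))];
    the wild-type entry is 0 by construction.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    _check_shapes(sel, unsel)
    if len(wt_aa) != len(sel):
        raise ValueError("wt_aa must give one residue per site")
    cols = list(sel.columns)
    col_idx = {a: i for i, a in enumerate(cols)}
    wt_idx = np.array([col_idx[a] for a in wt_aa])
    s = sel.to_numpy(dtype=float) + pseudocount
    u = unsel.to_numpy(dtype=float) + pseudocount
    rows = np.arange(len(wt_idx))
    s_wt = s[rows, wt_idx][:, None]
    u_wt = u[rows, wt_idx][:, None]
    d = np.log2(s / s_wt) - np.log2(u / u_wt)
    d[rows, wt_idx] = 0.0
    return pd.DataFrame(d, index=sel.index, columns=cols)


def aggregate_replicates(
    preference_matrices: Sequence[pd.DataFrame],
    diffsel_tables: Sequence[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Entrywise mean of preferences (rows renormalized to 1) and entrywise
    median of differential selection across replicates."""
    if not preference_matrices or not diffsel_tables:
        raise ValueError("need at least one replicate")
    ref_p, ref_d = preference_matrices[0], diffsel_tables[0]
    for m in preference_matrices[1:]:
        _check_shapes(ref_p, m)
    for m in diffsel_tables[1:]:
        _check_shapes(ref_d, m)
    mean_pref = sum(m.to_numpy(dtype=float) for m in preference_matrices) / len(
        preference_matrices
    )
    mean_pref = mean_pref / mean_pref.sum(axis=1, keepdims=True)
    med_diffsel = np.median(
        np.stack([m.to_numpy(dtype=float) for m in diffsel_tables]), axis=0
    )
    return (
        pd.DataFrame(mean_pref, index=ref_p.index, columns=ref_p.columns),
        pd.DataFrame(med_diffsel, index=ref_d.index, columns=ref_d.columns),
    )


def replicate_correlation(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Pearson r over all flattened (site, aa) entries of two replicates.

    Returns NaN (with a warning) when either matrix is constant.
    """
    _check_shapes(a, b)
    x = a.to_numpy(dtype=float).ravel()
    y = b.to_numpy(dtype=float).ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("replicate correlation undefined for constant matrix", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# TSV interchange


def write_tidy(df: pd.DataFrame, path, value_name: str) -> None:
    """Write a sites x amino-acids matrix as tidy TSV (site, aa, value)."""
    tidy = df.reset_index().melt(id_vars="site", var_name="aa", value_name=value_name)
    tidy.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_wide(df: pd.DataFrame, path) -> None:
    """Write a sites x amino-acids matrix as wide TSV for heatmap rendering."""
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_wide(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site")
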
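"""Site-level metrics and the composite gain-of-function score.

Per site: Shannon entropy of the preference row (bits), total positive
differential selection, largest differential selection over non-wild-type
residues; each metric min-max scaled per protein, then

    score = pos_sum_diffsel_scaled + max_diffsel_scaled - SE_scaled

so score lies in [-1, 2]. High-scoring sites combine low entropy with strong
positive selection; the top substitution at a site is its largest-diffsel
non-wild-type amino acid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

ROW_SUM_TOL = 1e-6


def shannon_entropy(prefs: pd.DataFrame | pd.Series | np.ndarray) -> pd.Series | float:
    """Shannon entropy in bits of preference row(s); 0*log0 := 0.

    Accepts a single row (returns a float) or a sites x aa matrix (returns a
    per-site Series). Rows must sum to 1 within 1e-6.
    """
    arr = np.asarray(prefs, dtype=float)
    single = arr.ndim == 1
    mat = arr[None, :] if single else arr
    sums = mat.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
        raise ValueError("preference rows must sum to 1 within 1e-6")
    if np.any(mat < 0):
        raise ValueError("preferences must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mat > 0, mat * np.log2(np.where(mat > 0, mat, 1.0)), 0.0)
    se = -terms.sum(axis=1)
    if single:
        return float(se[0])
    index = prefs.index if isinstance(prefs, pd.DataFrame) else pd.RangeIndex(len(se))
    return pd.Series(se, index=index, name="SE")


def site_diffsel_summaries(
    diffsel: pd.DataFrame, wt_aa: Sequence[str]
) -> pd.DataFrame:
    """Per-site total positive diffsel and the largest diffsel over
    non-wild-type residues (the wild-type entry is identically 0 and would
    otherwise floor the maximum)."""
    if len(wt_aa) != len(diffsel):
        raise ValueError("wt_aa must give one residue per site")
    vals = diffsel.to_numpy(dtype=float)
    cols = {a: i for i, a in enumerate(diffsel.columns)}
    wt_idx = np.array([cols[a] for a in wt_aa])
    pos_sum = np.clip(vals, 0.0, None).sum(axis=1)
    masked = vals.copy()
    masked[np.arange(len(wt_idx)), wt_idx] = -np.inf
    max_diffsel = masked.max(axis=1)
    return pd.DataFrame(
        {"pos_sum_diffsel": pos_sum, "max_diffsel": max_diffsel}, index=diffsel.index
    )


def minmax_scale(values: Sequence[float] | pd.Series | np.ndarray) -> np.ndarray:
    """Linear 0..1 scaling per protein and metric: min -> 0, max -> 1.

    A constant vector maps to all zeros ("all minimal"; avoids 0/0) with a
    warning so downstream reports can flag it.
    """
    arr = np.asarray(values, dtype=float)
    vmin, vmax = arr.min(), arr.max()
    if vmax == vmin:
        warnings.warn("constant metric vector; min-max scaling to all zeros", stacklevel=2)
        return np.zeros_like(arr)
    return (arr - vmin) / (vmax - vmin)


def composite_score(
    se: pd.Series,
    pos_sum_diffsel: pd.Series,
    max_diffsel: pd.Series,
) -> pd.DataFrame:
    """Scale the three site metrics and combine them into the composite score.

    Returned frame (one row per site) is sorted by descending score with
    stable site-index tie order; columns carry the raw metrics, the scaled
    triplet and ``score``.
    """
    if not (len(se) == len(pos_sum_diffsel) == len(max_diffsel)):
        raise ValueError("metric vectors must share length")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se_scaled = minmax_scale(se)
        pos_scaled = minmax_scale(pos_sum_diffsel)
        max_scaled = minmax_scale(max_diffsel)
    frame = pd.DataFrame(
        {
            "SE": np.asarray(se, dtype=float),
            "pos_sum_diffsel": np.asarray(pos_sum_diffsel, dtype=float),
            "max_diffsel": np.asarray(max_diffsel, dtype=float),
            "SE_scaled": se_scaled,
            "pos_sum_diffsel_scaled": pos_scaled,
            "max_diffsel_scaled": max_scaled,
        },
        index=se.index,
    )
    frame["score"] = (
        frame["pos_sum_diffsel_scaled"] + frame["max_diffsel_scaled"] - frame["SE_scaled"]
    )
    return frame.sort_values("score", ascending=False, kind="stable")


@dataclass(frozen=True)
class TopSubstitution:
    site: int
    wt_aa: str
    mutant_aa: str
    diffsel: float
    score: float


def select_top_substitutions(
    score_table: pd.DataFrame,
    diffsel: pd.DataFrame,
    wt_aa: Sequence[str],
    k: int = 8,
) -> list[TopSubstitution]:
    """Nominate one substitution at each of the k highest-scoring sites: the
    non-wild-type amino acid with the largest diffsel (ties broken by lower
    site index, then alphabetical amino acid)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    n_sites = len(score_table)
    if k > n_sites:
        warnings.warn(f"k={k} exceeds {n_sites} sites; truncating", stacklevel=2)
        k = n_sites
    wt_by_site = dict(zip(diffsel.index, wt_aa))
    out: list[TopSubstitution] = []
    for site in score_table.index[:k]:
        row = diffsel.loc[site]
        wt = wt_by_site[site]
        candidates = row.drop(labels=[wt])
        best_val = candidates.max()
        best_aa = min(a for a, v in candidates.items() if v == best_val)
        out.append(
            TopSubstitution(
                site=int(site),
                wt_aa=wt,
                mutant_aa=best_aa,
                diffsel=float(best_val),
                score=float(score_table.loc[site, "score"]),
            )
        )
    return out


def score_table_tsv(
    score_table: pd.DataFrame,
    diffsel: pd.DataFrame,
    wt_aa: Sequence[str],
    path,
) -> None:
    """Write the complete per-site scoring table (site, wt_aa, raw metrics,
    scaled triplet, score, top substitution), sorted by descending score."""
    wt_by_site = dict(zip(diffsel.index, wt_aa))
    rows = []
    for site in score_table.index:
        row = diffsel.loc[site]
        wt = wt_by_site[site]
        candidates = row.drop(labels=[wt])
        best_val = candidates.max()
        best_aa = min(a for a, v in candidates.items() if v == best_val)
        rec = {"site": int(site), "wt_aa": wt}
        rec.update(score_table.loc[site].to_dict())
        rec["top_substitution"] = f"{wt}{site}{best_aa}"
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
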
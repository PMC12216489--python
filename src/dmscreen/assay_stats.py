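"""Validation-assay statistics: plating rates, fold changes, Welch tests,
phage-immunity folds and growth-competition analysis.

Colony-count experiments are represented as :class:`PlatingExperiment`
records (one row per plate); rates are selective CFU over total CFU after
correcting each plate for its dilution and plated volume fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SELECTIVE = "selective"
TOTAL = "total"

#: Preferred colony-count window for choosing the plate used in rate estimates.
COUNTABLE_RANGE = (30, 300)


class DataError(ValueError):
    """Raised when an assay input is unusable (e.g. zero total CFU)."""


@dataclass(frozen=True)
class PlateCount:
    """A single plate: growth medium, tenfold dilution step and volume plated.

    ``dilution`` is the fraction of the original culture present in the plated
    aliquot (1e-5 for the fifth tenfold dilution); ``volume_fraction`` is the
    fraction of that dilution actually spread on the plate.
    """

    medium: str
    dilution: float
    volume_fraction: float
    colonies: int

    def __post_init__(self) -> None:
        if self.medium not in (SELECTIVE, TOTAL):
            raise ValueError(f"medium must be {SELECTIVE!r} or {TOTAL!r}: {self.medium!r}")
        if self.dilution <= 0:
            raise ValueError("dilution factor must be > 0")
        if self.volume_fraction <= 0:
            raise ValueError("plated volume fraction must be > 0")
        if self.colonies < 0:
            raise ValueError("colony counts must be >= 0")

    @property
    def plated_fraction(self) -> float:
        """Fraction of the undiluted culture represented on this plate."""
        return self.dilution * self.volume_fraction

    @property
    def cfu(self) -> float:
        """Dilution-corrected CFU estimate for the undiluted culture."""
        return self.colonies / self.plated_fraction


@dataclass(frozen=True)
class PlatingExperiment:
    strain_id: str
    plates: tuple[PlateCount, ...]

    def __post_init__(self) -> None:
        media = {p.medium for p in self.plates}
        if SELECTIVE not in media or TOTAL not in media:
            raise ValueError("experiment needs at least one selective and one total plate")

    def plates_for(self, medium: str) -> tuple[PlateCount, ...]:
        return tuple(p for p in self.plates if p.medium == medium)


@dataclass(frozen=True)
class AcquisitionRate:
    """Selective/total CFU ratio; ``below_detection`` flags a zero-colony
    selective plate (rate reported as 0)."""

    strain_id: str
    rate: float
    selective_cfu: float
    total_cfu: float
    below_detection: bool = False


@dataclass(frozen=True)
class PhageSurvivalRecord:
    strain_id: str
    total_survivors: int
    n_assayed: int
    n_pcr_positive: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_pcr_positive <= self.n_assayed):
            raise ValueError("need 0 <= n_pcr_positive <= n_assayed")
        if self.total_survivors < 0:
            raise ValueError("total_survivors must be >= 0")

    @property
    def pcr_positive_fraction(self) -> float:
        if self.n_assayed == 0:
            return float("nan")
        return self.n_pcr_positive / self.n_assayed


@dataclass(frozen=True)
class FoldChangeResult:
    fold: float
    t: float | None = None
    df: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float


def _best_plate(plates: Sequence[PlateCount]) -> PlateCount:
    """Most-countable-plate rule: prefer 30-300 colonies, else highest count."""
    lo, hi = COUNTABLE_RANGE
    countable = [p for p in plates if lo <= p.colonies <= hi]
    pool = countable if countable else list(plates)
    return max(pool, key=lambda p: p.colonies)


def acquisition_rate(exp: PlatingExperiment) -> AcquisitionRate:
    """Estimate the selective/total acquisition rate from one plating experiment.

    Each medium is summarized by its most countable plate; zero selective
    colonies give rate 0 flagged as below the limit of detection; zero total
    CFU is an error.
    """
    sel_plate = _best_plate(exp.plates_for(SELECTIVE))
    tot_plate = _best_plate(exp.plates_for(TOTAL))
    total_cfu = tot_plate.cfu
    if total_cfu == 0:
        raise DataError(f"{exp.strain_id}: zero total CFU, rate undefined")
    selective_cfu = sel_plate.cfu
    return AcquisitionRate(
        strain_id=exp.strain_id,
        rate=selective_cfu / total_cfu,
        selective_cfu=selective_cfu,
        total_cfu=total_cfu,
        below_detection=sel_plate.colonies == 0,
    )


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-tailed unpaired t-test with Welch's correction.

    Implemented from the textbook formulas (Welch-Satterthwaite degrees of
    freedom); the unit tests cross-check against an independent routine.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("Welch test needs at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    delta = a.mean() - b.mean()
    if se2 == 0.0:
        if delta == 0.0:
            return WelchResult(t=0.0, df=float(na + nb - 2), p_value=1.0)
        return WelchResult(t=math.copysign(math.inf, delta), df=float(na + nb - 2), p_value=0.0)
    t = delta / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p_value=min(p, 1.0))


def fold_change(
    variant_rates: Sequence[float], wt_rates: Sequence[float]
) -> FoldChangeResult:
    """Fold = ratio of group means (variant over wild type), with a Welch
    p-value when both groups have >= 2 replicates (raw rates, not logs)."""
    v = np.asarray(variant_rates, dtype=float)
    w = np.asarray(wt_rates, dtype=float)
    if v.size < 1 or w.size < 1:
        raise DataError("fold_change needs at least one replicate per group")
    wt_mean = w.mean()
    if wt_mean == 0:
        raise DataError("wild-type mean rate is zero, fold undefined")
    fold = float(v.mean() / wt_mean)
    if v.size >= 2 and w.size >= 2:
        res = welch_t_test(v, w)
        return FoldChangeResult(fold=fold, t=res.t, df=res.df, p_value=res.p_value)
    return FoldChangeResult(fold=fold)


def phage_immunity_fold(
    record: PhageSurvivalRecord, wt_record: PhageSurvivalRecord
) -> float:
    """Survivor colonies x PCR-positive fraction, normalized to wild type."""
    wt_frac = wt_record.pcr_positive_fraction
    if not wt_frac > 0:
        raise DataError("wild-type PCR-positive fraction is zero; fold undefined")
    wt_value = wt_record.total_survivors * wt_frac
    var_value = record.total_survivors * record.pcr_positive_fraction
    return float(var_value / wt_value)


def competition_analysis(
    series: Iterable[Sequence[float]], null_fraction: float = 0.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-day one-sample two-tailed t-test of replicate fractions vs 0.5.

    ``series`` holds one daily-fraction vector per replicate (day 0 first).
    Returns a frame with mean, 95% CI, t, p and a significance flag per day;
    with a single replicate only descriptive columns are filled.
    """
    mat = np.asarray(list(series), dtype=float)
    if mat.ndim != 2:
        raise DataError("replicate series must all have the same length")
    n_rep, n_days = mat.shape
    rows = []
    for day in range(n_days):
        vals = mat[:, day]
        mean = float(vals.mean())
        row: dict[str, float | int | bool | None] = {
            "day": day, "mean": mean, "n": n_rep,
            "ci_low": None, "ci_high": None, "t": None, "p_value": None,
            "significant": False,
        }
        if n_rep >= 2:
            sd = float(vals.std(ddof=1))
            sem = sd / math.sqrt(n_rep)
            if sem == 0.0:
                t = 0.0 if mean == null_fraction else math.copysign(math.inf, mean - null_fraction)
                p = 1.0 if mean == null_fraction else 0.0
                half = 0.0
            else:
                t = (mean - null_fraction) / sem
                p = 2.0 * float(stats.t.sf(abs(t), n_rep - 1))
                half = float(stats.t.ppf(0.975, n_rep - 1)) * sem
            row.update(
                ci_low=mean - half, ci_high=mean + half,
                t=float(t), p_value=min(p, 1.0), significant=bool(p < alpha),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("day")


# ---------------------------------------------------------------------------
# TSV interchange

PLATING_COLUMNS = ["strain_id", "medium", "dilution", "volume_fraction", "colonies"]


def read_plating_tsv(path) -> list[PlatingExperiment]:
    """Read plating experiments from a TSV with columns
    strain_id / medium / dilution / volume_fraction / colonies."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PLATING_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"plating table missing columns: {sorted(missing)}")
    out = []
    for strain, sub in df.groupby("strain_id", sort=False):
        plates = tuple(
            PlateCount(
                medium=str(r.medium),
                dilution=float(r.dilution),
                volume_fraction=float(r.volume_fraction),
                colonies=int(r.colonies),
            )
            for r in sub.itertuples()
        )
        out.append(PlatingExperiment(strain_id=str(strain), plates=plates))
    return out


def write_plating_tsv(experiments: Iterable[PlatingExperiment], path) -> None:
    rows = [
        {
            "strain_id": e.strain_id, "medium": p.medium, "dilution": p.dilution,
            "volume_fraction": p.volume_fraction, "colonies": p.colonies,
        }
        for e in experiments
        for p in e.plates
    ]
    pd.DataFrame(rows, columns=PLATING_COLUMNS).to_csv(path, sep="\t", index=False)
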
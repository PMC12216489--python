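"""Barcode grouping, consensus calling and codon counting for barcoded
subamplicon reads, plus library QC.

Two routes are provided and kept in agreement by the test suite:

* a generic per-group API (:func:`group_by_barcode`, :func:`call_consensus`)
  operating on read records, used for small inputs and FASTQ files;
* a vectorized batch path (:func:`consensus_calls`) over
  :class:`~dmscreen.synthetic_data.SegmentReads` arrays, used by the pipeline.

Consensus is strict majority per codon; ties and no-majority positions are
masked and contribute no counts. Reads whose length does not match their
segment are rejected (the subamplicon design is substitution-only, so no
indel alignment is attempted).
"""

from __future__ import annotations

import gzip
import json
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codons import CODONS, CODON_INDEX, encode_seq
from .synthetic_data import Segment, SegmentReads

MIN_READS_PER_BARCODE = 2

MASKED = -1  # no strict majority at this codon
AMBIGUOUS = -2  # consensus codon contains a non-ACGT base


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with its molecular barcode and segment of origin."""

    barcode: str
    segment_id: str
    seq: str
    clone_id: int | None = None


@dataclass(frozen=True)
class BarcodeGroup:
    barcode: str
    segment_id: str
    reads: tuple[str, ...]
    clone_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.reads) < 1:
            raise ValueError("barcode group needs at least one read")


@dataclass
class ProcessingStats:
    """Read-conservation ledger: every input read is retained or tallied
    under exactly one discard reason."""

    n_reads_in: int = 0
    n_reads_retained: int = 0
    n_reads_low_coverage: int = 0  # group below min_reads_per_barcode
    n_reads_malformed: int = 0  # bad barcode field or wrong length
    n_codons_masked: int = 0
    n_codons_ambiguous: int = 0

    def check_conservation(self) -> None:
        assert (
            self.n_reads_in
            == self.n_reads_retained + self.n_reads_low_coverage + self.n_reads_malformed
        )

    def merge(self, other: "ProcessingStats") -> None:
        for f in (
            "n_reads_in", "n_reads_retained", "n_reads_low_coverage",
            "n_reads_malformed", "n_codons_masked", "n_codons_ambiguous",
        ):
            setattr(self, f, getattr(self, f) + getattr(other, f))


# ---------------------------------------------------------------------------
# Generic per-group route


def group_by_barcode(
    reads: Iterable[ReadRecord],
    min_reads_per_barcode: int = MIN_READS_PER_BARCODE,
) -> tuple[list[BarcodeGroup], ProcessingStats]:
    """Partition reads by (barcode, segment); groups smaller than
    ``min_reads_per_barcode`` are discarded and tallied."""
    stats_ = ProcessingStats()
    buckets: dict[tuple[str, str], list[ReadRecord]] = defaultdict(list)
    for read in reads:
        stats_.n_reads_in += 1
        if not read.barcode or not read.seq:
            stats_.n_reads_malformed += 1
            continue
        buckets[(read.barcode, read.segment_id)].append(read)
    groups: list[BarcodeGroup] = []
    for (barcode, segment_id), members in buckets.items():
        lengths = {len(r.seq) for r in members}
        if len(lengths) != 1:
            # length-discordant reads cannot be offset-aligned; reject group
            stats_.n_reads_malformed += len(members)
            continue
        if len(members) < min_reads_per_barcode:
            stats_.n_reads_low_coverage += len(members)
            continue
        stats_.n_reads_retained += len(members)
        clone_ids = {r.clone_id for r in members}
        groups.append(
            BarcodeGroup(
                barcode=barcode,
                segment_id=segment_id,
                reads=tuple(r.seq for r in members),
                clone_id=clone_ids.pop() if len(clone_ids) == 1 else None,
            )
        )
    stats_.check_conservation()
    return groups, stats_


def call_consensus(group: BarcodeGroup) -> list[str | None]:
    """Per-codon strict-majority consensus of a barcode group.

    Returns one codon (or ``None`` when masked by a tie / no majority /
    ambiguous base) per codon position of the segment.
    """
    length = len(group.reads[0])
    if length % 3:
        raise ValueError("read length is not a whole number of codons")
    n_codons = length // 3
    majority_needed = len(group.reads) / 2.0
    out: list[str | None] = []
    for j in range(n_codons):
        votes = Counter(r[3 * j: 3 * j + 3] for r in group.reads)
        codon, count = votes.most_common(1)[0]
        if count > majority_needed and codon in CODON_INDEX:
            out.append(codon)
        else:
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# Vectorized batch route


@dataclass
class ConsensusBatch:
    """Consensus codon calls for the molecules of one segment.

    ``calls[m, j]`` is the codon index at codon ``start + j`` for molecule m,
    or MASKED / AMBIGUOUS.
    """

    segment_id: str
    start: int
    end: int
    calls: np.ndarray  # (n_molecules, n_codons) int16
    clone_ids: np.ndarray
    barcodes: np.ndarray


def consensus_calls(
    batch: SegmentReads,
    min_reads_per_barcode: int = MIN_READS_PER_BARCODE,
    stats_out: ProcessingStats | None = None,
) -> ConsensusBatch:
    """Vectorized strict-majority consensus over a simulated read batch."""
    st = stats_out if stats_out is not None else ProcessingStats()
    g = batch.reads_per_barcode
    n_mol = batch.n_molecules
    n_codons = batch.end - batch.start + 1
    st.n_reads_in += batch.n_reads
    if g < min_reads_per_barcode or n_mol == 0:
        st.n_reads_low_coverage += batch.n_reads
        empty = np.empty((0, n_codons), dtype=np.int16)
        return ConsensusBatch(
            batch.segment_id, batch.start, batch.end, empty,
            batch.clone_ids[:0], batch.barcodes[:0],
        )
    st.n_reads_retained += batch.n_reads

    s = batch.seqs.reshape(n_mol, g, n_codons, 3)
    votes = np.zeros((n_mol, g, n_codons), dtype=np.uint8)
    for a in range(g):
        for b in range(g):
            votes[:, a] += (s[:, a] == s[:, b]).all(axis=-1)
    majority = votes * 2 > g
    has_majority = majority.any(axis=1)
    first = majority.argmax(axis=1)

    codon_idx = (
        s[..., 0].astype(np.int16) * 16
        + s[..., 1].astype(np.int16) * 4
        + s[..., 2].astype(np.int16)
    )
    calls = np.take_along_axis(codon_idx, first[:, None, :], axis=1)[:, 0, :]
    ambiguous = np.take_along_axis(
        (s >= 4).any(axis=-1), first[:, None, :], axis=1
    )[:, 0, :]
    calls[has_majority & ambiguous] = AMBIGUOUS
    calls[~has_majority] = MASKED
    st.n_codons_masked += int((~has_majority).sum())
    st.n_codons_ambiguous += int((has_majority & ambiguous).sum())
    return ConsensusBatch(
        batch.segment_id, batch.start, batch.end, calls,
        batch.clone_ids.copy(), batch.barcodes.copy(),
    )


# ---------------------------------------------------------------------------
# Codon counting


@dataclass
class CodonCountTable:
    """Per-sample matrix of consensus codon observations.

    ``counts`` is a DataFrame indexed by codon position 1..L with the 64
    codons as columns; ``wt_codons`` is the reference gene.
    """

    sample_id: str
    counts: pd.DataFrame
    wt_codons: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("codon counts must be >= 0")

    @property
    def L(self) -> int:
        return len(self.wt_codons)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def empty_count_frame(L: int) -> pd.DataFrame:
    return pd.DataFrame(
        np.zeros((L, 64), dtype=np.int64),
        index=pd.RangeIndex(1, L + 1, name="site"),
        columns=list(CODONS),
    )


def count_codons(
    consensus_batches: Iterable[ConsensusBatch],
    wt_codons: Sequence[str],
    sample_id: str = "sample",
) -> CodonCountTable:
    """Tally consensus codon calls into a position x codon count matrix.

    Each unmasked consensus position of each molecule contributes one count;
    masked / ambiguous positions contribute nothing.
    """
    L = len(wt_codons)
    counts = np.zeros((L, 64), dtype=np.int64)
    for batch in consensus_batches:
        if batch.end > L or batch.start < 1:
            raise ValueError("consensus positions outside reference 1..L")
        for j in range(batch.calls.shape[1]):
            col = batch.calls[:, j]
            col = col[col >= 0]
            if col.size:
                counts[batch.start - 1 + j] += np.bincount(col, minlength=64)
    frame = empty_count_frame(L)
    frame.iloc[:, :] = counts
    return CodonCountTable(sample_id=sample_id, counts=frame, wt_codons=tuple(wt_codons))


def consensus_from_groups(groups: Iterable[BarcodeGroup], segments: Sequence[Segment]) -> list[ConsensusBatch]:
    """Adapter: run the per-group consensus route and pack results as batches."""
    seg_map = {s.segment_id: s for s in segments}
    buckets: dict[str, list[tuple[list[str | None], int | None, str]]] = defaultdict(list)
    for group in groups:
        buckets[group.segment_id].append(
            (call_consensus(group), group.clone_id, group.barcode)
        )
    out = []
    for seg_id, items in buckets.items():
        seg = seg_map[seg_id]
        calls = np.full((len(items), seg.n_codons), MASKED, dtype=np.int16)
        clone_ids = np.full(len(items), -1, dtype=np.int64)
        barcodes = np.zeros(len(items), dtype=np.int64)
        for m, (cons, clone_id, barcode) in enumerate(items):
            for j, codon in enumerate(cons):
                if codon is not None:
                    calls[m, j] = CODON_INDEX[codon]
            if clone_id is not None:
                clone_ids[m] = clone_id
            barcodes[m] = int(re.sub(r"\D", "", barcode) or 0)
        out.append(ConsensusBatch(seg_id, seg.start, seg.end, calls, clone_ids, barcodes))
    return out


# ---------------------------------------------------------------------------
# FASTQ input

_ID_RE = re.compile(r"bc(?P<bc>\d+);seg=(?P<seg>[^;]+);start=(?P<start>\d+);clone=(?P<clone>-?\d+)")


def read_fastq_records(path) -> list[ReadRecord]:
    """Parse a (optionally gzipped) FASTQ written by the simulator into read
    records; the barcode, segment and clone are recovered from the read ID."""
    opener = gzip.open if str(path).endswith(".gz") else open
    records: list[ReadRecord] = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # '+'
            fh.readline()  # quality (ignored; consensus dominates correction)
            m = _ID_RE.search(header)
            if m is None:
                records.append(ReadRecord(barcode="", segment_id="", seq=seq))
                continue
            records.append(
                ReadRecord(
                    barcode=m.group("bc"),
                    segment_id=m.group("seg"),
                    seq=seq,
                    clone_id=int(m.group("clone")),
                )
            )
    return records


def read_segment_map(path) -> list[Segment]:
    """Segment map TSV: segment_id / start_codon / end_codon."""
    df = pd.read_csv(path, sep="\t")
    return [
        Segment(str(r.segment_id), int(r.start_codon), int(r.end_codon))
        for r in df.itertuples()
    ]


def write_segment_map(segments: Sequence[Segment], path) -> None:
    pd.DataFrame(
        [(s.segment_id, s.start, s.end) for s in segments],
        columns=["segment_id", "start_codon", "end_codon"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clone reconstruction and library QC


def reconstruct_clone_genotypes(
    consensus_batches: Sequence[ConsensusBatch], L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble one genotype per clone from per-segment consensus molecules.

    Synthetic mode only (requires clone-resolved molecules). For each clone
    the first molecule of each segment is used; clones not observed in every
    segment are dropped (a partially covered genotype would bias the
    mutation-load estimate down). Returns ``(clone_ids, genotypes)`` where
    genotypes is (n_clones, L) of codon indices with negative values where no
    call is available.
    """
    n_segments = len(consensus_batches)
    seen: dict[int, int] = {}
    for batch in consensus_batches:
        for cid in np.unique(batch.clone_ids):
            if cid >= 0:
                seen[int(cid)] = seen.get(int(cid), 0) + 1
    all_ids = np.array(sorted(c for c, k in seen.items() if k == n_segments), dtype=np.int64)
    id_to_row = {int(cid): i for i, cid in enumerate(all_ids)}
    genotypes = np.full((len(all_ids), L), MASKED, dtype=np.int16)
    for batch in consensus_batches:
        if batch.calls.shape[0] == 0:
            continue
        _, first_idx = np.unique(batch.clone_ids, return_index=True)
        for m in first_idx:
            cid = int(batch.clone_ids[m])
            if cid < 0 or cid not in id_to_row:
                continue
            genotypes[id_to_row[cid], batch.start - 1: batch.end] = batch.calls[m]
    return all_ids, genotypes


@dataclass
class LibraryQCReport:
    """Mutation-load and positional-uniformity QC of a clone library."""

    mean_mut_per_clone: float
    mut_count_histogram: dict[int, int]
    poisson_gof_p: float
    positional_cv: float
    n_clones: int
    low_confidence: bool

    def to_json(self) -> str:
        payload = {
            "mean_mut_per_clone": self.mean_mut_per_clone,
            "mut_count_histogram": {str(k): v for k, v in self.mut_count_histogram.items()},
            "poisson_gof_p": self.poisson_gof_p,
            "positional_cv": self.positional_cv,
            "n_clones": self.n_clones,
            "low_confidence": self.low_confidence,
        }
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        lines = [
            "Library QC report",
            f"  clones observed:        {self.n_clones}",
            f"  mean mutated codons:    {self.mean_mut_per_clone:.4f}",
            f"  Poisson GOF p-value:    {self.poisson_gof_p:.4g}",
            f"  positional count CV:    {self.positional_cv:.4f}",
        ]
        if self.low_confidence:
            lines.append("  WARNING: fewer than 100 clones; low-confidence report")
        hist = " ".join(f"{k}:{v}" for k, v in sorted(self.mut_count_histogram.items()))
        lines.append(f"  load histogram:         {hist}")
        return "\n".join(lines)


def library_qc(
    genotypes: np.ndarray,
    wt_codons: Sequence[str],
) -> LibraryQCReport:
    """QC a set of clone genotypes against their reference.

    Reports the mean mutated-codon load, its histogram, a chi-square
    goodness-of-fit p-value against Poisson(estimated mean), and the
    coefficient of variation of per-position mutation counts.
    """
    wt_idx = np.array([CODON_INDEX[c] for c in wt_codons], dtype=np.int16)
    L = len(wt_idx)
    if genotypes.size == 0:
        raise ValueError("no clone genotypes to QC")
    mutated = (genotypes >= 0) & (genotypes != wt_idx[None, :])
    loads = mutated.sum(axis=1)
    n = len(loads)
    mean = float(loads.mean())
    hist_arr = np.bincount(loads)
    histogram = {int(k): int(v) for k, v in enumerate(hist_arr) if v > 0 or k == 0}

    gof_p = _poisson_gof(loads, mean)

    pos_counts = mutated.sum(axis=0).astype(float)
    pos_mean = pos_counts.mean()
    positional_cv = float(pos_counts.std() / pos_mean) if pos_mean > 0 else float("nan")
    return LibraryQCReport(
        mean_mut_per_clone=mean,
        mut_count_histogram=histogram,
        poisson_gof_p=gof_p,
        positional_cv=positional_cv,
        n_clones=n,
        low_confidence=n < 100,
    )


def _poisson_gof(loads: np.ndarray, mean: float) -> float:
    """Chi-square goodness of fit of integer loads against Poisson(mean),
    pooling bins with expected count < 5 into the tail."""
    n = len(loads)
    if n < 2 or mean == 0:
        return float("nan")
    kmax = int(loads.max())
    observed = np.bincount(loads, minlength=kmax + 1).astype(float)
    expected = stats.poisson.pmf(np.arange(kmax + 1), mean) * n
    expected[-1] += stats.poisson.sf(kmax, mean) * n  # fold the upper tail in
    # pool sparse bins from the right
    while len(expected) > 2 and expected[-1] < 5:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected, observed = expected[:-1], observed[:-1]
    if len(expected) <= 2:
        return float("nan")
    ddof = 1  # the Poisson mean was estimated from the data
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, len(expected) - 1 - ddof))
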
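"""Synthetic codon-mutant libraries, selection screens, sequencing reads and
colony-count assays with planted ground truth.

Every generator takes an explicit integer seed and is deterministic given it.
Mutant codons are drawn from all 63 non-wild-type triplets; fitness effects
are multiplicative per amino-acid change (synonymous changes are neutral);
coordinates are 1-based codon indices with residue 1 at the start codon.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assay_stats import (
    SELECTIVE,
    TOTAL,
    PhageSurvivalRecord,
    PlateCount,
    PlatingExperiment,
)
from .codons import (
    CODON_INDEX,
    CODON_TO_AA,
    CODONS,
    STOP_CODONS,
    codon_index,
    decode_seq,
    encode_seq,
    translate_codons,
)

__all__ = [
    "LibraryPreset", "CloneGenotype", "Mutation", "EffectTable", "VariantPreset",
    "ScreenConfig", "Segment", "SegmentReads", "SelectionResult",
    "get_preset", "get_variant_preset", "PRESETS", "VARIANT_PRESETS",
    "simulate_clone_library", "clone_selection_probability", "simulate_selection",
    "sample_molecules", "default_segments", "simulate_reads", "write_fastq",
    "simulate_plating", "default_dilution_scheme", "simulate_phage_survival",
    "simulate_competition", "child_seed", "write_truth_tsv", "write_reference_fasta",
]


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic, platform-stable per-stage seed derived from a master seed."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode("utf-8"))) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Presets and domain types


@dataclass(frozen=True)
class LibraryPreset:
    """A codon-mutant library recipe: gene, Poisson mutation load, clone count."""

    gene_id: str
    L: int
    wt_codons: tuple[str, ...]
    lambda_mut: float
    n_clones: int

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("gene length must be >= 1 codon")
        if self.lambda_mut < 0:
            raise ValueError("lambda_mut must be >= 0")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if len(self.wt_codons) != self.L:
            raise ValueError("wt_codons must have exactly L entries")
        for c in self.wt_codons:
            if c not in CODON_INDEX:
                raise ValueError(f"invalid wild-type codon {c!r}")

    @property
    def wt_aa(self) -> tuple[str, ...]:
        return translate_codons(self.wt_codons)

    @property
    def wt_seq(self) -> str:
        return "".join(self.wt_codons)


Mutation = tuple[int, str]  # (1-based codon position, mutant codon)


@dataclass(frozen=True)
class CloneGenotype:
    clone_id: int
    mutations: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError("duplicate mutated positions in clone")

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


class EffectTable:
    """Planted per-substitution fitness multipliers.

    Keys are (1-based position, mutant amino acid); anything absent has
    multiplier 1.0. Multipliers must be non-negative.
    """

    def __init__(self, entries: Mapping[tuple[int, str], float] | None = None):
        self._entries: dict[tuple[int, str], float] = {}
        for (pos, aa), mult in (entries or {}).items():
            if mult < 0:
                raise ValueError("effect multipliers must be >= 0")
            self._entries[(int(pos), aa)] = float(mult)

    def multiplier(self, position: int, mutant_aa: str) -> float:
        return self._entries.get((position, mutant_aa), 1.0)

    @property
    def entries(self) -> dict[tuple[int, str], float]:
        return dict(self._entries)

    def __len__(self) -> int:
        return len(self._entries)


@dataclass(frozen=True)
class VariantPreset:
    """A named strain with a planted true fold improvement over wild type."""

    name: str
    true_fold: float

    def __post_init__(self) -> None:
        if not self.true_fold > 0:
            raise ValueError("true_fold must be > 0")


VARIANT_PRESETS: dict[str, VariantPreset] = {
    p.name: p
    for p in (
        VariantPreset("YT-oligo", 3.9),
        VariantPreset("MYT-oligo", 5.0),
        VariantPreset("T-phage", 3.0),
        VariantPreset("YT-phage", 5.0),
        VariantPreset("MYT-phage", 7.0),
        VariantPreset("YT-ecoli", 1.7),
        VariantPreset("MYT-ecoli", 1.6),
    )
}


@dataclass(frozen=True)
class ScreenConfig:
    """Knobs of the simulated selection screen and sequencing run."""

    base_rate: float = 1e-5
    n_cells: int = 10_000_000
    reads_per_clone_mean: float = 3.0
    reads_per_barcode: int = 3
    seq_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must be in [0, 1]")
        if self.n_cells < 0 or self.reads_per_barcode < 0:
            raise ValueError("counts must be >= 0")
        if self.reads_per_clone_mean < 0:
            raise ValueError("reads_per_clone_mean must be >= 0")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0, 1)")


def _random_wt_codons(L: int, seed: int, start_codon: bool = True) -> tuple[str, ...]:
    """Deterministic stop-free wild-type gene for a preset."""
    rng = np.random.default_rng(seed)
    non_stop = [c for c in CODONS if c not in STOP_CODONS]
    codons = [non_stop[i] for i in rng.integers(0, len(non_stop), size=L)]
    if start_codon and L >= 1:
        codons[0] = "ATG"
    return tuple(codons)


PRESETS: dict[str, LibraryPreset] = {
    "cas1-like": LibraryPreset("cas1-like", 289, _random_wt_codons(289, 289_001), 1.8, 10_000),
    "cas2-like": LibraryPreset("cas2-like", 113, _random_wt_codons(113, 113_001), 1.3, 10_000),
    "csn2-like": LibraryPreset("csn2-like", 220, _random_wt_codons(220, 220_001), 1.5, 10_000),
}


def get_preset(name: str, **overrides) -> LibraryPreset:
    """Look up a library preset, optionally overriding fields (e.g. n_clones)."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown library preset {name!r}; choose from {sorted(PRESETS)}") from None
    return replace(preset, **overrides) if overrides else preset


def get_variant_preset(name: str) -> VariantPreset:
    try:
        return VARIANT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown variant preset {name!r}; choose from {sorted(VARIANT_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Clone library


def simulate_clone_library(preset: LibraryPreset, seed: int) -> list[CloneGenotype]:
    """Draw a clone library: per-clone mutation count ~ Poisson(lambda_mut)
    truncated at L, positions uniform without replacement, mutant codons
    uniform over the 63 non-wild-type triplets."""
    if preset.lambda_mut > preset.L:
        raise ValueError("degenerate preset: lambda_mut exceeds gene length")
    rng = np.random.default_rng(seed)
    ks = np.minimum(rng.poisson(preset.lambda_mut, size=preset.n_clones), preset.L)
    clones: list[CloneGenotype] = []
    for cid in range(preset.n_clones):
        k = int(ks[cid])
        if k == 0:
            clones.append(CloneGenotype(cid, ()))
            continue
        positions = rng.choice(preset.L, size=k, replace=False) + 1
        muts: list[Mutation] = []
        for pos in sorted(int(p) for p in positions):
            wt_idx = CODON_INDEX[preset.wt_codons[pos - 1]]
            j = int(rng.integers(0, 63))
            if j >= wt_idx:
                j += 1  # skip the wild-type codon
            muts.append((pos, CODONS[j]))
        clones.append(CloneGenotype(cid, tuple(muts)))
    return clones


def clone_selection_probability(
    clone: CloneGenotype,
    wt_codons: Sequence[str],
    effects: EffectTable,
    base_rate: float,
) -> float:
    """min(1, base_rate x product of per-amino-acid-change multipliers).

    Synonymous codon changes contribute a factor of 1.
    """
    p = float(base_rate)
    for pos, codon in clone.mutations:
        mut_aa = CODON_TO_AA[codon]
        if mut_aa == CODON_TO_AA[wt_codons[pos - 1]]:
            continue
        p *= effects.multiplier(pos, mut_aa)
    return min(1.0, p)


@dataclass(frozen=True)
class SelectionResult:
    """Clone-count tables for the unselected (total) and selected populations,
    aligned with the clone library order."""

    clones: tuple[CloneGenotype, ...]
    unselected: np.ndarray
    selected: np.ndarray


def simulate_selection(
    library: Sequence[CloneGenotype],
    preset: LibraryPreset,
    effects: EffectTable,
    config: ScreenConfig,
    seed: int | None = None,
) -> SelectionResult:
    """Sample cells over clones (multinomial) and thin each clone binomially
    with its selection probability. Warns when < 100 cells are selected."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(library)
    if n == 0:
        raise ValueError("empty clone library")
    unselected = rng.multinomial(config.n_cells, np.full(n, 1.0 / n))
    probs = np.array(
        [
            clone_selection_probability(c, preset.wt_codons, effects, config.base_rate)
            for c in library
        ]
    )
    selected = rng.binomial(unselected, probs)
    if selected.sum() < 100:
        warnings.warn(
            f"underpowered screen: only {int(selected.sum())} selected cells",
            stacklevel=2,
        )
    return SelectionResult(tuple(library), unselected, selected)


# ---------------------------------------------------------------------------
# Sequencing reads


@dataclass(frozen=True)
class Segment:
    """A subamplicon segment covering codons start..end inclusive (1-based)."""

    segment_id: str
    start: int
    end: int

    @property
    def n_codons(self) -> int:
        return self.end - self.start + 1


def default_segments(L: int, n_segments: int | None = None) -> list[Segment]:
    """Tile codons 1..L into contiguous segments (about 60 codons each by
    default, five segments for a 289-codon gene)."""
    if n_segments is None:
        n_segments = max(1, round(L / 60))
    n_segments = min(n_segments, L)
    bounds = np.linspace(0, L, n_segments + 1).round().astype(int)
    return [
        Segment(f"seg{i + 1}", int(bounds[i]) + 1, int(bounds[i + 1]))
        for i in range(n_segments)
    ]


def validate_segments(segments: Sequence[Segment], L: int) -> None:
    """Segments must tile 1..L contiguously without gaps or overlaps."""
    ordered = sorted(segments, key=lambda s: s.start)
    expected = 1
    for seg in ordered:
        if seg.start != expected or seg.end < seg.start:
            raise ValueError(
                f"segment tiling leaves codons uncovered or overlaps at {seg.segment_id}"
            )
        expected = seg.end + 1
    if expected != L + 1:
        raise ValueError("segment tiling does not cover codons 1..L")


@dataclass
class SegmentReads:
    """Simulated reads for one subamplicon segment.

    Reads are stored as uint8 base codes, ``reads_per_barcode`` consecutive
    rows per molecule; ``barcodes`` and ``clone_ids`` are per molecule.
    """

    segment_id: str
    start: int
    end: int
    barcodes: np.ndarray
    clone_ids: np.ndarray
    reads_per_barcode: int
    seqs: np.ndarray

    @property
    def n_molecules(self) -> int:
        return len(self.barcodes)

    @property
    def n_reads(self) -> int:
        return self.seqs.shape[0]


def sample_molecules(
    clone_counts: np.ndarray, n_molecules: int, seed: int
) -> np.ndarray:
    """Subsample sequencing molecules from a clone-count table (multinomial)."""
    counts = np.asarray(clone_counts, dtype=np.int64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot sample molecules from an empty count table")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_molecules, counts / total)


def simulate_reads(
    molecule_counts: np.ndarray,
    library: Sequence[CloneGenotype],
    preset: LibraryPreset,
    config: ScreenConfig,
    segments: Sequence[Segment] | None = None,
    seed: int | None = None,
) -> list[SegmentReads]:
    """Emit barcoded subamplicon reads for ``molecule_counts[i]`` molecules of
    each library clone, per segment.

    Every molecule gets a globally unique barcode and ``reads_per_barcode``
    full-length reads of its segment; per-base substitution errors are applied
    at ``seq_error_rate``.
    """
    if segments is None:
        segments = default_segments(preset.L)
    validate_segments(segments, preset.L)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts = np.asarray(molecule_counts, dtype=np.int64)
    if counts.shape != (len(library),):
        raise ValueError("molecule_counts must align with the clone library")

    active = np.nonzero(counts)[0]
    wt_codes = encode_seq(preset.wt_seq)
    seqmat = np.tile(wt_codes, (len(active), 1))
    for row, ci in enumerate(active):
        for pos, codon in library[ci].mutations:
            seqmat[row, 3 * (pos - 1): 3 * pos] = encode_seq(codon)
    clone_id_arr = np.array([library[ci].clone_id for ci in active], dtype=np.int64)

    rpb = config.reads_per_barcode
    mol_rows = np.repeat(np.arange(len(active)), counts[active])
    batches: list[SegmentReads] = []
    next_barcode = 0
    for seg in segments:
        sl = slice(3 * (seg.start - 1), 3 * seg.end)
        mols = seqmat[mol_rows][:, sl]
        reads = np.repeat(mols, rpb, axis=0)
        if config.seq_error_rate > 0 and reads.size:
            n_err = rng.binomial(reads.size, config.seq_error_rate)
            if n_err:
                flat_idx = rng.integers(0, reads.size, size=n_err)
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                flat = reads.reshape(-1)
                flat[flat_idx] = (flat[flat_idx] + shift) % 4
        n_mol = len(mol_rows)
        batches.append(
            SegmentReads(
                segment_id=seg.segment_id,
                start=seg.start,
                end=seg.end,
                barcodes=np.arange(next_barcode, next_barcode + n_mol, dtype=np.int64),
                clone_ids=clone_id_arr[mol_rows],
                reads_per_barcode=rpb,
                seqs=reads,
            )
        )
        next_barcode += n_mol
    return batches


def write_fastq(batches: Iterable[SegmentReads], path) -> None:
    """Write simulated reads as Phred+33 FASTQ (constant quality 'I').

    Read IDs encode segment, barcode and source clone for round-trip testing:
    ``@bc<barcode>;seg=<segment_id>;start=<codon>;clone=<id>;r=<k>``.
    """
    with open(path, "w") as fh:
        for batch in batches:
            rpb = batch.reads_per_barcode
            for m in range(batch.n_molecules):
                bc = batch.barcodes[m]
                clone = batch.clone_ids[m]
                for k in range(rpb):
                    seq = decode_seq(batch.seqs[m * rpb + k])
                    fh.write(
                        f"@bc{bc};seg={batch.segment_id};start={batch.start};"
                        f"clone={clone};r={k}\n{seq}\n+\n{'I' * len(seq)}\n"
                    )


def write_reference_fasta(preset: LibraryPreset, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{preset.gene_id}\n")
        seq = preset.wt_seq
        for i in range(0, len(seq), 70):
            fh.write(seq[i: i + 70] + "\n")


def write_truth_tsv(
    library: Sequence[CloneGenotype],
    preset: LibraryPreset,
    effects: EffectTable,
    path,
) -> None:
    """Ground-truth table: one row per planted mutation (clone_id, position,
    wt_codon, mut_codon, multiplier)."""
    with open(path, "w") as fh:
        fh.write("clone_id\tposition\twt_codon\tmut_codon\tmultiplier\n")
        for clone in library:
            for pos, codon in clone.mutations:
                mult = effects.multiplier(pos, CODON_TO_AA[codon])
                fh.write(
                    f"{clone.clone_id}\t{pos}\t{preset.wt_codons[pos - 1]}\t{codon}\t{mult:g}\n"
                )


# ---------------------------------------------------------------------------
# Plating / phage / competition assays


def default_dilution_scheme(
    selective_fractions: Sequence[float] = (1e-1, 1e-2),
    total_fractions: Sequence[float] = (1e-6, 1e-7),
    volume_fraction: float = 1.0,
) -> list[tuple[str, float, float]]:
    """(medium, dilution, volume_fraction) rows for a tenfold-dilution plating."""
    scheme = [(SELECTIVE, d, volume_fraction) for d in selective_fractions]
    scheme += [(TOTAL, d, volume_fraction) for d in total_fractions]
    return scheme


def simulate_plating(
    true_rate: float,
    n_cells: float,
    dilution_scheme: Sequence[tuple[str, float, float]],
    seed: int,
    strain_id: str = "strain",
) -> PlatingExperiment:
    """Poisson colony counts: selective plates see true_rate x n_cells x
    plated fraction cells on average, total plates n_cells x plated fraction."""
    if not 0.0 <= true_rate <= 1.0:
        raise ValueError("true_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    plates = []
    for medium, dilution, volume_fraction in dilution_scheme:
        plated = dilution * volume_fraction
        mean = n_cells * plated * (true_rate if medium == SELECTIVE else 1.0)
        plates.append(
            PlateCount(
                medium=medium,
                dilution=dilution,
                volume_fraction=volume_fraction,
                colonies=int(rng.poisson(mean)),
            )
        )
    return PlatingExperiment(strain_id=strain_id, plates=tuple(plates))


def simulate_phage_survival(
    mu_crispr_wt: float,
    nu_noncrispr: float,
    variant: VariantPreset,
    n_colonies_assayed: int,
    seed: int,
) -> dict[str, PhageSurvivalRecord]:
    """Simulate phage-challenge survivor counts for wild type and one variant.

    Survivors from spacer acquisition are Poisson(fold x mu_crispr_wt) (fold=1
    for wild type), non-CRISPR escapers Poisson(nu_noncrispr) for both strains;
    PCR-positive colonies among those assayed follow a hypergeometric draw
    from the two survivor classes.
    """
    rng = np.random.default_rng(seed)
    records: dict[str, PhageSurvivalRecord] = {}
    for name, fold in (("wt", 1.0), (variant.name, variant.true_fold)):
        crispr = int(rng.poisson(fold * mu_crispr_wt))
        escaper = int(rng.poisson(nu_noncrispr))
        total = crispr + escaper
        n_assayed = min(n_colonies_assayed, total)
        n_pos = int(rng.hypergeometric(crispr, escaper, n_assayed)) if n_assayed else 0
        records[name] = PhageSurvivalRecord(
            strain_id=name,
            total_survivors=total,
            n_assayed=n_assayed,
            n_pcr_positive=n_pos,
        )
    return records


def simulate_competition(
    fitness_ratio: float,
    days: int,
    bottleneck_size: int,
    seed: int,
) -> np.ndarray:
    """Daily variant fraction of a 1:1 competition passage.

    Day 0 starts at 0.5; every passage draws a binomial bottleneck and then
    grows deterministically with the variant weighted by ``fitness_ratio``.
    Returns ``days + 1`` fractions.
    """
    if fitness_ratio < 0:
        raise ValueError("fitness_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    fractions = np.empty(days + 1)
    f = 0.5
    fractions[0] = f
    for day in range(1, days + 1):
        n_var = rng.binomial(bottleneck_size, f)
        weighted = n_var * fitness_ratio
        denom = weighted + (bottleneck_size - n_var)
        f = weighted / denom if denom > 0 else 0.0
        fractions[day] = f
    return fractions
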
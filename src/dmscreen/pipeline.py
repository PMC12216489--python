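"""In-memory end-to-end screen: simulate -> process -> statistics -> scores.

The CLI wraps this with file I/O; tests and the acceptance report call it
directly. Stage seeds are derived deterministically from the master seed so
stage-level reruns reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import dms_core, read_processing, site_scoring
from .read_processing import (
    CodonCountTable,
    ConsensusBatch,
    LibraryQCReport,
    ProcessingStats,
)
from .synthetic_data import (
    CloneGenotype,
    EffectTable,
    LibraryPreset,
    ScreenConfig,
    Segment,
    SelectionResult,
    child_seed,
    default_segments,
    sample_molecules,
    simulate_clone_library,
    simulate_reads,
    simulate_selection,
)


@dataclass
class ScreenResult:
    """Everything produced by one simulated screen replicate set."""

    preset: LibraryPreset
    library: list[CloneGenotype]
    selection: SelectionResult
    counts_selected: list[CodonCountTable]
    counts_unselected: list[CodonCountTable]
    preferences: pd.DataFrame  # replicate-aggregated (mean, renormalized)
    diffsel: pd.DataFrame  # replicate-aggregated (median)
    replicate_preferences: list[pd.DataFrame]
    replicate_diffsel: list[pd.DataFrame]
    qc: LibraryQCReport | None
    stats: ProcessingStats
    score_table: pd.DataFrame
    top_substitutions: list[site_scoring.TopSubstitution]
    wt_aa: tuple[str, ...]


def process_sample(
    batches,
    wt_codons: Sequence[str],
    sample_id: str,
    min_reads_per_barcode: int = read_processing.MIN_READS_PER_BARCODE,
    stats_out: ProcessingStats | None = None,
) -> tuple[CodonCountTable, list[ConsensusBatch]]:
    """Consensus-call simulated read batches and tally codon counts."""
    consensus = [
        read_processing.consensus_calls(b, min_reads_per_barcode, stats_out)
        for b in batches
    ]
    table = read_processing.count_codons(consensus, wt_codons, sample_id=sample_id)
    return table, consensus


def run_screen(
    preset: LibraryPreset,
    effects: EffectTable,
    config: ScreenConfig,
    depth: int,
    seed: int,
    n_replicates: int = 1,
    segments: Sequence[Segment] | None = None,
    pseudocount: float = dms_core.DEFAULT_PSEUDOCOUNT,
    min_reads_per_barcode: int = read_processing.MIN_READS_PER_BARCODE,
    top_k: int = 8,
    run_qc: bool = True,
) -> ScreenResult:
    """Simulate a full selection screen and score its sites.

    ``depth`` is the number of sequencing molecules sampled per segment and
    sample. Each replicate reuses the library but redraws selection,
    molecule sampling and sequencing.
    """
    if segments is None:
        segments = default_segments(preset.L)
    library = simulate_clone_library(preset, child_seed(seed, "library"))
    wt_aa = preset.wt_aa

    stats = ProcessingStats()
    counts_sel: list[CodonCountTable] = []
    counts_unsel: list[CodonCountTable] = []
    rep_prefs: list[pd.DataFrame] = []
    rep_diffsel: list[pd.DataFrame] = []
    selection: SelectionResult | None = None
    qc: LibraryQCReport | None = None

    for rep in range(n_replicates):
        tag = f"rep{rep}"
        selection = simulate_selection(
            library, preset, effects, config, seed=child_seed(seed, f"selection-{tag}")
        )
        tables = {}
        for sample, clone_counts in (
            ("selected", selection.selected),
            ("unselected", selection.unselected),
        ):
            molecules = sample_molecules(
                clone_counts, depth, child_seed(seed, f"molecules-{sample}-{tag}")
            )
            batches = simulate_reads(
                molecules, library, preset, config, segments=segments,
                seed=child_seed(seed, f"reads-{sample}-{tag}"),
            )
            table, consensus = process_sample(
                batches, preset.wt_codons, f"{sample}-{tag}",
                min_reads_per_barcode=min_reads_per_barcode, stats_out=stats,
            )
            tables[sample] = table
            if sample == "unselected" and rep == 0 and run_qc:
                _, genotypes = read_processing.reconstruct_clone_genotypes(
                    consensus, preset.L
                )
                qc = read_processing.library_qc(genotypes, preset.wt_codons)
        counts_sel.append(tables["selected"])
        counts_unsel.append(tables["unselected"])

        sel_aa = dms_core.aggregate_to_aa(dms_core.to_rpm(tables["selected"]))
        unsel_aa = dms_core.aggregate_to_aa(dms_core.to_rpm(tables["unselected"]))
        enr = dms_core.enrichment(sel_aa.values, unsel_aa.values, pseudocount)
        rep_prefs.append(dms_core.preferences(enr))
        rep_diffsel.append(
            dms_core.differential_selection(
                sel_aa.values, unsel_aa.values, wt_aa, pseudocount
            )
        )

    prefs, diffsel = dms_core.aggregate_replicates(rep_prefs, rep_diffsel)
    se = site_scoring.shannon_entropy(prefs)
    summaries = site_scoring.site_diffsel_summaries(diffsel, wt_aa)
    score_table = site_scoring.composite_score(
        se, summaries["pos_sum_diffsel"], summaries["max_diffsel"]
    )
    top = site_scoring.select_top_substitutions(score_table, diffsel, wt_aa, k=top_k)
    assert selection is not None
    return ScreenResult(
        preset=preset,
        library=library,
        selection=selection,
        counts_selected=counts_sel,
        counts_unselected=counts_unsel,
        preferences=prefs,
        diffsel=diffsel,
        replicate_preferences=rep_prefs,
        replicate_diffsel=rep_diffsel,
        qc=qc,
        stats=stats,
        score_table=score_table,
        top_substitutions=top,
        wt_aa=wt_aa,
    )
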
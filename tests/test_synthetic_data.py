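from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dmscreen import synthetic_data as sd
from dmscreen.assay_stats import SELECTIVE, TOTAL, acquisition_rate
from dmscreen.codons import CODON_TO_AA, CODONS


class TestPresets:
    def test_builtin_presets(self):
        for name, L, lam in [
            ("cas1-like", 289, 1.8), ("cas2-like", 113, 1.3), ("csn2-like", 220, 1.5),
        ]:
            p = sd.get_preset(name)
            assert p.L == L
            assert p.lambda_mut == lam
            assert len(p.wt_codons) == L

    def test_preset_override(self):
        p = sd.get_preset("cas1-like", n_clones=123)
        assert p.n_clones == 123

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown library preset"):
            sd.get_preset("nope")

    def test_variant_presets_planted_folds(self):
        expected = {
            "YT-oligo": 3.9, "MYT-oligo": 5.0, "T-phage": 3.0,
            "YT-phage": 5.0, "MYT-phage": 7.0, "YT-ecoli": 1.7, "MYT-ecoli": 1.6,
        }
        for name, fold in expected.items():
            assert sd.get_variant_preset(name).true_fold == fold

    def test_invalid_preset_fields(self):
        with pytest.raises(ValueError):
            sd.LibraryPreset("x", 0, (), 1.0, 10)
        with pytest.raises(ValueError):
            sd.LibraryPreset("x", 1, ("ATG",), -1.0, 10)
        with pytest.raises(ValueError):
            sd.LibraryPreset("x", 2, ("ATG", "XXX"), 1.0, 10)


class TestCloneLibrary:
    def test_lambda_zero_gives_wt_clones(self, tiny_preset):
        preset = sd.LibraryPreset("z", 6, tiny_preset.wt_codons, 0.0, 200)
        clones = sd.simulate_clone_library(preset, seed=3)
        assert all(c.n_mutations == 0 for c in clones)

    def test_rejects_degenerate_lambda(self, tiny_preset):
        preset = sd.LibraryPreset("d", 6, tiny_preset.wt_codons, 7.0, 10)
        with pytest.raises(ValueError, match="degenerate"):
            sd.simulate_clone_library(preset, seed=0)

    def test_deterministic_given_seed(self, small_preset):
        a = sd.simulate_clone_library(small_preset, seed=7)
        b = sd.simulate_clone_library(small_preset, seed=7)
        assert a == b
        c = sd.simulate_clone_library(small_preset, seed=8)
        assert a != c

    def test_mutations_valid(self, small_preset):
        clones = sd.simulate_clone_library(small_preset, seed=5)
        for clone in clones:
            positions = [p for p, _ in clone.mutations]
            assert len(positions) == len(set(positions))
            for pos, codon in clone.mutations:
                assert 1 <= pos <= small_preset.L
                assert codon != small_preset.wt_codons[pos - 1]
                assert codon in CODONS

    def test_mean_load_matches_poisson_rate(self):
        # empirical mean within 3 sqrt(lambda/n) of 1.8 at n=10,000
        preset = sd.get_preset("cas1-like")
        clones = sd.simulate_clone_library(preset, seed=42)
        mean = np.mean([c.n_mutations for c in clones])
        assert abs(mean - 1.8) < 3 * np.sqrt(1.8 / 10_000)

    def test_variance_matches_poisson(self):
        preset = sd.get_preset("cas2-like")
        clones = sd.simulate_clone_library(preset, seed=9)
        loads = np.array([c.n_mutations for c in clones])
        # Poisson: var = lambda; sampling SE of the variance ~ lambda*sqrt(2/n)
        assert abs(loads.var() - 1.3) < 3 * 1.3 * np.sqrt(2 / len(loads))

    def test_positions_uniform_chisquare(self):
        preset = sd.get_preset("cas1-like")
        clones = sd.simulate_clone_library(preset, seed=1)
        tally = np.zeros(preset.L)
        for clone in clones:
            for pos, _ in clone.mutations:
                tally[pos - 1] += 1
        _, p = stats.chisquare(tally)
        assert p > 0.001


class TestSelectionProbability:
    def test_wild_type_clone(self, tiny_preset):
        clone = sd.CloneGenotype(0, ())
        p = sd.clone_selection_probability(clone, tiny_preset.wt_codons, sd.EffectTable(), 1e-5)
        assert p == 1e-5

    def test_single_enhancer(self, tiny_preset):
        # position 2 wt is AAA (K); CGT is R
        clone = sd.CloneGenotype(0, ((2, "CGT"),))
        effects = sd.EffectTable({(2, "R"): 5.0})
        p = sd.clone_selection_probability(clone, tiny_preset.wt_codons, effects, 1e-5)
        assert p == pytest.approx(5e-5)

    def test_null_effect_dominates(self, tiny_preset):
        clone = sd.CloneGenotype(0, ((2, "CGT"), (4, "CAT")))
        effects = sd.EffectTable({(2, "R"): 5.0, (4, "H"): 0.0})
        p = sd.clone_selection_probability(clone, tiny_preset.wt_codons, effects, 1e-5)
        assert p == 0.0

    def test_synonymous_change_is_neutral(self, tiny_preset):
        # position 3 wt CTG (L); CTA is also L; a planted effect on L is ignored
        clone = sd.CloneGenotype(0, ((3, "CTA"),))
        effects = sd.EffectTable({(3, "L"): 99.0})
        p = sd.clone_selection_probability(clone, tiny_preset.wt_codons, effects, 1e-5)
        assert p == 1e-5

    def test_probability_capped_at_one(self, tiny_preset):
        clone = sd.CloneGenotype(0, ((2, "CGT"),))
        effects = sd.EffectTable({(2, "R"): 1e9})
        assert sd.clone_selection_probability(clone, tiny_preset.wt_codons, effects, 0.5) == 1.0

    @given(mult=st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_scales_linearly_below_cap(self, mult):
        wt = ("ATG", "AAA")
        clone = sd.CloneGenotype(0, ((2, "CGT"),))
        effects = sd.EffectTable({(2, "R"): mult})
        p = sd.clone_selection_probability(clone, wt, effects, 1e-6)
        assert p == pytest.approx(min(1.0, 1e-6 * mult))

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            sd.EffectTable({(1, "A"): -0.5})


class TestSimulateSelection:
    def test_neutral_screen_fraction_near_base_rate(self, small_preset):
        cfg = sd.ScreenConfig(base_rate=1e-3, n_cells=1_000_000, seed=0)
        library = sd.simulate_clone_library(small_preset, seed=1)
        res = sd.simulate_selection(library, small_preset, sd.EffectTable(), cfg)
        frac = res.selected.sum() / res.unselected.sum()
        se = np.sqrt(1e-3 / 1_000_000)
        assert abs(frac - 1e-3) < 3 * se

    def test_planted_enhancer_frequency_ratio(self, small_preset):
        # one clone at ~1% frequency with multiplier 10: its selected:unselected
        # ratio should be ~10x that of the wild-type clones (binomial thinning)
        wt = small_preset.wt_codons
        clones = [sd.CloneGenotype(0, ((5, "CGT"),))] + [
            sd.CloneGenotype(i, ()) for i in range(1, 100)
        ]
        assert CODON_TO_AA["CGT"] != CODON_TO_AA[wt[4]]
        effects = sd.EffectTable({(5, CODON_TO_AA["CGT"]): 10.0})
        cfg = sd.ScreenConfig(base_rate=1e-3, n_cells=5_000_000, seed=3)
        res = sd.simulate_selection(clones, small_preset, effects, cfg)
        enh_ratio = res.selected[0] / res.unselected[0]
        wt_ratio = res.selected[1:].sum() / res.unselected[1:].sum()
        assert enh_ratio / wt_ratio == pytest.approx(10.0, rel=0.15)

    def test_all_zero_effects_and_base_rate(self, small_preset):
        library = sd.simulate_clone_library(small_preset, seed=2)
        cfg = sd.ScreenConfig(base_rate=0.0, n_cells=10_000, seed=0)
        with pytest.warns(UserWarning, match="underpowered"):
            res = sd.simulate_selection(library, small_preset, sd.EffectTable(), cfg)
        assert res.selected.sum() == 0

    def test_determinism(self, small_preset):
        library = sd.simulate_clone_library(small_preset, seed=2)
        cfg = sd.ScreenConfig(base_rate=1e-2, n_cells=100_000, seed=11)
        a = sd.simulate_selection(library, small_preset, sd.EffectTable(), cfg)
        b = sd.simulate_selection(library, small_preset, sd.EffectTable(), cfg)
        assert np.array_equal(a.selected, b.selected)
        assert np.array_equal(a.unselected, b.unselected)


class TestSimulateReads:
    def test_zero_error_reads_match_clone(self, tiny_preset):
        clone = sd.CloneGenotype(0, ((2, "CGT"),))
        cfg = sd.ScreenConfig(seq_error_rate=0.0, reads_per_barcode=3, seed=0)
        segs = [sd.Segment("seg1", 1, 6)]
        batches = sd.simulate_reads(np.array([5]), [clone], tiny_preset, cfg, segments=segs)
        (batch,) = batches
        expected = "ATG" + "CGT" + "CTGGATTTTGGC"
        from dmscreen.codons import decode_seq

        for r in range(batch.n_reads):
            assert decode_seq(batch.seqs[r]) == expected

    def test_read_and_barcode_counting(self, tiny_preset):
        cfg = sd.ScreenConfig(seq_error_rate=0.0, reads_per_barcode=3, seed=0)
        clones = [sd.CloneGenotype(i, ()) for i in range(10)]
        counts = np.full(10, 10)  # 100 molecules
        batches = sd.simulate_reads(counts, clones, tiny_preset, cfg,
                                    segments=[sd.Segment("seg1", 1, 6)])
        (batch,) = batches
        assert batch.n_reads == 300
        assert len(np.unique(batch.barcodes)) == 100

    def test_error_rate_mean_mismatches(self):
        # 150-nt reads at e=1e-3: mean mismatches/read ~ 0.15 over >= 10,000 reads
        preset = sd.LibraryPreset("g", 50, sd._random_wt_codons(50, 7), 0.0, 1)
        clones = [sd.CloneGenotype(0, ())]
        cfg = sd.ScreenConfig(seq_error_rate=1e-3, reads_per_barcode=3, seed=21)
        batches = sd.simulate_reads(np.array([4000]), clones, preset, cfg,
                                    segments=[sd.Segment("seg1", 1, 50)])
        (batch,) = batches
        from dmscreen.codons import encode_seq

        wt = encode_seq(preset.wt_seq)
        mismatches = (batch.seqs != wt[None, :]).sum()
        mean = mismatches / batch.n_reads
        assert batch.n_reads >= 10_000
        assert mean == pytest.approx(0.15, abs=0.02)

    def test_rejects_gapped_segments(self, tiny_preset):
        cfg = sd.ScreenConfig(seed=0)
        segs = [sd.Segment("a", 1, 2), sd.Segment("b", 4, 6)]
        with pytest.raises(ValueError, match="uncovered"):
            sd.simulate_reads(np.array([1]), [sd.CloneGenotype(0, ())], tiny_preset,
                              cfg, segments=segs)

    def test_default_segments_tile(self):
        for L in (1, 7, 113, 289):
            segs = sd.default_segments(L)
            sd.validate_segments(segs, L)
        assert len(sd.default_segments(289)) == 5

    def test_determinism(self, tiny_preset):
        cfg = sd.ScreenConfig(seq_error_rate=0.01, reads_per_barcode=2, seed=0)
        clones = [sd.CloneGenotype(0, ((3, "AAA"),))]
        kw = dict(segments=[sd.Segment("seg1", 1, 6)], seed=5)
        a = sd.simulate_reads(np.array([50]), clones, tiny_preset, cfg, **kw)
        b = sd.simulate_reads(np.array([50]), clones, tiny_preset, cfg, **kw)
        assert np.array_equal(a[0].seqs, b[0].seqs)


class TestSimulatePlating:
    SCHEME = [(SELECTIVE, 1e-2, 1.0), (TOTAL, 1e-7, 1.0)]

    def test_zero_rate_zero_selective_colonies(self):
        exp = sd.simulate_plating(0.0, 1e8, self.SCHEME, seed=0)
        for plate in exp.plates_for(SELECTIVE):
            assert plate.colonies == 0

    def test_expected_counts(self):
        # true_rate 1e-5, n=1e8, fractions 1e-2 / 1e-7 -> both means 10
        counts = []
        for seed in range(400):
            exp = sd.simulate_plating(1e-5, 1e8, self.SCHEME, seed=seed)
            counts.append([p.colonies for p in exp.plates])
        means = np.mean(counts, axis=0)
        assert means == pytest.approx([10, 10], abs=0.5)

    def test_rate_estimator_unbiased_over_seeds(self):
        scheme = sd.default_dilution_scheme()
        ratios = []
        for seed in range(50):
            exp = sd.simulate_plating(1e-5, 1e8, scheme, seed=seed)
            ratios.append(acquisition_rate(exp).rate / 1e-5)
        assert 0.9 < np.mean(ratios) < 1.1


class TestSimulatePhageSurvival:
    def test_fold_one_same_distribution(self):
        variant = sd.VariantPreset("null", 1.0)
        totals_wt, totals_var = [], []
        for seed in range(300):
            recs = sd.simulate_phage_survival(70, 50, variant, 12, seed=seed)
            totals_wt.append(recs["wt"].total_survivors)
            totals_var.append(recs["null"].total_survivors)
        assert np.mean(totals_var) == pytest.approx(np.mean(totals_wt), rel=0.05)

    def test_no_escapers_all_pcr_positive(self):
        variant = sd.VariantPreset("v", 2.0)
        for seed in range(20):
            recs = sd.simulate_phage_survival(70, 0, variant, 12, seed=seed)
            for rec in recs.values():
                assert rec.n_pcr_positive == rec.n_assayed

    def test_wt_pcr_fraction_matches_class_mixture(self):
        # with mu=70, nu=50 the expected wt PCR-positive fraction is 7/12
        variant = sd.VariantPreset("v", 7.0)
        fracs = [
            sd.simulate_phage_survival(70, 50, variant, 12, seed=s)["wt"].pcr_positive_fraction
            for s in range(400)
        ]
        assert np.mean(fracs) == pytest.approx(7 / 12, abs=0.02)


class TestSimulateCompetition:
    def test_day_zero_half(self):
        series = sd.simulate_competition(1.0, 6, 1000, seed=0)
        assert series[0] == 0.5
        assert len(series) == 7

    def test_neutral_large_bottleneck_stays_near_half(self):
        series = sd.simulate_competition(1.0, 6, 10_000_000, seed=1)
        assert np.allclose(series, 0.5, atol=0.01)

    def test_zero_fitness_extinct_day_one(self):
        series = sd.simulate_competition(0.0, 6, 1000, seed=2)
        assert series[1] == 0.0
        assert series[-1] == 0.0

    def test_deterministic_limit_closed_form(self):
        # fitness 1.1 for 6 days: 0.5*1.1^6 / (0.5*1.1^6 + 0.5)
        series = sd.simulate_competition(1.1, 6, 50_000_000, seed=3)
        expected = 0.5 * 1.1**6 / (0.5 * 1.1**6 + 0.5)
        assert series[-1] == pytest.approx(expected, abs=0.002)
        assert expected == pytest.approx(0.639, abs=0.001)


class TestChildSeed:
    def test_stable_and_stage_dependent(self):
        assert sd.child_seed(1, "a") == sd.child_seed(1, "a")
        assert sd.child_seed(1, "a") != sd.child_seed(1, "b")
        assert sd.child_seed(1, "a") != sd.child_seed(2, "a")
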
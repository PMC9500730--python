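"""Fragment alignment, the shift equations, filtration, scoring, dedup."""

import numpy as np
import pytest

from swath_annotator.annotate import (AlignedFragment, Identification,
                                      align_fragments, annotate_run,
                                      apply_filtration, dedup_redundant,
                                      identifications_to_frame, rt_shift,
                                      score, width_shift)
from swath_annotator.params import FiltrationParams
from swath_annotator.peaks import PeakFeature
from swath_annotator.screen import CandidatePrecursor, screen_precursors


class TestShiftEquations:
    def test_rt_shift_values(self):
        assert rt_shift(10.0, 10.0) == 0.0
        assert rt_shift(10.0, 10.001) == pytest.approx(1.0e-4)
        assert rt_shift(10.0, 10.02) == pytest.approx(2.0e-3)
        # against the published gate
        p = FiltrationParams()
        assert rt_shift(10.0, 10.001) < p.rt_shift_max
        assert rt_shift(10.0, 10.02) >= p.rt_shift_max

    def test_width_shift_values(self):
        assert width_shift(0.10, 0.10) == 0.0
        assert width_shift(0.10, 0.12) == pytest.approx(0.20)
        assert width_shift(0.10, 0.115) == pytest.approx(0.15)
        p = FiltrationParams()
        assert width_shift(0.10, 0.115) < p.width_shift_max
        assert width_shift(0.10, 0.12) >= p.width_shift_max

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rt_shift(0.0, 1.0)
        with pytest.raises(ValueError):
            width_shift(-0.1, 0.1)

    def test_shifts_are_scale_invariant(self):
        for c in (0.1, 3.0, 1e4):
            assert rt_shift(5.0 * c, 5.01 * c) == pytest.approx(rt_shift(5.0, 5.01))
            assert width_shift(0.1 * c, 0.13 * c) == pytest.approx(width_shift(0.1, 0.13))


def _aligned(height, rt_s=0.0, width_s=0.0, tag="F", lib_rel=50.0,
             blank_ratio=float("inf"), rt=5.0):
    return AlignedFragment(
        library_mz=100.0 + height % 97, tag=tag, library_relative_intensity=lib_rel,
        peak=PeakFeature(apex_rt=rt, height=height, fwhm=0.1),
        rt_shift=rt_s, width_shift=width_s, blank_ratio=blank_ratio)


class TestFiltration:
    def test_relative_intensity_recomputed_over_survivors(self):
        frags = [_aligned(1000.0, tag="D"), _aligned(400.0), _aligned(30.0)]
        apply_filtration(frags)
        assert [f.retained for f in frags] == [True, True, False]
        assert [f.observed_relative_intensity for f in frags[:2]] == \
               pytest.approx([100.0, 40.0])
        assert frags[2].observed_relative_intensity == pytest.approx(3.0)

    def test_all_failing_shift_gates_leaves_nothing(self):
        frags = [_aligned(1000.0, rt_s=0.01), _aligned(500.0, width_s=0.5)]
        apply_filtration(frags)
        assert not any(f.retained for f in frags)

    def test_single_survivor_is_its_own_base_peak(self):
        frags = [_aligned(123.0, tag="D")]
        apply_filtration(frags)
        assert frags[0].retained
        assert frags[0].observed_relative_intensity == pytest.approx(100.0)

    def test_blank_ratio_gate_is_inclusive(self):
        exactly5 = [_aligned(100.0, tag="D", blank_ratio=5.0)]
        apply_filtration(exactly5)
        assert exactly5[0].retained
        below = [_aligned(100.0, tag="D", blank_ratio=4.99)]
        apply_filtration(below)
        assert not below[0].retained

    def test_tightening_thresholds_is_monotone(self):
        rng = np.random.default_rng(3)
        frags = [_aligned(float(h), rt_s=float(r), width_s=float(w))
                 for h, r, w in zip(rng.uniform(10, 1000, 30),
                                    rng.uniform(0, 0.003, 30),
                                    rng.uniform(0, 0.4, 30))]
        apply_filtration(frags)
        loose = {id(f) for f in frags if f.retained}
        apply_filtration(frags, FiltrationParams(rt_shift_max=0.0008,
                                                 width_shift_max=0.1,
                                                 rel_int_min_pct=10.0))
        tight = {id(f) for f in frags if f.retained}
        assert tight <= loose


def _candidate(ppm=1.0, window=3, rt=5.0):
    return CandidatePrecursor(
        compound_id="C", splash_id="S", adduct_name="[M+H]+", library_mz=205.0,
        observed_mz=205.0, ppm_error=ppm, window_index=window,
        peak=PeakFeature(apex_rt=rt, height=1e4, fwhm=0.118),
        blank_ratio=float("inf"), snr=300.0)


def _ident(cid, frags, ppm=1.0, adduct="[M+H]+", window=3):
    cand = _candidate(ppm=ppm, window=window)
    cand.compound_id = cid
    cand.splash_id = f"splash-{cid}"
    cand.adduct_name = adduct
    ident = Identification(compound_id=cid, splash_id=cand.splash_id,
                           adducts=[adduct], candidate=cand, fragments=frags)
    ident.score = score(ident)
    return ident


class TestScore:
    def test_perfect_recovery_scores_one(self):
        frags = [_aligned(1000.0, tag="D", lib_rel=100.0),
                 _aligned(500.0, lib_rel=50.0)]
        apply_filtration(frags)
        ident = _ident("C1", frags)
        assert score(ident) == pytest.approx(1.0)

    def test_d_only_recovery_matches_formula(self):
        # library: D at 100, one missed F at 60 -> coverage w_D / W
        frags = [_aligned(1000.0, tag="D", lib_rel=100.0),
                 AlignedFragment(library_mz=146.0, tag="F",
                                 library_relative_intensity=60.0)]
        apply_filtration(frags)
        ident = _ident("C1", frags)
        expected = 0.5 * (100.0 / 160.0) + 0.3 + 0.2
        assert score(ident) == pytest.approx(expected)

    def test_no_retained_fragments_scores_nan(self):
        frags = [AlignedFragment(library_mz=1.0, tag="D",
                                 library_relative_intensity=100.0)]
        ident = _ident("C1", frags)
        assert np.isnan(score(ident))


class TestDedup:
    def test_shared_fragment_awarded_to_smaller_ppm_error(self):
        f1 = [_aligned(1000.0, tag="D", lib_rel=100.0)]
        f2 = [_aligned(1000.0, tag="D", lib_rel=100.0),
              _aligned(800.0, tag="D", lib_rel=90.0)]
        f2[0].library_mz = f1[0].library_mz  # same XIC claim
        apply_filtration(f1)
        apply_filtration(f2)
        a = _ident("A", f1, ppm=1.0)
        b = _ident("B", f2, ppm=6.0)
        out = dedup_redundant([a, b])
        kept = {i.compound_id: i for i in out}
        assert "A" in kept and kept["A"].fragments[0].retained
        # B lost the contested fragment but keeps its second D
        assert "B" in kept
        assert not kept["B"].fragments[0].retained

    def test_disjoint_fragment_sets_untouched(self):
        f1 = [_aligned(1000.0, tag="D")]
        f2 = [_aligned(900.0, tag="D")]
        f1[0].library_mz, f2[0].library_mz = 100.0, 200.0
        apply_filtration(f1)
        apply_filtration(f2)
        out = dedup_redundant([_ident("A", f1), _ident("B", f2)])
        assert {i.compound_id for i in out} == {"A", "B"}
        assert all(f.retained for i in out for f in i.fragments)

    def test_same_compound_adducts_merge(self):
        f1 = [_aligned(1000.0, tag="D")]
        f2 = [_aligned(300.0, tag="D")]
        apply_filtration(f1)
        apply_filtration(f2)
        a = _ident("A", f1, adduct="[M+H]+")
        b = _ident("A", f2, adduct="[M+Na]+")
        out = dedup_redundant([a, b])
        assert len(out) == 1
        assert out[0].adducts == ["[M+H]+", "[M+Na]+"]


class TestPipeline:
    def test_spiked_compounds_recovered_end_to_end(self, sim_pair,
                                                   identifications_seed7):
        spiked = set(sim_pair["truth"].spiked_ids)
        found = {i.compound_id for i in identifications_seed7}
        assert spiked <= found

    def test_aligned_fragments_of_spiked_compound_pass_gates(self, sim_pair,
                                                             default_params):
        entries = {e.compound_id: e for e in sim_pair["entries"]}
        cands = screen_precursors(sim_pair["sample"], sim_pair["blank"],
                                  sim_pair["entries"], default_params)
        spiked = set(sim_pair["truth"].spiked_ids)
        checked = 0
        for cand in cands:
            if cand.compound_id not in spiked:
                continue
            frags = align_fragments(cand, sim_pair["sample"],
                                    entries[cand.compound_id], default_params,
                                    blank=sim_pair["blank"])
            detected = [f for f in frags if f.peak is not None]
            assert detected
            ok = [f for f in detected
                  if f.rt_shift < default_params.rt_shift_max
                  and f.width_shift < default_params.width_shift_max]
            assert len(ok) >= 0.5 * len(detected)
            checked += 1
        assert checked >= len(spiked)

    def test_self_blank_yields_nothing(self, sim_pair, default_params):
        out = annotate_run(sim_pair["sample"], sim_pair["sample"],
                           sim_pair["entries"], default_params)
        assert out == []

    def test_empty_library_yields_nothing(self, sim_pair, default_params):
        assert annotate_run(sim_pair["sample"], sim_pair["blank"], [],
                            default_params) == []

    def test_every_identification_has_a_retained_main_daughter(
            self, identifications_seed7):
        assert identifications_seed7
        for ident in identifications_seed7:
            assert ident.has_d
            assert ident.n_retained >= 1

    def test_pipeline_is_deterministic(self, sim_pair, default_params,
                                       identifications_seed7):
        again = annotate_run(sim_pair["sample"], sim_pair["blank"],
                             sim_pair["entries"], default_params)
        t1 = identifications_to_frame(identifications_seed7).to_csv(index=False)
        t2 = identifications_to_frame(again).to_csv(index=False)
        assert t1 == t2
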
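"""Library parsing and curation into the DIA transition database."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swath_annotator.errors import (ConfigurationError,
                                    DegenerateSpectrumError, ParseError)
from swath_annotator.ionization import SwathWindowScheme, default_adducts
from swath_annotator.speclib import (CuratedFragment, DiaLibraryEntry,
                                     LibrarySpectrum, Rejection,
                                     build_dia_entry, collapse_near_duplicates,
                                     curate_spectrum, normalize_relative,
                                     parse_spectra, read_dia_library,
                                     tag_and_filter, write_dia_library,
                                     write_spectra)

MSP_TWO_RECORDS = """\
NAME: L-Tryptophan
SPLASH: splash10-0002-0900000000-aaaa
COMPOUND_ID: HMDB0000929
EXACTMASS: 204.08988
IONMODE: positive
RESOLUTION: high
COLLISION_ENERGY: 35
Num Peaks: 3
146.0600 999
188.0706 450
118.0651 30

NAME: Compound B
SPLASH: splash10-0002-0900000000-bbbb
COMPOUND_ID: HMDB0000002
EXACTMASS: 180.06339
IONMODE: positive
RESOLUTION: high
Num Peaks: 2
59.0139 100
89.0244 55
"""


def _spectrum(fragments, mass=204.08988, polarity="positive"):
    return LibrarySpectrum(splash_id="s", compound_id="c", compound_name="x",
                           neutral_mass=mass, polarity=polarity,
                           fragments=fragments)


class TestParsing:
    def test_msp_fixture_parses_two_records(self, tmp_path):
        p = tmp_path / "lib.msp"
        p.write_text(MSP_TWO_RECORDS)
        specs = parse_spectra(p, "msp")
        assert len(specs) == 2
        assert specs[0].splash_id == "splash10-0002-0900000000-aaaa"
        assert specs[0].neutral_mass == pytest.approx(204.08988)
        assert len(specs[0].fragments) == 3
        assert specs[1].collision_energy is None

    def test_csv_dialect_equivalent_to_msp(self, tmp_path):
        msp = tmp_path / "lib.msp"
        msp.write_text(MSP_TWO_RECORDS)
        specs = parse_spectra(msp, "msp")
        csv_path = tmp_path / "lib.csv"
        write_spectra(specs, csv_path, "csv")
        again = parse_spectra(csv_path, "csv")
        assert len(again) == len(specs)
        for a, b in zip(specs, again):
            assert (a.splash_id, a.compound_id, a.polarity) == \
                   (b.splash_id, b.compound_id, b.polarity)
            assert a.neutral_mass == pytest.approx(b.neutral_mass)
            assert sorted(a.fragments) == pytest.approx(sorted(b.fragments))

    def test_json_round_trip_preserves_curated_entries(self, tmp_path):
        msp = tmp_path / "lib.msp"
        msp.write_text(MSP_TWO_RECORDS)
        specs = parse_spectra(msp, "msp")
        jp = tmp_path / "lib.json"
        write_spectra(specs, jp, "json")
        again = parse_spectra(jp, "json")
        scheme = SwathWindowScheme()
        adducts = default_adducts("positive")
        for a, b in zip(specs, again):
            ea = build_dia_entry(a, adducts, scheme)
            eb = build_dia_entry(b, adducts, scheme)
            assert ea.fragments == eb.fragments
            assert [(p.adduct_name, p.window_index) for p in ea.precursors] == \
                   [(p.adduct_name, p.window_index) for p in eb.precursors]

    def test_negative_intensity_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.json"
        import json
        p.write_text(json.dumps([{
            "splash_id": "s", "compound_id": "c", "neutral_mass": 100.0,
            "polarity": "positive", "fragments": [[50.0, -3.0]]}]))
        with pytest.raises(ParseError, match="record 0"):
            parse_spectra(p, "json")

    def test_zero_fragment_records_are_dropped(self, tmp_path):
        import json
        p = tmp_path / "empty.json"
        p.write_text(json.dumps([
            {"splash_id": "a", "compound_id": "c1", "neutral_mass": 100.0,
             "polarity": "positive", "fragments": []},
            {"splash_id": "b", "compound_id": "c2", "neutral_mass": 100.0,
             "polarity": "positive", "fragments": [[60.0, 5.0]]}]))
        specs = parse_spectra(p, "json")
        assert [s.splash_id for s in specs] == ["b"]

    def test_unknown_dialect_is_a_configuration_error(self, tmp_path):
        with pytest.raises(ConfigurationError):
            parse_spectra(tmp_path / "x", "mgf")

    def test_biospecimen_predicate_filters(self, tmp_path):
        p = tmp_path / "lib.msp"
        p.write_text(MSP_TWO_RECORDS)
        specs = parse_spectra(p, "msp", where=lambda s: s.compound_id == "HMDB0000929")
        assert len(specs) == 1


class TestNormalization:
    def test_proportional_scaling(self):
        rel = normalize_relative(_spectrum([(100.0, 200.0), (110.0, 100.0), (120.0, 10.0)]))
        assert [r for _, r in rel] == pytest.approx([100.0, 50.0, 5.0])

    def test_ties_both_reach_base_peak(self):
        rel = normalize_relative(_spectrum([(100.0, 7.0), (110.0, 7.0)]))
        assert [r for _, r in rel] == pytest.approx([100.0, 100.0])

    def test_single_fragment_is_base_peak(self):
        rel = normalize_relative(_spectrum([(100.0, 42.0)]))
        assert [r for _, r in rel] == pytest.approx([100.0])

    def test_all_zero_intensities_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            normalize_relative(_spectrum([(100.0, 0.0), (110.0, 0.0)]))


class TestTagAndFilter:
    def test_published_thresholds(self):
        out = tag_and_filter([(100.0, 100.0), (110.0, 60.0), (120.0, 3.0)])
        assert [(f.relative_intensity, f.tag) for f in out] == [(100.0, "D"), (60.0, "F")]

    def test_multiple_main_daughters_allowed(self):
        out = tag_and_filter([(100.0, 100.0), (110.0, 80.0)])
        assert [f.tag for f in out] == ["D", "D"]

    def test_boundaries_are_strict(self):
        out = tag_and_filter([(100.0, 100.0), (110.0, 75.0), (120.0, 5.0)])
        assert [(f.relative_intensity, f.tag) for f in out] == \
               [(100.0, "D"), (75.0, "F"), (5.0, "F")]


class TestCollapse:
    def test_repeated_transitions_with_slight_mass_shift(self):
        # 28 retained transitions of which 9 duplicate an existing m/z
        base = [100.0 + 3.0 * i for i in range(19)]
        dups = [m + 0.004 for m in base[:9]]
        frags = [CuratedFragment(m, 50.0, "F") for m in base] + \
                [CuratedFragment(m, 40.0, "F") for m in dups]
        assert len(frags) == 28
        out = collapse_near_duplicates(frags, mz_tol=0.01)
        assert len(out) == 19

    def test_no_op_when_all_separated(self):
        frags = [CuratedFragment(100.0 + i, 50.0 - i, "F") for i in range(5)]
        assert collapse_near_duplicates(frags, mz_tol=0.01) == frags

    def test_exact_duplicate_keeps_max_intensity(self):
        frags = [CuratedFragment(100.0, 40.0, "F"), CuratedFragment(100.0, 90.0, "D")]
        out = collapse_near_duplicates(frags, mz_tol=0.01)
        assert out == [CuratedFragment(100.0, 90.0, "D")]


@given(st.lists(st.tuples(st.floats(min_value=60.0, max_value=900.0),
                          st.floats(min_value=0.0, max_value=1000.0)),
                min_size=1, max_size=30))
@settings(derandomize=True, max_examples=60)
def test_curation_is_idempotent_and_contractive(fragments):
    if max(i for _, i in fragments) <= 0:
        return
    spec = _spectrum(fragments)
    once = curate_spectrum(spec)
    # retained count never exceeds input; all retained >= 5%
    assert len(once) <= len(fragments)
    assert all(f.relative_intensity >= 5.0 for f in once)
    # re-running the pipeline on its own output changes nothing
    spec2 = _spectrum([(f.mz, f.relative_intensity) for f in once])
    if once:
        twice = curate_spectrum(spec2)
        assert twice == sorted(once, key=lambda f: (-f.relative_intensity, f.mz))


class TestBuildEntry:
    def test_tryptophan_like_positive_entry_has_five_precursors(self):
        spec = _spectrum([(146.06, 999.0), (188.07, 450.0), (118.06, 90.0)])
        entry = build_dia_entry(spec, default_adducts("positive"), SwathWindowScheme())
        assert isinstance(entry, DiaLibraryEntry)
        assert len(entry.precursors) == 5
        for p in entry.precursors:
            lo, hi = SwathWindowScheme().window_bounds(p.window_index)
            assert lo <= p.mz <= hi
        assert entry.has_d

    def test_no_main_daughter_is_rejected_not_raised(self):
        spec = _spectrum([(146.06, 60.0), (188.07, 100.0)])
        # curate drops nothing here, but pass a fragment list without D
        frags = [CuratedFragment(146.06, 60.0, "F")]
        out = build_dia_entry(spec, default_adducts("positive"),
                              SwathWindowScheme(), fragments=frags)
        assert isinstance(out, Rejection)
        assert "D" in out.reason

    def test_all_adducts_out_of_range_is_rejected(self):
        spec = _spectrum([(146.06, 999.0)], mass=2000.0)
        out = build_dia_entry(spec, default_adducts("positive"), SwathWindowScheme())
        assert isinstance(out, Rejection)

    def test_polarity_mismatch_raises(self):
        spec = _spectrum([(146.06, 999.0)])
        with pytest.raises(ConfigurationError):
            build_dia_entry(spec, default_adducts("negative"), SwathWindowScheme())


def test_dia_database_round_trip_csv_and_json(tmp_path, library_seed7):
    _, entries = library_seed7
    for fmt, name in (("csv", "db.csv"), ("json", "db.json")):
        path = tmp_path / name
        write_dia_library(entries, path, fmt=fmt)
        back = read_dia_library(path)
        assert len(back) == len(entries)
        for a, b in zip(entries, back):
            assert a.compound_id == b.compound_id
            assert [p.adduct_name for p in a.precursors] == \
                   [p.adduct_name for p in b.precursors]
            assert [f.tag for f in a.fragments] == [f.tag for f in b.fragments]
            np.testing.assert_allclose([f.mz for f in a.fragments],
                                       [f.mz for f in b.fragments])


def test_every_curated_entry_has_a_main_daughter(library_seed7):
    _, entries = library_seed7
    assert entries and all(e.has_d for e in entries)
    for e in entries:
        rels = [f.relative_intensity for f in e.fragments]
        assert rels == sorted(rels, reverse=True)
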
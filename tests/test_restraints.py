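"""ISPA calibration, NOE classification and Watson-Crick restraints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptdna.duplex import build_duplex_spec
from ptdna.restraints import (
    DistanceRestraint,
    NoePeak,
    calibrate_distance,
    classify_exchangeable_series,
    classify_noe,
    generate_wc_restraints,
    pseudoatom_correction,
    read_restraint_table,
    restraint_counts,
    write_restraint_table,
)


class TestCalibration:
    def test_identity_calibration(self):
        assert calibrate_distance(100.0, 100.0) == pytest.approx(2.45)

    def test_sixth_root_scaling(self):
        # V = Vref/64 -> d = 2.45 * 64^(1/6) = 4.90
        assert calibrate_distance(100.0 / 64, 100.0) == pytest.approx(4.90)

    @pytest.mark.parametrize("v,vref", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_nonpositive_volumes_rejected(self, v, vref):
        with pytest.raises(ValueError):
            calibrate_distance(v, vref)

    @given(
        v1=st.floats(1e-3, 1e6),
        v2=st.floats(1e-3, 1e6),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing_and_scale_invariant(self, v1, v2, scale):
        vref = 1000.0
        d1 = calibrate_distance(v1, vref)
        d2 = calibrate_distance(v2, vref)
        if v1 < v2:
            assert d1 >= d2
        assert calibrate_distance(scale * v1, scale * vref) == pytest.approx(
            d1, rel=1e-9
        )


class TestClassification:
    @pytest.mark.parametrize(
        "intensity,exch,bounds",
        [
            ("strong", False, (1.8, 2.9)),
            ("medium", False, (1.8, 3.5)),
            ("weak", False, (1.8, 6.0)),
            ("strong", True, (1.8, 4.0)),
            ("medium", True, (1.8, 5.0)),
            ("weak", True, (1.8, 8.0)),
        ],
    )
    def test_class_bounds(self, intensity, exch, bounds):
        peak = NoePeak(2, "H8", 2, "H1'", exchangeable=exch, intensity=intensity)
        r = classify_noe(peak)
        assert (r.lower, r.upper) == bounds

    @pytest.mark.parametrize(
        "distance,upper", [(2.5, 2.9), (3.2, 3.5), (4.8, 6.0)]
    )
    def test_distance_thresholding(self, distance, upper):
        r = classify_noe(NoePeak(2, "H8", 3, "H1'"), distance)
        assert r.upper == upper

    def test_unclassifiable_peak_errors(self):
        with pytest.raises(ValueError):
            classify_noe(NoePeak(2, "H8", 3, "H1'"))

    def test_exchangeable_series_mixing_time_rules(self):
        mk = lambda mt, v: NoePeak(10, "H3", 11, "H2", v, mt, exchangeable=True)
        strong = classify_exchangeable_series([mk(50, 900.0), mk(200, 950.0)], 500.0)
        assert strong[0].intensity == "strong"
        medium = classify_exchangeable_series([mk(50, 100.0), mk(200, 400.0)], 500.0)
        assert medium[0].intensity == "medium"
        weak = classify_exchangeable_series([mk(200, 300.0)], 500.0)
        assert weak[0].intensity == "weak"
        assert classify_noe(weak[0]).upper == 8.0

    def test_every_restraint_has_valid_bounds(self):
        with pytest.raises(ValueError):
            DistanceRestraint(1, "H8", 2, "H1'", 1.5, 2.9)
        with pytest.raises(ValueError):
            DistanceRestraint(1, "H8", 2, "H1'", 3.0, 2.9)


class TestPseudoatom:
    def test_methyl_correction(self):
        r = DistanceRestraint(11, "M7", 10, "H8", 1.8, 6.0, label="weak")
        c = pseudoatom_correction(r)
        assert (c.lower, c.upper) == (1.8, 7.0) and c.pseudoatom_corrected

    def test_zero_correction_is_identity(self):
        r = DistanceRestraint(11, "M7", 10, "H8", 1.8, 6.0)
        assert pseudoatom_correction(r, correction=0.0) == r

    def test_non_degenerate_group_rejected(self):
        r = DistanceRestraint(11, "H6", 10, "H8", 1.8, 6.0)
        with pytest.raises(ValueError):
            pseudoatom_correction(r, group="single")


class TestWatsonCrick:
    def test_decamer_has_29_hbonds(self, free_spec):
        hbonds, planes = generate_wc_restraints(free_spec)
        assert len(hbonds) == 29  # 9 G·C x 3 + 1 A·T x 2
        assert len(planes) == 10

    def test_single_pairs(self):
        hb_at, _ = generate_wc_restraints(build_duplex_spec("A", "T"))
        hb_gc, _ = generate_wc_restraints(build_duplex_spec("G", "C"))
        assert len(hb_at) == 2 and len(hb_gc) == 3


class TestBookkeeping:
    def test_table1_style_counts(self, free_spec):
        restraints = [
            DistanceRestraint(2, "H8", 2, "H1'", 1.8, 2.9),  # intra
            DistanceRestraint(2, "H8", 3, "H1'", 1.8, 3.5),  # sequential
            DistanceRestraint(2, "H8", 5, "H1'", 1.8, 6.0),  # non-sequential
            DistanceRestraint(10, "H2", 11, "H3", 1.8, 4.0),  # inter-strand |i-j|=1
        ]
        counts = restraint_counts(restraints, free_spec)
        assert counts == {
            "total": 4,
            "intra_residue": 1,
            "inter_residue": 3,
            "sequential": 1,
            "non_sequential": 2,
        }


class TestRestraintTable:
    def test_dialect_encoding(self, tmp_path):
        r = DistanceRestraint(2, "H8", 3, "H1'", 1.8, 2.9, label="strong")
        path = tmp_path / "one.tbl"
        write_restraint_table([r], path)
        line = path.read_text().strip()
        assert line.startswith("assign (resid   2 and name H8")
        assert "  2.900   1.100   0.000" in line

    def test_round_trip(self, tmp_path):
        rs = [
            DistanceRestraint(2, "H8", 3, "H1'", 1.8, 2.9, label="strong"),
            DistanceRestraint(11, "M7", 10, "H8", 1.8, 7.0, label="weak",
                              pseudoatom_corrected=True),
            DistanceRestraint(4, "H5", 4, "H6", 1.8, 3.5),
        ]
        path = tmp_path / "rt.tbl"
        write_restraint_table(rs, path)
        assert read_restraint_table(path) == rs

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_restraint_table([], tmp_path / "empty.tbl")
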
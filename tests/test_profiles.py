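"""Blood-profile I/O, validation, unit heuristics and range clipping."""

import io
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abps import (
    BloodProfile,
    ClipWarning,
    DEFAULT_RANGES,
    MARKERS,
    MarkerRanges,
    ProfileValidationError,
    check_units,
    clip_matrix,
    clip_profile,
    read_profiles,
    write_profiles,
)

CSV3 = """sample_id,HCT,HGB,MCH,MCHC,MCV,RBC,RETP
A,43.0,14.5,29.6,34.0,87.0,4.9,1.0
B,41.2,13.8,28.9,33.5,86.1,4.7,0.8
C,45.5,15.2,30.1,34.4,88.3,5.1,1.2
"""


def make_profile(sample_id="p", **over):
    vals = dict(HCT=43.0, HGB=14.5, MCH=29.6, MCHC=34.0, MCV=87.0, RBC=4.9, RETP=1.0)
    vals.update(over)
    return BloodProfile(sample_id=sample_id, **vals)


class TestReadProfiles:
    def test_three_rows_in_order(self):
        ps = read_profiles(io.StringIO(CSV3))
        assert [p.sample_id for p in ps] == ["A", "B", "C"]
        assert ps[0].HGB == 14.5 and ps[2].RETP == 1.2

    def test_missing_marker_column_is_hard_error(self):
        bad = CSV3.replace("RETP", "RET")
        with pytest.raises(ProfileValidationError, match="missing marker: RETP"):
            read_profiles(io.StringIO(bad))

    def test_non_numeric_row_rejected_others_returned(self):
        csv = CSV3.replace("B,41.2,13.8", "B,41.2,NA")
        ps = read_profiles(io.StringIO(csv))
        assert [p.sample_id for p in ps] == ["A", "C"]

    def test_empty_file_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            assert read_profiles(io.StringIO("")) == []

    def test_header_case_and_order_free_with_metadata(self):
        csv = "retp,rbc,mcv,mchc,mch,hgb,hct,site\n1.0,4.9,87.0,34.0,29.6,14.5,43.0,lab1\n"
        (p,) = read_profiles(io.StringIO(csv))
        assert p.HGB == 14.5 and p.HCT == 43.0
        assert p.metadata["site"] == "lab1"

    def test_sex_column_recognised(self):
        csv = CSV3.replace("RETP\n", "RETP,sex\n").replace("1.0\n", "1.0,F\n", 1)
        ps = read_profiles(io.StringIO(csv))
        assert ps[0].sex == "female"

    def test_write_read_round_trip_bit_exact(self):
        ps = read_profiles(io.StringIO(CSV3))
        buf = io.StringIO()
        write_profiles(ps, buf)
        buf.seek(0)
        qs = read_profiles(buf)
        for p, q in zip(ps, qs):
            assert p.values().tolist() == q.values().tolist()
            assert p.sample_id == q.sample_id


class TestValidation:
    @pytest.mark.parametrize("bad", [-1.0, 0.0, float("nan"), float("inf")])
    def test_nonpositive_or_nonfinite_marker_rejected(self, bad):
        with pytest.raises(ProfileValidationError):
            make_profile(HGB=bad)

    def test_ranges_require_lower_below_upper(self):
        bounds = {m: DEFAULT_RANGES.bounds[m] for m in MARKERS}
        bounds["HGB"] = (18.2, 12.9)
        with pytest.raises(ValueError):
            MarkerRanges(bounds)

    def test_default_hgb_bounds_are_fixed(self):
        assert DEFAULT_RANGES.bounds["HGB"] == (12.9, 18.2)


class TestClipping:
    @pytest.mark.parametrize(
        "hgb, expected, n_events",
        [(12.0, 12.9, 1), (15.0, 15.0, 0), (19.0, 18.2, 1)],
    )
    def test_hgb_bounds(self, hgb, expected, n_events):
        p = make_profile(HGB=hgb)
        if n_events:
            with pytest.warns(ClipWarning):
                q, events = clip_profile(p)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                q, events = clip_profile(p)
        assert q.HGB == expected
        assert len(events) == n_events
        if n_events:
            assert events[0].marker == "HGB" and events[0].original == hgb

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=500, allow_nan=False),
            min_size=7,
            max_size=7,
        )
    )
    def test_clip_is_idempotent(self, vals):
        p = BloodProfile("h", **dict(zip(MARKERS, vals)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q1, _ = clip_profile(p)
            q2, _ = clip_profile(q1)
        assert q1.values().tolist() == q2.values().tolist()

    @settings(derandomize=True, max_examples=60)
    @given(
        st.floats(min_value=0.01, max_value=500, allow_nan=False),
        st.floats(min_value=0.01, max_value=500, allow_nan=False),
    )
    def test_clip_is_order_preserving_per_marker(self, v1, v2):
        lo, hi = sorted([v1, v2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1, _ = clip_profile(make_profile(HGB=lo))
            c2, _ = clip_profile(make_profile(HGB=hi))
        assert c1.HGB <= c2.HGB

    def test_clip_matrix_matches_profile_clipping(self, rng):
        X = rng.uniform(0.05, 200, size=(50, 7))
        C = clip_matrix(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(50):
                p, _ = clip_profile(BloodProfile(str(i), **dict(zip(MARKERS, X[i]))))
                assert np.array_equal(p.values(), C[i])


class TestUnitHeuristics:
    def test_hgb_in_g_per_l_flagged(self):
        msgs = check_units(make_profile(HGB=145.0))
        assert len(msgs) == 1 and "HGB" in msgs[0]

    def test_plausible_profile_passes(self):
        assert check_units(make_profile()) == []

    def test_hct_as_fraction_flagged(self):
        msgs = check_units(make_profile(HCT=0.43))
        assert len(msgs) == 1 and "HCT" in msgs[0]

    def test_retp_absolute_count_flagged(self):
        msgs = check_units(make_profile(RETP=60.0))
        assert any("RETP" in m for m in msgs)
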
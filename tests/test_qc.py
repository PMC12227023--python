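"""File-level QC: substitution, missingness, rejection rules, gap interpolation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from accomstep import (QCThresholds, apply_rejection, interpolate_short_gaps,
                       longest_missing_run, missing_fraction, substitute_eye)
from accomstep.recordings import RecordingParseError, read_recording

from conftest import make_recording


class TestReadErrors:
    def test_truncated_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# participant_id: P1\n# cue: BDP\n# fs_hz: 50\n"
                     "time_s,od_refraction_d,os_refraction_d\n0.0,1.0,1.0\n0.02,1.0\n")
        with pytest.raises(RecordingParseError, match=":6"):
            read_recording(p)

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# no separator here\ntime_s,od_refraction_d,os_refraction_d\n")
        with pytest.raises(RecordingParseError, match=":1"):
            read_recording(p)

    def test_nonpositive_fs_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# participant_id: P1\n# cue: BDP\n# fs_hz: 0\n"
                     "time_s,od_refraction_d,os_refraction_d\n")
        with pytest.raises(ValueError, match="fs_hz"):
            read_recording(p)

    def test_empty_fields_become_missing(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("# participant_id: P1\n# cue: BDP\n# fs_hz: 50\n"
                     "time_s,od_refraction_d,os_refraction_d\n"
                     "0.0,,1.0\n0.02,2.0,\n")
        rec = read_recording(p)
        assert rec.od_missing.tolist() == [True, False]
        assert rec.os_missing.tolist() == [False, True]


class TestSubstituteEye:
    def test_single_eye_dropout_repaired_from_fellow_eye(self):
        rec = make_recording(np.arange(10.0), np.arange(10.0) + 0.5)
        rec.od[3] = np.nan
        out, counts = substitute_eye(rec)
        assert out.od[3] == rec.os[3]
        assert counts == {"od": 1, "os": 0}

    def test_both_missing_stays_missing(self):
        rec = make_recording(np.ones(10))
        rec.od[4] = np.nan
        rec.os[4] = np.nan
        out, _ = substitute_eye(rec)
        assert np.isnan(out.od[4]) and np.isnan(out.os[4])

    def test_valid_samples_never_changed(self):
        rng = np.random.default_rng(3)
        rec = make_recording(rng.normal(size=200), rng.normal(size=200))
        rec.od[rng.random(200) < 0.2] = np.nan
        rec.os[rng.random(200) < 0.2] = np.nan
        valid_od = ~rec.od_missing
        out, _ = substitute_eye(rec)
        np.testing.assert_array_equal(out.od[valid_od], rec.od[valid_od])

    def test_no_missing_is_identity(self):
        rec = make_recording(np.arange(20.0))
        out, counts = substitute_eye(rec)
        np.testing.assert_array_equal(out.od, rec.od)
        assert counts == {"od": 0, "os": 0}


class TestMissingness:
    def test_fraction_arithmetic(self):
        rec = make_recording(np.ones(250))
        rec.od[:50] = np.nan
        rec.os[:50] = np.nan
        assert missing_fraction(rec) == pytest.approx(0.20)

    def test_bounds(self):
        rec = make_recording(np.ones(10))
        assert missing_fraction(rec) == 0.0
        rec.od[:] = np.nan
        rec.os[:] = np.nan
        assert missing_fraction(rec) == 1.0

    def test_zero_length_rejected(self):
        rec = make_recording(np.array([]))
        with pytest.raises(ValueError):
            missing_fraction(rec)

    def test_longest_run_examples(self):
        mask = np.zeros(500, dtype=bool)
        mask[0:10] = True
        mask[50:280] = True
        mask[400:405] = True
        assert longest_missing_run(mask) == 230
        assert longest_missing_run(np.zeros(100, dtype=bool)) == 0

    @given(st.lists(st.booleans(), max_size=30))
    def test_longest_run_matches_exhaustive_scan(self, bits):
        mask = np.array(bits, dtype=bool)
        best = 0
        for i in range(len(bits)):
            for j in range(i, len(bits)):
                if all(bits[i:j + 1]):
                    best = max(best, j - i + 1)
        assert longest_missing_run(mask) == best


class TestRejection:
    def _rec(self, n=8000, missing=0, gap=0):
        rec = make_recording(np.ones(n))
        if missing:
            idx = np.linspace(0, n - 1, missing).astype(int)
            rec.od[idx] = np.nan
            rec.os[idx] = np.nan
        if gap:
            start = min(1000, n - gap)
            rec.od[start:start + gap] = np.nan
            rec.os[start:start + gap] = np.nan
        return rec

    def test_clean_file_accepted(self):
        report = apply_rejection(self._rec(missing=100, gap=100))
        assert report.accepted and report.reasons == []

    def test_quarter_loss_is_inclusive(self):
        report = apply_rejection(self._rec(n=8000, missing=2000))
        assert "DATA_LOSS_25PCT" in report.reasons

    def test_just_below_quarter_accepted(self):
        rec = self._rec(n=8000, missing=1990)
        report = apply_rejection(rec)
        assert "DATA_LOSS_25PCT" not in report.reasons

    def test_gap_225_is_inclusive(self):
        assert "GAP_225" in apply_rejection(self._rec(gap=225)).reasons
        assert "GAP_225" not in apply_rejection(self._rec(gap=224)).reasons

    def test_too_short_750(self):
        rec = self._rec(n=800)
        rec.od[750:] = np.nan
        rec.os[750:] = np.nan
        assert "TOO_SHORT_750" not in apply_rejection(rec).reasons  # exactly 750 valid
        rec.od[749:] = np.nan
        rec.os[749:] = np.nan
        assert "TOO_SHORT_750" in apply_rejection(rec).reasons

    def test_substitution_applied_before_rules(self):
        # one-eye loss alone never rejects: fellow eye repairs it
        rec = make_recording(np.ones(1000))
        rec.od[:] = np.nan
        report = apply_rejection(rec)
        assert report.accepted
        report_raw = apply_rejection(rec, substitute=False)
        assert report_raw.accepted  # combined mask still empty pre-substitution

    def test_rejection_monotone_in_missingness(self):
        rec = self._rec(n=2000, gap=225)
        assert not apply_rejection(rec).accepted
        rec.od[0:500] = np.nan
        rec.os[0:500] = np.nan
        assert not apply_rejection(rec).accepted

    def test_reasons_deterministic_and_sorted(self):
        rec = self._rec(n=1000, missing=400, gap=300)
        r1 = apply_rejection(rec)
        r2 = apply_rejection(rec)
        assert r1.reasons == r2.reasons == sorted(r1.reasons)
        assert len(r1.reasons) == 3


class TestInterpolation:
    def test_linear_fill(self):
        rec = make_recording(np.array([1.0, np.nan, np.nan, 1.3, 1.3]))
        out = interpolate_short_gaps(rec, max_gap=225)
        np.testing.assert_allclose(out.od, [1.0, 1.1, 1.2, 1.3, 1.3], atol=1e-12)
        assert out.od_interpolated.tolist() == [False, True, True, False, False]

    def test_no_gaps_identity_with_empty_mask(self):
        rec = make_recording(np.arange(5.0))
        out = interpolate_short_gaps(rec)
        np.testing.assert_array_equal(out.od, rec.od)
        assert not out.od_interpolated.any()

    def test_leading_gap_takes_nearest_value(self):
        rec = make_recording(np.array([np.nan, np.nan, np.nan, 2.0, 2.5]))
        out = interpolate_short_gaps(rec)
        np.testing.assert_allclose(out.od[:3], 2.0)

    def test_threshold_gap_refused(self):
        rec = make_recording(np.ones(1000))
        rec.od[0:225] = np.nan
        rec.os[0:225] = np.nan
        with pytest.raises(ValueError, match="reject"):
            interpolate_short_gaps(rec, max_gap=225)

    def test_all_missing_rejected(self):
        rec = make_recording(np.full(100, np.nan))
        with pytest.raises(ValueError):
            interpolate_short_gaps(rec)
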
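"""Condition registry, pulse-chase protocol construction, response tables."""

import numpy as np
import pandas as pd
import pytest

from fatekinetics import (
    N2B27,
    AC,
    Condition,
    ConditionLookupError,
    Protocol,
    PulseChaseDesign,
    PulseResponseTable,
    RateParameters,
    ValidationError,
    condition_from_name,
    crossing_time,
    fate_correlation,
    pulse_chase_protocols,
    pulse_response,
    register_condition,
)


class TestRegistry:
    def test_ac_is_ps_permissive_with_media_meta(self):
        cond = condition_from_name("AC")
        assert cond.ps_permissive
        assert cond.media_meta["Activin"] == "100 ng/ml"
        assert cond.media_meta["CHIR99021"] == "3 uM"

    def test_n2b27_is_neutral(self):
        cond = condition_from_name("N2B27")
        assert not cond.ps_permissive
        assert cond.media_meta["base"] == "N2B27"

    def test_unknown_condition_lists_known(self):
        with pytest.raises(ConditionLookupError, match="AC"):
            condition_from_name("XYZ")

    def test_user_conditions_can_be_registered(self):
        custom = Condition("AC+SB43", ps_permissive=True, media_meta={"SB431542": "10 uM"})
        register_condition(custom, overwrite=True)
        assert condition_from_name("AC+SB43") is custom


class TestPulseChaseProtocols:
    def test_day0_pulse_omits_empty_leading_segment(self):
        design = PulseChaseDesign(pulse_start_days=(0.0,))
        (protocol,) = pulse_chase_protocols(design)
        assert len(protocol.segments) == 2
        assert protocol.segments[0].condition is AC
        assert protocol.segments[1].duration == 5.0

    def test_mid_pulse_has_three_segments(self):
        design = PulseChaseDesign(pulse_start_days=(2.0,))
        (protocol,) = pulse_chase_protocols(design)
        durations = [seg.duration for seg in protocol.segments]
        names = [seg.condition.name for seg in protocol.segments]
        assert durations == [2.0, 1.0, 3.0]
        assert names == ["N2B27", "AC", "N2B27"]

    def test_all_protocols_span_total_duration(self, pulse_design):
        protocols = pulse_chase_protocols(pulse_design)
        assert len(protocols) == 6
        for protocol in protocols:
            assert protocol.total_duration == pytest.approx(6.0, abs=1e-12)

    def test_oversized_pulse_rejected(self):
        with pytest.raises(ValidationError):
            PulseChaseDesign(pulse_start_days=(5.5,))

    def test_unsorted_starts_rejected(self):
        with pytest.raises(ValidationError):
            PulseChaseDesign(pulse_start_days=(3.0, 1.0))


class TestPulseResponse:
    def test_rows_conserve_mass(self, pulse_design, params):
        table = pulse_response(pulse_design, params)
        totals = table.frame[["n_final", "m_final", "uncommitted_final"]].sum(axis=1)
        assert np.max(np.abs(totals - 1.0)) < 1e-9

    def test_closed_ps_channel_gives_zero_m(self, pulse_design):
        params = RateParameters(1.0, 0.5, 0.0, 0.0, theta=0.5)
        table = pulse_response(pulse_design, params)
        assert np.all(table.frame["m_final"] == 0.0)

    def test_instant_signal_response_tracks_uncommitted_pool(self, pulse_design):
        """With theta=0 and a dominant PS rate the pulse yield tracks the
        convertible pool: it is unimodal (the uncommitted pool d first
        builds up from P, then drains into NECT) and late pulses, which
        find the pool absorbed by NECT, give strictly declining yields."""
        params = RateParameters(1.0, 0.5, 0.0, 20.0, theta=0.0)
        table = pulse_response(pulse_design, params)
        m = table.frame["m_final"].to_numpy()
        peak = int(np.argmax(m))
        assert peak <= 2  # d peaks at ln(lambda_D/Lambda)/(lambda_D-Lambda) ~ 1.4 d
        assert np.all(np.diff(m[:peak + 1]) >= 0)
        assert np.all(np.diff(m[peak:]) < 0)

    def test_response_peaks_at_first_post_crossing_pulse(self, pulse_design):
        """PS yield is maximal for the first pulse day at/after the signal
        crossing: earlier pulses miss the permissive window, later ones
        find the pool drained by NECT."""
        theta = 1.0 - np.exp(-0.9 * 2.0)  # crossing exactly at day 2
        params = RateParameters(0.9, 0.5, 0.0, 12.0, theta=theta)
        t_star = crossing_time(params)
        assert t_star == pytest.approx(2.0, abs=1e-12)
        table = pulse_response(pulse_design, params)
        m = table.frame["m_final"].to_numpy()
        days = table.frame["pulse_start_day"].to_numpy()
        first_at_or_after = days[days >= t_star].min()
        assert days[np.argmax(m)] == first_at_or_after

    def test_window_of_opportunity_shape(self, pulse_design, params):
        """Unimodal PS response: rises to a peak near the crossing day,
        then declines as NECT absorbs the pool."""
        table = pulse_response(pulse_design, params)
        m = table.frame["m_final"].to_numpy()
        peak = int(np.argmax(m))
        assert peak in (2, 3)
        assert np.all(np.diff(m[peak:]) <= 0)

    def test_export_schema(self, pulse_design, params, tmp_path):
        table = pulse_response(pulse_design, params)
        path = tmp_path / "response.csv"
        table.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == [
            "pulse_start_day", "n_final", "m_final", "uncommitted_final",
        ]


class TestFateCorrelation:
    def _table(self, pairs):
        rows = [
            {
                "pulse_start_day": float(i),
                "n_final": n / 10.0,
                "m_final": m / 10.0,
                "uncommitted_final": 1.0 - n / 10.0 - m / 10.0,
            }
            for i, (n, m) in enumerate(pairs)
        ]
        return PulseResponseTable(pd.DataFrame(rows))

    def test_perfectly_antilinear(self):
        table = self._table([(1, 4), (2, 3), (3, 2), (4, 1)])
        assert fate_correlation(table) == pytest.approx(-1.0, abs=1e-12)

    def test_perfectly_linear(self):
        table = self._table([(1, 1), (2, 2), (3, 3)])
        assert fate_correlation(table) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        table = self._table([(1, 0), (2, 0), (3, 0)])
        with pytest.raises(ValidationError, match="variance"):
            fate_correlation(table)

    def test_too_few_rows_rejected(self):
        table = self._table([(1, 4), (2, 3)])
        with pytest.raises(ValidationError, match="3"):
            fate_correlation(table)

    def test_strong_anticorrelation_under_defaults(self, pulse_design, params):
        """Model analogue of the experimental NECT/PS anticorrelation."""
        table = pulse_response(pulse_design, params)
        assert fate_correlation(table) < -0.9
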
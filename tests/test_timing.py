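"""Mitotic phase durations, censoring rules and cohort statistics."""

import numpy as np
import pytest

from spheroidgeom.errors import EmptyInputError, SpheroidGeomError
from spheroidgeom.phantom import generate_mitosis_events, truncated_normal_mean
from spheroidgeom.timing import (
    MitosisEvent,
    cohort_summary,
    long_prometaphase_fraction,
    phase_durations,
)


def ev(**kw):
    kw.setdefault("cell_id", "c")
    return MitosisEvent(**kw)


def test_fully_observed_durations():
    d = phase_durations(
        ev(condensation_frame=0, metaphase_frame=4, anaphase_frame=7)
    )
    assert d.prometaphase_min == 16.0
    assert d.metaphase_min == 12.0
    assert not d.flags
    assert d.prometaphase_observed


def test_censored_condensation_lower_bound():
    d = phase_durations(
        ev(condensation_frame=0, metaphase_frame=3, condensation_censored=True)
    )
    assert d.prometaphase_min == 12.0
    assert "prometaphase-lower-bound" in d.flags
    assert not d.prometaphase_observed


def test_missing_metaphase_lower_bound_from_last_frame():
    d = phase_durations(
        ev(condensation_frame=1, metaphase_frame=None, last_observed_frame=12)
    )
    assert d.prometaphase_min == 44.0
    assert "prometaphase-lower-bound" in d.flags
    assert "metaphase-missing" in d.flags
    assert d.metaphase_min is None


def test_frame_order_violation_rejected():
    with pytest.raises(SpheroidGeomError):
        ev(condensation_frame=5, metaphase_frame=3)
    with pytest.raises(SpheroidGeomError):
        ev(metaphase_frame=5, anaphase_frame=4)


def test_durations_are_frame_multiples():
    for m in range(1, 6):
        d = phase_durations(ev(condensation_frame=0, metaphase_frame=m,
                               anaphase_frame=m + 2))
        assert d.prometaphase_min % 4.0 == 0.0
        assert d.prometaphase_min >= 0.0


def test_long_fraction_simple():
    events = [
        phase_durations(ev(condensation_frame=0, metaphase_frame=f))
        for f in (3, 13)  # 12 and 52 minutes
    ]
    res = long_prometaphase_fraction(events, cutoff_min=40.0)
    assert res.fraction == pytest.approx(0.5)
    assert res.n_indeterminate == 0


def test_long_fraction_all_short():
    events = [ev(condensation_frame=0, metaphase_frame=f) for f in (2, 4, 6)]
    assert long_prometaphase_fraction(events).fraction == 0.0


def test_long_fraction_lower_bound_rules():
    """A lower bound above the cutoff is determinate-long; below the cutoff
    it is indeterminate and leaves the denominator."""
    long_bound = phase_durations(
        ev(condensation_frame=1, metaphase_frame=None, last_observed_frame=12)
    )  # >= 44 min
    short_obs = phase_durations(ev(condensation_frame=0, metaphase_frame=3))
    res = long_prometaphase_fraction([long_bound, short_obs], cutoff_min=40.0)
    assert res.fraction == pytest.approx(0.5)
    assert res.n_indeterminate == 0
    short_bound = phase_durations(
        ev(condensation_frame=0, metaphase_frame=2, condensation_censored=True)
    )  # >= 8 min: indeterminate
    res2 = long_prometaphase_fraction(
        [long_bound, short_obs, short_bound], cutoff_min=40.0
    )
    assert res2.n_determinate == 2
    assert res2.n_indeterminate == 1
    assert res2.fraction == pytest.approx(0.5)
    assert res2.fraction_all_cells == pytest.approx(1 / 3)


def test_long_fraction_empty_rejected():
    with pytest.raises(EmptyInputError):
        long_prometaphase_fraction([])


def test_cohort_summary_arithmetic():
    events = [
        ev(cell_id=str(i), condensation_frame=0, metaphase_frame=m)
        for i, m in enumerate((3, 4, 5))  # 12, 16, 20 min
    ]
    s = cohort_summary(events)["prometaphase"]
    assert s.mean_min == pytest.approx(16.0)
    assert s.sd_min == pytest.approx(4.0)  # sample SD
    assert s.n == 3


def test_cohort_summary_single_value_sd_absent():
    s = cohort_summary([ev(condensation_frame=0, metaphase_frame=3)])
    assert s["prometaphase"].sd_min is None


def test_cohort_summary_excludes_censored():
    observed = [ev(cell_id="a", condensation_frame=0, metaphase_frame=4)]
    censored = [
        ev(
            cell_id="b",
            condensation_frame=0,
            metaphase_frame=20,
            condensation_censored=True,
        )
    ]
    s1 = cohort_summary(observed)
    s2 = cohort_summary(observed + censored)
    assert s1["prometaphase"].mean_min == s2["prometaphase"].mean_min
    assert s2["prometaphase"].n == 1


def test_simulated_cohort_recovers_truncated_normal_mean():
    """n=500 control-like cohort: the mean of fully monitored prometaphases
    matches the truncated-normal mean to within 1 minute."""
    events = generate_mitosis_events(
        n=500, prometaphase_mu_min=14.4, prometaphase_sigma_min=7.6, seed=31
    )
    s = cohort_summary(events)["prometaphase"]
    oracle = truncated_normal_mean(14.4, 7.6, lower=4.0)
    assert abs(s.mean_min - oracle) < 1.0


def test_zero_variance_durations_exact():
    """Tiny sigma, mu on the frame grid: every recovered duration equals mu."""
    events = generate_mitosis_events(
        n=50,
        prometaphase_mu_min=16.0,
        prometaphase_sigma_min=1e-9,
        metaphase_mu_min=12.0,
        metaphase_sigma_min=1e-9,
        seed=32,
    )
    for e in events:
        d = phase_durations(e)
        if d.prometaphase_observed:
            assert d.prometaphase_min == pytest.approx(16.0, abs=1e-9)
        if d.metaphase_min is not None:
            assert d.metaphase_min == pytest.approx(12.0, abs=1e-9)


def test_short_recording_censors_everything():
    events = generate_mitosis_events(
        n=30,
        prometaphase_mu_min=100.0,
        prometaphase_sigma_min=1.0,
        recording_length_frames=5,
        seed=33,
    )
    durations = [phase_durations(e) for e in events]
    assert all(not d.prometaphase_observed for d in durations)
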
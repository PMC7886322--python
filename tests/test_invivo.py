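"""In vivo analysis: peak extraction, normalization, group comparison."""
import numpy as np
import pytest

from subtendon import (CycleSpec, StimTrial, SubTendonID, cohort_table,
                       compare_groups, normalized_displacement,
                       peak_displacement)
from subtendon.synthetic import CohortGenSpec, _pulse_train


def make_trace(amplitude, n_cycles=3, fs=50.0, drift=0.0):
    cycle = CycleSpec()
    dur = cycle.first_onset_s + n_cycles * (cycle.on_s + cycle.off_s)
    t = np.arange(int(dur * fs) + 1) / fs
    y = _pulse_train(t, cycle, amplitude) + drift
    return t, y


def test_peak_of_clean_pulse():
    t, y = make_trace(2.0)
    assert peak_displacement(t, y) == pytest.approx(2.0, abs=1e-9)


def test_peak_is_baseline_relative():
    """A 0.5 mm offset present before onset does not inflate the peak."""
    t, y = make_trace(2.0, drift=0.5)
    assert peak_displacement(t, y) == pytest.approx(2.0, abs=1e-9)


def test_peak_median_across_cycles():
    cycle = CycleSpec()
    t, y = make_trace(0.0)
    for i, amp in enumerate((1.9, 2.0, 2.1)):
        onset = cycle.first_onset_s + i * (cycle.on_s + cycle.off_s)
        mask = (t >= onset) & (t <= onset + cycle.on_s)
        y[mask] += amp * np.minimum((t[mask] - onset) / 0.5, 1.0) * \
            np.minimum((onset + cycle.on_s - t[mask]) / 0.5 + 1, 1.0)
    assert peak_displacement(t, y) == pytest.approx(2.0, abs=0.01)


def test_peak_requires_a_cycle():
    with pytest.raises(ValueError):
        peak_displacement(np.array([0.0, 1.0]), np.array([0.0, 0.0]))


def trial_from_amplitudes(mtj_amp, ref_amp):
    t, mtj = make_trace(mtj_amp)
    _, ref = make_trace(ref_amp)
    return StimTrial(participant="p0", group="young", muscle=SubTendonID.SOL,
                     time_s=t, mtj_mm=mtj, reference_mm=ref)


def test_normalized_displacement_ratio_and_invariance():
    assert normalized_displacement(trial_from_amplitudes(1.2, 2.4)) == \
        pytest.approx(0.5, abs=1e-9)
    assert normalized_displacement(trial_from_amplitudes(2.0, 2.0)) == \
        pytest.approx(1.0, abs=1e-9)
    # common scaling leaves the ratio unchanged
    assert normalized_displacement(trial_from_amplitudes(3.6, 7.2)) == \
        pytest.approx(0.5, abs=1e-9)


def test_normalized_displacement_rejects_zero_reference():
    with pytest.raises(ValueError):
        normalized_displacement(trial_from_amplitudes(1.0, 0.0))


def test_trial_requires_three_cycles():
    t, y = make_trace(1.0, n_cycles=2)
    with pytest.raises(ValueError):
        StimTrial(participant="p", group="young", muscle=SubTendonID.SOL,
                  time_s=t, mtj_mm=y, reference_mm=y)


def test_identical_groups_not_significant():
    t, mtj = make_trace(1.0)
    _, ref = make_trace(2.0)
    trials = []
    for group in ("young", "old"):
        for i in range(4):
            trials.append(StimTrial(
                participant=f"{group}{i}", group=group,
                muscle=SubTendonID.SOL, time_s=t, mtj_mm=mtj,
                reference_mm=ref))
    res = compare_groups(cohort_table(trials), SubTendonID.SOL)
    assert res.p_value == pytest.approx(1.0)


def test_compare_groups_detects_designed_deficit():
    """Default cohort (d = 1.9 soleus deficit, n = 9 vs 7): the soleus
    comparison is significant, the gastrocnemius ones typically are not."""
    from subtendon.synthetic import gen_cohort

    ct = cohort_table(gen_cohort(CohortGenSpec(seed=12)))
    assert len(ct) == 48
    res = compare_groups(ct, SubTendonID.SOL)
    assert res.p_value < 0.05
    young = ct[(ct.muscle == "SOL") & (ct.group == "young")]
    old = ct[(ct.muscle == "SOL") & (ct.group == "old")]
    assert young["normalized_displacement"].mean() > \
        old["normalized_displacement"].mean()
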
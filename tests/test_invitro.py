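"""In vitro analysis: fixture integrity, curve metrics, group summary."""
import numpy as np
import pytest

from subtendon import (SubTendonID, TestCurve, posthoc_vs_soleus,
                       sex_subgroup_means, specimen_metrics, summarize_group)
from subtendon.invitro import METRICS
from subtendon.synthetic import CurveGenSpec, gen_test_curve

#: published group means and SDs, 1-decimal precision
PRINTED = {
    "csa_mm2": {"LG": (9.3, 4.0), "MG": (13.4, 2.7), "SOL": (32.8, 7.6)},
    "failure_force_n": {"LG": (414.5, 242.5), "MG": (586.2, 111.3),
                        "SOL": (1420.6, 277.1)},
    "ultimate_stress_mpa": {"LG": (53.4, 33.4), "MG": (45.1, 12.2),
                            "SOL": (45.2, 10.4)},
    "ultimate_strain_pct": {"LG": (10.1, 1.6), "MG": (10.4, 1.2),
                            "SOL": (14.7, 3.9)},
    "modulus_mpa": {"LG": (729.5, 449.5), "MG": (579.4, 149.9),
                    "SOL": (480.3, 192.7)},
    "stiffness_n_mm": {"LG": (93.5, 43.5), "MG": (130.5, 20.9),
                       "SOL": (263.9, 103.4)},
}


def linear_curve(slope_n_mm=150.0, csa=30.0, fail_force=1500.0, gauge=60.0):
    d = np.linspace(0, fail_force / slope_n_mm, 120)
    f = slope_n_mm * d
    d = np.concatenate([d, [d[-1]] * 3])
    f = np.concatenate([f, fail_force * np.array([0.7, 0.6, 0.5])])
    t = np.arange(len(d)) / 10.0
    return TestCurve(time_s=t, displacement_mm=d, force_n=f,
                     gauge_length_mm=gauge, csa_mm2=csa)


def test_fixture_loads_and_validates(table1):
    assert len(table1) == 15
    assert table1["specimen"].nunique() == 5
    assert set(table1["sub_tendon"]) == set(SubTendonID)


def test_summary_regenerates_printed_cells(table1):
    summary = summarize_group(table1)
    for metric, by_st in PRINTED.items():
        for st, (mean, sd) in by_st.items():
            assert round(summary.loc[("mean", st), metric], 1) == mean
            assert round(summary.loc[("sd", st), metric], 1) == sd


def test_sex_subgroup_means(table1):
    sub = sex_subgroup_means(table1)
    assert round(sub["M"]["combined_csa_mm2"], 1) == 62.1
    assert round(sub["F"]["combined_csa_mm2"], 1) == 51.2
    assert round(sub["M"]["combined_failure_force_n"], 1) == 2478.1
    assert round(sub["F"]["combined_failure_force_n"], 1) == 2383.5


def test_star_pattern(table1):
    """CSA, failure force and stiffness are starred for both gastrocnemii;
    the material properties (stress, strain, modulus) are not."""
    ph = posthoc_vs_soleus(table1)
    starred = {"csa_mm2", "failure_force_n", "stiffness_n_mm"}
    for metric in METRICS:
        for col in ("LG_star", "MG_star"):
            assert bool(ph.loc[metric, col]) == (metric in starred)
    # every starred comparison is the fully separated p = 2/252 case
    for metric in starred:
        assert ph.loc[metric, "LG_p"] == pytest.approx(2 / 252)
        assert ph.loc[metric, "MG_p"] == pytest.approx(2 / 252)


def test_posthoc_stricter_threshold_removes_stars(table1):
    ph = posthoc_vs_soleus(table1, threshold=0.001)
    assert not ph[["LG_star", "MG_star"]].to_numpy().any()


def test_posthoc_requires_soleus(table1):
    no_sol = table1[table1["sub_tendon"] != SubTendonID.SOL]
    with pytest.raises(ValueError):
        posthoc_vs_soleus(no_sol)


def test_summarize_requires_two_specimens(table1):
    one = table1[table1["specimen"] == "69 M"]
    with pytest.raises(ValueError):
        summarize_group(one)


def test_specimen_metrics_linear_closed_form():
    """Linear curve: stiffness = slope, modulus = slope * gauge / CSA."""
    m = specimen_metrics(linear_curve())
    assert m["stiffness_n_mm"] == pytest.approx(150.0, rel=1e-6)
    assert m["modulus_mpa"] == pytest.approx(150.0 * 60.0 / 30.0, rel=1e-6)
    assert m["failure_force_n"] == pytest.approx(1500.0)
    assert m["ultimate_stress_mpa"] == pytest.approx(50.0)


def test_specimen_metrics_reproduce_published_stress_cell():
    """Failure force 787.5 N over CSA 10.4 mm^2 gives 75.7 MPa (printed
    75.8, tolerance 0.2 in last printed units)."""
    m = specimen_metrics(linear_curve(csa=10.4, fail_force=787.5))
    assert m["ultimate_stress_mpa"] == pytest.approx(75.8, abs=0.2)


def test_specimen_metrics_requires_failure():
    d = np.linspace(0, 10, 100)
    monotone = TestCurve(time_s=d, displacement_mm=d, force_n=100 * d,
                         csa_mm2=30.0)
    with pytest.raises(ValueError):
        specimen_metrics(monotone)


def test_generator_round_trip_metrics():
    """Analysing a generated curve recovers the generating parameters.

    The windowed 20-80% slope of a hyperelastic curve slightly
    under-reads the initial tangent (the neo-Hookean uniaxial stiffness
    decays with stretch), so the stiffness check carries a wider band than
    the strain arithmetic.
    """
    spec = CurveGenSpec(E=300.0, csa_mm2=30.0, noise=0.0, toe_strain=0.005,
                        failure_strain=0.04, seed=0)
    m = specimen_metrics(gen_test_curve(spec))
    k_expected = 300.0 * 30.0 / 60.0  # E * A / L
    assert m["stiffness_n_mm"] == pytest.approx(k_expected, rel=0.03)
    assert m["ultimate_strain_pct"] == pytest.approx(4.0, abs=0.5)
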
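"""In vitro tensile-test analysis of the three Achilles sub-tendons.

Covers the per-specimen mechanical metrics extracted from force-displacement
curves (failure force, ultimate stress and strain, stiffness and Young's
modulus from a maximal-slope sliding-window fit of the linear region), the
group summary (mean and sample SD per metric per sub-tendon), the
Kruskal-Wallis comparison across sub-tendons and the exact Mann-Whitney post
hoc tests against the soleus at the Bonferroni-corrected threshold
p < 0.017 (0.05/3).

The packaged fixture ``data/table1.csv`` holds the published per-specimen
values (five donors, 1-decimal precision).  One cell (donor 69 M, soleus
ultimate stress) is internally inconsistent with failure_force/CSA even
after allowing for rounding of both operands and is exempted from the
consistency validation.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SUBTENDON_ORDER, SubTendonID, TestCurve
from .stats import TestResult, kruskal_wallis, mann_whitney_exact

__all__ = [
    "METRICS",
    "SpecimenRecord",
    "load_table1",
    "specimen_metrics",
    "summarize_group",
    "posthoc_vs_soleus",
    "sex_subgroup_means",
    "POSTHOC_THRESHOLD",
]

POSTHOC_THRESHOLD = 0.017  # Bonferroni 0.05 / 3, rounded as conventionally printed

#: metric column names of the per-specimen table
METRICS = (
    "csa_mm2",
    "failure_force_n",
    "ultimate_stress_mpa",
    "ultimate_strain_pct",
    "modulus_mpa",
    "stiffness_n_mm",
)

#: cells exempted from the stress = force/CSA consistency validation
#: (specimen, sub-tendon); the published value cannot be reproduced from the
#: published force and CSA even allowing for 1-decimal rounding of both.
KNOWN_INCONSISTENT = (("69 M", SubTendonID.SOL),)


@dataclass
class SpecimenRecord:
    """One donor's metrics for all three sub-tendons."""

    specimen: str
    values: dict  # SubTendonID -> {metric: float}

    def __post_init__(self) -> None:
        for st, row in self.values.items():
            for metric, v in row.items():
                if v <= 0:
                    raise ValueError(
                        f"{self.specimen}/{st}/{metric}: non-positive value")


def _consistency_ok(force: float, csa: float, stress: float,
                    digits: float = 0.05) -> bool:
    """Interval check of stress == force/CSA under 1-decimal rounding."""
    lo = (force - digits) / (csa + digits)
    hi = (force + digits) / (csa - digits)
    return (stress - digits) <= hi and (stress + digits) >= lo


def load_table1(validate: bool = True) -> pd.DataFrame:
    """Per-specimen mechanical metrics of the five donors (tidy table)."""
    with importlib.resources.files("subtendon.data").joinpath(
            "table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["sub_tendon"] = df["sub_tendon"].map(SubTendonID)
    if validate:
        for _, row in df.iterrows():
            if (row.specimen, row.sub_tendon) in KNOWN_INCONSISTENT:
                continue
            if not _consistency_ok(row.failure_force_n, row.csa_mm2,
                                   row.ultimate_stress_mpa):
                raise ValueError(
                    f"fixture row {row.specimen}/{row.sub_tendon}: ultimate "
                    "stress inconsistent with failure force / CSA")
    return df


# ---------------------------------------------------------------------------
# per-curve metrics
# ---------------------------------------------------------------------------

def _max_window_slope(x: np.ndarray, y: np.ndarray, min_window: int = 5,
                      window_fraction: float = 1 / 3) -> float:
    """Max slope of straight-line fits over sliding windows of the region."""
    n = len(x)
    w = max(min_window, int(round(window_fraction * n)))
    if n < min_window:
        raise ValueError(f"fitting region shorter than {min_window} samples")
    w = min(w, n)
    best = -np.inf
    for start in range(0, n - w + 1):
        xs = x[start:start + w]
        ys = y[start:start + w]
        slope = np.polyfit(xs, ys, 1)[0]
        best = max(best, float(slope))
    return best


def specimen_metrics(curve: TestCurve, drop_fraction: float = 0.2,
                     force_band: tuple[float, float] = (0.2, 0.8)) -> dict:
    """Mechanical metrics of one sub-tendon from its tensile test curve.

    Failure is the force maximum, which must be followed by a drop of at
    least ``drop_fraction`` of the peak.  Stiffness (N/mm) is the maximal
    slope of a sliding-window straight-line fit between 20% and 80% of the
    failure force on the force-displacement curve; Young's modulus (MPa) is
    the same procedure on the stress-strain curve.
    """
    f = curve.force_n
    i_peak = int(np.argmax(f))
    fmax = float(f[i_peak])
    if i_peak == len(f) - 1 or f[i_peak:].min() > (1 - drop_fraction) * fmax:
        raise ValueError("no failure detected (required force drop missing)")
    csa = curve.csa_mm2
    if np.isnan(csa) or csa <= 0:
        raise ValueError("curve lacks a valid CSA")

    pre = slice(0, i_peak + 1)
    band = np.flatnonzero((f[pre] >= force_band[0] * fmax)
                          & (f[pre] <= force_band[1] * fmax))
    if len(band) < 5:
        raise ValueError("fewer than 5 samples between 20% and 80% of "
                         "failure force")
    disp = curve.displacement_mm
    stiffness = _max_window_slope(disp[band], f[band])
    modulus = _max_window_slope(curve.strain[band], curve.stress_mpa[band])
    return {
        "csa_mm2": csa,
        "failure_force_n": fmax,
        "ultimate_stress_mpa": fmax / csa,
        "ultimate_strain_pct": float(disp[i_peak] / curve.gauge_length_mm * 100),
        "modulus_mpa": modulus,
        "stiffness_n_mm": stiffness,
    }


# ---------------------------------------------------------------------------
# group summary and tests
# ---------------------------------------------------------------------------

def summarize_group(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1) per metric per sub-tendon.

    Returns a table indexed by ('mean'|'sd', sub_tendon) with metric columns.
    """
    if table["specimen"].nunique() < 2:
        raise ValueError("need at least two specimens")
    rows = []
    for st in SUBTENDON_ORDER:
        sub = table[table["sub_tendon"] == st]
        rows.append(("mean", st.value, sub[list(METRICS)].mean()))
        rows.append(("sd", st.value, sub[list(METRICS)].std(ddof=1)))
    out = pd.DataFrame(
        [r[2] for r in rows],
        index=pd.MultiIndex.from_tuples([(r[0], r[1]) for r in rows],
                                        names=["stat", "sub_tendon"]),
    )
    out.attrs["n"] = int(table["specimen"].nunique())
    return out


def metric_tests(table: pd.DataFrame, metric: str) -> TestResult:
    """Kruskal-Wallis comparison of one metric across the three sub-tendons."""
    groups = [table.loc[table["sub_tendon"] == st, metric].to_numpy()
              for st in SUBTENDON_ORDER]
    return kruskal_wallis(groups)


def posthoc_vs_soleus(table: pd.DataFrame,
                      threshold: float = POSTHOC_THRESHOLD,
                      require_omnibus: bool = True) -> pd.DataFrame:
    """Exact Mann-Whitney post hoc tests of each gastrocnemius vs soleus.

    One row per metric with the exact two-sided p-value and the significance
    star for LG vs SOL and MG vs SOL.  When ``require_omnibus`` is set, a
    metric is only starred if its Kruskal-Wallis omnibus test is significant
    at 0.05.
    """
    if not (table["sub_tendon"] == SubTendonID.SOL).any():
        raise ValueError("table has no soleus rows to compare against")
    rows = []
    for metric in METRICS:
        kw = metric_tests(table, metric)
        sol = table.loc[table["sub_tendon"] == SubTendonID.SOL,
                        metric].to_numpy()
        row = {"metric": metric, "kw_h": kw.statistic, "kw_p": kw.p_value}
        for st in (SubTendonID.LG, SubTendonID.MG):
            g = table.loc[table["sub_tendon"] == st, metric].to_numpy()
            res = mann_whitney_exact(g, sol, threshold=threshold)
            starred = res.p_value < threshold
            if require_omnibus:
                starred = starred and kw.p_value < 0.05
            row[f"{st.value}_p"] = res.p_value
            row[f"{st.value}_star"] = bool(starred)
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def sex_subgroup_means(table: pd.DataFrame) -> dict:
    """Whole-tendon CSA and failure force averaged within each sex.

    Per donor, CSA and failure force are summed over the three sub-tendons;
    means are then taken within the male and female subgroups (the donor id
    encodes age and sex, e.g. ``"69 M"``).
    """
    per = table.groupby("specimen")[["csa_mm2", "failure_force_n"]].sum()
    sex = per.index.str.strip().str[-1]
    out = {}
    for s in ("M", "F"):
        sub = per[sex == s]
        out[s] = {
            "combined_csa_mm2": float(sub["csa_mm2"].mean()),
            "combined_failure_force_n": float(sub["failure_force_n"].mean()),
        }
    return out
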
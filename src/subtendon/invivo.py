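"""In vivo stimulation analysis: normalized soleus-junction displacement.

Each stimulation trial stimulates one muscle (LG, MG or SOL) with 4 s on /
4 s off cycles while the soleus musculotendinous junction (MTJ) displacement
and the contracted muscle's own displacement are tracked.  The trial outcome
is the peak MTJ displacement normalised by the peak muscular displacement;
per-cycle peaks are measured relative to the pre-onset baseline (median of
the 0.5 s before stimulation onset) and aggregated by the median across
cycles.  Group comparison (young vs old) uses the shared exact Mann-Whitney
test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SubTendonID
from .stats import TestResult, mann_whitney_exact, sample_size_two_group_t

__all__ = [
    "CycleSpec",
    "StimTrial",
    "peak_displacement",
    "normalized_displacement",
    "cohort_table",
    "compare_groups",
    "sample_size_two_group_t",
]

BASELINE_WINDOW_S = 0.5


@dataclass(frozen=True)
class CycleSpec:
    """Stimulation timing: ``first_onset`` then alternating on/off phases."""

    on_s: float = 4.0
    off_s: float = 4.0
    first_onset_s: float = 4.0

    def __post_init__(self) -> None:
        if min(self.on_s, self.off_s, self.first_onset_s) <= 0:
            raise ValueError("cycle durations must be positive")

    def onsets(self, t_end: float) -> np.ndarray:
        """Onset times of the complete on-phases within [0, t_end]."""
        period = self.on_s + self.off_s
        n = int(np.floor((t_end - self.first_onset_s) / period)) + 1
        starts = self.first_onset_s + period * np.arange(max(n, 0))
        return starts[starts + self.on_s <= t_end + 1e-9]


@dataclass
class StimTrial:
    """One stimulation trial of one participant."""

    participant: str
    group: str                      # "young" or "old"
    muscle: SubTendonID             # stimulated muscle
    time_s: np.ndarray
    mtj_mm: np.ndarray              # soleus MTJ displacement trace
    reference_mm: np.ndarray        # contracted-muscle displacement trace
    cycle: CycleSpec = field(default_factory=CycleSpec)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.mtj_mm = np.asarray(self.mtj_mm, dtype=float)
        self.reference_mm = np.asarray(self.reference_mm, dtype=float)
        if not (len(self.time_s) == len(self.mtj_mm)
                == len(self.reference_mm)):
            raise ValueError("traces must share one time base")
        if len(self.cycle.onsets(self.time_s[-1])) < 3:
            raise ValueError("trial must contain at least three complete "
                             "contraction cycles")


def peak_displacement(time_s, trace_mm, cycle: CycleSpec | None = None) -> float:
    """Median across cycles of the baseline-relative per-cycle peak (mm).

    The per-cycle baseline is the median of the trace over the 0.5 s before
    stimulation onset; the peak is the maximum displacement above that
    baseline during the on-phase.
    """
    cycle = cycle or CycleSpec()
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(trace_mm, dtype=float)
    onsets = cycle.onsets(t[-1])
    if len(onsets) == 0:
        raise ValueError("no complete on-phase in trace")
    peaks = []
    for onset in onsets:
        base_mask = (t >= onset - BASELINE_WINDOW_S) & (t < onset)
        on_mask = (t >= onset) & (t <= onset + cycle.on_s)
        if not base_mask.any() or not on_mask.any():
            continue
        baseline = float(np.median(y[base_mask]))
        peaks.append(float(y[on_mask].max() - baseline))
    if not peaks:
        raise ValueError("no usable cycle in trace")
    return float(np.median(peaks))


def normalized_displacement(trial: StimTrial) -> float:
    """Peak soleus-MTJ displacement over peak muscular displacement."""
    ref = peak_displacement(trial.time_s, trial.reference_mm, trial.cycle)
    if ref <= 0:
        raise ValueError("non-positive reference (muscular) peak displacement")
    mtj = peak_displacement(trial.time_s, trial.mtj_mm, trial.cycle)
    return mtj / ref


def cohort_table(trials) -> pd.DataFrame:
    """Normalized displacement per participant x stimulated muscle."""
    rows = [{
        "participant": tr.participant,
        "group": tr.group,
        "muscle": str(tr.muscle),
        "normalized_displacement": normalized_displacement(tr),
    } for tr in trials]
    return pd.DataFrame(rows)


def compare_groups(cohort: pd.DataFrame, muscle: SubTendonID,
                   threshold: float = 0.05) -> TestResult:
    """Exact Mann-Whitney comparison of young vs old for one muscle."""
    sub = cohort[cohort["muscle"] == str(SubTendonID(muscle))]
    young = sub.loc[sub["group"] == "young", "normalized_displacement"]
    old = sub.loc[sub["group"] == "old", "normalized_displacement"]
    if young.empty or old.empty:
        raise ValueError("both age groups must be present")
    return mann_whitney_exact(young.to_numpy(), old.to_numpy(),
                              threshold=threshold)
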
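"""Shared identifiers and containers for the Achilles sub-tendon toolkit.

Unit system: mm - N - MPa (1 N/mm^2 = 1 MPa) throughout. The longitudinal
axis is z, +z pointing proximally (distal calcaneal end at z = 0); x is
lateral, y posterior.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class SubTendonID(str, Enum):
    """The three Achilles sub-tendons, named after their muscles of origin."""

    LG = "LG"  # lateral gastrocnemius
    MG = "MG"  # medial gastrocnemius
    SOL = "SOL"  # soleus

    def __str__(self) -> str:  # tidy CSV / CLI output
        return self.value


#: Fixed ordering used for element labels and report columns.
SUBTENDON_ORDER: tuple[SubTendonID, ...] = (
    SubTendonID.LG,
    SubTendonID.MG,
    SubTendonID.SOL,
)


@dataclass
class TestCurve:
    """A uniaxial tensile test record for one sub-tendon specimen.

    Displacement is grip displacement measured from the preloaded reference
    state, so ``force`` includes the preload offset.  Strain is computed as
    displacement / gauge_length and stress as (force - preload) / csa.
    """

    __test__ = False  # name starts with "Test" but this is a data container

    time_s: np.ndarray
    displacement_mm: np.ndarray
    force_n: np.ndarray
    gauge_length_mm: float = 60.0
    csa_mm2: float = float("nan")
    preload_n: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if self.time_s.ndim != 1 or len(self.time_s) != len(self.force_n):
            raise ValueError("time and force must be 1-D and equal length")
        if len(self.displacement_mm) != len(self.time_s):
            raise ValueError("displacement and time must be equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.isnan(self.csa_mm2) and self.csa_mm2 <= 0:
            raise ValueError("CSA must be positive")
        if self.gauge_length_mm <= 0:
            raise ValueError("gauge length must be positive")

    @property
    def strain(self) -> np.ndarray:
        """Engineering strain (dimensionless)."""
        return self.displacement_mm / self.gauge_length_mm

    @property
    def stress_mpa(self) -> np.ndarray:
        """Nominal stress (MPa), preload subtracted."""
        return (self.force_n - self.preload_n) / self.csa_mm2
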
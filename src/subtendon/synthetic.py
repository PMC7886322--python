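"""Seeded generators for every synthetic input the analyses consume.

* tensile-test curves following the in vitro protocol (60 mm gauge,
  preload, 0.75 mm/s pull to failure) with a quadratic toe region joined
  C1 to the neo-Hookean uniaxial response and a terminal force drop;
* stimulation cohorts (young n = 9, old n = 7) of 4 s on / 4 s off trials
  whose normalized soleus-junction displacement carries a prescribed
  standardized group difference (default d = 1.9 for soleus stimulation,
  none for the gastrocnemii);
* jittered geometry parameter sets around the three archetypes.

All generators are pure functions of their spec (including the seed):
identical inputs give identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SUBTENDON_ORDER, SubTendonID, TestCurve
from .geometry import ARCHETYPES, DEFAULT_FRACTIONS
from .invivo import CycleSpec, StimTrial
from .material import neo_hookean_from_modulus, uniaxial_nominal_stress

__all__ = [
    "CurveGenSpec",
    "gen_test_curve",
    "CohortGenSpec",
    "gen_cohort",
    "gen_geometry_params",
]


# ---------------------------------------------------------------------------
# tensile test curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveGenSpec:
    """Parameters of one synthetic tensile test.

    ``toe_strain`` is the extent of the quadratic toe region; the post-toe
    response is the neo-Hookean uniaxial curve at modulus ``E`` shifted by
    half the toe extent (C1 continuity).  Failure truncates the ramp at
    ``failure_strain`` with a force drop of at least 20%.
    """

    E: float = 200.0               # MPa
    csa_mm2: float = 30.0
    gauge_length_mm: float = 60.0
    toe_strain: float = 0.02
    failure_strain: float = 0.14   # within the observed 8-19% range
    preload_n: float = 10.0
    pull_rate_mm_s: float = 0.75
    noise: float = 0.0             # fractional multiplicative force noise
    nu: float = 0.49
    sample_rate_hz: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("E", "csa_mm2", "gauge_length_mm", "toe_strain",
                     "failure_strain", "pull_rate_mm_s", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise < 0 or self.preload_n < 0:
            raise ValueError("noise and preload must be non-negative")
        if self.failure_strain <= self.toe_strain:
            raise ValueError("failure strain must exceed the toe extent")


def _toe_map(strain: np.ndarray, toe: float) -> np.ndarray:
    """C1 strain re-map: quadratic toe joined to a unit-slope line."""
    out = np.where(strain <= toe,
                   strain**2 / (2.0 * toe) if toe > 0 else strain,
                   strain - toe / 2.0)
    return out


def gen_test_curve(spec: CurveGenSpec) -> TestCurve:
    """Synthesise one force-displacement curve to failure."""
    rng = np.random.default_rng(spec.seed)
    params = neo_hookean_from_modulus(spec.E, spec.nu)
    t_fail = spec.failure_strain * spec.gauge_length_mm / spec.pull_rate_mm_s
    n = int(np.floor(t_fail * spec.sample_rate_hz)) + 1
    t = np.arange(n) / spec.sample_rate_hz
    disp = spec.pull_rate_mm_s * t
    strain = disp / spec.gauge_length_mm
    eff = _toe_map(strain, spec.toe_strain)
    stress = uniaxial_nominal_stress(params, 1.0 + eff)
    force = spec.preload_n + stress * spec.csa_mm2
    if spec.noise > 0:
        force = force * (1.0 + spec.noise * rng.standard_normal(n))
    # terminal failure: a sharp drop below 60% of the peak over 3 samples
    fmax = force.max()
    drop = fmax * np.array([0.75, 0.6, 0.55])
    t_post = t[-1] + (np.arange(1, 4)) / spec.sample_rate_hz
    curve = TestCurve(
        time_s=np.concatenate([t, t_post]),
        displacement_mm=np.concatenate(
            [disp, disp[-1] + np.zeros(3)]),
        force_n=np.concatenate([force, drop]),
        gauge_length_mm=spec.gauge_length_mm,
        csa_mm2=spec.csa_mm2,
        preload_n=spec.preload_n,
        meta={"spec": spec},
    )
    return curve


# ---------------------------------------------------------------------------
# stimulation cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGenSpec:
    """Statistical structure of a synthetic stimulation cohort.

    ``effects`` holds the standardized young-minus-old difference d of the
    normalized soleus-junction displacement per stimulated muscle; the old
    group mean is ``base_mean - d * sd``.  Defaults reproduce the study
    design: nine young and seven old participants, a soleus-stimulation
    deficit at the design effect size d = 1.9 and no gastrocnemius effect.
    """

    n_young: int = 9
    n_old: int = 7
    effects: dict = field(default_factory=lambda: {
        SubTendonID.LG: 0.0, SubTendonID.MG: 0.0, SubTendonID.SOL: 1.9})
    base_means: dict = field(default_factory=lambda: {
        SubTendonID.LG: 0.35, SubTendonID.MG: 0.35, SubTendonID.SOL: 0.5})
    sd: float = 0.12
    reference_amplitude_mm: float = 2.0
    reference_amplitude_sd: float = 0.3
    trace_noise_mm: float = 0.02
    cycle: CycleSpec = field(default_factory=CycleSpec)
    n_cycles: int = 3
    sample_rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 1 or self.n_old < 1:
            raise ValueError("need at least one participant per group")
        if self.sd <= 0:
            raise ValueError("within-group SD must be positive")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _pulse_train(t: np.ndarray, cycle: CycleSpec, amplitude: float,
                 rise_s: float = 0.5) -> np.ndarray:
    y = np.zeros_like(t)
    for onset in cycle.onsets(t[-1]):
        up = _smoothstep((t - onset) / rise_s)
        down = _smoothstep((t - onset - cycle.on_s) / rise_s)
        y += amplitude * (up - down)
    return y


def gen_cohort(spec: CohortGenSpec) -> list[StimTrial]:
    """Synthesise the full cohort: one trial per participant per muscle."""
    rng = np.random.default_rng(spec.seed)
    duration = (spec.cycle.first_onset_s
                + spec.n_cycles * (spec.cycle.on_s + spec.cycle.off_s))
    t = np.arange(int(duration * spec.sample_rate_hz) + 1) / spec.sample_rate_hz
    trials = []
    participants = ([("young", i) for i in range(spec.n_young)]
                    + [("old", i) for i in range(spec.n_old)])
    for group, idx in participants:
        for muscle in SUBTENDON_ORDER:
            d = spec.effects.get(muscle, 0.0)
            mean = spec.base_means.get(muscle, 0.5)
            if group == "old":
                mean = mean - d * spec.sd
            target = max(rng.normal(mean, spec.sd), 0.05)
            a_ref = max(rng.normal(spec.reference_amplitude_mm,
                                   spec.reference_amplitude_sd), 0.8)
            ref = _pulse_train(t, spec.cycle, a_ref)
            mtj = _pulse_train(t, spec.cycle, target * a_ref)
            if spec.trace_noise_mm > 0:
                ref = ref + rng.normal(0, spec.trace_noise_mm, len(t))
                mtj = mtj + rng.normal(0, spec.trace_noise_mm, len(t))
            trials.append(StimTrial(
                participant=f"{group}{idx:02d}",
                group=group,
                muscle=muscle,
                time_s=t,
                mtj_mm=mtj,
                reference_mm=ref,
                cycle=spec.cycle,
            ))
    return trials


# ---------------------------------------------------------------------------
# geometry parameter jitter
# ---------------------------------------------------------------------------

def gen_geometry_params(archetype_id: int, jitter: float = 0.0,
                        seed: int = 0) -> dict:
    """Jittered ``make_archetype`` overrides around an archetype's defaults.

    Total CSA and twist receive unbiased multiplicative Gaussian jitter;
    area fractions are jittered and renormalised.  Non-physical draws are
    clipped to 20% of the default.  Zero jitter returns the exact defaults.
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    if archetype_id not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype_id!r}")
    base = ARCHETYPES[archetype_id]
    rng = np.random.default_rng(seed)
    csa = base["total_csa"] * (1.0 + jitter * rng.standard_normal())
    twist = base["twist_deg"] * (1.0 + jitter * rng.standard_normal())
    fr = {s: f * max(1.0 + jitter * rng.standard_normal(), 0.2)
          for s, f in DEFAULT_FRACTIONS.items()}
    total = sum(fr.values())
    return {
        "total_csa": float(max(csa, 0.2 * base["total_csa"])),
        "twist_deg": float(twist),
        "fractions": {s: float(v / total) for s, v in fr.items()},
    }
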
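"""Seeded generative model of phage–host QCM-D experiments.

The generator reproduces, without any instrument, the statistical structure
of a phage screening run on a 5 MHz sensor: a PBS baseline, adsorption of
*E. coli* under flow, a medium flush, two hours of static growth, injection
of phage (or plain medium), another flush, and three hours of static
incubation.  Three scenarios are supported:

``control``
    No phage; the bacterial film keeps growing after the second injection
    and the overtone spread of ΔD saturates at a sensor-dependent level.
``infectious``
    A lytic phage (T7-like, 17-min latent period).  Infected cells rupture,
    the film collapses into a thin, stiff debris layer, and the δD spread
    drops by roughly 80% largely independent of titer; at low titer a
    surviving fraction resumes growth late in the run.
``non_infectious``
    A phage that adsorbs (mass load, Δf drop) but cannot infect the host
    (phi29-like); the film behaves like the control afterwards.

The latent state is a deterministic :class:`FilmTrajectory` (thickness,
softness, coverage, rigid mass); measured traces are obtained by pushing it
through the closed-form kernels in :mod:`qcmdlysis.physics`, scaling by a
per-sensor sensitivity, and adding i.i.d. Gaussian noise per channel.  With
the noise switched off, ``simulate_experiment`` equals kernels∘trajectory
exactly, which the test suite uses as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .physics import (
    WATER_25C,
    FilmState,
    LiquidProperties,
    dissipation_kernel,
    frequency_kernel,
    sauerbrey_constant,
)
from .traces import (
    ANALYSIS_OVERTONES,
    OvertoneTrace,
    Phase,
    PhaseSchedule,
    QcmdExperiment,
    ScheduleError,
)

__all__ = [
    "SimParams",
    "FilmTrajectory",
    "default_schedule",
    "infection_fraction",
    "film_trajectory",
    "simulate_experiment",
    "simulate_panel",
    "paper_panel_design",
    "DEFAULT_TITERS",
]

SCENARIOS = ("control", "infectious", "non_infectious")

#: T7 titers used by the default screening panel, PFU/mL.
DEFAULT_TITERS = (8e7, 2e6, 4e5)

#: Default titer of the non-infectious (phi29-like) phage, PFU/mL.
NON_INFECTIOUS_TITER = 2e8

#: Reference titer at which the phage mass amplitude is calibrated.
REFERENCE_TITER = 8e7

# Δf3 calibration: at the reference titer the rigid phage load saturates to
# phage_mass_amplitude within the 20-min injection (uptake rate 0.25/min,
# k·t = 5), and the amplitude is chosen so the resulting Sauerbrey step on
# the third overtone is -60 Hz.
_UPTAKE_RATE = 0.25
_INJECTION_MIN = 20.0
DEFAULT_PHAGE_MASS = (
    60.0 * sauerbrey_constant(5e6) / 3.0 / (1.0 - math.exp(-_UPTAKE_RATE * _INJECTION_MIN))
)


def default_schedule(phage: bool = True) -> PhaseSchedule:
    """The standard assay schedule (durations in minutes).

    20 PBS | 30 bacteria | 15 flush | 120 static growth | 20 second
    injection (phage or plain medium) | 15 flush | 180 static incubation.
    """
    flow = 30.0  # µL/min
    second_medium = "phage_in_medium" if phage else "medium"
    return PhaseSchedule(
        [
            Phase("baseline_pbs", 0.0, 20.0, "PBS", flow),
            Phase("bacteria_injection", 20.0, 50.0, "bacteria_in_medium", flow),
            Phase("flush_1", 50.0, 65.0, "medium", flow),
            Phase("growth_static", 65.0, 185.0, "medium", 0.0),
            Phase("second_injection", 185.0, 205.0, second_medium, flow),
            Phase("flush_2", 205.0, 220.0, "medium", flow),
            Phase("post_static", 220.0, 400.0, "medium", 0.0),
        ]
    )


@dataclass
class SimParams:
    """Generative parameters of one simulated experiment.

    The defaults encode the study conditions of the assay the generator
    emulates; see ``docs/methods.md`` for units, rationale and calibration
    of every default.
    """

    scenario: str = "control"
    titer: float = 0.0  # PFU/mL; 0 for control
    schedule: Optional[PhaseSchedule] = None  # default built from scenario
    fundamental_frequency: float = 5e6  # Hz
    liquid: LiquidProperties = WATER_25C

    # --- bacterial film formation ---
    adsorption_rate: float = 0.12  # k_a, 1/min (saturating adsorption)
    max_coverage: float = 0.6  # asymptotic fractional coverage
    adsorbed_thickness: float = 40.0  # nm, effective film right after adsorption
    growth_rate: float = 0.02  # r, 1/min (logistic growth in static phases)
    carrying_thickness: float = 150.0  # h_cap, nm
    flow_coverage_loss: float = 0.03  # fractional loss of θ per flow phase
    flow_thickness_loss: float = 0.06  # fractional loss of h per flow phase

    # --- infection and lysis ---
    latency: float = 17.0  # τ, min (T7 lytic cycle)
    infection_rate_constant: float = 7e-7  # k_i, mL/(PFU·min)
    infection_cooperativity: float = 0.6  # sublinear dose exponent γ
    collapse_time: float = 10.0  # min, film-collapse time constant
    debris_thickness: float = 60.0  # nm, effective collapsed-debris layer
    debris_softness: float = 0.4  # dimensionless
    survivor_regrowth_boost: float = 2.5  # multiplies r for survivors

    # --- phage adsorption (rigid load) ---
    phage_mass_amplitude: float = DEFAULT_PHAGE_MASS  # ng/cm²
    phage_uptake_rate: float = _UPTAKE_RATE  # 1/min at the reference titer

    # --- transduction amplitudes ---
    dissipation_amplitude: float = 120.0  # A_D, 1e-6 units
    resonance_amplitude: float = 30.0  # A_f, Hz

    # --- sensor individuality and noise ---
    sensor_sensitivity: float = 1.0  # λ, multiplies both channels
    resonance_sign: int = +1  # χ
    noise_sd_f: float = 0.5  # Hz
    noise_sd_D: float = 0.05  # 1e-6 units
    dt: float = 0.5  # min, grid step
    seed: int = 0

    sensor_id: str = ""

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.schedule is None:
            self.schedule = default_schedule(phage=self.scenario != "control")
        nonneg = (
            self.titer,
            self.adsorption_rate,
            self.adsorbed_thickness,
            self.growth_rate,
            self.carrying_thickness,
            self.latency,
            self.infection_rate_constant,
            self.collapse_time,
            self.debris_thickness,
            self.survivor_regrowth_boost,
            self.phage_mass_amplitude,
            self.phage_uptake_rate,
            self.dissipation_amplitude,
            self.noise_sd_f,
            self.noise_sd_D,
        )
        if any(v < 0 for v in nonneg):
            raise ValueError("rates, times and amplitudes must be >= 0")
        if not 0 <= self.debris_softness <= 1:
            raise ValueError("debris softness must lie in [0, 1]")
        if not 0 < self.max_coverage <= 1:
            raise ValueError("max coverage must lie in (0, 1]")
        for loss in (self.flow_coverage_loss, self.flow_thickness_loss):
            if not 0 <= loss < 1:
                raise ValueError("flow losses must lie in [0, 1)")
        if self.resonance_sign not in (+1, -1):
            raise ValueError("resonance_sign must be +1 or -1")
        if self.dt <= 0:
            raise ValueError("grid step must be positive")
        if self.infection_cooperativity <= 0:
            raise ValueError("infection cooperativity must be positive")
        if self.scenario != "control" and self.titer <= 0:
            raise ValueError("phage scenarios require a positive titer")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def control(cls, **kw) -> "SimParams":
        return cls(scenario="control", titer=0.0, **kw)

    @classmethod
    def infectious(cls, titer: float = DEFAULT_TITERS[0], **kw) -> "SimParams":
        return cls(scenario="infectious", titer=titer, **kw)

    @classmethod
    def non_infectious(cls, titer: float = NON_INFECTIOUS_TITER, **kw) -> "SimParams":
        return cls(scenario="non_infectious", titer=titer, **kw)


@dataclass
class FilmTrajectory:
    """Noise-free latent film state on the simulation grid."""

    time: np.ndarray  # min
    thickness: np.ndarray  # h(t), nm
    softness: np.ndarray  # s(t), [0, 1]
    coverage: np.ndarray  # θ(t), [0, 1]
    rigid_mass: np.ndarray  # m(t), ng/cm²
    infected_fraction: float  # p used for the collapse (0 outside infectious)
    schedule: PhaseSchedule = field(repr=False, default=None)


def infection_fraction(
    titer: float, k_i: float, exposure: float, cooperativity: float = 1.0
) -> float:
    """Fraction of surface bacteria infected during phage exposure.

    Poisson encounter model ``p = 1 − exp(−(k_i · titer · exposure)^γ)``.
    With ``γ = 1`` this is the classic single-hit form (``p = 1/2`` when
    the dose equals ln 2).  ``γ < 1`` flattens the titer dependence,
    standing in for secondary infection by burst progeny and
    surface-limited encounter kinetics, which make the lysed fraction far
    less titer-sensitive than a single-hit model predicts.
    """
    if titer < 0 or k_i < 0 or exposure < 0:
        raise ValueError("titer, rate constant and exposure must be >= 0")
    if cooperativity <= 0:
        raise ValueError("cooperativity must be positive")
    dose = k_i * titer * exposure
    return float(-np.expm1(-(dose**cooperativity))) if dose > 0 else 0.0


def _exp_step(x: float, target: float, rate: float, dt: float) -> float:
    """Exact update of dx/dt = rate·(target − x) over one step."""
    return target + (x - target) * math.exp(-rate * dt)


def _logistic_step(h: float, r: float, cap: float, dt: float) -> float:
    """Exact update of dh/dt = r·h·(1 − h/cap) over one step."""
    if h <= 0 or r == 0:
        return h
    return cap / (1.0 + (cap / h - 1.0) * math.exp(-r * dt))


def film_trajectory(params: SimParams) -> FilmTrajectory:
    """Integrate the noise-free latent film state over the schedule.

    Kinetics, phase by phase: coverage rises with saturating-exponential
    kinetics while bacteria flow in, and thickness tracks it; every flow
    phase after adsorption strips a small multiplicative fraction of
    coverage and thickness (desorption of loosely bound cells), applied as
    a front-loaded transient so the familiar flush dip settles within the
    phase and the signal is already recovering when the flush ends;
    thickness grows logistically in every phase after adsorption (fresh
    medium sustains growth under flow as well as under static
    incubation); in phage scenarios, rigid mass accumulates during the
    second injection at a titer-proportional uptake rate.  In the
    infectious scenario, one latent period after the phage injection
    starts, an infected fraction ``p`` of the film relaxes (time constant
    ``collapse_time``) onto a thin, stiff debris layer, while the
    surviving fraction resumes boosted logistic growth once the flow
    stops (the lysate that fuels survivor regrowth is washed out under
    flow but retained in the static flow cell).
    """
    sched = params.schedule
    if not sched.has_phase("second_injection"):
        raise ScheduleError("schedule must contain a second_injection phase")
    inj = sched.phase("second_injection")
    time = np.arange(sched.start, sched.end, params.dt)
    n = len(time)
    h_arr = np.zeros(n)
    s_arr = np.ones(n)
    th_arr = np.zeros(n)
    m_arr = np.zeros(n)

    has_phage = params.scenario != "control"
    p = 0.0
    if params.scenario == "infectious":
        p = infection_fraction(
            params.titer,
            params.infection_rate_constant,
            inj.duration,
            params.infection_cooperativity,
        )
    t_onset = inj.start + params.latency

    uptake = params.phage_uptake_rate * (params.titer / REFERENCE_TITER)
    theta = 0.0
    h = 0.0
    s = 1.0
    m = 0.0
    h_surv = None  # survivor component, set at collapse onset
    current_phase = None
    # Front-loaded desorption transient: within a flow phase of duration D
    # the fraction of the total multiplicative loss realized by elapsed
    # time x follows (1 - exp(-k x)) / (1 - exp(-k D)) with k = 5/D, so
    # the dip settles well before the phase ends.
    flush_k = 0.0
    flush_norm = 1.0
    flush_t0 = 0.0

    def _loss_increment(t_now: float, dt: float) -> float:
        f0 = -math.expm1(-flush_k * (t_now - flush_t0))
        f1 = -math.expm1(-flush_k * (t_now + dt - flush_t0))
        return (f1 - f0) / flush_norm

    for i, t in enumerate(time):
        th_arr[i], h_arr[i], s_arr[i], m_arr[i] = theta, h, s, m
        ph = sched.phase_at(t)
        is_flushing = ph.flow_rate > 0 and ph.name not in (
            "baseline_pbs",
            "bacteria_injection",
        )
        if ph is not current_phase:
            current_phase = ph
            if is_flushing:
                flush_k = 5.0 / ph.duration
                flush_norm = -math.expm1(-5.0)
                flush_t0 = ph.start
        dt = params.dt
        collapsing = params.scenario == "infectious" and t >= t_onset

        if ph.name == "bacteria_injection":
            theta = _exp_step(theta, params.max_coverage, params.adsorption_rate, dt)
            h = params.adsorbed_thickness * theta / params.max_coverage
        else:
            if is_flushing:
                frac = _loss_increment(t, dt)
                theta *= (1.0 - params.flow_coverage_loss) ** frac
                if not collapsing:
                    h *= (1.0 - params.flow_thickness_loss) ** frac
            if ph.name != "baseline_pbs" and not collapsing:
                h = _logistic_step(h, params.growth_rate, params.carrying_thickness, dt)

        if has_phage and ph.name == "second_injection":
            m = _exp_step(m, params.phage_mass_amplitude, uptake, dt)

        if collapsing:
            if h_surv is None:
                h_surv = (1.0 - p) * h
            debris = p * params.debris_thickness
            if ph.flow_rate == 0 and h_surv > 0:
                cap = max(params.carrying_thickness - debris, h_surv)
                h_surv = _logistic_step(
                    h_surv, params.growth_rate * params.survivor_regrowth_boost, cap, dt
                )
            h_target = h_surv + debris
            if h_target > 0:
                s_target = (h_surv + debris * params.debris_softness) / h_target
            else:
                s_target = 1.0
            rate = 1.0 / params.collapse_time if params.collapse_time > 0 else np.inf
            if np.isfinite(rate):
                h = _exp_step(h, h_target, rate, dt)
                s = _exp_step(s, s_target, rate, dt)
            else:
                h, s = h_target, s_target

    return FilmTrajectory(
        time=time,
        thickness=h_arr,
        softness=s_arr,
        coverage=th_arr,
        rigid_mass=m_arr,
        infected_fraction=p,
        schedule=sched,
    )


def simulate_experiment(params: SimParams) -> QcmdExperiment:
    """Simulate one multi-overtone experiment (overtones 3, 5, 7, 9, 11).

    The latent :func:`film_trajectory` is pushed through the frequency and
    dissipation kernels for each overtone, scaled by the sensor
    sensitivity λ, and independent Gaussian noise is added per channel.
    Identical parameters (including seed) give bit-identical output.
    """
    traj = film_trajectory(params)
    film = FilmState(
        thickness=traj.thickness,
        softness=traj.softness,
        rigid_mass=traj.rigid_mass,
        coverage=traj.coverage,
        resonance_sign=params.resonance_sign,
    )
    rng = np.random.default_rng(params.seed)
    lam = params.sensor_sensitivity
    traces = {}
    npts = len(traj.time)
    for n in ANALYSIS_OVERTONES:
        df = lam * frequency_kernel(
            film, n, params.fundamental_frequency, params.resonance_amplitude
        )
        dD = lam * dissipation_kernel(
            film,
            n,
            params.fundamental_frequency,
            params.liquid,
            params.dissipation_amplitude,
        )
        if params.noise_sd_f > 0:
            df = df + rng.normal(0.0, params.noise_sd_f, npts)
        if params.noise_sd_D > 0:
            dD = dD + rng.normal(0.0, params.noise_sd_D, npts)
        traces[n] = OvertoneTrace(n, traj.time, df, dD)
    sensor_id = params.sensor_id or f"sim-{params.scenario}-{params.seed}"
    return QcmdExperiment(
        sensor_id=sensor_id,
        traces=traces,
        schedule=params.schedule,
        fundamental_frequency=params.fundamental_frequency,
        label=params.scenario,
        metadata={"titer": params.titer, "seed": params.seed},
    )


def paper_panel_design(
    n_control: int = 2,
    titers: Sequence[float] = DEFAULT_TITERS,
    n_non_infectious: int = 1,
    **overrides,
) -> list[SimParams]:
    """Default screening panel: controls, one infectious arm per titer, and
    a non-infectious phage arm."""
    design = [SimParams.control(**overrides) for _ in range(n_control)]
    design += [SimParams.infectious(titer=t, **overrides) for t in titers]
    design += [SimParams.non_infectious(**overrides) for _ in range(n_non_infectious)]
    return design


def simulate_panel(
    design: Sequence[SimParams], master_seed: int
) -> list[tuple[QcmdExperiment, str]]:
    """Simulate a panel of experiments with sensor-to-sensor variability.

    Per-replicate seeds are derived deterministically from ``master_seed``;
    each replicate draws its own sensitivity λ ~ lognormal(0, 0.15²) and
    resonance sign χ = ±1 (equal probability) to emulate sensor
    individuality.  Returns ``(experiment, ground_truth_label)`` pairs.
    """
    if not design:
        raise ValueError("panel design must not be empty")
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31, size=len(design))
    out = []
    for i, base in enumerate(design):
        lam = float(rng.lognormal(mean=0.0, sigma=0.15))
        chi = int(rng.choice((1, -1)))
        params = replace(
            base,
            seed=int(seeds[i]),
            sensor_sensitivity=base.sensor_sensitivity * lam,
            resonance_sign=chi * base.resonance_sign,
            sensor_id=base.sensor_id or f"sim-{i:02d}-{base.scenario}",
        )
        exp = simulate_experiment(params)
        out.append((exp, base.scenario))
    return out
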
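"""Ground-truth simulator of the instrument coupled to a 1-D active tissue.

The "plant" is everything the measurement software cannot see directly:

* a piezo bender that converts commanded voltage to chip displacement, with a
  random-walk drift;
* a pair of plate capacitors flanking the piezo whose capacitance difference
  encodes the true chip position (with readout noise);
* an elastic cantilever (single-spring approximation, spring constant k)
  whose tip is inserted into the tissue;
* an active tissue front that advances against the probe following a linear
  (Hill-like, degree 1) force–velocity law with stall, optionally with
  exponential dissipation of its active-stress capacity.

Every other module is tested against this twin: the calibration and control
loops only ever see the noisy capacitances and rendered/synthetic tip
measurements, never the ``*_true`` fields.

Sign convention: the measurement axis is 1-D, positive in the direction the
tissue pushes the tip. Deflection δ = X_T − X_C is ≥ 0 while the tissue loads
the probe; constant-force loading drives δ < 0 (the chip leads the tip and the
spring assists the tissue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from tifm import units
from tifm.tracks import CellTrack

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

FOIL_WIDTH_RANGE_UM = (100.0, 400.0)  # fabrication range for cut foil pieces


@dataclass(frozen=True)
class ProbeSpec:
    """Cantilever/foil geometry and spring constant.

    Parameters
    ----------
    spring_constant : float
        k in N/m (commercial probes span 0.01–0.2 N/m).
    probe_length : float
        L in µm, base-to-tip extent of the cantilever (default 200 µm).
    tip_width : float
        Width of the bare tip in µm (sharp probes are 30–50 µm wide).
    tip_thickness : float
        Thickness in µm (~1 µm for bare tips, ~15 µm for foil).
    tip_shape : str
        "sharp" | "triangular" | "foil".
    foil_width, foil_height, foil_thickness : float, optional
        Foil dimensions in µm; required iff tip_shape == "foil".
    label : str
        "none" | "fluorescent" — whether the tip carries a fluorescent marker.
    """

    spring_constant: float
    probe_length: float = 200.0
    tip_width: float = 40.0
    tip_thickness: float = 1.0
    tip_shape: str = "sharp"
    foil_width: float | None = None
    foil_height: float | None = None
    foil_thickness: float | None = None
    label: str = "none"

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.probe_length <= 0:
            raise ValueError("probe_length must be > 0")
        if self.tip_shape not in ("sharp", "triangular", "foil"):
            raise ValueError(f"unknown tip_shape {self.tip_shape!r}")
        if self.label not in ("none", "fluorescent"):
            raise ValueError(f"unknown label {self.label!r}")
        foil_fields = (self.foil_width, self.foil_height, self.foil_thickness)
        if self.tip_shape == "foil":
            if any(f is None for f in foil_fields):
                raise ValueError("foil tip requires foil_width/height/thickness")
            lo, hi = FOIL_WIDTH_RANGE_UM
            if not (lo <= self.foil_width <= hi):
                raise ValueError(
                    f"foil_width {self.foil_width} µm outside fabrication "
                    f"range [{lo}, {hi}] µm"
                )
        elif any(f is not None for f in foil_fields):
            raise ValueError("foil fields only allowed when tip_shape='foil'")


@dataclass(frozen=True)
class PiezoModel:
    """Piezo bender + capacitor-pair parameters.

    gain : µm of chip travel per V.
    voltage_range : (min, max) V accepted by the driver.
    drift_rate : µm/√s scale of the random-walk drift of the energized piezo.
    readout_noise_capacitance : pF s.d. of each capacitance reading.
    capacitor_gap : g0, µm — plate gap at chip position 0.
    capacitor_coefficient : c0, pF·µm — C(x) = c0/(g0 ∓ x).
    """

    gain: float = 0.4
    voltage_range: tuple[float, float] = (0.0, 150.0)
    drift_rate: float = 0.01
    readout_noise_capacitance: float = 0.002
    capacitor_gap: float = 100.0
    capacitor_coefficient: float = 900.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.readout_noise_capacitance < 0 or self.drift_rate < 0:
            raise ValueError("noise scales must be ≥ 0")
        if self.capacitor_gap <= 0 or self.capacitor_coefficient <= 0:
            raise ValueError("capacitor geometry must be positive")
        vmax_excursion = max(abs(v) * self.gain for v in self.voltage_range)
        if self.capacitor_gap <= vmax_excursion:
            raise ValueError("capacitor gap must exceed maximal chip excursion")


@dataclass(frozen=True)
class TissueModel:
    """Phenomenological active tissue pushing against the probe.

    The tissue front advances at ``v = v0 (1 − σ_r/σ_a)``: free velocity v0
    with no load, linear slowdown with resisting stress σ_r, stall at
    σ_r = σ_a. An assisting (negative) σ_r speeds the front up. The active
    capacity σ_a decays exponentially with timescale τ_d when dissipation is
    enabled (τ_d = inf disables it).

    ``yield_when_overloaded`` lets the front recede (v < 0, capped at −v0)
    when σ_r exceeds σ_a, so that a dissipating tissue unloads the probe and
    the measured force trace decays with σ_a; with the default (False) the
    front simply stops when overloaded.
    """

    active_stress_capacity: float = 100.0  # σ_a0, Pa
    free_velocity: float = 150.0  # v0, µm/h
    dissipation_timescale: float = math.inf  # τ_d, h
    passive_viscous_coefficient: float = 0.0  # Pa·h/µm, reserved
    contact_mode: str = "blocking"  # "blocking" | "lateral"
    yield_when_overloaded: bool = False

    def __post_init__(self) -> None:
        if self.active_stress_capacity < 0:
            raise ValueError("active_stress_capacity must be ≥ 0")
        if self.free_velocity < 0:
            raise ValueError("free_velocity must be ≥ 0")
        if self.dissipation_timescale <= 0:
            raise ValueError("dissipation_timescale must be > 0")
        if self.contact_mode not in ("blocking", "lateral"):
            raise ValueError(f"unknown contact_mode {self.contact_mode!r}")


@dataclass
class PlantState:
    """Ground-truth instrument + tissue state at one time point."""

    time: float = 0.0  # s
    X_C_true: float = 0.0  # chip position, µm
    X_T_true: float = 0.0  # tip position, µm
    tissue_front: float = 0.0  # µm
    sigma_a: float = 100.0  # current active stress capacity, Pa
    applied_voltage: float = 0.0  # V
    C1: float = 0.0  # pF
    C2: float = 0.0  # pF
    drift_accum: float = 0.0  # accumulated piezo drift, µm
    saturated: bool = False
    beam_regime_exceeded: bool = False
    in_contact: bool = True
    cell_density: np.ndarray | None = None  # per-µm linear density
    density_grid: np.ndarray | None = None  # cell-center coordinates, µm


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def piezo_displacement(
    voltage: float,
    piezo: PiezoModel,
    dt: float,
    rng: np.random.Generator | None = None,
    drift_accum: float = 0.0,
) -> tuple[float, float, bool]:
    """One actuation step: commanded voltage → chip displacement.

    Returns ``(displacement_um, new_drift_accum, saturated)``. The voltage is
    clamped to the driver range (saturation is flagged, not raised); the drift
    accumulator performs a random walk with increments of s.d.
    ``drift_rate·√dt``.
    """
    vmin, vmax = piezo.voltage_range
    saturated = voltage < vmin or voltage > vmax
    v = min(max(voltage, vmin), vmax)
    if piezo.drift_rate > 0 and rng is not None and dt > 0:
        drift_accum = drift_accum + rng.normal(0.0, piezo.drift_rate * math.sqrt(dt))
    return piezo.gain * v + drift_accum, drift_accum, saturated


def capacitance_pair(
    chip_position: float,
    piezo: PiezoModel,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Noisy (C1, C2) readings for a chip at ``chip_position`` µm.

    C1 = c0/(g0 − x), C2 = c0/(g0 + x); ΔC = C1 − C2 is strictly increasing
    in x on (−g0, g0). Plates touching (|x| ≥ g0) is unphysical and raises.
    """
    g0, c0 = piezo.capacitor_gap, piezo.capacitor_coefficient
    if abs(chip_position) >= g0:
        raise ValueError(
            f"|chip position| = {abs(chip_position):g} µm ≥ capacitor gap {g0} µm"
        )
    c1 = c0 / (g0 - chip_position)
    c2 = c0 / (g0 + chip_position)
    if rng is not None and piezo.readout_noise_capacitance > 0:
        c1 += rng.normal(0.0, piezo.readout_noise_capacitance)
        c2 += rng.normal(0.0, piezo.readout_noise_capacitance)
    return c1, c2


def invert_capacitance(delta_c: float, piezo: PiezoModel) -> float:
    """Exact inverse of the noise-free capacitor formula: ΔC → chip position.

    ΔC = 2 c0 x / (g0² − x²) solves to x = ΔC g0² / (c0 + √(c0² + ΔC² g0²))
    (the conjugate form is numerically stable at small ΔC).
    """
    g0, c0 = piezo.capacitor_gap, piezo.capacitor_coefficient
    return (delta_c * g0 * g0) / (
        c0 + math.sqrt(c0 * c0 + delta_c * delta_c * g0 * g0)
    )


def tissue_velocity(resisting_stress: float, tissue: TissueModel) -> float:
    """Front velocity (µm/h) under a resisting stress σ_r (Pa).

    Linear force–velocity with stall: v = v0(1 − σ_r/σ_a), clamped to 0 when
    σ_r ≥ σ_a (unless the tissue yields when overloaded, in which case v may
    go negative down to −v0). A fully dissipated tissue (σ_a = 0) does not
    move under resistance.
    """
    sigma_a = tissue.active_stress_capacity
    v0 = tissue.free_velocity
    if sigma_a <= 0.0:
        if resisting_stress > 0.0 and tissue.yield_when_overloaded:
            return -v0
        return 0.0
    v = v0 * (1.0 - resisting_stress / sigma_a)
    if v < 0.0:
        return max(v, -v0) if tissue.yield_when_overloaded else 0.0
    return v


def _advect_density(
    density: np.ndarray,
    grid: np.ndarray,
    velocity_um_s: float,
    dt: float,
    block_position: float,
) -> np.ndarray:
    """Flux-conservative upwind advection with a zero-flux wall at the foil.

    Mass only moves between adjacent cells; the interface nearest to
    ``block_position`` and both domain edges carry zero flux, so total mass
    is conserved exactly (cells pile up anterior to the foil).
    """
    n = len(density)
    dx = grid[1] - grid[0]
    cfl = velocity_um_s * dt / dx
    if abs(cfl) > 1.0:
        raise ValueError("advection CFL > 1; reduce dt or coarsen grid")
    # interface j sits between cells j-1 and j, at grid[j] - dx/2
    flux = np.zeros(n + 1)
    if cfl >= 0:
        flux[1:n] = cfl * density[:-1]
    else:
        flux[1:n] = cfl * density[1:]
    # zero-flux wall at the interface closest to the foil
    j_block = int(np.clip(round((block_position - grid[0]) / dx + 0.5), 0, n))
    flux[j_block] = 0.0
    out = density + (flux[:-1] - flux[1:])
    return out


def step_plant(
    state: PlantState,
    voltage_command: float,
    probe: ProbeSpec,
    tissue: TissueModel,
    contact_area: float,
    piezo: PiezoModel,
    dt: float,
    rng: np.random.Generator | None = None,
) -> PlantState:
    """Advance the coupled instrument + tissue by one time step of ``dt`` s.

    The chip moves per the piezo model; the tip is pinned to the tissue front
    (no-slip insertion); the front moves at the force–velocity law evaluated
    at σ_r = k(X_T − X_C)/A; the active capacity decays when dissipation is
    enabled; capacitances are refreshed; the optional cell-density field is
    advected with flux blocked at the foil.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x_c, drift, saturated = piezo_displacement(
        voltage_command, piezo, dt, rng, state.drift_accum
    )
    # resisting stress on the tissue from the bent cantilever
    deflection = state.X_T_true - x_c
    sigma_r = units.stress_Pa(
        units.force_nN(probe.spring_constant, deflection), contact_area
    )
    tissue_now = replace(tissue, active_stress_capacity=state.sigma_a)
    v_um_h = tissue_velocity(sigma_r, tissue_now) if state.in_contact else 0.0
    v_um_s = units.um_per_h_to_um_per_s(v_um_h)
    front = state.tissue_front + v_um_s * dt
    x_t = front if state.in_contact else state.X_T_true

    sigma_a = state.sigma_a
    if math.isfinite(tissue.dissipation_timescale):
        sigma_a *= math.exp(-dt / (tissue.dissipation_timescale * units.S_PER_H))

    c1, c2 = capacitance_pair(x_c, piezo, rng)

    density = state.cell_density
    if density is not None:
        density = _advect_density(
            density, state.density_grid, v_um_s, dt, block_position=x_t
        )

    beam_flag = state.beam_regime_exceeded or abs(x_t - x_c) > 0.5 * probe.probe_length
    return replace(
        state,
        time=state.time + dt,
        X_C_true=x_c,
        X_T_true=x_t,
        tissue_front=front,
        sigma_a=sigma_a,
        applied_voltage=voltage_command,
        C1=c1,
        C2=c2,
        drift_accum=drift,
        saturated=state.saturated or saturated,
        beam_regime_exceeded=beam_flag,
        cell_density=density,
    )


def simulate_plant(
    state: PlantState,
    voltage_of_t,
    probe: ProbeSpec,
    tissue: TissueModel,
    contact_area: float,
    piezo: PiezoModel,
    duration: float,
    dt: float = 0.1,
    rng: np.random.Generator | None = None,
    record_every: int = 1,
) -> tuple[PlantState, pd.DataFrame]:
    """Open-loop simulation helper: run ``duration`` s with a voltage program.

    ``voltage_of_t`` is a callable ``t_s → V`` (or a constant). Returns the
    final state and a trajectory table with the export columns
    ``time_s, X_C_true_um, X_T_true_um, C1_pF, C2_pF, voltage_V, sigma_a_Pa,
    tissue_front_um``.
    """
    if not callable(voltage_of_t):
        v_const = float(voltage_of_t)
        voltage_of_t = lambda t: v_const  # noqa: E731
    n_steps = int(round(duration / dt))
    rows = []

    def _row(s: PlantState):
        return (s.time, s.X_C_true, s.X_T_true, s.C1, s.C2, s.applied_voltage,
                s.sigma_a, s.tissue_front)

    # initial capacitances reflect the initial chip position
    c1, c2 = capacitance_pair(state.X_C_true, piezo, rng)
    state = replace(state, C1=c1, C2=c2)
    rows.append(_row(state))
    for i in range(n_steps):
        state = step_plant(
            state, voltage_of_t(state.time), probe, tissue, contact_area, piezo,
            dt, rng,
        )
        if (i + 1) % record_every == 0:
            rows.append(_row(state))
    traj = pd.DataFrame(
        rows,
        columns=["time_s", "X_C_true_um", "X_T_true_um", "C1_pF", "C2_pF",
                 "voltage_V", "sigma_a_Pa", "tissue_front_um"],
    )
    return state, traj


def stall_deflection_um(sigma_a0: float, contact_area: float, k: float) -> float:
    """Fixed point of the stall: deflection where kδ/A balances σ_a0.

    δ∞ = σ_a0·A/k with unit bookkeeping (σ in Pa, A in µm², k in N/m → µm).
    """
    return sigma_a0 * contact_area / (k * 1e6)


# --------------------------------------------------------------------------
# synthetic cell tracks (loading experiments)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowConfig:
    """Parameterized U-shaped planar flow for labelled-cell cohorts.

    Cells leave the progenitor pool moving axially, then turn laterally into
    the paraxial tissue (the 'U'). The mean medial→lateral speed rises
    linearly with the applied load; per-cell speed noise is independent.

    Units: speeds µm/h, sensitivity µm/h per nN, timescale h, spacing s.
    """

    axial_speed: float = 30.0
    lateral_speed_base: float = 5.0
    load_sensitivity: float = 0.04
    turn_timescale: float = 1.0
    speed_noise: float = 6.0
    sampling_interval: float = 300.0

    def lateral_speed(self, load_nN: float) -> float:
        return self.lateral_speed_base + self.load_sensitivity * load_nN


def generate_cell_tracks(
    flow_config: FlowConfig,
    n_cells: int,
    load_level: float,
    duration: float,
    rng_seed: int,
) -> list[CellTrack]:
    """Generate labelled-cell tracks under a given load (nN).

    Positions are (axial, lateral) in µm at the configured sampling interval.
    The lateral velocity component equals ``lateral_speed(load)`` exactly in
    the noise-free limit; axial velocity decays with the turn timescale so
    trajectories bend from axial to lateral motion.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be ≥ 1")
    rng = np.random.default_rng(rng_seed)
    cfg = flow_config
    t = np.arange(0.0, duration + 0.5 * cfg.sampling_interval, cfg.sampling_interval)
    if len(t) < 2:
        raise ValueError("duration shorter than one sampling interval")
    t_h = t / units.S_PER_H
    label = "loaded" if load_level > 0 else "control"
    v_lat = cfg.lateral_speed(load_level)
    tracks = []
    for cid in range(n_cells):
        start = rng.normal(0.0, 20.0, size=2)
        # axial drift turns off along the U; closed-form integral of the decay
        ax = start[0] + cfg.axial_speed * cfg.turn_timescale * (
            1.0 - np.exp(-t_h / cfg.turn_timescale)
        )
        lat = start[1] + v_lat * t_h
        if cfg.speed_noise > 0:
            dt_h = np.diff(t_h)
            # per-interval velocity noise (µm/h s.d.), independent across
            # intervals and components, integrated to displacement
            ax[1:] += np.cumsum(rng.normal(0.0, cfg.speed_noise, len(dt_h)) * dt_h)
            lat[1:] += np.cumsum(rng.normal(0.0, cfg.speed_noise, len(dt_h)) * dt_h)
        tracks.append(
            CellTrack(cell_id=cid, t_s=t, positions_um=np.column_stack([ax, lat]),
                      label=label)
        )
    return tracks
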
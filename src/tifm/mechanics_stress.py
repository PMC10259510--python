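"""Deflection → force → stress conversion and the measurement error budget.

The instrument's core relation is σ = k (X_T − X_C) / A: cantilever spring
constant k times the deflection between the imaged tip (X_T) and the
capacitively sensed chip (X_C), divided by the tissue contact area A. Units
are centralized in :mod:`tifm.units` (k in N/m, positions in µm, F in nN,
A in µm², σ in Pa; 1 nN/µm² = 1000 Pa).

The uncertainty budget decomposes the relative error of σ into

* an insertion-angle term, 1 − cos θ_I (projected-area effect); the off-axis
  force fraction sin θ_I is reported alongside but not folded into σ, since
  no correction formula is applied;
* a depth term, ΔA/A propagated from the ±20 µm uncertainty of the focal
  insertion-depth protocol (zero for a fully inserted foil, whose area no
  longer depends on D);
* a fabrication term (10–20 % for cut foils; bare narrow tips are only
  order-of-magnitude accurate, which raises a flag instead of a percentage
  that would be meaningless);
* a tracking term, k·RMSE(X_T)/F relative to a reference force.

Components combine by worst-case sum (default; the quoted "maximum 20 %"
reads as a bound) or in quadrature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

from tifm import units
from tifm.plant_twin import ProbeSpec

DEFAULT_DEPTH_UNCERTAINTY_UM = 20.0
FOIL_FABRICATION_RANGE = (0.10, 0.20)
DEFAULT_FOIL_FABRICATION = 0.15
ORDER_OF_MAGNITUDE_RATIO = 10.0


@dataclass(frozen=True)
class ContactGeometry:
    """Probe-tissue contact geometry with stated uncertainties."""

    insertion_depth: float  # D, µm
    depth_uncertainty: float = DEFAULT_DEPTH_UNCERTAINTY_UM  # µm
    insertion_angle: float = 0.0  # θ_I, rad
    angle_uncertainty: float = 0.0  # rad
    imaging_depth: float = 50.0  # D_I, µm
    tissue_span: float = math.inf  # lateral extent available for contact, µm

    def __post_init__(self) -> None:
        if self.insertion_depth < 0:
            raise ValueError("insertion depth must be ≥ 0")
        if not (0.0 <= self.insertion_angle < math.pi / 2):
            raise ValueError("insertion angle must lie in [0, π/2)")
        if self.depth_uncertainty < 0 or self.angle_uncertainty < 0:
            raise ValueError("uncertainties must be ≥ 0")


@dataclass
class StressEstimate:
    force_nN: float
    contact_area_um2: float
    area_rel_uncertainty: float
    stress_Pa: float
    components: dict[str, float] = field(default_factory=dict)
    off_axis_force_fraction: float = 0.0
    total_rel_uncertainty: float = 0.0
    combination_rule: str = "worst_case"
    flags: list[str] = field(default_factory=list)


def force_from_deflection(k: float, X_T: float, X_C: float) -> float:
    """F (nN) from spring constant k (N/m) and tip/chip positions (µm)."""
    if not (math.isfinite(k) and math.isfinite(X_T) and math.isfinite(X_C)):
        raise ValueError("inputs must be finite")
    return units.force_nN(k, X_T - X_C)


def stress_estimate(force_nN: float, area_um2: float) -> float:
    """σ (Pa) from force (nN) over contact area (µm²)."""
    return units.stress_Pa(force_nN, area_um2)


def _area_at_depth(probe: ProbeSpec, depth: float, span: float) -> float:
    """Projected contact area at a given insertion depth (no angle factor)."""
    if probe.tip_shape == "foil":
        eff = min(depth, probe.foil_height)
        return min(probe.foil_width, span) * eff
    if probe.tip_shape == "triangular":
        # similar triangles: width at depth d from the apex scales as d/L
        d = min(depth, probe.probe_length)
        return 0.5 * probe.tip_width * d * d / probe.probe_length
    # sharp: thin rectangular blade of tip_width
    return min(probe.tip_width, span) * depth


def contact_area(probe: ProbeSpec, geom: ContactGeometry) -> tuple[float, float]:
    """Contact area (µm²) and its relative uncertainty from D ± ΔD.

    The projected area is scaled by cos θ_I. Depths beyond the probe's
    vertical extent are clipped to the full extent. D = 0 means no contact
    and raises.
    """
    if geom.insertion_depth <= 0:
        raise ValueError("insertion depth is 0: no contact")
    cos_t = math.cos(geom.insertion_angle)
    a0 = _area_at_depth(probe, geom.insertion_depth, geom.tissue_span)
    area = a0 * cos_t
    rel = _depth_rel_uncertainty(probe, geom)
    return area, rel


def _depth_rel_uncertainty(probe: ProbeSpec, geom: ContactGeometry) -> float:
    dd = geom.depth_uncertainty
    if dd == 0:
        return 0.0
    if probe.tip_shape == "foil" and geom.insertion_depth >= probe.foil_height:
        return 0.0  # fully inserted foil: A independent of D
    a0 = _area_at_depth(probe, geom.insertion_depth, geom.tissue_span)
    a_hi = _area_at_depth(probe, geom.insertion_depth + dd, geom.tissue_span)
    a_lo = _area_at_depth(
        probe, max(geom.insertion_depth - dd, 0.0), geom.tissue_span
    )
    return max(a_hi - a0, a0 - a_lo) / a0


def uncertainty_budget(
    probe: ProbeSpec,
    geom: ContactGeometry,
    tracking_rmse_um: float,
    reference_force_nN: float | None = None,
    combination_rule: str = "worst_case",
    fabrication_tolerance: float | None = None,
) -> StressEstimate:
    """Relative uncertainty budget for a stress measurement.

    ``reference_force_nN`` sets the scale for the tracking term
    k·RMSE/F (at F = 0 the term is unbounded and flagged instead).
    ``fabrication_tolerance`` overrides the default foil tolerance (0.15,
    within the fabricated 0.10–0.20 range).
    """
    if combination_rule not in ("worst_case", "quadrature"):
        raise ValueError(f"unknown combination rule {combination_rule!r}")
    flags: list[str] = []

    angle = 1.0 - math.cos(geom.insertion_angle)
    off_axis = math.sin(geom.insertion_angle)
    depth = _depth_rel_uncertainty(probe, geom)

    if probe.tip_shape == "foil":
        fab = (DEFAULT_FOIL_FABRICATION if fabrication_tolerance is None
               else fabrication_tolerance)
    else:
        fab = 0.0 if fabrication_tolerance is None else fabrication_tolerance
        # bare narrow tips: check whether D ± ΔD spans an order of magnitude in A
        d_lo = max(geom.insertion_depth - geom.depth_uncertainty, 1e-6)
        d_hi = geom.insertion_depth + geom.depth_uncertainty
        a_lo = _area_at_depth(probe, d_lo, geom.tissue_span)
        a_hi = _area_at_depth(probe, d_hi, geom.tissue_span)
        if a_lo <= 0 or a_hi / a_lo >= ORDER_OF_MAGNITUDE_RATIO:
            flags.append("order_of_magnitude")

    if tracking_rmse_um < 0:
        raise ValueError("tracking RMSE must be ≥ 0")
    if reference_force_nN is None or reference_force_nN == 0:
        tracking = 0.0
        if tracking_rmse_um > 0:
            flags.append("tracking_unbounded")
    else:
        tracking = units.force_nN(probe.spring_constant, tracking_rmse_um) / abs(
            reference_force_nN
        )

    comps = {"angle": angle, "depth": depth, "fabrication": fab,
             "tracking": tracking}
    if combination_rule == "worst_case":
        total = sum(comps.values())
    else:
        total = math.sqrt(sum(c * c for c in comps.values()))

    area, _ = contact_area(probe, geom) if geom.insertion_depth > 0 else (0.0, 0.0)
    f = reference_force_nN if reference_force_nN is not None else 0.0
    return StressEstimate(
        force_nN=f,
        contact_area_um2=area,
        area_rel_uncertainty=depth + fab if combination_rule == "worst_case"
        else math.sqrt(depth**2 + fab**2),
        stress_Pa=stress_estimate(f, area) if area > 0 else 0.0,
        components=comps,
        off_axis_force_fraction=off_axis,
        total_rel_uncertainty=total,
        combination_rule=combination_rule,
        flags=flags,
    )


def budget_to_frame(est: StressEstimate) -> pd.DataFrame:
    rows = [(name, value) for name, value in est.components.items()]
    rows.append(("total", est.total_rel_uncertainty))
    return pd.DataFrame(rows, columns=["component", "relative_uncertainty"])


def budget_to_json(est: StressEstimate) -> str:
    return json.dumps(
        {
            "force_nN": est.force_nN,
            "contact_area_um2": est.contact_area_um2,
            "stress_Pa": est.stress_Pa,
            "components": est.components,
            "off_axis_force_fraction": est.off_axis_force_fraction,
            "total_rel_uncertainty": est.total_rel_uncertainty,
            "combination_rule": est.combination_rule,
            "flags": est.flags,
        },
        indent=2,
        sort_keys=True,
    )
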
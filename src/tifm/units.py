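"""Centralized unit conversions.

Conventions used throughout the package:

========================  =========
quantity                  unit
========================  =========
position, deflection      µm
spring constant k         N/m
force F                   nN
contact area A            µm²
stress σ                  Pa
velocity                  µm/h
time                      s (internal), h for timescales
capacitance               pF
========================  =========

The two conversions that matter:

* ``F [nN] = 1000 · k [N/m] · δ [µm]``   (1 N/m × 1 µm = 1e-6 N = 1000 nN)
* ``σ [Pa] = 1000 · F [nN] / A [µm²]``   (1 nN/µm² = 1e-9 N / 1e-12 m² = 1000 Pa)
"""

NN_PER_NM_UM = 1000.0  # nN per (N/m · µm)
PA_PER_NN_UM2 = 1000.0  # Pa per (nN/µm²)
S_PER_H = 3600.0


def force_nN(k_N_per_m: float, deflection_um: float) -> float:
    """Cantilever force in nN from spring constant (N/m) and deflection (µm)."""
    return NN_PER_NM_UM * k_N_per_m * deflection_um


def stress_Pa(force_nN_: float, area_um2: float) -> float:
    """Stress in Pa from force (nN) over contact area (µm²)."""
    if area_um2 <= 0:
        raise ValueError(f"contact area must be positive, got {area_um2} µm²")
    return PA_PER_NN_UM2 * force_nN_ / area_um2


def deflection_um(k_N_per_m: float, force_nN_: float) -> float:
    """Deflection (µm) producing a given force (nN) at spring constant k."""
    return force_nN_ / (NN_PER_NM_UM * k_N_per_m)


def um_per_h_to_um_per_s(v: float) -> float:
    return v / S_PER_H


def um_per_s_to_um_per_h(v: float) -> float:
    return v * S_PER_H
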
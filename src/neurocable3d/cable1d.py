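"""Reference 1D cable-equation solver with Hodgkin-Huxley dynamics.

The standard cable equation maps a neurite to a line of cylindrical
compartments and assumes a vanishing extracellular potential:

    c_m dV/dt = (d sigma_in / 4) d^2V/dx^2 - j_ion(V, n, m, h) + j_stim

with sealed (zero axial flux) ends.  This solver plays the role of an
established compartment simulator for verifying the 3D model in its thin,
long-cylinder limit; it shares the 3D solver's membrane model, units and
backward-Euler/Newton time discretization, plus the two verification
metrics: the relative L2-in-time error between trace sets and the
conduction velocity from threshold-crossing times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .membrane import GatingState, HHParameters, advance_gating, hh_current
from .units import MS_PER_CM_TO_US_PER_UM, na_to_ua_per_cm2

__all__ = [
    "Cable1DConfig",
    "TraceSet",
    "solve_cable_1d",
    "relative_l2_error",
    "conduction_velocity",
    "space_constant",
]


@dataclass
class Cable1DConfig:
    """Uniform unbranched cable: geometry, membrane, stimulus, probes."""

    length: float = 9800.0  #: um
    diameter: float = 200.0  #: um
    sigma_in: float = 2.0  #: mS/cm axial conductivity (R_i = 1/sigma_in)
    n_compartments: int = 490
    params: HHParameters = field(default_factory=HHParameters)
    stim_amplitude: float = 0.0  #: nA into the first stim_length of cable
    stim_t_on: float = 0.0
    stim_t_off: float = 1.0  #: ms
    stim_length: float = 100.0  #: um
    dt: float = 0.01  #: ms
    t_end: float = 5.0  #: ms
    probe_positions: tuple = (0.0, 4900.0, 9800.0)  #: um
    passive: bool = False  #: leak-only membrane (no Na/K channels)

    def __post_init__(self):
        if self.n_compartments < 3:
            raise ValueError("need at least 3 compartments")
        for p in self.probe_positions:
            if not 0.0 <= p <= self.length:
                raise ValueError("probes must lie within [0, length]")


@dataclass
class TraceSet:
    """Membrane-potential time courses on a common time grid."""

    t: np.ndarray  #: ms
    v: np.ndarray  #: (n_probes, n_times) mV
    positions: tuple = ()

    def __post_init__(self):
        if not np.all(np.isfinite(self.v)):
            raise ValueError("trace contains non-finite values")


def solve_cable_1d(config: Cable1DConfig) -> TraceSet:
    """Backward-Euler/Newton solution of the HH cable; returns probe traces.

    The axial coupling coefficient per unit membrane area is
    d*sigma_in/4 * d2V/dx2; the stimulus current is spread over the lateral
    membrane of the first ``stim_length`` of cable (entering the cell).
    """
    n = config.n_compartments
    dx = config.length / n
    x = (np.arange(n) + 0.5) * dx
    sig = config.sigma_in * MS_PER_CM_TO_US_PER_UM  # uS/um
    p = config.params

    # axial conductance coefficient in uA/cm^2 per mV: (d sig / 4) / dx^2,
    # converted from nA/um^2 to uA/cm^2
    coef = (config.diameter * sig / 4.0) / dx**2 / 1e-5
    main = np.full(n, -2.0)
    main[0] = main[-1] = -1.0  # sealed ends
    L = sp.diags([np.ones(n - 1), main, np.ones(n - 1)], [-1, 0, 1], format="csc") * coef

    stim_mask = x <= config.stim_length
    stim_area = config.diameter * np.pi * dx * stim_mask.sum()
    stim_density = np.zeros(n)
    if config.stim_amplitude:
        stim_density[stim_mask] = -na_to_ua_per_cm2(config.stim_amplitude, stim_area)

    steps = int(round(config.t_end / config.dt))
    dt = config.dt
    v = np.zeros(n)
    gating = GatingState.rest(n)
    eye = sp.identity(n, format="csc")

    probe_idx = [int(np.clip(round(pp / dx - 0.5), 0, n - 1)) for pp in config.probe_positions]
    traces = np.zeros((len(probe_idx), steps + 1))
    times = np.arange(steps + 1) * dt
    traces[:, 0] = v[probe_idx]

    def ionic(vv, g):
        if config.passive:
            return p.g_l * (vv - p.e_l)
        return hh_current(vv, g.n, g.m, g.h, p)

    for k in range(1, steps + 1):
        t = k * dt
        j_stim = stim_density if config.stim_t_on < t <= config.stim_t_off else 0.0
        v_new = v.copy()
        for _ in range(30):
            g_new = gating if config.passive else advance_gating(gating, v_new, dt)
            resid = (
                p.c_m * (v_new - v) / dt
                - np.asarray(L @ v_new)
                + ionic(v_new, g_new)
                + j_stim
            )
            # diagonal channel linearization via finite differences
            eps = 1e-4
            g_eps = gating if config.passive else advance_gating(gating, v_new + eps, dt)
            dion = (ionic(v_new + eps, g_eps) - ionic(v_new, g_new)) / eps
            J = sp.diags(p.c_m / dt + dion) - L
            delta = spla.spsolve(J.tocsc(), resid)
            v_new -= delta
            if np.abs(delta).max() < 1e-10:
                break
        else:
            raise RuntimeError(f"1D Newton did not converge at t={t:.3f} ms")
        if not np.all(np.isfinite(v_new)):
            raise RuntimeError(f"1D cable solution became non-finite at t={t:.3f} ms")
        if not config.passive:
            gating = advance_gating(gating, v_new, dt)
        v = v_new
        traces[:, k] = v[probe_idx]

    return TraceSet(t=times, v=traces, positions=tuple(config.probe_positions))


def space_constant(diameter: float, sigma_in: float, g_l: float) -> float:
    """Passive length constant lambda = sqrt(d sigma_in / (4 g_L)) in um."""
    sig = sigma_in * MS_PER_CM_TO_US_PER_UM
    return float(np.sqrt(diameter * sig / (4.0 * g_l * 1e-5)))


def relative_l2_error(a: TraceSet, b: TraceSet, interval=None) -> float:
    """||a - b||_L2([0,T]) / ||b||_L2([0,T]) by trapezoidal quadrature.

    Traces are linearly resampled onto a common grid; multi-probe sets are
    combined by summing squared norms over probes before taking the ratio.
    """
    if a.v.shape[0] != b.v.shape[0]:
        raise ValueError("trace sets must have the same number of probes")
    t0 = max(a.t[0], b.t[0]) if interval is None else interval[0]
    t1 = min(a.t[-1], b.t[-1]) if interval is None else interval[1]
    tt = np.linspace(t0, t1, max(len(a.t), len(b.t)))
    num = den = 0.0
    for i in range(a.v.shape[0]):
        va = np.interp(tt, a.t, a.v[i])
        vb = np.interp(tt, b.t, b.v[i])
        num += np.trapezoid((va - vb) ** 2, tt)
        den += np.trapezoid(vb**2, tt)
    if den == 0.0:
        raise ValueError("reference trace has zero L2 norm; relative error undefined")
    return float(np.sqrt(num / den))


def first_upward_crossing(t: np.ndarray, v: np.ndarray, threshold: float) -> float:
    """Time of the first upward crossing of ``threshold`` (linear
    interpolation between samples); raises if the trace never crosses."""
    above = v >= threshold
    if above[0] or not above.any():
        if not above.any():
            raise ValueError("no spike detected: trace never crosses threshold")
        return float(t[0])
    i = int(np.argmax(above))
    f = (threshold - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def conduction_velocity(
    traces: TraceSet,
    probe_positions=None,
    threshold: float | None = None,
) -> float:
    """Propagation speed (m/s) between the first and last probe from first
    upward threshold-crossing times; default threshold is half the maximum
    spike amplitude over the probes."""
    pos = np.asarray(
        traces.positions if probe_positions is None else probe_positions, float
    )
    if len(pos) < 2:
        raise ValueError("need at least two probes")
    if threshold is None:
        threshold = 0.5 * float(traces.v.max())
    t_first = first_upward_crossing(traces.t, traces.v[0], threshold)
    t_last = first_upward_crossing(traces.t, traces.v[-1], threshold)
    if t_last == t_first:
        raise ValueError("coincident crossing times; cannot measure velocity")
    # um/ms == mm/s; convert to m/s
    return float(abs(pos[-1] - pos[0]) / abs(t_last - t_first)) * 1e-3
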
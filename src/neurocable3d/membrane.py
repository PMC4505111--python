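"""Transmembrane current model: Hodgkin-Huxley channels, synapses, stimuli.

Voltage convention is the shifted (resting potential = 0 mV) Hodgkin-Huxley
convention; rates are the classical squid-axon formulas at 6.3 C.  The total
transmembrane current density

    j_all = c_m dV_m/dt + delta_active * j_HH + delta_stim * j_stim
            + delta_syn * j_syn

is assembled per membrane patch: ACTIVE (and STIMULUS, SYNAPSE_PRE) patches
carry the full channel current, DENDRITE and SYNAPSE_POST patches are
passive (capacitive + leak), MYELIN patches carry only a capacitive current
with a reduced sheath capacitance.  Positive current is outward.

Units: mV, ms, mS/cm^2, uF/cm^2; current densities in uA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh.core import Patch
from .units import na_to_ua_per_cm2

__all__ = [
    "HHParameters",
    "GatingState",
    "SynapseSpec",
    "StimulusSpec",
    "MembraneModel",
    "gating_rates",
    "gating_steady_state",
    "hh_current",
    "advance_gating",
    "synaptic_current",
    "simulate_space_clamped",
]


@dataclass(frozen=True)
class HHParameters:
    """Hodgkin-Huxley membrane parameters (classical squid values)."""

    g_na: float = 120.0  #: mS/cm^2
    g_k: float = 36.0  #: mS/cm^2
    g_l: float = 0.3  #: mS/cm^2
    e_na: float = 115.0  #: mV
    e_k: float = -12.0  #: mV
    e_l: float = 10.6  #: mV
    c_m: float = 1.0  #: uF/cm^2
    c_m_myelin: float = 0.04  #: uF/cm^2, sheath capacitance

    def __post_init__(self):
        if min(self.g_na, self.g_k, self.g_l) < 0:
            raise ValueError("conductances must be non-negative")
        if self.c_m <= 0 or self.c_m_myelin <= 0:
            raise ValueError("membrane capacitances must be positive")


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    safe = np.where(small, 1.0, x)
    return np.where(small, y * (1.0 - x / (2.0 * y)), safe / np.expm1(safe / y))


def gating_rates(v_m):
    """Classical HH opening/closing rates (1/ms) at membrane potential mV.

    Returns ``(alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h)``; the
    removable singularities of alpha_n (V=10) and alpha_m (V=25) evaluate to
    their analytic limits.
    """
    v = np.asarray(v_m, dtype=float)
    alpha_n = 0.01 * _vtrap(10.0 - v, 10.0)
    beta_n = 0.125 * np.exp(-v / 80.0)
    alpha_m = 0.1 * _vtrap(25.0 - v, 10.0)
    beta_m = 4.0 * np.exp(-v / 18.0)
    alpha_h = 0.07 * np.exp(-v / 20.0)
    beta_h = 1.0 / (np.exp((30.0 - v) / 10.0) + 1.0)
    return alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h


def gating_steady_state(v_m):
    """Steady-state gating values (n_inf, m_inf, h_inf) at a fixed potential."""
    an, bn, am, bm, ah, bh = gating_rates(v_m)
    return an / (an + bn), am / (am + bm), ah / (ah + bh)


@dataclass
class GatingState:
    """Per-vertex gating variables, clamped to [0, 1]."""

    n: np.ndarray
    m: np.ndarray
    h: np.ndarray

    @classmethod
    def rest(cls, n_points: int, v_rest: float = 0.0) -> "GatingState":
        n_inf, m_inf, h_inf = gating_steady_state(v_rest)
        return cls(
            n=np.full(n_points, n_inf),
            m=np.full(n_points, m_inf),
            h=np.full(n_points, h_inf),
        )

    def copy(self) -> "GatingState":
        return GatingState(self.n.copy(), self.m.copy(), self.h.copy())


def advance_gating(gating: GatingState, v_m, dt: float, scheme: str = "implicit") -> GatingState:
    """One step of dx/dt = alpha(V)(1-x) - beta(V)x for each gating variable.

    ``implicit`` is backward Euler at frozen V (x_new = (x + dt a)/(1 + dt(a+b)));
    ``rush_larsen`` is the exact exponential relaxation toward x_inf(V).  Both
    are unconditionally stable and preserve [0, 1]; results are clamped.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    an, bn, am, bm, ah, bh = gating_rates(v_m)
    out = []
    for x, a, b in ((gating.n, an, bn), (gating.m, am, bm), (gating.h, ah, bh)):
        if scheme == "implicit":
            x_new = (x + dt * a) / (1.0 + dt * (a + b))
        elif scheme == "rush_larsen":
            tau = 1.0 / (a + b)
            x_inf = a * tau
            x_new = x_inf + (x - x_inf) * np.exp(-dt / tau)
        else:
            raise ValueError(f"unknown gating scheme {scheme!r}")
        out.append(np.clip(x_new, 0.0, 1.0))
    return GatingState(*out)


def e_l_for_rest(params: HHParameters, v_rest: float = 0.0) -> HHParameters:
    """Return a copy of ``params`` with the leak reversal adjusted so the
    total channel current vanishes exactly at ``v_rest`` with gating at its
    steady state (the classical E_L is only approximately balancing)."""
    n, m, h = gating_steady_state(v_rest)
    i_na = m**3 * h * params.g_na * (v_rest - params.e_na)
    i_k = n**4 * params.g_k * (v_rest - params.e_k)
    if params.g_l == 0:
        raise ValueError("cannot balance rest with zero leak conductance")
    return replace(params, e_l=v_rest + (i_na + i_k) / params.g_l)


def hh_current(v_m, n, m, h, params: HHParameters):
    """Channel current density m^3 h g_Na (V-E_Na) + n^4 g_K (V-E_K) +
    g_L (V-E_L) in uA/cm^2; positive = outward."""
    return (
        m**3 * h * params.g_na * (v_m - params.e_na)
        + n**4 * params.g_k * (v_m - params.e_k)
        + params.g_l * (v_m - params.e_l)
    )


@dataclass
class SynapseSpec:
    """Latched threshold synapse: once the (area-weighted mean) presynaptic
    membrane potential exceeds ``threshold`` the latch fires and the
    postsynaptic patch receives a predefined current pulse for
    ``post_duration``, regardless of the presynaptic potential thereafter."""

    pre_cell: int
    post_cell: int
    threshold: float = 5.0  #: mV
    post_current_amplitude: float = 1.0  #: nA (inward at the post patch)
    post_duration: float = 1.0  #: ms
    alpha_form: str = "rectangular"  #: or "alpha"
    latch_time: float = float("nan")  #: set by the simulation when fired

    def __post_init__(self):
        if self.post_duration <= 0:
            raise ValueError("post_duration must be positive")
        if self.alpha_form not in ("rectangular", "alpha"):
            raise ValueError("alpha_form must be 'rectangular' or 'alpha'")

    @property
    def fired(self) -> bool:
        return np.isfinite(self.latch_time)

    def update_latch(self, v_m_pre: float, t: float) -> None:
        if not self.fired and v_m_pre > self.threshold:
            self.latch_time = t

    def current_density(self, t: float, post_area_um2: float) -> float:
        """Postsynaptic current density (uA/cm^2, negative = depolarizing
        inward current) at time t given the post patch area."""
        if not self.fired:
            return 0.0
        s = t - self.latch_time
        if s <= 0.0 or s > self.post_duration:
            return 0.0
        amp = na_to_ua_per_cm2(self.post_current_amplitude, post_area_um2)
        if self.alpha_form == "alpha":
            tau = self.post_duration / 4.0
            return -amp * (s / tau) * np.exp(1.0 - s / tau)
        return -amp


def synaptic_current(syn: SynapseSpec, v_m_pre: float, t: float, post_area_um2: float) -> float:
    """Update the synapse latch with the presynaptic potential and return the
    postsynaptic current density at time ``t``."""
    syn.update_latch(v_m_pre, t)
    return syn.current_density(t, post_area_um2)


@dataclass
class StimulusSpec:
    """Current injection on a patch: ``amplitude`` nA spread over the patch
    area between ``t_on`` and ``t_off`` (positive amplitude depolarizes,
    i.e. enters the cell)."""

    cell: int = 0
    amplitude: float = 1.0  #: nA
    t_on: float = 0.0  #: ms
    t_off: float = 1.0  #: ms
    patch: Patch = Patch.STIMULUS

    def __post_init__(self):
        if self.t_off <= self.t_on:
            raise ValueError("t_off must exceed t_on")

    def current_density(self, t: float, area_um2: float) -> float:
        if self.t_on < t <= self.t_off:
            return -na_to_ua_per_cm2(self.amplitude, area_um2)
        return 0.0


#: patch label -> kinetics class
_DEFAULT_KINETICS = {
    Patch.ACTIVE: "hh",
    Patch.STIMULUS: "hh",
    Patch.SYNAPSE_PRE: "hh",
    Patch.DENDRITE: "passive",
    Patch.SYNAPSE_POST: "passive",
    Patch.MYELIN: "capacitive",
}


@dataclass
class MembraneModel:
    """Complete membrane description: HH parameters, per-patch kinetics,
    synapses and stimuli.  Defines j_all for the solvers."""

    params: HHParameters = field(default_factory=HHParameters)
    kinetics: dict = field(default_factory=lambda: dict(_DEFAULT_KINETICS))
    synapses: list = field(default_factory=list)
    stimuli: list = field(default_factory=list)

    def capacitance(self, patch: Patch) -> float:
        return self.params.c_m_myelin if self.kinetics_of(patch) == "capacitive" else self.params.c_m

    def kinetics_of(self, patch: Patch) -> str:
        try:
            return self.kinetics[Patch(patch)]
        except (KeyError, ValueError) as exc:
            raise ValueError(f"unknown membrane patch label {patch!r}") from exc

    def ionic_current(self, patch: Patch, v_m, n, m, h):
        """Region-gated channel current density (uA/cm^2), excluding the
        capacitive, stimulus and synaptic terms."""
        kind = self.kinetics_of(patch)
        if kind == "hh":
            return hh_current(v_m, n, m, h, self.params)
        if kind == "passive":
            return self.params.g_l * (np.asarray(v_m, float) - self.params.e_l)
        if kind == "capacitive":
            return np.zeros_like(np.asarray(v_m, float))
        raise ValueError(f"unknown kinetics class {kind!r}")

    def total_current_density(
        self,
        patch: Patch,
        v_m,
        dv_m_dt,
        gating: tuple,
        t: float,
        *,
        cell: int = -1,
        patch_area_um2: float = 1.0,
        synapse_densities: dict | None = None,
    ):
        """j_all on one patch: capacitive + region-gated channel + stimulus
        + synaptic current densities (uA/cm^2)."""
        try:
            patch = Patch(patch)
        except ValueError as exc:
            raise ValueError(f"unknown membrane patch label {patch!r}") from exc
        n, m, h = gating
        j = self.capacitance(patch) * np.asarray(dv_m_dt, float)
        j = j + self.ionic_current(patch, v_m, n, m, h)
        if patch == Patch.STIMULUS:
            for stim in self.stimuli:
                if stim.cell == cell or stim.cell < 0:
                    j = j + stim.current_density(t, patch_area_um2)
        if patch == Patch.SYNAPSE_POST and synapse_densities:
            j = j + synapse_densities.get(cell, 0.0)
        return j


def simulate_space_clamped(
    model: MembraneModel,
    t_end: float,
    dt: float,
    stimulus_density=None,
    v0: float = 0.0,
):
    """Single-point (space-clamped) membrane ODE: c_m dV/dt = -j_HH - j_stim.

    ``stimulus_density(t)`` returns an *outward* current density in uA/cm^2
    (negative = depolarizing).  Backward-Euler voltage update with implicit
    gating, matching the 3D solver's time discretization.  Returns (t, V).
    """
    steps = int(round(t_end / dt))
    v = v0
    gating = GatingState.rest(1, v0)
    ts = np.zeros(steps + 1)
    vs = np.zeros(steps + 1)
    vs[0] = v0
    c_m = model.params.c_m
    for i in range(1, steps + 1):
        t = i * dt
        j_ext = 0.0 if stimulus_density is None else float(stimulus_density(t))
        v_new = v
        for _ in range(50):  # Newton on the scalar implicit equation
            g_new = advance_gating(gating, np.full(1, v_new), dt)
            j_ion = float(hh_current(v_new, g_new.n[0], g_new.m[0], g_new.h[0], model.params))
            f = c_m * (v_new - v) / dt + j_ion + j_ext
            eps = 1e-6
            g_eps = advance_gating(gating, np.full(1, v_new + eps), dt)
            j_eps = float(
                hh_current(v_new + eps, g_eps.n[0], g_eps.m[0], g_eps.h[0], model.params)
            )
            df = c_m / dt + (j_eps - j_ion) / eps
            step = f / df
            v_new -= step
            if abs(step) < 1e-12:
                break
        gating = advance_gating(gating, np.full(1, v_new), dt)
        v = v_new
        ts[i] = t
        vs[i] = v
    return ts, vs
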
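"""Huber-Braun conductance-based neuron: currents and right-hand side.

The model has two fast spike-generating currents (Na, K), two slow
subthreshold currents (persistent Na and Ca-activated K) whose interplay
produces tonic spiking and bursting, and a leak.  Scale factors ``alpha`` and
``beta`` weight the spike and subthreshold currents in the membrane equation

    C dV/dt = -I_l - alpha (I_Na + I_K) - beta (I_pNa + I_KCa) - I_gj - I_ext

Units: mV, mS/cm^2, uA/cm^2, uF/cm^2, ms.  With C/g in uF/mS the membrane
time constant comes out directly in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MembraneParams", "GatingState", "activation_sigmoid", "ionic_currents", "membrane_rhs"]

# Exponent clip for the activation sigmoid: exp(+-500) is far beyond double
# overflow, so clipping there changes nothing representable.
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class MembraneParams:
    """Single-neuron membrane parameters; defaults are the standard set.

    Gating time constants are stored in ms.  The slow currents reuse the Na/K
    reversal potentials (``V_pNa = V_Na``, ``V_KCa = V_K``), the usual
    convention for this model.
    """

    C: float = 1.0        # membrane capacitance (uF/cm^2)
    g_l: float = 0.4      # leak conductance (mS/cm^2)
    g_Na: float = 1.3     # fast Na conductance (mS/cm^2)
    g_K: float = 1.75     # fast K conductance (mS/cm^2)
    g_pNa: float = 0.22   # persistent Na conductance (mS/cm^2)
    g_KCa: float = 0.35   # Ca-activated K conductance (mS/cm^2)
    E_l: float = -60.0    # leak reversal (mV)
    V_Na: float = 50.0    # Na reversal, also used by I_pNa (mV)
    V_K: float = -90.0    # K reversal, also used by I_KCa (mV)
    V0_Na: float = -25.0  # half-activation of a_Na (mV)
    V0_K: float = -25.0   # half-activation of a_K (mV)
    V0_pNa: float = -40.0  # half-activation of a_pNa (mV)
    s_Na: float = 0.25    # activation slope (1/mV)
    s_K: float = 0.25
    s_pNa: float = 0.09
    tau_K: float = 0.875    # ms
    tau_pNa: float = 4.25   # ms
    tau_KCa: float = 8.75   # ms
    eta: float = 0.012    # coupling of I_pNa into the KCa gate (cm^2/uA)
    k: float = 0.17       # KCa gate relaxation factor
    alpha: float = 4.0    # spike-current scale
    beta: float = 4.0     # subthreshold-current scale

    def __post_init__(self) -> None:
        for name in ("C", "g_l", "g_Na", "g_K", "g_pNa", "g_KCa",
                     "tau_K", "tau_pNa", "tau_KCa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MembraneParams.{name} must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")


@dataclass
class GatingState:
    """Dynamic variables of one neuron (or vectors across a population).

    ``a_Na`` is instantaneous (slaved to V through the sigmoid) and not
    stored.  ``a_KCa`` is driven by the persistent Na current and is not
    bounded in [0, 1] a priori.
    """

    V: np.ndarray      # membrane potential (mV)
    a_K: np.ndarray    # fast K activation
    a_pNa: np.ndarray  # persistent Na activation
    a_KCa: np.ndarray  # Ca-activated K activation

    def __post_init__(self) -> None:
        arrs = [np.asarray(x, dtype=float) for x in (self.V, self.a_K, self.a_pNa, self.a_KCa)]
        if not all(np.all(np.isfinite(a)) for a in arrs):
            raise ValueError("non-finite gating state")
        self.V, self.a_K, self.a_pNa, self.a_KCa = arrs


def activation_sigmoid(V, s: float, V0: float):
    """Steady-state activation ``1 / (1 + exp(-s (V - V0)))``.

    Strictly increasing in V for s > 0; saturates smoothly at 0/1 for extreme
    arguments (exponent clipped to avoid overflow).  Accepts arrays.
    """
    z = np.clip(s * (np.asarray(V, dtype=float) - V0), -_EXP_CLIP, _EXP_CLIP)
    return (1.0 / (1.0 + np.exp(-z)))[()]


def ionic_currents(state: GatingState, params: MembraneParams):
    """The five membrane currents (I_l, I_Na, I_K, I_pNa, I_KCa) in uA/cm^2.

    Each voltage-gated current is ``g a (V - E)`` with a_Na instantaneous;
    the slow currents use the Na/K reversal potentials.
    """
    V = state.V
    a_Na = activation_sigmoid(V, params.s_Na, params.V0_Na)
    I_l = params.g_l * (V - params.E_l)
    I_Na = params.g_Na * a_Na * (V - params.V_Na)
    I_K = params.g_K * state.a_K * (V - params.V_K)
    I_pNa = params.g_pNa * state.a_pNa * (V - params.V_Na)
    I_KCa = params.g_KCa * state.a_KCa * (V - params.V_K)
    return I_l, I_Na, I_K, I_pNa, I_KCa


def membrane_rhs(state: GatingState, params: MembraneParams, I_gj=0.0, I_ext=0.0):
    """Time derivatives (dV/dt, da_K/dt, da_pNa/dt, da_KCa/dt).

    ``I_gj`` and ``I_ext`` enter with a leading minus sign, matching the
    membrane equation as written; the simulation engine orients the circadian
    drive so that wake is depolarizing (see sim_engine).  dV/dt in mV/ms,
    gate derivatives in 1/ms.

    Raises on non-finite state, the signature of integration blow-up.
    """
    V = state.V
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite membrane potential (integration blow-up?)")
    I_l, I_Na, I_K, I_pNa, I_KCa = ionic_currents(state, params)
    dV = (-I_l - params.alpha * (I_Na + I_K) - params.beta * (I_pNa + I_KCa)
          - np.asarray(I_gj) - np.asarray(I_ext)) / params.C
    da_K = (activation_sigmoid(V, params.s_K, params.V0_K) - state.a_K) / params.tau_K
    da_pNa = (activation_sigmoid(V, params.s_pNa, params.V0_pNa) - state.a_pNa) / params.tau_pNa
    da_KCa = (-params.eta * I_pNa - params.k * state.a_KCa) / params.tau_KCa
    return dV, da_K, da_pNa, da_KCa
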
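"""Delayed dCLOCK/PER feedback oscillator and the sleep/wake drive current.

The Drosophila clock is reduced to two delay-differential equations: dCLOCK
activates *per* transcription (PER synthesis after a delay ``tau1``), PER
represses dCLOCK by binding it, and dCLOCK enhances its own synthesis after a
delay ``tau2``.  The unbound transcription factor

    dCLOCK_free = max([dCLOCK] - [PER], 0)

gates a postsynaptic current onto every neuron: positive during wake, exactly
zero during sleep (when PER fully sequesters dCLOCK).  Circadian time is
expressed in "model hours"; the simulation engine maps it onto fast membrane
time through a configurable compression factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CircadianParams",
    "CircadianState",
    "dclock_free",
    "hill_terms",
    "circadian_rhs",
    "external_current",
    "classify_epoch",
    "integrate_circadian",
    "circadian_period",
]

#: Threshold (nM) below which dCLOCK_free counts as zero for epoch labelling.
#: dCLOCK_free is exactly 0 on the sleep branch by the max(., 0) clamp, so any
#: tiny positive value works.
EPOCH_EPS = 1e-6


@dataclass(frozen=True)
class CircadianParams:
    """Clock parameters. Defaults are the standard set for this model.

    Rates are per model hour, concentrations in nM, delays in model hours.
    """

    v_sc: float = 0.25   # max dCLOCK synthesis rate (nM/h)
    v_sp: float = 0.5    # max PER synthesis rate (nM/h)
    k_dc: float = 0.5    # dCLOCK degradation rate (1/h)
    k_dp: float = 0.5    # PER degradation rate (1/h)
    K1: float = 0.3      # Hill constant for per activation (nM)
    K2: float = 0.1      # Hill constant for dclock autorepression relief (nM)
    tau1: float = 10.0   # per transcription -> PER protein delay (h)
    tau2: float = 10.0   # dclock transcription -> dCLOCK protein delay (h)
    g_dclock: float = 0.05  # drive conductance scaling [dCLOCK] (mS/cm^2)
    g_per: float = 0.05     # drive conductance scaling [PER] (mS/cm^2)
    E_syn: float = 50.0     # synaptic reversal potential (mV)

    def __post_init__(self) -> None:
        for name in ("v_sc", "v_sp", "k_dc", "k_dp", "K1", "K2", "tau1",
                     "tau2", "g_dclock", "g_per"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CircadianParams.{name} must be > 0")


class DelayHistory:
    """Ring buffer of past dCLOCK_free samples on a uniform time grid.

    Holds at least ``max_delay`` worth of samples; lookup is by linear
    interpolation.  Querying before the earliest stored sample raises.
    """

    def __init__(self, t0: float, dt: float, max_delay: float, x0: float):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.dt = dt
        self.capacity = int(np.ceil(max_delay / dt)) + 4
        self._buf = np.full(self.capacity, x0, dtype=float)
        self._head = 0          # index of the most recent sample
        self._t_head = t0       # time of the most recent sample
        self._n = self.capacity  # buffer starts pre-filled with constant history

    def push(self, x: float) -> None:
        self._head = (self._head + 1) % self.capacity
        self._buf[self._head] = x
        self._t_head += self.dt

    @property
    def t_latest(self) -> float:
        return self._t_head

    def lookup(self, t: float) -> float:
        """Linearly interpolated sample at time ``t`` (<= latest time)."""
        back = (self._t_head - t) / self.dt
        if back < -1e-9:
            raise ValueError(f"history lookup in the future: t={t}")
        back = max(back, 0.0)
        k = int(np.floor(back))
        frac = back - k
        if k + 1 >= self._n:
            if k >= self._n:
                raise ValueError(f"history underflow: t={t} predates buffer")
            frac = 0.0  # clamp onto the earliest stored sample
        i0 = (self._head - k) % self.capacity
        i1 = (self._head - k - 1) % self.capacity
        return (1.0 - frac) * self._buf[i0] + frac * self._buf[i1]


@dataclass
class CircadianState:
    """Instantaneous clock state plus the delay history it drags behind it."""

    dclock: float
    per: float
    history: DelayHistory = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.dclock < 0 or self.per < 0:
            raise ValueError("concentrations must be non-negative")


def dclock_free(dclock, per):
    """Unbound dCLOCK: ``max([dCLOCK] - [PER], 0)``. Accepts arrays."""
    return np.maximum(np.asarray(dclock) - np.asarray(per), 0.0)[()]


def hill_terms(x_tau2, x_tau1, params: CircadianParams):
    """Delayed regulation terms (R_sc, R_sp).

    ``R_sc = K2 / (K2 + x(t - tau2))`` releases dclock transcription as
    delayed free dCLOCK falls; ``R_sp = x(t - tau1) / (K1 + x(t - tau1))``
    activates per transcription with delayed free dCLOCK.
    """
    x2 = np.asarray(x_tau2, dtype=float)
    x1 = np.asarray(x_tau1, dtype=float)
    r_sc = params.K2 / (params.K2 + x2)
    r_sp = x1 / (params.K1 + x1)
    return r_sc[()], r_sp[()]


def circadian_rhs(state: CircadianState, t: float, params: CircadianParams):
    """Time derivatives (d[dCLOCK]/dt, d[PER]/dt) in nM/h at time ``t``.

    The delayed free-dCLOCK values are read from ``state.history``.
    """
    if state.history is None:
        raise ValueError("state carries no delay history")
    x1 = state.history.lookup(t - params.tau1)
    x2 = state.history.lookup(t - params.tau2)
    r_sc, r_sp = hill_terms(x2, x1, params)
    d_dclock = params.v_sc * r_sc - params.k_dc * state.dclock
    d_per = params.v_sp * r_sp - params.k_dp * state.per
    return d_dclock, d_per


def external_current(V, dclock, per, params: CircadianParams):
    """Per-neuron circadian drive current (uA/cm^2).

    ``I_ext = (g_dclock [dCLOCK] - g_per [PER]) (E_syn - V)`` clamped to the
    free-dCLOCK convention: exactly zero whenever PER >= dCLOCK, so the drive
    vanishes during sleep.  ``V`` may be a vector of membrane potentials.
    """
    V = np.asarray(V, dtype=float)
    gate = params.g_dclock * np.asarray(dclock) - params.g_per * np.asarray(per)
    awake = dclock_free(dclock, per) > 0
    return (np.where(awake, gate, 0.0) * (params.E_syn - V))[()]


def classify_epoch(dclock, per, eps: float = EPOCH_EPS):
    """Label samples ``"sleep"`` (dCLOCK_free <= eps) or ``"wake"``."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    free = dclock_free(dclock, per)
    return np.where(np.asarray(free) <= eps, "sleep", "wake")[()]


def integrate_circadian(
    params: CircadianParams = CircadianParams(),
    duration: float = 96.0,
    dt: float = 0.01,
    dclock0: float = 0.5,
    per0: float = 0.1,
):
    """Integrate the two-variable clock DDE with fixed-step RK4.

    Delayed arguments are linearly interpolated from a ring buffer holding the
    free-dCLOCK trajectory over the last ``max(tau1, tau2)`` hours; the initial
    history is constant at the initial state.

    Parameters
    ----------
    duration : total integration time in model hours.
    dt : step in model hours; must not exceed the smallest delay.

    Returns
    -------
    t, dclock, per : ndarrays of shape (duration/dt + 1,)
    """
    if dt <= 0 or dt > min(params.tau1, params.tau2):
        raise ValueError("dt must be positive and no larger than the delays")
    n_steps = int(round(duration / dt))
    max_delay = max(params.tau1, params.tau2)
    hist = DelayHistory(0.0, dt, max_delay + 2 * dt, float(dclock_free(dclock0, per0)))

    t = np.arange(n_steps + 1) * dt
    dclock = np.empty(n_steps + 1)
    per = np.empty(n_steps + 1)
    dclock[0], per[0] = dclock0, per0

    def rhs(ti, d, p):
        x1 = hist.lookup(ti - params.tau1)
        x2 = hist.lookup(ti - params.tau2)
        r_sc, r_sp = hill_terms(x2, x1, params)
        return (params.v_sc * r_sc - params.k_dc * d,
                params.v_sp * r_sp - params.k_dp * p)

    d, p = dclock0, per0
    for i in range(n_steps):
        ti = t[i]
        k1d, k1p = rhs(ti, d, p)
        k2d, k2p = rhs(ti + 0.5 * dt, d + 0.5 * dt * k1d, p + 0.5 * dt * k1p)
        k3d, k3p = rhs(ti + 0.5 * dt, d + 0.5 * dt * k2d, p + 0.5 * dt * k2p)
        k4d, k4p = rhs(ti + dt, d + dt * k3d, p + dt * k3p)
        d += dt / 6.0 * (k1d + 2 * k2d + 2 * k3d + k4d)
        p += dt / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        hist.push(float(dclock_free(d, p)))
        dclock[i + 1], per[i + 1] = d, p
    return t, dclock, per


def circadian_period(
    params: CircadianParams = CircadianParams(),
    duration: float = 240.0,
    dt: float = 0.01,
    transient: float = 48.0,
) -> float:
    """Mean peak-to-peak interval of [PER] after discarding ``transient`` hours.

    Returns the period in model hours; raises if fewer than two peaks remain.
    """
    from scipy.signal import find_peaks

    t, _, per = integrate_circadian(params, duration=duration, dt=dt)
    keep = t >= transient
    tk, pk = t[keep], per[keep]
    peaks, _ = find_peaks(pk, prominence=0.05 * (pk.max() - pk.min() + 1e-30))
    if len(peaks) < 2:
        raise ValueError("fewer than two [PER] peaks; lengthen the run")
    return float(np.mean(np.diff(tk[peaks])))
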
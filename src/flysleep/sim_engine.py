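"""Two-timescale co-simulation of the coupled network.

The membrane systems run on a fast millisecond clock (fixed-step RK4); the
circadian clock runs in "model hours" and is integrated separately on its own
coarse grid, then bridged into fast time through ``time_compression`` (seconds
of fast time per model hour, default 1 — one circadian cycle spans roughly
24 s of membrane time).  The circadian drive is shared: every neuron receives
the same gating signal g_dclock [dCLOCK] - g_per [PER] (clamped to zero during
sleep), applied with driving force (E_syn - V_i), so the current itself is
per-neuron.

Sign conventions.  The gap-junction term is applied diffusively (a neuron
sitting below its neighbors is pulled up); this is the orientation under which
coupling synchronizes, consistent with the outward-current convention used
for the other membrane currents.  The circadian drive defaults to the
excitatory orientation (wake drive depolarizes, sustaining spiking); the
literal sign printed in the membrane equation (wake drive hyperpolarizes) is
available as ``drive_sign="literal"``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .circadian_drive import CircadianParams, CircadianState, classify_epoch, dclock_free, integrate_circadian
from .neuron_dynamics import GatingState, MembraneParams, activation_sigmoid
from .network_topology import Topology, build_network

__all__ = ["SimulationConfig", "SimulationResult", "initial_state", "run_simulation"]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


# Membrane parameter packing order for the compiled kernel.
_PM_FIELDS = ("C", "g_l", "g_Na", "g_K", "g_pNa", "g_KCa", "E_l", "V_Na",
              "V_K", "V0_Na", "V0_K", "V0_pNa", "s_Na", "s_K", "s_pNa",
              "tau_K", "tau_pNa", "tau_KCa", "eta", "k", "alpha", "beta")


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run.

    ``duration`` and ``burn_in`` are in circadian model hours; ``dt_fast`` in
    ms of fast time; ``sample_rate`` in Hz of fast time.  ``network`` is
    either a Topology or a spec dict accepted by
    :func:`~flysleep.network_topology.build_network`.
    """

    membrane: MembraneParams = field(default_factory=MembraneParams)
    circadian: CircadianParams = field(default_factory=CircadianParams)
    network: object = field(default_factory=lambda: {"kind": "grid", "n": 100})
    g_gj: float = 1e-4            # gap-junction conductance (mS/cm^2)
    drive_sign: str = "excitatory"  # 'excitatory' | 'literal'
    dt_fast: float = 0.02         # membrane step (ms)
    dt_slow: float = 0.01         # circadian step (model hours)
    duration: float = 48.0        # total simulated circadian time (model hours)
    burn_in: float = 24.0         # discarded initial circadian time (model hours)
    time_compression: float = 1.0  # seconds of fast time per model hour
    sample_rate: float = 2000.0   # output sampling (Hz of fast time)
    dclock0: float = 0.5          # initial [dCLOCK] (nM)
    per0: float = 0.1             # initial [PER] (nM)
    V_init: tuple = (-70.0, -50.0)  # uniform range for initial V (mV)
    seed: int = 0

    def validate(self) -> None:
        m = self.membrane
        if self.dt_fast <= 0 or self.dt_fast > 0.1 * min(m.tau_K, m.tau_pNa):
            raise ValueError("dt_fast must be positive and resolve the fastest gate "
                             f"(<= {0.1 * min(m.tau_K, m.tau_pNa):g} ms)")
        if self.duration <= self.burn_in:
            raise ValueError("duration must exceed burn_in")
        if self.sample_rate <= 0 or self.sample_rate > 1000.0 / self.dt_fast:
            raise ValueError("sample_rate must be in (0, 1/dt_fast]")
        if self.drive_sign not in ("excitatory", "literal"):
            raise ValueError("drive_sign must be 'excitatory' or 'literal'")
        if self.time_compression <= 0 or self.dt_slow <= 0:
            raise ValueError("time_compression and dt_slow must be > 0")

    def topology(self) -> Topology:
        if isinstance(self.network, Topology):
            return self.network
        spec = dict(self.network)
        spec.setdefault("seed", self.seed)
        return build_network(**spec)

    def to_dict(self) -> dict:
        d = {
            "membrane": asdict(self.membrane),
            "circadian": asdict(self.circadian),
            "network": (dict(self.network) if isinstance(self.network, dict)
                        else {"kind": self.network.kind, "n": self.network.n}),
        }
        for name in ("g_gj", "drive_sign", "dt_fast", "dt_slow", "duration",
                     "burn_in", "time_compression", "sample_rate", "dclock0",
                     "per0", "seed"):
            d[name] = getattr(self, name)
        d["V_init"] = list(self.V_init)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = copy.deepcopy(d)
        kwargs = {}
        if "membrane" in d:
            kwargs["membrane"] = MembraneParams(**d.pop("membrane"))
        if "circadian" in d:
            kwargs["circadian"] = CircadianParams(**d.pop("circadian"))
        if "V_init" in d:
            kwargs["V_init"] = tuple(d.pop("V_init"))
        kwargs.update(d)
        return cls(**kwargs)


@dataclass
class SimulationResult:
    """Time-aligned outputs of one run (burn-in already removed).

    ``times`` are seconds of fast time from simulation start; ``V`` is the
    (n, T) downsampled potential matrix; the circadian traces and epoch
    labels are sampled on the same time base.  ``I_ext`` is the drive current
    seen by a neuron at the network-mean potential (uA/cm^2).
    """

    times: np.ndarray
    V: np.ndarray
    dclock: np.ndarray
    per: np.ndarray
    dclock_free: np.ndarray
    I_ext: np.ndarray
    epochs: np.ndarray
    config: SimulationConfig
    seed: int

    def __post_init__(self) -> None:
        T = len(self.times)
        for name in ("dclock", "per", "dclock_free", "I_ext", "epochs"):
            if len(getattr(self, name)) != T:
                raise ValueError(f"{name} not aligned with times")
        if self.V.shape[1] != T:
            raise ValueError("V not aligned with times")
        if not (np.all(np.isfinite(self.V)) and np.all(np.isfinite(self.times))):
            raise ValueError("non-finite simulation output")

    @property
    def n(self) -> int:
        return self.V.shape[0]

    @property
    def fs(self) -> float:
        """Output sampling rate (Hz of fast time)."""
        return float(1.0 / np.mean(np.diff(self.times)))

    def lfp_mean(self) -> np.ndarray:
        from .spatial_lfp import mean_lfp

        return mean_lfp(self.V)

    def epoch_slices(self, label: str, complete: bool = True) -> list:
        """Contiguous index slices carrying ``label`` ('sleep' or 'wake').

        With ``complete=True``, runs touching either end of the record are
        dropped (their true extent is unknown).
        """
        mask = self.epochs == label
        if not mask.any():
            return []
        d = np.diff(mask.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if mask[0]:
            starts.insert(0, 0)
        if mask[-1]:
            ends.append(len(mask))
        out = []
        for s, e in zip(starts, ends):
            if complete and (s == 0 or e == len(mask)):
                continue
            out.append(slice(s, e))
        return out

    def save(self, path) -> None:
        """Columnar text output: time, mean LFP, circadian traces, epoch."""
        phi = self.lfp_mean()
        sleep = (self.epochs == "sleep").astype(int)
        arr = np.column_stack([self.times, phi, self.dclock, self.per,
                               self.dclock_free, self.I_ext, sleep])
        np.savetxt(path, arr, fmt="%.6f",
                   header="time_s lfp_mean_mV dclock_nM per_nM dclock_free_nM "
                          "I_ext_uA_cm2 sleep")


def initial_state(config: SimulationConfig, seed: int | None = None):
    """Draw the random initial condition for a run.

    Initial V is uniform on ``config.V_init`` independently per neuron; the
    fast gates start at their steady-state sigmoid for that V and the slow
    KCa gate at 0; the clock starts at the configured concentrations with a
    constant history.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.topology().n
    lo, hi = config.V_init
    V = rng.uniform(lo, hi, size=n)
    m = config.membrane
    gating = GatingState(
        V=V,
        a_K=activation_sigmoid(V, m.s_K, m.V0_K),
        a_pNa=activation_sigmoid(V, m.s_pNa, m.V0_pNa),
        a_KCa=np.zeros(n),
    )
    circ = CircadianState(dclock=config.dclock0, per=config.per0)
    return gating, circ


@njit(cache=True)
def _rhs_into(V, aK, apNa, aKCa, indptr, indices, g_gj, gate_g, drive_mult,
              pm, E_syn, dV, daK, dapNa, daKCa):
    n = V.shape[0]
    (C, g_l, g_Na, g_K, g_pNa, g_KCa, E_l, V_Na, V_K, V0_Na, V0_K, V0_pNa,
     s_Na, s_K, s_pNa, tau_K, tau_pNa, tau_KCa, eta, kf, alpha, beta) = (
        pm[0], pm[1], pm[2], pm[3], pm[4], pm[5], pm[6], pm[7], pm[8], pm[9],
        pm[10], pm[11], pm[12], pm[13], pm[14], pm[15], pm[16], pm[17],
        pm[18], pm[19], pm[20], pm[21])
    for i in range(n):
        Vi = V[i]
        I_in = 0.0  # diffusive gap input: positive pulls V up
        for jj in range(indptr[i], indptr[i + 1]):
            I_in += V[indices[jj]] - Vi
        I_in *= g_gj
        z = s_Na * (Vi - V0_Na)
        if z > 500.0:
            z = 500.0
        elif z < -500.0:
            z = -500.0
        a_Na = 1.0 / (1.0 + np.exp(-z))
        I_l = g_l * (Vi - E_l)
        I_Na = g_Na * a_Na * (Vi - V_Na)
        I_K = g_K * aK[i] * (Vi - V_K)
        I_pNa = g_pNa * apNa[i] * (Vi - V_Na)
        I_KCa = g_KCa * aKCa[i] * (Vi - V_K)
        drive = drive_mult * gate_g * (E_syn - Vi)
        dV[i] = (-I_l - alpha * (I_Na + I_K) - beta * (I_pNa + I_KCa)
                 + I_in + drive) / C
        zk = s_K * (Vi - V0_K)
        if zk > 500.0:
            zk = 500.0
        elif zk < -500.0:
            zk = -500.0
        daK[i] = (1.0 / (1.0 + np.exp(-zk)) - aK[i]) / tau_K
        zp = s_pNa * (Vi - V0_pNa)
        if zp > 500.0:
            zp = 500.0
        elif zp < -500.0:
            zp = -500.0
        dapNa[i] = (1.0 / (1.0 + np.exp(-zp)) - apNa[i]) / tau_pNa
        daKCa[i] = (-eta * I_pNa - kf * aKCa[i]) / tau_KCa


@njit(cache=True)
def _rk4_loop(V, aK, apNa, aKCa, indptr, indices, g_gj, gate, dt, stride,
              pm, E_syn, drive_mult, out_V):
    """Fixed-step RK4 over all neurons; returns -1 on success, else the
    step index at which |V| exceeded 500 mV."""
    n = V.shape[0]
    n_steps = gate.shape[0]
    k1V = np.empty(n); k1a = np.empty(n); k1b = np.empty(n); k1c = np.empty(n)
    k2V = np.empty(n); k2a = np.empty(n); k2b = np.empty(n); k2c = np.empty(n)
    k3V = np.empty(n); k3a = np.empty(n); k3b = np.empty(n); k3c = np.empty(n)
    k4V = np.empty(n); k4a = np.empty(n); k4b = np.empty(n); k4c = np.empty(n)
    tV = np.empty(n); ta = np.empty(n); tb = np.empty(n); tc = np.empty(n)
    for i in range(n):
        out_V[i, 0] = V[i]
    s_idx = 0
    for step in range(n_steps):
        g = gate[step]
        _rhs_into(V, aK, apNa, aKCa, indptr, indices, g_gj, g, drive_mult,
                  pm, E_syn, k1V, k1a, k1b, k1c)
        h = 0.5 * dt
        for i in range(n):
            tV[i] = V[i] + h * k1V[i]
            ta[i] = aK[i] + h * k1a[i]
            tb[i] = apNa[i] + h * k1b[i]
            tc[i] = aKCa[i] + h * k1c[i]
        _rhs_into(tV, ta, tb, tc, indptr, indices, g_gj, g, drive_mult,
                  pm, E_syn, k2V, k2a, k2b, k2c)
        for i in range(n):
            tV[i] = V[i] + h * k2V[i]
            ta[i] = aK[i] + h * k2a[i]
            tb[i] = apNa[i] + h * k2b[i]
            tc[i] = aKCa[i] + h * k2c[i]
        _rhs_into(tV, ta, tb, tc, indptr, indices, g_gj, g, drive_mult,
                  pm, E_syn, k3V, k3a, k3b, k3c)
        for i in range(n):
            tV[i] = V[i] + dt * k3V[i]
            ta[i] = aK[i] + dt * k3a[i]
            tb[i] = apNa[i] + dt * k3b[i]
            tc[i] = aKCa[i] + dt * k3c[i]
        _rhs_into(tV, ta, tb, tc, indptr, indices, g_gj, g, drive_mult,
                  pm, E_syn, k4V, k4a, k4b, k4c)
        s6 = dt / 6.0
        ok = True
        for i in range(n):
            V[i] += s6 * (k1V[i] + 2.0 * k2V[i] + 2.0 * k3V[i] + k4V[i])
            aK[i] += s6 * (k1a[i] + 2.0 * k2a[i] + 2.0 * k3a[i] + k4a[i])
            apNa[i] += s6 * (k1b[i] + 2.0 * k2b[i] + 2.0 * k3b[i] + k4b[i])
            aKCa[i] += s6 * (k1c[i] + 2.0 * k2c[i] + 2.0 * k3c[i] + k4c[i])
            if not (-500.0 < V[i] < 500.0):
                ok = False
        if not ok:
            return step
        if (step + 1) % stride == 0:
            s_idx += 1
            if s_idx < out_V.shape[1]:
                for i in range(n):
                    out_V[i, s_idx] = V[i]
    return -1


def run_simulation(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run one full two-timescale simulation.

    The circadian DDE is integrated first on its coarse grid (the coupling is
    one-way: clock drives neurons); its gating signal is interpolated onto the
    fast grid, held constant within each fast step, and applied to every
    neuron.  The first ``burn_in`` model hours are discarded and outputs are
    downsampled to ``sample_rate``.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    topo = config.topology()
    n = topo.n
    cp = config.circadian

    # --- slow subsystem -------------------------------------------------
    t_h, dclock, per = integrate_circadian(
        cp, duration=config.duration, dt=config.dt_slow,
        dclock0=config.dclock0, per0=config.per0)
    free = dclock_free(dclock, per)
    gate_slow = np.where(free > 0, cp.g_dclock * dclock - cp.g_per * per, 0.0)

    # --- fast subsystem -------------------------------------------------
    dt = config.dt_fast
    ms_per_hour = config.time_compression * 1000.0
    n_steps = int(round(config.duration * ms_per_hour / dt))
    step_hours = (np.arange(n_steps) * dt + 0.5 * dt) / ms_per_hour
    gate = np.interp(step_hours, t_h, gate_slow)

    stride = max(int(round(1000.0 / (config.sample_rate * dt))), 1)
    n_samples = n_steps // stride + 1
    out_V = np.empty((n, n_samples), dtype=np.float64)

    gating, _ = initial_state(config, seed)
    V = gating.V.copy()
    aK = gating.a_K.copy()
    apNa = gating.a_pNa.copy()
    aKCa = gating.a_KCa.copy()
    indptr, indices = topo.csr()
    pm = np.array([getattr(config.membrane, f) for f in _PM_FIELDS], dtype=np.float64)
    drive_mult = 1.0 if config.drive_sign == "excitatory" else -1.0

    status = _rk4_loop(V, aK, apNa, aKCa, indptr, indices, float(config.g_gj),
                       gate, dt, stride, pm, float(cp.E_syn), drive_mult, out_V)
    if status >= 0:
        raise FloatingPointError(
            f"membrane potential blew up (|V| > 500 mV) at fast step {status}; "
            "reduce dt_fast or check parameters")

    # --- assemble, cut burn-in, align circadian traces ------------------
    times_s = np.arange(n_samples) * (stride * dt) / 1000.0
    sample_hours = times_s / config.time_compression
    keep = sample_hours >= config.burn_in
    times_s = times_s[keep]
    Vk = out_V[:, keep]
    d_s = np.interp(sample_hours[keep], t_h, dclock)
    p_s = np.interp(sample_hours[keep], t_h, per)
    free_s = dclock_free(d_s, p_s)
    gate_s = np.where(free_s > 0, cp.g_dclock * d_s - cp.g_per * p_s, 0.0)
    I_ext = gate_s * (cp.E_syn - Vk.mean(axis=0))
    epochs = np.asarray(classify_epoch(d_s, p_s))

    return SimulationResult(times=times_s, V=Vk, dclock=d_s, per=p_s,
                            dclock_free=free_s, I_ext=I_ext, epochs=epochs,
                            config=config, seed=seed)
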
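"""Scenario catalog and parameter-sweep runner.

Scenarios reproduce the study conditions of the network-structure figures
(full network, grid, long-range overlays, small-world rings, electrode
geometries, rasters).  Sweeps vary one parameter (g_gj, tau1 or tau2) over a
grid, run repeated simulations with distinct seeds, and average the sleep
band amplitudes and sleep time across repeats.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .circadian_drive import CircadianParams, dclock_free, integrate_circadian
from .sim_engine import SimulationConfig, SimulationResult, run_simulation
from .signal_analysis import (BANDS, epoch_band_summary, power_spectrum,
                              raster_from_matrix, sleep_time, spectrogram,
                              synchrony_index)
from .spatial_lfp import LfpParams, circle_layout, distance_lfp, grid_layout, mean_lfp

__all__ = ["SCENARIOS", "SweepSpec", "run_scenario", "run_sweep",
           "choose_duration", "scenario_config", "repeat_seed"]


def choose_duration(circ: CircadianParams, burn_in: float = 24.0,
                    n_epochs: int = 1, margin: float = 3.0,
                    dclock0: float = 0.5, per0: float = 0.1,
                    min_sleep_hours: float = 0.0) -> float:
    """Model-hour duration guaranteeing ``n_epochs`` complete sleep epochs.

    Integrates the clock alone (cheap), finds the end of the n-th sleep
    epoch that both starts and ends after ``burn_in``, and pads by
    ``margin`` hours of wake.  Delay changes (tau sweeps) shift both the
    period and the sleep fraction, so a fixed duration cannot be reused
    across sweep values.  With ``min_sleep_hours`` set, additional epochs
    are taken until that much total sleep is observed (short-cycle clocks
    need several episodes to support a stable spectral estimate).
    """
    dt = 0.01
    # some delay settings have very long transients before the clamped
    # (dCLOCK_free = 0) branch is reached; grow the search horizon as needed
    for horizon in (burn_in + 100.0 * max(n_epochs, 1),
                    burn_in + 500.0, burn_in + 2000.0):
        t, d, p = integrate_circadian(circ, duration=horizon, dt=dt,
                                      dclock0=dclock0, per0=per0)
        sleep = dclock_free(d, p) <= 1e-6
        chg = np.diff(sleep.astype(np.int8))
        starts = t[np.flatnonzero(chg == 1) + 1]
        ends = t[np.flatnonzero(chg == -1) + 1]
        done, total = 0, 0.0
        for s in starts:
            if s <= burn_in:
                continue
            later = ends[ends > s]
            if later.size == 0:
                break
            done += 1
            total += float(later[0] - s)
            if done >= n_epochs and total >= min_sleep_hours:
                return float(later[0] + margin)
    raise ValueError("clock does not produce enough complete sleep epochs; "
                     "lengthen the search horizon or check parameters")


def _grid_cfg(**kw) -> SimulationConfig:
    return SimulationConfig(network={"kind": "grid", "n": 100}, **kw)


#: Named study conditions.  Values are (config factory, analysis options).
SCENARIOS = {
    # full network, mean-value LFP
    "fig2_full": (lambda: SimulationConfig(network={"kind": "full", "n": 100}),
                  {"lfp": "mean"}),
    # distance-weighted LFP geometries (full network)
    "fig3_circle": (lambda: SimulationConfig(network={"kind": "full", "n": 100}),
                    {"lfp": "distance", "layout": "circle"}),
    "fig3_grid_e1": (lambda: SimulationConfig(network={"kind": "full", "n": 100}),
                     {"lfp": "distance", "layout": "grid", "electrode": (150.0, 500.0)}),
    "fig3_grid_e2": (lambda: SimulationConfig(network={"kind": "full", "n": 100}),
                     {"lfp": "distance", "layout": "grid", "electrode": (200.0, 500.0)}),
    # network-structure comparison, mean-value LFP
    "fig4_grid": (_grid_cfg, {"lfp": "mean"}),
    "fig5_lr5": (lambda: SimulationConfig(
        network={"kind": "grid_plus_long_range", "n": 100, "z": 9}), {"lfp": "mean"}),
    "fig5_lr20": (lambda: SimulationConfig(
        network={"kind": "grid_plus_long_range", "n": 100, "z": 24}), {"lfp": "mean"}),
    "fig5_lr50": (lambda: SimulationConfig(
        network={"kind": "grid_plus_long_range", "n": 100, "z": 54}), {"lfp": "mean"}),
    "fig6_ws4": (lambda: SimulationConfig(
        network={"kind": "ws", "n": 100, "z": 4, "p": 0.03}), {"lfp": "mean"}),
    "fig6_ws24": (lambda: SimulationConfig(
        network={"kind": "ws", "n": 100, "z": 24, "p": 0.03}), {"lfp": "mean"}),
    "fig6_ws54": (lambda: SimulationConfig(
        network={"kind": "ws", "n": 100, "z": 54, "p": 0.03}), {"lfp": "mean"}),
    # distance-LFP versions of the structure comparison
    "fig7_grid": (_grid_cfg, {"lfp": "distance", "layout": "grid"}),
    "fig7_lr5": (lambda: SimulationConfig(
        network={"kind": "grid_plus_long_range", "n": 100, "z": 9}),
        {"lfp": "distance", "layout": "grid"}),
    "fig7_ws24": (lambda: SimulationConfig(
        network={"kind": "ws", "n": 100, "z": 24, "p": 0.03}),
        {"lfp": "distance", "layout": "grid"}),
    # rasters at two coupling strengths, wake vs sleep windows
    "fig8_raster": (lambda: SimulationConfig(
        network={"kind": "grid_plus_long_range", "n": 100, "z": 24}),
        {"lfp": "mean", "raster": True, "g_gj_values": (1e-4, 1e-3), "epoch": "wake"}),
    "fig9_raster": (lambda: SimulationConfig(
        network={"kind": "grid_plus_long_range", "n": 100, "z": 24}),
        {"lfp": "mean", "raster": True, "g_gj_values": (1e-4, 1e-3), "epoch": "sleep"}),
}


def scenario_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Resolved configuration for a named scenario."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario: {name} (choose from {sorted(SCENARIOS)})")
    factory, _ = SCENARIOS[name]
    cfg = factory()
    cfg.seed = seed
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"SimulationConfig has no field {k!r}")
        setattr(cfg, k, v)
    return cfg


def _scenario_lfp(result: SimulationResult, opts: dict) -> np.ndarray:
    if opts.get("lfp") == "distance":
        n = result.n
        if opts.get("layout") == "circle":
            layout = circle_layout(n, radius=100.0)
        else:
            side = int(round(np.sqrt(n)))
            layout = grid_layout(side, side, spacing=100.0,
                                 electrode=opts.get("electrode", (150.0, 500.0)))
        return distance_lfp(result.V, layout, LfpParams())
    return mean_lfp(result.V)


def run_scenario(name: str, outdir=None, seed: int = 0, **overrides) -> dict:
    """Run one named scenario and its standard analyses.

    Returns a dict with the result(s), LFP series, epoch spectra, spectrogram
    and (for raster scenarios) spike rasters restricted to one sleep and one
    wake epoch.  With ``outdir`` set, writes the columnar time series, LFP,
    raster and a JSON summary there.
    """
    _, opts = SCENARIOS[name]
    cfg = scenario_config(name, seed=seed, **overrides)
    out = {"name": name, "config": cfg}
    g_values = opts.get("g_gj_values", (cfg.g_gj,))
    runs = []
    for g in g_values:
        c = SimulationConfig.from_dict(cfg.to_dict())
        c.g_gj = g
        res = run_simulation(c, seed=seed)
        phi = _scenario_lfp(res, opts)
        entry = {"g_gj": g, "result": res, "lfp": phi}
        f, t, S = spectrogram(phi, res.fs)
        entry["spectrogram"] = (f, t, S)
        for label in ("sleep", "wake"):
            sl = res.epoch_slices(label, complete=True) or res.epoch_slices(label, complete=False)
            if sl:
                longest = max(sl, key=lambda s: s.stop - s.start)
                try:
                    entry[f"spectrum_{label}"] = power_spectrum(phi[longest], res.fs)
                except ValueError:
                    pass
        if opts.get("raster"):
            label = opts.get("epoch", "wake")
            sl = res.epoch_slices(label, complete=True) or res.epoch_slices(label, complete=False)
            longest = max(sl, key=lambda s: s.stop - s.start)
            entry["raster"] = raster_from_matrix(res.V[:, longest], res.fs,
                                                 t0=float(res.times[longest][0]))
            entry["synchrony"] = synchrony_index(res.V[:, longest])
        runs.append(entry)
    out["runs"] = runs
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for entry in runs:
            tag = f"{name}_g{entry['g_gj']:g}"
            entry["result"].save(outdir / f"{tag}_timeseries.txt")
            np.savetxt(outdir / f"{tag}_lfp.txt",
                       np.column_stack([entry["result"].times, entry["lfp"]]),
                       fmt="%.6f", header="time_s lfp")
            f, t, S = entry["spectrogram"]
            np.savetxt(outdir / f"{tag}_spectrogram.txt", S, fmt="%.6e",
                       header=("rows: freq_Hz " +
                               " ".join(f"{x:.3f}" for x in f) +
                               "\ncols: time_s " +
                               " ".join(f"{x:.3f}" for x in t)))
            if "raster" in entry:
                entry["raster"].save(outdir / f"{tag}_raster.txt")
        summary = {"scenario": name, "seed": seed,
                   "g_gj_values": list(g_values),
                   "config": cfg.to_dict()}
        for entry in runs:
            for label in ("sleep", "wake"):
                sp = entry.get(f"spectrum_{label}")
                if sp is not None:
                    summary[f"dominant_{label}_g{entry['g_gj']:g}"] = sp.dominant_frequency
        (outdir / f"{name}_summary.json").write_text(json.dumps(summary, indent=2))
    return out


@dataclass
class SweepSpec:
    """One-parameter sweep with repeated, independently seeded runs."""

    parameter: str                      # 'g_gj' | 'tau1' | 'tau2'
    grid: tuple                         # values to sweep
    repeats: int = 10
    base: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        network={"kind": "grid_plus_long_range", "n": 100, "z": 9}))
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.parameter not in ("g_gj", "tau1", "tau2"):
            raise ValueError("parameter must be one of g_gj, tau1, tau2")
        if self.repeats < 1 or len(self.grid) == 0:
            raise ValueError("need repeats >= 1 and a nonempty grid")


def repeat_seed(base_seed: int, value: float, repeat: int) -> int:
    """Deterministic per-run seed: independent across repeats and values."""
    h = zlib.crc32(repr(float(value)).encode())
    return int((base_seed + 1000003 * repeat + h) % (2**31))


def _apply_value(cfg: SimulationConfig, parameter: str, value: float) -> SimulationConfig:
    c = SimulationConfig.from_dict(cfg.to_dict())
    if parameter == "g_gj":
        c.g_gj = float(value)
    else:
        c.circadian = replace(c.circadian, **{parameter: float(value)})
        # delay changes move the cycle length; re-fit the window so that at
        # least ~2.5 s (fast time) of complete sleep is observed
        c.duration = choose_duration(
            c.circadian, burn_in=c.burn_in, dclock0=c.dclock0, per0=c.per0,
            min_sleep_hours=2.5 / c.time_compression)
    return c


def run_sweep(spec: SweepSpec, outdir=None, progress: bool = False) -> pd.DataFrame:
    """Run the sweep and average sleep-epoch band amplitudes and sleep time.

    For every grid value, ``repeats`` simulations run with distinct seeds;
    per run, the mean-value LFP of the longest complete sleep epoch yields
    the 3-5 / 7-10 / 12-15 Hz band amplitudes, and the circadian-gated sleep
    time is measured.  Failed repeats are recorded and skipped.  Returns one
    row per grid value.
    """
    rows = []
    for value in spec.grid:
        cfg = _apply_value(spec.base, spec.parameter, value)
        amps = {name: [] for name in BANDS}
        stimes, doms, failures = [], [], 0
        for rep in range(spec.repeats):
            seed = repeat_seed(spec.base_seed, value, rep)
            try:
                res = run_simulation(cfg, seed=seed)
                phi = mean_lfp(res.V)
                sl = res.epoch_slices("sleep", complete=True)
                sp = epoch_band_summary(phi, res.fs, sl)
                for name in BANDS:
                    amps[name].append(sp.band_amplitudes[name])
                doms.append(sp.dominant_frequency)
                stimes.append(sleep_time(res))
            except (ValueError, FloatingPointError) as err:
                failures += 1
                if progress:
                    print(f"  repeat {rep} at {spec.parameter}={value} failed: {err}")
        row = {spec.parameter: value, "repeats_ok": spec.repeats - failures,
               "sleep_time_s": float(np.mean(stimes)) if stimes else np.nan,
               "sleep_time_sd": float(np.std(stimes)) if stimes else np.nan,
               "dominant_Hz": float(np.mean(doms)) if doms else np.nan}
        for name in BANDS:
            row[f"amp_{name}Hz"] = float(np.mean(amps[name])) if amps[name] else np.nan
        rows.append(row)
        if progress:
            print(f"{spec.parameter}={value}: sleep {row['sleep_time_s']:.2f} s, "
                  f"7-10 Hz amp {row['amp_7-10Hz']:.3g}")
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / f"sweep_{spec.parameter}.csv", index=False)
    return df
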
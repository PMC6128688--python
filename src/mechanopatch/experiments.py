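"""Canonical in-silico experiments.

These functions wire the simulator to the analyses exactly the way the
corresponding bench experiments are performed, so that tests, example
scripts and reproduction runs all execute one and the same pipeline:

* a whole-cell poking step with the standard recording chain, analyzed for
  peak / slow / slow fraction;
* a cohort of such recordings across cells (one seed per cell);
* the single-channel conductance experiment: pressure-evoked sweeps from a
  3-channel patch at five holding potentials, amplitude-histogram level
  fitting per voltage, and the i-V regression for the unitary conductance.

The module also bundles the worked proliferation example: per-line mitotic
indices (percent phosphohistone-H3-positive of total DAPI nuclei) for two
wild-type and three Piezo1-knockout mouse embryonic stem-cell lines.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .gating import (
    GatingModel,
    SimulationConfig,
    StimulusProtocol,
    build_preset,
    render_current,
    simulate_occupancy,
    simulate_single_channel,
)
from .single_channel import (
    ConductanceFit,
    build_histogram,
    conductance_fit,
    fit_levels,
    unitary_current,
)
from .sweeps import Sweep
from .wholecell import MSCurrentMetrics, compute_metrics

__all__ = [
    "standard_poke_protocol",
    "standard_pressure_protocol",
    "whole_cell_config",
    "single_channel_config",
    "BASELINE_WINDOW_MS",
    "simulate_whole_cell_sweep",
    "whole_cell_metrics",
    "slow_fraction_cohort",
    "conductance_recovery",
    "PH3_PERCENT_BY_LINE",
    "PH3_GENOTYPE_BY_LINE",
    "WT_PH3_LINES",
    "KO_PH3_LINES",
]

#: Pre-stimulus window used for baseline estimation, ms.
BASELINE_WINDOW_MS = (0.0, 18.0)


def standard_poke_protocol(amplitude: float = 8.0) -> StimulusProtocol:
    """Saturating 150-ms poking step, onset 20 ms (8 µm is deep into the
    Boltzmann saturation of the presets)."""
    return StimulusProtocol(kind="poke", onset=20.0, duration=150.0, amplitude=amplitude)


def standard_pressure_protocol(amplitude: float = 60.0) -> StimulusProtocol:
    """200-ms pressure step, onset 50 ms, ramped at 8.3 mmHg/ms."""
    return StimulusProtocol(kind="pressure", onset=50.0, duration=200.0, amplitude=amplitude)


def whole_cell_config(seed: int, n_channels: int = 500, **overrides) -> SimulationConfig:
    """Standard whole-cell recording chain: 500 channels, −80 mV, 20 kHz /
    1 kHz Bessel, 5 pA pre-filter noise, 200-ms sweep."""
    cfg = SimulationConfig(
        n_channels=n_channels, v_hold=-80.0, fs=20_000.0, filter_cutoff=1_000.0,
        noise_sd=5.0, sweep_length=200.0, seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def single_channel_config(seed: int, v_hold: float, n_channels: int = 3) -> SimulationConfig:
    """Excised-patch recording chain: 3 channels, 0.3 pA noise, 300-ms sweep."""
    return SimulationConfig(
        n_channels=n_channels, v_hold=v_hold, fs=20_000.0, filter_cutoff=1_000.0,
        noise_sd=0.3, sweep_length=300.0, seed=seed,
    )


def simulate_whole_cell_sweep(
    model: GatingModel | str, seed: int, n_channels: int = 500, **overrides
) -> Sweep:
    """One whole-cell sweep under the standard poke protocol."""
    if isinstance(model, str):
        model = build_preset(model)
    proto = standard_poke_protocol()
    cfg = whole_cell_config(seed, n_channels=n_channels, **overrides)
    rng = np.random.default_rng(cfg.seed)
    occ = simulate_occupancy(model, proto, cfg, rng=rng)
    return render_current(occ, model, cfg, protocol=proto, rng=rng,
                          sweep_id=f"{model.name}_seed{seed}")


def whole_cell_metrics(
    model: GatingModel | str, seed: int, n_channels: int = 500, **overrides
) -> MSCurrentMetrics:
    """Simulate one whole-cell sweep and compute its current metrics."""
    sweep = simulate_whole_cell_sweep(model, seed, n_channels=n_channels, **overrides)
    return compute_metrics(sweep, BASELINE_WINDOW_MS)


def slow_fraction_cohort(
    preset: str, seeds: range | list[int], n_channels: int = 500, **overrides
) -> np.ndarray:
    """Slow fractions of a cohort of simulated cells (one seed per cell)."""
    model = build_preset(preset)
    return np.array([
        whole_cell_metrics(model, seed, n_channels=n_channels, **overrides).slow_fraction
        for seed in seeds
    ])


def conductance_recovery(
    seed: int,
    voltages_mV: tuple[float, ...] = (-80.0, -60.0, -40.0, 40.0, 60.0),
    n_sweeps_per_voltage: int = 15,
    preset: str = "mes_slow",
    n_channels: int = 3,
    max_levels: int = 4,
) -> ConductanceFit:
    """Full single-channel conductance experiment on simulated patches.

    For each holding potential, ``n_sweeps_per_voltage`` pressure-evoked
    sweeps are simulated from an ``n_channels``-channel patch; the stimulus
    segments (skipping 10 ms after onset to avoid the activation ramp) are
    pooled into one amplitude histogram, current levels are fit as a
    Gaussian mixture, and the unitary current is the weighted adjacent-level
    spacing.  The unitary currents are then regressed on voltage, giving the
    unitary conductance in pS.
    """
    model = build_preset(preset)
    proto = standard_pressure_protocol()
    voltages, unitary = [], []
    for k, v in enumerate(voltages_mV):
        cfg = single_channel_config(seed + 1000 * (k + 1), v_hold=v, n_channels=n_channels)
        sweepset = simulate_single_channel(model, proto, cfg, n_repeats=n_sweeps_per_voltage)
        samples = np.concatenate([
            sw.slice_ms(sw.stim_onset + 10.0, sw.stim_onset + sw.stim_duration)
            for sw in sweepset
        ])
        pooled = Sweep(
            samples=samples, fs=cfg.fs, v_hold=v, stim_onset=0.0,
            stim_duration=samples.size * 1000.0 / cfg.fs,
            sweep_id=f"pooled_v{v:g}",
        )
        hist = build_histogram(pooled, (0.0, pooled.duration_ms), bin_width=0.05)
        levels = fit_levels(hist, max_levels=max_levels)
        voltages.append(v)
        unitary.append(unitary_current(levels))
    return conductance_fit(voltages, unitary)


#: Worked proliferation example: percent PH3-positive of total DAPI nuclei
#: per stem-cell line (two wild-type, three Piezo1-knockout lines; three 10x
#: fields per line, mean ~1500 cells/field).
PH3_PERCENT_BY_LINE: dict[str, float] = {
    "HB9": 3.487,
    "WT13": 2.961,
    "KO5": 3.331,
    "KO6": 3.268,
    "KO8": 3.673,
}

PH3_GENOTYPE_BY_LINE: dict[str, str] = {
    "HB9": "WT",
    "WT13": "WT",
    "KO5": "KO",
    "KO6": "KO",
    "KO8": "KO",
}

WT_PH3_LINES: list[float] = [
    v for k, v in PH3_PERCENT_BY_LINE.items() if PH3_GENOTYPE_BY_LINE[k] == "WT"
]
KO_PH3_LINES: list[float] = [
    v for k, v in PH3_PERCENT_BY_LINE.items() if PH3_GENOTYPE_BY_LINE[k] == "KO"
]
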
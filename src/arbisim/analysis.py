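"""Post-processing and designed evolution experiments.

Covers the standard read-outs of the passaging runs — variant frequency
distributions and the dominant (most abundant) variant — plus the three
designed experiments: regime scans over the passage interval T, noise
scans over the carrying-capacity coefficient of variation, and two-variant
head-to-head competition without mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import SystemState
from .grid import VariantGrid
from .parameters import ScaledParameters
from .passaging import PassagingConfig, SteadyStateReport, run_serial_passaging


def variant_frequencies(state: SystemState, pool: str = "phage") -> np.ndarray:
    """Normalised variant frequencies in the free-phage or lysogen pool."""
    if pool == "phage":
        masses = state.p
    elif pool == "lysogen":
        masses = state.l
    else:
        raise ValueError(f"unknown pool {pool!r}")
    total = masses.sum()
    if total <= 0:
        raise ValueError(f"{pool} pool is empty; frequencies are undefined")
    return masses / total


def dominant_variant_index(freq: np.ndarray, grid: VariantGrid) -> int:
    """Index of the most abundant variant; ties go to lower phi_max, then lower theta."""
    freq = np.asarray(freq, dtype=float)
    candidates = np.flatnonzero(freq == np.nanmax(freq))
    order = np.lexsort((grid.theta[candidates], grid.phi_max[candidates]))
    return int(candidates[order[0]])


def dominant_variant(freq: np.ndarray, grid: VariantGrid) -> tuple:
    """(phi_max, theta) of the most abundant variant."""
    return grid.traits(dominant_variant_index(freq, grid))


@dataclass
class RegimeScanResult:
    """Steady-state distribution per scanned value of T or CV."""

    axis: str                      # "T" or "cv"
    values: np.ndarray
    distributions: np.ndarray      # (n_values, n_variants)
    dominant: list                 # [(phi_max, theta), ...]
    reports: list                  # per-value SteadyStateReport
    grid: VariantGrid

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per scanned value per variant."""
        rows = []
        for v, dist in zip(self.values, self.distributions):
            for j in range(self.grid.n_variants):
                phi, theta = self.grid.traits(j)
                rows.append({self.axis: v, "phi_max": phi, "theta": theta,
                             "frequency": dist[j]})
        return pd.DataFrame(rows)


def regime_scan_T(
    T_values: Sequence[float],
    params: ScaledParameters,
    grid: VariantGrid,
    config: Optional[PassagingConfig] = None,
) -> RegimeScanResult:
    """Steady-state variant distribution as a function of the passage interval."""
    T_values = np.asarray(list(T_values), dtype=float)
    if np.any(T_values <= 0):
        raise ValueError("passage intervals must be positive")
    config = config or PassagingConfig()
    dists, dominants, reports = [], [], []
    for T in T_values:
        report = run_serial_passaging(params.replace(T=float(T)), grid, config)
        freq = report.final_phage_freq
        dists.append(freq)
        dominants.append(dominant_variant(freq, grid))
        reports.append(report)
    return RegimeScanResult("T", T_values, np.asarray(dists), dominants, reports, grid)


def regime_scan_cv(
    cv_values: Sequence[float],
    params: ScaledParameters,
    grid: VariantGrid,
    config: Optional[PassagingConfig] = None,
    seed: Optional[int] = None,
) -> RegimeScanResult:
    """Steady-state distribution under episode-to-episode carrying-capacity noise.

    Noisy runs never settle exactly, so each scan value runs a fixed number
    of episodes (config.n_episodes_max, default 1000 here) and reports the
    trailing-average distribution.  One seeded RNG stream is drawn per scan
    value from ``seed`` for reproducibility independent of scan order.
    """
    cv_values = np.asarray(list(cv_values), dtype=float)
    if np.any(cv_values < 0):
        raise ValueError("coefficients of variation must be non-negative")
    if config is None:
        config = PassagingConfig(n_episodes_max=1000, detect_steady_state=False,
                                 report_average_episodes=100)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(len(cv_values))
    dists, dominants, reports = [], [], []
    for cv, child in zip(cv_values, child_seeds):
        cfg = replace(config, cv_K=float(cv),
                      detect_steady_state=config.detect_steady_state and cv == 0)
        rng = np.random.default_rng(child)
        report = run_serial_passaging(params, grid, cfg, rng=rng)
        freq = report.final_phage_freq
        dists.append(freq)
        dominants.append(dominant_variant(freq, grid))
        reports.append(report)
    return RegimeScanResult("cv", cv_values, np.asarray(dists), dominants, reports, grid)


def competition_experiment(
    variant_a: tuple,
    variant_b: tuple,
    init_freq_b: float,
    params: ScaledParameters,
    config: Optional[PassagingConfig] = None,
) -> np.ndarray:
    """Two-variant competition without mutation.

    Returns the frequency of variant b among free phages at the end of each
    passaging episode.  Mutation is disabled so the comparison is between
    the two fixed strategies alone.
    """
    if not 0 < init_freq_b < 1:
        raise ValueError("init_freq_b must lie strictly between 0 and 1")
    grid = VariantGrid.pair(variant_a, variant_b)
    params = params.replace(mu_phi=0.0, mu_theta=0.0)
    config = config or PassagingConfig()
    config = replace(config, init_freq=np.array([1.0 - init_freq_b, init_freq_b]))
    report = run_serial_passaging(params, grid, config)
    return report.phage_freqs[:, 1]
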
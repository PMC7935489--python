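"""Serial-passaging protocols and the multi-episode evolutionary driver.

Each passaging episode starts from a fresh susceptible population at
(that episode's) carrying capacity plus a small phage inoculum, runs the
within-episode dynamics for T hours, and then transfers a fraction D of
the material into the next episode.  Two protocols are implemented:

* ``phage_only`` — only free phages are passaged (the standard protocol);
  relative variant frequencies are preserved exactly by the transfer.
* ``full_sample`` — susceptibles, lysogens, phages and arbitrium are all
  diluted by D and added to a fresh susceptible population.

Episode-to-episode variability of the environment is modelled by drawing
each episode's carrying capacity from a gamma distribution with mean 1
(units K) and a chosen coefficient of variation.  Repeating the cycle
drives a long series of epidemics under mutation and selection until the
end-of-episode phage-variant frequencies stop changing (an evolutionarily
steady state) or an episode cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import SystemState, integrate_episode
from .grid import VariantGrid
from .parameters import ScaledParameters

#: total phage densities below this are treated as extinction
EXTINCTION_FLOOR = 1e-30

#: solver absolute tolerance leaves per-variant noise of this order, so a
#: population is already numerically extinct well above EXTINCTION_FLOOR
_NOISE_PER_VARIANT = 1e-11


@dataclass
class PassagingConfig:
    """Settings of a serial-passaging run.

    ``p_total_init`` defaults to 1e-5 * B_eff, the scaled image of an
    inoculum of 1e-5 * K * B phages per mL.  ``init_freq`` defaults to a
    uniform distribution over the grid.  With ``detect_steady_state``
    false the run always executes ``n_episodes_max`` episodes (used for
    noisy-environment runs, which never settle exactly).
    ``report_average_episodes`` sets how many trailing episodes are
    averaged for the reported final frequency vector (1 = last episode).
    """

    n_episodes_max: int = 2000
    protocol: str = "phage_only"
    p_total_init: Optional[float] = None
    init_freq: Optional[np.ndarray] = None
    cv_K: float = 0.0
    seed: Optional[int] = None
    ss_tol: float = 1e-6
    ss_window: int = 10
    detect_steady_state: bool = True
    full_sample_cap: bool = False
    report_average_episodes: int = 1

    def __post_init__(self) -> None:
        if self.protocol not in ("phage_only", "full_sample"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.cv_K < 0:
            raise ValueError("cv_K must be non-negative")
        if self.p_total_init is not None and not self.p_total_init > 0:
            raise ValueError("p_total_init must be positive")
        if self.init_freq is not None:
            freq = np.asarray(self.init_freq, dtype=float)
            if np.any(freq < 0) or not np.isclose(freq.sum(), 1.0, atol=1e-9):
                raise ValueError("init_freq must be non-negative and sum to 1")
            self.init_freq = freq


@dataclass
class SteadyStateReport:
    """Per-episode end-state frequencies and the run's outcome."""

    phage_freqs: np.ndarray      # (n_episodes, n_variants); NaN rows = empty pool
    lysogen_freqs: np.ndarray
    k_values: np.ndarray
    converged_episode: Optional[int]
    extinct: bool
    final_state: SystemState
    report_average_episodes: int = 1

    @property
    def n_episodes(self) -> int:
        return self.phage_freqs.shape[0]

    @property
    def final_phage_freq(self) -> np.ndarray:
        """Phage-pool frequency vector averaged over the trailing episodes."""
        m = min(self.report_average_episodes, self.n_episodes)
        avg = np.nanmean(self.phage_freqs[-m:], axis=0)
        total = avg.sum()
        return avg / total if total > 0 else avg

    def dominant_index(self, grid: VariantGrid) -> int:
        from .analysis import dominant_variant_index

        return dominant_variant_index(self.final_phage_freq, grid)

    def dominant_traits(self, grid: VariantGrid) -> tuple:
        return grid.traits(self.dominant_index(grid))


def initialize_episode(
    grid: VariantGrid,
    k: float,
    p_total: float,
    freq: np.ndarray,
) -> SystemState:
    """Fresh episode: susceptibles at carrying capacity plus a phage inoculum."""
    freq = np.asarray(freq, dtype=float)
    if freq.size != grid.n_variants:
        raise ValueError("frequency vector length does not match grid")
    if np.any(freq < 0) or not np.isclose(freq.sum(), 1.0, atol=1e-9):
        raise ValueError("frequencies must be non-negative and sum to 1")
    if not p_total > 0:
        raise ValueError("p_total must be positive")
    return SystemState(s=k, l=np.zeros(grid.n_variants), p=p_total * freq, A=0.0, k=k)


def passage_phage_only(end_state: SystemState, params: ScaledParameters, k_next: float) -> SystemState:
    """Transfer a fraction D of the phages into a fresh susceptible population.

    Scalar dilution preserves the relative variant frequencies exactly.
    """
    return SystemState(
        s=k_next,
        l=np.zeros(end_state.n_variants),
        p=params.D * end_state.p,
        A=0.0,
        k=k_next,
    )


def passage_full_sample(
    end_state: SystemState,
    params: ScaledParameters,
    k_next: float,
    *,
    cap_bacteria: bool = False,
) -> SystemState:
    """Dilute the whole sample (cells, lysogens, phages, arbitrium) by D.

    Fresh susceptibles at carrying capacity are added on top of the
    carried-over material; with ``cap_bacteria`` the total bacterial
    density is instead capped at ``k_next``.
    """
    D = params.D
    l_new = D * end_state.l
    s_carry = D * end_state.s
    if cap_bacteria:
        s_new = max(k_next - l_new.sum() - s_carry, 0.0) + s_carry
    else:
        s_new = k_next + s_carry
    return SystemState(s=s_new, l=l_new, p=D * end_state.p, A=D * end_state.A, k=k_next)


def draw_carrying_capacity(cv: float, rng: np.random.Generator) -> float:
    """Episode carrying capacity (units K) from a mean-1 gamma distribution.

    cv = 0 returns exactly 1; cv = 1 is the exponential distribution.
    """
    if cv < 0:
        raise ValueError("coefficient of variation must be non-negative")
    if cv == 0:
        return 1.0
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, cv**2))


def detect_evolutionary_steady_state(
    freq_history: np.ndarray, tol: float, window: int
) -> Optional[int]:
    """First episode index after which consecutive end-of-episode phage
    frequency vectors stay within L1 distance ``tol`` for ``window``
    consecutive episodes; None if never."""
    freq_history = np.asarray(freq_history, dtype=float)
    if freq_history.shape[0] < window + 1:
        return None
    diffs = np.abs(np.diff(freq_history, axis=0)).sum(axis=1)
    small = diffs < tol
    run = 0
    for i, ok in enumerate(small):
        run = run + 1 if ok else 0
        if run >= window:
            return i + 1  # episode index of the last state in the window
    return None


def _pool_frequencies(pool: np.ndarray, floor: float = EXTINCTION_FLOOR) -> np.ndarray:
    total = pool.sum()
    if total <= floor:
        return np.full(pool.size, np.nan)
    return pool / total


def run_serial_passaging(
    params: ScaledParameters,
    grid: VariantGrid,
    config: PassagingConfig,
    *,
    rng: Optional[np.random.Generator] = None,
) -> SteadyStateReport:
    """Iterate initialise -> integrate -> passage until an evolutionarily
    steady state is detected (or the episode cap / extinction)."""
    nv = grid.n_variants
    freq0 = config.init_freq if config.init_freq is not None else np.full(nv, 1.0 / nv)
    if freq0.size != nv:
        raise ValueError("init_freq length does not match grid")
    p_total = config.p_total_init if config.p_total_init is not None else 1e-5 * params.B_eff
    if rng is None:
        rng = np.random.default_rng(config.seed)

    phage_freqs: list = []
    lysogen_freqs: list = []
    ks: list = []
    converged: Optional[int] = None
    extinct = False
    run = 0
    prev_freq: Optional[np.ndarray] = None

    k = draw_carrying_capacity(config.cv_K, rng)
    state = initialize_episode(grid, k, p_total, freq0)

    for episode in range(config.n_episodes_max):
        traj = integrate_episode(state, params, grid, store=False)
        end = traj.final_state()
        pf = _pool_frequencies(end.p)
        phage_freqs.append(pf)
        lysogen_freqs.append(_pool_frequencies(end.l))
        ks.append(state.k)

        if end.p.sum() <= max(EXTINCTION_FLOOR, _NOISE_PER_VARIANT * nv):
            extinct = True
            state = end
            break

        if config.detect_steady_state and prev_freq is not None and not np.any(np.isnan(pf)):
            d = np.abs(pf - prev_freq).sum()
            run = run + 1 if d < config.ss_tol else 0
            if run >= config.ss_window:
                converged = episode
                state = end
                break
        prev_freq = pf

        if episode == config.n_episodes_max - 1:
            state = end
            break

        k_next = draw_carrying_capacity(config.cv_K, rng)
        if config.protocol == "phage_only":
            state = passage_phage_only(end, params, k_next)
        else:
            state = passage_full_sample(end, params, k_next, cap_bacteria=config.full_sample_cap)

    return SteadyStateReport(
        phage_freqs=np.asarray(phage_freqs),
        lysogen_freqs=np.asarray(lysogen_freqs),
        k_values=np.asarray(ks),
        converged_episode=converged,
        extinct=extinct,
        final_state=state,
        report_average_episodes=config.report_average_episodes,
    )
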
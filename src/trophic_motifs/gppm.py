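"""The Generalized Preferential Preying Model (GPPM).

A growth model for directed food webs with tunable trophic coherence.
Starting from B basal nodes at (temporary) level 1, the remaining N - B
nodes are added one at a time, each choosing a single prey uniformly
among all existing nodes and taking temporary level one above its prey.
This skeleton guarantees every node is reachable from a basal node.
The remaining links are then drawn among all ordered pairs (i, j) with
j non-basal, each independently with probability

    P_ij = min(1, c * exp(-(x_ij - 1)^2 / (2 T^2))),

where x_ij is the temporary trophic distance and the constant c is set
so that the expected final link count is L.  The temperature T controls
how sharply link formation concentrates on adjacent levels: T = 0 gives
perfectly coherent webs (q = 0, only adjacent-level links are possible),
large T approaches uniform wiring.  Final trophic levels are recomputed
on the finished web, so realized q generally differs from the temporary
integer levels for T > 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .foodweb_io import FoodWeb
from .trophic import q_from_adjacency
from . import motif_census

logger = logging.getLogger(__name__)

__all__ = [
    "GPPMConfig",
    "GPPMDraw",
    "GPPMFit",
    "TransitionPoint",
    "generate",
    "ensemble_q",
    "fit_temperature",
    "s2_transition",
]


@dataclass(frozen=True)
class GPPMConfig:
    """Model parameters: B basal nodes, N total, L expected links, temperature T."""

    B: int
    N: int
    L: int
    T: float
    seed: int | None = None

    def __post_init__(self):
        if not 1 <= self.B < self.N:
            raise ValueError("need 1 <= B < N")
        if self.L < self.N - self.B:
            raise ValueError("L must be at least N - B (the growth skeleton)")
        if self.T < 0:
            raise ValueError("temperature must be nonnegative")


@dataclass(frozen=True)
class GPPMDraw:
    """A single generated web plus its temporary (growth-time) levels."""

    web: FoodWeb
    temporary_levels: dict[str, float]
    realized_links: int
    adjacency: np.ndarray = field(repr=False)
    q: float


def _skeleton(B: int, N: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sequential attachment: each new node takes one uniform prey; returns (A, s_hat)."""
    s_hat = np.ones(N)
    a = np.zeros((N, N), dtype=bool)
    for j in range(B, N):
        i = int(rng.integers(0, j))
        a[i, j] = True
        s_hat[j] = s_hat[i] + 1.0
    return a, s_hat


def _link_probabilities(a: np.ndarray, s_hat: np.ndarray, B: int, L: int, T: float) -> np.ndarray:
    """Per-pair extra-link probabilities, normalized to L - (N - B) expected links."""
    N = len(s_hat)
    extra = L - (N - B)
    x = s_hat[None, :] - s_hat[:, None]
    if T == 0.0:
        w = (x == 1.0).astype(float)
    else:
        w = np.exp(-((x - 1.0) ** 2) / (2.0 * T * T))
    w[:, :B] = 0.0  # basal nodes take no prey
    np.fill_diagonal(w, 0.0)
    w[a] = 0.0  # skeleton links are already present
    if extra == 0:
        return np.zeros_like(w)
    positive = w[w > 0]
    if positive.size < extra:
        raise ValueError(
            f"cannot reach L={L}: only {positive.size + (N - B)} links are "
            f"possible at T={T}"
        )
    c = _solve_norm_constant(positive, extra)
    return np.minimum(1.0, c * w)


def _solve_norm_constant(weights: np.ndarray, target: float) -> float:
    """Solve sum_i min(1, c * w_i) = target for c (w_i > 0, target <= len(w))."""
    ws = np.sort(weights)[::-1]
    tail = np.cumsum(ws[::-1])[::-1]  # tail[t] = sum of ws[t:]
    for t in range(int(math.ceil(target)) + 1):
        if t >= len(ws):
            break
        if tail[t] <= 0:
            continue
        c = (target - t) / tail[t]
        hi_ok = t == 0 or c * ws[t - 1] >= 1.0 - 1e-12
        lo_ok = c * ws[t] <= 1.0 + 1e-12
        if hi_ok and lo_ok:
            return c
    # all weights saturate
    return 1.0 / ws[-1]


def generate(config: GPPMConfig, rng: np.random.Generator | int | None = None) -> GPPMDraw:
    """Draw one GPPM web.

    Basal nodes keep in-degree zero by construction, every node is
    reachable from a basal node via the growth skeleton, and the
    realized link count has expectation L.
    """
    if rng is None:
        rng = config.seed
    rng = np.random.default_rng(rng)
    a, s_hat = _skeleton(config.B, config.N, rng)
    p = _link_probabilities(a, s_hat, config.B, config.L, config.T)
    a = a | (rng.random(p.shape) < p)
    q = q_from_adjacency(a)
    web = FoodWeb.from_adjacency(a)
    temp = {web.nodes[i]: float(s_hat[i]) for i in range(config.N)}
    return GPPMDraw(
        web=web,
        temporary_levels=temp,
        realized_links=int(a.sum()),
        adjacency=a,
        q=q,
    )


def ensemble_q(
    config: GPPMConfig, n_draws: int, seed: int | None = None
) -> tuple[float, float]:
    """Mean and sample sd of q over independent draws."""
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    qs = ensemble_q_samples(config, n_draws, seed)
    return float(qs.mean()), float(qs.std(ddof=1))


def ensemble_q_samples(
    config: GPPMConfig, n_draws: int, seed: int | None = None
) -> np.ndarray:
    """q of each of ``n_draws`` independent draws (child seeds from ``seed``)."""
    rng = np.random.default_rng(seed)
    qs = np.empty(n_draws)
    for i in range(n_draws):
        a, s_hat = _skeleton(config.B, config.N, rng)
        p = _link_probabilities(a, s_hat, config.B, config.L, config.T)
        a = a | (rng.random(p.shape) < p)
        qs[i] = q_from_adjacency(a)
    return qs


# ----------------------------------------------------------------------
# temperature calibration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GPPMFit:
    """Result of calibrating T so the ensemble-mean q matches a target."""

    target_q: float
    T: float
    mean_q: float
    sd_q: float
    evaluations: tuple[tuple[float, float, float], ...]  # (T, mean q, sd q)


def fit_temperature(
    B: int,
    N: int,
    L: int,
    target_q: float,
    tolerance: float = 0.01,
    seed: int | None = None,
    *,
    n_draws: int = 200,
    n_draws_final: int = 1000,
    t_max: float = 20.0,
) -> GPPMFit:
    """Stochastic root finding for the temperature matching an empirical q.

    Bracketing bisection on T: each evaluation is a Monte-Carlo estimate
    of the ensemble-mean q (``n_draws`` webs), escalating to
    ``n_draws_final`` once the bracket is narrow.  The mean q is
    monotone non-decreasing in T, which makes bisection consistent
    despite sampling noise.
    """
    if target_q < 0:
        raise ValueError("target q must be nonnegative")
    ss = np.random.SeedSequence(seed)
    evals: list[tuple[float, float, float]] = []

    def estimate(t: float, draws: int) -> tuple[float, float]:
        child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        m, s = ensemble_q(GPPMConfig(B=B, N=N, L=L, T=t), draws, seed=child)
        evals.append((t, m, s))
        return m, s

    if target_q <= tolerance:
        m, s = estimate(0.0, n_draws)
        return GPPMFit(target_q=target_q, T=0.0, mean_q=m, sd_q=s,
                       evaluations=tuple(evals))

    lo, hi = 0.0, 1.0
    m_hi, _ = estimate(hi, n_draws)
    while m_hi < target_q:
        lo = hi
        hi *= 2.0
        if hi > t_max:
            raise ValueError(
                f"target q={target_q} is above the large-T plateau "
                f"(mean q ~ {m_hi:.3f} at T={lo}); infeasible for "
                f"B={B}, N={N}, L={L}"
            )
        m_hi, _ = estimate(hi, n_draws)

    best_t, best_m, best_s = hi, m_hi, evals[-1][2]
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        draws = n_draws_final if (hi - lo) < 0.05 else n_draws
        m, s = estimate(mid, draws)
        if abs(m - target_q) < abs(best_m - target_q):
            best_t, best_m, best_s = mid, m, s
        if abs(m - target_q) <= tolerance and draws >= n_draws_final:
            return GPPMFit(target_q=target_q, T=mid, mean_q=m, sd_q=s,
                           evaluations=tuple(evals))
        if m < target_q:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    return GPPMFit(target_q=target_q, T=best_t, mean_q=best_m, sd_q=best_s,
                   evaluations=tuple(evals))


# ----------------------------------------------------------------------
# S2 over/under-representation transition
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionPoint:
    """Location of the S2 sign change at one basal ratio.

    ``open_interval`` is set when no sign change was found in the
    scanned temperature range (T_c/q_c are then NaN).
    """

    basal_ratio: float
    T_c: float
    q_c: float
    T_grid: tuple[float, ...]
    mean_z_hat_s2: tuple[float, ...]
    se_z_hat_s2: tuple[float, ...]
    mean_q: tuple[float, ...]
    open_interval: bool = False


_S2_INDEX = motif_census.TRIAD_LABELS.index("S2")


def mean_s2_significance(
    config: GPPMConfig,
    n_draws: int,
    seed: int | None = None,
    *,
    null_ensemble: int = 20,
    swaps_per_link: int = 5,
) -> tuple[float, float, float]:
    """Ensemble mean of the normalized S2 z-score (and its SE), plus mean q.

    Each draw's profile is measured against its own configuration-model
    null ensemble.
    """
    ss = np.random.SeedSequence(seed)
    zs = np.empty(n_draws)
    qs = np.empty(n_draws)
    for i, child in enumerate(ss.spawn(n_draws)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        draw = generate(config, rng=rng)
        _, _, profile = motif_census.tsp(
            draw.web, ensemble_size=null_ensemble,
            swaps_per_link=swaps_per_link, seed=child_seed + 1,
        )
        zs[i] = profile.z_hat[_S2_INDEX]
        qs[i] = draw.q
    return float(zs.mean()), float(zs.std(ddof=1) / np.sqrt(n_draws)), float(qs.mean())


def s2_transition(
    basal_ratios: list[float],
    N: int = 100,
    mean_degree: float = 10.0,
    n_draws: int = 100,
    seed: int | None = None,
    *,
    T_grid: list[float] | None = None,
    null_ensemble: int = 20,
    swaps_per_link: int = 5,
) -> list[TransitionPoint]:
    """Locate, per basal ratio, the temperature where omnivory (S2) flips
    from under- to over-represented.

    For each B/N the ensemble-mean normalized S2 z-score is scanned over
    a temperature grid; the critical T_c (and the associated critical
    incoherence q_c) is linearly interpolated at the sign change.
    """
    if T_grid is None:
        T_grid = [0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3]
    ss = np.random.SeedSequence(seed)
    points: list[TransitionPoint] = []
    for ratio, child in zip(basal_ratios, ss.spawn(len(basal_ratios))):
        if not 0.0 < ratio < 1.0:
            raise ValueError("basal ratios must lie in (0, 1)")
        B = max(1, round(ratio * N))
        L = round(mean_degree * (N - B))
        means, ses, q_means = [], [], []
        for t, tchild in zip(T_grid, child.spawn(len(T_grid))):
            cfg = GPPMConfig(B=B, N=N, L=L, T=float(t))
            m, se, qm = mean_s2_significance(
                cfg, n_draws, seed=int(tchild.generate_state(1)[0] % (2**31)),
                null_ensemble=null_ensemble, swaps_per_link=swaps_per_link,
            )
            means.append(m)
            ses.append(se)
            q_means.append(qm)
        t_c = q_c = float("nan")
        open_interval = True
        for a in range(len(T_grid) - 1):
            if means[a] < 0.0 <= means[a + 1]:
                frac = -means[a] / (means[a + 1] - means[a])
                t_c = T_grid[a] + frac * (T_grid[a + 1] - T_grid[a])
                q_c = q_means[a] + frac * (q_means[a + 1] - q_means[a])
                open_interval = False
                break
        if open_interval:
            logger.warning("no S2 sign change for B/N=%.2f in T range %s",
                           ratio, (T_grid[0], T_grid[-1]))
        points.append(TransitionPoint(
            basal_ratio=ratio, T_c=t_c, q_c=q_c,
            T_grid=tuple(float(t) for t in T_grid),
            mean_z_hat_s2=tuple(means), se_z_hat_s2=tuple(ses),
            mean_q=tuple(q_means), open_interval=open_interval,
        ))
    return points
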
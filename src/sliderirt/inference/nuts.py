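"""No-U-Turn sampler with dual-averaging step size and diagonal metric.

A self-contained multinomial NUTS implementation (dynamic trajectory
length, biased progressive sampling, generalised U-turn criterion on a
diagonal metric) in plain NumPy.  Warmup follows the usual scheme: an
initial step-size-only buffer, expanding metric-estimation windows, and
a terminal step-size buffer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsConfig", "sample_nuts"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold


@dataclass(frozen=True)
class NutsConfig:
    warmup: int = 500
    draws: int = 500
    thin: int = 1
    target_accept: float = 0.95
    max_treedepth: int = 10
    # early warmup trees can explode before the metric adapts; cap them
    max_treedepth_warmup: int = 8


@dataclass
class _Tree:
    q_minus: np.ndarray
    r_minus: np.ndarray
    g_minus: np.ndarray
    q_plus: np.ndarray
    r_plus: np.ndarray
    g_plus: np.ndarray
    q_prop: np.ndarray
    logp_prop: float
    g_prop: np.ndarray
    log_w: float
    turned: bool
    diverged: bool
    n_steps: int
    sum_accept: float


def _leapfrog(q, r, g, eps, inv_mass, logp_grad):
    r = r + 0.5 * eps * g
    q = q + eps * inv_mass * r
    logp, g = logp_grad(q)
    r = r + 0.5 * eps * g
    return q, r, g, logp


def _uturn(q_plus, q_minus, r_plus, r_minus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (dq @ (inv_mass * r_minus)) < 0 or (dq @ (inv_mass * r_plus)) < 0


def _build_tree(q, r, g, direction, depth, eps, h0, inv_mass, logp_grad, rng) -> _Tree:
    if depth == 0:
        q1, r1, g1, logp1 = _leapfrog(q, r, g, direction * eps, inv_mass, logp_grad)
        h1 = -logp1 + 0.5 * (r1 @ (inv_mass * r1))
        log_w = h0 - h1  # joint log weight relative to the initial energy
        diverged = not np.isfinite(h1) or (h1 - h0) > _MAX_ENERGY_ERROR
        accept = 0.0 if not np.isfinite(log_w) else min(1.0, np.exp(min(log_w, 0.0)))
        return _Tree(
            q1, r1, g1, q1, r1, g1, q1, logp1, g1,
            -np.inf if diverged else log_w,
            False, diverged, 1, accept,
        )
    inner = _build_tree(q, r, g, direction, depth - 1, eps, h0, inv_mass, logp_grad, rng)
    if inner.diverged or inner.turned:
        return inner
    if direction == 1:
        outer = _build_tree(
            inner.q_plus, inner.r_plus, inner.g_plus,
            direction, depth - 1, eps, h0, inv_mass, logp_grad, rng,
        )
        q_minus, r_minus, g_minus = inner.q_minus, inner.r_minus, inner.g_minus
        q_plus, r_plus, g_plus = outer.q_plus, outer.r_plus, outer.g_plus
    else:
        outer = _build_tree(
            inner.q_minus, inner.r_minus, inner.g_minus,
            direction, depth - 1, eps, h0, inv_mass, logp_grad, rng,
        )
        q_minus, r_minus, g_minus = outer.q_minus, outer.r_minus, outer.g_minus
        q_plus, r_plus, g_plus = inner.q_plus, inner.r_plus, inner.g_plus
    n_steps = inner.n_steps + outer.n_steps
    sum_accept = inner.sum_accept + outer.sum_accept
    if outer.diverged or outer.turned:
        return _Tree(
            q_minus, r_minus, g_minus, q_plus, r_plus, g_plus,
            inner.q_prop, inner.logp_prop, inner.g_prop, inner.log_w,
            outer.turned, outer.diverged, n_steps, sum_accept,
        )
    log_w = np.logaddexp(inner.log_w, outer.log_w)
    # multinomial sampling within the subtree
    if np.log(rng.uniform()) < outer.log_w - log_w:
        q_prop, logp_prop, g_prop = outer.q_prop, outer.logp_prop, outer.g_prop
    else:
        q_prop, logp_prop, g_prop = inner.q_prop, inner.logp_prop, inner.g_prop
    turned = _uturn(q_plus, q_minus, r_plus, r_minus, inv_mass)
    return _Tree(
        q_minus, r_minus, g_minus, q_plus, r_plus, g_plus,
        q_prop, logp_prop, g_prop, log_w, turned, False, n_steps, sum_accept,
    )


def _transition(q, logp, g, eps, inv_mass, max_depth, logp_grad, rng):
    """One NUTS update. Returns (q, logp, g, stats)."""
    r0 = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * (r0 @ (inv_mass * r0))
    q_minus = q_plus = q
    r_minus = r_plus = r0
    g_minus = g_plus = g
    q_cur, logp_cur, g_cur = q, logp, g
    log_w = 0.0
    n_steps = 0
    sum_accept = 0.0
    diverged = False
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(
                q_plus, r_plus, g_plus, 1, depth, eps, h0, inv_mass, logp_grad, rng
            )
            q_plus, r_plus, g_plus = sub.q_plus, sub.r_plus, sub.g_plus
        else:
            sub = _build_tree(
                q_minus, r_minus, g_minus, -1, depth, eps, h0, inv_mass, logp_grad, rng
            )
            q_minus, r_minus, g_minus = sub.q_minus, sub.r_minus, sub.g_minus
        n_steps += sub.n_steps
        sum_accept += sub.sum_accept
        if sub.diverged:
            diverged = True
            break
        if sub.turned:
            break
        # biased progressive sampling: favour the new subtree
        if np.log(rng.uniform()) < sub.log_w - log_w:
            q_cur, logp_cur, g_cur = sub.q_prop, sub.logp_prop, sub.g_prop
        log_w = np.logaddexp(log_w, sub.log_w)
        if _uturn(q_plus, q_minus, r_plus, r_minus, inv_mass):
            break
        depth += 1
    stats = {
        "accept": sum_accept / max(n_steps, 1),
        "n_steps": n_steps,
        "depth": depth,
        "diverging": diverged,
        "energy": h0,
    }
    return q_cur, logp_cur, g_cur, stats


def _find_epsilon(q, logp, g, inv_mass, logp_grad, rng) -> float:
    """Heuristic initial step size (double/halve to cross 50% accept)."""
    eps = 0.1
    r = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * (r @ (inv_mass * r))
    _, r1, _, logp1 = _leapfrog(q, r, g, eps, inv_mass, logp_grad)
    h1 = -logp1 + 0.5 * (r1 @ (inv_mass * r1))
    dh = h0 - h1 if np.isfinite(h1) else -np.inf
    direction = 1 if dh > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, _, logp1 = _leapfrog(q, r, g, eps, inv_mass, logp_grad)
        h1 = -logp1 + 0.5 * (r1 @ (inv_mass * r1))
        dh = h0 - h1 if np.isfinite(h1) else -np.inf
        if (direction == 1 and dh <= np.log(0.5)) or (
            direction == -1 and dh >= np.log(0.5)
        ):
            break
    return eps


def _metric_windows(warmup: int) -> list[tuple[int, int]]:
    """(start, end) iteration ranges of the expanding metric windows."""
    if warmup < 40:
        return [(0, warmup)] if warmup else []
    init = max(int(0.15 * warmup), 10)
    term = max(int(0.10 * warmup), 10)
    windows = []
    start, size = init, 25
    while start < warmup - term:
        end = min(start + size, warmup - term)
        # absorb a final stub window
        if (warmup - term - end) < size:
            end = warmup - term
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    cfg: NutsConfig,
    rng: np.random.Generator,
    inv_mass0: np.ndarray | None = None,
):
    """Run one chain; returns (draws array, sample-stats dict)."""
    q = np.array(q0, dtype=float)
    logp, g = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones_like(q) if inv_mass0 is None else np.array(inv_mass0, dtype=float)
    eps = _find_epsilon(q, logp, g, inv_mass, logp_grad, rng)

    # dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    windows = _metric_windows(cfg.warmup)
    window_samples: list[np.ndarray] = []

    warm_depth = min(cfg.max_treedepth, cfg.max_treedepth_warmup)
    for it in range(cfg.warmup):
        q, logp, g, stats = _transition(
            q, logp, g, eps, inv_mass, warm_depth, logp_grad, rng
        )
        da_count += 1
        frac = 1.0 / (da_count + t0)
        h_bar = (1.0 - frac) * h_bar + frac * (cfg.target_accept - stats["accept"])
        log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
        w = da_count ** (-kappa)
        log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
        eps = float(np.exp(log_eps))

        for wstart, wend in windows:
            if wstart <= it < wend:
                window_samples.append(q.copy())
                if it == wend - 1:
                    S = np.asarray(window_samples)
                    nW = len(S)
                    var = S.var(axis=0, ddof=1) if nW > 1 else np.ones_like(q)
                    inv_mass = (nW / (nW + 5.0)) * var + 1e-3 * (5.0 / (nW + 5.0))
                    window_samples = []
                    eps = _find_epsilon(q, logp, g, inv_mass, logp_grad, rng)
                    mu_da = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
                break

    if cfg.warmup:
        eps = float(np.exp(log_eps_bar))

    draws = np.empty((cfg.draws, len(q)))
    stat_keys = ("accept", "n_steps", "depth", "diverging", "energy")
    sample_stats = {k: np.empty(cfg.draws) for k in stat_keys}
    kept = 0
    total = cfg.draws * cfg.thin
    for it in range(total):
        q, logp, g, stats = _transition(
            q, logp, g, eps, inv_mass, cfg.max_treedepth, logp_grad, rng
        )
        if (it + 1) % cfg.thin == 0:
            draws[kept] = q
            for k in stat_keys:
                sample_stats[k][kept] = stats[k]
            kept += 1
    sample_stats["diverging"] = sample_stats["diverging"].astype(bool)
    sample_stats["step_size"] = np.full(cfg.draws, eps)
    return draws, sample_stats
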
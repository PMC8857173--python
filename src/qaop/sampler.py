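"""Gradient-based adaptive MCMC: a No-U-Turn sampler with adaptation.

Dynamic Hamiltonian Monte Carlo with slice-based tree doubling, dual-averaging
step-size adaptation and windowed diagonal mass-matrix estimation, in the
style of Stan's adaptive warmup.  Divergent transitions (energy error above
1000 nats) are detected and reported per chain; the caller is responsible for
acting on them and on convergence diagnostics.

Everything operates on an unconstrained parameter vector; the model layer owns
transforms (e.g. log-scale for half-normal standard deviations) and their
Jacobians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["NUTSResult", "sample_nuts"]

_MAX_ENERGY_ERROR = 1000.0  # nats; beyond this a transition is divergent


@dataclass
class NUTSResult:
    draws: np.ndarray  # (n_draws, dim), post-warmup
    divergences: int  # post-warmup divergent transitions
    warmup_divergences: int
    step_size: float
    inv_metric: np.ndarray  # diagonal of the inverse mass matrix
    accept_stat: np.ndarray  # (n_draws,) mean Metropolis acceptance per draw
    tree_depth: np.ndarray  # (n_draws,)
    energy: np.ndarray  # (n_draws,) Hamiltonian at the accepted state
    divergent: np.ndarray = None  # (n_draws,) per-draw divergence flags


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return np.exp(self.log_eps)

    def restart(self, eps: float) -> None:
        self.mu = np.log(10.0 * eps)
        self.log_eps = np.log(eps)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar)) if self.count else float(np.exp(self.log_eps))


def _find_reasonable_epsilon(logp_grad, x, inv_metric, rng) -> float:
    eps = 1.0
    lp, grad = logp_grad(x)
    p = rng.standard_normal(x.size) / np.sqrt(inv_metric)
    h0 = lp - 0.5 * np.sum(p * p * inv_metric)

    def joint_after(eps):
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * inv_metric * p1
        lp1, g1 = logp_grad(x1)
        p1 = p1 + 0.5 * eps * g1
        return lp1 - 0.5 * np.sum(p1 * p1 * inv_metric)

    h = joint_after(eps)
    if not np.isfinite(h):
        h = -np.inf
    direction = 1.0 if (h - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        h = joint_after(eps)
        if not np.isfinite(h):
            h = -np.inf
        if direction * (h - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-10)


def _build_schedule(n_warmup: int) -> tuple[int, int, list[int]]:
    """(init_buffer, term_buffer, slow-window end indices) within warmup."""
    if n_warmup < 40:
        return n_warmup, 0, []
    init = min(75, max(10, int(0.15 * n_warmup)))
    term = min(50, max(10, int(0.10 * n_warmup)))
    ends, start, size = [], init, 25
    while start + size < n_warmup - term:
        nxt = start + size
        # last window absorbs the remainder
        if nxt + 2 * size >= n_warmup - term:
            nxt = n_warmup - term
        ends.append(nxt)
        start, size = nxt, size * 2
    if not ends:
        ends = [n_warmup - term]
    return init, term, ends


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    *,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> NUTSResult:
    """Run one NUTS chain and return post-warmup draws plus sampler stats."""
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_metric = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    eps = _find_reasonable_epsilon(logp_grad, x, inv_metric, rng)
    da = _DualAveraging(eps, target_accept)
    init_buf, term_buf, window_ends = _build_schedule(n_warmup)
    window_ends = set(window_ends)

    draws = np.empty((n_draws, dim))
    accept_stat = np.empty(n_draws)
    tree_depth = np.empty(n_draws, dtype=int)
    energy = np.empty(n_draws)
    divergences = 0
    warmup_divergences = 0
    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    state = {"x": x, "lp": lp, "grad": grad}

    def leapfrog(x, p, grad, eps):
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * inv_metric * p1
        lp1, g1 = logp_grad(x1)
        p1 = p1 + 0.5 * eps * g1
        return x1, p1, lp1, g1

    def kinetic(p):
        return 0.5 * np.sum(p * p * inv_metric)

    def transition(eps):
        """One NUTS transition; returns (accept_prob_mean, depth, divergent, H)."""
        nonlocal state
        x0_, lp0, grad0 = state["x"], state["lp"], state["grad"]
        p0 = rng.standard_normal(dim) / np.sqrt(inv_metric)
        joint0 = lp0 - kinetic(p0)
        logu = joint0 + np.log(rng.random())

        x_minus = x_plus = x0_
        p_minus = p_plus = p0
        g_minus = g_plus = grad0
        lp_minus = lp_plus = lp0
        x_prop, lp_prop, g_prop = x0_, lp0, grad0
        n_valid, depth, keep_going = 1, 0, True
        sum_alpha, n_alpha, divergent = 0.0, 0, False

        def build(x, p, g, lp, direction, j):
            """Returns subtree summary; recursion depth = j."""
            nonlocal sum_alpha, n_alpha, divergent
            if j == 0:
                x1, p1, lp1, g1 = leapfrog(x, p, g, direction * eps)
                joint = lp1 - kinetic(p1) if np.isfinite(lp1) else -np.inf
                n1 = int(logu <= joint)
                div_here = (joint0 - joint) > _MAX_ENERGY_ERROR or not np.isfinite(joint)
                if div_here:
                    divergent = True
                sum_alpha += min(1.0, np.exp(min(joint - joint0, 0.0))) if np.isfinite(joint) else 0.0
                n_alpha += 1
                return (x1, p1, g1, lp1, x1, p1, g1, lp1, x1, lp1, g1, n1, not div_here)
            out = build(x, p, g, lp, direction, j - 1)
            (xm, pm, gm, lpm, xp, pp, gp, lpp, xc, lpc, gc, n1, ok) = out
            if ok:
                if direction == -1:
                    out2 = build(xm, pm, gm, lpm, direction, j - 1)
                    (xm, pm, gm, lpm, _, _, _, _, xc2, lpc2, gc2, n2, ok2) = out2
                else:
                    out2 = build(xp, pp, gp, lpp, direction, j - 1)
                    (_, _, _, _, xp, pp, gp, lpp, xc2, lpc2, gc2, n2, ok2) = out2
                if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
                    xc, lpc, gc = xc2, lpc2, gc2
                n1 += n2
                rho = xp - xm
                ok = (
                    ok2
                    and np.dot(rho, inv_metric * pm) >= 0
                    and np.dot(rho, inv_metric * pp) >= 0
                )
            return (xm, pm, gm, lpm, xp, pp, gp, lpp, xc, lpc, gc, n1, ok)

        while keep_going and depth < max_treedepth:
            direction = -1 if rng.random() < 0.5 else 1
            if direction == -1:
                out = build(x_minus, p_minus, g_minus, lp_minus, direction, depth)
                (x_minus, p_minus, g_minus, lp_minus, _, _, _, _, xc, lpc, gc, n1, ok) = out
            else:
                out = build(x_plus, p_plus, g_plus, lp_plus, direction, depth)
                (_, _, _, _, x_plus, p_plus, g_plus, lp_plus, xc, lpc, gc, n1, ok) = out
            if ok and n1 > 0 and rng.random() < min(1.0, n1 / n_valid):
                x_prop, lp_prop, g_prop = xc, lpc, gc
            n_valid += n1
            rho = x_plus - x_minus
            keep_going = (
                ok
                and np.dot(rho, inv_metric * p_minus) >= 0
                and np.dot(rho, inv_metric * p_plus) >= 0
            )
            depth += 1

        state = {"x": x_prop, "lp": lp_prop, "grad": g_prop}
        mean_alpha = sum_alpha / max(n_alpha, 1)
        return mean_alpha, depth, divergent, -(lp_prop)

    # ----- warmup -----
    for it in range(n_warmup):
        alpha, depth, divergent, _ = transition(eps)
        if divergent:
            warmup_divergences += 1
        eps = da.update(alpha)
        if it >= init_buf and it < n_warmup - term_buf:
            welford_n += 1
            delta = state["x"] - welford_mean
            welford_mean += delta / welford_n
            welford_m2 += delta * (state["x"] - welford_mean)
        if (it + 1) in window_ends and welford_n >= 5:
            var = welford_m2 / (welford_n - 1)
            # Stan-style regularization towards unit scale
            inv_metric = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                5.0 / (welford_n + 5.0)
            )
            inv_metric = np.clip(inv_metric, 1e-10, None)
            welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)
            eps = _find_reasonable_epsilon(logp_grad, state["x"], inv_metric, rng)
            da.restart(eps)

    eps = da.adapted if n_warmup else eps

    # ----- sampling -----
    divergent_flags = np.zeros(n_draws, dtype=bool)
    for it in range(n_draws):
        alpha, depth, divergent, ham = transition(eps)
        if divergent:
            divergences += 1
            divergent_flags[it] = True
        draws[it] = state["x"]
        accept_stat[it] = alpha
        tree_depth[it] = depth
        energy[it] = ham

    return NUTSResult(
        draws=draws,
        divergences=divergences,
        warmup_divergences=warmup_divergences,
        step_size=float(eps),
        inv_metric=inv_metric,
        accept_stat=accept_stat,
        tree_depth=tree_depth,
        energy=energy,
        divergent=divergent_flags,
    )
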
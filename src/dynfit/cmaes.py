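"""Minimal (mu/mu_w, lambda) CMA-ES in the unit box.

Covariance Matrix Adaptation Evolution Strategy (Hansen's standard
formulation with rank-one and rank-mu covariance updates and cumulative
step-size adaptation). The search space is the unit box [0, 1]^d; candidates
outside it are clipped before evaluation and charged a quadratic out-of-box
penalty, which keeps the ranking smooth while making every evaluated point
feasible. Fully deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass
class CMAResult:
    x_best: np.ndarray     # feasible best point (inside the unit box)
    f_best: float          # raw objective at x_best (no penalty)
    n_evaluations: int
    n_iterations: int
    converged: bool        # stopped on tolerance rather than budget


def cma_minimize(
    func: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float = 0.3,
    popsize: int | None = None,
    max_evaluations: int | None = None,
    tol_fun: float = 1e-9,
    seed: int = 0,
    penalty_weight: float = 1e3,
) -> CMAResult:
    """Minimize ``func`` over the unit box starting from ``x0``.

    The starting point itself is evaluated first, so the returned best is
    never worse than the start. ``tol_fun`` stops the run when the function
    value spread within the recent iterations falls below it.
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    if d == 0:
        raise ValueError("empty search space")
    if not 0 < sigma0 <= 1:
        raise ValueError(f"sigma0 must be in (0, 1], got {sigma0}")
    lam = popsize if popsize is not None else 4 + int(3 * np.log(d))
    lam = max(4, lam)
    if max_evaluations is None:
        max_evaluations = 500 * d
    rng = np.random.default_rng(seed)

    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)
    cc = (4 + mueff / d) / (d + 4 + 2 * mueff / d)
    cs = (mueff + 2) / (d + mueff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((d + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (d + 1)) - 1) + cs
    chi_d = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d**2))

    mean = np.clip(x0, 0.0, 1.0).copy()
    sigma = sigma0
    C = np.eye(d)
    ps = np.zeros(d)
    pc = np.zeros(d)
    B = np.eye(d)
    D = np.ones(d)

    f0 = float(func(mean.copy()))
    x_best, f_best = mean.copy(), f0
    n_eval = 1
    n_iter = 0
    converged = False
    recent: list[float] = [f0]

    while n_eval + lam <= max_evaluations:
        n_iter += 1
        Z = rng.standard_normal((lam, d))
        Y = Z * D @ B.T  # y_i = B @ (D * z_i)
        X = mean + sigma * Y
        X_feas = np.clip(X, 0.0, 1.0)
        fitness = np.empty(lam)
        for i in range(lam):
            raw = float(func(X_feas[i]))
            overshoot = X[i] - X_feas[i]
            fitness[i] = raw + penalty_weight * float(overshoot @ overshoot)
            if raw < f_best:
                f_best, x_best = raw, X_feas[i].copy()
        n_eval += lam

        idx = np.argsort(fitness)
        Ysel = Y[idx[:mu]]
        y_w = w @ Ysel
        mean = mean + sigma * y_w

        # step-size path (uses C^(-1/2) y = B D^-1 B^T y)
        C_inv_sqrt_y = B @ ((B.T @ y_w) / D)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * C_inv_sqrt_y
        h_sig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (n_iter + 1))) / chi_d
            < 1.4 + 2 / (d + 1)
        )
        pc = (1 - cc) * pc + h_sig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        rank_mu = (Ysel * w[:, None]).T @ Ysel
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - h_sig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_d - 1))
        sigma = min(sigma, 1.0)

        C = (C + C.T) / 2
        eigvals, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(eigvals, 1e-20))

        recent.append(float(fitness[idx[0]]))
        if len(recent) > 10 + int(30 * d / lam):
            recent.pop(0)
        if len(recent) >= 5 and (max(recent) - min(recent)) < tol_fun:
            converged = True
            break
        if sigma * D.max() < 1e-12:
            converged = True
            break

    return CMAResult(
        x_best=x_best, f_best=f_best, n_evaluations=n_eval,
        n_iterations=n_iter, converged=converged,
    )
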
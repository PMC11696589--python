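"""Newton-Raphson solver for the log-linear Poisson rate model.

The baseline model is tiny (an intercept plus one or a few harmonic
pairs), but the parametric bootstrap refits it tens of thousands of
times, so the solver is written to run either on a single response or on
a whole batch of bootstrap responses sharing one design matrix, using
batched 3x3 (or (2k+1)x(2k+1)) linear solves.

For the canonical log link the Newton step equals Fisher scoring:
the Hessian of the log-likelihood is -X' diag(mu) X.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_poisson", "fit_poisson_batch", "poisson_loglik", "PoissonFitError"]


class PoissonFitError(RuntimeError):
    """Raised when the Newton iteration fails to converge."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


def poisson_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
                   offset: np.ndarray) -> float:
    """Poisson log-likelihood (without the constant -log y! term)."""
    eta = offset + X @ beta
    return float(y @ eta - np.exp(eta).sum())


def _start_values(X: np.ndarray, y: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Least squares on log(y + 0.5) - offset: cheap, always finite."""
    z = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return beta


def fit_poisson(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
    start: np.ndarray | None = None,
):
    """Maximum-likelihood fit of log mu = offset + X beta, y ~ Poisson(mu).

    Returns ``(beta, cov, loglik, n_iter)`` where ``cov`` is the inverse
    observed (= expected, canonical link) information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if np.all(y == 0):
        raise PoissonFitError("degenerate likelihood: all counts are zero")
    beta = _start_values(X, y, offset) if start is None else np.array(start, float)
    trace = []
    for it in range(1, max_iter + 1):
        eta = offset + X @ beta
        mu = np.exp(eta)
        score = X.T @ (y - mu)
        info = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise PoissonFitError(f"singular information at iteration {it}",
                                  trace) from exc
        # halve the step while it blows up the linear predictor
        for _ in range(30):
            if np.all(np.abs(offset + X @ (beta + step)) < 500):
                break
            step = step / 2.0
        beta = beta + step
        delta = float(np.max(np.abs(step)))
        trace.append(delta)
        if delta < tol:
            mu = np.exp(offset + X @ beta)
            info = (X * mu[:, None]).T @ X
            cov = np.linalg.inv(info)
            return beta, cov, poisson_loglik(beta, X, y, offset), it
    raise PoissonFitError(
        f"no convergence in {max_iter} iterations (last step {trace[-1]:.3e})",
        trace,
    )


def fit_poisson_batch(
    X: np.ndarray,
    Y: np.ndarray,
    offset: np.ndarray,
    start: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 60,
):
    """Fit the same design to many responses at once.

    ``Y`` has shape (B, n); ``start`` (p,) seeds every replicate
    (the bootstrap resamples around the fitted means, so the original
    estimate is an excellent start). Returns ``(betas, ok)`` with
    ``betas`` (B, p) and a boolean convergence mask ``ok``; replicates
    with an all-zero response are marked failed, not raised.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    B, n = Y.shape
    p = X.shape[1]
    betas = np.tile(np.asarray(start, dtype=float), (B, 1))
    ok = Y.sum(axis=1) > 0
    active = ok.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        eta = offset[None, :] + betas[idx] @ X.T           # (b, n)
        mu = np.exp(np.clip(eta, -500, 500))
        score = (Y[idx] - mu) @ X                          # (b, p)
        info = np.einsum("bn,np,nq->bpq", mu, X, X)        # (b, p, p)
        try:
            step = np.linalg.solve(info, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # fall back to per-replicate solves, dropping singular ones
            step = np.zeros_like(score)
            for k in range(len(idx)):
                try:
                    step[k] = np.linalg.solve(info[k], score[k])
                except np.linalg.LinAlgError:
                    ok[idx[k]] = False
                    active[idx[k]] = False
        bad = ~np.isfinite(step).all(axis=1)
        if bad.any():
            ok[idx[bad]] = False
            active[idx[bad]] = False
            step = np.where(bad[:, None], 0.0, step)
        betas[idx] += step
        done = np.max(np.abs(step), axis=1) < tol
        active[idx[done]] = False
    ok &= ~active  # replicates still active never converged
    return betas, ok
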
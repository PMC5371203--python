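"""Parametric empirical-Bayes batch adjustment for beta matrices.

Implements the classic location-scale model for between-array (chip)
effects: per-probe standardisation, per-batch additive (``gamma``) and
multiplicative (``delta``) effect estimation, shrinkage of the per-probe
batch effects towards batch-level priors (normal prior for ``gamma``,
inverse-gamma for ``delta``), and back-transformation. The adjustment
operates on beta values directly; output is clipped to [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import BetaMatrix


@dataclass
class BatchParameters:
    """Estimated batch effects, one row per (batch, probe) summarised per batch."""

    batches: list[str]
    gamma_star: pd.DataFrame  # batches x probes, shrunken additive effects
    delta_star: pd.DataFrame  # batches x probes, shrunken variance factors

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "batch": self.batches,
                "mean_gamma": self.gamma_star.mean(axis=1).values,
                "mean_delta": self.delta_star.mean(axis=1).values,
            }
        )


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    if s2 == 0:
        return np.inf
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    if s2 == 0:
        return np.inf
    return (m * s2 + m**3) / s2


def _posterior_iteration(
    Z_b: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate iteration for the EB posterior of one batch's effects."""
    n = Z_b.shape[1]
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    if not np.isfinite(a) or not np.isfinite(b) or tau2 == 0:
        # degenerate priors (e.g. constant moments across probes): no shrinkage
        return gamma, delta
    for _ in range(max_iter):
        gamma_new = (n * tau2 * gamma_hat + delta * gamma_bar) / (n * tau2 + delta)
        ss = ((Z_b - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * ss + b) / (n / 2 + a - 1)
        change = max(
            np.abs(gamma_new - gamma).max(initial=0.0),
            np.abs(delta_new - delta).max(initial=0.0),
        )
        gamma, delta = gamma_new, delta_new
        if change < tol:
            break
    return gamma, delta


def combat_adjust(
    beta: BetaMatrix,
    batch: pd.Series,
    parametric: bool = True,
    eps: float = 1e-6,
) -> tuple[BetaMatrix, BatchParameters]:
    """Remove batch effects from a beta matrix by empirical-Bayes shrinkage.

    Parameters
    ----------
    beta:
        Probes x samples beta matrix.
    batch:
        Batch label per sample (indexed by sample id).
    parametric:
        Use the parametric (normal / inverse-gamma) priors. The
        non-parametric variant is not implemented.
    eps:
        Upper clipping margin keeping output strictly below 1.

    A single batch is a no-op (the standardise/back-transform round trip is
    exact up to floating point). Any batch with fewer than two samples is
    an error, since its scale effect is undefined.
    """
    if not parametric:
        raise NotImplementedError("only the parametric variant is provided")
    X = beta.beta
    batch = batch.reindex(X.columns)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    levels = sorted(batch.unique())
    groups = {b: X.columns[batch == b] for b in levels}
    sizes = {b: len(cols) for b, cols in groups.items()}
    small = [b for b, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"batches with a single sample: {small}")

    V = X.values.astype(float)
    n_total = V.shape[1]
    idx = {b: X.columns.get_indexer(groups[b]) for b in levels}

    if len(levels) == 1:
        out = BetaMatrix(X.copy(), rescaled=beta.rescaled, batch_adjusted=True)
        params = BatchParameters(
            batches=[str(levels[0])],
            gamma_star=pd.DataFrame(
                np.zeros((1, V.shape[0])), index=levels, columns=X.index
            ),
            delta_star=pd.DataFrame(
                np.ones((1, V.shape[0])), index=levels, columns=X.index
            ),
        )
        return out, params

    batch_means = np.column_stack([V[:, idx[b]].mean(axis=1) for b in levels])
    weights = np.array([sizes[b] / n_total for b in levels])
    stand_mean = batch_means @ weights
    means_per_sample = np.empty_like(V)
    for j, b in enumerate(levels):
        means_per_sample[:, idx[b]] = batch_means[:, [j]]
    # pooled residual variance about batch means, 1/N as in the reference model
    resid = V - means_per_sample
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)

    Z = (V - stand_mean[:, None]) / sd[:, None]

    gamma_rows, delta_rows = [], []
    for b in levels:
        Z_b = Z[:, idx[b]]
        gamma_hat = Z_b.mean(axis=1)
        delta_hat = Z_b.var(axis=1, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1))
        a, bb = _aprior(delta_hat), _bprior(delta_hat)
        gamma_star, delta_star = _posterior_iteration(
            Z_b, gamma_hat, delta_hat, gamma_bar, tau2, a, bb
        )
        gamma_rows.append(gamma_star)
        delta_rows.append(np.maximum(delta_star, 1e-12))

    adjusted = Z.copy()
    for j, b in enumerate(levels):
        adjusted[:, idx[b]] = (Z[:, idx[b]] - gamma_rows[j][:, None]) / np.sqrt(
            delta_rows[j][:, None]
        )
    adjusted = adjusted * sd[:, None] + stand_mean[:, None]
    adjusted = np.clip(adjusted, 0.0, 1.0 - eps)

    out = BetaMatrix(
        pd.DataFrame(adjusted, index=X.index, columns=X.columns),
        rescaled=beta.rescaled,
        batch_adjusted=True,
    )
    params = BatchParameters(
        batches=[str(b) for b in levels],
        gamma_star=pd.DataFrame(np.vstack(gamma_rows), index=levels, columns=X.index),
        delta_star=pd.DataFrame(np.vstack(delta_rows), index=levels, columns=X.index),
    )
    return out, params
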
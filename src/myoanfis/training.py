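"""Hybrid ANFIS learning.

Each epoch alternates the two half-steps of the classic hybrid rule: a
forward pass in which the consequent parameters are solved exactly by linear
least squares (the output is linear in them once the premises are frozen),
and a backward pass in which the premise parameters (Gaussian centers and
widths) take one batch gradient-descent step on the sum of squared errors.

A premise step is only accepted if the post-least-squares error does not
increase; otherwise the learning rate is halved and the step retried
(backtracking). Widths are clamped from below so memberships stay proper.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .fis import SugenoFIS

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainReport",
    "design_matrix",
    "lse_consequents",
    "premise_gradients",
    "hybrid_fit",
]


@dataclass
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 0.01
    min_sigma_frac: float = 1e-4  # lower sigma clamp, as a fraction of each input range
    tolerance: float = 1e-6  # early stop on absolute RMSE change
    min_learning_rate: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.min_sigma_frac <= 0:
            raise ValueError("min_sigma_frac must be positive")


@dataclass
class TrainReport:
    errors: list[float]  # RMSE after the LSE half-step, one per epoch
    fis: SugenoFIS
    converged: bool
    final_learning_rate: float = float("nan")


def design_matrix(fis: SugenoFIS, X: np.ndarray) -> np.ndarray:
    """Regressor matrix of the consequent least-squares problem.

    Row per sample; rule-major columns: first order gives
    ``(wbar_i x_1, .., wbar_i x_n, wbar_i)`` per rule, zero order just
    ``wbar_i``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    W = fis.firing_strengths_batch(X)
    Wbar = W / W.sum(axis=1, keepdims=True)
    n, L, d = len(X), fis.n_rules, fis.n_inputs
    if fis.order == "zero":
        return Wbar
    A = np.empty((n, L * (d + 1)))
    for i in range(L):
        A[:, i * (d + 1) : i * (d + 1) + d] = Wbar[:, [i]] * X
        A[:, i * (d + 1) + d] = Wbar[:, i]
    return A


def lse_consequents(fis: SugenoFIS, X: np.ndarray, y: np.ndarray) -> SugenoFIS:
    """Fit all consequent coefficients by (minimum-norm) least squares.

    Returns a new FIS; the premises are untouched. Rank deficiency falls back
    to the minimum-norm solution with a logged warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    A = design_matrix(fis, X)
    if len(y) != A.shape[0]:
        raise ValueError("X and y length mismatch")
    theta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        logger.warning(
            "rank-deficient consequent solve (rank %d < %d); using minimum-norm solution",
            rank,
            A.shape[1],
        )
    out = copy.deepcopy(fis)
    per_rule = fis.n_inputs + 1 if fis.order == "first" else 1
    for i, rule in enumerate(out.rules):
        rule.consequent = theta[i * per_rule : (i + 1) * per_rule].copy()
    return out


def premise_gradients(
    fis: SugenoFIS, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the SSE w.r.t. every MF center and sigma.

    Returns ``(dC, dS)``, each of shape (n_rules, n_inputs). Derivation: with
    ``gamma = sum_i wbar_i f_i`` and ``w_i`` a product of Gaussians,
    ``d gamma / d log w_i = wbar_i (f_i - gamma)`` and
    ``d log w_i / d c_ij = (x_j - c_ij) / sigma_ij^2``,
    ``d log w_i / d sigma_ij = (x_j - c_ij)^2 / sigma_ij^3``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    W = fis.firing_strengths_batch(X)  # (n, L)
    Wbar = W / W.sum(axis=1, keepdims=True)
    F = fis.rule_outputs_batch(X)  # (n, L)
    gamma = (Wbar * F).sum(axis=1)  # (n,)
    resid = gamma - y  # (n,)

    # per-sample sensitivity to log w_i
    S_log = Wbar * (F - gamma[:, None])  # (n, L)
    coef = 2.0 * resid[:, None] * S_log  # (n, L)

    C, Sig = fis.centers, fis.sigmas  # (L, d)
    diff = X[:, None, :] - C[None]  # (n, L, d)
    dC = np.einsum("nl,nld->ld", coef, diff / Sig[None] ** 2)
    dS = np.einsum("nl,nld->ld", coef, diff**2 / Sig[None] ** 3)
    return dC, dS


def _rmse(fis: SugenoFIS, X: np.ndarray, y: np.ndarray) -> float:
    r = fis.evaluate_batch(X) - np.asarray(y, dtype=float).ravel()
    return float(np.sqrt(np.mean(r**2)))


def hybrid_fit(
    fis: SugenoFIS, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None
) -> TrainReport:
    """Train premises and consequents by the hybrid LSE/gradient scheme.

    The reported per-epoch error is the training RMSE immediately after the
    consequent least-squares solve, so the sequence is non-increasing as long
    as premise steps keep being accepted. Training stops at ``epochs``, when
    the error change falls below ``tolerance``, or — with ``converged=False``
    — when backtracking pushes the learning rate below its floor.
    """
    cfg = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    ranges = X.max(axis=0) - X.min(axis=0)
    min_sigma = cfg.min_sigma_frac * np.where(ranges > 0, ranges, 1.0)

    current = lse_consequents(fis, X, y)
    errors = [_rmse(current, X, y)]
    lr = cfg.learning_rate
    converged = False

    if errors[0] < 1e-12:
        return TrainReport(errors=errors, fis=current, converged=True, final_learning_rate=lr)

    for _ in range(1, cfg.epochs):
        dC, dS = premise_gradients(current, X, y)
        gnorm = np.sqrt((dC**2).sum() + (dS**2).sum())
        if gnorm < 1e-14:  # stationary premises: LSE already optimal
            converged = True
            break
        accepted = False
        while lr >= cfg.min_learning_rate:
            cand = copy.deepcopy(current)
            new_sig = np.maximum(current.sigmas - lr * dS, min_sigma[None, :])
            cand.set_premises(current.centers - lr * dC, new_sig)
            cand = lse_consequents(cand, X, y)
            err = _rmse(cand, X, y)
            if err <= errors[-1] + 1e-15:
                current = cand
                errors.append(err)
                accepted = True
                break
            lr *= 0.5
            logger.debug("premise step rejected; learning rate halved to %g", lr)
        if not accepted:
            logger.warning("learning rate fell below %g; stopping", cfg.min_learning_rate)
            return TrainReport(
                errors=errors, fis=current, converged=False, final_learning_rate=lr
            )
        if len(errors) >= 2 and abs(errors[-2] - errors[-1]) < cfg.tolerance:
            converged = True
            break

    return TrainReport(errors=errors, fis=current, converged=converged, final_learning_rate=lr)
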
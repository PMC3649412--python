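"""Sugeno fuzzy inference system with Gaussian premises — the ANFIS forward
pass — plus construction of an initial rule base from subtractive-clustering
centers.

A rule ``i`` over inputs ``x = (x_1 .. x_n)`` fires with strength
``w_i = prod_j mu_ij(x_j)`` where ``mu_ij`` is a Gaussian membership function;
the crisp output is the normalized-firing-strength weighted average of the
rule consequents ``f_i`` (a constant for a zero-order model, an affine
function of the inputs for first order):

    gamma = sum_i wbar_i f_i(x),   wbar_i = w_i / sum_k w_k
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GaussianMF",
    "FuzzyRule",
    "SugenoFIS",
    "mf_eval",
    "firing_strengths",
    "normalize_strengths",
    "rule_consequent",
    "evaluate",
    "build_initial_fis",
]


@dataclass
class GaussianMF:
    """Gaussian membership function exp(-(x-c)^2 / (2 sigma^2))."""

    center: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def __call__(self, x):
        return np.exp(-((np.asarray(x, dtype=float) - self.center) ** 2) / (2.0 * self.sigma**2))


@dataclass
class FuzzyRule:
    """One Sugeno rule: a Gaussian premise per input plus consequent coefficients.

    First-order consequent coefficients are ``(p_1 .. p_n, s)`` so that
    ``f = p . x + s``; a zero-order consequent is the single constant ``(s,)``.
    """

    premises: list[GaussianMF]
    consequent: np.ndarray

    def __post_init__(self) -> None:
        self.consequent = np.asarray(self.consequent, dtype=float).ravel()


@dataclass
class SugenoFIS:
    rules: list[FuzzyRule]
    order: str = "first"  # 'zero' | 'first'
    input_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("a FIS needs at least one rule")
        if self.order not in ("zero", "first"):
            raise ValueError("order must be 'zero' or 'first'")
        n = len(self.rules[0].premises)
        expected = n + 1 if self.order == "first" else 1
        for r in self.rules:
            if len(r.premises) != n:
                raise ValueError("all rules must share the input dimension")
            if len(r.consequent) != expected:
                raise ValueError(
                    f"{self.order}-order consequent must have {expected} coefficients"
                )
        if not self.input_names:
            self.input_names = [f"x{i}" for i in range(n)]
        if len(self.input_names) != n:
            raise ValueError("input_names length mismatch")

    @property
    def n_inputs(self) -> int:
        return len(self.rules[0].premises)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    # -- parameter views (L rules x d inputs), shared by trainer and forward pass
    @property
    def centers(self) -> np.ndarray:
        return np.array([[mf.center for mf in r.premises] for r in self.rules])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([[mf.sigma for mf in r.premises] for r in self.rules])

    def set_premises(self, centers: np.ndarray, sigmas: np.ndarray) -> None:
        for i, r in enumerate(self.rules):
            for j, mf in enumerate(r.premises):
                mf.center = float(centers[i, j])
                mf.sigma = float(sigmas[i, j])
                if mf.sigma <= 0:
                    raise ValueError("sigma must stay positive")

    def consequent_matrix(self) -> np.ndarray:
        return np.array([r.consequent for r in self.rules])

    def firing_strengths_batch(self, X: np.ndarray) -> np.ndarray:
        """Rule firing strengths for a batch: shape (n_samples, n_rules)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {X.shape[1]}")
        z = (X[:, None, :] - self.centers[None]) / self.sigmas[None]
        return np.exp(-0.5 * (z**2).sum(axis=2))

    def rule_outputs_batch(self, X: np.ndarray) -> np.ndarray:
        """Per-rule consequent values f_i(x): shape (n_samples, n_rules)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        C = self.consequent_matrix()
        if self.order == "zero":
            return np.broadcast_to(C[:, 0], (len(X), self.n_rules)).copy()
        return X @ C[:, :-1].T + C[:, -1]

    def evaluate_batch(self, X: np.ndarray) -> np.ndarray:
        W = self.firing_strengths_batch(X)
        Wbar = W / W.sum(axis=1, keepdims=True)
        return (Wbar * self.rule_outputs_batch(X)).sum(axis=1)

    def evaluate(self, x: np.ndarray) -> float:
        return float(self.evaluate_batch(np.atleast_2d(x))[0])

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_inputs": self.n_inputs,
            "order": self.order,
            "input_names": self.input_names,
            "rules": [
                {
                    "premise": [
                        {"center": mf.center, "sigma": mf.sigma} for mf in r.premises
                    ],
                    "consequent": r.consequent.tolist(),
                }
                for r in self.rules
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SugenoFIS":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        rules = [
            FuzzyRule(
                premises=[GaussianMF(m["center"], m["sigma"]) for m in r["premise"]],
                consequent=np.asarray(r["consequent"], dtype=float),
            )
            for r in d["rules"]
        ]
        return cls(rules=rules, order=d["order"], input_names=list(d["input_names"]))


# -- functional surface ----------------------------------------------------

def mf_eval(mf: GaussianMF, x) -> float | np.ndarray:
    """Membership degree of ``x`` in the Gaussian fuzzy set."""
    out = mf(x)
    return float(out) if np.isscalar(x) else out


def firing_strengths(fis: SugenoFIS, x: np.ndarray) -> np.ndarray:
    """Per-rule firing strength (product of premise memberships) at one input."""
    return fis.firing_strengths_batch(np.atleast_2d(x))[0]


def normalize_strengths(w: np.ndarray) -> np.ndarray:
    """Normalized firing strengths wbar_i = w_i / sum_j w_j."""
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("all firing strengths are zero; cannot normalize")
    return w / total


def rule_consequent(rule: FuzzyRule, x: np.ndarray, order: str = "first") -> float:
    """Consequent value f(x) of a single rule."""
    x = np.asarray(x, dtype=float).ravel()
    if order == "zero":
        return float(rule.consequent[0])
    if len(rule.consequent) != len(x) + 1:
        raise ValueError("consequent/input dimension mismatch")
    return float(rule.consequent[:-1] @ x + rule.consequent[-1])


def evaluate(fis: SugenoFIS, x: np.ndarray) -> float:
    """Crisp FIS output gamma at one input vector."""
    return fis.evaluate(x)


def build_initial_fis(
    cluster_result,
    order: str = "first",
    data: np.ndarray | None = None,
    input_names: list[str] | None = None,
) -> SugenoFIS:
    """Seed one rule per cluster center.

    Premise MF ``j`` of rule ``i`` is Gaussian with center ``center_i[j]`` and
    width ``ra * range_j / sqrt(8)`` where ``range_j`` is the spread of
    dimension ``j`` (from the clustering normalization bounds, or from
    ``data`` if provided). Consequents start at zero and are fitted by least
    squares during training.
    """
    centers = np.atleast_2d(np.asarray(cluster_result.centers, dtype=float))
    if centers.size == 0:
        raise ValueError("need at least one cluster center")
    d = centers.shape[1]
    if data is not None:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        ranges = data.max(axis=0) - data.min(axis=0)
    else:
        ranges = cluster_result.bounds[:, 1] - cluster_result.bounds[:, 0]
    ra = cluster_result.config.ra
    sigmas = ra * np.where(ranges > 0, ranges, 1.0) / np.sqrt(8.0)

    n_cons = d + 1 if order == "first" else 1
    rules = [
        FuzzyRule(
            premises=[GaussianMF(float(c[j]), float(sigmas[j])) for j in range(d)],
            consequent=np.zeros(n_cons),
        )
        for c in centers
    ]
    return SugenoFIS(rules=rules, order=order, input_names=input_names or [])
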
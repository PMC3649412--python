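"""Subtractive clustering (Chiu 1994) for fuzzy-rule seeding.

Every data point is a candidate cluster center. Points are min-max normalized
to the unit hypercube; the density (potential) of point ``x_i`` is

    D_i = sum_j exp(-||x_i - x_j||^2 / (r_a / 2)^2)

The maximum-density point becomes the first center; each selection subtracts
its influence with the wider squash radius ``r_b``:

    D_i <- D_i - D_c * exp(-||x_i - x_c||^2 / (r_b / 2)^2)

and selection repeats until the accept/reject criteria (fractions of the
first center's density, plus Chiu's in-between distance test) or an optional
``max_clusters`` cap stop it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "normalize_hypercube",
    "denormalize",
    "density",
    "revise_density",
    "cluster",
]


@dataclass
class ClusterConfig:
    """Radii and stopping criteria, all in normalized hypercube units.

    ``ra`` is the neighbourhood radius of the density measure; ``rb``
    (default 1.5 * ra) is the larger squash radius so neighbouring centers
    stay apart. A candidate with density above ``accept_ratio`` times the
    first center's density is always accepted; below ``reject_ratio`` it is
    rejected and selection stops; in between, it is accepted only if
    ``d_min/ra + D/D1 >= 1`` where ``d_min`` is its distance to the nearest
    existing center.
    """

    ra: float = 0.5
    rb: float | None = None  # None -> 1.5 * ra
    accept_ratio: float = 0.5
    reject_ratio: float = 0.15
    max_clusters: int | None = None

    def __post_init__(self) -> None:
        if self.ra <= 0:
            raise ValueError("ra must be positive")
        if self.rb is None:
            self.rb = 1.5 * self.ra
        if self.rb <= self.ra:
            raise ValueError("rb must exceed ra")
        if not 0 < self.reject_ratio < self.accept_ratio <= 1:
            raise ValueError("need 0 < reject_ratio < accept_ratio <= 1")


@dataclass
class ClusterResult:
    """Selected centers in original units, with their selection-time densities
    and the per-dimension (min, max) bounds of the hypercube normalization."""

    centers: np.ndarray  # (k, d), original units
    densities: np.ndarray  # (k,)
    bounds: np.ndarray  # (d, 2) columns (min, max)
    config: ClusterConfig = field(default_factory=ClusterConfig)

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def normalized_centers(self) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        out = (self.centers - lo) / span
        return np.where(self.bounds[:, 1] > self.bounds[:, 0], out, 0.5)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "centers": np.asarray(self.centers).tolist(),
            "densities": np.asarray(self.densities).tolist(),
            "bounds": np.asarray(self.bounds).tolist(),
            "config": {
                "ra": self.config.ra,
                "rb": self.config.rb,
                "accept_ratio": self.config.accept_ratio,
                "reject_ratio": self.config.reject_ratio,
                "max_clusters": self.config.max_clusters,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ClusterResult":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            densities=np.asarray(d["densities"], dtype=float),
            bounds=np.asarray(d["bounds"], dtype=float),
            config=ClusterConfig(**d["config"]),
        )


def normalize_hypercube(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-max map each dimension onto [0, 1]; constant dimensions map to 0.5.

    Returns ``(normalized, bounds)`` with bounds of shape (d, 2).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one point")
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = hi - lo
    out = np.where(span > 0, (pts - lo) / np.where(span > 0, span, 1.0), 0.5)
    return out, np.stack([lo, hi], axis=1)


def denormalize(points: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_hypercube` (constant dims return their value)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    return np.where(span > 0, lo + pts * span, lo)


def density(points: np.ndarray, ra: float) -> np.ndarray:
    """Density (potential) of every point among its neighbours."""
    if ra <= 0:
        raise ValueError("ra must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    sq = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-sq / (ra / 2.0) ** 2).sum(axis=1)


def revise_density(
    densities: np.ndarray,
    points: np.ndarray,
    center: np.ndarray,
    center_density: float,
    rb: float,
) -> np.ndarray:
    """Subtract the selected center's influence from every point's density."""
    if rb <= 0:
        raise ValueError("rb must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    sq = ((pts - np.asarray(center, dtype=float)) ** 2).sum(axis=1)
    return np.asarray(densities, dtype=float) - center_density * np.exp(-sq / (rb / 2.0) ** 2)


def cluster(points: np.ndarray, config: ClusterConfig | None = None) -> ClusterResult:
    """Run the full subtractive-clustering selection loop.

    Ties at equal density break toward the lowest original point index, so the
    result is invariant to input ordering up to that tie rule.
    """
    cfg = config or ClusterConfig()
    pts_raw = np.atleast_2d(np.asarray(points, dtype=float))
    norm, bounds = normalize_hypercube(pts_raw)

    d = density(norm, cfg.ra)
    live = d.copy()
    centers_n: list[np.ndarray] = []
    densities: list[float] = []
    excluded = np.zeros(len(norm), dtype=bool)  # failed the distance test

    first_density: float | None = None
    while True:
        if cfg.max_clusters is not None and len(centers_n) >= cfg.max_clusters:
            break
        cand = np.where(~excluded, live, -np.inf)
        i = int(np.argmax(cand))
        di = cand[i]
        if not np.isfinite(di) or di <= 0:
            break
        if first_density is None:
            accept = True  # global density maximizer is always the first center
        elif di > cfg.accept_ratio * first_density:
            accept = True
        elif di < cfg.reject_ratio * first_density:
            break
        else:
            dmin = min(float(np.linalg.norm(norm[i] - c)) for c in centers_n)
            if dmin / cfg.ra + di / first_density >= 1.0:
                accept = True
            else:
                excluded[i] = True
                continue
        if accept:
            centers_n.append(norm[i].copy())
            densities.append(float(di))
            if first_density is None:
                first_density = float(di)
            live = revise_density(live, norm, norm[i], float(di), cfg.rb)
            excluded[:] = False
            live[i] = -np.inf  # a center is never reselected

    centers = denormalize(np.asarray(centers_n), bounds)
    return ClusterResult(
        centers=centers,
        densities=np.asarray(densities, dtype=float),
        bounds=bounds,
        config=cfg,
    )
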
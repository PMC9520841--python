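"""Generalized Procrustes analysis for 2-D landmark configurations.

Superimposition removes translation (centering), scale (unit centroid size)
and orientation (least-squares rotation, determinant +1 — reflections are
never applied) and yields a consensus shape, per-specimen full Procrustes
distances and tangent-space coordinates for multivariate statistics.

Conventions follow the classical landmark-morphometrics workflow:
configurations stay at unit centroid size during the iterations and are
only rotated toward the running consensus (partial-Procrustes alignment of
unit-size pre-shapes); distances between shapes are full Procrustes
distances, computed in closed form from planar complex coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tps import Configuration

__all__ = [
    "ShapeDataset",
    "GPAResult",
    "AlignmentResult",
    "DegenerateShapeError",
    "centroid_size",
    "align_pair",
    "gpa",
    "tangent_project",
    "procrustes_distance_matrix",
]

logger = logging.getLogger(__name__)


class DegenerateShapeError(ValueError):
    """Raised for configurations whose points are all coincident."""


@dataclass
class ShapeDataset:
    """n point configurations with identical landmark count plus specimen labels."""

    configurations: np.ndarray  # (n, p, 2)
    labels: pd.DataFrame  # index aligned with configurations; columns e.g. sex, species

    def __post_init__(self) -> None:
        self.configurations = np.asarray(self.configurations, dtype=float)
        if self.configurations.ndim != 3 or self.configurations.shape[2] != 2:
            raise ValueError("configurations must be an (n, p, 2) array")
        if len(self.configurations) < 2:
            raise ValueError("a shape dataset needs n >= 2 specimens")
        if len(self.labels) != len(self.configurations):
            raise ValueError("labels must have one row per configuration")

    @classmethod
    def from_configurations(
        cls, configs: Sequence[Configuration], labels: pd.DataFrame
    ) -> "ShapeDataset":
        ps = {c.p for c in configs}
        if len(ps) != 1:
            raise ValueError(f"all configurations must share one landmark count, got {sorted(ps)}")
        arr = np.stack([c.points for c in configs])
        return cls(configurations=arr, labels=labels.reset_index(drop=True))

    @property
    def n(self) -> int:
        return self.configurations.shape[0]

    @property
    def p(self) -> int:
        return self.configurations.shape[1]


@dataclass
class AlignmentResult:
    """Similarity transform of B onto A plus the full Procrustes distance."""

    rotation: float  # radians, counter-clockwise
    scale: float
    translation: np.ndarray  # (2,)
    distance: float


@dataclass
class GPAResult:
    aligned: np.ndarray  # (n, p, 2) unit-size, centered, rotated to consensus
    consensus: np.ndarray  # (p, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,) original sizes
    procrustes_to_mean: np.ndarray  # (n,) full Procrustes distance to consensus
    tangent: np.ndarray = field(default=None)  # (n, 2p) filled by tangent_project
    iterations: int = 0
    converged: bool = True

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def p(self) -> int:
        return self.aligned.shape[1]


def centroid_size(config: Configuration | np.ndarray) -> float:
    """Square root of the summed squared deviations of all coordinates from the centroid."""
    pts = config.points if isinstance(config, Configuration) else np.asarray(config, dtype=float)
    if len(pts) < 2:
        raise ValueError("centroid size needs p >= 2 points")
    dev = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(dev**2)))
    if cs == 0.0:
        raise DegenerateShapeError("all points coincide; centroid size is zero")
    return cs


def _preshape(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center and scale to unit centroid size; return (preshape, centroid, size)."""
    centroid = pts.mean(axis=0)
    dev = pts - centroid
    cs = float(np.sqrt(np.sum(dev**2)))
    if cs == 0.0:
        raise DegenerateShapeError("degenerate configuration (zero centroid size)")
    return dev / cs, centroid, cs


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) maximising trace((RB)^T A) for centered 2-D configs."""
    H = B.T @ A
    # planar closed form: R = [[c, -s], [s, c]] with angle atan2 of the
    # skew/symmetric parts of H
    a = H[0, 0] + H[1, 1]
    b = H[0, 1] - H[1, 0]
    theta = np.arctan2(b, a)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def align_pair(A: Configuration | np.ndarray, B: Configuration | np.ndarray) -> AlignmentResult:
    """Optimal similarity superimposition of B onto A (rotation + scale + translation).

    Both configurations are first centered and scaled to unit centroid
    size; the returned scale includes the extra least-squares shrink factor
    of the full Procrustes fit, and ``distance`` is the minimised
    root-sum-of-squares, i.e. the full Procrustes distance.  Reflections
    are excluded (rotation determinant +1).
    """
    Apts = A.points if isinstance(A, Configuration) else np.asarray(A, dtype=float)
    Bpts = B.points if isinstance(B, Configuration) else np.asarray(B, dtype=float)
    if Apts.shape != Bpts.shape:
        raise ValueError(f"configurations differ in shape: {Apts.shape} vs {Bpts.shape}")
    Za, cent_a, cs_a = _preshape(Apts)
    Zb, cent_b, cs_b = _preshape(Bpts)
    R = _optimal_rotation(Za, Zb)
    rotated = Zb @ R.T
    beta = float(np.sum(rotated * Za))  # least-squares scale; = |<za, zb>| in C
    dist_sq = max(0.0, 1.0 - beta**2)
    theta = float(np.arctan2(R[1, 0], R[0, 0]))
    full_scale = beta * cs_a / cs_b
    translation = cent_a - full_scale * (cent_b @ R.T)
    return AlignmentResult(
        rotation=theta,
        scale=full_scale,
        translation=translation,
        distance=float(np.sqrt(dist_sq)),
    )


def gpa(dataset: ShapeDataset, *, tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Iterative generalized Procrustes superimposition.

    All configurations are centered and fixed at unit centroid size, then
    repeatedly rotated to the running consensus; the consensus is the
    coordinate-wise mean renormalised to unit centroid size.  Iteration
    stops when the consensus moves by less than ``tol`` (root sum of
    squares) or after ``max_iter`` rounds (``converged=False`` with a
    logged warning).  Tangent coordinates are filled in via
    :func:`tangent_project`.
    """
    X = dataset.configurations
    n = len(X)
    pre = np.empty_like(X)
    sizes = np.empty(n)
    for i in range(n):
        pre[i], _, sizes[i] = _preshape(X[i])
    consensus = pre[0].copy()
    aligned = pre.copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            R = _optimal_rotation(consensus, pre[i])
            aligned[i] = pre[i] @ R.T
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        # anchor the consensus orientation to the previous one so the
        # movement criterion measures shape change, not drift
        move = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if move < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)
    for i in range(n):
        R = _optimal_rotation(consensus, pre[i])
        aligned[i] = pre[i] @ R.T
    # stable full-Procrustes distance: with r = z_aligned - consensus,
    # |r|^2 = 2 - 2 beta exactly, and d^2 = (1 - beta)(1 + beta)
    resid_sq = np.sum((aligned - consensus) ** 2, axis=(1, 2))
    beta = 1.0 - resid_sq / 2.0
    proc_dist = np.sqrt(resid_sq / 2.0 * np.clip(1.0 + beta, 0.0, None))
    result = GPAResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        procrustes_to_mean=proc_dist,
        iterations=iterations,
        converged=converged,
    )
    result.tangent = tangent_project(result)
    return result


def tangent_project(result: GPAResult) -> np.ndarray:
    """Orthogonal projection of aligned pre-shapes onto the tangent space at the consensus.

    Flattened aligned coordinates have their component along the (unit)
    consensus vector removed: ``t_i = x_i - (x_i . c) c``.  Because the
    aligned shapes are centered, unit-size and rotationally aligned to the
    consensus, the resulting n x 2p matrix has rank at most 2p - 4.
    """
    n, p = result.n, result.p
    c = result.consensus.reshape(-1)
    X = result.aligned.reshape(n, 2 * p)
    coef = X @ c
    return X - np.outer(coef, c)


def procrustes_distance_matrix(result: GPAResult) -> np.ndarray:
    """Pairwise full Procrustes distances between all specimens.

    Uses the planar complex-coordinate closed form
    ``d(z, w) = sqrt(1 - |<z, w>|^2)`` for unit-norm centered pre-shapes,
    which equals the pairwise :func:`align_pair` distance.
    """
    Z = result.aligned[..., 0] + 1j * result.aligned[..., 1]  # (n, p)
    G = Z @ Z.conj().T
    mag = np.abs(G)
    # rotate z_i onto z_j and take the residual norm: numerically stable for
    # near-identical shapes where 1 - |g|^2 cancels catastrophically
    with np.errstate(invalid="ignore", divide="ignore"):
        ghat = np.where(mag > 0, np.conj(G) / np.where(mag > 0, mag, 1.0), 1.0)
    R = Z[:, None, :] * ghat[:, :, None] - Z[None, :, :]
    resid_sq = np.sum(np.abs(R) ** 2, axis=2)  # = 2 - 2|g|
    D = np.sqrt(resid_sq / 2.0 * np.clip(1.0 + mag, 0.0, None))
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0
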
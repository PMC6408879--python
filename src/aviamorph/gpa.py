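"""Generalized Procrustes analysis (GPA) and centroid size.

Shape is what remains of a landmark configuration after position,
orientation and scale are removed. GPA does this jointly for a sample:
every configuration is centred, scaled to unit centroid size, and
iteratively rotated to the evolving sample mean until the mean stops
moving. The aligned coordinates, flattened to an ``N x 3L`` matrix, are
the trait matrix consumed by all downstream statistics.

Rotations are proper (determinant +1): a reflection is never introduced
by alignment, so chiral shapes stay chiral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from aviamorph.io import LandmarkConfiguration, ModulePartition


@dataclass
class ShapeDataset:
    """Ordered stack of specimen landmark configurations.

    After alignment each configuration is centred at the origin and has
    unit centroid size; ``centroid_sizes`` records the sizes of the
    original (pre-alignment) configurations, in their original units.
    """

    taxa: list[str]
    coords: np.ndarray                       # (N, L, 3)
    centroid_sizes: np.ndarray | None = None # (N,), original units
    is_aligned: bool = False
    landmark_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (N, L, 3), got {self.coords.shape}")
        if len(self.taxa) != self.coords.shape[0]:
            raise ValueError("taxa / coords length mismatch")
        if self.is_aligned:
            self.validate_aligned()

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def flatten(self) -> np.ndarray:
        """The trait matrix Y: (N, 3L), rows ordered as ``taxa``."""
        return self.coords.reshape(self.n_specimens, -1)

    def validate_aligned(self, tol: float = 1e-9) -> None:
        centroids = self.coords.mean(axis=1)
        if np.abs(centroids).max() >= tol:
            raise ValueError("aligned dataset has off-origin centroid(s)")
        sizes = np.sqrt((self.coords ** 2).sum(axis=(1, 2)))
        if np.abs(sizes - 1.0).max() >= tol:
            raise ValueError("aligned dataset has non-unit centroid size(s)")

    def configuration(self, i: int) -> LandmarkConfiguration:
        return LandmarkConfiguration(self.taxa[i], self.coords[i], self.landmark_labels)

    @classmethod
    def from_configurations(cls, configs: Sequence[LandmarkConfiguration]) -> "ShapeDataset":
        counts = {c.n_landmarks for c in configs}
        if len(counts) != 1:
            raise ValueError(f"landmark counts differ: {sorted(counts)}")
        return cls(
            taxa=[c.specimen_id for c in configs],
            coords=np.stack([c.coords for c in configs]),
            landmark_labels=configs[0].landmark_labels,
        )


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    size = float(np.sqrt((centred ** 2).sum()))
    if size == 0.0:
        raise ValueError("all landmarks coincide: centroid size is zero, cannot scale")
    return size


def _optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||moving @ R - target||_F.

    If the optimum would be a reflection, the singular direction with the
    smallest singular value is flipped (deterministic tie-break); a warning
    is emitted when that direction is degenerate (singular value ~ 0 twice
    over), since the optimum is then ambiguous.
    """
    H = moving.T @ target
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if d < 0 and s[-1] < 1e-12 * max(s[0], 1.0) and s.size > 1 and s[-2] < 1e-12 * max(s[0], 1.0):
        warnings.warn("degenerate configuration: optimal rotation is ambiguous", stacklevel=2)
    D = np.diag([1.0] * (len(s) - 1) + [d if d != 0 else 1.0])
    return U @ D @ Vt


def align_pair(
    moving: LandmarkConfiguration | np.ndarray,
    target: LandmarkConfiguration | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotate ``moving`` onto ``target`` (both centred, unit centroid size).

    Returns ``(rotated_coords, rotation, procrustes_distance)`` where the
    rotation is proper and the distance is the root summed squared
    difference after alignment.
    """
    m = moving.coords if isinstance(moving, LandmarkConfiguration) else np.asarray(moving, float)
    t = target.coords if isinstance(target, LandmarkConfiguration) else np.asarray(target, float)
    if m.shape != t.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {t.shape}")
    R = _optimal_rotation(m, t)
    rotated = m @ R
    distance = float(np.sqrt(((rotated - t) ** 2).sum()))
    return rotated, R, distance


@dataclass
class GPAResult:
    """Aligned dataset, consensus shape and convergence diagnostics."""

    dataset: ShapeDataset
    mean_shape: np.ndarray                   # (L, 3), unit centroid size
    n_iterations: int
    objective_history: list[float] = field(default_factory=list)
    # objective: sum over specimens of squared Procrustes distance to the mean


def gpa(
    configs: Sequence[LandmarkConfiguration] | ShapeDataset,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> GPAResult:
    """Generalized Procrustes analysis of a landmark sample.

    Each configuration is centred and scaled to unit centroid size, then
    repeatedly rotated to the current consensus; the consensus (itself
    rescaled to unit centroid size) is recomputed until its change (root
    summed squared difference) falls below ``tol``.
    """
    if isinstance(configs, ShapeDataset):
        dataset = configs
    else:
        dataset = ShapeDataset.from_configurations(list(configs))
    if dataset.n_specimens < 2:
        raise ValueError("GPA needs at least 2 configurations")

    coords = dataset.coords - dataset.coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((coords ** 2).sum(axis=(1, 2)))
    if np.any(sizes == 0):
        bad = [dataset.taxa[i] for i in np.flatnonzero(sizes == 0)]
        raise ValueError(f"zero centroid size (all landmarks coincide): {bad}")
    coords = coords / sizes[:, None, None]

    # Order-independent initial consensus: the plain average of the centred,
    # scaled configurations. Falls back to the first configuration if random
    # orientations cancel it out.
    mean = coords.mean(axis=0)
    if np.sqrt((mean ** 2).sum()) < 1e-6:
        mean = coords[0].copy()
    mean = mean / np.sqrt((mean ** 2).sum())

    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(coords.shape[0]):
            coords[i] = coords[i] @ _optimal_rotation(coords[i], mean)
        history.append(float(((coords - mean) ** 2).sum()))
        new_mean = coords.mean(axis=0)
        new_mean = new_mean / np.sqrt((new_mean ** 2).sum())
        # anchor the consensus orientation to the previous consensus: the
        # mean-change criterion then measures shape change only, not the
        # slow rotational drift of an unanchored average
        new_mean = new_mean @ _optimal_rotation(new_mean, mean)
        change = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last mean change {change:.3e})"
        )

    aligned = ShapeDataset(
        taxa=list(dataset.taxa),
        coords=coords,
        centroid_sizes=sizes,
        is_aligned=True,
        landmark_labels=dataset.landmark_labels,
    )
    return GPAResult(aligned, mean, n_iter, history)


def subset_module(
    aligned: ShapeDataset, partition: ModulePartition, module: str
) -> ShapeDataset:
    """Extract one module's landmarks from the whole-configuration alignment.

    No re-superimposition is performed: module coordinates are taken
    directly from the joint alignment, so the block is generally neither
    centred nor unit-size on its own (``is_aligned`` is False).
    """
    partition.validate_landmark_count(aligned.n_landmarks)
    idx = partition.indices(module)          # KeyError lists valid names
    labels = None
    if aligned.landmark_labels is not None:
        labels = tuple(aligned.landmark_labels[i] for i in idx)
    return ShapeDataset(
        taxa=list(aligned.taxa),
        coords=aligned.coords[:, idx, :],
        centroid_sizes=aligned.centroid_sizes,
        is_aligned=False,
        landmark_labels=labels,
    )
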
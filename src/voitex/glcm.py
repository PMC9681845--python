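"""Gray-level quantization and isotropic 3-D co-occurrence matrices.

A VOI's intensities are linearly binned to ``Ng`` gray levels (per-VOI
min-max, default 128) and pairs of levels separated by a fixed voxel
distance are counted over all 13 unique 3-D directions simultaneously
("isotropically"): the 26-neighborhood has 13 antipodal direction pairs, and
symmetric counting makes the two members of a pair equivalent. One matrix is
produced per distance (default distances 1-5 voxels), each normalized to sum
to one.

Conventions (declared, since the field is not unanimous):

* gray levels are 1-based, ``i in [1, Ng]``, so sum average ranges over
  ``[2, 2*Ng]``;
* diagonal offsets scale as ``d * u`` (Chebyshev distance), so "distance 2"
  along a body diagonal is the offset ``(2, 2, 2)``;
* offsets live in index space — anisotropic voxel spacing is deliberately
  ignored, distances are counted in voxels;
* counting is symmetric: each co-occurring pair contributes to ``(i, j)``
  and ``(j, i)``, and directions are pooled into a single matrix per
  distance, never averaged per-direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import VoxelSet

__all__ = [
    "QuantizationSpec",
    "QuantizedVOI",
    "GLCMSet",
    "DEFAULT_N_LEVELS",
    "DEFAULT_DISTANCES",
    "quantize",
    "direction_set",
    "accumulate_glcm",
    "glcm_all_distances",
]

DEFAULT_N_LEVELS = 128
DEFAULT_DISTANCES = (1, 2, 3, 4, 5)

# The 13 direction generators of the 26-neighborhood, one per antipodal
# pair, in fixed order: 3 axes, 6 face diagonals, 4 body diagonals.
_DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


def direction_set() -> list[tuple[int, int, int]]:
    """The 13 unique 3-D direction generators (one per antipodal pair)."""
    return list(_DIRECTIONS)


@dataclass(frozen=True)
class QuantizationSpec:
    """How to bin VOI intensities into gray levels.

    ``policy`` is per-VOI linear min-max binning (the only policy): MRI
    intensities carry no absolute calibration, so levels are relative to
    each VOI's own range.
    """

    n_levels: int = DEFAULT_N_LEVELS
    policy: str = "voi_min_max"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.policy != "voi_min_max":
            raise ValueError(f"unknown quantization policy {self.policy!r}")


@dataclass
class QuantizedVOI:
    """VOI voxels with intensities replaced by 1-based gray levels."""

    coordinates: np.ndarray
    levels: np.ndarray  # ints in [1, n_levels]
    n_levels: int
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if len(self.levels) and (
            self.levels.min() < 1 or self.levels.max() > self.n_levels
        ):
            raise ValueError("levels out of range [1, n_levels]")

    def __len__(self) -> int:
        return len(self.levels)

    def dense(self) -> np.ndarray:
        """Level volume with 0 marking voxels outside the VOI."""
        vol = np.zeros(self.grid_shape, dtype=np.int64)
        vol[tuple(self.coordinates.T)] = self.levels
        return vol


@dataclass
class GLCMSet:
    """Normalized symmetric co-occurrence matrices keyed by distance.

    ``matrices[d]`` is an ``Ng x Ng`` matrix summing to 1 whenever
    ``pair_counts[d] > 0``; a distance at which the VOI admits no
    co-occurring pair is degenerate (all-zero matrix, pair count 0) — data,
    not an error.
    """

    distances: tuple[int, ...]
    matrices: dict[int, np.ndarray]
    pair_counts: dict[int, int]
    n_levels: int = DEFAULT_N_LEVELS

    def label(self, distance: int) -> str:
        return f"q{self.distances.index(distance) + 1}"

    @property
    def labels(self) -> list[str]:
        return [f"q{i + 1}" for i in range(len(self.distances))]

    def degenerate(self, distance: int) -> bool:
        return self.pair_counts[distance] == 0

    def to_csv(self, distance: int, path: str | Path) -> None:
        """Headerless Ng-row CSV of one matrix."""
        np.savetxt(path, self.matrices[distance], delimiter=",", fmt="%.12g")

    def sidecar(self, distance: int) -> dict:
        return {
            "distance": int(distance),
            "label": self.label(distance),
            "n_levels": int(self.n_levels),
            "pair_count": int(self.pair_counts[distance]),
            "degenerate": self.degenerate(distance),
        }

    def write_sidecar(self, distance: int, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sidecar(distance), indent=1))


def quantize(voi: VoxelSet, spec: QuantizationSpec | None = None) -> QuantizedVOI:
    """Linearly bin VOI intensities into 1-based gray levels.

    ``level = floor((x - min) / (max - min) * Ng) + 1`` clamped to
    ``[1, Ng]``; a degenerate range (``max == min``) maps every voxel to
    level 1.
    """
    if spec is None:
        spec = QuantizationSpec()
    if len(voi) == 0:
        raise ValueError("cannot quantize an empty VOI")
    x = np.asarray(voi.values, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        levels = np.ones(len(x), dtype=np.int64)
    else:
        levels = np.floor((x - lo) / (hi - lo) * spec.n_levels).astype(np.int64) + 1
        np.clip(levels, 1, spec.n_levels, out=levels)
    return QuantizedVOI(
        coordinates=voi.coordinates,
        levels=levels,
        n_levels=spec.n_levels,
        grid_shape=voi.grid_shape,
    )


def _accumulate_dense(level_vol: np.ndarray, n_levels: int, distance: int):
    counts = np.zeros(n_levels * n_levels, dtype=np.int64)
    shape = level_vol.shape
    for u in _DIRECTIONS:
        off = tuple(distance * c for c in u)
        src = []
        dst = []
        ok = True
        for axis, o in enumerate(off):
            n = shape[axis]
            if abs(o) >= n:
                ok = False
                break
            if o >= 0:
                src.append(slice(0, n - o))
                dst.append(slice(o, n))
            else:
                src.append(slice(-o, n))
                dst.append(slice(0, n + o))
        if not ok:
            continue
        a = level_vol[tuple(src)]
        b = level_vol[tuple(dst)]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        pair_idx = (a[valid] - 1) * n_levels + (b[valid] - 1)
        counts += np.bincount(pair_idx, minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(np.float64)
    mat = mat + mat.T  # symmetric counting: each pair feeds (i,j) and (j,i)
    return mat


def accumulate_glcm(
    qvoi: QuantizedVOI, distance: int
) -> tuple[np.ndarray, int]:
    """Pooled isotropic co-occurrence matrix at one distance.

    For each VOI voxel ``v`` and direction ``u``, if ``v + distance*u`` is
    also in the VOI the level pair is counted at ``(i, j)`` and ``(j, i)``.
    Pairs with either endpoint outside the mask are skipped. Returns the
    normalized matrix and the total (symmetric) pair count; a VOI too small
    or fragmented for this distance yields an all-zero matrix with pair
    count 0.
    """
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    mat = _accumulate_dense(qvoi.dense(), qvoi.n_levels, int(distance))
    pair_count = int(round(mat.sum()))
    if pair_count > 0:
        mat = mat / mat.sum()
    return mat, pair_count


def glcm_all_distances(
    qvoi: QuantizedVOI, distances: tuple[int, ...] = DEFAULT_DISTANCES
) -> GLCMSet:
    """One normalized matrix per distance (degeneracy recorded, not raised)."""
    distances = tuple(int(d) for d in distances)
    if not distances or any(d < 1 for d in distances):
        raise ValueError("distances must be a nonempty list of positive ints")
    if list(distances) != sorted(distances):
        raise ValueError("distances must be sorted ascending")
    level_vol = qvoi.dense()
    matrices: dict[int, np.ndarray] = {}
    pair_counts: dict[int, int] = {}
    for d in distances:
        mat = _accumulate_dense(level_vol, qvoi.n_levels, d)
        pair_count = int(round(mat.sum()))
        matrices[d] = mat / mat.sum() if pair_count else mat
        pair_counts[d] = pair_count
    return GLCMSet(
        distances=distances,
        matrices=matrices,
        pair_counts=pair_counts,
        n_levels=qvoi.n_levels,
    )
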
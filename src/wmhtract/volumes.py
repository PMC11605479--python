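"""In-memory containers for voxel-gridded volumes and the tract atlas."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, GridMismatchError

#: Absolute tolerance when deciding whether two affines describe one grid.
AFFINE_ATOL = 1e-4


def _voxel_volume_mm3(affine: np.ndarray) -> float:
    """Voxel volume from the affine's spatial column norms (mm^3)."""
    cols = np.asarray(affine, dtype=float)[:3, :3]
    return float(np.prod(np.linalg.norm(cols, axis=0)))


@dataclass
class Volume:
    """A 3D scalar field on a voxel grid with a grid-to-world affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise DataError(f"volume must be 3D, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise DataError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return _voxel_volume_mm3(self.affine)

    def same_grid(self, other: "Volume | TractAtlas") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL
        )

    def require_same_grid(self, other: "Volume | TractAtlas", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} do not share a grid: shapes {self.shape} vs {other.shape}"
            )


@dataclass
class LesionVolume(Volume):
    """A lesion probability map: per-voxel probability of hyperintensity."""

    def __post_init__(self) -> None:
        super().__post_init__()
        v = self.values
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise DataError("lesion probabilities must lie in [0, 1]")


@dataclass
class TractAtlas:
    """Named probability maps for the tract inventory, on one shared grid."""

    maps: dict[str, np.ndarray]
    affine: np.ndarray
    _shape: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.maps:
            raise DataError("atlas has no entries")
        self.affine = np.asarray(self.affine, dtype=float)
        shapes = {np.asarray(m).shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise DataError(f"atlas entries disagree on grid shape: {shapes}")
        self._shape = shapes.pop()
        for name, m in self.maps.items():
            m = np.asarray(m)
            if m.min() < 0 or m.max() > 1:
                raise DataError(f"atlas entry {name!r} has values outside [0, 1]")
            if m.sum() <= 0:
                raise DataError(f"atlas entry {name!r} has zero probability mass")
            self.maps[name] = m

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.maps)

    @property
    def shape(self) -> tuple[int, ...]:
        return self._shape

    @property
    def voxel_volume(self) -> float:
        return _voxel_volume_mm3(self.affine)

    def mass(self, name: str) -> float:
        """Total probability mass of a tract over the whole grid."""
        return float(self.maps[name].sum())

    def __len__(self) -> int:
        return len(self.maps)
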
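"""Voxel-grid containers: scalar volumes and ordered tissue stacks.

All volumes live on a regular axis-aligned grid.  Voxel index ``(i, j, k)``
maps to millimetres as ``origin + (i*sx, j*sy, k*sz)``, with voxel *centers*
at integer indices.  Surfaces and meshes downstream are always expressed in
this mm coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VolumeGrid", "TissueStack"]

_KINDS = ("probability", "label", "binary")


@dataclass
class VolumeGrid:
    """A 3-D scalar field on a regular voxel grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Probability map (floats in [0, 1]), integer label mask, or binary mask.
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in mm; strictly positive.
    origin : tuple of float
        mm position of the center of voxel ``(0, 0, 0)``.
    kind : {"probability", "label", "binary"}
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    kind: str = "probability"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        self.origin = tuple(float(o) for o in np.broadcast_to(self.origin, (3,)))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        self._validate_values()

    def _validate_values(self, tol: float = 1e-6):
        v = self.values
        if self.kind == "probability":
            if not np.issubdtype(v.dtype, np.floating):
                v = v.astype(np.float64)
            lo, hi = float(v.min()), float(v.max())
            if lo < -tol or hi > 1.0 + tol:
                raise ValueError(
                    f"not a probability map: values span [{lo:g}, {hi:g}], "
                    "expected [0, 1]"
                )
            self.values = np.clip(v, 0.0, 1.0)
        elif self.kind == "label":
            if np.issubdtype(v.dtype, np.floating):
                r = np.rint(v)
                if not np.allclose(v, r, atol=tol):
                    raise ValueError("label volume holds non-integer values")
                v = r
            if v.min() < 0:
                raise ValueError("label volume holds negative values")
            self.values = v.astype(np.int32)
        else:  # binary
            u = np.unique(v)
            if not np.all(np.isin(u, (0, 1))):
                raise ValueError(f"binary volume holds values other than 0/1: {u[:5]}")
            self.values = v.astype(np.uint8)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """mm coordinates of (fractional) voxel indices, shape (..., 3)."""
        idx = np.asarray(idx, dtype=np.float64)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of mm points, shape (..., 3)."""
        xyz = np.asarray(xyz, dtype=np.float64)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def sample_nearest(self, xyz: np.ndarray, fill=0.0) -> np.ndarray:
        """Nearest-voxel lookup at mm points; out-of-grid points get `fill`."""
        idx = np.rint(self.voxel_index(xyz)).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)
        idx_c = np.clip(idx, 0, np.asarray(self.shape) - 1)
        out = self.values[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]].astype(np.float64)
        out[~inside] = fill
        return out

    def congruent(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "VolumeGrid":
        return replace(self, values=values, kind=kind or self.kind)


def _check_congruent(grids):
    first = grids[0]
    for g in grids[1:]:
        if not first.congruent(g):
            raise ValueError("volume grids are not congruent (shape/spacing/origin)")


@dataclass
class TissueStack:
    """Ordered per-tissue volumes, innermost (WM) first, outermost (scalp) last.

    ``air`` holds cavity masks as ``(host_tissue_name, VolumeGrid)`` pairs.
    """

    names: list
    grids: list
    air: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.names) != len(self.grids):
            raise ValueError("names and grids length mismatch")
        if len(self.grids) == 0:
            raise ValueError("empty tissue stack")
        _check_congruent(self.grids + [g for _, g in self.air])

    def __len__(self):
        return len(self.grids)

    def __getitem__(self, name: str) -> VolumeGrid:
        return self.grids[self.names.index(name)]

    @property
    def grid0(self) -> VolumeGrid:
        return self.grids[0]

    def cumulative(self) -> list:
        """Clamped running sums innermost->outermost, one VolumeGrid per layer.

        The i'th cumulative map covers tissues 0..i; for probability stacks
        built from nested interfaces its 0.5-level set is the i'th interface.
        """
        acc = np.zeros(self.grid0.shape, dtype=np.float64)
        out = []
        for g in self.grids:
            acc = np.clip(acc + g.values.astype(np.float64), 0.0, 1.0)
            out.append(self.grid0.with_values(acc.copy(), kind="probability"))
        return out

    def partition_labels(self) -> np.ndarray:
        """Assign each voxel to one tissue (index into names) or -1 (background).

        A voxel belongs to the innermost layer whose cumulative map is >= 0.5;
        cavity voxels (air mask >= 0.5) are assigned -2.
        """
        lab = np.full(self.grid0.shape, -1, dtype=np.int32)
        cums = self.cumulative()
        for i in range(len(self.grids) - 1, -1, -1):
            lab[cums[i].values >= 0.5] = i
        for _, mask in self.air:
            lab[mask.values.astype(np.float64) >= 0.5] = -2
        return lab

    def tissue_voxel_volume(self, name: str) -> float:
        """Segmentation volume (mm^3) of one tissue under the 0.5 partition."""
        if name not in self.names:
            raise ValueError(f"tissue {name!r} not in stack {self.names}")
        lab = self.partition_labels()
        i = self.names.index(name)
        n = int(np.count_nonzero(lab == i))
        if n == 0:
            raise ValueError(f"tissue {name!r} has zero segmentation volume")
        return n * self.grid0.voxel_volume
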
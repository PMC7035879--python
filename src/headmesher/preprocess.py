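"""Layered-tissue-model enforcement by morphological gap insertion.

Adjacent tissue layers whose boundaries merge would yield intersecting (or
coincident) iso-surfaces.  Before surface extraction we therefore insert a
controlled gap of width ``epsilon`` voxels between successive *cumulative*
tissue maps, using either a thickening operator T+ (grow the outer map by a
cubic max-filter dilation of the inner) or a thinning operator T- (shrink the
inner map by a cubic min-filter erosion of the union).  Both operators are
local: they only alter voxels within ``epsilon`` (Chebyshev) of regions where
the two boundaries merge, and they work for probabilistic and binary maps
alike.  The altered voxels are recorded so that the tetrahedral-mesh
relabeling step can later restore the original shared boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import TissueStack, VolumeGrid

__all__ = [
    "GapParams",
    "LayeredModel",
    "max_filter",
    "min_filter",
    "thicken",
    "thin",
    "build_layered_model",
]

log = logging.getLogger(__name__)

THICKEN_OUTER = "thicken_outer"
THIN_INNER = "thin_inner"


@dataclass
class GapParams:
    """Gap-insertion parameters.

    epsilon : int
        Half-edge length (in voxels) of the cubic filter neighborhood; the
        inserted gap width.  The default of 1 voxel is the smallest value
        that guarantees non-intersecting level sets.
    strategy : dict
        Optional per-pair override, keyed by ``(inner_name, outer_name)``,
        value ``"thicken_outer"`` or ``"thin_inner"``.  Unlisted pairs use
        ``default_strategy``, except that the innermost pair (WM inside GM in
        a standard head) defaults to thinning the inner tissue.
    """

    epsilon: int = 1
    strategy: dict = field(default_factory=dict)
    default_strategy: str = THICKEN_OUTER

    def __post_init__(self):
        if int(self.epsilon) != self.epsilon or self.epsilon < 1:
            raise ValueError("epsilon must be an integer >= 1")
        self.epsilon = int(self.epsilon)
        for pair, s in self.strategy.items():
            if s not in (THICKEN_OUTER, THIN_INNER):
                raise ValueError(f"unknown strategy {s!r} for pair {pair}")

    def for_pair(self, inner: str, outer: str, pair_index: int) -> str:
        if (inner, outer) in self.strategy:
            return self.strategy[(inner, outer)]
        if pair_index == 0:
            return THIN_INNER
        return self.default_strategy


@dataclass
class LayeredModel:
    """Nested extraction volumes plus the record of gap-altered voxels.

    ``extraction_volumes`` are cumulative maps, innermost tissue first; the
    0.5-level set of volume i is the boundary of tissues 0..i.  ``air`` holds
    ``(host_name, VolumeGrid)`` cavity extraction volumes.  ``altered`` maps
    a layer name to the boolean voxel mask where its cumulative map's 0.5
    super-level set changed during gap insertion.
    """

    names: list
    extraction_volumes: list
    air: list = field(default_factory=list)
    altered: dict = field(default_factory=dict)

    def altered_any(self) -> np.ndarray:
        m = np.zeros(self.extraction_volumes[0].shape, dtype=bool)
        for a in self.altered.values():
            m |= a
        return m


def _as_array(vol) -> np.ndarray:
    if isinstance(vol, VolumeGrid):
        return vol.values.astype(np.float64)
    return np.asarray(vol, dtype=np.float64)


def _wrap_like(vol, values):
    if isinstance(vol, VolumeGrid):
        return vol.with_values(values, kind="probability")
    return values


def max_filter(vol, epsilon: int):
    """Cubic max-filter (dilation) of half-edge `epsilon` voxels.

    Each voxel is replaced by the maximum over its (2*epsilon+1)^3 Chebyshev
    neighborhood; neighbors outside the grid are ignored (shrinking window).
    """
    if int(epsilon) != epsilon or epsilon < 1:
        raise ValueError("epsilon must be an integer >= 1")
    a = _as_array(vol)
    # edge replication reuses in-window values only, hence equals the
    # shrinking-window rule for a max
    out = ndimage.maximum_filter(a, size=2 * int(epsilon) + 1, mode="nearest")
    return _wrap_like(vol, out)


def min_filter(vol, epsilon: int):
    """Cubic min-filter (erosion), the dual of :func:`max_filter`."""
    if int(epsilon) != epsilon or epsilon < 1:
        raise ValueError("epsilon must be an integer >= 1")
    a = _as_array(vol)
    out = ndimage.minimum_filter(a, size=2 * int(epsilon) + 1, mode="nearest")
    return _wrap_like(vol, out)


def _check_shapes(a, b):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def thicken(p_out, p_in, epsilon: int = 1):
    """T+ : grow the outer map so it encloses the inner map with a gap.

    Voxelwise ``max(P_in + P_out, D_eps(P_in))`` clamped to [0, 1].  Voxels
    where the dilation does not exceed the plain sum are unchanged relative
    to that sum, so the operator is local to merged-boundary regions.
    """
    a_out, a_in = _as_array(p_out), _as_array(p_in)
    _check_shapes(a_out, a_in)
    dil = _as_array(max_filter(a_in, epsilon))
    return _wrap_like(p_out, np.clip(np.maximum(a_in + a_out, dil), 0.0, 1.0))


def thin(p_in, p_out, epsilon: int = 1):
    """T- : shrink the inner map away from the union boundary by `epsilon`.

    Voxelwise ``min(P_in, E_eps(clamp(P_in + P_out)))``; voxels deep inside
    the union (where the eroded union stays at 1) are unchanged.
    """
    a_in, a_out = _as_array(p_in), _as_array(p_out)
    _check_shapes(a_in, a_out)
    union = np.clip(a_in + a_out, 0.0, 1.0)
    ero = _as_array(min_filter(union, epsilon))
    return _wrap_like(p_in, np.minimum(a_in, ero))


def _level(a):
    return a >= 0.5


def build_layered_model(stack: TissueStack, gaps: GapParams | None = None) -> LayeredModel:
    """Enforce the layered tissue model on a stack of per-tissue maps.

    Cumulative maps are formed innermost outward; each adjacent pair is then
    processed in order (innermost pair first) with its gap strategy.  Air
    cavities are carved out of their host layer's cumulative map and returned
    as separate extraction volumes.  The result satisfies monotone nesting of
    the 0.5-level sets, with successive level sets separated wherever the
    original boundaries merged.
    """
    gaps = gaps or GapParams()
    names = list(stack.names)

    def cumulative_airfilled(st):
        # cavities are carved from their host *extraction volume* only; the
        # cumulative maps themselves must stay simply nested, so the air
        # mask is added back into its host layer first
        filled = []
        for name, g in zip(st.names, st.grids):
            v = g.values.astype(np.float64)
            for host, q in st.air:
                if host == name:
                    v = np.clip(v + q.values.astype(np.float64), 0.0, 1.0)
            filled.append(st.grid0.with_values(v, kind="probability"))
        return TissueStack(names=list(st.names), grids=filled).cumulative()

    cums = [c.values.astype(np.float64).copy() for c in cumulative_airfilled(stack)]

    # drop layers that occupy no voxel of the 0.5-threshold partition
    keep = []
    prev = np.zeros(stack.grid0.shape, dtype=bool)
    for i, name in enumerate(names):
        occupied = _level(cums[i]) & ~prev
        if occupied.any():
            keep.append(i)
            prev = _level(cums[i])
        else:
            warnings.warn(f"tissue {name!r} never reaches 0.5; layer skipped")
    if len(keep) != len(names):
        names = [names[i] for i in keep]
        stack = TissueStack(
            names=names, grids=[stack.grids[i] for i in keep], air=list(stack.air)
        )
        cums = [c.values.astype(np.float64).copy() for c in cumulative_airfilled(stack)]

    altered = {}
    for k in range(len(names) - 1):
        inner, outer = names[k], names[k + 1]
        strat = gaps.for_pair(inner, outer, k)
        layer_outer = np.clip(cums[k + 1] - cums[k], 0.0, 1.0)
        if strat == THICKEN_OUTER:
            new_outer = _as_array(thicken(layer_outer, cums[k], gaps.epsilon))
            changed = _level(new_outer) ^ _level(cums[k + 1])
            altered[outer] = altered.get(outer, np.zeros_like(changed)) | changed
            cums[k + 1] = new_outer
        else:
            new_inner = _as_array(thin(cums[k], layer_outer, gaps.epsilon))
            changed = _level(new_inner) ^ _level(cums[k])
            altered[inner] = altered.get(inner, np.zeros_like(changed)) | changed
            cums[k] = new_inner
        log.debug("gap pair (%s,%s): %s altered %d voxels", inner, outer, strat,
                  int(changed.sum()))

    # nesting and separation checks
    for k in range(len(names) - 1):
        if np.any(_level(cums[k]) & ~_level(cums[k + 1])):
            raise ValueError(
                f"nesting violated between {names[k]!r} and {names[k + 1]!r}; "
                f"inputs cannot be repaired with epsilon={gaps.epsilon}"
            )
        touched = altered.get(names[k], None)
        if touched is not None and touched.any():
            grown = ndimage.maximum_filter(_level(cums[k]).astype(np.uint8), size=3,
                                           mode="nearest").astype(bool)
            if np.any(grown & touched & ~_level(cums[k + 1])):
                raise ValueError(
                    f"gap insertion failed to separate {names[k]!r} from "
                    f"{names[k + 1]!r} with epsilon={gaps.epsilon}"
                )

    # the record keeps 0.5-threshold flips only: sub-threshold value changes
    # move the extracted interface by well under a voxel and must not widen
    # the relabeling zone
    for name in names:
        altered.setdefault(name, np.zeros(stack.grid0.shape, dtype=bool))

    air = []
    for host, q in stack.air:
        if host not in names:
            continue
        hi = names.index(host)
        qv = q.values.astype(np.float64)
        cums[hi] = np.minimum(cums[hi], 1.0 - qv)
        air.append((host, stack.grid0.with_values(qv, kind="probability")))

    vols = [stack.grid0.with_values(c, kind="probability") for c in cums]
    return LayeredModel(names=names, extraction_volumes=vols, air=air, altered=altered)
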
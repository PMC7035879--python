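"""Synthetic layered-head phantoms with analytically known volumes.

The phantoms emulate the nested scalp/skull/CSF/GM/WM anatomy as concentric
spherical (or ellipsoidal) interfaces.  Probability maps are built by passing
the radial signed distance to each interface through a Gaussian CDF of width
``blur_sigma``, so the 0.5-level set of every *cumulative* map lies exactly on
the analytic interface regardless of blur.  Controlled pathologies are
available: merged boundaries (an inner interface pushed onto the next outer
one over a polar cap), air cavities inside a host layer, and random
misclassified noise islands.

Default radii (40/36/33/31/27 mm on a 96^3 1 mm grid) give layer thicknesses
of 4/3/2/4 mm, bracketing typical adult scalp (~7 mm), skull (~4 mm), CSF
(~2.7 mm) and cortical GM (~3.3 mm) thicknesses at a desk-scale grid size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, ndimage
from scipy.special import ndtr

from .grid import TissueStack, VolumeGrid

__all__ = ["PhantomSpec", "make_layered_phantom", "add_noise_islands", "PRESETS"]

DEFAULT_NAMES = ["wm", "gm", "csf", "skull", "scalp"]  # innermost -> outermost
_MERGE_CAP_DEG = 60.0     # polar half-angle of the merged patch
_MERGE_BLEND_DEG = 12.0   # angular width of the smooth transition


@dataclass
class PhantomSpec:
    """Specification of a nested-layer phantom.

    ``layer_radii`` are interface radii in mm, outermost first, strictly
    decreasing; layer i occupies the shell between radii i and i+1 and the
    last layer fills the innermost ball.  ``merge_layers`` lists adjacent
    ``(outer_name, inner_name)`` pairs whose shared interface is forced onto
    the outer pair's interface over a polar cap (zero-thickness outer layer
    there).  ``cavity`` is ``(center_mm, radius_mm, host_layer_name)``.
    """

    shape: str = "sphere"
    layer_radii: tuple = (40.0, 36.0, 33.0, 31.0, 27.0)
    layer_names: tuple = tuple(reversed(DEFAULT_NAMES))  # outermost -> innermost
    grid_size: int = 96
    spacing: float = 1.0
    blur_sigma: float = 1.0
    merge_layers: list = field(default_factory=list)
    cavity: tuple | None = None
    ellipsoid_axes: tuple = (1.0, 0.9, 0.8)

    def __post_init__(self):
        r = np.asarray(self.layer_radii, dtype=float)
        if not np.all(np.diff(r) < 0):
            raise ValueError("layer_radii must be strictly decreasing outer->inner")
        if len(self.layer_names) != len(r):
            raise ValueError("one name per layer required")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        half_extent = (self.grid_size - 1) / 2.0 * self.spacing
        scale = max(self.ellipsoid_axes) if self.shape == "ellipsoid" else 1.0
        if r[0] * scale > half_extent - 2.0 * self.spacing:
            raise ValueError("outermost layer does not fit the grid with a 2-voxel margin")

    @property
    def names_in_to_out(self) -> list:
        return list(reversed(list(self.layer_names)))

    def analytic_interface_volume(self, i: int) -> float:
        """Enclosed volume (mm^3) of interface i (0 = outermost), including
        any merged-cap deformation, by exact closed form or 1-D quadrature."""
        radii = list(self.layer_radii)
        ax = self.ellipsoid_axes if self.shape == "ellipsoid" else (1.0, 1.0, 1.0)
        fac = ax[0] * ax[1] * ax[2]
        merged_to = self._merged_target(i)
        if merged_to is None:
            return 4.0 / 3.0 * math.pi * radii[i] ** 3 * fac

        r_in, r_out = radii[i], radii[merged_to]

        def r_of_theta(theta):
            return r_in + (r_out - r_in) * self._cap_blend(theta)

        val, _ = integrate.quad(
            lambda th: 2.0 * math.pi / 3.0 * r_of_theta(th) ** 3 * math.sin(th),
            0.0, math.pi, limit=200,
        )
        return val * fac

    def analytic_layer_volumes(self) -> dict:
        """Per-layer shell volumes (mm^3), cavity removed from its host."""
        n = len(self.layer_radii)
        enc = [self.analytic_interface_volume(i) for i in range(n)]
        out = {}
        for i, name in enumerate(self.layer_names):
            inner = enc[i + 1] if i + 1 < n else 0.0
            out[name] = enc[i] - inner
        if self.cavity is not None:
            _, r_cav, host = self.cavity
            out[host] -= 4.0 / 3.0 * math.pi * r_cav**3
        return out

    # -- internals --------------------------------------------------------
    def _merged_target(self, i: int) -> int | None:
        """If interface i is merged onto an outer interface, its index."""
        names = list(self.layer_names)
        for outer, inner in self.merge_layers:
            io, ii = names.index(outer), names.index(inner)
            if ii != io + 1:
                raise ValueError(f"merge pair {(outer, inner)} is not adjacent")
            if i == ii:
                return io
        return None

    @staticmethod
    def _cap_blend(theta):
        """1 inside the polar cap, 0 outside, smoothstep in between."""
        a0 = math.radians(_MERGE_CAP_DEG - _MERGE_BLEND_DEG)
        a1 = math.radians(_MERGE_CAP_DEG + _MERGE_BLEND_DEG)
        t = np.clip((a1 - np.asarray(theta)) / (a1 - a0), 0.0, 1.0)
        return t * t * (3.0 - 2.0 * t)


def _radial_coords(spec: PhantomSpec):
    n = spec.grid_size
    c = (n - 1) / 2.0 * spec.spacing
    ax = np.arange(n) * spec.spacing
    X, Y, Z = np.meshgrid(ax - c, ax - c, ax - c, indexing="ij")
    if spec.shape == "ellipsoid":
        a1, a2, a3 = spec.ellipsoid_axes
        rho = np.sqrt((X / a1) ** 2 + (Y / a2) ** 2 + (Z / a3) ** 2)
        zn = Z / a3
    else:
        rho = np.sqrt(X**2 + Y**2 + Z**2)
        zn = Z
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(zn / np.maximum(rho, 1e-12), -1.0, 1.0))
    return rho, theta


def _inclusion(signed_dist: np.ndarray, sigma: float) -> np.ndarray:
    """P(inside) from a signed distance (positive inside)."""
    if sigma <= 0:
        return (signed_dist >= 0).astype(np.float64)
    return ndtr(signed_dist / sigma)


def make_layered_phantom(spec: PhantomSpec):
    """Build the phantom.

    Returns
    -------
    stack : TissueStack
        One probability map per layer, innermost first; cavities carried as
        air masks with host bookkeeping.
    volumes : dict
        Analytic per-layer shell volumes (mm^3) plus ``"cavity"`` if present.
    """
    rho, theta = _radial_coords(spec)
    n_layers = len(spec.layer_radii)

    # inclusion probability of each interface (0 = outermost)
    incl = []
    for i in range(n_layers):
        tgt = spec._merged_target(i)
        if tgt is None:
            r_map = spec.layer_radii[i]
        else:
            blend = spec._cap_blend(theta)
            r_map = spec.layer_radii[i] + (spec.layer_radii[tgt] - spec.layer_radii[i]) * blend
        incl.append(_inclusion(r_map - rho, spec.blur_sigma))

    grids_out_to_in = []
    for i in range(n_layers):
        inner = incl[i + 1] if i + 1 < n_layers else 0.0
        layer = np.clip(incl[i] - inner, 0.0, 1.0)
        grids_out_to_in.append(layer)

    kind = "probability"
    air = []
    if spec.cavity is not None:
        center, r_cav, host = spec.cavity
        host_idx = list(spec.layer_names).index(host)
        n = spec.grid_size
        c0 = (n - 1) / 2.0 * spec.spacing
        ax = np.arange(n) * spec.spacing
        X, Y, Z = np.meshgrid(ax - c0, ax - c0, ax - c0, indexing="ij")
        cx, cy, cz = center
        d_cav = r_cav - np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        q = _inclusion(d_cav, spec.blur_sigma)
        host_map = grids_out_to_in[host_idx]
        margin = max(spec.blur_sigma * 2.0, spec.spacing)
        core = d_cav >= -margin
        if not np.all(host_map[core] > 0.45):
            raise ValueError(f"cavity does not fit inside host layer {host!r}")
        grids_out_to_in[host_idx] = np.minimum(host_map, 1.0 - q)
        air.append((host, VolumeGrid(q, spacing=spec.spacing, kind=kind)))

    names_in_out = spec.names_in_to_out
    grids_in_out = [
        VolumeGrid(g, spacing=spec.spacing, kind=kind)
        for g in reversed(grids_out_to_in)
    ]
    stack = TissueStack(names=names_in_out, grids=grids_in_out, air=air)

    volumes = spec.analytic_layer_volumes()
    if spec.cavity is not None:
        volumes["cavity"] = 4.0 / 3.0 * math.pi * spec.cavity[1] ** 3
    return stack, volumes


def add_noise_islands(stack: TissueStack, n: int, size: int, seed: int) -> TissueStack:
    """Inject `n` disjoint misclassified spherical blobs of `size` voxels radius.

    Each island rewrites a blob deep inside one (randomly chosen) host layer
    to a different (randomly chosen) source tissue, emulating segmentation
    noise.  Deterministic for a given seed; the original stack is untouched.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return stack
    rng = np.random.default_rng(seed)
    vals = [g.values.astype(np.float64).copy() for g in stack.grids]
    shape = np.asarray(stack.grid0.shape)
    placed_centers = []
    placements = []
    n_layers = len(vals)
    if n_layers < 2:
        raise ValueError("need at least two layers to misclassify between")
    for _ in range(n):
        for _attempt in range(5000):
            host = int(rng.integers(0, n_layers))
            src = int(rng.integers(0, n_layers - 1))
            if src >= host:
                src += 1
            idx = rng.integers(0, shape, size=3)
            i, j, k = (int(v) for v in idx)
            # deep inside host, far from previous islands
            lo = np.maximum(idx - (size + 1), 0)
            hi = np.minimum(idx + (size + 2), shape)
            region = vals[host][lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            if region.size == 0 or region.min() < 0.95:
                continue
            if any(np.linalg.norm(idx - c) < 2.5 * (size + 1) for c in placed_centers):
                continue
            ii, jj, kk = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            blob = (ii - i) ** 2 + (jj - j) ** 2 + (kk - k) ** 2 <= size**2
            if blob.sum() == 0:
                continue
            sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
            vals[host][sub][blob] = 0.0
            vals[src][sub][blob] = 1.0
            placed_centers.append(idx)
            placements.append({"host": stack.names[host], "source": stack.names[src],
                               "center": (i, j, k), "radius": int(size)})
            break
        else:
            raise ValueError(
                f"could not place island of radius {size} voxels inside any layer"
            )
    grids = [g.with_values(v) for g, v in zip(stack.grids, vals)]
    meta = dict(stack.meta)
    meta["islands"] = placements
    return TissueStack(names=list(stack.names), grids=grids,
                       air=list(stack.air), meta=meta)


def island_component_counts(stack: TissueStack) -> dict:
    """Connected-component count of each layer's 0.5-super-level set."""
    out = {}
    for name, g in zip(stack.names, stack.grids):
        _, cnt = ndimage.label(np.asarray(g.values, dtype=np.float64) >= 0.5)
        out[name] = int(cnt)
    return out


PRESETS = {
    "five-layer": PhantomSpec(),
    "five-layer-binary": PhantomSpec(blur_sigma=0.0),
    "merged-csf-gm": PhantomSpec(merge_layers=[("csf", "gm")]),
    "cavity": PhantomSpec(
        layer_radii=(42.0, 40.0, 30.0, 27.0, 24.0),
        cavity=((0.0, 0.0, 35.0), 2.8, "skull"),
    ),
    "ellipsoid": PhantomSpec(shape="ellipsoid"),
}
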
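"""Stick–zeppelin–ball forward model and the sparse system operator.

The measured, b0-normalised diffusion signal in a voxel is modelled as a
nonnegative combination of three compartment kernels:

* stick      — intra-axonal water, zero perpendicular diffusivity:
               ``S = exp(-b d_par (g.v)^2)``
* zeppelin   — extra-axonal hindered water, axially symmetric tensor:
               ``S = exp(-b (d_perp + (d_par - d_perp)(g.v)^2))``
* ball       — isotropic water: ``S = exp(-b d_iso)``

Each candidate streamline contributes one stick column whose per-voxel
scale is the chord length of the streamline inside that voxel: the key
modelling assumption is that a streamline's intra-axonal contribution is
constant along its whole path, while extra-axonal and isotropic
contributions vary voxel by voxel.  Stacking all voxels × measurements as
rows gives a sparse linear operator A with column blocks
(intra-axonal | extra-axonal | isotropic); the fit stage solves
``min_{x>=0} ||Ax - y||^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import ContractError, DegenerateInputError, ParameterError
from .gradients import GradientScheme

__all__ = [
    "TissueParams",
    "stick_signal",
    "zeppelin_signal",
    "ball_signal",
    "segment_lengths",
    "SegmentMap",
    "SystemMatrix",
    "build_system_matrix",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class TissueParams:
    """Compartment diffusivities, all in mm^2/s.

    Defaults are literature-conventional white-matter values: parallel
    diffusivity 1.7e-3 shared by stick and zeppelin, zeppelin perpendicular
    0.61e-3, free-water ball 3.0e-3.  ``d_iso_tissue`` (hindered isotropic)
    is carried for completeness; the default forward model uses a single
    free-water ball per voxel.
    """

    d_par: float = 1.7e-3
    d_perp: float = 0.61e-3
    d_iso_csf: float = 3.0e-3
    d_iso_tissue: float = 1.7e-3

    def __post_init__(self) -> None:
        if not (0 < self.d_perp <= self.d_par):
            raise ParameterError("require 0 < d_perp <= d_par")
        if self.d_iso_csf <= 0 or self.d_iso_tissue <= 0:
            raise ParameterError("isotropic diffusivities must be positive")


def _check_units(b, g, v) -> None:
    b = np.atleast_1d(np.asarray(b, dtype=float))
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if g.shape[0] == 1 and b.size > 1:
        g = np.broadcast_to(g, (b.size, 3))
    if b.size == 1 and g.shape[0] > 1:
        b = np.broadcast_to(b, (g.shape[0],))
    dw = b > 0
    if np.any(np.abs(np.linalg.norm(g[dw], axis=-1) - 1) > 1e-3):
        raise ContractError("gradient directions must be unit vectors at b>0")
    if np.abs(np.linalg.norm(v) - 1) > 1e-3:
        raise ContractError("fibre direction must be a unit vector")


def stick_signal(b, g, v, d_par: float):
    """Intra-axonal attenuation ``exp(-b d_par (g.v)^2)``.

    ``b`` may be scalar or (n,), ``g`` correspondingly (3,) or (n,3);
    ``v`` is a single unit fibre direction.  Sign flips of g or v leave
    the value unchanged.
    """
    b = np.asarray(b, dtype=float)
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_units(b, g, v)
    dot = g @ v
    return np.exp(-b * d_par * dot**2)


def zeppelin_signal(b, g, v, d_par: float, d_perp: float):
    """Extra-axonal attenuation of an axially symmetric tensor."""
    if d_perp > d_par:
        raise ParameterError("zeppelin requires d_perp <= d_par")
    b = np.asarray(b, dtype=float)
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_units(b, g, v)
    dot = g @ v
    return np.exp(-b * (d_perp + (d_par - d_perp) * dot**2))


def ball_signal(b, d_iso: float):
    """Isotropic attenuation ``exp(-b d_iso)``, direction-independent."""
    if d_iso <= 0:
        raise ParameterError("d_iso must be positive")
    return np.exp(-np.asarray(b, dtype=float) * d_iso)


# ---------------------------------------------------------------------------
# streamline geometry

#: voxel membership convention: a point belongs to voxel i along an axis
#: iff its coordinate lies in [i*size, (i+1)*size) (0-based indices).


class SegmentMap(dict):
    """Per-streamline map: flat voxel index -> (chord length mm, unit mean
    orientation).  Dict subclass so callers can iterate naturally."""

    @property
    def total_length(self) -> float:
        return float(sum(l for l, _ in self.values()))


def _resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (midpoints, step vectors) of a fixed-step resampling."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total == 0:
        return np.empty((0, 3)), np.empty((0, 3))
    n_steps = max(1, int(np.ceil(total / step)))
    s = np.linspace(0.0, total, n_steps + 1)
    # keep the original vertices among the sample points so corners are
    # never cut and the arc length is conserved exactly
    s = np.union1d(s, cum)
    xyz = np.column_stack([np.interp(s, cum, points[:, k]) for k in range(3)])
    vec = np.diff(xyz, axis=0)
    keep = np.linalg.norm(vec, axis=1) > 0
    mid = 0.5 * (xyz[:-1] + xyz[1:])
    return mid[keep], vec[keep]


def segment_lengths(streamline: np.ndarray,
                    grid_dims: tuple[int, int, int],
                    voxel_size: tuple[float, float, float],
                    step: float | None = None) -> SegmentMap:
    """Chord length and mean orientation of a streamline in each voxel.

    The polyline is resampled at a fixed arc-length step (default
    0.1 × min voxel size); each sub-step assigns its length to the voxel
    containing its midpoint.  Orientations are length-weighted mean chord
    directions, normalised to unit vectors.  Points outside the grid
    bounding box are dropped.
    """
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise DegenerateInputError("streamline needs at least 2 points in 3-D")
    vsize = np.asarray(voxel_size, dtype=float)
    if step is None:
        step = 0.1 * float(vsize.min())
    if step > 0.2 * vsize.min():
        raise ParameterError("step must be <= 0.2 x min voxel size")
    mid, vec = _resample_polyline(pts, step)
    if mid.shape[0] == 0:
        return SegmentMap()
    idx = np.floor(mid / vsize).astype(int)
    dims = np.asarray(grid_dims, dtype=int)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    idx = idx[inside]
    vec = vec[inside]
    if idx.shape[0] == 0:
        return SegmentMap()
    flat = np.ravel_multi_index(idx.T, tuple(dims))
    order = np.argsort(flat, kind="stable")
    flat_s, vec_s = flat[order], vec[order]
    uniq, starts = np.unique(flat_s, return_index=True)
    out = SegmentMap()
    for u, lo, hi in zip(uniq, starts, np.append(starts[1:], flat_s.size)):
        v = vec_s[lo:hi]
        lengths = np.linalg.norm(v, axis=1)
        total = lengths.sum()
        if total <= 0:
            continue
        mean_dir = v.sum(axis=0)
        nrm = np.linalg.norm(mean_dir)
        if nrm < 1e-12:  # perfectly folded chord; fall back to first step
            mean_dir = v[0] / max(lengths[0], 1e-300)
        else:
            mean_dir = mean_dir / nrm
        out[int(u)] = (float(total), mean_dir)
    return out


# ---------------------------------------------------------------------------
# system matrix


@dataclass
class SystemMatrix:
    """Sparse operator from (streamline, extra-axonal, isotropic)
    coefficients to the stacked signal.

    Row ordering is ``voxel_flat * n_measurements + measurement``.
    Column blocks in stable order: intra-axonal (one per streamline),
    extra-axonal (one per (voxel, orientation) pair as provided by the
    orientation source), isotropic (one per voxel in the mask).
    """

    A: sparse.csr_matrix
    n_streamlines: int
    ec_entries: list[tuple[int, np.ndarray]]  # (voxel_flat, unit orientation)
    iso_voxels: np.ndarray                    # flat voxel indices, sorted
    scheme: GradientScheme
    grid_dims: tuple[int, int, int]
    segment_maps: list[SegmentMap] = field(default_factory=list, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    @property
    def n_ec(self) -> int:
        return len(self.ec_entries)

    @property
    def n_iso(self) -> int:
        return int(self.iso_voxels.size)

    def __matmul__(self, x):
        return self.A @ x

    def block_slices(self) -> tuple[slice, slice, slice]:
        a = self.n_streamlines
        b = a + self.n_ec
        c = b + self.n_iso
        return slice(0, a), slice(a, b), slice(b, c)


def build_system_matrix(tractogram,
                        grid_dims: tuple[int, int, int],
                        voxel_size: tuple[float, float, float],
                        scheme: GradientScheme,
                        params: TissueParams,
                        ec_orientation_source: dict[int, list[np.ndarray]],
                        mask: np.ndarray | None = None,
                        step: float | None = None) -> SystemMatrix:
    """Assemble the sparse stick–zeppelin–ball operator.

    Parameters
    ----------
    tractogram:
        Object with a ``streamlines`` attribute (list of (k,3) mm arrays),
        or a plain list of such arrays.
    ec_orientation_source:
        Mapping flat voxel index -> list of unit orientations; one zeppelin
        column is created per (voxel, orientation).  At desk scale these
        come from the phantom's ground-truth bundle directions.
    mask:
        Boolean volume selecting voxels that receive an isotropic column;
        default: the whole grid.
    """
    streamlines = getattr(tractogram, "streamlines", tractogram)
    dims = tuple(int(d) for d in grid_dims)
    n_vox = int(np.prod(dims))
    nE = scheme.n
    b, g = scheme.bvals, scheme.bvecs

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    col = 0
    seg_maps: list[SegmentMap] = []

    def _add_column(voxel: int, kernel: np.ndarray, scale: float, c: int) -> None:
        rows.append(voxel * nE + np.arange(nE))
        cols.append(np.full(nE, c))
        vals.append(scale * kernel)

    # intra-axonal block
    for sl in streamlines:
        smap = segment_lengths(np.asarray(sl, dtype=float), dims, voxel_size, step)
        seg_maps.append(smap)
        for vox, (length, direction) in smap.items():
            if length <= 0:
                continue  # zero-length chords dropped
            _add_column(vox, stick_signal(b, g, direction, params.d_par), length, col)
        col += 1
    n_str = col

    # extra-axonal block
    ec_entries: list[tuple[int, np.ndarray]] = []
    for vox in sorted(ec_orientation_source):
        for direction in ec_orientation_source[vox]:
            direction = np.asarray(direction, dtype=float)
            if abs(np.linalg.norm(direction) - 1) > 1e-3:
                raise ContractError("extra-axonal orientations must be unit vectors")
            _add_column(vox, zeppelin_signal(b, g, direction, params.d_par,
                                             params.d_perp), 1.0, col)
            ec_entries.append((int(vox), direction))
            col += 1

    # isotropic block
    if mask is None:
        iso_voxels = np.arange(n_vox)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dims:
            raise ContractError("mask shape must equal grid dims")
        iso_voxels = np.flatnonzero(mask.ravel())
    ball = ball_signal(b, params.d_iso_csf)
    for vox in iso_voxels:
        _add_column(int(vox), ball, 1.0, col)
        col += 1

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        v = np.concatenate(vals)
    else:
        r = c = v = np.empty(0)
    A = sparse.csr_matrix((v, (r, c)), shape=(n_vox * nE, col))
    return SystemMatrix(A=A, n_streamlines=n_str, ec_entries=ec_entries,
                        iso_voxels=np.asarray(iso_voxels, dtype=int),
                        scheme=scheme, grid_dims=dims, segment_maps=seg_maps)
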
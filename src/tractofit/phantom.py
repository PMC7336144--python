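"""Synthetic diffusion phantoms with known ground truth.

Stands in for the study's MRI data: a small voxel grid carrying a few
fibre bundles (each a set of streamlines with known nonnegative signal
weights), optional lesions that raise free water and damage traversing
fibres, and spurious candidate streamlines with true weight zero.  All
generators are pure functions of (spec, seed).

Per voxel, the compartment fractions are constructed to sum to one:
``f_intra + f_extra + f_iso = 1`` where ``f_intra = sum_k w_k L_kv`` over
streamline chords.  Background voxels are pure isotropic water, so the
b0-normalised signal is exactly 1 everywhere before noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import substream
from .errors import GeometryError, InsufficientSampleError, ParameterError
from .gradients import GradientScheme
from .model import (SegmentMap, TissueParams, ball_signal, segment_lengths,
                    stick_signal, zeppelin_signal)

__all__ = [
    "Bundle", "BundleSpec", "LesionSpec", "Phantom", "Tractogram",
    "make_bundle_phantom", "simulate_dwi", "add_spurious_streamlines",
    "true_coefficient_vector", "two_bundle_phantom",
]

#: isotropic fraction inside healthy bundle tissue
BASE_ISO_FRACTION = 0.05
#: highest admissible intra-axonal fraction in any voxel
MAX_INTRA_FRACTION = 0.90


@dataclass
class Tractogram:
    """Candidate streamlines plus ground-truth bookkeeping.

    ``true_weights`` are signal-fraction densities (1/mm); spurious
    streamlines carry weight 0 and ``spurious`` True.  ``endpoint_nodes``
    holds the generating bundle's node pair, or None for spurious paths.
    """

    streamlines: list[np.ndarray]
    true_weights: np.ndarray
    spurious: np.ndarray
    endpoint_nodes: list[tuple[int, int] | None]

    def __post_init__(self) -> None:
        n = len(self.streamlines)
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        self.spurious = np.asarray(self.spurious, dtype=bool)
        if self.true_weights.size != n or self.spurious.size != n:
            raise ParameterError("tractogram metadata misaligned")
        if np.any(self.true_weights < 0):
            raise ParameterError("true weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        """Arc length (mm) of every streamline."""
        return np.array([
            float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum())
            for s in self.streamlines
        ])


@dataclass
class Bundle:
    """Streamlines connecting one node pair, with true weights."""

    streamlines: list[np.ndarray]
    true_weights: np.ndarray
    endpoint_nodes: tuple[int, int]

    def __post_init__(self) -> None:
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        if self.true_weights.size != len(self.streamlines):
            raise ParameterError("one weight per streamline required")
        if np.any(self.true_weights < 0):
            raise ParameterError("true weights must be nonnegative")


@dataclass(frozen=True)
class BundleSpec:
    """Geometry and weight distribution of one synthetic bundle.

    ``start``/``end`` are mm coordinates of the bundle axis endpoints;
    streamlines are parallel offsets of the axis placed on a lateral
    lattice of the given ``pitch`` (so distinct streamlines traverse
    distinct voxel rows and their signal columns stay distinguishable),
    each jittered by up to ``jitter`` mm inside its lattice cell.
    ``bend`` offsets the midpoint to produce a curved (quadratic Bezier)
    bundle.
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    endpoint_nodes: tuple[int, int]
    n_streamlines: int = 5
    pitch: float = 1.0
    jitter: float = 0.2
    weight_range: tuple[float, float] = (0.05, 0.15)
    bend: tuple[float, float, float] = (0.0, 0.0, 0.0)
    points_per_streamline: int = 20


@dataclass(frozen=True)
class LesionSpec:
    """Spherical lesion: raises free water and damages traversing fibres.

    ``iso_boost`` is added to the isotropic fraction of in-mask bundle
    voxels; ``damage`` multiplies the true weight of every streamline
    passing through the mask by (1 - damage), whole-streamline, matching
    the constant-contribution assumption.
    """

    center: tuple[float, float, float]
    radius: float
    iso_boost: float = 0.3
    damage: float = 0.5


@dataclass
class Phantom:
    """Voxel grid + ground-truth bundles, lesion mask and tissue model."""

    grid_dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    bundles: list[Bundle]
    lesion_mask: np.ndarray
    params: TissueParams
    affine: np.ndarray
    label_volume: np.ndarray            # int volume, 0 = background
    iso_fraction: np.ndarray            # flat (n_voxels,)
    ec_map: dict[int, list[tuple[np.ndarray, float]]]  # vox -> [(dir, frac)]
    intra_fraction: np.ndarray          # flat (n_voxels,)
    resample_step: float = 0.1

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))

    def ec_orientation_source(self) -> dict[int, list[np.ndarray]]:
        """Per-voxel fibre orientations for the extra-axonal block."""
        return {v: [d for d, _ in entries] for v, entries in self.ec_map.items()}


def _bezier(p0, p1, p2, t):
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _spec_streamlines(spec: BundleSpec, rng: np.random.Generator) -> list[np.ndarray]:
    p0 = np.asarray(spec.start, dtype=float)
    p2 = np.asarray(spec.end, dtype=float)
    axis = p2 - p0
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("bundle start and end coincide")
    axis = axis / norm
    # orthonormal frame perpendicular to the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    t = np.linspace(0.0, 1.0, spec.points_per_streamline)
    mid = 0.5 * (p0 + p2) + np.asarray(spec.bend, dtype=float)
    # lattice cells in the (u, w) plane: u steps {0, -1} (kept shallow for
    # thin grids), w steps 0, 1, -1, 2, -2, ...
    out = []
    for i in range(spec.n_streamlines):
        a = -(i % 2)
        j = i // 2
        b = (j + 1) // 2 * (1 if j % 2 == 0 else -1)
        off = rng.uniform(-spec.jitter, spec.jitter, size=2)
        shift = (a * spec.pitch + off[0]) * u + (b * spec.pitch + off[1]) * w
        pts = _bezier(p0 + shift, mid + shift, p2 + shift, t)
        out.append(pts)
    return out


def _check_inside(points: np.ndarray, dims, vsize) -> None:
    hi = np.asarray(dims) * np.asarray(vsize)
    if np.any(points < 0) or np.any(points >= hi):
        raise GeometryError("bundle streamline leaves the grid bounding box")


def make_bundle_phantom(grid_dims: tuple[int, int, int],
                        voxel_size: tuple[float, float, float],
                        bundle_specs: list[BundleSpec],
                        lesion_spec: LesionSpec | None = None,
                        params: TissueParams | None = None,
                        seed: int = 0) -> tuple[Phantom, Tractogram]:
    """Realise bundle specs on a grid and return the phantom plus the
    candidate tractogram (the union of all bundle streamlines, ground
    truth retained).  Deterministic given the seed."""
    if params is None:
        params = TissueParams()
    dims = tuple(int(d) for d in grid_dims)
    vsize = tuple(float(v) for v in voxel_size)
    n_vox = int(np.prod(dims))
    rng = substream(seed, "phantom")
    step = 0.1 * min(vsize)

    bundles: list[Bundle] = []
    for spec in bundle_specs:
        sls = _spec_streamlines(spec, rng)
        for s in sls:
            _check_inside(s, dims, vsize)
        weights = rng.uniform(*spec.weight_range, size=len(sls))
        bundles.append(Bundle(sls, weights, tuple(spec.endpoint_nodes)))

    # lesion mask
    lesion_mask = np.zeros(dims, dtype=bool)
    if lesion_spec is not None:
        centers = (np.indices(dims).reshape(3, -1).T + 0.5) * np.asarray(vsize)
        r = np.linalg.norm(centers - np.asarray(lesion_spec.center), axis=1)
        lesion_mask = (r <= lesion_spec.radius).reshape(dims)
        if not (0 <= lesion_spec.damage < 1):
            raise ParameterError("lesion damage must be in [0, 1)")
    lesion_flat = lesion_mask.ravel()

    # segment maps per bundle, lesion damage, per-voxel accounting
    seg_maps: list[list[SegmentMap]] = []
    for bundle in bundles:
        maps = [segment_lengths(s, dims, vsize, step) for s in bundle.streamlines]
        seg_maps.append(maps)
        if lesion_spec is not None and lesion_spec.damage > 0:
            hit = np.array([
                any(lesion_flat[v] for v in m) for m in maps
            ])
            bundle.true_weights = bundle.true_weights * np.where(
                hit, 1.0 - lesion_spec.damage, 1.0)

    intra = np.zeros(n_vox)
    # per-bundle per-voxel direction (length-weighted mean) and presence
    bundle_dirs: list[dict[int, np.ndarray]] = []
    for bundle, maps in zip(bundles, seg_maps):
        acc: dict[int, np.ndarray] = {}
        for w, m in zip(bundle.true_weights, maps):
            for vox, (length, direction) in m.items():
                intra[vox] += w * length
                acc.setdefault(vox, np.zeros(3))
                acc[vox] += length * direction
        dirs = {}
        for vox, v in acc.items():
            nrm = np.linalg.norm(v)
            if nrm > 1e-12:
                dirs[vox] = v / nrm
        bundle_dirs.append(dirs)

    if intra.max(initial=0.0) > MAX_INTRA_FRACTION:
        raise ParameterError(
            f"intra-axonal fraction {intra.max():.3f} exceeds "
            f"{MAX_INTRA_FRACTION}; lower bundle weights or density")

    tissue = intra > 0
    iso = np.where(tissue, BASE_ISO_FRACTION, 1.0)
    if lesion_spec is not None:
        boost = np.minimum(lesion_spec.iso_boost,
                           1.0 - intra - iso)  # never push the sum past 1
        iso = np.where(lesion_flat & tissue, iso + np.maximum(boost, 0.0), iso)
    if np.any(intra + iso > 1.0 + 1e-12):
        raise ParameterError("compartment fractions exceed 1 in some voxel")

    ec_total = np.clip(1.0 - intra - iso, 0.0, None)
    ec_total[~tissue] = 0.0
    ec_map: dict[int, list[tuple[np.ndarray, float]]] = {}
    for vox in np.flatnonzero(tissue):
        present = [dirs[vox] for dirs in bundle_dirs if vox in dirs]
        if not present:
            # weight-zero bundle chord: give the voxel's remainder to iso
            iso[vox] += ec_total[vox]
            ec_total[vox] = 0.0
            continue
        frac = ec_total[vox] / len(present)
        ec_map[int(vox)] = [(d, float(frac)) for d in present]

    # endpoint label volume from streamline endpoints
    labels = np.zeros(dims, dtype=int)
    for bundle in bundles:
        for s in bundle.streamlines:
            for point, node in ((s[0], bundle.endpoint_nodes[0]),
                                (s[-1], bundle.endpoint_nodes[1])):
                idx = tuple(np.floor(point / np.asarray(vsize)).astype(int))
                labels[idx] = node

    affine = np.diag([*vsize, 1.0])
    phantom = Phantom(grid_dims=dims, voxel_size=vsize, bundles=bundles,
                      lesion_mask=lesion_mask, params=params, affine=affine,
                      label_volume=labels, iso_fraction=iso, ec_map=ec_map,
                      intra_fraction=intra, resample_step=step)
    streamlines = [s for b in bundles for s in b.streamlines]
    weights = np.concatenate([b.true_weights for b in bundles]) if bundles \
        else np.empty(0)
    nodes: list[tuple[int, int] | None] = [
        b.endpoint_nodes for b in bundles for _ in b.streamlines]
    tractogram = Tractogram(streamlines, weights,
                            np.zeros(len(streamlines), dtype=bool), nodes)
    return phantom, tractogram


def add_spurious_streamlines(tractogram: Tractogram, phantom: Phantom,
                             n: int, seed: int = 0) -> Tractogram:
    """Append ``n`` streamlines with ground-truth weight zero.

    Spurious paths are straight oblique chords between random interior
    points, so they cross voxels at angles unmatched by any true fibre
    orientation and traverse pure-isotropic background."""
    if n < 0:
        raise ParameterError("n must be nonnegative")
    if n == 0:
        return tractogram
    rng = substream(seed, "spurious")
    hi = np.asarray(phantom.grid_dims) * np.asarray(phantom.voxel_size)
    margin = 0.25 * min(phantom.voxel_size)
    new = []
    min_len = 2.0 * min(phantom.voxel_size)
    while len(new) < n:
        a = rng.uniform(margin, hi - margin)
        b = rng.uniform(margin, hi - margin)
        if np.linalg.norm(b - a) < min_len:
            continue
        t = np.linspace(0, 1, 12)[:, None]
        new.append(a + t * (b - a))
    return Tractogram(
        streamlines=list(tractogram.streamlines) + new,
        true_weights=np.concatenate([tractogram.true_weights, np.zeros(n)]),
        spurious=np.concatenate([tractogram.spurious, np.ones(n, dtype=bool)]),
        endpoint_nodes=list(tractogram.endpoint_nodes) + [None] * n,
    )


def simulate_dwi(phantom: Phantom, scheme: GradientScheme,
                 snr: float | None = None, seed: int = 0,
                 noise: str = "rician") -> np.ndarray:
    """Simulate the b0-normalised DWI volume of a phantom.

    Per voxel the signal is the fraction-weighted sum of compartment
    kernels; every b = 0 sample equals 1 before noise.  With ``snr`` set,
    noise of scale 1/snr is added (Rician by default, Gaussian available
    for analytic checks).  Returns a 4-D array (x, y, z, measurement).
    """
    if snr is not None and snr <= 0:
        raise ParameterError("snr must be positive")
    if noise not in ("rician", "gaussian"):
        raise ParameterError(f"unknown noise model {noise!r}")
    dims, vsize, params = phantom.grid_dims, phantom.voxel_size, phantom.params
    n_vox = phantom.n_voxels
    b, g = scheme.bvals, scheme.bvecs
    sig = np.zeros((n_vox, scheme.n))

    sig += phantom.iso_fraction[:, None] * ball_signal(b, params.d_iso_csf)
    for vox, entries in phantom.ec_map.items():
        for direction, frac in entries:
            sig[vox] += frac * zeppelin_signal(b, g, direction,
                                               params.d_par, params.d_perp)
    for bundle in phantom.bundles:
        for w, s in zip(bundle.true_weights, bundle.streamlines):
            smap = segment_lengths(s, dims, vsize, phantom.resample_step)
            for vox, (length, direction) in smap.items():
                sig[vox] += w * length * stick_signal(b, g, direction,
                                                      params.d_par)
    if snr is not None:
        rng = substream(seed, "noise")
        sigma = 1.0 / snr
        if noise == "gaussian":
            sig = sig + sigma * rng.standard_normal(sig.shape)
        else:
            re = sig + sigma * rng.standard_normal(sig.shape)
            im = sigma * rng.standard_normal(sig.shape)
            sig = np.sqrt(re**2 + im**2)
    return sig.reshape(*dims, scheme.n)


def true_coefficient_vector(phantom: Phantom, tractogram: Tractogram,
                            system_matrix) -> np.ndarray:
    """Ground-truth coefficients aligned with a system matrix's columns
    (intra weights | extra-axonal fractions | isotropic fractions)."""
    n_str = system_matrix.n_streamlines
    if n_str != len(tractogram):
        raise ParameterError("tractogram does not match system matrix")
    x = np.zeros(system_matrix.shape[1])
    x[:n_str] = tractogram.true_weights
    lookup = {}
    for vox, entries in phantom.ec_map.items():
        for direction, frac in entries:
            lookup[(vox, tuple(np.round(direction, 9)))] = frac
    for j, (vox, direction) in enumerate(system_matrix.ec_entries):
        key = (vox, tuple(np.round(direction, 9)))
        x[n_str + j] = lookup.get(key, 0.0)
    iso_offset = n_str + system_matrix.n_ec
    x[iso_offset:iso_offset + system_matrix.n_iso] = \
        phantom.iso_fraction[system_matrix.iso_voxels]
    return x


def two_bundle_phantom(seed: int = 0,
                       grid_dims: tuple[int, int, int] = (10, 10, 3),
                       voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       n_streamlines: int = 6,
                       lesion: bool = False,
                       lesion_damage: float = 0.5,
                       curved: bool = False) -> tuple[Phantom, Tractogram]:
    """Convenience phantom: two orthogonal crossing bundles (left-right and
    front-back) on a small grid, optionally with a lesion on the first
    bundle; the workhorse configuration of the test-bench."""
    nx, ny, nz = grid_dims
    sx, sy, sz = voxel_size
    # axes centred on voxel centres so lattice offsets stay in one row
    ymid = (ny // 2 - 0.5) * sy
    xmid = (nx // 2 - 0.5) * sx
    zmid = (nz // 2 + 0.5) * sz
    bend_a = (0.0, 0.0, 0.4 * sz) if curved else (0.0, 0.0, 0.0)
    specs = [
        BundleSpec(start=(0.3 * sx, ymid, zmid),
                   end=((nx - 0.3) * sx, ymid, zmid),
                   endpoint_nodes=(1, 2), n_streamlines=n_streamlines,
                   pitch=1.0 * sy, jitter=0.2 * sy,
                   weight_range=(0.04, 0.10), bend=bend_a),
        BundleSpec(start=(xmid, 0.3 * sy, zmid),
                   end=(xmid, (ny - 0.3) * sy, zmid),
                   endpoint_nodes=(3, 4), n_streamlines=n_streamlines,
                   pitch=1.0 * sx, jitter=0.2 * sx,
                   weight_range=(0.04, 0.10)),
    ]
    lesion_spec = None
    if lesion:
        # on the left-right bundle, clear of the crossing and of the
        # front-back bundle's lateral extent
        lesion_spec = LesionSpec(center=(1.5 * sx, ymid, zmid),
                                 radius=1.2 * max(voxel_size),
                                 damage=lesion_damage)
    return make_bundle_phantom(grid_dims, voxel_size, specs, lesion_spec,
                               TissueParams(), seed=seed)
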
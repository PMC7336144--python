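"""Diffusion gradient schemes.

A scheme is the ordered list of (b-value, unit direction) pairs of a
diffusion acquisition.  The default protocol emulated throughout the
package is a two-shell scheme with b = 1000 and 2000 s/mm^2, 30 directions
per shell, plus one b = 0 measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .errors import InvalidSchemeError

__all__ = ["GradientScheme", "make_gradient_scheme", "DEFAULT_SHELLS"]

#: the emulated acquisition: two shells of 30 directions each
DEFAULT_SHELLS = [(1000.0, 30), (2000.0, 30)]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientScheme:
    """Per-measurement b-value (s/mm^2) and unit gradient direction.

    Invariants (checked at construction): b >= 0 everywhere, at least one
    b = 0 entry, unit-norm directions for b > 0 and zero vectors for b = 0.
    """

    bvals: np.ndarray  # (n,) s/mm^2
    bvecs: np.ndarray  # (n, 3) unitless

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise InvalidSchemeError(
                f"shape mismatch: bvals {bvals.shape}, bvecs {bvecs.shape}"
            )
        if np.any(bvals < 0):
            raise InvalidSchemeError("negative b-value")
        if not np.any(bvals == 0):
            raise InvalidSchemeError("scheme must contain at least one b=0 entry")
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > _UNIT_TOL):
            raise InvalidSchemeError("b>0 directions must be unit vectors")
        if np.any(norms[~dw] > _UNIT_TOL):
            raise InvalidSchemeError("b=0 entries must have zero direction")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


def _repulsed_directions(n: int, rng: np.random.Generator,
                         n_iter: int = 400, lr: float = 5e-3) -> np.ndarray:
    """Approximately uniform unit directions by antipodal electrostatic
    repulsion from a seeded random start.

    Directions are treated as axes (d and -d equivalent), the convention
    for diffusion encoding, so the energy sums 1/|di-dj| + 1/|di+dj|.
    """
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for _ in range(n_iter):
        diff = v[:, None, :] - v[None, :, :]
        summ = v[:, None, :] + v[None, :, :]
        dd = np.linalg.norm(diff, axis=2)
        ds = np.linalg.norm(summ, axis=2)
        np.fill_diagonal(dd, np.inf)
        np.fill_diagonal(ds, np.inf)
        ds[ds < 1e-9] = np.inf  # guard exact antipodes
        force = (diff / dd[..., None] ** 3).sum(axis=1) + (
            summ / ds[..., None] ** 3
        ).sum(axis=1)
        # project onto the tangent plane and take a small step
        force -= (force * v).sum(axis=1, keepdims=True) * v
        v = v + lr * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def make_gradient_scheme(n_b0: int = 1,
                         shells: list[tuple[float, int]] | None = None,
                         seed: int = 0) -> GradientScheme:
    """Build a multi-shell scheme with near-uniform directions per shell.

    Parameters
    ----------
    n_b0:
        Number of b = 0 measurements, placed first (>= 1).
    shells:
        List of (b, n_directions) with b > 0 and n_directions >= 6.
        Defaults to the emulated two-shell protocol.
    seed:
        Controls the direction sets; the output is a pure function of
        (n_b0, shells, seed).
    """
    if shells is None:
        shells = DEFAULT_SHELLS
    if n_b0 < 1:
        raise InvalidSchemeError("need at least one b=0 measurement")
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for i, (b, ndir) in enumerate(shells):
        if b <= 0:
            raise InvalidSchemeError(f"shell b must be positive, got {b}")
        if ndir < 6:
            raise InvalidSchemeError("need at least 6 directions per shell")
        rng = substream(seed, f"shell-{i}")
        dirs = _repulsed_directions(int(ndir), rng)
        bvals.extend([float(b)] * int(ndir))
        bvecs.extend(dirs)
    return GradientScheme(np.array(bvals), np.vstack(bvecs))


def min_pairwise_angle(directions: np.ndarray) -> float:
    """Smallest pairwise angular distance (radians) in a direction set,
    treating d and -d as the same axis."""
    d = np.asarray(directions, dtype=float)
    dots = np.abs(d @ d.T)
    np.fill_diagonal(dots, -np.inf)
    return float(np.arccos(np.clip(dots.max(), -1.0, 1.0)))
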
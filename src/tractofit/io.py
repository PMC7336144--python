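"""On-disk formats: TCK tractograms, NIfTI volumes, FSL-dialect
bvals/bvecs, and the package's CSV artifacts.

All tabular artifacts are headered CSV so runs diff cleanly; streamlines
are stored in scanner-mm coordinates; voxel indices on disk are 0-based.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram as NibTractogram
from nibabel.streamlines.tck import TckFile

from .connectome import Connectome
from .errors import DataError, FormatError
from .gradients import GradientScheme
from .phantom import Tractogram

__all__ = [
    "write_tractogram", "read_tractogram", "write_dwi", "read_dwi",
    "write_weights_csv", "read_weights_csv", "write_connectome_csv",
    "read_connectome_csv", "write_truth_csv", "read_truth_csv",
]

_BVEC_NORM_TOL = 1e-3


def write_tractogram(path: str, tractogram) -> None:
    """Write streamlines as TCK (scanner mm), preserving order."""
    streamlines = getattr(tractogram, "streamlines", tractogram)
    nt = NibTractogram([np.asarray(s, dtype=np.float32) for s in streamlines],
                       affine_to_rasmm=np.eye(4))
    TckFile(nt).save(path)


def read_tractogram(path: str) -> list[np.ndarray]:
    """Load a TCK file; returns streamlines in mm, order preserved.

    A malformed or truncated file raises :class:`FormatError` rather than
    returning a silent partial read."""
    try:
        tck = nib.streamlines.load(path)
    except Exception as exc:  # nibabel raises several header/IO errors
        raise FormatError(f"cannot read TCK {path!r}: {exc}") from exc
    return [np.asarray(s, dtype=float) for s in tck.streamlines]


def write_dwi(path_nifti: str, path_bvals: str, path_bvecs: str,
              volume: np.ndarray, scheme: GradientScheme,
              affine: np.ndarray | None = None) -> None:
    """Write a 4-D DWI volume plus FSL-dialect gradient files.

    bvals: one space-separated row; bvecs: three rows (x, y, z)."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine)
    nib.save(img, path_nifti)
    with open(path_bvals, "w") as fh:
        fh.write(" ".join(f"{b:.6g}" for b in scheme.bvals) + "\n")
    with open(path_bvecs, "w") as fh:
        for k in range(3):
            fh.write(" ".join(f"{v:.9f}" for v in scheme.bvecs[:, k]) + "\n")


def _load_numeric_rows(path: str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise FormatError(f"empty gradient file {path!r}")
    return np.array(rows)


def read_dwi(path_nifti: str, path_bvals: str, path_bvecs: str
             ) -> tuple[np.ndarray, GradientScheme, np.ndarray]:
    """Load a DWI volume with its gradient table.

    Accepts both FSL row-major and transposed (one entry per row)
    dialects; b>0 directions are renormalised when within 1e-3 of unit
    norm and rejected otherwise.  Returns (volume, scheme, affine).
    """
    img = nib.load(path_nifti)
    vol = np.asarray(img.dataobj, dtype=float)
    bvals = _load_numeric_rows(path_bvals).ravel()
    bvecs = _load_numeric_rows(path_bvecs)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        pass  # ambiguous 3x3: assume rows are entries
    elif bvecs.shape[1] != 3:
        raise FormatError(f"bvecs shape {bvecs.shape} not understood")
    if vol.ndim != 4 or vol.shape[3] != bvals.size or bvecs.shape[0] != bvals.size:
        raise DataError(
            f"gradient count mismatch: volume has {vol.shape[-1] if vol.ndim == 4 else '?'}"
            f" measurements, bvals {bvals.size}, bvecs {bvecs.shape[0]}")
    norms = np.linalg.norm(bvecs, axis=1)
    dw = bvals > 0
    bad = dw & (np.abs(norms - 1.0) > _BVEC_NORM_TOL)
    if np.any(bad):
        raise DataError(f"non-unit bvec at b>0 (norms {norms[bad]})")
    bvecs = bvecs.copy()
    bvecs[dw] /= norms[dw][:, None]
    bvecs[~dw] = 0.0
    return vol, GradientScheme(bvals, bvecs), np.asarray(img.affine)


# ---------------------------------------------------------------------------
# CSV artifacts


def write_weights_csv(path: str, weights: np.ndarray, lengths: np.ndarray,
                      kept: np.ndarray) -> None:
    df = pd.DataFrame({
        "streamline_index": np.arange(len(weights)),
        "weight": weights, "length_mm": lengths,
        "kept": np.asarray(kept, dtype=int),
    })
    df.to_csv(path, index=False, float_format="%.12g")


def read_weights_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_csv(path: str, tractogram: Tractogram) -> None:
    """Ground-truth sidecar keyed by streamline index."""
    nodes = [p if p is not None else (-1, -1) for p in tractogram.endpoint_nodes]
    df = pd.DataFrame({
        "streamline_index": np.arange(len(tractogram)),
        "true_weight": tractogram.true_weights,
        "spurious": tractogram.spurious.astype(int),
        "node_a": [p[0] for p in nodes],
        "node_b": [p[1] for p in nodes],
    })
    df.to_csv(path, index=False, float_format="%.12g")


def read_truth_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_connectome_csv(path: str, connectome: Connectome) -> None:
    """Symmetric matrix with node-name header row/column; the kind goes
    in a leading ``#kind=`` metadata line."""
    labels = connectome.node_labels or [
        f"node{i+1}" for i in range(connectome.n_nodes)]
    with open(path, "w") as fh:
        fh.write(f"#kind={connectome.kind}\n")
        fh.write("," + ",".join(labels) + "\n")
        for lab, row in zip(labels, connectome.matrix):
            fh.write(lab + "," + ",".join(f"{v:.12g}" for v in row) + "\n")


def read_connectome_csv(path: str) -> Connectome:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#kind="):
            raise FormatError(f"{path!r}: missing #kind metadata line")
        kind = first.split("=", 1)[1]
        df = pd.read_csv(fh, index_col=0)
    return Connectome(df.to_numpy(dtype=float), kind, list(df.columns))
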
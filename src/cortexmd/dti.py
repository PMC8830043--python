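"""Diffusion tensor fitting and mean diffusivity.

Per-voxel ordinary least squares on the log signal,
``ln S(g, b) = ln S0 - b g^T D g`` — the default behavior of FSL's
``dtifit`` — followed by MD = trace(D)/3.  No eddy/motion correction; the
mask and (optional) diffusion-to-anatomical affine are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .surface import ScalarVolume

__all__ = [
    "DiffusionProtocol",
    "DWIVolume",
    "TensorVolume",
    "design_matrix",
    "fit_tensor_loglinear",
    "mean_diffusivity",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_dwi_nifti",
    "write_nifti",
    "read_affine_text",
    "write_affine_text",
]

# tensor element order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
TENSOR_ELEMENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


@dataclass
class DiffusionProtocol:
    """b-values (s/mm^2) and unit gradient directions, one per DWI volume.

    Requires at least one b=0 volume and >= 6 non-collinear b>0 directions,
    otherwise the 6 tensor d.o.f. are unidentifiable.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=np.float64).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        if self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvecs must be (n_volumes, 3) matching bvals")
        if not np.any(self.bvals == 0):
            raise ValueError("protocol needs at least one b=0 volume")
        dwi = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if dwi.any() and np.any(np.abs(norms - 1.0) > 1e-4):
            raise ValueError("b>0 gradient vectors must have unit norm (tol 1e-4)")
        if self.n_directions < 6:
            raise ValueError(
                f"protocol has {self.n_directions} non-collinear b>0 directions; >= 6 required"
            )

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def n_directions(self) -> int:
        """Count of non-collinear b>0 directions (antipodal pairs collapse)."""
        g = self.bvecs[self.bvals > 0]
        if len(g) == 0:
            return 0
        # canonical sign so g and -g coincide
        sign = np.where(g[:, [0]] != 0, np.sign(g[:, [0]]), 1.0)
        gc = np.round(g * sign, 6)
        return len(np.unique(gc, axis=0))


@dataclass
class DWIVolume:
    """4-D diffusion signal (x, y, z, volume) with voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


@dataclass
class TensorVolume:
    """Per-voxel symmetric tensor (6 unique elements, mm^2/s) plus ln S0.

    ``d6`` is (x, y, z, 6) ordered Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.  ``valid``
    flags voxels where a fit exists; ``clamped`` flags voxels where
    non-positive signals had to be clamped before taking the log;
    ``negative_definite`` flags fits whose tensor has a negative eigenvalue
    (QC only — MD uses the raw trace).
    """

    d6: np.ndarray
    ln_s0: np.ndarray
    affine: np.ndarray
    valid: np.ndarray
    clamped: np.ndarray | None = None
    negative_definite: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d6 = np.asarray(self.d6, dtype=np.float64)
        if self.d6.ndim != 4 or self.d6.shape[3] != 6:
            raise ValueError("d6 must be (x, y, z, 6)")
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.d6.shape[:3]

    def full_tensors(self) -> np.ndarray:
        """(x, y, z, 3, 3) symmetric tensors."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.d6, -1, 0)
        out = np.empty(self.shape + (3, 3))
        out[..., 0, 0] = dxx
        out[..., 1, 1] = dyy
        out[..., 2, 2] = dzz
        out[..., 0, 1] = out[..., 1, 0] = dxy
        out[..., 0, 2] = out[..., 2, 0] = dxz
        out[..., 1, 2] = out[..., 2, 1] = dyz
        return out


def design_matrix(protocol: DiffusionProtocol) -> np.ndarray:
    """Log-linear design: columns [1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz]; ln S = B @ [ln S0, D6]."""
    b = protocol.bvals
    g = protocol.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor_loglinear(
    dwi: DWIVolume,
    protocol: DiffusionProtocol,
    mask: np.ndarray | None = None,
) -> TensorVolume:
    """OLS tensor fit on the log signal, voxelwise.

    Non-positive signals are clamped to ``1e-6 * S0`` (median b=0 signal per
    voxel) so the log exists; such voxels are flagged ``clamped``.  Raises if
    the gradient scheme is rank deficient (collinear directions).
    """
    if dwi.data.shape[3] != protocol.n_volumes:
        raise ValueError(
            f"DWI has {dwi.data.shape[3]} volumes but protocol lists {protocol.n_volumes}"
        )
    B = design_matrix(protocol)
    if np.linalg.matrix_rank(B) < 7:
        raise ValueError(
            "rank-deficient diffusion protocol: gradient directions are collinear "
            "and cannot identify all 6 tensor elements"
        )
    shape = dwi.data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape must match DWI grid")

    sig = dwi.data[mask]  # (n_voxels, n_volumes)
    s0 = np.median(sig[:, protocol.bvals == 0], axis=1)
    fit_ok = s0 > 0
    eps = 1e-6 * np.where(fit_ok, s0, 1.0)[:, None]
    clamped_vox = np.any(sig <= 0.0, axis=1) & fit_ok
    logsig = np.log(np.maximum(sig, eps))

    pinv = np.linalg.pinv(B)
    coef = logsig @ pinv.T  # (n_voxels, 7)

    d6 = np.full(shape + (6,), np.nan)
    ln_s0 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    clamped = np.zeros(shape, dtype=bool)
    idx = np.nonzero(mask)
    coef[~fit_ok] = np.nan
    d6[idx] = coef[:, 1:]
    ln_s0[idx] = coef[:, 0]
    valid[idx] = fit_ok
    clamped[idx] = clamped_vox

    # QC: negative-definite fits (any eigenvalue < 0)
    neg = np.zeros(shape, dtype=bool)
    if valid.any():
        tensors = TensorVolume(d6, ln_s0, dwi.affine, valid).full_tensors()[valid]
        eig = np.linalg.eigvalsh(tensors)
        neg[valid] = eig[:, 0] < 0
    return TensorVolume(d6, ln_s0, dwi.affine, valid, clamped, neg)


def mean_diffusivity(tensors: TensorVolume) -> ScalarVolume:
    """MD = (Dxx + Dyy + Dzz)/3 per voxel; invalid voxels propagate as NaN."""
    md = tensors.d6[..., :3].sum(axis=-1) / 3.0
    md = np.where(tensors.valid, md, np.nan)
    return ScalarVolume(md, tensors.affine)


# ---------------------------------------------------------------------------
# I/O: FSL-style bval/bvec text, NIfTI-1, plain-text affine


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> DiffusionProtocol:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T  # FSL convention: 3 rows x n columns
    return DiffusionProtocol(bvals, bvecs)


def write_bvals_bvecs(
    protocol: DiffusionProtocol, bval_path: str | Path, bvec_path: str | Path
) -> None:
    np.savetxt(bval_path, protocol.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, protocol.bvecs.T, fmt="%.10g")


def read_dwi_nifti(path: str | Path) -> DWIVolume:
    import nibabel as nib

    img = nib.load(str(path))
    return DWIVolume(np.asarray(img.get_fdata(), dtype=np.float64), img.affine)


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def read_affine_text(path: str | Path) -> np.ndarray:
    """4x4 row-major affine from whitespace-delimited text."""
    A = np.loadtxt(path)
    if A.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 affine, got {A.shape}")
    return A


def write_affine_text(affine: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(affine), fmt="%.12g")
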
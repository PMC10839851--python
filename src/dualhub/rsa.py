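"""Searchlight and ROI representational similarity statistics.

The statistic throughout is the partial Spearman correlation between a
neural RDM and a target (semantic) RDM controlling for a covariate
(visual) RDM, Fisher-z transformed.  The searchlight assigns each sphere's
statistic to its center voxel; spheres with fewer than ``min_voxels``
usable voxels are missing (NaN), never 0.

The searchlight engine ranks each sphere's neural dissimilarity vector
once and evaluates the partial correlation against any number of
(possibly label-permuted) model RDM pairs through the closed form

    rho = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))

on rank vectors, which is algebraically identical to residualizing the
ranks on the covariate ranks (plus intercept) and correlating the
residuals.  This makes the 100-permutation-per-subject null pass a single
matrix product per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .glm import BetaMaps
from .rdm import RDM, DegenerateRDMError, neural_rdm

__all__ = [
    "ROISpec",
    "StatMap",
    "sphere_offsets",
    "sphere_voxels",
    "partial_spearman",
    "fisher_z",
    "SearchlightEngine",
    "searchlight_rsa",
    "roi_rsa",
    "difference_map",
    "PAPER_ROIS",
]

_Z_CLIP = 1.0 - 1e-12


@dataclass
class ROISpec:
    """A spherical region of interest in MNI millimetre space."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not np.all(np.isfinite(self.center_mm)):
            raise ValueError("center_mm must be finite")


#: The four candidate semantic-hub ROIs: 10 mm spheres at MNI centers.
PAPER_ROIS = [
    ROISpec("left_vATL", (-36.0, -18.0, -30.0), 10.0),
    ROISpec("left_AG", (-51.0, -54.0, 15.0), 10.0),
    ROISpec("right_vATL", (33.0, -9.0, -39.0), 10.0),
    ROISpec("right_AG", (66.0, -45.0, 15.0), 10.0),
]


@dataclass
class StatMap:
    """3D field of Fisher-z RSA statistics; NaN marks non-evaluated voxels."""

    values: np.ndarray
    concept_type: str = "unspecified"   # 'event', 'object' or 'difference'
    n_pairs: int = 0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be 3D")

    def to_nifti(self, path) -> None:
        import nibabel as nib
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine),
                 str(path))


def sphere_offsets(radius: float) -> np.ndarray:
    """All integer lattice offsets with Euclidean norm <= radius (inclusive)."""
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = ox ** 2 + oy ** 2 + oz ** 2 <= radius ** 2 + 1e-9
    return np.column_stack([ox[keep], oy[keep], oz[keep]])


def sphere_voxels(center, radius: float, shape: tuple[int, int, int],
                  affine: np.ndarray | None = None, units: str = "vox",
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Voxels whose center lies within ``radius`` of ``center`` (inclusive).

    ``units='vox'``: center and radius in voxel coordinates.
    ``units='mm'``: center in mm (affine required); distances measured in mm.
    Intersected with ``mask`` when given; empty result raises (center
    outside the usable grid/mask).
    """
    shape = tuple(int(s) for s in shape)
    if units == "mm":
        if affine is None:
            raise ValueError("affine required for units='mm'")
        inv = np.linalg.inv(affine)
        c_vox = (inv @ np.append(np.asarray(center, float), 1.0))[:3]
        scale = np.abs(np.diag(np.asarray(affine)[:3, :3]))
        r_vox = radius / scale.min()
    elif units == "vox":
        c_vox = np.asarray(center, dtype=float)
        r_vox = float(radius)
    else:
        raise ValueError("units must be 'vox' or 'mm'")
    lo = np.maximum(np.floor(c_vox - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + r_vox).astype(int) + 1, shape)
    if np.any(lo >= hi):
        raise ValueError("sphere center lies outside the grid")
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                        indexing="ij")
    pts = np.column_stack([g.ravel() for g in grids])
    if units == "mm":
        aff = np.asarray(affine)
        mm = pts @ aff[:3, :3].T + aff[:3, 3]
        keep = np.linalg.norm(mm - np.asarray(center, float), axis=1) \
            <= radius + 1e-9
    else:
        keep = np.linalg.norm(pts - c_vox, axis=1) <= radius + 1e-9
    pts = pts[keep]
    if mask is not None:
        pts = pts[np.asarray(mask, bool)[tuple(pts.T)]]
    if not len(pts):
        raise ValueError("sphere has empty intersection with the mask")
    return pts


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """atanh with clipping so perfect correlations stay finite."""
    return np.arctanh(np.clip(rho, -_Z_CLIP, _Z_CLIP))


def _std_ranks(v: np.ndarray) -> np.ndarray | None:
    """Centered, unit-norm rank vector (average ranks for ties); None if
    the ranks are constant."""
    r = rankdata(v)
    r = r - r.mean()
    n = np.linalg.norm(r)
    if n == 0:
        return None
    return r / n


def partial_spearman(neural: RDM, target: RDM,
                     covariate: RDM) -> tuple[float, float]:
    """Partial Spearman correlation of two RDMs controlling a third.

    Rank-transforms the three lower-triangle vectors, residualizes the
    neural and target ranks on the covariate ranks (with intercept), and
    Pearson-correlates the residuals; returns (rho, Fisher z).  A
    zero-variance covariate degrades gracefully to a plain Spearman
    correlation; a zero-variance neural or target rank vector is a
    degenerate input and returns (nan, nan).
    """
    if not (neural.labels == target.labels == covariate.labels):
        raise ValueError("RDMs must share labels and order")
    x = _std_ranks(neural.vector())
    y = _std_ranks(target.vector())
    c = _std_ranks(covariate.vector())
    if x is None or y is None:
        return (float("nan"), float("nan"))
    if c is None:
        rho = float(x @ y)
    else:
        rx = x - (x @ c) * c        # residual after projection on {1, c}
        ry = y - (y @ c) * c        # (vectors are already centered)
        nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
        if nx < 1e-12 or ny < 1e-12:
            return (float("nan"), float("nan"))
        rho = float(rx @ ry / (nx * ny))
    rho = float(np.clip(rho, -1.0, 1.0))
    return rho, float(fisher_z(rho))


def _pair_permutation_index(perm: np.ndarray, n: int) -> np.ndarray:
    """Index into the lower-triangle pair vector induced by a joint
    row/column label permutation of an n x n symmetric matrix."""
    lut = np.zeros((n, n), dtype=np.int64)
    tri = np.tril_indices(n, k=-1)
    lut[tri] = np.arange(tri[0].size)
    lut[tri[1], tri[0]] = lut[tri]
    pi, pj = perm[tri[0]], perm[tri[1]]
    return lut[pi, pj]


def permuted_model_ranks(target: RDM, covariate: RDM,
                         perms: Sequence[np.ndarray | None]):
    """Standardized rank vectors of jointly permuted model RDM pairs.

    Returns (Y, Z, r_yz): Y and Z are (n_perms, n_pairs) standardized rank
    matrices for the target and covariate; r_yz their per-permutation
    correlation (Z is None for a rank-degenerate covariate).  Entry i uses
    ``perms[i]`` applied to rows and columns of both model RDMs (None means
    the identity).
    """
    tv, cv = target.vector(), covariate.vector()
    n = target.n
    idx = np.stack([np.arange(tv.size) if p is None
                    else _pair_permutation_index(np.asarray(p), n)
                    for p in perms])
    Yr = rankdata(tv[idx], axis=1)
    Yr -= Yr.mean(axis=1, keepdims=True)
    ny = np.linalg.norm(Yr, axis=1)
    if np.any(ny == 0):
        raise DegenerateRDMError("target RDM has zero rank variance")
    Y = Yr / ny[:, None]
    Zr = rankdata(cv[idx], axis=1)
    Zr -= Zr.mean(axis=1, keepdims=True)
    nz = np.linalg.norm(Zr, axis=1)
    if np.all(nz == 0):
        return Y, None, None
    Z = Zr / np.where(nz > 0, nz, 1.0)[:, None]
    return Y, Z, np.einsum("ij,ij->i", Y, Z)


def partial_rho_closed_form(r_xy: np.ndarray, r_xz: np.ndarray,
                            r_yz: np.ndarray) -> np.ndarray:
    """(r_xy - r_xz*r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)), NaN-guarded."""
    denom = (1.0 - np.asarray(r_xz) ** 2) * (1.0 - np.asarray(r_yz) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 1e-24,
                       (r_xy - r_xz * r_yz) / np.sqrt(denom), np.nan)
    return np.clip(rho, -1.0, 1.0)


class SearchlightEngine:
    """Per-subject searchlight machinery with reusable neural ranks.

    Builds, once per subject, the standardized rank vector of the neural
    RDM in every searchlight sphere; :meth:`stat_map` then evaluates the
    Fisher-z partial Spearman map for any (target, covariate, permutation)
    in one matrix product.
    """

    def __init__(self, betas: BetaMaps, labels: Sequence[str],
                 radius_vox: float = 4.0, min_voxels: int = 10,
                 chunk: int = 512):
        self.mask = betas.mask
        self.affine = betas.affine
        self.labels = [str(l) for l in labels]
        sel = betas.select(self.labels)
        P = sel.betas                              # (C, Vmask)
        C = P.shape[0]
        self.n_pairs = C * (C - 1) // 2
        tri = np.tril_indices(C, k=-1)
        shape = self.mask.shape
        flat_idx = np.full(shape, -1, dtype=np.int64)
        flat_idx[self.mask] = np.arange(int(self.mask.sum()))
        centers = np.argwhere(self.mask)
        off = sphere_offsets(radius_vox)
        M = centers.shape[0]
        self.centers = centers
        U = np.full((M, self.n_pairs), np.nan)
        finite = np.all(np.isfinite(P), axis=0)
        for a in range(0, M, chunk):
            cs = centers[a:a + chunk]                       # (m, 3)
            nb = cs[:, None, :] + off[None, :, :]           # (m, K, 3)
            inside = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=2)
            nbc = np.clip(nb, 0, np.asarray(shape) - 1)
            fi = flat_idx[nbc[..., 0], nbc[..., 1], nbc[..., 2]]
            valid = inside & (fi >= 0)
            fi = np.where(valid, fi, 0)
            valid = valid & finite[fi]
            w = valid.astype(float)                         # (m, K)
            A = P[:, fi]                                    # (C, m, K)
            A = np.where(valid[None], A, 0.0)
            n = w.sum(axis=1)                               # (m,)
            ok = n >= max(min_voxels, 2)
            nn = np.where(n > 0, n, 1.0)
            Am = A.transpose(1, 0, 2)                       # (m, C, K)
            S1 = Am.sum(axis=2)                             # (m, C)
            S2 = np.einsum("mik,mjk->mij", Am, Am)          # (m, C, C)
            cov = S2 - S1[:, :, None] * S1[:, None, :] / nn[:, None, None]
            var = np.einsum("mii->mi", cov)
            ok &= np.all(var > 1e-30, axis=1)
            sd = np.sqrt(np.where(var > 0, var, 1.0))
            corr = cov / (sd[:, :, None] * sd[:, None, :])
            dis = 1.0 - corr[:, tri[0], tri[1]]             # (m, n_pairs)
            r = rankdata(dis, axis=1)
            r -= r.mean(axis=1, keepdims=True)
            nrm = np.linalg.norm(r, axis=1)
            ok &= nrm > 0
            r /= np.where(nrm > 0, nrm, 1.0)[:, None]
            r[~ok] = np.nan
            U[a:a + chunk] = r
        self._U = U

    def _rho_matrix(self, target: RDM, covariate: RDM,
                    perms: Sequence[np.ndarray | None]) -> np.ndarray:
        """(n_perms, n_centers) partial Spearman rho under permutations."""
        Y, Z, r_yz = permuted_model_ranks(target, covariate, perms)
        r_xy = Y @ self._U.T                      # (n_perms, M)
        if Z is None:
            return np.clip(r_xy, -1.0, 1.0)
        r_xz = Z @ self._U.T
        return partial_rho_closed_form(r_xy, r_xz, r_yz[:, None])

    def _rho_vector(self, target: RDM, covariate: RDM,
                    perm: np.ndarray | None = None) -> np.ndarray:
        return self._rho_matrix(target, covariate, [perm])[0]

    def stat_map(self, target: RDM, covariate: RDM,
                 perm: np.ndarray | None = None,
                 concept_type: str = "unspecified") -> StatMap:
        z = fisher_z(self._rho_vector(target, covariate, perm))
        vals = np.full(self.mask.shape, np.nan)
        vals[tuple(self.centers.T)] = z
        return StatMap(vals, concept_type, self.n_pairs, self.affine)

    def null_maps(self, target: RDM, covariate: RDM,
                  permutations: Sequence[np.ndarray]) -> np.ndarray:
        """(n_perms, x, y, z) stack of Fisher-z maps under label reshuffling."""
        rho = self._rho_matrix(target, covariate, list(permutations))
        out = np.full((len(permutations), *self.mask.shape), np.nan)
        out[(slice(None), *tuple(self.centers.T))] = fisher_z(rho)
        return out


def searchlight_rsa(betas: BetaMaps, target: RDM, covariate: RDM,
                    radius_vox: float = 4.0, min_voxels: int = 10,
                    concept_type: str = "unspecified") -> StatMap:
    """Whole-mask searchlight map of Fisher-z partial Spearman statistics."""
    missing = [l for l in target.labels if l not in betas.labels]
    if missing or target.labels != covariate.labels:
        raise ValueError(
            f"target/covariate labels do not match beta labels: {missing}")
    eng = SearchlightEngine(betas, target.labels, radius_vox, min_voxels)
    return eng.stat_map(target, covariate, concept_type=concept_type)


def roi_rsa(betas: BetaMaps, roi: ROISpec | np.ndarray, target: RDM,
            covariate: RDM) -> tuple[float, float]:
    """Partial Spearman RSA on the voxel set of one spherical ROI."""
    if isinstance(roi, ROISpec):
        vox = sphere_voxels(roi.center_mm, roi.radius_mm, betas.mask.shape,
                            affine=betas.affine, units="mm", mask=betas.mask)
    else:
        vox = np.asarray(roi)
        vox = vox[betas.mask[tuple(vox.T)]]
        if not len(vox):
            raise ValueError("ROI has empty intersection with the mask")
    stack = betas.select(target.labels).stack()
    patterns = stack[:, vox[:, 0], vox[:, 1], vox[:, 2]]
    nrdm = neural_rdm(patterns, labels=target.labels)
    return partial_spearman(nrdm, target, covariate)


def difference_map(event_map: StatMap, object_map: StatMap) -> StatMap:
    """Voxelwise event z minus object z; missing wherever either is missing."""
    if event_map.values.shape != object_map.values.shape:
        raise ValueError("stat maps are on different grids")
    vals = event_map.values - object_map.values   # NaN propagates
    return StatMap(vals, "difference", event_map.n_pairs, event_map.affine)
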
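"""Design matrices, OLS estimation, LSS single-concept betas, smoothing.

The GLM stage follows the standard event-related construction: stimulus
boxcars convolved with a canonical double-gamma HRF and sampled at volume
acquisition times, a discrete-cosine high-pass basis (180 s cutoff by
default), optional motion covariates, and a constant term.  Estimation is
plain per-voxel OLS (no prewhitening; the simulator's AR(1) component is
mild and the calibration tests quantify the consequence).

Per-concept activation patterns use the least-squares-separate (LSS)
scheme: one GLM per concept, with that concept's trials as the regressor of
interest, all other stimulus trials collapsed into one nuisance regressor,
and catch events in a further regressor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import VolumeSeries

__all__ = [
    "DesignMatrix",
    "BetaMaps",
    "canonical_hrf",
    "build_design_matrix",
    "fit_ols",
    "contrast_map",
    "lss_betas",
    "gaussian_smooth",
    "roi_mean_beta",
]

# canonical double-gamma parameters: response gamma (shape 6, scale 1),
# undershoot gamma (shape 16, scale 1), undershoot ratio 1/6, 32 s support
_HRF_SHAPE1, _HRF_SHAPE2, _HRF_SCALE, _HRF_RATIO = 6.0, 16.0, 1.0, 1.0 / 6.0
_HRF_SUPPORT = 32.0


def _hrf_unnormalized(t: np.ndarray) -> np.ndarray:
    from scipy.stats import gamma
    t = np.asarray(t, dtype=float)
    h = (gamma.pdf(t, _HRF_SHAPE1, scale=_HRF_SCALE)
         - _HRF_RATIO * gamma.pdf(t, _HRF_SHAPE2, scale=_HRF_SCALE))
    return np.where(t < 0, 0.0, h)


_HRF_PEAK: float | None = None


def _hrf_peak_value() -> float:
    global _HRF_PEAK
    if _HRF_PEAK is None:
        tt = np.arange(0.0, _HRF_SUPPORT, 1e-3)
        _HRF_PEAK = float(_hrf_unnormalized(tt).max())
    return _HRF_PEAK


def canonical_hrf(tr: float, duration: float = _HRF_SUPPORT) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr`` seconds.

    Peak delay ~5 s, undershoot ~15 s, normalized to unit peak (on a dense
    grid, so coarse samplings may not contain the exact peak).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration, tr)
    return _hrf_unnormalized(t) / _hrf_peak_value()


def _convolved_column(onsets: np.ndarray, durations: np.ndarray,
                      tr: float, n_volumes: int, dt: float = 0.1) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at volume onsets (t = i*tr)."""
    total = n_volumes * tr
    n_fine = int(np.ceil(total / dt)) + 1
    box = np.zeros(n_fine)
    for on, du in zip(onsets, durations):
        a = int(np.round(on / dt))
        b = int(np.round((on + du) / dt))
        box[a:min(b, n_fine)] = 1.0
    kern = canonical_hrf(dt)
    conv = np.convolve(box, kern)[:n_fine] * dt
    idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[idx]


def dct_highpass_basis(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine high-pass basis: K = floor(2*T/cutoff) columns.

    Column k (k = 1..K) is sqrt(2/N) * cos(pi*(2n+1)*k / (2N)).
    """
    if cutoff <= 0:
        return np.zeros((n_volumes, 0))
    k_max = int(np.floor(2.0 * n_volumes * tr / cutoff))
    n = np.arange(n_volumes)
    cols = [np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * n + 1) * k / (2 * n_volumes))
            for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.zeros((n_volumes, 0))


@dataclass
class DesignMatrix:
    """Named design columns with per-column roles."""

    names: list[str]
    X: np.ndarray
    roles: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[1] != len(self.names) or len(self.roles) != len(self.names):
            raise ValueError("names/roles must match design columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("design column names must be unique")
        if self.roles.count("constant") != 1:
            raise ValueError("design must contain exactly one constant column")

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)

    def to_tsv(self, path: str | Path) -> None:
        import json
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"column_roles": dict(zip(self.names, self.roles))},
                       indent=2))


def build_design_matrix(trials: pd.DataFrame, tr: float, n_volumes: int,
                        hpf_cutoff: float = 180.0,
                        motion: np.ndarray | None = None,
                        condition_order: Sequence[str] | None = None,
                        dt: float = 0.1) -> DesignMatrix:
    """Condition-level design: one convolved column per trial condition,
    DCT high-pass columns, motion covariates, constant last."""
    total = n_volumes * tr
    late = trials[trials["onset"] >= total]
    if len(late):
        raise ValueError(
            "trial onset(s) beyond run end: "
            + ", ".join(f"{r.concept_id}@{r.onset:.1f}s" for r in late.itertuples()))
    if condition_order is None:
        condition_order = list(dict.fromkeys(trials["condition"]))
    names: list[str] = []
    cols: list[np.ndarray] = []
    roles: list[str] = []
    for cond in condition_order:
        sub = trials[trials["condition"] == cond]
        if not len(sub):
            continue
        cols.append(_convolved_column(sub["onset"].to_numpy(),
                                      sub["duration"].to_numpy(),
                                      tr, n_volumes, dt))
        names.append(str(cond))
        roles.append("catch" if cond == "catch" else "task")
    hp = dct_highpass_basis(n_volumes, tr, hpf_cutoff)
    for k in range(hp.shape[1]):
        cols.append(hp[:, k])
        names.append(f"dct_{k + 1:02d}")
        roles.append("nuisance_hpf")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_volumes:
            raise ValueError("motion covariates must have one row per volume")
        for k in range(motion.shape[1]):
            cols.append(motion[:, k])
            names.append(f"motion_{k + 1:02d}")
            roles.append("nuisance_motion")
    cols.append(np.ones(n_volumes))
    names.append("constant")
    roles.append("constant")
    return DesignMatrix(names, np.column_stack(cols), roles)


@dataclass
class BetaMaps:
    """Per-label 3D beta fields stored flat over the brain mask."""

    labels: list[str]
    betas: np.ndarray          # (labels, in-mask voxels)
    mask: np.ndarray           # 3D boolean
    affine: np.ndarray
    residual_variance: np.ndarray | None = None  # (in-mask voxels,)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.betas.shape != (len(self.labels), int(self.mask.sum())):
            raise ValueError("betas shape must be (labels, n_mask_voxels)")

    def map(self, label: str) -> np.ndarray:
        """3D field for one label, NaN outside the mask."""
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = self.betas[self.labels.index(label)]
        return out

    def stack(self) -> np.ndarray:
        """(labels, x, y, z) stack, NaN outside the mask."""
        out = np.full((len(self.labels), *self.mask.shape), np.nan)
        out[:, self.mask] = self.betas
        return out

    def select(self, labels: Sequence[str]) -> "BetaMaps":
        idx = [self.labels.index(str(l)) for l in labels]
        return BetaMaps(list(labels), self.betas[idx], self.mask, self.affine,
                        self.residual_variance)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib
        arr = np.moveaxis(self.stack(), 0, -1).astype(np.float32)
        nib.save(nib.Nifti1Image(arr, self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, labels: Sequence[str],
                   mask: np.ndarray) -> "BetaMaps":
        import nibabel as nib
        img = nib.load(str(path))
        arr = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        return cls(list(labels), arr[:, np.asarray(mask, bool)],
                   np.asarray(mask, bool), np.asarray(img.affine))


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify suspects via tiny R diagonal in a pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(diag))
               if diag[i] < 1e-10 * max(diag[0], 1e-300)]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {bad or 'undetermined'}")


def fit_ols(volumes: VolumeSeries | np.ndarray, design: DesignMatrix,
            mask: np.ndarray | None = None) -> BetaMaps:
    """Per-voxel ordinary least squares over the brain mask."""
    if isinstance(volumes, VolumeSeries):
        if mask is None:
            mask = volumes.brain_mask
        Y = volumes.data[mask].T
        affine = volumes.affine
    else:
        Y = np.asarray(volumes, dtype=float)
        if mask is None:
            mask = np.ones((Y.shape[1], 1, 1), dtype=bool)
        affine = np.eye(4)
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise ValueError("number of volumes does not match design rows")
    _check_rank(X, design.names)
    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    df = X.shape[0] - np.linalg.matrix_rank(X)
    rvar = (resid ** 2).sum(axis=0) / max(df, 1)
    return BetaMaps(list(design.names), B, mask, affine, rvar)


def contrast_map(betas: BetaMaps, weights: Mapping[str, float]) -> np.ndarray:
    """Voxelwise weighted sum of beta maps; NaN outside the mask."""
    unknown = [k for k in weights if k not in betas.labels]
    if unknown:
        raise KeyError(f"unknown beta label(s): {unknown}")
    flat = np.zeros(betas.betas.shape[1])
    for name, w in weights.items():
        flat = flat + w * betas.betas[betas.labels.index(name)]
    out = np.full(betas.mask.shape, np.nan)
    out[betas.mask] = flat
    return out


def lss_betas(volumes: VolumeSeries, trials: pd.DataFrame,
              concept_ids: Sequence[str], tr: float | None = None,
              hpf_cutoff: float = 180.0,
              motion: np.ndarray | None = None,
              dt: float = 0.1) -> BetaMaps:
    """Least-squares-separate per-concept activation maps.

    One GLM per concept: [target concept (all its trials), all other
    stimulus trials, catch events, DCT high-pass, motion, constant]; the
    target column's beta is kept.  Degenerate nuisance columns (all ~zero,
    e.g. in a single-concept run) are dropped.
    """
    if tr is None:
        tr = volumes.tr
    n_vol = volumes.n_volumes
    stim = trials[trials["condition"] != "catch"]
    missing = [c for c in concept_ids if c not in set(stim["concept_id"])]
    if missing:
        raise ValueError(f"concept(s) absent from the trial table: {missing}")
    # per-concept convolved columns; the all-trials column is their sum
    concept_cols = {}
    for cid in concept_ids:
        sub = stim[stim["concept_id"] == cid]
        concept_cols[cid] = _convolved_column(
            sub["onset"].to_numpy(), sub["duration"].to_numpy(), tr, n_vol, dt)
    total_col = np.sum(list(concept_cols.values()), axis=0)
    catch = trials[trials["condition"] == "catch"]
    catch_col = (_convolved_column(catch["onset"].to_numpy(),
                                   catch["duration"].to_numpy(), tr, n_vol, dt)
                 if len(catch) else None)
    hp = dct_highpass_basis(n_vol, tr, hpf_cutoff)
    nuis = [hp[:, k] for k in range(hp.shape[1])]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        nuis += [motion[:, k] for k in range(motion.shape[1])]
    Y = volumes.masked_timeseries()
    out = np.empty((len(concept_ids), Y.shape[1]))
    for i, cid in enumerate(concept_ids):
        target = concept_cols[cid]
        other = total_col - target
        cols = [target]
        names = [cid]
        if np.max(np.abs(other)) > 1e-12:
            cols.append(other)
            names.append("other_trials")
        if catch_col is not None and np.max(np.abs(catch_col)) > 1e-12:
            cols.append(catch_col)
            names.append("catch")
        cols += nuis + [np.ones(n_vol)]
        names += [f"nuis_{k}" for k in range(len(nuis))] + ["constant"]
        X = np.column_stack(cols)
        _check_rank(X, names)
        out[i] = (np.linalg.pinv(X) @ Y)[0]
    return BetaMaps(list(concept_ids), out, volumes.brain_mask, volumes.affine)


def _voxel_sizes(affine: np.ndarray) -> np.ndarray:
    lin = np.asarray(affine, dtype=float)[:3, :3]
    off = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off)) > 1e-6 * max(np.max(np.abs(lin)), 1e-300):
        raise ValueError("only axis-aligned affines are supported for smoothing")
    return np.abs(np.diag(lin))


def gaussian_smooth(field: np.ndarray, fwhm_mm: float, affine: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Mask-renormalized separable Gaussian smoothing.

    sigma (voxels) = fwhm / (2*sqrt(2*ln 2)) / voxel_size per axis.  When a
    mask is given, the kernel is renormalized at edges so a constant field
    stays constant inside the mask; outside-mask voxels return NaN.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    field = np.asarray(field, dtype=float)
    if fwhm_mm == 0:
        return field.copy()
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / _voxel_sizes(affine)
    is4d = field.ndim == 4
    if mask is None:
        mask = np.ones(field.shape[:3], dtype=bool)
    m = mask.astype(float)
    sm_mask = ndimage.gaussian_filter(m, sigma)

    def _one(vol: np.ndarray) -> np.ndarray:
        num = ndimage.gaussian_filter(np.where(mask, vol, 0.0), sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / sm_mask
        return np.where(mask, out, np.nan)

    if is4d:
        return np.stack([_one(field[..., t]) for t in range(field.shape[3])],
                        axis=-1)
    return _one(field)


def roi_mean_beta(betas: BetaMaps, roi_voxels: np.ndarray) -> dict[str, float]:
    """Arithmetic mean beta over the ROI voxels, per label."""
    roi_voxels = np.asarray(roi_voxels)
    if roi_voxels.ndim != 2 or roi_voxels.shape[1] != 3:
        raise ValueError("roi_voxels must be an (N, 3) voxel index array")
    inroi = betas.mask[tuple(roi_voxels.T)]
    if not inroi.any():
        raise ValueError("ROI has empty intersection with the brain mask")
    stack = betas.stack()
    vals = stack[:, roi_voxels[inroi, 0], roi_voxels[inroi, 1], roi_voxels[inroi, 2]]
    return {lab: float(np.nanmean(vals[i])) for i, lab in enumerate(betas.labels)}
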
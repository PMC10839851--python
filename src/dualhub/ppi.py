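"""Generalized psychophysiological interaction (gPPI) connectivity.

A seed region's time series is summarized by its first eigenvariate; the
gPPI design then contains (i) the seed series, (ii) one HRF-convolved
psychological regressor per condition, (iii) one seed-by-condition
interaction regressor per condition, (iv) motion covariates, plus a
constant.  Contrasts between interaction betas test condition-dependent
changes in seed-to-voxel coupling.

Two interaction constructions are available: ``bold_product`` (default;
mean-centered seed times mean-centered condition indicator, formed at BOLD
resolution) and ``deconvolved`` (ridge-regularized deconvolution of the
seed against the HRF, product at neural resolution, reconvolution — the
construction used by deconvolution-based PPI toolboxes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import DesignMatrix, _check_rank, _convolved_column, canonical_hrf
from .volumes import VolumeSeries

__all__ = ["SeedSeries", "first_eigenvariate", "build_ppi_design",
           "ppi_contrast"]


@dataclass
class SeedSeries:
    """Unit-scale seed summary time series, sign-aligned with the ROI mean."""

    roi_name: str
    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 1:
            raise ValueError("seed series must be 1D")


def first_eigenvariate(volumes: VolumeSeries, roi_voxels: np.ndarray,
                       roi_name: str = "roi") -> SeedSeries:
    """First left singular vector of the ROI's time x voxel matrix.

    Columns are mean-centered; the output is scaled by the first singular
    value and sign-fixed so its correlation with the ROI mean series is
    non-negative.
    """
    roi_voxels = np.asarray(roi_voxels)
    Y = volumes.data[roi_voxels[:, 0], roi_voxels[:, 1], roi_voxels[:, 2], :].T
    keep = np.all(np.isfinite(Y), axis=0) & (Y.std(axis=0) > 0)
    Y = Y[:, keep]
    if Y.shape[1] < 2:
        raise ValueError(
            f"ROI '{roi_name}' has {Y.shape[1]} usable voxel(s); "
            "need at least 2 with finite, non-constant series")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Yc, full_matrices=False)
    ev = u[:, 0] * s[0] / np.sqrt(Y.shape[0])
    mean_series = Yc.mean(axis=1)
    if np.dot(ev, mean_series) < 0:
        ev = -ev
    return SeedSeries(roi_name, ev)


def _condition_indicator(trials: pd.DataFrame, cond: str, tr: float,
                         n_volumes: int) -> np.ndarray:
    """Unconvolved condition indicator resampled at volume times."""
    sub = trials[trials["condition"] == cond]
    ind = np.zeros(n_volumes)
    t = np.arange(n_volumes) * tr
    for row in sub.itertuples():
        ind[(t >= row.onset) & (t < row.onset + row.duration)] = 1.0
    return ind


def _deconvolve(seed: np.ndarray, tr: float, ridge: float = 1e-2) -> np.ndarray:
    """Ridge-regularized least-squares deconvolution of a BOLD series
    against the canonical HRF, at volume resolution."""
    n = seed.size
    kern = canonical_hrf(tr)
    H = np.zeros((n, n))
    for i in range(min(len(kern), n)):
        H += np.diag(np.full(n - i, kern[i] * tr), -i)
    A = H.T @ H
    lam = ridge * np.trace(A) / n
    return np.linalg.solve(A + lam * np.eye(n), H.T @ seed)


def build_ppi_design(seed: SeedSeries, trials: pd.DataFrame, tr: float,
                     n_volumes: int, motion: np.ndarray | None = None,
                     mode: str = "bold_product",
                     conditions: list[str] | None = None) -> DesignMatrix:
    """gPPI design: seed + psychological + interaction + motion + constant.

    Psychological columns are HRF-convolved condition boxcars.  The seed
    column and each condition indicator are mean-centered before the
    product so main effects do not leak into the interactions.
    """
    if mode not in ("bold_product", "deconvolved"):
        raise ValueError(f"unknown PPI mode: {mode!r}")
    if conditions is None:
        conditions = list(dict.fromkeys(trials["condition"]))
    s = seed.series
    if s.size != n_volumes:
        raise ValueError("seed series length must equal n_volumes")
    sc = s - s.mean()
    if mode == "deconvolved":
        neural = _deconvolve(s, tr)
        neural = neural - neural.mean()
        kern = canonical_hrf(tr)
    names, cols, roles = ["seed"], [sc], ["seed"]
    for cond in conditions:
        sub = trials[trials["condition"] == cond]
        if not len(sub):
            raise ValueError(f"condition '{cond}' absent from trials")
        cols.append(_convolved_column(sub["onset"].to_numpy(),
                                      sub["duration"].to_numpy(),
                                      tr, n_volumes))
        names.append(f"psy_{cond}")
        roles.append("catch" if cond == "catch" else "task")
    for cond in conditions:
        ind = _condition_indicator(trials, cond, tr, n_volumes)
        indc = ind - ind.mean()
        if mode == "bold_product":
            inter = sc * indc
        else:
            inter = np.convolve(neural * indc, kern)[:n_volumes] * tr
        cols.append(inter)
        names.append(f"ppi_{cond}")
        roles.append("ppi")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        for k in range(motion.shape[1]):
            cols.append(motion[:, k])
            names.append(f"motion_{k + 1:02d}")
            roles.append("nuisance_motion")
    cols.append(np.ones(n_volumes))
    names.append("constant")
    roles.append("constant")
    return DesignMatrix(names, np.column_stack(cols), roles)


def ppi_contrast(volumes: VolumeSeries | np.ndarray, design: DesignMatrix,
                 pair: tuple[str, str]) -> np.ndarray:
    """Voxelwise interaction-beta difference beta(ppi_a) - beta(ppi_b)."""
    cond_a, cond_b = pair
    for c in (cond_a, cond_b):
        if f"ppi_{c}" not in design.names:
            raise KeyError(f"no interaction column for condition '{c}'")
    if isinstance(volumes, VolumeSeries):
        Y = volumes.masked_timeseries()
        mask = volumes.brain_mask
    else:
        Y = np.asarray(volumes, dtype=float)
        mask = None
    _check_rank(design.X, design.names)
    B = np.linalg.pinv(design.X) @ Y
    diff = (B[design.names.index(f"ppi_{cond_a}")]
            - B[design.names.index(f"ppi_{cond_b}")])
    if mask is None:
        return diff
    out = np.full(mask.shape, np.nan)
    out[mask] = diff
    return out
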
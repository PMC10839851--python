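"""Two-stage Monte Carlo permutation inference with TFCE correction.

Stage 1 builds, for each subject, a null distribution of RSA statistics by
jointly reshuffling the concept labels of the semantic and visual model
RDMs (the neural RDM is untouched).  Stage 2 draws, many times, one null
per subject and averages them, giving the group-level null.  Searchlight
maps are corrected familywise with threshold-free cluster enhancement
(TFCE) and the max-statistic over each null draw; ROI statistics use the
rank of the observed group mean in the null draws.

Univariate and PPI contrast maps, which have no label structure to
permute, are tested with whole-map sign flipping across subjects and the
same max-statistic correction.

All p-values use (1 + #{null >= observed}) / (1 + n): ties count against
the observed value and p can never be 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .glm import BetaMaps
from .rdm import RDM
from .rsa import ROISpec, SearchlightEngine, StatMap, roi_rsa

__all__ = [
    "NullSet",
    "TFCEParams",
    "random_permutations",
    "permuted_stat",
    "subject_null_maps",
    "subject_null_scalars",
    "group_null",
    "tfce",
    "tfce_max_stack",
    "corrected_map_p",
    "roi_p",
    "signflip_group_test",
]


@dataclass
class NullSet:
    """A stack of permutation-null maps or scalars at one inference level."""

    level: str                       # 'subject' or 'group'
    values: np.ndarray               # (n, ...) maps or (n,) scalars
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.level not in ("subject", "group"):
            raise ValueError("level must be 'subject' or 'group'")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class TFCEParams:
    """TFCE exponents and integration settings.

    Defaults E = 0.5, H = 2, dh = max/100, 26-connectivity — the
    field-standard choices for statistic maps.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float = 0.01                 # threshold step as a fraction of map max
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if not 0 < self.dh <= 1:
            raise ValueError("dh must be in (0, 1]")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def n_steps(self) -> int:
        return max(int(round(1.0 / self.dh)), 1)

    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, order)


def random_permutations(n_labels: int, n_perms: int,
                        seed: int) -> list[np.ndarray]:
    """Seeded uniform label permutations (bijections over concepts)."""
    rng = np.random.default_rng(seed)
    return [rng.permutation(n_labels) for _ in range(n_perms)]


def permuted_stat(betas: BetaMaps, target: RDM, covariate: RDM,
                  permutation: np.ndarray | None,
                  roi: ROISpec | np.ndarray | None = None,
                  radius_vox: float = 4.0, min_voxels: int = 10,
                  joint: bool = True):
    """RSA statistic after reshuffling the model RDM labels.

    The same permutation is applied to rows and columns of both the target
    and covariate RDMs (``joint=True``, the default; ``joint=False``
    permutes only the target, leaving the covariate aligned with the
    data).  The neural RDM is never permuted.  Returns a StatMap
    (searchlight) or an (rho, z) pair (ROI).
    """
    if permutation is not None:
        permutation = np.asarray(permutation)
        if sorted(permutation.tolist()) != list(range(len(target.labels))):
            raise ValueError("permutation is not a bijection over labels")
        t = target.permute(permutation)
        c = covariate.permute(permutation) if joint else covariate
    else:
        t, c = target, covariate
    if roi is not None:
        return roi_rsa(betas, roi, t, c)
    eng = SearchlightEngine(betas, target.labels, radius_vox, min_voxels)
    return eng.stat_map(t, c)


def subject_null_maps(engine: SearchlightEngine, target: RDM, covariate: RDM,
                      n_perms: int, seed: int) -> NullSet:
    """Stage-1 searchlight null maps for one subject by label reshuffling."""
    perms = random_permutations(len(target.labels), n_perms, seed)
    return NullSet("subject", engine.null_maps(target, covariate, perms),
                   seed=seed)


def subject_null_scalars(betas: BetaMaps, roi: ROISpec | np.ndarray,
                         target: RDM, covariate: RDM, n_perms: int,
                         seed: int) -> NullSet:
    """Stage-1 ROI null statistics (Fisher z) for one subject."""
    from .rdm import neural_rdm
    from .rsa import sphere_voxels
    if isinstance(roi, ROISpec):
        vox = sphere_voxels(roi.center_mm, roi.radius_mm, betas.mask.shape,
                            affine=betas.affine, units="mm", mask=betas.mask)
    else:
        vox = np.asarray(roi)
    stack = betas.select(target.labels).stack()
    patterns = stack[:, vox[:, 0], vox[:, 1], vox[:, 2]]
    nrdm = neural_rdm(patterns, labels=target.labels)
    from .rsa import _std_ranks, fisher_z, partial_rho_closed_form, \
        permuted_model_ranks
    x = _std_ranks(nrdm.vector())
    if x is None:
        return NullSet("subject", np.full(n_perms, np.nan), seed=seed)
    perms = random_permutations(len(target.labels), n_perms, seed)
    Y, Z, r_yz = permuted_model_ranks(target, covariate, perms)
    r_xy = Y @ x
    if Z is None:
        rho = np.clip(r_xy, -1.0, 1.0)
    else:
        rho = partial_rho_closed_form(r_xy, Z @ x, r_yz)
    return NullSet("subject", np.asarray(fisher_z(rho)), seed=seed)


def group_null(subject_nulls: Sequence[NullSet], n_draws: int,
               seed: int) -> NullSet:
    """Stage-2 Monte Carlo group null: each draw averages one uniformly
    chosen null per subject (independent across draws)."""
    if not subject_nulls or any(s.n < 1 for s in subject_nulls):
        raise ValueError("every subject must contribute at least one null")
    rng = np.random.default_rng(seed)
    picks = [rng.integers(0, s.n, size=n_draws) for s in subject_nulls]
    acc = np.zeros((n_draws, *subject_nulls[0].values.shape[1:]))
    cnt = np.zeros_like(acc)
    for s, idx in zip(subject_nulls, picks):
        v = s.values[idx]
        good = np.isfinite(v)
        acc += np.where(good, v, 0.0)
        cnt += good
    with np.errstate(invalid="ignore", divide="ignore"):
        out = acc / cnt
    return NullSet("group", out, seed=seed)


def group_mean(subject_values: Sequence[np.ndarray]) -> np.ndarray:
    """Observed group mean; missing values never enter the average
    (per-voxel valid-subject counts in the denominator)."""
    stack = np.asarray(subject_values, dtype=float)
    good = np.isfinite(stack)
    cnt = good.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(good, stack, 0.0).sum(axis=0) / cnt


def tfce(field_3d: np.ndarray, params: TFCEParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    For each voxel, sum_h e(h)^E * h^H * dh over thresholds h up to the map
    maximum, where e(h) is the extent of the supra-threshold cluster
    containing the voxel.  Negative values are processed on the negated map
    and returned negative; non-finite values are treated as 0 support.
    """
    if params is None:
        params = TFCEParams()
    f = np.asarray(field_3d, dtype=float)
    f = np.where(np.isfinite(f), f, 0.0)
    out = np.zeros_like(f)
    struct = params.structure()
    for sign in (1.0, -1.0):
        g = np.where(sign * f > 0, sign * f, 0.0)
        gmax = g.max()
        if gmax <= 0:
            continue
        dh = gmax / params.n_steps
        for k in range(1, params.n_steps + 1):
            h = k * dh
            sup = g >= h
            lab, nlab = ndimage.label(sup, structure=struct)
            if nlab == 0:
                continue
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            out += sign * (sizes[lab] ** params.E) * (h ** params.H) * dh * sup
    return out


def _tfce_max_positive(maps: np.ndarray, params: TFCEParams) -> np.ndarray:
    """Max positive TFCE per map, batched over a (n, x, y, z) stack.

    Each map is normalized by its own maximum; clusters across all maps at
    each relative threshold are labelled in one pass over a 4D stack whose
    first axis carries no connectivity.
    """
    n = maps.shape[0]
    g = np.where(np.isfinite(maps) & (maps > 0), maps, 0.0)
    gmax = g.reshape(n, -1).max(axis=1)
    active = gmax > 0
    out = np.zeros(n)
    if not active.any():
        return out
    gn = np.zeros_like(g)
    gn[active] = g[active] / gmax[active, None, None, None]
    struct4 = np.zeros((3, 3, 3, 3), dtype=bool)
    struct4[1] = params.structure()
    acc = np.zeros_like(gn, dtype=np.float64)
    du = 1.0 / params.n_steps
    for k in range(1, params.n_steps + 1):
        u = k * du
        sup = gn >= u
        lab, nlab = ndimage.label(sup, structure=struct4)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        acc += (sizes[lab] ** params.E) * (u ** params.H) * du * sup
    out = acc.reshape(n, -1).max(axis=1) * gmax ** (params.H + 1.0)
    return out


def tfce_max_stack(maps: np.ndarray, params: TFCEParams | None = None,
                   two_sided: bool = False) -> np.ndarray:
    """Per-map maximum TFCE statistic over a stack of null maps."""
    if params is None:
        params = TFCEParams()
    maps = np.asarray(maps, dtype=float)
    pos = _tfce_max_positive(maps, params)
    if two_sided:
        return np.maximum(pos, _tfce_max_positive(-maps, params))
    return pos


def corrected_map_p(observed: StatMap | np.ndarray, group_nulls: NullSet,
                    params: TFCEParams | None = None,
                    two_sided: bool = False) -> np.ndarray:
    """FWE-corrected voxelwise p-values by the max-TFCE statistic.

    p(v) = (1 + #{draws whose maximum TFCE >= observed TFCE at v}) / (1 + n).
    Two-sided tests compare |TFCE| of the signed observed map with the
    per-draw max of |TFCE|.
    """
    if params is None:
        params = TFCEParams()
    obs = observed.values if isinstance(observed, StatMap) else np.asarray(observed)
    nulls = group_nulls.values
    if nulls.shape[1:] != obs.shape:
        raise ValueError("null maps and observed map are on different grids")
    obs_tfce = tfce(obs, params)
    stat = np.abs(obs_tfce) if two_sided else obs_tfce
    null_max = tfce_max_stack(nulls, params, two_sided=two_sided)
    exceed = (null_max[:, None] >= stat.ravel()[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + group_nulls.n)
    return p.reshape(obs.shape)


def roi_p(observed: float, group_nulls: NullSet) -> float:
    """Rank p-value of an observed group statistic in the null draws."""
    nulls = group_nulls.values
    if nulls.ndim != 1 or nulls.size < 1:
        raise ValueError("group_nulls must hold at least one scalar draw")
    return float((1.0 + np.sum(nulls >= observed)) / (1.0 + nulls.size))


def signflip_group_test(subject_maps: np.ndarray, n_flips: int = 1000,
                        seed: int = 0, two_sided: bool = False,
                        return_t: bool = False):
    """One-sample group test of a stack of contrast maps against zero.

    Random whole-subject sign flips of the one-sample t map with
    max-statistic FWE correction.  When 2**n_subjects <= n_flips the full
    flip set is enumerated (exact test; the identity flip counts in the
    numerator and denominator); otherwise ``n_flips`` random flips are
    drawn and p = (1 + #{max >= observed}) / (1 + n_flips).
    """
    maps = np.asarray(subject_maps, dtype=float)
    n_sub = maps.shape[0]
    if n_sub < 4:
        raise ValueError("need at least 4 subjects for sign-flip inference")
    flat = maps.reshape(n_sub, -1)
    finite = np.all(np.isfinite(flat), axis=0)

    def tstat(signs: np.ndarray) -> np.ndarray:
        y = signs[:, None] * flat[:, finite]
        m = y.mean(axis=0)
        sd = y.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = m / (sd / np.sqrt(n_sub))
        return np.where(sd > 0, t, 0.0)

    t_obs = tstat(np.ones(n_sub))
    stat_obs = np.abs(t_obs) if two_sided else t_obs
    exhaustive = 2 ** n_sub <= n_flips
    if exhaustive:
        flips = [np.array(s) for s in itertools.product((1.0, -1.0),
                                                        repeat=n_sub)]
    else:
        rng = np.random.default_rng(seed)
        flips = [rng.choice([1.0, -1.0], size=n_sub) for _ in range(n_flips)]
    maxes = np.empty(len(flips))
    for i, s in enumerate(flips):
        t = tstat(s)
        maxes[i] = np.max(np.abs(t) if two_sided else t)
    exceed = (maxes[:, None] >= stat_obs[None, :]).sum(axis=0)
    if exhaustive:
        p_flat = exceed / len(flips)
    else:
        p_flat = (1.0 + exceed) / (1.0 + len(flips))
    p = np.ones(flat.shape[1])
    p[finite] = p_flat
    p = p.reshape(maps.shape[1:])
    if return_t:
        tmap = np.full(flat.shape[1], np.nan)
        tmap[finite] = t_obs
        return p, tmap.reshape(maps.shape[1:])
    return p
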
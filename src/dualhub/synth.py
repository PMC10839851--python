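"""Synthetic study generator: concept spaces, trial designs, BOLD volumes.

The generator emulates the study design under analysis — 60 concepts
(30 events, 30 objects) each shown 4 times across 4 randomized blocks,
2.5 s stimuli, ISI jittered uniformly on [1, 4] s (mean 2.5 s), one catch
question per concept (25% of trials), TR 1.7 s — and plants voxel patterns
whose pairwise correlation distance is, by construction, proportional to a
weighted mixture of the semantic RDM and the visual RDM within each
signal-carrying region.

Plant construction.  Within a region, each concept's pattern is the image
of the vector [sqrt(w_sem)*s_hat, sqrt(w_vis)*v_hat] under a fixed seeded
orthonormal linear map whose columns are also orthogonal to the constant
voxel vector (s_hat: unit-norm semantic vector; v_hat: unit-norm centered
mean visual feature).  Orthonormality preserves inner products and the
zero-voxel-mean property turns pattern Pearson correlation into the feature
cosine, so

    1 - corr(p_i, p_j) = (w_sem*d_sem_ij + w_vis*d_vis_ij) / (w_sem + w_vis)

exactly when exemplar jitter is zero — a rank-perfect plant of the target
mixture RDM.  Noise is AR(1) plus white Gaussian plus 3 slow cosine drift
terms; a per-subject log-normal gain provides between-subject spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import glm
from .volumes import VolumeSeries, default_affine

__all__ = [
    "ConceptSet",
    "RegionSignal",
    "SignalSpec",
    "make_concept_space",
    "make_design",
    "validate_design",
    "simulate_subject",
    "write_subject",
    "write_concepts",
]


@dataclass
class ConceptSet:
    """Concept ids with type labels, semantic vectors and exemplar features."""

    concept_ids: list[str]
    concept_types: list[str]                 # 'event' or 'object'
    semantic_vectors: np.ndarray             # (n, D)
    exemplar_features: np.ndarray            # (n, 4, F)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.semantic_vectors = np.asarray(self.semantic_vectors, dtype=float)
        self.exemplar_features = np.asarray(self.exemplar_features, dtype=float)
        n = len(self.concept_ids)
        if len(self.concept_types) != n:
            raise ValueError("concept_types length mismatch")
        if set(self.concept_types) - {"event", "object"}:
            raise ValueError("concept_type must be 'event' or 'object'")
        if self.semantic_vectors.shape[0] != n or self.exemplar_features.shape[0] != n:
            raise ValueError("vector arrays must have one row per concept")
        if self.exemplar_features.shape[1] != 4:
            raise ValueError("every concept needs exactly 4 exemplar vectors")
        if np.any(np.linalg.norm(self.semantic_vectors, axis=1) == 0):
            raise ValueError("semantic vectors must have nonzero norm")

    @property
    def n(self) -> int:
        return len(self.concept_ids)

    def ids_of_type(self, concept_type: str) -> list[str]:
        return [c for c, t in zip(self.concept_ids, self.concept_types)
                if t == concept_type]

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.concept_ids)}
        return np.array([lookup[str(c)] for c in ids])


def _ones_preserving_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Random orthogonal map that fixes the all-ones direction, so Pearson
    correlations between rotated vectors are preserved exactly."""
    ones = np.ones((dim, 1)) / np.sqrt(dim)
    g = rng.normal(size=(dim, dim - 1))
    g -= ones @ (ones.T @ g)
    b, _ = np.linalg.qr(g)
    q, _ = np.linalg.qr(rng.normal(size=(dim - 1, dim - 1)))
    return ones @ ones.T + b @ q @ b.T


def make_concept_space(n_event: int, n_object: int, dim: int,
                       n_clusters: int = 3, seed: int = 0,
                       feature_dim: int | None = None,
                       cluster_spread: float = 0.5,
                       exemplar_jitter: float = 0.3,
                       mirror_types: bool = False) -> ConceptSet:
    """Draw a clustered concept space with 4 exemplar feature vectors each.

    Semantic vectors are drawn around per-type cluster centroids so the
    semantic RDM has block structure; exemplar features are a shared
    per-concept visual component plus exemplar jitter (the visual space has
    its own, independent cluster structure so it acts as a genuine
    covariate rather than a copy of the semantic space).

    ``mirror_types=True`` makes the object-concept geometry an orthogonally
    rotated copy of the event-concept geometry: the two types then have
    bit-identical semantic and visual RDMs while occupying different
    directions of feature (and hence voxel) space.  This matched-geometry
    control isolates regional weight differences from stimulus-set
    differences in event-vs-object comparisons.
    """
    if n_event < 2 or n_object < 2 or dim < 2:
        raise ValueError("need >= 2 concepts per type and dim >= 2")
    if n_clusters > min(n_event, n_object):
        raise ValueError("n_clusters exceeds concepts per type")
    if mirror_types and n_event != n_object:
        raise ValueError("mirror_types requires n_event == n_object")
    if feature_dim is None:
        feature_dim = dim
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    types: list[str] = []
    sem = []
    vis_base = []
    for tname, count in (("event", n_event), ("object", n_object)):
        if mirror_types and tname == "object":
            break
        centroids = rng.normal(size=(n_clusters, dim)) * 2.0
        vis_centroids = rng.normal(size=(n_clusters, feature_dim)) * 2.0
        assign = np.arange(count) % n_clusters
        for i in range(count):
            ids.append(f"{tname}_{i + 1:02d}")
            types.append(tname)
            sem.append(centroids[assign[i]]
                       + cluster_spread * rng.normal(size=dim))
            vis_base.append(vis_centroids[rng.integers(n_clusters)]
                            + cluster_spread * rng.normal(size=feature_dim))
    sem = np.asarray(sem)
    vis_base = np.asarray(vis_base)
    exemplars = (vis_base[:, None, :]
                 + exemplar_jitter * rng.normal(size=(len(ids), 4, feature_dim)))
    if mirror_types:
        q_sem, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
        r_vis = _ones_preserving_rotation(feature_dim, rng)
        ids += [f"object_{i + 1:02d}" for i in range(n_object)]
        types += ["object"] * n_object
        sem = np.vstack([sem, sem @ q_sem])
        exemplars = np.concatenate([exemplars, exemplars @ r_vis.T], axis=0)
    return ConceptSet(ids, types, sem, exemplars, seed=seed)


def make_design(concepts: ConceptSet, n_blocks: int = 4,
                stim_dur: float = 2.5, isi_low: float = 1.0,
                isi_high: float = 4.0, catch_rate: float = 0.25,
                catch_dur: float = 1.0, seed: int = 0,
                t_start: float = 10.0) -> pd.DataFrame:
    """Randomized trial table: each block is a fresh permutation of all
    concepts; ISIs uniform on [isi_low, isi_high]; exactly one catch
    question per concept, balanced across blocks.

    ``catch_rate`` must equal 1/n_blocks (the one-catch-per-concept rule
    fixes the rate) or 0 for a catch-free design.
    """
    if isi_low > isi_high:
        raise ValueError("isi_low must be <= isi_high")
    if stim_dur <= 0:
        raise ValueError("stim_dur must be positive")
    if catch_rate != 0 and abs(catch_rate - 1.0 / n_blocks) > 1e-9:
        raise ValueError(
            f"catch_rate {catch_rate} is incompatible with one catch per "
            f"concept over {n_blocks} blocks (must be 0 or 1/{n_blocks})")
    rng = np.random.default_rng(seed)
    n = concepts.n
    # balanced catch assignment: concept -> block of its catch question
    catch_block = {}
    if catch_rate != 0:
        order = rng.permutation(n)
        for j, ci in enumerate(order):
            catch_block[concepts.concept_ids[ci]] = (j % n_blocks) + 1
    rows = []
    t = float(t_start)
    for block in range(1, n_blocks + 1):
        for ci in rng.permutation(n):
            cid = concepts.concept_ids[ci]
            ctype = concepts.concept_types[ci]
            has_catch = catch_block.get(cid) == block
            rows.append(dict(onset=t, duration=stim_dur, concept_id=cid,
                             condition=ctype, block=block,
                             catch_follows=bool(has_catch)))
            t += stim_dur
            if has_catch:
                rows.append(dict(onset=t, duration=catch_dur, concept_id=cid,
                                 condition="catch", block=block,
                                 catch_follows=False))
                t += catch_dur
            t += float(rng.uniform(isi_low, isi_high))
    return pd.DataFrame(rows)


def validate_design(design: pd.DataFrame, concepts: ConceptSet) -> None:
    """Raise if the trial table violates its invariants."""
    if not (np.diff(design["onset"].to_numpy()) > 0).all():
        raise ValueError("onsets are not strictly increasing")
    if not (design["duration"] > 0).all():
        raise ValueError("non-positive duration")
    stim = design[design["condition"] != "catch"]
    for block, sub in stim.groupby("block"):
        counts = sub["concept_id"].value_counts()
        if set(counts.index) != set(concepts.concept_ids) or (counts != 1).any():
            raise ValueError(f"block {block}: concepts not presented exactly once")
    if len(design[design["condition"] == "catch"]):
        n_catch = stim.groupby("concept_id")["catch_follows"].sum()
        if (n_catch != 1).any():
            raise ValueError("each concept must have exactly one catch question")


@dataclass
class RegionSignal:
    """One signal-carrying region: voxel set plus representational weights."""

    voxels: np.ndarray          # (N, 3) voxel indices
    w_sem_event: float = 1.0
    w_sem_object: float = 1.0
    w_vis: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        for w in (self.w_sem_event, self.w_sem_object, self.w_vis):
            if not np.isfinite(w) or w < 0:
                raise ValueError("region weights must be finite and >= 0")


@dataclass
class SignalSpec:
    """Forward-model parameters for one simulated subject cohort.

    ``amplitude`` is the per-voxel RMS of a unit-total-weight pattern in
    signal units; ``noise_sd`` the marginal SD of the AR(1) component;
    ``subject_sd`` the SD of the log-normal per-subject gain.
    """

    regions: dict[str, RegionSignal] = field(default_factory=dict)
    amplitude: float = 1.0
    noise_sd: float = 1.0
    white_sd_fraction: float = 0.5
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0
    subject_sd: float = 0.1
    catch_amplitude: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.drift_amplitude < 0 or self.subject_sd < 0:
            raise ValueError("drift_amplitude and subject_sd must be >= 0")


def planted_patterns(concepts: ConceptSet, region: RegionSignal,
                     rng: np.random.Generator,
                     amplitude: float = 1.0) -> np.ndarray:
    """(concepts, region voxels) amplitude patterns realizing the mixture RDM."""
    n_vox = region.voxels.shape[0]
    sem = concepts.semantic_vectors
    sem_hat = sem / np.linalg.norm(sem, axis=1, keepdims=True)
    vis = concepts.exemplar_features.mean(axis=1)
    vis_c = vis - vis.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(vis_c, axis=1, keepdims=True)
    vis_hat = np.divide(vis_c, norms, out=np.zeros_like(vis_c),
                        where=norms > 0)
    w_sem = np.where(np.asarray(concepts.concept_types) == "event",
                     region.w_sem_event, region.w_sem_object)
    feats = np.hstack([np.sqrt(w_sem)[:, None] * sem_hat,
                       np.sqrt(region.w_vis) * vis_hat])
    d_total = feats.shape[1]
    if n_vox <= d_total + 1:
        raise ValueError(
            f"region has {n_vox} voxels but needs > {d_total + 1} to embed "
            f"a {d_total}-dimensional feature space")
    g = rng.normal(size=(n_vox, d_total))
    g -= g.mean(axis=0, keepdims=True)          # orthogonal to the 1-vector
    q, _ = np.linalg.qr(g)
    return amplitude * np.sqrt(n_vox) * feats @ q.T


def _noise(rng: np.random.Generator, n_vox: int, n_vol: int,
           spec: SignalSpec) -> np.ndarray:
    """(voxels, volumes) AR(1) + white + slow cosine drift noise field."""
    out = np.zeros((n_vox, n_vol))
    if spec.noise_sd > 0:
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar1_coef ** 2)
        e = rng.normal(scale=innov_sd, size=(n_vox, n_vol))
        out += lfilter([1.0], [1.0, -spec.ar1_coef], e, axis=1)
        out += rng.normal(scale=spec.noise_sd * spec.white_sd_fraction,
                          size=(n_vox, n_vol))
    if spec.drift_amplitude > 0:
        n = np.arange(n_vol)
        basis = np.stack([np.sqrt(2.0 / n_vol)
                          * np.cos(np.pi * (2 * n + 1) * k / (2 * n_vol))
                          for k in (1, 2, 3)])
        coef = rng.normal(size=(n_vox, 3)) * spec.drift_amplitude * np.sqrt(n_vol)
        out += coef @ basis
    return out


def simulate_subject(concepts: ConceptSet, design: pd.DataFrame,
                     grid_shape: tuple[int, int, int], spec: SignalSpec,
                     tr: float = 1.7, n_volumes: int | None = None,
                     seed: int = 0, voxel_mm: float = 3.0) -> VolumeSeries:
    """Forward-simulate one subject's 4D BOLD run.

    Per region, concept patterns come from :func:`planted_patterns`; each
    concept's time course is its HRF-convolved trial boxcar scaled by the
    pattern; catch questions add a spatially uniform response.  Noise per
    :class:`SignalSpec` everywhere; a log-normal subject gain scales signal.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_volumes is None:
        t_end = float(design["onset"].iloc[-1] + design["duration"].iloc[-1])
        n_volumes = int(np.ceil((t_end + 20.0) / tr))
    for name, reg in spec.regions.items():
        if np.any(reg.voxels < 0) or np.any(
                reg.voxels >= np.asarray(grid_shape)):
            raise ValueError(f"region '{name}' does not fit in the grid")
    rng = np.random.default_rng(seed)
    gain = float(np.exp(rng.normal(0.0, spec.subject_sd))) if spec.subject_sd > 0 else 1.0

    stim = design[design["condition"] != "catch"]
    regressors = {}
    for cid in concepts.concept_ids:
        sub = stim[stim["concept_id"] == cid]
        regressors[cid] = glm._convolved_column(
            sub["onset"].to_numpy(), sub["duration"].to_numpy(), tr, n_volumes)
    R = np.column_stack([regressors[c] for c in concepts.concept_ids])

    n_vox = int(np.prod(grid_shape))
    data = _noise(rng, n_vox, n_volumes, spec).reshape(*grid_shape, n_volumes)

    planted: dict = {}
    for name, reg in spec.regions.items():
        pat = planted_patterns(concepts, reg, rng, spec.amplitude)  # (C, Nv)
        sig = gain * (R @ pat)                                      # (T, Nv)
        ix, iy, iz = reg.voxels.T
        data[ix, iy, iz, :] += sig.T
        planted[name] = {"voxels": reg.voxels.copy(),
                         "patterns": pat,
                         "concept_ids": list(concepts.concept_ids)}

    catch = design[design["condition"] == "catch"]
    if len(catch) and spec.catch_amplitude != 0:
        ccol = glm._convolved_column(catch["onset"].to_numpy(),
                                     catch["duration"].to_numpy(), tr, n_volumes)
        data += gain * spec.catch_amplitude * ccol

    affine = default_affine(grid_shape, voxel_mm)
    vols = VolumeSeries(data, affine, tr, planted=planted)
    vols.planted["subject_gain"] = gain
    return vols


# -- on-disk interfaces ----------------------------------------------------

def write_subject(vols: VolumeSeries, design: pd.DataFrame,
                  out_dir: str | Path, subject: str, seed: int) -> dict:
    """Write one subject's 4D NIfTI and BIDS-dialect events table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bold = out_dir / f"{subject}_bold.nii.gz"
    vols.to_nifti(bold)
    ev = design.rename(columns={"condition": "trial_type"})
    ev["catch"] = ev.pop("catch_follows").astype(int)
    events = out_dir / f"{subject}_events.tsv"
    ev[["onset", "duration", "trial_type", "concept_id", "catch"]].to_csv(
        events, sep="\t", index=False)
    manifest = {"subject": subject, "seed": int(seed), "tr": vols.tr,
                "n_volumes": vols.n_volumes,
                "bold": bold.name, "events": events.name}
    (out_dir / f"{subject}_manifest.json").write_text(
        json.dumps(manifest, indent=2))
    return manifest


def write_concepts(concepts: ConceptSet, out_dir: str | Path) -> dict:
    """Write concept vectors as TSV matrices plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(concepts.semantic_vectors, index=concepts.concept_ids).to_csv(
        out_dir / "semantic_vectors.tsv", sep="\t", header=False)
    n, k, f = concepts.exemplar_features.shape
    img_ids = [f"{c}_img{j + 1}" for c in concepts.concept_ids for j in range(k)]
    pd.DataFrame(concepts.exemplar_features.reshape(n * k, f),
                 index=img_ids).to_csv(out_dir / "visual_features.tsv",
                                       sep="\t", header=False)
    manifest = {
        "seed": concepts.seed,
        "concept_ids": concepts.concept_ids,
        "concept_types": concepts.concept_types,
        "n_exemplars": int(k),
        "isi_distribution": ("uniform on [isi_low, isi_high]; only the mean "
                             "and range of the emulated design are known, "
                             "the uniform shape is an assumption"),
    }
    (out_dir / "concepts_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
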
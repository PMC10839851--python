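"""End-to-end pipeline orchestration from a single JSON configuration.

Stage order mirrors the study's analysis sequence: simulate -> glm ->
rdm -> rsa -> infer -> univariate -> ppi -> report.  Every stochastic
stage draws from a named seed in the config; rerunning with the same
config reproduces byte-identical outputs.  Each stage writes a manifest
(config hash, seed, input hashes, wall time) next to its outputs and
reads its upstream artifacts from disk, so deleted downstream stages can
be reproduced exactly without rerunning upstream ones.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import glm, inference, rsa, synth
from .rdm import RDM, semantic_rdm, visual_rdm
from .volumes import VolumeSeries

__all__ = ["default_config", "load_config", "validate_config",
           "run_pipeline", "STAGES"]

log = logging.getLogger("dualhub.pipeline")

STAGES = ["simulate", "glm", "rdm", "rsa", "infer", "univariate", "ppi",
          "report"]


def default_config() -> dict:
    """A demo-scale configuration exercising every stage."""
    return {
        "paths": {"out_root": "results/pipeline"},
        "simulation": {
            "n_subjects": 4,
            "grid": [14, 14, 14],
            "n_event": 8, "n_object": 8,
            "dim": 6, "feature_dim": 6, "n_clusters": 2,
            "tr": 1.7, "stim_dur": 2.5, "isi": [1.0, 4.0],
            "n_blocks": 4, "catch_rate": 0.25,
            "amplitude": 1.0, "noise_sd": 1.0, "ar1_coef": 0.3,
            "drift_amplitude": 1.0, "subject_sd": 0.1,
            "regions": {
                "event_region": {"center_vox": [4, 4, 4], "radius_vox": 2.5,
                                 "w_sem_event": 1.0, "w_sem_object": 0.25,
                                 "w_vis": 0.2},
                "shared_region": {"center_vox": [9, 9, 9], "radius_vox": 2.5,
                                  "w_sem_event": 0.6, "w_sem_object": 0.6,
                                  "w_vis": 0.2},
            },
            "seed": 11,
        },
        "analysis": {
            "smooth_fwhm_univariate": 6.0,
            "smooth_fwhm_rsa": 4.0,
            "searchlight_radius_vox": 2.0,
            "min_voxels": 10,
            "rois": [
                {"name": "event_region", "center_vox": [4, 4, 4],
                 "radius_vox": 2.5},
                {"name": "shared_region", "center_vox": [9, 9, 9],
                 "radius_vox": 2.5},
            ],
            "n_subject_perms": 30,
            "n_group_draws": 500,
            "tfce": {"E": 0.5, "H": 2.0, "dh": 0.02, "connectivity": 26},
            "ppi_mode": "bold_product",
            "hpf_cutoff": 180.0,
            "seed": 77,
        },
    }


def load_config(path: str | Path) -> dict:
    cfg = json.loads(Path(path).read_text())
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    for section in ("paths", "simulation", "analysis"):
        if section not in cfg:
            raise ValueError(f"config missing section: {section}")
    sim, ana = cfg["simulation"], cfg["analysis"]
    for key in ("seed",):
        if key not in sim:
            raise ValueError("config field missing: simulation.seed")
        if key not in ana:
            raise ValueError("config field missing: analysis.seed")
    if ana.get("n_subject_perms", 1) < 1 or ana.get("n_group_draws", 1) < 1:
        raise ValueError("permutation counts must be >= 1")
    grid = sim["grid"]
    for roi in ana.get("rois", []):
        if "center_vox" not in roi and "center_mm" not in roi:
            raise ValueError(f"ROI {roi.get('name')} has no center")
    for name, reg in sim.get("regions", {}).items():
        c = reg.get("center_vox")
        if c is None or any(not 0 <= c[i] < grid[i] for i in range(3)):
            raise ValueError(f"region '{name}' center outside grid")


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _region_voxels(reg: dict, grid, mask=None) -> np.ndarray:
    return rsa.sphere_voxels(reg["center_vox"], reg["radius_vox"], tuple(grid),
                             units="vox", mask=mask)


def _roi_voxels(roi: dict, grid, affine, mask) -> np.ndarray:
    if "center_vox" in roi:
        return rsa.sphere_voxels(roi["center_vox"], roi["radius_vox"],
                                 tuple(grid), units="vox", mask=mask)
    return rsa.sphere_voxels(roi["center_mm"], roi["radius_mm"], tuple(grid),
                             affine=affine, units="mm", mask=mask)


class _Ctx:
    """Paths and lazily loaded shared artifacts for one pipeline run."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.root = Path(cfg["paths"]["out_root"])
        self.subjects = [f"sub-{i + 1:02d}"
                         for i in range(cfg["simulation"]["n_subjects"])]

    def dir(self, stage: str) -> Path:
        d = self.root / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def need(self, stage: str, path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage '{stage}' requires missing upstream artifact: {path}")
        return path

    def concepts(self) -> synth.ConceptSet:
        sim = self.cfg["simulation"]
        return synth.make_concept_space(
            sim["n_event"], sim["n_object"], sim["dim"],
            n_clusters=sim.get("n_clusters", 3), seed=sim["seed"],
            feature_dim=sim.get("feature_dim"))

    def load_bold(self, stage: str, subject: str) -> VolumeSeries:
        p = self.need(stage, self.dir("simulate") / f"{subject}_bold.nii")
        man = json.loads(
            (self.dir("simulate") / f"{subject}_manifest.json").read_text())
        return VolumeSeries.from_nifti(p, tr=man["tr"])

    def load_events(self, stage: str, subject: str) -> pd.DataFrame:
        p = self.need(stage, self.dir("simulate") / f"{subject}_events.tsv")
        ev = pd.read_csv(p, sep="\t")
        return ev.rename(columns={"trial_type": "condition",
                                  "catch": "catch_follows"})

    def load_lss(self, stage: str, subject: str) -> glm.BetaMaps:
        p = self.need(stage, self.dir("glm") / f"{subject}_lss.nii")
        labels = json.loads(
            self.need(stage, self.dir("glm") / "lss_labels.json").read_text())
        mask_img = nib.load(str(self.need(
            stage, self.dir("simulate") / "brain_mask.nii")))
        mask = np.asarray(mask_img.dataobj) > 0
        return glm.BetaMaps.from_nifti(p, labels, mask)

    def load_rdms(self, stage: str) -> dict[str, dict[str, RDM]]:
        out = {}
        for ctype in ("event", "object"):
            out[ctype] = {
                kind: RDM.from_tsv(self.need(
                    stage, self.dir("rdm") / f"{kind}_{ctype}.tsv"))
                for kind in ("semantic", "visual")}
        return out


def _manifest(ctx: _Ctx, stage: str, seed, inputs: list[Path],
              outputs: list[Path], t0: float) -> None:
    man = {
        "stage": stage,
        "config_hash": _hash_obj(ctx.cfg),
        "seed": seed,
        "inputs": {p.name: _hash_file(p) for p in inputs if p.exists()},
        "outputs": [p.name for p in outputs],
        "wall_time_s": round(time.time() - t0, 3),
    }
    (ctx.dir(stage) / "stage_manifest.json").write_text(
        json.dumps(man, indent=2))
    log.info("stage=%s seed=%s inputs=%d outputs=%d wall=%.2fs", stage, seed,
             len(man["inputs"]), len(outputs), man["wall_time_s"])


# -- stages ---------------------------------------------------------------

def _stage_simulate(ctx: _Ctx) -> None:
    t0 = time.time()
    cfg = ctx.cfg["simulation"]
    out = ctx.dir("simulate")
    concepts = ctx.concepts()
    synth.write_concepts(concepts, out)
    grid = tuple(cfg["grid"])
    regions = {name: synth.RegionSignal(
        _region_voxels(reg, grid),
        w_sem_event=reg.get("w_sem_event", 1.0),
        w_sem_object=reg.get("w_sem_object", 1.0),
        w_vis=reg.get("w_vis", 0.0))
        for name, reg in cfg.get("regions", {}).items()}
    spec = synth.SignalSpec(
        regions=regions, amplitude=cfg.get("amplitude", 1.0),
        noise_sd=cfg.get("noise_sd", 1.0), ar1_coef=cfg.get("ar1_coef", 0.3),
        drift_amplitude=cfg.get("drift_amplitude", 1.0),
        subject_sd=cfg.get("subject_sd", 0.1))
    outputs = []
    for i, subject in enumerate(ctx.subjects):
        dseed = cfg["seed"] + 1000 + i
        design = synth.make_design(
            concepts, n_blocks=cfg.get("n_blocks", 4),
            stim_dur=cfg.get("stim_dur", 2.5),
            isi_low=cfg.get("isi", [1.0, 4.0])[0],
            isi_high=cfg.get("isi", [1.0, 4.0])[1],
            catch_rate=cfg.get("catch_rate", 0.25), seed=dseed)
        vols = synth.simulate_subject(concepts, design, grid, spec,
                                      tr=cfg.get("tr", 1.7),
                                      seed=cfg["seed"] + 2000 + i)
        bold = out / f"{subject}_bold.nii"
        vols.to_nifti(bold)
        ev = design.rename(columns={"condition": "trial_type",
                                    "catch_follows": "catch"})
        ev["catch"] = ev["catch"].astype(int)
        events = out / f"{subject}_events.tsv"
        ev[["onset", "duration", "trial_type", "concept_id", "catch"]].to_csv(
            events, sep="\t", index=False)
        (out / f"{subject}_manifest.json").write_text(json.dumps(
            {"subject": subject, "seed": cfg["seed"] + 2000 + i,
             "design_seed": dseed, "tr": cfg.get("tr", 1.7),
             "n_volumes": vols.n_volumes}, indent=2))
        outputs += [bold, events]
    mask = np.ones(grid, dtype=np.uint8)
    nib.save(nib.Nifti1Image(mask, vols.affine), str(out / "brain_mask.nii"))
    _manifest(ctx, "simulate", cfg["seed"], [], outputs, t0)


def _stage_glm(ctx: _Ctx) -> None:
    t0 = time.time()
    ana = ctx.cfg["analysis"]
    out = ctx.dir("glm")
    concepts = ctx.concepts()
    outputs, inputs = [], []
    for subject in ctx.subjects:
        vols = ctx.load_bold("glm", subject)
        trials = ctx.load_events("glm", subject)
        inputs.append(ctx.dir("simulate") / f"{subject}_bold.nii")
        X = glm.build_design_matrix(trials, vols.tr, vols.n_volumes,
                                    hpf_cutoff=ana.get("hpf_cutoff", 180.0),
                                    condition_order=["event", "object",
                                                     "catch"])
        fit = glm.fit_ols(vols, X)
        cond = fit.select([n for n in ("event", "object", "catch")
                           if n in fit.labels])
        p = out / f"{subject}_condition_betas.nii"
        cond.to_nifti(p)
        X.to_tsv(out / f"{subject}_design.tsv")
        lss = glm.lss_betas(vols, trials, concepts.concept_ids,
                            hpf_cutoff=ana.get("hpf_cutoff", 180.0))
        pl = out / f"{subject}_lss.nii"
        lss.to_nifti(pl)
        outputs += [p, pl]
    (out / "lss_labels.json").write_text(json.dumps(concepts.concept_ids))
    (out / "condition_labels.json").write_text(
        json.dumps(["event", "object", "catch"]))
    _manifest(ctx, "glm", None, inputs, outputs, t0)


def _stage_rdm(ctx: _Ctx) -> None:
    t0 = time.time()
    out = ctx.dir("rdm")
    concepts = ctx.concepts()
    outputs = []
    for ctype in ("event", "object"):
        ids = concepts.ids_of_type(ctype)
        idx = concepts.index_of(ids)
        sem = semantic_rdm(concepts.semantic_vectors[idx], labels=ids)
        vis = visual_rdm(concepts.exemplar_features[idx], labels=ids)
        for kind, m in (("semantic", sem), ("visual", vis)):
            p = out / f"{kind}_{ctype}.tsv"
            m.to_tsv(p)
            outputs.append(p)
    _manifest(ctx, "rdm", None, [], outputs, t0)


def _smoothed_lss(ctx: _Ctx, stage: str, subject: str) -> glm.BetaMaps:
    ana = ctx.cfg["analysis"]
    betas = ctx.load_lss(stage, subject)
    fwhm = ana.get("smooth_fwhm_rsa", 4.0)
    if fwhm > 0:
        sm = np.stack([glm.gaussian_smooth(betas.map(l), fwhm, betas.affine,
                                           mask=betas.mask)[betas.mask]
                       for l in betas.labels])
        betas = glm.BetaMaps(betas.labels, sm, betas.mask, betas.affine)
    return betas


def _stage_rsa(ctx: _Ctx) -> None:
    t0 = time.time()
    ana = ctx.cfg["analysis"]
    out = ctx.dir("rsa")
    rdms = ctx.load_rdms("rsa")
    grid = tuple(ctx.cfg["simulation"]["grid"])
    rows, outputs, inputs = [], [], []
    for subject in ctx.subjects:
        betas = _smoothed_lss(ctx, "rsa", subject)
        inputs.append(ctx.dir("glm") / f"{subject}_lss.nii")
        maps = {}
        for ctype in ("event", "object"):
            sem, vis = rdms[ctype]["semantic"], rdms[ctype]["visual"]
            eng = rsa.SearchlightEngine(
                betas, sem.labels, ana.get("searchlight_radius_vox", 4.0),
                ana.get("min_voxels", 10))
            smap = eng.stat_map(sem, vis, concept_type=ctype)
            maps[ctype] = smap
            p = out / f"{subject}_z_{ctype}.nii"
            smap.to_nifti(p)
            outputs.append(p)
            for roi in ana.get("rois", []):
                vox = _roi_voxels(roi, grid, betas.affine, betas.mask)
                rho, z = rsa.roi_rsa(betas, vox, sem, vis)
                rows.append(dict(subject=subject, roi=roi["name"],
                                 concept_type=ctype, rho=rho, z=z))
        dmap = rsa.difference_map(maps["event"], maps["object"])
        p = out / f"{subject}_z_difference.nii"
        dmap.to_nifti(p)
        outputs.append(p)
    tab = out / "roi_rsa.tsv"
    pd.DataFrame(rows).to_csv(tab, sep="\t", index=False)
    _manifest(ctx, "rsa", None, inputs, outputs + [tab], t0)


def _stage_infer(ctx: _Ctx) -> None:
    t0 = time.time()
    ana = ctx.cfg["analysis"]
    out = ctx.dir("infer")
    seed = ana["seed"]
    rdms = ctx.load_rdms("infer")
    grid = tuple(ctx.cfg["simulation"]["grid"])
    tfce_params = inference.TFCEParams(**ana.get("tfce", {}))
    n_perms = ana.get("n_subject_perms", 50)
    n_draws = ana.get("n_group_draws", 1000)
    outputs = []

    subj_betas = {s: _smoothed_lss(ctx, "infer", s) for s in ctx.subjects}
    affine = next(iter(subj_betas.values())).affine

    obs_maps: dict[str, list[np.ndarray]] = {}
    null_maps: dict[str, list[np.ndarray]] = {}
    roi_obs: dict = {}
    roi_nulls: dict = {}
    for ctype in ("event", "object"):
        sem, vis = rdms[ctype]["semantic"], rdms[ctype]["visual"]
        obs_maps[ctype], null_maps[ctype] = [], []
        for si, subject in enumerate(ctx.subjects):
            betas = subj_betas[subject]
            eng = rsa.SearchlightEngine(
                betas, sem.labels, ana.get("searchlight_radius_vox", 4.0),
                ana.get("min_voxels", 10))
            obs_maps[ctype].append(eng.stat_map(sem, vis).values)
            sseed = seed + 10_000 * (1 + (ctype == "object")) + si
            null_maps[ctype].append(
                inference.subject_null_maps(eng, sem, vis, n_perms,
                                            sseed).values)
            for roi in ana.get("rois", []):
                vox = _roi_voxels(roi, grid, betas.affine, betas.mask)
                _, z = rsa.roi_rsa(betas, vox, sem, vis)
                roi_obs.setdefault((ctype, roi["name"]), []).append(z)
                roi_nulls.setdefault((ctype, roi["name"]), []).append(
                    inference.subject_null_scalars(betas, vox, sem, vis,
                                                   n_perms, sseed))
    # searchlight corrected maps per concept type and for the difference
    for key, subj_stack, null_stack, two_sided in (
            ("event", obs_maps["event"], null_maps["event"], False),
            ("object", obs_maps["object"], null_maps["object"], False),
            ("difference",
             [e - o for e, o in zip(obs_maps["event"], obs_maps["object"])],
             [e - o for e, o in zip(null_maps["event"], null_maps["object"])],
             True)):
        gmean = inference.group_mean(subj_stack)
        nulls = inference.group_null(
            [inference.NullSet("subject", n) for n in null_stack],
            n_draws,
            seed + 500 + {"event": 0, "object": 1, "difference": 2}[key])
        pmap = inference.corrected_map_p(
            np.where(np.isfinite(gmean), gmean, 0.0), nulls, tfce_params,
            two_sided=two_sided)
        for name, arr in ((f"group_z_{key}", gmean),
                          (f"group_p_{key}", pmap)):
            p = out / f"{name}.nii"
            nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(p))
            outputs.append(p)
    # ROI rank p-values
    rows = []
    for (ctype, roi_name), zs in roi_obs.items():
        obs = float(np.mean(zs))
        gnull = inference.group_null(roi_nulls[(ctype, roi_name)], n_draws,
                                     seed + 900)
        rows.append(dict(concept_type=ctype, roi=roi_name, group_z=obs,
                         p=inference.roi_p(obs, gnull)))
    tab = out / "roi_inference.tsv"
    pd.DataFrame(rows).to_csv(tab, sep="\t", index=False)
    man = out / "null_manifest.json"
    man.write_text(json.dumps({"seed": seed, "n_subject_perms": n_perms,
                               "n_group_draws": n_draws,
                               "tfce": ana.get("tfce", {})}, indent=2))
    _manifest(ctx, "infer", seed, [], outputs + [tab, man], t0)


def _stage_univariate(ctx: _Ctx) -> None:
    t0 = time.time()
    ana = ctx.cfg["analysis"]
    out = ctx.dir("univariate")
    grid = tuple(ctx.cfg["simulation"]["grid"])
    fwhm = ana.get("smooth_fwhm_univariate", 8.0)
    labels = json.loads(ctx.need(
        "univariate", ctx.dir("glm") / "condition_labels.json").read_text())
    mask_img = nib.load(str(ctx.need(
        "univariate", ctx.dir("simulate") / "brain_mask.nii")))
    mask = np.asarray(mask_img.dataobj) > 0
    contrasts, rows, outputs = [], [], []
    for subject in ctx.subjects:
        p = ctx.need("univariate",
                     ctx.dir("glm") / f"{subject}_condition_betas.nii")
        betas = glm.BetaMaps.from_nifti(p, labels, mask)
        cmap = glm.contrast_map(betas, {"event": 1.0, "object": -1.0})
        if fwhm > 0:
            cmap = glm.gaussian_smooth(cmap, fwhm, betas.affine, mask=mask)
        contrasts.append(cmap)
        pth = out / f"{subject}_event_minus_object.nii"
        nib.save(nib.Nifti1Image(cmap.astype(np.float32), betas.affine),
                 str(pth))
        outputs.append(pth)
        for roi in ana.get("rois", []):
            vox = _roi_voxels(roi, grid, betas.affine, mask)
            means = glm.roi_mean_beta(betas, vox)
            for cond in ("event", "object"):
                rows.append(dict(subject=subject, roi=roi["name"],
                                 condition=cond, mean_beta=means[cond]))
    pmap, tmap = inference.signflip_group_test(
        np.stack(contrasts), n_flips=ana.get("n_group_draws", 1000),
        seed=ana["seed"] + 40, two_sided=True, return_t=True)
    for name, arr in (("group_p_event_minus_object", pmap),
                      ("group_t_event_minus_object", tmap)):
        pth = out / f"{name}.nii"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), betas.affine),
                 str(pth))
        outputs.append(pth)
    tab = out / "roi_mean_betas.tsv"
    pd.DataFrame(rows).to_csv(tab, sep="\t", index=False)
    _manifest(ctx, "univariate", ana["seed"], [], outputs + [tab], t0)


def _stage_ppi(ctx: _Ctx) -> None:
    from . import ppi as ppimod
    t0 = time.time()
    ana = ctx.cfg["analysis"]
    out = ctx.dir("ppi")
    grid = tuple(ctx.cfg["simulation"]["grid"])
    outputs = []
    for roi in ana.get("rois", []):
        contrasts = []
        for subject in ctx.subjects:
            vols = ctx.load_bold("ppi", subject)
            trials = ctx.load_events("ppi", subject)
            vox = _roi_voxels(roi, grid, vols.affine, vols.brain_mask)
            seed_series = ppimod.first_eigenvariate(vols, vox, roi["name"])
            pd.DataFrame({"volume": np.arange(seed_series.series.size),
                          "value": seed_series.series}).to_csv(
                out / f"{subject}_{roi['name']}_seed.tsv", sep="\t",
                index=False)
            design = ppimod.build_ppi_design(
                seed_series, trials, vols.tr, vols.n_volumes,
                mode=ana.get("ppi_mode", "bold_product"),
                conditions=["event", "object", "catch"])
            cmap = ppimod.ppi_contrast(vols, design, ("event", "object"))
            contrasts.append(cmap)
            pth = out / f"{subject}_{roi['name']}_ppi_event_minus_object.nii"
            nib.save(nib.Nifti1Image(cmap.astype(np.float32), vols.affine),
                     str(pth))
            outputs.append(pth)
        pmap = inference.signflip_group_test(
            np.stack(contrasts), n_flips=ana.get("n_group_draws", 1000),
            seed=ana["seed"] + 50, two_sided=True)
        pth = out / f"group_p_{roi['name']}_ppi.nii"
        nib.save(nib.Nifti1Image(pmap.astype(np.float32), vols.affine),
                 str(pth))
        outputs.append(pth)
    (out / "ppi_manifest.json").write_text(json.dumps(
        {"mode": ana.get("ppi_mode", "bold_product")}, indent=2))
    _manifest(ctx, "ppi", ana["seed"], [], outputs, t0)


def _stage_report(ctx: _Ctx) -> None:
    t0 = time.time()
    out = ctx.dir("report")
    rsa_tab = pd.read_csv(ctx.need("report",
                                   ctx.dir("rsa") / "roi_rsa.tsv"), sep="\t")
    inf_tab = pd.read_csv(ctx.need(
        "report", ctx.dir("infer") / "roi_inference.tsv"), sep="\t")
    group = (rsa_tab.groupby(["roi", "concept_type"])[["rho", "z"]]
             .mean().reset_index())
    merged = group.merge(inf_tab, on=["roi", "concept_type"], how="left")
    tab = out / "summary.tsv"
    merged.to_csv(tab, sep="\t", index=False)
    _manifest(ctx, "report", None, [], [tab], t0)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "glm": _stage_glm,
    "rdm": _stage_rdm,
    "rsa": _stage_rsa,
    "infer": _stage_infer,
    "univariate": _stage_univariate,
    "ppi": _stage_ppi,
    "report": _stage_report,
}


def run_pipeline(config: dict, stages: list[str] | None = None) -> Path:
    """Run the requested stages in canonical order; returns the output root."""
    cfg = copy.deepcopy(config)
    validate_config(cfg)
    if stages is None:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    ctx = _Ctx(cfg)
    ctx.root.mkdir(parents=True, exist_ok=True)
    (ctx.root / "config.json").write_text(json.dumps(cfg, indent=2))
    for stage in STAGES:
        if stage in stages:
            _STAGE_FUNCS[stage](ctx)
    return ctx.root
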
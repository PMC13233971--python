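"""End-to-end pipeline orchestration from a single config mapping.

Stages: ingest (synthetic or NIfTI files) -> optional rotation -> subject
and group gradients -> alignment / QC -> retention-based gradient-count
selection -> trend-surface fits -> correspondence statistics (permutation,
parametric, voxel-wise, FDR) -> per-subject similarity -> behavioral
associations (raw and covariate-residualized) -> subgroup robustness
splits. All outputs are CSV/JSON/NIfTI in the results directory plus a
manifest with the config hash and seed, so a run is reproducible
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (align_subject, reports_frame, retention_table,
                        select_n_gradients)
from .core import group_gradients, subject_gradients
from .correspondence import (parametric_test, permutation_test,
                             subgroup_split, voxelwise_correlation)
from .errors import ArgumentError, ConfigurationError
from .image_io import MaskedVolume, read_run, read_volume, rotate_volume, write_volume
from .individual_stats import residualize, spearman_association, subject_similarity
from .synthetic import (generate_behavior, generate_bold, generate_templates,
                        make_scenario, planted_modes, planted_similarity)
from .trend_surface import SUPPORTED_ORDERS, fit_tsm

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "mode": "synthetic",          # or "files"
    "k_gradients": 6,
    "order_k": 9,
    "retention_threshold": 0.50,
    "min_retention": 0.50,
    "drop_threshold": 0.20,
    "n_perm": 10_000,
    "perm_scheme": "across",
    "alpha": 0.05,
    "seed": 7,
    "rotation": {"enabled": False, "angle_deg": 37.0, "axis": "X"},
    "aggregation": "affinity-mean",
    "subgroup_variables": ["motion", "medication"],
    "covariates": ["age", "sex", "motion", "medication"],
    "outcomes": ["ids_sr", "asi", "trauma_total", "comorbidity"],
    "synthetic": {},              # overrides for make_scenario
    "template_links": {"0": [0, 0.95], "1": [1, 0.92]},
    "n_templates": 18,
    "paths": {},                  # files mode: runs, roi, gm, templates, behavior
}


def validate_config(config: dict) -> dict:
    """Merge with defaults and check enumerations; returns the full config."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (config or {}).items():
        if key not in cfg:
            raise ConfigurationError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if cfg["order_k"] not in SUPPORTED_ORDERS:
        raise ConfigurationError(
            f"order_k = {cfg['order_k']} invalid; allowed values "
            f"{sorted(SUPPORTED_ORDERS)}")
    if cfg["mode"] not in ("synthetic", "files"):
        raise ConfigurationError("mode must be 'synthetic' or 'files'")
    if cfg["perm_scheme"] not in ("across", "within"):
        raise ConfigurationError("perm_scheme must be 'across' or 'within'")
    if not 0 < cfg["retention_threshold"] <= 1:
        raise ConfigurationError("retention_threshold must be in (0, 1]")
    if cfg["seed"] is None:
        raise ConfigurationError("seed is mandatory")
    if cfg["mode"] == "files":
        for key in ("runs", "roi", "gm", "templates", "behavior"):
            if key not in cfg["paths"]:
                raise ConfigurationError(f"files mode needs paths.{key}")
            entries = cfg["paths"][key]
            entries = entries if isinstance(entries, list) else [entries]
            for p in entries:
                if not Path(p).exists():
                    raise ConfigurationError(f"path does not exist: {p}")
    return cfg


def _ingest_synthetic(cfg):
    scen_kwargs = dict(cfg["synthetic"])
    scen_kwargs.setdefault("seed", cfg["seed"])
    scenario = make_scenario(**scen_kwargs)
    truth = planted_modes(scenario)
    runs = [generate_bold(scenario, s, truth)
            for s in range(scenario.n_subjects)]
    links = {int(k): (int(v[0]), float(v[1]))
             for k, v in cfg["template_links"].items()
             if int(v[0]) < scenario.n_modes}
    templates, truth = generate_templates(
        scenario, links, n_templates=cfg["n_templates"],
        order_k=cfg["order_k"], truth=truth)
    sim = planted_similarity(scenario, truth)
    behavior = generate_behavior(scenario, sim)
    return runs, templates, behavior


def _ingest_files(cfg):
    paths = cfg["paths"]
    roi, gm = paths["roi"], paths["gm"]
    runs = [read_run(p, roi, gm, subject_id=f"sub-{i:03d}")
            for i, p in enumerate(paths["runs"])]
    templates = [read_volume(p, roi) for p in paths["templates"]]
    behavior = pd.read_csv(paths["behavior"])
    return runs, templates, behavior


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the full analysis; returns the results directory path."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    stage = "ingest"
    try:
        tic = time.perf_counter()
        if cfg["mode"] == "synthetic":
            runs, templates, behavior = _ingest_synthetic(cfg)
        else:
            runs, templates, behavior = _ingest_files(cfg)
        timings[stage] = time.perf_counter() - tic

        if cfg["rotation"]["enabled"]:
            stage = "rotation"
            tic = time.perf_counter()
            runs = [rotate_volume(r, cfg["rotation"]["angle_deg"],
                                  cfg["rotation"]["axis"]) for r in runs]
            templates = [rotate_volume(t, cfg["rotation"]["angle_deg"],
                                       cfg["rotation"]["axis"])
                         for t in templates]
            timings[stage] = time.perf_counter() - tic

        stage = "gradients"
        tic = time.perf_counter()
        k = cfg["k_gradients"]
        group = group_gradients(runs, k, aggregation=cfg["aggregation"])
        subjects = {r.subject_id: subject_gradients(r, k) for r in runs}
        timings[stage] = time.perf_counter() - tic

        stage = "alignment"
        tic = time.perf_counter()
        reports, aligned = {}, {}
        for sid, grads in subjects.items():
            rep, ali = align_subject(grads, group,
                                     cfg["retention_threshold"],
                                     subject_id=sid)
            reports[sid] = rep
            aligned[sid] = ali
        retention = retention_table(reports.values())
        k_sel = select_n_gradients(retention, cfg["min_retention"],
                                   cfg["drop_threshold"])
        k_sel = max(k_sel, 1)
        reports_frame(reports.values()).to_csv(
            outdir / "alignment.csv", index=False)
        pd.DataFrame({"gradient": np.arange(k),
                      "retention": retention}).to_csv(
            outdir / "retention.csv", index=False)
        timings[stage] = time.perf_counter() - tic

        stage = "tsm"
        tic = time.perf_counter()
        roi_mask, affine = runs[0].roi_mask, runs[0].affine
        grad_vols = [MaskedVolume(group.modes[:, g], roi_mask, affine,
                                  name=f"gradient-{g}")
                     for g in range(k_sel)]
        grad_tsms = [fit_tsm(v, cfg["order_k"]) for v in grad_vols]
        tmpl_tsms = [fit_tsm(t, cfg["order_k"]) for t in templates]
        with open(outdir / "tsm_group.json", "w") as fh:
            json.dump([t.to_dict() for t in grad_tsms], fh, indent=1)
        for g, vol in enumerate(grad_vols):
            write_volume(vol, outdir / f"group_gradient_{g}.nii.gz")
        timings[stage] = time.perf_counter() - tic

        stage = "correspondence"
        tic = time.perf_counter()
        perm = permutation_test(grad_tsms, tmpl_tsms, cfg["n_perm"],
                                seed=cfg["seed"], scheme=cfg["perm_scheme"])
        par = parametric_test(grad_tsms, tmpl_tsms)
        corr_table = perm.table.merge(
            par[["gradient", "template", "p_param", "q_param"]],
            on=["gradient", "template"])
        corr_table["r_voxelwise"] = [
            voxelwise_correlation(grad_vols[row.gradient],
                                  templates[row.template])
            for row in corr_table.itertuples()]
        corr_table["template_name"] = [templates[t].name
                                       for t in corr_table["template"]]
        corr_table.to_csv(outdir / "correspondence.csv", index=False)
        timings[stage] = time.perf_counter() - tic

        stage = "subject-similarity"
        tic = time.perf_counter()
        alpha = cfg["alpha"]
        sig = corr_table[corr_table["q_perm"] < alpha]
        sel_templates = sorted(set(sig["template"])) or [0]
        subj_tsms, retained_flags = {}, {}
        for sid, grads in aligned.items():
            rep = reports[sid]
            subj_tsms[sid] = {
                g: fit_tsm(MaskedVolume(grads.modes[:, g], roi_mask, affine,
                                        name=f"{sid}-g{g}"), cfg["order_k"])
                for g in range(k_sel) if rep.retained[g]}
            retained_flags[sid] = {g: bool(rep.retained[g])
                                   for g in range(k_sel)}
        tmpl_map = {templates[t].name: tmpl_tsms[t] for t in sel_templates}
        sim_table = subject_similarity(subj_tsms, tmpl_map, retained_flags)
        sim_table.to_csv(outdir / "subject_similarity.csv", index=False)
        timings[stage] = time.perf_counter() - tic

        stage = "behavior"
        tic = time.perf_counter()
        outcomes = [c for c in cfg["outcomes"] if c in behavior.columns]
        assoc = spearman_association(sim_table, behavior, outcomes)
        assoc["covariates_regressed"] = ""
        resid_behavior = residualize(behavior, outcomes, cfg["covariates"])
        assoc_resid = spearman_association(sim_table, resid_behavior,
                                           outcomes)
        assoc_resid["covariates_regressed"] = "+".join(cfg["covariates"])
        pd.concat([assoc, assoc_resid], ignore_index=True).to_csv(
            outdir / "behavior_associations.csv", index=False)
        timings[stage] = time.perf_counter() - tic

        stage = "subgroups"
        tic = time.perf_counter()
        run_by_id = {r.subject_id: r for r in runs}
        sub_rows = []
        for var in cfg["subgroup_variables"]:
            if var not in behavior.columns:
                continue
            rule = "boolean" if set(behavior[var].unique()) <= {0, 1} \
                else "median"
            low, high = subgroup_split(behavior, var, rule)
            for label, part in (("low", low), ("high", high)):
                ids = [s for s in part["subject_id"] if s in run_by_id]
                if len(ids) < 3:
                    continue
                g_sub = group_gradients([run_by_id[s] for s in ids], k,
                                        aggregation=cfg["aggregation"])
                sub_tsms = [fit_tsm(MaskedVolume(g_sub.modes[:, g], roi_mask,
                                                 affine, name=f"{var}-{label}-g{g}"),
                                    cfg["order_k"]) for g in range(k_sel)]
                sub_perm = permutation_test(sub_tsms, tmpl_tsms,
                                            cfg["n_perm"], seed=cfg["seed"],
                                            scheme=cfg["perm_scheme"])
                t_sub = sub_perm.table.copy()
                t_sub.insert(0, "subgroup", f"{var}:{label}")
                t_sub.insert(1, "n_subjects", len(ids))
                sub_rows.append(t_sub)
        if sub_rows:
            pd.concat(sub_rows, ignore_index=True).to_csv(
                outdir / "subgroup_correspondence.csv", index=False)
        timings[stage] = time.perf_counter() - tic
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        raise

    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": cfg["seed"],
        "k_selected": int(k_sel),
        "version": __version__,
        "numpy": np.__version__,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir
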
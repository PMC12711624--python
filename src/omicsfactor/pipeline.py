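"""Stage orchestration: file-based pipeline with manifests.

Each stage reads its inputs from disk, writes versioned outputs plus a JSON
run manifest (stage, parameters, input/output checksums, seed, package
version) into the output directory, and never mutates its inputs. Stage
dependencies are explicit: ``fit`` needs preprocessed views, ``project`` /
``signature`` / ``associate`` need a fitted model container, and so on.
The ``demo`` stage runs the whole chain in memory on one synthetic cohort
and emits a ground-truth recovery report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .containers import BINARY, MultiOmicsDataset
from .clinical import factor_clinical_matrix
from .enrich import pcgse, read_gmt, write_results
from .factor import align_factors, fit_factor_model, load_model, save_model, variance_explained
from .preprocess import (
    attach_clinical,
    preprocess_dataset,
    read_clinical,
    read_matrix,
    write_clinical,
    write_matrix,
    zscore,
)
from .project import project_cohort, stratify_scores
from .scoring import lognormalize, module_score, positive_fraction, read_dense_counts
from .signature import extract_signature, read_signature, rotated_factor_weights, write_signature
from .simulate import SimulationConfig, ViewSpec, generate_multiomics, generate_sc_counts
from .survival import cox_fit, km_estimate, logrank_test

log = logging.getLogger(__name__)

STAGES = (
    "simulate", "preprocess", "fit", "project", "signature",
    "enrich", "associate", "survive", "score-sc", "demo",
)


class MissingDependencyError(RuntimeError):
    """A stage input produced by a prior stage is absent."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    (outdir / f"manifest_{stage.replace('-', '_')}.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n"
    )


def _require(path: Path, produced_by: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise MissingDependencyError(
            f"required artifact {path} not found; run the {produced_by!r} stage first"
        )
    return path


def _load_views(view_cfgs: list[dict]) -> MultiOmicsDataset:
    views = [
        read_matrix(
            _require(c["path"], "simulate/preprocess"),
            name=c.get("name"),
            modality=c.get("modality", "continuous"),
            features_in_rows=bool(c.get("features_in_rows", False)),
        )
        for c in view_cfgs
    ]
    return MultiOmicsDataset(views=views)


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    sim = cfg.get("simulate", {})
    views = [ViewSpec(**v) for v in sim["views"]] if "views" in sim else None
    kwargs = {k: v for k, v in sim.items() if k != "views"}
    if views is not None:
        kwargs["views"] = views
    config = SimulationConfig(**kwargs)
    dataset, truth = generate_multiomics(config)
    outputs = []
    for v in dataset.views:
        p = outdir / f"view_{v.name}.tsv"
        write_matrix(v, p)
        outputs.append(p)
    clin = outdir / "clinical.tsv"
    write_clinical(dataset.clinical, clin)
    outputs.append(clin)
    truth_path = outdir / "truth.h5"
    with h5py.File(truth_path, "w") as f:
        f.create_dataset("Z_true", data=truth.Z_true, track_times=False)
        f.attrs["hazard_coef"] = truth.hazard_coef
        f.attrs["prognostic_factor_index"] = truth.prognostic_factor_index
        f.create_dataset("stage_labels", data=truth.stage_labels, track_times=False)
        sd = h5py.string_dtype("utf-8")
        f.create_dataset("signature_genes", data=np.array(truth.signature_genes, dtype=sd), track_times=False)
        g = f.create_group("W_true")
        for name, W in truth.W_true.items():
            g.create_dataset(name, data=W, track_times=False)
        sf = f.create_group("signal_fraction")
        for name, frac in truth.signal_fraction.items():
            sf.attrs[name] = frac
        sfs = f.create_group("signal_fraction_std")
        for name, frac in truth.signal_fraction_std.items():
            sfs.attrs[name] = frac
    outputs.append(truth_path)
    _write_manifest(outdir, "simulate", {"seed": config.seed, "n_samples": config.n_samples}, [], outputs)
    return {"outputs": [str(p) for p in outputs]}


def stage_preprocess(cfg: dict, outdir: Path) -> dict:
    pp = cfg.get("preprocess", {})
    dataset = _load_views(cfg["views"])
    if cfg.get("clinical"):
        dataset = attach_clinical(dataset, read_clinical(_require(cfg["clinical"], "simulate")))
    ds = preprocess_dataset(
        dataset,
        min_mutated=int(pp.get("min_mutated", 10)),
        top_k={k: int(v) for k, v in pp.get("top_k", {}).items()},
        min_detection={k: float(v) for k, v in pp.get("min_detection", {}).items()},
    )
    outputs = []
    for v in ds.views:
        p = outdir / f"processed_{v.name}.tsv"
        write_matrix(v, p)
        outputs.append(p)
    if ds.clinical is not None:
        p = outdir / "processed_clinical.tsv"
        write_clinical(ds.clinical, p)
        outputs.append(p)
    _write_manifest(outdir, "preprocess", pp, [Path(c["path"]) for c in cfg["views"]], outputs)
    return {"outputs": [str(p) for p in outputs], "n_samples": len(ds.sample_ids)}


def _processed_dataset(cfg: dict, outdir: Path) -> MultiOmicsDataset:
    view_cfgs = []
    for c in cfg["views"]:
        name = c.get("name") or Path(c["path"]).stem.replace("view_", "")
        view_cfgs.append(
            {"path": outdir / f"processed_{name}.tsv", "name": name, "modality": "continuous"}
        )
    ds = _load_views(view_cfgs)
    clin_path = outdir / "processed_clinical.tsv"
    if clin_path.exists():
        ds = attach_clinical(ds, read_clinical(clin_path))
    return ds


def stage_fit(cfg: dict, outdir: Path) -> dict:
    _require(outdir / f"processed_{(cfg['views'][0].get('name') or 'view')}.tsv", "preprocess")
    ds = _processed_dataset(cfg, outdir)
    fm = cfg.get("model", {})
    model = fit_factor_model(
        ds,
        K=int(fm.get("K", 15)),
        max_iter=int(fm.get("max_iter", 2000)),
        tol=float(fm.get("tol", 1e-8)),
        seed=int(fm.get("seed", 0)),
        ard=bool(fm.get("ard", True)),
    )
    model_path = outdir / "model.h5"
    save_model(model, model_path)
    vt = variance_explained(model, ds)
    var_path = outdir / "variance_explained.tsv"
    pd.DataFrame(vt.R2, columns=vt.view_names).rename_axis("factor").to_csv(var_path, sep="\t")
    _write_manifest(outdir, "fit", fm, [], [model_path, var_path])
    return {"model": str(model_path), "grand_total_r2": vt.grand_total,
            "per_view_total": dict(zip(vt.view_names, vt.per_view_total.tolist()))}


def stage_project(cfg: dict, outdir: Path) -> dict:
    model = load_model(_require(outdir / "model.h5", "fit"))
    pr = cfg.get("projection", {})
    view_cfg = pr.get("cohort_view") or cfg["views"][0]
    view = read_matrix(
        _require(view_cfg["path"], "simulate"),
        name=view_cfg.get("name"),
        modality="continuous",
    )
    view = zscore(view)
    factors = pr.get("factors")
    res = project_cohort(
        model, view, view_name=pr.get("view_name", view.name),
        factors=factors, rcond=float(pr.get("rcond", 1e-10)),
    )
    out = pd.DataFrame(res.scores, index=res.sample_ids,
                       columns=[f"factor{f}" for f in res.factors])
    scores_path = outdir / "projected_scores.tsv"
    out.rename_axis("sample_id").to_csv(scores_path, sep="\t")
    log.info("projection: matched %d features, dropped %d", res.matched_features, len(res.dropped_features))
    _write_manifest(outdir, "project", pr, [Path(view_cfg["path"])], [scores_path])
    return {"scores": str(scores_path), "matched_features": res.matched_features,
            "dropped_features": len(res.dropped_features), "conditioning": res.conditioning}


def stage_signature(cfg: dict, outdir: Path) -> dict:
    model = load_model(_require(outdir / "model.h5", "fit"))
    ds = _processed_dataset(cfg, outdir)
    sg = cfg.get("signature", {})
    sig = extract_signature(
        model, ds,
        factor_index=int(sg.get("factor_index", 1)),
        weight_thresh=float(sg.get("weight_thresh", 0.5)),
        corr_thresh=sg.get("corr_thresh", 0.5),
        weight_view=sg.get("weight_view", "protein"),
        corr_views=tuple(sg.get("corr_views", ("mrna", "protein"))),
    )
    sig_path = outdir / "signature.tsv"
    write_signature(sig, sig_path)
    _write_manifest(outdir, "signature", sg, [outdir / "model.h5"], [sig_path])
    return {"signature": str(sig_path), "n_genes": len(sig)}


def stage_enrich(cfg: dict, outdir: Path) -> dict:
    model = load_model(_require(outdir / "model.h5", "fit"))
    en = cfg.get("enrichment", {})
    weights = rotated_factor_weights(
        model, int(en.get("factor_index", 1)), view=en.get("view", "protein")
    )
    sets = read_gmt(_require(en["gene_sets"], "user input (GMT file)"))
    results = pcgse(weights, sets, n_perm=int(en.get("n_perm", 1000)), seed=int(en.get("seed", 0)))
    res_path = outdir / "enrichment.tsv"
    write_results(results, res_path)
    _write_manifest(outdir, "enrich", en, [Path(en["gene_sets"])], [res_path])
    return {"results": str(res_path), "n_sets": len(results)}


def stage_associate(cfg: dict, outdir: Path) -> dict:
    model = load_model(_require(outdir / "model.h5", "fit"))
    clinical = read_clinical(_require(outdir / "processed_clinical.tsv", "preprocess"))
    clinical = clinical.subset_samples([s for s in model.sample_ids if s in clinical.data.index])
    rows = [model.sample_ids.index(s) for s in clinical.sample_ids]
    table = factor_clinical_matrix(model.Z[rows], clinical,
                                   variables=cfg.get("association", {}).get("variables"))
    path = outdir / "associations.tsv"
    table.to_csv(path, sep="\t", index=False)
    _write_manifest(outdir, "associate", {}, [outdir / "model.h5"], [path])
    return {"results": str(path)}


def stage_survive(cfg: dict, outdir: Path) -> dict:
    sv = cfg.get("survival", {})
    scores = pd.read_csv(_require(outdir / "projected_scores.tsv", "project"), sep="\t", index_col=0)
    clinical = read_clinical(_require(cfg["clinical"], "simulate"))
    col = sv.get("score_column", scores.columns[min(1, len(scores.columns) - 1)])
    shared = [s for s in scores.index.astype(str) if s in clinical.data.index]
    z = scores.loc[shared, col].to_numpy(dtype=float)
    time = clinical.data.loc[shared, "time"].to_numpy(dtype=float)
    event = clinical.data.loc[shared, "event"].to_numpy(dtype=int)
    groups = stratify_scores(z, rule=sv.get("rule", "median"), q=sv.get("q"), threshold=sv.get("threshold"))
    chi2, p = logrank_test(time, event, groups)
    curves = km_estimate(time, event, groups)
    km_path = outdir / "km_curves.tsv"
    pd.concat(
        [
            pd.DataFrame({"group": c.group_label, "time": c.times, "survival": c.survival, "at_risk": c.at_risk})
            for c in curves.values()
        ]
    ).to_csv(km_path, sep="\t", index=False)
    fit = cox_fit(time, event, pd.DataFrame({"score": z}))
    cox_path = outdir / "cox_fit.json"
    cox_path.write_text(json.dumps({
        "covariates": fit.covariates,
        "coef": fit.coefficients.tolist(),
        "HR": fit.hr.tolist(),
        "ci95": fit.ci95.tolist(),
        "p": fit.wald_p.tolist(),
        "n": fit.n, "n_events": fit.n_events, "converged": fit.converged,
        "logrank_chi2": chi2, "logrank_p": p,
    }, indent=2) + "\n")
    _write_manifest(outdir, "survive", sv, [outdir / "projected_scores.tsv"], [km_path, cox_path])
    return {"logrank_chi2": chi2, "logrank_p": p, "cox": str(cox_path)}


def stage_score_sc(cfg: dict, outdir: Path) -> dict:
    sc = cfg.get("single_cell", {})
    counts = read_dense_counts(_require(sc["counts"], "user input"))
    meta = pd.read_csv(_require(sc["metadata"], "user input"), sep="\t", index_col=0)
    sig = read_signature(_require(outdir / "signature.tsv", "signature"))
    expr = lognormalize(counts)
    res = module_score(expr, sig, n_bins=int(sc.get("n_bins", 24)),
                       n_ctrl=int(sc.get("n_ctrl", 100)), seed=int(sc.get("seed", 0)))
    summary = res.summarize_by(meta["cell_type"])
    pf = positive_fraction(res, meta["tissue"], threshold=float(sc.get("threshold", 0.0)),
                           seed=int(sc.get("seed", 0)))
    scores_path = outdir / "sc_scores.tsv"
    res.per_cell_score.rename_axis("cell").to_csv(scores_path, sep="\t")
    summary_path = outdir / "sc_summary.tsv"
    summary.to_csv(summary_path, sep="\t")
    _write_manifest(outdir, "score-sc", sc, [Path(sc["counts"])], [scores_path, summary_path])
    return {"scores": str(scores_path), "top_type": summary.index[0],
            "positive_fractions": pf["fractions"], "tumour_normal_ratio": pf["ratio"]}


def run_stage(stage: str, cfg: dict, outdir: str | Path) -> dict:
    """Run one pipeline stage; returns a small result summary dict."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fn = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "fit": stage_fit,
        "project": stage_project,
        "signature": stage_signature,
        "enrich": stage_enrich,
        "associate": stage_associate,
        "survive": stage_survive,
        "score-sc": stage_score_sc,
        "demo": run_demo,
    }[stage]
    return fn(cfg, outdir)


def run_demo(cfg: dict, outdir: Path, seed: int = 0) -> dict:
    """End-to-end synthetic run with a ground-truth recovery report.

    Simulates a cohort, fits the factor model, projects a held-out cohort,
    extracts and scores the planted signature, runs enrichment, clinical
    association and survival stratification, and writes
    ``demo_report.json`` summarising how well each stage recovered the
    planted structure.
    """
    seed = int(cfg.get("seed", seed))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed}

    config = SimulationConfig(seed=seed)
    dataset, truth = generate_multiomics(config)
    ds = preprocess_dataset(dataset, complete_cases=False)
    model = fit_factor_model(ds, K=8, seed=seed, ard=True)

    # factor recovery vs planted scores
    rows = [dataset.sample_ids.index(s) for s in model.sample_ids]
    Zt = truth.Z_true[rows]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(np.corrcoef(Zt.T, model.Z.T)[: Zt.shape[1], Zt.shape[1]:])
    C = np.nan_to_num(C)  # ARD-pruned factors have constant scores
    from scipy.optimize import linear_sum_assignment

    ri, ci = linear_sum_assignment(-C)
    matched = {int(r): int(c) for r, c in zip(ri, ci)}
    report["factor_recovery_mean_abs_corr"] = float(C[ri, ci].mean())

    vt = variance_explained(model, ds)
    report["variance_explained"] = dict(zip(vt.view_names, vt.per_view_total.tolist()))
    report["planted_signal_fraction"] = truth.signal_fraction_std
    report["grand_total_r2"] = vt.grand_total

    # held-out cohort projection on the protein view
    cfg_val = SimulationConfig(n_samples=150, seed=seed + 1, missing_view_fraction=0.0)
    val_ds, val_truth = generate_multiomics(cfg_val, loadings_from=truth)
    val_view = zscore(val_ds.view("protein"))
    k_fit = matched[config.prognostic_factor_index]
    proj = project_cohort(model, val_view)  # all factors: cross-talk removed
    zc = proj.scores[:, k_fit]
    zt = val_truth.Z_true[:, cfg_val.prognostic_factor_index]
    report["projection_abs_corr_with_truth"] = float(abs(np.corrcoef(zc, zt)[0, 1]))

    sig = extract_signature(model, ds, factor_index=k_fit)
    planted = set(truth.signature_genes)
    got = set(sig.genes)
    report["signature_n_genes"] = len(got)
    report["signature_precision"] = len(got & planted) / len(got) if got else 0.0
    report["signature_recall"] = len(got & planted) / len(planted) if planted else 1.0
    write_signature(sig, outdir / "demo_signature.tsv")

    weights = rotated_factor_weights(model, k_fit)
    rng = np.random.default_rng(seed)
    sets = {"planted": truth.signature_genes}
    feats = list(weights.index)
    for i in range(9):
        sets[f"random{i}"] = list(rng.choice(feats, size=30, replace=False))
    enr = pcgse(weights, sets, n_perm=1000, seed=seed)
    report["enrichment_planted_p"] = next(r.p_perm for r in enr if r.set_name == "planted")

    assoc = factor_clinical_matrix(model.Z, ds.clinical)
    stage_rows = assoc[assoc["variable"] == "stage"]
    best = stage_rows.loc[stage_rows["r"].abs().idxmax()]
    report["stage_best_factor"] = int(best["factor"])
    report["stage_best_r"] = float(best["r"])

    clin = val_ds.clinical.data
    groups = stratify_scores(zc, rule="median")
    chi2, p = logrank_test(clin["time"], clin["event"], groups)
    report["logrank_chi2"], report["logrank_p"] = chi2, p
    fit = cox_fit(clin["time"], clin["event"], pd.DataFrame({"score": zc}))
    report["cox_hr_per_score_unit"] = float(fit.hr[0])

    counts, labels, tissue = generate_sc_counts(
        n_cells=2000, n_genes=1000, cell_types=["myofibroblast", "fibroblast", "epithelial", "tcell"],
        signature_genes=truth.signature_genes, fold_change=4.0, seed=seed,
    )
    res = module_score(lognormalize(counts), truth.signature_genes, seed=seed)
    summary = res.summarize_by(labels)
    report["sc_top_scoring_type"] = str(summary.index[0])
    pf = positive_fraction(res, tissue, cell_mask=labels == "myofibroblast", seed=seed)
    report["sc_tumour_normal_positive_ratio"] = pf["ratio"]

    (outdir / "demo_report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    return report
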
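"""End-to-end orchestration: config handling, staged execution and a
reproducibility manifest.

Stages run in the fixed order qc -> trajectory -> branchtest ->
divergence -> deconv -> enrich; any stage can be toggled off.  Defaults
follow the analysis constants baked into the stage modules (QC 200/9000/
120000/8%, q < 0.05, |logFC| > 0.3, 6 kinetic clusters, 10 deciles, grid
over 0-100).  The manifest records the config, seed and SHA-256 hashes
of every output file so identical runs are byte-verifiable.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .branch_genes import filter_branch_genes, fit_branch_test, kinetic_clusters
from .deconv import build_stratum_profiles, estimate_fractions, read_signature
from .divergence import (annotate_gene_sets, detect_divergence_all,
                         read_gene_list, smooth_branch_curves)
from .enrichment import hypergeom_enrich, read_gmt
from .io_qc import QCThresholds, normalize_log, qc_filter, read_counts, \
    residualize, write_counts_mtx
from .synthetic import SimConfig, make_signature, simulate_bifurcation
from .trajectory import infer_bifurcation, stratify_deciles, stretch_pseudotime

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "qc": True,
        "trajectory": True,
        "branchtest": True,
        "divergence": True,
        "deconv": True,
        "enrich": True,
    },
    "input": {
        "counts": None,          # MTX dir or dense CSV/TSV; None -> simulate
        "meta": None,            # optional metadata CSV
        "simulate": {"n_cells": 800, "n_genes": 500,
                     "frac_branch_genes": 0.12,
                     "divergence_times": [20.0, 50.0],
                     "effect_size": 1.5, "seed": 0},
    },
    "qc": {"min_genes": 200, "max_genes": 9000, "max_umis": 120000,
           "max_mito_fraction": 0.08, "min_cells_per_gene": 3,
           "apply_mito_filter": True},
    "normalize": {"target_sum": 10000.0, "residualize": True},
    "trajectory": {"n_pcs": 15, "n_clusters": 12, "n_top_genes": 2000,
                   "use_true_labels": False, "n_deciles": 10},
    "branchtest": {"spline_df": 3, "family": "gaussian", "q_max": 0.05,
                   "lfc_min": 0.3, "k_clusters": 6},
    "divergence": {"grid_size": 100, "bandwidth": 10.0, "min_gap": 0.25,
                   "mode": "strict", "min_tail_points": 1,
                   "gene_lists": {}},
    "deconv": {"signature": None},
    "enrich": {"gmt": None},
}


def merge_config(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | None) -> dict:
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(DEFAULT_CONFIG, user)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[stage {stage}] {err}")
        self.stage = stage


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run the enabled stages and return the manifest (also written)."""
    cfg = merge_config(DEFAULT_CONFIG, config)
    os.makedirs(outdir, exist_ok=True)
    outputs: list[str] = []
    truth = None

    def save_df(df: pd.DataFrame, name: str):
        path = os.path.join(outdir, name)
        df.to_csv(path, index=False, float_format="%.10g")
        outputs.append(path)

    # --- input -------------------------------------------------------------
    try:
        if cfg["input"]["counts"]:
            cm = read_counts(cfg["input"]["counts"])
            meta = pd.read_csv(cfg["input"]["meta"]) \
                if cfg["input"]["meta"] else None
        else:
            sim_cfg = dict(cfg["input"]["simulate"])
            sim_cfg.setdefault("seed", cfg["seed"])
            sim_cfg["divergence_times"] = tuple(
                sim_cfg.get("divergence_times", (30.0, 60.0)))
            cm, meta, truth = simulate_bifurcation(SimConfig(**sim_cfg))
            simdir = os.path.join(outdir, "simulated")
            write_counts_mtx(cm, simdir)
            truth.to_json(os.path.join(outdir, "truth.json"))
            outputs.append(os.path.join(outdir, "truth.json"))
    except Exception as err:
        raise StageError("input", err) from err

    # --- qc ------------------------------------------------------------
    try:
        if cfg["stages"]["qc"]:
            th = QCThresholds(**cfg["qc"])
            cm, report = qc_filter(cm, th)
            with open(os.path.join(outdir, "qc_report.json"), "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            outputs.append(os.path.join(outdir, "qc_report.json"))
        nm = normalize_log(cm, target_sum=cfg["normalize"]["target_sum"])
        if cfg["normalize"]["residualize"]:
            covs = pd.DataFrame({"umi_total": cm.umi_totals(),
                                 "mito_fraction": cm.mito_fractions()})
            nm_res = residualize(nm, covs)
        else:
            nm_res = nm
    except StageError:
        raise
    except Exception as err:
        raise StageError("qc", err) from err

    # --- trajectory ----------------------------------------------------
    try:
        if cfg["stages"]["trajectory"]:
            tj = cfg["trajectory"]
            if tj["use_true_labels"] and meta is not None:
                traj = meta[["cell_id", "pseudotime_raw", "branch"]].copy()
                traj = traj[traj["cell_id"].isin(set(map(str, cm.cell_ids)))]
            else:
                u_markers = None
                if truth is not None:
                    fav = truth.genes
                    u_markers = fav.loc[
                        fav["favored_branch"] == "U", "gene_id"].tolist()[:25]
                traj = infer_bifurcation(
                    nm_res, n_pcs=tj["n_pcs"], n_clusters=tj["n_clusters"],
                    n_top_genes=tj["n_top_genes"], u_markers=u_markers,
                    random_state=cfg["seed"])
            traj = stretch_pseudotime(traj)
            strata = stratify_deciles(traj, n_bins=tj["n_deciles"])
            traj = traj.merge(strata[["cell_id", "decile", "stratum"]],
                              on="cell_id")
            save_df(traj, "trajectory.csv")
        else:
            traj = strata = None
    except StageError:
        raise
    except Exception as err:
        raise StageError("trajectory", err) from err

    # --- branch test -----------------------------------------------------
    results = None
    try:
        if cfg["stages"]["branchtest"] and traj is not None:
            bt = cfg["branchtest"]
            results = fit_branch_test(
                nm, traj, spline_df=bt["spline_df"], family=bt["family"],
                q_max=bt["q_max"], lfc_min=bt["lfc_min"],
                counts=cm if bt["family"] == "nb" else None)
    except StageError:
        raise
    except Exception as err:
        raise StageError("branchtest", err) from err

    # --- divergence ------------------------------------------------------
    try:
        if cfg["stages"]["divergence"] and traj is not None:
            dv = cfg["divergence"]
            sig_genes = filter_branch_genes(
                results, cfg["branchtest"]["q_max"],
                cfg["branchtest"]["lfc_min"]) if results is not None \
                else list(map(str, nm.gene_ids))
            wanted = sig_genes or list(map(str, nm.gene_ids))
            curves = smooth_branch_curves(
                nm, traj, genes=wanted, grid_size=dv["grid_size"],
                bandwidth=dv["bandwidth"])
            calls = detect_divergence_all(
                curves, min_gap=dv["min_gap"], mode=dv["mode"],
                min_tail_points=dv["min_tail_points"])
            save_df(calls, "divergence_calls.csv")
            if results is not None and len(sig_genes) >= \
                    cfg["branchtest"]["k_clusters"]:
                clusters = kinetic_clusters(
                    curves, sig_genes, k=cfg["branchtest"]["k_clusters"])
                results = results.set_index("gene_id")
                results.loc[clusters.index, "kinetic_cluster"] = \
                    clusters.astype("Int64")
                results = results.reset_index()
            lists = {name: read_gene_list(path)
                     for name, path in (dv["gene_lists"] or {}).items()}
            if lists:
                tables = annotate_gene_sets(calls, lists)
                for name, table in tables.items():
                    save_df(table, f"divergence_{name}.csv")
        if results is not None:
            save_df(results, "branch_test.csv")
    except StageError:
        raise
    except Exception as err:
        raise StageError("divergence", err) from err

    # --- deconvolution ---------------------------------------------------
    try:
        if cfg["stages"]["deconv"] and strata is not None:
            sig_path = cfg["deconv"]["signature"]
            if sig_path:
                signature = read_signature(sig_path)
            else:
                signature = make_signature(gene_ids=list(map(str, nm.gene_ids)),
                                           seed=cfg["seed"])
            profiles = build_stratum_profiles(nm, strata)
            fractions = estimate_fractions(profiles, signature)
            save_df(fractions, "deconvolution.csv")
    except StageError:
        raise
    except Exception as err:
        raise StageError("deconv", err) from err

    # --- enrichment --------------------------------------------------------
    try:
        if cfg["stages"]["enrich"] and results is not None:
            gmt_path = cfg["enrich"]["gmt"]
            if gmt_path:
                terms = read_gmt(gmt_path)
            elif truth is not None:
                tg = truth.genes
                terms = {
                    "planted_branch_genes":
                        tg.loc[tg.is_branch_gene, "gene_id"].tolist(),
                    "planted_U_genes":
                        tg.loc[tg.favored_branch == "U", "gene_id"].tolist(),
                    "planted_L_genes":
                        tg.loc[tg.favored_branch == "L", "gene_id"].tolist(),
                }
            else:
                terms = {}
            if terms:
                query = filter_branch_genes(results,
                                            cfg["branchtest"]["q_max"],
                                            cfg["branchtest"]["lfc_min"])
                if query:
                    enr = hypergeom_enrich(query, terms,
                                           list(map(str, nm.gene_ids)))
                    save_df(enr, "enrichment.csv")
    except StageError:
        raise
    except Exception as err:
        raise StageError("enrich", err) from err

    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "outputs": {os.path.relpath(p, outdir): _sha256(p)
                    for p in sorted(outputs)},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
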
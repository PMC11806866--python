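"""Config-driven end-to-end pipeline with seeded, reproducible outputs.

One structured config (YAML or dict) describes either paths to real inputs
or a synthetic-generation block; :func:`run_pipeline` then executes
signature -> alignment -> PLS -> gene selection -> receptor mapping ->
pathology overlap -> cross-form comparison, writing every artifact as TSV
or JSON into the run directory together with the resolved config, its
hash, and a file manifest. Identical configs produce byte-identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .crossform import compare_selections
from .enrichment import permutation_overlap_test
from .io import (
    ExpressionMatrix,
    align_regions,
    column_standardize,
    read_expression,
    read_gene_list,
    write_expression,
    write_gene_list,
)
from .pls import bootstrap_gene_weights, fit_pls1, null_variance_explained, select_genes
from .receptors import correlate_receptors, dominance_analysis
from .signature import apply_wscore, compute_contrast, fit_wscore_model, region_columns
from .synthetic import ReceptorAtlas

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "n_regions": 100,
        "n_genes": 2000,
        "n_latent": 3,
        "noise_sd": 0.5,
        "n_planted": 200,
        "n_controls": 172,
        "n_sporadic": 117,
        "forms": {"C9orf72": {"n": 32, "effect": 1.5}},
        "receptor_targets": [
            0.6, -0.4, 0.3, 0.0, 0.2, -0.3, 0.1, 0.0, 0.4, -0.2,
            0.5, 0.0, -0.1, 0.2, 0.3,
        ],
        "pathology": {"overlap_fraction": 0.5, "set_size": 500, "name": "pathology"},
    },
    "inputs": None,  # {"expression": path, "cohort": path, "receptors": path,
    #                  "pathology_lists": {name: path}}
    "contrast": {"reference_group": "sporadic"},
    "pls": {
        "k": 1,
        "n_boot": 5000,
        "n_iter_null": 5000,
        "null_method": "permute",
        "vip_cut": 1.0,
        "alpha": 0.05,
        "standardize": "center",
    },
    "enrichment": {"n_perm": 1000, "q_threshold": 0.05},
    "receptors": {"method": "pearson", "null": "parametric"},
}


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def load_config(source) -> dict:
    """Merge a YAML file path or dict over the pipeline defaults."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _deep_update(DEFAULT_CONFIG, user)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    pls = cfg["pls"]
    if not 0 < pls["alpha"] < 1:
        raise ValueError("pls.alpha must lie in (0, 1)")
    if pls["vip_cut"] < 0:
        raise ValueError("pls.vip_cut must be non-negative")
    if not 0 < cfg["enrichment"]["q_threshold"] < 1:
        raise ValueError("enrichment.q_threshold must lie in (0, 1)")
    if cfg.get("inputs") is None and cfg.get("synthetic") is None:
        raise ValueError("config needs either 'inputs' paths or a 'synthetic' block")
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


class _Run:
    """Bookkeeping for one pipeline execution."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: list[str] = []

    def path(self, name: str) -> Path:
        self.manifest.append(name)
        return self.outdir / name


def _generate_synthetic(cfg: dict, run: _Run, master_seed: int):
    """Generate all inputs for every genetic form; write them as artifacts."""
    syn = cfg["synthetic"]
    expr_df, truth = synthetic.make_expression(
        n_regions=syn["n_regions"],
        n_genes=syn["n_genes"],
        n_latent=syn["n_latent"],
        noise_sd=syn["noise_sd"],
        n_planted=syn["n_planted"],
        seed=_stage_seed(master_seed, "expression"),
    )
    expression = ExpressionMatrix(values=expr_df)
    atrophy = truth.spatial_factors["factor_1"]

    cohorts = {}
    for form, spec in syn["forms"].items():
        cohorts[form] = synthetic.make_cohort(
            n_controls=syn["n_controls"],
            n_sporadic=syn["n_sporadic"],
            n_genetic=spec["n"],
            atrophy_map=atrophy,
            effect=spec["effect"],
            seed=_stage_seed(master_seed, f"cohort:{form}"),
            genetic_label=form,
        )

    targets = syn["receptor_targets"]
    atlas, _ = synthetic.make_receptor_atlas(
        atrophy_map=atrophy,
        target_correlations=targets,
        seed=_stage_seed(master_seed, "receptors"),
    )

    write_expression(expression, run.path("expression.tsv"))
    for form, cohort in cohorts.items():
        cohort.to_csv(run.path(f"cohort_{form}.tsv"), sep="\t", index=False)
    atlas.to_tsv(run.path("receptor_atlas.tsv"))
    _write_json(
        {
            "planted_gene_ids": truth.planted_gene_ids,
            "receptor_target_correlations": list(targets),
            "seed": master_seed,
        },
        run.path("synthetic_truth.json"),
    )
    return expression, cohorts, atlas, truth


def _load_inputs(cfg: dict):
    paths = cfg["inputs"]
    expression = read_expression(paths["expression"])
    cohort = pd.read_csv(paths["cohort"], sep="\t")
    atlas = ReceptorAtlas.from_tsv(paths["receptors"]) if paths.get("receptors") else None
    pathology = {
        name: set(read_gene_list(p))
        for name, p in (paths.get("pathology_lists") or {}).items()
    }
    return expression, cohort, atlas, pathology


def run_pipeline(config=None, outdir="run") -> dict:
    """Execute the full pipeline and return a summary dict.

    ``config`` may be a YAML path, a dict of overrides, or None (defaults).
    All artifacts, the resolved config, its hash, and a manifest are written
    under ``outdir``.
    """
    cfg = load_config(config)
    master_seed = cfg["seed"]
    run = _Run(Path(outdir))
    t0 = time.time()
    summary: dict = {"config_hash": _config_hash(cfg), "forms": {}}

    # ---- inputs -----------------------------------------------------------
    truth = None
    if cfg.get("inputs"):
        expression, cohort, atlas, pathology_lists = _load_inputs(cfg)
        forms = cfg["contrast"].get("target_groups") or sorted(
            set(cohort["group"]) - {"control", cfg["contrast"]["reference_group"]}
        )
        cohorts = {f: cohort for f in forms}
    else:
        expression, cohorts, atlas, truth = _generate_synthetic(cfg, run, master_seed)
        forms = list(cohorts)
        pathology_lists = {}
    logger.info("inputs: %d regions x %d genes, %d forms", expression.n, expression.p, len(forms))

    expression_std = column_standardize(expression, cfg["pls"]["standardize"])
    reference = cfg["contrast"]["reference_group"]
    plscfg = cfg["pls"]

    selections = {}
    for form in forms:
        cohort = cohorts[form]
        t_stage = time.time()

        # ---- atrophy signature -------------------------------------------
        controls = cohort[cohort["group"] == "control"]
        model = fit_wscore_model(controls)
        patients = cohort[cohort["group"].isin([form, reference])]
        wscores = apply_wscore(model, patients)
        contrast = compute_contrast(
            wscores,
            groups=patients.set_index("subject_id")["group"],
            duration=patients.set_index("subject_id")["duration"],
            target_group=form,
            reference_group=reference,
        )
        contrast.to_tsv(run.path(f"contrast_{form}.tsv"))
        _write_json(
            {"df": contrast.df, "target": form, "reference": reference,
             **contrast.metadata},
            run.path(f"contrast_{form}.json"),
        )

        # ---- PLS association ---------------------------------------------
        x_al, y_al = align_regions(expression_std, contrast)
        pls_model = fit_pls1(x_al, y_al, k=plscfg["k"])
        null = null_variance_explained(
            x_al, y_al,
            n_iter=plscfg["n_iter_null"],
            method=plscfg["null_method"],
            seed=_stage_seed(master_seed, f"null:{form}"),
        )
        stats_ = bootstrap_gene_weights(
            x_al, y_al,
            n_boot=plscfg["n_boot"],
            seed=_stage_seed(master_seed, f"boot:{form}"),
        )
        sel = select_genes(stats_, vip_cut=plscfg["vip_cut"], alpha=plscfg["alpha"])
        selections[form] = sel

        gene_table = stats_.table.copy()
        gene_table["selected"] = [
            "+" if g in sel.pls1_plus else "-" if g in sel.pls1_minus else ""
            for g in gene_table.index
        ]
        gene_table.to_csv(run.path(f"pls_{form}_genes.tsv"), sep="\t",
                          index_label="gene", float_format="%.17g")
        _write_json(
            {
                "variance_explained": pls_model.variance_explained,
                "p_null": null.p_value,
                "null_method": null.method,
                "n_iter_null": null.n_iterations,
                "n_boot": stats_.n_boot,
                "n_pls1_plus": len(sel.pls1_plus),
                "n_pls1_minus": len(sel.pls1_minus),
                "vip_cut": sel.vip_cut,
                "alpha": sel.alpha,
                "seed_boot": stats_.seed,
            },
            run.path(f"pls_{form}_summary.json"),
        )

        # ---- receptor mapping --------------------------------------------
        receptor_summary = {}
        if atlas is not None:
            rcfg = cfg["receptors"]
            corr = correlate_receptors(
                y_al, atlas, method=rcfg["method"], null=rcfg["null"],
                seed=_stage_seed(master_seed, f"receptor:{form}"),
            )
            corr.to_csv(run.path(f"receptor_correlations_{form}.tsv"), sep="\t")
            dom = dominance_analysis(y_al, atlas)
            pd.DataFrame(
                {
                    "total_dominance": dom.total_dominance,
                    "relative_importance": dom.relative_importance,
                }
            ).to_csv(run.path(f"dominance_{form}.tsv"), sep="\t",
                     index_label="receptor")
            receptor_summary = {
                "full_r2": dom.full_r2,
                "n_subsets": dom.n_subsets,
                "max_abs_r": float(corr["r"].abs().max()),
            }

        # ---- pathology overlap -------------------------------------------
        background = expression.genes
        if truth is not None and sel.all_genes:
            pcfg = cfg["synthetic"]["pathology"]
            pathology_lists = {
                pcfg.get("name", "pathology"): synthetic.make_pathology_sets(
                    background=background,
                    signature_genes=sorted(sel.all_genes),
                    overlap_fraction=pcfg["overlap_fraction"],
                    set_size=pcfg["set_size"],
                    seed=_stage_seed(master_seed, f"pathology:{form}"),
                )
            }
        overlap_summaries = {}
        for lname, lgenes in pathology_lists.items():
            if not sel.all_genes:
                continue
            write_gene_list(lgenes, run.path(f"pathology_{lname}_{form}.txt"))
            res = permutation_overlap_test(
                query=sel.all_genes,
                target=lgenes,
                background=background,
                n_perm=cfg["enrichment"]["n_perm"],
                seed=_stage_seed(master_seed, f"overlap:{form}:{lname}"),
            )
            overlap_summaries[lname] = {
                "observed": res.observed,
                "p": res.p_value,
                "query_size": res.query_size,
                "target_size": res.target_size,
                "null_mean": float(res.null_counts.mean()),
            }
        if overlap_summaries:
            _write_json(overlap_summaries, run.path(f"overlap_{form}.json"))

        summary["forms"][form] = {
            "variance_explained": pls_model.variance_explained,
            "p_null": null.p_value,
            "n_pls1_plus": len(sel.pls1_plus),
            "n_pls1_minus": len(sel.pls1_minus),
            "receptors": receptor_summary,
            "overlap": overlap_summaries,
            "wall_s": round(time.time() - t_stage, 2),
        }
        logger.info("form %s done in %.1fs", form, time.time() - t_stage)

    # ---- cross-form comparison -------------------------------------------
    if len(selections) >= 2:
        conc = compare_selections(selections)
        conc.pairs.to_csv(run.path("crossform_pairs.tsv"), sep="\t", index=False)
        conc.membership.to_csv(run.path("crossform_membership.tsv"), sep="\t")
        summary["crossform"] = {
            "pairs": conc.pairs.to_dict(orient="records"),
            "common_to_all": conc.common_to_all,
        }

    summary["wall_s"] = round(time.time() - t0, 2)
    _write_json(cfg, run.path("config_resolved.json"))
    _write_json(
        {"files": sorted(run.manifest), "config_hash": summary["config_hash"]},
        run.outdir / "manifest.json",
    )
    _write_json(summary, run.outdir / "summary.json")
    return summary
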
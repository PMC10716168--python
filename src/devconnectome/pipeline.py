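"""End-to-end orchestration with config, logging and reproducibility.

``RunConfig`` is a flat, serializable description of one run: input paths
(or the synthetic stage to generate them), model options, ensemble sizes
and a single master seed.  Every stochastic stage receives a sub-seed
derived from the master seed via SeedSequence spawning; the resolved
config, sub-seeds and package version are written next to the outputs so a
run can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cortical as cortical_mod
from . import edges as edges_mod
from . import enrichment as enrich_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import surrogates as surr_mod
from . import synthetic as synth_mod
from . import trajectories as traj_mod
from . import transcriptomics as trans_mod

logger = logging.getLogger(__name__)

STAGES = ("simulate", "metrics", "slopes", "edges", "pls", "enrich", "cortical")


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    # inputs (populated by the simulate stage when synthetic=True)
    synthetic: bool = True
    regions_path: str | None = None
    manifest_path: str | None = None
    expression_path: str | None = None
    annotations_path: str | None = None
    categories_path: str | None = None
    cortical_map_paths: dict = field(default_factory=dict)
    # synthetic sizes
    n_regions: int = 90
    n_subjects: int = 200
    n_genes: int = 500
    export_connectomes: bool = False  # write per-scan matrices + manifest
    # analysis options
    stages: tuple = STAGES
    slope_metric: str = "nodal_efficiency"
    model: str = "auto"            # linear / quadratic / interaction / auto
    prevalence: float = 0.75
    n_nulls: int = 100             # matched random networks for small-world
    n_surr: int = 1000             # SA surrogates
    n_boot: int = 200              # gene-weight bootstrap
    n_perm: int = 10000            # cell-type permutations
    n_components: int = 15
    gene_alpha: float = 0.01

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def validate(self) -> None:
        if not self.synthetic:
            needed = {
                "metrics": ["regions_path", "manifest_path"],
                "slopes": ["regions_path", "manifest_path"],
                "edges": ["regions_path", "manifest_path"],
                "pls": ["regions_path", "manifest_path", "expression_path"],
                "enrich": ["regions_path", "manifest_path", "expression_path",
                           "annotations_path"],
                "cortical": ["regions_path", "manifest_path"],
            }
            for stage in self.stages:
                for key in needed.get(stage, []):
                    if getattr(self, key) is None:
                        raise ValueError(
                            f"stage '{stage}' enabled but config key '{key}' unset"
                        )


def _subseeds(master: int, n: int):
    return [int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence(master).spawn(n)]


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns a summary dict.

    Any stage failure aborts with the stage name; outputs of completed
    stages are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _subseeds(config.seed, len(STAGES))))
    logger.info("run seeds: %s", seeds)
    from . import __version__

    summary = {"version": __version__, "seed": config.seed, "sub_seeds": seeds}
    state: dict = {}
    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage '{stage}'")
        logger.info("stage %s ...", stage)
        try:
            _STAGE_FUNCS[stage](config, state, seeds[stage], out, summary)
        except Exception as err:
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err
    config.to_yaml(out / "config_resolved.yaml")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    (out / "outputs_manifest.txt").write_text(
        "\n".join(sorted(p.name for p in out.iterdir())) + "\n"
    )
    return summary


def _load_inputs(config: RunConfig, state: dict) -> None:
    if "cohort" in state:
        return
    regions = io_mod.read_region_table(config.regions_path)
    state["regions"] = regions
    state["cohort"] = io_mod.load_cohort(config.manifest_path, regions)


def _stage_simulate(config, state, seed, out, summary):
    s_reg, s_coh, s_expr, s_ann, s_maps = _subseeds(seed, 5)
    regions = synth_mod.make_regions(config.n_regions, seed=s_reg)
    params = synth_mod.CohortParams(n_subjects=config.n_subjects)
    cohort, gt_cohort = synth_mod.simulate_cohort(regions, seed=s_coh, params=params)
    n_true = min(50, max(4, config.n_genes // 10) // 2 * 2)
    expr, gt_expr = synth_mod.simulate_expression(
        regions, gt_cohort.nodal_slope_field, G=config.n_genes,
        n_true=n_true, seed=s_expr,
    )
    annotation, categories, gt_ann = synth_mod.simulate_annotations(
        expr.gene_ids, gt_expr, seed=s_ann,
        decoy_size=min(50, config.n_genes // 3),
    )
    maps, gt_maps = synth_mod.simulate_cortical_maps(
        regions, gt_cohort.nodal_slope_field, seed=s_maps
    )
    state.update(
        regions=regions, cohort=cohort, expression=expr, annotation=annotation,
        categories=categories, cortical_maps=maps,
        ground_truth={"cohort": gt_cohort, "expression": gt_expr,
                      "annotations": gt_ann, "maps": gt_maps},
    )
    io_mod.write_region_table(regions, out / "regions.tsv")
    trans_mod.write_expression(expr, out / "expression.tsv")
    enrich_mod.write_annotations(annotation, out / "annotations.tsv")
    enrich_mod.write_categories(categories, out / "categories.gmt")
    cort = regions.ids[regions.cortical]
    for name, m in maps.items():
        cortical_mod.write_cortical_map(m, cort, out / f"map_{name}.tsv")
    gt_cohort.to_json(out / "ground_truth_cohort.json")
    gt_expr.to_json(out / "ground_truth_expression.json")
    gt_maps.to_json(out / "ground_truth_maps.json")
    if config.export_connectomes:
        mdir = out / "connectomes"
        mdir.mkdir(exist_ok=True)
        rows = []
        for s in cohort.scans:
            rel = f"connectomes/{s.subject_id}_w{s.wave}.tsv"
            io_mod.write_connectome(s.connectome, out / rel)
            rows.append({"subject": s.subject_id, "wave": s.wave, "age": s.age,
                         "sex": s.sex, "tbv": s.tbv, "centre": s.centre,
                         "matrix_path": rel})
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    summary["simulate"] = {
        "n_regions": regions.n_regions,
        "n_scans": cohort.n_scans,
        "n_subjects": len(cohort.subjects),
        "truncation_rate": gt_cohort.truncation_rate,
    }


def _stage_metrics(config, state, seed, out, summary):
    _load_inputs(config, state)
    cohort = state["cohort"]
    group = io_mod.group_average_network(cohort, prevalence=config.prevalence)
    state["group_net"] = group
    ens = metrics_mod.random_ensemble(group, n=config.n_nulls, seed=seed)
    gm = metrics_mod.global_metrics(group, ensemble=ens)
    rows = []
    for s in cohort.scans:
        m = metrics_mod.global_metrics(s.connectome)
        rows.append({"subject": s.subject_id, "wave": s.wave, "age": s.age,
                     **{k: v for k, v in m.to_dict().items() if v is not None}})
    per_scan = pd.DataFrame(rows)
    per_scan.to_csv(out / "global_metrics_per_scan.tsv", sep="\t", index=False,
                    float_format="%.17g")
    state["global_per_scan"] = per_scan
    nm = metrics_mod.nodal_metrics(group)
    pd.DataFrame(
        {"region": state["regions"].ids, "nodal_efficiency": nm.n_eglob,
         "nodal_local_efficiency": nm.n_eloc, "degree_strength": nm.degree_strength,
         "betweenness": nm.betweenness}
    ).to_csv(out / "nodal_metrics_group.tsv", sep="\t", index=False,
             float_format="%.17g")
    summary["metrics"] = {"group": gm.to_dict(), "n_edges": group.n_edges}


def _stage_slopes(config, state, seed, out, summary):
    _load_inputs(config, state)
    cohort = state["cohort"]
    data = cohort.to_frame()
    per_scan = state.get("global_per_scan")
    fits = {}
    if per_scan is not None:
        y = per_scan["e_glob"].to_numpy()
        if config.model == "auto":
            cand = {k: traj_mod.fit_lmm(y, data, k) for k in ("linear", "quadratic")}
            kind = traj_mod.aic_select(cand)
            fits["e_glob"] = cand[kind]
        else:
            fits["e_glob"] = traj_mod.fit_lmm(y, data, config.model)
        with open(out / "trajectory_global.json", "w") as fh:
            json.dump({k: f.to_dict() for k, f in fits.items()}, fh, indent=1)
    smap = traj_mod.fit_slope_map(cohort, config.slope_metric)
    state["slope_map"] = smap
    smap.to_frame(state["regions"]).to_csv(
        out / "slope_map.tsv", sep="\t", index=False, float_format="%.17g"
    )
    grads = {}
    for axis in ("PA", "IS", "ML"):
        t, p = traj_mod.gradient_contrast(smap, state["regions"], axis)
        grads[axis] = {"t": t, "p": p}
    summary["slopes"] = {
        "n_significant": int(smap.significant.sum()),
        "gradients": grads,
        **({"e_glob_beta_age": fits["e_glob"].beta_age,
            "e_glob_model": fits["e_glob"].model_kind} if fits else {}),
    }


def _stage_edges(config, state, seed, out, summary):
    _load_inputs(config, state)
    if "group_net" not in state:
        state["group_net"] = io_mod.group_average_network(
            state["cohort"], prevalence=config.prevalence
        )
    cls = edges_mod.classify_edges(state["group_net"], state["regions"])
    cls.to_frame().to_csv(out / "edge_classification.tsv", sep="\t", index=False)
    table = edges_mod.edge_type_strength_table(state["cohort"], cls)
    table.to_csv(out / "edge_type_strength.tsv", sep="\t", index=False,
                 float_format="%.17g")
    summary["edges"] = {
        "n_hubs": int(cls.hubs.sum()),
        "counts": {c: int((cls.hub_class == c).sum())
                   for c in edges_mod.HUB_CLASSES},
    }


def _stage_pls(config, state, seed, out, summary):
    _load_inputs(config, state)
    if "expression" not in state:
        state["expression"] = trans_mod.read_expression(config.expression_path)
    if "slope_map" not in state:
        raise ValueError("pls stage requires the slopes stage")
    regions = state["regions"]
    y, X, genes, idx = trans_mod.align(state["slope_map"], state["expression"], regions)
    D = regions.distance_matrix()[np.ix_(idx, idx)]
    gen = surr_mod.VariogramSurrogates().fit(D)
    s_surr, s_boot = _subseeds(seed, 2)
    res = trans_mod.pls_with_sac(
        X, y, D, n_components=min(config.n_components, min(len(y) - 1, X.shape[1])),
        n_surr=config.n_surr, seed=s_surr, generator=gen,
    )
    table = trans_mod.bootstrap_gene_weights(
        X, y, gene_ids=genes, n_boot=config.n_boot, seed=s_boot,
        alpha=config.gene_alpha,
    )
    pos, neg = trans_mod.select_genes(table, alpha=config.gene_alpha)
    table.to_frame().to_csv(out / "gene_weights.tsv", sep="\t", index=False,
                            float_format="%.17g")
    with open(out / "pls_summary.json", "w") as fh:
        json.dump({**res.to_dict(), "n_positive": len(pos), "n_negative": len(neg)},
                  fh, indent=1)
    state.update(pls=res, gene_table=table, pls_X=X, pls_y=y, pls_genes=genes,
                 pls_D=D, pls_gen=gen, genes_pos=pos, genes_neg=neg)
    summary["pls"] = {"r1": res.r1, "p_sac": res.p_sac,
                      "explained1": float(res.explained[0]),
                      "n_positive": len(pos), "n_negative": len(neg)}


def _stage_enrich(config, state, seed, out, summary):
    if "gene_table" not in state:
        raise ValueError("enrich stage requires the pls stage")
    if "annotation" not in state:
        state["annotation"] = enrich_mod.read_annotations(config.annotations_path)
    s_cell, s_cat = _subseeds(seed, 2)
    genes = state["pls_genes"]
    results = {}
    for sign, sel in (("positive", state["genes_pos"]), ("negative", state["genes_neg"])):
        res = enrich_mod.cell_type_test(
            sel, state["annotation"], genes, n_perm=config.n_perm, seed=s_cell
        )
        enrich_mod.results_frame(res).to_csv(
            out / f"cell_enrichment_{sign}.tsv", sep="\t", index=False,
            float_format="%.17g",
        )
        results[sign] = res
    cat_results = None
    categories = state.get("categories")
    if categories is None and config.categories_path:
        categories = enrich_mod.read_categories(config.categories_path)
    if categories:
        cat_results = enrich_mod.category_enrichment_sa(
            state["gene_table"].weight, genes, categories,
            state["pls_y"], state["pls_X"], state["pls_D"],
            n_surr=min(config.n_surr, 500), seed=s_cat,
            generator=state.get("pls_gen"),
        )
        enrich_mod.results_frame(cat_results).to_csv(
            out / "category_enrichment.tsv", sep="\t", index=False,
            float_format="%.17g",
        )
    summary["enrich"] = {
        sign: {r.name: r.p for r in res} for sign, res in results.items()
    }
    if cat_results:
        summary["enrich"]["categories"] = {r.name: r.q for r in cat_results}


def _stage_cortical(config, state, seed, out, summary):
    _load_inputs(config, state)
    regions = state["regions"]
    if "cortical_maps" not in state:
        state["cortical_maps"] = {
            name: cortical_mod.read_cortical_map(p, name)
            for name, p in config.cortical_map_paths.items()
        }
    maps = state["cortical_maps"]
    if not maps:
        summary["cortical"] = {}
        return
    if "slope_map" not in state:
        raise ValueError("cortical stage requires the slopes stage")
    cort = np.flatnonzero(regions.cortical)
    slope_c = state["slope_map"].beta_age[cort]
    Dc = regions.distance_matrix()[np.ix_(cort, cort)]
    tab = cortical_mod.cytoarchitecture_table(
        slope_c, maps, Dc, n_surr=config.n_surr, seed=seed
    )
    tab.to_csv(out / "cytoarchitecture.tsv", sep="\t", index=False,
               float_format="%.17g")
    laminas = {k: maps[k] for k in ("L1", "L2", "L3", "L4", "L5", "L6") if k in maps}
    partial = {}
    if len(laminas) == 6:
        gen = surr_mod.VariogramSurrogates().fit(Dc)
        subs = _subseeds(seed + 1, 6)
        for s, lam in zip(subs, sorted(laminas)):
            rho, p = cortical_mod.partial_laminar(
                slope_c, laminas, lam, Dc, n_surr=config.n_surr, seed=s,
                generator=gen,
            )
            partial[lam] = {"rho_partial": rho, "p_sac": p}
        pd.DataFrame(
            [{"lamina": k, **v} for k, v in partial.items()]
        ).to_csv(out / "laminar_partial.tsv", sep="\t", index=False,
                 float_format="%.17g")
    summary["cortical"] = {
        "spearman": tab.set_index("map")["rho"].to_dict(),
        "partial": partial,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "metrics": _stage_metrics,
    "slopes": _stage_slopes,
    "edges": _stage_edges,
    "pls": _stage_pls,
    "enrich": _stage_enrich,
    "cortical": _stage_cortical,
}
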
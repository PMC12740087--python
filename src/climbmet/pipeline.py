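"""End-to-end orchestration of the synthetic study.

``run_pipeline`` runs synthesize -> demography -> preprocess -> screens ->
covariance networks -> graph enrichment -> stress assay in dependency
order, writes every stage's tabular output under ``out_dir``, and returns
a machine-readable report (also written as ``report.json``).  All
randomness derives from the single config seed; the report contains no
timestamps, so two runs with one seed produce byte-identical reports
(timestamps live in the JSONL run log).
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import covnet, demography, io, keggnet, preprocess, screens, stress, synthetic
from .fractionation import FRACTION_NAMES

__all__ = ["RunConfig", "run_pipeline"]


class StageToggles(BaseModel):
    demography: bool = True
    metabolome: bool = True
    networks: bool = True
    enrichment: bool = True
    stress: bool = True


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_flies: int = 2000
    fdr: float = 0.05
    nominal_p: float = 0.05
    mahalanobis_sd: float = 4.0
    tw_alpha: float = 0.01
    n_perm_label: int = 1000
    n_perm_rewire: int = 10000
    pair_family: str = "prefiltered"
    stages: StageToggles = Field(default_factory=StageToggles)

    @field_validator("fdr", "nominal_p", "tw_alpha")
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _log(fh, stage: str, **kv: Any) -> None:
    rec = {"stage": stage, "time": time.time(), **kv}
    fh.write(json.dumps(rec, default=str) + "\n")
    fh.flush()
    print(f"[climbmet] {stage}: " + ", ".join(f"{k}={v}" for k, v in kv.items()
                                              if k != "time"), file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    report: dict[str, Any] = {"config": config.model_dump(), "stages_run": []}
    logf = open(out / "run_log.jsonl", "w")

    def stage(name: str, fn):
        if not getattr(config.stages, name, True):
            _log(logf, name, skipped=True)
            return
        _log(logf, name, status="start")
        try:
            fn()
        except Exception as exc:
            _log(logf, name, status="failed", error=str(exc))
            logf.close()
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages_run"].append(name)
        _log(logf, name, status="done")

    # --- demography -------------------------------------------------------
    def run_demography():
        records = synthetic.simulate_lifespans(
            synthetic.CohortSpec(n_flies=config.n_flies, seed=sub[0]))
        io.write_survival_tsv(records, out / "survival.tsv")
        chi2, dfree, p = demography.log_rank(records)
        horizon = float(records["exit_age"].max())
        rmst = {}
        for f in range(5):
            grp = records[records["fraction"] == f]
            m, se = demography.restricted_mean_lifespan(grp, horizon)
            rmst[FRACTION_NAMES[f]] = {"rmst": m, "se": se, "n": int(len(grp))}
        full = demography.fit_gompertz(records, shared="none")
        shared_b = demography.fit_gompertz(records, shared="beta")
        shared_all = demography.fit_gompertz(records, shared="all")
        a_chi, a_df, a_p = demography.gompertz_lrt(shared_b, shared_all)
        b_chi, b_df, b_p = demography.gompertz_lrt(full, shared_b)
        aalen = demography.aalen_additive(records, reference_group=2)
        pd.DataFrame(
            {"fraction": list(full.fits),
             "alpha": [f.alpha for f in full.fits.values()],
             "beta": [f.beta for f in full.fits.values()]}
        ).to_csv(out / "gompertz.tsv", sep="\t", index=False)
        demography.life_table(records).to_csv(out / "life_table.tsv", sep="\t", index=False)
        report["demography"] = {
            "log_rank": {"chi2": chi2, "df": dfree, "p": p},
            "restricted_mean_lifespan": rmst,
            "gompertz": {FRACTION_NAMES[int(k)]: {"alpha": v.alpha, "beta": v.beta}
                         for k, v in full.fits.items()},
            "lrt_alpha": {"chi2": a_chi, "df": a_df, "p": a_p},
            "lrt_beta": {"chi2": b_chi, "df": b_df, "p": b_p},
            "aalen": {row: {"stat": float(aalen.tests.loc[row, "stat"]),
                            "p": float(aalen.tests.loc[row, "p"])}
                      for row in aalen.tests.index},
        }

    # --- metabolome -------------------------------------------------------
    state: dict[str, Any] = {}

    def run_metabolome():
        spec = synthetic.default_metabolome_spec(seed=sub[1])
        raw, meta = synthetic.simulate_metabolome(spec)
        io.write_metabolome_tsv(raw, meta, out / "metabolome_raw.tsv", out / "metabolome_meta.tsv")
        mm = preprocess.MetabolomeMatrix(raw, meta, "centered")  # generator is log-scale
        mm = preprocess.correct_batch(mm)
        mm = preprocess.residualize_run_order(mm)
        mm, removed = preprocess.remove_outliers(mm, n_sd=config.mahalanobis_sd)
        pca = preprocess.pca_tw(mm, alpha=config.tw_alpha)
        mm.data.rename_axis("sample").to_csv(out / "metabolome_clean.tsv", sep="\t")
        single = screens.screen_single_metabolites(mm, fdr=config.fdr)
        single.to_csv(out / "screen_single.tsv", sep="\t", index=False)
        resid = screens.residualize_main_effects(mm.data, mm.meta["fraction"],
                                                 mm.meta["age_week"])
        pairs = screens.screen_pair_interactions(resid, mm.meta,
                                                 family=config.pair_family, fdr=config.fdr)
        pairs.to_csv(out / "screen_pairs.tsv", sep="\t", index=False)
        perm = screens.permutation_null_pairs(mm, n_perm=config.n_perm_label,
                                              seed=sub[2], family=config.pair_family,
                                              fdr=config.fdr)
        state.update(mm=mm, single=single, pairs=pairs)
        report["metabolome"] = {
            "n_samples": int(len(mm.data)),
            "removed_samples": removed,
            "n_significant_pcs": int(pca.n_significant),
            "pc_variance_fractions": [round(float(v), 4)
                                      for v in pca.variance_fractions[:4]],
            "n_covarying_pairs": int((pairs["q_corr"] <= config.fdr).sum())
            if "q_corr" in pairs else None,
            "n_single_significant": int(single["significant"].sum()),
            "n_interaction_significant": int(pairs["significant"].sum()),
            "permutation": {"observed": perm.observed_count,
                            "null_mean": perm.null_mean,
                            "empirical_p": perm.empirical_p,
                            "n_perm": perm.n_perm},
        }

    # --- covariance networks ---------------------------------------------
    def run_networks():
        mm, pairs = state["mm"], state["pairs"]
        sig = pairs[pairs["significant"]]
        nets = {}
        for f in (4, 0):  # top, bottom
            net = covnet.build_fraction_network(sig, mm.data, mm.meta, f,
                                                p_thresh=config.nominal_p)
            covnet.write_network(net, out / f"network_{FRACTION_NAMES[f]}.tsv")
            nets[FRACTION_NAMES[f]] = net
        summ_top = covnet.network_summary(nets["top"], nets["bottom"])
        summ_bot = covnet.network_summary(nets["bottom"], nets["top"])
        state["networks"] = nets
        report["networks"] = {
            name: {"n_nodes": s["n_nodes"], "n_edges": s["n_edges"],
                   "shared_edges": s["shared_edges"],
                   "max_degree_node": s["max_degree_node"]}
            for name, s in (("top", summ_top), ("bottom", summ_bot))
        }

    # --- graph enrichment -------------------------------------------------
    def run_enrichment():
        graph = synthetic.simulate_hetero_graph(synthetic.GraphSpec(seed=sub[3]))
        io.write_graph_tsv(graph, out / "graph_nodes.tsv", out / "graph_edges.tsv")
        mm = state["mm"]
        gmets = graph.metabolites
        mapping = dict(zip(mm.data.columns[: len(gmets)], gmets))
        index = keggnet.build_path_index(graph)
        nets = state.get("networks", {})
        net = nets.get("bottom")
        cov_pairs = []
        if net is not None:
            for u, v in net.graph.edges:
                if u in mapping and v in mapping:
                    a, b = mapping[u], mapping[v]
                    if np.isfinite(index.pair_distance(a, b)):
                        cov_pairs.append((a, b))
        enr_section: dict[str, Any] = {"n_mapped_pairs": len(index.pairs),
                                       "n_covarying_mapped": len(cov_pairs)}
        if len(cov_pairs) >= 3:
            ple = keggnet.path_length_enrichment(index, cov_pairs)
            enr = keggnet.node_enrichment(index, cov_pairs)
            enr.to_csv(out / "node_enrichment.tsv", sep="\t", index=False)
            top_node = enr.iloc[0]
            rw = keggnet.rewire_permutation(index, cov_pairs, top_node["node"],
                                            n_perm=config.n_perm_rewire, seed=sub[4])
            enr_section.update(
                path_length={"chi2": ple["chi2"], "df": ple["df"], "p": ple["p"]},
                top_node={"node": str(top_node["node"]), "class": str(top_node["class"]),
                          "a": int(top_node["a"]), "A": int(top_node["A"]),
                          "p": float(top_node["p"]), "q": float(top_node["q"])},
                rewire={"observed": rw.observed, "null_mean": rw.null_mean,
                        "empirical_p": rw.empirical_p, "n_perm": rw.n_perm},
            )
        single = state["single"]
        seeds_m = [m for m in single[single["significant"]]["metabolite"] if m in mapping]
        if seeds_m:
            diff = keggnet.diffusion_enrichment(graph, [mapping[m] for m in seeds_m],
                                                n_perm=1000, seed=sub[5])
            pw = diff[diff["class"].isin(["pathway", "module"])].sort_values("p")
            pw.to_csv(out / "diffusion_pathways.tsv", sep="\t", index=False)
            enr_section["diffusion_top_pathway"] = {
                "node": str(pw.iloc[0]["node"]), "p": float(pw.iloc[0]["p"])}
        report["enrichment"] = enr_section

    # --- stress assay -----------------------------------------------------
    def run_stress():
        bang = synthetic.simulate_bang_assay(seed=sub[6])
        io.write_bang_tsv(bang, out / "bang.tsv")
        chi2, dfree, p = stress.fraction_effect_lrt(bang)
        fit = stress.fit_betareg(bang)
        v = bang[bang["treatment"] == "vortex"]
        surv = (v.groupby("fraction")["n_alive_24h"].sum()
                / v.groupby("fraction")["n_flies"].sum())
        report["stress"] = {
            "lrt": {"chi2": chi2, "df": dfree, "p": p},
            "fraction_slope_logit": float(fit.coef.get("fraction", np.nan)),
            "survival_by_fraction": {FRACTION_NAMES[int(f)]: float(s)
                                     for f, s in surv.items()},
        }

    stage("demography", run_demography)
    stage("metabolome", run_metabolome)
    if config.stages.metabolome:
        stage("networks", run_networks)
        stage("enrichment", run_enrichment)
    stage("stress", run_stress)
    logf.close()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
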
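"""End-to-end pipeline stages with file artifacts and a manifest.

Each stage reads/writes plain-text artifacts (CSV/JSON) in an output
directory so runs are inspectable and reproducible: simulate -> curate ->
fit -> evaluate -> group -> associate -> describe.  Every random stage is
seeded from the config; re-running with an identical config reproduces
identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import curation, descriptives, grouping, reproducibility
from .deconfounder import association_regression, build_design, fit_ppca
from .lms import LMSReference
from .mixture import DirichletProcessGMM
from .synthetic import CohortSpec, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "neostrat_run",
    "cohort": {"n_infants": 2000},
    "fit": {"truncation": 60, "weight_concentration": 1e-5, "tol": 1e-3,
            "max_iter": 500, "n_init": 1},
    "evaluate": {"n_runs": 10, "ppc_reps": 100, "holdout_frac": 0.2},
    "group": {"k": 9, "top_coverage": 0.95},
    "associate": {"c1": None, "c0": None, "outcome": "w36_zscore"},
}


def _merge_config(config: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _model_from_config(fit_cfg: dict, seed: int) -> DirichletProcessGMM:
    return DirichletProcessGMM(random_state=seed, **fit_cfg)


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict


def stage_simulate(cfg: dict, outdir: Path):
    spec = CohortSpec(seed=cfg["seed"], **cfg["cohort"])
    episodes, daily, truth = generate_cohort(spec)
    write_cohort(episodes, daily, truth, outdir)
    return episodes, daily, truth


def stage_curate(episodes, daily, outdir: Path):
    cohort = curation.curate(episodes, daily, reference=LMSReference.synthetic())
    cohort.infants.to_csv(outdir / "infants.csv")
    cohort.nutrition.to_csv(outdir / "nutrition_matrix.csv")
    return cohort


def stage_fit(cohort, cfg: dict, outdir: Path):
    model = _model_from_config(cfg["fit"], cfg["seed"]).fit(cohort.matrix)
    labels = model.predict(cohort.matrix)
    pd.Series(labels, index=cohort.nutrition.index, name="cluster") \
        .to_csv(outdir / "labels.csv")
    np.savez(outdir / "model.npz", weights=model.weights_, means=model.means_,
             covariances=model.covariances_, elbo_trace=model.elbo_trace_)
    return model, labels


def stage_evaluate(cohort, model, cfg: dict, outdir: Path) -> dict:
    X = cohort.matrix
    seed = cfg["seed"]
    n_runs = cfg["evaluate"]["n_runs"]
    runs = [_model_from_config(cfg["fit"], seed + 1 + r).fit(X).predict(X)
            for r in range(n_runs)]
    mean_f, sd_f, _ = reproducibility.pairwise_run_agreement(runs, seed=seed)

    odd, even = reproducibility.split_by_birth_year(cohort.infants)
    report = {"pairwise_f_mean": mean_f, "pairwise_f_sd": sd_f,
              "n_runs": n_runs}
    if len(odd) > 10 and len(even) > 10:
        X_odd = cohort.nutrition.loc[odd.index].to_numpy()
        X_even = cohort.nutrition.loc[even.index].to_numpy()
        protocol = reproducibility.split_cohort_protocol(
            X_odd, X_even, lambda s: _model_from_config(cfg["fit"], s),
            seeds=(seed + 101, seed + 102, seed + 103, seed + 104))
        report.update(protocol)

        m_odd = _model_from_config(cfg["fit"], seed + 101).fit(X_odd)
        ppc = reproducibility.posterior_predictive_check(
            m_odd, X_even, statistic="likelihood",
            n_reps=cfg["evaluate"]["ppc_reps"], seed=seed + 7)
        report["ppc_pvalue_heldout_years"] = ppc

        m_even = _model_from_config(cfg["fit"], seed + 103).fit(X_even)
        comparison = reproducibility.compare_cluster_pairs(
            cohort.infants.loc[odd.index], m_odd.predict(X_odd),
            cohort.infants.loc[even.index], m_even.predict(X_even),
            continuous=["ga_weeks", "bw_zscore", "apgar1", "los", "w36_zscore"],
            binary=["sex", "antenatal_steroids", "mortality", "bpd",
                    "mm_at_discharge"],
            match_on=(m_odd.predict(X), m_even.predict(X)))
        report["paired_tests_total"] = comparison.n_tests
        report["paired_tests_fraction_nonsignificant"] = \
            comparison.fraction_nonsignificant
        comparison.tests.to_csv(outdir / "paired_cluster_tests.csv", index=False)
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def stage_group(cohort, labels, cfg: dict, outdir: Path):
    profiles, z = grouping.profile_clusters(cohort.infants, labels,
                                            nutrition=cohort.nutrition)
    # restrict grouping to the most populated clusters covering the target share
    sizes = profiles["size"].sort_values(ascending=False)
    coverage = sizes.cumsum() / sizes.sum()
    top = coverage[coverage.shift(fill_value=0) < cfg["group"]["top_coverage"]].index
    z_top = z.loc[z.index.intersection(top)]
    admission_cols = [c for c in grouping.DEFAULT_PROFILE_ADMISSION if c in z.columns]
    z_adm = z_top[admission_cols]

    profiles.to_csv(outdir / "cluster_profiles.csv")
    k = min(cfg["group"]["k"], len(z_adm))
    if len(z_adm) >= 2:
        tree = grouping.ward_tree(z_adm)
        groups = grouping.cut_admission_groups(tree, k=k)
        coords, loadings, var_frac = grouping.pca_project(z_adm)
        (outdir / "dendrogram.txt").write_text(tree.to_newick() + "\n")
        pd.DataFrame(tree.linkage_matrix,
                     columns=["child_a", "child_b", "height", "n_leaves"]) \
            .to_csv(outdir / "merge_table.csv", index=False)
        coords.join(groups).to_csv(outdir / "pca_coords.csv")
        loadings.to_csv(outdir / "pca_loadings.csv")
        groups.to_csv(outdir / "admission_groups.csv")
        return {"n_clusters_grouped": len(z_adm), "k": k,
                "pca_variance_fractions": list(map(float, var_frac))}
    return {"n_clusters_grouped": len(z_adm), "k": 0}


def stage_associate(cohort, labels, cfg: dict, outdir: Path) -> dict:
    c1, c0 = cfg["associate"]["c1"], cfg["associate"]["c0"]
    if c1 is None or c0 is None:
        sizes = pd.Series(labels).value_counts()
        c1, c0 = sizes.index[0], sizes.index[1]
    outcome = cfg["associate"]["outcome"]
    design = build_design(cohort.infants, labels, c1, c0, outcome)
    factor = fit_ppca(design.covariates, k=3, seed=cfg["seed"] + 11)
    result = association_regression(design, latents=factor.latents)
    result.table.to_csv(outdir / f"association_{outcome}.csv")
    (outdir / f"association_{outcome}.md").write_text(result.to_markdown() + "\n")
    treatment = result.table.loc["Nutritional Treatment"]
    return {"c1": int(c1), "c0": int(c0), "outcome": outcome,
            "family": design.family, "n1": design.n1, "n0": design.n0,
            "ppc_pvalue_factor_model": factor.ppc_pvalue,
            "treatment_coef": float(treatment["coef"]),
            "treatment_ci": [float(treatment["ci_low"]),
                             float(treatment["ci_high"])],
            "treatment_p": float(treatment["p"]),
            "fit_quality": float(result.fit_quality)}


def stage_describe(cohort, episodes, daily, outdir: Path) -> dict:
    any_day = cohort.nutrition > 0
    receipt = descriptives.receipt_by_ga(cohort.infants, any_day)
    receipt.to_csv(outdir / "receipt_by_ga.csv")

    merged = curation.drop_incomplete_days(curation.merge_daily(daily))
    adm = curation.locf_episodic(episodes)
    merged = curation._with_postnatal_day(merged, adm["birth_time"])
    merged = merged[merged["infant_id"].isin(cohort.infants.index)]
    curves = descriptives.component_time_curves(merged, cohort.infants)
    curves.to_csv(outdir / "component_time_curves.csv", index=False)
    hists = descriptives.pattern_histograms(cohort.nutrition)
    hists.to_csv(outdir / "pattern_histograms.csv")
    timelines = descriptives.pattern_timelines(merged)
    timelines.to_csv(outdir / "pattern_timelines.csv")
    count = descriptives.count_pattern_space(6, 49)
    return {"pattern_space_count_6x49": count}


def run_pipeline(config: dict | None = None, outdir=None) -> PipelineResult:
    """Run all stages; returns the manifest of artifacts and key numbers."""
    cfg = _merge_config(config)
    outdir = Path(outdir or cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    logging.getLogger("neostrat").addHandler(handler)
    manifest = {"config": cfg}
    try:
        episodes, daily, truth = stage_simulate(cfg, outdir)
        cohort = stage_curate(episodes, daily, outdir)
        manifest["n_infants_curated"] = int(len(cohort.infants))
        model, labels = stage_fit(cohort, cfg, outdir)
        manifest["n_clusters_1pct"] = model.n_effective_clusters(labels=labels)
        manifest["fit_converged"] = bool(model.converged_)
        manifest["evaluate"] = stage_evaluate(cohort, model, cfg, outdir)
        manifest["group"] = stage_group(cohort, labels, cfg, outdir)
        manifest["associate"] = stage_associate(cohort, labels, cfg, outdir)
        manifest["describe"] = stage_describe(cohort, episodes, daily, outdir)
    finally:
        logging.getLogger("neostrat").removeHandler(handler)
        handler.close()
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return PipelineResult(outdir=outdir, manifest=manifest)
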
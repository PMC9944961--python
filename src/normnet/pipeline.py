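"""End-to-end orchestration of the norms/network analysis.

Stage order mirrors the study's analysis: build norm scores from raw items,
optionally explore the clustering with the feature-saliency mixture, fit
the latent transition model and assign norm groups, profile the baseline
groups against covariates, quantify network change, fit the per-school
STERGMs, and compute the influence descriptives. Each stage writes its
outputs to the run directory; the JSON bundle ties every table to the
config hash and master seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constructs, influence, io, lta, netchange, saliency, stergm
from .data import WAVES
from .synthetic import CohortConfig, generate_study, inject_missingness

log = logging.getLogger(__name__)

STAGES = (
    "scores",
    "cfsc",
    "lta",
    "profiles",
    "network",
    "stergm",
    "influence",
)


@dataclass
class PipelineConfig:
    """Run configuration: exactly one input source (files xor synthetic)."""

    output_dir: str = "normnet_run"
    attributes_csv: str | None = None
    edges_csv: str | None = None
    synthetic: CohortConfig | None = None
    missingness_rate: float = 0.0
    run_cfsc: bool = True
    cfsc_iter: int = 1500
    cfsc_burn_in: int = 300
    lta_classes: int = 3
    lta_restarts: int = 10
    stergm_spec: stergm.StergmSpec = field(default_factory=stergm.StergmSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        files = self.attributes_csv is not None and self.edges_csv is not None
        if files == (self.synthetic is not None):
            raise ValueError(
                "configure exactly one input source: attribute+edge CSVs or a "
                "synthetic cohort"
            )

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = asdict(self.synthetic)
        d["stergm_spec"] = {
            "formation": list(self.stergm_spec.formation),
            "dissolution": list(self.stergm_spec.dissolution),
        }
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_inputs(attributes_csv: str, edges_csv: str):
    """Load and validate the attribute table and per-school networks."""
    table = io.read_attributes_csv(attributes_csv)
    rosters = io.rosters_from_attributes(table)
    networks = io.read_edges_csv(edges_csv, rosters=rosters)
    return table, networks


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the report bundle (also on disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "config": config.to_jsonable(),
        }
    }

    # inputs
    if config.synthetic is not None:
        study = generate_study(config.synthetic)
        table = pd.concat([t for t, _ in study], ignore_index=True)
        if config.missingness_rate > 0:
            table = inject_missingness(
                table, config.missingness_rate, seed=config.seed + 1
            )
        networks = [net for _, net in study]
        io.write_attributes_csv(table, out / "attributes.csv")
        io.write_edges_csv(networks, out / "edges.csv")
    else:
        table, networks = read_inputs(config.attributes_csv, config.edges_csv)

    # stage: norm scores
    _checkpoint("scores")
    scores = constructs.build_norm_scores(table)
    scores.to_csv(out / "scores.csv", index=False)
    n_total = scores.groupby(["school", "student"]).ngroups
    n_complete = int(
        scores[scores["complete"]].groupby(["school", "student"]).ngroups
    )
    log.info("complete cases: %d of %d students", n_complete, n_total)
    report["complete_cases"] = {"complete": n_complete, "total": n_total}

    wide = lta.wide_scores(scores)
    y1 = wide[["descriptive_t0", "injunctive_t0"]].to_numpy(float)
    y2 = wide[["descriptive_t1", "injunctive_t1"]].to_numpy(float)

    # stage: feature-saliency clustering exploration (optional)
    if config.run_cfsc:
        _checkpoint("cfsc")
        pooled = np.vstack([y1, y2])
        cfsc = saliency.gibbs_fit(
            pooled,
            config.lta_classes,
            n_iter=config.cfsc_iter,
            burn_in=config.cfsc_burn_in,
            seed=config.seed + 11,
        )
        cfsc_summary = {
            "weights": cfsc.model.weights.tolist(),
            "means": cfsc.model.means.tolist(),
            "saliency": cfsc.model.saliency.tolist(),
            "bic": cfsc.bic,
            "diagnostics": cfsc.diagnostics,
        }
        (out / "cfsc_summary.json").write_text(json.dumps(cfsc_summary, indent=2))
        pd.DataFrame(
            {"iteration": np.arange(len(cfsc.ll_trace)), "log_likelihood": cfsc.ll_trace}
        ).to_csv(out / "cfsc_trace.csv", index=False)
        report["cfsc"] = cfsc_summary

    # stage: latent transition analysis
    _checkpoint("lta")
    model = lta.fit_lta(
        y1, y2, config.lta_classes, n_restarts=config.lta_restarts,
        seed=config.seed + 23,
    )
    assignments = lta.assign_students(model, wide)
    assignments.to_csv(out / "assignments.csv", index=False)
    model_json = {
        "n_classes": model.n_classes,
        "class_labels": model.class_labels,
        "means": model.means.tolist(),
        "variances": model.variances.tolist(),
        "pi": model.pi.tolist(),
        "tau": model.tau.tolist(),
        "log_likelihood": model.log_likelihood,
        "bic": model.bic,
        "relative_entropy": model.relative_entropy,
    }
    (out / "lta_model.json").write_text(json.dumps(model_json, indent=2))
    report["lta"] = model_json
    counts, prevalence = lta.transition_table(assignments, table)
    pd.DataFrame(
        counts,
        index=[f"baseline_{k}" for k in range(1, model.n_classes + 1)],
        columns=[f"followup_{k}" for k in range(1, model.n_classes + 1)],
    ).to_csv(out / "transition_counts.csv")
    if prevalence is not None:
        prevalence.to_csv(out / "table1_prevalence.csv", index=False)
        report["prevalence"] = prevalence.to_dict(orient="records")
    report["transition_counts"] = counts.tolist()

    # stage: covariate profiling of baseline groups
    _checkpoint("profiles")
    base = table[table["wave"] == WAVES[0]].drop_duplicates(
        subset=["school", "student"]
    )
    merged = assignments.merge(base, on=["school", "student"], how="inner")
    covar_cols = [
        "intervention", "sex", "age_category", "ethnic_minority",
        "home_composition", "setting", "self_efficacy", "need_to_belong",
        "fear_negative_evaluation", "prosocial_behavior", "openness",
        "extraversion", "agreeableness", "conscientiousness",
        "emotional_stability",
    ]
    covar_cols = [c for c in covar_cols if c in merged.columns]
    label_of = {k + 1: lab for k, lab in enumerate(model.class_labels)}
    outcome = merged["class_t0"].map(label_of)
    try:
        fit = _profiles(outcome, merged[covar_cols])
    except Exception as err:
        raise RuntimeError(f"stage 'profiles' failed: {err}") from err
    fit.table.to_csv(out / "table2_profile.csv", index=False)
    report["profiles"] = fit.table.to_dict(orient="records")

    # stage: network change
    _checkpoint("network")
    net_table = netchange.network_table(networks)
    net_table.to_csv(out / "table3_network.csv", index=False)
    report["network"] = net_table.to_dict(orient="records")

    # stage: STERGM homophily
    _checkpoint("stergm")
    stergm_table = stergm.fit_all_schools(networks, assignments, config.stergm_spec)
    stergm_table.to_csv(out / "table4_stergm.csv", index=False)
    report["stergm"] = stergm_table.to_dict(orient="records")

    # stage: influence descriptives
    _checkpoint("influence")
    cat_counts = (
        assignments["transition_category"].value_counts().sort_index()
    )
    cat_counts.rename_axis("transition_category").to_frame("n").to_csv(
        out / "fig1_transition_counts.csv"
    )
    report["transition_categories"] = cat_counts.to_dict()
    profile = influence.friend_change_profile(assignments, networks, table)
    profile = profile.sort_values(
        ["ego_category", "tie_class", "setting", "intervention", "friend_category"]
    ).reset_index(drop=True)
    profile.to_csv(out / "fig3_friend_profile.csv", index=False)
    report["friend_profile"] = profile.to_dict(orient="records")
    threshold = influence.baseline_threshold_table(assignments, networks)
    threshold.to_csv(out / "threshold_table.csv", index=False)
    report["threshold"] = threshold.to_dict(orient="records")
    try:
        stat, dof, p, obs = influence.transition_intervention_chisq(
            assignments, table
        )
    except Exception as err:
        raise RuntimeError(f"stage 'influence' failed: {err}") from err
    report["chisq"] = {
        "statistic": stat, "df": dof, "p_value": p, "table": obs.tolist(),
    }
    (out / "chisq.json").write_text(json.dumps(report["chisq"], indent=2))

    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=_jsonable, sort_keys=True)
    )
    return report


def _profiles(outcome, covariates):
    from .profiles import fit_multinomial

    return fit_multinomial(
        outcome,
        covariates,
        reference_class="both-against",
        references={
            "sex": "boy",
            "age_category": "11",
            "home_composition": "single parent",
            "setting": "COL",
            "intervention": "peer-led",
        },
    )


def _checkpoint(stage: str) -> None:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    log.info("stage: %s", stage)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
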
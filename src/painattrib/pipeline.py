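"""End-to-end orchestration: simulate → code/autoscore → wordfreq →
scale → analyze → report.

File dialect (UTF-8 CSV with header, quoting as needed):

* attributions.csv — participant_id, timepoint ∈ {pre, post}, rank ∈
  {1,2,3}, text
* participants.csv — participant_id, arm ∈ {prt, placebo, usual_care},
  pain_pre, pain_post, pain_1yr in [0,10] (optionally tsk/pcs/sopa
  totals)
* codings.csv — participant_id, timepoint, rank, coder_id, category
* lexicon.json — {"source": ..., "raw_terms": [...]}

A run directory receives every stage's tables, a ``report.json`` with
the inferential results, and a ``provenance.json`` (config hash, package
version, seed) sufficient to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codebook import DEFAULT_CODEBOOK, Codebook
from .coding import consensus_assignments, disagreement_rate, mind_brain_score, prevalence_table
from .corpus import build_dtm, save_dtm, tokenize_attributions
from .inference import (
    association_change_vs_outcome,
    hedges_g,
    mediate,
)
from .lexicon import Lexicon, autoscore_table, benchmark_against_human, default_lexicon
from .scaling import fit_scaling, orient_dimension, position_group_difference
from .synthetic import ARMS, SimulationConfig, generate_trial, truth_to_codings
from .wordfreq import frequency_change

log = logging.getLogger("painattrib")

VALID_TIMEPOINTS = {"pre", "post"}


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    output_dir: str = "painattrib_run"
    attributions: str | None = None
    participants: str | None = None
    codings: str | None = None
    lexicon: str | None = None
    simulate: SimulationConfig | None = None
    min_doc_freq: int = 1
    doc_unit: str = "participant_timepoint"
    lambda_beta: float = 0.1
    lambda_theta: float = 0.1
    n_boot: int = 5000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        sim = obj.pop("simulate", None)
        cfg = cls(**obj)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def canonical_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "simulate"}
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim.pop("codebook", None)
            d["simulate"] = sim
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidationFinding:
    file: str
    row: int | None
    column: str | None
    message: str

    def to_dict(self) -> dict:
        return asdict(self)


def validate_inputs(
    attributions: pd.DataFrame,
    participants: pd.DataFrame,
    codings: pd.DataFrame | None = None,
    codebook: Codebook = DEFAULT_CODEBOOK,
) -> list[ValidationFinding]:
    """Schema validation; returns a structured report, never fails silently."""
    findings: list[ValidationFinding] = []

    def err(file, row, column, message):
        findings.append(ValidationFinding(file, row, column, message))

    for i, tp in attributions["timepoint"].items():
        if tp not in VALID_TIMEPOINTS:
            err("attributions.csv", int(i), "timepoint", f"invalid timepoint {tp!r}")
    for i, rk in attributions["rank"].items():
        if rk not in (1, 2, 3):
            err("attributions.csv", int(i), "rank", f"rank must be 1-3, got {rk!r}")
    dup = attributions.duplicated(["participant_id", "timepoint", "rank"], keep=False)
    for i in attributions.index[dup]:
        err("attributions.csv", int(i), "rank", "duplicate rank within participant-timepoint")

    for i, arm in participants["arm"].items():
        if arm not in ARMS:
            err("participants.csv", int(i), "arm", f"invalid arm {arm!r}")
    for col in ("pain_pre", "pain_post", "pain_1yr"):
        if col not in participants.columns:
            continue
        vals = pd.to_numeric(participants[col], errors="coerce")
        for i in participants.index[(vals < 0) | (vals > 10)]:
            err("participants.csv", int(i), col,
                f"pain value {participants.loc[i, col]!r} outside [0, 10]")
    dup = participants.duplicated("participant_id", keep=False)
    for i in participants.index[dup]:
        err("participants.csv", int(i), "participant_id", "duplicated participant_id")
    unknown = set(attributions["participant_id"]) - set(participants["participant_id"])
    if unknown:
        err("attributions.csv", None, "participant_id",
            f"{len(unknown)} participant id(s) absent from participants.csv")

    if codings is not None:
        bad = set(codings["category"].dropna()) - set(codebook.categories)
        if bad:
            err("codings.csv", None, "category", f"categories outside codebook: {sorted(bad)}")
        dup = codings.duplicated(["participant_id", "timepoint", "rank", "coder_id"], keep=False)
        for i in codings.index[dup]:
            err("codings.csv", int(i), "coder_id", "duplicate coding for one coder")
    return findings


def _json_bytes(obj: dict) -> bytes:
    return (json.dumps(obj, sort_keys=True, indent=2) + "\n").encode()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order; returns the report dict.

    Reruns with an identical config and inputs produce byte-identical
    outputs (single seeded random stream, deterministic serialization,
    no timestamps in machine-readable artifacts).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    codebook = DEFAULT_CODEBOOK
    if config.simulate is not None:
        log.info("simulating trial (n_per_arm=%d)", config.simulate.n_per_arm)
        dataset, truth = generate_trial(config.simulate)
        attributions, participants = dataset.attributions, dataset.participants
        codings = truth_to_codings(truth)
        # codings cover only attributions that were actually observed
        codings = codings.merge(
            attributions[["participant_id", "timepoint", "rank"]],
            on=["participant_id", "timepoint", "rank"],
        )
        attributions.to_csv(out / "attributions.csv", index=False)
        participants.to_csv(out / "participants.csv", index=False)
        codings.to_csv(out / "codings.csv", index=False)
        (out / "truth.json").write_bytes(_json_bytes(truth.to_dict()))
        truth.categories.to_csv(out / "truth_categories.csv", index=False)
    else:
        for name in ("attributions", "participants"):
            path = getattr(config, name)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"required input missing: {name} ({path})")
        attributions = pd.read_csv(config.attributions)
        participants = pd.read_csv(config.participants)
        codings = pd.read_csv(config.codings) if config.codings else None

    findings = validate_inputs(attributions, participants, codings, codebook)
    (out / "validation.json").write_bytes(
        _json_bytes({"findings": [f.to_dict() for f in findings]})
    )
    if findings:
        raise ValueError(
            f"{len(findings)} input validation error(s); see {out / 'validation.json'}"
        )

    lexicon: Lexicon = (
        Lexicon.from_json(config.lexicon) if config.lexicon else default_lexicon()
    )
    report: dict = {"models": {
        "delta_score_contrast": "delta_score ~ arm indicator + score_pre (standardized)",
        "association": "pain_post ~ arm dummies + pain_pre + delta_score (standardized)",
        "mediation": "X = prt vs combined controls, M = delta_score, Y = pain_1yr, "
                     "covariate pain_pre; percentile bootstrap",
    }}

    # ---- human coding -----------------------------------------------------
    scores = None
    if codings is not None:
        n_dis, n_attr, pct = disagreement_rate(codings)
        consensus, _ = consensus_assignments(codings, require_two_coders=False)
        scores = mind_brain_score(consensus, codebook)
        scores.to_csv(out / "scores.csv", index=False)
        prev = prevalence_table(consensus, codebook, group_by=["arm", "timepoint"],
                                participants=participants)
        prev.to_csv(out / "prevalence.csv", index=False)
        pre_scores = scores[scores["timepoint"] == "pre"]["score"]
        report["coding"] = {
            "n_attributions_coded": n_attr,
            "n_disagreements": n_dis,
            "disagreement_percent": pct,
            "mean_pre_score": round(float(pre_scores.mean()), 6),
            "median_pre_score": float(pre_scores.median()),
        }

    # ---- automated scoring ------------------------------------------------
    auto = autoscore_table(attributions, lexicon)
    auto.to_csv(out / "auto_scores.csv", index=False)
    if scores is not None:
        bench = {}
        for tp in ("pre", "post"):
            bench[tp] = benchmark_against_human(auto, scores, timepoint=tp).to_dict()
        (out / "benchmark.json").write_bytes(_json_bytes(bench))
        report["benchmark"] = bench

    # ---- corpus, word frequency, scaling ---------------------------------
    docs = tokenize_attributions(attributions, config.doc_unit, participants)
    dtm = build_dtm(docs, min_doc_freq=config.min_doc_freq)
    save_dtm(dtm, out / "dtm")
    for arm in sorted(set(dtm.meta["arm"].dropna())):
        deltas = frequency_change(dtm, arm)
        deltas.to_csv(out / f"word_deltas_{arm}.csv", index=False)
        if arm == "prt":
            top = deltas.iloc[0]
            report["wordfreq_prt"] = {
                "top_increase_stem": str(top["stem"]),
                "top_increase_delta_per_100": round(float(top["delta"]), 6),
                "n_novel_stems": int(deltas["novel"].sum()),
            }

    fit = fit_scaling(dtm, config.lambda_beta, config.lambda_theta, seed=config.seed)
    fit = orient_dimension(fit, lexicon)
    pos = fit.position_table().merge(dtm.meta, on="doc_id")
    pos.to_csv(out / "positions.csv", index=False)
    fit.loading_table().to_csv(out / "loadings.csv", index=False)
    post = pos[pos["timepoint"] == "post"]
    scaling_block = {"converged": bool(fit.converged), "n_iter": int(fit.n_iter)}
    for other in ("placebo", "usual_care"):
        a = post.loc[post["arm"] == "prt", "theta"]
        b = post.loc[post["arm"] == other, "theta"]
        if len(a) >= 2 and len(b) >= 2:
            scaling_block[f"prt_vs_{other}"] = position_group_difference(a, b).to_dict()
    report["scaling"] = scaling_block
    (out / "scaling.json").write_bytes(_json_bytes(scaling_block))

    # ---- inferential analyses ---------------------------------------------
    if scores is not None:
        wide = scores.pivot(index="participant_id", columns="timepoint", values="score")
        wide = wide.rename(columns={"pre": "score_pre", "post": "score_post"})
        data = participants.merge(wide, on="participant_id", how="left")
        data["delta_score"] = data["score_post"] - data["score_pre"]
        data["prt"] = (data["arm"] == "prt").astype(float)

        analyses: dict = {}
        for other in ("placebo", "usual_care"):
            sub = data[data["arm"].isin(["prt", other])].dropna(subset=["delta_score"])
            eff = hedges_g(
                sub.loc[sub["arm"] == "prt", "delta_score"],
                sub.loc[sub["arm"] == other, "delta_score"],
            )
            analyses[f"delta_score_g_prt_vs_{other}"] = eff.to_dict()
        try:
            from .inference import ancova_effect

            contrasts = ancova_effect(
                data.dropna(subset=["delta_score"]),
                outcome="delta_score",
                contrasts=[("prt", "placebo"), ("prt", "usual_care")],
                covariates=["score_pre"],
            )
            analyses["delta_score_contrasts"] = {k: v.to_dict() for k, v in contrasts.items()}
        except ValueError as exc:
            analyses["delta_score_contrasts"] = {"error": str(exc)}

        try:
            model, r = association_change_vs_outcome(
                data, change_var="delta_score", outcome="pain_post", baseline="pain_pre"
            )
            analyses["association_delta_vs_pain_post"] = {
                "model": model.to_dict(), "pearson": r.to_dict()
            }
        except ValueError as exc:
            analyses["association_delta_vs_pain_post"] = {"error": str(exc)}

        try:
            med = mediate(
                data, x="prt", m="delta_score", y="pain_1yr",
                covariates=["pain_pre"], n_boot=config.n_boot, seed=config.seed,
            )
            analyses["mediation"] = med.to_dict()
        except (ValueError, RuntimeError) as exc:
            analyses["mediation"] = {"error": str(exc)}
        report["analyses"] = analyses

    (out / "report.json").write_bytes(_json_bytes(report))
    (out / "provenance.json").write_bytes(
        _json_bytes(
            {
                "package": "painattrib",
                "version": __version__,
                "config": config.canonical_dict(),
                "config_hash": config.content_hash(),
                "seed": config.seed,
            }
        )
    )
    return report
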
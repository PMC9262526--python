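"""End-to-end orchestration: simulate -> CAT -> standardize -> calibrate ->
agreement -> responsiveness/MCID -> responder classification -> logistic
linkage, with one master seed feeding named substreams and a JSONL run log.

Outputs are deterministic byte-for-byte for a fixed configuration and seed
(no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ELEMENTS, substream
from .cat_engine import (
    AbilityPrior,
    CATConfig,
    ItemBank,
    administer_cat,
    generate_item_bank,
)
from .diagnostic_evaluation import diagnostic_table
from .mcid_estimation import format_mcid_table, mcid_table, responsiveness_table
from .outcome_linkage import (
    classify_outcomes,
    element_change_frame,
    format_linkage_table,
    linkage_report,
)
from .standardization import fit_standardizer, standardize_frame
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "run_cat_on_cohort"]


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cat: CATConfig = field(default_factory=CATConfig)
    bank_source: str = "generate"  # "generate" or a CSV path
    n_items: int = 215
    n_categories: int = 5
    es: float = 0.2
    anchor_stratum: str = "pooled"
    predictor_coding: str = "continuous"
    outdir: str = "tcmcat_run"
    seed: int = 0

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        obj = json.loads(s)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "cohort" in obj:
            cfields = {f.name for f in dataclasses.fields(CohortConfig)}
            bad = set(obj["cohort"]) - cfields
            if bad:
                raise ValueError(f"unknown cohort keys: {sorted(bad)}")
            obj["cohort"] = CohortConfig(**obj["cohort"])
        if "cat" in obj:
            obj["cat"] = CATConfig(**obj["cat"])
        return cls(**obj)

    def to_json(self) -> str:
        obj = dataclasses.asdict(self)
        return json.dumps(obj, indent=2, default=lambda o: list(o) if isinstance(o, tuple) else o)


@dataclass
class ReportBundle:
    outdir: Path
    paths: dict[str, Path]
    cohort: list
    bank: ItemBank
    std_baseline: pd.DataFrame
    std_followup: pd.DataFrame
    diagnostics: pd.DataFrame
    mcid: pd.DataFrame
    responsiveness: pd.DataFrame
    linkage: dict


def run_cat_on_cohort(records, bank, cat_config, prior, rng, timepoint="baseline"):
    """Administer one CAT session per (eligible) patient at one timepoint.

    Returns (raw score frame indexed by patient_id, list of transcripts).
    """
    rows, transcripts = {}, []
    for r in records:
        theta = r.theta_baseline if timepoint == "baseline" else r.theta_followup
        if not np.all(np.isfinite(theta)):
            continue
        res = administer_cat(bank, true_theta=theta, config=cat_config, prior=prior, rng=rng)
        rows[r.patient_id] = res.raw_cat_score
        transcripts.append(
            {
                "patient_id": r.patient_id,
                "timepoint": timepoint,
                "steps": res.trajectory,
            }
        )
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(ELEMENTS))
    frame.index.name = "patient_id"
    return frame, transcripts


def _log_event(log_path: Path, **event) -> None:
    with open(log_path, "a") as fh:
        fh.write(json.dumps(event) + "\n")


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis; see the module docstring for the stages."""
    outdir = Path(config.outdir)
    stage = "validate"
    try:
        # configuration is validated by construction; re-resolve derived bits
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.cohort.seed)
        outdir.mkdir(parents=True, exist_ok=True)
        log_path = outdir / "run_log.jsonl"
        log_path.write_text("")
        paths: dict[str, Path] = {"log": log_path}
        _log_event(log_path, stage=stage, seed=config.seed, status="ok")

        stage = "simulate"
        cohort = generate_cohort(cohort_cfg, rng=substream(config.seed, "cohort"))
        paths["cohort"] = outdir / "cohort.csv"
        write_cohort(cohort, paths["cohort"])
        n_follow = sum(1 for r in cohort if not r.dropped)
        _log_event(log_path, stage=stage, n_baseline=len(cohort), n_followup=n_follow)

        stage = "item_bank"
        if config.bank_source == "generate":
            bank = generate_item_bank(
                n_items=config.n_items,
                n_categories=config.n_categories,
                seed=substream(config.seed, "bank"),
            )
        else:
            bank = ItemBank.read_csv(config.bank_source)
        paths["bank"] = outdir / "item_bank.csv"
        bank.to_csv(paths["bank"])
        _log_event(log_path, stage=stage, n_items=len(bank))

        stage = "cat"
        prior = AbilityPrior.standard()
        raw_b, tr_b = run_cat_on_cohort(
            cohort, bank, config.cat, prior, substream(config.seed, "cat_baseline"), "baseline"
        )
        raw_f, tr_f = run_cat_on_cohort(
            cohort, bank, config.cat, prior, substream(config.seed, "cat_followup"), "followup"
        )
        paths["transcripts"] = outdir / "cat_transcripts.json"
        paths["transcripts"].write_text(json.dumps(tr_b + tr_f))
        _log_event(log_path, stage=stage, sessions=len(raw_b) + len(raw_f))

        stage = "standardize"
        pooled = pd.concat([raw_b, raw_f], axis=0)
        params = fit_standardizer(pooled, provenance="pooled baseline+followup CAT scores")
        std_b = standardize_frame(raw_b, params)
        std_f = standardize_frame(raw_f, params)
        paths["standardization"] = outdir / "standardization_params.json"
        paths["standardization"].write_text(params.to_json())
        paths["scores_baseline"] = outdir / "standardized_baseline.csv"
        paths["scores_followup"] = outdir / "standardized_followup.csv"
        std_b.to_csv(paths["scores_baseline"])
        std_f.to_csv(paths["scores_followup"])
        _log_event(log_path, stage=stage, **{e: params.extremes[e] for e in ELEMENTS})

        stage = "diagnostics"
        dx = pd.DataFrame(
            {e: [r.clinician_dx_baseline[j] for r in cohort] for j, e in enumerate(ELEMENTS)},
            index=[r.patient_id for r in cohort],
        )
        diag = diagnostic_table(std_b, dx.loc[std_b.index])
        paths["diagnostics"] = outdir / "diagnostic_table.csv"
        diag.to_csv(paths["diagnostics"], index=False)
        _log_event(log_path, stage=stage, min_auc=float(diag["auc"].min()))

        stage = "mcid"
        resp = responsiveness_table(cohort)
        mcid = mcid_table(cohort, es=config.es, stratum=config.anchor_stratum)
        paths["responsiveness"] = outdir / "responsiveness.csv"
        paths["mcid"] = outdir / "mcid_table.csv"
        resp.to_csv(paths["responsiveness"], index=False)
        format_mcid_table(mcid).to_csv(paths["mcid"], index=False)
        _log_event(
            log_path,
            stage=stage,
            fallback_mean=int((mcid["anchor_method"] == "fallback_mean").sum()),
        )

        stage = "linkage"
        outcomes = classify_outcomes(cohort, mcid)
        changes = element_change_frame(std_b, std_f)
        fits = linkage_report(
            changes, outcomes, predictor_coding=config.predictor_coding, on_unfittable="null"
        )
        for domain, fit in fits.items():
            if not fit.converged and fit.n_iter == 0:
                _log_event(log_path, stage=stage, domain=domain, warning="unfittable outcome")
            p = outdir / f"linkage_{domain}.csv"
            format_linkage_table(fit).to_csv(p, index=False)
            paths[f"linkage_{domain}"] = p
            if fit.separation:
                _log_event(log_path, stage=stage, domain=domain, warning="quasi-separation")
        _log_event(log_path, stage=stage, tables=len(fits))

        stage = "snapshot"
        paths["config"] = outdir / "config.json"
        paths["config"].write_text(config.to_json())

        return ReportBundle(
            outdir=outdir,
            paths=paths,
            cohort=cohort,
            bank=bank,
            std_baseline=std_b,
            std_followup=std_f,
            diagnostics=diag,
            mcid=mcid,
            responsiveness=resp,
            linkage=fits,
        )
    except Exception:
        logger.exception("pipeline aborted at stage %s", stage)
        raise
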
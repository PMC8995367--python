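"""End-to-end study pipeline: ingest or simulate a cohort, run all fits and
group statistics, and emit a reproducible report bundle.

Stage order mirrors the analysis: validate -> RT filter -> confidence-set
split -> psychometric fits (chosen and unsorted) -> deviance check -> CMI +
transform + outlier exclusion -> RT cells + exponential RT fits -> EF
composite -> group statistics -> confidence-choice maps.  Every number in
the report is regenerable from the bundled config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .confidence import (choice_probability_map, cmi, flag_outliers,
                         split_sets, transform_cmi)
from .design import (DesignSpec, decisions_long, filter_rts,
                     read_participants_table, read_session_table,
                     write_participants_table, write_session_table)
from .observer import CohortSpec, DEFAULT_GROUPS, GroupParams, simulate_cohort
from .psychometric import aggregate_proportions, fit_cumulative_gaussian
from .rt_model import cell_medians, fit_rt_model
from .stats import (StatResult, correlation, ef_composite, mixed_anova,
                    one_sample_t, results_table, t_compare)

logger = logging.getLogger("metaconf")

DEFAULT_CONFIG = {
    "design": {},              # DesignSpec field overrides
    "filter": {"low_ms": 100.0, "high_ms": 3000.0},
    "bootstrap": {"n": 2000, "seed": 0},
    "cohort": {},              # CohortSpec field overrides (simulation only)
    "seed": 0,
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _cohort_spec(config: dict) -> CohortSpec:
    cfg = dict(config.get("cohort", {}))
    groups = dict(DEFAULT_GROUPS)
    for gname, overrides in (cfg.pop("groups", None) or {}).items():
        groups[gname] = GroupParams(**{**vars(DEFAULT_GROUPS[gname]),
                                       **overrides})
    design = DesignSpec(**config.get("design", {}))
    seed = cfg.pop("seed", config.get("seed", 0))
    return CohortSpec(groups=groups, design=design, seed=seed, **cfg)


@dataclass
class StudyReport:
    """Full analysis bundle for one (real or simulated) cohort."""

    participants: pd.DataFrame
    psychometric: pd.DataFrame     # per participant x confidence set
    confidence: pd.DataFrame       # per participant CMI summary
    rt_fits: pd.DataFrame          # per participant RT model parameters
    ef: pd.DataFrame               # EF composite z-scores
    stats: pd.DataFrame            # group-level inferential tests
    maps: pd.DataFrame             # long-format confidence-choice maps
    exclusion_rates: pd.Series     # RT-filter exclusion per participant
    provenance: dict = field(default_factory=dict)

    def included(self) -> pd.DataFrame:
        """Confidence rows of participants that survive outlier exclusion."""
        return self.confidence[~self.confidence["outlier"]]


def _analyse_participant(pid: str, trials: pd.DataFrame, config: dict):
    """Stages 2-7 for one participant; raises with stage context."""
    stage = "rt-filter"
    try:
        decisions = decisions_long(trials)
        kept, rate = filter_rts(decisions, **config["filter"])
        stage = "confidence-split"
        chosen, unsorted_set = split_sets(trials, decisions)
        stage = "psychometric-fit"
        fits = {}
        for label, dec in (("chosen", chosen), ("unsorted", unsorted_set)):
            counts = aggregate_proportions(dec["delta"], dec["decision"])
            fits[label] = fit_cumulative_gaussian(counts)
        stage = "rt-model"
        cells = cell_medians(kept, fits["unsorted"])
        rt_fit = fit_rt_model(cells)
        median_rts = {
            label: float(kept.loc[kept["confident"] >= lo, "rt_ms"].median())
            for label, lo in (("chosen", 1), ("unsorted", 0))}
    except Exception as err:
        raise RuntimeError(
            f"stage {stage!r} failed for participant {pid!r}: {err}") from err
    return fits, rt_fit, median_rts, rate


def run_study(config: dict | None = None, data_dir=None,
              simulate: bool = False, seed: int | None = None) -> StudyReport:
    """Run the complete analysis on a data directory or a simulated cohort.

    ``data_dir`` must contain ``participants.csv`` and one
    ``session_<participant_id>.csv`` per participant; with ``simulate=True``
    a cohort is generated from the config's cohort block instead.
    """
    config = _merge(DEFAULT_CONFIG, config)
    if seed is not None:
        config["seed"] = seed
    spec = DesignSpec(**config["design"])

    if simulate:
        cohort = simulate_cohort(_cohort_spec(config))
        participants, sessions = cohort.participants, cohort.sessions
    elif data_dir is not None:
        data_dir = Path(data_dir)
        participants = read_participants_table(data_dir / "participants.csv")
        sessions = {}
        for pid in participants["participant_id"]:
            _, sessions[pid] = read_session_table(
                data_dir / f"session_{pid}.csv", spec=spec)
    else:
        raise ValueError("either simulate=True or a data directory required")

    psych_rows, conf_rows, rt_rows, rates = [], [], [], {}
    for pid, trials in sessions.items():
        fits, rt_fit, median_rts, rate = _analyse_participant(
            pid, trials, config)
        rates[pid] = float(rate.iloc[0]) if len(rate) else 0.0
        for label, f in fits.items():
            psych_rows.append({
                "participant_id": pid, "set_label": label, "mu": f.mu,
                "sigma": f.sigma, "sensitivity": f.sensitivity,
                "lambda": f.lam, "deviance": f.deviance,
                "n_total": f.n_total,
                "median_rt_ms": median_rts[label]})
        value = cmi(fits["chosen"].sensitivity, fits["unsorted"].sensitivity)
        conf_rows.append({
            "participant_id": pid,
            "sensitivity_chosen": fits["chosen"].sensitivity,
            "sensitivity_unsorted": fits["unsorted"].sensitivity,
            "pse_chosen": fits["chosen"].mu,
            "pse_unsorted": fits["unsorted"].mu,
            "deviance_chosen": fits["chosen"].deviance,
            "deviance_unsorted": fits["unsorted"].deviance,
            "cmi": value, "cmi_transformed": transform_cmi(value)})
        rt_rows.append({"participant_id": pid, "alpha": rt_fit.alpha,
                        "beta": rt_fit.beta, "gamma": rt_fit.gamma,
                        "rss": rt_fit.rss, "n_cells": rt_fit.n_cells})

    psychometric = pd.DataFrame(psych_rows)
    confidence = pd.DataFrame(conf_rows)
    rt_fits = pd.DataFrame(rt_rows)
    confidence["outlier"] = flag_outliers(confidence["cmi"])
    n_out = int(confidence["outlier"].sum())
    if n_out:
        logger.info("outlier exclusion: %d participant(s) flagged (Tukey "
                    "fences on pooled CMIs)", n_out)
    confidence = confidence.merge(
        participants[["participant_id", "age_group"]], on="participant_id")
    ef = ef_composite(participants)

    stats = _group_statistics(participants, psychometric, confidence,
                              rt_fits, ef, config)
    maps = _group_maps(participants, sessions)

    provenance = {
        "version": __version__, "config": config, "simulated": simulate,
        "n_participants": int(len(participants)),
        "n_excluded_outlier": n_out,
    }
    return StudyReport(
        participants=participants, psychometric=psychometric,
        confidence=confidence, rt_fits=rt_fits, ef=ef, stats=stats,
        maps=maps, exclusion_rates=pd.Series(rates, name="exclusion_rate"),
        provenance=provenance)


def _group_statistics(participants, psychometric, confidence, rt_fits, ef,
                      config) -> pd.DataFrame:
    """The study's inferential battery on outlier-excluded data."""
    n_boot = config["bootstrap"]["n"]
    base_seed = config["bootstrap"]["seed"]
    seed_counter = iter(range(base_seed, base_seed + 10_000))

    included = confidence[~confidence["outlier"]]
    keep = included["participant_id"]
    psych = psychometric[psychometric["participant_id"].isin(keep)].merge(
        participants[["participant_id", "age_group"]], on="participant_id")
    rt = rt_fits[rt_fits["participant_id"].isin(keep)].merge(
        participants[["participant_id", "age_group"]], on="participant_id")
    efv = ef.merge(participants[["participant_id", "age_group", "digit_span"]],
                   on="participant_id")
    efv = efv[efv["participant_id"].isin(keep)]
    merged = included.merge(efv.drop(columns="age_group"),
                            on="participant_id")

    old = included["age_group"] == "older"
    results: list[StatResult] = []

    def grp(frame, col, group, label=None, set_label=None):
        sub = frame
        if set_label is not None:
            sub = sub[sub["set_label"] == set_label]
        return sub.loc[sub["age_group"] == group, col].to_numpy(float)

    # sensitivity: mixed ANOVA + follow-ups
    results += mixed_anova(psych, dv="sensitivity", within="set_label",
                           subject="participant_id", between="age_group")
    for label in ("chosen", "unsorted"):
        results.append(t_compare(
            grp(psych, "sensitivity", "older", set_label=label),
            grp(psych, "sensitivity", "younger", set_label=label),
            name=f"sensitivity {label}: older vs younger",
            n_boot=n_boot, seed=next(seed_counter)))
    for group in ("older", "younger"):
        results.append(t_compare(
            grp(psych, "sensitivity", group, set_label="chosen"),
            grp(psych, "sensitivity", group, set_label="unsorted"),
            paired=True, name=f"sensitivity chosen vs unsorted ({group})",
            n_boot=n_boot, seed=next(seed_counter)))
        results.append(t_compare(
            included.loc[included["age_group"] == group, "pse_chosen"],
            included.loc[included["age_group"] == group, "pse_unsorted"],
            paired=True, name=f"PSE chosen vs unsorted ({group})",
            n_boot=n_boot, seed=next(seed_counter)))
    # goodness of fit between sets
    results.append(t_compare(
        included["deviance_chosen"], included["deviance_unsorted"],
        paired=True, name="deviance chosen vs unsorted",
        n_boot=n_boot, seed=next(seed_counter)))

    # CMI: one-sample and group tests, raw and transformed
    for group in ("older", "younger"):
        sub = included[included["age_group"] == group]
        results.append(one_sample_t(
            sub["cmi"], 0.0, name=f"CMI vs 0 ({group})",
            n_boot=n_boot, seed=next(seed_counter)))
        results.append(one_sample_t(
            sub["cmi_transformed"], 0.0,
            name=f"transformed CMI vs 0 ({group})",
            n_boot=n_boot, seed=next(seed_counter)))
    results.append(t_compare(
        included.loc[old, "cmi"], included.loc[~old, "cmi"],
        name="CMI: older vs younger", n_boot=n_boot,
        seed=next(seed_counter)))
    results.append(t_compare(
        included.loc[old, "cmi_transformed"],
        included.loc[~old, "cmi_transformed"],
        name="transformed CMI: older vs younger", n_boot=n_boot,
        seed=next(seed_counter)))

    # EF and digit span
    results.append(t_compare(
        efv.loc[efv["age_group"] == "older", "ef"],
        efv.loc[efv["age_group"] == "younger", "ef"],
        name="EF score: older vs younger", n_boot=n_boot,
        seed=next(seed_counter)))
    results.append(t_compare(
        efv.loc[efv["age_group"] == "older", "digit_span"],
        efv.loc[efv["age_group"] == "younger", "digit_span"],
        name="digit span: older vs younger", n_boot=n_boot,
        seed=next(seed_counter)))

    # correlations with confidence efficiency
    group_code = (merged["age_group"] == "older").astype(float)
    results.append(correlation(
        merged["cmi"], merged["ef"], name="CMI x EF",
        n_boot=n_boot, seed=next(seed_counter)))
    results.append(correlation(
        merged["cmi"], merged["ef"], control=group_code,
        name="CMI x EF (partial, age group)",
        n_boot=n_boot, seed=next(seed_counter)))
    results.append(correlation(
        merged["cmi"], merged["digit_span"], name="CMI x digit span",
        n_boot=n_boot, seed=next(seed_counter)))

    # RTs: mixed ANOVA on median RT per set, parameter comparisons
    results += mixed_anova(psych, dv="median_rt_ms", within="set_label",
                           subject="participant_id", between="age_group")
    for par in ("alpha", "beta", "gamma"):
        results.append(t_compare(
            rt.loc[rt["age_group"] == "older", par],
            rt.loc[rt["age_group"] == "younger", par],
            name=f"RT {par}: older vs younger", n_boot=n_boot,
            seed=next(seed_counter)))
        for group in ("older", "younger"):
            results.append(one_sample_t(
                rt.loc[rt["age_group"] == group, par], 0.0,
                name=f"RT {par} vs 0 ({group})", n_boot=0))
    rt_wide = psych.pivot(index="participant_id", columns="set_label",
                          values="median_rt_ms")
    rt_diff = (rt_wide["unsorted"] - rt_wide["chosen"]).reindex(
        merged["participant_id"]).to_numpy(float)
    results.append(correlation(
        merged["cmi"], rt_diff, name="CMI x RT difference",
        n_boot=n_boot, seed=next(seed_counter)))

    table = results_table(results)
    # rename ANOVA duplicates (sensitivity vs RT run)
    first_block = table.index[table["name"].str.startswith(
        ("main effect", "interaction"))]
    half = len(first_block) // 2
    table.loc[first_block[:half], "name"] = \
        "sensitivity " + table.loc[first_block[:half], "name"]
    table.loc[first_block[half:], "name"] = \
        "median RT " + table.loc[first_block[half:], "name"]
    return table


def _group_maps(participants, sessions) -> pd.DataFrame:
    frames = []
    for group, sub in participants.groupby("age_group"):
        trials = pd.concat([sessions[p] for p in sub["participant_id"]],
                           ignore_index=True)
        for condition in ("aggregate", "lower_lower", "lower_higher",
                          "higher_lower", "higher_higher"):
            long = choice_probability_map(trials, condition).to_long()
            long["age_group"] = group
            frames.append(long)
    return pd.concat(frames, ignore_index=True)


def write_report(report: StudyReport, outdir) -> None:
    """Write the report bundle as delimited text plus a provenance block."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.participants.to_csv(outdir / "participants.csv", index=False)
    report.psychometric.to_csv(outdir / "psychometric_fits.csv", index=False)
    report.confidence.to_csv(outdir / "confidence_results.csv", index=False)
    report.rt_fits.to_csv(outdir / "rt_fits.csv", index=False)
    report.ef.to_csv(outdir / "ef_scores.csv", index=False)
    report.stats.to_csv(outdir / "group_statistics.csv", index=False)
    report.maps.to_csv(outdir / "confidence_maps.csv", index=False)
    report.exclusion_rates.rename_axis("participant_id").to_csv(
        outdir / "rt_exclusion_rates.csv")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, default=str)
    logger.info("report bundle written to %s", outdir)


def write_cohort(cohort, outdir) -> None:
    """Emit a simulated cohort in the session/participants file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_participants_table(cohort.participants,
                             outdir / "participants.csv")
    for pid, trials in cohort.sessions.items():
        write_session_table(trials, outdir / f"session_{pid}.csv")
    cohort.truth.to_csv(outdir / "generative_truth.csv", index=False)
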
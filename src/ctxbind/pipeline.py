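"""From trial-level records to the full context-binding test battery.

The pipeline mirrors the analysis of an auditory prime-probe study with
five context-variability groups:

1. validity filtering (RTs outside [100, 3000] ms are invalid),
2. participant exclusion (probe error rate > 0.50 in any within-subject
   Trial Type x Context Relation cell),
3. tabulation of probe-response frequencies into the four MPT trees of a
   group's joint model ({IR, C} x {repeated, changed}),
4. a three-stage battery of likelihood-ratio tests:
   stage 1 - distractor-response binding: prr_IR = prr_C per
   (context relation x group), 10 tests;
   stage 2 - binary context binding: prr_C,repeated = prr_C,changed per
   group, 5 tests;
   stage 3 - configural context binding: reparameterized interaction test
   equating (prr_IR - prr_C) across context relations per group, 5 tests;
   with Holm correction applied within each stage's family,
5. per-group classification of the binding pattern from the adjusted
   significance flags, plus descriptive negative-priming condition means.

Counts are pooled over participants within a group before fitting
(aggregate-data MPT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import GROUPS, RESPONSE_KEYS
from .mpt_core import (
    CATEGORIES,
    ConditionKey,
    FitResult,
    FrequencyTable,
    Restriction,
    fit_joint_saturated,
    fit_restricted,
    holm_correction,
    interaction_test,
)

RT_VALID_MIN_MS = 100.0
RT_VALID_MAX_MS = 3000.0
EXCLUSION_ERROR_RATE = 0.50
ALPHA = 0.05

#: Tree keys of one group's joint model, in canonical order.
TREE_KEYS = (
    ("IR", "repeated"),
    ("C", "repeated"),
    ("IR", "changed"),
    ("C", "changed"),
)


def _response_error(records: pd.DataFrame) -> np.ndarray:
    """True where the probe response key misses the probe target's key."""
    target_key = records["probe_target"].map(RESPONSE_KEYS).to_numpy()
    return records["probe_response_key"].to_numpy() != target_key


def filter_valid_responses(
    records: pd.DataFrame,
    rt_min_ms: float = RT_VALID_MIN_MS,
    rt_max_ms: float = RT_VALID_MAX_MS,
) -> tuple[pd.DataFrame, dict]:
    """Drop trials whose prime or probe RT falls outside the validity window.

    Boundaries are inclusive: an RT of exactly 100 or 3000 ms is kept.
    Returns the kept records and a rejection log with counts per reason
    (a trial failing both checks is counted under both reasons but removed
    once).
    """
    prime_bad = ~records["prime_rt_ms"].between(rt_min_ms, rt_max_ms)
    probe_bad = ~records["probe_rt_ms"].between(rt_min_ms, rt_max_ms)
    bad = prime_bad | probe_bad
    log = {
        "n_input": int(len(records)),
        "prime_rt_invalid": int(prime_bad.sum()),
        "probe_rt_invalid": int(probe_bad.sum()),
        "n_removed": int(bad.sum()),
        "n_kept": int((~bad).sum()),
        "rt_min_ms": rt_min_ms,
        "rt_max_ms": rt_max_ms,
    }
    return records.loc[~bad].reset_index(drop=True), log


def exclude_participants(
    records: pd.DataFrame, threshold: float = EXCLUSION_ERROR_RATE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude participants with excessive probe error rates.

    A participant is excluded when the probe error rate exceeds
    ``threshold`` (strict inequality) in at least one Trial Type x Context
    Relation cell.  Returns the kept records and a per-cell report listing
    every participant's cell error rates, an ``excluded`` flag, and an
    ``empty_cell`` flag for participants with unobserved cells (flagged,
    never silently dropped).
    """
    df = records.copy()
    df["_error"] = _response_error(df)
    cells = (
        df.groupby(["participant_id", "trial_type", "context_relation"], sort=True)
        .agg(n=("_error", "size"), error_rate=("_error", "mean"))
        .reset_index()
    )
    n_cells_expected = df["trial_type"].nunique() * df["context_relation"].nunique()
    per_participant = cells.groupby("participant_id").agg(
        max_error_rate=("error_rate", "max"), n_cells=("n", "size")
    )
    excluded_ids = set(
        per_participant.index[per_participant["max_error_rate"] > threshold]
    )
    empty_ids = set(
        per_participant.index[per_participant["n_cells"] < n_cells_expected]
    )
    cells["excluded"] = cells["participant_id"].isin(excluded_ids)
    cells["empty_cell"] = cells["participant_id"].isin(empty_ids)
    kept = records.loc[~records["participant_id"].isin(excluded_ids)].reset_index(
        drop=True
    )
    return kept, cells


def tabulate_frequencies(
    records: pd.DataFrame,
    group: str,
    drop_prime_errors: bool = True,
) -> dict[tuple[str, str], FrequencyTable]:
    """Pool one group's probe responses into the joint model's four trees.

    Only ignored-repetition and control trials enter.  The response
    category is assigned from the trial's stimulus configuration: the
    probe target's key is correct, the probe distractor's key a distractor
    confusion, the prime target's key a prime-response intrusion, and the
    remaining key the fourth option.  Trials with an incorrect prime
    response are dropped by default (configurable).
    """
    df = records.loc[
        (records["group"] == group)
        & records["trial_type"].isin(["ignored_repetition", "control"])
    ]
    if drop_prime_errors:
        df = df.loc[df["prime_correct"].astype(bool)]

    key = df["probe_response_key"].to_numpy()
    valid_keys = set(RESPONSE_KEYS.values())
    unknown = set(np.unique(key)) - valid_keys
    if unknown:
        raise ValueError(f"unknown response keys in records: {sorted(unknown)}")

    target_key = df["probe_target"].map(RESPONSE_KEYS).to_numpy()
    distractor_key = df["probe_distractor"].map(RESPONSE_KEYS).to_numpy()
    prime_key = df["prime_target"].map(RESPONSE_KEYS).to_numpy()
    cat_idx = np.select(
        [key == target_key, key == distractor_key, key == prime_key],
        [0, 1, 2],
        default=3,
    )
    code_idx = np.where(df["trial_type"].to_numpy() == "ignored_repetition", 0, 1)
    rel_idx = np.where(df["context_relation"].to_numpy() == "repeated", 0, 1)
    tree_idx = code_idx * 2 + rel_idx  # 0=IR/rep 1=IR/chg 2=C/rep 3=C/chg
    counts = np.bincount(tree_idx * 4 + cat_idx, minlength=16).reshape(4, 4)

    order = [("IR", "repeated"), ("IR", "changed"), ("C", "repeated"), ("C", "changed")]
    out = {}
    for (tt, rel), row in zip(order, counts):
        out[(tt, rel)] = FrequencyTable(
            ConditionKey(tt, rel, group), int(row[0]), int(row[1]), int(row[2]), int(row[3])
        )
    return out


@dataclass
class TestBatteryResult:
    """All three test families, Holm-adjusted p-values and classifications."""

    distractor_prr_tests: dict
    binary_binding_tests: dict
    interaction_tests: dict
    holm_adjusted: dict
    classification: dict
    prr_estimates: pd.DataFrame
    alpha: float
    failures: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def fits(d: Mapping) -> dict:
            return {str(k): v.to_dict() for k, v in sorted(d.items(), key=lambda kv: str(kv[0]))}

        return {
            "alpha": self.alpha,
            "distractor_prr_tests": fits(self.distractor_prr_tests),
            "binary_binding_tests": fits(self.binary_binding_tests),
            "interaction_tests": fits(self.interaction_tests),
            "holm_adjusted": {
                k: {"raw": v[0], "adjusted": v[1]}
                for k, v in sorted(self.holm_adjusted.items())
            },
            "classification": dict(sorted(self.classification.items())),
            "prr_estimates": self.prr_estimates.to_dict(orient="records"),
            "failures": {str(k): str(v) for k, v in sorted(self.failures.items())},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _stage1_id(group: str, relation: str) -> str:
    return f"prr_ir_vs_c|{group}|{relation}"


def _stage2_id(group: str) -> str:
    return f"binary|{group}"


def _stage3_id(group: str) -> str:
    return f"configural|{group}"


def run_test_battery(
    tables_by_group: Mapping[str, Mapping[tuple[str, str], FrequencyTable]],
    alpha: float = ALPHA,
) -> TestBatteryResult:
    """Run the three-stage battery on pooled per-group frequency tables.

    With the full five-group design this is 10 + 5 + 5 tests; Holm
    correction is applied within each stage's family.  Classification per
    group: ``binary`` if the stage-2 test is significant, ``configural``
    if the stage-3 test is significant and stage 2 is not, ``both`` if
    both are, ``none`` otherwise.  A group with missing trees yields a
    failure entry and the battery continues.
    """
    stage1: dict = {}
    stage2: dict = {}
    stage3: dict = {}
    failures: dict = {}
    est_rows = []

    groups = list(tables_by_group)
    for group in groups:
        tables = tables_by_group[group]
        missing = [k for k in TREE_KEYS if k not in tables]
        if missing:
            failures[group] = f"missing trees: {missing}"
            continue
        try:
            for rel in ("repeated", "changed"):
                ir, c = tables[("IR", rel)], tables[("C", rel)]
                stage1[(group, rel)] = fit_restricted(
                    [ir, c],
                    Restriction("equate_params", "prr", trees=(ir.tree_id, c.tree_id)),
                )
            joint = [tables[k] for k in TREE_KEYS]
            c_rep, c_chg = tables[("C", "repeated")], tables[("C", "changed")]
            stage2[group] = fit_restricted(
                joint,
                Restriction(
                    "equate_params", "prr", trees=(c_rep.tree_id, c_chg.tree_id)
                ),
            )
            stage3[group] = interaction_test(
                tables[("IR", "repeated")],
                tables[("C", "repeated")],
                tables[("IR", "changed")],
                tables[("C", "changed")],
            )
            sat = fit_joint_saturated(joint)
            for key in TREE_KEYS:
                t = tables[key]
                p = sat.estimates[t.tree_id]
                est_rows.append(
                    {
                        "group": group,
                        "trial_type": key[0],
                        "context_relation": key[1],
                        "ci": p.ci,
                        "psc": p.psc,
                        "prr": p.prr,
                        "n": t.n_total,
                    }
                )
        except ValueError as exc:
            failures[group] = str(exc)
            stage1 = {k: v for k, v in stage1.items() if k[0] != group}
            stage2.pop(group, None)
            stage3.pop(group, None)

    holm_adjusted: dict = {}
    families = [
        {_stage1_id(g, rel): fit for (g, rel), fit in stage1.items()},
        {_stage2_id(g): fit for g, fit in stage2.items()},
        {_stage3_id(g): fit for g, fit in stage3.items()},
    ]
    for family in families:
        if not family:
            continue
        ids = sorted(family)
        raw = [family[i].p_value for i in ids]
        adj = holm_correction(raw)
        for i, r, a in zip(ids, raw, adj):
            holm_adjusted[i] = (float(r), float(a))

    classification: dict = {}
    for group in groups:
        if group in failures:
            classification[group] = "error"
            continue
        binary_sig = holm_adjusted[_stage2_id(group)][1] < alpha
        configural_sig = holm_adjusted[_stage3_id(group)][1] < alpha
        if binary_sig and configural_sig:
            classification[group] = "both"
        elif binary_sig:
            classification[group] = "binary"
        elif configural_sig:
            classification[group] = "configural"
        else:
            classification[group] = "none"

    prr_estimates = pd.DataFrame(
        est_rows,
        columns=["group", "trial_type", "context_relation", "ci", "psc", "prr", "n"],
    )
    return TestBatteryResult(
        distractor_prr_tests=stage1,
        binary_binding_tests=stage2,
        interaction_tests=stage3,
        holm_adjusted=holm_adjusted,
        classification=classification,
        prr_estimates=prr_estimates,
        alpha=alpha,
        failures=failures,
    )


def descriptive_np_effect(records: pd.DataFrame) -> dict:
    """Descriptive negative-priming condition means (no inferential tests).

    Mean probe RT (correct probe responses only) and probe error rate per
    Trial Type x Context Relation x Group, plus ignored-repetition minus
    control differences per (group, relation).  Conditions without data
    appear in ``missing_cells`` rather than as zeros.
    """
    df = records.copy()
    df["_error"] = _response_error(df)
    grp = ["group", "trial_type", "context_relation"]
    err = df.groupby(grp)["_error"].agg(["mean", "size"]).reset_index()
    err = err.rename(columns={"mean": "error_rate", "size": "n"})
    rt = (
        df.loc[~df["_error"]]
        .groupby(grp)["probe_rt_ms"]
        .mean()
        .reset_index()
        .rename(columns={"probe_rt_ms": "mean_rt_correct_ms"})
    )
    means = err.merge(rt, on=grp, how="left")

    wide_rt = means.pivot_table(
        index=["group", "context_relation"],
        columns="trial_type",
        values="mean_rt_correct_ms",
        aggfunc="first",
    )
    wide_err = means.pivot_table(
        index=["group", "context_relation"],
        columns="trial_type",
        values="error_rate",
        aggfunc="first",
    )
    effects = pd.DataFrame(index=wide_rt.index)
    if {"ignored_repetition", "control"} <= set(wide_rt.columns):
        effects["np_rt_ms"] = (
            wide_rt["ignored_repetition"] - wide_rt["control"]
        )
        effects["np_error_rate"] = (
            wide_err["ignored_repetition"] - wide_err["control"]
        )
    effects = effects.reset_index()

    groups = df["group"].unique()
    types = df["trial_type"].unique()
    rels = df["context_relation"].unique()
    observed = set(map(tuple, means[grp].itertuples(index=False)))
    missing = [
        {"group": g, "trial_type": t, "context_relation": r}
        for g in groups
        for t in types
        for r in rels
        if (g, t, r) not in observed
    ]
    return {"condition_means": means, "np_effects": effects, "missing_cells": missing}


@dataclass
class PipelineResult:
    """End-to-end result of filtering, exclusion, tabulation and testing."""

    filter_log: dict
    exclusion_report: pd.DataFrame
    tables_by_group: dict
    battery: TestBatteryResult
    descriptives: dict
    config: dict

    def to_dict(self) -> dict:
        from .mpt_core import tables_to_frame

        return {
            "config": self.config,
            "filter_log": self.filter_log,
            "n_excluded_participants": int(
                self.exclusion_report.loc[
                    self.exclusion_report["excluded"], "participant_id"
                ].nunique()
            ),
            "frequency_tables": {
                g: tables_to_frame(tabs.values()).to_dict(orient="records")
                for g, tabs in sorted(self.tables_by_group.items())
            },
            "battery": self.battery.to_dict(),
            "descriptives": {
                "condition_means": self.descriptives["condition_means"].to_dict(
                    orient="records"
                ),
                "np_effects": self.descriptives["np_effects"].to_dict(
                    orient="records"
                ),
                "missing_cells": self.descriptives["missing_cells"],
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def run_pipeline(
    records: pd.DataFrame,
    alpha: float = ALPHA,
    drop_prime_errors: bool = True,
    exclusion_threshold: float = EXCLUSION_ERROR_RATE,
    rt_min_ms: float = RT_VALID_MIN_MS,
    rt_max_ms: float = RT_VALID_MAX_MS,
) -> PipelineResult:
    """Filter, exclude, tabulate per group and run the full test battery."""
    kept, filter_log = filter_valid_responses(records, rt_min_ms, rt_max_ms)
    kept, exclusion_report = exclude_participants(kept, exclusion_threshold)
    groups = [g for g in GROUPS if g in set(kept["group"])]
    groups += sorted(set(kept["group"]) - set(GROUPS))
    tables_by_group = {
        g: tabulate_frequencies(kept, g, drop_prime_errors) for g in groups
    }
    battery = run_test_battery(tables_by_group, alpha=alpha)
    descriptives = descriptive_np_effect(kept)
    config = {
        "alpha": alpha,
        "drop_prime_errors": drop_prime_errors,
        "exclusion_threshold": exclusion_threshold,
        "rt_min_ms": rt_min_ms,
        "rt_max_ms": rt_max_ms,
    }
    return PipelineResult(
        filter_log=filter_log,
        exclusion_report=exclusion_report,
        tables_by_group=tables_by_group,
        battery=battery,
        descriptives=descriptives,
        config=config,
    )
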
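"""Parameter-recovery and type-I-error calibration experiments.

These experiments exercise the whole stack: schedules are generated per
participant, probe responses are drawn from a known scenario, and the
pipeline re-estimates the generating prr parameters and classifies the
binding pattern.  Calibration experiments simulate under the null of each
likelihood-ratio test and measure the empirical rejection rate.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .design import build_basic_trial_set, build_context_pairs, build_group_schedule
from .mpt_core import (
    ConditionKey,
    FrequencyTable,
    MptParams,
    Restriction,
    category_probabilities,
    fit_restricted,
    interaction_test,
)
from .pipeline import run_pipeline
from .synthetic_data import SCENARIO_KEYS, Scenario, scenario_preset, simulate_study

#: Generating pattern implied by each scenario preset.
EXPECTED_LABEL = {
    "no_integration": "none",
    "configural": "configural",
    "binary": "binary",
}


def make_group_schedules(
    group: str, n_participants: int, seed: int, set_policy: str = "alternate"
) -> list:
    """Participant schedules for one group with seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    pairs = build_context_pairs()
    basic = {sid: build_basic_trial_set(set_id=sid) for sid in ("set1", "set2")}
    out = []
    for i in range(n_participants):
        if set_policy == "alternate":
            sid = "set1" if i % 2 == 0 else "set2"
        else:
            sid = set_policy
        out.append(
            build_group_schedule(group, basic[sid], pairs, int(rng.integers(2**31 - 1)))
        )
    return out


def recovery_experiment(
    preset: str = "configural",
    group: str = "disordered",
    n_participants: int = 48,
    replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    scenario: Optional[Scenario] = None,
) -> dict:
    """Simulate-and-refit replicates of one group under one preset.

    The trial schedules are generated once and held fixed across
    replicates (the design is a constant of the experiment); probe
    responses are redrawn each replicate.  Every replicate runs the full
    pipeline (validity filter, exclusion, tabulation, test battery).

    Returns recovery errors of the four generating prr values and the
    fraction of replicates whose battery classification matches the
    preset's generating pattern.
    """
    if scenario is None:
        scenario = scenario_preset(preset)
    expected = EXPECTED_LABEL[preset]
    rng = np.random.default_rng(seed)
    schedules = make_group_schedules(group, n_participants, int(rng.integers(2**31 - 1)))
    truth = np.array([scenario.params[k].prr for k in SCENARIO_KEYS])

    max_abs_err = np.empty(replicates)
    errors = np.empty((replicates, len(SCENARIO_KEYS)))
    labels = []
    for r in range(replicates):
        records, _ = simulate_study(
            [group],
            n_participants,
            {group: scenario},
            master_seed=int(rng.integers(2**31 - 1)),
            schedules_by_group={group: schedules},
        )
        result = run_pipeline(records, alpha=alpha)
        est = result.battery.prr_estimates.set_index(
            ["trial_type", "context_relation"]
        )["prr"]
        prr_hat = np.array([est.loc[k] for k in SCENARIO_KEYS])
        errors[r] = prr_hat - truth
        max_abs_err[r] = np.max(np.abs(errors[r]))
        labels.append(result.battery.classification[group])

    labels_arr = np.array(labels)
    return {
        "preset": preset,
        "group": group,
        "n_participants": n_participants,
        "replicates": replicates,
        "true_prr": {f"{tt}:{rel}": float(t) for (tt, rel), t in zip(SCENARIO_KEYS, truth)},
        "mean_prr_error": {
            f"{tt}:{rel}": float(e)
            for (tt, rel), e in zip(SCENARIO_KEYS, errors.mean(axis=0))
        },
        "median_max_abs_error": float(np.median(max_abs_err)),
        "frac_within_003": float(np.mean(max_abs_err <= 0.03)),
        "max_abs_errors": max_abs_err.tolist(),
        "expected_label": expected,
        "labels": labels,
        "classification_accuracy": float(np.mean(labels_arr == expected)),
    }


def lr_calibration(
    replicates: int = 10000,
    n_per_tree: int = 200,
    params: MptParams = MptParams(0.80, 0.25, 0.30),
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the df=1 prr-equality test under its null.

    Two trees are drawn from identical category probabilities (so
    prr_IR = prr_C holds) and refit with the equality restriction.
    """
    rng = np.random.default_rng(seed)
    probs = category_probabilities(params)
    ir_id = ConditionKey("IR", "repeated")
    c_id = ConditionKey("C", "repeated")
    restriction = Restriction("equate_params", "prr", trees=(ir_id, c_id))
    draws = rng.multinomial(n_per_tree, probs, size=(replicates, 2))
    rejections = 0
    for i in range(replicates):
        ir = FrequencyTable(ir_id, *(int(v) for v in draws[i, 0]))
        c = FrequencyTable(c_id, *(int(v) for v in draws[i, 1]))
        fit = fit_restricted([ir, c], restriction)
        rejections += fit.p_value < alpha
    return {
        "replicates": replicates,
        "n_per_tree": n_per_tree,
        "alpha": alpha,
        "rejection_rate": rejections / replicates,
    }


def interaction_calibration(
    replicates: int = 5000,
    n_per_tree: int = 200,
    ci: float = 0.80,
    psc: float = 0.25,
    prr_c: float = 0.30,
    shared_gap: float = 0.15,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the df=1 interaction test under equal prr gaps.

    All four trees are drawn with prr_IR - prr_C equal across context
    relations (the interaction null), then refit with the
    equal-difference restriction.
    """
    rng = np.random.default_rng(seed)
    tree_params = {
        ("IR", "repeated"): MptParams(ci, psc, prr_c + shared_gap),
        ("C", "repeated"): MptParams(ci, psc, prr_c),
        ("IR", "changed"): MptParams(ci, psc, prr_c + shared_gap),
        ("C", "changed"): MptParams(ci, psc, prr_c),
    }
    ids = {k: ConditionKey(k[0], k[1]) for k in tree_params}
    probs = {k: category_probabilities(p) for k, p in tree_params.items()}
    rejections = 0
    for _ in range(replicates):
        tabs = {
            k: FrequencyTable(ids[k], *(int(v) for v in rng.multinomial(n_per_tree, probs[k])))
            for k in tree_params
        }
        fit = interaction_test(
            tabs[("IR", "repeated")],
            tabs[("C", "repeated")],
            tabs[("IR", "changed")],
            tabs[("C", "changed")],
        )
        rejections += fit.p_value < alpha
    return {
        "replicates": replicates,
        "n_per_tree": n_per_tree,
        "alpha": alpha,
        "rejection_rate": rejections / replicates,
    }
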
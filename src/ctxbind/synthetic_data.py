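"""Trial-level data simulator.

Generates datasets with the statistical structure the analysis pipeline
assumes: probe responses drawn from condition-specific MPT category
probabilities on top of the five-group trial schedules, plus lognormal
response times with a configurable negative-priming slowdown on
ignored-repetition trials.

Three scenario presets encode the prototypical context-integration
patterns:

``no_integration``
    the distractor-response binding effect (prr_IR > prr_C) is present and
    independent of the context relation; the context is inert.
``configural``
    the prr_IR - prr_C gap is larger when the context repeats than when it
    changes, while prr_C itself does not depend on the context relation.
``binary``
    repeating the context alone retrieves the prime response: prr_C is
    larger under context repetition than under context change.

The preset magnitudes are synthetic choices (no empirical values are
asserted): ci = 0.80 and psc = 0.25 everywhere, a baseline distractor
binding gap of 0.15, a configural boost of +0.15 to the gap under context
repetition, and a binary boost of +0.12 to prr_C under repetition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    GROUPS,
    RESPONSE_KEYS,
    SOUNDS,
    GroupSchedule,
    build_basic_trial_set,
    build_context_pairs,
    build_group_schedule,
)
from .mpt_core import CATEGORIES, MptParams, category_probabilities

#: Condition keys a scenario must cover: analysis trial code x relation.
SCENARIO_KEYS = (
    ("IR", "repeated"),
    ("IR", "changed"),
    ("C", "repeated"),
    ("C", "changed"),
)

_SOUND_INDEX = {s: i for i, s in enumerate(SOUNDS)}
_KEY_BY_INDEX = np.array([RESPONSE_KEYS[s] for s in SOUNDS])
_POPCOUNT = np.array([bin(i).count("1") for i in range(16)])
_LOWBIT_LOG2 = np.full(16, -1)
for _i in range(4):
    _LOWBIT_LOG2[1 << _i] = _i


@dataclass(frozen=True)
class RtModel:
    """Lognormal RT model: mean base_ms, +np_shift_ms on IR probe trials."""

    base_ms: float = 900.0
    np_shift_ms: float = 50.0
    sigma_log: float = 0.3


@dataclass(frozen=True)
class Scenario:
    """True data-generating parameters per (trial code, context relation)."""

    name: str
    params: Mapping[tuple[str, str], MptParams]
    rt_model: RtModel = RtModel()
    prime_accuracy: float = 0.90

    def __post_init__(self) -> None:
        missing = [k for k in SCENARIO_KEYS if k not in self.params]
        if missing:
            raise ValueError(f"scenario {self.name!r} misses conditions {missing}")
        if not 0.0 <= self.prime_accuracy <= 1.0:
            raise ValueError("prime_accuracy must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": {
                f"{tt}:{rel}": p.as_dict() for (tt, rel), p in sorted(self.params.items())
            },
            "rt_model": {
                "base_ms": self.rt_model.base_ms,
                "np_shift_ms": self.rt_model.np_shift_ms,
                "sigma_log": self.rt_model.sigma_log,
            },
            "prime_accuracy": self.prime_accuracy,
        }


def scenario_preset(
    name: str,
    ci: float = 0.80,
    psc: float = 0.25,
    prr_c: float = 0.30,
    binding_gap: float = 0.15,
    configural_boost: float = 0.15,
    binary_boost: float = 0.12,
    rt_model: RtModel = RtModel(),
    prime_accuracy: float = 0.90,
) -> Scenario:
    """Build one of the three prototypical-pattern presets by name."""
    if name == "no_integration":
        prr = {
            ("C", "repeated"): prr_c,
            ("C", "changed"): prr_c,
            ("IR", "repeated"): prr_c + binding_gap,
            ("IR", "changed"): prr_c + binding_gap,
        }
    elif name == "configural":
        prr = {
            ("C", "repeated"): prr_c,
            ("C", "changed"): prr_c,
            ("IR", "repeated"): prr_c + binding_gap + configural_boost,
            ("IR", "changed"): prr_c + binding_gap,
        }
    elif name == "binary":
        prr = {
            ("C", "repeated"): prr_c + binary_boost,
            ("C", "changed"): prr_c,
            ("IR", "repeated"): prr_c + binary_boost + binding_gap,
            ("IR", "changed"): prr_c + binding_gap,
        }
    else:
        raise ValueError(f"unknown preset {name!r}")
    params = {k: MptParams(ci, psc, v) for k, v in prr.items()}
    return Scenario(name, params, rt_model, prime_accuracy)


RECORD_COLUMNS = [
    "participant_id",
    "group",
    "block",
    "index_in_block",
    "trial_type",
    "context_relation",
    "prime_target",
    "prime_distractor",
    "probe_target",
    "probe_distractor",
    "prime_context_label",
    "probe_context_label",
    "set_id",
    "prime_target_side",
    "prime_correct",
    "probe_category",
    "probe_response_key",
    "prime_rt_ms",
    "probe_rt_ms",
]


def _condition_index(trial_type: np.ndarray, relation: np.ndarray) -> np.ndarray:
    """Map each trial onto a SCENARIO_KEYS index.

    Attended-repetition trials and their controls are simulated from the
    control-condition parameters of the matching relation (no hypotheses
    are modeled for them).
    """
    is_ir = trial_type == "ignored_repetition"
    is_rep = relation == "repeated"
    # order matches SCENARIO_KEYS
    return np.where(is_ir, np.where(is_rep, 0, 1), np.where(is_rep, 2, 3))


def _other_response_index(
    probe_t: np.ndarray, probe_d: np.ndarray, prime_t: np.ndarray, prime_d: np.ndarray
) -> np.ndarray:
    """Index of the 'remaining fourth response option' per trial."""
    mask = 15 & ~((1 << probe_t) | (1 << probe_d) | (1 << prime_t))
    two = _POPCOUNT[mask] == 2
    mask = np.where(two, mask & ~(1 << prime_d), mask)
    return _LOWBIT_LOG2[mask]


def _lognormal_mean_mu(mean: np.ndarray, sigma: float) -> np.ndarray:
    return np.log(mean) - sigma**2 / 2.0


def simulate_participant(
    schedule: GroupSchedule,
    scenario: Scenario,
    seed: int,
    participant_id: int = 0,
) -> pd.DataFrame:
    """Simulate one participant's 384 trials (one row per trial).

    Per trial: prime accuracy is Bernoulli(prime_accuracy); the probe
    response category is drawn from the condition's MPT category
    probabilities and then mapped onto a concrete response key given the
    trial's stimulus configuration; RTs are lognormal with the scenario's
    mean (IR probes shifted by np_shift_ms), floored at 1 ms.
    """
    rng = np.random.default_rng(seed)
    f = schedule.to_frame()
    n = len(f)

    trial_type = f["trial_type"].to_numpy()
    relation = f["context_relation"].to_numpy()
    cond = _condition_index(trial_type, relation)

    cum = np.vstack(
        [
            np.cumsum(category_probabilities(scenario.params[k]))
            for k in SCENARIO_KEYS
        ]
    )
    prime_correct = rng.random(n) < scenario.prime_accuracy
    u = rng.random(n)
    cat_idx = (u[:, None] >= cum[cond][:, :3]).sum(axis=1)

    rt = scenario.rt_model
    probe_mean = np.where(
        trial_type == "ignored_repetition",
        rt.base_ms + rt.np_shift_ms,
        rt.base_ms,
    ).astype(float)
    prime_rt = rng.lognormal(
        _lognormal_mean_mu(np.full(n, rt.base_ms), rt.sigma_log), rt.sigma_log
    )
    probe_rt = rng.lognormal(_lognormal_mean_mu(probe_mean, rt.sigma_log), rt.sigma_log)
    prime_rt = np.maximum(prime_rt, 1.0)
    probe_rt = np.maximum(probe_rt, 1.0)

    pt = f["prime_target"].map(_SOUND_INDEX).to_numpy()
    pd_ = f["prime_distractor"].map(_SOUND_INDEX).to_numpy()
    bt = f["probe_target"].map(_SOUND_INDEX).to_numpy()
    bd = f["probe_distractor"].map(_SOUND_INDEX).to_numpy()
    other = _other_response_index(bt, bd, pt, pd_)
    chosen = np.choose(cat_idx, [bt, bd, pt, other])

    out = pd.DataFrame(
        {
            "participant_id": participant_id,
            "group": schedule.group,
            "block": f["block"].to_numpy(),
            "index_in_block": f["index_in_block"].to_numpy(),
            "trial_type": trial_type,
            "context_relation": relation,
            "prime_target": f["prime_target"].to_numpy(),
            "prime_distractor": f["prime_distractor"].to_numpy(),
            "probe_target": f["probe_target"].to_numpy(),
            "probe_distractor": f["probe_distractor"].to_numpy(),
            "prime_context_label": f["prime_context_label"].to_numpy(),
            "probe_context_label": f["probe_context_label"].to_numpy(),
            "set_id": f["set_id"].to_numpy(),
            "prime_target_side": f["prime_target_side"].to_numpy(),
            "prime_correct": prime_correct,
            "probe_category": np.array(CATEGORIES)[cat_idx],
            "probe_response_key": _KEY_BY_INDEX[chosen],
            "prime_rt_ms": prime_rt,
            "probe_rt_ms": probe_rt,
        },
        columns=RECORD_COLUMNS,
    )
    return out


def simulate_study(
    groups: Sequence[str] = GROUPS,
    n_per_group: int = 48,
    scenario_by_group: Optional[Mapping[str, Scenario]] = None,
    master_seed: int = 0,
    set_policy: str = "alternate",
    schedules_by_group: Optional[Mapping[str, Sequence[GroupSchedule]]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a multi-group study; returns (records, seed manifest).

    Participant schedule and response seeds are derived from
    ``master_seed`` and recorded in the manifest for exact reproduction.
    Participants alternate between basic-trial sets by index parity when
    ``set_policy`` is ``"alternate"`` (the default), or all use set 1 with
    ``"set1"`` / set 2 with ``"set2"``.

    Pre-built schedules can be supplied per group (``schedules_by_group``)
    to hold the design fixed across simulation replicates.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    if scenario_by_group is None:
        scenario_by_group = {g: scenario_preset("no_integration") for g in groups}
    missing = [g for g in groups if g not in scenario_by_group]
    if missing:
        raise ValueError(f"no scenario for groups {missing}")
    if set_policy not in ("alternate", "set1", "set2"):
        raise ValueError(f"unknown set policy {set_policy!r}")

    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=(len(groups), n_per_group, 2))
    pairs = build_context_pairs()
    basic_sets = {
        sid: build_basic_trial_set(set_id=sid) for sid in ("set1", "set2")
    }

    frames = []
    manifest: dict = {
        "master_seed": int(master_seed),
        "set_policy": set_policy,
        "scenarios": {g: scenario_by_group[g].to_dict() for g in groups},
        "participants": [],
    }
    pid = 0
    for gi, group in enumerate(groups):
        scenario = scenario_by_group[group]
        for j in range(n_per_group):
            if set_policy == "alternate":
                set_id = "set1" if pid % 2 == 0 else "set2"
            else:
                set_id = set_policy
            sched_seed, resp_seed = int(seeds[gi, j, 0]), int(seeds[gi, j, 1])
            if schedules_by_group is not None:
                schedule = schedules_by_group[group][j]
            else:
                schedule = build_group_schedule(
                    group, basic_sets[set_id], pairs, seed=sched_seed
                )
            frames.append(
                simulate_participant(schedule, scenario, resp_seed, participant_id=pid)
            )
            manifest["participants"].append(
                {
                    "participant_id": pid,
                    "group": group,
                    "set_id": set_id,
                    "schedule_seed": sched_seed,
                    "response_seed": resp_seed,
                }
            )
            pid += 1
    records = pd.concat(frames, ignore_index=True)
    return records, manifest


def write_dataset(records: pd.DataFrame, manifest: dict, csv_path, manifest_path) -> None:
    """Long-format CSV plus a JSON seed manifest."""
    records.to_csv(csv_path, index=False)
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
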
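"""Stimulus inventory and trial-schedule construction.

This module builds the factorial design of an auditory four-alternative
prime-probe (negative priming) task in which every presentation pairs a
target sound with a to-be-ignored distractor sound, and a task-irrelevant
sine tone ("context") accompanies both presentations of a trial.  Five
between-participant regimes vary how much the context tone changes from
trial to trial, from a fully blocked presentation (one prime-probe tone
combination per block) up to a uniformly random draw over all tone pairs.

Sounds are modeled as labels; no audio is rendered.  Presentation-timing
constants are kept as metadata only (see :data:`TIMING_METADATA_MS`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Printed context-tone inventory: label -> frequency in Hz.
TONE_FREQUENCIES_HZ = {1: 150, 2: 300, 3: 400, 4: 500, 5: 600, 6: 700, 7: 800, 8: 900}

#: The four environmental sounds used as targets/distractors.
SOUNDS = ("frog", "piano", "drum", "bell")

#: Response-key assignment (index/middle fingers of both hands).
RESPONSE_KEYS = {"frog": "F", "piano": "V", "drum": "J", "bell": "N"}

TRIAL_TYPES = (
    "ignored_repetition",
    "control",
    "attended_repetition",
    "attended_repetition_control",
)

GROUPS = ("blocked", "ordered", "disordered", "mixed", "random")

MIN_PAIR_SEPARATION_HZ = 200
N_BLOCKS = 8
TRIALS_PER_BLOCK = 48
N_TRIALS = N_BLOCKS * TRIALS_PER_BLOCK  # 384

#: Presentation timing, recorded for documentation only (not simulated).
TIMING_METADATA_MS = {
    "cue": 20,
    "cue_stimulus_interval": 500,
    "prime_probe_interval": 500,
    "inter_trial_interval": 1200,
}


@dataclass(frozen=True, order=True)
class ContextTone:
    """One sine tone of the printed inventory (label 1-8)."""

    label: int
    frequency_hz: int

    def __post_init__(self) -> None:
        if self.label not in TONE_FREQUENCIES_HZ:
            raise ValueError(f"unknown context-tone label {self.label!r}")
        if self.frequency_hz != TONE_FREQUENCIES_HZ[self.label]:
            raise ValueError(
                f"tone {self.label} must have frequency "
                f"{TONE_FREQUENCIES_HZ[self.label]} Hz, got {self.frequency_hz}"
            )


def tone(label: int) -> ContextTone:
    """Return the inventory tone with the given label."""
    return ContextTone(label, TONE_FREQUENCIES_HZ[label])


def default_tones() -> list[ContextTone]:
    """The full eight-tone inventory in ascending label order."""
    return [tone(lab) for lab in sorted(TONE_FREQUENCIES_HZ)]


@dataclass(frozen=True)
class ContextPair:
    """An unordered pair of same-parity tones at least 200 Hz apart.

    The pair is stored in canonical order (ascending label), so
    ``ContextPair(a, b) == ContextPair(b, a)``.
    """

    tone_a: ContextTone
    tone_b: ContextTone

    def __post_init__(self) -> None:
        a, b = self.tone_a, self.tone_b
        if a.label == b.label:
            raise ValueError("a context pair needs two distinct tones")
        if a.label > b.label:  # canonicalize
            object.__setattr__(self, "tone_a", b)
            object.__setattr__(self, "tone_b", a)
            a, b = self.tone_a, self.tone_b
        if a.label % 2 != b.label % 2:
            raise ValueError(
                f"tones {a.label} and {b.label} differ in label parity"
            )
        if abs(a.frequency_hz - b.frequency_hz) < MIN_PAIR_SEPARATION_HZ:
            raise ValueError(
                f"tones {a.label} and {b.label} are less than "
                f"{MIN_PAIR_SEPARATION_HZ} Hz apart: inventory mismatch"
            )

    @property
    def tones(self) -> tuple[ContextTone, ContextTone]:
        return (self.tone_a, self.tone_b)

    def combinations(self) -> list["ContextCombination"]:
        """The four prime/probe tone combinations, in canonical order.

        Order: (a,a), (a,b), (b,a), (b,b) with a the lower-label tone —
        two context repetitions and two context changes.
        """
        a, b = self.tone_a, self.tone_b
        return [
            ContextCombination(a, a),
            ContextCombination(a, b),
            ContextCombination(b, a),
            ContextCombination(b, b),
        ]


@dataclass(frozen=True)
class ContextCombination:
    """The tone heard at prime and at probe within one trial."""

    prime_tone: ContextTone
    probe_tone: ContextTone

    @property
    def relation(self) -> str:
        """``repeated`` iff the same tone plays at prime and probe."""
        return "repeated" if self.prime_tone == self.probe_tone else "changed"


@dataclass(frozen=True)
class TrialSpec:
    """One prime-probe trial (stimulus roles plus schedule position)."""

    trial_type: str
    prime_target: str
    prime_distractor: str
    probe_target: str
    probe_distractor: str
    set_id: str
    context: Optional[ContextCombination] = None
    block: Optional[int] = None
    index_in_block: Optional[int] = None
    prime_target_side: Optional[str] = None

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.prime_target == self.prime_distractor:
            raise ValueError("prime target and distractor must differ")
        if self.probe_target == self.probe_distractor:
            raise ValueError("probe target and distractor must differ")
        if (
            self.trial_type == "ignored_repetition"
            and self.probe_target != self.prime_distractor
        ):
            raise ValueError(
                "ignored-repetition trials must repeat the prime distractor "
                "as probe target"
            )
        if (
            self.trial_type == "attended_repetition"
            and self.probe_target != self.prime_target
        ):
            raise ValueError(
                "attended-repetition trials must repeat the prime target"
            )


@dataclass
class GroupSchedule:
    """A participant's full 384-trial sequence under one variability regime."""

    group: str
    trials: list[TrialSpec]
    designated_pair: Optional[ContextPair]
    seed: int
    _frame_cache: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """One row per trial, columns flattening all :class:`TrialSpec` fields."""
        if self._frame_cache is None:
            rows = [
                (
                    t.trial_type,
                    t.prime_target,
                    t.prime_distractor,
                    t.probe_target,
                    t.probe_distractor,
                    t.context.prime_tone.label,
                    t.context.prime_tone.frequency_hz,
                    t.context.probe_tone.label,
                    t.context.probe_tone.frequency_hz,
                    t.context.relation,
                    t.set_id,
                    t.block,
                    t.index_in_block,
                    t.prime_target_side,
                )
                for t in self.trials
            ]
            self._frame_cache = pd.DataFrame(
                rows, columns=SCHEDULE_COLUMNS
            )
        return self._frame_cache


SCHEDULE_COLUMNS = [
    "trial_type",
    "prime_target",
    "prime_distractor",
    "probe_target",
    "probe_distractor",
    "prime_context_label",
    "prime_context_hz",
    "probe_context_label",
    "probe_context_hz",
    "context_relation",
    "set_id",
    "block",
    "index_in_block",
    "prime_target_side",
]


def build_context_pairs(
    tones: Optional[Sequence[ContextTone]] = None,
) -> list[ContextPair]:
    """All same-parity tone pairs, in ascending canonical (label) order.

    For the full eight-tone inventory this yields exactly twelve pairs with
    every tone appearing in three of them.  Any candidate pair closer than
    200 Hz raises, which signals an inventory mismatch.
    """
    if tones is None:
        tones = default_tones()
    tones = sorted(set(tones))
    pairs = [
        ContextPair(a, b)
        for a, b in itertools.combinations(tones, 2)
        if a.label % 2 == b.label % 2
    ]
    return pairs


def _control_config_for_ir(t: str, d: str, p: str, sounds: Sequence[str]):
    """Control parallel of an ignored-repetition trial (t, d, p)."""
    fourth = next(s for s in sounds if s not in (t, d, p))
    # prime distractor replaced by the remaining fourth sound
    return (t, fourth, d, p)


def _control_config_for_ar(t: str, d: str, p: str, sounds: Sequence[str]):
    """Control parallel of an attended-repetition trial (t, d, p)."""
    fourth = next(s for s in sounds if s not in (t, d, p))
    # prime target replaced by the remaining fourth sound
    return (fourth, d, t, p)


def build_basic_trial_set(
    sounds: Sequence[str] = SOUNDS, set_id: str = "set1"
) -> list[TrialSpec]:
    """The 48-trial basic set: 12 trials of each of the four trial types.

    Ignored-repetition trials use three of the four sounds, with the probe
    target identical to the prime distractor; each has a parallel control
    trial in which only the prime distractor is replaced by the remaining
    fourth sound.  Attended-repetition trials repeat the prime target as
    probe target and are paralleled analogously by replacing the prime
    target.  Because every no-repetition stimulus configuration would
    otherwise arise twice (once per family), the 24 ignored- and 24
    attended-repetition trials are split into two complementary sets
    (``set1`` / ``set2``) inside which no control configuration repeats.
    """
    sounds = tuple(sounds)
    if len(sounds) != 4 or len(set(sounds)) != 4:
        raise ValueError("exactly four distinct sound labels are required")
    if set_id not in ("set1", "set2"):
        raise ValueError("set_id must be 'set1' or 'set2'")

    triples = list(itertools.permutations(sounds, 3))  # (t, d, p), 24 total
    ir_first, ir_second = triples[:12], triples[12:]
    ir_triples = ir_first if set_id == "set1" else ir_second

    used_controls = {_control_config_for_ir(*tr, sounds) for tr in ir_triples}
    ar_triples = [
        tr for tr in triples if _control_config_for_ar(*tr, sounds) not in used_controls
    ]
    assert len(ar_triples) == 12  # bijection of parallels guarantees this

    trials: list[TrialSpec] = []
    for t, d, p in ir_triples:
        trials.append(
            TrialSpec("ignored_repetition", t, d, d, p, set_id)
        )
        ct, cd, bt, bd = _control_config_for_ir(t, d, p, sounds)
        trials.append(TrialSpec("control", ct, cd, bt, bd, set_id))
    for t, d, p in ar_triples:
        trials.append(TrialSpec("attended_repetition", t, d, t, p, set_id))
        ct, cd, bt, bd = _control_config_for_ar(t, d, p, sounds)
        trials.append(
            TrialSpec("attended_repetition_control", ct, cd, bt, bd, set_id)
        )
    return trials


def _all_combinations(pairs: Sequence[ContextPair]) -> list[ContextCombination]:
    return [c for pair in pairs for c in pair.combinations()]


def build_group_schedule(
    group: str,
    basic_set: Optional[Sequence[TrialSpec]] = None,
    pairs: Optional[Sequence[ContextPair]] = None,
    seed: int = 0,
    designated_pair: Optional[ContextPair] = None,
) -> GroupSchedule:
    """Expand the basic set eightfold and assign contexts per group regime.

    All groups end up with 384 trials in 8 blocks of 48, 96 trials per
    trial type, and exactly 192 context-repeated and 192 context-changed
    trials.  Context assignment differs:

    blocked
        one combination of the designated pair per block; each of the four
        combinations fills exactly two blocks (block order randomized).
    ordered
        the designated pair's four combinations cycle in a fixed canonical
        order trial by trial.
    disordered
        the four combinations in random order, balanced to 96 occurrences.
    mixed
        per block, 36 trials (75%) follow the disordered regime on the
        designated pair and 12 trials (25%) follow the random regime.
    random
        combinations drawn over all twelve pairs, exactly balanced
        (eight occurrences of each of the 48 combinations).

    The prime-target side is a fair coin per trial; the probe target is
    always presented on the opposite side.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    if basic_set is None:
        basic_set = build_basic_trial_set()
    basic_set = list(basic_set)
    if len(basic_set) != TRIALS_PER_BLOCK:
        raise ValueError("the basic set must contain exactly 48 trials")
    if pairs is None:
        pairs = build_context_pairs()
    pairs = list(pairs)

    needs_pair = group in ("blocked", "ordered", "disordered", "mixed")
    if needs_pair:
        if designated_pair is None:
            designated_pair = pairs[int(rng.integers(len(pairs)))]
        elif designated_pair not in pairs:
            raise ValueError("designated pair is not in the supplied pair list")
        dcombos = designated_pair.combinations()
    else:
        if designated_pair is not None:
            raise ValueError("the random group uses all pairs; no designated pair")
        dcombos = []

    # --- trial ordering -------------------------------------------------
    if group == "blocked":
        ordered_trials: list[TrialSpec] = []
        for _ in range(N_BLOCKS):
            idx = rng.permutation(TRIALS_PER_BLOCK)
            ordered_trials.extend(basic_set[i] for i in idx)
    else:
        pool = basic_set * N_BLOCKS
        perm = rng.permutation(N_TRIALS)
        ordered_trials = [pool[i] for i in perm]

    # --- context assignment ----------------------------------------------
    contexts: list[ContextCombination]
    if group == "blocked":
        assignment = rng.permutation(np.repeat(np.arange(4), 2))
        contexts = [
            dcombos[assignment[b]]
            for b in range(N_BLOCKS)
            for _ in range(TRIALS_PER_BLOCK)
        ]
    elif group == "ordered":
        contexts = [dcombos[i % 4] for i in range(N_TRIALS)]
    elif group == "disordered":
        order = rng.permutation(np.repeat(np.arange(4), N_TRIALS // 4))
        contexts = [dcombos[k] for k in order]
    elif group == "mixed":
        all_combos = _all_combinations(pairs)
        rep = [c for c in all_combos if c.relation == "repeated"]
        chg = [c for c in all_combos if c.relation == "changed"]
        contexts = [None] * N_TRIALS  # type: ignore[list-item]
        for b in range(N_BLOCKS):
            random_pos = set(
                int(i) for i in rng.choice(TRIALS_PER_BLOCK, size=12, replace=False)
            )
            dis_part = [
                dcombos[k] for k in rng.permutation(np.repeat(np.arange(4), 9))
            ]
            rnd_part = [rep[int(i)] for i in rng.integers(0, len(rep), 6)]
            rnd_part += [chg[int(i)] for i in rng.integers(0, len(chg), 6)]
            rnd_part = [rnd_part[int(i)] for i in rng.permutation(12)]
            di, ri = iter(dis_part), iter(rnd_part)
            for j in range(TRIALS_PER_BLOCK):
                contexts[b * TRIALS_PER_BLOCK + j] = (
                    next(ri) if j in random_pos else next(di)
                )
    else:  # random
        all_combos = _all_combinations(pairs)
        order = rng.permutation(
            np.repeat(np.arange(len(all_combos)), N_TRIALS // len(all_combos))
        )
        contexts = [all_combos[k] for k in order]

    sides = np.where(rng.integers(0, 2, N_TRIALS) == 0, "left", "right")

    trials = [
        replace(
            t,
            context=ctx,
            block=i // TRIALS_PER_BLOCK + 1,
            index_in_block=i % TRIALS_PER_BLOCK + 1,
            prime_target_side=str(sides[i]),
        )
        for i, (t, ctx) in enumerate(zip(ordered_trials, contexts))
    ]
    return GroupSchedule(group, trials, designated_pair, seed)


def validate_schedule(schedule: GroupSchedule) -> dict:
    """Design report: named counts and invariant flags (never raises)."""
    trials = schedule.trials
    n = len(trials)
    type_counts = {tt: 0 for tt in TRIAL_TYPES}
    rel_counts = {"repeated": 0, "changed": 0}
    block_counts: dict[int, int] = {}
    block_combos: dict[int, set] = {}
    ir_identity_ok = True
    for t in trials:
        type_counts[t.trial_type] += 1
        rel_counts[t.context.relation] += 1
        block_counts[t.block] = block_counts.get(t.block, 0) + 1
        block_combos.setdefault(t.block, set()).add(t.context)
        if t.trial_type == "ignored_repetition" and t.probe_target != t.prime_distractor:
            ir_identity_ok = False

    flags = {
        "n_trials_ok": n == N_TRIALS,
        "blocks_ok": (
            len(block_counts) == N_BLOCKS
            and all(c == TRIALS_PER_BLOCK for c in block_counts.values())
        ),
        "trial_type_balanced": all(c == N_TRIALS // 4 for c in type_counts.values()),
        "context_relation_balanced": all(c == N_TRIALS // 2 for c in rel_counts.values()),
        "ignored_repetition_identity_ok": ir_identity_ok,
    }
    if schedule.group == "blocked":
        flags["blocked_one_combination_per_block"] = all(
            len(s) == 1 for s in block_combos.values()
        )
    if schedule.group == "ordered":
        combos = [t.context for t in trials]
        flags["ordered_fixed_cycle"] = all(
            combos[i] == combos[i + 4] for i in range(len(combos) - 4)
        )
    if schedule.group == "mixed" and schedule.designated_pair is not None:
        dset = set(schedule.designated_pair.combinations())
        per_block_designated = {
            b: sum(1 for t in trials if t.block == b and t.context in dset)
            for b in sorted(block_counts)
        }
        flags["mixed_designated_share_ok"] = all(
            c >= 36 for c in per_block_designated.values()
        )

    report = {
        "group": schedule.group,
        "counts": {
            "n_trials": n,
            "n_blocks": len(block_counts),
            "per_trial_type": type_counts,
            "per_context_relation": rel_counts,
            "per_block": [block_counts[b] for b in sorted(block_counts)],
            "distinct_combinations_per_block": [
                len(block_combos[b]) for b in sorted(block_combos)
            ],
        },
        "flags": flags,
        "ok": all(flags.values()),
    }
    return report


def write_schedule_csv(schedule: GroupSchedule, path) -> None:
    """Write one row per trial (UTF-8 CSV with header)."""
    schedule.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_schedule_csv(path, group: str = "random", seed: int = -1) -> GroupSchedule:
    """Read a schedule written by :func:`write_schedule_csv`.

    The CSV stores only trial rows, so group and seed metadata must be
    supplied by the caller if they are to be preserved.
    """
    df = pd.read_csv(path)
    trials = [
        TrialSpec(
            trial_type=r.trial_type,
            prime_target=r.prime_target,
            prime_distractor=r.prime_distractor,
            probe_target=r.probe_target,
            probe_distractor=r.probe_distractor,
            set_id=r.set_id,
            context=ContextCombination(
                tone(int(r.prime_context_label)), tone(int(r.probe_context_label))
            ),
            block=int(r.block),
            index_in_block=int(r.index_in_block),
            prime_target_side=r.prime_target_side,
        )
        for r in df.itertuples()
    ]
    return GroupSchedule(group, trials, None, seed)
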
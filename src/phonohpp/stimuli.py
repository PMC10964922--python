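"""Constrained CCVCV nonword generation and counterbalanced trial design.

The stimulus space is a fricative-plosive onset cluster (C1 ∈ {s, ʃ},
C2 ∈ {t, p}) followed by a VCV tail (V1 from six shared vowels, C3 from a
set of obstruents/sonorants, V2 ∈ {a, i}). Tails are shared across the two
phonotactic conditions (s-initial vs ʃ-initial), so condition differences
are carried entirely by the onset cluster. An OCP-Place constraint bans
C2–C3 pairs sharing place of articulation: labial /p/ never co-occurs with
C3 ∈ {m, b}, coronal /t/ never with C3 ∈ {n, d}.

Downstream, nonwords are grouped into fixed-duration trial lists (12 items,
18 s including interstimulus silence) per speaker pronunciation, and the
lists are arranged into eight counterbalanced experiment versions of
28 trials (2 blocks × [2 warm-ups + 12 test trials]) under pseudorandom
adjacency constraints: never more than two consecutive trials on the same
side, never more than two consecutive test trials of the same condition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DesignError

FRICATIVES = ("s", "ʃ")
PLOSIVES = ("t", "p")
CLUSTERS: tuple[tuple[str, str], ...] = tuple(itertools.product(FRICATIVES, PLOSIVES))
DEFAULT_VOWELS = ("a", "i", "o", "u", "e", "y")
DEFAULT_MEDIALS = ("k", "g", "d", "b", "m", "n", "r")
DEFAULT_FINALS = ("a", "i")

S_CONDITION = "s-initial"
SH_CONDITION = "ʃ-initial"
CONDITIONS = (S_CONDITION, SH_CONDITION)
PRONUNCIATIONS = ("French", "German")
SIDES = ("left", "right")

LIST_TARGET_S = 18.0
LIST_TOLERANCE_S = 0.001  # 1 ms

# Synthetic per-condition duration models (mean, sd) in seconds, by
# pronunciation; draws are clipped at ±3 sd. Means mirror the recorded
# material: s-initial items run ~100 ms (German) / ~20 ms (French) longer
# than ʃ-initial items.
DEFAULT_DURATION_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "German": {S_CONDITION: (0.779, 0.068), SH_CONDITION: (0.676, 0.043)},
    "French": {S_CONDITION: (0.461, 0.031), SH_CONDITION: (0.441, 0.025)},
}

Tail = tuple[str, str, str]  # (V1, C3, V2)
Cluster = tuple[str, str]  # (C1 fricative, C2 plosive)

_OCP_CLASHES = {"p": {"m": "labial", "b": "labial"}, "t": {"n": "coronal", "d": "coronal"}}


@dataclass(frozen=True)
class OCPResult:
    ok: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.ok


def check_ocp(cluster: Cluster, tail: Tail) -> OCPResult:
    """OCP-Place check on the non-adjacent consonants C2 (cluster) and C3 (tail)."""
    c2 = cluster[1]
    c3 = tail[1]
    clash = _OCP_CLASHES.get(c2, {})
    if c3 in clash:
        return OCPResult(False, f"{c2}–{c3} {clash[c3]} place clash")
    return OCPResult(True)


@dataclass(frozen=True)
class NonwordSpec:
    """One CCVCV nonword: onset cluster + VCV tail."""

    cluster: Cluster
    tail: Tail

    @property
    def condition(self) -> str:
        return S_CONDITION if self.cluster[0] == "s" else SH_CONDITION

    @property
    def surface(self) -> str:
        return "".join(self.cluster) + "".join(self.tail)

    @property
    def transcription(self) -> tuple[str, ...]:
        return self.cluster + self.tail


@dataclass
class StimulusSet:
    items: list[NonwordSpec]
    tails: list[Tail]
    clusters: tuple[Cluster, ...]

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def by_condition(self, condition: str) -> list[NonwordSpec]:
        return [s for s in self.items if s.condition == condition]


def generate_tails(
    vowels: Sequence[str] = DEFAULT_VOWELS,
    medials: Sequence[str] = DEFAULT_MEDIALS,
    finals: Sequence[str] = DEFAULT_FINALS,
    n: int = 36,
    seed: int | None = 0,
    clusters: Sequence[Cluster] = CLUSTERS,
) -> list[Tail]:
    """Select ``n`` unique VCV tails compatible with *every* onset cluster.

    Exactly half the tails end in each final vowel, and the selection is
    stratified round-robin over (V1, C3) cells so that vowel and medial
    material is spread as evenly as integer constraints allow. With the
    default sets, 36 candidates survive the OCP filter and all are returned.
    Deterministic for a fixed seed.
    """
    if len(finals) != 2:
        raise DesignError("tail generation expects exactly two final vowels")
    if n % 2 != 0:
        raise DesignError("n must be even to balance the two final vowels")
    candidates = [
        (v1, c3, v2)
        for v1, c3, v2 in itertools.product(vowels, medials, finals)
        if all(check_ocp(cl, (v1, c3, v2)) for cl in clusters)
    ]
    if n > len(candidates):
        raise DesignError(
            f"requested {n} tails but only {len(candidates)} survive OCP against all clusters"
        )
    rng = np.random.default_rng(seed)
    chosen: list[Tail] = []
    for final in finals:
        pool = [t for t in candidates if t[2] == final]
        if n // 2 > len(pool):
            raise DesignError(
                f"requested {n // 2} tails ending in /{final}/ but only {len(pool)} are feasible"
            )
        # stratified round-robin over (V1, C3) cells, seeded order within/among cells
        cells: dict[tuple[str, str], list[Tail]] = {}
        for t in pool:
            cells.setdefault((t[0], t[1]), []).append(t)
        keys = list(cells)
        rng.shuffle(keys)
        picked: list[Tail] = []
        while len(picked) < n // 2:
            for k in keys:
                if cells[k] and len(picked) < n // 2:
                    idx = rng.integers(len(cells[k]))
                    picked.append(cells[k].pop(idx))
        chosen.extend(picked)
    return chosen


def generate_nonwords(
    clusters: Sequence[Cluster] = CLUSTERS, tails: Sequence[Tail] | None = None
) -> StimulusSet:
    """Full cross of onset clusters × shared tails (144 nonwords by default)."""
    if tails is None:
        tails = generate_tails(clusters=clusters)
    if not tails:
        raise DesignError("no tails provided")
    for cl, t in itertools.product(clusters, tails):
        result = check_ocp(cl, t)
        if not result:
            raise DesignError(
                f"tail {'-'.join(t)} violates OCP against cluster /{''.join(cl)}/: {result.reason}"
            )
    items = [NonwordSpec(cluster=cl, tail=t) for cl in clusters for t in tails]
    surfaces = [s.surface for s in items]
    if len(set(surfaces)) != len(surfaces):
        raise DesignError("duplicate nonword surfaces generated")
    return StimulusSet(items=items, tails=list(tails), clusters=tuple(clusters))


def synthetic_durations(
    stimuli: StimulusSet,
    pronunciation: str,
    seed: int | None = 0,
    params: Mapping[str, Mapping[str, tuple[float, float]]] = DEFAULT_DURATION_PARAMS,
) -> dict[str, float]:
    """Draw per-nonword durations (s) from the per-condition Gaussian model."""
    rng = np.random.default_rng(seed)
    out = {}
    for s in stimuli:
        mean, sd = params[pronunciation][s.condition]
        d = float(np.clip(rng.normal(mean, sd), mean - 3 * sd, mean + 3 * sd))
        out[s.surface] = d
    return out


@dataclass
class TrialList:
    """A 12-item single-condition audio list padded with silence to 18 s."""

    id: str
    condition: str
    pronunciation: str
    items: list[NonwordSpec]
    durations: list[float]
    isis: list[float]

    @property
    def total_duration(self) -> float:
        return sum(self.durations) + sum(self.isis)

    def validate(self, per_list: int = 12, target: float = LIST_TARGET_S) -> list[str]:
        problems = []
        if len(self.items) != per_list:
            problems.append(f"list {self.id}: {len(self.items)} items, expected {per_list}")
        if any(s.condition != self.condition for s in self.items):
            problems.append(f"list {self.id}: mixed conditions")
        if abs(self.total_duration - target) > LIST_TOLERANCE_S:
            problems.append(
                f"list {self.id}: total duration {self.total_duration:.4f}s != {target}s"
            )
        if any(g < 0 for g in self.isis):
            problems.append(f"list {self.id}: negative interstimulus silence")
        return problems


def assemble_lists(
    stimuli: StimulusSet,
    durations: Mapping[str, float],
    pronunciation: str,
    per_list: int = 12,
    lists_per_condition: int = 6,
    target: float = LIST_TARGET_S,
    seed: int | None = 0,
    jitter: float = 0.0,
) -> list[TrialList]:
    """Partition the stimuli into fixed-duration trial lists for one speaker.

    Each nonword appears exactly once across the lists of a pronunciation;
    each list holds ``per_list`` same-condition items and is padded with
    post-item silences so the list lasts exactly ``target`` seconds
    (trailing silence after the last item included). Silences are equal by
    default; ``jitter`` > 0 perturbs the gaps with a seeded Dirichlet-like
    reallocation while keeping the exact total.
    """
    rng = np.random.default_rng(seed)
    lists: list[TrialList] = []
    for condition in CONDITIONS:
        pool = stimuli.by_condition(condition)
        if len(pool) != per_list * lists_per_condition:
            raise DesignError(
                f"{condition}: {len(pool)} stimuli cannot fill {lists_per_condition} "
                f"lists of {per_list}"
            )
        order = rng.permutation(len(pool))
        for j in range(lists_per_condition):
            chunk = [pool[k] for k in order[j * per_list : (j + 1) * per_list]]
            durs = [float(durations[s.surface]) for s in chunk]
            silence = target - sum(durs)
            if silence < 0:
                raise DesignError(
                    f"list {condition}-{j + 1} ({pronunciation}): item durations sum to "
                    f"{sum(durs):.3f}s > {target}s target"
                )
            gaps = np.full(per_list, silence / per_list)
            if jitter > 0 and silence > 0:
                w = rng.random(per_list) * jitter + (1 - jitter)
                gaps = silence * w / w.sum()
            prefix = "s" if condition == S_CONDITION else "sh"
            lists.append(
                TrialList(
                    id=f"{pronunciation}-{prefix}{j + 1}",
                    condition=condition,
                    pronunciation=pronunciation,
                    items=chunk,
                    durations=durs,
                    isis=[float(g) for g in gaps],
                )
            )
    return lists


# ---------------------------------------------------------------------------
# Experiment versions


@dataclass(frozen=True)
class Trial:
    trial_index: int  # 1..28
    block: int  # 1 or 2
    trial_type: str  # "warmup" | "test"
    side: str
    condition: str | None = None  # None for warm-ups
    pronunciation: str | None = None  # None for warm-ups (classical music)
    list_id: str | None = None


@dataclass
class ExperimentVersion:
    version_id: int
    first_pronunciation: str
    first_condition: str
    first_side: str
    trials: list[Trial]

    def block(self, b: int) -> list[Trial]:
        return [t for t in self.trials if t.block == b]


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def _max_run(seq: Sequence) -> int:
    best = run = 0
    prev = object()
    for x in seq:
        run = run + 1 if x == prev else 1
        best = max(best, run)
        prev = x
    return best


def _constrained_sequence(
    rng: np.random.Generator,
    symbols: tuple,
    n_each: int,
    first=None,
    max_run: int = 2,
    max_tries: int = 200,
):
    """Sequential sampling of a balanced two-symbol sequence with bounded runs."""
    a, b = symbols
    for _ in range(max_tries):
        remaining: dict = {a: n_each, b: n_each}
        seq = []
        ok = True
        while sum(remaining.values()) > 0:
            options = []
            for sym in symbols:
                if remaining[sym] == 0:
                    continue
                if seq and len(seq) >= max_run and all(x == sym for x in seq[-max_run:]):
                    continue
                options.append(sym)
            if not seq and first is not None:
                options = [first] if remaining[first] > 0 else options
            if not options:
                ok = False
                break
            sym = options[int(rng.integers(len(options)))]
            seq.append(sym)
            remaining[sym] -= 1
        if ok and _max_run(seq) <= max_run and (first is None or seq[0] == first):
            return seq
    raise DesignError("could not build a constrained sequence within retry budget")


def build_experiment_versions(
    lists: Sequence[TrialList],
    seed: int | None = 0,
    n_test_per_condition: int = 6,
) -> list[ExperimentVersion]:
    """Build the eight counterbalanced 28-trial experiment versions.

    Versions cross {first-block pronunciation} × {first test-trial condition}
    × {first test-trial side}. Each block is homogeneous in pronunciation,
    opens with two warm-up trials (one per side), and contains six test
    trials per phonotactic condition drawn from that pronunciation's twelve
    lists (each list used once per version). Side runs are bounded at two
    across the whole 28-trial sequence; condition runs are bounded at two
    within each block's test trials.
    """
    rng = np.random.default_rng(seed)
    by_pron: dict[str, dict[str, list[TrialList]]] = {}
    for tl in lists:
        by_pron.setdefault(tl.pronunciation, {}).setdefault(tl.condition, []).append(tl)
    for pron in PRONUNCIATIONS:
        for cond in CONDITIONS:
            have = len(by_pron.get(pron, {}).get(cond, []))
            if have < n_test_per_condition:
                raise DesignError(
                    f"need {n_test_per_condition} {cond} lists for {pron}, have {have}"
                )

    versions: list[ExperimentVersion] = []
    vid = 0
    # pronunciation varies fastest so that round-robin assignment of
    # consecutive participants stays counterbalanced at any sample size
    for first_cond, first_side, first_pron in itertools.product(
        CONDITIONS, SIDES, PRONUNCIATIONS
    ):
        vid += 1
        prons = (first_pron, PRONUNCIATIONS[0] if first_pron == PRONUNCIATIONS[1] else PRONUNCIATIONS[1])
        trials: list[Trial] = []
        index = 0
        prev_sides: list[str] = []
        for b, pron in enumerate(prons, start=1):
            conds = _constrained_sequence(
                rng, CONDITIONS, n_test_per_condition, first=first_cond if b == 1 else None
            )
            # per-block list order: seeded shuffle, one list per test trial
            assign: dict[str, list[TrialList]] = {}
            for cond in CONDITIONS:
                pool = list(by_pron[pron][cond])
                rng.shuffle(pool)
                assign[cond] = pool
            # side sequence: warm-ups one per side, then 12 test sides
            n_trials = 2 + 2 * n_test_per_condition
            for attempt in range(200):
                sides: list[str] = []
                tail = list(prev_sides)
                want_first_test = first_side if b == 1 else None
                feasible = True
                for i in range(n_trials):
                    if i == 1:
                        choice = [SIDES[0] if sides[0] == SIDES[1] else SIDES[1]]
                    elif i == 2 and want_first_test is not None:
                        choice = [want_first_test]
                    else:
                        choice = [
                            s
                            for s in SIDES
                            if not (len(tail) >= 2 and tail[-1] == tail[-2] == s)
                        ]
                    choice = [
                        s for s in choice if not (len(tail) >= 2 and tail[-1] == tail[-2] == s)
                    ]
                    if not choice:
                        feasible = False
                        break
                    s = choice[int(rng.integers(len(choice)))]
                    sides.append(s)
                    tail.append(s)
                if feasible:
                    break
            else:
                raise DesignError("could not build a side sequence within retry budget")
            prev_sides = (prev_sides + sides)[-2:]
            cond_iter = iter(conds)
            for i in range(n_trials):
                index += 1
                if i < 2:
                    trials.append(
                        Trial(trial_index=index, block=b, trial_type="warmup", side=sides[i])
                    )
                else:
                    cond = next(cond_iter)
                    tl = assign[cond].pop()
                    trials.append(
                        Trial(
                            trial_index=index,
                            block=b,
                            trial_type="test",
                            side=sides[i],
                            condition=cond,
                            pronunciation=pron,
                            list_id=tl.id,
                        )
                    )
        version = ExperimentVersion(
            version_id=vid,
            first_pronunciation=first_pron,
            first_condition=first_cond,
            first_side=first_side,
            trials=trials,
        )
        report = validate_sequence(version)
        if not report:
            raise DesignError(
                "generated version failed validation: " + "; ".join(report.violations)
            )
        versions.append(version)
    return versions


def validate_sequence(
    version: ExperimentVersion,
    n_test_per_condition: int = 6,
    max_run: int = 2,
) -> ValidationReport:
    """Check a version against the block-structure and adjacency constraints."""
    v: list[str] = []
    n_expected = 2 * (2 + 2 * n_test_per_condition)
    if len(version.trials) != n_expected:
        v.append(f"{len(version.trials)} trials, expected {n_expected}")
    for b in (1, 2):
        block = version.block(b)
        warm = [t for t in block if t.trial_type == "warmup"]
        test = [t for t in block if t.trial_type == "test"]
        if len(warm) != 2 or {t.side for t in warm} != set(SIDES):
            v.append(f"block {b}: warm-ups must be one per side")
        if block and [t.trial_type for t in block[:2]] != ["warmup", "warmup"]:
            v.append(f"block {b}: does not open with two warm-ups")
        if len(test) != 2 * n_test_per_condition:
            v.append(f"block {b}: {len(test)} test trials, expected {2 * n_test_per_condition}")
        for cond in CONDITIONS:
            n = sum(1 for t in test if t.condition == cond)
            if n != n_test_per_condition:
                v.append(f"block {b}: {n} {cond} trials, expected {n_test_per_condition}")
        prons = {t.pronunciation for t in test}
        if len(prons) > 1:
            v.append(f"block {b}: mixed pronunciations {sorted(map(str, prons))}")
        cond_seq = [t.condition for t in test]
        if _max_run(cond_seq) > max_run:
            run_at = _run_indices(test, cond_seq, max_run)
            v.append(f"block {b}: >{max_run} consecutive same-condition trials at {run_at}")
        lids = [t.list_id for t in test]
        if len(set(lids)) != len(lids):
            v.append(f"block {b}: a trial list is repeated")
    b1 = {t.pronunciation for t in version.block(1) if t.trial_type == "test"}
    b2 = {t.pronunciation for t in version.block(2) if t.trial_type == "test"}
    if b1 and b1 == b2:
        v.append("both blocks use the same pronunciation")
    side_seq = [t.side for t in version.trials]
    if _max_run(side_seq) > max_run:
        run_at = _run_indices(version.trials, side_seq, max_run)
        v.append(f">{max_run} consecutive same-side trials at {run_at}")
    return ValidationReport(ok=not v, violations=v)


def _run_indices(trials: Sequence[Trial], seq: Sequence, max_run: int) -> list[int]:
    """Trial indices where a run longer than max_run is completed."""
    out = []
    run = 0
    prev = object()
    for t, x in zip(trials, seq):
        run = run + 1 if x == prev else 1
        if run > max_run:
            out.append(t.trial_index)
        prev = x
    return out


def default_versions(seed: int | None = 0) -> list[ExperimentVersion]:
    """Stimuli → durations → lists → eight versions, all from one seed."""
    rng = np.random.default_rng(seed)
    stimuli = generate_nonwords(tails=generate_tails(seed=int(rng.integers(2**31))))
    lists: list[TrialList] = []
    for pron in PRONUNCIATIONS:
        durs = synthetic_durations(stimuli, pron, seed=int(rng.integers(2**31)))
        lists.extend(
            assemble_lists(stimuli, durs, pron, seed=int(rng.integers(2**31)))
        )
    return build_experiment_versions(lists, seed=int(rng.integers(2**31)))
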
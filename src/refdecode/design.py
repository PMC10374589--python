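"""Factorial delayed-movement experimental design.

The experiment crosses three two-level factors: stimulated foot (left/right),
foot posture (uncrossed/crossed, constant within a run and changed only every
three runs), and task rule (pro-/anti-pointing).  Each trial runs through four
phases -- fixation (1 TR), touch localization delay (1-4 TR), movement
planning delay (1-4 TR), movement execution (1 TR) -- with the two delays
jittered independently and uniformly.

Trial sequences are first-order counterbalanced run-wise over the four
within-run conditions (foot x task): every ordered pair of conditions,
self-transitions included, occurs equally often.  This is realized as an
Eulerian circuit on the complete 4-node transition multigraph.

The functions :func:`external_side` and :func:`goal_side` encode the spatial
logic that dissociates the three reference frames: anatomical (which foot),
external (which side of space), and motor goal (where the pointing movement
goes, after applying the pro/anti rule).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SIDES = ("left", "right")
POSTURES = ("uncrossed", "crossed")
TASKS = ("pro", "anti")
STIM_SITES = ("medial", "lateral")
PHASES = ("fixation", "touch", "planning", "execution")

TR_SECONDS = 1.88
REST_START_TR = 11
REST_END_TR = 4

#: the four within-run conditions over which transitions are balanced
RUN_CONDITIONS = tuple(itertools.product(SIDES, TASKS))


def _check_enum(value, allowed, name):
    if value not in allowed:
        raise ValueError(f"invalid {name}: {value!r} (expected one of {allowed})")


def opposite(side: str) -> str:
    _check_enum(side, SIDES, "side")
    return "right" if side == "left" else "left"


def external_side(foot: str, posture: str) -> str:
    """Side of external space a touch on `foot` occupies, given the posture.

    With crossed feet the anatomically right foot lies in the left side of
    space, and vice versa.
    """
    _check_enum(foot, SIDES, "foot")
    _check_enum(posture, POSTURES, "posture")
    return foot if posture == "uncrossed" else opposite(foot)


def goal_side(foot: str, posture: str, task: str) -> str:
    """External side of the pointing goal.

    Pro-pointing targets the touched foot; anti-pointing targets the
    homologous location on the other foot.  The goal's side in space is the
    external side of the target foot under the current posture.
    """
    _check_enum(task, TASKS, "task")
    target_foot = foot if task == "pro" else opposite(foot)
    return external_side(target_foot, posture)


@dataclass
class TrialRecord:
    participant_id: str
    run_index: int
    trial_index: int
    posture: str
    foot: str
    stim_site: str
    task_rule: str
    loc_delay_tr: int = 0
    plan_delay_tr: int = 0
    onsets_tr: dict = field(default_factory=dict)  # phase -> onset in TR
    is_error: bool = False

    @property
    def condition(self):
        """(posture, foot, task) cell of the 2x2x2 design."""
        return (self.posture, self.foot, self.task_rule)

    @property
    def run_condition(self):
        """(foot, task) cell used for run-wise counterbalancing."""
        return (self.foot, self.task_rule)

    def phase_duration_tr(self, phase: str) -> int:
        _check_enum(phase, PHASES, "phase")
        if phase == "touch":
            return self.loc_delay_tr
        if phase == "planning":
            return self.plan_delay_tr
        return 1

    @property
    def goal_side(self) -> str:
        return goal_side(self.foot, self.posture, self.task_rule)

    @property
    def external_side(self) -> str:
        return external_side(self.foot, self.posture)


@dataclass
class ExperimentDesign:
    participant_id: str
    trials: list  # ordered, all runs
    tr_seconds: float = TR_SECONDS
    n_runs: int = 12
    posture_schedule: dict = field(default_factory=dict)  # run -> posture
    run_length_tr: dict = field(default_factory=dict)  # run -> length
    rest_start_tr: int = REST_START_TR
    rest_end_tr: int = REST_END_TR
    seed: int | None = None

    def trials_for_run(self, run_index: int) -> list:
        return [t for t in self.trials if t.run_index == run_index]

    @property
    def run_indices(self):
        return sorted(self.posture_schedule)


def generate_run_sequence(
    posture: str,
    n_trials: int = 33,
    rng: np.random.Generator | None = None,
    start_condition: tuple | None = None,
    participant_id: str = "sub-01",
    run_index: int = 1,
) -> list:
    """Generate one run's first-order counterbalanced trial sequence.

    Requires ``n_trials = 16 k + 1`` so that each of the 16 ordered
    (foot x task) condition pairs can occur exactly ``k`` times.  The
    sequence is an Eulerian circuit of the complete transition multigraph
    with randomized edge order (so the circuit starts and ends on
    ``start_condition``, which therefore receives the single surplus
    occurrence).  The medial/lateral stimulation site is balanced marginally
    within each foot.
    """
    _check_enum(posture, POSTURES, "posture")
    rng = np.random.default_rng(rng)
    k, rem = divmod(n_trials - 1, 16)
    if rem != 0 or k < 1:
        raise ValueError(
            f"n_trials must be 16*k+1 for integer k>=1 to allow equal "
            f"transition counts; got {n_trials}"
        )
    if start_condition is None:
        start_condition = RUN_CONDITIONS[rng.integers(len(RUN_CONDITIONS))]
    elif start_condition not in RUN_CONDITIONS:
        raise ValueError(f"invalid start condition {start_condition!r}")

    # Hierholzer's algorithm on the complete digraph with self-loops; every
    # node has in-degree = out-degree = 4k and the graph is strongly
    # connected, so an Eulerian circuit always exists.
    adjacency = {}
    for u in RUN_CONDITIONS:
        targets = [v for v in RUN_CONDITIONS for _ in range(k)]
        rng.shuffle(targets)
        adjacency[u] = targets
    stack = [start_condition]
    circuit = []
    while stack:
        v = stack[-1]
        if adjacency[v]:
            stack.append(adjacency[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    assert len(circuit) == n_trials

    trials = [
        TrialRecord(
            participant_id=participant_id,
            run_index=run_index,
            trial_index=i + 1,
            posture=posture,
            foot=foot,
            stim_site="medial",  # assigned below
            task_rule=task,
        )
        for i, (foot, task) in enumerate(circuit)
    ]
    # balance medial/lateral within each foot as evenly as possible
    for foot in SIDES:
        idx = [i for i, t in enumerate(trials) if t.foot == foot]
        n_med = len(idx) // 2
        sites = ["medial"] * n_med + ["lateral"] * (len(idx) - n_med)
        rng.shuffle(sites)
        for i, site in zip(idx, sites):
            trials[i].stim_site = site
    return trials


def transition_counts(trials) -> dict:
    """Ordered-pair transition counts over the (foot, task) run conditions."""
    counts = {(u, v): 0 for u in RUN_CONDITIONS for v in RUN_CONDITIONS}
    for a, b in zip(trials[:-1], trials[1:]):
        counts[(a.run_condition, b.run_condition)] += 1
    return counts


def assign_delays(design: ExperimentDesign, rng=None) -> ExperimentDesign:
    """Draw jittered delays uniformly from {1,2,3,4} TR and recompute onsets.

    Each run starts with an 11 TR rest and ends with a 4 TR rest.  Within a
    trial the phases are contiguous: fixation (1 TR), touch localization
    (loc_delay), movement planning (plan_delay), execution (1 TR).
    """
    rng = np.random.default_rng(rng)
    trials = [replace(t, onsets_tr=dict(t.onsets_tr)) for t in design.trials]
    run_length = {}
    for run in sorted({t.run_index for t in trials}):
        t_cursor = design.rest_start_tr
        for trial in (t for t in trials if t.run_index == run):
            trial.loc_delay_tr = int(rng.integers(1, 5))
            trial.plan_delay_tr = int(rng.integers(1, 5))
            trial.onsets_tr = {
                "fixation": t_cursor,
                "touch": t_cursor + 1,
                "planning": t_cursor + 1 + trial.loc_delay_tr,
                "execution": t_cursor + 1 + trial.loc_delay_tr + trial.plan_delay_tr,
            }
            t_cursor += 2 + trial.loc_delay_tr + trial.plan_delay_tr
        run_length[run] = t_cursor + design.rest_end_tr
    return replace(design, trials=trials, run_length_tr=run_length)


def make_participant_design(
    participant_id: str = "sub-01",
    seed=None,
    start_posture: str = "uncrossed",
    n_runs: int = 12,
    n_trials: int = 33,
) -> ExperimentDesign:
    """Build a participant's full design: posture in triples, surplus rotated.

    Posture is held for three consecutive runs; the start posture alternates
    between the two halves (sessions) of the experiment.  The one surplus
    (foot x task) condition of each run -- the Eulerian circuit's start node,
    which occurs ``(n_trials-1)/4 + 1`` times -- is rotated across the runs of
    each posture so that experiment-wide per-condition totals stay within a
    one-trial band.
    """
    _check_enum(start_posture, POSTURES, "posture")
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    rng = np.random.default_rng(seed)
    other = POSTURES[1 - POSTURES.index(start_posture)]
    if n_runs % 6 == 0:
        # two sessions with alternated start posture, triples within session
        half = n_runs // 2
        schedule = []
        for first, second in ((start_posture, other), (other, start_posture)):
            for i in range(half):
                schedule.append(first if (i // 3) % 2 == 0 else second)
    else:
        # fallback for reduced designs: alternating posture triples
        schedule = [
            start_posture if (i // 3) % 2 == 0 else other for i in range(n_runs)
        ]
    posture_schedule = {r + 1: p for r, p in enumerate(schedule)}

    surplus_counter = {p: 0 for p in POSTURES}
    trials = []
    for run in range(1, n_runs + 1):
        posture = posture_schedule[run]
        start_condition = RUN_CONDITIONS[surplus_counter[posture] % len(RUN_CONDITIONS)]
        surplus_counter[posture] += 1
        trials.extend(
            generate_run_sequence(
                posture,
                n_trials=n_trials,
                rng=rng,
                start_condition=start_condition,
                participant_id=participant_id,
                run_index=run,
            )
        )
    design = ExperimentDesign(
        participant_id=participant_id,
        trials=trials,
        n_runs=n_runs,
        posture_schedule=posture_schedule,
        seed=seed if isinstance(seed, int) else None,
    )
    return assign_delays(design, rng=rng)


def design_criterion(design: ExperimentDesign, dm_builder) -> float:
    """Max absolute pairwise correlation among task predictors, over runs.

    Baseline and error predictors are excluded; constant or empty columns are
    skipped (their correlation is undefined).
    """
    worst = 0.0
    for run, names, X in dm_builder(design):
        keep = [
            j
            for j, nm in enumerate(names)
            if not nm.startswith(("baseline", "error")) and np.std(X[:, j]) > 0
        ]
        if len(keep) < 2:
            continue
        r = np.corrcoef(X[:, keep], rowvar=False)
        off = np.abs(r[~np.eye(len(keep), dtype=bool)])
        worst = max(worst, float(off.max()))
    return worst


def select_min_correlation_design(
    base_design: ExperimentDesign,
    dm_builder,
    n_candidates: int = 1000,
    rng=None,
) -> ExperimentDesign:
    """Re-randomize delays ``n_candidates`` times; keep the design whose GLM
    predictors are least correlated (minimal max |r|; ties -> first)."""
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = np.random.default_rng(rng)
    best, best_crit = None, np.inf
    for _ in range(n_candidates):
        cand = assign_delays(base_design, rng=rng)
        crit = design_criterion(cand, dm_builder)
        if crit < best_crit:
            best, best_crit = cand, crit
    return best


def count_condition_totals(cohort) -> pd.DataFrame:
    """Per-participant per-(posture,foot,task) trial totals, plus grand total.

    Returns a tidy frame with one row per participant x condition and a
    ``grand_total`` attribute with the cohort-wide trial count.
    """
    rows = []
    for design in cohort:
        counts = {}
        for t in design.trials:
            counts[t.condition] = counts.get(t.condition, 0) + 1
        for (posture, foot, task), n in sorted(counts.items()):
            rows.append(
                {
                    "participant_id": design.participant_id,
                    "posture": posture,
                    "foot": foot,
                    "task_rule": task,
                    "n_trials": n,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["grand_total"] = int(table["n_trials"].sum()) if len(table) else 0
    return table
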
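"""Accelerated titration design (ATD) with rule-triggered transition to 3+3.

The trial design enrolls single-patient cohorts that escalate one dose
level per patient while toxicity stays at grade 0-1. Three cohort-level
rules key on the initial treatment cycle:

* a tolerable grade 2 toxicity holds the dose (STAY);
* a dose-limiting toxicity (DLT) de-escalates the patient and, if it occurs
  in cycle 1, converts the design to a standard 3+3 at the current level;
* the second grade >= 2 toxicity occurrence across the cohort's first
  cycles also converts to 3+3 at the triggering level.

In the 3+3 phase, cohorts of three are evaluated per dose level: 0/3 DLTs
escalate, 1/3 expands to six, >= 2 DLTs declare the next lower level the
recommended phase-2 dose (RP2D); in an expanded cohort 1/6 escalates and
> 1/6 declares the next lower level. Escalation past the top configured
level declares the current level the RP2D.

A DLT is any intolerable grade 2 or any grade >= 3 neurological toxicity
related to the procedure or infusate, or any related systemic grade >= 3
toxicity (excepting nausea/vomiting/diarrhea responsive to maximal medical
management), occurring within 14 days of the last infusion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

DLT_WINDOW_DAYS = 14


class Phase(str, enum.Enum):
    ATD = "ATD"
    THREE_PLUS_THREE = "THREE_PLUS_THREE"
    COMPLETE = "COMPLETE"


class Action(str, enum.Enum):
    ESCALATE = "ESCALATE"
    STAY = "STAY"
    DE_ESCALATE = "DE_ESCALATE"
    TRANSITION_TO_3P3 = "TRANSITION_TO_3P3"
    EXPAND_TO_6 = "EXPAND_TO_6"
    DECLARE_RP2D_NEXT_LOWER = "DECLARE_RP2D_NEXT_LOWER"
    DECLARE_RP2D_CURRENT = "DECLARE_RP2D_CURRENT"
    CONTINUE = "CONTINUE"


@dataclass(frozen=True)
class DoseLevel:
    index: int
    volume_mL: float
    concentration_mg_per_mL: float = 20.0

    def __post_init__(self) -> None:
        if self.index < 1 or self.volume_mL <= 0 or self.concentration_mg_per_mL <= 0:
            raise ValueError("invalid dose level")


#: The completed ladder of the trial this design models: 2 mL and 3 mL of
#: 20 mg/mL nanoliposomal irinotecan per infusion.
DEFAULT_DOSE_LEVELS = (DoseLevel(1, 2.0), DoseLevel(2, 3.0))


def validate_ladder(levels: tuple[DoseLevel, ...]) -> None:
    if not levels:
        raise ValueError("dose ladder is empty")
    idx = [d.index for d in levels]
    vol = [d.volume_mL for d in levels]
    if idx != list(range(1, len(levels) + 1)):
        raise ValueError("dose level indices must be 1..n")
    if any(b <= a for a, b in zip(vol, vol[1:])):
        raise ValueError("dose volumes must increase strictly with index")


@dataclass(frozen=True)
class CycleOutcome:
    """Toxicity summary for one patient-cycle.

    ``max_related_grade`` is the worst treatment-related grade; unrelated
    AEs do not enter. ``tolerable_grade2`` is clinical adjudication supplied
    as input, not computed. ``n_grade2plus_events`` counts related grade >= 2
    AE *occurrences* in the cycle (the ATD transition tally counts
    occurrences, and one cycle can contribute several); it defaults to 1 if
    the max grade is >= 2, else 0. ``dlt`` may be given explicitly or left
    None to be derived by :func:`classify_dlt`.
    """

    subject_id: str
    cycle: int
    dose_level: int
    max_related_grade: int
    tolerable_grade2: bool = True
    dlt: bool | None = None
    within_dlt_window: bool = True
    systemic: bool = False
    managed_nvd: bool = False
    n_grade2plus_events: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.max_related_grade <= 5):
            raise ValueError("grade must be in 0..5")
        if self.cycle < 1:
            raise ValueError("cycle must be positive")
        if self.n_grade2plus_events is None:
            object.__setattr__(
                self, "n_grade2plus_events", 1 if self.max_related_grade >= 2 else 0
            )
        if self.dlt is None:
            object.__setattr__(self, "dlt", classify_dlt(self))
        if self.dlt and self.max_related_grade < 2:
            raise ValueError("a DLT requires related grade >= 2")


def classify_dlt(outcome: CycleOutcome) -> bool:
    """Apply the protocol DLT definition to a cycle outcome."""
    if not outcome.within_dlt_window:
        return False
    g = outcome.max_related_grade
    if g >= 3:
        if outcome.systemic and outcome.managed_nvd:
            return False  # managed nausea/vomiting/diarrhea exception
        return True
    if g == 2 and not outcome.systemic and not outcome.tolerable_grade2:
        return True  # intolerable grade 2 neurological toxicity
    return False


@dataclass(frozen=True)
class DoseDecision:
    action: Action
    rationale: str


@dataclass(frozen=True)
class DesignState:
    dose_levels: tuple[DoseLevel, ...] = DEFAULT_DOSE_LEVELS
    phase: Phase = Phase.ATD
    current_dl: int = 1
    grade2plus_count_cycle1: int = 0
    per_dl_enrolled: tuple[tuple[int, int], ...] = ()
    per_dl_dlt: tuple[tuple[int, int], ...] = ()
    rp2d: int | None = None
    n_enrolled: int = 0
    audit_log: tuple[tuple[str, str, int, str], ...] = ()

    def __post_init__(self) -> None:
        validate_ladder(self.dose_levels)
        if not (1 <= self.current_dl <= len(self.dose_levels)):
            raise ValueError("current_dl outside configured ladder")
        if (self.rp2d is not None) and self.phase is not Phase.COMPLETE:
            raise ValueError("rp2d defined only once the design is complete")

    def enrolled_at(self, dl: int) -> int:
        return dict(self.per_dl_enrolled).get(dl, 0)

    def dlt_at(self, dl: int) -> int:
        return dict(self.per_dl_dlt).get(dl, 0)

    def key(self) -> tuple:
        """Hashable projection of the decision-relevant state (memoization)."""
        return (
            self.phase,
            self.current_dl,
            min(self.grade2plus_count_cycle1, 2),
            self.per_dl_enrolled,
            self.per_dl_dlt,
            self.rp2d,
        )


def _bump(pairs: tuple[tuple[int, int], ...], dl: int, by: int = 1):
    d = dict(pairs)
    d[dl] = d.get(dl, 0) + by
    return tuple(sorted(d.items()))


def next_decision(
    state: DesignState, outcome: CycleOutcome
) -> tuple[DoseDecision, DesignState]:
    """Process one newly enrolled patient's cycle-1 outcome.

    The outcome must be observed at the cohort's current enrollment level;
    a mismatch is a rule violation. Intra-patient dose changes in later
    cycles (DE_ESCALATE) never move the cohort's enrollment level.
    """
    if state.phase is Phase.COMPLETE:
        raise ValueError("design already complete")
    dl = outcome.dose_level
    if not (1 <= dl <= len(state.dose_levels)):
        raise ValueError(f"outcome references unconfigured dose level {dl}")
    if outcome.cycle == 1 and dl != state.current_dl:
        raise ValueError(
            f"rule violation: patient treated at DL{dl} while cohort is at "
            f"DL{state.current_dl}"
        )
    top = len(state.dose_levels)
    dlt = bool(outcome.dlt)
    new = state
    if outcome.cycle == 1:
        new = replace(
            new,
            per_dl_enrolled=_bump(new.per_dl_enrolled, dl),
            per_dl_dlt=_bump(new.per_dl_dlt, dl) if dlt else new.per_dl_dlt,
            n_enrolled=new.n_enrolled + 1,
            grade2plus_count_cycle1=new.grade2plus_count_cycle1
            + int(outcome.n_grade2plus_events),
        )

    if state.phase is Phase.ATD:
        decision, new = _atd_decision(new, outcome, dlt, dl, top)
    else:
        decision, new = _three_plus_three_decision(new, outcome, dlt, dl, top)

    new = replace(
        new,
        audit_log=new.audit_log
        + ((outcome.subject_id, decision.action.value, dl, decision.rationale),),
    )
    return decision, new


def _atd_decision(new, outcome, dlt, dl, top):
    if dlt and outcome.cycle == 1:
        decision = DoseDecision(
            Action.TRANSITION_TO_3P3, "first cycle-1 DLT mandates 3+3 transition"
        )
        new = replace(new, phase=Phase.THREE_PLUS_THREE, current_dl=dl)
        return _maybe_resolve_cohort(decision, new, dl, top)
    if dlt:
        return (
            DoseDecision(Action.DE_ESCALATE, "DLT after cycle 1: intra-patient de-escalation"),
            new,
        )
    if outcome.cycle == 1 and new.grade2plus_count_cycle1 >= 2:
        decision = DoseDecision(
            Action.TRANSITION_TO_3P3,
            "second grade>=2 occurrence in cycle 1 mandates 3+3 transition",
        )
        new = replace(new, phase=Phase.THREE_PLUS_THREE, current_dl=dl)
        return _maybe_resolve_cohort(decision, new, dl, top)
    if outcome.max_related_grade >= 2:
        return DoseDecision(Action.STAY, "tolerable grade 2: dose unchanged"), new
    if dl >= top:
        new = replace(new, phase=Phase.COMPLETE, rp2d=top)
        return (
            DoseDecision(
                Action.DECLARE_RP2D_CURRENT, "grade 0-1 at top level: top level is RP2D"
            ),
            new,
        )
    new = replace(new, current_dl=dl + 1)
    return DoseDecision(Action.ESCALATE, "grade 0-1 toxicity permits escalation"), new


def _declare_next_lower(new, dl):
    if dl <= 1:
        new = replace(new, phase=Phase.COMPLETE, rp2d=None)
        return (
            DoseDecision(
                Action.DECLARE_RP2D_NEXT_LOWER,
                ">1 DLT at the lowest level: no RP2D on this ladder",
            ),
            new,
        )
    new = replace(new, phase=Phase.COMPLETE, rp2d=dl - 1)
    return (
        DoseDecision(Action.DECLARE_RP2D_NEXT_LOWER, ">=2/3 or >1/6 DLTs"),
        new,
    )


def _maybe_resolve_cohort(decision, new, dl, top):
    # a transition can complete or resolve a cohort immediately (e.g. the
    # triggering DLT is already the second at this level)
    if new.dlt_at(dl) >= 2:
        return _declare_next_lower(new, dl)
    return decision, new


def _three_plus_three_decision(new, outcome, dlt, dl, top):
    if outcome.cycle != 1:
        if dlt:
            return (
                DoseDecision(
                    Action.DE_ESCALATE, "DLT after cycle 1: intra-patient de-escalation"
                ),
                new,
            )
        return DoseDecision(Action.CONTINUE, "later cycle, no cohort rule fires"), new
    n, d = new.enrolled_at(dl), new.dlt_at(dl)
    if d >= 2:
        return _declare_next_lower(new, dl)
    if n == 3 and d == 0 or n == 6 and d <= 1:
        if dl >= top:
            new = replace(new, phase=Phase.COMPLETE, rp2d=top)
            return (
                DoseDecision(
                    Action.DECLARE_RP2D_CURRENT,
                    "escalation past top level: top level is RP2D",
                ),
                new,
            )
        new = replace(new, current_dl=dl + 1)
        return (
            DoseDecision(Action.ESCALATE, f"{d}/{n} DLTs permit escalation"),
            new,
        )
    if n == 3 and d == 1:
        return DoseDecision(Action.EXPAND_TO_6, "1/3 DLTs: expand cohort to six"), new
    if dlt:
        return (
            DoseDecision(Action.DE_ESCALATE, "cycle-1 DLT: intra-patient de-escalation"),
            new,
        )
    return DoseDecision(Action.CONTINUE, "cohort incomplete"), new


# --- Monte-Carlo simulation and exact enumeration --------------------------


@dataclass(frozen=True)
class TrialResult:
    rp2d: int | None
    n_enrolled: int
    trace: tuple[tuple[str, str, int, str], ...]
    final_state: DesignState


def _outcome_for_category(subject: str, dl: int, category: str) -> CycleOutcome:
    """Map a sampled toxicity category to a canonical cycle-1 outcome."""
    if category == "dlt":
        return CycleOutcome(subject, 1, dl, max_related_grade=3)
    if category == "grade2":
        return CycleOutcome(subject, 1, dl, max_related_grade=2, tolerable_grade2=True)
    return CycleOutcome(subject, 1, dl, max_related_grade=0)


def _category_probs(true_tox, dl: int) -> dict[str, float]:
    p_dlt, p_g2 = true_tox[dl - 1]
    if not (0 <= p_dlt <= 1 and 0 <= p_g2 <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return {
        "dlt": p_dlt,
        "grade2": (1 - p_dlt) * p_g2,
        "ok": (1 - p_dlt) * (1 - p_g2),
    }


def simulate_trial(
    true_tox,
    dose_levels: tuple[DoseLevel, ...] = DEFAULT_DOSE_LEVELS,
    n_max: int = 30,
    seed: int = 0,
) -> TrialResult:
    """Run one trial: sample cycle-1 outcomes per patient and apply the rules.

    ``true_tox`` gives (p_dlt, p_grade2_tolerable) per dose level; a DLT
    preempts the grade-2 draw. Cohort decisions key on cycle 1, so one
    decision-driving outcome is sampled per patient.
    """
    if len(true_tox) != len(dose_levels):
        raise ValueError("true_tox must give one (p_dlt, p_grade2) pair per dose level")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = np.random.default_rng(seed)
    state = DesignState(dose_levels=dose_levels)
    while state.phase is not Phase.COMPLETE and state.n_enrolled < n_max:
        dl = state.current_dl
        probs = _category_probs(true_tox, dl)
        category = rng.choice(["dlt", "grade2", "ok"], p=[probs["dlt"], probs["grade2"], probs["ok"]])
        outcome = _outcome_for_category(f"sim-{state.n_enrolled + 1}", dl, str(category))
        _, state = next_decision(state, outcome)
    return TrialResult(state.rp2d, state.n_enrolled, state.audit_log, state)


def enumerate_rp2d_distribution(
    true_tox,
    dose_levels: tuple[DoseLevel, ...] = DEFAULT_DOSE_LEVELS,
    n_max: int = 30,
) -> dict[int | None, float]:
    """Exact RP2D distribution by enumerating the decision tree.

    Walks the same :func:`next_decision` state machine symbolically,
    branching over the three outcome categories per enrolled patient and
    summing path probabilities; memoized on the decision-relevant state
    projection. Serves as the independent oracle for
    :func:`simulate_trial`.
    """
    if len(true_tox) != len(dose_levels):
        raise ValueError("true_tox must give one (p_dlt, p_grade2) pair per dose level")
    cache: dict[tuple, dict[int | None, float]] = {}

    def walk(state: DesignState) -> dict[int | None, float]:
        if state.phase is Phase.COMPLETE or state.n_enrolled >= n_max:
            return {state.rp2d: 1.0}
        key = (state.key(), state.n_enrolled)
        if key in cache:
            return cache[key]
        dist: dict[int | None, float] = {}
        probs = _category_probs(true_tox, state.current_dl)
        for category, p in probs.items():
            if p == 0.0:
                continue
            outcome = _outcome_for_category("enum", state.current_dl, category)
            _, nxt = next_decision(state, outcome)
            # drop the audit log so memoization keys collapse across paths
            nxt = replace(nxt, audit_log=())
            for rp2d, q in walk(nxt).items():
                dist[rp2d] = dist.get(rp2d, 0.0) + p * q
        cache[key] = dist
        return dist

    return walk(DesignState(dose_levels=dose_levels))


def replay_history(
    outcomes,
    dose_levels: tuple[DoseLevel, ...] = DEFAULT_DOSE_LEVELS,
) -> tuple[DesignState, list[DoseDecision]]:
    """Replay a recorded sequence of cycle outcomes through the state machine.

    Raises on any rule violation (e.g. a patient enrolled at a level the
    rules do not allow). Returns the final state and the decision list.
    """
    state = DesignState(dose_levels=dose_levels)
    decisions = []
    for outcome in outcomes:
        decision, state = next_decision(state, outcome)
        decisions.append(decision)
        if state.phase is Phase.COMPLETE:
            break
    return state, decisions
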
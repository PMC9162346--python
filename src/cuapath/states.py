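"""Nine-state disease model for advanced prostate cancer on long-term ADT.

States HS1–HS3 are hormone-naive entry states (non-metastatic/node-only,
bone-metastatic, visceral-metastatic); HS4–HS7 are the corresponding
castration-resistant (CRPC) states, with HS6 for skeletal-related events
after bone metastasis; HS8 is prostate-cancer death and HS9 other-cause
death.  25 transitions are allowed: 11 among the alive states plus one from
each alive state to each dead state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HealthState",
    "NAIVE_STATES",
    "CRPC_STATES",
    "DEAD_STATES",
    "TransitionMatrix",
    "build_transition_matrix",
    "RawEvent",
    "EventHistory",
    "classify_events",
    "tabulate_transitions",
    "ClassificationError",
    "read_histories",
    "write_histories",
]


class HealthState(IntEnum):
    """Health states HS1–HS9."""

    HS1 = 1  # naive, M0 or node-only (M0 subgroup)
    HS2 = 2  # naive, bone metastases
    HS3 = 3  # naive, visceral metastases
    HS4 = 4  # CRPC, M0 or node-only
    HS5 = 5  # CRPC, bone metastases
    HS6 = 6  # CRPC, bone metastases with SRE
    HS7 = 7  # CRPC, visceral metastases
    HS8 = 8  # prostate-cancer death
    HS9 = 9  # other-cause death

    @property
    def label(self) -> str:
        return _LABELS[self]

    @property
    def group(self) -> str:
        if self in NAIVE_STATES:
            return "naive"
        if self in CRPC_STATES:
            return "crpc"
        return "dead"

    @property
    def is_dead(self) -> bool:
        return self in DEAD_STATES


_LABELS = {
    HealthState.HS1: "Naive M0/M1a",
    HealthState.HS2: "Naive M1b (bone)",
    HealthState.HS3: "Naive M1c (visceral)",
    HealthState.HS4: "CRPC M0/M1a",
    HealthState.HS5: "CRPC M1b (bone)",
    HealthState.HS6: "CRPC SRE",
    HealthState.HS7: "CRPC M1c (visceral)",
    HealthState.HS8: "Prostate cancer death",
    HealthState.HS9: "Other cause death",
}

NAIVE_STATES = frozenset({HealthState.HS1, HealthState.HS2, HealthState.HS3})
CRPC_STATES = frozenset(
    {HealthState.HS4, HealthState.HS5, HealthState.HS6, HealthState.HS7}
)
DEAD_STATES = frozenset({HealthState.HS8, HealthState.HS9})

# 11 allowed transitions among alive states
_ALIVE_TRANSITIONS = (
    (HealthState.HS1, HealthState.HS4),
    (HealthState.HS1, HealthState.HS5),
    (HealthState.HS1, HealthState.HS7),
    (HealthState.HS2, HealthState.HS5),
    (HealthState.HS2, HealthState.HS7),
    (HealthState.HS3, HealthState.HS7),
    (HealthState.HS4, HealthState.HS5),
    (HealthState.HS4, HealthState.HS7),
    (HealthState.HS5, HealthState.HS6),
    (HealthState.HS5, HealthState.HS7),
    (HealthState.HS6, HealthState.HS7),
)


@dataclass(frozen=True)
class TransitionMatrix:
    """The fixed set of allowed (from, to) state pairs."""

    allowed: frozenset[tuple[HealthState, HealthState]]

    def is_allowed(self, src: HealthState, dst: HealthState) -> bool:
        return (src, dst) in self.allowed

    def exits(self, src: HealthState) -> tuple[HealthState, ...]:
        """Destinations reachable in one step from ``src``, in state order."""
        return tuple(
            sorted(d for s, d in self.allowed if s == src)
        )

    def __len__(self) -> int:
        return len(self.allowed)


def build_transition_matrix() -> TransitionMatrix:
    """Return the 25-transition structure (11 alive-to-alive + 14 to death)."""
    allowed = set(_ALIVE_TRANSITIONS)
    for src in sorted(NAIVE_STATES | CRPC_STATES):
        allowed.add((src, HealthState.HS8))
        allowed.add((src, HealthState.HS9))
    return TransitionMatrix(allowed=frozenset(allowed))


TRANSITIONS = build_transition_matrix()


class ClassificationError(ValueError):
    """A dated clinical event implies a transition outside the allowed set."""


# Priority for same-day events: metastasis < SRE < failure < death, so the
# resulting state sequence is always a chain of allowed transitions.
_EVENT_PRIORITY = {"metastasis": 0, "sre": 1, "failure": 2, "death": 3}


@dataclass(frozen=True)
class RawEvent:
    """A dated, typed clinical event.

    kind: 'metastasis' (detail = 'bone' | 'visceral' | 'node'),
    'sre', 'failure' (progression to CRPC), or 'death'
    (detail = 'pc' | 'other').
    """

    day: float
    kind: str
    detail: str = ""


@dataclass
class EventHistory:
    """Ordered health-state occupancy for one patient, entry times in days."""

    patient_id: str
    records: list[tuple[HealthState, float]]
    censor_day: float
    censored: bool

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("EventHistory requires at least the baseline state")
        if self.records[0][0] not in NAIVE_STATES:
            raise ValueError(
                f"first state must be naive, got {self.records[0][0].name}"
            )
        days = [d for _, d in self.records]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("entry days must be strictly increasing")
        for (s, _), (t, _) in zip(self.records, self.records[1:]):
            if not TRANSITIONS.is_allowed(s, t):
                raise ClassificationError(
                    f"patient {self.patient_id}: disallowed transition "
                    f"{s.name}->{t.name}"
                )
        dead = [s for s, _ in self.records if s.is_dead]
        if len(dead) > 1 or (dead and self.records[-1][0] not in DEAD_STATES):
            raise ValueError("at most one dead state, and it must be terminal")

    @property
    def states(self) -> list[HealthState]:
        return [s for s, _ in self.records]

    @property
    def death_day(self) -> float | None:
        s, d = self.records[-1]
        return d if s.is_dead else None

    @property
    def end_day(self) -> float:
        """Death day if dead, else censoring day."""
        dd = self.death_day
        return dd if dd is not None else self.censor_day

    def state_at(self, day: float) -> HealthState:
        """State occupied at ``day`` (entry days inclusive)."""
        current = self.records[0][0]
        for s, d in self.records:
            if d <= day:
                current = s
            else:
                break
        return current

    def intervals(self, horizon_day: float | None = None) -> list[tuple[HealthState, float, float]]:
        """Half-open occupancy intervals (state, start, stop) up to horizon/end."""
        stop_at = self.end_day if horizon_day is None else horizon_day
        out = []
        for i, (s, d) in enumerate(self.records):
            if s.is_dead:
                break
            nxt = (
                self.records[i + 1][1]
                if i + 1 < len(self.records)
                else self.end_day
            )
            lo, hi = d, min(nxt, stop_at)
            if hi > lo:
                out.append((s, lo, hi))
        return out


def _destination(
    current: HealthState, ev: RawEvent
) -> HealthState | None:
    """Destination implied by ``ev`` from ``current``; None means no move."""
    k, detail = ev.kind, ev.detail
    if k == "death":
        return HealthState.HS8 if detail == "pc" else HealthState.HS9
    if current is HealthState.HS1:
        if k == "metastasis":
            # metastatic progression in a naive patient is treatment failure
            if detail == "bone":
                return HealthState.HS5
            if detail == "visceral":
                return HealthState.HS7
            return None  # node-only: remains M0/M1a
        if k == "sre":
            # SRE without metastasis counts as treatment failure -> HS4 not HS6
            return HealthState.HS4
        if k == "failure":
            return HealthState.HS4
    elif current is HealthState.HS2:
        if k == "metastasis" and detail == "visceral":
            return HealthState.HS7
        if k in ("failure", "sre"):
            # SRE in a bone-metastatic naive patient marks failure; the SRE
            # state itself is post-CRPC, so land in HS5 (next SRE moves to HS6)
            return HealthState.HS5
    elif current is HealthState.HS3:
        if k == "failure":
            return HealthState.HS7
    elif current is HealthState.HS4:
        if k == "metastasis":
            if detail == "bone":
                return HealthState.HS5
            if detail == "visceral":
                return HealthState.HS7
    elif current is HealthState.HS5:
        if k == "sre":
            return HealthState.HS6
        if k == "metastasis" and detail == "visceral":
            return HealthState.HS7
    elif current is HealthState.HS6:
        if k == "metastasis" and detail == "visceral":
            return HealthState.HS7
    return None


def classify_events(
    raw_events: Sequence[RawEvent],
    baseline_state: HealthState,
    censor_day: float,
    patient_id: str = "",
) -> EventHistory:
    """Convert dated clinical events into a health-state occupancy history.

    Same-day ties are broken metastasis < SRE < failure < death.  Events that
    imply no state change (e.g. a repeat SRE in HS6) are ignored; an event
    implying a disallowed move raises :class:`ClassificationError`.
    """
    if baseline_state not in NAIVE_STATES:
        raise ClassificationError(
            f"patient {patient_id}: baseline state {baseline_state.name} "
            "is not a naive state"
        )
    events = sorted(raw_events, key=lambda e: (e.day, _EVENT_PRIORITY[e.kind]))
    records: list[tuple[HealthState, float]] = [(baseline_state, 0.0)]
    current = baseline_state
    for ev in events:
        if current.is_dead:
            break
        dst = _destination(current, ev)
        if dst is None or dst == current:
            continue
        if not TRANSITIONS.is_allowed(current, dst):
            raise ClassificationError(
                f"patient {patient_id}: event {ev.kind}@{ev.day} implies "
                f"disallowed transition {current.name}->{dst.name}"
            )
        day = float(ev.day)
        if day <= records[-1][1]:
            day = records[-1][1] + 0.5  # same-day chain: keep strict ordering
        records.append((dst, day))
        current = dst
    censored = not current.is_dead
    end = records[-1][1] if current.is_dead else float(censor_day)
    return EventHistory(
        patient_id=patient_id, records=records, censor_day=end, censored=censored
    )


def tabulate_transitions(histories: Iterable[EventHistory]) -> pd.DataFrame:
    """9x9 count matrix of used transitions across histories.

    Rows are source states, columns destinations; structurally impossible
    cells are 0 here (writers may render them as "np").
    """
    names = [s.name for s in HealthState]
    counts = pd.DataFrame(
        np.zeros((9, 9), dtype=int), index=names, columns=names
    )
    for h in histories:
        for (s, _), (t, _) in zip(h.records, h.records[1:]):
            counts.loc[s.name, t.name] += 1
    return counts


def write_transition_counts(counts: pd.DataFrame, path) -> None:
    """Write the count matrix with 'np' markers in impossible cells."""
    out = counts.astype(object).copy()
    for s in HealthState:
        for t in HealthState:
            if not TRANSITIONS.is_allowed(s, t):
                out.loc[s.name, t.name] = "np"
    out.to_csv(path, index_label="from")


def write_histories(histories: Iterable[EventHistory], path) -> None:
    rows = []
    for h in histories:
        for s, d in h.records:
            rows.append(
                dict(
                    patient_id=h.patient_id,
                    state=s.name,
                    entry_day=d,
                    censor_day=h.censor_day,
                    censored=int(h.censored),
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_histories(path) -> list[EventHistory]:
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("entry_day")
        records = [
            (HealthState[r.state], float(r.entry_day)) for r in grp.itertuples()
        ]
        out.append(
            EventHistory(
                patient_id=str(pid),
                records=records,
                censor_day=float(grp.censor_day.iloc[0]),
                censored=bool(grp.censored.iloc[0]),
            )
        )
    return out
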
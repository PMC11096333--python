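"""Trial-schedule construction for the melody omission design.

Four melodies per familiarity condition are each presented a fixed number of
times; every presentation contains a known number of target notes per pitch
class (E/F/A/C), and a fixed fraction of target events is replaced by
omissions.  Although omission is described probabilistically, the reported
trial totals are exact, so assignment is balanced: within each
(condition, note) cell exactly ``rate * n_events`` events are omitted
(rounded when the cell size does not divide evenly, and flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

NOTES = ("E", "F", "A", "C")
CONDITIONS = ("familiar", "unfamiliar")


class DesignError(ValueError):
    """Invalid design parameters."""


@dataclass(frozen=True)
class MelodySpec:
    """One melody: identity, condition, and target-note counts per presentation."""

    melody_id: str
    familiarity: str
    note_counts: dict[str, int]
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.familiarity not in CONDITIONS:
            raise DesignError(f"unknown familiarity {self.familiarity!r}")
        bad = {n: c for n, c in self.note_counts.items()
               if n not in NOTES or int(c) != c or c < 0}
        if bad:
            raise DesignError(f"invalid note counts: {bad}")
        if not any(c >= 1 for c in self.note_counts.values()):
            raise DesignError(f"melody {self.melody_id!r} has no target notes")


@dataclass(frozen=True)
class TrialRecord:
    condition: str
    melody_id: str
    note: str
    omitted: bool
    presentation_index: int


@dataclass
class ExperimentSchedule:
    """Ordered target-event records plus the parameters that generated them."""

    trials: list[TrialRecord]
    presentations_per_melody: int
    seed: int
    omission_rate: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def omission_count(self, condition: str) -> int:
        return sum(t.omitted for t in self.trials if t.condition == condition)

    def scheduled_counts(self, condition: str) -> dict[str, int]:
        """Omission-trial count per note for one condition."""
        out = {n: 0 for n in NOTES}
        for t in self.trials:
            if t.condition == condition and t.omitted:
                out[t.note] += 1
        return {n: c for n, c in out.items() if c > 0}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.condition, t.melody_id, t.note, t.omitted, t.presentation_index)
             for t in self.trials],
            columns=["condition", "melody_id", "note", "omitted",
                     "presentation_index"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, presentations_per_melody: int = 0,
                 seed: int = 0) -> "ExperimentSchedule":
        df = pd.read_csv(path)
        trials = [
            TrialRecord(r.condition, r.melody_id, r.note, bool(r.omitted),
                        int(r.presentation_index))
            for r in df.itertuples()
        ]
        return cls(trials, presentations_per_melody, seed)


def default_melody_specs(condition: str = "familiar") -> list[MelodySpec]:
    """The packaged default melody table (per-note condition totals 6/6/6/7).

    Unfamiliar melodies are shuffled variants of the familiar ones and reuse
    the same target-note counts.
    """
    if condition not in CONDITIONS:
        raise DesignError(f"unknown condition {condition!r}")
    with resources.files("ospipe.presets").joinpath("melodies.yaml").open() as fh:
        table = yaml.safe_load(fh)
    specs = []
    for entry in table["melodies"]:
        mid = entry["melody_id"]
        if condition == "unfamiliar":
            mid = f"shuffled_{mid}"
        specs.append(MelodySpec(mid, condition, dict(entry["note_counts"]),
                                float(entry.get("duration_s", 0.0))))
    return specs


def default_specs_both_conditions() -> list[MelodySpec]:
    return default_melody_specs("familiar") + default_melody_specs("unfamiliar")


def build_schedule(
    melody_specs: list[MelodySpec],
    presentations_per_melody: int,
    omission_rate: float = 0.5,
    seed: int = 0,
) -> ExperimentSchedule:
    """Enumerate all target events and assign omissions with exact balancing.

    Within each (condition, note) cell exactly ``round(rate * n)`` events are
    omitted, chosen at random; the full trial order is then shuffled.
    Deterministic given *seed*.
    """
    if not melody_specs:
        raise DesignError("melody_specs is empty")
    if not 0.0 <= omission_rate <= 1.0:
        raise DesignError(f"omission_rate {omission_rate} outside [0, 1]")
    if presentations_per_melody < 1:
        raise DesignError("presentations_per_melody must be >= 1")

    rng = np.random.default_rng(seed)
    events: list[TrialRecord] = []
    cells: dict[tuple[str, str], list[int]] = {}
    for spec in melody_specs:
        for pres in range(presentations_per_melody):
            for note, count in spec.note_counts.items():
                for _ in range(count):
                    cells.setdefault((spec.familiarity, note), []).append(len(events))
                    events.append(TrialRecord(spec.familiarity, spec.melody_id,
                                              note, False, pres))

    unbalanced: list[tuple[str, str]] = []
    for (cond, note), idx in sorted(cells.items()):
        exact = omission_rate * len(idx)
        k = int(round(exact))
        if abs(exact - k) > 1e-9:
            unbalanced.append((cond, note))
        chosen = rng.choice(len(idx), size=k, replace=False)
        for j in chosen:
            e = events[idx[j]]
            events[idx[j]] = TrialRecord(e.condition, e.melody_id, e.note, True,
                                         e.presentation_index)

    order = rng.permutation(len(events))
    trials = [events[i] for i in order]
    meta = {"balanced_exact": not unbalanced, "unbalanced_cells": unbalanced}
    return ExperimentSchedule(trials, presentations_per_melody, seed,
                              omission_rate, meta)


def per_cell_counts(schedule: ExperimentSchedule) -> pd.DataFrame:
    """Trial counts per (condition, note, omitted) cell."""
    if not schedule.trials:
        raise DesignError("schedule is empty")
    df = schedule.to_dataframe()
    out = (df.groupby(["condition", "note", "omitted"], sort=True)
             .size().rename("count").reset_index())
    return out
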
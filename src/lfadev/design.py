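"""Factorial experiment design for lateral flow assay development.

An LFA development campaign varies capture/detection antibodies, sample
matrices and reagent concentrations.  This module describes such a factorial
space (:class:`DesignSpec`), enumerates every assay permutation into concrete
:class:`Condition` objects (one per strip), and partitions the strips into
robot runs constrained by the deck's strip-holder capacity
(:class:`DeckLayout`, :func:`split_into_runs`).

Enumeration is a pure function: a given design always produces the same
conditions in the same order with the same human-readable ``condition_id``
strings, so downstream worklists are diffable across re-runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import groupby, product
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignSpec",
    "Condition",
    "DeckLayout",
    "SlotAssignment",
    "RunPlan",
    "LevelExclusion",
    "AllZeroExclusion",
    "enumerate_conditions",
    "split_into_runs",
    "conditions_to_frame",
    "runs_to_frame",
]

FACTOR_ROLES = (
    "capture_antibody",
    "detection_antibody",
    "sample_matrix",
    "concentration",
    "other",
)

Level = str | int | float


def format_level(level: Level) -> str:
    """Render a factor level for use in a condition id (``60`` -> ``"60"``)."""
    if isinstance(level, bool):  # bool is an int subclass; refuse silently odd ids
        return str(level)
    if isinstance(level, (int, float)):
        return format(level, "g")
    return str(level)


@dataclass(frozen=True)
class FactorSpec:
    """One experimental variable and its levels.

    Numeric levels are interpreted as concentrations in µg/mL when the role
    is ``concentration``.
    """

    name: str
    levels: tuple[Level, ...]
    role: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if not self.name:
            raise ValueError("factor name must be non-empty")
        if self.role not in FACTOR_ROLES:
            raise ValueError(f"unknown factor role {self.role!r}")
        if not self.levels:
            raise ValueError(f"factor {self.name!r} has no levels")
        labels = [format_level(v) for v in self.levels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"factor {self.name!r} has duplicate levels")
        for v in self.levels:
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if not math.isfinite(v) or v < 0:
                    raise ValueError(
                        f"factor {self.name!r}: numeric levels must be finite and >= 0"
                    )


@dataclass(frozen=True)
class LevelExclusion:
    """Exclude every assignment matching all listed factor=level tests."""

    where: tuple[tuple[str, Level], ...]

    def matches(self, assignment: Mapping[str, Level]) -> bool:
        return all(assignment.get(f) == v for f, v in self.where)


@dataclass(frozen=True)
class AllZeroExclusion:
    """Exclude assignments where every named (concentration) factor is zero.

    This is the rule that turns a 4 x 4 x 4 concentration grid into 63
    usable mixtures: the all-diluent point carries no antibody and is not a
    meaningful strip.
    """

    factors: tuple[str, ...]

    def matches(self, assignment: Mapping[str, Level]) -> bool:
        return all(assignment.get(f) == 0 for f in self.factors)


Exclusion = LevelExclusion | AllZeroExclusion


@dataclass(frozen=True)
class DesignSpec:
    """A full factorial design with replicates, exclusions and controls."""

    factors: tuple[FactorSpec, ...]
    replicates: int = 1
    exclusions: tuple[Exclusion, ...] = ()
    controls: Mapping[str, Mapping[str, Level]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "exclusions", tuple(self.exclusions))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        if not self.factors:
            raise ValueError("design requires at least one factor")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def n_grid_points(self) -> int:
        n = 1
        for f in self.factors:
            n *= len(f.levels)
        return n


@dataclass(frozen=True)
class Condition:
    """One strip's worth of settings: a point of the design, one replicate."""

    condition_id: str
    assignment: tuple[tuple[str, Level], ...]
    replicate_index: int

    def level(self, factor: str) -> Level:
        for f, v in self.assignment:
            if f == factor:
                return v
        raise KeyError(factor)

    @property
    def assignment_map(self) -> dict[str, Level]:
        return dict(self.assignment)

    @property
    def assignment_id(self) -> str:
        """Condition id without the replicate suffix (shared by replicates)."""
        return ";".join(f"{f}={format_level(v)}" for f, v in self.assignment)


def condition_id_for(assignment: Sequence[tuple[str, Level]], replicate: int) -> str:
    head = ";".join(f"{f}={format_level(v)}" for f, v in assignment)
    return f"{head};rep={replicate}"


def enumerate_conditions(design: DesignSpec) -> list[Condition]:
    """Enumerate every condition of a design, replicates included.

    The order is the lexicographic product over factors in declaration order
    and levels in declared order, with replicate index innermost.  Excluded
    assignments are dropped before replicate expansion.

    Raises
    ------
    ValueError
        If the exclusions eliminate every assignment
        (``"design eliminates all conditions"``).
    """
    names = design.factor_names
    out: list[Condition] = []
    for combo in product(*(f.levels for f in design.factors)):
        assignment = tuple(zip(names, combo))
        amap = dict(assignment)
        if any(e.matches(amap) for e in design.exclusions):
            continue
        for rep in range(1, design.replicates + 1):
            out.append(
                Condition(
                    condition_id=condition_id_for(assignment, rep),
                    assignment=assignment,
                    replicate_index=rep,
                )
            )
    if not out:
        raise ValueError("design eliminates all conditions")
    return out


@dataclass(frozen=True)
class DeckLayout:
    """Strip holders on the robot deck and (optionally) their image geometry.

    ``slot_coords`` maps ``(holder_id, slot_index)`` to a position: either a
    physical deck coordinate or a pixel-space region of a whole-deck
    photograph, depending on downstream use.
    """

    holders: tuple[tuple[str, int], ...]
    wells_per_strip: int = 2
    slot_coords: Mapping[tuple[str, int], tuple] = field(default_factory=dict)
    cassette_holders: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "holders", tuple(self.holders))
        if self.wells_per_strip < 1:
            raise ValueError("wells_per_strip must be >= 1")
        ids = [h for h, _ in self.holders]
        if len(set(ids)) != len(ids):
            raise ValueError("holder ids must be unique")
        for holder_id, cap in self.holders:
            limit = 96 if holder_id in self.cassette_holders else 16
            if not 1 <= cap <= limit:
                raise ValueError(
                    f"holder {holder_id!r}: capacity {cap} outside [1, {limit}]"
                )
        if self.run_capacity < 1:
            raise ValueError("deck has no strip capacity")

    @property
    def run_capacity(self) -> int:
        return sum(cap for _, cap in self.holders)

    def slots(self) -> list[tuple[str, int]]:
        """All (holder_id, slot_index) pairs in fill order."""
        return [(h, i) for h, cap in self.holders for i in range(cap)]


@dataclass(frozen=True)
class SlotAssignment:
    condition: Condition
    holder_id: str
    slot_index: int


@dataclass(frozen=True)
class RunPlan:
    run_index: int
    assignments: tuple[SlotAssignment, ...]

    @property
    def conditions(self) -> list[Condition]:
        return [a.condition for a in self.assignments]

    def __len__(self) -> int:
        return len(self.assignments)


def split_into_runs(conditions: Sequence[Condition], deck: DeckLayout) -> list[RunPlan]:
    """Partition conditions into runs of at most ``deck.run_capacity`` strips.

    The number of runs is always ``ceil(n / capacity)``.  Packing is
    sequential in enumeration order, filling holders slot by slot; when a
    replicate group of the same assignment would straddle a run boundary,
    the run is closed early if doing so does not increase the total number
    of runs (best-effort replicate adjacency).
    """
    conditions = list(conditions)
    if not conditions:
        return []
    cap = deck.run_capacity
    n = len(conditions)
    n_runs = math.ceil(n / cap)

    runs: list[list[Condition]] = [[]]
    placed = 0
    for _, grp in groupby(conditions, key=lambda c: c.assignment):
        group = list(grp)
        g = len(group)
        room = cap - len(runs[-1])
        remaining = n - placed
        can_close_early = (
            0 < room < g <= cap
            and remaining <= (n_runs - len(runs)) * cap
        )
        if can_close_early:
            runs.append([])
        for c in group:
            if len(runs[-1]) == cap:
                runs.append([])
            runs[-1].append(c)
        placed += g

    slots = deck.slots()
    plans = []
    for run_index, run_conditions in enumerate(runs):
        assignments = tuple(
            SlotAssignment(condition=c, holder_id=h, slot_index=s)
            for c, (h, s) in zip(run_conditions, slots)
        )
        plans.append(RunPlan(run_index=run_index, assignments=assignments))
    assert len(plans) == n_runs
    return plans


def conditions_to_frame(conditions: Sequence[Condition]) -> pd.DataFrame:
    """Flat table: one row per condition, one column per factor."""
    rows = []
    for c in conditions:
        row = {"condition_id": c.condition_id}
        row.update(c.assignment_map)
        row["replicate"] = c.replicate_index
        rows.append(row)
    return pd.DataFrame(rows)


def runs_to_frame(runs: Sequence[RunPlan]) -> pd.DataFrame:
    """Condition table augmented with run/holder/slot placement."""
    rows = []
    for run in runs:
        for a in run.assignments:
            row = {"condition_id": a.condition.condition_id}
            row.update(a.condition.assignment_map)
            row["replicate"] = a.condition.replicate_index
            row["run_index"] = run.run_index
            row["holder_id"] = a.holder_id
            row["slot_index"] = a.slot_index
            rows.append(row)
    return pd.DataFrame(rows)
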
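"""Timed pipetting-worklist generation and validation.

A run is a set of strips (conditions) on the deck plus a timed protocol
(reagent additions, sample addition, imaging).  This module expands the
protocol over all strips of a run, groups compatible transfers into
multichannel batches, schedules the batches on the single pipetting gantry
so that inter-step delays and imaging deadlines are met, and emits the
result as a plain CSV worklist.  A discrete-event simulator replays a
worklist against the protocol and reports every timing, capacity or
stock-balance violation, serving as an independent feasibility check.

Scheduling model
----------------
* All times are integer seconds; time zero is the start of the first batch.
* The gantry executes one batch at a time; a batch occupies it for the
  step's per-batch duration.
* For every strip, step *j* must start at least ``min_delay_after_previous``
  seconds after step *j-1* started (start-to-start delays).
* Imaging must happen ``target_time_after_sample`` seconds after that
  strip's sample dispense, within ``imaging_tolerance_s``.
* Batches are chosen greedily: a ready liquid batch runs if doing so cannot
  push any known imaging obligation past its deadline; otherwise the most
  urgent imaging batch runs at (or as soon after as possible) its target
  time.  Ties break by batch id, which follows condition order, so the
  schedule is deterministic.
"""

from __future__ import annotations

import csv
import hashlib
import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .design import DeckLayout, RunPlan, format_level
from .mixplan import DILUENT_ID, MixRecipe

__all__ = [
    "ProtocolStep",
    "Protocol",
    "RobotConfig",
    "Transfer",
    "Batch",
    "Worklist",
    "Violation",
    "FeasibilityReport",
    "InfeasibleSchedule",
    "expand_protocol",
    "batch_transfers",
    "schedule_run",
    "build_worklist",
    "simulate_worklist",
    "write_worklist_csv",
    "read_worklist_csv",
    "WORKLIST_COLUMNS",
]

ACTIONS = ("dispense_reagent", "dispense_sample", "image")

#: Column order of the worklist CSV dialect.
WORKLIST_COLUMNS = (
    "run",
    "batch",
    "channel",
    "action",
    "source_labware",
    "source_pos",
    "dest_holder",
    "dest_slot",
    "dest_well",
    "volume_ul",
    "liquid_class",
    "scheduled_start_s",
    "condition_id",
)

PREP_PREFIX = "prep:"


class InfeasibleSchedule(ValueError):
    """Imaging deadlines cannot be met; carries a suggested smaller run size."""

    def __init__(self, message: str, suggested_run_size: int):
        super().__init__(message)
        self.suggested_run_size = suggested_run_size


@dataclass(frozen=True)
class ProtocolStep:
    """One step of the assay protocol, applied to every strip of a run."""

    step_index: int
    action: str
    reagent_ref: str | None = None
    volume: float = 0.0
    destination: str = "sample_port"
    min_delay_after_previous: int = 0
    target_time_after_sample: int | None = None
    liquid_class: str = "default"
    duration: int = 10

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.volume < 0:
            raise ValueError("volume must be >= 0")
        if self.min_delay_after_previous < 0:
            raise ValueError("delay must be >= 0")
        if self.action == "image" and self.target_time_after_sample is None:
            raise ValueError("image steps require target_time_after_sample")
        if self.duration < 1:
            raise ValueError("duration must be >= 1 s")


@dataclass(frozen=True)
class Protocol:
    name: str
    steps: tuple[ProtocolStep, ...]
    imaging_tolerance_s: int = 60

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        idx = [s.step_index for s in self.steps]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("step_index values must be unique and increasing")
        n_sample = sum(1 for s in self.steps if s.action == "dispense_sample")
        n_image = sum(1 for s in self.steps if s.action == "image")
        if n_image and n_sample != 1:
            raise ValueError("imaging requires exactly one dispense_sample step")

    @property
    def sample_step_index(self) -> int | None:
        for s in self.steps:
            if s.action == "dispense_sample":
                return s.step_index
        return None

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.steps:
            h.update(repr(s).encode())
        h.update(str(self.imaging_tolerance_s).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class RobotConfig:
    """Timing/capacity parameters of the liquid handler.

    The per-batch durations are configuration placeholders covering the
    aspirate/dispense/tip-handling cycle, which is collapsed into a single
    number per batch.
    """

    n_channels: int = 8
    prep_duration_s: int = 10
    prepare_on_deck: bool = True

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass(eq=True)
class Transfer:
    """One pipetting transfer or imaging event.

    ``source`` is ``(labware_id, position)`` and is ``None`` for imaging
    events; ``destination`` is ``(holder_id, slot_index, well)``.
    Scheduling fields (``scheduled_start``, ``batch_id``, ``channel``) are
    filled in by :func:`batch_transfers` and :func:`schedule_run`.
    """

    run_index: int
    condition_id: str
    action: str
    source: tuple[str, str] | None
    destination: tuple[str, int, str]
    volume: float | None
    liquid_class: str
    step_index: int = field(default=-1, compare=False)
    earliest_start: int = field(default=0, compare=False)
    scheduled_start: int | None = None
    batch_id: int | None = None
    channel: int | None = None

    @property
    def is_image(self) -> bool:
        return self.action == "image"

    @property
    def is_prep(self) -> bool:
        return self.condition_id.startswith(PREP_PREFIX)


@dataclass
class Batch:
    batch_id: int
    transfers: list[Transfer]
    duration: int

    @property
    def action(self) -> str:
        return self.transfers[0].action

    @property
    def step_index(self) -> int:
        return self.transfers[0].step_index

    @property
    def start(self) -> int | None:
        return self.transfers[0].scheduled_start


@dataclass
class Worklist:
    """Ordered, timed, channel-batched events for one run."""

    run_index: int
    rows: list[Transfer]
    metadata: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.rows)

    def imaging_events(self) -> list[Transfer]:
        return [t for t in self.rows if t.is_image]


# ---------------------------------------------------------------------------
# expansion


def _resolve_ref(template: str, condition) -> str:
    fields = {f: format_level(v) for f, v in condition.assignment}
    fields["condition_id"] = condition.condition_id
    try:
        return template.format(**fields)
    except KeyError as exc:
        raise ValueError(
            f"condition {condition.condition_id!r}: reagent template "
            f"{template!r} references unknown factor {exc}"
        ) from None


def expand_protocol(
    run: RunPlan,
    protocol: Protocol,
    sources: Mapping[str, tuple[str, str]] | None = None,
    recipes: Mapping[str, MixRecipe] | None = None,
    prepare_on_deck: bool = True,
) -> list[Transfer]:
    """Expand a protocol over every strip of a run.

    Each (condition, step) pair yields exactly one transfer or imaging
    event.  A step's ``reagent_ref`` is a template formatted with the
    condition's factor levels (``"mix_{capture}"``); the formatted name must
    resolve to a stock in ``sources`` or a mixture in ``recipes``.  Mixture
    preparation transfers (from stocks into a mixture tube) are emitted
    before all strip transfers when ``prepare_on_deck`` is true; otherwise
    mixtures are assumed pre-made off-deck.

    The expansion order is step-major (step 1 for all strips, then step 2,
    ...), which lets :func:`batch_transfers` form full multichannel batches.
    """
    sources = dict(sources or {})
    recipes = dict(recipes or {})
    used_recipes: dict[str, int] = {}  # target_id -> mixture tube slot
    strip_transfers: list[Transfer] = []

    for step in protocol.steps:
        for a in run.assignments:
            cond = a.condition
            dest = (a.holder_id, a.slot_index, step.destination)
            if step.action == "image":
                strip_transfers.append(
                    Transfer(
                        run_index=run.run_index,
                        condition_id=cond.condition_id,
                        action="image",
                        source=None,
                        destination=(a.holder_id, a.slot_index, ""),
                        volume=None,
                        liquid_class="",
                        step_index=step.step_index,
                    )
                )
                continue
            ref = _resolve_ref(step.reagent_ref or "", cond)
            if ref in recipes:
                if ref not in used_recipes:
                    used_recipes[ref] = len(used_recipes)
                source = ("mixtures", ref)
            elif ref in sources:
                source = sources[ref]
            else:
                raise ValueError(
                    f"condition {cond.condition_id!r}, step {step.step_index}: "
                    f"unresolvable reagent {ref!r}"
                )
            strip_transfers.append(
                Transfer(
                    run_index=run.run_index,
                    condition_id=cond.condition_id,
                    action=step.action,
                    source=source,
                    destination=dest,
                    volume=step.volume,
                    liquid_class=step.liquid_class,
                    step_index=step.step_index,
                )
            )

    prep: list[Transfer] = []
    if prepare_on_deck:
        for ref, tube_slot in used_recipes.items():
            recipe = recipes[ref]
            moves = list(recipe.transfers)
            if recipe.diluent_volume > 0:
                moves.append((DILUENT_ID, recipe.diluent_volume))
            for stock_id, vol in moves:
                if vol <= 0:
                    continue
                prep.append(
                    Transfer(
                        run_index=run.run_index,
                        condition_id=f"{PREP_PREFIX}{ref}",
                        action="dispense_reagent",
                        source=("stocks", stock_id),
                        destination=("mixtures", tube_slot, "tube"),
                        volume=vol,
                        liquid_class="prep",
                        step_index=-1,
                    )
                )
    return prep + strip_transfers


# ---------------------------------------------------------------------------
# batching


def _batch_key(t: Transfer):
    if t.is_image:
        return (t.step_index, "image")
    return (t.step_index, t.action, t.source[0], t.volume, t.liquid_class)


def batch_transfers(
    transfers: Sequence[Transfer], n_channels: int = 8
) -> list[Batch]:
    """Group consecutive compatible transfers into multichannel batches.

    Transfers batch together only when they share step, action, source
    labware, volume and liquid class; batches hold at most ``n_channels``
    transfers.  Only consecutive transfers are merged, which preserves
    per-strip step order.  Channels are assigned 1..n in batch order.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    batches: list[Batch] = []
    current: list[Transfer] = []
    current_key = None
    for t in transfers:
        key = _batch_key(t)
        if current and key == current_key and len(current) < n_channels:
            current.append(t)
        else:
            if current:
                batches.append(Batch(len(batches), current, duration=0))
            current = [t]
            current_key = key
    if current:
        batches.append(Batch(len(batches), current, duration=0))
    for b in batches:
        for ch, t in enumerate(b.transfers, start=1):
            t.batch_id = b.batch_id
            t.channel = ch
    return batches


# ---------------------------------------------------------------------------
# scheduling


def _step_lookup(protocol: Protocol) -> dict[int, ProtocolStep]:
    return {s.step_index: s for s in protocol.steps}


def schedule_run(
    transfers: Sequence[Transfer],
    protocol: Protocol,
    config: RobotConfig | None = None,
    run_index: int = 0,
    deck: DeckLayout | None = None,
) -> Worklist:
    """Schedule expanded transfers into a feasible, deterministic worklist.

    Raises :class:`InfeasibleSchedule` when an imaging deadline cannot be
    met on the single gantry, proposing a smaller run size.
    """
    config = config or RobotConfig()
    steps = _step_lookup(protocol)
    n_strips = len({t.condition_id for t in transfers if not t.is_prep})
    if deck is not None and n_strips > deck.run_capacity:
        raise ValueError(
            f"run holds {n_strips} strips but deck capacity is {deck.run_capacity}"
        )

    batches = batch_transfers(list(transfers), config.n_channels)
    for b in batches:
        if b.step_index == -1:
            b.duration = config.prep_duration_s
        else:
            b.duration = steps[b.step_index].duration

    # Precedence: per condition, each step's batch depends on the previous
    # step's batch; transfers drawing from a mixture depend on its prep.
    batch_of: dict[int, Batch] = {id(t): b for b in batches for t in b.transfers}
    prev_in_cond: dict[str, Transfer] = {}
    prep_batches_of: dict[str, list[Batch]] = {}
    preds: dict[int, set[int]] = {b.batch_id: set() for b in batches}
    delay_edges: list[tuple[Transfer, Transfer, int]] = []  # (pred, succ, delay)
    for b in batches:
        for t in b.transfers:
            if t.is_prep:
                ref = t.condition_id[len(PREP_PREFIX):]
                prep_batches_of.setdefault(ref, []).append(b)
    for b in batches:
        for t in b.transfers:
            if t.is_prep:
                continue
            prev = prev_in_cond.get(t.condition_id)
            if prev is not None:
                pb = batch_of[id(prev)]
                if pb.batch_id != b.batch_id:
                    preds[b.batch_id].add(pb.batch_id)
                delay = steps[t.step_index].min_delay_after_previous
                delay_edges.append((prev, t, delay))
            if t.source is not None and t.source[0] == "mixtures":
                for pb in prep_batches_of.get(t.source[1], []):
                    preds[b.batch_id].add(pb.batch_id)
            prev_in_cond[t.condition_id] = t

    by_id = {b.batch_id: b for b in batches}
    delay_by_succ: dict[int, list[tuple[Transfer, Transfer, int]]] = {}
    for prev, t, delay in delay_edges:
        delay_by_succ.setdefault(batch_of[id(t)].batch_id, []).append((prev, t, delay))

    sample_idx = protocol.sample_step_index
    tol = protocol.imaging_tolerance_s

    def earliest_start(b: Batch) -> int:
        es = 0
        for prev, t, delay in delay_by_succ.get(b.batch_id, []):
            pb = batch_of[id(prev)]
            if pb.start is None:
                raise RuntimeError("predecessor unscheduled")
            es = max(es, pb.start + delay)
        for t in b.transfers:
            if t.source is not None and t.source[0] == "mixtures":
                for pb in prep_batches_of.get(t.source[1], []):
                    es = max(es, pb.start + pb.duration)
        return es

    sample_start: dict[str, int] = {}

    def image_window(b: Batch) -> tuple[int, int]:
        """(target point, latest allowed start) for an imaging batch."""
        step = steps[b.step_index]
        tgt = -math.inf
        latest = math.inf
        for t in b.transfers:
            s0 = sample_start[t.condition_id]
            tgt = max(tgt, s0 + step.target_time_after_sample)
            latest = min(latest, s0 + step.target_time_after_sample + tol)
        return int(tgt), int(latest) if latest < math.inf else int(tgt) + tol

    unscheduled = set(by_id)
    t_now = 0
    while unscheduled:
        ready = [
            by_id[i]
            for i in sorted(unscheduled)
            if all(p not in unscheduled for p in preds[i])
        ]
        if not ready:
            raise RuntimeError("precedence cycle in batch graph")
        image_ready = [
            b for b in ready
            if b.action == "image"
            and all(t.condition_id in sample_start for t in b.transfers)
        ]
        windows = {b.batch_id: image_window(b) for b in image_ready}
        image_ready.sort(key=lambda b: (windows[b.batch_id][0], b.batch_id))
        liquid_ready = sorted(
            (b for b in ready if b.action != "image"),
            key=lambda b: (max(t_now, earliest_start(b)), b.batch_id),
        )

        chosen: Batch | None = None
        start = 0
        chosen_es = 0
        for b in liquid_ready:
            es = earliest_start(b)
            s = max(t_now, es)
            end = s + b.duration
            if all(
                max(end, windows[i.batch_id][0]) <= windows[i.batch_id][1]
                for i in image_ready
            ):
                chosen, start, chosen_es = b, s, es
                break
        if chosen is None:
            if not image_ready:
                raise RuntimeError("no schedulable batch (precedence deadlock)")
            b = image_ready[0]
            tgt, latest = windows[b.batch_id]
            # the whole +/- tolerance window is usable: start early when a
            # backlog of imaging cohorts would otherwise drift past latest
            s = max(t_now, tgt - tol, earliest_start(b))
            if s > latest:
                suggested = max(1, n_strips // 2)
                raise InfeasibleSchedule(
                    f"imaging deadline missed by {s - latest} s for batch "
                    f"{b.batch_id}; try a run of <= {suggested} strips",
                    suggested_run_size=suggested,
                )
            chosen, start, chosen_es = b, s, max(0, tgt - tol)

        for tr in chosen.transfers:
            tr.scheduled_start = start
            tr.earliest_start = chosen_es
            if tr.step_index == sample_idx:
                sample_start[tr.condition_id] = start
        t_now = start + chosen.duration
        unscheduled.discard(chosen.batch_id)

    rows = sorted(
        (t for b in batches for t in b.transfers),
        key=lambda t: (t.scheduled_start, t.batch_id, t.channel),
    )
    meta = {"protocol_hash": protocol.content_hash()}
    return Worklist(run_index=run_index, rows=rows, metadata=meta)


def build_worklist(
    run: RunPlan,
    protocol: Protocol,
    sources: Mapping[str, tuple[str, str]] | None = None,
    recipes: Mapping[str, MixRecipe] | None = None,
    config: RobotConfig | None = None,
    deck: DeckLayout | None = None,
) -> Worklist:
    """Expand, batch and schedule one run in a single call."""
    config = config or RobotConfig()
    transfers = expand_protocol(
        run, protocol, sources=sources, recipes=recipes,
        prepare_on_deck=config.prepare_on_deck,
    )
    wl = schedule_run(
        transfers, protocol, config=config, run_index=run.run_index, deck=deck
    )
    h = hashlib.sha256()
    for a in run.assignments:
        h.update(a.condition.condition_id.encode())
    wl.metadata["design_hash"] = h.hexdigest()[:16]
    return wl


# ---------------------------------------------------------------------------
# CSV dialect


def _fmt_volume(v: float | None) -> str:
    if v is None:
        return ""
    return str(v)


def write_worklist_csv(worklist: Worklist, path_or_buf) -> None:
    """Write a worklist in the documented CSV dialect (UTF-8, comma)."""

    def _write(fh) -> None:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(WORKLIST_COLUMNS)
        for t in worklist.rows:
            src_lab, src_pos = t.source if t.source else ("", "")
            holder, slot, well = t.destination
            w.writerow(
                [
                    worklist.run_index,
                    t.batch_id,
                    t.channel,
                    t.action,
                    src_lab,
                    src_pos,
                    holder,
                    slot,
                    well,
                    _fmt_volume(t.volume),
                    t.liquid_class,
                    t.scheduled_start,
                    t.condition_id,
                ]
            )

    if hasattr(path_or_buf, "write"):
        _write(path_or_buf)
    else:
        with open(path_or_buf, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def read_worklist_csv(path_or_buf) -> Worklist:
    """Parse a worklist CSV; round-trips :func:`write_worklist_csv` exactly."""

    def _read(fh) -> Worklist:
        r = csv.reader(fh)
        header = next(r)
        if tuple(header) != WORKLIST_COLUMNS:
            raise ValueError(f"unexpected worklist header: {header}")
        rows: list[Transfer] = []
        run_index = 0
        for rec in r:
            (run, batch, channel, action, src_lab, src_pos, holder, slot,
             well, vol, lc, start, cid) = rec
            run_index = int(run)
            rows.append(
                Transfer(
                    run_index=run_index,
                    condition_id=cid,
                    action=action,
                    source=(src_lab, src_pos) if src_lab else None,
                    destination=(holder, int(slot), well),
                    volume=float(vol) if vol else None,
                    liquid_class=lc,
                    scheduled_start=int(start),
                    batch_id=int(batch),
                    channel=int(channel),
                )
            )
        return Worklist(run_index=run_index, rows=rows)

    if hasattr(path_or_buf, "read"):
        return _read(path_or_buf)
    with open(path_or_buf, "r", encoding="utf-8", newline="") as fh:
        return _read(fh)


def worklist_to_string(worklist: Worklist) -> str:
    buf = io.StringIO()
    write_worklist_csv(worklist, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class Violation:
    kind: str  # delay | deadline | gantry_overlap | stock_depletion | structure
    message: str


@dataclass
class FeasibilityReport:
    violations: list[Violation]

    @property
    def feasible(self) -> bool:
        return not self.violations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"kind": v.kind, "message": v.message} for v in self.violations],
            columns=["kind", "message"],
        )

    def __str__(self) -> str:
        if self.feasible:
            return "feasible"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [{v.kind}] {v.message}" for v in self.violations]
        return "\n".join(lines)


def simulate_worklist(
    worklist: Worklist,
    protocol: Protocol,
    stocks: Mapping[str, float] | None = None,
    config: RobotConfig | None = None,
) -> FeasibilityReport:
    """Replay a worklist on a virtual timeline and report violations.

    Checks: per-strip step completeness and inter-step delays, imaging
    deadlines, single-gantry batch overlap, channel capacity, and running
    stock balances (``stocks`` maps stock position -> available µL).
    Violations are report entries, never exceptions.
    """
    config = config or RobotConfig()
    violations: list[Violation] = []
    steps = list(protocol.steps)
    tol = protocol.imaging_tolerance_s

    # batches
    by_batch: dict[int, list[Transfer]] = {}
    for t in worklist.rows:
        by_batch.setdefault(t.batch_id, []).append(t)
    batch_info = []
    for bid, members in sorted(by_batch.items()):
        starts = {t.scheduled_start for t in members}
        if len(starts) != 1:
            violations.append(
                Violation("structure", f"batch {bid}: members disagree on start")
            )
        if len(members) > config.n_channels:
            violations.append(
                Violation(
                    "structure",
                    f"batch {bid}: {len(members)} transfers exceed "
                    f"{config.n_channels} channels",
                )
            )
        channels = [t.channel for t in members]
        if len(set(channels)) != len(channels):
            violations.append(
                Violation("structure", f"batch {bid}: duplicate channel assignment")
            )
        batch_info.append((bid, min(starts), members))

    # per-condition step mapping (events in time order <-> protocol steps)
    by_cond: dict[str, list[Transfer]] = {}
    for t in worklist.rows:
        if not t.is_prep:
            by_cond.setdefault(t.condition_id, []).append(t)
    dur_of_batch: dict[int, int] = {}
    sample_pos = next(
        (i for i, s in enumerate(steps) if s.action == "dispense_sample"), None
    )
    for cid, events in by_cond.items():
        events.sort(key=lambda t: (t.scheduled_start, t.batch_id))
        if len(events) != len(steps):
            violations.append(
                Violation(
                    "structure",
                    f"condition {cid}: {len(events)} events for "
                    f"{len(steps)} protocol steps",
                )
            )
            continue
        for j, (step, ev) in enumerate(zip(steps, events)):
            if ev.action != step.action:
                violations.append(
                    Violation(
                        "structure",
                        f"condition {cid}: event {j} is {ev.action}, "
                        f"protocol says {step.action}",
                    )
                )
            dur_of_batch[ev.batch_id] = step.duration
            if j > 0:
                gap = ev.scheduled_start - events[j - 1].scheduled_start
                if gap < step.min_delay_after_previous:
                    violations.append(
                        Violation(
                            "delay",
                            f"condition {cid}: step {j} starts {gap} s after "
                            f"step {j - 1}, needs {step.min_delay_after_previous} s",
                        )
                    )
            if step.action == "image" and sample_pos is not None:
                t_sample = events[sample_pos].scheduled_start
                target = t_sample + step.target_time_after_sample
                if abs(ev.scheduled_start - target) > tol:
                    violations.append(
                        Violation(
                            "deadline",
                            f"condition {cid}: imaged at {ev.scheduled_start} s, "
                            f"target {target} +/- {tol} s",
                        )
                    )

    # gantry overlap
    timeline = sorted(batch_info, key=lambda x: (x[1], x[0]))
    for (b1, s1, m1), (b2, s2, _m2) in zip(timeline, timeline[1:]):
        d1 = dur_of_batch.get(b1, config.prep_duration_s)
        if s2 < s1 + d1:
            violations.append(
                Violation(
                    "gantry_overlap",
                    f"batch {b2} starts at {s2} s while batch {b1} "
                    f"(start {s1} s, duration {d1} s) is still executing",
                )
            )

    # stock balances
    if stocks is not None:
        balance = dict(stocks)
        for _bid, _start, members in timeline:
            for t in members:
                if t.source is None or t.volume is None:
                    continue
                lab, pos = t.source
                if lab != "stocks" or pos not in balance:
                    continue
                balance[pos] -= t.volume
                if balance[pos] < -1e-9:
                    violations.append(
                        Violation(
                            "stock_depletion",
                            f"stock {pos!r} overdrawn by "
                            f"{-balance[pos]:.3f} µL at batch {_bid}",
                        )
                    )
                    balance[pos] = 0.0  # report once per depletion event
    return FeasibilityReport(violations)
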
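"""Readers for the structured-text configuration files.

All experiment inputs are plain text: designs, decks and protocols are
YAML; stock tables and screen tables are CSV.  Schema violations raise
:class:`ConfigError` with a message naming the offending field.

Design YAML::

    factors:
      - name: capture
        role: capture_antibody
        levels: [MAb001, MAb002]
    replicates: 2
    exclusions:
      - type: all_zero
        factors: [conc_a, conc_b]
      - type: levels
        where: {capture: MAb001}

Deck YAML::

    holders:
      - id: H1
        capacity: 16
        cassette: false
    wells_per_strip: 2
    slots:                      # optional image/deck geometry
      - {holder: H1, slot: 0, coords: [0, 120, 0, 40]}

Protocol YAML::

    name: standard
    imaging_tolerance_s: 60
    robot: {n_channels: 8}
    steps:
      - {action: dispense_reagent, reagent_ref: "det_{detection}",
         volume: 10, destination: conjugate_well, duration: 20}
      - {action: dispense_sample, reagent_ref: "sample_{matrix}",
         volume: 50, destination: sample_port,
         min_delay_after_previous: 120, duration: 20}
      - {action: image, target_time_after_sample: 1800, duration: 10}

Stocks CSV columns: ``stock_id, component, concentration_ug_ml, volume_ul``
(one row per stock; the diluent is a row with an empty component).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .design import (
    AllZeroExclusion,
    DeckLayout,
    DesignSpec,
    FactorSpec,
    LevelExclusion,
)
from .mixplan import StockSolution
from .schedule import Protocol, ProtocolStep, RobotConfig

__all__ = [
    "ConfigError",
    "load_design",
    "load_deck",
    "load_protocol",
    "load_stocks",
    "load_screen_table",
]


class ConfigError(ValueError):
    """A configuration file fails schema validation."""


def _load_yaml(path: str | Path) -> dict:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def load_design(path: str | Path) -> DesignSpec:
    data = _load_yaml(path)
    raw_factors = data.get("factors")
    if not isinstance(raw_factors, list) or not raw_factors:
        raise ConfigError(f"{path}: 'factors' must be a non-empty list")
    factors = []
    for i, f in enumerate(raw_factors):
        if not isinstance(f, dict) or "name" not in f or "levels" not in f:
            raise ConfigError(f"{path}: factor #{i} needs 'name' and 'levels'")
        try:
            factors.append(
                FactorSpec(
                    name=str(f["name"]),
                    levels=tuple(f["levels"]),
                    role=f.get("role", "other"),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"{path}: factor #{i}: {exc}") from exc
    exclusions = []
    for i, e in enumerate(data.get("exclusions") or []):
        kind = e.get("type") if isinstance(e, dict) else None
        if kind == "all_zero":
            exclusions.append(AllZeroExclusion(factors=tuple(e["factors"])))
        elif kind == "levels":
            where = e.get("where")
            if not isinstance(where, dict):
                raise ConfigError(f"{path}: exclusion #{i}: 'where' mapping required")
            exclusions.append(LevelExclusion(where=tuple(where.items())))
        else:
            raise ConfigError(
                f"{path}: exclusion #{i}: type must be 'all_zero' or 'levels'"
            )
    try:
        return DesignSpec(
            factors=tuple(factors),
            replicates=int(data.get("replicates", 1)),
            exclusions=tuple(exclusions),
            controls=data.get("controls") or {},
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_deck(path: str | Path) -> DeckLayout:
    data = _load_yaml(path)
    raw = data.get("holders")
    if not isinstance(raw, list) or not raw:
        raise ConfigError(f"{path}: 'holders' must be a non-empty list")
    holders = []
    cassette = set()
    for i, h in enumerate(raw):
        if not isinstance(h, dict) or "id" not in h or "capacity" not in h:
            raise ConfigError(f"{path}: holder #{i} needs 'id' and 'capacity'")
        holders.append((str(h["id"]), int(h["capacity"])))
        if h.get("cassette"):
            cassette.add(str(h["id"]))
    coords = {}
    for s in data.get("slots") or []:
        coords[(str(s["holder"]), int(s["slot"]))] = tuple(s["coords"])
    try:
        return DeckLayout(
            holders=tuple(holders),
            wells_per_strip=int(data.get("wells_per_strip", 2)),
            slot_coords=coords,
            cassette_holders=frozenset(cassette),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_protocol(path: str | Path) -> tuple[Protocol, RobotConfig]:
    data = _load_yaml(path)
    raw_steps = data.get("steps")
    if not isinstance(raw_steps, list) or not raw_steps:
        raise ConfigError(f"{path}: 'steps' must be a non-empty list")
    steps = []
    for i, s in enumerate(raw_steps):
        if not isinstance(s, dict) or "action" not in s:
            raise ConfigError(f"{path}: step #{i} needs an 'action'")
        try:
            steps.append(
                ProtocolStep(
                    step_index=int(s.get("step_index", i)),
                    action=str(s["action"]),
                    reagent_ref=s.get("reagent_ref"),
                    volume=float(s.get("volume", 0.0)),
                    destination=str(s.get("destination", "sample_port")),
                    min_delay_after_previous=int(s.get("min_delay_after_previous", 0)),
                    target_time_after_sample=(
                        int(s["target_time_after_sample"])
                        if s.get("target_time_after_sample") is not None
                        else None
                    ),
                    liquid_class=str(s.get("liquid_class", "default")),
                    duration=int(s.get("duration", 10)),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"{path}: step #{i}: {exc}") from exc
    robot = data.get("robot") or {}
    try:
        protocol = Protocol(
            name=str(data.get("name", Path(path).stem)),
            steps=tuple(steps),
            imaging_tolerance_s=int(data.get("imaging_tolerance_s", 60)),
        )
        config = RobotConfig(
            n_channels=int(robot.get("n_channels", 8)),
            prep_duration_s=int(robot.get("prep_duration_s", 10)),
            prepare_on_deck=bool(robot.get("prepare_on_deck", True)),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return protocol, config


def load_stocks(path: str | Path) -> list[StockSolution]:
    try:
        frame = pd.read_csv(path, dtype={"stock_id": str})
    except Exception as exc:  # malformed CSV
        raise ConfigError(f"{path}: cannot parse CSV ({exc})") from exc
    needed = {"stock_id", "component", "concentration_ug_ml", "volume_ul"}
    missing = needed - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: stocks CSV missing columns {sorted(missing)}")
    stocks = []
    for row in frame.itertuples():
        comp = "" if pd.isna(row.component) else str(row.component)
        concs = {comp: float(row.concentration_ug_ml)} if comp else {}
        try:
            stocks.append(
                StockSolution(
                    stock_id=str(row.stock_id),
                    component_concentrations=concs,
                    available_volume=float(row.volume_ul),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"{path}: stock {row.stock_id!r}: {exc}") from exc
    return stocks


def load_screen_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    needed = {"capture", "detection", "matrix", "signal"}
    missing = needed - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: screen table missing columns {sorted(missing)}")
    return frame
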
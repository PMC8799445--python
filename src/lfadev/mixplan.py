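"""Dilution and mixture planning by volume/mass balance.

Working solutions for a condition (an antibody mixture at prescribed
concentrations, or a serial dilution series) are prepared from
single-component stock solutions plus a diluent.  For a target component
concentration ``c_t`` in a final volume ``V_f`` drawn from a stock at
``c_s``, the transfer volume is ``V = c_t * V_f / c_s`` and the diluent
makes up the remainder.  Recipes carry exact volumes; quantisation to the
instrument's pipetting resolution is a separate, explicit step that reports
the concentration error it introduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "StockSolution",
    "MixRecipe",
    "InfeasibleMixture",
    "plan_mixture",
    "plan_serial_dilution",
    "quantize_recipe",
    "achieved_concentrations",
    "DILUENT_ID",
]

#: Distinguished stock id used for the diluent (all-zero concentrations).
DILUENT_ID = "buffer"

#: Relative tolerance for the mass-balance invariants.
MASS_BALANCE_RTOL = 1e-9


class InfeasibleMixture(ValueError):
    """A requested mixture cannot be prepared from the given stocks."""


@dataclass(frozen=True)
class StockSolution:
    """A stock: component concentrations in µg/mL and available volume in µL."""

    stock_id: str
    component_concentrations: Mapping[str, float]
    available_volume: float = math.inf

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "component_concentrations", dict(self.component_concentrations)
        )
        for comp, conc in self.component_concentrations.items():
            if conc < 0 or not math.isfinite(conc):
                raise ValueError(f"stock {self.stock_id!r}: {comp} concentration < 0")
        if self.available_volume < 0:
            raise ValueError(f"stock {self.stock_id!r}: negative available volume")

    @property
    def components(self) -> list[str]:
        return [c for c, v in self.component_concentrations.items() if v > 0]


@dataclass(frozen=True)
class MixRecipe:
    """How to prepare one working solution.

    ``transfers`` lists (stock_id, volume µL); ``diluent_volume`` tops the
    mixture up to ``final_volume``.  The invariants — volumes sum exactly to
    the final volume, and per-component mass balance holds — are checked on
    construction.
    """

    target_id: str
    target_concentrations: Mapping[str, float]
    final_volume: float
    transfers: tuple[tuple[str, float], ...]
    diluent_volume: float
    source_concentrations: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    check: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "target_concentrations", dict(self.target_concentrations)
        )
        object.__setattr__(self, "transfers", tuple(self.transfers))
        object.__setattr__(
            self,
            "source_concentrations",
            {k: dict(v) for k, v in self.source_concentrations.items()},
        )
        if any(v < 0 for _, v in self.transfers) or self.diluent_volume < 0:
            raise ValueError(f"recipe {self.target_id!r}: negative volume")
        total = sum(v for _, v in self.transfers) + self.diluent_volume
        if abs(total - self.final_volume) > 1e-9:
            raise ValueError(
                f"recipe {self.target_id!r}: volumes sum to {total}, "
                f"expected {self.final_volume}"
            )
        if self.check and self.source_concentrations:
            achieved = achieved_concentrations(self)
            for comp, c_t in self.target_concentrations.items():
                c_a = achieved.get(comp, 0.0)
                tol = MASS_BALANCE_RTOL * max(abs(c_t), 1.0)
                if abs(c_a - c_t) > tol:
                    raise ValueError(
                        f"recipe {self.target_id!r}: mass balance violated for "
                        f"{comp}: achieved {c_a}, target {c_t}"
                    )

    @property
    def total_stock_volume(self) -> float:
        return sum(v for _, v in self.transfers)


def achieved_concentrations(recipe: MixRecipe) -> dict[str, float]:
    """Recompute component concentrations implied by a recipe's transfers."""
    mass: dict[str, float] = {}
    for stock_id, vol in recipe.transfers:
        concs = recipe.source_concentrations.get(stock_id, {})
        for comp, conc in concs.items():
            mass[comp] = mass.get(comp, 0.0) + conc * vol
    return {comp: m / recipe.final_volume for comp, m in mass.items()}


def plan_mixture(
    targets: Mapping[str, float],
    stocks: Sequence[StockSolution],
    final_volume: float,
    target_id: str = "mix",
) -> MixRecipe:
    """Plan one mixture from single-component stocks.

    Each target component must be available in exactly one single-component
    stock; multi-component stocks are rejected (solving the general linear
    system is deliberately out of scope).

    Raises
    ------
    InfeasibleMixture
        ``"infeasible: over-concentrated"`` if a target exceeds its stock
        concentration; ``"infeasible: volume overflow"`` if the summed stock
        volumes exceed the final volume; ``"insufficient stock"`` if a
        stock's available volume is exhausted.
    """
    if final_volume <= 0:
        raise ValueError("final_volume must be > 0")
    by_component: dict[str, StockSolution] = {}
    for s in stocks:
        if s.stock_id == DILUENT_ID:
            continue
        comps = s.components
        if len(comps) > 1:
            raise InfeasibleMixture(
                f"stock {s.stock_id!r} holds multiple components; "
                "multi-component stocks are not supported"
            )
        if comps:
            comp = comps[0]
            if comp in by_component:
                raise InfeasibleMixture(
                    f"component {comp!r} available in more than one stock"
                )
            by_component[comp] = s

    transfers: list[tuple[str, float]] = []
    sources: dict[str, dict[str, float]] = {}
    for comp, c_t in targets.items():
        if c_t < 0:
            raise ValueError(f"negative target concentration for {comp!r}")
        if c_t == 0:
            continue
        stock = by_component.get(comp)
        if stock is None:
            raise InfeasibleMixture(f"no stock provides component {comp!r}")
        c_s = stock.component_concentrations[comp]
        if c_t > c_s:
            raise InfeasibleMixture(
                f"infeasible: over-concentrated ({comp}: target {c_t} > stock {c_s})"
            )
        vol = c_t * final_volume / c_s
        if vol > stock.available_volume + 1e-12:
            raise InfeasibleMixture(
                f"insufficient stock {stock.stock_id!r}: need {vol:.3f} µL, "
                f"have {stock.available_volume:.3f} µL"
            )
        transfers.append((stock.stock_id, vol))
        sources[stock.stock_id] = dict(stock.component_concentrations)

    total = sum(v for _, v in transfers)
    if total > final_volume + 1e-9:
        raise InfeasibleMixture(
            f"infeasible: volume overflow (stock volumes {total:.3f} µL "
            f"> final {final_volume:.3f} µL)"
        )
    diluent = final_volume - total
    return MixRecipe(
        target_id=target_id,
        target_concentrations={c: v for c, v in targets.items()},
        final_volume=final_volume,
        transfers=tuple(transfers),
        diluent_volume=diluent,
        source_concentrations=sources,
    )


def plan_serial_dilution(
    top_conc: float,
    fold: float,
    n_steps: int,
    volume_per_step: float,
    carryover: float | None = None,
    component: str = "analyte",
    stock_id: str = "top_stock",
) -> list[MixRecipe]:
    """Plan an n-step serial dilution from a stock at ``top_conc``.

    Step ``k`` (1-based) has concentration ``top_conc / fold**k`` and is
    prepared by carrying ``carryover`` µL of the previous solution into
    ``volume_per_step - carryover`` µL of diluent, so
    ``carryover = volume_per_step / fold``.  Passing an inconsistent
    explicit carryover is an error, as is ``carryover >= volume_per_step``.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if volume_per_step <= 0:
        raise ValueError("volume_per_step must be > 0")
    implied = volume_per_step / fold
    if carryover is None:
        carryover = implied
    if carryover >= volume_per_step:
        raise ValueError("carryover must be smaller than volume_per_step")
    if abs(carryover - implied) > 1e-9 * volume_per_step:
        raise ValueError(
            f"carryover {carryover} inconsistent with fold {fold} at "
            f"{volume_per_step} µL/step (expected {implied})"
        )

    recipes: list[MixRecipe] = []
    prev_id = stock_id
    prev_conc = top_conc
    for k in range(1, n_steps + 1):
        conc = top_conc / fold**k
        recipes.append(
            MixRecipe(
                target_id=f"dilution_step_{k}",
                target_concentrations={component: conc},
                final_volume=volume_per_step,
                transfers=((prev_id, carryover),),
                diluent_volume=volume_per_step - carryover,
                source_concentrations={prev_id: {component: prev_conc}},
            )
        )
        prev_id = f"dilution_step_{k}"
        prev_conc = conc
    return recipes


def quantize_recipe(
    recipe: MixRecipe, resolution: float = 0.1
) -> tuple[MixRecipe, dict[str, float]]:
    """Round transfer volumes to the instrument resolution (default 0.1 µL).

    The diluent absorbs the rounding so the final volume is preserved.
    Returns the rounded recipe plus the relative concentration error per
    component that the rounding introduces.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    rounded = tuple(
        (sid, round(v / resolution) * resolution) for sid, v in recipe.transfers
    )
    total = sum(v for _, v in rounded)
    diluent = recipe.final_volume - total
    if diluent < -1e-9:
        raise InfeasibleMixture(
            "quantisation overflows final volume; use finer resolution"
        )
    q = replace(
        recipe,
        transfers=rounded,
        diluent_volume=max(diluent, 0.0),
        check=False,
    )
    achieved = achieved_concentrations(q)
    errors = {}
    for comp, c_t in recipe.target_concentrations.items():
        if c_t > 0:
            errors[comp] = (achieved.get(comp, 0.0) - c_t) / c_t
        else:
            errors[comp] = achieved.get(comp, 0.0)
    return q, errors
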
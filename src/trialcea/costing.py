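"""Resource-use costing by category and perspective.

Window costs are unit counts × unit prices (medication gets a per-prescription
dispensing fee); cumulative costs are obtained by converting each 4-week recall
window into a per-week cost rate and integrating the piecewise-linear rate
curve from baseline. The societal perspective aggregates direct medical,
direct non-medical, and indirect non-medical (productivity) categories;
the provider perspective keeps direct medical costs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from trialcea.constants import RECALL_WINDOW_WEEKS, RESOURCE_PREFIX
from trialcea.errors import ConfigurationError, CostingError

CATEGORIES = ("direct_medical", "direct_nonmedical", "indirect_nonmedical")

#: Illustrative 2014-style unit prices (€). NOT the authoritative national
#: unit-cost manual values — supply a real table for substantive work.
DEFAULT_PRICES: dict[str, float] = {
    "gp_visit": 33.0,
    "specialist_visit": 98.0,
    "prescription": 15.0,
    "psychiatric_inpatient_day": 255.0,
    "hospital_day": 480.0,
    "informal_care_hour": 14.0,
    "productivity_hour": 35.0,
    "cbt_session": 95.0,
}

DEFAULT_CATEGORY_OF: dict[str, str] = {
    "gp_visit": "direct_medical",
    "specialist_visit": "direct_medical",
    "prescription": "direct_medical",
    "psychiatric_inpatient_day": "direct_medical",
    "hospital_day": "direct_medical",
    "cbt_session": "direct_medical",
    "informal_care_hour": "direct_nonmedical",
    "productivity_hour": "indirect_nonmedical",
}

DEFAULT_MEDICATION_ITEMS = frozenset({"prescription"})
DEFAULT_INPATIENT_ITEMS = frozenset({"psychiatric_inpatient_day", "hospital_day"})
DEFAULT_DISPENSING_FEE = 6.0


@dataclass(frozen=True)
class UnitCostTable:
    """Unit prices, item categories, and costing constants."""

    unit_price: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PRICES))
    category_of: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_OF)
    )
    medication_items: frozenset = DEFAULT_MEDICATION_ITEMS
    inpatient_items: frozenset = DEFAULT_INPATIENT_ITEMS
    dispensing_fee: float = DEFAULT_DISPENSING_FEE
    therapist_hourly_rate: float = 90.0
    feedback_minutes: float = 30.0

    def __post_init__(self) -> None:
        for item, price in self.unit_price.items():
            if price < 0:
                raise ConfigurationError("unit_price", f"{item}: price must be >= 0")
            if item not in self.category_of:
                raise ConfigurationError("category_of", f"{item} has no category")
        for item, cat in self.category_of.items():
            if cat not in CATEGORIES:
                raise ConfigurationError("category_of", f"{item}: unknown category {cat!r}")
        if self.dispensing_fee < 0:
            raise ConfigurationError("dispensing_fee", "must be >= 0")
        if self.therapist_hourly_rate < 0:
            raise ConfigurationError("therapist_hourly_rate", "must be >= 0")
        if self.feedback_minutes < 0:
            raise ConfigurationError("feedback_minutes", "must be >= 0")

    def effective_price(self, item: str) -> float:
        """Unit price including the dispensing fee for medication items."""
        if item not in self.unit_price:
            raise CostingError(f"no unit price for resource item '{item}'")
        price = self.unit_price[item]
        if item in self.medication_items:
            price += self.dispensing_fee
        return price

    def scaled(self, k: float) -> "UnitCostTable":
        """All prices, fees, and rates multiplied by ``k`` (for sensitivity)."""
        return UnitCostTable(
            unit_price={i: p * k for i, p in self.unit_price.items()},
            category_of=dict(self.category_of),
            medication_items=self.medication_items,
            inpatient_items=self.inpatient_items,
            dispensing_fee=self.dispensing_fee * k,
            therapist_hourly_rate=self.therapist_hourly_rate * k,
            feedback_minutes=self.feedback_minutes,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "UnitCostTable":
        """Load from YAML/JSON: items as {name: {price, category, medication?,
        inpatient?}} plus optional top-level costing constants."""
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ConfigurationError("unit_costs", f"{path} does not contain a mapping")
        items = data.get("items", {})
        prices, cats = {}, {}
        meds, inpat = set(), set()
        for name, entry in items.items():
            prices[name] = float(entry["price"])
            cats[name] = entry["category"]
            if entry.get("medication"):
                meds.add(name)
            if entry.get("inpatient"):
                inpat.add(name)
        kwargs = {}
        for key in ("dispensing_fee", "therapist_hourly_rate", "feedback_minutes"):
            if key in data:
                kwargs[key] = float(data[key])
        return cls(
            unit_price=prices,
            category_of=cats,
            medication_items=frozenset(meds),
            inpatient_items=frozenset(inpat),
            **kwargs,
        )

    def to_file(self, path: str | Path) -> None:
        data = {
            "items": {
                name: {
                    "price": price,
                    "category": self.category_of[name],
                    **({"medication": True} if name in self.medication_items else {}),
                    **({"inpatient": True} if name in self.inpatient_items else {}),
                }
                for name, price in self.unit_price.items()
            },
            "dispensing_fee": self.dispensing_fee,
            "therapist_hourly_rate": self.therapist_hourly_rate,
            "feedback_minutes": self.feedback_minutes,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_unit_cost_table() -> UnitCostTable:
    return UnitCostTable()


def window_costs(
    resource_use: Mapping[str, float],
    table: UnitCostTable,
    exclude_items: Iterable[str] = (),
) -> dict[str, float]:
    """Per-category € totals for one recall window: Σ count × unit price.

    Medication items contribute count × (price + dispensing fee). An item
    without a unit price raises :class:`CostingError` naming the item —
    never a silent zero.
    """
    excluded = set(exclude_items)
    totals = dict.fromkeys(CATEGORIES, 0.0)
    for item, count in resource_use.items():
        if item in excluded:
            continue
        if count is None or (isinstance(count, float) and np.isnan(count)):
            continue
        if count < 0:
            raise CostingError(f"negative count for '{item}': {count}")
        if item not in table.category_of:
            raise CostingError(f"no category for resource item '{item}'")
        totals[table.category_of[item]] += count * table.effective_price(item)
    return totals


def feedback_cost(n_messages: int, table: UnitCostTable) -> float:
    """Therapist cost of online feedback: messages × minutes/60 × hourly rate."""
    if n_messages < 0:
        raise CostingError(f"negative feedback message count: {n_messages}")
    return n_messages * table.feedback_minutes / 60.0 * table.therapist_hourly_rate


def cumulative_costs(
    weeks: np.ndarray,
    window_costs_series: np.ndarray,
    method: str = "rate_trapezoid",
    baseline_window: str = "include",
) -> np.ndarray:
    """Cumulative € at each assessment week from 4-week window costs.

    ``rate_trapezoid`` (default): each window cost becomes a per-week rate
    (window / 4) anchored at its assessment week, and the cumulative cost at
    week t is the trapezoid integral of the piecewise-linear rate from 0 to
    t. Missing windows are interpolated across; cumulative values past the
    last observed window are NaN. A constant window cost c therefore yields
    exactly c/4 € per week.

    ``window_scale``: the historical shortcut of scaling each follow-up
    window by (inter-assessment gap / recall window) and summing.

    ``baseline_window='exclude'`` treats the week-0 window as a pre-treatment
    reference: the rate at week 0 is back-filled from the first follow-up
    window instead.
    """
    weeks = np.asarray(weeks, dtype=float)
    costs = np.asarray(window_costs_series, dtype=float)
    if method not in ("rate_trapezoid", "window_scale"):
        raise ConfigurationError("method", f"unknown cumulative method {method!r}")
    if baseline_window not in ("include", "exclude"):
        raise ConfigurationError("baseline_window", f"got {baseline_window!r}")
    out = np.full(len(weeks), np.nan)
    rate = costs / RECALL_WINDOW_WEEKS
    if baseline_window == "exclude" and len(weeks) > 1:
        rate = rate.copy()
        fu = rate[1:]
        rate[0] = fu[~np.isnan(fu)][0] if np.any(~np.isnan(fu)) else np.nan
    ok = ~np.isnan(rate)
    if ok.sum() < 2 or not ok[0]:
        return out

    w_ok, r_ok = weeks[ok], rate[ok]
    if method == "window_scale":
        out[0] = 0.0
        cum = 0.0
        # scale each observed follow-up window by the gap since the previous
        # observed assessment; gaps spanned by a missing window accrue at the
        # next observed window's rate
        for j in range(1, len(w_ok)):
            gap = w_ok[j] - w_ok[j - 1]
            cum += r_ok[j] * gap
            out[np.where(weeks == w_ok[j])[0][0]] = cum
        return out

    last = w_ok[-1]
    for j, t in enumerate(weeks):
        if t > last:
            continue
        grid = np.unique(np.concatenate([w_ok[w_ok <= t], [t]]))
        vals = np.interp(grid, w_ok, r_ok)
        out[j] = np.trapezoid(vals, grid)
    return out


def build_cost_panel(
    data: pd.DataFrame,
    table: UnitCostTable | None = None,
    method: str = "rate_trapezoid",
    baseline_window: str = "include",
    include_treatment: bool = True,
) -> pd.DataFrame:
    """Per patient × assessment cost panel from a long-format trial dataset.

    Emits window costs per category (``win_*``), cumulative costs per
    category (``cum_*``), the two perspective aggregates (``cum_societal``,
    ``cum_provider``), the inpatient-excluded variants, and
    ``cum_indirect_only``. Treatment delivery costs (face-to-face sessions at
    the session unit price plus therapist feedback time for the blended arm)
    accrue linearly over the study and are added to direct-medical and the
    aggregates when ``include_treatment`` is set.
    """
    if table is None:
        table = default_unit_cost_table()
    ru_cols = [c for c in data.columns if c.startswith(RESOURCE_PREFIX)]
    items = [c[len(RESOURCE_PREFIX) :] for c in ru_cols]
    for item in items:
        table.effective_price(item)  # fail fast on unpriced items

    frames = []
    for pid, grp in data.sort_values(["patient_id", "week"]).groupby(
        "patient_id", sort=True
    ):
        weeks = grp["week"].to_numpy(dtype=float)
        horizon = weeks[-1] if len(weeks) else 0.0

        def _window_matrix(exclude: frozenset) -> dict[str, np.ndarray]:
            per_cat = {c: np.zeros(len(grp)) for c in CATEGORIES}
            any_missing = np.zeros(len(grp), dtype=bool)
            for col, item in zip(ru_cols, items):
                counts = grp[col].to_numpy(dtype=float)
                any_missing |= np.isnan(counts)
                if item in exclude:
                    continue
                per_cat[table.category_of[item]] += np.where(
                    np.isnan(counts), 0.0, counts
                ) * table.effective_price(item)
            for c in CATEGORIES:
                per_cat[c][any_missing] = np.nan
            return per_cat

        win = _window_matrix(frozenset())
        win_x = _window_matrix(table.inpatient_items)

        row = {"patient_id": pid, "arm": grp["arm"].iloc[0], "week": weeks}
        for c in CATEGORIES:
            row[f"win_{c}"] = win[c]
            row[f"cum_{c}"] = cumulative_costs(weeks, win[c], method, baseline_window)
        cum_x_dm = cumulative_costs(weeks, win_x["direct_medical"], method, baseline_window)

        if include_treatment and horizon > 0:
            n_f2f = float(grp["n_f2f_sessions"].iloc[0]) if "n_f2f_sessions" in grp else 0.0
            n_fb = float(grp["n_feedback_messages"].iloc[0]) if "n_feedback_messages" in grp else 0.0
            treatment_total = n_f2f * table.effective_price("cbt_session") + feedback_cost(
                n_fb, table
            )
            accrual = treatment_total * weeks / horizon
            row["cum_direct_medical"] = row["cum_direct_medical"] + accrual
            cum_x_dm = cum_x_dm + accrual

        row["cum_societal"] = (
            row["cum_direct_medical"]
            + row["cum_direct_nonmedical"]
            + row["cum_indirect_nonmedical"]
        )
        row["cum_provider"] = row["cum_direct_medical"]
        row["cum_provider_excl_inpatient"] = cum_x_dm
        row["cum_societal_excl_inpatient"] = (
            cum_x_dm + row["cum_direct_nonmedical"] + row["cum_indirect_nonmedical"]
        )
        row["cum_indirect_only"] = row["cum_indirect_nonmedical"]
        row["win_societal"] = (
            win["direct_medical"] + win["direct_nonmedical"] + win["indirect_nonmedical"]
        )
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


def perspective_costs(
    panel: pd.DataFrame,
    perspective: str,
    exclude_inpatient: bool = False,
    indirect_only: bool = False,
) -> pd.Series:
    """Select the cumulative cost series for a perspective / variant.

    ``indirect_only`` returns the absenteeism/presenteeism (indirect
    non-medical) cumulative alone and is only meaningful from the societal
    perspective; combining it with the provider perspective is a
    configuration error, as is combining it with ``exclude_inpatient``.
    """
    if perspective not in ("societal", "provider"):
        raise ConfigurationError("perspective", f"got {perspective!r}")
    if indirect_only and (perspective == "provider" or exclude_inpatient):
        raise ConfigurationError(
            "indirect_only", "incompatible with provider perspective or exclude_inpatient"
        )
    if indirect_only:
        return panel["cum_indirect_only"]
    key = f"cum_{perspective}" + ("_excl_inpatient" if exclude_inpatient else "")
    return panel[key]
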
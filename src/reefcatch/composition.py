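"""Catch composition by coral-dependence category.

Aggregates logbook-style catch records into per-category percentage
shares by gear, region or sector, over a fixed analysis window (the
default study window is the decade 2008-2017). Weight-based records
(commercial, charter; tonnes) and count-based records (recreational,
aquarium; individuals) are never mixed in one aggregation. A taxon-year
absent from the records contributes zero catch for that year — logbook
semantics — so annual means always divide by the full window length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .habitat import DependenceCategory

__all__ = ["CategoryProfile", "CATCH_COLUMNS", "mean_annual_catch", "aggregate_profile"]

CATCH_COLUMNS = ("taxon_label", "region", "sector", "year", "quantity", "basis")

#: grouping choices; "gear" is how commercial gear types appear in the
#: sector column, so it aliases "sector"
_GROUP_COLS = {"gear": "sector", "sector": "sector", "region": "region"}


@dataclass
class CategoryProfile:
    """Per-key category composition of catch.

    shares are percentages over the four categories (summing to 100 when
    anything was classifiable); ``excluded_quantity`` accumulates the
    mean annual quantity of taxa absent from the catalog, so that
    ``total_quantity + excluded_quantity`` conserves the input.
    ``undefined`` flags keys whose entire catch was unclassifiable.
    """

    key: str
    shares: np.ndarray  # length 4, percent, index 0 -> category 1
    total_quantity: float
    excluded_quantity: float
    basis: str
    undefined: bool = False

    def share(self, category: DependenceCategory | int) -> float:
        return float(self.shares[int(category) - 1])


def _validate_catch(catch: pd.DataFrame) -> None:
    missing = set(CATCH_COLUMNS) - set(catch.columns)
    if missing:
        raise DomainError(f"catch table missing columns: {sorted(missing)}")
    if len(catch) and (catch["quantity"] < 0).any():
        raise DomainError("catch quantities must be non-negative")


def mean_annual_catch(
    catch: pd.DataFrame, year_range: tuple[int, int]
) -> dict[str, float]:
    """Mean annual quantity per taxon over an inclusive year window.

    Years in which a taxon reports no catch count as zero, so the mean is
    (total quantity in window) / (number of years in window); a taxon
    landing 10 t in one year of a ten-year window averages 1 t/yr.
    """
    y0, y1 = year_range
    if y1 < y0:
        raise DomainError(f"empty year range {year_range}")
    _validate_catch(catch)
    n_years = y1 - y0 + 1
    window = catch[(catch["year"] >= y0) & (catch["year"] <= y1)]
    totals = window.groupby("taxon_label")["quantity"].sum()
    return {taxon: float(total) / n_years for taxon, total in totals.items()}


def aggregate_profile(
    catch: pd.DataFrame,
    catalog: Mapping[str, DependenceCategory | int],
    group_by: str = "region",
    year_range: tuple[int, int] = (2008, 2017),
    *,
    allow_unclassified: bool = True,
) -> list[CategoryProfile]:
    """Profile catch into category shares per gear/region/sector key.

    For each key, taxon quantities are averaged per year over
    ``year_range`` (zero-filled), mapped to categories through
    ``catalog``, summed per category and converted to percent shares.
    Catch of taxa not in the catalog accumulates in ``excluded_quantity``
    and is omitted from the shares (or raises if ``allow_unclassified``
    is False). Mixing weight- and count-based records in one aggregation
    is an error.
    """
    if group_by not in _GROUP_COLS:
        raise DomainError(f"group_by must be one of {sorted(_GROUP_COLS)}")
    _validate_catch(catch)
    col = _GROUP_COLS[group_by]
    y0, y1 = year_range
    if y1 < y0:
        raise DomainError(f"empty year range {year_range}")
    n_years = y1 - y0 + 1

    window = catch[(catch["year"] >= y0) & (catch["year"] <= y1)]
    bases = window["basis"].unique()
    if len(bases) > 1:
        raise DomainError(
            f"mixed quantity bases in one aggregation: {sorted(bases)}; "
            "profile weight- and count-based sectors separately"
        )
    basis = bases[0] if len(bases) else "weight_tonnes"

    profiles: list[CategoryProfile] = []
    for key, sub in window.groupby(col, sort=True):
        per_taxon = sub.groupby("taxon_label")["quantity"].sum() / n_years
        cat_totals = np.zeros(4)
        excluded = 0.0
        unclassified = []
        for taxon, qty in per_taxon.items():
            if taxon in catalog:
                cat_totals[int(catalog[taxon]) - 1] += qty
            else:
                unclassified.append(taxon)
                excluded += qty
        if unclassified and not allow_unclassified:
            raise DomainError(
                f"key {key!r}: taxa not in catalog: {sorted(unclassified)}"
            )
        total = float(cat_totals.sum())
        if total > 0:
            shares = cat_totals / total * 100.0
            undefined = False
        else:
            shares = np.full(4, np.nan)
            undefined = True
        profiles.append(
            CategoryProfile(
                key=str(key),
                shares=shares,
                total_quantity=total,
                excluded_quantity=float(excluded),
                basis=str(basis),
                undefined=undefined,
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[CategoryProfile]) -> pd.DataFrame:
    """Tidy long-format view: one row per key x category."""
    rows = []
    for p in profiles:
        for cat in range(1, 5):
            rows.append(
                {
                    "key": p.key,
                    "category": cat,
                    "percent": p.shares[cat - 1],
                    "total": p.total_quantity,
                    "excluded": p.excluded_quantity,
                    "basis": p.basis,
                }
            )
    return pd.DataFrame(
        rows, columns=["key", "category", "percent", "total", "excluded", "basis"]
    )
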
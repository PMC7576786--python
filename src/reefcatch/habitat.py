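"""Ordinal coral-dependence classification of fished taxa.

Species are rated on a four-level ordinal scale reflecting their expected
sensitivity to coral mortality:

1. not known to be associated with coral reefs (live or dead),
2. associated with coral reefs but not known to depend on live coral,
3. documented dependence on live coral cover,
4. obligate dependence on live coral cover.

Evidence is encoded as structured boolean flags on observation records
(one row per species x life-stage x method x habitat), so the literature
judgement is input data and the classification rules are pure functions.
Catch reported at genus/family/group level is assigned the highest
category of any member species (the conservative rule), and taxa that
cannot be resolved are reported in a rejects table rather than silently
defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ClassificationError, DomainError

__all__ = [
    "DependenceCategory",
    "LifeStage",
    "ObservationMethod",
    "HabitatKind",
    "Substrate",
    "GroupResolution",
    "HabitatEvidence",
    "TaxonGroup",
    "CatalogResult",
    "classify_species",
    "classify_species_table",
    "classify_group",
    "build_catalog",
    "coverage_rank",
]


class DependenceCategory(IntEnum):
    """Ordinal sensitivity-to-coral-loss category (higher = more sensitive)."""

    NOT_ASSOCIATED = 1
    REEF_ASSOCIATED = 2
    CORAL_DEPENDENT = 3
    CORAL_OBLIGATE = 4


class LifeStage(str, Enum):
    EGG = "egg"
    LARVA = "larva"
    JUVENILE = "juvenile"
    ADULT = "adult"
    UNSPECIFIED = "unspecified"


class ObservationMethod(str, Enum):
    DIRECT_OBSERVATION = "direct_observation"
    CATCH_SURVEY = "catch_survey"
    E_TAG = "e_tag"
    VIDEO_SURVEY = "video_survey"
    DIET_ANALYSIS = "diet_analysis"
    EXPERIMENT = "experiment"


class HabitatKind(str, Enum):
    PHYSICO_CHEMICAL = "physico_chemical"
    SUBSTRATE = "substrate"


class Substrate(str, Enum):
    CORAL_REEF = "coral_reef"
    ROCKY_REEF = "rocky_reef"
    SEAGRASS = "seagrass"
    MANGROVE = "mangrove"
    MACROALGAE = "macroalgae"
    UNVEGETATED_SOFT = "unvegetated_soft"
    NONE = "none"


class GroupResolution(str, Enum):
    SPECIES = "species"
    GENUS = "genus"
    FAMILY = "family"
    ARBITRARY = "arbitrary"


@dataclass(frozen=True)
class HabitatEvidence:
    """One observation linking a species/life-stage to a habitat.

    The three coral flags form a hierarchy: obligate live-coral dependence
    implies live-coral dependence, which implies coral association; an
    observation on coral-reef substrate implies coral association.
    Violations raise ``ValueError`` at construction.
    """

    species_id: str
    life_stage: LifeStage = LifeStage.UNSPECIFIED
    method: ObservationMethod = ObservationMethod.DIRECT_OBSERVATION
    habitat_kind: HabitatKind = HabitatKind.SUBSTRATE
    substrate: Substrate = Substrate.NONE
    coral_assoc: bool = False
    live_coral_dependent: bool = False
    live_coral_obligate: bool = False
    source_ref: str = ""

    def __post_init__(self):
        if self.live_coral_obligate and not self.live_coral_dependent:
            raise ValueError(
                f"{self.species_id}: obligate live-coral dependence implies "
                "live-coral dependence"
            )
        if self.live_coral_dependent and not self.coral_assoc:
            raise ValueError(
                f"{self.species_id}: live-coral dependence implies coral association"
            )
        if self.substrate == Substrate.CORAL_REEF and not self.coral_assoc:
            raise ValueError(
                f"{self.species_id}: coral-reef substrate implies coral association"
            )

    @property
    def category(self) -> DependenceCategory:
        """Category implied by this single row."""
        if self.live_coral_obligate:
            return DependenceCategory.CORAL_OBLIGATE
        if self.live_coral_dependent:
            return DependenceCategory.CORAL_DEPENDENT
        if self.coral_assoc:
            return DependenceCategory.REEF_ASSOCIATED
        return DependenceCategory.NOT_ASSOCIATED


@dataclass(frozen=True)
class TaxonGroup:
    """A catch-data label and the species it covers.

    ``arbitrary`` groups (e.g. a bare 'fish' bucket) may be flagged
    unclassifiable, in which case they carry no members and are routed to
    the rejects report by :func:`build_catalog`.
    """

    group_label: str
    member_species: frozenset[str] = field(default_factory=frozenset)
    resolution: GroupResolution = GroupResolution.SPECIES
    unclassifiable: bool = False

    def __post_init__(self):
        if not self.member_species and not (
            self.resolution == GroupResolution.ARBITRARY and self.unclassifiable
        ):
            raise ValueError(
                f"group {self.group_label!r}: empty member set is only allowed "
                "for arbitrary groups explicitly flagged unclassifiable"
            )


def classify_species(evidence: Iterable[HabitatEvidence]) -> DependenceCategory:
    """Classify one species from all its evidence rows.

    Returns 4 if any row records obligate live-coral dependence, else 3 if
    any records live-coral dependence, else 2 if any records coral
    association, else 1. Conflicting rows therefore resolve to the maximum
    level of evidence, mirroring the conservative group rule.

    Raises
    ------
    ClassificationError
        If the evidence set is empty (no evidence is *not* category 1).
    """
    rows = list(evidence)
    if not rows:
        raise ClassificationError("cannot classify a species with no evidence rows")
    return DependenceCategory(max(row.category for row in rows))


_FLAG_COLS = ("coral_assoc", "live_coral_dependent", "live_coral_obligate")


def classify_species_table(evidence: pd.DataFrame) -> dict[str, DependenceCategory]:
    """Vectorised :func:`classify_species` over an evidence table.

    ``evidence`` needs columns ``species_id`` plus the three boolean coral
    flags; extra columns are ignored.
    """
    missing = {"species_id", *_FLAG_COLS} - set(evidence.columns)
    if missing:
        raise DomainError(f"evidence table missing columns: {sorted(missing)}")
    if evidence.empty:
        return {}
    flags = evidence.groupby("species_id")[list(_FLAG_COLS)].any()
    cat = (
        1
        + flags["coral_assoc"].astype(int)
        + flags["live_coral_dependent"].astype(int)
        + flags["live_coral_obligate"].astype(int)
    )
    return {sp: DependenceCategory(int(c)) for sp, c in cat.items()}


def classify_group(
    member_categories: Iterable[DependenceCategory | int],
) -> DependenceCategory:
    """Highest category of any member: the conservative aggregation rule.

    A family-level catch group containing even one obligate coral feeder is
    rated obligate (category 4), because the logbook label cannot separate
    the sensitive member from the rest.
    """
    cats = [DependenceCategory(int(c)) for c in member_categories]
    if not cats:
        raise ClassificationError("cannot classify an empty group")
    return max(cats)


@dataclass
class CatalogResult:
    """Total category map over group labels, plus a rejects report."""

    categories: dict[str, DependenceCategory]
    rejects: pd.DataFrame  # columns: group_label, reason

    def __contains__(self, label: str) -> bool:
        return label in self.categories

    def __getitem__(self, label: str) -> DependenceCategory:
        return self.categories[label]


def build_catalog(
    evidence: pd.DataFrame,
    groups: Sequence[TaxonGroup] | None = None,
    overrides: Mapping[str, DependenceCategory | int] | None = None,
) -> CatalogResult:
    """Assign a dependence category to every catch label.

    Species-level categories come from the evidence table; group labels
    take the maximum over their members. ``overrides`` assign categories
    directly (used e.g. for aquarium taxa rated from prior global
    assessments, or fixed rules such as live coral itself being obligate)
    and take precedence over evidence. Labels that cannot be resolved —
    groups flagged unclassifiable, or with members lacking both evidence
    and an override — are returned in ``rejects`` with a reason, never
    silently defaulted.
    """
    overrides = {k: DependenceCategory(int(v)) for k, v in (overrides or {}).items()}
    species_cat = classify_species_table(evidence)

    categories: dict[str, DependenceCategory] = {}
    reject_rows: list[dict[str, str]] = []

    # every species with evidence is addressable under its own id
    categories.update(species_cat)

    for group in groups or []:
        label = group.group_label
        if label in overrides:
            continue  # handled below; overrides win
        if group.unclassifiable:
            reject_rows.append(
                {"group_label": label, "reason": "flagged unclassifiable (too broad)"}
            )
            continue
        missing = sorted(
            sp for sp in group.member_species
            if sp not in species_cat and sp not in overrides
        )
        if missing:
            reject_rows.append(
                {
                    "group_label": label,
                    "reason": "members without evidence or override: "
                    + ";".join(missing),
                }
            )
            continue
        member_cats = [
            overrides.get(sp, species_cat.get(sp)) for sp in group.member_species
        ]
        categories[label] = classify_group(member_cats)

    categories.update(overrides)

    rejects = pd.DataFrame(reject_rows, columns=["group_label", "reason"])
    return CatalogResult(categories=categories, rejects=rejects)


def coverage_rank(
    catch_by_taxon: Mapping[str, float], threshold_pct: float = 95.0
) -> list[str]:
    """Smallest top-catch prefix reaching ``threshold_pct`` of total catch.

    Taxa are ranked from highest to lowest catch (ties broken
    lexicographically by label) and the shortest prefix whose cumulative
    share is >= the threshold is returned. This is the selection rule used
    to decide which taxa need habitat-association review: the species and
    groups making up 95% of catch by weight for each gear type.
    """
    if not 0 < threshold_pct <= 100:
        raise DomainError("threshold_pct must be in (0, 100]")
    if any(w < 0 for w in catch_by_taxon.values()):
        raise DomainError("catch weights must be non-negative")
    total = float(sum(catch_by_taxon.values()))
    if total <= 0:
        raise DomainError("all-zero catch: coverage rank undefined")
    ranked = sorted(catch_by_taxon.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[str] = []
    cum = 0.0
    for taxon, weight in ranked:
        out.append(taxon)
        cum += weight
        if cum / total * 100.0 >= threshold_pct:
            break
    return out
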
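"""Protein record containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

from .categories import (
    CURATED_PRECEDENCE,
    UNMAPPED,
    LocationCategory,
    Qualifier,
)


@dataclass(frozen=True)
class CuratedLocation:
    """One curated subcellular-location token from a UniProt record.

    ``raw_term`` is kept verbatim so unrecognized vocabulary is never
    silently dropped; ``category`` is the mapped closed-vocabulary value or
    the ``UNMAPPED`` sentinel.
    """

    raw_term: str
    category: LocationCategory | str
    qualifier: Qualifier = Qualifier.NONE

    @property
    def is_mapped(self) -> bool:
        return self.category is not UNMAPPED


@dataclass
class ProteinRecord:
    """One protein entry: sequence plus curated annotation and provenance."""

    accession: str
    sequence: str
    entry_name: str = ""
    reviewed: bool = False
    is_fragment: bool = False
    species_name: str = ""
    taxon_id: int | None = None
    curated_locations: list[CuratedLocation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def starts_with_met(self) -> bool:
        return self.sequence[0] == "M"

    def mapped_curated_categories(self) -> list[LocationCategory]:
        """Distinct mapped curated categories, in curated precedence order.

        Co-annotation of cytoplasm and cytoskeleton collapses to
        cytoskeleton alone: curated cytoskeleton proteins are routinely also
        annotated as cytoplasm, and they belong in the cytoskeleton set.
        """
        cats = {
            loc.category
            for loc in self.curated_locations
            if isinstance(loc.category, LocationCategory)
        }
        if LocationCategory.CYTOSKELETON in cats:
            cats.discard(LocationCategory.CYTOPLASM)
        return [c for c in CURATED_PRECEDENCE if c in cats]

    def effective_curated_category(self) -> LocationCategory | None:
        """First mapped curated category by precedence, or None."""
        cats = self.mapped_curated_categories()
        return cats[0] if cats else None

    def has_qualified_location(self) -> bool:
        """True if any curated location carries a hedging qualifier."""
        return any(
            loc.qualifier is not Qualifier.NONE for loc in self.curated_locations
        )
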
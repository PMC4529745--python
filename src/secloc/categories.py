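"""Closed vocabularies for subcellular location assignment.

The category scheme distinguishes secreted (extracellular) proteins, the
major organellar compartments with membrane / non-membrane splits where a
transmembrane-helix call can separate them, GPI-anchored surface proteins,
and a residual ``OTHER_MEMBRANE`` / ``UNKNOWN`` pair for proteins the rule
cascade cannot place more precisely.
"""

from __future__ import annotations

import enum


class LocationCategory(enum.Enum):
    """One subcellular location category per protein (closed vocabulary)."""

    SECRETED = "secreted"
    MITO_MEMBRANE = "mito_membrane"
    MITO_NONMEMBRANE = "mito_nonmembrane"
    ER_MEMBRANE = "er_membrane"
    ER_LUMEN = "er_lumen"
    CYTOPLASM = "cytoplasm"
    CYTOSKELETON = "cytoskeleton"
    GOLGI_MEMBRANE = "golgi_membrane"
    GOLGI_LUMEN = "golgi_lumen"
    NUCLEAR_MEMBRANE = "nuclear_membrane"
    NUCLEAR_NONMEMBRANE = "nuclear_nonmembrane"
    VACUOLE_MEMBRANE = "vacuole_membrane"
    VACUOLE_NONMEMBRANE = "vacuole_nonmembrane"
    LYSOSOME = "lysosome"
    PEROXISOME = "peroxisome"
    PLASMA_MEMBRANE = "plasma_membrane"
    OTHER_MEMBRANE = "other_membrane"
    GPI_ANCHORED = "gpi_anchored"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Sentinel returned by the curated-vocabulary mapper for terms outside the
#: closed table. Never silently dropped; never a final assignment.
UNMAPPED = "UNMAPPED"

#: Categories whose members sit in (or span) a membrane.
MEMBRANE_CATEGORIES = frozenset(
    {
        LocationCategory.MITO_MEMBRANE,
        LocationCategory.ER_MEMBRANE,
        LocationCategory.GOLGI_MEMBRANE,
        LocationCategory.NUCLEAR_MEMBRANE,
        LocationCategory.VACUOLE_MEMBRANE,
        LocationCategory.PLASMA_MEMBRANE,
        LocationCategory.OTHER_MEMBRANE,
    }
)

#: Fixed precedence for multi-location curated records: the classifier keeps
#: the first annotated category in this order (secreted first; cytoskeleton
#: deliberately outranks cytoplasm because curated cytoskeleton entries are
#: routinely co-annotated as cytoplasm).
CURATED_PRECEDENCE: tuple[LocationCategory, ...] = (
    LocationCategory.SECRETED,
    LocationCategory.GPI_ANCHORED,
    LocationCategory.MITO_MEMBRANE,
    LocationCategory.MITO_NONMEMBRANE,
    LocationCategory.ER_MEMBRANE,
    LocationCategory.ER_LUMEN,
    LocationCategory.GOLGI_MEMBRANE,
    LocationCategory.GOLGI_LUMEN,
    LocationCategory.LYSOSOME,
    LocationCategory.PEROXISOME,
    LocationCategory.VACUOLE_MEMBRANE,
    LocationCategory.VACUOLE_NONMEMBRANE,
    LocationCategory.NUCLEAR_MEMBRANE,
    LocationCategory.NUCLEAR_NONMEMBRANE,
    LocationCategory.CYTOSKELETON,
    LocationCategory.CYTOPLASM,
    LocationCategory.PLASMA_MEMBRANE,
    LocationCategory.OTHER_MEMBRANE,
)


class SecretionTier(enum.Enum):
    """Confidence tier for secreted proteins.

    Curated entries form their own tier; predicted entries are tiered by how
    many of the four voting predictors (SignalP 4, Phobius, TargetP, WoLF
    PSORT) called them secreted: 3-4 votes = highly likely, 2 = likely,
    1 = weakly likely.
    """

    CURATED_SECRETED = "curated_secreted"
    HIGHLY_LIKELY = "highly_likely"
    LIKELY = "likely"
    WEAKLY_LIKELY = "weakly_likely"
    NOT_SECRETED = "not_secreted"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def tier_from_votes(votes: int) -> SecretionTier:
    """Map a 0-4 secretion vote count to the predicted-entry tier."""
    if not 0 <= votes <= 4:
        raise ValueError(f"vote count must be 0-4, got {votes}")
    if votes >= 3:
        return SecretionTier.HIGHLY_LIKELY
    if votes == 2:
        return SecretionTier.LIKELY
    if votes == 1:
        return SecretionTier.WEAKLY_LIKELY
    return SecretionTier.NOT_SECRETED


class Qualifier(enum.Enum):
    """Evidence qualifier attached to a curated location term."""

    NONE = "none"
    BY_SIMILARITY = "by_similarity"
    PROBABLE = "probable"
    POTENTIAL = "potential"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value
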
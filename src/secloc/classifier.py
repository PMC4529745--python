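"""Rule-based consensus assignment of protein subcellular location.

The cascade combines curated annotation with seven predictor verdicts.
Curated UniProt annotation always wins; for unannotated proteins the rules
fire in a fixed order, each terminal when it matches:

1. curated location (first category by the curated precedence list);
2. secretion: >=1 of the four voting tools (SignalP 4, Phobius, TargetP,
   WoLF PSORT) positive, AND no transmembrane helix outside the first 70
   residues, AND no C-terminal ER-retention signal. The tier reflects the
   vote count (3-4 highly likely, 2 likely, 1 weakly likely). Proteins in
   this set with a SignalP 3 signal peptide and a strong FragAnchor call
   become GPI-anchored;
3. mitochondrial: TargetP 'M' AND WoLF PSORT 'mito' (membrane split by
   TMHMM);
4. ER: WoLF PSORT 'E.R.' OR (SignalP 4 signal peptide AND ER-retention
   motif); membrane vs lumen split by TMHMM;
5. remaining WoLF PSORT compartments (cytoplasm, cytoskeleton, Golgi,
   lysosome, nucleus, peroxisome, plasma membrane, vacuole), with a
   TMHMM membrane split for Golgi / nucleus / vacuole;
6. any other protein with a transmembrane helix beyond residue 70 is
   'other membrane';
7. otherwise unknown.

Every assignment carries a reproducible ``rule_trace`` naming the rules
that fired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .categories import (
    MEMBRANE_CATEGORIES,
    LocationCategory,
    SecretionTier,
    tier_from_votes,
)
from .motif_scan import PrositePattern, ps00014, scan
from .predictor_io import (
    VOTING_TOOLS,
    GpiClass,
    PredictionBundle,
    Tool,
)
from .records import ProteinRecord

__all__ = [
    "LocationAssignment",
    "IncompleteBundleError",
    "count_secretion_votes",
    "is_membrane_by_tmhmm",
    "classify",
    "classify_all",
    "write_assignment_table",
]

#: A transmembrane helix starting at or before this residue is treated as a
#: potential signal peptide, not as evidence of a membrane protein.
NTERM_WINDOW = 70

#: WoLF PSORT labels consumed by cascade step 5 (the non-secretory,
#: non-mitochondrial, non-ER compartments).
_WOLF_STEP5: dict[str, LocationCategory] = {
    "cyto": LocationCategory.CYTOPLASM,
    "cysk": LocationCategory.CYTOSKELETON,
    "golg": LocationCategory.GOLGI_LUMEN,
    "lyso": LocationCategory.LYSOSOME,
    "nucl": LocationCategory.NUCLEAR_NONMEMBRANE,
    "pero": LocationCategory.PEROXISOME,
    "plas": LocationCategory.PLASMA_MEMBRANE,
    "vacu": LocationCategory.VACUOLE_NONMEMBRANE,
}

_WOLF_MEMBRANE_SPLIT: dict[LocationCategory, LocationCategory] = {
    LocationCategory.GOLGI_LUMEN: LocationCategory.GOLGI_MEMBRANE,
    LocationCategory.NUCLEAR_NONMEMBRANE: LocationCategory.NUCLEAR_MEMBRANE,
    LocationCategory.VACUOLE_NONMEMBRANE: LocationCategory.VACUOLE_MEMBRANE,
}


class IncompleteBundleError(ValueError):
    """Raised in strict mode when required tool verdicts are missing."""


@dataclass
class LocationAssignment:
    """Final category (+ tier, membrane and GPI flags) for one protein."""

    protein_id: str
    category: LocationCategory
    tier: SecretionTier | None
    evidence: str  # "curated" | "predicted"
    gpi_anchored: bool
    is_membrane: bool
    rule_trace: list[str] = field(default_factory=list)


def wolf_top_component(label: str | None) -> str | None:
    """First component of a (possibly dual) WoLF PSORT label.

    Dual labels like 'extr_plas' name the dominant compartment first; the
    'E.R.' label is matched whole because its dots are not separators.
    """
    if label is None:
        return None
    if label == "E.R." or label.startswith("E.R._"):
        return "E.R."
    return label.split("_")[0]


def _missing(bundle: PredictionBundle, tools: Iterable[Tool]) -> list[Tool]:
    return [t for t in tools if t not in bundle.verdicts]


def _lenient_warn(protein_id: str, tools: list[Tool]) -> None:
    warnings.warn(
        f"{protein_id}: missing verdicts from "
        f"{', '.join(t.value for t in tools)}; treated as negative",
        stacklevel=3,
    )


def count_secretion_votes(bundle: PredictionBundle, mode: str = "strict") -> int:
    """Count 0-4 positive secretion calls among the four voting tools.

    SignalP 4 and Phobius vote through their signal-peptide decision,
    TargetP through Loc == 'S', WoLF PSORT through a top label whose first
    component is 'extr'. In lenient mode a missing tool counts as a
    negative vote (with a warning); in strict mode it is an error.
    """
    missing = _missing(bundle, VOTING_TOOLS)
    if missing:
        if mode == "strict":
            raise IncompleteBundleError(
                f"{bundle.protein_id}: missing voting tools: "
                f"{', '.join(t.value for t in missing)}"
            )
        _lenient_warn(bundle.protein_id, missing)
    votes = 0
    v = bundle.get(Tool.SIGNALP4)
    votes += bool(v and v.signal_peptide)
    v = bundle.get(Tool.PHOBIUS)
    votes += bool(v and v.signal_peptide)
    v = bundle.get(Tool.TARGETP)
    votes += bool(v and v.targetp_loc == "S")
    v = bundle.get(Tool.WOLFPSORT)
    votes += bool(v and wolf_top_component(v.wolf_top_label) == "extr")
    return votes


def is_membrane_by_tmhmm(
    bundle: PredictionBundle, length: int | None = None, mode: str = "strict"
) -> bool:
    """True iff TMHMM predicts a helix starting beyond the first 70 residues.

    Helices wholly within the N-terminal window (start <= 70) are ignored:
    they are indistinguishable from signal peptides / signal anchors.
    """
    v = bundle.get(Tool.TMHMM)
    if v is None:
        if mode == "strict":
            raise IncompleteBundleError(f"{bundle.protein_id}: missing tmhmm verdict")
        _lenient_warn(bundle.protein_id, [Tool.TMHMM])
        return False
    helices = v.tm_helices or ()
    if length is not None:
        for start, end in helices:
            if end > length:
                raise ValueError(
                    f"{bundle.protein_id}: helix ({start}, {end}) beyond "
                    f"sequence length {length}"
                )
    return any(start > NTERM_WINDOW for start, _ in helices)


def _gpi_call(bundle: PredictionBundle, threshold: GpiClass) -> bool:
    sp3 = bundle.get(Tool.SIGNALP3)
    frag = bundle.get(Tool.FRAGANCHOR)
    return bool(
        sp3
        and sp3.signal_peptide
        and frag
        and frag.gpi_class is not None
        and frag.gpi_class.value >= threshold.value
    )


def classify(
    record: ProteinRecord,
    bundle: PredictionBundle,
    ps00014_hit: bool,
    *,
    mode: str = "strict",
    gpi_threshold: GpiClass = GpiClass.HIGHLY_PROBABLE,
    honor_unreviewed: bool = False,
) -> LocationAssignment:
    """Assign one subcellular location via the rule cascade.

    ``ps00014_hit`` is the precomputed C-terminal ER-retention-motif scan
    result for the record's sequence. In strict mode (default) an
    incomplete bundle is an error naming the missing tools; in lenient
    mode missing verdicts count as negative evidence.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    if mode == "strict" and not bundle.complete:
        raise IncompleteBundleError(
            f"{bundle.protein_id}: incomplete bundle; missing "
            f"{', '.join(t.value for t in bundle.missing_tools())}"
        )
    trace: list[str] = []

    # 1. curated annotation wins over any prediction
    if record.reviewed or honor_unreviewed:
        curated = record.mapped_curated_categories()
        if curated:
            category = curated[0]
            if len(curated) > 1:
                trace.append(
                    "curated_multi:" + ",".join(c.name for c in curated)
                )
            trace.append(f"curated:{category.name}")
            tier = (
                SecretionTier.CURATED_SECRETED
                if category is LocationCategory.SECRETED
                else None
            )
            return LocationAssignment(
                protein_id=record.accession,
                category=category,
                tier=tier,
                evidence="curated",
                gpi_anchored=category is LocationCategory.GPI_ANCHORED,
                is_membrane=category in MEMBRANE_CATEGORIES,
                rule_trace=trace,
            )

    votes = count_secretion_votes(bundle, mode)
    tm = is_membrane_by_tmhmm(bundle, record.length, mode)
    trace.append(f"votes={votes}")
    trace.append("tm" if tm else "no_tm")
    trace.append("kdel" if ps00014_hit else "no_kdel")

    def _done(category: LocationCategory, tier: SecretionTier | None, gpi: bool):
        return LocationAssignment(
            protein_id=record.accession,
            category=category,
            tier=tier,
            evidence="predicted",
            gpi_anchored=gpi,
            is_membrane=category in MEMBRANE_CATEGORIES,
            rule_trace=trace,
        )

    # 2. secretion with transmembrane / ER-retention exclusions
    if votes >= 1 and not tm and not ps00014_hit:
        tier = tier_from_votes(votes)
        trace.append(f"secreted_tier={tier.value}")
        if _gpi_call(bundle, gpi_threshold):
            # GPI-anchored proteins are reported as their own category,
            # outside the secretion tiers (and outside secretome totals).
            trace.append("gpi_anchor")
            return _done(LocationCategory.GPI_ANCHORED, None, True)
        return _done(LocationCategory.SECRETED, tier, False)

    # 3. mitochondrial consensus (TargetP AND WoLF PSORT)
    targetp = bundle.get(Tool.TARGETP)
    wolf = bundle.get(Tool.WOLFPSORT)
    wolf_top = wolf_top_component(wolf.wolf_top_label if wolf else None)
    if targetp and targetp.targetp_loc == "M" and wolf_top == "mito":
        trace.append("mito_consensus")
        return _done(
            LocationCategory.MITO_MEMBRANE
            if tm
            else LocationCategory.MITO_NONMEMBRANE,
            None,
            False,
        )

    # 4. ER: WoLF PSORT label OR signal peptide plus retention motif
    sp4 = bundle.get(Tool.SIGNALP4)
    if wolf_top == "E.R." or (sp4 and sp4.signal_peptide and ps00014_hit):
        trace.append("er_rule")
        return _done(
            LocationCategory.ER_MEMBRANE if tm else LocationCategory.ER_LUMEN,
            None,
            False,
        )

    # 5. remaining WoLF PSORT compartments
    if wolf_top in _WOLF_STEP5:
        category = _WOLF_STEP5[wolf_top]
        if tm and category in _WOLF_MEMBRANE_SPLIT:
            category = _WOLF_MEMBRANE_SPLIT[category]
        trace.append(f"wolf={wolf_top}")
        return _done(category, None, False)

    # 6. unexplained transmembrane protein
    if tm:
        trace.append("other_membrane")
        return _done(LocationCategory.OTHER_MEMBRANE, None, False)

    # 7. no rule fired
    trace.append("unassigned")
    return _done(LocationCategory.UNKNOWN, None, False)


def classify_all(
    records: Iterable[ProteinRecord],
    bundles: Mapping[str, PredictionBundle],
    *,
    pattern: PrositePattern | None = None,
    mode: str = "strict",
    gpi_threshold: GpiClass = GpiClass.HIGHLY_PROBABLE,
    honor_unreviewed: bool = False,
) -> list[LocationAssignment]:
    """Scan each record for the ER-retention motif and run the cascade."""
    if pattern is None:
        pattern = ps00014()
    out: list[LocationAssignment] = []
    for record in records:
        bundle = bundles.get(record.accession, PredictionBundle(record.accession))
        hit, _ = scan(record.sequence, pattern)
        out.append(
            classify(
                record,
                bundle,
                hit,
                mode=mode,
                gpi_threshold=gpi_threshold,
                honor_unreviewed=honor_unreviewed,
            )
        )
    return out


def read_assignment_table(stream) -> list[LocationAssignment]:
    """Read an assignment TSV written by :func:`write_assignment_table`."""
    import io as _io

    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    header = handle.readline().rstrip("\n").split("\t")
    expected = ["protein_id", "category", "tier", "evidence", "gpi", "membrane",
                "rule_trace"]
    if header != expected:
        raise ValueError(f"assignment table: unexpected header {header!r}")
    out = []
    for lineno, line in enumerate(handle, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"assignment table: line {lineno}: bad row")
        pid, cat, tier, evidence, gpi, mem, trace = parts
        out.append(
            LocationAssignment(
                protein_id=pid,
                category=LocationCategory(cat),
                tier=None if tier == "N/A" else SecretionTier(tier),
                evidence=evidence,
                gpi_anchored=gpi == "1",
                is_membrane=mem == "1",
                rule_trace=trace.split(";") if trace else [],
            )
        )
    return out


def write_assignment_table(
    assignments: Iterable[LocationAssignment], handle: TextIO
) -> None:
    """Write assignments as TSV (tier 'N/A' for non-secretory categories)."""
    handle.write("protein_id\tcategory\ttier\tevidence\tgpi\tmembrane\trule_trace\n")
    for a in assignments:
        tier = a.tier.value if a.tier is not None else "N/A"
        handle.write(
            f"{a.protein_id}\t{a.category.value}\t{tier}\t{a.evidence}\t"
            f"{int(a.gpi_anchored)}\t{int(a.is_membrane)}\t{';'.join(a.rule_trace)}\n"
        )
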
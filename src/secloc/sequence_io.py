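"""Sequence and curated-annotation input/output.

Reads protein FASTA and UniProt flat-text records (the Swiss-Prot/TrEMBL
dialect), extracts the SUBCELLULAR LOCATION comment block, and normalizes
the curated vocabulary into the package's closed category scheme via a
config-shipped mapping table.
"""

from __future__ import annotations

import io
import re
from importlib import resources
from typing import Iterable, TextIO

import yaml
from Bio import SeqIO, SwissProt
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .categories import UNMAPPED, LocationCategory, Qualifier
from .records import CuratedLocation, ProteinRecord

__all__ = [
    "load_term_table",
    "map_curated_term",
    "parse_curated_comment",
    "parse_fasta",
    "write_fasta",
    "parse_uniprot_flat",
    "read_id_mapping",
    "write_records_table",
]

_QUALIFIER_PHRASES = (
    ("by similarity", Qualifier.BY_SIMILARITY),
    ("probable", Qualifier.PROBABLE),
    ("potential", Qualifier.POTENTIAL),
)


def _as_stream(stream: TextIO | str) -> TextIO:
    return io.StringIO(stream) if isinstance(stream, str) else stream


# ---------------------------------------------------------------------------
# curated vocabulary
# ---------------------------------------------------------------------------

_TERM_TABLE: dict[str, LocationCategory] | None = None


def load_term_table(path: str | None = None) -> dict[str, LocationCategory]:
    """Load the curated-vocabulary mapping (packaged default or a file)."""
    if path is None:
        text = (
            resources.files("secloc.data")
            .joinpath("curated_locations.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {
        term.lower(): LocationCategory[name] for term, name in raw["terms"].items()
    }


def _default_table() -> dict[str, LocationCategory]:
    global _TERM_TABLE
    if _TERM_TABLE is None:
        _TERM_TABLE = load_term_table()
    return _TERM_TABLE


def map_curated_term(
    raw_term: str, table: dict[str, LocationCategory] | None = None
) -> LocationCategory | str:
    """Map one curated location term to a category, or ``UNMAPPED``.

    The lookup is case-insensitive and total: unrecognized vocabulary
    returns the ``UNMAPPED`` sentinel rather than raising or dropping.
    """
    if table is None:
        table = _default_table()
    return table.get(raw_term.strip().lower(), UNMAPPED)


def parse_curated_comment(
    comment: str, table: dict[str, LocationCategory] | None = None
) -> list[CuratedLocation]:
    """Split a SUBCELLULAR LOCATION comment into curated location tokens.

    The comment lists locations separated by '.', each optionally followed
    by a topology clause after ';' and evidence braces '{...}'. Free-text
    notes after ``Note=`` are ignored. Hedging phrases ('By similarity',
    'Probable', 'Potential') anywhere in a location token set its qualifier.
    """
    body = comment.split("Note=", 1)[0]
    out: list[CuratedLocation] = []
    for chunk in body.split("."):
        chunk = chunk.strip()
        if not chunk:
            continue
        low = chunk.lower()
        qualifier = Qualifier.NONE
        for phrase, qual in _QUALIFIER_PHRASES:
            if phrase in low:
                qualifier = qual
                break
        # strip evidence/qualifier braces, keep the phrase before topology
        term = re.sub(r"\{[^}]*\}", "", chunk).split(";")[0].strip().rstrip(",")
        if not term:
            continue
        out.append(
            CuratedLocation(
                raw_term=term,
                category=map_curated_term(term, table),
                qualifier=qualifier,
            )
        )
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_OS_RE = re.compile(r"\bOS=(.+?)(?=\s+[A-Z]{2}=|$)")
_OX_RE = re.compile(r"\bOX=(\d+)")


def parse_fasta(stream: TextIO | str) -> list[ProteinRecord]:
    """Read protein FASTA into bare records (sequence fields only).

    The accession is the first whitespace-delimited header token (the token
    the external predictors also key on). ``OS=`` / ``OX=`` header fields
    (the UniProt FASTA convention) populate species name and taxon id when
    present. Sequences are upper-cased and a trailing '*' stop is stripped.
    Empty input and duplicate accessions are errors.
    """
    handle = _as_stream(stream)
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession in FASTA: {acc!r}")
        seen.add(acc)
        seq = str(rec.seq).upper().rstrip("*")
        os_m = _OS_RE.search(rec.description)
        ox_m = _OX_RE.search(rec.description)
        out.append(
            ProteinRecord(
                accession=acc,
                sequence=seq,
                species_name=os_m.group(1).strip() if os_m else "",
                taxon_id=int(ox_m.group(1)) if ox_m else None,
            )
        )
    if not out:
        raise ValueError("empty FASTA input: no sequence records found")
    return out


def write_fasta(records: Iterable[ProteinRecord], handle: TextIO) -> None:
    """Write records back to FASTA (accession as the full header)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(seqs, handle, "fasta")


# ---------------------------------------------------------------------------
# UniProt flat text
# ---------------------------------------------------------------------------

def _prevalidate_flat(text: str) -> None:
    """Check record framing, reporting 1-based line numbers on failure."""
    open_line: int | None = None
    has_sq = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        tag = line[:2]
        if tag == "ID":
            if open_line is not None:
                raise ValueError(
                    f"line {lineno}: new ID line before '//' terminator of the "
                    f"record opened at line {open_line}"
                )
            open_line, has_sq = lineno, False
        elif tag == "SQ":
            has_sq = True
        elif line.startswith("//"):
            if open_line is None:
                raise ValueError(f"line {lineno}: '//' with no open record")
            if not has_sq:
                raise ValueError(
                    f"line {lineno}: record opened at line {open_line} has no "
                    "SQ block"
                )
            open_line = None
    if open_line is not None:
        raise ValueError(
            f"record opened at line {open_line} is missing its '//' terminator"
        )


def parse_uniprot_flat(
    stream: TextIO | str, table: dict[str, LocationCategory] | None = None
) -> list[ProteinRecord]:
    """Parse UniProt flat-text records into :class:`ProteinRecord`.

    The reviewed flag comes from the ID-line status token (``Reviewed`` =
    Swiss-Prot, ``Unreviewed`` = TrEMBL), the fragment flag from the DE
    ``Flags: Fragment`` marker, and curated locations from the SUBCELLULAR
    LOCATION comment. Feature (FT) lines and isoform-specific locations are
    ignored.
    """
    text = _as_stream(stream).read()
    _prevalidate_flat(text)
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SwissProt.parse(io.StringIO(text)):
        acc = rec.accessions[0]
        if acc in seen:
            raise ValueError(f"duplicate accession in UniProt input: {acc!r}")
        seen.add(acc)
        curated: list[CuratedLocation] = []
        for comment in rec.comments:
            if comment.startswith("SUBCELLULAR LOCATION:"):
                payload = comment.split(":", 1)[1].strip()
                curated.extend(parse_curated_comment(payload, table))
        taxid: int | None = None
        if rec.taxonomy_id:
            try:
                taxid = int(rec.taxonomy_id[0])
            except ValueError:
                taxid = None
        out.append(
            ProteinRecord(
                accession=acc,
                entry_name=rec.entry_name,
                reviewed=rec.data_class == "Reviewed",
                sequence=rec.sequence.upper(),
                is_fragment="Flags: Fragment" in rec.description,
                species_name=rec.organism.rstrip("."),
                taxon_id=taxid,
                curated_locations=curated,
            )
        )
    return out


def merge_curated(
    fasta_records: Iterable[ProteinRecord],
    uniprot_records: Iterable[ProteinRecord],
) -> list[ProteinRecord]:
    """Overlay curated UniProt annotation onto FASTA-derived records.

    The FASTA set defines the proteome; UniProt records matched by
    accession contribute review status, fragment flag, species and curated
    locations. UniProt accessions absent from the FASTA are an error (the
    two inputs must describe the same protein set).
    """
    by_acc = {r.accession: r for r in uniprot_records}
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in fasta_records:
        seen.add(rec.accession)
        cur = by_acc.get(rec.accession)
        if cur is None:
            out.append(rec)
            continue
        out.append(
            ProteinRecord(
                accession=rec.accession,
                entry_name=cur.entry_name,
                reviewed=cur.reviewed,
                sequence=rec.sequence,
                is_fragment=cur.is_fragment,
                species_name=cur.species_name,
                taxon_id=cur.taxon_id,
                curated_locations=list(cur.curated_locations),
            )
        )
    stray = set(by_acc) - seen
    if stray:
        raise ValueError(
            f"{len(stray)} UniProt accessions not in the FASTA set "
            f"(e.g. {sorted(stray)[:3]})"
        )
    return out


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_id_mapping(stream: TextIO | str) -> dict[str, dict[str, str]]:
    """Read a 3+-column ID-mapping TSV keyed by accession.

    Columns: accession, entry name, then one or more cross-reference ids
    (RefSeq / gi). Lines starting with '#' are skipped.
    """
    handle = _as_stream(stream)
    mapping: dict[str, dict[str, str]] = {}
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected >= 3 tab-separated columns")
        acc, entry, *xrefs = parts
        mapping[acc] = {"entry_name": entry, "xrefs": ";".join(xrefs)}
    return mapping


def write_records_table(records: Iterable[ProteinRecord], handle: TextIO) -> None:
    """Write records as a TSV (one row per protein, locations ';'-joined)."""
    handle.write(
        "accession\tentry_name\treviewed\tlength\tis_fragment\t"
        "starts_with_met\tspecies_name\ttaxon_id\tcurated_locations\n"
    )
    for r in records:
        locs = ";".join(
            f"{loc.raw_term}"
            f"[{loc.category.name if isinstance(loc.category, LocationCategory) else UNMAPPED}"
            f"/{loc.qualifier.value}]"
            for loc in r.curated_locations
        )
        handle.write(
            f"{r.accession}\t{r.entry_name}\t{int(r.reviewed)}\t{r.length}\t"
            f"{int(r.is_fragment)}\t{int(r.starts_with_met)}\t{r.species_name}\t"
            f"{r.taxon_id if r.taxon_id is not None else ''}\t{locs}\n"
        )
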
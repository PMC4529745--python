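"""Parsers for the native short-format outputs of the seven predictors.

Supported tools: SignalP 3 and 4 (secretory signal peptide + cleavage
site), TargetP (N-terminal targeting: secretory / mitochondrial / other),
Phobius (signal peptide), WoLF PSORT (k-nearest-neighbour subcellular
location with a ranked score list), TMHMM 2 (transmembrane helices) and
FragAnchor (GPI-anchor class). Only the batch short/summary layouts are
supported; fields a tool does not emit stay ``None`` — parsers never invent
defaults. Protein ids are the first whitespace-delimited FASTA header
token, matching how the predictors themselves truncate headers.
"""

from __future__ import annotations

import enum
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "Tool",
    "GpiClass",
    "ToolVerdict",
    "PredictionBundle",
    "parse_signalp",
    "parse_targetp",
    "parse_phobius",
    "parse_wolfpsort",
    "parse_tmhmm",
    "parse_fraganchor",
    "assemble_bundles",
    "write_verdict_table",
    "read_verdict_table",
]


class Tool(enum.Enum):
    SIGNALP3 = "signalp3"
    SIGNALP4 = "signalp4"
    TARGETP = "targetp"
    PHOBIUS = "phobius"
    WOLFPSORT = "wolfpsort"
    TMHMM = "tmhmm"
    FRAGANCHOR = "fraganchor"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The four tools whose positive calls count as secretion votes.
VOTING_TOOLS = (Tool.SIGNALP4, Tool.PHOBIUS, Tool.TARGETP, Tool.WOLFPSORT)


class GpiClass(enum.Enum):
    """FragAnchor qualitative GPI-anchor confidence classes."""

    HIGHLY_PROBABLE = 3
    PROBABLE = 2
    WEAKLY_PROBABLE = 1
    NONE = 0


_GPI_STRINGS = {
    "highly probable": GpiClass.HIGHLY_PROBABLE,
    "probable": GpiClass.PROBABLE,
    "weakly probable": GpiClass.WEAKLY_PROBABLE,
    "potential false positive": GpiClass.NONE,
    "none": GpiClass.NONE,
}


@dataclass
class ToolVerdict:
    """One tool's parsed verdict for one protein.

    Fields irrelevant to the emitting tool are ``None`` (printed as ``N/A``
    in the unified verdict table), never fabricated.
    """

    tool: Tool
    protein_id: str
    signal_peptide: bool | None = None
    cleavage_site: int | None = None
    targetp_loc: str | None = None  # "S" | "M" | "OTHER"
    wolf_top_label: str | None = None
    wolf_scores: tuple[tuple[str, float], ...] | None = None
    tm_helices: tuple[tuple[int, int], ...] | None = None
    gpi_class: GpiClass | None = None

    def __post_init__(self) -> None:
        if self.tm_helices is not None:
            for start, end in self.tm_helices:
                if not 1 <= start <= end:
                    raise ValueError(
                        f"{self.protein_id}: bad helix interval ({start}, {end})"
                    )


@dataclass
class PredictionBundle:
    """All collected verdicts for one protein, keyed by tool."""

    protein_id: str
    verdicts: dict[Tool, ToolVerdict] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return len(self.verdicts) == len(Tool)

    def missing_tools(self) -> list[Tool]:
        return [t for t in Tool if t not in self.verdicts]

    def get(self, tool: Tool) -> ToolVerdict | None:
        return self.verdicts.get(tool)


def _as_stream(stream: TextIO | str) -> TextIO:
    return io.StringIO(stream) if isinstance(stream, str) else stream


def _data_lines(stream: TextIO | str) -> Iterable[tuple[int, str]]:
    for lineno, line in enumerate(_as_stream(stream), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def _parse_flag(token: str, lineno: int, tool: str) -> bool:
    if token == "Y":
        return True
    if token in ("N", "0"):
        return False
    raise ValueError(f"{tool}: line {lineno}: expected Y/N flag, got {token!r}")


# ---------------------------------------------------------------------------
# SignalP
# ---------------------------------------------------------------------------

def parse_signalp(stream: TextIO | str, version: int) -> list[ToolVerdict]:
    """Parse SignalP short-format output (version 3 or 4).

    Version 3 (neural-network summary)::

        name  Cmax pos ?  Ymax pos ?  Smax pos ?  Smean ?  D ?

    where the final ``?`` column is the tool's Y/N decision. Version 4::

        name  Cmax pos  Ymax pos  Dmax pos  Smean  D  ?  Dcutoff  net

    Either way the printed decision is taken as-is and the cleavage site is
    the residue before the Ymax position (SignalP reports cleavage between
    positions p-1 and p).
    """
    if version not in (3, 4):
        raise ValueError(f"unsupported SignalP version: {version}")
    tool = Tool.SIGNALP3 if version == 3 else Tool.SIGNALP4
    out: list[ToolVerdict] = []
    for lineno, line in _data_lines(stream):
        parts = line.split()
        if version == 3:
            if len(parts) != 14:
                raise ValueError(
                    f"signalp3: line {lineno}: expected 14 columns, got {len(parts)}"
                )
            name, ypos, decision = parts[0], parts[5], parts[13]
        else:
            if len(parts) != 12:
                raise ValueError(
                    f"signalp4: line {lineno}: expected 12 columns, got {len(parts)}"
                )
            name, ypos, decision = parts[0], parts[4], parts[9]
        sp = _parse_flag(decision, lineno, tool.value)
        try:
            cleavage = int(ypos) - 1
        except ValueError as exc:
            raise ValueError(
                f"{tool.value}: line {lineno}: bad cleavage position {ypos!r}"
            ) from exc
        out.append(
            ToolVerdict(
                tool=tool,
                protein_id=name,
                signal_peptide=sp,
                cleavage_site=cleavage if sp else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# TargetP
# ---------------------------------------------------------------------------

_TARGETP_LOC = {"S": "S", "M": "M", "_": "OTHER"}


def parse_targetp(stream: TextIO | str) -> list[ToolVerdict]:
    """Parse TargetP (non-plant networks) table output.

    Data rows are ``Name Len mTP SP other Loc RC``; the Loc column is 'S'
    (secretory), 'M' (mitochondrial) or '_' (any other location). Header
    and ruler lines are skipped.
    """
    out: list[ToolVerdict] = []
    for lineno, line in _data_lines(stream):
        if line.startswith("---") or line.split()[0] in ("Name", "cutoff"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(
                f"targetp: line {lineno}: expected 7 columns, got {len(parts)}"
            )
        loc = parts[5]
        if loc not in _TARGETP_LOC:
            raise ValueError(f"targetp: line {lineno}: unknown Loc symbol {loc!r}")
        out.append(
            ToolVerdict(
                tool=Tool.TARGETP, protein_id=parts[0], targetp_loc=_TARGETP_LOC[loc]
            )
        )
    return out


# ---------------------------------------------------------------------------
# Phobius
# ---------------------------------------------------------------------------

def parse_phobius(stream: TextIO | str) -> list[ToolVerdict]:
    """Parse Phobius short-format output.

    Data rows are ``id  TM  SP  prediction`` with SP printed as 'Y' or '0'.
    The transmembrane-segment count is parsed but membrane decisions are
    taken from TMHMM downstream.
    """
    out: list[ToolVerdict] = []
    for lineno, line in _data_lines(stream):
        parts = line.split()
        if parts[0] in ("SEQENCE", "SEQUENCE"):  # header (Phobius misspells it)
            continue
        if len(parts) != 4:
            raise ValueError(
                f"phobius: line {lineno}: expected 4 columns, got {len(parts)}"
            )
        try:
            int(parts[1])
        except ValueError as exc:
            raise ValueError(
                f"phobius: line {lineno}: bad TM count {parts[1]!r}"
            ) from exc
        out.append(
            ToolVerdict(
                tool=Tool.PHOBIUS,
                protein_id=parts[0],
                signal_peptide=_parse_flag(parts[2], lineno, "phobius"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# WoLF PSORT
# ---------------------------------------------------------------------------

def parse_wolfpsort(stream: TextIO | str) -> list[ToolVerdict]:
    """Parse WoLF PSORT summary output.

    Each data line is ``id label1 score1, label2 score2, ...`` with labels
    ordered by decreasing score. Dual labels ('extr_plas') are preserved
    verbatim; downstream consumers split on '_'. An empty or unsorted score
    list is an error.
    """
    out: list[ToolVerdict] = []
    for lineno, line in _data_lines(stream):
        name, _, rest = line.partition(" ")
        if rest.strip() == "details":  # optional header variant
            continue
        pairs: list[tuple[str, float]] = []
        for item in rest.split(","):
            item = item.strip()
            if not item:
                continue
            try:
                label, score = item.split()
                pairs.append((label, float(score)))
            except ValueError as exc:
                raise ValueError(
                    f"wolfpsort: line {lineno}: bad 'label score' pair {item!r}"
                ) from exc
        if not pairs:
            raise ValueError(f"wolfpsort: line {lineno}: empty score list for {name!r}")
        scores = [s for _, s in pairs]
        if scores != sorted(scores, reverse=True):
            raise ValueError(
                f"wolfpsort: line {lineno}: scores not sorted in decreasing order"
            )
        out.append(
            ToolVerdict(
                tool=Tool.WOLFPSORT,
                protein_id=name,
                wolf_top_label=pairs[0][0],
                wolf_scores=tuple(pairs),
            )
        )
    return out


# ---------------------------------------------------------------------------
# TMHMM
# ---------------------------------------------------------------------------

_HELIX_RE = re.compile(r"[io](\d+)-(\d+)")


def parse_tmhmm(stream: TextIO | str) -> list[ToolVerdict]:
    """Parse TMHMM 2 one-line (short) output.

    Lines look like::

        id  len=500  ExpAA=44.6  First60=0.0  PredHel=2  Topology=o120-142i200-222o

    Helix intervals are kept 1-based inclusive (the tool's native
    convention). A PredHel count that disagrees with the helices parsed
    from the topology string is an error.
    """
    out: list[ToolVerdict] = []
    for lineno, line in _data_lines(stream):
        parts = line.split()
        fields = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
        if "PredHel" not in fields or "Topology" not in fields:
            raise ValueError(
                f"tmhmm: line {lineno}: missing PredHel/Topology field"
            )
        pred_hel = int(fields["PredHel"])
        helices = tuple(
            (int(a), int(b)) for a, b in _HELIX_RE.findall(fields["Topology"])
        )
        if len(helices) != pred_hel:
            raise ValueError(
                f"tmhmm: line {lineno}: PredHel={pred_hel} but "
                f"{len(helices)} helices parsed from topology"
            )
        out.append(
            ToolVerdict(tool=Tool.TMHMM, protein_id=parts[0], tm_helices=helices)
        )
    return out


# ---------------------------------------------------------------------------
# FragAnchor
# ---------------------------------------------------------------------------

def parse_fraganchor(stream: TextIO | str) -> list[ToolVerdict]:
    """Parse FragAnchor output: ``id<TAB>qualitative class`` rows.

    Classes are 'Highly probable', 'Probable', 'Weakly probable' and
    'Potential false positive' (the last meaning no credible GPI anchor).
    """
    out: list[ToolVerdict] = []
    for lineno, line in _data_lines(stream):
        try:
            name, klass = line.split("\t")
        except ValueError as exc:
            raise ValueError(
                f"fraganchor: line {lineno}: expected 'id<TAB>class'"
            ) from exc
        key = klass.strip().lower()
        if key not in _GPI_STRINGS:
            raise ValueError(
                f"fraganchor: line {lineno}: unknown class string {klass!r}"
            )
        out.append(
            ToolVerdict(
                tool=Tool.FRAGANCHOR, protein_id=name, gpi_class=_GPI_STRINGS[key]
            )
        )
    return out


# ---------------------------------------------------------------------------
# bundles and the unified verdict table
# ---------------------------------------------------------------------------

def assemble_bundles(
    verdicts: Iterable[ToolVerdict],
) -> dict[str, PredictionBundle]:
    """Group verdicts per protein; incompleteness is a flag, not an error."""
    bundles: dict[str, PredictionBundle] = {}
    for v in verdicts:
        bundle = bundles.setdefault(v.protein_id, PredictionBundle(v.protein_id))
        bundle.verdicts[v.tool] = v
    return bundles


_NA = "N/A"


def _serialize_field(value) -> str:
    if value is None:
        return _NA
    if isinstance(value, bool):
        return "Y" if value else "N"
    if isinstance(value, GpiClass):
        return value.name
    if isinstance(value, tuple):
        return ";".join(
            f"{a}:{b}" if not isinstance(a, int) else f"{a}-{b}" for a, b in value
        )
    return str(value)


_FIELDS = (
    "signal_peptide",
    "cleavage_site",
    "targetp_loc",
    "wolf_top_label",
    "wolf_scores",
    "tm_helices",
    "gpi_class",
)


def write_verdict_table(verdicts: Iterable[ToolVerdict], handle: TextIO) -> None:
    """Write verdicts to the unified long-format TSV (id, tool, field, value)."""
    handle.write("protein_id\ttool\tfield\tvalue\n")
    for v in verdicts:
        for name in _FIELDS:
            value = getattr(v, name)
            if value is None:
                continue
            handle.write(
                f"{v.protein_id}\t{v.tool.value}\t{name}\t{_serialize_field(value)}\n"
            )


def read_verdict_table(stream: TextIO | str) -> list[ToolVerdict]:
    """Read the unified verdict TSV back into :class:`ToolVerdict` objects."""
    handle = _as_stream(stream)
    header = handle.readline()
    if not header.startswith("protein_id\t"):
        raise ValueError("verdict table: missing header line")
    staged: dict[tuple[str, Tool], dict[str, object]] = {}
    order: list[tuple[str, Tool]] = []
    for lineno, line in enumerate(handle, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        try:
            pid, tool_s, name, value = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"verdict table: line {lineno}: bad row") from exc
        key = (pid, Tool(tool_s))
        if key not in staged:
            staged[key] = {}
            order.append(key)
        staged[key][name] = _deserialize_field(name, value)
    return [
        ToolVerdict(tool=tool, protein_id=pid, **fields)  # type: ignore[arg-type]
        for (pid, tool), fields in ((k, staged[k]) for k in order)
    ]


def _deserialize_field(name: str, value: str):
    if value == _NA:
        return None
    if name == "signal_peptide":
        return value == "Y"
    if name == "cleavage_site":
        return int(value)
    if name == "gpi_class":
        return GpiClass[value]
    if name == "wolf_scores":
        return tuple(
            (lab, float(s))
            for lab, s in (item.rsplit(":", 1) for item in value.split(";"))
        )
    if name == "tm_helices":
        if not value:
            return ()
        return tuple(
            (int(a), int(b)) for a, b in (item.split("-") for item in value.split(";"))
        )
    return value
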
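"""Synthetic proteomes with known truth and matching predictor outputs.

The generator plants a ground-truth subcellular category per protein,
builds a random sequence consistent with it (methionine start, a KDEL-type
C-terminus for ER-luminal truth, transmembrane helices beyond residue 70
for membrane truth), derives the seven tools' ideal verdicts from the
truth, and then passes each verdict through an independent per-tool error
channel (configurable false-positive / false-negative rates). Errors are
injected at the verdict level, not by simulating sequence biology: the
unit under test is the rule cascade and the evaluation machinery, not the
predictors themselves.

A configurable fraction of proteins carries curated UniProt annotation
instead (reviewed records), including hedged qualifiers, multi-location
comments, fragment flags, non-methionine starts and short sequences so the
benchmark filters are exercised. Secondary locations in multi-location
records always rank below the truth category in the curated precedence
list, so the cascade still recovers the truth.

Identical seeds give byte-identical output files, and every emitted file
round-trips through the package's own parsers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .categories import CURATED_PRECEDENCE, LocationCategory, SecretionTier
from .motif_scan import ps00014, scan
from .predictor_io import GpiClass, PredictionBundle, Tool, ToolVerdict, assemble_bundles
from .records import ProteinRecord
from .sequence_io import parse_curated_comment

__all__ = ["SimulationConfig", "SimulatedDataset", "generate", "truth_benchmark"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Truth categories whose proteins carry a transmembrane helix beyond
#: residue 70 (and therefore need a long enough sequence).
_MEMBRANE_TRUTH = frozenset(
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

_CURATED_TERM = {
    LocationCategory.SECRETED: "Secreted",
    LocationCategory.MITO_MEMBRANE: "Mitochondrion inner membrane",
    LocationCategory.MITO_NONMEMBRANE: "Mitochondrion",
    LocationCategory.ER_MEMBRANE: "Endoplasmic reticulum membrane",
    LocationCategory.ER_LUMEN: "Endoplasmic reticulum lumen",
    LocationCategory.CYTOPLASM: "Cytoplasm",
    LocationCategory.CYTOSKELETON: "Cytoplasm, cytoskeleton",
    LocationCategory.GOLGI_MEMBRANE: "Golgi apparatus membrane",
    LocationCategory.GOLGI_LUMEN: "Golgi apparatus",
    LocationCategory.NUCLEAR_MEMBRANE: "Nucleus membrane",
    LocationCategory.NUCLEAR_NONMEMBRANE: "Nucleus",
    LocationCategory.VACUOLE_MEMBRANE: "Vacuole membrane",
    LocationCategory.VACUOLE_NONMEMBRANE: "Vacuole",
    LocationCategory.LYSOSOME: "Lysosome",
    LocationCategory.PEROXISOME: "Peroxisome",
    LocationCategory.PLASMA_MEMBRANE: "Cell membrane",
    LocationCategory.OTHER_MEMBRANE: "Membrane",
    LocationCategory.GPI_ANCHORED: "GPI-anchor",
}

#: Default category mix: roughly the per-species averages seen across
#: animal proteomes (cytoplasm ~31%, nucleus ~30%, plasma membrane ~12%,
#: secreted ~8%, mitochondria ~6%), with small organellar classes and an
#: unassignable remainder.
DEFAULT_MIX: dict[LocationCategory, float] = {
    LocationCategory.SECRETED: 0.08,
    LocationCategory.CYTOPLASM: 0.31,
    LocationCategory.NUCLEAR_NONMEMBRANE: 0.28,
    LocationCategory.NUCLEAR_MEMBRANE: 0.02,
    LocationCategory.PLASMA_MEMBRANE: 0.12,
    LocationCategory.MITO_NONMEMBRANE: 0.04,
    LocationCategory.MITO_MEMBRANE: 0.02,
    LocationCategory.CYTOSKELETON: 0.01,
    LocationCategory.ER_LUMEN: 0.01,
    LocationCategory.ER_MEMBRANE: 0.01,
    LocationCategory.GOLGI_LUMEN: 0.005,
    LocationCategory.GOLGI_MEMBRANE: 0.005,
    LocationCategory.LYSOSOME: 0.005,
    LocationCategory.PEROXISOME: 0.005,
    LocationCategory.VACUOLE_NONMEMBRANE: 0.0025,
    LocationCategory.VACUOLE_MEMBRANE: 0.0025,
    LocationCategory.GPI_ANCHORED: 0.01,
    LocationCategory.OTHER_MEMBRANE: 0.03,
    LocationCategory.UNKNOWN: 0.035,
}

#: Error-channel keys understood by the generator (all default 0):
#: '<tool>.fn' drops a true positive signal, '<tool>.fp' fabricates one;
#: 'targetp.fp_s' / 'targetp.fp_m' turn an 'other' call into S / M;
#: 'wolf.err' replaces the top label with a wrong compartment;
#: 'wolf.fp_mito' replaces a non-mito label with 'mito'.
ERROR_KEYS = (
    "signalp3.fn", "signalp3.fp", "signalp4.fn", "signalp4.fp",
    "phobius.fn", "phobius.fp", "targetp.fn", "targetp.fp_s", "targetp.fp_m",
    "wolf.err", "wolf.fp_mito", "tmhmm.fn", "tmhmm.fp",
    "fraganchor.fn", "fraganchor.fp",
)


@dataclass
class SimulationConfig:
    n_proteins: int = 1000
    category_mix: dict[LocationCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_MIX)
    )
    per_tool_error: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    length_range: tuple[int, int] = (100, 400)
    n_species: int = 1
    curated_fraction: float = 0.1
    #: among curated records: fractions given a hedged qualifier, a second
    #: location, a fragment flag, a non-Met start, or a short sequence
    inject_qualifier: float = 0.05
    inject_multiloc: float = 0.05
    inject_fragment: float = 0.03
    inject_nonmet: float = 0.03
    inject_short: float = 0.03
    #: fraction of secreted-truth proteins given an N-terminal (start <= 70)
    #: TMHMM helix, which must NOT block the secretion call
    nterm_helix_frac: float = 0.1

    def validate(self) -> None:
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix sums to {total}, expected 1")
        for key, p in self.per_tool_error.items():
            if key not in ERROR_KEYS:
                raise ValueError(f"unknown error channel {key!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"error rate {key}={p} outside [0, 1]")
        lmin, lmax = self.length_range
        if lmin < 10 or lmax < lmin:
            raise ValueError(f"bad length_range {self.length_range}")
        if lmax < 120 and any(
            self.category_mix.get(c, 0) > 0 for c in _MEMBRANE_TRUTH
        ):
            raise ValueError(
                "impossible mix: membrane-truth proteins need sequences of "
                f">= 120 residues, but length_range max is {lmax}"
            )
        if self.n_proteins < 1 or self.n_species < 1:
            raise ValueError("n_proteins and n_species must be >= 1")


@dataclass
class SimulatedDataset:
    """Generated records, verdicts, truth table and serialized files."""

    config: SimulationConfig
    records: list[ProteinRecord]
    verdicts: list[ToolVerdict]
    truth: pd.DataFrame  # protein_id, category, tier
    files: dict[str, str]  # filename -> text content

    def bundles(self) -> dict[str, PredictionBundle]:
        return assemble_bundles(self.verdicts)

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, text in self.files.items():
            path = outdir / name
            path.write_text(text)
            written.append(path)
        return written


def truth_benchmark(truth: pd.DataFrame) -> dict[LocationCategory, set[str]]:
    """Truth table as a category -> protein-id set map (for evaluation)."""
    out: dict[LocationCategory, set[str]] = {}
    for cat_value, group in truth.groupby("category"):
        out[LocationCategory(cat_value)] = set(group["protein_id"])
    return out


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(rng.choice(_AA, size=length - 1))


def _flip(rng: np.random.Generator, p: float) -> bool:
    return p > 0 and rng.random() < p


@dataclass
class _Plan:
    """Per-protein ground truth before error channels."""

    pid: str
    category: LocationCategory
    sequence: str
    helices: tuple[tuple[int, int], ...]
    sp_positive: bool  # carries a secretory signal peptide
    cleavage: int
    targetp_loc: str
    wolf_label: str
    gpi: GpiClass
    curated_terms: list[str]
    qualifier: bool
    fragment: bool
    taxon: int
    species: str
    tier: SecretionTier | None


_WOLF_BASE = {
    LocationCategory.SECRETED: "extr",
    LocationCategory.GPI_ANCHORED: "extr",
    LocationCategory.MITO_NONMEMBRANE: "mito",
    LocationCategory.MITO_MEMBRANE: "mito",
    LocationCategory.ER_LUMEN: "E.R.",
    LocationCategory.ER_MEMBRANE: "E.R.",
    LocationCategory.CYTOPLASM: "cyto",
    LocationCategory.CYTOSKELETON: "cysk",
    LocationCategory.GOLGI_LUMEN: "golg",
    LocationCategory.GOLGI_MEMBRANE: "golg",
    LocationCategory.LYSOSOME: "lyso",
    LocationCategory.NUCLEAR_NONMEMBRANE: "nucl",
    LocationCategory.NUCLEAR_MEMBRANE: "nucl",
    LocationCategory.PEROXISOME: "pero",
    LocationCategory.PLASMA_MEMBRANE: "plas",
    LocationCategory.VACUOLE_NONMEMBRANE: "vacu",
    LocationCategory.VACUOLE_MEMBRANE: "vacu",
    LocationCategory.OTHER_MEMBRANE: "extr_plas",  # signal-anchor-like dual
    LocationCategory.UNKNOWN: "mito_nucl",  # uninformative dual label
}


def _plan_protein(
    rng: np.random.Generator, cfg: SimulationConfig, i: int,
    category: LocationCategory, curated: bool,
) -> _Plan:
    pid = f"SYN{i:06d}"
    lmin, lmax = cfg.length_range
    membrane = category in _MEMBRANE_TRUTH
    short = (
        curated
        and not membrane
        and category is not LocationCategory.ER_LUMEN
        and _flip(rng, cfg.inject_short)
    )
    if short:
        length = int(rng.integers(25, 65))
    elif membrane:
        length = int(rng.integers(max(lmin, 130), lmax + 1))
    else:
        length = int(rng.integers(lmin, lmax + 1))
    seq = _random_sequence(rng, length)

    # ER-luminal proteins end in a KDEL-type retention signal; everything
    # else must not spuriously match the C-terminal motif.
    if category is LocationCategory.ER_LUMEN:
        seq = seq[:-4] + "KDEL"
    elif scan(seq, ps00014())[0]:
        seq = seq[:-1] + "G"

    helices: tuple[tuple[int, int], ...] = ()
    if membrane:
        start = int(rng.integers(75, length - 22))
        helices = ((start, start + 21),)
    secretory = category in (LocationCategory.SECRETED, LocationCategory.GPI_ANCHORED)
    if secretory and _flip(rng, cfg.nterm_helix_frac):
        helices = ((7, 29),)  # signal-anchor-like, inside the N-terminal window

    curated_terms: list[str] = []
    qualifier = fragment = False
    if curated and category in _CURATED_TERM:
        curated_terms = [_CURATED_TERM[category]]
        if (
            category is not LocationCategory.OTHER_MEMBRANE
            and _flip(rng, cfg.inject_multiloc)
        ):
            # a secondary location strictly after the truth in precedence
            curated_terms.append(_CURATED_TERM[LocationCategory.OTHER_MEMBRANE])
        qualifier = _flip(rng, cfg.inject_qualifier)
        fragment = _flip(rng, cfg.inject_fragment)
        if _flip(rng, cfg.inject_nonmet):
            seq = "A" + seq[1:]

    k = int(rng.integers(0, cfg.n_species))
    if curated and category is LocationCategory.SECRETED:
        tier: SecretionTier | None = SecretionTier.CURATED_SECRETED
    elif not curated and category is LocationCategory.SECRETED:
        tier = SecretionTier.HIGHLY_LIKELY
    else:
        tier = None
    return _Plan(
        pid=pid,
        category=category,
        sequence=seq,
        helices=helices,
        sp_positive=secretory,
        cleavage=int(rng.integers(16, 31)),
        targetp_loc=(
            "S"
            if secretory
            else "M"
            if category
            in (LocationCategory.MITO_MEMBRANE, LocationCategory.MITO_NONMEMBRANE)
            else "OTHER"
        ),
        wolf_label=_WOLF_BASE[category],
        gpi=GpiClass.HIGHLY_PROBABLE
        if category is LocationCategory.GPI_ANCHORED
        else GpiClass.NONE,
        curated_terms=curated_terms,
        qualifier=qualifier,
        fragment=fragment,
        taxon=900001 + k,
        species=f"Synthetica exempli {k + 1}",
        tier=tier,
    )


def _noisy_verdicts(
    rng: np.random.Generator, cfg: SimulationConfig, plan: _Plan
) -> dict[Tool, ToolVerdict]:
    err = cfg.per_tool_error.get
    out: dict[Tool, ToolVerdict] = {}

    for tool, fn_key, fp_key in (
        (Tool.SIGNALP3, "signalp3.fn", "signalp3.fp"),
        (Tool.SIGNALP4, "signalp4.fn", "signalp4.fp"),
        (Tool.PHOBIUS, "phobius.fn", "phobius.fp"),
    ):
        sp = plan.sp_positive
        if sp and _flip(rng, err(fn_key, 0.0)):
            sp = False
        elif not sp and _flip(rng, err(fp_key, 0.0)):
            sp = True
        out[tool] = ToolVerdict(
            tool=tool,
            protein_id=plan.pid,
            signal_peptide=sp,
            cleavage_site=plan.cleavage if sp else None,
        )

    loc = plan.targetp_loc
    if loc in ("S", "M") and _flip(rng, err("targetp.fn", 0.0)):
        loc = "OTHER"
    elif loc == "OTHER":
        u = rng.random()
        fp_s, fp_m = err("targetp.fp_s", 0.0), err("targetp.fp_m", 0.0)
        if u < fp_s:
            loc = "S"
        elif u < fp_s + fp_m:
            loc = "M"
    out[Tool.TARGETP] = ToolVerdict(
        tool=Tool.TARGETP, protein_id=plan.pid, targetp_loc=loc
    )

    label = plan.wolf_label
    if _flip(rng, err("wolf.err", 0.0)):
        label = "nucl" if label.startswith("cyto") else "cyto"
    if not label.startswith("mito") and _flip(rng, err("wolf.fp_mito", 0.0)):
        label = "mito"
    second = "plas" if label != "plas" else "nucl"
    out[Tool.WOLFPSORT] = ToolVerdict(
        tool=Tool.WOLFPSORT,
        protein_id=plan.pid,
        wolf_top_label=label,
        wolf_scores=((label, 25.0), (second, 5.0)),
    )

    helices = plan.helices
    if helices and _flip(rng, err("tmhmm.fn", 0.0)):
        helices = ()
    elif (
        not helices
        and len(plan.sequence) >= 130
        and _flip(rng, err("tmhmm.fp", 0.0))
    ):
        helices = ((101, 123),)
    out[Tool.TMHMM] = ToolVerdict(
        tool=Tool.TMHMM, protein_id=plan.pid, tm_helices=helices
    )

    gpi = plan.gpi
    if gpi is not GpiClass.NONE and _flip(rng, err("fraganchor.fn", 0.0)):
        gpi = GpiClass.NONE
    elif gpi is GpiClass.NONE and _flip(rng, err("fraganchor.fp", 0.0)):
        gpi = GpiClass.HIGHLY_PROBABLE
    out[Tool.FRAGANCHOR] = ToolVerdict(
        tool=Tool.FRAGANCHOR, protein_id=plan.pid, gpi_class=gpi
    )
    return out


# ---------------------------------------------------------------------------
# serialization into the native tool dialects
# ---------------------------------------------------------------------------

def _fasta_text(plans: list[_Plan]) -> str:
    lines = []
    for p in plans:
        lines.append(f">{p.pid} synthetic protein OS={p.species} OX={p.taxon}")
        for i in range(0, len(p.sequence), 60):
            lines.append(p.sequence[i : i + 60])
    return "\n".join(lines) + "\n"


def _uniprot_text(plans: list[_Plan]) -> str:
    blocks = []
    for p in plans:
        if not p.curated_terms:
            continue
        terms = []
        for j, term in enumerate(p.curated_terms):
            if j == 0 and p.qualifier:
                terms.append(f"{term} {{Probable}}")
            else:
                terms.append(term)
        cc = ". ".join(terms) + "."
        lines = [
            f"ID   {p.pid}_SYNTH             Reviewed;         {len(p.sequence)} AA.",
            f"AC   {p.pid};",
            f"DE   RecName: Full=Synthetic protein {p.pid};",
        ]
        if p.fragment:
            lines.append("DE   Flags: Fragment;")
        lines += [
            f"OS   {p.species}.",
            f"OX   NCBI_TaxID={p.taxon};",
            f"CC   -!- SUBCELLULAR LOCATION: {cc}",
            f"SQ   SEQUENCE   {len(p.sequence)} AA;  {len(p.sequence) * 110} MW;"
            "  0000000000000000 CRC64;",
        ]
        seq = p.sequence
        for i in range(0, len(seq), 60):
            chunk = seq[i : i + 60]
            lines.append(
                "     " + " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
            )
        lines.append("//")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + ("\n" if blocks else "")


def _signalp3_text(verdicts: dict[str, dict[Tool, ToolVerdict]]) -> str:
    lines = ["# SignalP-NN euk predictions (short format)"]
    for pid, vmap in verdicts.items():
        v = vmap[Tool.SIGNALP3]
        flag = "Y" if v.signal_peptide else "N"
        ypos = (v.cleavage_site or 11) + 1
        lines.append(
            f"{pid}  0.800  {ypos} {flag}  0.750  {ypos} {flag}  "
            f"0.900  {max(ypos - 5, 1)} {flag}  0.850 {flag}  0.820 {flag}"
        )
    return "\n".join(lines) + "\n"


def _signalp4_text(verdicts: dict[str, dict[Tool, ToolVerdict]]) -> str:
    lines = [
        "# SignalP-4.1 euk predictions",
        "# name Cmax pos Ymax pos Dmax pos Smean D ? Dmaxcut Networks-used",
    ]
    for pid, vmap in verdicts.items():
        v = vmap[Tool.SIGNALP4]
        flag = "Y" if v.signal_peptide else "N"
        ypos = (v.cleavage_site or 11) + 1
        lines.append(
            f"{pid}  0.500 {ypos}  0.520 {ypos}  0.540 {ypos}  0.480  0.510 "
            f"{flag}  0.450  SignalP-noTM"
        )
    return "\n".join(lines) + "\n"


def _targetp_text(
    verdicts: dict[str, dict[Tool, ToolVerdict]], lengths: dict[str, int]
) -> str:
    lines = [
        "# TargetP 1.1 predictions (non-plant networks)",
        "Name                  Len            mTP     SP  other  Loc  RC",
        "----------------------------------------------------------------------",
    ]
    loc_symbol = {"S": "S", "M": "M", "OTHER": "_"}
    for pid, vmap in verdicts.items():
        v = vmap[Tool.TARGETP]
        sym = loc_symbol[v.targetp_loc]
        mtp = 0.800 if sym == "M" else 0.100
        sp = 0.850 if sym == "S" else 0.080
        other = 0.900 if sym == "_" else 0.050
        lines.append(
            f"{pid}  {lengths[pid]}  {mtp:.3f}  {sp:.3f}  {other:.3f}  {sym}  2"
        )
    return "\n".join(lines) + "\n"


def _phobius_text(
    verdicts: dict[str, dict[Tool, ToolVerdict]], plans: dict[str, _Plan]
) -> str:
    lines = ["SEQENCE ID                     TM SP PREDICTION"]
    for pid, vmap in verdicts.items():
        v = vmap[Tool.PHOBIUS]
        sp = "Y" if v.signal_peptide else "0"
        ntm = len(plans[pid].helices)
        topo = "n4-15c20/21o" if v.signal_peptide else "o"
        lines.append(f"{pid}  {ntm}  {sp}  {topo}")
    return "\n".join(lines) + "\n"


def _wolfpsort_text(verdicts: dict[str, dict[Tool, ToolVerdict]]) -> str:
    lines = ["# k used for kNN is 27"]
    for pid, vmap in verdicts.items():
        v = vmap[Tool.WOLFPSORT]
        pairs = ", ".join(f"{label} {score:g}" for label, score in v.wolf_scores)
        lines.append(f"{pid} {pairs}")
    return "\n".join(lines) + "\n"


def _tmhmm_text(
    verdicts: dict[str, dict[Tool, ToolVerdict]], lengths: dict[str, int]
) -> str:
    lines = []
    for pid, vmap in verdicts.items():
        v = vmap[Tool.TMHMM]
        helices = v.tm_helices or ()
        topo = "o"
        for j, (start, end) in enumerate(helices):
            topo += f"{start}-{end}" + ("i" if j % 2 == 0 else "o")
        exp = sum(end - start + 1 for start, end in helices)
        lines.append(
            f"{pid}\tlen={lengths[pid]}\tExpAA={exp:.2f}\tFirst60=0.00\t"
            f"PredHel={len(helices)}\tTopology={topo}"
        )
    return "\n".join(lines) + "\n"


_GPI_TEXT = {
    GpiClass.HIGHLY_PROBABLE: "Highly probable",
    GpiClass.PROBABLE: "Probable",
    GpiClass.WEAKLY_PROBABLE: "Weakly probable",
    GpiClass.NONE: "Potential false positive",
}


def _fraganchor_text(verdicts: dict[str, dict[Tool, ToolVerdict]]) -> str:
    lines = ["# FragAnchor NN-HMM GPI anchor predictions"]
    for pid, vmap in verdicts.items():
        lines.append(f"{pid}\t{_GPI_TEXT[vmap[Tool.FRAGANCHOR].gpi_class]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def generate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a synthetic dataset under the configured study conditions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    categories = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in categories], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(categories), size=config.n_proteins, p=probs)

    plans: list[_Plan] = []
    for i, k in enumerate(draws, start=1):
        category = categories[int(k)]
        curated = (
            category is not LocationCategory.UNKNOWN
            and _flip(rng, config.curated_fraction)
        )
        plans.append(_plan_protein(rng, config, i, category, curated))

    verdict_map: dict[str, dict[Tool, ToolVerdict]] = {}
    for plan in plans:
        verdict_map[plan.pid] = _noisy_verdicts(rng, config, plan)

    records = [
        ProteinRecord(
            accession=p.pid,
            entry_name=f"{p.pid}_SYNTH",
            reviewed=bool(p.curated_terms),
            sequence=p.sequence,
            is_fragment=p.fragment,
            species_name=p.species,
            taxon_id=p.taxon,
            curated_locations=parse_curated_comment(
                ". ".join(
                    f"{t} {{Probable}}" if (j == 0 and p.qualifier) else t
                    for j, t in enumerate(p.curated_terms)
                )
                + "."
            )
            if p.curated_terms
            else [],
        )
        for p in plans
    ]
    truth = pd.DataFrame(
        {
            "protein_id": [p.pid for p in plans],
            "category": [p.category.value for p in plans],
            "tier": [p.tier.value if p.tier else "N/A" for p in plans],
        }
    )
    lengths = {p.pid: len(p.sequence) for p in plans}
    plan_map = {p.pid: p for p in plans}
    files = {
        "proteins.fasta": _fasta_text(plans),
        "curated.dat": _uniprot_text(plans),
        "signalp3.txt": _signalp3_text(verdict_map),
        "signalp4.txt": _signalp4_text(verdict_map),
        "targetp.txt": _targetp_text(verdict_map, lengths),
        "phobius.txt": _phobius_text(verdict_map, plan_map),
        "wolfpsort.txt": _wolfpsort_text(verdict_map),
        "tmhmm.txt": _tmhmm_text(verdict_map, lengths),
        "fraganchor.txt": _fraganchor_text(verdict_map),
        "truth.tsv": truth.to_csv(sep="\t", index=False),
    }
    verdicts = [v for vmap in verdict_map.values() for v in vmap.values()]
    return SimulatedDataset(
        config=replace(config),
        records=records,
        verdicts=verdicts,
        truth=truth,
        files=files,
    )
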
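"""Benchmark construction and Sn / Sp / MCC evaluation.

The benchmark is built from reviewed records carrying exactly one
unambiguous curated location: entries with multiple locations, hedged
qualifiers ('By similarity', 'Probable', 'Potential'), fragment flags, a
non-methionine start or fewer than 70 residues are excluded, with a tally
of exclusion reasons. Each category is then scored one-vs-rest over the
whole retained set with

    sensitivity (%) = TP / (TP + FN) * 100
    specificity (%) = TN / (TN + FP) * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is reported on the -1..1 scale. Display rounding is half-up to one
decimal for the percentages and two for MCC.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Callable, Iterable, Mapping

import pandas as pd

from .categories import LocationCategory
from .classifier import (
    count_secretion_votes,
    is_membrane_by_tmhmm,
    wolf_top_component,
)
from .predictor_io import GpiClass, PredictionBundle, Tool
from .records import ProteinRecord

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "UndefinedMetricError",
    "build_benchmark",
    "confusion",
    "sensitivity",
    "specificity",
    "mcc",
    "metric_set",
    "compile_rule",
    "evaluate_rule",
    "load_reference_counts",
]

#: Minimum sequence length for a benchmark protein.
MIN_BENCHMARK_LENGTH = 70


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator (or an MCC marginal) is zero."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def actual_positives(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negatives(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Rounded display metrics; ``mcc`` is None when undefined."""

    sensitivity: float
    specificity: float
    mcc: float | None


def round_half_up(value: float | Decimal, ndigits: int) -> float:
    """Decimal half-up rounding (display convention for all reports)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value) if not isinstance(value, Decimal) else value)
                 .quantize(q, rounding=ROUND_HALF_UP))


def sensitivity(cm: ConfusionMatrix, ndigits: int = 1) -> float:
    """TP / (TP + FN) as a percentage, half-up rounded."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no actual positives")
    return round_half_up(Decimal(cm.tp * 100) / Decimal(cm.tp + cm.fn), ndigits)


def specificity(cm: ConfusionMatrix, ndigits: int = 1) -> float:
    """TN / (TN + FP) as a percentage, half-up rounded."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no actual negatives")
    return round_half_up(Decimal(cm.tn * 100) / Decimal(cm.tn + cm.fp), ndigits)


def mcc(cm: ConfusionMatrix, ndigits: int = 2) -> float:
    """Matthews correlation coefficient on the -1..1 scale.

    The numerator is exact integer arithmetic; the denominator is the
    square root of the product of the four marginals. Any zero marginal
    makes the coefficient undefined (reported as '-' in tables).
    """
    marginals = (
        cm.tp + cm.fp,
        cm.tp + cm.fn,
        cm.tn + cm.fp,
        cm.tn + cm.fn,
    )
    if 0 in marginals:
        raise UndefinedMetricError("mcc undefined: zero marginal sum")
    numerator = cm.tp * cm.tn - cm.fp * cm.fn
    return round_half_up(numerator / math.sqrt(math.prod(marginals)), ndigits)


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    """Sn/Sp/MCC bundle; an undefined MCC becomes None instead of raising."""
    try:
        m: float | None = mcc(cm)
    except UndefinedMetricError:
        m = None
    return MetricSet(sensitivity=sensitivity(cm), specificity=specificity(cm), mcc=m)


# ---------------------------------------------------------------------------
# benchmark construction
# ---------------------------------------------------------------------------

def build_benchmark(
    records: Iterable[ProteinRecord],
) -> tuple[dict[LocationCategory, set[str]], dict[str, int]]:
    """Curated single-location benchmark plus an exclusion-reason tally.

    Keeps reviewed, full-length (>= 70 aa), methionine-initiated,
    non-fragment records whose curated annotation maps to exactly one
    category with no hedging qualifier. Cytoskeleton entries are kept out
    of the cytoplasm set (the cytoplasm co-annotation is collapsed), and
    cell-membrane entries populate the plasma-membrane category.
    """
    benchmark: dict[LocationCategory, set[str]] = {}
    tally: dict[str, int] = {
        "kept": 0,
        "unreviewed": 0,
        "no_mapped_location": 0,
        "multiple_locations": 0,
        "qualifier": 0,
        "fragment": 0,
        "non_met_start": 0,
        "short": 0,
    }
    for rec in records:
        if not rec.reviewed:
            tally["unreviewed"] += 1
            continue
        cats = rec.mapped_curated_categories()
        if not cats:
            tally["no_mapped_location"] += 1
            continue
        if len(cats) > 1:
            tally["multiple_locations"] += 1
            continue
        if rec.has_qualified_location():
            tally["qualifier"] += 1
            continue
        if rec.is_fragment:
            tally["fragment"] += 1
            continue
        if not rec.starts_with_met:
            tally["non_met_start"] += 1
            continue
        if rec.length < MIN_BENCHMARK_LENGTH:
            tally["short"] += 1
            continue
        tally["kept"] += 1
        benchmark.setdefault(cats[0], set()).add(rec.accession)
    return benchmark, tally


def confusion(
    predicted_pos: set[str], actual_pos: set[str], universe: set[str]
) -> ConfusionMatrix:
    """Standard 2x2 counts of a predicted set against an actual set."""
    if not actual_pos <= universe:
        raise ValueError("actual positives are not a subset of the universe")
    if not predicted_pos <= universe:
        raise ValueError("predicted positives are not a subset of the universe")
    tp = len(predicted_pos & actual_pos)
    fp = len(predicted_pos - actual_pos)
    fn = len(actual_pos - predicted_pos)
    tn = len(universe) - tp - fp - fn
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# rule language: boolean expressions over tool verdicts
# ---------------------------------------------------------------------------
# grammar:  expr   := and_expr ('OR' and_expr)*
#           and_expr := unary ('AND' unary)*
#           unary  := 'NOT' unary | '(' expr ')' | atom
#           atoms: votes>=K | tm | kdel | signalp3=Y|N | signalp4=Y|N |
#                  phobius=Y|N | targetp=S|M|OTHER | wolf=<label> |
#                  fraganchor=<class>

_TOKEN_RE = re.compile(
    r"\s*(\(|\)|AND\b|OR\b|NOT\b|votes\s*>=\s*\d"
    r"|[A-Za-z0-9_.]+\s*=\s*[A-Za-z0-9_.]+|[A-Za-z0-9_.]+)",
)


class RuleContext:
    """Per-protein evaluation context handed to compiled rule predicates."""

    def __init__(
        self, bundle: PredictionBundle, tm: bool, kdel: bool, mode: str = "strict"
    ):
        self.bundle = bundle
        self.tm = tm
        self.kdel = kdel
        self.mode = mode


Predicate = Callable[[RuleContext], bool]


def _atom_predicate(token: str) -> Predicate:
    token = token.strip()
    if token == "tm":
        return lambda ctx: ctx.tm
    if token == "kdel":
        return lambda ctx: ctx.kdel
    m = re.fullmatch(r"votes\s*>=\s*(\d)", token)
    if m:
        k = int(m.group(1))
        return lambda ctx: count_secretion_votes(ctx.bundle, ctx.mode) >= k
    name, _, value = token.partition("=")
    name, value = name.strip().lower(), value.strip()
    if name in ("signalp3", "signalp4", "phobius"):
        tool = Tool(name)
        want = value.upper() == "Y"
        return lambda ctx: bool(
            (v := ctx.bundle.get(tool)) and v.signal_peptide is not None
        ) and ctx.bundle.get(tool).signal_peptide == want
    if name == "targetp":
        want_loc = {"_": "OTHER"}.get(value, value.upper())
        if want_loc not in ("S", "M", "OTHER"):
            raise ValueError(f"rule: unknown TargetP location {value!r}")
        return lambda ctx: bool(
            (v := ctx.bundle.get(Tool.TARGETP)) and v.targetp_loc == want_loc
        )
    if name == "wolf":
        return lambda ctx: bool(
            (v := ctx.bundle.get(Tool.WOLFPSORT))
            and wolf_top_component(v.wolf_top_label) == value
        )
    if name == "fraganchor":
        try:
            want_class = GpiClass[value.upper()]
        except KeyError as exc:
            raise ValueError(f"rule: unknown FragAnchor class {value!r}") from exc
        return lambda ctx: bool(
            (v := ctx.bundle.get(Tool.FRAGANCHOR))
            and v.gpi_class is not None
            and v.gpi_class.value >= want_class.value
        )
    raise ValueError(f"rule: unknown atom {token!r}")


def compile_rule(rule: str) -> Predicate:
    """Compile a rule string like ``"votes>=3 AND NOT tm AND NOT kdel"``."""
    tokens: list[str] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            if rule[pos:].strip():
                raise ValueError(f"rule: cannot tokenize at {rule[pos:]!r}")
            break
        tokens.append(m.group(1).strip())
        pos = m.end()
    if not tokens:
        raise ValueError("rule: empty expression")

    idx = 0

    def peek() -> str | None:
        return tokens[idx] if idx < len(tokens) else None

    def take() -> str:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_expr() -> Predicate:
        terms = [parse_and()]
        while peek() == "OR":
            take()
            terms.append(parse_and())
        return (lambda ts: lambda ctx: any(t(ctx) for t in ts))(terms)

    def parse_and() -> Predicate:
        factors = [parse_unary()]
        while peek() == "AND":
            take()
            factors.append(parse_unary())
        return (lambda fs: lambda ctx: all(f(ctx) for f in fs))(factors)

    def parse_unary() -> Predicate:
        tok = peek()
        if tok == "NOT":
            take()
            inner = parse_unary()
            return lambda ctx: not inner(ctx)
        if tok == "(":
            take()
            inner = parse_expr()
            if peek() != ")":
                raise ValueError("rule: unbalanced parentheses")
            take()
            return inner
        if tok is None or tok == ")":
            raise ValueError("rule: unexpected end of expression")
        return _atom_predicate(take())

    predicate = parse_expr()
    if idx != len(tokens):
        raise ValueError(f"rule: trailing tokens {tokens[idx:]!r}")
    return predicate


def evaluate_rule(
    rule: str | Predicate,
    benchmark: Mapping[LocationCategory, set[str]],
    bundles: Mapping[str, PredictionBundle],
    *,
    kdel_hits: set[str] | None = None,
    lengths: Mapping[str, int] | None = None,
    categories: Iterable[LocationCategory] | None = None,
    mode: str = "strict",
) -> pd.DataFrame:
    """Score a predictor rule one-vs-rest for each benchmark category.

    The universe is the union of all benchmark categories (every retained
    protein), so specificity counts the other categories' proteins as
    negatives. Undefined MCCs are reported as NaN (printed '-').
    """
    predicate = compile_rule(rule) if isinstance(rule, str) else rule
    kdel_hits = kdel_hits or set()
    universe: set[str] = set().union(*benchmark.values()) if benchmark else set()
    missing = universe - set(bundles)
    if missing and mode == "strict":
        raise ValueError(
            f"missing prediction bundles for {len(missing)} benchmark proteins "
            f"(e.g. {sorted(missing)[:3]})"
        )
    predicted: set[str] = set()
    for pid in universe:
        bundle = bundles.get(pid)
        if bundle is None:
            continue
        tm = is_membrane_by_tmhmm(
            bundle, lengths.get(pid) if lengths else None, mode
        )
        if predicate(RuleContext(bundle, tm, pid in kdel_hits, mode)):
            predicted.add(pid)
    cats = list(categories) if categories is not None else sorted(
        benchmark, key=lambda c: c.value
    )
    rows = []
    for cat in cats:
        if cat not in benchmark:
            raise ValueError(f"category {cat} not present in benchmark")
        cm = confusion(predicted, benchmark[cat], universe)

        def _safe(fn):
            try:
                return fn(cm)
            except UndefinedMetricError:
                return float("nan")

        rows.append(
            {
                "category": cat.value,
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "sn": _safe(sensitivity),
                "sp": _safe(specificity),
                "mcc": _safe(mcc),
            }
        )
    return pd.DataFrame(rows)


def load_reference_counts() -> pd.DataFrame:
    """Packaged reference benchmark confusion counts with printed metrics.

    One row per published evaluation rule: the group, rule name, the four
    confusion counts and the Sn/Sp/MCC values as printed in the reference
    evaluation ('-' for an undefined MCC).
    """
    with resources.files("secloc.data").joinpath(
        "reference_benchmark_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"mcc": str})
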
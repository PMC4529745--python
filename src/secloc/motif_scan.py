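"""PROSITE-pattern scanning for the C-terminal ER-retention signal.

Implements the small PROSITE syntax subset needed for KDEL-type patterns
(entry PS00014, ``[KRHQSA]-[DENQ]-E-L>``): literal residues, ``[...]``
alternative classes, ``{...}`` exclusion classes, the ``x`` wildcard, ``-``
element separators and the ``>`` C-terminal anchor. Repetition counts and
N-terminal anchors are out of scope and raise a clean error. The default
PS00014 pattern string ships in package config so a pattern revision is a
data update.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = ["PrositePattern", "compile_prosite", "scan", "load_pattern", "ps00014"]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PrositePattern:
    """A compiled PROSITE pattern: one residue-class set per position."""

    pattern_id: str
    elements: tuple[frozenset[str], ...]
    anchored_cterm: bool

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"{self.pattern_id}: pattern has no elements")
        for elem in self.elements:
            if not elem or not elem <= AMINO_ACIDS:
                raise ValueError(
                    f"{self.pattern_id}: element {sorted(elem)!r} is not a "
                    "non-empty subset of the 20 amino acids"
                )

    def __len__(self) -> int:
        return len(self.elements)


class UnsupportedConstructError(ValueError):
    """Raised for PROSITE syntax outside the supported subset."""


def compile_prosite(pattern_text: str, pattern_id: str = "") -> PrositePattern:
    """Compile a PROSITE pattern string into element sets.

    >>> p = compile_prosite("[KRHQSA]-[DENQ]-E-L>", "PS00014")
    >>> len(p), p.anchored_cterm
    (4, True)
    """
    text = pattern_text.strip().rstrip(".")
    anchored_cterm = text.endswith(">")
    if anchored_cterm:
        text = text[:-1]
    if text.startswith("<"):
        raise UnsupportedConstructError(
            f"{pattern_id or pattern_text}: unsupported construct: "
            "N-terminal anchor '<'"
        )
    elements: list[frozenset[str]] = []
    for token in text.split("-"):
        token = token.strip()
        if not token:
            raise UnsupportedConstructError(
                f"{pattern_id or pattern_text}: empty pattern element"
            )
        if "(" in token or ")" in token:
            raise UnsupportedConstructError(
                f"{pattern_id or pattern_text}: unsupported construct: "
                f"repetition in {token!r}"
            )
        if token == "x":
            elements.append(AMINO_ACIDS)
        elif token.startswith("[") and token.endswith("]"):
            elements.append(_residue_set(token[1:-1], pattern_id))
        elif token.startswith("{") and token.endswith("}"):
            elements.append(AMINO_ACIDS - _residue_set(token[1:-1], pattern_id))
        elif len(token) == 1 and token in AMINO_ACIDS:
            elements.append(frozenset(token))
        else:
            raise UnsupportedConstructError(
                f"{pattern_id or pattern_text}: unsupported construct: {token!r}"
            )
    return PrositePattern(
        pattern_id=pattern_id or pattern_text,
        elements=tuple(elements),
        anchored_cterm=anchored_cterm,
    )


def _residue_set(chars: str, pattern_id: str) -> frozenset[str]:
    residues = frozenset(chars)
    if not residues or not residues <= AMINO_ACIDS:
        raise UnsupportedConstructError(
            f"{pattern_id}: invalid residue class {chars!r}"
        )
    return residues


def _window_matches(seq: str, start: int, pattern: PrositePattern) -> bool:
    return all(
        seq[start + i] in elem for i, elem in enumerate(pattern.elements)
    )


def scan(sequence: str, pattern: PrositePattern) -> tuple[bool, int | None]:
    """Scan an upper-case sequence for the pattern.

    For C-terminally anchored patterns only the final ``len(pattern)``
    residues are tested. Returns ``(hit, 1-based start position)``;
    sequences shorter than the pattern simply miss.

    >>> scan("MAASKDEL", ps00014())
    (True, 5)
    """
    k = len(pattern)
    n = len(sequence)
    if n < k:
        return False, None
    if pattern.anchored_cterm:
        start = n - k
        if _window_matches(sequence, start, pattern):
            return True, start + 1
        return False, None
    for start in range(n - k + 1):
        if _window_matches(sequence, start, pattern):
            return True, start + 1
    return False, None


def load_pattern(pattern_id: str = "PS00014") -> PrositePattern:
    """Load a named pattern from the packaged pattern config."""
    text = resources.files("secloc.data").joinpath("prosite_patterns.yaml").read_text()
    patterns = yaml.safe_load(text)["patterns"]
    if pattern_id not in patterns:
        raise KeyError(f"pattern {pattern_id!r} not in packaged pattern config")
    return compile_prosite(patterns[pattern_id], pattern_id)


_PS00014: PrositePattern | None = None


def ps00014() -> PrositePattern:
    """The ER-retention (KDEL-type) C-terminal pattern, cached."""
    global _PS00014
    if _PS00014 is None:
        _PS00014 = load_pattern("PS00014")
    return _PS00014
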
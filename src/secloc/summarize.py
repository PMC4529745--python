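"""Per-species subcellular proteome summaries and secretome sizing.

The secretome of a species is defined as its curated secreted proteins
plus the predicted highly-likely-secreted tier (>= 3 of 4 predictor
votes). Likely and weakly-likely tiers are reported alongside but never
counted in the secretome size by default; a switch adds the likely tier
for sensitivity analysis. A simple ordinary-least-squares fit relates
secretome size to proteome size across species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence, TextIO

import numpy as np
from scipy import stats

from .categories import LocationCategory, SecretionTier
from .classifier import LocationAssignment
from .metrics import round_half_up
from .records import ProteinRecord

__all__ = ["SpeciesSummary", "RegressionResult", "summarize_species",
           "secretome_regression", "write_summary_table"]

#: Sentinel group for proteins whose record carries no taxon id.
UNKNOWN_TAXON = -1


@dataclass
class SpeciesSummary:
    taxon_id: int
    species_name: str
    total_proteins: int
    per_category: dict[LocationCategory, int]
    curated_secreted: int
    hls: int
    ls: int
    wls: int
    include_ls_in_secretome: bool = False

    @property
    def secretome_size(self) -> int:
        size = self.curated_secreted + self.hls
        if self.include_ls_in_secretome:
            size += self.ls
        return size

    @property
    def secretome_pct(self) -> float:
        return round_half_up(self.secretome_size * 100 / self.total_proteins, 1)

    def category_pct(self, category: LocationCategory) -> float:
        return round_half_up(
            self.per_category.get(category, 0) * 100 / self.total_proteins, 1
        )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    n_species: int
    slope_stderr: float = field(default=float("nan"))
    intercept_stderr: float = field(default=float("nan"))


def summarize_species(
    assignments: Iterable[LocationAssignment],
    records: Iterable[ProteinRecord],
    *,
    include_ls_in_secretome: bool = False,
    accession_filter: set[str] | None = None,
) -> list[SpeciesSummary]:
    """Group assignments by species and count categories and secretion tiers.

    ``accession_filter`` optionally restricts counting to a user-supplied
    accession list (e.g. a reference-proteome membership list). Proteins
    whose record has no taxon id are collected under a sentinel group with
    a warning. Output order is by taxon id; input order never matters.
    """
    by_acc = {r.accession: r for r in records}
    groups: dict[int, dict] = {}
    n_untaxed = 0
    for a in sorted(assignments, key=lambda a: a.protein_id):
        if accession_filter is not None and a.protein_id not in accession_filter:
            continue
        rec = by_acc.get(a.protein_id)
        if rec is None:
            raise ValueError(f"assignment {a.protein_id} has no matching record")
        taxon = rec.taxon_id if rec.taxon_id is not None else UNKNOWN_TAXON
        if taxon == UNKNOWN_TAXON:
            n_untaxed += 1
        g = groups.setdefault(
            taxon,
            {
                "name": rec.species_name,
                "total": 0,
                "cats": {},
                "curated_secreted": 0,
                "hls": 0,
                "ls": 0,
                "wls": 0,
            },
        )
        g["total"] += 1
        g["cats"][a.category] = g["cats"].get(a.category, 0) + 1
        if a.tier is SecretionTier.CURATED_SECRETED:
            g["curated_secreted"] += 1
        elif a.tier is SecretionTier.HIGHLY_LIKELY:
            g["hls"] += 1
        elif a.tier is SecretionTier.LIKELY:
            g["ls"] += 1
        elif a.tier is SecretionTier.WEAKLY_LIKELY:
            g["wls"] += 1
    if n_untaxed:
        warnings.warn(
            f"{n_untaxed} proteins without a taxon id grouped under the "
            f"sentinel taxon {UNKNOWN_TAXON}"
        )
    return [
        SpeciesSummary(
            taxon_id=taxon,
            species_name=g["name"],
            total_proteins=g["total"],
            per_category=g["cats"],
            curated_secreted=g["curated_secreted"],
            hls=g["hls"],
            ls=g["ls"],
            wls=g["wls"],
            include_ls_in_secretome=include_ls_in_secretome,
        )
        for taxon, g in sorted(groups.items())
    ]


def secretome_regression(
    summaries: Sequence[SpeciesSummary],
    exclusions: Callable[[SpeciesSummary], bool] | None = None,
) -> RegressionResult:
    """OLS of secretome size (Y) on proteome size (X) across species.

    ``exclusions`` is a predicate returning True for species to drop
    (e.g. species whose entry count departs far from their reference
    proteome). Requires >= 3 species and non-degenerate X variance.
    """
    kept = [s for s in summaries if exclusions is None or not exclusions(s)]
    if len(kept) < 3:
        raise ValueError(f"regression needs >= 3 species, got {len(kept)}")
    x = np.array([s.total_proteins for s in kept], dtype=float)
    y = np.array([s.secretome_size for s in kept], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("regression undefined: proteome sizes are all equal")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n_species=len(kept),
        slope_stderr=float(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
    )


def write_summary_table(summaries: Iterable[SpeciesSummary], handle: TextIO) -> None:
    """Write per-species counts for the major compartments as TSV."""
    cols = [
        ("mito_mem", LocationCategory.MITO_MEMBRANE),
        ("mito_nonmem", LocationCategory.MITO_NONMEMBRANE),
        ("cytoplasm", LocationCategory.CYTOPLASM),
        ("nuc_mem", LocationCategory.NUCLEAR_MEMBRANE),
        ("nuc_nonmem", LocationCategory.NUCLEAR_NONMEMBRANE),
        ("plasma_mem", LocationCategory.PLASMA_MEMBRANE),
    ]
    handle.write(
        "taxon_id\tspecies\ttotal_proteins\tcurated_secreted\thls\tls\twls\t"
        + "\t".join(name for name, _ in cols)
        + "\tsecretome_size\tsecretome_pct\n"
    )
    for s in summaries:
        counts = "\t".join(str(s.per_category.get(cat, 0)) for _, cat in cols)
        handle.write(
            f"{s.taxon_id}\t{s.species_name}\t{s.total_proteins}\t"
            f"{s.curated_secreted}\t{s.hls}\t{s.ls}\t{s.wls}\t{counts}\t"
            f"{s.secretome_size}\t{s.secretome_pct}\n"
        )
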
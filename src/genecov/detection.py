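"""Detection sets, cut-off sweeps, and per-chromosome coverage tables.

A gene is *detected* on a platform when its abundance passes that
platform's cut-off: FPKM > 0 (Illumina), TPM > 0 (ONT), Ct <= 40 (qPCR).
``greater_than`` is strict and ``at_most`` inclusive, exactly as the
rules are written.  Coverage is gene-centric: the fraction of a
chromosome's protein-coding genes with at least one detected transcript,
and combined-platform coverage comes from the inclusion-exclusion union
|A ∪ B| = |A| + |B| − |A ∩ B|.

Reported proportions are formatted by TRUNCATION (floor at the printed
precision), not rounding — e.g. 453/812 = 0.5578 prints as 0.55 — which
is the convention the reference coverage tables follow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneCatalog
from .errors import ConfigurationError, ValidationError
from .quant_io import QuantTable

logger = logging.getLogger(__name__)

Comparator = Literal["greater_than", "at_most"]

#: Canonical per-platform detection rules.
CANONICAL_RULES: dict[str, "CutoffRule"]


@dataclass(frozen=True)
class CutoffRule:
    metric: Literal["FPKM", "TPM", "copies_per_cell", "Ct"]
    comparator: Comparator
    threshold: float

    def passes(self, values: np.ndarray) -> np.ndarray:
        if self.comparator == "greater_than":
            return values > self.threshold
        return values <= self.threshold

    def __str__(self) -> str:
        op = ">" if self.comparator == "greater_than" else "<="
        return f"{self.metric}{op}{self.threshold:g}"


CANONICAL_RULES = {
    "illumina": CutoffRule("FPKM", "greater_than", 0.0),
    "ont": CutoffRule("TPM", "greater_than", 0.0),
    "qpcr": CutoffRule("Ct", "at_most", 40.0),
}

_METRIC_UNITS = {"FPKM": "FPKM", "TPM": "TPM", "copies_per_cell": "copies_per_cell", "Ct": "copies_per_cell"}


def parse_rule(text: str) -> CutoffRule:
    """Parse a rule such as ``"fpkm>0"`` or ``"ct<=40"``."""
    for op, comparator in (("<=", "at_most"), (">", "greater_than")):
        if op in text:
            metric_raw, value = text.split(op, 1)
            metric = {"fpkm": "FPKM", "tpm": "TPM", "ct": "Ct", "copies_per_cell": "copies_per_cell"}.get(
                metric_raw.strip().lower()
            )
            if metric is None:
                raise ValidationError(f"unknown cut-off metric in rule {text!r}")
            return CutoffRule(metric, comparator, float(value))
    raise ValidationError(f"cannot parse cut-off rule {text!r} (expected e.g. 'fpkm>0' or 'ct<=40')")


@dataclass(frozen=True)
class DetectionSet:
    platform: str
    donor: str  # sample label, or "pooled"
    rule: CutoffRule
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def detect(quant: QuantTable, rule: CutoffRule, catalog: GeneCatalog) -> DetectionSet:
    """Apply a cut-off rule to a quantification table within a catalog.

    Genes present in ``quant`` but absent from the catalog are ignored
    with a logged count; a rule whose metric does not match the table's
    unit raises :class:`ConfigurationError`.
    """
    if len(catalog) == 0:
        raise ConfigurationError("catalog is empty")
    if _METRIC_UNITS[rule.metric] != quant.unit:
        raise ConfigurationError(f"rule metric {rule.metric} incompatible with table unit {quant.unit}")
    df = quant.df
    values = df["ct"].to_numpy() if rule.metric == "Ct" else df["abundance"].to_numpy()
    mask = rule.passes(values)
    if rule.metric == "Ct":
        mask &= ~np.isnan(values)
    candidates = set(df.loc[mask, "gene_id"])
    in_catalog = candidates & catalog.gene_ids
    dropped = len(candidates) - len(in_catalog)
    if dropped:
        logger.info("%s/%s: %d detected genes outside catalog ignored", quant.platform, quant.donor, dropped)
    return DetectionSet(platform=quant.platform, donor=quant.donor, rule=rule, genes=frozenset(in_catalog))


def cutoff_sweep(
    quant: QuantTable,
    catalog: GeneCatalog,
    thresholds: Sequence[float],
    comparator: Comparator = "greater_than",
) -> list[tuple[float, int]]:
    """Count detected genes at each threshold of an ascending sweep.

    For ``greater_than`` rules the counts are non-increasing along the
    sweep.  Unsorted or empty threshold lists raise
    :class:`ValidationError`.
    """
    if len(thresholds) == 0:
        raise ValidationError("thresholds list is empty")
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValidationError("thresholds must be sorted ascending")
    metric = {"FPKM": "FPKM", "TPM": "TPM", "copies_per_cell": "copies_per_cell"}.get(quant.unit, quant.unit)
    if comparator == "at_most" and quant.platform == "qpcr":
        metric = "Ct"
    return [
        (float(t), len(detect(quant, CutoffRule(metric, comparator, float(t)), catalog)))
        for t in thresholds
    ]


def truncate_proportion(x: float, decimals: int = 2) -> float:
    """Truncate ``x`` in [0, 1] toward zero at ``decimals`` places.

    Truncation, not rounding: 0.5578 -> 0.55 at two decimals.  Uses the
    shortest decimal representation of the float so that ratios of small
    integer counts truncate as their exact decimal expansions do.
    """
    if not 0.0 <= x <= 1.0:
        raise ValidationError(f"proportion {x} outside [0, 1]")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_DOWN))


def format_percent(x: float, decimals: int = 1) -> float:
    """Format a proportion as a percentage.

    One or more decimals truncate (224/275 -> 81.4); zero decimals round
    half-up (63/275 = 22.909 -> 23), matching the reporting convention of
    figure captions vs. integer percentages in running text.
    """
    if not 0.0 <= x <= 1.0:
        raise ValidationError(f"proportion {x} outside [0, 1]")
    pct = Decimal(repr(float(x))) * 100
    q = Decimal(1).scaleb(-decimals)
    rounding = ROUND_DOWN if decimals >= 1 else ROUND_HALF_UP
    return float(pct.quantize(q, rounding=rounding))


@dataclass(frozen=True)
class CoverageRow:
    chromosome: str
    n_genes: int
    n_a: int
    n_b: int
    n_both: int
    prop_a: float
    prop_b: float
    prop_union: float

    def __post_init__(self) -> None:
        if max(self.n_a, self.n_b) > self.n_genes:
            raise ValidationError(f"chr{self.chromosome}: detected count exceeds gene total")
        if self.n_both > min(self.n_a, self.n_b):
            raise ValidationError(f"chr{self.chromosome}: intersection exceeds a platform count")
        if self.n_union > self.n_genes:
            raise ValidationError(f"chr{self.chromosome}: union exceeds gene total")

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_both


def coverage_row_from_counts(
    chromosome: str, n_genes: int, n_a: int, n_b: int, n_both: int, decimals: int = 2
) -> CoverageRow:
    """Build one coverage row from raw counts, formatting by truncation."""
    if n_genes == 0:
        props = (0.0, 0.0, 0.0)
    else:
        props = tuple(
            truncate_proportion(n / n_genes, decimals) for n in (n_a, n_b, n_a + n_b - n_both)
        )
    return CoverageRow(chromosome, n_genes, n_a, n_b, n_both, *props)


def coverage_table(
    sets_by_platform: Mapping[str, DetectionSet],
    catalog: GeneCatalog,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-chromosome two-platform coverage with a summary row.

    Counts in the summary row are column sums; its proportions are the
    UNWEIGHTED MEAN of the per-chromosome raw proportions (then
    truncated), so small chromosomes weigh as much as large ones.
    """
    if len(sets_by_platform) != 2:
        raise ConfigurationError("coverage_table expects exactly two platforms")
    (label_a, set_a), (label_b, set_b) = sets_by_platform.items()
    rows: list[CoverageRow] = []
    raw_props: list[tuple[float, float, float]] = []
    for chrom in catalog.chromosomes:
        universe = catalog.genes_on(chrom)
        a = set_a.genes & universe
        b = set_b.genes & universe
        row = coverage_row_from_counts(chrom, len(universe), len(a), len(b), len(a & b), decimals)
        rows.append(row)
        n = len(universe)
        raw_props.append((len(a) / n, len(b) / n, len(a | b) / n) if n else (0.0, 0.0, 0.0))

    df = pd.DataFrame(
        [
            (r.chromosome, r.n_genes, r.n_a, r.n_b, r.n_both, r.prop_a, r.prop_b, r.prop_union)
            for r in rows
        ],
        columns=["chromosome", "n_genes", f"n_{label_a}", f"n_{label_b}", "n_both",
                 f"prop_{label_a}", f"prop_{label_b}", "prop_union"],
    )
    means = [truncate_proportion(float(np.mean([p[i] for p in raw_props])), decimals) for i in range(3)]
    summary = pd.DataFrame(
        [["total", int(df["n_genes"].sum()), int(df[f"n_{label_a}"].sum()), int(df[f"n_{label_b}"].sum()),
          int(df["n_both"].sum()), means[0], means[1], means[2]]],
        columns=df.columns,
    )
    return pd.concat([df, summary], ignore_index=True)


def venn_region_counts(sets_by_label: Mapping[str, Iterable[str]]) -> dict[frozenset[str], int]:
    """Exclusive-region sizes for k labeled sets, by brute-force
    classification of every member's membership vector (2^k − 1 regions)."""
    labels = list(sets_by_label)
    as_sets = {lab: set(s) for lab, s in sets_by_label.items()}
    regions: dict[frozenset[str], int] = {}
    for g in set().union(*as_sets.values()) if as_sets else set():
        member = frozenset(lab for lab in labels if g in as_sets[lab])
        regions[member] = regions.get(member, 0) + 1
    return regions
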
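"""Tanimoto set similarity, Venn decompositions, and donor variability.

The Tanimoto (Jaccard) coefficient between gene sets a and b is

    T(a, b) = P_ab / (P_a + P_b − P_ab)

with P_a, P_b the set sizes and P_ab the intersection size.  Verdict
bands: T >= 0.70 — the sets are effectively identical; 0.55 <= T < 0.70
— similarity is much weaker; T < 0.55 — the sets differ considerably.

Inter-donor variability of a technology is the mean, over donors, of the
number of genes detected ONLY in that donor divided by the total number
of genes the technology detects across all donors.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import AbstractSet, Iterable, Mapping

from .errors import ValidationError

Band = str  # "identical" | "weaker" | "different"

BAND_IDENTICAL_MIN = 0.70
BAND_WEAKER_MIN = 0.55


def classify_band(t: float) -> Band:
    """Map a Tanimoto coefficient onto its interpretation band."""
    if not 0.0 <= t <= 1.0:
        raise ValidationError(f"Tanimoto coefficient {t} outside [0, 1]")
    if t >= BAND_IDENTICAL_MIN:
        return "identical"
    if t >= BAND_WEAKER_MIN:
        return "weaker"
    return "different"


@dataclass(frozen=True)
class SimilarityResult:
    p_a: int
    p_b: int
    p_ab: int
    t: float
    band: Band

    def to_dict(self) -> dict:
        return {"p_a": self.p_a, "p_b": self.p_b, "p_ab": self.p_ab, "t": self.t, "band": self.band}


def tanimoto(a: AbstractSet[str], b: AbstractSet[str]) -> SimilarityResult:
    """Tanimoto similarity of two gene sets.

    Two empty sets are defined as identical (T = 1.0) by convention.
    """
    a, b = set(a), set(b)
    p_ab = len(a & b)
    denom = len(a) + len(b) - p_ab
    t = p_ab / denom if denom else 1.0
    return SimilarityResult(p_a=len(a), p_b=len(b), p_ab=p_ab, t=t, band=classify_band(t))


@dataclass(frozen=True)
class VennDecomposition:
    labels: tuple[str, ...]
    #: exclusive region counts keyed by the subset of labels, e.g.
    #: frozenset({"A", "B"}) -> genes in A and B but not in any other set
    region_counts: dict

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def count(self, *labels: str) -> int:
        return self.region_counts.get(frozenset(labels), 0)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "regions": {"&".join(sorted(k)): v for k, v in sorted(self.region_counts.items(), key=lambda kv: sorted(kv[0]))},
            "union": self.union_size,
        }


def venn(sets_by_label: Mapping[str, Iterable[str]]) -> VennDecomposition:
    """Exclusive Venn regions of 2 or 3 labeled gene sets.

    Every gene of the union is classified by its exact membership vector;
    regions are therefore disjoint and sum to the union size.  More than
    three sets are explicitly unsupported.
    """
    labels = tuple(sets_by_label)
    if len(labels) != len(set(labels)):
        raise ValidationError("set labels must be distinct")
    if not 2 <= len(labels) <= 3:
        raise ValidationError(f"venn supports 2 or 3 sets, got {len(labels)}")
    as_sets = {lab: set(s) for lab, s in sets_by_label.items()}
    counts: dict[frozenset, int] = {}
    for g in set().union(*as_sets.values()):
        member = frozenset(lab for lab in labels if g in as_sets[lab])
        counts[member] = counts.get(member, 0) + 1
    return VennDecomposition(labels=labels, region_counts=counts)


@dataclass(frozen=True)
class VariabilityResult:
    per_donor_specific: dict
    denominator: int
    mean_variability: float

    def to_dict(self) -> dict:
        return {
            "per_donor_specific": dict(self.per_donor_specific),
            "denominator": self.denominator,
            "mean_variability": self.mean_variability,
        }


def donor_variability(sets_by_donor: Mapping[str, Iterable[str]]) -> VariabilityResult:
    """Mean fraction of technology-detected genes specific to one donor.

    specific(d) = |set_d \\ union of the other donors' sets|; the shared
    denominator is the union across all donors.  Requires at least two
    donors; an all-empty input leaves the statistic undefined and raises
    :class:`ValidationError`.
    """
    donors = list(sets_by_donor)
    if len(donors) < 2:
        raise ValidationError("donor variability needs at least two donors")
    as_sets = {d: set(s) for d, s in sets_by_donor.items()}
    union = set().union(*as_sets.values())
    if not union:
        raise ValidationError("variability undefined: all donor sets are empty")
    specific = {
        d: len(as_sets[d] - set().union(*(as_sets[o] for o in donors if o != d)))
        for d in donors
    }
    return VariabilityResult(
        per_donor_specific=specific,
        denominator=len(union),
        mean_variability=mean(specific[d] / len(union) for d in donors),
    )
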
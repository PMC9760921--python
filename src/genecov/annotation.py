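"""Protein-coding gene catalog built from a GTF annotation.

The catalog is the gene universe of the whole analysis: every coverage
proportion downstream uses its per-chromosome counts as denominator.
Gene identity is the Ensembl-style ``gene_id`` with any ``.version``
suffix stripped; gene symbols are carried for reporting but never used
as keys.  The chromosome universe is fixed to the 24 nuclear chromosomes
(1-22, X, Y); mitochondrial and alt/random/scaffold contigs are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils.feature
import pandas as pd

from .errors import EmptyCatalogError, FormatError

logger = logging.getLogger(__name__)

#: Normalized nuclear chromosome labels, in karyotype order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_SET = frozenset(CHROMOSOMES)

CATALOG_COLUMNS = ["gene_id", "gene_name", "chromosome", "biotype", "max_transcript_length"]


def normalize_chromosome(raw_label: str) -> Optional[str]:
    """Map a raw contig label onto the 24-chromosome universe.

    ``"chr18"`` and ``"18"`` both normalize to ``"18"``; ``"chrX"`` to
    ``"X"``.  Mitochondrial labels (``chrM``/``MT``) and alt/random/patch
    contigs are rejected by returning ``None`` (rejection is a return
    state, not an error).
    """
    label = raw_label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    label = label.upper()
    return label if label in _CHROM_SET else None


def strip_version(identifier: str) -> str:
    """Drop an Ensembl-style ``.version`` suffix from a gene/transcript id."""
    return identifier.rsplit(".", 1)[0] if "." in identifier else identifier


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    gene_name: str
    chromosome: str
    biotype: str
    #: Longest annotated isoform in nucleotides; only the simulator's
    #: length model consumes it.
    max_transcript_length: int


@dataclass
class GeneCatalog:
    """Collection of unique genes with per-chromosome counts."""

    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate gene_id in catalog")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(g.gene_id for g in self.genes)

    @property
    def per_chromosome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.genes:
            counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
        return counts

    def genes_on(self, chromosome: str) -> frozenset[str]:
        return frozenset(g.gene_id for g in self.genes if g.chromosome == chromosome)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosomes present, in karyotype order."""
        present = {g.chromosome for g in self.genes}
        return [c for c in CHROMOSOMES if c in present]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.gene_name, g.chromosome, g.biotype, g.max_transcript_length) for g in self.genes],
            columns=CATALOG_COLUMNS,
        )


def load_annotation(gtf_path: str | Path, biotype_filter: str = "protein_coding") -> GeneCatalog:
    """Build a :class:`GeneCatalog` from a GTF file.

    Genes are read from ``gene`` features; the biotype comes from the
    ``gene_type`` attribute (GENCODE dialect) with fallback to
    ``gene_biotype`` (Ensembl dialect).  Transcript features set
    ``max_transcript_length`` (genomic span of the longest isoform); a
    gene without annotated transcripts falls back to its own span.

    Raises :class:`FormatError` naming the offending line on malformed
    input and :class:`EmptyCatalogError` when no gene survives filtering.
    """
    gtf_path = Path(gtf_path)
    genes: dict[str, dict] = {}
    tx_length: dict[str, int] = {}

    with open(gtf_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise FormatError(f"{gtf_path}:{lineno}: expected 9 tab-separated GTF columns")
            try:
                feature = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"{gtf_path}:{lineno}: unparseable GTF line ({exc})") from exc
            if feature.featuretype not in ("gene", "transcript"):
                continue
            attrs = feature.attributes
            raw_id = (attrs.get("gene_id") or [None])[0]
            if raw_id is None:
                raise FormatError(f"{gtf_path}:{lineno}: {feature.featuretype} feature lacks gene_id")
            gene_id = strip_version(raw_id)
            span = feature.end - feature.start + 1
            if feature.featuretype == "transcript":
                tx_length[gene_id] = max(tx_length.get(gene_id, 0), span)
                continue
            chrom = normalize_chromosome(feature.seqid)
            if chrom is None:
                logger.debug("%s:%d: gene %s on excluded contig %s", gtf_path, lineno, gene_id, feature.seqid)
                continue
            biotype = (attrs.get("gene_type") or attrs.get("gene_biotype") or [""])[0]
            if biotype != biotype_filter:
                continue
            name = (attrs.get("gene_name") or [gene_id])[0]
            genes[gene_id] = {"gene_name": name, "chromosome": chrom, "biotype": biotype, "span": span}

    if not genes:
        raise EmptyCatalogError(f"{gtf_path}: no genes with biotype {biotype_filter!r} on chromosomes 1-22/X/Y")

    records = [
        GeneRecord(
            gene_id=gid,
            gene_name=info["gene_name"],
            chromosome=info["chromosome"],
            biotype=info["biotype"],
            max_transcript_length=tx_length.get(gid, info["span"]),
        )
        for gid, info in genes.items()
    ]
    return GeneCatalog(records)


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    """Write the catalog as TSV (columns per :data:`CATALOG_COLUMNS`)."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def load_catalog(path: str | Path) -> GeneCatalog:
    """Reload a catalog written by :func:`write_catalog` (exact round-trip)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: catalog TSV missing columns {missing}")
    if df.empty:
        raise EmptyCatalogError(f"{path}: catalog file holds no genes")
    records = [
        GeneRecord(
            gene_id=str(r.gene_id),
            gene_name=str(r.gene_name),
            chromosome=str(r.chromosome),
            biotype=str(r.biotype),
            max_transcript_length=int(r.max_transcript_length),
        )
        for r in df.itertuples(index=False)
    ]
    bad = sorted({g.chromosome for g in records} - _CHROM_SET)
    if bad:
        raise FormatError(f"{path}: non-normalized chromosome labels {bad}")
    return GeneCatalog(records)


def catalog_from_records(records: Iterable[GeneRecord]) -> GeneCatalog:
    return GeneCatalog(list(records))
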
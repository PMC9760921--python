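"""Readers and writers for platform quantification tables.

Three dialects are supported, one per platform:

* Salmon ``quant.sf`` transcript TSV (ONT, TPM) aggregated to genes
  through a transcript-to-gene map — gene abundance is the SUM of member
  transcript TPMs, so a gene is detectable whenever any isoform is;
* gene-level FPKM TSV (Illumina);
* qPCR CSV carrying the threshold cycle (Ct) and the copies-per-cell
  estimate.  Genes past the detection limit are kept with abundance 0
  rather than dropped, so denominators stay catalog-driven and the
  detection decision happens downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import strip_version
from .errors import EmptyTableError, FormatError, ValidationError

logger = logging.getLogger(__name__)

PLATFORM_UNITS = {"illumina": "FPKM", "ont": "TPM", "qpcr": "copies_per_cell"}

SALMON_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


@dataclass(frozen=True)
class QuantRecord:
    gene_id: str
    abundance: float  # platform units: FPKM | TPM | copies-per-cell
    ct: Optional[float] = None  # qPCR threshold cycle, when measured

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValidationError(f"gene {self.gene_id}: negative abundance {self.abundance}")
        if self.ct is not None and not self.ct > 0:
            raise ValidationError(f"gene {self.gene_id}: non-positive Ct {self.ct}")


@dataclass
class QuantTable:
    """One platform x donor measurement set, one record per gene."""

    platform: str
    donor: str
    unit: str
    df: pd.DataFrame = field(repr=False)  # columns: gene_id, abundance[, ct]
    #: transcripts dropped because the tx2gene map did not cover them
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        if self.platform not in PLATFORM_UNITS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.unit != PLATFORM_UNITS[self.platform]:
            raise ValidationError(
                f"unit {self.unit!r} inconsistent with platform {self.platform!r} "
                f"(expected {PLATFORM_UNITS[self.platform]!r})"
            )
        df = self.df.reset_index(drop=True)
        if "ct" not in df.columns:
            df = df.assign(ct=np.nan)
        df = df[["gene_id", "abundance", "ct"]]
        if df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id after aggregation")
        if (df["abundance"] < 0).any():
            bad = df.loc[df["abundance"] < 0, "gene_id"].iloc[0]
            raise ValidationError(f"gene {bad}: negative abundance")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> dict[str, QuantRecord]:
        return {
            r.gene_id: QuantRecord(r.gene_id, float(r.abundance), None if math.isnan(r.ct) else float(r.ct))
            for r in self.df.itertuples(index=False)
        }

    def abundance(self, gene_id: str) -> float:
        hit = self.df.loc[self.df["gene_id"] == gene_id, "abundance"]
        return float(hit.iloc[0]) if len(hit) else 0.0


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, dtype={"gene_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty (no header)") from exc


def load_tx2gene(path: str | Path) -> dict[str, str]:
    """Read a two-column transcript->gene TSV; version suffixes stripped."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "gene_id"], dtype=str)
    return {strip_version(t): strip_version(g) for t, g in zip(df["transcript_id"], df["gene_id"])}


def load_salmon_quant(path: str | Path, tx2gene: dict[str, str], donor: str = "sample") -> QuantTable:
    """Read a Salmon ``quant.sf`` file and aggregate transcript TPM to genes.

    Transcripts absent from ``tx2gene`` are dropped and counted on the
    returned table (``n_unmapped``).  Raises :class:`FormatError` when a
    required column is missing and :class:`EmptyTableError` when no
    transcript maps to a gene.
    """
    df = _read_table(path, sep="\t")
    missing = [c for c in SALMON_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: quant.sf missing required columns {missing}")
    names = df["Name"].astype(str).map(strip_version)
    genes = names.map(lambda t: tx2gene.get(t))
    unmapped = int(genes.isna().sum())
    if unmapped:
        logger.warning("%s: %d transcripts not covered by tx2gene; dropped", path, unmapped)
    kept = df.loc[genes.notna()].assign(gene_id=genes[genes.notna()])
    if kept.empty:
        raise EmptyTableError(f"{path}: no transcript maps to a gene via tx2gene")
    per_gene = kept.groupby("gene_id", sort=True)["TPM"].sum().reset_index()
    per_gene = per_gene.rename(columns={"TPM": "abundance"})
    return QuantTable(platform="ont", donor=donor, unit="TPM", df=per_gene, n_unmapped=unmapped)


def load_fpkm_table(path: str | Path, donor: str = "sample") -> QuantTable:
    """Read a gene-level FPKM TSV (columns ``gene_id``, ``fpkm``).

    Duplicate gene rows are aggregated by sum with a warning; a negative
    abundance raises :class:`ValidationError` naming the row.
    """
    df = _read_table(path, sep="\t")
    missing = [c for c in ("gene_id", "fpkm") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: FPKM table missing columns {missing}")
    neg = df.index[df["fpkm"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative FPKM at data row {int(neg[0]) + 1}")
    df = df.assign(gene_id=df["gene_id"].map(strip_version))
    if df["gene_id"].duplicated().any():
        logger.warning("%s: duplicate gene_ids aggregated by sum", path)
        df = df.groupby("gene_id", sort=True, as_index=False)["fpkm"].sum()
    out = df.rename(columns={"fpkm": "abundance"})[["gene_id", "abundance"]]
    return QuantTable(platform="illumina", donor=donor, unit="FPKM", df=out)


def load_qpcr_table(path: str | Path, donor: str = "sample") -> QuantTable:
    """Read a qPCR CSV (columns ``gene_id``, ``ct``, ``copies_per_cell``).

    ``copies_per_cell`` may be blank past the detection limit; such genes
    are retained with abundance 0 so detection can be decided downstream
    from the carried Ct.  A missing ``ct`` column raises
    :class:`FormatError`.
    """
    df = _read_table(path, sep=",")
    if "ct" not in df.columns:
        raise FormatError(f"{path}: qPCR CSV missing required column 'ct'")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: qPCR CSV missing required column 'gene_id'")
    if "copies_per_cell" not in df.columns:
        df = df.assign(copies_per_cell=np.nan)
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].map(strip_version),
            "abundance": df["copies_per_cell"].fillna(0.0).astype(float),
            "ct": df["ct"].astype(float),
        }
    )
    return QuantTable(platform="qpcr", donor=donor, unit="copies_per_cell", df=out)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Write a table back in the dialect of its platform.

    ONT tables are written as single-isoform ``quant.sf`` files (the
    matching tx2gene map is ``<path>.tx2gene.tsv``), so every output
    reloads through the reader that produced it.
    """
    path = Path(path)
    if table.platform == "illumina":
        table.df[["gene_id", "abundance"]].rename(columns={"abundance": "fpkm"}).to_csv(path, sep="\t", index=False)
    elif table.platform == "qpcr":
        out = table.df.rename(columns={"abundance": "copies_per_cell"})[["gene_id", "ct", "copies_per_cell"]]
        out.to_csv(path, index=False)
    else:  # ont -> quant.sf with one pseudo-transcript per gene
        n = len(table.df)
        sf = pd.DataFrame(
            {
                "Name": table.df["gene_id"] + ".tx1",
                "Length": np.full(n, 1000, dtype=int),
                "EffectiveLength": np.full(n, 800.0),
                "TPM": table.df["abundance"],
                "NumReads": np.zeros(n),
            }
        )
        sf.to_csv(path, sep="\t", index=False)
        pd.DataFrame(
            {"transcript_id": table.df["gene_id"] + ".tx1", "gene_id": table.df["gene_id"]}
        ).to_csv(path.with_suffix(path.suffix + ".tx2gene.tsv"), sep="\t", index=False, header=False)


def read_quant_table(path: str | Path, platform: str, donor: str = "sample") -> QuantTable:
    """Dispatch to the platform-appropriate reader."""
    if platform == "illumina":
        return load_fpkm_table(path, donor=donor)
    if platform == "qpcr":
        return load_qpcr_table(path, donor=donor)
    if platform == "ont":
        side = Path(path).with_suffix(Path(path).suffix + ".tx2gene.tsv")
        if not side.exists():
            raise FormatError(f"{path}: ONT quant.sf requires tx2gene map (expected {side})")
        return load_salmon_quant(path, load_tx2gene(side), donor=donor)
    raise ValidationError(f"unknown platform {platform!r}")
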
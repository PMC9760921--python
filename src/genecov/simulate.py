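"""Synthetic multi-donor, multi-platform expression study generator.

Emulates the structure of a three-donor liver profiling study measured
by Illumina RNA-Seq (FPKM), ONT direct RNA sequencing (TPM), and qPCR
(copies per cell with Ct): ~19,593 protein-coding genes across the 24
nuclear chromosomes, a unimodal (liver) or bimodal (proliferating cell
line) log10 copies-per-cell profile, per-gene lognormal donor effects,
and per-platform detection models:

* Illumina — reads ~ Poisson(depth · copies · length_kb), gene detected
  iff reads >= 1; FPKM proportional to copies with lognormal
  measurement noise;
* ONT — same sampling with a much smaller depth factor (single-flow-cell
  output of 1-1.5 Gb vs. tens of Gb), a per-gene capture-efficiency
  factor shared across donors (native-RNA capture is strongly
  transcript-dependent, which also keeps donor profiles correlated),
  and a length floor: transcripts shorter than ``ont_min_length`` have
  their expected read count scaled down, because short native-RNA
  fragments are poorly captured by nanopore sequencing;
* qPCR — Ct = c0 − k·log10(copies) + N(0, σ_ct), detected iff Ct <= 40;
  the reported copies-per-cell estimate is back-computed from Ct.

Expected detection probability is non-decreasing in true copy number on
every platform.  One RNG stream is derived from the master seed per
(donor, platform), so adding a platform never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import CHROMOSOMES, GeneCatalog, GeneRecord, write_catalog
from .errors import ValidationError
from .quant_io import QuantTable, write_quant_table

#: Protein-coding gene totals per human nuclear chromosome (GENCODE scale,
#: 19,593 genes); the default gene universe of the simulator.
HUMAN_PROTEIN_CODING_COUNTS: dict[str, int] = {
    "1": 2022, "2": 1247, "3": 1059, "4": 755, "5": 856, "6": 972,
    "7": 962, "8": 675, "9": 778, "10": 720, "11": 1281, "12": 1013,
    "13": 326, "14": 662, "15": 589, "16": 822, "17": 1126, "18": 275,
    "19": 1396, "20": 537, "21": 209, "22": 459, "X": 812, "Y": 40,
}

_PLATFORM_CODES = {"illumina": 1, "ont": 2, "qpcr": 3}


@dataclass(frozen=True)
class PlatformModel:
    """Per-platform detection/noise parameters (see module docstring)."""

    illumina_depth: float = 10.0  # expected reads per copy·kb
    illumina_noise_sd: float = 0.10  # lognormal (log10) FPKM measurement noise
    ont_depth: float = 0.4  # expected reads per copy·kb — shallow flow cell
    ont_capture_sd: float = 2.0  # log10 sd of the shared per-gene capture efficiency
    ont_min_length: int = 500  # nt; below this the capture rate drops
    ont_short_penalty: float = 0.1  # multiplier on expected reads below the floor
    qpcr_ct_intercept: float = 39.5  # Ct at 1 copy per cell
    qpcr_ct_slope: float = 1.0 / math.log10(2.0)  # Ct decrease per 10x copies (perfect efficiency)
    qpcr_ct_sd: float = 0.5  # cycle-to-cycle measurement noise
    qpcr_ct_limit: float = 40.0  # detection limit

    def validate(self) -> None:
        for name in ("illumina_depth", "ont_depth", "ont_short_penalty"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("illumina_noise_sd", "qpcr_ct_sd", "ont_capture_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.qpcr_ct_slope <= 0:
            raise ValidationError("qpcr_ct_slope must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level configuration; ``seed`` fully determines the output."""

    n_genes_per_chromosome: Mapping[str, int] = field(
        default_factory=lambda: dict(HUMAN_PROTEIN_CODING_COUNTS)
    )
    profile: str = "unimodal"  # "unimodal" | "bimodal" log10 copies-per-cell
    unimodal_mu: float = 0.7
    unimodal_sigma: float = 1.0
    mixture_weights: tuple[float, ...] = (0.4, 0.6)
    mixture_means: tuple[float, ...] = (0.5, 2.5)
    mixture_sigmas: tuple[float, ...] = (0.6, 0.6)
    n_donors: int = 3
    donor_effect_sd: float = 0.15  # per-gene log10 jitter across donors
    length_median_nt: float = 2000.0  # lognormal transcript lengths
    length_sigma_ln: float = 0.6  # natural-log sd
    chry_length_median_nt: float = 400.0  # chrY preset: short transcripts
    platform: PlatformModel = field(default_factory=PlatformModel)
    seed: int = 0

    def validate(self) -> None:
        if self.profile not in ("unimodal", "bimodal"):
            raise ValidationError(f"unknown profile {self.profile!r}")
        if not self.n_genes_per_chromosome:
            raise ValidationError("n_genes_per_chromosome is empty")
        bad = set(self.n_genes_per_chromosome) - set(CHROMOSOMES)
        if bad:
            raise ValidationError(f"unknown chromosomes in config: {sorted(bad)}")
        if any(n <= 0 for n in self.n_genes_per_chromosome.values()):
            raise ValidationError("gene counts must be strictly positive")
        if self.n_donors < 1:
            raise ValidationError("n_donors must be >= 1")
        if not math.isclose(sum(self.mixture_weights), 1.0, abs_tol=1e-9):
            raise ValidationError("mixture weights must sum to 1")
        if not (len(self.mixture_weights) == len(self.mixture_means) == len(self.mixture_sigmas)):
            raise ValidationError("mixture parameter lengths disagree")
        if any(s <= 0 for s in self.mixture_sigmas) or self.unimodal_sigma <= 0:
            raise ValidationError("all sigmas must be positive")
        if self.donor_effect_sd < 0:
            raise ValidationError("donor_effect_sd must be non-negative")
        self.platform.validate()

    @property
    def donors(self) -> list[str]:
        return [f"donor{i + 1}" for i in range(self.n_donors)]


def preset(name: str, size_factor: float = 1.0, seed: int = 0, n_donors: int = 3) -> SimulationConfig:
    """Named study configurations.

    ``liver`` — unimodal log-abundance profile with low inter-donor
    variability; ``hepg2`` — bimodal profile with an elevated
    high-expression component, as seen in actively proliferating cells.
    ``size_factor`` scales the gene universe proportionally (for quick
    runs); 1.0 keeps the full 19,593-gene genome.
    """
    counts = {
        c: max(1, round(n * size_factor)) for c, n in HUMAN_PROTEIN_CODING_COUNTS.items()
    }
    if name == "liver":
        cfg = SimulationConfig(n_genes_per_chromosome=counts, profile="unimodal",
                               seed=seed, n_donors=n_donors)
    elif name == "hepg2":
        cfg = SimulationConfig(n_genes_per_chromosome=counts, profile="bimodal",
                               seed=seed, n_donors=n_donors)
    else:
        raise ValidationError(f"unknown preset {name!r} (expected 'liver' or 'hepg2')")
    cfg.validate()
    return cfg


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)


def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Draw the ground-truth table: gene, chromosome, transcript length,
    consensus copies per cell, and per-donor copies.

    Deterministic given ``config.seed``.  Per-donor copies are the
    consensus value times a lognormal factor with sd
    ``donor_effect_sd`` (log10); sd 0 makes all donors identical.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])

    chroms: list[str] = []
    for c in CHROMOSOMES:
        if c in config.n_genes_per_chromosome:
            chroms.extend([c] * int(config.n_genes_per_chromosome[c]))
    n = len(chroms)
    chrom_arr = np.array(chroms)
    gene_ids = np.array([f"SYNG{c}G{i:05d}" for i, c in enumerate(chroms)])

    # transcript lengths: lognormal, with deliberately short chrY genes
    median = np.where(chrom_arr == "Y", config.chry_length_median_nt, config.length_median_nt)
    lengths = np.maximum(
        (median * np.exp(rng.normal(0.0, config.length_sigma_ln, n))).round().astype(int), 50
    )

    if config.profile == "unimodal":
        log_copies = rng.normal(config.unimodal_mu, config.unimodal_sigma, n)
        component = np.zeros(n, dtype=int)
    else:
        component = rng.choice(len(config.mixture_weights), size=n, p=config.mixture_weights)
        means = np.asarray(config.mixture_means)[component]
        sigmas = np.asarray(config.mixture_sigmas)[component]
        log_copies = rng.normal(means, sigmas)
    copies = 10.0 ** log_copies

    # gene-specific nanopore capture efficiency, shared across donors
    capture_rng = np.random.default_rng([config.seed, 104])
    ont_capture = 10.0 ** capture_rng.normal(0.0, config.platform.ont_capture_sd, n)

    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chrom_arr,
            "length_nt": lengths,
            "component": component,
            "copies_per_cell": copies,
            "ont_capture": ont_capture,
        }
    )
    for d_idx, donor in enumerate(config.donors):
        jitter_rng = np.random.default_rng([config.seed, 202, d_idx])
        jitter = 10.0 ** jitter_rng.normal(0.0, config.donor_effect_sd, n)
        out[f"copies_{donor}"] = copies * jitter
    return out


def catalog_from_truth(truth: pd.DataFrame) -> GeneCatalog:
    """Gene catalog matching a simulated truth table."""
    records = [
        GeneRecord(
            gene_id=str(r.gene_id),
            gene_name=str(r.gene_id),
            chromosome=str(r.chromosome),
            biotype="protein_coding",
            max_transcript_length=int(r.length_nt),
        )
        for r in truth.itertuples(index=False)
    ]
    return GeneCatalog(records)


def simulate_platform_tables(
    truth: pd.DataFrame, config: SimulationConfig
) -> dict[tuple[str, str], QuantTable]:
    """Measure the truth on every (donor, platform), in platform units.

    Returns a map ``(donor, platform) -> QuantTable``; every gene of the
    truth table appears in every output (undetected genes carry
    abundance 0, and qPCR tables always carry Ct).
    """
    config.validate()
    pm = config.platform
    length_kb = truth["length_nt"].to_numpy() / 1000.0
    n = len(truth)
    tables: dict[tuple[str, str], QuantTable] = {}

    for d_idx, donor in enumerate(config.donors):
        copies = truth[f"copies_{donor}"].to_numpy()

        rng = np.random.default_rng([config.seed, 303, d_idx, _PLATFORM_CODES["illumina"]])
        lam = pm.illumina_depth * copies * length_kb
        reads = rng.poisson(lam)
        noise = 10.0 ** rng.normal(0.0, pm.illumina_noise_sd, n)
        fpkm = np.where(reads >= 1, copies * noise, 0.0)
        tables[(donor, "illumina")] = QuantTable(
            platform="illumina", donor=donor, unit="FPKM",
            df=pd.DataFrame({"gene_id": truth["gene_id"], "abundance": fpkm}),
        )

        rng = np.random.default_rng([config.seed, 303, d_idx, _PLATFORM_CODES["ont"]])
        penalty = np.where(truth["length_nt"].to_numpy() < pm.ont_min_length, pm.ont_short_penalty, 1.0)
        capture = (
            truth["ont_capture"].to_numpy() if "ont_capture" in truth.columns else np.ones(n)
        )
        lam = pm.ont_depth * copies * length_kb * penalty * capture
        reads = rng.poisson(lam)
        total = reads.sum()
        tpm = reads / total * 1e6 if total > 0 else np.zeros(n)
        tables[(donor, "ont")] = QuantTable(
            platform="ont", donor=donor, unit="TPM",
            df=pd.DataFrame({"gene_id": truth["gene_id"], "abundance": tpm}),
        )

        rng = np.random.default_rng([config.seed, 303, d_idx, _PLATFORM_CODES["qpcr"]])
        ct = pm.qpcr_ct_intercept - pm.qpcr_ct_slope * np.log10(copies) + rng.normal(0.0, pm.qpcr_ct_sd, n)
        ct = np.maximum(ct, 1.0)  # a cycle count cannot be <= 0
        detected = ct <= pm.qpcr_ct_limit
        est_copies = np.where(detected, 10.0 ** ((pm.qpcr_ct_intercept - ct) / pm.qpcr_ct_slope), 0.0)
        tables[(donor, "qpcr")] = QuantTable(
            platform="qpcr", donor=donor, unit="copies_per_cell",
            df=pd.DataFrame({"gene_id": truth["gene_id"], "abundance": est_copies, "ct": ct}),
        )
    return tables


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: truth, matching catalog, and all platform tables."""
    truth = simulate_truth(config)
    return catalog_from_truth(truth), truth, simulate_platform_tables(truth, config)


def write_simulation(outdir: str | Path, config: SimulationConfig) -> dict[str, str]:
    """Run a simulation and write all artifacts in the dialects the
    readers consume: catalog TSV, truth TSV, per-sample FPKM TSV /
    quant.sf (+tx2gene) / qPCR CSV.  Returns a manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, truth, tables = simulate_study(config)
    paths: dict[str, str] = {}
    write_catalog(catalog, outdir / "catalog.tsv")
    paths["catalog"] = str(outdir / "catalog.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.tsv")
    ext = {"illumina": "tsv", "ont": "quant.sf", "qpcr": "csv"}
    for (donor, platform), table in tables.items():
        p = outdir / f"{platform}_{donor}.{ext[platform]}"
        write_quant_table(table, p)
        paths[f"{platform}_{donor}"] = str(p)
    return paths
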
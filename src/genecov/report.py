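"""Full-analysis driver: one configured run -> a bundle of report files.

Given a gene catalog and per-(platform, donor) quantification files, the
driver computes pooled detection sets, the per-chromosome two-platform
coverage table, per-platform donor Venn decompositions and variability,
per-donor cross-platform Venn decompositions, pairwise Tanimoto
similarities, calibration fits against qPCR, and a cut-off sweep.  All
outputs are plain TSV/JSON carrying raw counts next to formatted
proportions, plus a manifest with the package version and a hash of the
configuration, so a run is reproducible from its persisted config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import load_catalog
from .calibration import fit_calibration, pair_for_calibration
from .detection import CANONICAL_RULES, coverage_table, cutoff_sweep, detect, parse_rule
from .errors import ConfigurationError, GenecovError, InsufficientDataError
from .quant_io import read_quant_table
from .similarity import donor_variability, tanimoto, venn

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass
class RunConfig:
    catalog: str
    #: platform -> donor -> quantification file path
    inputs: dict
    rules: dict = field(default_factory=dict)  # platform -> rule string
    thresholds: tuple = DEFAULT_THRESHOLDS
    sweep_platform: str = "illumina"
    decimals: int = 2
    outdir: str = "genecov_report"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "catalog" not in raw or "inputs" not in raw:
        raise ConfigurationError(f"{path}: run config needs 'catalog' and 'inputs' keys")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    if "thresholds" in raw:
        raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    return RunConfig(**raw)


@contextmanager
def _stage(name: str):
    """Propagate any stage failure with the stage name attached."""
    try:
        yield
    except GenecovError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc
    except OSError as exc:
        raise OSError(f"[{name}] {exc}") from exc


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_full_analysis(config: RunConfig) -> dict[str, str]:
    """Execute every stage and write the report bundle.

    Returns the manifest mapping artifact names to paths.  Outputs are
    deterministic: rerunning the same config on the same inputs gives
    byte-identical files (no timestamps are written).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    with _stage("annotation"):
        catalog = load_catalog(config.catalog)

    tables: dict[tuple[str, str], object] = {}
    with _stage("quantification"):
        for platform, by_donor in config.inputs.items():
            for donor, path in by_donor.items():
                if not Path(path).exists():
                    raise ConfigurationError(f"missing quant file for {platform}/{donor}: {path}")
                tables[(platform, donor)] = read_quant_table(path, platform, donor=donor)

    rules = {
        p: parse_rule(config.rules[p]) if p in config.rules else CANONICAL_RULES[p]
        for p in config.inputs
    }

    with _stage("detection"):
        det = {
            (p, d): detect(tables[(p, d)], rules[p], catalog)
            for (p, d) in tables
        }
        pooled = {
            p: frozenset().union(*(det[(p, d)].genes for d in config.inputs[p]))
            for p in config.inputs
        }

    with _stage("coverage"):
        if {"illumina", "ont"} <= set(pooled):
            from .detection import DetectionSet

            two = {
                p: DetectionSet(p, "pooled", rules[p], pooled[p]) for p in ("illumina", "ont")
            }
            cov = coverage_table(two, catalog, decimals=config.decimals)
            cov_path = outdir / "coverage.tsv"
            cov.to_csv(cov_path, sep="\t", index=False)
            paths["coverage"] = str(cov_path)

    with _stage("similarity"):
        platforms = sorted(pooled)
        sim = {
            f"{a}|{b}": tanimoto(pooled[a], pooled[b]).to_dict()
            for i, a in enumerate(platforms)
            for b in platforms[i + 1:]
        }
        _dump_json(sim, outdir / "similarity.json")
        paths["similarity"] = str(outdir / "similarity.json")

    with _stage("venn"):
        venns: dict[str, dict] = {}
        for p in platforms:
            donors = list(config.inputs[p])
            if 2 <= len(donors) <= 3:
                venns[f"donors_{p}"] = venn({d: det[(p, d)].genes for d in donors}).to_dict()
        all_donors = sorted({d for by in config.inputs.values() for d in by})
        for d in all_donors:
            present = [p for p in platforms if d in config.inputs[p]]
            if 2 <= len(present) <= 3:
                venns[f"platforms_{d}"] = venn({p: det[(p, d)].genes for p in present}).to_dict()
        _dump_json(venns, outdir / "venn.json")
        paths["venn"] = str(outdir / "venn.json")

    with _stage("variability"):
        variability = {}
        for p in platforms:
            donors = list(config.inputs[p])
            if len(donors) >= 2:
                variability[p] = donor_variability({d: det[(p, d)].genes for d in donors}).to_dict()
        _dump_json(variability, outdir / "variability.json")
        paths["variability"] = str(outdir / "variability.json")

    with _stage("calibration"):
        calib: dict[str, dict] = {}
        if "qpcr" in config.inputs:
            for p in ("illumina", "ont"):
                if p not in config.inputs:
                    continue
                for d in config.inputs[p]:
                    if d not in config.inputs["qpcr"]:
                        continue
                    key = f"{p}_{d}"
                    try:
                        pairs = pair_for_calibration(tables[(p, d)], tables[("qpcr", d)])
                        calib[key] = fit_calibration(pairs, platform=p).to_dict()
                    except InsufficientDataError as exc:
                        calib[key] = {"error": str(exc)}
        _dump_json(calib, outdir / "calibration.json")
        paths["calibration"] = str(outdir / "calibration.json")

    with _stage("sweep"):
        p = config.sweep_platform
        if p in config.inputs and config.inputs[p]:
            donor0 = next(iter(config.inputs[p]))
            points = cutoff_sweep(tables[(p, donor0)], catalog, list(config.thresholds))
            sweep_path = outdir / "sweep.tsv"
            with open(sweep_path, "w") as fh:
                fh.write("threshold\tdetected\n")
                for t, c in points:
                    fh.write(f"{t:g}\t{c}\n")
            paths["sweep"] = str(sweep_path)

    manifest = {
        "genecov_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "outputs": paths,
    }
    _dump_json(manifest, outdir / "manifest.json")
    paths["manifest"] = str(outdir / "manifest.json")
    return paths
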
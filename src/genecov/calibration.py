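"""FPKM/TPM -> copies-per-cell calibration against qPCR.

Sequencing abundances (FPKM, TPM) are relative; qPCR gives absolute
copies per cell.  A log-log ordinary-least-squares fit over genes
detected by BOTH platforms (abundance > 0, copies > 0, Ct within the
detection limit) yields a conversion model

    log10(copies) = slope * log10(abundance) + intercept

which is acceptable for unit conversion only when its determination
coefficient exceeds 0.5; below that the model refuses to convert.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConversionRefusedError,
    DegenerateFitError,
    InsufficientDataError,
    ValidationError,
)
from .quant_io import QuantTable

#: Minimum determination coefficient for a usable conversion model.
R2_ACCEPTABLE = 0.5

CalibrationPairs = list[tuple[float, float]]  # (log10 abundance, log10 copies)


def pair_for_calibration(
    quant: QuantTable, qpcr: QuantTable, ct_limit: float = 40.0
) -> CalibrationPairs:
    """Log10 (abundance, copies) pairs for genes detected by both platforms.

    A gene contributes a pair only when its sequencing abundance and its
    qPCR copy number are both positive and its Ct is within the
    detection limit.  Fewer than three pairs raise
    :class:`InsufficientDataError`.
    """
    if qpcr.platform != "qpcr":
        raise ValidationError("second table must be a qPCR table")
    merged = quant.df.merge(qpcr.df, on="gene_id", suffixes=("_seq", "_pcr"))
    ok = (
        (merged["abundance_seq"] > 0)
        & (merged["abundance_pcr"] > 0)
        & merged["ct_pcr"].notna()
        & (merged["ct_pcr"] <= ct_limit)
    )
    sub = merged.loc[ok]
    pairs = list(zip(np.log10(sub["abundance_seq"]), np.log10(sub["abundance_pcr"])))
    if len(pairs) < 3:
        raise InsufficientDataError(f"only {len(pairs)} calibration pairs (need >= 3)")
    return [(float(x), float(y)) for x, y in pairs]


@dataclass(frozen=True)
class CalibrationModel:
    platform: str
    slope: float  # log10-copies per log10-abundance
    intercept: float  # log10 copies-per-cell at unit abundance
    r_squared: float
    n: int

    @property
    def conversion_acceptable(self) -> bool:
        return self.r_squared > R2_ACCEPTABLE

    def to_dict(self) -> dict:
        return {
            "platform": self.platform,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "conversion_acceptable": self.conversion_acceptable,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(platform=d["platform"], slope=d["slope"], intercept=d["intercept"],
                   r_squared=d["r_squared"], n=d["n"])


def fit_calibration(pairs: Sequence[tuple[float, float]], platform: str = "illumina") -> CalibrationModel:
    """Ordinary least squares on log-log pairs.

    Zero variance in either axis makes the fit (or R^2) undefined and
    raises :class:`DegenerateFitError`; non-finite inputs raise
    :class:`ValidationError`.
    """
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite calibration pair")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in log-abundance: slope undefined")
    if np.ptp(y) == 0:
        raise DegenerateFitError("zero variance in log-copies: R^2 undefined (SS_tot = 0)")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        platform=platform,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=len(pairs),
    )


def convert_abundance(model: CalibrationModel, abundance: float) -> float:
    """Convert a positive sequencing abundance to copies per cell.

    Refuses (raises :class:`ConversionRefusedError`) when the model's
    R^2 does not exceed 0.5; non-positive abundance is a domain error.
    """
    if not abundance > 0:
        raise ValidationError(f"abundance must be positive, got {abundance}")
    if not model.conversion_acceptable:
        raise ConversionRefusedError(
            f"R² = {model.r_squared:.3g} ≤ {R2_ACCEPTABLE}: model not acceptable for conversion"
        )
    return 10.0 ** (model.slope * math.log10(abundance) + model.intercept)
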
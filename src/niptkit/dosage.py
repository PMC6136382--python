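"""Chromosome-dosage statistics: proportions, reference normalization and
Z-score calls for trisomy 21 and fetal sex.

The dosage statistic for a chromosome of interest is its read count
divided by the read count of all other autosomes.  Test samples are
standardized against a platform-matched euploid reference whose outliers
have been removed at three (unscaled) median absolute deviations:

    z = (P_test - mean_ref) / sd_ref

Trisomy 21 is called positive at z >= 3 provided the fetal fraction
passes the 0.04 QC gate; fetal sex is male when the chrY z-score against
a female-fetus reference clears the sex threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import AUTOSOMES, normalize_chrom
from .simulate import ReadCountSample

__all__ = [
    "ReferenceStats", "TrisomyCall", "SexCall",
    "chromosome_proportion", "chry_proportion",
    "normalize_reference", "z_score", "call_t21", "call_sex",
    "DEFAULT_Z_THRESHOLD", "DEFAULT_FF_THRESHOLD", "DEFAULT_SEX_THRESHOLD",
]

DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_FF_THRESHOLD = 0.04
# Between the empirical female maximum (~12) and male minimum (~26) chrY z.
DEFAULT_SEX_THRESHOLD = 20.0


def _counts(sample: ReadCountSample | Mapping[str, int]) -> Mapping[str, int]:
    counts = sample.counts if isinstance(sample, ReadCountSample) else sample
    return {normalize_chrom(k): int(v) for k, v in counts.items()}


def chromosome_proportion(sample: ReadCountSample | Mapping[str, int],
                          target: str) -> float:
    """Reads on ``target`` divided by reads on all *other* autosomes."""
    counts = _counts(sample)
    target = normalize_chrom(target)
    denom = sum(counts.get(c, 0) for c in AUTOSOMES if c != target)
    if denom == 0:
        raise ValueError("no reads on the remaining autosomes")
    return counts.get(target, 0) / denom


def chry_proportion(sample: ReadCountSample | Mapping[str, int]) -> float:
    """Reads on chrY divided by reads on all autosomes."""
    counts = _counts(sample)
    denom = sum(counts.get(c, 0) for c in AUTOSOMES)
    if denom == 0:
        raise ValueError("no autosomal reads")
    return counts.get("Y", 0) / denom


@dataclass
class ReferenceStats:
    """Mean/SD of a reference cohort's proportions after 3-MAD filtering."""

    mean_proportion: float
    sd_proportion: float
    n_retained: int
    n_removed: int
    platform: str | None = None
    target: str | None = None

    def __post_init__(self) -> None:
        if self.sd_proportion <= 0:
            raise ValueError("reference SD must be positive")
        if self.n_retained < 2:
            raise ValueError("reference needs at least 2 retained samples")


def normalize_reference(proportions: Sequence[float] | Iterable[float],
                        platform: str | None = None,
                        target: str | None = None,
                        n_mad: float = 3.0) -> ReferenceStats:
    """Normalize a reference cohort: drop samples outside ``n_mad`` raw
    median absolute deviations of the median, then summarise the rest."""
    p = np.asarray(list(proportions), dtype=float)
    if p.size < 5:
        raise ValueError("reference too small to normalize (need >= 5)")
    med = np.median(p)
    mad = np.median(np.abs(p - med))
    keep = np.abs(p - med) <= n_mad * mad
    retained = p[keep]
    if retained.size == 0:
        raise ValueError("all reference samples removed by the MAD filter")
    sd = float(retained.std(ddof=1))
    if sd == 0:
        raise ValueError("reference proportions have zero spread after filtering")
    return ReferenceStats(mean_proportion=float(retained.mean()),
                          sd_proportion=sd,
                          n_retained=int(retained.size),
                          n_removed=int(p.size - retained.size),
                          platform=platform, target=target)


def z_score(p_test: float, ref: ReferenceStats) -> float:
    """Standardized deviation of a test proportion from the reference."""
    return (p_test - ref.mean_proportion) / ref.sd_proportion


@dataclass
class TrisomyCall:
    z: float
    ff: float
    qc_pass: bool
    call: str  # positive | negative | no_call

    def __post_init__(self) -> None:
        if self.call not in ("positive", "negative", "no_call"):
            raise ValueError(f"bad call {self.call!r}")


def call_t21(z: float, ff: float,
             z_threshold: float = DEFAULT_Z_THRESHOLD,
             ff_threshold: float = DEFAULT_FF_THRESHOLD) -> TrisomyCall:
    """Trisomy-21 decision: no_call below the FF gate, else positive at
    z >= z_threshold (inclusive)."""
    qc = ff >= ff_threshold
    if not qc:
        call = "no_call"
    else:
        call = "positive" if z >= z_threshold else "negative"
    return TrisomyCall(z=float(z), ff=float(ff), qc_pass=qc, call=call)


@dataclass
class SexCall:
    z_y: float
    call: str  # male | female


def call_sex(z_y: float, male_threshold: float = DEFAULT_SEX_THRESHOLD) -> SexCall:
    """Fetal sex from the chrY z-score against a female-fetus reference."""
    return SexCall(z_y=float(z_y),
                   call="male" if z_y >= male_threshold else "female")
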
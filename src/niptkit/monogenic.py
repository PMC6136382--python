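"""Monogenic-disease screening in maternal plasma.

A de novo (or paternally inherited) heterozygous fetal variant is absent
from the maternal genome, so its plasma allele fraction is expected at
half the fetal fraction.  The screen keeps rare variants (population
frequency < 0.5%) in a disease gene set and flags those whose observed
allele fraction falls inside an exact binomial confidence window around
FF/2 at the variant's depth.  Rare variants outside the window are
reported with a best-effort origin annotation (e.g. maternal
heterozygous at AF ~ 0.5), never a pathogenicity claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

__all__ = [
    "AnnotatedVariant", "CandidateCall",
    "filter_rare", "expected_af_window", "screen_candidates",
    "DEFAULT_POP_FREQ_THRESHOLD", "DEFAULT_CONFIDENCE",
]

DEFAULT_POP_FREQ_THRESHOLD = 0.005
DEFAULT_CONFIDENCE = 0.99


@dataclass
class AnnotatedVariant:
    """A plasma variant call with gene and population-frequency annotation.

    population_frequency is the maximum over the supplied databases; a
    variant never seen in any database carries 0 and novel=True.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    observed_af: float
    depth: int
    population_frequency: float = 0.0
    disease_group: str | None = None
    novel: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.observed_af <= 1.0:
            raise ValueError("observed_af must be in [0, 1]")
        if not 0.0 <= self.population_frequency <= 1.0:
            raise ValueError("population_frequency must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class CandidateCall:
    variant: AnnotatedVariant
    expected_af: float
    af_window: tuple[float, float]
    in_window: bool
    rationale: str


def filter_rare(variants: Iterable[AnnotatedVariant],
                gene_set: Sequence[str] | set[str],
                pop_freq_threshold: float = DEFAULT_POP_FREQ_THRESHOLD,
                ) -> list[AnnotatedVariant]:
    """Keep rare variants (population frequency below threshold) within the
    disease gene set; order-preserving and idempotent."""
    genes = set(gene_set)
    if not genes:
        raise ValueError("gene_set is empty")
    return [v for v in variants
            if v.population_frequency < pop_freq_threshold and v.gene in genes]


def expected_af_window(ff: float, depth: int,
                       inheritance: str = "de_novo_or_paternal",
                       confidence: float = DEFAULT_CONFIDENCE,
                       ) -> tuple[float, float, float]:
    """Expected allele fraction FF/2 of a de novo fetal heterozygote, with
    an exact binomial confidence window at the observed depth.

    Returns (expected, low, high) on the allele-fraction scale.
    """
    if inheritance != "de_novo_or_paternal":
        raise ValueError(f"unsupported inheritance model {inheritance!r}")
    if ff <= 0:
        raise ValueError("no fetal signal: ff must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    expected = ff / 2.0
    lo_c, hi_c = stats.binom.interval(confidence, depth, expected)
    low = min(lo_c / depth, expected)
    high = max(hi_c / depth, expected)
    return expected, float(low), float(high)


def _origin_rationale(v: AnnotatedVariant, ff: float,
                      confidence: float) -> str:
    """Annotate a rare variant outside the de-novo window with its likely
    origin from the genotype-combination MAF expectations."""
    for p, label in ((0.5, "allele fraction near 0.5: likely maternal "
                           "heterozygous variant"),
                     (0.5 - ff / 2.0, "allele fraction near 0.5 - FF/2: "
                           "possible maternal carrier with fetus homozygous "
                           "reference")):
        lo_c, hi_c = stats.binom.interval(confidence, v.depth, p)
        if lo_c / v.depth <= v.observed_af <= hi_c / v.depth:
            return label
    return "allele fraction inconsistent with a de novo fetal heterozygote"


def screen_candidates(variants: Iterable[AnnotatedVariant],
                      ff: float,
                      gene_set: Sequence[str] | set[str],
                      pop_freq_threshold: float = DEFAULT_POP_FREQ_THRESHOLD,
                      confidence: float = DEFAULT_CONFIDENCE,
                      ) -> list[CandidateCall]:
    """Rare-variant screen at the expected de-novo allele fraction.

    Every rare in-gene-set variant is reported: candidates (in_window)
    have observed AF inside the binomial window around FF/2; the rest
    carry an origin rationale.
    """
    rare = filter_rare(variants, gene_set, pop_freq_threshold)
    calls = []
    for v in rare:
        expected, low, high = expected_af_window(ff, v.depth,
                                                 confidence=confidence)
        in_window = low <= v.observed_af <= high
        if in_window:
            rationale = ("rare variant at ~FF/2: candidate de novo or "
                         "paternally inherited fetal variant")
        else:
            rationale = _origin_rationale(v, ff, confidence)
        calls.append(CandidateCall(variant=v, expected_af=expected,
                                   af_window=(low, high),
                                   in_window=in_window, rationale=rationale))
    return calls
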
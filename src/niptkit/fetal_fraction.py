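"""Fetal-fraction estimation from the plasma SNP MAF distribution.

At a biallelic SNP in maternal plasma the expected minor-allele fraction
(MAF) depends only on the maternal/fetal genotype combination and the
fetal fraction FF:

====  ==================  ==============
id    mother / fetus      expected MAF
====  ==================  ==============
1     hom / hom (same)    0
2     hom / het           FF / 2
3     het / hom           0.5 - FF / 2
4     het / het           0.5
====  ==================  ==============

The genotype combination at a locus is unknown, so the estimator works
at the distribution level: observed MAFs are restricted to the window
[0.02, 0.25] (which retains essentially only the informative
mother-homozygous / fetus-heterozygous loci, above the sequencing-error
noise and below the heterozygous cloud), summarised as a fixed-length
quantile vector plus the retained-locus fraction, and matched by an
inverse-variance-weighted quantile distance against a library of
simulated samples on a grid of candidate FFs built at the sample's
coverage and SNP number.  The arg-min grid point is refined by a
parabola fitted to the squared-distance curve.

Two orthogonal validators used for mock samples are also provided:
fetal-specific alleles given maternal genotypes (FF = 2 x median plasma
fraction of the non-maternal allele) and the chrY read proportion scaled
by a fully-male reference proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel import FF_EXCLUDED_CHROMOSOMES, PanelDesign, default_panel
from .simulate import (PlasmaSnpSample, PopulationModel, ReadCountSample,
                       SimSampleConfig, as_rng, simulate_plasma_snp_sample)

__all__ = [
    "GenotypeCombo", "GENOTYPE_COMBOS", "expected_maf",
    "MafVector", "extract_maf_vector",
    "SimLibrary", "build_sim_library", "fit_ff",
    "ff_from_fetal_specific", "ff_from_chry", "degree_of_deviation",
    "FFEstimate", "DEFAULT_MAF_WINDOW", "COVERAGE_BUCKETS",
]

DEFAULT_MAF_WINDOW = (0.02, 0.25)
DEFAULT_FF_GRID = np.round(np.arange(0.0, 0.35 + 1e-9, 0.005), 4)
COVERAGE_BUCKETS = (50, 100, 150, 200, 300, 500)


@dataclass(frozen=True)
class GenotypeCombo:
    id: int
    maternal: str
    fetal: str

    def expected_maf(self, ff: float) -> float:
        return expected_maf(self.id, ff)


GENOTYPE_COMBOS: dict[int, GenotypeCombo] = {
    1: GenotypeCombo(1, "AA", "AA"),
    2: GenotypeCombo(2, "AA", "AB"),
    3: GenotypeCombo(3, "AB", "AA"),
    4: GenotypeCombo(4, "AB", "AB"),
}


def expected_maf(combo: int | GenotypeCombo, ff: float) -> float:
    """Expected plasma minor-allele fraction for a genotype combination."""
    if isinstance(combo, GenotypeCombo):
        combo = combo.id
    if not 0.0 <= ff <= 1.0:
        raise ValueError(f"ff must be in [0, 1], got {ff}")
    if combo == 1:
        return 0.0
    if combo == 2:
        return ff / 2.0
    if combo == 3:
        return 0.5 - ff / 2.0
    if combo == 4:
        return 0.5
    raise ValueError(f"unknown genotype combination id {combo}")


@dataclass
class MafVector:
    """Sorted minor-allele fractions retained in the fitting window."""

    values: np.ndarray
    window: tuple[float, float] = DEFAULT_MAF_WINDOW
    n_source_loci: int = 0
    mean_depth: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        lo, hi = self.window
        if len(self.values) and (self.values[0] < lo or self.values[-1] > hi):
            raise ValueError("MAF values outside the fitting window")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def retained_fraction(self) -> float:
        return len(self.values) / self.n_source_loci if self.n_source_loci else 0.0


def fold_maf(b_fraction: np.ndarray) -> np.ndarray:
    """Fold a B-allele fraction to the minor allele: min(f, 1 - f)."""
    f = np.asarray(b_fraction, dtype=float)
    return np.minimum(f, 1.0 - f)


def extract_maf_vector(sample: PlasmaSnpSample,
                       window: tuple[float, float] = DEFAULT_MAF_WINDOW,
                       excluded_chromosomes: Sequence[str] = FF_EXCLUDED_CHROMOSOMES,
                       min_depth: int = 20) -> MafVector:
    """Filter a plasma sample down to the MAF values the model fits.

    Keeps loci on allowed chromosomes with depth >= min_depth whose folded
    MAF lies inside the (closed) window; raises if nothing is retained.
    """
    excluded = {str(c) for c in excluded_chromosomes}
    allowed = ~np.isin(sample.chrom.astype(str), list(excluded))
    deep = sample.depth >= min_depth
    usable = allowed & deep
    if not usable.any():
        raise ValueError("no loci pass the chromosome/depth filters; "
                         "sample unusable for FF estimation")
    maf = fold_maf(sample.b_count[usable] / sample.depth[usable])
    lo, hi = window
    kept = maf[(maf >= lo) & (maf <= hi)]
    if kept.size == 0:
        raise ValueError("no MAF values inside the fitting window; "
                         "sample unusable for FF estimation")
    return MafVector(kept, window=window, n_source_loci=int(usable.sum()),
                     mean_depth=float(sample.depth[usable].mean()))


@dataclass
class FFEstimate:
    fitted_ff: float
    fit_distance: float
    n_values_used: int
    method: str


@dataclass
class SimLibrary:
    """Simulated MAF-distribution references on a grid of candidate FFs.

    ``vectors`` has shape (n_grid, n_reps, n_quantiles + 1): per replicate,
    evenly spaced quantiles of the windowed MAF values followed by the
    retained-locus fraction (weighted), so both the location of the
    fetal MAF cloud and how much of it enters the window inform the fit.
    """

    ff_grid: np.ndarray
    vectors: np.ndarray = field(repr=False)
    coverage: float = 150.0
    n_snps: int = 2000
    n_reps: int = 40
    seed: int | None = None
    window: tuple[float, float] = DEFAULT_MAF_WINDOW
    min_depth: int = 20
    n_quantiles: int = 101
    count_weight: float = 1.0

    def __post_init__(self) -> None:
        self.ff_grid = np.asarray(self.ff_grid, dtype=float)
        if len(self.ff_grid) == 0:
            raise ValueError("ff_grid is empty")
        if np.any(np.diff(self.ff_grid) <= 0):
            raise ValueError("ff_grid must be strictly increasing")
        if self.ff_grid[0] < 0.0 or self.ff_grid[-1] > 0.5:
            raise ValueError("ff_grid must lie within [0, 0.5]")
        expect = (len(self.ff_grid), self.n_reps, self.n_quantiles + 1)
        if self.vectors.shape != expect:
            raise ValueError(f"vectors shape {self.vectors.shape} != {expect}")

    @property
    def component_weights(self) -> np.ndarray:
        """Inverse of the pooled per-component replicate variance, so noisy
        summary components (e.g. the extreme quantiles) are down-weighted
        in the fit distance."""
        if getattr(self, "_weights", None) is None:
            if self.n_reps < 2:
                self._weights = np.ones(self.vectors.shape[-1])
            else:
                var = self.vectors.var(axis=1, ddof=1).mean(axis=0)
                self._weights = 1.0 / np.maximum(var, 1e-12)
        return self._weights

    def summarize(self, maf: MafVector) -> np.ndarray:
        """Reduce a MAF vector to this library's fixed-length summary."""
        q = np.linspace(0.0, 1.0, self.n_quantiles)
        if len(maf) == 0:
            quant = np.full(self.n_quantiles, self.window[0])
        else:
            quant = np.quantile(maf.values, q)
        return np.concatenate([quant, [self.count_weight * maf.retained_fraction]])

    def save(self, path) -> None:
        np.savez(path, ff_grid=self.ff_grid, vectors=self.vectors,
                 meta=np.array([self.coverage, self.n_snps, self.n_reps,
                                -1 if self.seed is None else self.seed,
                                *self.window, self.min_depth,
                                self.n_quantiles, self.count_weight]))

    @classmethod
    def load(cls, path) -> "SimLibrary":
        z = np.load(path)
        m = z["meta"]
        seed = None if m[3] < 0 else int(m[3])
        return cls(z["ff_grid"], z["vectors"], coverage=float(m[0]),
                   n_snps=int(m[1]), n_reps=int(m[2]), seed=seed,
                   window=(float(m[4]), float(m[5])), min_depth=int(m[6]),
                   n_quantiles=int(m[7]), count_weight=float(m[8]))


def build_sim_library(ff_grid: Sequence[float] = DEFAULT_FF_GRID,
                      coverage: float = 150.0,
                      n_snps: int = 2000,
                      n_reps: int = 40,
                      pop: PopulationModel | None = None,
                      seed: int | None = None,
                      panel: PanelDesign | None = None,
                      window: tuple[float, float] = DEFAULT_MAF_WINDOW,
                      min_depth: int = 20,
                      n_quantiles: int = 101,
                      count_weight: float = 1.0) -> SimLibrary:
    """Simulate the reference library the MAF model fits against."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    pop = pop or PopulationModel()
    panel = panel or default_panel()
    rng = as_rng(seed)
    grid = np.asarray(ff_grid, dtype=float)
    lib = SimLibrary(grid, np.zeros((len(grid), n_reps, n_quantiles + 1)),
                     coverage=coverage, n_snps=n_snps, n_reps=n_reps,
                     seed=seed, window=window, min_depth=min_depth,
                     n_quantiles=n_quantiles, count_weight=count_weight)
    for i, ff in enumerate(grid):
        cfg = SimSampleConfig(ff=float(ff), mean_coverage=coverage,
                              n_snps=n_snps)
        for r in range(n_reps):
            sample = simulate_plasma_snp_sample(cfg, pop, panel, rng=rng)
            try:
                maf = extract_maf_vector(sample, window=window,
                                         min_depth=min_depth)
            except ValueError:
                # degenerate replicate (e.g. ff ~ 0): empty window
                maf = MafVector(np.empty(0), window=window,
                                n_source_loci=n_snps)
            lib.vectors[i, r] = lib.summarize(maf)
    return lib


def _coverage_bucket(x: float) -> int:
    return min(COVERAGE_BUCKETS, key=lambda b: abs(b - x))


def fit_ff(maf: MafVector, lib: SimLibrary, interp_halfwidth: int = 2
           ) -> FFEstimate:
    """Fit fetal fraction by matching the sample's MAF summary to the library.

    The score at each grid FF is the mean (over that grid point's
    replicates) of the weighted squared distance between summary vectors;
    weights down-scale noisy components (see
    :attr:`SimLibrary.component_weights`).  The minimum is refined by a
    least-squares parabola over the arg-min grid point and its
    ``interp_halfwidth`` neighbours on each side — the squared-distance
    curve is locally quadratic in the candidate FF.
    """
    if maf.mean_depth and _coverage_bucket(maf.mean_depth) != _coverage_bucket(lib.coverage):
        warnings.warn(f"sample coverage {maf.mean_depth:.0f}X does not match "
                      f"library coverage {lib.coverage:.0f}X", stacklevel=2)
    if maf.n_source_loci and not (1 / 1.5 <= maf.n_source_loci / lib.n_snps <= 1.5):
        warnings.warn(f"sample SNP number {maf.n_source_loci} far from "
                      f"library n_snps {lib.n_snps}", stacklevel=2)
    v = lib.summarize(maf)
    w = lib.component_weights
    dists = ((lib.vectors - v) ** 2 * w).sum(axis=2).mean(axis=1)
    if not np.isfinite(dists).any():
        raise ValueError("no finite distances against the library")
    i = int(np.argmin(dists))
    grid = lib.ff_grid
    fitted = grid[i]
    lo, hi = max(0, i - interp_halfwidth), min(len(grid), i + interp_halfwidth + 1)
    if hi - lo >= 3:
        a, b, _ = np.polyfit(grid[lo:hi], dists[lo:hi], 2)
        if a > 0:
            vertex = -b / (2.0 * a)
            if grid[lo] <= vertex <= grid[hi - 1]:
                fitted = vertex
    fitted = float(np.clip(fitted, 0.0, 0.5))
    return FFEstimate(fitted_ff=fitted, fit_distance=float(dists[i]),
                      n_values_used=len(maf), method="maf_model")


def ff_from_fetal_specific(sample: PlasmaSnpSample,
                           maternal_genotypes: Mapping[tuple[str, int], int],
                           min_depth: int = 100,
                           min_fetal_reads: int = 2,
                           min_fetal_af: float = 0.01,
                           min_informative: int = 10) -> FFEstimate:
    """FF from fetal-specific alleles, given the maternal genotype calls.

    At loci where the mother is homozygous and the other allele is seen —
    at least ``min_fetal_reads`` reads and ``min_fetal_af`` of the depth,
    so stray sequencing-error reads (~0.1%) do not pass as fetal signal —
    the plasma fraction of that allele estimates FF/2; FF is twice the
    median over informative loci with depth >= min_depth.
    """
    fracs = []
    for c, q, d, b in zip(sample.chrom, sample.pos, sample.depth, sample.b_count):
        g = maternal_genotypes.get((str(c), int(q)))
        if g is None or g == 1 or d < min_depth:
            continue
        fetal = b if g == 0 else d - b
        if fetal >= max(min_fetal_reads, int(np.ceil(min_fetal_af * d))):
            fracs.append(fetal / d)
    if len(fracs) < min_informative:
        raise ValueError(f"only {len(fracs)} informative fetal-specific loci "
                         f"(need >= {min_informative}); estimate unreliable")
    ff = 2.0 * float(np.median(fracs))
    return FFEstimate(fitted_ff=ff, fit_distance=0.0,
                      n_values_used=len(fracs), method="fetal_specific")


def ff_from_chry(y_prop_sample: float, y_prop_male_reference: float) -> FFEstimate:
    """FF from the chrY read proportion of a male-fetus pregnancy, scaled by
    the proportion a fully male genome yields on the same panel/platform."""
    if y_prop_male_reference <= 0:
        raise ValueError("male reference chrY proportion must be positive")
    ff = float(y_prop_sample / y_prop_male_reference)
    return FFEstimate(fitted_ff=ff, fit_distance=0.0, n_values_used=1,
                      method="chr_y")


def calibrate_male_chry_reference(panel: PanelDesign | None = None,
                                  platform: str = "miseq",
                                  n: int = 20,
                                  seed: int | np.random.Generator | None = None,
                                  ) -> float:
    """Mean chrY proportion of simulated 100%-male samples on this panel."""
    from .dosage import chry_proportion
    from .simulate import PLATFORM_DEFAULTS, simulate_readcount_sample
    panel = panel or default_panel()
    rng = as_rng(seed)
    defaults = PLATFORM_DEFAULTS[platform]
    props = []
    for _ in range(n):
        cfg = SimSampleConfig(ff=1.0, fetal_sex="male",
                              mean_coverage=defaults["mean_coverage"],
                              total_reads=int(defaults["total_reads"]))
        s = simulate_readcount_sample(cfg, panel, platform=platform, rng=rng)
        props.append(chry_proportion(s))
    return float(np.mean(props))


def degree_of_deviation(expected: float, fitted: float) -> float:
    """Relative fitting error (expected - fitted) / expected."""
    if expected == 0:
        raise ValueError("degree of deviation undefined for expected FF 0")
    return (expected - fitted) / expected
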
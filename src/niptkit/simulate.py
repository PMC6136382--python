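"""Synthetic plasma-sequencing cohorts.

Maternal plasma cfDNA is modelled as a two-genome mixture: a fraction
``ff`` (the fetal fraction) of fragments derive from the fetus, the rest
from the mother.  At a biallelic SNP the expected plasma B-allele
fraction is therefore::

    f = (1 - ff) * g_m / 2 + ff * g_f / 2

with ``g_m``, ``g_f`` the maternal/fetal B-allele dosages (0, 1, 2).
The four maternal/fetal genotype combinations give expected minor-allele
fractions 0, ff/2, 0.5 - ff/2 and 0.5, which is what the fetal-fraction
model fits downstream.

Read counts per chromosome follow a multinomial whose cell probabilities
are proportional to panel bases weighted by copy number in the mixture:
trisomy 21 inflates the chr21 share by (1 + ff/2); a male fetus
contributes a hemizygous chrY share of ff * y_bases / 2; female-fetus
pregnancies see only a small misalignment noise floor on chrY.

Mock pregnancies are built the way wet-lab mocks are: a mother and her
child are sampled as separate individuals with genotypes linked by
inheritance, and their reads are thinned and recombined at the chosen
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .panel import AUTOSOMES, PanelDesign, default_panel

__all__ = [
    "PopulationModel",
    "SimSampleConfig",
    "PlasmaSnpSample",
    "ReadCountSample",
    "FamilyPair",
    "simulate_plasma_snp_sample",
    "simulate_readcount_sample",
    "simulate_family_pair",
    "mix_mock_sample",
    "simulate_reference_cohort",
    "CHR_Y_NOISE_FLOOR",
    "PLATFORM_DEFAULTS",
]

# Female-fetus pregnancies still show a trickle of chrY-mapped reads from
# misalignment; modelled as a fixed share of the autosomal read mass.
CHR_Y_NOISE_FLOOR = 5.0e-7

# Per-platform operating points: mean SNP coverage (X) and total panel-wide
# reads, at the scale of typical MiSeq / HiSeq runs of this assay.
PLATFORM_DEFAULTS: dict[str, dict[str, float]] = {
    "miseq": {"mean_coverage": 150.0, "total_reads": 15_000_000},
    "hiseq": {"mean_coverage": 500.0, "total_reads": 100_000_000},
}


def as_rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class PopulationModel:
    """Population allele frequencies and sequencing noise at panel SNPs.

    allele_frequency_sampler draws B-allele population frequencies for a
    batch of loci; the default is uniform on [0.05, 0.5], i.e. common
    panel SNPs.  sequencing_error_rate is the per-read probability of
    reporting the wrong allele.
    """

    allele_frequency_sampler: Callable[[np.random.Generator, int], np.ndarray] = (
        lambda rng, n: rng.uniform(0.05, 0.5, size=n)
    )
    sequencing_error_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.sequencing_error_rate <= 0.01:
            raise ValueError("sequencing_error_rate must be in [0, 0.01]")

    def sample_frequencies(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = np.asarray(self.allele_frequency_sampler(rng, n), dtype=float)
        if p.shape != (n,) or np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("sampled population frequencies must be in (0, 1)")
        return p


@dataclass
class SimSampleConfig:
    """Parameters of one simulated plasma (or individual) sample.

    ff=0 denotes a non-pregnant individual; ff=1 a pure (child) genome.
    """

    ff: float = 0.1
    mean_coverage: float = 150.0
    n_snps: int = 2000
    trisomy21: bool = False
    fetal_sex: str = "female"
    total_reads: int = 15_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff <= 1.0:
            raise ValueError(f"ff must be in [0, 1], got {self.ff}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.fetal_sex not in ("male", "female"):
            raise ValueError("fetal_sex must be 'male' or 'female'")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


@dataclass
class PlasmaSnpSample:
    """Per-locus allelic read depths from a plasma variant call.

    Arrays are parallel over loci.  ``true_combo`` carries the simulator's
    maternal/fetal genotype-combination labels (1-4, or -1 when unknown,
    e.g. after VCF round-trips of real data).
    """

    chrom: np.ndarray
    pos: np.ndarray
    depth: np.ndarray
    b_count: np.ndarray
    true_combo: np.ndarray | None = None
    config: SimSampleConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.b_count = np.asarray(self.b_count, dtype=np.int64)
        n = len(self.chrom)
        for arr in (self.pos, self.depth, self.b_count):
            if len(arr) != n:
                raise ValueError("locus arrays must be parallel")
        if np.any(self.depth < 0) or np.any(self.b_count < 0):
            raise ValueError("read counts must be non-negative")
        if np.any(self.b_count > self.depth):
            raise ValueError("b_count may not exceed depth")
        if self.true_combo is not None:
            self.true_combo = np.asarray(self.true_combo, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self) else 0.0


@dataclass
class ReadCountSample:
    """Per-chromosome read counts from a depth-of-coverage table."""

    counts: dict[str, int]
    platform: str = "miseq"
    truth: dict | None = None

    def __post_init__(self) -> None:
        counts = {str(k): int(v) for k, v in self.counts.items()}
        missing = [c for c in (*AUTOSOMES, "Y") if c not in counts]
        if missing:
            raise ValueError(f"read-count table missing chromosomes: {missing}")
        if any(v < 0 for v in counts.values()):
            raise ValueError("read counts must be non-negative")
        self.counts = counts


@dataclass
class FamilyPair:
    """A mother and her child sampled as separate individuals, genotype-linked."""

    mother_snp: PlasmaSnpSample
    mother_counts: ReadCountSample
    child_snp: PlasmaSnpSample
    child_counts: ReadCountSample
    maternal_genotypes: dict[tuple[str, int], int]
    child_sex: str
    child_trisomy21: bool


def _locus_layout(panel: PanelDesign, n_snps: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign n_snps loci to FF-informative probes (round-robin)."""
    probes = panel.ff_probes()
    if len(probes) == 0:
        raise ValueError("panel has no ff_informative probes")
    idx = np.arange(n_snps) % len(probes)
    lap = np.arange(n_snps) // len(probes)
    chrom = probes["chrom"].to_numpy()[idx]
    pos = probes["start"].to_numpy()[idx] + 1 + lap  # VCF-style 1-based
    return chrom, pos


def _draw_genotypes(rng: np.random.Generator, p: np.ndarray, ff: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Maternal dosage under Hardy-Weinberg; fetal dosage by transmitting one
    maternal allele uniformly plus an independent paternal allele.  For a
    non-pregnant individual (ff == 0) there is no fetus and the fetal dosage
    mirrors the maternal one."""
    g_m = rng.binomial(2, p)
    if ff == 0.0:
        return g_m, g_m.copy()
    transmitted = rng.binomial(1, g_m / 2.0)
    paternal = rng.binomial(1, p)
    return g_m, transmitted + paternal


def combo_id(g_m: np.ndarray, g_f: np.ndarray) -> np.ndarray:
    """Genotype-combination label: 1 both homozygous, 2 maternal hom / fetal
    het (expected MAF ff/2), 3 maternal het / fetal hom (0.5 - ff/2),
    4 both het (0.5)."""
    m_het = g_m == 1
    f_het = g_f == 1
    out = np.ones(len(g_m), dtype=np.int64)
    out[~m_het & f_het] = 2
    out[m_het & ~f_het] = 3
    out[m_het & f_het] = 4
    return out


def _sample_reads(rng: np.random.Generator, cfg: SimSampleConfig,
                  pop: PopulationModel, g_m: np.ndarray, g_f: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    f = (1.0 - cfg.ff) * g_m / 2.0 + cfg.ff * g_f / 2.0
    e = pop.sequencing_error_rate
    f = f * (1.0 - e) + (1.0 - f) * e
    depth = rng.poisson(cfg.mean_coverage, size=len(g_m))
    b = rng.binomial(depth, f)
    return depth, b


def simulate_plasma_snp_sample(config: SimSampleConfig,
                               pop: PopulationModel | None = None,
                               panel: PanelDesign | None = None,
                               rng: int | np.random.Generator | None = None,
                               ) -> PlasmaSnpSample:
    """Simulate one plasma variant-call sample at the panel's SNP probes."""
    pop = pop or PopulationModel()
    panel = panel or default_panel()
    rng = as_rng(config.seed if rng is None else rng)
    chrom, pos = _locus_layout(panel, config.n_snps)
    p = pop.sample_frequencies(rng, config.n_snps)
    g_m, g_f = _draw_genotypes(rng, p, config.ff)
    depth, b = _sample_reads(rng, config, pop, g_m, g_f)
    return PlasmaSnpSample(chrom, pos, depth, b,
                           true_combo=combo_id(g_m, g_f), config=config)


def _chromosome_weights(panel: PanelDesign, cfg: SimSampleConfig,
                        noise_floor: float) -> tuple[list[str], np.ndarray]:
    bases = panel.bases_by_chromosome()
    chroms = [*AUTOSOMES, "Y"]
    w = np.array([bases.get(c, 0) for c in chroms], dtype=float)
    i21 = chroms.index("21")
    iy = chroms.index("Y")
    if cfg.trisomy21:
        w[i21] *= 1.0 + cfg.ff / 2.0  # three fetal copies of chr21 vs two
    auto_mass = w[:iy].sum()
    w[iy] = noise_floor * auto_mass
    if cfg.fetal_sex == "male":
        w[iy] += cfg.ff * bases.get("Y", 0) / 2.0  # hemizygous fetal Y
    return chroms, w


def simulate_readcount_sample(config: SimSampleConfig,
                              panel: PanelDesign | None = None,
                              dispersion: float = 1.0,
                              platform: str = "miseq",
                              noise_floor: float = CHR_Y_NOISE_FLOOR,
                              rng: int | np.random.Generator | None = None,
                              ) -> ReadCountSample:
    """Simulate a per-chromosome read-count table.

    ``dispersion`` >= 1 inflates between-sample variance (Dirichlet-
    multinomial); 1.0 is a plain multinomial.
    """
    panel = panel or default_panel()
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    rng = as_rng(config.seed if rng is None else rng)
    chroms, w = _chromosome_weights(panel, config, noise_floor)
    if w.sum() <= 0:
        raise ValueError("panel defines no read mass")
    probs = w / w.sum()
    n = int(config.total_reads)
    if dispersion > 1.0:
        conc = (n - dispersion) / (dispersion - 1.0)
        probs = rng.dirichlet(probs * conc)
    counts = rng.multinomial(n, probs)
    truth = {"ff": config.ff, "trisomy21": config.trisomy21,
             "fetal_sex": config.fetal_sex}
    return ReadCountSample(dict(zip(chroms, counts.tolist())),
                           platform=platform, truth=truth)


def expected_chr21_inflation(ff: float) -> float:
    """Closed-form chr21 read-share inflation factor under trisomy 21."""
    return 1.0 + ff / 2.0


def simulate_family_pair(config: SimSampleConfig,
                         pop: PopulationModel | None = None,
                         panel: PanelDesign | None = None,
                         dispersion: float = 1.0,
                         platform: str = "miseq",
                         rng: int | np.random.Generator | None = None,
                         ) -> FamilyPair:
    """Simulate a mother and her child as separate sequenced individuals.

    ``config.fetal_sex`` / ``config.trisomy21`` describe the child;
    ``config.ff`` is ignored (the pair is meant for mock mixing).  The
    child's SNP sample carries the mother/child genotype-combination
    labels, so mocks mixed from the pair keep interpretable truth.
    """
    pop = pop or PopulationModel()
    panel = panel or default_panel()
    rng = as_rng(config.seed if rng is None else rng)
    chrom, pos = _locus_layout(panel, config.n_snps)
    p = pop.sample_frequencies(rng, config.n_snps)
    g_m = rng.binomial(2, p)
    transmitted = rng.binomial(1, g_m / 2.0)
    g_c = transmitted + rng.binomial(1, p)

    mother_cfg = replace(config, ff=0.0, trisomy21=False, fetal_sex="female")
    child_cfg = replace(config, ff=1.0)
    md, mb = _sample_reads(rng, mother_cfg, pop, g_m, g_m)
    cd, cb = _sample_reads(rng, child_cfg, pop, g_m, g_c)
    combos = combo_id(g_m, g_c)
    mother_snp = PlasmaSnpSample(chrom, pos, md, mb,
                                 true_combo=combo_id(g_m, g_m), config=mother_cfg)
    child_snp = PlasmaSnpSample(chrom, pos, cd, cb,
                                true_combo=combos, config=child_cfg)
    mother_counts = simulate_readcount_sample(mother_cfg, panel, dispersion,
                                              platform, rng=rng)
    child_counts = simulate_readcount_sample(child_cfg, panel, dispersion,
                                             platform, rng=rng)
    genotypes = {(c, int(q)): int(g) for c, q, g in zip(chrom, pos, g_m)}
    return FamilyPair(mother_snp, mother_counts, child_snp, child_counts,
                      genotypes, config.fetal_sex, config.trisomy21)


def _check_shared_loci(a: PlasmaSnpSample, b: PlasmaSnpSample) -> None:
    if len(a) != len(b):
        raise ValueError(f"locus mismatch: {len(a)} vs {len(b)} loci")
    bad = (a.chrom != b.chrom) | (a.pos != b.pos)
    if np.any(bad):
        idx = np.flatnonzero(bad)[:10]
        loci = [f"{a.chrom[i]}:{a.pos[i]}!={b.chrom[i]}:{b.pos[i]}" for i in idx]
        raise ValueError(f"locus mismatch at {bad.sum()} positions, e.g. {loci}")


def mix_mock_sample(maternal_snp: PlasmaSnpSample,
                    maternal_counts: ReadCountSample,
                    child_snp: PlasmaSnpSample,
                    child_counts: ReadCountSample,
                    ff: float,
                    rng: int | np.random.Generator | None = None,
                    ) -> tuple[PlasmaSnpSample, ReadCountSample]:
    """In-silico pregnancy mock: thin the child's reads to fraction ``ff``
    and the mother's to ``1 - ff``, then recombine, per locus and per
    chromosome.  The statistical equivalent of mixing the pair's FASTQs."""
    if not 0.0 <= ff <= 1.0:
        raise ValueError("ff must be in [0, 1]")
    _check_shared_loci(maternal_snp, child_snp)
    rng = as_rng(rng)

    keep_cb = rng.binomial(child_snp.b_count, ff)
    keep_cr = rng.binomial(child_snp.depth - child_snp.b_count, ff)
    keep_mb = rng.binomial(maternal_snp.b_count, 1.0 - ff)
    keep_mr = rng.binomial(maternal_snp.depth - maternal_snp.b_count, 1.0 - ff)
    b = keep_cb + keep_mb
    depth = b + keep_cr + keep_mr
    cfg = None
    if child_snp.config is not None:
        cfg = replace(child_snp.config, ff=ff)
    snp = PlasmaSnpSample(maternal_snp.chrom, maternal_snp.pos, depth, b,
                          true_combo=child_snp.true_combo, config=cfg)

    counts = {}
    for c in (*AUTOSOMES, "Y"):
        counts[c] = int(rng.binomial(child_counts.counts[c], ff)
                        + rng.binomial(maternal_counts.counts[c], 1.0 - ff))
    child_truth = child_counts.truth or {}
    truth = {"ff": ff, "trisomy21": child_truth.get("trisomy21", False),
             "fetal_sex": child_truth.get("fetal_sex", "female")}
    return snp, ReadCountSample(counts, platform=maternal_counts.platform,
                                truth=truth)


def simulate_reference_cohort(n: int,
                              panel: PanelDesign | None = None,
                              platform: str = "miseq",
                              seed: int | np.random.Generator | None = None,
                              fetal_sex: str = "female",
                              ff_range: tuple[float, float] = (0.02, 0.25),
                              dispersion: float = 1.0,
                              total_reads: int | None = None,
                              ) -> list[ReadCountSample]:
    """A cohort of euploid pregnancies for reference normalization.

    Fetal sex defaults to female so the same cohort serves both the chr21
    and the chrY (fetal sex) reference.
    """
    if n < 5:
        raise ValueError("reference cohort needs at least 5 samples")
    if platform not in PLATFORM_DEFAULTS:
        raise ValueError(f"unknown platform {platform!r}")
    panel = panel or default_panel()
    rng = as_rng(seed)
    if total_reads is None:
        total_reads = int(PLATFORM_DEFAULTS[platform]["total_reads"])
    cohort = []
    for _ in range(n):
        cfg = SimSampleConfig(ff=float(rng.uniform(*ff_range)),
                              trisomy21=False, fetal_sex=fetal_sex,
                              total_reads=total_reads)
        cohort.append(simulate_readcount_sample(cfg, panel, dispersion,
                                                platform, rng=rng))
    return cohort
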
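"""Readers and writers for the pipeline's interchange formats.

VCF (with per-sample AD/DP) is the single variant interchange format:
the simulator writes it and the estimators read it back, so the pipeline
exercises real-world I/O.  Read counts travel as two-column TSV
(chromosome, count), the panel as BED4 (half-open, 0-based, role in
column 4), annotated variants for the monogenic screen as TSV, and runs
are described by a sample manifest (TSV) plus a flat YAML config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .dosage import (DEFAULT_FF_THRESHOLD, DEFAULT_SEX_THRESHOLD,
                     DEFAULT_Z_THRESHOLD)
from .fetal_fraction import DEFAULT_MAF_WINDOW
from .monogenic import AnnotatedVariant, DEFAULT_POP_FREQ_THRESHOLD
from .panel import AUTOSOMES, normalize_chrom
from .simulate import PlasmaSnpSample, ReadCountSample

SCHEMA_VERSION = "1"

_CONTIGS = [*AUTOSOMES, "X", "Y"]


# ---------------------------------------------------------------------------
# VCF

def _vcf_header(sample_name: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in _CONTIGS:
        header.contigs.add(c, length=250_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths for the ref and alt alleles")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample_name)
    return header


def write_snp_vcf(sample: PlasmaSnpSample, path: str | Path,
                  sample_name: str = "PLASMA") -> None:
    """Write a plasma sample's allelic depths as an uncompressed VCF."""
    header = _vcf_header(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c, p, d, b in zip(sample.chrom, sample.pos, sample.depth,
                              sample.b_count):
            rec = vcf.new_record(contig=str(c), start=int(p) - 1,
                                 alleles=("A", "C"))
            rec.samples[sample_name]["GT"] = (None, None)
            rec.samples[sample_name]["AD"] = (int(d - b), int(b))
            rec.samples[sample_name]["DP"] = int(d)
            vcf.write(rec)


def write_genotypes_vcf(genotypes: dict[tuple[str, int], int],
                        path: str | Path, sample_name: str = "MOTHER") -> None:
    """Write genotype calls (B-allele dosage 0/1/2) as a VCF."""
    header = _vcf_header(sample_name)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for (c, p), g in sorted(genotypes.items(),
                                key=lambda kv: (_CONTIGS.index(kv[0][0]), kv[0][1])):
            rec = vcf.new_record(contig=str(c), start=int(p) - 1,
                                 alleles=("A", "C"))
            rec.samples[sample_name]["GT"] = gt_map[int(g)]
            vcf.write(rec)


def read_vcf_with_depths(path: str | Path) -> PlasmaSnpSample:
    """Read plasma variant records with per-allele depths.

    Multiallelic records are decomposed into biallelic rows (ref vs each
    alt, each with its own AD pair).  Records without an AD field raise,
    naming the offending record.
    """
    chroms, poss, depths, bs = [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if not sample_names:
            raise ValueError(f"{path}: VCF has no sample columns")
        name = sample_names[0]
        for rec in vcf:
            sample = rec.samples[name]
            ad = sample.get("AD")
            if ad is None or all(a is None for a in ad):
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} "
                                 "has no allelic depths (AD)")
            ref_d = int(ad[0] or 0)
            for alt_d in ad[1:]:
                alt_d = int(alt_d or 0)
                chroms.append(normalize_chrom(rec.chrom))
                poss.append(rec.pos)
                depths.append(ref_d + alt_d)
                bs.append(alt_d)
    return PlasmaSnpSample(np.array(chroms, dtype=object), poss, depths, bs)


def read_genotypes_vcf(path: str | Path) -> dict[tuple[str, int], int]:
    """Read genotype calls as {(chrom, pos): B-allele dosage}."""
    out: dict[tuple[str, int], int] = {}
    with pysam.VariantFile(str(path)) as vcf:
        name = list(vcf.header.samples)[0]
        for rec in vcf:
            gt = rec.samples[name].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            out[(normalize_chrom(rec.chrom), rec.pos)] = int(sum(gt))
    return out


# ---------------------------------------------------------------------------
# Read-count tables

def write_counts_tsv(sample: ReadCountSample, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tcount\n")
        for c, n in sample.counts.items():
            fh.write(f"{c}\t{n}\n")


def read_counts_table(path: str | Path, platform: str = "miseq"
                      ) -> ReadCountSample:
    """Read a two-column (chromosome, count) TSV; chr-prefix tolerant."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (chromosome, count)")
    chrom = df.iloc[:, 0].map(normalize_chrom)
    if chrom.duplicated().any():
        dups = sorted(chrom[chrom.duplicated()].unique())
        raise ValueError(f"{path}: duplicate chromosome rows: {dups}")
    raw = df.iloc[:, 1]
    counts_f = pd.to_numeric(raw, errors="raise")
    if not np.allclose(counts_f, counts_f.round()):
        raise ValueError(f"{path}: read counts must be integers")
    return ReadCountSample(dict(zip(chrom, counts_f.astype(int))),
                           platform=platform)


# ---------------------------------------------------------------------------
# Annotated variants (monogenic screen)

_VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "observed_af",
                    "depth", "population_frequency", "disease_group"]


def write_annotated_variants(variants: list[AnnotatedVariant],
                             path: str | Path) -> None:
    rows = [{k: getattr(v, k) for k in _VARIANT_COLUMNS} for v in variants]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t",
                                                        index=False)


def read_annotated_variants(path: str | Path) -> list[AnnotatedVariant]:
    """Read an annotated variant TSV.  A missing population frequency is
    treated as 0 (never-seen variant) and flagged novel."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_VARIANT_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        pf = getattr(row, "population_frequency")
        novel = pd.isna(pf)
        group = getattr(row, "disease_group", None)
        out.append(AnnotatedVariant(
            chrom=normalize_chrom(row.chrom), pos=int(row.pos),
            ref=str(row.ref), alt=str(row.alt), gene=str(row.gene),
            observed_af=float(row.observed_af), depth=int(row.depth),
            population_frequency=0.0 if novel else float(pf),
            disease_group=None if pd.isna(group) else str(group),
            novel=bool(novel)))
    return out


def read_gene_set(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and #-comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


# ---------------------------------------------------------------------------
# Manifest and run configuration

@dataclass
class ManifestRow:
    sample_id: str
    platform: str
    role: str  # reference | test
    vcf: str | None = None
    counts: str | None = None
    maternal_vcf: str | None = None
    variants: str | None = None
    true_ff: float | None = None

    def __post_init__(self) -> None:
        if self.platform not in ("miseq", "hiseq"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.role not in ("reference", "test"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class SampleManifest:
    rows: list[ManifestRow]
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        for r in self.rows:
            for attr in ("vcf", "counts", "maternal_vcf", "variants"):
                rel = getattr(r, attr)
                if rel is not None and not (self.base_dir / rel).exists():
                    raise ValueError(f"{r.sample_id}: missing file {rel}")

    def resolve(self, rel: str) -> Path:
        return self.base_dir / rel

    @property
    def references(self) -> list[ManifestRow]:
        return [r for r in self.rows if r.role == "reference"]

    @property
    def tests(self) -> list[ManifestRow]:
        return [r for r in self.rows if r.role == "test"]


def read_manifest(path: str | Path) -> SampleManifest:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows = []
    for rec in df.to_dict("records"):
        clean = {k: (None if pd.isna(v) else v) for k, v in rec.items()}
        if clean.get("true_ff") is not None:
            clean["true_ff"] = float(clean["true_ff"])
        rows.append(ManifestRow(**clean))
    return SampleManifest(rows, base_dir=path.parent)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in manifest.rows]).to_csv(
        path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Flat run configuration; every CLI flag overrides a config key."""

    ff_threshold: float = DEFAULT_FF_THRESHOLD
    z_threshold: float = DEFAULT_Z_THRESHOLD
    sex_threshold: float = DEFAULT_SEX_THRESHOLD
    pop_freq_threshold: float = DEFAULT_POP_FREQ_THRESHOLD
    maf_window_low: float = DEFAULT_MAF_WINDOW[0]
    maf_window_high: float = DEFAULT_MAF_WINDOW[1]
    excluded_chromosomes: tuple[str, ...] = ("18", "21")
    confidence: float = 0.99
    seed: int = 0
    gene_set: str | None = None
    library: str | None = None
    out_dir: str = "nipt_out"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff_threshold <= 1.0:
            raise ValueError("ff_threshold must be in [0, 1]")
        if self.z_threshold <= 0 or self.sex_threshold <= 0:
            raise ValueError("z thresholds must be positive")
        if not 0.0 < self.maf_window_low < self.maf_window_high <= 0.5:
            raise ValueError("bad MAF window")

    @property
    def maf_window(self) -> tuple[float, float]:
        return (self.maf_window_low, self.maf_window_high)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "excluded_chromosomes" in data:
            data["excluded_chromosomes"] = tuple(
                str(c) for c in data["excluded_chromosomes"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["excluded_chromosomes"] = list(self.excluded_chromosomes)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def write_json(obj, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
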
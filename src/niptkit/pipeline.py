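"""End-to-end test workflow: FF -> fetal sex -> T21 -> monogenic screen.

``run_all`` consumes a sample manifest (reference and test samples with
their VCF / read-count paths) plus a run configuration, and produces a
single report with per-sample fetal-fraction estimates (all applicable
methods), sex and trisomy-21 calls, monogenic candidates, and the
cohort-level reference statistics.  A missing platform-matched reference
degrades that sample to no_call with an explicit reason; the run
continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as nio
from .dosage import (ReferenceStats, call_sex, call_t21,
                     chromosome_proportion, chry_proportion,
                     normalize_reference, z_score)
from .fetal_fraction import (SimLibrary, build_sim_library, extract_maf_vector,
                             ff_from_chry, ff_from_fetal_specific, fit_ff,
                             COVERAGE_BUCKETS)
from .io import ManifestRow, RunConfig, SampleManifest
from .monogenic import screen_candidates
from .panel import PanelDesign, default_panel
from .simulate import (PLATFORM_DEFAULTS, SimSampleConfig,
                       simulate_plasma_snp_sample, simulate_readcount_sample,
                       simulate_reference_cohort)

log = logging.getLogger("niptkit")

__all__ = ["run_all", "Report", "build_demo_cohort"]


@dataclass
class Report:
    samples: list[dict]
    references: dict[str, dict]
    config: dict

    def to_json(self, path: str | Path) -> None:
        nio.write_json({"samples": self.samples,
                        "references": self.references,
                        "config": self.config}, path)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        flat = []
        for s in self.samples:
            flat.append({
                "sample_id": s["sample_id"],
                "platform": s["platform"],
                "ff_maf_model": s["ff"].get("maf_model"),
                "ff_fetal_specific": s["ff"].get("fetal_specific"),
                "ff_chr_y": s["ff"].get("chr_y"),
                "sex_call": (s.get("sex") or {}).get("call"),
                "sex_z": (s.get("sex") or {}).get("z_y"),
                "t21_call": (s.get("t21") or {}).get("call"),
                "t21_z": (s.get("t21") or {}).get("z"),
                "n_candidates": len(s.get("monogenic") or []),
                "qc_flags": ";".join(s.get("qc_flags", [])),
            })
        pd.DataFrame(flat).to_csv(path, sep="\t", index=False)


def _reference_stats(manifest: SampleManifest, config: RunConfig
                     ) -> tuple[dict, dict, dict[str, dict]]:
    """Per-platform chr21 and chrY reference stats from the manifest's
    reference samples (assumed euploid; female-fetus for the chrY set)."""
    t21_refs: dict[str, ReferenceStats] = {}
    sex_refs: dict[str, ReferenceStats] = {}
    summary: dict[str, dict] = {}
    by_platform: dict[str, list[ManifestRow]] = {}
    for r in manifest.references:
        by_platform.setdefault(r.platform, []).append(r)
    for platform, rows in sorted(by_platform.items()):
        p21, py = [], []
        for r in rows:
            counts = nio.read_counts_table(manifest.resolve(r.counts),
                                           platform=platform)
            p21.append(chromosome_proportion(counts, "21"))
            py.append(chry_proportion(counts))
        try:
            t21_refs[platform] = normalize_reference(p21, platform, "21")
            sex_refs[platform] = normalize_reference(py, platform, "Y")
        except ValueError as exc:
            log.warning("platform %s reference unusable: %s", platform, exc)
            continue
        summary[platform] = {
            "n_reference": len(rows),
            "chr21": {"mean": t21_refs[platform].mean_proportion,
                      "sd": t21_refs[platform].sd_proportion,
                      "n_removed": t21_refs[platform].n_removed},
            "chrY": {"mean": sex_refs[platform].mean_proportion,
                     "sd": sex_refs[platform].sd_proportion,
                     "n_removed": sex_refs[platform].n_removed},
        }
        log.info("platform %s: reference normalized (chr21 removed %d, "
                 "chrY removed %d of %d)", platform,
                 t21_refs[platform].n_removed, sex_refs[platform].n_removed,
                 len(rows))
    return t21_refs, sex_refs, summary


class _LibraryCache:
    """Build simulation libraries lazily, one per coverage bucket/SNP-count
    combination actually encountered."""

    def __init__(self, config: RunConfig, panel: PanelDesign):
        self.config = config
        self.panel = panel
        self._cache: dict[tuple[int, int], SimLibrary] = {}
        if config.library and Path(config.library).exists():
            lib = SimLibrary.load(config.library)
            self._cache[(int(lib.coverage), lib.n_snps)] = lib

    def get(self, mean_depth: float, n_loci: int) -> SimLibrary:
        bucket = min(COVERAGE_BUCKETS, key=lambda b: abs(b - mean_depth))
        n_snps = max(500, int(round(n_loci / 500.0)) * 500)
        for (cov, n), lib in self._cache.items():
            if cov == bucket and 1 / 1.5 <= n / n_snps <= 1.5:
                return lib
        log.info("building MAF simulation library at %dX / %d SNPs", bucket,
                 n_snps)
        lib = build_sim_library(coverage=float(bucket), n_snps=n_snps,
                                seed=self.config.seed, panel=self.panel,
                                window=self.config.maf_window)
        self._cache[(bucket, n_snps)] = lib
        return lib


def _process_test_sample(row: ManifestRow, manifest: SampleManifest,
                         config: RunConfig, libs: _LibraryCache,
                         t21_refs: dict, sex_refs: dict,
                         male_y_ref: float, gene_set: set[str] | None) -> dict:
    result: dict = {"sample_id": row.sample_id, "platform": row.platform,
                    "ff": {}, "sex": None, "t21": None, "monogenic": None,
                    "qc_flags": []}
    ff = None
    if row.vcf:
        sample = nio.read_vcf_with_depths(manifest.resolve(row.vcf))
        try:
            maf = extract_maf_vector(sample, window=config.maf_window,
                                     excluded_chromosomes=config.excluded_chromosomes)
            est = fit_ff(maf, libs.get(maf.mean_depth, maf.n_source_loci))
            ff = est.fitted_ff
            result["ff"]["maf_model"] = round(ff, 4)
            log.info("%s: fitted FF %.3f from %d MAF values", row.sample_id,
                     ff, est.n_values_used)
        except ValueError as exc:
            result["qc_flags"].append(f"ff_unusable: {exc}")
        if row.maternal_vcf:
            genotypes = nio.read_genotypes_vcf(manifest.resolve(row.maternal_vcf))
            try:
                fs = ff_from_fetal_specific(sample, genotypes)
                result["ff"]["fetal_specific"] = round(fs.fitted_ff, 4)
            except ValueError as exc:
                result["qc_flags"].append(f"fetal_specific: {exc}")

    counts = None
    if row.counts:
        counts = nio.read_counts_table(manifest.resolve(row.counts),
                                       platform=row.platform)
        sex_ref = sex_refs.get(row.platform)
        if sex_ref is None:
            result["qc_flags"].append(
                f"no platform-matched reference ({row.platform})")
        else:
            zy = z_score(chry_proportion(counts), sex_ref)
            sex = call_sex(zy, config.sex_threshold)
            result["sex"] = {"z_y": round(zy, 3), "call": sex.call}
            if sex.call == "male":
                est = ff_from_chry(chry_proportion(counts), male_y_ref)
                result["ff"]["chr_y"] = round(est.fitted_ff, 4)
        t21_ref = t21_refs.get(row.platform)
        if t21_ref is None:
            result["t21"] = {"z": None, "call": "no_call",
                             "reason": "no platform-matched reference"}
        else:
            z21 = z_score(chromosome_proportion(counts, "21"), t21_ref)
            tc = call_t21(z21, ff if ff is not None else 0.0,
                          config.z_threshold, config.ff_threshold)
            result["t21"] = {"z": round(z21, 3), "ff": tc.ff,
                             "call": tc.call}
            if tc.call == "no_call":
                result["t21"]["reason"] = ("low fetal fraction"
                                           if ff is not None
                                           else "fetal fraction unavailable")

    if row.variants and gene_set and ff:
        variants = nio.read_annotated_variants(manifest.resolve(row.variants))
        calls = screen_candidates(variants, ff, gene_set,
                                  config.pop_freq_threshold,
                                  config.confidence)
        result["monogenic"] = [
            {"gene": c.variant.gene, "locus": f"{c.variant.chrom}:{c.variant.pos}",
             "observed_af": c.variant.observed_af,
             "expected_af": round(c.expected_af, 4),
             "af_window": [round(c.af_window[0], 4), round(c.af_window[1], 4)],
             "in_window": c.in_window, "rationale": c.rationale}
            for c in calls]
    return result


def run_all(manifest: SampleManifest, config: RunConfig,
            panel: PanelDesign | None = None) -> Report:
    """Run the full workflow over every test sample in the manifest."""
    if not manifest.tests:
        raise ValueError("manifest has no test samples")
    panel = panel or default_panel()
    t21_refs, sex_refs, ref_summary = _reference_stats(manifest, config)
    libs = _LibraryCache(config, panel)
    male_y_ref = panel.male_chry_proportion
    gene_set = nio.read_gene_set(config.gene_set) if config.gene_set else None
    samples = [_process_test_sample(r, manifest, config, libs, t21_refs,
                                    sex_refs, male_y_ref, gene_set)
               for r in manifest.tests]
    from dataclasses import asdict
    cfg = asdict(config)
    cfg["excluded_chromosomes"] = list(config.excluded_chromosomes)
    return Report(samples=samples, references=ref_summary, config=cfg)


# ---------------------------------------------------------------------------
# Packaged demo cohort

def build_demo_cohort(out_dir: str | Path, seed: int = 7,
                      n_reference: int = 54, n_t21: int = 10,
                      n_euploid: int = 30, platform: str = "miseq",
                      n_snps: int = 2000) -> Path:
    """Generate a synthetic cohort shaped like the study's mock experiment
    (euploid reference cohort plus T21 and euploid test pregnancies) and
    write it to disk; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    panel = default_panel()
    defaults = PLATFORM_DEFAULTS[platform]
    coverage = defaults["mean_coverage"]
    total_reads = int(defaults["total_reads"])
    rows: list[ManifestRow] = []

    for i, counts in enumerate(simulate_reference_cohort(
            n_reference, panel, platform, rng, total_reads=total_reads)):
        path = f"ref{i:03d}.counts.tsv"
        nio.write_counts_tsv(counts, out / path)
        rows.append(ManifestRow(f"REF{i:03d}", platform, "reference",
                                counts=path))

    specs = ([(True, f"T21-{i:02d}") for i in range(n_t21)]
             + [(False, f"EUP-{i:02d}") for i in range(n_euploid)])
    gene_set_path = out / "genes.txt"
    gene_set_path.write_text("FGFR3\nFLNB\nCOL1A1\nSERPINH1\n")
    for trisomy, sid in specs:
        ff = float(rng.uniform(0.04, 0.25))
        sex = "male" if rng.random() < 0.5 else "female"
        cfg = SimSampleConfig(ff=ff, mean_coverage=coverage, n_snps=n_snps,
                              trisomy21=trisomy, fetal_sex=sex,
                              total_reads=total_reads)
        snp = simulate_plasma_snp_sample(cfg, panel=panel, rng=rng)
        counts = simulate_readcount_sample(cfg, panel, platform=platform,
                                           rng=rng)
        vcf_path = f"{sid}.vcf"
        counts_path = f"{sid}.counts.tsv"
        nio.write_snp_vcf(snp, out / vcf_path, sample_name=sid)
        nio.write_counts_tsv(counts, out / counts_path)
        variants_path = None
        if sid == "EUP-00":
            # spike one de novo FGFR3 candidate among common background variants
            from .monogenic import AnnotatedVariant
            depth = 250
            spiked = [AnnotatedVariant("4", 1803568, "C", "T", "FGFR3",
                                       round(ff / 2, 4), depth,
                                       population_frequency=0.0)]
            for j in range(20):
                spiked.append(AnnotatedVariant(
                    "2", 1_000_000 + j, "A", "G", "COMMON",
                    float(rng.binomial(depth, 0.5)) / depth, depth,
                    population_frequency=0.2))
            variants_path = f"{sid}.variants.tsv"
            nio.write_annotated_variants(spiked, out / variants_path)
        rows.append(ManifestRow(sid, platform, "test", vcf=vcf_path,
                                counts=counts_path, variants=variants_path,
                                true_ff=round(ff, 4)))

    manifest = SampleManifest(rows, base_dir=out)
    manifest_path = out / "manifest.tsv"
    nio.write_manifest(manifest, manifest_path)
    RunConfig(seed=seed, gene_set=str(gene_set_path),
              out_dir=str(out)).to_yaml(out / "config.yaml")
    return manifest_path
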
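"""Targeted capture panel model.

The panel drives two statistics: which loci are usable for fetal-fraction
estimation (SNP probes on autosomes, excluding the common-trisomy
chromosomes 18 and 21) and the per-chromosome base totals that set the
expected share of reads each chromosome receives in a depth-of-coverage
table (chromosome 21 dosage probes for trisomy calling, a single SRY
region for fetal sex).

Probes are half-open, 0-based intervals, BED-style, with a fourth column
giving the probe role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))
FF_EXCLUDED_CHROMOSOMES: tuple[str, ...] = ("18", "21")

ROLE_FF = "ff_informative"
ROLE_CHR21 = "chr21_dosage"
ROLE_SRY = "sry"
ROLE_OTHER = "other"
ROLES = (ROLE_FF, ROLE_CHR21, ROLE_SRY, ROLE_OTHER)

# Approximate autosome lengths (Mb, GRCh37 scale), used only to spread the
# SNP probes across chromosomes in realistic proportions.
_AUTOSOME_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51,
}


def normalize_chrom(name: str) -> str:
    """Strip a ``chr`` prefix so '21' and 'chr21' compare equal."""
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


@dataclass
class PanelDesign:
    """A set of capture probes with roles.

    probes columns: chrom (str, no 'chr' prefix), start, end (half-open,
    0-based), role (one of :data:`ROLES`).
    """

    probes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.probes.copy()
        required = {"chrom", "start", "end", "role"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        df["chrom"] = df["chrom"].map(normalize_chrom)
        if (df["end"] <= df["start"]).any() or (df["start"] < 0).any():
            raise ValueError("panel probes must be non-empty half-open intervals")
        bad_role = set(df["role"]) - set(ROLES)
        if bad_role:
            raise ValueError(f"unknown probe roles: {sorted(bad_role)}")
        ff = df[df["role"] == ROLE_FF]
        if ff["chrom"].isin(FF_EXCLUDED_CHROMOSOMES).any():
            raise ValueError("FF-informative probes may not lie on chromosomes 18/21")
        if not ff["chrom"].isin(AUTOSOMES).all():
            raise ValueError("FF-informative probes must be autosomal")
        c21 = df[df["role"] == ROLE_CHR21]
        if not (c21["chrom"] == "21").all():
            raise ValueError("chr21_dosage probes must lie on chromosome 21")
        sry = df[df["role"] == ROLE_SRY]
        if not (sry["chrom"] == "Y").all():
            raise ValueError("sry probes must lie on chromosome Y")
        self.probes = df.reset_index(drop=True)

    # -- aggregate base totals -------------------------------------------------

    def bases_by_chromosome(self, roles: tuple[str, ...] | None = None) -> dict[str, int]:
        df = self.probes
        if roles is not None:
            df = df[df["role"].isin(roles)]
        widths = df["end"] - df["start"]
        return widths.groupby(df["chrom"]).sum().astype(int).to_dict()

    @property
    def totals_by_role(self) -> dict[str, int]:
        widths = self.probes["end"] - self.probes["start"]
        return widths.groupby(self.probes["role"]).sum().astype(int).to_dict()

    @property
    def autosome_bases(self) -> int:
        by_chrom = self.bases_by_chromosome()
        return sum(by_chrom.get(c, 0) for c in AUTOSOMES)

    @property
    def y_bases(self) -> int:
        return self.bases_by_chromosome().get("Y", 0)

    @property
    def male_chry_proportion(self) -> float:
        """Expected chrY/autosome read ratio for a fully male (non-pregnant)
        sample on this panel: the Y target is hemizygous, autosomes diploid."""
        if self.autosome_bases == 0:
            raise ValueError("panel has no autosomal probes")
        return (self.y_bases / 2) / self.autosome_bases

    def ff_probes(self) -> pd.DataFrame:
        return self.probes[self.probes["role"] == ROLE_FF].reset_index(drop=True)

    # -- BED I/O ---------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        out = self.probes.copy()
        out["chrom"] = "chr" + out["chrom"]
        out.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "role"])

    @classmethod
    def from_bed(cls, path: str | Path) -> "PanelDesign":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "role"],
                         dtype={"chrom": str})
        return cls(df)


def _spread_probes(chrom: str, n: int, width: int, role: str,
                   offset: int = 1_000_000, spacing: int = 20_000) -> pd.DataFrame:
    starts = offset + spacing * pd.RangeIndex(n)
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + width, "role": role,
    })


def default_panel() -> PanelDesign:
    """The packaged clinical-style panel.

    6739 SNP probes (~1.5 Mb) spread over the autosomes minus chromosomes
    18 and 21 for fetal-fraction estimation; 240 probes (~33.5 kb) on
    chromosome 21 for trisomy dosage; one SRY region on chromosome Y for
    fetal sex; and a block of other disease-panel probes on chromosome 18
    so every autosome contributes reads.
    """
    ff_chroms = [c for c in AUTOSOMES if c not in FF_EXCLUDED_CHROMOSOMES]
    weights = pd.Series({c: _AUTOSOME_MB[c] for c in ff_chroms}, dtype=float)
    alloc = (weights / weights.sum() * 6739).round().astype(int)
    # fix rounding so the probe count is exact
    alloc[ff_chroms[0]] += 6739 - int(alloc.sum())
    parts = [_spread_probes(c, int(n), width=222, role=ROLE_FF)
             for c, n in alloc.items()]
    parts.append(_spread_probes("21", 240, width=140, role=ROLE_CHR21))
    parts.append(_spread_probes("18", 128, width=234, role=ROLE_OTHER))
    parts.append(pd.DataFrame({"chrom": ["Y"], "start": [2_654_000],
                               "end": [2_656_000], "role": [ROLE_SRY]}))
    return PanelDesign(pd.concat(parts, ignore_index=True))
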
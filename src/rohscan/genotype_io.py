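"""Genotype containers, VCF/TSV input, SNP/sample quality control.

Genotype calls are coded per (sample, SNP) cell as ``HOM_REF`` (0), ``HET``
(1), ``HOM_ALT`` (2) or ``MISSING`` (-1).  Half-missing diploid calls
(one allele unknown) are coded MISSING.  Coordinates are 1-based inclusive
internally (VCF convention); BED exports are 0-based half-open.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

#: chromosome labels (after stripping a ``chr`` prefix) treated as non-autosomal
NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M", "W", "Z"}

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
SEGMENT_COLUMNS = [
    "sample_id",
    "population",
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_kb",
]


def is_autosome(chrom: str) -> bool:
    return re.sub(r"^chr", "", str(chrom), flags=re.IGNORECASE).upper() not in NON_AUTOSOMES


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid genotype codes plus the variant map.

    ``variants`` is a DataFrame with columns chrom, pos, id, ref, alt,
    sorted by (chrom, pos) with strictly increasing positions within each
    chromosome.  ``calls`` is an int8 array of shape
    (n_samples, n_variants).  ``allele_freq`` optionally carries the true
    per-SNP alternate-allele frequency (set by the simulator; used for
    allele-frequency-weighted tract planting).
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray
    allele_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {0, 1, 2, -1}")
        self.variants = self.variants.reset_index(drop=True)
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.variants["chrom"]))

    def take_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=[s for s, k in zip(self.samples, keep) if k],
            variants=self.variants,
            calls=self.calls[keep],
            allele_freq=self.allele_freq,
        )

    def take_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.loc[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
            allele_freq=None if self.allele_freq is None else self.allele_freq[keep],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.copy(),
            calls=self.calls.copy(),
            allele_freq=None if self.allele_freq is None else self.allele_freq.copy(),
        )


@dataclass(frozen=True)
class QCParams:
    """SNP/sample quality-control thresholds.

    Defaults follow the common resequencing workflow: drop samples with
    >10% missing genotypes, SNPs with >10% missingness, SNPs out of
    Hardy-Weinberg equilibrium at p < 1e-3, and (in the ``structure``
    profile only) SNPs with minor allele frequency below 5%.  The ``roh``
    profile disables the MAF filter so that low-MAF homozygous stretches
    are retained.
    """

    max_geno_missing: float | None = 0.1
    min_maf: float | None = 0.05
    hwe_p_threshold: float | None = 1e-3
    max_sample_missing: float | None = 0.1

    def __post_init__(self) -> None:
        for name in ("max_geno_missing", "min_maf", "max_sample_missing"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hwe_p_threshold is not None and not 0.0 < self.hwe_p_threshold < 1.0:
            raise ValueError("hwe_p_threshold must be in (0, 1)")

    @classmethod
    def structure_profile(cls) -> "QCParams":
        return cls()

    @classmethod
    def roh_profile(cls) -> "QCParams":
        return cls(min_maf=None)

    @classmethod
    def profile(cls, name: str) -> "QCParams":
        if name == "structure":
            return cls.structure_profile()
        if name == "roh":
            return cls.roh_profile()
        raise ValueError(f"unknown QC profile {name!r} (expected 'structure' or 'roh')")


@dataclass
class QCReport:
    """Counts removed at each QC step, in the order the steps ran."""

    n_samples_in: int = 0
    n_variants_in: int = 0
    samples_removed_missing: int = 0
    snps_removed_missing: int = 0
    snps_removed_hwe: int = 0
    snps_removed_maf: int = 0
    n_samples_out: int = 0
    n_variants_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": list(vars(self)), "count": list(vars(self).values())}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

_HWE_TIE_REL = 1e-10  # relative guard when comparing configuration probabilities


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic SNP.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed configuration (the conventional exact HWE test).  The
    distribution is evaluated with a numerically stable recurrence over
    heterozygote counts.

    Raises ``ValueError`` when all three counts are zero (all-missing SNP:
    the test is undefined and QC keeps such a SNP untested).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("HWE test undefined for an all-missing SNP")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_ref, n_alt)
    if rare == 0:
        return 1.0  # monomorphic: single possible configuration

    # heterozygote counts share the parity of the rare allele count
    het_values = list(range(rare % 2, rare + 1, 2))
    # start the recurrence at the modal (expected) het count
    mid = rare * (n_ref + n_alt - rare) // (n_ref + n_alt)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward: P(h-2)/P(h) = h(h-1) / ((R-h+2)/2 * (C-h+2)/2) with
    # R, C the rare/common allele counts
    common = n_ref + n_alt - rare
    h = mid
    p = 1.0
    while h >= 2:
        p *= h * (h - 1) / ((rare - h + 2.0) * (common - h + 2.0))
        h -= 2
        probs[h] = p
    h = mid
    p = 1.0
    while h <= rare - 2:
        p *= (rare - h) * (common - h) / ((h + 2.0) * (h + 1.0))
        h += 2
        probs[h] = p
    total = sum(probs.values())
    obs = probs.get(n_het)
    if obs is None:
        raise ValueError(
            f"heterozygote count {n_het} impossible for allele counts "
            f"({n_ref}, {n_alt})"
        )
    cutoff = obs * (1.0 + _HWE_TIE_REL)
    pval = sum(q for q in probs.values() if q <= cutoff) / total
    return min(1.0, pval)


def genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (hom_ref, het, hom_alt, missing) counts from a calls array."""
    return (
        (calls == HOM_REF).sum(axis=0),
        (calls == HET).sum(axis=0),
        (calls == HOM_ALT).sum(axis=0),
        (calls == MISSING).sum(axis=0),
    )


def minor_allele_frequency(calls: np.ndarray) -> np.ndarray:
    """Per-SNP MAF from non-missing calls; NaN where no call is present."""
    n_ref, n_het, n_alt, _ = genotype_counts(calls)
    valid = n_ref + n_het + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = (2.0 * n_alt + n_het) / (2.0 * valid)
    f_alt = np.where(valid > 0, f_alt, np.nan)
    return np.minimum(f_alt, 1.0 - f_alt)


def apply_qc(gm: GenotypeMatrix, params: QCParams) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample and SNP filters in a fixed order.

    Order: (1) samples with missing fraction > max_sample_missing;
    (2) SNPs with missing fraction > max_geno_missing; (3) SNPs with exact
    HWE p < hwe_p_threshold (pooled over retained samples; all-missing
    SNPs are not tested); (4) SNPs with MAF < min_maf when enabled.
    Raises ``ValueError`` naming the step that removed the last SNP or
    sample.  Idempotent: a second run with the same params is a no-op.
    """
    if gm.n_variants == 0 or gm.n_samples == 0:
        raise ValueError("apply_qc requires a non-empty genotype matrix")
    report = QCReport(n_samples_in=gm.n_samples, n_variants_in=gm.n_variants)

    if params.max_sample_missing is not None:
        miss = (gm.calls == MISSING).mean(axis=1)
        keep = miss <= params.max_sample_missing
        report.samples_removed_missing = int((~keep).sum())
        if not keep.any():
            raise ValueError("QC removed every sample at step 'sample-missingness'")
        if report.samples_removed_missing:
            gm = gm.take_samples(keep)

    def _drop(keep: np.ndarray, step: str) -> GenotypeMatrix:
        if not keep.any():
            raise ValueError(f"QC removed every SNP at step {step!r}")
        return gm.take_variants(keep) if not keep.all() else gm

    if params.max_geno_missing is not None:
        miss = (gm.calls == MISSING).mean(axis=0)
        keep = miss <= params.max_geno_missing
        report.snps_removed_missing = int((~keep).sum())
        gm = _drop(keep, "snp-missingness")

    if params.hwe_p_threshold is not None:
        n_ref, n_het, n_alt, _ = genotype_counts(gm.calls)
        keep = np.ones(gm.n_variants, dtype=bool)
        for j in range(gm.n_variants):
            if n_ref[j] + n_het[j] + n_alt[j] == 0:
                continue  # all-missing: untestable, kept
            keep[j] = hwe_exact_p(int(n_ref[j]), int(n_het[j]), int(n_alt[j])) >= params.hwe_p_threshold
        report.snps_removed_hwe = int((~keep).sum())
        gm = _drop(keep, "hwe")

    if params.min_maf is not None:
        maf = minor_allele_frequency(gm.calls)
        keep = ~(maf < params.min_maf)  # NaN (no calls) kept
        report.snps_removed_maf = int((~keep).sum())
        gm = _drop(keep, "maf")

    report.n_samples_out = gm.n_samples
    report.n_variants_out = gm.n_variants
    logger.info(
        "QC: %d/%d samples, %d/%d SNPs retained (removed: %d sample-miss, "
        "%d snp-miss, %d hwe, %d maf)",
        report.n_samples_out, report.n_samples_in,
        report.n_variants_out, report.n_variants_in,
        report.samples_removed_missing, report.snps_removed_missing,
        report.snps_removed_hwe, report.snps_removed_maf,
    )
    return gm, report


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a GenotypeMatrix.

    Keeps biallelic SNPs on autosomes only; multi-allelic, non-SNP and
    non-autosomal records are skipped with a logged count.  Phase is
    ignored; a call with either allele missing is coded MISSING.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[tuple] = []
    codes: list[np.ndarray] = []
    n_skipped = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or not is_autosome(v.CHROM)
        ):
            n_skipped += 1
            continue
        gts = np.array(v.genotypes, dtype=np.int16)[:, :2]
        g = gts.sum(axis=1).astype(np.int8)
        g[(gts < 0).any(axis=1)] = MISSING
        rows.append((str(v.CHROM), int(v.POS), v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0]))
        codes.append(g)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-SNP/multi-allelic/non-autosomal records", n_skipped)
    if not rows:
        raise ValueError(f"no usable biallelic autosomal SNP records in {path}")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    variants = variants.drop_duplicates(subset=["chrom", "pos"], keep="first")
    calls = np.column_stack([codes[i] for i in variants.index])
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the tabular genotype alternative: chrom, pos, id, ref, alt,
    then one column per sample with codes 0/1/2/NA (one row per SNP)."""
    df = gm.variants.copy()
    codes = gm.calls.astype(object).T
    for i, s in enumerate(gm.samples):
        col = codes[:, i].copy()
        col[col == MISSING] = "NA"
        df[s] = col
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype TSV missing columns {missing_cols}")
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    if not samples:
        raise ValueError("genotype TSV has no sample columns")
    auto = df["chrom"].map(is_autosome)
    df = df[auto].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no autosomal SNPs in {path}")
    calls = df[samples].replace("NA", MISSING).to_numpy(dtype=np.int8).T
    return GenotypeMatrix(samples=samples, variants=df[VARIANT_COLUMNS], calls=calls)


def read_population_map(path: str | Path) -> pd.Series:
    """Sample -> population mapping from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("population map needs columns sample_id, population")
    df = df.rename(columns=dict(zip(df.columns[:2], ["sample_id", "population"])))
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate samples in population map: {dups}")
    return df.set_index("sample_id")["population"]


def write_segments(
    segments: pd.DataFrame,
    path: str | Path,
    population_map: Mapping[str, str] | pd.Series | None = None,
) -> None:
    """Write ROH segments as TSV (start/end 1-based inclusive)."""
    out = segments.copy()
    if "population" not in out.columns:
        if population_map is not None:
            out["population"] = out["sample_id"].map(dict(population_map) if not isinstance(population_map, pd.Series) else population_map)
        else:
            out["population"] = "NA"
    out = out.reindex(columns=SEGMENT_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str, "population": str})
    for col in ("start_bp", "end_bp", "n_snps"):
        if col in df.columns:
            df[col] = df[col].astype(np.int64)
    return df


def write_bed(
    intervals: pd.DataFrame,
    path: str | Path,
    name_column: str | None = None,
) -> None:
    """Write 1-based inclusive intervals (chrom, start_bp, end_bp) as
    0-based half-open BED."""
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            fields = [str(row["chrom"]), str(int(row["start_bp"]) - 1), str(int(row["end_bp"]))]
            if name_column is not None:
                fields.append(str(row[name_column]))
            fh.write("\t".join(fields) + "\n")
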
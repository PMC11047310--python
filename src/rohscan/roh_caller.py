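"""Sliding-window runs-of-homozygosity detection (PLINK ``--homozyg`` style).

The scan mirrors the classical two-stage design: a 50-SNP window slides
along each chromosome and is scored homozygous when it contains at most
``window_het_max`` heterozygous and ``window_missing_max`` missing calls;
each SNP's hit fraction is the share of homozygous windows among the
windows that contain it (SNPs near chromosome ends belong to fewer than
``window_snp`` windows and only instantiated windows count).  SNPs whose
hit fraction reaches ``window_threshold`` are eligible.  Maximal eligible
stretches are split at inter-SNP gaps above ``max_gap_kb``, trimmed so
both endpoints are non-missing homozygous calls, and kept when they
satisfy the SNP-count, length and SNP-density criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from rohscan.genotype_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

SEGMENT_DTYPES = {
    "sample_id": str,
    "chrom": str,
    "start_bp": np.int64,
    "end_bp": np.int64,
    "n_snps": np.int64,
    "length_kb": float,
}


@dataclass(frozen=True)
class ROHCallParams:
    """Detection thresholds; defaults are the standard resequencing set
    (50-SNP window, 1 het / 5 missing allowed, threshold 0.05; segments
    need >= 30 SNPs, >= 200 kb, <= 30 kb/SNP density, and are split at
    inter-SNP gaps > 500 kb)."""

    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    window_threshold: float = 0.05
    min_snp: int = 30
    min_length_kb: float = 200.0
    max_density_kb_per_snp: float = 30.0
    max_gap_kb: float = 500.0

    def __post_init__(self) -> None:
        if self.window_snp <= 0 or self.min_snp <= 0:
            raise ValueError("window_snp and min_snp must be positive")
        if not 0.0 < self.window_threshold <= 1.0:
            raise ValueError("window_threshold must be in (0, 1]")
        if self.min_length_kb <= 0 or self.max_density_kb_per_snp <= 0 or self.max_gap_kb <= 0:
            raise ValueError("length/density/gap thresholds must be positive")
        if self.window_het_max < 0 or self.window_missing_max < 0:
            raise ValueError("window het/missing caps must be >= 0")


def window_eligibility(
    genotypes: np.ndarray, positions: np.ndarray, params: ROHCallParams
) -> np.ndarray:
    """Per-SNP eligibility for one sample on one chromosome.

    Chromosomes shorter than one full window are evaluated with a single
    truncated window covering every SNP.
    """
    genotypes = np.asarray(genotypes)
    n = genotypes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    if positions is not None and len(positions) != n:
        raise ValueError("genotypes and positions differ in length")
    w = min(params.window_snp, n)
    het = (genotypes == HET).astype(np.int64)
    mis = (genotypes == MISSING).astype(np.int64)
    c_het = np.concatenate(([0], np.cumsum(het)))
    c_mis = np.concatenate(([0], np.cumsum(mis)))
    n_windows = n - w + 1
    het_in_win = c_het[w:] - c_het[:-w]
    mis_in_win = c_mis[w:] - c_mis[:-w]
    hom_win = (het_in_win <= params.window_het_max) & (mis_in_win <= params.window_missing_max)
    c_hom = np.concatenate(([0], np.cumsum(hom_win)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)          # first window start containing SNP i
    hi = np.minimum(idx, n_windows - 1)       # last window start containing SNP i
    hits = c_hom[hi + 1] - c_hom[lo]
    counts = hi - lo + 1
    return hits / counts >= params.window_threshold


def _trim_run(genotypes: np.ndarray, i: int, j: int) -> tuple[int, int]:
    """Shrink [i, j] until both endpoints are non-missing homozygous."""
    while i <= j and genotypes[i] in (HET, MISSING):
        i += 1
    while j >= i and genotypes[j] in (HET, MISSING):
        j -= 1
    return i, j


def call_sample(
    genotypes: np.ndarray,
    positions: np.ndarray,
    params: ROHCallParams | None = None,
) -> list[dict]:
    """Call ROH segments for one sample on one chromosome.

    Returns a list of dicts with keys start_bp, end_bp, n_snps, length_kb
    (coordinates 1-based inclusive, length = end - start + 1).
    """
    params = params or ROHCallParams()
    genotypes = np.asarray(genotypes)
    positions = np.asarray(positions, dtype=np.int64)
    eligible = window_eligibility(genotypes, positions, params)
    if not eligible.any():
        return []
    max_gap_bp = params.max_gap_kb * 1000.0
    segments: list[dict] = []
    n = genotypes.size
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        # extend the eligible run, breaking at gaps > max_gap
        while j + 1 < n and eligible[j + 1] and positions[j + 1] - positions[j] <= max_gap_bp:
            j += 1
        a, b = _trim_run(genotypes, i, j)
        if a <= b:
            n_snps = b - a + 1
            length_kb = (positions[b] - positions[a] + 1) / 1000.0
            if (
                n_snps >= params.min_snp
                and length_kb >= params.min_length_kb
                and length_kb / n_snps <= params.max_density_kb_per_snp
            ):
                segments.append(
                    dict(
                        start_bp=int(positions[a]),
                        end_bp=int(positions[b]),
                        n_snps=int(n_snps),
                        length_kb=float(length_kb),
                    )
                )
        i = j + 1
    return segments


def call_all(
    gm: GenotypeMatrix,
    params: ROHCallParams | None = None,
    population_map=None,
) -> pd.DataFrame:
    """Call ROH segments for every sample over every chromosome.

    Returns a DataFrame with columns sample_id, (population,) chrom,
    start_bp, end_bp, n_snps, length_kb ordered by (sample, chromosome
    appearance order, start).
    """
    params = params or ROHCallParams()
    chrom_arr = gm.variants["chrom"].to_numpy()
    pos_arr = gm.variants["pos"].to_numpy(dtype=np.int64)
    rows: list[dict] = []
    for chrom in gm.chromosomes():
        mask = chrom_arr == chrom
        positions = pos_arr[mask]
        sub = gm.calls[:, mask]
        for s_idx, sample in enumerate(gm.samples):
            for seg in call_sample(sub[s_idx], positions, params):
                rows.append(dict(sample_id=sample, chrom=chrom, **seg))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"])
    if not df.empty:
        chrom_order = {c: k for k, c in enumerate(gm.chromosomes())}
        df = (
            df.assign(_c=df["chrom"].map(chrom_order))
            .sort_values(["sample_id", "_c", "start_bp"], kind="mergesort")
            .drop(columns="_c")
            .reset_index(drop=True)
        )
    if population_map is not None:
        pm = population_map if isinstance(population_map, pd.Series) else pd.Series(dict(population_map))
        df["population"] = df["sample_id"].map(pm)
    return df


def validate_segments(
    segments: pd.DataFrame, gm: GenotypeMatrix, params: ROHCallParams
) -> None:
    """Independent post-hoc validator for every emitted segment.

    Asserts the structural invariants: SNP count / length / density / gap
    thresholds, homozygous non-missing boundary SNPs, and no overlap
    between segments of the same sample on the same chromosome.  Raises
    ``AssertionError`` on the first violation.
    """
    chrom_arr = gm.variants["chrom"].to_numpy()
    pos_arr = gm.variants["pos"].to_numpy(dtype=np.int64)
    sample_idx = {s: k for k, s in enumerate(gm.samples)}
    for (sample, chrom), grp in segments.groupby(["sample_id", "chrom"], sort=False):
        mask = chrom_arr == chrom
        positions = pos_arr[mask]
        geno = gm.calls[sample_idx[sample], mask]
        spans = sorted(zip(grp["start_bp"], grp["end_bp"], grp["n_snps"], grp["length_kb"]))
        prev_end = -1
        for start, end, n_snps, length_kb in spans:
            assert start > prev_end, f"overlapping segments for {sample} on {chrom}"
            prev_end = end
            a = int(np.searchsorted(positions, start, side="left"))
            b = int(np.searchsorted(positions, end, side="right")) - 1
            assert positions[a] == start and positions[b] == end, "boundaries must be SNP positions"
            assert b - a + 1 == n_snps, "n_snps must count every SNP in the span"
            assert n_snps >= params.min_snp
            assert length_kb >= params.min_length_kb
            assert length_kb / n_snps <= params.max_density_kb_per_snp
            assert abs(length_kb - (end - start + 1) / 1000.0) < 1e-9
            assert geno[a] in (HOM_REF, HOM_ALT) and geno[b] in (HOM_REF, HOM_ALT), (
                "boundary SNPs must be non-missing homozygous"
            )
            gaps = np.diff(positions[a : b + 1])
            assert (gaps <= params.max_gap_kb * 1000.0).all(), "internal gap above max_gap"
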
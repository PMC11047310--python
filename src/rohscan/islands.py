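"""ROH islands: per-SNP incidence, top-fraction thresholding and island
calling, with optional gene-interval annotation.

The incidence of a SNP within a population is the fraction of that
population's individuals whose ROH set covers the SNP's position.  Regions
where incidence is exceptional across many individuals are candidate
selection sweeps ("ROH islands"): the threshold is the k-th largest
incidence with k = ceil(top_fraction * n_snps) (the "top 0.1% of SNPs"
rule), and an island is a maximal run of consecutive SNPs whose incidence
STRICTLY exceeds it.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ISLAND_COLUMNS = ["chrom", "start_bp", "end_bp", "n_snps", "peak_incidence"]


def incidence(
    segments: pd.DataFrame,
    variants: pd.DataFrame,
    pop_samples: Sequence[str],
) -> pd.DataFrame:
    """Per-SNP fraction of ``pop_samples`` covered by an ROH.

    A sample covers a SNP when any of its segments satisfies
    start_bp <= pos <= end_bp.  Segments of samples outside
    ``pop_samples`` are ignored; the denominator is ``len(pop_samples)``.
    """
    pop_samples = list(pop_samples)
    if not pop_samples:
        raise ValueError("incidence requires a non-empty population")
    segs = segments[segments["sample_id"].isin(pop_samples)]
    counts = np.zeros(len(variants), dtype=np.int64)
    chrom_arr = variants["chrom"].to_numpy()
    pos_all = variants["pos"].to_numpy(dtype=np.int64)
    offset = 0
    for chrom in dict.fromkeys(chrom_arr):
        mask = chrom_arr == chrom
        pos = pos_all[mask]
        diff = np.zeros(pos.size + 1, dtype=np.int64)
        # within-sample segments never overlap, so a sample adds at most 1
        for _, row in segs[segs["chrom"] == chrom].iterrows():
            a = np.searchsorted(pos, row["start_bp"], side="left")
            b = np.searchsorted(pos, row["end_bp"], side="right")
            diff[a] += 1
            diff[b] -= 1
        counts[offset : offset + pos.size] = np.cumsum(diff[:-1])
        offset += pos.size
    out = variants[["chrom", "pos"]].copy()
    out["incidence"] = counts / len(pop_samples)
    return out


def island_threshold(track: pd.DataFrame, top_fraction: float = 0.001) -> float:
    """Incidence value delimiting the top ``top_fraction`` of SNPs.

    Returns the k-th largest incidence with k = ceil(top_fraction * n);
    only SNPs STRICTLY above this value qualify for islands, so ties at
    the threshold are excluded (a constant track yields no islands).
    """
    if track.empty:
        raise ValueError("island_threshold requires a non-empty track")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    vals = np.sort(track["incidence"].to_numpy())
    k = max(1, math.ceil(top_fraction * vals.size))
    return float(vals[vals.size - k])


def call_islands(
    track: pd.DataFrame,
    threshold: float,
    min_snps: int = 2,
) -> pd.DataFrame:
    """Maximal runs of consecutive SNPs with incidence > threshold.

    Runs shorter than ``min_snps`` SNPs are dropped; the island span runs
    from the first to the last member SNP position.
    """
    rows = []
    chrom_arr = track["chrom"].to_numpy()
    pos_arr = track["pos"].to_numpy(dtype=np.int64)
    inc_arr = track["incidence"].to_numpy(dtype=float)
    for chrom in dict.fromkeys(chrom_arr):
        mask = chrom_arr == chrom
        pos = pos_arr[mask]
        inc = inc_arr[mask]
        above = inc > threshold
        i = 0
        n = above.size
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_snps:
                rows.append(
                    dict(
                        chrom=chrom,
                        start_bp=int(pos[i]),
                        end_bp=int(pos[j]),
                        n_snps=int(j - i + 1),
                        peak_incidence=float(inc[i : j + 1].max()),
                    )
                )
            i = j + 1
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


# ---------------------------------------------------------------------------
# Gene-interval annotation
# ---------------------------------------------------------------------------


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open) or GFF3 (1-based
    inclusive, ``gene`` features), normalised to 1-based inclusive columns
    chrom, start_bp, end_bp, name."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols, dtype={"seqid": str})
        df = df[df["type"] == "gene"]

        def _name(attrs: str) -> str:
            m = re.search(r"(?:^|;)\s*Name=([^;]+)", attrs) or re.search(r"(?:^|;)\s*ID=([^;]+)", attrs)
            return m.group(1) if m else "NA"

        return pd.DataFrame(
            {
                "chrom": df["seqid"].astype(str),
                "start_bp": df["start"].astype(np.int64),
                "end_bp": df["end"].astype(np.int64),
                "name": df["attributes"].map(_name),
            }
        ).reset_index(drop=True)
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path} does not look like BED (need >= 3 columns)")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start_bp": df[1].astype(np.int64) + 1,
            "end_bp": df[2].astype(np.int64),
        }
    )
    out["name"] = df[3].astype(str) if df.shape[1] > 3 else "NA"
    return out


def annotate_intervals(
    islands: pd.DataFrame, gene_intervals: pd.DataFrame
) -> pd.DataFrame:
    """List every gene whose interval overlaps each island span by >= 1 bp.

    Adds a ``genes`` column (comma-joined sorted unique names, "" when
    none).  Both inputs are 1-based inclusive; an exactly abutting gene
    (zero shared bases) is not listed.
    """
    import pyranges as pr

    out = islands.copy()
    if out.empty or gene_intervals.empty:
        out["genes"] = pd.Series(dtype=str) if out.empty else ""
        return out
    isl = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": out["chrom"].astype(str),
                "Start": out["start_bp"].astype(np.int64) - 1,
                "End": out["end_bp"].astype(np.int64),
                "island_idx": np.arange(len(out)),
            }
        )
    )
    genes = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": gene_intervals["chrom"].astype(str),
                "Start": gene_intervals["start_bp"].astype(np.int64) - 1,
                "End": gene_intervals["end_bp"].astype(np.int64),
                "gene_name": gene_intervals["name"].astype(str),
            }
        )
    )
    joined = isl.join(genes).df
    names = ["" for _ in range(len(out))]
    if not joined.empty:
        for idx, grp in joined.groupby("island_idx"):
            names[int(idx)] = ",".join(sorted(set(grp["gene_name"])))
    out["genes"] = names
    return out
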
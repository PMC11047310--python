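"""Length-class summaries, per-chromosome/per-individual statistics and
the genomic inbreeding coefficient FROH.

FROH for an individual is the fraction of the SNP-covered autosomal genome
lying inside that individual's ROH segments (McQuillan-style):
``FROH = sum(L_ROH) / L_auto``.  ``L_AUTO_MB`` (2466.19 Mb) is the
autosomal length covered by the goat resequencing panel this package was
developed around; supply your own value for other panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: autosomal genome length (Mb) covered by the reference goat SNP panel
L_AUTO_MB: float = 2466.19

CLASS_ORDER = ["small", "medium", "large"]


@dataclass(frozen=True)
class LengthClassBounds:
    """ROH length classes: small (< small_max_mb), medium (closed
    interval [small_max_mb, large_min_mb]), large (> large_min_mb).
    Segments exactly on a boundary are medium."""

    small_max_mb: float = 0.3
    large_min_mb: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.small_max_mb < self.large_min_mb:
            raise ValueError("need 0 < small_max_mb < large_min_mb")

    def classify_length_mb(self, length_mb: np.ndarray) -> np.ndarray:
        length_mb = np.asarray(length_mb, dtype=float)
        out = np.full(length_mb.shape, "medium", dtype=object)
        out[length_mb < self.small_max_mb] = "small"
        out[length_mb > self.large_min_mb] = "large"
        return out


def classify(segments: pd.DataFrame, bounds: LengthClassBounds | None = None) -> pd.DataFrame:
    """Annotate a segment table with length_mb and length_class columns."""
    bounds = bounds or LengthClassBounds()
    out = segments.copy()
    out["length_mb"] = out["length_kb"] / 1000.0
    out["length_class"] = bounds.classify_length_mb(out["length_mb"].to_numpy())
    return out


def summarize_classes(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-class counts, percentages, total/mean/SD lengths (Mb).

    SD is the population standard deviation (ddof=0).  Percentages are of
    the grand totals, so each percentage column sums to 100.
    """
    if labeled.empty:
        raise ValueError("summarize_classes requires at least one segment")
    grp = labeled.groupby("length_class")["length_mb"]
    summary = pd.DataFrame(
        {
            "roh_number": grp.size(),
            "total_length_mb": grp.sum(),
            "mean_length_mb": grp.mean(),
            "sd_length_mb": grp.std(ddof=0),
        }
    ).reindex(CLASS_ORDER)
    summary["roh_number"] = summary["roh_number"].fillna(0).astype(np.int64)
    summary["total_length_mb"] = summary["total_length_mb"].fillna(0.0)
    summary["number_pct"] = 100.0 * summary["roh_number"] / summary["roh_number"].sum()
    summary["length_pct"] = 100.0 * summary["total_length_mb"] / summary["total_length_mb"].sum()
    summary.index.name = "length_class"
    return summary.reset_index()[
        ["length_class", "roh_number", "number_pct", "total_length_mb",
         "mean_length_mb", "sd_length_mb", "length_pct"]
    ]


def froh(
    segments: pd.DataFrame,
    samples: Sequence[str] | None = None,
    l_auto_mb: float = L_AUTO_MB,
) -> pd.DataFrame:
    """Per-sample summed ROH length (Mb) and FROH = sum / l_auto_mb.

    ``samples``, when given, fixes the output universe so that samples
    without any ROH appear with FROH = 0.
    """
    if l_auto_mb <= 0:
        raise ValueError("l_auto_mb must be positive")
    sums = segments.groupby("sample_id")["length_kb"].sum() / 1000.0
    if samples is not None:
        sums = sums.reindex(list(samples), fill_value=0.0)
    out = sums.rename("sum_roh_mb").reset_index().rename(columns={"index": "sample_id"})
    out["froh"] = out["sum_roh_mb"] / l_auto_mb
    return out


def population_froh(
    per_sample: pd.DataFrame,
    population_map: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Population rollup of per-sample FROH.

    ``n`` counts samples with at least one ROH, and ``mean_froh`` averages
    over those samples only (samples with zero ROH are excluded from the
    mean but reported via ``n_zero``).
    """
    pm = population_map if isinstance(population_map, pd.Series) else pd.Series(dict(population_map))
    df = per_sample.copy()
    df["population"] = df["sample_id"].map(pm)
    if df["population"].isna().any():
        missing = df.loc[df["population"].isna(), "sample_id"].tolist()
        raise ValueError(f"samples missing from population map: {missing}")
    has_roh = df[df["sum_roh_mb"] > 0]
    out = pd.DataFrame(
        {
            "n": has_roh.groupby("population").size(),
            "n_zero": df[df["sum_roh_mb"] == 0].groupby("population").size(),
            "total_roh_length_mb": df.groupby("population")["sum_roh_mb"].sum(),
            "mean_froh": has_roh.groupby("population")["froh"].mean(),
        }
    )
    out["n"] = out["n"].fillna(0).astype(np.int64)
    out["n_zero"] = out["n_zero"].fillna(0).astype(np.int64)
    out.index.name = "population"
    return out.reset_index()


def per_chromosome_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    """Chromosome x length-class segment counts (plot-ready)."""
    if labeled.empty:
        return pd.DataFrame(columns=["chrom", *CLASS_ORDER, "total"])
    tab = (
        labeled.groupby(["chrom", "length_class"], sort=False)
        .size()
        .unstack("length_class", fill_value=0)
        .reindex(columns=CLASS_ORDER, fill_value=0)
    )
    tab["total"] = tab.sum(axis=1)
    return tab.reset_index()


def per_individual_nroh_sroh(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample segment count (NROH) and summed length in Mb (SROH)."""
    if segments.empty:
        return pd.DataFrame(columns=["sample_id", "nroh", "sroh_mb"])
    grp = segments.groupby("sample_id")["length_kb"]
    return pd.DataFrame(
        {"nroh": grp.size(), "sroh_mb": grp.sum() / 1000.0}
    ).reset_index()
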
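"""Consensus (CON) regions from overlapping ROH segments across animals.

Segments from different individuals that overlap on a chromosome are
pooled greedily; a pool's CON span is the intersection of all member
segments and its UNION span their combined extent.  Pools backed by
enough animals and a long enough CON are candidate selection-signature
regions.

The pooling rule is deterministic: the seed of each pool is the unpooled
segment overlapped by the most other unpooled segments (ties broken by
longer length, then leftmost start, then smaller end, then sample id);
members are added in (start, end, sample) order as long as their
intersection with the running CON stays non-empty.  Each segment joins at
most one pool and pools need at least two animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ConsensusPool:
    pool_id: int
    chrom: str
    con_start: int
    con_end: int
    union_start: int
    union_end: int
    members: list[tuple[str, int, int]] = field(default_factory=list)  # (sample, start, end)

    @property
    def n_animals(self) -> int:
        return len({m[0] for m in self.members})

    @property
    def con_length_mb(self) -> float:
        return (self.con_end - self.con_start + 1) / 1e6

    @property
    def con_length_kb(self) -> float:
        return (self.con_end - self.con_start + 1) / 1e3


@dataclass(frozen=True)
class ConsensusFilter:
    """Selection thresholds: CON longer than ``min_con_length_mb`` AND
    shared by a fraction of the reference sample set STRICTLY greater
    than ``min_sample_fraction``."""

    min_con_length_mb: float = 0.1
    min_sample_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.min_con_length_mb <= 0:
            raise ValueError("min_con_length_mb must be positive")
        if not 0.0 < self.min_sample_fraction <= 1.0:
            raise ValueError("min_sample_fraction must be in (0, 1]")


def _sorted_records(segments: pd.DataFrame) -> list[tuple]:
    recs = [
        (str(r.chrom), int(r.start_bp), int(r.end_bp), str(r.sample_id))
        for r in segments.itertuples()
    ]
    return sorted(recs, key=lambda t: (t[0], t[1], t[2], t[3]))


def pool_segments(segments: pd.DataFrame) -> list[ConsensusPool]:
    """Greedy per-chromosome pooling of overlapping ROH segments.

    Input order does not matter: records are canonically sorted first, so
    permuting the segment table yields identical pools.
    """
    pools: list[ConsensusPool] = []
    if segments.empty:
        return pools
    recs = _sorted_records(segments)
    by_chrom: dict[str, list[tuple]] = {}
    for r in recs:
        by_chrom.setdefault(r[0], []).append(r)
    pool_id = 0
    for chrom in sorted(by_chrom):
        active = by_chrom[chrom]  # already (start, end, sample) sorted
        while True:
            n = len(active)
            if n < 2:
                break
            counts = np.zeros(n, dtype=np.int64)
            for i in range(n):
                _, si, ei, _ = active[i]
                for j in range(i + 1, n):
                    _, sj, ej, _ = active[j]
                    if sj > ei:
                        break  # sorted by start: no later segment overlaps i
                    if si <= ej:
                        counts[i] += 1
                        counts[j] += 1
            if counts.max() == 0:
                break
            # seed: most overlapped; ties -> longest, then leftmost, then sample
            best = min(
                range(n),
                key=lambda i: (
                    -counts[i],
                    -(active[i][2] - active[i][1]),
                    active[i][1],
                    active[i][2],
                    active[i][3],
                ),
            )
            _, seed_start, seed_end, seed_sample = active[best]
            con_start, con_end = seed_start, seed_end
            uni_start, uni_end = seed_start, seed_end
            members = [(seed_sample, seed_start, seed_end)]
            member_idx = {best}
            for i in range(n):
                if i == best:
                    continue
                _, s, e, samp = active[i]
                if s > seed_end or e < seed_start:
                    continue  # must overlap the seed
                ns, ne = max(con_start, s), min(con_end, e)
                if ns <= ne:
                    con_start, con_end = ns, ne
                    uni_start, uni_end = min(uni_start, s), max(uni_end, e)
                    members.append((samp, s, e))
                    member_idx.add(i)
            if len(members) >= 2:
                pools.append(
                    ConsensusPool(
                        pool_id=pool_id,
                        chrom=chrom,
                        con_start=con_start,
                        con_end=con_end,
                        union_start=uni_start,
                        union_end=uni_end,
                        members=members,
                    )
                )
                pool_id += 1
            active = [r for i, r in enumerate(active) if i not in member_idx]
    return pools


def filter_consensus(
    pools: Sequence[ConsensusPool],
    filt: ConsensusFilter,
    reference_samples: Sequence[str],
) -> list[ConsensusPool]:
    """Keep pools with CON length > min_con_length_mb and animal share of
    ``reference_samples`` > min_sample_fraction (both strict)."""
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValueError("filter_consensus requires a non-empty reference sample set")
    n_ref = len(reference_samples)
    return [
        p
        for p in pools
        if p.con_length_mb > filt.min_con_length_mb
        and p.n_animals / n_ref > filt.min_sample_fraction
    ]


def consensus_report(
    pools: Sequence[ConsensusPool],
    population_map: Mapping[str, str] | pd.Series | None = None,
    gene_intervals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabulate pools: CON/UNION spans, animal counts, per-population
    membership and (optionally) overlapping genes."""
    pm = None
    if population_map is not None:
        pm = population_map if isinstance(population_map, pd.Series) else pd.Series(dict(population_map))
    rows = []
    for p in pools:
        samples = sorted({m[0] for m in p.members})
        row = dict(
            pool_id=p.pool_id,
            chrom=p.chrom,
            con_start=p.con_start,
            con_end=p.con_end,
            con_kb=p.con_length_kb,
            union_start=p.union_start,
            union_end=p.union_end,
            n_animals=p.n_animals,
            members=",".join(samples),
        )
        if pm is not None:
            pops = pm.reindex(samples).fillna("NA")
            row["populations"] = ";".join(
                f"{pop}={n}" for pop, n in pops.value_counts().sort_index().items()
            )
        rows.append(row)
    cols = ["pool_id", "chrom", "con_start", "con_end", "con_kb",
            "union_start", "union_end", "n_animals", "members"]
    if pm is not None:
        cols.append("populations")
    df = pd.DataFrame(rows, columns=cols)
    if gene_intervals is not None:
        from rohscan.islands import annotate_intervals

        spans = df.rename(columns={"con_start": "start_bp", "con_end": "end_bp"})[
            ["chrom", "start_bp", "end_bp"]
        ]
        df["genes"] = annotate_intervals(spans, gene_intervals)["genes"].values if not df.empty else ""
    return df
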
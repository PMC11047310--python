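"""Independent brute-force oracles used to verify the implementation.

Everything here is written with explicit loops and textbook formulas,
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


def hwe_enumeration_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p-value by enumerating every heterozygote count.

    P(h | n, allele counts) computed directly from log factorials:
    P = 2^h * n! / (nAA! h! nBB!) * nA! nB! / (2n)!.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het

    def logp(h: int) -> float:
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return (
            h * math.log(2)
            + gammaln(n + 1) - gammaln(aa + 1) - gammaln(h + 1) - gammaln(bb + 1)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
        )

    rare = min(n_a, n_b)
    hets = [h for h in range(rare % 2, rare + 1, 2)]
    probs = {h: math.exp(logp(h)) for h in hets}
    obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1.0 + 1e-10)))


def naive_window_eligibility(
    genotypes, positions, window_snp=50, het_max=1, missing_max=5, threshold=0.05
):
    """Per-SNP eligibility by enumerating every window explicitly."""
    g = list(genotypes)
    n = len(g)
    if n == 0:
        return []
    w = min(window_snp, n)
    window_ok = []
    for start in range(n - w + 1):
        win = g[start : start + w]
        n_het = sum(1 for x in win if x == HET)
        n_mis = sum(1 for x in win if x == MISSING)
        window_ok.append(n_het <= het_max and n_mis <= missing_max)
    eligible = []
    for i in range(n):
        hits = 0
        count = 0
        for start in range(n - w + 1):
            if start <= i <= start + w - 1:
                count += 1
                if window_ok[start]:
                    hits += 1
        eligible.append(hits / count >= threshold)
    return eligible


def naive_call_sample(
    genotypes,
    positions,
    window_snp=50,
    het_max=1,
    missing_max=5,
    threshold=0.05,
    min_snp=30,
    min_length_kb=200.0,
    max_density_kb_per_snp=30.0,
    max_gap_kb=500.0,
):
    """Brute-force segment caller: maximal eligible runs, gap split, end
    trimming to non-missing homozygous, then every filter applied
    independently."""
    g = list(genotypes)
    pos = list(positions)
    eligible = naive_window_eligibility(g, pos, window_snp, het_max, missing_max, threshold)
    runs = []
    current = []
    for i in range(len(g)):
        if not eligible[i]:
            if current:
                runs.append(current)
                current = []
            continue
        if current and pos[i] - pos[current[-1]] > max_gap_kb * 1000.0:
            runs.append(current)
            current = []
        current.append(i)
    if current:
        runs.append(current)
    segments = []
    for run in runs:
        idx = list(run)
        while idx and g[idx[0]] in (HET, MISSING):
            idx.pop(0)
        while idx and g[idx[-1]] in (HET, MISSING):
            idx.pop()
        if not idx:
            continue
        a, b = idx[0], idx[-1]
        n_snps = b - a + 1
        length_kb = (pos[b] - pos[a] + 1) / 1000.0
        if n_snps < min_snp:
            continue
        if length_kb < min_length_kb:
            continue
        if length_kb / n_snps > max_density_kb_per_snp:
            continue
        segments.append((pos[a], pos[b], n_snps, length_kb))
    return segments


def naive_incidence(segments_rows, variants_rows, pop_samples):
    """Per-SNP coverage fraction by a per-sample membership loop."""
    pop = list(pop_samples)
    out = []
    for chrom, p in variants_rows:
        n_cov = 0
        for sample in pop:
            covered = any(
                s_chrom == chrom and start <= p <= end
                for s_sample, s_chrom, start, end in segments_rows
                if s_sample == sample
            )
            n_cov += covered
        out.append(n_cov / len(pop))
    return out


def sort_percentile_threshold(values, top_fraction=0.001):
    """k-th largest value with k = ceil(top_fraction * n), via full sort."""
    vals = sorted(values, reverse=True)
    k = max(1, math.ceil(top_fraction * len(vals)))
    return vals[k - 1]


def quadratic_overlaps(islands_rows, gene_rows):
    """All-pairs >=1 bp overlap on 1-based inclusive intervals.

    Returns {island_index: sorted unique gene names}.
    """
    out = {}
    for i, (ichrom, istart, iend) in enumerate(islands_rows):
        names = set()
        for gchrom, gstart, gend, name in gene_rows:
            if gchrom == ichrom and max(istart, gstart) <= min(iend, gend):
                names.add(name)
        out[i] = sorted(names)
    return out
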
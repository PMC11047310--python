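"""Synthetic diploid genotype matrices with planted autozygous tracts.

Background genotypes are drawn per SNP under Hardy-Weinberg proportions
from a configurable allele-frequency distribution, independently across
SNPs (no background LD).  Autozygosity is then created by direct tract
planting: inside a tract every SNP is set homozygous, the allele drawn
with probability equal to its population frequency (an
allele-frequency-weighted IBD draw), after which heterozygote genotyping
errors and missingness are sprinkled.  Planting gives exact ground truth
(``TruthTract``) for recovery testing of the whole pipeline; it does not
emulate pedigree structure or background LD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rohscan.genotype_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from rohscan.roh_stats import LengthClassBounds

#: uniform tract-length ranges (Mb) per design class
CLASS_LENGTH_RANGES_MB = {
    "small": (0.21, 0.3),
    "medium": (0.3, 1.5),
    "large": (1.5, 5.0),
}
DEFAULT_LENGTH_MIX = {"small": 0.25, "medium": 0.50, "large": 0.25}


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of a simulation run.

    ``snp_density_per_kb`` of 0.1 is one SNP per 10 kb — the marker
    spacing at which the default window caller resolves tracts well above
    its 200 kb minimum length.  ``maf_range`` bounds the uniform
    alternate-allele frequency draw (default [0.05, 0.5], i.e. the
    post-QC spectrum of a MAF-filtered panel).  ``seed`` is mandatory: all
    randomness flows from it.
    """

    n_samples: int
    chrom_lengths: Mapping[str, int]
    seed: int
    snp_density_per_kb: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    het_error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not self.chrom_lengths or any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chrom_lengths must be positive")
        for name in ("het_error_rate", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def total_length_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def rng(self, stream: int) -> np.random.Generator:
        # independent deterministic streams, all rooted at config.seed
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass(frozen=True)
class TruthTract:
    """A planted autozygous interval: ground truth for recovery tests."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("tract start must not exceed end")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def design_class(self) -> str:
        bounds = LengthClassBounds()
        return str(bounds.classify_length_mb(np.array([self.length_bp / 1e6]))[0])


def sample_names(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(n)]


def simulate_background(config: SimulationConfig) -> GenotypeMatrix:
    """Hardy-Weinberg background genotypes on a uniformly placed SNP map."""
    rng = config.rng(0)
    chroms, positions = [], []
    for chrom, length in config.chrom_lengths.items():
        n_snps = int(round(length / 1000.0 * config.snp_density_per_kb))
        if n_snps <= 0:
            raise ValueError(
                f"snp_density_per_kb={config.snp_density_per_kb} places no SNPs on "
                f"{chrom} (length {length} bp)"
            )
        pos = np.unique(rng.integers(1, length + 1, size=n_snps))
        chroms.extend([chrom] * pos.size)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    n_snps = pos_all.size
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos_all,
            "id": [f"snp{i}" for i in range(n_snps)],
            "ref": "A",
            "alt": "G",
        }
    )
    p_alt = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
    shape = (config.n_samples, n_snps)
    calls = (
        (rng.random(shape) < p_alt).astype(np.int8)
        + (rng.random(shape) < p_alt).astype(np.int8)
    )
    if config.missing_rate > 0:
        calls[rng.random(shape) < config.missing_rate] = MISSING
    return GenotypeMatrix(
        samples=sample_names(config.n_samples),
        variants=variants,
        calls=calls,
        allele_freq=p_alt,
    )


def _merge_sample_tracts(tracts: Sequence[TruthTract]) -> list[TruthTract]:
    merged: list[TruthTract] = []
    by_key: dict[tuple[str, str], list[TruthTract]] = {}
    for t in tracts:
        by_key.setdefault((t.sample_id, t.chrom), []).append(t)
    for (sample, chrom), ts in by_key.items():
        ts = sorted(ts, key=lambda t: (t.start_bp, t.end_bp))
        cur = ts[0]
        for t in ts[1:]:
            if t.start_bp <= cur.end_bp:
                warnings.warn(
                    f"overlapping tracts for {sample} on {chrom} merged", stacklevel=3
                )
                cur = TruthTract(sample, chrom, cur.start_bp, max(cur.end_bp, t.end_bp))
            else:
                merged.append(cur)
                cur = t
        merged.append(cur)
    return merged


def plant_tracts(
    gm: GenotypeMatrix,
    tracts: Sequence[TruthTract],
    config: SimulationConfig,
) -> GenotypeMatrix:
    """Overwrite tract SNPs with homozygous calls, then apply heterozygote
    error and missingness inside the tracts.

    The homozygous allele at each SNP is alt with probability equal to the
    SNP's alternate-allele frequency (the matrix's ``allele_freq`` when
    present, else the empirical frequency).
    """
    rng = config.rng(1)
    out = gm.copy()
    if not tracts:
        return out
    if out.allele_freq is not None:
        p_alt = out.allele_freq
    else:
        valid = out.calls >= 0
        with np.errstate(invalid="ignore"):
            p_alt = np.where(
                valid.sum(axis=0) > 0,
                (out.calls * valid).sum(axis=0) / (2.0 * np.maximum(valid.sum(axis=0), 1)),
                0.5,
            )
    sample_idx = {s: i for i, s in enumerate(out.samples)}
    chrom_arr = out.variants["chrom"].to_numpy()
    pos_arr = out.variants["pos"].to_numpy(dtype=np.int64)
    for t in _merge_sample_tracts(tracts):
        if t.sample_id not in sample_idx:
            raise KeyError(f"unknown sample {t.sample_id!r}")
        length = config.chrom_lengths.get(t.chrom)
        if length is not None and t.end_bp > length:
            raise ValueError(f"tract {t} exceeds chromosome {t.chrom} length")
        mask = (chrom_arr == t.chrom) & (pos_arr >= t.start_bp) & (pos_arr <= t.end_bp)
        n_in = int(mask.sum())
        if n_in == 0:
            continue  # tract falls in a SNP gap: matrix unchanged
        s = sample_idx[t.sample_id]
        hom = np.where(rng.random(n_in) < p_alt[mask], HOM_ALT, HOM_REF).astype(np.int8)
        if config.het_error_rate > 0:
            hom[rng.random(n_in) < config.het_error_rate] = HET
        if config.missing_rate > 0:
            hom[rng.random(n_in) < config.missing_rate] = MISSING
        out.calls[s, mask] = hom
    return out


def design_population(
    target_froh: float,
    config: SimulationConfig,
    length_mix: Mapping[str, float] | None = None,
    min_separation_bp: int = 200_000,
    max_attempts: int = 10_000,
) -> list[TruthTract]:
    """Draw per-sample tract sets totalling ~``target_froh`` x genome length.

    Tract lengths are drawn uniformly within the chosen class range and
    placed uniformly (chromosome picked proportionally to its length)
    without overlap, keeping ``min_separation_bp`` between tracts of the
    same sample; drawing stops once the planted total reaches the target,
    so the overshoot is below one tract length.
    """
    if not 0.0 <= target_froh <= 0.6:
        raise ValueError("target_froh must be in [0, 0.6]")
    length_mix = dict(length_mix or DEFAULT_LENGTH_MIX)
    if abs(sum(length_mix.values()) - 1.0) > 1e-9:
        raise ValueError("length_mix proportions must sum to 1")
    if target_froh == 0.0:
        return []
    rng = config.rng(2)
    chrom_names = list(config.chrom_lengths)
    chrom_len = np.array([config.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_len / chrom_len.sum()
    target_bp = target_froh * config.total_length_bp
    classes = list(length_mix)
    class_p = np.array([length_mix[c] for c in classes])
    tracts: list[TruthTract] = []
    for sample in sample_names(config.n_samples):
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
        total = 0.0
        attempts = 0
        while total < target_bp:
            cls = classes[rng.choice(len(classes), p=class_p)]
            lo_mb, hi_mb = CLASS_LENGTH_RANGES_MB[cls]
            length = int(rng.uniform(lo_mb, hi_mb) * 1e6)
            ci = int(rng.choice(len(chrom_names), p=chrom_p))
            chrom = chrom_names[ci]
            cl = int(chrom_len[ci])
            if length >= cl:
                attempts += 1
                if attempts > max_attempts:
                    raise ValueError(
                        f"cannot place tracts reaching FROH {target_froh} on the "
                        "configured chromosomes"
                    )
                continue
            start = int(rng.integers(1, cl - length + 1))
            end = start + length - 1
            clash = any(
                start - min_separation_bp <= e and end + min_separation_bp >= s
                for s, e in placed[chrom]
            )
            if clash:
                attempts += 1
                if attempts > max_attempts:
                    raise ValueError(
                        f"cannot place tracts reaching FROH {target_froh} on the "
                        "configured chromosomes"
                    )
                continue
            placed[chrom].append((start, end))
            tracts.append(TruthTract(sample, chrom, start, end))
            total += length
    return tracts


def truth_to_frame(tracts: Sequence[TruthTract]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                sample_id=t.sample_id,
                chrom=t.chrom,
                start_bp=t.start_bp,
                end_bp=t.end_bp,
                design_class=t.design_class,
            )
            for t in tracts
        ],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "design_class"],
    )


@dataclass
class RecoveryReport:
    """Tract-recovery metrics; NaN marks undefined ratios (no truth or no
    calls)."""

    sensitivity: float
    precision: float
    length_concordance: float
    truth_length_covered: float
    per_class_sensitivity: dict[str, float]
    n_truth: int
    n_called: int


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def evaluate_recovery(
    called: pd.DataFrame,
    truth: Sequence[TruthTract],
    min_reciprocal_overlap: float = 0.9,
) -> RecoveryReport:
    """Score called segments against planted tracts.

    A truth tract is recovered when some called segment of the same sample
    and chromosome overlaps it by >= ``min_reciprocal_overlap`` of BOTH
    lengths; precision counts called segments matching some truth tract
    the same way.
    """
    truth = list(truth)
    n_truth, n_called = len(truth), len(called)
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in called.itertuples():
        by_key.setdefault((str(r.sample_id), str(r.chrom)), []).append(
            (int(r.start_bp), int(r.end_bp))
        )

    def _recovered(t: TruthTract) -> bool:
        for s, e in by_key.get((t.sample_id, t.chrom), []):
            ov = _overlap(t.start_bp, t.end_bp, s, e)
            if ov >= min_reciprocal_overlap * t.length_bp and ov >= min_reciprocal_overlap * (e - s + 1):
                return True
        return False

    hits = [(t, _recovered(t)) for t in truth]
    sensitivity = float(np.mean([h for _, h in hits])) if truth else float("nan")
    per_class: dict[str, float] = {}
    for cls in ("small", "medium", "large"):
        cls_hits = [h for t, h in hits if t.design_class == cls]
        per_class[cls] = float(np.mean(cls_hits)) if cls_hits else float("nan")

    truth_by_key: dict[tuple[str, str], list[TruthTract]] = {}
    for t in truth:
        truth_by_key.setdefault((t.sample_id, t.chrom), []).append(t)

    def _matches(sample: str, chrom: str, s: int, e: int) -> bool:
        for t in truth_by_key.get((sample, chrom), []):
            ov = _overlap(t.start_bp, t.end_bp, s, e)
            if ov >= min_reciprocal_overlap * t.length_bp and ov >= min_reciprocal_overlap * (e - s + 1):
                return True
        return False

    if n_called:
        precision = float(
            np.mean(
                [
                    _matches(str(r.sample_id), str(r.chrom), int(r.start_bp), int(r.end_bp))
                    for r in called.itertuples()
                ]
            )
        )
    else:
        precision = float("nan")
    truth_len = float(sum(t.length_bp for t in truth))
    called_len = float((called["end_bp"] - called["start_bp"] + 1).sum()) if n_called else 0.0
    concordance = called_len / truth_len if truth_len > 0 else float("nan")
    covered = 0.0
    for t in truth:
        covered += sum(
            _overlap(t.start_bp, t.end_bp, s, e)
            for s, e in by_key.get((t.sample_id, t.chrom), [])
        )
    covered_frac = covered / truth_len if truth_len > 0 else float("nan")
    return RecoveryReport(
        sensitivity=sensitivity,
        precision=precision,
        length_concordance=concordance,
        truth_length_covered=covered_frac,
        per_class_sensitivity=per_class,
        n_truth=n_truth,
        n_called=n_called,
    )
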
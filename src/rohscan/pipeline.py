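"""End-to-end orchestration: QC -> ROH calling -> stats/FROH -> islands ->
consensus, with a fixed artifact layout and a resolved-config copy for
provenance.

Every stage writes plain TSV/BED; a rerun on the same inputs is
byte-identical apart from timestamps in the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from rohscan import __version__
from rohscan.consensus import (
    ConsensusFilter,
    consensus_report,
    filter_consensus,
    pool_segments,
)
from rohscan.genotype_io import (
    GenotypeMatrix,
    QCParams,
    apply_qc,
    read_genotype_tsv,
    read_population_map,
    read_vcf,
    write_bed,
    write_segments,
)
from rohscan.islands import (
    annotate_intervals,
    call_islands,
    incidence,
    island_threshold,
    read_gene_intervals,
)
from rohscan.roh_caller import ROHCallParams, call_all
from rohscan.roh_stats import (
    L_AUTO_MB,
    LengthClassBounds,
    classify,
    froh,
    per_chromosome_counts,
    per_individual_nroh_sroh,
    population_froh,
    summarize_classes,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str                       # VCF (.vcf/.vcf.gz) or genotype TSV
    population_map: str
    out_dir: str
    qc_profile: str = "roh"              # "roh" (no MAF filter) or "structure"
    call_params: ROHCallParams = field(default_factory=ROHCallParams)
    class_bounds: LengthClassBounds = field(default_factory=LengthClassBounds)
    l_auto_mb: float | None = None       # default: SNP-covered span of the input map
    island_top_fraction: float = 0.001
    island_min_snps: int = 2
    consensus_filter: ConsensusFilter = field(default_factory=ConsensusFilter)
    consensus_populations: tuple[str, ...] = ()   # empty = all populations
    genes: str | None = None

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def load_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_genotype_tsv(path)


def snp_covered_length_mb(variants: pd.DataFrame) -> float:
    """Autosomal length (Mb) spanned by the SNP map: per chromosome, first
    to last SNP position."""
    span = variants.groupby("chrom")["pos"].agg(["min", "max"])
    return float((span["max"] - span["min"] + 1).sum() / 1e6)


def run(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact set under ``config.out_dir``.

    Raises with the failing stage's name in the message; partial artifacts
    of completed stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("rohscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "setup"
    try:
        with open(out / "config.json", "w") as fh:
            json.dump(config.resolved(), fh, indent=2, default=str)

        stage = "load"
        gm = load_genotypes(config.genotypes)
        pop_map = read_population_map(config.population_map)
        logger.info("loaded %d samples x %d SNPs", gm.n_samples, gm.n_variants)

        stage = "qc"
        gm, report = apply_qc(gm, QCParams.profile(config.qc_profile))
        report.write(out / "qc_report.tsv")

        stage = "call"
        if gm.n_variants == 0:
            raise ValueError("no SNPs available for ROH calling after QC")
        segments = call_all(gm, config.call_params, population_map=pop_map)
        write_segments(segments, out / "roh_segments.tsv", population_map=pop_map)
        logger.info("called %d ROH segments", len(segments))

        stage = "stats"
        l_auto = config.l_auto_mb or snp_covered_length_mb(gm.variants)
        logger.info("L_auto = %.2f Mb (%s)", l_auto,
                    "configured" if config.l_auto_mb else "SNP-covered span")
        labeled = classify(segments, config.class_bounds)
        if not segments.empty:
            summarize_classes(labeled).to_csv(out / "class_summary.tsv", sep="\t", index=False)
            per_chromosome_counts(labeled).to_csv(out / "per_chromosome.tsv", sep="\t", index=False)
        per_individual_nroh_sroh(segments).to_csv(out / "nroh_sroh.tsv", sep="\t", index=False)
        per_sample = froh(segments, samples=gm.samples, l_auto_mb=l_auto)
        per_sample.to_csv(out / "froh.tsv", sep="\t", index=False)
        population_froh(per_sample, pop_map).to_csv(out / "froh_populations.tsv", sep="\t", index=False)

        stage = "islands"
        genes = read_gene_intervals(config.genes) if config.genes else None
        populations = sorted(set(pop_map.reindex(gm.samples).dropna()))
        for pop in populations:
            pop_samples = [s for s in gm.samples if pop_map.get(s) == pop]
            track = incidence(segments, gm.variants, pop_samples)
            track.to_csv(out / f"incidence_{pop}.tsv", sep="\t", index=False)
            thr = island_threshold(track, config.island_top_fraction)
            isl = call_islands(track, thr, config.island_min_snps)
            if genes is not None:
                isl = annotate_intervals(isl, genes)
            isl.insert(0, "population", pop)
            isl.to_csv(out / f"islands_{pop}.tsv", sep="\t", index=False)
            write_bed(isl, out / f"islands_{pop}.bed")
            logger.info("%s: threshold %.4f, %d islands", pop, thr, len(isl))

        stage = "consensus"
        if config.consensus_populations:
            ref_samples = [s for s in gm.samples if pop_map.get(s) in config.consensus_populations]
        else:
            ref_samples = list(gm.samples)
        if not ref_samples:
            raise ValueError(f"no samples in populations {config.consensus_populations}")
        pools = pool_segments(segments[segments["sample_id"].isin(ref_samples)])
        selected = filter_consensus(pools, config.consensus_filter, ref_samples)
        consensus_report(selected, population_map=pop_map, gene_intervals=genes).to_csv(
            out / "consensus.tsv", sep="\t", index=False
        )
        logger.info("%d pools, %d selected consensus regions", len(pools), len(selected))
        return out
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
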
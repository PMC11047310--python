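"""Demonstration cohort: seven goat-like populations with designed
autozygosity levels on a shared SNP map.

Emulates the structure of a multi-breed resequencing panel: two cashmere
breeds (IMC lowest inbreeding, HSC higher), three other domestic breeds,
a meat breed, and a small wild population (IBE) with extreme
autozygosity.  Designed FROH values set the ordering only; the absolute
levels are recovered by the pipeline up to tract-placement overshoot.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from rohscan.genotype_io import GenotypeMatrix, write_genotype_tsv
from rohscan.synthetic_data import (
    SimulationConfig,
    TruthTract,
    design_population,
    plant_tracts,
    simulate_background,
    truth_to_frame,
)

#: designed per-population FROH (cashmere breeds low, wild ibex-like high)
POPULATION_DESIGN = {
    "IMC": 0.03,
    "HSC": 0.07,
    "JNG": 0.045,
    "SAA": 0.065,
    "ALG": 0.065,
    "BOE": 0.06,
    "IBE": 0.45,
}
DEFAULT_CHROM_LENGTHS = {str(c): 30_000_000 for c in (1, 2, 3)}


def simulate_goatlike_cohort(
    seed: int,
    samples_per_pop: int = 4,
    chrom_lengths: dict[str, int] | None = None,
    snp_density_per_kb: float = 0.15,
    het_error_rate: float = 0.002,
    missing_rate: float = 0.01,
) -> tuple[GenotypeMatrix, pd.Series, list[TruthTract]]:
    """Simulate the cohort; returns (genotypes, population map, truth).

    All samples share one background simulation (one SNP map); each
    population's tract design is planted on its block of samples.
    """
    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    cfg = SimulationConfig(
        n_samples=samples_per_pop * len(POPULATION_DESIGN),
        chrom_lengths=chrom_lengths,
        seed=seed % (2**31 - 1),
        snp_density_per_kb=snp_density_per_kb,
        het_error_rate=het_error_rate,
        missing_rate=missing_rate,
    )
    gm = simulate_background(cfg)
    sample_names: list[str] = []
    pops: list[str] = []
    tracts: list[TruthTract] = []
    for k, (pop, target) in enumerate(POPULATION_DESIGN.items()):
        design_cfg = SimulationConfig(
            n_samples=samples_per_pop,
            chrom_lengths=chrom_lengths,
            seed=(seed * 101 + 7 * k + 1) % (2**31 - 1),
            snp_density_per_kb=snp_density_per_kb,
        )
        offset = k * samples_per_pop
        for t in design_population(target, design_cfg):
            idx = int(t.sample_id[1:]) + offset
            tracts.append(TruthTract(f"S{idx:03d}", t.chrom, t.start_bp, t.end_bp))
        sample_names.extend(f"{pop}_{i:02d}" for i in range(samples_per_pop))
        pops.extend([pop] * samples_per_pop)
    gm = plant_tracts(gm, tracts, cfg)
    # rename samples (and their truth tracts) to population-prefixed ids
    rename = dict(zip(gm.samples, sample_names))
    gm.samples = sample_names
    tracts = [
        TruthTract(rename[t.sample_id], t.chrom, t.start_bp, t.end_bp) for t in tracts
    ]
    pop_map = pd.Series(pops, index=sample_names, name="population")
    pop_map.index.name = "sample_id"
    return gm, pop_map, tracts


def write_cohort(
    gm: GenotypeMatrix, pop_map: pd.Series, tracts: list[TruthTract], out_dir: str | Path
) -> tuple[Path, Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geno = out_dir / "cohort.genotypes.tsv"
    popmap = out_dir / "cohort.popmap.tsv"
    truth = out_dir / "cohort.truth.tsv"
    write_genotype_tsv(gm, geno)
    pop_map.reset_index().to_csv(popmap, sep="\t", index=False)
    truth_to_frame(tracts).to_csv(truth, sep="\t", index=False)
    return geno, popmap, truth
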
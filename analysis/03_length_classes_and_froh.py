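"""Length-class summary and genomic inbreeding (FROH) per population.

Classifies segments into small (<0.3 Mb), medium (0.3-1.5 Mb) and large
(>1.5 Mb), and computes FROH = sum(L_ROH)/L_auto per individual with
L_auto taken as the SNP-covered autosome span of the simulated panel.
"""

from pathlib import Path

from rohscan import (
    classify,
    froh,
    per_chromosome_counts,
    per_individual_nroh_sroh,
    population_froh,
    read_genotype_tsv,
    read_population_map,
    read_segments,
    summarize_classes,
)
from rohscan.pipeline import snp_covered_length_mb

out = Path("results/stats")
out.mkdir(parents=True, exist_ok=True)

segments = read_segments("results/roh/roh_segments.tsv")
gm = read_genotype_tsv("results/roh/genotypes.qc.tsv")
pop_map = read_population_map("results/cohort/cohort.popmap.tsv")
l_auto = snp_covered_length_mb(gm.variants)

labeled = classify(segments)
summary = summarize_classes(labeled)
summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
per_chromosome_counts(labeled).to_csv(out / "per_chromosome.tsv", sep="\t", index=False)
per_individual_nroh_sroh(segments).to_csv(out / "nroh_sroh.tsv", sep="\t", index=False)

per_sample = froh(segments, samples=gm.samples, l_auto_mb=l_auto)
per_sample.to_csv(out / "froh.tsv", sep="\t", index=False)
pops = population_froh(per_sample, pop_map)
pops.to_csv(out / "froh_populations.tsv", sep="\t", index=False)

print(f"L_auto = {l_auto:.2f} Mb (SNP-covered span)")
print(summary.to_string(index=False))
ranked = pops.sort_values("mean_froh")
print("population FROH (ascending):")
for _, row in ranked.iterrows():
    print(f"  {row['population']}: {row['mean_froh']:.4f} (n={row['n']})")
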
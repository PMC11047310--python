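"""Quality control and ROH calling on the simulated cohort.

Applies the ROH QC profile (sample/SNP missingness and HWE filters, no
MAF cut) and the default 50-SNP sliding-window scan; writes the QC report
and the per-individual segment table to results/roh/.
"""

from pathlib import Path

from rohscan import QCParams, apply_qc, call_all, read_genotype_tsv, read_population_map, write_segments
from rohscan.genotype_io import write_genotype_tsv

out = Path("results/roh")
out.mkdir(parents=True, exist_ok=True)

gm = read_genotype_tsv("results/cohort/cohort.genotypes.tsv")
pop_map = read_population_map("results/cohort/cohort.popmap.tsv")

gm, report = apply_qc(gm, QCParams.roh_profile())
report.write(out / "qc_report.tsv")
write_genotype_tsv(gm, out / "genotypes.qc.tsv")
print(f"QC: kept {report.n_samples_out}/{report.n_samples_in} samples, "
      f"{report.n_variants_out}/{report.n_variants_in} SNPs "
      f"(missingness {report.snps_removed_missing}, HWE {report.snps_removed_hwe})")

segments = call_all(gm, population_map=pop_map)
write_segments(segments, out / "roh_segments.tsv", population_map=pop_map)
print(f"called {len(segments)} ROH segments across {segments['sample_id'].nunique()} individuals")
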
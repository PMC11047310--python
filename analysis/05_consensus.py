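"""Consensus ROH regions in the two cashmere-like populations (IMC+HSC).

Pools overlapping segments across individuals; a pool's CON span is the
intersection of its members.  Selected regions need CON > 0.1 Mb shared
by > 30% of the IMC+HSC animals (both strict).
"""

from pathlib import Path

from rohscan import ConsensusFilter, consensus_report, filter_consensus, pool_segments, read_population_map, read_segments

out = Path("results/consensus")
out.mkdir(parents=True, exist_ok=True)

segments = read_segments("results/roh/roh_segments.tsv")
pop_map = read_population_map("results/cohort/cohort.popmap.tsv")
ref = [s for s in pop_map.index if pop_map[s] in {"IMC", "HSC"}]

pools = pool_segments(segments[segments["sample_id"].isin(ref)])
selected = filter_consensus(pools, ConsensusFilter(), ref)
report = consensus_report(selected, population_map=pop_map)
report.to_csv(out / "consensus.tsv", sep="\t", index=False)
consensus_report(pools, population_map=pop_map).to_csv(out / "pools_all.tsv", sep="\t", index=False)

print(f"{len(pools)} pools among {len(ref)} IMC+HSC animals; "
      f"{len(selected)} pass CON > 0.1 Mb in > 30% of animals")
if not report.empty:
    print(report[["pool_id", "chrom", "con_start", "con_end", "con_kb", "n_animals"]].to_string(index=False))
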
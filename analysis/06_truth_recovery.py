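"""Score the called ROH segments against the planted ground truth.

Reports per-class sensitivity at 90% reciprocal overlap, precision, and
the fraction of planted tract length recovered.  Small tracts (<0.3 Mb)
sit near the caller's design limits (30 SNPs / 200 kb / 50-SNP window),
so their per-tract sensitivity is expected to be low at this marker
density while total-length recovery stays high.
"""

import json
from pathlib import Path

import pandas as pd

from rohscan import TruthTract, evaluate_recovery, read_segments

out = Path("results/recovery")
out.mkdir(parents=True, exist_ok=True)

segments = read_segments("results/roh/roh_segments.tsv")
truth_df = pd.read_csv("results/cohort/cohort.truth.tsv", sep="\t", dtype={"chrom": str})
truth = [
    TruthTract(r.sample_id, r.chrom, int(r.start_bp), int(r.end_bp))
    for r in truth_df.itertuples()
]

rep = evaluate_recovery(segments, truth, min_reciprocal_overlap=0.9)
result = dict(
    sensitivity=rep.sensitivity,
    precision=rep.precision,
    truth_length_covered=rep.truth_length_covered,
    length_concordance=rep.length_concordance,
    per_class_sensitivity=rep.per_class_sensitivity,
    n_truth=rep.n_truth,
    n_called=rep.n_called,
)
(out / "recovery.json").write_text(json.dumps(result, indent=2))
print(json.dumps(result, indent=2))
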
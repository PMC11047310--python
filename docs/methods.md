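# Methods

## ROH detection model

Detection is the classical two-stage sliding-window scan over one
individual's genotypes on one chromosome.

**Window stage.** A window of `window_snp` (default 50) consecutive SNPs
is homozygous when it contains at most `window_het_max` (1) heterozygous
and `window_missing_max` (5) missing calls. Each SNP's *hit fraction* is
the share of homozygous windows among the windows that contain it; only
instantiated windows count, so SNPs within 49 positions of a chromosome
end have fewer than 50 windows in the denominator. A SNP is *eligible*
when its hit fraction is ≥ `window_threshold` (0.05, compared with `>=`).
Chromosomes with fewer SNPs than one window are scanned with a single
truncated window covering every SNP (with the same absolute het/missing
caps) rather than skipped.

**Segment stage.** Maximal runs of eligible SNPs are split wherever the
distance between consecutive SNPs exceeds `max_gap_kb` (500 kb; splitting
precedes the count/length tests, so a long gap always terminates a run).
Each run is trimmed from both ends until the endpoints are non-missing
homozygous calls, then kept iff it has ≥ `min_snp` (30) SNPs, spans
≥ `min_length_kb` (200 kb), and its density `length_kb / n_snps` is
≤ `max_density_kb_per_snp` (30). Segment length is the inclusive span
`end_bp − start_bp + 1`; `n_snps` counts every SNP in the span, including
interior heterozygous/missing calls admitted by the window stage. No
segment-level heterozygote cap is imposed beyond what window eligibility
admits. Two runs separated by at least one ineligible SNP are never
merged.

These choices (hit-fraction denominator, trimming rule, inclusive length)
are fixed by a brute-force enumerator oracle in the test suite — 500
random instances must match exactly — not by comparison against any
external binary, whose internal trimming is not publicly specified.

A practical design limit worth knowing: a tract spanning fewer SNPs than
one window is nearly undetectable, because every window containing it
also contains enough flanking (heterozygote-rich) background to fail the
het cap. At default parameters the effective detection floor is a tract
of roughly one window span plus the 30-SNP/200-kb minima.

## Quality control

Filter order is samples before SNPs: (1) samples with missing fraction
> 0.1; (2) SNPs with missing fraction > 0.1; (3) SNPs failing the exact
Hardy–Weinberg test at p < 1e-3, computed on the pooled retained samples
(per-population testing is possible by running per-population); (4) MAF
< 0.05, enabled only in the `structure` profile — the `roh` profile omits
it because autozygous regions depress MAF by construction. The order
makes QC idempotent. All-missing SNPs are untestable for HWE and are kept
at that step (step 2 removes them at its default threshold anyway).

The HWE test is the exact conditional test: given the observed allele
counts, the probability of each possible heterozygote count follows the
standard recurrence; the two-sided p-value sums the probabilities of all
configurations no more likely than the observed one (relative tie guard
1e-10). An independent log-gamma enumeration oracle pins it to 1e-9 for
totals ≤ 200.

## Length classes and F<sub>ROH</sub>

Classes: small < 0.3 Mb, medium 0.3–1.5 Mb (closed on both boundaries),
large > 1.5 Mb. Class summaries report counts, count and length
percentages of the grand totals, and mean ± SD length with the population
SD (÷N). F<sub>ROH</sub> = Σ segment lengths / L<sub>auto</sub> per individual;
the population mean averages over individuals with at least one ROH
(individuals without any are tallied separately), which reproduces the
published goat-panel coefficients from their printed totals at 4-decimal
precision (acceptance test). L<sub>auto</sub> must be supplied for a real
panel (2466.19 Mb for the goat panel this package was built around); the
pipeline's default is the SNP-covered autosome span of the input map,
logged at run time.

## Islands

Incidence of a SNP in a population = fraction of that population's
individuals whose ROH set covers the position (denominator: all analyzed
individuals, not only ROH carriers). The island threshold is the k-th
largest incidence with k = ceil(0.001·n_snps) — the "top 0.1% of SNPs"
rule — and only SNPs *strictly* above it qualify, so ties at the
threshold are excluded and a constant track yields no islands. Islands
are maximal runs of consecutive qualifying SNPs with at least
`min_snps` = 2 members (a one-SNP "contiguous string" is degenerate).
Thresholds are computed per population; with few individuals the
incidence track is quantized (multiples of 1/n) and ties at the maximum
make the scan legitimately empty — the analysis drivers demonstrate this
and the properly powered case side by side. Gene annotation is a plain
≥1 bp interval join (via pyranges) against user-supplied BED/GFF3
intervals; functional enrichment is out of scope.

## Consensus pooling

Pools are built greedily per chromosome: the seed is the segment
overlapped by the most other unpooled segments (ties: longer, then
leftmost, then smaller end, then sample id); candidates joining in
(start, end, sample) order are admitted while their intersection with the
running CON stays non-empty. CON = intersection of members, UNION = their
span; pools need ≥2 animals and each segment joins at most one pool. The
rule is a deterministic, order-invariant definition of "overlapping ROH
pool" validated against the CON concept (shared interval of ≥2 animals),
not a re-implementation of any external tool's grouping internals.
Selection keeps pools with CON > 0.1 Mb shared by > 30% (both strict) of
the reference animals, with the combined reference set (e.g. both
cashmere breeds) as the default denominator.

## Synthetic data

The simulator states a world, it does not fit one:

- SNP positions uniform per chromosome at `snp_density_per_kb` (default
  0.1 = one per 10 kb; the dense setting 0.2 is used where a criterion
  specifies dense markers).
- Per-SNP alternate-allele frequency uniform on [0.05, 0.5] (a post-QC,
  MAF-filtered spectrum); genotypes Hardy–Weinberg, independent across
  SNPs and samples. There is no background LD — island behaviour is
  driven by shared planted tracts, not linkage.
- Autozygosity by direct tract planting: inside a tract each SNP is
  homozygous, allele drawn with probability equal to its frequency; then
  heterozygote errors (`het_error_rate`) and missingness
  (`missing_rate`) are sprinkled inside the tract. Planting gives exact
  ground truth; no pedigree or coalescent process is simulated.
- `design_population` draws tract lengths from per-class uniform ranges
  (small 0.21–0.3 Mb, chosen above the caller's 200 kb minimum so the
  class is not undetectable by construction; medium 0.3–1.5 Mb; large
  1.5–5 Mb) and places them without overlap until the planted total
  reaches `target_froh` × genome length. The stopping rule overshoots by
  less than one tract length per sample — in expectation about
  E[L²]/2E[L] ≈ 1.2 Mb with the default mix — so recovered F<sub>ROH</sub>
  carries a positive bias of roughly that amount divided by genome
  length. On the 150 Mb genomes used for parameter-recovery checks this
  is under 0.01; on the 90 Mb demonstration cohort it is ~0.015, which is
  why two populations designed 0.030 vs 0.045 apart may swap ranks there.
- All randomness flows from the single mandatory config seed through
  named substreams; identical configs give identical outputs.

A green recovery test therefore establishes that the caller finds planted
homozygous tracts under HWE background noise at the stated density and
error rates — not that it would match any particular tool on real
LD-structured data.

## Numerical and degenerate-input choices

- Coordinates 1-based inclusive internally; BED export 0-based half-open.
- Half-missing diploid VCF calls are MISSING.
- Genotype codes int8: 0/1/2 hom-ref/het/hom-alt, −1 missing.
- Window threshold comparison `>=`; HWE tie guard multiplicative 1e-10;
  island threshold strict `>`; consensus filters strict `>` twice.
- Empty inputs: empty segment tables are valid everywhere; recovery
  ratios over empty sets are NaN (undefined), never 0/0 errors; QC raises
  naming the step that removed the last sample/SNP.

## Known limitations

- No LD in the simulator; no pedigree mode.
- The caller is not validated bit-for-bit against PLINK binaries (end
  trimming there is undocumented); it is validated against this package's
  specification via the enumerator oracle.
- Sample-size-quantized incidence makes the top-0.1% island rule
  degenerate for very small populations (see Islands).
- X chromosome and genotype-likelihood/HMM calling are out of scope.
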
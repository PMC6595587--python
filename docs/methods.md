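# Methods

## Data model and preprocessing

Inputs follow the TCGA legacy conventions: per-sample segment tables
(`Sample / Chromosome / Start / End / Num_Probes / Segment_Mean`, segment
means on a log2-ratio scale where 0 is copy-neutral), two-column
RSEM-normalized expression files, a gene annotation table keyed by HUGO
symbol, and a per-chromosome centromere layout. All coordinates are
treated as 1-based, fully closed intervals, the seg-file convention;
every overlap computation in the package states this. Chromosome labels
are normalized by stripping a case-insensitive `chr` prefix, so `chr7`
and `7` are one key.

Sample classes come from the TCGA barcode's two-digit sample-type code:
`01` is a primary tumor, `10`–`14` are nonmalignant controls
(solid-tissue/blood normals), `02`–`09` are other tumor samples. The
primary filter keeps only `01`; analyses are further restricted to
autosomes (chromosomes 1–22).

The gene-level CNV of a gene in a sample is the **unweighted arithmetic
mean** of the segment means of all segments intersecting the gene, with
any nonzero overlap counting. An overlap-length-weighted mean is
available behind a flag but is not the default: with typical array
segment lengths far exceeding gene lengths, most genes fall entirely
inside one segment and the two estimators coincide; where they differ the
unweighted mean is the simpler, documented choice. Genes not covered by
any segment in a sample carry a missing value that is excluded pairwise
downstream, never imputed. Overlapping segments within one sample are
rejected as a data error (abutting segments are fine).

Arm assignment: a gene wholly left of the centromere is `p`, wholly right
is `q`; a centromere-spanning gene goes to the arm holding the larger
per-base share of the gene body, ties to `p`. Acrocentric chromosomes
(13, 14, 15, 21, 22) carry no p-arm genes on the profiling platform, so
p slots are kept as empty curves by default; a flag admits p-arm genes
when an annotation provides them.

## Mountain curves

A Mountain curve is the per-gene group **median** (default) or mean,
restricted to one arm and ordered by genomic start position, ties broken
by symbol. The median is the default summary because the mean is highly
sensitive to the extreme single-sample amplifications that occur in tumor
copy-number data (amplicons two orders of magnitude above baseline);
median curves change by at most the gap to the adjacent order statistic
when one outlier sample is added. Genes dropped for all-missing values
are recorded in curve metadata so two groups can later be intersected to
a common gene set.

## DTW similarity

Two arm curves x (length n) and y (length m) are aligned by dynamic time
warping with local cost d(i,j) = |x_i − y_j| (squared cost selectable)
and the standard three-predecessor recursion

    D(i,j) = d(i,j) + min[D(i−1,j), D(i,j−1), D(i−1,j−1)],  D(1,1) = d(1,1),

with boundary rows/columns accumulating along the single feasible
direction. The optimal monotone warping path is recovered by backtracking
from (n,m); ties prefer the diagonal predecessor, then the vertical one —
fixed purely for reproducibility, since tied predecessors yield equal
accumulated distance. The inner loop is a numba kernel so 500-point
curves and bootstrap loops stay fast.

**Normalization.** The raw accumulated distance is mapped to a similarity
score via `score = 1/(1 + D/K)` with K the warping-path length. This form
was an open design choice; it is adopted because it is endpoint-correct
(D = 0 gives exactly 1, the score of coinciding curves), strictly
decreasing in D, bounded in [0, 1], and scaled by path length so arms
with different gene counts are comparable. An exponential alternative
`exp(−D/K)` with the same endpoints is selectable by config; the default
is fixed and documented. Because DTW accumulates cost along the whole
path, a long alteration depresses the score more than a tall short one —
the length of an alteration matters more than its height — which the test
suite asserts on constructed arm pairs.

**Genome-wide aggregation** is the sum of the arm scores, reported with
the arm count (39 non-empty arms on a full human-like genome).

**Bootstrap test.** To ask whether the divergence of two groups' curves
on an arm exceeds random fluctuation, the two groups' sample columns are
pooled; `n_boot` times, two pseudo-groups of the original sizes are drawn
with replacement from the pool, both summary curves are rebuilt and
scored, and the add-one p-value

    p = (1 + #{null score ≤ observed score}) / (n_boot + 1)

is reported — low scores mark dissimilar curves, so the lower tail is
extreme. The attainable floor is 1/(n_boot+1). The procedure is
deterministic under a fixed seed, and at large `n_boot` the p-value is
seed-insensitive up to sampling error. Arm matrices entering the
bootstrap must be complete; genes with a missing value in either group
are dropped from that arm's resampling.

## Per-gene statistics

- **Two-group test:** Welch's unequal-variance t-test by default — group
  variances differ across cancer types, so the pooled-variance variant is
  deliberately not used — with a Mann-Whitney rank test as the option.
  Degenerate cases: two identical constant groups give p = 1;
  constant-but-different groups with zero variance give the smallest
  representable positive p with a warning.
- **Multiple testing:** Benjamini–Hochberg step-up q-values over exactly
  the tested gene set (delegated to statsmodels, verified in tests
  against the literal step-up definition); chosen over a λ-based
  estimator, which is not offered, for determinism. A Bonferroni per-test threshold α/n is
  provided as the conservative family-wise alternative.
- **Directional Manhattan:** each gene's −log10 Q carries sign −1 when
  the group-1 median is below the group-2 median (bar under the
  baseline), +1 when above, 0 on an exact tie (baseline).
- **Deflection:** per cancer type k, amplitude_k = sign(tumor median −
  nonmalignant median) · (−log10 q_k); the winner is the type with the
  larger absolute amplitude, `tie` on equality. All amplitudes use log
  base 10.
- **Volcano:** raw p-values (not Q), per convention for this plot, with
  strict significance p < cutoff (p = cutoff is not significant). In
  expression mode the effect is log2((mean1+ε)/(mean2+ε)) with
  pseudo-count ε = 1 on RSEM-normalized counts to avoid division by
  zero; in CNV mode — where values are already log2 ratios and a ratio of
  ratios is meaningless — the effect is the difference of group means.
- **Bee-swarm layout:** deterministic greedy packing. Points are placed
  in sorted value order; each takes the smallest-magnitude lateral offset
  (positive side on ties) such that it sits at least one point diameter,
  in the plane spanned by the value and offset axes, from every
  previously placed point. No two points are ever closer than one
  diameter; offsets fill both sides alternately.
- **CNV-expression regression:** Pearson r plus OLS slope/intercept on
  pairwise-complete values (≥ 3 pairs); constant vectors raise an
  undefined-correlation error rather than returning NaN.

## Synthetic cohorts

The generator emulates the structure of the real inputs, not their
biology: arms tiled by a fixed number of abutting segments (5 per arm by
default), baseline segment mean 0 with i.i.d. Gaussian segment noise, and
injected events — broad (whole-arm) or focal (a gene-index span, which
gets its own breakpoints) — of configurable magnitude added to a
deterministic fraction of tumor samples. Expression is
`max(0, 10 + 2·CNV + N(0, 1))` per gene and sample. Defaults are
22 chromosomes × 20 genes per arm, 30 tumors + 30 normals, noise sd 0.1
on the log2-ratio scale — group sizes and noise at which an arm-level
+1.0 gain is unambiguous while per-segment noise is still visible in the
curves; null calibration scenarios use 20+20. Sample ids are TCGA-style
barcodes (`-01` tumors, `-11` normals) so the barcode filters are
exercised end to end.

What passing tests on these fixtures do **not** show: real segment
lengths are heterogeneous and breakpoints correlate with genomic
features; real noise is not i.i.d. Gaussian and normal contamination,
ploidy shifts and GC waves are absent; expression regulation is far
richer than a single linear coupling. The fixtures validate the
arithmetic and the statistical calibration of the methods, not their
biological discovery rate on real cohorts.

## Numerical and interface choices

- p-values are clamped to the open interval (0, 1]; −log10 transforms
  therefore never overflow to infinity.
- Result tables round floats to 6 decimals at serialization, which makes
  repeated runs with identical config and seed byte-identical.
- All randomness (simulation, bootstrap) flows through
  `numpy.random.default_rng` seeded from explicit config fields.
- The CLI is a thin layer over the library and takes flags only (no
  config-file merging): every number in a figure comes from a table
  produced by the library, so figures are only smoke-tested. Exit codes:
  0 success, 1 computation error, 2 usage error; each output table gets a
  `.log` sidecar recording config, seed and versions.

## Known limitations

- No segmentation (CBS), no GISTIC-style broad/focal decomposition, no
  banded or multivariate DTW, no gene-set enrichment or survival
  analysis; methylation and miRNA data types are out of scope.
- The normalization and bootstrap formulations are this package's own
  documented constructions with the stated endpoint semantics; published
  arm-score tables produced by other platforms are not expected to be
  numerically reproduced, since they depend on data snapshots and
  normalization details not public.
- The bootstrap pools samples under the null of exchangeability; it does
  not model patient-level covariates or batch structure.
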
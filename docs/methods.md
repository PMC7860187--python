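# Methods

## Panel model

A panel is a list of targets, each with a cDNA sequence, a forward primer
(a subsequence at the amplicon's 5′ end) and a 17-nt gene-specific
reverse-primer tag whose reverse complement ends the amplicon. Hotspot
positions are 1-based on the target cDNA plus strand, and all internal
intervals are 1-based closed — the convention in which amino-acid
hotspots (e.g. PIK3CA E545K) are communicated. Validation enforces: tag
length 17 and uniqueness across the panel (the tag is the sole gene
assignment key in the UMI pipeline, so sharing one would be ambiguous),
hotspot reference bases matching the cDNA, and member/reference
disjointness within each signature (a gene may belong to several
signatures' member sets). The bundled toy panel is five synthetic
random-sequence genes with realistic amplicon lengths (150–200 nt), one
synthetic PIK3CA-style hotspot and two signatures sharing one member
gene; production primer sets are proprietary and not reproduced.

## Alignment

Reads are mapped with an exact affine-gap local aligner (Biopython's
`PairwiseAligner`; match +1, mismatch −2, gap open −5, gap extend −2,
a gap of length L scoring −5 −2(L−1)) over every target and both
strands. The reference is only tens of kilobases, so full dynamic
programming is fast; a 15-mer index pre-screens candidate targets per
read and falls back to scanning everything when no seed hits, so the
screen cannot change which alignments are reachable. Ties are broken by
panel order, then plus strand. A best score below 30 is reported as "no
hit"; random 150-nt sequences score well below this floor against the
toy panel, while any genuine amplicon read scores far above it.
Filtering keeps alignments with matched region ≥ 90 nt AND identity
≥ 80 % — the boundaries are kept because the removal rule is "shorter
than 90 nt" / "less than 80 %". Quality strings are parsed and carried
but play no role in filtering. R1 and R2 are aligned independently; a
pair enters counting only if both mates pass the filter and agree on the
target (disagreements are tallied, not errors) — mate agreement is
needed anyway for the R1/R2 mutation-ratio rule.

Externally produced 12-column tabular alignments can be ingested for
counting; they carry no per-base calls, so mutation pileups on that path
raise an explicit error rather than guessing.

## UMI processing

R2 positions 1–8 (1-based) are the UMI, positions 9–25 the 17-nt tag,
read inclusively — consistent with the stated tag length. The tag must
match exactly; UMI must be full-length plain A/C/G/T. No edit-distance
UMI clustering is performed: artefactual UMIs are handled solely by the
per-target abundance filter that removes groups holding 2 % or less of
the reads of the target's largest group. That comparison is integer
arithmetic (`50·n ≤ M`), so boundary cases (e.g. sizes 1000/21/20 →
threshold 20: 21 kept, 20 removed) cannot be perturbed by floating-point
rounding, and the maximal group always survives. Ties at the threshold
are removed ("2 % or less"). One representative read per group is drawn
uniformly; a single generator is seeded per run and groups are visited
in (target, UMI) lexicographic order, making the draw reproducible
across platforms for a given seed and input order.

## Counting, expression, signatures

Reads-mode counts are target-consistent filter-passing pairs per target;
UMI-mode counts are surviving groups. Expression is
`log2(count + 0.5) − mean_ref log2(count_ref + 0.5)` over the panel's
control genes; the 0.5 pseudocount keeps zero-count genes (including
reference genes) defined, at the cost of making scale invariance
approximate at very low counts (exact as counts grow). Signature scores
are the mean reference-normalised expression over member genes. The
published clinical signature formulas (weights, offsets, cutoffs) are
defined by their source assays and are not public; the generic
mean-difference score is a labelled stand-in, and output headers say so.

## Mutation calling

Depth at a hotspot counts every mate call covering the position with a
non-gap aligned column (a pair whose mates both cover contributes two
calls; with 150–200 bp inserts and 215 bp reads both mates essentially
always cover the amplicon). Reads-mode calls require depth > 100
(strict), AF > 5 % (strict) and variant-supporting R1/R2 ratio within
[0.8, 1.2] (inclusive); a zero variant-R2 denominator records the ratio
as undefined and blocks the call. The ratio's alternative reading — all
covering R1 vs R2 reads — is available behind a flag
(`ratio_on_all_reads`). UMI-mode calls use representative reads only
(one per molecule): depth ≥ 10 unique UMIs (inclusive) and AF > 5 %;
the "roughly 80–100 reads" gloss on that threshold is treated as
commentary, not a second cutoff. When every UMI group has size one,
deduplication is the identity and the two modes' AFs coincide. CV across
replicates is `100 · sd(sample, ddof=1) / mean`.

## Statistics

Lin's CCC uses population (1/n) moments, per the original estimator:
`ccc = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`, decomposed as precision
(Pearson ρ) times accuracy `C_b = 2/(v + 1/v + u²)` with `v = s_x/s_y`,
`u = (x̄ − ȳ)/√(s_x s_y)`. The 95 % CI applies the Fisher z-transform to
the CCC with standard error `1/√(n−2)`; no CI method is canonical for
the CCC and this is the common choice. At |ccc| = 1 the transform
degenerates and the CI collapses to the point. Location tests are
Wilcoxon signed-rank (paired; undefined and an explicit error when all
differences are zero) or Mann-Whitney U (unpaired); variance comparison
is Levene's test with median centring (Brown-Forsythe), the robust
variant. α = 0.05 throughout.

Saturation treats each aligned read's UMI as a uniform draw from
`k = 4^umi_len`: expected observed fraction `1 − (1 − 1/k)^n`, expected
reads per UMI `n / (k·sat)`. Saturation is computed per library across
all targets jointly, since the UMI space is shared. Overdispersed
amplification is modelled as a negative binomial on reads-per-possible-
UMI with mean `μ = n/k` and dispersion `r`; `r` is estimated by least
squares of observed saturation percentages on the curve (optimising
log r for positivity; Levenberg-Marquardt). Least squares on the
saturation scale is a pragmatic choice — the curve is what the model is
used to draw — and requires at least three points at two distinct
library sizes. As `r → ∞` the fit converges to the binomial curve.
Floor-average reads per target is integer division (400,000 over 47
targets → 8,510).

## Simulator

`simulate_molecules` draws per-gene molecule counts as
Poisson(abundance × rt_efficiency); abundance comes from a per-gene map
or a log-normal draw. Each molecule receives a uniform random 8-nt UMI —
collisions allowed, so the binomial saturation math is exercised
honestly; a force-unique switch exists for exact-recovery runs. Hotspot
gene molecules are flagged mutant with the planted molecular fraction.
`amplify_and_sequence` amplifies each molecule by a branching process:
its per-cycle duplication probability is drawn once from Beta(a, b), and
every copy duplicates with that probability each cycle (default 40
cycles, the droplet-PCR depth). This reproduces overdispersed
reads-per-UMI distributions, unlike a lognormal shortcut. Reads are a
multinomial subsample of the final copy pool at the requested library
size (`None` emits every copy, intended for small-cycle exact-recovery
runs; Beta b = 0 denotes the degenerate efficiency-1 limit, giving
exactly 2^cycles reads per molecule). R2 is
`UMI + reverse_tag + revcomp(amplicon)` running into the forward
adaptor, R1 the forward amplicon running into the reverse adaptor, both
clipped at 215 nt; substitution errors are applied per base. Output is
gzip with zeroed name/timestamp header fields, so a seed fully
determines the bytes.

Sample type and protocol are two knobs: FF vs FFPE is rt_efficiency 0.8
vs 0.3 (fragmented, modified FFPE RNA reverse-transcribes poorly), and
even vs biased amplification is Beta(20, 1) vs Beta(0.5, 2). The
simulator does not model FFPE chemical base damage, quality-dependent or
indel sequencing errors, primer cross-interaction, or adapter chemistry;
insert length equals the amplicon (primer positions fix the fragment
ends in an amplicon assay — RT failures on fragmented templates are
absorbed into rt_efficiency). Passing tests therefore demonstrate
correctness of the pipeline logic and calibration of the counting
statistics under these idealisations, not robustness to every artefact
of real FFPE libraries.

## Validation experiment sizes

The validation experiments (`umiamp.experiments`, also driven by
`scripts/acceptance.py`) run at desk scale, chosen so binomial error
bars are meaningful: saturation Monte-Carlo uses 50 replicate draws at
library sizes 10⁴–10⁶ (with a one-UMI discreteness floor on the
comparison, since near-exhausted libraries have zero empirical spread);
dispersion recovery fits 12 points per true r ∈ {0.5, 2, 10};
exact-recovery and planted-AF runs use 20 seeds of ~60 molecules per
gene with one doubling cycle and no errors; the CV contrast amplifies
one molecule population (80 per gene, planted AF 0.30) twenty times per
bias regime at 3,000 read pairs per replicate over 20 PCR cycles. The
contrast's sampling depth (~7.5 reads per molecule) and cycle count are
part of the design, keeping each library inside the assay's operating
range — most of the library complexity sequenced, and hotspot UMI depth
above the caller's own 10-UMI floor; with shallower sampling or many
more biased cycles a handful of molecules monopolise the pool and the
UMI-side quantities become undefined rather than merely noisy. Under
high bias the reads-based across-replicate CV of counts and AF is a
multiple of the UMI-based CV; under low bias the two converge — the
qualitative behaviour expected when UMIs remove amplification noise.

## Known limitations

* The exact published signature formulas and clinical cutoffs are out of
  scope; scores here are generic mean-difference scores.
* No UMI error correction beyond the abundance filter; heavily
  error-laden UMIs inflate singleton groups (mitigated by the 2 % rule
  only when duplication is substantial).
* The NB saturation fit is a curve fit, not a likelihood fit; with few
  points or a narrow library-size range the dispersion is weakly
  identified.
* Tabular-alignment ingestion supports counting but not mutation
  calling (no per-base information).
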
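# Methods

This note records the models behind each module, the defaults that matter,
and what the synthetic benchmarks do and do not demonstrate.

## PWM model and relative match score

A motif of width W is a matrix of per-position base probabilities estimated
from N aligned sites with a pseudocount ε:

    f[i][b] = (count_i(b) + ε) / (N + 4ε)

ε defaults to 0.25 per base, enough to avoid −∞ log-odds with collections of
tens of sites while barely moving well-populated columns. Scores are summed
log2-odds against a background q (uniform 0.25 by default; a genome
composition background can be supplied — for short bacterial motifs the
uniform choice matches common practice). For matrices that contain true
zeros (e.g. a one-hot matrix built from a single consensus with ε = 0) the
log-odds are floored at −20 bits so the score range stays finite; the floor
is irrelevant whenever ε > 0.

The reported score is min–max relative: 100·(S − S_min)/(S_max − S_min),
where S_min/S_max are the column-wise worst/best sums. The threshold 82.5
used throughout therefore means "82.5 % of the way from the anti-consensus
to the consensus". Published scans often inherit whatever convention their
scanning library uses without stating it; both this convention and
percent-of-maximum (`score_mode="max"`) are implemented, and every report
names the one in effect.

Numerical care: S_min, S_max, the scalar scorer and the vectorized scanner
all accumulate the W position weights strictly left to right, and the
percent scale is computed as 100·((S−S_min)/(S_max−S_min)). This makes the
identities rel(consensus) = 100 and rel(anti-consensus) = 0 exact in
floating point, and makes the scanner's hit sets bit-reproducible against a
naive per-window evaluation — which the test suite asserts exactly, at
thresholds including 100.

Scanning evaluates every start position of the circular sequence on both
strands (windows wrap across the coordinate origin); windows containing N
are skipped and counted in a log line. Overlapping hits are all reported —
no greedy collapsing — so the scanner's semantics match plain window
enumeration. Minus-strand hits report the site as read 5′→3′ on the minus
strand and the forward-coordinate start of the matched span.

Promoter attribution assigns a hit to every gene whose window
(upstream, downstream) around the translational start contains the hit's
gene-proximal end, measured along the gene's strand with circular
arithmetic. The default window (−300, +50) bp is a conventional bacterial
promoter region; it is prominently echoed in config and report headers
because attribution is sensitive to it. A hit between divergently
transcribed genes is deliberately assigned to both.

## GC skew and replichore geometry

Windowed skew (nG − nC)/(nG + nC) is computed every `step` bp (defaults
1000/500) with wrap-around windows; a window with no G or C scores 0. Under
leading-strand G enrichment the cumulative profile falls on the arc entering
*ori* and rises from *ori* to *ter*, so the caller places ori at the
cumulative minimum and ter at the maximum (ties to the smallest coordinate).
On genomes where the opposite convention holds, reverse-complementing the
input flips the calls. Confidence is the observed amplitude
(max − min of the cumulative profile) divided by the 95th percentile of
amplitudes from 200 permutations of the window values — an
order-destroying, composition-preserving null; calls below 1 carry a
low-confidence flag rather than an error.

Gene positions use the circular midpoint (correct for genes spanning the
coordinate origin). The "clockwise" arm runs from ori toward ter in
increasing coordinates — a labeling convention only, stated in every
report. d_ori and d_ter are measured along the gene's own arm and sum to
that arm's length; the fraction d_ori/(d_ori + d_ter) ∈ [0, 1] is the
replichore coordinate used for symmetry and ortholog comparisons. A
midpoint exactly at ori or ter is assigned to the clockwise arm. No numeric
threshold for "symmetric" or "near ori/ter" is claimed to reproduce any
published visual judgment; both are plain config parameters (defaults
20 kb symmetry tolerance, 100 kb proximity).

## Two-arm time-course cascade

Design: induction arm sampled at t = 0, 10, 20, 40, 60, 120, 180 min;
solvent control arm at t = 0, 60, 180 min; ≥ 2 (default 3) replicates.

- **Normalization**: per-sample size factor = total count / geometric mean
  of totals. Adequate for the simulated data; on real data with strong
  composition effects a robust external factor set can be passed in.
- **Baseline pooling**: the t = 0 samples of both arms describe the same
  pre-induction culture and form one baseline group. Besides the extra
  degrees of freedom, this makes the control comparison (below) cancel the
  baseline term exactly.
- **Dispersion**: gene-wise method of moments pooled over all (arm, time)
  cells: with per-cell residual sums of squares SS_c around the cell mean
  μ̂_c, φ̂ = (Σ SS_c − Σ(k_c−1)μ̂_c) / Σ(k_c−1)μ̂_c², floored at 1e−6
  (negative estimates = Poisson-like genes). Pooling across cells (~20 df at
  3 replicates) rather than using only the contrast's 6 samples is what
  keeps the test calibrated; per-contrast estimates were measurably
  anti-conservative in simulation.
- **Test**: NB likelihood-ratio test of separate group means vs a common
  mean (size factors as offsets), p from χ²₁. Group means of normalized
  counts serve as the mean estimates. All-zero genes are fixed at
  (log2FC 0, p 1). log2 fold changes use a continuity constant c = 0.5:
  log2((m_t + c)/(m_0 + c)) — finite and monotone for zero counts.
- **FDR**: Benjamini–Hochberg step-up per contrast, implemented directly and
  tested for exact agreement with enumeration and with statsmodels.
- **Responsiveness gate**: FDR < 0.05 and |log2FC| > 1 at some induction
  time point.
- **Control rule**: a gate-passing gene is excluded (flag
  `excluded_by_control`) when its induction response never separates from
  the control arm, i.e. |log2FC_AHL(t) − log2FC_DMSO(t)| ≤ 1 at *every*
  sequenced control time (60 and 180 min). Such changes are attributable to
  the solvent or cultivation time rather than the autoinducer. The statistic
  (same-time fold-change difference), threshold (1) and control times are
  all config-exposed. Whether shrunken or raw fold changes should enter this
  comparison is an open choice; raw ones are used.
- **Onset**: earliest gate-passing time point; its fold-change sign is the
  direction. Genes slightly below threshold that belong to responding
  operons are *not* rescued automatically — an operon/category annotation
  column is carried through for human review instead.

The DE statistic is intentionally a simple, fully documented test rather
than a port of any published package's shrinkage machinery: the scientific
surface here is the filter cascade, which consumes any
(gene, arm, time, log2FC, FDR) table — externally produced DE results in
that schema can be substituted for the built-in test.

## Synthetic data: what it emulates, what it does not

- **Genome**: bases i.i.d. per position with arc-specific probabilities.
  On the leading arc P(G) − P(C) = s·gc and P(T) − P(A) = s·(1 − gc)
  (skew strength s, GC content gc), mirrored on the lagging arc — the
  planted skew amplitude is therefore analytically predictable. No codon
  structure, repeats, or operons; sufficient for scanner and skew-caller
  validation, not for benchmarking against real genome composition.
- **Sites**: one site per target promoter, uniform in-window offset,
  uniform strand (reverse complement written for minus), a configurable
  number of random substitutions; overlap collisions re-drawn (error after
  100 attempts). Ground truth records position, strand, target and sequence.
- **Counts**: NB with mean baseline·2^(log2FC·[t ≥ onset])·libsize-factor
  per sample; the induction effect applies to the AHL arm, and also to the
  control arm for the "both-arms artifact" class that exercises the control
  rule. Dispersion 0 gives the Poisson limit. Library-size factors default
  to 1 and exist to test normalization, since the normalization truth is
  otherwise unconstrained.

Default simulation scale (also used by `scripts/acceptance.py`): 200 kb
genome, skew strength 0.1, GC 0.5–0.6; 50 planted sites for recovery runs;
4,192 genes with 200 responders (|log2FC| = 2, onsets on the sampling grid),
50 both-arms artifacts, dispersion 0.1, baseline mean 200, 3 replicates.
These sizes keep the full benchmark suite at desk scale (seconds to a
minute) while leaving the recovery margins far from their thresholds.
Passing them demonstrates internal consistency of the method chain on data
matching the generative assumptions — not performance on real RNA-seq,
where dispersion trends, composition effects and operon structure are
harsher.

## Pipeline reproducibility

A run is a pure function of its YAML config: every artifact embeds the
config hash (computed over the semantic fields, excluding the output
location) and the seed; no timestamps are written. Re-running an identical
config produces byte-identical TSV/JSON/BED outputs, and running the stages
individually on the same intermediates reproduces the orchestrated result —
both are asserted in the test suite. On a stage failure the partial outputs
are preserved under `failed/` and the error names the failing stage.

## Known limitations

- The NB test's χ² asymptotics are approximate at 3 replicates; the pooled
  dispersion makes it conservative in simulation (null responsive rate
  ≈ 0.2 % against the 1 % budget) but real-data behavior depends on the
  dispersion–mean relationship, which is not modeled.
- Total-count normalization is not robust to heavy asymmetric regulation.
- The ori/ter caller assumes a single replichore pair (one global skew
  switch); plasmids and multi-replicon architectures are out of scope.
- The scanner is an exhaustive enumerator — exact, but not sublinear; fine
  for bacterial replicons, not tuned for large eukaryotic genomes.
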
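# regnet

Regulatory-genomics toolkit for circular bacterial chromosomes: position
weight matrix (PWM) binding-site discovery, GC-skew-based replication
origin/terminus calling with replichore coordinates, and responsiveness
classification of two-arm induction time courses. It was built around the
kind of experiment used to map quorum-sensing (QS) regulons in marine
alphaproteobacteria such as *Dinoroseobacter shibae*: a QS-negative mutant is
induced with an acyl-homoserine-lactone autoinducer (AHL), expression is
sampled over three hours against a solvent (DMSO) control arm, and the
responding genes are cross-referenced with transcription-factor binding sites
(CtrA, LexA) and with their position on the two replication arms.

Everything is testable without external data: a first-class synthetic-data
module generates seeded genomes with planted ori/ter strand bias, promoters
carrying planted motif sites, and negative-binomial count time courses with
planted responders, together with complete ground-truth tables.

## Methods at a glance

**Motif scanning.** A PWM is estimated from aligned sites with pseudocount
ε (default 0.25): `f[i][b] = (count_i(b) + ε) / (N + 4ε)`, with log-odds
weights `w[i][b] = log2(f[i][b]/q[b])` against a background `q` (uniform by
default). A window *s* scores `S(s) = Σᵢ w[i][sᵢ]` and is reported on the
*relative* scale

    rel(s) = 100 · (S(s) − S_min) / (S_max − S_min),

so a threshold of 82.5 means 82.5 % of the way from the worst to the best
attainable score (percent-of-maximum is available as `score_mode="max"`).
Both strands of the circular genome are scanned, windows wrap across the
origin, and hits are attributed to genes whose promoter window (default
−300…+50 bp around the translational start, strand-aware) contains them.
LexA-type hits are grouped by their GTTC/GAAC core.

**Replichore analysis.** The windowed GC skew (G−C)/(G+C) switches sign at
the replication origin and terminus; the cumulative profile is minimal at
*ori* and maximal at *ter* (leading-strand G enrichment). Calls carry a
confidence from a permutation null (shuffled window values), and gene
positions become (d_ori, d_ter, arm, fraction) coordinates that make
ori/ter-symmetric gene pairs and cross-species positional conservation
directly computable.

**Time-course cascade.** Counts are normalized by total-count size factors;
each (arm, time) is contrasted against the pooled pre-induction baseline
with a negative-binomial likelihood-ratio test using a gene-wise
method-of-moments dispersion pooled over all sample groups; p-values are
Benjamini-Hochberg adjusted per contrast. A gene is *responsive* when some
AHL time point has FDR < 0.05 and |log2FC| > 1 and its AHL trajectory
separates from the control (|log2FC_AHL − log2FC_DMSO| > 1 at a sequenced
control time, 60 or 180 min); otherwise a gate-passing gene is flagged
`excluded_by_control` (change attributable to solvent/cultivation). The
earliest gate-passing time is the activation onset.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```bash
# 1. generate a synthetic dataset with planted truth (200 kb genome,
#    ori=0/ter=100000, 200 genes, 30 planted GTTCGAAC sites, 24 responders)
regnet simulate --config demo.yaml --out sim     # demo.yaml may just set "seed: 1"

# 2. run the full pipeline on it
regnet run --config sim/run.yaml --out run

# 3. compare the run against the planted truth
regnet recover --run run --truth sim --out recovery.json
```

The recovery report printed for seed 1:

```json
{
  "ori_localization_error_bp":   {"value": 500},
  "ter_localization_error_bp":   {"value": 1000},
  "site_recovery_rate":          {"value": 1.0},
  "promoter_assignment_rate":    {"value": 1.0},
  "timecourse_sensitivity":      {"value": 1.0},
  "onset_accuracy":              {"value": 0.958},
  "false_call_rate":             {"value": 0.0059},
  "artifact_exclusion_rate":     {"value": 1.0}
}
```

Reading it: the ori/ter calls land within one skew window (1 kb) of the
planted positions; every planted binding site is found at threshold 82.5 and
mapped to its target promoter; all 24 planted responders are recovered with
~96 % exact onset assignment, ~0.6 % of null genes are falsely called, and
every planted both-arms artifact gene is removed by the control rule.

Individual stages are also available as `regnet scan`, `regnet oriter`,
`regnet positions`, `regnet symmetry` and `regnet timecourse`, and the same
functionality is importable (`from regnet import scan_genome, call_ori_ter,
responsive_filter, ...`).

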
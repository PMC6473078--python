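"""Seeded synthetic data with planted ground truth.

Three generators mirror the study conditions end to end: a circular genome
whose strand composition switches at planted ori/ter loci, promoters carrying
planted (optionally degenerate) motif sites, and a two-arm induction time
course (AHL at t = 0,10,20,40,60,120,180 min; solvent control at 0,60,180 min;
3 replicates) with planted responder genes of defined onset and fold change.
Every generator is a pure function of its arguments including the seed, so
downstream recovery tests are exactly reproducible.

The strand bias is parameterized so the planted skew amplitude is analytically
predictable: on the leading arc (ori -> ter in increasing coordinates)
P(G) - P(C) = skew_strength * gc_content and P(T) - P(A) =
skew_strength * (1 - gc_content); both biases are mirrored on the lagging arc.
Bases are drawn i.i.d. per position (no codon or repeat structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ALPHABET, CircularGenome, GeneAnnotation, reverse_complement
from .motif import PWM
from .timeseries import AHL_TIMES, DMSO_TIMES, ExpressionSeries


@dataclass
class GenomeTruth:
    ori_true: int
    ter_true: int
    skew_strength: float
    gc_content: float
    seed: int


@dataclass
class PlantedSiteTruth:
    position: int  # forward-coordinate start of the planted span
    strand: str
    locus_tag: str
    site: str  # as read 5'->3' on its strand
    n_mutations: int


@dataclass
class ResponderTruth:
    locus_tag: str
    onset_min: int | None  # None = null gene
    log2fc: float  # planted effect; 0 iff onset is None
    both_arms: bool = False  # True = artifact gene changing in the control arm too

    def __post_init__(self) -> None:
        if (self.onset_min is None) != (self.log2fc == 0):
            raise ValueError("onset=None exactly when the planted log2FC is 0")

    @property
    def direction(self) -> str | None:
        if self.onset_min is None:
            return None
        return "up" if self.log2fc > 0 else "down"


def generate_genome(
    length: int,
    ori: int,
    ter: int,
    skew_strength: float,
    gc_content: float,
    seed: int,
    genome_id: str = "synthetic_chromosome",
) -> tuple[CircularGenome, GenomeTruth]:
    """Circular genome with a strand-composition switch at ori and ter."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0 <= ori < length and 0 <= ter < length):
        raise ValueError("ori and ter must lie in [0, length)")
    if ori == ter:
        raise ValueError("invalid geometry: ori and ter must differ")
    if not 0 <= skew_strength < 1:
        raise ValueError("skew_strength must lie in [0, 1)")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must lie in (0, 1)")

    def arc_probs(sign: float) -> np.ndarray:
        g = gc_content / 2 * (1 + sign * skew_strength)
        c = gc_content / 2 * (1 - sign * skew_strength)
        t = (1 - gc_content) / 2 * (1 + sign * skew_strength)
        a = (1 - gc_content) / 2 * (1 - sign * skew_strength)
        p = np.array([a, c, g, t])
        if (p < 0).any() or (p > 1).any():
            raise ValueError("skew parameters push a base probability outside [0, 1]")
        return p

    rng = np.random.default_rng(seed)
    leading_len = (ter - ori) % length
    codes = np.empty(length, dtype=np.int8)
    lead = rng.choice(4, size=leading_len, p=arc_probs(+1.0))
    lag = rng.choice(4, size=length - leading_len, p=arc_probs(-1.0))
    idx_lead = (ori + np.arange(leading_len)) % length
    idx_lag = (ter + np.arange(length - leading_len)) % length
    codes[idx_lead] = lead
    codes[idx_lag] = lag
    seq = "".join(ALPHABET[c] for c in codes)
    genome = CircularGenome(id=genome_id, sequence=seq)
    truth = GenomeTruth(ori_true=ori, ter_true=ter, skew_strength=skew_strength,
                        gc_content=gc_content, seed=seed)
    return genome, truth


def annotate_genes(
    length: int,
    n_genes: int,
    gene_length: int = 900,
    spacing: int | None = None,
    seed: int = 0,
    prefix: str = "SYN",
) -> list[GeneAnnotation]:
    """Evenly spaced CDS annotations with random strands (no operon structure)."""
    if spacing is None:
        spacing = length // n_genes
    if spacing < gene_length + 400:
        raise ValueError("genes too dense for promoter windows to fit")
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        start0 = i * spacing + 350  # leave room upstream for a promoter window
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                locus_tag=f"{prefix}_{i:04d}",
                start=start0 + 1,
                end=start0 + gene_length,
                strand=strand,
                product="hypothetical protein",
            )
        )
    return genes


def plant_sites(
    genome: CircularGenome,
    pwm_or_consensus: PWM | str,
    targets: list[GeneAnnotation],
    promoter_window: tuple[int, int] = (300, 50),
    mutations_per_site: int = 0,
    seed: int = 0,
) -> tuple[CircularGenome, list[PlantedSiteTruth]]:
    """Write one motif site into each target's promoter window.

    The insertion offset is drawn uniformly so the whole site lies inside the
    window (measured along the gene's strand from its translational start);
    the site strand is drawn uniformly and the reverse complement is written
    for minus-strand sites. ``mutations_per_site`` random positions are
    substituted with a random different base. Overlaps between planted spans
    are resolved by re-drawing (error after 100 failed draws per site).
    """
    consensus = pwm_or_consensus.consensus if isinstance(pwm_or_consensus, PWM) else str(pwm_or_consensus).upper()
    W = len(consensus)
    if mutations_per_site >= W:
        raise ValueError("mutations_per_site must be < motif width")
    upstream, downstream = promoter_window
    if upstream + downstream < W:
        raise ValueError("promoter window too small to hold the motif")
    rng = np.random.default_rng(seed)
    L = genome.length
    seq = list(genome.sequence)
    occupied: set[int] = set()
    truths: list[PlantedSiteTruth] = []
    for gene in targets:
        t0 = gene.translational_start0
        for attempt in range(100):
            offset = int(rng.integers(-upstream, downstream - W + 1))
            if gene.strand == "+":
                start = (t0 + offset) % L
            else:
                start = (t0 - offset - W + 1) % L
            span = {(start + k) % L for k in range(W)}
            if span & occupied:
                continue
            occupied |= span
            break
        else:
            raise RuntimeError(f"could not place a site for {gene.locus_tag} in 100 draws")
        site = list(consensus)
        mut_positions = rng.choice(W, size=mutations_per_site, replace=False)
        for pos in mut_positions:
            alternatives = [b for b in ALPHABET if b != site[pos]]
            site[pos] = alternatives[int(rng.integers(3))]
        site_seq = "".join(site)
        strand = "+" if rng.random() < 0.5 else "-"
        written = site_seq if strand == "+" else reverse_complement(site_seq)
        for k, b in enumerate(written):
            seq[(start + k) % L] = b
        truths.append(
            PlantedSiteTruth(position=start, strand=strand, locus_tag=gene.locus_tag,
                             site=site_seq, n_mutations=int(mutations_per_site))
        )
    new_genome = CircularGenome(id=genome.id, sequence="".join(seq), circular=genome.circular)
    return new_genome, truths


def generate_counts(
    genes: list[str],
    truth: list[ResponderTruth],
    dispersion: float = 0.1,
    baseline_mean: float = 200.0,
    libsize_factors: dict[str, float] | None = None,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[ExpressionSeries, list[ResponderTruth]]:
    """Negative-binomial two-arm time course with planted responders.

    mu_g,t,arm = baseline * 2^(log2FC if t >= onset and the arm is induced,
    else 0) * libsize factor, where the AHL arm is always induced and the
    control (DMSO) arm only for both-arms artifact genes. The control arm is
    sampled at t = 0, 60, 180 min only. dispersion = 0 gives the Poisson limit.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates per (arm, time) for testing")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be > 0")
    gene_set = set(genes)
    truth_by_gene: dict[str, ResponderTruth] = {}
    for t in truth:
        if t.locus_tag not in gene_set:
            raise ValueError(f"truth refers to unknown locus_tag {t.locus_tag!r}")
        truth_by_gene[t.locus_tag] = t

    sample_rows = []
    for arm, times in (("AHL", AHL_TIMES), ("DMSO", DMSO_TIMES)):
        for t in times:
            for r in range(1, replicates + 1):
                sample_rows.append({"sample": f"{arm}_t{t}_r{r}", "arm": arm,
                                    "time_min": t, "replicate": r})
    samples = pd.DataFrame(sample_rows).set_index("sample")
    factors = np.array([
        1.0 if libsize_factors is None else float(libsize_factors.get(s, 1.0))
        for s in samples.index
    ])
    if (factors <= 0).any():
        raise ValueError("libsize factors must be positive")

    lfc = np.zeros(len(genes))
    onset = np.full(len(genes), np.inf)
    both = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        tr = truth_by_gene.get(g)
        if tr is not None and tr.onset_min is not None:
            lfc[i] = tr.log2fc
            onset[i] = tr.onset_min
            both[i] = tr.both_arms

    rng = np.random.default_rng(seed)
    mat = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j, (name, row) in enumerate(samples.iterrows()):
        induced = (row["arm"] == "AHL") | both
        effect = np.where(induced & (row["time_min"] >= onset), lfc, 0.0)
        mu = baseline_mean * np.power(2.0, effect) * factors[j]
        if dispersion == 0:
            mat[:, j] = rng.poisson(mu)
        else:
            shape = 1.0 / dispersion
            mat[:, j] = rng.poisson(rng.gamma(shape, mu * dispersion))
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="locus_tag"), columns=samples.index)
    return ExpressionSeries(counts=counts, samples=samples), truth


def truth_tables(
    genome_truth: GenomeTruth | None = None,
    site_truths: list[PlantedSiteTruth] | None = None,
    responder_truths: list[ResponderTruth] | None = None,
) -> dict[str, pd.DataFrame]:
    """Ground-truth sidecar tables in TSV-ready form."""
    out: dict[str, pd.DataFrame] = {}
    if genome_truth is not None:
        out["genome"] = pd.DataFrame([vars(genome_truth)])
    if site_truths is not None:
        out["sites"] = pd.DataFrame(
            [vars(s) for s in site_truths],
            columns=["position", "strand", "locus_tag", "site", "n_mutations"],
        )
    if responder_truths is not None:
        out["responders"] = pd.DataFrame(
            [
                {
                    "locus_tag": r.locus_tag,
                    "onset_min": -1 if r.onset_min is None else r.onset_min,
                    "log2fc": r.log2fc,
                    "direction": r.direction or "none",
                    "both_arms": r.both_arms,
                }
                for r in responder_truths
            ]
        )
    return out
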
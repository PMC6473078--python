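"""Position weight matrices and genome scanning.

A PWM is built from an alignment of equal-length binding sites. Matches are
reported with a *relative* score: the summed log-odds of the window,
min–max-scaled so that the per-column argmax sequence scores 100 and the
per-column argmin sequence scores 0. A threshold of 82.5 therefore means
"82.5% of the way from the worst to the best achievable score". The
alternative convention (percent of the maximal score alone) is available via
``score_mode="max"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import ALPHABET, CircularGenome, GeneAnnotation, encode, reverse_complement

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# log2-odds floor in bits: probability ratios below 2^-20 are clamped so that
# zero-probability cells (pseudocount 0) keep S_min finite and the min-max
# scale well defined. Irrelevant whenever pseudocount > 0.
WEIGHT_FLOOR = -20.0


@dataclass
class PWM:
    """Per-position base probabilities with log2-odds weights.

    probs has shape (W, 4) in A,C,G,T order and rows summing to 1.
    """

    probs: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    id: str = "pwm"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probabilities must have shape (W, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if np.any(self.background <= 0):
            raise ValueError("background probabilities must be positive")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """log2(f/q), floored at WEIGHT_FLOOR bits so zero cells stay finite."""
        with np.errstate(divide="ignore"):
            w = np.log2(self.probs / self.background)
        return np.maximum(w, WEIGHT_FLOOR)

    # S_min/S_max accumulate strictly left-to-right, the same order used by
    # relative_score and the scanner, so the consensus scores exactly 100 and
    # the anti-consensus exactly 0 in floating point.
    @property
    def s_min(self) -> float:
        total = 0.0
        for x in self.weights.min(axis=1):
            total += float(x)
        return total

    @property
    def s_max(self) -> float:
        total = 0.0
        for x in self.weights.max(axis=1):
            total += float(x)
        return total

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        """PWM matching the reverse complement of this motif."""
        return PWM(
            probs=self.probs[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
            id=self.id,
        )


@dataclass
class MotifHit:
    """A scored PWM match; position is the 0-based forward-coordinate start."""

    pwm_id: str
    position: int
    strand: str
    site: str
    rel_score: float
    group: str = "not-applicable"


@dataclass
class PromoterAssignment:
    locus_tag: str
    hit: MotifHit
    offset: int


def build_pwm(
    sites: list[str],
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    pwm_id: str = "pwm",
) -> PWM:
    """Estimate a PWM from aligned equal-length sites.

    f[i][b] = (count_i(b) + pseudocount) / (N + 4*pseudocount).
    """
    if not sites:
        raise ValueError("site collection is empty")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites have unequal lengths (not an alignment)")
    counts = np.zeros((width, 4), dtype=float)
    for s in sites:
        s = s.upper()
        for i, b in enumerate(s):
            if b not in _BASE_INDEX:
                raise ValueError(f"non-ACGT character {b!r} in site {s!r}")
            counts[i, _BASE_INDEX[b]] += 1
    n = len(sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(probs=probs, pseudocount=pseudocount, background=bg, id=pwm_id)


def pwm_from_consensus(consensus: str, pwm_id: str = "consensus") -> PWM:
    """One-hot PWM (pseudocount 0) from a single consensus sequence."""
    return build_pwm([consensus], pseudocount=0.0, pwm_id=pwm_id)


def relative_score(pwm: PWM, s: str, score_mode: str = "minmax") -> float:
    """Percent score of a W-mer under the PWM.

    "minmax": 100*(S - S_min)/(S_max - S_min); "max": 100*S/S_max.
    """
    if len(s) != pwm.width:
        raise ValueError(f"sequence length {len(s)} != PWM width {pwm.width}")
    s = s.upper()
    if any(b not in _BASE_INDEX for b in s):
        raise ValueError("sequence contains non-ACGT characters")
    w = pwm.weights
    score = 0.0
    for i, b in enumerate(s):
        score += w[i, _BASE_INDEX[b]]
    return _to_percent(score, pwm, score_mode)


def _to_percent(score, pwm: PWM, score_mode: str):
    smin, smax = pwm.s_min, pwm.s_max
    if score_mode == "minmax":
        if smax == smin:
            raise ValueError("degenerate PWM: S_max equals S_min, relative score undefined")
        # ratio first: consensus and anti-consensus land on exactly 100 and 0
        return 100.0 * ((score - smin) / (smax - smin))
    if score_mode == "max":
        if smax == 0:
            raise ValueError("degenerate PWM: S_max is 0, percent-of-max undefined")
        return 100.0 * score / smax
    raise ValueError(f"unknown score_mode {score_mode!r}")


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all windows plus a validity mask (False where the window has N).

    codes is the int-encoded sequence already extended for wrap-around;
    returns one score per start position 0..len(codes)-W.
    """
    W = weights.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(codes, W)
    valid = ~(win == 4).any(axis=1)
    safe = np.where(win == 4, 0, win)
    # accumulate position by position (left-to-right, matching relative_score)
    scores = np.zeros(win.shape[0])
    for i in range(W):
        scores += weights[i, safe[:, i]]
    return scores, valid


def scan_genome(
    genome: CircularGenome,
    pwm: PWM,
    min_percent: float,
    strands: str = "both",
    score_mode: str = "minmax",
) -> list[MotifHit]:
    """Score every start position on the requested strands, keep hits ≥ threshold.

    On circular genomes windows wrapping past the end are included. A minus
    strand hit reports the reverse-complement W-mer (the site as read 5'→3'
    on the minus strand) and the forward-coordinate start of the matched span.
    Windows containing N are skipped (counted in a log line). Output is
    sorted by (position, strand).
    """
    if not 0 <= min_percent <= 100:
        raise ValueError("min_percent must be in [0, 100]")
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    W = pwm.width
    L = genome.length
    if W > L:
        raise ValueError(f"PWM width {W} exceeds genome length {L}")
    seq = genome.sequence + (genome.sequence[: W - 1] if genome.circular and W > 1 else "")
    codes = encode(seq)
    n_starts = L if genome.circular else L - W + 1

    smin, smax = pwm.s_min, pwm.s_max
    if score_mode == "minmax" and smax == smin:
        raise ValueError("degenerate PWM: S_max equals S_min")

    hits: list[MotifHit] = []
    n_skipped = 0
    strand_list = ["+", "-"] if strands == "both" else [strands]
    w = pwm.weights
    for strand in strand_list:
        if strand == "+":
            scores, valid = _window_scores(codes, w)
        else:
            # score each window's reverse complement under the forward weights,
            # by scanning the reverse-complemented sequence and mapping starts
            # back to forward coordinates (keeps per-window summation order
            # identical to scoring the minus-strand word directly)
            rc_scores, rc_valid = _window_scores(encode(reverse_complement(seq)), w)
            scores, valid = rc_scores[::-1], rc_valid[::-1]
        scores, valid = scores[:n_starts], valid[:n_starts]
        n_skipped += int((~valid).sum())
        rel = _to_percent(scores, pwm, score_mode)
        keep = valid & (rel >= min_percent)
        for p in np.nonzero(keep)[0]:
            word = genome.fetch(int(p), W)
            site = word if strand == "+" else reverse_complement(word)
            hits.append(
                MotifHit(
                    pwm_id=pwm.id,
                    position=int(p),
                    strand=strand,
                    site=site,
                    rel_score=float(rel[p]),
                )
            )
    if n_skipped:
        logger.info("scan %s on %s: skipped %d windows containing N", pwm.id, genome.id, n_skipped)
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def assign_to_promoters(
    hits: list[MotifHit],
    annotation: list[GeneAnnotation],
    window: tuple[int, int] = (300, 50),
    L: int | None = None,
    circular: bool = True,
) -> list[PromoterAssignment]:
    """Assign hits to genes whose promoter window contains the hit start.

    The window (upstream, downstream) is measured along the gene's strand from
    its translational start; offsets are signed, negative = upstream. A hit
    between two divergently transcribed genes may be assigned to both.
    """
    upstream, downstream = window
    if upstream < 0 or downstream < 0:
        raise ValueError("promoter window extents must be non-negative")
    if L is None:
        if annotation:
            L = max(g.end for g in annotation) + upstream + downstream
        else:
            return []
    out: list[PromoterAssignment] = []
    for gene in annotation:
        t0 = gene.translational_start0
        for hit in hits:
            width = len(hit.site)
            # hit boundary closest to the gene's 5' direction, on the gene's strand
            hit_start = hit.position if gene.strand == "+" else hit.position + width - 1
            delta = (hit_start - t0) % L if circular else hit_start - t0
            if circular and delta > L // 2:
                delta -= L
            offset = delta if gene.strand == "+" else -delta
            if -upstream <= offset <= downstream:
                out.append(PromoterAssignment(locus_tag=gene.locus_tag, hit=hit, offset=int(offset)))
    return out


def classify_lexa_group(hit: MotifHit, pwm: PWM | None = None) -> str:
    """Classify a LexA-type site by its core: GTTC-consensus vs GAAC-consensus.

    If both cores occur, the one positioned closer to the PWM's
    highest-information column wins; ties (or no PWM) are unclassified.
    """
    site = hit.site.upper()
    pos_gttc = site.find("GTTC")
    pos_gaac = site.find("GAAC")
    if pos_gttc >= 0 and pos_gaac < 0:
        return "GTTC"
    if pos_gaac >= 0 and pos_gttc < 0:
        return "GAAC"
    if pos_gttc < 0 and pos_gaac < 0:
        return "unclassified"
    if pwm is None:
        return "unclassified"
    peak = int(np.argmax(information_content(pwm)))
    # distance from the core's centre to the most informative column
    d_gttc = abs(pos_gttc + 1.5 - peak)
    d_gaac = abs(pos_gaac + 1.5 - peak)
    if d_gttc < d_gaac:
        return "GTTC"
    if d_gaac < d_gttc:
        return "GAAC"
    return "unclassified"


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information in bits: IC_i = 2 + sum_b f log2 f (0*log 0 = 0)."""
    f = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    return 2.0 + terms.sum(axis=1)
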
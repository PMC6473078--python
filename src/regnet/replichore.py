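"""GC-skew profiles, ori/ter calling and replichore geometry.

On circular bacterial chromosomes the leading strand is typically G-enriched,
so the windowed GC skew (G-C)/(G+C) switches sign at the replication origin
and terminus and its cumulative profile is minimal at *ori* and maximal at
*ter*. Gene positions are expressed per replication arm ("replichore") as the
fractional distance from ori to ter along that arm, which makes positional
symmetry around ori or ter directly comparable within and across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CircularGenome, GeneAnnotation


@dataclass
class SkewProfile:
    window: int
    step: int
    starts: np.ndarray  # window start coordinates, bp
    values: np.ndarray  # per-window skew in [-1, 1]
    genome_length: int

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.values)


@dataclass
class ReplichoreMap:
    ori: int
    ter: int
    amplitude: float
    confidence: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")


@dataclass
class ReplichorePosition:
    locus_tag: str
    midpoint: int
    d_ori: int
    d_ter: int
    arm: str  # "clockwise" = increasing coordinates from ori toward ter

    @property
    def fraction(self) -> float:
        return self.d_ori / (self.d_ori + self.d_ter)


def gc_skew(genome: CircularGenome, window: int = 1000, step: int = 500) -> SkewProfile:
    """Windowed GC skew (nG - nC)/(nG + nC); 0 where a window has no G or C.

    Windows start every ``step`` bp; on circular genomes the trailing windows
    wrap around, giving ceil(L/step) windows in total.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    L = genome.length
    if window > L:
        raise ValueError(f"window {window} exceeds genome length {L}")
    seq = genome.sequence + (genome.sequence[: window - 1] if genome.circular else "")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_g = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    is_c = np.concatenate([[0], np.cumsum(arr == ord("C"))])
    if genome.circular:
        starts = np.arange(0, L, step)
    else:
        starts = np.arange(0, L - window + 1, step)
    ng = is_g[starts + window] - is_g[starts]
    nc = is_c[starts + window] - is_c[starts]
    tot = ng + nc
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(tot > 0, (ng - nc) / np.where(tot > 0, tot, 1), 0.0)
    return SkewProfile(window=window, step=step, starts=starts, values=values, genome_length=L)


def call_ori_ter(
    profile: SkewProfile, n_shuffles: int = 200, seed: int = 0
) -> ReplichoreMap:
    """Call ori/ter from the cumulative skew extrema.

    Convention (configurable upstream by reverse-complementing): leading-strand
    G-enrichment makes the cumulative skew rise from ori to ter, so ori is the
    window start minimizing the cumulative profile and ter the one maximizing
    it; ties break to the smallest coordinate. Confidence is the amplitude
    relative to the 95th percentile of amplitudes from shuffled window values
    (order-destroying, composition-preserving null); below 1 the call is
    flagged low-confidence.
    """
    cum = profile.cumulative
    ori = int(profile.starts[int(np.argmin(cum))])
    ter = int(profile.starts[int(np.argmax(cum))])
    amplitude = float(cum.max() - cum.min())
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    vals = profile.values
    for i in range(n_shuffles):
        c = np.cumsum(rng.permutation(vals))
        null[i] = c.max() - c.min()
    null95 = float(np.quantile(null, 0.95))
    confidence = amplitude / null95 if null95 > 0 else np.inf
    if ori == ter:
        # degenerate profile (e.g. constant skew); report antipode as ter
        ter = int((ori + profile.genome_length // 2) % profile.genome_length)
        return ReplichoreMap(ori=ori, ter=ter, amplitude=amplitude,
                             confidence=confidence, low_confidence=True)
    return ReplichoreMap(
        ori=ori, ter=ter, amplitude=amplitude,
        confidence=confidence, low_confidence=confidence < 1.0,
    )


def circular_distance(a: int, b: int, L: int) -> int:
    """Shorter-arc distance between two positions on a circle of size L."""
    if not (0 <= a < L and 0 <= b < L):
        raise ValueError("positions must lie in [0, L)")
    d = abs(a - b)
    return min(d, L - d)


def replichore_position(
    gene: GeneAnnotation, rmap: ReplichoreMap, L: int
) -> ReplichorePosition:
    """Express a gene's midpoint in replichore coordinates.

    The clockwise arm runs from ori in increasing coordinates to ter; distances
    to ori and ter are measured along the arm containing the midpoint (their
    sum is that arm's length). A midpoint exactly at ori or ter is assigned to
    the clockwise arm.
    """
    mid = gene.midpoint(L)
    arm_cw = (rmap.ter - rmap.ori) % L  # clockwise arm length
    d_fwd = (mid - rmap.ori) % L
    if d_fwd <= arm_cw:
        return ReplichorePosition(gene.locus_tag, mid, d_ori=int(d_fwd),
                                  d_ter=int(arm_cw - d_fwd), arm="clockwise")
    d_ori = L - d_fwd  # going backwards from ori
    return ReplichorePosition(gene.locus_tag, mid, d_ori=int(d_ori),
                              d_ter=int(d_fwd - arm_cw), arm="counterclockwise")


def symmetric_pairs(
    positions: list[ReplichorePosition], anchor: str = "ori", tolerance: int = 20000
) -> pd.DataFrame:
    """Gene pairs on opposite arms equidistant (within tolerance) from ori or ter.

    Returns a table sorted by distance mismatch; each unordered pair appears once.
    """
    if anchor not in ("ori", "ter"):
        raise ValueError("anchor must be 'ori' or 'ter'")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    key = "d_ori" if anchor == "ori" else "d_ter"
    rows = []
    for i, g1 in enumerate(positions):
        for g2 in positions[i + 1 :]:
            if g1.arm == g2.arm:
                continue
            mismatch = abs(getattr(g1, key) - getattr(g2, key))
            if mismatch <= tolerance:
                rows.append(
                    {
                        "gene_a": g1.locus_tag,
                        "gene_b": g2.locus_tag,
                        "d_anchor_a": getattr(g1, key),
                        "d_anchor_b": getattr(g2, key),
                        "mismatch_bp": mismatch,
                    }
                )
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "d_anchor_a", "d_anchor_b", "mismatch_bp"])
    return df.sort_values(["mismatch_bp", "gene_a", "gene_b"], kind="stable").reset_index(drop=True)


def compare_orthologs(
    pos_a: list[ReplichorePosition],
    pos_b: list[ReplichorePosition],
    pairs: pd.DataFrame,
    near_threshold: int = 100000,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Positional conservation of ortholog pairs across two genomes.

    ``pairs`` has two columns: locus tags in genome A and genome B. Returns a
    per-pair table (fraction_A, fraction_B, delta_fraction, near-ori/near-ter
    classes under ``near_threshold`` bp) plus the list of unresolved pairs
    whose locus tags were absent from either position list.
    """
    index_a = {p.locus_tag: p for p in pos_a}
    index_b = {p.locus_tag: p for p in pos_b}
    col_a, col_b = pairs.columns[:2]
    rows, unresolved = [], []
    for a_tag, b_tag in zip(pairs[col_a], pairs[col_b]):
        pa, pb = index_a.get(a_tag), index_b.get(b_tag)
        if pa is None or pb is None:
            unresolved.append((a_tag, b_tag))
            continue
        rows.append(
            {
                "locus_a": a_tag,
                "locus_b": b_tag,
                "fraction_a": pa.fraction,
                "fraction_b": pb.fraction,
                "delta_fraction": abs(pa.fraction - pb.fraction),
                "near_ori_a": pa.d_ori <= near_threshold,
                "near_ori_b": pb.d_ori <= near_threshold,
                "near_ter_a": pa.d_ter <= near_threshold,
                "near_ter_b": pb.d_ter <= near_threshold,
            }
        )
    cols = ["locus_a", "locus_b", "fraction_a", "fraction_b", "delta_fraction",
            "near_ori_a", "near_ori_b", "near_ter_a", "near_ter_b"]
    return pd.DataFrame(rows, columns=cols), unresolved
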
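"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython, GFF3 reading through gffutils; all coordinates
written to GFF3 are 1-based inclusive, BED output is 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import CircularGenome, GeneAnnotation
from .motif import PWM, MotifHit, PromoterAssignment
from .replichore import ReplichoreMap, ReplichorePosition, SkewProfile


# --- FASTA ---------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> CircularGenome:
    """First record of a FASTA file; ``topology=circular`` in the description
    (or absence of any topology tag) marks the replicon as circular."""
    record = next(SeqIO.parse(str(path), "fasta"))
    circular = "topology=linear" not in record.description
    return CircularGenome(id=record.id, sequence=str(record.seq), circular=circular)


def write_genome_fasta(genome: CircularGenome, path: str | Path) -> None:
    topo = "circular" if genome.circular else "linear"
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description=f"topology={topo}")
    SeqIO.write([rec], str(path), "fasta")


def read_sites_fasta(path: str | Path) -> list[str]:
    """Aligned binding sites from a multi-FASTA (all records, upper-cased)."""
    return [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]


# --- GFF3 ----------------------------------------------------------------

def read_gff3(path: str | Path, feature_type: str = "CDS") -> list[GeneAnnotation]:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        locus = feat.attributes.get("locus_tag", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        genes.append(GeneAnnotation(locus_tag=locus, start=feat.start, end=feat.end,
                                    strand=feat.strand, product=product))
    return genes


def write_gff3(genes: list[GeneAnnotation], genome_id: str, genome_length: int,
               path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome_id} 1 {genome_length}\n")
        for g in genes:
            attrs = f"ID=cds-{g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{genome_id}\tregnet\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


# --- PWM matrices --------------------------------------------------------

def read_matrix_tsv(path: str | Path, pwm_id: str | None = None) -> PWM:
    """Probability matrix: columns A,C,G,T; one row per motif position."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.upper() for c in df.columns]
    df.columns = cols
    missing = set("ACGT") - set(cols)
    if missing:
        raise ValueError(f"matrix file lacks columns {sorted(missing)}")
    probs = df[list("ACGT")].to_numpy(float)
    return PWM(probs=probs, id=pwm_id or Path(path).stem)


def write_matrix_tsv(pwm: PWM, path: str | Path) -> None:
    pd.DataFrame(pwm.probs, columns=list("ACGT")).to_csv(path, sep="\t", index=False,
                                                         float_format="%.6f")


# --- hits ----------------------------------------------------------------

def write_hits_bed(hits: list[MotifHit], genome_id: str, path: str | Path) -> None:
    """BED6: 0-based half-open spans, score = rel_score*10 rounded."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{genome_id}\t{h.position}\t{h.position + len(h.site)}\t{h.pwm_id}"
                f"\t{round(h.rel_score * 10)}\t{h.strand}\n"
            )


def hits_table(hits: list[MotifHit],
               assignments: list[PromoterAssignment] | None = None) -> pd.DataFrame:
    assigned: dict[int, list[str]] = {}
    offsets: dict[int, list[str]] = {}
    if assignments:
        by_id = {id(a.hit): a.hit for a in assignments}
        for a in assignments:
            assigned.setdefault(id(a.hit), []).append(a.locus_tag)
            offsets.setdefault(id(a.hit), []).append(str(a.offset))
    rows = []
    for h in hits:
        rows.append(
            {
                "pwm_id": h.pwm_id,
                "position": h.position,
                "strand": h.strand,
                "site": h.site,
                "rel_score": round(h.rel_score, 3),
                "group": h.group,
                "locus_tags": ",".join(assigned.get(id(h), [])),
                "offsets": ",".join(offsets.get(id(h), [])),
            }
        )
    return pd.DataFrame(rows, columns=["pwm_id", "position", "strand", "site",
                                       "rel_score", "group", "locus_tags", "offsets"])


# --- skew / replichore ---------------------------------------------------

def write_skew_profile(profile: SkewProfile, path_tsv: str | Path,
                       path_bedgraph: str | Path | None = None,
                       genome_id: str = "genome") -> None:
    df = pd.DataFrame({"window_start": profile.starts, "skew": profile.values,
                       "cumulative": profile.cumulative})
    df.to_csv(path_tsv, sep="\t", index=False, float_format="%.6f")
    if path_bedgraph is not None:
        with open(path_bedgraph, "w") as fh:
            fh.write(f'track type=bedGraph name="{genome_id}_cumulative_gc_skew"\n')
            L = profile.genome_length
            for s, c in zip(profile.starts, profile.cumulative):
                end = min(int(s) + profile.step, L)
                fh.write(f"{genome_id}\t{int(s)}\t{end}\t{c:.6f}\n")


def write_replichore_map(rmap: ReplichoreMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "ori": rmap.ori,
                "ter": rmap.ter,
                "amplitude": rmap.amplitude,
                "confidence": rmap.confidence,
                "low_confidence": rmap.low_confidence,
                "arm_convention": "clockwise = increasing coordinates from ori to ter",
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_replichore_map(path: str | Path) -> ReplichoreMap:
    with open(path) as fh:
        d = json.load(fh)
    return ReplichoreMap(ori=d["ori"], ter=d["ter"], amplitude=d["amplitude"],
                         confidence=d["confidence"], low_confidence=d["low_confidence"])


def positions_table(positions: list[ReplichorePosition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_tag": p.locus_tag,
                "midpoint": p.midpoint,
                "d_ori": p.d_ori,
                "d_ter": p.d_ter,
                "arm": p.arm,
                "fraction": round(p.fraction, 6),
            }
            for p in positions
        ],
        columns=["locus_tag", "midpoint", "d_ori", "d_ter", "arm", "fraction"],
    )


# --- counts / samples ----------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="locus_tag")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus_tag")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


# --- config sidecars ------------------------------------------------------

def write_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
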
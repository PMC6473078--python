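"""End-to-end orchestration: simulate, run, and truth-recovery summary.

A run is driven by a single YAML config whose thresholds (PWM match cut-off,
FDR, fold-change, control delta, promoter window, skew window) are the
scientific surface of the analysis; the fully resolved config and its hash are
echoed into every run directory so an artifact can always be traced back to
the exact settings that produced it. Identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .genome import CircularGenome, GeneAnnotation
from .motif import (PWM, MotifHit, assign_to_promoters, build_pwm,
                    classify_lexa_group, pwm_from_consensus, scan_genome)
from .replichore import (ReplichoreMap, call_ori_ter, circular_distance, gc_skew,
                         replichore_position, symmetric_pairs)
from .synthetic import (ResponderTruth, annotate_genes, generate_counts,
                        generate_genome, plant_sites, truth_tables)
from .timeseries import (CONTROL_TIMES, ExpressionSeries, de_test_all,
                         normalize_libsizes, replicate_correlation,
                         responsive_filter)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """Raised with the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def config_hash(config: dict) -> str:
    """Stable hash of the semantic config (output location excluded)."""
    sem = {k: v for k, v in config.items() if k != "output_dir"}
    blob = yaml.safe_dump(sem, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


DEFAULT_THRESHOLDS = {
    "min_percent": 82.5,
    "fdr_max": 0.05,
    "lfc_min": 1.0,
    "control_delta": 1.0,
    "control_times": [60, 180],
    "promoter_window": [300, 50],
    "skew_window": 1000,
    "skew_step": 500,
    "symmetry_tolerance": 20000,
}


def _resolve_thresholds(config: dict) -> dict:
    th = dict(DEFAULT_THRESHOLDS)
    th.update(config.get("thresholds", {}))
    return th


# --- simulation ------------------------------------------------------------

DEFAULT_SIMULATION = {
    "seed": 1,
    "genome": {"length": 200000, "ori": 0, "ter": 100000,
               "skew_strength": 0.1, "gc_content": 0.6},
    "genes": {"n": 200, "gene_length": 500},
    "sites": {"consensus": "GTTCGAAC", "n_targets": 30, "mutations_per_site": 0,
              "n_pwm_sites": 40, "promoter_window": [300, 50]},
    "counts": {"n_responders": 24, "n_artifacts": 6, "log2fc": 2.0,
               "dispersion": 0.1, "baseline_mean": 200.0, "replicates": 3},
}


def simulate(config: dict, output_dir: str | Path) -> Path:
    """Generate a complete synthetic input set plus truth sidecars.

    Writes genome FASTA, GFF3 annotation, a binding-site collection, the count
    matrix with its sample sheet, truth tables, the echoed generation
    parameters, and a ready-to-use run config (run.yaml).
    """
    cfg = {**DEFAULT_SIMULATION, **config}
    for key in ("genome", "genes", "sites", "counts"):
        cfg[key] = {**DEFAULT_SIMULATION[key], **(config.get(key) or {})}
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    g = cfg["genome"]
    genome, genome_truth = generate_genome(
        length=int(g["length"]), ori=int(g["ori"]), ter=int(g["ter"]),
        skew_strength=float(g["skew_strength"]), gc_content=float(g["gc_content"]),
        seed=seed,
    )
    genes = annotate_genes(genome.length, int(cfg["genes"]["n"]),
                           gene_length=int(cfg["genes"]["gene_length"]), seed=seed + 1)

    s = cfg["sites"]
    targets = genes[: int(s["n_targets"])]
    genome, site_truths = plant_sites(
        genome, str(s["consensus"]), targets,
        promoter_window=tuple(s["promoter_window"]),
        mutations_per_site=int(s["mutations_per_site"]), seed=seed + 2,
    )
    # degenerate site collection for PWM estimation (one substitution per site
    # at a rotating position emulates cross-species binding-site variation)
    rng = np.random.default_rng(seed + 3)
    consensus = str(s["consensus"]).upper()
    collection = []
    for i in range(int(s["n_pwm_sites"])):
        site = list(consensus)
        if i % 2 == 1:  # half the collection carries one off-consensus base
            pos = int(rng.integers(len(site)))
            site[pos] = "ACGT"[int(rng.integers(4))]
        collection.append("".join(site))

    c = cfg["counts"]
    locus_tags = [gn.locus_tag for gn in genes]
    onsets = [10, 20, 40, 60, 120, 180]
    truth: list[ResponderTruth] = []
    n_resp, n_art = int(c["n_responders"]), int(c["n_artifacts"])
    for i, tag in enumerate(locus_tags[:n_resp]):
        sign = 1.0 if i % 3 else -1.0
        truth.append(ResponderTruth(tag, onsets[i % len(onsets)],
                                    sign * float(c["log2fc"]), both_arms=False))
    for i, tag in enumerate(locus_tags[n_resp : n_resp + n_art]):
        truth.append(ResponderTruth(tag, onsets[i % len(onsets)],
                                    float(c["log2fc"]), both_arms=True))
    series, _ = generate_counts(
        locus_tags, truth, dispersion=float(c["dispersion"]),
        baseline_mean=float(c["baseline_mean"]), replicates=int(c["replicates"]),
        seed=seed + 4,
    )

    rio.write_genome_fasta(genome, out / "genome.fasta")
    rio.write_gff3(genes, genome.id, genome.length, out / "annotation.gff3")
    with open(out / "sites.fasta", "w") as fh:
        for i, site in enumerate(collection):
            fh.write(f">site_{i}\n{site}\n")
    rio.write_counts_tsv(series.counts, out / "counts.tsv")
    rio.write_sample_sheet(series.samples, out / "samples.tsv")
    for name, table in truth_tables(genome_truth, site_truths, truth).items():
        table.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)
    rio.write_yaml({"schema_version": SCHEMA_VERSION, **cfg}, out / "params.yaml")

    run_cfg = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "genome": str(out / "genome.fasta"),
        "annotation": str(out / "annotation.gff3"),
        "counts": str(out / "counts.tsv"),
        "samples": str(out / "samples.tsv"),
        "motifs": [
            {"id": "LexA", "sites": str(out / "sites.fasta"),
             "min_percent": 82.5, "classify_groups": True}
        ],
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "score_mode": "minmax",
        "output_dir": str(out / "run"),
    }
    rio.write_yaml(run_cfg, out / "run.yaml")
    return out


# --- run -------------------------------------------------------------------

def _load_motif(entry: dict) -> PWM:
    if "sites" in entry:
        pwm = build_pwm(rio.read_sites_fasta(entry["sites"]),
                        pseudocount=float(entry.get("pseudocount", 0.25)),
                        pwm_id=entry["id"])
    elif "matrix" in entry:
        pwm = rio.read_matrix_tsv(entry["matrix"], pwm_id=entry["id"])
    elif "consensus" in entry:
        pwm = pwm_from_consensus(entry["consensus"], pwm_id=entry["id"])
    else:
        raise ValueError(f"motif entry {entry.get('id')} needs sites, matrix or consensus")
    return pwm


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> pd.DataFrame:
    """Execute scan -> oriter -> positions -> timecourse -> join.

    Returns the annotated gene table; all artifacts are written under the
    output directory. On a stage failure the partial outputs are moved under
    ``failed/`` and a PipelineError naming the stage is raised.
    """
    out = Path(output_dir if output_dir is not None else config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = int(config.get("seed", 0))
    th = _resolve_thresholds(config)
    score_mode = config.get("score_mode", "minmax")
    stage = "setup"
    counts_per_stage: dict[str, int] = {}
    try:
        stage = "inputs"
        genome = rio.read_genome_fasta(config["genome"])
        genes = rio.read_gff3(config["annotation"])

        stage = "scan"
        window = tuple(th["promoter_window"])
        all_hits: dict[str, list[MotifHit]] = {}
        assignments_by_pwm: dict[str, list] = {}
        for entry in config.get("motifs", []):
            pwm = _load_motif(entry)
            hits = scan_genome(genome, pwm,
                               float(entry.get("min_percent", th["min_percent"])),
                               strands="both", score_mode=score_mode)
            assignments = assign_to_promoters(hits, genes, window=window,
                                              L=genome.length, circular=genome.circular)
            if entry.get("classify_groups"):
                for h in hits:
                    h.group = classify_lexa_group(h, pwm)
            all_hits[pwm.id] = hits
            assignments_by_pwm[pwm.id] = assignments
            rio.write_hits_bed(hits, genome.id, out / f"hits_{pwm.id}.bed")
            rio.hits_table(hits, assignments).to_csv(
                out / f"hits_{pwm.id}.tsv", sep="\t", index=False)
            counts_per_stage[f"hits_{pwm.id}"] = len(hits)

        stage = "oriter"
        profile = gc_skew(genome, window=int(th["skew_window"]), step=int(th["skew_step"]))
        rmap = call_ori_ter(profile, seed=seed)
        rio.write_skew_profile(profile, out / "gc_skew.tsv", out / "gc_skew.bedgraph",
                               genome_id=genome.id)
        rio.write_replichore_map(rmap, out / "replichore_map.json")
        counts_per_stage["skew_windows"] = len(profile.values)

        stage = "positions"
        positions = [replichore_position(g, rmap, genome.length) for g in genes]
        pos_table = rio.positions_table(positions)
        pos_table.to_csv(out / "positions.tsv", sep="\t", index=False)
        pairs = symmetric_pairs(positions, anchor="ori",
                                tolerance=int(th["symmetry_tolerance"]))
        pairs.to_csv(out / "symmetric_pairs_ori.tsv", sep="\t", index=False)
        counts_per_stage["genes_positioned"] = len(positions)
        counts_per_stage["symmetric_pairs_ori"] = len(pairs)

        stage = "timecourse"
        counts = rio.read_counts_tsv(config["counts"])
        samples = rio.read_sample_sheet(config["samples"])
        series = ExpressionSeries(counts=counts, samples=samples)
        size_factors = normalize_libsizes(series)
        de = de_test_all(series, size_factors)
        de.to_csv(out / "de_results.tsv", sep="\t", index=False,
                  float_format="%.6g")
        calls = responsive_filter(
            de[de["arm"] == "AHL"], de[de["arm"] == "DMSO"],
            fdr_max=float(th["fdr_max"]), lfc_min=float(th["lfc_min"]),
            control_delta=float(th["control_delta"]),
            control_times=tuple(th["control_times"]),
        )
        calls_out = calls.copy()
        calls_out["onset_min"] = calls_out["onset_min"].map(
            lambda v: "" if pd.isna(v) else int(v))
        calls_out["direction"] = calls_out["direction"].map(
            lambda v: "" if pd.isna(v) else v)
        header = (f"# config_hash={chash} seed={seed} fdr_max={th['fdr_max']} "
                  f"lfc_min={th['lfc_min']} control_delta={th['control_delta']} "
                  f"control_times={','.join(map(str, th['control_times']))}\n")
        with open(out / "response_calls.tsv", "w") as fh:
            fh.write(header)
            calls_out.to_csv(fh, sep="\t", index=False)
        qc = replicate_correlation(series)
        qc.to_csv(out / "replicate_qc.tsv", sep="\t", index=False,
                  float_format="%.6f")
        counts_per_stage["responsive_genes"] = int(calls["responsive"].sum())
        counts_per_stage["control_excluded"] = int(calls["excluded_by_control"].sum())

        stage = "join"
        table = _join_annotated(genes, calls, assignments_by_pwm, positions)
        table.to_csv(out / "annotated_genes.tsv", sep="\t", index=False)
        counts_per_stage["annotated_genes"] = len(table)

        _write_report(out, config, chash, counts_per_stage)
        return table
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for item in list(out.iterdir()):
            if item.name != "failed":
                shutil.move(str(item), str(failed / item.name))
        raise PipelineError(stage, exc) from exc


def _join_annotated(genes, calls, assignments_by_pwm, positions) -> pd.DataFrame:
    pos_by_tag = {p.locus_tag: p for p in positions}
    flags: dict[str, dict[str, bool]] = {}
    groups: dict[str, dict[str, str]] = {}
    for pwm_id, assignments in assignments_by_pwm.items():
        f: dict[str, bool] = {}
        g: dict[str, str] = {}
        for a in assignments:
            f[a.locus_tag] = True
            if a.hit.group in ("GTTC", "GAAC"):
                g.setdefault(a.locus_tag, a.hit.group)
        flags[pwm_id] = f
        groups[pwm_id] = g
    rows = []
    for gene in genes:
        tag = gene.locus_tag
        call = calls.loc[tag] if tag in calls.index else None
        p = pos_by_tag[tag]
        row = {
            "locus_tag": tag,
            "category": "" if call is None else call["category"],
            "responsive": bool(call["responsive"]) if call is not None else False,
            "excluded_by_control": bool(call["excluded_by_control"]) if call is not None else False,
            "onset_min": "" if call is None or pd.isna(call["onset_min"]) else int(call["onset_min"]),
            "direction": "" if call is None or pd.isna(call["direction"]) else call["direction"],
            "fraction": round(p.fraction, 6),
            "d_ori": p.d_ori,
            "d_ter": p.d_ter,
            "arm": p.arm,
        }
        for pwm_id in assignments_by_pwm:
            row[f"has_{pwm_id}_site"] = flags[pwm_id].get(tag, False)
            row[f"{pwm_id}_group"] = groups[pwm_id].get(tag, "")
        rows.append(row)
    return pd.DataFrame(rows)


def _write_report(out: Path, config: dict, chash: str, counts: dict[str, int]) -> None:
    rio.write_yaml({"config_hash": chash, **config}, out / "resolved_config.yaml")
    lines = ["# Run report", "", f"- config hash: `{chash}`",
             f"- seed: {config.get('seed', 0)}",
             "- arm convention: clockwise = increasing coordinates from ori to ter", ""]
    lines.append("| stage record | count |")
    lines.append("|---|---|")
    for k, v in counts.items():
        lines.append(f"| {k} | {v} |")
    (out / "report.md").write_text("\n".join(lines) + "\n")


# --- truth recovery ---------------------------------------------------------

def summarize_truth_recovery(run_dir: str | Path, truth_dir: str | Path) -> dict:
    """Compare a synthetic run's outputs against the generator's truth tables.

    Returns a JSON-ready dict of scalar metrics, each with a definition string.
    """
    run, truth = Path(run_dir), Path(truth_dir)
    metrics: dict[str, dict] = {}

    gt = pd.read_csv(truth / "truth_genome.tsv", sep="\t").iloc[0]
    L = None
    genome_fa = truth / "genome.fasta"
    if genome_fa.exists():
        L = rio.read_genome_fasta(genome_fa).length
    rmap = rio.read_replichore_map(run / "replichore_map.json")
    if L is not None:
        ori_err = circular_distance(int(rmap.ori), int(gt["ori_true"]), L)
        ter_err = circular_distance(int(rmap.ter), int(gt["ter_true"]), L)
        metrics["ori_localization_error_bp"] = {
            "value": int(ori_err),
            "definition": "circular distance between called and planted ori (bp)",
        }
        metrics["ter_localization_error_bp"] = {
            "value": int(ter_err),
            "definition": "circular distance between called and planted ter (bp)",
        }

    sites = pd.read_csv(truth / "truth_sites.tsv", sep="\t")
    hit_files = sorted(run.glob("hits_*.tsv"))
    if len(sites) and hit_files:
        hits = pd.concat([pd.read_csv(f, sep="\t") for f in hit_files])
        hit_positions = set(hits["position"])
        recovered = sites["position"].isin(hit_positions)
        metrics["site_recovery_rate"] = {
            "value": float(recovered.mean()),
            "definition": "fraction of planted sites with a scan hit at the planted start",
        }
        assigned_tags = set()
        for tags in hits["locus_tags"].dropna():
            assigned_tags.update(str(tags).split(","))
        promoter_hit = sites["locus_tag"].isin(assigned_tags)
        metrics["promoter_assignment_rate"] = {
            "value": float(promoter_hit.mean()),
            "definition": "fraction of planted sites whose target gene received a promoter assignment",
        }

    resp_truth = pd.read_csv(truth / "truth_responders.tsv", sep="\t")
    calls = pd.read_csv(run / "response_calls.tsv", sep="\t", comment="#")
    merged = calls.merge(resp_truth, on="locus_tag", how="left")
    merged["onset_true"] = merged["onset_min_y"].fillna(-1)
    both_arms = merged["both_arms"].map(lambda v: bool(v) if pd.notna(v) else False)
    is_responder = (merged["onset_true"] >= 0) & ~both_arms
    is_artifact = both_arms
    is_null = ~is_responder & ~is_artifact
    called = merged["responsive"].astype(bool)

    if is_responder.any():
        detected = called & is_responder
        metrics["timecourse_sensitivity"] = {
            "value": float(detected.sum() / is_responder.sum()),
            "definition": "fraction of planted AHL-only responders called responsive",
        }
        det = merged[detected]
        onset_ok = det["onset_min_x"].astype(float) == det["onset_true"].astype(float)
        metrics["onset_accuracy"] = {
            "value": float(onset_ok.mean()) if len(det) else float("nan"),
            "definition": "fraction of detected responders assigned their planted onset time",
        }
    if is_null.any():
        metrics["false_call_rate"] = {
            "value": float((called & is_null).sum() / is_null.sum()),
            "definition": "fraction of null genes called responsive",
        }
    if is_artifact.any():
        excluded = merged["excluded_by_control"].astype(bool)
        metrics["artifact_exclusion_rate"] = {
            "value": float((excluded & is_artifact).sum() / is_artifact.sum()),
            "definition": "fraction of planted both-arms artifact genes flagged excluded_by_control",
        }
    return metrics


def write_recovery_json(metrics: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2)
        fh.write("\n")
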
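"""End-to-end orchestration: run every analysis stage from one config.

A run config is a flat YAML mapping with one section per stage
(``conservation``, ``codon_usage``, ``synteny``, ``utr``); a stage runs iff
its section is present and its ``enabled`` flag (default true) is set. Every
stage writes TSV tables with ``#``-prefixed metadata headers into the output
directory, and :func:`run_all` writes a ``manifest.json`` recording inputs,
thresholds, seed and package version, so every table cell can be reproduced
by calling the underlying module function with the manifest's parameters.

:func:`write_dataset` emits a complete synthetic input bundle (ortholog
FASTAs, 3'UTRs, two annotated genomes, program gene sets, a genome-wide
codon table, planted truth) together with a ready-to-run config file.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import codon_align, global_align, identity_gap_excluded
from .codon_usage import (
    benchmark_gene,
    codon_counts,
    group_profile,
    profile_correlation,
    profile_from_counts,
)
from .conservation import (
    classify_sites,
    conservation_table,
    conserved_report,
    distance_matrix,
    gc3,
)
from .io import (
    read_bed_genes,
    read_codon_table,
    read_fasta,
    read_gene_list,
    write_codon_alignment_fasta,
    write_codon_table,
    write_bed_genes,
    write_fasta,
    write_gene_list,
    write_phylip,
    write_tsv,
)
from .synteny import (
    SyntenyThresholds,
    matches_table,
    neighborhood,
    score_neighborhoods,
    synteny_count_ratio,
)
from .synthetic import (
    PlantedTruth,
    SimulationConfig,
    evolve_utr,
    random_utr,
    sample_program_gene_sets,
    simulate_family,
    simulate_neighborhoods,
    _rng,
)
from .alignment import utr3_similarity

__all__ = ["run_all", "write_dataset", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sequence_species(seq_id: str) -> str:
    """Species label of a sequence id of the form ``<paralog>_<species>``."""
    return seq_id.split("_", 1)[1] if "_" in seq_id else seq_id


def _subset_by_group(sequences: Mapping[str, str], species: Sequence[str]) -> list[tuple[str, str]]:
    wanted = set(species)
    return [
        (sid, seq)
        for sid, seq in sequences.items()
        if sid in wanted or _sequence_species(sid) in wanted
    ]


def _run_conservation(cfg: Mapping[str, Any], outdir: Path) -> dict[str, Any]:
    paralogs = {
        name: read_fasta(path) for name, path in cfg["paralog_fastas"].items()
    }
    groups: Mapping[str, Sequence[str]] = cfg.get("species_groups", {})
    out: dict[str, Any] = {"tables": []}

    # pairwise substitution scores within each paralog
    long_tables = []
    for name, seqs in paralogs.items():
        dm = distance_matrix(list(seqs.items()))
        long_tables.append(dm.to_long(group=name))
    distances = pd.concat(long_tables, ignore_index=True)
    write_tsv(distances, outdir / "pairwise_distances.tsv",
              {"stage": "conservation", "statistic": "substitution_score"})
    out["tables"].append("pairwise_distances.tsv")

    # neighboring-gene conservation control, when neighbor panels are given
    if cfg.get("neighbor_fastas"):
        rows = []
        for name, paths in cfg["neighbor_fastas"].items():
            for path in paths:
                seqs = read_fasta(path)
                if len(seqs) < 2:
                    continue
                dm = distance_matrix(list(seqs.items()))
                t = dm.to_long(group=f"{name}_neighbors")
                t["source"] = Path(path).name
                rows.append(t)
        if rows:
            write_tsv(pd.concat(rows, ignore_index=True),
                      outdir / "neighbor_distances.tsv",
                      {"stage": "conservation", "control": "neighboring genes"})
            out["tables"].append("neighbor_distances.tsv")

    # conserved-site reports per species group x site class
    names = sorted(paralogs)
    if len(names) >= 2 and groups:
        a_name, b_name = names[0], names[1]
        paired = []
        for group, species in groups.items():
            sub_a = _subset_by_group(paralogs[a_name], species)
            sub_b = _subset_by_group(paralogs[b_name], species)
            if len(sub_a) < 2 or len(sub_b) < 2:
                warnings.warn(f"group {group!r}: fewer than 2 sequences; skipped")
                continue
            aln_a, aln_b = codon_align(sub_a), codon_align(sub_b)
            for site_class in ("third_position", "fourfold"):
                paired.append(
                    (
                        conserved_report(aln_a, site_class, group),
                        conserved_report(aln_b, site_class, group),
                    )
                )
        table = conservation_table(paired)
        write_tsv(table, outdir / "conservation_report.tsv",
                  {"stage": "conservation", "paralog_a": a_name,
                   "paralog_b": b_name})
        out["tables"].append("conservation_report.tsv")

    # GC3 per sequence (composition analog)
    gc3_rows = [
        {"paralog": name, "seq_id": sid, "gc3": gc3(seq)}
        for name, seqs in paralogs.items()
        for sid, seq in seqs.items()
    ]
    write_tsv(pd.DataFrame(gc3_rows), outdir / "gc3.tsv",
              {"stage": "conservation"})
    out["tables"].append("gc3.tsv")

    # all-vs-all CDS similarity across paralogs
    all_seqs = {
        f"{name}:{sid}": seq
        for name, seqs in paralogs.items()
        for sid, seq in seqs.items()
    }
    ids = list(all_seqs)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ident = identity_gap_excluded(global_align(all_seqs[a], all_seqs[b]))
            rows.append({"id_a": a, "id_b": b, "identity": ident})
    write_tsv(pd.DataFrame(rows), outdir / "cds_similarity.tsv",
              {"stage": "conservation", "statistic": "gap-excluded identity"})
    out["tables"].append("cds_similarity.tsv")

    # alignment export for external tree building
    for name, seqs in paralogs.items():
        if len(seqs) >= 2:
            aln = codon_align(list(seqs.items()))
            write_codon_alignment_fasta(aln, outdir / f"alignment_{name}.fasta")
            write_phylip(aln, outdir / f"alignment_{name}.phy")
    return out


def _run_codon_usage(cfg: Mapping[str, Any], outdir: Path) -> dict[str, Any]:
    metric = cfg.get("metric", "aa_specific")
    genes = read_fasta(cfg["genes_fasta"])
    genomewide = (
        read_codon_table(cfg["genome_table"], metric)
        if cfg.get("genome_table")
        else None
    )

    program_counts: dict[str, list[Counter]] = {}
    for name, paths in (cfg.get("gene_sets") or {}).items():
        ids = read_gene_list(paths["list"])
        fasta = read_fasta(paths["fasta"])
        missing = [i for i in ids if i not in fasta]
        if missing:
            warnings.warn(f"gene set {name!r}: {len(missing)} ids missing from FASTA")
        program_counts[name] = [
            codon_counts(fasta[i]) for i in ids if i in fasta
        ]

    rows = []
    bench_rows = []
    for gid, cds in genes.items():
        counts = codon_counts(cds)
        prof = profile_from_counts(counts, metric, source=gid)
        if genomewide is not None:
            res = profile_correlation(prof, genomewide)
            rows.append({"gene": gid, "reference_profile": "genome-wide",
                         "metric": metric, "r": res.r, "n_codons": res.n_codons})
        for name, members in program_counts.items():
            gp = group_profile(members, metric, source=name)
            res = profile_correlation(prof, gp)
            rows.append({"gene": gid, "reference_profile": name,
                         "metric": metric, "r": res.r, "n_codons": res.n_codons})
        if len(program_counts) >= 2:
            bench = benchmark_gene(
                counts, program_counts, genomewide,
                metric=metric, gene_id=gid, compute_benchmarks=True,
            )
            row = {"gene": gid, "assignment": bench.assignment,
                   "ambiguous": bench.ambiguous,
                   "r_genomewide": bench.r_genomewide}
            for name in program_counts:
                row[f"r_{name}"] = bench.r_by_program[name]
                row[f"percentile_{name}"] = bench.percentile_by_program[name]
                row[f"benchmark_own_median_{name}"] = float(
                    np.median(bench.benchmark_own[name])
                )
                row[f"benchmark_opposite_mean_{name}"] = float(
                    np.mean(bench.benchmark_opposite[name])
                )
            bench_rows.append(row)

    write_tsv(pd.DataFrame(rows), outdir / "codon_usage_correlations.tsv",
              {"stage": "codon_usage", "metric": metric})
    tables = ["codon_usage_correlations.tsv"]

    # per-set calibration against the genome-wide profile: the mean
    # correlation of a set's member genes (e.g. a ubiquitously-expressed
    # gene list) is the reference line focal genes are compared to
    if genomewide is not None and program_counts:
        calib_rows = []
        for name, members in program_counts.items():
            member_rs = []
            for member in members:
                prof = profile_from_counts(member, metric)
                member_rs.append(profile_correlation(prof, genomewide).r)
            calib_rows.append({
                "gene_set": name,
                "mean_r_genomewide": float(np.mean(member_rs)),
                "n_genes": len(member_rs),
            })
        write_tsv(pd.DataFrame(calib_rows),
                  outdir / "gene_set_calibration.tsv",
                  {"stage": "codon_usage", "metric": metric})
        tables.append("gene_set_calibration.tsv")
    if bench_rows:
        write_tsv(pd.DataFrame(bench_rows), outdir / "program_benchmark.tsv",
                  {"stage": "codon_usage", "metric": metric})
        tables.append("program_benchmark.tsv")

    # per-gene profile table (61 codon columns + metadata)
    prof_rows = []
    for gid, cds in genes.items():
        series = profile_from_counts(codon_counts(cds), metric, source=gid).to_series()
        series["gene"] = gid
        prof_rows.append(series)
    profile_df = pd.DataFrame(prof_rows).set_index("gene").reset_index()
    write_tsv(profile_df, outdir / "codon_usage_profiles.tsv",
              {"stage": "codon_usage", "metric": metric})
    tables.append("codon_usage_profiles.tsv")
    return {"tables": tables}


def _run_synteny(cfg: Mapping[str, Any], outdir: Path) -> dict[str, Any]:
    thr = SyntenyThresholds(**cfg.get("thresholds", {}))
    n_genes = int(cfg.get("n_genes", 30))
    window_bp = int(cfg.get("window_bp", 1_500_000))

    def load(section: Mapping[str, Any]):
        genes = read_bed_genes(section["bed"], section["fasta"])
        return neighborhood(genes, section["focal"], n_genes, window_bp)

    tables = []
    counts = {}
    comparisons = cfg.get("comparisons") or [
        {"name": "query_vs_reference", "query": cfg["query"],
         "reference": cfg["reference"]}
    ]
    for comp in comparisons:
        q = load(comp["query"])
        r = load(comp["reference"])
        matches = score_neighborhoods(q, r, thr)
        name = comp.get("name", f"{q.focal.gene_id}_vs_{r.focal.gene_id}")
        fname = f"synteny_{name}.tsv"
        write_tsv(matches_table(matches), outdir / fname,
                  {"stage": "synteny",
                   "protein_identity_threshold": thr.protein_identity,
                   "cds_identity_threshold": thr.cds_identity,
                   "min_protein_coverage": thr.min_protein_coverage,
                   "n_genes": n_genes, "window_bp": window_bp})
        tables.append(fname)
        counts[name] = sum(1 for m in matches if m.is_syntenic)
    return {"tables": tables, "syntenic_counts": counts}


def _run_utr(cfg: Mapping[str, Any], outdir: Path) -> dict[str, Any]:
    utrs_a = read_fasta(cfg["fasta_a"])
    utrs_b = read_fasta(cfg["fasta_b"])
    rows = []
    for ida, ua in utrs_a.items():
        for idb, ub in utrs_b.items():
            rows.append(
                {"id_a": ida, "id_b": idb,
                 "identity": utr3_similarity(ua, ub)}
            )
    write_tsv(pd.DataFrame(rows), outdir / "utr_identity.tsv",
              {"stage": "utr", "statistic": "gap-excluded identity"})
    return {"tables": ["utr_identity.tsv"]}


_STAGES = {
    "conservation": _run_conservation,
    "codon_usage": _run_codon_usage,
    "synteny": _run_synteny,
    "utr": _run_utr,
}


def run_all(config: Mapping[str, Any], outdir: str | Path | None = None) -> dict[str, Any]:
    """Run every enabled stage of a run config; returns the manifest.

    A failing stage aborts the run with a :class:`StageError` naming the
    stage; tables written by earlier stages are listed in the partial
    manifest inside the error.
    """
    out = Path(outdir if outdir is not None else config.get("outdir", "."))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "synsel",
        "version": __version__,
        "seed": config.get("seed"),
        "stages": {},
    }
    for stage, runner in _STAGES.items():
        section = config.get(stage)
        if not section or not section.get("enabled", True):
            continue
        try:
            result = runner(section, out)
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "config": {k: v for k, v in section.items()},
            **result,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def write_dataset(config: SimulationConfig, outdir: str | Path) -> Path:
    """Write a complete synthetic input bundle plus a runnable config file.

    Emits ortholog CDS FASTAs per paralog, per-tip 3'UTR FASTAs, two
    annotated genomes (BED + CDS FASTA) with planted orthologs, program
    gene sets (FASTA + id lists), a Kazusa-style genome-wide codon table,
    the planted-truth JSON, and ``config.yaml`` wired to all of it.
    Returns the path of the config file.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    families, truth = simulate_family(config)
    for paralog, tips in families.items():
        write_fasta(dict(tips), out / f"family_{paralog}.fasta")

    # 3'UTRs: one ancestral UTR per paralog, diverged per tip
    up = config.utr
    for paralog in families:
        anc = random_utr(_rng(config.seed, "utr", paralog, "anc"), up.length)
        utrs = {}
        for tip_id, _ in families[paralog]:
            utrs[tip_id] = evolve_utr(
                anc, up.sub_rate, up.indel_rate, up.mean_indel_len,
                _rng(config.seed, "utr", tip_id), truth, tip_id,
            )
        write_fasta(utrs, out / f"utr_{paralog}.fasta")

    genome_a, genome_b, nb_truth = simulate_neighborhoods(config)
    truth.ortholog_pairs.update(nb_truth.ortholog_pairs)
    write_bed_genes(genome_a, out / "genomeA.bed", out / "genomeA.fasta")
    write_bed_genes(genome_b, out / "genomeB.bed", out / "genomeB.fasta")

    profiles, gene_cds, genomewide = sample_program_gene_sets(config)
    program_fasta = {}
    for name, genes in gene_cds.items():
        program_fasta.update(dict(genes))
        write_gene_list(
            [gid for gid, _ in genes], out / f"genes_{name}.txt",
            header=f"synthetic {name} program gene set",
        )
    write_fasta(program_fasta, out / "program_genes.fasta")
    write_codon_table(genomewide, out / "codon_table.txt")

    # focal genes for codon-usage analysis: one tip of each paralog family
    focal = {tips[0][0]: tips[0][1] for tips in families.values()}
    write_fasta(focal, out / "focal_genes.fasta")

    truth.to_json(out / "truth.json")

    tips = [f"sp{i + 1}" for i in range(config.n_tips)]
    groups = {
        "narrow": tips[: max(2, config.n_tips // 3)],
        "intermediate": tips[: max(3, (2 * config.n_tips) // 3)],
        "full": tips,
    }
    paralogs = sorted(families)
    run_config = {
        "seed": config.seed,
        "outdir": str(out / "results"),
        "conservation": {
            "paralog_fastas": {
                p: str(out / f"family_{p}.fasta") for p in paralogs
            },
            "species_groups": groups,
        },
        "codon_usage": {
            "genes_fasta": str(out / "focal_genes.fasta"),
            "genome_table": str(out / "codon_table.txt"),
            "metric": "aa_specific",
            "gene_sets": {
                name: {
                    "list": str(out / f"genes_{name}.txt"),
                    "fasta": str(out / "program_genes.fasta"),
                }
                for name in gene_cds
            },
        },
        "synteny": {
            "query": {"bed": str(out / "genomeA.bed"),
                      "fasta": str(out / "genomeA.fasta"),
                      "focal": "A_focal"},
            "reference": {"bed": str(out / "genomeB.bed"),
                          "fasta": str(out / "genomeB.fasta"),
                          "focal": "B_focal"},
        },
        "utr": {
            "fasta_a": str(out / f"utr_{paralogs[0]}.fasta"),
            "fasta_b": str(out / f"utr_{paralogs[-1]}.fasta"),
        },
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(run_config, sort_keys=False))
    return config_path
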
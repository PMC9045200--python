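"""End-to-end orchestration: simulate -> map -> quantify -> test -> report.

One root seed drives every stage; identical configurations produce
byte-identical outputs including the final ``report.json`` (keys sorted, no
timestamps or absolute paths inside the report).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from . import diffte, mapping, positional, quantify, simulate
from .io import read_annotation, read_fasta, iter_fastq_sequences, \
    write_annotation, write_bedgraph, write_fasta

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: Path
    sim: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    min_len: int = 20
    max_len: int = 40
    asite_offset: int = 12
    min_cpm: float = 1.0
    fc_cutoff: float = 2.0
    q_cutoff: float = 0.05
    start_window_codons: int = 5
    edge_exclude_codons: int = 5

    @property
    def seed(self) -> int:
        return self.sim.seed


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage under ``config.outdir``; return the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_run_log(outdir)
    log.info("pipeline start: seed=%d outdir=%s", config.seed, outdir.name)

    genome, annotations, truth, manifest = stage_simulate(config)
    counts, cov_by_cond, asites_by_cond, map_summary = stage_map_and_count(
        config, genome, annotations, manifest
    )
    cpm, samples, stats_table, summary = stage_differential(
        config, counts, outdir
    )
    pos_report = stage_positional(config, genome, annotations, cov_by_cond,
                                  outdir)
    report = _build_report(config, annotations, truth, stats_table, summary,
                           pos_report, map_summary)
    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n"
    )
    log.info("pipeline done")
    return report


def _setup_run_log(outdir: Path) -> None:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("ribotide")
    root.setLevel(logging.INFO)
    # replace any previous run's file handler
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
    root.addHandler(handler)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig):
    outdir = Path(config.outdir) / "sim"
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotations, truth = simulate.generate_genome(config.sim)
    truth = simulate.plant_effects(
        truth, simulate.default_effect_panel(annotations)
    )
    write_fasta([genome], outdir / "genome.fasta")
    write_annotation(annotations, outdir / "annotation.gff3")
    truth.to_tsv(outdir / "ground_truth.tsv")
    manifest = simulate.simulate_reads(genome, annotations, truth,
                                       config.sim, outdir)
    for name in ("genome.fasta", "annotation.gff3"):
        log.info("simulate: %s md5=%s", name, _md5(outdir / name))
    log.info("simulate: %d samples, config=%s", len(manifest),
             config.sim)
    return genome, annotations, truth, manifest


def stage_map_and_count(config: PipelineConfig, genome, annotations,
                        manifest: pd.DataFrame):
    outdir = Path(config.outdir)
    index = mapping.GenomeIndex([genome])
    lookup = quantify.GeneLookup(annotations, {genome.chrom_id: len(genome)})

    columns: dict[str, dict[str, pd.Series]] = {"rpf": {}, "rna": {}}
    summary_rows = []
    cov_by_cond: dict[str, "object"] = {}
    asites_by_cond: dict[str, list[np.ndarray]] = {}
    pooled = {
        cond: {"pos": [], "plus": []} for cond in simulate.CONDITIONS
    }

    for sample_id, row in manifest.iterrows():
        fastq = outdir / "sim" / row["path"]
        result = mapping.align_sequences_bulk(
            iter_fastq_sequences(fastq), index,
            min_len=config.min_len, max_len=config.max_len,
        )
        if row["assay"] == "rpf":
            pos, ok = mapping.asite_positions(
                result["start"], result["end"], result["strand_plus"],
                offset=config.asite_offset,
            )
            plus = result["strand_plus"][ok]
            counted = quantify.count_asites(lookup, genome.chrom_id, pos, plus)
            pooled[row["condition"]]["pos"].append(pos)
            pooled[row["condition"]]["plus"].append(plus)
        else:
            counted = quantify.count_rna_midpoints(
                lookup, genome.chrom_id, result["start"], result["end"],
                result["strand_plus"],
            )
        columns[row["assay"]][sample_id] = counted.counts
        summary_rows.append(
            {
                "sample_id": sample_id,
                "n_input": result["n_input"],
                "n_length_dropped": result["n_length_dropped"],
                "n_unaligned": result["n_unaligned"],
                "n_ambiguous": result["n_ambiguous"],
                "n_assigned": counted.assigned,
                "n_unassigned_position": counted.unassigned,
                "n_ambiguous_position": counted.ambiguous,
            }
        )
        log.info("map: %s assigned=%d", sample_id, counted.assigned)

    map_summary = pd.DataFrame(summary_rows).set_index("sample_id")
    map_summary.to_csv(outdir / "mapping_summary.tsv", sep="\t")

    for cond in simulate.CONDITIONS:
        pos = np.concatenate(pooled[cond]["pos"])
        plus = np.concatenate(pooled[cond]["plus"])
        track = mapping.coverage_from_arrays(genome.chrom_id, pos, plus,
                                             [genome])
        cov_by_cond[cond] = track
        asites_by_cond[cond] = [pos, plus]
        for strand, tag in (("+", "plus"), ("-", "minus")):
            write_bedgraph(track, outdir / f"rpf_asite_{cond}_{tag}.bedgraph",
                           strand, name=f"rpf_asite_{cond}_{tag}")

    matrices = {}
    for assay_key, assay_name in (("rpf", "RPF"), ("rna", "RNA")):
        sample_ids = [s for s in manifest.index
                      if manifest.loc[s, "assay"] == assay_key]
        samples = manifest.loc[sample_ids, ["condition", "replicate"]]
        matrices[assay_key] = quantify.assemble_count_matrix(
            assay_name, columns[assay_key], samples
        )
        matrices[assay_key].counts.to_csv(
            outdir / f"counts_{assay_key}.tsv", sep="\t"
        )
    return matrices, cov_by_cond, asites_by_cond, map_summary


def stage_differential(config: PipelineConfig, matrices, outdir: Path):
    outdir = Path(outdir)
    cpm = {key: quantify.normalize_cpm(m) for key, m in matrices.items()}
    for key, frame in cpm.items():
        frame.to_csv(outdir / f"cpm_{key}.tsv", sep="\t")
    samples = {key: matrices[key].samples for key in matrices}
    keep = quantify.low_expression_mask(
        cpm["rpf"], cpm["rna"], samples["rpf"], samples["rna"],
        min_cpm=config.min_cpm,
    )
    stats_table, summary = diffte.compute_gene_stats(
        cpm["rpf"].loc[keep],
        cpm["rna"].loc[keep],
        samples["rpf"],
        samples["rna"],
        fc_cutoff=config.fc_cutoff,
        q_cutoff=config.q_cutoff,
    )
    summary["n_genes_prefilter"] = int(len(keep))
    summary["n_genes_filtered_out"] = int((~keep).sum())
    stats_table.to_csv(outdir / "diffte.tsv", sep="\t")
    diffte.scatter_table(stats_table).to_csv(outdir / "scatter.tsv", sep="\t")
    diffte.volcano_table(stats_table, "te").to_csv(
        outdir / "volcano_te.tsv", sep="\t"
    )
    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n"
    )
    log.info("differential: %d genes tested", summary["n_genes"])
    return cpm, samples, stats_table, summary


def stage_positional(config: PipelineConfig, genome, annotations,
                     cov_by_cond, outdir: Path) -> dict:
    outdir = Path(outdir)
    start_stats = positional.start_region_stats(
        cov_by_cond["WT"], cov_by_cond["MUT"], annotations,
        window_codons=config.start_window_codons,
    )
    start_stats.to_csv(outdir / "start_stats.tsv", sep="\t")
    scores = {
        cond: positional.codon_pause_scores(
            cov_by_cond[cond], annotations, genome,
            exclude_edge_codons=config.edge_exclude_codons,
        )
        for cond in ("WT", "MUT")
    }
    pause = positional.pause_ratio_table(scores["WT"], scores["MUT"])
    pause.to_csv(outdir / "codon_occupancy.tsv", sep="\t")
    valid = start_stats["depletion_score"].dropna()
    return {
        "start_stats": start_stats,
        "pause_table": pause,
        "min_depletion_gene": str(valid.idxmin()) if len(valid) else None,
    }


# ---------------------------------------------------------------------------
# report


def _build_report(config: PipelineConfig, annotations, truth, stats_table,
                  summary, pos_report, map_summary) -> dict:
    roles = simulate.panel_gene_ids(annotations)
    start_stats = pos_report["start_stats"]
    pause = pos_report["pause_table"]

    per_gene = {}
    for role, gid in roles.items():
        planted = truth.table.loc[gid]
        entry = {
            "gene_id": gid,
            "planted_mrna_fold": float(planted["mrna_fold"]),
            "planted_te_fold": float(planted["te_fold"]),
            "planted_start_depletion": float(planted["start_depletion"]),
        }
        if gid in stats_table.index:
            row = stats_table.loc[gid]
            entry.update(
                estimated_fc_mrna=float(row["fc_mrna"]),
                estimated_fc_rpf=float(row["fc_rpf"]),
                estimated_fc_te=float(row["fc_te"]),
                q_te=float(row["q_te"]),
                class_te=str(row["class_te"]),
            )
        if gid in start_stats.index:
            entry["depletion_score"] = float(
                start_stats.loc[gid, "depletion_score"]
            )
        per_gene[role] = entry

    # genome-wide recovery of planted log2 TE folds
    common = stats_table.index[stats_table["fc_te"].notna()]
    planted_log2 = np.log2(
        [diffte.signed_to_ratio(truth.table.loc[g, "te_fold"])
         for g in common]
    )
    estimated_log2 = np.log2(
        [diffte.signed_to_ratio(stats_table.loc[g, "fc_te"])
         for g in common]
    )
    if len(common) >= 2 and np.std(planted_log2) > 0:
        pearson_r = float(
            _scipy_stats.pearsonr(planted_log2, estimated_log2).statistic
        )
    else:
        pearson_r = float("nan")

    aga = float(pause.loc["AGA", "pause_ratio"]) if "AGA" in pause.index \
        else float("nan")

    report = {
        "seed": config.seed,
        "parameters": {
            "min_len": config.min_len,
            "max_len": config.max_len,
            "asite_offset": config.asite_offset,
            "min_cpm": config.min_cpm,
            "fc_cutoff": config.fc_cutoff,
            "q_cutoff": config.q_cutoff,
            "start_window_codons": config.start_window_codons,
            "edge_exclude_codons": config.edge_exclude_codons,
            "n_operons": config.sim.n_operons,
            "genes_per_operon": config.sim.genes_per_operon,
            "rpf_depth": config.sim.rpf_depth,
            "rna_depth": config.sim.rna_depth,
            "nb_dispersion": config.sim.nb_dispersion,
            "replicates_per_group": config.sim.replicates_per_group,
        },
        "summary": summary,
        "recovery": {
            "pearson_r_log2_te": pearson_r,
            "n_genes": int(len(common)),
            "panel": per_gene,
        },
        "positional": {
            "min_depletion_gene": pos_report["min_depletion_gene"],
            "aga_pause_ratio": aga,
        },
        "te_down_genes": sorted(
            stats_table.index[stats_table["class_te"] == "down"]
        ),
        "te_up_genes": sorted(
            stats_table.index[stats_table["class_te"] == "up"]
        ),
        "mapping_totals": {
            "n_input": int(map_summary["n_input"].sum()),
            "n_assigned": int(map_summary["n_assigned"].sum()),
            "n_ambiguous": int(map_summary["n_ambiguous"].sum()),
        },
    }
    return report
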
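"""End-to-end synthetic study: simulate -> call -> normalize -> merge ->
annotate -> diff -> profile -> motifscan -> qpcr.

Every stage writes its outputs into the run directory and registers them in
a manifest (row counts + SHA-256 checksums, config echo, per-stage seeds).
The whole run is deterministic given the configured seed; running twice
with the same seed yields checksum-identical manifests.
"""

from __future__ import annotations

import hashlib
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import differential as diff
from . import intervals as iv
from . import io as pio
from . import motifs as mo
from . import profiles as pr
from . import qpcr as qp
from . import simulate as sim
from .config import PipelineConfig
from .islands import bin_tags, call_islands

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "downsample",
    "callpeaks",
    "merge",
    "annotate",
    "differential",
    "profiles",
    "motifscan",
    "qpcr",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _rows(path: Path) -> int:
    with open(path, "rb") as fh:
        return sum(1 for _ in fh)


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.outdir = outdir
        self.data = {"config": config.to_dict(), "seed": config.seed, "stages": {}}

    def add(self, stage: str, *paths: Path, checksum: bool = True) -> None:
        files = self.data["stages"].setdefault(stage, {"files": {}})["files"]
        for p in paths:
            entry = {"rows": _rows(p)}
            if checksum:
                entry["sha256"] = _sha256(p)
            files[p.name] = entry

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        pio.write_json(self.data, path)
        return path


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic study; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    cfg_s, cfg_i = config.simulation, config.islands
    cfg_a, cfg_d = config.annotation, config.differential
    cfg_p, cfg_m = config.profiles, config.motifs
    seed = config.seed
    t0 = time.time()

    # ---- simulate ----------------------------------------------------
    layout, genes, seqs = sim.simulate_genome(
        cfg_s.n_chroms, cfg_s.chrom_length, cfg_s.n_genes, seed,
        gene_length_range=tuple(cfg_s.gene_length_range),
    )
    truth = sim.make_truth(
        genes, seed, cfg_s.n_enriched, cfg_s.base_fold,
        cfg_s.n_diff_up, cfg_s.n_diff_down, cfg_s.diff_fold,
        spotlight_fold=cfg_s.spotlight_fold,
        n_weak=cfg_s.n_weak, weak_fold=cfg_s.weak_fold,
        fold_spread=cfg_s.fold_spread,
        background_rate=cfg_s.depth / (cfg_s.n_chroms * cfg_s.chrom_length)
        * cfg_i.bin_size,
    )
    motif_lib = mo.load_pfm_library(mo.BUILTIN_MOTIFS_PFM)
    gene_by_id = {g.gene_id: g for g in genes}
    promoter_ivs = [
        (gene_by_id[gid].chrom, *gene_by_id[gid].promoter(1000))
        for gid in sorted(truth.enriched_genes)
    ]
    for m in motif_lib:
        truth.planted_motif_sites.extend(
            sim.plant_motif_sites(
                seqs, promoter_ivs, m.consensus, m.motif_id,
                cfg_m.mean_planted_sites, seed,
            )
        )
    samples = sim.simulate_tags(
        layout, genes, truth, cfg_s.n_samples_per_group, cfg_s.depth, cfg_s.sigma
    )
    qpcr_table = sim.simulate_qpcr(replicates=cfg_s.qpcr_replicates, seed=seed)

    pio.write_chrom_sizes(layout, outdir / "chrom.sizes")
    pio.write_fasta(seqs, outdir / "genome.fa")
    pio.write_genes_bed12(genes, outdir / "genes.bed")
    pio.write_json(truth.to_dict(), outdir / "truth.json")
    (outdir / "motifs.pfm").write_text(mo.BUILTIN_MOTIFS_PFM)
    pio.write_tsv(qpcr_table, outdir / "qpcr.tsv")
    tag_files = []
    for ts in samples:
        p = outdir / f"tags_{ts.sample_id}.bed"
        pio.write_tags_bed(ts, p)
        tag_files.append(p)
    manifest.add(
        "simulate", outdir / "chrom.sizes", outdir / "genome.fa",
        outdir / "genes.bed", outdir / "truth.json", outdir / "motifs.pfm",
        outdir / "qpcr.tsv", *tag_files,
    )
    log.info("simulate: %d genes, %d samples (%.1fs)", len(genes), len(samples),
             time.time() - t0)

    # ---- normalize (downsample to smallest library) ------------------
    normed = iv.downsample_tags(samples, seed)
    norm_files = []
    for ts in normed:
        p = outdir / f"tags_norm_{ts.sample_id}.bed"
        pio.write_tags_bed(ts, p)
        norm_files.append(p)
    manifest.add("downsample", *norm_files)

    # ---- island calling ----------------------------------------------
    per_sample_islands = {}
    island_files = []
    for ts in normed:
        cov = bin_tags(ts, layout, cfg_i.bin_size)  # density track
        score_cov = bin_tags(ts, layout, cfg_i.window)  # scoring grid
        isl = call_islands(score_cov, cfg_i.window, cfg_i.gap, cfg_i.window_p,
                           cfg_i.fdr_cutoff)
        per_sample_islands[ts.sample_id] = isl
        bed = outdir / f"islands_{ts.sample_id}.bed"
        tsv = outdir / f"islands_{ts.sample_id}.tsv"
        bg = outdir / f"coverage_{ts.sample_id}.bedgraph"
        pio.write_islands(isl, bed, tsv)
        pio.write_bedgraph(cov, bg)
        island_files += [bed, tsv, bg]
    manifest.add("callpeaks", *island_files)
    groups = {ts.sample_id: ts.group for ts in normed}

    # ---- merged regions / venn / per-chromosome / overlap QC ---------
    regions = iv.merge_regions(per_sample_islands, groups)
    venn = iv.group_venn(regions)
    per_chrom = iv.per_chromosome_counts(regions)
    sids = sorted(per_sample_islands)
    ov = pd.DataFrame(
        [
            {
                "sample_a": a, "sample_b": b,
                "overlap_fraction": iv.pairwise_overlap_fraction(
                    per_sample_islands[a], per_sample_islands[b]),
            }
            for a in sids for b in sids if a != b
        ]
    )
    pio.write_tsv(
        pd.DataFrame(
            [{"chrom": r.chrom, "start": r.start, "end": r.end,
              "name": r.region_id, "score": 0, "strand": "."} for r in regions]
        ),
        outdir / "merged_regions.bed",
    )
    presence = diff.presence_matrix(regions) if regions else pd.DataFrame()
    pio.write_tsv(presence.reset_index(names="region_id"), outdir / "presence.tsv")
    pio.write_tsv(pd.DataFrame([venn]), outdir / "venn.tsv")
    pio.write_tsv(per_chrom.rename("n_regions").rename_axis("chrom").reset_index(),
                  outdir / "per_chromosome.tsv")
    pio.write_tsv(ov, outdir / "pairwise_overlap.tsv")
    manifest.add("merge", outdir / "merged_regions.bed", outdir / "presence.tsv",
                 outdir / "venn.tsv", outdir / "per_chromosome.tsv",
                 outdir / "pairwise_overlap.tsv")

    # ---- annotation ---------------------------------------------------
    annotations = ann.annotate_regions(
        regions, genes, proximal=cfg_a.proximal_bp, distal=cfg_a.distal_bp,
        utr_fraction=cfg_a.utr_fraction,
    )
    ann_df = pd.DataFrame(
        [
            {"region_id": f"{a.region[0]}:{a.region[1]}-{a.region[2]}",
             "category": a.category,
             "gene_id": a.gene_id if a.gene_id else ".",
             "tss_distance": a.tss_distance if a.tss_distance is not None else "."}
            for a in annotations
        ]
    )
    pie = ann.feature_pie(annotations) if annotations else {}
    controls = ann.random_control_peaks(regions, layout, seed) if regions else []
    control_pie = (
        ann.feature_pie(ann.annotate_regions(controls, genes,
                                             proximal=cfg_a.proximal_bp,
                                             distal=cfg_a.distal_bp,
                                             utr_fraction=cfg_a.utr_fraction))
        if controls else {}
    )
    pie_df = pd.DataFrame(
        {"category": list(ann.CATEGORIES),
         "fraction": [pie.get(c, 0.0) for c in ann.CATEGORIES],
         "random_control_fraction": [control_pie.get(c, 0.0) for c in ann.CATEGORIES]}
    )
    pio.write_tsv(ann_df, outdir / "annotations.tsv")
    pio.write_tsv(pie_df, outdir / "feature_pie.tsv")
    manifest.add("annotate", outdir / "annotations.tsv", outdir / "feature_pie.tsv")

    # ---- differential -------------------------------------------------
    diff_tables = {}
    for window in ("promoter", "gene_body"):
        dens = diff.density_matrix(normed, genes, window, cfg_d.promoter_half)
        table = diff.differential_call(
            dens, groups, cfg_d.fc_cutoff, cfg_d.alpha, cfg_d.pseudo
        )
        diff_tables[window] = table
        pio.write_tsv(table, outdir / f"differential_{window}.tsv")
    manifest.add("differential", outdir / "differential_promoter.tsv",
                 outdir / "differential_gene_body.tsv")

    # ---- profiles ------------------------------------------------------
    by_group = {g: [ts for ts in normed if ts.group == g] for g in sorted(set(groups.values()))}
    profile_files = []
    region_group_means = {}
    for gname, members in by_group.items():
        for anchor_set, anchors, flank in (
            ("gene_body", genes, cfg_p.gene_flank),
            ("merged_region", regions, cfg_p.region_flank),
            ("promoter", genes, cfg_p.promoter_flank),
        ):
            if not len(anchors):
                continue
            pm = pr.build_profile(members, anchors, anchor_set, flank,
                                  cfg_p.bin_size, cfg_p.meta_length)
            pm.cluster_labels = pr.cluster_profiles(pm.matrix, cfg_p.k, seed)
            mat = pd.DataFrame(pm.matrix, index=pm.row_ids)
            mat.insert(0, "cluster", pm.cluster_labels)
            mpath = outdir / f"profile_{anchor_set}_{gname}.tsv"
            pio.write_tsv(mat.reset_index(names="anchor"), mpath)
            avg = pr.average_plot(pm.matrix)
            apath = outdir / f"average_{anchor_set}_{gname}.tsv"
            pio.write_tsv(pd.DataFrame({"bin": range(len(avg)), "mean": avg}), apath)
            profile_files += [mpath, apath]
            if anchor_set == "merged_region":
                region_group_means[gname] = pm.matrix.mean(axis=1)
            if cfg_p.make_plots:
                pr.save_average_plot(avg, outdir / f"average_{anchor_set}_{gname}.png",
                                     f"{anchor_set} ({gname})", cfg_p.bin_size)
    if len(region_group_means) == 2 and len(regions) >= 3:
        (ga, a_means), (gb, b_means) = sorted(region_group_means.items())
        r, slope = pr.group_scatter_qc(a_means, b_means)
        qc = pd.DataFrame([{"group_x": ga, "group_y": gb,
                            "pearson_r": r, "ols_slope": slope,
                            "n_regions": len(regions)}])
    else:
        qc = pd.DataFrame(columns=["group_x", "group_y", "pearson_r", "ols_slope",
                                   "n_regions"])
    pio.write_tsv(qc, outdir / "scatter_qc.tsv")
    profile_files.append(outdir / "scatter_qc.tsv")
    manifest.add("profiles", *profile_files)

    # ---- motif scan ----------------------------------------------------
    if regions:
        summaries = mo.motif_frequency_table(regions, seqs, motif_lib,
                                             cfg_m.flank, cfg_m.cutoff)
        pio.write_tsv(mo.summary_frame(summaries), outdir / "motif_summary.tsv")
        hits = mo.scan_hits_bed(regions, seqs, motif_lib, cfg_m.flank, cfg_m.cutoff)
        pio.write_tsv(hits, outdir / "motif_hits.bed")
        manifest.add("motifscan", outdir / "motif_summary.tsv",
                     outdir / "motif_hits.bed")

    # ---- qPCR ----------------------------------------------------------
    enr = qp.enrichment_table(qpcr_table)
    pio.write_tsv(enr, outdir / "qpcr_enrichment.tsv")
    anova_rows, pair_frames = [], []
    for antibody, sub in enr[enr["target"] == "GAPDH"].groupby("antibody"):
        f_stat, p_val, pairs = qp.stability_anova(sub)
        anova_rows.append({"antibody": antibody, "F": f_stat, "p": p_val})
        pairs.insert(0, "antibody", antibody)
        pair_frames.append(pairs)
    pio.write_tsv(pd.DataFrame(anova_rows), outdir / "qpcr_anova.tsv")
    pio.write_tsv(pd.concat(pair_frames, ignore_index=True),
                  outdir / "qpcr_posthoc.tsv")
    slopes = qp.decay_slope(enr[enr["target"] == "GAPDH"])
    pio.write_tsv(slopes, outdir / "qpcr_slopes.tsv")
    manifest.add("qpcr", outdir / "qpcr_enrichment.tsv", outdir / "qpcr_anova.tsv",
                 outdir / "qpcr_posthoc.tsv", outdir / "qpcr_slopes.tsv")

    path = manifest.write()
    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, path)
    return manifest.data


def evaluate_against_truth(outdir) -> dict:
    """Planted-truth recovery metrics computed from a finished run directory.

    Reads truth.json and the differential / island outputs and reports
    differential sensitivity, the null pass rate among non-planted genes,
    and the recovered fold of the single spotlight gene.
    """
    import json

    outdir = Path(outdir)
    truth = sim.SimulationTruth.from_dict(json.loads((outdir / "truth.json").read_text()))
    table = pd.read_csv(outdir / "differential_promoter.tsv", sep="\t")
    table = table.set_index("target_id")
    planted = sorted(truth.differential_genes)
    non_planted = [t for t in table.index if t not in truth.differential_genes]
    sens = float(table.loc[planted, "passes_filter"].mean()) if planted else math.nan
    null_rate = float(table.loc[non_planted, "passes_filter"].mean())
    out = {
        "differential_sensitivity": sens,
        "differential_null_pass_rate": null_rate,
        "n_planted": len(planted),
        "n_null": len(non_planted),
    }
    spot = None
    for gid in sorted(truth.enriched_genes):
        folds = truth.enriched_genes[gid]
        r = folds["B"] / folds["A"]
        if gid not in truth.differential_genes and not math.isclose(r, 1.0):
            spot = (gid, r)
            break
    if spot is not None:
        out["spotlight_gene"] = spot[0]
        out["spotlight_planted_fold"] = spot[1]
        out["spotlight_recovered_fold"] = float(table.loc[spot[0], "ratio"])
    return out
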
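"""End-to-end orchestration: chain the analysis stages over files on disk.

Each stage reads the standard-format inputs, runs the corresponding
module, and writes TSV result tables; a JSON manifest records versions,
thresholds and the seed so a run is auditable and reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import ase as ase_mod
from . import de as de_mod
from . import enrichment as enr_mod
from . import io as eio
from . import lncrna as lnc_mod
from . import qpcr as qpcr_mod
from . import splicing as spl_mod
from .models import PipelineError, TranscriptRecord

log = logging.getLogger("emboliseq.pipeline")


@dataclass
class PipelineConfig:
    """Input paths, output directory, and the decision thresholds."""

    outdir: str
    counts: str
    design: str
    gtf: Optional[str] = None
    genome: Optional[str] = None
    junctions: Optional[str] = None
    vcf: Optional[str] = None
    transcripts: Optional[str] = None
    homology: Optional[str] = None
    annotation_map: Optional[str] = None
    cq: Optional[str] = None
    qpcr_targets: Optional[list[str]] = None
    qpcr_references: list[str] = field(default_factory=lambda: ["ACTB", "GAPDH"])
    seed: int = 0

    deg_padj: float = de_mod.DEG_PADJ_THRESHOLD
    das_padj: float = spl_mod.DAS_PADJ_THRESHOLD
    das_dpsi: float = spl_mod.DAS_DPSI_THRESHOLD
    daaf: float = ase_mod.DAAF_THRESHOLD
    ase_fdr: float = ase_mod.FDR_THRESHOLD
    ase_sd: float = ase_mod.ASE_SD_THRESHOLD
    enrichment_fdr: float = enr_mod.ENRICHMENT_FDR
    trans_r: float = lnc_mod.TRANS_R_THRESHOLD


def _require(cfg: PipelineConfig, *names: str) -> None:
    for name in names:
        path = getattr(cfg, name)
        if path is None:
            raise PipelineError(f"pipeline stage needs input {name!r}")
        if not Path(path).exists():
            raise PipelineError(f"input path does not exist: {name}={path}")


def run_pipeline(cfg: PipelineConfig, stages: Optional[list[str]] = None) -> dict:
    """Run the requested stages (default: all with satisfiable inputs).

    Writes result tables under ``cfg.outdir`` and returns a dict of output
    paths plus the run manifest.  Any stage failure aborts with the stage
    name and cause.
    """
    all_stages = ["de", "lncrna", "splice", "ase", "enrich", "qpcr"]
    stages = stages or all_stages
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # validate every input named by the requested stages up front
    needed = {"de": ["counts", "design"]}
    needed["lncrna"] = ["counts", "design", "transcripts", "homology"]
    needed["splice"] = ["gtf", "junctions", "design"]
    needed["ase"] = ["vcf", "design", "gtf", "genome"]
    needed["enrich"] = ["annotation_map"]
    needed["qpcr"] = ["cq"]
    for stage in stages:
        _require(cfg, *needed[stage])

    outputs: dict[str, str] = {}
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "deg_padj": cfg.deg_padj, "das_padj": cfg.das_padj,
            "das_dpsi": cfg.das_dpsi, "daaf": cfg.daaf,
            "ase_fdr": cfg.ase_fdr, "ase_sd": cfg.ase_sd,
            "enrichment_fdr": cfg.enrichment_fdr, "trans_r": cfg.trans_r,
        },
        "stages": {},
    }

    design = eio.read_design(cfg.design)
    de_table = None

    def _run(stage: str, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].setdefault(stage, {})["seconds"] = round(time.time() - t0, 3)
        return result

    if "de" in stages or "lncrna" in stages or "enrich" in stages:
        def _de():
            counts = eio.read_counts(cfg.counts, design)
            table = de_mod.run_de(counts)
            path = outdir / "deg.tsv"
            table.to_csv(path, sep="\t", index=False)
            outputs["deg"] = str(path)
            manifest["stages"].setdefault("de", {})
            return counts, table
        counts, de_table = _run("de", _de)
        total, up, down = de_mod.deg_partition(de_table)
        manifest["stages"]["de"].update({"n_deg": total, "n_up": up, "n_down": down})

    if "lncrna" in stages:
        def _lnc():
            seqs = eio.read_sequences_fasta(cfg.transcripts)
            flags = eio.read_homology_flags(cfg.homology).set_index("transcript_id")
            records = []
            for tid, seq in seqs.items():
                rfam = bool(flags.loc[tid, "rfam_hit"]) if tid in flags.index else False
                pfam = bool(flags.loc[tid, "pfam_hit"]) if tid in flags.index else False
                # exon counts travel with the GTF when given; default 2
                records.append(TranscriptRecord(tid, seq, 2, rfam, pfam))
            if cfg.gtf:
                by_tid = {tm.transcript_id: tm for tm in eio.read_gtf(cfg.gtf)}
                for rec in records:
                    if rec.transcript_id in by_tid:
                        rec.exon_count = by_tid[rec.transcript_id].exon_count
            short = [r for r in records if r.length <= lnc_mod.MIN_LNCRNA_LENGTH]
            scored = [r for r in records if r.length > lnc_mod.MIN_LNCRNA_LENGTH]
            lnc_ids = lnc_mod.identify_lncrnas(scored)
            lnc_tx = pd.DataFrame({"transcript_id": sorted(lnc_ids)})
            path = outdir / "lncrna.tsv"
            lnc_tx.to_csv(path, sep="\t", index=False)
            outputs["lncrna"] = str(path)

            # transcript → gene mapping for DEL calls and the trans network
            gene_of = {}
            if cfg.gtf:
                gene_of = {tm.transcript_id: tm.gene_id
                           for tm in eio.read_gtf(cfg.gtf)}
            lnc_genes = {gene_of.get(t, t) for t in lnc_ids}
            dels = lnc_mod.detect_dels(lnc_genes, de_table)
            dpath = outdir / "del.tsv"
            dels.to_csv(dpath, sep="\t", index=False)
            outputs["del"] = str(dpath)

            expr = lnc_mod.log_normalized_expression(counts)
            degs = de_table[de_table["is_deg"] &
                            ~de_table["gene_id"].isin(lnc_genes)]["gene_id"]
            edges = lnc_mod.trans_network(
                expr.loc[[g for g in dels["gene_id"] if g in expr.index]],
                expr.loc[[g for g in degs if g in expr.index]],
            )
            npath = outdir / "trans_network.tsv"
            edges.to_csv(npath, sep="\t", index=False)
            outputs["trans_network"] = str(npath)
            manifest["stages"]["lncrna"] = {
                "n_lncrna": len(lnc_ids), "n_del": len(dels),
                "n_links": len(edges), "n_below_length": len(short),
            }
        _run("lncrna", _lnc)

    if "splice" in stages:
        def _splice():
            models = eio.read_gtf(cfg.gtf)
            events = spl_mod.enumerate_events(models)
            junctions = eio.read_junction_counts(cfg.junctions)
            das = spl_mod.das_test(events, junctions, design)
            path = outdir / "das.tsv"
            das.to_csv(path, sep="\t", index=False)
            outputs["das"] = str(path)
            dasg = spl_mod.summarize_dasg(das)
            gpath = outdir / "dasg.tsv"
            dasg.to_csv(gpath, sep="\t", index=False)
            outputs["dasg"] = str(gpath)
            manifest["stages"]["splice"] = {
                "n_events": len(events),
                "n_sig_events": int(das["is_das"].sum()),
                "n_dasg": len(dasg),
                "per_type": spl_mod.dasg_type_counts(das),
            }
        _run("splice", _splice)

    if "ase" in stages:
        def _ase():
            sites = eio.read_allele_sites(cfg.vcf)
            genome = eio.read_fasta(cfg.genome)
            models = eio.read_gtf(cfg.gtf)
            called = ase_mod.call_snvs(sites, design)
            masks = ase_mod.build_region_masks(models, genome=genome)
            for cls, mask in masks.items():
                eio.write_bed_mask(outdir / f"mask_{cls}.bed", mask)
            surviving = ase_mod.filter_sites_by_mask(called, masks)
            table = ase_mod.delta_aaf_test(surviving, design)
            spath = outdir / "ase_sites.tsv"
            table.to_csv(spath, sep="\t", index=False)
            outputs["ase_sites"] = str(spath)
            final = ase_mod.select_final_ases(table, sd_threshold=cfg.ase_sd)
            fpath = outdir / "ase_final.tsv"
            final.to_csv(fpath, sep="\t", index=False)
            outputs["ase_final"] = str(fpath)
            sig = table[table["is_significant"]]
            key = set(zip(sig["chrom"], sig["pos"]))
            sig_sites = [s for s in surviving if (s.chrom, s.pos) in key]
            cons = ase_mod.annotate_consequence(sig_sites, models, genome)
            cpath = outdir / "ase_consequences.tsv"
            cons.to_csv(cpath, sep="\t", index=False)
            outputs["ase_consequences"] = str(cpath)
            props = ase_mod.consequence_proportions(cons)
            with open(outdir / "ase_class_proportions.json", "w") as fh:
                json.dump(props, fh, indent=2)
            outputs["ase_class_proportions"] = str(outdir / "ase_class_proportions.json")
            manifest["stages"]["ase"] = {
                "n_input": len(sites), "n_called": len(called),
                "n_after_masks": len(surviving),
                "n_significant": int(table["is_significant"].sum()),
                "n_final": len(final),
            }
        _run("ase", _ase)

    if "enrich" in stages:
        def _enrich():
            amap = eio.read_annotation_map(cfg.annotation_map)
            degs = de_table[de_table["is_deg"]]["gene_id"]
            enr = enr_mod.fisher_enrichment(degs, amap)
            enr = enr_mod.add_trend_zscores(enr, amap, de_table)
            path = outdir / "enrichment.tsv"
            enr.to_csv(path, sep="\t", index=False)
            outputs["enrichment"] = str(path)
            manifest["stages"]["enrich"] = {
                "n_terms": len(enr),
                "n_significant": int(enr["significant"].sum()),
            }
        _run("enrich", _enrich)

    if "qpcr" in stages:
        def _qpcr():
            cq = eio.read_cq_table(cfg.cq)
            targets = cfg.qpcr_targets or sorted(
                set(cq["gene"]) - set(cfg.qpcr_references)
            )
            table = qpcr_mod.analyze_qpcr(cq, targets, cfg.qpcr_references)
            path = outdir / "qpcr_rq.tsv"
            table.to_csv(path, sep="\t", index=False)
            outputs["qpcr"] = str(path)
            manifest["stages"]["qpcr"] = {"n_targets": len(targets)}
        _run("qpcr", _qpcr)

    manifest_path = outdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"manifest": manifest, "config": asdict(cfg)}, fh, indent=2)
    outputs["manifest"] = str(manifest_path)
    return outputs
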
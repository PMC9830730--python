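"""Synthetic-data generator with planted truth for every pipeline stage.

Emulates the study design the pipeline targets: 6 embolism (PA-E) vs 5
control (CTR) pulmonary-artery RNA-seq libraries.  Gene counts are
negative-binomial with planted log2 fold changes; junction reads are
binomial at planted per-group PSI with effective-length weighting; allele
counts are binomial at planted per-group alternative-allele fractions;
transcript sequences follow a biased codon model (coding) or
composition-matched text without long ORFs (noncoding); Cq values follow
an amplification-efficiency model.  Every generated entity is recorded in
the truth tables, so each stage has a recovery oracle.

Randomness: one root seed; per-stage generators are spawned
deterministically from it, so equal seeds give byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as eio
from .codon import SENSE_CODONS, coding_nucleotide_probs, sense_codon_probs
from .models import (
    CASE_GROUP,
    CTRL_GROUP,
    AlleleSite,
    CountMatrix,
    GenomeModel,
    JunctionCounts,
    PipelineError,
    SampleDesign,
    SpliceEvent,
    TranscriptModel,
    TranscriptRecord,
)

_STAGES = (
    "genome", "counts", "junctions", "alleles", "sequences", "qpcr", "links",
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the emulated study design."""

    seed: int = 0
    n_case: int = 6
    n_ctrl: int = 5

    # expression
    n_genes: int = 2000
    frac_de: float = 0.1
    log2fc_values: tuple = (2.0, -2.0)   # point masses, drawn uniformly
    log2fc_normal: Optional[tuple] = None  # (mean, sd) overrides point masses
    mean_log_mu: float = np.log(100.0)   # log-normal baseline expression
    mean_log_sd: float = 1.0
    dispersion_shape: float = 2.0        # gamma(shape, rate) per-gene dispersion
    dispersion_rate: float = 20.0
    libsize_log_sd: float = 0.2          # log-normal library-size factors

    # splicing
    n_events_per_type: int = 60
    frac_das: float = 0.2
    delta_psi: float = 0.3
    junction_coverage: float = 100.0     # Poisson mean per sample

    # allele sites
    n_sites: int = 3000
    frac_ase: float = 0.1
    delta_aaf: float = 0.5
    site_depth: float = 50.0             # Poisson mean, floor 1
    frac_masked_per_class: float = 0.02

    # transcript sequences
    n_transcripts: int = 500
    frac_noncoding: float = 0.4
    min_tx_length: int = 250
    max_tx_length: int = 1500
    coding_homology_rate: float = 0.8

    # lncRNA–mRNA links
    n_links: int = 20
    frac_negative_links: float = 0.2

    # qPCR
    qpcr_genes: tuple = ("ACSL4", "LIFR", "PIK3C2A", "COL1A1", "COL1A2", "C4A")
    qpcr_fold_changes: tuple = (2.0, 2.5, 2.0, 0.3, 0.35, 0.5)
    qpcr_references: tuple = ("ACTB", "GAPDH")
    qpcr_efficiency: float = 2.0
    cq_noise_sd: float = 0.1
    cq_bio_log2_sd: float = 0.15
    n_technical: int = 4

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_das", "frac_ase", "frac_noncoding",
                     "frac_masked_per_class", "frac_negative_links"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PipelineError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.delta_psi <= 1.0 or not 0.0 <= self.delta_aaf <= 1.0:
            raise PipelineError("planted effect sizes must lie in [0, 1]")
        if self.n_case < 2 or self.n_ctrl < 2:
            raise PipelineError("need >= 2 samples per group")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the root seed."""
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return np.random.default_rng(ss)

    def design(self) -> SampleDesign:
        samples = [f"PA-E{i + 1}" for i in range(self.n_case)] + [
            f"CTR{i + 1}" for i in range(self.n_ctrl)
        ]
        groups = [CASE_GROUP] * self.n_case + [CTRL_GROUP] * self.n_ctrl
        return SampleDesign(samples, groups)


# ---------------------------------------------------------------------------
# expression counts

def simulate_counts(cfg: SimulationConfig,
                    rng: Optional[np.random.Generator] = None,
                    gene_ids: Optional[list[str]] = None,
                    log2fc_overrides: Optional[dict[str, float]] = None,
                    ) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts with planted fold changes.

    count_gj ~ NB(mean = s_j · q_gj, dispersion α_g) with q in the case
    group scaled by 2^log2FC for DE genes.  Returns the matrix and a truth
    table (gene_id, is_de, log2fc, base_mean, dispersion).
    """
    rng = cfg.rng("counts") if rng is None else rng
    design = cfg.design()
    n = cfg.n_genes if gene_ids is None else len(gene_ids)
    gene_ids = gene_ids or [f"G{i + 1:05d}" for i in range(n)]

    base = rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sd, size=n)
    disp = rng.gamma(cfg.dispersion_shape, 1.0 / cfg.dispersion_rate, size=n)
    disp = np.maximum(disp, 1e-8)
    is_de = rng.random(n) < cfg.frac_de
    if cfg.log2fc_normal is not None:
        lfc = rng.normal(cfg.log2fc_normal[0], cfg.log2fc_normal[1], size=n)
    else:
        lfc = rng.choice(np.asarray(cfg.log2fc_values, dtype=float), size=n)
    lfc = np.where(is_de, lfc, 0.0)
    if log2fc_overrides:
        for gid, val in log2fc_overrides.items():
            idx = gene_ids.index(gid)
            lfc[idx] = val
            is_de[idx] = val != 0.0

    n_samples = cfg.n_case + cfg.n_ctrl
    sf = rng.lognormal(0.0, cfg.libsize_log_sd, size=n_samples)
    case = np.array([g == CASE_GROUP for g in design.groups])
    mu = base[:, None] * np.where(case[None, :], 2.0 ** lfc[:, None], 1.0) * sf[None, :]
    # NB via gamma-Poisson: shape 1/α, scale α·μ
    shape = 1.0 / disp
    lam = rng.gamma(shape[:, None], disp[:, None] * mu)
    counts = rng.poisson(lam)

    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": is_de, "log2fc": lfc,
         "base_mean": base, "dispersion": disp}
    )
    return CountMatrix(gene_ids, design, counts.astype(np.int64)), truth


# ---------------------------------------------------------------------------
# junction counts

def synthetic_events(cfg: SimulationConfig) -> list[SpliceEvent]:
    """Abstract events of the five types with standard effective lengths."""
    from .splicing import JUNCTION_POSITIONS as J

    lengths = {"SE": (2 * J, J), "RI": (2 * J, J), "A3SS": (J, J),
               "A5SS": (J, J), "MXE": (2 * J, 2 * J)}
    events = []
    pos = 0
    for etype in ("SE", "RI", "A3SS", "A5SS", "MXE"):
        li, ls = lengths[etype]
        for i in range(cfg.n_events_per_type):
            pos += 10_000
            events.append(
                SpliceEvent(
                    event_id=f"{etype}_{i + 1:05d}",
                    gene_id=f"SG{len(events) + 1:05d}",
                    event_type=etype,
                    chrom="sim1",
                    strand="+",
                    inclusion_coords=((pos, pos + 100),),
                    skipping_coords=((pos + 200, pos + 300),),
                    li=li,
                    ls=ls,
                )
            )
    return events


def simulate_junctions(cfg: SimulationConfig,
                       events: Optional[list[SpliceEvent]] = None,
                       rng: Optional[np.random.Generator] = None,
                       ) -> tuple[dict[str, JunctionCounts], pd.DataFrame]:
    """Binomial junction reads at planted per-group PSI.

    Per sample, total reads T ~ Poisson(coverage); inclusion reads
    I ~ Binomial(T, ψ·lI / (ψ·lI + (1−ψ)·lS)); S = T − I.
    """
    rng = cfg.rng("junctions") if rng is None else rng
    design = cfg.design()
    events = synthetic_events(cfg) if events is None else events

    truth_rows = []
    junctions: dict[str, JunctionCounts] = {}
    case_set = set(design.case_samples)
    for ev in events:
        psi_ctrl = rng.uniform(0.05, 0.95)
        if rng.random() < cfg.frac_das:
            shift = cfg.delta_psi if psi_ctrl + cfg.delta_psi <= 1.0 else -cfg.delta_psi
            psi_case = float(np.clip(psi_ctrl + shift, 0.0, 1.0))
            is_das = True
        else:
            psi_case = psi_ctrl
            is_das = False
        incl, skip = {}, {}
        for sample in design.sample_ids:
            psi = psi_case if sample in case_set else psi_ctrl
            p = psi * ev.li / (psi * ev.li + (1.0 - psi) * ev.ls)
            total = rng.poisson(cfg.junction_coverage)
            i = rng.binomial(total, p) if total > 0 else 0
            incl[sample] = int(i)
            skip[sample] = int(total - i)
        junctions[ev.event_id] = JunctionCounts(ev.event_id, incl, skip)
        truth_rows.append(
            {"event_id": ev.event_id, "gene_id": ev.gene_id,
             "event_type": ev.event_type, "psi_case": psi_case,
             "psi_ctrl": psi_ctrl, "is_das": is_das}
        )
    return junctions, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# allele counts

def simulate_allele_counts(cfg: SimulationConfig,
                           rng: Optional[np.random.Generator] = None,
                           positions: Optional[list[tuple[str, int]]] = None,
                           mask_classes: Optional[list[str]] = None,
                           ) -> tuple[list[AlleleSite], pd.DataFrame]:
    """Binomial allele counts at planted per-group AAF.

    depth ~ Poisson(site_depth) floored at 1; alt ~ Binomial(depth,
    AAF_group).  A configured fraction of sites is tagged with each region
    mask class in the truth (placement happens in the bundle generator).
    """
    rng = cfg.rng("alleles") if rng is None else rng
    design = cfg.design()
    n = cfg.n_sites if positions is None else len(positions)
    if positions is None:
        positions = [("sim1", 100 + 50 * i) for i in range(n)]
    if mask_classes is None:
        mask_classes = []
        classes = ("ssr", "pseudogene", "bidirectional", "intron_flank")
        for i in range(n):
            draw = rng.random()
            assigned = "none"
            for j, cls in enumerate(classes):
                if draw < cfg.frac_masked_per_class * (j + 1):
                    assigned = cls
                    break
            mask_classes.append(assigned)

    bases = np.array(list("ACGT"))
    case_set = set(design.case_samples)
    sites, rows = [], []
    for idx, (chrom, pos) in enumerate(positions):
        aaf_ctrl = rng.uniform(0.1, 0.9)
        if rng.random() < cfg.frac_ase:
            shift = cfg.delta_aaf if aaf_ctrl + cfg.delta_aaf <= 1.0 else -cfg.delta_aaf
            aaf_case = float(np.clip(aaf_ctrl + shift, 0.0, 1.0))
            is_ase = True
        else:
            aaf_case = aaf_ctrl
            is_ase = False
        ref, alt = rng.choice(bases, size=2, replace=False)
        ref_counts, alt_counts = {}, {}
        for sample in design.sample_ids:
            aaf = aaf_case if sample in case_set else aaf_ctrl
            depth = max(1, int(rng.poisson(cfg.site_depth)))
            a = int(rng.binomial(depth, aaf))
            alt_counts[sample] = a
            ref_counts[sample] = depth - a
        sites.append(AlleleSite(chrom, pos, str(ref), str(alt),
                                ref_counts, alt_counts))
        rows.append(
            {"chrom": chrom, "pos": pos, "aaf_case": aaf_case,
             "aaf_ctrl": aaf_ctrl, "is_ase": is_ase,
             "mask_class": mask_classes[idx]}
        )
    return sites, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transcript sequences

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    probs = coding_nucleotide_probs()
    bases = np.array(list("ACGT"))
    p = np.array([probs[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=length, p=p))


def _coding_sequence(rng: np.random.Generator, length: int) -> str:
    """UTR + (ATG + biased codons + stop) + UTR; planted ORF >= 300 nt."""
    n_codons = int(rng.integers(100, max(101, (length - 150) // 3)))
    orf = "ATG" + "".join(
        rng.choice(np.array(SENSE_CODONS),
                   p=np.array([sense_codon_probs()[c] for c in SENSE_CODONS]),
                   size=n_codons)
    ) + "TAA"
    remaining = max(0, length - len(orf))
    utr5 = _random_sequence(rng, remaining // 2)
    utr3 = _random_sequence(rng, remaining - remaining // 2)
    return utr5 + orf + utr3


def _noncoding_sequence(rng: np.random.Generator, length: int,
                        max_tries: int = 1000) -> str:
    """Composition-matched text with every ORF shorter than 100 codons."""
    from .lncrna import longest_orf

    for _ in range(max_tries):
        seq = _random_sequence(rng, length)
        if longest_orf(seq)[2] < 300:
            return seq
    raise PipelineError("could not sample an ORF-free noncoding sequence")


def simulate_transcript_sequences(cfg: SimulationConfig,
                                  models: Optional[list[TranscriptModel]] = None,
                                  rng: Optional[np.random.Generator] = None,
                                  ) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Transcript records with planted coding/noncoding structure.

    When transcript models are given, the coding flag follows their
    biotype; otherwise abstract transcripts are drawn.  Planted lncRNAs
    always carry false Rfam/Pfam flags; coding transcripts carry homology
    hits at the configured rate.
    """
    rng = cfg.rng("sequences") if rng is None else rng
    if models is None:
        n = cfg.n_transcripts
        ids = [f"T{i + 1:05d}" for i in range(n)]
        noncoding = rng.random(n) < cfg.frac_noncoding
        exon_counts = [int(rng.integers(2, 5)) if nc else int(rng.integers(2, 9))
                       for nc in noncoding]
    else:
        ids = [tm.transcript_id for tm in models]
        noncoding = np.array([tm.cds_start is None for tm in models])
        exon_counts = [tm.exon_count for tm in models]

    records, rows = [], []
    for tid, nc, n_exons in zip(ids, noncoding, exon_counts):
        length = int(rng.integers(cfg.min_tx_length, cfg.max_tx_length + 1))
        if nc:
            seq = _noncoding_sequence(rng, length)
            rfam = pfam = False
        else:
            seq = _coding_sequence(rng, length)
            rfam = bool(rng.random() < cfg.coding_homology_rate)
            pfam = bool(rng.random() < cfg.coding_homology_rate)
        records.append(TranscriptRecord(tid, seq, n_exons, rfam, pfam))
        rows.append(
            {"transcript_id": tid, "is_noncoding": bool(nc),
             "length": len(seq), "exon_count": n_exons,
             "rfam_hit": rfam, "pfam_hit": pfam}
        )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr(cfg: SimulationConfig,
                  rng: Optional[np.random.Generator] = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cq tables under the amplification-efficiency model.

    Cq = Cq0 − log_E(concentration) + Normal(0, sd); control concentration
    1 (up to biological noise), case concentration = planted fold change;
    four technical replicates per biological sample.
    """
    rng = cfg.rng("qpcr") if rng is None else rng
    design = cfg.design()
    E = cfg.qpcr_efficiency
    fold = dict(zip(cfg.qpcr_genes, cfg.qpcr_fold_changes))
    for ref in cfg.qpcr_references:
        fold[ref] = 1.0

    rows, truth = [], []
    for gene, fc in fold.items():
        cq0 = float(rng.uniform(18.0, 26.0))
        for sample, group in zip(design.sample_ids, design.groups):
            conc = fc if group == CASE_GROUP else 1.0
            conc *= 2.0 ** rng.normal(0.0, cfg.cq_bio_log2_sd)
            true_cq = cq0 - np.log(conc) / np.log(E)
            for rep in range(1, cfg.n_technical + 1):
                rows.append(
                    {"gene": gene, "sample": sample, "group": group,
                     "rep": rep,
                     "cq": float(true_cq + rng.normal(0.0, cfg.cq_noise_sd))}
                )
        truth.append(
            {"gene": gene, "fold_change": fc,
             "is_reference": gene in cfg.qpcr_references, "cq0": cq0}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# genome + gene models for the end-to-end bundle

def simulate_gene_models(cfg: SimulationConfig,
                         rng: Optional[np.random.Generator] = None,
                         n_chroms: int = 2,
                         ) -> tuple[GenomeModel, list[TranscriptModel]]:
    """A random genome with multi-exon genes, alternative isoforms of the
    five event geometries, CDS spans for coding genes, pseudogenes, and a
    few planted SSR stretches."""
    rng = cfg.rng("genome") if rng is None else rng
    bases = np.array(list("ACGT"))

    per_chrom = [[] for _ in range(n_chroms)]
    for i in range(cfg.n_genes):
        per_chrom[i % n_chroms].append(i)

    chrom_seqs: dict[str, str] = {}
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    models: list[TranscriptModel] = []
    noncoding = rng.random(cfg.n_genes) < cfg.frac_noncoding
    pseudo = rng.random(cfg.n_genes) < 0.02
    alt_geometry = rng.choice(["SE", "RI", "A3SS", "A5SS", "MXE", "none"],
                              size=cfg.n_genes,
                              p=[0.12, 0.12, 0.12, 0.12, 0.12, 0.40])

    for ci, chrom in enumerate(chrom_names):
        cursor = 0
        pieces: list[str] = []

        def pad_to(target: int) -> None:
            nonlocal cursor
            if target > cursor:
                pieces.append("".join(rng.choice(bases, size=target - cursor)))
                cursor = target

        for gi in per_chrom[ci]:
            gene_id = f"G{gi + 1:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor + int(rng.integers(200, 600))
            # four exons leave room for every alternative geometry
            exon_lens = rng.integers(120, 280, size=4)
            intron_lens = rng.integers(250, 700, size=3)
            exons = []
            p = start
            for k in range(4):
                exons.append((p, p + int(exon_lens[k])))
                p = exons[-1][1] + (int(intron_lens[k]) if k < 3 else 0)
            gene_end = exons[-1][1]
            biotype = ("pseudogene" if pseudo[gi]
                       else "lncRNA" if noncoding[gi] else "protein_coding")
            cds = {}
            if biotype == "protein_coding":
                cds = {"cds_start": exons[0][0] + exon_lens[0] // 2,
                       "cds_end": exons[3][1] - exon_lens[3] // 2}
            t1 = TranscriptModel(gene_id, f"{gene_id}.t1", chrom, strand,
                                 exons, biotype, **cds)
            models.append(t1)
            geom = alt_geometry[gi]
            e = exons
            if geom == "SE":
                alt = [e[0], e[2], e[3]]
            elif geom == "RI":
                alt = [(e[0][0], e[1][1]), e[2], e[3]]
            elif geom == "A3SS":
                # acceptor of exon 2 moves into the intron (strand-aware
                # typing happens at enumeration)
                shift = 30
                alt = [e[0], (e[1][0] - shift, e[1][1]), e[2], e[3]]
            elif geom == "A5SS":
                shift = 30
                alt = [(e[0][0], e[0][1] + shift), e[1], e[2], e[3]]
            elif geom == "MXE":
                alt = [e[0], e[2], e[3]]  # paired with t1's (e0, e1, e3)
            else:
                alt = None
            if geom == "MXE":
                t1_mxe = TranscriptModel(gene_id, f"{gene_id}.t1", chrom,
                                         strand, [e[0], e[1], e[3]], biotype,
                                         **cds)
                models[-1] = t1_mxe
            if alt is not None:
                models.append(
                    TranscriptModel(gene_id, f"{gene_id}.t2", chrom, strand,
                                    alt, biotype, **cds)
                )
            pad_to(gene_end + 300)
        pad_to(cursor + 2000)
        seq = "".join(pieces)
        chrom_seqs[chrom] = seq

    # plant a few SSR stretches in intergenic space near the chromosome ends
    for chrom in chrom_names:
        seq = chrom_seqs[chrom]
        ssr = "A" * 20 + "".join(rng.choice(bases, size=50)) + "AT" * 8
        chrom_seqs[chrom] = seq[: len(seq) - len(ssr) - 10] + ssr + seq[len(seq) - 10:]

    return GenomeModel(chrom_names, chrom_seqs), models


# ---------------------------------------------------------------------------
# full bundle

def simulate_bundle(cfg: SimulationConfig, outdir) -> dict:
    """Generate and write every input the pipeline consumes, plus truth.

    Returns a dict of file paths.  Equal configs (including seed) produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = cfg.design()

    genome, models = simulate_gene_models(cfg)
    gene_ids = sorted({tm.gene_id for tm in models})

    # lncRNA–mRNA links: tie selected noncoding genes to DE mRNAs by
    # giving both the same (or negated) planted fold change
    link_rng = cfg.rng("links")
    nc_genes = sorted({tm.gene_id for tm in models if tm.biotype == "lncRNA"})
    pc_genes = sorted({tm.gene_id for tm in models if tm.biotype == "protein_coding"})
    n_links = min(cfg.n_links, len(nc_genes), len(pc_genes))
    link_lnc = list(link_rng.choice(nc_genes, size=n_links, replace=False))
    link_mrna = list(link_rng.choice(pc_genes, size=n_links, replace=False))
    overrides: dict[str, float] = {}
    link_rows = []
    for lnc, mrna in zip(link_lnc, link_mrna):
        fc = float(link_rng.choice([2.5, -2.5]))
        negative = link_rng.random() < cfg.frac_negative_links
        overrides[mrna] = fc
        overrides[lnc] = -fc if negative else fc
        link_rows.append(
            {"lnc_id": lnc, "gene_id": mrna,
             "sign": "negative" if negative else "positive"}
        )
    links_truth = pd.DataFrame(link_rows)

    counts, genes_truth = simulate_counts(cfg, gene_ids=gene_ids,
                                          log2fc_overrides=overrides)

    events = [ev for ev in _enumerate(models)]
    junctions, events_truth = simulate_junctions(cfg, events=events)

    site_positions, site_classes = _place_sites(cfg, genome, models)
    sites, sites_truth = simulate_allele_counts(
        cfg, positions=site_positions, mask_classes=site_classes
    )

    records, tx_truth = simulate_transcript_sequences(cfg, models=models)

    annotation_map = _simulate_annotation_map(cfg, gene_ids, genes_truth)

    cq_table, qpcr_truth = simulate_qpcr(cfg)

    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "models.gtf",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "junctions": outdir / "junctions.tsv",
        "vcf": outdir / "sites.vcf",
        "transcripts": outdir / "transcripts.fa",
        "homology": outdir / "homology.tsv",
        "annotation_map": outdir / "annotation_map.tsv",
        "cq": outdir / "cq.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_events": outdir / "truth_events.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_transcripts": outdir / "truth_transcripts.tsv",
        "truth_links": outdir / "truth_links.tsv",
        "truth_qpcr": outdir / "truth_qpcr.tsv",
        "manifest": outdir / "sim_manifest.json",
    }
    eio.write_fasta(paths["genome"], genome)
    eio.write_gtf(paths["gtf"], models)
    eio.write_counts(paths["counts"], counts)
    eio.write_design(paths["design"], design)
    eio.write_junction_counts(paths["junctions"], junctions.values())
    eio.write_allele_sites(
        paths["vcf"], sites, design.sample_ids,
        contigs={c: genome.length(c) for c in genome.chrom_names},
    )
    eio.write_sequences_fasta(
        paths["transcripts"], {r.transcript_id: r.sequence for r in records}
    )
    eio.write_homology_flags(
        paths["homology"],
        tx_truth[["transcript_id", "rfam_hit", "pfam_hit"]],
    )
    eio.write_annotation_map(paths["annotation_map"], annotation_map)
    eio.write_cq_table(paths["cq"], cq_table)
    genes_truth.to_csv(paths["truth_genes"], sep="\t", index=False)
    events_truth.to_csv(paths["truth_events"], sep="\t", index=False)
    sites_truth.to_csv(paths["truth_sites"], sep="\t", index=False)
    tx_truth.to_csv(paths["truth_transcripts"], sep="\t", index=False)
    links_truth.to_csv(paths["truth_links"], sep="\t", index=False)
    qpcr_truth.to_csv(paths["truth_qpcr"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump({"config": _jsonable(asdict(cfg))}, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def _enumerate(models):
    from .splicing import enumerate_events

    return enumerate_events(models)


def _simulate_annotation_map(cfg: SimulationConfig, gene_ids: list[str],
                             genes_truth: pd.DataFrame) -> pd.DataFrame:
    """Term→gene maps over the simulated genes: mostly random terms, plus
    a few terms deliberately packed with DE genes so enrichment has
    signal to find."""
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(102,))
    rng = np.random.default_rng(ss)
    de_genes = list(genes_truth.loc[genes_truth["is_de"], "gene_id"])
    rows = []
    for namespace, n_terms in (("BP", 25), ("CC", 10), ("MF", 5),
                               ("KEGG", 10), ("HP", 5)):
        for t in range(n_terms):
            term_id = f"{namespace}:{t + 1:04d}"
            name = f"{namespace.lower()} term {t + 1}"
            size = int(rng.integers(10, 60))
            if t < 2 and len(de_genes) >= 5:  # enriched terms
                n_de = min(len(de_genes), max(5, size // 2))
                members = set(rng.choice(de_genes, size=n_de, replace=False))
                n_extra = max(1, size - len(members))
                members |= set(rng.choice(gene_ids, size=n_extra, replace=False))
            else:
                members = set(rng.choice(gene_ids, size=size, replace=False))
            for g in sorted(members):
                rows.append((namespace, term_id, name, g))
    return pd.DataFrame(
        rows, columns=["namespace", "term_id", "term_name", "gene_id"]
    )


def _place_sites(cfg: SimulationConfig, genome: GenomeModel,
                 models: list[TranscriptModel]):
    """Scatter allele-site positions over gene bodies, with a configured
    fraction planted inside each mask class."""
    from .ase import build_region_masks

    # independent spawn so the allele-count draws stay aligned with the
    # "alleles" stage stream
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(101,))
    rng = np.random.default_rng(ss)

    masks = build_region_masks(models, genome=genome)
    positions: list[tuple[str, int]] = []
    classes: list[str] = []
    mask_list = ["ssr", "pseudogene", "bidirectional", "intron_flank"]
    per_class = int(cfg.n_sites * cfg.frac_masked_per_class)
    for cls in mask_list:
        ivs = [(c, s, e) for c, lst in masks[cls].intervals.items() for s, e in lst]
        if not ivs:
            continue
        for _ in range(per_class):
            c, s, e = ivs[int(rng.integers(len(ivs)))]
            positions.append((c, int(rng.integers(s, e))))
            classes.append(cls)

    spans = [(tm.chrom, tm.start, tm.end) for tm in models]
    other_masks = list(masks.values())
    n_free = cfg.n_sites - len(positions)
    tries = 0
    while n_free > 0 and tries < cfg.n_sites * 50:
        tries += 1
        c, s, e = spans[int(rng.integers(len(spans)))]
        pos = int(rng.integers(s, e))
        if any(m.contains(c, pos) for m in other_masks):
            continue
        positions.append((c, pos))
        classes.append("none")
        n_free -= 1
    order = np.argsort([f"{c}:{p:012d}" for c, p in positions])
    positions = [positions[i] for i in order]
    classes = [classes[i] for i in order]
    # drop duplicate positions (one biallelic record per locus)
    seen: set[tuple[str, int]] = set()
    uniq_pos, uniq_cls = [], []
    for pc, cl in zip(positions, classes):
        if pc in seen:
            continue
        seen.add(pc)
        uniq_pos.append(pc)
        uniq_cls.append(cl)
    return uniq_pos, uniq_cls


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
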
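"""Readers and writers for the formats the pipeline touches.

External coordinates follow the conventions of each format: GTF and VCF are
1-based inclusive, BED is 0-based half-open.  Everything is converted to the
internal 0-based half-open representation here and nowhere else.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AlleleSite,
    CountMatrix,
    GenomeModel,
    JunctionCounts,
    PipelineError,
    RegionMask,
    SampleDesign,
    TranscriptModel,
)

log = logging.getLogger("emboliseq.io")


# ---------------------------------------------------------------------------
# coordinate conversion — the single site where conventions change

def gtf_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    return start_1based - 1, end_inclusive


def internal_to_gtf(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


def vcf_pos_to_internal(pos_1based: int) -> int:
    return pos_1based - 1


def internal_to_vcf_pos(pos: int) -> int:
    return pos + 1


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> GenomeModel:
    names, seqs = [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if not names:
        raise PipelineError(f"no sequences in {path}")
    return GenomeModel(names, seqs)


def write_fasta(path, genome: GenomeModel) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[name]), id=name, description="")
        for name in genome.chrom_names
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sequences_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_sequences_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GTF

def _parse_gtf_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(" ", 1)
        if len(parts) != 2:
            raise PipelineError(f"malformed GTF attribute at line {lineno}: {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Parse transcript models from a GTF file.

    Exon rows are grouped per transcript_id and sorted by start; CDS rows,
    when present, define the genomic CDS span.  A transcript_id seen on two
    chromosomes or strands is an error, as is a transcript with no exon rows.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, biotype)
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise PipelineError(f"GTF line {lineno}: expected 9 fields")
            chrom, _source, feature, start, end, _score, strand, _frame, raw = fields
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_gtf_attributes(raw, lineno)
            try:
                tid = attrs["transcript_id"]
                gid = attrs["gene_id"]
            except KeyError as exc:
                raise PipelineError(
                    f"GTF line {lineno}: missing attribute {exc}"
                ) from None
            biotype = attrs.get("transcript_biotype", attrs.get("gene_biotype", "unknown"))
            iv = gtf_to_internal(int(start), int(end))
            if tid in meta:
                if meta[tid][1] != chrom or meta[tid][2] != strand:
                    raise PipelineError(
                        f"GTF line {lineno}: transcript_id {tid!r} reused across "
                        "chromosomes or strands"
                    )
            else:
                meta[tid] = (gid, chrom, strand, biotype)
                order.append(tid)
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)

    out = []
    for tid in order:
        gid, chrom, strand, biotype = meta[tid]
        if tid not in exons:
            raise PipelineError(f"transcript {tid!r} has no exon rows")
        kwargs = {}
        if tid in cds:
            spans = sorted(cds[tid])
            kwargs = {"cds_start": spans[0][0], "cds_end": spans[-1][1]}
        out.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=sorted(exons[tid]),
                biotype=biotype,
                **kwargs,
            )
        )
    return out


def write_gtf(path, models: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for tm in models:
            attrs = (
                f'gene_id "{tm.gene_id}"; transcript_id "{tm.transcript_id}"; '
                f'transcript_biotype "{tm.biotype}";'
            )
            for s, e in tm.exons:
                g1, g2 = internal_to_gtf(s, e)
                fh.write(
                    f"{tm.chrom}\temboliseq\texon\t{g1}\t{g2}\t.\t{tm.strand}\t.\t{attrs}\n"
                )
            if tm.cds_start is not None and tm.cds_end is not None:
                for s, e in tm.exons:
                    cs, ce = max(s, tm.cds_start), min(e, tm.cds_end)
                    if cs < ce:
                        g1, g2 = internal_to_gtf(cs, ce)
                        fh.write(
                            f"{tm.chrom}\temboliseq\tCDS\t{g1}\t{g2}\t.\t{tm.strand}\t0\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# counts TSV

def read_counts(path, design: SampleDesign) -> CountMatrix:
    """Read a genes × samples TSV of raw counts, matching columns to design."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise PipelineError(f"samples in design missing from counts header: {missing}")
    extra = [c for c in df.columns if c not in design.sample_ids]
    if extra:
        warnings.warn(f"dropping {len(extra)} column(s) not in design: {extra}")
        df = df.drop(columns=extra)
    df = df[design.sample_ids]
    if df.isna().any().any():
        raise PipelineError("missing cells in count matrix")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or (values % 1 != 0).any():
        raise PipelineError("counts must be integers")
    if (values < 0).any():
        raise PipelineError("negative counts in matrix")
    return CountMatrix(list(df.index), design, values.astype(np.int64))


def write_counts(path, counts: CountMatrix) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# VCF with per-sample AD

def read_allele_sites(path, multiallelic: str = "reject") -> list[AlleleSite]:
    """Read biallelic SNVs with per-sample allele depths from a VCF.

    ``multiallelic`` is ``"reject"`` (error) or ``"split"`` (one AlleleSite
    per alternate allele).  Indel records are skipped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[AlleleSite] = []
    n_indels = 0
    for var in vcf:
        if "AD" not in (var.FORMAT or []):
            raise PipelineError(f"AD field missing at {var.CHROM}:{var.POS}")
        alts = var.ALT
        if any(len(a) != 1 for a in alts) or len(var.REF) != 1:
            n_indels += 1
            continue
        if len(alts) > 1 and multiallelic == "reject":
            raise PipelineError(
                f"multiallelic record at {var.CHROM}:{var.POS} "
                "(set multiallelic='split' to keep)"
            )
        ad = var.format("AD")  # samples × (1 + n_alt)
        if ad is None:
            raise PipelineError(f"AD field missing at {var.CHROM}:{var.POS}")
        ad = np.where(ad < 0, 0, ad)
        for ai, alt in enumerate(alts, start=1):
            sites.append(
                AlleleSite(
                    chrom=var.CHROM,
                    pos=vcf_pos_to_internal(var.POS),
                    ref=var.REF,
                    alt=alt,
                    ref_counts={s: int(ad[j, 0]) for j, s in enumerate(samples)},
                    alt_counts={s: int(ad[j, ai]) for j, s in enumerate(samples)},
                    known_id=var.ID,
                )
            )
    if n_indels:
        log.info("skipped %d indel record(s)", n_indels)
    vcf.close()
    return sites


def write_allele_sites(path, sites: list[AlleleSite], sample_ids: list[str],
                       contigs: Optional[dict[str, int]] = None) -> None:
    """Write sites as a VCF v4.2 with per-sample AD."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in sorted({s.chrom for s in sites}):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            cells = []
            for s in sample_ids:
                cells.append(f"./.:{site.ref_counts[s]},{site.alt_counts[s]}")
            fh.write(
                f"{site.chrom}\t{internal_to_vcf_pos(site.pos)}\t"
                f"{site.known_id or '.'}\t{site.ref}\t{site.alt}\t.\tPASS\t.\t"
                "GT:AD\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# BED masks

def read_bed_mask(path, mask_class: str) -> RegionMask:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.setdefault(chrom, []).append((int(start), int(end)))
    return RegionMask(mask_class, intervals)


def write_bed_mask(path, mask: RegionMask) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{mask.mask_class}\n")


# ---------------------------------------------------------------------------
# junction counts TSV (event_id, sample, inclusion, skipping)

def read_junction_counts(path) -> dict[str, JunctionCounts]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, JunctionCounts] = {}
    for event_id, sub in df.groupby("event_id", sort=False):
        out[event_id] = JunctionCounts(
            event_id=event_id,
            inclusion=dict(zip(sub["sample"], sub["inclusion"].astype(int))),
            skipping=dict(zip(sub["sample"], sub["skipping"].astype(int))),
        )
    return out


def write_junction_counts(path, junctions: Iterable[JunctionCounts]) -> None:
    rows = []
    for jc in junctions:
        for sample in jc.inclusion:
            rows.append(
                (jc.event_id, sample, jc.inclusion[sample], jc.skipping[sample])
            )
    pd.DataFrame(rows, columns=["event_id", "sample", "inclusion", "skipping"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# annotation maps (namespace, term_id, term_name, gene)

def read_annotation_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"namespace", "term_id", "term_name", "gene_id"}
    if not required.issubset(df.columns):
        raise PipelineError(f"annotation map missing columns {required - set(df.columns)}")
    return df


def write_annotation_map(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR Cq tables (gene, sample, group, rep, Cq)

def read_cq_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "group", "rep", "cq"}
    if not required.issubset(df.columns):
        raise PipelineError(f"Cq table missing columns {required - set(df.columns)}")
    if (df["cq"] <= 0).any():
        raise PipelineError("Cq values must be positive")
    return df


def write_cq_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homology flags (transcript_id, rfam_hit, pfam_hit)

def read_homology_flags(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "rfam_hit", "pfam_hit"}
    if not required.issubset(df.columns):
        raise PipelineError(f"homology table missing columns {required - set(df.columns)}")
    return df.astype({"rfam_hit": bool, "pfam_hit": bool})


def write_homology_flags(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t")
    return SampleDesign(list(df["sample"]), list(df["group"]))


def write_design(path, design: SampleDesign) -> None:
    pd.DataFrame({"sample": design.sample_ids, "group": design.groups}).to_csv(
        path, sep="\t", index=False
    )
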
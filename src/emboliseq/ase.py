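"""The ΔAAF allele-specific-expression cascade.

SNV calling from allele counts, region-mask filtration (bidirectional
loci, intron flanks, simple sequence repeats, pseudogenes), Fisher's exact
comparison of pooled group allele counts with BH control, standard-
deviation-based final ASE selection, and strand-aware consequence
annotation against transcript models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as sps

from .models import (
    CASE_GROUP,
    CONSEQUENCE_SEVERITY,
    CTRL_GROUP,
    AlleleSite,
    GenomeModel,
    RegionMask,
    SampleDesign,
    TranscriptModel,
    revcomp,
)
from .stats import benjamini_hochberg

log = logging.getLogger("emboliseq.ase")

MIN_COVERAGE = 10            # per-sample depth floor
MIN_ALT_READS = 2
MIN_ALT_FRACTION = 0.05
DAAF_THRESHOLD = 0.3
FDR_THRESHOLD = 0.001
ASE_SD_THRESHOLD = 0.1       # within-group AAF SD ceiling, both groups
FLANK_WIDTH = 10             # intronic flank masked at each intron end
BIDIRECTIONAL_WINDOW = 1000  # head-to-head TSS distance
STREAM_WINDOW = 5000         # upstream/downstream annotation span

#: minimum repeat counts for SSR motif lengths 1..6
SSR_MIN_REPEATS = {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


# ---------------------------------------------------------------------------
# SNV calling

def call_snvs(sites: list[AlleleSite], design: SampleDesign) -> list[AlleleSite]:
    """Coverage and alt-support filter.

    Retain sites with total depth >= 10 in *every* sample of both groups
    and alt support (>= 2 alt reads at alt fraction >= 0.05) in at least
    one sample.
    """
    kept = []
    n_low_cov = n_no_alt = 0
    for site in sites:
        if any(site.depth(s) < MIN_COVERAGE for s in design.sample_ids):
            n_low_cov += 1
            continue
        supported = any(
            site.alt_counts[s] >= MIN_ALT_READS
            and site.alt_counts[s] / site.depth(s) >= MIN_ALT_FRACTION
            for s in design.sample_ids
        )
        if not supported:
            n_no_alt += 1
            continue
        kept.append(site)
    log.info(
        "call_snvs: %d in, %d low-coverage, %d without alt support, %d kept",
        len(sites), n_low_cov, n_no_alt, len(kept),
    )
    return kept


# ---------------------------------------------------------------------------
# SSR detection

def _smallest_period(motif: str) -> int:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return p
    return len(motif)


def detect_ssrs(genome: GenomeModel) -> RegionMask:
    """Perfect tandem repeats, motif length 1–6, GMATo-style thresholds.

    A repeat is reported when a primitive motif of length k occurs in >=
    SSR_MIN_REPEATS[k] complete consecutive copies.  The reported interval
    is the leftmost maximal run of complete copies: the periodicity breaks
    immediately left of the start, and no further complete copy follows;
    motifs containing N are ignored.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = arr.size
        found: set[tuple[int, int]] = set()
        for k in range(1, 7):
            min_rep = SSR_MIN_REPEATS[k]
            if n < k * min_rep:
                continue
            eq = arr[:-k] == arr[k:]
            # boundaries of maximal True runs of the period-k predicate
            padded = np.concatenate(([False], eq, [False]))
            diff = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(diff == 1)
            ends = np.flatnonzero(diff == -1)  # exclusive, in eq coords
            for a, b in zip(starts, ends):
                span = (b - a) + k  # periodic stretch length incl. partial
                count = span // k
                if count < min_rep:
                    continue
                motif = seq[a : a + k]
                if "N" in motif or _smallest_period(motif) != k:
                    continue
                found.add((int(a), int(a + count * k)))
        if found:
            intervals[chrom] = sorted(found)
    return RegionMask("ssr", intervals)


# ---------------------------------------------------------------------------
# region masks

def build_region_masks(models: list[TranscriptModel],
                       genome: Optional[GenomeModel] = None,
                       ssr: Optional[RegionMask] = None) -> dict[str, RegionMask]:
    """Build the four elimination masks.

    bidirectional: opposite-strand gene overlap, or head-to-head TSSs
    within 1,000 bp; intron_flank: first/last 10 bp of every intron;
    ssr: from :func:`detect_ssrs`; pseudogene: transcript spans with a
    pseudogene biotype.
    """
    genes: dict[str, dict] = {}
    for tm in models:
        g = genes.setdefault(
            tm.gene_id,
            {"chrom": tm.chrom, "strand": tm.strand, "start": tm.start,
             "end": tm.end, "pseudo": False},
        )
        g["start"] = min(g["start"], tm.start)
        g["end"] = max(g["end"], tm.end)
        if "pseudogene" in tm.biotype:
            g["pseudo"] = True

    bidi: dict[str, list[tuple[int, int]]] = {}
    glist = sorted(genes.items(), key=lambda kv: (kv[1]["chrom"], kv[1]["start"]))
    for i, (gi, a) in enumerate(glist):
        for gj, b in glist[i + 1:]:
            if b["chrom"] != a["chrom"]:
                break
            if a["strand"] == b["strand"]:
                continue
            overlap = min(a["end"], b["end"]) - max(a["start"], b["start"])
            if overlap > 0:
                s, e = max(a["start"], b["start"]), min(a["end"], b["end"])
                bidi.setdefault(a["chrom"], []).append((s, e))
                continue
            # head-to-head: minus-strand gene upstream of plus-strand gene,
            # TSSs facing each other within the window
            left, right = (a, b) if a["start"] <= b["start"] else (b, a)
            if left["strand"] == "-" and right["strand"] == "+":
                gap = right["start"] - left["end"]
                if 0 <= gap <= BIDIRECTIONAL_WINDOW:
                    bidi.setdefault(a["chrom"], []).append((left["end"], right["start"] + 1))

    flank: dict[str, list[tuple[int, int]]] = {}
    for tm in models:
        for s, e in tm.introns():
            width = min(FLANK_WIDTH, e - s)
            flank.setdefault(tm.chrom, []).append((s, s + width))
            flank.setdefault(tm.chrom, []).append((e - width, e))

    pseudo: dict[str, list[tuple[int, int]]] = {}
    for gid, g in genes.items():
        if g["pseudo"]:
            pseudo.setdefault(g["chrom"], []).append((g["start"], g["end"]))

    if ssr is None:
        ssr = detect_ssrs(genome) if genome is not None else RegionMask("ssr", {})
    return {
        "bidirectional": RegionMask("bidirectional", bidi),
        "intron_flank": RegionMask("intron_flank", flank),
        "ssr": ssr,
        "pseudogene": RegionMask("pseudogene", pseudo),
    }


def filter_sites_by_mask(sites: list[AlleleSite],
                         masks: dict[str, RegionMask] | Iterable[RegionMask]
                         ) -> list[AlleleSite]:
    """Drop every site whose position falls inside any mask class."""
    if isinstance(masks, dict):
        masks = list(masks.values())
    else:
        masks = list(masks)
    kept = []
    tallies = {m.mask_class: 0 for m in masks}
    for site in sites:
        hit = None
        for mask in masks:
            if mask.contains(site.chrom, site.pos):
                hit = mask.mask_class
                break
        if hit is None:
            kept.append(site)
        else:
            tallies[hit] += 1
    log.info("mask filtration: %s removed, %d kept", tallies, len(kept))
    return kept


# ---------------------------------------------------------------------------
# ΔAAF testing and final ASE selection

def delta_aaf_test(sites: list[AlleleSite], design: SampleDesign,
                   method: str = "fisher") -> pd.DataFrame:
    """Group allele-frequency comparison per site.

    Pooled (ref, alt) counts within each group form a 2×2 table tested
    with Fisher's exact test (or chi-square via ``method='chi2'``); BH FDR
    across testable sites.  ΔAAF is the difference of unweighted means of
    per-sample alt fractions (PA-E minus CTR).
    """
    case_ids, ctrl_ids = design.case_samples, design.ctrl_samples
    rows = []
    for site in sites:
        case_ref = sum(site.ref_counts[s] for s in case_ids)
        case_alt = sum(site.alt_counts[s] for s in case_ids)
        ctrl_ref = sum(site.ref_counts[s] for s in ctrl_ids)
        ctrl_alt = sum(site.alt_counts[s] for s in ctrl_ids)
        case_aafs = [site.aaf(s) for s in case_ids if site.depth(s) > 0]
        ctrl_aafs = [site.aaf(s) for s in ctrl_ids if site.depth(s) > 0]
        mean_case = float(np.mean(case_aafs)) if case_aafs else float("nan")
        mean_ctrl = float(np.mean(ctrl_aafs)) if ctrl_aafs else float("nan")
        sd_case = float(np.std(case_aafs, ddof=1)) if len(case_aafs) > 1 else float("nan")
        sd_ctrl = float(np.std(ctrl_aafs, ddof=1)) if len(ctrl_aafs) > 1 else float("nan")
        if case_ref + case_alt == 0 or ctrl_ref + ctrl_alt == 0:
            pval = float("nan")
        else:
            table = [[case_ref, case_alt], [ctrl_ref, ctrl_alt]]
            if method == "fisher":
                _, pval = sps.fisher_exact(table, alternative="two-sided")
            elif method == "chi2":
                pval = sps.chi2_contingency(table, correction=True)[1]
            else:
                raise ValueError(f"unknown test method {method!r}")
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "mean_aaf_case": mean_case,
                "mean_aaf_ctrl": mean_ctrl,
                "delta_aaf": mean_case - mean_ctrl,
                "sd_case": sd_case,
                "sd_ctrl": sd_ctrl,
                "pvalue": float(pval),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["fdr"] = []
        df["is_significant"] = []
        return df
    df["fdr"] = benjamini_hochberg(df["pvalue"].to_numpy())
    df["is_significant"] = (
        (df["delta_aaf"].abs() > DAAF_THRESHOLD)
        & (df["fdr"] < FDR_THRESHOLD)
        & df["fdr"].notna()
    )
    return df


def select_final_ases(ase_table: pd.DataFrame,
                      sd_threshold: float = ASE_SD_THRESHOLD) -> pd.DataFrame:
    """Final ASE set: significant sites whose within-group AAF standard
    deviation stays <= threshold in both groups, ranked by max(SD)."""
    sig = ase_table[ase_table["is_significant"]].copy()
    if sig.empty:
        return sig
    sig["max_sd"] = sig[["sd_case", "sd_ctrl"]].max(axis=1)
    final = sig[(sig["sd_case"] <= sd_threshold) & (sig["sd_ctrl"] <= sd_threshold)]
    return final.sort_values(["max_sd", "chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# consequence annotation

@dataclass
class ConsequenceAnnotation:
    chrom: str
    pos: int
    transcript_id: str
    consequence: str
    ref_codon: str = ""
    alt_codon: str = ""
    ref_aa: str = ""
    alt_aa: str = ""


def _annotate_transcript(pos: int, ref: str, alt: str, tm: TranscriptModel,
                         genome: Optional[GenomeModel]) -> Optional[str | ConsequenceAnnotation]:
    """Consequence of a substitution against one transcript (or None)."""
    start, end = tm.start, tm.end
    fwd = tm.strand == "+"
    if pos < start or pos >= end:
        if start - STREAM_WINDOW <= pos < start:
            return "upstream" if fwd else "downstream"
        if end <= pos < end + STREAM_WINDOW:
            return "downstream" if fwd else "upstream"
        return None

    in_exon = any(s <= pos < e for s, e in tm.exons)
    if not in_exon:
        # intronic: splice acceptor = last two intron bases before the next
        # exon in transcript orientation
        for s, e in tm.introns():
            if s <= pos < e:
                if fwd and pos >= e - 2:
                    return "splice_acceptor"
                if not fwd and pos < s + 2:
                    return "splice_acceptor"
                return "intron"
        return "intron"

    if tm.cds_start is None or tm.cds_end is None:
        # noncoding transcript: exonic positions count as intragenic
        # noncoding sequence; report as intron-class (no CDS geometry)
        return "intron"

    if pos < tm.cds_start:
        return "five_prime_utr" if fwd else "three_prime_utr"
    if pos >= tm.cds_end:
        return "three_prime_utr" if fwd else "five_prime_utr"

    if genome is None:
        return "synonymous"  # cannot resolve codon without sequence

    # CDS substitution: build the spliced CDS and locate the codon
    cds_exons = [
        (max(s, tm.cds_start), min(e, tm.cds_end))
        for s, e in tm.exons
        if min(e, tm.cds_end) > max(s, tm.cds_start)
    ]
    cds_seq = "".join(genome.fetch(tm.chrom, s, e) for s, e in cds_exons)
    offset = 0
    cds_pos = None
    for s, e in cds_exons:
        if s <= pos < e:
            cds_pos = offset + (pos - s)
            break
        offset += e - s
    if cds_pos is None:
        return "intron"  # within the CDS span but intronic
    if not fwd:
        cds_seq = revcomp(cds_seq)
        cds_pos = len(cds_seq) - 1 - cds_pos
        ref_t, alt_t = revcomp(ref), revcomp(alt)
    else:
        ref_t, alt_t = ref, alt
    codon_idx = cds_pos // 3
    within = cds_pos % 3
    codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:
        return "synonymous"  # trailing partial codon
    alt_codon = codon[:within] + alt_t + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    cons = "synonymous" if ref_aa == alt_aa else "missense"
    return ConsequenceAnnotation(
        tm.chrom, pos, tm.transcript_id, cons,
        ref_codon=codon, alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa,
    )


def annotate_consequence(sites: list[AlleleSite], models: list[TranscriptModel],
                         genome: Optional[GenomeModel] = None) -> pd.DataFrame:
    """Most-severe consequence per site across overlapping transcripts.

    Sites farther than 5 kb from every transcript are labelled
    ``intergenic`` and excluded from the eight-class proportion summary.
    """
    severity = {c: i for i, c in enumerate(CONSEQUENCE_SEVERITY)}
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for tm in models:
        by_chrom.setdefault(tm.chrom, []).append(tm)
    # windowed span arrays per chromosome, for fast candidate lookup
    bounds = {
        chrom: (
            np.array([tm.start - STREAM_WINDOW for tm in tms]),
            np.array([tm.end + STREAM_WINDOW for tm in tms]),
        )
        for chrom, tms in by_chrom.items()
    }

    rows = []
    for site in sites:
        best: Optional[tuple[int, str, ConsequenceAnnotation | None]] = None
        tms = by_chrom.get(site.chrom, [])
        if tms:
            lo, hi = bounds[site.chrom]
            idx = np.flatnonzero((lo <= site.pos) & (site.pos < hi))
            candidates = [tms[i] for i in idx]
        else:
            candidates = []
        for tm in candidates:
            res = _annotate_transcript(site.pos, site.ref, site.alt, tm, genome)
            if res is None:
                continue
            if isinstance(res, ConsequenceAnnotation):
                cls, detail = res.consequence, res
            else:
                cls, detail = res, None
            rank = severity[cls]
            if best is None or rank < best[0]:
                best = (rank, tm.transcript_id, detail)
                best_cls = cls
        if best is None:
            rows.append(
                {"chrom": site.chrom, "pos": site.pos, "ref": site.ref,
                 "alt": site.alt, "transcript_id": "", "consequence": "intergenic",
                 "ref_codon": "", "alt_codon": "", "ref_aa": "", "alt_aa": ""}
            )
        else:
            detail = best[2]
            rows.append(
                {"chrom": site.chrom, "pos": site.pos, "ref": site.ref,
                 "alt": site.alt, "transcript_id": best[1],
                 "consequence": best_cls,
                 "ref_codon": detail.ref_codon if detail else "",
                 "alt_codon": detail.alt_codon if detail else "",
                 "ref_aa": detail.ref_aa if detail else "",
                 "alt_aa": detail.alt_aa if detail else ""}
            )
    return pd.DataFrame(rows)


def consequence_proportions(annotations: pd.DataFrame) -> dict[str, float]:
    """Percentage of sites per consequence class, intergenic excluded."""
    tallied = annotations[annotations["consequence"] != "intergenic"]
    if tallied.empty:
        return {c: 0.0 for c in CONSEQUENCE_SEVERITY}
    frac = tallied["consequence"].value_counts(normalize=True) * 100.0
    return {c: float(frac.get(c, 0.0)) for c in CONSEQUENCE_SEVERITY}
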
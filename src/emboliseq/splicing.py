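"""Alternative-splicing event enumeration, PSI quantification, and
differential alternative splicing (DAS).

Events in the five classic geometries (SE, RI, A3SS, A5SS, MXE) are
enumerated by pairwise transcript comparison within each gene.  PSI is the
length-normalized inclusion fraction computed from junction reads only, and
groups are compared with a pooled binomial likelihood-ratio test; an event
is called DAS at BH-adjusted p < 0.01 and |ΔPSI| > 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import (
    CASE_GROUP,
    CTRL_GROUP,
    JunctionCounts,
    SampleDesign,
    SpliceEvent,
    TranscriptModel,
)
from .stats import benjamini_hochberg

READ_LENGTH = 120       # post-trimming read length
ANCHOR = 8              # minimum junction overhang per side
#: junction-mappable read start positions per junction
JUNCTION_POSITIONS = READ_LENGTH - 2 * ANCHOR + 1

DAS_PADJ_THRESHOLD = 0.01
DAS_DPSI_THRESHOLD = 0.1
MIN_EVENT_COVERAGE = 5


def _introns(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]


def _donor_acceptor(intron: tuple[int, int], strand: str) -> tuple[int, int]:
    """(donor, acceptor) genomic coordinates of an intron, strand-aware."""
    s, e = intron
    return (s, e) if strand == "+" else (e, s)


def _pair_events(t1: TranscriptModel, t2: TranscriptModel) -> list[dict]:
    """Raw events distinguishing a transcript pair (symmetric)."""
    events: list[dict] = []
    strand = t1.strand
    J = JUNCTION_POSITIONS
    i1, i2 = set(_introns(t1.exons)), set(_introns(t2.exons))

    for a, b in ((t1, t2), (t2, t1)):
        a_introns = set(_introns(a.exons))
        b_introns = set(_introns(b.exons))
        # SE: a has (flank.end→x.start) and (x.end→flank'.start); b splices
        # straight across the cassette exon x.
        for idx in range(1, len(a.exons) - 1):
            x = a.exons[idx]
            up_anchor = a.exons[idx - 1][1]
            down_anchor = a.exons[idx + 1][0]
            if (up_anchor, x[0]) in a_introns and (x[1], down_anchor) in a_introns \
                    and (up_anchor, down_anchor) in b_introns:
                events.append(
                    dict(
                        type="SE",
                        inclusion=((up_anchor, x[0]), x, (x[1], down_anchor)),
                        skipping=((up_anchor, down_anchor),),
                        li=2 * J,
                        ls=J,
                    )
                )
        # RI: a carries one exon spanning exactly two adjacent exons of b.
        for s2, e2 in zip(b.exons, b.exons[1:]):
            intron = (s2[1], e2[0])
            if (s2[0], e2[1]) in {tuple(e) for e in a.exons}:
                events.append(
                    dict(
                        type="RI",
                        inclusion=((s2[0], e2[1]), intron),
                        skipping=(s2, e2),
                        li=2 * J,
                        ls=J,
                    )
                )
        # MXE: shared flanks, one distinct non-overlapping middle exon each.
        for idx in range(1, len(a.exons) - 1):
            x = a.exons[idx]
            up_anchor = a.exons[idx - 1][1]
            down_anchor = a.exons[idx + 1][0]
            if (up_anchor, x[0]) not in a_introns or (x[1], down_anchor) not in a_introns:
                continue
            for jdx in range(1, len(b.exons) - 1):
                y = b.exons[jdx]
                if y == x or max(x[0], y[0]) < min(x[1], y[1]):
                    continue  # identical or overlapping
                if b.exons[jdx - 1][1] != up_anchor or b.exons[jdx + 1][0] != down_anchor:
                    continue
                if (up_anchor, y[0]) not in b_introns or (y[1], down_anchor) not in b_introns:
                    continue
                first, second = sorted([x, y])
                if strand == "-":
                    first, second = second, first  # 5'-most exon first
                events.append(
                    dict(
                        type="MXE",
                        inclusion=((up_anchor, first[0]), first, (first[1], down_anchor)),
                        skipping=((up_anchor, second[0]), second, (second[1], down_anchor)),
                        li=2 * J,
                        ls=2 * J,
                    )
                )

    # A5SS / A3SS: introns sharing one boundary where the alternative
    # exons share their far boundary (true splice-site shift, not a
    # cassette-exon junction pair); typed by which splice site (donor =
    # 5', acceptor = 3') moves, relative to the strand.
    def _flanks(tx: TranscriptModel) -> dict[tuple[int, int], tuple]:
        return {
            intron: (tx.exons[i], tx.exons[i + 1])
            for i, intron in enumerate(_introns(tx.exons))
        }

    f1, f2 = _flanks(t1), _flanks(t2)
    for in1 in i1:
        for in2 in i2:
            if in1 == in2:
                continue
            up1, down1 = f1[in1]
            up2, down2 = f2[in2]
            if in1[1] == in2[1] and in1[0] != in2[0] and up1[0] == up2[0]:
                # shared genomic end; upstream exon end shifts
                moved_donor = strand == "+"
            elif in1[0] == in2[0] and in1[1] != in2[1] and down1[1] == down2[1]:
                # shared genomic start; downstream exon start shifts
                moved_donor = strand == "-"
            else:
                continue
            etype = "A5SS" if moved_donor else "A3SS"
            # inclusion (long) form = shorter intron: exon extends inward
            long_iv, short_iv = sorted((in1, in2), key=lambda iv: iv[1] - iv[0])
            events.append(
                dict(
                    type=etype,
                    inclusion=(long_iv,),
                    skipping=(short_iv,),
                    li=JUNCTION_POSITIONS,
                    ls=JUNCTION_POSITIONS,
                )
            )
    return events


def enumerate_events(models: list[TranscriptModel]) -> list[SpliceEvent]:
    """Enumerate distinct splice events per gene by pairwise comparison."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tm in models:
        by_gene.setdefault(tm.gene_id, []).append(tm)

    seen: set[tuple] = set()
    out: list[SpliceEvent] = []
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        if len(txs) < 2:
            continue
        for t1, t2 in combinations(txs, 2):
            if t1.chrom != t2.chrom or t1.strand != t2.strand:
                continue
            for ev in _pair_events(t1, t2):
                key = (t1.chrom, ev["type"], ev["inclusion"], ev["skipping"])
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    SpliceEvent(
                        event_id=f"{ev['type']}_{len(out) + 1:05d}",
                        gene_id=gene_id,
                        event_type=ev["type"],
                        chrom=t1.chrom,
                        strand=t1.strand,
                        inclusion_coords=ev["inclusion"],
                        skipping_coords=ev["skipping"],
                        li=ev["li"],
                        ls=ev["ls"],
                    )
                )
    return out


def compute_psi(inclusion: int, skipping: int, li: int, ls: int) -> float:
    """Length-normalized percent spliced-in; NaN when no reads."""
    if inclusion + skipping == 0:
        return float("nan")
    num = inclusion / li
    return num / (num + skipping / ls)


def _psi_from_p(p: float, li: int, ls: int) -> float:
    """Invert the length-adjusted inclusion-read probability to PSI."""
    if not 0.0 <= p <= 1.0:
        return float("nan")
    num = p / li
    den = num + (1.0 - p) / ls
    return num / den if den > 0 else float("nan")


def _binom_ll(i: np.ndarray, t: np.ndarray, p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.sum(i * np.log(p) + (t - i) * np.log1p(-p)))


@dataclass
class DasResult:
    event_id: str
    gene_id: str
    event_type: str
    psi_per_sample: dict[str, float]
    mean_psi_case: float
    mean_psi_ctrl: float
    delta_psi: float
    lrt: float
    pvalue: float
    padj: float = float("nan")
    is_das: bool = False


def das_test(events: list[SpliceEvent], junctions: dict[str, JunctionCounts],
             design: SampleDesign, min_coverage: int = MIN_EVENT_COVERAGE) -> pd.DataFrame:
    """Pooled binomial LRT per event, BH over tested events, dual threshold.

    H0 pools inclusion reads across all samples with one inclusion
    probability; H1 allows one per group.  Events with no group reaching
    ``min_coverage`` in any sample are untestable (NaN p, excluded from BH).
    """
    rows: list[DasResult] = []
    case_ids = design.case_samples
    ctrl_ids = design.ctrl_samples
    for ev in events:
        jc = junctions.get(ev.event_id)
        if jc is None:
            continue
        psi = {
            s: compute_psi(jc.inclusion[s], jc.skipping[s], ev.li, ev.ls)
            for s in design.sample_ids
        }
        case_psi = [psi[s] for s in case_ids if np.isfinite(psi[s])]
        ctrl_psi = [psi[s] for s in ctrl_ids if np.isfinite(psi[s])]
        mean_case = float(np.mean(case_psi)) if case_psi else float("nan")
        mean_ctrl = float(np.mean(ctrl_psi)) if ctrl_psi else float("nan")
        delta = mean_case - mean_ctrl

        def _pool(samples):
            i = np.array([jc.inclusion[s] for s in samples], dtype=float)
            t = i + np.array([jc.skipping[s] for s in samples], dtype=float)
            return i, t

        i_case, t_case = _pool(case_ids)
        i_ctrl, t_ctrl = _pool(ctrl_ids)
        testable = (t_case >= min_coverage).any() and (t_ctrl >= min_coverage).any()
        if not testable or t_case.sum() == 0 or t_ctrl.sum() == 0:
            rows.append(DasResult(ev.event_id, ev.gene_id, ev.event_type, psi,
                                  mean_case, mean_ctrl, delta,
                                  float("nan"), float("nan")))
            continue
        p_case = i_case.sum() / t_case.sum()
        p_ctrl = i_ctrl.sum() / t_ctrl.sum()
        p_all = (i_case.sum() + i_ctrl.sum()) / (t_case.sum() + t_ctrl.sum())
        ll1 = _binom_ll(i_case, t_case, p_case) + _binom_ll(i_ctrl, t_ctrl, p_ctrl)
        ll0 = _binom_ll(i_case, t_case, p_all) + _binom_ll(i_ctrl, t_ctrl, p_all)
        lrt = max(0.0, 2.0 * (ll1 - ll0))
        pval = float(sps.chi2.sf(lrt, df=1))
        rows.append(DasResult(ev.event_id, ev.gene_id, ev.event_type, psi,
                              mean_case, mean_ctrl, delta, lrt, pval))

    df = pd.DataFrame(
        {
            "event_id": [r.event_id for r in rows],
            "gene_id": [r.gene_id for r in rows],
            "event_type": [r.event_type for r in rows],
            "mean_psi_case": [r.mean_psi_case for r in rows],
            "mean_psi_ctrl": [r.mean_psi_ctrl for r in rows],
            "delta_psi": [r.delta_psi for r in rows],
            "lrt": [r.lrt for r in rows],
            "pvalue": [r.pvalue for r in rows],
        }
    )
    df["padj"] = benjamini_hochberg(df["pvalue"].to_numpy())
    df["is_das"] = (
        (df["padj"] < DAS_PADJ_THRESHOLD)
        & (df["delta_psi"].abs() > DAS_DPSI_THRESHOLD)
        & df["padj"].notna()
    )
    return df


def summarize_dasg(das_table: pd.DataFrame) -> pd.DataFrame:
    """Gene-level DASG table: genes with >= 1 significant event, with
    per-type significant-event indicator columns (a gene may count in
    several types)."""
    sig = das_table[das_table["is_das"]]
    if sig.empty:
        return pd.DataFrame(
            columns=["gene_id", "n_sig_events", "SE", "RI", "A3SS", "A5SS", "MXE"]
        )
    rows = []
    for gene_id, sub in sig.groupby("gene_id"):
        types = set(sub["event_type"])
        rows.append(
            {
                "gene_id": gene_id,
                "n_sig_events": len(sub),
                **{t: (t in types) for t in ("SE", "RI", "A3SS", "A5SS", "MXE")},
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def dasg_type_counts(das_table: pd.DataFrame) -> dict[str, int]:
    """Number of DASGs per event type over significant events."""
    sig = das_table[das_table["is_das"]]
    return {
        t: int(sig.loc[sig["event_type"] == t, "gene_id"].nunique())
        for t in ("SE", "RI", "A3SS", "A5SS", "MXE")
    }
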
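"""lncRNA identification by a three-scorer coding-potential consensus,
differential-lncRNA calling, and the trans lncRNA–mRNA correlation network.

A transcript is kept as a lncRNA iff it is longer than 200 nt,
multi-exonic, carries neither an Rfam nor a Pfam homology hit, and all
three coding-potential scorers (ORF geometry, Fickett TESTCODE-style
position/composition statistic, in-frame hexamer usage) vote noncoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon import hexamer_log_ratios
from .models import PipelineError, TranscriptRecord
from .stats import pearson_pvalue

MIN_LNCRNA_LENGTH = 200          # "> 200 bp": strict
MIN_EXONS = 2
ORF_CODING_MIN_NT = 300
ORF_CODING_MIN_COVERAGE = 0.3
FICKETT_CODING_CUTOFF = 0.95     # classic TESTCODE "coding" bound
TRANS_R_THRESHOLD = 0.9
TRANS_P_THRESHOLD = 0.05

STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(sequence: str) -> tuple[int, int, int]:
    """Longest ATG..stop ORF over the three forward frames.

    Returns (start, end, length) in nt with end exclusive; the length
    includes the stop codon.  Ties go to the 5'-most start.  (0, 0, 0) if
    no ORF exists.
    """
    seq = sequence.upper()
    best = (0, 0, 0)
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOPS:
                length = i + 3 - start
                if length > best[2] or (length == best[2] and start < best[0]):
                    best = (start, i + 3, length)
                start = None
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE statistic
#
# Classic position/composition lookup: position parameter = max/min of the
# per-frame base counts, content parameter = base fraction; each is mapped
# to a coding probability through the published-style tables below and the
# eight probabilities are combined with per-base weights.

_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.60, 0.46, 0.38],
    "T": [0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_BOUNDS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.46, 0.45, 0.47, 0.56, 0.59, 0.33],
    "G": [0.21, 0.40, 0.47, 0.50, 0.52, 0.56, 0.57, 0.52, 0.44, 0.23],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.52, 0.57, 0.60, 0.51],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_BOUNDS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, bounds: list[float], probs: list[float]) -> float:
    for bound, prob in zip(bounds, probs):
        if value >= bound:
            return prob
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic on the full sequence (higher = coding)."""
    seq = sequence.upper()
    if len(seq) < 6:
        return 0.0
    score = 0.0
    for base in "ACGT":
        counts = [seq[frame::3].count(base) for frame in range(3)]
        position = max(counts) / (min(counts) + 1.0)
        content = seq.count(base) / len(seq)
        score += _lookup(position, _POSITION_BOUNDS, _POSITION_PROB[base]) \
            * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_BOUNDS, _CONTENT_PROB[base]) \
            * _CONTENT_WEIGHT[base]
    return score


def hexamer_score(sequence: str) -> float:
    """Mean in-frame hexamer log-ratio (coding vs uniform background).

    Computed over the longest ORF when it spans at least 60 nt, otherwise
    over frame 0 of the whole sequence; positive values indicate
    codon-structured text.
    """
    seq = sequence.upper()
    table = hexamer_log_ratios()
    start, end, length = longest_orf(seq)
    region = seq[start:end] if length >= 60 else seq
    vals = []
    for i in range(0, len(region) - 5, 3):
        h = region[i : i + 6]
        if h in table:
            vals.append(table[h])
    return float(np.mean(vals)) if vals else 0.0


@dataclass
class CodingPotentialScore:
    transcript_id: str
    orf_score: float       # longest-ORF coverage fraction of the transcript
    fickett: float
    hexamer: float
    orf_coding: bool
    fickett_coding: bool
    hexamer_coding: bool

    @property
    def n_coding_votes(self) -> int:
        return int(self.orf_coding) + int(self.fickett_coding) + int(self.hexamer_coding)

    @property
    def all_noncoding(self) -> bool:
        return self.n_coding_votes == 0


def coding_potential(record: TranscriptRecord) -> CodingPotentialScore:
    """Score one transcript with the three coding-potential methods."""
    seq = record.sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise PipelineError(
            f"transcript {record.transcript_id}: invalid symbols {sorted(bad)}"
        )
    if len(seq) < MIN_LNCRNA_LENGTH:
        raise PipelineError(
            f"transcript {record.transcript_id}: coding potential undefined "
            f"for sequences < {MIN_LNCRNA_LENGTH} nt"
        )
    _, _, orf_len = longest_orf(seq)
    coverage = orf_len / len(seq)
    fick = fickett_score(seq)
    hexa = hexamer_score(seq)
    return CodingPotentialScore(
        transcript_id=record.transcript_id,
        orf_score=coverage,
        fickett=fick,
        hexamer=hexa,
        orf_coding=(orf_len >= ORF_CODING_MIN_NT and coverage >= ORF_CODING_MIN_COVERAGE),
        fickett_coding=(fick >= FICKETT_CODING_CUTOFF),
        hexamer_coding=(hexa > 0.0),
    )


def identify_lncrnas(records: list[TranscriptRecord]) -> set[str]:
    """Consensus lncRNA gate.

    Keep a transcript iff length > 200 nt, >= 2 exons, no Rfam hit, no
    Pfam hit, and all three coding-potential verdicts are noncoding.
    """
    kept: set[str] = set()
    for rec in records:
        if rec.length <= MIN_LNCRNA_LENGTH:
            continue
        if rec.exon_count < MIN_EXONS:
            continue
        if rec.rfam_hit or rec.pfam_hit:
            continue
        if coding_potential(rec).all_noncoding:
            kept.add(rec.transcript_id)
    return kept


def detect_dels(lncrna_ids: set[str], de_table: pd.DataFrame) -> pd.DataFrame:
    """Differentially expressed lncRNAs: lncRNA ids with is_deg true."""
    sub = de_table[de_table["gene_id"].isin(lncrna_ids) & de_table["is_deg"]]
    return sub.reset_index(drop=True)


def trans_network(del_expr: pd.DataFrame, deg_expr: pd.DataFrame) -> pd.DataFrame:
    """All DEL × DEG Pearson correlations over samples, |r| > 0.9 and p < 0.05.

    Both inputs are id × sample frames on the log2(normalized count + 1)
    scale; zero-variance profiles are skipped.  Returns an edge list with
    columns lnc_id, gene_id, r, p, sign.
    """
    if del_expr.shape[1] < 3:
        raise PipelineError("need >= 3 samples for correlation testing")
    n = del_expr.shape[1]
    rows = []
    lnc_mat = del_expr.to_numpy(dtype=float)
    deg_mat = deg_expr.to_numpy(dtype=float)
    lnc_sd = lnc_mat.std(axis=1)
    deg_sd = deg_mat.std(axis=1)
    lnc_c = lnc_mat - lnc_mat.mean(axis=1, keepdims=True)
    deg_c = deg_mat - deg_mat.mean(axis=1, keepdims=True)
    for i, lnc_id in enumerate(del_expr.index):
        if lnc_sd[i] == 0:
            continue
        for j, gene_id in enumerate(deg_expr.index):
            if deg_sd[j] == 0 or lnc_id == gene_id:
                continue
            r = float(lnc_c[i] @ deg_c[j] / (n * lnc_sd[i] * deg_sd[j]))
            if abs(r) <= TRANS_R_THRESHOLD:
                continue
            p = pearson_pvalue(r, n)
            if p < TRANS_P_THRESHOLD:
                rows.append(
                    (lnc_id, gene_id, r, p, "positive" if r > 0 else "negative")
                )
    return pd.DataFrame(rows, columns=["lnc_id", "gene_id", "r", "p", "sign"])


def log_normalized_expression(counts, sf=None) -> pd.DataFrame:
    """log2(size-factor-normalized counts + 1), id × sample."""
    from .de import size_factors

    if sf is None:
        sf = size_factors(counts)
    norm = counts.counts / sf[None, :]
    return pd.DataFrame(
        np.log2(norm + 1.0), index=counts.gene_ids, columns=counts.sample_ids
    )
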
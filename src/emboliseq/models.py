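"""Domain types shared across the pipeline.

Coordinate convention: every internal interval is 0-based half-open
``[start, end)``.  External formats (GTF, VCF) are converted at the I/O
boundary; BED files are already half-open and pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CASE_GROUP = "PA-E"
CTRL_GROUP = "CTR"

EVENT_TYPES = ("SE", "RI", "A3SS", "A5SS", "MXE")

#: Consequence classes in decreasing severity; the most severe class wins
#: when a site is annotated against several transcripts.
CONSEQUENCE_SEVERITY = (
    "splice_acceptor",
    "missense",
    "synonymous",
    "five_prime_utr",
    "three_prime_utr",
    "intron",
    "upstream",
    "downstream",
)

MASK_CLASSES = ("bidirectional", "intron_flank", "ssr", "pseudogene")


class PipelineError(Exception):
    """Raised on contract violations anywhere in the pipeline."""


@dataclass
class GenomeModel:
    """A set of named chromosome sequences (uppercase A/C/G/T/N)."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise PipelineError("duplicate chromosome names")
        for name in self.chrom_names:
            seq = self.sequences.get(name, "")
            if not seq:
                raise PipelineError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise PipelineError(
                    f"chromosome {name!r} contains invalid symbols {sorted(bad)}"
                )

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence in internal (0-based half-open) coordinates."""
        return self.sequences[chrom][start:end]


@dataclass
class TranscriptModel:
    """A transcript: ordered exons on a strand, optionally with a CDS span.

    ``exons`` are 0-based half-open, sorted, non-overlapping.  ``cds_start``
    and ``cds_end`` (when set) delimit the genomic CDS span, also half-open;
    they are required for UTR/CDS consequence classes.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unknown"
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise PipelineError(f"bad strand {self.strand!r} on {self.transcript_id}")
        exons = sorted(self.exons)
        for (s, e) in exons:
            if s >= e:
                raise PipelineError(
                    f"empty exon [{s},{e}) on transcript {self.transcript_id}"
                )
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise PipelineError(
                    f"overlapping exons on transcript {self.transcript_id}"
                )
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        """Spliced (mature) length in nucleotides."""
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site (genomic position, strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def spliced_sequence(self, genome: GenomeModel) -> str:
        """Mature transcript sequence, reverse-complemented on minus strand."""
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.exons)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SampleDesign:
    """Sample → group assignment for the two-group comparison."""

    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise PipelineError("sample_ids and groups differ in length")
        bad = set(self.groups) - {CASE_GROUP, CTRL_GROUP}
        if bad:
            raise PipelineError(f"unknown group labels {sorted(bad)}")
        for grp in (CASE_GROUP, CTRL_GROUP):
            if self.groups.count(grp) < 2:
                raise PipelineError(f"group {grp} has fewer than 2 samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PipelineError("duplicate sample ids")

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    @property
    def case_samples(self) -> list[str]:
        return self.samples_in(CASE_GROUP)

    @property
    def ctrl_samples(self) -> list[str]:
        return self.samples_in(CTRL_GROUP)

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups])

    def swapped(self) -> "SampleDesign":
        """Design with case/control labels exchanged (antisymmetry checks)."""
        flip = {CASE_GROUP: CTRL_GROUP, CTRL_GROUP: CASE_GROUP}
        return SampleDesign(list(self.sample_ids), [flip[g] for g in self.groups])


@dataclass
class CountMatrix:
    """Genes × samples integer counts with the group design attached."""

    gene_ids: list[str]
    design: SampleDesign
    counts: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.design.sample_ids)):
            raise PipelineError("count matrix dimensions inconsistent with labels")
        if (self.counts < 0).any():
            raise PipelineError("negative counts")
        if self.counts.sum() == 0:
            raise PipelineError("all counts are zero")

    @property
    def sample_ids(self) -> list[str]:
        return self.design.sample_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class AlleleSite:
    """Biallelic SNV with per-sample (ref, alt) read counts."""

    chrom: str
    pos: int  # 0-based internal
    ref: str
    alt: str
    ref_counts: dict[str, int]
    alt_counts: dict[str, int]
    known_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise PipelineError(f"ref == alt at {self.chrom}:{self.pos}")
        for counts in (self.ref_counts, self.alt_counts):
            if any(c < 0 for c in counts.values()):
                raise PipelineError("negative allele counts")

    def depth(self, sample: str) -> int:
        return self.ref_counts[sample] + self.alt_counts[sample]

    def aaf(self, sample: str) -> float:
        d = self.depth(sample)
        return self.alt_counts[sample] / d if d > 0 else float("nan")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class SpliceEvent:
    """One alternative-splicing event in rMATS-style geometry.

    ``inclusion_coords`` / ``skipping_coords`` are tuples of half-open
    genomic intervals identifying the two isoform-specific forms; the
    effective lengths ``li`` / ``ls`` count junction-mappable read start
    positions for each form.
    """

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    inclusion_coords: tuple
    skipping_coords: tuple
    li: int
    ls: int

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise PipelineError(f"unknown event type {self.event_type!r}")
        if self.li < 1 or self.ls < 1:
            raise PipelineError("effective lengths must be >= 1")

    @property
    def coord_key(self) -> tuple:
        return (
            self.chrom,
            self.event_type,
            self.inclusion_coords,
            self.skipping_coords,
        )


@dataclass
class JunctionCounts:
    """Per-sample inclusion / skipping junction read counts for one event."""

    event_id: str
    inclusion: dict[str, int]
    skipping: dict[str, int]

    def __post_init__(self) -> None:
        for counts in (self.inclusion, self.skipping):
            if any(c < 0 for c in counts.values()):
                raise PipelineError("negative junction counts")


@dataclass
class RegionMask:
    """Named class of genomic intervals (half-open) per chromosome."""

    mask_class: str
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask_class not in MASK_CLASSES:
            raise PipelineError(f"unknown mask class {self.mask_class!r}")
        for chrom, ivs in self.intervals.items():
            for s, e in ivs:
                if s >= e:
                    raise PipelineError(
                        f"empty mask interval [{s},{e}) on {chrom}"
                    )
            self.intervals[chrom] = sorted(ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        for s, e in self.intervals.get(chrom, ()):
            if s <= pos < e:
                return True
            if s > pos:
                break
        return False


@dataclass
class TranscriptRecord:
    """Spliced transcript sequence with homology flags, for the lncRNA gate."""

    transcript_id: str
    sequence: str
    exon_count: int
    rfam_hit: bool = False
    pfam_hit: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


def as_interval_key(intervals: Sequence[tuple[int, int]]) -> tuple:
    return tuple((int(s), int(e)) for s, e in intervals)
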
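"""Biased codon-usage model shared by the sequence simulator and the
hexamer coding-potential scorer.

Frequencies are approximate mammalian codon usage (occurrences per
thousand codons); stop codons are listed but never drawn for ORF
interiors.  The hexamer background tables for the coding-potential scorer
are derived from this table in closed form, so scorer and generator share
one model by construction.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

STOP_CODONS = ("TAA", "TAG", "TGA")

# per-thousand usage, mammalian-like bias
CODON_USAGE: dict[str, float] = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "TAA": 1.0, "TAG": 0.8,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGA": 1.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}

SENSE_CODONS = tuple(c for c in CODON_USAGE if c not in STOP_CODONS)


@lru_cache(maxsize=1)
def sense_codon_probs() -> dict[str, float]:
    """Probability of each sense codon under the usage model."""
    total = sum(CODON_USAGE[c] for c in SENSE_CODONS)
    return {c: CODON_USAGE[c] / total for c in SENSE_CODONS}


@lru_cache(maxsize=1)
def coding_nucleotide_probs() -> dict[str, float]:
    """Mononucleotide marginal of the codon model (composition target)."""
    probs = sense_codon_probs()
    acc = {b: 0.0 for b in "ACGT"}
    for codon, p in probs.items():
        for base in codon:
            acc[base] += p / 3.0
    return acc


@lru_cache(maxsize=1)
def hexamer_log_ratios() -> dict[str, float]:
    """log(P_coding(h) / P_background(h)) for every hexamer.

    Coding probability of a hexamer is the product of two adjacent in-frame
    sense-codon probabilities; the background is the uniform hexamer
    distribution (1/4096).  Hexamers containing a stop codon in frame get
    the smallest coding probability seen, to keep the ratio finite.
    """
    probs = sense_codon_probs()
    background = 1.0 / 4096.0
    floor = min(probs.values()) ** 2
    out: dict[str, float] = {}
    for a, b in product(CODON_USAGE, CODON_USAGE):
        p = probs.get(a, 0.0) * probs.get(b, 0.0)
        out[a + b] = float(np.log(max(p, floor * 1e-3) / background))
    return out
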
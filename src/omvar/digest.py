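"""In silico digestion: motif scanning, resolution merging, inaccessible regions.

A nicking endonuclease (default Nt.BspQI, recognition site GCTCTTC) defines
the label pattern of an optical map. The in silico reference map records the
start offsets of all motif occurrences on both strands, merges occurrences
closer than the instrument resolution (450 bp) into one label at the chain
midpoint, and excludes occurrences overlapping runs of N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .models import LabelMap

DEFAULT_MOTIF = "GCTCTTC"
DEFAULT_RESOLUTION_BP = 450.0

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class InaccessibleRegion:
    chrom: str
    start: int
    end: int
    reason: str  # sequence_gap_ge_50kb | label_desert_ge_100kb

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceDigest:
    """Per-chromosome label maps plus the N-gap inventory of the source sequence."""

    chromosomes: Dict[str, LabelMap]
    n_gap_intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    motif: str = DEFAULT_MOTIF

    def chrom_ids(self) -> List[str]:
        return list(self.chromosomes)

    def total_length(self) -> float:
        return sum(m.length_bp for m in self.chromosomes.values())


def scan_motif(sequence: str, motif: str = DEFAULT_MOTIF) -> np.ndarray:
    """Start offsets of motif occurrences on both strands, N-overlaps excluded.

    Returns the sorted union of forward-strand match starts and
    reverse-complement match starts (both reported on the forward strand).
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"degenerate characters in motif {motif!r} are unsupported")
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over the alphabet {A,C,G,T,N}")
    hits = set()
    for m in (motif, reverse_complement(motif)):
        pat = re.compile("(?=" + m + ")")
        hits.update(match.start() for match in pat.finditer(seq))
    return np.array(sorted(hits), dtype=float)


def merge_labels(positions, resolution: float = DEFAULT_RESOLUTION_BP) -> np.ndarray:
    """Collapse maximal chains of labels with consecutive gaps <= resolution.

    Each chain is replaced by a single label at the midpoint of its first and
    last member; output gaps are therefore all > resolution. Idempotent.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        return pos.copy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    out = []
    chain_start = pos[0]
    prev = pos[0]
    for p in pos[1:]:
        if p - prev <= resolution:
            prev = p
        else:
            out.append(0.5 * (chain_start + prev))
            chain_start = prev = p
    out.append(0.5 * (chain_start + prev))
    merged = np.array(out)
    # merging can create new sub-resolution adjacencies between chain midpoints
    while merged.size > 1 and np.any(np.diff(merged) <= resolution):
        merged = merge_labels(merged, resolution)
    return merged


def find_n_gaps(sequence: str) -> List[Tuple[int, int]]:
    """Half-open intervals of runs of N in a sequence."""
    return [(m.start(), m.end()) for m in re.finditer("N+", sequence.upper())]


def digest_sequence(
    sequences: Dict[str, str],
    motif: str = DEFAULT_MOTIF,
    resolution: float = DEFAULT_RESOLUTION_BP,
) -> ReferenceDigest:
    """Build the in silico reference map of a genome.

    N-gap exclusion happens before resolution merging: occurrences whose match
    window overlaps an N cannot exist and never participate in a merge chain.
    """
    chromosomes = {}
    gaps = {}
    for chrom, seq in sequences.items():
        pos = scan_motif(seq, motif)  # N-overlapping windows never match
        merged = merge_labels(pos, resolution)
        length = float(len(seq))
        merged = merged[(merged >= 0) & (merged < length)]
        chromosomes[chrom] = LabelMap(chrom, "reference", length, merged)
        gaps[chrom] = find_n_gaps(seq)
    return ReferenceDigest(chromosomes, gaps, motif)


def digest_fasta(path, motif: str = DEFAULT_MOTIF, resolution: float = DEFAULT_RESOLUTION_BP) -> ReferenceDigest:
    from Bio import SeqIO

    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return digest_sequence(sequences, motif, resolution)


def find_inaccessible(
    digest: ReferenceDigest,
    gap_min: float = 50_000,
    desert_min: float = 100_000,
) -> List[InaccessibleRegion]:
    """Mapping-inaccessible reference regions.

    Two reasons, reported separately even when they overlap: sequence N-gaps
    of at least ``gap_min`` bp, and maximal label-free stretches (label
    deserts) of at least ``desert_min`` bp.
    """
    regions: List[InaccessibleRegion] = []
    for chrom, lm in digest.chromosomes.items():
        for start, end in digest.n_gap_intervals.get(chrom, []):
            if end - start >= gap_min:
                regions.append(InaccessibleRegion(chrom, start, end, "sequence_gap_ge_50kb"))
        bounds = np.concatenate(([0.0], lm.positions, [lm.length_bp]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi - lo >= desert_min:
                regions.append(InaccessibleRegion(chrom, int(lo), int(hi), "label_desert_ge_100kb"))
    return regions
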
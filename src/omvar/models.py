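"""Core domain containers for nick-label optical maps and SV calls.

All coordinates are 0-based, half-open, in basepairs. Format writers alone
perform any 1-based conversion (see :mod:`omvar.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SV_TYPES = (
    "insertion",
    "deletion",
    "inversion",
    "duplication",
    "intra_translocation",
    "inter_translocation",
    "multi_indel",
)
ZYGOSITIES = ("hom", "het", "tri", "unknown")
MODULES = ("MR", "CR", "MCR", "complex")


@dataclass
class LabelMap:
    """Ordered nick-label positions on one named map.

    Parameters
    ----------
    map_id : str
        Identifier of the map (chromosome, molecule, or contig name).
    kind : {"reference", "molecule", "contig"}
    length_bp : float
        Total map length in bp.
    positions : ndarray
        Strictly increasing label offsets from the map start, in bp.
    sample_id : str, optional
        Sample of origin for molecule/contig maps.
    """

    map_id: str
    kind: str
    length_bp: float
    positions: np.ndarray
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.kind not in ("reference", "molecule", "contig"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        self.validate()

    def validate(self) -> None:
        p = self.positions
        if p.size:
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"map {self.map_id}: positions not strictly increasing")
            if p[0] < 0 or p[-1] >= self.length_bp:
                raise ValueError(
                    f"map {self.map_id}: positions outside [0, {self.length_bp})"
                )

    @property
    def n_labels(self) -> int:
        return int(self.positions.size)

    def reversed(self) -> "LabelMap":
        """The same physical map read from the other end."""
        pos = np.sort(self.length_bp - self.positions)
        # guard against a label landing exactly at length_bp when position 0 exists
        pos = np.clip(pos, 0.0, np.nextafter(self.length_bp, 0.0))
        return LabelMap(self.map_id, self.kind, self.length_bp, pos, self.sample_id)


@dataclass
class Alignment:
    """Orientation-aware label correspondence between a query and a reference map.

    ``pairs`` lists (query_label_index, ref_label_index), monotone increasing
    in the ref index; for orientation "-" the query indices decrease.
    """

    query_id: str
    ref_id: str
    orientation: str  # "+" or "-"
    pairs: list  # list[tuple[int, int]]
    score: float
    confidence: float = float("nan")
    ref_start_bp: float = 0.0
    ref_end_bp: float = 0.0
    n_matched: int = 0
    n_extra_query: int = 0
    n_missed_ref: int = 0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("alignment must contain at least one pair")
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")
        self.n_matched = len(self.pairs)

    @property
    def query_indices(self) -> list:
        return [q for q, _ in self.pairs]

    @property
    def ref_indices(self) -> list:
        return [r for _, r in self.pairs]


@dataclass
class SplitAlignment:
    """A query aligned in pieces to different reference locations/orientations."""

    query_id: str
    segments: list  # list[Alignment], ordered by query coordinate
    breakpoints: list = field(default_factory=list)  # reference (chrom, bp) junctions


@dataclass
class SVCall:
    sv_type: str
    chrom: str
    start_bp: float
    end_bp: float
    size_delta_bp: float
    zygosity: str
    support_count: int
    score: float
    module: str
    chrom2: Optional[str] = None  # partner chromosome for inter-translocations
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.module not in MODULES:
            raise ValueError(f"unknown module {self.module!r}")
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    def reciprocal_overlap(self, other: "SVCall") -> float:
        if self.chrom != other.chrom:
            return 0.0
        lo = max(self.start_bp, other.start_bp)
        hi = min(self.end_bp, other.end_bp)
        if hi < lo:
            return 0.0
        ov = hi - lo
        span1 = max(self.end_bp - self.start_bp, 1.0)
        span2 = max(other.end_bp - other.start_bp, 1.0)
        return min(ov / span1, ov / span2)


@dataclass
class CohortMetadata:
    """sample_id -> (population, super_population, sex)."""

    entries: dict  # sample_id -> dict(population=..., super_population=..., sex=...)

    SUPER_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

    def population(self, sample_id: str) -> str:
        return self.entries[sample_id]["population"]

    def super_population(self, sample_id: str) -> str:
        return self.entries[sample_id]["super_population"]

    def samples(self) -> list:
        return sorted(self.entries)

    def require(self, sample_ids: Sequence[str]) -> None:
        missing = [s for s in sample_ids if s not in self.entries]
        if missing:
            raise KeyError(f"samples without cohort metadata: {missing}")
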
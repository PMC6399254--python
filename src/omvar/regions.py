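"""Genome classification: inaccessible / low-coverage / low-complexity /
complex-candidate regions, feature annotation, permutation enrichment, and
map-based N-gap sizing.

The classification mirrors a population optical-mapping study design: a locus
covered by two or more consensus meta-scaffolds, or by none despite high
per-sample assembly coverage, is a candidate for structural complexity; a
candidate is confirmed when it harbors at least three distinct recurrent SVs
(indels only counting above 10 kb, and an all-indel region needing one over
100 kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import Alignment, LabelMap

INDEL_TYPES = ("insertion", "deletion", "multi_indel")


@dataclass
class RegionClassification:
    intervals: pd.DataFrame  # chrom, start, end, region_class

    def total_length(self, region_class: Optional[str] = None) -> float:
        df = self.intervals
        if region_class is not None:
            df = df[df["region_class"] == region_class]
        return float((df["end"] - df["start"]).sum())


def _mask_to_intervals(chrom: str, labels: np.ndarray) -> List[Tuple[str, int, int, str]]:
    out = []
    if labels.size == 0:
        return out
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate(([0], change, [labels.size]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out.append((chrom, int(lo), int(hi), str(labels[lo])))
    return out


def classify_coverage_state(
    indiv_cov: Dict[str, np.ndarray],
    consensus_scaffold_count: Dict[str, np.ndarray],
    cov_threshold: float = 92.0,
    cov_threshold_by_chrom: Optional[Dict[str, float]] = None,
    inaccessible: Optional[Sequence[Tuple[str, int, int]]] = None,
    n_samples: Optional[int] = None,
    fraction: float = 0.6,
) -> RegionClassification:
    """Pre-complex classification from per-bp coverage tracks.

    ``indiv_cov`` counts samples with an aligned individual assembly at each
    bp; ``consensus_scaffold_count`` counts consensus meta-scaffolds. The
    coverage threshold defaults to 92 (i.e. 60% of a 154-sample cohort) and
    may be overridden per chromosome (46 on chrY) or derived from
    ``n_samples``x``fraction``. Scaffold count >= 2, or 0 with high coverage,
    yields a complex candidate; low coverage wins below threshold; exactly
    one scaffold with high coverage is low complexity. Inaccessible intervals
    override everything.
    """
    rows = []
    for chrom, cov in indiv_cov.items():
        scaf = consensus_scaffold_count[chrom]
        if len(scaf) != len(cov):
            raise ValueError(f"{chrom}: coverage and scaffold tracks differ in length")
        thr = cov_threshold
        if n_samples is not None:
            thr = n_samples * fraction
        if cov_threshold_by_chrom and chrom in cov_threshold_by_chrom:
            thr = cov_threshold_by_chrom[chrom]
        labels = np.where(
            scaf >= 2, "complex_candidate",
            np.where(
                cov < thr, "low_coverage",
                np.where(scaf == 0, "complex_candidate", "low_complexity"),
            ),
        )
        if inaccessible:
            for ichrom, lo, hi in inaccessible:
                if ichrom == chrom:
                    labels[max(lo, 0) : min(hi, labels.size)] = "inaccessible"
        rows.extend(_mask_to_intervals(chrom, labels))
    return RegionClassification(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "region_class"])
    )


def flag_complex_candidate(region: Tuple[str, float, float], sv_inventory: Sequence[dict]) -> bool:
    """Confirm a candidate region against the cohort SV inventory.

    ``sv_inventory`` entries carry ``sv_type``, ``size`` (bp, absolute) and
    ``cohort_count`` (samples in which the SV occurs). Rules: drop singletons
    (count < 2); drop indels of 10 kb or less; at least 3 distinct SVs must
    remain; and if all remaining SVs are indels, at least one must exceed
    100 kb.
    """
    kept = []
    for sv in sv_inventory:
        if sv.get("cohort_count", 1) < 2:
            continue
        if sv["sv_type"] in INDEL_TYPES and abs(sv.get("size", 0.0)) <= 10_000:
            continue
        kept.append(sv)
    if len(kept) < 3:
        return False
    if all(sv["sv_type"] in INDEL_TYPES for sv in kept):
        return any(abs(sv.get("size", 0.0)) > 100_000 for sv in kept)
    return True


# ---------------------------------------------------------------------------
# Permutation feature-overlap test
# ---------------------------------------------------------------------------

def _allowed_gaps(
    chrom_lengths: Dict[str, float],
    excluded: Sequence[Tuple[str, int, int]],
) -> List[Tuple[str, float, float]]:
    gaps = []
    by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for chrom, lo, hi in excluded:
        if chrom in by_chrom:
            by_chrom[chrom].append((int(lo), int(hi)))
    for chrom, L in chrom_lengths.items():
        cur = 0
        for lo, hi in sorted(by_chrom[chrom]):
            if lo > cur:
                gaps.append((chrom, float(cur), float(lo)))
            cur = max(cur, hi)
        if cur < L:
            gaps.append((chrom, float(cur), float(L)))
    return gaps


def _count_overlaps(
    regions: Sequence[Tuple[str, float, float]],
    feature_by_chrom: Dict[str, np.ndarray],
) -> int:
    n = 0
    for chrom, lo, hi in regions:
        feats = feature_by_chrom.get(chrom)
        if feats is None or feats.size == 0:
            continue
        starts, ends = feats[:, 0], feats[:, 1]
        n += int(np.sum((starts < hi) & (ends > lo)))
    return n


def permutation_overlap_test(
    regions: Sequence[Tuple[str, float, float]],
    feature: Sequence[Tuple[str, float, float]],
    excluded: Sequence[Tuple[str, int, int]],
    chrom_lengths: Dict[str, float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical p for feature overlap of the regions vs uniform re-placement.

    Each permutation independently re-places every region uniformly in the
    allowed space (lengths preserved, excluded space avoided, regions may
    overlap each other); the statistic is the number of (region, feature)
    overlapping pairs, and p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    feature_by_chrom: Dict[str, np.ndarray] = {}
    for chrom, lo, hi in feature:
        feature_by_chrom.setdefault(chrom, []).append((float(lo), float(hi)))
    feature_by_chrom = {c: np.array(v) for c, v in feature_by_chrom.items()}
    observed = _count_overlaps(regions, feature_by_chrom)
    gaps = _allowed_gaps(chrom_lengths, excluded)
    count_ge = 0
    lens = [hi - lo for _, lo, hi in regions]
    for L in lens:
        if not any(g[2] - g[1] >= L for g in gaps):
            raise ValueError(f"no allowed gap can hold a region of length {L}")
    for _ in range(n_perm):
        placed = []
        for L in lens:
            weights = np.array([max(g[2] - g[1] - L, 0.0) + 1.0 if g[2] - g[1] >= L else 0.0 for g in gaps])
            gi = rng.choice(len(gaps), p=weights / weights.sum())
            chrom, glo, ghi = gaps[gi]
            start = rng.uniform(glo, ghi - L) if ghi - glo > L else glo
            placed.append((chrom, start, start + L))
        if _count_overlaps(placed, feature_by_chrom) >= observed:
            count_ge += 1
    return (1 + count_ge) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------

def annotate_region_features(
    regions: Sequence[Tuple[str, float, float]],
    segdups: Optional[pd.DataFrame] = None,
    tandem_repeats: Optional[pd.DataFrame] = None,
    chrom_lengths: Optional[Dict[str, float]] = None,
    centromeres: Optional[Dict[str, float]] = None,
    sd_min_length: float = 10_000.0,
    sd_min_identity: float = 0.95,
    tr_min_score: float = 2_000.0,
    subtelomeric_bp: float = 7_000_000.0,
    pericentromeric_bp: float = 9_000_000.0,
) -> pd.DataFrame:
    """Per-region overlap lengths with filtered feature tracks and zone flags.

    Segmental duplications are filtered to length >= 10 kb and identity >=
    0.95 (``identity`` column required); tandem repeats to score > 2000
    (``score`` column required). Subtelomeric means within 7 Mb of a
    chromosome end, pericentromeric within 9 Mb of the centromere midpoint.
    """

    def _overlap_len(chrom, lo, hi, df):
        if df is None or df.empty:
            return 0.0
        sub = df[df["chrom"] == chrom]
        if sub.empty:
            return 0.0
        s = np.maximum(sub["start"].to_numpy(float), lo)
        e = np.minimum(sub["end"].to_numpy(float), hi)
        return float(np.clip(e - s, 0, None).sum())

    if segdups is not None and not segdups.empty:
        if "identity" not in segdups.columns:
            raise KeyError("segdups must carry an 'identity' column")
        segdups = segdups[
            ((segdups["end"] - segdups["start"]) >= sd_min_length)
            & (segdups["identity"].astype(float) >= sd_min_identity)
        ]
    if tandem_repeats is not None and not tandem_repeats.empty:
        if "score" not in tandem_repeats.columns:
            raise KeyError("tandem_repeats must carry a 'score' column")
        tandem_repeats = tandem_repeats[tandem_repeats["score"].astype(float) > tr_min_score]

    rows = []
    for chrom, lo, hi in regions:
        subtel = peri = False
        if chrom_lengths is not None and chrom in chrom_lengths:
            L = chrom_lengths[chrom]
            subtel = lo < subtelomeric_bp or hi > L - subtelomeric_bp
        if centromeres is not None and chrom in centromeres:
            c = centromeres[chrom]
            peri = lo < c + pericentromeric_bp and hi > c - pericentromeric_bp
        rows.append(
            {
                "chrom": chrom, "start": lo, "end": hi,
                "segdup_bp": _overlap_len(chrom, lo, hi, segdups),
                "tandem_repeat_bp": _overlap_len(chrom, lo, hi, tandem_repeats),
                "subtelomeric": bool(subtel), "pericentromeric": bool(peri),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Map-based N-gap sizing
# ---------------------------------------------------------------------------

def estimate_gap_size(
    gap: Tuple[str, float, float],
    spanning_alignments: Sequence[Alignment],
    ref_map: LabelMap,
    query_maps: Dict[str, LabelMap],
) -> Optional[float]:
    """Map-based size of a reference N-gap from spanning alignments.

    For each alignment pairing a label on each side of the gap, the estimate
    is (query distance between the innermost flanking paired labels) minus
    (the reference distance those labels cover outside the gap). Negative
    sizes indicate deletions swallowing the gap flanks. Returns the median
    estimate, or None when nothing spans.
    """
    chrom, glo, ghi = gap
    rpos = ref_map.positions
    estimates = []
    for a in spanning_alignments:
        if a.ref_id != chrom:
            continue
        qpos = query_maps[a.query_id].positions
        left = [(q, r) for q, r in a.pairs if rpos[r] <= glo]
        right = [(q, r) for q, r in a.pairs if rpos[r] >= ghi]
        if not left or not right:
            continue
        ql, rl = max(left, key=lambda p: rpos[p[1]])
        qr, rr = min(right, key=lambda p: rpos[p[1]])
        qdist = abs(float(qpos[qr] - qpos[ql]))
        ref_outside = float((glo - rpos[rl]) + (rpos[rr] - ghi))
        estimates.append(qdist - ref_outside)
    if not estimates:
        return None
    return float(np.median(estimates))
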
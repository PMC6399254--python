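"""Complex-SV detection from split alignments.

Split alignments of long consensus contigs nominate candidate inversions,
duplications, and translocations; single molecules around the candidate
breakpoints then vote. A molecule split consistently with the candidate
supports it, a molecule contiguously aligned across a breakpoint rejects it,
and each molecule contributes the score

    S_M = min over the two adjacent split maps of  n/(n+l) * ln(n)

where n counts mapping (matched) sites on the split map and l its extra or
missing sites. The candidate is accepted iff the summed supporting score
exceeds the summed rejecting score (S_s > S_r, strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .align import AlignParams
from .models import Alignment, LabelMap, SplitAlignment, SVCall

INV_MAX_SPAN_BP = 5_000_000.0


@dataclass
class ComplexCandidate:
    candidate_type: str  # inversion | intra_translocation | inter_translocation | duplication
    breakpoints: List[Tuple[str, float]]  # one or two (chrom, bp)
    source_contig: str
    supporting: List[Tuple[str, float]] = field(default_factory=list)
    rejecting: List[Tuple[str, float]] = field(default_factory=list)

    @property
    def s_s(self) -> float:
        return float(sum(s for _, s in self.supporting))

    @property
    def s_r(self) -> float:
        return float(sum(s for _, s in self.rejecting))


def _segment_span(seg: Alignment) -> Tuple[float, float]:
    return (min(seg.ref_start_bp, seg.ref_end_bp), max(seg.ref_start_bp, seg.ref_end_bp))


def classify_pair(left: Alignment, right: Alignment) -> Optional[str]:
    """Signature of one pair of query-consecutive split segments.

    Decided on the junction vector d = (right junction bp) - (left junction
    bp): different chromosomes give an inter-chromosomal break end, |d| over
    5 Mb an intra-chromosomal one, an orientation flip within 5 Mb an
    inversion, and a backward jump onto overlapping same-orientation
    intervals a duplication.
    """
    if left.ref_id != right.ref_id:
        return "inter_translocation"
    left_bp = left.ref_end_bp if left.orientation == "+" else left.ref_start_bp
    right_bp = right.ref_start_bp if right.orientation == "+" else right.ref_end_bp
    d = right_bp - left_bp
    if abs(d) > INV_MAX_SPAN_BP:
        return "intra_translocation"
    if left.orientation != right.orientation:
        return "inversion"
    l0, l1 = _segment_span(left)
    r0, r1 = _segment_span(right)
    if d < 0 and min(l1, r1) > max(l0, r0):
        return "duplication"
    return None


def classify_split_signature(sa: SplitAlignment) -> Optional[str]:
    """Candidate type of a split alignment (first classifiable adjacent pair)."""
    if len(sa.segments) < 2:
        return None
    for left, right in zip(sa.segments[:-1], sa.segments[1:]):
        t = classify_pair(left, right)
        if t is not None:
            return t
    return None


def split_molecule_score(split_maps: Sequence[Tuple[int, int]]) -> float:
    """Per-molecule split score: min over adjacent pairs of min_i [n/(n+l)] ln n.

    ``split_maps`` lists (n_sites, n_errors) per split map in query order;
    with more than two maps the score is the minimum over adjacent pairs.
    """
    if len(split_maps) < 2:
        raise ValueError("need at least two adjacent split maps")
    vals = []
    for n, l in split_maps:
        if n < 1:
            raise ValueError("a split map must have at least one mapping site")
        if l < 0:
            raise ValueError("error count cannot be negative")
        vals.append(n / (n + l) * np.log(n))
    return float(min(min(a, b) for a, b in zip(vals[:-1], vals[1:])))


def _seg_nl(seg: Alignment) -> Tuple[int, int]:
    return seg.n_matched, seg.n_extra_query + seg.n_missed_ref


def junction_breakpoints(left: Alignment, right: Alignment) -> List[Tuple[str, float]]:
    """Reference coordinates where two query-consecutive segments abut.

    For a duplication (overlapping same-orientation intervals) the
    breakpoints are the ends of the duplicated unit (interval overlap);
    otherwise the junction-facing ends of the two segments.
    """
    t = classify_pair(left, right)
    if t == "duplication":
        l0, l1 = _segment_span(left)
        r0, r1 = _segment_span(right)
        return [(left.ref_id, max(l0, r0)), (left.ref_id, min(l1, r1))]
    left_bp = left.ref_end_bp if left.orientation == "+" else left.ref_start_bp
    right_bp = right.ref_start_bp if right.orientation == "+" else right.ref_end_bp
    return [(left.ref_id, float(left_bp)), (right.ref_id, float(right_bp))]


def candidates_from_contigs(
    split_alignments: Sequence[Union[Alignment, SplitAlignment]],
    merge_bp: float = 100_000.0,
) -> List[ComplexCandidate]:
    """Candidate complex SVs from contig split alignments, de-duplicated by
    type and breakpoint proximity."""
    cands: List[ComplexCandidate] = []
    for sa in split_alignments:
        if not isinstance(sa, SplitAlignment):
            continue
        for left, right in zip(sa.segments[:-1], sa.segments[1:]):
            t = classify_pair(left, right)
            if t is None:
                continue
            bp = junction_breakpoints(left, right)
            cand = ComplexCandidate(t, bp, sa.query_id)
            dup = None
            for c in cands:
                if c.candidate_type != t:
                    continue
                if all(
                    any(b1[0] == b2[0] and abs(b1[1] - b2[1]) <= merge_bp for b2 in c.breakpoints)
                    for b1 in cand.breakpoints
                ):
                    dup = c
                    break
            if dup is None:
                cands.append(cand)
    return cands


def _molecule_vote(
    mol_aln: Union[Alignment, SplitAlignment],
    cand: ComplexCandidate,
    window_bp: float,
) -> Tuple[Optional[str], float]:
    """(side, score) of one molecule for a candidate; side None = abstain."""
    if isinstance(mol_aln, SplitAlignment):
        best = -np.inf
        found = False
        for i, (left, right) in enumerate(
            zip(mol_aln.segments[:-1], mol_aln.segments[1:])
        ):
            t = classify_pair(left, right)
            if t != cand.candidate_type:
                continue
            junction = junction_breakpoints(left, right)
            near = any(
                j[0] == b[0] and abs(j[1] - b[1]) <= window_bp
                for j in junction
                for b in cand.breakpoints
            )
            if not near:
                continue
            s = split_molecule_score([_seg_nl(left), _seg_nl(right)])
            best = max(best, s)
            found = True
        if found:
            return "support", float(best)
        return None, 0.0
    # contiguous alignment: rejecting if it spans the breakpoint(s); notionally
    # split at the breakpoint to score it with the same formula. For a
    # duplication the informative wild-type molecule must span the whole unit
    # (crossing a single breakpoint inside one copy is reference-like for
    # carriers too), so both breakpoints are required.
    a = mol_aln
    best = -np.inf
    found = False
    if cand.candidate_type == "duplication":
        # a single tandem copy with its flank looks reference-like and spans
        # the unit coordinates; a genuine wild-type witness must anchor well
        # outside the unit on both sides
        margin = 20_000.0
        chroms = {c for c, _ in cand.breakpoints}
        bps = [b for _, b in cand.breakpoints]
        if a.ref_id in chroms and len(chroms) == 1:
            lo, hi = _segment_span(a)
            if lo < min(bps) - margin and hi > max(bps) + margin:
                test_bps = [(a.ref_id, float(np.mean(bps)))]
            else:
                test_bps = []
        else:
            test_bps = []
    else:
        test_bps = cand.breakpoints
    for chrom, bp in test_bps:
        if a.ref_id != chrom:
            continue
        lo, hi = _segment_span(a)
        if not (lo < bp < hi):
            continue
        ref_positions = a.pair_ref_positions  # attached by adjudicate
        left_pairs = [(q, r) for (q, r), rp in zip(a.pairs, ref_positions) if rp <= bp]
        right_pairs = [(q, r) for (q, r), rp in zip(a.pairs, ref_positions) if rp > bp]
        if len(left_pairs) < 1 or len(right_pairs) < 1:
            continue

        def nl(pairs):
            n = len(pairs)
            qs = sorted(q for q, _ in pairs)
            rs = sorted(r for _, r in pairs)
            l = (qs[-1] - qs[0] + 1 - n) + (rs[-1] - rs[0] + 1 - n)
            return n, l

        s = split_molecule_score([nl(left_pairs), nl(right_pairs)])
        best = max(best, s)
        found = True
    if found:
        return "reject", float(best)
    return None, 0.0


def adjudicate_candidate(
    cand: ComplexCandidate,
    molecule_alignments: Sequence[Union[Alignment, SplitAlignment]],
    ref_maps: Dict[str, LabelMap],
    window_bp: float = 200_000.0,
) -> Optional[SVCall]:
    """Vote molecules around the breakpoints and apply the S_s > S_r rule.

    Molecules are de-duplicated keeping the largest score; a molecule voting
    on both sides goes to the side with the higher score. Returns the call or
    None (rejected or no molecules in the window).
    """
    votes: Dict[str, Tuple[str, float]] = {}
    for a in molecule_alignments:
        segs = a.segments if isinstance(a, SplitAlignment) else [a]
        for s in segs:
            if not hasattr(s, "pair_ref_positions"):
                rp = ref_maps[s.ref_id].positions
                s.pair_ref_positions = [float(rp[r]) for _, r in s.pairs]
        side, score = _molecule_vote(a, cand, window_bp)
        if side is None:
            continue
        qid = a.query_id if isinstance(a, Alignment) else a.query_id
        prev = votes.get(qid)
        if prev is None or score > prev[1]:
            votes[qid] = (side, score)
    cand.supporting = [(q, s) for q, (side, s) in votes.items() if side == "support"]
    cand.rejecting = [(q, s) for q, (side, s) in votes.items() if side == "reject"]
    if not votes:
        return None
    if not (cand.s_s > cand.s_r):
        return None
    chroms = [c for c, _ in cand.breakpoints]
    bps = [b for _, b in cand.breakpoints]
    chrom = chroms[0]
    if cand.candidate_type == "inter_translocation":
        start, end = bps[0], bps[0]
        chrom2 = chroms[-1]
    else:
        start, end = float(min(bps)), float(max(bps))
        chrom2 = None
    return SVCall(
        sv_type=cand.candidate_type, chrom=chrom, start_bp=start, end_bp=end,
        size_delta_bp=0.0, zygosity="unknown", support_count=len(cand.supporting),
        score=cand.s_s - cand.s_r, module="complex", chrom2=chrom2,
    )


def call_complex_svs(
    contig_alignments,
    molecule_alignments,
    ref_maps: Dict[str, LabelMap],
    window_bp: float = 200_000.0,
) -> List[SVCall]:
    """Candidate generation from contigs plus molecule adjudication."""
    calls = []
    for cand in candidates_from_contigs(contig_alignments):
        call = adjudicate_candidate(cand, molecule_alignments, ref_maps, window_bp)
        if call is not None:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# Small inversions and tandem-unit counting
# ---------------------------------------------------------------------------

def find_small_inversions(
    contig_alignments: Sequence[Union[Alignment, SplitAlignment]],
    contig_maps: Sequence[LabelMap],
    ref_maps: Dict[str, LabelMap],
    min_labels: int = 4,
    margin: float = 3.0,
    params: AlignParams = AlignParams(),
) -> List[ComplexCandidate]:
    """Re-align poorly aligned contig windows in reversed orientation.

    Runs of at least ``min_labels`` consecutive unpaired contig labels inside
    an alignment's span are re-aligned to the local reference window in both
    orientations; a reversed fit better by ``margin`` nominates an inversion.
    Spans over 5 Mb are re-typed as intra-chromosomal translocations.
    """
    from .align import bad_label_windows

    by_id = {m.map_id: m for m in contig_maps}
    out: List[ComplexCandidate] = []
    for a in contig_alignments:
        segs = a.segments if isinstance(a, SplitAlignment) else [a]
        for seg in segs:
            contig = by_id[seg.query_id]
            paired = set(q for q, _ in seg.pairs)
            q_to_r = dict(seg.pairs)
            runs = bad_label_windows(seg, contig, ref_maps[seg.ref_id], params, min_labels)
            for run in runs:
                left_anchor = next((q for q in range(run[0] - 1, -1, -1) if q in paired), None)
                right_anchor = next(
                    (q for q in range(run[-1] + 1, contig.n_labels) if q in paired), None
                )
                if left_anchor is None or right_anchor is None:
                    continue
                rl, rr = q_to_r[left_anchor], q_to_r[right_anchor]
                if rl > rr:
                    rl, rr = rr, rl
                rmap = ref_maps[seg.ref_id]
                sub_ref_idx = np.arange(rl, rr + 1)
                sub_ref = LabelMap(
                    seg.ref_id, "reference",
                    float(rmap.positions[rr] - rmap.positions[rl] + 2),
                    rmap.positions[sub_ref_idx] - rmap.positions[rl],
                )
                qpos = contig.positions[run] - contig.positions[run[0]]
                p = AlignParams(
                    match_bonus=params.match_bonus, cq=params.cq, cr=params.cr,
                    sf_pen=params.sf_pen, sr_pen=params.sr_pen,
                    outlier_pen=params.outlier_pen, max_skip=params.max_skip,
                    min_labels_per_segment=min(min_labels, params.min_labels_per_segment),
                    min_query_labels=min(min_labels, params.min_query_labels),
                )
                scores = {}
                for orient, pos in (("+", qpos), ("-", qpos[-1] - qpos[::-1])):
                    from .align import _best_chain

                    chain, s = _best_chain(pos, sub_ref.positions, p)
                    scores[orient] = s if chain else -np.inf
                if scores["-"] > scores["+"] + margin:
                    span = float(rmap.positions[rr] - rmap.positions[rl])
                    ctype = "inversion" if span <= INV_MAX_SPAN_BP else "intra_translocation"
                    out.append(
                        ComplexCandidate(
                            ctype,
                            [
                                (seg.ref_id, float(rmap.positions[rl])),
                                (seg.ref_id, float(rmap.positions[rr])),
                            ],
                            seg.query_id,
                        )
                    )
    return out


class Uncountable(ValueError):
    """Tandem-unit copy number cannot be determined on this contig."""


def _find_pattern(gaps: np.ndarray, pattern: np.ndarray, tol: float) -> List[int]:
    """Start indices where the gap sequence matches the distance pattern."""
    k = pattern.size
    hits = []
    for i in range(gaps.size - k + 1):
        seg = gaps[i : i + k]
        if np.all(np.abs(seg - pattern) <= tol * pattern):
            hits.append(i)
    return hits


def count_tandem_units(
    contig: LabelMap,
    left_flank_pattern: Sequence[float],
    right_flank_pattern: Sequence[float],
    unit_pattern: Sequence[float],
    tol: float = 0.15,
) -> int:
    """Exact copy number of a tandem unit between unique flank patterns.

    Patterns are inter-label distance sequences (bp); each interval must match
    within relative tolerance ``tol``. Raises :class:`Uncountable` when a
    flank is absent or ambiguous.
    """
    gaps = np.diff(contig.positions)
    lf = np.asarray(left_flank_pattern, float)
    rf = np.asarray(right_flank_pattern, float)
    up = np.asarray(unit_pattern, float)
    lhits = _find_pattern(gaps, lf, tol)
    rhits = _find_pattern(gaps, rf, tol)
    if len(lhits) != 1 or len(rhits) != 1:
        raise Uncountable(
            f"flank patterns must occur exactly once (left x{len(lhits)}, right x{len(rhits)})"
        )
    lo = lhits[0] + lf.size
    hi = rhits[0]
    if hi < lo:
        raise Uncountable("right flank precedes left flank")
    count = 0
    i = lo
    while i + up.size <= hi:
        seg = gaps[i : i + up.size]
        if np.all(np.abs(seg - up) <= tol * up):
            count += 1
            i += up.size
        else:
            i += 1
    return count
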
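"""Orientation-aware, split-capable alignment of label maps by dynamic programming.

An ordered-restriction-map alignment pairs query labels with reference labels
so that paired inter-label distances agree up to sizing noise, while skipped
labels on either side are penalized. The chain score maximized is

    sum over steps of [ match_bonus - min(outlier_pen, (dq - dr)^2 / (sf_pen^2 + (sr_pen*dr)^2))
                        - cq * (skipped query labels) - cr * (skipped ref labels) ]

with at most K labels skipped per step on either map. Capping the sizing
penalty (an "outlier" interval) lets a chain step across a large indel at a
bounded cost instead of breaking or absorbing the size change into shifted
mis-pairings; the indel then shows up as one oversized/undersized interval. Both orientations are
tried; unaligned query remainders with enough labels are re-aligned
recursively to produce split alignments. Confidence is calibrated by a
permutation null (see :class:`ConfidenceModel`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit

from .models import Alignment, LabelMap, SplitAlignment


@dataclass(frozen=True)
class AlignParams:
    match_bonus: float = 3.0
    cq: float = 1.5
    cr: float = 1.5
    sf_pen: float = 500.0  # bp
    sr_pen: float = 0.02
    outlier_pen: float = 6.0  # cap on the per-step sizing penalty (indel crossing)
    max_skip: int = 12  # K: labels skippable per DP step (field convention deltaX/deltaY)
    min_query_labels: int = 5
    min_labels_per_segment: int = 5
    score_floor: float = 0.0  # reporting floor (exclusive)
    min_confidence: float = 9.0
    # search shortcut: stop trying further references/orientations once a
    # placement reaches this fraction of the maximum attainable score
    early_exit_frac: float = 0.85

    def key(self) -> tuple:
        return (
            self.match_bonus, self.cq, self.cr, self.sf_pen, self.sr_pen,
            self.outlier_pen, self.max_skip,
        )


@njit(cache=True)
def _dp_kernel(q, r, K, match_bonus, cq, cr, sf2, sr_pen, outlier_pen):  # pragma: no cover
    Q = q.shape[0]
    R = r.shape[0]
    S = np.full((Q, R), match_bonus)
    Pi = np.full((Q, R), -1, np.int64)
    Pj = np.full((Q, R), -1, np.int64)
    # per-reference-interval lookups: distance and inverse penalty denominator
    W = np.empty((R, K + 2))
    D = np.empty((R, K + 2))
    for j in range(R):
        kmax = j if j < K + 1 else K + 1
        for k in range(1, kmax + 1):
            dr = r[j] - r[j - k]
            D[j, k] = dr
            W[j, k] = 1.0 / (sf2 + (sr_pen * dr) ** 2)
    for i in range(Q):
        kq_max = i if i < K + 1 else K + 1
        for j in range(R):
            best = match_bonus  # free chain start at any pair
            bi = -1
            bj = -1
            kr_max = j if j < K + 1 else K + 1
            for kq in range(1, kq_max + 1):
                dq = q[i] - q[i - kq]
                base = match_bonus - cq * (kq - 1)
                for kr in range(1, kr_max + 1):
                    diff = dq - D[j, kr]
                    pen = diff * diff * W[j, kr]
                    if pen > outlier_pen:
                        pen = outlier_pen
                    s = S[i - kq, j - kr] + base - pen - cr * (kr - 1)
                    if s > best:
                        best = s
                        bi = i - kq
                        bj = j - kr
            S[i, j] = best
            Pi[i, j] = bi
            Pj[i, j] = bj
    return S, Pi, Pj


def _best_chain(qpos: np.ndarray, rpos: np.ndarray, params: AlignParams):
    """Best chain of (query_idx, ref_idx) pairs and its score."""
    if qpos.size == 0 or rpos.size == 0:
        return [], -np.inf
    S, Pi, Pj = _dp_kernel(
        qpos.astype(np.float64), rpos.astype(np.float64), params.max_skip,
        params.match_bonus, params.cq, params.cr,
        params.sf_pen ** 2, params.sr_pen, params.outlier_pen,
    )
    i, j = np.unravel_index(int(np.argmax(S)), S.shape)
    score = float(S[i, j])
    chain = []
    while i >= 0:
        chain.append((int(i), int(j)))
        i, j = int(Pi[i, j]), int(Pj[i, j])
        if i < 0:
            break
    chain.reverse()
    return chain, score


def _chain_to_alignment(
    query: LabelMap, ref: LabelMap, chain, score: float, orientation: str,
    query_index_map: Optional[np.ndarray] = None,
) -> Alignment:
    """Convert a DP chain on (possibly reversed/subset) coordinates to an Alignment."""
    ref_idx = [j for _, j in chain]
    if orientation == "+":
        q_idx = [i for i, _ in chain]
    else:
        n = query.n_labels
        q_idx = [n - 1 - i for i, _ in chain]
    if query_index_map is not None:
        q_idx = [int(query_index_map[i]) for i in q_idx]
    pairs = list(zip(q_idx, ref_idx))
    ref_start = float(ref.positions[ref_idx[0]])
    ref_end = float(ref.positions[ref_idx[-1]])
    qs = sorted(q_idx)
    n_extra = (qs[-1] - qs[0] + 1) - len(pairs)
    n_missed = (ref_idx[-1] - ref_idx[0] + 1) - len(pairs)
    return Alignment(
        query_id=query.map_id, ref_id=ref.map_id, orientation=orientation,
        pairs=pairs, score=score, ref_start_bp=ref_start, ref_end_bp=ref_end,
        n_extra_query=n_extra, n_missed_ref=n_missed,
    )


def _align_positions(
    query: LabelMap, qpos: np.ndarray, refs: Sequence[LabelMap],
    params: AlignParams, query_index_map: Optional[np.ndarray] = None,
) -> Optional[Alignment]:
    """Best placement of the given query label subset across refs and orientations."""
    best: Optional[Alignment] = None
    rev = qpos[-1] - qpos[::-1] if qpos.size else qpos
    exit_score = params.early_exit_frac * params.match_bonus * qpos.size
    for ref in refs:
        if best is not None and best.score >= exit_score:
            break
        for orientation, pos in (("+", qpos), ("-", rev)):
            if best is not None and best.score >= exit_score:
                break
            chain, score = _best_chain(pos, ref.positions, params)
            if not chain or score <= params.score_floor:
                continue
            if best is None or score > best.score:
                if orientation == "-" and query_index_map is None:
                    # reversed full-query index convention handled in converter
                    aln = _chain_to_alignment(query, ref, chain, score, orientation)
                elif orientation == "-":
                    n = qpos.size
                    sub_map = query_index_map[::-1]
                    q_idx = [int(sub_map[i]) for i, _ in chain]
                    pairs = list(zip(q_idx, [j for _, j in chain]))
                    aln = Alignment(
                        query_id=query.map_id, ref_id=ref.map_id, orientation="-",
                        pairs=pairs, score=score,
                        ref_start_bp=float(ref.positions[pairs[0][1]]),
                        ref_end_bp=float(ref.positions[pairs[-1][1]]),
                    )
                    qs = sorted(q_idx)
                    aln.n_extra_query = (qs[-1] - qs[0] + 1) - len(pairs)
                    aln.n_missed_ref = (pairs[-1][1] - pairs[0][1] + 1) - len(pairs)
                else:
                    aln = _chain_to_alignment(
                        query, ref, chain, score, orientation, query_index_map
                    )
                best = aln
    return best


def align_map(
    query: LabelMap,
    refs: Sequence[LabelMap],
    params: AlignParams = AlignParams(),
    split: bool = True,
) -> List[Union[Alignment, SplitAlignment]]:
    """Align one query map to a set of reference maps.

    Returns a single :class:`Alignment`, a :class:`SplitAlignment` when
    unaligned query remainders of at least ``min_labels_per_segment`` labels
    re-align elsewhere, or an empty list when nothing clears the reporting
    floor.
    """
    if query.n_labels < params.min_query_labels:
        return []
    segments = _split_search(query, np.arange(query.n_labels), refs, params, split)
    if not segments:
        return []
    if len(segments) == 1:
        return [segments[0]]
    segments.sort(key=lambda a: min(query.positions[q] for q, _ in a.pairs))
    breakpoints = []
    for left, right in zip(segments[:-1], segments[1:]):
        lq = max(left.pairs, key=lambda p: query.positions[p[0]])
        rq = min(right.pairs, key=lambda p: query.positions[p[0]])
        breakpoints.append(
            ((left.ref_id, float(_ref_pos(refs, left.ref_id, lq[1]))),
             (right.ref_id, float(_ref_pos(refs, right.ref_id, rq[1]))))
        )
    return [SplitAlignment(query.map_id, segments, breakpoints)]


def _ref_pos(refs: Sequence[LabelMap], ref_id: str, idx: int) -> float:
    for r in refs:
        if r.map_id == ref_id:
            return float(r.positions[idx])
    raise KeyError(ref_id)


def _split_search(
    query: LabelMap, label_subset: np.ndarray, refs: Sequence[LabelMap],
    params: AlignParams, split: bool,
) -> List[Alignment]:
    if label_subset.size < params.min_labels_per_segment:
        return []
    qpos = query.positions[label_subset]
    qpos0 = qpos - qpos[0]
    aln = _align_positions(query, qpos0, refs, params, query_index_map=label_subset)
    if aln is None or len(aln.pairs) < params.min_labels_per_segment:
        return []
    out = [aln]
    if split:
        used = set(q for q, _ in aln.pairs)
        # maximal runs of unpaired labels (end flanks and interior gaps alike)
        run: List[int] = []
        for i in list(label_subset) + [None]:
            if i is not None and i not in used:
                run.append(int(i))
            else:
                if len(run) >= params.min_labels_per_segment:
                    out.extend(
                        _split_search(query, np.array(run, dtype=int), refs, params, split)
                    )
                run = []
    return out


def step_penalty(dq: float, dr: float, params: AlignParams) -> float:
    raw = (abs(dq) - abs(dr)) ** 2 / (params.sf_pen ** 2 + (params.sr_pen * abs(dr)) ** 2)
    return min(raw, params.outlier_pen)


def bad_label_windows(
    seg: Alignment, query: LabelMap, ref: LabelMap, params: AlignParams,
    min_len: int,
) -> List[List[int]]:
    """Query-label runs inside a segment that align poorly.

    A run is either a stretch of unpaired labels or a stretch of steps with
    high sizing penalties — the signature of foreign or inverted content
    absorbed by the chain (inverted blocks pair with elevated but not
    necessarily capped penalties, since point reflection preserves central
    distances). Runs shorter than ``min_len`` labels are ignored (a single
    outlier step is an ordinary indel crossing).
    """
    chain = sorted(seg.pairs, key=lambda p: query.positions[p[0]])
    if len(chain) < 2:
        return []
    qpos = query.positions
    rpos = ref.positions
    bad_threshold = 0.4 * params.outlier_pen
    bad_steps = []
    for (q1, r1), (q2, r2) in zip(chain[:-1], chain[1:]):
        pen = step_penalty(qpos[q2] - qpos[q1], rpos[r2] - rpos[r1], params)
        bad_steps.append(pen >= bad_threshold)
    paired = {q for q, _ in chain}
    q_first, q_last = chain[0][0], chain[-1][0]
    lo, hi = min(q_first, q_last), max(q_first, q_last)
    # unpaired labels are bad; a paired label is bad only when every step it
    # anchors is capped (an anchor with one good flank stays good)
    bad = {q: q not in paired for q in range(lo, hi + 1)}
    capped_count: Dict[int, int] = {}
    step_count: Dict[int, int] = {}
    for k, is_bad in enumerate(bad_steps):
        for q in (chain[k][0], chain[k + 1][0]):
            step_count[q] = step_count.get(q, 0) + 1
            if is_bad:
                capped_count[q] = capped_count.get(q, 0) + 1
        if is_bad:
            qa, qb = chain[k][0], chain[k + 1][0]
            for q in range(min(qa, qb) + 1, max(qa, qb)):
                bad[q] = True  # skipped labels inside a capped step
    for q in paired:
        if lo <= q <= hi and step_count.get(q, 0) > 0:
            if capped_count.get(q, 0) == step_count[q]:
                bad[q] = True
    # close short good gaps between bad runs: a lucky well-fitting step inside
    # an absorbed block should not fragment the window
    flags = [bad.get(q, False) for q in range(lo, hi + 1)]
    i = 0
    while i < len(flags):
        if not flags[i]:
            j = i
            while j < len(flags) and not flags[j]:
                j += 1
            gap_len = j - i
            if 0 < i and j < len(flags) and gap_len < min_len:
                for k in range(i, j):
                    flags[k] = True
            i = j
        else:
            i += 1
    runs: List[List[int]] = []
    run: List[int] = []
    for off, is_bad in enumerate(flags):
        if is_bad:
            run.append(lo + off)
        else:
            if len(run) >= min_len:
                runs.append(run)
            run = []
    if len(run) >= min_len:
        runs.append(run)
    return runs


def refine_alignment(
    a: Union[Alignment, "SplitAlignment"],
    query: LabelMap,
    refs: Sequence[LabelMap],
    params: AlignParams = AlignParams(),
) -> Union[Alignment, "SplitAlignment"]:
    """Excise poorly aligned windows of a (split) alignment and re-align them.

    A long best chain happily absorbs an inverted or translocated block at
    outlier cost; this pass detects such blocks, removes them from the host
    segment (splitting it), and aligns each block independently against all
    references in both orientations, yielding a split alignment whose
    segments partition the query.
    """
    ref_by_id = {r.map_id: r for r in refs}
    segs = a.segments if isinstance(a, SplitAlignment) else [a]
    new_segs: List[Alignment] = []
    for seg in segs:
        windows = bad_label_windows(
            seg, query, ref_by_id[seg.ref_id], params, params.min_labels_per_segment
        )
        if not windows:
            new_segs.append(seg)
            continue
        in_window = {q for w in windows for q in w}
        chain = sorted(seg.pairs, key=lambda p: query.positions[p[0]])
        part: List[tuple] = []
        parts: List[List[tuple]] = []
        prev_q: Optional[int] = None
        for q, r in chain:
            crosses_window = prev_q is not None and any(
                min(prev_q, q) < w < max(prev_q, q) for w in in_window
            )
            if q in in_window or crosses_window:
                if part:
                    parts.append(part)
                    part = []
            if q not in in_window:
                part.append((q, r))
            prev_q = q
        if part:
            parts.append(part)
        for part in parts:
            if len(part) < params.min_labels_per_segment:
                continue
            sub = Alignment(
                query_id=seg.query_id, ref_id=seg.ref_id,
                orientation=seg.orientation, pairs=part,
                score=seg.score * len(part) / max(len(chain), 1),
                confidence=seg.confidence,
            )
            rpos = ref_by_id[seg.ref_id].positions
            ridx = [r for _, r in part]
            sub.ref_start_bp = float(rpos[min(ridx)])
            sub.ref_end_bp = float(rpos[max(ridx)])
            new_segs.append(sub)
        for w in windows:
            idx = np.array(w, dtype=int)
            qp = query.positions[idx]
            sub_aln = _align_positions(query, qp - qp[0], refs, params, query_index_map=idx)
            if sub_aln is not None and len(sub_aln.pairs) >= params.min_labels_per_segment:
                sub_aln.confidence = seg.confidence
                new_segs.append(sub_aln)
    if not new_segs:
        return a
    # window re-alignment can recreate a segment the initial split search
    # already found; keep one copy
    unique: List[Alignment] = []
    seen = set()
    for s in new_segs:
        key = (s.ref_id, s.orientation, s.pairs[0], s.pairs[-1])
        if key not in seen:
            seen.add(key)
            unique.append(s)
    if len(unique) == 1:
        return unique[0]
    unique.sort(key=lambda s: min(query.positions[q] for q, _ in s.pairs))
    return SplitAlignment(query.map_id, unique, [])


# ---------------------------------------------------------------------------
# Permutation-calibrated confidence
# ---------------------------------------------------------------------------

_CONF_CACHE: Dict[tuple, "ConfidenceModel"] = {}


@dataclass
class ConfidenceModel:
    """Null distribution of best alignment scores of permuted queries.

    For each label-count bucket the model holds the Gumbel location/scale
    fitted to the best-placement scores of label-shuffled (gap-resampled)
    queries of that size. Confidence of an observed score s for a query of n
    labels is -log10 P(null best score >= s) under the fitted right tail,
    which extends the empirical distribution beyond its 1/N resolution so the
    conventional filter threshold of 9 is expressible.
    """

    buckets: Dict[int, Tuple[float, float]]  # n_labels -> (loc, scale)
    n_permutations: int

    def confidence(self, score: float, n_labels: int) -> float:
        from scipy.stats import gumbel_r

        key = min(self.buckets, key=lambda b: abs(b - n_labels))
        loc, scale = self.buckets[key]
        p = gumbel_r.sf(score, loc=loc, scale=scale)
        p = max(p, 1e-300)
        return float(-np.log10(p))


def calibrate_confidence(
    refs: Sequence[LabelMap],
    params: AlignParams = AlignParams(),
    seed: Optional[int] = None,
    n_permutations: int = 10_000,
    bucket_sizes: Sequence[int] = (6, 10, 15, 22, 32, 45),
    calibration_window_labels: int = 400,
) -> ConfidenceModel:
    """Estimate the permutation null once per (reference set, parameter set).

    Null queries are built by resampling inter-label gaps from the pooled
    reference gap distribution (the score a label-shuffled query of the same
    label count achieves at its best placement); results are cached in-process.

    For large references the null is measured against a contiguous window of
    ``calibration_window_labels`` labels and the fitted Gumbel location is
    shifted by scale * ln(N_total / N_window) — the max-stability property of
    the Gumbel family makes the best score over k times as many candidate
    placements another Gumbel with the location moved by scale*ln(k).
    """
    ref_sig = tuple((r.map_id, r.n_labels, round(float(r.length_bp))) for r in refs)
    if seed is None:
        # the null is a property of (reference, parameters): derive a stable
        # seed so repeated pipeline runs share one cached calibration
        import zlib

        seed = zlib.crc32(repr(ref_sig).encode()) % (2**31)
    cache_key = (ref_sig, params.key(), seed, n_permutations, tuple(bucket_sizes))
    if cache_key in _CONF_CACHE:
        return _CONF_CACHE[cache_key]

    from scipy.stats import gumbel_r

    rng = np.random.default_rng(seed)
    gaps = np.concatenate([np.diff(r.positions) for r in refs if r.n_labels >= 2])
    if gaps.size == 0:
        raise ValueError("reference maps carry too few labels to calibrate")
    n_total = int(sum(r.n_labels for r in refs))
    widest = max(refs, key=lambda r: r.n_labels)
    if widest.n_labels > calibration_window_labels:
        start = int(rng.integers(0, widest.n_labels - calibration_window_labels))
        wpos = widest.positions[start : start + calibration_window_labels]
        targets = [LabelMap("cal", "reference", float(wpos[-1] - wpos[0] + 2), wpos - wpos[0])]
        n_window = calibration_window_labels
    else:
        targets = list(refs)
        n_window = n_total
    shift_factor = float(np.log(max(n_total, 2) / n_window))
    per_bucket = max(50, n_permutations // len(bucket_sizes))
    buckets = {}
    for nb in bucket_sizes:
        scores = np.empty(per_bucket)
        for t in range(per_bucket):
            g = rng.choice(gaps, size=nb - 1, replace=True)
            rng.shuffle(g)
            qpos = np.concatenate(([0.0], np.cumsum(g)))
            best = -np.inf
            rev = qpos[-1] - qpos[::-1]
            for ref in targets:
                for pos in (qpos, rev):
                    _, s = _best_chain(pos, ref.positions, params)
                    if s > best:
                        best = s
            scores[t] = best
        loc, scale = gumbel_r.fit(scores)
        buckets[nb] = (float(loc + scale * shift_factor), float(scale))
    model = ConfidenceModel(buckets, per_bucket * len(bucket_sizes))
    _CONF_CACHE[cache_key] = model
    return model


def confidence_score(alignment: Alignment, null_model: Optional[ConfidenceModel]) -> float:
    """Permutation-calibrated confidence of an alignment (monotone in score)."""
    if null_model is None:
        raise ValueError(
            "no null model: run calibrate_confidence(refs, params, seed) first"
        )
    return null_model.confidence(alignment.score, alignment.n_matched)


def score_alignments(
    alignments: Sequence[Union[Alignment, SplitAlignment]],
    null_model: ConfidenceModel,
) -> None:
    """Attach confidence to alignments (and split-alignment segments) in place."""
    for a in alignments:
        segs = a.segments if isinstance(a, SplitAlignment) else [a]
        for s in segs:
            s.confidence = null_model.confidence(s.score, s.n_matched)


# ---------------------------------------------------------------------------
# Molecule -> contig -> reference composition (MCR)
# ---------------------------------------------------------------------------

def align_indirect(
    mol_to_contig: Sequence[Alignment],
    contig_to_ref: Sequence[Alignment],
) -> Tuple[List[Alignment], int]:
    """Compose molecule->contig and contig->reference alignments.

    Each molecule uses only the contig it aligned to with the highest score
    (ties broken by lexicographic contig id). Returns (composed alignments,
    number of molecules omitted for lack of a usable composition).
    """
    ctr_by_contig: Dict[str, Alignment] = {}
    for a in contig_to_ref:
        prev = ctr_by_contig.get(a.query_id)
        if prev is None or a.score > prev.score:
            ctr_by_contig[a.query_id] = a

    best_mc: Dict[str, Alignment] = {}
    for a in mol_to_contig:
        prev = best_mc.get(a.query_id)
        if (
            prev is None
            or a.score > prev.score
            or (a.score == prev.score and a.ref_id < prev.ref_id)
        ):
            best_mc[a.query_id] = a

    composed: List[Alignment] = []
    omitted = 0
    for mol_id, mc in sorted(best_mc.items()):
        cr = ctr_by_contig.get(mc.ref_id)
        if cr is None:
            omitted += 1
            continue
        contig_to_refidx = dict(cr.pairs)
        pairs = []
        for i, j in mc.pairs:
            k = contig_to_refidx.get(j)
            if k is not None:
                pairs.append((i, k))
        if len(pairs) < 2:
            omitted += 1
            continue
        orientation = "+" if mc.orientation == cr.orientation else "-"
        pairs.sort(key=lambda p: p[1])
        conf = min(
            mc.confidence if np.isfinite(mc.confidence) else np.inf,
            cr.confidence if np.isfinite(cr.confidence) else np.inf,
        )
        aln = Alignment(
            query_id=mol_id, ref_id=cr.ref_id, orientation=orientation,
            pairs=pairs, score=mc.score,
            confidence=float(conf) if np.isfinite(conf) else float("nan"),
        )
        composed.append(aln)
    return composed, omitted
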
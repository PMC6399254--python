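"""Large-indel calling from aligned label distances (MR, CR, MCR).

For every pair of nick sites that is adjacent on the reference or on some
aligned map, the reference distance d0 is compared with the corresponding
distances d1..dn on all maps spanning the locus. Five hypotheses about the
true spanned length t are scored with a Normal sizing-error model
sigma(t)^2 = (1000*sf)^2 + (sr*t)^2:

  H0        t = d0 on both chromosomes (no indel)
  Hhom      t = d0 + delta on both chromosomes
  Hhet_ins  equal mixture of t = d0 and t = d0 + delta, delta >= +min_delta
  Hhet_del  same with delta <= -min_delta
  Htri      equal mixture of two distinct indel alleles d0+delta1, d0+delta2

A call is emitted when the winning alternative's log10 likelihood ratio over
H0 clears the cutoff, the size estimate exceeds the 2-kb floor, and enough
molecules support the variant component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .align import Alignment, SplitAlignment
from .digest import ReferenceDigest
from .models import SVCall
from .simulate import NoiseModel

LOG_HALF = float(np.log(0.5))
MAX_DELTA_BP = 500_000.0


@dataclass
class IntervalEvidence:
    chrom: str
    ref_left_label: int
    ref_right_label: int
    d0: float
    molecule_distances: np.ndarray
    molecule_ids: List[str]
    source: str = "MR"

    def __post_init__(self) -> None:
        self.molecule_distances = np.asarray(self.molecule_distances, dtype=float)
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.molecule_distances.size < 1 or np.any(self.molecule_distances <= 0):
            raise ValueError("need at least one positive molecule distance")

    @property
    def n(self) -> int:
        return int(self.molecule_distances.size)


@dataclass
class HypothesisResult:
    loglik: Dict[str, float]
    mle_deltas: Tuple[float, ...]
    winning: str
    log10_lr_vs_h0: float
    support: int = 0
    under_supported: bool = False


def _flatten(alignments) -> List[Alignment]:
    out = []
    for a in alignments:
        if isinstance(a, SplitAlignment):
            out.extend(a.segments)
        else:
            out.append(a)
    return out


def collect_interval_evidence(
    alignments: Sequence[Union[Alignment, SplitAlignment]],
    ref: ReferenceDigest,
    min_confidence: float = 9.0,
    source: str = "MR",
) -> List[IntervalEvidence]:
    """Interval evidence from confidence-filtered alignments.

    Candidate intervals are the reference label pairs adjacent in some
    alignment chain (this covers both reference-adjacent pairs and pairs made
    adjacent on a molecule by deleted labels). For each interval every
    alignment pairing both labels contributes the distance between the paired
    query labels; interior unpaired query labels contribute to the distance
    but not to the pairing.
    """
    # uncalibrated alignments (confidence NaN) pass through unfiltered
    alns = [
        a for a in _flatten(alignments)
        if not np.isfinite(a.confidence) or a.confidence > min_confidence
    ]
    keys = set()
    by_label: Dict[Tuple[str, int], set] = {}
    for ai, a in enumerate(alns):
        chain = sorted(a.pairs, key=lambda p: p[1])
        for (q1, r1), (q2, r2) in zip(chain[:-1], chain[1:]):
            keys.add((a.ref_id, r1, r2))
        for q, r in chain:
            by_label.setdefault((a.ref_id, r), set()).add(ai)
    evidence: List[IntervalEvidence] = []
    for (ref_id, rl, rr) in sorted(keys):
        lm = ref.chromosomes[ref_id]
        d0 = float(lm.positions[rr] - lm.positions[rl])
        if d0 <= 0:
            continue
        dists, ids = [], []
        for ai in by_label.get((ref_id, rl), set()) & by_label.get((ref_id, rr), set()):
            a = alns[ai]
            qmap = dict((r, q) for q, r in a.pairs)
            qpos = a.query_positions  # attached by the pipeline
            di = abs(float(qpos[qmap[rr]] - qpos[qmap[rl]]))
            if di > 0:
                dists.append(di)
                ids.append(a.query_id)
        if dists:
            evidence.append(
                IntervalEvidence(ref_id, rl, rr, d0, np.array(dists), ids, source)
            )
    return evidence


def attach_query_positions(alignments, query_maps) -> None:
    """Attach each alignment's query label positions (bp) for evidence collection."""
    pos = {m.map_id: m.positions for m in query_maps}
    for a in _flatten(alignments):
        a.query_positions = pos[a.query_id]


# ---------------------------------------------------------------------------
# Five-hypothesis likelihood-ratio test
# ---------------------------------------------------------------------------

# contamination component: a small fraction of spanning distances come from
# mis-paired or chimeric alignments rather than sizing noise, modelled as
# uniform over a wide window so no hypothesis is forced to absorb them
OUTLIER_FRAC = 0.05
OUTLIER_WINDOW_BP = 500_000.0


def _lp(d: np.ndarray, t: float, noise: NoiseModel) -> np.ndarray:
    """Per-molecule log density of observed distance d for true length t.

    Normal sizing error with a uniform contamination component.
    """
    s2 = (1000.0 * noise.sizing_sf) ** 2 + (noise.sizing_sr * t) ** 2
    if s2 <= 0:
        s2 = 1.0  # noiseless simulations: degenerate scale, keep densities finite
    core = -0.5 * np.log(2 * np.pi * s2) - (d - t) ** 2 / (2 * s2)
    return np.logaddexp(
        np.log1p(-OUTLIER_FRAC) + core,
        np.log(OUTLIER_FRAC / OUTLIER_WINDOW_BP),
    )


def _ll_hom(d, d0, noise, delta):
    return float(np.sum(_lp(d, d0 + delta, noise)))


def _ll_mix(d, d0, noise, delta1, delta2):
    a = LOG_HALF + _lp(d, d0 + delta1, noise)
    b = LOG_HALF + _lp(d, d0 + delta2, noise)
    return float(np.sum(np.logaddexp(a, b)))


def _maximize_1d(fun, lo: float, hi: float, starts: Sequence[float]) -> Tuple[float, float]:
    """Maximize fun over [lo, hi] from a coarse candidate set plus local refinement."""
    if hi <= lo:
        return np.nan, -np.inf
    cands = [x for x in starts if lo <= x <= hi]
    cands += list(np.linspace(lo, hi, 9))
    best_x, best_v = lo, -np.inf
    for x in cands:
        v = fun(x)
        if v > best_v:
            best_x, best_v = x, v
    w = max((hi - lo) * 0.02, 300.0)
    res = minimize_scalar(
        lambda x: -fun(min(max(x, lo), hi)),
        bounds=(max(lo, best_x - w), min(hi, best_x + w)),
        method="bounded",
        options={"xatol": 1.0},
    )
    if -res.fun > best_v:
        best_x, best_v = float(np.clip(res.x, lo, hi)), float(-res.fun)
    return best_x, best_v


def _fit_tri(d, d0, noise, min_delta, seed) -> Tuple[float, Tuple[float, float]]:
    """Two-component equal-weight mixture of indel alleles via EM with restarts."""
    rng = np.random.default_rng(seed)
    dev = d - d0
    best_ll, best = -np.inf, (min_delta, -min_delta)
    for r in range(5):
        if r == 0 and d.size >= 2:
            d1, d2 = float(np.quantile(dev, 0.25)), float(np.quantile(dev, 0.75))
        else:
            d1, d2 = rng.choice(dev, 2, replace=True)
        for _ in range(50):
            la = LOG_HALF + _lp(d, d0 + d1, noise)
            lb = LOG_HALF + _lp(d, d0 + d2, noise)
            m = np.maximum(la, lb)
            wa = np.exp(la - m)
            wb = np.exp(lb - m)
            ra = wa / (wa + wb)
            if ra.sum() > 1e-9:
                d1n = float(np.sum(ra * dev) / ra.sum())
            else:
                d1n = d1
            if (1 - ra).sum() > 1e-9:
                d2n = float(np.sum((1 - ra) * dev) / (1 - ra).sum())
            else:
                d2n = d2
            if abs(d1n - d1) < 1.0 and abs(d2n - d2) < 1.0:
                d1, d2 = d1n, d2n
                break
            d1, d2 = d1n, d2n
        # both alleles are indels, distinguishable at the calling floor:
        # components must each exceed min_delta and differ by >= min_delta
        def proj(x):
            return float(np.sign(x) * max(abs(x), min_delta)) if x != 0 else min_delta
        d1c, d2c = proj(d1), proj(d2)
        if abs(d1c - d2c) < min_delta:
            mid = 0.5 * (d1c + d2c)
            d1c, d2c = mid - min_delta / 2, mid + min_delta / 2
            d1c, d2c = proj(d1c), proj(d2c)
            if abs(d1c - d2c) < min_delta:
                d2c = d1c + min_delta if d2c >= d1c else d1c - min_delta
        ll = _ll_mix(d, d0, noise, d1c, d2c)
        if ll > best_ll:
            best_ll, best = ll, (d1c, d2c)
    return best_ll, best


def test_interval(
    ev: IntervalEvidence,
    noise: NoiseModel,
    min_delta_bp: float = 2_000.0,
    min_support: int = 10,
    lr_cutoff_log10: float = 3.0,
    seed: int = 0,
) -> Tuple[HypothesisResult, Optional[SVCall]]:
    """Likelihood-ratio test of one interval; optionally an SVCall.

    Fast path: when every molecule distance sits within the size floor of d0
    no alternative with |delta| > min_delta_bp can win, and H0 is returned
    without optimization.
    """
    d = ev.molecule_distances
    d0 = ev.d0
    ll0 = _ll_hom(d, d0, noise, 0.0)
    if np.max(np.abs(d - d0)) < min_delta_bp:
        res = HypothesisResult({"H0": ll0}, (), "H0", 0.0)
        res.under_supported = ev.n < min_support
        return res, None

    dev = d - d0
    starts = [float(np.mean(dev)), float(np.median(dev))] + list(
        np.quantile(dev, [0.1, 0.5, 0.9])
    )
    lo_del = -d0 + 50.0

    dh, ll_hom = _maximize_1d(lambda x: _ll_hom(d, d0, noise, x), lo_del, MAX_DELTA_BP, starts)
    di_, ll_hi = _maximize_1d(
        lambda x: _ll_mix(d, d0, noise, 0.0, x), min_delta_bp, MAX_DELTA_BP, starts
    )
    dd_, ll_hd = _maximize_1d(
        lambda x: _ll_mix(d, d0, noise, 0.0, x), lo_del, -min_delta_bp, starts
    )
    ll_tri, (t1, t2) = _fit_tri(d, d0, noise, min_delta_bp, seed)

    logliks = {
        "H0": ll0, "Hhom": ll_hom, "Hhet_ins": ll_hi, "Hhet_del": ll_hd, "Htri": ll_tri,
    }
    alts = {k: v for k, v in logliks.items() if k != "H0"}
    winning = max(alts, key=alts.get)
    if alts[winning] <= ll0:
        winning = "H0"
    lr = max(0.0, (logliks[winning] - ll0) / np.log(10)) if winning != "H0" else 0.0

    deltas = {
        "H0": (), "Hhom": (dh,), "Hhet_ins": (di_,), "Hhet_del": (dd_,), "Htri": (t1, t2),
    }[winning]
    res = HypothesisResult(logliks, tuple(deltas), winning, lr)

    # supporting molecules: better explained by the variant component
    support_ids: List[str] = []
    if winning == "Hhom":
        mask = _lp(d, d0 + dh, noise) > _lp(d, d0, noise)
    elif winning in ("Hhet_ins", "Hhet_del"):
        delta = deltas[0]
        mask = _lp(d, d0 + delta, noise) > _lp(d, d0, noise)
    elif winning == "Htri":
        mask = np.ones(d.size, dtype=bool)
    else:
        mask = np.zeros(d.size, dtype=bool)
    res.support = int(mask.sum())
    support_ids = [m for m, keep in zip(ev.molecule_ids, mask) if keep]

    res.under_supported = ev.n < min_support
    if res.under_supported or winning == "H0":
        return res, None
    primary = max(deltas, key=abs)
    if lr < lr_cutoff_log10 or abs(primary) <= min_delta_bp or res.support < min_support:
        return res, None

    zyg = {"Hhom": "hom", "Hhet_ins": "het", "Hhet_del": "het", "Htri": "tri"}[winning]
    if winning == "Htri":
        sv_type = "multi_indel"
    else:
        sv_type = "insertion" if primary > 0 else "deletion"
    call = SVCall(
        sv_type=sv_type, chrom=ev.chrom, start_bp=0.0, end_bp=0.0,
        size_delta_bp=float(primary), zygosity=zyg, support_count=res.support,
        score=lr, module=ev.source,
    )
    call.support_ids = support_ids
    return res, call


test_interval.__test__ = False  # not a test despite the name (pytest collection)


def call_mr_indels(
    alignments,
    query_maps,
    ref: ReferenceDigest,
    noise: NoiseModel,
    min_confidence: float = 9.0,
    min_delta_bp: float = 2_000.0,
    min_support: int = 10,
    lr_cutoff_log10: float = 3.0,
    source: str = "MR",
    seed: int = 0,
) -> List[SVCall]:
    """Molecule-vs-reference indel calls (also used for MCR with composed alignments)."""
    attach_query_positions(alignments, query_maps)
    evidence = collect_interval_evidence(alignments, ref, min_confidence, source)
    calls = []
    for ev in evidence:
        _, call = test_interval(
            ev, noise, min_delta_bp, min_support, lr_cutoff_log10, seed
        )
        if call is not None:
            lm = ref.chromosomes[ev.chrom]
            call.start_bp = float(lm.positions[ev.ref_left_label])
            call.end_bp = float(lm.positions[ev.ref_right_label])
            calls.append(call)
    return _dedupe_overlapping(calls)


def _dedupe_overlapping(calls: List[SVCall]) -> List[SVCall]:
    """Nested interval keys can restate one event: keep the best-scoring call
    per overlap cluster, localized to the tightest member interval."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.start_bp, c.end_bp))
    kept: List[SVCall] = []
    for c in calls:
        merged = False
        for i, k in enumerate(kept):
            if (
                k.chrom == c.chrom and k.sv_type == c.sv_type
                and c.start_bp < k.end_bp and k.start_bp < c.end_bp
            ):
                tight = min((k, c), key=lambda x: x.end_bp - x.start_bp)
                best = max((k, c), key=lambda x: x.score)
                best.start_bp, best.end_bp = tight.start_bp, tight.end_bp
                kept[i] = best
                merged = True
                break
        if not merged:
            kept.append(c)
    return kept


def call_cr_indels(
    contig_alignments,
    contig_maps,
    ref: ReferenceDigest,
    noise: NoiseModel,
    min_confidence: float = 9.0,
    min_delta_bp: float = 2_000.0,
) -> List[SVCall]:
    """Contig-vs-reference calls; zygosity is not determined by this module.

    A call requires both |d_contig - d0| > min_delta_bp and a discrepancy
    beyond 3 sigma(d0).
    """
    attach_query_positions(contig_alignments, contig_maps)
    calls: List[SVCall] = []
    for a in _flatten(contig_alignments):
        if np.isfinite(a.confidence) and a.confidence <= min_confidence:
            continue
        chain = sorted(a.pairs, key=lambda p: p[1])
        lm = ref.chromosomes[a.ref_id]
        qpos = a.query_positions
        for (q1, r1), (q2, r2) in zip(chain[:-1], chain[1:]):
            d0 = float(lm.positions[r2] - lm.positions[r1])
            dc = abs(float(qpos[q2] - qpos[q1]))
            if d0 <= 0 or dc <= 0:
                continue
            disc = dc - d0
            if abs(disc) > min_delta_bp and abs(disc) > 3.0 * float(noise.sigma(d0)):
                calls.append(
                    SVCall(
                        sv_type="insertion" if disc > 0 else "deletion",
                        chrom=a.ref_id, start_bp=float(lm.positions[r1]),
                        end_bp=float(lm.positions[r2]), size_delta_bp=float(disc),
                        zygosity="unknown", support_count=1,
                        score=abs(disc) / float(noise.sigma(d0)), module="CR",
                        sample_id=a.query_id,
                    )
                )
    return _dedupe_overlapping(calls)


def bagging_normalize(
    molecule_ids: Sequence[str],
    total_aligned_in_sample: int,
    target_total: int = 1_000_000,
    seed: int = 0,
) -> List[str]:
    """With-replacement resampling so the locus behaves as if the sample had
    ``target_total`` aligned molecules in total. No-op for samples at or above
    the target."""
    if total_aligned_in_sample < 1:
        raise ValueError("total_aligned_in_sample must be >= 1")
    ids = list(molecule_ids)
    if total_aligned_in_sample >= target_total:
        return ids
    m = int(round(len(ids) * target_total / total_aligned_in_sample))
    rng = np.random.default_rng(seed)
    return [ids[i] for i in rng.integers(0, len(ids), m)]


def _sizes_agree(a: float, b: float) -> bool:
    return abs(a - b) <= max(2_000.0, 0.2 * max(abs(a), abs(b)))


def harmonize_calls(
    mr: Sequence[SVCall],
    cr: Sequence[SVCall],
    mcr: Sequence[SVCall],
    merge_tol: float = 0.5,
) -> List[SVCall]:
    """Merge per-module calls into one high-confidence list.

    Same-type calls with reciprocal overlap >= merge_tol and agreeing sizes
    (within max(2 kb, 20%)) collapse into one; zygosity is taken from MR/MCR
    when available; contributing modules are recorded on ``call.modules``.
    """
    pool = [(c, c.module) for c in list(mr) + list(mcr) + list(cr)]
    merged: List[SVCall] = []
    for c, mod in pool:
        hit = None
        for k in merged:
            if (
                k.sv_type == c.sv_type
                and k.reciprocal_overlap(c) >= merge_tol
                and _sizes_agree(k.size_delta_bp, c.size_delta_bp)
            ):
                hit = k
                break
        if hit is None:
            c.modules = (mod,)
            merged.append(c)
        else:
            hit.modules = tuple(sorted(set(hit.modules) | {mod}))
            if hit.zygosity == "unknown" and c.zygosity != "unknown":
                hit.zygosity = c.zygosity
            hit.support_count = max(hit.support_count, c.support_count)
    # flag conflicting types at one locus
    for i, a in enumerate(merged):
        for b in merged[i + 1 :]:
            if a.sv_type != b.sv_type and a.reciprocal_overlap(b) >= merge_tol:
                a.flags = getattr(a, "flags", ()) + ("type_conflict",)
                b.flags = getattr(b, "flags", ()) + ("type_conflict",)
    return sorted(merged, key=lambda c: (c.chrom, c.start_bp, c.end_bp))
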
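"""Joining calls to simulator ground truth for recall/precision/zygosity checks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .models import SVCall
from .simulate import TruthRecord


@dataclass
class TruthMatch:
    truth: TruthRecord
    call: Optional[SVCall]  # None = missed
    zygosity_ok: bool = False
    size_error_bp: float = float("nan")


def _compatible(call: SVCall, rec: TruthRecord, tol_bp: float) -> bool:
    if call.chrom != rec.chrom:
        return False
    mid = 0.5 * (rec.ref_start + rec.ref_end)
    if not (call.start_bp - tol_bp <= mid <= call.end_bp + tol_bp):
        return False
    type_ok = call.sv_type == rec.sv_type or (
        call.sv_type == "multi_indel"
        and rec.sv_type in ("insertion", "deletion")
    )
    if not type_ok:
        return False
    if rec.sv_type in ("insertion", "deletion"):
        if call.size_delta_bp * rec.size_delta_bp <= 0:
            return False
        return abs(call.size_delta_bp - rec.size_delta_bp) <= max(
            3_000.0, 0.5 * abs(rec.size_delta_bp)
        )
    return True


def match_calls_to_truth(
    calls: Sequence[SVCall],
    truth: Sequence[TruthRecord],
    tol_bp: float = 30_000.0,
) -> List[TruthMatch]:
    """One-to-one truth/call assignment, closest size agreement first."""
    pairs = []
    for ti, rec in enumerate(truth):
        for ci, call in enumerate(calls):
            if _compatible(call, rec, tol_bp):
                cost = abs(call.size_delta_bp - rec.size_delta_bp) + 1e-6 * abs(
                    call.start_bp - rec.ref_start
                )
                pairs.append((cost, ti, ci))
    pairs.sort()
    used_t, used_c = set(), set()
    assigned = {}
    for _, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        assigned[ti] = ci
    out = []
    for ti, rec in enumerate(truth):
        if ti in assigned:
            call = calls[assigned[ti]]
            out.append(
                TruthMatch(
                    rec, call,
                    zygosity_ok=(call.zygosity == rec.zygosity),
                    size_error_bp=call.size_delta_bp - rec.size_delta_bp,
                )
            )
        else:
            out.append(TruthMatch(rec, None))
    return out


def recall_by_type(matches: Sequence[TruthMatch]) -> dict:
    out = {}
    for m in matches:
        hit, tot = out.get(m.truth.sv_type, (0, 0))
        out[m.truth.sv_type] = (hit + (m.call is not None), tot + 1)
    return {k: (h / t if t else float("nan")) for k, (h, t) in out.items()}


def zygosity_accuracy(matches: Sequence[TruthMatch]) -> float:
    rec = [m for m in matches if m.call is not None]
    if not rec:
        return float("nan")
    return sum(m.zygosity_ok for m in rec) / len(rec)


def false_calls(calls: Sequence[SVCall], matches: Sequence[TruthMatch]) -> List[SVCall]:
    matched_ids = {id(m.call) for m in matches if m.call is not None}
    return [c for c in calls if id(c) not in matched_ids]
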
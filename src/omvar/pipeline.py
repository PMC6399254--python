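"""End-to-end convenience drivers tying simulator, aligner, and callers together."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

from .align import (
    AlignParams,
    align_map,
    calibrate_confidence,
    refine_alignment,
    score_alignments,
)
from .complexsv import call_complex_svs
from .digest import ReferenceDigest
from .indels import call_mr_indels
from .models import LabelMap, SVCall
from .simulate import NoiseModel, Sample, generate_molecules, make_contigs


def align_molecules(
    molecules: Sequence[LabelMap],
    ref: ReferenceDigest,
    params: AlignParams = AlignParams(),
    seed: int = 0,
    refine: bool = False,
    calibrate: bool = True,
):
    """Align molecules to the reference, with confidence scoring attached."""
    refs = list(ref.chromosomes.values())
    alns = []
    for m in molecules:
        for a in align_map(m, refs, params):
            alns.append(refine_alignment(a, m, refs, params) if refine else a)
    if calibrate:
        model = calibrate_confidence(refs, params)  # null seed derived from ref
        score_alignments(alns, model)
    return alns


def mr_call_sample(
    sample: Sample,
    noise: NoiseModel,
    seed: int,
    params: AlignParams = AlignParams(),
    coverage: Optional[float] = None,
    min_support: int = 10,
    lr_cutoff_log10: float = 3.0,
    molecules: Optional[Sequence[LabelMap]] = None,
) -> Tuple[List[SVCall], List[LabelMap]]:
    """Simulate molecules for a sample (unless given) and run the MR caller."""
    if molecules is None:
        molecules = generate_molecules(sample, noise, seed, coverage=coverage)
    alns = align_molecules(molecules, sample.reference, params, seed=seed + 1)
    calls = call_mr_indels(
        alns, molecules, sample.reference, noise,
        min_support=min_support, lr_cutoff_log10=lr_cutoff_log10, seed=seed + 2,
    )
    for c in calls:
        c.sample_id = sample.sample_id
    return calls, list(molecules)


def complex_call_sample(
    sample: Sample,
    noise: NoiseModel,
    seed: int,
    params: AlignParams = AlignParams(),
    coverage: Optional[float] = None,
    window_bp: float = 200_000.0,
    molecules: Optional[Sequence[LabelMap]] = None,
) -> List[SVCall]:
    """Contig candidates plus molecule adjudication for one sample."""
    ref = sample.reference
    refs = list(ref.chromosomes.values())
    contigs = make_contigs(sample, noise, seed)
    calns = [
        refine_alignment(a, c, refs, params)
        for c in contigs
        for a in align_map(c, refs, params)
    ]
    if molecules is None:
        molecules = generate_molecules(sample, noise, seed + 1, coverage=coverage)
    malns = [
        refine_alignment(a, m, refs, params)
        for m in molecules
        for a in align_map(m, refs, params)
    ]
    calls = call_complex_svs(calns, malns, ref.chromosomes, window_bp)
    for c in calls:
        c.sample_id = sample.sample_id
    return calls
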
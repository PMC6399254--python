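"""Desk-scale study recipes exercising the full pipeline on synthetic data.

These functions define the reference experiments the package is validated
against: indel recovery and type-I error at production noise and coverage,
complex-SV recovery per signature type, trio Mendelian concordance, and
population-structure recovery. Problem sizes are chosen so one study runs in
minutes on a single core while keeping enough events for stable rates; the
SV size ranges follow the large-indel regime the method targets (calling
floor 2 kb, typical sizes up to tens of kb).
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from .complexsv import ComplexCandidate, adjudicate_candidate
from .evaluate import false_calls, match_calls_to_truth, recall_by_type, zygosity_accuracy
from .pipeline import complex_call_sample, mr_call_sample
from .popstruct import (
    build_occurrence_matrix,
    pca_samples,
    population_tree,
    sharing_fractions,
    trio_concordance,
)
from .simulate import (
    NoiseModel,
    generate_molecules,
    implant_svs,
    make_contigs,
    simulate_cohort,
    simulate_reference,
    simulate_trio,
    truth_calls,
)


def indel_recovery_study(
    seed: int,
    n_svs: int = 200,
    n_replicates: int = 10,
    chrom_len: float = 6_000_000.0,
    size_range=(3_000.0, 50_000.0),
    coverage: Optional[float] = None,
    min_support: int = 6,
) -> Dict[str, float]:
    """Implant hom/het indels in replicate samples, run the MR caller, join
    to truth.

    The indels are spread over ``n_replicates`` samples sharing one simulated
    reference (one confidence calibration), giving an SV density of about one
    per 300 kb — several-fold denser than a typical individual genome but
    sparse enough that a 262-kb molecule rarely has to cross two large SVs in
    one alignment. Support threshold defaults to the loose value (6) used for
    high-confidence lists under uneven molecule support.
    """
    rng = np.random.default_rng(seed)
    ref = simulate_reference(1, chrom_len, 10_000, seed=seed + 1)
    noise = NoiseModel()
    per_rep = int(np.ceil(n_svs / n_replicates))
    all_matches = []
    n_unmatched = 0
    remaining = n_svs
    for rep in range(n_replicates):
        k = min(per_rep, remaining)
        remaining -= k
        if k == 0:
            break
        spec = [
            {
                "sv_type": str(rng.choice(["deletion", "insertion"])),
                "size": float(rng.uniform(*size_range)),
                "zygosity": str(rng.choice(["hom", "het"])),
            }
            for _ in range(k)
        ]
        sample = implant_svs(ref, spec, seed=seed + 2 + 13 * rep, sample_id=f"R{rep}")
        calls, _ = mr_call_sample(
            sample, noise, seed=seed + 3 + 13 * rep, coverage=coverage,
            min_support=min_support,
        )
        matches = match_calls_to_truth(calls, sample.truth.records)
        all_matches.extend(matches)
        n_unmatched += len(false_calls(calls, matches))
    recalls = recall_by_type(all_matches)
    errors = np.array([m.size_error_bp for m in all_matches if m.call is not None])
    return {
        "deletion_recall": recalls.get("deletion", float("nan")),
        "insertion_recall": recalls.get("insertion", float("nan")),
        "zygosity_accuracy": zygosity_accuracy(all_matches),
        "size_bias_bp": float(errors.mean()) if errors.size else float("nan"),
        "size_bias_sem_bp": float(errors.std(ddof=1) / np.sqrt(errors.size)) if errors.size > 1 else float("nan"),
        "n_truth": float(len(all_matches)),
        "n_recovered": float(sum(m.call is not None for m in all_matches)),
        "n_unmatched_calls": float(n_unmatched),
    }


def false_call_study(
    seed: int,
    n_replicates: int = 20,
    chrom_len: float = 5_000_000.0,
    coverage: Optional[float] = None,
    min_support: int = 6,
) -> Dict[str, float]:
    """Type-I error: SV-free molecule replicates over one reference.

    Replicates share the simulated reference (one confidence calibration) and
    draw independent molecule noise.
    """
    ref = simulate_reference(1, chrom_len, 10_000, seed=seed + 10)
    sample = implant_svs(ref, [], seed=seed + 11)
    noise = NoiseModel()
    total = 0
    for rep in range(n_replicates):
        calls, _ = mr_call_sample(
            sample, noise, seed=seed + 100 + 7 * rep, coverage=coverage,
            min_support=min_support,
        )
        total += len(calls)
    return {
        "false_calls_total": float(total),
        "false_calls_per_5mb": total / n_replicates * (5_000_000.0 / chrom_len),
        "n_replicates": float(n_replicates),
    }


def _complex_sv_spec() -> List[dict]:
    inv = [
        {"sv_type": "inversion", "chrom": "chr1", "start": s, "end": e, "zygosity": "hom"}
        for s, e in [
            (1_000_000, 1_250_000), (2_000_000, 2_200_000), (3_000_000, 3_300_000),
            (4_000_000, 4_150_000), (5_000_000, 5_350_000),
        ]
    ]
    dup = [
        {"sv_type": "duplication", "chrom": c, "start": s, "end": e, "copies": k, "zygosity": "hom"}
        for c, s, e, k in [
            ("chr1", 6_000_000, 6_100_000, 1), ("chr1", 6_600_000, 6_700_000, 2),
            ("chr2", 3_200_000, 3_300_000, 1), ("chr2", 3_600_000, 3_700_000, 2),
            ("chr2", 4_000_000, 4_100_000, 1),
        ]
    ]
    intra = [
        {"sv_type": "intra_translocation", "chrom": "chr2", "start": s, "end": s + 150_000,
         "dest_pos": d, "zygosity": "hom"}
        for s, d in [
            (300_000, 8_200_000), (900_000, 8_600_000), (1_500_000, 9_000_000),
            (2_100_000, 9_400_000), (2_700_000, 9_800_000),
        ]
    ]
    inter = [
        {"sv_type": "inter_translocation", "chrom": "chr2", "start": s, "end": s + 150_000,
         "dest_chrom": "chr1", "dest_pos": d, "zygosity": "hom"}
        for s, d in [
            (4_400_000, 7_600_000), (5_000_000, 8_000_000), (5_600_000, 8_400_000),
            (6_200_000, 8_800_000), (6_800_000, 9_200_000),
        ]
    ]
    return inv + dup + intra + inter


def complex_recovery_study(
    seed: int,
    coverage: Optional[float] = None,
    breakpoint_tol: float = 150_000.0,
) -> Dict[str, float]:
    """Recall per complex-SV signature type on one implanted sample."""
    ref = simulate_reference(2, 10_000_000, 10_000, seed=seed + 20)
    spec = _complex_sv_spec()
    # a duplicated unit is only visible to split alignment when it carries at
    # least min_labels_per_segment labels; extend sparse units to the 6th
    # interior label (the same kind of floor the small-inversion search
    # applies with its 4-label rule)
    for entry in spec:
        if entry["sv_type"] == "duplication":
            pos = ref.chromosomes[entry["chrom"]].positions
            inside = pos[(pos >= entry["start"]) & (pos < entry["end"])]
            if inside.size < 6:
                after = pos[pos >= entry["start"]]
                if after.size >= 6:
                    entry["end"] = float(after[5] + 1_000.0)
    sample = implant_svs(ref, spec, seed=seed + 21)
    noise = NoiseModel()
    calls = complex_call_sample(sample, noise, seed=seed + 22, coverage=coverage)

    def recovered(rec) -> bool:
        # breakpoints of the truth event, in reference coordinates
        if rec.sv_type == "inversion":
            truth_bps = [(rec.chrom, rec.ref_start), (rec.chrom, rec.ref_end)]
            want = {"inversion"}
        elif rec.sv_type == "duplication":
            truth_bps = [(rec.chrom, rec.ref_start), (rec.chrom, rec.ref_end)]
            want = {"duplication"}
        elif rec.sv_type == "intra_translocation":
            truth_bps = [(rec.chrom, rec.ref_start), (rec.chrom, rec.ref_end),
                         (rec.dest_chrom or rec.chrom, rec.dest_pos)]
            want = {"intra_translocation"}
        else:
            truth_bps = [(rec.chrom, rec.ref_start), (rec.chrom, rec.ref_end),
                         (rec.dest_chrom, rec.dest_pos)]
            want = {"inter_translocation"}
        for c in calls:
            if c.sv_type not in want:
                continue
            call_bps = [(c.chrom, c.start_bp), (c.chrom, c.end_bp)]
            if c.chrom2:
                call_bps.append((c.chrom2, c.start_bp))
            hit = any(
                tb[0] == cb[0] and abs(tb[1] - cb[1]) <= breakpoint_tol
                for tb in truth_bps
                for cb in call_bps
            )
            if hit:
                return True
        return False

    out: Dict[str, float] = {}
    for sv_type in ("inversion", "duplication", "intra_translocation", "inter_translocation"):
        recs = [r for r in sample.truth.records if r.sv_type == sv_type]
        out[f"{sv_type}_recall"] = sum(recovered(r) for r in recs) / len(recs)
    out["n_complex_calls"] = float(len(calls))
    return out


def complex_null_study(seed: int, n_seeds: int = 20) -> Dict[str, float]:
    """SV-free contigs must nominate no complex candidates, and constructed
    all-rejecting candidates must fail the S_s > S_r rule."""
    from .align import align_map, refine_alignment
    from .complexsv import candidates_from_contigs

    noise = NoiseModel()
    n_candidates = 0
    for k in range(n_seeds):
        ref = simulate_reference(1, 5_000_000, 10_000, seed=seed + 30 + k)
        sample = implant_svs(ref, [], seed=seed + 60 + k)
        refs = list(ref.chromosomes.values())
        contigs = make_contigs(sample, noise, seed=seed + 90 + k)
        calns = [
            refine_alignment(a, c, refs)
            for c in contigs
            for a in align_map(c, refs)
        ]
        n_candidates += len(candidates_from_contigs(calns))

    # constructed all-rejecting candidates on one SV-free replicate
    ref = simulate_reference(1, 5_000_000, 10_000, seed=seed + 200)
    sample = implant_svs(ref, [], seed=seed + 201)
    mols = generate_molecules(sample, noise, seed=seed + 202, coverage=30)
    refs = list(ref.chromosomes.values())
    from .align import align_map, refine_alignment

    malns = [refine_alignment(a, m, refs) for m in mols for a in align_map(m, refs)]
    rng = np.random.default_rng(seed + 203)
    rejected = 0
    n_cand = 20
    for _ in range(n_cand):
        lo = float(rng.uniform(500_000, 4_000_000))
        cand = ComplexCandidate(
            "inversion", [("chr1", lo), ("chr1", lo + 300_000)], "fake_contig"
        )
        if adjudicate_candidate(cand, malns, ref.chromosomes) is None:
            rejected += 1
    return {
        "sv_free_candidates": float(n_candidates),
        "n_sv_free_seeds": float(n_seeds),
        "all_rejecting_rejected_fraction": rejected / n_cand,
    }


def trio_study(
    seed: int,
    n_trios: int = 20,
    chrom_len: float = 3_000_000.0,
    n_svs_per_parent: int = 10,
    coverage: Optional[float] = None,
    min_support: int = 6,
) -> Dict[str, float]:
    """Mendelian concordance of independently called trios.

    Parent SV sizes follow the large-indel regime (about 5-30 kb, bracketing
    the ~11 kb average the method typically reports). All three members are
    called independently; a child call is concordant when the merge rule
    finds it in a parent.
    """
    ref = simulate_reference(1, chrom_len, 10_000, seed=seed + 40)
    noise = NoiseModel()
    rng = np.random.default_rng(seed + 41)
    total_child = 0
    total_concordant = 0
    per_trio = []
    for t in range(n_trios):
        # one shared, non-overlapping locus pool split between the parents
        # (parental SVs are population variants; independent placement would
        # fabricate colliding distinct SVs that no real trio would carry)
        pool = implant_svs(
            ref,
            [
                {
                    "sv_type": str(rng.choice(["deletion", "insertion"])),
                    "size": float(rng.uniform(5_000, 30_000)),
                    "zygosity": "hom",
                }
                for _ in range(2 * n_svs_per_parent)
            ],
            seed=seed + 299 + 5 * t,
        )
        loci = sorted(pool.truth.records, key=lambda r: (r.chrom, r.ref_start))
        specs = [[], []]
        for i, rec in enumerate(loci):
            size = abs(rec.size_delta_bp) or rec.ref_end - rec.ref_start
            specs[i % 2].append(
                {
                    "sv_type": rec.sv_type, "chrom": rec.chrom, "start": rec.ref_start,
                    "end": rec.ref_end if rec.sv_type != "insertion" else rec.ref_start,
                    "size": size,
                    "zygosity": str(rng.choice(["hom", "het"])),
                }
            )
        father = implant_svs(ref, specs[0], seed=seed + 300 + 5 * t, sample_id="father")
        mother = implant_svs(ref, specs[1], seed=seed + 301 + 5 * t, sample_id="mother")
        child = simulate_trio(father, mother, seed=seed + 302 + 5 * t)
        calls = {}
        for k, (name, smp) in enumerate(
            (("father", father), ("mother", mother), ("child", child))
        ):
            calls[name], _ = mr_call_sample(
                smp, noise, seed=seed + 400 + 11 * t + k,
                coverage=coverage, min_support=min_support,
            )
        frac = trio_concordance(calls["child"], calls["father"], calls["mother"])
        if frac is not None:
            n_child = len(calls["child"])
            total_child += n_child
            total_concordant += round(frac * n_child)
            per_trio.append(frac)
    return {
        "mendelian_concordance": total_concordant / total_child if total_child else float("nan"),
        "n_child_calls": float(total_child),
        "n_trios": float(len(per_trio)),
    }


def _tree_groups_pair(newick_tree, pair) -> bool:
    subsets = set()
    for node in newick_tree.non_tips(include_self=False):
        subsets.add(frozenset(t.name for t in node.tips()))
    names = frozenset(t.name for t in newick_tree.tips())
    pair = frozenset(pair)
    other = names - pair
    return pair in subsets or other in subsets


def topology_recovery_study(
    seed: int,
    n_runs: int = 100,
    n_svs: int = 60,
    samples_per_pop: int = 6,
    divergence: float = 0.1,
) -> Dict[str, float]:
    """How often NJ on the occurrence matrix recovers ((P1,P2),(P3,P4))."""
    ref = simulate_reference(1, 6_000_000, 10_000, seed=seed + 50)
    from .models import CohortMetadata

    hits = 0
    for run in range(n_runs):
        cohort = simulate_cohort(
            ref, 4, samples_per_pop, n_svs, divergence, seed=seed + 500 + run,
            nested=True, sv_size_range=(5_000.0, 20_000.0),
        )
        per_sample = {s.sample_id: truth_calls(s) for s in cohort.samples}
        om = build_occurrence_matrix(per_sample)
        meta = CohortMetadata(
            {
                s.sample_id: {
                    "population": cohort.populations[s.sample_id],
                    "super_population": cohort.super_populations[cohort.populations[s.sample_id]],
                    "sex": "F",
                }
                for s in cohort.samples
            }
        )
        tree, _ = population_tree(om, meta)
        if _tree_groups_pair(tree, ("P1", "P2")):
            hits += 1
    return {"topology_recovery_rate": hits / n_runs, "n_runs": float(n_runs)}


def pca_separation_study(seed: int, divergence: float = 0.35) -> Dict[str, float]:
    """PC1 must separate the two deeply diverged population pairs."""
    from .models import CohortMetadata

    ref = simulate_reference(1, 6_000_000, 10_000, seed=seed + 60)
    cohort = simulate_cohort(
        ref, 4, 6, 80, divergence, seed=seed + 61, nested=True,
        sv_size_range=(5_000.0, 20_000.0),
    )
    per_sample = {s.sample_id: truth_calls(s) for s in cohort.samples}
    om = build_occurrence_matrix(per_sample)
    scores, _ = pca_samples(om)
    group_a = [s for s in om.samples if s.startswith(("P1", "P2"))]
    group_b = [s for s in om.samples if s.startswith(("P3", "P4"))]
    a = scores.loc[group_a, "PC1"]
    b = scores.loc[group_b, "PC1"]
    separated = float(max(a) < min(b) or max(b) < min(a))
    margin = float(min(b) - max(a)) if np.mean(a) < np.mean(b) else float(min(a) - max(b))
    return {"pc1_separates_clades": separated, "pc1_margin": margin}


def sharing_recovery_study(
    seed: int,
    n_cosmopolitan: int = 20,
    n_private: int = 10,
    samples_per_sp: int = 8,
) -> Dict[str, float]:
    """Sharing fractions must sum to one and recover a constructed private-SV
    proportion."""
    from .models import CohortMetadata, SVCall

    samples = [f"{sp}{i}" for sp in ("A", "B") for i in range(samples_per_sp)]
    calls: Dict[str, list] = {s: [] for s in samples}
    for k in range(n_cosmopolitan):
        for s in samples:
            calls[s].append(
                SVCall("deletion", "chr1", 1e5 + 60_000 * k, 1e5 + 60_000 * k + 8_000,
                       -8_000.0, "hom", 12, 10.0, "MR")
            )
    for k in range(n_private):
        for s in samples:
            if s.startswith("A"):
                calls[s].append(
                    SVCall("insertion", "chr2", 1e5 + 60_000 * k, 1e5 + 60_000 * k,
                           9_000.0, "het", 12, 10.0, "MR")
                )
    om = build_occurrence_matrix(calls)
    meta = CohortMetadata(
        {s: {"population": s[0], "super_population": "AFR" if s.startswith("A") else "EAS",
             "sex": "F"} for s in samples}
    )
    out = sharing_fractions(om, meta, n_subsamples=100, seed=seed + 70)
    expected_unique = n_private / (n_private + n_cosmopolitan)
    return {
        "sharing_row_sum_max_dev": float(np.abs(out.sum(axis=1) - 1.0).max()),
        "private_fraction_expected": expected_unique,
        "private_fraction_observed": float(out.loc["AFR", "unique"]),
    }
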
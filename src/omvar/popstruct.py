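"""Cohort-level SV analyses: occurrence matrix, sharing, tree, PCA, size
ANOVA, and trio Mendelian concordance.

The occurrence matrix codes each sample's allele count (0/1/2) at each merged
SV locus; unknown-zygosity presence counts 1. Population allele-frequency
vectors derived from it drive a neighbor-joining tree; sample-level structure
comes from a PCA of the allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import CohortMetadata, SVCall

_ZYG_COUNT = {"hom": 2, "het": 1, "tri": 2, "unknown": 1}


def _sizes_agree(a: float, b: float) -> bool:
    return abs(a - b) <= max(2_000.0, 0.2 * max(abs(a), abs(b)))


@dataclass
class OccurrenceMatrix:
    counts: pd.DataFrame  # samples x loci, allele counts in {0,1,2}
    loci: pd.DataFrame  # locus metadata: chrom, start, end, sv_type
    sizes: Dict[int, Dict[str, float]] = field(default_factory=dict)  # locus -> sample -> size

    @property
    def samples(self) -> List[str]:
        return list(self.counts.index)


def build_occurrence_matrix(
    per_sample_calls: Dict[str, Sequence[SVCall]],
    merge_tol: float = 0.5,
) -> OccurrenceMatrix:
    """Merge per-sample calls into cohort loci and code allele counts.

    Same-type calls from different samples merge into one locus by
    single-linkage under reciprocal overlap >= merge_tol plus size agreement
    within max(2 kb, 20%). Insertions (point intervals on the reference) are
    compared on their [start, start+|size|) footprint.
    """
    pool: List[Tuple[str, SVCall]] = [
        (sid, c) for sid, calls in per_sample_calls.items() for c in calls
    ]

    def footprint(c: SVCall) -> Tuple[float, float]:
        if c.sv_type == "insertion" and c.end_bp - c.start_bp < abs(c.size_delta_bp):
            return c.start_bp, c.start_bp + abs(c.size_delta_bp)
        return c.start_bp, c.end_bp

    parent = list(range(len(pool)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(len(pool)), key=lambda i: (pool[i][1].chrom, footprint(pool[i][1])[0]))
    for a_pos, i in enumerate(order):
        _, ci = pool[i]
        fi = footprint(ci)
        for j in order[a_pos + 1 :]:
            _, cj = pool[j]
            if cj.chrom != ci.chrom:
                break
            fj = footprint(cj)
            if fj[0] > fi[1]:
                break
            if ci.sv_type != cj.sv_type:
                continue
            lo, hi = max(fi[0], fj[0]), min(fi[1], fj[1])
            if hi <= lo:
                continue
            ov = hi - lo
            ro = min(ov / max(fi[1] - fi[0], 1.0), ov / max(fj[1] - fj[0], 1.0))
            if ro >= merge_tol and _sizes_agree(ci.size_delta_bp, cj.size_delta_bp):
                union(i, j)

    clusters: Dict[int, List[int]] = {}
    for i in range(len(pool)):
        clusters.setdefault(find(i), []).append(i)

    samples = sorted(per_sample_calls)
    loci_rows = []
    counts = np.zeros((len(samples), len(clusters)), dtype=int)
    sizes: Dict[int, Dict[str, float]] = {}
    sample_idx = {s: k for k, s in enumerate(samples)}
    for col, members in enumerate(sorted(clusters.values(), key=lambda ms: (
        pool[ms[0]][1].chrom, footprint(pool[ms[0]][1])[0]
    ))):
        calls = [pool[i] for i in members]
        starts = [footprint(c)[0] for _, c in calls]
        ends = [footprint(c)[1] for _, c in calls]
        loci_rows.append(
            {
                "locus": col, "chrom": calls[0][1].chrom,
                "start": float(np.median(starts)), "end": float(np.median(ends)),
                "sv_type": calls[0][1].sv_type,
            }
        )
        sizes[col] = {}
        for sid, c in calls:
            k = sample_idx[sid]
            counts[k, col] = max(counts[k, col], _ZYG_COUNT.get(c.zygosity, 1))
            sizes[col][sid] = c.size_delta_bp
    return OccurrenceMatrix(
        pd.DataFrame(counts, index=samples, columns=range(len(clusters))),
        pd.DataFrame(loci_rows),
        sizes,
    )


def sharing_fractions(
    matrix: OccurrenceMatrix,
    meta: CohortMetadata,
    n_subsamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per super-population (unique, partial, universal) sharing fractions.

    Each sub-sample draws equal numbers of samples per super-population to
    remove sample-size effects; an SV present in the focal super-population
    is unique (nowhere else), universal (in all others too), or partially
    shared; fractions are averaged over sub-samples.
    """
    meta.require(matrix.samples)
    by_sp: Dict[str, List[str]] = {}
    for s in matrix.samples:
        by_sp.setdefault(meta.super_population(s), []).append(s)
    sps = sorted(by_sp)
    if len(sps) < 2:
        raise ValueError("sharing requires at least two super-populations")
    draw = min(len(v) for v in by_sp.values())
    rng = np.random.default_rng(seed)
    acc = {sp: np.zeros(3) for sp in sps}
    for _ in range(n_subsamples):
        chosen = {
            sp: list(rng.choice(by_sp[sp], draw, replace=False)) for sp in sps
        }
        present = {
            sp: matrix.counts.loc[chosen[sp]].to_numpy().sum(axis=0) > 0 for sp in sps
        }
        n_present = np.sum([present[sp] for sp in sps], axis=0)
        for sp in sps:
            mask = present[sp]
            tot = int(mask.sum())
            if tot == 0:
                continue
            unique = int(np.sum(mask & (n_present == 1)))
            universal = int(np.sum(mask & (n_present == len(sps))))
            partial = tot - unique - universal
            acc[sp] += np.array([unique, partial, universal]) / tot
    out = pd.DataFrame(
        {sp: acc[sp] / n_subsamples for sp in sps},
        index=["unique", "partial", "universal"],
    ).T
    return out


def population_frequencies(matrix: OccurrenceMatrix, meta: CohortMetadata) -> pd.DataFrame:
    """Per-population SV allele frequencies (mean allele count / 2)."""
    meta.require(matrix.samples)
    pops: Dict[str, List[str]] = {}
    for s in matrix.samples:
        pops.setdefault(meta.population(s), []).append(s)
    return pd.DataFrame(
        {p: matrix.counts.loc[ss].mean(axis=0) / 2.0 for p, ss in sorted(pops.items())}
    ).T


def population_tree(matrix: OccurrenceMatrix, meta: CohortMetadata):
    """Neighbor-joining tree over populations from allele-frequency distances.

    Returns (skbio TreeNode, newick string).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    freqs = population_frequencies(matrix, meta)
    if len(freqs) < 3:
        raise ValueError("tree building requires at least three populations")
    ids = list(freqs.index)
    X = freqs.to_numpy(float)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    tree = nj(DistanceMatrix(D, ids))
    return tree, str(tree)


def pca_samples(matrix: OccurrenceMatrix, n_components: int = 10):
    """Column-centered PCA of allele counts.

    Returns (scores DataFrame, variance-explained fractions). A constant
    matrix yields all-zero scores.
    """
    X = matrix.counts.to_numpy(float)
    X = X - X.mean(axis=0, keepdims=True)
    k = min(n_components, min(X.shape))
    if not np.any(X):
        scores = np.zeros((X.shape[0], k))
        return (
            pd.DataFrame(scores, index=matrix.samples, columns=[f"PC{i+1}" for i in range(k)]),
            np.zeros(k),
        )
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    var = S ** 2
    var_frac = (var / var.sum())[:k]
    scores = (U * S)[:, :k]
    # deterministic sign: largest-magnitude loading positive
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    return (
        pd.DataFrame(scores, index=matrix.samples, columns=[f"PC{i+1}" for i in range(k)]),
        var_frac,
    )


def size_anova(
    matrix: OccurrenceMatrix,
    meta: CohortMetadata,
    min_samples: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Loci whose SV sizes differ among super-populations.

    One-way ANOVA per locus with at least ``min_samples`` carriers, Bonferroni
    corrected over the tested loci.
    """
    from scipy.stats import f_oneway

    meta.require(matrix.samples)
    rows = []
    for locus, sample_sizes in matrix.sizes.items():
        if len(sample_sizes) < min_samples:
            continue
        groups: Dict[str, List[float]] = {}
        for sid, size in sample_sizes.items():
            groups.setdefault(meta.super_population(sid), []).append(size)
        usable = [v for v in groups.values() if len(v) >= 2]
        if len(usable) < 2:
            continue
        if all(np.var(v) == 0 for v in usable) and len({np.mean(v) for v in usable}) == 1:
            continue  # identical sizes everywhere: nothing to test
        stat, p = f_oneway(*usable)
        rows.append({"locus": locus, "F": float(stat), "p": float(p)})
    df = pd.DataFrame(rows, columns=["locus", "F", "p"])
    if df.empty:
        df["p_bonferroni"] = []
        df["significant"] = []
        return df
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    df["significant"] = df["p_bonferroni"] < alpha
    return df[df["significant"]].reset_index(drop=True)


def trio_concordance(
    child: Sequence[SVCall],
    father: Sequence[SVCall],
    mother: Sequence[SVCall],
    merge_tol: float = 0.5,
) -> Optional[float]:
    """Fraction of child calls matched (same type, merge rule) in a parent.

    Returns None for an empty child call set.
    """
    child = list(child)
    if not child:
        return None
    om = build_occurrence_matrix(
        {"child": child, "father": list(father), "mother": list(mother)},
        merge_tol=merge_tol,
    )
    counts = om.counts
    child_loci = counts.loc["child"] > 0
    parental = (counts.loc["father"] > 0) | (counts.loc["mother"] > 0)
    concordant = int((child_loci & parental).sum())
    return concordant / int(child_loci.sum())
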
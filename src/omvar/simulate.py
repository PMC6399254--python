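"""Synthetic optical-map data with ground truth.

Generates reference label maps, diploid samples with implanted SVs, noisy
single molecules, consensus-contig stand-ins, trios, and multi-population
cohorts. The noise defaults mirror a production nick-label mapping run:
6% missed labels, 0.6 false labels per 100 kb, additive sizing noise of
0.20 kb plus 1% relative error, a 450-bp label resolution, a 150-kb molecule
length floor with 262-kb length N50, and 79x coverage.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import lognorm

from .digest import DEFAULT_RESOLUTION_BP, ReferenceDigest, merge_labels
from .models import LabelMap, SVCall


@dataclass(frozen=True)
class NoiseModel:
    fn_rate: float = 0.06
    fp_per_100kb: float = 0.6
    sizing_sf: float = 0.20  # kb, additive scale
    sizing_sr: float = 0.01  # relative coefficient
    resolution_bp: float = DEFAULT_RESOLUTION_BP
    min_molecule_bp: float = 150_000.0
    target_coverage: float = 79.0
    length_n50_bp: float = 262_000.0

    def __post_init__(self) -> None:
        if not 0 <= self.fn_rate <= 1:
            raise ValueError("fn_rate must be in [0,1]")
        if self.min_molecule_bp > self.length_n50_bp:
            raise ValueError("min_molecule_bp must be <= length_n50_bp")

    def sigma(self, t) -> np.ndarray:
        """Sizing-noise scale (bp) for a spanned length t (bp)."""
        return np.sqrt((1000.0 * self.sizing_sf) ** 2 + (self.sizing_sr * np.asarray(t, float)) ** 2)


NOISELESS = NoiseModel(fn_rate=0.0, fp_per_100kb=0.0, sizing_sf=0.0, sizing_sr=0.0)


@dataclass
class TruthRecord:
    sv_type: str
    chrom: str
    ref_start: float
    ref_end: float
    size_delta_bp: float
    zygosity: str  # hom | het
    haplotypes: Tuple[int, ...]
    dest_chrom: Optional[str] = None
    dest_pos: Optional[float] = None
    copies: int = 1
    locus_id: Optional[int] = None


@dataclass
class TruthSet:
    records: List[TruthRecord] = field(default_factory=list)
    allele_freqs: Dict[int, Dict[str, float]] = field(default_factory=dict)  # locus -> pop -> freq

    def for_sample(self) -> List[TruthRecord]:
        return list(self.records)


@dataclass
class Sample:
    sample_id: str
    haplotypes: Tuple[Dict[str, LabelMap], Dict[str, LabelMap]]
    truth: TruthSet
    reference: ReferenceDigest


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(
    n_chrom: int,
    chrom_len_bp: float,
    mean_label_spacing_bp: float,
    seed: int,
    resolution_bp: float = DEFAULT_RESOLUTION_BP,
) -> ReferenceDigest:
    """Reference label maps from a homogeneous point process, resolution-merged."""
    if mean_label_spacing_bp <= resolution_bp:
        raise ValueError("mean label spacing must exceed the merge resolution")
    rng = np.random.default_rng(seed)
    chroms = {}
    gaps = {}
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        n_draw = int(2 * chrom_len_bp / mean_label_spacing_bp) + 20
        pos = np.cumsum(rng.exponential(mean_label_spacing_bp, n_draw))
        pos = pos[pos < chrom_len_bp - 1]
        pos = merge_labels(pos, resolution_bp)
        chroms[name] = LabelMap(name, "reference", float(chrom_len_bp), pos)
        gaps[name] = []
    return ReferenceDigest(chroms, gaps)


# ---------------------------------------------------------------------------
# SV implantation
# ---------------------------------------------------------------------------

def _apply_deletion(lm: LabelMap, start: float, end: float) -> LabelMap:
    size = end - start
    p = lm.positions
    new = np.concatenate([p[p < start], p[p >= end] - size])
    return LabelMap(lm.map_id, lm.kind, lm.length_bp - size, new, lm.sample_id)


def _insertion_labels(size: float, label_spacing: Optional[float], rng) -> np.ndarray:
    if label_spacing is None or label_spacing <= 0:
        return np.empty(0)
    ins = np.cumsum(rng.exponential(label_spacing, int(3 * size / label_spacing) + 5))
    return ins[ins < size - 1]


def _apply_insertion(lm: LabelMap, start: float, size: float, ins: np.ndarray) -> LabelMap:
    p = lm.positions
    new = np.concatenate([p[p < start], start + ins, p[p >= start] + size])
    new = merge_labels(new)
    return LabelMap(lm.map_id, lm.kind, lm.length_bp + size, new, lm.sample_id)


def _apply_inversion(lm: LabelMap, start: float, end: float) -> LabelMap:
    p = lm.positions
    inside = (p >= start) & (p < end)
    new = p.copy()
    new[inside] = start + end - p[inside]
    return LabelMap(lm.map_id, lm.kind, lm.length_bp, np.sort(new), lm.sample_id)


def _apply_duplication(lm: LabelMap, start: float, end: float, extra_copies: int) -> LabelMap:
    unit = end - start
    p = lm.positions
    unit_labels = p[(p >= start) & (p < end)] - start
    parts = [p[p < end]]
    for m in range(extra_copies):
        parts.append(end + m * unit + unit_labels)
    parts.append(p[p >= end] + extra_copies * unit)
    new = merge_labels(np.concatenate(parts))
    return LabelMap(lm.map_id, lm.kind, lm.length_bp + extra_copies * unit, new, lm.sample_id)


def implant_svs(
    ref: ReferenceDigest,
    sv_spec: Sequence[dict],
    seed: int,
    sample_id: str = "S1",
    insert_label_spacing: Optional[float] = "reference",  # type: ignore[assignment]
) -> Sample:
    """Build a diploid sample by implanting SVs into reference label maps.

    ``sv_spec`` entries are dicts with keys ``sv_type``, ``zygosity`` and
    either explicit loci (``chrom``, ``start``, ``end``/``size``) or only a
    ``size`` for random non-overlapping placement. Heterozygous SVs go to one
    randomly chosen haplotype. Inserted segments carry labels at the
    reference density by default (``insert_label_spacing=None`` makes
    label-free insertions).
    """
    rng = np.random.default_rng(seed)
    mean_spacing = {
        c: (lm.length_bp / max(lm.n_labels, 1)) for c, lm in ref.chromosomes.items()
    }
    chrom_ids = list(ref.chromosomes)
    lengths = np.array([ref.chromosomes[c].length_bp for c in chrom_ids])

    # resolve loci (random placement keeps loci apart by >= one mean label interval)
    placed: List[dict] = []
    occupied: Dict[str, List[Tuple[float, float]]] = {c: [] for c in chrom_ids}

    def overlaps(chrom, lo, hi):
        pad = 2 * mean_spacing[chrom]
        return any(lo - pad < e and s < hi + pad for s, e in occupied[chrom])

    for entry in sv_spec:
        entry = dict(entry)
        svt = entry["sv_type"]
        if "chrom" in entry and "start" in entry:
            chrom = entry["chrom"]
            start = float(entry["start"])
            span = float(entry.get("end", start + entry.get("size", 0)) - start)
            if svt == "insertion":
                span = 0.0
            if overlaps(chrom, start, start + max(span, entry.get("size", 0))):
                raise ValueError(f"SV at {chrom}:{start} overlaps a previous locus")
        else:
            size = float(entry["size"])
            span = 0.0 if svt == "insertion" else size
            for _ in range(1000):
                chrom = chrom_ids[rng.choice(len(chrom_ids), p=lengths / lengths.sum())]
                L = ref.chromosomes[chrom].length_bp
                margin = 0.08 * L
                start = float(rng.uniform(margin, L - margin - span))
                if not overlaps(chrom, start, start + max(span, size)):
                    break
            else:
                raise ValueError("could not place SV without overlap")
            entry["chrom"], entry["start"] = chrom, start
        entry["end"] = entry["start"] + span
        occupied[entry["chrom"]].append((entry["start"], entry["end"] + entry.get("size", 0)))
        placed.append(entry)

    truth = TruthSet()
    haps: List[Dict[str, LabelMap]] = [
        {c: replace(ref.chromosomes[c], sample_id=sample_id) for c in chrom_ids}
        for _ in range(2)
    ]
    # Decompose every SV into single-coordinate edits and apply them in
    # descending coordinate order per chromosome, so reference coordinates of
    # not-yet-applied edits stay valid. A translocation becomes a paste (with
    # segment content captured from the still-unedited source interval) plus
    # a cut.
    def _paste(hmaps, chrom, pos, seg, length_delta, sid):
        lm = hmaps[chrom]
        ins = np.concatenate([
            lm.positions[lm.positions < pos], pos + seg,
            lm.positions[lm.positions >= pos] + length_delta,
        ])
        hmaps[chrom] = LabelMap(
            lm.map_id, lm.kind, lm.length_bp + length_delta, merge_labels(ins), sid
        )

    edits_per_hap: List[List[tuple]] = [[], []]
    for entry in placed:
        svt = entry["sv_type"]
        chrom = entry["chrom"]
        start, end = float(entry["start"]), float(entry["end"])
        zyg = entry.get("zygosity", "hom")
        if zyg == "hom":
            targets = (0, 1)
        else:
            targets = (int(entry.get("haplotype", rng.integers(0, 2))),)
        entry["_targets"] = targets
        size = float(entry.get("size", end - start))
        copies = int(entry.get("copies", 1))
        for h in targets:
            if svt == "deletion":
                edits_per_hap[h].append(
                    (chrom, start, lambda hm, c=chrom, s=start, e=end: hm.__setitem__(
                        c, _apply_deletion(hm[c], s, e)))
                )
            elif svt == "insertion":
                spacing = (
                    mean_spacing[chrom]
                    if insert_label_spacing == "reference"
                    else insert_label_spacing
                )
                if "_ins_labels" not in entry:
                    # one allele: both haplotypes of a hom insertion carry the
                    # same inserted label pattern
                    entry["_ins_labels"] = _insertion_labels(size, spacing, rng)
                edits_per_hap[h].append(
                    (chrom, start,
                     lambda hm, c=chrom, s=start, z=size, il=entry["_ins_labels"]:
                     hm.__setitem__(c, _apply_insertion(hm[c], s, z, il)))
                )
            elif svt == "inversion":
                edits_per_hap[h].append(
                    (chrom, start, lambda hm, c=chrom, s=start, e=end: hm.__setitem__(
                        c, _apply_inversion(hm[c], s, e)))
                )
            elif svt == "duplication":
                edits_per_hap[h].append(
                    (chrom, start, lambda hm, c=chrom, s=start, e=end, k=copies:
                     hm.__setitem__(c, _apply_duplication(hm[c], s, e, k)))
                )
            elif svt in ("intra_translocation", "inter_translocation"):
                dest_chrom = entry.get("dest_chrom", chrom)
                dest_pos = float(entry["dest_pos"])
                seg = (
                    ref.chromosomes[chrom].positions[
                        (ref.chromosomes[chrom].positions >= start)
                        & (ref.chromosomes[chrom].positions < end)
                    ]
                    - start
                )
                span = end - start
                edits_per_hap[h].append(
                    (dest_chrom, dest_pos,
                     lambda hm, dc=dest_chrom, dp=dest_pos, sg=seg, sp=span:
                     _paste(hm, dc, dp, sg, sp, sample_id))
                )
                edits_per_hap[h].append(
                    (chrom, start, lambda hm, c=chrom, s=start, e=end: hm.__setitem__(
                        c, _apply_deletion(hm[c], s, e)))
                )
            else:
                raise ValueError(f"unsupported sv_type {svt!r}")
    for h in (0, 1):
        for chrom, coord, fn in sorted(edits_per_hap[h], key=lambda e: -e[1]):
            fn(haps[h])
    for entry in placed:
        svt = entry["sv_type"]
        start, end = float(entry["start"]), float(entry["end"])
        size = float(entry.get("size", end - start))
        copies = int(entry.get("copies", 1))
        if svt == "deletion":
            delta = -(end - start)
        elif svt == "insertion":
            delta = size
        elif svt == "duplication":
            delta = copies * (end - start)
        else:
            delta = 0.0
        truth.records.append(
            TruthRecord(
                svt, entry["chrom"], start, end, delta, entry.get("zygosity", "hom"),
                entry["_targets"],
                dest_chrom=entry.get("dest_chrom"), dest_pos=entry.get("dest_pos"),
                copies=copies, locus_id=entry.get("locus_id"),
            )
        )
    return Sample(sample_id, (haps[0], haps[1]), truth, ref)


# ---------------------------------------------------------------------------
# Molecule generation
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=32)
def _lognorm_mu(n50_bp: float, min_bp: float, sigma: float = 0.55) -> float:
    """Log-normal location so the truncated length law has the requested N50.

    N50 is the length-weighted median: solve E[L; L >= x] = 0.5 E[L; L >= min]
    at x = n50 for the scale parameter.
    """

    def weighted_tail(mu):
        # E[L 1{L>=x}] for lognormal = exp(mu+s^2/2) * Phi((mu+s^2-ln x)/s)
        from scipy.stats import norm

        def tail_mass(x):
            return np.exp(mu + sigma ** 2 / 2) * norm.sf((np.log(x) - mu - sigma ** 2) / sigma)

        return tail_mass(n50_bp) - 0.5 * tail_mass(min_bp)

    return brentq(weighted_tail, np.log(min_bp) - 3, np.log(n50_bp) + 3)


def _draw_lengths(rng, n, noise: NoiseModel) -> np.ndarray:
    mu = _lognorm_mu(noise.length_n50_bp, noise.min_molecule_bp)
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(mu, 0.55, size=2 * n)
        out = np.concatenate([out, draw[draw >= noise.min_molecule_bp]])
    return out[:n]


def generate_molecules(
    sample: Sample,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    coverage: Optional[float] = None,
) -> List[LabelMap]:
    """Noisy single molecules sampled uniformly from both haplotypes.

    Molecules are drawn until total molecule length reaches
    ``coverage x genome length``. Each molecule keeps every true label with
    probability 1 - fn_rate, gains false labels as a Poisson process, has
    every inter-label distance perturbed by Normal sizing noise, is randomly
    flipped, and finally merged at the instrument resolution. The attribute
    ``origin`` on each returned map records (haplotype, chrom, start, flipped)
    for testing.
    """
    rng = np.random.default_rng(seed)
    cov = noise.target_coverage if coverage is None else coverage
    genome_len = sum(lm.length_bp for lm in sample.haplotypes[0].values())
    chrom_ids = list(sample.haplotypes[0])
    mols: List[LabelMap] = []
    total = 0.0
    idx = 0
    lengths = _draw_lengths(rng, max(8, int(cov * genome_len / noise.length_n50_bp) + 8), noise)
    li = 0
    while total < cov * genome_len:
        if li >= lengths.size:
            lengths = _draw_lengths(rng, 64, noise)
            li = 0
        mol_len = float(lengths[li])
        li += 1
        hap = int(rng.integers(0, 2))
        hmaps = sample.haplotypes[hap]
        w = np.array([hmaps[c].length_bp for c in chrom_ids])
        chrom = chrom_ids[rng.choice(len(chrom_ids), p=w / w.sum())]
        lm = hmaps[chrom]
        if mol_len >= lm.length_bp:
            mol_len = lm.length_bp
            start = 0.0
        else:
            start = float(rng.uniform(0, lm.length_bp - mol_len))
        pos = lm.positions[(lm.positions >= start) & (lm.positions < start + mol_len)] - start
        # false negatives
        if noise.fn_rate > 0 and pos.size:
            pos = pos[rng.random(pos.size) >= noise.fn_rate]
        # sizing noise on inter-label distances (and on the leading flank)
        if pos.size and (noise.sizing_sf > 0 or noise.sizing_sr > 0):
            gaps = np.diff(np.concatenate(([0.0], pos)))
            eps = rng.normal(0.0, noise.sigma(gaps))
            gaps = np.maximum(gaps + eps, 1.0)
            pos = np.cumsum(gaps)
            mol_len = max(mol_len + float(eps.sum()), float(pos[-1]) + 1.0)
        # false positives
        n_fp = rng.poisson(noise.fp_per_100kb * mol_len / 1e5)
        if n_fp:
            pos = np.sort(np.concatenate([pos, rng.uniform(0, mol_len, n_fp)]))
        flipped = bool(rng.integers(0, 2))
        if flipped:
            pos = np.sort(mol_len - pos)
        pos = merge_labels(pos, noise.resolution_bp)
        pos = pos[(pos >= 0) & (pos < mol_len)]
        idx += 1
        m = LabelMap(f"{sample.sample_id}_mol{idx}", "molecule", mol_len, pos, sample.sample_id)
        m.origin = (hap, chrom, start, flipped)
        mols.append(m)
        total += mol_len
    return mols


def make_contigs(
    sample: Sample,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    break_per_bp: float = 0.0,
    consensus_factor: Optional[float] = None,
) -> List[LabelMap]:
    """Consensus-map stand-ins: per-haplotype chromosome maps with attenuated noise.

    Consensus averaging shrinks single-molecule error; ``consensus_factor``
    (default 1/sqrt(coverage)) scales fn rate, fp rate, and sizing noise.
    ``break_per_bp`` fragments contigs at a Poisson rate.
    """
    rng = np.random.default_rng(seed)
    f = consensus_factor if consensus_factor is not None else 1.0 / np.sqrt(noise.target_coverage)
    contigs: List[LabelMap] = []
    for hap in (0, 1):
        for chrom, lm in sample.haplotypes[hap].items():
            breaks = []
            if break_per_bp > 0:
                n_br = rng.poisson(break_per_bp * lm.length_bp)
                breaks = sorted(rng.uniform(0, lm.length_bp, n_br))
            bounds = [0.0] + list(breaks) + [lm.length_bp]
            for k, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
                if hi - lo < 2 * noise.resolution_bp:
                    continue
                pos = lm.positions[(lm.positions >= lo) & (lm.positions < hi)] - lo
                if f > 0 and noise.fn_rate > 0 and pos.size:
                    pos = pos[rng.random(pos.size) >= noise.fn_rate * f]
                if f > 0 and pos.size and (noise.sizing_sf > 0 or noise.sizing_sr > 0):
                    gaps = np.diff(np.concatenate(([0.0], pos)))
                    gaps = np.maximum(gaps + rng.normal(0.0, f * noise.sigma(gaps)), 1.0)
                    pos = np.cumsum(gaps)
                n_fp = rng.poisson(f * noise.fp_per_100kb * (hi - lo) / 1e5) if f > 0 else 0
                if n_fp:
                    pos = np.sort(np.concatenate([pos, rng.uniform(0, hi - lo, n_fp)]))
                pos = merge_labels(pos, noise.resolution_bp)
                length = hi - lo
                pos = pos[(pos >= 0) & (pos < length)]
                c = LabelMap(
                    f"{sample.sample_id}_h{hap}_{chrom}_c{k}", "contig", length, pos,
                    sample.sample_id,
                )
                c.origin = (hap, chrom, lo, False)
                contigs.append(c)
    return contigs


# ---------------------------------------------------------------------------
# Trios and cohorts
# ---------------------------------------------------------------------------

def simulate_trio(
    father: Sample, mother: Sample, seed: int, sample_id: str = "child",
    recombination: int = 0,
) -> Sample:
    """Child sample from whole-haplotype transmission.

    By default one haplotype index per parent is transmitted genome-wide;
    with ``recombination > 0`` the transmitted haplotype is re-drawn
    independently per chromosome (chromosome-granularity recombination).
    """
    if father.reference is not mother.reference and set(father.reference.chromosomes) != set(
        mother.reference.chromosomes
    ):
        raise ValueError("parents must share one reference")
    rng = np.random.default_rng(seed)
    chroms = list(father.haplotypes[0])
    child_haps: List[Dict[str, LabelMap]] = [{}, {}]
    transmitted = {}
    for pi, parent in enumerate((father, mother)):
        h_genome = int(rng.integers(0, 2))
        for chrom in chroms:
            h = int(rng.integers(0, 2)) if recombination > 0 else h_genome
            transmitted[(pi, chrom)] = h
            child_haps[pi][chrom] = replace(parent.haplotypes[h][chrom], sample_id=sample_id)
    truth = TruthSet()
    for pi, parent in enumerate((father, mother)):
        for rec in parent.truth.records:
            h = transmitted[(pi, rec.chrom)]
            if h in rec.haplotypes:
                truth.records.append(
                    replace(rec, zygosity="het", haplotypes=(pi,))
                )
    # collapse biparental hits on the same locus to hom
    seen: Dict[tuple, TruthRecord] = {}
    merged: List[TruthRecord] = []
    for rec in truth.records:
        key = (rec.sv_type, rec.chrom, round(rec.ref_start), round(rec.ref_end))
        if key in seen:
            seen[key].zygosity = "hom"
            seen[key].haplotypes = (0, 1)
        else:
            seen[key] = rec
            merged.append(rec)
    truth.records = merged
    return Sample(sample_id, (child_haps[0], child_haps[1]), truth, father.reference)


@dataclass
class Cohort:
    samples: List[Sample]
    populations: Dict[str, str]  # sample_id -> population
    super_populations: Dict[str, str]  # population -> super population
    truth: TruthSet  # loci + per-population allele frequencies
    loci: List[dict] = field(default_factory=list)


def _balding_nichols(rng, p: float, F: float) -> float:
    if F <= 0:
        return p
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return float(rng.beta(a, b))


def simulate_cohort(
    ref: ReferenceDigest,
    n_pops: int,
    samples_per_pop: int,
    n_svs: int,
    divergence: float,
    seed: int,
    sv_size_range: Tuple[float, float] = (3_000.0, 50_000.0),
    sv_types: Sequence[str] = ("deletion", "insertion"),
    global_freq_range: Tuple[float, float] = (0.1, 0.9),
    nested: bool = False,
    super_pop_cycle: Sequence[str] = ("AFR", "EAS", "EUR", "SAS", "AMR"),
) -> Cohort:
    """Multi-population cohort with population-differentiated SV frequencies.

    Per-population allele frequencies follow a Balding-Nichols Beta model
    around a global frequency with dispersion ``divergence`` (F). With
    ``nested=True`` and 4 populations, drift is applied twice along the
    balanced topology ((P1,P2),(P3,P4)) so population pairs are hierarchically
    related. Genotypes are Hardy-Weinberg draws per sample.
    """
    if n_svs < 1:
        raise ValueError("n_svs must be >= 1")
    rng = np.random.default_rng(seed)
    # loci via a throw-away random placement on one template sample
    template = implant_svs(
        ref,
        [
            {
                "sv_type": sv_types[int(rng.integers(0, len(sv_types)))],
                "size": float(rng.uniform(*sv_size_range)),
                "zygosity": "hom",
                "locus_id": i,
            }
            for i in range(n_svs)
        ],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    loci = [
        {
            "locus_id": rec.locus_id, "sv_type": rec.sv_type, "chrom": rec.chrom,
            "start": rec.ref_start, "end": rec.ref_end,
            "size": abs(rec.size_delta_bp) if rec.size_delta_bp else rec.ref_end - rec.ref_start,
            "size_delta": rec.size_delta_bp,
        }
        for rec in sorted(template.truth.records, key=lambda r: r.locus_id)
    ]

    pops = [f"P{i + 1}" for i in range(n_pops)]
    super_pops = {p: super_pop_cycle[i % len(super_pop_cycle)] for i, p in enumerate(pops)}
    truth = TruthSet()
    freqs: Dict[int, Dict[str, float]] = {}
    for loc in loci:
        p0 = float(rng.uniform(*global_freq_range))
        if nested and n_pops == 4:
            pa = _balding_nichols(rng, p0, divergence)
            pb = _balding_nichols(rng, p0, divergence)
            freqs[loc["locus_id"]] = {
                pops[0]: _balding_nichols(rng, pa, divergence),
                pops[1]: _balding_nichols(rng, pa, divergence),
                pops[2]: _balding_nichols(rng, pb, divergence),
                pops[3]: _balding_nichols(rng, pb, divergence),
            }
        else:
            freqs[loc["locus_id"]] = {
                p: _balding_nichols(rng, p0, divergence) for p in pops
            }
    truth.allele_freqs = freqs

    samples = []
    populations = {}
    for p in pops:
        for s in range(samples_per_pop):
            sid = f"{p}_S{s + 1}"
            spec = []
            for loc in loci:
                f = freqs[loc["locus_id"]][p]
                n_alleles = int(rng.random() < f) + int(rng.random() < f)
                if n_alleles == 0:
                    continue
                spec.append(
                    {
                        "sv_type": loc["sv_type"], "chrom": loc["chrom"],
                        "start": loc["start"], "end": loc["end"], "size": loc["size"],
                        "zygosity": "hom" if n_alleles == 2 else "het",
                        "locus_id": loc["locus_id"],
                    }
                )
            smp = implant_svs(ref, spec, seed=int(rng.integers(0, 2**31 - 1)), sample_id=sid)
            samples.append(smp)
            populations[sid] = p
            truth.records.extend(smp.truth.records)
    return Cohort(samples, populations, super_pops, truth, loci)


def truth_calls(sample: Sample, module: str = "MR") -> List[SVCall]:
    """Ground-truth SVs of a sample expressed as SVCall objects.

    Used to exercise cohort-level analyses independently of the callers.
    """
    calls = []
    for rec in sample.truth.records:
        delta = rec.size_delta_bp
        calls.append(
            SVCall(
                sv_type=rec.sv_type, chrom=rec.chrom, start_bp=rec.ref_start,
                end_bp=max(rec.ref_end, rec.ref_start + abs(delta)),
                size_delta_bp=delta, zygosity=rec.zygosity,
                support_count=0, score=float("inf"), module=module,
                sample_id=sample.sample_id,
            )
        )
    return calls
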
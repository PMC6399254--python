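import numpy as np
import pytest

from omvar.simulate import (
    NOISELESS,
    NoiseModel,
    generate_molecules,
    implant_svs,
    make_contigs,
    simulate_cohort,
    simulate_reference,
    simulate_trio,
)


class TestSimulateReference:
    def test_label_count_near_poisson_expectation(self):
        ref = simulate_reference(1, 1_000_000, 10_000, seed=1)
        n = ref.chromosomes["chr1"].n_labels
        lam = 100
        assert abs(n - lam) < 4 * np.sqrt(lam)

    def test_deterministic_under_seed(self):
        a = simulate_reference(2, 500_000, 8_000, seed=5)
        b = simulate_reference(2, 500_000, 8_000, seed=5)
        for c in a.chromosomes:
            np.testing.assert_array_equal(a.chromosomes[c].positions, b.chromosomes[c].positions)

    def test_spacing_at_or_below_resolution_rejected(self):
        with pytest.raises(ValueError):
            simulate_reference(1, 100_000, 400, seed=1)


class TestImplantSvs:
    def test_hom_deletion_removes_labels_and_length(self, small_ref):
        lm = small_ref.chromosomes["chr1"]
        inner = lm.positions[(lm.positions > 2_000_000) & (lm.positions < 2_005_000)]
        smp = implant_svs(
            small_ref,
            [{"sv_type": "deletion", "chrom": "chr1", "start": 2_000_000, "end": 2_005_000, "zygosity": "hom"}],
            seed=3,
        )
        for h in (0, 1):
            hp = smp.haplotypes[h]["chr1"]
            assert hp.length_bp == lm.length_bp - 5_000
            assert hp.n_labels == lm.n_labels - inner.size

    def test_het_inversion_on_exactly_one_haplotype(self, small_ref):
        smp = implant_svs(
            small_ref,
            [{"sv_type": "inversion", "chrom": "chr1", "start": 1_000_000, "end": 1_010_000, "zygosity": "het"}],
            seed=4,
        )
        lm = small_ref.chromosomes["chr1"]
        changed = [
            h for h in (0, 1)
            if not np.array_equal(smp.haplotypes[h]["chr1"].positions, lm.positions)
        ]
        assert len(changed) == 1

    def test_tandem_duplication_arithmetic(self, small_ref):
        start, end, copies = 3_000_000, 3_020_000, 3
        lm = small_ref.chromosomes["chr1"]
        unit_labels = lm.positions[(lm.positions >= start) & (lm.positions < end)] - start
        smp = implant_svs(
            small_ref,
            [{"sv_type": "duplication", "chrom": "chr1", "start": start, "end": end,
              "copies": copies, "zygosity": "hom"}],
            seed=5,
        )
        hp = smp.haplotypes[0]["chr1"]
        assert hp.length_bp == lm.length_bp + copies * 20_000
        expected = np.sort(np.concatenate(
            [lm.positions[lm.positions < end]]
            + [end + m * 20_000 + unit_labels for m in range(copies)]
            + [lm.positions[lm.positions >= end] + copies * 20_000]
        ))
        np.testing.assert_allclose(hp.positions, expected)

    def test_overlapping_loci_rejected(self, small_ref):
        with pytest.raises(ValueError, match="overlap"):
            implant_svs(
                small_ref,
                [
                    {"sv_type": "deletion", "chrom": "chr1", "start": 2_000_000, "end": 2_050_000, "zygosity": "hom"},
                    {"sv_type": "deletion", "chrom": "chr1", "start": 2_030_000, "end": 2_060_000, "zygosity": "hom"},
                ],
                seed=6,
            )


class TestGenerateMolecules:
    def test_noiseless_molecules_are_exact_submaps(self, small_ref):
        smp = implant_svs(small_ref, [], seed=7)
        mols = generate_molecules(smp, NOISELESS, seed=8, coverage=2)
        for m in mols[:20]:
            hap, chrom, start, flipped = m.origin
            src = smp.haplotypes[hap][chrom]
            expect = src.positions[(src.positions >= start) & (src.positions < start + m.length_bp)] - start
            if flipped:
                expect = np.sort(m.length_bp - expect)
            np.testing.assert_allclose(np.sort(m.positions), np.sort(expect), atol=1e-6)

    def test_fn_rate_binomial(self, small_ref):
        smp = implant_svs(small_ref, [], seed=7)
        noise = NoiseModel(fp_per_100kb=0.0, sizing_sf=0.0, sizing_sr=0.0)
        true_total = 0
        kept_total = 0
        mols = generate_molecules(smp, noise, seed=9, coverage=25)
        for m in mols:
            hap, chrom, start, flipped = m.origin
            src = smp.haplotypes[hap][chrom]
            n_true = int(np.sum((src.positions >= start) & (src.positions < start + m.length_bp)))
            true_total += n_true
            kept_total += m.n_labels
        assert true_total > 10_000
        frac = kept_total / true_total
        sd = np.sqrt(0.94 * 0.06 / true_total)
        assert abs(frac - 0.94) < 4 * sd

    def test_target_coverage_reached(self):
        ref = simulate_reference(1, 1_000_000, 10_000, seed=10)
        smp = implant_svs(ref, [], seed=11)
        mols = generate_molecules(smp, NoiseModel(), seed=12, coverage=79)
        total = sum(m.length_bp for m in mols)
        assert 75 <= total / 1e6 <= 84

    def test_molecule_length_floor(self, small_ref):
        smp = implant_svs(small_ref, [], seed=7)
        mols = generate_molecules(smp, NoiseModel(), seed=13, coverage=5)
        assert min(m.length_bp for m in mols) >= 145_000  # floor minus sizing jitter


class TestMakeContigs:
    def test_zero_break_density_one_contig_per_haplotype_chrom(self, small_ref):
        smp = implant_svs(small_ref, [], seed=7)
        contigs = make_contigs(smp, NoiseModel(), seed=14, break_per_bp=0.0)
        assert len(contigs) == 2  # 2 haplotypes x 1 chromosome

    def test_zero_consensus_factor_contigs_equal_haplotypes(self, small_ref):
        smp = implant_svs(small_ref, [], seed=7)
        contigs = make_contigs(smp, NoiseModel(), seed=15, consensus_factor=0.0)
        for c in contigs:
            hap, chrom, lo, _ = c.origin
            np.testing.assert_allclose(c.positions, smp.haplotypes[hap][chrom].positions)

    def test_break_density_poisson_fragmentation(self):
        ref = simulate_reference(1, 1_000_000, 10_000, seed=16)
        smp = implant_svs(ref, [], seed=17)
        counts = []
        for s in range(30):
            contigs = make_contigs(smp, NoiseModel(), seed=100 + s, break_per_bp=1 / 500_000)
            counts.append(len(contigs) / 2)  # per haplotype
        # 2 expected breaks -> ~3 fragments per haplotype, minus sub-resolution ones
        assert 1.5 < np.mean(counts) < 4.5


class TestTrio:
    def _parents(self, small_ref):
        f = implant_svs(
            small_ref,
            [{"sv_type": "deletion", "chrom": "chr1", "start": 2_000_000, "end": 2_010_000, "zygosity": "hom"}],
            seed=20, sample_id="father",
        )
        m = implant_svs(
            small_ref,
            [{"sv_type": "deletion", "chrom": "chr1", "start": 2_000_000, "end": 2_010_000, "zygosity": "hom"}],
            seed=21, sample_id="mother",
        )
        return f, m

    def test_both_parents_hom_child_hom(self, small_ref):
        f, m = self._parents(small_ref)
        child = simulate_trio(f, m, seed=22)
        assert len(child.truth.records) == 1
        assert child.truth.records[0].zygosity == "hom"

    def test_het_transmission_fraction(self, small_ref):
        f = implant_svs(
            small_ref,
            [{"sv_type": "deletion", "chrom": "chr1", "start": 2_000_000, "end": 2_010_000,
              "zygosity": "het", "haplotype": 0}],
            seed=23, sample_id="father",
        )
        m = implant_svs(small_ref, [], seed=24, sample_id="mother")
        transmitted = sum(
            bool(simulate_trio(f, m, seed=1000 + s).truth.records) for s in range(1000)
        )
        sd = np.sqrt(0.25 * 1000)
        assert abs(transmitted - 500) < 4 * sd

    def test_child_svs_subset_of_parents(self, small_ref):
        rng = np.random.default_rng(25)
        spec = [
            {"sv_type": "deletion", "size": 8_000.0, "zygosity": str(rng.choice(["hom", "het"]))}
            for _ in range(5)
        ]
        f = implant_svs(small_ref, spec, seed=26, sample_id="father")
        m = implant_svs(small_ref, spec[:3], seed=27, sample_id="mother")
        child = simulate_trio(f, m, seed=28)
        parent_keys = {
            (r.sv_type, r.chrom, round(r.ref_start)) for r in f.truth.records + m.truth.records
        }
        for r in child.truth.records:
            assert (r.sv_type, r.chrom, round(r.ref_start)) in parent_keys


class TestCohort:
    def test_zero_divergence_frequencies_equal(self):
        ref = simulate_reference(1, 2_000_000, 10_000, seed=30)
        cohort = simulate_cohort(ref, n_pops=2, samples_per_pop=4, n_svs=10,
                                 divergence=0.0, seed=31)
        for locus, freqs in cohort.truth.allele_freqs.items():
            assert len(set(freqs.values())) == 1  # identical across populations

    def test_divergence_increases_frequency_differences(self):
        ref = simulate_reference(1, 4_000_000, 10_000, seed=32)

        def mean_abs_diff(divergence, seed):
            cohort = simulate_cohort(ref, 2, 2, 60, divergence, seed=seed,
                                     sv_size_range=(3_000.0, 10_000.0))
            diffs = [
                abs(f["P1"] - f["P2"]) for f in cohort.truth.allele_freqs.values()
            ]
            return np.mean(diffs)

        assert mean_abs_diff(0.3, 33) > mean_abs_diff(0.0, 34)

    def test_hardy_weinberg_genotype_counts(self):
        ref = simulate_reference(1, 1_000_000, 10_000, seed=35)
        cohort = simulate_cohort(ref, 1, 500, 1, divergence=0.0, seed=36,
                                 global_freq_range=(0.4, 0.4))
        locus = cohort.loci[0]["locus_id"]
        p = cohort.truth.allele_freqs[locus]["P1"]
        genos = []
        for smp in cohort.samples:
            recs = [r for r in smp.truth.records if r.locus_id == locus]
            genos.append(0 if not recs else (2 if recs[0].zygosity == "hom" else 1))
        counts = np.bincount(genos, minlength=3)
        n = len(genos)
        expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        for obs, exp in zip(counts, expected):
            assert abs(obs - exp) < 4 * np.sqrt(exp)
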
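"""Synthetic panel, pedigree, error-layer, and read-simulation behavior."""

import numpy as np
import pysam
import pytest

from microkin.containers import MISSING
from microkin.freqs import AlleleFrequencySet
from microkin.synthetic import (
    CalibrationError,
    PanelSpec,
    PedigreeSpec,
    apply_genotyping_error,
    build_catalog,
    make_validation_scenario,
    pedigree_relationship,
    read_count_totals,
    simulate_allele_frequencies,
    simulate_pedigree_genotypes,
    simulate_reads,
)


class TestAlleleFrequencies:
    def test_default_panel_calibrates_to_target(self, panel170):
        assert len(panel170) == 170
        assert 0.44 <= panel170.mean_expected_heterozygosity() <= 0.48
        for locus in panel170:
            assert 2 <= locus.n_alleles <= 8
            assert abs(locus.freqs.sum() - 1.0) < 1e-12
            assert (locus.freqs > 0).all()

    def test_seed_reproducibility(self):
        a = simulate_allele_frequencies(PanelSpec(n_loci=30, seed=42))
        b = simulate_allele_frequencies(PanelSpec(n_loci=30, seed=42))
        c = simulate_allele_frequencies(PanelSpec(n_loci=30, seed=43))
        for la, lb in zip(a, b):
            assert np.array_equal(la.freqs, lb.freqs)
        assert any(
            la.n_alleles != lc.n_alleles or not np.array_equal(la.freqs, lc.freqs)
            for la, lc in zip(a, c)
        )

    def test_maximal_biallelic_heterozygosity_forces_equifrequency(self):
        spec = PanelSpec(
            n_loci=1, allele_count_range=(2, 2), target_mean_he=0.5,
            he_tolerance=0.02, seed=3,
        )
        locus = simulate_allele_frequencies(spec)[0]
        # He >= 0.48 requires |p - 0.5| <= 0.1
        assert np.all(np.abs(locus.freqs - 0.5) <= 0.1)

    def test_infeasible_target_names_achievable_bound(self):
        with pytest.raises(CalibrationError, match="achievable range"):
            simulate_allele_frequencies(
                PanelSpec(allele_count_range=(2, 2), target_mean_he=0.9)
            )


class TestPedigree:
    def test_relationship_labels(self):
        ped = PedigreeSpec(
            founders=["A", "B", "C", "D"],
            matings=[
                ("A", "B", ["S1", "S2"]),   # full sibs, PO with A and B
                ("A", "C", ["H1"]),          # half sib of S1/S2 via A
                ("S1", "D", ["G1"]),         # grandchild of A/B
            ],
        )
        parents = ped.parent_map()
        assert pedigree_relationship(parents, "A", "S1") == "PO"
        assert pedigree_relationship(parents, "S1", "S2") == "FS"
        assert pedigree_relationship(parents, "S1", "H1") == "HS"
        assert pedigree_relationship(parents, "A", "G1") == "OTHER"   # grandparent
        assert pedigree_relationship(parents, "S2", "G1") == "OTHER"  # avuncular
        assert pedigree_relationship(parents, "C", "D") == "U"
        assert pedigree_relationship(parents, "A", "A") == "SELF"

    def test_structural_validation(self):
        with pytest.raises(ValueError, match="unknown individual"):
            PedigreeSpec(founders=["A"], matings=[("A", "Z", 1)]).validate()
        with pytest.raises(ValueError, match="self-mating"):
            PedigreeSpec(founders=["A"], matings=[("A", "A", 1)]).validate()

    def test_parent_offspring_share_allele_everywhere(self, panel170):
        ped = PedigreeSpec(founders=["P1", "P2"], matings=[("P1", "P2", ["C"])])
        matrix, truth = simulate_pedigree_genotypes(panel170, ped, seed=5)
        p = matrix.sample_index("P1_s1")
        c = matrix.sample_index("C_s1")
        share = (
            (matrix.a1[p] == matrix.a1[c])
            | (matrix.a1[p] == matrix.a2[c])
            | (matrix.a2[p] == matrix.a1[c])
            | (matrix.a2[p] == matrix.a2[c])
        )
        assert share.all()

    def test_founders_follow_hardy_weinberg(self):
        """Founder heterozygote fraction at p=(1/2,1/2) is ~1/2."""
        from conftest import make_freqs

        freqs = make_freqs([[0.5, 0.5]])
        ped = PedigreeSpec(founders=[f"F{i}" for i in range(4000)])
        matrix, _ = simulate_pedigree_genotypes(freqs, ped, seed=23)
        het = float((matrix.a1[:, 0] != matrix.a2[:, 0]).mean())
        se = np.sqrt(0.5 * 0.5 / 4000)
        assert abs(het - 0.5) < 3 * se

    def test_full_sib_ibd_fractions_match_cotterman(self):
        """Empirical IBD-sharing of FS pairs approximates (1/4, 1/2, 1/4)."""
        from conftest import make_freqs

        freqs = make_freqs([[0.5, 0.5]])
        n_fam = 5000
        founders = [f"F{i}" for i in range(2 * n_fam)]
        matings = [
            (f"F{2 * i}", f"F{2 * i + 1}", [f"S{i}A", f"S{i}B"])
            for i in range(n_fam)
        ]
        ped = PedigreeSpec(founders=founders, matings=matings)
        _, _, (tags, inds) = simulate_pedigree_genotypes(
            freqs, ped, seed=17, return_ibd=True
        )
        pos = {ind: k for k, ind in enumerate(inds)}
        shared = []
        for i in range(n_fam):
            ta = set(tags[pos[f"S{i}A"], 0])
            tb = tags[pos[f"S{i}B"], 0]
            shared.append(sum(1 for t in tb if t in ta))
        counts = np.bincount(shared, minlength=3) / n_fam
        se = np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / n_fam)
        assert np.all(np.abs(counts - [0.25, 0.5, 0.25]) < 3 * se)


class TestGenotypingError:
    def test_zero_epsilon_is_identity(self, panel170):
        ped = PedigreeSpec(founders=[f"X{i}" for i in range(4)])
        matrix, _ = simulate_pedigree_genotypes(panel170, ped, seed=2)
        out = apply_genotyping_error(matrix, panel170, 0.0, seed=3)
        assert np.array_equal(out.a1, matrix.a1)
        assert np.array_equal(out.a2, matrix.a2)

    def test_full_replacement_reaches_hwe(self):
        from conftest import make_freqs

        freqs = make_freqs([[0.5, 0.5]])
        ped = PedigreeSpec(founders=[f"X{i}" for i in range(4000)])
        matrix, _ = simulate_pedigree_genotypes(freqs, ped, seed=4)
        # force every input genotype to {A,A}; epsilon=1 must restore HWE
        matrix.a1[:] = 0
        matrix.a2[:] = 0
        out = apply_genotyping_error(matrix, freqs, 1.0, seed=5)
        het = float(((out.a1 == 0) & (out.a2 == 1)).mean())
        hom_a = float(((out.a1 == 0) & (out.a2 == 0)).mean())
        se = np.sqrt(0.5 * 0.5 / 4000)
        assert abs(het - 0.5) < 3 * se
        assert abs(hom_a - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 4000)

    def test_replicate_mismatch_rate_matches_closed_form(self, panel170):
        """Mismatches between ε-perturbed replicates track 2·ε·Σ(1-Σg²)."""
        ped = PedigreeSpec(
            founders=[f"X{i}" for i in range(50)],
            recapture_counts={f"X{i}": 2 for i in range(50)},
        )
        matrix, truth = simulate_pedigree_genotypes(panel170, ped, seed=6)
        noisy = apply_genotyping_error(matrix, panel170, 0.005, seed=7)
        # per-locus probability that one member's call changed
        p_change = []
        for locus in panel170:
            from microkin.kinship import hwe_genotype_frequencies

            g = hwe_genotype_frequencies(locus.freqs)
            p_change.append(0.005 * (1.0 - float((g**2).sum())))
        lam = 2 * float(np.sum(p_change))  # expected mismatches per replicate pair
        mism = []
        for i in range(50):
            r1 = noisy.sample_index(f"X{i}_s1")
            r2 = noisy.sample_index(f"X{i}_s2")
            mism.append(
                int(((noisy.a1[r1] != noisy.a1[r2]) | (noisy.a2[r1] != noisy.a2[r2])).sum())
            )
        mean = float(np.mean(mism))
        se = float(np.std(mism, ddof=1) / np.sqrt(len(mism)))
        assert mean <= 2 * 0.005 * 170  # coincidental equal redraws only reduce it
        assert abs(mean - lam) < 3 * max(se, 1e-3) + 0.05

    def test_epsilon_validation(self, panel170):
        ped = PedigreeSpec(founders=["A", "B"])
        matrix, _ = simulate_pedigree_genotypes(panel170, ped, seed=1)
        with pytest.raises(ValueError):
            apply_genotyping_error(matrix, panel170, -0.1, seed=0)


@pytest.fixture(scope="module")
def small_setup(tmp_path_factory):
    freqs = simulate_allele_frequencies(PanelSpec(n_loci=12, seed=8))
    catalog = build_catalog(freqs, seed=9)
    ped = PedigreeSpec(founders=["A", "B", "C"])
    matrix, truth = simulate_pedigree_genotypes(freqs, ped, seed=10)
    outdir = tmp_path_factory.mktemp("reads")
    sex = {"A_s1": "M", "B_s1": "F", "C_s1": "F"}
    counts = simulate_reads(
        matrix, catalog, outdir, sex=sex, depth_mean=60,
        seq_error_rate=0.0, seed=11,
    )
    return freqs, catalog, matrix, outdir, counts, sex


class TestReads:
    def test_sam_is_valid_and_full_match(self, small_setup):
        _, catalog, matrix, outdir, _, _ = small_setup
        with pysam.AlignmentFile(str(outdir / "A_s1.sam"), "r") as sam:
            reads = list(sam)
        assert reads
        for read in reads[:50]:
            assert not read.is_unmapped
            assert read.mapping_quality == 60
            assert len(read.cigartuples) == 1 and read.cigartuples[0][0] == 0

    def test_homozygote_reads_carry_single_haplotype(self, small_setup):
        freqs, catalog, matrix, outdir, _, _ = small_setup
        by_id = {c.locus_id: c for c in catalog}
        i = matrix.sample_index("B_s1")
        hom = [
            j for j in range(matrix.n_loci)
            if matrix.a1[i, j] == matrix.a2[i, j] != MISSING
        ]
        assert hom
        j = hom[0]
        locus_id = matrix.locus_ids[j]
        loc = by_id[locus_id]
        expected = loc.haplotype_sequence(loc.alleles[matrix.a1[i, j]])
        with pysam.AlignmentFile(str(outdir / "B_s1.sam"), "r") as sam:
            seqs = {r.query_sequence for r in sam if r.reference_name == locus_id}
        assert seqs == {expected}

    def test_female_has_zero_sry_reads(self, small_setup):
        _, _, _, _, counts, sex = small_setup
        sry = counts[counts["locus_id"] == "SRY"].set_index("sample_id")["n_reads"]
        assert sry["B_s1"] == 0 and sry["C_s1"] == 0

    def test_missing_locus_in_catalog_raises(self, small_setup):
        freqs, catalog, matrix, outdir, _, _ = small_setup
        with pytest.raises(KeyError, match="missing from catalog"):
            simulate_reads(matrix, catalog[:5], outdir, seed=1)

    def test_heterozygote_allele_balance(self, small_setup):
        """Binomial(n, 1/2) read split rarely violates the 0.4 ratio at depth 200."""
        from scipy.stats import binom

        # P(min/max >= 0.4) for Binomial(200, 0.5): tail outside [58, 142]
        p_ok = binom.cdf(142, 200, 0.5) - binom.cdf(57, 200, 0.5)
        assert p_ok > 0.99


class TestValidationScenario:
    def test_scenario_shape_and_truth(self, tmp_path):
        sc = make_validation_scenario(tmp_path, seed=9, depth_mean=30)
        assert sc.n_samples == 82
        assert sc.n_individuals == 36
        sexes = list(sc.truth.true_sex.values())
        assert sexes.count("F") == 24 and sexes.count("M") == 12
        assert sorted(sc.truth.recapture_multiset().elements()) == sorted(
            [1] * 21 + [7, 6, 5, 5, 5, 4, 4, 4, 4, 4, 3, 3, 3, 2, 2]
        )
        for s in sc.matrix_observed.sample_ids:
            assert sc.truth.individual_of_sample[s] in sc.truth.individuals
        # matriarch has the maximum PO degree
        po_deg = {ind: 0 for ind in sc.truth.individuals}
        for (a, b), rel in sc.truth.pair_relationships().items():
            if rel == "PO":
                po_deg[a] += 1
                po_deg[b] += 1
        assert max(po_deg, key=po_deg.get) == "MAT"
        totals = read_count_totals(sc.read_counts)
        assert (totals["total_reads"] > 0).all()
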
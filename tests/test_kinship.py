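"""Tests of pedigree and genomic relationship matrices."""

import numpy as np
import pandas as pd
import pytest

import forestgs as fgs
from forestgs.containers import UNKNOWN_PARENT, Pedigree, RelationshipMatrix


def _ped(rows):
    return Pedigree(pd.DataFrame(
        rows, columns=["id", "sire", "dam", "family", "generation"]
    ))


NUCLEAR = _ped([
    ("s", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0),
    ("d", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0),
    ("d2", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0),
    ("c1", "s", "d", "F1", 1),
    ("c2", "s", "d", "F1", 1),
    ("h1", "s", "d2", "F2", 1),
])


def gene_drop_relatedness(pedigree: Pedigree, n_drops: int, seed: int = 0):
    """Monte-Carlo oracle: drop founder alleles through the pedigree and
    estimate additive relatedness as twice the realized coancestry."""
    rng = np.random.default_rng(seed)
    ids = pedigree.ids
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    alleles = np.zeros((n, 2, n_drops), dtype=np.int32)
    next_founder_allele = 0
    for row in pedigree.table.itertuples(index=False):
        i = index[row.id]
        for slot, parent in enumerate((row.sire, row.dam)):
            if parent == UNKNOWN_PARENT:
                alleles[i, slot] = 2 * index[row.id] + slot
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[i, slot] = alleles[
                    index[parent], pick, np.arange(n_drops)
                ]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = sum(
                (alleles[i, a] == alleles[j, b]).mean()
                for a in (0, 1) for b in (0, 1)
            )
            A[i, j] = A[j, i] = ibd / 2.0
    return A


def _random_four_generation_pedigree(seed: int) -> Pedigree:
    rng = np.random.default_rng(seed)
    rows = [(f"G0_{i}", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0) for i in range(6)]
    prev = [r[0] for r in rows]
    for gen in range(1, 4):
        cur = []
        for k in range(6):
            s, d = rng.choice(prev, size=2, replace=False)
            name = f"G{gen}_{k}"
            rows.append((name, s, d, f"F{gen}_{k}", gen))
            cur.append(name)
        prev = cur + list(rng.choice(prev, size=2, replace=False))
    return _ped(rows)


class TestBuildA:
    def test_founders_are_identity(self):
        ped = _ped([
            ("a", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0),
            ("b", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0),
        ])
        np.testing.assert_array_equal(fgs.build_A(ped).values, np.eye(2))

    def test_closed_forms(self):
        A = fgs.build_A(NUCLEAR)
        idx = {s: i for i, s in enumerate(A.ids)}
        assert A.values[idx["c1"], idx["c2"]] == 0.5  # full sibs
        assert A.values[idx["s"], idx["c1"]] == 0.5  # parent-offspring
        assert A.values[idx["c1"], idx["h1"]] == 0.25  # half sibs
        assert A.values[idx["c1"], idx["c1"]] == 1.0  # non-inbred diagonal

    def test_inbred_diagonal(self):
        ped = _ped([
            ("s", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0),
            ("d", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0),
            ("c1", "s", "d", "F1", 1),
            ("c2", "s", "d", "F1", 1),
            ("x", "c1", "c2", "F2", 2),  # full-sib mating
        ])
        A = fgs.build_A(ped)
        assert A.values[-1, -1] == pytest.approx(1.25)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_gene_dropping_oracle(self, seed):
        ped = _random_four_generation_pedigree(seed)
        A = fgs.build_A(ped).values
        A_mc = gene_drop_relatedness(ped, n_drops=100_000, seed=seed)
        assert np.abs(A - A_mc).max() < 0.01

    def test_unordered_pedigree_rejected(self):
        with pytest.raises(Exception, match="precede"):
            _ped([
                ("c1", "s", "d", "F1", 1),
                ("s", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0),
                ("d", UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0),
            ])


class TestBuildD:
    def test_closed_forms(self):
        D = fgs.build_D(NUCLEAR)
        idx = {s: i for i, s in enumerate(D.ids)}
        assert D.values[idx["c1"], idx["c2"]] == 0.25  # full sibs
        assert D.values[idx["s"], idx["c1"]] == 0.0  # parent-offspring
        assert D.values[idx["c1"], idx["h1"]] == 0.0  # half sibs
        assert np.all(np.diag(D.values) == 1.0)

    def test_diagonal_bounds_on_random_pedigrees(self):
        ped = _random_four_generation_pedigree(3)
        D = fgs.build_D(ped)
        assert ((np.diag(D.values) >= 0) & (np.diag(D.values) <= 2)).all()
        assert np.allclose(D.values, D.values.T)


def _single_snp(values):
    return fgs.GenotypeMatrix(
        ids=[f"I{i}" for i in range(len(values))],
        snp_ids=["S1"],
        values=np.asarray(values, dtype=float).reshape(-1, 1),
    )


class TestBuildGa:
    def test_single_snp_direct_formula(self):
        # p = 0.5, dosages (2, 0): Z = (1, -1), denominator 2pq = 0.5
        Ga = fgs.build_Ga(_single_snp([2, 0]))
        np.testing.assert_allclose(Ga.values, [[2, -2], [-2, 2]])

    def test_hwe_sample_mean_diagonal_near_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.5, 2000)
        vals = rng.binomial(2, p, size=(500, 2000)).astype(float)
        Ga = fgs.build_Ga(fgs.GenotypeMatrix(
            ids=[f"I{i}" for i in range(500)],
            snp_ids=[f"S{j}" for j in range(2000)],
            values=vals,
        ))
        assert abs(np.diag(Ga.values).mean() - 1.0) < 0.02

    def test_panel_wide_denominator_keeps_entries_finite(self):
        # an individual with zero dosage variance across SNPs is fine: the
        # denominator is panel-wide, never per individual
        geno = fgs.GenotypeMatrix(
            ids=["I0", "I1", "I2"],
            snp_ids=["S1", "S2"],
            values=np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 1.0]]),
        )
        Ga = fgs.build_Ga(geno)
        assert np.isfinite(Ga.values).all()

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            fgs.build_Ga(_single_snp([2, 2, 2]))

    def test_invariant_to_row_and_column_order(self, small_trial):
        geno = small_trial.genotypes
        rng = np.random.default_rng(1)
        snp_perm = list(rng.permutation(geno.snp_ids))
        ind_perm = list(rng.permutation(geno.ids))
        base = fgs.build_Ga(geno)
        shuffled = fgs.build_Ga(
            geno.subset_snps(snp_perm).subset_individuals(ind_perm)
        )
        np.testing.assert_allclose(
            shuffled.align(base.ids), base.values, atol=1e-10
        )

    def test_missing_mean_imputed_and_counted(self):
        vals = np.array([[2.0, np.nan], [0.0, 1.0], [1.0, 0.0]])
        geno = fgs.GenotypeMatrix(ids=["a", "b", "c"], snp_ids=["s1", "s2"],
                                  values=vals)
        Ga = fgs.build_Ga(geno)
        assert Ga.provenance["n_imputed"] == 1
        assert np.isfinite(Ga.values).all()

    def test_subset_deviation_shrinks_with_more_snps(self, small_trial):
        geno = small_trial.genotypes
        full = fgs.build_Ga(geno).values
        devs = []
        for n in (50, 400):
            ds = []
            for rep in range(5):
                sub = fgs.subsample_snps(geno, n, seed=100 * n + rep)
                ds.append(np.abs(fgs.build_Ga(sub).values - full).mean())
            devs.append(np.mean(ds))
        assert devs[1] < devs[0]


class TestBuildGd:
    def test_single_snp_heterozygote_diagonal(self):
        # p = 0.5: het codes 2pq = 0.5; denominator (2pq)^2 = 0.25
        Gd = fgs.build_Gd(_single_snp([1, 1]))
        assert Gd.values[0, 0] == pytest.approx(1.0)

    def test_het_vs_major_homozygote(self):
        # dosages (1, 0, 2) give sample p = 0.5; the het/homozygote entry is
        # 0.5 * (-0.5) / 0.25 = -1
        Gd = fgs.build_Gd(_single_snp([1, 0, 2]))
        assert Gd.values[0, 1] == pytest.approx(-1.0)

    def test_hwe_sample_mean_diagonal_near_one(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.15, 0.5, 2000)
        vals = rng.binomial(2, p, size=(500, 2000)).astype(float)
        Gd = fgs.build_Gd(fgs.GenotypeMatrix(
            ids=[f"I{i}" for i in range(500)],
            snp_ids=[f"S{j}" for j in range(2000)],
            values=vals,
        ))
        assert abs(np.diag(Gd.values).mean() - 1.0) < 0.03


class TestBlendAndInvert:
    @pytest.mark.parametrize("weight", [0.02, 0.05, 0.01])
    def test_elementwise_blend(self, weight):
        G = RelationshipMatrix(
            values=np.array([[1.2, 0.4, 0.1], [0.4, 0.9, 0.2],
                             [0.1, 0.2, 1.1]]),
            ids=["a", "b", "c"], kind="Ga",
        )
        P = RelationshipMatrix(
            values=np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.25],
                             [0.0, 0.25, 1.0]]),
            ids=["a", "b", "c"], kind="A",
        )
        blended, inv = fgs.blend_and_invert(G, P, weight)
        np.testing.assert_allclose(
            blended.values, (1 - weight) * G.values + weight * P.values
        )
        np.testing.assert_allclose(
            blended.values @ inv, np.eye(3), atol=1e-8
        )

    def test_weight_zero_inverts_g_itself(self):
        G = RelationshipMatrix(np.array([[2.0, 0.5], [0.5, 1.0]]),
                               ["a", "b"], "Ga")
        P = RelationshipMatrix(np.eye(2), ["a", "b"], "A")
        blended, inv = fgs.blend_and_invert(G, P, 0.0)
        np.testing.assert_allclose(blended.values, G.values)
        np.testing.assert_allclose(inv, np.linalg.inv(G.values), atol=1e-10)

    def test_blend_of_matrix_with_itself_is_identity_operation(self):
        A = RelationshipMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]),
                               ["a", "b"], "A")
        for w in (0.0, 0.02, 0.5, 1.0):
            blended, _ = fgs.blend_and_invert(
                RelationshipMatrix(A.values.copy(), ["a", "b"], "Ga"), A, w
            )
            np.testing.assert_allclose(blended.values, A.values)

    def test_id_mismatch_and_reordering(self):
        G = RelationshipMatrix(np.eye(2), ["a", "b"], "Ga")
        P = RelationshipMatrix(np.array([[1.0, 0.2], [0.2, 1.0]]),
                               ["b", "a"], "A")
        blended, _ = fgs.blend_and_invert(G, P, 0.5)
        assert blended.ids == ["a", "b"]
        with pytest.raises(ValueError, match="different ids"):
            fgs.blend_and_invert(
                G, RelationshipMatrix(np.eye(2), ["x", "y"], "A"), 0.5
            )

    def test_singular_matrix_reports_smallest_eigenvalue(self):
        G = RelationshipMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]),
                               ["a", "b"], "Ga")
        P = RelationshipMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]),
                               ["a", "b"], "A")
        with pytest.raises(ValueError, match="eigenvalue"):
            fgs.blend_and_invert(G, P, 0.02)

    def test_blending_restores_positive_definiteness(self, small_trial,
                                                     small_matrices):
        # a rank-deficient Ga (more individuals than SNPs after a tiny
        # subset) becomes invertible after blending with A
        sub = fgs.subsample_snps(small_trial.genotypes, 30, seed=0)
        Ga = fgs.build_Ga(sub)
        blended, inv = fgs.blend_and_invert(Ga, small_matrices["A"], 0.02)
        assert np.abs(blended.values @ inv - np.eye(len(blended.ids))).max() < 1e-8
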
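"""Estimator unit and property tests with independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortqc.popgen import (allele_frequencies, allele_frequency,
                             hwe_exact_test, ibd_mom,
                             inbreeding_coefficient,
                             inbreeding_coefficients, ld_prune, pca,
                             pairwise_ibd, sample_missing_rate,
                             x_inbreeding)
from cohortqc.simulate import plant_related_pair
from cohortqc.store import MISSING

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration over all heterozygote counts sharing
    the observed allele counts."""
    n = n_AA + n_Aa + n_aa
    rare = 2 * min(n_AA, n_aa) + n_Aa
    weights = {}
    for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        w = (Fraction(math.factorial(n),
                      math.factorial(hom_r) * math.factorial(h)
                      * math.factorial(hom_c)) * 2 ** h)
        weights[h] = w
    total = sum(weights.values())
    if total == 0:
        return 1.0
    w_obs = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= w_obs) / total
    return float(min(Fraction(1), p))


def ld_prune_oracle(values, chroms, positions, r2_threshold, window_bp):
    """Literal greedy rule: keep a variant unless it correlates above
    threshold with an already-kept variant within the window."""
    m = values.shape[1]
    order = sorted(range(m), key=lambda j: (chroms[j], positions[j]))
    kept = []
    keep = np.zeros(m, dtype=bool)
    for j in order:
        ok = True
        for k in kept:
            if chroms[k] != chroms[j]:
                continue
            if abs(positions[k] - positions[j]) > window_bp:
                continue
            a, b = values[:, k].astype(float), values[:, j].astype(float)
            good = (values[:, k] != MISSING) & (values[:, j] != MISSING)
            if good.sum() < 2:
                continue
            a, b = a[good], b[good]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
            keep[j] = True
    return keep


# ---------------------------------------------------------------------------
# frequencies / missing rates
# ---------------------------------------------------------------------------

class TestFrequencies:
    @pytest.mark.parametrize("column, expected", [
        ([0, 1, 2], 0.5),
        ([2, 2, 2], 1.0),
        ([0, MISSING, 1], 0.25),
    ])
    def test_alt_frequency(self, column, expected):
        values = np.array(column, dtype=np.int8)[:, None]
        assert allele_frequency(values, 0) == pytest.approx(expected)

    def test_all_missing_is_error(self):
        values = np.full((3, 1), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="missing"):
            allele_frequency(values, 0)

    @pytest.mark.parametrize("row, expected", [
        ([0, 1, 2, MISSING], 0.25),
        ([MISSING] * 4, 1.0),
        ([0, 1, 2, 2], 0.0),
    ])
    def test_sample_missing_rate(self, row, expected):
        values = np.array([row], dtype=np.int8)
        assert sample_missing_rate(values, 0) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# exact HWE
# ---------------------------------------------------------------------------

class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(42, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    @pytest.mark.parametrize("table", [(0, 100, 0), (25, 50, 25),
                                       (3, 5, 40), (10, 1, 10)])
    def test_matches_enumeration_oracle(self, table):
        assert hwe_exact_test(*table) == pytest.approx(
            hwe_oracle(*table), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_oracle_equivalence_random_tables(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_exact_test(a, b, c)
        assert 0 < p <= 1
        assert p == pytest.approx(hwe_oracle(a, b, c), abs=1e-12)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

class TestLDPrune:
    def test_identical_columns_second_removed(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=40).astype(np.int8)
        values = np.stack([col, col], axis=1)
        keep = ld_prune(values, ["1", "1"], [1000, 2000],
                        r2_threshold=0.2)
        assert keep.tolist() == [True, False]

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(3)
        while True:     # draw until empirically uncorrelated
            values = rng.integers(0, 3, size=(60, 2)).astype(np.int8)
            r = np.corrcoef(values[:, 0], values[:, 1])[0, 1]
            if r * r < 0.2:
                break
        keep = ld_prune(values, ["1", "1"], [1000, 2000],
                        r2_threshold=0.2)
        assert keep.tolist() == [True, True]

    def test_outside_window_not_compared(self):
        col = np.tile([0, 1, 2], 10).astype(np.int8)
        values = np.stack([col, col], axis=1)
        keep = ld_prune(values, ["1", "1"], [1000, 600_000],
                        r2_threshold=0.2, window_bp=500_000)
        assert keep.tolist() == [True, True]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 31))
        n = 25
        # correlated blocks + missing values to exercise the estimator
        base = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        for j in range(1, m):
            if rng.random() < 0.4:
                base[:, j] = base[:, j - 1]
                flip = rng.random(n) < 0.2
                base[flip, j] = rng.integers(0, 3, size=flip.sum())
        base[rng.random((n, m)) < 0.05] = MISSING
        chroms = np.array(["1"] * m)
        positions = np.sort(rng.choice(10_000, size=m, replace=False))
        keep = ld_prune(base, chroms, positions, r2_threshold=0.2,
                        window_bp=5_000)
        oracle = ld_prune_oracle(base, chroms, positions, 0.2, 5_000)
        assert keep.tolist() == oracle.tolist()

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(9)
        n, m = 30, 25
        values = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        values[:, 1] = values[:, 0]
        chroms = np.array(["1"] * m)
        positions = np.arange(m) * 100
        keep = ld_prune(values, chroms, positions, r2_threshold=0.2,
                        window_bp=10_000)
        kept = np.nonzero(keep)[0]
        for a_i, j in enumerate(kept):
            for k in kept[a_i + 1:]:
                if abs(positions[j] - positions[k]) > 10_000:
                    continue
                a = values[:, j].astype(float)
                b = values[:, k].astype(float)
                good = (values[:, j] != MISSING) & (values[:, k] != MISSING)
                if good.sum() < 2:
                    continue
                a, b = a[good], b[good]
                if a.std() == 0 or b.std() == 0:
                    continue
                assert np.corrcoef(a, b)[0, 1] ** 2 <= 0.2 + 1e-12


# ---------------------------------------------------------------------------
# inbreeding coefficient
# ---------------------------------------------------------------------------

class TestInbreeding:
    def test_all_het_at_half_is_minus_one(self):
        m = 200
        values = np.ones((1, m), dtype=np.int8)
        p = np.full(m, 0.5)
        f = inbreeding_coefficient(values, 0, np.arange(m), p)
        assert f == pytest.approx(-1.0, abs=1e-12)

    def test_all_hom_is_one(self):
        m = 200
        values = np.concatenate([np.zeros(100), np.full(100, 2)]
                                ).astype(np.int8)[None, :]
        p = np.linspace(0.1, 0.9, m)
        f = inbreeding_coefficient(values, 0, np.arange(m), p)
        assert f == pytest.approx(1.0, abs=1e-12)

    def test_hwe_simulation_near_zero(self):
        rng = np.random.default_rng(5)
        m = 10_000
        p = rng.uniform(0.05, 0.5, m)
        values = rng.binomial(2, p, size=(1, m)).astype(np.int8)
        f = inbreeding_coefficient(values, 0, np.arange(m), p)
        assert abs(f) < 0.05

    def test_invariant_to_variant_order_and_missing_padding(self):
        rng = np.random.default_rng(6)
        m = 500
        p = rng.uniform(0.1, 0.5, m)
        values = rng.binomial(2, p, size=(1, m)).astype(np.int8)
        f0 = inbreeding_coefficient(values, 0, np.arange(m), p)
        perm = rng.permutation(m)
        f1 = inbreeding_coefficient(values[:, perm], 0, np.arange(m),
                                    p[perm])
        padded = np.hstack([values,
                            np.full((1, 50), MISSING, dtype=np.int8)])
        f2 = inbreeding_coefficient(
            padded, 0, np.arange(m + 50),
            np.concatenate([p, np.full(50, 0.3)]))
        assert f1 == pytest.approx(f0, abs=1e-12)
        assert f2 == pytest.approx(f0, abs=1e-12)

    def test_undefined_when_no_informative_sites(self):
        values = np.zeros((1, 10), dtype=np.int8)
        p = np.zeros(10)
        with pytest.raises(ValueError, match="undefined"):
            inbreeding_coefficient(values, 0, np.arange(10), p)


class TestXInbreeding:
    PAR = ((60001, 2699520), (154931044, 155260560))

    def test_hemizygous_male_is_one(self):
        rng = np.random.default_rng(7)
        m = 300
        p = rng.uniform(0.1, 0.5, m)
        values = (2 * rng.binomial(1, p, size=(1, m))).astype(np.int8)
        pos = 3_000_000 + np.arange(m) * 1000
        f, n_used = x_inbreeding(values, 0, np.arange(m), pos, self.PAR, p)
        assert f == pytest.approx(1.0, abs=1e-12)
        assert n_used == m

    def test_female_hwe_near_zero(self):
        rng = np.random.default_rng(8)
        m = 2000
        p = rng.uniform(0.1, 0.5, m)
        values = rng.binomial(2, p, size=(1, m)).astype(np.int8)
        pos = 3_000_000 + np.arange(m) * 1000
        f, _ = x_inbreeding(values, 0, np.arange(m), pos, self.PAR, p)
        assert abs(f) < 0.1

    def test_par_variants_excluded(self):
        # two informative variants; the PAR one is heterozygous and
        # would drag F away from 1 if it were included
        values = np.array([[2, 1]], dtype=np.int8)
        pos = np.array([3_000_000, 100_000])     # second is inside PAR1
        p = np.array([0.4, 0.4])
        with pytest.warns(UserWarning, match="non-PAR X"):
            f, n_used = x_inbreeding(values, 0, [0, 1], pos, self.PAR, p)
        assert n_used == 1
        assert f == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# method-of-moments IBD
# ---------------------------------------------------------------------------

def _pairs_k(rng, relation, n_pairs=60, m=5000):
    """Gene-drop pairs and estimate (k0, k1) with true frequencies."""
    p = rng.uniform(0.1, 0.5, m)
    rows = []
    for _ in range(n_pairs):
        a, b = plant_related_pair(rng, p, relation)
        rows += [a, b]
    values = np.stack(rows)
    k0, k1, _, kin, _ = pairwise_ibd(values, p)
    idx = np.arange(0, 2 * n_pairs, 2)
    return k0[idx, idx + 1], k1[idx, idx + 1], kin[idx, idx + 1]


class TestIBD:
    def test_duplicate_pair(self):
        rng = np.random.default_rng(10)
        m = 5000
        p = rng.uniform(0.1, 0.5, m)
        a = rng.binomial(2, p).astype(np.int8)
        values = np.stack([a, a.copy()])
        rel = ibd_mom(values, 0, 1, np.arange(m), p)
        assert rel.k2 == pytest.approx(1.0, abs=0.02)
        assert rel.kinship == pytest.approx(0.5, abs=0.02)
        assert rel.pi_hat == pytest.approx(1.0, abs=0.02)

    def test_parent_offspring_pair(self):
        rng = np.random.default_rng(11)
        k0, k1, kin = _pairs_k(rng, "PO", n_pairs=20)
        assert np.mean(np.abs(k0 - 0.0)) < 0.03
        assert np.mean(np.abs(k1 - 1.0)) < 0.03
        assert np.mean(kin) == pytest.approx(0.25, abs=0.03)

    def test_unrelated_pairs(self):
        # the simplex truncation biases k0 slightly below 1 for
        # unrelated pairs, so the mean is checked at the MAE level
        rng = np.random.default_rng(12)
        m = 5000
        p = rng.uniform(0.1, 0.5, m)
        values = rng.binomial(2, p, size=(50, m)).astype(np.int8)
        # frequencies estimated from the cohort, as the QC step does
        k0, _, _, kin, _ = pairwise_ibd(values, allele_frequencies(values))
        iu = np.triu_indices(50, 1)
        assert np.mean(np.abs(k0[iu] - 1.0)) < 0.05
        assert abs(np.mean(kin[iu])) < 0.01
        assert np.mean(np.abs(kin[iu])) < 0.03

    def test_expected_positions_all_relationships(self):
        expected = {"DU": (0.0, 0.0), "PO": (0.0, 1.0),
                    "FS": (0.25, 0.5), "HF": (0.5, 0.5)}
        rng = np.random.default_rng(13)
        for rel, (e0, e1) in expected.items():
            k0, k1, _ = _pairs_k(rng, rel, n_pairs=40)
            assert np.mean(np.abs(k0 - e0)) < 0.05, rel
            assert np.mean(np.abs(k1 - e1)) < 0.05, rel

    def test_too_few_variants_is_error(self):
        rng = np.random.default_rng(14)
        values = rng.integers(0, 3, size=(2, 50)).astype(np.int8)
        with pytest.raises(ValueError, match="unstable"):
            ibd_mom(values, 0, 1, np.arange(50), np.full(50, 0.3))

    def test_simplex_constraints(self):
        rng = np.random.default_rng(15)
        m = 2000
        p = rng.uniform(0.05, 0.5, m)
        values = rng.binomial(2, p, size=(10, m)).astype(np.int8)
        k0, k1, k2, kin, _ = pairwise_ibd(values, p)
        iu = np.triu_indices(10, 1)
        total = k0[iu] + k1[iu] + k2[iu]
        assert np.allclose(total, 1.0, atol=1e-9)
        for k in (k0[iu], k1[iu], k2[iu]):
            assert (k >= 0).all() and (k <= 1).all()
        assert (kin[iu] >= 0).all() and (kin[iu] <= 0.5).all()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def _two_pop(self, rng, n_per=50, m=2000, fst=0.1):
        anc = rng.uniform(0.1, 0.5, m)
        a = anc * (1 - fst) / fst
        b = (1 - anc) * (1 - fst) / fst
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
        g = np.vstack([rng.binomial(2, p1, size=(n_per, m)),
                       rng.binomial(2, p2, size=(n_per, m))]
                      ).astype(np.int8)
        return g

    def test_separates_populations(self):
        rng = np.random.default_rng(16)
        g = self._two_pop(rng)
        res = pca(g, np.arange(g.shape[1]))
        pc1 = res.eigenvectors[:, 0]
        g1, g2 = pc1[:50], pc1[50:]
        between = abs(g1.mean() - g2.mean())
        within = max(g1.std(), g2.std())
        assert between > 4 * within

    def test_eigen_structure(self):
        rng = np.random.default_rng(17)
        g = self._two_pop(rng, n_per=20, m=500)
        res = pca(g, np.arange(g.shape[1]), n_components=4)
        assert (res.eigenvalues >= 0).all()
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        gram = res.eigenvectors.T @ res.eigenvectors
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_sample_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(18)
        g = self._two_pop(rng, n_per=15, m=400)
        res = pca(g, np.arange(g.shape[1]), n_components=2)
        perm = rng.permutation(g.shape[0])
        res_p = pca(g[perm], np.arange(g.shape[1]), n_components=2)
        for j in range(2):
            a = res.eigenvectors[perm, j]
            b = res_p.eigenvectors[:, j]
            assert (np.allclose(a, b, atol=1e-8)
                    or np.allclose(a, -b, atol=1e-8))

    def test_k_reduced_with_warning(self):
        rng = np.random.default_rng(19)
        g = rng.integers(0, 3, size=(3, 50)).astype(np.int8)
        with pytest.warns(UserWarning, match="components"):
            res = pca(g, np.arange(50), n_components=4)
        assert res.eigenvectors.shape[1] == 3
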
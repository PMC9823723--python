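"""Diversity parameters, identity probabilities, rarefaction, marker sets, Fst."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cherry_curator.core import SSRGenotype
from cherry_curator.diversity_stats import (
    allele_frequencies,
    allelic_richness,
    fst,
    locus_diversity,
    minimal_marker_set,
    pi,
    pi_single_locus,
)
from _oracles import enumerate_allelic_richness, mc_pi, mc_pi_sib


def _geno(pairs):
    return SSRGenotype(pairs)


class TestAlleleFrequencies:
    def test_two_homozygotes(self):
        table = allele_frequencies([_geno({"L1": (150, 150)}), _geno({"L1": (152, 152)})])
        lf = table["L1"]
        assert lf.freqs == {150: 0.5, 152: 0.5}
        assert lf.n_individuals == 2
        assert lf.n_heterozygotes == 0

    def test_single_heterozygote(self):
        table = allele_frequencies([_geno({"L1": (150, 152)})])
        lf = table["L1"]
        assert lf.freqs == {150: 0.5, 152: 0.5}
        assert lf.n_heterozygotes == 1

    def test_missing_reduces_locus_n(self):
        table = allele_frequencies(
            [_geno({"L1": (150, 152), "L2": None}), _geno({"L1": (150, 150), "L2": (160, 160)})]
        )
        assert table["L1"].n_individuals == 2
        assert table["L2"].n_individuals == 1

    def test_untyped_locus_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="0 individuals"):
            table = allele_frequencies(
                [_geno({"L1": (150, 152), "L2": None})]
            )
        assert table.loci == ("L1",)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_frequencies_sum_to_one_and_ne_he_relation(self, seed):
        rng = np.random.default_rng(seed)
        genos = [
            _geno({"L1": tuple(sorted(rng.integers(150, 160, size=2).tolist()))})
            for _ in range(20)
        ]
        table = allele_frequencies(genos)
        p = table["L1"].freq_array
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        s2 = float(np.sum(p**2))
        ne, he = 1.0 / s2, 1.0 - s2
        assert ne == pytest.approx(1.0 / (1.0 - he), abs=1e-9)


class TestPI:
    def test_biallelic_closed_form(self):
        p = np.array([0.5, 0.5])
        pi_v, pisib_v = pi_single_locus(p)
        assert pi_v == pytest.approx(0.375)
        assert pisib_v == pytest.approx(0.59375)

    def test_monomorphic_locus(self):
        pi_v, pisib_v = pi_single_locus(np.array([1.0]))
        assert pi_v == 1.0 and pisib_v == 1.0

    def test_four_equifrequent_alleles_vs_enumeration(self):
        # brute force over all 10 genotypes: sum of squared HWE probabilities
        p = {a: 0.25 for a in range(4)}
        exact = 0.0
        for a in range(4):
            for b in range(a, 4):
                prob = p[a] * p[b] * (2 if a != b else 1)
                exact += prob**2
        pi_v, _ = pi_single_locus(np.array([0.25] * 4))
        assert pi_v == pytest.approx(exact)
        assert pi_v == pytest.approx(0.109375)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    def test_pisib_at_least_pi(self, seed, k):
        p = np.random.default_rng(seed).dirichlet(np.full(k, 0.4))
        pi_v, pisib_v = pi_single_locus(p)
        assert pisib_v >= pi_v - 1e-12

    def test_monte_carlo_oracle_20_random_loci(self):
        """PI and PIsib agree with 10^6-pair genotype simulations within
        3 standard errors at 20 random loci."""
        rng = np.random.default_rng(4242)
        n_pairs = 1_000_000
        for _ in range(20):
            k = int(rng.integers(2, 20))
            p = rng.dirichlet(np.full(k, 0.3))
            pi_v, pisib_v = pi_single_locus(p)
            est, se = mc_pi(p, n_pairs, rng)
            assert abs(est - pi_v) <= 3 * max(se, 1e-9)
            est_s, se_s = mc_pi_sib(p, n_pairs, rng)
            assert abs(est_s - pisib_v) <= 3 * max(se_s, 1e-9)

    def test_cumulative_products_sorted_ascending(self):
        genos = [
            _geno({"L1": (150 + 2 * i, 150 + 2 * j), "L2": (160, 162)})
            for i in range(4)
            for j in range(i, 4)
        ]
        res = pi(allele_frequencies(genos))
        assert res.order_pi[0] == min(res.pi, key=res.pi.get)
        assert res.cumulative_pi[-1] == pytest.approx(
            math.prod(res.pi.values())
        )
        assert all(
            b <= a + 1e-15 for a, b in zip(res.cumulative_pi, res.cumulative_pi[1:])
        )


class TestAllelicRichness:
    def _table(self, counts):
        genos = []
        copies = [a for allele, c in counts.items() for a in [allele] * c]
        for i in range(0, len(copies), 2):
            genos.append(_geno({"L1": (copies[i], copies[i + 1])}))
        return allele_frequencies(genos)

    def test_monomorphic_is_one_for_all_g(self):
        table = self._table({150: 8})
        for g in (2, 4, 8):
            ar, _ = allelic_richness(table, g)
            assert ar["L1"] == pytest.approx(1.0)

    def test_two_plus_two_at_g2_is_five_thirds(self):
        table = self._table({150: 2, 152: 2})
        ar, _ = allelic_richness(table, 2)
        assert ar["L1"] == pytest.approx(5 / 3)
        assert ar["L1"] == pytest.approx(enumerate_allelic_richness({150: 2, 152: 2}, 2))

    @pytest.mark.parametrize(
        "counts",
        [
            {150: 2, 152: 2},
            {150: 5, 152: 3, 154: 2},
            {150: 1, 152: 1, 154: 4, 156: 6},
            {150: 7, 152: 3},
        ],
    )
    def test_matches_enumeration_exactly(self, counts):
        table = self._table(counts)
        n = sum(counts.values())
        for g in range(2, n + 1):
            ar, _ = allelic_richness(table, g)
            assert ar["L1"] == pytest.approx(
                enumerate_allelic_richness(counts, g), abs=1e-12
            )

    def test_nondecreasing_in_g(self):
        table = self._table({150: 5, 152: 3, 154: 2, 156: 2})
        values = [allelic_richness(table, g)[0]["L1"] for g in range(2, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_bad_g_rejected(self):
        table = self._table({150: 2, 152: 2})
        with pytest.raises(ValueError):
            allelic_richness(table, 1)
        with pytest.raises(ValueError):
            allelic_richness(table, 5)


class TestLocusDiversityTable:
    def test_mean_row_is_unweighted_column_mean(self, noisy_collection):
        _, records, _ = noisy_collection
        df = locus_diversity([r.genotype for r in records])
        body = df.iloc[:-1]
        mean = df.iloc[-1]
        for col in ("Na", "Ne", "Ho", "He", "Ar"):
            assert mean[col] == pytest.approx(body[col].mean())

    def test_monomorphic_locus_values(self):
        genos = [_geno({"L1": (150, 150), "L2": (160, 162)}) for _ in range(4)]
        df = locus_diversity(genos)
        row = df[df["locus"] == "L1"].iloc[0]
        assert row["Na"] == 1 and row["Ne"] == pytest.approx(1.0)
        assert row["He"] == 0.0 and row["Ho"] == 0.0


class TestMinimalMarkerSet:
    def test_one_fully_discriminating_locus(self):
        genos = [_geno({"L1": (150 + 2 * i, 150 + 2 * i), "L2": (160, 160)}) for i in range(5)]
        freqs = allele_frequencies(genos)
        res = minimal_marker_set(genos, freqs, mode="empirical")
        assert res.size == 1

    def test_identical_genotypes_reported_unresolved(self):
        g = _geno({"L1": (150, 152), "L2": (160, 162)})
        genos = [g, g, _geno({"L1": (154, 156), "L2": (160, 162)})]
        res = minimal_marker_set(genos, allele_frequencies(genos), mode="empirical")
        assert res.unresolved_pairs == ((0, 1),)

    def test_empirical_not_larger_than_sib_mode(self):
        """Over seeded synthetic panels the empirical stopping rule needs
        at most as many loci as the conservative sib criterion."""
        from cherry_curator.synthetic_collection import GeneratorConfig, generate
        from cherry_curator.harmonization import harmonize
        from cherry_curator.identity_dedup import build_groups

        for seed in range(20):
            cfg = GeneratorConfig(
                seed=1000 + seed,
                n_cultivars=40,
                clones_per_cultivar=(1, 1),
                clone_error_rate=0.0,
                missing_rate=0.0,
                sizing_jitter_rate=0.0,
            )
            records, _ = generate(cfg)
            genos = [r.genotype for r in records]
            freqs = allele_frequencies(genos)
            emp = minimal_marker_set(genos, freqs, mode="empirical")
            sib = minimal_marker_set(genos, freqs, mode="sib")
            if emp.unresolved_pairs:
                continue
            assert emp.size <= sib.size


class TestFst:
    def _genos(self, pairs_list):
        return [_geno({"L1": p}) for p in pairs_list]

    def test_identical_clusters_zero(self):
        cluster = [(150, 152), (150, 150), (152, 152), (150, 152)]
        genos = self._genos(cluster * 2)
        labels = ["A"] * 4 + ["B"] * 4
        res = fst(genos, labels)
        assert res[0].fst == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternative_alleles_one(self):
        genos = self._genos([(150, 150)] * 3 + [(152, 152)] * 3)
        res = fst(genos, ["A"] * 3 + ["B"] * 3)
        assert res[0].fst == pytest.approx(1.0)

    def test_small_cluster_excluded_with_warning(self):
        genos = self._genos([(150, 150)] * 3 + [(152, 152)] * 3 + [(150, 152)])
        with pytest.warns(UserWarning, match="<2"):
            res = fst(genos, ["A"] * 3 + ["B"] * 3 + ["C"])
        assert len(res) == 1

    def test_two_island_model_matches_frequency_oracle(self):
        """Empirical Fst on large planted two-island samples is within 0.01
        of the same estimator applied to the true island frequencies."""
        rng = np.random.default_rng(77)
        n_loci, k = 12, 8
        n_per = 400
        genos_a, genos_b = [], []
        true_fst_terms = []
        for l in range(n_loci):
            base = rng.dirichlet(np.full(k, 0.8))
            pa = 0.85 * base + 0.15 * rng.dirichlet(np.full(k, 0.5))
            pb = 0.85 * base + 0.15 * rng.dirichlet(np.full(k, 0.5))
            hs = 0.5 * ((1 - np.sum(pa**2)) + (1 - np.sum(pb**2)))
            pm = 0.5 * (pa + pb)
            ht = 1 - float(np.sum(pm**2))
            true_fst_terms.append((ht - hs) / ht)
            draws_a = rng.choice(k, size=(n_per, 2), p=pa)
            draws_b = rng.choice(k, size=(n_per, 2), p=pb)
            for i in range(n_per):
                if l == 0:
                    genos_a.append({})
                    genos_b.append({})
                genos_a[i][f"L{l}"] = (150 + 2 * draws_a[i, 0], 150 + 2 * draws_a[i, 1])
                genos_b[i][f"L{l}"] = (150 + 2 * draws_b[i, 0], 150 + 2 * draws_b[i, 1])
        genos = [_geno(g) for g in genos_a + genos_b]
        labels = ["A"] * n_per + ["B"] * n_per
        res = fst(genos, labels)
        oracle = float(np.mean(true_fst_terms))
        assert res[0].fst == pytest.approx(oracle, abs=0.01)
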
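"""Simple-matching similarity, molecular groups, trueness-to-type categories."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cherry_curator.core import AccessionRecord, PomologicalStatus, SSRGenotype
from cherry_curator.harmonization import harmonize
from cherry_curator.identity_dedup import (
    Category,
    assign_categories,
    build_groups,
    category_summary,
    similarity,
    similarity_matrix,
)
from cherry_curator.synthetic_collection import GeneratorConfig, generate


def _geno(pairs):
    return SSRGenotype(pairs)


def _full(pair_by_locus, n_loci=16):
    return _geno({f"L{i}": pair_by_locus(i) for i in range(n_loci)})


def _rec(acc, genotype, status=None, name=""):
    return AccessionRecord(
        accession_id=acc,
        collection="C",
        assumed_name=name,
        genotype=genotype,
        pomological_status=status or PomologicalStatus.not_determined(),
    )


class TestSimilarity:
    def test_identical_complete_genotypes(self):
        g = _full(lambda i: (150 + 2 * i, 152 + 2 * i))
        res = similarity(g, g)
        assert res.similarity == 1.0
        assert res.shared_loci == 16
        assert res.matching_alleles == 32

    def test_fully_disjoint(self):
        g1 = _full(lambda i: (150, 152))
        g2 = _full(lambda i: (160, 162))
        assert similarity(g1, g2).similarity == 0.0

    def test_single_allele_difference_hand_count(self):
        # 16 loci, one locus {150,152} vs {150,154}: 31 of 32 alleles match
        g1 = _full(lambda i: (150, 152))
        g2 = _geno(
            {f"L{i}": (150, 152) for i in range(15)} | {"L15": (150, 154)}
        )
        res = similarity(g1, g2)
        assert res.matching_alleles == 31
        assert res.similarity == pytest.approx(31 / 32)

    def test_homozygote_vs_heterozygote_counts_one_match(self):
        res = similarity(
            _geno({f"L{i}": (150, 150) for i in range(8)}),
            _geno({f"L{i}": (150, 152) for i in range(8)}),
        )
        assert res.matching_alleles == 8
        assert res.similarity == 0.5

    def test_missing_loci_shrink_denominator(self):
        g1 = _geno({"L0": (150, 152), "L1": None, "L2": (160, 160)})
        g2 = _geno({"L0": (150, 152), "L1": (140, 142), "L2": (160, 160)})
        res = similarity(g1, g2, min_shared=2)
        assert res.shared_loci == 2
        assert res.similarity == 1.0

    def test_too_few_shared_loci_flagged(self):
        g1 = _geno({"L0": (150, 152), "L1": None})
        g2 = _geno({"L0": (150, 152), "L1": (140, 142)})
        res = similarity(g1, g2, min_shared=2)
        assert not res.comparable
        assert math.isnan(res.similarity)

    def test_locus_mode_scores_whole_loci(self):
        g1 = _geno({"L0": (150, 152), "L1": (160, 162)})
        g2 = _geno({"L0": (150, 154), "L1": (160, 162)})
        assert similarity(g1, g2, min_shared=1, mode="locus").similarity == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_matrix_agreement(self, seed):
        rng = np.random.default_rng(seed)
        genos = []
        for _ in range(4):
            pairs = {}
            for i in range(6):
                if rng.random() < 0.15:
                    pairs[f"L{i}"] = None
                else:
                    a, b = rng.integers(150, 160, size=2)
                    pairs[f"L{i}"] = (int(a), int(b))
            if all(p is None for p in pairs.values()):
                pairs["L0"] = (150, 150)
            genos.append(_geno(pairs))
        sim, _ = similarity_matrix(genos, min_shared=1)
        for i in range(4):
            for j in range(4):
                a = similarity(genos[i], genos[j], min_shared=1)
                b = similarity(genos[j], genos[i], min_shared=1)
                assert a.similarity == b.similarity or (
                    math.isnan(a.similarity) and math.isnan(b.similarity)
                )
                if not math.isnan(a.similarity):
                    assert sim[i, j] == pytest.approx(a.similarity)


class TestBuildGroups:
    def test_exact_copies_group_together(self):
        g = _full(lambda i: (150, 152))
        other = _full(lambda i: (170, 180))
        recs = [_rec(f"T{i}", g) for i in range(3)] + [_rec("T9", other)]
        groups = build_groups(recs)
        assert sorted(gr.size for gr in groups) == [1, 3]
        assert groups[0].representative_support == 3

    def test_single_linkage_chain_merges(self):
        # A~B and B~C above threshold, A~C below: one group by chaining
        base = {f"L{i}": (150, 152) for i in range(16)}
        a = _geno(base)
        b = _geno(base | {"L0": (150, 154)})  # 31/32 vs a
        c = _geno(base | {"L0": (150, 154), "L1": (150, 154), "L2": (150, 154)})
        sab = similarity(a, b).similarity
        sbc = similarity(b, c).similarity
        sac = similarity(a, c).similarity
        assert sab > 0.9 and sbc > 0.9 and sac <= 0.91
        groups = build_groups([_rec("A", a), _rec("B", b), _rec("C", c)], threshold=0.92)
        assert len(groups) == 1
        assert set(groups[0].member_ids) == {"A", "B", "C"}

    def test_groups_partition_accessions(self, noisy_collection):
        _, records, _ = noisy_collection
        harmonized, _, _ = harmonize(records)
        groups = build_groups(harmonized)
        seen = [a for g in groups for a in g.member_ids]
        assert sorted(seen) == sorted(r.accession_id for r in records)

    def test_planted_clones_recovered_exactly(self):
        cfg = GeneratorConfig(
            seed=31,
            n_cultivars=50,
            clones_per_cultivar=(2, 6),
            max_mistypes_per_clone=1,  # corruption <= 5% of alleles
        )
        records, truth = generate(cfg)
        assert truth.min_within_similarity > 0.9
        assert truth.max_between_similarity < 0.9
        harmonized, _, _ = harmonize(records)
        groups = build_groups(harmonized)
        assert len(groups) == 50
        found = {frozenset(g.member_ids) for g in groups}
        assert found == {frozenset(a) for a in truth.clones().values()}

    def test_representative_is_modal_genotype(self):
        g = _full(lambda i: (150, 152))
        variant = _geno({f"L{i}": (150, 152) for i in range(15)} | {"L15": (150, 154)})
        recs = [_rec("T1", g), _rec("T2", g), _rec("T3", variant)]
        groups = build_groups(recs)
        assert len(groups) == 1
        assert groups[0].representative.key() == g.key()
        assert groups[0].representative_support == 2


class TestAssignCategories:
    def _group_records(self, statuses):
        g = _full(lambda i: (150, 152))
        recs = [
            _rec(f"T{i}", g, status=s, name="Regina") for i, s in enumerate(statuses)
        ]
        return recs, build_groups(recs)

    def test_unanimous_determination_gives_category_1(self):
        recs, groups = self._group_records(
            [PomologicalStatus.determined("Regina")] * 5
        )
        out = assign_categories(groups, recs)
        assert all(a.category is Category.TRUE_TO_TYPE for a in out)
        assert all(a.resolved_name == "Regina" for a in out)

    def test_conflicting_name_relabelled_to_consensus(self):
        recs, groups = self._group_records(
            [PomologicalStatus.determined("Büttners Rote Knorpelkirsche")] * 3
            + [PomologicalStatus.determined("Querfurter Königskirsche")]
        )
        out = assign_categories(groups, recs)
        flagged = [a for a in out if a.relabel]
        assert len(flagged) == 1
        assert flagged[0].resolved_name == "Büttners Rote Knorpelkirsche"
        assert flagged[0].category is Category.TRUE_TO_TYPE

    def test_tied_consensus_reports_unresolved(self):
        recs, groups = self._group_records(
            [
                PomologicalStatus.determined("A"),
                PomologicalStatus.determined("B"),
            ]
        )
        out = assign_categories(groups, recs)
        assert all(a.unresolved and a.category is None for a in out)

    def test_status_driven_categories(self):
        recs, groups = self._group_records(
            [
                PomologicalStatus.no_reference(),
                PomologicalStatus.no_reference(),
            ]
        )
        out = assign_categories(groups, recs)
        assert all(a.category is Category.OWN_GROUP_NO_REFERENCE for a in out)
        recs, groups = self._group_records([PomologicalStatus.not_determined()])
        assert (
            assign_categories(groups, recs)[0].category
            is Category.NO_POMOLOGICAL_DETERMINATION
        )
        recs, groups = self._group_records(
            [PomologicalStatus.with_reservation("Regina")]
        )
        a = assign_categories(groups, recs)[0]
        assert a.category is Category.APPROVED_WITH_RESERVATION
        assert a.resolved_name == "Regina"

    def test_planted_category_proportions_recovered(self):
        """Planted labels at the published proportions (85.64 / 8.32 / 4.4 /
        1.6 percent of trees) come back as exactly the planted counts."""
        cfg = GeneratorConfig(
            seed=47,
            n_cultivars=95,
            clones_per_cultivar=(3, 5),
            max_mistypes_per_clone=1,
            reference_prob=1.0,
            not_determined_rate=0.0,
            reservation_rate=0.0,
        )
        records, truth = generate(cfg)
        rng = np.random.default_rng(48)
        # plant: whole cultivars become no-reference; individual trees
        # become undetermined / with-reservation
        cultivars = sorted({truth.cultivar_of[r.accession_id] for r in records})
        no_ref = set(rng.choice(cultivars, size=8, replace=False))
        planted = {1: 0, 3: 0, 4: 0, 5: 0}
        out_records = []
        n4 = n5 = 0
        for r in records:
            cv = truth.cultivar_of[r.accession_id]
            if cv in no_ref:
                status, cat = PomologicalStatus.no_reference(), 3
            elif n4 < 17:
                status, cat = PomologicalStatus.not_determined(), 4
                n4 += 1
            elif n5 < 6:
                status, cat = PomologicalStatus.with_reservation(cv), 5
                n5 += 1
            else:
                status, cat = PomologicalStatus.determined(cv), 1
            planted[cat] += 1
            out_records.append(dataclasses.replace(r, pomological_status=status))
        harmonized, _, _ = harmonize(out_records)
        groups = build_groups(harmonized)
        out = assign_categories(groups, harmonized)
        counts = {c: sum(1 for a in out if a.category == c) for c in (1, 3, 4, 5)}
        assert counts == planted
        summary = category_summary(out)
        assert summary["total"] == len(records)
        assert sum(summary["counts"].values()) == len(records)
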
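import numpy as np
import pytest

from sorlscan.pedigree_segregation import (
    infer_families,
    merge_pedigrees,
    prioritize_segregating,
    segregation_summary,
    select_informative,
)
from sorlscan.synthetic_cohort import PlantedFamily, SimulationConfig, simulate_families
from sorlscan.types import Family, GenotypeMatrix, KinshipPair, PedigreeMember, SampleRecord
from sorlscan.variant_prioritization import filter_family_damaging

from conftest import make_samples


def pair(a, b, k):
    return KinshipPair(a, b, k)


def fam(fid, members, source="core"):
    return Family(fid, [PedigreeMember(fid, m, "0", "0") for m in members], source=source)


def record(sid, phenotype="control"):
    return SampleRecord(sid, "EUR", phenotype, 1, 60.0)


class TestInferFamilies:
    def test_transitive_closure(self):
        fams = infer_families([pair("A", "B", 0.25), pair("B", "C", 0.20), pair("D", "E", 0.30)])
        assert [f.member_ids for f in fams] == [["A", "B", "C"], ["D", "E"]]
        assert all(f.n_founders == len(f.member_ids) for f in fams)

    def test_threshold_is_strict(self):
        assert infer_families([pair("A", "B", 0.0884)]) == []
        assert len(infer_families([pair("A", "B", 0.0885)])) == 1

    def test_excluded_core_members_never_enter(self):
        fams = infer_families([pair("A", "B", 0.25), pair("B", "C", 0.25)], exclude={"B"})
        assert fams == []

    def test_random_graphs_match_bruteforce_flood_fill(self, rng):
        for _ in range(5):
            nodes = [f"N{i}" for i in range(200)]
            pairs = []
            adj = {n: set() for n in nodes}
            for _ in range(250):
                a, b = rng.choice(200, size=2, replace=False)
                k = float(rng.uniform(0, 0.4))
                pairs.append(pair(nodes[a], nodes[b], k))
                if k > 0.0884:
                    adj[nodes[a]].add(nodes[b])
                    adj[nodes[b]].add(nodes[a])
            # brute-force flood fill
            seen, truth = set(), []
            for n in nodes:
                if n in seen or not adj[n]:
                    continue
                stack, comp = [n], set()
                while stack:
                    x = stack.pop()
                    if x in comp:
                        continue
                    comp.add(x)
                    stack.extend(adj[x] - comp)
                seen |= comp
                if len(comp) >= 2:
                    truth.append(sorted(comp))
            got = sorted(f.member_ids for f in infer_families(pairs))
            assert got == sorted(truth)

    def test_partition_property(self, rng):
        pairs = [
            pair(f"N{a}", f"N{b}", float(rng.uniform(0.05, 0.4)))
            for a, b in rng.integers(0, 50, size=(80, 2))
            if a != b
        ]
        fams = infer_families(pairs)
        members = [m for f in fams for m in f.member_ids]
        assert len(members) == len(set(members))  # nobody in two families


class TestMergePedigrees:
    def test_335_core_plus_134_inferred_is_469(self):
        core = [fam(f"C{i}", [f"c{i}a", f"c{i}b"]) for i in range(335)]
        inferred = [fam(f"I{i}", [f"i{i}a", f"i{i}b"], "inferred") for i in range(134)]
        assert len(merge_pedigrees(core, inferred)) == 469

    def test_empty_inferred_identity(self):
        core = [fam("C1", ["a", "b"])]
        assert [f.family_id for f in merge_pedigrees(core, [])] == ["C1"]

    def test_split_by_source_recovers_inputs(self):
        core = [fam("F", ["a", "b"])]
        inferred = [fam("F", ["c", "d"], "inferred")]
        merged = merge_pedigrees(core, inferred)
        back_core = [f for f in merged if f.source == "core"]
        back_inf = [f for f in merged if f.source == "inferred"]
        assert [f.member_ids for f in back_core] == [["a", "b"]]
        assert [f.member_ids for f in back_inf] == [["c", "d"]]
        assert {f.family_id for f in merged} == {"core:F", "inf:F"}

    def test_overlapping_membership_rejected(self):
        with pytest.raises(ValueError, match="both core and inferred"):
            merge_pedigrees([fam("C", ["a", "b"])], [fam("I", ["b", "c"], "inferred")])


class TestSelectInformative:
    def test_family_with_pd_member_retained(self):
        fams = [fam("F1", ["a", "b", "c"])]
        samples = [record("a", "PD"), record("b"), record("c")]
        assert select_informative(fams, samples) == fams

    def test_family_without_pd_removed(self):
        fams = [fam("F1", ["a", "b"])]
        samples = [record("a"), record("b")]
        assert select_informative(fams, samples) == []

    def test_matches_independent_predicate(self, rng):
        fams, samples = [], []
        for i in range(30):
            n = int(rng.integers(1, 5))
            ids = [f"F{i}_{j}" for j in range(n)]
            fams.append(fam(f"F{i}", ids))
            for sid in ids:
                samples.append(record(sid, "PD" if rng.random() < 0.4 else "control"))
        by_id = {s.sample_id: s for s in samples}
        expected = [
            f for f in fams
            if len(f.member_ids) >= 2
            and any(by_id[m].phenotype == "PD" for m in f.member_ids)
        ]
        assert select_informative(fams, samples) == expected

    def test_missing_sample_record_rejected(self):
        with pytest.raises(ValueError, match="no sample record"):
            select_informative([fam("F", ["a", "b"])], [record("a", "PD")])


class TestSegregation:
    def make_family_matrix(self, dosages, phenos, keys=None):
        n = len(phenos)
        ids = [f"M{i}" for i in range(n)]
        keys = keys or [f"11:{121500000 + j}:A:G" for j in range(np.shape(dosages)[1])]
        matrix = GenotypeMatrix(ids, keys, dosages)
        family = fam("FAM", ids)
        samples = [record(i, p) for i, p in zip(ids, phenos)]
        return family, matrix, samples, keys

    def test_full_het_pair_prioritized(self):
        family, matrix, samples, keys = self.make_family_matrix(
            [[1.0], [1.0]], ["PD", "PD"]
        )
        (s,) = segregation_summary(family, matrix, keys, samples)
        assert s.segregates and s.zygosity == "Het"
        assert s.n_genotyped_pd == 2 and s.n_pd_carriers == 2
        assert prioritize_segregating([s]) == keys

    def test_incomplete_carriership_not_prioritized(self):
        family, matrix, samples, keys = self.make_family_matrix(
            [[1.0], [1.0], [0.0]], ["PD", "PD", "PD"]
        )
        (s,) = segregation_summary(family, matrix, keys, samples)
        assert not s.segregates
        assert prioritize_segregating([s]) == []

    def test_carrier_family_control_vetoes(self):
        family, matrix, samples, keys = self.make_family_matrix(
            [[1.0], [1.0], [1.0]], ["PD", "PD", "control"]
        )
        (s,) = segregation_summary(family, matrix, keys, samples)
        assert not s.segregates

    def test_missing_genotype_excluded_not_vetoing(self):
        family, matrix, samples, keys = self.make_family_matrix(
            [[1.0], [np.nan]], ["PD", "PD"]
        )
        (s,) = segregation_summary(family, matrix, keys, samples)
        assert s.n_genotyped_pd == 1 and s.segregates

    def test_co_occurring_known_pd_variant_attached(self):
        family, matrix, samples, keys = self.make_family_matrix(
            [[1.0, 1.0], [1.0, 0.0]], ["PD", "PD"],
            keys=["11:121545392:G:A", "1:155235252:T:C"],
        )
        summaries = segregation_summary(
            family, matrix, ["11:121545392:G:A"], samples,
            known_pd_keys=["1:155235252:T:C"],
        )
        assert summaries[0].co_occurring_known_pd_variants == ["1:155235252:T:C"]

    def test_output_invariant_to_family_and_variant_order(self, rng):
        family, matrix, samples, keys = self.make_family_matrix(
            rng.integers(0, 2, size=(4, 5)).astype(float), ["PD", "PD", "control", "control"]
        )
        fwd = segregation_summary(family, matrix, keys, samples)
        rev = segregation_summary(family, matrix, keys[::-1], samples)
        assert prioritize_segregating(fwd) == prioritize_segregating(rev)


class TestPlantedTruthRecovery:
    def test_fifty_random_families_exact_recovery(self, rng):
        # planted kinship components and segregating variants recovered
        # with sensitivity 1 and no false positives
        planted = [
            PlantedFamily(
                n_members=int(rng.integers(2, 5)),
                n_pd_cases=0,  # fixed below
                segregating=bool(rng.random() < 0.6),
            )
            for _ in range(50)
        ]
        for p in planted:
            p.n_pd_cases = int(rng.integers(1, p.n_members + 1))
            if p.segregating is False and p.n_pd_cases == 1 and p.n_members == 1:
                p.n_members = 2
        cfg = SimulationConfig(seed=99, planted_families=planted)
        fams_true, matrix, samples, annots, pairs, truth = simulate_families(cfg)
        inferred = infer_families(pairs)
        assert sorted(f.member_ids for f in inferred) == sorted(
            f.member_ids for f in fams_true
        )
        informative = select_informative(inferred, samples)
        candidates = [a.variant_key for a in filter_family_damaging(annots, "EUR", gene="SORL1")]
        summaries = []
        for f in informative:
            summaries.extend(segregation_summary(f, matrix, candidates, samples))
        got = set(prioritize_segregating(summaries))
        assert got == set(truth.values())
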
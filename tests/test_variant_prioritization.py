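import numpy as np
import pytest

from sorlscan.synthetic_cohort import PlantedCaseOnly, SimulationConfig, simulate_case_control
from sorlscan.types import VariantAnnotation
from sorlscan.variant_prioritization import (
    AlleleStats,
    FilterCriteria,
    compute_allele_stats,
    filter_disease_causing,
    filter_family_damaging,
    flag_known,
    sig3,
)

from conftest import make_matrix


def ann(key, cls="missense", cadd=25.0, **kw):
    return VariantAnnotation(variant_key=key, consequence_class=cls, cadd=cadd, **kw)


def stats(key, mac, het=None, hom=0, n=100, stratum="EUR:AD"):
    het = mac - 2 * hom if het is None else het
    return AlleleStats(key, stratum, n, mac, mac / (2 * n), het, hom)


class TestAlleleStats:
    def test_three_hets_among_5812_cases(self):
        # 3 heterozygotes in 5,812 cases: MAF 3 / 11,624 = 2.58E-04
        d = np.zeros((5812, 1))
        d[:3, 0] = 1
        m = make_matrix(d)
        (s,) = compute_allele_stats(m, m.sample_ids)
        assert sig3(s.af) == "2.58E-04"
        assert s.zygosity == "het (3), hom (0)"

    def test_all_reference_column(self):
        (s,) = compute_allele_stats(make_matrix(np.zeros((10, 1))), [f"S{i}" for i in range(10)])
        assert s.mac == 0 and s.af == 0.0

    def test_missing_excluded_from_denominator(self):
        d = np.array([[1.0], [np.nan], [2.0], [0.0]])
        (s,) = compute_allele_stats(make_matrix(d), ["S0", "S1", "S2", "S3"])
        assert s.n_nonmissing == 3
        assert s.af == pytest.approx(3 / 6)

    def test_random_matrix_matches_elementwise_recount(self, rng):
        d = rng.integers(0, 3, size=(20, 6)).astype(float)
        d[rng.random(size=d.shape) < 0.1] = np.nan
        m = make_matrix(d)
        got = compute_allele_stats(m, m.sample_ids)
        for j, s in enumerate(got):
            col = [x for x in d[:, j] if not np.isnan(x)]
            assert s.het_count == sum(1 for x in col if x == 1)
            assert s.hom_count == sum(1 for x in col if x == 2)
            assert s.mac == int(sum(col))
            assert s.af == pytest.approx(sum(col) / (2 * len(col)))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_allele_stats(make_matrix(np.zeros((2, 1))), [])


class TestDiseaseCausingFilter:
    KEY = "11:121514282:A:G"

    def test_planted_case_only_variant_retained(self):
        retained, _ = filter_disease_causing(
            [stats(self.KEY, mac=3, n=5812)],
            [stats(self.KEY, mac=0, n=4411)],
            [ann(self.KEY, cadd=27.3)],
        )
        assert [v.variant_key for v in retained] == [self.KEY]

    def test_one_control_het_removes(self):
        retained, _ = filter_disease_causing(
            [stats(self.KEY, mac=3)], [stats(self.KEY, mac=1)], [ann(self.KEY, cadd=27.3)]
        )
        assert retained == []

    @pytest.mark.parametrize(
        "case_mac,cadd,cls,kept",
        [
            (2, 20.1, "missense", True),
            (1, 27.0, "missense", False),  # MAC below 2
            (2, 20.0, "missense", False),  # CADD not strictly above 20
            (2, 27.0, "synonymous", False),
            (2, 27.0, "splicing", True),
            (2, 27.0, "frameshift", True),
        ],
    )
    def test_threshold_boundaries(self, case_mac, cadd, cls, kept):
        retained, _ = filter_disease_causing(
            [stats(self.KEY, mac=case_mac)], [stats(self.KEY, mac=0)],
            [ann(self.KEY, cls=cls, cadd=cadd)],
        )
        assert bool(retained) is kept

    def test_unannotated_variant_reported_not_dropped(self):
        retained, skipped = filter_disease_causing(
            [stats(self.KEY, mac=3)], [stats(self.KEY, mac=0)], []
        )
        assert retained == [] and skipped == [self.KEY]

    def test_planted_truth_on_synthetic_cohort(self):
        # 5 planted damaging case-only variants among 500 benign background
        cfg = SimulationConfig(
            seed=21, n_cases=400, n_controls=300, n_background_variants=500,
            planted_caseonly=[PlantedCaseOnly("missense", 25.0 + k, 3) for k in range(5)],
        )
        matrix, samples, annots = simulate_case_control(cfg)
        cases = [s.sample_id for s in samples if s.is_case]
        ctrls = [s.sample_id for s in samples if not s.is_case]
        retained, skipped = filter_disease_causing(
            compute_allele_stats(matrix, cases),
            compute_allele_stats(matrix, ctrls),
            annots,
        )
        planted = {a.variant_key for a in annots if a.protein_change.startswith("p.X")}
        assert {v.variant_key for v in retained} == planted
        assert len(retained) == 5 and skipped == []

    def test_cascade_monotonicity(self, rng):
        keys = [f"11:{121500000 + i}:A:G" for i in range(40)]
        sc = [stats(k, mac=int(rng.integers(0, 5))) for k in keys]
        s0 = [stats(k, mac=int(rng.integers(0, 2))) for k in keys]
        annots = [
            ann(k, cls=str(rng.choice(["missense", "synonymous", "splicing"])),
                cadd=float(rng.uniform(0, 40)))
            for k in keys
        ]
        loose = FilterCriteria(cadd_min=10.0, mac_min=1)
        tight = FilterCriteria(cadd_min=20.0, mac_min=2)
        kept_loose = {v.variant_key for v in filter_disease_causing(sc, s0, annots, loose)[0]}
        kept_tight = {v.variant_key for v in filter_disease_causing(sc, s0, annots, tight)[0]}
        assert kept_tight <= kept_loose
        # every survivor satisfies the case-MAC floor
        by_key = {s.variant_key: s for s in sc}
        assert all(by_key[k].mac >= 2 for k in kept_tight)


class TestFamilyDamagingFilter:
    def test_rare_damaging_missense_retained(self):
        # high-CADD missense at EAS reference frequency 5E-04
        a = ann("11:121478242:G:A", cadd=28.6, ref_af_by_ancestry={"EAS": 5e-4})
        assert filter_family_damaging([a], "EAS") == [a]

    @pytest.mark.parametrize(
        "cls,cadd,af,kept",
        [
            ("missense", 15.0, 1e-4, False),  # CADD below threshold
            ("synonymous", 25.0, 1e-4, False),  # class rule
            ("stopgain", 5.0, 1e-4, True),  # LOF kept regardless of CADD
            ("missense", 28.0, 0.02, False),  # too common
            ("missense", 28.0, None, True),  # absent from reference panel
        ],
    )
    def test_rules(self, cls, cadd, af, kept):
        afs = {} if af is None else {"EUR": af}
        a = ann("11:121545392:G:A", cls=cls, cadd=cadd, ref_af_by_ancestry=afs)
        assert bool(filter_family_damaging([a], "EUR")) is kept

    def test_unknown_ancestry_rejected(self):
        with pytest.raises(ValueError, match="ancestry"):
            filter_family_damaging([], "KLINGON")

    def test_gene_restriction(self):
        a = ann("11:1:A:G", cadd=30, gene="SORL1")
        b = ann("1:1:A:G", cadd=30, gene="GBA1")
        assert filter_family_damaging([a, b], "EUR", gene="SORL1") == [a]


class TestFlagKnown:
    def test_known_and_novel_labels(self):
        vs = [
            type("V", (), {"variant_key": "1:1:A:G", "status": ""})(),
            type("V", (), {"variant_key": "1:2:A:G", "status": ""})(),
        ]
        flag_known(vs, ["1:1:A:G"])
        assert [v.status for v in vs] == ["known", "novel"]

    def test_duplicate_known_list_equivalent_to_set(self):
        a = type("V", (), {"variant_key": "1:1:A:G", "status": ""})()
        b = type("V", (), {"variant_key": "1:1:A:G", "status": ""})()
        flag_known([a], ["1:1:A:G", "1:1:A:G"])
        flag_known([b], ["1:1:A:G"])
        assert a.status == b.status == "known"
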
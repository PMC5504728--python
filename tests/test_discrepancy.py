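import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlacheck.allele_db import (
    UNKNOWN,
    AlleleDefinition,
    AlleleName,
    AlleleTable,
    SnpMarker,
    make_pair,
)
from hlacheck.discrepancy import (
    ExpectedGenotype,
    PairSearch,
    best_pairs,
    check_assignment,
    expected_genotype,
    marker_discrepancy,
    pair_discrepancy,
)
from hlacheck.genotype_io import GenotypePosterior, IndividualGenotypes
from hlacheck.synthetic import SimulationConfig, gen_allele_table, gen_population

from naive_oracle import naive_best_pairs, naive_pair_D


def _marker(mid="m1", pos=1, a="C", b="G"):
    return SnpMarker(id=mid, gene="HLA-A", cdna_pos=pos, strand="+",
                     alleleA=a, alleleB=b)


def _table(base_rows, markers):
    """base_rows: {allele short name: [base per marker]}"""
    alleles = tuple(
        AlleleDefinition(
            AlleleName.parse(name),
            {m.id: b for m, b in zip(markers, bases)},
        )
        for name, bases in base_rows.items()
    )
    return AlleleTable(gene="HLA-A", markers=tuple(markers), alleles=alleles)


class TestExpectedGenotype:
    @pytest.mark.parametrize(
        "b1, b2, expected",
        [
            ("G", "C", ExpectedGenotype.HET),       # the worked-example setup
            ("C", "C", ExpectedGenotype.HOM_A),
            ("G", "G", ExpectedGenotype.HOM_B),
            ("T", "C", ExpectedGenotype.IMPOSSIBLE),
            (UNKNOWN, "C", ExpectedGenotype.UNDEFINED),
            (UNKNOWN, "T", ExpectedGenotype.UNDEFINED),  # unknown wins over off-panel
        ],
    )
    def test_base_pair_maps_to_genotype_class(self, b1, b2, expected):
        m = _marker()
        t = _table({"A*01:01": [b1], "A*80:01": [b2]}, [m])
        pair = make_pair(AlleleName.parse("A*01:01"), AlleleName.parse("A*80:01"))
        assert expected_genotype(pair, m, t) is expected

    def test_symmetric_in_allele_order(self):
        m = _marker()
        t = _table({"A*01:01": ["G"], "A*80:01": ["C"]}, [m])
        a, b = AlleleName.parse("A*01:01"), AlleleName.parse("A*80:01")
        assert expected_genotype((a, b), m, t) is expected_genotype((b, a), m, t)

    def test_missing_allele_is_lookup_error(self):
        m = _marker()
        t = _table({"A*01:01": ["G"]}, [m])
        pair = (AlleleName.parse("A*01:01"), AlleleName.parse("A*99:99"))
        with pytest.raises(KeyError):
            expected_genotype(pair, m, t)


class TestMarkerDiscrepancy:
    def test_worked_example_heterozygote(self):
        # p(CC)=0.10, p(CG)=0.65, p(GG)=0.25 against an expected heterozygote
        post = GenotypePosterior(p_AA=0.10, p_AB=0.65, p_BB=0.25)
        assert marker_discrepancy(post, ExpectedGenotype.HET) == pytest.approx(0.35)

    @pytest.mark.parametrize("expected, s", [
        (ExpectedGenotype.HOM_A, 0.0),
        (ExpectedGenotype.HET, 1.0),
        (ExpectedGenotype.IMPOSSIBLE, 1.0),
        (ExpectedGenotype.UNDEFINED, 0.0),
    ])
    def test_degenerate_posterior(self, expected, s):
        post = GenotypePosterior(1.0, 0.0, 0.0)
        assert marker_discrepancy(post, expected) == s

    @given(
        p=st.lists(st.floats(0, 1), min_size=3, max_size=3).filter(
            lambda v: sum(v) <= 1.0),
        g=st.sampled_from([ExpectedGenotype.HOM_A, ExpectedGenotype.HET,
                           ExpectedGenotype.HOM_B, ExpectedGenotype.IMPOSSIBLE]),
    )
    @settings(derandomize=True, max_examples=100)
    def test_always_within_unit_interval(self, p, g):
        post = GenotypePosterior(*p)
        assert 0.0 <= marker_discrepancy(post, g) <= 1.0


class TestPairDiscrepancy:
    def test_worked_example_sums_to_035(self, worked_table, worked_individual):
        pair = make_pair(AlleleName.parse("A*01:01"), AlleleName.parse("A*80:01"))
        score = pair_discrepancy(worked_individual, pair, worked_table)
        assert score.D == pytest.approx(0.35)
        assert score.n_used == 1

    def test_certain_matching_posteriors_give_zero(self):
        markers = [_marker(f"m{i}", i) for i in (1, 2)]
        t = _table({"A*01:01": ["C", "G"], "A*02:01": ["G", "G"]}, markers)
        ind = IndividualGenotypes("i", {
            "m1": GenotypePosterior(0, 1, 0),   # C/G het
            "m2": GenotypePosterior(0, 0, 1),   # G/G hom
        })
        pair = make_pair(AlleleName.parse("A*01:01"), AlleleName.parse("A*02:01"))
        assert pair_discrepancy(ind, pair, t).D == 0.0

    def test_hand_summed_three_markers(self):
        # s per marker: 0.1, 0.0, 0.5 -> D = 0.6
        markers = [_marker(f"m{i}", i) for i in (1, 2, 3)]
        t = _table({"A*01:01": ["C", "G", "C"], "A*02:01": ["C", "G", "G"]}, markers)
        ind = IndividualGenotypes("i", {
            "m1": GenotypePosterior(0.9, 0.1, 0.0),
            "m2": GenotypePosterior(0.0, 0.0, 1.0),
            "m3": GenotypePosterior(0.3, 0.5, 0.2),
        })
        pair = make_pair(AlleleName.parse("A*01:01"), AlleleName.parse("A*02:01"))
        score = pair_discrepancy(ind, pair, t)
        assert score.D == pytest.approx(0.6)
        assert score.n_used == 3
        # cross-check against the independent per-marker recomputation
        a1, a2 = t.alleles
        assert naive_pair_D(ind, a1, a2, t)[0] == pytest.approx(score.D)

    def test_symmetry_in_pair_order(self):
        markers = [_marker(f"m{i}", i) for i in (1, 2)]
        t = _table({"A*01:01": ["C", "G"], "A*02:01": ["G", "C"]}, markers)
        ind = IndividualGenotypes("i", {
            "m1": GenotypePosterior(0.2, 0.3, 0.5),
            "m2": GenotypePosterior(0.6, 0.3, 0.1),
        })
        a, b = AlleleName.parse("A*01:01"), AlleleName.parse("A*02:01")
        assert pair_discrepancy(ind, (a, b), t).D == pair_discrepancy(ind, (b, a), t).D

    def test_additive_over_disjoint_marker_sets(self):
        markers = [_marker(f"m{i}", i) for i in (1, 2, 3, 4)]
        rows = {"A*01:01": ["C", "G", "C", "G"], "A*02:01": ["G", "G", "C", "C"]}
        t_all = _table(rows, markers)
        t_left = _table({k: v[:2] for k, v in rows.items()}, markers[:2])
        t_right = _table({k: v[2:] for k, v in rows.items()}, markers[2:])
        ind = IndividualGenotypes("i", {
            f"m{i}": GenotypePosterior(0.25, 0.5, 0.25) for i in (1, 2, 3, 4)})
        pair = make_pair(AlleleName.parse("A*01:01"), AlleleName.parse("A*02:01"))
        assert pair_discrepancy(ind, pair, t_all).D == pytest.approx(
            pair_discrepancy(ind, pair, t_left).D
            + pair_discrepancy(ind, pair, t_right).D
        )

    def test_undefined_markers_excluded_from_n_used(self):
        markers = [_marker(f"m{i}", i) for i in (1, 2)]
        t = _table({"A*01:01": ["C", UNKNOWN], "A*02:01": ["C", "G"]}, markers)
        ind = IndividualGenotypes("i", {
            "m1": GenotypePosterior(1, 0, 0),
            "m2": GenotypePosterior(1, 0, 0),
        })
        pair = make_pair(AlleleName.parse("A*01:01"), AlleleName.parse("A*02:01"))
        assert pair_discrepancy(ind, pair, t).n_used == 1

    def test_zero_usable_markers_is_flagged_not_zero(self):
        m = _marker()
        t = _table({"A*01:01": [UNKNOWN], "A*02:01": ["C"]}, [m])
        ind = IndividualGenotypes("i", {"m1": GenotypePosterior(1, 0, 0)})
        pair = make_pair(AlleleName.parse("A*01:01"), AlleleName.parse("A*02:01"))
        score = pair_discrepancy(ind, pair, t)
        assert not score.defined
        assert math.isnan(score.D)

    def test_monotone_in_posterior_mass_on_expected(self):
        # raising p(expected) at one marker can only lower D
        m = _marker()
        t = _table({"A*01:01": ["G"], "A*80:01": ["C"]}, [m])
        pair = make_pair(AlleleName.parse("A*01:01"), AlleleName.parse("A*80:01"))
        last = math.inf
        for p_het in np.linspace(0, 1, 11):
            ind = IndividualGenotypes("i", {
                "m1": GenotypePosterior(1 - p_het, p_het, 0.0)})
            D = pair_discrepancy(ind, pair, t).D
            assert D <= last + 1e-12
            last = D


def _random_instance(rng, n_alleles, n_markers, unknown_rate=0.15):
    cfg = SimulationConfig(
        n_alleles=n_alleles, n_markers=n_markers, unknown_rate=unknown_rate,
        n_individuals=1, noise=0.3, corrupt_frac=0.0,
        seed=int(rng.integers(2**31)),
    )
    table = gen_allele_table(cfg, rng)
    # posteriors deliberately arbitrary (not generated from any true pair)
    posteriors = {}
    for m in table.markers:
        raw = rng.dirichlet([1.0, 1.0, 1.0]) * rng.uniform(0.7, 1.0)
        posteriors[m.id] = GenotypePosterior(*raw)
    return table, IndividualGenotypes("i", posteriors)


class TestBestPairs:
    def test_single_allele_table_yields_its_homozygote(self):
        m = _marker()
        t = _table({"A*01:01": ["C"]}, [m])
        ind = IndividualGenotypes("i", {"m1": GenotypePosterior(0.5, 0.4, 0.1)})
        d_min, pairs = best_pairs(ind, t)
        a = AlleleName.parse("A*01:01")
        assert pairs == {make_pair(a, a)}
        assert d_min == pytest.approx(0.5)

    def test_noise_free_individual_recovers_true_pair(self):
        cfg = SimulationConfig(n_alleles=8, n_markers=10, unknown_rate=0.0,
                               n_individuals=20, noise=0.0, corrupt_frac=0.0, seed=3)
        table = gen_allele_table(cfg)
        cohort = gen_population(table, cfg)
        for ind, truth in zip(cohort.individuals, cohort.truth):
            d_min, pairs = best_pairs(ind, table)
            assert d_min == pytest.approx(0.0, abs=1e-12)
            assert truth.pair in pairs

    @pytest.mark.parametrize("n_alleles, n_markers", [(2, 2), (5, 8), (12, 15)])
    def test_matches_naive_enumeration(self, n_alleles, n_markers):
        rng = np.random.default_rng(n_alleles * 100 + n_markers)
        for _ in range(40):
            table, ind = _random_instance(rng, n_alleles, n_markers)
            d_vec, pairs_vec = best_pairs(ind, table)
            d_naive, pairs_naive = naive_best_pairs(ind, table)
            assert d_vec == pytest.approx(d_naive, abs=1e-12)
            assert pairs_vec == pairs_naive

    def test_vectorized_scores_equal_scalar_path_pairwise(self):
        rng = np.random.default_rng(99)
        table, ind = _random_instance(rng, 6, 9)
        search = PairSearch(table, min_coverage=0.0)
        D, n_used = search.score_all(ind)
        for k, (i, j) in enumerate(zip(search._ii, search._jj)):
            pair = make_pair(search.alleles[i].name, search.alleles[j].name)
            score = pair_discrepancy(ind, pair, table)
            if score.defined:
                assert D[k] == pytest.approx(score.D, abs=1e-12)
                assert n_used[k] == score.n_used

    def test_min_coverage_excludes_sparse_alleles(self):
        markers = [_marker(f"m{i}", i) for i in (1, 2)]
        t = _table({"A*01:01": ["C", "G"], "A*02:01": [UNKNOWN, UNKNOWN]}, markers)
        ind = IndividualGenotypes("i", {
            "m1": GenotypePosterior(1, 0, 0), "m2": GenotypePosterior(1, 0, 0)})
        _, pairs = best_pairs(ind, t, min_coverage=0.5)
        a = AlleleName.parse("A*01:01")
        assert pairs == {make_pair(a, a)}

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            PairSearch(AlleleTable(gene="HLA-A", markers=(), alleles=()))


class TestCheckAssignment:
    def test_attributed_in_best_pairs_gives_zero_delta(self, worked_table,
                                                       worked_individual):
        pair = make_pair(AlleleName.parse("A*01:01"), AlleleName.parse("A*80:01"))
        r = check_assignment(worked_individual, pair, worked_table)
        # with the single het-favoring marker, the het pair is the optimum
        assert r.D_attributed == pytest.approx(0.35)
        assert r.delta == 0.0
        assert pair in r.best_pairs
        assert r.status == "ok"

    def test_wrong_pair_delta_counts_informative_markers(self):
        # noise-free individual; attributed pair differs at k=2 markers where
        # each mismatch contributes s=1 against s=0 for the truth
        markers = [_marker(f"m{i}", i) for i in (1, 2, 3)]
        t = _table({"A*01:01": ["C", "C", "C"], "A*02:01": ["G", "G", "C"]}, markers)
        a1, a2 = AlleleName.parse("A*01:01"), AlleleName.parse("A*02:01")
        # truth (a1,a1): CC at all markers
        ind = IndividualGenotypes("i", {
            f"m{i}": GenotypePosterior(1, 0, 0) for i in (1, 2, 3)})
        r = check_assignment(ind, make_pair(a1, a2), t)
        assert r.delta == pytest.approx(2.0)

    def test_allele_absent_from_database_is_status_not_crash(self, worked_table,
                                                             worked_individual):
        pair = (AlleleName.parse("A*01:01"), AlleleName.parse("A*99:01"))
        r = check_assignment(worked_individual, pair, worked_table)
        assert r.status == "allele_not_in_db"
        assert math.isnan(r.delta)

    def test_delta_nonnegative_and_zero_iff_among_best(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            table, ind = _random_instance(rng, 6, 8, unknown_rate=0.0)
            names = [a.name for a in table.alleles]
            i, j = rng.integers(len(names), size=2)
            r = check_assignment(ind, make_pair(names[i], names[j]), table)
            assert r.delta >= 0.0
            assert (r.delta == 0.0) == (r.attributed in r.best_pairs)
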
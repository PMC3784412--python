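import itertools
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromnest.expression import pairwise_correlation
from chromnest.genome import GenomeAnnotation
from chromnest.neighborhoods import (
    SyntenyMap,
    anc,
    anc_null,
    best_tns_per_gene,
    enumerate_windows,
    isolated_genes,
    membership_excess_test,
    permutation_p,
    present_run_neighborhoods,
    score_windows,
    shared_fraction,
    synteny_score,
    tns,
)
from tests.conftest import make_gene, make_matrix


def _chain_annotation(n, chrom="chr1", gap=10_000):
    genes = [make_gene(f"g{i:02d}", chrom, i * gap, i * gap + 2_000) for i in range(n)]
    return GenomeAnnotation(genes)


class TestEnumerateWindows:
    def test_five_genes(self):
        ann = _chain_annotation(5)
        assert sum(1 for _ in enumerate_windows(ann)) == 4 + 3 + 2 + 1

    def test_single_gene(self):
        assert sum(1 for _ in enumerate_windows(_chain_annotation(1))) == 0

    def test_twelve_genes_matches_formula(self):
        ann = _chain_annotation(12)
        count = sum(1 for _ in enumerate_windows(ann))
        oracle = sum(max(0, 12 - k + 1) for k in range(2, 11))
        assert count == oracle == 63

    def test_min_k_below_two_errors(self):
        with pytest.raises(ValueError):
            list(enumerate_windows(_chain_annotation(5), min_k=1))

    def test_windows_never_cross_chromosomes(self):
        genes = [make_gene(f"a{i}", "chr1", i * 10_000, i * 10_000 + 100) for i in range(3)]
        genes += [make_gene(f"b{i}", "chr2", i * 10_000, i * 10_000 + 100) for i in range(3)]
        windows = list(enumerate_windows(GenomeAnnotation(genes)))
        for w in windows:
            assert len({g.interval.chrom for g in w}) == 1


class TestAnc:
    def test_pair_equals_single_correlation(self):
        m = make_matrix({"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5]})
        genes = [make_gene("a", "chr1", 0, 100), make_gene("b", "chr1", 200, 300)]
        assert anc(genes, m) == pytest.approx(pairwise_correlation(m, "a", "b"))

    def test_identical_profiles_give_one(self):
        m = make_matrix({g: [1, 2, 3, 4, 5] for g in "abc"})
        genes = [make_gene(g, "chr1", i * 200, i * 200 + 100) for i, g in enumerate("abc")]
        assert anc(genes, m) == pytest.approx(1.0)

    def test_four_genes_mean_of_six_pairs(self):
        rng = np.random.default_rng(0)
        data = {g: list(rng.normal(size=8)) for g in "abcd"}
        m = make_matrix(data)
        genes = [make_gene(g, "chr1", i * 200, i * 200 + 100) for i, g in enumerate("abcd")]
        oracle = np.mean(
            [pairwise_correlation(m, x, y) for x, y in itertools.combinations("abcd", 2)]
        )
        assert anc(genes, m) == pytest.approx(float(oracle))

    def test_unscorable_pair_flags_window(self):
        m = make_matrix({"a": [1, 1, 1, 1, 1], "b": [1, 2, 3, 4, 5]})
        genes = [make_gene("a", "chr1", 0, 100), make_gene("b", "chr1", 200, 300)]
        assert np.isnan(anc(genes, m))


def _smap(assignments, n_genomes):
    """assignments: genome index -> {gene_id: (block, order)}."""
    genomes = {f"gen{i}": assignments.get(i, {}) for i in range(n_genomes)}
    return SyntenyMap(genomes=genomes)


class TestSyntenyScore:
    def _genes(self, ids="abc"):
        return [make_gene(g, "chr1", i * 200, i * 200 + 100) for i, g in enumerate(ids)]

    def test_all_same_block_everywhere(self):
        genes = self._genes()
        smap = _smap({i: {g.gene_id: (1, j) for j, g in enumerate(genes)} for i in range(10)}, 10)
        assert synteny_score(genes, smap) == 1.0

    def test_half_of_genomes(self):
        genes = self._genes()
        good = {g.gene_id: (1, j) for j, g in enumerate(genes)}
        bad = {"a": (1, 0), "b": (2, 0), "c": (1, 1)}
        smap = _smap({i: (good if i < 5 else bad) for i in range(10)}, 10)
        assert synteny_score(genes, smap) == 0.5

    def test_missing_gene_breaks_synteny(self):
        genes = self._genes()
        partial = {"a": (1, 0), "b": (1, 1)}  # c missing
        smap = _smap({0: partial}, 1)
        assert synteny_score(genes, smap) == 0.0

    def test_randomized_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        genes = self._genes("abcde")
        for _ in range(20):
            assignments = {}
            for gi in range(6):
                mapping = {}
                for j, g in enumerate(genes):
                    if rng.random() < 0.9:
                        mapping[g.gene_id] = (int(rng.integers(0, 3)), j)
                assignments[gi] = mapping
            smap = _smap(assignments, 6)
            # exhaustive per-genome oracle
            kept = 0
            for mapping in smap.genomes.values():
                entries = [mapping.get(g.gene_id) for g in genes]
                if all(e is not None for e in entries) and len({b for b, _ in entries}) == 1:
                    kept += 1
            assert synteny_score(genes, smap) == pytest.approx(kept / 6)

    def test_strict_order_mode(self):
        genes = self._genes()
        shuffled = {"a": (1, 0), "b": (1, 2), "c": (1, 1)}  # same block, scrambled
        smap = _smap({0: shuffled}, 1)
        assert synteny_score(genes, smap) == 1.0
        assert synteny_score(genes, smap, strict_order=True) == 0.0

    def test_monotone_under_subwindows(self):
        """SS of a window never exceeds SS of any contiguous sub-window."""
        rng = np.random.default_rng(7)
        genes = self._genes("abcdef")
        for _ in range(10):
            assignments = {
                gi: {
                    g.gene_id: (int(rng.integers(0, 3)), j)
                    for j, g in enumerate(genes)
                    if rng.random() < 0.85
                }
                for gi in range(5)
            }
            smap = _smap(assignments, 5)
            full = synteny_score(genes, smap)
            for i in range(len(genes) - 1):
                for j in range(i + 2, len(genes) + 1):
                    assert full <= synteny_score(genes[i:j], smap) + 1e-12


class TestTns:
    def test_formula(self):
        assert tns(1.0, 0.7, 0.001) == pytest.approx(0.7)

    def test_p_above_alpha_scores_zero(self):
        assert tns(0.9, 1.0, 0.06) == 0.0

    def test_negative_anc_scores_zero(self):
        assert tns(-0.4, 1.0, 0.01) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(
        anc_v=st.floats(-1, 1), ss=st.floats(0, 1), p=st.floats(0, 1),
    )
    def test_always_in_unit_interval(self, anc_v, ss, p):
        t = tns(anc_v, ss, p)
        assert 0.0 <= t <= 1.0
        if p > 0.05:
            assert t == 0.0


class TestAncNull:
    def test_plus_one_rule(self):
        null = np.linspace(-0.5, 0.5, 999)
        assert permutation_p(0.9, null) == pytest.approx(1 / 1000)

    def test_exhaustive_small_genome(self):
        rng = np.random.default_rng(8)
        ann = _chain_annotation(3)
        m = make_matrix({g.gene_id: list(rng.normal(size=6)) for g in ann})
        null = anc_null(m, ann, k=2, exhaustive=True)
        # oracle: enumerate all 3! placements, windows = adjacent pairs
        ids = [g.gene_id for g in ann]
        corr = {
            frozenset((a, b)): pairwise_correlation(m, a, b)
            for a, b in itertools.combinations(ids, 2)
        }
        oracle = []
        for perm in itertools.permutations(ids):
            oracle.append(corr[frozenset((perm[0], perm[1]))])
            oracle.append(corr[frozenset((perm[1], perm[2]))])
        assert sorted(null) == pytest.approx(sorted(oracle))

    def test_null_calibration_small(self):
        """i.i.d. profiles: ~5% of windows get p <= 0.05."""
        from chromnest import simulate as sim

        ann = sim.simulate_genome(n_genes=600, n_chroms=2, seed=21)
        truth = sim.SyntheticTruth(seed=21, decay_c=0.0)
        expr = sim.simulate_expression(ann, truth, seed=22)
        smap = sim.simulate_synteny(ann, truth, seed=23)
        scored = score_windows(ann, expr, smap, min_k=3, max_k=3, n_perm=300, seed=24)
        frac = (scored["p"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(scored))
        assert abs(frac - 0.05) < 3 * se


class TestScoreWindows:
    def test_consistent_with_per_window_functions(self, small_bundle):
        ann, truth, expr, smap, marks = small_bundle
        scored = score_windows(ann, expr, smap, min_k=2, max_k=4, n_perm=100, seed=5)
        rng = np.random.default_rng(0)
        sample = scored.sample(20, random_state=1)
        by_id = {g.gene_id: g for g in ann}
        for row in sample.itertuples(index=False):
            genes = [by_id[g] for g in row.gene_ids]
            assert row.ANC == pytest.approx(anc(genes, expr), abs=1e-9, nan_ok=True)
            assert row.SS == pytest.approx(synteny_score(genes, smap))

    def test_planted_neighborhoods_recovered(self, small_bundle):
        ann, truth, expr, smap, marks = small_bundle
        scored = score_windows(ann, expr, smap, n_perm=200, seed=6)
        plant_keys = [tuple(p["gene_ids"]) for p in truth.planted_neighborhoods]
        mask = scored["gene_ids"].isin(plant_keys)
        assert mask.sum() == len(plant_keys)
        assert (scored.loc[mask, "TNS"] >= 0.4).all()

    def test_best_tns_per_gene(self, small_bundle):
        ann, truth, expr, smap, marks = small_bundle
        scored = score_windows(ann, expr, smap, min_k=2, max_k=3, n_perm=100, seed=7)
        best = best_tns_per_gene(scored, ann)
        # brute-force oracle over the table
        oracle: dict[str, float] = {g.gene_id: 0.0 for g in ann}
        for gids, t in zip(scored["gene_ids"], scored["TNS"]):
            if np.isnan(t):
                continue
            for g in gids:
                oracle[g] = max(oracle[g], t)
        pd.testing.assert_series_equal(best, pd.Series(oracle, name="best_TNS"))

    def test_best_tns_simple_max_and_singleton(self):
        scored = pd.DataFrame(
            {
                "gene_ids": [("a", "b"), ("a", "b", "c"), ("b", "c")],
                "TNS": [0.0, 0.3, 0.69],
            }
        )
        genes = [make_gene(g, "chr1", i * 1000, i * 1000 + 100) for i, g in enumerate("abc")]
        genes.append(make_gene("lonely", "chr2", 0, 100))
        best = best_tns_per_gene(scored, GenomeAnnotation(genes))
        assert best["b"] == pytest.approx(0.69)
        assert best["a"] == pytest.approx(0.3)
        assert best["lonely"] == 0.0


def _flags_series(ann, pattern):
    return pd.Series({g.gene_id: bool(int(c)) for g, c in zip(ann, pattern)})


class TestRunsAndIsolated:
    def test_run_pattern(self):
        ann = _chain_annotation(6)
        runs = present_run_neighborhoods(_flags_series(ann, "110111"), ann)
        assert [r["gene_ids"] for r in runs] == [("g00", "g01"), ("g03", "g04", "g05")]
        assert runs[0]["n_genes"] == 2

    def test_no_expression_no_runs(self):
        ann = _chain_annotation(4)
        assert present_run_neighborhoods(_flags_series(ann, "0000"), ann) == []

    def test_isolated_middle(self):
        ann = _chain_annotation(3)
        assert isolated_genes(_flags_series(ann, "010"), ann) == ["g01"]

    def test_adjacent_pair_not_isolated(self):
        ann = _chain_annotation(2)
        assert isolated_genes(_flags_series(ann, "11"), ann) == []

    def test_chromosome_end_single_flank(self):
        ann = _chain_annotation(3)
        assert isolated_genes(_flags_series(ann, "100"), ann) == ["g00"]

    @pytest.mark.parametrize("seed", range(4))
    def test_random_patterns_match_regex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        ann = _chain_annotation(n)
        pattern = "".join(str(int(b)) for b in rng.random(n) < 0.4)
        flags = _flags_series(ann, pattern)
        runs = present_run_neighborhoods(flags, ann)
        oracle_runs = [m for m in re.finditer(r"1{2,}", pattern)]
        assert len(runs) == len(oracle_runs)
        for r, m in zip(runs, oracle_runs):
            assert r["gene_ids"] == tuple(f"g{i:02d}" for i in range(m.start(), m.end()))
        iso = isolated_genes(flags, ann)
        oracle_iso = [
            f"g{m.start(1):02d}" for m in re.finditer(r"(?:^|0)(1)(?=0|$)", pattern)
        ]
        assert iso == oracle_iso


class TestSharedFraction:
    def _runs(self):
        return [
            {"gene_ids": ("a", "b")},
            {"gene_ids": ("c", "d")},
            {"gene_ids": ("e", "f")},
        ]

    def test_everything_expressed(self):
        calls = pd.Series({g: True for g in "abcdef"})
        assert shared_fraction(self._runs(), calls) == 100.0

    def test_nothing_expressed(self):
        calls = pd.Series({g: False for g in "abcdef"})
        assert shared_fraction(self._runs(), calls) == 0.0

    def test_two_of_three(self):
        calls = pd.Series({"a": True, "b": True, "c": True, "d": True, "e": True, "f": False})
        assert shared_fraction(self._runs(), calls) == pytest.approx(200 / 3)


class TestMembershipExcess:
    def test_all_expressed_p_one(self):
        ann = _chain_annotation(8)
        out = membership_excess_test(_flags_series(ann, "1" * 8), ann, n_perm=100, seed=0)
        assert out["observed_in_run"] == 8
        assert out["p_in_run"] == 1.0

    def test_planted_clustering_small_p(self):
        ann = _chain_annotation(40)
        pattern = "1" * 12 + "0" * 28  # strongly clustered expressed genes
        out = membership_excess_test(_flags_series(ann, pattern), ann, n_perm=400, seed=1)
        assert out["p_in_run"] < 0.05
        assert out["p_isolated"] < 0.05

    def test_exhaustive_matches_enumeration(self):
        ann = _chain_annotation(6)
        flags = _flags_series(ann, "110100")
        out = membership_excess_test(flags, ann, exhaustive=True)
        # independent enumeration oracle
        arr = np.array([1, 1, 0, 1, 0, 0], dtype=bool)
        def stat(f):
            in_run = sum(
                f[i] and ((i > 0 and f[i - 1]) or (i < 5 and f[i + 1])) for i in range(6)
            )
            iso = sum(
                f[i] and not ((i > 0 and f[i - 1]) or (i < 5 and f[i + 1])) for i in range(6)
            )
            return in_run, iso
        obs_run, obs_iso = stat(arr)
        ge = le = total = 0
        for ones in itertools.combinations(range(6), int(arr.sum())):
            f = np.zeros(6, dtype=bool)
            f[list(ones)] = True
            r, s = stat(f)
            ge += r >= obs_run
            le += s <= obs_iso
            total += 1
        assert out["p_in_run"] == pytest.approx(ge / total)
        assert out["p_isolated"] == pytest.approx(le / total)
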
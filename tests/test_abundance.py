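"""Relative abundance, ratios, Spearman/BH oracles and presence calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gvmine import abundance as ab
from gvmine import simulate as sim


def coverage_frame(rows):
    return pd.DataFrame(rows, columns=["scaffold_id", "sample_id", "mean_coverage"])


class TestRelativeAbundance:
    def test_single_group_normalizes_to_one(self):
        cov = coverage_frame([("sc1", "A", 30.0), ("sc2", "A", 70.0)])
        m = ab.relative_abundance(cov, {"sc1": "g", "sc2": "g"}, {"sc1": 20000, "sc2": 15000})
        assert m.loc["A", "g"] == pytest.approx(1.0)

    def test_two_groups_direct_ratio(self):
        cov = coverage_frame([("sc1", "A", 30.0), ("sc2", "A", 70.0)])
        m = ab.relative_abundance(cov, {"sc1": "x", "sc2": "y"}, {"sc1": 20000, "sc2": 15000})
        assert m.loc["A", "x"] == pytest.approx(0.3)
        assert m.loc["A", "y"] == pytest.approx(0.7)

    def test_short_scaffold_enters_neither_side(self):
        cov = coverage_frame([("sc1", "A", 30.0), ("short", "A", 1000.0)])
        m = ab.relative_abundance(
            cov, {"sc1": "x", "short": "x"}, {"sc1": 20000, "short": 9999}
        )
        assert m.loc["A", "x"] == pytest.approx(1.0)

    def test_unassigned_scaffold_dilutes_denominator(self):
        cov = coverage_frame([("sc1", "A", 25.0), ("sc2", "A", 75.0)])
        m = ab.relative_abundance(cov, {"sc1": "x"}, {"sc1": 20000, "sc2": 20000})
        assert m.loc["A", "x"] == pytest.approx(0.25)

    def test_rows_sum_to_one_over_exhaustive_groups(self):
        rng = np.random.default_rng(0)
        rows, tax, lengths = [], {}, {}
        for s in "ABC":
            for i in range(30):
                sid = f"sc{i}"
                rows.append((sid, s, float(rng.uniform(0.1, 50))))
                tax[sid] = f"g{i % 4}"
                lengths[sid] = 15000
        m = ab.relative_abundance(coverage_frame(rows), tax, lengths)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_denominator_is_an_error(self):
        cov = coverage_frame([("sc1", "A", 0.0)])
        with pytest.raises(ValueError, match="zero total coverage"):
            ab.relative_abundance(cov, {"sc1": "x"}, {"sc1": 20000})


class TestGroupRatio:
    def test_equal_abundances_ratio_one_sd_zero(self):
        m = pd.DataFrame({"v": [0.2, 0.3, 0.1], "e": [0.2, 0.3, 0.1]}, index=list("ABC"))
        r = ab.group_ratio(m, "v", "e")
        assert (r.per_sample == 1.0).all()
        assert r.mean == pytest.approx(1.0) and r.sd == pytest.approx(0.0)

    def test_zero_denominator_sample_excluded_and_flagged(self):
        m = pd.DataFrame({"v": [0.4, 0.2], "e": [0.1, 0.0]}, index=["A", "B"])
        r = ab.group_ratio(m, "v", "e")
        assert r.excluded == ["B"]
        assert list(r.per_sample.index) == ["A"]

    def test_mean_sd_match_hand_computation(self):
        m = pd.DataFrame({"v": [0.4, 0.6, 0.9], "e": [0.1, 0.2, 0.3]}, index=list("ABC"))
        r = ab.group_ratio(m, "v", "e")
        ratios = np.array([4.0, 3.0, 3.0])
        assert r.mean == pytest.approx(ratios.mean())
        assert r.sd == pytest.approx(ratios.std(ddof=1))


def midrank(x):
    """Hand-rolled midranks (average rank for ties)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestSpearman:
    @pytest.mark.parametrize("seed", range(25))
    def test_rho_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        x = rng.integers(0, 10, size=n).astype(float)  # plenty of ties
        y = rng.integers(0, 10, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho, _ = ab.spearman_with_p(x, y, method="t")
        oracle = np.corrcoef(midrank(x), midrank(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_p_matches_enumeration_oracle(self):
        # independent full enumeration: hand-rolled midranks and Pearson via
        # np.corrcoef for every pairing of the two vectors
        import itertools

        rng = np.random.default_rng(3)
        for n in (5, 6, 7):
            x = rng.integers(0, 5, size=n).astype(float)  # ties on purpose
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            _, p = ab.spearman_with_p(x, y, method="exact")
            rx, ry = midrank(x), midrank(y)
            observed = abs(np.corrcoef(rx, ry)[0, 1])
            hits = total = 0
            for perm in itertools.permutations(range(n)):
                total += 1
                if abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= observed - 1e-12:
                    hits += 1
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_auto_picks_exact_below_ten(self):
        x = np.arange(8.0)
        y = np.array([1.0, 0, 2, 4, 3, 5, 7, 6])
        rho_a, p_a = ab.spearman_with_p(x, y, method="auto")
        rho_e, p_e = ab.spearman_with_p(x, y, method="exact")
        assert (rho_a, p_a) == (rho_e, p_e)

    def test_constant_vector_gives_nan(self):
        rho, p = ab.spearman_with_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


def bh_oracle(p):
    """Step-up BH by the textbook formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = ab.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 60)))
        assert np.allclose(ab.benjamini_hochberg(p), bh_oracle(p))

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        q = ab.benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        perm = rng.permutation(30)
        assert np.allclose(ab.benjamini_hochberg(p[perm]), q[perm])
        assert (q >= p - 1e-15).all()


class TestCooccurrence:
    def make_matrix(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.lognormal(size=(11, 4)), columns=["v1", "v2", "e1", "e2"],
            index=[f"s{i}" for i in range(11)],
        )
        m["v1"] = m["e1"] * 2  # identical ranks
        return m

    def test_identical_vectors_rho_one(self):
        m = self.make_matrix()
        res = ab.cooccurrence(m, ["v1"], ["e1"])
        assert res.loc[0, "rho"] == pytest.approx(1.0)

    def test_rare_taxon_not_tested(self):
        m = self.make_matrix()
        m["v2"] = 0.0
        m.loc["s0", "v2"] = 5.0  # present in exactly one sample
        res = ab.cooccurrence(m, ["v2"], ["e1"])
        assert not res.loc[0, "tested"]
        assert np.isnan(res.loc[0, "rho"])

    def test_constant_vector_flagged_and_excluded_from_family(self):
        m = self.make_matrix()
        m["v2"] = 3.0  # constant but present everywhere
        res = ab.cooccurrence(m, ["v1", "v2"], ["e1"], method="t")
        const = res[res["virus"] == "v2"].iloc[0]
        assert const["tested"] and const["note"] == "constant abundance vector"
        assert np.isnan(const["q_value"])
        tested_q = res[res["virus"] == "v1"]["q_value"]
        assert tested_q.notna().all()

    def test_bh_family_spans_all_tested_pairs(self):
        m = self.make_matrix()
        res = ab.cooccurrence(m, ["v1", "v2"], ["e1", "e2"], method="t")
        family = res[res["tested"] & res["p_value"].notna()]
        assert np.allclose(
            family["q_value"], bh_oracle(family["p_value"].to_numpy())
        )

    def test_planted_pairs_rank_first_by_q(self):
        # at strength 0.9 and 11 samples the planted pair should sort at the
        # top of the q-value ranking (BH step-up routinely ties top q-values,
        # so a tie still counts as top rank) in at least 95% of seeds
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            m = sim.simulate_abundance_matrix(
                ["v1", "v2", "v3", "e1", "e2", "e3"],
                planted_pairs=[("v1", "e1", 0.9)],
                seed=seed,
            )
            res = ab.cooccurrence(m, ["v1", "v2", "v3"], ["e1", "e2", "e3"], method="t")
            res = res.set_index(["virus", "eukaryote"])
            planted = res.loc[("v1", "e1")]
            others = res.drop(index=("v1", "e1"))
            if (planted["q_value"] <= others["q_value"]).all():
                wins += 1
        assert wins / n_seeds >= 0.95


class TestPresence:
    def test_strict_boundary_at_10kb_covered(self):
        covered = pd.DataFrame(
            {
                "scaffold_id": ["sc1", "sc2", "sc3"],
                "sample_id": ["A", "A", "A"],
                "covered_length": [10_000, 10_001, 50_000],
            }
        )
        calls, sharing = ab.presence_calls(covered)
        assert list(calls["present"]) == [False, True, True]
        assert sharing.loc["A", "A"] == 2

    def test_sharing_counts_scaffolds_in_both_samples(self):
        covered = pd.DataFrame(
            {
                "scaffold_id": ["sc1", "sc1", "sc2", "sc3"],
                "sample_id": ["A", "B", "A", "B"],
                "covered_length": [20_000, 15_000, 30_000, 12_000],
            }
        )
        calls, sharing = ab.presence_calls(covered)
        assert sharing.loc["A", "B"] == 1  # only sc1 is shared
        assert sharing.loc["A", "A"] == 2 and sharing.loc["B", "B"] == 2

    def test_sample_specific_scaffold_contributes_zero_off_diagonal(self):
        covered = pd.DataFrame(
            {
                "scaffold_id": ["sc1", "sc2"],
                "sample_id": ["A", "B"],
                "covered_length": [20_000, 20_000],
            }
        )
        _, sharing = ab.presence_calls(covered)
        assert sharing.loc["A", "B"] == 0
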
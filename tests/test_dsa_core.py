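"""DSA statistics: distance vectors, scores, ranking, cumulative ratios."""

import numpy as np
import pandas as pd
import pytest

from distscore import (
    DataError,
    SyntheticSpec,
    chain_distance_vector,
    cumulative_ratio,
    enumerate_pairs,
    make_ensemble,
    pair_statistics,
    rank_pairs,
    score_distance_table,
)

from conftest import make_bundle, make_chain, random_rotation


def brute_force_distances(coords, present):
    """Independent O(N²) double-loop oracle in canonical (i<j) order."""
    n = len(coords)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if present[i] and present[j]:
                out.append(float(np.sqrt(np.sum((coords[i] - coords[j]) ** 2))))
            else:
                out.append(np.nan)
    return np.array(out)


def toy_ensemble_from_distances(distances):
    """Chains of one 2-residue helix whose single pair realises each distance."""
    bundle = make_bundle([2])
    return [
        make_chain([[0.0, 0.0, 0.0], [d, 0.0, 0.0]], bundle, structure_id=f"c{k}")
        for k, d in enumerate(distances)
    ]


class TestDistanceVector:
    def test_3_4_5_triangle(self):
        bundle = make_bundle([2])
        chain = make_chain([[0, 0, 0], [3, 4, 0]], bundle)
        vec = chain_distance_vector(chain, enumerate_pairs(bundle))
        assert vec.shape == (1,)
        assert vec[0] == pytest.approx(5.0)

    def test_full_bundle_has_14365_defined_entries(self):
        ens = make_ensemble(SyntheticSpec(seed=0, n_chains=2))
        vec = chain_distance_vector(ens[0], enumerate_pairs(ens[0].bundle))
        assert vec.shape == (14365,)
        assert np.isfinite(vec).sum() == 14365

    def test_matches_brute_force_with_masking(self):
        rng = np.random.default_rng(11)
        bundle = make_bundle([4, 3, 3])
        coords = rng.normal(size=(10, 3)) * 5
        present = np.ones(10, dtype=bool)
        present[[2, 7]] = False
        chain = make_chain(coords, bundle, present=present)
        vec = chain_distance_vector(chain, enumerate_pairs(bundle))
        oracle = brute_force_distances(np.where(present[:, None], coords, np.nan), present)
        np.testing.assert_allclose(vec, oracle, rtol=1e-12, equal_nan=True)


class TestPairStatistics:
    def test_hand_computed_three_chain_toy(self):
        """Distances {4, 5, 6} Å: mean 5, population std √(2/3), score 6.1237."""
        stats = pair_statistics(toy_ensemble_from_distances([4.0, 5.0, 6.0]))
        row = stats.iloc[0]
        assert row["n_chains"] == 3
        assert row["mean"] == pytest.approx(5.0)
        assert row["std"] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert row["score"] == pytest.approx(5.0 / np.sqrt(2.0 / 3.0))
        assert row["score"] == pytest.approx(6.1237, abs=1e-4)

    def test_sample_convention_is_switchable(self):
        stats = pair_statistics(
            toy_ensemble_from_distances([4.0, 5.0, 6.0]), std_convention="sample"
        )
        assert stats.iloc[0]["std"] == pytest.approx(1.0)
        assert stats.iloc[0]["score"] == pytest.approx(5.0)

    def test_identical_chains_score_infinite(self):
        ens = make_ensemble(SyntheticSpec(seed=5, n_chains=4, noise_sigma=0.0))
        stats = pair_statistics(ens)
        assert (stats["std"] == 0).all()
        assert np.isinf(stats["score"]).all()

    def test_isometry_invariance(self):
        """Arbitrary per-chain rigid motions leave every statistic unchanged."""
        rng = np.random.default_rng(2)
        ens = make_ensemble(SyntheticSpec(seed=2, n_chains=5, helix_lengths=(6, 5, 4)))
        moved = [
            c.transformed(random_rotation(rng), rng.uniform(-30, 30, 3)) for c in ens
        ]
        a, b = pair_statistics(ens), pair_statistics(moved)
        for col in ("mean", "std", "score"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-9)

    def test_scale_behaviour(self):
        """Scaling coordinates by c scales mean and std by c; scores unchanged."""
        ens = make_ensemble(SyntheticSpec(seed=9, n_chains=4, helix_lengths=(5, 5)))
        c = 2.75
        scaled = [
            make_chain(ch.coords * c, ch.bundle, ch.present.copy(), ch.structure_id)
            for ch in ens
        ]
        a, b = pair_statistics(ens), pair_statistics(scaled)
        np.testing.assert_allclose(b["mean"], a["mean"] * c, rtol=1e-12)
        np.testing.assert_allclose(b["std"], a["std"] * c, rtol=1e-9)
        np.testing.assert_allclose(b["score"], a["score"], rtol=1e-9)

    def test_oracle_equivalence_small_ensembles(self):
        """Naive per-pair loop agrees with the vectorised path to 1e-9 relative."""
        rng = np.random.default_rng(21)
        bundle = make_bundle([5, 5, 5])
        pairs = enumerate_pairs(bundle)
        ens = []
        for k in range(5):
            present = rng.random(15) > 0.1
            coords = rng.normal(size=(15, 3)) * 8
            ens.append(make_chain(coords, bundle, present=present, structure_id=f"c{k}"))
        stats = pair_statistics(ens, min_chains=2)
        dmats = [
            brute_force_distances(np.where(c.present[:, None], c.coords, np.nan), c.present)
            for c in ens
        ]
        for k in range(len(pairs)):
            vals = np.array([d[k] for d in dmats])
            vals = vals[~np.isnan(vals)]
            row = stats.iloc[k]
            assert row["n_chains"] == len(vals)
            if len(vals) < 2:
                continue
            assert row["mean"] == pytest.approx(vals.mean(), rel=1e-9)
            assert row["std"] == pytest.approx(vals.std(), rel=1e-9, abs=1e-12)

    def test_min_chains_flags_scores_undefined(self):
        bundle = make_bundle([3])
        ens = []
        for k in range(4):
            present = np.array([True, True, k < 2])  # last residue in only 2 chains
            coords = np.arange(9, dtype=float).reshape(3, 3) + k
            ens.append(make_chain(coords, bundle, present=present, structure_id=f"c{k}"))
        stats = pair_statistics(ens, min_chains=3)
        by_pair = stats.set_index(["label_i", "label_j"])["score"]
        assert np.isnan(by_pair.loc[("1.49", "1.51")])
        assert np.isnan(by_pair.loc[("1.50", "1.51")])
        assert not np.isnan(by_pair.loc[("1.49", "1.50")])

    def test_requires_two_chains_and_matching_bundles(self):
        ens = toy_ensemble_from_distances([4.0])
        with pytest.raises(DataError, match="2 chains"):
            pair_statistics(ens)
        other = make_chain(np.zeros((3, 3)), make_bundle([3]), structure_id="odd")
        with pytest.raises(DataError, match="bundle"):
            pair_statistics(toy_ensemble_from_distances([4.0, 5.0]) + [other])


class TestRanking:
    def test_tie_break_by_canonical_pair_order(self):
        stats = pd.DataFrame(
            {
                "pair_index": [0, 1, 2, 3],
                "label_i": ["p"] * 4,
                "label_j": ["q"] * 4,
                "kind": ["intra"] * 4,
                "group": ["A"] * 4,
                "n_chains": [3] * 4,
                "mean": [1.0] * 4,
                "std": [0.1] * 4,
                "score": [2.0, 9.0, 9.0, 1.0],
            }
        )
        ranked = rank_pairs(stats)
        assert ranked["pair_index"].tolist() == [1, 2, 0, 3]
        assert ranked["rank"].tolist() == [1, 2, 3, 4]

    def test_all_identical_ensemble_ranks_in_canonical_order(self):
        ens = make_ensemble(SyntheticSpec(seed=4, n_chains=3, noise_sigma=0.0,
                                          helix_lengths=(4, 4)))
        ranked = rank_pairs(pair_statistics(ens))
        assert ranked["pair_index"].tolist() == list(range(len(ranked)))
        assert np.isinf(ranked["score"]).all()

    def test_matches_brute_force_sort_oracle(self):
        ens = make_ensemble(SyntheticSpec(seed=17, n_chains=4, helix_lengths=(10, 10)))
        stats = pair_statistics(ens)
        ranked = rank_pairs(stats)
        oracle = sorted(
            stats.itertuples(), key=lambda r: (-r.score, r.pair_index)
        )
        assert ranked["pair_index"].tolist() == [r.pair_index for r in oracle]

    def test_undefined_scores_excluded(self):
        stats = pair_statistics(toy_ensemble_from_distances([4.0, 5.0]), min_chains=3)
        assert np.isnan(stats["score"]).all()
        assert len(rank_pairs(stats)) == 0


class TestCumulativeRatio:
    def ranked_toy(self):
        """12 ranked pairs: group A at ranks 1–3, B at 4–9, C at 10–12."""
        groups = ["A"] * 3 + ["B"] * 6 + ["C"] * 3
        df = pd.DataFrame(
            {
                "rank": np.arange(1, 13),
                "pair_index": np.arange(12),
                "group": groups,
                "score": np.linspace(10, 1, 12),
                "kind": ["intra"] * 12,
            }
        )
        return df

    def test_block_occupancy_curve(self):
        curves = cumulative_ratio(self.ranked_toy(), top_n=12)
        assert curves.loc[3, "A"] == pytest.approx(1.0)
        assert (curves["A"].loc[3:] == 1.0).all()
        assert curves.loc[9, "B"] == pytest.approx(1.0)
        assert curves.loc[5, "B"] == pytest.approx(2 / 6)

    def test_partition_property(self):
        """Raw top-r counts across groups sum to r at every rank."""
        ranked = self.ranked_toy()
        curves = cumulative_ratio(ranked, top_n=12)
        totals = ranked["group"].value_counts()
        raw = curves * totals[curves.columns]
        np.testing.assert_allclose(raw.sum(axis=1), np.arange(1, 13))

    def test_monotone_and_bounded(self):
        curves = cumulative_ratio(self.ranked_toy(), top_n=10)
        arr = curves.to_numpy()
        assert (np.diff(arr, axis=0) >= 0).all()
        assert (arr >= 0).all() and (arr <= 1).all()

    def test_grand_total_denominator(self):
        curves = cumulative_ratio(self.ranked_toy(), top_n=12, denominator="grand")
        np.testing.assert_allclose(curves.sum(axis=1), np.arange(1, 13) / 12)

    def test_empty_group_warns_and_is_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="distscore"):
            curves = cumulative_ratio(self.ranked_toy(), top_n=5, groups=["A", "Z"])
        assert (curves["Z"] == 0).all()
        assert "empty" in caplog.text

    def test_quiet_helix_dominates_top_ranks(self):
        """Reducing helix B's jitter pushes its pairs up the intrahelical ranking."""
        spec = SyntheticSpec(seed=31, n_chains=8,
                             noise_sigma={"A": 0.5, "B": 0.1, "C": 0.5, "D": 0.5,
                                          "E": 0.5, "F": 0.5, "G": 0.5})
        stats = pair_statistics(make_ensemble(spec))
        intra = stats[stats["kind"] == "intra"]
        ranked = rank_pairs(intra)
        curves = cumulative_ratio(ranked, top_n=1000)
        assert curves.loc[1000, "B"] > curves.loc[1000, "A"]
        assert curves.loc[1000, "B"] > curves.loc[1000, "C"]

    def test_top_n_validation(self):
        with pytest.raises(DataError):
            cumulative_ratio(self.ranked_toy(), top_n=13)


class TestScoreDistanceTable:
    def test_two_chain_toy_values(self):
        stats = pair_statistics(toy_ensemble_from_distances([4.0, 6.0]), min_chains=2)
        table = score_distance_table(stats)
        assert len(table) == 1
        assert table.iloc[0]["mean"] == pytest.approx(5.0)
        assert table.iloc[0]["score"] == pytest.approx(5.0)  # mean 5, pop std 1

    def test_row_count_excludes_undefined(self):
        ens = make_ensemble(SyntheticSpec(seed=8, n_chains=4))
        stats = pair_statistics(ens)
        assert len(score_distance_table(stats)) == 14365
        stats.loc[0, "score"] = np.nan
        assert len(score_distance_table(stats)) == 14364

    def test_empty_input_no_crash(self):
        ens = make_ensemble(SyntheticSpec(seed=8, n_chains=2, helix_lengths=(2,)))
        stats = pair_statistics(ens, min_chains=3)  # undefined everywhere
        table = score_distance_table(stats)
        assert len(table) == 0
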
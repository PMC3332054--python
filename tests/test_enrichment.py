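"""Gene-set over-representation, GMT parsing and TF/target circuits."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import rasosig as rs


def enumerate_hypergeom_p(M, K, N, k):
    """P(overlap >= k) by exhaustive enumeration of all C(M, N) draws."""
    universe = range(M)
    special = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, N):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def enumerate_binomial_two_sided_p(k, n):
    """Two-sided exact binomial p at p0=0.5 by enumerating all 2^n outcomes."""
    pk = math.comb(n, k)
    return sum(math.comb(n, j) for j in range(n + 1)
               if math.comb(n, j) <= pk) / 2**n


def make_collection(sets, universe=None):
    return rs.GeneSetCollection("toy", sets, universe)


class TestReadGmt:
    def test_parse_and_universe_union(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg3\tg4\n")
        coll = rs.read_gmt(p)
        assert coll.sets == {"setA": ["g1", "g2", "g3"], "setB": ["g3", "g4"]}
        assert sorted(coll.universe) == ["g1", "g2", "g3", "g4"]

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("setA\tdesc\tg1\nsetB_only_name\n")
        with pytest.raises(ValueError, match="bad.gmt:2"):
            rs.read_gmt(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.gmt"
        p.write_text("")
        with pytest.raises(ValueError, match="no gene sets"):
            rs.read_gmt(p)

    def test_roundtrip(self, tmp_path):
        coll = make_collection({"a": ["g1", "g2"], "b": ["g2", "g3", "g4"]})
        rs.write_gmt(coll, tmp_path / "out.gmt")
        back = rs.read_gmt(tmp_path / "out.gmt", name="toy")
        assert back.sets == coll.sets
        assert sorted(back.universe) == sorted(coll.universe)

    def test_duplicates_within_set_deduplicated(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg1\n")
        assert rs.read_gmt(p).sets["setA"] == ["g1", "g2"]


class TestHypergeomEnrich:
    def test_matches_exhaustive_enumeration_example(self):
        """Universe 20, set 5, signature 4, overlap 3."""
        universe = [f"g{i}" for i in range(20)]
        coll = make_collection({"s": universe[:5]}, universe)
        signature = universe[:3] + [universe[10]]
        res = rs.hypergeom_enrich(signature, coll, max_p=1.1)
        expected = enumerate_hypergeom_p(20, 5, 4, 3)
        assert res[0].p == pytest.approx(expected)
        assert res[0].p == pytest.approx(0.03199, abs=5e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_on_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(6, 20))
        K = int(rng.integers(1, M))
        N = int(rng.integers(2, min(M, 6)))
        universe = [f"g{i}" for i in range(M)]
        signature = list(rng.choice(universe, size=N, replace=False))
        coll = make_collection({"s": universe[:K]}, universe)
        k = len(set(signature) & set(universe[:K]))
        res = rs.hypergeom_enrich(signature, coll, max_p=1.1)
        assert res[0].p == pytest.approx(enumerate_hypergeom_p(M, K, N, k))

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        coll = make_collection({"s": universe[:3]}, universe)
        res = rs.hypergeom_enrich(universe[5:8], coll, max_p=1.1)
        assert res[0].p == 1.0
        assert res[0].overlap == 0

    def test_set_equal_to_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        coll = make_collection({"all": universe}, universe)
        res = rs.hypergeom_enrich(universe[:4], coll, max_p=1.1)
        assert res[0].p == 1.0

    def test_monotone_decreasing_in_overlap(self):
        universe = [f"g{i}" for i in range(30)]
        coll = make_collection({"s": universe[:10]}, universe)
        ps = []
        for k in range(6):
            signature = universe[:k] + universe[10 : 10 + (5 - k)]
            res = rs.hypergeom_enrich(signature, coll, max_p=1.1)
            ps.append(res[0].p)
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_disjoint_namespace_instructs_harmonization(self):
        coll = make_collection({"s": ["g1", "g2", "g3"]})
        with pytest.raises(ValueError, match="harmonize"):
            rs.hypergeom_enrich(["x1", "x2"], coll)

    def test_direction_stratified_subsetting(self):
        universe = [f"g{i}" for i in range(12)]
        coll = make_collection({"s": universe[:4]}, universe)
        directions = {g: ("up" if i < 6 else "down") for i, g in enumerate(universe)}
        res_up = rs.hypergeom_enrich(
            universe[:8], coll, max_p=1.1, directions=directions, direction="up"
        )
        assert res_up[0].signature_size == 6
        assert res_up[0].overlap == 4

    def test_uniformity_under_label_shuffling(self):
        """Shuffled signatures give p-values uniform on their attainable set."""
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(25)]
        coll = make_collection({"s": universe[:8]}, universe)
        ps = []
        for _ in range(400):
            signature = list(rng.choice(universe, size=5, replace=False))
            ps.append(rs.hypergeom_enrich(signature, coll, max_p=1.1)[0].p)
        # upper-tail p is super-uniform: P(p <= x) <= x, with equality on
        # the attainable values; check both sides at attainable cut points
        ps = np.array(ps)
        from scipy.stats import hypergeom

        for k in range(1, 5):
            x = hypergeom.sf(k - 1, 25, 8, 5)
            frac = (ps <= x + 1e-12).mean()
            se = np.sqrt(x * (1 - x) / 400)
            assert abs(frac - x) < 4 * se + 1e-9


def make_signature(entries):
    df = pd.DataFrame(
        {
            "mean_log2ratio": [1.0 if d == "up" else -1.0 for _, d in entries],
            "t_p": [1e-4] * len(entries),
            "snr": [1.0 if d == "up" else -1.0 for _, d in entries],
            "direction": [d for _, d in entries],
        },
        index=[g for g, _ in entries],
    )
    return rs.Signature("toy", ("PTPN11",), "control", df)


class TestCircuitDetect:
    def test_eight_of_ten_down_is_not_biased_enough(self):
        sig = make_signature(
            [("TF1", "down")]
            + [(f"t{i}", "down") for i in range(8)]
            + [(f"t{i}", "up") for i in range(8, 10)]
        )
        coll = make_collection({"TF1": [f"t{i}" for i in range(10)]})
        (res,) = rs.circuit_detect(sig, coll)
        assert res.n_targets_in_signature == 10
        assert res.direction_bias_p == pytest.approx(
            enumerate_binomial_two_sided_p(8, 10)
        )
        assert res.direction_bias_p == pytest.approx(2 * 56 / 1024)
        assert not res.circuit

    def test_even_split_gives_p_one_and_no_circuit(self):
        sig = make_signature(
            [("TF1", "up")]
            + [(f"t{i}", "down") for i in range(5)]
            + [(f"t{i}", "up") for i in range(5, 10)]
        )
        coll = make_collection({"TF1": [f"t{i}" for i in range(10)]})
        (res,) = rs.circuit_detect(sig, coll)
        assert res.direction_bias_p == 1.0
        assert not res.circuit
        assert res.orientation == "none"

    def test_tf_up_all_targets_down_is_a_discordant_circuit(self):
        sig = make_signature(
            [("TF1", "up")] + [(f"t{i}", "down") for i in range(6)]
        )
        coll = make_collection({"TF1": [f"t{i}" for i in range(6)]})
        (res,) = rs.circuit_detect(sig, coll)
        assert res.direction_bias_p == pytest.approx(2 / 64)
        assert res.circuit
        assert res.orientation == "discordant"
        assert res.n_targets_concordant_with_tf == 0

    def test_tf_down_targets_down_is_concordant(self):
        sig = make_signature(
            [("TF1", "down")] + [(f"t{i}", "down") for i in range(6)]
        )
        coll = make_collection({"TF1": [f"t{i}" for i in range(6)]})
        (res,) = rs.circuit_detect(sig, coll)
        assert res.circuit and res.orientation == "concordant"

    def test_too_few_targets_skipped(self):
        sig = make_signature([("TF1", "up"), ("t0", "down")])
        coll = make_collection({"TF1": ["t0", "t1", "t2"]})
        assert rs.circuit_detect(sig, coll, min_targets=3) == []

    def test_absent_tf_not_reported(self):
        sig = make_signature([(f"t{i}", "down") for i in range(5)])
        coll = make_collection({"TF1": [f"t{i}" for i in range(5)]})
        assert rs.circuit_detect(sig, coll) == []

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 7), (6, 11), (5, 12)])
    def test_binomial_p_matches_enumeration(self, k, n):
        sig = make_signature(
            [("TF1", "up")]
            + [(f"t{i}", "up") for i in range(k)]
            + [(f"t{i}", "down") for i in range(k, n)]
        )
        coll = make_collection({"TF1": [f"t{i}" for i in range(n)]})
        (res,) = rs.circuit_detect(sig, coll)
        assert res.direction_bias_p == pytest.approx(
            enumerate_binomial_two_sided_p(k, n)
        )
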
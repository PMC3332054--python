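"""Triple-criterion selection, SNR statistic and permutation FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import rasosig as rs

from conftest import ratios_from_array, small_config, toy_sample_sheet


class TestSNR:
    @pytest.mark.parametrize(
        "case, control, expected",
        [
            ([3, 1], [1, -1], 2 / (np.sqrt(2) + np.sqrt(2))),  # ~0.7071
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([5, 5, 5], [5, 5, 5], 0.0),  # constant, equal means
        ],
    )
    def test_hand_computed_values(self, case, control, expected):
        assert rs.snr(case, control) == pytest.approx(expected)

    def test_constant_groups_with_unequal_means_is_signed_infinity(self):
        assert rs.snr([2, 2], [0, 0]) == np.inf
        assert rs.snr([0, 0], [2, 2]) == -np.inf

    def test_rejects_groups_of_one(self):
        with pytest.raises(ValueError, match="at least 2"):
            rs.snr([1.0], [0.0, 1.0])

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert rs.snr(a, b) == pytest.approx(-rs.snr(b, a), nan_ok=True)


class TestSelectSignature:
    def _toy(self, probe_rows, groups={"control": 4, "PTPN11": 4}):
        samples = toy_sample_sheet(groups)
        return ratios_from_array(np.asarray(probe_rows, float), samples), samples

    def test_single_criterion_veto_on_fold_change(self):
        # strong separation but mean case log2ratio 0.4 < 0.5: excluded
        ratios, samples = self._toy(
            [[0.0, 0.01, -0.01, 0.0, 0.40, 0.41, 0.39, 0.40]]
        )
        sig = rs.select_signature(ratios, samples, ["PTPN11"])
        probe = ratios.values.index[0]
        # it clears t and SNR comfortably, fails fold change alone
        case = ratios.values.iloc[0, 4:]
        ctrl = ratios.values.iloc[0, :4]
        assert stats.ttest_ind(case, ctrl).pvalue < 0.01
        assert abs(rs.snr(case, ctrl)) > 0.5
        assert probe not in sig.probe_ids

    def test_passing_probe_has_consistent_entry(self):
        ratios, samples = self._toy(
            [[0.0, 0.05, -0.05, 0.0, 1.0, 1.1, 0.9, 1.0],
             [0.0, 0.05, -0.05, 0.0, -1.0, -1.1, -0.9, -1.0]]
        )
        sig = rs.select_signature(ratios, samples, ["PTPN11"])
        assert len(sig) == 2
        assert list(sig.entries["direction"]) == ["up", "down"] or \
            list(sig.entries["direction"]) == ["down", "up"]
        for _, row in sig.entries.iterrows():
            assert abs(row["mean_log2ratio"]) > 0.5
            assert row["t_p"] < 0.01
            assert abs(row["snr"]) > 0.5
            assert row["direction"] == ("up" if row["mean_log2ratio"] > 0 else "down")

    def test_entries_sorted_by_abs_snr(self, small_signatures):
        for sig in small_signatures.values():
            s = np.abs(sig.entries["snr"].to_numpy())
            assert (np.diff(s) <= 1e-12).all()

    def test_small_arms_rejected(self):
        samples = toy_sample_sheet({"control": 4, "SOS1": 1, "PTPN11": 3})
        ratios = ratios_from_array(np.zeros((3, 8)), samples)
        with pytest.raises(ValueError, match=">= 2 samples"):
            rs.select_signature(ratios, samples, ["SOS1"])

    def test_planted_probes_recovered(self, small_ratios, small_dataset):
        sig = rs.select_signature(small_ratios, small_dataset.samples, ["PTPN11"])
        planted = set(small_dataset.planted_probes("PTPN11"))
        recovered = planted & set(sig.probe_ids)
        assert len(recovered) >= 0.9 * len(planted)
        # planted directions come out right
        for p in recovered:
            assert sig.directions()[p] == small_dataset.truth[p]["direction"]


def _null_ratios(n_probes, seed, residual_sd=1.0):
    cfg = small_config(
        n_probes=n_probes,
        signature_spec={},
        confound_spec=rs.ConfoundSpec(0, 0, 0),
        residual_sd=residual_sd,
        seed=seed,
    )
    ds = rs.simulate(cfg)
    logged = rs.scale_and_log(ds.matrix)
    return rs.to_log2ratio(logged, ds.samples), ds.samples


def test_triple_rate_never_exceeds_ttest_rate_under_null():
    """The fold-change and SNR criteria only remove probes."""
    for rep in range(5):
        ratios, samples = _null_ratios(2000, seed=50 + rep)
        sig = rs.select_signature(ratios, samples, ["PTPN11"])
        case = samples.samples_in(["PTPN11"])
        ctrl = samples.samples_in(["control"])
        t_p = stats.ttest_ind(
            ratios.values[case], ratios.values[ctrl], axis=1, equal_var=False
        ).pvalue
        assert len(sig) <= (t_p < 0.01).sum()
        # and stays below the t-bound in expectation (binomial 4-sigma)
        bound = 0.01 * 2000 + 4 * np.sqrt(2000 * 0.01 * 0.99)
        assert len(sig) <= bound


class TestPermutationFDR:
    def test_ratio_definition(self):
        fdr = rs.PermutationFDR("x", 100, 4, np.array([1, 1, 1, 1]), seed=0)
        assert fdr.fdr_estimate == pytest.approx(0.01)

    def test_zero_observed_hits_reports_nan(self):
        fdr = rs.PermutationFDR("x", 0, 3, np.array([0, 1, 0]), seed=0)
        assert np.isnan(fdr.fdr_estimate)
        assert fdr.mean_null_hits == pytest.approx(1 / 3)

    def test_same_seed_reproduces_null_counts(self, small_ratios, small_dataset):
        kw = dict(n_permutations=30, seed=17)
        a = rs.permutation_fdr(small_ratios, small_dataset.samples, ["PTPN11"], **kw)
        b = rs.permutation_fdr(small_ratios, small_dataset.samples, ["PTPN11"], **kw)
        np.testing.assert_array_equal(a.null_hit_counts, b.null_hit_counts)

    def test_global_null_estimate_concentrates_near_one(self):
        """With no real signal, observed hits look like permutation hits."""
        ests = []
        for rep in range(6):
            ratios, samples = _null_ratios(3000, seed=400 + rep, residual_sd=1.2)
            fdr = rs.permutation_fdr(
                ratios, samples, ["PTPN11"], n_permutations=60, seed=rep
            )
            if fdr.n_observed_hits > 0:
                ests.append(fdr.fdr_estimate)
        assert ests, "every null replicate produced zero observed hits"
        mean_est = np.mean(ests)
        assert 0.3 < mean_est < 3.0

    def test_invariant_to_probe_and_sample_order(self, small_ratios, small_dataset):
        samples = small_dataset.samples
        kw = dict(n_permutations=25, seed=5)
        base = rs.permutation_fdr(small_ratios, samples, ["PTPN11"], **kw)
        rng = np.random.default_rng(0)
        probe_perm = rng.permutation(len(small_ratios.probe_ids))
        col_perm = rng.permutation(len(small_ratios.sample_ids))
        shuffled = rs.Log2RatioMatrix(
            small_ratios.values.iloc[probe_perm, col_perm]
        )
        other = rs.permutation_fdr(shuffled, samples, ["PTPN11"], **kw)
        np.testing.assert_array_equal(base.null_hit_counts, other.null_hit_counts)
        assert base.fdr_estimate == other.fdr_estimate

    def test_json_roundtrip(self, tmp_path, small_ratios, small_dataset):
        import json

        fdr = rs.permutation_fdr(
            small_ratios, small_dataset.samples, ["SOS1"],
            n_permutations=10, seed=2,
        )
        fdr.to_json(tmp_path / "fdr.json")
        payload = json.loads((tmp_path / "fdr.json").read_text())
        assert payload["n_permutations"] == 10
        assert len(payload["null_hit_counts"]) == 10


class TestSignatureOverlap:
    def _sig(self, entries):
        df = pd.DataFrame(
            {
                "mean_log2ratio": [1.0 if d == "up" else -1.0 for _, d in entries],
                "t_p": 0.001,
                "snr": [1.0 if d == "up" else -1.0 for _, d in entries],
                "direction": [d for _, d in entries],
            },
            index=[p for p, _ in entries],
        )
        return rs.Signature("toy", ("PTPN11",), "control", df)

    def test_identical_signatures_fully_concordant(self):
        a = self._sig([("P1", "up"), ("P2", "down")])
        shared, conc, disc = rs.signature_overlap(a, a)
        assert shared == {"P1", "P2"} and conc == 2 and disc == 0

    def test_disjoint_signatures(self):
        a = self._sig([("P1", "up")])
        b = self._sig([("P2", "up")])
        assert rs.signature_overlap(a, b) == (set(), 0, 0)

    def test_partial_overlap_with_flip(self):
        a = self._sig([("P1", "up"), ("P2", "down"), ("P3", "up"), ("P4", "up"),
                       ("P5", "down")])
        b = self._sig([("P1", "up"), ("P2", "up"), ("P9", "down")])
        shared, conc, disc = rs.signature_overlap(a, b)
        assert (shared, conc, disc) == ({"P1", "P2"}, 1, 1)
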
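import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sscatac import core, differential, simulate

from conftest import intensity_matrix


class TestDifferentialPeaks:
    def test_identical_groups_have_zero_lfc_and_no_calls(self):
        rng = np.random.default_rng(0)
        block = rng.normal(5, 1, size=(30, 3))
        m = intensity_matrix(np.hstack([block, block]), [f"s{j}" for j in range(6)])
        res = differential.differential_peaks(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        np.testing.assert_allclose(res["log2fc"], 0.0)
        assert not res["significant"].any()

    def test_planted_peak_called_and_welch_t_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 0.1, size=(20, 6))
        vals[0, :3] = rng.normal(8, 0.1, 3)
        vals[0, 3:] = rng.normal(2, 0.1, 3)
        m = intensity_matrix(vals, [f"s{j}" for j in range(6)])
        res = differential.differential_peaks(
            m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], p_thr=0.005, lfc_thr=2
        )
        assert res["significant"].iloc[0]
        # direct Welch formula as an oracle for the first peak
        a, b = vals[0, :3], vals[0, 3:]
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t = (a.mean() - b.mean()) / se
        df = se**4 / (
            (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2
        )
        p_direct = 2 * stats.t.sf(abs(t), df)
        assert res["p"].iloc[0] == pytest.approx(p_direct, rel=1e-10)

    def test_swapping_groups_negates_lfc_and_preserves_p(self):
        rng = np.random.default_rng(2)
        m = intensity_matrix(rng.normal(5, 1, size=(25, 6)), [f"s{j}" for j in range(6)])
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        r1 = differential.differential_peaks(m, a, b)
        r2 = differential.differential_peaks(m, b, a)
        np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"])
        np.testing.assert_allclose(r1["p"], r2["p"])

    def test_singleton_group_requires_fc_only(self):
        m = intensity_matrix(np.zeros((5, 3)), ["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="fc_only"):
            differential.differential_peaks(m, ["s0"], ["s1", "s2"])

    def test_fc_only_mode_ignores_p(self):
        vals = np.array([[8.0, 2.0], [5.0, 5.5]])
        m = intensity_matrix(vals, ["a", "b"])
        res = differential.differential_peaks(m, ["a"], ["b"], lfc_thr=2, mode="fc_only")
        assert res["significant"].tolist() == [True, False]
        assert res["p"].isna().all()


def bh_step_up_oracle(p):
    """Independent step-up BH implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        adj = differential.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_independent_step_up_on_random_lists(self):
        rng = np.random.default_rng(3)
        for n in (1, 7, 100, 5000):
            p = rng.uniform(size=n)
            np.testing.assert_allclose(
                differential.benjamini_hochberg(p), bh_step_up_oracle(p), rtol=1e-12
            )

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        assert (differential.benjamini_hochberg(p) >= p - 1e-15).all()


class TestCellTypeSpecificPeaks:
    def test_zero_in_cov_for_constant_focal_group(self):
        # focal group exactly (10,10,10) on the intensity scale: CV = 0 and
        # the peak clears every filter against the ~5-intensity rest
        rng = np.random.default_rng(8)
        vals = rng.normal(5, 0.05, size=(6, 9))
        vals[0, :3] = 10.0
        m = intensity_matrix(vals, [f"s{j}" for j in range(9)])
        meta = pd.DataFrame(
            {
                "sample_id": m.intensity.columns,
                "cell_type": ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                "state": ["normal"] * 9,
                "donor_id": ["d"] * 9,
            }
        ).set_index("sample_id", drop=False)
        calls = differential.cell_type_specific_peaks(m, meta)
        assert calls.loc["p0", "cell_type"] == "A"
        assert calls.loc["p0", "in_cov"] == pytest.approx(0.0, abs=1e-12)

    def test_high_in_cov_vetoes_call_despite_p_and_lfc(self):
        # focal values wildly variable -> inCov > 0.5 -> no call
        rng = np.random.default_rng(5)
        raw = rng.integers(45, 55, size=(30, 9))
        raw[0, :3] = [80, 800, 8000]
        df = pd.DataFrame(raw, index=[f"p{i}" for i in range(30)],
                          columns=[f"s{j}" for j in range(9)])
        m = core.intensity(core.quantile_normalize(core.AccessibilityMatrix(df)))
        meta = pd.DataFrame(
            {
                "sample_id": df.columns,
                "cell_type": ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                "state": ["normal"] * 9,
                "donor_id": ["d"] * 9,
            }
        ).set_index("sample_id", drop=False)
        calls = differential.cell_type_specific_peaks(m, meta, p_thr=1.0, lfc_thr=0.5)
        assert calls.loc["p0", "cell_type"] == "none"

    def test_calls_mutually_exclusive_on_simulation(self, default_study, normalized_matrix):
        calls = differential.cell_type_specific_peaks(
            normalized_matrix, default_study.meta
        )
        per_type = calls.attrs["per_type"]
        stacked = pd.DataFrame({ct: df["specific"] for ct, df in per_type.items()})
        assert (stacked.sum(axis=1) <= 1).all()


class TestClassifySixStates:
    @staticmethod
    def _matrix_and_meta(group_means, spread=0.1, reps=3):
        """One peak per row of group_means (normal, unaffected, affected)."""
        vals = []
        for means in group_means:
            row = []
            for mean in means:
                row.extend(mean + spread * np.linspace(-1, 1, reps))
            vals.append(row)
        samples = [f"{s}_{r}" for s in core.STATES for r in range(reps)]
        m = intensity_matrix(np.array(vals), samples)
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "cell_type": "Fib",
                "state": np.repeat(core.STATES, reps),
                "donor_id": "d",
            }
        ).set_index("sample_id", drop=False)
        return m, meta

    def test_pattern_rules(self):
        m, meta = self._matrix_and_meta([(8, 8, 2), (5, 5.5, 5.9), (2, 2, 8)])
        res = differential.classify_six_states(m, meta)
        labels = res.labels
        assert labels.get("p0") == "C2"      # normal + unaffected high
        assert labels.get("p2") == "C5"      # affected only
        assert labels.get("p1", "absent") in ("unassigned", "absent")

    def test_wide_within_group_range_blocks_assignment(self):
        m, meta = self._matrix_and_meta([(8, 8, 2)], spread=1.0)
        res = differential.classify_six_states(m, meta, range_max=1.5)
        # spread 1.0 -> range 2.0 > 1.5
        assert (res.labels == "unassigned").all()

    def test_invariant_to_sample_order_and_intensity_shift(self):
        m, meta = self._matrix_and_meta([(8, 8, 2), (2, 8, 8), (9, 2, 9)])
        res1 = differential.classify_six_states(m, meta)
        perm = np.random.default_rng(6).permutation(m.intensity.columns)
        m2 = intensity_matrix(m.intensity[perm].to_numpy() + 3.0, list(perm))
        res2 = differential.classify_six_states(m2, meta.loc[perm])
        pd.testing.assert_series_equal(res1.labels, res2.labels)

    def test_recovers_planted_clusters(self):
        cfg = simulate.SimulationConfig(
            seed=7, n_peaks=600, cell_types=("Fib",),
            replicates={"normal": 3, "unaffected": 3, "affected": 3},
            n_specific_per_type=0, state_peaks_per_cluster=100, state_gap=3.0,
            noise_sd=0.1, lr_planted_up=(), lr_planted_down=(),
            base_log2_mean_range=(7.0, 10.0), n_padding_peaks=0,
        )
        study = simulate.simulate_accessibility(cfg)
        m = core.intensity(core.quantile_normalize(study.matrix))
        res = differential.classify_six_states(m, study.meta)
        truth = study.truth.state_peaks
        correct = sum(res.labels.get(pid) == lab for pid, lab in truth.items())
        assert correct / len(truth) >= 0.95
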
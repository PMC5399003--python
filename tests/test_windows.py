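import numpy as np
import pandas as pd
import pytest

from conftest import make_map
from sweepscan.windows import (
    GenomeSpec,
    ScanConfig,
    bootstrap_pvalues,
    call_outlier_regions,
    cm_to_kb,
    genome_fraction,
    make_windows,
    smooth_statistic,
    window_pi_ratio,
)

CFG = ScanConfig(n_boot=1000)


def sites_frame(cm, fst, pi1=None, pi2=None, lg="1"):
    n = len(cm)
    return pd.DataFrame(
        {
            "lg": lg,
            "cm": np.asarray(cm, dtype=float),
            "fst": np.asarray(fst, dtype=float),
            "pi_pop1": np.asarray(pi1 if pi1 is not None else np.full(n, 0.3)),
            "pi_pop2": np.asarray(pi2 if pi2 is not None else np.full(n, 0.1)),
        }
    )


class TestMakeWindows:
    def test_arithmetic_progression_of_centers(self):
        gmap = make_map(["a", "b"], ["1", "1"], [0.0, 0.06])
        w = make_windows(gmap, CFG)
        assert w["center_cm"].tolist() == pytest.approx([0.0, 0.03, 0.06])

    def test_single_snp_group(self):
        gmap = make_map(["a"], ["1"], [3.3])
        w = make_windows(gmap, CFG)
        assert len(w) == 1
        assert w["center_cm"].iloc[0] == pytest.approx(3.3)

    def test_step_equal_window_tiles(self):
        cfg = ScanConfig(window_cm=0.15, step_cm=0.15, n_boot=1000)
        gmap = make_map(list("abcd"), ["1"] * 4, [0.0, 0.1, 0.2, 0.3])
        w = make_windows(gmap, cfg)
        starts = w["start_cm"].to_numpy()
        ends = w["end_cm"].to_numpy()
        assert np.allclose(starts[1:], ends[:-1])  # non-overlapping tiling


class TestSmoothing:
    def test_uniform_window_mean(self):
        sites = sites_frame([0.10, 0.12, 0.20], [0.1, 0.2, 0.6])
        windows = pd.DataFrame(
            {"lg": ["1"], "center_cm": [0.15], "start_cm": [0.075],
             "end_cm": [0.225]}
        )
        out = smooth_statistic(sites, windows, CFG)
        assert out["k"].iloc[0] == 3
        assert out["fst_mean"].iloc[0] == pytest.approx(0.3)

    def test_single_site_window(self):
        sites = sites_frame([0.1], [0.42])
        windows = pd.DataFrame(
            {"lg": ["1"], "center_cm": [0.1], "start_cm": [0.025],
             "end_cm": [0.175]}
        )
        out = smooth_statistic(sites, windows, CFG)
        assert out["fst_mean"].iloc[0] == pytest.approx(0.42)

    def test_empty_window_missing(self):
        sites = sites_frame([5.0], [0.42])
        windows = pd.DataFrame(
            {"lg": ["1"], "center_cm": [0.1], "start_cm": [0.025],
             "end_cm": [0.175]}
        )
        out = smooth_statistic(sites, windows, CFG)
        assert out["k"].iloc[0] == 0
        assert np.isnan(out["fst_mean"].iloc[0])

    def test_window_covering_group_gives_group_mean(self, rng):
        cm = np.sort(rng.uniform(0, 1, 25))
        fst = rng.normal(0.2, 0.1, 25)
        sites = sites_frame(cm, fst)
        windows = pd.DataFrame(
            {"lg": ["1"], "center_cm": [0.5], "start_cm": [-0.1],
             "end_cm": [1.1]}
        )
        out = smooth_statistic(sites, windows, CFG)
        assert out["fst_mean"].iloc[0] == pytest.approx(fst.mean())

    def test_gaussian_kernel_single_site_and_weighting(self):
        cfg = ScanConfig(kernel="gaussian", n_boot=1000)
        sites = sites_frame([0.1], [0.42])
        windows = pd.DataFrame(
            {"lg": ["1"], "center_cm": [0.1], "start_cm": [0.025],
             "end_cm": [0.175]}
        )
        out = smooth_statistic(sites, windows, cfg)
        assert out["fst_mean"].iloc[0] == pytest.approx(0.42)
        # off-centre sites weigh less: mean pulled toward the central value
        sites2 = sites_frame([0.1, 0.17], [1.0, 0.0])
        windows2 = pd.DataFrame(
            {"lg": ["1"], "center_cm": [0.1], "start_cm": [0.025],
             "end_cm": [0.175]}
        )
        out2 = smooth_statistic(sites2, windows2, cfg)
        assert out2["fst_mean"].iloc[0] > 0.5


class TestPiRatio:
    def test_values(self):
        assert window_pi_ratio(0.3, 0.1) == pytest.approx(3.0)
        assert window_pi_ratio(0.2, 0.2) == pytest.approx(1.0)
        assert np.isnan(window_pi_ratio(0.3, 0.0))


class TestBootstrap:
    def _windows(self, k, fst_mean, pi_ratio=2.0):
        return pd.DataFrame(
            {
                "lg": "1",
                "center_cm": np.arange(len(k), dtype=float),
                "k": k,
                "fst_mean": fst_mean,
                "pi_ratio": pi_ratio,
            }
        )

    def test_add_one_p_when_observed_tops_all_replicates(self):
        sites = sites_frame(np.arange(50.0), np.zeros(50))
        cfg = ScanConfig(n_boot=999)
        out = bootstrap_pvalues(sites, self._windows([3], [1.0]), cfg, seed=0)
        assert out["p_fst"].iloc[0] == pytest.approx(1 / 1000)

    def test_symmetric_pool_gives_half(self):
        vals = np.tile([0.0, 1.0], 500)
        sites = sites_frame(np.arange(1000.0), vals)
        cfg = ScanConfig(n_boot=10_000)
        out = bootstrap_pvalues(sites, self._windows([1], [0.5]), cfg, seed=1)
        assert out["p_fst"].iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_reproducible_and_order_invariant(self, rng):
        sites = sites_frame(np.arange(200.0), rng.normal(0.2, 0.1, 200))
        w = self._windows([3, 5, 3, 7], [0.25, 0.3, 0.18, 0.22])
        cfg = ScanConfig(n_boot=2000)
        a = bootstrap_pvalues(sites, w, cfg, seed=42)
        b = bootstrap_pvalues(sites, w, cfg, seed=42)
        pd.testing.assert_frame_equal(a, b)
        shuffled = w.sample(frac=1, random_state=7)
        c = bootstrap_pvalues(sites, shuffled, cfg, seed=42).sort_index()
        np.testing.assert_allclose(a["p_fst"], c["p_fst"])

    def test_undefined_ratio_keeps_nan_p(self):
        sites = sites_frame(np.arange(50.0), np.zeros(50))
        w = self._windows([3], [0.5], pi_ratio=np.nan)
        out = bootstrap_pvalues(sites, w, ScanConfig(n_boot=500), seed=0)
        assert np.isnan(out["p_ratio"].iloc[0])


class TestRegions:
    def _sig_windows(self, centers, sig, lg="1", width=0.15):
        w = pd.DataFrame(
            {
                "lg": lg,
                "center_cm": np.asarray(centers, dtype=float),
                "sig_fst": sig,
                "sig_ratio": False,
            }
        )
        w["start_cm"] = w["center_cm"] - width / 2
        w["end_cm"] = w["center_cm"] + width / 2
        return w

    def test_merge_and_clip_at_group_start(self):
        gmap = make_map(["a", "b"], ["1", "1"], [0.0, 1.0])
        w = self._sig_windows([0.03, 0.06], [True, True])
        regions, totals = call_outlier_regions(w, CFG, gmap)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert r["start_cm"] == pytest.approx(0.0)  # clipped at group min
        assert r["end_cm"] == pytest.approx(0.135)
        assert totals.window_extent["fst"] == pytest.approx(0.135)

    def test_no_significant_windows(self):
        gmap = make_map(["a", "b"], ["1", "1"], [0.0, 1.0])
        w = self._sig_windows([0.5], [False])
        regions, totals = call_outlier_regions(w, CFG, gmap)
        assert regions.empty
        assert totals.window_extent["fst"] == 0.0

    def test_gap_splits_regions(self):
        gmap = make_map(["a", "b"], ["1", "1"], [0.0, 2.0])
        w = self._sig_windows([0.2, 1.5], [True, True])
        regions, _ = call_outlier_regions(w, CFG, gmap)
        assert len(regions) == 2

    def test_merged_regions_never_overlap(self, rng):
        gmap = make_map(["a", "b"], ["1", "1"], [0.0, 5.0])
        centers = np.arange(0.0, 5.0, 0.03)
        sig = rng.random(len(centers)) < 0.3
        w = self._sig_windows(centers, sig)
        regions, totals = call_outlier_regions(w, CFG, gmap)
        sub = regions.sort_values("start_cm")
        assert (sub["start_cm"].to_numpy()[1:]
                >= sub["end_cm"].to_numpy()[:-1]).all()
        assert totals.window_extent["fst"] <= 5.0


class TestGenomeArithmetic:
    SPEC = GenomeSpec(total_map_length_cm=837.11, genome_size_mb=630.0)

    def test_sweep_fraction_of_map(self):
        assert genome_fraction(15.33, self.SPEC) == pytest.approx(1.83, abs=0.005)
        assert genome_fraction(15.33, self.SPEC) == pytest.approx(1.8, abs=0.05)

    def test_zero_fraction(self):
        assert genome_fraction(0.0, self.SPEC) == 0.0

    def test_fst_outlier_fraction(self):
        assert genome_fraction(40.5, self.SPEC) == pytest.approx(
            100 * 40.5 / 837.11
        )

    def test_cm_to_kb(self):
        assert cm_to_kb(0.15, self.SPEC) == pytest.approx(112.9, abs=0.05)
        assert cm_to_kb(0.03, self.SPEC) == pytest.approx(22.6, abs=0.05)
        assert cm_to_kb(0.0, self.SPEC) == 0.0
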
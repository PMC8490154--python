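"""Trajectory linking, length filtering, density annotation."""

import numpy as np
import pandas as pd
import pytest

from mspt.simulate import SimulationConfig, gen_trajectories
from mspt.track import (annotate_density, density_bin, filter_min_length,
                        flag_censored, link, summarize_trajectories)


def det_table(rows):
    return pd.DataFrame(rows, columns=["frame", "x", "y", "contrast"])


class TestLink:
    def test_close_detections_link(self):
        df = det_table([(0, 10.0, 10.0, 1e-3), (1, 11.0, 10.0, 1e-3)])
        linked = link(df, search_range_px=5.0)
        assert linked["particle"].nunique() == 1

    def test_distant_detections_stay_separate(self):
        df = det_table([(0, 10.0, 10.0, 1e-3), (1, 20.0, 10.0, 1e-3)])
        linked = link(df, search_range_px=5.0)
        assert linked["particle"].nunique() == 2

    def test_memory_bridges_single_gap(self):
        df = det_table([(0, 10.0, 10.0, 1e-3), (2, 10.5, 10.0, 1e-3)])
        assert link(df, 5.0, memory_frames=1)["particle"].nunique() == 1
        assert link(df, 5.0, memory_frames=0)["particle"].nunique() == 2

    def test_no_detection_assigned_twice(self):
        rng = np.random.default_rng(0)
        rows = [(f, rng.uniform(0, 50), rng.uniform(0, 50), 1e-3)
                for f in range(20) for _ in range(5)]
        linked = link(det_table(rows), 5.0)
        assert (linked.groupby(["particle", "frame"]).size() == 1).all()

    def test_ground_truth_links_recovered(self):
        cfg = SimulationConfig(fov_px=(128, 35), n_frames=60,
                               particle_density_um2=0.1, seed=17)
        tracks = gen_trajectories(cfg, 1.0)
        rows = []
        for tr in tracks:
            for f in range(cfg.n_frames):
                rows.append((f, tr.x_px[f], tr.y_px[f], 1e-3,
                             tr.particle_id))
        df = pd.DataFrame(rows, columns=["frame", "x", "y", "contrast",
                                         "true_id"])
        # only in-FOV positions reach the linker in the real pipeline
        df = df[(df.x >= 0) & (df.x < 128) & (df.y >= 0) & (df.y < 35)]
        linked = link(df[["frame", "x", "y", "contrast"]], search_range_px=8.0)
        merged = linked.merge(df, on=["frame", "x", "y"]).sort_values("frame")
        # score frame-to-frame links: consecutive in-FOV detections of the
        # same true particle must carry the same linked id
        total = correct = 0
        for _, g in merged.groupby("true_id"):
            f = g["frame"].to_numpy()
            p = g["particle"].to_numpy()
            consec = f[1:] == f[:-1] + 1
            total += consec.sum()
            correct += (p[1:][consec] == p[:-1][consec]).sum()
        assert total > 100
        assert correct / total >= 0.95


class TestFilters:
    def test_min_length_boundary_inclusive(self):
        rows = ([(f, 1.0, 1.0, 1e-3) for f in range(4)]
                + [(f, 30.0, 30.0, 1e-3) for f in range(5)])
        linked = link(det_table(rows), 5.0)
        kept, removed = filter_min_length(linked, min_length=5)
        assert kept["particle"].nunique() == 1
        lengths = kept.groupby("particle").size()
        assert (lengths >= 5).all()
        assert removed == pytest.approx(0.5)

    def test_empty_input(self):
        kept, removed = filter_min_length(
            pd.DataFrame(columns=["frame", "particle"]), 5)
        assert kept.empty and removed == 0.0


class TestDensity:
    def _four_concurrent(self):
        rows = []
        for pid in range(4):
            for f in range(10):
                rows.append((f, 10.0 * pid + 5, 10.0, 1e-3, pid))
        return pd.DataFrame(rows, columns=["frame", "x", "y", "contrast",
                                           "particle"])

    def test_four_trajectories_give_paper_density(self):
        dens = annotate_density(self._four_concurrent(), fov_area_um2=31.9)
        np.testing.assert_allclose(dens["density_um2"], 4 / 31.9)
        assert dens["density_um2"].iloc[0] == pytest.approx(0.125, abs=0.005)

    def test_single_trajectory(self):
        df = self._four_concurrent()
        df = df[df["particle"] == 0]
        dens = annotate_density(df, 31.9)
        assert dens["density_um2"].iloc[0] == pytest.approx(1 / 31.9)

    def test_invariant_under_id_relabel(self):
        df = self._four_concurrent()
        relabeled = df.copy()
        relabeled["particle"] = 10 - relabeled["particle"]
        a = annotate_density(df, 31.9)["density_um2"].to_numpy()
        b = annotate_density(relabeled, 31.9)["density_um2"].to_numpy()
        np.testing.assert_allclose(np.sort(a), np.sort(b))

    def test_density_bin_selection(self):
        summary = pd.DataFrame({"particle": range(7),
                                "median_count": [1, 2, 3, 4, 5, 6, 7]})
        sel = density_bin(summary, center_count=4, half_width=2)
        assert sorted(sel["median_count"]) == [2, 3, 4, 5, 6]
        exact = density_bin(summary, 4, 0)
        assert list(exact["median_count"]) == [4]

    def test_sliding_bins_cover_everything(self):
        summary = pd.DataFrame({"particle": range(9),
                                "median_count": np.arange(1, 10)})
        covered = set()
        for center in range(1, 10):
            covered.update(density_bin(summary, center, 2)["particle"])
        assert covered == set(range(9))


class TestSummary:
    def test_censoring_flags_video_edges(self):
        rows = ([(f, 1.0, 1.0, 1e-3) for f in range(0, 6)]
                + [(f, 30.0, 30.0, 1e-3) for f in range(10, 16)])
        linked = link(det_table(rows), 5.0)
        cens = flag_censored(linked, first_frame=0, last_frame=20)
        by_start = linked.groupby("particle")["frame"].min()
        for pid, start in by_start.items():
            assert cens[pid] == (start == 0)

    def test_summary_contains_mass_and_density(self, calibration):
        rows = [(f, 10.0, 10.0, 3.5e-3) for f in range(8)]
        linked = link(det_table(rows), 5.0)
        s = summarize_trajectories(linked, calibration, 31.9)
        assert s["mass_kda"].iloc[0] == pytest.approx(66.0, abs=1e-9)
        assert s["length"].iloc[0] == 8
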
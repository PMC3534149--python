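"""Synthetic baseline arrays and spike-in generation."""

import numpy as np
import pytest
import scipy.ndimage
import scipy.stats

from celstain import (FlagMask, ProbeGrid, generate_baseline_arrays,
                      project_artefact, random_spike, stain_mask, stain_spike)


class TestGenerateBaseline:
    def test_seeded_determinism(self):
        a = generate_baseline_arrays(20, 21, 3, seed=7)
        b = generate_baseline_arrays(20, 21, 3, seed=7)
        for ga, gb in zip(a.grids, b.grids):
            np.testing.assert_array_equal(ga.intensities, gb.intensities)
        assert a.map.entries.equals(b.map.entries)

    def test_zero_replicate_noise_gives_identical_replicates(self):
        a = generate_baseline_arrays(10, 11, 3, seed=1, replicate_sd_log2=0.0)
        np.testing.assert_array_equal(a.grids[0].intensities, a.grids[2].intensities)

    def test_log2_mean_clt_bound(self):
        aset = generate_baseline_arrays(320, 320, 2, seed=3)  # > 1e5 probes
        mean = np.log2(aset.grids[0].intensities).mean()
        assert mean == pytest.approx(8.0, abs=0.05)

    def test_probeset_probes_never_adjacent(self):
        aset = generate_baseline_arrays(12, 10, 2, seed=0)
        df = aset.map.entries
        for _, sub in df.groupby("probeset_id"):
            xs, ys = sub["x"].to_numpy(), sub["y"].to_numpy()
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    d = abs(xs[i] - xs[j]) + abs(ys[i] - ys[j])
                    assert d > 1, "probes of one probeset are grid-adjacent"

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_baseline_arrays(1, 4, 2, seed=0)


class TestRandomSpike:
    def _aset(self, n=40, seed=0):
        return generate_baseline_arrays(n, n, 2, seed=seed)

    def test_delta_zero_unchanged(self):
        aset = self._aset()
        out, truth = random_spike(aset.grids[0], aset.map, 0.0, seed=1)
        assert truth.n_spiked == 0
        np.testing.assert_array_equal(out.intensities, aset.grids[0].intensities)

    def test_delta_one_spikes_every_eligible_probe(self):
        aset = self._aset()
        out, truth = random_spike(aset.grids[0], aset.map, 1.0, seed=1)
        n_core = aset.map.entries["is_core"].sum()
        assert truth.n_spiked == n_core

    def test_spiked_count_binomial_bound(self):
        aset = self._aset(104)  # > 1e4 eligible probes
        n_elig = len(aset.map.entries)
        out, truth = random_spike(aset.grids[0], aset.map, 0.05, seed=9)
        lo, hi = scipy.stats.binom.ppf([0.0005, 0.9995], n_elig, 0.05)
        assert lo <= truth.n_spiked <= hi

    def test_unspiked_probes_bit_identical(self):
        aset = self._aset()
        out, truth = random_spike(aset.grids[0], aset.map, 0.1, seed=2)
        m = truth.mask()
        np.testing.assert_array_equal(out.intensities[~m],
                                      aset.grids[0].intensities[~m])
        np.testing.assert_array_equal(np.sort(out.intensities[m]),
                                      np.sort(truth.planted_values))

    def test_planted_log2_mean_lln(self):
        aset = generate_baseline_arrays(104, 104, 2, seed=4)
        out, truth = random_spike(aset.grids[0], aset.map, 1.0, seed=5)
        n = truth.n_spiked
        assert n > 1e4
        mean = np.log2(truth.planted_values).mean()
        assert abs(mean - np.log2(850)) < 3 * 1.0 / np.sqrt(n)

    def test_delta_out_of_range_rejected(self):
        aset = self._aset()
        with pytest.raises(ValueError, match="delta"):
            random_spike(aset.grids[0], aset.map, 1.5, seed=0)


class TestStain:
    def test_stain_mask_coverage_and_connectivity(self):
        mask = stain_mask(200, 200, coverage=0.02, seed=3)
        frac = mask.n_flagged / mask.flagged.size
        assert 0.01 < frac < 0.04
        # the disc core is one connected component holding most of the stain
        labels, n = scipy.ndimage.label(mask.flagged)
        sizes = np.bincount(labels.ravel())[1:]
        assert sizes.max() > 0.5 * mask.n_flagged

    def test_stain_spike_restricted_to_core(self):
        aset = generate_baseline_arrays(60, 60, 2, seed=1)
        mask = stain_mask(60, 60, coverage=0.05, seed=2)
        out, truth = stain_spike(aset.grids[0], mask, seed=3, pmap=aset.map)
        core = np.zeros((60, 60), dtype=bool)
        df = aset.map.entries
        core[df["y"], df["x"]] = True
        assert np.all(core[truth.spiked_xy[:, 1], truth.spiked_xy[:, 0]])


class TestProjectArtefact:
    def _source_block(self, values):
        src = ProbeGrid(np.asarray(values, dtype=float))
        mask = FlagMask(np.ones_like(src.intensities, dtype=bool))
        return src, mask

    def test_block_max_unit_scale(self):
        src, mask = self._source_block([[100, 200], [150, 120]])
        target = ProbeGrid(src.intensities.copy())  # equal q75 on both
        out, truth = project_artefact(mask, src, target, factor=2)
        assert out.intensities[0, 0] == pytest.approx(200)
        assert truth.n_spiked == 1

    def test_q75_scale_ratio(self):
        src, mask = self._source_block([[100, 200], [150, 120]])
        target = ProbeGrid(2.0 * src.intensities)
        out, truth = project_artefact(mask, src, target, factor=2)
        assert out.intensities[0, 0] == pytest.approx(400)

    def test_unmasked_block_untouched(self):
        src = ProbeGrid(np.full((4, 4), 100.0))
        m = np.zeros((4, 4), dtype=bool)
        m[0, 0] = True  # only block (0,0) masked
        target = ProbeGrid(np.full((2, 2), 7.0))
        out, truth = project_artefact(FlagMask(m), src, target, factor=2)
        assert out.intensities[0, 1] == 7.0
        assert out.intensities[1, 1] == 7.0
        assert truth.n_spiked == 1

    def test_footprint_exceeding_target_rejected(self):
        src = ProbeGrid(np.full((8, 8), 5.0))
        mask = FlagMask(np.ones((8, 8), dtype=bool))
        target = ProbeGrid(np.full((2, 2), 5.0))
        with pytest.raises(ValueError, match="exceeds"):
            project_artefact(mask, src, target, factor=2)

    def test_connected_stain_stays_connected(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disc = np.hypot(xx - 20, yy - 20) <= 8
        src = ProbeGrid(np.full((40, 40), 100.0))
        target = ProbeGrid(np.full((20, 20), 100.0))
        out, truth = project_artefact(FlagMask(disc), src, target, factor=2)
        labels, n = scipy.ndimage.label(truth.mask())  # 4-connectivity
        assert n == 1
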
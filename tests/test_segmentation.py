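import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohortcna.datatypes import GT_AA, GT_AB, SnpManifest
from cohortcna.segmentation import (
    SegParams,
    aspcf,
    folded_mean_correct,
    mirror_baf,
    pcf,
    pcf_breaks,
    robust_sd,
    segment_sample_lrr,
    segments_to_track,
)


from oracles import pcf_oracle_cost


def pcf_cost(segments, y, gamma):
    y = np.asarray(y, float)
    cost = gamma * (len(segments) - 1)
    for i, j, mean in segments:
        cost += float(np.sum((y[i:j + 1] - mean) ** 2))
    return cost


class TestPcf:
    def test_constant_vector_single_segment(self):
        segs = pcf_breaks(np.full(50, 0.3), gamma=5, kmin=10)
        assert segs == [(0, 49, pytest.approx(0.3))]

    def test_step_split_when_penalty_below_sse_saving(self):
        y = np.concatenate([np.zeros(25), np.ones(25)])
        segs = pcf_breaks(y, gamma=5, kmin=10)
        assert [(s[0], s[1]) for s in segs] == [(0, 24), (25, 49)]
        assert segs[0][2] == pytest.approx(0.0)
        assert segs[1][2] == pytest.approx(1.0)

    def test_step_merged_when_penalty_exceeds_saving(self):
        # one-segment SSE = 50 * 0.25 = 12.5 < gamma = 20
        y = np.concatenate([np.zeros(25), np.ones(25)])
        segs = pcf_breaks(y, gamma=20, kmin=10)
        assert segs == [(0, 49, pytest.approx(0.5))]

    def test_fewer_probes_than_kmin(self):
        with pytest.warns(UserWarning, match="kmin"):
            segs = pcf_breaks(np.array([1.0, 2.0, 3.0]), gamma=5, kmin=10)
        assert segs == [(0, 2, pytest.approx(2.0))]

    @pytest.mark.parametrize("gamma", [1.0, 5.0, 20.0, 80.0])
    @pytest.mark.parametrize("kmin", [1, 3, 10])
    def test_matches_exhaustive_oracle_on_random_signals(self, gamma, kmin):
        rng = np.random.default_rng(int(gamma * 10 + kmin))
        for _ in range(12):
            n = int(rng.integers(2 * kmin, 61))
            y = rng.normal(0, 1, n)
            if rng.random() < 0.5:  # add a real step half the time
                y[n // 2:] += rng.normal(0, 2)
            segs = pcf_breaks(y, gamma, kmin)
            got = pcf_cost(segs, y, gamma)
            want = pcf_oracle_cost(y, gamma, kmin)
            assert got == pytest.approx(want, abs=1e-9)

    def test_breakpoint_count_monotone_in_gamma(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 0.3, 200)
        y[60:130] += 1.0
        counts = [len(pcf_breaks(y, g, 5)) for g in (1, 5, 20, 80, 300)]
        assert counts == sorted(counts, reverse=True)

    def test_fit_error_monotone_in_gamma(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 0.5, 150)

        def sse_of(gamma):
            segs = pcf_breaks(y, gamma, 5)
            return sum(float(np.sum((y[i:j + 1] - m) ** 2))
                       for i, j, m in segs)
        sses = [sse_of(g) for g in (1, 5, 20, 80)]
        assert sses == sorted(sses)

    def test_segment_means_conserve_track_sum(self, toy_manifest):
        rng = np.random.default_rng(13)
        y = rng.normal(0, 0.3, toy_manifest.n_probes)
        segs = segment_sample_lrr(y, toy_manifest,
                                  SegParams(gamma_pcf=10, kmin=5))
        total = sum(s.mean_lrr * s.n_probes for s in segs)
        assert total == pytest.approx(float(y.sum()), abs=1e-6)
        # tiling: no gaps, no overlaps
        for chrom in toy_manifest.chromosomes:
            cs = [s for s in segs if s.chrom == chrom]
            sl = toy_manifest.chrom_slice(chrom)
            assert cs[0].start_idx == sl.start
            assert cs[-1].end_idx == sl.stop - 1
            for a, b in zip(cs, cs[1:]):
                assert b.start_idx == a.end_idx + 1

    def test_missing_probes_inherit_flanking_segment(self, toy_manifest):
        y = np.zeros(toy_manifest.n_probes)
        y[:200][100:] = 1.0
        y[50] = np.nan
        segs = pcf(y[:200], toy_manifest, "chr1", gamma=5, kmin=10)
        track = segments_to_track(segs, toy_manifest.n_probes)
        assert np.isfinite(track[50])
        assert track[50] == pytest.approx(0.0, abs=1e-9)


class TestMirrorBaf:
    def test_examples(self):
        baf = np.array([0.5, 0.2, 0.8, 0.01])
        gt = np.array([GT_AB, GT_AB, GT_AB, GT_AA], dtype=np.int8)
        m = mirror_baf(baf, gt)
        np.testing.assert_allclose(m[:3], [0.5, 0.8, 0.8])
        assert np.isnan(m[3])

    @given(st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, b):
        gt = np.array([GT_AB], dtype=np.int8)
        m1 = mirror_baf(np.array([b]), gt)[0]
        m2 = mirror_baf(np.array([1 - b]), gt)[0]
        assert m1 == pytest.approx(m2, abs=1e-12)
        assert m1 >= 0.5


def _aspcf_manifest(n):
    return SnpManifest(pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)], "chrom": "chr1",
        "pos": (np.arange(n) + 1) * 10_000, "gc_fraction": 0.45}))


class TestAspcf:
    def test_constant_tracks_single_segment(self):
        n = 60
        man = _aspcf_manifest(n)
        segs = aspcf(np.zeros(n), np.full(n, 0.5), man, "chr1",
                     penalty=0.8, kmin=10)
        assert len(segs) == 1
        assert segs[0].n_probes == n
        assert segs[0].n_het == n

    def test_joint_step_shared_breakpoint(self):
        n = 60
        man = _aspcf_manifest(n)
        lrr = np.where(np.arange(n) < 30, 0.0, 0.3)
        mbaf = np.where(np.arange(n) < 30, 0.5, 0.75)
        segs = aspcf(lrr, mbaf, man, "chr1", penalty=0.1, kmin=10)
        assert len(segs) == 2
        assert segs[0].end_idx == 29
        assert segs[1].start_idx == 30
        assert segs[0].mean_lrr == pytest.approx(0.0, abs=1e-9)
        assert segs[1].mean_mbaf == pytest.approx(0.75, abs=1e-9)

    def test_baf_only_step_detected(self):
        # copy-neutral LOH pattern: flat LRR, mirrored BAF jumps to 1.0
        n = 60
        man = _aspcf_manifest(n)
        lrr = np.zeros(n)
        mbaf = np.where(np.arange(n) < 30, 0.5, 1.0)
        segs = aspcf(lrr, mbaf, man, "chr1", penalty=0.1, kmin=10)
        assert len(segs) == 2
        assert segs[1].start_idx == 30

    def test_no_het_probes_flagged(self):
        n = 40
        man = _aspcf_manifest(n)
        with pytest.warns(UserWarning, match="heterozygous"):
            segs = aspcf(np.zeros(n), np.full(n, np.nan), man, "chr1")
        assert len(segs) == 1
        assert segs[0].n_het == 0

    def test_breakpoints_constrained_to_het_grid(self):
        n = 80
        man = _aspcf_manifest(n)
        lrr = np.where(np.arange(n) < 40, 0.0, 0.5)
        mbaf = np.full(n, np.nan)
        mbaf[::4] = 0.5  # het probes every 4th position
        mbaf[40::4] = 0.9
        segs = aspcf(lrr, mbaf, man, "chr1", penalty=0.1, kmin=5)
        assert len(segs) == 2
        assert segs[1].start_idx == 40  # 40 is on the het grid


class TestFoldedMeanCorrect:
    def test_identity_far_from_half(self):
        # band well separated from 0.5: folding has no effect
        assert folded_mean_correct(0.3, 0.3 ** 2 + 1e-8) == pytest.approx(
            0.3, abs=1e-3)

    def test_balanced_band_debiased_to_zero(self):
        # pure noise around 0.5: E|x| = sd*sqrt(2/pi), E[x^2] = sd^2
        sd = 0.03
        d_mean = sd * np.sqrt(2 / np.pi)
        assert folded_mean_correct(d_mean, sd ** 2) == pytest.approx(0.0)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(14)
        delta, sd = 0.02, 0.03
        x = np.abs(rng.normal(delta, sd, 200_000))
        est = folded_mean_correct(float(x.mean()), float((x ** 2).mean()))
        assert est == pytest.approx(delta, abs=0.003)


def test_robust_sd_ignores_level_shifts():
    rng = np.random.default_rng(15)
    y = rng.normal(0, 0.1, 2000)
    y[1000:] += 5.0  # one huge step should not inflate the noise estimate
    assert robust_sd(y) == pytest.approx(0.1, rel=0.1)
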
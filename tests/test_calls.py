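import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohortcna.calls import (
    CallTrack,
    STATE_GAIN,
    STATE_LOSS,
    STATE_NEUTRAL,
    annotate_regions,
    call_ascat,
    call_threshold,
    cohort_frequencies,
    gene_hit_counts,
    recurrent_regions,
)
from cohortcna.datatypes import AscatProfile, FrequencyTrack, Segment


def _seg(start, end, mean, n_het=5, chrom="chr1"):
    return Segment(chrom=chrom, start_idx=start, end_idx=end,
                   start_bp=(start + 1) * 50_000, end_bp=(end + 1) * 50_000,
                   n_probes=end - start + 1, mean_lrr=mean, n_het=n_het)


class TestCallThreshold:
    @pytest.mark.parametrize("mean,expected", [
        (0.06, STATE_GAIN),
        (0.05, STATE_NEUTRAL),   # strictly "above 0.05"
        (-0.05, STATE_NEUTRAL),
        (-0.051, STATE_LOSS),
        (-0.04, STATE_NEUTRAL),
    ])
    def test_thresholds(self, mean, expected):
        track = call_threshold([_seg(0, 9, mean)], 10, "s")
        assert (track.state == expected).all()


def _profile(segments_with_cn, psi, sample_id="s"):
    segs = [( _seg(a, b, 0.0, n_het=h), na, nb)
            for (a, b, na, nb, h) in segments_with_cn]
    return AscatProfile(sample_id=sample_id, rho=0.8, psi=psi, goodness=1.0,
                        segments=segs)


class TestCallAscat:
    def test_cnloh_neutral_total(self):
        p = _profile([(0, 9, 2, 0, 5)], psi=2.0)
        t = call_ascat(p, 10)
        assert (t.state == STATE_NEUTRAL).all()
        assert t.loh.all() and t.cnloh.all()
        assert not t.homdel.any()

    def test_single_copy_loss_with_loh(self):
        p = _profile([(0, 9, 1, 0, 5)], psi=2.0)
        t = call_ascat(p, 10)
        assert (t.state == STATE_LOSS).all()
        assert t.loh.all() and not t.cnloh.any()

    def test_homdel_implies_loss_and_loh(self):
        p = _profile([(0, 9, 0, 0, 5)], psi=2.0)
        t = call_ascat(p, 10)
        assert (t.state == STATE_LOSS).all()
        assert t.loh.all() and t.homdel.all()

    def test_gain_relative_to_rounded_ploidy(self):
        p = _profile([(0, 4, 3, 1, 5), (5, 9, 2, 2, 5)], psi=3.6)
        t = call_ascat(p, 10)
        # reference = round(3.6) = 4
        assert (t.state[:5] == STATE_NEUTRAL).all()
        assert (t.state[5:] == STATE_NEUTRAL).all()

    def test_loh_requires_het_probe(self):
        p = _profile([(0, 9, 2, 0, 0)], psi=2.0)
        t = call_ascat(p, 10)
        assert not t.loh.any()


def _track(sample_id, state, loh=None):
    return CallTrack(sample_id=sample_id, state=np.asarray(state, np.int8),
                     loh=None if loh is None else np.asarray(loh, bool))


class TestCohortFrequencies:
    def test_counting(self):
        tracks = [_track(f"s{i}", [1 if i < 3 else 0, 0]) for i in range(10)]
        f = cohort_frequencies(tracks)["all"]
        assert f.gain_freq[0] == pytest.approx(0.3)
        assert f.gain_freq[1] == 0.0

    def test_neutral_sample_contributes_nothing(self):
        tracks = [_track("a", [0, 0]), _track("b", [1, -1])]
        f = cohort_frequencies(tracks)["all"]
        assert f.gain_freq[0] == 0.5
        assert f.loss_freq[1] == 0.5

    def test_empty_group_is_error(self):
        tracks = [_track("a", [0])]
        with pytest.raises(ValueError, match="ghosts"):
            cohort_frequencies(tracks, groups={"ghosts": ["nope"]})

    @given(st.lists(st.tuples(st.sampled_from([-1, 0, 1]),
                              st.sampled_from([-1, 0, 1])),
                    min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_group_frequencies_average_to_overall(self, states):
        tracks = [_track(f"s{i}", list(s)) for i, s in enumerate(states)]
        half = len(tracks) // 2
        ga = [t.sample_id for t in tracks[:half]]
        gb = [t.sample_id for t in tracks[half:]]
        if not ga or not gb:
            return
        fr = cohort_frequencies(tracks, groups={"a": ga, "b": gb})
        na, nb = fr["a"].n_samples, fr["b"].n_samples
        combined = (fr["a"].gain_freq * na + fr["b"].gain_freq * nb) / (na + nb)
        np.testing.assert_allclose(combined, fr["all"].gain_freq, atol=1e-12)

    def test_permutation_invariant_in_sample_order(self):
        rng = np.random.default_rng(0)
        tracks = [_track(f"s{i}", rng.integers(-1, 2, 20)) for i in range(8)]
        f1 = cohort_frequencies(tracks)["all"]
        f2 = cohort_frequencies(tracks[::-1])["all"]
        np.testing.assert_array_equal(f1.gain_freq, f2.gain_freq)


class TestRecurrentRegions:
    def _freq(self, manifest, gain, n):
        z = np.zeros(manifest.n_probes)
        return FrequencyTrack(group="all", n_samples=n, gain_freq=gain,
                              loss_freq=z, loh_freq=z)

    def test_count_rule_inclusive_at_20(self, toy_manifest):
        n = toy_manifest.n_probes
        gain = np.zeros(n)
        gain[10:30] = 20 / 113
        ft = self._freq(toy_manifest, gain, 113)
        regs = recurrent_regions(ft, toy_manifest, mode="count", min_count=20,
                                 directions=("gain",))
        assert len(regs) == 1
        gain[10:30] = 19 / 113
        regs = recurrent_regions(ft, toy_manifest, mode="count", min_count=20,
                                 directions=("gain",))
        assert regs == []

    def test_fraction_rule_inclusive(self, toy_manifest):
        gain = np.zeros(toy_manifest.n_probes)
        gain[5:15] = 0.20
        ft = self._freq(toy_manifest, gain, 10)
        regs = recurrent_regions(ft, toy_manifest, mode="fraction",
                                 threshold=0.20, directions=("gain",))
        assert len(regs) == 1
        # 1 of 10 carriers does not qualify
        gain[5:15] = 0.10
        assert recurrent_regions(ft, toy_manifest, mode="fraction",
                                 threshold=0.20, directions=("gain",)) == []

    def test_gap_splits_runs(self, toy_manifest):
        gain = np.zeros(toy_manifest.n_probes)
        gain[10:20] = 0.5
        gain[21:30] = 0.5  # probe 20 below threshold
        ft = self._freq(toy_manifest, gain, 10)
        regs = recurrent_regions(ft, toy_manifest, mode="fraction",
                                 directions=("gain",))
        assert len(regs) == 2

    def test_monotone_in_threshold(self, toy_manifest):
        rng = np.random.default_rng(1)
        gain = rng.random(toy_manifest.n_probes)
        ft = self._freq(toy_manifest, gain, 100)

        def n_probes_called(thr):
            regs = recurrent_regions(ft, toy_manifest, mode="fraction",
                                     threshold=thr, directions=("gain",))
            return sum(r.end_idx - r.start_idx + 1 for r in regs)
        counts = [n_probes_called(t) for t in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)


class TestAnnotateRegions:
    def _regions(self, toy_manifest):
        from cohortcna.datatypes import RecurrentRegion
        return [RecurrentRegion(chrom="chr1", start_bp=201, end_bp=300,
                                direction="gain", peak_freq=0.5,
                                n_samples_affected=5)]

    def test_empty_gene_file(self, toy_manifest):
        genes = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        regs = annotate_regions(self._regions(toy_manifest), genes)
        assert regs[0].genes == []

    def test_half_open_abutment_no_overlap(self, toy_manifest):
        # gene [100,200) vs region [200,300) in 0-based half-open terms
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                              "end": [200], "name": ["G"]})
        regs = annotate_regions(self._regions(toy_manifest), genes)
        assert regs[0].genes == []

    def test_one_bp_overlap_reported(self, toy_manifest):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [150],
                              "end": [250], "name": ["G"]})
        regs = annotate_regions(self._regions(toy_manifest), genes)
        assert regs[0].genes == ["G"]

    def test_gene_list_sorted_by_start(self, toy_manifest):
        genes = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [260, 210], "end": [280, 240],
                              "name": ["B", "A"]})
        regs = annotate_regions(self._regions(toy_manifest), genes)
        assert regs[0].genes == ["A", "B"]


class TestGeneHitCounts:
    def test_homdel_counting_and_missing(self, toy_manifest):
        n = toy_manifest.n_probes
        tracks = []
        for i in range(7):
            state = np.zeros(n, np.int8)
            homdel = np.zeros(n, bool)
            if i < 5:
                state[:10] = STATE_LOSS
                homdel[:10] = True
            tracks.append(CallTrack(sample_id=f"s{i}", state=state,
                                    homdel=homdel))
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr9"], "start": [60_000, 100],
            "end": [200_000, 500], "name": ["PTEN_like", "OFF_MANIFEST"]})
        hd = gene_hit_counts(tracks, genes, toy_manifest, states=("homdel",))
        assert hd["PTEN_like"] == 5
        assert np.isnan(hd["OFF_MANIFEST"])

    def test_homdel_count_never_exceeds_loss_count(self, toy_manifest):
        rng = np.random.default_rng(2)
        n = toy_manifest.n_probes
        tracks = []
        for i in range(10):
            homdel = rng.random(n) < 0.05
            state = np.where(homdel | (rng.random(n) < 0.1),
                             STATE_LOSS, STATE_NEUTRAL).astype(np.int8)
            tracks.append(CallTrack(sample_id=f"s{i}", state=state,
                                    homdel=homdel))
        genes = pd.DataFrame({"chrom": ["chr1", "chr2"],
                              "start": [0, 1_000_000],
                              "end": [2_000_000, 3_000_000],
                              "name": ["G1", "G2"]})
        loss = gene_hit_counts(tracks, genes, toy_manifest, states=("loss",))
        hd = gene_hit_counts(tracks, genes, toy_manifest, states=("homdel",))
        assert (hd <= loss).all()
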
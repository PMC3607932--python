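"""T-RFLP pipeline: filtering, replicate QC, alignment, normalization, consensus."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sludge_archaea.synthetic import (
    CommunityScenario,
    render_electropherograms,
    skewed_weights,
    write_peak_table,
)
from sludge_archaea.trflp import (
    Peak,
    RawProfile,
    align_peaks,
    consensus,
    filter_peaks,
    normalize_profiles,
    read_peak_table,
    run_pipeline,
    select_replicates,
)


def profile(heights_sizes, sample="S", enzyme="AluI", rep=1):
    peaks = [Peak(size=s, height=h, area=h) for s, h in heights_sizes]
    return RawProfile(sample, enzyme, rep, peaks)


class TestFilterPeaks:
    def test_size_window_and_floor(self):
        prof = profile([(40, 500), (100, 50), (100, 60), (1021, 70), (1020, 70)])
        kept = filter_peaks(prof)
        assert [(p.size, p.height) for p in kept.peaks] == [(100, 60), (1020, 70)]
        assert kept.total_fluorescence == pytest.approx(130)


class TestSelectReplicates:
    def test_top_two_kept(self):
        reps = [profile([(100, tf)], rep=i + 1) for i, tf in enumerate([600, 550, 400])]
        sel = select_replicates(reps)
        assert not sel.rejected
        assert [r.total_fluorescence for r in sel.selected] == [600, 550]

    def test_single_passing_replicate_rejects_sample(self):
        reps = [profile([(100, tf)], rep=i + 1) for i, tf in enumerate([600, 450, 400])]
        assert select_replicates(reps).rejected

    def test_tie_broken_by_replicate_id(self):
        reps = [profile([(100, tf)], rep=i + 1) for i, tf in enumerate([600, 600, 100])]
        sel = select_replicates(reps)
        assert [r.replicate_id for r in sel.selected] == [1, 2]


class TestAlignPeaks:
    def test_within_gap_merge(self):
        a = profile([(183.1, 100)], rep=1)
        b = profile([(183.4, 100)], rep=2)
        binned = align_peaks([a, b])
        assert len(binned[0].bin_sizes) == 1

    def test_beyond_gap_split(self):
        binned = align_peaks([profile([(183.0, 100)]), profile([(185.0, 100)], rep=2)])
        assert len(binned[0].bin_sizes) == 2

    def test_moving_average_traced_example(self):
        # 100.0 starts; 100.6 joins (gap 0.6, mean -> 100.3); 101.4 is 1.1
        # beyond the running mean -> new bin
        binned = align_peaks(
            [profile([(100.0, 10), (101.4, 10)]), profile([(100.6, 10)], rep=2)]
        )
        assert len(binned[0].bin_sizes) == 2
        assert binned[0].bin_sizes[0] == pytest.approx(100.3)
        assert binned[0].bin_sizes[1] == pytest.approx(101.4)

    def test_same_profile_peaks_in_bin_are_summed(self):
        binned = align_peaks([profile([(100.0, 30), (100.5, 10)])])
        assert len(binned[0].bins) == 1
        s, h, a = binned[0].bins[0]
        assert h == pytest.approx(40)
        assert s == pytest.approx((100.0 * 30 + 100.5 * 10) / 40)


class TestNormalizeProfiles:
    def test_equal_profiles_fixed_point(self):
        profs = [profile([(100, 300), (200, 700)], rep=i) for i in (1, 2)]
        out, removed = normalize_profiles(profs)
        assert removed == [0.0, 0.0]
        for prof in out:
            assert [p.height for p in prof.peaks] == [300, 700]

    def test_hand_iterated_example(self):
        a = profile([(100, 1000)], rep=1)
        b = profile([(100, 1910), (200, 90)], rep=2)
        out, removed = normalize_profiles([a, b])
        assert [p.height for p in out[0].peaks] == [pytest.approx(955)]
        assert [p.height for p in out[1].peaks] == [pytest.approx(955)]
        assert removed[0] == 0.0
        assert removed[1] == pytest.approx(0.045)

    def test_single_profile_unchanged(self):
        out, removed = normalize_profiles([profile([(100, 600)])])
        assert out[0].peaks[0].height == 600
        assert removed == [0.0]

    def test_never_increases_heights(self, rng):
        for _ in range(10):
            profs = [
                profile([(50 + 10 * j, float(h)) for j, h in
                         enumerate(rng.uniform(51, 500, size=rng.integers(1, 6)))],
                        rep=i)
                for i in range(3)
            ]
            originals = [{p.size: p.height for p in prof.peaks} for prof in profs]
            out, removed = normalize_profiles(profs)
            for prof, orig, f in zip(out, originals, removed):
                for p in prof.peaks:
                    assert p.height <= orig[p.size] + 1e-9
                # a profile losing every peak has removed fraction exactly 1
                assert 0.0 <= f <= 1.0
                if prof.peaks:
                    assert f < 1.0

    def test_fixed_point_equal_total_fluorescence(self, rng):
        """After convergence every surviving profile carries the same TF."""
        profs = [
            profile([(60 + 5 * j, float(h)) for j, h in
                     enumerate(rng.uniform(40, 800, size=5))], rep=i)
            for i in range(3)
        ]
        out, _ = normalize_profiles(profs)
        tfs = [p.total_fluorescence for p in out if p.peaks]
        assert np.allclose(tfs, tfs[0])


class TestConsensus:
    def _binned(self, heights, rep):
        profs = [profile([(100.0, h1), (200.0, h2)], rep=rep)
                 for h1, h2 in [heights]]
        return profs[0]

    def test_identical_profiles_preserved(self):
        a, b = [profile([(100.0, 80), (200.0, 20)], rep=i) for i in (1, 2)]
        cons = consensus(*align_peaks([a, b]))
        assert [round(x[3], 9) for x in cons.bins] == [0.8, 0.2]
        assert sum(x[3] for x in cons.bins) == pytest.approx(1.0)

    def test_unshared_bin_dropped(self):
        a = profile([(100.0, 80), (300.0, 20)], rep=1)
        b = profile([(100.0, 80)], rep=2)
        cons = consensus(*align_peaks([a, b]))
        assert cons.sizes == [100.0]

    def test_mean_heights_define_abundance(self):
        a = profile([(100.0, 80), (200.0, 20)], rep=1)
        b = profile([(100.0, 60), (200.0, 40)], rep=2)
        cons = consensus(*align_peaks([a, b]))
        assert [x[1] for x in cons.bins] == [70, 30]
        assert [x[3] for x in cons.bins] == [pytest.approx(0.7), pytest.approx(0.3)]


class TestRunPipeline:
    def test_full_loop_recovers_weights(self, scenario):
        consensi, qc = run_pipeline(render_electropherograms(scenario))
        assert len(consensi) == 2 and not qc["rejected"]
        w = np.sort(np.asarray(scenario.abundance_weights))[::-1]
        for cons in consensi:
            ab = np.sort([b[3] for b in cons.bins])[::-1]
            assert np.allclose(ab, w, atol=1e-9)
            true_sizes = sorted(
                float(t.true_trf[cons.enzyme] - scenario.drift) for t in scenario.taxa
            )
            assert np.allclose(cons.sizes, true_sizes, atol=1e-9)

    def test_low_fluorescence_replicate_tolerated(self, taxa5):
        sc = CommunityScenario(taxa=taxa5, abundance_weights=skewed_weights(5),
                               drift=0, noise_sd=0.0, n_replicates=3, seed=2,
                               spurious_rate=0.0)
        profiles = render_electropherograms(sc)
        # cripple replicate 3 of each enzyme below the 500 FU gate
        for prof in profiles:
            if prof.replicate_id == 3:
                prof.peaks = [Peak(p.size, p.height * 0.1, p.area * 0.1)
                              for p in prof.peaks]
        consensi, qc = run_pipeline(profiles)
        assert len(consensi) == 2
        assert not qc["rejected"]

    def test_empty_table(self):
        consensi, qc = run_pipeline([])
        assert consensi == [] and qc["n_samples"] == 0

    def test_row_order_invariance(self, tmp_path, scenario):
        profiles = render_electropherograms(scenario)
        path_a = tmp_path / "a.csv"
        path_b = tmp_path / "b.csv"
        write_peak_table(profiles, path_a)
        import pandas as pd

        df = pd.read_csv(path_a).sample(frac=1.0, random_state=0)
        df.to_csv(path_b, index=False)
        cons_a, _ = run_pipeline(path_a)
        cons_b, _ = run_pipeline(path_b)
        assert [(c.sample_id, c.enzyme, c.bins) for c in cons_a] == \
               [(c.sample_id, c.enzyme, c.bins) for c in cons_b]

    @given(factor=st.floats(min_value=0.5, max_value=5.0))
    def test_common_scaling_leaves_abundances(self, factor):
        base = [
            profile([(100.0, 4000.0), (200.0, 3000.0)], rep=1),
            profile([(100.0, 5000.0), (200.0, 3500.0)], rep=2),
        ]
        scaled = [
            RawProfile(p.sample_id, p.enzyme, p.replicate_id,
                       [Peak(pk.size, pk.height * factor, pk.area * factor)
                        for pk in p.peaks])
            for p in base
        ]
        cons_a, _ = run_pipeline(base)
        cons_b, _ = run_pipeline(scaled)
        ab_a = [b[3] for b in cons_a[0].bins]
        ab_b = [b[3] for b in cons_b[0].bins]
        assert np.allclose(ab_a, ab_b, atol=1e-9)

    def test_malformed_csv_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,enzyme,replicate,size_bases,height_fu,area\n"
            "S1,AluI,1,100.0,200.0,200.0\n"
            "S1,AluI,1,oops,200.0,200.0\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            read_peak_table(path)
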
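"""Community dynamics: Bray-Curtis, baseline distances, TRF identification, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from sludge_archaea.digest import DigestRecord, DigestStatus, TRFPrediction
from sludge_archaea.dynamics import (
    OUT_OF_RANGE,
    ProfileSeries,
    TRFCombination,
    bray_curtis,
    build_profile_series,
    correlate,
    distance_to_baseline,
    identify_combinations,
)
from sludge_archaea.trflp import ConsensusProfile


def series_from_rows(rows, dates=None, enzyme="AluI", cols=None):
    dates = dates or pd.date_range("2003-05-16", periods=len(rows), freq="14D")
    cols = cols or [100.0 + 10 * i for i in range(len(rows[0]))]
    return ProfileSeries(enzyme=enzyme,
                         abundances=pd.DataFrame(rows, index=dates, columns=cols))


class TestBrayCurtis:
    def test_identity_zero(self):
        assert bray_curtis([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_disjoint_support_is_100(self):
        assert bray_curtis([1, 0], [0, 1]) == pytest.approx(100.0)

    def test_direct_formula(self):
        assert bray_curtis([0.8, 0.2], [0.6, 0.4]) == pytest.approx(20.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_matches_scipy(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            assert bray_curtis(p, q) == pytest.approx(100 * scipy_braycurtis(p, q))

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(50):
            p, q, r = (rng.dirichlet(np.ones(5)) for _ in range(3))
            dpq, dqr, dpr = bray_curtis(p, q), bray_curtis(q, r), bray_curtis(p, r)
            assert 0 <= dpq <= 100
            assert dpq == pytest.approx(bray_curtis(q, p))
            assert dpr <= dpq + dqr + 1e-9


class TestDistanceToBaseline:
    def test_constant_series_all_zero(self):
        s = series_from_rows([[0.7, 0.3]] * 4)
        assert all(d == pytest.approx(0.0) for _, d in distance_to_baseline(s))

    def test_single_spike_and_return(self):
        s = series_from_rows([[0.7, 0.3], [0.7, 0.3], [0.2, 0.8], [0.7, 0.3]])
        dists = [d for _, d in distance_to_baseline(s)]
        assert dists[0] == 0.0 and dists[1] == 0.0 and dists[3] == pytest.approx(0.0)
        assert dists[2] == pytest.approx(50.0)  # |0.5| + |0.5| over 2

    def test_hand_computed_values(self):
        s = series_from_rows([[1.0, 0.0], [0.9, 0.1], [0.5, 0.5]])
        dists = [d for _, d in distance_to_baseline(s)]
        assert dists == [pytest.approx(0.0), pytest.approx(10.0), pytest.approx(50.0)]

    def test_invariant_under_bin_relabeling(self):
        rows = [[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]]
        a = series_from_rows(rows, cols=[100.0, 110.0, 120.0])
        b = series_from_rows(rows, cols=[77.0, 300.0, 901.0])
        assert [d for _, d in distance_to_baseline(a)] == \
               [d for _, d in distance_to_baseline(b)]


def db_record(seq_id, alui, rsai, taxon):
    def entry(v):
        if v is None:
            return TRFPrediction(DigestStatus.ND)
        if not 50 <= v <= 1020:
            return TRFPrediction(DigestStatus.OUT_OF_RANGE, v)
        return TRFPrediction(DigestStatus.OK, v)

    return DigestRecord(seq_id, {"AluI": entry(alui), "RsaI": entry(rsai)}, taxon=taxon)


class TestIdentifyCombinations:
    # fixture database encoding dominant observed/predicted pairs of the study:
    # the acetoclastic methanogen gives predicted (180, 80) for observed (176, 74)
    DB = [
        db_record("seq1", 180, 80, "Methanosaeta"),
        db_record("seq2", 188, 80, "Methanosaeta"),
        db_record("seq3", 188, 242, "Methanosaeta"),
        db_record("seq4", 1040, 80, "Methanosarcina"),
        db_record("seq5", None, 613, "Thermoplasmatales"),
    ]

    def test_within_window_candidate(self):
        combo = TRFCombination(176, 74)
        result = identify_combinations([combo], self.DB)
        assert result[combo] == ["Methanosaeta"]  # seq1: drifts 4 and 6

    def test_excessive_drift_not_candidate(self):
        combo = TRFCombination(176, 74)
        result = identify_combinations([combo], [self.DB[1]])
        assert result[combo] == []  # AluI drift 12

    def test_out_of_range_slot_matches_nd_or_oor(self):
        combo = TRFCombination(OUT_OF_RANGE, 75)
        result = identify_combinations([combo], self.DB)
        assert result[combo] == ["Methanosarcina"]

    def test_empty_database(self):
        combo = TRFCombination(184, 238)
        assert identify_combinations([combo], [])[combo] == []

    def test_monotone_in_drift_window(self):
        combos = [TRFCombination(176, 74), TRFCombination(184, 238),
                  TRFCombination(OUT_OF_RANGE, 75)]
        narrow = identify_combinations(combos, self.DB, drift_window=(4, 6))
        wide = identify_combinations(combos, self.DB, drift_window=(3, 8))
        for combo in combos:
            assert set(narrow[combo]) <= set(wide[combo])


class TestCorrelate:
    def params(self, values, name="temperature", dates=None):
        dates = dates if dates is not None else pd.date_range(
            "2003-05-16", periods=len(values), freq="14D")
        return pd.DataFrame({name: values}, index=dates)

    def test_exact_linear_relation(self):
        x = np.linspace(10, 20, 8)
        s = series_from_rows([[v, 1 - v] for v in np.linspace(0.2, 0.9, 8)])
        results = correlate(s, self.params(np.linspace(0.2, 0.9, 8) * 10 + 3))
        first = [r for r in results if r.trf_id.endswith("100")][0]
        assert first.r == pytest.approx(1.0)
        assert first.p < 1e-9
        assert first.stars == "***"

    def test_closed_form_five_points(self):
        a = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        x = np.array([12.0, 15.0, 13.0, 19.0, 16.0])
        s = series_from_rows([[v, 1 - v] for v in a])
        res = [r for r in correlate(s, self.params(x)) if r.trf_id.endswith("100")][0]
        ac, xc = a - a.mean(), x - x.mean()
        r_hand = (ac @ xc) / np.sqrt((ac @ ac) * (xc @ xc))
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        t_hand = r_hand * np.sqrt(3 / (1 - r_hand**2))
        assert res.t == pytest.approx(t_hand, abs=1e-9)
        from scipy import stats

        assert res.p == pytest.approx(2 * stats.t.sf(abs(t_hand), 3), abs=1e-12)

    def test_zero_variance_flagged(self):
        s = series_from_rows([[0.5, 0.5]] * 5)
        results = correlate(s, self.params([12, 14, 13, 15, 16]))
        assert all(r.r is None and r.flagged == "zero variance" for r in results)

    def test_observation_count_is_presence_count(self):
        s = series_from_rows([[0.0, 1.0], [0.4, 0.6], [0.5, 0.5], [0.0, 1.0]])
        results = correlate(s, self.params([12, 14, 13, 15]))
        first = [r for r in results if r.trf_id.endswith("100")][0]
        assert first.n == 2 and first.n_pairs == 4


class TestBuildProfileSeries:
    def make_consensus(self, sizes_abunds, sample, enzyme="AluI", tf=1000.0):
        bins = [(s, a * tf, a * tf, a) for s, a in sizes_abunds]
        return ConsensusProfile(sample, enzyme, bins, tf)

    def test_rows_sum_to_one_and_bins_shared(self):
        dated = [
            ("2003-05-16", self.make_consensus([(100.0, 0.8), (200.0, 0.2)], "S1")),
            ("2003-05-30", self.make_consensus([(100.2, 0.6), (200.3, 0.4)], "S2")),
        ]
        series = build_profile_series(dated, "AluI")
        assert series.abundances.shape == (2, 2)
        assert np.allclose(series.abundances.sum(axis=1), 1.0)

    def test_low_tf_consensus_excluded(self):
        dated = [
            ("2003-05-16", self.make_consensus([(100.0, 1.0)], "S1", tf=1000.0)),
            ("2003-05-30", self.make_consensus([(100.0, 1.0)], "S2", tf=1000.0)),
            ("2003-06-13", self.make_consensus([(100.0, 1.0)], "S3", tf=100.0)),
        ]
        series = build_profile_series(dated, "AluI")
        assert len(series.abundances) == 2
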
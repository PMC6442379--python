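"""Border signal profiles, directionality scores and rank/ECDF tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hicarch import signal_tracks as st
from hicarch import simulate
from hicarch.tads import Border


def _borders(positions, chrom="c"):
    return [Border(chrom, int(p), 0, 0.1, 0.001, 0.001) for p in positions]


class TestProfiles:
    def test_constant_track(self):
        track = {"c": np.full(10_000, 3.0)}
        prof = st.profile_around_borders(track, _borders([5000]), flank=1000)
        assert np.allclose(prof.mean_profile, 3.0)
        assert prof.peaks.tolist() == [3.0]

    def test_mean_of_two_borders_and_peaks(self):
        track = {"c": np.zeros(10_000)}
        track["c"][2000] = 3.0
        track["c"][7000] = 5.0
        prof = st.profile_around_borders(track, _borders([2000, 7000]),
                                         flank=100)
        assert sorted(prof.peaks.tolist()) == [3.0, 5.0]
        assert prof.mean_profile[100] == 4.0   # centre bp averages the peaks

    def test_border_near_end_excluded(self):
        track = {"c": np.ones(5000)}
        prof = st.profile_around_borders(track, _borders([100, 2500]),
                                         flank=1000)
        assert prof.n_excluded == 1
        assert prof.vectors.shape[0] == 1


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = st.peak_compare_mannwhitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = st.peak_compare_mannwhitney([1, 2, 5], [1, 2, 5])
        assert p == 1.0

    def test_shift_invariance(self):
        a, b = [1.0, 3.0, 8.0], [2.0, 4.0, 4.0]
        u1, p1 = st.peak_compare_mannwhitney(a, b)
        u2, p2 = st.peak_compare_mannwhitney([x + 7 for x in a],
                                             [x + 7 for x in b])
        assert u1 == u2 and p1 == p2

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(3, 3), (4, 5), (6, 6), (2, 7)]:
            a = rng.integers(0, 6, n1).astype(float)   # ties likely
            b = rng.integers(0, 6, n2).astype(float)
            u_obs, p_impl = st.peak_compare_mannwhitney(a, b)
            # independent oracle: U by pairwise comparison counting
            pooled = np.concatenate([a, b])

            def u_stat(idx_a):
                aa = pooled[list(idx_a)]
                bb = pooled[[i for i in range(n1 + n2) if i not in idx_a]]
                return sum((x > y) + 0.5 * (x == y)
                           for x in aa for y in bb)

            mid = n1 * n2 / 2
            dev = abs(u_stat(tuple(range(n1))) - mid)
            hits = total = 0
            for comb in itertools.combinations(range(n1 + n2), n1):
                total += 1
                if abs(u_stat(comb) - mid) >= dev - 1e-12:
                    hits += 1
            assert p_impl == pytest.approx(hits / total)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        _, p = st.peak_compare_mannwhitney(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(ref)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            st.peak_compare_mannwhitney([], [1.0])


class TestKolmogorovSmirnov:
    def test_fully_separated_exact(self):
        d, p = st.ks_compare([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert d == 1.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        d, _ = st.ks_compare([1.0, 2.0], [1.0, 2.0])
        assert d == 0.0

    def test_monotone_transform_invariance(self):
        a, b = [0.5, 1.5, 4.0], [1.0, 2.0, 9.0]
        d1, p1 = st.ks_compare(a, b)
        d2, p2 = st.ks_compare(np.exp(a), np.exp(b))
        assert d1 == d2 and p1 == p2

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        for n1, n2 in [(3, 3), (5, 4), (6, 6)]:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            d_obs, p_impl = st.ks_compare(a, b)
            pooled = np.concatenate([a, b])

            def ecdf_d(idx_a):
                aa = np.sort(pooled[list(idx_a)])
                bb = np.sort(pooled[[i for i in range(n1 + n2)
                                     if i not in idx_a]])
                grid = np.sort(pooled)
                fa = np.searchsorted(aa, grid, "right") / n1
                fb = np.searchsorted(bb, grid, "right") / n2
                return np.abs(fa - fb).max()

            hits = total = 0
            for comb in itertools.combinations(range(n1 + n2), n1):
                total += 1
                if ecdf_d(comb) >= d_obs - 1e-12:
                    hits += 1
            assert p_impl == pytest.approx(hits / total)


class TestDirectionality:
    def _tracks(self, plus_val, minus_val, length=10_000):
        plus = {"c": np.zeros(length)}
        minus = {"c": np.zeros(length)}
        plus["c"][5500:6000] = plus_val     # [pos+500, pos+1000) for pos 5000
        minus["c"][4000:4500] = minus_val   # [pos-1000, pos-500)
        return st.StrandTrackPair(plus, minus)

    def test_symmetric_signal_zero_score(self):
        recs = st.directionality_score(self._tracks(0.1, 0.1),
                                       _borders([5000]))
        assert recs["score"].iloc[0] == 0.0

    def test_three_fold_ratio(self):
        recs = st.directionality_score(self._tracks(0.6, 0.2),
                                       _borders([5000]), pseudocount=1e-12)
        assert recs["score"].iloc[0] == pytest.approx(math.log10(3), abs=1e-9)

    def test_zero_plus_with_unit_pseudocount(self):
        recs = st.directionality_score(self._tracks(0.0, 0.2),
                                       _borders([5000]), pseudocount=1.0)
        assert recs["score"].iloc[0] == pytest.approx(
            math.log10(1 / 101), abs=1e-9)

    def test_out_of_bounds_border_skipped(self):
        recs = st.directionality_score(self._tracks(1, 1),
                                       _borders([400, 5000]))
        assert len(recs) == 1

    def test_cutoff_derivation_and_boundary(self):
        assert st.divergence_cutoff() == 0.47
        recs = np.array([0.0, 0.5])
        import pandas as pd
        df = pd.DataFrame({"score": [0.0, 0.5]})
        flagged, pct = st.classify_bidirectional(df)
        assert pct == 50.0
        df2 = pd.DataFrame({"score": [0.47, -0.3]})
        flagged2, _ = st.classify_bidirectional(df2)
        assert flagged2["bidirectional"].tolist() == [False, True]

    def test_signed_option(self):
        import pandas as pd
        df = pd.DataFrame({"score": [-0.6, 0.3]})
        flagged, _ = st.classify_bidirectional(df, signed=True)
        assert flagged["bidirectional"].tolist() == [True, True]


class TestStrandRatioProfile:
    def test_equal_strands_zero_profile(self):
        tracks = st.StrandTrackPair({"c": np.ones(6000)},
                                    {"c": np.ones(6000)})
        prof = st.strand_ratio_profile(tracks, _borders([3000]), flank=500)
        assert np.allclose(prof, 0.0)

    def test_swapping_strands_negates(self):
        rng = np.random.default_rng(3)
        plus = {"c": rng.random(6000)}
        minus = {"c": rng.random(6000)}
        p1 = st.strand_ratio_profile(st.StrandTrackPair(plus, minus),
                                     _borders([3000]), flank=500)
        p2 = st.strand_ratio_profile(st.StrandTrackPair(minus, plus),
                                     _borders([3000]), flank=500)
        assert np.allclose(p1, -p2)

    def test_planted_divergence_changes_sign_at_border(self):
        params = simulate.SimulationParams(seed=8, divergent_fraction=1.0,
                                           transcription_noise=False)
        truth = simulate.generate_truth(params)
        tracks = simulate.simulate_transcription(truth, "A")
        prof = st.strand_ratio_profile(tracks, _borders(
            truth.borders_a, chrom=params.chrom), flank=1000)
        # antisense dominates upstream, sense downstream
        assert prof[:500].mean() < 0 < prof[1500:].mean()


class TestDivergenceRecovery:
    @pytest.mark.parametrize("ratio,expect_bidirectional", [
        (1.0, True), (10.0, False)])
    def test_planted_ratio_classified(self, ratio, expect_bidirectional):
        correct = []
        for seed in range(3):
            params = simulate.SimulationParams(
                seed=seed, divergent_fraction=1.0, strand_rate_ratio=ratio)
            truth = simulate.generate_truth(params)
            tracks = simulate.simulate_transcription(truth, "A",
                                                     seed=seed + 500)
            recs = st.directionality_score(
                tracks, _borders(truth.borders_a, chrom=params.chrom))
            flagged, _ = st.classify_bidirectional(recs)
            ok = (flagged["bidirectional"] if expect_bidirectional
                  else ~flagged["bidirectional"])
            correct.extend(ok.tolist())
        assert np.mean(correct) >= 0.95


class TestBedgraphIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        track = {"c": np.round(rng.random(300) * 3)}
        path = str(tmp_path / "t.bedgraph")
        st.write_bedgraph(track, path)
        back = st.read_bedgraph(path, {"c": 300})
        assert np.array_equal(track["c"], back["c"])
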
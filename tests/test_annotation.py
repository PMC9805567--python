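import numpy as np
import pandas as pd
import pytest

from segcond import (ZINBParams, annotate_segments, call_enhancer_bins,
                     compare_background_models, count_per_segment, fit_zinb,
                     make_grid, shuffle_background, zinb_pmf, zinb_pvalue,
                     zinb_rvs)
from segcond.segmentation import Segment


def _seg(chrom, b0, b1, bin_size=5000, mean_pc1=0.0):
    return Segment(id=f"{chrom}:{b0}-{b1}", chrom=chrom, start=b0 * bin_size,
                   end=b1 * bin_size, mean_pc1=mean_pc1, sd_pc1=0.0,
                   n_bins=b1 - b0, start_bin=b0, end_bin=b1)


class TestCallEnhancerBins:
    @pytest.mark.parametrize("z1,z2,expected", [
        (1.2, 1.2, 1),   # both marks above threshold
        (1.2, 0.5, 0),   # joint requirement fails on one mark
        (1.0, 1.0, 1),   # threshold is inclusive
    ])
    def test_joint_threshold(self, z1, z2, expected):
        zm = pd.DataFrame({"H3K27ac": [z1], "ATAC": [z2]})
        assert call_enhancer_bins(zm)[0] == expected

    def test_unknown_mark_rejected(self):
        zm = pd.DataFrame({"H3K27ac": [1.0]})
        with pytest.raises(KeyError, match="ATAC"):
            call_enhancer_bins(zm, marks=("H3K27ac", "ATAC"))


class TestCountPerSegment:
    def test_counts_and_conservation(self):
        grid = make_grid({"c": 40_000}, 5_000)  # 8 bins
        bins = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        segs = [_seg("c", 0, 4), _seg("c", 4, 8)]
        counts = count_per_segment(bins, segs, grid)
        assert counts.tolist() == [3, 1]
        assert counts.sum() == bins.sum()

    def test_off_grid_segment_rejected(self):
        grid = make_grid({"c": 40_000}, 5_000)
        bad = Segment(id="x", chrom="c", start=1, end=10_001, mean_pc1=0,
                      sd_pc1=0, n_bins=2, start_bin=0, end_bin=2)
        with pytest.raises(ValueError, match="not aligned"):
            count_per_segment(np.zeros(8), [bad], grid)


class TestShuffleBackground:
    GRID = make_grid({"c1": 500_000, "c2": 300_000}, 5_000)  # 100 + 60 bins

    def test_all_zero_and_all_one_vectors(self):
        zeros = shuffle_background(10, self.GRID, np.zeros(160), 50, seed=0)
        assert (zeros == 0).all()
        ones = shuffle_background(10, self.GRID, np.ones(160), 50, seed=0)
        assert (ones == 10).all()

    def test_mean_matches_enumeration_oracle(self):
        """Shuffle mean matches exact enumeration over all valid placements."""
        rng = np.random.default_rng(5)
        L = 15
        vec = (rng.random(160) < 0.2).astype(int)
        counts = shuffle_background(L, self.GRID, vec, 1000, seed=1)
        # oracle: every admissible window on both chromosomes, equally likely
        window_sums = []
        for sl in (slice(0, 100), slice(100, 160)):
            v = vec[sl]
            window_sums += [v[s:s + L].sum() for s in range(v.size - L + 1)]
        exact_mean = np.mean(window_sums)
        se = counts.std() / np.sqrt(1000)
        assert abs(counts.mean() - exact_mean) <= 3 * se + 1e-9

    def test_seeded_reproducibility(self):
        vec = (np.arange(160) % 7 == 0).astype(int)
        a = shuffle_background(12, self.GRID, vec, 200, seed=42)
        b = shuffle_background(12, self.GRID, vec, 200, seed=42)
        assert np.array_equal(a, b)

    def test_oversized_segment_rejected(self):
        with pytest.raises(ValueError, match="no chromosome"):
            shuffle_background(101, self.GRID, np.zeros(160), 10, seed=0)


class TestZINB:
    def test_pmf_normalizes(self):
        params = dict(pi=0.3, mu=5.0, theta=2.0)
        k = np.arange(0, 500)  # tail mass beyond is < 1e-10
        assert zinb_pmf(k, **params).sum() == pytest.approx(1.0, abs=1e-8)

    def test_pvalue_equals_brute_force_tail(self):
        p = ZINBParams(pi=0.25, mu=4.0, theta=1.5, loglik=0, converged=True)
        k = np.arange(0, 2000)
        pmf = zinb_pmf(k, p.pi, p.mu, p.theta)
        for obs in [0, 1, 3, 10]:
            assert zinb_pvalue(p, obs) == pytest.approx(pmf[obs:].sum(), abs=1e-12)

    def test_pvalue_boundaries(self):
        p = ZINBParams(pi=0.5, mu=3.0, theta=1.0, loglik=0, converged=True)
        assert zinb_pvalue(p, 0) == 1.0
        degenerate = ZINBParams(pi=1.0, mu=1.0, theta=1.0, loglik=0, converged=False)
        assert zinb_pvalue(degenerate, 1) == 0.0

    def test_fit_without_zeros_gives_small_pi(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, 500) + 1
        fit = fit_zinb(counts)
        assert fit.pi < 0.02

    def test_fit_recovers_parameters(self):
        rng = np.random.default_rng(3)
        counts = zinb_rvs(0.3, 5.0, 2.0, 5000, rng)
        fit = fit_zinb(counts)
        assert fit.pi == pytest.approx(0.3, rel=0.10)
        assert fit.mu == pytest.approx(5.0, rel=0.10)
        assert fit.theta == pytest.approx(2.0, rel=0.10)
        assert fit.converged

    def test_all_zero_counts_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_zinb(np.zeros(100, dtype=int))
        assert fit.pi == 1.0 and not fit.converged


class TestModelComparison:
    def test_nb_data_keeps_nb_competitive(self):
        """Without zero inflation, NB sits within 2 AIC of the ZINB (parsimony)."""
        rng = np.random.default_rng(4)
        counts = zinb_rvs(0.0, 6.0, 3.0, 1000, rng)
        df = compare_background_models(counts).set_index("model")
        assert df.loc["NB", "AIC"] <= df.loc["ZINB", "AIC"] + 2.0

    def test_truncated_normal_data_prefers_tobit(self):
        rng = np.random.default_rng(5)
        latent = rng.normal(1.0, 3.0, 1000)
        counts = np.maximum(np.round(latent), 0).astype(int)
        df = compare_background_models(counts).set_index("model")
        assert df.loc["TobitNormal", "loglik"] > df.loc["Normal", "loglik"]

    def test_best_flag_marks_min_aic(self):
        rng = np.random.default_rng(6)
        counts = zinb_rvs(0.4, 5.0, 2.0, 800, rng)
        df = compare_background_models(counts)
        assert df.loc[df["best"], "AIC"].iloc[0] == df["AIC"].min()


class TestAnnotateSegments:
    def _fit(self, pi=0.2, mu=4.0, theta=2.0):
        return ZINBParams(pi=pi, mu=mu, theta=theta, loglik=0.0, converged=True)

    def test_labels(self):
        segs = [_seg("c", 0, 4), _seg("c", 4, 8)]
        fits = [self._fit(), self._fit()]
        out = annotate_segments(segs, np.array([20, 2]), fits,
                                expected=np.array([4.0, 4.0]))
        assert out["label"].tolist() == ["enhancer_enriched", "enhancer_depleted"]
        assert out["enrichment"].iloc[0] == pytest.approx(np.log2(21 / 5))

    def test_significant_but_not_enriched_stays_depleted(self):
        """Low p alone is insufficient: the enrichment must also be positive."""
        seg = [_seg("c", 0, 4)]
        # heavy zero inflation: the upper tail can be small even below the mean
        fit = ZINBParams(pi=0.97, mu=250.0, theta=50.0, loglik=0.0, converged=True)
        out = annotate_segments(seg, np.array([20]), [fit],
                                expected=np.array([25.0]))
        assert out["pvalue"].iloc[0] < 0.05
        assert out["enrichment"].iloc[0] < 0
        assert out["label"].iloc[0] == "enhancer_depleted"
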
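import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from arrestseq import normquant, synthgen


class TestCpm:
    def test_whole_library_single_gene(self):
        counts = pd.DataFrame({"s1": [13]}, index=["g1"])
        out = normquant.cpm(counts, exclude_spikes=False)
        assert out.loc["g1", "s1"] == pytest.approx(1e6)

    def test_zero_count_stays_zero(self, toy_counts):
        out = normquant.cpm(toy_counts)
        assert out.loc["gene2", "s1"] == 0.0

    def test_hand_arithmetic_two_genes(self):
        counts = pd.DataFrame({"s1": [2, 8]}, index=["g1", "g2"])
        out = normquant.cpm(counts, exclude_spikes=False)
        assert out["s1"].tolist() == pytest.approx([2e5, 8e5])
        assert out["s1"].sum() == pytest.approx(1e6)

    def test_column_sums_over_basis_genes(self, ts_small):
        out = normquant.cpm(ts_small.counts, exclude_spikes=True)
        genes = ~ts_small.counts.index.str.startswith("ERCC-")
        sums = out.loc[genes].sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_all_zero_library_names_sample(self):
        counts = pd.DataFrame({"bad": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="bad"):
            normquant.cpm(counts)

    def test_spike_exclusion_changes_basis(self, toy_counts):
        incl = normquant.cpm(toy_counts, exclude_spikes=False)
        excl = normquant.cpm(toy_counts, exclude_spikes=True)
        assert (excl.loc["gene1"] > incl.loc["gene1"]).all()


class TestLog2MeanCentered:
    def test_constant_gene_all_zero(self):
        cpm = pd.DataFrame({"a": [5.0], "b": [5.0], "c": [5.0]}, index=["g"])
        out = normquant.log2_mean_centered(cpm)
        assert np.allclose(out, 0.0)

    def test_hand_arithmetic(self):
        cpm = pd.DataFrame({"a": [1.0], "b": [7.0]}, index=["g"])
        out = normquant.log2_mean_centered(cpm, pseudocount=1.0)
        assert out.loc["g"].tolist() == pytest.approx([-1.0, 1.0])

    def test_row_means_zero(self, ts_small):
        cpm = normquant.cpm(ts_small.counts)
        out = normquant.log2_mean_centered(cpm)
        assert np.abs(out.mean(axis=1)).max() < 1e-12

    def test_pseudocount_must_be_positive(self):
        cpm = pd.DataFrame({"a": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            normquant.log2_mean_centered(cpm, pseudocount=0.0)


class TestUpperQuartileFactors:
    def test_identical_samples_give_unit_factors(self):
        col = [10, 20, 30, 40, 50]
        counts = pd.DataFrame({"a": col, "b": col, "c": col},
                              index=[f"g{i}" for i in range(5)])
        out = normquant.upper_quartile_factors(counts)
        assert np.allclose(out, 1.0)

    def test_doubled_sample_hand_arithmetic(self):
        a = [10, 20, 30, 40]
        counts = pd.DataFrame({"a": a, "b": [2 * x for x in a]},
                              index=[f"g{i}" for i in range(4)])
        out = normquant.upper_quartile_factors(counts)
        assert out["a"] == pytest.approx(1 / np.sqrt(2))
        assert out["b"] == pytest.approx(np.sqrt(2))

    def test_percentile_convention_order_statistics_oracle(self):
        # linear interpolation between order statistics on 8 values:
        # position (n-1)*0.75 = 5.25 -> x[5] + 0.25*(x[6]-x[5])
        values = [3, 1, 4, 1, 5, 9, 2, 6]
        srt = sorted(values)
        expected = srt[5] + 0.25 * (srt[6] - srt[5])
        counts = pd.DataFrame({"a": values, "b": values},
                              index=[f"g{i}" for i in range(8)])
        out = normquant.upper_quartile_factors(counts)
        # both samples identical -> factor 1, but the raw quantile must match
        nz = np.array(values)
        assert np.percentile(nz, 75) == pytest.approx(expected)
        assert np.allclose(out, 1.0)

    def test_too_few_nonzero_genes_rejected(self):
        counts = pd.DataFrame({"a": [5, 0, 0, 0], "b": [1, 2, 3, 4]},
                              index=[f"g{i}" for i in range(4)])
        with pytest.raises(ValueError, match="a"):
            normquant.upper_quartile_factors(counts)


class TestUnwantedVariationFactor:
    def test_constant_controls_give_zero_scores(self):
        logc = pd.DataFrame(np.ones((5, 6)),
                            index=[f"c{i}" for i in range(5)],
                            columns=[f"s{j}" for j in range(6)])
        out = normquant.unwanted_variation_factor(logc, logc.index, k=1)
        assert np.allclose(out.scores.to_numpy(), out.scores.to_numpy()[0, 0])

    def test_recovers_planted_offset_vector(self):
        # controls = outer product of a sample offset + small noise; the
        # construction itself is the oracle for what the factor must recover
        rng = np.random.default_rng(0)
        offset = rng.normal(0, 1.0, 6)
        loading = rng.normal(1.0, 0.1, 10)
        data = np.outer(loading, offset) + rng.normal(0, 0.01, (10, 6))
        logc = pd.DataFrame(data, index=[f"c{i}" for i in range(10)],
                            columns=[f"s{j}" for j in range(6)])
        out = normquant.unwanted_variation_factor(logc, logc.index, k=1)
        r = np.corrcoef(out.scores["W1"], offset)[0, 1]
        assert abs(r) > 0.99
        # and it matches a dense SVD computed independently
        centered = data - data.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered)
        r2 = np.corrcoef(out.scores["W1"], vt[0])[0, 1]
        assert abs(r2) > 0.999999

    def test_unit_norm(self):
        rng = np.random.default_rng(1)
        logc = pd.DataFrame(rng.normal(size=(8, 5)),
                            index=[f"c{i}" for i in range(8)],
                            columns=[f"s{j}" for j in range(5)])
        out = normquant.unwanted_variation_factor(logc, logc.index, k=2)
        norms = np.linalg.norm(out.scores.to_numpy(), axis=0)
        assert np.allclose(norms, 1.0)

    def test_k_too_large_rejected(self):
        logc = pd.DataFrame(np.zeros((8, 3)),
                            index=[f"c{i}" for i in range(8)],
                            columns=list("abc"))
        with pytest.raises(ValueError):
            normquant.unwanted_variation_factor(logc, logc.index, k=3)

    def test_sign_flip_leaves_lrt_pvalues_unchanged(self, aid_small):
        from arrestseq import tsde
        counts = aid_small.counts
        expressed = tsde.filter_expressed(counts, 10, 4, mode="count")[:100]
        spike_ids = [s for s in counts.index if s.startswith("ERCC-")]
        logc = np.log2(counts.loc[expressed + spike_ids] + 1.0)
        ruv = normquant.unwanted_variation_factor(logc, spike_ids, k=1)
        meta = aid_small.samples.set_index("sample_id")
        a = meta[(meta.strain == "soma_TIR1_AID")
                 & (meta.treatment == "ethanol")].index.tolist()
        b = meta[(meta.strain == "soma_TIR1_AID")
                 & (meta.treatment == "auxin")].index.tolist()
        t1 = tsde.lrt_pairwise(counts.loc[expressed], a, b, covariates=ruv)
        flipped = normquant.UnwantedFactor(scores=-ruv.scores, k=1,
                                           control_ids=ruv.control_ids)
        t2 = tsde.lrt_pairwise(counts.loc[expressed], a, b, covariates=flipped)
        assert np.allclose(t1["p"], t2["p"], atol=1e-6)


class TestSpikeRegression:
    def _mix(self, concs):
        return pd.DataFrame({
            "spike_id": [f"ERCC-{i:05d}" for i in range(1, len(concs) + 1)],
            "conc_attomol_per_ul": concs,
            "volume_ul": 2.0,
        })

    def test_exact_linearity(self):
        mix = self._mix([1.0, 10.0, 100.0])
        counts = pd.DataFrame({"s1": [5, 50, 500]},
                              index=mix["spike_id"].tolist())
        fit = normquant.fit_spike_regression(counts, mix)
        assert fit.slope["s1"] == pytest.approx(1.0)
        assert fit.intercept["s1"] == pytest.approx(np.log10(5.0))
        assert fit.r_squared["s1"] == pytest.approx(1.0)

    def test_constant_counts_slope_zero(self):
        mix = self._mix([1.0, 10.0, 100.0, 1000.0])
        counts = pd.DataFrame({"s1": [7, 7, 7, 7]},
                              index=mix["spike_id"].tolist())
        fit = normquant.fit_spike_regression(counts, mix)
        assert fit.slope["s1"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_nonzero_spikes_names_sample(self):
        mix = self._mix([1.0, 10.0, 100.0])
        counts = pd.DataFrame({"weird": [5, 0, 0]},
                              index=mix["spike_id"].tolist())
        with pytest.raises(ValueError, match="weird"):
            normquant.fit_spike_regression(counts, mix)

    def test_noisy_simulation_recovers_unit_slope(self, aid_default):
        fit = normquant.fit_spike_regression(aid_default.counts,
                                             aid_default.spikes)
        assert (np.abs(fit.slope - 1.0) < 0.1).all()

    def test_noiseless_expected_counts_slope_exactly_one(self, aid_default):
        design = synthgen.default_aid_design()
        expected = synthgen.expected_counts(aid_default.truth,
                                            aid_default.spikes, design)
        fit = normquant.fit_spike_regression(expected, aid_default.spikes)
        assert np.allclose(fit.slope, 1.0, atol=1e-9)
        assert np.allclose(fit.r_squared, 1.0, atol=1e-12)


class TestAttomolesPerWorm:
    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s1": [50]}, index=["g1"])
        fit = normquant.SpikeFit(
            slope=pd.Series({"s1": 1.0}),
            intercept=pd.Series({"s1": np.log10(5.0)}),
            r_squared=pd.Series({"s1": 1.0}),
            n_spikes=pd.Series({"s1": 3}))
        sheet = pd.DataFrame({"sample_id": ["s1"], "worms_per_sample": [4],
                              "spike_volume_ul": [2.0]})
        out = normquant.to_attomoles_per_worm(counts, fit, sheet)
        assert out.loc["g1", "s1"] == pytest.approx(5.0, rel=1e-6)

    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g1"])
        fit = normquant.SpikeFit(
            slope=pd.Series({"s1": 1.0}), intercept=pd.Series({"s1": 0.7}),
            r_squared=pd.Series({"s1": 1.0}), n_spikes=pd.Series({"s1": 3}))
        sheet = pd.DataFrame({"sample_id": ["s1"], "worms_per_sample": [4],
                              "spike_volume_ul": [2.0]})
        out = normquant.to_attomoles_per_worm(counts, fit, sheet)
        assert out.loc["g1", "s1"] == 0.0

    def test_missing_sheet_fields_rejected(self):
        counts = pd.DataFrame({"s1": [5]}, index=["g1"])
        fit = normquant.SpikeFit(
            slope=pd.Series({"s1": 1.0}), intercept=pd.Series({"s1": 0.0}),
            r_squared=pd.Series({"s1": 1.0}), n_spikes=pd.Series({"s1": 3}))
        sheet = pd.DataFrame({"sample_id": ["s1"]})
        with pytest.raises(ValueError, match="worms_per_sample"):
            normquant.to_attomoles_per_worm(counts, fit, sheet)

    def test_noiseless_inversion_within_2_percent(self, aid_default):
        design = synthgen.default_aid_design()
        expected = synthgen.expected_counts(aid_default.truth,
                                            aid_default.spikes, design)
        fit = normquant.fit_spike_regression(expected, aid_default.spikes)
        amol = normquant.to_attomoles_per_worm(expected, fit,
                                               aid_default.samples)
        truth = (aid_default.truth.abundance
                 / synthgen.MOLECULES_PER_ATTOMOLE)
        mask = (expected.loc[truth.index] >= 10).to_numpy()
        rel = np.abs(amol.to_numpy() / truth.to_numpy() - 1.0)[mask]
        assert rel.max() < 0.02

    def test_noisy_spearman_recovery(self, aid_default):
        fit = normquant.fit_spike_regression(aid_default.counts,
                                             aid_default.spikes)
        amol = normquant.to_attomoles_per_worm(aid_default.counts, fit,
                                               aid_default.samples)
        truth = (aid_default.truth.abundance
                 / synthgen.MOLECULES_PER_ATTOMOLE)
        mask = (aid_default.counts.loc[truth.index] >= 10).to_numpy()
        rho = spearmanr(amol.to_numpy()[mask], truth.to_numpy()[mask]).statistic
        assert rho > 0.95


class TestSpikeReadProportion:
    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s1": [900, 100]}, index=["g1", "ERCC-1"])
        out = normquant.spike_read_proportion(counts)
        assert out["s1"] == pytest.approx(0.1)

    def test_no_spike_reads(self):
        counts = pd.DataFrame({"s1": [900, 0]}, index=["g1", "ERCC-1"])
        assert normquant.spike_read_proportion(counts)["s1"] == 0.0

    def test_all_spike_reads(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["g1", "ERCC-1"])
        assert normquant.spike_read_proportion(counts)["s1"] == 1.0

    def test_invariant_to_row_relabeling(self, toy_counts):
        base = normquant.spike_read_proportion(toy_counts)
        shuffled = toy_counts.sample(frac=1.0, random_state=0)
        again = normquant.spike_read_proportion(shuffled)
        assert np.allclose(base, again.loc[base.index])
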
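"""Interpretation machinery: filter motifs, pruning, attribution maps, exports."""

import numpy as np
import pytest

from m6acnn.datasets import SequenceSample
from m6acnn.encoding import enac_encode, enac_encode_batch
from m6acnn.interpretation import (
    AttributionMap,
    LinearENACScorer,
    MotifPFM,
    activated_amount,
    attribution_similarity,
    auc_drop,
    best_offset_pcc,
    build_pfm,
    cluster_motifs,
    export_meme,
    extract_activated_subsequences,
    filter_position_profile,
    filter_reports,
    first_layer_activations,
    global_position_profile,
    gradient_attribution,
    impact_score,
    ism_attribution,
    motif_pcc,
    pcc_matrix,
    read_meme,
    subsequence_length,
)

from conftest import TINY_CONFIG


# ---------------------------------------------------------------------------
# filter-level interpretation
# ---------------------------------------------------------------------------

class TestActivations:
    def test_nonnegative_and_shape(self, tiny_results, tiny_encoded, tiny_samples):
        X, _ = tiny_encoded
        acts = first_layer_activations(tiny_results, X)
        k = TINY_CONFIG.conv_blocks[0]["kernel_rows"]
        assert acts.shape == (len(tiny_samples), X.shape[1] - k + 1, 8)
        assert acts.min() >= 0

    def test_zeroed_filter_gives_zero_activations(self, tiny_results, tiny_encoded):
        X, _ = tiny_encoded
        with tiny_results.net.filters_nullified([3]):
            acts = first_layer_activations(tiny_results, X)
        assert np.all(acts[:, :, 3] == 0)


class TestActivatedSubsequences:
    def _toy_acts(self):
        # 2 sequences, 3 positions, 2 filters; filter 0 max activation 1.0
        acts = np.zeros((2, 3, 2))
        acts[0, 0, 0] = 1.0
        acts[0, 2, 0] = 0.6
        acts[1, 1, 0] = 0.5  # exactly at threshold: excluded (strict >)
        return acts

    def test_threshold_is_half_of_filter_max_strict(self):
        samples = [
            SequenceSample("GGACUAA", "positive", "a"),
            SequenceSample("AAGGACU", "negative", "b"),
        ]
        subs = extract_activated_subsequences(
            self._toy_acts(), samples, kernel_rows=4, window=2
        )
        # filter 0: positions (0,0) and (0,2) pass; (1,1) at exactly 0.5 excluded
        assert subs[0] == ["GGACU", "ACUAA"]
        assert subs[1] == []  # dead filter

    def test_subsequence_length_rule(self):
        assert subsequence_length(kernel_rows=4, window=2) == 5
        assert subsequence_length(kernel_rows=7, window=2) == 8

    def test_activated_amount_hand_average(self):
        acts = self._toy_acts()
        amounts = activated_amount(acts)
        # filter 0: 2 above-threshold placements over 2 sequences -> 1.0
        assert amounts[0] == pytest.approx(1.0)
        assert amounts[1] == 0.0


class TestBuildPfm:
    def test_hand_counted_frequencies(self):
        pfm = build_pfm(["GGACU", "GGACU", "AGACU"])
        np.testing.assert_allclose(pfm.freq[0], [1 / 3, 0, 2 / 3, 0])
        for i, base in enumerate("GACU", start=1):
            expected = np.zeros(4)
            expected["ACGU".index(base)] = 1.0
            np.testing.assert_allclose(pfm.freq[i], expected)
        assert pfm.support == 3

    def test_single_subsequence_one_hot(self):
        pfm = build_pfm(["ACGU"])
        assert set(np.unique(pfm.freq)) == {0.0, 1.0}
        np.testing.assert_allclose(pfm.freq.sum(axis=1), 1.0)

    def test_empty_set_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="uniform"):
            pfm = build_pfm([])
        np.testing.assert_allclose(pfm.freq, 0.25)
        assert pfm.support == 0

    def test_mixed_lengths_raise(self):
        with pytest.raises(ValueError):
            build_pfm(["ACG", "ACGU"])


class TestVirtualPruning:
    def test_zero_downstream_weights_zero_impact(self, tiny_encoded):
        from m6acnn.model import M6AConvNet

        X, y = tiny_encoded
        res = M6AConvNet(X, y, TINY_CONFIG).fit()
        # zero all dense rows fed by filter 0's pooled features: flatten
        # layout is (position, filter) with filter fastest
        n_filters = res.net.params["conv0_W"].shape[0]
        res.net.params["fc0_W"][0::n_filters] = 0.0
        assert impact_score(res, X, 0) == pytest.approx(0.0, abs=1e-12)

    def test_model_restored_after_scoring(self, tiny_results, tiny_encoded):
        X, _ = tiny_encoded
        before = tiny_results.predict_proba(X)
        impact_score(tiny_results, X, 1)
        np.testing.assert_array_equal(tiny_results.predict_proba(X), before)

    def test_nullifying_all_filters_makes_predictions_constant(
        self, tiny_results, tiny_encoded
    ):
        X, _ = tiny_encoded
        n_filters = tiny_results.net.params["conv0_W"].shape[0]
        with tiny_results.net.filters_nullified(range(n_filters)):
            p = tiny_results.predict_proba(X)
        assert np.ptp(p) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_index_raises(self, tiny_results, tiny_encoded):
        X, _ = tiny_encoded
        with pytest.raises(ValueError):
            impact_score(tiny_results, X, 99)

    def test_auc_drop_zero_for_untouched_model(self, tiny_results, tiny_encoded):
        X, y = tiny_encoded
        d = auc_drop(tiny_results, X, y, 0)
        assert np.isfinite(d)


class TestFilterReports:
    def test_reports_complete(self, tiny_results, tiny_samples):
        reports = filter_reports(tiny_results, tiny_samples[:40])
        assert len(reports) == 8
        for r in reports:
            assert r.activated_amount >= 0
            np.testing.assert_allclose(r.pfm.freq.sum(axis=1), 1.0)


class TestMotifPcc:
    def test_identical_pfms(self):
        pfm = build_pfm(["GGACU", "AGACU"])
        assert motif_pcc(pfm, pfm) == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        a = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        b = 0.25 - (a - 0.25) / 3  # mass moved off the peaks
        r = motif_pcc(a, b)
        brute = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert r == pytest.approx(brute) and r < 0

    def test_uniform_pfm_is_nan(self):
        uniform = np.full((3, 4), 0.25)
        assert np.isnan(motif_pcc(uniform, np.eye(4)[:3]))

    def test_best_offset_alignment_finds_planted_position(self):
        long = np.full((9, 4), 0.25)
        motif = build_pfm(["GGACU"]).freq
        long[3:8] = motif
        assert best_offset_pcc(motif, long) == pytest.approx(1.0)

    def test_pcc_matrix_symmetric_unit_diagonal(self):
        pfms = [build_pfm(["GGACU"]), build_pfm(["AAACA"]), build_pfm(["UGACC"])]
        m = pcc_matrix(pfms)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)


class TestClusterMotifs:
    def test_identical_pair_co_clusters(self):
        a = build_pfm(["GGACU", "GGACA"])
        b = build_pfm(["GGACU", "GGACA"])
        c = build_pfm(["UUUUU"])
        _, labels = cluster_motifs([a, b, c], n_clusters=2)
        assert labels[0] == labels[1] != labels[2]

    def test_labels_invariant_under_reordering(self):
        a = build_pfm(["GGACU", "GGACA"])
        b = build_pfm(["GGACU", "GGACA"])
        c = build_pfm(["UUUUU"])
        _, l1 = cluster_motifs([a, b, c], n_clusters=2)
        _, l2 = cluster_motifs([c, a, b], n_clusters=2)
        assert (l1[0] == l1[1]) and (l2[1] == l2[2]) and (l2[0] != l2[1])

    def test_uniform_pfm_excluded_with_warning(self):
        a = build_pfm(["GGACU"])
        b = build_pfm(["UGACC"])
        u = MotifPFM(np.full((5, 4), 0.25), support=1)
        with pytest.warns(UserWarning, match="excluded"):
            _, labels = cluster_motifs([a, u, b], n_clusters=2)
        assert labels[1] == 0 and labels[0] > 0 and labels[2] > 0


# ---------------------------------------------------------------------------
# propagation-based interpretation
# ---------------------------------------------------------------------------

def _linear_scorer(rows, seed=0):
    rng = np.random.default_rng(seed)
    return LinearENACScorer(rng.normal(size=(rows, 4)), b=0.3)


class TestIsm:
    def test_observed_base_entries_zero(self, tiny_results, tiny_samples):
        s = tiny_samples[0]
        amap = ism_attribution(tiny_results, s)
        for i, base in enumerate(s.sequence):
            assert amap.values["ACGU".index(base), i] == 0.0

    def test_constant_model_zero_map(self, tiny_encoded, tiny_samples):
        from m6acnn.model import M6AConvNet

        X, y = tiny_encoded
        model = M6AConvNet(X, y, TINY_CONFIG)
        res_net = model._build_net()
        res_net.params["out_W"][:] = 0.0
        res_net.params["out_b"][:] = 0.0
        import pandas as pd
        from m6acnn.model import M6AConvNetResults

        res = M6AConvNetResults(model, res_net, pd.DataFrame())
        amap = ism_attribution(res, tiny_samples[0])
        np.testing.assert_allclose(amap.values, 0.0, atol=1e-12)

    def test_linear_scorer_matches_closed_form(self, tiny_samples):
        """ISM on a linear ENAC scorer equals the weight difference of the
        encoded rows overlapping the mutated position."""
        s = tiny_samples[0]
        L = len(s.sequence)
        scorer = _linear_scorer(L - 1)
        amap = ism_attribution(scorer, s, output="logit")
        W = scorer.W
        for i in range(L):
            cover = [r for r in (i - 1, i) if 0 <= r <= L - 2]
            for b in "ACGU":
                bi = "ACGU".index(b)
                xi = "ACGU".index(s.sequence[i])
                expected = sum(0.5 * (W[r, bi] - W[r, xi]) for r in cover)
                assert amap.values[bi, i] == pytest.approx(expected, abs=1e-10)

    def test_map_shape_4_by_l(self, tiny_results, tiny_samples):
        amap = ism_attribution(tiny_results, tiny_samples[0])
        assert amap.values.shape == (4, len(tiny_samples[0].sequence))
        assert amap.method == "ism"


class TestGradientAttribution:
    def test_linear_scorer_matches_closed_form_projection(self, tiny_samples):
        s = tiny_samples[0]
        L = len(s.sequence)
        scorer = _linear_scorer(L - 1, seed=3)
        amap = gradient_attribution(scorer, s, output="logit")
        W = scorer.W
        for i in range(L):
            cover = [r for r in (i - 1, i) if 0 <= r <= L - 2]
            for bi in range(4):
                expected = sum(W[r, bi] for r in cover) / 2
                assert amap.values[bi, i] == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_ism_in_linear_limit(self, tiny_samples):
        """For a linear scorer, ISM deltas are exact gradient differences."""
        s = tiny_samples[0]
        scorer = _linear_scorer(len(s.sequence) - 1, seed=4)
        ism = ism_attribution(scorer, s, output="logit").values
        grad = gradient_attribution(scorer, s, output="logit").values
        for i, base in enumerate(s.sequence):
            xi = "ACGU".index(base)
            for bi in range(4):
                assert ism[bi, i] == pytest.approx(
                    grad[bi, i] - grad[xi, i], abs=1e-10
                )

    def test_model_map_shape(self, tiny_results, tiny_samples):
        amap = gradient_attribution(tiny_results, tiny_samples[0])
        assert amap.values.shape == (4, len(tiny_samples[0].sequence))


class TestProfilesAndSimilarity:
    def test_zero_and_cancelling_maps(self):
        z = AttributionMap(np.zeros((4, 10)), "ism")
        np.testing.assert_array_equal(global_position_profile([z]), np.zeros(10))
        m = np.random.default_rng(0).normal(size=(4, 10))
        pair = [AttributionMap(m, "ism"), AttributionMap(-m, "ism")]
        np.testing.assert_allclose(global_position_profile(pair), 0.0, atol=1e-12)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            global_position_profile([])

    def test_filter_profile_counts_coverage(self):
        acts = np.zeros((2, 3, 1))
        acts[0, 1, 0] = 1.0  # one placement starting at row 1, covers nt 1..5
        profile = filter_position_profile(acts, kernel_rows=4, seq_len=7)
        expected = np.array([0, 0.5, 0.5, 0.5, 0.5, 0.5, 0])
        np.testing.assert_allclose(profile, expected)

    def test_cosine_similarity_limits(self):
        v = np.array([1.0, 2.0, 3.0])
        assert attribution_similarity(v, v) == pytest.approx(1.0)
        assert attribution_similarity(v, -v) == pytest.approx(-1.0)
        assert attribution_similarity(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])
        ) == pytest.approx(0.0)
        assert np.isnan(attribution_similarity(v, np.zeros(3)))
        with pytest.raises(ValueError):
            attribution_similarity(v, np.ones(4))


class TestMemeExport:
    def test_round_trip(self, tmp_path):
        pfms = [build_pfm(["GGACU", "AGACU"], filter_index=0),
                build_pfm(["UGACC"], filter_index=1)]
        path = tmp_path / "motifs.meme"
        export_meme(pfms, path)
        text = path.read_text()
        assert text.startswith("MEME version 4")
        assert "ALPHABET= ACGU" in text
        back = read_meme(path)
        assert len(back) == 2
        np.testing.assert_allclose(back[0].freq, pfms[0].freq, atol=1e-6)
        assert back[0].support == 2

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "empty.meme"
        export_meme([], path)
        assert "MEME version 4" in path.read_text()
        assert read_meme(path) == []

    def test_non_stochastic_rows_rejected(self, tmp_path):
        bad = MotifPFM(np.ones((2, 4)), support=1)
        with pytest.raises(ValueError, match="sum to 1"):
            export_meme([bad], tmp_path / "bad.meme")
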
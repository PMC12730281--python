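import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import omicnet as on
from omicnet.markers import MarkerSet, SaliencyProfile, _interval_distance
from omicnet.nn import MultiBranchNet
from omicnet.omics_io import PhenotypeTable, get_modality


def _linear_bundle(weights):
    """Single continuous modality whose samples are identity-ish probes."""
    n_feat = len(weights)
    tensor = np.random.default_rng(0).normal(size=(4, n_feat, 1))
    enc = on.EncodedModality(
        get_modality("gene_expression"),
        [f"s{i}" for i in range(4)],
        [f"f{j}" for j in range(n_feat)],
        tensor,
    )
    pheno = PhenotypeTable(
        labels=pd.Series(np.zeros(4), index=enc.sample_ids), task="regression"
    )
    return on.merge_modalities([enc], pheno)


def _linear_net(weights):
    """A network that computes exactly w . x (no conv, no head nonlinearity)."""
    net = MultiBranchNet(
        [(len(weights), 1)],
        task="regression",
        n_conv_layers=0,
        pooling="local",
        pool_size=1,
        dense_sizes=(),
        dropout=0.0,
        batch_norm=False,
        seed=0,
    )
    dense = net.head[-1]
    dense.w[:, 0] = weights
    dense.b[:] = 0.0
    return net


class TestComputeSaliency:
    def test_linear_map_saliency_is_absolute_weight(self):
        weights = np.array([2.0, -3.0, 0.5])
        bundle = _linear_bundle(weights)
        handle = on.build_multi_cnn(
            on.ModelSpec(task="regression"), bundle.input_shapes()
        )
        handle.net = _linear_net(weights)
        handle.fitted = True
        profile = on.compute_saliency(handle, bundle)
        np.testing.assert_allclose(
            profile.scores["saliency"].to_numpy(), np.abs(weights), atol=1e-12
        )

    def test_zero_weight_network_zero_saliency(self):
        weights = np.zeros(4)
        bundle = _linear_bundle(weights)
        handle = on.build_multi_cnn(
            on.ModelSpec(task="regression"), bundle.input_shapes()
        )
        handle.net = _linear_net(weights)
        handle.fitted = True
        profile = on.compute_saliency(handle, bundle)
        assert (profile.scores["saliency"] == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        net = MultiBranchNet(
            [(2, 1)],
            task="classification",
            n_conv_layers=1,
            filters=2,
            kernel_size=3,
            dense_sizes=(3,),
            dropout=0.0,
            batch_norm=False,
            seed=seed,
        )
        x = rng.normal(size=(5, 2, 1))
        grads = net.input_gradients([x], class_index=1)[0]
        eps = 1e-3
        for i in range(5):
            for j in range(2):
                xp, xm = x.copy(), x.copy()
                xp[i, j, 0] += eps
                xm[i, j, 0] -= eps
                fd = (net.forward([xp])[i, 1] - net.forward([xm])[i, 1]) / (2 * eps)
                assert abs(grads[i, j, 0] - fd) <= 1e-3 * max(1.0, abs(fd))

    def test_baseline_model_redirected(self, tiny_bundle):
        handle = on.build_baseline("logistic_l2")
        split = on.split_dataset(tiny_bundle, seed=0)
        handle, _ = on.train_model(handle, tiny_bundle, split)
        with pytest.raises(ValueError, match="coefficient_importance"):
            on.compute_saliency(handle, tiny_bundle)


class TestCoefficientImportance:
    def test_logistic_absolute_coefficients(self, tiny_bundle):
        handle = on.build_baseline("logistic_l2")
        split = on.split_dataset(tiny_bundle, seed=0)
        handle, _ = on.train_model(handle, tiny_bundle, split)
        profile = on.coefficient_importance(handle, tiny_bundle)
        assert (profile.scores["saliency"] >= 0).all()
        assert len(profile) == sum(len(m.feature_ids) for m in tiny_bundle.modalities)

    def test_forest_importances_sum_to_one(self, tiny_bundle):
        handle = on.build_baseline("random_forest", params={"n_estimators": 20})
        split = on.split_dataset(tiny_bundle, seed=0)
        handle, _ = on.train_model(handle, tiny_bundle, split)
        assert handle.estimator.feature_importances_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_one_hot_feature_aggregated_by_channel_max(self):
        # hand-built: 1 snp feature (5 channels) + 1 expression feature
        tensor_snp = np.zeros((3, 1, 5))
        tensor_snp[:, 0, 0] = 1.0
        snp = on.EncodedModality(get_modality("snp"), ["a", "b", "c"], ["rs1"], tensor_snp)
        expr = on.EncodedModality(
            get_modality("gene_expression"), ["a", "b", "c"], ["g1"], np.zeros((3, 1, 1))
        )
        pheno = PhenotypeTable(
            labels=pd.Series(["x", "y", "x"], index=["a", "b", "c"]),
            task="classification",
        )
        bundle = on.merge_modalities([snp, expr], pheno)

        class FakeEstimator:
            coef_ = np.array([[0.1, -0.9, 0.4, 0.0, 0.2, 0.3]])

        handle = on.build_baseline("logistic_l2")
        handle.estimator = FakeEstimator()
        handle.fitted = True
        profile = on.coefficient_importance(handle, bundle)
        scores = dict(zip(profile.scores["feature_id"], profile.scores["saliency"]))
        assert scores["rs1"] == pytest.approx(0.9)
        assert scores["g1"] == pytest.approx(0.3)

    def test_rbf_svm_has_no_coefficients(self, tiny_bundle):
        handle = on.build_baseline("svm_rbf")
        split = on.split_dataset(tiny_bundle, seed=0)
        handle, _ = on.train_model(handle, tiny_bundle, split)
        with pytest.raises(ValueError, match="RBF"):
            on.coefficient_importance(handle, tiny_bundle)


def _profile(values):
    return SaliencyProfile(
        scores=pd.DataFrame(
            {
                "modality": "gene_expression",
                "feature_id": [f"f{i}" for i in range(len(values))],
                "saliency": values,
            }
        )
    )


class TestDenseRank:
    def test_ties_share_rank(self):
        table = on.dense_rank(_profile([0.9, 0.9, 0.5]))
        assert list(table.records["dense_rank"]) == [1, 1, 2]

    def test_single_feature_rank_one(self):
        assert list(on.dense_rank(_profile([0.1])).records["dense_rank"]) == [1]

    @given(
        st.lists(
            st.integers(min_value=0, max_value=8).map(lambda v: v / 4.0),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_sort_and_scan_oracle(self, values):
        table = on.dense_rank(_profile(values)).records
        # oracle: scan descending distinct values
        distinct = sorted(set(values), reverse=True)
        oracle = {v: i + 1 for i, v in enumerate(distinct)}
        for _, row in table.iterrows():
            assert row["dense_rank"] == oracle[row["saliency"]]
        assert sorted(table["dense_rank"].unique()) == list(
            range(1, len(distinct) + 1)
        )


class TestSelectTopMarkers:
    def test_distinct_values_exact_k(self):
        table = on.dense_rank(_profile(list(np.linspace(1, 0, 1000))))
        assert len(on.select_top_markers(table, k=100).records) == 100

    def test_threshold_at_max_keeps_argmax_only(self):
        table = on.dense_rank(_profile([0.9, 0.7, 0.9]))
        selected = on.select_top_markers(table, saliency_threshold=0.9)
        assert set(selected.records["feature_id"]) == {"f0", "f2"}

    def test_boundary_ties_included(self):
        table = on.dense_rank(_profile([0.9, 0.7, 0.7, 0.1]))
        assert len(on.select_top_markers(table, k=2).records) == 3

    def test_oversized_k_returns_all_with_warning(self):
        table = on.dense_rank(_profile([0.5, 0.4]))
        with pytest.warns(UserWarning, match="whole table"):
            selected = on.select_top_markers(table, k=10)
        assert len(selected.records) == 2


class TestMapMarkersToGenes:
    @pytest.fixture
    def annotation(self):
        return on.GeneAnnotation(
            pd.DataFrame(
                [
                    ("chr1", 100, 200, "+", "geneA"),
                    ("chr1", 300, 400, "-", "geneB"),
                ],
                columns=["chromosome", "start", "end", "strand", "gene_id"],
            )
        )

    def _markers(self, feats):
        return MarkerSet(
            records=pd.DataFrame(
                {
                    "modality": "snp",
                    "feature_id": feats,
                    "saliency": np.linspace(1, 0.5, len(feats)),
                    "dense_rank": range(1, len(feats) + 1),
                }
            ),
            rule="test",
        )

    def test_containment_maps_to_gene(self, annotation):
        out = on.map_markers_to_genes(
            self._markers(["m1"]), {"m1": ("chr1", 150)}, annotation
        )
        assert list(out["gene_id"]) == ["geneA"]

    def test_nearest_mode_half_open_distance(self, annotation):
        # position 250: 51 bases from geneA's last base (199), 50 from geneB's start
        out = on.map_markers_to_genes(
            self._markers(["m1"]),
            {"m1": ("chr1", 250)},
            annotation,
            mode="nearest",
            max_distance=100,
        )
        assert list(out["gene_id"]) == ["geneB"]

    def test_intergenic_marker_unmapped_in_overlap_mode(self, annotation):
        out = on.map_markers_to_genes(
            self._markers(["m1"]), {"m1": ("chr1", 250)}, annotation
        )
        assert len(out) == 0
        assert out.attrs["unmapped"][0][0] == "m1"

    def test_unknown_chromosome_recorded_not_fatal(self, annotation):
        out = on.map_markers_to_genes(
            self._markers(["m1"]), {"m1": ("chrX", 10)}, annotation
        )
        assert any("chrX" in reason for _, reason in out.attrs["unmapped"])

    def test_best_rank_is_minimum_over_markers(self, annotation):
        out = on.map_markers_to_genes(
            self._markers(["m1", "m2"]),
            {"m1": ("chr1", 150), "m2": ("chr1", 160)},
            annotation,
        )
        assert out.iloc[0]["best_rank"] == 1 and out.iloc[0]["n_markers"] == 2

    def test_invariant_to_marker_order(self, annotation):
        feats = ["m1", "m2", "m3"]
        positions = {"m1": ("chr1", 150), "m2": ("chr1", 350), "m3": ("chr1", 120)}
        fwd = on.map_markers_to_genes(self._markers(feats), positions, annotation)
        rev_records = self._markers(feats).records.iloc[::-1].reset_index(drop=True)
        rev = on.map_markers_to_genes(
            MarkerSet(records=rev_records, rule="test"), positions, annotation
        )
        pd.testing.assert_frame_equal(fwd, rev)

    def test_interval_distance_convention(self):
        assert _interval_distance(250, 100, 200) == 51
        assert _interval_distance(250, 300, 400) == 50
        assert _interval_distance(150, 100, 200) == 0
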
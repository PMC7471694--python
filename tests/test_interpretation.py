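"""Activation PCA and explanatory linear models."""

import numpy as np
import pandas as pd
import pytest

from padbench.benchmark import ArchitectureSpec, build_model
from padbench.codec import default_alphabet
from padbench.data import LabeledSample
from padbench.interpretation import (ActivationMatrix, InterpretationError,
                                     QUESTION_DESIGNS, explain_f1,
                                     extract_activations, fit_f1_model,
                                     pc1_model, pca_filters,
                                     sample_test_proteins, score_density_grids)

ARCHS = ("only_denses", "1_conv", "stack_conv")
PADDINGS = ("post", "pre", "mid", "ext", "strf", "rnd", "zoom", "aug")


def _samples_with_classes():
    rng = np.random.default_rng(0)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    out = []
    i = 0
    for cls in range(8):
        for _ in range(8):
            seq = "".join(rng.choice(aa, size=30))
            if cls == 0:
                out.append(LabeledSample(f"s{i}", seq, 0, None, f"s{i}"))
            else:
                out.append(LabeledSample(f"s{i}", seq, 1, cls, f"s{i}"))
            i += 1
    return out


class TestSampleTestProteins:
    def test_task1_panel_is_14(self):
        ids = sample_test_proteins(_samples_with_classes(), task=1, per_class=7)
        assert len(ids) == 14 and len(set(ids)) == 14

    def test_task2_panel_is_14(self):
        ids = sample_test_proteins(_samples_with_classes(), task=2)
        assert len(ids) == 14

    def test_class_too_small_names_class(self):
        with pytest.raises(InterpretationError, match="class 1"):
            sample_test_proteins(_samples_with_classes(), task=2, per_class=9)

    def test_seeded_selection_is_stable(self):
        s = _samples_with_classes()
        assert (sample_test_proteins(s, 2, seed=1)
                == sample_test_proteins(s, 2, seed=1))


class TestExtractActivations:
    def test_count_and_shape_follow_configuration_product(self):
        samples = {s.id: s for s in _samples_with_classes()}
        ids = sample_test_proteins(list(samples.values()), task=2)
        alphabet = default_alphabet()
        spec = ArchitectureSpec("1_conv", conv_filters=16)
        models = {(fold, mode): build_model(spec, (26, 40), 1, seed=fold)
                  for fold in range(2) for mode in ("post", "strf", "zoom")}
        mats = extract_activations(models, samples, ids, task=2, T=40,
                                   alphabet=alphabet)
        assert len(mats) == 2 * 3 * 14
        assert all(m.values.shape == (16, 40) for m in mats)
        assert {m.padding for m in mats} == {"post", "strf", "zoom"}


class TestPcaFilters:
    def _matrices(self, rows, T, n, seed=0):
        rng = np.random.default_rng(seed)
        return [ActivationMatrix(rng.random((rows, T)), fold=0, padding="post",
                                 enzyme_type="1", source_id=f"m{i}")
                for i in range(n)]

    def test_filter_rows_become_samples(self):
        res = pca_filters(self._matrices(8, 20, 5), n_components=3)
        assert len(res.scores) == 8 * 5
        assert res.loadings.shape == (3, 20)

    def test_loadings_orthonormal_and_ratios_non_increasing(self):
        res = pca_filters(self._matrices(8, 20, 5), n_components=4)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(4), atol=1e-8)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all() and evr.sum() <= 1 + 1e-9

    def test_planar_data_explained_by_two_components(self):
        rng = np.random.default_rng(1)
        basis = rng.random((2, 30))
        coords = rng.random((40, 2)) @ basis   # exactly rank 2
        mats = [ActivationMatrix(coords[i * 4:(i + 1) * 4], 0, "post", "1", f"m{i}")
                for i in range(10)]
        res = pca_filters(mats, n_components=3)
        assert res.explained_variance_ratio[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_match_covariance_eigendecomposition(self):
        """Independent oracle: eigenvectors of the sample covariance."""
        mats = self._matrices(5, 12, 10)
        res = pca_filters(mats, n_components=3)
        X = np.vstack([m.values for m in mats])
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for k in range(3):
            expected = Xc @ v[:, order[k]]
            got = res.scores[f"pc{k+1}"].to_numpy()
            # eigenvector sign is arbitrary
            assert (np.allclose(got, expected, atol=1e-6)
                    or np.allclose(got, -expected, atol=1e-6))


class TestPc1Model:
    def _scores(self, rng, class_effects, pad_effects, n_per=30, sigma=1.0):
        rows = []
        for etype, ce in class_effects.items():
            for pmode, pe in pad_effects.items():
                for _ in range(n_per):
                    rows.append(dict(enzyme_type=etype, padding=pmode,
                                     pc1=ce + pe + rng.normal(0, sigma)))
        return pd.DataFrame(rows)

    def test_recovers_planted_additive_effects(self, rng):
        class_effects = {"1": 0.0, "2": -3.0, "5": 2.0}
        pad_effects = {"post": 0.0, "strf": 4.0, "rnd": -1.5}
        df = self._scores(rng, class_effects, pad_effects)
        res = pc1_model(df)
        for _, row in res.params.iterrows():
            planted = (class_effects if row["term"] == "enzyme_type"
                       else pad_effects)[row["level"]]
            assert abs(row["estimate"] - planted) <= 3 * row["se"]

    def test_zero_variance_response_gives_zero_slopes(self, rng):
        df = self._scores(rng, {"1": 0.0, "2": 0.0}, {"post": 0.0, "strf": 0.0},
                          sigma=0.0)
        res = pc1_model(df)
        assert np.allclose(res.params["estimate"], 0.0, atol=1e-10)

    def test_permuted_labels_rarely_significant(self):
        """Null calibration: after shuffling labels, adjusted p > 0.05 for
        every term in >= 90% of replicates."""
        rng = np.random.default_rng(42)
        base = self._scores(rng, {"1": 0.0, "2": 5.0}, {"post": 0.0, "strf": 3.0},
                            n_per=20)
        clean = 0
        n_rep = 100
        for _ in range(n_rep):
            perm = base.copy()
            perm["pc1"] = rng.permutation(perm["pc1"].to_numpy())
            res = pc1_model(perm)
            if (res.params["p_adj"] > 0.05).all():
                clean += 1
        assert clean >= 0.9 * n_rep


def _f1_table(rng, arch_eff, pad_eff, enz_eff, task=1, sigma=0.02, folds=10):
    labels = ["0", "1"] if task == 1 else [str(c) for c in range(1, 8)]
    rows = []
    for a in ARCHS:
        for p in PADDINGS:
            for e in labels:
                for fold in range(folds):
                    rows.append(dict(task=task, architecture=a, padding=p,
                                     metric="f1", label=e, fold=fold,
                                     value=0.7 + arch_eff.get(a, 0.0)
                                     + pad_eff.get(p, 0.0) + enz_eff.get(e, 0.0)
                                     + rng.normal(0, sigma)))
    return pd.DataFrame(rows)


class TestExplainF1:
    def test_pure_architecture_effect_recovered_padding_null(self, rng):
        arch_eff = {"1_conv": -0.06, "stack_conv": -0.03}
        table = _f1_table(rng, arch_eff, {}, {})
        res = explain_f1(table, "full", task=1)
        arch_rows = res.params[res.params["term"] == "architecture"]
        for _, row in arch_rows.iterrows():
            assert abs(row["estimate"] - arch_eff[row["level"]]) <= 3 * row["se"]
        pad_rows = res.params[res.params["term"] == "padding"]
        assert (pad_rows["p_adj"] > 0.05).all()

    def test_question_d_planted_aug_deficit(self, rng):
        """With a planted aug deficit, post and strf beat the aug reference."""
        table = _f1_table(rng, {}, {"aug": -0.08}, {})
        res = explain_f1(table, "D", task=1)
        main = res.params[res.params["term"] == "padding"]
        assert set(main["level"]) == {"post", "strf"}
        assert (main["estimate"] > 0).all()
        assert (main["p_adj"] < 0.05).all()

    def test_intercept_of_reference_only_design_is_mean(self, rng):
        table = _f1_table(rng, {}, {}, {}, sigma=0.01)
        sub = table.query(
            "architecture == 'only_denses' and padding == 'post' and label == '0'")
        res = fit_f1_model(
            sub.rename(columns={"label": "enzyme_type", "value": "f1"}),
            pad_ref="post", enzyme_ref="0", question="ref-only")
        assert res.intercept == pytest.approx(sub["value"].mean(), abs=1e-10)

    def test_question_e_rejected_for_task1(self, rng):
        table = _f1_table(rng, {}, {}, {})
        with pytest.raises(InterpretationError, match="task 2"):
            explain_f1(table, "E", task=1)

    def test_question_e_interaction_terms_present(self, rng):
        table = _f1_table(rng, {}, {"strf": 0.02}, {"4": -0.1}, task=2)
        res = explain_f1(table, "E", task=2)
        inter = res.params[res.params["term"] == "padding:enzyme_type"]
        assert len(inter) == 6   # (2-1) paddings x (7-1) enzyme types

    def test_missing_required_padding_is_an_error(self, rng):
        table = _f1_table(rng, {}, {}, {})
        with pytest.raises(InterpretationError, match="missing"):
            explain_f1(table[table["padding"] != "aug"], "D", task=1)

    def test_bh_adjustment_monotone_and_at_least_raw(self, rng):
        table = _f1_table(rng, {"1_conv": -0.05}, {"rnd": -0.04}, {})
        res = explain_f1(table, "full", task=1)
        df = res.params.sort_values("p")
        assert (df["p_adj"].to_numpy() >= df["p"].to_numpy() - 1e-15).all()
        assert (np.diff(df["p_adj"].to_numpy()) >= -1e-12).all()

    def test_question_designs_match_benchmark_protocol(self):
        assert QUESTION_DESIGNS["A"]["archs"] == ("only_denses",)
        assert QUESTION_DESIGNS["B"]["paddings"] == ("post", "pre", "mid", "ext")
        assert QUESTION_DESIGNS["C"]["paddings"] == ("post", "strf", "rnd", "zoom")
        assert QUESTION_DESIGNS["D"]["pad_ref"] == "aug"
        assert QUESTION_DESIGNS["E"]["interaction"] == "padding:enzyme_type"


class TestDensityGrids:
    def test_density_grid_per_stratum(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "pc1": rng.normal(size=200), "pc2": rng.normal(size=200),
            "padding": np.repeat(["post", "strf"], 100),
            "enzyme_type": np.tile(np.repeat(["1", "2"], 50), 2),
        })
        grids = score_density_grids(df, gridsize=8)
        assert set(grids["padding"]) == {"post", "strf"}
        assert (grids["density"] >= 0).all()
        assert len(grids) == 4 * 64
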
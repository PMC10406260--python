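import numpy as np
import pandas as pd
import pytest

from contexseg.dataset import build_study_data
from contexseg.grid import (
    GridConfig,
    dice,
    evaluate_setting_pair,
    locate_extremes,
    relative_improvement,
    run_grid,
    settings_axis,
)
from contexseg.model import ModelConfig, TrainConfig
from contexseg.modifications import ModificationSetting
from contexseg.phantom import Protocol, enumerate_protocols


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:3, 1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), dtype=bool)
        b = np.zeros((5, 5), dtype=bool)
        a[0, 0] = True
        b[4, 4] = True
        assert dice(a, b) == 0.0

    def test_partial_overlap_counts(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a.flat[:4] = True          # |A| = 4
        b.flat[1:7] = True         # |B| = 6, overlap 3
        assert dice(a, b) == pytest.approx(2 * 3 / (4 + 6))

    def test_empty_conventions(self):
        empty = np.zeros((3, 3), dtype=bool)
        full = ~empty
        assert dice(empty, empty) == 1.0
        assert dice(empty, full) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestSettingsAxis:
    def test_ori_centered_for_symmetric_strengths(self):
        axis = settings_axis("contrast", (-21, -11, -4, 4, 11, 21))
        labels = [s.label for s in axis]
        assert labels == ["-21", "-11", "-4", "Ori", "4", "11", "21"]

    def test_reference_scale_axis_has_41_settings(self):
        strengths = list(range(-21, -1)) + list(range(2, 22))
        axis = settings_axis("contrast", strengths)
        assert len(axis) == 41


class TestLocateExtremes:
    @staticmethod
    def _matrix(vals, labels):
        return pd.DataFrame(vals, index=labels, columns=labels)

    def test_constant_matrix_ties_break_row_major(self):
        m = self._matrix(np.full((3, 3), 0.5), ["-5", "Ori", "5"])
        ext = locate_extremes(m)
        assert ext["best"] == ("-5", "-5", 0.5)
        assert ext["worst"] == ("-5", "-5", 0.5)

    def test_opposite_is_point_reflection_of_worst(self):
        labels = ["-21", "Ori", "21"]
        vals = np.full((3, 3), 0.8)
        vals[0, 2] = 0.1  # worst at (-21, 21)
        ext = locate_extremes(self._matrix(vals, labels))
        assert ext["worst"][:2] == ("-21", "21")
        assert ext["opposite_bad"][:2] == ("21", "-21")

    def test_matches_exhaustive_scan_on_random_matrix(self):
        rng = np.random.default_rng(0)
        labels = ["-9", "-3", "Ori", "3", "9"]
        vals = rng.uniform(0, 1, (5, 5))
        ext = locate_extremes(self._matrix(vals, labels))
        bi, bj = divmod(int(vals.argmax()), 5)
        wi, wj = divmod(int(vals.argmin()), 5)
        assert ext["best"] == (labels[bi], labels[bj], vals[bi, bj])
        assert ext["worst"] == (labels[wi], labels[wj], vals[wi, wj])

    def test_missing_cells_rejected(self):
        vals = np.full((3, 3), 0.5)
        vals[1, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            locate_extremes(self._matrix(vals, ["-5", "Ori", "5"]))

    def test_relative_improvement_matches_table_convention(self):
        labels = ["-5", "Ori", "5"]
        vals = np.full((3, 3), 0.813)
        vals[0, 2] = 0.897
        m = self._matrix(vals, labels)
        assert relative_improvement(m, "-5", "5") == pytest.approx(
            (0.897 - 0.813) / 0.813)


class TestEvaluation:
    def test_overfit_model_scores_its_own_image(self, toy_model,
                                                toy_phantom):
        scores = evaluate_setting_pair(
            toy_model, ModificationSetting.none(), [toy_phantom],
            [toy_phantom.protocol])
        assert scores.shape == (3, 1)
        assert (scores > 0.95).all()

    def test_single_image_equals_direct_dice(self, toy_model, toy_phantom):
        from contexseg.model import predict_labels, prepare_input

        scores = evaluate_setting_pair(
            toy_model, ModificationSetting.none(), [toy_phantom],
            [toy_phantom.protocol])
        x = prepare_input(toy_phantom, ModificationSetting.none())
        pred = predict_labels(toy_model, x)
        gt = toy_phantom.label_map.labels
        for ti, t in enumerate((1, 2, 3)):
            assert scores[ti, 0] == pytest.approx(dice(pred == t, gt == t))


def _micro_grid_pieces():
    protocols = enumerate_protocols((400, 600, 200), (20, 20, 5))  # 2
    data = build_study_data(protocols, n_subjects=5, size=(32, 32),
                            ratio=(3, 1, 1), seed=9)
    model_cfg = ModelConfig(input_size=(32, 32), depth=2, base_channels=4,
                            dropout_rate=0.0)
    train_cfg = TrainConfig(epochs=2, learning_rate=1e-3, batch_size=4)
    return protocols, data, model_cfg, train_cfg


class TestRunGrid:
    def test_single_cell_grid_equals_direct_evaluation(self):
        protocols, data, model_cfg, train_cfg = _micro_grid_pieces()
        none = (ModificationSetting.none(),)
        cfg = GridConfig(train_settings=none, test_settings=none,
                         protocols=tuple(protocols), n_runs=1, base_seed=5,
                         model_cfg=model_cfg, train_cfg=train_cfg)
        result = run_grid(cfg, data)
        from contexseg.model import train_model

        model = train_model(data.train, data.val,
                            ModificationSetting.none(), model_cfg,
                            TrainConfig(epochs=2, learning_rate=1e-3,
                                        batch_size=4, seed=5))
        direct = evaluate_setting_pair(model, ModificationSetting.none(),
                                       data.test, protocols)
        for ti, tissue in enumerate(("CSF", "GM", "WM")):
            cell = result.heatmaps[tissue].values.loc["Ori", "Ori"]
            assert cell == pytest.approx(direct[ti].mean(), abs=1e-12)

    def test_cell_values_independent_of_axis_order(self):
        protocols, data, model_cfg, train_cfg = _micro_grid_pieces()
        s_pos = ModificationSetting("contrast", 11)
        none = ModificationSetting.none()
        cfg_a = GridConfig(train_settings=(none, s_pos),
                           test_settings=(none, s_pos),
                           protocols=tuple(protocols), n_runs=1,
                           base_seed=5, model_cfg=model_cfg,
                           train_cfg=train_cfg)
        cfg_b = GridConfig(train_settings=(s_pos, none),
                           test_settings=(s_pos, none),
                           protocols=tuple(protocols), n_runs=1,
                           base_seed=5, model_cfg=model_cfg,
                           train_cfg=train_cfg)
        res_a = run_grid(cfg_a, data)
        res_b = run_grid(cfg_b, data)
        for tissue in ("CSF", "GM", "WM"):
            va = res_a.heatmaps[tissue].values
            vb = res_b.heatmaps[tissue].values
            for tr in ("Ori", "11"):
                for te in ("Ori", "11"):
                    assert va.loc[tr, te] == vb.loc[tr, te]

    def test_heatmap_invariant_mean_over_protocols(self):
        protocols, data, model_cfg, train_cfg = _micro_grid_pieces()
        none = (ModificationSetting.none(),)
        cfg = GridConfig(train_settings=none, test_settings=none,
                         protocols=tuple(protocols), n_runs=2, base_seed=0,
                         model_cfg=model_cfg, train_cfg=train_cfg)
        result = run_grid(cfg, data)
        for hm in result.heatmaps.values():
            assert np.allclose(hm.values.to_numpy(),
                               hm.per_protocol.mean(axis=2))
            assert ((hm.values.to_numpy() >= 0)
                    & (hm.values.to_numpy() <= 1)).all()

    def test_resume_from_cache_restores_models(self, tmp_path):
        protocols, data, model_cfg, train_cfg = _micro_grid_pieces()
        none = (ModificationSetting.none(),)
        cfg = GridConfig(train_settings=none, test_settings=none,
                         protocols=tuple(protocols), n_runs=1, base_seed=1,
                         model_cfg=model_cfg, train_cfg=train_cfg)
        first = run_grid(cfg, data, cache_dir=tmp_path)
        second = run_grid(cfg, data, cache_dir=tmp_path)  # all cached
        assert set(second.models) == set(first.models)
        for tissue in ("CSF", "GM", "WM"):
            assert first.heatmaps[tissue].values.equals(
                second.heatmaps[tissue].values)

    def test_mixed_kinds_rejected(self):
        protocols = (Protocol(500, 25),)
        with pytest.raises(ValueError, match="mix"):
            GridConfig(
                train_settings=(ModificationSetting("contrast", 5),
                                ModificationSetting("texture", 5)),
                test_settings=(ModificationSetting.none(),),
                protocols=protocols,
            )
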
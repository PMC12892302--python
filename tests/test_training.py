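"""Pair selection, fold balance, augmentation, train loop, inference."""

import numpy as np
import pandas as pd
import pytest

from deepsuvr import centiloid as cc
from deepsuvr import phantom as ph
from deepsuvr import training as tr
from deepsuvr.model import desk_config


def _table(times, subject="s1"):
    return pd.DataFrame(
        {
            "scan_id": [f"{subject}_{i}" for i in range(len(times))],
            "subject_id": subject,
            "time_years": times,
        }
    )


class TestSelectPairs:
    def test_three_visits_all_permutations(self):
        pairs = tr.select_pairs(_table([0.0, 1.0, 2.0]))
        got = {(r.idx_a, r.idx_b) for r in pairs.itertuples()}
        assert got == {(0, 1), (1, 2), (0, 2)}

    def test_short_interval_excluded(self):
        assert len(tr.select_pairs(_table([0.0, 0.1]))) == 0

    def test_long_interval_excluded(self):
        pairs = tr.select_pairs(_table([0.0, 2.0, 4.0]))
        got = {(r.idx_a, r.idx_b) for r in pairs.itertuples()}
        assert got == {(0, 1), (1, 2)}

    def test_no_cross_subject_pairs(self):
        t = pd.concat([_table([0.0, 1.0], "a"), _table([0.0, 1.0], "b")], ignore_index=True)
        pairs = tr.select_pairs(t)
        assert len(pairs) == 2
        assert set(pairs["subject_id"]) == {"a", "b"}


def _subject_table(n=100, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        sid = f"s{i:03d}"
        tracer = rng.choice(["PIB", "FBB", "FBP"], p=[0.5, 0.25, 0.25])
        for v in range(int(rng.integers(2, 4))):
            rows.append(
                dict(
                    scan_id=f"{sid}_{v}",
                    subject_id=sid,
                    tracer=tracer,
                    time_years=float(v),
                    true_CL=float(rng.uniform(0, 100)),
                )
            )
    return pd.DataFrame(rows)


class TestSplitFolds:
    def test_partition_and_determinism(self):
        t = _subject_table()
        f1 = tr.split_folds(t, seed=4)
        f2 = tr.split_folds(t, seed=4)
        assert f1 == f2
        assert set(f1) == set(t["subject_id"].unique())
        assert set(f1.values()) == {0, 1, 2, 3, 4}

    def test_tracer_proportions_balanced(self):
        t = _subject_table(150, seed=1)
        folds = tr.split_folds(t, seed=2)
        subj = t.groupby("subject_id")["tracer"].first()
        overall = subj.value_counts(normalize=True)
        for k in range(5):
            members = [s for s, f in folds.items() if f == k]
            frac = subj.loc[members].value_counts(normalize=True)
            for tracer in overall.index:
                assert abs(frac.get(tracer, 0.0) - overall[tracer]) < 0.10

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="subjects"):
            tr.split_folds(_subject_table(3), n_folds=5)


class TestAugment:
    def test_identity_spec_returns_input(self, grid16):
        vol = ph.render_volume(grid16, 40.0, ph.AcquisitionSpec("PIB", psf_fwhm_mm=4.0))
        spec = tr.AugmentationSpec(
            max_rotation_deg=0.0, nonrigid_sigma_vox=0.0, nonrigid_magnitude_vox=0.0, max_fwhm_mm=4.0
        )
        out = tr.augment(vol, spec, seed=0, psf_fwhm_mm=4.0, voxel_size_mm=6.0)
        np.testing.assert_allclose(out, vol, atol=1e-6)

    def test_deterministic_given_seed(self, grid16):
        vol = ph.render_volume(grid16, 40.0, ph.AcquisitionSpec("PIB", psf_fwhm_mm=4.0))
        spec = tr.AugmentationSpec(seed=0)
        a = tr.augment(vol, spec, seed=5, psf_fwhm_mm=4.0, voxel_size_mm=6.0)
        b = tr.augment(vol, spec, seed=5, psf_fwhm_mm=4.0, voxel_size_mm=6.0)
        assert np.array_equal(a, b)
        c = tr.augment(vol, spec, seed=6, psf_fwhm_mm=4.0, voxel_size_mm=6.0)
        assert not np.array_equal(a, c)

    def test_approximately_mass_conserving(self, grid16):
        """Blur and small rotations/warps redistribute intensity but leave
        the total image mass nearly unchanged (interpolation and field-of-
        view edges account for the small remainder)."""
        vol = ph.render_volume(grid16, 60.0, ph.AcquisitionSpec("FBP", psf_fwhm_mm=4.0))
        spec = tr.desk_augmentation(grid16.voxel_size_mm)
        out = tr.augment(vol, spec, seed=1, psf_fwhm_mm=4.0, voxel_size_mm=6.0)
        assert out.sum() == pytest.approx(vol.sum(), rel=0.02)

    def test_psf_above_cap_raises(self, grid16):
        vol = np.zeros(grid16.shape)
        with pytest.raises(ValueError, match="cap"):
            tr.augment(vol, tr.AugmentationSpec(), seed=0, psf_fwhm_mm=9.0)


class TestTrainLoop:
    def test_subject_leakage_rejected(self, small_data, small_pairs, pib_curve):
        subjects = set(small_data.table["subject_id"])
        with pytest.raises(ValueError, match="overlap"):
            tr.train_model(small_data, small_pairs, pib_curve, subjects, subjects)

    def test_short_training_reduces_loss(self, small_data, small_pairs, pib_curve):
        subjects = sorted(set(small_data.table["subject_id"]))
        val = set(subjects[:12])
        train = set(subjects[12:])
        cfg = tr.TrainConfig(max_epochs=15, restarts=1, patience=15, seed=0)
        res = tr.train_model(small_data, small_pairs, pib_curve, train, val, train_cfg=cfg)
        log = res.log
        first = log.iloc[0][["L_d", "L_c", "L_s", "L_i"]]
        last = log.iloc[-1][["L_d", "L_c", "L_s", "L_i"]]
        w = dict(alpha=0.2, beta=1.0, gamma=0.01)
        total_first = first.L_d + w["alpha"] * first.L_c + w["beta"] * first.L_s + w["gamma"] * first.L_i
        total_last = last.L_d + w["alpha"] * last.L_c + w["beta"] * last.L_s + w["gamma"] * last.L_i
        assert total_last <= total_first
        assert res.restart == 0
        assert np.isfinite(res.val_spearman)


class _ConstantCF:
    def __init__(self, cf):
        self.cf = cf

    def predict(self, vols, one_hot):
        return np.full(np.asarray(vols).shape[0], self.cf)


class TestInference:
    def test_identity_correction_preserves_standard_cl(self, grid_desk, transforms_desk):
        target, reference = cc.standard_masks(grid_desk)
        vol = ph.render_volume(grid_desk, 60.0, ph.AcquisitionSpec("PIB"))
        cf, suvr_c, cl_c = tr.infer_corrected_centiloid(
            _ConstantCF(1.0), vol, "PIB", target, reference, transforms_desk["PIB"]
        )
        suvr_std, cl_std = cc.quantify(vol, target, reference, transforms_desk["PIB"])
        assert cf == 1.0
        assert suvr_c == pytest.approx(suvr_std)
        assert cl_c == pytest.approx(cl_std)

    def test_cf_composes_through_transform(self, grid_desk, transforms_desk):
        target, reference = cc.standard_masks(grid_desk)
        vol = ph.render_volume(grid_desk, 80.0, ph.AcquisitionSpec("FBP"))
        suvr_std, _ = cc.quantify(vol, target, reference, transforms_desk["FBP"])
        _, suvr_c, cl_c = tr.infer_corrected_centiloid(
            _ConstantCF(0.8), vol, "FBP", target, reference, transforms_desk["FBP"]
        )
        assert suvr_c == pytest.approx(0.8 * suvr_std)
        assert cl_c == pytest.approx(cc.apply_centiloid(0.8 * suvr_std, transforms_desk["FBP"]))

    def test_wrong_transform_tracer_raises(self, grid_desk, transforms_desk):
        target, reference = cc.standard_masks(grid_desk)
        vol = ph.render_volume(grid_desk, 10.0, ph.AcquisitionSpec("PIB"))
        with pytest.raises(ValueError, match="transform"):
            tr.infer_corrected_centiloid(
                _ConstantCF(1.0), vol, "PIB", target, reference, transforms_desk["FBB"]
            )

    def test_batch_inference_equals_per_scan(self, small_data):
        model = tr.build_network(desk_config(small_data.volumes.shape[1:], seed=3))
        out = tr.infer_cohort(model, small_data)
        for i in (0, 5, 17):
            single = model.predict(small_data.volumes[i][None], small_data.one_hot[i][None])
            assert out["CF"].iloc[i] == pytest.approx(float(single[0]), rel=1e-12)
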
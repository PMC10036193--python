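"""Preprocessing, dataset round-trips, pipeline contracts, CLI smoke."""
import json

import numpy as np
import pandas as pd
import pytest

from vertemtl import interfaces, phantom
from vertemtl.interfaces import CaseSkipped, preprocess, run_pipeline
from vertemtl.model import JointConfig, JointModel


class TestPreprocess:
    def test_uint8_nominal_range(self):
        img = np.zeros((512, 512), np.uint8)
        img[0, 0] = 255
        img[0, 1] = 0
        out = preprocess(img)
        assert out[0, 0] == pytest.approx(1.0)
        assert out[0, 1] == pytest.approx(0.0)

    def test_uint16_nominal_range(self):
        img = np.full((512, 512), 65535, np.uint16)
        assert preprocess(img).max() == pytest.approx(1.0)

    def test_already_512_is_identity(self, rng):
        img = (rng.random((512, 512)) * 255).astype(np.uint8)
        out = preprocess(img)
        assert np.allclose(out, img / 255.0, atol=1e-7)

    def test_resize_to_512(self, rng):
        img = (rng.random((256, 300)) * 255).astype(np.uint8)
        assert preprocess(img).shape == (512, 512)

    def test_constant_stays_constant(self):
        out = preprocess(np.full((100, 100), 40, np.uint8))
        assert np.allclose(out, 40 / 255.0, atol=1e-6)

    def test_unit_float_kept_on_nominal_scale(self):
        img = np.full((512, 512), 0.25, np.float32)
        img[0, 0] = 0.75
        out = preprocess(img)
        assert out[5, 5] == pytest.approx(0.25)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((4, 4, 3)))


def test_nifti_export_round_trip(tmp_path, small_cfg):
    import nibabel as nib

    cases, manifest = phantom.generate_dataset(small_cfg, (1, 0, 0),
                                               np.random.default_rng(2))
    phantom.save_dataset(cases, manifest, tmp_path, nifti=True)
    vol = nib.load(tmp_path / "nifti" / f"{cases[0].case_id}_l1.nii.gz")
    assert np.array_equal(np.asarray(vol.dataobj),
                          cases[0].slice_l1.astype(np.float32))


def test_dataset_round_trip_is_stable(tmp_path, small_cfg):
    cases, manifest = phantom.generate_dataset(small_cfg, (1, 1, 1),
                                               np.random.default_rng(5))
    phantom.save_dataset(cases, manifest, tmp_path / "a")
    loaded, man2 = phantom.load_dataset(tmp_path / "a")
    pd.testing.assert_frame_equal(manifest, man2)
    # write what was read: every artifact re-reads bit-identically
    phantom.save_dataset(loaded, man2, tmp_path / "b")
    loaded2, _ = phantom.load_dataset(tmp_path / "b")
    for a, b in zip(loaded, loaded2):
        assert np.array_equal(a.slice_l1, b.slice_l1)
        assert np.array_equal(a.mask_l2, b.mask_l2)
        assert a.box_l1 == b.box_l1


@pytest.fixture(scope="module")
def tiny_model():
    return JointModel(JointConfig(seed=0))


def test_missing_slice_is_an_error(tiny_model):
    img = np.random.default_rng(0).random((512, 512)).astype(np.float32)
    with pytest.raises(ValueError):
        run_pipeline(img, None, tiny_model)


def test_pipeline_deterministic_and_complete(tiny_model, small_case):
    # untrained weights: force detection with a zero threshold, skip the
    # level-set stage for speed
    r1 = run_pipeline(small_case.slice_l1, small_case.slice_l2, tiny_model,
                      refine=False, obj_threshold=0.0)
    r2 = run_pipeline(small_case.slice_l1, small_case.slice_l2, tiny_model,
                      refine=False, obj_threshold=0.0)
    assert np.array_equal(r1.prediction.posterior, r2.prediction.posterior)
    assert r1.boxes["l1"] == r2.boxes["l1"]
    assert r1.prediction.posterior.sum() == pytest.approx(1.0, abs=1e-5)
    assert r1.crops["l1"].shape == (224, 224)
    assert r1.metadata["config_hash"] == interfaces.config_hash(tiny_model.config)


def test_failed_case_does_not_abort_batch(tiny_model, small_case, monkeypatch):
    calls = {"n": 0}
    real = interfaces.loc.detect

    def flaky(img, net, **kw):
        calls["n"] += 1
        return None if calls["n"] == 1 else real(img, net, obj_threshold=0.0)

    monkeypatch.setattr(interfaces.loc, "detect", flaky)
    cases = [small_case, small_case]
    results, skipped = interfaces.run_batch(cases, tiny_model, refine=False)
    assert len(results) == 1 and len(skipped) == 1


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    from vertemtl import nn
    from vertemtl.nn import Tensor

    path = tmp_path / "ckpt.npz"
    tiny_model.save(path)
    clone = JointModel.load(path)
    x = Tensor(rng.random((1, 1, 224, 224)).astype(np.float32))
    tiny_model.eval()
    clone.eval()
    with nn.no_grad():
        a = tiny_model.segnet(x).mask_prob.data
        b = clone.segnet(x).mask_prob.data
    assert np.array_equal(a, b)


def test_write_results_round_trip(tmp_path, tiny_model, small_case):
    res = run_pipeline(small_case.slice_l1, small_case.slice_l2, tiny_model,
                       case_id=small_case.case_id, refine=False,
                       obj_threshold=0.0)
    interfaces.write_results([res], tmp_path)
    preds = pd.read_csv(tmp_path / "predictions.csv")
    assert preds.loc[0, "label"] == res.prediction.predicted_label
    assert preds.loc[0, "p_normal"] == pytest.approx(res.prediction.posterior[0],
                                                     abs=1e-6)
    with open(tmp_path / "boxes.json") as fh:
        boxes = json.load(fh)
    assert boxes["fix_case_l1"]["cx"] == pytest.approx(res.boxes["l1"][0])
    heat = np.load(tmp_path / "heat" / "fix_case_l1.npy")
    assert np.array_equal(heat, res.heat_maps["l1"].astype(np.float32))


def test_yaml_config_resolution(tmp_path):
    cfg_path = tmp_path / "cfg.yaml"
    cfg_path.write_text(
        "model:\n  lf: false\n  seg:\n    base_channels: 2\n"
        "sampler:\n  alpha: 0.3\n"
        "trainer:\n  epochs: 1\n  lr: 0.01\n"
        "levelset:\n  n_iter: 7\n")
    cfgs = interfaces.load_config(cfg_path)
    assert cfgs["joint"].lf is False
    assert cfgs["joint"].seg.base_channels == 2
    assert cfgs["trainer"].mix.alpha == 0.3
    assert cfgs["trainer"].epochs == 1
    assert cfgs["levelset"].n_iter == 7
    interfaces.write_resolved_config(cfgs, tmp_path)
    assert (tmp_path / "resolved_config.yaml").exists()


def test_cli_phantom_and_heatlabel(tmp_path):
    from click.testing import CliRunner

    from vertemtl.cli import main

    runner = CliRunner()
    out = tmp_path / "cohort"
    res = runner.invoke(main, ["phantom", "--n-per-class", "1", "1", "1",
                               "--seed", "3", "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "manifest.csv").exists()
    assert len(list((out / "images").glob("*.png"))) == 6
    res = runner.invoke(main, ["heatlabel", "--masks", str(out / "masks"),
                               "--sigma", "2", "--out", str(tmp_path / "heat")])
    assert res.exit_code == 0, res.output
    assert len(list((tmp_path / "heat").glob("*.npy"))) == 6
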
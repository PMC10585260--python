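"""Configuration loading, per-image processing, batch determinism."""

import json
from pathlib import Path

import numpy as np
import pytest
import yaml
from PIL import Image

from fruitpheno.batch import (
    ConfigError,
    PipelineConfig,
    load_config,
    process_batch,
    process_image,
    result_columns,
)
from fruitpheno.color_model import ChannelInterval, ThresholdSpec
from fruitpheno.synthetic import (
    default_scene,
    render_scene,
    scene_analysis_config,
    truth_report,
)

# The six published settings rows: (step, year, a* lower bound); L and b FR.
SETTINGS_ROWS = [
    ("background", 2019, -10.00),
    ("background", 2020, -12.00),
    ("background", 2021, -8.50),
    ("rdr", 2019, 7.51),
    ("rdr", 2020, 16.15),
    ("rdr", 2021, 8.58),
]


def year_config_dict(year):
    bg = {v for s, y, v in SETTINGS_ROWS if s == "background" and y == year}.pop()
    rdr = {v for s, y, v in SETTINGS_ROWS if s == "rdr" and y == year}.pop()
    return {
        "background": [{"space": "lab", "channel": "a", "min": bg}],
        "features": {"rdr": [{"space": "lab", "channel": "a", "min": rdr}]},
        "traits": ["feature_pct"],
    }


class TestConfig:
    @pytest.mark.parametrize("year", [2019, 2020, 2021])
    def test_settings_table_rows_load_verbatim(self, tmp_path, year):
        """Each year's published settings row (FR channels unconstrained,
        strict '>' bounds on a*) is expressible directly as a config."""
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(year_config_dict(year)))
        cfg = load_config(path)
        (iv,) = cfg.background.intervals
        assert iv.channel == "a" and iv.lo_strict and iv.hi is None
        expected = {2019: -10.00, 2020: -12.00, 2021: -8.50}[year]
        assert iv.lo == expected
        (riv,) = cfg.features["rdr"].intervals
        assert riv.lo == {2019: 7.51, 2020: 16.15, 2021: 8.58}[year]

    @pytest.mark.parametrize("year", [2019, 2020, 2021])
    def test_round_trip_identity(self, tmp_path, year):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(year_config_dict(year)))
        cfg = load_config(path)
        out = tmp_path / "echo.yaml"
        cfg.save(out)
        cfg2 = load_config(out)
        assert cfg2 == cfg
        assert cfg2.to_dict() == cfg.to_dict()

    def test_unknown_keys_rejected_with_listing(self, tmp_path):
        d = year_config_dict(2019)
        d["bogus_key"] = 1
        d["another_bad"] = 2
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(d))
        with pytest.raises(ConfigError) as exc:
            load_config(path)
        assert "bogus_key" in str(exc.value) and "another_bad" in str(exc.value)

    def test_size_traits_require_calibration(self):
        with pytest.raises(ConfigError, match="calibration"):
            PipelineConfig(
                background=ThresholdSpec((ChannelInterval("a", lo=-10.0),)),
                traits=("length",),
            )

    def test_missing_background_rejected(self):
        with pytest.raises(ConfigError, match="background"):
            PipelineConfig.from_dict({"traits": ["feature_pct"]})

    def test_unknown_trait_rejected(self):
        with pytest.raises(ConfigError, match="unknown traits"):
            PipelineConfig(
                background=ThresholdSpec((ChannelInterval("a", lo=-10.0),)),
                traits=("girth",),
            )


class TestProcessImage:
    def test_three_berry_scene_recovers_truth(self, hard_scene, hard_cfg):
        spec, img, truth = hard_scene
        rows, summary, _ = process_image(img, hard_cfg, image_id="scene")
        assert summary["status"] == "ok"
        assert len(rows) == len(truth.berry_masks)
        report = truth_report(truth, rows)
        assert not report["count_mismatch"]
        assert report["length_max_error_mm"] == pytest.approx(0.0, abs=1e-9)
        assert report["width_max_error_mm"] == pytest.approx(0.0, abs=1e-9)
        assert summary["rdr_pct"] == pytest.approx(100 * truth.reverted_fraction, abs=1e-3)

    def test_all_background_image(self, hard_cfg):
        img_px = np.full((60, 80, 3), (60, 120, 60), dtype=np.uint8)
        from fruitpheno.preprocess import ImageRGB

        rows, summary, _ = process_image(ImageRGB(pixels=img_px), hard_cfg, image_id="green")
        assert rows == []
        assert summary["status"] == "empty_segmentation"
        assert summary["rdr_pct"] == 0.0

    def test_corrupt_file_yields_error_row(self, tmp_path, hard_cfg):
        bad = tmp_path / "broken.jpg"
        bad.write_bytes(b"this is not a JPEG")
        rows, summary, _ = process_image(bad, hard_cfg)
        assert rows == []
        assert summary["status"] == "decode_error"


class TestProcessBatch:
    @pytest.fixture()
    def scene_dir(self, tmp_path):
        d = tmp_path / "scenes"
        d.mkdir()
        for i in range(4):
            spec = default_scene(seed=100 + i, reverted_fraction=0.2, n_specks=0)
            img, _ = render_scene(spec)
            Image.fromarray(img.pixels).save(d / f"scene_{i}.png")
        return d

    def test_rows_in_filename_order_and_schema(self, scene_dir, tmp_path, hard_cfg):
        out = tmp_path / "results.csv"
        table, n_errors = process_batch(scene_dir, hard_cfg, out)
        assert n_errors == 0
        assert list(table.columns) == result_columns(hard_cfg)
        summaries = table[table.object_label == 0]
        assert list(summaries.image_id) == [f"scene_{i}.png" for i in range(4)]

    def test_reruns_are_byte_identical(self, scene_dir, tmp_path, hard_cfg):
        out1 = tmp_path / "a" / "results.csv"
        out2 = tmp_path / "b" / "results.csv"
        process_batch(scene_dir, hard_cfg, out1)
        process_batch(scene_dir, hard_cfg, out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_settings_sidecar_replays_identically(self, scene_dir, tmp_path, hard_cfg):
        out1 = tmp_path / "a" / "results.csv"
        process_batch(scene_dir, hard_cfg, out1)
        sidecar = out1.with_name("settings.json")
        replay_cfg = PipelineConfig.from_dict(json.loads(sidecar.read_text()))
        assert replay_cfg == hard_cfg
        out2 = tmp_path / "b" / "results.csv"
        process_batch(scene_dir, replay_cfg, out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_empty_directory_rejected(self, tmp_path, hard_cfg):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(FileNotFoundError):
            process_batch(empty, hard_cfg, tmp_path / "r.csv")

    def test_batch_continues_past_corrupt_file(self, scene_dir, tmp_path, hard_cfg):
        (scene_dir / "broken.jpg").write_bytes(b"junk")
        out = tmp_path / "results.csv"
        table, n_errors = process_batch(scene_dir, hard_cfg, out)
        assert n_errors == 1
        statuses = table[table.object_label == 0].set_index("image_id")["status"]
        assert statuses["broken.jpg"] == "decode_error"
        assert (statuses.drop("broken.jpg") == "ok").all()


class TestGoldenSchema:
    def test_csv_header_is_stable(self, tmp_path, hard_scene, hard_cfg):
        _, img, _ = hard_scene
        d = tmp_path / "one"
        d.mkdir()
        Image.fromarray(img.pixels).save(d / "s.png")
        out = tmp_path / "results.csv"
        process_batch(d, hard_cfg, out)
        header = out.read_text().splitlines()[0]
        assert header == (
            "image_id,object_label,n_pixels,length_mm,width_mm,area_mm2,"
            "rdr_pct,color_min_name,color_median_name,color_max_name,flags,status"
        )
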
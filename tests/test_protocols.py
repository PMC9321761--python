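"""End-to-end protocol pipelines: reports, determinism, configuration."""

import json

import numpy as np
import pytest

from pyporoscope import (
    BinaryVolume,
    DistanceVolume,
    PhantomSpec,
    ProtocolConfig,
    chamfer_distance,
    generate_binary_phantom,
    generate_gray_phantom,
    h_minima,
    label_components,
    parse_config_file,
    run_morphometry_protocol,
    run_multiphase_protocol,
    run_pore_protocol,
    watershed,
)


def _pore_phantom(shape=(48, 48, 48), seed=7):
    """Bright pore phase (Boolean balls) over a darker matrix, mild noise."""
    return generate_gray_phantom(
        PhantomSpec(
            "bimodal_gray",
            shape,
            voxel_size=2.0,
            seed=seed,
            params={
                "means": [60, 180],
                "sigma": 10,
                "geometry": {"kind": "boolean_balls", "params": {"r": 5.0, "fraction": 0.25}},
            },
        )
    )


def _grain_phantom(shape=(72, 72, 72)):
    """Three-phase gray volume: 8 touching bright grains, matrix, air pockets."""
    gp = generate_binary_phantom(
        PhantomSpec("grain_pack", shape, seed=3, params={"r": 16.0, "pitch": 28.0, "jitter": 1.0})
    )
    lab = np.where(gp.volume.data, 2, 1).astype(np.int32)
    air = generate_binary_phantom(
        PhantomSpec("boolean_balls", shape, seed=11, params={"r": 4.0, "fraction": 0.1})
    )
    lab[(~gp.volume.data) & air.volume.data] = 0
    gray = generate_gray_phantom(
        PhantomSpec(
            "multiphase_gray",
            shape,
            voxel_size=3.44,
            seed=5,
            params={"means": [20, 110, 220], "sigma": 8, "label_data": lab},
        )
    )
    return gray, gp.truth["n_grains"]


_FAST = dict(mil_directions=64)


class TestPoreProtocol:
    def test_report_contains_all_basic_analysis_fields(self, tmp_path):
        report = run_pore_protocol(
            _pore_phantom().volume, ProtocolConfig(**_FAST), outdir=tmp_path
        )
        assert set(report["basic"]) == {
            "VV", "SV_per_mm", "MV_per_mm2", "chi_v_per_mm3", "I", "EA",
        }
        assert "connectivity_density_per_mm3" in report["skeleton"]
        assert 0 < report["basic"]["VV"] < 1
        # parameters echoed, intermediates and log written
        assert report["parameters"]["median_width"] == 3
        assert (tmp_path / "pore.log").exists()
        assert (tmp_path / "blobs.csv").exists()
        assert (tmp_path / "pore_report.json").exists()
        assert any(p.name.startswith("01_") for p in tmp_path.iterdir())

    def test_two_disjoint_balls_give_two_blobs(self):
        gray = generate_gray_phantom(
            PhantomSpec(
                "bimodal_gray",
                (48, 24, 24),
                voxel_size=2.0,
                seed=1,
                params={
                    "means": [50, 200],
                    "sigma": 0,
                    "geometry": {
                        "kind": "balls",
                        "params": {"centers": [(12, 12, 12), (36, 12, 12)], "radii": [7, 7]},
                    },
                },
            )
        )
        report = run_pore_protocol(gray.volume, ProtocolConfig(**_FAST))
        assert report["blobs"]["n_blobs"] == 2

    def test_rerun_is_byte_identical(self):
        gray = _pore_phantom(shape=(40, 40, 40))
        cfg = ProtocolConfig(**_FAST)
        a = json.dumps(run_pore_protocol(gray.volume, cfg), sort_keys=True)
        b = json.dumps(run_pore_protocol(gray.volume, cfg), sort_keys=True)
        assert a == b


class TestMultiphaseProtocol:
    def test_touching_grains_separated_and_counted(self):
        gray, n_grains = _grain_phantom()
        labels, table, report = run_multiphase_protocol(gray.volume, ProtocolConfig(k=4, h=4.0))
        assert report["n_objects"] == n_grains
        assert len(table) == n_grains
        # k = 4 on a 3-phase volume: two centroids land inside one phase
        cents = np.asarray(report["kmeans_centroids"])
        assert cents.size == 4
        assert np.min(np.diff(cents)) < 30  # redundant pair within a phase
        assert np.max(np.diff(cents)) > 80  # genuine phase separations remain

    def test_two_separated_grains_any_h(self):
        gray = generate_gray_phantom(
            PhantomSpec(
                "bimodal_gray",
                (48, 24, 24),
                voxel_size=1.0,
                seed=2,
                params={
                    "means": [40, 210],
                    "sigma": 0,
                    "geometry": {
                        "kind": "balls",
                        "params": {"centers": [(12, 12, 12), (36, 12, 12)], "radii": [7, 7]},
                    },
                },
            )
        )
        for h in (0.0, 2.0, 8.0):
            _, _, report = run_multiphase_protocol(gray.volume, ProtocolConfig(k=2, h=h))
            assert report["n_objects"] == 2

    def test_h_above_max_distance_one_label_per_component(self):
        gp = generate_binary_phantom(
            PhantomSpec("grain_pack", (72, 72, 72), seed=3, params={"r": 16.0, "pitch": 28.0, "jitter": 1.0})
        )
        mask = gp.volume
        dist = chamfer_distance(mask)
        relief = h_minima(DistanceVolume(-dist.data, 1.0), float(dist.data.max()) + 1)
        lab = watershed(relief, mask)
        assert lab.n_labels == label_components(mask).n_labels

    def test_k_below_two_rejected(self):
        gray = _pore_phantom(shape=(16, 16, 16))
        with pytest.raises(ValueError):
            run_multiphase_protocol(gray.volume, ProtocolConfig(k=1))

    def test_rerun_is_byte_identical(self):
        gray, _ = _grain_phantom()
        cfg = ProtocolConfig(k=4, h=4.0)
        _, _, a = run_multiphase_protocol(gray.volume, cfg)
        _, _, b = run_multiphase_protocol(gray.volume, cfg)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


class TestMorphometryProtocol:
    def test_slab_phantom_within_tolerance(self):
        res = generate_binary_phantom(
            PhantomSpec("slab_stack", (64, 64, 80), voxel_size=5.0, params={"thickness": 8, "period": 40})
        )
        result, report = run_morphometry_protocol(res.volume)
        assert result.TbTh == pytest.approx(res.truth["TbTh_mm"], rel=0.10)
        assert result.TbSp == pytest.approx(res.truth["TbSp_mm"], rel=0.10)
        assert set(report["indices"]) == {"BvTv", "BsBv_per_mm", "TbTh_mm", "TbN_per_mm", "TbSp_mm"}

    def test_fully_solid_phantom(self):
        result, _ = run_morphometry_protocol(BinaryVolume(np.ones((16, 16, 16), bool), 5.0))
        assert result.BvTv == 1.0

    def test_gray_input_is_segmented_first(self):
        res = generate_binary_phantom(
            PhantomSpec("slab_stack", (32, 32, 40), voxel_size=5.0, params={"thickness": 6, "period": 20})
        )
        gray = generate_gray_phantom(
            PhantomSpec(
                "multiphase_gray",
                (32, 32, 40),
                voxel_size=5.0,
                seed=8,
                params={"means": [40, 200], "sigma": 5, "label_data": res.volume.data.astype(np.int32)},
            )
        )
        from_gray, _ = run_morphometry_protocol(gray.volume)
        from_mask, _ = run_morphometry_protocol(res.volume)
        assert from_gray.BvTv == pytest.approx(from_mask.BvTv, rel=0.02)

    def test_rerun_is_byte_identical(self):
        res = generate_binary_phantom(
            PhantomSpec("slab_stack", (64, 64, 80), voxel_size=5.0, params={"thickness": 8, "period": 40})
        )
        _, a = run_morphometry_protocol(res.volume)
        _, b = run_morphometry_protocol(res.volume)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


class TestConfig:
    def test_parse_flat_key_value_file(self, tmp_path):
        cfg_file = tmp_path / "run.cfg"
        cfg_file.write_text(
            "# pore run\n"
            "median_width = 5\n"
            "h = 2.5\n"
            "closing = true\n"
            "voi_origin = 4,4,4\n"
            "voi_shape = 16,16,16\n"
            "phase_classes = 2,3\n"
        )
        cfg = parse_config_file(cfg_file)
        assert cfg.median_width == 5
        assert cfg.h == 2.5
        assert cfg.closing is True
        assert cfg.voi_origin == (4, 4, 4)
        assert cfg.phase_classes == (2, 3)
        assert cfg.k == 4  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        bad = tmp_path / "bad.cfg"
        bad.write_text("median = 3\n")
        with pytest.raises(ValueError):
            parse_config_file(bad)

    def test_voi_crop_applied(self):
        gray = _pore_phantom(shape=(32, 32, 32))
        cfg = ProtocolConfig(voi_origin=(4, 4, 4), voi_shape=(16, 16, 16), **_FAST)
        report = run_pore_protocol(gray.volume, cfg)
        assert report["input"]["shape"] == [16, 16, 16]
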
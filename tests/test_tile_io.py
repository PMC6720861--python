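"""File-name patterns, tile assembly, prefetch contract, hyperstack I/O."""

import threading

import numpy as np
import pytest
import tifffile

from cytotile import config as cfg
from cytotile import tile_io
from conftest import make_config_doc


class TestFileNamePattern:
    PATTERN = tile_io.FileNamePattern(
        "r{region}_t{tile:03d}_c{cycle}_z{z:02d}_ch{channel}.tif", index_base=1
    )

    def test_parse_known_name(self):
        idx = self.PATTERN.parse("r1_t005_c2_z07_ch3.tif")
        assert idx == {"region": 0, "tile": 4, "cycle": 1, "z": 6, "channel": 2}

    def test_non_matching_name_raises(self):
        with pytest.raises(tile_io.ParseError):
            self.PATTERN.parse("garbage.tif")

    def test_format_parse_round_trip_random_tuples(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            idx = {
                "region": int(rng.integers(0, 9)),
                "tile": int(rng.integers(0, 999)),
                "cycle": int(rng.integers(0, 8)),
                "z": int(rng.integers(0, 99)),
                "channel": int(rng.integers(0, 8)),
            }
            name = self.PATTERN.format(**idx)
            assert self.PATTERN.parse(name) == idx
            assert self.PATTERN.format(**self.PATTERN.parse(name)) == name

    def test_duplicate_placeholder_rejected(self):
        with pytest.raises(tile_io.ParseError):
            tile_io.FileNamePattern("a{cycle}b{cycle}.tif")


def _write_experiment(tmp_path, config, value_fn):
    """Write one uint16 plane per index with values from value_fn(c, z, ch)."""
    pattern = tile_io.pattern_from_config(config)
    for region in range(config.n_regions):
        for tile in range(config.n_tiles):
            for c in range(config.n_cycles):
                for z in range(config.n_z):
                    for ch in range(config.channels_per_cycle):
                        plane = np.full(
                            (config.tile_height, config.tile_width),
                            value_fn(region, tile, c, z, ch), dtype=np.uint16,
                        )
                        name = pattern.format(region=region, tile=tile,
                                              cycle=c, z=z, channel=ch)
                        tifffile.imwrite(tmp_path / name, plane)


class TestAssembleTile:
    def test_identity_assembly_single_plane(self, tmp_path, minimal_config):
        rng = np.random.default_rng(0)
        plane = rng.integers(0, 65535, size=(128, 128), dtype=np.uint16)
        pattern = tile_io.pattern_from_config(minimal_config)
        tifffile.imwrite(
            tmp_path / pattern.format(region=0, tile=0, cycle=0, z=0, channel=0),
            plane,
        )
        vol = tile_io.assemble_tile(tmp_path, minimal_config, 0, 0)
        assert vol.shape == (1, 1, 1, 128, 128)
        assert np.array_equal(vol.data[0, 0, 0], plane)

    def test_constant_planes_land_in_right_slots(self, tmp_path):
        config = cfg.load_config(make_config_doc(
            cycles=2, z_planes=3, channels_per_cycle=4, tile=(96, 96),
            channel_roles=["reference"] + ["expression"] * 3,
        ))
        _write_experiment(tmp_path, config,
                          lambda r, t, c, z, ch: c * 100 + z * 10 + ch)
        vol = tile_io.assemble_tile(tmp_path, config, 0, 0)
        for c in range(2):
            for z in range(3):
                for ch in range(4):
                    assert np.all(vol.data[c, z, ch] == c * 100 + z * 10 + ch)

    def test_z_depth_matches_configured_stack(self, tmp_path):
        config = cfg.load_config(make_config_doc(z_planes=25, tile=(96, 96)))
        _write_experiment(tmp_path, config, lambda *a: 1)
        vol = tile_io.assemble_tile(tmp_path, config, 0, 0)
        assert vol.shape[1] == 25

    def test_missing_file_lists_indices(self, tmp_path, small_multicycle_config):
        config = small_multicycle_config
        _write_experiment(tmp_path, config, lambda *a: 1)
        pattern = tile_io.pattern_from_config(config)
        (tmp_path / pattern.format(region=0, tile=0, cycle=1, z=2, channel=0)).unlink()
        with pytest.raises(tile_io.AssemblyError, match=r"\(1, 2, 0\)"):
            tile_io.assemble_tile(tmp_path, config, 0, 0)

    def test_allow_missing_fills_zeros(self, tmp_path, small_multicycle_config):
        config = small_multicycle_config
        _write_experiment(tmp_path, config, lambda *a: 7)
        pattern = tile_io.pattern_from_config(config)
        (tmp_path / pattern.format(region=0, tile=0, cycle=1, z=2, channel=0)).unlink()
        vol = tile_io.assemble_tile(tmp_path, config, 0, 0, allow_missing=True)
        assert np.all(vol.data[1, 2, 0] == 0)
        assert np.all(vol.data[0, 0, 0] == 7)

    def test_wrong_size_rejected(self, tmp_path, minimal_config):
        pattern = tile_io.pattern_from_config(minimal_config)
        tifffile.imwrite(
            tmp_path / pattern.format(region=0, tile=0, cycle=0, z=0, channel=0),
            np.zeros((64, 64), dtype=np.uint16),
        )
        with pytest.raises(tile_io.FormatError):
            tile_io.assemble_tile(tmp_path, minimal_config, 0, 0)

    def test_float_input_rejected(self, tmp_path, minimal_config):
        pattern = tile_io.pattern_from_config(minimal_config)
        tifffile.imwrite(
            tmp_path / pattern.format(region=0, tile=0, cycle=0, z=0, channel=0),
            np.zeros((128, 128), dtype=np.float32),
        )
        with pytest.raises(tile_io.FormatError):
            tile_io.assemble_tile(tmp_path, minimal_config, 0, 0)


class TestPrefetchTiles:
    @pytest.fixture
    def four_tile_setup(self, tmp_path):
        config = cfg.load_config(make_config_doc(grid=(2, 2), tile=(96, 96)))
        _write_experiment(tmp_path, config,
                          lambda r, t, c, z, ch: t * 10 + 1)
        return tmp_path, config

    def test_matches_sequential_assembly(self, four_tile_setup):
        data_dir, config = four_tile_setup
        sequential = [tile_io.assemble_tile(data_dir, config, 0, t)
                      for t in range(4)]
        prefetched = list(tile_io.prefetch_tiles(data_dir, config, 1))
        assert len(prefetched) == 4
        for a, b in zip(sequential, prefetched):
            assert np.array_equal(a.data, b.data)
            assert (a.region, a.tile) == (b.region, b.tile)

    def test_capacity_zero_rejected(self, four_tile_setup):
        data_dir, config = four_tile_setup
        with pytest.raises(ValueError):
            list(tile_io.prefetch_tiles(data_dir, config, 0))

    def test_row_major_order(self, four_tile_setup):
        data_dir, config = four_tile_setup
        order = [(v.region, v.tile)
                 for v in tile_io.prefetch_tiles(data_dir, config, 2)]
        assert order == [(0, 0), (0, 1), (0, 2), (0, 3)]

    @pytest.mark.parametrize("capacity", [1, 2, 3])
    def test_capacity_independent_content(self, four_tile_setup, capacity):
        data_dir, config = four_tile_setup
        ref = [v.data for v in tile_io.prefetch_tiles(data_dir, config, 1)]
        got = [v.data for v in tile_io.prefetch_tiles(data_dir, config, capacity)]
        assert all(np.array_equal(a, b) for a, b in zip(ref, got))

    def test_bounded_lookahead_contract(self, four_tile_setup):
        """At most `capacity` assembled-but-unconsumed volumes ever exist."""
        data_dir, config = four_tile_setup
        capacity = 2
        lock = threading.Lock()
        in_flight = 0
        consumed = 0
        max_outstanding = 0

        def counting_loader(d, c, r, t):
            nonlocal in_flight, max_outstanding
            with lock:
                in_flight += 1
                max_outstanding = max(max_outstanding, in_flight - consumed)
            return tile_io.assemble_tile(d, c, r, t)

        gen = tile_io.prefetch_tiles(data_dir, config, capacity,
                                     loader=counting_loader)
        import time
        for vol in gen:
            time.sleep(0.02)  # let the producer run as far ahead as it can
            with lock:
                consumed += 1
        assert max_outstanding <= capacity

    def test_assembly_error_surfaces_at_consumption(self, tmp_path):
        config = cfg.load_config(make_config_doc(grid=(1, 2), tile=(96, 96)))
        _write_experiment(tmp_path, config, lambda *a: 1)
        pattern = tile_io.pattern_from_config(config)
        (tmp_path / pattern.format(region=0, tile=1, cycle=0, z=0, channel=0)).unlink()
        gen = tile_io.prefetch_tiles(tmp_path, config, 1)
        first = next(gen)
        assert first.tile == 0
        with pytest.raises(tile_io.AssemblyError):
            list(gen)


class TestHyperstack:
    @pytest.mark.parametrize("dtype", [np.uint8, np.uint16])
    def test_bit_exact_round_trip(self, tmp_path, dtype):
        rng = np.random.default_rng(5)
        info = np.iinfo(dtype)
        vol = rng.integers(0, info.max, size=(2, 3, 2, 64, 64)).astype(dtype)
        path = tmp_path / "stack.tif"
        tile_io.write_hyperstack(vol, path, channel_names=["a", "b"])
        back, names = tile_io.read_hyperstack(path)
        assert np.array_equal(back, vol)
        assert back.dtype == dtype
        assert names == ["a", "b"]

    def test_single_plane_single_page(self, tmp_path):
        path = tmp_path / "plane.tif"
        tile_io.write_hyperstack(np.zeros((32, 32), dtype=np.uint16), path)
        with tifffile.TiffFile(path) as tif:
            assert len(tif.pages) == 1

    def test_channel_names_metadata_round_trip(self, tmp_path):
        vol = np.zeros((1, 1, 3, 16, 16), dtype=np.uint16)
        path = tmp_path / "named.tif"
        tile_io.write_hyperstack(vol, path, channel_names=["DAPI", "CD3", "CD8"])
        _, names = tile_io.read_hyperstack(path)
        assert names == ["DAPI", "CD3", "CD8"]

    def test_wrong_name_count_rejected(self, tmp_path):
        vol = np.zeros((1, 1, 3, 16, 16), dtype=np.uint16)
        with pytest.raises(tile_io.FormatError):
            tile_io.write_hyperstack(vol, tmp_path / "x.tif", channel_names=["a"])
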
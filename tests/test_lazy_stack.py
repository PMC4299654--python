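"""Lazy disk-backed tensor semantics: reads equal eager data, structural
operations are O(1) metadata changes, writes round-trip."""

import numpy as np
import pytest
import tifffile

from calstack.lazy_stack import (
    BoundsError,
    DimensionMismatchError,
    ReadOnlyStackError,
    SizeMismatchError,
    create_temp_stack,
    open_binary_stack,
    open_tiff_stack,
    storage_bytes,
)
from calstack import StackHeader

from conftest import write_raw_blocks


def full(stack):
    return stack.read_region([slice(None)] * 4)


class TestOpenBinary:
    def test_multi_file_shape_and_laziness(self, raw_stack_pair):
        stack, eager = raw_stack_pair
        assert stack.shape == eager.shape
        assert stack.io_read_count == 0

    def test_minimal_one_byte_stack(self, tmp_path):
        p = tmp_path / "one.bin"
        p.write_bytes(b"\x07")
        h = StackHeader(n_rows=1, n_cols=1, n_channels=1, dtype="u8",
                        frames_per_file=[1])
        st = open_binary_stack([str(p)], h)
        assert st.shape == (1, 1, 1, 1)
        assert full(st)[0, 0, 0, 0] == 7

    def test_truncated_file_names_offender(self, tmp_path, raw_stack_pair):
        stack, eager = raw_stack_pair
        bad = tmp_path / "short.bin"
        good_bytes = 12 * 14 * 2 * 5
        bad.write_bytes(bytes(good_bytes - 1))
        h = StackHeader(n_rows=12, n_cols=14, n_channels=2, dtype="u8",
                        frames_per_file=[5])
        with pytest.raises(SizeMismatchError, match="short.bin"):
            open_binary_stack([str(bad)], h)


class TestReadRegion:
    def test_reads_match_eager_oracle(self, raw_stack_pair):
        """1000 seeded random region reads agree bit-exactly with the
        eagerly loaded copy."""
        stack, eager = raw_stack_pair
        rng = np.random.default_rng(0)
        for _ in range(1000):
            sel = []
            for ax, size in enumerate(eager.shape):
                kind = rng.integers(3)
                if kind == 0:
                    sel.append(int(rng.integers(size)))
                elif kind == 1:
                    a, b = sorted(rng.integers(0, size + 1, size=2))
                    sel.append(slice(a, max(b, a + 1)))
                else:
                    sel.append(rng.integers(0, size,
                                            size=rng.integers(1, 5)))
            got = stack.read_region(sel)
            ix = np.ix_(*[np.atleast_1d(np.arange(s)[v] if isinstance(v, slice)
                                        else v) for s, v in
                          zip(eager.shape, sel)])
            assert np.array_equal(got, eager[ix])

    def test_single_pixel_trace(self, raw_stack_pair):
        stack, eager = raw_stack_pair
        got = stack.read_region([3, 5, slice(None), 1])
        assert got.shape == (1, 1, 20, 1)
        assert np.array_equal(got[0, 0, :, 0], eager[3, 5, :, 1])

    def test_out_of_range_names_axis(self, raw_stack_pair):
        stack, _ = raw_stack_pair
        with pytest.raises(BoundsError, match="axis 2"):
            stack.read_region([0, 0, 99, 0])

    def test_repeated_reads_identical(self, raw_stack_pair):
        stack, _ = raw_stack_pair
        sel = [slice(2, 7), slice(None), slice(3, 15), 0]
        assert np.array_equal(stack.read_region(sel), stack.read_region(sel))

    def test_only_overlapping_blocks_touched(self, raw_stack_pair):
        stack, _ = raw_stack_pair
        before = stack.io_read_count
        stack.read_region([slice(None), slice(None), slice(0, 3), slice(None)])
        assert stack.io_read_count == before + 1  # frames 0-2 live in block 0


class TestStructuralOps:
    def test_permute_is_lazy_and_matches_eager(self, raw_stack_pair):
        stack, eager = raw_stack_pair
        before = stack.io_read_count
        perm = stack.permute_axes((2, 0, 1, 3))
        assert stack.io_read_count == before
        assert perm.shape == tuple(eager.shape[a] for a in (2, 0, 1, 3))
        assert np.array_equal(full(perm), eager.transpose(2, 0, 1, 3))

    def test_permute_inverse_round_trip(self, raw_stack_pair):
        stack, eager = raw_stack_pair
        perm = stack.permute_axes((3, 1, 2, 0)).permute_axes((3, 1, 2, 0))
        assert np.array_equal(full(perm), eager)

    def test_invalid_permutation(self, raw_stack_pair):
        stack, _ = raw_stack_pair
        with pytest.raises(ValueError):
            stack.permute_axes((0, 0, 1, 2))

    def test_scale_offset_lazy_compose_identity(self, raw_stack_pair):
        stack, eager = raw_stack_pair
        before = stack.io_read_count
        tr = stack.scale_offset(2.0, 3.0).scale_offset(0.5, -1.5)
        assert stack.io_read_count == before
        assert np.allclose(full(tr), eager, atol=1e-12)

    def test_negation(self, raw_stack_pair):
        stack, eager = raw_stack_pair
        assert np.array_equal(full(stack.scale_offset(-1.0, 0.0)),
                              -eager.astype(float))

    def test_transform_algebra_random_chain(self, raw_stack_pair):
        """Composed affine transforms equal the single equivalent affine
        applied to eager data."""
        stack, eager = raw_stack_pair
        rng = np.random.default_rng(3)
        a_tot, b_tot = 1.0, 0.0
        tr = stack
        for _ in range(5):
            a, b = rng.uniform(-2, 2, size=2)
            tr = tr.scale_offset(a, b)
            a_tot, b_tot = a * a_tot, a * b_tot + b
        assert np.allclose(full(tr), a_tot * eager.astype(float) + b_tot,
                           atol=1e-12)


class TestWrites:
    def test_write_read_round_trip(self, tmp_path):
        st = create_temp_stack((6, 5, 8, 2), "u8", dir=str(tmp_path))
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 256, size=(6, 5, 8, 2))
        st.write_region([slice(None)] * 4, vals)
        assert np.array_equal(full(st), vals)

    def test_constant_frame(self, tmp_path):
        st = create_temp_stack((4, 4, 2, 1), "u8", dir=str(tmp_path))
        st.write_region([slice(None), slice(None), 0, 0], 7)
        assert (st.read_region([slice(None), slice(None), 0, 0]) == 7).all()

    def test_overflow_clips_with_warning(self, tmp_path):
        st = create_temp_stack((2, 2, 1, 1), "u8", dir=str(tmp_path))
        with pytest.warns(RuntimeWarning, match="clipped"):
            st.write_region([slice(None)] * 4, np.full((2, 2, 1, 1), 300))
        assert (full(st) == 255).all()

    def test_write_ignores_value_transform(self, tmp_path):
        st = create_temp_stack((2, 2, 1, 1), "u8", dir=str(tmp_path))
        neg = st.scale_offset(-1.0, 0.0)
        neg.write_region([slice(None)] * 4, np.full((2, 2, 1, 1), 5))
        assert (full(st) == 5).all()  # stored raw
        assert (full(neg) == -5).all()

    def test_write_through_permuted_view(self, tmp_path):
        st = create_temp_stack((3, 4, 5, 2), "u8", dir=str(tmp_path))
        vals = np.arange(3 * 4 * 5 * 2).reshape(5, 3, 4, 2) % 256
        st.permute_axes((2, 0, 1, 3)).write_region([slice(None)] * 4, vals)
        assert np.array_equal(full(st), vals.transpose(1, 2, 0, 3))


class TestTiff:
    def test_two_files_concatenate(self, tmp_path):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2**16, size=(4, 10, 11), dtype=np.uint16)
        b = rng.integers(0, 2**16, size=(6, 10, 11), dtype=np.uint16)
        tifffile.imwrite(tmp_path / "a.tif", a, photometric="minisblack")
        tifffile.imwrite(tmp_path / "b.tif", b, photometric="minisblack")
        st = open_tiff_stack([str(tmp_path / "a.tif"), str(tmp_path / "b.tif")])
        assert st.shape == (10, 11, 10, 1)
        assert not st.writable
        eager = np.concatenate([a, b], axis=0).transpose(1, 2, 0)[..., None]
        assert np.array_equal(full(st), eager)

    def test_single_frame(self, tmp_path):
        tifffile.imwrite(tmp_path / "s.tif", np.zeros((7, 9), dtype=np.uint8))
        st = open_tiff_stack([str(tmp_path / "s.tif")])
        assert st.shape == (7, 9, 1, 1)

    def test_write_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "s.tif", np.zeros((8, 8), dtype=np.uint8))
        st = open_tiff_stack([str(tmp_path / "s.tif")])
        with pytest.raises(ReadOnlyStackError):
            st.write_region([0, 0, 0, 0], 1)

    def test_mixed_dims_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "a.tif", np.zeros((8, 8), dtype=np.uint8))
        tifffile.imwrite(tmp_path / "b.tif", np.zeros((9, 8), dtype=np.uint8))
        with pytest.raises(DimensionMismatchError):
            open_tiff_stack([str(tmp_path / "a.tif"), str(tmp_path / "b.tif")])


class TestSliceApply:
    def test_identity_map(self, raw_stack_pair, tmp_path):
        stack, eager = raw_stack_pair
        out = stack.slice_apply(lambda s: s, axis=2, out_dir=str(tmp_path))
        assert np.array_equal(full(out), eager)

    def test_reduction_matches_eager(self, raw_stack_pair):
        stack, eager = raw_stack_pair
        means = stack.slice_apply(lambda s: float(s.mean()), axis=2,
                                  reduce=True)
        assert np.allclose(means, eager.mean(axis=(0, 1, 3)))

    def test_memory_bounded_by_one_slice(self, raw_stack_pair, tmp_path):
        """No single disk read materializes more than one slice."""
        stack, eager = raw_stack_pair
        stack.slice_apply(lambda s: s * 1.0, axis=2, out_dir=str(tmp_path))
        slice_elements = eager.shape[0] * eager.shape[1] * eager.shape[3]
        assert stack.max_read_elements <= slice_elements

    def test_wrong_shape_names_slice(self, raw_stack_pair, tmp_path):
        stack, _ = raw_stack_pair
        with pytest.raises(ValueError, match="slice 0"):
            stack.slice_apply(lambda s: s[:2], axis=2, out_dir=str(tmp_path))


class TestStorageBytes:
    @pytest.mark.parametrize(
        "shape, bits, expect",
        [
            ((128, 128, 7378, 2), 8, 241_762_304),
            ((1, 1, 1, 1), 8, 1),
            ((512, 512, 1800, 1), 16, 943_718_400),
        ],
    )
    def test_accounting(self, shape, bits, expect):
        assert storage_bytes(shape, bits) == expect

    def test_rejects_bad_bits(self):
        with pytest.raises(ValueError):
            storage_bytes((1, 1, 1, 1), 12)
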
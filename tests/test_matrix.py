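"""Encrypted-matrix algebra against plaintext oracles: packing arithmetic,
padding, expansions, expansion-based products, row-row inner products with
rotation accounting, and Gaussian masking."""

import numpy as np
import pytest

from fcg import matrix as fm
from fcg.errors import ShapeError
from fcg.matrix import EncryptedMatrix, PlainMatrix

from conftest import decrypt_oracle

TOL = 1e-3


# ---------------------------------------------------------------------------
# packing


def test_block_capacity_arithmetic():
    # 57,344 packed values fill exactly 7 ciphertexts of 8192 slots, and
    # 557,056 variants fill exactly 68 blocks
    assert fm.n_blocks(1, 57_344, 8192) == 7
    assert fm.n_blocks(1, 557_056, 8192) == 68
    assert fm.n_blocks(64, 128, 8192) == 1
    assert fm.n_blocks(3, 3, 8192) == 1


def test_small_matrix_occupies_one_block_row_major(backend, bundle):
    m = PlainMatrix(np.arange(9, dtype=float).reshape(3, 3))
    em = fm.encrypt_matrix(m, backend)
    assert len(em.blocks) == 1
    flat = backend.decrypt_with_master(em.blocks[0], bundle.master_key)
    assert np.allclose(flat[:9], np.arange(9), atol=TOL)
    assert np.allclose(flat[9:], 0, atol=TOL)


def test_matrix_roundtrip(backend, bundle):
    rng = np.random.default_rng(0)
    m = PlainMatrix(rng.normal(size=(5, 7)))
    out = decrypt_oracle(fm.encrypt_matrix(m, backend), backend, bundle)
    assert np.abs(out - m.values).max() < TOL


def test_multiblock_packing_matches_flattening(backend, bundle):
    slot = backend.params.slot_size
    rng = np.random.default_rng(1)
    m = PlainMatrix(rng.normal(size=(3, slot)))  # 3 blocks
    em = fm.encrypt_matrix(m, backend)
    assert len(em.blocks) == 3
    out = decrypt_oracle(em, backend, bundle)
    assert np.abs(out - m.values).max() < TOL


# ---------------------------------------------------------------------------
# padding and scaling


def test_pad_matrix_and_pow2():
    m = PlainMatrix(np.ones((3, 3)))
    p = fm.pad_matrix(m, 4, 4)
    assert p.shape == (4, 4)
    assert np.all(p.values[3, :] == 0) and np.all(p.values[:, 3] == 0)
    assert np.array_equal(fm.pad_matrix(m, 3, 3).values, m.values)
    assert fm.next_pow2(9) == 16
    assert fm.next_pow2(8) == 8
    with pytest.raises(ShapeError):
        fm.pad_matrix(m, 2, 3)


def test_scale_matrix_tracks_factor():
    m = PlainMatrix(np.array([[1.0, 2.0]]))
    assert np.array_equal(fm.scale_matrix(m, 1.0).values, m.values)
    back = fm.scale_matrix(fm.scale_matrix(m, 2.0), 0.5)
    assert np.abs(back.values - m.values).max() < 1e-12
    assert back.scale_factor == 1.0
    with pytest.raises(ValueError):
        fm.scale_matrix(m, 0.0)


# ---------------------------------------------------------------------------
# expansions


def test_plain_expansions():
    col = PlainMatrix(np.array([[1.0], [2.0]]))
    ce = fm.expand_columns(col, 3)
    assert np.array_equal(ce.matrices[0].values, [[1, 1, 1], [2, 2, 2]])
    row = PlainMatrix(np.array([[1.0, 2.0, 3.0]]))
    re = fm.expand_rows(row, 2)
    assert np.array_equal(re.matrices[0].values, [[1, 2, 3], [1, 2, 3]])


def test_expansion_distributive_over_addition():
    rng = np.random.default_rng(2)
    m1, m2 = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
    re_sum = fm.expand_rows(PlainMatrix(m1 + m2), 5)
    re1 = fm.expand_rows(PlainMatrix(m1), 5)
    re2 = fm.expand_rows(PlainMatrix(m2), 5)
    for s, a, b in zip(re_sum.matrices, re1.matrices, re2.matrices):
        assert np.abs(s.values - (a.values + b.values)).max() < 1e-6


def test_expand_rows_encrypted(backend, bundle):
    a = PlainMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
    em = fm.encrypt_matrix(a, backend)
    stats = {}
    es = fm.expand_rows_encrypted(em, 2, backend, stats=stats)
    assert len(es) == 2
    out0 = decrypt_oracle(es.matrices[0], backend, bundle)
    out1 = decrypt_oracle(es.matrices[1], backend, bundle)
    assert np.abs(out0 - [[1, 2], [1, 2]]).max() < TOL
    assert np.abs(out1 - [[3, 4], [3, 4]]).max() < TOL
    # rows * log2(width) accumulation rotations
    assert stats["accumulation_rotations"] == 2 * 1


def test_expand_rows_encrypted_scalar_broadcast(backend, bundle):
    em = fm.encrypt_matrix(PlainMatrix(np.array([[7.0]])), backend)
    es = fm.expand_rows_encrypted(em, 4, backend)
    out = decrypt_oracle(es.matrices[0], backend, bundle)
    assert np.abs(out - 7.0).max() < TOL
    with pytest.raises(ShapeError):
        fm.expand_rows_encrypted(em, 3, backend)


# ---------------------------------------------------------------------------
# products


def test_matmul_identity(backend, bundle):
    a = PlainMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
    em = fm.encrypt_matrix(a, backend)
    out = decrypt_oracle(
        fm.secure_matmul(PlainMatrix(np.eye(2)), em, backend), backend, bundle
    )
    assert np.abs(out - a.values).max() < TOL


def test_matmul_known_product(backend, bundle):
    a = PlainMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
    b = PlainMatrix(np.array([[5.0, 6.0], [7.0, 8.0]]))
    ce = fm.encrypt_expansion(fm.expand_columns(a, 2), backend)
    re = fm.expand_rows(b, 2)
    out = decrypt_oracle(fm.matmul(ce, re, backend), backend, bundle)
    assert np.abs(out - [[19, 22], [43, 50]]).max() < TOL


def test_matmul_random_against_oracle(backend, bundle):
    rng = np.random.default_rng(3)
    for _ in range(2):
        a, b = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        out = decrypt_oracle(
            fm.secure_matmul(PlainMatrix(a), PlainMatrix(b), backend),
            backend,
            bundle,
        )
        assert np.abs(out - a @ b).max() < 1e-2


def test_row_row_inner_example(backend, bundle):
    m = PlainMatrix(np.array([[1.0, 1, 1, 1], [2, 2, 2, 2]]))
    em = fm.encrypt_matrix(m, backend)
    stats = {}
    out = decrypt_oracle(
        fm.row_row_inner(em, m, backend, stats=stats), backend, bundle
    )
    assert np.abs(out.ravel() - [4.0, 16.0]).max() < TOL
    # exactly log2(4) = 2 accumulation rotations for the single block
    assert stats["accumulation_rotations"] == 2


def test_row_row_inner_zero_and_shape_guard(backend, bundle):
    m = PlainMatrix(np.ones((2, 4)))
    em = fm.encrypt_matrix(m, backend)
    zero = PlainMatrix(np.zeros((2, 4)))
    out = decrypt_oracle(fm.row_row_inner(em, zero, backend), backend, bundle)
    assert np.abs(out).max() < TOL
    bad = PlainMatrix(np.ones((2, 3)))
    with pytest.raises(ShapeError):
        fm.row_row_inner(fm.encrypt_matrix(bad, backend), bad, backend)


def test_row_row_inner_random_oracle(backend, bundle):
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=(8, 16)), rng.normal(size=(8, 16))
    ea = fm.encrypt_matrix(PlainMatrix(a), backend)
    out = decrypt_oracle(
        fm.row_row_inner(ea, PlainMatrix(b), backend), backend, bundle
    )
    assert np.abs(out.ravel() - np.einsum("ij,ij->i", a, b)).max() < 1e-2


def test_row_row_inner_multi_block(backend, bundle):
    slot = backend.params.slot_size
    rows = 2 * slot // 8  # spans two ciphertext blocks
    rng = np.random.default_rng(5)
    a = rng.normal(size=(rows, 8))
    ea = fm.encrypt_matrix(PlainMatrix(a), backend)
    stats = {}
    out = decrypt_oracle(
        fm.row_row_inner(ea, PlainMatrix(a), backend, stats=stats),
        backend,
        bundle,
    )
    assert np.abs(out.ravel() - (a * a).sum(axis=1)).max() < 1e-2
    assert stats["accumulation_rotations"] == 2 * 3  # log2(8) per block


# ---------------------------------------------------------------------------
# masks


def test_additive_mask_roundtrip(backend, bundle):
    rng = np.random.default_rng(6)
    m = PlainMatrix(rng.normal(size=(3, 3)))
    em = fm.encrypt_matrix(m, backend)
    mask = fm.make_mask((3, 3), sd=5.0, seed=1)
    masked = fm.apply_mask_add(em, mask, backend)
    plain = PlainMatrix(decrypt_oracle(masked, backend, bundle))
    out = fm.remove_mask_add(plain, mask)
    assert np.abs(out.values - m.values).max() < TOL


def test_mask_determinism_and_invertibility():
    m1 = fm.make_mask((4, 4), sd=1.0, seed=42)
    m2 = fm.make_mask((4, 4), sd=1.0, seed=42)
    assert np.array_equal(m1.values, m2.values)
    inv = fm.make_mask((4, 4), sd=1.0, seed=42, invertible=True)
    assert np.linalg.cond(inv.values) <= 1e8


def test_masked_values_uncorrelated_with_plaintext():
    rng = np.random.default_rng(7)
    data = rng.normal(0, 1.0, size=1000)
    mask = fm.make_mask((1000,), sd=100.0, seed=3)
    masked = data + mask.values
    r = np.corrcoef(data, masked)[0, 1]
    assert abs(r) < 0.1


def test_scaling_improves_near_zero_accuracy(backend, bundle):
    """Pre-scaling small-magnitude entries reduces relative error through an
    encrypted multiply (paired comparison over random draws)."""
    rng = np.random.default_rng(8)
    wins = 0
    trials = 5
    for _ in range(trials):
        small = rng.normal(0, 1e-4, size=(2, 2))
        other = rng.normal(0, 10.0, size=(2, 2))
        truth = small * other

        em_plain = fm.encrypt_matrix(PlainMatrix(small), backend)
        raw = decrypt_oracle(
            fm.matrix_mul_elementwise(em_plain, PlainMatrix(other), backend),
            backend,
            bundle,
        )
        err_raw = np.abs(raw[:2, :2] - truth).max()

        scaled = fm.scale_matrix(PlainMatrix(small), 1e3)
        em_scaled = fm.encrypt_matrix(scaled, backend)
        cooked = decrypt_oracle(
            fm.matrix_mul_elementwise(em_scaled, PlainMatrix(other), backend),
            backend,
            bundle,
        ) / 1e3
        err_scaled = np.abs(cooked[:2, :2] - truth).max()
        wins += err_scaled <= err_raw
    assert wins >= trials - 1


# ---------------------------------------------------------------------------
# io


def test_plain_matrix_io_roundtrips(tmp_path):
    rng = np.random.default_rng(9)
    m = PlainMatrix(rng.normal(size=(4, 6)))
    m.to_tsv(tmp_path / "m.tsv")
    assert np.abs(PlainMatrix.from_tsv(tmp_path / "m.tsv").values - m.values).max() < 1e-8
    m.to_pmat(tmp_path / "m.pmat")
    assert np.array_equal(PlainMatrix.from_pmat(tmp_path / "m.pmat").values, m.values)


def test_encrypted_matrix_io_roundtrip(backend, bundle, tmp_path):
    m = PlainMatrix(np.array([[1.0, -2.0], [3.5, 0.25]]))
    em = fm.encrypt_matrix(m, backend)
    em.save(tmp_path / "m.encmat")
    em2 = EncryptedMatrix.load(tmp_path / "m.encmat")
    assert (em2.rows, em2.cols) == (2, 2)
    assert np.abs(decrypt_oracle(em2, backend, bundle) - m.values).max() < TOL
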
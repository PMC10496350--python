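"""Packed encrypted-matrix algebra.

A matrix is flattened row-major and packed into ``ceil(a*b/slot_size)``
ciphertext blocks.  Matrix products are expressed through column/row
expansions (``M1·M2 = sum_i ce_i(M1) ⊙ re_i(M2)``), and per-row inner
products use the shift-and-add rotation scheme: one elementwise product
followed by ``log2(b)`` accumulation rotations per block, after which every
``b``-th slot carries one row's inner product and is masked and copied into
the output vector.

Rotation-based operations require the column count to be a power of two
dividing the slot size so that rows never straddle ciphertext blocks;
callers pad with :func:`pad_to_pow2`.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .backend import (
    Ciphertext,
    HEBackend,
    ciphertext_from_bytes,
    ciphertext_to_bytes,
)
from .errors import ShapeError
from .keys import MasterSecretKey, SecretKeyShare

_PMAT_MAGIC = b"FCGM"
_ENCMAT_MAGIC = b"FCGX"


@dataclass
class PlainMatrix:
    """Dense real matrix with optional scale-factor metadata."""

    values: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.size == 0:
            raise ShapeError("matrix must be 2-D and non-empty")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("matrix entries must be finite")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self):
        return self.values.shape

    # -- io -----------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: Path | str) -> "PlainMatrix":
        return cls(np.loadtxt(path, delimiter="\t", ndmin=2))

    def to_tsv(self, path: Path | str) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.10g")

    @classmethod
    def from_pmat(cls, path: Path | str) -> "PlainMatrix":
        data = Path(path).read_bytes()
        if data[:4] != _PMAT_MAGIC or data[4] != 1:
            raise ValueError("not a pmat file")
        a, b = struct.unpack("<II", data[5:13])
        vals = np.frombuffer(data[13:], dtype="<f8", count=a * b)
        return cls(vals.reshape(a, b).copy())

    def to_pmat(self, path: Path | str) -> None:
        head = _PMAT_MAGIC + bytes([1]) + struct.pack(
            "<II", self.rows, self.cols
        )
        Path(path).write_bytes(
            head + self.values.astype("<f8").tobytes()
        )


@dataclass
class EncryptedMatrix:
    rows: int
    cols: int
    blocks: List[Ciphertext]

    @property
    def level(self) -> int:
        return min(b.level for b in self.blocks)

    @property
    def scale(self) -> float:
        return self.blocks[0].scale

    def to_bytes(self) -> bytes:
        parts = [ciphertext_to_bytes(b) for b in self.blocks]
        head = _ENCMAT_MAGIC + bytes([1]) + struct.pack(
            "<III", self.rows, self.cols, len(parts)
        )
        body = b"".join(struct.pack("<I", len(p)) + p for p in parts)
        return head + zlib.compress(body)

    @classmethod
    def from_bytes(cls, data: bytes) -> "EncryptedMatrix":
        if data[:4] != _ENCMAT_MAGIC or data[4] != 1:
            raise ValueError("not an encrypted-matrix container")
        a, b, nb = struct.unpack("<III", data[5:17])
        body = zlib.decompress(data[17:])
        blocks, off = [], 0
        for _ in range(nb):
            (ln,) = struct.unpack("<I", body[off : off + 4])
            blocks.append(ciphertext_from_bytes(body[off + 4 : off + 4 + ln]))
            off += 4 + ln
        return cls(rows=a, cols=b, blocks=blocks)

    def save(self, path: Path | str) -> None:
        Path(path).write_bytes(self.to_bytes())

    @classmethod
    def load(cls, path: Path | str) -> "EncryptedMatrix":
        return cls.from_bytes(Path(path).read_bytes())


@dataclass
class ExpansionSet:
    """Ordered column (``ce``) or row (``re``) expansions of a matrix."""

    kind: str  # "column" | "row"
    matrices: List[Union[PlainMatrix, EncryptedMatrix]]

    def __len__(self) -> int:
        return len(self.matrices)


@dataclass
class MaskMatrix:
    values: np.ndarray
    sd: float
    seed: int

    @property
    def shape(self):
        return self.values.shape


MatrixLike = Union[PlainMatrix, EncryptedMatrix]


# ---------------------------------------------------------------------------
# packing


def n_blocks(rows: int, cols: int, slot_size: int) -> int:
    """Ciphertext blocks needed for an ``rows x cols`` matrix."""
    return -(-(rows * cols) // slot_size)


def encrypt_matrix(m: PlainMatrix, backend: HEBackend) -> EncryptedMatrix:
    slot = backend.params.slot_size
    flat = m.values.ravel()
    blocks = []
    for k in range(n_blocks(m.rows, m.cols, slot)):
        chunk = flat[k * slot : (k + 1) * slot]
        blocks.append(backend.encrypt(backend.encode(chunk)))
    return EncryptedMatrix(rows=m.rows, cols=m.cols, blocks=blocks)


def _reshape(flat: np.ndarray, rows: int, cols: int) -> PlainMatrix:
    return PlainMatrix(flat[: rows * cols].reshape(rows, cols))


def decrypt_matrix_collective(
    em: EncryptedMatrix,
    backend: HEBackend,
    shares: Sequence[SecretKeyShare],
    rng: Optional[np.random.Generator] = None,
) -> PlainMatrix:
    """Single-process threshold decryption of every block."""
    flat = np.concatenate(
        [backend.collective_decrypt(b, shares, rng=rng) for b in em.blocks]
    )
    return _reshape(flat, em.rows, em.cols)


def decrypt_matrix_with_master(
    em: EncryptedMatrix, backend: HEBackend, msk: Optional[MasterSecretKey]
) -> PlainMatrix:
    """Oracle decryption for tests."""
    flat = np.concatenate(
        [backend.decrypt_with_master(b, msk) for b in em.blocks]
    )
    return _reshape(flat, em.rows, em.cols)


# ---------------------------------------------------------------------------
# elementwise arithmetic


def _aligned(a: EncryptedMatrix, b: EncryptedMatrix, backend: HEBackend):
    lv = min(a.level, b.level)
    ab = [backend.align_to_level(x, lv) for x in a.blocks]
    bb = [backend.align_to_level(x, lv) for x in b.blocks]
    return ab, bb


def matrix_add(
    a: EncryptedMatrix, b: EncryptedMatrix, backend: HEBackend
) -> EncryptedMatrix:
    _check_same_shape(a, b)
    ab, bb = _aligned(a, b, backend)
    return EncryptedMatrix(
        a.rows, a.cols, [backend.he_add(x, y) for x, y in zip(ab, bb)]
    )


def matrix_sub(
    a: EncryptedMatrix, b: EncryptedMatrix, backend: HEBackend
) -> EncryptedMatrix:
    _check_same_shape(a, b)
    ab, bb = _aligned(a, b, backend)
    return EncryptedMatrix(
        a.rows, a.cols, [backend.he_sub(x, y) for x, y in zip(ab, bb)]
    )


def matrix_mul_elementwise(
    a: EncryptedMatrix, b: MatrixLike, backend: HEBackend
) -> EncryptedMatrix:
    _check_same_shape(a, b)
    if isinstance(b, PlainMatrix):
        slot = backend.params.slot_size
        flat = b.values.ravel()
        out = []
        for k, blk in enumerate(a.blocks):
            pv = backend.encode(flat[k * slot : (k + 1) * slot])
            out.append(backend.he_mul_plain(blk, pv))
        return EncryptedMatrix(a.rows, a.cols, out)
    ab, bb = _aligned(a, b, backend)
    return EncryptedMatrix(
        a.rows, a.cols, [backend.he_mul(x, y) for x, y in zip(ab, bb)]
    )


def _check_same_shape(a, b) -> None:
    if (a.rows, a.cols) != (b.rows, b.cols):
        raise ShapeError(
            f"shape mismatch: {(a.rows, a.cols)} vs {(b.rows, b.cols)}"
        )


# ---------------------------------------------------------------------------
# padding / scaling


def pad_matrix(m: PlainMatrix, c: int, d: int) -> PlainMatrix:
    if c < m.rows or d < m.cols:
        raise ShapeError(
            f"cannot pad {m.shape} down to {(c, d)}"
        )
    out = np.zeros((c, d))
    out[: m.rows, : m.cols] = m.values
    return PlainMatrix(out, scale_factor=m.scale_factor)


def next_pow2(p: int) -> int:
    if p < 1:
        raise ShapeError("size must be positive")
    return 1 << (p - 1).bit_length()


def pad_to_pow2(m: PlainMatrix, rows: bool = True, cols: bool = True) -> PlainMatrix:
    return pad_matrix(
        m,
        next_pow2(m.rows) if rows else m.rows,
        next_pow2(m.cols) if cols else m.cols,
    )


def scale_matrix(m: PlainMatrix, factor: float) -> PlainMatrix:
    if factor == 0:
        raise ValueError("scale factor must be nonzero")
    return PlainMatrix(
        m.values * factor, scale_factor=m.scale_factor * factor
    )


# ---------------------------------------------------------------------------
# expansions


def expand_columns(m: PlainMatrix, c: int) -> ExpansionSet:
    """ce_i^(c): for each column i of M, an a×c matrix of that column tiled."""
    mats = [
        PlainMatrix(np.tile(m.values[:, [i]], (1, c))) for i in range(m.cols)
    ]
    return ExpansionSet(kind="column", matrices=mats)


def expand_rows(m: PlainMatrix, a: int) -> ExpansionSet:
    """re_i^(a): for each row i of M, an a×cols matrix of that row tiled."""
    mats = [
        PlainMatrix(np.tile(m.values[[i], :], (a, 1))) for i in range(m.rows)
    ]
    return ExpansionSet(kind="row", matrices=mats)


def encrypt_expansion(es: ExpansionSet, backend: HEBackend) -> ExpansionSet:
    return ExpansionSet(
        kind=es.kind,
        matrices=[encrypt_matrix(m, backend) for m in es.matrices],
    )


def expand_rows_encrypted(
    em: EncryptedMatrix,
    height: int,
    backend: HEBackend,
    stats: Optional[Dict[str, int]] = None,
) -> ExpansionSet:
    """Row expansion of an encrypted matrix by masking and shift-and-add.

    Each row is isolated with a slot selector, then replicated with
    ``log2(height)`` doubling rotations; copies are tiled at the row stride,
    so a full output block is one ciphertext repeated.  ``height`` must be a
    power of two.
    """
    b = em.cols
    slot = backend.params.slot_size
    if height < 1 or (height & (height - 1)) != 0:
        raise ShapeError("replication height must be a power of 2")
    if b & (b - 1) or b > slot:
        raise ShapeError("column count must be a power of 2 dividing slots")
    if len(em.blocks) != 1:
        raise ShapeError("row expansion supports single-block matrices")
    rows_out = height
    blocks_out = n_blocks(rows_out, b, slot)
    acc_rot = 0
    mats: List[EncryptedMatrix] = []
    for i in range(em.rows):
        sel = np.zeros(slot)
        sel[i * b : (i + 1) * b] = 1.0
        x = backend.he_mul_plain(
            em.blocks[0], backend.encode(sel)
        )
        if i > 0:
            x = backend.he_rotate(x, i * b)
        # doubling: after k rounds the row occupies 2^k tiled positions
        copies = 1
        while copies < min(height, slot // b):
            shift = slot - copies * b  # circular right shift by copies*b
            x = backend.he_add(x, backend.he_rotate(x, shift))
            copies *= 2
            acc_rot += 1
        blocks = [x] * blocks_out
        mats.append(EncryptedMatrix(rows=rows_out, cols=b, blocks=blocks))
    if stats is not None:
        stats["accumulation_rotations"] = acc_rot
    return ExpansionSet(kind="row", matrices=mats)


# ---------------------------------------------------------------------------
# products


def matmul(
    a_ce: ExpansionSet, b_re: ExpansionSet, backend: HEBackend
) -> EncryptedMatrix:
    """M1·M2 as sum_i ce_i(M1) ⊙ re_i(M2); consumes one multiplicative level.

    At least one side of each elementwise product must be encrypted.
    """
    if a_ce.kind != "column" or b_re.kind != "row":
        raise ShapeError("matmul expects (column expansion, row expansion)")
    if len(a_ce) != len(b_re):
        raise ShapeError(
            f"inner dimension mismatch: {len(a_ce)} vs {len(b_re)}"
        )
    acc: Optional[EncryptedMatrix] = None
    for x, y in zip(a_ce.matrices, b_re.matrices):
        if isinstance(x, EncryptedMatrix):
            term = matrix_mul_elementwise(x, y, backend)
        elif isinstance(y, EncryptedMatrix):
            term = matrix_mul_elementwise(y, x, backend)
        else:
            raise ShapeError("at least one expansion side must be encrypted")
        acc = term if acc is None else matrix_add(acc, term, backend)
    assert acc is not None
    return acc


def secure_matmul(
    a: PlainMatrix, b: MatrixLike, backend: HEBackend
) -> EncryptedMatrix:
    """Convenience product of a plaintext left factor with any right factor."""
    if isinstance(b, PlainMatrix):
        if a.cols != b.rows:
            raise ShapeError("inner dimensions disagree")
        ce = expand_columns(a, b.cols)
        re = encrypt_expansion(expand_rows(b, a.rows), backend)
        return matmul(ce, re, backend)
    if a.cols != b.rows:
        raise ShapeError("inner dimensions disagree")
    re = expand_rows_encrypted(b, next_pow2(max(a.rows, 1)), backend)
    re = ExpansionSet(
        kind="row",
        matrices=[_crop_rows(m, a.rows) for m in re.matrices],
    )
    ce = expand_columns(a, b.cols)
    return matmul(ce, re, backend)


def _crop_rows(em: EncryptedMatrix, rows: int) -> EncryptedMatrix:
    return EncryptedMatrix(rows=rows, cols=em.cols, blocks=em.blocks)


def row_row_inner(
    a: EncryptedMatrix,
    b: MatrixLike,
    backend: HEBackend,
    stats: Optional[Dict[str, int]] = None,
) -> EncryptedMatrix:
    """Per-row inner products ⟨A_i, B_i⟩ as an (rows x 1) encrypted vector."""
    _check_same_shape(a, b)
    w = a.cols
    slot = backend.params.slot_size
    if w & (w - 1) or slot % w:
        raise ShapeError(
            "column count must be a power of 2 dividing the slot size"
        )
    prod = matrix_mul_elementwise(a, b, backend)
    acc_rot = 0
    summed: List[Ciphertext] = []
    for blk in prod.blocks:
        t = 1
        while t < w:
            blk = backend.he_add(blk, backend.he_rotate(blk, t))
            t *= 2
            acc_rot += 1
        summed.append(blk)
    if stats is not None:
        stats["accumulation_rotations"] = acc_rot

    # mask and copy every w-th slot into the compact output vector
    rows_per_block = slot // w
    out_blocks_n = n_blocks(a.rows, 1, slot)
    out: List[Optional[Ciphertext]] = [None] * out_blocks_n
    for kb, blk in enumerate(summed):
        first_row = kb * rows_per_block
        for r_local in range(min(rows_per_block, a.rows - first_row)):
            r = first_row + r_local
            sel = np.zeros(slot)
            sel[r_local * w] = 1.0
            piece = backend.he_mul_plain(blk, backend.encode(sel))
            dest = r % slot
            shift = (r_local * w - dest) % slot
            if shift:
                piece = backend.he_rotate(piece, shift)
            ob = r // slot
            out[ob] = piece if out[ob] is None else backend.he_add(
                out[ob], piece
            )
    return EncryptedMatrix(rows=a.rows, cols=1, blocks=[c for c in out if c is not None])


# ---------------------------------------------------------------------------
# masking


def make_mask(
    shape,
    sd: float = 1.0,
    seed: int = 0,
    invertible: bool = False,
    max_cond: float = 1e8,
) -> MaskMatrix:
    """Gaussian mask; for square multiplicative masks an ill-conditioned draw
    is rejected and regenerated from the next seed."""
    s = int(seed)
    while True:
        rng = np.random.default_rng(s)
        vals = rng.normal(0.0, sd, size=shape)
        if not invertible:
            return MaskMatrix(values=vals, sd=sd, seed=s)
        if vals.shape[0] != vals.shape[1]:
            raise ShapeError("multiplicative masks must be square")
        if np.linalg.cond(vals) <= max_cond:
            return MaskMatrix(values=vals, sd=sd, seed=s)
        s += 1


def apply_mask_add(
    em: EncryptedMatrix, mask: MaskMatrix, backend: HEBackend
) -> EncryptedMatrix:
    if mask.shape != (em.rows, em.cols):
        raise ShapeError("mask shape mismatch")
    enc = encrypt_matrix(PlainMatrix(mask.values), backend)
    return matrix_add(em, enc, backend)


def remove_mask_add(m: PlainMatrix, mask: MaskMatrix) -> PlainMatrix:
    if mask.shape != m.shape:
        raise ShapeError("mask shape mismatch")
    return PlainMatrix(m.values - mask.values, scale_factor=m.scale_factor)


def apply_mask_mul_elementwise(
    em: EncryptedMatrix, mask: MaskMatrix, backend: HEBackend
) -> EncryptedMatrix:
    if mask.shape != (em.rows, em.cols):
        raise ShapeError("mask shape mismatch")
    return matrix_mul_elementwise(em, PlainMatrix(mask.values), backend)


def remove_mask_mul_elementwise(m: PlainMatrix, mask: MaskMatrix) -> PlainMatrix:
    return PlainMatrix(m.values / mask.values, scale_factor=m.scale_factor)
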
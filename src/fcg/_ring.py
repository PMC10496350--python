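"""Negacyclic polynomial ring Z_q[X]/(X^n + 1) with arbitrary-precision coefficients.

Ring elements are Python lists of ints in [0, q).  Multiplication uses
Kronecker substitution: coefficients are packed into one large integer at a
fixed byte stride, multiplied with CPython's big-integer arithmetic, and the
product is unpacked and folded negacyclically.  This is exact for any modulus
(no NTT-friendly prime needed) and far faster than schoolbook convolution in
pure Python.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

RingElem = List[int]


def zero(n: int) -> RingElem:
    return [0] * n


def add(a: Sequence[int], b: Sequence[int], q: int) -> RingElem:
    return [(x + y) % q for x, y in zip(a, b)]


def sub(a: Sequence[int], b: Sequence[int], q: int) -> RingElem:
    return [(x - y) % q for x, y in zip(a, b)]


def neg(a: Sequence[int], q: int) -> RingElem:
    return [(-x) % q for x in a]


def scalar_mul(a: Sequence[int], c: int, q: int) -> RingElem:
    c %= q
    return [(x * c) % q for x in a]


def _stride_bytes(n: int, q: int) -> int:
    # product coefficients are bounded by n * (q-1)^2
    bits = (n * (q - 1) * (q - 1)).bit_length() + 1
    return (bits + 7) // 8


def mul(a: Sequence[int], b: Sequence[int], q: int) -> RingElem:
    """Negacyclic product a*b mod (X^n + 1, q) via Kronecker substitution."""
    n = len(a)
    if n != len(b):
        raise ValueError("ring element length mismatch")
    stride = _stride_bytes(n, q)
    sb = stride * 8
    ai = sum(x << (sb * k) for k, x in enumerate(a))
    bi = sum(x << (sb * k) for k, x in enumerate(b))
    prod = ai * bi
    raw = prod.to_bytes(stride * 2 * n, "little")
    coeffs = [
        int.from_bytes(raw[k * stride : (k + 1) * stride], "little")
        for k in range(2 * n)
    ]
    return [(coeffs[k] - coeffs[k + n]) % q for k in range(n - 1)] + [
        coeffs[n - 1] % q
    ]


def mul_schoolbook(a: Sequence[int], b: Sequence[int], q: int) -> RingElem:
    """Quadratic-time reference used only as a cross-check in tests."""
    n = len(a)
    out = [0] * n
    for i, x in enumerate(a):
        if x == 0:
            continue
        for j, y in enumerate(b):
            k = i + j
            t = x * y
            if k >= n:
                out[k - n] = (out[k - n] - t) % q
            else:
                out[k] = (out[k] + t) % q
    return out


def centered(a: Sequence[int], q: int) -> List[int]:
    """Lift residues to the centered interval (-q/2, q/2]."""
    h = q // 2
    return [x - q if x > h else x for x in a]


def automorphism(a: Sequence[int], g: int) -> RingElem:
    """Apply X -> X^g (g odd) to a ring element; sign flips past degree n."""
    n = len(a)
    out = [0] * n
    for k, x in enumerate(a):
        e = (k * g) % (2 * n)
        if e < n:
            out[e] = x
        else:
            out[e - n] = -x
    return out


def automorphism_mod(a: Sequence[int], g: int, q: int) -> RingElem:
    return [x % q for x in automorphism(a, g)]


def sample_ternary(n: int, rng: np.random.Generator) -> RingElem:
    return [int(v) for v in rng.integers(-1, 2, size=n)]


def sample_gaussian(n: int, sd: float, rng: np.random.Generator) -> RingElem:
    return [int(round(v)) for v in rng.normal(0.0, sd, size=n)]


def sample_uniform(n: int, q: int, rng: np.random.Generator) -> RingElem:
    # compose from 32-bit draws so arbitrary-precision q is supported
    nwords = (q.bit_length() + 31) // 32
    out = []
    for _ in range(n):
        v = 0
        for w in rng.integers(0, 2**32, size=nwords, dtype=np.uint64):
            v = (v << 32) | int(w)
        out.append(v % q)
    return out


def decompose(a: Sequence[int], base_bits: int, ndigits: int) -> List[RingElem]:
    """Digit decomposition of residues in [0, q): a = sum_i digit_i * B^i."""
    mask = (1 << base_bits) - 1
    digits = []
    cur = list(a)
    for _ in range(ndigits):
        digits.append([x & mask for x in cur])
        cur = [x >> base_bits for x in cur]
    return digits


def infinity_norm(a: Sequence[int], q: int) -> int:
    return max(abs(x) for x in centered(a, q)) if a else 0

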
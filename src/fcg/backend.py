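"""Ciphertext arithmetic backends with a common threshold-CKKS contract.

Two interchangeable implementations are provided:

``ToyCKKS``
    A genuine single-modulus RLWE/CKKS scheme at desk scale: canonical-
    embedding encoding over the primitive 2n-th roots of unity (slots ordered
    along powers of 5 so that Galois automorphisms act as slot rotations),
    randomized public-key encryption, digit-decomposed relinearization and
    rotation key switching, rescale-by-division in place of a modulus switch,
    and additive-share partial decryption with smudging noise.

``EmulatedCKKS``
    Plaintext slot vectors with CKKS semantics: identical packing, level
    budget and rotation behaviour, small injected approximation noise per
    operation, and partial decryptions formed from zero-sum share material
    plus smudging perturbation.  It preserves every protocol observable at
    plaintext speed and is the backend of choice for large cohorts.

Both backends run the same contract test suite; the protocols above them
never branch on the backend.
"""

from __future__ import annotations

import hashlib
import json
import struct
import zlib
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import _ring
from .errors import (
    AlignmentError,
    CapabilityError,
    CapacityError,
    DepthError,
    IncompleteError,
    KeyMaterialError,
    ProtocolError,
)
from .keys import EvalKeys, KeyBundle, MasterSecretKey, PublicKey, SecretKeyShare
from .params import EncryptionParams

_CT_MAGIC = b"FCG1"

_ENC_ERROR_SD = 3.2


@dataclass
class PlainVector:
    """Encoded plaintext: exactly ``slot_size`` real slots at a known scale."""

    slots: np.ndarray
    scale: float


@dataclass
class Ciphertext:
    payload: object
    level: int
    scale: float
    n_slots: int
    backend_id: str


@dataclass
class PartialDecryption:
    site_id: int
    payload: object
    includes_c0: bool
    scale: float
    n_slots: int
    level: int
    backend_id: str


class HEBackend:
    """Abstract ciphertext-arithmetic contract."""

    backend_id: str = "abstract"

    def __init__(
        self,
        params: EncryptionParams,
        public_key: Optional[PublicKey] = None,
        eval_keys: Optional[EvalKeys] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.params = params
        self.public_key = public_key
        self.eval_keys = eval_keys
        self.rng = rng if rng is not None else np.random.default_rng()
        self.rotation_count = 0

    # -- encoding -----------------------------------------------------------
    def encode(self, values: Sequence[float]) -> PlainVector:
        v = np.asarray(values, dtype=float).ravel()
        slot = self.params.slot_size
        if v.size > slot:
            raise CapacityError(
                f"{v.size} values exceed slot capacity {slot}"
            )
        slots = np.zeros(slot)
        slots[: v.size] = v
        return PlainVector(slots=slots, scale=self.params.scale)

    def decode(self, pv: PlainVector) -> np.ndarray:
        return np.asarray(pv.slots, dtype=float)

    # -- contract -----------------------------------------------------------
    def encrypt(self, pt: PlainVector) -> Ciphertext:
        raise NotImplementedError

    def he_add(self, a: Ciphertext, b: Ciphertext) -> Ciphertext:
        raise NotImplementedError

    def he_sub(self, a: Ciphertext, b: Ciphertext) -> Ciphertext:
        raise NotImplementedError

    def he_mul(self, a: Ciphertext, b: Ciphertext) -> Ciphertext:
        raise NotImplementedError

    def he_mul_plain(self, a: Ciphertext, p: PlainVector) -> Ciphertext:
        raise NotImplementedError

    def he_rotate(self, a: Ciphertext, t: int) -> Ciphertext:
        raise NotImplementedError

    def align_to_level(self, a: Ciphertext, level: int) -> Ciphertext:
        """Drop a ciphertext to a lower level (bookkeeping-only here)."""
        if level > a.level:
            raise AlignmentError(
                f"cannot raise level {a.level} to {level}; refresh instead"
            )
        return replace(a, level=level)

    def partial_decrypt(
        self,
        ct: Ciphertext,
        share: SecretKeyShare,
        include_c0: bool,
        rng: Optional[np.random.Generator] = None,
    ) -> PartialDecryption:
        raise NotImplementedError

    def aggregate_partials(
        self, partials: Sequence[PartialDecryption]
    ) -> PlainVector:
        raise NotImplementedError

    # -- shared checks ------------------------------------------------------
    def _check_pair(self, a: Ciphertext, b: Ciphertext) -> None:
        if a.backend_id != self.backend_id or b.backend_id != self.backend_id:
            raise KeyMaterialError("ciphertext from a different backend")
        if a.level != b.level:
            raise AlignmentError(f"level mismatch: {a.level} vs {b.level}")
        if not np.isclose(a.scale, b.scale, rtol=1e-9):
            raise AlignmentError(f"scale mismatch: {a.scale} vs {b.scale}")

    def _check_depth(self, *cts: Ciphertext) -> None:
        for c in cts:
            if c.level < 1:
                raise DepthError(
                    "multiplicative budget exhausted; run a collective "
                    "ciphertext refresh to restore depth"
                )

    def _check_partials(
        self, partials: Sequence[PartialDecryption]
    ) -> None:
        if len(partials) != self.params.n_sites:
            raise IncompleteError(
                f"need {self.params.n_sites} partials, got {len(partials)}"
            )
        sids = sorted(p.site_id for p in partials)
        if sids != list(range(1, self.params.n_sites + 1)):
            raise IncompleteError(f"partials from sites {sids}")
        n_c0 = sum(p.includes_c0 for p in partials)
        if n_c0 != 1:
            raise ProtocolError(
                f"exactly one partial must include c0, got {n_c0}"
            )

    # -- collective decryption convenience (single-process) -----------------
    def collective_decrypt(
        self,
        ct: Ciphertext,
        shares: Sequence[SecretKeyShare],
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        partials = [
            self.partial_decrypt(ct, sh, include_c0=(i == 0), rng=rng)
            for i, sh in enumerate(shares)
        ]
        return self.decode(self.aggregate_partials(partials))


# ---------------------------------------------------------------------------
# ToyCKKS: real RLWE arithmetic at small degree


_embed_cache: Dict[int, np.ndarray] = {}


def _embedding_matrix(n: int) -> np.ndarray:
    """Rows: evaluation of X^k at zeta^(5^j mod 2n), j < n/2."""
    E = _embed_cache.get(n)
    if E is None:
        exps = np.array(
            [pow(5, j, 2 * n) for j in range(n // 2)], dtype=float
        )
        k = np.arange(n, dtype=float)
        ang = np.pi / n * np.outer(exps, k)
        E = np.exp(1j * ang)
        _embed_cache[n] = E
    return E


class ToyCKKS(HEBackend):
    backend_id = "toy_ckks"

    def __init__(self, params, public_key=None, eval_keys=None, rng=None):
        super().__init__(params, public_key, eval_keys, rng)
        self._n = params.poly_degree

    def _q_at(self, level: int) -> int:
        return self.params.modulus_at_level(level)

    # -- encoding via the inverse canonical embedding ------------------------
    def _encode_poly(self, slots: np.ndarray, scale: float) -> List[int]:
        n = self._n
        E = _embedding_matrix(n)
        coeffs = (2.0 / n) * (E.conj().T @ slots.astype(complex)).real
        return [int(round(c)) for c in coeffs * scale]

    def _decode_poly(self, coeffs: Sequence[int], scale: float) -> np.ndarray:
        E = _embedding_matrix(self._n)
        m = np.array([float(c) for c in coeffs])
        return (E @ m).real / scale

    def encrypt(self, pt: PlainVector) -> Ciphertext:
        if self.public_key is None:
            raise KeyMaterialError("backend has no public key")
        q, n = self.params.modulus, self._n
        m = [c % q for c in self._encode_poly(pt.slots, pt.scale)]
        v = [x % q for x in _ring.sample_ternary(n, self.rng)]
        e0 = [x % q for x in _ring.sample_gaussian(n, _ENC_ERROR_SD, self.rng)]
        e1 = [x % q for x in _ring.sample_gaussian(n, _ENC_ERROR_SD, self.rng)]
        c0 = _ring.add(
            _ring.add(_ring.mul(v, self.public_key.pk0, q), m, q), e0, q
        )
        c1 = _ring.add(_ring.mul(v, self.public_key.pk1, q), e1, q)
        return Ciphertext(
            payload=(c0, c1),
            level=self.params.max_level,
            scale=pt.scale,
            n_slots=self.params.slot_size,
            backend_id=self.backend_id,
        )

    def he_add(self, a, b):
        self._check_pair(a, b)
        q = self._q_at(a.level)
        c0 = _ring.add(a.payload[0], b.payload[0], q)
        c1 = _ring.add(a.payload[1], b.payload[1], q)
        return replace(a, payload=(c0, c1))

    def he_sub(self, a, b):
        self._check_pair(a, b)
        q = self._q_at(a.level)
        c0 = _ring.sub(a.payload[0], b.payload[0], q)
        c1 = _ring.sub(a.payload[1], b.payload[1], q)
        return replace(a, payload=(c0, c1))

    def _rescale(self, coeffs: Sequence[int], level: int) -> List[int]:
        """Round-divide by the scale, switching from Q_level to Q_{level-1}."""
        q_old = self._q_at(level)
        q_new = self._q_at(level - 1)
        d = 1 << self.params.scale_bits
        half = d >> 1
        return [
            ((x + half) >> self.params.scale_bits) % q_new
            for x in _ring.centered(coeffs, q_old)
        ]

    def he_mul(self, a, b):
        if a.level != b.level:
            raise AlignmentError(f"level mismatch: {a.level} vs {b.level}")
        self._check_depth(a, b)
        if self.eval_keys is None or self.eval_keys.relin is None:
            raise CapabilityError("relinearization key unavailable")
        q = self._q_at(a.level)
        c0, c1 = a.payload
        d0, d1 = b.payload
        t0 = _ring.mul(c0, d0, q)
        t1 = _ring.add(_ring.mul(c0, d1, q), _ring.mul(c1, d0, q), q)
        t2 = _ring.mul(c1, d1, q)
        r0, r1 = self._key_switch(t2, self.eval_keys.relin, a.level)
        t0 = _ring.add(t0, r0, q)
        t1 = _ring.add(t1, r1, q)
        new_scale = a.scale * b.scale / self.params.scale
        return Ciphertext(
            payload=(self._rescale(t0, a.level), self._rescale(t1, a.level)),
            level=a.level - 1,
            scale=new_scale,
            n_slots=a.n_slots,
            backend_id=self.backend_id,
        )

    def he_mul_plain(self, a, p: PlainVector):
        self._check_depth(a)
        q = self._q_at(a.level)
        mp = [c % q for c in self._encode_poly(p.slots, p.scale)]
        c0 = _ring.mul(a.payload[0], mp, q)
        c1 = _ring.mul(a.payload[1], mp, q)
        new_scale = a.scale * p.scale / self.params.scale
        return Ciphertext(
            payload=(self._rescale(c0, a.level), self._rescale(c1, a.level)),
            level=a.level - 1,
            scale=new_scale,
            n_slots=a.n_slots,
            backend_id=self.backend_id,
        )

    def _key_switch(self, d: Sequence[int], ksk, level: int) -> tuple:
        q = self._q_at(level)
        ev = self.eval_keys
        ndig = -(-self.params.modulus_bits_at_level(level) // ev.base_bits)
        digits = _ring.decompose(d, ev.base_bits, ndig)
        acc0 = _ring.zero(self._n)
        acc1 = _ring.zero(self._n)
        for dig, k0, k1 in zip(digits, ksk.k0, ksk.k1):
            acc0 = _ring.add(acc0, _ring.mul(dig, [x % q for x in k0], q), q)
            acc1 = _ring.add(acc1, _ring.mul(dig, [x % q for x in k1], q), q)
        return acc0, acc1

    def he_rotate(self, a, t: int):
        slot = self.params.slot_size
        t %= slot
        if t == 0:
            return replace(a)
        if self.eval_keys is None or not self.eval_keys.galois:
            raise CapabilityError("rotation keys unavailable")
        n = self._n
        q = self._q_at(a.level)
        ct = a
        step = 1
        while step < slot:
            if t & step:
                if step not in self.eval_keys.galois:
                    raise CapabilityError(f"missing rotation key for {step}")
                g = pow(5, step, 2 * n)
                c0g = _ring.automorphism_mod(ct.payload[0], g, q)
                c1g = _ring.automorphism_mod(ct.payload[1], g, q)
                k0, k1 = self._key_switch(
                    c1g, self.eval_keys.galois[step], ct.level
                )
                ct = replace(ct, payload=(_ring.add(c0g, k0, q), k1))
                self.rotation_count += 1
            step <<= 1
        return ct

    # -- threshold decryption ------------------------------------------------
    def partial_decrypt(self, ct, share, include_c0, rng=None):
        if len(share.coeffs) != self._n:
            raise KeyMaterialError("share length does not match poly degree")
        rng = rng if rng is not None else self.rng
        q = self._q_at(ct.level)
        sm_sd = float(2 ** (self.params.smudging_bits / 2.0))
        e_sm = (
            _ring.sample_gaussian(self._n, sm_sd, rng)
            if self.params.smudging_bits > 0
            else _ring.zero(self._n)
        )
        dsk = [x % q for x in share.coeffs]
        p = _ring.add(_ring.mul(ct.payload[1], dsk, q), e_sm, q)
        if include_c0:
            p = _ring.add(p, ct.payload[0], q)
        return PartialDecryption(
            site_id=share.site_id,
            payload=p,
            includes_c0=include_c0,
            scale=ct.scale,
            n_slots=ct.n_slots,
            level=ct.level,
            backend_id=self.backend_id,
        )

    def aggregate_partials(self, partials):
        self._check_partials(partials)
        q = self._q_at(partials[0].level)
        acc = _ring.zero(self._n)
        for p in partials:
            acc = _ring.add(acc, p.payload, q)
        coeffs = _ring.centered(acc, q)
        vals = self._decode_poly(coeffs, partials[0].scale)
        return PlainVector(slots=vals, scale=partials[0].scale)

    def align_to_level(self, a: Ciphertext, level: int) -> Ciphertext:
        if level > a.level:
            raise AlignmentError(
                f"cannot raise level {a.level} to {level}; refresh instead"
            )
        if level == a.level:
            return replace(a)
        q = self._q_at(level)
        return replace(
            a,
            level=level,
            payload=([x % q for x in a.payload[0]], [x % q for x in a.payload[1]]),
        )

    def decrypt_with_master(
        self, ct: Ciphertext, msk: MasterSecretKey
    ) -> np.ndarray:
        """Oracle decryption with the (normally discarded) master key."""
        q = self._q_at(ct.level)
        s = [x % q for x in msk.coeffs]
        m = _ring.add(ct.payload[0], _ring.mul(ct.payload[1], s, q), q)
        return self._decode_poly(_ring.centered(m, q), ct.scale)


# ---------------------------------------------------------------------------
# EmulatedCKKS: plaintext slots with CKKS semantics


@dataclass
class _EmuPayload:
    slots: np.ndarray
    noise_bound: float


class EmulatedCKKS(HEBackend):
    backend_id = "emulated"

    @property
    def _op_sd(self) -> float:
        return float(2.0 ** (-self.params.scale_bits))

    def _perturb(self, slots: np.ndarray) -> np.ndarray:
        return slots + self.rng.normal(0.0, self._op_sd, size=slots.shape)

    def encrypt(self, pt: PlainVector) -> Ciphertext:
        return Ciphertext(
            payload=_EmuPayload(
                slots=self._perturb(np.asarray(pt.slots, dtype=float)),
                noise_bound=self._op_sd,
            ),
            level=self.params.max_level,
            scale=pt.scale,
            n_slots=self.params.slot_size,
            backend_id=self.backend_id,
        )

    def _combine(self, a, slots, level, scale, extra_noise=0.0):
        return Ciphertext(
            payload=_EmuPayload(
                slots=self._perturb(slots),
                noise_bound=a.payload.noise_bound + self._op_sd + extra_noise,
            ),
            level=level,
            scale=scale,
            n_slots=a.n_slots,
            backend_id=self.backend_id,
        )

    def he_add(self, a, b):
        self._check_pair(a, b)
        return self._combine(
            a, a.payload.slots + b.payload.slots, a.level, a.scale
        )

    def he_sub(self, a, b):
        self._check_pair(a, b)
        return self._combine(
            a, a.payload.slots - b.payload.slots, a.level, a.scale
        )

    def he_mul(self, a, b):
        if a.level != b.level:
            raise AlignmentError(f"level mismatch: {a.level} vs {b.level}")
        self._check_depth(a, b)
        return self._combine(
            a,
            a.payload.slots * b.payload.slots,
            a.level - 1,
            a.scale * b.scale / self.params.scale,
        )

    def he_mul_plain(self, a, p: PlainVector):
        self._check_depth(a)
        return self._combine(
            a,
            a.payload.slots * np.asarray(p.slots, dtype=float),
            a.level - 1,
            a.scale * p.scale / self.params.scale,
        )

    def he_rotate(self, a, t: int):
        t %= self.params.slot_size
        if t == 0:
            return replace(a)
        self.rotation_count += 1
        return self._combine(
            a, np.roll(a.payload.slots, -t), a.level, a.scale
        )

    def partial_decrypt(self, ct, share, include_c0, rng=None):
        if share.slot_share is None or len(share.slot_share) != ct.n_slots:
            raise KeyMaterialError(
                "share has no slot material for the emulated backend"
            )
        rng = rng if rng is not None else self.rng
        # deterministic per-ciphertext sign flips keep the zero-sum share
        # material from repeating verbatim across decryptions
        h = hashlib.sha256(
            np.ascontiguousarray(ct.payload.slots).tobytes()
        ).digest()
        sgn_rng = np.random.default_rng(
            int.from_bytes(h[:8], "little")
        )
        signs = sgn_rng.choice([-1.0, 1.0], size=ct.n_slots)
        sm_sd = float(
            2 ** (self.params.smudging_bits / 2.0)
        ) * self._op_sd
        payload = share.slot_share * signs + rng.normal(
            0.0, sm_sd, size=ct.n_slots
        )
        if include_c0:
            payload = payload + ct.payload.slots
        return PartialDecryption(
            site_id=share.site_id,
            payload=payload,
            includes_c0=include_c0,
            scale=ct.scale,
            n_slots=ct.n_slots,
            level=ct.level,
            backend_id=self.backend_id,
        )

    def aggregate_partials(self, partials):
        self._check_partials(partials)
        acc = np.zeros(partials[0].n_slots)
        for p in partials:
            acc = acc + p.payload
        return PlainVector(slots=acc, scale=partials[0].scale)

    def decrypt_with_master(self, ct: Ciphertext, msk=None) -> np.ndarray:
        """Oracle readout of the emulated payload (testing only)."""
        return np.asarray(ct.payload.slots, dtype=float)


# ---------------------------------------------------------------------------


BACKENDS = {"toy_ckks": ToyCKKS, "emulated": EmulatedCKKS}


def make_backend(
    name: str,
    params: EncryptionParams,
    public_key: Optional[PublicKey] = None,
    eval_keys: Optional[EvalKeys] = None,
    rng: Optional[np.random.Generator] = None,
) -> HEBackend:
    try:
        cls = BACKENDS[name]
    except KeyError:
        raise CapabilityError(f"unknown backend {name!r}") from None
    return cls(params, public_key, eval_keys, rng)


def backend_from_bundle(
    bundle: KeyBundle, name: str, rng: Optional[np.random.Generator] = None
) -> HEBackend:
    return make_backend(
        name, bundle.params, bundle.public_key, bundle.eval_keys, rng
    )


# -- ciphertext container serialization -------------------------------------


def ciphertext_to_bytes(ct: Ciphertext) -> bytes:
    if ct.backend_id == "toy_ckks":
        doc = {
            "c0": [format(x, "x") for x in ct.payload[0]],
            "c1": [format(x, "x") for x in ct.payload[1]],
        }
        bid = 0
    elif ct.backend_id == "emulated":
        doc = {
            "slots": ct.payload.slots.tolist(),
            "noise_bound": ct.payload.noise_bound,
        }
        bid = 1
    else:  # pragma: no cover
        raise CapabilityError(f"cannot serialize backend {ct.backend_id}")
    blob = zlib.compress(json.dumps(doc).encode())
    head = _CT_MAGIC + struct.pack(
        "<BBidI", 1, bid, ct.level, ct.scale, ct.n_slots
    )
    return head + blob


def ciphertext_from_bytes(data: bytes) -> Ciphertext:
    if data[:4] != _CT_MAGIC:
        raise ValueError("not a ciphertext container")
    ver, bid, level, scale, n_slots = struct.unpack("<BBidI", data[4:22])
    doc = json.loads(zlib.decompress(data[22:]))
    if bid == 0:
        payload = (
            [int(x, 16) for x in doc["c0"]],
            [int(x, 16) for x in doc["c1"]],
        )
        backend_id = "toy_ckks"
    else:
        payload = _EmuPayload(
            slots=np.asarray(doc["slots"], dtype=float),
            noise_bound=float(doc["noise_bound"]),
        )
        backend_id = "emulated"
    return Ciphertext(
        payload=payload,
        level=level,
        scale=scale,
        n_slots=n_slots,
        backend_id=backend_id,
    )
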
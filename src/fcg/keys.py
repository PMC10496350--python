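"""Master-key generation, additive secret-key sharing, and key bundles.

This is the offline key-authority role: it samples one ternary master secret
key for the whole collaboration, splits it into per-site additive shares over
the ring modulus (so that the shares sum back to the master key entrywise),
derives the common public key and the evaluation keys (relinearization and
rotation), and packages everything into a bundle in which each site's share
is sealed under that site's passphrase.  The master key is discarded after
the bundle is built unless a test explicitly asks for it to be retained.

Share construction, per coefficient j of the master key: the site order is
shuffled, one random site receives ``msk_j`` added to its running value, all
non-final sites receive discrete-Gaussian noise with variance ``2**dsk_bits``,
and the final site receives the modular complement, which makes the
reconstruction identity exact:  sum_s share_{s,j} = msk_j  (mod q).
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _aead, _ring
from .params import EncryptionParams, ParameterError

_MAGIC_PUBLIC = b"FCGP"
_MAGIC_EVAL = b"FCGE"
_MAGIC_SEALED = b"FCGS"
_VERSION = 1

#: digit-decomposition base (bits) for relinearization / rotation key switching
KS_BASE_BITS = 12

#: range of the emulated backend's zero-sum slot shares
_SLOT_SHARE_SPAN = float(2**20)


@dataclass
class MasterSecretKey:
    coeffs: List[int]  # entries in {-1, 0, 1}

    def __len__(self) -> int:
        return len(self.coeffs)


@dataclass
class SecretKeyShare:
    site_id: int  # 1-based
    coeffs: List[int]  # residues mod q
    # zero-sum real-valued share material used by the plaintext-emulation
    # backend to form partial decryptions without the ring layer
    slot_share: Optional[np.ndarray] = None


@dataclass
class PublicKey:
    pk0: List[int]
    pk1: List[int]


@dataclass
class KeySwitchKey:
    """Digit-decomposed key-switching key: one (k0, k1) pair per digit."""

    k0: List[List[int]]
    k1: List[List[int]]


@dataclass
class EvalKeys:
    base_bits: int
    ndigits: int
    relin: Optional[KeySwitchKey]
    galois: Dict[int, KeySwitchKey] = field(default_factory=dict)
    # galois is keyed by rotation step (power of two); the automorphism
    # exponent for step t is 5**t mod 2n


@dataclass
class KeyBundle:
    params: EncryptionParams
    public_key: PublicKey
    eval_keys: EvalKeys
    sealed_shares: Dict[int, bytes]
    sealed_symkeys: Dict[int, bytes]
    # retained only when make_key_bundle(..., keep_master=True); never saved
    master_key: Optional[MasterSecretKey] = None


def generate_master_key(
    params: EncryptionParams, seed: int | np.random.Generator
) -> MasterSecretKey:
    rng = np.random.default_rng(seed)
    return MasterSecretKey(_ring.sample_ternary(params.poly_degree, rng))


def split_secret_key(
    msk: MasterSecretKey,
    params: EncryptionParams,
    seed: int | np.random.Generator,
) -> List[SecretKeyShare]:
    """Additively share the master key among ``params.n_sites`` sites."""
    rng = np.random.default_rng(seed)
    S = params.n_sites
    if S < 1:
        raise ParameterError("need at least one site")
    n = params.poly_degree
    q = params.modulus
    sd = float(2 ** (params.dsk_noise_bits / 2.0))

    shares = np.zeros((S, n), dtype=object)
    for j in range(n):
        order = rng.permutation(S)
        star = int(order[int(rng.integers(S))])
        vals = [0] * S
        vals[star] += int(msk.coeffs[j])
        for s in order[:-1]:
            vals[int(s)] += int(round(rng.normal(0.0, sd)))
        last = int(order[-1])
        # modular complement makes the reconstruction identity exact
        others = sum(v for s, v in enumerate(vals) if s != last)
        vals[last] = int(msk.coeffs[j]) - others
        for s in range(S):
            shares[s, j] = vals[s] % q

    # emulated-backend share material: zero-sum uniform slot vectors
    slot = params.slot_size
    mats = rng.uniform(-_SLOT_SHARE_SPAN, _SLOT_SHARE_SPAN, size=(S, slot))
    if S > 1:
        mats[-1] = -mats[:-1].sum(axis=0)
    else:
        mats[0] = 0.0

    return [
        SecretKeyShare(
            site_id=s + 1,
            coeffs=[int(x) for x in shares[s]],
            slot_share=mats[s].copy(),
        )
        for s in range(S)
    ]


def reconstruct_master(
    shares: Sequence[SecretKeyShare], params: EncryptionParams
) -> List[int]:
    """Entrywise modular sum of shares (testing utility)."""
    q = params.modulus
    acc = [0] * params.poly_degree
    for sh in shares:
        acc = _ring.add(acc, sh.coeffs, q)
    return acc


_ERROR_SD = 3.2  # standard RLWE error width


def generate_public_key(
    msk: MasterSecretKey,
    params: EncryptionParams,
    seed: int | np.random.Generator,
) -> PublicKey:
    """(pk0, pk1) = (-a*msk + e, a) over the negacyclic ring."""
    rng = np.random.default_rng(seed)
    q = params.modulus
    n = params.poly_degree
    a = _ring.sample_uniform(n, q, rng)
    e = _ring.sample_gaussian(n, _ERROR_SD, rng)
    s = [x % q for x in msk.coeffs]
    pk0 = _ring.sub(_ring.add(e, [0] * n, q), _ring.mul(a, s, q), q)
    return PublicKey(pk0=pk0, pk1=a)


def _keyswitch_key(
    target: List[int],
    msk_mod: List[int],
    params: EncryptionParams,
    rng: np.random.Generator,
) -> KeySwitchKey:
    """Key that re-keys a component encrypted under ``target`` to ``msk``."""
    q = params.modulus
    n = params.poly_degree
    ndigits = -(-params.modulus_bits // KS_BASE_BITS)
    k0, k1 = [], []
    power = 1
    for _ in range(ndigits):
        a = _ring.sample_uniform(n, q, rng)
        e = _ring.sample_gaussian(n, _ERROR_SD, rng)
        body = _ring.add(
            _ring.sub(e, _ring.mul(a, msk_mod, q), q),
            _ring.scalar_mul(target, power, q),
            q,
        )
        k0.append(body)
        k1.append(a)
        power = (power << KS_BASE_BITS) % q
    return KeySwitchKey(k0=k0, k1=k1)


def generate_eval_keys(
    msk: MasterSecretKey,
    params: EncryptionParams,
    seed: int | np.random.Generator,
) -> EvalKeys:
    """Relinearization key plus rotation keys for all power-of-two steps."""
    rng = np.random.default_rng(seed)
    q = params.modulus
    n = params.poly_degree
    s = [x % q for x in msk.coeffs]
    ndigits = -(-params.modulus_bits // KS_BASE_BITS)
    relin = _keyswitch_key(_ring.mul(s, s, q), s, params, rng)
    galois: Dict[int, KeySwitchKey] = {}
    step = 1
    while step < params.slot_size:
        g = pow(5, step, 2 * n)
        s_g = _ring.automorphism_mod(s, g, q)
        galois[step] = _keyswitch_key(s_g, s, params, rng)
        step *= 2
    return EvalKeys(
        base_bits=KS_BASE_BITS, ndigits=ndigits, relin=relin, galois=galois
    )


# ---------------------------------------------------------------------------
# bundle assembly and serialization


def default_passphrases(n_sites: int) -> List[str]:
    return [f"site-{s + 1}-passphrase" for s in range(n_sites)]


def make_key_bundle(
    params: EncryptionParams,
    seed: int,
    passphrases: Optional[Sequence[str]] = None,
    keep_master: bool = False,
    with_eval_keys: bool = True,
) -> KeyBundle:
    """Run the whole key ceremony and seal per-site material.

    ``keep_master`` retains the master key in memory for oracle tests; it is
    never serialized.
    """
    if passphrases is None:
        passphrases = default_passphrases(params.n_sites)
    if len(passphrases) != params.n_sites:
        raise ParameterError("one passphrase per site required")
    ss = np.random.SeedSequence(seed)
    r_msk, r_split, r_pk, r_eval, r_sym = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]
    msk = generate_master_key(params, r_msk)
    shares = split_secret_key(msk, params, r_split)
    pk = generate_public_key(msk, params, r_pk)
    if with_eval_keys:
        evk = generate_eval_keys(msk, params, r_eval)
    else:
        ndig = -(-params.modulus_bits // KS_BASE_BITS)
        evk = EvalKeys(base_bits=KS_BASE_BITS, ndigits=ndig, relin=None)
    symkey = bytes(r_sym.integers(0, 256, size=32, dtype=np.uint8))

    sealed_shares: Dict[int, bytes] = {}
    sealed_symkeys: Dict[int, bytes] = {}
    for sh, phrase in zip(shares, passphrases):
        salt = os.urandom(16)
        key = _aead.derive_key(phrase, salt)
        payload = _pack_share(sh)
        sealed_shares[sh.site_id] = (
            _MAGIC_SEALED
            + bytes([_VERSION])
            + salt
            + _aead.seal(key, payload, aad=b"dsk%d" % sh.site_id)
        )
        salt2 = os.urandom(16)
        key2 = _aead.derive_key(phrase, salt2)
        sealed_symkeys[sh.site_id] = (
            _MAGIC_SEALED
            + bytes([_VERSION])
            + salt2
            + _aead.seal(key2, symkey, aad=b"sym%d" % sh.site_id)
        )

    return KeyBundle(
        params=params,
        public_key=pk,
        eval_keys=evk,
        sealed_shares=sealed_shares,
        sealed_symkeys=sealed_symkeys,
        master_key=msk if keep_master else None,
    )


def open_site_share(
    bundle: KeyBundle, site_id: int, passphrase: str
) -> Tuple[SecretKeyShare, bytes]:
    """Unseal one site's secret-key share and the shared symmetric key."""
    blob = bundle.sealed_shares[site_id]
    _check_magic(blob, _MAGIC_SEALED)
    salt, sealed = blob[5:21], blob[21:]
    key = _aead.derive_key(passphrase, salt)
    share = _unpack_share(_aead.open_(key, sealed, aad=b"dsk%d" % site_id))
    blob2 = bundle.sealed_symkeys[site_id]
    _check_magic(blob2, _MAGIC_SEALED)
    salt2, sealed2 = blob2[5:21], blob2[21:]
    key2 = _aead.derive_key(passphrase, salt2)
    symkey = _aead.open_(key2, sealed2, aad=b"sym%d" % site_id)
    return share, symkey


def _check_magic(blob: bytes, magic: bytes) -> None:
    if blob[:4] != magic or blob[4] != _VERSION:
        raise ValueError("bad magic or version in key file")


def _hex(elems: Sequence[int]) -> List[str]:
    return [format(x, "x") for x in elems]


def _unhex(strs: Sequence[str]) -> List[int]:
    return [int(s, 16) for s in strs]


def _pack_share(sh: SecretKeyShare) -> bytes:
    doc = {
        "site_id": sh.site_id,
        "coeffs": _hex(sh.coeffs),
        "slot_share": None
        if sh.slot_share is None
        else sh.slot_share.tolist(),
    }
    return zlib.compress(json.dumps(doc).encode())


def _unpack_share(payload: bytes) -> SecretKeyShare:
    doc = json.loads(zlib.decompress(payload))
    slot = doc["slot_share"]
    return SecretKeyShare(
        site_id=doc["site_id"],
        coeffs=_unhex(doc["coeffs"]),
        slot_share=None if slot is None else np.asarray(slot, dtype=float),
    )


def _pack_ksk(k: Optional[KeySwitchKey]) -> Optional[dict]:
    if k is None:
        return None
    return {"k0": [_hex(x) for x in k.k0], "k1": [_hex(x) for x in k.k1]}


def _unpack_ksk(d: Optional[dict]) -> Optional[KeySwitchKey]:
    if d is None:
        return None
    return KeySwitchKey(
        k0=[_unhex(x) for x in d["k0"]], k1=[_unhex(x) for x in d["k1"]]
    )


def save_bundle(bundle: KeyBundle, path: Path | str) -> None:
    """Write the bundle directory: params.json, public.key, eval.keys,
    site_<s>.dsk.enc, shared.symkey.enc."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    bundle.params.save(root / "params.json")
    pk_doc = {"pk0": _hex(bundle.public_key.pk0), "pk1": _hex(bundle.public_key.pk1)}
    (root / "public.key").write_bytes(
        _MAGIC_PUBLIC
        + bytes([_VERSION])
        + zlib.compress(json.dumps(pk_doc).encode())
    )
    ev = bundle.eval_keys
    ev_doc = {
        "base_bits": ev.base_bits,
        "ndigits": ev.ndigits,
        "relin": _pack_ksk(ev.relin),
        "galois": {str(t): _pack_ksk(k) for t, k in ev.galois.items()},
    }
    (root / "eval.keys").write_bytes(
        _MAGIC_EVAL + bytes([_VERSION]) + zlib.compress(json.dumps(ev_doc).encode())
    )
    for sid, blob in bundle.sealed_shares.items():
        (root / f"site_{sid}.dsk.enc").write_bytes(blob)
    sym_doc = {str(s): b.hex() for s, b in bundle.sealed_symkeys.items()}
    (root / "shared.symkey.enc").write_bytes(
        _MAGIC_SEALED
        + bytes([_VERSION])
        + zlib.compress(json.dumps(sym_doc).encode())
    )


def load_bundle(path: Path | str) -> KeyBundle:
    root = Path(path)
    params = EncryptionParams.load(root / "params.json")
    blob = (root / "public.key").read_bytes()
    _check_magic(blob, _MAGIC_PUBLIC)
    pk_doc = json.loads(zlib.decompress(blob[5:]))
    pk = PublicKey(pk0=_unhex(pk_doc["pk0"]), pk1=_unhex(pk_doc["pk1"]))
    blob = (root / "eval.keys").read_bytes()
    _check_magic(blob, _MAGIC_EVAL)
    ev_doc = json.loads(zlib.decompress(blob[5:]))
    evk = EvalKeys(
        base_bits=ev_doc["base_bits"],
        ndigits=ev_doc["ndigits"],
        relin=_unpack_ksk(ev_doc["relin"]),
        galois={int(t): _unpack_ksk(k) for t, k in ev_doc["galois"].items()},
    )
    sealed_shares = {}
    for f in sorted(root.glob("site_*.dsk.enc")):
        sid = int(f.stem.split("_")[1].split(".")[0])
        sealed_shares[sid] = f.read_bytes()
    blob = (root / "shared.symkey.enc").read_bytes()
    _check_magic(blob, _MAGIC_SEALED)
    sym_doc = json.loads(zlib.decompress(blob[5:]))
    sealed_symkeys = {int(s): bytes.fromhex(h) for s, h in sym_doc.items()}
    return KeyBundle(
        params=params,
        public_key=pk,
        eval_keys=evk,
        sealed_shares=sealed_shares,
        sealed_symkeys=sealed_symkeys,
    )
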
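"""Authenticated symmetric encryption built from HMAC-SHA256 primitives.

Used to protect secret-key shares at rest and partial decryptions in transit.
Construction: a counter-mode keystream generated by HMAC-SHA256 under an
encryption subkey, with an encrypt-then-MAC tag under an independent
authentication subkey.  Passphrase keys are derived with scrypt.
"""

from __future__ import annotations

import hashlib
import hmac
import os

_TAG_LEN = 32
_NONCE_LEN = 16


class AuthenticationError(Exception):
    """Ciphertext failed integrity verification."""


def derive_key(passphrase: str, salt: bytes) -> bytes:
    return hashlib.scrypt(
        passphrase.encode(), salt=salt, n=2**14, r=8, p=1, dklen=32
    )


def _subkeys(key: bytes) -> tuple[bytes, bytes]:
    enc = hmac.new(key, b"fcg-enc", hashlib.sha256).digest()
    mac = hmac.new(key, b"fcg-mac", hashlib.sha256).digest()
    return enc, mac


def _keystream(enc_key: bytes, nonce: bytes, length: int) -> bytes:
    blocks = []
    for ctr in range((length + 31) // 32):
        blocks.append(
            hmac.new(
                enc_key, nonce + ctr.to_bytes(8, "big"), hashlib.sha256
            ).digest()
        )
    return b"".join(blocks)[:length]


def seal(
    key: bytes, plaintext: bytes, aad: bytes = b"", nonce: bytes | None = None
) -> bytes:
    """Seal a message; a caller-supplied 16-byte nonce makes the output
    deterministic (used for replayable protocol transcripts)."""
    enc_key, mac_key = _subkeys(key)
    if nonce is None:
        nonce = os.urandom(_NONCE_LEN)
    if len(nonce) != _NONCE_LEN:
        raise ValueError("nonce must be 16 bytes")
    ct = bytes(
        a ^ b for a, b in zip(plaintext, _keystream(enc_key, nonce, len(plaintext)))
    )
    tag = hmac.new(mac_key, nonce + aad + ct, hashlib.sha256).digest()
    return nonce + ct + tag


def open_(key: bytes, sealed: bytes, aad: bytes = b"") -> bytes:
    if len(sealed) < _NONCE_LEN + _TAG_LEN:
        raise AuthenticationError("sealed message too short")
    nonce = sealed[:_NONCE_LEN]
    ct = sealed[_NONCE_LEN:-_TAG_LEN]
    tag = sealed[-_TAG_LEN:]
    enc_key, mac_key = _subkeys(key)
    expect = hmac.new(mac_key, nonce + aad + ct, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expect):
        raise AuthenticationError("authentication tag mismatch")
    return bytes(
        a ^ b for a, b in zip(ct, _keystream(enc_key, nonce, len(ct)))
    )
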
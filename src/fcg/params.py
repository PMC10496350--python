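"""Encryption parameters for the threshold CKKS schemes.

The parameter set mirrors the configuration surface of an RNS-CKKS library:
a power-of-two polynomial degree ``n`` (slot count is ``n/2``), a vector of
coefficient-modulus bit sizes whose length fixes the multiplicative depth,
an encoding scale ``2**scale_bits``, the smudging-noise budget for partial
decryptions (40 bits by default), and the noise level used when additively
sharing the master secret key among sites.

The toy backend realizes the chain as powers of two: the top modulus is
``2**sum(coeff_modulus_bits)`` and each rescale divides both the ciphertext
and the modulus by ``2**scale_bits``, so every lower modulus divides every
higher one and all congruences survive modulus reduction exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List

#: depth-6 default chain: enough budget for one full secure GWAS scoring pass
DEFAULT_COEFF_MODULUS_BITS = [60, 40, 40, 40, 40, 40, 60]


class ParameterError(ValueError):
    """Raised for invalid or inconsistent encryption parameters."""


@dataclass(frozen=True)
class EncryptionParams:
    poly_degree: int = 1024
    coeff_modulus_bits: List[int] = field(
        default_factory=lambda: list(DEFAULT_COEFF_MODULUS_BITS)
    )
    scale_bits: int = 40
    smudging_bits: int = 40
    dsk_noise_bits: int = 20
    n_sites: int = 3

    def __post_init__(self) -> None:
        n = self.poly_degree
        if n < 2 or (n & (n - 1)) != 0:
            raise ParameterError(f"poly_degree must be a power of 2, got {n}")
        if not self.coeff_modulus_bits or any(
            b <= 0 for b in self.coeff_modulus_bits
        ):
            raise ParameterError("coeff_modulus_bits must be positive")
        if self.scale_bits <= 0:
            raise ParameterError("scale_bits must be positive")
        if self.smudging_bits < 0:
            raise ParameterError("smudging_bits must be >= 0")
        if self.dsk_noise_bits <= 0:
            raise ParameterError("dsk_noise_bits must be positive")
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")
        if self.modulus_bits_at_level(0) <= self.scale_bits:
            raise ParameterError(
                "modulus chain leaves no headroom at level 0; "
                "increase coeff_modulus_bits"
            )

    @property
    def slot_size(self) -> int:
        # slot count is exactly half of the polynomial degree modulus
        return self.poly_degree // 2

    @property
    def scale(self) -> float:
        return float(2**self.scale_bits)

    @property
    def max_level(self) -> int:
        """Multiplicative depth: one less than the modulus-chain length."""
        return len(self.coeff_modulus_bits) - 1

    @property
    def modulus_bits(self) -> int:
        return sum(self.coeff_modulus_bits)

    @property
    def modulus(self) -> int:
        """Top-level toy coefficient modulus (power of two)."""
        return 1 << self.modulus_bits

    def modulus_bits_at_level(self, level: int) -> int:
        if not 0 <= level <= self.max_level:
            raise ParameterError(f"level {level} outside [0, {self.max_level}]")
        return self.modulus_bits - (self.max_level - level) * self.scale_bits

    def modulus_at_level(self, level: int) -> int:
        return 1 << self.modulus_bits_at_level(level)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncryptionParams":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: Path | str) -> "EncryptionParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def emulated_params(
    n_sites: int = 3,
    poly_degree: int = 16384,
    depth: int = 6,
    scale_bits: int = 40,
    smudging_bits: int = 40,
    **kw,
) -> EncryptionParams:
    """Convenience parameter set for the plaintext-emulation backend.

    The production-scale degree 16384 gives 8192 slots per ciphertext, the
    packing used throughout the reference workloads.
    """
    bits = [60] + [scale_bits] * (depth - 1) + [60]
    return EncryptionParams(
        poly_degree=poly_degree,
        coeff_modulus_bits=bits,
        scale_bits=scale_bits,
        smudging_bits=smudging_bits,
        n_sites=n_sites,
        **kw,
    )


def toy_params(
    n_sites: int = 3,
    poly_degree: int = 1024,
    depth: int = 6,
    scale_bits: int = 40,
    **kw,
) -> EncryptionParams:
    """Small-degree parameter set for the real single-modulus RLWE backend."""
    bits = [60] + [scale_bits] * (depth - 1) + [60]
    return EncryptionParams(
        poly_degree=poly_degree,
        coeff_modulus_bits=bits,
        scale_bits=scale_bits,
        n_sites=n_sites,
        **kw,
    )
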
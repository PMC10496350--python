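"""Shared-space exchange and multiparty protocol building blocks.

Sites communicate through a star-shaped shared space — here a local
directory with the same probe/wait contract a bucket or FTP drop box would
offer.  Uploaded files are immutable and named ``r<round>_s<site>_<tag>``.
All protocols are orchestrated round-robin in one process: each step is a
pure function of a site's context and the files visible in the space, so a
run is fully replayable.

Building blocks:

* collective decryption of an encrypted matrix (partials AEAD-protected with
  the shared symmetric key; the lowest-id site contributes the ``c0`` term);
* masked collaborative inversion of a pooled matrix (pool encrypted Gaussian
  masks, multiply locally, decrypt the masked pool, invert in plaintext,
  re-apply the encrypted mask);
* collective ciphertext refresh (additively mask, decrypt, re-encrypt fresh,
  subtract the mask in the encrypted domain).
"""

from __future__ import annotations

import pickle
import time
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from . import _aead, matrix as fm
from .backend import HEBackend, PartialDecryption
from .errors import ConditionError, ProtocolError, StallError, TamperError
from .keys import SecretKeyShare
from .matrix import EncryptedMatrix, PlainMatrix


class SharedSpace:
    """Immutable file drop box with probe/wait semantics."""

    def __init__(
        self,
        root: Path | str,
        poll_interval: float = 0.1,
        timeout: float = 60.0,
    ) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.poll_interval = poll_interval
        self.timeout = timeout

    def upload(self, name: str, data: bytes) -> None:
        path = self.root / name
        if path.exists():
            raise ProtocolError(f"shared file {name!r} already exists")
        tmp = path.with_suffix(path.suffix + ".part")
        tmp.write_bytes(data)
        tmp.rename(path)

    def probe(self, name: str) -> bool:
        return (self.root / name).exists()

    def download(self, name: str) -> bytes:
        path = self.root / name
        if not path.exists():
            raise StallError(f"shared file {name!r} not present")
        return path.read_bytes()

    def wait_for(self, name: str, timeout: Optional[float] = None) -> bytes:
        deadline = time.monotonic() + (
            self.timeout if timeout is None else timeout
        )
        while True:
            if self.probe(name):
                return self.download(name)
            if time.monotonic() >= deadline:
                raise StallError(
                    f"timed out waiting for shared file {name!r}"
                )
            time.sleep(self.poll_interval)

    def listing(self) -> List[str]:
        return sorted(
            p.name for p in self.root.iterdir() if not p.name.endswith(".part")
        )


@dataclass
class SiteContext:
    """One site's key material, randomness and round bookkeeping."""

    site_id: int
    backend: HEBackend
    share: SecretKeyShare
    sym_key: bytes
    rng: np.random.Generator
    round: int = 0

    def next_round(self) -> int:
        self.round += 1
        return self.round


def make_site_contexts(
    bundle,
    backend_name: str,
    seed: int,
    passphrases: Optional[Sequence[str]] = None,
) -> List[SiteContext]:
    """Open every site's share and build per-site backends and RNG streams."""
    from .backend import make_backend
    from .keys import default_passphrases, open_site_share

    S = bundle.params.n_sites
    if passphrases is None:
        passphrases = default_passphrases(S)
    streams = np.random.SeedSequence(seed).spawn(S)
    sites = []
    for sid, phrase, stream in zip(range(1, S + 1), passphrases, streams):
        share, sym = open_site_share(bundle, sid, phrase)
        rng = np.random.default_rng(stream)
        backend = make_backend(
            backend_name,
            bundle.params,
            bundle.public_key,
            bundle.eval_keys,
            rng=np.random.default_rng(stream.spawn(1)[0]),
        )
        sites.append(
            SiteContext(
                site_id=sid,
                backend=backend,
                share=share,
                sym_key=sym,
                rng=rng,
            )
        )
    return sites


def _fname(rnd: int, site: int, tag: str, ext: str) -> str:
    return f"r{rnd}_s{site}_{tag}.{ext}"


def _em_bytes(em: EncryptedMatrix) -> bytes:
    return em.to_bytes()


# ---------------------------------------------------------------------------
# collective matrix decryption


def _seal_partials(
    ctx: SiteContext, partials: List[PartialDecryption]
) -> bytes:
    # nonce drawn from the site RNG keeps protocol transcripts replayable
    nonce = ctx.rng.bytes(16)
    return _aead.seal(ctx.sym_key, pickle.dumps(partials), nonce=nonce)


def _open_partials(key: bytes, blob: bytes) -> List[PartialDecryption]:
    try:
        return pickle.loads(_aead.open_(key, blob))
    except _aead.AuthenticationError as e:
        raise TamperError(f"partial decryption failed to verify: {e}") from e


def collective_decrypt_matrix(
    em: EncryptedMatrix,
    sites: Sequence[SiteContext],
    space: SharedSpace,
    tag: str,
    return_all: bool = False,
):
    """All sites decrypt ``em`` together; every site gets the same plaintext.

    Each site uploads symmetric-encrypted partial decryptions for every
    block; the lowest site id includes the ``c0`` term.  Returns the result
    as computed by the first site (the round-robin driver checks the others
    agree in tests).
    """
    lowest = min(ctx.site_id for ctx in sites)
    rnd = max(ctx.round for ctx in sites) + 1
    for ctx in sites:
        ctx.round = rnd
        partials = [
            ctx.backend.partial_decrypt(
                blk, ctx.share, include_c0=(ctx.site_id == lowest), rng=ctx.rng
            )
            for blk in em.blocks
        ]
        space.upload(
            _fname(rnd, ctx.site_id, tag, "pdec"), _seal_partials(ctx, partials)
        )
    results = []
    for ctx in sites:
        per_site = [
            _open_partials(
                ctx.sym_key,
                space.wait_for(_fname(rnd, other.site_id, tag, "pdec")),
            )
            for other in sites
        ]
        flat = np.concatenate(
            [
                ctx.backend.decode(
                    ctx.backend.aggregate_partials(
                        [per_site[s][k] for s in range(len(sites))]
                    )
                )
                for k in range(len(em.blocks))
            ]
        )
        results.append(flat[: em.rows * em.cols].reshape(em.rows, em.cols))
    if return_all:
        return [PlainMatrix(r) for r in results]
    return PlainMatrix(results[0])


# ---------------------------------------------------------------------------
# masked collaborative inversion (pool -> mask -> decrypt -> invert -> unmask)


def masked_collaborative_inverse(
    local_terms: Sequence[PlainMatrix],
    sites: Sequence[SiteContext],
    space: SharedSpace,
    tag: str,
    mask_sd: float = 1.0,
) -> EncryptedMatrix:
    """Encrypted padded inverse of the pooled matrix sum_s local_terms[s].

    Each site holds its own p×p term in plaintext and must learn only the
    (padded) inverse of the pool, in encrypted form.  Sites pool encrypted
    unit-Gaussian masks H_s into H, locally compute the encrypted product
    Υ_s·H from the plaintext column expansion of Υ_s, pool into Υ·H, decrypt
    it collectively, invert in plaintext (yielding H^{-1}Υ^{-1}), and
    re-apply the encrypted column expansion of pad(H) on the left to obtain
    pad(Υ^{-1}) without any site seeing Υ or Υ^{-1} in the clear.
    """
    p = local_terms[0].rows
    if any(t.shape != (p, p) for t in local_terms):
        raise ProtocolError("local terms must be square and equal-shaped")
    P = fm.next_pow2(p)
    rnd = max(ctx.round for ctx in sites) + 1
    for ctx in sites:
        ctx.round = rnd

    # step 1: every site uploads encrypted expansions of its mask
    for ctx in sites:
        h = ctx.rng.normal(0.0, mask_sd, size=(p, p))
        hm = PlainMatrix(h)
        re_h = fm.encrypt_expansion(fm.expand_rows(hm, p), ctx.backend)
        ce_hp = fm.encrypt_expansion(
            fm.expand_columns(fm.pad_matrix(hm, P, P), P), ctx.backend
        )
        for i, m in enumerate(re_h.matrices):
            space.upload(_fname(rnd, ctx.site_id, f"{tag}-reh{i}", "encmat"), _em_bytes(m))
        for i, m in enumerate(ce_hp.matrices):
            space.upload(_fname(rnd, ctx.site_id, f"{tag}-cehp{i}", "encmat"), _em_bytes(m))

    # step 2: pool mask expansions, compute and upload local masked products
    first = sites[0]
    re_H = [
        _pool_encmats(sites, space, rnd, f"{tag}-reh{i}", first.backend)
        for i in range(p)
    ]
    ce_Hp = [
        _pool_encmats(sites, space, rnd, f"{tag}-cehp{i}", first.backend)
        for i in range(P)
    ]
    for ctx, term in zip(sites, local_terms):
        ce_t = fm.expand_columns(term, p)
        masked = fm.matmul(
            fm.ExpansionSet(kind="column", matrices=ce_t.matrices),
            fm.ExpansionSet(kind="row", matrices=re_H),
            ctx.backend,
        )
        space.upload(
            _fname(rnd, ctx.site_id, f"{tag}-masked", "encmat"),
            _em_bytes(masked),
        )

    # step 3: pool masked products and decrypt the masked pool
    pooled = _pool_encmats(sites, space, rnd, f"{tag}-masked", first.backend)
    masked_plain = collective_decrypt_matrix(pooled, sites, space, f"{tag}-mdec")

    # step 4: plaintext inversion of the masked pool
    cond = np.linalg.cond(masked_plain.values)
    if not np.isfinite(cond) or cond > 1e12:
        raise ConditionError(
            f"masked pooled matrix is numerically singular (cond={cond:.3g}); "
            "re-run with fresh mask seeds"
        )
    hinv_uinv = np.linalg.inv(masked_plain.values)  # H^{-1} Υ^{-1}

    # step 5: unmask in the encrypted domain: pad(Υ^{-1}) = ce(pad H) · re(pad(H^{-1}Υ^{-1}))
    re_part = fm.expand_rows(
        fm.pad_matrix(PlainMatrix(hinv_uinv), P, P), P
    )
    inv_enc = fm.matmul(
        fm.ExpansionSet(kind="column", matrices=ce_Hp),
        re_part,
        first.backend,
    )
    return inv_enc


def _pool_encmats(
    sites: Sequence[SiteContext],
    space: SharedSpace,
    rnd: int,
    tag: str,
    backend: HEBackend,
) -> EncryptedMatrix:
    acc: Optional[EncryptedMatrix] = None
    for ctx in sites:
        em = EncryptedMatrix.from_bytes(
            space.wait_for(_fname(rnd, ctx.site_id, tag, "encmat"))
        )
        acc = em if acc is None else fm.matrix_add(acc, em, backend)
    assert acc is not None
    return acc


# ---------------------------------------------------------------------------
# collective ciphertext refresh


def collective_refresh(
    em: EncryptedMatrix,
    sites: Sequence[SiteContext],
    space: SharedSpace,
    tag: str,
    mask_sd: float = 100.0,
) -> EncryptedMatrix:
    """Restore a (possibly level-exhausted) encrypted matrix to full depth.

    Sites pool fresh encrypted additive masks, the masked matrix is
    collectively decrypted (revealing only masked values), re-encrypted at
    the maximum level, and the encrypted mask is subtracted again.
    """
    rnd = max(ctx.round for ctx in sites) + 1
    for ctx in sites:
        ctx.round = rnd
    for ctx in sites:
        r = ctx.rng.normal(0.0, mask_sd, size=(em.rows, em.cols))
        enc = fm.encrypt_matrix(PlainMatrix(r), ctx.backend)
        space.upload(
            _fname(rnd, ctx.site_id, f"{tag}-mask", "encmat"), _em_bytes(enc)
        )
    backend = sites[0].backend
    mask_pool = _pool_encmats(sites, space, rnd, f"{tag}-mask", backend)
    masked = fm.matrix_add(em, mask_pool, backend)
    masked_plain = collective_decrypt_matrix(masked, sites, space, f"{tag}-rdec")
    fresh = fm.encrypt_matrix(masked_plain, backend)
    return fm.matrix_sub(fresh, mask_pool, backend)
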
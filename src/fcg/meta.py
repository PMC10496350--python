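"""Secure meta-analysis of per-site score statistics.

Each site fits its own covariate-only logistic null model entirely locally
and computes the per-variant score numerator and variance,

    T_s = G_s'(y_s - μ0_s)
    S_s = diag(G_s'W_sG_s) - diag(G_s'W_sX_s (X_s'W_sX_s)^{-1} X_s'W_sG_s),

then encrypts both vectors.  Combination is pooling by encrypted summation;
the pooled score is squared homomorphically, both (ΣT)² and ΣS receive the
same collectively-pooled positive mask, and the masked pair is decrypted to
yield the χ²₁ statistic (ΣT)²/(ΣS).  Only summary vectors ever leave a
site, and only in encrypted or masked form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from . import matrix as fm
from .collab import SharedSpace, SiteContext, collective_decrypt_matrix
from .errors import ProtocolError
from .gwas import (
    GwasResult,
    SiteCohort,
    chi2_pvalues,
    pooled_irls,
)
from .matrix import EncryptedMatrix, PlainMatrix


@dataclass
class SiteSummary:
    """Per-variant local score statistics (plaintext, site-private)."""

    variant_ids: List[str]
    T: np.ndarray
    S: np.ndarray

    def to_tsv(self, path: Path | str) -> None:
        pd.DataFrame(
            {"variant_id": self.variant_ids, "T": self.T, "S": self.S}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: Path | str) -> "SiteSummary":
        df = pd.read_csv(path, sep="\t")
        return cls(
            variant_ids=df["variant_id"].astype(str).tolist(),
            T=df["T"].to_numpy(dtype=float),
            S=df["S"].to_numpy(dtype=float),
        )


def local_site_summary(
    cohort: SiteCohort,
    tol: float = 1e-4,
    max_epochs: int = 10,
) -> SiteSummary:
    """Local null fit (single-site IRLS) and GMMAT-style score components."""
    alpha, terms, converged = pooled_irls(
        [cohort], tol=tol, max_epochs=max_epochs
    )
    if not converged:
        warnings.warn(
            "local null model did not converge; summary emitted anyway",
            RuntimeWarning,
            stacklevel=2,
        )
    t = terms[0]
    G, X = cohort.G, cohort.X
    T = G.T @ (cohort.y - t.mu0)
    S1 = np.einsum("ij,i,ij->j", G, t.W, G)
    gwx = (G * t.W[:, None]).T @ X
    ups_inv = np.linalg.inv(t.Upsilon)
    S = S1 - np.einsum("ij,jk,ik->i", gwx, ups_inv, gwx)
    return SiteSummary(variant_ids=list(cohort.variant_ids), T=T, S=S)


def secure_meta_combine(
    summaries: Sequence[SiteSummary],
    sites: Sequence[SiteContext],
    space: SharedSpace,
) -> GwasResult:
    """Encrypted pooling of site summaries, masking, and p-value assignment."""
    if len(summaries) != len(sites):
        raise ProtocolError("one summary per site required")
    ids = summaries[0].variant_ids
    for s in summaries[1:]:
        if s.variant_ids != ids:
            raise ProtocolError("variant sets differ across site summaries")
    M = len(ids)
    backend = sites[0].backend

    rnd = max(ctx.round for ctx in sites) + 1
    for ctx, summ in zip(sites, summaries):
        ctx.round = rnd
        t_enc = fm.encrypt_matrix(PlainMatrix(summ.T[:, None]), ctx.backend)
        s_enc = fm.encrypt_matrix(PlainMatrix(summ.S[:, None]), ctx.backend)
        space.upload(f"r{rnd}_s{ctx.site_id}_metaT.encmat", t_enc.to_bytes())
        space.upload(f"r{rnd}_s{ctx.site_id}_metaS.encmat", s_enc.to_bytes())

    T = _pool_named(sites, space, rnd, "metaT", backend)
    S = _pool_named(sites, space, rnd, "metaS", backend)
    T2 = fm.matrix_mul_elementwise(T, T, backend)

    rnd = max(ctx.round for ctx in sites) + 1
    for ctx in sites:
        ctx.round = rnd
        c_s = ctx.rng.uniform(0.5, 1.5, size=M)
        mask = PlainMatrix(c_s[:, None])
        space.upload(
            f"r{rnd}_s{ctx.site_id}_metamT2.encmat",
            fm.matrix_mul_elementwise(T2, mask, ctx.backend).to_bytes(),
        )
        space.upload(
            f"r{rnd}_s{ctx.site_id}_metamS.encmat",
            fm.matrix_mul_elementwise(S, mask, ctx.backend).to_bytes(),
        )
    t2_pool = _pool_named(sites, space, rnd, "metamT2", backend)
    s_pool = _pool_named(sites, space, rnd, "metamS", backend)

    t2_plain = collective_decrypt_matrix(
        t2_pool, sites, space, "meta-T2"
    ).values.ravel()
    s_plain = collective_decrypt_matrix(
        s_pool, sites, space, "meta-S"
    ).values.ravel()

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = t2_plain / s_plain
    stat[s_plain <= 0] = np.nan
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "statistic": stat,
            "p_value": chi2_pvalues(stat),
        }
    )
    return GwasResult(table=table)


def _pool_named(sites, space, rnd, tag, backend) -> EncryptedMatrix:
    acc = None
    for ctx in sites:
        em = EncryptedMatrix.from_bytes(
            space.wait_for(f"r{rnd}_s{ctx.site_id}_{tag}.encmat")
        )
        acc = em if acc is None else fm.matrix_add(acc, em, backend)
    return acc


def plaintext_meta_analysis(
    summaries: Sequence[SiteSummary],
) -> GwasResult:
    """Unencrypted reference combination (oracle for tests)."""
    T = sum(s.T for s in summaries)
    S = sum(s.S for s in summaries)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = T**2 / S
    stat[S <= 0] = np.nan
    return GwasResult(
        pd.DataFrame(
            {
                "variant_id": summaries[0].variant_ids,
                "statistic": stat,
                "p_value": chi2_pvalues(stat),
            }
        )
    )
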
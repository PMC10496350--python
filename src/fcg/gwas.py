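"""Federated binary-trait GWAS over the threshold-HE toolkit.

The association model is a logistic regression score test in the two-step
style of GMMAT: a covariate-only null model is fitted once by federated
IRLS, then every variant is scored against the fitted null.

Null model (iterated until convergence of the covariate weights α):

    μ0 = logistic(Xα),   W = diag(μ0(1-μ0)),   z = Xα + (y-μ0)/(μ0(1-μ0))
    α_new = (X'WX)^{-1} X'Wz

Each site only ever uploads encrypted aggregates (Υ_s = X_s'W_sX_s masked by
the pooled Gaussian mask, padded X_s'W_sz_s); the pooled weighted covariance
is inverted through the masked collaborative-inversion protocol and α_new is
recovered with an encrypted row-row product, then collectively decrypted —
the weights themselves are the only cleartext intermediates, mirroring the
fact that a handful of regression coefficients leaks far less than any
subject-level quantity.

Variant scoring: with the null fit frozen,

    T = G'(y - μ0)                       (score numerator, per variant)
    S = diag(G'WG) - diag(G'WX Υ^{-1} X'WG)   (score variance)

and T²/S is χ²₁ under the null.  T and S are pooled encrypted; T is squared
homomorphically and both T² and S receive the same collectively-pooled
positive multiplicative mask before decryption, so the revealed pair leaks
neither statistic while preserving the ratio exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import matrix as fm
from .collab import (
    SharedSpace,
    SiteContext,
    collective_decrypt_matrix,
    collective_refresh,
    masked_collaborative_inverse,
)
from .errors import ProtocolError, ShapeError
from .matrix import EncryptedMatrix, ExpansionSet, PlainMatrix

MU_CLAMP = 1e-8

#: IRLS defaults: start at zero weights, stop on max|Δα| < tol
IRLS_TOL = 1e-4
IRLS_MAX_EPOCHS = 10


# ---------------------------------------------------------------------------
# cohort container and imputation


@dataclass
class SiteCohort:
    """One site's aligned covariate / phenotype / genotype arrays.

    ``X`` carries the intercept column first; ``y`` is 0/1; ``G`` holds
    dosages in [0, 2] (real-valued after mean imputation).
    """

    X: np.ndarray
    y: np.ndarray
    G: np.ndarray
    variant_ids: List[str] = field(default_factory=list)
    n_missing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ShapeError("phenotype must be binary 0/1")
        if len(self.y) != self.X.shape[0] or len(self.y) != self.G.shape[0]:
            raise ShapeError("X, y, G row counts disagree")
        if not self.variant_ids:
            self.variant_ids = [f"v{j}" for j in range(self.G.shape[1])]
        if self.n_missing is None:
            self.n_missing = np.zeros(self.G.shape[1], dtype=int)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.G.shape[1]

    @classmethod
    def from_dir(cls, path: Path | str) -> "SiteCohort":
        path = Path(path)
        X = pd.read_csv(path / "covars.tsv", sep="\t").to_numpy(dtype=float)
        y = pd.read_csv(path / "pheno.tsv", sep="\t").to_numpy(dtype=float).ravel()
        gdf = pd.read_csv(path / "geno.tsv", sep="\t")
        G, n_missing, dropped = mean_impute(gdf.to_numpy(dtype=float))
        ids = [c for j, c in enumerate(gdf.columns) if j not in dropped]
        G = np.delete(G, list(dropped), axis=1)
        n_missing = np.delete(n_missing, list(dropped))
        return cls(X=X, y=y, G=G, variant_ids=ids, n_missing=n_missing)

    def save(self, path: Path | str) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cov_cols = ["intercept"] + [f"c{j}" for j in range(1, self.p)]
        pd.DataFrame(self.X, columns=cov_cols).to_csv(
            path / "covars.tsv", sep="\t", index=False
        )
        pd.DataFrame({"phenotype": self.y.astype(int)}).to_csv(
            path / "pheno.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.G, columns=self.variant_ids).to_csv(
            path / "geno.tsv", sep="\t", index=False, float_format="%.6g"
        )


def mean_impute(
    G: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, set]:
    """Replace missing dosages by the per-variant mean of observed ones.

    Returns the imputed matrix, per-variant missing counts, and the set of
    column indices that were entirely missing (flagged for exclusion).
    """
    G = np.array(G, dtype=float)
    miss = ~np.isfinite(G)
    n_missing = miss.sum(axis=0)
    dropped = set(np.where(miss.all(axis=0))[0].tolist())
    observed = (~miss).sum(axis=0)
    col_mean = np.where(miss, 0.0, G).sum(axis=0) / np.maximum(observed, 1)
    idx = np.where(miss)
    G[idx] = col_mean[idx[1]]
    return G, n_missing, dropped


# ---------------------------------------------------------------------------
# IRLS local quantities


def sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a, dtype=float)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


@dataclass
class IrlsLocalTerms:
    mu0: np.ndarray
    W: np.ndarray  # diagonal entries
    z: np.ndarray
    Upsilon: np.ndarray  # X'WX, p×p
    XWz: np.ndarray  # p-vector


def irls_local_terms(cohort: SiteCohort, alpha: np.ndarray) -> IrlsLocalTerms:
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.shape[0] != cohort.p:
        raise ShapeError("alpha length must equal the covariate count")
    if not np.all(np.isfinite(alpha)):
        raise ShapeError("alpha must be finite")
    eta = cohort.X @ alpha
    mu = np.clip(sigmoid(eta), MU_CLAMP, 1.0 - MU_CLAMP)
    w = mu * (1.0 - mu)
    z = eta + (cohort.y - mu) / w
    Xw = cohort.X * w[:, None]
    return IrlsLocalTerms(
        mu0=mu,
        W=w,
        z=z,
        Upsilon=cohort.X.T @ Xw,
        XWz=Xw.T @ z,
    )


@dataclass
class NullModelState:
    alpha: np.ndarray
    epoch: int = 0
    converged: bool = False
    encrypted_inverse: Optional[EncryptedMatrix] = None  # pad(Υ^{-1})
    local_terms: Optional[List[IrlsLocalTerms]] = None


# ---------------------------------------------------------------------------
# federated null-model fitting


def _row_vector_view(em: EncryptedMatrix) -> EncryptedMatrix:
    """Reinterpret an encrypted column vector as the transposed row vector
    (identical flat slot layout)."""
    return EncryptedMatrix(rows=1, cols=em.rows * em.cols, blocks=em.blocks)


def null_model_epoch(
    cohorts: Sequence[SiteCohort],
    sites: Sequence[SiteContext],
    space: SharedSpace,
    state: NullModelState,
    tol: float = IRLS_TOL,
) -> NullModelState:
    """One federated IRLS update of the covariate weights."""
    if len(cohorts) != len(sites):
        raise ProtocolError("one cohort per site required")
    p = cohorts[0].p
    if any(c.p != p for c in cohorts):
        raise ProtocolError("covariate count differs across sites")
    P = fm.next_pow2(p)
    terms = [irls_local_terms(c, state.alpha) for c in cohorts]

    tag = f"e{state.epoch}"
    inv_enc = masked_collaborative_inverse(
        [PlainMatrix(t.Upsilon) for t in terms], sites, space, f"{tag}-inv"
    )

    # pool the encrypted padded X'Wz vectors
    rnd = max(ctx.round for ctx in sites) + 1
    for ctx, t in zip(sites, terms):
        ctx.round = rnd
        padded = np.zeros(P)
        padded[:p] = t.XWz
        enc = fm.encrypt_matrix(PlainMatrix(padded[:, None]), ctx.backend)
        space.upload(f"r{rnd}_s{ctx.site_id}_{tag}-xwz.encmat", enc.to_bytes())
    backend = sites[0].backend
    xwz = None
    for ctx in sites:
        em = EncryptedMatrix.from_bytes(
            space.wait_for(f"r{rnd}_s{ctx.site_id}_{tag}-xwz.encmat")
        )
        xwz = em if xwz is None else fm.matrix_add(xwz, em, backend)

    # α_new via row-row product of pad(Υ^{-1}) with the replicated X'Wz row
    re0 = _expand_rows_multiblock(_row_vector_view(xwz), P, backend)
    alpha_enc = fm.row_row_inner(inv_enc, re0, backend)
    alpha_new = collective_decrypt_matrix(
        alpha_enc, sites, space, f"{tag}-alpha"
    ).values.ravel()[:p]

    delta = float(np.max(np.abs(alpha_new - state.alpha)))
    return NullModelState(
        alpha=alpha_new,
        epoch=state.epoch + 1,
        converged=delta < tol,
        encrypted_inverse=inv_enc,
        local_terms=terms,
    )


def fit_null_model(
    cohorts: Sequence[SiteCohort],
    sites: Sequence[SiteContext],
    space: SharedSpace,
    tol: float = IRLS_TOL,
    max_epochs: int = IRLS_MAX_EPOCHS,
) -> NullModelState:
    """Federated IRLS from α = 0 until max|Δα| < tol or the epoch cap."""
    import warnings

    state = NullModelState(alpha=np.zeros(cohorts[0].p))
    while state.epoch < max_epochs:
        state = null_model_epoch(cohorts, sites, space, state, tol=tol)
        if state.converged:
            break
    if not state.converged:
        warnings.warn(
            f"null model did not converge in {max_epochs} epochs "
            "(possible separation)",
            RuntimeWarning,
            stacklevel=2,
        )
    # refresh per-site terms at the final α so scoring uses the fitted null
    state.local_terms = [irls_local_terms(c, state.alpha) for c in cohorts]
    return state


def _expand_rows_multiblock(
    em: EncryptedMatrix, height: int, backend, stats=None
) -> EncryptedMatrix:
    """Row-0 expansion of a single-row encrypted matrix to ``height`` rows,
    possibly spanning several output blocks (all identical tiles)."""
    es = fm.expand_rows_encrypted(em, _pow2_at_least(height), backend, stats=stats)
    first = es.matrices[0]
    needed = fm.n_blocks(height, em.cols, backend.params.slot_size)
    return EncryptedMatrix(
        rows=height, cols=em.cols, blocks=(first.blocks * needed)[:needed]
    )


def _pow2_at_least(x: int) -> int:
    return fm.next_pow2(max(int(x), 1))


# ---------------------------------------------------------------------------
# variant scoring (steps: local encrypted terms, pooling, masking, p-values)


@dataclass
class ScoreStats:
    T: EncryptedMatrix
    S1: EncryptedMatrix
    S21: EncryptedMatrix
    S22: EncryptedMatrix


def score_local_terms(
    cohort: SiteCohort,
    state: NullModelState,
    terms: IrlsLocalTerms,
    ctx: SiteContext,
    sites: Sequence[SiteContext],
    space: SharedSpace,
) -> ScoreStats:
    """One site's encrypted score-test components.

    T_s = G'(y-μ0) and diag(G'WG) are packed M-vectors; G'WX is padded to a
    power-of-two column count and multiplied on the right by the encrypted
    pad(Υ^{-1}) through expansion-based matrix multiplication.
    """
    if state.encrypted_inverse is None:
        raise ProtocolError("null model must be fitted first")
    G, X = cohort.G, cohort.X
    p, M = cohort.p, cohort.m
    P = fm.next_pow2(p)
    backend = ctx.backend

    t_vec = G.T @ (cohort.y - terms.mu0)
    d_vec = np.einsum("ij,i,ij->j", G, terms.W, G)  # diag(G'WG)
    gwx = (G * terms.W[:, None]).T @ X  # M×p
    gwx_pad = np.zeros((M, P))
    gwx_pad[:, :p] = gwx

    T_enc = fm.encrypt_matrix(PlainMatrix(t_vec[:, None]), backend)
    S1_enc = fm.encrypt_matrix(PlainMatrix(d_vec[:, None]), backend)
    S21_enc = fm.encrypt_matrix(PlainMatrix(gwx_pad), backend)

    inv_enc = _ensure_level(
        state.encrypted_inverse, 2, sites, space, f"s{ctx.site_id}-invref"
    )
    re_inv = _rows_of_encrypted(inv_enc, M, backend)
    ce_gwx = fm.expand_columns(PlainMatrix(gwx_pad), P)
    S22_enc = fm.matmul(ce_gwx, re_inv, backend)
    return ScoreStats(T=T_enc, S1=S1_enc, S21=S21_enc, S22=S22_enc)


def _rows_of_encrypted(em: EncryptedMatrix, height: int, backend) -> ExpansionSet:
    """Row expansion of an encrypted P×P matrix to ``height``-row matrices."""
    es = fm.expand_rows_encrypted(em, _pow2_at_least(height), backend)
    needed = fm.n_blocks(height, em.cols, backend.params.slot_size)
    mats = [
        EncryptedMatrix(
            rows=height, cols=em.cols, blocks=(m.blocks * needed)[:needed]
        )
        for m in es.matrices
    ]
    return ExpansionSet(kind="row", matrices=mats)


def _ensure_level(
    em: EncryptedMatrix,
    need: int,
    sites: Sequence[SiteContext],
    space: SharedSpace,
    tag: str,
) -> EncryptedMatrix:
    """Collectively refresh an encrypted matrix when depth runs short."""
    if em.level >= need:
        return em
    return collective_refresh(em, sites, space, f"{tag}-refresh")


@dataclass
class GwasResult:
    table: pd.DataFrame  # variant_id, statistic, p_value, alt_freq, n_missing

    def to_tsv(self, path: Path | str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: Path | str) -> "GwasResult":
        return cls(pd.read_csv(path, sep="\t"))


def chi2_pvalues(stat: np.ndarray) -> np.ndarray:
    """Upper-tail χ²₁ p-values; invalid statistics map to NaN."""
    stat = np.asarray(stat, dtype=float)
    out = np.full(stat.shape, np.nan)
    ok = np.isfinite(stat) & (stat >= 0)
    out[ok] = sps.chi2.sf(stat[ok], df=1)
    return out


def pool_and_finalize(
    cohorts: Sequence[SiteCohort],
    sites: Sequence[SiteContext],
    space: SharedSpace,
    per_site: Sequence[ScoreStats],
) -> GwasResult:
    """Pool encrypted score components, mask, decrypt, and assign p-values.

    S = S1 - ⟨S21, S22⟩_r2r per variant; T is squared homomorphically after
    pooling; per-site positive mask vectors (Uniform(0.5, 1.5)) multiply
    both T² and S, and the pooled masked pair is collectively decrypted, so
    the ratio (and hence the χ²₁ statistic) is exact while the decrypted
    values are uninformative.
    """
    backend = sites[0].backend
    M = cohorts[0].m

    T = _pool([s.T for s in per_site], backend)
    S1 = _pool([s.S1 for s in per_site], backend)
    S21 = _pool([s.S21 for s in per_site], backend)
    S22 = _pool([s.S22 for s in per_site], backend)

    S2 = fm.row_row_inner(S21, S22, backend)
    S = fm.matrix_sub(S1, S2, backend)
    T = _ensure_level(T, 2, sites, space, "T")
    T2 = fm.matrix_mul_elementwise(T, T, backend)
    S = _ensure_level(S, 1, sites, space, "S")
    T2 = _ensure_level(T2, 1, sites, space, "T2")

    # collective positive mask: each site multiplies both statistics by its
    # own vector and uploads; summation makes the effective mask sum_s c_s
    rnd = max(ctx.round for ctx in sites) + 1
    for ctx in sites:
        ctx.round = rnd
        c_s = ctx.rng.uniform(0.5, 1.5, size=M)
        mask = PlainMatrix(c_s[:, None])
        t2m = fm.matrix_mul_elementwise(T2, mask, ctx.backend)
        sm = fm.matrix_mul_elementwise(S, mask, ctx.backend)
        space.upload(f"r{rnd}_s{ctx.site_id}_maskedT2.encmat", t2m.to_bytes())
        space.upload(f"r{rnd}_s{ctx.site_id}_maskedS.encmat", sm.to_bytes())
    t2_pool = _download_pool(sites, space, rnd, "maskedT2", backend)
    s_pool = _download_pool(sites, space, rnd, "maskedS", backend)

    t2_plain = collective_decrypt_matrix(
        t2_pool, sites, space, "final-T2"
    ).values.ravel()
    s_plain = collective_decrypt_matrix(
        s_pool, sites, space, "final-S"
    ).values.ravel()

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = t2_plain / s_plain
    stat[s_plain <= 0] = np.nan  # numerically degenerate variants flagged
    pvals = chi2_pvalues(stat)

    n_total = sum(c.n for c in cohorts)
    alt_freq = sum(c.G.sum(axis=0) for c in cohorts) / (2.0 * n_total)
    n_missing = sum(np.asarray(c.n_missing) for c in cohorts)
    table = pd.DataFrame(
        {
            "variant_id": cohorts[0].variant_ids,
            "statistic": stat,
            "p_value": pvals,
            "alt_freq": alt_freq,
            "n_missing": n_missing,
        }
    )
    return GwasResult(table=table)


def _pool(ems: Sequence[EncryptedMatrix], backend) -> EncryptedMatrix:
    acc = ems[0]
    for em in ems[1:]:
        acc = fm.matrix_add(acc, em, backend)
    return acc


def _download_pool(sites, space, rnd, tag, backend) -> EncryptedMatrix:
    acc = None
    for ctx in sites:
        em = EncryptedMatrix.from_bytes(
            space.wait_for(f"r{rnd}_s{ctx.site_id}_{tag}.encmat")
        )
        acc = em if acc is None else fm.matrix_add(acc, em, backend)
    return acc


def run_secure_gwas(
    cohorts: Sequence[SiteCohort],
    sites: Sequence[SiteContext],
    space: SharedSpace,
    tol: float = IRLS_TOL,
    max_epochs: int = IRLS_MAX_EPOCHS,
) -> Tuple[NullModelState, GwasResult]:
    """Full secure pipeline: null-model fit then variant scoring."""
    _check_variant_alignment(cohorts)
    state = fit_null_model(cohorts, sites, space, tol=tol, max_epochs=max_epochs)
    per_site = [
        score_local_terms(c, state, t, ctx, sites, space)
        for c, t, ctx in zip(cohorts, state.local_terms, sites)
    ]
    result = pool_and_finalize(cohorts, sites, space, per_site)
    return state, result


def _check_variant_alignment(cohorts: Sequence[SiteCohort]) -> None:
    ids = cohorts[0].variant_ids
    for c in cohorts[1:]:
        if c.variant_ids != ids:
            raise ProtocolError("variant sets differ across sites")


# ---------------------------------------------------------------------------
# plaintext reference: identical federated math without encryption


def pooled_irls(
    cohorts: Sequence[SiteCohort],
    tol: float = IRLS_TOL,
    max_epochs: int = IRLS_MAX_EPOCHS,
) -> Tuple[np.ndarray, List[IrlsLocalTerms], bool]:
    """Centralized/pooled IRLS on the union of cohorts (reference oracle)."""
    p = cohorts[0].p
    alpha = np.zeros(p)
    converged = False
    for _ in range(max_epochs):
        terms = [irls_local_terms(c, alpha) for c in cohorts]
        ups = sum(t.Upsilon for t in terms)
        xwz = sum(t.XWz for t in terms)
        alpha_new = np.linalg.solve(ups, xwz)
        delta = float(np.max(np.abs(alpha_new - alpha)))
        alpha = alpha_new
        if delta < tol:
            converged = True
            break
    terms = [irls_local_terms(c, alpha) for c in cohorts]
    return alpha, terms, converged


def plaintext_federated_gwas(
    cohorts: Sequence[SiteCohort],
    tol: float = IRLS_TOL,
    max_epochs: int = IRLS_MAX_EPOCHS,
) -> Tuple[np.ndarray, GwasResult]:
    """The same federated score test computed without any encryption."""
    alpha, terms, _ = pooled_irls(cohorts, tol=tol, max_epochs=max_epochs)
    ups = sum(t.Upsilon for t in terms)
    ups_inv = np.linalg.inv(ups)
    T = np.zeros(cohorts[0].m)
    S1 = np.zeros(cohorts[0].m)
    S21 = np.zeros((cohorts[0].m, cohorts[0].p))
    for c, t in zip(cohorts, terms):
        T += c.G.T @ (c.y - t.mu0)
        S1 += np.einsum("ij,i,ij->j", c.G, t.W, c.G)
        S21 += (c.G * t.W[:, None]).T @ c.X
    S = S1 - np.einsum("ij,jk,ik->i", S21, ups_inv, S21)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = T**2 / S
    stat[S <= 0] = np.nan
    n_total = sum(c.n for c in cohorts)
    table = pd.DataFrame(
        {
            "variant_id": cohorts[0].variant_ids,
            "statistic": stat,
            "p_value": chi2_pvalues(stat),
            "alt_freq": sum(c.G.sum(axis=0) for c in cohorts) / (2.0 * n_total),
            "n_missing": sum(np.asarray(c.n_missing) for c in cohorts),
        }
    )
    return alpha, GwasResult(table=table)
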
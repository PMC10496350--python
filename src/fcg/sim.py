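"""Synthetic multi-site cohorts and plaintext reference analyses.

The generator emulates a three-population collaborative GWAS study design:
per-variant ancestral allele frequencies are drawn uniformly on
(0.05, 0.95), each site's population-specific frequencies come from a
Balding–Nichols Beta distribution parameterized by FST, and genotypes are
independent Binomial(2, p) dosages (no linkage disequilibrium).  Phenotypes
follow a liability construction: 20 causal variants with effects
β ~ Uniform(-0.5, 0.5), a fixed gender effect of 0.1, Gaussian environmental
noise with variance 0.5, and a hard logistic threshold (case iff the linear
predictor is positive; the zero boundary maps to control).  Covariates are
an intercept, gender, and the top principal components of the pooled
standardized genotype matrix, split back per site.

The module also provides the centralized reference analyses used to judge
the secure pipelines: pooled IRLS score tests, per-variant logistic Wald
tests, and squared Spearman rank correlation of p-value vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FcgError
from .gwas import SiteCohort, chi2_pvalues, pooled_irls


@dataclass(frozen=True)
class SimConfig:
    n_sites: int = 3
    subjects_per_site: int = 4800
    n_variants: int = 57_344
    n_causal: int = 20
    beta_range: float = 0.5
    gender_effect: float = 0.1
    env_noise_var: float = 0.5
    n_pcs: int = 8
    fst: float = 0.05
    maf_low: float = 0.05
    maf_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.n_sites < 1 or self.subjects_per_site < 2:
            raise ValueError("need at least one site with two subjects")


@dataclass
class SimTruth:
    causal_indices: np.ndarray
    beta: np.ndarray  # length n_variants, zero off-causal
    gender_effect: float

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "causal_indices": self.causal_indices.tolist(),
                    "beta": self.beta[self.causal_indices].tolist(),
                    "gender_effect": self.gender_effect,
                }
            )
        )


@dataclass
class SimCohortSet:
    cohorts: List[SiteCohort]
    truth: SimTruth
    config: SimConfig

    def save(self, root: Path | str) -> None:
        root = Path(root)
        for s, c in enumerate(self.cohorts, start=1):
            c.save(root / f"site_{s}")
        self.truth.to_json(root / "truth.json")
        (root / "sim_config.json").write_text(json.dumps(asdict(self.config)))


def simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Balding–Nichols genotypes per site; returns (matrices, pop freqs)."""
    p_anc = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_variants)
    k = (1.0 - cfg.fst) / cfg.fst
    p_pop = np.empty((cfg.n_sites, cfg.n_variants))
    genos = []
    for s in range(cfg.n_sites):
        p_s = rng.beta(p_anc * k, (1.0 - p_anc) * k)
        p_s = np.clip(p_s, 1e-6, 1.0 - 1e-6)
        p_pop[s] = p_s
        genos.append(
            rng.binomial(2, p_s, size=(cfg.subjects_per_site, cfg.n_variants)).astype(
                float
            )
        )
    return genos, p_pop


def pc_covariates(
    genotypes: Sequence[np.ndarray], n_pcs: int
) -> List[np.ndarray]:
    """Top principal-component scores of the pooled standardized genotypes,
    split back per site."""
    pooled = np.vstack(genotypes)
    n, m = pooled.shape
    if n_pcs >= min(n, m):
        raise ValueError("n_pcs must be smaller than both dimensions")
    if n_pcs == 0:
        return [np.zeros((g.shape[0], 0)) for g in genotypes]
    freq = pooled.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * freq * (1.0 - freq))
    sd[sd == 0] = 1.0
    Z = (pooled - 2.0 * freq) / sd
    from sklearn.decomposition import PCA

    scores = PCA(
        n_components=n_pcs, svd_solver="auto", random_state=0
    ).fit_transform(Z)
    out, off = [], 0
    for g in genotypes:
        out.append(scores[off : off + g.shape[0]])
        off += g.shape[0]
    return out


def simulate_phenotypes(
    cfg: SimConfig,
    genotypes: Sequence[np.ndarray],
    gender: Sequence[np.ndarray],
    rng: np.random.Generator,
    max_retries: int = 10,
) -> Tuple[List[np.ndarray], SimTruth]:
    """Liability-threshold binary phenotypes with sparse causal effects."""
    for attempt in range(max_retries):
        causal = rng.choice(cfg.n_variants, size=cfg.n_causal, replace=False)
        beta = np.zeros(cfg.n_variants)
        beta[causal] = rng.uniform(-cfg.beta_range, cfg.beta_range, cfg.n_causal)
        ys = []
        ok = True
        for g, sex in zip(genotypes, gender):
            eta = (
                g @ beta
                + cfg.gender_effect * sex
                + rng.normal(0.0, np.sqrt(cfg.env_noise_var), size=g.shape[0])
            )
            y = (eta > 0).astype(float)  # η = 0 maps to control
            if y.min() == y.max():
                ok = False
                break
            ys.append(y)
        if ok:
            if attempt:
                warnings.warn(
                    f"degenerate phenotype draw; regenerated {attempt} time(s)",
                    RuntimeWarning,
                    stacklevel=2,
                )
            return ys, SimTruth(
                causal_indices=np.sort(causal),
                beta=beta,
                gender_effect=cfg.gender_effect,
            )
    raise FcgError("could not simulate a non-degenerate phenotype")


def simulate_cohorts(cfg: SimConfig) -> SimCohortSet:
    """Full study simulation: genotypes, PCs, gender, phenotypes, truth."""
    rng = np.random.default_rng(cfg.seed)
    genos, _ = simulate_genotypes(cfg, rng)
    # deterministic half/half gender split, shuffled per site
    gender = []
    for g in genos:
        n = g.shape[0]
        sex = np.zeros(n)
        sex[n // 2 :] = 1.0
        rng.shuffle(sex)
        gender.append(sex)
    pcs = pc_covariates(genos, cfg.n_pcs)
    ys, truth = simulate_phenotypes(cfg, genos, gender, rng)
    ids = [f"v{j}" for j in range(cfg.n_variants)]
    cohorts = [
        SiteCohort(
            X=np.column_stack([np.ones(g.shape[0]), sex, pc]),
            y=y,
            G=g,
            variant_ids=list(ids),
        )
        for g, sex, pc, y in zip(genos, gender, pcs, ys)
    ]
    return SimCohortSet(cohorts=cohorts, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# centralized reference analyses


def pooled_score_test(cohorts: Sequence[SiteCohort]) -> pd.DataFrame:
    """Centralized GMMAT-style score test on the pooled data."""
    alpha, terms, _ = pooled_irls(cohorts)
    ups_inv = np.linalg.inv(sum(t.Upsilon for t in terms))
    m = cohorts[0].m
    T = np.zeros(m)
    S1 = np.zeros(m)
    S21 = np.zeros((m, cohorts[0].p))
    for c, t in zip(cohorts, terms):
        T += c.G.T @ (c.y - t.mu0)
        S1 += np.einsum("ij,i,ij->j", c.G, t.W, c.G)
        S21 += (c.G * t.W[:, None]).T @ c.X
    S = S1 - np.einsum("ij,jk,ik->i", S21, ups_inv, S21)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = T**2 / S
    stat[S <= 0] = np.nan
    return pd.DataFrame(
        {
            "variant_id": cohorts[0].variant_ids,
            "statistic": stat,
            "p_value": chi2_pvalues(stat),
        }
    )


def pooled_wald_test(cohorts: Sequence[SiteCohort]) -> pd.DataFrame:
    """Per-variant logistic regression Wald test on the pooled data.

    For every variant a logistic model with all covariates plus the genotype
    is refitted by Newton iterations warm-started at the null fit; the
    p-value comes from the Wald statistic of the genotype coefficient.
    Variants whose fit separates or fails to converge get a missing p-value.
    """
    X = np.vstack([c.X for c in cohorts])
    y = np.concatenate([c.y for c in cohorts])
    G = np.vstack([c.G for c in cohorts])
    alpha0, _, _ = pooled_irls(cohorts)
    m = G.shape[1]
    stat = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    start = np.append(alpha0, 0.0)
    for j in range(m):
        Xj = np.column_stack([X, G[:, j]])
        beta = _newton_logistic(Xj, y, start)
        if beta is None:
            continue
        from .gwas import sigmoid

        mu = np.clip(sigmoid(Xj @ beta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        info = Xj.T @ (Xj * w[:, None])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            continue
        se = np.sqrt(cov[-1, -1])
        if not np.isfinite(se) or se <= 0 or abs(beta[-1]) > 20:
            continue
        zst = beta[-1] / se
        stat[j] = zst * zst
        pvals[j] = sps.chi2.sf(stat[j], df=1)
    return pd.DataFrame(
        {
            "variant_id": cohorts[0].variant_ids,
            "statistic": stat,
            "p_value": pvals,
        }
    )


def _newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> Optional[np.ndarray]:
    from .gwas import sigmoid

    beta = start.astype(float).copy()
    for _ in range(max_iter):
        mu = np.clip(sigmoid(X @ beta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return None
        beta += step
        if np.max(np.abs(step)) < tol:
            return beta
        if np.max(np.abs(beta)) > 50:  # separation guard
            return None
    return beta


def spearman_r2(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Squared Spearman rank correlation over finite pairs (ties mid-ranked)."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.all(a[ok] == a[ok][0]) or np.all(b[ok] == b[ok][0]):
        raise ValueError("rank correlation undefined for constant input")
    rho = sps.spearmanr(a[ok], b[ok]).statistic
    return float(rho * rho)
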
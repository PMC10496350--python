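# Methods

## Threat model and overall design

All protocols assume honest-but-curious sites: every participant executes
the agreed steps faithfully but inspects everything it receives. Under this
model the design goal is that nothing a site uploads to the shared space is
informative about another site's subject-level data: uploads are either
ciphertexts under the common public key, AEAD-sealed partial decryptions,
or quantities that were deliberately masked before a collective decryption.
Malicious deviations (wrong shares, skipped masking) are out of scope; they
can corrupt results or decrypt unintended values, which is inherent to
threshold schemes without verifiable computation.

## Key ceremony

The key authority samples a ternary master secret key `msk ∈ {−1,0,1}^n`
and splits it additively: per coefficient, the site order is shuffled, one
random site receives the master coefficient, all non-final sites receive
rounded-Gaussian noise with variance `2^λ_dsk` (`λ_dsk = 20` bits by
default, configurable), and the final site receives the modular complement.
The complement rule makes the reconstruction identity `Σ_s dsk_s ≡ msk
(mod q)` exact by construction, which is the property every collective
decryption relies on; the shuffled order and per-coefficient noise keep any
single share statistically uninformative about `msk`. The public key is
`(pk0, pk1) = (−a·msk + e, a)` with uniform `a` and small Gaussian error.
Relinearization and rotation keys are digit-decomposed key-switching keys
(base `2^12`), one rotation key per power-of-two step; arbitrary rotations
compose from the binary expansion of the step.

Shares are sealed per site with passphrase-derived keys (scrypt KDF) under
an encrypt-then-MAC construction built from HMAC-SHA256 (a counter-mode
keystream plus an authentication tag). The same construction, keyed by the
ceremony's shared 256-bit symmetric key, protects partial decryptions in
transit. The master key is discarded after the ceremony; tests that need a
decryption oracle ask the ceremony to retain it in memory explicitly.

## Ciphertext backends

Both backends expose one contract — encode/encrypt, add/sub, ciphertext and
plaintext multiply, slot rotation, level alignment, partial decryption and
aggregation — and the protocol layer never branches on which one is active.

**ToyCKKS** is a real RLWE/CKKS scheme at desk scale (default degree
n = 1024 in tests; any power of two works). Encoding uses the inverse
canonical embedding over the primitive 2n-th roots of unity with slots
ordered along powers of 5, so the Galois automorphism `X → X^(5^t)` acts as
a left rotation by `t` slots. Encryption is the standard randomized
public-key form `c0 = v·pk0 + m + e0`, `c1 = v·pk1 + e1` with ternary
ephemeral `v` — the textbook simplification `c0 = pk0 + m` is deterministic
and therefore not semantically secure, so it is not used. Ring
multiplication is exact via Kronecker substitution: coefficients are packed
into one large integer at a fixed byte stride, multiplied with CPython's
big-integer arithmetic, unpacked, and folded negacyclically. This needs no
NTT-friendly prime and outperforms schoolbook convolution by a wide margin
in pure Python.

The modulus chain is realized as powers of two: the top modulus is
`2^(Σ bits)` for the configured bit-size vector, and level `l` lives under
`Q_l = 2^(Σbits − (L−l)·scale_bits)`. Rescaling after a multiplication
round-divides both ciphertext polynomials by `2^scale_bits` **and** moves to
the next modulus down. The divisibility `Q_{l−1} | Q_l` is what makes this
correct: the `k·Q_l` ambiguity in a ciphertext maps to a multiple of
`Q_{l−1}` after division, so decryption survives. (A single fixed modulus
cannot support this: RLWE ciphertext polynomials are uniform modulo q, so
dividing them without switching the modulus destroys the plaintext; and
tracking an ever-growing scale without division overflows the modulus after
about two levels.) The multiplicative depth is one less than the length of
the bit-size vector; the default chain `[60, 40×5, 60]` gives depth 6,
which covers one full secure scoring pass without a refresh. The toy scheme
makes no security claims at these parameter sizes — it exists so that the
protocol stack runs against genuine ciphertext arithmetic, noise growth and
rotation keys.

**EmulatedCKKS** stores the slot vector in the clear, injects zero-mean
Gaussian noise of sd `2^−scale_bits` per slot per operation, and enforces
the same level budget and rotation semantics. Partial decryptions are
formed from per-site zero-sum share vectors (magnitude ~2^20, sign-flipped
per ciphertext) plus smudging perturbation, so protocol observables —
approximation error, depth exhaustion, share-like partials, aggregation
contracts — are preserved at plaintext speed. The emulation makes no
confidentiality claim for the ciphertext files themselves; transcript-
privacy tests therefore run on the toy backend.

Smudging: partial decryptions carry rounded-Gaussian noise of variance
`2^smudging_bits` at the ring layer (40 bits by default). With the default
scale `2^40` this perturbs decoded values by about `√n·2^20/2^40`, i.e.
~1e-5 at n = 1024 — far below the 1e-3 comparison tolerance used
throughout, and dominated by the masking applied before any decryption that
could reveal sensitive aggregates. The mapping from ring-layer bits to
decoded perturbation depends on the scale; both knobs are configurable.

## Encrypted matrix algebra

Matrices are flattened row-major into `ceil(a·b/slot)` blocks
(slot = n/2). Rotation-based operations require the column count to be a
power of two dividing the slot size so rows never straddle blocks; callers
pad columns with zeros. The row-row inner product performs one elementwise
product and `log2(b)` accumulation rotations per block, after which every
b-th slot holds a row's inner product; these are masked with a 0/1 selector
(one multiplicative level) and rotated into a compact output vector. Row
expansion of an encrypted matrix isolates each row by selector and tiles it
with `log2(height)` doubling rotations. Both operations report their
accumulation-rotation counts for instrumenting tests.

Multiplicative masks are square Gaussian matrices (almost surely
invertible); a condition-number guard (1e8) regenerates from the next seed.
Scaling helpers multiply a matrix by a recorded factor; pre-scaling
near-zero entries before encrypted products measurably reduces relative
error (tested as a paired comparison), which matters when masked inverses
mix large and small magnitudes.

## Multiparty building blocks

*Collective decryption*: every site uploads AEAD-sealed partial
decryptions for every block; the lowest site id contributes the `c0` term
(a fixed convention — some site must add it exactly once). Aggregation
checks one-partial-per-site and exactly one `c0` inclusion.

*Masked collaborative inversion* of a pooled p×p matrix `Υ = Σ Υ_s`: sites
pool encrypted row expansions of unit-Gaussian masks `H_s` into `H`; each
site multiplies its plaintext `Υ_s` against the encrypted `H` by expansion
products and uploads `Υ_s·H`; the pooled `Υ·H` is collectively decrypted,
inverted in plaintext (`H⁻¹Υ⁻¹`), and the encrypted column expansion of
`pad(H)` is re-applied on the left, yielding the encrypted `pad(Υ⁻¹)`
(padded to the next power of two for later rotation-based use). No site
ever sees `Υ` or `Υ⁻¹` unmasked; the decrypted intermediate is the
Gaussian-masked product only. A condition check on the decrypted masked
matrix raises with reseeding advice instead of silently amplifying noise.

*Collective refresh*: pooled encrypted additive masks are added (levels
align downward for free in a chain of nested moduli), the masked matrix is
collectively decrypted and re-encrypted fresh, and the encrypted mask is
subtracted. The default mask sd (100) is deliberately far above the data
scale of the statistics being refreshed.

## Federated GWAS

The null model is covariate-only logistic regression fitted by federated
IRLS from `α = 0` with the textbook updates `μ = logistic(Xα)`,
`W = μ(1−μ)`, `z = Xα + (y−μ)/W`, `α_new = (X'WX)⁻¹X'Wz`; `μ` is clamped
to `[1e−8, 1−1e−8]` to keep `W` positive. Per epoch, the pooled `X'WX` is
inverted through the masking protocol, the padded `X'Wz` vectors are pooled
encrypted, and `α_new` is recovered as a row-row product of `pad(Υ⁻¹)` with
the replicated `(X'Wz)'` row, then collectively decrypted. The weights are
the only cleartext intermediates: a p-vector of regression coefficients
aggregates thousands of subjects and is treated as safe to reveal, unlike
any subject-level or variant-level quantity. Convergence is
`max|Δα| < 1e−4` with at most 10 epochs; non-convergence (e.g. separation)
warns and proceeds, matching standard GLM practice.

Scoring freezes the final-epoch `μ₀` and `W`. Each site encrypts
`T_s = G'(y−μ₀)` and `diag(G'WG)` as packed M-vectors (the full M×M matrix
`G'WG` is never formed — only its diagonal enters the variance), pads
`G'WX` to a power-of-two column count, and multiplies it by the encrypted
`pad(Υ⁻¹)` with expansion products. After pooling,
`S = S1 − ⟨S21, S22⟩_r2r` per variant.

Masking the decrypted statistics: a single common positive scalar on `T`
and `S` would not survive the squaring the χ²₁ statistic needs
(`(cT)²/(cS) ≠ T²/S`), so the pooled `T` is squared homomorphically first
and the common mask `c = Σ_s c_s`, with per-site vectors
`c_s ~ U(0.5, 1.5)` per variant, multiplies both `T²` and `S`. The site
masks are applied by each site to the encrypted statistics and combined by
summation of the masked vectors, keeping the pooled mask bounded away from
zero; the ratio of the two decrypted vectors is exactly `T²/S`. Variants
whose decrypted `S` is non-positive (numerically degenerate, e.g.
monomorphic) are flagged with missing p-values. Missing genotypes are
mean-imputed per variant within each site before analysis; all-missing
variants are excluded and flagged.

If any encrypted matrix runs out of multiplicative depth mid-protocol
(e.g. a reused `pad(Υ⁻¹)` on a shallow parameter set), a collective refresh
is invoked automatically; with the default depth-6 chain the whole scoring
pass fits without one.

## Meta-analysis

Each site fits its own null model on local data only (same IRLS code with
one site) and computes `T_s` and
`S_s = diag(G'WG) − diag(G'WX(X'WX)⁻¹X'WG)` locally in plaintext — these
summaries never leave the site unencrypted. Combination pools the encrypted
vectors by summation, squares `ΣT` homomorphically, applies the same
common-positive-mask construction as the GWAS finalization, and decrypts
`(ΣT)²/(ΣS)`. Masking before or after pooling commutes for a summed mask;
masking is applied after pooling here. Sites must present identical variant
sets in identical order; covariate harmonization across sites is the
caller's responsibility.

## Simulated cohorts

The generator emulates a three-population collaborative study. Ancestral
allele frequencies are `U(0.05, 0.95)`; population frequencies follow a
Balding–Nichols Beta distribution with parameter F_ST (default 0.05, a
typical between-continental-population value); genotypes are independent
`Binomial(2, p)` dosages with no linkage disequilibrium. Gender is split
50/50 per site and shuffled. Covariates are an intercept, gender, and the
top 8 principal components of the pooled standardized genotype matrix
split back per site — the functional equivalent of projecting study
subjects onto reference-population axes. Phenotypes follow a liability
threshold: `η = Gβ + 0.1·gender + ε` with 20 causal variants,
`β ~ U(−0.5, 0.5)` and `ε ~ N(0, 0.5)` (variance 0.5); `y = 1` iff
`η > 0`, with the measure-zero boundary `η = 0` assigned to controls. A
degenerate all-case/all-control draw is regenerated with fresh randomness
and a warning. The whole cohort set is a pure function of its
configuration, including the seed.

What the simulator does **not** emulate: linkage disequilibrium, realistic
minor-allele-frequency spectra, kinship or cryptic relatedness,
case-control ascertainment, genotyping error. Because the causal model
feeds raw dosages into the liability, the genetic mean shift varies by seed
and realized case fractions range from a few percent to nearly all cases —
a property of the stated design, not a bug. Near-degenerate draws (only a
handful of controls per site) leave per-site null models weakly identified,
which depresses meta-analysis concordance in particular.
Consequently, passing tests demonstrate protocol correctness and
statistical behaviour under idealized population structure, not performance
on real genotype panels.

## Reference analyses and problem sizes

The pooled score test and the per-variant logistic Wald regression
(Newton iterations warm-started at the null fit, separation guarded) serve
as centralized references; concordance is measured as squared Spearman rank
correlation of p-value vectors, ties mid-ranked.

The packaged concordance study runs at 3 sites × 400 subjects and 2048
variants on the emulated backend — sizes chosen so the full stack,
including ~2000 per-variant Wald refits, completes in a few minutes on one
CPU. At this scale the secure-vs-plaintext and secure-vs-Wald correlations
are ≥ 0.999. Meta-analysis concordance is sample-size limited: per-site
null models carry 11 covariates on 400 subjects (sometimes under 50 cases
or controls), and the meta-vs-Wald R² typically ranges about 0.89–0.96
across seeds, dipping lower on near-degenerate case-fraction draws; at
4800 subjects per site the same code measures 0.993. The demo manifest
reports pass/fail verdicts against 0.99/0.97/0.95 thresholds and will
honestly flag the meta route at small sample sizes.

## Numerical choices

* Default encoding scale `2^40`; comparison tolerance 1e-3 absolute in
  backend tests (scale-dependent: looser scales need looser tolerances).
* Centered lift maps residues to `(−q/2, q/2]` before decoding.
* Key-switching digit base `2^12`, keeping switch noise ≈ 3e-5 per slot at
  n = 1024 — an order of magnitude under the comparison tolerance.
* χ²₁ p-values are computed by the survival function; near statistic 0 the
  χ² density diverges, so approximate arithmetic moves p-values there by
  up to ~1e-4 even when the statistic is accurate to 1e-7 — comparisons of
  p-values should exclude a small neighbourhood of zero or compare
  statistics directly.
* The Gaussian-masked inversion mixes magnitudes; on the real backend this
  is the dominant noise source in end-to-end runs (log10 p agreement ~0.1
  at toy scale versus ~1e-5 emulated).

## Known limitations

No bootstrapping or cross-key switching; depth is budgeted per protocol
and restored only by collective refresh. The toy backend's parameters are
not chosen for cryptographic security. Single-process round-robin
orchestration only — the shared-space contract matches a real deployment,
but concurrent multi-process execution is untested. Fixed-effects logistic
null only: no kinship/random effects, no quantitative traits, no dosage
uncertainty.
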
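# fcg — threshold-HE collaborative analysis and federated GWAS

`fcg` is a toolkit for multi-site biomedical studies in which the
collaborating sites are honest-but-curious: every site follows the agreed
protocol but must never see another site's subject-level data. It provides

* **threshold CKKS-style encryption with additive key sharing** — a key
  authority generates one master secret key, splits it into per-site
  additive shares over the ring modulus (the shares sum back to the master
  key entrywise, mod q), publishes a common public key plus relinearization
  and rotation keys, and discards the master key. Decryption then requires a
  *partial decryption* `c1·dsk_s + e_sm (mod q)` from every site, protected
  by large "smudging" noise (40 bits by default) and symmetric encryption in
  transit;
* **slot-packed encrypted matrix algebra** — matrices are flattened
  row-major into ciphertexts of `n/2` slots; products are written as sums of
  elementwise products of column/row expansions,
  `M1·M2 = Σ_i ce_i(M1) ⊙ re_i(M2)`, and per-row inner products
  `⟨A,B⟩_r2r` use one elementwise product plus `log2(b)` shift-and-add
  rotations per ciphertext block;
* **multiparty building blocks** — collective decryption through a shared
  directory, masked collaborative matrix inversion (pool encrypted Gaussian
  masks `H = Σ H_s`, decrypt only `Υ·H`, invert in plaintext, re-apply the
  encrypted mask to obtain `pad(Υ⁻¹)`), and collective ciphertext refresh;
* **federated binary-trait GWAS** — a logistic null model
  `E[y] = logistic(Xα)` fitted by federated IRLS
  (`α_new = (X'WX)⁻¹ X'Wz`, with the pooled weighted covariance inverted
  through the masking protocol), followed by a per-variant score test in the
  two-step GMMAT style: `T = G'(y−μ₀)`,
  `S = diag(G'WG) − diag(G'WX (X'WX)⁻¹ X'WG)`, with `T²/S ~ χ²₁` under the
  null. `T` is squared homomorphically and both `T²` and `S` receive the
  same pooled positive mask before collective decryption, so the revealed
  pair preserves the statistic exactly while hiding both components;
* **secure meta-analysis** — each site computes `T_s, S_s` against its own
  local null model; combination is encrypted summation, masking, and
  collective decryption of `(ΣT)²/(ΣS)`;
* **a Balding–Nichols cohort simulator** — three populations with
  Beta-distributed allele frequencies around ancestral `U(0.05, 0.95)`
  frequencies (F_ST 0.05 by default), binomial dosages, pooled-PC
  covariates, and liability-threshold phenotypes (20 causal variants with
  `β ~ U(−0.5, 0.5)`, gender effect 0.1, environmental noise variance 0.5).

Two interchangeable ciphertext backends implement one contract: `toy_ckks`,
a real single-chain RLWE/CKKS scheme at desk scale (canonical-embedding
encoding, randomized public-key encryption, digit-decomposed
relinearization and Galois rotations, power-of-two modulus chain, smudging
partial decryptions), and `emulated`, plaintext slot vectors with identical
packing, level-budget and rotation semantics plus injected approximation
noise, for large cohorts at plaintext speed. The protocol layer never
branches on the backend, and the test suite runs the same contract against
both.

## Worked example

A self-contained smoke study (2 sites × 50 subjects × 16 variants,
emulated backend) runs the whole stack — simulation, key ceremony, secure
federated GWAS, plaintext federated GWAS, pooled per-variant Wald
regression, secure meta-analysis — and prints a run manifest:

```sh
$ fcg demo --tiny --seed 4
{
 "backend": "emulated",
 "metrics": {
  "r2_secure_vs_plain_federated": 1.0,
  "r2_secure_vs_pooled_wald": 1.0,
  "r2_meta_vs_pooled_wald": 0.9080968858131487,
  "null_model_epochs": 3.0
 },
 "verdicts": {
  "r2_secure_vs_plain_federated": true,
  "r2_secure_vs_pooled_wald": true,
  "r2_meta_vs_pooled_wald": false
 },
 "files_exchanged": 92
}
```

The metrics are squared Spearman rank correlations between per-variant
p-value vectors. `r2_secure_vs_plain_federated = 1.0` says the encrypted
protocol reproduces the unprotected federated computation variant-for-
variant; `r2_secure_vs_pooled_wald` compares the federated score test with
a centralized per-variant logistic Wald regression (the two tests are
asymptotically equivalent, so high concordance is expected);
`r2_meta_vs_pooled_wald` measures how much ranking fidelity survives when
sites share only summary statistics — at smoke-test size the per-site null
models are noisy, so this value sits below the two federated routes (see
`docs/methods.md` for the sample-size dependence). `files_exchanged` counts
the encrypted/masked files that crossed the shared space; nothing else
leaves a site.

Step-by-step workflows are also exposed:

```sh
fcg keygen --sites 3 --out bundle/ --seed 1
fcg simulate --out data/ --seed 1 --sites 3 --subjects-per-site 400 --variants 2048
fcg gwas run --data data/ --bundle bundle/ --shared shared/ --out gwas_results.tsv
fcg meta local-summary --site-dir data/site_1 --out s1.tsv
```

`gwas_results.tsv` has one row per variant: `variant_id`, the masked-ratio
statistic `T²/S`, its χ²₁ p-value, the pooled alternate-allele frequency,
and the number of mean-imputed missing genotypes.

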
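# Methods

## Model

A mutation catalog is a C × n matrix of counts (C = 96 SBS classes or 83
indel classes; n tumors). Each observed mutation is modeled as generated by
one latent mutational process; a process's signature is a multinomial
probability vector over the C classes. Tumor j draws its mutations from a
tumor-specific Dirichlet process DP_j whose base distribution is a shared
parent DP, so processes (signatures) are shared across tumors with
tumor-specific weights. Two hierarchy layouts are supported: two-layer
(root DP over all tumors) and three-layer (a DP per sample group, typically
cancer type, between the root and the tumors; chosen with
`RunConfig.use_groups` when the catalog carries a sample → group map).
The root's base distribution H is a symmetric Dirichlet(1) on the
(C−1)-simplex: uniform over all possible signatures.

### Gibbs sampling in the Chinese restaurant franchise

Integrating out both the DP weights and the signature profiles leaves the
seating arrangement of a Chinese restaurant franchise as the latent state:
mutations are customers at tables of their tumor's restaurant, each table
serves one dish (signature) and is itself a customer of the parent
restaurant, recursively; a new table at the root creates a new dish. Because
H is continuous, dishes coincide with root tables. Given the mutations
currently ascribed to dish k (class counts n_k·), the probability that the
dish emits class c is the Dirichlet-multinomial predictive
(n_kc + 1)/(n_k· + C); a brand-new dish emits uniformly, 1/C.

A sweep removes and reseats every mutation from its full conditional:
existing table t with probability ∝ n_jt · p(c | dish(t)), a new table with
probability ∝ α_j · p(c | parent), where the parent predictive recurses up
the hierarchy and bottoms out at 1/C. Seating at a new table seats a virtual
customer at the parent by the same rule; emptied tables cascade removals
upward. Mutations are visited in a freshly drawn random order each sweep.
This item-level kernel (dish assignments of surviving tables are not
re-sampled directly; they mix through table birth/death) is validated
against exact brute-force enumeration — see *Validation* below.

Each concentration parameter α (one per hierarchy level by default, one per
node optionally) has a Gamma(shape, beta) prior — rate parameterization, so
the prior mean is shape/beta — and is resampled once per sweep with the
standard auxiliary-variable update: per node with n_j customers and t_j
tables, w_j ~ Beta(α+1, n_j), s_j ~ Bernoulli(n_j/(n_j+α)), then
α ~ Gamma(shape + Σt_j − Σs_j, beta − Σlog w_j). Defaults: shape 1, beta 20
for SBS96 and 50 for ID83. Larger beta pulls α toward 0, discouraging
spurious extra signatures; shape 1 / beta 20 has mean 0.05.

### Chains, snapshots, checkpoints

After `burnin` sweeps a snapshot is recorded every `spacing` sweeps until
`n_samples` are collected; a snapshot stores, per dish, the class-count
vector and the per-tumor counts. `n_chains` chains run independently with
seeds `seed + chain_index`, so results are identical whether chains run
serially or in parallel (joblib). Two sampling profiles ship with the
package: `desk_profile()` (4 chains × 20 samples × spacing 10, burn-in 500,
8 initial dishes) for desk-scale cohorts — all continuous testing uses this
profile with ~30 tumors and ~500 mutations per tumor — and
`paper_profile()` (20 × 200 × 100, burn-in 5000) for full-scale cohorts.
Chains checkpoint periodically (pickled state + RNG, versioned; resuming is
bit-for-bit identical to an uninterrupted run). The state initializes by
round-robining mutations over `init_dishes` dishes (default 10) with one
table per (node, dish) path, and α at its prior mean; a dispersed start
speeds early mixing and is reproducible.

## Signature extraction

All non-empty clusters from all snapshots of all chains are pooled
(typically thousands of columns) and grouped by divisive hierarchical
clustering (DIANA) on cosine distance between normalized profiles:
repeatedly split the cluster of largest diameter, seeding the splinter with
the member of maximal average dissimilarity and moving members that are on
average closer to the splinter than to the remainder (ties break to the
lowest column index). A branch stops splitting when its members' mean
cosine similarity to the branch's summed-count profile reaches the
cohesion threshold (default 0.90); stopped branches are the groups. The
cohesion stop rule is this package's tree-cut criterion: it directly
operationalizes "members resemble their group consensus" and is exposed as
a parameter.

A group's signature estimate is its summed class counts normalized to 1;
its support is the fraction of distinct Gibbs samples contributing ≥ 1
member (several members from one sample count once). Groups with support ≥
`support_cutoff` (default 0.9) are retained. Exposures are posterior means
over *all* Gibbs samples — a sample in which the group is absent
contributes zero — with the across-sample standard deviation reported
alongside; averaging over contributing samples only would bias low-support
signatures upward. Groups with > 0.95 of their mass on one mutation class
are flagged `single_class` (such signatures are suspect in SBS data) but
not removed. Diagnostics per signature: per-tumor attributed counts and
proportions (zero-total tumors get proportion 0), the top-5 tumors by
proportion, and a per-Gibbs-sample trace of contributing clusters.

## Downsampling

Spectra whose total exceeds a threshold are rescaled class-wise by
round(c · threshold/total), half-up. Rounding is deterministic by design
(reproducibility; stochastic rounding would add noise without benefit).
Consequences: totals land within C/2 of the threshold, per-class
proportions relative to the target total move by < 1/threshold, counts
never increase, and a second pass changes totals by at most C/2. Default:
threshold 3000 for SBS96; off for ID83, where downsampling hurts accuracy.

## Synthetic data

Per cancer type and signature s the generator holds p_s (presence
probability), mu_s (mean burden among carriers) and size_s (NB dispersion,
variance = mu + mu²/size). A tumor is synthesized by: presence ~
Bernoulli(p_s); burden m_s ~ NB(mu_s, size_s); expected class counts
m_{s,t} = m_s · profile; per-class resampling noise m_{s,t,d} ~
NB(m_{s,t}, d) independently per class (d = ∞ disables noise; NB with mean
0 returns 0 deterministically); the spectrum is the class-wise sum over
signatures, rounded. Noise defaults: d = 30 (SBS96), d = 10 (ID83). Note
that d is a per-class dispersion, so the relative per-class noise floor is
~1/√d regardless of burden — with d = 30 a single-signature spectrum
plateaus near cosine 0.97 to its generating profile. That matches the
variability of real spectra reconstruction and is the reason recovered
signatures are assessed against a 0.1 cosine-distance cutoff rather than
near-exactness.

Parameters can be fitted from a real exposure matrix: p_s is the carrier
fraction; (mu_s, size_s) are maximum-likelihood NB estimates on positive
exposures (mean = sample mean, size by 1-D likelihood maximization over
log size). Signatures with < 3 carriers, or underdispersed exposures, get
size fixed at a large sentinel (10^6, effectively Poisson) — too few points
to estimate dispersion. The generator emulates presence/burden/noise
structure of real cohorts but not inter-signature correlation, subclonal
structure, or sequencing artifacts; passing recovery tests therefore shows
the inference machinery works under realistic noise and burden dispersion,
not that every real-data complication is handled.

A small hand-written example model (2 cancer types, 5 signatures, burdens
100–400, prevalences 0.25–1.0 — the range seen in moderately mutated
cancer types) ships in code (`example_prevalence_model`), as do
`uniform_prevalence_model` and `random_signatures` (sparse Dirichlet(0.15)
profiles, rejection-sampled to a pairwise-cosine bound) for constructing
test beds with controllable separation.

## Assessment

Discovered vs truth matching: cosine-distance matrix, entries > 0.1
replaced by L = 1000 (any value ≫ n · max_distance works; fixed for
determinism), rectangular matrices padded square with L-cost dummies,
Hungarian assignment, L-cost matches discarded. Metrics: PPV = TP/(TP+FP),
TPR = TP/(TP+FN), mean cosine over TP pairs (defined as 0 when TP = 0 so
the composite stays well-defined), composite = their sum (0..3).
`reconstruct_signature` solves min_{w≥0} ‖target − Rw‖₂ by NNLS, with no
penalty on the number of references used, and reports the reconstruction
cosine — the tool for checking whether a putative false positive is a merge
of known signatures.

## Validation

Two independent oracles validate the sampler (`hdpsig.validation`):

* **Exact partition posterior.** For a handful of mutations in one tumor,
  every seating arrangement can be enumerated (set partitions of mutations
  into tables × set partitions of tables into dishes), weighting each by
  the two CRP probabilities and the Dirichlet-multinomial likelihood per
  dish. Long sampler runs at fixed α match these exact dish-partition
  probabilities to < 0.01 absolute error (observed ~2 × 10⁻⁴ at 2 × 10⁵
  sweeps).
* **Concentration posterior by quadrature.** The conditional density of α
  given (n customers, t tables) is known up to normalization
  (prior × αᵗ Γ(α)/Γ(α+n)); chained auxiliary-variable updates match its
  grid-integrated mean and median.

Conservation invariants (every snapshot partitions the catalog's mutations
exactly; grouping re-partitions the pooled counts exactly) are asserted
throughout the test suite, and the Hungarian matcher is checked against
exhaustive permutation on instances up to 5 × 5.

## Numerical choices and degenerate inputs

* Dish predictives are exact rational expressions; no log-space machinery
  is needed because per-item conditionals are small products.
* Deterministic tie-breaking everywhere (first-index argmax in DIANA,
  fixed seeded visit order in sweeps, stable sorts in output ordering).
* Empty tumors (zero mutations) are legal: they simply seat no customers
  and get zero exposures and proportion 0 in diagnostics.
* An extraction in which no group reaches the support cutoff returns an
  empty result with a warning status rather than raising.
* Checkpoints refuse to load across incompatible format versions.
* All randomness flows through per-chain `numpy` Generators seeded from the
  run seed; there is no global RNG state.

## Known limitations

* The item-level Gibbs kernel can mix slowly on very large catalogs or
  nearly-collinear signatures; the desk profile is calibrated for ~10⁴–10⁵
  mutations, and full-scale cohorts should use `paper_profile()` and
  downsampling for SBS data.
* Exposures are posterior means over a multimodal posterior; when two
  retained groups are near-duplicates their exposures can trade off.
* The hierarchy assumes exchangeability of tumors within a level; no
  covariates beyond the optional grouping layer.
* The generator does not model correlated signature co-occurrence (e.g.
  paired APOBEC signatures) or cohort batch effects.
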
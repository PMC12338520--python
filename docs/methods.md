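# Methods

## The inference problem

A fluorosequencing experiment observes `N_r` reads; read `k` is an
intensity matrix `x_k` with one row per dye channel and one column per
imaging timepoint. Peptides that share the same pattern of labeled
positions are indistinguishable and collapse to one *fluorescence string*
`f`; the finite universe `D_F` of strings is determined by the protein set,
the protease and the labeling chemistry. The dye-free null string `f_null`
can never be observed. The goal is the relative abundance vector `p` over
the `N_P` proteins that maximizes the likelihood of the observed reads.

Two hidden variables mediate between proteins and reads: the protein
indicator `I_k` (which protein produced read `k`) and the observable string
`F°_k`. Because proteins differ in how many observable strings they emit,
the indicator distribution `q` is a reweighting of `p`:

    q_y = K · E_F°(y) · p_y ,      E_F°(y) = Σ_peptides (1 − m^{N_d(f_j)}) ,

with `m` the per-dye dud probability and `N_d` the string's ideally labeled
position count. The transform is invertible on the observable support, so
EM is run entirely in indicator space and inverted once at the end.

### Observability factor

The per-string observability weight is `1 − m^{N_d(f)}` — the probability
that at least one dye attached. The alternative reading `(1 − m)^{N_d}`
(all dyes attached) is inconsistent with the null string being unobservable
with certainty (`N_d = 0` must force weight 0), so it is not used.

## EM update

With classifier posteriors `P̂(f | x_k)` computed under a uniform string
prior, the read-wise likelihood normalizer cancels from the update, leaving

    η_{y,k} = Σ_{f ∈ D_F(y)} P̂(f | x_k) · P_F°|I(f | y)
    q'_y    = (1/N_r) Σ_k η_{y,k} q_y / Σ_l η_{l,k} q_l .

Sparse posteriors retain the top `N_b` strings per read (`G_k`) and spread
the residual mass `r_k = (1 − Σ_{G_k} P̂)/|D_F|` uniformly over every
string; `η` then gains the constant floor `r_k` and sums only over
`D_F(y) ∩ G_k`. At `N_b = |D_F|` the sparse update is algebraically the
dense one (`r_k = 0`), which the tests verify to 1e−10 per epoch.

Implementation choices:

* **Initialization** is the uniform indicator vector; any custom indicator
  vector is accepted so the method can refine another estimator's output.
* **Update cadence** is one `q` update per full pass (classic batch EM);
  responsibilities are accumulated over configurable read chunks only to
  bound memory. Partial updates between chunks are deliberately not done.
* **Stopping** is a fixed epoch budget (default 30). MAE against a known
  truth is not monotone in the epoch count, and the likelihood itself is
  too expensive to track at scale, so no tolerance-based stop is offered.
  A guarded brute-force `data_loglikelihood` (capped at `N_r·N_P ≤ 1e6`)
  exists solely so tests can verify the monotone-likelihood guarantee
  numerically.
* **Zeros are absorbing** in `q` (a structural property of the update);
  a read whose weighted evidence vanishes for every protein raises an
  error naming the read rather than being dropped — it indicates a
  model/posterior mismatch.
* MAE is computed in protein space, after the inverse reweighting.

## Read simulator

The generative model per molecule of string `f`:

1. each dye is independently a dud with probability `p_dud`; molecules
   whose dyes are all duds are rejected and resampled (the observability
   conditioning — rejections are counted and reported);
2. with `p_block_init` the molecule starts blocked (Edman cannot proceed);
3. an initial image is recorded;
4. per cycle, in this fixed order: surface detachment (`p_detach`, all
   dyes vanish permanently) → Edman removal (succeeds with
   `1 − p_edman_fail` unless blocked; deletes the dye at the removed
   position) → cyclic blocking (`p_block_cyclic`) → per-dye bleaching
   (`p_bleach`) → image.

The within-cycle event order is not dictated by the chemistry description;
it is fixed as above and the per-cycle marginal rates of every channel are
tested against the configured parameters. Images follow the independent
emitter model: `c` active dyes in one channel emit
`Normal(c·mu, sqrt(c)·sigma)` plus channel background `Normal(0, sigma_bg)`
— the square-root scaling (variances add) is an assumption, as only the
single-dye intensity moments are specified. The pre-Edman image is included
by default and configurable off.

Default parameters are the standard five-protein simulation settings:
11 cycles, `p_edman_fail 0.06`, `p_detach 0.05`, `p_bleach 0.05`,
`p_dud 0.07`, blocking 0, `mu 10000`, `sigma 1600`, `sigma_bg 66.7`; the
reduced-error whole-proteome variant (39 cycles, failure rates ÷100,
`sigma 160`) ships as `IMPROVED_ERROR`.

Reproducibility: one root seed; string draws and per-string simulation
batches use spawned child streams keyed by string index, so a dataset is
byte-identical for fixed seed and inputs regardless of batching. Dataset
generation can skip intensity simulation entirely when only the generating
strings are needed (oracle-classifier experiments), and supports a
shared-pool mode (pre-simulate `pool_size` reads per string, sample with
replacement) matching the shared-dataset protocol of the benchmark design.

## Classifiers

* **Oracle**: `P̂(f|x_k) = (1−e)·[f = f_true] + e/|D_F|`. At `e = 0` it is
  the perfect classifier used for upper-bound analyses; drawing a call from
  the posterior hits the truth with probability `(1−e) + e/|D_F|`.
* **Exact Bayes**: the marginal likelihood `P(x_k | f)` is computed for
  every candidate string by a forward recursion over the hidden state
  (residues removed so far × alive-dye mask, with detachment collapsed
  into an absorbing dark state), then normalized across strings under a
  uniform prior. Dud conditioning mirrors the simulator's rejection step.
  Blocking is *not* modeled (simulator defaults keep it at 0), matching
  the practical peptide classifiers this stands in for. The recursion runs
  in log space with per-read max shifts, so widely separated Gaussian
  densities cannot underflow; a brute-force enumeration over all hidden
  event sequences validates it to 1e−8 on every ≤2-dye, ≤3-cycle
  configuration in the test grid. The state space is capped at 4096 states
  (~12 dyes); beyond that a capacity error advises pruning.
* **Sparsification** keeps the `N_b` highest-posterior strings (ties to
  the lower index) and spreads the remainder uniformly; it is exactly
  mass-preserving and idempotent at fixed `N_b`.

## Synthetic proteins

`synthetic_proteins` concatenates random tryptic segments (12 residues
ending in K/R, never followed by P, drawn from the standard alphabet minus
K/R/P) so digestion recovers the segments exactly; D/E/C/Y occur at their
uniform alphabet rate (~23%), giving a realistic mixture of 0–4-dye
peptides and, at five proteins, a ~40-string universe. What the generator
does *not* emulate: real amino-acid composition biases, missed cleavages,
post-translational modifications, shared peptides between homologous
proteins at their natural rate, and image-level artifacts. A green
recovery test therefore establishes correctness of the inference machinery
under the stated error model, not performance on any particular real
proteome.

The labeling scheme (D/E, C, Y on three channels) is itself a convention
choice — the benchmark experiments that motivated this package do not pin
it down — so absolute classification accuracies depend on it; all
structural claims (monotone likelihood, sparse/dense equivalence,
sensitivity shapes) are invariant to it.

## Numerical notes

* Simplex tolerances: abundance vectors validate to 1e−9; conditional
  model rows to 1e−12; round-trip `p → q → p` is exact to 1e−9.
* Posterior ties break to the lower string index everywhere (sorting is
  stable), which affects nothing statistically but makes runs replayable.
* Probabilities serialize with 17 significant digits; model JSON is
  deterministic, so identical inputs give byte-identical model files.
* Degenerate inputs: all abundance mass on unobservable proteins, indicator
  mass on a zero-yield protein, `f_null` as a read source, and universe
  mismatches all raise typed errors rather than propagating NaNs.

## Known limitations

* The exact classifier is exponential in the per-string dye count (capped
  at 4096 hidden states) and linear in `|D_F|`; it is a desk-scale
  reference, not a production classifier.
* Whole-proteome scale (2×10⁴ proteins, 10⁷ reads) is supported by the
  algorithmic sparsity but not exercised at full size in the tests; a
  200-protein, 10⁵-read smoke run stands in.
* Blocking is simulated but unmodeled by the classifier; with nonzero
  blocking rates the "exact" posterior is exact only for the unblocked
  generative process.
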
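# fluorem

Expectation-maximization inference of relative protein abundances from
single-molecule fluorosequencing reads.

Fluorosequencing labels specific amino acids (by default D/E, C and Y, one
dye color each) on tryptic peptides, immobilizes the peptides in a flow
cell, and removes one N-terminal residue per Edman cycle while imaging the
fluorescence in each channel. A read is therefore a channels × timepoints
intensity matrix whose staircase of intensity drops carries partial sequence
information. Peptide-level classifiers turn each read into a posterior over
*fluorescence strings* — the equivalence classes of peptides sharing one
labeled-position pattern. `fluorem` closes the remaining gap: it converts
those per-read string posteriors into maximum-likelihood estimates of the
relative abundance of each protein in the sample.

## Model

Let `p_y` be the relative abundance of protein `y` (the estimation target)
and `E_F°(y)` the expected number of experimentally observable fluorescence
strings protein `y` emits per molecule (a string with `N_d` ideally labeled
residues survives per-dye dud failures with probability `1 − m^N_d`). The
hidden per-read protein indicator `I_k` then has distribution

    q_y ∝ E_F°(y) · p_y ,

and each read contributes the evidence weight

    η_{y,k} = r_k + Σ_{f ∈ D_F(y) ∩ G_k}  P̂(f | x_k) · P_F°|I(f | y) ,

where `G_k` is the read's retained top-`N_b` posterior set, `r_k` its
uniformly spread residual mass, and `P_F°|I(f|y)` the protein's conditional
string distribution. EM iterates

    q'_y = (1/N_r) Σ_k  η_{y,k} q_y / Σ_l η_{l,k} q_l ,

which provably never decreases the data likelihood, and finally inverts the
observability reweighting (`p_y ∝ q_y / E_F°(y)`) to report abundances.

The package also ships a full generative read simulator (duds, Edman
failure, detachment, bleaching, blocking, Gaussian intensity noise), an
oracle classifier with tunable error rate for upper-bound analyses, and an
exact Bayes HMM classifier that computes each read's marginal likelihood
under the simulator's own generative process.

## Worked example

```python
import numpy as np
import fluorem as fl
from fluorem.benchmark import oracle_em_run, uniform_baseline_mae

proteins = fl.synthetic_proteins(5, seed=1)       # 5 tryptic-style proteins
model = fl.build_model(proteins, m=0.07)          # 7% per-dye dud rate
print(f"universe: {model.n_strings} fluorescence strings, "
      f"E_Fo = {np.round(model.e_fo, 2)}")

p_true = fl.sample_abundances(5, seed=7)          # normalized exponentials
trace = oracle_em_run(model, p_true, n_reads=100_000, e=0.0,
                      epochs=30, seed=7)          # perfect-classifier EM
print(f"true abundances: {np.round(p_true.values, 4)}")
print(f"estimated:       {np.round(trace.p_hat.values, 4)}")
print(f"final MAE {trace.final_mae:.2e} "
      f"(uniform guess: {uniform_baseline_mae(p_true):.2e})")
```

prints

```
universe: 40 fluorescence strings, E_Fo = [7.78 6.85 7.92 7.78 7.98]
true abundances: [0.2079 0.3013 0.1671 0.263  0.0607]
estimated:       [0.2072 0.3012 0.1676 0.2631 0.0609]
final MAE 3.21e-04 (uniform guess: 6.89e-02)
```

The five synthetic proteins generate 40 distinct observable fluorescence
strings; 100 000 reads classified by an error-free oracle let 30 EM epochs
recover the abundances roughly 200× more accurately than the
uniform-abundance baseline.

## Command line

```
fluorem build-model --fasta proteins.fasta --out model.json
fluorem simulate    --model model.json --n-reads 100000 --seed 1 --out-prefix sim/run
fluorem classify    --model model.json --method oracle --truth sim/run.truth.tsv \
                    --oracle-error 0.0 --top-nb 40 --out post.tsv
fluorem infer       --post post.tsv --model model.json --epochs 30 --out est/run
fluorem benchmark   --out-prefix bench/run          # oracle + exact sweeps
```

All formats are plain TSV/JSON; every command writes a manifest with the
seeds and configuration needed to replay it bit-identically.

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference quantities from
scratch — the two-protein indicator-distribution worked example, through
the forward and inverse observability transforms — and writes them to JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
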
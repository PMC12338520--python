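"""End-to-end experiment drivers at the five-protein scale.

These reproduce the shape of the small-mixture experiments: ten datasets
with independently sampled true abundances, a shared proteome model, oracle
and exact-Bayes classification, EM inference, and MAE summaries against the
uniform-abundance baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifiers import PosteriorBatch, exact_posterior_batch
from .em_inference import EMTrace, mae, run_em, top1_accuracy
from .proteome_model import AbundanceVector, ProteomeModel, build_model
from .read_simulator import (
    ErrorModel,
    generate_dataset,
    sample_abundances,
    synthetic_proteins,
)


def uniform_baseline_mae(p_true: AbundanceVector) -> float:
    """MAE of the uniform-abundance guess against the truth."""
    n = len(p_true)
    uniform = AbundanceVector(np.full(n, 1.0 / n), "protein")
    return mae(uniform, p_true)


def oracle_em_run(
    model: ProteomeModel,
    p_true: AbundanceVector,
    n_reads: int,
    e: float,
    epochs: int,
    seed: int,
    n_b: int | None = None,
    em: ErrorModel | None = None,
) -> EMTrace:
    """Simulate true strings, classify with an error-``e`` oracle, run EM.

    Oracle posteriors depend only on the generating string, so intensity
    simulation is skipped.  ``n_b`` defaults to the full universe (dense
    oracle posterior).
    """
    em = em or ErrorModel()
    ds = generate_dataset(
        model, p_true, n_reads, em, seed, simulate_intensities=False
    )
    n_b = model.n_strings if n_b is None else n_b
    batch = PosteriorBatch.from_oracle(ds.true_strings, e, model.n_strings, n_b)
    return run_em(batch, model, epochs=epochs, truth=p_true)


def exact_em_run(
    model: ProteomeModel,
    p_true: AbundanceVector,
    n_reads: int,
    epochs: int,
    seed: int,
    n_b: int | None = None,
    em: ErrorModel | None = None,
) -> tuple[EMTrace, float]:
    """Simulate reads, classify with the exact Bayes HMM, run EM.

    Returns the EM trace and the classifier's top-1 accuracy.
    """
    em = em or ErrorModel()
    ds = generate_dataset(model, p_true, n_reads, em, seed)
    reads = np.stack([r.intensities for r in ds.reads])
    dense = exact_posterior_batch(reads, model, em)
    n_b = model.n_strings if n_b is None else n_b
    batch = PosteriorBatch.from_dense(dense, n_b)
    acc = top1_accuracy(dense, ds.true_strings)
    trace = run_em(batch, model, epochs=epochs, truth=p_true)
    return trace, acc


def five_protein_benchmark(
    fasta: str | None = None,
    n_datasets: int = 10,
    n_reads: int = 100_000,
    n_reads_exact: int = 2_000,
    epochs: int = 30,
    seed: int = 0,
    oracle_errors: tuple[float, ...] = (0.0, 0.2, 0.5),
    sparse_nb: int = 40,
) -> pd.DataFrame:
    """Oracle sweep plus full and sparse exact-Bayes runs over datasets.

    The exact classifier runs on ``n_reads_exact`` reads (forward passes
    over every candidate string are the bottleneck); oracle runs use the
    full ``n_reads``.  Returns one tidy row per (method, dataset).
    """
    if fasta is None:
        proteins = synthetic_proteins(n_proteins=5, seed=seed)
    else:
        from .cli_io import read_fasta

        proteins = read_fasta(fasta)
    em = ErrorModel()
    model = build_model(proteins, m=em.p_dud)
    rows = []
    for d in range(n_datasets):
        p_true = sample_abundances(model.n_proteins, seed * 1009 + d)
        base = uniform_baseline_mae(p_true)
        for e in oracle_errors:
            trace = oracle_em_run(
                model, p_true, n_reads, e, epochs, seed * 7919 + d, em=em
            )
            rows.append(
                {
                    "method": f"oracle_e{e}",
                    "dataset": d,
                    "final_mae": trace.final_mae,
                    "uniform_mae": base,
                    "top1_accuracy": np.nan,
                }
            )
        for label, n_b in (("exact_full", None), (f"exact_nb{sparse_nb}", sparse_nb)):
            trace, acc = exact_em_run(
                model, p_true, n_reads_exact, epochs, seed * 7919 + d, n_b=n_b, em=em
            )
            rows.append(
                {
                    "method": label,
                    "dataset": d,
                    "final_mae": trace.final_mae,
                    "uniform_mae": base,
                    "top1_accuracy": acc,
                }
            )
    return pd.DataFrame(rows)
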
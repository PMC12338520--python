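"""Expectation-maximization over the protein indicator distribution.

Each read ``k`` contributes a per-protein evidence weight

    η_{y,k} = r_k + Σ_{f ∈ D_F(y) ∩ G_k}  P̂(f | x_k) · P_F°|I(f | y),

the sparse posterior's retained strings intersected with the protein's own
string support, floored by the uniform residual ``r_k``.  The M-step is the
classic mixture update

    q'_y = (1/N_r) Σ_k  η_{y,k} q_y / Σ_l η_{l,k} q_l ,

which never decreases the data likelihood; with a dense posterior
(``r_k = 0``, all strings retained) the sparse form reduces exactly to the
dense one.  After the final epoch the indicator estimate is mapped back to
protein space by the inverse observability reweighting, and accuracy is
reported as the mean absolute error between abundance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .classifiers import PosteriorBatch, SparsePosterior
from .errors import CapacityError, ConfigurationError, DegenerateInputError, InconsistencyError
from .proteome_model import AbundanceVector, ProteomeModel, indicator_to_protein

_DENSE_GUARD = 10**6  # N_r * N_P cap for the brute-force likelihood oracle


# ---------------------------------------------------------------------------
# η computation (E-step evidence weights)
# ---------------------------------------------------------------------------


def compute_eta(
    posterior: SparsePosterior | PosteriorBatch, model: ProteomeModel
) -> np.ndarray:
    """Evidence weights ``η_{y,k}`` for one sparse posterior or a batch.

    Returns a (n_proteins,) vector for a single posterior, or a
    (n_reads, n_proteins) matrix for a batch.  Proteins whose support does
    not meet the retained set carry exactly the floor ``r_k``.
    """
    single = isinstance(posterior, SparsePosterior)
    batch = (
        PosteriorBatch.from_sparse_list([posterior]) if single else posterior
    )
    if batch.n_strings != model.n_strings:
        raise InconsistencyError(
            f"posterior universe ({batch.n_strings} strings) does not match "
            f"model ({model.n_strings})"
        )
    eta = _eta_matrix(batch, model)
    return eta[0] if single else eta


def _eta_matrix(batch: PosteriorBatch, model: ProteomeModel) -> np.ndarray:
    n, width = batch.indices.shape
    rows = np.repeat(np.arange(n), width)
    S = sp.csr_matrix(
        (batch.probs.ravel(), (rows, batch.indices.ravel())),
        shape=(n, model.n_strings),
    )
    eta = np.asarray((S @ model.cond_FI.T).todense())
    eta += batch.residuals[:, None]
    return eta


# ---------------------------------------------------------------------------
# EM updates
# ---------------------------------------------------------------------------


def em_step(
    q: AbundanceVector, etas: np.ndarray, n_reads: int | None = None
) -> AbundanceVector:
    """One M-step from the (n_reads, n_proteins) evidence matrix.

    Zeros of ``q`` are absorbing; a read whose weighted evidence vanishes
    entirely signals a model/posterior mismatch and aborts.
    """
    if q.space != "indicator":
        raise InconsistencyError("em_step operates in indicator space")
    etas = np.atleast_2d(np.asarray(etas, dtype=np.float64))
    if etas.shape[1] != len(q):
        raise InconsistencyError("eta/abundance length mismatch")
    if n_reads is None:
        n_reads = etas.shape[0]
    if n_reads < 1:
        raise ConfigurationError("at least one read required")
    w = etas * q.values[None, :]
    denom = w.sum(axis=1)
    dead = np.flatnonzero(denom == 0)
    if dead.size:
        raise DegenerateInputError(
            f"read {dead[0]} has zero weighted evidence for every protein"
        )
    q_new = (w / denom[:, None]).sum(axis=0) / n_reads
    return AbundanceVector(q_new / q_new.sum(), "indicator")


@dataclass
class EMTrace:
    """Per-epoch snapshots of an EM run."""

    q_hats: list[AbundanceVector] = field(default_factory=list)
    p_hats: list[AbundanceVector] = field(default_factory=list)
    maes: list[float] = field(default_factory=list)
    epochs: int = 0
    batch_size: int = 0

    @property
    def q_hat(self) -> AbundanceVector:
        return self.q_hats[-1]

    @property
    def p_hat(self) -> AbundanceVector:
        return self.p_hats[-1]

    @property
    def final_mae(self) -> float:
        return self.maes[-1]


def run_em(
    posteriors: list[SparsePosterior] | PosteriorBatch,
    model: ProteomeModel,
    epochs: int = 30,
    init: AbundanceVector | str = "uniform",
    truth: AbundanceVector | None = None,
    batch_size: int = 100_000,
) -> EMTrace:
    """Batch EM: one indicator update per full pass over the reads.

    Responsibilities are accumulated over ``batch_size``-read chunks (the η
    matrix of a chunk is materialized densely), and ``q`` is updated once
    per epoch.  The trace records the indicator and protein estimates after
    every epoch, plus the MAE against ``truth`` when given.
    """
    if epochs < 1:
        raise ConfigurationError("epochs must be >= 1")
    if isinstance(posteriors, list):
        if not posteriors:
            raise ConfigurationError("empty posterior stream")
        posteriors = PosteriorBatch.from_sparse_list(posteriors)
    if posteriors.n_reads < 1:
        raise ConfigurationError("empty posterior stream")
    if isinstance(init, str):
        if init != "uniform":
            raise ConfigurationError(f"unknown init {init!r}")
        q = AbundanceVector(
            np.full(model.n_proteins, 1.0 / model.n_proteins), "indicator"
        )
    else:
        if init.space != "indicator":
            raise InconsistencyError("init must live in indicator space")
        q = init

    n = posteriors.n_reads
    chunks = [
        PosteriorBatch(
            posteriors.indices[a : a + batch_size],
            posteriors.probs[a : a + batch_size],
            posteriors.residuals[a : a + batch_size],
            posteriors.n_strings,
        )
        for a in range(0, n, batch_size)
    ]
    etas = [_eta_matrix(c, model) for c in chunks]

    trace = EMTrace(epochs=epochs, batch_size=batch_size)
    for _ in range(epochs):
        acc = np.zeros(model.n_proteins)
        offset = 0
        for eta in etas:
            w = eta * q.values[None, :]
            denom = w.sum(axis=1)
            dead = np.flatnonzero(denom == 0)
            if dead.size:
                raise DegenerateInputError(
                    f"read {offset + dead[0]} has zero weighted evidence "
                    "for every protein"
                )
            acc += (w / denom[:, None]).sum(axis=0)
            offset += eta.shape[0]
        q = AbundanceVector(acc / acc.sum(), "indicator")
        p = indicator_to_protein(q, model)
        trace.q_hats.append(q)
        trace.p_hats.append(p)
        if truth is not None:
            trace.maes.append(mae(p, truth))
    return trace


# ---------------------------------------------------------------------------
# Brute-force likelihood oracle and metrics
# ---------------------------------------------------------------------------


def data_loglikelihood(
    q: AbundanceVector,
    posteriors: np.ndarray | None,
    model: ProteomeModel | None = None,
    etas: np.ndarray | None = None,
) -> float:
    """Relative data log-likelihood ``Σ_k log Σ_y η_{y,k} q_y``.

    A small-instance oracle (guarded at ``N_r · N_P ≤ 10^6``) for verifying
    the monotone-likelihood guarantee of the EM update; the read-wise
    classifier normalizer is omitted, so only differences are meaningful.
    Dense posteriors only; precomputed ``etas`` may be passed directly.
    """
    if etas is None:
        if posteriors is None or model is None:
            raise ConfigurationError("need dense posteriors + model, or etas")
        posteriors = np.atleast_2d(np.asarray(posteriors, dtype=np.float64))
        etas = np.asarray(posteriors @ model.cond_FI.T.todense())
    etas = np.atleast_2d(np.asarray(etas, dtype=np.float64))
    if etas.shape[0] * etas.shape[1] > _DENSE_GUARD:
        raise CapacityError(
            "data_loglikelihood is a small-instance oracle "
            f"(N_r * N_P <= {_DENSE_GUARD})"
        )
    if etas.shape[1] != len(q):
        raise InconsistencyError("eta/abundance length mismatch")
    per_read = etas @ q.values
    if np.any(per_read <= 0):
        return -np.inf
    return float(np.log(per_read).sum())


def mae(p_hat: AbundanceVector, p_true: AbundanceVector) -> float:
    """Mean absolute error ``(1/N_P) Σ_y |p̂_y − p_y|`` between abundance
    vectors of the same space."""
    if len(p_hat) != len(p_true):
        raise InconsistencyError("abundance length mismatch")
    return float(np.mean(np.abs(p_hat.values - p_true.values)))


def top1_accuracy(
    posteriors: list[SparsePosterior] | PosteriorBatch | np.ndarray,
    truth: np.ndarray,
) -> float:
    """Fraction of reads whose highest-posterior string (ties → lowest
    index) is the generating one."""
    truth = np.asarray(truth, dtype=np.int64)
    if isinstance(posteriors, list):
        posteriors = PosteriorBatch.from_sparse_list(posteriors)
    if isinstance(posteriors, PosteriorBatch):
        if posteriors.n_reads != truth.size:
            raise InconsistencyError("posterior/truth length mismatch")
        # retained entries dominate the flat residual; ties -> lowest index
        rowmax = posteriors.probs.max(axis=1, keepdims=True)
        tied = posteriors.probs == rowmax
        calls = np.where(tied, posteriors.indices, posteriors.n_strings).min(
            axis=1
        )
        # zero retained mass: every string ties at the residual
        calls = np.where(rowmax.ravel() > 0, calls, 0)
    else:
        dense = np.atleast_2d(np.asarray(posteriors))
        if dense.shape[0] != truth.size:
            raise InconsistencyError("posterior/truth length mismatch")
        calls = np.argmax(dense, axis=1)
    return float(np.mean(calls == truth))
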
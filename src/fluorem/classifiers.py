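"""Per-read posterior estimates over fluorescence strings.

Three estimators are provided:

* an *oracle* that knows the generating string of each simulated read and
  mislabels it with a configurable error rate ``e`` — the analytical
  upper-bound classifier;
* an *exact Bayes* classifier: the marginal likelihood of a read under the
  simulator's own generative process is computed for every candidate string
  by a forward recursion over the hidden degradation state, and combined
  with a uniform prior over strings.  This is the Bayes-optimal reference
  the abundance-inference framework assumes of a peptide classifier (the
  role filled by beam-search or kNN+HMM tools in practice); blocking is not
  modeled, matching those tools;
* *sparsification*: truncation of a dense posterior to its top ``N_b``
  strings, with the left-over mass spread uniformly over the whole universe
  as a per-string residual ``r_k``.

Hidden state of the forward recursion: number of residues removed so far
and the alive/dead status of each dye (dud, bleached and Edman-removed dyes
are indistinguishable in their effect), with surface detachment collapsed
into the absorbing all-dark state.  Emissions are Gaussian per channel:
``c`` active dyes emit ``Normal(c·mu, c·sigma² + sigma_bg²)`` including
background.  The likelihood conditions on at least one non-dud dye,
mirroring the simulator's rejection of invisible molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import CapacityError, ConfigurationError, InconsistencyError
from .proteome_model import FluorescenceString, ProteomeModel
from .read_simulator import ErrorModel, Read

#: Largest hidden-state space the exact classifier will enumerate.
MAX_HMM_STATES = 4096

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Oracle
# ---------------------------------------------------------------------------


def oracle_posterior(true_string: int, e: float, n_strings: int) -> np.ndarray:
    """Posterior of an oracle with error rate ``e``: mass ``1−e`` on the
    true string plus ``e`` spread uniformly over all ``|D_F|`` strings."""
    if not 0 <= e <= 1:
        raise ConfigurationError(f"oracle error rate e={e} outside [0, 1]")
    if not 0 <= true_string < n_strings:
        raise ConfigurationError("true string index out of range")
    post = np.full(n_strings, e / n_strings)
    post[true_string] += 1.0 - e
    return post


# ---------------------------------------------------------------------------
# Exact Bayes classifier (forward algorithm over the degradation HMM)
# ---------------------------------------------------------------------------


class _StringHMM:
    """Enumerated hidden-state machine for one fluorescence string."""

    def __init__(self, f: FluorescenceString, em: ErrorModel, n_channels: int):
        positions = np.array(f.dye_positions, dtype=np.int64)
        channels = np.array(f.dye_channels, dtype=np.int64)
        nd = positions.size
        if nd == 0:
            raise ConfigurationError("f_null has no generative model")
        max_pos = int(positions.max())
        if 2**nd > MAX_HMM_STATES:
            raise CapacityError(
                f"string with {nd} dyes exceeds the {MAX_HMM_STATES}-state "
                "cap; prune the string universe or reduce dye counts"
            )

        # State 0 is the absorbing dark state (detached, or all dyes dead).
        # Other states: (residues removed e, non-empty alive mask over dyes
        # whose position has not yet been degraded).
        states: list[tuple[int, int]] = [(-1, 0)]
        index: dict[tuple[int, int], int] = {(-1, 0): 0}
        for e in range(max_pos + 1):
            live = [i for i in range(nd) if positions[i] >= e]
            for r in range(1, len(live) + 1):
                for combo in combinations(live, r):
                    mask = 0
                    for i in combo:
                        mask |= 1 << i
                    index[(e, mask)] = len(states)
                    states.append((e, mask))
            if len(states) > MAX_HMM_STATES:
                raise CapacityError(
                    f"HMM state space exceeds {MAX_HMM_STATES}; prune the "
                    "string universe or reduce dye counts"
                )
        self.n_states = len(states)
        self.states = states

        # Per-state active-dye counts per channel (dark state: all zero).
        counts = np.zeros((self.n_states, n_channels), dtype=np.int64)
        for s, (e, mask) in enumerate(states):
            for i in range(nd):
                if mask >> i & 1:
                    counts[s, channels[i]] += 1
        self.counts = counts

        # Initial distribution: i.i.d. duds conditioned on >= 1 alive dye.
        init = np.zeros(self.n_states)
        norm = 1.0 - em.p_dud**nd
        full = (1 << nd) - 1
        for mask in range(1, full + 1):
            k = bin(mask).count("1")
            init[index[(0, mask)]] = (
                (1 - em.p_dud) ** k * em.p_dud ** (nd - k) / norm
            )
        self.init = init

        # One-cycle transition matrix: detach -> dark; else Edman advance
        # with 1 − p_edman_fail (deleting the dye at the removed position);
        # then independent bleaching of the survivors.
        T = np.zeros((self.n_states, self.n_states))
        T[0, 0] = 1.0
        pb = em.p_bleach
        for s, (e, mask) in enumerate(states):
            if s == 0:
                continue
            T[s, 0] += em.p_detach
            stay = 1.0 - em.p_detach
            for p_ed, e2 in (
                (1.0 - em.p_edman_fail, e + 1),
                (em.p_edman_fail, e),
            ):
                if p_ed == 0.0:
                    continue
                mask2 = mask
                if e2 > e:  # the residue at position e was removed
                    for i in range(nd):
                        if positions[i] == e and mask >> i & 1:
                            mask2 &= ~(1 << i)
                live = [i for i in range(nd) if mask2 >> i & 1]
                # enumerate bleach outcomes over the surviving dyes
                for sub in range(1 << len(live)):
                    mask3 = 0
                    kept = 0
                    for j, i in enumerate(live):
                        if sub >> j & 1:
                            mask3 |= 1 << i
                            kept += 1
                    p_bl = (1 - pb) ** kept * pb ** (len(live) - kept)
                    if p_bl == 0.0:
                        continue
                    if mask3 == 0:
                        tgt = 0
                    else:
                        tgt = index[(min(e2, max_pos), mask3)]
                    T[s, tgt] += stay * p_ed * p_bl
        self.T = T

        # Emission parameters per distinct channel-count row.
        self.uniq_counts, self.state_to_uniq = np.unique(
            counts, axis=0, return_inverse=True
        )
        self.mu = em.mu
        self.var = self.uniq_counts * em.sigma**2 + em.sigma_bg**2  # (U, C)
        self.mean = self.uniq_counts * em.mu  # (U, C)

    def log_emission(self, reads: np.ndarray) -> np.ndarray:
        """Log density of each image under each state.

        ``reads``: (n, C, T) → returns (n, n_states, T).
        """
        x = reads[:, None, :, :]  # (n, 1, C, T)
        mean = self.mean[None, :, :, None]
        var = self.var[None, :, :, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            le = -0.5 * ((x - mean) ** 2 / var + np.log(var) + _LOG_2PI)
        if np.any(self.var == 0):  # degenerate noise-free channels
            exact = np.broadcast_to(x == mean, le.shape)
            le = np.where(
                np.broadcast_to(var == 0, le.shape),
                np.where(exact, 0.0, -np.inf),
                le,
            )
        return le.sum(axis=2)[:, self.state_to_uniq, :]  # (n, S, T)

    def loglikelihood(self, reads: np.ndarray, em: ErrorModel) -> np.ndarray:
        """Log-domain forward pass; ``reads`` is (n, C, T) → (n,) log P(x|f).

        The transition step runs in probability space after a per-read max
        shift; emissions stay in log space so widely separated Gaussian
        densities cannot underflow.
        """
        logemit = self.log_emission(reads)
        n = reads.shape[0]
        with np.errstate(divide="ignore"):
            logalpha = np.broadcast_to(
                np.log(self.init), (n, self.n_states)
            ).copy()
        t = 0
        if em.include_initial_image:
            logalpha = logalpha + logemit[:, :, 0]
            t = 1
        for _ in range(em.n_cycles):
            shift = logalpha.max(axis=1)
            ok = np.isfinite(shift)
            safe_shift = np.where(ok, shift, 0.0)
            a = np.where(
                ok[:, None], np.exp(logalpha - safe_shift[:, None]), 0.0
            )
            a = a @ self.T
            with np.errstate(divide="ignore"):
                logalpha = np.log(a) + safe_shift[:, None] + logemit[:, :, t]
            logalpha[~ok] = -np.inf
            t += 1
        shift = logalpha.max(axis=1)
        ok = np.isfinite(shift)
        safe_shift = np.where(ok, shift, 0.0)
        out = safe_shift + np.log(
            np.where(ok[:, None], np.exp(logalpha - safe_shift[:, None]), 0.0).sum(
                axis=1
            )
        )
        return np.where(ok, out, -np.inf)


def hmm_loglikelihood(read: Read, f: FluorescenceString, em: ErrorModel) -> float:
    """Exact ``log P(x_k | F°_k = f)`` under the simulator's generative
    process, conditioned on observability (>= 1 non-dud dye)."""
    x = read.intensities
    if x.shape[1] != em.n_timepoints:
        raise InconsistencyError(
            f"read has {x.shape[1]} timepoints, error model expects "
            f"{em.n_timepoints}"
        )
    hmm = _StringHMM(f, em, n_channels=x.shape[0])
    return float(hmm.loglikelihood(x[None], em)[0])


def loglikelihood_matrix(
    reads: np.ndarray, model: ProteomeModel, em: ErrorModel
) -> np.ndarray:
    """(n_reads, n_strings) log-likelihoods; ``−inf`` in the f_null column."""
    if reads.ndim != 3 or reads.shape[1] != model.scheme.n_channels:
        raise InconsistencyError("reads array must be (n, n_channels, T)")
    n = reads.shape[0]
    out = np.full((n, model.n_strings), -np.inf)
    for s, f in enumerate(model.strings):
        if f.is_null:
            continue
        hmm = _StringHMM(f, em, model.scheme.n_channels)
        out[:, s] = hmm.loglikelihood(reads, em)
    return out


def exact_posterior(read: Read, model: ProteomeModel, em: ErrorModel) -> np.ndarray:
    """Bayes posterior over ``D_F`` with a uniform prior over observable
    strings; the read-wise normalizer cancels and is never materialized."""
    return exact_posterior_batch(read.intensities[None], model, em)[0]


def exact_posterior_batch(
    reads: np.ndarray, model: ProteomeModel, em: ErrorModel
) -> np.ndarray:
    """(n_reads, n_strings) posterior matrix via max-shifted softmax."""
    ll = loglikelihood_matrix(reads, model, em)
    shift = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - shift)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Sparsification
# ---------------------------------------------------------------------------


@dataclass
class SparsePosterior:
    """Top-``N_b`` truncation of a posterior with uniform residual.

    ``top_probs`` stores the untruncated posterior values of the retained
    strings; every string in the universe — including the retained ones —
    additionally carries the residual ``r_k``, so total mass is exactly 1:
    ``Σ top_probs + n_strings · residual == 1``.
    """

    read_id: int
    top_indices: np.ndarray
    top_probs: np.ndarray
    residual: float
    n_strings: int

    def __post_init__(self) -> None:
        self.top_indices = np.asarray(self.top_indices, dtype=np.int64)
        self.top_probs = np.asarray(self.top_probs, dtype=np.float64)
        if self.top_indices.size != self.top_probs.size:
            raise InconsistencyError("indices/probs length mismatch")
        if self.residual < 0:
            raise InconsistencyError("negative residual")
        total = self.top_probs.sum() + self.n_strings * self.residual
        if abs(total - 1.0) > 1e-9:
            raise InconsistencyError(f"sparse posterior mass {total} != 1")

    def dense(self) -> np.ndarray:
        """Reconstruct the sparsified posterior as a dense vector."""
        out = np.full(self.n_strings, self.residual)
        out[self.top_indices] += self.top_probs
        return out


def sparsify(
    posterior: np.ndarray | SparsePosterior, n_b: int, read_id: int = 0
) -> SparsePosterior:
    """Keep the ``n_b`` highest-posterior strings (ties broken by lower
    index) and spread the remaining mass uniformly over the universe.

    Applied to an already-sparse posterior it truncates the retained set
    further (or returns an equal object if nothing is cut), so the
    operation is idempotent at fixed ``n_b``.
    """
    if n_b < 1:
        raise ConfigurationError("n_b must be >= 1")
    if isinstance(posterior, SparsePosterior):
        k = min(n_b, posterior.top_indices.size)
        top = posterior.top_probs[:k]
        residual = max(0.0, (1.0 - top.sum()) / posterior.n_strings)
        return SparsePosterior(
            read_id=posterior.read_id,
            top_indices=posterior.top_indices[:k].copy(),
            top_probs=top.copy(),
            residual=residual,
            n_strings=posterior.n_strings,
        )
    posterior = np.asarray(posterior, dtype=np.float64)
    n = posterior.size
    k = min(n_b, n)
    order = np.argsort(-posterior, kind="stable")[:k]
    top = posterior[order]
    residual = max(0.0, (1.0 - top.sum()) / n)
    return SparsePosterior(
        read_id=read_id,
        top_indices=order,
        top_probs=top,
        residual=residual,
        n_strings=n,
    )


@dataclass
class PosteriorBatch:
    """Column-oriented container for many sparse posteriors of equal width.

    The array form the EM engine consumes directly; convertible to and from
    lists of :class:`SparsePosterior`.
    """

    indices: np.ndarray  # (n_reads, n_b)
    probs: np.ndarray  # (n_reads, n_b)
    residuals: np.ndarray  # (n_reads,)
    n_strings: int
    read_ids: np.ndarray | None = None

    @property
    def n_reads(self) -> int:
        return self.indices.shape[0]

    @classmethod
    def from_sparse_list(cls, posts: list[SparsePosterior]) -> "PosteriorBatch":
        if not posts:
            raise ConfigurationError("empty posterior stream")
        n_strings = posts[0].n_strings
        width = max(p.top_indices.size for p in posts)
        idx = np.zeros((len(posts), width), dtype=np.int64)
        prb = np.zeros((len(posts), width))
        res = np.empty(len(posts))
        rid = np.empty(len(posts), dtype=np.int64)
        for k, p in enumerate(posts):
            if p.n_strings != n_strings:
                raise InconsistencyError("mixed string universes in one batch")
            w = p.top_indices.size
            idx[k, :w] = p.top_indices
            prb[k, :w] = p.top_probs
            res[k] = p.residual
            rid[k] = p.read_id
        return cls(idx, prb, res, n_strings, rid)

    @classmethod
    def from_dense(cls, posteriors: np.ndarray, n_b: int) -> "PosteriorBatch":
        """Sparsify a dense (n_reads, n_strings) posterior matrix."""
        if n_b < 1:
            raise ConfigurationError("n_b must be >= 1")
        posteriors = np.asarray(posteriors, dtype=np.float64)
        n, ns = posteriors.shape
        k = min(n_b, ns)
        order = np.argsort(-posteriors, axis=1, kind="stable")[:, :k]
        top = np.take_along_axis(posteriors, order, axis=1)
        res = np.maximum(0.0, (1.0 - top.sum(axis=1)) / ns)
        return cls(order, top, res, ns, np.arange(n))

    @classmethod
    def from_oracle(
        cls, true_strings: np.ndarray, e: float, n_strings: int, n_b: int = 1
    ) -> "PosteriorBatch":
        """Sparsified oracle posteriors for a whole dataset at once.

        The true string always ranks first; the remaining ``n_b − 1`` slots
        are the lowest-index other strings (all ties at ``e/|D_F|``).
        """
        if not 0 <= e <= 1:
            raise ConfigurationError(f"oracle error rate e={e} outside [0, 1]")
        true_strings = np.asarray(true_strings, dtype=np.int64)
        n = true_strings.size
        k = min(n_b, n_strings)
        base = e / n_strings
        idx = np.empty((n, k), dtype=np.int64)
        idx[:, 0] = true_strings
        if k > 1:
            # lowest-index strings, skipping the true one
            fill = np.broadcast_to(np.arange(k), (n, k)).copy()
            bump = fill >= true_strings[:, None]
            fill = np.where(bump, fill + 1, fill)
            idx[:, 1:] = fill[:, : k - 1]
        prb = np.full((n, k), base)
        prb[:, 0] += 1.0 - e
        res = np.maximum(0.0, (1.0 - prb.sum(axis=1)) / n_strings)
        return cls(idx, prb, res, n_strings, np.arange(n))

    def to_sparse_list(self) -> list[SparsePosterior]:
        ids = (
            self.read_ids
            if self.read_ids is not None
            else np.arange(self.n_reads)
        )
        return [
            SparsePosterior(
                read_id=int(ids[k]),
                top_indices=self.indices[k],
                top_probs=self.probs[k],
                residual=float(self.residuals[k]),
                n_strings=self.n_strings,
            )
            for k in range(self.n_reads)
        ]
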
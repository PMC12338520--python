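"""Shared fixtures and the brute-force likelihood oracle.

The brute-force oracle enumerates every hidden event sequence of the
generative process (dud pattern, then per cycle: detach bit, Edman bit,
per-dye bleach bits) and sums the exact probability of the observed
intensities.  It is deliberately independent of the forward-recursion
implementation it validates.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from fluorem import (
    ErrorModel,
    FluorescenceString,
    LabelScheme,
    ProteinRecord,
    build_model,
    synthetic_proteins,
)

_LOG_2PI = float(np.log(2.0 * np.pi))


@pytest.fixture(scope="session")
def five_protein_model():
    """Synthetic five-protein model under the default labeling scheme."""
    return build_model(synthetic_proteins(5, seed=1), m=0.07)


@pytest.fixture(scope="session")
def two_protein_model():
    """Hand-checkable universe: protein A emits strings {a, b} equally,
    protein B emits only b (single-channel scheme, no duds)."""
    scheme = LabelScheme(channels=(frozenset("C"),))
    prots = [
        ProteinRecord("A", "CKCCK"),  # peptides CK -> a=[0], CCK -> b=[0,0]
        ProteinRecord("B", "CCK"),  # peptide CCK -> b
    ]
    return build_model(prots, scheme, m=0.0)


@pytest.fixture
def default_error_model():
    return ErrorModel()


def gaussian_logpdf(x: float, mean: float, var: float) -> float:
    if var == 0:
        return 0.0 if x == mean else -np.inf
    return -0.5 * ((x - mean) ** 2 / var + np.log(var) + _LOG_2PI)


def brute_force_loglik(
    x: np.ndarray, f: FluorescenceString, em: ErrorModel
) -> float:
    """log P(x | f) by exhaustive enumeration of hidden event sequences."""
    with np.errstate(divide="ignore"):
        return _brute_force_loglik(x, f, em)


def _brute_force_loglik(
    x: np.ndarray, f: FluorescenceString, em: ErrorModel
) -> float:
    positions = list(f.dye_positions)
    channels = list(f.dye_channels)
    nd = len(positions)
    n_channels, n_t = x.shape
    assert n_t == em.n_timepoints

    def emit_logp(alive: tuple[bool, ...], detached: bool, t: int) -> float:
        counts = [0] * n_channels
        if not detached:
            for i in range(nd):
                if alive[i]:
                    counts[channels[i]] += 1
        lp = 0.0
        for c in range(n_channels):
            mean = counts[c] * em.mu
            var = counts[c] * em.sigma**2 + em.sigma_bg**2
            lp += gaussian_logpdf(x[c, t], mean, var)
        return lp

    terms = []
    norm = 1.0 - em.p_dud**nd
    for duds in product([False, True], repeat=nd):
        alive0 = tuple(not d for d in duds)
        if not any(alive0):
            continue
        logp = sum(
            np.log(em.p_dud) if d else np.log1p(-em.p_dud) for d in duds
        ) - np.log(norm)

        # one branch per full per-cycle event assignment
        cycle_events = list(
            product([False, True], [False, True], product([False, True], repeat=nd))
        )
        for seq in product(cycle_events, repeat=em.n_cycles):
            lp = logp
            alive = alive0
            detached = False
            pos = 0
            t = 0
            if em.include_initial_image:
                lp += emit_logp(alive, detached, 0)
                t = 1
            for detach_bit, edman_ok, bleach_bits in seq:
                lp += (
                    np.log(em.p_detach)
                    if detach_bit
                    else np.log1p(-em.p_detach)
                )
                if detach_bit:
                    detached = True
                lp += (
                    np.log1p(-em.p_edman_fail)
                    if edman_ok
                    else np.log(em.p_edman_fail)
                )
                if edman_ok:
                    alive = tuple(
                        a and positions[i] != pos for i, a in enumerate(alive)
                    )
                    pos += 1
                for i, b in enumerate(bleach_bits):
                    lp += (
                        np.log(em.p_bleach) if b else np.log1p(-em.p_bleach)
                    )
                alive = tuple(
                    a and not b for a, b in zip(alive, bleach_bits)
                )
                lp += emit_logp(alive, detached, t)
                t += 1
                if lp == -np.inf:
                    break
            terms.append(lp)
    terms = np.array(terms)
    hi = terms.max()
    if hi == -np.inf:
        return -np.inf
    return float(hi + np.log(np.exp(terms - hi).sum()))
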
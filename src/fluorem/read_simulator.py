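"""Generative simulator of fluorosequencing reads.

Each read is a channels × timepoints intensity matrix: one pre-Edman image
followed by one image per degradation cycle.  The error model covers the
dominant experimental failure modes — dud dyes (never attached), per-cycle
Edman failure, surface detachment, photobleaching, an optional blocking
artifact that halts degradation, and Gaussian measurement noise.

The default parameters are the standard five-protein simulation settings
(11 Edman cycles, 6% Edman failure, 5% detach, 5% bleach, 7% dud, light
intensity 10000 ± 1600 per dye, background sd 66.7, blocking off).

Event order within a cycle is fixed as: detachment → Edman removal (unless
blocked) → cyclic blocking → bleaching → image.  A read whose dyes are all
duds would be invisible; such molecules are rejected and resampled, which is
exactly the observability conditioning applied to the string distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FluoremError
from .proteome_model import (
    AbundanceVector,
    FluorescenceString,
    ProteomeModel,
    ProteinRecord,
    protein_to_indicator,
    string_distribution,
)


@dataclass(frozen=True)
class ErrorModel:
    """Per-cycle and per-dye failure rates plus the intensity model.

    ``p_dud`` is the dye miss rate ``m`` used to build the proteome model;
    the two must agree for the simulator and the model to describe the same
    experiment.  Intensities: ``c`` co-located active dyes of one channel
    emit ``Normal(c·mu, sqrt(c)·sigma)`` (independent emitters, variances
    add), plus ``Normal(0, sigma_bg)`` background per channel per image.
    """

    n_cycles: int = 11
    p_edman_fail: float = 0.06
    p_detach: float = 0.05
    p_bleach: float = 0.05
    p_dud: float = 0.07
    p_block_init: float = 0.0
    p_block_cyclic: float = 0.0
    mu: float = 10000.0
    sigma: float = 1600.0
    sigma_bg: float = 66.7
    include_initial_image: bool = True

    def __post_init__(self) -> None:
        for name in (
            "p_edman_fail",
            "p_detach",
            "p_bleach",
            "p_dud",
            "p_block_init",
            "p_block_cyclic",
        ):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name}={v} outside [0, 1)")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if self.mu <= 0 or self.sigma < 0 or self.sigma_bg < 0:
            raise ConfigurationError("intensity parameters out of range")

    @property
    def n_timepoints(self) -> int:
        return self.n_cycles + (1 if self.include_initial_image else 0)


#: Reduced-error settings of the whole-proteome experiments (39 cycles,
#: every failure rate divided by 100, tighter per-dye intensity spread).
IMPROVED_ERROR = ErrorModel(
    n_cycles=39,
    p_edman_fail=0.0006,
    p_detach=0.0005,
    p_bleach=0.0005,
    p_dud=0.0007,
    mu=10000.0,
    sigma=160.0,
    sigma_bg=66.7,
)


@dataclass
class Read:
    """One fluorosequencing read: channels × timepoints intensities."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2 or not np.all(np.isfinite(self.intensities)):
            raise ConfigurationError("read must be a finite 2-D matrix")


@dataclass
class Dataset:
    """Simulated reads with their generating truth."""

    reads: list[Read]
    true_strings: np.ndarray  # index into the model's string list, never 0
    true_p: AbundanceVector
    seed: int
    model_ref: str = ""
    n_rejected: int = 0  # all-dud molecules resampled during generation

    @property
    def n_reads(self) -> int:
        return self.true_strings.size


# ---------------------------------------------------------------------------
# Abundance sampling (the dataset protocol)
# ---------------------------------------------------------------------------


def sample_abundances(n_proteins: int, seed: int) -> AbundanceVector:
    """True abundances: i.i.d. unit-rate exponentials normalized to the
    simplex, spanning several orders of magnitude at proteome scale."""
    if n_proteins < 1:
        raise ConfigurationError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.exponential(scale=1.0, size=n_proteins)
    return AbundanceVector(draws / draws.sum(), "protein")


def synthetic_proteins(
    n_proteins: int = 5,
    n_peptides: int = 8,
    peptide_length: int = 12,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random tryptic-style proteins for self-contained experiments.

    Each protein is a concatenation of ``n_peptides`` segments ending in K
    or R (never followed by P), with residues drawn uniformly from the
    standard alphabet minus K/R/P inside segments, so digestion recovers the
    segments exactly.  Labelable residues (D/E/C/Y) occur at their natural
    uniform rate, giving a realistic mix of 0–4-dye peptides.
    """
    rng = np.random.default_rng(seed)
    body = np.array(sorted(set("ACDEFGHILMNQSTVWY")))  # no K/R (sites), no P
    records = []
    for i in range(n_proteins):
        segs = []
        for _ in range(n_peptides):
            core = "".join(rng.choice(body, size=peptide_length - 1))
            segs.append(core + rng.choice(["K", "R"]))
        records.append(ProteinRecord(id=f"SYN{i + 1}", sequence="".join(segs)))
    return records


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def _simulate_batch(
    f: FluorescenceString,
    em: ErrorModel,
    n: int,
    rng: np.random.Generator,
    n_channels: int | None = None,
) -> tuple[np.ndarray, int]:
    """Simulate ``n`` reads of string ``f`` vectorized over molecules.

    Returns ``(intensities with shape (n, n_channels, T), n_rejected)``.
    """
    positions = np.array(f.dye_positions, dtype=np.int64)
    channels = np.array(f.dye_channels, dtype=np.int64)
    nd = positions.size
    if nd == 0:
        raise FluoremError("f_null cannot generate a read")
    if n_channels is None:
        n_channels = int(channels.max()) + 1

    # Dud assignment with rejection: condition on >= 1 functional dye.
    alive = rng.random((n, nd)) >= em.p_dud
    n_rejected = 0
    while True:
        dead_rows = ~alive.any(axis=1)
        k = int(dead_rows.sum())
        if k == 0:
            break
        n_rejected += k
        alive[dead_rows] = rng.random((k, nd)) >= em.p_dud

    blocked = rng.random(n) < em.p_block_init
    detached = np.zeros(n, dtype=bool)
    edman_pos = np.zeros(n, dtype=np.int64)

    images = []

    def snapshot() -> np.ndarray:
        active = alive & ~detached[:, None]
        counts = np.zeros((n, n_channels))
        for c in range(n_channels):
            counts[:, c] = (active & (channels == c)[None, :]).sum(axis=1)
        sig = counts * em.mu + np.sqrt(counts) * em.sigma * rng.standard_normal(
            (n, n_channels)
        )
        return sig + em.sigma_bg * rng.standard_normal((n, n_channels))

    if em.include_initial_image:
        images.append(snapshot())

    for _ in range(em.n_cycles):
        detached |= rng.random(n) < em.p_detach
        alive &= ~detached[:, None]  # detachment removes the molecule for good
        removed = (~blocked) & (rng.random(n) >= em.p_edman_fail)
        # Edman success deletes the dye at the removed position, if any.
        hit = removed[:, None] & (positions[None, :] == edman_pos[:, None])
        alive &= ~hit
        edman_pos += removed.astype(np.int64)
        blocked |= rng.random(n) < em.p_block_cyclic
        alive &= rng.random((n, nd)) >= em.p_bleach
        images.append(snapshot())

    return np.stack(images, axis=2), n_rejected


def simulate_read(
    f: FluorescenceString, em: ErrorModel, rng: np.random.Generator
) -> Read:
    """Simulate a single read of string ``f`` (see module docstring for the
    event order)."""
    intens, _ = _simulate_batch(f, em, 1, rng)
    return Read(intens[0])


def generate_dataset(
    model: ProteomeModel,
    p: AbundanceVector,
    n_reads: int,
    em: ErrorModel,
    seed: int,
    pool_size: int | None = None,
    simulate_intensities: bool = True,
) -> Dataset:
    """Draw generating strings from the mixture distribution and simulate.

    The string of read ``k`` is drawn i.i.d. from ``P_F°`` under the
    indicator distribution implied by ``p``.  In pool mode (``pool_size``),
    ``pool_size`` reads per string are pre-simulated once and sampled with
    replacement — the shared-dataset protocol; identical in distribution to
    fresh draws.  With ``simulate_intensities=False`` only the true string
    indices are generated (sufficient for oracle-classifier experiments).
    """
    if n_reads < 1:
        raise ConfigurationError("n_reads must be >= 1")
    if pool_size is not None and pool_size < 1:
        raise ConfigurationError("pool_size must be >= 1 in pool mode")
    q = protein_to_indicator(p, model)
    pf = string_distribution(q, model)
    root = np.random.SeedSequence(seed)
    draw_ss, sim_ss = root.spawn(2)
    rng = np.random.default_rng(draw_ss)
    true_strings = rng.choice(model.n_strings, size=n_reads, p=pf)

    reads: list[Read] = []
    n_rejected = 0
    if simulate_intensities:
        # Per-string substreams: reads sharing a string simulate in one batch
        # under a child stream keyed by string index, so the dataset is
        # reproducible regardless of how reads interleave.
        n_ch = model.scheme.n_channels
        intens = np.empty((n_reads, n_ch, em.n_timepoints))
        children = sim_ss.spawn(model.n_strings)
        for s in np.unique(true_strings):
            idx = np.flatnonzero(true_strings == s)
            srng = np.random.default_rng(children[s])
            f = model.strings[s]
            if pool_size is None:
                batch, rej = _simulate_batch(f, em, idx.size, srng, n_ch)
            else:
                pool, rej = _simulate_batch(f, em, pool_size, srng, n_ch)
                batch = pool[srng.integers(0, pool_size, size=idx.size)]
            n_rejected += rej
            intens[idx] = batch
        reads = [Read(intens[k]) for k in range(n_reads)]

    return Dataset(
        reads=reads,
        true_strings=true_strings,
        true_p=p,
        seed=seed,
        n_rejected=n_rejected,
    )
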
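"""Fluorescence-string universe and the deterministic probability transforms.

Fluorosequencing observes peptides only through the positions of their
fluorescent labels, so distinct peptides frequently collapse onto one
*fluorescence string*: the per-position pattern of dye channels, truncated
after the last labeled residue.  This module builds the finite universe of
such strings for a protein set under a digestion/labeling scheme, and houses
the exact probability transforms that connect three distributions:

* ``p`` — relative protein abundance (protein space),
* ``q`` — the per-read protein *indicator* distribution, obtained from ``p``
  by reweighting with the expected number of observable strings each protein
  emits, ``E_F°(y)``,
* ``P_F°`` — the distribution of observable fluorescence strings, a mixture
  of the per-protein conditional string distributions weighted by ``q``.

A string is *observable* only if at least one of its dyes attached and is
functional; with per-dye dud probability ``m`` a string with ``N_d`` ideally
labeled positions survives with probability ``1 − m^N_d``.  The dye-free
null string therefore has observation probability exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InconsistencyError,
    ModelError,
)

#: The 20 standard amino acids.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Code for an unlabeled position inside ``FluorescenceString.labels``.
UNLABELED = -1

#: Default three-channel labeling: acidic residues, cysteine, tyrosine.
DEFAULT_CHANNELS = (frozenset("DE"), frozenset("C"), frozenset("Y"))

_SIMPLEX_ATOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence over the 20 standard residues."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ModelError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ModelError(
                f"protein {self.id!r}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class LabelScheme:
    """Protease rule plus the amino-acid target set of each dye channel.

    Channels must be pairwise disjoint: a residue carries at most one dye.
    """

    protease: str = "trypsin"
    channels: tuple[frozenset, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        chans = tuple(frozenset(c) for c in self.channels)
        object.__setattr__(self, "channels", chans)
        seen: set[str] = set()
        for c in chans:
            if seen & c:
                raise ConfigurationError(
                    f"channel target sets overlap on {sorted(seen & c)}"
                )
            seen |= c

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class FluorescenceString:
    """Canonical dye pattern of a peptide.

    ``labels[i]`` is the channel index of the dye at peptide position ``i``
    (N-terminus first) or :data:`UNLABELED`; positions after the last dye are
    dropped.  The empty tuple is the null string ``f_null``.
    """

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.labels and self.labels[-1] == UNLABELED:
            raise ModelError("fluorescence string not canonical: trailing unlabeled")

    @property
    def dye_count(self) -> int:
        """``N_d(f)``: number of ideally labeled positions."""
        return sum(1 for c in self.labels if c != UNLABELED)

    def per_channel_counts(self, n_channels: int) -> np.ndarray:
        counts = np.zeros(n_channels, dtype=np.int64)
        for c in self.labels:
            if c != UNLABELED:
                counts[c] += 1
        return counts

    @property
    def dye_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.labels) if c != UNLABELED)

    @property
    def dye_channels(self) -> tuple[int, ...]:
        return tuple(c for c in self.labels if c != UNLABELED)

    @property
    def is_null(self) -> bool:
        return not self.labels

    def compact(self) -> str:
        """Serialization code: '.' per unlabeled position, the digit else."""
        return "".join("." if c == UNLABELED else str(c) for c in self.labels)

    @classmethod
    def from_compact(cls, code: str) -> "FluorescenceString":
        return cls(tuple(UNLABELED if ch == "." else int(ch) for ch in code))


F_NULL = FluorescenceString(())


@dataclass
class AbundanceVector:
    """A probability vector over proteins, in protein (``p``) or indicator
    (``q``) space."""

    values: np.ndarray
    space: str  # "protein" | "indicator"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.space not in ("protein", "indicator"):
            raise ConfigurationError(f"unknown abundance space {self.space!r}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise DegenerateInputError("abundance vector must be 1-D and non-empty")
        if np.any(self.values < 0) or not np.isclose(
            self.values.sum(), 1.0, atol=_SIMPLEX_ATOL, rtol=0
        ):
            raise DegenerateInputError(
                "abundance vector must be non-negative and sum to 1"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ProteomeModel:
    """The string universe ``D_F`` and per-protein conditionals.

    ``cond_FI`` is the sparse matrix ``P_F°|I(f|y)`` with proteins as rows
    and strings as columns; ``f_null`` is always column 0 and carries no
    mass.  ``e_fo`` is the expected observable-string count per protein.
    """

    proteins: list[ProteinRecord]
    scheme: LabelScheme
    strings: list[FluorescenceString]
    cond_FI: sp.csr_matrix
    e_fo: np.ndarray
    dud_rate: float
    peptide_counts: np.ndarray = field(default=None)  # total tryptic peptides / protein

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_strings(self) -> int:
        return len(self.strings)

    def support(self, y: int) -> np.ndarray:
        """``D_F(y)``: string indices reachable from protein ``y``."""
        row = self.cond_FI.getrow(y)
        return row.indices[row.data > 0]

    def validate(self) -> None:
        """Check the structural invariants; raises ModelError on violation."""
        if not self.strings or not self.strings[0].is_null:
            raise ModelError("f_null must sit at string index 0")
        col0 = np.asarray(self.cond_FI[:, 0].todense()).ravel()
        if np.any(col0 != 0):
            raise ModelError("f_null must carry zero conditional mass")
        rowsums = np.asarray(self.cond_FI.sum(axis=1)).ravel()
        observable = self.e_fo > 0
        if not np.allclose(rowsums[observable], 1.0, atol=1e-12, rtol=0):
            raise ModelError("conditional rows of observable proteins must sum to 1")
        if np.any(rowsums[~observable] != 0):
            raise ModelError("unobservable proteins must have empty support")


# ---------------------------------------------------------------------------
# Digestion and labeling
# ---------------------------------------------------------------------------


def digest(protein: ProteinRecord, protease: str = "trypsin") -> list[str]:
    """In-silico digest with zero missed cleavages.

    Trypsin cleaves C-terminal to K or R unless the next residue is P.
    Duplicate peptides are retained with multiplicity.
    """
    if protease != "trypsin":
        raise ConfigurationError(f"unknown protease {protease!r}")
    seq = protein.sequence
    peptides: list[str] = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            peptides.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    return peptides


def label_peptide(peptide: str, scheme: LabelScheme) -> FluorescenceString:
    """Map a peptide to its canonical fluorescence string.

    Position ``i`` carries a channel-``c`` dye iff ``peptide[i]`` is in the
    channel's target set; the result is truncated after the last dye.
    Peptides with no labelable residue map to ``f_null``.
    """
    if not peptide:
        raise ConfigurationError("empty peptide cannot be labeled")
    labels = []
    for aa in peptide:
        code = UNLABELED
        for c, targets in enumerate(scheme.channels):
            if aa in targets:
                code = c
                break
        labels.append(code)
    while labels and labels[-1] == UNLABELED:
        labels.pop()
    return FluorescenceString(tuple(labels))


def observable_weight(f: FluorescenceString, m: float) -> float:
    """Probability that string ``f`` is experimentally observable.

    With per-dye dud probability ``m``, observability requires at least one
    of the ``N_d(f)`` dyes to attach: ``1 − m^N_d``.  Zero for ``f_null``.
    """
    if not 0 <= m < 1:
        raise ConfigurationError(f"dud rate m={m} outside [0, 1)")
    nd = f.dye_count
    if nd == 0:
        return 0.0
    return 1.0 - m**nd


def build_model(
    proteins: list[ProteinRecord],
    scheme: LabelScheme = LabelScheme(),
    m: float = 0.07,
) -> ProteomeModel:
    """Digest, label, deduplicate and reweight into a :class:`ProteomeModel`.

    For protein ``y`` with tryptic peptides ``j`` mapping to strings ``f_j``
    and observability weights ``w_j = 1 − m^{N_d(f_j)}``:

    * ``P_F°|I(f|y) = Σ_{j: f_j = f} w_j / Σ_j w_j``
    * ``E_F°(y) = Σ_j w_j``

    Duplicate peptides count with multiplicity — required for the mixture
    over ``q`` to equal the simulator's empirical string frequencies.
    Proteins without any labelable peptide are kept with ``E_F° = 0`` and an
    empty support row.
    """
    if not proteins:
        raise ModelError("no proteins supplied")
    string_index: dict[FluorescenceString, int] = {F_NULL: 0}
    strings: list[FluorescenceString] = [F_NULL]
    rows, cols, vals = [], [], []
    e_fo = np.zeros(len(proteins))
    pep_counts = np.zeros(len(proteins), dtype=np.int64)
    for y, prot in enumerate(proteins):
        weights: dict[int, float] = {}
        total = 0.0
        peptides = digest(prot, scheme.protease)
        pep_counts[y] = len(peptides)
        for pep in peptides:
            f = label_peptide(pep, scheme)
            idx = string_index.setdefault(f, len(strings))
            if idx == len(strings):
                strings.append(f)
            w = observable_weight(f, m)
            if w > 0:
                weights[idx] = weights.get(idx, 0.0) + w
                total += w
        e_fo[y] = total
        for idx, w in sorted(weights.items()):
            rows.append(y)
            cols.append(idx)
            vals.append(w / total)
    if not np.any(e_fo > 0):
        raise ModelError("empty observable universe: no labelable peptide anywhere")
    cond = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(proteins), len(strings)), dtype=np.float64
    )
    model = ProteomeModel(
        proteins=list(proteins),
        scheme=scheme,
        strings=strings,
        cond_FI=cond,
        e_fo=e_fo,
        dud_rate=m,
        peptide_counts=pep_counts,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Probability transforms between protein, indicator and string space
# ---------------------------------------------------------------------------


def protein_to_indicator(
    p: AbundanceVector, model: ProteomeModel | np.ndarray
) -> AbundanceVector:
    """``q_y ∝ E_F°(y) · p_y``: reads are emitted in proportion to abundance
    times expected observable-string yield.

    ``model`` may be a full :class:`ProteomeModel` or just the ``E_F°``
    vector.
    """
    if p.space != "protein":
        raise InconsistencyError("protein_to_indicator expects a protein-space vector")
    e_fo = model if isinstance(model, np.ndarray) else model.e_fo
    if len(p) != e_fo.size:
        raise InconsistencyError("abundance/model length mismatch")
    w = e_fo * p.values
    z = w.sum()
    if z == 0:
        raise DegenerateInputError("all abundance mass on unobservable proteins")
    return AbundanceVector(w / z, "indicator")


def indicator_to_protein(
    q: AbundanceVector, model: ProteomeModel | np.ndarray
) -> AbundanceVector:
    """Inverse of :func:`protein_to_indicator`: ``p_y ∝ q_y / E_F°(y)``.

    A protein with ``E_F°(y) = 0`` emits no reads, so positive indicator
    mass there is inconsistent.
    """
    if q.space != "indicator":
        raise InconsistencyError("indicator_to_protein expects an indicator-space vector")
    e_fo = model if isinstance(model, np.ndarray) else model.e_fo
    if len(q) != e_fo.size:
        raise InconsistencyError("abundance/model length mismatch")
    unobservable = e_fo == 0
    if np.any(q.values[unobservable] > 0):
        raise InconsistencyError(
            "positive indicator mass on proteins with zero observable yield"
        )
    p = np.zeros_like(q.values)
    obs = ~unobservable
    p[obs] = q.values[obs] / e_fo[obs]
    return AbundanceVector(p / p.sum(), "protein")


def string_distribution(q: AbundanceVector, model: ProteomeModel) -> np.ndarray:
    """Mixture ``P_F°(f) = Σ_y P_F°|I(f|y) q_y`` over the string universe."""
    if q.space != "indicator":
        raise InconsistencyError("string_distribution expects an indicator-space vector")
    if len(q) != model.n_proteins:
        raise InconsistencyError("abundance/model length mismatch")
    return np.asarray(model.cond_FI.T @ q.values).ravel()
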
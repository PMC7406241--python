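"""Domain types and composition-dependent rate laws.

The model coarse-grains the Golgi apparatus into compartments made of
membrane patches of unit size.  Each patch carries one of three biochemical
identities (*cis*, *medial*, *trans*) and converts irreversibly
cis -> medial -> trans, mimicking a Rab-cascade-like identity switch.
Compartments interact through three composition-dependent stochastic
mechanisms:

* homotypic fusion — two compartments fuse at a rate proportional to the
  probability that they present the same identity at the contact site,
  ``Kf * sum_i phi_i(a) phi_i(b)``;
* vesicle budding — a compartment of size ``n >= 2`` emits a pure
  single-patch vesicle of identity *i*, either at the saturated rate
  ``Kb * n`` per present identity, or at the linear rate ``Kb * n_i``;
* biochemical conversion — each cis (medial) patch becomes medial (trans)
  at rate ``Km`` per patch.

Time is measured in units of ``1/Kf`` so the fusion prefactor is 1 and the
model reduces to the dimensionless rates ``kb = Kb/Kf``, ``km = Km/Kf`` and
the vesicle injection rate ``j = J/Kf``.  Two absorbing boundaries bracket
the system: the ER (a fraction ``alpha_ER`` of cis patches) and the TGN
(a fraction ``alpha_TGN`` of trans patches); fusing with a boundary removes
a compartment permanently.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Identity",
    "Compartment",
    "Boundary",
    "Parameters",
    "fusion_rate",
    "boundary_fusion_rate",
    "budding_rates",
    "conversion_rates",
    "purity",
    "purity_from_fractions",
]


class Identity(enum.IntEnum):
    """The three membrane identities, in strict maturation order."""

    CIS = 0
    MEDIAL = 1
    TRANS = 2

    @property
    def successor(self) -> "Identity | None":
        """Next identity in the cis -> medial -> trans cascade.

        ``TRANS`` is terminal: conversion never maps it anywhere.
        """
        if self is Identity.TRANS:
            return None
        return Identity(self.value + 1)


_comp_ids = itertools.count()


@dataclass(eq=False)
class Compartment:
    """A membrane compartment: integer patch counts per identity plus cargo.

    ``counts`` is a length-3 integer vector ``(n_cis, n_medial, n_trans)``
    with total size ``n >= 1``.  A compartment of size 1 is a *vesicle*.
    Cargo molecules are passive, indistinguishable labels, stored as a count.
    """

    counts: np.ndarray
    cargo: int = 0
    id: int = field(default_factory=lambda: next(_comp_ids))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3,):
            raise ValueError("counts must be a length-3 vector")
        if np.any(self.counts < 0):
            raise ValueError("patch counts must be non-negative")
        if self.n < 1:
            raise ValueError("a compartment has size >= 1")
        if self.cargo < 0:
            raise ValueError("cargo count must be non-negative")

    @property
    def n(self) -> int:
        """Total size (number of membrane patches)."""
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        """Composition vector phi on the 2-simplex (sums to 1)."""
        return self.counts / self.n

    @property
    def is_vesicle(self) -> bool:
        return self.n == 1

    @classmethod
    def pure(cls, identity: Identity, n: int = 1, cargo: int = 0) -> "Compartment":
        counts = np.zeros(3, dtype=np.int64)
        counts[int(identity)] = n
        return cls(counts=counts, cargo=cargo)

    def copy(self) -> "Compartment":
        return Compartment(counts=self.counts.copy(), cargo=self.cargo)


@dataclass(frozen=True)
class Boundary:
    """An absorbing exit: the ER (cis-faced) or the TGN (trans-faced).

    ``alpha`` is the fraction of the boundary's membrane carrying its
    nominal identity (the rest is neutral and dilutes homotypic fusion).
    """

    role: str  # "ER" | "TGN"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("ER", "TGN"):
            raise ValueError("boundary role must be 'ER' or 'TGN'")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def identity(self) -> Identity:
        return Identity.CIS if self.role == "ER" else Identity.TRANS


@dataclass
class Parameters:
    """Normalised model parameters (time unit 1/Kf, so Kf = 1).

    Attributes
    ----------
    kb : budding/fusion rate ratio Kb/Kf.
    km : conversion/fusion rate ratio Km/Kf.
    j : injection/fusion rate ratio J/Kf; if ``None`` it is derived from
        ``n_target`` by the well-sorted influx calibration at run time.
    n_target : target mean total system size in patches.
    alpha_er, alpha_tgn : homotypic fractions of the boundaries.
    budding_mode : ``"saturated"`` (rate kb*n per present identity) or
        ``"linear"`` (rate kb*n_i per identity).
    inter_compartment_fusion : whether compartment-compartment fusion is
        allowed (boundary fusion is always on).
    t_max, t_burn : simulation horizon and burn-in, in units of 1/Kf.
    seed : RNG seed.
    """

    kb: float = 1.0
    km: float = 1.0
    j: float | None = None
    n_target: float = 300.0
    alpha_er: float = 1.0
    alpha_tgn: float = 1.0
    budding_mode: str = "saturated"
    inter_compartment_fusion: bool = True
    t_max: float = 100.0
    t_burn: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kb < 0 or self.km < 0:
            raise ValueError("rates must be non-negative")
        if self.j is not None and self.j < 0:
            raise ValueError("injection rate must be non-negative")
        if self.n_target < 0:
            raise ValueError("n_target must be non-negative")
        for a in (self.alpha_er, self.alpha_tgn):
            if not 0.0 <= a <= 1.0:
                raise ValueError("boundary fractions must lie in [0, 1]")
        if self.budding_mode not in ("saturated", "linear"):
            raise ValueError(
                f"unknown budding_mode {self.budding_mode!r}; "
                "expected 'saturated' or 'linear'"
            )
        if not self.t_burn < self.t_max:
            raise ValueError("t_burn must be smaller than t_max")

    @property
    def boundaries(self) -> tuple[Boundary, Boundary]:
        return (Boundary("ER", self.alpha_er), Boundary("TGN", self.alpha_tgn))


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def fusion_rate(a: Compartment, b: Compartment, params: Parameters) -> float:
    """Homotypic fusion rate between two compartments, in units of Kf.

    The rate is ``sum_i phi_i(a) * phi_i(b)``: the probability that the two
    compartments present the same identity at a random contact site.  It is
    1 for identical pure compartments, 0 for orthogonal ones, and 0 for any
    pair when inter-compartment fusion is switched off.
    """
    if a is b or a.id == b.id:
        raise ValueError("self-fusion is undefined: pass two distinct compartments")
    if not params.inter_compartment_fusion:
        return 0.0
    return float(np.dot(a.fractions, b.fractions))


def boundary_fusion_rate(a: Compartment, boundary: Boundary) -> float:
    """Fusion rate of a compartment with the ER or TGN boundary.

    Same homotypic rule as compartment-compartment fusion, with the
    boundary's composition being ``alpha`` of its nominal identity:
    ``alpha * phi_identity(a)``.
    """
    return float(boundary.alpha * a.fractions[int(boundary.identity)])


def budding_rates(a: Compartment, params: Parameters) -> dict[Identity, float]:
    """Per-identity vesicle budding rates of a compartment.

    Only compartments larger than a vesicle (``n >= 2``) bud.  In the
    saturated mode every identity present in the compartment buds at rate
    ``kb * n`` (Michaelis-Menten-saturated budding machinery); in the linear
    mode identity ``i`` buds at rate ``kb * n_i``.
    """
    n = a.n
    rates = {i: 0.0 for i in Identity}
    if n < 2:
        return rates
    if params.budding_mode == "saturated":
        for i in Identity:
            if a.counts[int(i)] >= 1:
                rates[i] = params.kb * n
    elif params.budding_mode == "linear":
        for i in Identity:
            rates[i] = params.kb * float(a.counts[int(i)])
    else:  # pragma: no cover - Parameters validates, defensive for raw dicts
        raise ValueError(f"unknown budding_mode {params.budding_mode!r}")
    return rates


def conversion_rates(a: Compartment, params: Parameters) -> dict[Identity, float]:
    """Biochemical conversion rates, keyed by the *source* identity.

    Each cis patch converts to medial and each medial patch to trans at the
    same per-patch rate ``km``; trans is terminal.  Vesicles convert too
    (a cis vesicle becomes a medial vesicle, etc.).
    """
    return {
        Identity.CIS: params.km * float(a.counts[0]),
        Identity.MEDIAL: params.km * float(a.counts[1]),
    }


def purity_from_fractions(phi: np.ndarray) -> np.ndarray | float:
    """Purity of one or many composition vectors.

    P = sqrt(3/2 * sum_i (phi_i - 1/3)^2), the Euclidean distance from the
    perfectly mixed composition (1/3, 1/3, 1/3) scaled so that P = 0 for a
    fully mixed compartment, 1/2 for an equal two-identity mix, and 1 for a
    pure compartment.  ``phi`` may be shape (3,) or (k, 3).
    """
    phi = np.asarray(phi, dtype=float)
    d2 = np.sum((phi - 1.0 / 3.0) ** 2, axis=-1)
    p = np.sqrt(1.5 * d2)
    return float(p) if p.ndim == 0 else p


def purity(a: Compartment) -> float:
    """Compositional purity of a compartment, in [0, 1]."""
    return float(purity_from_fractions(a.fractions))
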
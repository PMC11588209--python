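"""Metabolic reaction networks for the cross-feeding chemostat model.

A topology is a directed acyclic graph over metabolites.  An edge
``(src, dst, w)`` says that a unit of metabolite ``src``, when degraded,
yields ``w`` units of metabolite ``dst`` (``w`` is the transfer ratio);
the remaining fraction is retained by the degrading species as growth
benefit.  Only externally supplied metabolites have nonzero supply; every
metabolite decays at a first-order rate.  One metabolite is singled out as
the measured community function (by default the end product of a linear
degradation chain).

Metabolites are indexed from 0 internally; the canonical linear chain is
``0 -> 1 -> ... -> N-1`` with the function metabolite ``N-1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MetabolicTopology", "linear_chain", "custom_topology"]


@dataclass(frozen=True)
class MetabolicTopology:
    """A reaction network: transfer edges, supply, decay, function metabolite.

    Parameters
    ----------
    n_metabolites:
        Number of tracked metabolites (>= 2).
    edges:
        Tuple of ``(src, dst, w)`` transfer edges with ``0 < w <= 1``.
    supply:
        Per-metabolite external supply rate (length ``n_metabolites``).
    decay:
        Per-metabolite first-order decay rate (positive).
    function_index:
        Index of the metabolite whose equilibrium concentration is the
        community function of interest.
    """

    n_metabolites: int
    edges: tuple[tuple[int, int, float], ...]
    supply: np.ndarray
    decay: np.ndarray
    function_index: int

    def __post_init__(self):
        N = self.n_metabolites
        if N < 2:
            raise ValueError(f"need at least 2 metabolites, got {N}")
        object.__setattr__(self, "supply", np.asarray(self.supply, dtype=float))
        object.__setattr__(self, "decay", np.asarray(self.decay, dtype=float))
        if self.supply.shape != (N,) or self.decay.shape != (N,):
            raise ValueError("supply and decay must have one entry per metabolite")
        if (self.supply < 0).any():
            raise ValueError("supply rates must be non-negative")
        if (self.decay <= 0).any():
            raise ValueError("decay rates must be positive")
        if not 0 <= self.function_index < N:
            raise ValueError(f"function_index {self.function_index} out of range")
        for s, t, w in self.edges:
            if not (0 <= s < N and 0 <= t < N):
                raise ValueError(f"edge ({s}, {t}) references unknown metabolite")
            if s == t:
                raise ValueError(f"self-loop on metabolite {s}")
            if not 0 < w <= 1:
                raise ValueError(f"transfer ratio must be in (0, 1], got {w}")
        self._check_acyclic()
        if (self.retained_fraction < -1e-12).any():
            raise ValueError("outgoing transfer ratios of a metabolite exceed 1")
        if not self._reaches_function():
            warnings.warn(
                f"function metabolite {self.function_index} is not reachable "
                "from any supplied metabolite; the function will be "
                "identically zero",
                stacklevel=3,
            )

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on the tiny metabolite graph.
        indeg = np.zeros(self.n_metabolites, dtype=int)
        for _, t, _ in self.edges:
            indeg[t] += 1
        queue = [i for i in range(self.n_metabolites) if indeg[i] == 0]
        seen = 0
        while queue:
            u = queue.pop()
            seen += 1
            for s, t, _ in self.edges:
                if s == u:
                    indeg[t] -= 1
                    if indeg[t] == 0:
                        queue.append(t)
        if seen != self.n_metabolites:
            raise ValueError("reaction network contains a cycle")

    def _reaches_function(self) -> bool:
        reach = set(np.flatnonzero(self.supply > 0))
        frontier = list(reach)
        while frontier:
            u = frontier.pop()
            for s, t, _ in self.edges:
                if s == u and t not in reach:
                    reach.add(t)
                    frontier.append(t)
        return self.function_index in reach

    @property
    def consumable(self) -> tuple[int, ...]:
        """Metabolites with an outgoing edge; each defines a functional group."""
        return tuple(sorted({s for s, _, _ in self.edges}))

    @property
    def n_groups(self) -> int:
        """Ground-truth group count: one per consumable metabolite plus the
        nonfunctional group."""
        return len(self.consumable) + 1

    @property
    def retained_fraction(self) -> np.ndarray:
        """Per-metabolite growth benefit per unit degraded, ``1 - sum(w_out)``."""
        g = np.ones(self.n_metabolites)
        for s, _, w in self.edges:
            g[s] -= w
        return g

    @property
    def is_linear_chain(self) -> bool:
        """True iff the edges form ``0 -> 1 -> ... -> N-1``, only metabolite 0
        is supplied, and the end product is the function of interest."""
        N = self.n_metabolites
        structure = sorted((s, t) for s, t, _ in self.edges)
        return (
            structure == [(i, i + 1) for i in range(N - 1)]
            and self.function_index == N - 1
            and not (self.supply[1:] > 0).any()
        )

    @property
    def chain_ratios(self) -> np.ndarray:
        """Per-step transfer ratios ``w_i`` of a linear chain."""
        if not self.is_linear_chain:
            raise ValueError("not a linear chain")
        ratios = np.empty(self.n_metabolites - 1)
        for s, _, w in self.edges:
            ratios[s] = w
        return ratios


def linear_chain(n_metabolites: int, transfer_ratio: float = 0.5, decay_rate: float = 1.0) -> MetabolicTopology:
    """The canonical linear degradation chain ``0 -> 1 -> ... -> N-1``.

    Only the first metabolite is supplied, at rate ``w^-(N-1)`` so that the
    equilibrium end-product concentration stays of order one as the chain
    length varies.  The end product is the function of interest.
    """
    N = int(n_metabolites)
    if N < 2:
        raise ValueError(f"a chain needs at least 2 metabolites, got {N}")
    w = float(transfer_ratio)
    d = float(decay_rate)
    if not 0 < w <= 1:
        raise ValueError(f"transfer ratio must be in (0, 1], got {w}")
    if d <= 0:
        raise ValueError(f"decay rate must be positive, got {d}")
    supply = np.zeros(N)
    supply[0] = w ** (-(N - 1))
    edges = tuple((i, i + 1, w) for i in range(N - 1))
    return MetabolicTopology(
        n_metabolites=N,
        edges=edges,
        supply=supply,
        decay=np.full(N, d),
        function_index=N - 1,
    )


def custom_topology(
    edges,
    supply,
    decay,
    function_index: int,
) -> MetabolicTopology:
    """Build an arbitrary acyclic topology (branched or merging chains).

    ``edges`` is an iterable of ``(src, dst, transfer_ratio)``.  The number
    of metabolites is inferred from the length of ``supply``.  If the edges
    happen to form the canonical linear chain the result is equivalent to
    :func:`linear_chain`.
    """
    supply = np.asarray(supply, dtype=float)
    decay = np.asarray(decay, dtype=float)
    N = len(supply)
    edges = tuple((int(s), int(t), float(w)) for s, t, w in edges)
    return MetabolicTopology(
        n_metabolites=N,
        edges=edges,
        supply=supply,
        decay=decay,
        function_index=int(function_index),
    )
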
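"""Partitions of species into functional groups.

A :class:`Grouping` is a partition of species indices ``0..S-1`` into ``k``
disjoint non-empty groups.  Groups are stored in canonical order (sorted by
their smallest member) so that two groupings are equal iff they induce the
same partition, regardless of label order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Grouping", "random_grouping"]


@dataclass(frozen=True)
class Grouping:
    """A partition of ``n_species`` species indices into non-empty groups."""

    groups: tuple[frozenset[int], ...]
    n_species: int

    def __post_init__(self):
        object.__setattr__(
            self, "groups", tuple(sorted((frozenset(g) for g in self.groups), key=min))
        )
        seen: set[int] = set()
        total = 0
        for g in self.groups:
            if not g:
                raise ValueError("groups must be non-empty")
            total += len(g)
            seen.update(g)
        if total != len(seen):
            raise ValueError("groups must be disjoint")
        if seen != set(range(self.n_species)):
            raise ValueError(f"groups must cover all {self.n_species} species exactly")

    @property
    def k(self) -> int:
        """Number of groups."""
        return len(self.groups)

    @classmethod
    def from_labels(cls, labels: Sequence[int] | np.ndarray) -> "Grouping":
        """Build from a per-species label vector (labels need not be dense)."""
        labels = np.asarray(labels)
        groups = [frozenset(np.flatnonzero(labels == lab).tolist()) for lab in np.unique(labels)]
        return cls(tuple(groups), n_species=len(labels))

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[int]], n_species: int | None = None) -> "Grouping":
        groups = tuple(frozenset(int(i) for i in g) for g in sets)
        if n_species is None:
            n_species = sum(len(g) for g in groups)
        return cls(groups, n_species=int(n_species))

    def to_labels(self) -> np.ndarray:
        """Per-species group labels, ``0..k-1`` in canonical group order."""
        labels = np.empty(self.n_species, dtype=np.intp)
        for lab, g in enumerate(self.groups):
            labels[list(g)] = lab
        return labels

    def member_arrays(self) -> list[np.ndarray]:
        """Sorted member indices of each group."""
        return [np.fromiter(sorted(g), dtype=np.intp) for g in self.groups]

    def relabel_species(self, permutation: np.ndarray) -> "Grouping":
        """Apply a species permutation: species ``i`` becomes ``permutation[i]``."""
        perm = np.asarray(permutation)
        return Grouping(
            tuple(frozenset(int(perm[i]) for i in g) for g in self.groups), self.n_species
        )

    def merge(self, i: int, j: int) -> "Grouping":
        """Merge groups ``i`` and ``j`` (canonical indices) into one."""
        if i == j:
            raise ValueError("cannot merge a group with itself")
        keep = [g for idx, g in enumerate(self.groups) if idx not in (i, j)]
        keep.append(self.groups[i] | self.groups[j])
        return Grouping(tuple(keep), self.n_species)

    def split(self, i: int, part: Iterable[int]) -> "Grouping":
        """Split group ``i``, moving the members in ``part`` into a new group."""
        part = frozenset(int(p) for p in part)
        g = self.groups[i]
        if not part or not part < g:
            raise ValueError("part must be a non-empty proper subset of the group")
        keep = [h for idx, h in enumerate(self.groups) if idx != i]
        keep.extend([g - part, part])
        return Grouping(tuple(keep), self.n_species)


def random_grouping(
    n_species: int, k: int, rng: np.random.Generator | int | None = None
) -> Grouping:
    """Draw a uniform random partition of ``n_species`` species into ``k``
    non-empty groups.

    The species are randomly permuted, and ``k - 1`` of the ``S - 1`` gaps in
    the permuted order are chosen (without replacement) as group boundaries.
    This is the standard control against which algorithm outputs are scored.
    """
    if not 1 <= k <= n_species:
        raise ValueError(f"need 1 <= k <= {n_species}, got k={k}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    perm = rng.permutation(n_species)
    if k == 1:
        cuts = np.array([], dtype=np.intp)
    else:
        cuts = np.sort(rng.choice(n_species - 1, size=k - 1, replace=False)) + 1
    bounds = np.concatenate([[0], cuts, [n_species]])
    groups = tuple(
        frozenset(perm[bounds[i] : bounds[i + 1]].tolist()) for i in range(k)
    )
    return Grouping(groups, n_species)
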
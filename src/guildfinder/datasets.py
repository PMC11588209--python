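"""Synthetic abundance-function datasets.

A dataset is what a grouping algorithm sees: a ``(n_samples, S)`` abundance
table ``A`` and a length-``n_samples`` function vector ``y``.  Each sample
is an independently assembled community: a random subset of species is
seeded at abundance 1, equilibrated under the chemostat dynamics, and the
final abundances and the function-metabolite concentration are corrupted
with multiplicative Gaussian measurement noise (mean 1, width ``noise``;
negative values clipped to 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_rng
from .dynamics import SolverOptions, equilibrate_batch
from .partition import Grouping
from .pool import SpeciesPool

__all__ = ["Dataset", "corrupt_measurements", "generate_dataset", "read_dataset"]

_STREAM_MEMBERS, _STREAM_NOISE = 10, 11


@dataclass(frozen=True)
class Dataset:
    """Noisy abundance table and function vector with generation metadata."""

    abundance: np.ndarray  # (n_samples, S), noisy, non-negative
    function: np.ndarray  # (n_samples,), noisy, non-negative
    noise_level: float
    subset_size: int
    seed: int | None = None
    truth: Grouping | None = None
    members: np.ndarray | None = None  # (n_samples, subset_size)
    converged: np.ndarray | None = None  # (n_samples,) bool
    clean_abundance: np.ndarray | None = None
    clean_function: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    def __post_init__(self):
        if self.abundance.ndim != 2 or self.function.shape != (self.abundance.shape[0],):
            raise ValueError("abundance must be (n_samples, S) with matching function")
        if (self.abundance < 0).any() or (self.function < 0).any():
            raise ValueError("measured values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """One row per sample: ``species_1..species_S`` then ``function``."""
        cols = [f"species_{i + 1}" for i in range(self.n_species)]
        df = pd.DataFrame(self.abundance, columns=cols)
        df["function"] = self.function
        return df

    def write_tsv(self, path: str | Path) -> None:
        """Write the table as TSV plus a ``<stem>.meta.json`` sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {
            "noise_level": self.noise_level,
            "subset_size": self.subset_size,
            "seed": self.seed,
            "n_samples": int(self.n_samples),
            "n_species": int(self.n_species),
        }
        if self.truth is not None:
            meta["truth"] = {
                str(sp + 1): int(lab) for sp, lab in enumerate(self.truth.to_labels())
            }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    def subset(self, n_samples: int) -> "Dataset":
        """The first ``n_samples`` rows as a new dataset (rows are i.i.d.)."""
        if n_samples > self.n_samples:
            raise ValueError("cannot take more samples than the dataset holds")
        sl = slice(0, n_samples)
        return Dataset(
            abundance=self.abundance[sl],
            function=self.function[sl],
            noise_level=self.noise_level,
            subset_size=self.subset_size,
            seed=self.seed,
            truth=self.truth,
            members=None if self.members is None else self.members[sl],
            converged=None if self.converged is None else self.converged[sl],
            clean_abundance=None if self.clean_abundance is None else self.clean_abundance[sl],
            clean_function=None if self.clean_function is None else self.clean_function[sl],
        )

    def with_noise(self, noise: float, seed: int | None = None) -> "Dataset":
        """Re-corrupt the retained clean measurements at a new noise level."""
        if self.clean_abundance is None or self.clean_function is None:
            raise ValueError("clean copies were not retained")
        rng = child_rng(self.seed if seed is None else seed, _STREAM_NOISE, 1)
        A = corrupt_measurements(self.clean_abundance, noise, rng)
        y = corrupt_measurements(self.clean_function, noise, rng)
        return Dataset(
            abundance=A,
            function=y,
            noise_level=noise,
            subset_size=self.subset_size,
            seed=self.seed,
            truth=self.truth,
            members=self.members,
            converged=self.converged,
            clean_abundance=self.clean_abundance,
            clean_function=self.clean_function,
        )


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset written by :meth:`Dataset.write_tsv`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "function" not in df.columns:
        raise ValueError("dataset TSV must have a 'function' column")
    y = df.pop("function").to_numpy(dtype=float)
    A = df.to_numpy(dtype=float)
    meta_path = path.with_suffix(".meta.json")
    noise, subset_size, seed, truth = 0.0, A.shape[1], None, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        noise = meta.get("noise_level", 0.0)
        subset_size = meta.get("subset_size", A.shape[1])
        seed = meta.get("seed")
        if "truth" in meta:
            labels = np.empty(A.shape[1], dtype=int)
            for sp, lab in meta["truth"].items():
                labels[int(sp) - 1] = lab
            truth = Grouping.from_labels(labels)
    return Dataset(
        abundance=A,
        function=y,
        noise_level=noise,
        subset_size=subset_size,
        seed=seed,
        truth=truth,
    )


def corrupt_measurements(
    values: np.ndarray, noise: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Multiplicative Gaussian measurement noise.

    Each entry is multiplied by an i.i.d. ``Normal(1, noise^2)`` draw;
    negative results are set to 0.  ``noise = 0`` returns a copy.
    """
    if noise < 0:
        raise ValueError(f"noise width must be >= 0, got {noise}")
    values = np.asarray(values, dtype=float)
    if noise == 0:
        return values.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    noisy = values * rng.normal(1.0, noise, size=values.shape)
    return np.where(noisy < 0, 0.0, noisy)


def generate_dataset(
    pool: SpeciesPool,
    n_samples: int,
    subset_size: int = 15,
    noise: float = 0.1,
    seed: int | None = None,
    keep_clean: bool = True,
    solver: SolverOptions | None = None,
) -> Dataset:
    """Generate ``n_samples`` independent equilibrated, noise-corrupted samples.

    Fully reproducible from ``seed``; membership draws and measurement noise
    use independent derived streams.  Clean (pre-noise) copies are retained
    by default for testing and for re-corruption at other noise levels.
    """
    if subset_size > pool.n_species:
        raise ValueError("subset_size cannot exceed the pool size")
    rng_members = child_rng(seed, _STREAM_MEMBERS)
    members = np.stack(
        [
            rng_members.choice(pool.n_species, size=subset_size, replace=False)
            for _ in range(n_samples)
        ]
    )
    states = equilibrate_batch(pool, members, solver)
    if len(states) < len(members):  # non-converged samples dropped per config
        members = np.stack([s.members for s in states])
    A_clean = np.stack([s.n for s in states])
    y_clean = np.array([s.m[pool.topology.function_index] for s in states])
    converged = np.array([s.converged for s in states])

    rng_noise = child_rng(seed, _STREAM_NOISE, 1)
    A = corrupt_measurements(A_clean, noise, rng_noise)
    y = corrupt_measurements(y_clean, noise, rng_noise)
    return Dataset(
        abundance=A,
        function=y,
        noise_level=noise,
        subset_size=subset_size,
        seed=seed,
        truth=pool.truth,
        members=members,
        converged=converged,
        clean_abundance=A_clean if keep_clean else None,
        clean_function=y_clean if keep_clean else None,
    )
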
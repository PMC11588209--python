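"""Species pools for the cross-feeding consumer-resource model.

A pool of ``S`` species is defined by three traits per species: the
degradation-rate row ``tau[mu]`` over chain metabolites (in the baseline
pool, a one-hot row: each species degrades at most one metabolite, which
defines its ground-truth functional group), a binary exploitation strategy
``sigma[mu]`` over the ``H`` generalized resources, and a maintenance cost
``chi[mu]`` that matches the expected benefit of the species' strategy up to
a small Gaussian tiebreaker:

    chi_mu = sum_i g_i * tau_mu_i + sum_a sigma_mu_a + eps * x_mu,

with ``g_i`` the fraction of degraded metabolite retained as benefit
(``1 - w`` on a chain) and ``x_mu`` standard normal.  Competition outcomes
are therefore decided by the luck of the ``eps * x_mu`` draw rather than by
an obvious generalist/specialist advantage.

Two controlled perturbations blur the ground truth: *inter-group
promiscuity* (every zero degradation rate on a consumable metabolite is
replaced by a small ``xi``) and *intra-group heterogeneity* (each species'
whole ``tau`` row is scaled by a lognormal factor ``eta_mu`` with log-mean 0
and log-sd ``sigma_tau``).  Costs are recomputed from the perturbed rates so
the cost-benefit balance is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._rng import child_rng
from .partition import Grouping
from .topology import MetabolicTopology

__all__ = [
    "GeneralizedResources",
    "SpeciesPool",
    "generate_pool",
    "apply_promiscuity",
    "apply_heterogeneity",
]

# stream ids for seed splitting
_STREAM_SIGMA, _STREAM_COST, _STREAM_ETA = 0, 1, 2


@dataclass(frozen=True)
class GeneralizedResources:
    """The ``H`` substitutable background resources species compete over.

    ``max_benefit`` (h0) is the benefit an unexploited resource provides and
    ``half_saturation`` (K) the total exploitation level at which that
    benefit is halved.  Canonical values: ``H = 15``, ``h0 = 3``, ``K = 1``.
    """

    n_resources: int = 15
    max_benefit: float = 3.0
    half_saturation: float = 1.0

    def __post_init__(self):
        if self.n_resources < 0:
            raise ValueError("n_resources must be >= 0")
        if self.max_benefit <= 0 or self.half_saturation <= 0:
            raise ValueError("max_benefit and half_saturation must be positive")


@dataclass(frozen=True)
class SpeciesPool:
    """A pool of species with a hard-coded ground-truth grouping."""

    topology: MetabolicTopology
    resources: GeneralizedResources
    tau: np.ndarray  # (S, N) degradation rates
    sigma: np.ndarray  # (S, H) binary resource use
    chi: np.ndarray  # (S,) maintenance costs
    cost_noise: float  # eps of the cost tiebreaker
    cost_draws: np.ndarray  # (S,) standard-normal x_mu
    truth: Grouping
    heterogeneity: float = 0.0  # sigma_tau actually applied
    promiscuity: float = 0.0  # xi actually applied
    seed: int | None = None

    @property
    def n_species(self) -> int:
        return self.tau.shape[0]

    def __post_init__(self):
        S, N = self.tau.shape
        if N != self.topology.n_metabolites:
            raise ValueError("tau width must match the number of metabolites")
        if self.sigma.shape != (S, self.resources.n_resources):
            raise ValueError("sigma must be (n_species, n_resources)")
        if self.chi.shape != (S,) or self.cost_draws.shape != (S,):
            raise ValueError("chi and cost_draws must have one entry per species")
        if self.truth.n_species != S:
            raise ValueError("truth grouping must cover all species")
        if (self.tau < 0).any():
            raise ValueError("degradation rates must be non-negative")


def _cost(topology: MetabolicTopology, tau, sigma, eps, draws) -> np.ndarray:
    g = topology.retained_fraction
    return tau @ g + sigma.sum(axis=1) + eps * draws


def generate_pool(
    n_species: int,
    topology: MetabolicTopology,
    resources: GeneralizedResources | None = None,
    density: float = 0.3,
    cost_noise: float = 0.01,
    seed: int | None = None,
) -> SpeciesPool:
    """Generate a baseline species pool with equal-size ground-truth groups.

    One group of specialists per consumable metabolite, plus one
    "nonfunctional" group of species not involved in the chain.  If
    ``n_species`` is not divisible by the number of groups it is adjusted to
    the nearest multiple (with a warning) so groups stay equal-sized.
    ``sigma`` entries are i.i.d. Bernoulli(``density``).
    """
    if resources is None:
        resources = GeneralizedResources()
    if not 0 <= density <= 1:
        raise ValueError(f"density must be in [0, 1], got {density}")
    n_groups = topology.n_groups
    if n_species < n_groups:
        raise ValueError(
            f"need at least one species per group: {n_species} < {n_groups}"
        )
    S = int(n_groups * round(n_species / n_groups))
    S = max(S, n_groups)
    if S != n_species:
        warnings.warn(
            f"adjusted n_species from {n_species} to {S} to keep "
            f"{n_groups} equal-sized groups",
            stacklevel=2,
        )
    per = S // n_groups
    N = topology.n_metabolites

    labels = np.repeat(np.arange(n_groups), per)
    tau = np.zeros((S, N))
    for gi, met in enumerate(topology.consumable):
        tau[labels == gi, met] = 1.0
    # the last group is nonfunctional: all-zero tau rows

    rng_sigma = child_rng(seed, _STREAM_SIGMA)
    rng_cost = child_rng(seed, _STREAM_COST)
    sigma = (rng_sigma.random((S, resources.n_resources)) < density).astype(float)
    # A species with no traits at all (idle in the chain and using no
    # resources) has cost eps*x, which is negative for half the draws, and
    # no feedback limiting its growth: its abundance would diverge.  Such
    # trait-less species are degenerate, so chain-idle species redraw their
    # resource row until it is non-empty (Bernoulli(density) conditioned on
    # at least one resource).
    if density > 0 and resources.n_resources > 0:
        idle = tau.sum(axis=1) == 0
        for mu in np.flatnonzero(idle):
            while sigma[mu].sum() == 0:
                sigma[mu] = rng_sigma.random(resources.n_resources) < density
    draws = rng_cost.standard_normal(S)
    chi = _cost(topology, tau, sigma, cost_noise, draws)
    return SpeciesPool(
        topology=topology,
        resources=resources,
        tau=tau,
        sigma=sigma,
        chi=chi,
        cost_noise=cost_noise,
        cost_draws=draws,
        truth=Grouping.from_labels(labels),
        seed=seed,
    )


def apply_promiscuity(pool: SpeciesPool, xi: float) -> SpeciesPool:
    """Give every species a small rate ``xi`` for reactions outside its group.

    Every zero ``tau[mu, i]`` on a consumable metabolite becomes ``xi``;
    nonzero entries (the group-defining reactions) are untouched, as are
    metabolites nothing can consume (e.g. the end product).  Ground-truth
    labels are unchanged; costs are recomputed from the new rates.
    """
    if xi < 0:
        raise ValueError(f"promiscuity must be >= 0, got {xi}")
    if xi == 0:
        return pool
    tau = pool.tau.copy()
    cols = list(pool.topology.consumable)
    block = tau[:, cols]
    block[block == 0] = xi
    tau[:, cols] = block
    chi = _cost(pool.topology, tau, pool.sigma, pool.cost_noise, pool.cost_draws)
    return replace(pool, tau=tau, chi=chi, promiscuity=xi)


def apply_heterogeneity(
    pool: SpeciesPool, sigma_tau: float, seed: int | None = None
) -> SpeciesPool:
    """Scale each species' degradation rates by a lognormal factor.

    ``log eta_mu ~ Normal(0, sigma_tau^2)`` applied as a global factor to the
    species' whole ``tau`` row (so post-promiscuity off-group rates scale
    too).  Labels unchanged; costs recomputed.
    """
    if sigma_tau < 0:
        raise ValueError(f"heterogeneity must be >= 0, got {sigma_tau}")
    if sigma_tau == 0:
        return pool
    rng = child_rng(seed, _STREAM_ETA)
    eta = rng.lognormal(mean=0.0, sigma=sigma_tau, size=pool.n_species)
    tau = pool.tau * eta[:, None]
    chi = _cost(pool.topology, tau, pool.sigma, pool.cost_noise, pool.cost_draws)
    return replace(pool, tau=tau, chi=chi, heterogeneity=sigma_tau)
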
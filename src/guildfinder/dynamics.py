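"""Chemostat dynamics of cross-feeding communities and their equilibria.

The state of a community is the vector of species abundances ``n`` and
metabolite concentrations ``m``.  Species grow on the benefit retained from
degrading chain metabolites plus the availability of generalized resources,
minus a fixed maintenance cost:

    dn_mu/dt = n_mu [ sum_i g_i tau_mu_i m_i + sum_a sigma_mu_a h_a - chi_mu ]
    dm_i/dt  = R_i + sum_{edges j->i} w_e m_j T_j - m_i T_i - d_i m_i
    h_a      = h0 / (1 + sum_nu sigma_nu_a n_nu / K)

with ``T_i = sum_mu tau_mu_i n_mu`` the total degradation pressure on
metabolite ``i`` and ``g_i`` the retained fraction (``1 - w`` on a chain).
``h_a`` is an instantaneous (algebraic) function of the abundances, not a
dynamical variable.

On a linear chain the equilibrium end-product concentration has a closed
form in the group abundances alone:

    m_N = (R_1 / d_N) * prod_i [ w_i T_i / (T_i + d_i) ],

which is manifestly nonlinear and vanishes whenever any upstream group is
absent.  :func:`closed_form_function` implements it and serves as an
independent oracle for the ODE integration.

Synthetic samples are produced by seeding a random subset of species at
abundance 1 (metabolites also start at 1) and integrating to approximate
equilibrium.  Because samples are independent, :func:`equilibrate_batch`
integrates many communities as one block-diagonal system, freezing each
sample as it converges; this is numerically identical per sample and far
faster than a Python loop over samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import ode

from .pool import SpeciesPool
from .topology import MetabolicTopology

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "CommunityState",
    "SolverOptions",
    "resource_availability",
    "dynamics_rhs",
    "equilibrate",
    "equilibrate_batch",
    "closed_form_function",
]


@dataclass(frozen=True)
class CommunityState:
    """Abundances and metabolite concentrations of one community sample."""

    n: np.ndarray  # (S,) species abundances; non-members are exactly 0
    m: np.ndarray  # (N,) metabolite concentrations
    members: np.ndarray  # indices of species seeded in this sample
    converged: bool = True


@dataclass(frozen=True)
class SolverOptions:
    """Integration and convergence controls for equilibration.

    The system is integrated in windows of ``window`` time units until the
    normalized residual ``max |dX/dt| / (|X| + 1)`` drops below
    ``convergence_tol``, or ``max_time`` is reached (in which case the
    sample is flagged as non-converged and, by default, kept).
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    window: float = 500.0
    max_time: float = 1e4
    convergence_tol: float = 1e-6
    on_nonconverged: str = "keep"  # keep | drop | error

    def __post_init__(self):
        if self.on_nonconverged not in ("keep", "drop", "error"):
            raise ValueError("on_nonconverged must be keep, drop or error")


def resource_availability(pool: SpeciesPool, n: np.ndarray) -> np.ndarray:
    """Instantaneous availability ``h_a`` of each generalized resource.

    ``h_a = h0 / (1 + sum_nu sigma_nu_a n_nu / K)``: in (0, h0], equal to h0
    with no consumers and approaching 0 as total exploitation diverges.
    """
    n = np.asarray(n, dtype=float)
    if (n < 0).any():
        raise ValueError("abundances must be non-negative")
    res = pool.resources
    exploitation = pool.sigma.T @ n
    return res.max_benefit / (1.0 + exploitation / res.half_saturation)


def dynamics_rhs(
    n: np.ndarray, m: np.ndarray, pool: SpeciesPool
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives ``(dn/dt, dm/dt)`` of the full community state.

    Reference (pure numpy) implementation over the whole pool; the batched
    integrator uses a compiled kernel over sample members only, and the two
    are cross-checked in the test suite.
    """
    topo = pool.topology
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    if n.shape != (pool.n_species,) or m.shape != (topo.n_metabolites,):
        raise ValueError("state dimensions do not match the pool")
    h = resource_availability(pool, n)
    g = topo.retained_fraction
    growth = pool.tau @ (g * m) + pool.sigma @ h - pool.chi
    dn = n * growth
    T = pool.tau.T @ n
    dm = topo.supply - m * T - topo.decay * m
    for src, dst, w in topo.edges:
        dm[dst] += w * m[src] * T[src]
    return dn, dm


if _HAVE_NUMBA:

    @njit(cache=True)
    def _batch_rhs_kernel(z, out, tau_b, sig_b, chi_b, supply, decay, g, h0, K, esrc, edst, ew):
        nB, nb, N = tau_b.shape[0], tau_b.shape[1], supply.shape[0]
        H = sig_b.shape[2]
        nE = esrc.shape[0]
        for b in range(nB):
            base = b * (nb + N)
            m = z[base + nb : base + nb + N]
            T = np.zeros(N)
            for i in range(N):
                acc = 0.0
                for s in range(nb):
                    acc += tau_b[b, s, i] * z[base + s]
                T[i] = acc
            h = np.empty(H)
            for a in range(H):
                e = 0.0
                for s in range(nb):
                    e += sig_b[b, s, a] * z[base + s]
                h[a] = h0 / (1.0 + e / K)
            for s in range(nb):
                gr = -chi_b[b, s]
                for i in range(N):
                    gr += tau_b[b, s, i] * g[i] * m[i]
                for a in range(H):
                    gr += sig_b[b, s, a] * h[a]
                out[base + s] = z[base + s] * gr
            for i in range(N):
                out[base + nb + i] = supply[i] - m[i] * T[i] - decay[i] * m[i]
            for e in range(nE):
                out[base + nb + edst[e]] += ew[e] * m[esrc[e]] * T[esrc[e]]


def _batch_rhs_numpy(z, out, tau_b, sig_b, chi_b, supply, decay, g, h0, K, esrc, edst, ew):
    nB, nb, N = tau_b.shape[0], tau_b.shape[1], supply.shape[0]
    zz = z.reshape(nB, nb + N)
    n, m = zz[:, :nb], zz[:, nb:]
    h = h0 / (1.0 + np.einsum("bsa,bs->ba", sig_b, n) / K)
    T = np.einsum("bsi,bs->bi", tau_b, n)
    dn = n * (np.einsum("bsi,i,bi->bs", tau_b, g, m) + np.einsum("bsa,ba->bs", sig_b, h) - chi_b)
    dm = supply - m * T - decay * m
    for e in range(len(esrc)):
        dm[:, edst[e]] += ew[e] * m[:, esrc[e]] * T[:, esrc[e]]
    o = out.reshape(nB, nb + N)
    o[:, :nb] = dn
    o[:, nb:] = dm


def _topology_args(pool: SpeciesPool):
    topo = pool.topology
    res = pool.resources
    esrc = np.array([e[0] for e in topo.edges], dtype=np.intp)
    edst = np.array([e[1] for e in topo.edges], dtype=np.intp)
    ew = np.array([e[2] for e in topo.edges], dtype=float)
    return (
        topo.supply,
        topo.decay,
        topo.retained_fraction,
        res.max_benefit,
        res.half_saturation,
        esrc,
        edst,
        ew,
    )


def equilibrate_batch(
    pool: SpeciesPool,
    members: np.ndarray,
    options: SolverOptions | None = None,
) -> list[CommunityState]:
    """Equilibrate many independent communities of the same size at once.

    ``members`` is an integer array of shape ``(n_communities, subset_size)``
    giving the species seeded in each community.  All initial abundances and
    metabolite concentrations are 1.  Returns one :class:`CommunityState`
    per row, with non-member abundances exactly 0 and tiny negative solver
    artifacts clipped to 0.
    """
    if options is None:
        options = SolverOptions()
    members = np.atleast_2d(np.asarray(members, dtype=np.intp))
    B, nb = members.shape
    N = pool.topology.n_metabolites
    dim = nb + N
    tau_b = np.ascontiguousarray(pool.tau[members])
    sig_b = np.ascontiguousarray(pool.sigma[members])
    chi_b = np.ascontiguousarray(pool.chi[members])
    kernel = _batch_rhs_kernel if _HAVE_NUMBA else _batch_rhs_numpy
    topo_args = _topology_args(pool)

    z = np.ones(B * dim)
    live = np.arange(B)
    final = np.empty((B, dim))
    converged = np.zeros(B, dtype=bool)
    t = 0.0
    while t < options.max_time and len(live):
        tb, sb, cb = tau_b[live], sig_b[live], chi_b[live]

        def rhs(_t, zv):
            out = np.empty_like(zv)
            kernel(zv, out, tb, sb, cb, *topo_args)
            return out

        solver = ode(rhs)
        solver.set_integrator(
            "dop853", rtol=options.rtol, atol=options.atol, nsteps=10**6
        )
        solver.set_initial_value(z, t)
        z = solver.integrate(t + options.window)
        if not solver.successful():
            raise RuntimeError("ODE integration failed")
        t += options.window
        zz = z.reshape(len(live), dim)
        dz = rhs(t, z).reshape(len(live), dim)
        done = (np.abs(dz) / (np.abs(zz) + 1.0)).max(axis=1) < options.convergence_tol
        final[live[done]] = zz[done]
        converged[live[done]] = True
        live = live[~done]
        z = zz[~done].ravel()
    if len(live):
        final[live] = z.reshape(len(live), dim)
        if options.on_nonconverged == "error":
            raise RuntimeError(
                f"{len(live)} of {B} communities did not converge "
                f"within t = {options.max_time}"
            )

    states = []
    for b in range(B):
        if not converged[b] and options.on_nonconverged == "drop":
            continue
        n_full = np.zeros(pool.n_species)
        nb_vals = final[b, :nb]
        nb_vals = np.where(nb_vals < 0, 0.0, nb_vals)  # clip solver artifacts
        n_full[members[b]] = nb_vals
        m = np.where(final[b, nb:] < 0, 0.0, final[b, nb:])
        states.append(
            CommunityState(n=n_full, m=m, members=members[b].copy(), converged=bool(converged[b]))
        )
    return states


def equilibrate(
    pool: SpeciesPool,
    members,
    options: SolverOptions | None = None,
) -> CommunityState:
    """Equilibrate a single community seeded with the given species.

    An empty member set yields the trivial fixed point ``n = 0``,
    ``m_i = R_i / d_i`` for supplied metabolites and 0 downstream.
    """
    members = np.asarray(sorted(members), dtype=np.intp)
    topo = pool.topology
    if len(members) == 0:
        return CommunityState(
            n=np.zeros(pool.n_species),
            m=topo.supply / topo.decay,
            members=members,
            converged=True,
        )
    if members.min() < 0 or members.max() >= pool.n_species:
        raise ValueError("member indices out of range")
    return equilibrate_batch(pool, members[None, :], options)[0]


def closed_form_function(T, topology: MetabolicTopology) -> np.ndarray | float:
    """Equilibrium end-product concentration of a linear chain.

    ``T`` holds the abundances of the ``N - 1`` functional groups (group
    ``i`` degrades metabolite ``i``); broadcasting over leading axes is
    supported.  Returns ``(R_1 / d_N) * prod_i w_i T_i / (T_i + d_i)``:
    zero whenever any group is absent, saturating at ``R_1 prod w_i / d_N``
    as all groups become large.  Only defined for linear chains; use the ODE
    for any other topology.
    """
    if not topology.is_linear_chain:
        raise ValueError("closed form only applies to a linear chain topology")
    T = np.asarray(T, dtype=float)
    N = topology.n_metabolites
    if T.shape[-1] != N - 1:
        raise ValueError(f"expected {N - 1} group abundances, got {T.shape[-1]}")
    if (T < 0).any():
        raise ValueError("group abundances must be non-negative")
    w = topology.chain_ratios
    d = topology.decay
    factors = w * T / (T + d[:-1])
    out = topology.supply[0] / d[-1] * np.prod(factors, axis=-1)
    return float(out) if out.ndim == 0 else out
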
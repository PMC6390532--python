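"""MCMC over site allocations, mixture weights, mutation parameters and
branch lengths.

Two allocation samplers are provided. The collapsed (Polya-urn) sampler
integrates the mixture weights out under a flat Dirichlet prior: site
n's component is redrawn with probability proportional to
(eta_k + 1) p(D_n | theta, psi^(k)), where eta_k counts the other
sites currently allocated to component k. The weighted sampler keeps
the weights explicit — w | z is a conjugate Dirichlet(1 + eta) draw and
each site is then reallocated independently with probability
proportional to w_k p(D_n | theta, psi^(k)). The two demarginalize the
same posterior over allocations; the weighted one is the default since
sites update independently (parallelizable).

Mutation parameters and branch lengths, when free, move by standard
multiplicative Metropolis-Hastings proposals (simplex profile move for
rho/phi under flat Dirichlet priors; per-branch scaling under i.i.d.
exponential priors). Proposal tunings adapt toward ~25% acceptance
during burn-in only and are frozen afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .likelihood import LikelihoodEngine
from .mutation import MutationParams

TARGET_ACCEPTANCE = 0.25
MAX_STORED_DRAWS = 2000


@dataclass
class AllocationState:
    """Site-to-component allocation vector z with occupancy counts eta."""

    z: np.ndarray
    eta: np.ndarray

    @classmethod
    def from_z(cls, z: np.ndarray, K: int) -> "AllocationState":
        z = np.asarray(z, dtype=np.int64)
        if z.size and (z.min() < 0 or z.max() >= K):
            raise ValueError("allocation indices out of range")
        eta = np.bincount(z, minlength=K)
        return cls(z=z, eta=eta)

    def check(self) -> None:
        if not np.array_equal(self.eta, np.bincount(self.z, minlength=self.eta.size)):
            raise RuntimeError("allocation counts inconsistent with z")


@dataclass
class ChainState:
    """Full parameter state of one chain."""

    allocation: AllocationState
    mut: MutationParams
    edge_lengths: np.ndarray
    weights: np.ndarray | None = None
    logliks: np.ndarray | None = None  # N x K table under current (mut, lengths)

    @property
    def site_logliks(self) -> np.ndarray:
        n = self.allocation.z.size
        return self.logliks[np.arange(n), self.allocation.z]

    @property
    def total_loglik(self) -> float:
        return float(self.site_logliks.sum())


@dataclass
class McmcConfig:
    """Chain settings.

    sampler : "weighted" (default, parallelizable) or "gibbs" (collapsed).
    n_sweeps : total sweeps; burn_in defaults to the first 20%.
    thin : stored-draw spacing; by default chosen so at most 2000
        post-burn-in draws are kept.
    update_mutation / update_branch_lengths : sample (rho, phi) and
        branch lengths rather than fixing them.
    """

    sampler: str = "weighted"
    n_sweeps: int = 1000
    burn_in: int | None = None
    thin: int | None = None
    update_mutation: bool = False
    update_branch_lengths: bool = False
    bl_prior_mean: float = 0.1
    lambda_mut: float = 0.5
    lambda_bl: float = 0.7
    mutation_params: MutationParams | None = None

    def resolve(self) -> tuple[int, int]:
        if self.sampler not in ("weighted", "gibbs"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        burn = self.burn_in if self.burn_in is not None else self.n_sweeps // 5
        if burn >= self.n_sweeps:
            raise ValueError("burn-in must be shorter than the chain")
        kept = self.n_sweeps - burn
        thin = self.thin if self.thin is not None else max(1, int(np.ceil(kept / MAX_STORED_DRAWS)))
        return burn, thin


@dataclass
class McmcTrace:
    """Stored post-burn-in draws and chain metadata."""

    z: np.ndarray  # (M, N)
    loglik: np.ndarray  # (M,)
    weights: np.ndarray | None  # (M, K) for the weighted sampler
    rho: np.ndarray  # (M, 6)
    phi: np.ndarray  # (M, 4)
    sweep_index: np.ndarray  # (M,)
    K: int
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.z.shape[0]

    @property
    def n_sites(self) -> int:
        return self.z.shape[1]

    def write_tsv(self, path: str | Path) -> None:
        """One row per stored draw: sweep, loglik, theta summary, RLE'd z."""
        with open(path, "w") as fh:
            fh.write("sweep\tloglik\trho\tphi\tz_rle\n")
            for m in range(self.n_draws):
                rho = ",".join(repr(x) for x in self.rho[m])
                phi = ",".join(repr(x) for x in self.phi[m])
                fh.write(
                    f"{self.sweep_index[m]}\t{self.loglik[m]!r}\t{rho}\t{phi}\t"
                    f"{_rle(self.z[m])}\n"
                )

    def write_meta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _rle(z: np.ndarray) -> str:
    """Run-length encode an allocation vector as 'component*count' segments."""
    parts = []
    start = 0
    for i in range(1, len(z) + 1):
        if i == len(z) or z[i] != z[start]:
            parts.append(f"{z[start]}*{i - start}")
            start = i
    return ",".join(parts)


def rle_decode(s: str) -> np.ndarray:
    out = []
    for seg in s.split(","):
        comp, count = seg.split("*")
        out.extend([int(comp)] * int(count))
    return np.array(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# allocation sweeps

def _relative_likelihoods(logliks: np.ndarray) -> np.ndarray:
    """Per-site likelihoods rescaled by the row maximum (ratios preserved)."""
    m = logliks.max(axis=1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return np.exp(logliks - m)


def gibbs_allocation_sweep(
    state: AllocationState, logliks: np.ndarray, rng: np.random.Generator
) -> AllocationState:
    """Collapsed (Polya-urn) sweep: sequential site updates.

    For each site in turn the count of its current component is
    decremented, a new component is drawn with probability proportional
    to (eta_k + 1) p(D_n | theta, psi^(k)) using the current counts,
    and the chosen count is incremented. The sequential dependence is
    what integrates the weights out exactly.
    """
    state.check()
    rel = _relative_likelihoods(logliks)
    z, eta = state.z, state.eta
    n_sites = z.size
    u = rng.random(n_sites)
    for n in range(n_sites):
        eta[z[n]] -= 1
        w = (eta + 1.0) * rel[n]
        cum = np.cumsum(w)
        k = int(np.searchsorted(cum, u[n] * cum[-1], side="right"))
        k = min(k, eta.size - 1)
        z[n] = k
        eta[k] += 1
    return state


def weighted_allocation_sweep(
    state: AllocationState,
    logliks: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> AllocationState:
    """Weighted sweep: every site reallocated independently given w.

    Probability of component k at site n is proportional to
    w_k p(D_n | theta, psi^(k)); the update is vectorized over sites and
    its result does not depend on site processing order.
    """
    if weights is None:
        raise ValueError("weighted sampler requires mixture weights")
    rel = _relative_likelihoods(logliks)
    p = rel * weights[None, :]
    cum = np.cumsum(p, axis=1)
    u = rng.random(state.z.size) * cum[:, -1]
    z = (u[:, None] >= cum).sum(axis=1).astype(np.int64)
    np.minimum(z, weights.size - 1, out=z)
    state.z = z
    state.eta = np.bincount(z, minlength=weights.size)
    return state


def update_weights(eta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Conjugate weight draw: w ~ Dirichlet(1 + eta) under the flat prior.

    Together with the independent per-site reallocation this reproduces,
    marginally over w, the same allocation law as the collapsed sampler.
    """
    return rng.dirichlet(1.0 + np.asarray(eta, dtype=float))


# ---------------------------------------------------------------------------
# parameter moves

def _simplex_move(
    x: np.ndarray, lam: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Multiply one coordinate by exp(lam (U - 1/2)) and renormalize.

    Returns the proposal and the log Hastings ratio log f - K log T,
    where T is the renormalization total (the Jacobian of the move).
    """
    m = int(rng.integers(x.size))
    logf = lam * (rng.random() - 0.5)
    y = x.copy()
    y[m] *= np.exp(logf)
    T = y.sum()
    return y / T, logf - x.size * np.log(T)


def update_mutation_params(
    state: ChainState,
    engine: LikelihoodEngine | None,
    rng: np.random.Generator,
    lam: float = 0.5,
) -> tuple[ChainState, bool]:
    """One MH update of (rho, phi) under flat Dirichlet priors.

    ``engine=None`` targets the prior alone (constant likelihood), used
    for move validation. Returns the state and whether the proposal was
    accepted. Accepted moves refresh the cached N x K table.
    """
    which = int(rng.integers(2))  # 0: rho, 1: phi
    if which == 0:
        new_rho, log_h = _simplex_move(state.mut.rho, lam, rng)
        proposal = MutationParams(rho=new_rho, phi=state.mut.phi)
    else:
        new_phi, log_h = _simplex_move(state.mut.phi, lam, rng)
        proposal = MutationParams(rho=state.mut.rho, phi=new_phi)
    if engine is None:
        delta_ll, new_table = 0.0, None
    else:
        new_table = engine.table(proposal, state.edge_lengths)
        n = state.allocation.z.size
        new_ll = float(new_table[np.arange(n), state.allocation.z].sum())
        delta_ll = new_ll - state.total_loglik
    if np.log(rng.random()) < delta_ll + log_h:
        state.mut = proposal
        if new_table is not None:
            state.logliks = new_table
        return state, True
    return state, False


def update_branch_lengths(
    state: ChainState,
    engine: LikelihoodEngine | None,
    rng: np.random.Generator,
    lam: float = 0.7,
    prior_mean: float = 0.1,
) -> tuple[ChainState, float]:
    """Per-branch multiplicative MH moves under i.i.d. exponential priors.

    Each edge is proposed l' = l exp(lam (U - 1/2)) in turn (log
    Hastings ratio log(l'/l)). Returns the state and the acceptance
    fraction over edges.
    """
    accepted = 0
    lengths = state.edge_lengths
    for e in range(lengths.size):
        old = lengths[e]
        if old == 0.0:
            continue
        logf = lam * (rng.random() - 0.5)
        new = old * np.exp(logf)
        log_prior = -(new - old) / prior_mean
        if engine is None:
            delta_ll, new_table = 0.0, None
        else:
            trial = lengths.copy()
            trial[e] = new
            new_table = engine.table(state.mut, trial)
            n = state.allocation.z.size
            new_ll = float(new_table[np.arange(n), state.allocation.z].sum())
            delta_ll = new_ll - state.total_loglik
        if np.log(rng.random()) < delta_ll + log_prior + logf:
            lengths[e] = new
            if new_table is not None:
                state.logliks = new_table
            accepted += 1
    return state, accepted / max(1, lengths.size)


def _adapt(lam: float, acc_rate: float) -> float:
    """Robbins-Monro-flavoured tuning toward the target acceptance."""
    return float(np.clip(lam * np.exp(0.5 * (acc_rate - TARGET_ACCEPTANCE)), 1e-3, 20.0))


# ---------------------------------------------------------------------------
# orchestration

def run_chain(
    aln,
    tree,
    profiles,
    config: McmcConfig,
    rng: np.random.Generator | int,
) -> McmcTrace:
    """Run one MCMC chain and return the thinned post-burn-in trace.

    Allocation sweeps alternate with any enabled parameter updates; the
    likelihood table is recomputed only when theta moves. Fully
    reproducible from the seed.
    """
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = None
    burn, thin = config.resolve()
    engine = LikelihoodEngine(aln, tree, profiles)
    K = profiles.K
    n_sites = aln.n_sites

    mut = config.mutation_params or MutationParams.uniform()
    edge_lengths = engine.arrays.edge_lengths
    z0 = rng.integers(K, size=n_sites)
    state = ChainState(
        allocation=AllocationState.from_z(z0, K),
        mut=mut,
        edge_lengths=edge_lengths,
        weights=np.full(K, 1.0 / K),
    )
    state.logliks = engine.table(state.mut, state.edge_lengths)

    lam_mut, lam_bl = config.lambda_mut, config.lambda_bl
    mut_acc: list[bool] = []
    zs, lls, ws, rhos, phis, sweeps = [], [], [], [], [], []
    for sweep in range(config.n_sweeps):
        if config.update_mutation:
            state, acc = update_mutation_params(state, engine, rng, lam_mut)
            mut_acc.append(acc)
            if sweep < burn and len(mut_acc) >= 20:
                lam_mut = _adapt(lam_mut, float(np.mean(mut_acc[-20:])))
        if config.update_branch_lengths:
            state, acc_rate = update_branch_lengths(
                state, engine, rng, lam_bl, config.bl_prior_mean
            )
            if sweep < burn:
                lam_bl = _adapt(lam_bl, acc_rate)
        if config.sampler == "weighted":
            state.weights = update_weights(state.allocation.eta, rng)
            weighted_allocation_sweep(state.allocation, state.logliks, state.weights, rng)
        else:
            gibbs_allocation_sweep(state.allocation, state.logliks, rng)
        if sweep >= burn and (sweep - burn) % thin == 0:
            zs.append(state.allocation.z.copy())
            lls.append(state.total_loglik)
            ws.append(state.weights.copy() if state.weights is not None else None)
            rhos.append(state.mut.rho.copy())
            phis.append(state.mut.phi.copy())
            sweeps.append(sweep)

    meta = {
        "seed": seed,
        "sampler": config.sampler,
        "n_sweeps": config.n_sweeps,
        "burn_in": burn,
        "thin": thin,
        "n_sites": n_sites,
        "K": K,
        "n_draws": len(zs),
        "update_mutation": config.update_mutation,
        "update_branch_lengths": config.update_branch_lengths,
    }
    return McmcTrace(
        z=np.array(zs, dtype=np.int64),
        loglik=np.array(lls),
        weights=np.array([w for w in ws]) if ws and ws[0] is not None else None,
        rho=np.array(rhos),
        phi=np.array(phis),
        sweep_index=np.array(sweeps),
        K=K,
        meta=meta,
    )
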
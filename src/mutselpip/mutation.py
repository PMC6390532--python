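"""Mutation-selection codon substitution generators.

Per mixture component k, the 61x61 infinitesimal rate matrix is

    Q_ij = mu_ij * S_ij / (1 - exp(-S_ij))          (single-nt changes)

with mu_ij = rho_{i_c j_c} * phi_{j_c} a GTR-style nucleotide mutation
kernel (rho: six exchangeabilities over unordered pairs, sum 1; phi:
four target-nucleotide propensities, sum 1), and the scaled selection
coefficient S_ij = ln psi_f(j) - ln psi_f(i) from the component's amino
acid profile psi. Multi-nucleotide changes and changes into stop codons
have rate 0. The process is reversible with stationary distribution
pi_i proportional to phi_{i1} phi_{i2} phi_{i3} psi_f(i).

By default each generator is rescaled so that the expected substitution
rate at its own stationary distribution is 1, making branch lengths
interpretable as expected substitutions per codon site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm as _dense_expm

from .codons import GeneticCode, UNIVERSAL_CODE
from .profiles import AminoAcidProfile

# Unordered nucleotide pairs for the six exchangeabilities, A<C<G<T order.
NUC_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class MutationParams:
    """Nucleotide-level mutation parameters (rho, phi).

    rho : 6 exchangeabilities over unordered pairs AC, AG, AT, CG, CT, GT
        (non-negative, sum 1).
    phi : 4 nucleotide propensities over A, C, G, T (positive, sum 1).
    """

    rho: np.ndarray
    phi: np.ndarray

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if rho.shape != (6,) or phi.shape != (4,):
            raise ValueError("rho must have 6 entries and phi 4")
        if np.any(rho < 0) or abs(rho.sum() - 1.0) > 1e-9:
            raise ValueError("rho must be non-negative and sum to 1")
        if np.any(phi <= 0) or abs(phi.sum() - 1.0) > 1e-9:
            raise ValueError("phi must be positive and sum to 1")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "phi", phi)

    @classmethod
    def uniform(cls) -> "MutationParams":
        return cls(rho=np.full(6, 1 / 6), phi=np.full(4, 0.25))

    @classmethod
    def random(cls, rng: np.random.Generator) -> "MutationParams":
        return cls(rho=rng.dirichlet(np.ones(6)), phi=rng.dirichlet(np.ones(4)))

    def rho_matrix(self) -> np.ndarray:
        """Symmetric 4x4 exchangeability matrix (zero diagonal)."""
        m = np.zeros((4, 4))
        for r, (a, b) in zip(self.rho, NUC_PAIRS):
            m[a, b] = m[b, a] = r
        return m


def selection_coefficient(profile: AminoAcidProfile, i: int, j: int,
                          code: GeneticCode = UNIVERSAL_CODE) -> float:
    """Scaled selection coefficient S_ij = ln psi_f(j) - ln psi_f(i).

    Antisymmetric in (i, j); zero for synonymous pairs.
    """
    lp = profile.log_psi
    return float(lp[code.aa_index[j]] - lp[code.aa_index[i]])


def fixation_factor(S: np.ndarray | float) -> np.ndarray | float:
    """Relative fixation rate S / (1 - exp(-S)).

    Continuous at S = 0 with value 1 (a second-order series 1 + S/2 is
    used for |S| < 1e-8); strictly positive; satisfies the reversibility
    identity h(S) = exp(S) * h(-S).
    """
    S = np.asarray(S, dtype=float)
    small = np.abs(S) < 1e-8
    safe = np.where(small, 1.0, S)
    out = np.where(small, 1.0 + S / 2.0, safe / -np.expm1(-safe))
    return out if out.ndim else float(out)


@dataclass
class ComponentGenerator:
    """A normalized 61x61 rate matrix for one mixture component.

    Carries its stationary distribution ``pi`` (closed form) and the
    normalization constant ``scale`` by which the raw rates were divided
    (expected substitutions per unit time at stationarity before
    rescaling).
    """

    Q: np.ndarray
    pi: np.ndarray
    scale: float
    component_index: int = -1
    _eig: tuple[np.ndarray, np.ndarray] | None = None  # cached symmetric eigendecomposition

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of the pi-symmetrized generator.

        Returns (eigenvalues, V) with Q = D^-1 V diag(vals) V^T D where
        D = diag(sqrt(pi)); valid because the process is reversible.
        """
        if self._eig is None:
            d = np.sqrt(self.pi)
            B = (self.Q * d[:, None]) / d[None, :]
            B = 0.5 * (B + B.T)  # symmetrize away rounding noise
            vals, V = np.linalg.eigh(B)
            self._eig = (vals, V)
        return self._eig


def stationary_closed_form(mut: MutationParams, profile: AminoAcidProfile,
                           code: GeneticCode = UNIVERSAL_CODE) -> np.ndarray:
    """pi_i proportional to phi_{i1} phi_{i2} phi_{i3} psi_f(i), normalized."""
    n = code.n_codons
    pi = np.empty(n)
    for i in range(n):
        p = profile.psi[code.aa_index[i]]
        for c in range(3):
            p *= mut.phi[code.nucleotide_at(i, c)]
        pi[i] = p
    return pi / pi.sum()


def build_generator(mut: MutationParams, profile: AminoAcidProfile,
                    code: GeneticCode = UNIVERSAL_CODE,
                    component_index: int = -1,
                    normalize: bool = True) -> ComponentGenerator:
    """Assemble the mutation-selection rate matrix for one component.

    With ``normalize=True`` (default) the matrix is divided by its
    expected total rate at stationarity so that -sum_i pi_i Q_ii = 1;
    the raw-rate option is kept for cross-checks against other software.
    """
    n = code.n_codons
    Q = np.zeros((n, n))
    rho_m = mut.rho_matrix()
    lp = profile.log_psi
    for i, j, c, a, b in code.neighbor_table():
        S = lp[code.aa_index[j]] - lp[code.aa_index[i]]
        Q[i, j] = rho_m[a, b] * mut.phi[b] * fixation_factor(S)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = stationary_closed_form(mut, profile, code)
    scale = float(-np.dot(pi, np.diag(Q)))
    if normalize:
        Q = Q / scale
    return ComponentGenerator(Q=Q, pi=pi, scale=scale, component_index=component_index)


def stationary_distribution(gen: ComponentGenerator) -> np.ndarray:
    """Stationary distribution of the generator (normalized left null vector)."""
    return gen.pi.copy()


def stationary_nullspace(Q: np.ndarray) -> np.ndarray:
    """Numerical left null vector of Q (independent oracle for the closed form)."""
    vals, vecs = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(vals)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()


def transition_probabilities(gen: ComponentGenerator, t: float) -> np.ndarray:
    """Transition matrix exp(Q t) for branch length t >= 0.

    Computed from the reversibility-based symmetric eigendecomposition;
    rows sum to 1 and tiny negative entries from rounding are clamped
    to 0.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if t == 0:
        return np.eye(gen.Q.shape[0])
    vals, V = gen.eigensystem()
    d = np.sqrt(gen.pi)
    core = (V * np.exp(vals * t)) @ V.T
    P = (core / d[:, None]) * d[None, :]
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def transition_probabilities_expm(gen: ComponentGenerator, t: float) -> np.ndarray:
    """Dense scaling-and-squaring fallback, used to validate the eigendecomposition path."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    return _dense_expm(gen.Q * t)
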
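# Methods

## Model

The substitution process at each codon site is a continuous-time Markov
chain on the 61 sense codons of the universal genetic code (stops
TAA/TAG/TGA excluded; codons ordered lexicographically over A<C<G<T,
amino acids alphabetically by one-letter code). Rates for
single-nucleotide changes are the product of a mutation term and a
fixation term:

    Q_ij = rho_{i_c j_c} * phi_{j_c} * S_ij / (1 - exp(-S_ij)),
    S_ij = ln psi_{f(j)} - ln psi_{f(i)}.

Multi-nucleotide changes and changes into stop codons have rate zero.
The six exchangeabilities ρ (unordered pairs AC, AG, AT, CG, CT, GT)
sum to 1 and the four propensities φ sum to 1; this makes the mutation
kernel GTR-like and, combined with the antisymmetry of S and the
identity `h(S) = e^S h(-S)` of the fixation factor, the full process is
reversible with stationary distribution

    pi_i ∝ phi_{i1} * phi_{i2} * phi_{i3} * psi_{f(i)}.

The closed form is used directly; tests verify it against a numerical
null-space solve. The model mechanistically produces across-site rate
heterogeneity: under a profile dominated by one amino acid the fixation
factor of any move away from it approaches 0, so non-synonymous flux is
suppressed; under a flat profile all fixation factors approach 1.

**Normalization.** Each component generator is rescaled so its expected
substitution rate at its own stationary distribution is 1
(−Σ π_i Q_ii = 1), making branch lengths read as expected substitutions
per codon site. This is the dominant convention but it is a choice;
comparisons with other software may differ by a global branch-length
scale, so the unscaled matrix is available via `normalize=False`.

**Profiles.** The mixture components are fixed in advance and never
re-estimated. The built-in set groups the 20 amino acids into eight
disjoint biochemical classes — small nonpolar (A,G,S,T), aromatic
(F,W,Y), nonpolar aliphatic (I,L,V,M), polar positive (H,K,R), polar
negative (D,E), polar neutral (N,Q), proline, cysteine. The
*peakedness* p ∈ (0,1] is the mass shared equally by a group's members;
the complement is spread equally over the remaining residues. Profile
entries below 1e-10 (possible in loaded empirical tables or at p = 1)
are floored and the profile renormalized so log-fitnesses stay finite.
Empirical K×20 tables (with an optional leading weight column,
auto-detected by field count) are read and written as plain whitespace
tables; the C-series values themselves are external data and are not
bundled.

## Likelihood

Per-site, per-component likelihoods p(D_n | θ, ψ^(k)) are computed by
Felsenstein pruning with per-node rescaling of partials (log-scale
accumulators), so hundreds of taxa do not underflow. Root states are
weighted by the component's stationary distribution — the equilibrium
assumption, which reversibility makes consistent with any rooting (an
invariance the tests assert). Transition matrices exp(Qt) come from the
π-symmetrized eigendecomposition, with a dense scaling-and-squaring
fallback retained as a cross-check (agreement within 1e-10 asserted).
Gaps, Ns and partially resolved codons are treated as fully missing at
the codon level (all-ones partials); per-nucleotide ambiguity expansion
is deliberately not attempted. In-frame stop codons are rejected at
read time, naming taxon and site.

## MCMC

The sampler updates the site allocations z and, optionally, (ρ, φ) and
branch lengths; the N×K log-likelihood table does not depend on z and
is recomputed only when those parameters move.

- **Collapsed (Pólya-urn) sweep.** Sites updated sequentially:
  decrement the current component's count η_k, draw a new component
  with probability ∝ (η_k+1)·p(D_n|θ,ψ^(k)), increment. This integrates
  the mixture weights out exactly under a flat Dirichlet prior.
- **Weighted sweep (default).** Draw w ~ Dirichlet(1+η) (the conjugate
  update under the flat prior), then reallocate every site
  independently with probability ∝ w_k·p(D_n|θ,ψ^(k)). Marginally over
  w this targets the same posterior as the collapsed sweep
  (demarginalization; asserted against exact enumeration on a two-site
  fixture), and the vectorized site updates are order-independent.
- **Parameter moves.** ρ and φ move by the standard simplex profile
  proposal (multiply one coordinate by exp(λ(U−½)), renormalize; log
  Hastings ratio log f − K log T) under flat Dirichlet priors; branch
  lengths move per edge by l′ = l·exp(λ(U−½)) under i.i.d.
  exponential(mean 0.1) priors. Prior recovery of both move types under
  a constant likelihood is tested. Proposal tunings adapt toward ~25%
  acceptance during burn-in only and are frozen afterwards, keeping the
  post-burn-in chain a fixed valid kernel.

Defaults: burn-in = first 20% of sweeps; thinning chosen so at most
2000 draws are stored. Everything is driven by one seeded generator;
identical seed and configuration give byte-identical trace and report
files.

## PIP and shift calls

From M stored draws, p^(n)(k) is the fraction of draws with z_n = k.
The chain is run independently on the two taxon partitions — the focal
monophyletic sub-clade (induced subtree re-rooted at the sub-clade MRCA,
stem branch removed) and the complement (sub-clade taxa pruned,
unifurcations suppressed). Dropping the stem amounts to treating the
connecting branch as infinitely long; it is a deliberate, crude
independence assumption. By default each partition re-estimates any
free parameters on its own; θ can also be fixed.

PIP_n is the dot product of the two partitions' allocation vectors at
site n: 1 for certain agreement, 0 for disjoint allocation, 0.5 when
both partitions split 50/50 over the same two components (the chance
level of drawing the same profile twice), ~1/K when both are near
uniform. Sites with PIP ≤ threshold (default 0.05, boundary inclusive)
are flagged. Because diffuse allocation in both partitions also drives
PIP down without any real shift, an optional filter additionally
requires both partitions' allocation entropies (−Σ p ln p, in nats) to
be at most a user-set bound; it is off by default since it is a
refinement, not part of the core statistic. Evaluation helpers report
TPR = TP/|truth|, FPR = FP/(N−|truth|), precision (0 when nothing is
called), and a precision-recall curve swept over the observed PIP
values.

## Synthetic data

The simulator draws per-site allocations i.i.d. uniformly over the K
components, selects `n_shift` sites uniformly without replacement, and
at each gives the sub-clade regime a component drawn uniformly from the
other K−1. The shifted regime applies from the sub-clade's stem branch
downward (the transfer event is taken to precede the sub-clade's MRCA;
since inference treats the partitions as independent, this choice only
affects simulation). Root codons are drawn from the main component's
stationary distribution and states propagate down each branch by
sampling from exp(Qt) — equivalent in distribution to event-by-event
simulation and easier to verify. Random trees use uniform
coalescent-style joins with exponential branch lengths, with the focal
clade constrained to coalesce first so it is monophyletic.

Default study conditions for the evaluation sweeps: 16 taxa with a
6-taxon focal clade, 200 codon sites of which 20 are shifted (the same
~10% shifted fraction as an 80-of-759 design), mean branch length 0.3
(total tree length ≈ 9–10 expected substitutions/site), uniform ρ and
φ, and the grouped profiles over a peakedness grid {0.5, 0.75, 0.95}
and branch-scale grid {0.1, 1, 10}. These sizes keep a full
simulate-analyze-evaluate replicate to a couple of seconds while
preserving the qualitative regimes of interest: at peakedness 0.95 the
pipeline recovers ≥70% of planted shifts with FPR ≤ 10% at the 0.05
cutoff, detection power increases monotonically with peakedness and
with branch-length scale, and at peakedness 0.5 power is poor — the
same orderings expected at full scale, though the absolute rates at
desk scale are not calibrated to any particular larger study.

What the simulator does *not* emulate: indels (alignments are
simulated gap-free; missing data is exercised separately in unit
tests), codon-usage variation beyond the φ composition, rate variation
other than what the mixture itself induces, non-equilibrium root
composition, and recombination or other violations of a single fixed
topology. Passing tests therefore demonstrate correctness of the
machinery and the qualitative behaviour of PIP under the model's own
assumptions, not robustness to model misspecification on real data.

## Numerical choices and edge cases

- `S/(1−e^{−S})` evaluated as `S / −expm1(−S)`, with the second-order
  series 1 + S/2 for |S| < 1e-8.
- Tiny negative entries of exp(Qt) from rounding are clamped to 0 and
  rows renormalized.
- Likelihood-zero columns (impossible data under a branch of length 0)
  return log-likelihood −inf and are handled by the samplers through
  row-max rescaling of the likelihood table.
- An all-missing column has likelihood 1 by construction.
- Site indices are 0-based in memory; every written report and truth
  table is 1-based.
- Component caches key on the exact bytes of (ρ, φ), so branch-length
  moves reuse eigensystems while any accepted mutation move invalidates
  them.

## Limitations

- K is fixed; there is no reversible-jump over the number of
  components, and profile values are never estimated from data.
- The two-partition independence assumption discards information in the
  stem branch and cannot localize a shift more finely than "within the
  sub-clade".
- Only the universal genetic code is supported.
- Empirical profile sets whose components share dominant residues
  inflate false positives (allocation can switch between near-identical
  components); the entropy filter mitigates but does not remove this.
- No multiple-testing correction is applied to the PIP cutoff.
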
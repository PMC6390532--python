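# mutselpip

Detection of **site-specific shifts in amino acid preference** between a
focal monophyletic sub-clade and the rest of a fixed phylogeny, using a
codon-level **mutation-selection substitution model** with a predefined
finite mixture of amino acid fitness profiles and the **probability of
identical profiles (PIP)** statistic.

The intended user is a molecular evolutionist with an in-frame
protein-coding nucleotide alignment, a rooted tree with branch lengths,
and a hypothesis that selective preferences changed within a known
sub-clade — for example viral strains that switched host.

## The model

At codon site *n*, the 61×61 rate matrix over sense codons is

```
Q_ij = mu_ij * S_ij / (1 - exp(-S_ij))
```

for codons *i → j* differing at one nucleotide position *c*, where

- `mu_ij = rho_{i_c j_c} * phi_{j_c}` is a GTR-style mutation kernel
  (six exchangeabilities ρ summing to 1, four nucleotide propensities φ
  summing to 1), and
- `S_ij = ln psi_{f(j)} - ln psi_{f(i)}` is the scaled selection
  coefficient from the amino acid fitness profile ψ allocated to the
  site (`f` maps codons to amino acids); `S/(1-e^{-S})` is the relative
  fixation rate of the mutation.

Profiles come from a fixed mixture of K components: either the built-in
eight biochemically grouped profiles (disjoint groups AGST / FWY / ILVM /
HKR / DE / NQ / P / C, with a *peakedness* parameter giving the mass the
group shares), or a K×20 table of published empirical profiles
(C10–C60 style). Each site carries a latent allocation `z_n ∈ 1..K`,
sampled by MCMC — either a collapsed Pólya-urn Gibbs sweep
(∝ (η_k+1)·p(D_n|θ,ψ^(k)), weights integrated out) or the default
parallelizable sweep with explicit Dirichlet(1+η) weights. Running the
sampler separately on the sub-clade and on the remainder of the tree
(stem branch dropped, i.e. partitions treated as independent) gives two
posterior allocation tables `p_A^{(n)}(k)` and `p_B^{(n)}(k)`, and

```
PIP_n = sum_k p_A^(n)(k) * p_B^(n)(k)
```

is the posterior probability that the same component governed site *n*
in both partitions. Sites with `PIP <= 0.05` (inclusive, configurable)
are flagged as candidate preference shifts; an optional entropy filter
excludes sites whose low PIP merely reflects weak, diffuse allocation.

## Worked example

```python
import numpy as np
from mutselpip import (mutsel_bc, run_shift_analysis, confusion_metrics,
                       simulate_alignment)
from mutselpip.simulate import make_design

profiles = mutsel_bc(0.95)                      # 8 peaked profiles
design = make_design(n_taxa=16, clade_size=6, n_sites=200, n_shift=20,
                     profiles=profiles, rng=42)
aln, truth = simulate_alignment(design, rng=42)

report, res_sub, res_rest = run_shift_analysis(
    aln, design.tree, design.subclade, profiles,
    seed=7, n_sweeps=2000, mutation_params=design.mut)
print(report.summary())
print(confusion_metrics(report.called_sites, set((truth + 1).tolist()), 200))
```

prints

```
PIP shift report
  sites:            200
  PIP threshold:    <= 0.05
  entropy filter:   off
  flagged shifts:   15
  median PIP:       0.9984
{'TPR': 0.75, 'FPR': 0.0, 'precision': 1.0, 'recall': 0.75, 'TP': 15,
 'FP': 0, 'n_calls': 15}
```

i.e. with strongly peaked profiles (peakedness 0.95) 15 of the 20
planted shifts are recovered at the 0.05 PIP cutoff with no false calls
among the 180 unshifted sites; unshifted sites sit near PIP ≈ 1. Power
falls as peakedness decreases and as branch lengths (information
content) shrink — the `pipeline` CLI subcommand sweeps these settings.

The same analysis runs from the shell:

```sh
mutselpip pipeline --peakedness 0.95 --taxa 16 --clade-size 6 \
    --sites 200 --shifts 20 --seed 42 --out-dir runs/demo
```

For real data, use `mutselpip run` twice (sub-clade and background
alignments/trees, or let `run_shift_analysis` split them), then
`mutselpip pip` and `mutselpip evaluate`.

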
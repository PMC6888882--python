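# memcoev

Memory-kernel coevolution model of protein sequence evolution: a stochastic
simulator of substitution dynamics on protein contact maps, plus the
statistics used to analyze real pairwise alignments.

## The scientific problem

Substitutions in proteins are neither independent across sites nor constant
in time: residues in structural contact coevolve (a mildly destabilizing
substitution favors compensatory changes in its spatial neighbors), and
per-site rates drift, overdispersing the molecular clock.  `memcoev`
implements a minimal model that produces both phenomena from one mechanism.
The substitution rate of site *i* at time *t* is

    r_i(t) = r0(i) + J * Σ_k C_ik · exp(−(t − t_k))

where `C` is the binary contact map (Cα–Cα distance < 10 Å by default),
`t_k` is the time of the **last** substitution at site *k* (never-mutated
sites contribute 0), and time is measured in units of the memory time.  A
substitution transiently boosts its contacting neighbors' rates; if no
compensatory substitution follows within a few memory times, the
perturbation is forgotten.  Substitutions therefore arrive in *avalanches*
localized in space and time, and the among-site distribution of substitution
counts is negative-binomial-like — the classic covarion picture with an
explicit spatial substrate.

The package is aimed at molecular-evolution researchers who want to simulate
this model on real or synthetic contact maps, reproduce its analysis
statistics (along-chain conditional substitution profiles, negative-binomial
shape-parameter fits, overlap ratios, avalanche partitions), or fit its two
parameters to reference profiles.

## Library tour

| Module | Contents |
| --- | --- |
| `memcoev.contact_model` | `ContactMap`, PDB/coordinate readers, synthetic map generator, submaps, edge-list serialization |
| `memcoev.rate_dynamics` | Eq.-style rate evaluation, discrete-time stepping, equilibration, one- and two-class parameters |
| `memcoev.divergence_sim` | two-branch divergence from a common equilibrated ancestor; identity-binned ensembles |
| `memcoev.alignment_stats` | binary alignments, conditional profile P(d), substitutions-per-site histogram, negative-binomial α fit, overlap ratio |
| `memcoev.param_fit` | profile-RMSD objective and (J, r0) optimization with common random numbers |
| `memcoev.avalanche` | consensus sequences, mutation matrices, spatio-temporal avalanche detection |
| `memcoev.cli` / `memcoev.io_utils` | `memcoev` command-line tool and plain-text serialization |

## Worked example

```python
import memcoev as mc

# A 200-site synthetic map: backbone band, five helices, ~11 contacts/site.
spans = [(10, 30), (50, 70), (90, 110), (130, 150), (170, 190)]
cmap, classes = mc.synthetic_contact_map(200, spans, long_range_pairs_per_site=5.0,
                                         backbone_width=2, seed=7)

params = mc.ModelParams(r0=4e-4, J=0.02)       # fitted one-class values
config = mc.SimulationConfig(dt=0.01, equilibration_time=50.0)

res = mc.simulate_divergence(cmap, params, config, target_identity=0.60, seed=1)
print(f"identity {res.identity:.2f} after {res.n_steps} steps "
      f"({res.identity_trajectory[-1][0]:.0f} memory-time units)")
print(f"multi-substitution steps: {res.multi_substitution_fraction:.2e}")
print(f"overlap ratio: {mc.overlap_ratio(res.counts_a):.3f}")

prof = mc.conditional_profile([res.alignment], d_max=10, trim=5)
print("P(d), d=1..10:", [f"{p:.2f}" for p in prof.p])
```

prints

```
identity 0.60 after 41927 steps (419 memory-time units)
multi-substitution steps: 0.00e+00
overlap ratio: 0.083
P(d), d=1..10: ['0.46', '0.47', '0.39', '0.41', '0.42', '0.39', '0.42', '0.39', '0.45', '0.46']
```

Reading the output: the window reached 60% identity (40% of sites hit in at
least one branch) after ~419 memory-time units; no time step carried two or
more substitutions, confirming the discretization; 8.3% of branch-A's
mutated sites were hit more than once; and the conditional probability of
finding a substitution `d` sites away from another one sits above the ~0.40
marginal at the shortest distances — the excess produced by contact
coupling.  One alignment is noisy; pooling many replicates (see
`run_ensemble`) resolves the full profile shape, including the helix
periodicity peaks at d = 3–4 and 7.

The same pipeline is scriptable from the shell:

```sh
memcoev synth -L 200 --helix "10:30,50:70" --long-range 5.0 --seed 7 --out-prefix fx
memcoev simulate --map fx.contacts.txt --target-identity 0.6 --seed 1 --out-dir run1
memcoev stats --alignments run1/alignment.txt --counts run1/counts.tsv --out-dir stats1
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch, the model's
discretization-quality bound: it generates a 200-site synthetic contact map,
equilibrates, simulates two-branch divergence at `J = 0.02`, `r0 = 4e-4`,
`dt = 0.01` down to 60% identity over 10 seeds, and reports the percentage
of time steps in which two or more sites substituted:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model, the discretization and equilibration
scheme, every statistic's exact definition, the synthetic-map generator and
what it does and does not emulate, and the package's numerical choices.
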
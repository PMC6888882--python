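# Methods

## Model

`memcoev` simulates the fixation of point substitutions on a protein chain
whose sites interact through a structural contact map `C` (symmetric, binary,
zero diagonal).  Site `i` substitutes at time `t` with rate

    r_i(t) = r0(i) + J * sum_k C_ik * exp(-(t - t_k)),

where `t_k` is the time of the **last** substitution at site `k`; a site that
has never substituted contributes exactly zero.  The exponential memory
kernel is the defining ingredient: a substitution transiently raises the
substitution rate of its spatial neighbors (compensatory-mutation pressure),
and the effect is forgotten on the time scale of one memory unit.  All times
are dimensionless, measured in units of the kernel decay time.  The process
is a self-exciting (Hawkes-like) point process on the contact graph, with
the non-standard twist that only the most recent event per site enters the
intensity.

Two parameterizations are provided:

* **one-class** (`ModelParams`): uniform baseline `r0` for all sites.
  Defaults `r0 = 4e-4`, `J = 0.02` (per site per memory-time unit), the
  values fitted on large ensembles of real pairwise alignments.
* **two-class** (`TwoClassParams`): residues labeled *structured* have
  baseline 0 and mutate only through the coupling; *unstructured* residues
  have baseline `r0_unstructured`.  Both classes share `J`.  Defaults
  `J = 0.021`, `r0_unstructured = 0.01`.  Class labels are inputs (e.g. a
  STRIDE assignment), never computed here.

With mean contact degree `z`, the expected number of substitutions directly
triggered by one substitution is `J*z` (the integral of the kernel is 1).
At the default parameters and realistic degree (`z ~ 11` for 10 Å Cα maps)
the cascade is subcritical (`J*z ~ 0.22`): substitutions occur in small
avalanches localized in space and time on top of a Poisson background.

## Simulation scheme

Time is discretized in steps `dt` (default 0.01).  Rates are evaluated from
the state at the start of each step (explicit scheme), each site then
substitutes independently with probability `p_i = r_i*dt`, and substituted
sites get their last-mutation time set to the end-of-step clock.  A
configuration with any `p_i > 1` raises an error.  The scheme's validity is
monitored, not assumed: every divergence run reports the fraction of steps
with two or more substitutions (both branches pooled), which stays far below
1% at the default parameters (this is the quantity `scripts/acceptance.py`
recomputes).  Kernel terms with lag > 40 are truncated to zero (below
1e-17); never-mutated sites carry a boolean sentinel rather than a fake
time, so no overflow-prone exponentials are evaluated.

**Equilibration.**  Before a divergence run the chain evolves alone for
`equilibration_time` (default 50) memory-time units so the lag distribution
`{t - t_k}` reaches stationarity; the clock is then reset to zero with lags
preserved, and pre-split substitutions do not count.  Fifty units is two
orders of magnitude above the kernel memory and was validated by a
stationarity test (mean total rate equal in the two halves of a long run,
within Monte-carlo error).  Note that with `r0 = 4e-4` the *per-site
waiting time* (~2500 units) far exceeds the equilibration window; what must
be stationary is the recent-lag distribution that feeds the kernel, not the
full mutation history, and that relaxes on the kernel time scale.

**Two-branch divergence.**  Both branches copy the equilibrated ancestor
(same initial `t_k`) and then evolve with independent random streams — no
cross-branch coupling.  Sequence identity of the measured window is
`1 - (#sites substituted in >= 1 branch)/window length`, a lower bound on
true identity because back and convergent mutations are ignored.  Runs stop
at the first step whose window identity reaches the target, or at
`max_time` (flagged, never an exception).

**Ensembles.**  `run_ensemble` draws a window length from a supplied
distribution, a contact map at least that long, and a uniformly placed
window; the chain evolves on its full length while identity is measured on
the window, and the state is snapshotted as the identity first crosses each
requested bin's midpoint (the stand-in for stopping at the mean identity of
a real alignment set).  Snapshots record the window's binary alignment,
window counts, and whole-chain per-site counts.

## Statistics

* **Conditional profile** `P(d) = N1(d) / (N0(d) + N1(d))`: for every
  substitution in the trimmed interior (default trim 5 at each end) and
  every offset `±d` with the partner also interior, the partner's symbol is
  tallied.  Ordered pairs are counted in both directions; the ratio is
  invariant under that convention (tested).  Bins with no observations are
  NaN, never silently zero.
* **Negative-binomial fit**: the histogram of substitutions per site is fit
  to `p(k | alpha, <k>) = Gamma(alpha+k)/(Gamma(alpha) k!) *
  (<k>/(<k>+alpha))^k * (alpha/(<k>+alpha))^alpha` with the mean constrained
  to the data and only the shape `alpha` free (bounded scalar minimization
  on log alpha in [1e-3, 1e6]).  Weights follow Poisson counting errors
  (`sigma_k = sqrt(n_k)/N`); empty bins inside the fitted range get one
  pseudo-count, bins beyond the last occupied `k` are excluded.  `alpha` is
  the usual among-site rate-variability shape parameter: `alpha -> inf`
  recovers Poisson.
* **Overlap ratio**: sites hit at least twice over sites hit at least once —
  a molecular-clock overdispersion summary.
* **Parameter fit**: `(J, r0)` minimize the RMSD between model and reference
  `P(d)` over the identity bins, restricted to `d < 30`.  Each candidate
  point re-simulates the ensemble under common random numbers (same seed
  stream at every point), so the objective is deterministic and exactly zero
  when the reference was produced by the same generator; a coarse log-grid
  search is followed by Nelder-Mead on log-parameters.
* **Avalanches**: substitution events `(site, time-bin)` are linked when the
  sites are in contact (optionally also when identical) and the times differ
  by at most 2 bins (inclusive); avalanches are connected components with at
  least 3 events, smaller components are "minor".  The 8.5 Å threshold is
  the documented default for this analysis, versus 10 Å for simulations.

## Which per-site counts feed which statistic

Stopping a run when the *window* reaches a fixed identity pins the number of
never-substituted window sites, which slightly *under*-disperses window
counts and can mask the weak one-class overdispersion.  The
rate-variability statistics (histogram, alpha) therefore use whole-chain
counts — the chain evolves on its full length and only the window is
conditioned — while the overlap ratio, a property of the observed alignment,
uses window counts.  Both are exposed (`EnsembleBin.pooled_counts(chain=...)`).

With this convention the one-class model shows the expected behavior: the
dispersion excess `D - 1` of per-site counts is roughly constant in depth
while the mean grows, so the fitted `alpha ~ mean/(D-1)` grows as identity
decreases — time-averaged rates homogenize with depth.  The two-class model
has a permanent (quenched) rate dichotomy, so its `alpha` stays of order 1
at all depths and grows much less, and its overlap ratio exceeds the
one-class value in every bin.  These are the behaviors the acceptance tests
check; their magnitudes at publication-scale ensembles are not reproduced at
test scale.

## Synthetic contact maps

The generator emulates globular-protein Cα maps: a backbone band
(`|i-k| <= backbone_width`, default 2), α-helix periodicity contacts at
offsets 3 and 4 inside declared helix spans (whose residues are labeled
structured), and Poisson-distributed random long-range pairs.  The default
long-range density of 5 pairs/site together with ~45% helical coverage gives
a mean degree near 11, typical of 10 Å Cα maps.  What the generator does
*not* reproduce: the fractal/clustered geometry of real long-range contacts
(they are uniform here), domain structure, chain-compactness correlations,
and beta-sheet ladder periodicity.  A green test on synthetic maps therefore
establishes the dynamics and statistics machinery, not agreement with any
real structure ensemble.  Real maps can be supplied as PDB files (Cα atoms,
first model, one chain) or as edge-list text files.

## Numerical and design choices

* `dt = 0.01` keeps `max p_i` around 1e-3 at default parameters; validated
  by the multi-substitution-step bound rather than assumed.
* Per-run randomness derives from one seed via `numpy` `SeedSequence`
  spawning (equilibration, branch A, branch B, and per-replicate streams),
  so every result is bit-reproducible from its recorded seed.
* Site update order is fixed (vectorized over ascending index).
* Consensus ties break lexicographically; documented, arbitrary.
* Same-site events at nearby times join one avalanche by default
  (`self_links=True`), exposed as a flag since repeated same-site
  substitutions have no canonical treatment.
* The stand-in alignment-length distribution is uniform on [80, 300].
* Identity-bin snapshots use bin midpoints as stop targets.

## Known limitations

* No amino-acid identities: sequences are characterized solely by length and
  last-mutation times, so substitution matrices, back mutations, and
  convergent changes are out of scope by construction.
* The discrete-`dt` scheme is the object of study; no event-driven sampler
  is provided.
* Fitted-parameter uncertainty is not quantified; the optimizer returns a
  point estimate and its evaluation trace.
* One-class among-site dispersion at the default parameters is weak
  (`D - 1 ~ 0.02`), so alpha estimates need ~1e5 site-samples per identity
  bin to stabilize; smaller ensembles give noisy alpha.
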
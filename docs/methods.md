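# Methods

## Model

The simulated system is a coarse-grained Cα chain whose segments mirror a
four-helix-bundle protein: helices H1–H4, a hinge linker and a flexible
C-terminal tail (the apolipoprotein E architecture, scaled down to 56
beads by default so a full replica-exchange run takes minutes on one CPU;
a 299-residue preset with the ApoE segment boundaries is retained but not
used in tests).

All interactions are multistep square-well potentials — sorted distance
thresholds with constant energy between them.  Three pair classes:

* **Covalent bonds**: an infinitely deep well between
  `bond_length·(1±tolerance)` (3.8 Å ± 2 %), the standard DMD bond
  realization.  The idealized geometry cannot connect two helices on a
  10 Å grid through a single 3.8 Å bond, so the three helix–helix junction
  neighbours are confined around their built distance instead (±2 %);
  every intra-segment bond keeps 3.8 Å.
* **Native contacts** (Gō prescription): pairs with sequence separation
  ≥ 3 that lie within 7.5 Å in the idealized structure receive one
  attractive well of depth 1.0 kcal/mol spanning
  `[hard core, d_native + 1.5 Å]`.  The ground state therefore has energy
  exactly −(depth × number of contacts), which the tests assert.
* **Everything else**: a 4.0 Å hard core.

The idealized geometry uses canonical α-helix Cα parameters (1.5 Å rise,
100° turn, 2.3 Å cylinder radius, right-handed for both chain
directions), four antiparallel helices on a 10 Å square grid, and planar
zig-zag (120° bond angle) hinge and tail.  A seeded 10⁻³ Å jitter breaks
exact degeneracies.  With these defaults the chain carries 74 native
contacts and its melting transition falls inside the replica ladder.

**Units.** Energies kcal/mol, lengths Å, temperatures kcal/(mol·kB) with
kB = 0.002 kcal/mol/K (0.6 ≡ 300 K); one time unit ≡ 50 fs.  In this base
system the derived mass unit is ≈1.05 g/mol, so the default bead mass of
110 (an average residue mass in Daltons) gives physically realistic
thermal velocities (~150 m/s at 300 K).

## Event-driven dynamics

Between events beads fly ballistically.  For each interacting pair the
next threshold crossing is the earliest positive root of
|r + v t|² = d² over the boundaries adjacent to the pair's current shell.
At a crossing the relative velocity is split into radial and tangential
parts; only the radial component v_r changes, which conserves angular
momentum.  With reduced mass μ and step height ΔU the pair crosses iff
½μv_r² > ΔU, leaving with v_r′ = sign(v_r)·√(v_r² − 2ΔU/μ); otherwise it
reflects (v_r′ = −v_r).  Hard cores and bond walls always reflect.  Energy
bookkeeping is exact by construction; the test suite verifies total
energy, momentum and angular momentum drift below 10⁻⁹ kcal/mol (and
equivalents) per processed event against from-scratch recomputation.

The queue is a binary heap with lazy invalidation: events carry per-bead
collision counters and are dropped on pop if a counter moved.  Two purely
performance-motivated devices sit on top and are checked not to change
the dynamics beyond float round-off:

* **Scheduling window** (default 2 t.u.): only events due within the
  look-ahead window are heaped; at each window boundary all predictions
  are rebuilt.
* **Pair screening**: at each rebuild, pairs outside their outermost
  threshold by more than 2·v_cap·window are dormant, where v_cap is 1.4×
  the fastest bead at rebuild time.  Any bead exceeding v_cap (after a
  thermostat kick or a well capture) forces an immediate rebuild, so no
  crossing can be missed.

Grazing approaches (quadratic discriminant < 10⁻¹²) count as no crossing.
Simultaneous events are processed in nondecreasing time order.  Because
chaotic dynamics amplifies last-ulp differences, cross-implementation
comparisons (the naive O(n²) reference loop) are asserted over horizons
short enough that round-off cannot reorder events.

**Thermostat.** Andersen: a Poisson stream (default 0.1 kicks per bead
per t.u. — the rate is a design choice, not an inference) picks a random
bead and redraws its full velocity from the Maxwell–Boltzmann
distribution.  Equipartition and velocity normality under the thermostat
are tested at 3-standard-error / 1 % levels.

## Replica exchange

One replica per ladder temperature (default 0.35–0.81 in 0.02 steps → 24
replicas, i.e. 175–405 K).  Replicas run independently between swap
barriers (default every 10³ t.u.); at a barrier adjacent pairs — even
pairs on even sweeps, odd on odd — attempt a Metropolis exchange with
acceptance min(1, exp[(β_i−β_j)(E_i−E_j)]).  Accepted swaps exchange
*temperatures* with velocity rescaling by √(T_new/T_old), which is
equivalent to exchanging configurations and cheaper.  Replicas advance
sequentially, making runs bit-reproducible from the master seed; the
temperature assignment is asserted to remain a permutation of the ladder
at all times.  Replica mobility is the count of distinct rungs each
replica visits.

## WHAM and heat capacity

Per-temperature potential-energy histograms (1 kcal/mol bins) are
combined by direct self-consistent substitution in log space,

    ln Ω(E) = ln Σ_k n_k(E) − logsumexp_k[ln N_k + f_k − β_k E]
    f_k     = −logsumexp_E[ln Ω(E) − β_k E + ln ΔE],

iterated to max|Δf| < 10⁻⁷ and normalized to Ω_max = 1.  Disconnected
histogram islands raise a warning (relative Ω between islands is
undetermined); non-convergence raises with the residual attached.  The
heat capacity is the canonical energy-fluctuation curve
Cv/kB = Var(E)/T², evaluated on a 1 K-equivalent grid; extrema are local
extrema after a 3-point moving-average smooth.  The leading 1/12 of each
run (the source protocol's 5×10⁵ of 6×10⁶ steps, expressed as a fraction
so it scales with the horizon) is discarded as equilibration before any
histogram.  Uncertainty bands are a block bootstrap (20 contiguous blocks
per temperature) — the estimator behind the published "variance of the
specific heat" is unspecified, so the bootstrap is this package's own
choice.  The per-temperature energy marginals are screened with the
D'Agostino–Pearson skewness/kurtosis omnibus test.

## Landscape and state assignment

Reaction coordinates are the least-squares superposed RMSD (proper
rotations only, via the SVD/Kabsch construction) and the radius of
gyration, both over the four helices' beads; the flexible hinge/tail is
excluded by default to reduce state degeneracy.  The reference structure
is the run's starting conformation.  The PMF over 1 Å × 1 Å bins is
−kBT ln W + C with the occupied minimum pinned at zero; empty bins are
masked (NaN), never zero.  ΔPMF between bins equals −kBT·ln(count ratio)
exactly, which is tested as an identity and, on Gaussian-mixture samples,
against the analytic −kBT·ln(weight ratio).

State temperatures follow the heat-capacity topology: T1 is the lowest
analysis temperature, T2 the minimum below the first peak, T3 the minimum
between first and second peaks, T4 the final minimum; with fewer extrema,
fewer labels.  A basin is the 4-connected component of bins with
PMF ≤ cutoff (default 1 kcal/mol) containing the global minimum.

## Conformer analytics

Leader clustering makes a single pass in frame order: a frame joins the
first leader within the cutoff, else founds a cluster.  The cutoff is the
center of the modal bin (1 Å bins, ties to the lower bin) of the pairwise
RMSD distribution.  Centroid = member minimizing summed RMSD to
co-members; clusters are reported by size, then leader index.  Pairwise
RMSD uses batched 3×3 SVDs (absolute accuracy ~10⁻⁸ Å from the trace
formulation — ample for Å-scale clustering).

Distance matrices report the ensemble mean in the upper triangle and the
standard deviation in the lower; only the Cα mode is computable on a bead
model, so the side-chain-centroid mode raises an explicit error.
Contact occupancy is the fraction of frames with a pair within a
threshold, with 1 Å distance histograms.  The inter-domain angle θ is
measured at three anchors (two-thirds along helix 4, the helix-4
C-terminus as vertex, the tail midpoint); the dihedral φ between the
helix-4 and tail axes (each N→C) uses the standard four-point dihedral,
which realizes the convention 0° = antiparallel, ±180° = parallel.
Helicity is a coarse-grained surrogate (not an all-atom secondary-
structure assignment): residue i is helical when the virtual dihedral of
beads (i−1…i+2) lies in [30°, 70°] and both flanking virtual bond angles
in [75°, 115°]; |dihedral| ≥ 150° counts as extended; the rest (and chain
termini) as loop.  The idealized helix sits at +50.0°/90.4°, the zig-zag
tail at 180°/120°.  SASA uses Shrake–Rupley-style sphere-point sampling
with a fixed 960-point Fibonacci set and a 1.4 Å probe; it is exact under
reindexing and rotation-invariant only to the ~1 % sampling tolerance.

## Synthetic ensembles and what the tests show

`generate_energy_series` draws *exactly* Boltzmann-distributed energies
for named systems (two-level: Bernoulli with the analytic occupancy;
harmonic: (kBT/2)·χ²₁), so WHAM and Cv code are validated against closed
forms (degeneracy ratios, the Schottky peak at T = ε/2.3994) without any
dynamics in the loop.  `generate_rc_samples` draws (RMSD, Rg) pairs from
Gaussian mixtures for the PMF stage.  These generators share none of the
statistical caveats of real trajectories — no autocorrelation, no
equilibration transient — so passing those tests certifies the estimator
implementations, not the sampler; the sampler itself is covered by the
conservation, equipartition, detailed-balance and integration tests.

The integration run (24 replicas × 2×10⁵ t.u., seed-pinned) reproduces
the qualitative unfolding picture of the full-scale protocol: one Cv peak
inside the ladder (~235 K for the default seed), a low-temperature basin
whose dominant cluster sits within the clustering cutoff of the start
structure, and a high-temperature ensemble with clearly expanded Rg
(ratio ~1.7).  The desk-scale toy cannot and does not target the
published full-protein numbers (peak temperatures per isoform, the
13.9 ± 4.8 replica mobility), which required an all-atom force field and
~71,000 CPU-hours; only protocol arithmetic and qualitative structure
carry over.

## Numerical choices and limitations

* Problem sizes: 2×10⁵ t.u. horizons, 50 t.u. frame interval, ≤400 frames
  per clustering pass (uniform random subsample) keep the full pipeline
  around 2–3 minutes on one CPU.
* WHAM tolerance 10⁻⁷, ≤10⁵ iterations; PMF/contact/geometry histograms
  all use 1 Å (or 1°, or 1 kcal/mol) bins.
* The engine supports arbitrary step-potential tables; the Gō surrogate
  is deliberately minimal (no solvation model, no electrostatics, no
  side chains, uniform well depth).  Conclusions about real ApoE isoforms
  are out of reach of this model by design; the package's claim is a
  correct, tested implementation of the methodology.
* No Hamiltonian exchange, no multidimensional WHAM/MBAR, no 1-D PMFs.
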
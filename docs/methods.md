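# Methods

## Model

Nucleosomes are hard rods on a periodic one-dimensional lattice of
`L = 14700` base pairs; the particle coordinate is the dyad (central bp) and
the footprint covers 147 bp, `[x-73, x+73]`. Two circularly consecutive
dyads must be at least 147 bp apart (infinite hard-core pair potential
below that distance). Energies are in units of `k_B T` throughout
(`beta = 1`).

The energy of a configuration is a sum of three kinds of terms:

* **Site binding energy.** Each base pair carries `V_s`; a nucleosome pays
  the footprint sum. The default is uniform with `sum = -42 kBT` per
  footprint. Sequence-specific profiles from the dinucleotide scorer (below)
  can replace the uniform field.
* **Promoter barrier** (dyad-evaluated): a symmetric triangle centred
  150 bp upstream of the TSS, height 25 `kBT` (2 `kBT` in the
  `intermediate` preset), falling linearly to zero at the TSS and at
  −300 bp. It models competition from transcription factors, the
  pre-initiation complex and Pol II for promoter DNA. Evaluating it at the
  dyad only (not summed over the footprint) keeps the promoter occupiable
  at finite probability and leaves `14400/147 ≈ 98` footprints of
  effectively free DNA.
* **Positioning well** (dyad-evaluated): a flat well of depth −2 `kBT` on
  `[TSS, TSS+30]`, standing in for INO80-like +1-positioning remodelers.

Dynamics consist of three elementary processes, simulated exactly with the
Gillespie algorithm:

* **Thermal diffusion**: 1-bp hops at rate `(D/Δl²)·exp(−ΔU/2)` with
  `D = 1 bp²/s`, `Δl = 1 bp`; the symmetric split of `ΔU` satisfies
  detailed balance.
* **Spacer enzymes** (ISW1/Chd1-like): a pair of neighbouring nucleosomes
  with dyad distance in `(147, 332]` bp is remodeled at rate `k`
  (presets 0.16, 0.12, 0.08 /s): one member, chosen uniformly, moves one bp
  toward the other *regardless of the energy landscape*. This breaks
  detailed balance. Since an inward move only shrinks the shared gap
  (which eligibility guarantees is above the hard core) and grows the
  outer gap, both members are always feasible movers.
* **Histone exchange**: whole-nucleosome absorption at
  `r_on = r_const·exp(−ΔV/2)` per free dyad site and desorption at
  `r_off = r_const·exp(+ΔV/2)` per bound nucleosome, with
  `ΔV = ΔU + μ`. The chemical potential `μ` sets the mean density;
  `r_const = 0.1 /s` models Pol II-driven turnover of the most active
  genes, `r_const = 12 /s` is the artificial fast-sampling rate (below).

The engine recomputes all event propensities from the current
configuration at each step (O(n + free sites) per event, a few
microseconds compiled); this is trivially consistent with the energy
model and is cross-checked exactly against an independent pure-Python
event enumeration and distributionally against enumeration oracles.

## Enzyme-renormalized equilibrium sampling

Without enzymes the dynamics are in equilibrium and the stationary law
depends only on the energies, not on which detailed-balance moves are
simulated. We therefore sample with absorption/desorption moves *only*
(`r_const = 12 /s`), which bypass the jamming of one-dimensional diffusion
at density ~0.9 and converge orders of magnitude faster.

With enzymes, the non-equilibrium steady state is represented by an
equilibrium system with an effective attractive nearest-neighbour
potential `u_eff(gap)`. We obtain `u_eff` by calibration rather than from
a closed form: a linear well on `[147, 332]` bp whose slope is fitted so
the *exact* Boltzmann gap distribution of the effective ring (computed by
convolution over gap compositions) reproduces the gap distribution
measured from direct fixed-N diffusion+enzyme kinetics on a reduced
lattice (L = 2940 bp, N = 17, six replicas of 7×10⁵ s). The fit
residual (total-variation distance) is recorded and must stay below 0.2;
in practice it is ≈0.01. A useful a-priori estimate comes from the biased
random walk of a single pair gap, which shrinks at `2D + k` and grows at
`2D`, giving slope `ln(1 + k/2D)` per bp: 0.077 for `k = 0.16`
(fitted: ≈0.081, contact depth ≈15 kBT), 0.039 for `k = 0.08`
(fitted: ≈0.054, depth ≈10 kBT; the single-pair estimate ignores
many-body screening and anchors only the magnitude). The fitted depth
carries a few-kBT spread across reference seeds because individual
reduced-lattice trajectories linger in few-cluster coarsening states;
the chemical-potential calibration downstream absorbs this spread, so
ensemble density statistics are robust to it. The implementation
contract is steady-state
equivalence, which the test suite verifies directly; if the closed-form
renormalized potential became available it could slot in as an
alternative `u_eff` provider and would be held to the same test.

## Chemical-potential calibration

`calibrate_mu` finds `μ` such that the steady-state mean occupied
fraction `⟨n⟩·147 / L_eff` hits a target (default 0.88). Following the
convention that density is measured over accessible DNA, the barrier
presets use `L_eff = 14400` bp (lattice minus barrier support), which
puts the bound-count mode at ≈86 nucleosomes. The search is a stochastic
bisection: the mean count is strictly decreasing in `μ`, each probe is a
short ensemble under the model's own dynamics, and the full probe trace
is returned. Probes start from a crystalline cluster with a single large
void rather than a random placement: at a badly wrong `μ` the
absorption/desorption dynamics jam (no insertable ≥294-bp gap and
negligible desorption), and a jammed random-init probe would freeze at
its initial density and mislead the bracketing, whereas a jammed
crystalline-init probe first fills its void and still lands on the
correct side of any sub-saturation target.

## Analysis layer

Density profiles are dyad counts per bp, averaged over samples and
normalised by the lattice-wide mean dyad density (bulk = 1), over a
default window of [−500, +1500] bp around the TSS at 1-bp bins.
Smoothing is a mass-preserving Gaussian kernel (default bandwidth 10 bp,
configurable, recorded in profile metadata). Peaks are local maxima of
the smoothed profile with prominence ≥5% of the profile range and
≥100 bp separation. Profiles are classified `mouse_like` when the second
downstream peak is higher than the first, `yeast_like` when lower, and
`boundary` within a 2% relative tie tolerance. The radial distribution
function counts all circular dyad pair distances and normalises by the
ideal homogeneous expectation; the mean neighbour gap statistic excludes
the gap spanning the TSS (the promoter void) so it tracks bulk spacing.
The +1 nucleosome of a configuration or molecule is the first dyad in
[0, 1000] bp ([−50, 1000] under the yeast convention flag).

## Single-molecule pipeline and synthetic cohorts

Fragment tables (gene, molecule, start, end on the TSS-oriented axis) are
filtered to 140–180 bp, midpoints (floored for odd spans) become dyads,
and each molecule's +1 is its first dyad in the search window; molecules
without one are dropped and genes with no qualifying molecule are
reported. Per-gene standard deviations use the population convention
(divide by n; switchable). The synthetic cohort generator plants per-gene
+1 distributions, downstream arrays at a fixed repeat length, nucleosome
dropout, fragment-length jitter and out-of-band contaminants, providing
ground truth for the recovery and artefact-diagnostic tests.

## Numerical and protocol choices

* Simulated ensembles in the tests and the acceptance script are scaled
  down from the original protocols (hundreds–thousands of replicas,
  5×10³–5×10⁵ s horizons) to 4–8 replicas × 10³–10⁴ s chosen so the
  statistics they feed are converged at the tolerances asserted:
  equilibrium ensembles decorrelate in seconds at `r_const = 12 /s`, and
  explicit-exchange runs use burn-ins ≥20 nucleosome turnover times.
* Replica seeds derive from one master seed through NumPy's
  `SeedSequence`; trajectories are bit-for-bit reproducible.
* Exponential arguments are clamped at ±700 before `exp` (rates far
  beyond any observable scale); blocked moves carry rate exactly 0.
* Degenerate inputs: empty configurations have zero energy and only
  insertion events; a model with all rates zero (or all moves blocked) is
  reported as an absorbing state and the configuration persists to the
  sampling horizon.

## What the synthetic generators do and do not emulate

The fixtures emulate dinucleotide phasing and the *structure* of
single-molecule fragment data (arrays, dropout, length jitter), not real
genome composition, mappability, or MNase/chemical-cleavage biases.
Passing tests therefore demonstrate the correctness of the algorithms and
the internal consistency of the model's phenomenology — statistical
positioning, enzyme condensation with ill-positioned +1 nucleosomes,
exchange-driven erasure — not quantitative agreement with any particular
experimental dataset.

## Known limitations

* No sub-nucleosomal states, partial unwrapping, or explicit
  transcription-factor/Pol II particles; Pol II enters only through the
  exchange rates and the barrier.
* The effective pair attraction is a one-parameter fit validated at one
  reduced scale and density; its transferability across densities is an
  approximation inherited from the renormalization picture.
* On small rings with the deep `k = 0.16` attraction the density-vs-`μ`
  isotherm develops a condensation jump; intermediate target densities
  are then unreachable and `calibrate_mu` reports the discontinuity
  instead of converging. The standard 14.7-kb lattice is large enough
  that the isotherm is smooth at the densities used here.
* In the explicit exchange model the collective ordering of the array
  against the promoter barrier relaxes far more slowly than single-rod
  turnover (hundreds of turnover times); explicit-kinetics ensembles
  therefore need burn-ins of order 10⁴ s at `r_const = 0.1 /s`, and the
  exchange-erasure comparison is asserted relatively (the exchange
  profile must sit several times closer to the no-enzyme profile than
  the enzyme-dominated profile does) rather than to sampling noise.
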
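# Methods

Units everywhere: nm, ns, kJ/mol, degrees, Kelvin; k_B = 0.0083145
kJ/mol/K; default temperature 300 K (k_BT ≈ 2.494 kJ/mol).  Nucleotides are
1-based throughout.

## Collective variables

* **Q** — fraction of native contacts.  The native contact set is built
  from guanine base atoms (O6, N9, C8 by default) on nucleotide pairs
  separated by at least 2 residues, with native distance < 0.45 nm.
  Sharp mode counts pairs with current distance < λ·d_native (λ = 1.2);
  smooth mode averages the rational switch s(r) = (1−(r/r₀)ⁿ)/(1−(r/r₀)ᵐ)
  with (n, m) = (6, 10), r₀ = λ·d_native, and the removable singularity at
  r = r₀ filled with its limit n/m = 0.6.  Q is stored as a fraction; the
  count-scale hill width 2.5 (of 130 contacts) therefore becomes 2.5/130.
  Sharp and smooth agree in the limit of steep switching, except for pairs
  sitting exactly on the cutoff — the property tests exempt a vanishing
  boundary band.
* **dRMSD** — √(mean over i<j of (d_ij − d_ij^native)²) over the C4′
  backbone selection; rigid-motion invariant by construction (only
  internal distances enter), which the tests verify to 1e-9 nm.
* **N_ion** — K⁺–O6 coordination, sharp count below r₀ = 0.35 nm or smooth
  switched sum.
* **R_g** — mass-uniform RMS distance of the selection from its centroid.
* **χ (glycosidic)** — signed dihedral of O4′–C1′–N9–C8 in [−180°, 180°);
  the convention folds +180 to −180 so the syn window (−90°, +90°] and its
  complement partition the circle cleanly.

## Metadynamics, Langevin dynamics and bias exchange

Hills are standard (non-well-tempered) Gaussians; V_G(s,t) sums all hills
deposited at or before t, is non-negative and pointwise non-decreasing in
time.  Dynamics is overdamped Euler–Maruyama,
x′ = x + (dt/γ)F + √(2k_BT·dt/γ)·ξ, with the bias force read from a
600-point grid mirror of the hill history (linear interpolation; outside
the grid the bias is flat, so the landscape itself must confine the
walker).  Exchange partners are drawn uniformly at random per attempt and
accepted with min(1, exp(Δ/k_BT)), Δ = V_a(s_a(x_a)) + V_b(s_b(x_b)) −
V_a(s_a(x_b)) − V_b(s_b(x_a)); on accept, coordinates swap and each bias
stays with its replica.  Neutral replicas carry zero bias, so a
neutral–neutral attempt is always accepted.

**Free-energy readout.**  −V_G(s, t_final) (provided as
`bias_to_free_energy`) fluctuates with an amplitude set by the deposition
flux.  The benchmark readout (`run_metadynamics_1d`) therefore snapshots
the mean-subtracted bias shape every 0.5 ns, declares the landscape filled
once the RMS change between consecutive shapes drops below 1 k_BT (a
plateau of the bias-minus-linear-trend), and averages the shape over the
post-fill window; the negated, min-shifted average is the profile.  If no
plateau is detected the last half is averaged.

**Deposition rate matters.**  Hills must accumulate more slowly than the
walker relaxes inside a well, or the bias surfs ahead of the ensemble and
overfills.  On the double-well benchmark (D = k_BT/γ ≈ 2.5 nm²/ns, well
relaxation ≈ 70 ps) the validated protocol is 0.05 kJ/mol hills of width
0.1 every 20 ps for 100 ns, which recovers the 5 kJ/mol barrier to within
≈ 0.2 kJ/mol averaged over seeds.  The package defaults (0.2 kJ/mol per
1 ps) are kept for the BEMD toy runs, whose basins are deep enough that
only basin identification, not barrier heights, is read off.

**Boltzmann check.**  Unbiased samples are compared to the analytic
Boltzmann density via a chi-square test on 10 equal-probability bins
(quantiles of the analytic CDF).  Langevin samples are serially
correlated, so the statistic is scaled by n_eff/n with n_eff from the
Sokal-windowed integrated autocorrelation time of the coordinate series —
the well-hopping mode dominates τ, which makes the test conservative (it
under-rejects); that is acceptable for a sanity check and stated here so
nobody mistakes its p-values for calibrated ones.

## FEL estimation and basins

The FEL is histogrammed solely from neutral-replica samples (no
reweighting of biased replicas): 40 bins per axis by default over the
observed range padded 5 %, first 20 % of samples discarded as
equilibration, F_bin = −k_BT·ln(count/max count).  Bins below `min_count`
are masked unsupported, and small isolated islands of support (fewer than
max(4, 5 %) of supported bins, 4-connected) are masked as well — such
stragglers carry no information about the barriers separating them from
the rest of the landscape and would otherwise surface as spurious basins.

Basins: every supported bin descends to its lowest 2-/4-neighbour until a
local minimum (ties broken toward the lexicographically smallest bin);
minima whose separating saddle — the lowest max-of-pair over boundary-
adjacent bins — lies less than `min_barrier` (default 1 k_BT) above the
shallower minimum are merged, shallowest persistence first.  Basins are
numbered by ascending minimum free energy.  Frame assignment digitises CV
values into the same bins; frames outside the range or in unsupported bins
are labelled −1.

Exchange diagnostics fit cumulative accepted-exchange counts against time
per replica (least squares; slope and R²); CV coverage reports the
fraction of range segments visited and the number of alternations between
the lowest and highest decile of the range.

## Ensemble statistics

* **Leader clustering** is the one-pass algorithm: each frame joins the
  first existing representative within the threshold (0.3 nm dRMSD; 0.45
  nm for high-temperature unfolding runs) in creation order, else founds a
  new cluster.  Order dependence is inherent to the recipe and is kept;
  the acceptance benchmark checks exact agreement with an independent
  reference that precomputes the full pairwise distance matrix.
* **Hydrogen bonds** use a distance-only criterion (donor–acceptor points
  ≤ 0.35 nm) because the reduced representation carries no explicit
  hydrogens; with hydrogens present a 135° donor–H–acceptor angle would
  additionally apply.  A pair is bonded in a frame when any donor/acceptor
  combination of the two nucleotides satisfies the criterion; the map is
  the per-pair fraction of bonded frames, annotated native/non-native
  against the same criterion on the reference structure.
* **Ion binding**: a nucleotide is bound when an ion sits within 0.35 nm
  of its O6 (shared default with the N_ion CV); the mean bound count
  counts each ion once per frame if it is near at least one O6.
* **Syn/anti**: χ ∈ (−90°, +90°] is syn.  A nucleotide is classified as
  its single state when that state occupies ≥ 0.8 of frames with fewer
  than 2 transitions, else "fluctuating".  Mean dwell times average
  uncensored runs (first and last runs touch the trajectory boundaries and
  are dropped when at least three runs exist); at the 1 ns default stride
  the geometric-discretisation bias on a 10 ns dwell is ≈ 5 %, well inside
  the factor-1.5 recovery target.
* **Pathway graphs**: stage-label sequences are run-length collapsed;
  consecutive distinct labels become directed edges with counts aggregated
  over trajectories, and per-path multiplicities sum to the trajectory
  count.

## Synthetic generators (the study conditions)

`make_toy_quadruplex` builds a deterministic pseudo-atom (3+1)-style
quadruplex: `repeat_len` stacked tetrad layers (0.34 nm rise) of
`n_repeats` guanines on concentric rings (O6 at 0.18 nm from the channel
axis, C8/N9/C1′/C4′ at 0.45/0.55/0.70/0.95 nm), channel K⁺ sites between
layers, and per-nucleotide donor/acceptor points arranged so that D0 of
each guanine meets A0 of its ring neighbour at ≈ 0.29 nm — twelve
Hoogsteen-like native bonds for the default 4×3 geometry.  C8 is placed by
natural-extension-reference-frame construction so the χ torsion is exact;
the first repeat is syn, the rest anti, emulating a mixed hybrid pattern.

`make_intermediate_ensemble` plants, per frame: Bernoulli hydrogen-bond
contacts (in-contact donor distance uniform in [0.28, 0.33] nm,
out-of-contact in [0.5, 0.8] nm — straddling the 0.35 nm criterion with
margin; the donor moves along a fixed outward direction whose entire
placement segment is validated to clear every acceptor that would change
another pair's statistic, otherwise the generator raises an infeasibility
error naming the pair), channel-site ion occupancies (unoccupied ions are
parked in a far reservoir), two-state Markov χ dynamics with exponential
dwell times (libration noise 6°, five sigma inside the window edges so
state labels follow the planted telegraph, not noise tails), and Gaussian
noise (0.01 nm) on the core atoms.  The default study conditions are 2000
frames at 1 ns stride, native bond probability 0.9 on three tetrad bonds,
non-native probability 0.3 on two cross-ring pairs, site occupancies
(1.0, 0.5) (mean bound count 1.5), and 10 ns dwell on two nucleotides.

`make_unfolding_set` realises each stage as the native structure uniformly
scaled (step 0.5 per stage rank, i.e. consecutive stages are ≈ 0.7 nm
apart in dRMSD — far beyond both clustering thresholds), with 5 frames per
stage and 0.02 nm noise; the planted pathway multiplicities (default
8/1/1 over 10 trajectories) are returned alongside the trajectories.

Analytic landscapes: `double_well` U = h(x²−1)² (barrier h at x = 0,
minima ±1), `two_basin_2d` adds a harmonic y confinement (minima (±1, 0)),
`multi_basin_2d` sums Gaussian wells under a quartic confinement; all with
exact gradients (tested against central differences at 1e-5 relative).

**What the generators do not emulate:** real DNA mechanics, force-field
energetics, solvent, sequence effects, or correlated multi-pair bond
dynamics.  Passing tests demonstrate that the estimators recover planted
statistical structure at realistic sample sizes — not that the toy
geometry reproduces any particular experimental quadruplex.

## Numerical choices and limitations

* Euler–Maruyama needs dt·U″_max/γ ≲ 0.1 for faithful stationary
  statistics; the benchmarks use dt = 2e-4 ns (γ = 1) on landscapes with
  U″ ≤ ~150 kJ/mol/nm².
* Histogram FELs inherit binomial noise ≈ k_BT/√count per bin; basin
  minimum positions therefore wander by about one bin at the benchmark
  sample sizes, and the integration test checks locations at ±1 bin.
* The exchange scheme (uniform random pair per attempt) is one of several
  reasonable choices; diagnostics are computed from the logs and are
  scheme-agnostic.
* PDB I/O (via biotite) stores Ångström with 3 decimals, so coordinates
  round-trip to 1e-4 nm; frame times are not representable in PDB and must
  be re-supplied on read.
* Leader clustering is O(frames × clusters) with a dRMSD per comparison;
  the streaming path precomputes per-frame pairwise-distance vectors, so
  frames must fit in memory.
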
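# gqfold

Bias-exchange metadynamics (BEMD) and folding-pathway analysis for
G-quadruplex-like systems, exercised on analytic landscapes and synthetic
conformational ensembles.

## The problem

Folding of a DNA G-quadruplex — four-stranded structures of stacked
G-tetrads coordinating channel K⁺ ions — happens far beyond the reach of
plain molecular dynamics.  The established computational route is:

1. **Bias-exchange metadynamics.**  Several replicas run in parallel, each
   depositing repulsive Gaussian hills along one collective variable (CV),

   *V_G(s, t) = Σ_{t' ≤ t} w · exp(−(s − s(t'))² / 2σ²)*,

   so that after filling, *F(s) ≈ −V_G(s, t)*.  Replicas periodically
   attempt configuration swaps accepted with the Metropolis-like
   probability *min(1, exp([V_a(s_a(x_a)) + V_b(s_b(x_b)) − V_a(s_a(x_b)) −
   V_b(s_b(x_a))]/k_BT))*.  Unbiased "neutral" replicas sample the
   corrected ensemble, from which the free-energy landscape (FEL) is
   histogram-estimated as *F_bin = −k_BT ln(n_bin/n_max)*.
2. **Four collective variables**: the fraction of native contacts *Q*, the
   distance-RMSD of the backbone (C4′ atoms) to the native structure, the
   K⁺–O6 coordination number *N_ion*, and the radius of gyration *R_g*
   (hill widths 2.5/130, 0.02 nm, 0.5 and 0.2 nm respectively).
3. **Per-intermediate statistics** on ensembles of each FEL basin: one-pass
   leader clustering (0.3 nm dRMSD threshold), hydrogen-bond formation
   probability maps, per-nucleotide ion-binding probabilities and mean
   bound-ion counts, syn/anti classification of the glycosidic torsion
   (O4′–C1′–N9–C8), and directed pathway graphs counting how many
   unfolding trajectories traverse each stage sequence.

`gqfold` implements this analysis stack and validates it where it can be
validated exactly: on analytic toy landscapes (overdamped Langevin dynamics
replaces the MD engine) and on synthetic pseudo-atom ensembles with planted
statistical structure, so that every estimator can be checked against the
ground truth it should recover.  It does not run all-atom MD.

## Worked example

```python
import numpy as np
from gqfold import (make_toy_quadruplex, build_native_contacts, evaluate_cv_vector,
                    make_analytic_landscape, run_metadynamics_1d, Schedule,
                    default_intermediate_spec, make_intermediate_ensemble,
                    hbond_map, ion_binding_profile)

# the four CVs on the synthetic native quadruplex
native = make_toy_quadruplex()
contacts = build_native_contacts(native)
print(evaluate_cv_vector(native, native, contacts))

# metadynamics on a double well, h = 5 kJ/mol at 300 K
land = make_analytic_landscape("double_well", h=5.0)
sched = Schedule(dt=2e-4, deposit_stride=0.02, total_time=100.0)
run = run_metadynamics_1d(land, sched, width=0.1, height=0.05, seed=1)
print(f"barrier estimate: {np.interp(0.0, run.grid, run.profile):.2f} kJ/mol "
      f"(true 5.00), filled at {run.fill_time:.1f} ns")

# planted-statistics recovery on a 2000-frame synthetic intermediate
spec = default_intermediate_spec(seed=0)
traj = make_intermediate_ensemble(spec, native)
h = hbond_map(traj, native=native)
print(f"H-bond p(1,4): {h.pair(1, 4):.3f} (planted 0.90)")
print(f"mean bound ions: {ion_binding_profile(traj).mean_bound_count:.3f} (planted 1.50)")
```

prints

```
CVVector(q=1.0, drmsd=0.0, n_ion=16.0, rg=0.9897306030767498)
barrier estimate: 5.18 kJ/mol (true 5.00), filled at 1.0 ns
H-bond p(1,4): 0.906 (planted 0.90)
mean bound ions: 1.494 (planted 1.50)
```

The native reference scores `q = 1`, `drmsd = 0` by definition; `n_ion = 16`
counts the sharp K⁺–O6 contacts of the two channel ions; the metadynamics
barrier estimate lands within a few percent of the analytic 5 kJ/mol; and
the ensemble estimators recover the planted hydrogen-bond probability and
ion occupancies to binomial accuracy.

## Command line

Each analysis chain is also a `gqfold` subcommand (`bemd-toy`, `fel`,
`cluster`, `analyze-ensemble`, `unfold-pathways`, `full-synthetic`,
`make-fixtures`), e.g.

```
gqfold full-synthetic --out run1 --seed 1
```

writes CV traces, the neutral-replica FEL with identified basins, exchange
diagnostics, the hydrogen-bond map, ion-binding profile, syn/anti table,
cluster table and pathway graph, plus a checksummed manifest; re-running
with the same seed reproduces the summary byte for byte.

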
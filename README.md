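# ferrobind

Analysis toolkit for studying how acidic, iron-binding proteins and
peptides (such as the magnetosome protein Mms6 and its C-terminal peptide
C20Mms6) steer room-temperature co-precipitation of mixed Fe²⁺/Fe³⁺
solutions toward magnetite. It is aimed at researchers combining pH
titration, molecular simulation and NMR titration data on
peptide–metal–mineral systems.

Three pipelines, usable independently from Python:

1. **Titration → mass balance.** A co-precipitation titration is described
   by *X* = Fe³⁺/(Fe²⁺+Fe³⁺) and *R* = mol NaOH per mol Fe. The staircase
   pH record has equivalence points E1 (ferric precipitation; theory
   R₁ = 2.75·X for schwertmannite at sulfate substitution z = 1/8) and E2
   (mixed-mineral end point). E2 decomposes by the lever rule into
   iron-molar fractions f of ferrous hydroxide, green rust and magnetite:
   Σf = 1, Σf·Xᵢ = X, Σf·Rᵢ = R. The package generates synthetic
   three-plateau curves with known ground truth, detects E1/E2/E* on noisy
   curves via smoothed-derivative peak picking, compares control vs
   additive runs, and solves the mass balance — including the constrained
   variant with equal green-rust and magnetite fractions, which at X = 0.2
   forces f_GR = f_M = X (20 % magnetite).
2. **Ion binding → free energy.** A toy Metropolis Monte Carlo sampler
   moves one ion among fixed oxygen sites with Gaussian distance-shell
   wells (tunable depth, 300 K, periodic 40 Å box). Trajectory analysis
   classifies binding at the 3 Å ion–oxygen criterion, computes site
   occupancy and co-binding statistics, builds the shell-normalized radial
   distribution function g(r) (tail-normalized to 1), Boltzmann-inverts it
   to the free-energy profile A(r) = −RT ln g(r), and annotates the
   binding well and desorption barrier.
3. **NMR chemical-shift perturbation.** For the C20Mms6 peptide
   (Ac-KSRDIESAQSDEEVELRDAL-Am), per-residue amide and mean side-chain
   shift changes between apo and metal-added conditions, random-coil Hα
   deviation statistics, and hotspot ranking with contiguous-cluster
   reporting (the DEEVE acidic cluster, residues 11–15).

See `docs/methods.md` for models, parameters and limitations.

## Worked example

`examples/titration_mass_balance.py` simulates a noisy control/additive
titration pair at X = 0.2, detects the equivalence points and solves the
mass balance:

```
control   E1 = 0.551  E2 = 2.134  pH(E*) = 7.01
additive  E1 = 0.544  E2 = 1.983  pH(E*) = 6.60

control - additive:  dpH(E*) = 0.403  dE2 = 0.151
...
E1 residual vs schwertmannite line R = 2.75 X: +0.0012

iron-molar mineral fractions at the control E2 (percent):
  ferrous_hydroxide 60.1%, green_rust 19.8%, magnetite 20.1%
...
additive-mediated scenario at X = 0.2 — equal green-rust and magnetite fractions:
  ferrous_hydroxide 60%, green_rust 20%, magnetite 20%
```

Both E1 values sit on the schwertmannite line (residual ≈ 0); the additive
run shows the ferrous-sequestration signature (middle plateau 0.4 pH lower,
E2 advanced by 0.15 R — the injected generator truth, recovered by the
detector); and the decomposition recovers the generating end mixture to a
fraction of a percent. `examples/ion_binding_pmf.py` recovers a −6.7 kJ/mol
binding well to 0.02 kJ/mol from 2×10⁶ Monte Carlo sweeps and prints the
occupancy ranking of the 12-site cluster; `examples/csp_hotspots.py` ranks
residues 11, 12, 13, 15 as the top perturbed set with clusters
(11–13) and (15).

A thin CLI mirrors the library (`ferrobind titrate-sim | detect |
massbalance | binder-sim | traj-analyze | csp | run | fixtures`), e.g.

```bash
ferrobind titrate-sim --x 0.3 --protein --seed 1 -o run.csv
ferrobind detect -i run.csv -o points.json
ferrobind massbalance --x 0.3 -i points.json -o fractions.json
```

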
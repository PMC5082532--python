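"""Ion-binding free energy: from a Monte Carlo trajectory to a binding well.

Runs the toy single-ion Metropolis sampler in a one-site model with a known
well depth, classifies binding at the 3 A contact criterion, builds the
tail-normalized radial distribution function and Boltzmann-inverts it to a
free-energy profile whose annotated well should recover the input depth.
"""

import ferrobind as fb

DEPTH = -6.7  # kJ/mol ground truth

model = fb.single_site_model(DEPTH)
traj = fb.simulate_ion(model, n_sweeps=2_000_000, sample_every=10,
                       start_site="o01", seed=1)
print(f"sampled {len(traj)} frames, acceptance {traj.acceptance_rate:.2f}")

records = fb.binding_series(traj, cutoff=3.0)
print(f"bound fraction (ion within 3 A of an oxygen): "
      f"{records.bound_fraction:.3f}")

profile = fb.well_and_barrier(fb.free_energy(fb.rdf(traj)))
r_min, depth = profile.well
print(f"\nfree-energy well: {depth:.2f} kJ/mol at r = {r_min:.2f} A "
      f"(ground truth {DEPTH} kJ/mol at 2.85 A)")
print(f"desorption barrier: {profile.desorption_barrier:.2f} kJ/mol")
print("(well depth = -RT ln g at the first RDF peak; the recovery error "
      "reflects finite sampling only)")

# multi-site ensemble: occupancy statistics over the 12-site cluster
cluster = fb.default_deev_model()
ensemble = fb.batch_ensemble(cluster, n_starts=12, seeds=list(range(12)),
                             n_sweeps=200_000, sample_every=10)
import numpy as np
import dataclasses
pooled = dataclasses.replace(
    ensemble[0], frames=np.concatenate([t.frames for t in ensemble]))
occ = fb.site_occupancy(fb.binding_series(pooled))
top = sorted(occ.items(), key=lambda kv: -kv[1][0])[:3]
print("\nmost-occupied sites in the 12-site cluster "
      "(occupancy among bound frames):")
for sid, (p, cat) in top:
    print(f"  {sid}: {p:.2f} ({cat})")
print("(the three deep sites of the cluster dominate binding, as built)")
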
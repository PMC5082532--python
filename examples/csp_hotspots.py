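"""Chemical-shift perturbation: mapping the metal-binding hotspot.

Generates a synthetic apo/holo shift-table pair for the C20Mms6 peptide with
a DEEVE-cluster perturbation, computes per-residue amide and mean side-chain
shift changes, checks the apo state against random-coil values, and ranks
the perturbed residues.
"""

import ferrobind as fb

apo, holo = fb.synth_shift_tables(
    hotspot_residues=(11, 12, 13, 15),   # D11, E12, E13, E15
    effect_size=0.05,                    # ppm on side-chain protons
    noise_sd=0.005,
    secondary_residues={6: 0.4},         # weaker E6 site
    seed=7,
)

_, summary = fb.random_coil_deviation(apo)
print("apo Halpha deviation from random coil: "
      f"max {summary['max_abs']:.3f} ppm, mean {summary['mean_abs']:.3f} ppm")
print("(small deviations = unstructured peptide, as expected for the apo "
      "state)")

table = fb.delta_shifts(apo, holo)
ranked, clusters = fb.rank_hotspots(table, k=4)
print(f"\ntop-4 perturbed residues: {sorted(ranked[:4])}")
print(f"contiguous clusters: {clusters}")
print(f"next-ranked residue: {ranked[4]}")

seq = fb.PEPTIDE_SEQUENCE
print("\nper-residue mean side-chain shift change (ppm):")
for row in table.itertuples():
    bar = "#" * int(abs(row.mean_sidechain_delta) / 0.005) \
        if row.mean_sidechain_delta == row.mean_sidechain_delta else ""
    print(f"  {row.residue:2d} {seq[row.residue - 1]}  "
          f"{row.mean_sidechain_delta:+.3f}  {bar}")
print("(the DEEVE cluster 11-15 carries the signal; residue 6 is the weak "
      "secondary site)")
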
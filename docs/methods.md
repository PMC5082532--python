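# Methods

`ferrobind` implements three desk-scale analysis pipelines for studying how
an acidic, ferrous-binding peptide or protein steers alkaline iron
co-precipitation toward magnetite. Each pipeline pairs a synthetic-data
generator (the testbed, with known ground truth) with the analysis that
would be applied to real measurements.

## 1. Titration mass balance

### Coordinates and mineral vertices

A co-precipitation titration is tracked in the dimensionless coordinates
*X* = Fe³⁺/(Fe²⁺+Fe³⁺) (ferric molar fraction of the initial solution) and
*R* = mol NaOH added per mol total Fe. Every candidate mineral maps to a
vertex (Xᵢ, Rᵢ) given exactly by its stoichiometry, with hydroxide counted
per mole of iron:

| species | formula basis | X | R |
|---|---|---|---|
| ferrous hydroxide | Fe(OH)₂ | 0 | 2 |
| green rust (sulfate) | Fe″₄Fe‴₂(OH)₁₂·SO₄ | 1/3 | 2 |
| magnetite | Fe″Fe‴₂O₄ (8 OH⁻ per formula) | 2/3 | 8/3 |
| goethite | FeOOH | 1 | 3 |
| schwertmannite | FeO(OH)₁₋₂z(SO₄)z per Fe | 1 | 3−2z |

The sulfate substitution of schwertmannite defaults to z = 1/8, giving
OH/Fe = 2.75 and hence the first-equivalence-point line R₁ = 2.75·X (all
ferric iron precipitating as schwertmannite). z is configurable; 1/8 is the
only value for which the formula balances cleanly. Vertices are computed as
exact rationals before conversion to float. Goethite is registered for
diagram completeness but excluded from the default decomposition candidate
set, which covers the 0 ≤ X ≤ 2/3 mixed-mineral regime with
{ferrous hydroxide, green rust, magnetite}.

### Decomposition (lever rule)

A second equivalence point (X, R) inside the triangle of three candidate
vertices has unique iron-molar fractions f solving total-iron, ferric-iron
and hydroxide conservation:

    Σ fᵢ = 1,  Σ fᵢXᵢ = X,  Σ fᵢRᵢ = R.

This is a 3×3 linear solve (barycentric coordinates). Fractions with
|f| < tol are clamped to zero and renormalized; any fraction below −tol
flags the point as outside the region, naming the violated constraint.
Default tol = 1e−6 separates numerical noise from genuinely infeasible
points; analyses of noisy detected points may pass a larger tol at the
scale of their measurement error (a true boundary mixture — e.g. zero
ferrous hydroxide at X = 0.6 — lands marginally outside the simplex about
half the time under noise). Percentages are per mole of iron, because the
conservation laws are written per Fe; a per-formula-unit basis would weight
green rust 6× per formula and is not used.

The constrained variant `equal_pair_solve` imposes equal fractions on two
ferric-bearing species; with the green-rust/magnetite pair over ferrous
hydroxide, ferric conservation forces f_GR = f_M = X, e.g. 20 % magnetite,
20 % green rust, 60 % ferrous hydroxide at X = 0.2 — the additive-mediated
end point in ferrous-rich conditions.

### Synthetic titration curves

The generator emulates the staircase morphology of a constant-feed
titration: three pH plateaus joined by two logistic steps centred at the
stoichiometric breakpoints E1 = 2.75·X and E2 = Σ fᵢRᵢ of a chosen end
mixture:

    pH(R) = p₁ + (p₂−p₁)σ(s(R−E1)) + (p₃−p₂)σ(s(R−E2)) + ε,  ε ~ N(0, σ_pH²)

Defaults: plateau levels (2.5, 7.0, 12.5) — qualitative values for the
ferric-precipitation, mixed-mineral and excess-base stages; step sharpness
s = 20 R⁻¹; logger noise σ_pH = 0.02 (a realistic pH-meter figure; chosen,
not measured); feed rate 0.05 R/min with 3 s logging cadence, so the R grid
step is exactly 0.0025 (matching 50 µL/min of 1 M NaOH into 20 mL at 50 mM
total Fe); total iron 50 mM. The default end mixture splits ferric iron
equally between green rust and magnetite for X ≤ 0.5 and exhausts ferrous
hydroxide beyond. The "protein" mode lowers the middle plateau by 0.4 pH
and advances E2 by 0.15 R for X ≤ 0.4 — the empirical signature of a
ferrous-sequestering additive in ferrous-rich runs. Note the E2 advance is
a curve-shape effect only; it is not itself a feasible re-mixture (a
magnetite-richer end point at fixed X has a *larger* E2), and decomposing
such a shifted point correctly reports out-of-region.

What the generator does **not** emulate: precipitation kinetics and
speciation equilibria, electrode drift and hysteresis, CO₂ ingress, the
overnight maturation that converts green rust to magnetite, and redox
evolution (an Eh channel is carried through file I/O but never modelled).
Passing closure tests therefore show the detection and decomposition
machinery is correct, not that real curves are this clean.

### Detection

E1 and E2 are the two most prominent local maxima of the Savitzky–Golay
smoothed derivative dpH/dR (window 11 samples, polynomial order 3, edge
handling by the filter's polynomial edge fit; prominence floor 1 pH/R).
Peak positions are refined to sub-grid precision with the first moment of
the derivative over its contiguous half-maximum region — unbiased for
symmetric steps, and an order of magnitude more stable under noise than a
three-point parabola (±0.004 R vs ±0.03 R at σ_pH = 0.02). This matters
because the linear solve amplifies E2 error into the green-rust fraction
with slope 3. The middle plateau is delimited where the gradient falls
below 20 % of the adjacent step peak; E* is the span midpoint, and its pH
is read from the smoothed curve to damp logger noise. Control-vs-additive
deltas are taken at each run's own E* by default (evaluation at a common R
is available as an option). A strictly monotone ramp, or any curve with
fewer than two qualifying peaks, raises "steps not found" rather than
returning garbage.

## 2. Ion-binding simulation and free energy

### The toy sampler

A single ion moves in a periodic cube (edge 40 Å) containing fixed oxygen
sites. Each site k contributes an attractive Gaussian well in the
ion–oxygen distance d:

    u_k(d) = D_k · exp(−(d − r0)² / 2w²),  D_k ≤ 0,

with bond-distance offset r0 = 2.85 Å and width w = 0.35 Å by default, so
the bound population occupies a shell at chemically sensible Fe–O
separations (≈2.5–3.25 Å). Placing the well minimum on a shell rather than
at d = 0 is deliberate: the free-energy estimator reads g(r) from
spherical-shell histograms, and a minimum at r → 0 sits where shell volume
— and therefore counts — vanish, making depth recovery statistically
hopeless at desk-scale run lengths. The shell form keeps closed-form
ground truth: for a single site the exact tail-normalized RDF is
g(r) = exp(−u(r)/RT), so the expected well depth equals D.

Sampling is Metropolis at 300 K (β = 1/RT, R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹):
uniform proposals in a cube of edge 5 Å, minimum-image distances, periodic
wrapping, 1000 burn-in sweeps, one retained frame per 10 sweeps. With
mostly-flat energy landscapes acceptance sits near unity and is logged per
run. The sweep kernel is compiled with numba; 2×10⁶ sweeps take about a
second. Runs are deterministic per seed (the kernel RNG is seeded from the
user seed).

The bundled 12-site cluster is a synthetic stand-in for the oxygen
constellation of a DEEV-like acidic tetrapeptide: 12 sites on a 4.5 Å
shell around the box centre, three strong (−9 to −11 kJ/mol, the
carboxylate/bridging-carbonyl class) and nine weak (−4 kJ/mol). It is a
documented fixture, not a structural claim. An "Fe3" model applies a
uniform depth scale > 1, the minimal representation of the extra charge
making binding more favourable but unselective. Omitted entirely: explicit
solvent, electrostatics and force-field energetics, peptide flexibility,
and concentration effects — so absolute occupancies are not comparable to
molecular-dynamics values; only the analysis chain is.

### Trajectory analysis

A frame is *bound* when the ion is within the cutoff (3.0 Å, closed
interval — the boundary convention is documented and configurable) of at
least one site. Site occupancy is the fraction of bound frames in which a
given site is in contact, labelled high/medium/low at configurable
thresholds (0.4 / 0.15). Co-binding is the conditional probability
P(b bound | a bound), reported as undefined (not 0) when the marginal is
empty.

The RDF pools ion–site distances over frames and sites into bins of 0.05 Å
(resolving a 2.55–3.25 Å first peak with 14 bins) up to r_max = half the
box edge; each bin is divided by its spherical-shell volume and the profile
is scaled so the mean over the tail window [r_max−3 Å, r_max] is 1 — tail
normalization is chosen over box-density normalization precisely so that
g → 1 at large separation and the free energy is zero there. Boltzmann
inversion gives A(r) = −RT ln g(r); bins with g = 0 are reported as absent
(NaN), never ±∞.

Well/barrier annotation: the well is the global minimum of A (required
negative), the barrier the highest maximum between the well and the first
return of A to the tail level, and the desorption barrier their sum
|depth| + max(height, 0). For histogram-derived profiles, bins holding
fewer than 5 counts are ineligible as the well: a near-empty small-radius
shell has order-one Poisson error in g and otherwise yields spurious deep
minima. Recovery accuracy at the default run length (2×10⁶ sweeps) is a
few tenths of a kJ/mol across the −4 … −11 kJ/mol depth range.

## 3. Chemical-shift perturbation

The peptide is fixed to the 20-residue acidic sequence
KSRDIESAQSDEEVELRDAL (capped termini; caps are not indexed). Per residue,
the analysis reports the amide-proton shift change and the mean side-chain
(HB/HG) shift change between an apo and a metal-added condition, averaging
only atoms observed in both (paramagnetic broadening removes atoms; the
count of lost atoms is reported, absent residues are flagged NaN rather
than zero). Conditions must match in pH within 0.05 — metal stocks acidify
the sample and pH drift mimics binding shifts — and in sequence.

Hotspot ranking orders residues by |mean side-chain Δδ|, breaking ties by
|amide Δδ| then index (so an all-zero table yields stable index order),
and reports maximal runs of adjacent indices within the top-k as clusters.
Random-coil deviation is observed − reference for Hα, summarized by max
|dev|, mean |dev| and the sample standard deviation (ddof = 1) of |dev|.
The packaged reference table carries standard literature random-coil ¹H
values for the ten residue types present; it is plain CSV and fully
substitutable, since published deviation statistics depend on which
reference set is used.

The generator draws the apo table as reference + N(0, σ) jitter
(σ = 0.005 ppm default) and adds a specified effect (0.05 ppm default) to
the side-chain protons of hotspot residues (half of it to the amide),
optional weaker secondary residues, fresh noise, and optional atom dropout
emulating PRE losses. It models endpoint comparison only (e.g. 3 metal
equivalents); no binding-isotherm/Kd model is fitted anywhere.

## Workflows, determinism, problem sizes

`run_workflow` executes one pipeline end to end into an output directory
and writes a manifest with the package version, parameters, seed and a
sha256 checksum per artifact. All numeric text output is formatted at 6
significant digits, which is what makes byte-for-bit reproducibility a
testable contract across platforms. Every workflow requires an explicit
seed because every bundled input is generated.

Default problem sizes are chosen so the full test suite and the acceptance
script each run in minutes on one CPU: titration curves of ~1–2×10³
samples, closure sweeps of 20 seeds, single-well recovery at 2×10⁶ sweeps
per depth, hotspot recovery over 50 seeds. These are the package's
standard operating points; all are parameters.

## Known limitations

- The titration model is morphological; it cannot answer kinetic or
  mechanistic questions about the precipitation chemistry itself.
- The decomposition assumes the chosen three minerals are the only sinks
  of iron and base; goethite-bearing regimes (X > 2/3) need a different
  candidate set, which the API accepts but no default covers.
- The ion sampler's statistics (bound fractions, occupancies) depend
  entirely on the synthetic well parameters and are not predictions for
  any real peptide.
- The CSP stage ranks perturbations; it does not locate metals, fit
  affinities, or model exchange broadening.
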
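# Methods

`ligandshell` simulates the self-assembly of binary thiolate monolayers
(a short PEG thiol, 2-ethoxyethane-1-thiol, paired with dodecanethiol, DDT)
on ultrasmall gold nanoparticles, and converts monolayer structures into
the Au₄L₄ fragment statistics that MALDI mass spectrometry measures.  This
note records the model, its assumptions, the tunable parameters, and the
design choices taken where the problem was genuinely open.

## The particle model

**Core.**  The gold core is a closed-shell Mackay icosahedron on an FCC
lattice (lattice constant a = 4.08 Å, the bulk gold value), rigid and
centred at the origin.  Atoms are generated shell by shell from the 20
triangular faces of an ideal icosahedron; the radial shell spacing is the
FCC nearest-neighbour distance a/√2 = 2.885 Å, which is also the minimum
interatomic distance (tangential spacings are the usual 1/sin 72° ≈ 1.05
larger).  A k-shell cluster has N(k) = 10k³/3 + 5k² + 11k/3 + 1 atoms,
10k² + 2 of them on the surface.

*Diameter convention.*  "Mid-diameter" is defined as the mean of the
vertex-to-vertex and face-to-face outer diameters, measured across atom
surfaces (one Au atom diameter, a/√2, is added to the centre-to-centre
value).  Electron-microscopy sizing measures the projected extent of the
electron density, which includes the atomic radii, so this is the
convention an experimental 2.8 nm readout corresponds to.  Under it, k = 5
(561 atoms, 252 surface) gives 2.88 nm and is the default shell count; a
pure centre-to-centre mean would give 2.59 nm and make k = 5 look too
small, which we judged the less faithful reading.  Only the outer three
layers are retained by default (506 atoms); inner shells are outside every
interaction range.

**Binding sites.**  One atop site per surface gold atom, with the outward
normal taken as the radial unit vector.  Sulfur sits on that normal at the
Morse equilibrium distance.  Atop sites are the simplest model consistent
with at most one thiolate per surface atom; nothing in the fragment
statistics depends on the hollow-vs-atop distinction at this resolution.
Vertex sites (the 12 atoms with five surface neighbours) can be excluded
as Jump-move targets ("gap sites on facets"), the default.

## Force field

United-atom OPLS-style ligands: DDT is 13 beads (S + 12 C), PEG is 6 beads
(S, CH₂, CH₂, ether O, CH₂, CH₃).  No hydrogens.  Terms:

* harmonic bonds and angles, E = k (x − x₀)² — note the convention carries
  no ½; the shipped constants are stated for this form;
* OPLS Fourier dihedrals, E = ½[V₁(1+cos φ) + V₂(1−cos 2φ) + V₃(1+cos 3φ)
  + V₄(1−cos 4φ)], zero at trans;
* 12-6 Lennard-Jones, truncated (unshifted) at 10 Å, geometric mixing for
  both ε and σ;
* Debye-screened Coulomb, q₁q₂ e^(−κr)/(ε_r r), truncated at 12 Å, with
  ε_r = 24.35 (ethanol-like) and Debye length 5 Å (κ = 0.2 Å⁻¹).  The
  screening length is configurable: the value "5 Å" is dimensionally a
  length, and we interpret it as such; κ = 5 Å⁻¹ can be set instead via
  `debye_length: 0.2`;
* S–Au Morse attachment between each sulfur and its anchor-site gold atom
  (defaults D_e = 8.763 kcal/mol, α = 1.47 Å⁻¹, r_e = 2.65 Å, from the
  gold–thiolate Morse literature);
* a purely repulsive quadratic guard (k = 50 kcal/mol/Ų inside 2.5 Å of
  any core atom) that keeps beads out of the rigid core.  Gold otherwise
  interacts only through the Morse term; there is no Au–Au energy.

Intra-ligand nonbonded pairs separated by one or two bonds are excluded,
1–4 pairs are scaled by 0.5, and farther pairs count fully.  PEG carries
the OPLS ether charges (O −0.5 e, α-carbons +0.25 e); DDT is apolar.

All numeric constants live in a versioned YAML
(`src/ligandshell/data/opls_ua.yaml`) and every entry can be overridden per
run (`ParameterSet.default({"morse_s_au.D_e": 9.0})` or `--set` on the
CLI).  These values are configuration, not fitted ground truth: the
quantitative monolayer morphology (e.g. composition-resolved SSR levels)
depends on them, and the package's validation targets are therefore the
algorithmic and statistical properties that do not (oracle equalities,
detailed balance, the combinatorial and analytic results), plus
scale-reduced behavioural checks.

## Composition plans

The ligand surface density interpolates linearly between the alkanethiol
packing density on gold (4.70 nm⁻²) and the PEG-thiol density (6.29 nm⁻²):
σ(x) = 4.70 + x(6.29 − 4.70).  Counts use half-up rounding of x·L_total.
The nine published study compositions are also available verbatim
(`plan_from_table`), because the published σ at x ≥ 0.7 deviates from the
linear average (5.73/5.84/6.04 vs 5.81/5.97/6.13) and two L_PEG entries
differ by one from half-up rounding; when reproducing those systems the
printed counts are authoritative.  For arbitrary compositions the total
count comes from σ times the sphere area of the mid-diameter
(A = π·d_mid², ≈ 26 nm² for the default core), a convention consistent
with the published totals to within a few ligands.

## Initial morphologies

All initializers pick `L_total` distinct anchor sites uniformly at random,
then assign types:

* **random** — a random permutation of the (L_PEG, L_DDT) multiset;
* **striped** — 5 Å bands along a random axis, types alternating by band
  parity (PEG on even `floor(z/5)`), then the sites nearest a band
  boundary are flipped until the counts match the plan exactly;
* **janus** — sites sorted by projection on a random pole; the top L_PEG
  are PEG, so one plane separates the types.

Chains start all-trans along the site normal at equilibrium bond lengths
and angles.  On shells below ~2 nm the 5 Å stripe width spans a
hemisphere, so the striped construction degenerates to a Janus split —
the expected limiting behaviour.  `make_perfect_janus_ensemble` draws 50
unrelaxed Janus configurations (fresh pole and site subset each) as the
upper-bound SSR reference at each composition.

## The CBMC engine

Five moves with default proposal weights 10 : 10 : 1 : 1 : 1:

* **Translation** (Metropolis): rigid tangential displacement of one
  ligand, magnitude uniform on [0, 4 Å]; the sulfur is re-projected onto
  the sulfur shell of its nearest anchor site (not snapped to the site),
  and the move is rejected outright if that site already hosts another
  ligand or the sulfur would detach (> r_e + 1.5 Å from the anchor atom).
* **Rotation** (Metropolis): the beads distal to a uniformly chosen pivot
  bead rotate about a random axis through it, angle uniform on
  [−0.1745, 0.1745] rad.  A terminal-bead pivot is the identity.
* **Regrowth** (configurational bias): the chain is cut back to the sulfur
  plus three beads — preserving the first dihedral — and regrown bead by
  bead.  Each bead draws five trial positions at the equilibrium bond
  length, with the polar angle sampled from the exact bending Boltzmann
  density (sin θ · e^(−βk(θ−θ₀)²), rejection-sampled from a Gaussian) and
  the torsion uniform; the Rosenbluth weight carries the remaining
  ("external") energy only — dihedral, nonbonded, core guard.  The old
  chain is retraced with its existing position plus four fresh candidates.
  Acceptance is min(1, W_trial/W_init).  *Why the split:* putting the
  stiff bending term inside the weight of uniformly drawn directions
  (βk ≈ 106 rad⁻²) rejects essentially every multi-bead regrowth; drawing
  from the bonded density and weighting by the external energy is the
  standard construction for stiff chains and leaves detailed balance
  intact because the generation density cancels the bending Boltzmann
  factor.  Bonds are placed exactly at r₀ and every move preserves bond
  lengths, so bonds are effectively rigid.
* **Swap**: a random PEG and a random DDT exchange anchor sites; both are
  rebuilt at the new sites (deterministic all-trans stub, then CBMC
  regrowth, the second chain grown in the presence of the first's new
  coordinates, mirrored in the retrace) and accepted on the product of
  Rosenbluth ratios times the Metropolis factor of the deterministic stub
  energy change.
* **Jump**: a random ligand relocates to a vacant facet anchor site
  10–20 Å from its current anchor (sampling up to 20 gap sites — which is
  marginally uniform over all vacancies, so the proposal density is
  1/n_vacant) and is regrown there; acceptance carries the
  forward/reverse vacancy-count ratio for detailed balance.

Acceptance rates at 298 K on dense shells are ~10–15 % (translation),
~75 % (rotation), ~15–20 % (regrowth), and small for Swap/Jump of the long
DDT chain (log-ratio ≈ −10 to −20): inserting a 13-bead chain into a
PEG-sized vacancy of a packed monolayer is intrinsically rare.  Monolayer
reorganisation is therefore carried mostly by translation diffusion and
PEG relocation; full-scale equilibration needs budgets of order 10⁶
proposals per trial.

Randomness: a single seed feeds a `SeedSequence` that spawns one stream
for move selection and one per move type, so runs are bit-reproducible.
The running energy is updated from accepted proposals and cross-checked
against a full recomputation at every snapshot (observed drift < 1e-11
kcal/mol); snapshots default to every 10,000 proposals.

**Plateau detection** splits the energy log into non-overlapping windows
and declares a plateau when consecutive window means differ by less than
one pooled standard error — a conservative test that becomes stricter with
larger windows.  The default window (50,000 proposals) suits production
budgets; tests use smaller windows on their shorter series.

## Fragment statistics

A fragment draw picks a uniformly random ligand and groups it with its
three nearest neighbours by sulfur–sulfur distance within 6 Å (ties broken
by ligand id); seeds with fewer than three in-cutoff neighbours are
discarded and redrawn, which is implemented — equivalently — as uniform
sampling over eligible seeds.  50,000 draws with replacement build the
five-bin distribution θ (index = PEG count; PEG is ligand A because x_PEG
is the composition axis).  The alternative "three nearest regardless of
distance" rule sits behind `neighbor_rule="nearest"`.  Because a seed
ligand's fragment is deterministic, the exact expectation of the sampler
is the average over eligible seeds (`exhaustive_fragment_distribution`),
which the test suite uses as an oracle.

From θ: the surface fraction x = Σᵢ i·θᵢ/4 (the other ligand's fraction is
1 − x by mole balance); the binomial reference θᵢ = C(4,i) xⁱ(1−x)⁴⁻ⁱ for
random mixing; and the SSR Σᵢ(θᵢ − θ_ref,ᵢ)², which lies in [0, 2] and
reaches 0.6484375 for the ideal Janus histogram at x = 0.5.  The Janus
character of an ensemble is mean SSR_sim / mean SSR_Janus with
quotient-rule error propagation.

**The random-mixing null.**  A single random assignment on a finite shell
(140 ligands) keeps an exhaustive-fragment SSR of ~0.006 (range
0.0006–0.02 across assignments) from finite-size composition structure; it
does not vanish with more draws.  The experimental statement "random SAMs
give SSR ≈ 0.001" refers to spectra that pool ~10¹⁰ particles, so the
simulation null pools draws over an ensemble of independent random
assignments (`random_null_fragment_distribution`, default 50 monolayers
sharing 50,000 draws), which lands at SSR ≈ 1e-4 — the faithful analogue
of the measurement.

**Patches** are connected components of the graph linking same-type
ligands whose anchor sulfurs lie within 6 Å, found with a k-d-tree
neighbour query plus an iterative depth-first search that visits each
ligand once.  The number-weighted average patch size is S = ΣNᵢ²/ΣNᵢ.

## MALDI experimental path

Fragment masses are 4·m(Au) + i·m(PEG-thiolate) + (4−i)·m(DDT-thiolate),
thiolate = molecular mass − 1 H, average atomic masses by default (a
linear TOF at 5000 FWHM does not resolve isotopes near m/z 1600; the
monoisotopic table and cation-adduct offsets are options).  The family
spans 1208.57–1593.43 Da with uniform 96.22 Da spacing, all above the
700 Da ion gate.  Peak areas are trapezoidal integrals in ±window/2
(default 10 Da) around each family mass after subtracting the per-window
median as a constant baseline (disable with `baseline=None` for clean
synthetic spectra).  `synthesize_spectrum` renders Gaussian peaks with
FWHM = m/resolution and an additive absolute noise floor; the
integrate→normalize round trip recovers θ to quadrature accuracy, and the
recovery error falls as total signal grows at fixed noise.

**Exchange-volume calculator.**  The published relation for the PEG volume
to add during ligand exchange is typographically ambiguous (the grouping
of the bracket, and a bulk DDT density appearing where only a surface
density is dimensionally possible).  We implement the dimensionally
consistent per-particle mole balance: dry mass = cores (V_NP·ρ_Au) plus
shells (A_NP·Γ_DDT ligands of mass M_DDT/N_A), giving the attached-DDT
count; then V_PEG = 2R·N_DDT·M_PEG/(N_A·ρ_PEG).  Every factor is a recipe
field; Γ_DDT defaults to the 4.70 nm⁻² packing density, and ρ_DDT is kept
in the recipe but unused on this route.  The contracts that survive any
plausible reading — linearity in R and in the dry mass — are the tested
surface, together with a step-by-step unit-conversion oracle.

## Orchestration and reproducibility

`run_grid` executes a manifest (compositions × trials × init classes),
keeps the final ten snapshots per trial, converts each into θ/SSR/patch
rows, and aggregates per-composition statistics including the Janus
character against the 50-configuration reference.  All seeds derive from
the single grid seed via `SeedSequence` spawning: a rerun is
byte-identical, and every statistic is recomputable from the stored
trajectories alone (XYZ frames store full float precision; the per-row
sampling seed is recorded).  Box statistics use linear-interpolation
(type-7) quantiles with 1.5·IQR whiskers and explicit outliers.  Failed
trials are recorded and the grid continues.

## Scaled-down study conditions used by the test suite

The full protocol (9 × 18 trials, ~10⁶ proposals each) is an
overnight-scale computation (`examples/full_grid.py`).  The suite instead
validates behaviour at reduced, fixed scales chosen so that the relevant
physics is observable:

* engine statistics and bookkeeping on a two-shell core (42 sites,
  ~16–30 ligands);
* detailed balance on a 2-ligand/3-site toy whose sites are equivalent and
  mutually non-interacting (nonbonded terms off), where the exact
  stationary occupancy is uniform; the discrete-site moves (Jump, Swap,
  and a combined set) are checked against it with batch-means errors.
  Translation and Rotation act on continuous coordinates and cannot be
  pinned to a finite state space; their symmetric kernels and the
  Metropolis rule are verified directly instead;
* initialization-independence at x = 0.5 on the two-shell core
  (30 ligands): three trials per starting class, 30,000 proposals each,
  class means of post-burn-in SSR compared within two pooled SDs.  The
  equilibrium SSR distribution on so small a shell is intrinsically broad
  (single trajectories wander ~0.01–0.2), which the pooled-SD band
  reflects.

Passing these says the machinery is correct and the sampler forgets its
initialization at desk scale; it does not certify the quantitative 298 K
morphology of the full-size system, which additionally depends on the
overridable force-field constants above.

## Known limitations

* No explicit solvent; solvation enters only through the dielectric and
  Debye screening.  No polarizability, no Ewald electrostatics, no
  hydrogens, no Au–Au energetics, rigid core.
* Monolayers are at full coverage; exchange kinetics and partial coverage
  are out of scope.
* Swap/Jump acceptance for the long DDT chain is very low in dense shells,
  so composition-pattern decorrelation at full scale is slow; budget
  accordingly and verify the energy plateau plus cross-init agreement.
* Only the Au₄L₄ fragment family is analysed; other AuₙLₙ families exist
  in spectra but are not modelled beyond the mass table.
* Isotope structure, matrix chemistry and instrument effects beyond a
  Gaussian resolution model and additive noise are not simulated.
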
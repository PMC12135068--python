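# Methods

This note documents the models, estimators, defaults and numerical choices
behind `prosolv`, and what the synthetic-system validation does and does
not demonstrate about real MD data.

## Data model and units

Internal units are nm and ps (the GROMACS convention); PDB coordinates
(Å) are converted at the read/write boundary, so writing a frame to both
PDB and GRO produces a 10× raw-coordinate scale factor by design. Atom
and residue indices are 0-based internally; file-facing numbering follows
each format. Boxes are rectangular and periodic; triclinic input is
rejected with an explicit error because every distance-based observable
here assumes an orthorhombic minimal image. `minimal_image` returns
components in [−L/2, L/2); at the exact half-box boundary the two
candidate images are equidistant, so observables built on distances are
unaffected by the side chosen.

Molecules are detected from residue records: protein chains are maximal
runs of amino-acid residues with ascending file residue numbers and a
constant chain id (a decrease or a chain-id change starts a new chain);
every non-protein residue is one molecule. This is why the generators
emit conventional file layouts — chains first, residues numbered per
chain, solvent blocks with unique residue numbers — as GRO files carry no
chain column.

## Hydrogen bonds

A bond is a donor–hydrogen–acceptor triple with D–A distance ≤ 0.35 nm
and H–D–A angle ≤ 30°. These are the GROMACS `hbond` defaults; the
distance, the angle, and the convention (H–D–A with an upper bound, or
D–H–A with a lower bound, typically 150°) are all configurable and echoed
into every report. Donor/acceptor annotations come either from the
generators (exact) or from an inference pass for file-read systems
(hydrogens attached to the nearest N/O of their residue within 0.12 nm;
all N/O as acceptors; ions optionally as acceptors).

The census assigns each bond to exactly one category from the molecule
classes of its endpoints, so category counts partition the bond list —
an invariant asserted per frame. Dispersion over frames is reported as
the standard deviation; the standard error (sd/√n_frames) is bookkeeping
only.

### Bridging waters

The group-count formula for protein–water–protein bridging bonds,

    HB_bridging = (1/n) ( Σᵢ HB(pᵢ ∪ w) + Σᵢ HB(pᵢ) ) − HB(w–w),

with w = water and ions, has the exact decomposition
HB(pᵢ ∪ w) = HB(pᵢ) + HB(pᵢ–w) + HB(w–w) for disjoint groups, and hence
reduces algebraically to 2·mean HB(pᵢ) + mean HB(pᵢ–w): a bond *total*,
not a count of bridging waters. With the inner sign flipped it reduces to
mean HB(pᵢ–w). Because neither reduction equals a bridge count, the
package evaluates the formula literally, evaluates the sign-flipped
variant, and additionally enumerates bridges directly — a water (or ion)
molecule hydrogen-bonded to at least two *distinct residues* of the same
chain, counted once per chain it bridges. All three numbers are reported
side by side and never silently merged; a water double-bonded to one
residue is deliberately not a bridge. Whether a published bridging figure
counted bonds or waters is generally unknowable from the formula alone,
so reports must state which estimator a number came from.

### Contacts

A contact is any heavy-atom pair of two residues within 0.6 nm (minimal
image); sequence neighbours with |Δresidue| ≤ 1 on the same chain are
excluded. Both values are unstandardised in the literature, so they are
config with the defaults stamped into each report. The per-residue count
is the number of partner residues, averaged over residues and frames.

## Dynamics

RMSD uses Kabsch superposition (SVD with determinant correction,
optional mass weighting) per chain per frame against a reference frame,
then an arithmetic mean over chains — per-chain first, chain average
second. Chains are made whole across periodic boundaries before
superposition (anchor-atom minimal-image reconstruction, valid for
molecules smaller than half the box).

The self van Hove function G_s(r,t) is the normalised histogram of
single-particle displacement magnitudes at one lag, averaged over
particles and time origins. The SISF is its isotropic transform,
F_s(q,t) = ⟨ sinc(q·|Δr|) ⟩, so F_s(q,0) = 1 exactly and free diffusion
gives exp(−q²Dt). Displacements use unwrapped coordinates: generators
store them exactly; file-read trajectories are unwrapped by a
minimal-image step heuristic that raises if any per-frame step exceeds
L/4 (beyond which wrapping is ambiguous). Time origins run over the
first half of the trajectory with a configurable stride; lags default to
~60 log-spaced values up to half the run.

Relaxation times come from least-squares fits of A·exp(−t/τ) with free
amplitude (A absorbs any short-time plateau), over a window from the
first lag with F < 0.95 down to the first lag with F < 0.05; windows are
logged, A can be fixed to 1, and fewer than 5 usable points or a
non-converging optimiser is reported as such rather than replaced.
Default q values are 5, 10, 15.71 and 25 nm⁻¹; 15.71 nm⁻¹ (= 2π/0.4 nm,
roughly the inter-residue length scale) is the anchor at which τ is
taken for cross-system correlation. In a pipeline run a q whose decay is
faster than the frame spacing yields an unconverged row (NaN τ), not a
stage failure.

## Residue–cosolute RDFs and association

g(r) is computed between residue and cosolute centres of mass (atomic
masses; side chains included) with minimal-image distances and
shell-volume/bulk-density normalisation, frame-averaged; bin width
defaults to 0.02 nm and r_max to half the box. Rows can be kept per
residue instance or aggregated by within-chain residue position
(chain-averaged maps). The exact bookkeeping identity — raw per-bin
counts summing to the mean neighbour count within the map range — is
kept alongside g(r) and asserted in tests.

"Associated" residues are those whose g(r) reaches ≥ 1.0 within 0.8 nm.
No published criterion exists for the association counts this mirrors,
so the criterion is explicit, configurable, monotone in both thresholds,
and printed next to every count; association counts are only meaningful
as criterion-conditional numbers.

## Compositions

The composition calculator turns mass ratios into whole-molecule counts
(nearest integer per species) and closes the charge balance with
counterions: anions = protein charge total + cation charge total. The
lysozyme molar mass (≈ 14,305 Da) and formal charge (+8 = 11 Arg + 6 Lys
− 7 Asp − 2 Glu at neutral pH) are derived from the packaged 129-residue
hen-egg sequence rather than hard-coded. Nine named presets reproduce
published solution compositions; their water counts absorb the preset's
molecule total (published counts round species independently, so the
literal 1:1.3 sugar ratio gives 217 molecules where the preset lists 223,
a ~3% difference the calculator surfaces rather than hides). Salt counts
can be given directly or derived from a molar concentration and an
explicit volume; published salt counts are not derivable from
concentration and any obvious box volume, so no volume is assumed
silently.

## Synthetic systems: what they validate

The generators produce three kinds of ground truth:

* **Walkers.** Free Brownian motion (Gaussian steps, variance 2DΔt per
  axis) validates MSD, G_s, F_s and τ against closed forms;
  Ornstein–Uhlenbeck walkers (exact discretisation, stationary start)
  validate plateau behaviour and the confinement ordering of τ. Defaults
  for the oracle runs are n = 500 particles, 2000 frames at 1 ps,
  D = 0.002 nm²/ps — sizes chosen so closed-form agreement at the 5%
  level is well inside sampling error on one CPU.
* **Bond scenes.** Each intended bond is built in its own 1.6 nm grid
  cell with ≥ 0.07 nm distance margin and ≥ 60° angular margin against
  accidental bonds, so the intended list *is* the detection ground truth;
  planted bridge counts (B*) and same-residue double bonds exercise the
  distinct-residue rule. Scene ledgers are exported as CSV edge lists.
* **Toy solutions.** A designed frame-0 scene plus per-molecule
  rigid-body diffusion gives multi-species trajectories with exact
  composition and frame-0 bonds, enough to run every pipeline stage
  end to end.

The toy "protein" is a bead chain with N–H donor and carbonyl-like
acceptor sites, "water" a three-site triad, "sugar" an eight-site cluster
with three hydroxyl triads — enough sites to realise every census
category, with no physical energetics. Passing these suites shows the
*estimators* are correct (detection geometry, counting, normalisation,
fitting); it says nothing about force fields, sampling convergence, or
the magnitudes real mixtures produce, which require actual MD input. The
synthetic lysozyme stand-in carries the real sequence and disulfide
topology but schematic coordinates: sequence-derived quantities (129
residues/chain, 4 SG–SG bridges, +8 charge) are faithful; geometry is
not, and it must never be used for geometric observables beyond the
disulfide construction itself.

All generators are bit-reproducible from a single integer seed,
hierarchically split per stage and recorded in output metadata.

## Correlations

Pearson is the product-moment coefficient; Spearman is Pearson on
midranks. P-values are two-sided. With few systems the t-transform
(n − 2 df) is only asymptotic, so for n ≤ 9 the exact permutation P over
all n! orderings is the default and the t value is reported alongside;
at n = 9 the two agree to ~0.01 on average but can differ by ~0.08 on
individual draws, which is why both are kept. No multiple-testing
correction is applied (report footers say so). Strength bands:
|ρ| ≥ 0.5 strong, 0.3–0.49 moderate, < 0.3 weak, < 0.05 none
(thresholds configurable).

## Pipeline

A run is configured by a TOML file (flags override; the effective config
is dumped into the manifest with a content hash). Stages run in order —
census + bridging, contacts, RMSD/Rg, SISF + fits, RDF + association —
with per-stage timing and error capture; a failed stage is recorded with
its exception and does not abort the bundle. Every CSV embeds the
criterion/parameter block that produced it. Re-running from the same
config and seed reproduces seeded outputs byte-for-byte. Sweeps over ≥ 3
systems assemble a systems × observables table and correlate named column
pairs, with τ taken at q = 15.71 nm⁻¹ by default.

## Known limitations

* Orthorhombic boxes only; no triclinic minimal image.
* Hydrogen-bond definitions are geometric; no energetic or
  orbital-based criteria, and no bond lifetime/autocorrelation analysis.
* The unwrapping heuristic requires per-step displacements < L/4;
  heavily strided real trajectories can violate this and are rejected
  rather than silently unwrapped.
* Single-exponential relaxation fits only; stretched exponentials and
  coherent scattering are out of scope.
* The toy dynamics are rigid-body diffusive: internal protein motion,
  solvent structure and realistic bond kinetics are not emulated.
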
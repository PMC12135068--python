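# prosolv

Post-simulation analysis for molecular-dynamics studies of proteins in
disaccharide/water/salt solutions — the kind of system used to ask why
sugars such as sucrose and trehalose stabilise a protein like hen egg white
lysozyme. The package implements the complete analysis battery such a study
needs, plus synthetic solvated systems with known ground truth so that
every stage can be validated without running any MD.

## What it computes

* **Hydrogen-bond census** — geometric detection (donor–acceptor distance
  ≤ 0.35 nm, H–D–A angle ≤ 30°, both configurable) and per-frame counts in
  the eight categories that matter for a protein–sugar–water mixture:
  protein–protein inter/intra, protein–water, water–water,
  protein–disaccharide, disaccharide–disaccharide, disaccharide–water,
  and protein–water–protein *bridging* bonds.
* **Bridging waters** — three estimators reported side by side: the
  group-count formula
  `HB_bridging = (1/n) (Σᵢ HB(pᵢ∪w) + Σᵢ HB(pᵢ)) − HB(w–w)`
  evaluated literally (which reduces algebraically to `2·HB(pᵢ) +
  HB(pᵢ–w)` per chain), its sign-flipped variant (which reduces to
  `HB(pᵢ–w)`), and a direct graph enumeration of water molecules
  hydrogen-bonded to ≥ 2 distinct residues of one chain.
* **Backbone dynamics** — self van Hove function `G_s(r,t)`, the
  self-intermediate scattering function
  `F_s(q,t) = ⟨ sin(q·Δr)/(q·Δr) ⟩`, and relaxation times τ from
  least-squares fits of `A·exp(−t/τ)`, by default at q values including
  15.71 nm⁻¹ (= 2π/0.4 nm).
* **Structure** — Kabsch-superposition RMSD per chain, radius of gyration,
  per-residue heavy-atom contacts, and residue–disaccharide
  centre-of-mass radial distribution functions with an explicit
  associated-residue criterion (first maximum ≥ 1.0 within 0.8 nm).
* **Cross-system statistics** — Pearson and Spearman correlations with
  exact permutation P-values for small system counts (n ≤ 9) alongside the
  t-transform values, plus strength bands (|ρ| ≥ 0.5 strong, 0.3–0.49
  moderate, < 0.3 weak).
* **Solution compositions** — whole-molecule counts from mass ratios
  (e.g. protein:water = 1:2.7), salt content, and counterion closure, with
  electroneutrality guaranteed; presets for nine published
  lysozyme-solution compositions.

Standard formats are supported end to end: GRO/PDB structures, XTC/DCD
trajectories (via MDAnalysis and mdtraj), and a plain-text multi-frame XYZ
dialect for fixtures. Internal units are nm and ps.

## Worked example

Generate a toy solvated system (2 protein chains, 16 waters, 4 sugars with
designed hydrogen bonds, rigid-body Brownian dynamics) and run the full
battery:

```python
from prosolv.pipeline import RunConfig, run_pipeline

cfg = RunConfig(name="toy",
                generator={"counts": {"protein": 2, "water": 16,
                                      "disaccharide": 4},
                           "n_frames": 300,
                           "diffusion": {"protein": 2e-3}},
                seed=1, out_dir="out")
bundle = run_pipeline(cfg)
print(bundle.observables)
```

prints (numbers from this exact configuration and seed):

```
{'hb_pp_intra': 0.0, 'hb_pw': 0.03, 'hb_ww': 0.043, 'hb_dd': 0.0,
 'hb_dw': 0.023, 'hb_pd': 0.0, 'hb_bridging_direct': 0.0,
 'hb_bridging_eq1_variant': 1.0, 'contacts_mean': 0.002,
 'rmsd_final': 0.0, 'tau_q5': 19.229, 'tau_q10': 4.755,
 'tau_q15.71': nan, 'tau_q25': nan, 'associated_residues': 0}
```

Reading the output: the planted frame-0 hydrogen bonds dilute to small
per-frame means once the molecules diffuse apart (`hb_*` are means over
300 frames); rigid-body motion gives zero superposition RMSD; the fitted
relaxation times follow free diffusion, τ ≈ 1/(q²D) = 20 ps at
q = 5 nm⁻¹ and 5 ps at q = 10 nm⁻¹ for D = 2×10⁻³ nm²/ps, while at
q ≥ 15.71 nm⁻¹ the decay is faster than the 2 ps frame spacing and the
fit is correctly reported as not converged (`nan`). Each stage also writes
a CSV under `out/toy/` with the criterion block that produced it, plus a
`manifest.json` sufficient to re-run seeded stages bit-identically.

The same operations are available from the shell:

```bash
prosolv generate --n-chains 2 --n-waters 16 --n-sugars 4 --out-prefix toy
prosolv hbonds -s toy.gro -f toy.xyz
prosolv run --config run.toml
```

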
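# cosolvmap

Druggable-hotspot mapping from cosolvent molecular-dynamics trajectories.

In cosolvent MD, a protein is simulated in water spiked with small drug-like
probe molecules (benzene, isopropanol, acetamide, ...). Probes accumulate at
surface patches with genuine ligand affinity — including allosteric and
cryptic sites that rigid-receptor docking tools miss. `cosolvmap` turns such
a trajectory into a ranked list of candidate binding regions and a
viewer-ready PDB whose B-factors carry the scores.

## The scoring function

For every protein residue, a sphere of radius `R_residue` (default 8 Å,
about three solvation shells) is centered on the residue's per-frame center
of geometry. Three terms are computed over the `N` trajectory frames:

- **Interaction** — the softcore nonbonded energy between every probe
  molecule inside the sphere and the protein atoms inside the sphere,
  averaged over frames and normalized by the mean probe count ⟨M⟩:

  `S_interaction = (1/⟨M⟩) Σ_t E_t / N`   (kcal/mol)

  Pair energies use a softcore Lennard-Jones + Coulomb potential with
  distance offsets δ_lj = δ_elec = 1 Å in the denominators, so transient
  atomic clashes cannot blow up the score:

  `E = 4ε[(σ/(r+δ_lj))¹² − (σ/(r+δ_lj))⁶] + K q_i q_j/(r+δ_elec)`

- **Stability** — `(1 − √ΔM²)/(⟨M⟩ − √ΔM²)`, where `√ΔM²` is the standard
  deviation of the per-frame probe count, clamped to [0, 1]. Probes that
  are *retained* (low fluctuation) score high; transient visits score 0.

- **Depth** — the mean number of protein atoms inside the sphere,
  normalized by the maximum over all residues: a [0, 1] burial proxy.

The composite residue score is the product
`S_residue = S_interaction · S_stability · S_depth` (negative = favorable).
Residue centers then become scoring dummy atoms; clustering spheres of
radius `R_cluster` (default 5 Å) swept along the backbone average the
member residue scores into region scores (`S_region`), overlapping regions
are suppressed, and the survivors are ranked most-negative-first.

## Worked example

The package ships a synthetic-system generator that plants a binding site
on a toy helix: a few "bound" probes revisit one surface patch in 90% of
frames while the rest diffuse randomly.

```sh
cosolvmap fixtures --outdir demo --seed 42      # topology, trajectory, params, sites, config
cosolvmap score    --config demo/config.yaml --outdir demo/out
cosolvmap evaluate --config demo/config.yaml --outdir demo/out
```

`demo/out/scores.tsv` (planted site = residues 10–12; abridged, rounded):

```
residue_index  s_interaction  s_stability  s_depth  s_residue
10             -1.939         0.095        1.0      -0.184
11             -1.613         0.179        1.0      -0.289
12             -1.957         0.134        1.0      -0.262
13             -1.633         0.0          1.0      -0.0

rank  members      s_region
1     11+13+14+15  -0.389
2     12+14+15+16  -0.382
```

Only residues the bound probes actually revisit get a non-zero stability
factor, so their composite scores are the only negative ones; the rank-1
region contains planted residues. `evaluate` confirms the recovery:

```
planted: found=True best_rank=1 hits=[1, 2, 3, 4, 5, 10]
```

`demo/out/hotspots.pdb` holds one dummy atom per residue (resname `CAT`,
chain R, B-factor = `S_residue`) and one per ranked region (resname `REG`,
chain C, residue number = rank, B-factor = `S_region`), directly colorable
in PyMOL/Chimera/VMD.

## Scope

`cosolvmap` analyzes trajectories; it does not run MD, parametrize probes,
or handle triclinic boxes. Inputs are PDB/GRO structures, XTC/DCD or
multi-model-PDB trajectories, and a plain-text per-atom parameter table
(ε, σ, q). See `docs/methods.md` for the model details and limitations.
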
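# Methods

## Model

`cosolvmap` scores how strongly, how persistently and how deeply cosolvent
probe molecules engage each protein residue over an MD trajectory, then
aggregates residues into ranked surface regions.

Per residue and frame, a sphere of radius `r_residue` is placed at the
residue's center of geometry (recomputed every frame — the protein moves).
Inside it we measure:

- `M_t` — the number of probe molecules whose center of geometry lies
  strictly inside the sphere. Membership is by molecular COG, not by
  any-atom contact, so `M_t` is integer-valued per molecule; ring-centroid
  dummy atoms are excluded from the COG.
- `J_t` — the number of protein atoms strictly inside the sphere (the
  residue's own atoms included), a local-burial proxy.
- `E_t` — the sum of softcore pair energies between *all* atoms of
  in-sphere probe molecules (dummies included, they carry charge) and the
  protein atoms inside the sphere. Restricting the protein side to the
  sphere keeps the term local; probe–probe and probe–water interactions
  are excluded. Hydrogens, when present, participate in both `E_t` and
  `J_t` and must be covered by the parameter table.

The three per-residue scores are

    S_interaction = (Σ_t E_t / N) / ⟨M⟩        (0 if ⟨M⟩ = 0)
    S_stability   = (1 − s) / (⟨M⟩ − s),  s = population std of M_t
    S_depth       = ⟨J⟩ / max_residues ⟨J⟩

and the composite is their product. Frames with `M_t = 0` still count in
`N`: empty frames dilute the average, penalizing transient sites — the
retention-time emphasis is deliberate. `S_stability` is clamped to [0, 1]
and defined as 0 when ⟨M⟩ = 0 or when the denominator is non-positive
(fluctuation at least as large as the mean); the raw formula can exceed 1
or diverge, while the score is meant to range from 0 to 1. Note the
numerator is `1 − s`, not `⟨M⟩ − s`: a perfectly retained occupancy of
`c > 1` molecules scores `1/c`. That is the formula as published and is
implemented as printed rather than "corrected". The arg-max residue of
`S_depth` scores exactly 1 by construction; all mean contact counts being
zero is rejected as an empty protein.

### Softcore pair potential

    E = 4ε[(σ/(r+δ_lj))¹² − (σ/(r+δ_lj))⁶] + K q_i q_j/(r+δ_elec)

with Lorentz–Berthelot mixing (σ_ij arithmetic mean, ε_ij geometric mean)
and K = 332.0636 kcal·Å/(mol·e²), the standard electrostatic constant for
Å/e/kcal·mol⁻¹ units. The deltas (default 1 Å each) keep the energy finite
at `r = 0`, smoothing over the transient clashes that plague per-frame
energy analysis of unminimized trajectory snapshots. As δ → 0 the form
converges to plain LJ + Coulomb; both limits are tested.

### Regions

One dummy point per residue (trajectory-average COG, carrying
`S_residue`) is swept by clustering spheres of radius `r_cluster` centered
at each residue's trajectory-average Cα (fallback: backbone-atom COG).
A sphere's members are every residue point strictly inside it; spheres
whose members are all non-negative are background and dropped. The region
score is the unweighted member mean, so zero-score members dilute a
region — concentrated hotspots outrank diffuse ones. Near-duplicate
spheres are removed by greedy non-maximum suppression on member-set
Jaccard overlap (threshold 0.5), visiting candidates by ascending score so
the result is order-independent; survivors are ranked most-negative-first,
ties broken by smallest member residue index. The dummy points carry the
composite `S_residue` (not `S_interaction` alone); the region mean over
composites is what the ranking is defined on.

Site recovery (`evaluation`) declares a region a hit for a known site when
their residue sets intersect — single-residue overlap counts, matching how
published site tables list individual contact residues — and reports all
hitting ranks up to `top_k` (default 10).

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| `r_residue` | 8 | Å | residue sphere; ≈3 solvation shells |
| `r_cluster` | 5 | Å | clustering sphere; inter-Cα scale of secondary structure |
| `delta_lj`, `delta_elec` | 1 | Å | softcore offsets |
| `coulomb_constant` | 332.0636 | kcal·Å/(mol·e²) | electrostatic conversion |
| `overlap_threshold` | 0.5 | – | Jaccard NMS threshold |
| `top_k` | 10 | – | recovery report depth |
| `stride` | 1 | – | frame subsampling for large trajectories |

## Numerical choices

- Internal units: Å, kcal/mol, elementary charge; GRO/XTC nm are converted
  on read (via MDAnalysis).
- Strict `<` at every sphere boundary — a measure-zero tie, fixed for
  reproducibility.
- Only orthorhombic boxes; minimum-image wrapping is applied in all
  distance computations whenever a frame carries a box, and any query
  radius above half the smallest box length is rejected. Non-periodic
  (stripped) trajectories are supported by omitting the box.
- Residue and probe COGs are computed from raw coordinates, assuming
  molecules are whole (not split across the boundary); re-wrap broken
  molecules upstream if needed.
- Neighbor queries use a KD-tree with periodic box support and are
  verified against an exhaustive double loop; candidate hits are refined
  with exact minimum-image distances so the strict boundary rule holds.
- Probe membership, dedup and ranking tie-breaks are all deterministic:
  identical inputs give identical outputs.
- PDB B-factor output is clamped to [−99.99, 999.99] (field width) with a
  logged warning; the TSV table keeps full precision.

## Synthetic systems

The `fixtures` module generates everything the test suite and the demo
need, with no MD and no downloads:

- a rigid helix-like chain of pseudo-residues (N/CA/C/O at fixed internal
  geometry, 1.5 Å rise, 100° twist) centered in a cubic periodic box
  (default 20 residues, 40 Å box);
- benzene-like 6-carbon probes. "Bound" probes sit at per-probe anchors
  4.5 Å radially outward of the planted site's central Cα for a
  Bernoulli(`residence_fraction`) subset of frames (Gaussian jitter
  0.5 Å), and are placed uniformly otherwise; the remaining probes are
  re-inserted uniformly every frame. The anchor sits on the protein
  *surface* rather than at the site COG because the COG of a compact site
  lies inside the helix; the probes remain well inside the 8 Å residue
  sphere, which is what a planted site requires. Defaults (3 bound probes,
  residence fraction 0.9, 10 bulk probes, 200 frames) model a clearly
  occupied site over a desk-scale trajectory.
- every insertion rejects configurations placing any probe *atom* within
  2 Å of a protein atom (up to 1000 resamples). Atom-level rejection
  matters: a clash-free molecular center can still put a ring atom at
  sub-Å contact, producing multi-thousand-kcal softcore spikes that are
  artifacts of rigid random insertion rather than of the scoring function.
- `add_ring_dummy` appends the standard aromatic anti-stacking treatment:
  a massless site at the 6-ring centroid with charge −0.01 e and zero LJ
  well depth, member of its molecule for occupancy but excluded from the
  COG.
- `compute_probe_count` returns the minimal probe count reaching a target
  mass-per-mass concentration (ceiling, so the stated concentration is
  reached, never undershot); with 1000 waters and benzene at 10% m/m it
  gives 26.

What the generator does *not* emulate: real dynamics (no forces, no
protein motion between frames), solvent (water is energetically inert
here and omitted by default), probe–probe interactions, rotameric site
plasticity, and phase separation. Passing tests therefore demonstrate
that the scoring machinery recovers a site whose occupancy statistics
match its design — not that any particular force field or sampling
protocol would produce those statistics on a real protein.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
20-residue, 13-probe, 200-frame systems (about 0.4 s per run) and repeat
the planted-site recovery over 20 seeds with a residence-fraction-0
control. These sizes give stable occupancy statistics (the binomial
standard error of the planted occupancy at 200 frames is ≈0.04) while
keeping every run interactive.

## Known limitations

- Residue identity in region membership and site files is the 1-based
  residue number only; proteins with duplicate numbering across chains
  need renumbering before evaluation.
- No triclinic boxes, no Ewald/PME electrostatics, no switching
  functions: the energy is cut off purely by sphere membership.
- The parameter table is a deliberately engine-agnostic TSV; converting
  GROMACS/AMBER/CHARMM topologies into it is out of scope.
- Scores from different probe types are not merged; run and rank each
  cosolvent separately.
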
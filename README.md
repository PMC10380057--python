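# tnkit

Conformational **t**ransition-**n**etwork analysis for peptide trajectories,
with companion analyses of solvation structure, hydrogen-bond kinetics,
contacts and formal charges.

## The problem

Intrinsically disordered peptides such as amyloid-β (Aβ1−42) do not fold
into a single structure; they wander over a flat free-energy landscape of
many shallow minima. Binding partners — sulfated glycosaminoglycans, lipid
clusters, ions — can push such a peptide through a disorder-to-order
transition. Detecting and describing that transition from simulation data
requires reducing millions of coordinates per frame to a small set of
interpretable features, and following how the system hops between the
discrete states those features define.

`tnkit` implements that reduction as a reusable pipeline for
structural-biophysics researchers:

1. **Descriptors** — each frame x(t) is projected onto a state
   S(t) = [f₁(x), …, fₙ(x)]. The default descriptors are Nα (residues in
   α-helix), Nβ (residues in β-strand) and d_NC (N-to-C end-to-end
   distance, Å, floor-binned at 1 Å). Secondary structure comes from a
   deterministic backbone-dihedral window classifier (runs of ≥4 helical
   (φ,ψ); runs of ≥3 extended (φ,ψ) with a partner strand < 5.5 Å).
2. **Transition network** — a directed graph whose nodes are the observed
   states and whose edge (i, j) counts frame pairs (t, t+lag) with
   S(t)=i, S(t+lag)=j inside one contiguous trajectory segment. Diagonal
   (self-transition) counts are the node *population*, displayed on a
   linear 1–10 size scale; modularity communities of the symmetrized graph
   are interpreted as free-energy basins and summarized by
   population-weighted averages of the raw descriptors. Networks export to
   GEXF/GraphML for Gephi.
3. **Solvent structure** — the translational order parameter
   T = (1/ζc)∫₀^ζc |g(ζ)−1| dζ with ζ = r·ρ^{1/3} (ζc = 2.8), and the
   tetrahedral order parameter
   q = 1 − (3/8)Σ_{j<k}(cos ψ_jk + ⅓)² over the four nearest
   water-oxygen neighbors (T = 0 and ⟨q⟩ = 0 for an ideal gas; q = 1 for a
   perfect tetrahedron).
4. **H-bond kinetics** — intermittent existence autocorrelation c(t) of
   geometric donor–H–acceptor bonds (3.5 Å / 150° defaults), fitted by a
   stretched exponential c(t) = exp(−(t/τ)^β) with mean lifetime
   ⟨τ⟩ = (τ/β)·Γ(1/β).
5. **Contacts & charges** — contact-probability maps (minimum heavy-atom
   distance < 10 Å, normalized per frame), ion radial distributions around
   charged groups, and formal net charges (e.g. Aβ1−42 with neutral His
   and free termini is −3; a chondroitin-4-sulfate 16-mer is −16).
6. **Synthetic data** — geometry-backed generators with known ground
   truth: a 42-residue chain switching among coil/helix/β-hairpin
   macrostates under a prescribed Markov matrix (backbones built from
   internal coordinates), water-oxygen configurations from ideal gas to
   diamond lattice, renewal-process H-bond traces, and toy ion systems.

## Worked example

Build a three-macrostate synthetic trajectory (designed stationary
populations 0.6 coil / 0.3 helix / 0.1 hairpin), project it onto
(Nα, Nβ, d_NC) states and summarize the network communities:

```python
import numpy as np
from tnkit import (abeta_like_spec, realize_trajectory, project_trajectory,
                   build_transition_matrix, detect_communities,
                   summarize_communities, net_charge, AB42_SEQUENCE)

spec = abeta_like_spec(n_frames=2000, seed=1)
ens, truth = realize_trajectory(spec)
series = project_trajectory(ens)
net = build_transition_matrix(series, ens.segments)
detect_communities(net, seed=0)
print(summarize_communities(net, series).round(2))
print("net charge of Abeta(1-42):", net_charge(AB42_SEQUENCE))
```

```
           n_states  Nalpha  Nbeta     dNC  population_fraction
community
0                17     0.0   0.00  122.80                 0.61
1                32    26.0   0.00   67.19                 0.32
2                44     0.0  16.01   49.24                 0.07
net charge of Abeta(1-42): -3
```

The three communities recover the designed macrostates: an extended
random coil (no secondary structure, end-to-end distance ≈ 123 Å), a
partially helical state (Nα = 26) and a compact β-hairpin state
(Nβ = 16, d_NC ≈ 49 Å). The recovered population fractions
(0.61 / 0.32 / 0.07) match this realization's empirical macrostate
fractions exactly at the printed precision.

The same pipeline is available from the shell:

```bash
tnkit synth abeta-like-3state --n-frames 500 --out run1
tnkit tn run1.pdb --lag 1 --seed 0 --format gexf --out run1.gexf
tnkit charge DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA   # -> -3
```

## Layout

| module | contents |
| --- | --- |
| `tnkit.trajectory_io` | PDB/XYZ/CSV trajectory reading and writing, atom selection |
| `tnkit.descriptors` | secondary-structure classifier, (Nα, Nβ, d_NC), state projection |
| `tnkit.transition_network` | transition counting, communities, node sizing, Gephi export |
| `tnkit.solvent_structure` | RDF, translational order T, tetrahedral order Q, vicinity selection |
| `tnkit.hbond_kinetics` | H-bond detection, c(t), stretched-exponential fits, ⟨τ⟩ |
| `tnkit.contacts_charges` | contact maps, ion RDFs, formal net charges |
| `tnkit.synthetic_data` | ground-truth generators (peptide, water, H-bond traces, ions) |

See `docs/methods.md` for the scientific conventions, default parameters
and known limitations.
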
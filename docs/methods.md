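# Methods

This note records the scientific conventions `tnkit` implements, the
defaults it ships, the choices that were genuinely open, and what the
synthetic-data generators do and do not emulate.

## State projection and descriptors

A trajectory frame is reduced to the tuple (Nα, Nβ, d_NC).

**Secondary-structure assignment.** No single assignment algorithm is
canonical for disordered ensembles, and energy-based assigners (DSSP)
need full backbone carbonyl geometry. `tnkit` uses a purely geometric
dihedral-window classifier:

* helix candidate: φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°]; label H
  requires a run of ≥ 4 consecutive candidates;
* strand candidate: φ ∈ [−180°, −90°] and ψ ∈ [90°, 180°] or
  ψ ∈ [−180°, −170°]; label E requires a run of ≥ 3, and in
  *paired-strand* mode (default) at least one Cα–Cα pair < 5.5 Å to a
  different strand run — a lone extended stretch is coil;
* all other residues, and termini without computable (φ, ψ), are C.

The classifier is total, deterministic, and exactly testable on chains
built from prescribed dihedrals. Its absolute Nβ values can differ from
DSSP-family assigners (it has no H-bond energy term); comparisons across
systems analysed with the same classifier remain meaningful. A different
assigner can be substituted at the `assign_secondary_structure` seam.

**End-to-end distance.** "N-to-C distance" is ambiguous at the atom
level; the default is Cα(first residue)–Cα(last residue), robust to
capping and protonation conventions, with backbone N(first)–C(last)
available via `DescriptorSpec(dnc_mode="n_c")`. Minimum-image distances
are used whenever a periodic box is present.

**Binning.** Nα and Nβ enter the state tuple as exact integers; d_NC is
floor-binned at 1 Å (configurable). One ångström keeps the state count
tractable while preserving the sub-residue resolution at which community
averages are typically reported. State ids are dense integers assigned
in first-appearance order, so a projection is reproducible frame-for-frame.

## Transition networks

Transitions are counted at a fixed lag (default: 1 stored frame) between
state ids, never across segment boundaries (segments mark independent
simulation runs). The matrix is stored directed; nothing is normalized
on export, so downstream tools see raw counts.

* **Population** of a node is its diagonal self-transition count — a
  kinetic-stability notion, not a connectivity one; self-loops are
  therefore excluded from community detection but kept for node sizing.
* **Display sizes** map populations linearly onto [1, 10]
  (all-equal populations collapse to the midpoint 5.5).
* **Communities** come from Louvain modularity maximization on the
  symmetrized weighted graph (weight(i,j) = count(i,j) + count(j,i)),
  seeded for reproducibility. On graphs small enough to enumerate
  (≤ 10 nodes) the test suite checks the partition against exhaustive
  modularity maximization. Community summaries average the *raw*
  (unbinned) descriptor values over all frames whose state belongs to
  the community, weighting states by their visitation automatically.
* Exports: GEXF, GraphML (Gephi-readable; node attributes carry per-state
  and per-community descriptor means, population, size, community) and a
  plain CSV edge list.

This is geometric clustering of visited states — deliberately *not* a
Markov state model: no lag-time selection, no detailed-balance
enforcement, no kinetic coarse-graining.

## Water structure

**Translational order.** T = (1/ζc) ∫₀^ζc |g(ζ) − 1| dζ on the rescaled
distance ζ = r·ρ^(1/3), ρ = N_O/V. Default ζc = 2.8, the conventional
choice where the pair-correlation deviation has decayed. The integral is
a trapezoid on the RDF's native bins (default width 0.05 Å) after
rescaling, extended flat from the first bin center to ζ = 0 and
interpolated at ζc; the suite checks it against a 2·10⁶-point Riemann
oracle to 10⁻³. T = 0 for an ideal gas, large for crystals. Note that a
*sampled* ideal-gas T is positive-biased (it integrates |noise|), so
finite-sampling comparisons should use matched bin widths and frame
counts.

**Tetrahedral order.** q_i = 1 − (3/8) Σ_{j<k} (cos ψ_jk + ⅓)² over the
four nearest oxygen neighbors of center i (minimum image), Q = ⟨q_i⟩.
The four-nearest-neighbor convention is implied by the fixed pair sum.
q = 1 for a perfect tetrahedron and ⟨q⟩ = 0 for uniformly random
orientations; individual q values can be negative (the degenerate
all-collinear geometry gives exactly −3), though condensed-phase values
fall in [0, 1]. When a vicinity subset defines the centers, neighbors
are still searched among *all* oxygens, avoiding artificial depletion at
the selection boundary.

**Vicinity selection** re-evaluates membership every frame (oxygens
within 10 Å of any solute atom by default; 5 Å is the common tighter
variant), and T/Q are ensemble-and-time averages over frames. For
ζ-rescaling the density of the full water phase is used by default; the
density of the vicinity subset is a documented alternative via a custom
`RDFProfile`.

## Hydrogen-bond kinetics

A candidate bond is a donor–hydrogen–acceptor triple with
d(D, A) ≤ 3.5 Å and ∠(D–H–A) ≥ 150° (community-standard geometric
criterion; both knobs in `HBondCriteria`). Hydrogens attach to donors
via topology bonds, or geometrically (element H within 1.2 Å) when bonds
are absent.

The pooled intermittent autocorrelation is

  c(t) = Σ_bonds Σ_t0 h(t0)·h(t0+t) / Σ_bonds Σ_t0 h(t0)²,

with every frame a time origin and recrossings allowed; origins for lag
t run to the end of the series, so c(0) = 1 exactly. No ⟨h⟩ plateau is
subtracted: pooling over every pair observed bonded at least once keeps
the baseline small, and the fit window (t = 0 until c < 0.01) truncates
before the plateau matters. A continuous-lifetime variant is the
`origins="formation"` mode, where only 0→1 bond-formation events are
origins and c(t) estimates the survival probability t after formation.

The distinction matters for validation: origins sampled uniformly over
on-time weight long bond episodes (the inspection paradox), so for a
renewal process with Weibull(β, τ) on-intervals the all-origins c(t)
fits to an *effective* β̂ systematically above β (≈ 0.72 for β = 0.5 in
the asymptotic curve). The generator-recovery test therefore uses
formation origins, which restore (τ, β) exactly; the all-origins
estimator is validated instead against the closed-form correlation of a
two-state telegraph process. Fitted parameters from the default
convention should be read as effective relaxation parameters — exactly
as they are in the simulation literature that fits stretched
exponentials to H-bond correlation functions.

The stretched exponential exp(−(t/τ)^β) is fitted by unweighted least
squares (bounds τ > 0, β ∈ (0, 1]; initial guess τ at the 1/e crossing,
β = 0.8); the mean lifetime is the exact survival integral
⟨τ⟩ = (τ/β)·Γ(1/β), checked against quadrature to 10⁻⁶ relative error.
The recommended analysis stride for H-bond kinetics is 0.5 ps; `dt`
must be supplied by the user, since a stored trajectory does not always
record its output stride.

## Contacts, ions, charges

* Contact: minimum distance over heavy-atom pairs of the two groups
  strictly below the cutoff (default 10 Å); hydrogens are excluded by
  convention (positions depend on the H model). Probability = contacting
  frames / total frames. For residue–monosaccharide or residue–lipid
  maps each monosaccharide or lipid molecule is one column group.
* Ion RDFs use each ion's distance to the *nearest* reference-group atom,
  normalized by ion bulk density and spherical shell volume — exact for a
  single reference atom and a good approximation for compact groups such
  as carboxylates; for extended references the large-r normalization is
  only approximate.
* Net charges follow physiological-pH bookkeeping: Asp/Glu −1, Lys/Arg
  +1, His neutral by default (`his_charged=True` models His+, which
  renders Aβ1−42 neutral overall), free termini +1/−1 unless `capped`.
  Chondroitin-4-sulfate units GalNAc(4S) and GlcUA each carry −1, so the
  16-mer totals −16 with no terminal correction.

## Synthetic data: what it emulates, and what it does not

The generators provide *statistical* stand-ins for MD data, not physics:

* **Peptide frames** are backbones (N, Cα, C) built by NeRF internal-
  coordinate extension with ideal bond geometry (N–Cα 1.458 Å, Cα–C
  1.525 Å, C–N 1.329 Å, ω = 180°) and per-label (φ, ψ): helix
  (−57°, −47°), strand (−139°, 135°), PPII-like coil (−75°, 145°),
  plus Gaussian dihedral jitter (default σ = 6°). Frames that
  self-collide (< 1.5 Å nonbonded) are rebuilt with fresh jitter.
* The default **three-macrostate system** (42 residues) switches among
  extended coil, a 26-residue central helix, and a β-hairpin (strands at
  residues 17–24/27–34 around a two-residue left-handed turn,
  (65°, 30°)/(70°, 20°), designed with the builder itself so the strands
  pair below 5.5 Å). A proximity constraint holds the Cα atoms of
  residues 23 and 28 within 5 Å in hairpin frames — the analogue of the
  salt-bridge contact that stabilizes hairpins in charged-peptide
  systems — so the intrapeptide contact map shows the characteristic
  perpendicular-to-diagonal trace. Macrostate switching follows a
  detailed-balance Markov matrix with stationary distribution
  (0.6, 0.3, 0.1), started from stationarity.
* **Water** configurations are oxygen-only point sets (T and Q need no
  hydrogens): uniform ideal gas, perfect diamond lattice (the
  tetrahedral-order reference), and jittered lattice, at liquid-water
  oxygen density 0.0334 Å⁻³ by default.
* **H-bond traces** are alternating renewal processes — Weibull(β, τ)
  on-intervals (survival exactly exp(−(t/τ)^β)), exponential
  off-intervals (default scale 200 ps, i.e. sparse ≈ 6% occupancy like a
  pooled candidate set) — sampled on the frame grid, so episodes shorter
  than dt are clipped.
* **Ion systems** place ions uniformly (flat g(r)) or in Gaussian shells
  around reference atoms (g(r) peak at the shell radius).

Passing tests on these inputs demonstrates that the *analysis* is
correct on data whose ground truth is known exactly. They do not show
force-field realism: no excluded-volume solvent, no side chains, no
correlated backbone dynamics, no real H-bond geometry behind the binary
traces. Quantities that depend on those features (absolute T/Q of real
water, experimental lifetimes) are outside what the synthetic suite can
certify.

## Numerical conventions and edge cases

* Coordinates are Å, times ps, orthorhombic boxes only, minimum-image
  distances throughout; 1-based residue numbering at the API surface,
  0-based atom indexing internally.
* Degenerate inputs are errors, not silences: empty ensembles refuse to
  write, empty solute selections refuse vicinity analysis, all-zero
  H-bond traces refuse correlation, RDFs refuse r_max beyond half the
  shortest box edge, and T reports the maximum covered ζ when the
  profile falls short of ζc.
* Ties and randomness: community detection fixes its RNG seed and orders
  nodes by state id; every generator is a pure function of its seed.
* The test suite's problem sizes (10⁴-frame end-to-end run, 10⁵-step
  Markov chains, 2·10⁴-sample order-parameter averages) were chosen so
  statistical tolerances (3 standard errors, ±0.02 population recovery)
  are meaningful while the whole suite completes in minutes on one CPU.

## Known limitations

* The dihedral-window classifier under-counts β-structure relative to
  H-bond-energy assigners for twisted or bulged sheets.
* PDB round-trips are limited by the format's fixed 3-decimal coordinate
  precision; use the CSV dialect for exact round-trips.
* The ion-RDF normalization around multi-atom references is approximate
  at radii comparable to the group extent.
* `contact_map` is O(frames × group-pair atoms²) in Python/numpy; it is
  meant for residue-scale groups, not whole-system pair analysis.
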
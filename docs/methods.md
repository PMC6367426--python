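# Methods

## The system and the analysis model

The package analyses coordinate ensembles of a homodimeric, three-domain-per-protomer
protein (chains A and B, each split into an N-terminal domain NTD, a middle domain M
and a C-terminal domain CTD that forms the dimer interface). All analyses operate on
one representative coordinate per residue: Cβ with Cα for glycine (and Cα fallback
when Cβ is absent) for network construction, Cα for communication propensity and
essential dynamics. Coordinates are Ångström internally; residue indices are 0-based
in code and 1-based in every written table.

### Dynamic residue networks

A residue interaction network (RIN) for one frame connects residues whose
representative atoms lie within a cutoff, 6.7 Å by default; the comparison is
inclusive (≤), which must be fixed one way for determinism. The dynamic residue
network (DRN) is the sequence of RINs along the trajectory, sampled every 200 ps by
default. Per frame:

- `L_i` is the mean unweighted shortest-path length from residue *i* to every
  residue it can reach (breadth-first search). Pairs in different components are
  excluded from the average and reported per residue as `unreachable_count`; an
  isolated residue gets NaN. Exclusion rather than a penalty constant keeps the
  statistic auditable — any imputed penalty would be arbitrary.
- Betweenness centrality uses the standard all-shortest-paths fractional credit
  (Brandes), endpoints excluded, and is rescaled per frame by the frame's maximum
  positive value so each frame spans [0, 1] while zeros stay "no traffic".

Time averages over the DRN give `L_mean` and mean BC. The reachability drift is
reported as `ΔL_i = (1/F) Σ_n (L_i^n − L_i^0)` by default — positive when paths
lengthen over the trajectory, matching the narrative convention that degraded
reachability is a positive ΔL. The opposite (first-minus-later) form is available
via `sign="literal"` because both conventions appear in the literature.

### Contact persistence

Cross-group residue contacts (e.g. NTD against M within a protomer) use the same
6.7 Å inclusive cutoff on representative atoms; a pair's persistence is the fraction
of sampled frames it is in contact, and the stable-contact filter keeps pairs at or
above 70 % (inclusive, reading "at least 70 %"). Ligand contacts are a
distance-only surrogate: any ligand atom within 4.0 Å of any residue atom counts,
with no chemical typing of hydrophobic or hydrogen-bond character — outputs are
labelled accordingly and should not be read as interaction chemistry.

### Communication propensity

`CP_ij = ⟨(d_ij − d̄_ij)²⟩` over Cα–Cα distances, in Å². Distances are
frame-internal, so CP needs no superposition and is exactly invariant under
per-frame rigid transforms (a property the tests assert at 1e-10 Å²). CP behaves as
a communication time: coherently moving pairs (low CP) coordinate fast. Derived
quantities:

- ΔCP = CP(free) − CP(bound): positive where ligand speeds communication.
- The neighbour baseline averages CP over intra-chain pairs with sequence
  separation 1–4 ("i ± 4"; the exact-4 reading is available via a flag). Inter-chain
  pairs are excluded.
- The fast-communication scan counts, per residue, partners whose time-averaged
  distance exceeds a floor (80 Å default, taken on the time-averaged distance matrix
  for frame independence) and whose CP is at or below a threshold. The threshold
  defaults to the neighbour baseline rather than any fixed literature value, whose
  units are not portable across systems; the denominator is N−1 (all partners), with
  a far-partners-only alternative.

### Essential dynamics

The 3N × 3N Cα positional covariance `C = ⟨(x − ⟨x⟩)(x − ⟨x⟩)ᵀ⟩` is built after
superposing every frame onto an iteratively refined mean structure and
eigendecomposed with a symmetric solver (N is desk-scale; no trajectory-space trick
is needed). The mean refinement iterates to self-consistency (tolerance 1e-10 Å,
typically 3–5 passes): a fixed two-pass scheme leaves the fitting target and the
fitted average slightly inconsistent, which breaks the exact PCA identity that
projecting the fitting trajectory must reproduce each eigenvalue. No mass weighting
is applied. An initial equilibration window (default 10 ns) is skipped when the
frame times allow; otherwise the full trajectory is used with a warning.

`fit_modes(superpose_frames=False)` skips the alignment entirely. This is the right
setting for ensembles generated in a common lab frame (the synthetic generator adds
noise after mode displacement and never re-superposes), where the raw covariance is
exactly the planted low-rank-plus-σ²I matrix and closed-form spectrum checks apply.
A finite-amplitude Kabsch fit perturbs that spectrum at second order in
(amplitude/size), well above the 1e-6 tolerance of the exact two-mode check.

Projections superpose each query frame to the modes' mean (skipped when the modes
were fitted without superposition). Extreme-projection interpolation emits
structures spanning [min score, max score] on one mode plus per-atom displacement
arrows. Reference-state projection fits modes on concatenated labelled reference
ensembles only — every frame superposed to the concatenated mean, a choice recorded
in the output — then projects query and references together.

### Geometry

Superposition is Kabsch with the proper-rotation correction (flip the smallest
singular direction when the optimal orthogonal transform is a reflection), requiring
≥3 non-collinear points. RMSF uses the same converged mean refinement as essential
dynamics. Centre-of-mass distances are unweighted over representative atoms by
default (mass weighting optional). gromos clustering is the Daura greedy
neighbour-count algorithm on the pairwise fitted-RMSD matrix with a 2 Å default
cutoff; ties in neighbour count go to the lowest frame index (the published
algorithm does not specify), cluster sizes are reported non-increasing, and each
representative is the member closest to the member-average coordinates. Histograms
default to Freedman–Diaconis bins; bimodality is left to inspection, not
auto-detected.

## The synthetic generator

`SyntheticSpec` defines the study conditions. Defaults: 20 residues per domain (120
residues), 2000 frames at 200 ps, opening/closing amplitude 4 Å, twist 2 Å,
isotropic noise σ = 0.5 Å.

The scaffold is a planar "v": two straight, zig-zagged arms (3.3 Å backbone
spacing, ±0.8 Å in-plane wiggle) meeting at the CTD vertex 4.4 Å apart. The 3.3 Å
spacing keeps second-neighbour pairs (6.6 Å) inside the 6.7 Å cutoff, so the RIN is
redundant like a real Cβ contact network; at wider spacing the network degenerates
to a path graph that fragments under noise, and the exclusion convention then
*lowers* L for noisy residues, inverting the expected RMSF↔L coupling. Construction
verifies per-protomer connectivity and the CTD interface.

Frame *t* is `mean + Σ_m (bias_m + a_m sin(2π c_m t/F)) v_m + ε_t`:

- Mode vectors are unit-norm 3N vectors, projected free of rigid-body content and
  mutually orthogonalized. `open_close` swings the arms apart along x with a
  height-proportional ramp (changes the NTD–NTD distance); `twist` rotates the
  protomers oppositely about the dimer axis.
- Sinusoidal activation over whole cycles (c = 2 and 3 per trajectory) makes each
  planted variance exactly a²/2 and keeps modes uncorrelated, enabling closed-form
  spectrum checks. `mode_bias` adds a constant offset along a mode — how the
  activator/inhibitor scenarios shift the *mean* geometry, which a pure amplitude
  change cannot.
- Noise is i.i.d. Gaussian per coordinate (scalar σ or per-residue profile), added
  in the lab frame with no re-superposition, so expected RMSF is σ√3 and the
  covariance stays planted-low-rank + σ²I.
- Because the mode vectors are unit-norm, amplitude converts to NTD–NTD distance
  through a geometry-dependent factor; `PlantedTruth.com_distance_params` stores the
  exact planted mean and oscillation amplitude for recovery tests.
- Contact-plan partners are placed at an exact distance from their pair residue
  (5.5 Å in contact, 9.0 Å out) in a seeded choice of exactly round(fraction × F)
  frames; persistence recovery is therefore exact, at the price of overriding the
  partner's own noise (such residues are not valid RMSF probes, and the partner's
  sequence neighbours can pick up incidental contacts).
- The optional ligand is a rigid pseudo-atom cluster tethered to an anchor residue
  with its own noise — it exercises ligand-contact timelines without any chemistry.

Named scenarios pin the comparison study: `scenario_free` (defaults),
`scenario_activator` (open/close amplitude doubled to 8 Å, bias −4 Å toward
closing, M-domain noise +0.5 Å, CTD-anchored ligand) and `scenario_inhibitor`
(bias +4 Å toward opening, protomer-A NTD noise halved, same ligand). These mimic
the signature directions of CTD activators and inhibitors: the activator closes the
NTD–NTD separation, mobilizes NTD/M and slows communication; the inhibitor opens it.

What the generator does *not* emulate: force-field energetics, solvent, anharmonic
or stochastic mode dynamics, realistic contact topology beyond the redundant chain,
sequence-specific packing, or chemical ligand interactions. Passing tests therefore
demonstrate the *correctness of the estimators* (they recover known planted
quantities at the stated tolerances) — not that the toy reproduces real chaperone
dynamics.

## Problem sizes and tolerances

Tests and the acceptance script run on one CPU in minutes: graph oracles on 200
random connected graphs of ≤30 nodes; mode recovery at 120 residues × 2000 frames;
the RMSF closed form at 5000 frames; the free/activator/inhibitor pipeline at 120
residues × 500 frames; the self-comparison null at 60 residues × 100 frames.
Tolerances: exact (1e-12) for graph metrics against enumeration; 1e-10 Å² for the
CP rigid-body null; 1e-6 for the analytic two-mode variance ratio; 5 % for
stochastic closed forms (RMSF, PC1 variance fraction); direction-of-effect only for
the scenario comparison. The RMSF↔L coupling test uses a noisy subdomain at
σ = 1.2 Å over a 0.3 Å base — fluctuations comparable to the cutoff while the
network stays connected, which is the stated precondition of that proportionality;
at σ ≳ 1.5 Å the toy chain fragments and the correlation genuinely degrades.

## Known limitations

- The multi-model PDB reader requires identical atom ordering across models and
  resolves altlocs by highest occupancy then altloc letter; no binary trajectory
  formats (XTC/DCD) and no topology perception.
- Network metrics treat the RIN as unweighted; no attenuated or weighted variants,
  community detection, or perturbation-response scanning.
- The CP fast-communication threshold is system-relative (neighbour baseline); CP
  values are not comparable across systems without that normalization.
- gromos clustering is O(F²) in frames with per-pair Kabsch fits — intended for
  conformer analysis of modest frame counts, not whole long trajectories.
- The pipeline's reference-projection stage runs only when reference ensembles are
  supplied; the standard report covers geometry, DRN, contacts, CP and per-complex
  essential dynamics.
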
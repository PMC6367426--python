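# allodyn

Trajectory analysis of allosteric modulation in homodimeric chaperones.

Large dimeric chaperones of the Hsp90 family cycle between an open, client-loading
"v"-shaped conformation and a closed, ATPase-active one, and small molecules bound at
the C-terminal-domain (CTD) dimer interface can bias that cycle in either direction.
`allodyn` implements the analysis stack used to detect such modulation in molecular
dynamics ensembles of a two-protomer, three-domain-per-protomer protein:

- **Geometry** — Kabsch superposition, RMSD/RMSF/ΔRMSF, inter-domain
  centre-of-mass distance series, and gromos (Daura) conformer clustering.
- **Dynamic residue networks (DRN)** — per-frame residue interaction networks
  (representative atoms within 6.7 Å), average reachability
  `L_i = (1/(N−1)) Σ_j L_ij` over unweighted shortest paths, its drift over the
  trajectory, and per-frame-rescaled betweenness centrality.
- **Contact persistence** — time-resolved inter-domain and ligand–residue contact
  maps with an inclusive ≥70 % stability filter.
- **Communication propensity (CP)** — `CP_ij = ⟨(d_ij − d̄_ij)²⟩` on Cα–Cα
  distances (Å²; low CP = fast communication), ΔCP difference maps, the
  sequence-neighbour (i ± 4) baseline, and the long-range (>80 Å)
  fast-communication scan.
- **Essential dynamics** — the Cα positional covariance
  `C = ⟨(x − ⟨x⟩)(x − ⟨x⟩)ᵀ⟩`, eigenmodes and variance fractions, trajectory
  projections, extreme-projection interpolation (porcupine arrows), and projection
  onto concatenated reference-state ensembles.
- **Pipeline** — `run_all` sequences the whole free-vs-bound comparison from one
  config, with deterministic TSV outputs and a machine-readable manifest.

Because public trajectories of the real system are unavailable, the package ships a
first-class **synthetic-data generator**: a toy dimer with planted collective modes
(opening/closing, axial twist), per-residue Gaussian noise, exact-fraction contacts
and an optional tethered pseudo-ligand. Every planted quantity is analytic, so every
downstream analysis is tested by parameter recovery.

## Worked example

```sh
python examples/06_essential_dynamics.py
```

```
PC1 | planted open/close cosine: 0.997
eigenvalues (A^2): PC1 7.98 (analytic 4^2/2 = 8), PC2 2.08 (analytic 2^2/2 = 2)
cumulative variance, first 3 modes: 0.40
PC1 score range: [-4.5, 4.4] (the planted +-4 A sinusoid)
```

The generator planted a 4 Å opening/closing mode and a 2 Å twist under 0.3 Å noise;
the leading covariance eigenvector recovers the planted direction (cosine 0.997) and
its analytic variance a²/2, and the projected scores trace the planted ±4 Å swing.

```sh
python examples/07_full_pipeline.py
```

```
NTD-NTD distance, free: 142.5 A
  activator: -1.03 A (closes the dimer)
  inhibitor: +1.04 A (opens the dimer)
activator dRMSF over NTD+M: +0.54 A (positive: binding mobilizes these domains)
activator dCP over NTD(A) x NTD(B): -1.67 A^2 (negative: larger fluctuations slow cross-protomer communication)
```

An activator-like bound ensemble pulls the N-terminal domains together, mobilizes the
NTD/M domains and slows cross-protomer communication; an inhibitor-like ensemble
shifts the dimer the opposite way. The remaining scripts in `examples/` walk through
each capability (generation, geometry, networks, contacts, CP) in the same style.

A thin CLI covers the two shell-shaped entry points:

```sh
allodyn synth --out toy.pdb --truth truth.json --domains domains.tsv
allodyn run --config run.yaml
```

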
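# waterdyn

Binding-site waters are short-lived tenants: they exchange with bulk on
picosecond timescales, tumble between orientations, and their reluctance to
leave — or eagerness to be displaced — shapes protein–ligand binding
thermodynamics.  `waterdyn` quantifies this behaviour from coordinate
trajectories and high-resolution structures of the kind produced for
serine-protease binding pockets (e.g. the S1 pocket of trypsin, where a
buried aspartate anchors both substrate head groups and a small, imperfect
water network).

The package computes:

- **Residence lifetimes.**  A water is *bound* to a residue when its oxygen
  lies within a cutoff of a residue-anchored reference frame origin; the
  cutoff is the first minimum of the solvent radial distribution function
  g(r) around that origin.  With per-frame indicators B_j(k) (water j,
  frame k), the survival-product correlation

      C_trans(t) = Σ_j Σ_{t'} Π_{k=t'}^{t'+t} B_j(k)

  counts windows of t+1 consecutively occupied frames; the translational
  lifetime is τ_trans = Δt ∫ C_trans(t)/C_trans(0) dt (trapezoidal), and
  curves are averaged over 2 ns chunks.  A single unoccupied frame ends a
  run — continuity is strict.
- **Rotational lifetimes.**  Each bound water carries an internal axis triad
  (Rx along O–H1, Rz normal to the molecular plane, Ry completing it);
  weighting each surviving window by R(t')·R(t'+t) gives C_rot(t) per axis
  and, through the same integral, τ_rot,x/y/z.
- **Normalised residence times**: τ_site / τ_reference against a fully
  solvent-exposed residue of the same type.
- **Structure analyses** (single-model PDB): per-water hydrogen-bond census
  with geometric criteria; a linear water-stability estimate from the
  H-bond deficit; two-state alternate-conformer energetics
  ΔE = RT ln(p_major/p_minor); pyramidalization of trisubstituted centres
  (improper torsion and out-of-plane distance); and relative binding free
  energies ΔΔG° = RT ln(K_d,weak/K_d,tight).
- **Synthetic benchmarks.**  A generator produces trajectories whose waters
  exchange with known exponential kinetics and tumble with a calibrated
  rotational correlation time, writing a ground-truth event log alongside —
  every pipeline stage is testable without external data.

## Worked example

Generate a ten-picosecond-residence benchmark, analyse it, and compare
against the generator's own event log:

```sh
waterdyn synth --seed 7 --n-waters 30 --n-frames 4000 --timestep 0.5 \
    --tau-res 8 --tau-rot 3 --n-shell-slots 4 --out run/
waterdyn lifetimes --traj run/trajectory.pdb --timestep 0.5 \
    --chunk-length 1000 --out run/analysis/
```

The second command logs the decided parameters to stderr and writes
`run/analysis/lifetimes.json`:

```
INFO waterdyn: hydration cutoff: 3.225 A (rdf first minimum)
INFO waterdyn: translational tau = 8.204 ps over 2 chunks (0 skipped)
INFO waterdyn: rotational tau (x axis) = 2.320 ps
INFO waterdyn: rotational tau (y axis) = 2.201 ps
INFO waterdyn: rotational tau (z axis) = 2.154 ps
```

The cutoff ≈ 3.2 Å is the detected g(r) first minimum (the generator digs a
depletion gap just outside its 3 Å shell).  τ_trans ≈ 8.2 ps recovers the
configured 8 ps mean residence from the occupancy statistics alone, and the
rotational lifetimes are shorter than the translational one because both
orientational decorrelation (3 ps) and shell escape (8 ps) attenuate the
orientation-weighted curve: 1/τ_rot ≈ 1/3 + 1/8 ⇒ τ_rot ≈ 2.2 ps.

The closed-form analyses run off tabulated inputs directly.  For two
inhibitor dissociation-constant pairs measured by isothermal titration
calorimetry at 25 °C:

```pycon
>>> from waterdyn import AffinityPair, delta_delta_g
>>> delta_delta_g(AffinityPair(kd_weak=366e-6, kd_tight=23.8e-6))
6.774483088754172
>>> delta_delta_g(AffinityPair(kd_weak=143e-6, kd_tight=20.7e-6))
4.790840768034465
```

i.e. the weaker binder pays 4.8–6.8 kJ/mol relative to the tighter one,
depending on the titration protocol.  Two-state water occupancies of 75/25%
refined at 100 K map to an energy gap RT ln 3 = 0.913 kJ/mol; 53/47% at
295 K to 0.295 kJ/mol.

## Layout

| module | contents |
| --- | --- |
| `waterdyn.trajectory_io` | PDB/XYZ readers and writers, topology model, selections |
| `waterdyn.reference_frames` | residue-anchored frames, water axis triads |
| `waterdyn.hydration_shell` | radial distribution, first-minimum cutoff, occupancy matrices |
| `waterdyn.lifetime_analysis` | survival-product correlations, chunked lifetime integration |
| `waterdyn.structure_geometry` | H-bond census, Boltzmann gaps, pyramidalization, ΔΔG° |
| `waterdyn.synthetic_data` | ground-truth trajectory and structure generators |
| `waterdyn.cli` | `waterdyn synth / rdf / lifetimes / geometry / report` |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
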
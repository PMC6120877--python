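# Methods

This note documents the models, conventions and numerical choices behind
`waterdyn`, in the order the pipeline runs.

## Units and coordinate conventions

Coordinates are Angstrom, times picoseconds, energies kJ/mol, temperatures
Kelvin, throughout; no unit inference is performed.  Multi-model PDB is the
trajectory interchange format (frame times are assigned 0, Δt, 2Δt from a
caller-supplied timestep, default 1 ps, since PDB carries none); an XYZ
reader with a sidecar-PDB topology exists for synthetic data.  Boxes are
orthorhombic only: when a CRYST1 record is present its edge lengths enable
minimum-image distances, otherwise coordinates are taken as unwrapped.
Waters are recognised by residue name (default HOH/WAT/SOL/DOD — heavy
water refines under DOD); hydrogen and deuterium are both "H-like" and
never distinguished chemically.

## Residue-anchored reference frames

A hydration site is defined in the internal coordinate system of an
anchoring side chain, so that the analysis is invariant under rigid-body
motion of the protein and under internal flips of symmetric groups (a
carboxylate rotating about Cβ–Cγ leaves the frame unchanged).

- **z-axis**: the mean of the unit normals of all C(n,3) planes through a
  designated atom subset (≥3 atoms).  Each triplet normal is sign-aligned
  with the first non-degenerate triplet before averaging; for the intended
  near-planar rigid subsets all triplet normals share a hemisphere and the
  result is independent of atom order up to overall sign.  The final sign
  is fixed by requiring the angle α between z and the direction to a
  user-chosen neighbouring residue's geometric centre to satisfy
  −90° < α < 90°; a neighbour lying exactly in the xy-plane is a
  degenerate-geometry error.
- **x-axis**: the difference vector of a two-atom subset, orthogonalised
  against z by projection (the raw vector need not be orthogonal to z;
  downstream transforms need an orthonormal triad).  y = z × x completes a
  right-handed frame.  The origin is the geometric centre of the union of
  both subsets.

Shipped subset defaults (overridable per site, in config or flags):
Asp {CB,CG,OD1,OD2}/{OD1,OD2}; Tyr {CG,CD1,CD2,CE1,CE2,CZ}/{CG,CZ};
His {CB,CG,ND1,CD2,CE1,NE2}/{ND1,NE2}.  These are reasonable rigid-group
choices, not canonical values; the neighbour residue has no default and
must always be chosen.  When alternate-location copies of a frame atom
exist, the highest-occupancy copy is used.

Each water carries an internal triad: Rx = normalised O→H1,
Rz = normalised O→H1 × O→H2, Ry = Rx × Rz.  Taking Ry literally as
Rx × Rz makes the triad left-handed; handedness cancels in the dot-product
autocorrelations it feeds, and the construction is kept as stated for
transparency.  H1/H2 are ordered by atom serial — a tie-break Rx genuinely
depends on, so it is fixed and documented.

## Hydration cutoff from g(r)

The solvent radial distribution function is accumulated around the
per-frame frame origin (bin width 0.05 Å, r_max 8 Å by default), with
counts normalised by exact shell volumes and by the mean solvent density
inside the r_max sphere, so an ideal gas gives g ≈ 1.  An alternative
minimum-distance-to-subset-atoms criterion sits behind a config switch,
default off.

The hydration cutoff is the first interior local minimum of g(r) after the
first local maximum exceeding 1, with two robustness refinements that a
literal reading would lack:

1. **Volume-weighted smoothing** (default window 5 bins): the smoothed
   value is Σ g·w / Σ w over the window with w ∝ the bin's shell volume —
   equivalently, a kernel estimate built from aggregated counts.  Without
   it, the tiny-volume bins at small r are dominated by Poisson noise
   (single counts produce huge g spikes, empty bins g = 0) and noise dips
   masquerade as the first minimum.
2. **Depth qualification** (default 0.35): a candidate minimum must fall to
   at most 0.35× the running maximum of g since the peak.  Genuine first
   minima in hydration-shell g(r) are deep (the synthetic benchmark's gap
   reaches 0; typical solvation shells reach ~0.25–0.3× peak height);
   shallow wiggles on a plateau are skipped.  Setting the ratio to 1
   restores the literal rule.

Exact ties — a flat plateau of minimal values, as a fully depleted region
produces — resolve to the plateau's midpoint bin.  Boundary bins never
qualify, and a profile without a qualifying minimum is an error, not a
guess.

## Occupancy and lifetime functionals

B[j,k] = 1 iff water j's oxygen is within the cutoff of the frame-k origin.
The translational correlation counts fully occupied windows,

    C_trans(t) = Σ_j Σ_{t'} Π_{k=t'..t'+t} B_j(k),

with windows that would extend past the last frame skipped.  Continuity is
strict: one unoccupied frame terminates a run, re-entry starts a new run,
and no transient-excursion tolerance is applied.  The per-frame indicator
form of B is used; a two-frame definition is redundant once the continuity
product is applied.  Internally the sum is evaluated by run-length
encoding — a run of length L contributes max(0, L−t) — which is
algebraically identical to the triple loop and is verified against a
literal transcription, exactly in integer arithmetic, in the tests.

The rotational correlation weights each surviving window by the dot
product of one water-internal axis with itself t frames later (axes
expressed in the residue frame).  Both orientational decorrelation and
site escape attenuate it, so for exponential tumbling (τ_r) under
exponential escape (τ_res) the recovered decay is 1/τ ≈ 1/τ_r + 1/τ_res.

Lifetimes are trapezoidal integrals of the curve normalised by its lag-0
value.  C_rot is normalised by C_rot(0) (not C_trans(0)); the choice is
recorded in the result metadata.  Curves are computed over consecutive
non-overlapping chunks (default 2000 ps) aligned to the series start; the
integration upper limit is the largest lag available in a chunk (max_lag
defaults to chunk length − 1 frame); a trailing partial chunk shorter than
half the chunk length is dropped; chunks whose curve starts at zero are
skipped and counted, not averaged in as zero.  The reported τ is the mean
of per-chunk values.  Normalised residence times are the plain ratio
τ_site/τ_reference, the reference being the same pipeline applied to a
fully solvent-exposed residue of the same type.

## Synthetic benchmarks

The generator is a statistical stand-in for solvated-protein MD, not a
physical simulation: it reproduces exactly the features the estimators
measure, with closed-form ground truth.

- **Exchange**: each water alternates bound/unbound with independent
  exponential durations (teleporting state switches, not diffusion, so the
  residence distribution is exactly exponential).  The unbound mean is set
  from the target mean shell population: p_bound = n_slots/n_waters.
  Every bound interval is written to a TSV event log (with truncation
  flags); recovery tests compare against the log's sample mean, never the
  configured value alone.
- **Geometry**: a rigid planar Asp-like anchor (CB/CG/OD1/OD2 in a plane,
  compatible with the default frame spec), a neighbour marker fixing the
  z sign, and 3-site rigid waters (O–H 0.96 Å, H–O–H 104.5°).  Bound
  waters sit uniformly within 0.9× the shell radius; unbound waters sit
  uniformly in a bulk cube excluding a sphere of radius shell_radius+0.8 Å,
  so g(r) has an exactly empty gap and a detectable first minimum near
  shell_radius+0.4 Å.  No periodic box by default (a boxed variant exists
  to exercise minimum-image code).
- **Rotation**: each frame every water is rotated about a uniform random
  axis by a Gaussian angle of width σ.  One such step gives
  E[u·u′] = (2e^{−σ²/2}+1)/3 for any axis, so
  σ² = −2 ln((3e^{−Δt/τ_rot}−1)/2) makes every axis autocorrelation decay
  as e^{−t/τ_rot} by construction (requires Δt < τ_rot ln 3, enforced).
- **Determinism**: one seeded generator in a fixed draw order; identical
  configs give bit-identical trajectories.

Default conditions — 100 waters, 40 000 frames at 0.5 ps (20 ns), 3 Å
shell with mean occupancy 4, τ_res 20 ps, τ_rot 5 ps — are the package's
standard benchmark scale: ~4000 complete residence events, giving ~2%
sampling error on τ_trans against a 10% acceptance band.  What passing
these benchmarks shows is that the estimators are unbiased on data with
known statistics; what it cannot show is anything force-field- or
protein-specific (no diffusion, no correlated exchange, no rotational
anisotropy, no H-bond-coupled orientations).

## Structure analyses

- **H-bond census**: an H-bond is counted when H···acceptor ≤ d_max
  (default 2.7 Å) and donor–H···acceptor angle ≥ angle_min (default 120°);
  intra-residue pairs never count; a donor–H pair ≥ 1.3 Å apart is
  rejected as mispaired.  A water's score sums bonds donated by its
  hydrogens and accepted by its oxygen.  The thresholds are declared
  defaults — experimental reports label distances without stating census
  criteria — and are configurable.
- **Stability from H-bond deficit**: a deliberately minimal linear
  surrogate, ΔΔG = (n_ref − n_site) × per_bond with per_bond = 10 kJ/mol
  by default, calibrated so a three-vs-two-bond comparison gives
  ~10 kJ/mol.  Published count-to-energy relations are non-linear; this
  module makes no claim beyond the linear regime around 2–3 bonds.
- **Boltzmann gaps**: ΔE = RT ln(p_major/p_minor) with
  R = 8.314×10⁻³ kJ/(mol·K); occupancies come from altloc fields or direct
  input.  Note the two candidate occupancy/temperature pairs for a typical
  cryo-vs-ambient comparison give different gaps (75/25 at 100 K → 0.913;
  53/47 at 295 K → 0.295 kJ/mol); both are reported side by side by the
  acceptance script rather than adjudicated.
- **Pyramidalization**: with serial-ordered neighbours (A,B,C) and centre
  X, the improper torsion is the torsion over the quadruple A–B–C–X folded
  into [0°, 90°]; it is 0 for a planar centre and, for a 0.29 Å lift at
  1.47 Å bonds, 21.9° — the scale least-squares refinements report for
  pyramidal guanidino nitrogens, which is why this quadruple ordering was
  chosen over placing the centre inside the quadruple (that convention
  yields 37.7° for the same geometry).  The out-of-plane distance is the
  exact point-to-plane distance to the three-neighbour plane; both metrics
  are zero together and increase together in the lift.
- **ΔΔG° from dissociation constants**: RT ln(K_weak/K_tight) at 298.15 K
  by default (ITC at 25 °C).

## Degenerate inputs and tolerances

Unit vectors are checked to 1e-9; collinear plane subsets, parallel O–H
bonds, x-subset vectors parallel to z (< 1e-6 rad) and in-plane neighbour
placements raise degenerate-geometry errors rather than returning
arbitrary axes.  PDB round trips are exact to the format's 1e-3 Å
precision.  An all-zero occupancy matrix yields a zero curve flagged by
c0 = 0; integrating it, or normalising by a non-positive reference, is an
error.

## Known limitations

Exchange is memoryless and positions are resampled per frame, so the
generator cannot test estimators' response to diffusive re-crossings at
the shell boundary (a strict-continuity estimator undercounts residence
when a water grazes the cutoff; quantifying that requires diffusive
dynamics, out of scope here).  Only orthorhombic boxes are supported.  The
RDF mode ties the shell to a single origin per residue; strongly
anisotropic shells would need the subset-minimum-distance variant or a
non-radial definition, which this package does not provide.
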
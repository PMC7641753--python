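# Methods

## Scope and data model

The package covers the desk-computable side of bulge-loop-inducing
peptidyl-oligonucleotide conjugate (POC) work: sequence-level design,
hybridization equilibrium analysis, geometric scoring of cleavage competence
on conformational ensembles, conformer clustering, and mass
characterization. It does not run molecular dynamics, compute energies or
charges, fold RNA secondary structure, or interpret gels/NMR/HPLC; ensembles
enter as multi-model PDB files regardless of how they were produced, and
simulated-annealing protocols appear only as bookkeeping descriptors.

## Conjugate design and hybridization

A conjugate is two DNA arms (5′ and 3′ of the attachment point) plus an
attachment mode: a modified adenosine (A\*, still pairs as A via its
Watson–Crick face) or an abasic sugar in α- or β-configuration (never
pairs). Hybridization uses exact Watson–Crick matching only — the study
designs are exact complements, and wobble support is an explicit non-goal.
Arm placement is an exhaustive substring search of the arm's reverse
complement against the target; zero placements and multiple placements are
both hard errors (ambiguity is surfaced, never silently resolved). The
bulge is the contiguous unpaired target run strictly between the two arm
footprints; target positions outside the arm span are dangling.

Conventions:

* Local target positions are 1-based; study numbering is attached through a
  single integer offset (the packaged 23-nt window starts at residue 54, so
  the CACAG bulge region spans 61–65).
* The internucleotide linkage "Xn−Yn+1" belongs to residue n's 3′-phosphate,
  consistently with the attack-angle convention below.
* An A\* opposite a single unpaired U is counted as a pair (bulge size 0);
  opposite any other single base it is left unpaired with a warning.
* Mer counting: A\* counts as a nucleotide, the abasic residue does not
  (an 11 + A\* + 7 conjugate is a 19-mer; 11 + abasic + 15 is a 26-mer).

## Binding model

The single-site equilibrium relates fraction bound α to Kₐ and total
concentrations; the forward expression is evaluated per titration point and
the inverse solves the quadratic in α with the cancellation-free two-root
form, selecting the smaller (physical) root in [0, min(1, [BC]₀/[RNA]₀)).
Round-trip identity holds to better than 1e-9 relative error across
Kₐ ∈ 10³–10⁸ M⁻¹.

`fit_ka` defaults to the per-point estimator (mean ± sd of per-point Kₐ
values) because the study reports symmetric ± errors; a least-squares
variant with bootstrap sd is available as `method="ls"`. The default
α-window (0.05, 0.95) excludes near-empty and near-saturated points, which
carry almost no Kₐ information and amplify read-out noise through the
(1−α) factors; exclusions are logged. Whether published errors of this kind
are per-point sd or replicate sd is generally ambiguous, so the estimator
never merges the two: per-point sd is what it reports, and replicate
statistics are left to the caller. Concentrations are molar internally; the
CLI accepts μM and converts.

## Ensemble I/O

Multi-model PDB is the single interchange format (structures, not
production trajectories, are what this workflow exchanges). Reading is
strict: alternate locations and insertion codes are rejected, every model
must match the first model's (residue number, residue name, atom name)
sequence exactly, and malformed coordinate records are reported with their
line number. O2\*/O2′ dialects are normalized to the primed form. Writing
is fixed-width to 3 decimals, so read(write(E)) reproduces coordinates to
1e-3 Å; values outside the fixed-width field are a format error, not a
truncation.

## Cleavage geometry

* **Attack angle.** Θ at linkage i−(i+1) uses O2′(i), P(i+1), O5′(i+1) —
  the attacking 2′-oxygen and the 5′-leaving oxygen sit apical around the
  phosphorus in the transition state. The in-line probability is the exact
  integer ratio of frames with Θ strictly above the threshold (default
  155°). The strict ">" is deliberate and configurable; sources vary
  between "> 155°" and "≥ 155°", and we follow the stricter counting rule.
* **Dihedral filter.** A generic signed-torsion primitive is provided, but
  the atom quadruple defining the auxiliary Φ filter is not standardized,
  so Φ-based filtering requires the caller to specify the quadruple
  explicitly; no default is assumed.
* **Guanidinium proximity.** Distances are minimized over each arginine's
  available {NE, NH1, NH2} and recorded separately to O2′(i) and P(i+1).
  The productive criterion (≤ 6 Å to both, same frame) has two modes
  because the mechanistic literature motivates both a single catalytic
  guanidinium and a cooperative guanidine–guanidinium dyad: `single`
  (default) requires one arginine, `dyad` two distinct ones; dyad fraction
  ≤ single fraction by construction.
* **Weighted average distance.** Defined as the plain mean over all
  (frame, arginine, target-atom) observations. Weighting by frame or by
  histogram bin coincide under this definition, which is why it is the one
  implemented. Histograms use 0.5 Å bins over 0–45 Å with one overflow bin
  so counts always total the number of observations.
* **Reach.** Maximum reach = unfolded peptide length + linker length
  (36.5 + 8.6 = 45.1 Å for the study peptides); a site is reachable when
  the P(attachment)–P(site) distance does not exceed it, boundary
  inclusive. Frames are weighted uniformly everywhere — annealing
  snapshots are treated as equally weighted samples, with no energy
  reweighting.
* Missing required atoms (e.g. O5′ at a 3′-terminal residue) reject the
  site with a named error rather than silently skipping frames.

All primitives are validated against independent oracles (arccos/atan2
forms, brute-force distance scans) at 1e-9 tolerance, and all statistics
are invariant under rigid-body motion to 1e-6.

## Conformer clustering

Pairwise RMSD after Kabsch superposition (proper rotations only; the
determinant sign correction forbids reflections) on heavy atoms (element ≠
H) by default. Hierarchical agglomerative clustering with average linkage
as the robust default for RMSD matrices (single and complete available);
the dendrogram can be cut by cluster count k or by RMSD threshold — no
particular cut is privileged, since the appropriate granularity depends on
the ensemble. Representatives are medoids (minimum mean RMSD to cluster
members), ties broken by lowest frame index so output is deterministic.
Reproducing any specific published cluster layout is out of scope: that
depends on trajectories not shipped with this package.

## Mass characterization

Monoisotopic masses use most-abundant-isotope masses and average masses the
standard atomic weights, both pinned in source (NIST Atomic Weights and
Isotopic Compositions; IUPAC 2021 standard weights) for C, H, N, O, P, S,
Na, K, Li, F, Cl. Adduct m/z = (M + Σ cation masses)/charge with
electron-corrected cation masses (proton 1.007276 Da). The two catalytic
peptide formulas reproduce their printed characterization values as
monoisotopic sums (1193.78 Da / 597.9 m/z; 1251 Da / 1252 m/z at printed
precision). Known limitation: several full-conjugate printed "calc." MW
values (e.g. 8144 for C₂₇₆H₃₈₂N₁₁₁O₁₄₀P₂₁) fall between the monoisotopic
(≈8141) and average (≈8145) sums and match neither to < 1 Da; the mass
convention behind those printed values is not recoverable, so the package
reports both sums and does not force-fit them.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated:

* **Titrations**: RNA at 1 μM, conjugate grid 0.25–10 μM (8 points),
  additive truncated Gaussian noise with sd 0.02 on fraction bound —
  the error character of gel densitometry read-outs. Under these
  conditions the median relative Kₐ recovery error over 200 seeds is
  below 10%.
* **Ensembles**: 100 frames by default, one per round of the emulated
  100-round annealing protocol. Geometry is planted, not simulated: each
  scissile site is a minimal O2′/P/O5′ pseudo-residue pair (residue name
  SYN) whose per-frame Θ is set explicitly (165° above threshold, 120°
  below), and each arginine is its three guanidinium nitrogens, placed
  within ~3 Å of both target atoms in exactly the planted number of
  productive frames and at background distances (10–43 Å, rejection-sampled
  with a 1 Å clearance margin) otherwise. Planted counts are therefore
  recovered *exactly* by the analysis code — these ensembles validate the
  counting and geometry machinery, not any physical model: no force field,
  no energies, no correlation structure between frames, so passing tests
  say nothing about how a real annealing ensemble is distributed.
* **Design families**: targets and arm sets constructed so hybridization
  yields requested bulge sizes by construction, either on the packaged
  23-nt study window or on random cores (re-drawn if arm placement is
  ambiguous).
* **Schedules**: the reference annealing descriptor is heat 300→800 K over
  0.5 ns, 5 ns at 800 K, cool over 0.5 ns, 5 ns at 300 K (11 ns per step,
  100 rounds), with the restraint force constant stored verbatim with its
  unit string ("0.01 kcal⋅mol−1⋅Å−1") because that printed unit is
  nonstandard for a harmonic positional restraint and silent "correction"
  would be a guess.

Every generator takes an explicit seed, owns its `numpy.random.Generator`,
and is byte-identical across runs; noise on α is additive truncated
Gaussian (a beta-noise model was considered and left out as needless
complexity at these noise levels).

## Numerical choices

* Binding quadratic solved in the two-root cancellation-free form; α
  clamped a half-ulp inside its physical upper bound.
* Angle cosines clipped to [−1, 1] before arccos; degenerate geometry
  (zero-length vectors, < 3 or collinear superposition atoms) raises
  rather than returning NaN.
* Dihedral sign follows the standard polymer convention, range (−180°, 180°].
* Test problem sizes (100-frame ensembles, 200-seed recovery studies,
  8-point titrations) match the generator defaults above; the full suite
  runs in a few seconds on one core.
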
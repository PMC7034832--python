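# Methods

## Scope and model

`sranet` post-processes molecular-dynamics trajectories of protein–DNA
complexes in which a reader domain (the motivating system is the SRA domain
of UHRF1) holds a modified cytosine flipped out of a CpG duplex.  The
package computes four families of observables, plus the quantification
formulas of the accompanying binding assays:

1. **Geometric contacts.**  A hydrogen bond is a donor-heavy-atom/acceptor
   pair at ≤ 4.0 Å whose D–H–A angle is ≥ 120° (180° ideal); the distance
   is between heavy atoms, the convention of the common trajectory tools.
   A salt bridge is a heavy-atom pair from two formal-charge groups of
   opposite sign at ≤ 5.0 Å.  The charged set comprises the Arg
   (NE/NH1/NH2) and Lys (NZ) side chains, Glu/Asp carboxylates, nucleotide
   phosphates (OP1/OP2) and the 5-carboxyl oxygens (O51/O52) of
   carboxylcytosine.  Histidine is neutral by default and terminal charge
   groups are excluded; both are role-table entries, not code.
   Salt bridges are counted per atom pair, so a guanidinium group facing
   both phosphate oxygens contributes several simultaneous interactions —
   this is what lets network edge weights exceed 2 interactions/frame.
   A pair qualifying as both kinds in one frame is kept twice; display
   precedence is a network-layer decision.

2. **Interaction networks.**  Per-pair, per-frame counts are aggregated
   under a node map (default: one node per residue; individual atoms or
   atom groups such as O51/O52 can be carved out).  Atom counts are summed
   into node-level per-frame counts *before* statistics.  Each edge carries
   the mean number of interactions per frame (the printed edge weight) and
   the occupancy (fraction of frames with ≥ 1 interaction).  Occupancy
   drives pruning: edges occurring in ≤ the threshold fraction of frames
   are omitted, strictly, so an edge sitting exactly at the threshold is
   dropped.  Defaults are 0.15 for binding-pocket views and 0.10 for
   NKR-finger views.  When a node pair retains both kinds, only the
   salt-bridge edge is emitted if precedence is on; statistics are always
   computed per kind first so the alternative reading can be audited.
   Note that precedence interacts with pruning: raising the threshold can
   prune a salt-bridge edge and thereby re-admit the hydrogen-bond edge it
   was masking.  Pruning proper is monotone; the property tests check
   monotonicity with precedence off.

3. **Superposition metrics.**  RMSD fits every frame to a reference (run
   start or crystal structure) on a fit selection — canonically the protein
   Cα atoms without terminal regions — and measures over a separate calc
   selection without refitting, which is how DNA divergence is scored under
   a protein-frame alignment.  The fit is the Kabsch least-squares rigid
   transform (SVD with the determinant correction, always a proper
   rotation).  RMSF uses a two-pass protocol: prefit to the first frame,
   average, refit to the mean, fluctuations about the mean position;
   per-residue values are unweighted means over heavy atoms (mass weighting
   off, switchable in principle but not exposed — the convention is the
   cited tools' default).  Replica QC excludes a replica iff its
   tail-window DNA RMSD exceeds 4.0 Å; exclusions are reported with max and
   mean tail RMSD, never silent.  "Last N ns" tail slicing resolves to a
   frame count via the uniform frame spacing, rounding to the nearest
   frame.

4. **Groove widths.**  The El Hassan–Calladine-style construction is read
   as cross-strand phosphate distances with opposite offsets: at base-pair
   position *i*, minor = |P(strand 1, i+2) − P(strand 2, i−2)| and major =
   |P(strand 1, i−2) − P(strand 2, i+2)|.  The ±2 offset is a config value
   so the ±3 variant can be compared, and an independent brute-force oracle
   in the tests pins whichever convention is configured.  Raw P–P distances
   are reported; a flag subtracts 5.8 Å (two phosphate radii) for
   comparison with tools reporting accessible widths.  Base pairing is
   supplied in the config — a flipped-out base breaks geometric pair
   detection — and positions lacking a required phosphate (termini, the
   gap left by the flipped base) are undefined: NaN plus an explicit mask,
   never zero.  Base-pair numbering follows the strand binding the
   flipped-out base.

5. **Binding assays.**  The dual-colour EMSA normalization is
   (bound₅₅₀/bound₆₄₇)·(total₆₄₇/total₅₅₀): the modified probe's bound
   fraction relative to an unmodified internal control in the same lane,
   invariant under per-channel rescaling.  Titrations are fitted by
   nonlinear least squares to the non-depleting 1:1 isotherm
   R(c) = R₀ + A·c/(c + K_D), with the K_D start value at the concentration
   nearest half-amplitude so the fit is deterministic given the data.  The
   hyperbolic form is justified when the fixed partner concentration is
   well below K_D (tens of nM against sub-μM to μM K_Ds); a quadratic
   depletion model is available behind a flag.  Stoichiometry is fixed at
   1:1 (no Hill coefficient).

## Synthetic data: what it emulates and what it does not

No public trajectories accompany the motivating study, so correctness is
established on generators with planted ground truth:

* **Fiber duplex** (`generate_bdna`): two antiparallel strands of
  pseudo-nucleotides (P, OP1, OP2 and a six-membered ring with N1/N3; O51/
  O52 on carboxylcytosine) at rise 3.38 Å and twist 36°/bp.  Phosphates sit
  8.91 Å from the axis at ∓77° around the base-pair direction — chosen once
  so the ±2 cross-strand convention yields major > minor, as in B-DNA.
  Helical symmetry makes interior groove widths exactly constant, which is
  the fixture's point.  A flipped base keeps its backbone and swings only
  the ring outward.  The generator does not model sugars, sequence-
  dependent helical parameters or real base geometry; passing tests
  demonstrate the correctness of the width bookkeeping, not agreement with
  any experimental groove profile.
* **Planted contacts** (`plant_contact_trajectory`): each planted
  interaction lives in its own cluster 200 Å from the next; "on" frames put
  the atoms 0.5 Å inside the cutoff at the ideal angle, "off" frames move
  the donor-side residue 12 Å away (≥ cutoff + 1 Å), so floating-point
  jitter can never flip a detection and realized occupancies are exact.
  On-frames are a seeded permutation; per-frame counts of 1–3 are built
  from multiple donor/charged atoms per residue.
* **Harmonic ensembles**: reference + isotropic Gaussian noise of known
  per-coordinate σ, giving per-atom RMSF → √3·σ.  The calibration leaves
  the fit atoms noise-free; with noisy fit atoms the alignment itself
  jitters and the far-atom RMSF picks up a lever-arm contribution, which is
  a property of superposed fluctuations generally, not of this
  implementation.
* **Replica sets**: jittered copies (σ = 0.05 Å) of a base run; divergent
  members get all DNA atoms rigidly displaced in the tail window.
* **Titrations**: exact isotherm plus Gaussian noise, seeded.

None of these fixtures have force-field realism; what the passing tests
show is that the bookkeeping — criteria, aggregation, pruning, alignment
conventions, width conventions, fit protocols — is exactly right on inputs
where the truth is known.  They say nothing about sampling convergence or
force-field accuracy on real trajectories.

## Numerical choices

* Kabsch refuses < 3 fit atoms or a rank-deficient (collinear) cloud.
* KDE wraps `scipy.stats.gaussian_kde`; Scott's rule is the default
  bandwidth, and a fixed bandwidth in Å is translated into scipy's
  covariance-factor convention (h/σ̂).  Constant samples are a degenerate-
  input error, not a delta function.  The normalization check integrates
  over ±6 bandwidths beyond the sample range (tolerance 1e-3).
* Edge weights are kept at full precision internally; 2-decimal rounding
  happens only in the presentation table.
* Tables are written with fixed formats and sorted keys, and the summary
  records SHA-256 hashes of all input coordinates and output tables, so a
  rerun of the same config on the same inputs is byte-identical.
* Zero-length distance vectors in the angle computation (coincident atoms)
  skip the candidate rather than dividing by zero.

## Problem sizes

The test and acceptance workloads are sized for a laptop-class single
core: 100-frame plants, 200 random frames for the detector oracle, 2000
frames for the RMSF calibration, 14-bp duplexes, 16-point titrations,
5-replica QC sets of 40 frames.  All quantities they compute are either
exact recoveries (independent of size) or estimates whose tolerance the
tests state explicitly.

## Known limitations

* No periodic-boundary minimum-image handling is applied by the synthetic
  fixtures (they are non-periodic by construction); trajectories with a
  box should be imaged upstream.
* No π-stacking detection, no energetic scoring, no pKa/protonation
  prediction beyond the static role table, no helicoidal parameters beyond
  groove widths, no PCA/clustering, no thermophoresis physics upstream of
  the titration table.
* Whether the D–H–A or H–D–A angle convention was used by the original
  trajectory tooling is not documented there; D–H–A with ≥ 120° acceptance
  is implemented, and the cutoff is a parameter for sensitivity testing.
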
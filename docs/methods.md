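# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `loopsom`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Geometry

Torsions use the atan2 formulation with the IUPAC sign convention (clockwise
positive viewed from the second toward the third atom); values live in
(−180°, 180°], with −180° mapped to +180°. Worked anchor:
torsion((1,1,0), (1,0,0), (0,0,0), (0, cos 60°, sin 60°)) = +60°. A dihedral
is invariant under reversing the atom path and changes sign under mirror
reflection; both identities are property-tested. Degenerate inputs
(coincident consecutive points, collinear bond vectors) raise rather than
returning a sentinel, as do missing backbone atoms; undefined terminal φ/ψ
are reported as NaN.

Backbones are rebuilt from internal coordinates by sequential natural
extension (NeRF). Ideal geometry defaults: N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å, angles N–Cα–C 111.0°, Cα–C–N 116.6°, C–N–Cα 121.7°, ω = 180°
for regular chains; all configurable. Build→extract round-trip error is
≤ 10⁻³ degrees by test (observed ~10⁻¹³).

Superposition is classical Kabsch via SVD with the determinant correction
restricting to proper rotations; the subset must contain ≥ 3 non-collinear
atoms. Residue indices are 1-based and carried from input; mapping between
an author's residue labels (precursor numbering, e.g. E59) and a structure's
indices is configuration, with helpers for the reference allergen
(mature-chain ↔ precursor offset +23; the modelled chain spans precursor
residues 38–135).

## Synthetic generators

The generators define the conditions every downstream test runs under; they
emulate the *statistical shape* of trajectory and MS data, not the physics.

* **Dihedral macrostates** — a first-order Markov chain over K discrete
  states; each angle emits von Mises noise (the canonical circular analogue
  of a Gaussian) about the active state's mean. Defaults used by the
  recovery analyses: K = 3 states, 6 angles, per-angle state means 60° apart
  with the lattice kept away from the ±180° seam when K allows (see
  "Limitations"), concentration κ = 20 (circular SD ≈ 13°, a tight
  rotameric well), self-transition probability 0.98 (metastable dwell ≈ 50
  frames), n = 5000 frames.
* **Positional fluctuation** — i.i.d. isotropic Gaussian displacement per
  residue applied rigidly to the residue's N/Cα/C, per-coordinate SD σᵢ.
  Rigid-per-residue displacement keeps positional and dihedral noise
  independent and makes the RMSF ground truth exactly σᵢ√3.
* **Scores** — per-frame scalar = cluster mean + Gaussian noise, standing in
  for an external effective-energy table.
* **Peptide observations** — tryptic peptides (≤ 2 missed cleavages) with
  fixed carbamidomethyl-C; peptides covering planted arginine sites
  additionally emit a single-PG ion at the site's intensity; masses are
  perturbed multiplicatively by Gaussian ppm noise (default scenarios use 0
  and 5 ppm against the 20 ppm matching window — a 4σ margin).

All generators are bit-reproducible given (parameters, seed); seeds are
explicit arguments, never global state. What passing tests show is that the
analysis recovers *planted* structure of these statistical forms; they say
nothing about force-field accuracy, solvent effects, autocorrelated
anisotropic fluctuations, chromatographic intensity biases, or co-eluting
isobaric species, none of which the generators model.

## Flexibility measures

RMSF is computed over Cα atoms by default (all-backbone optional):
RMSFᵢ = √⟨|rᵢ(t) − r̄ᵢ|²⟩. With alignment on, frames are superposed onto an
iteratively refined average structure (align to an initial reference →
average → realign to the average); the aligned RMSF is invariant under
global rigid transforms of the whole trajectory (tested at 10⁻⁶ Å). With
alignment off, a supplied reference may serve as the fluctuation center,
which is what makes the σ√3 recovery test exact. Replica aggregation is
mean ± sample SD (N−1 denominator); a single replica reports SD 0 with
n = 1 recorded rather than a missing value. Region summaries average within
each replica first, then report mean ± SD of the per-replica averages —
the order matching how triplicate-simulation loop flexibilities are
conventionally quoted. Absolute loop-RMSF magnitudes from microsecond
simulations are not reproducible at desk scale and are not targets.

## Divergence filter

Per-system dihedral means are circular (direction of the mean resultant
vector; undefined and raised when the resultant length vanishes), because
arithmetic means of angles depend on where the ±180° seam falls; an
arithmetic-mean flag exists for strict replication of pipelines that used
plain means. Divergence is the maximum *pairwise* angular difference across
systems (a baseline-vs-rest mode is available), and an angle is selected
when it strictly exceeds the 30° threshold. Angles missing from some
systems are excluded with a warning. Selection is invariant under system
relabeling and under adding 360° to raw angles (tested).

## SOM pipeline

* **Standardization**: zero mean, unit population variance; zero-variance
  features are an error naming the column.
* **Training**: online single-sample updates, Gaussian neighborhood
  h = exp(−d²_grid/2σ(t)²), learning rate α₀ = 0.5, 5000 update steps;
  α and σ decay by the asymptotic schedule x(t) = x₀/(1 + t/(T/2)) (a
  common online-SOM default; the schedule is a configurable, logged choice).
  Weights initialize from randomly drawn data samples. "Neuron count"
  grid values are interpreted as the **side length of a square map** (the
  final-settings notation "65 × 65 neurons" fixes this semantics); defaults
  scan sides {5, 10, …, 100} and σ ∈ {1.00, 1.25, …, 6.25} with every σ
  required to be smaller than the smallest side.
* **Metrics**: QE = mean sample→BMU Euclidean distance; TE = fraction of
  samples whose best and second-best units are not grid-adjacent under the
  8-neighborhood (4-neighborhood optional); distortion =
  Σ_samples Σ_units h(BMU, unit)·‖x − w‖² evaluated with the final-epoch σ
  (the distortion definition is otherwise open; this choice is logged).
* **Selection rule**: keep the ⌈10%⌉ of models (minimum 1) with the lowest
  TE, ties broken by grid order; among them choose lexicographically by
  (QE, distortion, grid order). The rule is pure-function testable and is
  checked against a literal restatement on random metric tables.
* **Macrostates**: weights of distinct BMU-hit units (unweighted — whether
  frequently-hit units should be weighted is genuinely open; unweighted
  distinct units is the default) are clustered by Ward/Euclidean HAC
  (complete/average available); silhouette scores on the unit weights over
  k ∈ [5, 20] select k at the **second-largest** value, ties toward smaller
  k — a deliberately conservative reading of the "second maximum" heuristic
  (second-largest value, not second local maximum), with the global maximum
  behind a flag. Fewer hit units than k_max truncates the range with a
  warning; fewer than 3 is an error.
* **Representatives**: per cluster, the argmin-score frame and the
  argmax-subset-Cα-RMSD frame versus a reference, ties toward the lowest
  frame index.

Desk-scale analyses in the tests and acceptance script use reduced grids
(sides {5, 10}, σ {1.0, 1.5, 2.0}) — the selection rule and recovery
behaviour are grid-size-independent, and recovery is measured by adjusted
Rand index against generator truth (≥ 0.9 required; ≈ 1.0 observed).
Per-system hyperparameters of the original microsecond-trajectory analysis
(65×65/σ 5.25 etc.) depend on those trajectories and are not targets.

## Modification-site mapping

Digestion cleaves C-terminal to K/R, suppressed before proline (toggleable);
Lys-C/trypsin double digestion collapses onto this rule for K/R specificity.
Peptides carry parent coordinates and missed-cleavage counts; enumeration
satisfies the combinatorial identities (0-missed concatenation reconstructs
the sequence; F fragments give F − m peptides with exactly m missed sites).

Masses are neutral monoisotopic throughout: Σ residue masses + H₂O
(18.0105646 Da), via pyteomics, plus modification deltas computed from
elemental compositions — carbamidomethyl-C +57.02146 (C₂H₃NO), oxidation-M
+15.99491 (O), PG-R +116.02621 (C₈H₄O, i.e. phenylglyoxal C₈H₆O₂ condensed
with loss of water). Charge-state deconvolution is out of scope; the
nominal integer shifts (+57/+16/+116) are what search configurations quote.
Variable-modification enumeration caps placements at 3 per peptide by
default to bound the combinatorics.

Matching reports **every** theoretical ion within the ppm window (default
20 ppm, relative to the theoretical mass) and flags observations with
multiple hits as ambiguous. Site-intensity profiles count only unambiguous
matches by default: equal-mass PG placements on a multi-arginine peptide
cannot be localized by neutral mass alone (localization is an MS2 problem,
out of scope), and summing them would smear intensity onto unmodified
arginines; with this convention the planted-site round trip at zero ppm
noise recovers the planted set exactly. A flag restores inclusive summing.
Per-site intensity totals scale with the number of unambiguous covering
peptides, so profiles are comparable across sites only under max- or
sum-normalization with that caveat in mind. Profiles are reported per input
record; cross-isoform residue-number alignment is not attempted.

The reference module carries the mature Ana o 3.0101 chain (precursor
residues 24–138; 15 arginines), the four disulfide pairings of the modelled
structure (C39–C87, C52–C76, C77–C124, C89–C132), the loop/feature residue
ranges, and the 21-angle feature list from the original analysis — the
latter strictly as a label-format fixture, since the selection depends on
the original trajectories.

## Pipeline and reproducibility

The `loopsom run` pipeline executes stages in dependency order, records the
SHA-256 of the canonical config, the seed and all selected hyperparameters
in `summary.json`, dumps the effective config and a machine-readable
warnings file, and is byte-identical on rerun with the same inputs and
config. Exit codes: 0 success, 2 validation error, 1 runtime failure.

## Limitations

* Clustering operates on raw standardized degrees (faithful to the
  described scaling); this encoding is seam-sensitive — a state whose
  angular well straddles ±180° splits into two distant blobs and can
  fragment clusters. The generator's default well lattice therefore avoids
  the seam, and a sine/cosine circular encoding is the recommended remedy
  for seam-straddling data.
* The silhouette second-maximum heuristic is exactly that; on clean
  synthetic data the global maximum is the correct oracle and is what the
  recovery tests use.
* RMSF mass-weighting and heavy-atom selections beyond Cα/backbone are not
  implemented; the defaults are documented choices, not claims about any
  external tool's behaviour.
* The in-silico MS stage models neutral masses and intensities only — no
  isotope envelopes, charge states, retention behaviour, FDR control or
  fragment spectra.
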
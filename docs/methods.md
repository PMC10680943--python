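# Methods

Model assumptions, parameter choices and limitations of the `heatdyn`
toolkit. Defaults shown here are the package defaults; all are exposed as
function / spec arguments and in the CLI configs.

## Gaussian network model (`heatdyn.gnm`)

The GNM represents a structure as Cα beads connected by identical
harmonic springs whenever two beads lie within a distance cutoff. The
Kirchhoff (graph Laplacian) matrix is
`K_ij = -γ` for contacts, `K_ii = γ · degree(i)`; slow eigenvectors of
`K` are the collective mode shapes.

| parameter | default | unit | meaning |
|---|---|---|---|
| `cutoff` | 10.0 | Å | Cα–Cα contact distance |
| `gamma` | 1.0 | — | spring constant (scales eigenvalues only) |
| `band` | 0.0025 | — | mode-shape magnitude defining "in-band" hinge residues |

Assumptions and choices:

* Isotropic, single-parameter springs; no mass weighting, no distance
  dependence. Eigenvalues are relative stiffnesses, not frequencies.
* The zero eigenvalue (rigid-body mode of the connected graph) is
  discarded; a disconnected contact graph is an error reporting the
  component count rather than a silent multi-zero spectrum.
* Eigenvector sign is fixed deterministically (largest-magnitude
  component made positive) so mode shapes are reproducible across runs
  and platforms.
* **Hinge detection**: a hinge is a zero-crossover of a slow mode shape.
  Residues whose shape value lies within ±`band` are "in-band"; for each
  sign crossover without an in-band member, both flanking residues are
  reported. This matches the common convention of treating both
  crossover neighbours as the hinge when the mode shape jumps through
  zero between residues.
* Validated against closed-form path-graph Laplacian spectra
  (`P_n` eigenvalues `2 − 2 cos(kπ/n)`) and against an independent
  normal-mode package (bio3d's `gnm`, cutoff 10 Å) on an identical bead
  geometry: eigenvalues agree to 12 significant digits, mode shapes to
  the sign convention.

## Superposition (`heatdyn.superpose`)

* Kabsch superposition via SVD of the weighted cross-covariance, with the
  determinant correction that enforces a *proper* rotation (no
  reflections), verified against brute-force minimisation over rotations.
* Collinear or near-collinear selections (cross-covariance rank < 2) are
  rejected as degenerate rather than returning an arbitrary rotation.
* RMSF is computed about the ensemble mean *after* aligning every frame
  to a reference, optionally on a sub-selection so that a localized
  displacement is not absorbed into the fit.
* Internal (segmental) RMSD superposes on the section alone, so it
  measures internal deformation and is invariant to rigid motion of the
  section; by construction it is never larger than the section RMSD
  under a global superposition.

## Ensemble PCA and deformation overlap (`heatdyn.pca`)

* Frames are flattened to an F×3N matrix, centered, and decomposed by
  SVD; eigenvalues use the 1/F (population) normalization of the
  covariance. Components are returned as orthonormal 3N vectors with the
  deterministic sign convention.
* The deformation vector between two conformers is the coordinate
  difference after superposing the second onto the first over their
  common residue roster (matched by chain and residue number; at least 3
  common residues required).
* Correlation cosine is `|p · d̂|` for a unit component `p`; cumulative
  overlap is the root-sum-square over a component subset and requires the
  subset to be orthonormal (checked, tolerance 1e-6). With a complete
  basis the cumulative overlap is exactly 1.
* End-to-end distance histograms pool one or more series into shared
  1 Å bins (default), lightly smooth with a 3-bin moving average before
  peak picking, and merge peaks closer than 2 bins. Histograms shorter
  than the smoothing kernel skip smoothing.

## Trap-trace analysis (`heatdyn.tweezer`)

The post-trap transmission of an overdamped particle in a harmonic trap
is modelled as an Ornstein–Uhlenbeck (OU) process; its one-sided power
spectral density is Lorentzian, `S(f) = A/(f_c² + f²) + B`, with
`A = 2σ² f_c / π` for stationary variance σ², plus a white detector
floor `B`.

| parameter | default | unit | meaning |
|---|---|---|---|
| `jump_threshold` | 0.10 | — | minimum relative mean increase at the step |
| `noise_increase_threshold` | 0.10 | — | minimum relative rolling-SD increase |
| `window` | 0.1 s of samples | samples | rolling-statistics window |
| `margin` | 0.2 | s | post-step transient excluded from analysis |
| `segment_length` | 2¹⁵ | samples | Welch segment (Hann, 50% overlap) |
| `fit_range` | (5, 10⁴) | Hz | Lorentzian fit band |

Numerical choices:

* **Step detection** requires an upward mean jump *and* a noise increase
  over rolling windows. The noise comparison uses a window starting one
  full window past the candidate index, because any window straddling a
  clean level shift has an inflated SD; without the offset a noise-free
  step would be accepted.
* **Normalization** divides the post-step segment (after the margin) by
  the pre-step mean; normalized RMSD is the SD of that normalized
  segment.
* **Lorentzian fitting** minimizes log-PSD residuals
  (Levenberg–Marquardt, positivity enforced by exponential
  parameterization), which weights each frequency decade evenly instead
  of letting the dense high-frequency floor dominate. Initial guesses
  come from the spectrum itself (low-frequency plateau, half-plateau
  crossing, high-frequency floor).
* The Welch segment default of 2¹⁵ samples (~3 Hz bins at 100 kHz) was
  chosen because ~6 Hz bins visibly bias the fitted corner upward
  (≈ +5%) for corners near 20 Hz, the low end of the experimentally
  relevant 16–123 Hz range; at 2¹⁵ the bias is below 0.5% across that
  range.
* A fit whose corner lands within 5% of the fit-range boundary, or whose
  Lorentzian plateau `A/f_c²` falls below the fitted floor `B` (no
  resolvable knee, e.g. pure white noise), raises a `boundary_flag`
  rather than reporting a meaningless corner silently.

## Synthetic generators (`heatdyn.synthetic`)

* **Solenoid pair**: beads on a helix (radius 15 Å, rise 10 Å per
  4-bead repeat, 25° twist per repeat, 15 repeats); the extended
  conformer scales the rise by 1.6. This reproduces the topology and
  end-to-end contrast of a HEAT-repeat solenoid, *not* its atomic
  geometry — no side chains, no inter-helix packing, a single planted
  collective direction.
* **Planted-mode ensembles**: Gaussian displacements along the planted
  deformation direction (SD `mode_amplitude`, default 10 Å) plus
  isotropic noise projected orthogonal to it (SD `noise_amplitude`,
  default 1 Å), with optional linear drift or two-centre (bimodal)
  populations. Real MD ensembles have correlated, anharmonic noise;
  these do not.
* **OU traces**: exact AR(1) discretization
  `x[n+1] = x[n]·e^(−2πf_c·Δt) + σ·√(1 − e^(−4πf_c·Δt))·ξ[n]`,
  initialised from the stationary law, on top of a flat pre-trap
  baseline, a relative step of 15%, and white detector noise. Real
  traces add drift, 1/f laser noise, and occasional escape/retrap
  events; none are modelled.
* Defaults of the generators define the simulated study conditions and
  are never adjusted to make analyses pass: analysis parameters were
  chosen on first principles or closed-form/oracle checks.
* Shipped data tables: `table1.tsv` (six interface mutations with
  predicted ΔΔG and pathogenicity) and `table2.tsv` (per-system mean/SD
  end-to-end distance, corner frequency and normalized RMSD for the wild
  type and six hinge mutants).

## Mutation triage and cross-modality joins (`heatdyn.pipeline`)

* `classify_mutation`: group `a` (pathogenic) when the pathogenicity
  score strictly exceeds 0.65; otherwise by ΔΔG: `b1` (< 0, not
  destabilizing), `b2` (0 ≤ ΔΔG < 1.25 kcal/mol, mildly destabilizing),
  `b3` (≥ 1.25, highly destabilizing); `unclassified` when ΔΔG is
  missing. Total over [0,1] × (ℝ ∪ missing).
* Score aggregation over repeat/element annotations excludes unscored
  residues from denominators and reports them; an element left empty is
  NaN, never a silent zero.
* Cross-modality correlations join per-system summaries by label
  (order-independent), require ≥ 3 common systems, and report `r` at
  full precision with `n`. On the shipped table, mean end-to-end vs
  normalized RMSD gives r = −0.8215 (−0.82 at 2 dp); the SD column gives
  r = +0.80. The SD-side value is sensitive to the 2-decimal rounding of
  the shipped inputs, so only its sign and magnitude (> 0.7) are treated
  as reproducible.

## Limitations

* The GNM is topology-only: it predicts relative mobilities and hinge
  locations, not absolute amplitudes, time scales or anharmonic paths.
* PCA overlap statistics assume the ensemble is well superposed; large
  internal rearrangements can alias into apparent rigid-body motion.
* The Lorentzian fit assumes a single trapped species and a single
  relaxation; multi-state hopping produces spectra this model
  mis-summarizes with one corner.
* The trapping-step detector assumes one upward step per trace; traces
  with multiple trapping/escape events report only the earliest step.
* Synthetic generators are contract tests for the analysis chain, not
  physical simulations; conclusions about real proteins require real
  trajectories and recordings.
* The two reference crystal structures used by one acceptance check are
  downloaded on demand and never redistributed.
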
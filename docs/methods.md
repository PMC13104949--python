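# Methods

## Scope and model overview

bindkin analyzes receptor–ligand binding kinetics from two directions that
meet at the same observable, the residence half-life t_1/2:

1. **Experiment side.** Radioligand counts-per-minute (cpm) curves are fit to
   the classical single-site models (saturation hyperbola, one-phase
   association, one-phase exponential decay, four-parameter logistic
   displacement). Dissociation measured in the presence of excess unlabeled
   antagonist is treated as satisfying the no-rebinding condition of the
   one-phase decay model — the antagonist occupies receptors as the
   radioligand leaves — so k_off is read directly from the decay rather than
   from a full kinetic-competition (Motulsky–Mahan) model, which is out of
   scope.
2. **Simulation side.** Biased (well-tempered metadynamics-style)
   dissociation trajectories yield one physical unbinding time each via the
   hyperdynamics rescaling t_phys = Σ Δt_i·exp(V(s_i,t_i)/kT). Assuming
   unbinding is a memoryless single-barrier event, the times are exponential
   with mean τ; the MLE is the sample mean and t_1/2 = τ·ln2. The assumption
   is *tested*, not presumed: a one-sample KS statistic against
   1 − e^(−t/τ̂) is calibrated by parametric bootstrap (redraw n times from
   Exp(τ̂), refit τ, recompute the statistic), which accounts for τ being
   estimated from the same sample — the plain asymptotic KS p-value would be
   systematically inflated (Lilliefors effect).

Free-energy profiles along contact-number coordinates connect the two sides
mechanistically: more persistent contacts at the bound minimum mean a deeper
well and a slower exit.

## Assay fitting choices

- **Weighting.** Counting noise in these assays scales with the signal
  (approximately constant coefficient of variation). The default is
  therefore a two-pass relative-weighted least squares: an unweighted pass
  for a consistent point estimate, then a refit with σ_i proportional to the
  first-pass model values. With unweighted least squares the asymptotic
  standard errors on k_off are anti-conservative (Monte-Carlo coverage of
  nominal 95 % intervals ≈ 88 % at 5 % CV noise); relative weighting
  restores 94–96 % coverage. `weighted=None` gives plain unweighted fits.
- **Confidence intervals** use Student-t quantiles with n − p degrees of
  freedom on the asymptotic covariance; t_1/2 errors propagate from k_off by
  the delta method (dt = ln2/k² dk).
- **Dissociation plateau.** The decay model includes a fitted floor
  (nonspecific binding); a fit is flagged failed when the decay is not
  significant (k_off CI touching 0, or span negligible against the signal).
- **k_on** comes from a single-concentration k_obs with an independently
  fitted k_off: k_on = (k_obs − k_off)/[L]. k_obs < k_off is unphysical and
  reported as a clamped failure state rather than a negative rate.
- **Cheng–Prusoff** requires the radioligand concentration L and its
  independently measured K_d; K_i ≤ IC50 always, and K_i is strictly
  decreasing in L at fixed IC50 (property-tested).

## Synthetic generators (what they emulate, what they do not)

The generators define the test conditions for every stage:

- **Assay tables**: exact closed-form curves plus multiplicative Gaussian
  noise with fixed CV, floored at 0 cpm. Grids: 16 points over 3
  characteristic times (kinetic modes), 16 log-spaced concentrations over
  K_d/10–10·K_d (saturation) or IC50/300–300·IC50 (competition); B_max
  5000 cpm. Real assays add plate effects, pipetting error and correlated
  replicates — none modeled, so passing recovery tests demonstrates
  estimator correctness and calibration under the stated noise model, not
  robustness to systematic experimental error.
- **Unbinding times**: i.i.d. exponential, n = 15 by default — the study
  condition for a metadynamics campaign. Real rescaled times also carry
  bias-convergence error that the exponential model does not represent;
  the KS reliability test is the package's guard for that in real use.
- **Langevin + well-tempered metadynamics** (1-D): BAOAB discretization
  (stable and accurate for configurational sampling at modest timesteps),
  default double well V(s) = h((s/a)² − 1)² with h = 6 kcal/mol, a = 1 —
  analytic minima and barrier give exact oracles. Defaults: T = 300 K,
  friction 1 ps⁻¹, mass 1, timestep 0.01 ps, hills of 0.5 kcal/mol ×
  σ = 0.2 every 500 steps, bias factor γ = 8, bias kept on a 1024-point grid
  over [−4, 4] with linear interpolation. These are declared toy choices —
  ordinary well-tempered settings scaled to a 1-D barrier of ~10 kT — not
  values inferred from any production protocol. Divergence (|s| → ∞/NaN)
  raises immediately, flagging an unstable timestep.
- **Toy complexes**: pocket residues are anchored 3.5 Å from the ligand
  center with one atom pointing inward, so every SP residue is in contact in
  every bound frame (frequency exactly 1) and distal residues never are
  (frequency 0); the escaping model translates the ligand 30 Å away; the
  two-pose model separates poses by a 5 Å ligand RMSD. Contact ground truth
  is therefore known by construction, with no reliance on sampling.

## Reweighting estimators

Two weight schemes, both recovery-tested against the analytic potential:

- **final_bias** (default): w_i ∝ exp(V_final(s_i)/kT), where V_final is the
  bias at the end of the run evaluated at each frame's CV. Robust once the
  well-tempered bias has nearly converged; the toy simulator writes this
  column (and c(t)) directly into its COLVAR output.
- **time_dependent**: w_i ∝ exp((V(s_i,t_i) − c(t_i))/kT) with the standard
  well-tempered offset c(t) = kT·ln(Σ e^{βγV/(γ−1)} / Σ e^{βV/(γ−1)})
  evaluated on the bias grid at each deposition. If c(t) is absent from an
  external file, the bias column is assumed to be already offset-corrected
  (PLUMED's rbias) and a warning is emitted.

PMFs discard the first 20 % of frames as burn-in when computed by the
pipeline; accuracy is quoted as RMS deviation from the analytic potential
over bins with at least 50 raw frames (≈0.3 kcal/mol at 10⁶ steps, i.e.
half of kT). Weights are shift-invariant in the bias and guarded against
overflow by max-subtraction; time rescaling is evaluated entirely in log
space, so arbitrarily large accelerations cannot overflow intermediate sums.
Empty PMF bins are undefined (NaN), never zero; the minimum-location
tie-break prefers the larger contact number (the more-bound state).
Per-bin errors are the SE across independent blocks/trajectories, each block
min-shifted before comparison.

## Contact machinery

- Contact: ligand-heavy × receptor-heavy pair at distance ≤ 4.5 Å, boundary
  inclusive ("not exceeding"); hydrogens and solvent excluded. Counts are
  verified against a brute-force double loop on random geometries.
- Per-residue frequency is binary per frame (≥1 atomic contact), pooled
  frame-weighted across trajectories (identical to concatenation); the
  persistence filter keeps residues at frequency ≥ 0.5 exactly.
- No periodic-boundary imaging is performed; a guard warns when the
  receptor–ligand separation exceeds half the box if box metadata exists.
- π-hole detection is purely geometric (nitro N···O distance, default
  3.5 Å — a declared choice, comparable to heavy-atom hydrogen-bond
  cutoffs); a nitro-less ligand returns an explicit absent-with-reason
  result. Salt bridges use the min over carboxylate oxygens; hydrogen bonds
  use distance plus the D–H···A angle when the hydrogen exists, distance
  only otherwise.
- Pose clustering is greedy leader clustering on ligand heavy-atom RMSD
  after backbone Kabsch alignment to the window's first frame. The
  algorithm is order-dependent by construction; tests bound the sensitivity
  by shuffling frames on designed two-pose systems. Representative = medoid
  of the largest cluster. Kabsch uses SVD with a determinant correction
  (proper rotations only) and rejects collinear selections; it is verified
  against an independent quaternion (Horn) oracle.
- Ballesteros–Weinstein labels and subpocket membership (SP1/SP2/SP3) are
  supplied as configuration tables — no automatic GPCR numbering. Shipped
  toy defaults use SP2 ⊇ {1.39, 2.61, 2.64, 7.35, 7.38} and SP3 ⊇ {5.39,
  5.42, 5.43, 6.51, 6.52, 6.55, 6.56}, configurable and not asserted
  complete.

## Pipeline and determinism

Every stage seed derives from the config seed via a CRC-based `subseed`
(stable across runs and platforms, < 2³¹). Stage failures are collected into
the per-compound report instead of aborting the run; reports are written
with sorted keys so identical configs produce byte-identical JSON.

## Numerical notes and limitations

- Exponential MLE at n = 15 is unbiased for τ but individual estimates
  scatter by ±25 % (Gamma(15) relative SD); rank-order conclusions across
  compounds whose τ differ by ~70× are nonetheless stable (>99.9 % joint
  recovery).
- The bootstrap SE on t_1/2 is a pragmatic choice; at n = 15 the percentile
  CI is asymmetric and should be preferred over ±SE.
- The toy simulator is 1-D and overdamped-ish; it validates estimators, not
  force fields or sampling of real receptor–ligand systems. PMF minima at
  specific experimental contact numbers, per-residue frequencies of real
  trajectories, and cryo-EM distances require the corresponding external
  structure/trajectory inputs, which the code reads through the standard
  formats (PDB, DCD/XTC, COLVAR tables).
- Unbound-event defaults (z > 10 Å, contacts = 0 optional, dwell 10 frames)
  are configuration-exposed; trajectories without an event are excluded
  (right-censoring is not modeled).
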
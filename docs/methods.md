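# Methods

## The anchor-point generative model

The generator treats the 36-residue H3 tail as a chain of residues, each with
a microscopic DNA site-binding strength: arginine 1.0, lysine 0.7, all other
residues 0.1 (dimensionless, in [0, 1]). Because a bound residue restrains
its neighbours, the raw strengths are smoothed with a triangular window of
half-width 2 residues (weights 3:2:1, renormalized at the chain ends), giving
the latent per-residue strength profile S_r. Slow local motion follows strong
local binding, so the three observables are affine in S_r:

    hnNOE_r = a0 + a1·S_r,   R1_r = b0 + b1·S_r (b1 < 0),   R2_r = c0 + c1·S_r.

**Mutations.** Neutralizing an arginine at position p subtracts a kernel
A·w_p·K_p(r) from S_r, where K_p decays as exp(−d/λ_N) toward the N-terminus
(λ_N = 3 residues) and exp(−d/λ_C) toward the C-terminus (λ_C = 6 residues),
encoding the observed C-terminal bias of mutational effects. Kernels from
multiple mutations subtract additively, so quadruple-mutant truth deltas are
*exactly* the sum of the four single-mutant deltas — the additivity test's
null model is built in. The per-site weights w_p (R2: 0.50, R8: 0.95,
R17: 0.90, R26: 2.00) encode that R26 abuts the already-mobile hinge and
unzips the widest region while R2 sits at the free N-terminus; they were set
so the truth-level summed-ΔhnNOE ranking (R26Q ≫ R8Q > R17Q > R2Q) and the
breadth ordering (R26Q broadest, R2Q narrowest) hold with margin.

**Salt.** Added monovalent salt screens all tail–DNA contacts; S_r is
multiplied by f_salt (1.0 at 0 mM KCl, 0.65 at 150 mM). Lower f_salt lowers
hnNOE and R2 and raises R1 everywhere — the global mobilization seen at
physiological salt.

**Calibration.** The defaults are solved in closed form from experimental
anchors rather than hand-tuned: a0, a1 from the WT/0 mM tail-average hnNOE
(0.34 over T3–K36) and hinge average (0.16 over S28–K36); the perturbation
scale A from the quadruple-mutant tail-average hnNOE (0.24); b0, c0 from the
WT averages R1 = 1.07 s⁻¹ and R2 = 22 s⁻¹. The R1/R2 *slopes* are calibrated
from the WT per-residue scatter (SD 0.09 s⁻¹ and 8 s⁻¹ respectively), not
from the quadruple-mutant rate averages: with a single latent profile and
affine maps, slopes steep enough to reproduce the mutant rate shifts
(+17% R1, −54% R2) would drive R2 negative in the hinge. We chose spatial
realism and positivity; the synthetic quadruple mutant consequently shifts
R1/R2 less than the experiment does, while its hnNOE shift is on target.
This is the model's main known distortion.

**Noise and bookkeeping.** Measurements add Gaussian noise with SD equal to
a fixed fraction (default 0.02) of the residue's reference intensity,
mirroring a single per-spectrum noise figure; reference intensities are
drawn lognormally (15% spread) around 1000 units. The generator reproduces
the acquisition design: the R1 schedule {0.033, 0.195, 0.390×2, 0.813×2,
1.301, 1.951} s, the R2 CPMG schedule {0.0088, 0.031×2, 0.053, 0.079,
0.110×2, 0.150} s (a shorter variant for WT at 150 mM), doublet peaks at
0 mM KCl (per-construct sets; 55/45 intensity split, fixed small shift
splitting) that merge at 150 mM, and the per-construct omission lists (A1
and prolines never visible; R2 and sample-dependent L20 unanalyzable; K36
dropped at 150 mM).

**What the generator does not emulate.** Overall-tumbling contributions to
R2/R1 near the histone core, exchange (µs–ms) contributions to R2 at the
500 Hz CPMG field, peak overlap and lineshape convolution, assignment
ambiguity, and NCP-asymmetry physics behind the doublets (doublets are a
configured label set). Passing tests therefore validate the *analysis*
pipeline and the qualitative anchor-point phenomenology, not spectral
realism.

## Analysis choices

- **Exponential fits** are unweighted least squares of I(t) = I₀e^(−Rt)
  (no offset), started from the log-linear closed form on positive
  intensities; negative intensities are excluded from initialization only.
  Errors come from the covariance matrix scaled by residual variance with an
  n−2 denominator (the spectral-noise-based alternative is switchable).
  With 8-point schedules this gives ~65% one-sigma coverage (the small-n
  Student-t effect), within the accepted 0.58–0.78 band. Fit failures flag
  the residue (`not fit`) instead of aborting the profile.
- **Jackknife errors** (leave-one-point-out, √(((n−1)/n)·Σ(Rᵢ−R̄)²)) are
  provided as a robustness cross-check and agree with covariance errors
  within a factor of ~2 at 2% noise.
- **Doublets** are fit independently per peak; the pairing rules (both peaks
  against a lone singlet, otherwise by peak id) are shared between CSPs and
  Δ profiles. Where one number per residue is needed (region averages,
  summed Δ, additivity) a doublet contributes the mean of its peaks; for
  region qualification a residue qualifies if *any* pairing qualifies.
- **Region detection** operationalizes "≥3 residues with non-overlapping
  error bars, single-residue interruptions allowed" as: a residue qualifies
  when |Δ| strictly exceeds k = 1 times the combined error; runs break at two
  consecutive observed non-qualifying residues; endpoints must qualify;
  invisible residues are spanned (and counted — printed range counts are
  inclusive, so T22–V35 is 14 residues including P30). Two combined-error
  conventions are exposed: quadrature (default, the statistical convention)
  and the sum of half-widths, which is what visually non-overlapping error
  bars mean and which suppresses the ~32%-per-residue false-qualification
  rate of the 1-sigma quadrature rule. Fidelity analyses of breadth use the
  latter. The implementation is verified against an exhaustive
  span-enumeration oracle.
- **Additivity** compares Σ(single Δ) with the quadruple Δ. Because the one
  WT dataset enters every Δ, naive per-profile quadrature misstates the
  discrepancy error; we propagate exactly (D = 3·WT − Σmutᵢ + quad, so
  σ_D = √(9σ_WT² + Σσᵢ² + σ_q²)). A residue is labelled *consistent with
  additivity* when the error bars of the two compared curves overlap
  (|D| < σ_Σ + σ_Δq, each propagated with its own WT multiplicity), the
  criterion a reader applies to the plotted comparison.
- **Sums over residues** (summed Δ, additivity) run over the intersection of
  residues observed in all profiles involved; missing residues contribute
  nothing and never qualify for regions, but do not break runs.

## Problem sizes and determinism

Monte-Carlo checks use 500 replicate fits (bias, coverage), 10⁵ draws for
brute-force error propagation, 50 seeded study replicates for ranking and
breadth stability, and 10 for the noisy additivity fraction — sizes at which
the binomial wobble of the checked proportions is small compared to their
margins. All randomness flows through named integer seeds (numpy
`SeedSequence` streams keyed by construct, salt, and experiment), so any
table, profile, or report is byte-reproducible from its manifest.

## Known limitations

Beyond the generator caveats above: the affine observable maps are the
simplest monotone link, with no spectral-density (Lipari–Szabo) realism, so
absolute R1/R2 values off the calibration anchors should not be
over-interpreted; mutant R1/R2 shifts are muted (see Calibration); the
overlap criterion the original visual analysis used is not recoverable, so
both conventions are kept and reported explicitly; and CSP magnitudes for
mutated sites themselves reflect the residue-type change and are flagged,
not interpreted.
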
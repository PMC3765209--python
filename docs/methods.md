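# Methods

## Problem

Given a family of *nested* kinetic models — every candidate a special case of
one parameterised superstructure — and noisy time-course data, `kdpselect`
selects the best-supported structure and estimates its rate constants in a
single step.  The decision vector mixes continuous rate constants **p** and
integer/binary structure switches **q**; the objective is the Akaike
information criterion

    AIC = −2·Jml(p, q) + 2·Np(q),

where `Jml` is the Gaussian log-likelihood of the data under known
heteroscedastic standard deviations,

    Jml = Σ ln(1/√(2πσ²ᵢⱼₖ)) − ½ Σ ((ỹᵢⱼₖ − yᵢⱼₖ)/σᵢⱼₖ)²,

summed over experiments i, measured variables j and sampling times k, and
`Np` is the number of decision variables active in the candidate structure.
Minimising AIC over (p, q) is a mixed-integer nonlinear program (MINLP)
subject to the model DAEs; no convexity or relaxability is assumed, and the
objective is evaluated only at integer points of q.

By default `Np` counts the active continuous parameters **plus** the active
integer exponents and the three binaries, since all are decision variables
of the MINLP and structural complexity should be penalised; a reals-only
convention is available (`count_active_parameters(..., include_integers=False)`).

## The KdpD/KdpE superstructure

The bundled case study is the two-component system controlling the kdpFABC
K⁺-uptake operon of *E. coli*: sensor kinase KdpD phosphorylates response
regulator KdpE; phosphorylated KdpE (KdpEᴾ) dimerises on the promoter and
activates transcription.  After model reduction (the phosphorylated-sensor
pool is small and fast, so KdpDᴾ is held constant and its balance equation
dropped), the core model has 5 ODE states — mRNA, total sensor KdpD₀, total
regulator KdpE₀, phosphorylated regulator KdpEᴾ, transporter complex
KdpFABC (written F below) — plus 2 algebraic promoter-binding constraints
determining free regulator KdpEfᴾ and free promoter DNAf:

    dmRNA/dt   = ktr·(DNAf/K)·(1 + KdpEfᴾ²/(α·Ka))/DNA₀ − (kz+μ)·mRNA
    dKdpD₀/dt  = ktl·mRNA − (kd+μ)·KdpD₀
    dKdpE₀/dt  = ktl2·mRNA − (kd+μ)·KdpE₀
    dKdpEᴾ/dt  = k2·KdpDᴾ·(KdpE₀−KdpEᴾ) − (kd + k3f + k₋₂·KdpD)·KdpEᴾ
    dF/dt      = ktl3·mRNA·R1 − (kd2·R2 + μ)·F

    0 = KdpEᴾ − KdpEfᴾ − 2·(KdpEfᴾ²·DNAf/Ka)·(1 + 1/(α·K))
    0 = DNA₀ − DNAf·(1 + 1/K) − (KdpEfᴾ²·DNAf/Ka)·(1 + 1/(α·K))

Transcription is proportional to the fraction of promoter in its two
transcribing states (RNAP-bound free DNA, weight DNAf/K, and the
KdpEfᴾ₂-activated ternary complex, weight DNAf·KdpEfᴾ²/(Ka·α·K)).  The
algebraic pair is solved by eliminating DNAf (linear) and applying
safeguarded Newton to the remaining cubic in KdpEfᴾ on [0, KdpEᴾ]; the
returned root satisfies both residuals to 1e-10 relative (cross-checked
against an independent bisection oracle in the tests).

Three hypothesised feedback mechanisms extend the core model and are
switched by binaries, with Hill-type integer exponents n ∈ [0, 3]
(x⁰ ≡ 1 everywhere, including x = 0):

* **Regulation of translation** (bin1, n1): R1 = 1/(Fⁿ¹ + ktrans), else 1.
* **Regulation of proteolysis** (bin2, n2, n3): R2 = Fⁿ²/(Fⁿ³ + kdeg), else 1.
* **Stimulus counteraction** (bin3, n4, n5): the KdpEᴾ dephosphorylation
  rate is k3f = k3·S + khy·Fⁿ⁴ (bin3 = 0) or k3·S + khy·Fⁿ⁴/(Fⁿ⁵ + Khy)
  (bin3 = 1) for the wild strain; the uptake-defective mutant lacks the
  feedback entirely, k3f = k3·S.  Mutant dynamics are therefore invariant
  to bin3, n4, n5, khy and Khy (a tested exact invariant).

Identifying structures that differ only in inactive switches, the exponent
range 0–3 yields 5 × 17 × 20 = 1700 distinct nested models; the full
superstructure has 25 decision variables (17 reals, 5 integers, 3 binaries).

### Stimulus and fixed constants

The stimulus is the ratio S = K⁺/K0 with reference K0 = 1e-3 mM; K⁺-replete
growth (large S) speeds KdpEᴾ dephosphorylation and shuts the operon down,
K⁺ downshift induces it.  The ratio form, rather than a saturating
K⁺/(K⁺+K0), is a deliberate design choice: with the Table-value feedback
constant khy = 2e6 and the transporter operating range F ≈ 1.4–4 implied by
the nominal loop constants (the crossover scales ktrans^(1/3) ≈ 1 and
kdeg^(1/2) ≈ 0.37 only influence the dynamics if F passes through them), the
counteraction term khy·Fⁿ⁴ is of order 10⁶–10⁸ and a stimulus bounded by 1
could never be commensurate with it — the wild strain would show no K⁺
response at all.

Constants that are fixed rather than estimated: growth/dilution rate
μ = 0.5 h⁻¹; reverse phosphotransfer k₋₂ = 1.0 (its term k₋₂·KdpD·KdpEᴾ is
deliberately small relative to k3·S, making k₋₂ the least sensitive
parameter); constant phosphorylated-sensor level KdpDᴾ = 1e-6 (chosen, via
a one-time design scan, so that both strains show graded K⁺-dependent
induction: ≈17-fold in the mutant and ≈1.3-fold in the wild strain between
1 and 500 mM — the counteraction loop actively flattens the wild response).
Concentrations are in the model's internal concentration unit, time in hours.

### Simulation

Initial conditions are the pre-stimulus steady state at K⁺ = 1000 mM
(K⁺-replete growth), computed by relaxing the ODEs from an analytic basal
seed and polishing with a damped Newton solve until the maximum relative
derivative is below 1e-8 (1e-6 is accepted when roundoff on near-zero
states dominates); explicit initial vectors may be supplied instead.
Integration uses LSODA with rtol 1e-8 / atol 1e-12 and a compiled
finite-difference Jacobian; states are clipped at zero inside the
right-hand side so that integer power laws never see negative excursions.
Each integration carries a hard budget of 1e5 right-hand-side evaluations;
pathological parameter corners that exceed it are reported as flagged
failures, which the optimizer penalises (base 1e10) rather than crashes on.
Feasible objective values are capped at 1e9 in the search ordering so every
feasible point compares strictly better than every failure.

## Synthetic data (study conditions)

The generator reproduces the in-silico protocol: 2 strains (wild, mutant) ×
5 extracellular K⁺ levels (1, 10, 50, 100, 500 mM), observing only mRNA and
KdpFABC on 15 equispaced times over the first hour after downshift, from
the nominal parameters (Table values) under the nominal structure
bin = (1, 1, 0), n = (3, 1, 2, 3, 0).  Each observation is perturbed
multiplicatively, ỹ = y·(1 + 0.05·ε) with ε ~ N(0,1), and stored with
σ = 0.05·|y| (floored away from zero); negative draws are kept as drawn.
Everything is deterministic given the seed.

What the generator does *not* emulate: biological replicate variability,
systematic (non-Gaussian, correlated) measurement error, sampling jitter,
or any property of the original wet-lab in vitro/in vivo measurements.
Passing recovery tests therefore demonstrate the *method* (the MINLP search
finds the generating structure and parameters under the stated noise), not
the fidelity of the model to real KdpD/KdpE data.

## Search

`scatter_search` maintains a reference set of 10 members (half best quality,
half maximum-minimum-distance diversity) seeded from a Latin-hypercube /
uniform-integer diversification sample (default 10 × dimension), stratified
over the on/off combinations of the binary switches.  An opening *stratum
tournament* gives each binary combination short refinements of its best
diversification members from fresh space-filling starts, so that no switch
combination is discarded on unpolished objective values — essential here,
because the AIC margins between competing structures are tens of units at
most while unpolished values differ by orders of magnitude.  All reference
pairs are then combined by path-relinking moves sampled inside, beyond and
short of the connecting segment; integer coordinates are rounded
half-away-from-zero after every combination.  Deep refinement rotates over
the champions of the leading binary patterns, so the final verdict compares
structures that received comparable optimisation effort.

`local_refine` performs bounded descent on the reals with integers fixed —
trust-region nonlinear least squares on the weighted residuals when the
objective exposes them (with an explicit finite-difference step of 1e-5,
since the default square-root-of-eps step probes log-space coordinates
below the integration noise floor), bounded Powell search otherwise — then
sweeps the integer neighbourhood: unit moves, or the objective's own
model-aware compound moves (`CaseStudyProblem.integer_neighbors` proposes
switching a loop on jointly with every admissible value of the exponents it
activates, since a flip with stale dormant values never looks attractive).
The most promising neighbours earn a short real-polish before the verdict.
Remaining budget goes to perturbation restarts (basin hops): jitter the
reals around the incumbent and re-descend, which reliably escapes the poor
local minima that trap a single descent.  Every refinement holds a hard
local evaluation cap, enforced in the evaluation wrapper itself rather than
through optimizer iteration limits.  Stagnation refreshes the diversity
half of the reference set.  The evaluation budget is a hard cap, all
randomness flows from one mandatory seed, and the best-so-far trace is
non-increasing by construction.

Continuous decisions are searched in log10 space; default bounds are the
nominal value ×/÷ 100 (Khy, which has no nominal value, gets [1e-2, 1e2]).
The multistart baseline draws uniform random feasible starts and applies
the same local refinement with a short budget — the classical protocol for
exposing multi-modality, and on this problem its final values stay far above
the scatter-search optimum.

## Identifiability

Relative sensitivities S = (pθ/y)·∂y/∂pθ are central finite differences
with relative step 1e-4 on the active parameters (entries with |y| < 1e-12
are zeroed and counted); step halving changes entries by < 1e-4, the
self-convergence check.  The msqr ranking index is the plain sum of squared
relative sensitivities (an RMS variant is available by flag).  The Fisher
information matrix is assembled from the same raw derivatives,
FIM = Σ (1/σᵢ²)(∂yᵢ/∂p)ᵀ(∂yᵢ/∂p).  Because the parameters span nine orders
of magnitude, rank and correlation are computed from the unit-diagonal
rescaled FIM (D·FIM·D with D = diag(FIM)^(-1/2)) — a transformation that
preserves the mathematical rank and leaves the correlation matrix exactly
unchanged while making the numerics meaningful.  Numerical rank uses an
explicit cutoff rtol·σmax (default rtol = 1e-12, always reported; the
smallest singular values of the case study sit around 1e-11 of the largest,
i.e. genuinely nonzero but reflecting the strong parameter correlations).
Correlations are the inverse scaled FIM rescaled to unit diagonal, defined
only at full rank — a rank-deficient FIM raises a non-identifiability error
instead.  The pseudo-global variant
repeats the local analysis at scrambled-Sobol' points in the (log-space)
search box and averages correlation matrices and msqr indices with weights
proportional to each point's likelihood (log-shifted before
exponentiation); failed simulations and rank-deficient points get zero
weight and are counted.  The signature default of 2¹⁰ Sobol' points follows
the reference protocol; the bundled pipeline and tests use far fewer, since
each point costs 2·(number of active parameters) + 1 full simulations.

## Scaled-down study protocol

`kdpselect.study.run_recovery_study` is the packaged protocol, used by the
command-line `fit`, the test suite and `scripts/acceptance.py`: three
independent scatter-search runs of 9000 evaluations each (reference-set 10,
diversification 100, per-refinement budget 1000, two tournament restarts
per binary stratum) on the loose-tolerance objective, then a 1200-evaluation
polish of the overall winner on the tight objective — instead of the
reference ten-run protocol.  The multi-modality probe is a 50-start
multistart with 60 evaluations per start.  These sizes are the package's
own single-CPU protocol; every reported number is computed at run time from
the seeded pipeline.

## What the in-silico data can and cannot identify

The likelihood surface of the study conditions has near-flat correlated
valleys, visible in the correlation analysis as several off-diagonal
entries close to ±1.  Three consequences, worth stating plainly:

* **ktr and K are nearly redundant.**  Transcription depends on them almost
  exclusively through the ratio ktr/K (the separate appearances of K in the
  promoter balance scale as 1/K ≈ 1e-3 at the nominal value), so the pair
  carries a correlation extremely close to −1.
* **ktl is structurally weakly identifiable.**  After the model reduction
  fixes KdpDᴾ, the total sensor pool KdpD₀ influences the observed states
  only through the reverse-phosphotransfer term k₋₂·KdpD·KdpEᴾ, which is
  orders of magnitude below the other KdpEᴾ turnover terms here; the data
  therefore barely constrain ktl (and, partially, kd).
* **Exponent variants are near-degenerate.**  Refitted structures with
  neighbouring Hill exponents (for example n1 = 2 instead of 3) reach AIC
  values within a few units of the generating structure, with ktrans, kdeg
  and ktl3 absorbing the difference.  Exact exponent recovery is at the
  information limit of 5% noise on this design.
* **Maximum-likelihood parameter estimates wander along the flat
  directions.**  A refinement started at the exact generating parameters
  improves the AIC by only ~4 units while moving several constants far
  from their generating values.  Recovered *structures* (which mechanisms
  are active) are therefore a much more robust output of the pipeline than
  recovered *parameter values*, and downstream use should lean on the
  former.  The binary switches bin1/bin2 carry margins of roughly 10–20
  AIC units in favour of the generating structure; bin3 is degenerate by
  construction.

## Known limitations

* Model-II calibration against the original (unpublished) wet-lab data is
  out of scope; all quantitative statements refer to the in-silico study.
* The two wild-strain counteraction forms are near-degenerate by
  construction (bin3 = 1 with n5 = 0 equals bin3 = 0 with khy scaled by
  1/(1+Khy)), so bin3 is not reliably recoverable and is not asserted.
* kdeg and the n3 exponent are weakly identifiable in the operating regime
  (Fⁿ³ ≫ kdeg over much of the trajectories); recovered values of kdeg can
  deviate substantially more than the well-identified parameters.
* Derivatives are finite differences, not forward sensitivity equations;
  the step is validated by halving but very flat responses can lose
  precision.
* AIC with known σ is the only selection metric implemented; pairwise
  metrics (likelihood-ratio, F-tests) do not apply to a 1700-member family.
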
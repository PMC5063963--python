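# Methods

## Deterministic steady-state model

Network activity `A ∈ [0, 1]` is the common occupancy of the
Gal4-regulated promoters. Assuming every regulated gene is expressed in
proportion to `b + (1 − b)·A` (basal fraction `b`), synthesis/dilution
balance gives the steady-state totals of active inducer and repressor:

    X(A) = λ · [a3·(b3 + (1−b3)A) + w1·a1·(b1 + (1−b1)A)] · h(s) / δ
    h(s) = s^m / (s^m + K_s^m)

with `λ` the global dosage multiplier, `w1 = 1/40` the relative inducer
strength of Gal1, and `h(s)` the galactose activation of the inducers
(Gal2-mediated import is folded into `K_s`; transporter abundance only
rescales the effective half-saturation at steady state). The repressor
total is `I(A) = λ·a80·(b80 + (1−b80)A)/δ` for the natural topology; for
the synthetic topology Gal80 is produced from the TET promoter driven by
rtTA (itself expressed from the Gal80 promoter at rate
`r(A) = λ·a_r·(b80 + (1−b80)A)/δ`):

    I(A) = λ · [t_basal + (t_max − t_basal)·(r·dox)^q/((r·dox)^q + K_T^q)] / δ

with `q = 2` for the two rtTA operators. Free repressor after 1-to-1
sequestration is the exact two-species equilibrium (quadratic root,
evaluated in a cancellation-safe form), and the implied activity is the
decreasing Hill function `1/(1 + (I_f/K_act)^p)`. Fixed points of this
one-dimensional self-consistency map are found by a dense sign-change
scan (10,001 points) refined by bisection to `1e−10`, classified stable
or unstable by the map's finite-difference slope; the 1-D grid+bisection
approach was preferred to continuation for robustness. Gal4 and Gal2 do
not appear as dynamical variables: Gal4 is constitutive and enters only
through constants, which is exactly why compensation needs only the
inducer/repressor pair to scale with dosage.

In the strong-binding, inducer-excess regime (`Kd → 0`, `X > I`) the free
repressor reduces to `Kd·I/(X − I)`, a ratio from which `λ` cancels: the
natural ON branch is dosage invariant. The synthetic link breaks the
cancellation whenever the TET output actually depends on rtTA; making the
TET output rtTA-independent (`t_basal = t_max`) restores invariance. The
numerical invariance threshold is `1e−6` (far above fixed-point
refinement error) and the abolishment threshold `0.05` (far below the
observed effect, which reaches ~0.97 when dosage scaling moves the
bistable onset past a grid dose). Perturbations are applied to synthesis
rates only; `δ` is shared and unscaled.

Default parameters were chosen once so that the model is bistable over
roughly 0.05–0.5% galactose with a tight OFF state (`A ≈ 0.001`) and a
nearly saturated ON state, with Gal80's basal expression (`b80 = 0.5`)
well above the inducers' (`b3 = 0.05`) so that the uninduced state holds
repressor in excess.

## Stochastic simulation engine

The kernel is a direct-method SSA over integer molecule counts and
per-locus promoter-copy states, with three volume/cycle features:

* **Volume-aware propensities.** Each reaction has a mass-action base
  form (constant, unimolecular, bimolecular, or per-ON/OFF/total gene
  copy), a volume exponent (bimolecular reactions scale as `1/V`), and an
  optional Hill modifier in a regulator species' *concentration*
  (positive or negative Hill exponent for activation or repression).
* **Cell cycle.** Volume grows exponentially (or linearly) from the birth
  volume, doubling over one cycle. Every gene locus doubles its copy
  count at the S-phase point and the ON-copy states are inherited by the
  duplicated copies; at division the followed daughter keeps half the
  volume, a hypergeometric share of ON copies, and a binomial(1/2) share
  of every molecular species (asymmetric division is available through a
  configurable daughter fraction). Individual cycle lengths are
  log-normal with CV 0.2 and the S-phase point is jittered by ±0.15 of
  the cycle, desynchronizing the gene-dosage state from cell size: at
  harvest the population carries genuine copy-number heterogeneity
  rather than a purely periodic, size-predictable signal. Yeast cycle
  variability of this order is well documented; setting both knobs to
  zero recovers a strictly periodic cycle.
* **Waiting-time cap.** Volume is held constant between firings and the
  sampled waiting time is truncated at `doubling_time/200` (the cell
  advances without firing). By the memorylessness of the exponential this
  is statistically identical to including a null "clock" reaction; it
  bounds the volume staleness per step below ~0.35% and vanishes exactly
  when growth is disabled, where the kernel reduces to a textbook SSA
  (validated against Poisson and telegraph-model closed forms and against
  an independently coded direct-method SSA).

Populations are simulated as independent single-cell lineages (one
daughter followed per division), approximating a snapshot of a constant
population without tree-pruning decisions. Cells start at uniformly
random cycle phase with growth-law-consistent volume. Induction runs
start after a 600-minute zero-inducer burn-in of the same network, so the
t = 0 state carries the quenched cell-to-cell heterogeneity of a
pre-growth culture rather than identical initial counts; inductions last
1,320 minutes (22 h), matching the experimental protocol.

An optional per-lineage extrinsic channel scales flagged reactions by a
log-normal Ornstein–Uhlenbeck factor. In the shipped networks this
channel is attached to the inducer-activation reactions (σ = 0.5,
correlation time 2,000 min, i.e. quasi-static per lineage), modelling
stable cell-to-cell differences in galactose uptake and signalling
capacity; it spreads the per-cell induction threshold and thereby grades
the population dose response, without adding a direct common-mode term to
the reporter. A global synthesis-capacity interpretation of the same
channel is available by flagging synthesis reactions instead. We note an
instructive negative result found during development: a global
multiplicative capacity factor applied to *all* synthesis rates makes the
*non*-compensated topology quieter in reporter output, because the
repressor arm's response partially cancels the factor's direct effect on
reporter synthesis, whereas the compensated topology transmits the factor
with unit exponent while holding activity fixed. The topology comparison
below therefore rests on dosage heterogeneity generated by the cell cycle
and on the rtTA/P_TET transmission properties, not on an injected global
capacity noise.

## Concrete networks and calibrated defaults

The GAL networks track Gal4, Gal3/Gal3*, Gal1/Gal1*, Gal2, Gal80, the two
inducer–repressor complexes, YFP, and (synthetic only) rtTA, with one
locus per gene. Promoter switching is double-regulated by free Gal80:
since Gal4 is constitutive, the free-Gal4 level available for activation
tracks the free-Gal80 concentration, so the ON rate falls and the OFF
rate rises with free Gal80 (Hill coefficient 2, shared half-repression
constant `K80`), each with a small regulator-independent floor. This
gives the wide, clean ON/OFF separation of the GAL switch with one
parameter class for "promoter transitions". Protein synthesis is a single
effective per-copy step (the mRNA layer is folded into the rate, since
promoter transitions — not mRNA lifetimes — are the identifiable noise
source in endpoint histograms; the engine itself supports explicit
mRNA/translation networks, as the validation tests do). Internal
galactose is the external dose times a saturating function of Gal2
concentration; activation/deactivation of Gal3 (and Gal1 at `w1 = 1/40`)
is slow (minutes-scale) and sequestration strong
(`Kd ≈ 10^-3` molecules/fl).

Because the supplementary parameter tables of the original study are not
redistributable here, kinetic defaults were calibrated once, against the
deterministic model plus small pilot simulations, to reproduce the
documented qualitative regimes — a tight uninduced state, bimodal
induction over 0–0.5% galactose with the ON fraction rising through
~0.075%, an ON-mode mean that still increases with dose (partial
repression), natural-topology dosage compensation, and its loss in the
synthetic topology — and then frozen. Parameter classes carry provenance
tags mirroring the staged-fit roles (literature-style scale constants;
stage-1 promoter/action constants; stage-2 rtTA/P_TET constants plus the
fluorescence scale). The synthetic topology's TET promoter switches
slowly (`k_on 0.15/min`, `k_off 0.3/min`), delivering Gal80 in bursts of
~4 molecules; its doxycycline default (1.8) matches the synthetic
network's activity to the natural network's in the low-dose
(linear-response) region, after which the synthetic dose curve rises more
shallowly — the non-compensated network both lags and carries
repressor-delivery noise, which is what elevates its ON-cell CV across
the analysed dose range. In the β-estradiol cascade control the same
rtTA·dox → P_TET link architecture is used, but with the cascade's own
strong-promoter switching class for P_TET and rtTA expressed at the full
P_LexA output rate (the constructs are chromosomally distinct from the
GAL-context P_TET-GAL80 integration, whose switching constants are
stage-2 fit properties of that strain); at `dox = 1.2` the linked and
unlinked cascades have matched mean output and statistically
indistinguishable CV.

Cell-cycle defaults: 100-minute doubling, 30 fl haploid birth volume
(doubled in diploids), S phase at 0.4 of the cycle. Fluorescence is
`20 a.u. per YFP molecule` plus a log-normal autofluorescence floor
(median 300 a.u.); forward/side scatter are synthesized from the
simulated volume with 10% multiplicative noise so scatter gating selects
on cell size.

## Cytometry analysis

The small scatter gate keeps the 20% of cells closest to the scatter
medians (MAD-scaled rectangle, matched to the target within one cell);
the middle-third gate keeps cells inside the central third of each
scatter axis's range. The ON/OFF cutoff is the 0.995 quantile of the
gated uninduced (zero-galactose) distribution — the source of the cutoff
follows the experimental protocol, the specific quantile is a package
choice and is configurable. Fraction ON, mean and CV (unbiased SD over
ON cells only) follow; doses below 0.075% galactose are flagged excluded
from noise analysis, and CV estimates from fewer than 50 ON cells are
flagged unreliable rather than dropped. CSV is the interchange format
(diffable and language-portable), with provenance headers.

## Staged fitting

The objective is the sum over induction conditions of the Jensen–Shannon
divergence (natural log; bounded by ln 2) between observed and simulated
histograms on 64 shared log-fluorescence bins spanning the dimmest cell
to the pooled 99.9th percentile. Optimization is Latin-hypercube
multi-start plus Nelder–Mead in log-parameter space, with common random
numbers: every candidate is simulated with the same per-condition seeds,
making the objective a deterministic function of the parameters. Stage 1
(haploid natural) may free only promoter-transition and action-scale
constants plus the fluorescence scale; stage 2 (haploid synthetic)
inherits the stage-1 result and may free only rtTA/P_TET constants plus
the fluorescence scale, and refuses to run without a stage-1 result;
diploid prediction uses no free parameters at all — volume and all gene
copies are doubled and 22 h inductions are simulated directly. The
objective and optimizer are package choices; only the free-parameter
ledger per stage is constrained by the staged protocol.

## Synthetic fixtures

`synthdata` draws log-normal mixtures: an autofluorescent OFF mode, an ON
mode whose fraction follows a Hill curve in galactose and whose log-mean
carries a latent per-cell size factor (the extrinsic component, shared
with the scatter channels) plus an intrinsic private term. Two presets
differ only in the extrinsic spread ("compensated-like" 0.12,
"noncompensated-like" 0.30), reproducing the qualitative CV ordering
through the full pipeline. Fixtures are for analysis-stage testing: they
have exact, analytically checkable ground truth but no time dynamics or
cell cycle — passing fixture tests validates the measurement pipeline,
not the simulator, and conversely.

## Problem sizes and reproducibility

The acceptance driver uses reduced but representative sizes chosen as a
compromise between statistical power and desk-scale runtime: 10,000 cells
for kernel validation against closed forms, 1,500 cells per condition
(4,000 uninduced) for the noise comparison at five analysed doses, 700
cells per condition over seven doses for the dosage-compensation curves,
2,000 cells per cascade arm, and a two-parameter self-fit with ~50
objective evaluations at 250 cells per condition. All randomness derives
from the single `--seed` via seed sequences; repeated runs are identical.

## Known limitations

* The kinetic defaults are a calibrated parameterization, not the
  original study's fitted values; quantitative CV magnitudes should be
  read as qualitative reproductions.
* Promoter ON/OFF state inheritance at replication (duplicated copies
  inherit the mother copy's state) and instantaneous S phase are
  modelling guesses; both are localized in the kernel.
* Single-lineage bookkeeping ignores mother–daughter age structure and
  any growth-rate coupling to galactose metabolism.
* The FCS binary format is not read; samples are CSV (or constructed
  in memory from simulations).
* The statistical margin of the noise-ordering comparison is a few
  hundredths of a CV unit per dose at the default sizes; substantially
  smaller cell counts will not resolve it.
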
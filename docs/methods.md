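# Methods

## Physical model

`fdflim` analyses frequency-domain (homodyne) FLIM acquisitions. The
excitation laser intensity is modulated at f = 10 MHz; a fluorophore with
mono-exponential lifetime τ re-emits at the same frequency with phase delay
φ = arctan(ωτ) and modulation depth m = 1/√(1+(ωτ)²), ω = 2πf. The camera
records K = 16 frames at equally spaced detector phase offsets
θ_k = 2πk/K; frame k of a pixel with DC level I₀ has expectation

    I_k = I₀ · (1 + m_tot · cos(θ_k − φ_tot)),

where (φ_tot, m_tot) combine the decay phasor with the instrument's phase
offset φ_inst and modulation gain m_inst. The single-frequency DFT estimator
(C = (2/K)ΣI_k cosθ_k, S = (2/K)ΣI_k sinθ_k) is exact on noiseless
sinusoids for any K ≥ 3 with uniform spacing, which is why uniform spacing
is assumed: the published acquisition states 16 frames but not their
spacing, and uniform stepping is the standard homodyne scheme. The camera's
two-charge-bin tap architecture is abstracted away; each stored frame is the
homodyne intensity at its phase offset.

Calibration uses a reference target of known lifetime τ_ref (default 0 ns,
an ideal scatterer, since the real reference material is instrument-specific):
φ_inst = ⟨φ_measured⟩ − arctan(ωτ_ref) and
m_inst = ⟨m_measured⟩·√(1+(ωτ_ref)²), as global (not per-pixel) means.

Lifetimes are computed from phase only: τ_φ = tan(φ)/ω, in ns. The
modulation lifetime τ_m = √(1/m²−1)/ω is exposed as a diagnostic but never
enters the pipeline. Calibrated phases outside [0, π/2) are marked invalid
rather than wrapped — wrapping noise-driven negative phases would create
spuriously huge lifetimes.

## Phasors and decay mixtures

A pixel's phasor is (g, s) = (m cos φ, m sin φ) after instrument correction.
Mono-exponential decays lie on the universal semicircle
(g−½)² + s² = ¼; an n-component mixture with intensity fractions a_i is the
convex combination Σ a_i (g_i, s_i), so two-component mixtures populate the
chord between their component phasors. The apparent phase lifetime of a
mixture is τ_app = (s/g)/ω, strictly increasing in the long-component
fraction α, and invertible in closed form:

    α = (t·g₂ − s₂) / ((s₁ − s₂) − t·(g₁ − g₂)),   t = ω·τ_target.

The pooled-cloud chord is fitted by total least squares (principal axis of
the 2×2 (g,s) covariance) because both coordinates carry comparable noise;
the chord's two semicircle intersections, solved as a quadratic, give the
short and long component lifetimes via τ = s/(g·ω). An intersection at
g ≤ 0 is reported as unbounded. Clouds whose principal-axis ratio is below
1.5 are flagged ill-conditioned and yield no component estimate. The NADH
cloud at 10 MHz has intrinsically poor lifetime resolution (the frequency is
optimized for the ~16 ns PPIX decay, 1/(2πf) = 15.9 ns), so NADH chord fits
frequently carry that flag; they are emitted, not suppressed.

## Synthetic cohort

The generator emulates a 42-sample / 21-patient brain-tumor cohort with the
study inventory hard-coded per patient: tissue classes NPL 2 / REA 5 /
INF 12 / NEC 7 / TUM 16, 21 ALA+ and 21 ALA− samples, grade partition
LGG 3 patients (7 samples) / HGG 14 (24) / MET 4 (11).

Per-sample apparent lifetimes are drawn from lognormals matched to the
published group summaries — median m and σ = ln(q75/q25)/(2·z₀.₇₅) — which
preserves the median and the quartile *ratio* exactly (a lognormal cannot
match two asymmetric quartiles and the median simultaneously). Draws are
censored to the feasible mixture interval of the channel
(τ_short + 0.05 ns, τ_long − 0.05 ns); censoring is in the tails and leaves
the median untouched whenever the median itself is feasible. Two
conditioning modes exist because the published marginal summaries by tissue
class and by ALA status cannot both be matched by one generative law:
`mode="tissue"` draws PPIX from the per-tissue parameters, `mode="ala"`
from the ALA± groups. NADH is always tissue-conditioned, and NPL samples
always use NPL parameters for both channels.

Each apparent lifetime is realized physically as a two-component mixture:
PPIX as 16 ns native PPIX diluted by 1.9 ns tissue autofluorescence, NADH as
a bound/free mixture with components 4.0 / 0.4 ns. The bound component is
set at the top of the physiological 1–4 ns range so that every published
NADH group median is reachable as a mixture. Artifacts: necrotic samples
receive a core ellipse (10 % of the sample area) with NADH near 0.7 ns and
PPIX reduced by 40 %; 30 % of samples receive a vessel streak emitting at a
mono-exponential 5.5 ns in NADH (vessels exceed the bound-NADH limit, so
they are modelled as a distinct emitter, and the 5 ns mask ceiling removes
them downstream).

Remaining free choices, stated once and not revisited: per-pixel lognormal
jitter with CV 0.05 (within-sample heterogeneity is not quantified in the
source data); photon budget 1000 counts/frame inside the sample and
10 counts background (the real system auto-exposed per sample; saturation
behaviour is not modelled, so exposure reduces to a per-channel scalar);
image size 256×256 (the real sensor geometry is unstated; statistics depend
on the 100 sampled pixels, not the image size); instrument φ_inst = 0.2 rad,
m_inst = 0.85 so that calibration is genuinely exercised. Every sample has
its own rng stream derived from (cohort seed, CRC32(sample id)), making
cohorts reproducible independent of generation order.

What the generator does **not** emulate: optical scattering/absorption,
spectral bleed-through (FAD), realistic vasculature or necrosis morphology,
inter-patient correlation beyond the shared inventory, and any
concentration–lifetime coupling. Passing recovery tests therefore shows the
analysis chain is correct and unbiased under shot noise — not that the
published tissue values would be reproduced on real acquisitions.

## Post-processing and statistics

Masking keeps a pixel iff it is inside the segmentation, demodulated
validly, below the channel ceiling (NADH < 5 ns, PPIX < 17 ns) and at or
above the intensity noise floor. The floor is dark-mean + 2·SD when dark
statistics exist; synthetic data use a fixed 50-count floor. 100 random
pixels per sample are drawn without replacement from the *intersection* of
both channels' valid masks, so NADH/PPIX values are colocalized pairs — the
classification uses the colocalized pair, which forces one coordinate set
per sample. A shortfall (< 100 valid pixels) draws with replacement and
warns by default.

Statistics operate on per-sample means of the 100 sampled values (a pooled
per-pixel mode exists for sensitivity analysis). Group summaries are median
and type-7 (linear-interpolation) 25/75 % quantiles. All unordered group
pairs are compared with two-tailed Mann–Whitney U tests at α = 5 %: exact
enumeration when the pooled size is ≤ 12 without ties, otherwise the normal
approximation with tie and continuity correction; a dead-center
U = n₁n₂/2 is p = 1 by symmetry. No multiple-testing correction is applied
— a deliberate mirror of the analysis being reproduced, and a known
limitation. Patient clustering is ignored (samples treated independently).

## Classification

RUSBoost: AdaBoost.M2 boosting on the pseudo-loss with per-iteration random
undersampling of every non-minority class to the minority size, weak
learners being depth-limited decision trees (max 20 splits), 30 learners,
learning rate 0.1 in the weight-update exponent. A learner with pseudo-loss
≥ 0.5 is discarded and weights reset (standard safeguard). These
hyper-parameters are unstated in the source analysis; the defaults mirror
the common RUSBoost configuration and are config-exposed. Cross-validation
is fivefold, drawn uniformly over observations, deliberately patient
*unspecific* (the class-preserving but over-fit-prone choice of the original
analysis); a stratified redraw handles folds that would miss a class, and an
optional patient-grouped mode exists. Non-pathological rows are excluded
from both classification tasks (two samples cannot form a class), so the
4200-row cohort table yields 4000 classification observations. Accuracy is
observation-level; confusion matrices are reported as counts and
row-normalized percentages.

## Problem sizes in tests and the acceptance script

Stochastic recovery targets use 25 independently seeded default cohorts
(256×256, full 42-sample inventory) per conditioning mode — enough that the
across-cohort median of group medians is stable to well under the stated
tolerances — while unit tests run reduced image sizes (32–96 px) where the
property under test does not depend on the field of view. The CV-improvement
check uses 11 cohorts with 20-learner ensembles; the sign of the
NADH-feature effect is insensitive to ensemble size.

## Known limitations

- The chord decomposition quantifies what the source treated qualitatively;
  estimates are chord intersections, not fitted decay amplitudes.
- Lognormal group laws are an assumption; only medians and quartile ratios
  of the published summaries are honoured.
- The demodulated modulation depth is Rice-biased upward at low SNR; the
  pipeline's phase-only lifetime is unaffected, but phasor clouds at very
  low photon budgets sit slightly outside their noiseless position.
- Mann–Whitney exact enumeration is capped at pooled n = 12; larger groups
  always use the corrected normal approximation.
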
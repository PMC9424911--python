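# Methods

This note documents the models implemented in `sfebci`, the assumptions
behind them, the synthetic data they are exercised on, and the numerical
and design choices made where the problem left them open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and preprocessing

All processing operates on 30-channel scalp EEG in microvolts at 1000 Hz,
in the fixed montage order Fp1, Fp2, Fz, F3, F4, F7, F8, FC1, FC2, FC5,
FC6, Cz, C3, C4, T3, T4, CP1, CP2, CP5, CP6, Pz, P3, P4, T5, T6, PO3,
PO4, Oz, O1, O2. The decoding unit is a 100-sample (100 ms) window,
0-based half-open `[start, start+100)`.

Two bands matter: the typical EEG band (5, 50) Hz, which the classifiers
consume, and the screening band (55, 95) Hz, where facial-EMG energy
dominates. Band-pass filtering uses a 4th-order Butterworth applied
forward–backward (`sosfiltfilt`), i.e. zero phase: the filter family and
order are our choice (only the pass-bands are prescribed), and zero-phase
filtering preserves the alignment of the 100 ms decoding windows with the
underlying events. Streaming decode filters the whole recording once per
band and slices windows from the filtered streams, so window edges carry
no filter transients. Decimation to 512 Hz (used by the connectivity
analysis) applies an 8th-order zero-phase low-pass at 0.45 × the target
rate before index selection, to keep folded energy out of the gOPDC
spectra.

## Synthetic study conditions

No public recordings exist for this paradigm, so a generator
(`sfebci.synth`) defines the study conditions. One seed fixes a "subject":
the background dynamics, the per-class spatial patterns, and all
per-trial randomness (spawned sub-streams), making sessions byte-identical
across runs.

The trial timing is 3 s countdown + 4 s rest + 4 s expression + 4 s
relax = 15 s; sessions concatenate trials in seeded random class order.

**Background.** Four stationary ingredients, mixed per channel with
profiles fixed by the subject seed:

* a stable random MVAR(6) process (spectral radius 0.8, innovation sd
  1.2 µV) low-passed below 12 Hz — it carries the cross-channel directed
  structure the connectivity analysis estimates;
* steep 1/f² drift (6 µV) — the bulk of resting-EEG amplitude;
* a narrow-band alpha rhythm (9–11 Hz, ≈2.5 µV, channel-varying);
* a 0.15 µV white sensor floor.

The deliberate property of this mixture is that the fast end of the
background spectrum is *rhythmic, not broadband*. Broadband noise above
roughly 18 Hz — at any amplitude — has sample entropy above the 0.45
EMG decision threshold at a 1000 Hz sampling rate, so a generator with a
flat or shallow background spectrum cannot reproduce the audit pattern
that brain-band components are regular while EMG components are not.
Real resting EEG has the same character (steep spectrum plus narrow-band
rhythms), which is why the audit threshold works on real data.

**Expression content.** Each class adds (i) a narrow-band
amplitude-modulated oscillation at a class-specific center frequency
(8–45 Hz allowed; defaults 13–35 Hz, off the alpha band, s-RB highest at
35 Hz) with a class-specific unit-norm spatial pattern whose weight is
concentrated ×3 on the six facial-muscle-adjacent reference channels, at
18 µV; and (ii) an EMG-like burst: white noise band-passed to 20–95 Hz
with a 150 ms rise envelope, weighted onto the reference channels,
scaled by an intensity gain — 0.4 for slight expressions, 6.0 for
regular-amplitude expressions (the ratio, ≥3 by construction, is a free
parameter; the qualitative contrast is the point). Relax segments add
large slow (0.5–3 Hz) frontal transients that carry almost no energy
above 55 Hz, so screening passes them while the ON detector labels them
"else".

Tone centers are capped at 35 Hz because faster AM carriers approach the
0.45 sample-entropy threshold intrinsically at this sampling rate, which
would blur the artifact-audit contrast the generator exists to emulate.

**What the generator does not emulate.** Volume conduction and realistic
head geometry, eye-blink/EOG artifacts, electrode drift and impedance
changes, inter-subject variability, and non-stationarity within a
session. Class content is far more stereotyped (a stable narrow-band tone
per class) than real expression EEG. Consequently the decoding accuracies
reached on synthetic sessions characterize the *implementation* — that
the pipeline trains, separates separable classes, and runs the state
machine correctly — not expected performance on human data.

## The four-step decoder

**Step A.** For each reference channel, threshold = 1.05 × the largest
(55, 95) Hz temporal energy `Σxᵢ²` over all slight-expression training
windows; a window is rejected iff any reference channel exceeds its own
threshold. The 5 % margin guarantees no training window is ever rejected.
The composite score used to compare threshold statistics is
`100/(1/AR + 1/RR + Ts)` with AR/RR as fractions and Ts in ms.

**Step B.** CSP with 2 filter pairs. Per-window channel covariances are
trace-normalized and averaged per class; filters come from the
generalized eigenproblem `C_on w = λ (C_on + C_else) w`, keeping two
eigenvectors from each end. Features are `log var(Y_k)` normalized by the
*sum* of the four log-variances — implemented exactly as specified, so the
4-vector sums to 1; the classical `log(var/Σvar)` variant is available
behind a flag. The SVM kernel scale is `γ = 1/(4 · var(X))` with the
variance pooled over every entry of the training feature matrix (pooled
vs per-feature was open; pooled chosen), box constraint 1.0, no feature
standardization (γ already carries the scaling).

**Step C.** The window network: Conv1D(64, kernel 3, stride 1, valid,
linear) → max-pool(3, stride 3) → Conv1D(128, kernel 3, linear) →
GRU(128, tanh/sigmoid, dropout 0.1, recurrent dropout 0.1, last state) →
dense 64 ReLU → dense 32 ReLU → dense 9 softmax; categorical
cross-entropy, RMSprop (lr 0.001, ρ = 0.9, ε = 1e-7), batch 128. Shapes
along the way: 100×30 → 98×64 → 32×64 → 30×128 → 128 → 64 → 32 → 9. The
convolutions are linear (only the dense layers specify activations); the
pooling and GRU supply the non-linearity. The implementation is pure
numpy with hand-derived gradients (verified against finite differences in
the test suite); dropout masks, shuffling and initialization (Glorot /
orthogonal) all flow from the training seed, so runs are bit-reproducible.
Inputs are standardized by the global mean/std of the training set,
frozen into the model — a scaling choice of this implementation, needed
because the gates saturate on raw microvolt scales. Training keeps the
best-validation-accuracy parameters over 30 epochs (10 % validation
split). Tie-breaks in argmax go to the lowest one-hot index. Class
imbalance is handled by re-slicing minority-class segments with
progressively halved stride (50 % overlap first) until counts match;
"NON" training windows come from resting-state only.

**Step D and the state machine.** A label is valid iff at least x % of
the latest n = 20 decoded labels (the current one included; boundary
inclusive) equal it; "NON" never triggers. Criteria default to the
robotic-arm task map (s-RB 0.95, s-FB 0.95, s-LS 0.45, s-RS 0.45, s-OM
0.45, s-S 0.95, s-PM 0.55, s-DM 0.80) or the prosthetic-hand map (s-RB
0.95, s-FB 0.95, s-LS 0.35, s-RS 0.40, s-S 0.95; disabled classes carry
1.0 and no instruction mapping, so their instructions are never
transmitted). In NC mode only the binary detector runs; a valid s-RB
toggles NC↔IC; in IC mode valid control classes emit stepping
instructions (arm: Right +30/X, Left −2/X, Forward +20/Y, Backward −3/Y,
Up +30/Z, Down −10/Z above 21 mm else −3/Z, Open; hand: Open +7.0 mm,
Close −10.5 mm, Extorsion +11.0°, Intorsion −12.0°, aperture clamped to
[0, 95] mm). The streaming stride defaults to 10 ms (90 % overlap). The
theoretical instruction latency is `Ts = 100 + n·ts` ms.

Two behaviors were genuinely open and are configurable:

* the consistency history is cleared after every mode transition and
  (default on) after every emitted instruction, so a sustained expression
  produces at most one instruction per refilled buffer rather than one
  per window;
* a **switch debounce** (default on): one uninterrupted run of s-RB
  labels can produce at most one NC/IC switch. The switch re-arms only
  after a 10·n-label stretch (~2 s at the default stride) contains fewer
  than 25 % s-RB labels. Without this, the algorithm taken literally
  toggles the interface every ~300 ms during a multi-second brow-raise;
  a live user stops the expression on interface feedback, and the
  debounce is the software-side equivalent. The 2 s window is chosen to
  exceed the longest transient mis-detection runs observed on synthetic
  streams while staying well under the natural gap between a user's
  distinct switching gestures.

Every processed window appends a time-log event (timestamp, counter, step
outcomes, transition, instruction, device acknowledgment), written as
JSON Lines; replaying a recording through the same models reproduces the
log exactly.

## Effective connectivity (gOPDC)

An MVAR model `y(n) = Σ_{r=1..m} A_r y(n−r) + w(n)` is fitted by
least squares on de-meaned data (residual covariance → Σw); the order
minimizes `AIC = ln det Σw + 2·m·ch²/N`. The spectral transform is
`A(f) = I − Σ_r A_r e^{−j2πfr/rate}` on a 1 Hz grid from 1 Hz to Nyquist.
The directed measure from channel q to p (p ≠ q) is

    gOPDC_pq(f) = (1/λ²_pp) · |Re A_pq(f)| / (a_q^H Σw⁻¹ a_q)
                             · |Im A_pq(f)| / (a_q^H Σw⁻¹ a_q)

with λ_pp the diagonal of Σw and a_q the q-th column of A(f) —
implemented exactly as printed (no square root in the denominator; the
square-root GPDC variant is a flag). Multiplying real- and imaginary-part
terms zeroes any interaction that is purely real at a frequency, the
orthogonalization that suppresses volume-conduction-like zero-lag
co-variability. The diagonal is NaN. A singular Σw gets a ridge
(1e-12 × mean diagonal) with a warning.

Time variation uses sliding-window refitting (default 0.5 s windows):
the alternative time-varying estimator referenced in the field (dual
extended Kalman filtering) is not specified anywhere usable, and 0.5 s
summaries are what the analysis reports anyway. Band summaries average
over low (4, 12), medium (12, 30) and high (30, 50) Hz; the resting-state
baseline is the 99th percentile of pooled finite resting map values, and
thresholding keeps only strictly larger entries. Map normalization to
max = 1 happens only in the reporting layer. Whether trial averaging
precedes thresholding was unstated; this implementation thresholds the
trial-averaged map.

## Component audit (sample entropy)

`SampEn(m, r, N) = −ln(A^m(r)/B^m(r))` with m = 2, r = 0.2 × the std of
the analyzed sequence itself, Chebyshev distance, self-matches excluded
(the standard convention; it avoids a bias toward zero), both counts over
the N−m templates fully inside the series. A constant sequence returns 0;
if no (m+1)-template matches, +inf. Components with SampEn > 0.45 are
labeled EMG and discarded when reconstructing clean EEG; the per-channel
energy-reduction ratio is `100·(1 − E_clean/E_orig)`.

Decompositions: FastICA (scikit-learn, tanh/logcosh contrast, up to one
component per channel, whitening retained at eigenvalue > 1e-10 of max)
for the multi-channel view, and per-channel empirical mode decomposition
for the single-channel view. EMD is implemented here by classic sifting —
cubic-spline envelopes through local extrema with mirrored boundary
knots, Cauchy SD stopping criterion 0.2, ≤50 sifts, ≤10 IMFs, residual
appended last so rows sum exactly to the input. The noise-assisted mode
is ensemble averaging over 8 realizations of 10 %-of-std white assisting
noise; a true multivariate sifting over jointly projected channels is
out of scope, and the per-channel (ensemble) form is the documented
fallback. Exact sifting parameters are unstated in the source material;
these are standard defaults.

## Task metrics

Placement quality of the object-moving task is the intersection over
union of two equal axis-aligned squares (side 40 mm) offset by the
placement deviation: `IoU = 100·(s−|dx|)₊(s−|dy|)₊ / (2s² − overlap)`.
Summaries use the sample (n−1) standard deviation — it, and not the
population form, reproduces the printed subject-table spreads — and
percentages are reported at 2 decimals with half-up rounding.

## Problem sizes and limitations

The benchmark suite trains on one synthetic session of 8 classes × 10
trials (400 expression windows per class at 100 ms), evaluates on a 15 %
window-level held-out split, and streams 12 s scripted sessions at the
10 ms stride; these sizes keep a full run on one CPU core in a few
minutes while leaving all statistical margins wide. Known limitations:
the numpy network trains on CPU only and is not optimized for large
datasets; window-level held-out splits share trials between train and
test, so they measure within-session generalization (the scripted-stream
benchmarks, generated from fresh random streams, are the cross-trial
check); EMD mode-mixing is not mitigated beyond noise assistance; and
all accuracy figures describe the synthetic conditions above, not human
EEG.
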
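# Methods

This note documents the models, algorithms and design choices behind
`ephysq`, in the spirit of a methods section: what is computed, under which
assumptions, and what the synthetic generators do and do not emulate.

## Synthetic voltage-clamp traces

A recording is modelled as

```
I(t) = sign · Σ_k a_k · w(t − t_k) + ε(t),   ε ~ N(0, σ²) i.i.d.
```

with event onsets `t_k` from a homogeneous Poisson process (rate
`event_rate_hz`), amplitudes `a_k` log-normal, and a unit-peak event
waveform

```
w(t) = normalise[ (1 − e^(−t/τ_rise)) · (f e^(−t/τ1) + (1 − f) e^(−t/τ2)) ].
```

The decay is the standard two-exponential synaptic model; the
single-exponential rise factor is an extension for realism — detection needs
a finite rise, while decay fitting starts at the peak and is unaffected by
the rise window.  Events superpose linearly and there is no refractory
period in the generator; detection's refractory handling is therefore tested
on separately constructed non-overlapping fixtures.

Defaults and rationale (the values define the simulated study conditions and
are fixed once):

| parameter | default | why |
|---|---|---|
| `fs_hz` | 5000 | digitisation rate of the emulated acquisition chain |
| `event_sign` | −1 | inward currents at a −70 mV holding potential |
| `event_rate_hz` | 1.0 | typical basal sPSC frequency in hippocampal cultures |
| `amp_mu, amp_sigma` | ln 20, 0.4 | right-skewed amplitudes, median ≈ 20 pA |
| `rise_tau_ms` | 0.5 | sub-millisecond synaptic rise |
| `tau1_ms, tau2_ms, f` | 2, 20, 0.63 | mixed fast/slow decay; the pure-decay weighted τ is 8.7 ms, the scale of reported per-cell decay constants |
| `noise_sd_pa` | 2.0 | baseline noise of a decent whole-cell recording |

Ground truth records event **peak** times (onset plus the waveform's rise
delay) and peak amplitudes, because peaks are what detection localises and
aligns on.  Note that the realised waveform's fitted decay is slower than
the `f·τ1 + (1−f)·τ2` mixture (≈11.6 ms vs 8.7 ms at the defaults): the
rise factor has not saturated at the peak, which redistributes amplitude
toward the slow component.  Recovery tests therefore compare like with like
(fits of noisy data against fits of the noise-free waveform, or pure
biexponentials against their known parameters).

The current-clamp generator places stereotyped Gaussian-shaped spikes
(peak ≈ +25 mV, FWHM 0.6 ms) riding on the resting potential at evenly
spaced times inside the step window, with the per-sweep counts given by the
protocol schedule — enough structure to validate counting and amplitude
measurement, with no pretence of biophysics.

### What the generator does not emulate

Series-resistance and filtering artefacts, nonstationary rates or
amplitudes, correlated (1/f) noise, seal instability, and kinetic
heterogeneity across events.  Passing tests demonstrate correctness of the
algorithms under the stated statistical model, not performance on any
particular real recording.

## Event detection

The detector replaces an undocumented commercial tool with a transparent
pipeline:

1. baseline: centred rolling median, window 200 ms;
2. residual `r = trace − baseline`; robust noise scale
   `σ̂ = 1.4826 · MAD(r)`;
3. working signal `s = sign · r`, lightly smoothed (1 ms moving average)
   for the crossing logic only;
4. upward crossings of `k·σ̂` (default k = 4) with **hysteresis**: a new
   event requires `s` to have dropped below `k·σ̂/2` since the previous
   accepted event;
5. peak search within 10 ms of the crossing, refined on the *unsmoothed*
   residual; amplitude = |peak residual|; event time = peak time;
6. refractory merging (5 ms): of two candidates closer than the refractory
   interval the larger survives.

Smoothing and hysteresis are required in practice: on the long biexponential
tail, noise re-crosses a bare threshold after the refractory interval and
produces duplicate events at a rate that would violate the intended
false-positive budget (≤0.05 events/s at 2 pA noise).  Peak/amplitude
refinement on the raw residual keeps noise-free accuracy exact.  On
noise-free input the MAD estimate is zero, so an absolute noise floor
(0.01 pA) keeps the threshold positive; flat traces then yield an empty
table rather than wall-to-wall "events".

Known bias: with a 200 ms median window and ~100 ms event support, the
baseline under an event sits a fraction of a percent into the tail, biasing
amplitudes by ≈ +0.3% at the default kinetics — well inside the 2% accuracy
contract.  Long supra-threshold bursts yield one event per crossing, so
heavily overlapping events are undercounted; that regime is outside the
detector's contract.

Action potentials are upward crossings of 0 mV separated by ≥1 ms, again
with hysteresis (re-arm below −10 mV) so threshold flicker on spike flanks
is not double-counted; spike amplitude is peak voltage minus the pre-step
baseline (the reference for AP amplitude is a convention; threshold-to-peak
is the main alternative and would give systematically smaller values).

## Highest-activity window and averaging

The one-minute analysis window maximises the event count over windows
anchored at event times (clamped to the record) plus the record start; ties
break to the earliest start.  Anchoring at event times is sufficient: the
count as a function of the window start only changes at event boundaries.

Peak-aligned averaging takes `pre_ms`/`post_ms` segments around each event
peak, drops (and logs) events whose window leaves the record, and averages
pointwise; per-cell averages are averaged again to give one trace per group,
weighting cells equally regardless of event count.

## Decay fitting

`fit_biexponential` fits `A1 e^(−t/τ1) + A2 e^(−t/τ2)` (optionally plus a
constant) to the magnitude of the waveform from its extremum to the end,
by trust-region least squares.  Initialisation: τ2 from a log-linear fit of
the last third of the decay, τ1 = τ2/5, amplitudes by linear least squares
given the τs; up to 5 deterministic jittered restarts on failure.  Fits are
canonicalised to τ1 ≤ τ2; degenerate inputs (all-zero or flat) return
`converged=False` with the residual recorded, never a silent success.  The
summary statistic is the amplitude-weighted τ — reported per-group decay
numbers rarely state their definition, and the weighted τ is the convention
adopted here (it lies between τ1 and τ2 for positive amplitudes).

## Bootstrap-subsampled KS decision

For pooled samples `x`, `y`: repeat `B = 1000` times — draw `m = 100`
values from each group (without replacement by default; a `replace` flag
exists for sensitivity analysis), compute the two-sample KS test, record
its p-value.  The fraction of repeats with p < α (α = 0.05) is reported to
full precision and formatted as a percentage with one decimal; the groups
are declared different **iff the fraction strictly exceeds 0.5**.  One RNG
stream is used, iteration-major, x drawn before y, so results are portable
given (data, seed).

The inner test computes D exactly as the ECDF supremum and the p-value from
the asymptotic two-sided Kolmogorov distribution at `√(n_eff)·D`,
`n_eff = n_x n_y/(n_x+n_y)`; an exact small-sample variant is unnecessary at
m = 100.  Two forced cases pin down the rule's semantics: identical
multisets with n = m (every subsample pair is a permutation → fraction 0)
and disjoint supports (fraction 1).  Null calibration keeps the mean
fraction near the inner level (≈3–6% at n = 500), far from the 50% rule —
which is the point: the procedure trades sensitivity for robustness against
trivial differences that a single KS test on thousands of pooled events
would flag.

Subsampling treats events pooled within each group as exchangeable; there is
no per-cell (hierarchical) resampling.

KDE summaries use Gaussian kernels with Silverman's rule; heavily skewed
quantities (interevent intervals) can be estimated on the log scale and
mapped back with the 1/x Jacobian.

## Inference from (mean, SEM, n)

With per-group mean `m_i`, SEM `s_i`, size `n_i` (SD `= s_i √n_i`):

```
SSB = Σ n_i (m_i − m̄)²,  m̄ = Σ n_i m_i / N
SSW = Σ (n_i − 1)(s_i √n_i)²
F   = [SSB/(k−1)] / [SSW/(N−k)],  df = (k−1, N−k)
```

identical to a one-way ANOVA on any raw data realising those summaries
(verified against reconstructed raw groups to 1e−10 relative).  The ±
values attached to the electrophysiology summaries are treated as SEM —
the printed F statistics are only reproducible under that reading, which
the reconstruction oracle confirms — while expression figures in the same
literature often state ±SD; `GroupSummary.from_sd` makes the alternative
explicit.  T-tests (pooled df = n_a+n_b−2, or Welch–Satterthwaite) follow
the same convention.  Reproduction of printed statistics is checked to 1%
relative (F) and 0.01 absolute (p), the precision the rounded inputs
support.

P-value adjustment supports Bonferroni, Holm and Benjamini–Hochberg.

## qPCR relative quantification

Triplicate wells are averaged per (sample, gene); replicate SD > 0.5 cycles
flags a record for QC without removing it.  Quantification follows the
geNorm-style multi-reference scheme:

```
RQ_{s,g} = E_g^(CT̄_g − CT_{s,g})          (CT̄_g: mean CT of gene g over all samples)
NF_s     = geometric mean of RQ_{s,r} over reference genes r
norm     = RQ_{s,g} / NF_s, anchored so the control-group mean is 1
           within each gene × (ZT, hemisphere) stratum
```

Amplification efficiency defaults to the ideal doubling E = 2 (the `2^−ΔCT`
reading), overridable per gene in (1, 2].  A per-sample loading offset (a
constant added to all of a sample's CTs) cancels exactly when E is uniform.
The anchoring makes control means 1 by construction — and deliberately
removes across-stratum structure, so circadian profiles are inspected with
`rescale=False`.  Group comparisons are per-stratum Welch t-tests on
normalized expression, excluding the reference genes (testing the
normaliser would be circular), with BH adjustment across the gene × stratum
family; BH is a package default, not a claim about any particular study.
Zero-variance strata (exactly identical noise-free values) are decided
directly: identical → p = 1, different constants → p = 0.

The panel simulator draws
`CT = baseline − A cos(2π(ZT − φ)/24) − log_E(fold) · 1[treated] + N(0, σ)`
per well.  The default design mirrors a clock-output panel: activators Hlf
(4-fold down in the treated group), Dbp and Tef (2-fold down), repressor
E4bp4 (2-fold up), references Hprt1/Eef1a1 flat; cosinor amplitudes are low
(0.3–0.5 cycles) because these factors oscillate weakly in brain tissue;
n = 5 per group per ZT, triplicates, σ = 0.25 cycles.  With σ = 0 the
quantification inverts the ΔCT transform exactly (the round-trip test).

## Pipeline, determinism, problem sizes

A single global seed spawns per-stage substreams through
`SeedSequence([seed, crc32(stage_name)])`, so stages rerun in isolation
reproduce exactly; rerunning a configuration is byte-identical.  Every
artifact embeds the package version, a SHA-256 configuration digest and the
stage seed; the manifest lists all artifacts.

Test and acceptance workloads use deliberately modest sizes — 20–120 s
records at 5 kHz, 10–300 seeds per Monte-Carlo property, B = 100–1000
bootstrap repeats, qPCR panels of 6 genes × 4 ZT × 2 × 5 samples — chosen
so the full suite runs in well under a minute of simulation-heavy work
while keeping every statistical bound at least ~3 standard errors from its
threshold.

## Known limitations

- No template-matching/deconvolution detection, no EPSC/IPSC kinetic
  classification, no series-resistance bookkeeping.
- Detection undercounts genuinely overlapping events (single crossing per
  supra-threshold excursion).
- The decay model excludes the rise; fits summarise the post-peak waveform
  only.
- No hierarchical resampling across cells; no rhythm (cosinor) fitting or
  phase tests in the qPCR stage — only per-ZT group contrasts.
- No primer-efficiency estimation or melt-curve QC; efficiencies are inputs.
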
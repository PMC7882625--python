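# Methods note

This note documents the model implemented by `neurodyn`, the parameters
and their defaults, what the synthetic generator does and does not
emulate, the numerical choices made where the method leaves room, and the
known limitations. It describes what the code computes; it makes no
empirical claim beyond what the test suite verifies.

## 1. Model

### 1.1 From EEG to symbols

Input is multi-channel EEG (µV). For each channel the signal is cut into
contiguous non-overlapping 1-s epochs and a power spectral density is
computed per epoch by Welch's method with a single segment per epoch
(i.e. a tapered modified periodogram; Hann taper by default, no
detrending). Band power for each integer bin *c* ∈ {1, …, 40} Hz is the
density integrated over [c − 0.5, c + 0.5) Hz, giving a
time × channel × bin power tensor with 1-s cadence
(`spectral.welch_psd`). Epochs containing non-finite samples are masked,
not dropped, so cadence is preserved.

Each (member, channel, bin) power series is then symbolized by **equal
occupancy** (`symbolize.symbolize_stream`): epochs are ranked (stable
sort, ties broken by time index) and split into three groups as equal as
possible — group sizes differ pairwise by at most 1, with the remainder
assigned to the lower groups. The bottom third is labelled **−1** (below
average power), the middle **1** (average), the top **3** (above
average). Symbolization therefore depends only on ranks: any strictly
increasing transform of power (log, normalization) leaves the symbols
unchanged. A stream whose values are all identical cannot be ranked into
thirds and raises `DegenerateInputError` rather than emitting arbitrary
symbols.

### 1.2 Team symbols

The *k* member symbols at each second combine into one composite team
symbol (`symbolize.compose_team`): with rank map −1→0, 1→1, 3→2, the
label is 1 + Σᵢ rank(sᵢ)·3^(k−1−i) over members in the given order,
giving alphabets of 9 (dyad) and 27 (triad) labels. The encoding is
bijective (`decode_team` inverts it exactly) and member order is part of
the definition. A second is valid for the team only when it is valid for
every member (mask intersection).

### 1.3 Neurodynamic information

For a trailing window of *N* symbols (default 60 s, stepped 1 s) with
empirical proportions p̂₁ … p̂_S,

- plug-in entropy H = −Σ p̂ᵢ log₂ p̂ᵢ (terms with p̂ᵢ = 0 contribute 0),
- NI = log₂(S) − H, clipped at 0 from below,

so NI is 0 for a window visiting all symbols equally and log₂(S) for a
window frozen on one symbol: 1.585 bits for a member stream (S = 3),
3.170 for a dyad (S = 9), 4.755 for a triad (S = 27). Traces are
anchored at the last second of each window; a window is emitted only
when at least `min_occupancy` (default 0.5) of its seconds are valid,
and masked windows appear as NaN so cadence never changes.

The decomposition `NI_team = NI_member1 + NI_member2 + MI` holds as an
algebraic identity per window for dyads (`shared_information` computes
the per-window mutual information from the joint 9-symbol code); the
test suite verifies it to machine precision.

### 1.4 Randomized baseline and bias

The plug-in estimator is biased: even an i.i.d. uniform stream shows
positive NI at finite N, approximately (S − 1)/(2N ln 2) bits to first
order (≈ 0.096 bits for S = 9, N = 60). The correction implemented is
empirical, not analytic: each stream is temporally permuted (unmasked
positions only) `n_shuffles` times (default 6), the full NI trace is
recomputed per shuffle, and the per-index mean of the shuffled traces is
subtracted, clipping at 0 (`randomized_baseline`, `subtract_baseline`).
Shuffling destroys temporal order while preserving the symbol
composition, so the baseline carries the estimator bias plus whatever NI
the global composition alone produces.

Note on the first-order law: it is an asymptotic approximation. The
exact finite-sample expectation (computable in closed form from the
Binomial(N, 1/S) distribution of per-symbol counts, which the test suite
uses as an oracle) exceeds the first-order term noticeably when S is
large relative to N — by ≈ 0.10 bits at (S = 27, N = 30) and ≈ 0.04 bits
at (27, 60). The first-order formula is therefore documentation of the
leading behavior, not the quantity the software relies on; the shuffle
baseline captures the bias exactly in expectation regardless of S/N.

### 1.5 EEG-PV and NI–PV correlation

EEG-PV is the moving average of the numeric symbol values −1/1/3 over
the same window (`power_values.eeg_pv`). Unlike NI it is signed: values
above 1 mean net activation, below 1 net deactivation. NI–PV coupling is
quantified with Pearson correlation (`ni_pv_correlation`), either one
coefficient over the whole performance or a windowed rolling coefficient
(minimum 3 points; windows with near-zero variance in either series are
masked). `correlation_map` aggregates **before** correlating —
scalp / region / region × frequency means of NI and PV are formed first,
then correlated — because correlations of averages and averages of
correlations differ and the drill-down question is about the aggregate
signals. Default scalp regions are frontal (Fp1, Fp2, F3, F4, F7, F8,
Fz), central (C3, C4, Cz, T3, T4), parietal (P3, P4, Pz, T5, T6) and
occipital (O1, O2).

### 1.6 Peaks and incidence

Peaks are local maxima of the corrected NI trace with topographic
prominence ≥ `min_prominence` (default 0.1 bits), detected with
`scipy.signal.find_peaks`; each peak's duration is its width at half
prominence (`peak_widths`, `rel_height = 0.5`), with sub-sample edges by
linear interpolation, converted to seconds via the window step. Traces
with NaN gaps are split into finite runs analyzed independently, and run
boundary samples cannot be peaks (prominence is undefined there).
`incidence` reports the fraction of analyzed stream-epochs lying inside
the union of half-prominence intervals, and `duration_vs_magnitude`
tabulates peak count and duration statistics across a grid of prominence
thresholds.

## 2. Parameters and defaults

| Parameter | Default | Rationale |
|---|---|---|
| window length | 60 s | standard window of the method; ≥ 5× alphabet warning below that |
| window step | 1 s | matches the 1-s symbol cadence |
| alignment | trailing | causal; anchor = last second of the window |
| `min_occupancy` | 0.5 | a window estimated from < 50% of its seconds is masked |
| frequency bins | 1–40 Hz, 1-Hz width | EEG band of interest at the method's resolution |
| Welch taper | Hann | standard leakage/variance tradeoff for single-segment epochs |
| `n_shuffles` | 6 | cost/variance tradeoff for the empirical baseline |
| `min_prominence` | 0.1 bits | separates organized episodes from estimator noise |
| symbol values | −1, 1, 3 | carry deactivation/average/activation meaning in EEG-PV |
| generator baseline | i.i.d. uniform thirds | makes equal occupancy hold by construction |
| `hold_prob` | 0.8 | planted epochs are persistent, not frozen |
| `snr` | 10 | raw-EEG synthesis clearly recoverable but not noiseless |

## 3. What the generator emulates — and what it does not

`synthetic.simulate_symbols` produces per-stream symbol sequences that
are i.i.d. uniform over {−1, 1, 3} (optionally a sticky Markov chain via
`markov_persistence`) except inside *planted epochs*, where the held
symbol is emitted with probability `hold_prob`. `member_coupling` is the
probability that a non-target member co-expresses a planted epoch with
shared timing but independent emissions — the team-level analogue of
joint organization. Every expressed epoch is returned in a ground-truth
table, so recovery (recall/precision of detected peaks against planted
intervals) is directly testable; co-expressions that would overlap an
existing epoch on the same stream are dropped rather than merged.

`simulate_raw_eeg` goes one level deeper: each (channel, bin) carries a
sinusoid at the bin frequency whose amplitude switches per second among
three levels driven by the same symbol process, plus white noise scaled
to a target SNR. This exercises the full Welch → symbolize → NI path
against known symbols.

The generator emulates exactly one statistical feature: intermittent
persistence of a power level in specific streams against a disorganized
background. It does **not** emulate 1/f spectra, volume conduction,
cross-channel correlation, artifacts, nonstationary broadband power, or
any physiological structure. Conclusions supported by the synthetic
benchmarks are therefore about the estimator and pipeline (detection,
calibration, invariances), not about EEG physiology.

## 4. Numerical choices

- **Trailing windows.** Anchors at the window's last second keep the
  trace causal and make "NI at time t" depend only on the preceding
  60 s. Peak times are therefore late by up to one window length
  relative to the underlying episode midpoint.
- **Windowed counts by one-hot cumulative sums**, giving O(nS) exact
  integer counts with no per-window loop; entropy from counts avoids
  0·log 0 by masking zero cells.
- **Clamping.** Corrected NI is clipped at 0: a shuffle baseline can
  exceed the raw trace by sampling noise, and negative information is
  not meaningful here. Raw NI above log₂(S) + 1e−6 raises instead of
  clipping — it can only come from a bug.
- **Tie handling.** Ranking uses a stable sort so equal power values are
  ordered by time; symbolization is then deterministic and the
  pairwise-≤1 occupancy guarantee is exact even with heavy ties.
- **Taper caveat.** Under the default Hann taper a pure sinusoid at a
  bin center leaks ≈ 33% of its power into the adjacent 1-Hz bins (1-s
  segments put bin edges at the taper's first nulls). A boxcar taper
  concentrates ≥ 95% in-bin and is available via the `window` argument;
  Hann remains the default because real EEG is broadband and leakage
  control matters more than single-tone concentration.
- **Determinism.** All randomness flows from user seeds through
  `numpy.random.default_rng`; the pipeline derives one child seed per
  stream from SHA-256 of `"{seed}:{tag}"` (reduced mod 2³¹), so adding
  or removing a stream does not perturb the others and identical
  config + seed yields byte-identical output tables.
- **Masks, not drops.** Invalid seconds and low-occupancy windows become
  NaN in place; every downstream stage (baseline, PV, correlation,
  peaks) handles NaN explicitly, so cadence and alignment never silently
  change.

## 5. Limitations

- The plug-in estimator is used as-is; the shuffle baseline removes its
  bias in expectation but adds variance of its own (6 shuffles is a
  point estimate of the null mean, not a null distribution). No
  coverage-adjusted or Bayesian entropy estimator is provided.
- 60 windows over a 27-symbol triad alphabet is a severely undersampled
  regime; triad NI values at the default window are dominated by
  small-sample effects, which is precisely why the baseline subtraction
  is mandatory there. `WindowSpec` warns when N < 5S.
- Equal-occupancy cuts are computed over the whole performance, so
  symbols are not causally computable online and a stream's
  symbolization changes if the recording is truncated.
- Consecutive windows overlap in 59 of 60 symbols; NI traces are
  strongly autocorrelated, and no correction for this is applied to the
  windowed NI–PV correlations. Whole-performance correlations likewise
  come with no inference (no p-values) because the effective sample
  size is far below the nominal one.
- Peak durations at half prominence depend on local topography; two
  episodes of equal length can yield different measured durations when
  riding on different backgrounds.
- Raw-EEG support covers EDF (via `mne`) and plain delimited samples;
  no artifact rejection, re-referencing, or filtering is provided —
  inputs are assumed preprocessed.

## 6. Problem sizes exercised by the test suite

Unit and property tests run streams of 10²–10³ s at 1–9 streams per
scenario; the estimator-calibration tests compare Monte-Carlo NI means
(400–1000 replicates) against the exact closed-form finite-sample
expectation for S ∈ {3, 9, 27} × N ∈ {30, 60, 120}; pipeline tests run
the full bundle on 8-stream dyad configurations of 200–600 s; the
reference-value script (`scripts/acceptance.py`) averages 10 independent
3600-s dyad performances. The whole suite completes in a few seconds on
one CPU.
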
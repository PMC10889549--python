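# Methods

## Pipeline

One analysis unit is a (task, hand). Per session the stages are:

1. **Conditioning.** Each muscle channel is band-pass filtered with a
   zero-phase 4th-order Butterworth (20–300 Hz; `scipy.signal.sosfiltfilt`,
   so the effective attenuation is doubled and no phase lag is introduced),
   enveloped with a 150-ms centred moving-window RMS (window truncated at
   the signal edges, output same length as input), and expressed as percent
   of the participant's per-muscle maximal voluntary contraction (MVC).
   One MVC value per participant–muscle is used for all sessions.
2. **Features.** Each muscle's %MVC envelope is linearly resampled to
   L = 100 points of normalised time (making the feature invariant to
   uniform time stretching, so faster and slower executions of the same
   activation shape compare equal), averaged pointwise over the session's
   trials, and concatenated over the four muscles in a fixed order →
   one vector of 4L = 400 values per participant-hand-session-task.
   The feature definition is a design choice of this package: it preserves
   the temporal activation *shape* that the similarity network is meant to
   compare, rather than summary amplitudes.
3. **Network.** Pearson correlation between every pair of participants'
   vectors gives the correlation matrix; the similarity network links i and
   j iff ρ(i, j) ≥ k. Default k = 0.9 interpreted as a correlation value;
   a percentile interpretation (k as a quantile level of the off-diagonal ρ
   distribution) is available via `threshold_mode="percentile"` since the
   phrasing "threshold (e.g., 90 %)" admits both readings. Ties at the
   threshold produce an edge (the criterion is ≥); negative correlations
   never create edges (the criterion is one-sided); the network always
   keeps the full roster, so isolated participants remain visible.
4. **Metrics.** Density 2E/N(N−1); Jaccard overlap of edge sets between
   every unordered pair of session networks, with J(∅, ∅) = 1 by convention
   (two empty networks are maximally similar — this also keeps degenerate
   high-threshold runs well defined); global clustering as the mean local
   clustering coefficient, with nodes of degree < 2 contributing 0
   (`variant="transitivity"` switches to the triangle/triple ratio — the
   average-local default is what reproduces high clustering on sparse
   multi-component graphs); modularity from greedy agglomerative (CNM)
   community detection, chosen over Louvain because it is deterministic,
   with communities renumbered by lowest member id and Q always re-evaluated
   with the Newman–Girvan formula on the returned partition.
5. **Labels.** *Best* = the ceil(0.25 · N) participants with the lowest
   completion time in the final trial of the final session (ties to lower
   id). *Improved* = not best, mean completion time dropped ≥ 20 %
   relatively from the first to the last session, and adjacent to at least
   one best performer in the last-session network — adjacency is the only
   similarity primitive the network offers. Best performers are *not*
   required to be connected: an outperformer with an idiosyncratic muscle
   pattern can be isolated. Both the 0.25 fraction and the 20 % improvement
   threshold are exposed as flags; neither has a canonical value in the
   literature.
6. **TLX enrichment.** Six workload dimensions on 0–10. Group means pool
   sessions (reported group means carry no session index). Association with
   improvement uses Spearman rank correlation (TLX is ordinal-like;
   `method="pearson"` available) between the per-participant dimension mean
   and the relative session-1→3 improvement; two-sided p by exhaustive
   pairing permutation for N ≤ 10, asymptotic otherwise. p-values are
   descriptive: no correction across the six dimensions.

All file formats are plain text: long-format CSV for inputs, GraphML and
tab-separated edge lists for networks (the edge list carries a roster
comment so isolated nodes round-trip), JSON for metrics. Reruns with
identical inputs and configuration are byte-identical for all metric
outputs.

## Synthetic cohort

The generator emulates an 18-participant, 3-session, 5-trial, 2-hand,
2-task, 4-muscle study sampled at 2000 Hz.

* **EMG model.** Amplitude-modulated band-limited noise: a smooth
  non-negative envelope template (baseline 0.1 plus four Gaussian bursts
  with random centres, widths 0.04–0.12 of the trial, heights 0.2–1.2)
  multiplies a unit-RMS 60–150 Hz noise carrier, plus white noise of
  standard deviation `noise_sd` (default 0.05). This is deliberately not a
  physiological motor-unit simulation: the analysis consumes only RMS
  envelopes, so envelope fidelity is what matters. The carrier band sits
  strictly inside the 20–300 Hz passband, so conditioning passes the signal
  essentially unchanged.
* **Planted similarity.** Participants split into two blocks (9 + 9 by
  default); all members of a block share envelope templates, so their
  features correlate → 1 as noise → 0. The carrier is shared by all
  participants within one (session, trial, hand, task, muscle), which makes
  same-block signals bit-identical at `noise_sd = 0` — the property the
  correlation-of-1 tests rely on.
* **Strength and MVC.** A lognormal per-participant-muscle strength factor
  scales both the raw signal and the recorded MVC, so %MVC normalisation
  removes it — which is precisely the inter-subject variability MVC
  calibration exists to remove.
* **Learners.** Three planted learners (in the non-best block) have non-dominant-hand
  envelopes mixed with the best block's template, weight
  w(s) = 0.85 · (s−1)/(S−1): 0 in session 1, 0.85 in session 3. Their
  network position migrates accordingly; dominant-hand patterns stay put.
* **Completion times.** t(s, trial) = a + b·e^(−x), x = (s−1) +
  (trial−1)/n_trials, times a lognormal factor (σ = 0.02) and a per-
  participant asymptote jitter (σ = 3 %). Non-dominant parameters (a, b):
  learners (55, 90) ≈ 46 % session-1→3 drop, best (40, 15) ≈ 18 %, others
  (70, 12) ≈ 9 %; dominant-hand curves are flat (< 10 % drop) for everyone,
  with best performers fastest on both hands. The margins around the 20 %
  improvement rule are several noise standard deviations wide, so planted
  labels are recovered exactly across seeds.
* **NASA-TLX.** Additive group-effect model, uniform ±1.2 noise, clipped
  to [0, 10]: physical demand 5.0 baseline, +2.2 for learners, +1.8 for
  best (group means ≈ 7.2 / 6.8); mental demand 5.5 baseline, −2.0 / −2.3
  (≈ 3.5 / 3.2); effort 4.6 + 4.2 × planned relative improvement + 0.9 for
  best (≈ 6.5 / 6.2 / 5.0), which plants a positive effort–progression
  rank correlation; temporal demand, performance and frustration (4.0) have
  no group effect. `tlx_effect_scale = 0` yields the null model used in the
  permutation-uniformity test.
* **Trial duration** has no canonical value and defaults to 2.0 s with no
  claimed fidelity; tests and the acceptance script use 0.25–0.75 s trials
  and a single task for most experiments, which keeps the full suite around
  two minutes while leaving every recovery property intact (the envelope
  templates and filters are duration-agnostic).

### What the generator does and does not show

Passing recovery tests demonstrates that the pipeline detects the planted
structure: block similarity, learner migration, performance separation, and
TLX group effects, under amplitude noise. It does not demonstrate
robustness to features of real sEMG the generator omits: electrode-contact
drift, crosstalk between channels, fatigue-induced spectral shifts,
inter-day MVC variation, or activation shapes that differ between
repetitions of the task. Results on real recordings depend on those factors
and on the threshold k, which should be examined with the percentile mode
and a sensitivity sweep.

## Numerical choices and degenerate inputs

* Report rounding is half-up to 2 decimals (`round_half_up`), matching how
  tabulated values are conventionally printed; Python's bankers' rounding
  would differ on exact ties.
* Correlation of a constant feature vector is undefined and raises an error
  naming the participant; a constant TLX dimension is flagged per dimension
  instead of aborting the report.
* Density needs ≥ 2 nodes, clustering ≥ 3, modularity ≥ 1 edge; inside the
  pipeline bundle these fall back to `null` so degenerate networks (e.g.
  k = 1.0 with noisy data → empty graphs) still flow through, with Jaccard
  1.0 between empty networks.
* Sub-network (connected-component) densities report singletons as `null`.
* Best-performer ties break toward the lower participant id, making
  selection deterministic.

## Known limitations

* One tabulated density cell per hand-task combination in the emulated
  study design is not internally consistent with its printed edge count
  (e.g. 41 edges on 18 nodes gives 0.268 → 0.27, not 0.26); the package
  reports the arithmetic value. Likewise a reported dominant-hand percent
  difference of 27 % is inconsistent with (1 − 0.63) × 100 = 37 %; the
  package always reports (1 − J) × 100.
* Clustering-coefficient and modularity values of the original study cannot
  be recomputed without its raw recordings; the implementation fixes
  definitions (average-local clustering, CNM communities) and verifies them
  against brute-force oracles instead.
* The feature definition (trial-averaged, time-normalised %MVC envelopes)
  is one reasonable operationalisation of "EMG features"; per-trial
  (non-averaged) analyses are not implemented.
* Weighted or signed networks, multiple-testing correction of the pairwise
  correlations, and statistical tests on graph metrics are out of scope.
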
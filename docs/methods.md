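# Methods

## Problem setting and assumptions

Chronic high-density probe recordings are spike-sorted one session at a
time; cluster identities do not carry over between sessions. The package
assigns cross-session identities under three assumptions:

- between-session tissue motion is dominated by a rigid shift along the
  insertion axis (z), with smaller per-unit residual motion on top;
- within-session drift has already been handled by the sorter;
- a unit's physical location and its spatial-temporal waveform are more
  stable across days than its firing statistics, which is what makes
  tracking possible during learning or representational drift.

Only clusters the sorter labels `good` (single units, low ISI
violations) enter matching by default; multi-unit clusters can be
included with a flag but degrade the drift estimate.

## Unit localization

Per-channel peak-to-peak (ptp) amplitudes of the mean waveform are
background-subtracted and fit with a monopole source: amplitude
α/R at distance R from the source at (x, y, z), y ≥ 0 the off-plane
distance. The fit uses the 10 sites nearest the peak site (peak row ±2
rows, both columns), bounded least squares (trust-region reflective),
initialized at the peak-site coordinates with y = 20 µm and source
strength α = peak ptp × 20 µm, up to 3 restarts with increasing initial
y, cost tolerance 1e-8. The free amplitude α is required for
dimensional consistency between µV amplitudes and the 1/R geometry.

Numerical notes:

- The background estimate is the median channel ptp over the unit's
  shank outside the 22-channel waveform neighborhood. It is robust to
  the spike's own footprint but, by construction, absorbs any genuine
  far-field signal of the unit; for very large, shallow units this
  biases the subtracted amplitudes slightly.
- Negative background-subtracted amplitudes are floored at 0 rather
  than dropped, so the channel set stays geometrically balanced.
- Units whose raw peak ptp does not exceed 60 µV are excluded from all
  matching: below that, amplitude-based localization is unreliable.
- Degenerate inputs (fewer than 4 informative channels, or all
  amplitudes equal) fall back to the peak-site coordinates with a large
  y and are flagged rather than fitted.
- For sources lateral to the two-column array, x and y are close to
  unidentifiable (both move the source away from all sites); z remains
  well determined, which is what the drift and threshold logic uses.

## Waveform distance

Units are summarized on 22 channels: the peak row ±5 rows across both
columns. Patches are aligned in *peak-relative* coordinates (row offset
from each unit's own peak, column index), so a unit recorded a few rows
higher after drift still aligns with itself. Per aligned channel the
contribution is ‖w_a − w_b‖₂ / max(‖w_a‖₂, ‖w_b‖₂); the distance is
the mean over the intersection of the two patches' offset sets (edge
truncation near the probe ends shrinks the set; the denominator follows
it). A channel silent in both patches contributes 0. The per-channel
ratio can mathematically reach 2 for anticorrelated waveforms; it is
clipped at 1 (occurrences logged) so the combined weight ω·d_wf stays
on the intended scale. Windows are compared as stored; there is no
sub-sample temporal realignment.

## Transport problem

Costs combine both spaces: D = d_loc + ω·d_wf with d_loc the 3D
Euclidean distance between estimated locations. Default ω = 1500 µm per
unit of waveform distance; matching performance is insensitive to ω
above this scale, so it needs no precise tuning. With unit masses the
EMD constraint polytope is totally unimodular, so the optimum is an
integral partial assignment (every unit of the smaller session matched
to a distinct unit of the larger) and the problem is solved exactly as
a rectangular linear assignment (modified Jonker–Volgenant). Ties are
broken deterministically by an added lexicographic perturbation below
1e-9, keeping assignments byte-reproducible across platforms; reported
costs use unperturbed D. Tests verify the solver against brute-force
enumeration over all injective assignments for sizes up to 7.

## Drift estimation and correction

Stage-1 matched pairs (good units only) give displacements Δz = z₂ −
z₁. Their Gaussian kernel density — Silverman bandwidth, floored at
0.5 µm, evaluated on a 0.1 µm grid — peaks at the rigid drift: the
true pairs concentrate at the consensus shift while unmatched-against-
unmatched pairs spread widely. The mode is subtracted from the second
session's depths and matching is repeated with recomputed location
distances (waveform distances are peak-relative, hence reused). With
several shanks the mode is estimated and applied per shank, falling
back to the global mode when a shank has fewer than 10 pairs. Fewer
than 10 matched pairs overall is an error; the caller should supply the
drift manually.

## z-distance threshold

Post-correction |Δz| of all matched pairs is modeled as

P(z) = d·( f·N·e^(−z²/2σ²) + (1−f)/c·e^(−z/c) ),  N = 2/(σ√(2π)),

f the fraction of correct pairs, σ the z-localization error width, c
the decay of incorrect pairs, d an amplitude normalization. The default
fit is least squares on a 1 µm-binned histogram over [0, 50] µm with
bounds f ∈ [0,1], σ ∈ (0.1, 20], c ∈ (1, 500]; the objective is
multimodal (a wide half-normal can mimic a truncated exponential), so
the fit multi-starts over six initializations and keeps the lowest
residual. A maximum-likelihood fit on the raw distances is available
(`method="mle"`); it avoids the truncation bias of the 50 µm window and
recovers c more accurately when the correct-pair fraction is small.
When reference pairs exist, their fitted σ should be fixed in this fit
(`sigma_fixed`): a free fit slightly underestimates σ, which makes the
derived false-positive rate, and hence any accuracy claim, conservative.
A fitted σ > 10 µm or f ≈ 0 triggers a warning — both indicate few or
no correct matches (e.g. a very large drift pair, which also shows up
as an outlying per-pair transport cost; `match_all` warns when a pair's
cost exceeds 2× the median).

The false-positive rate uses closed forms: FPR(z) =
(1−f)(1−e^(−z/c)) / ( f·erf(z/(σ√2)) + (1−f)(1−e^(−z/c)) ). It is
non-decreasing in z except for a ~1e-4 dip just above zero (the
exponential CDF is concave where the folded-Gaussian CDF is still
linear); the monotonicity assertion therefore uses a 1e-3 tolerance.
Threshold selection returns the largest 0.1 µm-grid z with FPR ≤
target, i.e. the most permissive threshold meeting the target; when no
fit is possible the operating default of 10 µm is used and flagged.

## Reference set from visual responses

Per unit: the PSTH (1 ms bins over −400…+1400 ms around onset,
averaged over presentations, Gaussian-smoothed with σ = 10 ms —
unstated in common protocols, logged and configurable) and the visual
fingerprint (mean spike count per image in the first second after
onset, over trials; defaults 112 images × 5 shuffled trials).
Significance of visual drive is a Kruskal–Wallis test across images on
the trial-wise counts at α = 0.05. Pair similarity is the sum of the
two Pearson correlations, in (−2, 2); zero-variance responses make it
NaN and the pair never qualifies. Reference pairs require similarity
> 1, both units good and significant, and 3D distance < 30 µm both
before and after drift correction (a z-only variant is available).
Conflicts are resolved mutual-best by similarity, which guarantees a
partial matching; one-sided "highest similarity" resolution could leave
a unit claimed twice.

## Synthetic data: what it emulates, what it does not

The generator emulates the features the method must be robust to: units
uniform over a 720 µm probe section (single 96-site, 2-column shank by
default; the 4-shank 384-site layout is available), 1/R amplitude decay
with peak ptp drawn in 80–300 µV (all included units clear the 60 µV
filter), per-step rigid drift (default 12 µm) plus per-unit z jitter
(default σ = 3 µm, accumulating as a random walk), 60% survival per
step with fresh units restoring the count, per-channel multiplicative
amplitude jitter (5%) plus additive noise (1.5 µV rms) on re-rendered
waveforms, a 10% multi-unit label fraction, and optionally tuned
Poisson visual responses (peak 20 Hz over baseline ~4 Hz) whose tuning
and temporal dynamics (per-unit onset latency 30–150 ms, exponential
decay 0.1–0.6 s) persist across sessions. The spike template is a
biphasic difference-of-exponentials with per-unit parameters — adequate
for amplitude- and shape-comparison metrics, with no biophysical claim.

Not emulated: non-rigid (depth-dependent) drift, sorter errors other
than unit turnover (no splits/merges or contamination), bursting or
non-Poisson firing, electrode-surface effects, and raw voltage traces.
Passing tests therefore demonstrate correctness of the algorithmic
chain and its behavior under the stated noise model, not performance on
any particular real dataset. One deliberate realism: because every
tuned unit shares a stimulus-locked PSTH transient, *non*-matching
pairs still show median similarity ≈ 0.7 (driven entirely by the PSTH
term; their fingerprint correlation is ≈ 0). Coincidentally similar
pairs above threshold do occur — which is exactly why the reference
criteria also demand spatial proximity.

All generator randomness flows from one mandatory seed; written
sessions and match tables are byte-identical across runs.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use 60 units/session (about
the per-shank yield of real chronic recordings), 10–20 seeds per
Monte-Carlo statement, mixture fits at n = 5000, and enumeration
oracles up to 7×7 — sizes chosen so each statement is statistically
meaningful while the whole suite stays interactive.

## Known limitations

- Matching is pairwise-greedy across the session sequence; no joint
  optimization over more than two sessions.
- The x/y degeneracy for lateral units means d_loc partly reflects
  localization artifacts; the z-threshold logic deliberately uses z
  only.
- The histogram mixture fit's c estimate is biased high when f is
  small (truncation at 50 µm); use `method="mle"` in that regime.
- Chains require passing matches in *consecutive* sessions; a unit
  missed in one session ends its chain even if recoverable later.
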
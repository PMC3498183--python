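# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-data design behind `meggraph`, and states what the validation
suite does and does not establish about real MEG data.

## Data model

A subject's recording is a `channels × samples × epochs` array at a fixed
sampling rate (full-scale defaults: 136 channels, 625 Hz, five epochs of
4096 samples = 6.554 s each). Epochs are treated as independent selections
from the resting state. Visual artifact rejection is replaced by a
deterministic amplitude threshold (`validate_epochs`): any epoch whose peak
absolute value exceeds the threshold is dropped wholesale, and a subject
failing to retain the minimum epoch count raises an error naming the
subject. This trades the flexibility of a human rater for exact
reproducibility.

## Spectral preprocessing

Seven analysis bands: delta 0.5–4, theta 4–8, lower alpha 8–10, upper alpha
10–13, beta 13–30, lower gamma 30–45, higher gamma 55–80 Hz (the 45–55 Hz
gap avoids mains interference). The filter is a 4th-order Butterworth
band-pass applied forward and backward (`sosfiltfilt`), i.e. zero-phase,
because any phase distortion would bias the phase-lag estimates
downstream; the filter family and order are free choices documented here,
not properties of the estimator. The first and last 5 % of each filtered
epoch are excluded from phase analysis (`EDGE_TRIM_FRACTION`) to suppress
filter and analytic-signal edge transients.

## Phase lag index

Instantaneous phases come from the FFT-based analytic signal; the PLI of a
channel pair is the absolute mean of the sign of the wrapped phase
difference. Conventions, fixed once:

- wrapping to (−π, π] via `angle(exp(iΔΦ))`; the boundary ΔΦ = ±π wraps to
  +π and counts as sign +1;
- ΔΦ exactly 0 contributes sign 0 (zero-lag samples carry no asymmetry
  information). Numerically, wrapped differences with magnitude below
  1e−12 are treated as exactly zero — complex products of *identical*
  signals otherwise leave ±1e−17-scale imaginary residue whose random
  signs would turn an exact zero into sampling noise;
- PLI is computed per epoch and averaged across epochs (not on
  concatenated samples), since epochs are independent selections.

Finite epochs impose a PLI noise floor: the per-epoch |mean sign| of two
*independent* narrowband signals is positive with magnitude set by the
number of phase-difference decorrelation times per epoch, and averaging
over epochs does not remove it. At 4096-sample epochs the theta-band floor
is ≈ 0.07; at 1024 samples it is ≈ 0.25. Null-sensitivity checks (volume
conduction) therefore run at the full 4096-sample epoch length, while
desk-scale analyses accept the higher floor — rank-based statistics are
unaffected by a common additive floor.

## Weighted graph metrics and surrogate normalization

Clustering uses the triple-product form C_w,i = Σ w_ik w_il w_kl / Σ w_ik
w_il (ordered and unordered pair sums cancel; implemented via matrix
powers). Path length resolves the "strongest path" notion as the minimal
total *inverse-weight* cost (Dijkstra on 1/w), under which strongly
connected pairs are close; zero-weight edges are absent (infinite cost).
The average is the harmonic mean, so disconnected pairs contribute zero
and a fully disconnected graph has undefined L_w, reported as `inf`.

Surrogates shuffle the upper-triangle weight multiset uniformly and
re-symmetrize; 1000 surrogates at full scale. One master seed spawns an
independent substream per surrogate (`numpy` `SeedSequence`), so results
do not depend on evaluation order and are reproducible. Surrogate L_w uses
the same harmonic rule, so occasional disconnected surrogates contribute
finite values rather than being dropped.

## Modularity and annealing

Weighted modularity Q = Σ_s [W_s/W_total − (d_s/2W_total)²]. The search is
Metropolis simulated annealing on C = −Q: each vertex starts in its own
module; a step moves one uniformly random vertex to a uniformly random
label in [0, N); moves that do not increase the cost are always accepted,
others with probability exp(−ΔC/T). Full-scale schedule: T₀ = 1, T ←
0.995·T every 100 steps, 10⁶ steps. ΔQ is evaluated incrementally in O(N)
per step from running per-module strength totals, and the exact Q of the
returned partition is recomputed from scratch to eliminate accumulation
drift.

Two safeguards shape the returned partition: (i) the best-Q state visited
anywhere along the walk is returned, not the final state, guarding against
late-schedule drift; (ii) the trivial single-module partition (Q = 0) is a
floor, since "no modular structure" is always an admissible answer —
relevant only for near-uniform graphs under heavily reduced schedules.
Reduced schedules used in tests and the demo preset keep the full
schedule's cooling *ratio* (one cooling event per 10⁻⁴ of the budget), so
shorter runs still end cold instead of random-walking at T ≈ 1.

Node roles: within-module degree z-score uses the population standard
deviation of the within-module strength distribution, per module;
singleton modules and zero-spread modules define Z = 0. Participation
P_i = 1 − Σ_m (κ_im/s_i)²; isolated vertices define P = 0. The network
mean of Z is ≈ 0 for every subject by construction (z-scores average to
zero within each module); it is carried through the pipeline as a
deliberately null reference metric.

## Synchronizability

S = λ₂/λ_N of the weighted Laplacian L = D − W, computed with a symmetric
eigensolver; eigenvalues below 1e−9·λ_N are clamped to zero, so
disconnected graphs report S = 0 exactly. The all-zero graph has no
spectrum to speak of and reports S = 0 with a `degenerate` flag. The
weighted (not binarized) Laplacian is used throughout, consistent with the
weighted analysis everywhere else.

## Group statistics

Per band, Kruskal–Wallis omnibus tests over the five network
characteristics (C_w/C_ws, L_w/L_ws, S, Q, P_w) form one
Benjamini–Hochberg FDR family (α = 0.05, two-sided throughout); FDR is
applied per band. Mean PLI and the mean within-module z are tested and
reported but sit outside the corrected family. Post-hoc pairwise
Mann–Whitney U tests (U = min(U_x, U_y), exact for small tie-free samples)
run only for FDR-significant metrics. Covariate correlations use Kendall
tau-b (tie-corrected), computed within each group; zero-variance inputs
return NaN as an explicit "undefined" flag. Cognitive scores are z-scored
per subtest against matched control means/SDs, averaged within domain
after conversion, then across domains. All degenerate cases (identical
values everywhere) short-circuit to H = 0, p = 1.

## Synthetic cohorts

Each channel is a phase oscillator, Euler-integrated at the sampling
interval:

    dθ_i/dt = 2π f_i + (1/N) Σ_j K_ij sin(θ_j − θ_i + A_ij)

with f_i uniform in the analysis band, K_ij = within- or between-module
coupling (rad/s) by the planted block partition, and A_ij = ±phase_lag an
*antisymmetric* frustration matrix. The antisymmetry is essential: a
symmetric lag cancels out of the pairwise phase-difference dynamics and
coupled pairs would lock at zero lag, invisible to PLI; with the
antisymmetric lag they lock near a nonzero offset. Observation:
cos θ, mixed instantaneously across channels with unit diagonal
(mixing_strength × the mean of the other channels — the volume-conduction
emulation), plus white sensor noise. No phase-diffusion term is used:
frequency detuning already decorrelates independent channels, and complete
beat cycles cancel exactly in the sign average, which a random-walk phase
would spoil.

Default couplings (within 40, between 8 rad/s, noise SD 1, mixing 0.1,
phase lag 0.6 rad) put within-module pairs above and between-module pairs
below the partial-synchronization threshold for a band-wide frequency
spread, producing graded PLI matrices with planted modular contrast.

A cohort adds: group sizes mirroring the study design (13/12/10/36 across
LGG/HGG/NGL-like patients and controls), multiplicative group effects on
the couplings (the LGG- and NGL-like groups get stronger modular contrast
and slightly lower overall coupling, the direction that lowers S and
raises normalized clustering), and a per-subject lognormal jitter (σ =
0.2) of the overall coupling level — the subject-level latent that drives
individual differences in measured synchronizability.

Clinical covariates attach to each subject's *planted* network metric,
computed on the planted coupling graph after the saturating transform
w = k/(k + 20 rad/s), which emulates how measured PLI saturates with
coupling strength (so planted and measured metrics share their monotone
drivers). Seizure frequency uses a log-linear link (positive, strictly
monotone; intercepts per group at plausible seizures/month scales),
cognitive domain z-scores a linear link with per-group, per-domain
intercepts (attention/executive deficits around −1 for the glioma-like
groups, memory ≈ 0); link noise SDs (1.2 and 0.75 on the linear
predictors) were chosen so the planted rank correlations land near the
|τ| ≈ 0.45–0.65 range reported for such cohorts. Controls carry no
clinical covariates (NaN). Epilepsy duration is a per-group lognormal with
medians on the months scale and no metric link.

What the generator does *not* emulate: realistic head geometry or forward
fields (mixing is a uniform spread, not a leadfield), 1/f background
spectra, artifacts (blinks, drowsiness), nonstationarity across epochs,
and — importantly — the study's dissociation between topology and
connectivity level: in the generator, synchronizability differences ride
partly on overall PLI-level differences, whereas the real finding is a
topological difference at comparable mean PLI. Passing tests therefore
validate the estimators and the statistical machinery, not the
neurophysiological claim itself.

## Reproducibility and problem sizes

Every stochastic component (cohort generation, surrogates, annealing)
derives its stream from a master seed through named `SeedSequence`
substreams, so reruns are bit-identical and changing, say, the surrogate
count does not perturb the cohort. The test suite and the demo preset run
desk-scale problems by design: 8–16 channels, 1024–2048-sample epochs
(null-sensitivity checks use the full 4096), 10–200 surrogates,
10³–2×10⁴ annealing steps, exhaustive oracles up to 8 vertices, and
statistics-level null-cohort simulations (200 replicates) that exercise
the omnibus+FDR procedure directly on metrics tables — the procedure only
ever sees the metrics table, so this is the component the type-I-error
property constrains. The full-scale profile (`paper` preset: 136 channels,
4096-sample epochs, 1000 surrogates, 10⁶ annealing steps, all seven bands)
is the configuration default and runs unchanged, just longer.

## Known limitations

- The annealing proposal draws labels from [0, N); it cannot split a
  module in one move, so heavily reduced schedules on large dense graphs
  can return coarse partitions (mitigated by the Q ≥ 0 floor).
- Harmonic-mean L_w is finite for disconnected graphs but `inf` for fully
  edgeless ones; downstream code must tolerate that sentinel.
- The PLI noise floor at short epochs biases absolute connectivity levels
  upward; comparisons across configurations with different epoch lengths
  are not meaningful.
- Kendall correlations with seizure frequency are computed within groups
  of ~10–13 subjects; at those sizes only |τ| ≳ 0.45 reaches nominal
  significance, matching the resolution of the original design.
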
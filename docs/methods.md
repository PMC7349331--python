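# Methods

`dlsann` implements an artificial-neural-network-assisted dynamic light
scattering (DLS) sizing procedure: synthetic DLS time-series with a known
hydrodynamic diameter are generated from the Lorentzian intensity
spectrum, their intensity autocorrelations are estimated and normalized,
a reference single-exponential fit provides per-series diameters, and a
350-26-1 feed-forward network is trained to map the first 350
autocorrelation lags directly to the diameter. A monitoring pipeline
applies the trained network to long-duration experiments (e.g. yeast
fermentation followed for days with one short record every 30 minutes).

## Physical model

A mono-dispersed suspension of Brownian scatterers illuminated by a
coherent beam produces an intensity autocorrelation

    G(tau) = A exp(-2 D q^2 tau) + B,

with scattering vector modulus `q = 4 pi n / lambda sin(theta/2)` and
Einstein–Stokes diffusion coefficient `D = k_B T / (3 pi eta d)`, `d`
the hydrodynamic diameter. Equivalently the intensity spectrum is the
Lorentzian `S(f) = a0 a1 / ((2 pi f)^2 + a1^2)` with half-width
`a1 = 2 D q^2` (rad/s). All sizing in this package is "DLS average
diameter": the diameter of spheres that diffuse like the observed
scatterers.

Default optical setup (all overridable in `OpticalSetup` or a YAML
config): He-Ne laser, `lambda` = 633 nm; scattering angle 90 degrees;
solvent refractive index 1.331 (water at 633 nm); temperature 295.15 K
(22 C); dynamic viscosity 9.5e-4 Pa s (water at 22 C); sampling rate
16 kHz; Boltzmann constant fixed at the exact SI value 1.380649e-23 J/K.
Note that for sugar syrups the true viscosity is higher than water's;
since `d` enters only through `eta * d`, a viscosity error rescales every
reported diameter by the same factor.

## Synthetic time-series

A clean series of `N` = 32,768 samples is the harmonic sum
`x(t_k) = sum_i sqrt(S(f_i)) sin(2 pi f_i t_k + phi_i)` with phases
i.i.d. uniform on (0, 2 pi). The frequency grid is the real-FFT bin grid
`f_i = i f_s / N`, `i = 0..N/2` — 16,385 equally spaced frequencies from
0 to the Nyquist frequency. (The zero bin contributes a random constant
offset; autocorrelation normalization removes it.) On this grid the sum
is evaluated exactly by one inverse real FFT; a literal O(N · N_f)
summation is retained as a reference implementation and the two are
verified to agree to 1e-9 on small instances. The Lorentzian scale `a0`
defaults to 50; it cancels in the normalized autocorrelation, so sizing
is insensitive to it.

Measurement noise is added in two stages, each scaled by the
peak-to-peak amplitude `A_ts` of the series as it stands:

* power-grid noise: harmonics `50 i` Hz for `i = 1..round(f_s/50)` (320
  at 16 kHz) with amplitudes `0.03 A_ts exp(-0.25 i)` and random phases.
  Harmonics above Nyquist are injected as written and alias, as they
  would in a real acquisition. When `f_s/50` is an integer the noise is
  periodic over `f_s/50` samples and is evaluated on one period and
  tiled.
* broadband noise: 300 sinusoids at frequencies uniform on [1, f_s] with
  amplitudes `0.01 A_ts exp(-0.005 i)` and random phases.

The training corpus holds one noisy series per diameter on an arithmetic
grid (defaults 25–6000 nm; the package's desk-scale grid step is 5 nm,
giving 1,196 series; a 0.5 nm step giving 11,951 series is supported but
takes roughly ten times longer to simulate and much longer to train).
Per-series seeds derive from a single master seed through
`numpy.random.SeedSequence`, so any row is independently reproducible
and the whole corpus is bit-reproducible.

What the generator does *not* emulate: photon shot noise and detector
dark counts, polydisperse mixtures, number fluctuations, multiple
scattering, and drifts of the optical alignment. Passing tests therefore
demonstrate correctness of the method under its own stated noise model,
not performance on arbitrary real data.

## Autocorrelation and normalization

The raw estimator is the sample autocorrelation without mean removal,
`G[k] = (1/(N-k)) sum_t x[t] x[t+k]` (computed via FFT). Division by the
per-lag product count, rather than by `N`, avoids a `(1-k/N)` taper that
would otherwise bias slow decays; it also makes a constant series give an
exactly flat curve.

Normalization is two steps: subtract the baseline `B_hat` and divide by
the coherent amplitude `A_hat`, then anchor the lag-0 value to 1 (the
software counterpart of matching the detector to a single speckle, which
sets the spatial coherence factor to one). `A_hat` and `B_hat` are
estimated jointly by a deterministic profiled fit of
`A exp(-gamma tau) + B` over lags 1..(8·350−1): for each candidate
`gamma` on a 200-point log grid the linear pair (A, B) has a closed
form; the best grid point is refined by bounded scalar minimization.

Two numerical points motivated this estimator (both verified by
measurement during development):

* the broadband noise adds 20–40% extra variance that decorrelates
  within a single lag; reading the amplitude off `G[0]` therefore
  underestimates the coherent contrast and biases *every* diameter about
  20% low. Profiling over lags >= 1 ignores the spike.
* a tail-mean baseline over a 2·350-lag window is biased for diameters
  above ~4 um (the decay has not finished) and noisy; the joint fit over
  an 8·350-lag window uses all lags and is much more stable.

An already-normalized curve re-normalizes to itself to ~1e-12
(idempotence), and an exact `A exp(-2 D q^2 tau) + B` input yields
exactly `exp(-2 D q^2 tau)`.

## Reference fit

The reference sizing procedure fits the single-parameter model
`exp(-2 D(d) q^2 tau)` to the normalized 350-lag curve by unweighted
least squares. The optimizer is deterministic: a coarse scan over 200
log-spaced diameters in [10 nm, 20 um] followed by bounded scalar
refinement between the neighbours of the best grid point; a minimizer at
the search boundary is flagged `converged=False`. On noiseless curves the
fit recovers the diameter to better than 1e-6 relative across
25–6000 nm.

Measured truth-accuracy on *noisy* single records (the package's own
study conditions, 12 seeds per diameter): mean bias about +17% at 50 nm,
+10% at 100 nm, between -3% and +2% from 0.5 to 6 um, with a
seed-to-seed standard deviation of 2–7%. The small-diameter bias is
caused by the deterministic autocorrelation ripple of the 50 Hz
harmonics, which mimics a slowly decaying component once the true signal
has decayed; the scatter is the genuine information limit of a single
2-second record. These numbers bound what *any* downstream consumer of
the reference fit (including the network, whose targets they are) can
achieve against ground truth.

## The network

Architecture 350-26-1: inputs are the first 350 normalized
autocorrelation lags fed in raw units; hidden layer 26 tanh units;
output one tanh unit mapped affinely from [-0.9, 0.9] to the logarithm
of the diameter over the training range. Two scaling choices differ from
the more common defaults, both adopted after measurement:

* per-lag min-max input rescaling was rejected: late lags are
  noise-dominated with a small dynamic range, and stretching them to
  [-1, 1] injects ~340 high-amplitude noise coordinates (range maxima
  worsened several-fold). Raw ACR values already share a physical scale.
* a linear diameter target was rejected: with a span of 25–6000 nm a
  fixed absolute output error costs 240 times more relative error at
  25 nm than at 6000 nm; the log target equalizes relative error, which
  is the quantity the method reports.

Targets are the reference-fit diameters, so the network learns to
reproduce the reference procedure (including its response to noise), not
the hidden ground truth.

Training is full-batch Levenberg-Marquardt on the scaled residuals with
an analytic Jacobian; damping starts at 1e-3, divides by 10 on an
accepted step and multiplies by 10 on a rejected one. With more
parameters (9,153) than desk-scale training rows, the damped step is
solved in data space via the push-through identity
`(J^T J + lam I)^{-1} J^T r = J^T (J J^T + lam I)^{-1} r`, reducing each
factorization from O(p^3) to O(n^3). The 70/15/15
train/validation/test split is a seeded shuffle. Stopping: validation
error not improving for 6 consecutive accepted steps (the best-validation
weights are restored), a training-split R-value rounding to 1 at 8
digits, or the iteration cap (150). The historical 5-digit R rule is
available (`r_stop_digits=5`) but fires long before the achievable error
floor on desk-scale corpora, because a correlation taken over a
25–6000 nm span is insensitive to small-diameter relative error.

Prediction is a fixed sequence of matrix operations (no iteration),
which is why batch inference over hundreds of curves costs microseconds
per curve while each reference fit runs an optimization.

### Accuracy at desk scale

On the desk-scale corpus (step 5 nm, 1,196 series) training reaches
exact interpolation of the training split if left running (SSE ~1e-20),
so the residual error is generalization to the held-out 30%: per-range
maxima of |d_ANN/d_ref - 1| are typically 3–10% below 350 nm and 1–3%
in 350–6000 nm, varying with the master seed (the small ranges contain
only 10–40 series, so their maxima are noisy statistics). Tighter
figures require a denser diameter grid: reproducing the reference fit's
*noise response* — which is what agreement far below the ~3% single-
record scatter means — needs many series per quasi-linear neighbourhood
of the 350-dimensional input manifold, and the density grows with the
corpus. A 0.5 nm grid (11,951 series) supplies ten times the local
sampling of the 5 nm grid; it is supported (`--step-nm 0.5`) but is a
multi-hour computation. Hidden widths of 52 and 104 and
Tikhonov-regularized variants of the optimizer were tried and do not
improve desk-scale generalization.

A network trained on *clean* curves degrades several-fold when fed noisy
curves and its worst case far exceeds a noisy-trained network's — the
reason the corpus is noisy by default. The degradation is moderate
rather than catastrophic here because the amplitude-profiled
normalization keeps noisy curves close to the clean manifold; with a
lag-0-anchored normalization the same experiment produces wild errors.

## Monitoring pipeline

`process_run` reads one series file per record (text, CSV, or 16-bit
mono WAV; WAV integer samples are used without rescaling), computes the
normalized 350-lag curve, applies the network (and optionally the
reference fit), and assigns elapsed time either uniformly (default
30 min per record) or from a manifest CSV of timestamps. Records that
fail (short series, degenerate normalization, boundary fit) are flagged,
never dropped silently, and excluded from plateau statistics by default.
`plateau_stats` reports median and quartiles of the diameter over
user-chosen, non-overlapping time intervals — the plateau summary used
for fermentation stages. Automatic change-point detection is out of
scope; intervals are chosen by the user, as in post-hoc analysis.

No real fermentation recordings ship with the package (none are publicly
deposited); the tests substitute synthetic three-plateau trajectories
and simulated runs, which exercise the pipeline but cannot validate
biology.

## Numerical and testing notes

* Problem sizes in the test suite: the corpus-level checks run on the
  5 nm desk grid; unit tests use coarser grids (24–120 series) and
  shorter series (4,096–16,384 points) chosen to keep the whole suite in
  a few minutes while preserving every code path.
* Ensemble Wiener-Khinchin check: the mean of 200 single-seed raw
  curves, normalized, matches `exp(-2 D q^2 tau)` within 0.05 at 100 nm,
  1 um and 5 um (typically within 0.01).
* Degenerate inputs: constant series (zero peak-to-peak) refuse noise
  injection; flat curves refuse normalization; a flat unit curve drives
  the reference fit to the upper search bound and is flagged.
* Model files are canonical JSON with a SHA-256 payload checksum:
  save -> load -> save is byte-identical, and truncation or tampering is
  detected at load.
* All randomness flows from explicit seeds (`numpy.random.default_rng`
  / `SeedSequence`); identical seeds give bit-identical corpora, models
  and predictions.
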
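# Methods

`cosim` couples two neural simulators that operate at different scales and
run concurrently: a spiking microcircuit simulator for a small number of
regions of interest (here: left and right hippocampal CA1), and a
rate-based neural-mass network for the rest of the brain.  Five components
cooperate: a launcher, the two simulators, and two transfer modules that
convert data between scales while moving it.  This note records the models,
the numerical choices, and the reasoning behind the places where the design
was genuinely open.

## Spiking microcircuit

Each spiking region is a sparse random (Erdős–Rényi, connection probability
`p_conn`, no autapses) network of adaptive exponential integrate-and-fire
(AdEx) neurons, one excitatory and one inhibitory homogeneous population,
with exponential conductance-based synapses:

    C dV/dt   = −g_L (V−E_L) + g_L Δ_T exp((V−V_T)/Δ_T)
                + g_ex (E_ex−V) + g_in (E_in−V) − w + I_ext
    τ_w dw/dt = a (V−E_L) − w
    τ_s dg/dt = −g

A spike is emitted when `V ≥ V_peak`; then `V ← V_reset`, `w ← w + b`, and
the neuron is clamped for `t_ref`.  Each presynaptic spike increments the
conductance of its targets by the quantal `Q_ex`/`Q_in` after the minimal
transmission delay `d_min` (within-region transmission is treated as
instantaneous, implemented as the smallest delay the integrator supports,
one step).  Every neuron additionally receives an independent Poisson
background train and `n_ext_synapses_per_neuron` external synapse slots
carrying input from the rest of the brain (below).

Numerics: fixed-step forward Euler at `dt = 0.1 ms` (the common grid shared
with the mass model; the LIF-limit test keeps the scheme honest at
`dt = 0.01 ms`).  The exponential term is evaluated with `V` clamped at
`V_peak`, the standard overflow guard.  Threshold crossings are detected at
the *start* of the following step, so a chunk `[t0, t1)` contains exactly
the spikes time-stamped in it and chunked execution is bit-identical to one
long run — the property that makes windowed co-simulation valid.  Euler
(rather than exponential) decay is also used for the conductances so that
the update is a single consistent first-order scheme.

## Neural-mass network

Each non-spiking region carries a rate node (excitatory rate ν_e,
inhibitory rate ν_i, adaptation W_ad):

    T dν_e/dt   = −ν_e + F(J_ee (ν_e + I) − J_ei ν_i − W_ad/w_scale − θ_e) + ξ
    T dν_i/dt   = −ν_i + F(J_ie (ν_e + I) − J_ii ν_i − θ_i) + ξ
    τ_w dW_ad/dt = −W_ad + b_w ν_e

with the sigmoid `F(x) = ν_max / (1 + exp(−x/σ_s))` and the delayed linear
network input `I_i(t) = G Σ_j W[i,j] ν_e,j(t − L_ij/v)`.  This is a
deliberately simple first-order sigmoidal rate model with linear
adaptation, kept behind a pluggable interface: every property the framework
is responsible for (delayed coupling, history buffers, proxy nodes,
windowed transfer, reproducibility) is model-agnostic, so a richer
mean-field closure (e.g. a second-order adaptive-exponential mean field,
whose published form also evolves rate covariances) can replace it without
touching the co-simulation machinery.  Whether the covariance should feed
back on the mean in such a closure is left to that extension.

Numerics: stochastic Heun at the shared `dt`, additive Gaussian noise of
standard deviation `noise_sigma·√dt` on both rates, a single increment
shared by predictor and corrector; the delayed coupling is evaluated once
per step at the left endpoint (delays ≫ dt make the difference O(dt²));
rates are clamped to `[0, ν_max]` after each stage.  The default node
parameters (`J_ee=0.8, J_ei=1.2, J_ie=1.2, J_ii=0.8, θ_e=4, θ_i=8, σ_s=2,
ν_max=60 Hz, T=20 ms` in the presets) were chosen by fixed-point analysis
to give a single stable operating point near 5 Hz that remains monostable
for network inputs up to ~30 Hz — an inhibition-stabilized configuration
that cannot run away to saturation when the spiking side bursts.

The excitatory-rate history is a ring buffer at `dt` resolution covering
the longest delay plus one synchronization window.  *Proxy* regions (the
spiking-scale regions) are not integrated; their ν_e history is overwritten
each window with the rates received from the spiking side.  Their recorded
value during window k is the last sample of window k−1 (a one-window
display lag; the coupling itself always reads the correctly delayed
history).  The realized initial history is written to a text file and can
be replayed (`stored` mode) for exact reproduction.

## Scale-bridging transforms

**Spikes → rates.**  The excitatory spikes of a window are counted in
non-overlapping sub-windows and divided by `N·W` (Hz).  Inside the
co-simulation the sub-window equals the integration step: the exchange is
resolved at `dt` and only *batched* per synchronization window.  This is
what makes delay aggregation exact (below); a coarser standalone window is
available in the API.

**Rates → spikes.**  The multiple interaction process (MIP): for a target
train rate r and copy probability c, a mother Poisson train of rate `r/c`
is thinned independently per child with probability c, giving child rate r
and pairwise count correlation c.  Copied spikes carry no jitter (the
canonical MIP).  Each neuron owns `n_ext` synapse slots split across source
regions by largest-remainder rounding proportional to the afferent weights;
per source j the train rate is the delayed, weighted rate `G·W[r,j]·ν_e,j`,
and a neuron's drive from j is the sum of its `s_j` child trains —
implemented as Binomial(s_j, c) copies per mother spike.  Because the MIP
correlates trains, the round-trip (rate → spikes → windowed rate) has
compound-Poisson variance `r(1−c)/(N·W) + c·r/W`, not the independent
Poisson `r/(N·W)`; the tests use the correct bound.  The default `c = 0.1`
keeps afferents quasi-independent while exercising the mechanism.

All random draws in the transformer are made in bin-major, then
source-major order, so the generator stream is identical however bins are
grouped into windows.

## Synchronization and the clock contract

The synchronization step must be a multiple of both simulators' `dt` (the
launcher enforces equal `dt`) and no longer than the minimum non-zero
inter-regional delay.  Under that bound, window k−1's outputs fully
determine every coupling input of window k, so the loop

    mass:    receive proxy rates (window k−1) → send afferent rates
             (for window k, from history) → integrate window k
    spiking: receive external spike trains (window k) → integrate window k
             → send spike block (window k)

is causal and deadlock-free; the two transfer modules sit between,
transforming while both simulators run.  The first mass-bound message (the
initial proxy window `[t0−sync, t0)`) is produced by the transformer from
the configured initial rate; the first spiking-bound message is the MIP
transform of the mass model's stored initial condition, labelled with the
first simulated window since its spikes are injected there.  Termination is
initiated by the simulators after the final window; the mass side drains
one trailing proxy window so every channel closes cleanly.

Because (i) exchanged data are resolved at `dt` and only batched, (ii) all
transformer draws are bin-major, and (iii) each component consumes its
generator at a fixed per-step rate, changing the synchronization step at
equal seeds changes *no* simulated number: spike, rate and sensor dumps are
bitwise identical (the delay-aggregation optimisation is exact).  The same
holds for chunking, for reruns, and for the choice of backend.

## Channels and backends

Each channel carries one window's payload (one-window buffering) behind the
four-function endpoint API: ready / transfer / end-transfer / release.  Two
backends implement the contract: shared-memory (components as threads, a
one-slot condition-variable buffer) and message-passing (components as
processes connected by Unix-domain sockets; the sender may run one window
ahead, the in-flight message being the buffer, with explicit
acknowledgements).  Rendezvous uses `.addr` files in the run directory,
published by the transfer modules (which are started first) and polled by
the simulators, with bind and accept split so mutually-listening components
cannot deadlock during start-up.  Every blocking call carries a timeout
(default 60 s) that converts a silent deadlock into a diagnosable error
naming the blocked endpoint.

## Sensors

ECoG is a point-dipole-in-homogeneous-medium forward model: sensor k
records `gain · Σ_i ν_e,i(t)/‖x_k − c_i‖^p`, sources are scalar (orientation
ignored — the model's two assumptions, homogeneous medium and
excitatory-only sources, contain no orientation term).  The distance
exponent defaults to `p = 2` (point-dipole far field) and is configurable
down to 1, since only "weighted by distance" is specified by the modelling
tradition this follows.  Morphology-based LFP for penetrating probes is out
of scope.

## Diagnostics

The instantaneous rate is the windowed count estimator at 1 ms bins.
Spectra are Welch periodograms (2 s Hann segments, 50 % overlap, constant
detrend), lightly smoothed over 3 bins.  A peak qualifies when its
prominence is ≥ `prominence_frac` (default 0.2) of the in-band maximum
*and* its height is ≥ `floor_ratio` (default 4) times a running median
baseline (~100 Hz window).  The baseline guard is necessary: on a
featureless spectrum the largest chi-square wiggle is always "prominent"
relative to itself, so a prominence-only rule can never report an empty
peak set; the wide median separates narrow genuine lines (which tower over
it) from the gentle broadband shaping of an asynchronous network.

Regime classification analyses the low (< 100 Hz) and high (> 100 Hz) bands
separately — a dominant slow peak would otherwise mask the much weaker
intra-burst peak under the relative-prominence rule.  Regular bursting (RB)
requires prominent peaks in both bands; otherwise a large coefficient of
variation of the 20 ms-smoothed rate (default threshold 0.3) indicates the
irregular synchronous state (IS), and a flat rate the asynchronous state
(A).  Both criteria are invariant to rate scaling.  The CV smoothing
matters: raw 1 ms bins carry Poisson counting noise whose CV depends on the
rate, not on the dynamics.

For reporting a peak *location*, `dominant_frequency` refines the top peak
as the power-weighted centroid of its half-maximum region; the acceptance
script instead reports the maximum bin of the hemisphere-averaged smoothed
PSD, which for the sharp RB peaks equals the peak bin and for the broad IS
bump is the bump mode.

## Regime presets

Three shipped parameter files (JSON, one object per module section) realize
the canonical regimes in the full co-simulation.  The published parameter
tables for these regimes are not reproduced here; the presets follow the
qualitative recipes (IS: fluctuation-driven with strong slow
spike-triggered adaptation; A: reduced adaptation, extra Poisson drive,
stronger inhibition, reduced coupling and noise; RB: raised voltage reset
and leak reversal with strong, fast adaptation) and were tuned empirically
to the stated spectral signatures.  Key excitatory-cell values:

| regime | E_L (mV) | V_reset (mV) | b (pA) | τ_w (ms) | Q_ex (nS) | background (Hz) |
|--------|----------|--------------|--------|----------|-----------|-----------------|
| A      | −63      | −65          | 0      | 500      | 7.5       | 200             |
| IS     | −63      | −65          | 100    | 680      | 7.5       | 25              |
| RB     | −54      | −48          | 1200   | 25       | 10        | 20              |

The RB mechanism: `V_reset > V_T` makes neurons re-fire immediately after
reset, so the population locks into refractory-paced firing at
`1/(t_ref + recharge) ≈ 160 Hz` during a burst, while the strong fast
adaptation (`b = 1200 pA`, `τ_w = 25 ms`) terminates each burst and the
elevated leak reversal re-ignites the network deterministically, setting a
regular ~6 Hz burst rhythm.  The IS mechanism is adaptation-gated UP/DOWN
alternation whose timing is noise-driven and therefore irregular; its
spectral bump (centred near 3 Hz) is intrinsically broad, which is why the
acceptance measurement averages both hemispheres over a long run.

**Scale.**  The presets use 2,000 neurons per region (1,600 excitatory,
400 inhibitory) with quantal conductances rescaled by the size ratio from
the 10,000-neuron configuration (`Q_ex 1.5 → 7.5 nS`, `Q_in 5 → 25 nS`),
preserving the mean recurrent drive; the brain network uses 16 regions.
These sizes keep a full multi-second co-simulation comfortably on one CPU
core while leaving the regimes intact; the same presets run unchanged at
the larger size by resetting `n_ex`, `n_in` and the quantal weights.

## Synthetic connectome

The fixture generator stands in for a tracer-derived atlas: centres drawn
uniformly in a ~10 mm cube with a 2 mm minimum separation (so no delay
collapses below the synchronization window), the two spiking regions placed
mirror-symmetrically; directed log-normal weights on an Erdős–Rényi
skeleton (the framework never assumes weight symmetry); symmetric tract
lengths equal to Euclidean distance times a tortuosity factor uniform in
[1.0, 1.5], so paths are never shorter than a straight line.  Delays are
tract length over conduction speed, rounded *up* to a step multiple and
clamped at one step, so batched communication can never arrive early.  Row
normalization of weights (each region's afferents sum to 1) keeps total
afferent drive comparable across regions; the presets use full density, as
in tracer connectomes, which also equalizes the `Σ_j W²` factor that sets
the external drive of the two hemispheres.  What the generator does not
emulate: realistic geometry, community structure, hemispheric asymmetries
of real atlases — so passing tests demonstrate the machinery and regime
mechanisms, not quantitative fidelity to a particular animal.

## Timers

Every component accumulates five wall-clock categories — initialisation,
simulation, wait (blocking inside ready/transfer), io (exchange minus
wait), ending — written per component as CSV and aggregated into one table.
Wall-clock behaviour is asserted only qualitatively (categories sum to at
most the component's wall time; an artificially slowed spiking side makes
the mass network's wait dominate its simulation time), since absolute
timings are hardware-bound.

## Known limitations

- The mass model is a stand-in closure; quantitative whole-brain rates are
  not matched to any published mean-field.
- Proxy rates are displayed with a one-window lag in the mass recordings
  (coupling is unaffected).
- The message-passing backend uses Unix-domain sockets on one machine;
  cross-machine distribution is out of scope.
- The IS spectral bump is broad by nature; its reported peak carries
  ±0.5–1 Hz realization-to-realization spread even with 40 s of data.
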
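# cosim — parallel multiscale neural co-simulation

`cosim` embeds spiking microcircuit models of selected brain regions inside
a rate-based whole-brain network and runs both scales *concurrently*,
exchanging data through transfer modules once per synchronization window.
It is aimed at computational neuroscientists who want cellular-level
resolution (spikes, membrane voltages, adaptation currents) in a region of
interest — here, left and right hippocampal CA1 — while the rest of the
brain is simulated cheaply at the population level, with sensor-level
output (ECoG) that can be compared with experiments.

The co-simulation follows a five-component design: a launcher, two
simulators, and two transfer modules, each of the latter made of a receive
interface, a transformer and a send interface.

**Spiking scale.** Each flagged region is a sparse random network of
adaptive exponential integrate-and-fire neurons (one excitatory, one
inhibitory population) with conductance-based synapses:

    C dV/dt   = −g_L (V−E_L) + g_L Δ_T e^{(V−V_T)/Δ_T} + g_ex (E_ex−V) + g_in (E_in−V) − w + I
    τ_w dw/dt = a (V−E_L) − w,   spike: V→V_reset, w→w+b

**Brain-network scale.** Every other region carries a neural-mass node
(excitatory/inhibitory rates with a sigmoidal transfer and linear
adaptation) coupled linearly through the connectome with axonal delays
`L_ij / v`.  Spiking regions appear in the network as *proxy nodes* whose
excitatory rate is supplied by the spiking simulator.

**Scale bridging.** Spikes → rates by windowed population averaging;
rates → spikes by the multiple interaction process (MIP): a mother Poisson
train of rate r/c thinned with copy probability c yields spike trains with
per-train rate r and pairwise correlation c.

**Synchronization.** Data are exchanged every `sync_step`, bounded above by
the minimum inter-regional transmission delay; under that bound the
windowed exchange is *exactly* equivalent to step-by-step exchange, and the
package guarantees it bitwise (see `docs/methods.md`).  Components run
either as threads (shared memory) or as processes (message passing over
Unix sockets with rendezvous files); both give identical results.

## Worked example

Run the regular-bursting preset for 11 s of biological time and analyse
the left-CA1 spiking output:

```bash
cosim run --regime RB --t-end 11000 --out /tmp/rb_run
cosim analyze --run /tmp/rb_run --band 1 250
```

which prints (runtime ≈ a minute on one core):

```
run complete: /tmp/rb_run
  launcher: total 61.79 s
  mass: total 56.46 s
  spiking: total 56.45 s
  transfer_m2s: total 56.51 s
  transfer_s2m: total 56.54 s
spikes_CA1-L: regime RB
  peak 6.50 Hz power 2716
  peak 157.50 Hz power 34.73
  peak 163.50 Hz power 28.68
peak table: /tmp/rb_run/analysis_peaks.csv
```

The five totals are the per-component wall-clock times of the concurrently
running design-pattern components (the launcher's includes waiting for all
of them); `timers/report.csv` splits each into initialisation, simulation,
wait, io and ending.  The analysis classifies the excitatory population
rate as regular bursting (RB): a dominant burst-rhythm peak near 6 Hz
together with a much weaker intra-burst peak near 160 Hz set by the
refractory-paced firing inside each burst (this 11 s single-hemisphere
estimate splits it across two bins around 160 Hz; the longer averaged
measurement in the acceptance script resolves one peak).  The run
directory contains the spike dump
(`spiking/spikes_CA1-L.txt`), voltage and adaptation recordings of 20
neurons per population, per-region mass rates (`mass/rates.txt`) and the
16-channel ECoG forward solution (`sensors/ecog.txt`).

Presets `A` (asynchronous: flat rate, featureless spectrum) and `IS`
(irregular synchronous: a broad slow peak near 3 Hz from adaptation-gated
UP/DOWN alternation) ship alongside `RB`; `cosim fixtures` generates
standalone synthetic connectomes and sensor layouts, and `cosim transform`
exposes the spike/rate conversions for file-to-file use.

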
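"""Spiking microcircuit of one brain region.

Two homogeneous populations (excitatory, inhibitory) of adaptive exponential
integrate-and-fire (AdEx) neurons with exponential conductance-based
synapses, random (Erdos-Renyi) within-region connectivity, independent
Poisson background drive and externally injected spike trains standing in
for the input from the rest of the brain.

The membrane equation per neuron is

    C dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_T)/Delta_T)
              + g_ex (E_ex - V) + g_in (E_in - V) - w + I_ext
    tau_w dw/dt = a (V - E_L) - w
    tau dg/dt = -g                     (each synaptic conductance)

with spike emission when V crosses ``V_peak``: V is reset to ``V_reset``,
the adaptation current jumps by ``b`` and the neuron is clamped for the
refractory period ``t_ref``.  Integration is fixed-step forward Euler,
which keeps windowed (chunked) simulation exactly equivalent to one long
run -- the property that makes co-simulation in synchronization windows
valid.  The exponential term is evaluated with V clamped at ``V_peak`` to
avoid overflow.

Within-region synaptic transmission uses the smallest supported delay
(``d_min``, one integration step by default); spikes are delivered as
instantaneous conductance increments ``Q_ex``/``Q_in``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import (
    ContractError,
    IntegrationError,
    ParameterError,
    SequencingError,
    ValidationError,
)

__all__ = [
    "AdExParams",
    "SynapseParams",
    "SpikeBlock",
    "SpikingNetwork",
    "adex_excitatory",
    "adex_inhibitory",
    "build_spiking_region",
    "adex_step",
    "inject_external_spike_trains",
    "run_chunk",
    "poisson_counts",
    "apportion_slots",
]


@dataclass
class AdExParams:
    """AdEx neuron parameters (units: pF, nS, mV, ms, pA)."""

    C: float = 200.0
    g_L: float = 10.0
    E_L: float = -64.0
    V_T: float = -50.0
    Delta_T: float = 2.0
    V_peak: float = 0.0
    V_reset: float = -65.0
    tau_w: float = 500.0
    a: float = 0.0
    b: float = 60.0
    t_ref: float = 5.0

    def __post_init__(self) -> None:
        for name in ("C", "g_L", "tau_w", "t_ref"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"AdEx parameter {name} must be > 0, got {getattr(self, name)}")
        if self.Delta_T < 0:
            raise ParameterError(f"Delta_T must be >= 0, got {self.Delta_T}")
        if self.V_reset >= self.V_peak:
            raise ParameterError(
                f"V_reset ({self.V_reset}) must be below V_peak ({self.V_peak})"
            )


def adex_excitatory(**overrides) -> AdExParams:
    """Default regular-spiking excitatory cell (pyramidal-like)."""
    return AdExParams(**overrides)


def adex_inhibitory(**overrides) -> AdExParams:
    """Default fast-spiking inhibitory cell (basket-like): sharp spike
    initiation, no adaptation."""
    kw = dict(E_L=-65.0, Delta_T=0.5, tau_w=1.0, a=0.0, b=0.0)
    kw.update(overrides)
    return AdExParams(**kw)


@dataclass
class SynapseParams:
    """Exponential conductance-based synapse parameters."""

    E_ex: float = 0.0
    E_in: float = -80.0
    tau_ex: float = 5.0
    tau_in: float = 5.0
    Q_ex: float = 1.5
    Q_in: float = 5.0
    p_conn: float = 0.05
    d_min: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_ex <= 0 or self.tau_in <= 0:
            raise ParameterError("synaptic time constants must be > 0")
        if self.Q_ex < 0 or self.Q_in < 0:
            raise ParameterError("quantal conductances must be >= 0")
        if not (0.0 < self.p_conn <= 1.0):
            raise ParameterError(f"p_conn must be in (0, 1], got {self.p_conn}")
        if self.E_in >= self.E_ex:
            raise ParameterError("E_in must be below E_ex")
        if self.d_min <= 0:
            raise ParameterError("d_min must be > 0")


@dataclass
class SpikeBlock:
    """Spike events (neuron id, time) in a half-open window [t0, t1)."""

    t0: float
    t1: float
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.t1 <= self.t0:
            raise ValidationError(f"window [{self.t0}, {self.t1}) is empty or inverted")
        if self.ids.shape != self.times.shape:
            raise ValidationError("ids and times must have the same length")
        if self.times.size:
            if not np.all(np.isfinite(self.times)):
                raise ValidationError("spike times must be finite")
            if np.any(self.times < self.t0 - 1e-9) or np.any(self.times >= self.t1 - 1e-9):
                raise ValidationError(
                    f"spike times must lie in [{self.t0}, {self.t1})"
                )
            if np.any(np.diff(self.times) < 0):
                order = np.argsort(self.times, kind="stable")
                self.times = self.times[order]
                self.ids = self.ids[order]

    @property
    def events(self) -> list[tuple[int, float]]:
        return list(zip(self.ids.tolist(), self.times.tolist()))

    @property
    def n_events(self) -> int:
        return int(self.ids.size)

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


def apportion_slots(weights: np.ndarray, n_slots: int) -> np.ndarray:
    """Split ``n_slots`` across sources proportionally to ``weights`` using
    largest-remainder rounding, so the result sums exactly to ``n_slots``."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ParameterError("afferent weights must be non-negative")
    total = w.sum()
    if n_slots < 0:
        raise ParameterError("n_slots must be >= 0")
    if total == 0 or n_slots == 0:
        return np.zeros(w.size, dtype=int)
    quota = n_slots * w / total
    base = np.floor(quota).astype(int)
    remainder = quota - base
    missing = n_slots - int(base.sum())
    if missing > 0:
        # stable tie-break: larger remainder first, then lower index
        order = np.lexsort((np.arange(w.size), -remainder))
        base[order[:missing]] += 1
    return base


def poisson_counts(
    rate_hz: float, n_neurons: int, n_steps: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent Poisson event counts per neuron per time step.

    ``rate_hz`` is in Hz, ``dt`` in ms; the per-step mean is rate*dt/1000.
    """
    if rate_hz < 0:
        raise ParameterError(f"rate must be >= 0, got {rate_hz}")
    lam = rate_hz * dt * 1e-3
    return rng.poisson(lam, size=(n_steps, n_neurons))


class SpikingNetwork:
    """One spiking-scale brain region.

    Built by :func:`build_spiking_region`.  Neurons ``0..n_ex-1`` are
    excitatory, ``n_ex..n-1`` inhibitory.  State advances in chunks whose
    length equals the co-simulation synchronization window; chunk
    concatenation is bitwise-equivalent to one long run at equal seeds.
    """

    def __init__(
        self,
        adex_ex: AdExParams,
        adex_in: AdExParams,
        syn: SynapseParams,
        n_ex: int,
        n_in: int,
        n_ext_synapses_per_neuron: int,
        seed: int,
        afferent_weights: np.ndarray | None = None,
        dt: float = 0.1,
        background_rate_hz: float = 0.0,
        I_ext_pA: float | np.ndarray = 0.0,
        n_record: int = 20,
        record_interval_ms: float = 1.0,
    ) -> None:
        if n_ex < 1 or n_in < 1:
            raise ParameterError("n_ex and n_in must be >= 1")
        if dt <= 0:
            raise ParameterError("dt must be > 0")
        if syn.d_min < dt - 1e-12:
            raise ParameterError(
                f"d_min ({syn.d_min}) must be at least one integration step ({dt})"
            )
        if background_rate_hz < 0:
            raise ParameterError("background rate must be >= 0")
        self.n_ex, self.n_in = int(n_ex), int(n_in)
        self.n = self.n_ex + self.n_in
        self.syn = syn
        self.dt = float(dt)
        self.params_ex, self.params_in = adex_ex, adex_in
        self.background_rate_hz = float(background_rate_hz)
        self.rng = np.random.default_rng(seed)

        def pervec(name: str) -> np.ndarray:
            v = np.empty(self.n)
            v[: self.n_ex] = getattr(adex_ex, name)
            v[self.n_ex:] = getattr(adex_in, name)
            return v

        self._C = pervec("C")
        self._g_L = pervec("g_L")
        self._E_L = pervec("E_L")
        self._V_T = pervec("V_T")
        self._Delta_T = pervec("Delta_T")
        self._V_peak = pervec("V_peak")
        self._V_reset = pervec("V_reset")
        self._tau_w = pervec("tau_w")
        self._a = pervec("a")
        self._b = pervec("b")
        self._t_ref = pervec("t_ref")
        self.I_ext = np.broadcast_to(np.asarray(I_ext_pA, dtype=float), (self.n,)).copy()

        # precomputed integration constants (Delta_T = 0 disables the exp term)
        has_dt = self._Delta_T > 0
        self._gLDT = np.where(has_dt, self._g_L * self._Delta_T, 0.0)
        self._inv_DT = np.where(has_dt, 1.0 / np.where(has_dt, self._Delta_T, 1.0), 0.0)
        self._inv_C = 1.0 / self._C
        self._inv_tau_w = 1.0 / self._tau_w
        self._decay_ex = 1.0 - dt / syn.tau_ex
        self._decay_in = 1.0 - dt / syn.tau_in

        self._d_steps = max(1, int(round(syn.d_min / dt)))

        # external input slots per source region (identical for every neuron)
        self.n_ext_synapses_per_neuron = int(n_ext_synapses_per_neuron)
        if afferent_weights is None:
            afferent_weights = np.empty(0)
        self.ext_slots = apportion_slots(afferent_weights, self.n_ext_synapses_per_neuron)

        self._build_connectivity()

        # state
        self.V = self._E_L.copy()
        self.w = np.zeros(self.n)
        self.g_ex = np.zeros(self.n)
        self.g_in = np.zeros(self.n)
        self.ref = np.zeros(self.n)
        self._step = 0  # absolute step counter; time = _step * dt
        self._horizon = 0
        self._arr_ex = np.zeros((1, self.n))
        self._arr_in = np.zeros((1, self.n))
        self.n_resets = 0

        # recording: first n_record of each population at record_interval
        self.record_interval_ms = float(record_interval_ms)
        self._rec_stride = max(1, int(round(record_interval_ms / dt)))
        nr = min(int(n_record), self.n_ex, self.n_in)
        self.flagged = np.concatenate(
            [np.arange(nr), self.n_ex + np.arange(nr)]
        ).astype(int)

    # -- construction ---------------------------------------------------

    def _build_connectivity(self) -> None:
        """Erdos-Renyi: every ordered pair (i != j) connected independently
        with probability p_conn; no self-connections."""
        n, p = self.n, self.syn.p_conn
        block = 512
        cols = []
        for c0 in range(0, n, block):
            c1 = min(c0 + block, n)
            mask = self.rng.random((n, c1 - c0)) < p
            idx = np.arange(c0, c1)
            mask[idx, idx - c0] = False  # no autapses
            cols.append(sparse.csc_matrix(mask))
        A = sparse.hstack(cols, format="csc")
        # adjacency stored column-wise: _adj_indices[_adj_ptr[j]:_adj_ptr[j+1]]
        # are the targets of source neuron j
        self._adj_ptr = A.indptr
        self._adj_indices = A.indices
        self.n_synapses = int(A.nnz)

    def _delivery(self, sources: np.ndarray) -> np.ndarray:
        """Per-target synapse counts from the given source neurons."""
        ptr, ind = self._adj_ptr, self._adj_indices
        chunks = [ind[ptr[j]:ptr[j + 1]] for j in sources]
        if not chunks:
            return np.zeros(self.n)
        targets = np.concatenate(chunks)
        return np.bincount(targets, minlength=self.n).astype(float)

    # -- event scheduling ----------------------------------------------

    def _ensure_horizon(self, steps_ahead: int) -> None:
        need = steps_ahead + 1
        if need <= self._horizon:
            return
        new_h = max(need, 2 * self._horizon, 16)
        new_ex = np.zeros((new_h, self.n))
        new_in = np.zeros((new_h, self.n))
        for k in range(self._horizon):
            abs_k = self._step + k
            new_ex[abs_k % new_h] = self._arr_ex[abs_k % self._horizon]
            new_in[abs_k % new_h] = self._arr_in[abs_k % self._horizon]
        self._arr_ex, self._arr_in = new_ex, new_in
        self._horizon = new_h

    def _schedule(self, abs_step: int, increments: np.ndarray, inhibitory: bool) -> None:
        ahead = abs_step - self._step
        if ahead < 0:
            raise SequencingError("cannot schedule a delivery in the past")
        self._ensure_horizon(ahead)
        buf = self._arr_in if inhibitory else self._arr_ex
        buf[abs_step % self._horizon] += increments

    @property
    def time(self) -> float:
        return self._step * self.dt

    # -- external input -------------------------------------------------

    def inject_external_spike_trains(
        self, trains: list[np.ndarray], window: tuple[float, float]
    ) -> None:
        """Enqueue one excitatory spike train per neuron.

        Each external spike becomes a conductance increment ``Q_ex`` at its
        time plus the minimal transmission delay ``d_min``.
        """
        t0, t1 = window
        if len(trains) != self.n:
            raise ContractError(
                f"expected {self.n} trains (one per neuron), got {len(trains)}"
            )
        for nid, tr in enumerate(trains):
            tr = np.asarray(tr, dtype=float)
            if tr.size == 0:
                continue
            if np.any(tr < t0 - 1e-9) or np.any(tr >= t1 - 1e-9):
                raise ContractError(
                    f"train for neuron {nid} has spikes outside [{t0}, {t1})"
                )
            steps = np.floor(tr / self.dt + 1e-9).astype(int) + self._d_steps
            for s in steps:
                inc = np.zeros(self.n)
                inc[nid] = self.syn.Q_ex
                self._schedule(int(s), inc, inhibitory=False)

    def inject_external_counts(self, counts: np.ndarray, t0: float) -> None:
        """Vectorized external drive: ``counts[k, i]`` spikes arrive on the
        excitatory conductance of neuron ``i`` in the dt-bin starting at
        ``t0 + k*dt`` (plus the minimal delay d_min)."""
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[1] != self.n:
            raise ContractError(
                f"counts must be (n_steps, {self.n}), got {counts.shape}"
            )
        base = int(round(t0 / self.dt))
        for k in range(counts.shape[0]):
            row = counts[k]
            if row.any():
                self._schedule(
                    base + k + self._d_steps, self.syn.Q_ex * row.astype(float), False
                )

    # -- integration ----------------------------------------------------

    def step(
        self,
        I_ext: np.ndarray | None = None,
        _bg_counts: np.ndarray | None = None,
    ) -> np.ndarray:
        """Advance one forward-Euler step; returns ids of neurons that
        spiked at the *start* of this step (threshold crossings produced by
        the previous update)."""
        dt = self.dt
        t = self._step * dt
        # 1. spike detection & reset (crossings from the previous update)
        spikers = np.flatnonzero(self.V >= self._V_peak)
        if spikers.size:
            self.V[spikers] = self._V_reset[spikers]
            self.w[spikers] += self._b[spikers]
            self.ref[spikers] = self._t_ref[spikers]
            self.n_resets += spikers.size
            exc = spikers[spikers < self.n_ex]
            inh = spikers[spikers >= self.n_ex]
            if exc.size:
                self._schedule(self._step + self._d_steps,
                               self.syn.Q_ex * self._delivery(exc), inhibitory=False)
            if inh.size:
                self._schedule(self._step + self._d_steps,
                               self.syn.Q_in * self._delivery(inh), inhibitory=True)
        # 2. deliver conductance increments scheduled for this step
        if self._horizon:
            slot = self._step % self._horizon
            self.g_ex += self._arr_ex[slot]
            self.g_in += self._arr_in[slot]
            self._arr_ex[slot] = 0.0
            self._arr_in[slot] = 0.0
        # 3. Poisson background onto the excitatory conductance
        if self.background_rate_hz > 0:
            if _bg_counts is None:
                lam = self.background_rate_hz * dt * 1e-3
                _bg_counts = self.rng.poisson(lam, self.n)
            self.g_ex += self.syn.Q_ex * _bg_counts
        # 4. forward-Euler update from the state at time t
        V, w = self.V, self.w
        I_drive = self.I_ext if I_ext is None else np.broadcast_to(I_ext, (self.n,))
        # exp term clamped at V_peak: its largest argument is (V_peak-V_T)/Delta_T
        exp_term = self._gLDT * np.exp(
            (np.minimum(V, self._V_peak) - self._V_T) * self._inv_DT
        )
        I_syn = self.g_ex * (self.syn.E_ex - V) + self.g_in * (self.syn.E_in - V)
        dV = (-self._g_L * (V - self._E_L) + exp_term + I_syn - w + I_drive) * self._inv_C
        dw = (self._a * (V - self._E_L) - w) * self._inv_tau_w
        V += (dt * (self.ref <= 0)) * dV
        w += dt * dw
        self.g_ex *= self._decay_ex
        self.g_in *= self._decay_in
        np.maximum(self.ref - dt, 0.0, out=self.ref)
        if not np.all(np.isfinite(V)):
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise IntegrationError(
                f"membrane potential of neuron {bad} became non-finite at t={t:.3f} ms"
            )
        self._step += 1
        return spikers

    def run_chunk(
        self,
        t0: float,
        t1: float,
        external_trains: list[np.ndarray] | None = None,
        external_counts: np.ndarray | None = None,
        I_ext: np.ndarray | None = None,
    ) -> tuple[SpikeBlock, dict]:
        """Simulate the half-open window [t0, t1).

        Returns every spike fired in the window exactly once, plus V/w
        recordings for the flagged neurons.  Chunks must be contiguous.
        """
        if abs(t0 - self.time) > 1e-6:
            raise SequencingError(
                f"chunk [{t0}, {t1}) is not contiguous with current time {self.time}"
            )
        n_steps = int(round((t1 - t0) / self.dt))
        if n_steps < 1 or abs(n_steps * self.dt - (t1 - t0)) > 1e-6:
            raise ContractError("chunk length must be a positive multiple of dt")
        if external_trains is not None:
            self.inject_external_spike_trains(external_trains, (t0, t1))
        if external_counts is not None:
            self.inject_external_counts(external_counts, t0)
        ids_acc, times_acc = [], []
        rec_t, rec_V, rec_w = [], [], []
        # Poisson background prefetched in blocks; elementwise draw order is
        # identical to per-step draws, so chunking never shifts the stream
        bg_block: np.ndarray | None = None
        bg_pos = 0
        lam = self.background_rate_hz * self.dt * 1e-3
        for k in range(n_steps):
            if self._step % self._rec_stride == 0:
                rec_t.append(self.time)
                rec_V.append(self.V[self.flagged].copy())
                rec_w.append(self.w[self.flagged].copy())
            bg_row = None
            if lam > 0:
                if bg_block is None or bg_pos >= bg_block.shape[0]:
                    n_block = min(256, n_steps - k)
                    bg_block = self.rng.poisson(lam, size=(n_block, self.n))
                    bg_pos = 0
                bg_row = bg_block[bg_pos]
                bg_pos += 1
            t_now = self.time
            spikers = self.step(I_ext, _bg_counts=bg_row)
            if spikers.size:
                ids_acc.append(spikers)
                times_acc.append(np.full(spikers.size, t_now))
        ids = np.concatenate(ids_acc) if ids_acc else np.empty(0, dtype=np.int64)
        times = np.concatenate(times_acc) if times_acc else np.empty(0)
        block = SpikeBlock(t0=t0, t1=t1, ids=ids, times=times)
        recordings = {
            "time": np.array(rec_t),
            "V": np.array(rec_V) if rec_V else np.empty((0, self.flagged.size)),
            "w": np.array(rec_w) if rec_w else np.empty((0, self.flagged.size)),
            "neuron_ids": self.flagged.copy(),
        }
        return block, recordings


def build_spiking_region(
    adex_ex: AdExParams,
    adex_in: AdExParams,
    syn: SynapseParams,
    n_ex: int,
    n_in: int,
    n_ext_synapses_per_neuron: int = 0,
    seed: int = 0,
    afferent_weights: np.ndarray | None = None,
    **kwargs,
) -> SpikingNetwork:
    """Build one spiking region (see :class:`SpikingNetwork`)."""
    return SpikingNetwork(
        adex_ex, adex_in, syn, n_ex, n_in, n_ext_synapses_per_neuron, seed,
        afferent_weights=afferent_weights, **kwargs,
    )


def adex_step(network: SpikingNetwork, I_ext: np.ndarray | None = None) -> np.ndarray:
    """One forward-Euler step of the network (functional wrapper)."""
    return network.step(I_ext)


def inject_external_spike_trains(
    network: SpikingNetwork, trains: list[np.ndarray], window: tuple[float, float]
) -> None:
    network.inject_external_spike_trains(trains, window)


def run_chunk(network: SpikingNetwork, t0: float, t1: float, **kwargs):
    return network.run_chunk(t0, t1, **kwargs)
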
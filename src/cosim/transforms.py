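"""Scale-bridging transformations between spike trains and firing rates.

Two directions:

* spikes -> rate: non-overlapping window count, ``rate = count / (N * W)``
  with W in seconds, i.e. the population mean firing rate in Hz.  Total
  spike count is conserved across the tiling.
* rate -> spikes: the multiple interaction process (MIP).  For a target
  per-train rate r and copy probability c, a mother Poisson train of rate
  r/c is drawn and each child train independently copies each mother spike
  with probability c.  Children then have rate r and pairwise spike-count
  correlation coefficient c; c -> 0 recovers independent Poisson trains,
  c = 1 makes all children identical to the mother.  No jitter is applied
  to copied spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ParameterError
from .spiking import SpikeBlock

__all__ = [
    "TransformConfig",
    "RateSample",
    "RateWindow",
    "spikes_to_rate",
    "spikes_to_rate_array",
    "rate_to_spikes_mip",
    "mip_child_counts",
    "mip_drive",
    "units_convert",
]


@dataclass
class TransformConfig:
    """Configuration of one transfer direction."""

    window: float = 0.1          # ms, rate-sample tiling width
    n_source_neurons: int = 1
    n_target_trains: int = 1
    mip_c: float = 0.1           # MIP copy probability / pairwise correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ParameterError(f"window must be > 0, got {self.window}")
        if not (0.0 < self.mip_c <= 1.0):
            raise ParameterError(f"mip_c must be in (0, 1], got {self.mip_c}")


@dataclass
class RateSample:
    """Mean firing rate of one population over a half-open window (ms)."""

    region_id: int
    pop: str
    t0: float
    t1: float
    rate: float

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ParameterError(f"window [{self.t0}, {self.t1}) is empty or inverted")
        if self.rate < 0:
            raise ParameterError(f"rate must be >= 0, got {self.rate}")


@dataclass
class RateWindow:
    """A contiguous block of rate samples on a regular dt grid (array form
    of a RateSample sequence, used on the co-simulation fast path).

    ``values`` has shape (n_sub,) or (n_sub, n_sources); sample k covers
    [t0 + k*dt, t0 + (k+1)*dt).
    """

    t0: float
    t1: float
    dt: float
    values: np.ndarray
    sources: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_sub = int(round((self.t1 - self.t0) / self.dt))
        if n_sub < 1 or abs(n_sub * self.dt - (self.t1 - self.t0)) > 1e-6:
            raise ContractError("RateWindow duration must be a positive multiple of dt")
        if self.values.shape[0] != n_sub:
            raise ContractError(
                f"expected {n_sub} sub-window values, got {self.values.shape[0]}"
            )
        if np.any(self.values < 0):
            raise ParameterError("rates must be >= 0")

    @property
    def n_sub(self) -> int:
        return self.values.shape[0]


def spikes_to_rate_array(block: SpikeBlock, n_neurons: int, window: float) -> np.ndarray:
    """Windowed population mean rate in Hz, one value per tile of ``window``
    ms across the block, computed by histogramming event times."""
    if n_neurons < 1:
        raise ParameterError(f"n_neurons must be >= 1, got {n_neurons}")
    if window <= 0:
        raise ParameterError(f"window must be > 0, got {window}")
    duration = block.t1 - block.t0
    n_win = int(round(duration / window))
    if n_win < 1 or abs(n_win * window - duration) > 1e-6:
        raise ContractError(
            f"window {window} ms does not divide the block duration {duration} ms"
        )
    edges = block.t0 + window * np.arange(n_win + 1)
    counts, _ = np.histogram(block.times, bins=edges)
    return counts / (n_neurons * window * 1e-3)


def spikes_to_rate(
    block: SpikeBlock,
    n_neurons: int,
    window: float,
    region_id: int = 0,
    pop: str = "exc",
) -> list[RateSample]:
    """Sliding-window population rate: RateSample sequence tiling the block."""
    rates = spikes_to_rate_array(block, n_neurons, window)
    return [
        RateSample(
            region_id=region_id,
            pop=pop,
            t0=block.t0 + k * window,
            t1=block.t0 + (k + 1) * window,
            rate=float(r),
        )
        for k, r in enumerate(rates)
    ]


def _check_saturation(rate: float, c: float, dt_hint: float = 0.1) -> None:
    if rate / c * dt_hint * 1e-3 > 1.0:
        warnings.warn(
            f"mother rate {rate / c:.1f} Hz exceeds one spike per {dt_hint} ms "
            "on average; the MIP is saturating",
            RuntimeWarning,
            stacklevel=3,
        )


def rate_to_spikes_mip(
    samples: list[RateSample],
    n_trains: int,
    c: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Generate ``n_trains`` correlated spike trains from a rate profile.

    Per sample window with rate r: a mother Poisson train of rate r/c is
    drawn on the window, and each child train copies each mother spike
    independently with probability c.  Expected per-train rate is r and the
    expected pairwise spike-count correlation coefficient is c.
    """
    if not (0.0 < c <= 1.0):
        raise ParameterError(f"copy probability c must be in (0, 1], got {c}")
    if n_trains < 1:
        raise ParameterError(f"n_trains must be >= 1, got {n_trains}")
    trains: list[list[np.ndarray]] = [[] for _ in range(n_trains)]
    for s in samples:
        if s.rate == 0:
            continue
        _check_saturation(s.rate, c)
        dur_s = (s.t1 - s.t0) * 1e-3
        m = rng.poisson(s.rate / c * dur_s)
        if m == 0:
            continue
        mother = np.sort(rng.uniform(s.t0, s.t1, size=m))
        if c >= 1.0:
            for tr in trains:
                tr.append(mother.copy())
            continue
        keep = rng.random((m, n_trains)) < c
        for i in range(n_trains):
            sel = mother[keep[:, i]]
            if sel.size:
                trains[i].append(sel)
    return [
        np.concatenate(tr) if tr else np.empty(0)
        for tr in trains
    ]


def mip_child_counts(
    rates: np.ndarray,
    dt: float,
    slots: int,
    c: float,
    n_targets: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Aggregate MIP drive for targets that each own ``slots`` child trains.

    ``rates[k]`` is the per-train rate (Hz) in the dt-bin k.  For every
    mother spike, each target receives Binomial(slots, c) copies (the sum of
    its ``slots`` independent children).  Returns integer counts of shape
    (len(rates), n_targets).  This is the windowed-transfer fast path of
    :func:`rate_to_spikes_mip`; the per-bin counts define the individual
    spike trains at dt resolution.
    """
    if not (0.0 < c <= 1.0):
        raise ParameterError(f"copy probability c must be in (0, 1], got {c}")
    rates = np.asarray(rates, dtype=float)
    counts = np.zeros((rates.size, n_targets), dtype=np.int64)
    if slots == 0:
        return counts
    # bin-major draw order: the generator stream does not depend on how
    # bins are later grouped into synchronization windows
    lam = rates / c * dt * 1e-3
    for k in range(rates.size):
        m = int(rng.poisson(lam[k]))
        for _ in range(m):
            counts[k] += rng.binomial(slots, c, size=n_targets)
    return counts


def mip_drive(
    values: np.ndarray,
    dt: float,
    slots: np.ndarray,
    c: float,
    n_targets: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Summed MIP drive from several sources at once.

    ``values[k, j]`` is the per-train rate of source j in dt-bin k and
    ``slots[j]`` the number of child trains each target owns from source j.
    Draw order is bin-major, then source-major, so the generator stream is
    identical however the bins are batched into synchronization windows.
    Sources with zero slots draw nothing.
    """
    if not (0.0 < c <= 1.0):
        raise ParameterError(f"copy probability c must be in (0, 1], got {c}")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    slots = np.asarray(slots, dtype=int)
    if slots.shape[0] != values.shape[1]:
        raise ContractError("slots must have one entry per source")
    active = np.flatnonzero(slots > 0)
    counts = np.zeros((values.shape[0], n_targets), dtype=np.int64)
    if active.size == 0:
        return counts
    lam = values[:, active] / c * dt * 1e-3
    for k in range(values.shape[0]):
        mothers = rng.poisson(lam[k])
        for idx in np.flatnonzero(mothers):
            s = int(slots[active[idx]])
            for _ in range(int(mothers[idx])):
                counts[k] += rng.binomial(s, c, size=n_targets)
    return counts


_UNIT_FACTORS = {
    ("Hz", "Hz"): 1.0,
    ("Hz", "spikes_per_ms_per_neuron"): 1e-3,
    ("spikes_per_ms_per_neuron", "Hz"): 1e3,
    ("spikes_per_ms_per_neuron", "spikes_per_ms_per_neuron"): 1.0,
}


def units_convert(rate, from_unit: str, to_unit: str):
    """Convert between Hz and spikes/ms/neuron (factor 1000)."""
    try:
        factor = _UNIT_FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise ParameterError(f"unknown unit conversion {from_unit!r} -> {to_unit!r}")
    return np.asarray(rate) * factor if isinstance(rate, np.ndarray) else rate * factor
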
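"""Rate-based whole-brain network with delayed connectome coupling.

Each region holds a neural-mass node: excitatory and inhibitory population
rates (nu_e, nu_i, Hz) and an adaptation variable W_ad (pA), evolving as

    T  d nu_e/dt = -nu_e + F(J_ee (nu_e + I) - J_ei nu_i - W_ad/w_scale - theta_e) + noise
    T  d nu_i/dt = -nu_i + F(J_ie (nu_e + I) - J_ii nu_i - theta_i) + noise
    tau_w d W_ad/dt = -W_ad + b_w nu_e

with the sigmoidal transfer F(x) = nu_max / (1 + exp(-x / sigma_s)) and
I the delayed network input

    I_i(t) = G * sum_{j != i} W[i, j] * nu_e_j(t - delay[i, j]).

This is a deliberately simple first-order sigmoidal rate model with linear
adaptation behind a pluggable interface: every framework property exercised
here (delayed linear coupling, history buffers, proxy nodes, windowed
transfer) is model-agnostic, so richer mean-field closures can be swapped
in without touching the co-simulation machinery.

Integration is stochastic Heun with additive Gaussian noise on the rates
(one increment per step, shared between predictor and corrector; the
delayed coupling is evaluated once per step at the left endpoint).  Rates
are clamped to [0, nu_max] after every update.

Proxy regions are the interface to an external simulator: their excitatory
rate history is overwritten by supplied data and their own dynamics are not
integrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectome import Connectome
from .errors import (
    ContractError,
    InitializationError,
    IntegrationError,
    ParameterError,
    SequencingError,
)
from .transforms import RateSample, RateWindow

__all__ = ["MassParams", "MassNetwork"]


@dataclass
class MassParams:
    """Neural-mass node and coupling parameters."""

    T: float = 20.0              # rate relaxation time, ms
    nu_max: float = 100.0        # saturation rate, Hz
    theta_e: float = 6.0         # excitatory transfer threshold (input units)
    theta_i: float = 10.0        # inhibitory transfer threshold
    sigma_s: float = 2.0         # transfer slope
    J_ee: float = 1.1
    J_ei: float = 1.0
    J_ie: float = 1.4
    J_ii: float = 0.6
    b_w: float = 0.0             # adaptation increment, pA per Hz
    tau_w: float = 500.0         # adaptation time constant, ms
    w_scale: float = 1.0         # pA per transfer-input unit
    G: float = 0.2               # global coupling scale
    noise_sigma: float = 0.0     # additive rate noise SD, Hz * ms^-1/2

    def __post_init__(self) -> None:
        if self.T <= 0 or self.tau_w <= 0:
            raise ParameterError("T and tau_w must be > 0")
        if self.nu_max <= 0:
            raise ParameterError("nu_max must be > 0")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.sigma_s <= 0:
            raise ParameterError("sigma_s must be > 0")
        if self.w_scale <= 0:
            raise ParameterError("w_scale must be > 0")

    def F(self, x: np.ndarray) -> np.ndarray:
        """Sigmoidal rate transfer function; F(0) = nu_max / 2."""
        return self.nu_max / (1.0 + np.exp(-np.asarray(x, dtype=float) / self.sigma_s))


class MassNetwork:
    """Delay-coupled network of neural-mass nodes with proxy regions.

    The excitatory-rate history is a ring buffer at dt resolution covering
    at least the longest delay; proxy regions (the connectome's spiking
    regions by default) have their history written from external rate data
    instead of being integrated.
    """

    def __init__(
        self,
        conn: Connectome,
        params: MassParams,
        delays: np.ndarray,
        dt: float = 0.1,
        seed: int = 0,
        proxy_regions: list[int] | None = None,
    ) -> None:
        if dt <= 0:
            raise ParameterError("dt must be > 0")
        self.conn = conn
        self.params = params
        self.dt = float(dt)
        self.rng = np.random.default_rng(seed)
        self.n = conn.n_regions
        delays = np.asarray(delays, dtype=float)
        if delays.shape != (self.n, self.n):
            raise ParameterError("delay matrix shape must match the connectome")
        self._d_steps = np.maximum(np.round(delays / dt).astype(int), 1)
        self.max_delay_steps = int(self._d_steps.max()) if self.n > 1 else 1
        self.proxy_regions = sorted(
            conn.spiking_regions if proxy_regions is None else [int(p) for p in proxy_regions]
        )
        for p in self.proxy_regions:
            if not (0 <= p < self.n):
                raise ParameterError(f"proxy region {p} out of range")
        self._integrated = np.array(
            [i not in self.proxy_regions for i in range(self.n)], dtype=bool
        )
        # earliest (in steps) any integrated region reads a proxy rate;
        # bounds how far simulation may run ahead of the supplied proxy data
        proxy_cols = np.array(self.proxy_regions, dtype=int)
        if proxy_cols.size and self._integrated.any():
            sub_w = conn.weights[np.ix_(self._integrated.nonzero()[0], proxy_cols)]
            sub_d = self._d_steps[np.ix_(self._integrated.nonzero()[0], proxy_cols)]
            used = sub_w > 0
            self._min_proxy_delay_steps = int(sub_d[used].min()) if used.any() else np.iinfo(int).max
        else:
            self._min_proxy_delay_steps = np.iinfo(int).max

        self.nu_e = np.zeros(self.n)
        self.nu_i = np.zeros(self.n)
        self.W_ad = np.zeros(self.n)
        self._step = 0
        self._hist: np.ndarray | None = None   # ring buffer of nu_e
        self._hist_len = 0
        self._proxy_filled_until = 0           # absolute step (exclusive)

    # -- history --------------------------------------------------------

    @property
    def time(self) -> float:
        return self._step * self.dt

    def init_history(
        self,
        length_ms: float,
        mode: str = "constant",
        value: float | np.ndarray = 0.0,
        stored: np.ndarray | None = None,
        save_path: str | Path | None = None,
    ) -> None:
        """Fill the rate history ring buffer covering ``length_ms`` before t0.

        ``constant`` mode fills with a fixed rate; ``stored`` mode replays a
        trajectory (rows = steps, oldest first).  The realized initial
        condition can be written to a text file for reproducibility and fed
        back via ``stored`` mode.
        """
        n_hist = int(round(length_ms / self.dt))
        if n_hist * self.dt + 1e-9 < self.max_delay_steps * self.dt:
            raise InitializationError(
                f"history length {length_ms} ms is shorter than the maximum delay "
                f"{self.max_delay_steps * self.dt} ms"
            )
        self._hist_len = n_hist + 1
        self._hist = np.zeros((self._hist_len, self.n))
        if mode == "constant":
            init = np.broadcast_to(np.asarray(value, dtype=float), (self.n,))
            self._hist[:] = init
            self.nu_e = init.copy()
        elif mode == "stored":
            if stored is None:
                raise InitializationError("stored mode requires a trajectory array")
            stored = np.atleast_2d(np.asarray(stored, dtype=float))
            if stored.shape != (n_hist, self.n):
                raise InitializationError(
                    f"stored history must be ({n_hist}, {self.n}), got {stored.shape}"
                )
            for k in range(n_hist):
                self._hist[(self._step - n_hist + k) % self._hist_len] = stored[k]
            self.nu_e = stored[-1].copy()
        else:
            raise ParameterError(f"unknown history mode {mode!r}")
        self._proxy_filled_until = self._step
        if save_path is not None:
            hist = self.history_array()
            np.savetxt(save_path, hist, fmt="%.17g")

    def history_array(self) -> np.ndarray:
        """The pre-t0 history (oldest row first), for saving/round-trip."""
        self._require_history()
        n_hist = self._hist_len - 1
        rows = [
            self._hist[(self._step - n_hist + k) % self._hist_len]
            for k in range(n_hist)
        ]
        return np.array(rows)

    def _require_history(self) -> None:
        if self._hist is None:
            raise InitializationError("init_history must be called before simulating")

    def _hist_lookup(self, step_offsets: np.ndarray) -> np.ndarray:
        """nu_e[j] at absolute step indices given per (i, j) offsets."""
        assert self._hist is not None
        rows = step_offsets % self._hist_len
        cols = np.broadcast_to(np.arange(self.n), step_offsets.shape)
        return self._hist[rows, cols]

    # -- coupling -------------------------------------------------------

    def coupled_input(self, at_step: int | None = None) -> np.ndarray:
        """Delayed linear network input G * sum_j W[i,j] nu_e_j(t - d_ij)
        for every region i, evaluated at the given absolute step (default:
        the current time)."""
        self._require_history()
        k = self._step if at_step is None else int(at_step)
        oldest = self._step - (self._hist_len - 1)
        lookup = k - self._d_steps  # (n, n) absolute step per (target, source)
        if np.any(lookup[self.conn.weights > 0] < oldest):
            raise InitializationError(
                "history underrun: delayed lookup precedes the stored history"
            )
        vals = self._hist_lookup(lookup)
        return self.params.G * np.einsum("ij,ij->i", self.conn.weights, vals)

    def coupled_input_at(self, region: int, t: float) -> float:
        """Scalar convenience wrapper for one region at time t (ms)."""
        return float(self.coupled_input(at_step=int(round(t / self.dt)))[region])

    # -- proxies --------------------------------------------------------

    def set_proxy_rate(self, region_id: int, samples: list[RateSample] | RateWindow) -> None:
        """Overwrite the region's excitatory-rate history for the coming
        window with externally supplied piecewise-constant rates."""
        self._require_history()
        if region_id not in self.proxy_regions:
            raise ContractError(f"region {region_id} is not a proxy region")
        if isinstance(samples, RateWindow):
            t0, dt_s, values = samples.t0, samples.dt, samples.values
            if abs(dt_s - self.dt) > 1e-9:
                # resample piecewise-constant data onto the model grid
                n_sub = int(round((samples.t1 - samples.t0) / self.dt))
                idx = np.minimum(
                    (np.arange(n_sub) * self.dt / dt_s + 1e-9).astype(int),
                    len(values) - 1,
                )
                values = np.asarray(values)[idx]
        else:
            if not samples:
                raise ContractError("empty proxy sample sequence")
            samples = sorted(samples, key=lambda s: s.t0)
            t0 = samples[0].t0
            values = []
            expected = t0
            for s in samples:
                if abs(s.t0 - expected) > 1e-9:
                    raise ContractError(
                        f"proxy samples have a gap or overlap at t={s.t0} ms"
                    )
                n_sub = int(round((s.t1 - s.t0) / self.dt))
                if n_sub < 1 or abs(n_sub * self.dt - (s.t1 - s.t0)) > 1e-6:
                    raise ContractError("proxy sample windows must be multiples of dt")
                values.extend([s.rate] * n_sub)
                expected = s.t1
            values = np.array(values)
        base = int(round(t0 / self.dt))
        if base > self._proxy_filled_until:
            raise SequencingError(
                f"proxy window starting at step {base} leaves a gap after the "
                f"previously filled history (step {self._proxy_filled_until})"
            )
        oldest = self._step - (self._hist_len - 1)
        if base < oldest:
            raise InitializationError(
                "proxy window starts before the stored history horizon"
            )
        for k, v in enumerate(values):
            self._hist[(base + k) % self._hist_len, region_id] = v
        if region_id == self.proxy_regions[-1]:
            self._proxy_filled_until = max(self._proxy_filled_until, base + len(values))
        if base + len(values) > self._step:
            self.nu_e[region_id] = values[-1]

    # -- integration ----------------------------------------------------

    def step(self) -> None:
        """One stochastic-Heun step of all integrated (non-proxy) regions."""
        self._require_history()
        if (
            self.proxy_regions
            and self._min_proxy_delay_steps < np.iinfo(int).max
            and self._proxy_filled_until < self._step + 1 - self._min_proxy_delay_steps
        ):
            raise SequencingError(
                "simulating past the proxy data: set_proxy_rate must cover "
                "times the delayed proxy coupling will read"
            )
        p = self.params
        dt = self.dt
        coupling = self.coupled_input()
        noise_e = p.noise_sigma * np.sqrt(dt) * self.rng.standard_normal(self.n)
        noise_i = p.noise_sigma * np.sqrt(dt) * self.rng.standard_normal(self.n)

        def drift(nu_e, nu_i, W_ad):
            x_e = p.J_ee * (nu_e + coupling) - p.J_ei * nu_i - W_ad / p.w_scale - p.theta_e
            x_i = p.J_ie * (nu_e + coupling) - p.J_ii * nu_i - p.theta_i
            d_e = (-nu_e + p.F(x_e)) / p.T
            d_i = (-nu_i + p.F(x_i)) / p.T
            d_w = (-W_ad + p.b_w * nu_e) / p.tau_w
            return d_e, d_i, d_w

        d1 = drift(self.nu_e, self.nu_i, self.W_ad)
        pred_e = np.clip(self.nu_e + dt * d1[0] + noise_e, 0.0, p.nu_max)
        pred_i = np.clip(self.nu_i + dt * d1[1] + noise_i, 0.0, p.nu_max)
        pred_w = self.W_ad + dt * d1[2]
        d2 = drift(pred_e, pred_i, pred_w)
        new_e = np.clip(self.nu_e + 0.5 * dt * (d1[0] + d2[0]) + noise_e, 0.0, p.nu_max)
        new_i = np.clip(self.nu_i + 0.5 * dt * (d1[1] + d2[1]) + noise_i, 0.0, p.nu_max)
        new_w = self.W_ad + 0.5 * dt * (d1[2] + d2[2])

        mask = self._integrated
        self.nu_e[mask] = new_e[mask]
        self.nu_i[mask] = new_i[mask]
        self.W_ad[mask] = new_w[mask]
        if not np.all(np.isfinite(self.nu_e[mask])):
            bad = int(np.flatnonzero(~np.isfinite(self.nu_e))[0])
            raise IntegrationError(
                f"rate of region {bad} became non-finite at t={self.time:.3f} ms"
            )
        self._step += 1
        # integrated regions write their own history; proxies were written
        # ahead of time by set_proxy_rate
        slot = self._step % self._hist_len
        self._hist[slot, mask] = self.nu_e[mask]

    def run_window(self, t0: float, t1: float, record_stride: int = 0):
        """Integrate [t0, t1); optionally record (time, nu_e, nu_i, W_ad)
        every ``record_stride`` steps."""
        if abs(t0 - self.time) > 1e-6:
            raise SequencingError(
                f"window [{t0}, {t1}) is not contiguous with current time {self.time}"
            )
        n_steps = int(round((t1 - t0) / self.dt))
        rec = {"time": [], "nu_e": [], "nu_i": [], "W_ad": []} if record_stride else None
        for _ in range(n_steps):
            if record_stride and self._step % record_stride == 0:
                rec["time"].append(self.time)
                rec["nu_e"].append(self.nu_e.copy())
                rec["nu_i"].append(self.nu_i.copy())
                rec["W_ad"].append(self.W_ad.copy())
            self.step()
        if rec is not None:
            out = {"time": np.array(rec["time"])}
            for k in ("nu_e", "nu_i", "W_ad"):
                out[k] = (
                    np.array(rec[k]) if rec[k] else np.empty((0, self.n))
                )
            return out
        return None

    # -- transfer interface ---------------------------------------------

    def get_afferent_rates(self, target_region: int, t0: float, t1: float) -> RateWindow:
        """Delayed, weighted excitatory rates every source region contributes
        to ``target_region`` over [t0, t1), at dt resolution, exposed
        per-source so the spiking side can apportion its synapse slots.

        The sum across sources equals ``coupled_input`` of the target at the
        matching times.  The window may extend up to one synchronization
        window beyond the current time because all inter-scale delays are at
        least that long.
        """
        self._require_history()
        if target_region not in self.proxy_regions:
            raise ContractError(f"region {target_region} is not a spiking/proxy region")
        base = int(round(t0 / self.dt))
        n_sub = int(round((t1 - t0) / self.dt))
        if n_sub < 1:
            raise ContractError("empty afferent window")
        d_row = self._d_steps[target_region]
        has_afferents = np.any(self.conn.weights[target_region] > 0)
        min_d = int(d_row[self.conn.weights[target_region] > 0].min()) if has_afferents else n_sub
        if has_afferents and base + n_sub - min_d > self._step:
            raise SequencingError(
                f"afferent window [{t0}, {t1}) requires history beyond the "
                f"simulated time {self.time} ms"
            )
        oldest = self._step - (self._hist_len - 1)
        values = np.zeros((n_sub, self.n))
        W_row = self.conn.weights[target_region]
        for k in range(n_sub):
            lookup = base + k - d_row
            if np.any(lookup[W_row > 0] < oldest):
                raise InitializationError("history underrun in afferent window")
            rows = lookup % self._hist_len
            values[k] = self.params.G * W_row * self._hist[rows, np.arange(self.n)]
        values[:, target_region] = 0.0
        return RateWindow(
            t0=t0, t1=t1, dt=self.dt, values=values, sources=list(range(self.n))
        )
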
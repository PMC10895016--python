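"""The launcher: parameter handling, run-directory setup, component
start-up, the windowed simulation loop and termination.

A co-simulation run involves five components: the launcher (this module),
the spiking simulator (one microcircuit per spiking-scale region), the
neural-mass simulator, and two transfer modules (spikes->rates toward the
mass network, rates->spikes toward the microcircuits).  The components
exchange data once per synchronization window; the window length is bounded
above by the minimum non-zero inter-regional transmission delay, which is
what makes windowed exchange exactly equivalent to step-by-step exchange
(data from window k-1 fully determines the coupling inputs of window k).

Rate data travel at the integration-step resolution and are merely batched
per synchronization window, so changing the window length at equal seeds
changes no simulated number, only the communication granularity.

Components can run either as threads of one process (shared-memory
channels) or as separate processes (message-passing channels with
rendezvous files); both backends produce bitwise-identical dumps at equal
seeds.
"""

from __future__ import annotations

import copy
import json
import shutil
import time
import traceback
from dataclasses import dataclass, field
from multiprocessing import get_context
from pathlib import Path
from threading import Thread

import numpy as np

from . import transfer as tr
from .connectome import (
    Connectome,
    compute_delays,
    generate_sensor_grid,
    generate_synthetic_connectome,
    normalize_weights,
    read_connectome_dir,
    write_connectome,
    write_sensor_layout,
)
from .errors import CosimError, ParameterError, ValidationError
from .mass import MassNetwork, MassParams
from .sensors import EcogConfig, ecog_forward, write_ecog
from .spiking import (
    AdExParams,
    SpikeBlock,
    SpikingNetwork,
    SynapseParams,
    apportion_slots,
)
from .timers import ComponentTimer, TimerReport
from .transforms import RateWindow, mip_drive, spikes_to_rate_array

__all__ = [
    "CoSimParameters",
    "DEFAULT_PARAMETERS",
    "load_and_validate",
    "prepare_run_dir",
    "run_cosimulation",
    "timers_report",
    "COMPONENTS",
]

COMPONENTS = ("launcher", "spiking", "mass", "transfer_s2m", "transfer_m2s")

DEFAULT_PARAMETERS: dict = {
    "fixtures": {
        "n_regions": 16,
        "density": 0.4,
        "length_scale_mm": 10.0,
        "min_distance_mm": 2.0,
        "n_spiking": 2,
        "seed": 0,
        "speed_mm_per_ms": 1.0,
        "weight_normalization": "row_sum",
        "connectome_dir": None,
    },
    "spiking": {
        "dt": 0.1,
        "n_ex": 80,
        "n_in": 20,
        "n_ext_synapses_per_neuron": 10,
        "background_rate_hz": 0.0,
        "I_ext_pA": 0.0,
        "n_record": 20,
        "record_interval_ms": 1.0,
        "adex_ex": {},
        "adex_in": {},
        "synapse": {},
    },
    "mass": {
        "dt": 0.1,
        "record_interval_ms": 1.0,
        "init_rate_hz": 0.0,
        "params": {},
    },
    "transfer": {
        "mip_c": 0.1,
        "timeout_s": 60.0,
    },
    "sensors": {
        "n_per_hemisphere": 8,
        "exponent": 2.0,
        "gain": 1.0,
        "elevation_mm": 2.0,
    },
    "run": {
        "t_end_ms": 20.0,
        "sync_step_ms": 2.0,
        "master_seed": 42,
        "backend": "processes",
        "run_dir": "cosim_run",
        "throttle_s": {},
    },
}


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise ParameterError(f"unknown parameter {path}{key}")
        if isinstance(base[key], dict) and key in (
            "fixtures", "spiking", "mass", "transfer", "sensors", "run",
        ) and not path:
            out[key] = _deep_merge(base[key], val, path=f"{key}.")
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class CoSimParameters:
    """Resolved, validated co-simulation parameters.

    ``resolved`` is the JSON-serializable parameter tree including the
    ``derived`` section (per-component seeds, delays summary, window
    count); the connectome and delay matrix are materialized alongside.
    """

    resolved: dict
    connectome: Connectome
    delays: np.ndarray
    field_hash: int = field(default=0, repr=False)

    def section(self, name: str) -> dict:
        return self.resolved[name]

    @property
    def dt(self) -> float:
        return float(self.resolved["spiking"]["dt"])

    @property
    def sync_step(self) -> float:
        return float(self.resolved["run"]["sync_step_ms"])

    @property
    def n_windows(self) -> int:
        return int(self.resolved["derived"]["n_windows"])

    @property
    def seeds(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.resolved["derived"]["seeds"].items()}

    def to_json(self) -> str:
        return json.dumps(self.resolved, indent=2, sort_keys=True)


def _derive_seeds(master_seed: int) -> dict[str, int]:
    """Counter-based seed splitting: component i gets the first word of
    SeedSequence([master_seed, i]), reduced below 2^31."""
    return {
        name: int(np.random.SeedSequence([int(master_seed), i]).generate_state(1)[0] % (2**31))
        for i, name in enumerate(COMPONENTS)
    }


def _build_connectome(fx: dict) -> Connectome:
    if fx.get("connectome_dir"):
        conn = read_connectome_dir(fx["connectome_dir"])
    else:
        conn = generate_synthetic_connectome(
            n_regions=fx["n_regions"],
            density=fx["density"],
            length_scale_mm=fx["length_scale_mm"],
            seed=fx["seed"],
            min_distance_mm=fx["min_distance_mm"],
            n_spiking=fx["n_spiking"],
        )
    conn.weights = normalize_weights(conn.weights, fx["weight_normalization"])
    return conn


def load_and_validate(source: dict | str | Path) -> CoSimParameters:
    """Load a parameter file (or dict), fill defaults, materialize derived
    parameters and enforce the cross-module consistency rules.

    Every violation is reported with the offending section and key.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            override = json.load(fh)
    else:
        override = source
    override = dict(override)
    override.pop("derived", None)  # re-derived below
    resolved = _deep_merge(DEFAULT_PARAMETERS, override)

    spk, mass, run = resolved["spiking"], resolved["mass"], resolved["run"]
    dt_s, dt_m = float(spk["dt"]), float(mass["dt"])
    if dt_s <= 0 or dt_m <= 0:
        raise ParameterError("spiking.dt and mass.dt must be > 0")
    if abs(dt_s - dt_m) > 1e-12:
        raise ParameterError(
            f"spiking.dt ({dt_s}) and mass.dt ({dt_m}) must be equal: both "
            "simulators must share the integration step for synchronization"
        )
    sync = float(run["sync_step_ms"])
    n_sub = sync / dt_s
    if sync <= 0 or abs(round(n_sub) - n_sub) > 1e-9 or round(n_sub) < 1:
        raise ParameterError(
            f"run.sync_step_ms ({sync}) must be a positive integer multiple of dt ({dt_s})"
        )
    t_end = float(run["t_end_ms"])
    n_win = t_end / sync
    if t_end <= 0 or abs(round(n_win) - n_win) > 1e-9:
        raise ParameterError(
            f"run.t_end_ms ({t_end}) must be a positive multiple of run.sync_step_ms ({sync})"
        )

    conn = _build_connectome(resolved["fixtures"])
    delays = compute_delays(conn, resolved["fixtures"]["speed_mm_per_ms"], dt_s)
    nz = conn.weights > 0
    if not nz.any():
        raise ValidationError("fixtures: connectome has no non-zero weights")
    min_delay = float(delays[nz].min())
    if sync > min_delay + 1e-9:
        raise ParameterError(
            f"run.sync_step_ms ({sync}) exceeds the minimum non-zero inter-regional "
            f"delay ({min_delay} ms); windowed synchronization would violate causality"
        )
    resolved["derived"] = {
        "seeds": _derive_seeds(int(run["master_seed"])),
        "min_delay_ms": min_delay,
        "max_delay_ms": float(delays.max()),
        "n_windows": int(round(n_win)),
        "n_substeps_per_window": int(round(n_sub)),
    }
    return CoSimParameters(resolved=resolved, connectome=conn, delays=delays)


def prepare_run_dir(
    params: CoSimParameters, run_dir: str | Path | None = None, force: bool = False
) -> Path:
    """Create the run-directory layout: one folder per component, a logs
    folder, and a frozen copy of the resolved parameter file."""
    run_dir = Path(run_dir if run_dir is not None else params.resolved["run"]["run_dir"])
    if run_dir.exists() and any(run_dir.iterdir()):
        if not force:
            raise ValidationError(
                f"run directory {run_dir} exists and is not empty (use force=True)"
            )
        shutil.rmtree(run_dir)
    for sub in ("spiking", "mass", "transfer_s2m", "transfer_m2s", "sensors",
                "logs", "timers", "connectome"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)
    write_connectome(params.connectome, run_dir / "connectome")
    # freeze: later loads (e.g. by worker processes) reuse the exact copy
    frozen = copy.deepcopy(params.resolved)
    frozen["fixtures"]["connectome_dir"] = str(run_dir / "connectome")
    (run_dir / "parameters.json").write_text(
        json.dumps(frozen, indent=2, sort_keys=True) + "\n"
    )
    return run_dir


class _Log:
    def __init__(self, run_dir: Path, component: str):
        self.path = Path(run_dir) / "logs" / f"{component}.log"
        self.component = component
        self._fh = open(self.path, "a")

    def __call__(self, msg: str) -> None:
        self._fh.write(f"[{time.strftime('%H:%M:%S')}] {self.component}: {msg}\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------


def _spiking_networks(params: CoSimParameters) -> dict[int, SpikingNetwork]:
    spk = params.section("spiking")
    conn = params.connectome
    adex_ex = AdExParams(**spk["adex_ex"])
    adex_in = AdExParams(**{**dict(E_L=-65.0, Delta_T=0.5, tau_w=1.0, b=0.0), **spk["adex_in"]})
    syn = SynapseParams(**spk["synapse"])
    seed0 = params.seeds["spiking"]
    nets = {}
    for r in conn.spiking_regions:
        seed_r = int(np.random.SeedSequence([seed0, r]).generate_state(1)[0] % (2**31))
        nets[r] = SpikingNetwork(
            adex_ex, adex_in, syn,
            n_ex=spk["n_ex"], n_in=spk["n_in"],
            n_ext_synapses_per_neuron=spk["n_ext_synapses_per_neuron"],
            seed=seed_r,
            afferent_weights=conn.weights[r],
            dt=params.dt,
            background_rate_hz=spk["background_rate_hz"],
            I_ext_pA=spk["I_ext_pA"],
            n_record=spk["n_record"],
            record_interval_ms=spk["record_interval_ms"],
        )
    return nets


def _counts_to_block(counts: np.ndarray, t0: float, t1: float, dt: float) -> SpikeBlock:
    """External-drive counts per (dt-bin, neuron) as an explicit spike
    train block (spike times quantized at bin starts)."""
    bins, ids = np.nonzero(counts)
    reps = counts[bins, ids].astype(int)
    times = np.repeat(t0 + bins * dt, reps)
    full_ids = np.repeat(ids, reps)
    order = np.argsort(times, kind="stable")
    return SpikeBlock(t0=t0, t1=t1, ids=full_ids[order], times=times[order])


def _block_to_counts(block: SpikeBlock, n_neurons: int, n_sub: int, dt: float) -> np.ndarray:
    counts = np.zeros((n_sub, n_neurons), dtype=np.int64)
    if block.n_events:
        bins = np.minimum(
            np.floor((block.times - block.t0) / dt + 1e-9).astype(int), n_sub - 1
        )
        np.add.at(counts, (bins, block.ids), 1)
    return counts


def _spiking_main(params: CoSimParameters, run_dir: Path, ep_in, ep_out,
                  timer: ComponentTimer, log) -> None:
    """Spiking simulator component: one AdEx microcircuit per flagged region."""
    spk = params.section("spiking")
    sync, dt = params.sync_step, params.dt
    n_sub = params.resolved["derived"]["n_substeps_per_window"]
    throttle = float(params.section("run")["throttle_s"].get("spiking", 0.0))
    with timer.section("initialisation"):
        nets = _spiking_networks(params)
        log(f"built {len(nets)} microcircuits of {next(iter(nets.values())).n} neurons")
    blocks_acc: dict[int, list[SpikeBlock]] = {r: [] for r in nets}
    rec_acc: dict[int, list[dict]] = {r: [] for r in nets}
    try:
        for k in range(params.n_windows):
            t0, t1 = k * sync, (k + 1) * sync
            payload = ep_in.transfer()
            with timer.section("simulation"):
                out_body = {}
                for r in sorted(nets):
                    counts = _block_to_counts(payload.body[r], nets[r].n, n_sub, dt)
                    block, rec = nets[r].run_chunk(t0, t1, external_counts=counts)
                    blocks_acc[r].append(block)
                    rec_acc[r].append(rec)
                    out_body[r] = block
                if throttle:
                    time.sleep(throttle)
            ep_out.transfer(tr.TransferPayload(kind="spikes", window=(t0, t1), body=out_body))
        ep_out.end_transfer()
        ep_in.end_transfer()
    finally:
        with timer.section("ending"):
            ep_in.release()
            ep_out.release()
            _dump_spiking(params, run_dir, blocks_acc, rec_acc)
            timer.finish()
            timer.write_csv(run_dir / "timers" / "spiking.csv")
        log("done")


def _dump_spiking(params, run_dir: Path, blocks_acc, rec_acc) -> None:
    labels = params.connectome.labels
    for r, blocks in blocks_acc.items():
        label = labels[r]
        ids = np.concatenate([b.ids for b in blocks]) if blocks else np.empty(0, int)
        times = np.concatenate([b.times for b in blocks]) if blocks else np.empty(0)
        with open(run_dir / "spiking" / f"spikes_{label}.txt", "w") as fh:
            fh.write("# neuron_id spike_time_ms\n")
            for i, t in zip(ids, times):
                fh.write(f"{int(i)} {t:.17g}\n")
        recs = rec_acc[r]
        if recs:
            t = np.concatenate([rec["time"] for rec in recs])
            V = np.vstack([rec["V"] for rec in recs])
            w = np.vstack([rec["w"] for rec in recs])
            nid = recs[0]["neuron_ids"]
            hdr = "time_ms " + " ".join(f"n{int(i)}" for i in nid)
            np.savetxt(run_dir / "spiking" / f"voltage_{label}.txt",
                       np.column_stack([t, V]), fmt="%.17g", header=hdr)
            np.savetxt(run_dir / "spiking" / f"adaptation_{label}.txt",
                       np.column_stack([t, w]), fmt="%.17g", header=hdr)


def _mass_main(params: CoSimParameters, run_dir: Path, ep_in, ep_out,
               timer: ComponentTimer, log) -> None:
    """Neural-mass simulator component with proxy regions for the spiking
    scale."""
    conn = params.connectome
    sync, dt = params.sync_step, params.dt
    mp = params.section("mass")
    throttle = float(params.section("run")["throttle_s"].get("mass", 0.0))
    with timer.section("initialisation"):
        net = MassNetwork(
            conn, MassParams(**mp["params"]), params.delays, dt=dt,
            seed=params.seeds["mass"],
        )
        hist_ms = params.resolved["derived"]["max_delay_ms"] + sync
        net.init_history(
            hist_ms, mode="constant", value=float(mp["init_rate_hz"]),
            save_path=run_dir / "mass" / "initial_condition.txt",
        )
        rec_stride = max(1, int(round(mp["record_interval_ms"] / dt)))
        log(f"mass network of {net.n} regions, history {hist_ms} ms")
    records = []
    try:
        for k in range(params.n_windows):
            t0, t1 = k * sync, (k + 1) * sync
            proxy_payload = ep_in.transfer()
            with timer.section("simulation"):
                for r in sorted(conn.spiking_regions):
                    net.set_proxy_rate(r, proxy_payload.body[r])
                aff = {
                    r: net.get_afferent_rates(r, t0, t1)
                    for r in sorted(conn.spiking_regions)
                }
            ep_out.transfer(tr.TransferPayload(kind="rates", window=(t0, t1), body=aff))
            with timer.section("simulation"):
                rec = net.run_window(t0, t1, record_stride=rec_stride)
                records.append(rec)
                if throttle:
                    time.sleep(throttle)
        # drain the final proxy window so the channel terminates cleanly
        try:
            final = ep_in.transfer()
            for r in sorted(conn.spiking_regions):
                net.set_proxy_rate(r, final.body[r])
        except CosimError:
            pass
        ep_out.end_transfer()
        ep_in.end_transfer()
    finally:
        with timer.section("ending"):
            ep_in.release()
            ep_out.release()
            _dump_mass(params, run_dir, records)
            timer.finish()
            timer.write_csv(run_dir / "timers" / "mass.csv")
        log("done")


def _dump_mass(params, run_dir: Path, records: list[dict]) -> None:
    if not records:
        return
    rec_int = float(params.section("mass")["record_interval_ms"])
    t = np.concatenate([r["time"] for r in records])
    nu_e = np.vstack([r["nu_e"] for r in records])
    nu_i = np.vstack([r["nu_i"] for r in records])
    with open(run_dir / "mass" / "rates.txt", "w") as fh:
        fh.write("# t0_ms t1_ms region_id pop rate_hz\n")
        for k, tk in enumerate(t):
            for r in range(nu_e.shape[1]):
                fh.write(f"{tk:.17g} {tk + rec_int:.17g} {r} exc {nu_e[k, r]:.17g}\n")
                fh.write(f"{tk:.17g} {tk + rec_int:.17g} {r} inh {nu_i[k, r]:.17g}\n")


def read_mass_rates(run_dir: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse mass/rates.txt -> (times, nu_e matrix, nu_i matrix)."""
    rows = []
    with open(Path(run_dir) / "mass" / "rates.txt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            t0, t1, rid, pop, rate = line.split()
            rows.append((float(t0), int(rid), pop, float(rate)))
    times = sorted({r[0] for r in rows})
    n = max(r[1] for r in rows) + 1
    t_index = {t: i for i, t in enumerate(times)}
    nu_e = np.zeros((len(times), n))
    nu_i = np.zeros((len(times), n))
    for t0, rid, pop, rate in rows:
        (nu_e if pop == "exc" else nu_i)[t_index[t0], rid] = rate
    return np.array(times), nu_e, nu_i


def _s2m_main(params: CoSimParameters, run_dir: Path, ep_in, ep_out,
              timer: ComponentTimer, log) -> None:
    """Transfer module spiking -> mass: windowed excitatory population
    rates at dt resolution, preceded by the initial proxy message."""
    conn = params.connectome
    sync, dt = params.sync_step, params.dt
    n_ex = params.section("spiking")["n_ex"]
    with timer.section("initialisation"):
        init_rate = float(params.section("mass")["init_rate_hz"])
        init_body = {
            r: RateWindow(t0=-sync, t1=0.0, dt=dt,
                          values=np.full(params.resolved["derived"]["n_substeps_per_window"],
                                         init_rate))
            for r in sorted(conn.spiking_regions)
        }
        initial = tr.TransferPayload(kind="rates", window=(-sync, 0.0), body=init_body)

    def transform(payload: tr.TransferPayload) -> tr.TransferPayload:
        with timer.section("simulation"):
            t0, t1 = payload.window
            body = {}
            for r, block in payload.body.items():
                exc = block.ids < n_ex
                sub = SpikeBlock(t0=block.t0, t1=block.t1,
                                 ids=block.ids[exc], times=block.times[exc])
                body[r] = RateWindow(
                    t0=t0, t1=t1, dt=dt,
                    values=spikes_to_rate_array(sub, n_ex, dt),
                )
            return tr.TransferPayload(kind="rates", window=payload.window, body=body)

    try:
        tr.run_transfer_module(ep_in, transform, ep_out, initial=initial, log=log)
    finally:
        with timer.section("ending"):
            timer.finish()
            timer.write_csv(run_dir / "timers" / "transfer_s2m.csv")
        log("done")


def _m2s_main(params: CoSimParameters, run_dir: Path, ep_in, ep_out,
              timer: ComponentTimer, log) -> None:
    """Transfer module mass -> spiking: multiple-interaction-process spike
    generation from the per-source afferent rates, one train per synapse
    slot, aggregated per target neuron."""
    conn = params.connectome
    dt = params.dt
    spk = params.section("spiking")
    n_neurons = spk["n_ex"] + spk["n_in"]
    n_slots = spk["n_ext_synapses_per_neuron"]
    c = float(params.section("transfer")["mip_c"])
    seed0 = params.seeds["transfer_m2s"]
    with timer.section("initialisation"):
        rngs = {
            r: np.random.default_rng(np.random.SeedSequence([seed0, r]))
            for r in sorted(conn.spiking_regions)
        }
        slots = {
            r: apportion_slots(conn.weights[r], n_slots)
            for r in sorted(conn.spiking_regions)
        }

    def transform(payload: tr.TransferPayload) -> tr.TransferPayload:
        with timer.section("simulation"):
            t0, t1 = payload.window
            body = {}
            for r in sorted(payload.body):
                win: RateWindow = payload.body[r]
                counts = mip_drive(win.values, dt, slots[r], c, n_neurons, rngs[r])
                body[r] = _counts_to_block(counts, t0, t1, dt)
            return tr.TransferPayload(kind="spikes", window=payload.window, body=body)

    try:
        tr.run_transfer_module(ep_in, transform, ep_out, log=log)
    finally:
        with timer.section("ending"):
            timer.finish()
            timer.write_csv(run_dir / "timers" / "transfer_m2s.csv")
        log("done")


_COMPONENT_MAINS = {
    "spiking": _spiking_main,
    "mass": _mass_main,
    "transfer_s2m": _s2m_main,
    "transfer_m2s": _m2s_main,
}

# channel name -> (listening component, sender component, receiver component)
_CHANNELS = {
    "transfer_s2m/from_spiking": ("transfer_s2m", "spiking", "transfer_s2m"),
    "transfer_s2m/to_mass": ("transfer_s2m", "transfer_s2m", "mass"),
    "transfer_m2s/from_mass": ("transfer_m2s", "mass", "transfer_m2s"),
    "transfer_m2s/to_spiking": ("transfer_m2s", "transfer_m2s", "spiking"),
}


def _component_endpoints_process(name: str, run_dir: Path, timeout: float, timer):
    """Establish this component's two endpoints over the message-passing
    backend.  Transfer modules listen (they host the rendezvous files);
    simulators connect.  All listeners bind before any accept blocks."""
    roles = {}
    for chan, (listener, sender, receiver) in _CHANNELS.items():
        if name == sender:
            roles[chan] = "send"
        elif name == receiver:
            roles[chan] = "receive"
    pendings = {}
    if name in ("transfer_s2m", "transfer_m2s"):
        for chan in roles:
            if _CHANNELS[chan][0] == name:
                pendings[chan] = tr.PendingListener(chan, run_dir)
    eps = {}
    for chan, role in roles.items():
        if chan in pendings:
            eps[chan] = pendings[chan].accept(role, timeout=timeout, timer=timer)
        else:
            eps[chan] = tr.make_client_endpoint(chan, run_dir, role, timeout=timeout, timer=timer)
    return eps


def _component_entry(param_file: str, run_dir: str, name: str) -> None:
    """Entry point of a worker process: rebuild everything from the frozen
    parameter file (bitwise-identical to the launcher's view)."""
    run_dir = Path(run_dir)
    log = _Log(run_dir, name)
    timer = ComponentTimer(name)
    try:
        with timer.section("initialisation"):
            params = load_and_validate(param_file)
            timeout = float(params.section("transfer")["timeout_s"])
            eps = _component_endpoints_process(name, run_dir, timeout, timer)
        if name == "spiking":
            _spiking_main(params, run_dir, eps["transfer_m2s/to_spiking"],
                          eps["transfer_s2m/from_spiking"], timer, log)
        elif name == "mass":
            _mass_main(params, run_dir, eps["transfer_s2m/to_mass"],
                       eps["transfer_m2s/from_mass"], timer, log)
        elif name == "transfer_s2m":
            _s2m_main(params, run_dir, eps["transfer_s2m/from_spiking"],
                      eps["transfer_s2m/to_mass"], timer, log)
        elif name == "transfer_m2s":
            _m2s_main(params, run_dir, eps["transfer_m2s/from_mass"],
                      eps["transfer_m2s/to_spiking"], timer, log)
    except BaseException:
        log("FAILED:\n" + traceback.format_exc())
        raise SystemExit(1)
    finally:
        log.close()


def run_cosimulation(
    params: CoSimParameters,
    run_dir: str | Path | None = None,
    force: bool = False,
    backend: str | None = None,
) -> tuple[Path, TimerReport]:
    """Execute a full co-simulation run.

    Start-up launches the transfer modules first (they host the rendezvous
    addresses), then the simulators; the windowed clock contract guarantees
    no simulator advances past window k+1 before its window-k input has
    been delivered; termination is initiated by the simulators themselves
    once the final window is done, followed by channel drain and release.
    Returns the run directory and the five-component timer report.
    """
    backend = backend or params.resolved["run"]["backend"]
    if backend not in ("threads", "processes"):
        raise ParameterError(f"run.backend must be 'threads' or 'processes', got {backend!r}")
    launcher_timer = ComponentTimer("launcher")
    with launcher_timer.section("initialisation"):
        run_dir = prepare_run_dir(params, run_dir, force=force)
        log = _Log(run_dir, "launcher")
        log(f"starting co-simulation, backend={backend}, "
            f"{params.n_windows} windows of {params.sync_step} ms")
    timeout = float(params.section("transfer")["timeout_s"])
    join_timeout = max(600.0, 10.0 * timeout)

    failures: dict[str, BaseException] = {}
    if backend == "threads":
        timers = {n: ComponentTimer(n) for n in _COMPONENT_MAINS}
        chans = {}
        with launcher_timer.section("initialisation"):
            for chan, (_, sender, receiver) in _CHANNELS.items():
                chans[chan] = tr.make_thread_channel(
                    timeout=timeout, send_timer=timers[sender],
                    recv_timer=timers[receiver], name=chan,
                )
        ep = {chan: {"send": pair[0], "receive": pair[1]} for chan, pair in chans.items()}
        logs = {n: _Log(run_dir, n) for n in _COMPONENT_MAINS}

        def wrap(name, fn, *args):
            def runner():
                try:
                    fn(*args)
                except BaseException as exc:  # noqa: BLE001 - reported to launcher
                    failures[name] = exc
                    logs[name]("FAILED:\n" + traceback.format_exc())
            return Thread(target=runner, name=name, daemon=True)

        threads = [
            wrap("transfer_s2m", _s2m_main, params, run_dir,
                 ep["transfer_s2m/from_spiking"]["receive"],
                 ep["transfer_s2m/to_mass"]["send"], timers["transfer_s2m"],
                 logs["transfer_s2m"]),
            wrap("transfer_m2s", _m2s_main, params, run_dir,
                 ep["transfer_m2s/from_mass"]["receive"],
                 ep["transfer_m2s/to_spiking"]["send"], timers["transfer_m2s"],
                 logs["transfer_m2s"]),
            wrap("spiking", _spiking_main, params, run_dir,
                 ep["transfer_m2s/to_spiking"]["receive"],
                 ep["transfer_s2m/from_spiking"]["send"], timers["spiking"],
                 logs["spiking"]),
            wrap("mass", _mass_main, params, run_dir,
                 ep["transfer_s2m/to_mass"]["receive"],
                 ep["transfer_m2s/from_mass"]["send"], timers["mass"],
                 logs["mass"]),
        ]
        for t in threads:  # transfer modules first
            t.start()
        with launcher_timer.section("wait"):
            deadline = time.monotonic() + join_timeout
            for t in threads:
                t.join(timeout=max(0.0, deadline - time.monotonic()))
                if t.is_alive():
                    failures.setdefault(t.name, TimeoutError("component did not terminate"))
        for lg in logs.values():
            lg.close()
    else:
        ctx = get_context("fork")
        procs = {}
        param_file = str(run_dir / "parameters.json")
        for name in ("transfer_s2m", "transfer_m2s", "spiking", "mass"):
            procs[name] = ctx.Process(
                target=_component_entry, args=(param_file, str(run_dir), name), name=name
            )
        for name in ("transfer_s2m", "transfer_m2s"):  # transfer modules first
            procs[name].start()
        for name in ("spiking", "mass"):
            procs[name].start()
        with launcher_timer.section("wait"):
            deadline = time.monotonic() + join_timeout
            for name, p in procs.items():
                p.join(timeout=max(0.0, deadline - time.monotonic()))
                if p.is_alive():
                    p.terminate()
                    failures[name] = TimeoutError("component did not terminate (deadlock?)")
                elif p.exitcode != 0:
                    failures[name] = RuntimeError(f"exit code {p.exitcode}")

    if failures:
        excerpts = []
        for name in failures:
            log_path = run_dir / "logs" / f"{name}.log"
            tail = log_path.read_text().splitlines()[-12:] if log_path.exists() else []
            excerpts.append(f"--- {name}: {failures[name]!r}\n" + "\n".join(tail))
        log("run FAILED")
        log.close()
        raise CosimError(
            "co-simulation aborted; failing component log excerpt(s):\n" + "\n".join(excerpts)
        )

    with launcher_timer.section("ending"):
        _compute_sensors(params, run_dir)
        launcher_timer.finish()
        launcher_timer.write_csv(run_dir / "timers" / "launcher.csv")
        report = timers_report(run_dir)
        log("run complete")
        log.close()
    return run_dir, report


def _compute_sensors(params: CoSimParameters, run_dir: Path) -> None:
    """ECoG forward model applied to the recorded excitatory rates."""
    sens = params.section("sensors")
    layout = generate_sensor_grid(
        params.connectome,
        n_per_hemisphere=sens["n_per_hemisphere"],
        elevation_mm=sens["elevation_mm"],
        seed=params.section("fixtures")["seed"],
    )
    write_sensor_layout(layout, run_dir / "sensors" / "layout.txt")
    rates_file = run_dir / "mass" / "rates.txt"
    if not rates_file.exists():
        return
    times, nu_e, _ = read_mass_rates(run_dir)
    cfg = EcogConfig(layout=layout, exponent=sens["exponent"], gain=sens["gain"])
    series = ecog_forward(nu_e, params.connectome.centres, cfg)
    write_ecog(series, times, run_dir / "sensors" / "ecog.txt")


def timers_report(run_dir: str | Path) -> TimerReport:
    """Aggregate every component's timer CSV and write the combined
    ``timers/report.csv`` table."""
    report = TimerReport.from_run_dir(run_dir)
    report.write_table(Path(run_dir) / "timers" / "report.csv")
    return report
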
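"""Transfer channels and transfer modules.

A *channel* connects a sending component to a receiving one and carries one
synchronization window's payload at a time (one-window buffering).  Each
endpoint exposes the four-function API:

* ``ready()``      -- can a transfer proceed without blocking?
* ``transfer()``   -- move one window's payload (blocks, bounded by timeout)
* ``end_transfer()`` -- no further windows will follow
* ``release()``    -- free resources (idempotent)

Two interchangeable backends implement the same contract: a shared-memory
backend for components running as threads of one process, and a
message-passing backend (Unix-domain socket connections, rendezvous via
``.addr`` files in the run directory) for components running as separate
processes.  Blocking calls carry a configurable timeout that converts a
silent deadlock into a diagnosable error.

A *transfer module* is the receive -> transform -> send pipeline between
the two simulators; with one-window buffering on both sides, window k+1 can
be received and transformed while window k is still waiting to be consumed.
"""

from __future__ import annotations

import os
import tempfile
import time
from dataclasses import dataclass
from multiprocessing.connection import Client, Connection, Listener
from pathlib import Path
from threading import Condition
from typing import Any, Callable

import numpy as np

from .errors import (
    BrokenChannelError,
    ChannelStateError,
    ContractError,
    DeadlockError,
    EndOfStream,
    SequencingError,
    TransferModuleError,
    ValidationError,
)
from .spiking import SpikeBlock
from .transforms import RateSample, RateWindow, rate_to_spikes_mip

__all__ = [
    "TransferPayload",
    "ChannelEndpoint",
    "make_thread_channel",
    "PendingListener",
    "make_listener_endpoint",
    "make_client_endpoint",
    "run_transfer_module",
    "initial_message",
]

DEFAULT_TIMEOUT = 60.0  # seconds


def _window_of(body: Any) -> tuple[float, float] | None:
    if isinstance(body, SpikeBlock):
        return (body.t0, body.t1)
    if isinstance(body, RateWindow):
        return (body.t0, body.t1)
    if isinstance(body, RateSample):
        return (body.t0, body.t1)
    if isinstance(body, dict) and body:
        wins = [_window_of(v) for v in body.values()]
        if all(w is not None for w in wins):
            return (min(w[0] for w in wins), max(w[1] for w in wins))
    if isinstance(body, (list, tuple)) and body:
        wins = [_window_of(v) for v in body]
        if all(w is not None for w in wins):
            return (min(w[0] for w in wins), max(w[1] for w in wins))
    return None


@dataclass
class TransferPayload:
    """One synchronization window's data: spike events or rate samples."""

    kind: str                       # "spikes" | "rates"
    window: tuple[float, float]
    body: Any

    def __post_init__(self) -> None:
        if self.kind not in ("spikes", "rates"):
            raise ValidationError(f"unknown payload kind {self.kind!r}")
        t0, t1 = self.window
        if t1 <= t0:
            raise ValidationError(f"payload window [{t0}, {t1}) is empty or inverted")
        inner = _window_of(self.body)
        if inner is not None:
            if abs(inner[0] - t0) > 1e-6 or abs(inner[1] - t1) > 1e-6:
                raise ValidationError(
                    f"body window {inner} does not match payload window {self.window}"
                )
        kinds_ok = {
            "spikes": (SpikeBlock,),
            "rates": (RateWindow, RateSample),
        }[self.kind]
        probe = self.body
        if isinstance(probe, dict):
            probe = next(iter(probe.values()), None)
        if isinstance(probe, (list, tuple)):
            probe = probe[0] if probe else None
        if probe is not None and not isinstance(probe, kinds_ok):
            raise ValidationError(
                f"payload kind {self.kind!r} does not match body type {type(probe).__name__}"
            )


class ChannelEndpoint:
    """Base endpoint: status tracking and window sequencing."""

    def __init__(self, role: str, peer: str = "?", timeout: float = DEFAULT_TIMEOUT):
        if role not in ("send", "receive"):
            raise ChannelStateError(f"unknown role {role!r}")
        self.role = role
        self.peer = peer
        self.timeout = timeout
        self.status = "idle"
        self._expected_t0: float | None = None
        self._ended = False
        self._released = False

    # sequencing helpers -------------------------------------------------
    def _check_usable(self) -> None:
        if self._released:
            raise ChannelStateError(f"{self.role} endpoint used after release")

    def _check_window(self, window: tuple[float, float]) -> None:
        if self._expected_t0 is not None and abs(window[0] - self._expected_t0) > 1e-6:
            raise SequencingError(
                f"window {window} out of sequence; expected start {self._expected_t0}"
            )
        self._expected_t0 = window[1]

    # four-function API --------------------------------------------------
    def ready(self) -> bool:
        raise NotImplementedError

    def transfer(self, payload: TransferPayload | None = None):
        raise NotImplementedError

    def end_transfer(self) -> None:
        raise NotImplementedError

    def release(self) -> None:
        raise NotImplementedError


class _SharedSlot:
    """One-payload buffer shared by a thread-backend endpoint pair."""

    def __init__(self):
        self.cond = Condition()
        self.item: TransferPayload | None = None
        self.ended = False
        self.released_by: set[str] = set()


class _ThreadSendEndpoint(ChannelEndpoint):
    def __init__(self, slot: _SharedSlot, peer="receiver", timeout=DEFAULT_TIMEOUT, timer=None):
        super().__init__("send", peer, timeout)
        self._slot = slot
        self._timer = timer

    def ready(self) -> bool:
        self._check_usable()
        with self._slot.cond:
            return self._slot.item is None and not self._ended

    def transfer(self, payload: TransferPayload | None = None):
        self._check_usable()
        if self._ended:
            raise SequencingError("transfer after end_transfer")
        if payload is None:
            raise ContractError("send endpoint requires a payload")
        self._check_window(payload.window)
        t_start = time.perf_counter()
        with self._slot.cond:
            ok = self._slot.cond.wait_for(
                lambda: self._slot.item is None or "receive" in self._slot.released_by,
                timeout=self.timeout,
            )
            wait = time.perf_counter() - t_start
            if "receive" in self._slot.released_by:
                raise BrokenChannelError(f"peer {self.peer} released the channel")
            if not ok:
                raise DeadlockError(
                    f"send to {self.peer} blocked for more than {self.timeout} s"
                )
            self.status = "transferring"
            self._slot.item = payload
            self._slot.cond.notify_all()
        if self._timer is not None:
            total = time.perf_counter() - t_start
            self._timer.add("wait", wait)
            self._timer.add("io", total - wait)
        self.status = "ready"

    def end_transfer(self) -> None:
        self._check_usable()
        self._ended = True
        self.status = "ended"
        with self._slot.cond:
            self._slot.ended = True
            self._slot.cond.notify_all()

    def release(self) -> None:
        if self._released:
            return
        self._released = True
        self.status = "released"
        with self._slot.cond:
            self._slot.released_by.add("send")
            self._slot.cond.notify_all()


class _ThreadReceiveEndpoint(ChannelEndpoint):
    def __init__(self, slot: _SharedSlot, peer="sender", timeout=DEFAULT_TIMEOUT, timer=None):
        super().__init__("receive", peer, timeout)
        self._slot = slot
        self._timer = timer

    def ready(self) -> bool:
        self._check_usable()
        with self._slot.cond:
            return self._slot.item is not None or self._slot.ended

    def transfer(self, payload: TransferPayload | None = None) -> TransferPayload:
        self._check_usable()
        t_start = time.perf_counter()
        with self._slot.cond:
            ok = self._slot.cond.wait_for(
                lambda: self._slot.item is not None
                or self._slot.ended
                or "send" in self._slot.released_by,
                timeout=self.timeout,
            )
            wait = time.perf_counter() - t_start
            if self._slot.item is None:
                if self._slot.ended:
                    self.status = "ended"
                    raise EndOfStream("peer ended the transfer")
                if "send" in self._slot.released_by:
                    raise BrokenChannelError(f"peer {self.peer} released the channel")
                raise DeadlockError(
                    f"receive from {self.peer} blocked for more than {self.timeout} s"
                )
            item = self._slot.item
            self._slot.item = None
            self._slot.cond.notify_all()
        self._check_window(item.window)
        if self._timer is not None:
            total = time.perf_counter() - t_start
            self._timer.add("wait", wait)
            self._timer.add("io", total - wait)
        self.status = "ready"
        return item

    def end_transfer(self) -> None:
        self._check_usable()
        self._ended = True
        self.status = "ended"

    def release(self) -> None:
        if self._released:
            return
        self._released = True
        self.status = "released"
        with self._slot.cond:
            self._slot.released_by.add("receive")
            self._slot.cond.notify_all()


def make_thread_channel(
    timeout: float = DEFAULT_TIMEOUT,
    send_timer=None,
    recv_timer=None,
    name: str = "channel",
) -> tuple[ChannelEndpoint, ChannelEndpoint]:
    """Shared-memory channel: (send endpoint, receive endpoint)."""
    slot = _SharedSlot()
    return (
        _ThreadSendEndpoint(slot, peer=f"{name}:recv", timeout=timeout, timer=send_timer),
        _ThreadReceiveEndpoint(slot, peer=f"{name}:send", timeout=timeout, timer=recv_timer),
    )


# ---------------------------------------------------------------------------
# message-passing backend (separate processes, Unix-domain sockets)
# ---------------------------------------------------------------------------


def _poll_conn(conn: Connection, timeout: float, what: str) -> None:
    if not conn.poll(timeout):
        raise DeadlockError(f"{what} blocked for more than {timeout} s")


class _ProcessSendEndpoint(ChannelEndpoint):
    """Sender over a Connection.  May run one window ahead of the consumer:
    window k+1 is sent only after the acknowledgement of window k, so the
    in-flight message is the one-window buffer."""

    def __init__(self, conn: Connection, peer="receiver", timeout=DEFAULT_TIMEOUT, timer=None):
        super().__init__("send", peer, timeout)
        self._conn = conn
        self._outstanding = 0
        self._timer = timer

    def _drain_acks(self, block: bool) -> None:
        while self._outstanding > 0:
            if not block and not self._conn.poll(0):
                return
            _poll_conn(self._conn, self.timeout, f"send to {self.peer} (awaiting ack)")
            msg = self._conn.recv()
            if msg[0] != "ACK":
                raise BrokenChannelError(f"unexpected message {msg[0]!r} from {self.peer}")
            self._outstanding -= 1

    def ready(self) -> bool:
        self._check_usable()
        self._drain_acks(block=False)
        return self._outstanding == 0 and not self._ended

    def transfer(self, payload: TransferPayload | None = None):
        self._check_usable()
        if self._ended:
            raise SequencingError("transfer after end_transfer")
        if payload is None:
            raise ContractError("send endpoint requires a payload")
        self._check_window(payload.window)
        t_start = time.perf_counter()
        try:
            self._drain_acks(block=True)
            wait = time.perf_counter() - t_start
            self._conn.send(("DATA", payload))
        except (EOFError, BrokenPipeError, OSError) as exc:
            raise BrokenChannelError(f"peer {self.peer} disappeared: {exc}") from exc
        self._outstanding += 1
        if self._timer is not None:
            total = time.perf_counter() - t_start
            self._timer.add("wait", wait)
            self._timer.add("io", total - wait)
        self.status = "ready"

    def end_transfer(self) -> None:
        self._check_usable()
        if self._ended:
            return
        self._ended = True
        self.status = "ended"
        try:
            # END follows any in-flight DATA on the stream; the final ack
            # needs no waiting (release closes the connection regardless)
            self._drain_acks(block=False)
            self._conn.send(("END",))
        except (EOFError, BrokenPipeError, OSError):
            pass

    def release(self) -> None:
        if self._released:
            return
        self._released = True
        self.status = "released"
        try:
            self._conn.close()
        except OSError:
            pass


class _ProcessReceiveEndpoint(ChannelEndpoint):
    def __init__(self, conn: Connection, peer="sender", timeout=DEFAULT_TIMEOUT, timer=None):
        super().__init__("receive", peer, timeout)
        self._conn = conn
        self._timer = timer
        self._eos = False

    def ready(self) -> bool:
        self._check_usable()
        return self._eos or self._conn.poll(0)

    def transfer(self, payload: TransferPayload | None = None) -> TransferPayload:
        self._check_usable()
        if self._eos:
            raise EndOfStream("peer ended the transfer")
        t_start = time.perf_counter()
        try:
            _poll_conn(self._conn, self.timeout, f"receive from {self.peer}")
            wait = time.perf_counter() - t_start
            msg = self._conn.recv()
        except (EOFError, OSError) as exc:
            raise BrokenChannelError(f"peer {self.peer} disappeared: {exc}") from exc
        if msg[0] == "END":
            self._eos = True
            self.status = "ended"
            raise EndOfStream("peer ended the transfer")
        if msg[0] != "DATA":
            raise BrokenChannelError(f"unexpected message {msg[0]!r} from {self.peer}")
        item: TransferPayload = msg[1]
        self._check_window(item.window)
        try:
            self._conn.send(("ACK", item.window))
        except (EOFError, BrokenPipeError, OSError):
            pass
        if self._timer is not None:
            total = time.perf_counter() - t_start
            self._timer.add("wait", wait)
            self._timer.add("io", total - wait)
        self.status = "ready"
        return item

    def end_transfer(self) -> None:
        self._check_usable()
        self._ended = True
        self.status = "ended"

    def release(self) -> None:
        if self._released:
            return
        self._released = True
        self.status = "released"
        try:
            self._conn.close()
        except OSError:
            pass


class PendingListener:
    """Bound-but-not-yet-accepted side of a message-passing channel.

    Binding and accepting are split so a component can publish *all* its
    rendezvous addresses before blocking in any accept -- otherwise two
    components listening for each other would deadlock during start-up.
    """

    def __init__(self, name: str, run_dir: str | Path):
        self.name = name
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        # AF_UNIX paths are limited to ~107 characters, so the socket lives
        # in a short scratch directory; the .addr file points to it
        scratch = tempfile.mkdtemp(prefix="cosim-")
        self.address = str(Path(scratch) / "ch.sock")
        self._listener = Listener(self.address, family="AF_UNIX")
        addr_file = run_dir / f"{name}.addr"
        addr_file.parent.mkdir(parents=True, exist_ok=True)
        addr_file.write_text(self.address + "\n")

    def accept(self, role: str, timeout: float = DEFAULT_TIMEOUT, timer=None) -> ChannelEndpoint:
        try:
            sock = self._listener._listener._socket  # noqa: SLF001 - stdlib has no public knob
            sock.settimeout(timeout)
        except AttributeError:
            pass
        try:
            conn = self._listener.accept()
        except OSError as exc:
            self._listener.close()
            raise DeadlockError(
                f"no peer connected to channel {self.name!r} within {timeout} s"
            ) from exc
        self._listener.close()
        cls = _ProcessSendEndpoint if role == "send" else _ProcessReceiveEndpoint
        return cls(conn, peer=self.name, timeout=timeout, timer=timer)


def make_listener_endpoint(
    name: str,
    run_dir: str | Path,
    role: str,
    timeout: float = DEFAULT_TIMEOUT,
    timer=None,
) -> ChannelEndpoint:
    """Bind, publish the ``.addr`` rendezvous file and accept the peer
    (convenience wrapper; see :class:`PendingListener`)."""
    return PendingListener(name, run_dir).accept(role, timeout=timeout, timer=timer)


def make_client_endpoint(
    name: str,
    run_dir: str | Path,
    role: str,
    timeout: float = DEFAULT_TIMEOUT,
    timer=None,
) -> ChannelEndpoint:
    """Connect to the listening side via its rendezvous ``.addr`` file,
    polling until the file appears (start-up order independence)."""
    addr_file = Path(run_dir) / f"{name}.addr"
    deadline = time.monotonic() + timeout
    while not addr_file.exists():
        if time.monotonic() > deadline:
            raise DeadlockError(
                f"rendezvous file {addr_file} did not appear within {timeout} s"
            )
        time.sleep(0.005)
    address = addr_file.read_text().strip()
    while True:
        try:
            conn = Client(address, family="AF_UNIX")
            break
        except (ConnectionRefusedError, FileNotFoundError):
            if time.monotonic() > deadline:
                raise DeadlockError(f"could not connect to channel {name!r}")
            time.sleep(0.005)
    cls = _ProcessSendEndpoint if role == "send" else _ProcessReceiveEndpoint
    return cls(conn, peer=name, timeout=timeout, timer=timer)


# ---------------------------------------------------------------------------
# transfer module
# ---------------------------------------------------------------------------


def run_transfer_module(
    receive_from: ChannelEndpoint,
    transform: Callable[[TransferPayload], TransferPayload],
    send_to: ChannelEndpoint,
    n_windows: int | None = None,
    initial: TransferPayload | None = None,
    log: Callable[[str], None] | None = None,
) -> int:
    """Receive -> transform -> send until end-of-stream (or n_windows).

    Returns the number of windows moved.  Because both channels buffer one
    window, the next window can be received and transformed while the
    previous one waits to be consumed.  On a transform error the module
    aborts (both endpoints released) with the cause logged and re-raised.
    """
    moved = 0
    try:
        if initial is not None:
            send_to.transfer(initial)
        while n_windows is None or moved < n_windows:
            try:
                payload = receive_from.transfer()
            except EndOfStream:
                break
            try:
                out = transform(payload)
            except Exception as exc:
                if log:
                    log(f"transform failed on window {payload.window}: {exc!r}")
                raise TransferModuleError(
                    f"transform failed on window {payload.window}: {exc!r}"
                ) from exc
            if not isinstance(out, TransferPayload):
                raise ContractError("transform must return a TransferPayload")
            send_to.transfer(out)
            moved += 1
        send_to.end_transfer()
        receive_from.end_transfer()
    finally:
        receive_from.release()
        send_to.release()
    if log:
        log(f"transfer module done, {moved} windows moved")
    return moved


def initial_message(
    direction: str,
    t0: float,
    sync_step: float,
    spiking_regions: list[int] | None = None,
    initial_rates: dict[int, float] | None = None,
    n_trains: int = 1,
    mip_c: float = 0.1,
    rng: np.random.Generator | None = None,
) -> TransferPayload:
    """The message each simulator consumes before its first window.

    Toward the mass network: one window of (by default zero-) rate samples
    for every spiking region covering [t0 - sync_step, t0), preloading the
    proxy history.  Toward the spiking network: the MIP transform applied to
    the mass network's stored initial-condition rates.
    """
    window = (t0 - sync_step, t0)
    spiking_regions = spiking_regions or [0]
    if direction == "mass":
        body = {
            r: [
                RateSample(
                    region_id=r, pop="exc", t0=window[0], t1=window[1],
                    rate=float((initial_rates or {}).get(r, 0.0)),
                )
            ]
            for r in spiking_regions
        }
        return TransferPayload(kind="rates", window=window, body=body)
    if direction == "spiking":
        rng = rng or np.random.default_rng(0)
        body = {}
        for r in spiking_regions:
            rate = float((initial_rates or {}).get(r, 0.0))
            sample = RateSample(region_id=r, pop="exc", t0=window[0], t1=window[1], rate=rate)
            trains = rate_to_spikes_mip([sample], n_trains, mip_c, rng)
            times = np.sort(np.concatenate(trains)) if trains else np.empty(0)
            ids = np.zeros(times.size, dtype=np.int64)
            # flatten train ids by repetition order for inspection purposes
            lens = [t.size for t in trains]
            ids = np.concatenate(
                [np.full(sz, i, dtype=np.int64) for i, sz in enumerate(lens)]
            ) if sum(lens) else np.empty(0, dtype=np.int64)
            all_times = np.concatenate(trains) if sum(lens) else np.empty(0)
            order = np.argsort(all_times, kind="stable")
            body[r] = SpikeBlock(t0=window[0], t1=window[1], ids=ids[order], times=all_times[order])
        return TransferPayload(kind="spikes", window=window, body=body)
    raise ContractError(f"unknown direction {direction!r}")
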
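import threading
import time

import numpy as np
import pytest

from cosim.errors import (
    BrokenChannelError,
    ChannelStateError,
    ContractError,
    DeadlockError,
    EndOfStream,
    SequencingError,
    ValidationError,
)
from cosim.spiking import SpikeBlock
from cosim.transfer import (
    PendingListener,
    TransferPayload,
    initial_message,
    make_client_endpoint,
    make_thread_channel,
    run_transfer_module,
)
from cosim.transforms import RateSample, RateWindow, spikes_to_rate_array


def rate_payload(t0, t1, value=5.0, dt=1.0):
    n = int(round((t1 - t0) / dt))
    return TransferPayload(
        kind="rates", window=(t0, t1),
        body=RateWindow(t0=t0, t1=t1, dt=dt, values=np.full(n, value)),
    )


def spike_payload(t0, t1, n_events=10, seed=0):
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(t0, t1 - 1e-9, n_events))
    ids = rng.integers(0, 5, n_events)
    return TransferPayload(
        kind="spikes", window=(t0, t1),
        body=SpikeBlock(t0=t0, t1=t1, ids=ids, times=times),
    )


class TestPayload:
    def test_kind_body_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            TransferPayload(kind="rates", window=(0.0, 1.0),
                            body=SpikeBlock(0.0, 1.0))

    def test_window_body_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            TransferPayload(kind="spikes", window=(0.0, 2.0),
                            body=SpikeBlock(1.0, 3.0))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            TransferPayload(kind="frames", window=(0.0, 1.0), body=None)


class ChannelContract:
    """Behavioural contract shared by both channel backends."""

    def make(self, timeout=5.0):
        raise NotImplementedError

    def test_fresh_send_endpoint_is_ready(self):
        send, recv = self.make()
        assert send.ready()
        send.release(); recv.release()

    def test_one_window_buffering(self):
        send, recv = self.make()
        send.transfer(rate_payload(0.0, 2.0))
        assert not send.ready()          # unconsumed window in the buffer
        assert recv.ready()
        recv.transfer()
        assert send.ready()              # consumption frees the slot
        send.release(); recv.release()

    def test_fifo_exactly_once_round_trip(self):
        send, recv = self.make()
        payloads = [spike_payload(2 * k, 2 * k + 2, seed=k) for k in range(3)]
        got = []

        def consumer():
            for _ in range(3):
                got.append(recv.transfer())

        t = threading.Thread(target=consumer)
        t.start()
        for p in payloads:
            send.transfer(p)
        t.join(timeout=5)
        assert [g.window for g in got] == [p.window for p in payloads]
        for g, p in zip(got, payloads):
            np.testing.assert_array_equal(g.body.times, p.body.times)
            np.testing.assert_array_equal(g.body.ids, p.body.ids)
        send.release(); recv.release()

    def test_sender_two_ahead_blocks_until_consumption(self):
        send, recv = self.make(timeout=0.3)
        send.transfer(rate_payload(0.0, 1.0))
        start = time.perf_counter()
        released = []

        def consume_later():
            time.sleep(0.15)
            released.append(recv.transfer())

        t = threading.Thread(target=consume_later)
        t.start()
        send.transfer(rate_payload(1.0, 2.0))  # must block ~0.15 s
        elapsed = time.perf_counter() - start
        t.join()
        assert elapsed >= 0.1
        recv.transfer()
        send.release(); recv.release()

    def test_blocked_sender_times_out_as_deadlock(self):
        send, recv = self.make(timeout=0.2)
        send.transfer(rate_payload(0.0, 1.0))
        with pytest.raises(DeadlockError):
            send.transfer(rate_payload(1.0, 2.0))
        send.release(); recv.release()

    def test_out_of_sequence_window_rejected(self):
        send, recv = self.make()
        send.transfer(rate_payload(0.0, 2.0))
        with pytest.raises(SequencingError):
            send.transfer(rate_payload(5.0, 7.0))
        send.release(); recv.release()

    def test_end_then_transfer_is_an_error(self):
        send, recv = self.make()
        send.end_transfer()
        with pytest.raises(SequencingError):
            send.transfer(rate_payload(0.0, 1.0))
        send.release(); recv.release()

    def test_double_release_is_idempotent(self):
        send, recv = self.make()
        for _ in range(2):
            send.release()
            recv.release()

    def test_use_after_release_rejected(self):
        send, recv = self.make()
        send.release()
        with pytest.raises(ChannelStateError):
            send.transfer(rate_payload(0.0, 1.0))
        recv.release()

    def test_end_of_stream_after_draining(self):
        send, recv = self.make()
        send.transfer(rate_payload(0.0, 2.0))
        send.end_transfer()
        got = recv.transfer()  # buffered window drains first
        assert got.window == (0.0, 2.0)
        with pytest.raises(EndOfStream):
            recv.transfer()
        send.release(); recv.release()


class TestThreadChannel(ChannelContract):
    def make(self, timeout=5.0):
        return make_thread_channel(timeout=timeout)

    def test_receiver_sees_broken_channel_if_sender_vanishes(self):
        send, recv = self.make(timeout=0.5)
        send.release()
        with pytest.raises(BrokenChannelError):
            recv.transfer()
        recv.release()


class TestProcessChannel(ChannelContract):
    """Same contract over the message-passing backend (exercised with the
    two endpoints living in threads of this process)."""

    def make(self, timeout=5.0, tmpdir=[0]):
        import tempfile
        d = tempfile.mkdtemp(prefix="chan")
        pending = PendingListener("chan", d)
        result = {}

        def connect():
            result["recv"] = make_client_endpoint("chan", d, "receive", timeout=timeout)

        t = threading.Thread(target=connect)
        t.start()
        send = pending.accept("send", timeout=timeout)
        t.join(timeout=5)
        return send, result["recv"]


class TestTransferModule:
    def test_identity_transform_preserves_windows(self):
        a_send, a_recv = make_thread_channel()
        b_send, b_recv = make_thread_channel()
        payloads = [rate_payload(2 * k, 2 * k + 2, value=k) for k in range(5)]

        def producer():
            for p in payloads:
                a_send.transfer(p)
            a_send.end_transfer()
            a_send.release()

        got = []

        def consumer():
            while True:
                try:
                    got.append(b_recv.transfer())
                except EndOfStream:
                    break
            b_recv.release()

        threads = [threading.Thread(target=producer), threading.Thread(target=consumer)]
        for t in threads:
            t.start()
        moved = run_transfer_module(a_recv, lambda p: p, b_send)
        for t in threads:
            t.join(timeout=5)
        assert moved == 5
        assert [g.window for g in got] == [p.window for p in payloads]
        np.testing.assert_array_equal(got[3].body.values, payloads[3].body.values)

    def test_spikes_to_rate_transform_matches_offline(self):
        a_send, a_recv = make_thread_channel()
        b_send, b_recv = make_thread_channel()
        payloads = [spike_payload(5 * k, 5 * k + 5, n_events=40, seed=k) for k in range(4)]

        def transform(p):
            rates = spikes_to_rate_array(p.body, 5, 1.0)
            return TransferPayload(
                kind="rates", window=p.window,
                body=RateWindow(p.window[0], p.window[1], 1.0, rates),
            )

        def producer():
            for p in payloads:
                a_send.transfer(p)
            a_send.end_transfer()
            a_send.release()

        got = []

        def consumer():
            while True:
                try:
                    got.append(b_recv.transfer())
                except EndOfStream:
                    return

        threads = [threading.Thread(target=producer), threading.Thread(target=consumer)]
        for t in threads:
            t.start()
        run_transfer_module(a_recv, transform, b_send)
        for t in threads:
            t.join(timeout=5)
        for g, p in zip(got, payloads):
            np.testing.assert_array_equal(
                g.body.values, spikes_to_rate_array(p.body, 5, 1.0)
            )

    def test_zero_windows_clean_drain(self):
        a_send, a_recv = make_thread_channel()
        b_send, b_recv = make_thread_channel()
        a_send.end_transfer()
        moved = run_transfer_module(a_recv, lambda p: p, b_send)
        assert moved == 0
        with pytest.raises((EndOfStream, BrokenChannelError)):
            b_recv.transfer()


class TestInitialMessage:
    def test_mass_direction_zero_rates_preceding_t0(self):
        msg = initial_message("mass", t0=0.0, sync_step=2.0, spiking_regions=[0, 1])
        assert msg.kind == "rates"
        assert msg.window == (-2.0, 0.0)
        for r in (0, 1):
            assert msg.body[r][0].rate == 0.0
            assert (msg.body[r][0].t0, msg.body[r][0].t1) == (-2.0, 0.0)

    def test_spiking_direction_mip_grand_mean(self):
        rate, n_trains = 10.0, 50
        totals = []
        for seed in range(40):
            msg = initial_message(
                "spiking", t0=0.0, sync_step=1000.0, spiking_regions=[0],
                initial_rates={0: rate}, n_trains=n_trains, mip_c=0.1,
                rng=np.random.default_rng(seed),
            )
            assert msg.window == (-1000.0, 0.0)
            totals.append(msg.body[0].n_events / (n_trains * 1.0))
        # grand-mean per-train rate over seeds ~ 10 Hz
        assert np.mean(totals) == pytest.approx(rate, rel=0.1)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ContractError):
            initial_message("sideways", 0.0, 1.0)
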
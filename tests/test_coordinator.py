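"""Transfer safety, registry semantics, exactly-once reconstruction triggering."""

import itertools
import threading
from pathlib import Path

import numpy as np
import pytest

from tiltpipe.coordinator import (CoordinatorServer, TransferItem, client_scan,
                                  file_checksum, transfer)


# ---------------------------------------------------------------------------
# scanning and transfer
# ---------------------------------------------------------------------------

class TestClientScan:
    def test_empty_dir_yields_nothing(self, tmp_path):
        ready, sizes = client_scan(tmp_path, set(), {})
        assert ready == [] and sizes == {}

    def test_sidecars_order_before_movies_once_stable(self, tmp_path):
        for name in ("b.mrc", "a.mrc", "s.mdoc"):
            (tmp_path / name).write_bytes(b"x" * 10)
        ready, sizes = client_scan(tmp_path, set(), {})
        assert ready == []  # first sighting: not yet size-stable
        ready, _ = client_scan(tmp_path, set(), sizes)
        assert [Path(p).name for p in ready] == ["s.mdoc", "a.mrc", "b.mrc"]

    def test_growing_file_excluded_until_stable(self, tmp_path):
        f = tmp_path / "grow.mrc"
        f.write_bytes(b"x")
        _, sizes = client_scan(tmp_path, set(), {})
        f.write_bytes(b"xxxx")  # grew between scans
        ready, sizes = client_scan(tmp_path, set(), sizes)
        assert ready == []
        ready, _ = client_scan(tmp_path, set(), sizes)
        assert [Path(p).name for p in ready] == ["grow.mrc"]

    def test_unreadable_root_is_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            client_scan(tmp_path / "ghost", set(), {})


class TestTransfer:
    def _item(self, tmp_path, payload=b"m" * (1 << 20)):
        src = tmp_path / "det" / "a.mrc"
        src.parent.mkdir()
        src.write_bytes(payload)
        return TransferItem(source=str(src), destination=str(tmp_path / "fac" / "a.mrc"))

    def test_verified_copy_with_source_removal(self, tmp_path):
        item = self._item(tmp_path)
        checksum = file_checksum(item.source)
        transfer(item, remove_source=True)
        assert item.state == "removed"
        assert not Path(item.source).exists()
        assert file_checksum(item.destination) == checksum == item.checksum

    def test_source_retained_without_removal_flag(self, tmp_path):
        item = self._item(tmp_path)
        transfer(item, remove_source=False)
        assert item.state == "verified" and Path(item.source).exists()

    def test_interrupted_copy_fails_cleanly_then_retry_succeeds(self, tmp_path):
        item = self._item(tmp_path)

        def interrupt(copied):
            if copied > 200_000:
                raise IOError("link dropped")

        transfer(item, remove_source=True, fault=interrupt)
        assert item.state == "failed"
        assert Path(item.source).exists()  # never removed without verification
        assert not Path(item.destination).exists()  # no partial left behind
        transfer(item, remove_source=True)
        assert item.state == "removed" and Path(item.destination).exists()

    def test_no_source_loss_across_many_random_interruptions(self, tmp_path):
        """Seeded interruptions at random byte offsets: sources survive until
        their destination copy is checksum-verified, and all converge."""
        rng = np.random.default_rng(1234)
        n = 100
        for i in range(n):
            payload = rng.integers(0, 256, size=int(rng.integers(1, 200_000)),
                                   dtype=np.uint8).tobytes()
            src = tmp_path / "det" / f"f{i:03d}.mrc"
            src.parent.mkdir(exist_ok=True)
            src.write_bytes(payload)
            item = TransferItem(source=str(src),
                                destination=str(tmp_path / "fac" / src.name))
            cut = int(rng.integers(0, len(payload) + 1))

            def interrupt(copied, cut=cut):
                if copied >= cut:
                    raise IOError("injected")

            transfer(item, remove_source=True, fault=interrupt)
            if item.state != "removed":
                assert Path(item.source).exists()  # safety invariant
                transfer(item, remove_source=True)
            assert item.state == "removed"
            assert file_checksum(item.destination) == item.checksum


# ---------------------------------------------------------------------------
# registry server
# ---------------------------------------------------------------------------

class CountingDispatcher:
    def __init__(self):
        self.requests = []

    def dispatch(self, request):
        self.requests.append(request)
        return f"m{len(self.requests)}"


@pytest.fixture
def server():
    s = CoordinatorServer(dispatcher=CountingDispatcher(), session="s")
    return s


def _register_series(server, sid="Pos1", n=3, corrected=True):
    for i in range(n):
        angle = -10.0 + 10 * i
        server.register_movie(f"/fac/{sid}_{i:03d}_{angle:+.1f}.mrc", None)
    if corrected:
        for i in range(n):
            angle = -10.0 + 10 * i
            server.mark_motion_corrected(f"{sid}_{i:03d}_{angle:+.1f}", {},
                                         micrograph_path=f"/mc/{sid}_{i}.mrc")


class TestRegistry:
    def test_register_resolves_series_from_filename_and_dispatches_once(self, server):
        rec = server.register_movie("/fac/Pos1_005_-20.0.mrc", None)
        assert rec["series_id"] == "Pos1" and rec["tilt_angle"] == -20.0
        assert rec["preprocess_dispatched"] == 1
        assert len(server.dispatched) == 1
        server.register_movie("/fac/Pos1_005_-20.0.mrc", None)  # duplicate
        assert len(server.dispatched) == 1

    def test_sidecar_metadata_takes_precedence(self, server):
        rec = server.register_movie("/fac/whatever.mrc", {
            "series_id": "GridA", "tilt": {"TiltAngle": -35.0}})
        assert rec["series_id"] == "GridA" and rec["tilt_angle"] == -35.0

    def test_unresolvable_movie_quarantined_without_blocking_others(self, server):
        rec = server.register_movie("/fac/garbage.mrc", None)
        assert rec["quarantined"] == 1
        assert server.alerts[0]["kind"] == "unresolved_series"
        # an unrelated series still completes
        _register_series(server, "Pos2", 2)
        server.mark_series_acquired("Pos2", 2)
        assert server.series_record("Pos2")["reconstruction_triggered"] == 1

    def test_reconstruction_triggers_only_when_all_corrected_and_acquired(self, server):
        _register_series(server, "Pos1", 3, corrected=False)
        server.mark_series_acquired("Pos1", 3)
        assert server.series_record("Pos1")["reconstruction_triggered"] == 0
        for i in range(2):
            angle = -10.0 + 10 * i
            server.mark_motion_corrected(f"Pos1_{i:03d}_{angle:+.1f}", {})
        assert server.series_record("Pos1")["reconstruction_triggered"] == 0
        server.mark_motion_corrected("Pos1_002_+10.0", {})
        assert server.series_record("Pos1")["reconstruction_triggered"] == 1
        recons = [r for r in server.dispatched if r["recipe"] == "reconstruct"]
        assert len(recons) == 1
        assert [t["tilt_angle"] for t in recons[0]["parameters"]["tilts"]] == \
            [-10.0, 0.0, 10.0]

    def test_acquired_event_may_arrive_first(self, server):
        server.mark_series_acquired("Pos1", 2)
        assert server.series_record("Pos1")["reconstruction_triggered"] == 0
        _register_series(server, "Pos1", 2)
        assert server.series_record("Pos1")["reconstruction_triggered"] == 1

    def test_duplicate_corrected_marks_do_not_double_dispatch(self, server):
        _register_series(server, "Pos1", 2)
        server.mark_series_acquired("Pos1", 2)
        for _ in range(3):  # redeliveries
            server.mark_motion_corrected("Pos1_000_-10.0", {})
        recons = [r for r in server.dispatched if r["recipe"] == "reconstruct"]
        assert len(recons) == 1

    def test_unknown_movie_mark_is_logged_noop(self, server):
        server.mark_motion_corrected("ghost", {})
        assert server.registry_state()["movies"] == []

    def test_declared_count_conflict_raises_expected_and_alerts(self, server):
        _register_series(server, "Pos1", 4)
        server.mark_series_acquired("Pos1", 3)  # fewer than observed
        assert server.alerts[-1]["kind"] == "expected_tilts_conflict"
        assert server.series_record("Pos1")["expected_tilts"] == 4
        assert server.series_record("Pos1")["reconstruction_triggered"] == 1


class TestOrderingIndependence:
    def _events(self, sid="Pos1", n=4):
        events = [("acquired", sid, n)]
        for i in range(n):
            angle = -10.0 + 10 * i
            mid = f"{sid}_{i:03d}_{angle:+.1f}"
            events.append(("register", f"/fac/{mid}.mrc"))
            events.append(("mark", mid))
        return events

    def _apply(self, events):
        server = CoordinatorServer(dispatcher=CountingDispatcher(), session="s")
        for ev in events:
            if ev[0] == "register":
                server.register_movie(ev[1], None)
            elif ev[0] == "mark":
                server.mark_motion_corrected(ev[1], {})
            else:
                server.mark_series_acquired(ev[1], ev[2])
        return server

    def test_permuted_arrival_orders_converge_to_identical_state(self):
        """Causally consistent permutations (a movie registers before its
        correction mark) all reach the same registry state, one dispatch."""
        base = self._events()
        rng = np.random.default_rng(99)
        reference = None
        for _ in range(50):
            order = list(base)
            while True:
                rng.shuffle(order)
                ok = all(
                    order.index(("register", f"/fac/{mid}.mrc"))
                    < order.index(("mark", mid))
                    for mid in [e[1] for e in base if e[0] == "mark"])
                if ok:
                    break
            server = self._apply(order)
            state = server.registry_state()
            recons = [r for r in server.dispatched if r["recipe"] == "reconstruct"]
            assert len(recons) == 1
            if reference is None:
                reference = state
            else:
                assert state == reference

    def test_concurrent_completion_checks_dispatch_exactly_once(self):
        server = CoordinatorServer(dispatcher=CountingDispatcher(), session="s")
        _register_series(server, "Pos1", 3, corrected=True)
        barrier = threading.Barrier(8)

        def race():
            barrier.wait()
            server.mark_series_acquired("Pos1", 3)
            server.series_ready("Pos1")

        threads = [threading.Thread(target=race) for _ in range(8)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        recons = [r for r in server.dispatched if r["recipe"] == "reconstruct"]
        assert len(recons) == 1


class TestHttpBinding:
    def test_endpoints_mirror_in_process_semantics(self):
        from tiltpipe.http_api import HttpCoordinatorClient, serve_coordinator
        server = CoordinatorServer(dispatcher=CountingDispatcher(), session="s")
        httpd, _ = serve_coordinator(server, port=0)
        try:
            client = HttpCoordinatorClient(f"http://127.0.0.1:{httpd.server_address[1]}")
            rec = client.register_movie("/fac/Pos9_000_-10.0.mrc")
            assert rec["series_id"] == "Pos9"
            client.mark_series_acquired("Pos9", 1)
            client.mark_motion_corrected("Pos9_000_-10.0", {}, "/mc/x.mrc")
            assert client.series_record("Pos9")["reconstruction_triggered"] == 1
            assert len(client.registry_state()["movies"]) == 1
        finally:
            httpd.shutdown()
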
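"""File watcher: detection, stability, exactly-once delivery, logging."""

import time
from datetime import datetime, timedelta
from pathlib import Path

import pytest
from hypothesis import given, strategies as st

from scopeflow.filewatch import (
    ExecutionRecord,
    ExperimentLog,
    LogParseError,
    WatchConfig,
    WatchState,
    latency_summary,
    parse_log,
    run_watcher,
    scan_folder,
    write_log,
)
from tests.conftest import FAST_POLL, wait_until


def _cfg(folder, **kw):
    kw.setdefault("extensions", (".h5",))
    kw.setdefault("poll_interval_s", FAST_POLL)
    return WatchConfig(folder=folder, **kw)


class TestScanFolder:
    def test_empty_folder_yields_empty_batch(self, tmp_path):
        batch = scan_folder(WatchState(), _cfg(tmp_path))
        assert batch.paths == ()

    def test_two_polls_deliver_stable_files_in_canonical_order(self, tmp_path):
        state = WatchState()
        cfg = _cfg(tmp_path)
        (tmp_path / "b.h5").write_bytes(b"bbb")
        (tmp_path / "a.h5").write_bytes(b"aaa")
        (tmp_path / "ignored.txt").write_bytes(b"x")
        assert scan_folder(state, cfg).paths == ()  # first poll: snapshot only
        batch = scan_folder(state, cfg)
        assert [p.name for p in batch.paths] == ["a.h5", "b.h5"]

    def test_delivered_paths_never_redelivered(self, tmp_path):
        state = WatchState()
        cfg = _cfg(tmp_path)
        (tmp_path / "a.h5").write_bytes(b"aaa")
        scan_folder(state, cfg)
        assert scan_folder(state, cfg).paths != ()
        for _ in range(3):
            assert scan_folder(state, cfg).paths == ()

    def test_growing_file_held_until_stable(self, tmp_path):
        state = WatchState()
        cfg = _cfg(tmp_path)
        f = tmp_path / "grow.h5"
        f.write_bytes(b"12")
        scan_folder(state, cfg)
        f.write_bytes(b"1234")  # grew between polls: signature changed
        assert scan_folder(state, cfg).paths == ()
        batch = scan_folder(state, cfg)  # unchanged since previous poll
        assert [p.name for p in batch.paths] == ["grow.h5"]

    def test_directory_dataset_stability(self, tmp_path):
        """A .zarr store (a directory) is judged on recursive contents."""
        state = WatchState()
        cfg = _cfg(tmp_path, extensions=(".zarr",))
        store = tmp_path / "x.zarr"
        store.mkdir()
        (store / "0.0").write_bytes(b"chunk")
        scan_folder(state, cfg)
        (store / "1.0").write_bytes(b"chunk")  # still being filled
        assert scan_folder(state, cfg).paths == ()
        batch = scan_folder(state, cfg)
        assert [p.name for p in batch.paths] == ["x.zarr"]

    def test_missing_folder_raises(self, tmp_path):
        cfg = _cfg(tmp_path / "nope")
        with pytest.raises(FileNotFoundError):
            scan_folder(WatchState(), cfg)


class TestRunWatcher:
    def test_preexisting_files_suppressed_by_default(self, tmp_path):
        for i in range(3):
            (tmp_path / f"old{i}.h5").write_bytes(b"x")
        seen = []
        session = run_watcher(_cfg(tmp_path), item_handler=seen.append)
        time.sleep(4 * FAST_POLL)
        session.stop_and_join()
        assert seen == []

    def test_preexisting_files_delivered_when_requested(self, tmp_path):
        for i in range(3):
            (tmp_path / f"old{i}.h5").write_bytes(b"x")
        seen = []
        session = run_watcher(
            _cfg(tmp_path, process_preexisting=True), item_handler=seen.append
        )
        wait_until(lambda: len(seen) == 3, message="preexisting delivery")
        session.stop_and_join()

    def test_dropper_files_delivered_once_each_in_drop_order(self, tmp_path):
        """Scripted file-dropper: one file per poll interval, delivered
        exactly once each, in drop order (exactly-once + FIFO)."""
        seen = []
        session = run_watcher(_cfg(tmp_path), item_handler=seen.append)
        names = [f"f{i}.h5" for i in range(5)]
        for name in names:
            (tmp_path / name).write_bytes(b"payload")
            time.sleep(FAST_POLL)
        wait_until(lambda: len(seen) == 5, message="5 deliveries")
        time.sleep(4 * FAST_POLL)  # no late duplicates
        session.stop_and_join()
        assert [p.name for p in seen] == names
        assert len(set(seen)) == len(seen)
        assert len(session.log.records) == 5
        assert all(r.status == "ok" for r in session.log.records)

    def test_handler_failure_recorded_and_queue_continues(self, tmp_path):
        processed = []

        def handler(path: Path) -> None:
            if "f1" in path.name:
                raise RuntimeError("boom")
            processed.append(path.name)

        session = run_watcher(_cfg(tmp_path), item_handler=handler)
        for name in ("f0.h5", "f1.h5", "f2.h5"):
            (tmp_path / name).write_bytes(b"x")
        wait_until(lambda: len(session.log.records) == 3, message="3 records")
        session.stop_and_join()
        assert processed == ["f0.h5", "f2.h5"]
        statuses = [r.status for r in session.log.records]
        assert statuses.count("failed") == 1
        assert statuses.count("ok") == 2

    def test_logger_conservation(self, tmp_path):
        """Record count equals items handled, ok and failed together."""
        session = run_watcher(_cfg(tmp_path), item_handler=lambda p: None)
        for i in range(7):
            (tmp_path / f"f{i}.h5").write_bytes(b"x")
        wait_until(lambda: len(session.delivered) == 7, message="deliveries")
        session.stop_and_join()
        assert len(session.log.records) == len(session.delivered) == 7


# ---------------------------------------------------------------------------
# logger file
# ---------------------------------------------------------------------------


def _ms(dt: datetime) -> datetime:
    return dt.replace(microsecond=(dt.microsecond // 1000) * 1000)


def _mklog(latencies, role="reconstruction", status="ok"):
    t0 = _ms(datetime(2024, 5, 1, 12, 0, 0))
    log = ExperimentLog(host_name="unitA", started_at=t0, unit_role=role)
    for i, lat in enumerate(latencies):
        arr = t0 + timedelta(seconds=10 * i)
        fin = arr + timedelta(seconds=lat)
        log.append(ExecutionRecord(Path(f"/data/f{i}.zarr"), arr, fin, lat, status))
    return log


class TestLoggerFile:
    def test_empty_log_writes_header_only(self, tmp_path):
        path = write_log(_mklog([]), tmp_path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        assert lines[0] == "host: unitA"
        assert lines[1] == "role: reconstruction"

    def test_roundtrip_identity(self, tmp_path):
        log = _mklog([2.0, 4.0, 1.5])
        parsed = parse_log(write_log(log, tmp_path))
        assert parsed == log

    def test_records_written_in_arrival_order(self, tmp_path):
        log = _mklog([1.0, 2.0])
        log.records.reverse()
        parsed = parse_log(write_log(log, tmp_path))
        assert [r.item_path.name for r in parsed.records] == ["f0.zarr", "f1.zarr"]

    def test_same_folder_writes_never_collide(self, tmp_path):
        log = _mklog([1.0])
        paths = {write_log(log, tmp_path) for _ in range(3)}
        assert len(paths) == 3

    def test_inconsistent_latency_names_line(self, tmp_path):
        path = write_log(_mklog([2.0]), tmp_path)
        text = path.read_text().replace("\t2.000\t", "\t9.999\t")
        bad = tmp_path / "bad.log"
        bad.write_text(text)
        with pytest.raises(LogParseError, match=r":4:"):
            parse_log(bad)

    def test_malformed_line_rejected(self, tmp_path):
        path = write_log(_mklog([1.0]), tmp_path)
        bad = tmp_path / "bad.log"
        bad.write_text(path.read_text() + "not a record line\n")
        with pytest.raises(LogParseError, match=r":5:"):
            parse_log(bad)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=3600.0).map(lambda x: round(x, 3)),
            max_size=20,
        )
    )
    def test_roundtrip_property(self, tmp_path_factory, latencies):
        log = _mklog(latencies)
        folder = tmp_path_factory.mktemp("logs")
        assert parse_log(write_log(log, folder)) == log


class TestLatencySummary:
    def test_basic_stats(self):
        s = latency_summary(_mklog([2.0, 4.0]))
        assert s == {"n": 2, "min_s": 2.0, "max_s": 4.0, "mean_s": 3.0, "n_failed": 0}

    def test_constant_latencies(self):
        assert latency_summary(_mklog([1.5] * 100))["mean_s"] == pytest.approx(1.5)

    def test_failed_records_excluded_but_counted(self):
        log = _mklog([2.0, 4.0])
        t0 = log.started_at
        log.append(ExecutionRecord(Path("/data/bad.zarr"), t0, t0, 0.0, "failed"))
        s = latency_summary(log)
        assert s["n"] == 2 and s["n_failed"] == 1 and s["mean_s"] == 3.0

    def test_empty_log_flagged(self):
        s = latency_summary(_mklog([]))
        assert s["n"] == 0 and s["mean_s"] is None
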
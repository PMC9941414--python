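"""Polling file watcher and per-experiment execution logger.

The watcher is the framework's only synchronization primitive: units are
coupled through a shared folder, so a unit discovers work by periodically
listing that folder and picking up files that (a) match a configured
suffix, (b) have not been delivered before, and (c) are *stable* — their
size and mtime are unchanged across two consecutive polls, so a writer on
another machine has plausibly finished with them.  Zarr stores are
directories; those are judged stable on recursive file count + total size.

Every unit also keeps an :class:`ExperimentLog` — one timing record per
item processed (arrival to finish) — written as a plain-text logger file
when the session ends, and parseable back for latency analysis.
"""

from __future__ import annotations

import logging
import os
import socket
import threading
import time
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Callable, Iterable

__all__ = [
    "WatchConfig",
    "FileBatch",
    "WatchState",
    "ExecutionRecord",
    "ExperimentLog",
    "WatchSession",
    "scan_folder",
    "run_watcher",
    "write_log",
    "parse_log",
    "latency_summary",
    "LogParseError",
]

logger = logging.getLogger(__name__)

_TS_FMT = "%Y-%m-%dT%H:%M:%S.%f"


class LogParseError(ValueError):
    """Raised when a logger file line cannot be parsed or is inconsistent."""


@dataclass(frozen=True)
class WatchConfig:
    """Where and how to poll.

    Parameters
    ----------
    folder:
        The watched directory; must exist when a session starts.
    extensions:
        Filename suffixes to pick up (e.g. ``[".zarr", ".h5"]``).
    poll_interval_s:
        Seconds between directory listings (> 0).  Default 1 s.
    process_preexisting:
        If False (default), files already present when the session starts
        are marked seen without being delivered — the session watches from
        "now on".  Set True to reprocess a folder's existing contents.
    """

    folder: Path
    extensions: tuple[str, ...] = (".zarr", ".h5", ".hdf5", ".tiff", ".tif")
    poll_interval_s: float = 1.0
    process_preexisting: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "folder", Path(self.folder))
        object.__setattr__(self, "extensions", tuple(self.extensions))
        if self.poll_interval_s <= 0:
            raise ValueError("poll_interval_s must be > 0")
        if not self.extensions:
            raise ValueError("extensions must be non-empty")


@dataclass(frozen=True)
class FileBatch:
    """An ordered batch of newly detected, stable paths."""

    paths: tuple[Path, ...]
    detected_at: datetime

    def __len__(self) -> int:
        return len(self.paths)


@dataclass
class WatchState:
    """Per-session delivery bookkeeping.

    ``seen`` holds every path already delivered (or suppressed at startup);
    it only grows, which is what makes delivery exactly-once.
    ``pending_snapshot`` maps candidate paths to the (size, mtime_ns)
    signature observed at the previous poll; a candidate is delivered only
    when its signature is unchanged.
    """

    seen: set[Path] = field(default_factory=set)
    pending_snapshot: dict[Path, tuple[int, int]] = field(default_factory=dict)


@dataclass
class ExecutionRecord:
    """Arrival-to-finish timing of one processed item."""

    item_path: Path
    arrival_time: datetime
    finish_time: datetime
    latency_s: float
    status: str  # "ok" | "failed"

    def __post_init__(self) -> None:
        self.item_path = Path(self.item_path)
        if self.status not in ("ok", "failed"):
            raise ValueError(f"status must be ok|failed, got {self.status!r}")
        if self.finish_time < self.arrival_time:
            raise ValueError("finish_time must be >= arrival_time")


@dataclass
class ExperimentLog:
    """One unit's per-session processing log."""

    host_name: str
    started_at: datetime
    unit_role: str  # acquisition | reconstruction | orchestrator
    records: list[ExecutionRecord] = field(default_factory=list)

    def append(self, record: ExecutionRecord) -> None:
        self.records.append(record)


def _entry_signature(path: Path) -> tuple[int, int] | None:
    """(size, mtime_ns) for a file; (n_files, total_size) for a directory
    dataset such as a ``.zarr`` store.  None if unreadable."""
    try:
        st = path.stat()
    except OSError:
        return None
    if path.is_dir():
        n = 0
        total = 0
        try:
            for root, _dirs, files in os.walk(path):
                for f in files:
                    n += 1
                    try:
                        total += os.stat(os.path.join(root, f)).st_size
                    except OSError:
                        pass
        except OSError:
            return None
        return (n, total)
    return (st.st_size, st.st_mtime_ns)


def _list_candidates(config: WatchConfig) -> list[Path]:
    out = []
    for entry in config.folder.iterdir():
        if any(entry.name.endswith(ext) for ext in config.extensions):
            out.append(entry.resolve())
    return out


def _batch_order(paths: Iterable[Path]) -> list[Path]:
    """Canonical ordering: lexicographic by filename, mtime tie-break."""

    def key(p: Path):
        try:
            mt = p.stat().st_mtime_ns
        except OSError:
            mt = 0
        return (p.name, mt)

    return sorted(set(paths), key=key)


def scan_folder(state: WatchState, config: WatchConfig) -> FileBatch:
    """One poll: return the batch of new stable files, updating ``state``.

    A path is delivered when its size+mtime signature matches the one
    captured at the previous poll; otherwise the fresh signature is stored
    and the path is retried next poll.  Delivered paths enter
    ``state.seen`` and are never delivered again.
    """
    if not config.folder.is_dir():
        raise FileNotFoundError(f"watched folder does not exist: {config.folder}")
    ready: list[Path] = []
    for path in _list_candidates(config):
        if path in state.seen:
            continue
        sig = _entry_signature(path)
        if sig is None:
            logger.warning("unreadable entry skipped: %s", path)
            continue
        previous = state.pending_snapshot.get(path)
        if previous is not None and previous == sig:
            ready.append(path)
            state.seen.add(path)
            del state.pending_snapshot[path]
        else:
            state.pending_snapshot[path] = sig
    return FileBatch(paths=tuple(_batch_order(ready)), detected_at=datetime.now())


class WatchSession:
    """A running watch loop on its own thread.

    Created by :func:`run_watcher`; call :meth:`stop` to terminate after
    the current poll, then :meth:`join`.  The session owns an
    :class:`ExperimentLog`; with an ``item_handler`` each delivered path is
    processed individually and timed into an :class:`ExecutionRecord`
    (exceptions yield a ``failed`` record and the loop continues).
    """

    def __init__(
        self,
        config: WatchConfig,
        handler: Callable[[FileBatch], None] | None = None,
        item_handler: Callable[[Path], None] | None = None,
        role: str = "orchestrator",
    ) -> None:
        if (handler is None) == (item_handler is None):
            raise ValueError("provide exactly one of handler / item_handler")
        if not config.folder.is_dir():
            raise FileNotFoundError(f"watched folder does not exist: {config.folder}")
        self.config = config
        self._handler = handler
        self._item_handler = item_handler
        self.state = WatchState()
        self.log = ExperimentLog(
            host_name=socket.gethostname(),
            started_at=datetime.now(),
            unit_role=role,
        )
        self.delivered: list[Path] = []
        self._stop = threading.Event()
        self._busy = threading.Event()
        self.last_activity = time.monotonic()
        if not config.process_preexisting:
            # mark startup contents seen without delivery
            for path in _list_candidates(config):
                self.state.seen.add(path)
        self._thread = threading.Thread(target=self._loop, daemon=True)

    def start(self) -> "WatchSession":
        self._thread.start()
        return self

    def _process_batch(self, batch: FileBatch) -> None:
        self.last_activity = time.monotonic()
        if self._handler is not None:
            arrival = datetime.now()
            try:
                self._handler(batch)
                status = "ok"
            except Exception:
                logger.exception("batch handler failed")
                status = "failed"
            finish = datetime.now()
            for p in batch.paths:
                self.log.append(
                    ExecutionRecord(p, arrival, finish, (finish - arrival).total_seconds(), status)
                )
        else:
            assert self._item_handler is not None
            for p in batch.paths:
                arrival = datetime.now()
                try:
                    self._item_handler(p)
                    status = "ok"
                except Exception:
                    logger.exception("item handler failed for %s", p)
                    status = "failed"
                finish = datetime.now()
                self.log.append(
                    ExecutionRecord(p, arrival, finish, (finish - arrival).total_seconds(), status)
                )
        self.delivered.extend(batch.paths)
        self.last_activity = time.monotonic()

    def _loop(self) -> None:
        while not self._stop.is_set():
            try:
                batch = scan_folder(self.state, self.config)
            except FileNotFoundError:
                logger.error("watched folder vanished: %s", self.config.folder)
                break
            if batch.paths:
                self._busy.set()
                try:
                    self._process_batch(batch)
                finally:
                    self._busy.clear()
            self._stop.wait(self.config.poll_interval_s)

    @property
    def idle(self) -> bool:
        """True when no batch is being processed and nothing is pending."""
        return not self._busy.is_set() and not self.state.pending_snapshot

    def stop(self) -> None:
        self._stop.set()

    def join(self, timeout: float | None = None) -> None:
        self._thread.join(timeout)

    def stop_and_join(self, timeout: float | None = None) -> None:
        self.stop()
        self.join(timeout)


def run_watcher(
    config: WatchConfig,
    handler: Callable[[FileBatch], None] | None = None,
    item_handler: Callable[[Path], None] | None = None,
    role: str = "orchestrator",
) -> WatchSession:
    """Start a watch session; returns the running :class:`WatchSession`."""
    return WatchSession(config, handler=handler, item_handler=item_handler, role=role).start()


# ---------------------------------------------------------------------------
# logger file I/O
# ---------------------------------------------------------------------------


def _fmt_ts(ts: datetime) -> str:
    return ts.strftime(_TS_FMT)[:-3]  # millisecond precision


def _parse_ts(text: str) -> datetime:
    return datetime.strptime(text, _TS_FMT)


def write_log(log: ExperimentLog, folder: Path) -> Path:
    """Write the session logger file; returns its path.

    One file per session, ``<role>_<host>_<start timestamp>.log``; an
    existing name is never overwritten (a numeric suffix is appended).
    """
    folder = Path(folder)
    stamp = log.started_at.strftime("%Y%m%dT%H%M%S.%f")
    base = f"{log.unit_role}_{log.host_name}_{stamp}"
    path = folder / f"{base}.log"
    k = 1
    while path.exists():
        path = folder / f"{base}_{k}.log"
        k += 1
    lines = [
        f"host: {log.host_name}",
        f"role: {log.unit_role}",
        f"started: {_fmt_ts(log.started_at)}",
    ]
    for rec in sorted(log.records, key=lambda r: r.arrival_time):
        lines.append(
            "\t".join(
                [
                    str(rec.item_path),
                    _fmt_ts(rec.arrival_time),
                    _fmt_ts(rec.finish_time),
                    f"{rec.latency_s:.3f}",
                    rec.status,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def parse_log(path: Path) -> ExperimentLog:
    """Parse a logger file written by :func:`write_log`.

    Round-trips ``write_log`` field-for-field (timestamps at millisecond
    precision).  A record whose latency field disagrees with its
    timestamps by more than ~1 ms raises :class:`LogParseError` naming the
    offending line.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise LogParseError(f"{path}: truncated header")
    header: dict[str, str] = {}
    for i, key in enumerate(("host", "role", "started")):
        prefix = f"{key}: "
        if not lines[i].startswith(prefix):
            raise LogParseError(f"{path}:{i + 1}: expected '{key}:' header line")
        header[key] = lines[i][len(prefix):]
    try:
        started = _parse_ts(header["started"])
    except ValueError as exc:
        raise LogParseError(f"{path}:3: bad timestamp: {exc}") from exc
    log = ExperimentLog(host_name=header["host"], started_at=started, unit_role=header["role"])
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise LogParseError(f"{path}:{lineno}: expected 5 tab-separated fields")
        item, arr_s, fin_s, lat_s, status = parts
        try:
            arrival = _parse_ts(arr_s)
            finish = _parse_ts(fin_s)
            latency = float(lat_s)
        except ValueError as exc:
            raise LogParseError(f"{path}:{lineno}: {exc}") from exc
        if status not in ("ok", "failed"):
            raise LogParseError(f"{path}:{lineno}: bad status {status!r}")
        if abs(latency - (finish - arrival).total_seconds()) > 0.0015:
            raise LogParseError(
                f"{path}:{lineno}: latency {latency} inconsistent with timestamps"
            )
        log.append(ExecutionRecord(Path(item), arrival, finish, latency, status))
    return log


def latency_summary(log: ExperimentLog) -> dict[str, float | int | None]:
    """Summary statistics over the latencies of ``ok`` records.

    Returns ``{"n", "min_s", "max_s", "mean_s", "n_failed"}``; for an
    empty log the statistics are None with n == 0.
    """
    oks = [r.latency_s for r in log.records if r.status == "ok"]
    n_failed = sum(1 for r in log.records if r.status == "failed")
    if not oks:
        return {"n": 0, "min_s": None, "max_s": None, "mean_s": None, "n_failed": n_failed}
    return {
        "n": len(oks),
        "min_s": min(oks),
        "max_s": max(oks),
        "mean_s": sum(oks) / len(oks),
        "n_failed": n_failed,
    }
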
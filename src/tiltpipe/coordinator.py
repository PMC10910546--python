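"""Client–server coordination between the detector and the processing system.

The *transfer client* runs on the detector side: it polls the detector
tree for new files (a file is only picked up once its size has been stable
across two scans), copies each to the facility tree, verifies the copy by
checksum, and only then — optionally — removes the source. The *server*
keeps the registry that exists outside any single pipeline run: which
movies belong to which tilt series, which have been motion-corrected, and
whether each series has finished acquiring; it requests preprocessing at
the point of transfer and triggers reconstruction exactly once per
completed series.

The registry is an embedded SQLite database; triggering is made
single-shot by an atomic compare-and-set on the series row, so concurrent
completion checks (worker races, message redeliveries) cannot
double-dispatch. Series membership comes from the mdoc-like sidecar,
falling back to the ``<series>_<index>_<angle>.mrc`` filename convention;
movies with neither are quarantined without affecting their neighbours.
"""

from __future__ import annotations

import hashlib
import logging
import os
import re
import shutil
import sqlite3
import threading
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Optional

from . import mdoc
from .recipes import Dispatcher, ProcessingRequest, make_idempotency_key

logger = logging.getLogger(__name__)

__all__ = ["TransferItem", "TransferError", "TransferClient", "CoordinatorServer",
           "transfer", "client_scan", "file_checksum"]

_NAME_RE = re.compile(r"^(?P<series>.+)_(?P<index>\d+)_(?P<angle>[+-]?\d+(?:\.\d+)?)$")
_CHUNK = 64 * 1024


# ---------------------------------------------------------------------------
# transfer client
# ---------------------------------------------------------------------------

class TransferError(Exception):
    pass


@dataclass
class TransferItem:
    source: str
    destination: str
    size: int = 0
    checksum: str = ""
    state: str = "discovered"  # discovered | copying | verified | removed | failed
    attempts: int = 0


def file_checksum(path: str | os.PathLike) -> str:
    """MD5 of file contents (content identity check, not a security boundary)."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        while chunk := fh.read(_CHUNK):
            h.update(chunk)
    return h.hexdigest()


def client_scan(watch_root: str | Path, known: set[str],
                previous_sizes: dict[str, int]) -> tuple[list[str], dict[str, int]]:
    """One polling pass over the detector tree.

    Returns (ready paths, current size map). A file is ready when it is not
    yet known and its size matches the previous scan (write-completion
    heuristic); still-growing files wait for the next round. Metadata
    sidecars sort before movies so series membership is resolvable when the
    movie arrives.
    """
    root = Path(watch_root)
    if not root.is_dir():
        raise FileNotFoundError(f"watch root {root} does not exist")
    sizes: dict[str, int] = {}
    ready: list[str] = []
    for p in sorted(root.rglob("*")):
        if not p.is_file():
            continue
        sp = str(p)
        sizes[sp] = p.stat().st_size
        if sp in known:
            continue
        if previous_sizes.get(sp) == sizes[sp]:
            ready.append(sp)
    ready.sort(key=lambda s: (0 if s.endswith(".mdoc") else 1, s))
    return ready, sizes


def transfer(item: TransferItem, remove_source: bool = False,
             fault: Optional[Callable[[int], None]] = None) -> TransferItem:
    """Copy source to destination with checksum verification.

    The source is deleted only after the destination checksum matches
    (``remove_source``). Any interruption or mismatch leaves the source
    intact, removes the partial destination, and marks the item failed for
    retry. ``fault`` is a test hook called with the running byte count
    after each copied chunk; raising from it simulates an interrupted copy.
    """
    src, dst = Path(item.source), Path(item.destination)
    item.attempts += 1
    item.state = "copying"
    try:
        item.size = src.stat().st_size
        source_sum = hashlib.md5()
        dst.parent.mkdir(parents=True, exist_ok=True)
        copied = 0
        with open(src, "rb") as fin, open(dst, "wb") as fout:
            while chunk := fin.read(_CHUNK):
                fout.write(chunk)
                source_sum.update(chunk)
                copied += len(chunk)
                if fault is not None:
                    fault(copied)
        item.checksum = source_sum.hexdigest()
        if dst.stat().st_size != item.size or file_checksum(dst) != item.checksum:
            raise TransferError("checksum mismatch")
    except Exception as exc:  # interrupted copy, I/O error, mismatch
        item.state = "failed"
        dst.unlink(missing_ok=True)
        logger.warning("transfer of %s failed (%s); source retained", src, exc)
        return item
    item.state = "verified"
    if remove_source:
        src.unlink()
        item.state = "removed"
    return item


class TransferClient:
    """Detector-side agent: scan, transfer, notify the coordination server."""

    def __init__(self, watch_root: str | Path, dest_root: str | Path,
                 server: "CoordinatorServer", remove_source: bool = False,
                 max_attempts: int = 5) -> None:
        self.watch_root = Path(watch_root)
        self.dest_root = Path(dest_root)
        self.server = server
        self.remove_source = remove_source
        self.max_attempts = max_attempts
        self.known: set[str] = set()
        self.previous_sizes: dict[str, int] = {}
        self.items: list[TransferItem] = []
        self._sidecar_positions: dict[str, int] = {}  # bytes of sidecar processed
        self._series_acquired_sent: set[str] = set()

    def _destination(self, source: str) -> str:
        rel = Path(source).relative_to(self.watch_root)
        return str(self.dest_root / rel)

    def poll(self, fault: Optional[Callable[[int], None]] = None) -> list[TransferItem]:
        """One scan-transfer-notify cycle; returns the items acted on.

        Metadata sidecars grow in place while a series is being acquired,
        so they bypass the size-stability gate: every poll mirrors them to
        the facility tree *before* any movie is registered, keeping series
        membership and completion information ahead of the data.
        """
        for sc in sorted(self.watch_root.rglob("*.mdoc")):
            self._process_sidecar(self._destination(str(sc)), refresh_from=str(sc))
        ready, self.previous_sizes = client_scan(self.watch_root, self.known,
                                                self.previous_sizes)
        acted: list[TransferItem] = []
        for src in ready:
            if src.endswith(".mdoc"):
                self.known.add(src)
                continue
            item = TransferItem(source=src, destination=self._destination(src))
            transfer(item, remove_source=False, fault=fault)
            while item.state == "failed" and item.attempts < self.max_attempts:
                transfer(item, remove_source=False)  # fault hooks are one-shot
            if item.state != "verified":
                acted.append(item)
                continue
            self.known.add(src)
            self.items.append(item)
            acted.append(item)
            if src.endswith(".mrc"):
                self.server.register_movie(item.destination,
                                           self._sidecar_for(item.destination))
            if self.remove_source and src.endswith(".mrc"):
                Path(src).unlink()
                item.state = "removed"
        return acted

    def _sidecar_for(self, movie_path: str) -> Optional[dict]:
        for sc in Path(movie_path).parent.glob("*.mdoc"):
            parsed = mdoc.parse_mdoc(sc)
            tilt = mdoc.tilt_for_movie(parsed, movie_path)
            if tilt is not None:
                return {"global": parsed["global"], "tilt": tilt,
                        "series_id": parsed["global"].get("SeriesID", sc.stem)}
        return None

    def _process_sidecar(self, dest_path: str, refresh_from: str | None = None) -> None:
        if refresh_from is not None:
            # mirror appended lines from the detector copy
            Path(dest_path).parent.mkdir(parents=True, exist_ok=True)
            shutil.copyfile(refresh_from, dest_path)
        if not Path(dest_path).exists():
            return
        parsed = mdoc.parse_mdoc(dest_path)
        sid = parsed["global"].get("SeriesID", Path(dest_path).stem)
        if parsed["expected_tilts"] is not None and sid not in self._series_acquired_sent:
            self.server.mark_series_acquired(sid, parsed["expected_tilts"])
            self._series_acquired_sent.add(sid)


# ---------------------------------------------------------------------------
# coordination server
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE IF NOT EXISTS movies (
    movie_id TEXT PRIMARY KEY,
    path TEXT NOT NULL,
    series_id TEXT,
    tilt_angle REAL,
    transferred INTEGER NOT NULL DEFAULT 1,
    motion_corrected INTEGER NOT NULL DEFAULT 0,
    preprocess_dispatched INTEGER NOT NULL DEFAULT 0,
    quarantined INTEGER NOT NULL DEFAULT 0,
    micrograph_path TEXT
);
CREATE TABLE IF NOT EXISTS series (
    series_id TEXT PRIMARY KEY,
    expected_tilts INTEGER,
    acquisition_complete INTEGER NOT NULL DEFAULT 0,
    reconstruction_triggered INTEGER NOT NULL DEFAULT 0
);
"""


class CoordinatorServer:
    """Registry of movies and tilt series; triggers processing requests.

    Preprocessing is requested exactly once per movie at registration;
    reconstruction exactly once per series, when the series is fully
    acquired and every member movie is motion-corrected. Both are
    idempotent under redelivery and event reordering.
    """

    def __init__(self, db_path: str = ":memory:", dispatcher: Dispatcher | None = None,
                 session: str = "session", request_queue: str | None = None,
                 broker=None) -> None:
        self.db = sqlite3.connect(db_path, check_same_thread=False)
        self.db.executescript(_SCHEMA)
        self.dispatcher = dispatcher
        self.broker = broker
        self.request_queue = request_queue
        self.session = session
        self._lock = threading.Lock()
        self.alerts: list[dict] = []
        self.dispatched: list[dict] = []  # log of processing requests issued

    # -- dispatch plumbing --------------------------------------------------

    def _request(self, recipe: str, parameters: dict, input_key: str) -> None:
        """Issue a processing request, via the request queue when wired."""
        entry = {"preprocess": "motioncorr", "reconstruct": "tomo_align_recon"}.get(
            recipe, recipe)
        key = make_idempotency_key(self.session, recipe, entry, input_key)
        req = {"recipe": recipe, "parameters": parameters, "session": self.session,
               "idempotency_key": key}
        self.dispatched.append(req)
        if self.broker is not None and self.request_queue is not None:
            self.broker.publish(self.request_queue, {
                "recipe": "request", "vertex": "dispatch", "parameters": req,
                "session": self.session, "idempotency_key": f"request:{key}"})
        elif self.dispatcher is not None:
            self.dispatcher.dispatch(ProcessingRequest(
                recipe=recipe, parameters=parameters, session=self.session,
                idempotency_key=key))

    # -- registration -------------------------------------------------------

    def register_movie(self, path: str, sidecar: Optional[dict] = None) -> dict:
        """Register a verified-transferred movie; dispatch preprocess once.

        Series membership comes from the sidecar when available, else from
        the filename convention. Unresolvable movies are quarantined (with
        an alert) without affecting other movies or series.
        """
        movie_id = Path(path).stem
        series_id: Optional[str] = None
        tilt_angle: Optional[float] = None
        if sidecar is not None:
            series_id = sidecar.get("series_id")
            tilt = sidecar.get("tilt", {})
            if "TiltAngle" in tilt:
                tilt_angle = float(tilt["TiltAngle"])
        if series_id is None or tilt_angle is None:
            m = _NAME_RE.match(movie_id)
            if m:
                series_id = series_id or m.group("series")
                tilt_angle = tilt_angle if tilt_angle is not None else float(m.group("angle"))
        with self._lock:
            if series_id is None or tilt_angle is None:
                self.db.execute(
                    "INSERT OR IGNORE INTO movies (movie_id, path, quarantined) "
                    "VALUES (?, ?, 1)", (movie_id, path))
                self.db.commit()
                self.alerts.append({"kind": "unresolved_series", "movie_id": movie_id})
                logger.warning("movie %s quarantined: series membership unresolved", movie_id)
                return self.movie_record(movie_id)
            self.db.execute(
                "INSERT OR IGNORE INTO movies (movie_id, path, series_id, tilt_angle) "
                "VALUES (?, ?, ?, ?)", (movie_id, path, series_id, tilt_angle))
            self.db.execute(
                "INSERT OR IGNORE INTO series (series_id) VALUES (?)", (series_id,))
            cur = self.db.execute(
                "UPDATE movies SET preprocess_dispatched = 1 "
                "WHERE movie_id = ? AND preprocess_dispatched = 0", (movie_id,))
            self.db.commit()
            first_dispatch = cur.rowcount == 1
        if first_dispatch:
            self._request("preprocess", {
                "movie_id": movie_id, "movie_path": path,
                "series_id": series_id, "tilt_angle": tilt_angle}, movie_id)
        return self.movie_record(movie_id)

    def mark_motion_corrected(self, movie_id: str, metrics: dict | None = None,
                              micrograph_path: str | None = None) -> None:
        """Record a movie's motion correction, then re-check series readiness."""
        with self._lock:
            row = self.db.execute("SELECT series_id FROM movies WHERE movie_id = ?",
                                  (movie_id,)).fetchone()
            if row is None:
                logger.warning("motion-corrected mark for unknown movie %s ignored", movie_id)
                return
            self.db.execute(
                "UPDATE movies SET motion_corrected = 1, micrograph_path = "
                "COALESCE(?, micrograph_path) WHERE movie_id = ?",
                (micrograph_path, movie_id))
            self.db.commit()
        if row[0]:
            self.series_ready(row[0])

    def mark_series_acquired(self, series_id: str, expected_tilts: int) -> None:
        """Record the acquisition-complete event; may precede registrations."""
        with self._lock:
            self.db.execute("INSERT OR IGNORE INTO series (series_id) VALUES (?)",
                            (series_id,))
            observed = self.db.execute(
                "SELECT COUNT(*) FROM movies WHERE series_id = ?", (series_id,)
            ).fetchone()[0]
            if observed > expected_tilts:
                self.alerts.append({"kind": "expected_tilts_conflict",
                                    "series_id": series_id,
                                    "declared": expected_tilts, "observed": observed})
                expected_tilts = observed
            self.db.execute(
                "UPDATE series SET acquisition_complete = 1, expected_tilts = ? "
                "WHERE series_id = ?", (expected_tilts, series_id))
            self.db.commit()
        self.series_ready(series_id)

    # -- completion detection ----------------------------------------------

    def series_ready(self, series_id: str) -> bool:
        """True iff fully acquired and every member motion-corrected.

        When ready and not yet triggered, dispatch reconstruction — the
        trigger flag is flipped by an atomic compare-and-set inside the
        same lock, so N concurrent checks dispatch exactly once.
        """
        with self._lock:
            row = self.db.execute(
                "SELECT expected_tilts, acquisition_complete, reconstruction_triggered "
                "FROM series WHERE series_id = ?", (series_id,)).fetchone()
            if row is None:
                return False
            expected, complete, triggered = row
            if not complete or expected is None:
                return False
            members = self.db.execute(
                "SELECT movie_id, tilt_angle, micrograph_path, motion_corrected "
                "FROM movies WHERE series_id = ? AND quarantined = 0 "
                "ORDER BY tilt_angle", (series_id,)).fetchall()
            ready = (len(members) == expected
                     and all(m[3] for m in members) and expected > 0)
            if not ready:
                return False
            if triggered:
                return True
            cur = self.db.execute(
                "UPDATE series SET reconstruction_triggered = 1 "
                "WHERE series_id = ? AND reconstruction_triggered = 0", (series_id,))
            self.db.commit()
            claimed = cur.rowcount == 1
            tilts = [{"movie_id": m[0], "tilt_angle": m[1], "micrograph_path": m[2]}
                     for m in members]
        if claimed:
            self._request("reconstruct", {"series_id": series_id, "tilts": tilts},
                          series_id)
        return True

    # -- queries ------------------------------------------------------------

    def movie_record(self, movie_id: str) -> dict:
        row = self.db.execute(
            "SELECT movie_id, path, series_id, tilt_angle, transferred, "
            "motion_corrected, preprocess_dispatched, quarantined "
            "FROM movies WHERE movie_id = ?", (movie_id,)).fetchone()
        if row is None:
            raise KeyError(movie_id)
        keys = ["movie_id", "path", "series_id", "tilt_angle", "transferred",
                "motion_corrected", "preprocess_dispatched", "quarantined"]
        return dict(zip(keys, row))

    def series_record(self, series_id: str) -> dict:
        row = self.db.execute(
            "SELECT series_id, expected_tilts, acquisition_complete, "
            "reconstruction_triggered FROM series WHERE series_id = ?",
            (series_id,)).fetchone()
        if row is None:
            raise KeyError(series_id)
        keys = ["series_id", "expected_tilts", "acquisition_complete",
                "reconstruction_triggered"]
        rec = dict(zip(keys, row))
        rec["movie_ids"] = sorted(r[0] for r in self.db.execute(
            "SELECT movie_id FROM movies WHERE series_id = ?", (series_id,)))
        return rec

    def registry_state(self) -> dict:
        """Canonical snapshot of the whole registry, for state comparisons."""
        movies = [dict(zip(["movie_id", "series_id", "tilt_angle", "motion_corrected",
                            "preprocess_dispatched", "quarantined"], r))
                  for r in self.db.execute(
                      "SELECT movie_id, series_id, tilt_angle, motion_corrected, "
                      "preprocess_dispatched, quarantined FROM movies ORDER BY movie_id")]
        series = [dict(zip(["series_id", "expected_tilts", "acquisition_complete",
                            "reconstruction_triggered"], r))
                  for r in self.db.execute(
                      "SELECT series_id, expected_tilts, acquisition_complete, "
                      "reconstruction_triggered FROM series ORDER BY series_id")]
        return {"movies": movies, "series": series}
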
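"""LIMS-like outcome store and static session reports.

The outcome store is the desk-scale stand-in for the facility LIMS
connector: every successful processing completion is persisted as one
record, idempotently — a redelivered completion message maps onto the same
uniqueness key and does not duplicate the row. The report generator
replaces the live web frontend with static HTML pages (micrograph
thumbnails and power spectra in tilt order, tomogram central slice and
projections, denoised beside raw) plus a machine-readable JSON summary,
which is the surface the tests assert against.
"""

from __future__ import annotations

import html
import json
import shutil
import sqlite3
import threading
import time
from pathlib import Path
from typing import Any, Optional

__all__ = ["OutcomeStore", "generate_report", "RECORD_KINDS"]

RECORD_KINDS = ("motioncorr", "ctf", "tomogram", "denoised_tomogram", "images")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS outcomes (
    record_id INTEGER PRIMARY KEY AUTOINCREMENT,
    session TEXT NOT NULL,
    series_id TEXT NOT NULL DEFAULT '',
    movie_id TEXT NOT NULL DEFAULT '',  -- '' not NULL: NULLs break UNIQUE dedup
    kind TEXT NOT NULL,
    metrics TEXT NOT NULL DEFAULT '{}',
    artifact_paths TEXT NOT NULL DEFAULT '[]',
    idempotency_key TEXT NOT NULL DEFAULT '',
    created_at REAL NOT NULL,
    UNIQUE (session, kind, series_id, movie_id, idempotency_key)
);
"""


class OutcomeStore:
    """Embedded store of processing outcomes, unique per completion."""

    def __init__(self, db_path: str = ":memory:") -> None:
        self.db = sqlite3.connect(db_path, check_same_thread=False)
        self.db.executescript(_SCHEMA)
        self._lock = threading.Lock()

    def record_outcome(self, record: dict) -> int:
        """Insert-or-ignore on the uniqueness key; returns the record id.

        Raises ValueError for malformed records (missing/unknown kind), the
        dead-letter path of the connector service.
        """
        kind = record.get("kind")
        if kind not in RECORD_KINDS:
            raise ValueError(f"missing or unknown record kind: {kind!r}")
        if "session" not in record:
            raise ValueError("record missing session")
        movie_id = record.get("movie_id") or ""
        with self._lock:
            self.db.execute(
                "INSERT OR IGNORE INTO outcomes "
                "(session, series_id, movie_id, kind, metrics, artifact_paths, "
                " idempotency_key, created_at) VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                (record["session"], record.get("series_id", ""),
                 movie_id, kind,
                 json.dumps(record.get("metrics", {})),
                 json.dumps(record.get("artifact_paths", [])),
                 record.get("idempotency_key", ""), time.time()))
            self.db.commit()
            row = self.db.execute(
                "SELECT record_id FROM outcomes WHERE session = ? AND kind = ? "
                "AND series_id = ? AND movie_id = ? AND idempotency_key = ?",
                (record["session"], kind, record.get("series_id", ""),
                 movie_id, record.get("idempotency_key", ""))).fetchone()
            return int(row[0])

    def records(self, session: str, kind: Optional[str] = None,
                series_id: Optional[str] = None) -> list[dict]:
        q = ("SELECT record_id, session, series_id, movie_id, kind, metrics, "
             "artifact_paths, created_at FROM outcomes WHERE session = ?")
        args: list[Any] = [session]
        if kind is not None:
            q += " AND kind = ?"
            args.append(kind)
        if series_id is not None:
            q += " AND series_id = ?"
            args.append(series_id)
        q += " ORDER BY record_id"
        out = []
        for r in self.db.execute(q, args):
            out.append({"record_id": r[0], "session": r[1], "series_id": r[2],
                        "movie_id": r[3], "kind": r[4], "metrics": json.loads(r[5]),
                        "artifact_paths": json.loads(r[6]), "created_at": r[7]})
        return out

    def session_summary(self, session: str) -> dict:
        """Counts by kind plus per-series completeness; pure query."""
        counts = {k: 0 for k in RECORD_KINDS}
        for kind, n in self.db.execute(
                "SELECT kind, COUNT(*) FROM outcomes WHERE session = ? GROUP BY kind",
                (session,)):
            counts[kind] = n
        series: dict[str, dict] = {}
        for sid, kind, n in self.db.execute(
                "SELECT series_id, kind, COUNT(*) FROM outcomes WHERE session = ? "
                "AND series_id != '' GROUP BY series_id, kind", (session,)):
            series.setdefault(sid, {k: 0 for k in RECORD_KINDS})[kind] = n
        for sid, per in series.items():
            per["complete"] = bool(per["tomogram"] >= 1 and per["motioncorr"] >= 1
                                   and per["ctf"] >= 1)
        return {"session": session, "counts": counts, "series": series}


# ---------------------------------------------------------------------------
# static report
# ---------------------------------------------------------------------------

def _img_tile(out_dir: Path, path: str, label: str) -> str:
    src = Path(path)
    if src.exists():
        dst = out_dir / "assets" / src.name
        dst.parent.mkdir(parents=True, exist_ok=True)
        if src.resolve() != dst.resolve():
            shutil.copyfile(src, dst)
        return (f'<figure><img src="assets/{html.escape(src.name)}" alt="{html.escape(label)}">'
                f"<figcaption>{html.escape(label)}</figcaption></figure>")
    return (f'<figure class="missing"><div class="placeholder">missing</div>'
            f"<figcaption>{html.escape(label)} (missing artifact)</figcaption></figure>")


def generate_report(store: OutcomeStore, session: str, out_dir: str | Path) -> dict:
    """Write a static HTML report plus ``summary.json``; returns the summary.

    One page per tilt series: micrograph thumbnails and power spectra in
    tilt order, the tomogram central slice and projections, and the
    denoised slice beside the raw one when present. Missing artifact files
    become placeholder tiles with a warning; the report is still produced.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = store.session_summary(session)
    warnings: list[str] = []
    series_ids = sorted(summary["series"])
    pages = []
    for sid in series_ids:
        mc = sorted(store.records(session, "motioncorr", sid),
                    key=lambda r: r["metrics"].get("tilt_angle", 0.0))
        imgs = {r["movie_id"]: r for r in store.records(session, "images", sid)
                if r["movie_id"]}
        vol_imgs = [r for r in store.records(session, "images", sid) if not r["movie_id"]]
        tiles = []
        for rec in mc:
            img_rec = imgs.get(rec["movie_id"])
            paths = img_rec["artifact_paths"] if img_rec else []
            for p, label in zip(paths, (f"{rec['movie_id']} micrograph",
                                        f"{rec['movie_id']} power spectrum")):
                tiles.append(_img_tile(out, p, label))
                if not Path(p).exists():
                    warnings.append(f"missing artifact {p}")
        tomo_tiles = []
        for r in vol_imgs:
            for p in r["artifact_paths"]:
                label = Path(p).stem.replace("_", " ")
                tomo_tiles.append(_img_tile(out, p, label))
                if not Path(p).exists():
                    warnings.append(f"missing artifact {p}")
        page = out / f"{sid}.html"
        page.write_text(
            "<!doctype html><html><head><meta charset='utf-8'>"
            f"<title>{html.escape(sid)}</title></head><body>"
            f"<h1>Tilt series {html.escape(sid)}</h1>"
            f"<h2>Micrographs ({len(mc)} tilts)</h2><div class='tiles'>"
            + "".join(tiles) + "</div><h2>Tomogram</h2><div class='tiles'>"
            + ("".join(tomo_tiles) or "<p>no reconstruction yet</p>")
            + "</div></body></html>")
        pages.append(page.name)
    index = out / "index.html"
    links = "".join(f'<li><a href="{html.escape(p)}">{html.escape(p)}</a></li>'
                    for p in pages)
    index.write_text(
        "<!doctype html><html><head><meta charset='utf-8'>"
        f"<title>Session {html.escape(session)}</title></head><body>"
        f"<h1>Session {html.escape(session)}</h1><ul>{links or '<li>empty session</li>'}"
        "</ul></body></html>")
    summary["pages"] = pages
    summary["warnings"] = warnings
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
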
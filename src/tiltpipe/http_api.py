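"""JSON-over-HTTP binding for the coordination server.

The transfer client and the server normally share a process in this
package (the in-process binding); this module exposes the same three
operations over the wire for a genuinely detector-side client:

    POST /movies                          {"path": ..., "sidecar": {...}}
    POST /movies/<id>/motion_corrected    {"metrics": {...}, "micrograph_path": ...}
    POST /series/<id>/acquired            {"expected_tilts": n}
    GET  /series/<id>
    GET  /registry

Built on the standard library's threading HTTP server: the payloads are
small JSON bookkeeping messages, not data transfer.
"""

from __future__ import annotations

import json
import threading
import urllib.request
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Optional

from .coordinator import CoordinatorServer

__all__ = ["serve_coordinator", "HttpCoordinatorClient"]


def _make_handler(server: CoordinatorServer):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args: Any) -> None:  # quiet
            pass

        def _reply(self, code: int, body: dict) -> None:
            data = json.dumps(body).encode()
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def _body(self) -> dict:
            length = int(self.headers.get("Content-Length", 0))
            return json.loads(self.rfile.read(length) or b"{}")

        def do_POST(self) -> None:
            parts = self.path.strip("/").split("/")
            try:
                body = self._body()
                if parts == ["movies"]:
                    rec = server.register_movie(body["path"], body.get("sidecar"))
                    self._reply(201, rec)
                elif len(parts) == 3 and parts[0] == "movies" and parts[2] == "motion_corrected":
                    server.mark_motion_corrected(parts[1], body.get("metrics"),
                                                 body.get("micrograph_path"))
                    self._reply(200, {"ok": True})
                elif len(parts) == 3 and parts[0] == "series" and parts[2] == "acquired":
                    server.mark_series_acquired(parts[1], int(body["expected_tilts"]))
                    self._reply(200, {"ok": True})
                else:
                    self._reply(404, {"error": "unknown endpoint"})
            except Exception as exc:
                self._reply(400, {"error": str(exc)})

        def do_GET(self) -> None:
            parts = self.path.strip("/").split("/")
            try:
                if parts == ["registry"]:
                    self._reply(200, server.registry_state())
                elif len(parts) == 2 and parts[0] == "series":
                    self._reply(200, server.series_record(parts[1]))
                elif len(parts) == 2 and parts[0] == "movies":
                    self._reply(200, server.movie_record(parts[1]))
                else:
                    self._reply(404, {"error": "unknown endpoint"})
            except KeyError:
                self._reply(404, {"error": "not found"})
    return Handler


def serve_coordinator(server: CoordinatorServer, host: str = "127.0.0.1",
                      port: int = 0) -> tuple[ThreadingHTTPServer, threading.Thread]:
    """Start serving in a daemon thread; returns (http server, thread).

    Use ``httpd.server_address[1]`` for the bound port (port 0 picks one).
    Call ``httpd.shutdown()`` to stop.
    """
    httpd = ThreadingHTTPServer((host, port), _make_handler(server))
    thread = threading.Thread(target=httpd.serve_forever, daemon=True)
    thread.start()
    return httpd, thread


class HttpCoordinatorClient:
    """Client-side stub speaking the endpoints above."""

    def __init__(self, base_url: str) -> None:
        self.base_url = base_url.rstrip("/")

    def _call(self, method: str, path: str, body: Optional[dict] = None) -> dict:
        req = urllib.request.Request(
            self.base_url + path, method=method,
            data=json.dumps(body or {}).encode() if method == "POST" else None,
            headers={"Content-Type": "application/json"})
        with urllib.request.urlopen(req, timeout=10) as resp:
            return json.loads(resp.read() or b"{}")

    def register_movie(self, path: str, sidecar: Optional[dict] = None) -> dict:
        return self._call("POST", "/movies", {"path": path, "sidecar": sidecar})

    def mark_motion_corrected(self, movie_id: str, metrics: Optional[dict] = None,
                              micrograph_path: Optional[str] = None) -> dict:
        return self._call("POST", f"/movies/{movie_id}/motion_corrected",
                          {"metrics": metrics, "micrograph_path": micrograph_path})

    def mark_series_acquired(self, series_id: str, expected_tilts: int) -> dict:
        return self._call("POST", f"/series/{series_id}/acquired",
                          {"expected_tilts": expected_tilts})

    def series_record(self, series_id: str) -> dict:
        return self._call("GET", f"/series/{series_id}")

    def registry_state(self) -> dict:
        return self._call("GET", "/registry")
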
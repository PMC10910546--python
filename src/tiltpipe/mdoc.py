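"""Reader/writer for the per-series metadata sidecar (mdoc-like dialect).

One sidecar file per tilt series, key/value lines with one ``[ZValue = n]``
block per tilt, in the style acquisition software writes next to the
movies:

    SeriesID = Pos1
    PixelSpacing = 4.0

    [ZValue = 0]
    TiltAngle = -50.0
    SubFramePath = Pos1_000_-50.0.mrc

    ExpectedTilts = 11        # appended when the series finishes acquiring
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional

__all__ = ["write_header", "append_tilt", "append_series_end", "parse_mdoc"]


def _fmt(value: Any) -> str:
    return f"{value}"


def write_header(path: str | Path, series_id: str, **globals_: Any) -> None:
    with open(path, "w") as fh:
        fh.write(f"SeriesID = {series_id}\n")
        for k, v in globals_.items():
            fh.write(f"{k} = {_fmt(v)}\n")
        fh.write("\n")


def append_tilt(path: str | Path, z_value: int, tilt_angle: float,
                sub_frame_path: str, **extra: Any) -> None:
    with open(path, "a") as fh:
        fh.write(f"[ZValue = {z_value}]\n")
        fh.write(f"TiltAngle = {tilt_angle}\n")
        fh.write(f"SubFramePath = {sub_frame_path}\n")
        for k, v in extra.items():
            fh.write(f"{k} = {_fmt(v)}\n")
        fh.write("\n")


def append_series_end(path: str | Path, expected_tilts: int) -> None:
    """Completion marker: the acquisition's declared tilt count for the series."""
    with open(path, "a") as fh:
        fh.write(f"ExpectedTilts = {expected_tilts}\n")


def parse_mdoc(path: str | Path) -> dict:
    """Parse a sidecar into {"global": {...}, "tilts": [...], "expected_tilts": n|None}.

    Unknown keys are preserved verbatim (as strings) so the dialect can
    grow without breaking the parser; TiltAngle and ZValue are coerced to
    numbers.
    """
    out: dict = {"global": {}, "tilts": [], "expected_tilts": None}
    current: Optional[dict] = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[ZValue"):
            z = int(line.split("=", 1)[1].rstrip("]").strip())
            current = {"ZValue": z}
            out["tilts"].append(current)
            continue
        if "=" not in line:
            continue
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "ExpectedTilts":
            out["expected_tilts"] = int(value)
        elif current is not None:
            current[key] = float(value) if key == "TiltAngle" else value
        else:
            out["global"][key] = value
    return out


def tilt_for_movie(parsed: dict, movie_name: str) -> Optional[dict]:
    """Find the tilt block whose SubFramePath matches a movie filename."""
    for t in parsed["tilts"]:
        if Path(t.get("SubFramePath", "")).name == Path(movie_name).name:
            return t
    return None
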
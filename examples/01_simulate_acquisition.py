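"""Simulate a cryoET acquisition session onto a fake detector filesystem.

Builds a beam-shift schedule (several tilt series exposed per stage tilt,
so whole groups of series finish nearly simultaneously), replays it as MRC
movies plus mdoc-like sidecars, and prints what was written. The manifest
carries the ground truth (per-frame drift, defocus, phantom seeds) that
the processing stages are later scored against.
"""

import tempfile
from pathlib import Path

from tiltpipe.synthetic import build_schedule, replay

root = Path(tempfile.mkdtemp()) / "detector"
schedule = build_schedule("beam_shift", n_series=6, n_tilts=11, burst_size=3)
manifest = replay(schedule, root, seed=42, time_scale=0.0)

print(f"detector tree: {root}")
print(f"movies written: {len(manifest['movies'])}  "
      f"series: {len(manifest['series'])}  pattern: {manifest['pattern']}")
first = next(iter(manifest["movies"].values()))
print(f"example ground truth for one movie: series={first['series_id']} "
      f"angle={first['angle']:+.1f} deg drift/frame={first['drift_per_frame']} px")
# Expected output: 66 movies in 6 series; each movie records the exact
# cumulative drift the motion-correction stage must recover.
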
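"""Recover known per-frame drift from a synthetic movie.

Generates an 8-frame movie of a tilted sphere phantom with 1 px/frame
drift in x and -2 px/frame in y, runs motion correction, and compares the
estimated drift trace with the generation ground truth and with an
independent brute-force shift search.
"""

import numpy as np

from tiltpipe.stages import brute_force_shift, motion_correct
from tiltpipe.synthetic import make_phantom, project_movie

phantom = make_phantom(seed=7)
movie, truth = project_movie(phantom, angle_deg=-20.0, n_frames=8,
                             drift_per_frame=(1, -2), noise_sigma=1.0, seed=3)
mic, result = motion_correct(movie, max_shift=16)

err = np.abs(np.array(mic.drift_trace) - np.array(truth["shifts"], float)).max()
print("true cumulative shifts:", truth["shifts"])
print("estimated drift trace :", [(round(dx, 2), round(dy, 2))
                                  for dx, dy in mic.drift_trace])
print(f"max |error| = {err:.3f} px   total drift = {result.metrics['total_drift']:.1f} px")
print("brute-force oracle for frame 7:",
      brute_force_shift(movie.frames[0], movie.frames[7], 16))
# The estimates match the injected integer drift to a fraction of a pixel
# (exactly, in the noiseless case); the exhaustive search agrees.
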
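"""Fault isolation, operator reinjection, and burst autoscaling.

Part 1 poisons one movie (its stage always fails permanently): the other
series still produce tomograms, the poisoned message dead-letters, and an
operator reinjection after clearing the fault completes the session.

Part 2 replays a beam-shift acquisition (12 series in bursts of 6 finish
almost simultaneously): the reconstruction queue spikes, the autoscaler
raises reconstruction replicas to their maximum, and remote-pool
submitters spin up only while local GPU capacity is saturated.
"""

import tempfile
from pathlib import Path

from tiltpipe.pipeline import Pipeline
from tiltpipe.synthetic import build_schedule, replay

# -- part 1: poison + reinject ------------------------------------------------
root = Path(tempfile.mkdtemp())
replay(build_schedule("sequential", 3, 11), root / "detector", seed=11)
pipe = Pipeline(root / "work", session="faults")
pipe.attach_detector(root / "detector")
bad = "Pos1_005_+0.0"
pipe.fault_injector.schedule(
    "motioncorr", "fail_permanent",
    match=lambda p: p.get("parameters", {}).get("movie_id") == bad, times=None)
pipe.run_until_drained()
print("with poisoned movie:", pipe.summary()["counts"],
      "| dead-lettered:", pipe.broker.dead_count("motioncorr"))

pipe.fault_injector.clear("motioncorr")
pipe.broker.reinject_dead("motioncorr")
pipe.run_until_drained()
print("after reinjection:  ", pipe.summary()["counts"])

# -- part 2: beam-shift burst -------------------------------------------------
root2 = Path(tempfile.mkdtemp())
replay(build_schedule("beam_shift", 12, 11, burst_size=6), root2 / "detector", seed=4)
pipe2 = Pipeline(root2 / "work", session="burst")
pipe2.attach_detector(root2 / "detector")
pipe2.run_until_drained()
depths = [d.get("tomo_align_recon", 0) for d in pipe2.depth_history]
desired = [h["tomo_align_recon"]["desired"] for h in pipe2.replica_history]
print(f"reconstruction queue peak depth {max(depths)}, desired replicas "
      f"peak {max(desired)} (max 4), final {desired[-1]}")
print(f"remote spillover spin-ups: {len(pipe2.event_log.filter('spillover_up'))} "
      "(only while local GPU slots were saturated)")
# The burst drives the queue to >= 6; the autoscaler pins reconstruction
# at its maximum of 4 replicas until the backlog clears, then returns to 0.
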
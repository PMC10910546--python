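"""End-to-end pipeline orchestration on a simulated clock.

The :class:`Pipeline` wires the broker, dispatcher, coordination server,
outcome store and service workers into one deterministic scheduler. Each
tick advances simulated time by one second and, in order: polls the
transfer client, sweeps expired deliveries back onto their queues,
reconciles the autoscaler, adjusts worker slots (scale-up, idle-only
scale-down, GPU-capacity-limited local allocation and remote spillover),
and steps every worker once. Determinism makes the resilience and scaling
behaviour reproducible: a given fault schedule always produces the same
event log.

Replica accounting: a service's *desired* count is the autoscaler's
target; its local *running* slots grow toward desired but, for GPU-class
services, never beyond the remaining local GPU capacity (allocation in
service-catalogue order). Remote-pool submitters appear for a GPU service
only while the local GPU slots are saturated and its queue has depth, and
consume from the same queue.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .broker import InMemoryBroker
from .config import PipelineConfig, default_config
from .coordinator import CoordinatorServer, TransferClient
from .recipes import Dispatcher, IdempotencyStore, Router, builtin_recipes
from .results import OutcomeStore, generate_report
from .runtime import Autoscaler, EventLog, FaultInjector, Worker, spillover_count
from .stages.registry import StageContext

__all__ = ["SimClock", "Pipeline"]


class SimClock:
    """Monotonic simulated clock, advanced explicitly by the scheduler."""

    def __init__(self, start: float = 0.0) -> None:
        self.t = start

    def now(self) -> float:
        return self.t

    def advance(self, dt: float = 1.0) -> float:
        self.t += dt
        return self.t


class Pipeline:
    """A complete desk-scale deployment bound to one processing session."""

    def __init__(self, work_dir: str | Path, config: Optional[PipelineConfig] = None,
                 session: str = "session-1", db_dir: str | Path | None = None) -> None:
        self.config = config or default_config()
        self.work_dir = Path(work_dir)
        self.work_dir.mkdir(parents=True, exist_ok=True)
        self.session = session
        self.clock = SimClock()
        self.event_log = EventLog()
        self.broker = InMemoryBroker(self.config.queues,
                                     delivery_limit=self.config.broker.delivery_limit,
                                     clock=self.clock.now)
        self.recipes = builtin_recipes()
        self.idempotency = IdempotencyStore()
        self.dispatcher = Dispatcher(self.broker, self.config, self.recipes,
                                     self.idempotency)
        self.router = Router(self.broker, self.config, self.recipes, self.idempotency)
        db_dir = Path(db_dir) if db_dir is not None else self.work_dir
        self.store = OutcomeStore(str(db_dir / "outcomes.sqlite"))
        self.server = CoordinatorServer(
            db_path=str(db_dir / "registry.sqlite"),
            session=session, broker=self.broker,
            request_queue=self.config.service("dispatcher").queue)
        self.context = StageContext(
            work_dir=self.work_dir,
            optics=self.config.optics.model_dump(),
            ctf_search={"defocus_min_um": self.config.ctf_search.defocus_min_um,
                        "defocus_max_um": self.config.ctf_search.defocus_max_um,
                        "step_um": self.config.ctf_search.step_um},
            outcome_store=self.store, dispatcher=self.dispatcher)
        self.autoscaler = Autoscaler(self.config.scaling, self.config.services,
                                     self.event_log)
        self.fault_injector = FaultInjector()
        self.client: Optional[TransferClient] = None
        self.workers: dict[str, list[Worker]] = {s.name: [] for s in self.config.services}
        self.remote_workers: dict[str, list[Worker]] = {
            s.name: [] for s in self.config.services}
        self._worker_seq = 0
        #: per-tick {queue: depth} snapshots, for scaling assertions
        self.depth_history: list[dict[str, int]] = []
        self.replica_history: list[dict[str, dict[str, int]]] = []

    # -- wiring -------------------------------------------------------------

    def attach_detector(self, detector_root: str | Path,
                        facility_root: str | Path | None = None,
                        remove_source: bool = False) -> TransferClient:
        """Connect a transfer client watching a (synthetic) detector tree."""
        facility_root = Path(facility_root) if facility_root is not None \
            else self.work_dir / "facility"
        self.client = TransferClient(detector_root, facility_root, self.server,
                                     remove_source=remove_source)
        return self.client

    def _new_worker(self, spec, pool: str) -> Worker:
        self._worker_seq += 1
        callbacks = {}
        if spec.stage == "motioncorr":
            def on_motioncorr(payload, result, _server=self.server):
                params = payload.get("parameters", {})
                _server.mark_motion_corrected(
                    params.get("movie_id", ""), result.metrics,
                    micrograph_path=result.forward.get("micrograph_path"))
            callbacks["motioncorr"] = on_motioncorr
        return Worker(spec, self.broker, self.context, self.router, self.recipes,
                      self.event_log, ack_timeout=self.config.broker.ack_timeout,
                      fault_injector=self.fault_injector, callbacks=callbacks,
                      pool=pool, worker_id=f"{spec.name}/{pool}#{self._worker_seq}")

    # -- scheduling ---------------------------------------------------------

    def _adjust_workers(self) -> None:
        """Grow/shrink worker slots toward desired; idle-only scale-down."""
        gpu_specs = [s for s in self.config.services if s.resource_class == "gpu"]
        # drop dead workers (their messages are already unacked in the broker)
        for pools in (self.workers, self.remote_workers):
            for name, lst in pools.items():
                pools[name] = [w for w in lst if not w.dead]
        gpu_running = sum(len(self.workers[s.name]) for s in gpu_specs)
        for spec in self.config.services:
            state = self.autoscaler.states[spec.name]
            slots = self.workers[spec.name]
            # scale down: remove idle workers above the desired count
            while len(slots) > state.desired:
                idle = next((w for w in slots if not w.busy), None)
                if idle is None:
                    break  # all busy; never stop a worker mid-message
                slots.remove(idle)
                if spec.resource_class == "gpu":
                    gpu_running -= 1
            # scale up, bounded by local GPU capacity for gpu-class services
            while len(slots) < state.desired:
                if spec.resource_class == "gpu":
                    if gpu_running >= self.config.scaling.local_gpu_capacity:
                        break
                    gpu_running += 1
                slots.append(self._new_worker(spec, "local"))
            state.running = len(slots)
        # remote spillover: same queue, second pool, saturation-gated
        for spec in self.config.services:
            depth = self.broker.queue_depth(spec.queue)
            target = spillover_count(
                spec.model_copy(update={"executor_pool": "remote"}), depth,
                self.config.scaling, gpu_running)
            slots = self.remote_workers[spec.name]
            while len(slots) > target:
                idle = next((w for w in slots if not w.busy), None)
                if idle is None:
                    break
                slots.remove(idle)
            while len(slots) < target:
                slots.append(self._new_worker(spec, "remote"))
                # remote submitters only ever *spin up* under saturation;
                # busy ones may outlive it (never stopped mid-message)
                self.event_log.append("spillover_up", service=spec.name,
                                      gpu_running=gpu_running,
                                      capacity=self.config.scaling.local_gpu_capacity,
                                      depth=depth, time=self.clock.now())

    def step(self, dt: float = 1.0) -> None:
        """One scheduler tick."""
        now = self.clock.advance(dt)
        if self.client is not None:
            self.client.poll()
        self.broker.redeliver_expired()
        depths = {q: self.broker.queue_depth(q) for q in self.broker.queue_names}
        self.autoscaler.reconcile(depths, now)
        self._adjust_workers()
        for spec in self.config.services:
            for w in list(self.workers[spec.name]) + list(self.remote_workers[spec.name]):
                w.tick()
        self.depth_history.append(depths)
        self.replica_history.append({
            s.name: {"desired": self.autoscaler.states[s.name].desired,
                     "local": len(self.workers[s.name]),
                     "remote": len(self.remote_workers[s.name])}
            for s in self.config.services})

    def _quiescent(self) -> bool:
        if self.broker.total_depth() > 0:
            return False
        busy = any(w.busy for lst in self.workers.values() for w in lst) or \
            any(w.busy for lst in self.remote_workers.values() for w in lst)
        return not busy

    def run_until_drained(self, max_ticks: int = 2000, settle_ticks: int | None = None,
                          dt: float = 1.0) -> int:
        """Tick until all queues are empty and workers idle, then settle.

        The settle phase (default: one cooldown plus two ticks) lets the
        autoscaler return every service to its minimum. Returns the number
        of ticks executed; raises if the system fails to drain within
        ``max_ticks`` (a liveness failure).
        """
        if settle_ticks is None:
            settle_ticks = int(self.config.scaling.cooldown) + 2
        ticks = 0
        quiet = 0
        while ticks < max_ticks:
            self.step(dt)
            ticks += 1
            if self._quiescent():
                quiet += 1
                if quiet > max(2, settle_ticks):
                    return ticks
            else:
                quiet = 0
        raise RuntimeError(f"pipeline did not drain within {max_ticks} ticks")

    # -- results ------------------------------------------------------------

    def summary(self) -> dict:
        return self.store.session_summary(self.session)

    def report(self, out_dir: str | Path | None = None) -> dict:
        out_dir = Path(out_dir) if out_dir is not None else self.work_dir / "report"
        return generate_report(self.store, self.session, out_dir)

    def reconstruction_dispatches(self) -> list[dict]:
        return [d for d in self.server.dispatched if d["recipe"] == "reconstruct"]
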
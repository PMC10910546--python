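"""Service workers, replica management, queue-depth autoscaling and spillover.

A *worker* is one consumer of a service queue: it consumes a message, runs
the service's stage, and on success routes the result along the recipe's
edges and acknowledges; stage failures become message state (requeue for
transient, dead-letter for permanent). A worker that dies mid-message
simply never acks — the broker's redelivery sweep recovers the message for
another worker.

Replicas are concurrent workers inside one runtime, individually killable
— the same contract a container orchestrator provides, at desk scale. The
autoscaler derives each service's desired replica count from its queue
depth (``ceil(depth / messages_per_instance)``, clamped to the configured
bounds) with a cooldown between changes; scale-down only ever removes idle
workers. When every local GPU-class worker slot is occupied and a
GPU-class queue still has depth, *spillover* submitters for the remote
pool spin up, consuming from the same queue as the local workers.

Everything observable (publish/consume/ack/fail/scale events, per-tick
depths and replica counts) is appended to a structured event log — the
single source for monitoring and for test assertions.
"""

from __future__ import annotations

import json
import logging
import math
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

from .broker import InMemoryBroker, Message
from .config import PipelineConfig, ScalingPolicy, ServiceSpec
from .recipes import Router
from .stages.registry import StageContext, get_runner
from .stages.types import StageResult

logger = logging.getLogger(__name__)

__all__ = ["EventLog", "FaultInjector", "ReplicaState", "Worker",
           "desired_replicas", "Autoscaler", "spillover_count"]


class EventLog:
    """Append-only structured event log (JSON-serializable records)."""

    def __init__(self) -> None:
        self.events: list[dict] = []
        self._lock = threading.Lock()

    def append(self, kind: str, **fields: Any) -> None:
        with self._lock:
            self.events.append({"kind": kind, **fields})

    def filter(self, kind: str, **match: Any) -> list[dict]:
        return [e for e in self.events
                if e["kind"] == kind and all(e.get(k) == v for k, v in match.items())]

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")


class FaultInjector:
    """Scripted failure injection at worker kill points.

    Modes: ``die_before_ack`` (worker dies right after consuming — the
    message stays unacked until the broker sweep), ``die_after_work``
    (dies after routing but before acking — exercises downstream
    deduplication), ``fail_transient`` / ``fail_permanent`` (the stage
    reports a classified failure).
    """

    def __init__(self) -> None:
        self._rules: list[dict] = []
        self._lock = threading.Lock()

    def schedule(self, service: str, mode: str,
                 match: Optional[Callable[[dict], bool]] = None,
                 times: Optional[int] = 1) -> None:
        with self._lock:
            self._rules.append({"service": service, "mode": mode,
                                "match": match, "times": times})

    def clear(self, service: Optional[str] = None) -> None:
        with self._lock:
            self._rules = [r for r in self._rules
                           if service is not None and r["service"] != service]

    def check(self, service: str, payload: dict, point: str) -> Optional[str]:
        """Return the triggered mode for this (service, message), if any.

        ``point`` is "consume" (only die_before_ack fires there) or
        "complete" (all other modes).
        """
        with self._lock:
            for rule in self._rules:
                if rule["service"] != service:
                    continue
                at_consume = rule["mode"] == "die_before_ack"
                if (point == "consume") != at_consume:
                    continue
                if rule["match"] is not None and not rule["match"](payload):
                    continue
                if rule["times"] is not None:
                    if rule["times"] <= 0:
                        continue
                    rule["times"] -= 1
                return rule["mode"]
        return None


@dataclass
class ReplicaState:
    service: str
    running: int = 0
    desired: int = 0
    last_scale_time: float = -math.inf


def desired_replicas(depth: int, policy: ScalingPolicy, spec: ServiceSpec) -> int:
    """Queue-length-driven replica target, clamped to the service's bounds."""
    raw = math.ceil(depth / policy.messages_per_instance)
    return max(spec.min_instances, min(spec.max_instances, raw))


class Autoscaler:
    """Per-service desired-replica reconciliation with cooldown."""

    def __init__(self, policy: ScalingPolicy, services: list[ServiceSpec],
                 event_log: Optional[EventLog] = None) -> None:
        self.policy = policy
        self.specs = {s.name: s for s in services}
        self.states = {s.name: ReplicaState(service=s.name, desired=s.min_instances)
                       for s in services}
        self.event_log = event_log

    def reconcile(self, depths: dict[str, int], now: float) -> list[dict]:
        """Update desired counts where the cooldown allows; returns actions."""
        actions = []
        for name, spec in self.specs.items():
            state = self.states[name]
            target = desired_replicas(depths.get(spec.queue, 0), self.policy, spec)
            if target != state.desired and now - state.last_scale_time >= self.policy.cooldown:
                actions.append({"service": name, "from": state.desired, "to": target,
                                "time": now})
                if self.event_log is not None:
                    self.event_log.append("scale", service=name,
                                          from_=state.desired, to=target, time=now)
                state.desired = target
                state.last_scale_time = now
        return actions


def spillover_count(spec: ServiceSpec, depth: int, policy: ScalingPolicy,
                    local_gpu_running: int) -> int:
    """Remote submitters for a GPU-class service's queue.

    Nonzero only while every local GPU-class slot is in concurrent use
    *and* the queue still has depth — the saturation rule for pushing work
    to the remote pool. Remote submitters consume from the same queue as
    the local workers.
    """
    if spec.resource_class != "gpu" or spec.executor_pool != "remote":
        return 0
    if local_gpu_running < policy.local_gpu_capacity or depth <= 0:
        return 0
    return min(math.ceil(depth / policy.messages_per_instance), spec.max_instances)


class Worker:
    """One replica of a service: consume -> run stage -> route -> ack.

    Multi-tick stages model processing time on the simulated clock: a
    consumed message occupies the worker for ``spec.service_time`` ticks
    before completing. ``tick()`` is the deterministic scheduler entry
    point; ``run()`` wraps it in a thread loop for free-running use.
    """

    def __init__(self, spec: ServiceSpec, broker: InMemoryBroker, context: StageContext,
                 router: Optional[Router], recipes: dict, event_log: EventLog,
                 ack_timeout: float = 30.0, fault_injector: Optional[FaultInjector] = None,
                 callbacks: Optional[dict[str, Callable[[dict, StageResult], None]]] = None,
                 pool: str = "local", worker_id: str = "") -> None:
        self.spec = spec
        self.broker = broker
        self.context = context
        self.router = router
        self.recipes = recipes
        self.event_log = event_log
        self.ack_timeout = ack_timeout
        self.fault_injector = fault_injector
        self.callbacks = callbacks or {}
        self.pool = pool
        self.worker_id = worker_id or f"{spec.name}/{pool}"
        self.current: Optional[Message] = None
        self._remaining = 0
        self.dead = False  # set when a die_* fault killed this worker

    @property
    def busy(self) -> bool:
        return self.current is not None

    def tick(self) -> bool:
        """Advance one scheduler step; returns True if work was in progress.

        A sub-tick service (service_time 1 with messages_per_tick > 1)
        completes up to that many messages within the step; a multi-tick
        stage occupies the worker for service_time consecutive steps.
        """
        if self.spec.service_time == 1 and self.spec.messages_per_tick > 1:
            worked = False
            for _ in range(self.spec.messages_per_tick):
                if self.dead or not self._tick_one():
                    break
                worked = True
            return worked
        return self._tick_one()

    def _tick_one(self) -> bool:
        if self.dead:
            return False
        if self.current is None:
            msg = self.broker.consume(self.spec.queue, self.ack_timeout)
            if msg is None:
                return False
            self.event_log.append("consume", service=self.spec.name, pool=self.pool,
                                  worker=self.worker_id, message=msg.id,
                                  delivery=msg.delivery_count)
            if self.fault_injector is not None:
                mode = self.fault_injector.check(self.spec.name, msg.payload, "consume")
                if mode == "die_before_ack":
                    # the worker is gone; the message stays unacked until
                    # the broker's redelivery sweep reclaims it
                    self.dead = True
                    self.event_log.append("worker_died", service=self.spec.name,
                                          worker=self.worker_id, message=msg.id)
                    return True
            self.current = msg
            self._remaining = self.spec.service_time
        self._remaining -= 1
        if self._remaining > 0:
            return True
        msg, self.current = self.current, None
        self._complete(msg)
        return True

    def _complete(self, msg: Message) -> None:
        payload = msg.payload
        params = payload.get("parameters", {})
        mode = (self.fault_injector.check(self.spec.name, payload, "complete")
                if self.fault_injector else None)
        if mode == "fail_permanent":
            result = StageResult.failure(self.spec.stage, str(params.get("movie_id", "")),
                                         "injected_failure", error_class="permanent")
        elif mode == "fail_transient":
            result = StageResult.failure(self.spec.stage, str(params.get("movie_id", "")),
                                         "injected_failure", error_class="transient")
        else:
            try:
                result = get_runner(self.spec.stage)(params, self.context)
            except Exception as exc:  # defensive: a crash is a permanent failure
                logger.exception("stage %s crashed", self.spec.stage)
                result = StageResult.failure(self.spec.stage, "", f"crash:{exc}")
        if result.success:
            self._route_and_record(payload, result)
            if mode == "die_after_work":
                self.dead = True
                self.event_log.append("worker_died", service=self.spec.name,
                                      worker=self.worker_id, message=msg.id)
                return
            self.broker.ack(msg.id)
            self.event_log.append("ack", service=self.spec.name, worker=self.worker_id,
                                  message=msg.id, input_key=result.input_key)
        else:
            transient = result.metrics.get("error_class") == "transient"
            self.broker.nack(msg.id, requeue=transient)
            self.event_log.append("stage_failed", service=self.spec.name,
                                  message=msg.id, error=result.metrics.get("error"),
                                  error_class=result.metrics.get("error_class"),
                                  requeued=transient)

    def _route_and_record(self, payload: dict, result: StageResult) -> None:
        if self.router is None:
            return
        recipe = payload.get("recipe", "")
        vertex = payload.get("vertex", "")
        if recipe in self.recipes and vertex in self.recipes[recipe].vertices:
            routed = self.router.route_output(recipe, vertex, payload, result)
            if routed:
                self.event_log.append("routed", service=self.spec.name,
                                      vertex=vertex, downstream=routed)
            if self.spec.record_kind:
                self.router.publish_record(self.spec.record_kind, payload, result)
        cb = self.callbacks.get(self.spec.stage)
        if cb is not None:
            cb(payload, result)

    def run(self, stop: threading.Event, idle_sleep: float = 0.005) -> None:
        """Free-running thread loop (used outside the simulated scheduler)."""
        while not stop.is_set() and not self.dead:
            if not self.tick():
                time.sleep(idle_sleep)
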
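"""Worker loop semantics, autoscaling arithmetic, spillover gating."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiltpipe.broker import InMemoryBroker
from tiltpipe.config import ScalingPolicy, ServiceSpec, default_config
from tiltpipe.recipes import IdempotencyStore, Router, builtin_recipes
from tiltpipe.runtime import (Autoscaler, EventLog, FaultInjector, Worker,
                              desired_replicas, spillover_count)
from tiltpipe.stages.registry import STAGE_RUNNERS, StageContext
from tiltpipe.stages.types import StageResult
from tests.conftest import FakeClock


# ---------------------------------------------------------------------------
# scaling arithmetic
# ---------------------------------------------------------------------------

MOTIONCORR = ServiceSpec(name="motioncorr", queue="motioncorr", stage="motioncorr",
                         min_instances=0, max_instances=8, resource_class="gpu")


@pytest.mark.parametrize("depth, mpi, lo, hi, expected", [
    (0, 1, 0, 8, 0),
    (17, 2, 0, 8, 8),   # ceil(17/2)=9, clamped to the configured maximum
    (3, 2, 1, 4, 2),
    (1, 5, 1, 4, 1),
    (0, 1, 2, 4, 2),    # never below the minimum
])
def test_desired_replicas_clamped_ceiling(depth, mpi, lo, hi, expected):
    spec = ServiceSpec(name="s", queue="q", stage="x", min_instances=lo,
                       max_instances=hi)
    policy = ScalingPolicy(messages_per_instance=mpi)
    assert desired_replicas(depth, policy, spec) == expected


@settings(derandomize=True)
@given(depth=st.integers(0, 10_000), mpi=st.integers(1, 64),
       lo=st.integers(0, 4), span=st.integers(0, 12))
def test_desired_replicas_always_within_bounds(depth, mpi, lo, span):
    spec = ServiceSpec(name="s", queue="q", stage="x", min_instances=lo,
                       max_instances=lo + span)
    policy = ScalingPolicy(messages_per_instance=mpi)
    d = desired_replicas(depth, policy, spec)
    assert lo <= d <= lo + span
    assert d == max(lo, min(lo + span, math.ceil(depth / mpi)))


class TestAutoscalerCooldown:
    def test_desired_changes_only_after_cooldown(self):
        policy = ScalingPolicy(cooldown=5.0)
        scaler = Autoscaler(policy, [MOTIONCORR])
        scaler.reconcile({"motioncorr": 6}, now=0.0)
        assert scaler.states["motioncorr"].desired == 6
        scaler.reconcile({"motioncorr": 0}, now=3.0)  # within cooldown
        assert scaler.states["motioncorr"].desired == 6
        scaler.reconcile({"motioncorr": 0}, now=5.0)
        assert scaler.states["motioncorr"].desired == 0

    def test_all_queues_empty_converges_to_minimum(self):
        config = default_config()
        scaler = Autoscaler(config.scaling, config.services)
        scaler.reconcile({q: 0 for q in config.queues}, now=100.0)
        for s in config.services:
            assert scaler.states[s.name].desired == s.min_instances


class TestSpillover:
    GPU_REMOTE = ServiceSpec(name="recon", queue="recon", stage="tomo_align_recon",
                             min_instances=0, max_instances=4, resource_class="gpu",
                             executor_pool="remote")

    @pytest.mark.parametrize("running, capacity, depth, expect_positive", [
        (2, 2, 5, True),    # saturated + backlog -> remote submitters
        (1, 2, 5, False),   # not saturated
        (2, 2, 0, False),   # no backlog
    ])
    def test_saturation_rule(self, running, capacity, depth, expect_positive):
        policy = ScalingPolicy(local_gpu_capacity=capacity)
        n = spillover_count(self.GPU_REMOTE, depth, policy, running)
        assert (n > 0) == expect_positive
        assert n <= self.GPU_REMOTE.max_instances

    def test_cpu_services_never_spill(self):
        cpu = ServiceSpec(name="ctf", queue="q", stage="ctffind", max_instances=4,
                          resource_class="cpu", executor_pool="remote")
        assert spillover_count(cpu, 100, ScalingPolicy(local_gpu_capacity=0), 0) == 0


# ---------------------------------------------------------------------------
# worker loop
# ---------------------------------------------------------------------------

@pytest.fixture
def rig(tmp_path, monkeypatch):
    """Broker + router + one motioncorr worker with a stubbed stage."""
    config = default_config()
    clock = FakeClock()
    broker = InMemoryBroker(config.queues, delivery_limit=3, clock=clock)
    idem = IdempotencyStore()
    recipes = builtin_recipes()
    router = Router(broker, config, recipes, idem)
    log = EventLog()
    ctx = StageContext(work_dir=tmp_path, optics={}, ctf_search={})
    calls = []

    def stub_runner(params, context):
        calls.append(params)
        return StageResult(stage="motioncorr", input_key=params.get("movie_id", ""),
                           metrics={"total_drift": 1.0},
                           forward={"micrograph_path": "/mc.mrc"})

    monkeypatch.setitem(STAGE_RUNNERS, "motioncorr", stub_runner)

    def make_worker(**kw):
        return Worker(config.service("motioncorr"), broker, ctx, router, recipes, log,
                      ack_timeout=10.0, **kw)

    def publish(movie_id="m1"):
        return broker.publish("motioncorr", {
            "recipe": "preprocess", "vertex": "motioncorr",
            "parameters": {"movie_id": movie_id, "movie_path": f"/{movie_id}.mrc"},
            "session": "s", "idempotency_key": f"s:preprocess:motioncorr:{movie_id}"})

    return dict(broker=broker, clock=clock, log=log, make_worker=make_worker,
                publish=publish, calls=calls)


class TestWorkerLoop:
    def test_healthy_path_acks_routes_and_records(self, rig):
        rig["publish"]()
        worker = rig["make_worker"]()
        assert worker.tick()
        assert rig["broker"].queue_depth("motioncorr") == 0
        assert rig["broker"].queue_depth("ctffind") == 1   # routed downstream
        assert rig["broker"].queue_depth("images") == 1
        assert rig["broker"].queue_depth("ispyb") == 1     # outcome record request
        assert rig["log"].filter("ack")

    def test_callback_invoked_on_success(self, rig):
        rig["publish"]()
        seen = []
        worker = rig["make_worker"](callbacks={
            "motioncorr": lambda payload, result: seen.append(
                payload["parameters"]["movie_id"])})
        worker.tick()
        assert seen == ["m1"]

    def test_transient_failure_requeues_for_retry(self, rig):
        rig["publish"]()
        injector = FaultInjector()
        injector.schedule("motioncorr", "fail_transient", times=1)
        worker = rig["make_worker"](fault_injector=injector)
        worker.tick()
        assert rig["broker"].queue_depth("motioncorr") == 1  # back on the queue
        worker.tick()  # retry succeeds
        assert rig["broker"].queue_depth("motioncorr") == 0
        assert rig["broker"].queue_depth("ctffind") == 1

    def test_poison_message_dead_letters_within_delivery_limit(self, rig):
        rig["publish"]("poison")
        rig["publish"]("healthy")
        injector = FaultInjector()
        injector.schedule("motioncorr", "fail_transient",
                          match=lambda p: p["parameters"]["movie_id"] == "poison",
                          times=None)
        worker = rig["make_worker"](fault_injector=injector)
        for _ in range(6):
            worker.tick()
        assert rig["broker"].dead_count("motioncorr") == 1
        deliveries = [e["delivery"] for e in rig["log"].filter("consume")]
        assert max(deliveries) <= 3
        # the healthy message was unaffected
        assert any(e["input_key"] == "healthy" for e in rig["log"].filter("ack"))

    def test_permanent_failure_dead_letters_immediately(self, rig):
        rig["publish"]()
        injector = FaultInjector()
        injector.schedule("motioncorr", "fail_permanent", times=1)
        worker = rig["make_worker"](fault_injector=injector)
        worker.tick()
        assert rig["broker"].dead_count("motioncorr") == 1

    def test_worker_death_recovered_by_redelivery_sweep(self, rig):
        rig["publish"]()
        injector = FaultInjector()
        injector.schedule("motioncorr", "die_before_ack", times=1)
        victim = rig["make_worker"](fault_injector=injector)
        victim.tick()
        assert victim.dead
        assert rig["broker"].queue_depth("motioncorr") == 1  # held unacked
        rig["clock"].advance(11)
        assert rig["broker"].redeliver_expired() == 1
        survivor = rig["make_worker"]()
        survivor.tick()
        assert rig["broker"].queue_depth("motioncorr") == 0
        acks = rig["log"].filter("ack")
        assert len(acks) == 1  # processed exactly once overall

    def test_death_after_routing_does_not_duplicate_downstream(self, rig):
        rig["publish"]()
        injector = FaultInjector()
        injector.schedule("motioncorr", "die_after_work", times=1)
        victim = rig["make_worker"](fault_injector=injector)
        victim.tick()
        rig["clock"].advance(11)
        rig["broker"].redeliver_expired()
        survivor = rig["make_worker"]()
        survivor.tick()
        # downstream publication deduplicated on the idempotency key
        assert rig["broker"].queue_depth("ctffind") == 1
        assert rig["broker"].queue_depth("images") == 1

    def test_multi_tick_stage_occupies_worker(self, rig):
        spec = MOTIONCORR.model_copy(update={"service_time": 3})
        rig["publish"]()
        broker = rig["broker"]
        worker = Worker(spec, broker, StageContext(work_dir=".", optics={},
                                                   ctf_search={}),
                        None, {}, rig["log"], ack_timeout=10.0)
        worker.tick()
        assert worker.busy
        worker.tick()
        assert worker.busy
        worker.tick()
        assert not worker.busy

    def test_sub_tick_service_absorbs_multiple_messages(self, rig):
        for i in range(5):
            rig["publish"](f"m{i}")
        spec = default_config().service("motioncorr").model_copy(
            update={"messages_per_tick": 4})
        worker = Worker(spec, rig["broker"], StageContext(work_dir=".", optics={},
                                                          ctf_search={}),
                        None, {}, rig["log"], ack_timeout=10.0)
        worker.tick()
        assert rig["broker"].queue_depth("motioncorr") == 1
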
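"""In-memory message broker with acknowledgement, timeout requeue and dead-lettering.

This is the reference implementation of the queue contract the pipeline is
built on: services communicate only through named FIFO queues; a consumed
message is held un-acknowledged by exactly one consumer until it is acked,
nacked, or its acknowledgement deadline expires and a redelivery sweep
returns it to the queue.  Messages whose delivery count has reached the
configured limit are parked on a per-queue dead-letter collection from
which an operator can reinject them.

The broker is process-local and thread-safe; payloads are round-tripped
through JSON at publish time so that a networked backend implementing the
same contract could be swapped in without changing producers or consumers.
"""

from __future__ import annotations

import itertools
import json
import logging
import threading
import time
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable

logger = logging.getLogger(__name__)

__all__ = ["Message", "InMemoryBroker", "UnknownQueueError"]


class UnknownQueueError(KeyError):
    """Raised when a queue name is not declared in the broker configuration."""


@dataclass
class Message:
    """A routable unit of work.

    ``delivery_count`` counts consume events; it is 0 until first consumed.
    ``state`` is one of pending | unacked | acked | dead.
    """

    id: str
    queue: str
    payload: dict[str, Any]
    delivery_count: int = 0
    ack_deadline: float | None = None
    state: str = "pending"


@dataclass
class _QueueState:
    name: str
    pending: deque = field(default_factory=deque)
    unacked: dict[str, Message] = field(default_factory=dict)
    dead: deque = field(default_factory=deque)


class InMemoryBroker:
    """Reference broker backend.

    Parameters
    ----------
    queues:
        Names of the queues to declare. Publishing or observing an
        undeclared queue is a configuration error.
    delivery_limit:
        Maximum number of deliveries per message. A message that would be
        delivered again beyond the limit is dead-lettered instead of
        requeued. The limit bounds retries of poison messages so that one
        bad input cannot occupy a consumer forever.
    clock:
        Callable returning the current time in seconds; injectable so the
        pipeline can run on a simulated clock.
    """

    def __init__(
        self,
        queues: Iterable[str],
        delivery_limit: int = 3,
        clock: Callable[[], float] = time.monotonic,
    ) -> None:
        if delivery_limit < 1:
            raise ValueError("delivery_limit must be >= 1")
        self._queues: dict[str, _QueueState] = {}
        self._messages: dict[str, Message] = {}
        self.delivery_limit = delivery_limit
        self.clock = clock
        self._lock = threading.RLock()
        self._ids = itertools.count(1)
        self.counters = {"published": 0, "acked": 0, "dead": 0}
        for q in queues:
            self.declare_queue(q)

    # -- queue management ---------------------------------------------------

    def declare_queue(self, name: str) -> None:
        with self._lock:
            self._queues.setdefault(name, _QueueState(name))

    @property
    def queue_names(self) -> list[str]:
        return list(self._queues)

    def _queue(self, name: str) -> _QueueState:
        try:
            return self._queues[name]
        except KeyError:
            raise UnknownQueueError(f"queue {name!r} is not declared") from None

    # -- core operations ----------------------------------------------------

    def publish(self, queue: str, payload: dict[str, Any]) -> str:
        """Append a message to a queue; returns the message id.

        The payload must survive JSON serialization; the stored payload is
        the deserialized copy, which keeps the in-memory backend honest
        about what a wire backend could carry.
        """
        q = self._queue(queue)
        payload = json.loads(json.dumps(payload))
        with self._lock:
            msg = Message(id=f"m{next(self._ids)}", queue=queue, payload=payload)
            self._messages[msg.id] = msg
            q.pending.append(msg)
            self.counters["published"] += 1
        return msg.id

    def consume(self, queue: str, ack_timeout: float = 30.0) -> Message | None:
        """Move the oldest pending message to the unacked set and return it.

        Returns None on an empty queue (not an error). The returned object
        is the live message; consumers must not mutate the payload.
        """
        q = self._queue(queue)
        with self._lock:
            if not q.pending:
                return None
            msg = q.pending.popleft()
            msg.state = "unacked"
            msg.delivery_count += 1
            msg.ack_deadline = self.clock() + ack_timeout
            q.unacked[msg.id] = msg
            return msg

    def ack(self, message_id: str) -> None:
        """Acknowledge a delivered message; idempotent on unknown/acked ids."""
        with self._lock:
            msg = self._messages.get(message_id)
            if msg is None or msg.state != "unacked":
                logger.warning("ack of unknown or non-unacked message %s ignored", message_id)
                return
            q = self._queues[msg.queue]
            del q.unacked[message_id]
            msg.state = "acked"
            msg.ack_deadline = None
            self.counters["acked"] += 1

    def nack(self, message_id: str, requeue: bool = True) -> None:
        """Negatively acknowledge: requeue at the front, or dead-letter.

        A requeue that would exceed the delivery limit dead-letters instead,
        so a permanently failing message cannot cycle forever. Requeued
        messages go to the *front* of the queue so transient failures retry
        promptly.
        """
        with self._lock:
            msg = self._messages.get(message_id)
            if msg is None or msg.state != "unacked":
                logger.warning("nack of unknown or non-unacked message %s ignored", message_id)
                return
            q = self._queues[msg.queue]
            del q.unacked[message_id]
            msg.ack_deadline = None
            if requeue and msg.delivery_count < self.delivery_limit:
                msg.state = "pending"
                q.pending.appendleft(msg)
            else:
                msg.state = "dead"
                q.dead.append(msg)
                self.counters["dead"] += 1

    def redeliver_expired(self, now: float | None = None) -> int:
        """Return expired unacked messages to their queues; dead-letter at limit.

        This is the broker-side recovery path for consumers that died
        between consume and ack. Returns the number of messages moved
        (requeued or dead-lettered).
        """
        if now is None:
            now = self.clock()
        moved = 0
        with self._lock:
            for q in self._queues.values():
                expired = [m for m in q.unacked.values()
                           if m.ack_deadline is not None and m.ack_deadline < now]
                for msg in expired:
                    del q.unacked[msg.id]
                    msg.ack_deadline = None
                    if msg.delivery_count < self.delivery_limit:
                        msg.state = "pending"
                        q.pending.appendleft(msg)
                    else:
                        msg.state = "dead"
                        q.dead.append(msg)
                        self.counters["dead"] += 1
                    moved += 1
        return moved

    def reinject_dead(self, queue: str) -> int:
        """Operator action: return all dead messages of a queue to pending.

        Delivery counts are reset so the reinjected message gets a full
        retry budget. Never triggered automatically.
        """
        q = self._queue(queue)
        with self._lock:
            n = len(q.dead)
            while q.dead:
                msg = q.dead.popleft()
                msg.state = "pending"
                msg.delivery_count = 0
                self.counters["dead"] -= 1
                q.pending.append(msg)
            return n

    # -- observers ----------------------------------------------------------

    def queue_depth(self, queue: str) -> int:
        q = self._queue(queue)
        with self._lock:
            return len(q.pending) + len(q.unacked)

    def dead_count(self, queue: str) -> int:
        q = self._queue(queue)
        with self._lock:
            return len(q.dead)

    def dead_messages(self, queue: str) -> list[Message]:
        q = self._queue(queue)
        with self._lock:
            return list(q.dead)

    def total_depth(self) -> int:
        with self._lock:
            return sum(len(q.pending) + len(q.unacked) for q in self._queues.values())

    def get_message(self, message_id: str) -> Message | None:
        with self._lock:
            return self._messages.get(message_id)

    def conservation_ok(self) -> bool:
        """At a quiescent point: published == acked + dead + in-flight depth."""
        with self._lock:
            return self.counters["published"] == (
                self.counters["acked"] + self.counters["dead"] + self.total_depth()
            )
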
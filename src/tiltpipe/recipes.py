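"""Processing recipes: DAGs of service vertices, dispatch and output routing.

A recipe is a small directed acyclic graph over named services, one recipe
per data domain: ``preprocess`` acts on individual movies, ``reconstruct``
on complete tilt series. Recipes are data (YAML), not code, so the
pipeline can be extended without touching existing services. The
dispatcher turns a processing request into exactly one message on the
entry vertex's queue, idempotently, and the router fans a finished
vertex's result out along the recipe's edges.

The transition from the movie domain to the tilt-series domain is *not* an
edge in any recipe: a DAG edge cannot express "N inputs, when complete".
That aggregation belongs to the coordination server (see
:mod:`tiltpipe.coordinator`).
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import yaml

from .broker import InMemoryBroker
from .config import PipelineConfig

__all__ = [
    "Recipe",
    "ProcessingRequest",
    "IdempotencyStore",
    "Dispatcher",
    "Router",
    "load_recipe",
    "builtin_recipes",
    "validate_recipe",
    "make_idempotency_key",
]


@dataclass
class Recipe:
    name: str
    domain: str  # "movie" | "tilt_series"
    entry: str
    vertices: dict[str, dict]  # vertex -> {"service": str, "parameters": {...}}
    edges: dict[str, list[str]]  # vertex -> downstream vertices

    def service_of(self, vertex: str) -> str:
        return self.vertices[vertex]["service"]

    def parameters_of(self, vertex: str) -> dict:
        return dict(self.vertices[vertex].get("parameters") or {})

    def downstream(self, vertex: str) -> list[str]:
        return list(self.edges.get(vertex, []))


@dataclass
class ProcessingRequest:
    """A request to run one recipe on one primary input.

    The idempotency key is a deterministic function of the session, recipe
    and primary input identifier, so re-requests (redeliveries, client
    retries) collapse onto a single pipeline run.
    """

    recipe: str
    parameters: dict[str, Any]
    session: str
    idempotency_key: str


def make_idempotency_key(session: str, recipe: str, vertex: str, input_key: str) -> str:
    return f"{session}:{recipe}:{vertex}:{input_key}"


def load_recipe(source: str | Path | dict) -> Recipe:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    return Recipe(
        name=raw["name"],
        domain=raw.get("domain", "movie"),
        entry=raw["entry"],
        vertices={k: dict(v or {}) for k, v in raw.get("vertices", {}).items()},
        edges={k: list(v or []) for k, v in (raw.get("edges") or {}).items()},
    )


def builtin_recipes() -> dict[str, Recipe]:
    """The two shipped recipes: per-movie preprocess, per-series reconstruct."""
    out: dict[str, Recipe] = {}
    base = resources.files("tiltpipe").joinpath("data/recipes")
    for entry in base.iterdir():
        if entry.name.endswith(".yaml"):
            r = load_recipe(yaml.safe_load(entry.read_text()))
            out[r.name] = r
    return out


def validate_recipe(recipe: Recipe, known_services: set[str] | None = None) -> list[str]:
    """Return a list of structural violations; an empty list means valid.

    Checks: acyclicity, dangling edge endpoints, entry existence and
    in-degree zero, reachability of every vertex from the entry, and (when
    a service catalogue is given) that every vertex's service is declared.
    """
    violations: list[str] = []
    verts = set(recipe.vertices)
    if recipe.entry not in verts:
        violations.append(f"entry vertex {recipe.entry!r} is not defined")
    for src, dsts in recipe.edges.items():
        if src not in verts:
            violations.append(f"edge source {src!r} is not a vertex")
        for d in dsts:
            if d not in verts:
                violations.append(f"dangling edge {src!r} -> {d!r}")
            if d == recipe.entry:
                violations.append(f"entry vertex {recipe.entry!r} has incoming edge from {src!r}")
    # cycle detection on the well-formed part of the graph
    ts = TopologicalSorter(
        {v: [s for s, ds in recipe.edges.items() if v in ds and s in verts] for v in verts}
    )
    try:
        ts.prepare()
    except CycleError as exc:
        violations.append(f"cycle: {' -> '.join(map(str, exc.args[1]))}")
    if known_services is not None:
        for name, v in recipe.vertices.items():
            if v.get("service") not in known_services:
                violations.append(f"vertex {name!r} references unknown service {v.get('service')!r}")
    # reachability
    if recipe.entry in verts and not violations:
        seen = {recipe.entry}
        stack = [recipe.entry]
        while stack:
            for d in recipe.downstream(stack.pop()):
                if d not in seen:
                    seen.add(d)
                    stack.append(d)
        for v in verts - seen:
            violations.append(f"vertex {v!r} is unreachable from entry")
    return violations


class IdempotencyStore:
    """Thread-safe first-writer-wins key registry used to deduplicate work."""

    def __init__(self) -> None:
        self._seen: dict[str, Any] = {}
        self._lock = threading.Lock()

    def claim(self, key: str, value: Any = True) -> tuple[bool, Any]:
        """Claim a key. Returns (first_claim, stored_value)."""
        with self._lock:
            if key in self._seen:
                return False, self._seen[key]
            self._seen[key] = value
            return True, value

    def __contains__(self, key: str) -> bool:
        with self._lock:
            return key in self._seen


@dataclass
class Dispatcher:
    """Workflow-triggering service: request in, entry-vertex message out."""

    broker: InMemoryBroker
    config: PipelineConfig
    recipes: dict[str, Recipe]
    idempotency: IdempotencyStore
    rejected: list[dict] = field(default_factory=list)

    _REQUIRED: dict[str, list[str]] = field(default_factory=lambda: {
        "movie": ["movie_id", "movie_path"],
        "tilt_series": ["series_id", "tilts"],
    })

    def dispatch(self, request: ProcessingRequest) -> Optional[str]:
        """Publish the recipe's entry message; idempotent per request key.

        Returns the entry message id (the original id for a repeated key),
        or None when the request is rejected (unknown recipe or missing
        required parameters); rejections are recorded, not raised, so a bad
        request cannot take the dispatcher down.
        """
        recipe = self.recipes.get(request.recipe)
        if recipe is None:
            self.rejected.append({"reason": "unknown_recipe", "request": request.recipe})
            return None
        missing = [k for k in self._REQUIRED.get(recipe.domain, []) if k not in request.parameters]
        if missing:
            self.rejected.append({"reason": "missing_parameters", "missing": missing,
                                  "request": request.recipe})
            return None
        first, msg_id = self.idempotency.claim(request.idempotency_key, None)
        if not first:
            return msg_id
        payload = {
            "recipe": recipe.name,
            "vertex": recipe.entry,
            "parameters": {**recipe.parameters_of(recipe.entry), **request.parameters},
            "session": request.session,
            "idempotency_key": request.idempotency_key,
        }
        queue = self.config.service_queue(recipe.service_of(recipe.entry))
        msg_id = self.broker.publish(queue, payload)
        # store the real id for repeat claims
        self.idempotency._seen[request.idempotency_key] = msg_id
        return msg_id


class Router:
    """Fans a completed vertex's result out along recipe edges.

    Downstream payloads carry value copies of the result's forwarded
    fields, so a downstream retry is self-contained. Each downstream
    vertex execution is deduplicated on its idempotency key; a service
    with a configured ``record_kind`` additionally gets an outcome-record
    request published to the LIMS connector queue.
    """

    def __init__(self, broker: InMemoryBroker, config: PipelineConfig,
                 recipes: dict[str, Recipe], idempotency: IdempotencyStore,
                 results_queue: str = "ispyb") -> None:
        self.broker = broker
        self.config = config
        self.recipes = recipes
        self.idempotency = idempotency
        self.results_queue = results_queue

    def route_output(self, recipe_name: str, vertex: str, payload: dict,
                     result: "StageResult") -> list[str]:
        """Publish one message per outgoing edge; returns downstream ids."""
        recipe = self.recipes[recipe_name]
        if vertex not in recipe.vertices:
            raise KeyError(f"vertex {vertex!r} not in recipe {recipe_name!r}")
        session = payload.get("session", "")
        out: list[str] = []
        for dst in recipe.downstream(vertex):
            key = make_idempotency_key(session, recipe_name, dst, result.input_key)
            first, _ = self.idempotency.claim(key, None)
            if not first:
                continue
            params = {**recipe.parameters_of(dst), **payload.get("parameters", {}),
                      **result.forward}
            msg_id = self.broker.publish(
                self.config.service_queue(recipe.service_of(dst)),
                {"recipe": recipe_name, "vertex": dst, "parameters": params,
                 "session": session, "idempotency_key": key},
            )
            self.idempotency._seen[key] = msg_id
            out.append(msg_id)
        return out

    def publish_record(self, service_record_kind: str, payload: dict,
                       result: "StageResult") -> str:
        """Ask the LIMS connector to persist this outcome (dedup downstream)."""
        params = payload.get("parameters", {})
        record = {
            "session": payload.get("session", ""),
            "series_id": params.get("series_id", ""),
            "movie_id": params.get("movie_id"),
            "kind": service_record_kind,
            "metrics": result.metrics,
            "artifact_paths": result.artifact_paths,
            "idempotency_key": payload.get("idempotency_key", ""),
        }
        return self.broker.publish(
            self.results_queue,
            {"recipe": payload.get("recipe", ""), "vertex": "ispyb",
             "parameters": record, "session": record["session"],
             "idempotency_key": f"record:{record['idempotency_key']}"},
        )


from .stages.types import StageResult  # noqa: E402  (cycle-free: types only)
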
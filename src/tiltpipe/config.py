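"""Pipeline configuration: service catalogue, scaling policy, broker settings.

The defaults mirror a production cryoET facility deployment scaled to a
desk: the same service names, queue topology and per-service replica
bounds (motion correction 8, CTF estimation 4, reconstruction 4, denoising
2, LIMS connector 4, images 4, dispatcher 2), with the GPU tools replaced
by the package's own numeric stages. Configuration is plain YAML validated
through pydantic models.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "ServiceSpec",
    "ScalingPolicy",
    "BrokerConfig",
    "OpticsConfig",
    "CtfSearchConfig",
    "PipelineConfig",
    "default_config",
    "load_config",
]


class ServiceSpec(BaseModel):
    """One deployable service: a queue, the stage it runs, and replica bounds."""

    name: str
    queue: str
    stage: str
    min_instances: int = 0
    max_instances: int = 1
    resource_class: str = Field(default="cpu", pattern="^(gpu|cpu)$")
    executor_pool: str = Field(default="local", pattern="^(local|remote)$")
    #: outcome kind recorded on success (None: service produces no LIMS record)
    record_kind: Optional[str] = None
    #: simulated processing duration, in scheduler ticks, for one message
    service_time: int = 1
    #: for sub-tick services (service_time 1): messages one replica can
    #: absorb per tick — dispatch and record inserts are orders of
    #: magnitude cheaper than the imaging stages
    messages_per_tick: int = 1

    @model_validator(mode="after")
    def _check_bounds(self) -> "ServiceSpec":
        if not (0 <= self.min_instances <= self.max_instances):
            raise ValueError(
                f"service {self.name}: need 0 <= min_instances <= max_instances"
            )
        if self.service_time < 1:
            raise ValueError(f"service {self.name}: service_time must be >= 1")
        return self


class ScalingPolicy(BaseModel):
    """Queue-depth-driven autoscaling parameters.

    ``messages_per_instance`` is the queue depth one replica is expected to
    absorb (KEDA-style queue-length trigger); ``local_gpu_capacity`` is the
    number of GPU-class worker slots available locally before submission to
    the remote pool spills over.
    """

    messages_per_instance: int = Field(default=1, gt=0)
    cooldown: float = Field(default=5.0, ge=0.0)
    local_gpu_capacity: int = Field(default=8, ge=0)


class BrokerConfig(BaseModel):
    delivery_limit: int = Field(default=3, ge=1)
    ack_timeout: float = Field(default=30.0, gt=0)
    extra_queues: list[str] = Field(default_factory=list)


class OpticsConfig(BaseModel):
    """Microscope optics used by CTF simulation and estimation."""

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.1


class CtfSearchConfig(BaseModel):
    defocus_min_um: float = 0.5
    defocus_max_um: float = 5.0
    step_um: float = 0.05

    @model_validator(mode="after")
    def _check(self) -> "CtfSearchConfig":
        if not (self.defocus_min_um < self.defocus_max_um and self.step_um > 0):
            raise ValueError("need defocus_min < defocus_max and step > 0")
        return self


class PipelineConfig(BaseModel):
    broker: BrokerConfig = Field(default_factory=BrokerConfig)
    services: list[ServiceSpec]
    scaling: ScalingPolicy = Field(default_factory=ScalingPolicy)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    ctf_search: CtfSearchConfig = Field(default_factory=CtfSearchConfig)
    #: command templates for the external GPU tools; built but never executed
    stage_templates: dict[str, dict] = Field(default_factory=dict)

    @field_validator("services")
    @classmethod
    def _unique_names(cls, v: list[ServiceSpec]) -> list[ServiceSpec]:
        names = [s.name for s in v]
        if len(set(names)) != len(names):
            raise ValueError("duplicate service names")
        return v

    @property
    def queues(self) -> list[str]:
        qs: list[str] = []
        for s in self.services:
            if s.queue not in qs:
                qs.append(s.queue)
        for q in self.broker.extra_queues:
            if q not in qs:
                qs.append(q)
        return qs

    def service(self, name: str) -> ServiceSpec:
        for s in self.services:
            if s.name == name:
                return s
        raise KeyError(f"unknown service {name!r}")

    def service_queue(self, name: str) -> str:
        return self.service(name).queue


#: Replica bounds per service, as deployed facility-side for live analysis
#: on four microscopes; the dispatcher turns processing requests into entry
#: messages and the LIMS connector persists outcomes.
_DEFAULT_SERVICES: list[dict] = [
    dict(name="dispatcher", queue="processing_requests", stage="dispatch",
         min_instances=1, max_instances=2, resource_class="cpu",
         messages_per_tick=32),
    dict(name="motioncorr", queue="motioncorr", stage="motioncorr",
         min_instances=0, max_instances=8, resource_class="gpu",
         record_kind="motioncorr", service_time=1),
    dict(name="ctffind", queue="ctffind", stage="ctffind",
         min_instances=0, max_instances=4, resource_class="cpu",
         record_kind="ctf", service_time=1),
    dict(name="tomo_align_recon", queue="tomo_align_recon", stage="tomo_align_recon",
         min_instances=0, max_instances=4, resource_class="gpu",
         record_kind="tomogram", service_time=5),
    dict(name="denoise", queue="denoise", stage="denoise",
         min_instances=0, max_instances=2, resource_class="gpu",
         record_kind="denoised_tomogram", service_time=2),
    dict(name="images", queue="images", stage="images",
         min_instances=0, max_instances=4, resource_class="cpu",
         record_kind="images", messages_per_tick=8),
    dict(name="ispyb", queue="ispyb", stage="ispyb",
         min_instances=1, max_instances=4, resource_class="cpu",
         messages_per_tick=32),
]

_DEFAULT_TEMPLATES: dict[str, dict] = {
    # Example invocations of the production GPU tools; these are built into
    # argument vectors for operators to run elsewhere, never executed here.
    "motioncorr": {
        "binary": "MotionCor2",
        "args": ["-InMrc", "{movie}", "-OutMrc", "{micrograph}",
                 "-PixSize", "{pixel_size}", "-Patch", "1", "1"],
    },
    "ctffind": {
        "binary": "ctffind4",
        "args": ["{micrograph}", "{diagnostic}", "{pixel_size}", "{voltage}",
                 "{cs}", "{amplitude_contrast}", "512", "30", "5",
                 "{defocus_min}", "{defocus_max}", "{defocus_step}"],
    },
    "tomo_align_recon": {
        "binary": "AreTomo",
        "args": ["-InMrc", "{stack}", "-OutMrc", "{tomogram}",
                 "-AngFile", "{angles}", "-VolZ", "{thickness}"],
    },
    "denoise": {
        "binary": "topaz",
        "args": ["denoise3d", "{tomogram}", "-o", "{output_dir}"],
    },
}


def default_config() -> PipelineConfig:
    return PipelineConfig(
        services=[ServiceSpec(**s) for s in _DEFAULT_SERVICES],
        stage_templates=dict(_DEFAULT_TEMPLATES),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML configuration file; absent keys fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "services" not in raw:
        raw["services"] = _DEFAULT_SERVICES
    if "stage_templates" not in raw:
        raw["stage_templates"] = dict(_DEFAULT_TEMPLATES)
    return PipelineConfig(**raw)
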
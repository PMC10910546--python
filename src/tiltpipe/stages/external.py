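"""Command-template builders for the production GPU tools.

At the facility each stage runs an external program (MotionCor2, CTFFind4,
AreTomo, Topaz). At desk scale only the argument vectors are built — with
absolute paths, no shell interpolation, fully deterministic — so the
templates can be validated and handed to an operator; they are never
executed by this package.
"""

from __future__ import annotations

import os
import string
from typing import Any

__all__ = ["build_external_command", "MissingTemplateParameters"]

_PATH_KEYS = {"movie", "micrograph", "stack", "tomogram", "angles", "diagnostic",
              "output_dir"}


class MissingTemplateParameters(KeyError):
    def __init__(self, stage: str, missing: list[str]) -> None:
        self.missing = sorted(missing)
        super().__init__(f"stage {stage!r}: unbound template parameters: "
                         f"{', '.join(self.missing)}")


def build_external_command(stage: str, templates: dict[str, dict],
                           inputs: dict[str, Any], params: dict[str, Any] | None = None
                           ) -> list[str]:
    """Render a stage's command template into an argument vector.

    ``inputs`` values under path-like keys are made absolute. Missing
    template parameters raise :class:`MissingTemplateParameters` naming
    every unbound key at once.
    """
    if stage not in templates:
        raise KeyError(f"no command template configured for stage {stage!r}")
    template = templates[stage]
    values: dict[str, Any] = {**(params or {}), **inputs}
    for key in list(values):
        if key in _PATH_KEYS:
            values[key] = os.path.abspath(os.fspath(values[key]))

    formatter = string.Formatter()
    missing: set[str] = set()
    argv = [str(template["binary"])]
    for arg in template.get("args", []):
        fields = [f for _, f, _, _ in formatter.parse(str(arg)) if f]
        absent = [f for f in fields if f not in values]
        if absent:
            missing.update(absent)
            continue
        argv.append(str(arg).format(**values))
    if missing:
        raise MissingTemplateParameters(stage, list(missing))
    return argv
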
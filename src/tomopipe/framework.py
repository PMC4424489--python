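"""Plugin framework: space-tagged data blocks, registry, chain validation,
sequential pipeline execution with provenance.

Parallel-beam tomographic processing moves data through four geometrical
spaces — detector, projection, sinogram and image — and each correction has
a natural space in which it is applied.  The framework keeps plugins honest
about that: every plugin declares its input and output space, a process list
is validated for space compatibility before anything runs, and every executed
step appends a provenance record with its fully resolved parameters so the
run can be replayed bit-identically.

Execution is single-process and sequential.  Plugins declare a ``granularity``
(``frame``, ``slice`` or ``global``) so a parallel runner could be layered on
later without touching plugin code.
"""

from __future__ import annotations

import copy
import datetime
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Space",
    "DataBlock",
    "PluginSpec",
    "ProcessList",
    "ProvenanceRecord",
    "PluginRegistry",
    "ChainReport",
    "validate_chain",
    "run_pipeline",
    "TomoError",
    "ChainValidationError",
]

VERSION = "0.1.0"

# Canonical axis labels per space.
PROJECTION_AXES = ("angle", "vertical", "horizontal")
SINOGRAM_AXES = ("vertical_slice", "angle", "horizontal")
VOLUME_AXES = ("z", "y", "x")


class TomoError(Exception):
    """Base class for errors raised by tomopipe operations."""


class ChainValidationError(TomoError):
    """A process list failed space-compatibility validation."""


class Space(str, enum.Enum):
    """The four geometrical spaces of parallel-beam tomographic processing."""

    DETECTOR = "detector"
    PROJECTION = "projection"
    SINOGRAM = "sinogram"
    IMAGE = "image"

    @classmethod
    def coerce(cls, value: "Space | str") -> "Space":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown space {value!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None


@dataclass
class ProvenanceRecord:
    """One executed pipeline step: plugin, resolved parameters, spaces."""

    plugin: str
    params: dict[str, Any]
    version: str
    timestamp: str
    input_space: Space
    output_space: Space

    def to_dict(self) -> dict[str, Any]:
        return {
            "plugin": self.plugin,
            "params": self.params,
            "version": self.version,
            "timestamp": self.timestamp,
            "input_space": self.input_space.value,
            "output_space": self.output_space.value,
        }


@dataclass
class DataBlock:
    """An n-dimensional array tagged with its geometrical space and metadata.

    Parameters
    ----------
    values : ndarray
        The data.  Raw counts in detector space, transmission/attenuation in
        projection and sinogram space, reconstructed density in image space.
    space : Space or str
        Which of the four geometrical spaces the values live in.
    axes : sequence of str
        Ordered axis labels; length must equal ``values.ndim``.
    angles_deg : ndarray or None
        Per-frame rotation angles in degrees; required when an ``angle`` axis
        exists, and its length must match that axis.
    pixel_size : float
        Physical detector pixel pitch (length units; default 1.0 = pixel
        units).
    meta : dict
        Open key-value metadata (scan title, monitor readings, flats/darks
        attached by the loader, ...).
    provenance : list of ProvenanceRecord
        Processing history, appended by :func:`run_pipeline`.
    """

    values: np.ndarray
    space: Space
    axes: tuple[str, ...]
    angles_deg: np.ndarray | None = None
    pixel_size: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)
    provenance: list[ProvenanceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.space = Space.coerce(self.space)
        self.axes = tuple(self.axes)
        if len(self.axes) != self.values.ndim:
            raise ValueError(
                f"axes {self.axes} has length {len(self.axes)} but values "
                f"have rank {self.values.ndim}"
            )
        if self.angles_deg is not None:
            self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if "angle" in self.axes:
            if self.angles_deg is None:
                raise ValueError("block has an angle axis but no angles_deg")
            n = self.values.shape[self.axes.index("angle")]
            if len(self.angles_deg) != n:
                raise ValueError(
                    f"angle axis has extent {n} but angles_deg has length "
                    f"{len(self.angles_deg)}"
                )

    def replace(self, **kwargs: Any) -> "DataBlock":
        """Return a shallow-copied block with the given fields replaced.

        Metadata and provenance are carried over (copied) unless overridden.
        """
        out = DataBlock(
            values=kwargs.get("values", self.values),
            space=kwargs.get("space", self.space),
            axes=kwargs.get("axes", self.axes),
            angles_deg=kwargs.get("angles_deg", self.angles_deg),
            pixel_size=kwargs.get("pixel_size", self.pixel_size),
            meta=kwargs.get("meta", dict(self.meta)),
            provenance=kwargs.get("provenance", list(self.provenance)),
        )
        return out

    def require_space(self, space: Space | str) -> None:
        space = Space.coerce(space)
        if self.space is not space:
            raise TomoError(
                f"operation requires {space.value}-space data, got "
                f"{self.space.value}"
            )


@dataclass
class PluginSpec:
    """Declaration of one pipeline step.

    ``param_schema`` maps parameter name to a dict with at least a
    ``default`` key, or ``{"required": True}`` for mandatory parameters.
    ``granularity`` states whether the plugin operates per-frame, per-slice
    or globally — informational here, but lets a parallel runner partition
    work without changing plugin code.
    """

    name: str
    input_space: Space
    output_space: Space
    param_schema: dict[str, dict[str, Any]] = field(default_factory=dict)
    citation: str = ""
    granularity: str = "global"

    def __post_init__(self) -> None:
        self.input_space = Space.coerce(self.input_space)
        self.output_space = Space.coerce(self.output_space)
        for pname, schema in self.param_schema.items():
            if "default" not in schema and not schema.get("required", False):
                raise ValueError(
                    f"parameter {pname!r} of plugin {self.name!r} has no "
                    "default and is not marked required"
                )

    def resolve_params(self, params: Mapping[str, Any] | None) -> dict[str, Any]:
        """Fill in defaults; reject unknown or missing-required parameters."""
        params = dict(params or {})
        resolved: dict[str, Any] = {}
        for pname, schema in self.param_schema.items():
            if pname in params:
                resolved[pname] = params.pop(pname)
            elif schema.get("required", False):
                raise TomoError(
                    f"plugin {self.name!r}: required parameter {pname!r} missing"
                )
            else:
                resolved[pname] = schema["default"]
        if params:
            raise TomoError(
                f"plugin {self.name!r}: unknown parameter(s) {sorted(params)}"
            )
        return resolved


class PluginRegistry:
    """Name → (spec, implementation) mapping, insertion-ordered."""

    def __init__(self) -> None:
        self._plugins: dict[str, tuple[PluginSpec, Callable[..., DataBlock]]] = {}

    def register(
        self, spec: PluginSpec, implementation: Callable[..., DataBlock]
    ) -> "PluginRegistry":
        if spec.name in self._plugins:
            raise TomoError(f"plugin {spec.name!r} already registered")
        self._plugins[spec.name] = (spec, implementation)
        return self

    def get(self, name: str) -> tuple[PluginSpec, Callable[..., DataBlock]]:
        try:
            return self._plugins[name]
        except KeyError:
            raise TomoError(f"unknown plugin {name!r}") from None

    def spec(self, name: str) -> PluginSpec:
        return self.get(name)[0]

    def __contains__(self, name: str) -> bool:
        return name in self._plugins

    def __len__(self) -> int:
        return len(self._plugins)

    def names(self) -> list[str]:
        return list(self._plugins)


def register_plugin(
    registry: PluginRegistry,
    spec: PluginSpec,
    implementation: Callable[..., DataBlock],
) -> PluginRegistry:
    """Functional wrapper over :meth:`PluginRegistry.register`."""
    return registry.register(spec, implementation)


@dataclass
class ProcessList:
    """Ordered, parameterised plugin chain; the unit of provenance.

    Serialises to JSON as
    ``{"steps": [{"plugin": name, "params": {...}}, ...], "description": str}``
    and is embedded verbatim (as that JSON string) in HDF5 outputs.
    """

    steps: list[tuple[str, dict[str, Any]]] = field(default_factory=list)
    description: str = ""
    created: str = field(
        default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds")
    )

    def add(self, plugin: str, **params: Any) -> "ProcessList":
        self.steps.append((plugin, params))
        return self

    def to_json(self) -> str:
        doc = {
            "steps": [
                {"plugin": name, "params": params} for name, params in self.steps
            ],
            "description": self.description,
            "created": self.created,
        }
        return json.dumps(doc, indent=2, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "ProcessList":
        doc = json.loads(text)
        if not isinstance(doc, dict) or "steps" not in doc:
            raise TomoError("process list JSON must be an object with a 'steps' key")
        steps = [
            (step["plugin"], dict(step.get("params", {}))) for step in doc["steps"]
        ]
        return cls(
            steps=steps,
            description=doc.get("description", ""),
            created=doc.get("created", ""),
        )

    def __eq__(self, other: object) -> bool:
        # Equality on content, not creation time.
        if not isinstance(other, ProcessList):
            return NotImplemented
        return self.steps == other.steps and self.description == other.description


@dataclass
class ChainReport:
    """Result of validating a process list against a registry."""

    valid: bool
    final_space: Space | None
    failure_index: int | None = None
    reason: str | None = None


def validate_chain(
    process_list: ProcessList,
    registry: PluginRegistry,
    initial_space: Space | str,
) -> ChainReport:
    """Check that each step's input space matches the running space.

    Only space compatibility is enforced; scientific ordering within a space
    (e.g. ring removal before reconstruction) is the user's responsibility.
    """
    space = Space.coerce(initial_space)
    for i, (name, params) in enumerate(process_list.steps):
        if name not in registry:
            return ChainReport(False, None, i, f"unknown plugin {name!r}")
        spec = registry.spec(name)
        if spec.input_space is not space:
            return ChainReport(
                False,
                None,
                i,
                f"step {i} ({name!r}) expects {spec.input_space.value}-space "
                f"input but running space is {space.value}",
            )
        try:
            spec.resolve_params(params)
        except TomoError as exc:
            return ChainReport(False, None, i, str(exc))
        space = spec.output_space
    return ChainReport(True, space)


def _timestamp() -> str:
    return datetime.datetime.now().isoformat(timespec="seconds")


def run_pipeline(
    block: DataBlock,
    process_list: ProcessList,
    registry: PluginRegistry,
    *,
    keep_intermediates: bool = False,
    intermediate_dir: str | Path | None = None,
) -> DataBlock:
    """Apply a validated plugin chain to a block, recording provenance.

    One :class:`ProvenanceRecord` (with fully resolved parameters) is
    appended per executed step, so the run can be replayed bit-identically
    from the output's provenance.  With ``keep_intermediates`` each step's
    output is persisted as an HDF5 file named ``step_<i>_<plugin>.h5``; on a
    mid-chain plugin failure, intermediates written so far are retained for
    inspection.
    """
    report = validate_chain(process_list, registry, block.space)
    if not report.valid:
        raise ChainValidationError(
            f"invalid chain at step {report.failure_index}: {report.reason}"
        )
    if keep_intermediates:
        if intermediate_dir is None:
            raise TomoError("keep_intermediates requires intermediate_dir")
        intermediate_dir = Path(intermediate_dir)
        intermediate_dir.mkdir(parents=True, exist_ok=True)

    current = block
    for i, (name, params) in enumerate(process_list.steps):
        spec, impl = registry.get(name)
        resolved = spec.resolve_params(params)
        out = impl(current, **copy.deepcopy(resolved))
        if not isinstance(out, DataBlock):
            raise TomoError(f"plugin {name!r} returned {type(out)}, not DataBlock")
        if out.space is not spec.output_space:
            raise TomoError(
                f"plugin {name!r} declared output space "
                f"{spec.output_space.value} but produced {out.space.value}"
            )
        if not np.all(np.isfinite(out.values)):
            raise TomoError(
                f"plugin {name!r} produced non-finite values (contract violation)"
            )
        out.provenance = list(current.provenance) + [
            ProvenanceRecord(
                plugin=name,
                params=resolved,
                version=VERSION,
                timestamp=_timestamp(),
                input_space=spec.input_space,
                output_space=spec.output_space,
            )
        ]
        if keep_intermediates:
            from . import nxtomo  # deferred: avoid import cycle

            path = Path(intermediate_dir) / f"step_{i:02d}_{name}.h5"
            nxtomo.write_block(path, out)
        current = out
    return current
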
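"""The movement registry: which landmarks define which joint movement.

Each entry names a standing range-of-motion evaluation movement, the
subject's recording orientation relative to the camera, and — for each
device dialect — the two segment endpoints (single landmark or midpoint of
two) whose connecting vector sweeps out the movement angle.  Bilateral
movements (shoulder, elbow, hip) are stored once with ``LEFT/RIGHT``
marker notation and expanded into left and right sided variants.

The built-in registry covers the 11 movements of a standard standing ROM
chart: spine (back flexion/extension, back lateral flexion, trunk
rotation), neck (flexion/extension, lateral bending, rotation), upper
extremity (shoulder adduction/abduction, shoulder flexion/extension, elbow
flexion) and lower extremity (hip flexion/extension, hip
adduction/abduction).  Distal joints (wrist, ankle) are intentionally
absent: single-camera pose estimation does not track hands and feet
reliably enough for ROM work.  Users can extend the registry from YAML
without code changes (:func:`load_registry`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .trajectory_io import (
    ConfigurationError,
    EndpointSpec,
    landmark_vocabulary,
)

ORIENTATIONS = ("lateral_sagittal", "anterior_coronal")
SIDES = ("left", "right", "n/a")


@dataclass(frozen=True)
class MovementSpec:
    """One (possibly sided) movement definition.

    ``endpoints`` maps dialect name to the (joint1, joint2) endpoint pair.
    ``side`` is ``"n/a"`` for midline movements.  ``label`` is the key used
    in downstream ROM tables: the movement name, suffixed with the side
    for bilateral movements.
    """

    name: str
    orientation: str
    endpoints: Mapping[str, tuple[EndpointSpec, EndpointSpec]]
    bilateral: bool = False
    side: str = "n/a"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")
        if self.side not in SIDES:
            raise ConfigurationError(f"unknown side {self.side!r}")
        if self.bilateral == (self.side == "n/a"):
            raise ConfigurationError(
                f"{self.name}: bilateral specs must carry side left/right, "
                "midline specs side 'n/a'"
            )

    @property
    def label(self) -> str:
        if self.side == "n/a":
            return self.name
        return f"{self.name} ({self.side})"

    def endpoint_pair(self, dialect: str) -> tuple[EndpointSpec, EndpointSpec]:
        try:
            return self.endpoints[dialect]
        except KeyError:
            raise ConfigurationError(
                f"{self.label}: no endpoints defined for dialect {dialect!r}"
            ) from None


def _expand_marker(token: str, side: str) -> str:
    """Resolve 'LSHO/RSHO' notation to one side's marker name."""
    if "/" in token:
        left, _, right = token.partition("/")
        return left if side == "left" else right
    return token


def _row_to_specs(row: Mapping) -> list[MovementSpec]:
    name = row["name"]
    orientation = row["orientation"]
    raw = row["endpoints"]
    bilateral = any(
        "/" in marker
        for dialect_eps in raw.values()
        for ep in dialect_eps.values()
        for marker in ep
    )
    sides = ("left", "right") if bilateral else ("n/a",)
    specs = []
    for side in sides:
        endpoints = {}
        for dialect, eps in raw.items():
            pair = tuple(
                EndpointSpec.of(*(_expand_marker(m, side) for m in eps[joint]))
                for joint in ("joint1", "joint2")
            )
            endpoints[dialect] = pair
        specs.append(
            MovementSpec(
                name=name,
                orientation=orientation,
                endpoints=endpoints,
                bilateral=bilateral,
                side=side,
            )
        )
    return specs


def load_registry(path: str | Path) -> list[MovementSpec]:
    """Load and expand a YAML movement registry."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [spec for row in doc["movements"] for spec in _row_to_specs(row)]


def dump_registry(specs: Iterable[MovementSpec], path: str | Path) -> Path:
    """Serialize sided specs back to YAML (one row per sided variant)."""
    rows = []
    for spec in specs:
        rows.append(
            {
                "name": spec.name if spec.side == "n/a" else spec.label,
                "orientation": spec.orientation,
                "endpoints": {
                    dialect: {
                        "joint1": list(pair[0].markers),
                        "joint2": list(pair[1].markers),
                    }
                    for dialect, pair in spec.endpoints.items()
                },
            }
        )
    path = Path(path)
    path.write_text(yaml.safe_dump({"movements": rows}, sort_keys=False))
    return path


@lru_cache(maxsize=1)
def _builtin() -> tuple[MovementSpec, ...]:
    with resources.files("romkit.data").joinpath("movements.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return tuple(spec for row in doc["movements"] for spec in _row_to_specs(row))


def builtin_registry() -> list[MovementSpec]:
    """The built-in 11-movement registry, bilateral rows expanded (16 specs)."""
    return list(_builtin())


def lookup(
    name: str,
    side: str | None = None,
    registry: Iterable[MovementSpec] | None = None,
) -> MovementSpec:
    """Find a movement by name (and side for bilateral movements).

    ``name`` may be the plain movement name or a sided label like
    ``"Elbow Flexion (left)"``.
    """
    registry = list(registry) if registry is not None else builtin_registry()
    if side is None and name.endswith(")") and "(" in name:
        base, _, rest = name.rpartition("(")
        candidate = rest.rstrip(")").strip()
        if candidate in ("left", "right"):
            name, side = base.strip(), candidate
    matches = [s for s in registry if s.name == name]
    if not matches:
        raise KeyError(f"no movement named {name!r}")
    if matches[0].bilateral:
        if side not in ("left", "right"):
            raise ConfigurationError(
                f"{name!r} is bilateral; specify side='left' or 'right'"
            )
        matches = [s for s in matches if s.side == side]
    return matches[0]


def validate_spec(spec: MovementSpec, dialect: str) -> list[str]:
    """Check a spec against a dialect vocabulary; returns violations.

    Never raises: an empty list means the spec is usable for the dialect.
    """
    errors: list[str] = []
    try:
        vocab = set(landmark_vocabulary(dialect))
    except ConfigurationError as exc:
        return [str(exc)]
    if dialect not in spec.endpoints:
        return [f"{spec.label}: no endpoints for dialect {dialect!r}"]
    for joint_idx, ep in enumerate(spec.endpoints[dialect], start=1):
        if len(ep.markers) == 2 and ep.rule != "midpoint":
            errors.append(f"{spec.label} joint{joint_idx}: two markers need midpoint rule")
        for marker in ep.markers:
            if marker not in vocab:
                errors.append(
                    f"{spec.label} joint{joint_idx}: marker {marker!r} not in "
                    f"{dialect} vocabulary"
                )
    return errors
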
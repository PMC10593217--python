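"""Reading, validating and filtering 3D landmark trajectory files.

Two device dialects are supported:

``pose33``
    33 landmarks inferred per frame by a single-camera pose estimator.
    Coordinates are unitless world coordinates; each sample carries a
    per-frame *visibility* index in [0, 1] expressing the estimator's
    confidence (low values indicate occlusion or tracking failure).

``mocap39``
    39 physical reflective markers tracked by an optical motion-capture
    system, coordinates in meters, no visibility channel.

The on-disk format is long-format delimited text: one row per frame per
landmark with columns ``t, landmark, x, y, z[, visibility]``, preceded by
``# key: value`` comment lines carrying trial metadata (subject, movement,
device, trial, fps).  A line-delimited JSON variant is also supported
(first line a metadata object, then one object per sample).

All downstream quantities are angles, which are invariant to global
translation, rotation and positive scaling, so no unit conversion or
coordinate-frame alignment between dialects is performed.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DIALECTS = ("pose33", "mocap39")

#: Default visibility threshold: samples with visibility strictly below
#: this are discarded before any angle computation.
DEFAULT_VISIBILITY_THRESHOLD = 0.5

_META_KEYS = ("subject", "movement", "device", "trial", "fps")


class TrajectoryError(ValueError):
    """Malformed trajectory data (parse failure or invariant violation)."""


class ConfigurationError(ValueError):
    """Invalid dialect, unknown landmark, or inconsistent endpoint spec."""


def _load_vocabularies() -> dict[str, list[str]]:
    with resources.files("romkit.data").joinpath("vocabularies.yaml").open() as fh:
        return yaml.safe_load(fh)


_VOCAB: dict[str, list[str]] = _load_vocabularies()


def landmark_vocabulary(dialect: str) -> tuple[str, ...]:
    """Ordered landmark names of a device dialect."""
    if dialect not in _VOCAB:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_VOCAB)}"
        )
    return tuple(_VOCAB[dialect])


@dataclass(frozen=True)
class EndpointSpec:
    """A segment endpoint: a single landmark or the midpoint of two.

    ``rule`` is ``"single"`` for one marker and ``"midpoint"`` for two
    (the endpoint is then the frame-wise average location of the pair).
    """

    markers: tuple[str, ...]
    rule: str = "single"

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        object.__setattr__(self, "markers", markers)
        expected = "midpoint" if len(markers) == 2 else "single"
        if len(markers) not in (1, 2):
            raise ConfigurationError(
                f"endpoint needs 1 or 2 markers, got {markers}"
            )
        if self.rule != expected:
            raise ConfigurationError(
                f"rule {self.rule!r} inconsistent with {len(markers)} marker(s)"
            )

    @classmethod
    def of(cls, *markers: str) -> "EndpointSpec":
        return cls(tuple(markers), "midpoint" if len(markers) == 2 else "single")


@dataclass
class TrialTrajectory:
    """Time-stamped 3D landmark samples for one subject/movement/trial.

    ``df`` is a long-format frame with columns ``t, landmark, x, y, z``
    and, for the pose33 dialect, ``visibility``.  Frames are the groups of
    samples sharing a timestamp; timestamps are strictly increasing.
    ``provenance`` accumulates processing counters (samples removed by the
    visibility filter, frames dropped for missing markers, ...).
    """

    subject: str
    movement: str
    device: str
    trial: int
    fps: float
    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.device not in DIALECTS:
            raise ConfigurationError(f"unknown dialect {self.device!r}")
        if int(self.trial) < 1:
            raise TrajectoryError(f"trial index must be >= 1, got {self.trial}")

    # -- derived views ---------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        """Sorted unique frame timestamps, seconds."""
        return np.unique(self.df["t"].to_numpy())

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def landmarks(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["landmark"].unique()))

    def validate(self, min_frames: int = 2) -> None:
        """Check the trajectory invariants, raising on violation."""
        df = self.df
        required = {"t", "landmark", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise TrajectoryError(f"missing columns: {sorted(missing)}")
        pos = df[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(pos)):
            bad = int(np.flatnonzero(~np.isfinite(pos).all(axis=1))[0])
            raise TrajectoryError(f"non-finite position at row {bad}")
        vocab = set(landmark_vocabulary(self.device))
        unknown = set(df["landmark"].unique()) - vocab
        if unknown:
            raise TrajectoryError(
                f"unknown landmark(s) for dialect {self.device}: {sorted(unknown)}"
            )
        if "visibility" in df.columns:
            vis = df["visibility"].to_numpy(float)
            if np.any((vis < 0) | (vis > 1)):
                raise TrajectoryError("visibility outside [0, 1]")
        # strictly increasing frame timestamps: check per landmark, since
        # rows are grouped by frame in file order
        per_frame = df.groupby("landmark", sort=False)["t"]
        if not all(g.is_monotonic_increasing and g.is_unique for _, g in per_frame):
            raise TrajectoryError("timestamps not strictly increasing within trial")
        if self.n_frames < min_frames:
            raise TrajectoryError(
                f"trial has {self.n_frames} frame(s); need at least {min_frames}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_meta_header(lines: Iterable[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def read_trajectory(
    path: str | Path,
    dialect: str | None = None,
    **meta_overrides,
) -> TrialTrajectory:
    """Read a trajectory file (CSV or JSONL) into a validated trajectory.

    Metadata comes from the ``#`` header (CSV) or the leading metadata
    object (JSONL); keyword overrides win.  ``dialect`` overrides the
    file's ``device`` field.  Unknown landmark names and non-monotone
    timestamps are rejected; a visibility column on a mocap39 file is
    ignored with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        meta, df = _read_jsonl(path)
    else:
        meta, df = _read_csv(path)
    meta.update({k: v for k, v in meta_overrides.items() if v is not None})
    if dialect is not None:
        meta["device"] = dialect
    device = meta.get("device")
    if device not in DIALECTS:
        raise ConfigurationError(
            f"{path}: dialect {device!r} unknown (pass dialect= or set a "
            "'# device:' header)"
        )
    if device == "mocap39" and "visibility" in df.columns:
        logger.warning("%s: visibility column ignored for mocap39 dialect", path)
        df = df.drop(columns=["visibility"])
    traj = TrialTrajectory(
        subject=str(meta.get("subject", "unknown")),
        movement=str(meta.get("movement", "unknown")),
        device=device,
        trial=int(meta.get("trial", 1)),
        fps=float(meta.get("fps", 0.0) or 0.0),
        df=df.reset_index(drop=True),
    )
    traj.validate()
    return traj


def _read_csv(path: Path) -> tuple[dict, pd.DataFrame]:
    header_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                break
    meta = _parse_meta_header(header_lines)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # surface the offending location
        raise TrajectoryError(f"{path}: cannot parse CSV: {exc}") from exc
    _check_body(path, df)
    return meta, df


def _read_jsonl(path: Path) -> tuple[dict, pd.DataFrame]:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TrajectoryError(f"{path}: bad JSON at line {lineno}: {exc}")
            if "_meta" in obj:
                meta.update(obj["_meta"])
            else:
                rows.append(obj)
    if not rows:
        raise TrajectoryError(f"{path}: no samples")
    df = pd.DataFrame(rows)
    _check_body(path, df)
    return meta, df


def _check_body(path: Path, df: pd.DataFrame) -> None:
    required = {"t", "landmark", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("t", "x", "y", "z"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise TrajectoryError(f"{path}: non-numeric {col!r} near line {line}")


def write_trajectory(traj: TrialTrajectory, path: str | Path) -> Path:
    """Write a trajectory as commented-header CSV (or JSONL by extension)."""
    path = Path(path)
    meta = {
        "subject": traj.subject,
        "movement": traj.movement,
        "device": traj.device,
        "trial": traj.trial,
        "fps": traj.fps,
    }
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with open(path, "w") as fh:
            fh.write(json.dumps({"_meta": meta}) + "\n")
            for row in traj.df.to_dict(orient="records"):
                fh.write(json.dumps(row) + "\n")
        return path
    buf = io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}: {value}\n")
    traj.df.to_csv(buf, index=False, float_format="%.9g")
    path.write_text(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# filtering and endpoint resolution
# ---------------------------------------------------------------------------

def filter_visibility(
    traj: TrialTrajectory, threshold: float = DEFAULT_VISIBILITY_THRESHOLD
) -> TrialTrajectory:
    """Drop samples whose visibility index is strictly below ``threshold``.

    Only meaningful for the pose33 dialect (mocap has no visibility
    channel).  The number of removed samples is recorded under
    ``provenance["visibility_removed"]``.  Frames that lose a landmark
    required by a movement are subsequently dropped by
    :func:`resolve_endpoint`, not interpolated.
    """
    if traj.device != "pose33":
        raise ConfigurationError(
            f"visibility filtering applies to pose33 only, not {traj.device}"
        )
    if "visibility" not in traj.df.columns:
        return traj
    keep = traj.df["visibility"].to_numpy(float) >= threshold
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "%s/%s trial %d: removed %d low-visibility sample(s) (< %g)",
            traj.subject, traj.movement, traj.trial, removed, threshold,
        )
    out = replace(traj, df=traj.df.loc[keep].reset_index(drop=True))
    out.provenance = dict(traj.provenance)
    out.provenance["visibility_removed"] = (
        out.provenance.get("visibility_removed", 0) + removed
    )
    return out


def resolve_endpoint(
    traj: TrialTrajectory, spec: EndpointSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve an endpoint spec to a per-frame 3D point series.

    Returns ``(t, points)`` where ``points`` has shape (n_frames, 3).
    ``rule="single"`` yields the landmark's own positions; ``"midpoint"``
    the component-wise mean of the two landmarks.  Frames where any
    required marker is missing (filtered out, or never recorded) are
    dropped from the series.
    """
    vocab = set(landmark_vocabulary(traj.device))
    unknown = [m for m in spec.markers if m not in vocab]
    if unknown:
        raise ConfigurationError(
            f"marker(s) {unknown} not in {traj.device} vocabulary"
        )
    sub = traj.df[traj.df["landmark"].isin(spec.markers)]
    wide = sub.pivot_table(
        index="t", columns="landmark", values=["x", "y", "z"], aggfunc="first"
    )
    # keep only frames where every required marker is present
    present = wide.notna().all(axis=1)
    wide = wide.loc[present]
    t = wide.index.to_numpy(float)
    coords = np.stack(
        [
            np.mean([wide[(axis, m)].to_numpy(float) for m in spec.markers], axis=0)
            for axis in ("x", "y", "z")
        ],
        axis=1,
    )
    return t, coords
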
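"""Readers and writers for the package's on-disk formats.

Sensor logs are plain CSV with a mandatory header
``timestamp,sensor,v1,v2,v3,v4`` (comma separator, ``.`` decimals, float
seconds timestamps).  One row is one sample of one sensor kind:

* ``accelerometer`` / ``gyroscope``: v1..v3 = x, y, z (m/s^2 or rad/s);
* ``proximity``: v1 = raw distance in cm (binarization, if any, is a
  feature-extraction concern — I/O stays lossless);
* ``gps``: v1 = latitude (deg), v2 = longitude (deg), v3 = speed (km/h),
  v4 = fix quality in [0, 1].

Rows that cannot be parsed or violate a sample invariant are counted as
malformed and skipped; decreasing timestamps within one kind are rejected
(with the offending row index), never silently repaired.  Model files and
location registries are JSON with an explicit ``schema_version``.

Floats are serialized with ``repr`` so every writer/reader pair round-trips
bit exactly.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .anb import ClassModel
from .errors import FormatError, OrderingError, SchemaVersionError
from .hierarchy import RegisteredLocation

logger = logging.getLogger(__name__)

SENSOR_KINDS = ("accelerometer", "gyroscope", "proximity", "gps")
CSV_COLUMNS = ("timestamp", "sensor", "v1", "v2", "v3", "v4")
MODEL_SCHEMA_VERSION = 1
REGISTRY_SCHEMA_VERSION = 1

#: number of value columns each sensor kind uses
_ARITY = {"accelerometer": 3, "gyroscope": 3, "proximity": 1, "gps": 4}
_KIND_ORDER = {k: i for i, k in enumerate(SENSOR_KINDS)}


@dataclass(frozen=True)
class SensorSample:
    """A single time-stamped reading of one sensor kind."""

    timestamp: float
    kind: str
    values: tuple

    def __post_init__(self) -> None:
        if self.kind not in SENSOR_KINDS:
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        if len(self.values) != _ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} sample needs {_ARITY[self.kind]} values, "
                f"got {len(self.values)}"
            )
        if self.kind == "gps":
            lat, lon, speed, q = self.values
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"gps coordinates out of range ({lat}, {lon})")
            if speed < 0:
                raise ValueError(f"gps speed must be >= 0, got {speed}")
            if not (0 <= q <= 1):
                raise ValueError(f"gps fix_quality must lie in [0, 1], got {q}")


@dataclass
class SensorLog:
    """Per-kind sample streams, each a 2-D float array sorted by time.

    Column layouts: accelerometer/gyroscope ``(t, x, y, z)``, proximity
    ``(t, value_cm)``, gps ``(t, lat, lon, speed_kmh, fix_quality)``.
    """

    accelerometer: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    gyroscope: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    proximity: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    gps: np.ndarray = field(default_factory=lambda: np.empty((0, 5)))
    nominal_rate_hz: float = 50.0
    malformed_rows: int = 0

    def __post_init__(self) -> None:
        if not self.nominal_rate_hz > 0:
            raise ValueError("nominal_rate_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return sum(s.shape[0] for s in self._streams().values())

    def _streams(self) -> dict:
        return {
            "accelerometer": self.accelerometer,
            "gyroscope": self.gyroscope,
            "proximity": self.proximity,
            "gps": self.gps,
        }

    def time_span(self) -> tuple[float, float] | None:
        """(first, last) timestamp over all kinds, or None if empty."""
        firsts = [s[0, 0] for s in self._streams().values() if s.shape[0]]
        lasts = [s[-1, 0] for s in self._streams().values() if s.shape[0]]
        if not firsts:
            return None
        return float(min(firsts)), float(max(lasts))

    def __eq__(self, other) -> bool:
        if not isinstance(other, SensorLog):
            return NotImplemented
        return (
            all(
                np.array_equal(a, b)
                for a, b in zip(self._streams().values(), other._streams().values())
            )
            and self.nominal_rate_hz == other.nominal_rate_hz
        )


# ---------------------------------------------------------------------------
# sensor-log CSV
# ---------------------------------------------------------------------------

def read_sensor_log(path, nominal_rate_hz: float = 50.0) -> SensorLog:
    """Parse a sensor-log CSV into per-kind streams.

    Malformed rows (bad arity, unparseable numbers, unknown kinds, GPS
    values out of range) are counted on ``SensorLog.malformed_rows`` and
    logged; a timestamp decrease within one kind raises
    :class:`~harf.errors.OrderingError` naming the row.
    """
    path = Path(path)
    rows: dict[str, list] = {k: [] for k in SENSOR_KINDS}
    last_t: dict[str, float] = {}
    malformed = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected header {CSV_COLUMNS}")
        if tuple(h.strip().lower() for h in header[: len(CSV_COLUMNS)]) != CSV_COLUMNS:
            raise FormatError(
                f"{path}: missing required columns; expected header "
                f"{','.join(CSV_COLUMNS)!r}, found {','.join(header)!r}"
            )
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            if not row or all(not c.strip() for c in row):
                continue
            try:
                t = float(row[0])
                kind = row[1].strip()
                arity = _ARITY[kind]  # KeyError -> malformed
                vals = tuple(float(row[2 + k]) for k in range(arity))
                SensorSample(t, kind, vals)  # range/invariant validation
            except (KeyError, ValueError, IndexError) as exc:
                malformed += 1
                logger.warning("%s row %d malformed: %s", path, i, exc)
                continue
            if kind in last_t and t < last_t[kind]:
                raise OrderingError(
                    f"{path} row {i}: {kind} timestamp {t} decreases "
                    f"(previous {last_t[kind]})"
                )
            last_t[kind] = t
            rows[kind].append((t, *vals))
    log = SensorLog(
        accelerometer=np.array(rows["accelerometer"], dtype=float).reshape(-1, 4),
        gyroscope=np.array(rows["gyroscope"], dtype=float).reshape(-1, 4),
        proximity=np.array(rows["proximity"], dtype=float).reshape(-1, 2),
        gps=np.array(rows["gps"], dtype=float).reshape(-1, 5),
        nominal_rate_hz=nominal_rate_hz,
        malformed_rows=malformed,
    )
    return log


def write_sensor_log(log: SensorLog, path) -> None:
    """Write a :class:`SensorLog` as canonical CSV (stable, bit round-trip).

    Rows are merged across kinds sorted by ``(timestamp, kind)``; within one
    kind the original order is preserved.
    """
    merged = []
    for kind, stream in log._streams().items():
        for idx in range(stream.shape[0]):
            merged.append((stream[idx, 0], _KIND_ORDER[kind], idx, kind, stream[idx, 1:]))
    merged.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for t, _, _, kind, vals in merged:
            cells = [repr(float(t)), kind] + [repr(float(v)) for v in vals]
            cells += [""] * (4 - len(vals))
            writer.writerow(cells)


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

def write_models(models: Sequence[ClassModel], path, feature_config: dict | None = None) -> None:
    """Serialize a non-empty model set (plus its feature schema) to JSON."""
    models = list(models)
    if not models:
        raise ValueError("refusing to write an empty model set")
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_names": list(models[0].feature_names),
        "models": [m.to_dict() for m in models],
    }
    if feature_config is not None:
        doc["feature_config"] = feature_config
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_models(path) -> list[ClassModel]:
    """Read a model set; schema-version problems raise a versioned error."""
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaVersionError(
            f"{path}: not a valid schema-v{MODEL_SCHEMA_VERSION} model file "
            f"(JSON parse failed: {exc})"
        ) from exc
    version = doc.get("schema_version") if isinstance(doc, dict) else None
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: model schema_version {version!r} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        return [ClassModel.from_dict(d) for d in doc["models"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed model entry: {exc}") from exc


def read_model_feature_config(path) -> dict | None:
    """Feature configuration stored alongside the models, if any."""
    with open(path) as fh:
        return json.load(fh).get("feature_config")


# ---------------------------------------------------------------------------
# location-registry JSON
# ---------------------------------------------------------------------------

def write_location_registry(registry: Sequence[RegisteredLocation], path) -> None:
    doc = {
        "schema_version": REGISTRY_SCHEMA_VERSION,
        "locations": [
            {
                "label": r.label,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "radius_m": r.radius_m,
                "category": r.category,
            }
            for r in registry
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_location_registry(path) -> list[RegisteredLocation]:
    """Read and validate a registry of geofenced venues.

    Categories are restricted to home/office/type2, radii must be positive,
    and labels must be unique; a violation names the offending entry.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaVersionError(f"{path}: registry JSON parse failed: {exc}") from exc
    if isinstance(doc, dict):
        version = doc.get("schema_version")
        if version != REGISTRY_SCHEMA_VERSION:
            raise SchemaVersionError(
                f"{path}: registry schema_version {version!r} unsupported"
            )
        entries = doc.get("locations", [])
    else:  # bare JSON array is accepted as version-1 content
        entries = doc
    out: list[RegisteredLocation] = []
    seen: set = set()
    for i, e in enumerate(entries):
        try:
            loc = RegisteredLocation(
                label=e["label"],
                latitude=float(e["latitude"]),
                longitude=float(e["longitude"]),
                radius_m=float(e["radius_m"]),
                category=e["category"],
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: registry entry {i} ({e!r}): {exc}") from exc
        if loc.label in seen:
            raise FormatError(f"{path}: duplicate registry label {loc.label!r}")
        seen.add(loc.label)
        out.append(loc)
    return out


# re-exported confusion-matrix I/O lives with the evaluation code
def write_confusion(cm, path) -> None:
    from .evaluation import write_confusion as _write

    _write(cm, path)


def read_confusion(path):
    from .evaluation import read_confusion as _read

    return _read(path)
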
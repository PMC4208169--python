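"""Hierarchical activity-recognition routing (HARF).

The framework recognizes 15 smartphone activities organized in three types:

* Type 1 — physical activities qualified by where they happen
  (Home/Office/Outdoor x {Walking, Sitting, Standing} plus Outdoor/Jogging),
  classified by Gaussian naïve Bayes over inertial features with the
  candidate set restricted to the matched area;
* Type 2 — activities implied purely by presence at a registered venue
  (bus stop, cafeteria, gym, park): the venue label is returned directly and
  the statistical classifier is never invoked;
* Type 3 — "Riding a car", a heuristic override: whatever the classifier
  says outdoors, a windowed GPS mean speed strictly above 25 km/h relabels
  the window as riding a car (cars at speed otherwise masquerade as walking
  or jogging through road vibration).

Routing order per window: match the last GPS fix against the registered
location list (nearest geofence containing the point); a Type-2 match
short-circuits, a home/office match restricts the classifier to that area's
three labels, an unmatched location falls to the outdoor candidate set and
is the only branch where the speed override applies.  Every decision is
recorded in the prediction's route trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

from .anb import ClassModel
from .classifier import PosteriorScore, classify
from .errors import ConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureVector, GpsSummary

EARTH_RADIUS_M = 6_371_000.0

#: GPS speed above which a window is compulsorily labeled "Riding a car".
SPEED_OVERRIDE_KMH = 25.0

#: Minimum fix quality regarded as a usable open-sky (outdoor) GPS signal.
DEFAULT_QUALITY_THRESHOLD = 0.5

DEFAULT_GEOFENCE_RADIUS_M = 50.0

AREAS = ("Home", "Office", "Outdoor")
LOCATION_CATEGORIES = ("home", "office", "type2")


# ---------------------------------------------------------------------------
# activity taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityLabel:
    """One of the 15 recognizable activities."""

    name: str
    area: str
    activity_type: int  # 1 = location+multimodal, 2 = location only, 3 = heuristic


_PHYSICAL = ("Walking", "Sitting", "Standing")

TYPE1_LABELS: tuple[ActivityLabel, ...] = tuple(
    ActivityLabel(f"{area}/{act}", area, 1)
    for area in ("Home", "Office")
    for act in _PHYSICAL
) + tuple(
    ActivityLabel(f"Outdoor/{act}", "Outdoor", 1)
    for act in _PHYSICAL + ("Jogging",)
)

TYPE2_LABELS: tuple[ActivityLabel, ...] = tuple(
    ActivityLabel(name, "Outdoor", 2)
    for name in (
        "Waiting for bus at bus stop",
        "Having a meal at cafeteria",
        "Exercising at gym",
        "Visiting a park",
    )
)

RIDING_A_CAR = ActivityLabel("Riding a car", "Outdoor", 3)

ACTIVITY_LABELS: tuple[ActivityLabel, ...] = TYPE1_LABELS + TYPE2_LABELS + (RIDING_A_CAR,)
LABELS_BY_NAME = {lab.name: lab for lab in ACTIVITY_LABELS}
TYPE2_NAMES = tuple(lab.name for lab in TYPE2_LABELS)


def area_candidates(area: str) -> tuple[str, ...]:
    """Type-1 candidate label names for a routing area, in taxonomy order."""
    if area not in AREAS:
        raise ValueError(f"unknown area {area!r}")
    acts = _PHYSICAL + ("Jogging",) if area == "Outdoor" else _PHYSICAL
    return tuple(f"{area}/{a}" for a in acts)


# ---------------------------------------------------------------------------
# registered locations / geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegisteredLocation:
    """A geofenced venue: circular region on the WGS84 sphere."""

    label: str
    latitude: float
    longitude: float
    radius_m: float = DEFAULT_GEOFENCE_RADIUS_M
    category: str = "type2"

    def __post_init__(self) -> None:
        if self.category not in LOCATION_CATEGORIES:
            raise ValueError(
                f"location {self.label!r}: unknown category {self.category!r}"
            )
        if not (self.radius_m > 0):
            raise ValueError(f"location {self.label!r}: radius_m must be > 0")
        _check_coords(self.latitude, self.longitude, context=self.label)
        if self.category == "type2" and self.label not in TYPE2_NAMES:
            raise ValueError(
                f"type2 location label {self.label!r} is not a location-based "
                f"activity; expected one of {TYPE2_NAMES}"
            )


def _check_coords(lat: float, lon: float, context: str = "") -> None:
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ValueError(f"non-finite coordinates {context}")
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"coordinates out of range ({lat}, {lon}) {context}")


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters on a sphere of mean Earth radius."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def match_location(
    lat: float, lon: float, registry: Sequence[RegisteredLocation]
) -> Optional[RegisteredLocation]:
    """Registered location whose geofence contains the point, nearest first.

    Returns ``None`` when no geofence contains the point.  Among overlapping
    fences the entry with the smallest center distance wins (label order
    breaks exact distance ties deterministically).
    """
    _check_coords(lat, lon)
    best = None
    best_key = None
    for loc in registry:
        d = haversine_m(lat, lon, loc.latitude, loc.longitude)
        if d <= loc.radius_m:
            key = (d, loc.label)
            if best_key is None or key < best_key:
                best, best_key = loc, key
    return best


# ---------------------------------------------------------------------------
# environment / heuristic rules
# ---------------------------------------------------------------------------

def detect_environment(
    gps_summary: Optional["GpsSummary"],
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> str:
    """``"outdoor"`` iff some fix in the window has quality >= threshold.

    Absence of GPS fixes is a valid state and maps to
    ``"indoor_or_unknown"`` (an indoor phone typically loses satellite lock
    rather than reporting a flagged weak fix).
    """
    if gps_summary is None or gps_summary.n_fixes == 0:
        return "indoor_or_unknown"
    if gps_summary.max_fix_quality >= quality_threshold:
        return "outdoor"
    return "indoor_or_unknown"


def heuristic_speed_override(
    mean_speed_kmh: float, threshold_kmh: float = SPEED_OVERRIDE_KMH
) -> bool:
    """True iff the windowed mean GPS speed is strictly over the threshold."""
    if mean_speed_kmh < 0:
        raise ValueError(f"negative speed {mean_speed_kmh}")
    return mean_speed_kmh > threshold_kmh


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarfConfig:
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
    speed_threshold_kmh: float = SPEED_OVERRIDE_KMH


@dataclass(frozen=True)
class Prediction:
    """Routed per-window prediction with a replayable decision trace."""

    label: ActivityLabel
    posteriors: Optional[tuple]  # tuple of PosteriorScore, None when NB skipped
    route: tuple
    heuristic_override: bool
    tie: bool = False


def _classify_area(
    models: Sequence[ClassModel], fv, area: str, trace: list
) -> tuple[str, tuple, bool]:
    candidates = area_candidates(area)
    available = {m.label for m in models}
    missing = [c for c in candidates if c not in available]
    if missing:
        raise ConfigError(
            f"routing to {area} requires models for {list(candidates)}; "
            f"missing {missing}"
        )
    trace.append("candidates:" + "|".join(candidates))
    result = classify(models, fv, candidates)
    trace.append(f"nb:{result.label}")
    return result.label, result.scores, result.tie


def route(
    fv: "FeatureVector",
    gps_summary: Optional["GpsSummary"],
    registry: Sequence[RegisteredLocation],
    models: Sequence[ClassModel],
    config: HarfConfig = HarfConfig(),
) -> Prediction:
    """Route one window through the hierarchical decision tree.

    Decision order: registered-location match on the window's last GPS fix
    (Type-2 match returns the venue's activity directly; home/office match
    classifies within that area); otherwise the outdoor candidate set is
    classified and, lastly, the speed heuristic may override the label with
    "Riding a car".  The trace lists every decision taken, in order.
    """
    trace: list = []
    loc = None
    if gps_summary is not None and gps_summary.n_fixes > 0:
        loc = match_location(gps_summary.last_lat, gps_summary.last_lon, registry)
        trace.append(f"location:{loc.label if loc else 'none'}")
    else:
        trace.append("location:no-fix")

    if loc is not None and loc.category == "type2":
        trace.append("branch:type2-shortcut")
        return Prediction(
            label=LABELS_BY_NAME[loc.label],
            posteriors=None,
            route=tuple(trace),
            heuristic_override=False,
        )

    if loc is not None:  # home or office
        area = "Home" if loc.category == "home" else "Office"
        trace.append(f"branch:indoor-{loc.category}")
        name, scores, tie = _classify_area(models, fv, area, trace)
        return Prediction(
            label=LABELS_BY_NAME[name],
            posteriors=scores,
            route=tuple(trace),
            heuristic_override=False,
            tie=tie,
        )

    env = detect_environment(gps_summary, config.quality_threshold)
    trace.append(f"environment:{env}")
    trace.append("branch:outdoor")
    name, scores, tie = _classify_area(models, fv, "Outdoor", trace)
    override = False
    if gps_summary is not None and gps_summary.n_fixes > 0:
        if heuristic_speed_override(
            gps_summary.mean_speed_kmh, config.speed_threshold_kmh
        ):
            override = True
            name = RIDING_A_CAR.name
            trace.append("override:riding-a-car")
    return Prediction(
        label=LABELS_BY_NAME[name],
        posteriors=scores,
        route=tuple(trace),
        heuristic_override=override,
        tie=tie,
    )
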
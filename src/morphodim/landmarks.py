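"""Landmark I/O: TPS-dialect files, configurations, and the landmark scheme.

A facial configuration is an ordered set of 71 two-dimensional points:
37 fixed anatomical landmarks (glabella, nasion, subnasale, stomion,
gnathion, zygion, gonion, cheilion, alare, the eye-fissure and eyelid
points, eyebrow anchors, ...) plus 34 semilandmarks covering the facial
outline, the eyebrows and the lip vermillion borders.  Raw digitized
coordinates are image pixels with y pointing down; on read they are
multiplied by the record's physical scale (cm per raw unit) and the y axis
is flipped so that all downstream geometry uses the mathematical
orientation (y up: a higher forehead has a larger y).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LandmarkConfiguration",
    "LandmarkScheme",
    "SchemaError",
    "read_tps",
    "write_tps",
    "load_scheme",
    "save_scheme",
    "default_scheme",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A landmark file or scheme violates its structural contract."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One digitized face: ordered (x, y) coordinates in cm, y up."""

    subject_id: str
    coords: np.ndarray  # (n_points, 2), cm
    scale_factor: float = 1.0  # cm per raw digitizing unit
    digitized_by: str | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise SchemaError(
                f"{self.subject_id!r}: coords must be (n, 2), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise SchemaError(f"{self.subject_id!r}: non-finite coordinates")
        if not self.scale_factor > 0:
            raise SchemaError(f"{self.subject_id!r}: scale_factor must be > 0")
        object.__setattr__(self, "coords", coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass(frozen=True)
class LandmarkScheme:
    """Names, roles, bilateral pairing and slider topology of a landmark set.

    ``sliders`` maps each semilandmark index to the ``(prev, self, next)``
    triple whose chord defines its sliding tangent.
    """

    names: tuple[str, ...]
    roles: tuple[str, ...]  # "fixed" | "semilandmark"
    bilateral_pairs: tuple[tuple[int, int], ...]  # (left, right)
    midline: tuple[int, ...]
    sliders: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        if len(self.roles) != n:
            raise SchemaError("roles length must match names length")
        if len(set(self.names)) != n:
            raise SchemaError("duplicate landmark names")
        bad = [r for r in self.roles if r not in ("fixed", "semilandmark")]
        if bad:
            raise SchemaError(f"unknown roles: {bad}")
        seen: dict[int, str] = {}
        for i in self.midline:
            if i in seen:
                raise SchemaError(f"index {i} appears twice in midline/pairs")
            seen[i] = "midline"
        for left, right in self.bilateral_pairs:
            for i in (left, right):
                if i in seen:
                    raise SchemaError(f"index {i} appears twice in midline/pairs")
                seen[i] = "pair"
        if set(seen) != set(range(n)):
            missing = sorted(set(range(n)) - set(seen))
            raise SchemaError(f"indices not covered by midline/pairs: {missing}")
        semis = set(self.semilandmarks)
        if set(self.sliders) != semis:
            raise SchemaError("sliders must be given for exactly the semilandmarks")
        for j, (a, b, c) in self.sliders.items():
            if b != j or len({a, b, c}) != 3:
                raise SchemaError(f"slider triple for {j} must be (prev, {j}, next)")
            if not all(0 <= k < n for k in (a, b, c)):
                raise SchemaError(f"slider triple for {j} out of range")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_fixed(self) -> int:
        return sum(r == "fixed" for r in self.roles)

    @property
    def semilandmarks(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.roles) if r == "semilandmark")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def validate(self, config: LandmarkConfiguration) -> None:
        if config.n_points != len(self):
            raise SchemaError(
                f"{config.subject_id!r}: expected {len(self)} points, "
                f"got {config.n_points}"
            )


# --- TPS dialect -----------------------------------------------------------

_KNOWN_KEYS = {"LM", "ID", "IMAGE", "SCALE", "CURVES", "POINTS"}


def read_tps(
    path: str | Path,
    scheme: LandmarkScheme | None = None,
    fallback_scale: float | None = None,
) -> list[LandmarkConfiguration]:
    """Read a tpsDig-dialect landmark file.

    Each record is ``LM=<n>`` followed by *n* whitespace-separated ``x y``
    lines, then optional ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.  Unknown
    keys are ignored with a warning.  Coordinates are multiplied by SCALE
    and the y axis is flipped to the mathematical (up-positive) orientation.
    A missing SCALE is an error unless ``fallback_scale`` is given.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[dict] = []
    current: dict | None = None
    points_left = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if "=" in line and points_left == 0:
            key, _, value = line.partition("=")
            key = key.strip().upper()
            if key == "LM":
                current = {"points": [], "lineno": lineno}
                records.append(current)
                current["lm"] = int(value)
                points_left = current["lm"]
            elif current is None:
                raise SchemaError(f"{path}:{lineno}: data before first LM= record")
            elif key in _KNOWN_KEYS:
                current[key.lower()] = value.strip()
            else:
                logger.warning("%s:%d: ignoring unknown TPS key %r", path, lineno, key)
        else:
            if current is None or points_left == 0:
                raise SchemaError(f"{path}:{lineno}: unexpected coordinate line")
            x, y = line.split()[:2]
            current["points"].append((float(x), float(y)))
            points_left -= 1
    if points_left != 0:
        raise SchemaError(f"{path}: last record truncated ({points_left} points missing)")

    configs: list[LandmarkConfiguration] = []
    for k, rec in enumerate(records):
        subject_id = rec.get("id") or rec.get("image") or f"record_{k}"
        if len(rec["points"]) != rec["lm"]:
            raise SchemaError(
                f"{path}: record {subject_id!r} declares LM={rec['lm']} but has "
                f"{len(rec['points'])} points"
            )
        if scheme is not None and rec["lm"] != len(scheme):
            raise SchemaError(
                f"{path}: record {subject_id!r} has {rec['lm']} landmarks, "
                f"scheme requires {len(scheme)}"
            )
        if "scale" in rec:
            scale = float(rec["scale"])
        elif fallback_scale is not None:
            scale = float(fallback_scale)
            logger.warning(
                "%s: record %r has no SCALE; using fallback %g", path, subject_id, scale
            )
        else:
            raise SchemaError(
                f"{path}: record {subject_id!r} has no SCALE= and no fallback "
                "scale was supplied"
            )
        pts = np.asarray(rec["points"], dtype=float) * scale
        pts[:, 1] *= -1.0  # image y-down -> mathematical y-up
        configs.append(
            LandmarkConfiguration(subject_id=subject_id, coords=pts, scale_factor=scale)
        )
    return configs


def write_tps(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations in the dialect read by :func:`read_tps` (lossless)."""
    path = Path(path)
    chunks: list[str] = []
    for cfg in configs:
        raw = cfg.coords / cfg.scale_factor
        lines = [f"LM={cfg.n_points}"]
        for x, y in raw:
            lines.append(f"{x:.10g} {-y:.10g}")
        lines.append(f"ID={cfg.subject_id}")
        lines.append(f"SCALE={cfg.scale_factor:.10g}")
        chunks.append("\n".join(lines))
    path.write_text("\n".join(chunks) + "\n")


# --- scheme config files ---------------------------------------------------


def load_scheme(path: str | Path) -> LandmarkScheme:
    """Load a landmark scheme from its YAML description (names resolved)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        entries = doc["landmarks"]
        names = tuple(e["name"] for e in entries)
        roles = tuple(e["role"] for e in entries)
        idx = {name: i for i, name in enumerate(names)}
        pairs = tuple((idx[l], idx[r]) for l, r in doc["bilateral_pairs"])
        midline = tuple(idx[m] for m in doc["midline"])
        sliders = {
            idx[s]: (idx[a], idx[s], idx[c])
            for s, (a, _, c) in ((k, v) for k, v in doc.get("sliders", {}).items())
        }
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed scheme file ({exc})") from exc
    return LandmarkScheme(
        names=names, roles=roles, bilateral_pairs=pairs, midline=midline, sliders=sliders
    )


def save_scheme(scheme: LandmarkScheme, path: str | Path) -> None:
    doc = {
        "landmarks": [
            {"name": n, "role": r} for n, r in zip(scheme.names, scheme.roles)
        ],
        "bilateral_pairs": [
            [scheme.names[l], scheme.names[r]] for l, r in scheme.bilateral_pairs
        ],
        "midline": [scheme.names[i] for i in scheme.midline],
        "sliders": {
            scheme.names[j]: [scheme.names[a], scheme.names[j], scheme.names[c]]
            for j, (a, _, c) in sorted(scheme.sliders.items())
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_scheme() -> LandmarkScheme:
    """The bundled 71-point facial scheme (37 fixed + 34 semilandmarks)."""
    ref = resources.files("morphodim.data").joinpath("default_scheme.yaml")
    with resources.as_file(ref) as p:
        return load_scheme(p)
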
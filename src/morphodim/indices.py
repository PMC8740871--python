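"""Classical facial indices from landmark coordinates.

Twelve dimensionless ratios commonly used in studies of facial sexual
dimorphism, computed from named landmarks of a configuration:

====================  =====================================
upper_fwhr_n_sto      |Zy-Zy| / |N-Sto|
upper_fwhr_gl_sto     |Zy-Zy| / |Gl-Sto|
upper_fwhr_n_ls       |Zy-Zy| / |N-Ls|
upper_fwhr_gl_ls      |Zy-Zy| / |Gl-Ls|
total_fwhr            |Zy-Zy| / |N-Gn|
lower_fwhr            |Zy-Zy| / |Sn-Gn|
cheekbone_prominence  |Zy-Zy| / |Go-Go|
mandibular_index      |Go-Go| / |Sto-Gn|
nasal_index           |Al-Al| / |N-Sn|
mouth_shape           |Ls-Li| / |Ch-Ch|
mouth_face_index      |Ch-Ch| / |Zy-Zy|
eye_hw_mean           mean of |Ps-Pi| / |Ex-En|, left and right
====================  =====================================

All distances are Euclidean point distances (heights are *not* axis
projections), so every index is invariant under rotation, translation and
uniform scaling of the configuration.  Glabella and nasion fall back to
their defining midpoints (between the medial eyebrow anchors and between
the upper-eyelid points) when a scheme does not digitize them directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration, LandmarkScheme

__all__ = ["FacialIndexSet", "INDEX_NAMES", "compute_indices", "index_table"]

INDEX_NAMES = (
    "upper_fwhr_n_sto",
    "upper_fwhr_gl_sto",
    "upper_fwhr_n_ls",
    "upper_fwhr_gl_ls",
    "total_fwhr",
    "lower_fwhr",
    "cheekbone_prominence",
    "mandibular_index",
    "nasal_index",
    "mouth_shape",
    "mouth_face_index",
    "eye_hw_mean",
)


@dataclass(frozen=True)
class FacialIndexSet:
    upper_fwhr_n_sto: float
    upper_fwhr_gl_sto: float
    upper_fwhr_n_ls: float
    upper_fwhr_gl_ls: float
    total_fwhr: float
    lower_fwhr: float
    cheekbone_prominence: float
    mandibular_index: float
    nasal_index: float
    mouth_shape: float
    mouth_face_index: float
    eye_hw_mean: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _point(coords: np.ndarray, scheme: LandmarkScheme, name: str) -> np.ndarray:
    """A named landmark, with midpoint fallbacks for derived points."""
    if name in scheme.names:
        return coords[scheme.index(name)]
    if name == "Gl":  # midpoint between the medial eyebrow anchors
        return (_point(coords, scheme, "EbM_l") + _point(coords, scheme, "EbM_r")) / 2
    if name == "N":  # midpoint between the highest upper-eyelid points
        return (_point(coords, scheme, "Ps_l") + _point(coords, scheme, "Ps_r")) / 2
    raise KeyError(f"landmark {name!r} not in scheme and no derivation is defined")


def _dist(coords, scheme, a: str, b: str) -> float:
    return float(np.linalg.norm(_point(coords, scheme, a) - _point(coords, scheme, b)))


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0.0:
        warnings.warn(f"zero denominator for index {name}; returning NaN")
        return float("nan")
    return num / den


def compute_indices(config, scheme: LandmarkScheme) -> FacialIndexSet:
    """All 12 facial indices of one configuration."""
    coords = (
        config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config)
    )
    if coords.shape[0] != len(scheme):
        raise ValueError(
            f"configuration has {coords.shape[0]} points, scheme {len(scheme)}"
        )
    zy = _dist(coords, scheme, "Zy_l", "Zy_r")
    go = _dist(coords, scheme, "Go_l", "Go_r")
    ch = _dist(coords, scheme, "Ch_l", "Ch_r")
    al = _dist(coords, scheme, "Al_l", "Al_r")
    eye_l = _ratio(
        _dist(coords, scheme, "Ps_l", "Pi_l"),
        _dist(coords, scheme, "Ex_l", "En_l"),
        "eye_hw_left",
    )
    eye_r = _ratio(
        _dist(coords, scheme, "Ps_r", "Pi_r"),
        _dist(coords, scheme, "Ex_r", "En_r"),
        "eye_hw_right",
    )
    values = {
        "upper_fwhr_n_sto": _ratio(zy, _dist(coords, scheme, "N", "Sto"), "upper_fwhr_n_sto"),
        "upper_fwhr_gl_sto": _ratio(zy, _dist(coords, scheme, "Gl", "Sto"), "upper_fwhr_gl_sto"),
        "upper_fwhr_n_ls": _ratio(zy, _dist(coords, scheme, "N", "Ls"), "upper_fwhr_n_ls"),
        "upper_fwhr_gl_ls": _ratio(zy, _dist(coords, scheme, "Gl", "Ls"), "upper_fwhr_gl_ls"),
        "total_fwhr": _ratio(zy, _dist(coords, scheme, "N", "Gn"), "total_fwhr"),
        "lower_fwhr": _ratio(zy, _dist(coords, scheme, "Sn", "Gn"), "lower_fwhr"),
        "cheekbone_prominence": _ratio(zy, go, "cheekbone_prominence"),
        "mandibular_index": _ratio(go, _dist(coords, scheme, "Sto", "Gn"), "mandibular_index"),
        "nasal_index": _ratio(al, _dist(coords, scheme, "N", "Sn"), "nasal_index"),
        "mouth_shape": _ratio(_dist(coords, scheme, "Ls", "Li"), ch, "mouth_shape"),
        "mouth_face_index": _ratio(ch, zy, "mouth_face_index"),
        "eye_hw_mean": (eye_l + eye_r) / 2.0,
    }
    return FacialIndexSet(**values)


def index_table(
    configs,
    scheme: LandmarkScheme,
    subjects: pd.DataFrame | None = None,
    id_column: str = "subject_id",
) -> pd.DataFrame:
    """Tidy per-subject table of the 12 indices, joined with subject data.

    Subjects present in ``subjects`` but without a configuration (or vice
    versa) are listed in a warning and excluded from the join.
    """
    rows = []
    for i, cfg in enumerate(configs):
        sid = cfg.subject_id if isinstance(cfg, LandmarkConfiguration) else f"config_{i}"
        rows.append({id_column: sid, **compute_indices(cfg, scheme).as_dict()})
    table = pd.DataFrame(rows)
    if subjects is None:
        return table
    missing_meta = sorted(set(table[id_column]) - set(subjects[id_column]))
    missing_conf = sorted(set(subjects[id_column]) - set(table[id_column]))
    if missing_meta or missing_conf:
        warnings.warn(
            f"unmatched subjects excluded: no metadata for {missing_meta}, "
            f"no configuration for {missing_conf}"
        )
    return table.merge(subjects, on=id_column, how="inner")
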
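"""Network-level spatial decoding of statistic maps.

Given a partition of the voxel grid into labeled networks (e.g., a
7-network cortical parcellation, or a finer 17-network variant with
left/right subnetworks), this module computes: the spatial similarity
profile of a map with each network indicator (the quantity shown as
wedge radii in wedge plots); paired subnetwork contrasts of z-scored
subject-level effect maps; the octant classification of voxels by their
joint (Social, CS) mediation weights with per-octant sum of squared
distances from the origin; and top-k term decoding against a stack of
named meta-analytic maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multilevel import GroupEffect, one_sample_group

__all__ = [
    "NetworkPartition",
    "network_similarity",
    "subnetwork_contrast",
    "octant_classify",
    "octant_summary",
    "term_decode",
]


@dataclass(frozen=True)
class NetworkPartition:
    """Integer label per in-mask voxel; 0 means unassigned.

    ``names`` maps label id -> network name; every named label must be
    present in the image.
    """

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self):
        labels = np.asarray(self.labels, int).ravel()
        object.__setattr__(self, "labels", labels)
        present = set(np.unique(labels)) - {0}
        missing = set(self.names) - present - {0}
        if missing:
            raise ValueError(f"named labels absent from image: "
                             f"{sorted(missing)}")

    def indicator(self, label: int) -> np.ndarray:
        return (self.labels == label).astype(float)


def network_similarity(
    values: np.ndarray,
    partition: NetworkPartition,
) -> pd.DataFrame:
    """Pearson r of a map with each network's binary indicator.

    ``values`` should be the map's in-mask voxel values — for a
    thresholded map, the signed effects zeroed outside surviving tiers
    (see :meth:`ThresholdedMap.display_values`).  The wedge-plot radius
    convention is radius proportional to r (negative r rendered as zero
    radius with the sign reported) and area proportional to r^2.
    """
    values = np.asarray(values, float).ravel()
    if len(values) != len(partition.labels):
        raise ValueError("map and partition are not co-registered")
    rows = []
    const = values.std() == 0
    if const:
        warnings.warn("constant map: similarity undefined", stacklevel=2)
    for label, name in sorted(partition.names.items()):
        if label == 0:
            continue
        ind = partition.indicator(label)
        if const or ind.std() == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(values, ind)[0])
        rows.append({"network": name, "label": label, "r": r,
                     "wedge_radius": max(r, 0.0) if np.isfinite(r) else 0.0})
    return pd.DataFrame(rows)


def subnetwork_contrast(
    social_maps: np.ndarray,
    cs_maps: np.ndarray,
    partition: NetworkPartition,
    labels: list[int] | None = None,
) -> dict[str, GroupEffect]:
    """Paired Social-vs-CS contrast of mean activation per subnetwork.

    Each subject's unthresholded effect map is z-scored across in-mask
    voxels (so the contrast is invariant to per-subject offset and
    scale), averaged within each subnetwork, and the Social - CS
    difference is tested with a paired t-test.
    """
    social_maps = np.atleast_2d(np.asarray(social_maps, float))
    cs_maps = np.atleast_2d(np.asarray(cs_maps, float))
    if social_maps.shape != cs_maps.shape:
        raise ValueError("map stacks must have matching shape")
    if social_maps.shape[1] != len(partition.labels):
        raise ValueError("maps and partition are not co-registered")

    def _z(m):
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        return (m - mu) / sd

    zs, zc = _z(social_maps), _z(cs_maps)
    out: dict[str, GroupEffect] = {}
    for label, name in sorted(partition.names.items()):
        if label == 0 or (labels is not None and label not in labels):
            continue
        sel = partition.labels == label
        if not sel.any():
            warnings.warn(f"subnetwork {name!r} empty in mask; skipped",
                          stacklevel=2)
            continue
        diff = zs[:, sel].mean(axis=1) - zc[:, sel].mean(axis=1)
        out[name] = one_sample_group(diff, f"Social - CS in {name}")
    return out


# --------------------------------------------------------------------------
# octants
# --------------------------------------------------------------------------

#: octant id per 45-degree sector index, sectors counted counterclockwise
#: from the sector centered on the +x axis.  The numbering runs clockwise
#: from the +y axis: octant 1 is centered at 90 deg (uniquely positive CS
#: mediation), 2 at 45 deg (shared positive), 3 at 0 deg (uniquely
#: positive Social), then 4..8 continuing clockwise.
_SECTOR_TO_OCTANT = np.array([3, 2, 1, 8, 7, 6, 5, 4])


def octant_classify(social: np.ndarray, cs: np.ndarray) -> np.ndarray:
    """Octant (1..8) of each (Social, CS) mediation-weight pair.

    The plane (x = Social effect, y = CS effect) is divided into eight
    45-degree sectors with boundaries at odd multiples of 22.5 degrees;
    sectors are half-open (a boundary angle belongs to the sector it
    opens), so classification is total and deterministic.  The origin
    (0, 0) maps to 0 ("none").
    """
    x = np.asarray(social, float)
    y = np.asarray(cs, float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite mediation weights")
    theta = np.degrees(np.arctan2(y, x))
    sector = np.floor(((theta + 22.5) % 360.0) / 45.0).astype(int) % 8
    out = _SECTOR_TO_OCTANT[sector]
    return np.where((x == 0) & (y == 0), 0, out)


def octant_summary(
    social_map: np.ndarray,
    cs_map: np.ndarray,
    partition: NetworkPartition | None = None,
) -> pd.DataFrame:
    """Per-network octant counts and sum of squared distances.

    For every network (or the whole mask when ``partition`` is None),
    classifies each voxel's unthresholded (Social, CS) mediation weights
    into octants and accumulates the voxel count and
    SSD = sum(x^2 + y^2) per octant; the octant with the largest SSD is
    flagged as the peak.
    """
    x = np.asarray(social_map, float).ravel()
    y = np.asarray(cs_map, float).ravel()
    if x.shape != y.shape:
        raise ValueError("mediation maps must be on the same grid")
    if partition is not None and len(x) != len(partition.labels):
        raise ValueError("maps and partition are not co-registered")
    octants = octant_classify(x, y)
    d2 = x ** 2 + y ** 2

    groups = ([("whole", np.ones(len(x), bool))] if partition is None else
              [(name, partition.labels == label)
               for label, name in sorted(partition.names.items())
               if label != 0])
    rows = []
    for name, sel in groups:
        ssd_per = np.zeros(8)
        for k in range(1, 9):
            in_oct = sel & (octants == k)
            ssd = float(d2[in_oct].sum())
            ssd_per[k - 1] = ssd
            rows.append({"network": name, "octant": k,
                         "count": int(in_oct.sum()), "ssd": ssd})
        peak = int(np.argmax(ssd_per)) + 1 if ssd_per.any() else 0
        for r in rows[-8:]:
            r["peak"] = r["octant"] == peak
    return pd.DataFrame(rows)


def term_decode(
    values: np.ndarray,
    term_maps: dict[str, np.ndarray],
    k: int = 10,
) -> pd.DataFrame:
    """Top-k most positively correlated terms for a map.

    Computes Pearson r between the map and each named term map, keeps
    the best r per distinct term (lowercased), and returns the top ``k``
    in descending r.
    """
    values = np.asarray(values, float).ravel()
    best: dict[str, float] = {}
    for name, tmap in term_maps.items():
        tmap = np.asarray(tmap, float).ravel()
        if tmap.shape != values.shape:
            raise ValueError(f"term map {name!r} is not co-registered")
        if values.std() == 0 or tmap.std() == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(values, tmap)[0])
        key = name.lower()
        if key not in best or (np.isfinite(r) and r > best[key]):
            best[key] = r
    if k > len(best):
        warnings.warn(f"requested top {k} of {len(best)} terms; "
                      "returning all", stacklevel=2)
    ranked = sorted(best.items(),
                    key=lambda kv: (-kv[1] if np.isfinite(kv[1]) else np.inf))
    return pd.DataFrame(ranked[:k], columns=["term", "r"])
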
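"""Region-of-interest atlas for the fetal brain at a reference gestational week.

The atlas is a flat table of labelled regions: an integer id, a lobe label
(six-value scheme: frontal, parietal, occipital, temporal, subcortical,
limbic), a hemisphere (L/R/midline) and a 3-D coordinate in millimetres at
the 37-week reference brain. Coordinates for younger brains are obtained by
isotropic rescaling under a linear brain-volume growth model
(77 cm3 at gestational week 21 to 469.1 cm3 at week 37).

The default synthetic atlas places mirrored left/right region pairs on an
ellipsoidal cortical shell with interior subcortical points; it is geometry
plumbing for the simulator, not an anatomical claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LOBES",
    "RoiAtlas",
    "brain_volume_cm3",
    "make_default_atlas",
    "scale_atlas",
]

LOBES = ("frontal", "parietal", "occipital", "temporal", "subcortical", "limbic")

#: Linear brain-volume growth anchors (cm3 at gestational weeks 21 and 37).
V_GW21, V_GW37 = 77.0, 469.1
GA_MIN, GA_MAX, GA_REF = 21.0, 38.0, 37.0

# Ellipsoid semi-axes in mm at the 37-week reference: x = left-right,
# y = posterior-anterior, z = inferior-superior. Volume ~ 475 cm3.
_SEMI_AXES = np.array([45.0, 60.0, 42.0])

# Share of mirrored region pairs per lobe for the default atlas.
_LOBE_PROPS = {
    "frontal": 0.26,
    "parietal": 0.17,
    "temporal": 0.20,
    "occipital": 0.14,
    "subcortical": 0.14,
    "limbic": 0.09,
}

# Angular sectors (azimuth from +y toward +x, elevation), degrees, plus a
# radial factor: where each lobe's shell points are drawn.
_LOBE_SECTORS = {
    "frontal": ((5.0, 60.0), (0.0, 55.0), 1.0),
    "parietal": ((60.0, 140.0), (40.0, 75.0), 1.0),
    "temporal": ((50.0, 130.0), (-50.0, -10.0), 1.0),
    "occipital": ((140.0, 175.0), (-10.0, 40.0), 1.0),
    "limbic": ((30.0, 150.0), (-10.0, 50.0), 0.55),
}


@dataclass(frozen=True)
class RoiAtlas:
    """Immutable region table; ``coord_ref`` holds mm coordinates at week 37."""

    region_id: np.ndarray
    name: tuple
    lobe: np.ndarray
    hemisphere: np.ndarray
    coord_ref: np.ndarray

    def __post_init__(self):
        rid = np.asarray(self.region_id)
        if rid.size != len(set(rid.tolist())) or not np.array_equal(rid, np.arange(rid.size)):
            raise ValueError("region_ids must be unique and contiguous from 0")
        if set(np.unique(self.lobe)) - set(LOBES):
            raise ValueError(f"unknown lobe label; allowed: {LOBES}")
        if np.asarray(self.coord_ref).shape != (rid.size, 3):
            raise ValueError("coord_ref must be (n_regions, 3)")

    @property
    def n_regions(self) -> int:
        return int(np.asarray(self.region_id).size)

    def lobe_indices(self, lobe: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.lobe) == lobe)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.asarray(self.region_id),
                "name": list(self.name),
                "lobe": np.asarray(self.lobe),
                "hemisphere": np.asarray(self.hemisphere),
                "x_mm": self.coord_ref[:, 0],
                "y_mm": self.coord_ref[:, 1],
                "z_mm": self.coord_ref[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RoiAtlas":
        return cls(
            region_id=df["region_id"].to_numpy(dtype=int),
            name=tuple(df["name"].astype(str)),
            lobe=df["lobe"].to_numpy(dtype=str),
            hemisphere=df["hemisphere"].to_numpy(dtype=str),
            coord_ref=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        )


def brain_volume_cm3(ga_weeks: float) -> float:
    """Linear brain-volume model anchored at 77 cm3 (week 21) and 469.1 cm3 (week 37)."""
    ga = float(ga_weeks)
    if not GA_MIN <= ga <= GA_MAX:
        raise ValueError(f"ga_weeks must lie in [{GA_MIN}, {GA_MAX}], got {ga}")
    return V_GW21 + (V_GW37 - V_GW21) * (ga - 21.0) / 16.0


def scale_atlas(atlas: RoiAtlas, ga_weeks: float) -> np.ndarray:
    """Region coordinates at ``ga_weeks``: isotropic cube-root volume rescaling.

    Returns an (n_regions, 3) array; the scale factor is
    ``(V(ga)/V(37))**(1/3)`` and equals 1 at the 37-week reference.
    """
    factor = (brain_volume_cm3(ga_weeks) / brain_volume_cm3(GA_REF)) ** (1.0 / 3.0)
    return atlas.coord_ref * factor


def _lobe_quota(n_pairs: int) -> dict:
    """Largest-remainder apportionment of mirrored pairs to lobes."""
    raw = {lb: n_pairs * p for lb, p in _LOBE_PROPS.items()}
    quota = {lb: int(np.floor(v)) for lb, v in raw.items()}
    left = n_pairs - sum(quota.values())
    order = sorted(_LOBE_PROPS, key=lambda lb: (-(raw[lb] - quota[lb]), lb))
    for lb in order[:left]:
        quota[lb] += 1
    return quota


def _shell_point(rng: np.random.Generator, sector) -> np.ndarray:
    (az_lo, az_hi), (el_lo, el_hi), radial = sector
    az = np.deg2rad(rng.uniform(az_lo, az_hi))
    el = np.deg2rad(rng.uniform(el_lo, el_hi))
    direction = np.array([np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)])
    return _SEMI_AXES * direction * radial


def make_default_atlas(n_regions: int = 70, seed: int = 0) -> RoiAtlas:
    """Synthetic mirrored-pair atlas with ``n_regions`` regions.

    Even counts give ``n_regions/2`` left/right pairs; an odd count adds one
    midline subcortical region. Deterministic for a given seed.
    """
    n_regions = int(n_regions)
    if n_regions < 8:
        raise ValueError(f"n_regions must be at least 8, got {n_regions}")
    rng = np.random.default_rng(seed)
    n_pairs = n_regions // 2
    quota = _lobe_quota(n_pairs)

    names, lobes, hemis, coords = [], [], [], []
    for lobe in LOBES:
        for k in range(quota.get(lobe, 0)):
            if lobe == "subcortical":
                point = np.array(
                    [rng.uniform(5.0, 15.0), rng.uniform(-20.0, 20.0), rng.uniform(-10.0, 8.0)]
                )
            else:
                point = _shell_point(rng, _LOBE_SECTORS[lobe])
                if lobe == "limbic":  # medial structures hug the midline
                    point[0] *= 0.35
            point[0] = abs(point[0])
            for hemi, sign in (("L", -1.0), ("R", 1.0)):
                names.append(f"{lobe}_{k}_{hemi}")
                lobes.append(lobe)
                hemis.append(hemi)
                coords.append(point * np.array([sign, 1.0, 1.0]))
    if n_regions % 2:
        names.append("subcortical_mid_M")
        lobes.append("subcortical")
        hemis.append("midline")
        coords.append(np.array([0.0, -5.0, 0.0]))

    return RoiAtlas(
        region_id=np.arange(n_regions),
        name=tuple(names),
        lobe=np.array(lobes),
        hemisphere=np.array(hemis),
        coord_ref=np.vstack(coords),
    )
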
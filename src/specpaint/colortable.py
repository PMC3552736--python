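"""Color-table model for pseudocolor metabolite maps.

A vendor snapshot encodes a normalized metabolite ratio u in [0, 1] as the
hue of an overlay pixel, with u = 1 (the per-slice maximum of Cho/NAA)
rendered pure red.  This module provides the forward map u -> hue -> RGB,
its exact inverse, and the per-slice / global calibration that turns
normalized values back into absolute Cho/NAA ratios.

The vendor's exact table is not published; the default is a linear hue ramp
from 240 deg (blue, u = 0) to 0 deg (red, u = 1).  Tables are pluggable:
any strictly monotone piecewise-linear set of (u, hue) control points works,
and can be loaded from YAML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import CsiGeometry

__all__ = [
    "ColorTable",
    "RatioMap",
    "default_table",
    "rgb_to_hsv",
    "hsv_to_rgb8",
    "hue_to_normalized",
    "calibrate_slice",
    "global_normalize",
    "OutOfGamutError",
    "CalibrationError",
]


class OutOfGamutError(ValueError):
    """A hue falls outside the color table's range beyond tolerance."""


class CalibrationError(ValueError):
    """Slice calibration is impossible (non-positive slice maximum)."""


# Hues in (360 - HUE_WRAP_TOL, 360) are treated as red at 0 deg: red sits on
# the circular wrap point and 8-bit rounding can land on either side of it.
HUE_WRAP_TOL = 10.0

# Slack (degrees) allowed when snapping a hue onto the table's range before
# declaring it out of gamut; covers quantization of the table endpoints.
HUE_SNAP_TOL = 1.5


@dataclass(frozen=True)
class ColorTable:
    """Invertible map between normalized value u in [0,1] and hue (degrees).

    ``control_points`` is an ordered list of (u, hue) pairs with u strictly
    increasing and hue strictly monotone; interpolation between points is
    linear.  u = 1.0 must map to red (hue 0).
    """

    control_points: tuple[tuple[float, float], ...] = ((0.0, 240.0), (1.0, 0.0))
    name: str = "linear-bgr"

    def __post_init__(self) -> None:
        pts = tuple((float(u), float(h)) for u, h in self.control_points)
        if len(pts) < 2:
            raise ValueError("a color table needs at least two control points")
        us = np.array([p[0] for p in pts])
        hs = np.array([p[1] for p in pts])
        if not np.all(np.diff(us) > 0):
            raise ValueError("control-point u values must be strictly increasing")
        dh = np.diff(hs)
        if not (np.all(dh > 0) or np.all(dh < 0)):
            raise ValueError("u -> hue must be strictly monotone (invertible)")
        if us[0] != 0.0 or us[-1] != 1.0:
            raise ValueError("control points must span u = 0 ... 1")
        if abs(hs[-1]) > 1e-9 and abs(hs[-1] - 360.0) > 1e-9:
            raise ValueError("u = 1.0 must map to red (hue 0)")
        object.__setattr__(self, "control_points", pts)

    @property
    def _u(self) -> np.ndarray:
        return np.array([p[0] for p in self.control_points])

    @property
    def _hue(self) -> np.ndarray:
        return np.array([p[1] for p in self.control_points])

    @property
    def hue_range(self) -> tuple[float, float]:
        h = self._hue
        return float(h.min()), float(h.max())

    def hue(self, u):
        """Forward map: normalized value(s) -> hue in degrees."""
        u = np.asarray(u, dtype=float)
        if np.any((u < -1e-12) | (u > 1 + 1e-12)):
            raise ValueError("normalized values must lie in [0, 1]")
        out = np.interp(np.clip(u, 0.0, 1.0), self._u, self._hue)
        return float(out) if out.ndim == 0 else out

    def normalized(self, hue):
        """Inverse map: hue in degrees -> normalized value(s) in [0, 1].

        Hues just past the red/360-degree wrap snap to 0; hues outside the
        table's span beyond a small tolerance raise :class:`OutOfGamutError`.
        NaN hues (achromatic pixels) propagate as NaN.
        """
        hue = np.asarray(hue, dtype=float)
        scalar = hue.ndim == 0
        h = np.atleast_1d(hue).astype(float).copy()
        finite = np.isfinite(h)
        # red sits on the circular wrap point: near-360 hues are red
        h[finite & (h >= 360.0 - HUE_WRAP_TOL) & (h < 360.0 + HUE_WRAP_TOL)] = 0.0
        lo, hi = self.hue_range
        bad = finite & ((h < lo - HUE_SNAP_TOL) | (h > hi + HUE_SNAP_TOL))
        if np.any(bad):
            raise OutOfGamutError(
                f"hue(s) outside table range [{lo}, {hi}] deg: "
                f"{np.unique(np.round(h[bad], 2))[:5]}"
            )
        h = np.clip(h, lo, hi)
        # np.interp needs ascending x; reverse a descending table.
        hu, uu = self._hue, self._u
        if hu[0] > hu[-1]:
            hu, uu = hu[::-1], uu[::-1]
        out = np.where(finite, np.interp(h, hu, uu), np.nan)
        return float(out[0]) if scalar else out.reshape(hue.shape)

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "name": self.name,
                    "control_points": [[float(u), float(h)] for u, h in self.control_points],
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "ColorTable":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            control_points=tuple((u, h) for u, h in data["control_points"]),
            name=data.get("name", "custom"),
        )


def default_table() -> ColorTable:
    """The package default: linear hue ramp 240 deg (u=0) -> 0 deg red (u=1)."""
    return ColorTable()


@dataclass
class RatioMap:
    """Cho/NAA ratios on the CSI grid, with acceptance flags and slice maxima.

    ``values`` is (n_slices, ny, nx); rejected voxels hold NaN, never zero
    (zero is a legal ratio).  ``slice_max`` holds the per-slice maximum of
    Cho/NAA among accepted voxels — in the clinical workflow these scalars
    come from the scanner console as a sidecar, not from the image.
    """

    values: np.ndarray
    accepted: np.ndarray
    slice_max: np.ndarray
    geometry: CsiGeometry = field(default_factory=CsiGeometry)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        self.slice_max = np.asarray(self.slice_max, dtype=float)
        if self.values.shape != self.accepted.shape:
            raise ValueError("values and accepted must have the same shape")
        if self.values.ndim != 3:
            raise ValueError("values must be (n_slices, ny, nx)")
        if self.slice_max.shape != (self.values.shape[0],):
            raise ValueError("one slice maximum per slice is required")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[self.accepted] < 0):
                raise ValueError("Cho/NAA ratios must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def global_max(self) -> float:
        return float(np.nanmax(self.slice_max))

    def recomputed_slice_maxima(self) -> np.ndarray:
        """Per-slice maxima recomputed from the stored values (consistency)."""
        out = np.full(self.n_slices, np.nan)
        for s in range(self.n_slices):
            vals = self.values[s][self.accepted[s]]
            if vals.size:
                out[s] = np.nanmax(vals)
        return out


# ---------------------------------------------------------------------------
# RGB <-> HSV
# ---------------------------------------------------------------------------

def rgb_to_hsv(r, g, b):
    """Standard hexcone RGB -> (hue deg, saturation, value) for 8-bit channels.

    Accepts scalars or broadcastable arrays in [0, 255].  Hue is undefined for
    achromatic pixels (saturation 0) and is returned as NaN there.
    """
    from skimage.color import rgb2hsv

    r, g, b = np.broadcast_arrays(
        np.asarray(r, dtype=float), np.asarray(g, dtype=float), np.asarray(b, dtype=float)
    )
    if np.any((r < 0) | (r > 255) | (g < 0) | (g > 255) | (b < 0) | (b > 255)):
        raise ValueError("channels must lie in [0, 255]")
    scalar = r.ndim == 0
    rgb = np.stack([np.atleast_1d(r), np.atleast_1d(g), np.atleast_1d(b)], axis=-1) / 255.0
    hsv = rgb2hsv(rgb)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    hue = np.where(sat == 0.0, np.nan, hue)
    if scalar:
        return float(hue[0]), float(sat[0]), float(val[0])
    shape = r.shape
    return hue.reshape(shape), sat.reshape(shape), val.reshape(shape)


def hsv_to_rgb8(hue_deg, sat=1.0, val=1.0) -> np.ndarray:
    """HSV -> 8-bit RGB (rounded), for rendering overlay pixels."""
    from skimage.color import hsv2rgb

    hue_deg, sat, val = np.broadcast_arrays(
        np.asarray(hue_deg, dtype=float), np.asarray(sat, dtype=float), np.asarray(val, dtype=float)
    )
    hsv = np.stack(
        [np.atleast_1d(hue_deg) / 360.0, np.atleast_1d(sat), np.atleast_1d(val)], axis=-1
    )
    rgb = hsv2rgb(hsv)
    out = np.round(rgb * 255.0).astype(np.uint8)
    if hue_deg.ndim == 0:
        return out[0]
    return out.reshape(hue_deg.shape + (3,))


def hue_to_normalized(hue, table: ColorTable):
    """Invert the table: hue in degrees -> normalized value u in [0, 1]."""
    return table.normalized(hue)


# ---------------------------------------------------------------------------
# Calibration / normalization
# ---------------------------------------------------------------------------

def calibrate_slice(u_map, slice_max: float):
    """Scale normalized values of one slice to absolute Cho/NAA.

    ratio = u * slice_max; the per-slice maximum is the value the scanner
    console reports for the red end of the color table.
    """
    if not np.isfinite(slice_max) or slice_max <= 0:
        raise CalibrationError(f"slice maximum must be positive, got {slice_max}")
    u_map = np.asarray(u_map, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((u_map < -1e-12) | (u_map > 1 + 1e-12)):
            raise ValueError("normalized values must lie in [0, 1]")
    out = u_map * float(slice_max)
    return float(out) if out.ndim == 0 else out


def global_normalize(
    u_maps: np.ndarray,
    slice_maxima,
    geometry: CsiGeometry | None = None,
    accepted: np.ndarray | None = None,
) -> RatioMap:
    """Place all slices on one absolute Cho/NAA scale.

    Each slice's normalized map is calibrated by its own console-reported
    maximum; the result is a single 3D RatioMap whose values are directly
    comparable across slices.  The global maximum (max over slice maxima) is
    exposed as ``RatioMap.global_max``; a rescaled-to-global-max view is
    available via ``RatioMap.values / global_max`` but the absolute scale is
    canonical.

    Voxels flagged as not accepted (or NaN in ``u_maps``) carry no value.
    """
    u_maps = np.asarray(u_maps, dtype=float)
    if u_maps.ndim != 3:
        raise ValueError("u_maps must be (n_slices, ny, nx)")
    slice_maxima = np.asarray(slice_maxima, dtype=float)
    n_slices = u_maps.shape[0]
    if slice_maxima.shape != (n_slices,):
        raise ValueError("exactly one maximum per slice is required")
    if geometry is None:
        geometry = CsiGeometry(
            matrix=(u_maps.shape[2], u_maps.shape[1]), n_slices=n_slices
        )
    if geometry.shape != u_maps.shape:
        raise ValueError(
            f"u_maps shape {u_maps.shape} does not match geometry {geometry.shape}"
        )
    if accepted is None:
        accepted = np.isfinite(u_maps)
    accepted = np.asarray(accepted, dtype=bool) & np.isfinite(u_maps)

    values = np.full(u_maps.shape, np.nan)
    for s in range(n_slices):
        if not accepted[s].any():
            continue
        if not np.isfinite(slice_maxima[s]) or slice_maxima[s] <= 0:
            raise CalibrationError(
                f"slice {s} has accepted voxels but no positive maximum"
            )
        values[s][accepted[s]] = calibrate_slice(
            u_maps[s][accepted[s]], slice_maxima[s]
        )
    empty = ~accepted.reshape(n_slices, -1).any(axis=1)
    if empty.any():
        warnings.warn(
            f"slices with no accepted voxels: {np.flatnonzero(empty).tolist()}",
            stacklevel=2,
        )
    return RatioMap(
        values=values, accepted=accepted, slice_max=slice_maxima, geometry=geometry
    )
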
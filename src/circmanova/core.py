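"""Angle conventions, transforms and basic circular summaries.

Angles are stored internally in radians on [0, 2*pi). Public constructors
accept degrees or radians via an explicit unit flag. Axial data (where theta
and theta + 180 deg are equivalent) are handled by the classical
angle-doubling transform; a sample records whether it has been doubled so
the transform cannot be applied twice by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

TWO_PI = 2.0 * np.pi

#: tolerance below which the mean direction of a sample is considered
#: undefined (the mean vector is indistinguishable from the origin)
UNDEFINED_DIRECTION_TOL = 1e-12


@dataclass(frozen=True)
class AngleSample:
    """A validated sample of circular observations.

    Parameters
    ----------
    angles
        Angles in radians, each reduced to [0, 2*pi).
    source_unit
        Unit the data arrived in ("degrees" or "radians"); provenance only.
    axial_doubled
        True if the angle-doubling transform for axial data has been applied.
    """

    angles: np.ndarray
    source_unit: str = "radians"
    axial_doubled: bool = False

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("angles must be a 1-d vector with n >= 1")
        if np.any((angles < 0.0) | (angles >= TWO_PI)):
            raise ValueError("angles must lie in [0, 2*pi)")
        if self.source_unit not in ("degrees", "radians"):
            raise ValueError(f"unknown source_unit {self.source_unit!r}")
        object.__setattr__(self, "angles", angles)

    @property
    def n(self) -> int:
        return self.angles.size

    def __len__(self) -> int:
        return self.n


def to_radians(values, unit: str = "radians") -> AngleSample:
    """Build an :class:`AngleSample` from raw angles in degrees or radians.

    Values are reduced modulo 360 deg / 2*pi into [0, 2*pi).  Non-finite
    entries are rejected with the index of the first offending value.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 0:
        values = values.reshape(1)
    bad = ~np.isfinite(values)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite angle at index {idx}: {values[idx]}")
    if unit == "degrees":
        rad = np.deg2rad(values)
    elif unit == "radians":
        rad = values
    else:
        raise ValueError(f"unknown unit {unit!r}; use 'degrees' or 'radians'")
    rad = np.mod(rad, TWO_PI)
    # mod can return 2*pi for tiny negative inputs due to rounding
    rad[rad >= TWO_PI] = 0.0
    return AngleSample(rad, source_unit=unit)


def axial_transform(sample: AngleSample) -> AngleSample:
    """Double angles modulo 2*pi, identifying theta with theta + pi.

    The standard preprocessing for axial data (undirected orientations such
    as body alignments), after which ordinary circular methods apply.
    """
    if sample.axial_doubled:
        raise ValueError("axial transform already applied to this sample")
    doubled = np.mod(2.0 * sample.angles, TWO_PI)
    return replace(sample, angles=doubled, axial_doubled=True)


@dataclass(frozen=True)
class EmbeddedResponse:
    """The n x 2 matrix of (cos theta, sin theta) used as MANOVA response."""

    Y: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("Y must be an n x 2 matrix")
        norms = np.hypot(Y[:, 0], Y[:, 1])
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("each (cos, sin) row must have unit norm")
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.Y.shape[0]


def embed(sample: AngleSample) -> EmbeddedResponse:
    """Map each angle to its unit vector (cos theta, sin theta)."""
    return EmbeddedResponse(
        np.column_stack([np.cos(sample.angles), np.sin(sample.angles)])
    )


def mean_resultant(sample: AngleSample) -> tuple[float, float | None]:
    """Mean resultant length rbar and mean direction of a sample.

    Returns ``(rbar, direction)`` with direction in [0, 2*pi), or
    ``(rbar, None)`` when rbar is numerically zero (antipodal cancellation
    leaves the direction undefined).
    """
    c = float(np.mean(np.cos(sample.angles)))
    s = float(np.mean(np.sin(sample.angles)))
    rbar = float(np.hypot(c, s))
    if rbar < UNDEFINED_DIRECTION_TOL:
        return rbar, None
    direction = float(np.mod(np.arctan2(s, c), TWO_PI))
    if direction >= TWO_PI:
        direction = 0.0
    return rbar, direction


def bin_angles(sample: AngleSample, width: float = 10.0) -> AngleSample:
    """Aggregate angles into bins of `width` degrees around the circle.

    Each angle is replaced by the nearest multiple of the bin width, with
    exact midpoints rounded to the upper bin (bins are half-open
    [k*w - w/2, k*w + w/2)).  Mimics field measurements recorded to the
    nearest 10 degrees.  Idempotent.
    """
    if width <= 0 or abs(360.0 / width - round(360.0 / width)) > 1e-9:
        raise ValueError(f"bin width {width} does not divide 360")
    deg = np.rad2deg(sample.angles)
    k = np.floor(deg / width + 0.5)
    centers = np.mod(k * width, 360.0)
    return replace(sample, angles=np.mod(np.deg2rad(centers), TWO_PI))
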
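"""Secondary-structure composition and the 4D structural target vector.

A domain's secondary structure is a per-residue string over four element
codes: ``H`` (alpha-helix), ``A`` (anti-parallel beta sheet), ``P``
(parallel beta sheet) and ``C`` (coil/other).  A sliding-window average
composition of the three structured elements summarises how each element
is distributed along the backbone, and four scalar scores derived from it
— (x, y1, y2, z) — place each structural class in its own orthant of a 4D
structural space:

* ``x``  separates all-alpha (x > 0) from all-beta (x < 0);
* ``y1`` separates all-alpha (y1 < 0) from mixed alpha-beta (y1 > 0);
* ``y2`` separates all-beta (y2 < 0) from mixed alpha-beta (y2 > 0);
* ``z``  separates alpha/beta (z > 0, parallel sheets) from alpha+beta
  (z < 0, anti-parallel sheets).

For training, each coordinate whose sign its class dictates is clamped to
at least a margin on the correct side; well-separated domains keep their
raw score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SS_CODES",
    "CLASSES",
    "DIMENSIONS",
    "REQUIRED_SIGNS",
    "TargetParams",
    "StructuralVector",
    "validate_ss",
    "window_composition",
    "base_scores",
    "make_target",
]

#: Secondary-structure element codes: helix, anti-parallel sheet,
#: parallel sheet, coil.
SS_CODES = "HAPC"

#: Canonical structural class labels, fixed order.
CLASSES = ("all-alpha", "all-beta", "alpha/beta", "alpha+beta")

#: The four structural-score dimensions, fixed order.
DIMENSIONS = ("x", "y1", "y2", "z")

#: Sign each class requires per dimension; 0 means the raw score is kept.
REQUIRED_SIGNS: dict[str, tuple[int, int, int, int]] = {
    "all-alpha": (+1, -1, +1, 0),
    "all-beta": (-1, +1, -1, 0),
    "alpha/beta": (0, +1, +1, +1),
    "alpha+beta": (0, +1, +1, -1),
}


@dataclass(frozen=True)
class TargetParams:
    """Constants of the structural-score construction.

    window
        Sliding-window length k0 for the element composition (residues);
        capped at the domain length.
    theta
        Sheet/helix content offset separating "all" classes from mixed
        alpha-beta in y1 and y2.
    delta
        Regulariser in the z denominator, keeps z finite for sheet-free
        domains.
    margin
        Minimum magnitude a class-required coordinate is clamped to.
    """

    window: int = 8
    theta: float = 0.1
    delta: float = 1e-6
    margin: float = 0.05


@dataclass(frozen=True)
class StructuralVector:
    """A point in the 4D structural space."""

    x: float
    y1: float
    y2: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y1, self.y2, self.z], dtype=float)


def validate_ss(ss: str) -> str:
    """Validate a secondary-structure string; returns it unchanged."""
    if not ss:
        raise ValueError("secondary-structure string is empty")
    bad = set(ss) - set(SS_CODES)
    if bad:
        raise ValueError(
            f"secondary-structure string contains invalid codes {sorted(bad)!r}; "
            f"allowed: {SS_CODES!r}"
        )
    return ss


def window_composition(ss: str, k: int) -> dict[str, float]:
    """Average composition of H/A/P over all length-``k`` windows.

    Walking a window of length ``k`` along the string, each window
    contributes its fractional content ``n_i/k`` of element ``i``; the
    result averages these fractions over all ``L - k + 1`` windows.  At
    ``k == L`` this reduces to the whole-sequence content of each element.

    Returns a mapping ``{"H": f_H, "A": f_A, "P": f_P}``.
    """
    validate_ss(ss)
    L = len(ss)
    if not 1 <= k <= L:
        raise ValueError(f"window length k={k} outside [1, {L}]")
    n_windows = L - k + 1
    out: dict[str, float] = {}
    for code in "HAP":
        ind = np.fromiter((c == code for c in ss), dtype=float, count=L)
        csum = np.concatenate(([0.0], np.cumsum(ind)))
        counts = csum[k:] - csum[:-k]  # per-window counts n_{i,t}
        out[code] = float(counts.sum() / (k * n_windows))
    return out


def base_scores(ss: str, params: TargetParams | None = None) -> StructuralVector:
    """Raw (unclamped) structural scores of a secondary-structure string."""
    params = params or TargetParams()
    validate_ss(ss)
    k = min(params.window, len(ss))
    comp = window_composition(ss, k)
    c_h, c_a, c_p = comp["H"], comp["A"], comp["P"]
    x = c_h - (c_a + c_p)
    y1 = (c_a + c_p) - params.theta
    y2 = c_h - params.theta
    z = (c_p - c_a) / (c_p + c_a + params.delta)
    return StructuralVector(x, y1, y2, z)


def _clamp(value: float, sign: int, margin: float) -> float:
    if sign == 0:
        return value
    if sign > 0:
        return value if value >= margin else margin
    return value if value <= -margin else -margin


def make_target(
    ss: str, class_label: str, params: TargetParams | None = None
) -> StructuralVector:
    """Training target vector for a domain of known structural class.

    Each coordinate whose sign the class requires is clamped to lie at
    least ``params.margin`` on the required side; coordinates the class
    leaves free, and coordinates already on the correct side, keep their
    raw score.  The clamp is idempotent.
    """
    params = params or TargetParams()
    if class_label not in REQUIRED_SIGNS:
        raise ValueError(
            f"unknown structural class {class_label!r}; expected one of {CLASSES}"
        )
    base = base_scores(ss, params)
    signs = REQUIRED_SIGNS[class_label]
    vals = [
        _clamp(v, s, params.margin) for v, s in zip(base.as_array(), signs)
    ]
    return StructuralVector(*vals)
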
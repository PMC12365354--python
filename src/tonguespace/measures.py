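"""The 16 tongue position / height / shape measures.

Eight position measures (K2_X..K7_X, HP_X, HV_X) and eight height/shape
measures (K5_Y..K7_Y, HP_Y, HV_Y, TCP, TC, MCI); their cross product gives
the 64 position x height/shape combinations evaluated downstream.

Knot-coordinate measures are read directly off the raw landmarks.  The
remaining measures are computed from a smoothed 100-point interpolation of
the 11 knots (natural cubic splines of x and y against cumulative chord
length, so the curve passes through every knot):

* HP — highest point: the contour point with maximal y (occlusal frame).
* HV — highest vertex: the contour point farthest (perpendicular distance)
  from the chord joining vallecula (A, knot 1) and tongue tip (B, knot 11).
  With D the foot of the perpendicular from HV onto AB, the triangle ratios
  are TCP = HVD/AB (apex height over chord) and TC = AD/DB (apex position
  along the chord).
* MCI — Modified Curvature Index: the integral of absolute curvature with
  respect to arc length, evaluated at equally spaced arc-length points; a
  dimensionless total-turning measure, invariant under rigid motion and
  uniform scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .io import (
    MEASURE_COLUMNS,
    METADATA_COLUMNS,
    Dataset,
    KnotContour,
)

logger = logging.getLogger(__name__)

POSITION_MEASURES = ("K2_X", "K3_X", "K4_X", "K5_X", "K6_X", "K7_X", "HP_X", "HV_X")
HEIGHT_SHAPE_MEASURES = ("K5_Y", "K6_Y", "K7_Y", "HP_Y", "HV_Y", "TCP", "TC", "MCI")

EPS_FLAT = 1e-6  # mm; below this apex height a contour counts as flat
_EPS_CHORD = 1e-6  # mm; degenerate vallecula-tip chord


@dataclass
class DenseContour:
    """An ordered dense polyline through a token's tongue surface."""

    points: np.ndarray
    source: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("DenseContour.points must be an (n, 2) array")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TriangleGeometry:
    """Chord-apex triangle of a contour: A = vallecula, B = tip, HV = apex."""

    A: np.ndarray
    B: np.ndarray
    HV: np.ndarray
    D: np.ndarray
    AB: float
    AD: float
    DB: float
    HVD: float
    hv_index: int


@dataclass
class MeasureRecord:
    """The 16 scalar measures for one token, plus its metadata key."""

    speaker_id: str
    token_id: str
    vowel: str
    repetition: int
    values: dict = field(default_factory=dict)
    degenerate: bool = False

    def as_row(self) -> dict:
        row = {
            "speaker": self.speaker_id,
            "token": self.token_id,
            "vowel": self.vowel,
            "repetition": self.repetition,
        }
        row.update(self.values)
        return row


def _chord_params(knots: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("coincident consecutive knots (zero-length chord segment)")
    return np.concatenate([[0.0], np.cumsum(seg)])


def densify(contour: KnotContour | np.ndarray, n: int = 100) -> DenseContour:
    """Interpolate the 11 knots to an ``n``-point smooth contour.

    x(t) and y(t) are natural cubic splines against the shared cumulative
    chord-length parameter t.  The evaluation grid always contains the 11
    knot parameters, so every original knot is reproduced exactly; the
    remaining n - 11 points are spread over the inter-knot segments in
    proportion to their chord length (largest-remainder rounding).
    """
    if isinstance(contour, KnotContour):
        knots = contour.knots
        source = contour.token_id
    else:
        knots = np.asarray(contour, dtype=float)
        source = None
    if n < knots.shape[0]:
        raise ValueError(f"n={n} must be at least the number of knots ({knots.shape[0]})")
    t = _chord_params(knots)
    cs_x = CubicSpline(t, knots[:, 0], bc_type="natural")
    cs_y = CubicSpline(t, knots[:, 1], bc_type="natural")

    n_extra = n - len(t)
    seg_len = np.diff(t)
    quota = n_extra * seg_len / seg_len.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder)[: n_extra - counts.sum()]:
        counts[i] += 1
    grid = [t[:1]]
    for i, c in enumerate(counts):
        interior = np.linspace(t[i], t[i + 1], c + 2)[1:]
        grid.append(interior)
    tt = np.concatenate(grid)
    assert len(tt) == n
    return DenseContour(points=np.c_[cs_x(tt), cs_y(tt)], source=source)


def highest_point(dense: DenseContour) -> np.ndarray:
    """The contour point with maximal y; ties go to the most posterior."""
    return dense.points[int(np.argmax(dense.points[:, 1]))]


def highest_vertex(dense: DenseContour) -> TriangleGeometry:
    """Find the contour point farthest from the vallecula-tip chord.

    Returns the full triangle geometry (A, B, HV, the foot of the
    perpendicular D, and the lengths AB, AD, DB, HVD).  All outputs are
    invariant under rigid motion of the contour, unlike the highest point.
    """
    pts = dense.points
    a, b = pts[0], pts[-1]
    chord = b - a
    ab = float(np.linalg.norm(chord))
    if ab < _EPS_CHORD:
        raise ValueError("degenerate contour: vallecula-tip chord is (near) zero")
    u = chord / ab
    rel = pts - a
    along = rel @ u                       # signed position of each point along AB
    perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    i = int(np.argmax(perp))
    hv = pts[i]
    d = a + along[i] * u
    return TriangleGeometry(
        A=a, B=b, HV=hv, D=d,
        AB=ab,
        AD=float(np.linalg.norm(d - a)),
        DB=float(np.linalg.norm(b - d)),
        HVD=float(perp[i]),
        hv_index=i,
    )


@dataclass
class CurvatureRatios:
    tcp: float
    tc: float
    degenerate: bool = False


def curvature_ratios(tri: TriangleGeometry, eps_flat: float = EPS_FLAT) -> CurvatureRatios:
    """TCP = HVD/AB and TC = AD/DB from the chord-apex triangle.

    A flat contour (apex height below ``eps_flat``) yields TCP = 0 and
    TC = NaN with the degeneracy flag set; an apex at the tongue tip
    (DB = 0) yields TC = +inf with the flag set.
    """
    if tri.AB <= 0:
        raise ValueError("triangle has zero chord length")
    if tri.HVD < eps_flat:
        return CurvatureRatios(tcp=0.0, tc=float("nan"), degenerate=True)
    tcp = tri.HVD / tri.AB
    if tri.DB == 0.0:
        return CurvatureRatios(tcp=tcp, tc=float("inf"), degenerate=True)
    return CurvatureRatios(tcp=tcp, tc=tri.AD / tri.DB, degenerate=False)


def mci(dense: DenseContour, n: int = 100) -> float:
    """Modified Curvature Index: integral of |curvature| over arc length.

    The contour is resampled at ``n`` points equally spaced in cumulative
    arc length (natural cubic splines of x and y against arc length), the
    derivatives estimated by central finite differences (one-sided at the
    ends), the signed curvature formed as
    (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2), and |curvature| integrated by the
    trapezoid rule.  The result is the total absolute turning in radians.
    """
    pts = dense.points
    if len(pts) < 5:
        raise ValueError("MCI needs at least 5 contour points")
    s = _chord_params(pts)
    cs_x = CubicSpline(s, pts[:, 0], bc_type="natural")
    cs_y = CubicSpline(s, pts[:, 1], bc_type="natural")
    u = np.linspace(0.0, s[-1], n)
    x, y = cs_x(u), cs_y(u)
    h = u[1] - u[0]
    xp = np.gradient(x, h, edge_order=1)
    yp = np.gradient(y, h, edge_order=1)
    xpp = np.gradient(xp, h, edge_order=1)
    ypp = np.gradient(yp, h, edge_order=1)
    kappa = (xp * ypp - yp * xpp) / (xp**2 + yp**2) ** 1.5
    return float(np.trapezoid(np.abs(kappa), u))


def extract_measures(
    contour: KnotContour,
    n_dense: int = 100,
    hp_knot_range: tuple[int, int] | None = None,
) -> MeasureRecord:
    """Compute all 16 measures for one (occlusal-rotated) token.

    Knot coordinates are taken from the raw landmarks; HP/HV/TCP/TC/MCI from
    the densified contour.  ``hp_knot_range`` optionally restricts the
    highest-point search to a knot-index window (1-based, inclusive), e.g.
    (5, 7) for a dorsum-only search; the default searches the whole contour.
    """
    if not contour.rotated:
        raise ValueError(f"token {contour.token_id!r}: contour must be occlusal-rotated")
    try:
        dense = densify(contour, n=n_dense)
        tri = highest_vertex(dense)
    except ValueError as exc:
        raise ValueError(f"token {contour.token_id!r}: {exc}") from exc
    ratios = curvature_ratios(tri)

    if hp_knot_range is None:
        hp = highest_point(dense)
    else:
        lo, hi = hp_knot_range
        t = _chord_params(contour.knots)
        # match by normalized arc fraction: knot t and dense chord length
        # differ slightly in scale but agree proportionally
        seg = _chord_params(dense.points)
        frac = seg / seg[-1]
        mask = (frac >= t[lo - 1] / t[-1] - 1e-12) & (frac <= t[hi - 1] / t[-1] + 1e-12)
        hp = highest_point(DenseContour(dense.points[mask]))

    k = contour.knots
    values = {
        "K2_X": k[1, 0], "K3_X": k[2, 0], "K4_X": k[3, 0],
        "K5_X": k[4, 0], "K6_X": k[5, 0], "K7_X": k[6, 0],
        "HP_X": hp[0], "HV_X": tri.HV[0],
        "K5_Y": k[4, 1], "K6_Y": k[5, 1], "K7_Y": k[6, 1],
        "HP_Y": hp[1], "HV_Y": tri.HV[1],
        "TCP": ratios.tcp, "TC": ratios.tc, "MCI": mci(dense),
    }
    return MeasureRecord(
        speaker_id=contour.speaker_id,
        token_id=contour.token_id,
        vowel=contour.vowel,
        repetition=contour.repetition,
        values=values,
        degenerate=ratios.degenerate,
    )


def extract_measures_table(
    dataset: Dataset,
    n_dense: int = 100,
    hp_knot_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Measure table (metadata + 16 columns) for a whole dataset."""
    records = [
        extract_measures(c, n_dense=n_dense, hp_knot_range=hp_knot_range)
        for c in dataset.contours
    ]
    n_degen = sum(r.degenerate for r in records)
    if n_degen:
        logger.info("extract_measures: %d degenerate (flat/tip-apex) tokens", n_degen)
    df = pd.DataFrame([r.as_row() for r in records])
    return df[list(METADATA_COLUMNS) + list(MEASURE_COLUMNS)]


class TongueMeasureExtractor(BaseEstimator, TransformerMixin):
    """Transformer from a landmark :class:`Dataset` to the 16-measure table.

    Parameters
    ----------
    n_dense : int
        Number of points in the smoothed interpolation (default 100).
    hp_knot_range : tuple of (int, int), optional
        Restrict the highest-point search to a knot-index window.
    name_aliases : dict, optional
        Output column renames, e.g. ``{"TCP": "TC", "TC": "TCP"}`` to adopt
        the alternative curvature-ratio naming; the math is unaffected.
    """

    def __init__(self, n_dense: int = 100, hp_knot_range=None, name_aliases=None):
        self.n_dense = n_dense
        self.hp_knot_range = hp_knot_range
        self.name_aliases = name_aliases

    def fit(self, X: Dataset, y=None):
        self.n_tokens_ = len(X)
        return self

    def transform(self, X: Dataset) -> pd.DataFrame:
        df = extract_measures_table(
            X, n_dense=self.n_dense, hp_knot_range=self.hp_knot_range
        )
        if self.name_aliases:
            df = df.rename(columns=self.name_aliases)
        return df
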
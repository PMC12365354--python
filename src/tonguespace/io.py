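"""Reading, validation and geometric normalization of tongue-landmark tables.

The atomic input is one vowel token's midsagittal tongue contour: 11 ordered
landmarks ("knots") on the tongue surface, posterior to anterior, in mm.
Knot 1 sits at the vallecula, knots 2-3 on the tongue root, knots 5-7 on the
tongue dorsum, and knot 11 on the tongue tip.  Coordinates are assumed to be
occlusal-plane rotated, so that after rotation x increases anteriorly and y
superiorly; the origin is arbitrary per speaker.

Two CSV dialects are supported:

* ``long`` (canonical): columns ``speaker, token, vowel, repetition, knot, x, y``
  with one row per knot, ``knot`` in 1..11.
* ``wide`` (AAA-style export): one row per token with columns
  ``x1..x11, y1..y11`` plus the same metadata.

Optional formant records (F1/F2 in Hz at the vowel midpoint) ride along in a
separate table keyed by (speaker, token).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

N_KNOTS = 11

#: canonical five-vowel label set (lax vowels in a b_d frame)
CANONICAL_VOWELS = ("bid", "bed", "bad", "bod", "bud")

#: the 16 measure column names, position measures first, then height/shape
MEASURE_COLUMNS = (
    "K2_X", "K3_X", "K4_X", "K5_X", "K6_X", "K7_X", "HP_X", "HV_X",
    "K5_Y", "K6_Y", "K7_Y", "HP_Y", "HV_Y", "TCP", "TC", "MCI",
)

METADATA_COLUMNS = ("speaker", "token", "vowel", "repetition")


class ContourValidationError(ValueError):
    """Raised when a landmark table fails structural validation."""


@dataclass
class KnotContour:
    """One token's 11 ordered tongue-surface landmarks with metadata.

    ``knots`` is an (11, 2) float array ordered posterior (vallecula) to
    anterior (tongue tip).  ``rotated`` records whether occlusal-plane
    rotation has been applied; all downstream measures require it.
    """

    speaker_id: str
    token_id: str
    vowel: str
    repetition: int
    knots: np.ndarray
    rotated: bool = True

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.shape != (N_KNOTS, 2):
            raise ContourValidationError(
                f"token {self.token_id!r}: expected {N_KNOTS} knots, "
                f"got array of shape {self.knots.shape}"
            )
        if not np.all(np.isfinite(self.knots)):
            raise ContourValidationError(
                f"token {self.token_id!r}: non-finite knot coordinate"
            )
        if int(self.repetition) < 1:
            raise ContourValidationError(
                f"token {self.token_id!r}: repetition must be a positive integer"
            )
        self.repetition = int(self.repetition)
        if self.rotated and np.any(np.diff(self.knots[:, 0]) <= 0):
            # ill-formed but not fatal: e.g. a curled tongue tip
            warnings.warn(
                f"token {self.token_id!r}: x is not strictly increasing "
                "posterior->anterior after occlusal rotation",
                stacklevel=2,
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.speaker_id, self.token_id)


@dataclass
class FormantRecord:
    """Vowel-midpoint F1/F2 for one token, in Hz."""

    speaker_id: str
    token_id: str
    f1_hz: float
    f2_hz: float

    def __post_init__(self) -> None:
        if not (self.f1_hz > 0):
            raise ContourValidationError(
                f"token {self.token_id!r}: F1 must be positive"
            )
        if not (self.f2_hz > self.f1_hz):
            raise ContourValidationError(
                f"token {self.token_id!r}: F2 must exceed F1"
            )


@dataclass
class Dataset:
    """A validated collection of contours plus optional formants."""

    contours: list[KnotContour]
    formants: list[FormantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [c.key for c in self.contours]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ContourValidationError(f"duplicate (speaker, token) keys: {dupes}")
        keyset = set(keys)
        for f in self.formants:
            if (f.speaker_id, f.token_id) not in keyset:
                raise ContourValidationError(
                    f"formant record ({f.speaker_id}, {f.token_id}) has no contour"
                )

    def __len__(self) -> int:
        return len(self.contours)

    @property
    def speakers(self) -> list[str]:
        return sorted({c.speaker_id for c in self.contours})

    def by_speaker(self, speaker_id: str) -> list[KnotContour]:
        return [c for c in self.contours if c.speaker_id == speaker_id]

    def to_frame(self) -> pd.DataFrame:
        """Long-format landmark table (canonical dialect)."""
        rows = []
        for c in self.contours:
            for k in range(N_KNOTS):
                rows.append(
                    (c.speaker_id, c.token_id, c.vowel, c.repetition,
                     k + 1, c.knots[k, 0], c.knots[k, 1])
                )
        return pd.DataFrame(
            rows, columns=["speaker", "token", "vowel", "repetition", "knot", "x", "y"]
        )

    def formants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.speaker_id, f.token_id, f.f1_hz, f.f2_hz) for f in self.formants],
            columns=["speaker", "token", "f1_hz", "f2_hz"],
        )


def _check_vowel(label: str, vowels: tuple[str, ...], label_map: dict | None) -> str:
    if label_map and label in label_map:
        label = label_map[label]
    if label not in vowels:
        raise ContourValidationError(
            f"unknown vowel label {label!r}; expected one of {vowels} "
            "(pass label_map to translate)"
        )
    return label


def read_contours(
    path,
    dialect: str = "long",
    vowels: tuple[str, ...] = CANONICAL_VOWELS,
    label_map: dict | None = None,
    rotated: bool = True,
) -> Dataset:
    """Read a landmark CSV/TSV in the ``long`` or ``wide`` dialect.

    Raises :class:`ContourValidationError` on missing/duplicate knot indices
    (naming the token), non-numeric coordinates (naming the row) and unknown
    vowel labels.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if dialect == "long":
        required = {"speaker", "token", "vowel", "repetition", "knot", "x", "y"}
        missing = required - set(df.columns)
        if missing:
            raise ContourValidationError(f"long dialect: missing columns {sorted(missing)}")
        for col in ("x", "y"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ContourValidationError(
                    f"non-numeric {col!r} value at data row {row + 1}"
                )
            df[col] = coerced
        contours = []
        for (spk, tok), grp in df.groupby(["speaker", "token"], sort=False):
            idx = grp["knot"].to_numpy()
            if sorted(idx.tolist()) != list(range(1, N_KNOTS + 1)):
                raise ContourValidationError(
                    f"token {tok!r}: knot indices must be exactly 1..{N_KNOTS}, "
                    f"got {sorted(idx.tolist())}"
                )
            grp = grp.sort_values("knot")
            contours.append(
                KnotContour(
                    speaker_id=str(spk),
                    token_id=str(tok),
                    vowel=_check_vowel(str(grp["vowel"].iloc[0]), vowels, label_map),
                    repetition=int(grp["repetition"].iloc[0]),
                    knots=grp[["x", "y"]].to_numpy(),
                    rotated=rotated,
                )
            )
        return Dataset(contours=contours)
    elif dialect == "wide":
        coord_cols = [f"x{i}" for i in range(1, N_KNOTS + 1)] + [
            f"y{i}" for i in range(1, N_KNOTS + 1)
        ]
        missing = set(coord_cols) - set(df.columns)
        if missing:
            raise ContourValidationError(f"wide dialect: missing columns {sorted(missing)}")
        contours = []
        for i, row in df.iterrows():
            vals = pd.to_numeric(row[coord_cols], errors="coerce")
            if vals.isna().any():
                raise ContourValidationError(f"non-numeric coordinate at data row {i + 1}")
            knots = np.c_[
                vals[coord_cols[:N_KNOTS]].to_numpy(float),
                vals[coord_cols[N_KNOTS:]].to_numpy(float),
            ]
            contours.append(
                KnotContour(
                    speaker_id=str(row.get("speaker", "S1")),
                    token_id=str(row.get("token", f"t{i + 1}")),
                    vowel=_check_vowel(str(row.get("vowel", vowels[0])), vowels, label_map),
                    repetition=int(row.get("repetition", 1)),
                    knots=knots,
                    rotated=rotated,
                )
            )
        return Dataset(contours=contours)
    raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")


def read_formants(path) -> list[FormantRecord]:
    """Read a formant CSV with columns speaker, token, f1_hz, f2_hz."""
    df = pd.read_csv(path)
    return [
        FormantRecord(str(r.speaker), str(r.token), float(r.f1_hz), float(r.f2_hz))
        for r in df.itertuples()
    ]


def rotate_to_occlusal(contour: KnotContour, occlusal_angle: float) -> KnotContour:
    """Rigidly rotate a raw contour by ``-occlusal_angle`` about the origin.

    ``occlusal_angle`` is the angle (radians, counter-clockwise positive) of
    the imaged occlusal plane relative to the x-axis; rotating by its negative
    brings the bite plane horizontal.  Inter-knot distances are preserved
    exactly (rigid motion).
    """
    if contour.rotated:
        raise ValueError(f"token {contour.token_id!r} is already occlusal-rotated")
    if abs(occlusal_angle) > math.pi / 2:
        raise ValueError(
            f"implausible occlusal angle {occlusal_angle:.3f} rad (|angle| > pi/2)"
        )
    c, s = math.cos(-occlusal_angle), math.sin(-occlusal_angle)
    rot = np.array([[c, -s], [s, c]])
    return replace(contour, knots=contour.knots @ rot.T, rotated=True)


def write_measures(records: pd.DataFrame, path) -> None:
    """Write a measure table (metadata + the 16 measure columns) to CSV.

    NaN measures (degenerate contours) serialize as empty fields and read
    back as NaN; the round trip is lossless to float precision.
    """
    if len(records) == 0:
        raise ValueError("no measure records to write")
    missing = [c for c in MEASURE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"measure table is missing columns {missing}")
    meta = [c for c in METADATA_COLUMNS if c in records.columns]
    records[meta + list(MEASURE_COLUMNS)].to_csv(path, index=False, float_format="%.12g")


def read_measures(path) -> pd.DataFrame:
    """Read back a measure table written by :func:`write_measures`."""
    df = pd.read_csv(path)
    missing = [c for c in MEASURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measure file is missing columns {missing}")
    return df
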
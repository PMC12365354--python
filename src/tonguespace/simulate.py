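"""Synthetic articulatory cohort with known ground truth.

Emulates a midsagittal ultrasound vowel study — ~40 speakers, the five lax
vowels (*bid, bed, bad, bod, bud*), 4-6 repetitions — so every pipeline
stage can be exercised end to end with the generating latents in hand.

Per-token tongue surface (canonical frame, mm):

* a reference arc (circle segment, posterior to anterior, vertically
  flattened) standing in for the resting tongue body;
* a Gaussian radial bump of height ``degree_mm`` centered at the vowel's
  constriction location ``theta_c`` (radians from the tongue tip along the
  arc, so *bid* has the smallest, most anterior value and *bod* the
  largest);
* a root-advancement shear ``root_adv_mm`` applied to the posterior third;
* a whole-body advancement proportional to frontness (mid - theta_c).

Eleven knots are sampled at fixed arc fractions: nine equally spaced plus
two extra in the tip/blade area.  Speaker anatomy is a similarity transform
(size scale, translation) fixed per speaker; each token gets a small probe
rotation jitter about the contour centroid, per-token articulation jitter
on the constriction latents, and per-knot Gaussian landmark noise (noisier
toward the posterior, where ultrasound imaging degrades).

Formants are linearly coupled to the latents with additive noise:
F2 = b0 - b1 * theta_c (front vowels high F2) and
F1 = g0 - g1 * apex_height (high vowels low F1), where apex_height is the
maximum y of the noiseless canonical contour.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset, FormantRecord, KnotContour
from .measures import DenseContour

#: arc fractions of the 11 knots, posterior (vallecula) to anterior (tip):
#: nine equally spaced, plus two extra tip/blade knots
KNOT_FRACTIONS = np.array(
    [0.0, 0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.8125, 0.875, 0.9375, 1.0]
)


@dataclass
class VowelTarget:
    """Generative latents for one vowel category."""

    label: str
    theta_c: float        # constriction location, rad from the tip, in (0, pi)
    degree_mm: float      # constriction degree (bump height)
    root_adv_mm: float    # root advancement (+ = advanced/front)


DEFAULT_VOWELS = (
    VowelTarget("bid", 1.20, 8.0, 1.5),
    VowelTarget("bed", 1.35, 6.0, 1.0),
    VowelTarget("bad", 1.50, 1.2, -0.5),
    VowelTarget("bud", 1.65, 4.5, -1.0),
    VowelTarget("bod", 1.80, 6.5, -1.5),
)


@dataclass
class CohortConfig:
    """Parameters of the synthetic articulatory cohort."""

    n_speakers: int = 40
    vowels: tuple[VowelTarget, ...] = DEFAULT_VOWELS
    reps_min: int = 4
    reps_max: int = 6
    # anatomy / acquisition
    arc_radius_mm: float = 35.0
    arc_flatten: float = 0.55
    bump_width: float = 0.12          # Gaussian sd in arc-fraction units
    frontness_gain_mm: float = 8.0    # body advancement per rad of frontness
    scale_range: tuple[float, float] = (0.85, 1.15)
    translation_range_mm: tuple[float, float] = (-8.0, 8.0)
    rotation_jitter_sd_deg: float = 2.0
    landmark_noise_sd_mm: float = 1.0
    posterior_noise_gain: float = 0.6  # extra noise fraction at the vallecula
    # per-token articulation jitter
    theta_jitter_sd: float = 0.10
    degree_jitter_sd_mm: float = 0.5
    # coarticulatory tip/blade raising from the coda /d/: a second, anterior
    # ridge of random per-token height, which destabilizes the highest point
    # on flat tongue shapes
    coda_ridge_u: float = 0.93
    coda_ridge_mm: float = 1.2
    coda_ridge_sd_mm: float = 0.8
    coda_ridge_width: float = 0.05
    # formant model
    f2_intercept_hz: float = 2450.0
    f2_slope_hz_per_rad: float = 700.0
    f2_noise_sd_hz: float = 60.0
    f1_intercept_hz: float = 1900.0
    f1_slope_hz_per_mm: float = 60.0
    f1_noise_sd_hz: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_speakers < 1 or self.reps_min < 1 or self.reps_max < self.reps_min:
            raise ValueError("nonsensical cohort counts")
        thetas = [v.theta_c for v in self.vowels]
        if any(np.diff(thetas) <= 0):
            raise ValueError(
                "vowel constriction locations must be strictly ordered "
                "front (bid) to back (bod)"
            )
        for sd in (self.rotation_jitter_sd_deg, self.landmark_noise_sd_mm,
                   self.theta_jitter_sd, self.degree_jitter_sd_mm,
                   self.f1_noise_sd_hz, self.f2_noise_sd_hz):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["vowels"] = [asdict(v) for v in self.vowels]
        return json.dumps(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


_PHI_POSTERIOR = 2.85   # arc angle at the vallecula (rad)
_PHI_ANTERIOR = 0.30    # arc angle at the tongue tip (rad)


def _canonical_surface(
    config: CohortConfig, theta_c: float, degree: float, root_adv: float,
    u: np.ndarray, coda_ridge: float = 0.0,
) -> np.ndarray:
    """Noiseless canonical contour evaluated at arc fractions ``u``."""
    phi = _PHI_POSTERIOR + u * (_PHI_ANTERIOR - _PHI_POSTERIOR)
    base = np.c_[
        config.arc_radius_mm * np.cos(phi),
        config.arc_radius_mm * config.arc_flatten * np.sin(phi),
    ]
    u_c = 1.0 - theta_c / np.pi
    bump = degree * np.exp(-0.5 * ((u - u_c) / config.bump_width) ** 2)
    bump = bump + coda_ridge * np.exp(
        -0.5 * ((u - config.coda_ridge_u) / config.coda_ridge_width) ** 2
    )
    pts = base + bump[:, None] * np.c_[np.cos(phi), np.sin(phi)]
    pts[:, 0] += root_adv * np.exp(-((u / 0.25) ** 2))          # posterior shear
    pts[:, 0] += config.frontness_gain_mm * (1.5 - theta_c)     # body advancement
    return pts


def generate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[Dataset, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns the landmark/formant :class:`Dataset` and a ground-truth table
    recording every latent per token.  Bit-identical output for the same
    config and seed.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    u_dense = np.linspace(0.0, 1.0, 200)
    noise_profile = 1.0 + config.posterior_noise_gain * (1.0 - KNOT_FRACTIONS)

    contours, formants, truth = [], [], []
    for s in range(config.n_speakers):
        spk = f"S{s + 1:02d}"
        scale = rng.uniform(*config.scale_range)
        trans = rng.uniform(*config.translation_range_mm, size=2)
        n_reps = int(rng.integers(config.reps_min, config.reps_max + 1))
        for vowel in config.vowels:
            for rep in range(1, n_reps + 1):
                theta = vowel.theta_c + rng.normal(0.0, config.theta_jitter_sd)
                degree = max(
                    vowel.degree_mm + rng.normal(0.0, config.degree_jitter_sd_mm), 0.0
                )
                ridge = max(
                    rng.normal(config.coda_ridge_mm, config.coda_ridge_sd_mm), 0.0
                )
                knots = _canonical_surface(
                    config, theta, degree, vowel.root_adv_mm, KNOT_FRACTIONS, ridge
                )
                apex = float(
                    _canonical_surface(
                        config, theta, degree, vowel.root_adv_mm, u_dense, ridge
                    )[:, 1].max()
                )
                jitter = np.deg2rad(rng.normal(0.0, config.rotation_jitter_sd_deg))
                c, sn = np.cos(jitter), np.sin(jitter)
                centroid = knots.mean(axis=0)
                knots = (knots - centroid) @ np.array([[c, sn], [-sn, c]]) + centroid
                knots = scale * knots + trans
                knots = knots + rng.normal(
                    0.0, config.landmark_noise_sd_mm, size=(11, 2)
                ) * noise_profile[:, None]

                token = f"{spk}_{vowel.label}{rep}"
                contours.append(KnotContour(
                    speaker_id=spk, token_id=token, vowel=vowel.label,
                    repetition=rep, knots=knots, rotated=True,
                ))
                f2 = (config.f2_intercept_hz
                      - config.f2_slope_hz_per_rad * theta
                      + rng.normal(0.0, config.f2_noise_sd_hz))
                f1 = (config.f1_intercept_hz
                      - config.f1_slope_hz_per_mm * apex
                      + rng.normal(0.0, config.f1_noise_sd_hz))
                # formants of adjacent resonances cannot cross
                f2 = max(f2, f1 + 10.0)
                formants.append(FormantRecord(spk, token, f1, f2))
                truth.append({
                    "speaker": spk, "token": token, "vowel": vowel.label,
                    "repetition": rep, "theta_c": theta, "degree_mm": degree,
                    "root_adv_mm": vowel.root_adv_mm,
                    "advance_mm": config.frontness_gain_mm * (1.5 - theta),
                    "coda_ridge_mm": ridge,
                    "apex_height_mm": apex, "speaker_scale": scale,
                    "trans_x_mm": trans[0], "trans_y_mm": trans[1],
                    "rot_jitter_deg": float(np.rad2deg(jitter)),
                    "f1_hz": f1, "f2_hz": f2,
                })
    return Dataset(contours=contours, formants=formants), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# analytic reference fixtures


@dataclass
class Fixture:
    """An analytic test contour with its closed-form expected values."""

    name: str
    dense: DenseContour
    knots: np.ndarray | None = None
    expected: dict = field(default_factory=dict)


def circular_arc(theta: float, n: int = 100, radius: float = 1.0) -> DenseContour:
    """A circular arc of subtended angle ``theta``; its MCI equals theta."""
    ang = np.linspace(np.pi / 2 + theta / 2, np.pi / 2 - theta / 2, n)
    return DenseContour(radius * np.c_[np.cos(ang), np.sin(ang)], source=f"arc_{theta:.3f}")


def reference_fixtures() -> dict[str, Fixture]:
    """The bundled analytic contours used throughout the test suite."""
    fixtures = {}

    knots_line = np.c_[np.linspace(0.0, 10.0, 11), np.zeros(11)]
    line = DenseContour(np.c_[np.linspace(0.0, 10.0, 100), np.zeros(100)], "line")
    fixtures["line"] = Fixture(
        "line", line, knots=knots_line, expected={"mci": 0.0, "tcp": 0.0}
    )

    fixtures["semicircle"] = Fixture(
        "semicircle", circular_arc(np.pi, 100), expected={"mci": np.pi}
    )

    # unit quarter circle from (-1, 0) to (0, 1), then straight to (1.5, 1)
    arc = np.c_[np.cos(np.linspace(np.pi, np.pi / 2, 60)),
                np.sin(np.linspace(np.pi, np.pi / 2, 60))]
    seg = np.c_[np.linspace(0.0, 1.5, 41)[1:], np.ones(40)]
    fixtures["quarter_segment"] = Fixture(
        "quarter_segment", DenseContour(np.vstack([arc, seg]), "quarter_segment"),
        expected={"mci": np.pi / 2},
    )

    # triangle contour A=(0,0), apex=(4,3), B=(10,0); the apex is a sample
    leg1 = np.c_[np.linspace(0.0, 4.0, 41), np.linspace(0.0, 3.0, 41)]
    leg2 = np.c_[np.linspace(4.0, 10.0, 61)[1:], np.linspace(3.0, 0.0, 61)[1:]]
    fixtures["triangle"] = Fixture(
        "triangle", DenseContour(np.vstack([leg1, leg2]), "triangle"),
        expected={"tcp": 0.3, "tc": 2.0 / 3.0, "hv": (4.0, 3.0),
                  "d": (4.0, 0.0), "hvd": 3.0, "ab": 10.0, "ad": 4.0, "db": 6.0},
    )

    # two Gaussian bumps of height 3 at t=0.3 and 5 at t=0.7
    t = np.linspace(0.0, 1.0, 100)
    y = (3.0 * np.exp(-0.5 * ((t - 0.3) / 0.08) ** 2)
         + 5.0 * np.exp(-0.5 * ((t - 0.7) / 0.08) ** 2))
    fixtures["two_bump"] = Fixture(
        "two_bump", DenseContour(np.c_[20.0 * t, y], "two_bump"),
        expected={"hp_x_near": 14.0},  # apex of the taller t=0.7 bump
    )
    return fixtures
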
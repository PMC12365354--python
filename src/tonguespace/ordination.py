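"""Per-speaker MDS reference vowel spaces and Procrustes measure evaluation.

Each speaker's tokens are represented as 22-dim vectors (the 11 knot x's
followed by the 11 knot y's).  Multidimensional scaling reduces their
pairwise Euclidean distances to a 2-D configuration — the speaker's
reference vowel space — which is PCA-rotated so MDS1 carries the largest
variance.  Every pairwise combination of one position measure and one
height/shape measure (64 in all) then forms a physical 2-D vowel space that
is superimposed onto the reference by ordinary Procrustes analysis
(rotation + uniform scale + translation); the residual sum of squares,
averaged over speakers, ranks the combinations.

Two MDS variants are available: ``nonmetric`` (Kruskal stress-1, SMACOF
with 20 random starts plus a classical start; the default) and
``classical`` (principal coordinates).  Stress-1 is computed the same way
for both so the variants are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof
from sklearn.utils.validation import check_is_fitted

from .io import N_KNOTS, Dataset
from .measures import HEIGHT_SHAPE_MEASURES, POSITION_MEASURES

logger = logging.getLogger(__name__)


def contours_to_vectors(contours) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack one speaker's contours into a tokens x 22 matrix."""
    X = np.stack([np.concatenate([c.knots[:, 0], c.knots[:, 1]]) for c in contours])
    assert X.shape[1] == 2 * N_KNOTS
    return X, [c.token_id for c in contours], [c.vowel for c in contours]


def kruskal_stress1(dissimilarities: np.ndarray, config: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against input dissimilarities.

    Disparities are the isotonic (monotone least-squares) regression of the
    configuration distances on the input dissimilarity ranks:
    stress-1 = sqrt( sum (d - dhat)^2 / sum d^2 ).
    """
    iu = np.triu_indices(len(config), 1)
    d = squareform(pdist(config))[iu]
    delta = np.asarray(dissimilarities)[iu]
    denom = float(np.sum(d**2))
    if denom == 0:
        raise ValueError("degenerate configuration: all points identical")
    dhat = IsotonicRegression().fit_transform(delta, d)
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Principal-coordinate (Torgerson) solution from a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w)


def _pca_rotate(coords: np.ndarray) -> np.ndarray:
    """Rotate a centered 2-D configuration so axis 1 has maximal variance."""
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return c @ vt.T


class SpeakerMDS(BaseEstimator):
    """2-D MDS ordination of one speaker's tokens (22-dim knot vectors).

    Parameters
    ----------
    variant : {"nonmetric", "classical"}
        Nonmetric SMACOF (default) or principal coordinates.
    n_init : int
        Random SMACOF starts in addition to the classical-solution start.
    random_state : int or None
        Seed for the random starts; fitting is deterministic given it.

    Attributes
    ----------
    embedding_ : (n_tokens, 2) array, PCA-rotated, least-squares rescaled
        to the input distance scale.
    stress_ : float, Kruskal stress-1 of the final configuration.
    """

    def __init__(self, variant: str = "nonmetric", n_init: int = 20,
                 max_iter: int = 150, eps: float = 1e-6, random_state=None):
        self.variant = variant
        self.n_init = n_init
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if len(X) < 5:
            raise ValueError("speaker MDS needs at least 5 tokens")
        D = squareform(pdist(X))
        if np.unique(X, axis=0).shape[0] < 3:
            raise ValueError("fewer than 3 distinct token configurations")
        classical = _classical_mds(D)
        if self.variant == "classical":
            best = classical
        elif self.variant == "nonmetric":
            rng = np.random.RandomState(self.random_state)
            candidates = []
            emb, _ = smacof(
                D, n_components=2, metric=False, init=classical, n_init=1,
                max_iter=self.max_iter, eps=self.eps, normalized_stress=True,
                random_state=rng,
            )
            candidates.append(emb)
            for _ in range(self.n_init):
                emb, _ = smacof(
                    D, n_components=2, metric=False, n_init=1,
                    max_iter=self.max_iter, eps=self.eps, normalized_stress=True,
                    random_state=rng,
                )
                candidates.append(emb)
            best = min(candidates, key=lambda e: kruskal_stress1(D, e))
        else:
            raise ValueError(f"unknown MDS variant {self.variant!r}")

        # nonmetric solutions have arbitrary scale: least-squares rescale the
        # configuration distances onto the input distances, then PCA-rotate
        iu = np.triu_indices(len(best), 1)
        d = squareform(pdist(best))[iu]
        delta = D[iu]
        scale = float(delta @ d / (d @ d)) if d @ d > 0 else 1.0
        self.embedding_ = _pca_rotate(best * scale)
        self.stress_ = kruskal_stress1(D, self.embedding_)
        self.dissimilarities_ = D
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


@dataclass
class SpeakerOrdination:
    """One speaker's reference vowel space: 2-D token coordinates + stress."""

    speaker_id: str
    token_ids: list[str]
    vowels: list[str]
    coords: np.ndarray
    stress: float
    variant: str


def speaker_mds(contours, variant: str = "nonmetric",
                random_state=None, n_init: int = 20) -> SpeakerOrdination:
    """Fit :class:`SpeakerMDS` on one speaker's contours."""
    X, token_ids, vowels = contours_to_vectors(contours)
    est = SpeakerMDS(variant=variant, n_init=n_init, random_state=random_state)
    est.fit(X)
    return SpeakerOrdination(
        speaker_id=contours[0].speaker_id,
        token_ids=token_ids,
        vowels=vowels,
        coords=est.embedding_,
        stress=est.stress_,
        variant=variant,
    )


def ordinate_dataset(dataset: Dataset, variant: str = "nonmetric",
                     random_state=None, n_init: int = 20) -> dict[str, SpeakerOrdination]:
    """Per-speaker ordinations for a whole dataset, seeded reproducibly."""
    out = {}
    ss = np.random.SeedSequence(random_state)
    seeds = ss.generate_state(len(dataset.speakers))
    for spk, seed in zip(dataset.speakers, seeds):
        out[spk] = speaker_mds(
            dataset.by_speaker(spk), variant=variant,
            random_state=int(seed % (2**31 - 1)), n_init=n_init,
        )
    return out


@dataclass
class ProcrustesFit:
    """An ordinary Procrustes superimposition of source onto target."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    ss: float


class ProcrustesAligner(BaseEstimator):
    """Least-squares similarity superimposition (rotation, scale, translation).

    Parameters
    ----------
    allow_reflection : bool
        Permit an improper rotation (default True; MDS axes have arbitrary
        orientation, so reflections are not meaningful to exclude).
    symmetric : bool
        Center and scale both configurations to unit root-sum-of-squares
        before fitting (default True), so the residual ``ss_`` lies in
        [0, 1] and is symmetric in source/target.
    """

    def __init__(self, allow_reflection: bool = True, symmetric: bool = True):
        self.allow_reflection = allow_reflection
        self.symmetric = symmetric

    def fit(self, X, Y):
        """Superimpose source X onto target Y (same row order, n >= 3)."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape != Y.shape:
            raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
        if len(X) < 3:
            raise ValueError("Procrustes needs at least 3 points")
        if np.any(~np.isfinite(X)) or np.any(~np.isfinite(Y)):
            raise ValueError("NaN/inf rows must be dropped before fitting")
        mx, my = X.mean(axis=0), Y.mean(axis=0)
        Xc, Yc = X - mx, Y - my
        normx = float(np.sqrt(np.sum(Xc**2)))
        normy = float(np.sqrt(np.sum(Yc**2)))
        if normx == 0:
            raise ValueError("rank-deficient source: all points identical")
        if self.symmetric:
            if normy == 0:
                raise ValueError("rank-deficient target: all points identical")
            Xc, Yc = Xc / normx, Yc / normy
        U, s, Vt = np.linalg.svd(Xc.T @ Yc)
        R = U @ Vt
        if not self.allow_reflection and np.linalg.det(R) < 0:
            flip = np.ones(len(s))
            flip[-1] = -1
            R = (U * flip) @ Vt
            s = s * flip
        trace = float(np.sum(s))
        ssx = float(np.sum(Xc**2))
        c = trace / ssx
        self.rotation_ = R
        self.scale_ = c
        self._center_x = mx
        self._norm_x = normx if self.symmetric else 1.0
        # in symmetric mode the fit lives in the centered, unit-size target
        # frame, so the affine translation term is zero there
        self.translation_ = (
            np.zeros(2) if self.symmetric else my - c * (mx @ R)
        )
        self.ss_ = float(np.sum(Yc**2) - trace**2 / ssx)
        self.ss_ = max(self.ss_, 0.0)
        return self

    def transform(self, X):
        """Map source points into the (possibly normalized) target frame."""
        check_is_fitted(self, "rotation_")
        X = np.asarray(X, dtype=float)
        if self.symmetric:
            return self.scale_ * (((X - self._center_x) / self._norm_x) @ self.rotation_)
        return self.scale_ * (X @ self.rotation_) + self.translation_


def procrustes_fit(source, target, allow_reflection: bool = True,
                   symmetric: bool = True) -> ProcrustesFit:
    """Functional wrapper around :class:`ProcrustesAligner`."""
    est = ProcrustesAligner(allow_reflection=allow_reflection, symmetric=symmetric)
    est.fit(source, target)
    return ProcrustesFit(
        rotation=est.rotation_, scale=est.scale_,
        translation=est.translation_, ss=est.ss_,
    )


def combo_sweep(
    measures: pd.DataFrame,
    ordinations: dict[str, SpeakerOrdination],
    position_measures=POSITION_MEASURES,
    height_shape_measures=HEIGHT_SHAPE_MEASURES,
    allow_reflection: bool = True,
    symmetric: bool = True,
) -> pd.DataFrame:
    """Rank all position x height/shape measure pairs by mean Procrustes ss.

    For each of the 64 combinations and each speaker, the two measure
    columns form a tokens x 2 physical configuration that is superimposed
    onto that speaker's MDS coordinates; the residual sum of squares is
    averaged across speakers.  Tokens with NaN in either measure (flat-shape
    TC) are dropped pairwise; a speaker with fewer than 3 valid tokens is
    skipped for that combination (logged).  Returns a frame with columns
    ``position, height_shape, mean_ss, n_speakers`` sorted ascending.
    """
    rows = []
    measures = measures.replace([np.inf, -np.inf], np.nan)
    by_speaker = dict(tuple(measures.groupby("speaker", sort=False)))
    for pos in position_measures:
        for hs in height_shape_measures:
            ss_values = []
            for spk, ordn in ordinations.items():
                sub = by_speaker.get(spk)
                if sub is None:
                    continue
                sub = sub.set_index("token").loc[ordn.token_ids]
                config = sub[[pos, hs]].to_numpy(float)
                valid = np.all(np.isfinite(config), axis=1)
                if valid.sum() < 3:
                    logger.info("combo (%s, %s): speaker %s skipped "
                                "(<3 valid tokens)", pos, hs, spk)
                    continue
                n_dropped = int((~valid).sum())
                if n_dropped:
                    logger.debug("combo (%s, %s): speaker %s dropped %d NaN tokens",
                                 pos, hs, spk, n_dropped)
                try:
                    fit = procrustes_fit(
                        config[valid], ordn.coords[valid],
                        allow_reflection=allow_reflection, symmetric=symmetric,
                    )
                except ValueError:
                    logger.info("combo (%s, %s): speaker %s skipped "
                                "(degenerate configuration)", pos, hs, spk)
                    continue
                ss_values.append(fit.ss)
            rows.append({
                "position": pos,
                "height_shape": hs,
                "mean_ss": float(np.mean(ss_values)) if ss_values else np.nan,
                "n_speakers": len(ss_values),
            })
    out = pd.DataFrame(rows).sort_values("mean_ss", kind="mergesort")
    return out.reset_index(drop=True)


def stress_summary(ordinations: dict[str, SpeakerOrdination]) -> dict:
    """Median and upper-quartile stress across speakers."""
    stresses = np.array([o.stress for o in ordinations.values()])
    return {
        "n_speakers": len(stresses),
        "median": float(np.median(stresses)),
        "upper_quartile": float(np.quantile(stresses, 0.75)),
    }
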
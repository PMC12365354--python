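"""Speaker-held-out vowel classification over measure pairs.

For each of the 64 position x height/shape measure pairs, a linear
discriminant classifier is trained on the within-speaker z-scored measures
of 75% of the speakers and tested on the remaining, unseen speakers; the
procedure is repeated with resampled speaker splits (100 replicates by
default).  Common random numbers — the same split sequence across all
combinations — keep the combo ranking free of split noise.

The per-trial errors feed a Bernoulli mixed-effects logistic regression
with vowel x position-measure and vowel x height/shape-measure fixed-effect
interactions and random intercepts for speaker and replicate, yielding
per-cell predicted error probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .measures import HEIGHT_SHAPE_MEASURES, POSITION_MEASURES

logger = logging.getLogger(__name__)


def scale_within_speaker(
    df: pd.DataFrame,
    columns,
    speaker_col: str = "speaker",
) -> pd.DataFrame:
    """Z-score each column within each speaker (sample sd, n-1 denominator).

    Removes anatomy- and probe-placement offsets before cross-speaker
    statistics.  A measure with zero within-speaker variance is emitted as
    all zeros with a warning.  NaN values stay NaN.
    """
    out = df.copy()
    for col in columns:
        grouped = out.groupby(speaker_col)[col]
        mean = grouped.transform("mean")
        sd = grouped.transform(lambda s: s.std(ddof=1))
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"column {col!r}: zero within-speaker variance for "
                f"{out.loc[zero, speaker_col].nunique()} speaker(s); emitted as 0",
                stacklevel=2,
            )
            sd = sd.mask(zero, 1.0)
            mean = mean.mask(zero, out[col])
        out[col] = (out[col] - mean) / sd
    return out


class WithinSpeakerScaler(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`scale_within_speaker`.

    Operates on a DataFrame carrying a speaker column; ``columns=None``
    scales every numeric column except the speaker key.
    """

    def __init__(self, columns=None, speaker_col: str = "speaker"):
        self.columns = columns
        self.speaker_col = speaker_col

    def fit(self, X: pd.DataFrame, y=None):
        if self.columns is None:
            self.columns_ = [
                c for c in X.select_dtypes("number").columns if c != self.speaker_col
            ]
        else:
            self.columns_ = list(self.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return scale_within_speaker(X, self.columns_, speaker_col=self.speaker_col)


@dataclass
class ClassificationRun:
    """One resampling replicate of the speaker-held-out task."""

    replicate: int
    train_speakers: list[str]
    test_speakers: list[str]
    accuracy: float


@dataclass
class ClassificationResult:
    """All replicates for one measure pair."""

    position: str
    height_shape: str
    runs: list[ClassificationRun]
    trials: pd.DataFrame = field(repr=False, default=None)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.runs])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


def make_speaker_splits(
    speakers,
    n_reps: int = 100,
    train_fraction: float = 0.75,
    seed=None,
) -> list[tuple[list, list]]:
    """Draw the replicate train/test speaker splits once, for reuse.

    Each replicate samples floor(train_fraction * S) speakers without
    replacement for training; the remainder test.  Sharing one split
    sequence across measure pairs implements common random numbers.
    """
    speakers = sorted(speakers)
    n_train = int(np.floor(train_fraction * len(speakers)))
    if n_train < 1 or n_train >= len(speakers):
        raise ValueError("train_fraction leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_reps):
        perm = rng.permutation(len(speakers))
        train = sorted(speakers[i] for i in perm[:n_train])
        test = sorted(speakers[i] for i in perm[n_train:])
        splits.append((train, test))
    return splits


def resampled_classification(
    scaled: pd.DataFrame,
    combo: tuple[str, str],
    n_reps: int = 100,
    train_fraction: float = 0.75,
    seed=None,
    splits=None,
    vowel_col: str = "vowel",
    speaker_col: str = "speaker",
    keep_trials: bool = True,
) -> ClassificationResult:
    """Speaker-held-out LDA classification for one measure pair.

    ``scaled`` must already be within-speaker z-scored.  Tokens with NaN in
    either measure are dropped (flat-shape TC).  A replicate whose training
    data miss a vowel class is re-drawn (at most 10 times, logged).
    Fully reproducible from ``seed`` (or an externally supplied ``splits``
    sequence for common random numbers).
    """
    pos, hs = combo
    data = scaled.dropna(subset=[pos, hs])
    n_dropped = len(scaled) - len(data)
    if n_dropped:
        logger.debug("combo (%s, %s): dropped %d NaN tokens", pos, hs, n_dropped)
    speakers = sorted(data[speaker_col].unique())
    if splits is None:
        splits = make_speaker_splits(speakers, n_reps, train_fraction, seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    classes = set(data[vowel_col].unique())
    runs, trial_frames = [], []
    for rep, (train_spk, test_spk) in enumerate(splits, start=1):
        for attempt in range(11):
            train = data[data[speaker_col].isin(train_spk)]
            if set(train[vowel_col].unique()) == classes:
                break
            logger.info("replicate %d: vowel class missing in training "
                        "speakers, re-drawing", rep)
            perm = rng.permutation(len(speakers))
            n_train = len(train_spk)
            train_spk = sorted(speakers[i] for i in perm[:n_train])
            test_spk = sorted(speakers[i] for i in perm[n_train:])
        else:
            raise RuntimeError("could not draw a training split with all classes")
        assert not set(train_spk) & set(test_spk)
        test = data[data[speaker_col].isin(test_spk)]
        lda = LinearDiscriminantAnalysis()
        lda.fit(train[[pos, hs]].to_numpy(), train[vowel_col].to_numpy())
        pred = lda.predict(test[[pos, hs]].to_numpy())
        err = pred != test[vowel_col].to_numpy()
        runs.append(ClassificationRun(
            replicate=rep,
            train_speakers=list(train_spk),
            test_speakers=list(test_spk),
            accuracy=float(1.0 - err.mean()),
        ))
        if keep_trials:
            trial_frames.append(pd.DataFrame({
                "replicate": rep,
                "speaker": test[speaker_col].to_numpy(),
                "token": test["token"].to_numpy() if "token" in test else np.arange(len(test)),
                "vowel": test[vowel_col].to_numpy(),
                "predicted": pred,
                "error": err.astype(int),
                "position_measure": pos,
                "height_shape_measure": hs,
            }))
    trials = pd.concat(trial_frames, ignore_index=True) if trial_frames else None
    return ClassificationResult(position=pos, height_shape=hs, runs=runs, trials=trials)


def sweep_accuracy(
    scaled: pd.DataFrame,
    position_measures=POSITION_MEASURES,
    height_shape_measures=HEIGHT_SHAPE_MEASURES,
    n_reps: int = 100,
    train_fraction: float = 0.75,
    seed=None,
    keep_trials: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Mean held-out accuracy for every measure pair, ranked descending.

    Returns (table, trials): the 64-row accuracy table and, when
    ``keep_trials``, the pooled per-trial error records for the error model.
    """
    speakers = sorted(scaled["speaker"].unique())
    splits = make_speaker_splits(speakers, n_reps, train_fraction, seed)
    rows, trial_frames = [], []
    for pos in position_measures:
        for hs in height_shape_measures:
            res = resampled_classification(
                scaled, (pos, hs), n_reps=n_reps, train_fraction=train_fraction,
                seed=seed, splits=splits, keep_trials=keep_trials,
            )
            rows.append({
                "position": pos,
                "height_shape": hs,
                "accuracy": res.mean_accuracy,
                "accuracy_sd": float(res.accuracies.std(ddof=1)),
            })
            if keep_trials and res.trials is not None:
                trial_frames.append(res.trials)
    table = pd.DataFrame(rows).sort_values(
        "accuracy", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    trials = pd.concat(trial_frames, ignore_index=True) if trial_frames else None
    return table, trials


@dataclass
class ErrorModelResult:
    """Fitted Bernoulli mixed-logistic error model."""

    coefficients: pd.Series
    random_sd: pd.Series
    cell_predictions: pd.DataFrame
    converged: bool


def fit_error_model(
    trials: pd.DataFrame,
    vowel_col: str = "vowel",
    position_col: str = "position_measure",
    height_shape_col: str = "height_shape_measure",
    speaker_col: str = "speaker",
    trial_col: str = "replicate",
) -> ErrorModelResult:
    """Mixed-effects logistic regression of classification errors.

    Fixed effects: vowel x position-measure and vowel x height/shape-measure
    interaction cells (one log-odds coefficient per cell, no separate
    intercept).  Random intercepts: speaker and trial (the resampling
    replicate).  Fitted by variational Bayes (statsmodels
    BinomialBayesMixedGLM); the weak normal prior on the fixed effects
    doubles as a ridge guard against complete separation.

    Returns per-coefficient posterior means (log-odds), random-intercept
    sds, and predicted error probabilities for every
    vowel x position x height/shape cell at random effects zero.
    """
    df = trials[[vowel_col, position_col, height_shape_col,
                 speaker_col, trial_col, "error"]].copy()
    df.columns = ["vowel", "pos", "hs", "speaker", "trial", "error"]
    for c in ("vowel", "pos", "hs", "speaker", "trial"):
        df[c] = df[c].astype(str)
    if df["speaker"].nunique() < 2:
        raise ValueError("error model needs at least 2 speakers")
    model = BinomialBayesMixedGLM.from_formula(
        "error ~ 0 + C(vowel):C(pos) + C(vowel):C(hs)",
        {"speaker": "0 + C(speaker)", "trial": "0 + C(trial)"},
        df,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit_vb()
    coef = pd.Series(result.fe_mean, index=model.exog_names)
    random_sd = pd.Series(np.exp(result.vcp_mean), index=["speaker", "trial"])

    def _cell_name(prefix, vowel, level):
        return f"C(vowel)[{vowel}]:C({prefix})[{level}]"

    rows = []
    for vowel in sorted(df["vowel"].unique()):
        for pos in sorted(df["pos"].unique()):
            for hs in sorted(df["hs"].unique()):
                eta = coef.get(_cell_name("pos", vowel, pos), 0.0) + \
                    coef.get(_cell_name("hs", vowel, hs), 0.0)
                rows.append({
                    "vowel": vowel, "position": pos, "height_shape": hs,
                    "p_error": float(1.0 / (1.0 + np.exp(-eta))),
                })
    cells = pd.DataFrame(rows)
    assert ((cells["p_error"] > 0) & (cells["p_error"] < 1)).all()
    return ErrorModelResult(
        coefficients=coef,
        random_sd=random_sd,
        cell_predictions=cells,
        converged=bool(getattr(result, "converged", True)),
    )
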
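"""The two-stage stacked classifier for anticancer peptide identification.

Stage 1 trains one gradient-boosted-tree model (LightGBM, library-default
parameters) per feature encoding; its positive-class probabilities form a
k-dimensional meta-feature vector per peptide (k = 19 with the full
encoder bank, 11 when no sequence profiles are available). Stage 2 fits an
RBF-kernel SVM on the meta-features, its C and gamma chosen by exhaustive
grid search under internal stratified 5-fold accuracy. The final call is
positive when the stage-2 positive score reaches the decision threshold
(default 0.5, matching balanced benchmark classes).

By default stage 1 scores its own training rows in-sample, exactly as the
stacked construction trains; an out-of-fold mode is provided (and
recommended for honest generalization estimates) in which each training
row is scored by a model trained without it, after which every stage-1
model is refit on all rows for deployment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import autocorrelation_features as ac
from . import composition_features as comp
from . import profile_features as prof
from . import pseaac_features as pse
from .core import FeatureVector
from .seqio import LabeledDataset, PeptideRecord

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

_LGBM_NAME_WARNING = "X does not have valid feature names"


def _positive_scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1] for a fitted classifier.

    SVMs are scored by the logistic-squashed signed margin
    1/(1 + exp(-margin / s)), which is monotone in the margin and puts
    the 0.5 threshold exactly on the decision boundary — unlike Platt
    probability calibration, which can invert on (near-)separable
    meta-features. The scale s is the margin's training-set spread
    (attached at fit time), so scores use the full [0, 1] range. Learners
    with native probabilities use predict_proba.
    """
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=_LGBM_NAME_WARNING)
        if isinstance(model, SVC):
            margin = model.decision_function(X)
            if model.classes_[1] != 1:  # margin signed toward classes_[1]
                margin = -margin
            scale = getattr(model, "margin_scale_", 1.0)
            return 1.0 / (1.0 + np.exp(-margin / scale))
        proba = model.predict_proba(X)
        return proba[:, int(np.where(model.classes_ == 1)[0][0])]


# ---------------------------------------------------------------------------
# Encoder registry and bank
# ---------------------------------------------------------------------------

def _enc_kmer(rec, **p):
    return comp.kmer_encode(rec, **p)


def _enc_dr(rec, **p):
    return comp.dr_encode(rec, **p)


def _enc_distance_pair(rec, alphabet="cp14", **p):
    return comp.distance_pair_encode(
        rec, alphabet=comp.load_reduced_alphabet(alphabet), **p
    )


def _autocorr_params(dmax):
    return ac.AutocorrParams(indices=ac.default_index_panel(), dmax=dmax)


def _enc_autocorr(mode):
    def enc(rec, dmax=2):
        return ac.autocorrelation_encode(rec, _autocorr_params(dmax), mode=mode)
    return enc


def _enc_pdt(rec, dmax=2):
    return ac.pdt_encode(rec, _autocorr_params(dmax))


def _enc_pc_pseaac(rec, lam=4, w=0.05):
    return pse.pc_pseaac_encode(rec, pse.PseaacParams(lam=lam, w=w))


def _enc_sc_pseaac(rec, lam=4, w=0.05):
    return pse.sc_pseaac_encode(
        rec, pse.PseaacParams(lam=lam, w=w,
                              property_set=pse.builtin_pseaac_properties()[:2])
    )


def _enc_general(mode):
    def enc(rec, lam=4, w=0.05):
        params = pse.PseaacParams(lam=lam, w=w,
                                  property_set=ac.default_index_panel())
        return pse.general_pseaac_encode(rec, params, mode=mode)
    return enc


#: encoder id -> (family, needs_profile, callable). The callable takes a
#: PeptideRecord (sequence encoders) or a Pssm (profile encoders) plus
#: keyword parameters and returns a FeatureVector.
ENCODER_REGISTRY: dict[str, tuple[str, bool, Callable[..., FeatureVector]]] = {
    # amino acid composition (3)
    "kmer": ("composition", False, _enc_kmer),
    "dr": ("composition", False, _enc_dr),
    "distance_pair": ("composition", False, _enc_distance_pair),
    # physicochemical autocorrelation (4)
    "ac": ("autocorrelation", False, _enc_autocorr("AC")),
    "cc": ("autocorrelation", False, _enc_autocorr("CC")),
    "acc": ("autocorrelation", False, _enc_autocorr("ACC")),
    "pdt": ("autocorrelation", False, _enc_pdt),
    # pseudo amino acid composition (4)
    "pc_pseaac": ("pseaac", False, _enc_pc_pseaac),
    "sc_pseaac": ("pseaac", False, _enc_sc_pseaac),
    "pc_pseaac_general": ("pseaac", False, _enc_general("parallel")),
    "sc_pseaac_general": ("pseaac", False, _enc_general("series")),
    # profile-based (8)
    "top_n_gram": ("profile", True, lambda pssm, **p: prof.top_n_gram_encode(pssm, **p)),
    "pdt_profile": ("profile", True, lambda pssm, **p: prof.pdt_profile_encode(pssm, **p)),
    "dt": ("profile", True, lambda pssm, **p: prof.dt_encode(pssm, **p)),
    "ac_pssm": ("profile", True, lambda pssm, **p: prof.pssm_covariance_encode(pssm, mode="AC", **p)),
    "cc_pssm": ("profile", True, lambda pssm, **p: prof.pssm_covariance_encode(pssm, mode="CC", **p)),
    "acc_pssm": ("profile", True, lambda pssm, **p: prof.pssm_covariance_encode(pssm, mode="ACC", **p)),
    "pssm_dt": ("profile", True, lambda pssm, **p: prof.pssm_dt_encode(pssm, **p)),
    "pssm_rt": ("profile", True, lambda pssm, **p: prof.pssm_rt_encode(pssm, **p)),
}

#: The full default bank: 3 composition + 4 autocorrelation + 4 PseAAC +
#: 8 profile encoders = 19 feature encodings.
DEFAULT_ENCODERS: tuple[str, ...] = tuple(ENCODER_REGISTRY)

#: The sequence-only bank used when no profiles are available (k = 11).
SEQUENCE_ENCODERS: tuple[str, ...] = tuple(
    eid for eid, (_, needs_profile, _fn) in ENCODER_REGISTRY.items()
    if not needs_profile
)


@dataclass(frozen=True)
class EncoderBank:
    """An ordered bank of (encoder id, parameter map) pairs.

    Meta-feature column m always corresponds to encoder m in bank order.
    """

    encoders: tuple[tuple[str, Mapping[str, Any]], ...]

    def __post_init__(self) -> None:
        ids = [eid for eid, _ in self.encoders]
        if not ids:
            raise ValueError("encoder bank must contain at least one encoder")
        dupes = {eid for eid in ids if ids.count(eid) > 1}
        if dupes:
            raise ValueError(f"duplicate encoder ids in bank: {sorted(dupes)}")
        unknown = [eid for eid in ids if eid not in ENCODER_REGISTRY]
        if unknown:
            raise ValueError(f"unknown encoder ids: {unknown}")

    @property
    def k(self) -> int:
        return len(self.encoders)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(eid for eid, _ in self.encoders)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for eid, _ in self.encoders:
            fam = ENCODER_REGISTRY[eid][0]
            counts[fam] = counts.get(fam, 0) + 1
        return counts

    def needs_profiles(self) -> bool:
        return any(ENCODER_REGISTRY[eid][1] for eid, _ in self.encoders)


def build_encoder_bank(
    config: Sequence[str] | Mapping[str, Mapping[str, Any]] | None = None,
    profiles_available: bool = True,
) -> EncoderBank:
    """Assemble the encoder bank from a config (default: all 19 encoders).

    ``config`` may be a list of encoder ids or a mapping id -> parameter
    overrides; omitted parameters take the registry defaults. Without
    profiles the 8 profile encoders are dropped with a logged warning,
    leaving the 11 sequence encoders.
    """
    if config is None:
        ids = list(DEFAULT_ENCODERS)
        params: Mapping[str, Mapping[str, Any]] = {}
    elif isinstance(config, Mapping):
        ids = list(config)
        params = config
    else:
        ids = list(config)
        params = {}
    if not profiles_available:
        dropped = [eid for eid in ids
                   if eid in ENCODER_REGISTRY and ENCODER_REGISTRY[eid][1]]
        if dropped:
            logger.warning(
                "no profiles available: dropping profile encoders %s "
                "(bank reduced from %d to %d encoders)",
                dropped, len(ids), len(ids) - len(dropped),
            )
            ids = [eid for eid in ids if eid not in dropped]
    return EncoderBank(
        encoders=tuple((eid, dict(params.get(eid, {}) or {})) for eid in ids)
    )


def encode_records(
    encoder_id: str,
    params: Mapping[str, Any],
    records: Sequence[PeptideRecord],
    pssms: Mapping[str, prof.Pssm] | None = None,
) -> np.ndarray:
    """Feature matrix (n_records x dim) for one encoder."""
    family, needs_profile, fn = ENCODER_REGISTRY[encoder_id]
    rows = []
    for rec in records:
        if needs_profile:
            if pssms is None or rec.id not in pssms:
                raise KeyError(
                    f"encoder {encoder_id!r} needs a profile for {rec.id!r}"
                )
            fv = fn(pssms[rec.id], **params)
        else:
            fv = fn(rec, **params)
        rows.append(fv.values)
    return np.vstack(rows)


def encode_bank_matrices(
    bank: EncoderBank,
    records: Sequence[PeptideRecord],
    pssms: Mapping[str, prof.Pssm] | None = None,
) -> list[np.ndarray]:
    """One feature matrix per bank encoder, in bank order."""
    return [encode_records(eid, params, records, pssms)
            for eid, params in bank.encoders]


# ---------------------------------------------------------------------------
# Stage-1: one learner per encoder
# ---------------------------------------------------------------------------

def make_stage1_learner(spec: str, seed: int):
    """Stage-1 learner factory; gradient-boosted trees by default.

    LightGBM is used at library-default parameters (only the seed, thread
    count and verbosity are pinned for reproducibility). Alternatives are
    pluggable for ablation experiments.
    """
    if spec == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbosity=-1)
    if spec == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if spec == "logistic":
        return LogisticRegression(max_iter=2000)
    raise ValueError(f"unknown stage-1 learner {spec!r}")


def fit_stage1(
    matrices: Sequence[np.ndarray],
    labels: np.ndarray,
    learner_spec: str = "lightgbm",
    mode: str = "in_sample",
    seed: int = 0,
) -> tuple[list, np.ndarray]:
    """Fit one stage-1 model per encoder and build the meta-feature matrix.

    Column m of the returned matrix is the positive-class probability of
    model m on the training rows. ``in_sample`` scores the rows with the
    model trained on all of them; ``out_of_fold`` scores each row from an
    internal stratified 5-fold model that never saw it, then refits on all
    rows for deployment.
    """
    if mode not in ("in_sample", "out_of_fold"):
        raise ValueError(f"unknown stage-1 mode {mode!r}")
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("stage-1 training requires both classes")
    models = []
    meta = np.empty((labels.size, len(matrices)))
    for m, X in enumerate(matrices):
        model = make_stage1_learner(learner_spec, seed + m)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=_LGBM_NAME_WARNING)
            if mode == "out_of_fold":
                cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed + m)
                oof = cross_val_predict(model, X, labels, cv=cv,
                                        method="predict_proba")
                meta[:, m] = oof[:, 1]
                model.fit(X, labels)
            else:
                model.fit(X, labels)
        if mode == "in_sample":
            meta[:, m] = _positive_scores(model, X)
        models.append(model)
    return models, meta


def stage1_meta(models: Sequence, matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Meta-feature matrix of fitted stage-1 models on new rows."""
    meta = np.empty((matrices[0].shape[0], len(models)))
    for m, (model, X) in enumerate(zip(models, matrices)):
        meta[:, m] = _positive_scores(model, X)
    return meta


# ---------------------------------------------------------------------------
# Stage-2: SVM (or alternates) on the meta-features
# ---------------------------------------------------------------------------

#: The classical RBF grid: C in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2.
DEFAULT_SVM_GRID: dict[str, list[float]] = {
    "C": [float(2.0**e) for e in range(-5, 16, 2)],
    "gamma": [float(2.0**e) for e in range(-15, 4, 2)],
}

STAGE2_LEARNERS = (
    "svm", "adaboost", "decision_tree", "logistic_regression",
    "naive_bayes", "random_forest",
)


def fit_stage2(
    meta: np.ndarray,
    labels: np.ndarray,
    learner: str = "svm",
    grid: Mapping[str, list[float]] | None = None,
    seed: int = 0,
) -> tuple[Any, dict[str, Any]]:
    """Fit the second-layer classifier on the meta-feature matrix.

    For the default SVM, (C, gamma) are chosen by exhaustive grid search
    under internal stratified 5-fold accuracy and the winner refit on all
    rows; the chosen parameters and CV accuracy are returned. Its positive
    score is the logistic-squashed margin (see ``_positive_scores``). The
    alternate learners (for second-layer swap experiments) are fit at
    library defaults.
    """
    labels = np.asarray(labels, dtype=int)
    if meta.ndim != 2 or meta.shape[0] != labels.size:
        raise ValueError("meta matrix rows must match labels")
    if np.all(meta.std(axis=0) < 1e-12):
        warnings.warn("meta-feature matrix has only constant columns",
                      stacklevel=2)
    if learner == "svm":
        param_grid = dict(grid or DEFAULT_SVM_GRID)
        min_class = int(np.bincount(labels).min())
        if min_class < 2:
            # too small to cross-validate: take the first grid point
            best_params = {"C": param_grid["C"][0],
                           "gamma": param_grid["gamma"][0]}
            best_score = float("nan")
        else:
            cv = StratifiedKFold(n_splits=min(5, min_class), shuffle=True,
                                 random_state=seed)
            search = GridSearchCV(SVC(kernel="rbf"), param_grid,
                                  scoring="accuracy", cv=cv, n_jobs=1)
            search.fit(meta, labels)
            best_params = search.best_params_
            best_score = float(search.best_score_)
        model = SVC(kernel="rbf", **best_params)
        model.fit(meta, labels)
        spread = float(np.std(model.decision_function(meta)))
        model.margin_scale_ = spread if spread > 1e-12 else 1.0
        fitted = {"learner": "svm",
                  **{k: float(v) for k, v in best_params.items()},
                  "cv_accuracy": best_score}
        return model, fitted
    factories = {
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "logistic_regression": lambda: LogisticRegression(max_iter=2000),
        "naive_bayes": lambda: GaussianNB(),
        "random_forest": lambda: RandomForestClassifier(random_state=seed, n_jobs=1),
    }
    if learner not in factories:
        raise ValueError(f"unknown stage-2 learner {learner!r}")
    model = factories[learner]().fit(meta, labels)
    return model, {"learner": learner}


# ---------------------------------------------------------------------------
# The trained stacked model
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Per-record outcome: a score and label, or an error message."""

    id: str
    score: float | None
    label: int | None
    error: str | None = None


@dataclass
class StackedModel:
    """The trained two-stage model: encoder bank, stage-1 models, stage-2."""

    bank: EncoderBank
    stage1_models: list
    stage2_model: Any
    stage1_mode: str
    seed: int
    fitted_params: dict[str, Any] = field(default_factory=dict)
    threshold: float = 0.5
    format_version: int = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        if len(self.stage1_models) != self.bank.k:
            raise ValueError("one stage-1 model per bank encoder required")

    def predict(
        self,
        records: Sequence[PeptideRecord],
        pssms: Mapping[str, prof.Pssm] | None = None,
    ) -> list[PredictionResult]:
        return predict_enacp(self, records, pssms)

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": self.format_version, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "StackedModel":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model file format version {version} does not match "
                f"this package's version {MODEL_FORMAT_VERSION}; refusing to load"
            )
        return payload["model"]


def train_enacp(
    dataset: LabeledDataset,
    config: Mapping[str, Any] | None = None,
    seed: int = 0,
    pssms: Mapping[str, prof.Pssm] | None = None,
) -> StackedModel:
    """Train the full stacked model on a labeled dataset.

    ``config`` keys: ``encoders`` (bank config), ``stage1_mode``
    (in_sample / out_of_fold), ``stage1_learner``, ``stage2`` (svm or an
    alternate), ``svm_grid``, ``threshold``. Deterministic given the seed.
    """
    config = dict(config or {})
    dataset.require_both_classes()
    bank = config.get("bank") or build_encoder_bank(
        config.get("encoders"), profiles_available=pssms is not None
    )
    matrices = encode_bank_matrices(bank, dataset.records, pssms)
    for (eid, _), X in zip(bank.encoders, matrices):
        logger.info("encoder %s: %d features", eid, X.shape[1])
    mode = config.get("stage1_mode", "in_sample")
    models, meta = fit_stage1(
        matrices, dataset.labels,
        learner_spec=config.get("stage1_learner", "lightgbm"),
        mode=mode, seed=seed,
    )
    stage2, fitted = fit_stage2(
        meta, dataset.labels,
        learner=config.get("stage2", "svm"),
        grid=config.get("svm_grid"), seed=seed,
    )
    return StackedModel(
        bank=bank, stage1_models=models, stage2_model=stage2,
        stage1_mode=mode, seed=seed, fitted_params=fitted,
        threshold=float(config.get("threshold", 0.5)),
    )


def predict_enacp(
    model: StackedModel,
    records: Sequence[PeptideRecord],
    pssms: Mapping[str, prof.Pssm] | None = None,
) -> list[PredictionResult]:
    """Score records with a trained model, in input order.

    A record an encoder cannot handle (too short for a lag, missing
    profile) yields an error entry; the run continues for the rest.
    """
    results: list[PredictionResult] = [None] * len(records)  # type: ignore
    valid_idx: list[int] = []
    valid_recs: list[PeptideRecord] = []
    for i, rec in enumerate(records):
        try:
            row_mats = encode_bank_matrices(model.bank, [rec], pssms)
        except (ValueError, KeyError) as exc:
            results[i] = PredictionResult(id=rec.id, score=None, label=None,
                                          error=str(exc))
            continue
        valid_idx.append(i)
        valid_recs.append(rec)
    if valid_recs:
        matrices = encode_bank_matrices(model.bank, valid_recs, pssms)
        meta = stage1_meta(model.stage1_models, matrices)
        scores = _positive_scores(model.stage2_model, meta)
        for j, i in enumerate(valid_idx):
            score = float(scores[j])
            results[i] = PredictionResult(
                id=valid_recs[j].id, score=score,
                label=int(score >= model.threshold),
            )
    return results


def cross_val_scores(
    dataset: LabeledDataset,
    bank: EncoderBank,
    matrices: Sequence[np.ndarray] | None = None,
    k: int = 5,
    seed: int = 0,
    pssms: Mapping[str, prof.Pssm] | None = None,
    stage1_mode: str = "in_sample",
    stage1_learner: str = "lightgbm",
    stage2: str = "svm",
    svm_grid: Mapping[str, list[float]] | None = None,
) -> np.ndarray:
    """Held-out stage-2 scores from one stratified k-fold pass.

    Each fold trains the full two-stage model on the remaining folds and
    scores the held-out rows; the returned vector is aligned to dataset
    order. Feature matrices may be precomputed and reused, since encoding
    is label-free and per-peptide.
    """
    if matrices is None:
        matrices = encode_bank_matrices(bank, dataset.records, pssms)
    labels = dataset.labels
    scores = np.empty(len(dataset))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(dataset)), labels)):
        train_mats = [X[train_idx] for X in matrices]
        test_mats = [X[test_idx] for X in matrices]
        models, meta = fit_stage1(
            train_mats, labels[train_idx], learner_spec=stage1_learner,
            mode=stage1_mode, seed=seed + 101 * fold,
        )
        stage2_model, _ = fit_stage2(
            meta, labels[train_idx], learner=stage2, grid=svm_grid,
            seed=seed + 101 * fold,
        )
        test_meta = stage1_meta(models, test_mats)
        scores[test_idx] = _positive_scores(stage2_model, test_meta)
    return scores
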
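"""Feature assembly and the extremely-randomised-trees interface classifier.

The feature table carries one row per TMD residue and exactly 103 named
feature columns in seven families (coevolution 52, PSSM 25, conservation 8,
polarity 8, position/TMD 5, motifs 3, physical 2); the census is enforced so
any drift in the feature extractors fails loudly.  Feature reduction keeps 27
features by recursive elimination on cross-validated permutation importance,
with folds grouped by TMD so residues of one helix never straddle a fold
boundary.  The classifier is an extremely-randomised-trees ensemble tuned by
grouped grid search maximising average precision; its per-residue output is
the probability that the residue lies at a homotypic interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, GroupKFold

from . import errors
from .coevolution import DcaParams, coevolution_features
from .msa_features import (
    Alignment,
    build_pssm,
    conservation_features,
    depth_profile,
    lips_face_scores,
    motif_and_physical_flags,
    polarity_features,
)
from .reference import AMINO_ACIDS

FORMAT_VERSION = 1

FEATURE_CENSUS = {
    "coevolution": 52,
    "pssm": 25,
    "conservation": 8,
    "polarity": 8,
    "position": 5,
    "motifs": 3,
    "physical": 2,
}

_CONSERVATION_COLS = (
    "entropy", "conservation", "entropy_gaps", "conservation_gaps",
    "majority_fraction", "ref_identity", "conservation_rel", "entropy_rel",
)
_POLARITY_COLS = (
    "polarity", "relative_polarity", "polarity_query", "relative_polarity_query",
    "lips_score", "lips_conservation", "lips_polarity", "lips_top_face",
)
_POSITION_COLS = (
    "residue_depth", "position_fraction", "tmd_length",
    "tmd_mean_polarity", "tmd_mean_conservation",
)
_MOTIF_COLS = ("in_gxxxg", "in_smallxxxsmall", "in_polarxxxpolar")
_PHYSICAL_COLS = ("is_branched", "is_small")

DEFAULT_GRID = {
    "n_estimators": [100],
    "max_depth": [None, 6],
    "min_samples_leaf": [1, 3],
    "max_features": ["sqrt", 0.5],
}


@dataclass
class SplitSpec:
    """Disjoint train / blind-test TMD id sets."""

    train_ids: tuple
    test_ids: tuple

    def __post_init__(self):
        self.train_ids = tuple(self.train_ids)
        self.test_ids = tuple(self.test_ids)
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train and test ids overlap: {sorted(overlap)}")


@dataclass
class TrainedModel:
    estimator: ExtraTreesClassifier
    selected_features: tuple
    hyperparameters: dict
    seed: int
    train_ids: tuple = field(default_factory=tuple)


def feature_group(name: str) -> str:
    """Census family of a feature column."""
    if name.startswith(("mi_", "di_")):
        return "coevolution"
    if name.startswith("pssm_"):
        return "pssm"
    if name in _CONSERVATION_COLS:
        return "conservation"
    if name in _POLARITY_COLS:
        return "polarity"
    if name in _POSITION_COLS:
        return "position"
    if name in _MOTIF_COLS:
        return "motifs"
    if name in _PHYSICAL_COLS:
        return "physical"
    raise errors.SchemaError(f"unknown feature column {name!r}")


def feature_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in ("residue", "interface")]


def _check_census(columns) -> None:
    counts = dict.fromkeys(FEATURE_CENSUS, 0)
    for c in columns:
        counts[feature_group(c)] += 1
    if counts != FEATURE_CENSUS:
        raise errors.SchemaError(
            f"feature census mismatch: got {counts}, expected {FEATURE_CENSUS}"
        )


def tmd_feature_frame(aln: Alignment, dca_params: DcaParams | None = None) -> pd.DataFrame:
    """All 103 features for one TMD (rows indexed by 0-based position)."""
    seq = aln.tmd_sequence
    length = len(seq)
    pssm = build_pssm(aln)
    pssm_block = pssm.rename(columns=lambda c: f"pssm_{c}")
    cons = conservation_features(aln, pssm)
    pol = polarity_features(aln)
    lips = lips_face_scores(aln)
    pol_block = pd.concat([pol, lips], axis=1)[list(_POLARITY_COLS)]
    position = pd.DataFrame(
        {
            "residue_depth": depth_profile(length),
            "position_fraction": np.arange(length) / (length - 1),
            "tmd_length": float(length),
            "tmd_mean_polarity": np.nan_to_num(pol["polarity"]).mean(),
            "tmd_mean_conservation": np.nan_to_num(cons["conservation"]).mean(),
        }
    )
    flags = motif_and_physical_flags(seq)
    motif_block = flags[list(_MOTIF_COLS)]
    phys_block = flags[list(_PHYSICAL_COLS)]
    coevo = coevolution_features(aln, dca_params)
    frame = pd.concat(
        [coevo, pssm_block, cons, pol_block, position, motif_block, phys_block], axis=1
    )
    frame = frame.astype(float).fillna(0.0)
    frame.insert(0, "residue", list(seq))
    return frame


def assemble_feature_table(
    tmds, alignments: dict, dca_params: DcaParams | None = None
) -> pd.DataFrame:
    """Residue-level feature table over a set of TMDs.

    Index is (tmd_id, position) with 1-based positions; the ``interface``
    column holds labels where the record carries a mask and NaN elsewhere.
    Raises :class:`SchemaError` if the census drifts from 103.
    """
    frames = []
    for rec in tmds:
        aln = alignments.get(rec.id)
        if aln is None:
            raise errors.ConfigurationError(f"{rec.id}: no alignment provided")
        if aln.tmd_sequence != rec.sequence:
            raise errors.ConfigurationError(
                f"{rec.id}: alignment reference does not match the TMD sequence"
            )
        frame = tmd_feature_frame(aln, dca_params)
        frame["interface"] = (
            rec.interface_mask.astype(float) if rec.interface_mask is not None else np.nan
        )
        frame.index = pd.MultiIndex.from_product(
            [[rec.id], range(1, len(rec.sequence) + 1)], names=["tmd_id", "position"]
        )
        frames.append(frame)
    table = pd.concat(frames)
    _check_census(feature_columns(table))
    return table


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def select_features(
    table: pd.DataFrame,
    k: int = 27,
    seed: int = 0,
    step_fraction: float = 0.25,
    n_estimators: int = 50,
    n_splits: int = 4,
    n_repeats: int = 2,
) -> tuple[list, list]:
    """Recursive elimination on grouped-CV permutation importance.

    At each round an extremely-randomised-trees model is fitted per
    TMD-grouped fold and permutation importances (average-precision drop) are
    averaged over folds; the weakest quarter of the surviving features is
    eliminated until ``k`` remain.  Returns ``(selected, elimination_order)``
    where the elimination order lists dropped features worst-first.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    features = list(feature_columns(table))
    if k > len(features):
        raise ValueError(f"k={k} exceeds {len(features)} available features")
    labelled = table.dropna(subset=["interface"])
    y = labelled["interface"].to_numpy(int)
    groups = labelled.index.get_level_values("tmd_id").to_numpy()
    eliminated: list = []
    rng_seed = seed
    while len(features) > k:
        X = labelled[features].to_numpy(float)
        importances = np.zeros(len(features))
        cv = GroupKFold(n_splits=min(n_splits, len(np.unique(groups))))
        for fold, (tr, va) in enumerate(cv.split(X, y, groups)):
            est = ExtraTreesClassifier(
                n_estimators=n_estimators, random_state=rng_seed,
                class_weight="balanced", n_jobs=1,
            )
            est.fit(X[tr], y[tr])
            res = permutation_importance(
                est, X[va], y[va], scoring="average_precision",
                n_repeats=n_repeats, random_state=rng_seed + fold,
            )
            importances += res.importances_mean
        importances /= cv.get_n_splits()
        n_drop = min(len(features) - k, max(1, int(step_fraction * len(features))))
        # drop the weakest features; ties resolved by column order for determinism
        order = np.lexsort((np.arange(len(features)), importances))
        drop_idx = sorted(order[:n_drop], reverse=True)
        for i in drop_idx:
            eliminated.append(features[i])
        features = [f for i, f in enumerate(features) if i not in set(drop_idx)]
        rng_seed += 1
    return features, eliminated


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def train_classifier(
    table: pd.DataFrame,
    split: SplitSpec,
    grid: dict | None = None,
    seed: int = 0,
    features: list | None = None,
    n_splits: int = 5,
) -> TrainedModel:
    """Grouped grid search + refit of the extremely-randomised-trees classifier.

    Hyperparameters maximise mean average precision over TMD-grouped
    validation folds of the training split; the winning configuration is
    refitted on all training TMDs.
    """
    grid = grid or DEFAULT_GRID
    features = list(features) if features is not None else feature_columns(table)
    train_tbl = table.loc[table.index.get_level_values("tmd_id").isin(split.train_ids)]
    train_tbl = train_tbl.dropna(subset=["interface"])
    if train_tbl.empty:
        raise errors.EmptyDataError("no labelled training rows")
    y = train_tbl["interface"].to_numpy(int)
    if y.min() == y.max():
        raise errors.DegenerateLabelError("training labels contain a single class")
    X = train_tbl[features].to_numpy(float)
    groups = train_tbl.index.get_level_values("tmd_id").to_numpy()
    cv = GroupKFold(n_splits=min(n_splits, len(np.unique(groups))))
    base = ExtraTreesClassifier(random_state=seed, class_weight="balanced", n_jobs=1)
    search = GridSearchCV(
        base, grid, scoring="average_precision",
        cv=cv.split(X, y, groups), n_jobs=1, refit=False,
    )
    search.fit(X, y)
    best = ExtraTreesClassifier(
        random_state=seed, class_weight="balanced", n_jobs=1, **search.best_params_
    )
    best.fit(X, y)
    return TrainedModel(
        estimator=best,
        selected_features=tuple(features),
        hyperparameters=dict(search.best_params_),
        seed=seed,
        train_ids=tuple(sorted(set(groups))),
    )


def predict_interface(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Per-residue interface probabilities for one TMD's feature frame."""
    missing = set(model.selected_features) - set(features.columns)
    if missing:
        raise errors.SchemaError(f"feature frame missing columns {sorted(missing)}")
    X = features[list(model.selected_features)].to_numpy(float)
    proba = model.estimator.predict_proba(X)
    positive = list(model.estimator.classes_).index(1)
    return proba[:, positive]


def predictions_by_tmd(model: TrainedModel, table: pd.DataFrame, ids) -> dict:
    """Map tmd_id -> per-residue probabilities for the requested TMDs."""
    out = {}
    for tmd_id in ids:
        frame = table.loc[tmd_id]
        out[tmd_id] = predict_interface(model, frame)
    return out


def save_model(model: TrainedModel, path) -> None:
    """Versioned archive: fitted ensemble plus JSON-serialisable metadata."""
    payload = {
        "format_version": FORMAT_VERSION,
        "estimator": model.estimator,
        "metadata": json.dumps(
            {
                "selected_features": list(model.selected_features),
                "hyperparameters": model.hyperparameters,
                "seed": model.seed,
                "train_ids": list(model.train_ids),
            }
        ),
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != FORMAT_VERSION:
        raise errors.SchemaError("unsupported model archive version")
    meta = json.loads(payload["metadata"])
    return TrainedModel(
        estimator=payload["estimator"],
        selected_features=tuple(meta["selected_features"]),
        hyperparameters=meta["hyperparameters"],
        seed=meta["seed"],
        train_ids=tuple(meta["train_ids"]),
    )
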
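"""Random-forest species classifier over the feature-panel abundances."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import DataError
from .matrix import SCALE_LOG10, AbundanceMatrix
from .metrics import FeaturePanel


@dataclass
class ClassifierState:
    """Fitted forest plus everything needed to reapply it.

    ``feature_order`` is frozen at train time; prediction refuses any vector
    that is not aligned to it.
    """

    feature_order: list[str]
    species_classes: list[str]
    model: RandomForestClassifier
    seed: int
    n_trees: int
    oob_error: float | None


def train(
    matrix: AbundanceMatrix,
    panel: FeaturePanel,
    seed: int = 0,
    n_trees: int = 500,
) -> ClassifierState:
    """Fit the forest on log10-scale, fully imputed panel abundances.

    Out-of-bag error is recorded as the internal performance estimate; with
    very few samples per class some samples may never be out of bag, in
    which case sklearn's OOB machinery warns and the estimate is noisy.
    """
    if matrix.scale != SCALE_LOG10:
        raise DataError("classifier trains on the log10 scale")
    features = panel.feature_order
    missing = [p for p in features if p not in matrix.values.index]
    if missing:
        raise DataError(f"panel peptides absent from matrix: {missing[:5]}")
    X = matrix.values.loc[features].T.to_numpy()
    if np.isnan(X).any():
        raise DataError("training matrix contains missing values; impute first")
    y = matrix.species[matrix.values.columns].to_numpy()
    counts = pd.Series(y).value_counts()
    singletons = counts.index[counts < 2]
    if len(singletons):
        warnings.warn(
            f"species with a single sample (degenerate bootstrap): {list(singletons)}"
        )
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        model.fit(X, y)
    oob_error = float(1.0 - model.oob_score_) if hasattr(model, "oob_score_") else None
    return ClassifierState(
        feature_order=list(features),
        species_classes=[str(c) for c in model.classes_],
        model=model,
        seed=seed,
        n_trees=n_trees,
        oob_error=oob_error,
    )


def predict_proba(state: ClassifierState, query_vector: pd.Series) -> dict[str, float]:
    """Class probabilities for one aligned, fully imputed feature vector."""
    if list(query_vector.index) != state.feature_order:
        raise DataError("query vector is not aligned to the classifier feature order")
    if query_vector.isna().any():
        raise DataError("query vector contains missing values; impute first")
    proba = state.model.predict_proba(query_vector.to_numpy()[None, :])[0]
    return {sp: float(p) for sp, p in zip(state.species_classes, proba)}
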
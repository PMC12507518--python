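"""Elastic-net fine-tuning of Diff features against measured variant effects.

A single motif column of the Diff matrix is rarely the whole story: TF
binding in vivo is shaped by co-factors whose motifs also sit near the
variant.  The fine-tuning layer therefore treats the full variant x motif
Diff matrix as a feature block and fits an L1/L2-penalized (elastic-net)
linear regression to a measured allelic-effect value — typically a
z-score-like quantity, -log10(P) * sign(effect), that carries both the
direction and the confidence of the measured effect.

Evaluation is on a held-out split: Pearson correlation for the
quantitative task and, because effect magnitudes depend on per-variant
statistical power, AUROC of the predictions against the sign of the true
effect for the direction task.  ``single_motif_eval`` provides the
no-fitting baseline: the correlation between one motif's Diff column and
the effect values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .variant_scoring import DiffMatrix

DEFAULT_L1_RATIOS = (0.1, 0.5, 0.9)


@dataclass
class EvalReport:
    """Holdout evaluation of a fine-tuned model."""

    correlation: float
    auroc: float
    hyperparameters: dict = field(default_factory=dict)
    weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    n_train: int = 0
    n_holdout: int = 0

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"#correlation={self.correlation!r}\n")
            fh.write(f"#auroc={self.auroc!r}\n")
            for key, value in self.hyperparameters.items():
                fh.write(f"#{key}={value}\n")
            fh.write(f"#n_train={self.n_train}\n#n_holdout={self.n_holdout}\n")
            self.weights.rename("weight").to_csv(fh, sep="\t", index_label="motif")


def load_labels(path: str | Path) -> pd.DataFrame:
    """Read a label table (columns ``id`` and ``effect``) from TSV."""
    labels = pd.read_csv(path, sep="\t", comment="#")
    missing = {"id", "effect"} - set(labels.columns)
    if missing:
        raise ValueError(f"label table lacks required columns: {sorted(missing)}")
    return labels


def join_features_labels(
    diff: DiffMatrix | pd.DataFrame, labels: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Inner-join Diff rows to labels on variant id; report unmatched counts."""
    data = diff.data if isinstance(diff, DiffMatrix) else diff
    labels = labels.set_index("id") if "id" in labels.columns else labels
    common = data.index.intersection(labels.index)
    n_unmatched = (len(data) - len(common)) + (len(labels) - len(common))
    if len(common) == 0:
        raise ValueError("no variant ids shared between Diff matrix and label table")
    if n_unmatched:
        warnings.warn(
            f"{len(data) - len(common)} Diff rows and "
            f"{len(labels) - len(common)} labels had no match",
            stacklevel=2,
        )
    return data.loc[common], labels.loc[common, "effect"].astype(float)


def _clean_features(X: pd.DataFrame) -> pd.DataFrame:
    """Drop all-missing columns (warned) and impute remaining NaN as 0.

    A missing Diff means no scoreable binding change, so zero is the
    natural fill value.
    """
    all_missing = X.columns[X.isna().all()]
    if len(all_missing):
        warnings.warn(
            f"dropping {len(all_missing)} all-missing feature columns", stacklevel=2
        )
        X = X.drop(columns=all_missing)
    return X.fillna(0.0)


def fit_elastic_net(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    folds: int = 5,
    seed: int = 0,
    l1_ratios: tuple[float, ...] = DEFAULT_L1_RATIOS,
    n_alphas: int = 50,
) -> Pipeline:
    """Cross-validated elastic net on standardized features.

    Penalty strength (the alpha path, auto-scaled by scikit-learn) and the
    L1/L2 mixing ratio are chosen by k-fold cross-validation inside the
    training data; features are centred and scaled on the training split.
    """
    if isinstance(X, pd.DataFrame):
        X = _clean_features(X)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("labels are constant; nothing to fit")
    if len(y) < 2 * folds:
        raise ValueError(f"need at least {2 * folds} samples for {folds}-fold CV")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "enet",
                ElasticNetCV(
                    l1_ratio=list(l1_ratios),
                    alphas=n_alphas,  # length of the auto-scaled penalty path
                    cv=KFold(n_splits=folds, shuffle=True, random_state=seed),
                    random_state=seed,
                    max_iter=5000,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on weak-signal folds
        model.fit(X, y)
    return model


def sign_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC of continuous scores against the sign of the true effect.

    Returns NaN when only one sign class is present.
    """
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(y_true) > 0
    if labels.all() or not labels.any():
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores)))


def evaluate(
    model: Pipeline,
    X_holdout: pd.DataFrame | np.ndarray,
    y_holdout: pd.Series | np.ndarray,
    feature_names: list[str] | None = None,
) -> EvalReport:
    """Holdout Pearson correlation, sign AUROC, and the selected weights."""
    if isinstance(X_holdout, pd.DataFrame):
        feature_names = list(X_holdout.columns)
        X_holdout = _clean_features(X_holdout)
    y_holdout = np.asarray(y_holdout, dtype=float)
    preds = model.predict(X_holdout)
    corr = float(stats.pearsonr(preds, y_holdout).statistic) if np.ptp(preds) > 0 else float("nan")
    enet: ElasticNetCV = model.named_steps["enet"]
    coefs = enet.coef_
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(len(coefs))]
    weights = pd.Series(coefs, index=feature_names)
    weights = weights[weights != 0.0].sort_values(key=np.abs, ascending=False)
    return EvalReport(
        correlation=corr,
        auroc=sign_auroc(y_holdout, preds),
        hyperparameters={"alpha": float(enet.alpha_), "l1_ratio": float(enet.l1_ratio_)},
        weights=weights,
        n_holdout=len(y_holdout),
    )


def train_and_evaluate(
    diff: DiffMatrix | pd.DataFrame,
    labels: pd.DataFrame,
    test_size: float = 0.2,
    folds: int = 5,
    seed: int = 0,
    l1_ratios: tuple[float, ...] = DEFAULT_L1_RATIOS,
) -> EvalReport:
    """Join, split 80/20, fit on the training split, evaluate on holdout."""
    X, y = join_features_labels(diff, labels)
    X = _clean_features(X)
    X_train, X_hold, y_train, y_hold = train_test_split(
        X, y, test_size=test_size, random_state=seed
    )
    model = fit_elastic_net(X_train, y_train, folds=folds, seed=seed, l1_ratios=l1_ratios)
    report = evaluate(model, X_hold, y_hold, feature_names=list(X.columns))
    report.n_train = len(y_train)
    return report


def single_motif_eval(
    diff: DiffMatrix | pd.DataFrame, labels: pd.DataFrame, motif_name: str
) -> float:
    """Pearson correlation of one motif's Diff column with the effect values."""
    data = diff.data if isinstance(diff, DiffMatrix) else diff
    if motif_name not in data.columns:
        available = ", ".join(map(str, data.columns[:20]))
        raise KeyError(
            f"motif {motif_name!r} not in Diff matrix; available motifs include: {available}"
        )
    X, y = join_features_labels(data[[motif_name]], labels)
    col = X[motif_name].fillna(0.0).to_numpy()
    return float(stats.pearsonr(col, y.to_numpy()).statistic)
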
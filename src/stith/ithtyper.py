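"""ITHtyper: a compact heterogeneity gene signature and boosted classifier.

A bootstrap-aggregated autoencoder ranks genes by how faithfully a
capacity-constrained network reconstructs them (genes carrying the shared
heterogeneity structure reconstruct well; isolated noise genes do not);
the top genes form the signature.  A gradient-boosted tree classifier
(logistic objective) trained on the signature genes scores samples in
[0, 1]; scores at or above the 0.45 threshold call the high-complexity
(ITHtyper-hi) phenotype.  Discrimination is evaluated with rank-based
(Mann-Whitney) AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neural_network import MLPRegressor
from xgboost import XGBClassifier

__all__ = [
    "SignatureModel",
    "ScoreResult",
    "ROCResult",
    "PRINTED_SIGNATURE",
    "select_signature_genes",
    "train_classifier",
    "score_samples",
    "evaluate_roc",
]

# Reference 10-gene signature for scoring real SCLC data (PD-L1 -> CD274);
# models learned on synthetic cohorts carry their own learned gene lists.
PRINTED_SIGNATURE = (
    "NKX1-2", "TLE2", "TPBG", "GPR31", "SRSF6",
    "DAZ4", "CD274", "LYZ", "PCP4", "ZIC1",
)

DEFAULT_AE_CONFIG = {
    "hidden": (100, 300, 100),
    "activation": "tanh",
    "epochs": 10,
    # optimizer internals (unconstrained choices, recorded for audit)
    "solver": "adam",
    "learning_rate_init": 0.01,
    "batch_size": 16,
    "alpha": 10.0,  # strong weight decay: capacity control at small n
}

DEFAULT_BOOST_CONFIG = {
    "objective": "binary:logistic",
    "n_rounds": 100,
    "max_depth": 5,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "cv_folds": 5,
    "eval_metric": "error",
}

POSITIVE_CLASS = "HCs"  # scores estimate P(high-complexity class)


@dataclass
class SignatureModel:
    genes: list[str]
    importance: pd.Series  # gene -> mean bootstrap rank (lower = more important)
    ae_config: dict = field(default_factory=lambda: dict(DEFAULT_AE_CONFIG))
    boost_config: dict = field(default_factory=lambda: dict(DEFAULT_BOOST_CONFIG))
    threshold: float = 0.45
    train_fraction: float = 0.70
    seed: int = 0
    booster: XGBClassifier | None = None
    harmonize: str = "none"  # {"none", "rank"} feature transform
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    def save(self, path: str | Path) -> None:
        """Serialize as structured text: gene list, configs, tree ensemble."""
        payload = {
            "genes": self.genes,
            "importance": self.importance.to_dict(),
            "ae_config": {k: list(v) if isinstance(v, tuple) else v
                          for k, v in self.ae_config.items()},
            "boost_config": self.boost_config,
            "threshold": self.threshold,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "harmonize": self.harmonize,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "booster": (
                None if self.booster is None
                else self.booster.get_booster().save_raw("json").decode()
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SignatureModel":
        payload = json.loads(Path(path).read_text())
        booster = None
        if payload["booster"] is not None:
            booster = XGBClassifier()
            booster.load_model(bytearray(payload["booster"].encode()))
        return cls(
            genes=payload["genes"],
            importance=pd.Series(payload["importance"]),
            ae_config=payload["ae_config"],
            boost_config=payload["boost_config"],
            threshold=payload["threshold"],
            train_fraction=payload["train_fraction"],
            seed=payload["seed"],
            booster=booster,
            harmonize=payload["harmonize"],
            train_ids=payload["train_ids"],
            test_ids=payload["test_ids"],
        )


@dataclass
class ScoreResult:
    sample_id: str
    score: float
    label: str  # {ITHtyper-hi, ITHtyper-lo}


@dataclass
class ROCResult:
    auc: float
    curve: pd.DataFrame  # columns fpr, tpr


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def _fit_autoencoder(X: np.ndarray, cfg: dict, seed: int) -> MLPRegressor:
    model = MLPRegressor(
        hidden_layer_sizes=tuple(cfg["hidden"]),
        activation=cfg["activation"],
        solver=cfg["solver"],
        learning_rate_init=cfg["learning_rate_init"],
        batch_size=cfg["batch_size"],
        alpha=cfg["alpha"],
        max_iter=cfg["epochs"],
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ConvergenceWarning at epoch budget
        model.fit(X, X)
    return model


def _garson_importance(model: MLPRegressor) -> np.ndarray:
    """Aggregated absolute input-to-output weight-path magnitude."""
    path = None
    for W in model.coefs_:
        A = np.abs(W)
        path = A if path is None else path @ A
    return path.sum(axis=1)


def select_signature_genes(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_genes: int = 10,
    n_bootstrap: int = 25,
    subsample: float = 0.90,
    seed: int = 0,
    method: str = "reconstruction",
    ae_config: dict | None = None,
) -> SignatureModel:
    """Bootstrap autoencoder gene ranking; returns the top ``n_genes``.

    Per bootstrap, ``subsample`` of the samples are drawn without
    replacement, a tanh autoencoder (hidden 100/300/100, 10 epochs) is fit
    to the standardized expression, and genes are ranked by importance:

    * "reconstruction" (default): per-gene reconstruction fidelity, i.e.
      low mean squared reconstruction error on the standardized scale;
    * "garson": aggregated absolute input-to-output weight-path magnitude.

    The final importance is each gene's mean rank across bootstraps.
    """
    genes = list(matrix.index)
    if n_genes > len(genes):
        raise ValueError(f"n_genes={n_genes} exceeds available genes ({len(genes)})")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    classes = set(labels.loc[matrix.columns])
    if len(classes) < 2:
        raise ValueError(f"need both classes in labels, got {classes}")
    if method not in ("reconstruction", "garson"):
        raise ValueError(f"unknown method {method!r}")
    cfg = dict(DEFAULT_AE_CONFIG, **(ae_config or {}))

    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    n = X.shape[0]
    n_sub = max(2, int(round(subsample * n)))
    ranks = np.zeros((n_bootstrap, len(genes)))
    for b in range(n_bootstrap):
        idx = rng.choice(n, n_sub, replace=False)
        model = _fit_autoencoder(Xs[idx], cfg, int(rng.integers(2**31)))
        if method == "garson":
            imp = _garson_importance(model)
        else:
            mse = ((Xs[idx] - model.predict(Xs[idx])) ** 2).mean(axis=0)
            imp = -mse
        # rank 1 = most important; average ranks on ties
        ranks[b] = stats.rankdata(-imp)
    mean_rank = pd.Series(ranks.mean(axis=0), index=genes, name="mean_rank")
    ordered = mean_rank.sort_values(kind="stable")
    return SignatureModel(
        genes=list(ordered.index[:n_genes]),
        importance=mean_rank,
        ae_config=cfg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def _rank_scale(X: np.ndarray) -> np.ndarray:
    """Per-sample rank scaling of the signature-gene vector to [0, 1]."""
    r = stats.rankdata(X, axis=1)
    return (r - 1) / (X.shape[1] - 1)


def _features(matrix: pd.DataFrame, genes: list[str], harmonize: str) -> np.ndarray:
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValueError(f"signature gene(s) missing from profiles: {missing}")
    X = matrix.loc[genes].to_numpy(dtype=float).T
    if harmonize == "rank":
        X = _rank_scale(X)
    elif harmonize != "none":
        raise ValueError(f"unknown harmonization {harmonize!r}")
    return X


def train_classifier(
    matrix: pd.DataFrame,
    labels: pd.Series,
    model: SignatureModel | None = None,
    genes: list[str] | None = None,
    boost_config: dict | None = None,
    train_fraction: float = 0.70,
    patient_map: pd.Series | None = None,
    harmonize: str = "none",
    seed: int = 0,
) -> SignatureModel:
    """Fit the boosted-tree classifier on a train split of the samples.

    The 70/30 split is performed at the patient level when ``patient_map``
    is given (no patient spans both splits); otherwise samples split
    independently.  ``labels`` maps sample -> {HCs, LCs}-style class; the
    positive class is the one matching ``POSITIVE_CLASS`` as a prefix.
    ``train_fraction=1.0`` disables the held-out split (warned).
    """
    if model is None:
        if genes is None:
            raise ValueError("provide a SignatureModel or an explicit gene list")
        model = SignatureModel(genes=list(genes),
                               importance=pd.Series(dtype=float), seed=seed)
    cfg = dict(DEFAULT_BOOST_CONFIG, **(boost_config or {}))
    y_all = labels.loc[matrix.columns].astype(str)
    y_bin = y_all.str.startswith(POSITIVE_CLASS).astype(int)
    if y_bin.nunique() < 2:
        raise ValueError("labels contain a single class")

    rng = np.random.default_rng(seed)
    samples = list(matrix.columns)
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    if train_fraction == 1.0:
        warnings.warn("train_fraction=1.0: no test split, evaluation disabled")
        train_ids, test_ids = samples, []
    elif patient_map is not None:
        patients = sorted(set(patient_map.loc[samples]))
        rng.shuffle(patients)
        n_train = int(round(train_fraction * len(patients)))
        train_patients = set(patients[:n_train])
        train_ids = [s for s in samples if patient_map[s] in train_patients]
        test_ids = [s for s in samples if patient_map[s] not in train_patients]
    else:
        order = list(samples)
        rng.shuffle(order)
        n_train = int(round(train_fraction * len(order)))
        train_ids, test_ids = order[:n_train], order[n_train:]

    if y_bin.loc[train_ids].nunique() < 2 or (test_ids and y_bin.loc[test_ids].nunique() < 2):
        raise ValueError("a split is missing a class; try another seed")

    X_train = _features(matrix[train_ids], model.genes, harmonize)
    booster = XGBClassifier(
        objective=cfg["objective"],
        n_estimators=cfg["n_rounds"],
        max_depth=cfg["max_depth"],
        subsample=cfg["subsample"],
        colsample_bytree=cfg["colsample_bytree"],
        eval_metric=cfg["eval_metric"],
        random_state=seed,
        verbosity=0,
    )
    booster.fit(X_train, y_bin.loc[train_ids].to_numpy())
    model.booster = booster
    model.boost_config = cfg
    model.train_fraction = train_fraction
    model.harmonize = harmonize
    model.seed = seed
    model.train_ids = [str(s) for s in train_ids]
    model.test_ids = [str(s) for s in test_ids]
    return model


def score_samples(model: SignatureModel, profiles: pd.DataFrame) -> list[ScoreResult]:
    """Score profiles (gene x sample) with the fitted classifier.

    Scores are P(high-complexity) in [0, 1]; labels apply the model's
    threshold (default 0.45): score >= threshold -> ITHtyper-hi.  Bulk
    profiles should be scored with a model trained with
    ``harmonize="rank"`` so that per-sample signature-gene ranks, not
    platform-specific magnitudes, drive the features.
    """
    if model.booster is None:
        raise ValueError("model has no fitted classifier; run train_classifier")
    X = _features(profiles, model.genes, model.harmonize)
    scores = model.booster.predict_proba(X)[:, 1]
    return [
        ScoreResult(
            sample_id=str(s),
            score=float(p),
            label="ITHtyper-hi" if p >= model.threshold else "ITHtyper-lo",
        )
        for s, p in zip(profiles.columns, scores)
    ]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_roc(scores, truth) -> ROCResult:
    """AUC by the rank (Mann-Whitney) formulation with midrank ties.

    ``truth`` is binary (1/True = positive class).  The curve is the
    standard empirical ROC stepping through unique score thresholds.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("truth must contain both classes")
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = stats.rankdata(s)
    auc = (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    order = np.argsort(-s, kind="stable")
    tps = np.cumsum(y[order])
    fps = np.cumsum(1 - y[order])
    # collapse ties so each unique score contributes one point
    keep = np.r_[np.diff(s[order]) != 0, True]
    curve = pd.DataFrame(
        {
            "fpr": np.r_[0.0, fps[keep] / n0],
            "tpr": np.r_[0.0, tps[keep] / n1],
        }
    )
    return ROCResult(auc=float(auc), curve=curve)
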
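"""Feature fusion and the three-stage signature selection chain.

Blocks of per-patient features (handcrafted HC, transfer-learning TL,
fine-tuned FT) are concatenated into one fused matrix, then reduced by

1. a median-absolute-deviation (MAD) dispersion filter,
2. greedy minimum-redundancy maximum-relevance (mRMR, MID criterion)
   selection of ``k`` features against the histology label, and
3. an L1-penalised multinomial logistic model (LASSO) whose penalty is
   chosen by stratified cross-validation; the signature is the set of
   features with any nonzero class coefficient at the CV-optimal penalty.

An empty signature is a valid outcome of stage 3, not an error: a block
with no label-relevant features simply yields no signature, and the
pipeline carries on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .core import BLOCKS

_COEF_TOL = 1e-8


@dataclass
class FusedFeatureMatrix:
    """Patients x features matrix with per-column block provenance."""

    matrix: pd.DataFrame  # patients x features
    blocks: pd.Series  # feature name -> block tag

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate feature names in fused matrix")
        if self.matrix.isna().to_numpy().any():
            raise ValueError("fused matrix contains missing values")
        self.blocks = self.blocks.reindex(self.matrix.columns)
        bad = set(self.blocks.unique()) - set(BLOCKS)
        if bad:
            raise ValueError(f"unknown block tags: {bad}")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, columns: list[str]) -> "FusedFeatureMatrix":
        return FusedFeatureMatrix(self.matrix[columns], self.blocks[columns])


@dataclass
class Signature:
    """Selected feature subset with its provenance and selection trace."""

    feature_ids: list[str]
    source: str  # FF, HC, TL or FT
    trace: dict = field(default_factory=dict)
    lambda_min: float | None = None

    def __len__(self) -> int:
        return len(self.feature_ids)

    @property
    def empty(self) -> bool:
        return len(self.feature_ids) == 0


@dataclass
class SelectionConfig:
    mad_drop_quantile: float = 0.25
    mrmr_k: int = 100
    lasso_folds: int = 10
    lasso_n_lambdas: int = 100
    lasso_decades: float = 4.0


def fuse(blocks: list[pd.DataFrame],
         block_tags: list[str]) -> FusedFeatureMatrix:
    """Column-wise concatenation of per-block feature tables.

    All tables must carry identical patient indices in identical order.
    """
    if len(blocks) != len(block_tags):
        raise ValueError("one block tag per table required")
    base = blocks[0].index
    for tbl in blocks[1:]:
        if not tbl.index.equals(base):
            raise ValueError("patient sets/order differ between blocks")
    matrix = pd.concat(blocks, axis=1)
    tags = pd.Series(
        np.concatenate([[t] * b.shape[1] for t, b in zip(block_tags, blocks)]),
        index=matrix.columns,
    )
    return FusedFeatureMatrix(matrix, tags)


def mad_values(matrix: pd.DataFrame) -> pd.Series:
    """Per-feature median absolute deviation about the median."""
    med = matrix.median(axis=0)
    return (matrix - med).abs().median(axis=0)


def mad_filter(m: FusedFeatureMatrix,
               drop_quantile: float = 0.25) -> FusedFeatureMatrix:
    """Drop features with MAD strictly below the given quantile of the MAD
    distribution; zero-MAD (near-constant) features are always dropped."""
    if m.matrix.shape[0] < 2:
        raise ValueError("MAD filter needs at least 2 patients")
    mads = mad_values(m.matrix)
    cut = mads.quantile(drop_quantile)
    keep = (mads >= cut) & (mads > 0)
    if not keep.any():
        raise ValueError(
            "MAD filter removed every feature; lower drop_quantile"
        )
    return m.subset(list(m.matrix.columns[keep]))


def discretise_3state(matrix: np.ndarray) -> np.ndarray:
    """Per-feature 3-state discretisation at mean +/- sd (0: low, 1: mid,
    2: high)."""
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    out = np.ones(matrix.shape, dtype=np.int8)
    out[matrix < mu - sd] = 0
    out[matrix > mu + sd] = 2
    return out


def _mi_many(D: np.ndarray, y: np.ndarray, n_y: int) -> np.ndarray:
    """Mutual information (nats) between each column of 3-state ``D`` and
    the integer label vector ``y``, vectorised over columns."""
    n, p = D.shape
    codes = D.astype(np.intp) * n_y + y[:, None]
    flat = codes + (np.arange(p) * (3 * n_y))[None, :]
    counts = np.bincount(flat.ravel(), minlength=p * 3 * n_y).reshape(p, 3, n_y)
    joint = counts / n
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return np.nansum(terms, axis=(1, 2))


def mrmr_select(m: FusedFeatureMatrix, histology: pd.Series | np.ndarray,
                k: int = 100) -> FusedFeatureMatrix:
    """Greedy mRMR (MID criterion) selection of ``k`` features.

    Features are discretised to 3 states at mean +/- sd; the first pick
    maximises MI with the label and each later pick maximises
    MI(feature; label) - mean MI(feature; already selected).  Score ties
    break towards the earlier column.  Returns the selected columns in
    selection order.
    """
    y_codes, classes = pd.factorize(pd.Series(np.asarray(histology)))
    if len(classes) < 2:
        raise ValueError("histology labels have a single class")
    p = m.n_features
    if k > p:
        warnings.warn(f"k={k} exceeds {p} surviving features; selecting all",
                      stacklevel=2)
        k = p
    D = discretise_3state(m.matrix.to_numpy())
    relevance = _mi_many(D, y_codes.astype(np.intp), len(classes))
    selected = [int(np.argmax(relevance))]
    red_sum = np.zeros(p)
    mask = np.zeros(p, dtype=bool)
    mask[selected[0]] = True
    while len(selected) < k:
        red_sum += _mi_many(D, D[:, selected[-1]].astype(np.intp), 3)
        score = relevance - red_sum / len(selected)
        score[mask] = -np.inf
        nxt = int(np.argmax(score))
        selected.append(nxt)
        mask[nxt] = True
    return m.subset(list(m.matrix.columns[selected]))


def _standardise(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _lambda_path(X: np.ndarray, y_codes: np.ndarray, n_classes: int,
                 n_lambdas: int, decades: float) -> np.ndarray:
    """Log-spaced penalty path from the smallest lambda that zeroes every
    coefficient (given class-proportion intercepts) down ``decades``."""
    n = X.shape[0]
    Y = np.eye(n_classes)[y_codes]
    pi = Y.mean(axis=0)
    grad = X.T @ (Y - pi) / n  # p x c
    # 1.1 safety factor: the top of the path sits strictly inside the
    # all-zero region instead of exactly on the stationarity boundary
    lam_max = 1.1 * max(np.abs(grad).max(), 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades,
                       n_lambdas)


def _fit_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
              seed: int) -> list[np.ndarray]:
    """Warm-started L1 multinomial fits along a descending penalty path."""
    n = X.shape[0]
    clf = LogisticRegression(penalty="l1", solver="saga", warm_start=True,
                             max_iter=3000, tol=1e-4, C=1.0,
                             random_state=seed)
    coefs = []
    for lam in lambdas:
        clf.set_params(C=1.0 / (lam * n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        coefs.append(clf.coef_.copy())
    return coefs


def lasso_select(m: FusedFeatureMatrix, histology: pd.Series | np.ndarray,
                 folds: int = 10, seed: int = 0,
                 n_lambdas: int = 100, decades: float = 4.0,
                 source: str = "FF",
                 trace: dict | None = None) -> Signature:
    """LASSO stage: multinomial L1 path + stratified CV deviance.

    The signature is the set of features with any nonzero class
    coefficient at the penalty minimising mean held-out multinomial
    deviance.  An empty selection is returned as an empty ``Signature``.
    """
    y = np.asarray(pd.Series(np.asarray(histology)).astype(str))
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("histology labels have a single class")
    X = _standardise(m.matrix.to_numpy())
    y_codes = np.searchsorted(classes, y)
    lambdas = _lambda_path(X, y_codes, len(classes), n_lambdas, decades)

    min_class = pd.Series(y).value_counts().min()
    eff_folds = min(folds, int(min_class))
    if eff_folds < folds:
        warnings.warn(
            f"reducing CV folds from {folds} to {eff_folds}: smallest class "
            f"has {min_class} patients", stacklevel=2)
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    deviance = np.zeros(len(lambdas))
    for tr, te in skf.split(X, y):
        clf = LogisticRegression(penalty="l1", solver="saga", warm_start=True,
                                 max_iter=3000, tol=1e-4, C=1.0,
                                 random_state=seed)
        for li, lam in enumerate(lambdas):
            clf.set_params(C=1.0 / (lam * len(tr)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X[tr], y[tr])
            prob = clf.predict_proba(X[te])
            deviance[li] += log_loss(y[te], prob, labels=list(clf.classes_))
    deviance /= eff_folds
    best = int(np.argmin(deviance))
    lam_star = float(lambdas[best])

    coefs = _fit_path(X, y, lambdas[: best + 1], seed)[-1]
    nonzero = np.abs(coefs).max(axis=0) > _COEF_TOL
    feature_ids = list(m.matrix.columns[nonzero])
    full_trace = dict(trace or {})
    full_trace.update({
        "lasso_in": m.n_features,
        "selected": len(feature_ids),
        "lambda_min": lam_star,
        "cv_deviance_min": float(deviance[best]),
        "cv_folds": eff_folds,
    })
    return Signature(feature_ids=feature_ids, source=source,
                     trace=full_trace, lambda_min=lam_star)


def select_signature(m: FusedFeatureMatrix, histology, source: str,
                     config: SelectionConfig | None = None,
                     seed: int = 0) -> Signature:
    """Run the full MAD -> mRMR -> LASSO chain on one feature matrix."""
    cfg = config or SelectionConfig()
    trace = {"input": m.n_features}
    m1 = mad_filter(m, cfg.mad_drop_quantile)
    trace["after_mad"] = m1.n_features
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        m2 = mrmr_select(m1, histology, min(cfg.mrmr_k, m1.n_features))
    trace["after_mrmr"] = m2.n_features
    return lasso_select(m2, histology, folds=cfg.lasso_folds, seed=seed,
                        n_lambdas=cfg.lasso_n_lambdas,
                        decades=cfg.lasso_decades, source=source, trace=trace)


def build_signatures(hc: pd.DataFrame, tl: pd.DataFrame, ft: pd.DataFrame,
                     histology, config: SelectionConfig | None = None,
                     seed: int = 0) -> dict[str, Signature]:
    """Signatures for the fused matrix (FF) and each block alone."""
    fused = fuse([hc, tl, ft], ["HC", "TL", "FT"])
    out = {"FF": select_signature(fused, histology, "FF", config, seed)}
    for tag, tbl in (("HC", hc), ("TL", tl), ("FT", ft)):
        single = fuse([tbl], [tag])
        out[tag] = select_signature(single, histology, tag, config, seed)
    return out
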
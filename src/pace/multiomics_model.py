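"""Multivariate drug-response modelling: lasso variance decomposition and
sparse adaptive-lasso predictor profiles.

Per drug, the response is a dose summary (all-5 mean for cytotoxics, low-2
mean for targeted drugs).  Predictor blocks are the field's usual data types:
demographics (age, sex), binary genetics, IGHV status, pretreatment, and the
top 20 principal components of the expression and methylation matrices.  For
each block — and the concatenation of all blocks — an L1-penalized linear
model with lambda chosen by inner cross-validation is fit repeatedly on
shuffled fold assignments, and the out-of-fold R^2 = 1 - SS_res/SS_tot is
reported as mean +- sd over the repetitions (negative estimates floored at 0
for reporting, since the quantity of interest is nonnegative explanatory
power).

Predictor profiles come from a two-stage adaptive lasso: a ridge fit supplies
per-feature weights w_j = 1/|beta_j|, and the second-stage lasso with
per-feature penalty w_j (lambda again by cross-validation) yields a sparse
signed profile on the original feature scale.  Negative coefficients mean
lower viability — greater sensitivity — when the feature is present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LassoCV, RidgeCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureBlocks",
    "build_blocks",
    "VarianceDecomposition",
    "cv_lasso_r2",
    "PredictorProfile",
    "adaptive_lasso_profile",
]

MAX_PCS = 20


@dataclass
class FeatureBlocks:
    """Named predictor blocks sharing a sample universe."""

    blocks: dict[str, pd.DataFrame]

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.blocks[name]

    def names(self) -> list[str]:
        return list(self.blocks.keys())

    def concatenated(self, names: list[str] | None = None) -> pd.DataFrame:
        """Inner-join concatenation of the requested blocks ('all')."""
        names = names or [n for n in self.blocks if n != "all"]
        frames = [self.blocks[n] for n in names]
        out = pd.concat(frames, axis=1, join="inner")
        return out


def _top_pcs(matrix: pd.DataFrame, prefix: str, n_components: int = MAX_PCS) -> pd.DataFrame:
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicated sample row in {prefix} matrix: {dup!r}")
    x = matrix.values - matrix.values.mean(axis=0, keepdims=True)
    k = min(n_components, min(x.shape) - 1 if min(x.shape) > 1 else 1, np.linalg.matrix_rank(x))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    return pd.DataFrame(
        scores, index=matrix.index, columns=[f"{prefix}_pc{i + 1}" for i in range(k)]
    )


def build_blocks(
    annotation: pd.DataFrame,
    features: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
) -> FeatureBlocks:
    """Assemble predictor blocks from annotations, genetics and omic matrices.

    Blocks: demographics (age, sex), genetics (binary features), IGHV (0/1,
    U = 1), pretreatment (0/1), expression_pc / methylation_pc (top 20 PCs of
    the column-centered matrices, fewer if rank-limited), and 'all'.  Samples
    missing a whole block are simply absent from that block's frame; models
    drop them with a logged count.
    """
    if annotation.index.duplicated().any():
        raise ValueError("duplicated sample ids in annotation")
    samples = annotation.index
    blocks: dict[str, pd.DataFrame] = {}
    demo = pd.DataFrame(
        {"age": annotation["age"].astype(float), "sex_male": annotation["sex_male"].astype(float)},
        index=samples,
    ).dropna()
    blocks["demographics"] = demo
    gen_cols = [c for c in features.columns if c != "methylation_cluster"]
    blocks["genetics"] = features[gen_cols].dropna(how="any").astype(float)
    blocks["IGHV"] = pd.DataFrame(
        {"IGHV_U": (annotation["IGHV"] == "U").astype(float)[annotation["IGHV"].notna()]}
    )
    blocks["pretreatment"] = pd.DataFrame(
        {"pretreated": annotation["pretreated"].astype(float)}
    ).dropna()
    if expression is not None:
        blocks["expression_pc"] = _top_pcs(expression, "expr")
    if methylation is not None:
        blocks["methylation_pc"] = _top_pcs(methylation, "meth")

    universe = set(samples)
    for name, frame in blocks.items():
        n_drop = len(universe) - len(set(frame.index) & universe)
        if n_drop:
            logger.info("block %s: %d samples missing and dropped from models using it",
                        name, n_drop)
    fb = FeatureBlocks(blocks)
    all_frame = fb.concatenated()
    if all_frame.shape[0] < 3:
        raise ValueError("fewer than 3 samples remain after reconciling blocks")
    fb.blocks["all"] = all_frame
    return fb


@dataclass
class VarianceDecomposition:
    """Cross-validated per-block explained variance for one drug."""

    drug_id: str
    r2_mean: dict[str, float]
    r2_sd: dict[str, float]
    n_repetitions: int
    cv_folds: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r2_mean": pd.Series(self.r2_mean), "r2_sd": pd.Series(self.r2_sd)}
        )


def _cv_r2_once(
    x: np.ndarray, y: np.ndarray, folds: int, rs: int,
    inner_folds: int, n_alphas: int, lambda_rule: str,
) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=rs)
    pred = np.empty_like(y)
    for train, test in kf.split(x):
        scaler = StandardScaler().fit(x[train])
        xt = scaler.transform(x[train])
        model = LassoCV(
            cv=inner_folds, alphas=n_alphas, max_iter=5000, tol=1e-3,
            random_state=rs,
        ).fit(xt, y[train])
        alpha = model.alpha_
        if lambda_rule == "1se":
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
            best = int(np.argmin(mse))
            ok = np.where(mse <= mse[best] + se[best])[0]
            alpha = float(model.alphas_[ok.min()])  # largest alpha within 1 SE
            from sklearn.linear_model import Lasso

            model = Lasso(alpha=alpha, max_iter=5000, tol=1e-3).fit(xt, y[train])
        pred[test] = model.predict(scaler.transform(x[test]))
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def cv_lasso_r2(
    y: pd.Series,
    blocks: FeatureBlocks,
    drug_id: str = "",
    repetitions: int = 100,
    folds: int = 10,
    seed: int = 0,
    inner_folds: int = 5,
    n_alphas: int = 30,
    lambda_rule: str = "min",
    block_names: list[str] | None = None,
) -> VarianceDecomposition:
    """Out-of-fold lasso R^2 per predictor block, mean +- sd over repetitions.

    Each repetition reshuffles the outer fold assignment; lambda is chosen on
    the training folds only (inner CV, minimum-error rule by default, '1se'
    available), and predictors are standardized within training folds only.
    Negative out-of-fold R^2 values are floored at 0.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    names = block_names or blocks.names()
    r2_mean: dict[str, float] = {}
    r2_sd: dict[str, float] = {}
    rng = np.random.default_rng(seed)
    for name in names:
        frame = blocks[name]
        common = frame.index.intersection(y.dropna().index)
        if len(common) < 2 * folds:
            raise ValueError(
                f"block {name!r}: only {len(common)} samples with response; need >= {2 * folds}"
            )
        yv = y.loc[common].values.astype(float)
        if np.std(yv) == 0:
            raise ValueError("constant response")
        xv = frame.loc[common].values.astype(float)
        r2s = np.empty(repetitions)
        for rep in range(repetitions):
            rs = int(rng.integers(0, 2**31 - 1))
            r2s[rep] = max(
                0.0,
                _cv_r2_once(xv, yv, folds, rs, inner_folds, n_alphas, lambda_rule),
            )
        r2_mean[name] = float(np.mean(r2s))
        r2_sd[name] = float(np.std(r2s, ddof=1)) if repetitions > 1 else 0.0
    return VarianceDecomposition(drug_id, r2_mean, r2_sd, repetitions, folds, seed)


@dataclass
class PredictorProfile:
    """Sparse signed predictor profile for one drug."""

    drug_id: str
    coefficients: pd.Series  # non-zero only, original feature scale
    intercept: float
    alpha: float  # second-stage lambda chosen by CV
    weights: pd.Series  # adaptive per-feature penalty weights


def adaptive_lasso_profile(
    y: pd.Series,
    features: pd.DataFrame,
    drug_id: str = "",
    seed: int = 0,
    inner_folds: int = 5,
    gamma: float = 1.0,
    lambda_rule: str = "1se",
) -> PredictorProfile:
    """Two-stage adaptive lasso: ridge weights, weighted L1, CV-chosen lambda.

    Stage 1 fits ridge regression (alpha by CV) on standardized predictors and
    sets w_j = 1 / |beta_j|^gamma; stage 2 solves the lasso on predictors
    rescaled by 1/w_j, which is equivalent to a per-feature penalty of w_j.
    The second-stage lambda uses the one-standard-error rule by default: the
    profile exists to display a sparse biomarker signature, so the sparsest
    model within one SE of the CV optimum is preferred (``lambda_rule='min'``
    gives the CV-minimum instead).  Coefficients are reported on the original
    feature scale; only non-zero entries are kept.  Units: percent-viability
    change per unit feature.
    """
    common = features.dropna(how="any").index.intersection(y.dropna().index)
    if len(common) < 10:
        raise ValueError(f"adaptive_lasso_profile: only {len(common)} complete samples")
    yv = y.loc[common].values.astype(float)
    if np.std(yv) == 0:
        raise ValueError("constant response")
    x = features.loc[common].values.astype(float)
    cols = list(features.columns)

    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    ridge = RidgeCV(alphas=np.logspace(-3, 3, 25)).fit(xs, yv)
    beta1 = np.abs(ridge.coef_) ** gamma
    w = 1.0 / np.maximum(beta1, 1e-10)
    xw = xs * beta1[None, :]  # lasso on xw == weighted-penalty lasso on xs
    lasso = LassoCV(cv=inner_folds, alphas=50, max_iter=10000, tol=1e-4,
                    random_state=int(seed)).fit(xw, yv)
    alpha = float(lasso.alpha_)
    if lambda_rule == "1se":
        mse = lasso.mse_path_.mean(axis=1)
        se = lasso.mse_path_.std(axis=1, ddof=1) / np.sqrt(lasso.mse_path_.shape[1])
        best = int(np.argmin(mse))
        within = np.where(mse <= mse[best] + se[best])[0]
        alpha = float(lasso.alphas_[within.min()])  # alphas_ sorted descending
        from sklearn.linear_model import Lasso

        lasso = Lasso(alpha=alpha, max_iter=10000, tol=1e-4).fit(xw, yv)
    elif lambda_rule != "min":
        raise ValueError("lambda_rule must be 'min' or '1se'")
    coef_std = lasso.coef_ * beta1  # back to standardized-predictor scale
    with np.errstate(divide="ignore", invalid="ignore"):
        coef_orig = np.where(scaler.scale_ > 0, coef_std / scaler.scale_, 0.0)
    intercept = float(np.mean(yv) - np.sum(coef_orig * scaler.mean_))
    nz = np.abs(coef_orig) > 0
    return PredictorProfile(
        drug_id=drug_id,
        coefficients=pd.Series(coef_orig[nz], index=[c for c, k in zip(cols, nz) if k]),
        intercept=intercept,
        alpha=alpha,
        weights=pd.Series(w, index=cols),
    )
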
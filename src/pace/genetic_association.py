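"""Gene-drug association testing.

Per-drug viability matrices (samples x concentrations) are collapsed to one
value per sample with Tukey's median polish — the two-way table is decomposed
into overall + row (sample) + column (concentration) effects + residuals, and
the per-sample aggregate is overall + row effect, i.e. the concentration trend
is removed robustly.  Aggregates are then tested against binary genetic
features (Student's two-sample t test, optionally a two-factor linear model
when blocking on a nuisance covariate such as pretreatment), with
Benjamini-Hochberg FDR control applied once across the whole drug x feature
family.

The pooled-variance (Student) t is the default rather than Welch: recurrent
aberrations often have only a handful of carriers, and with 3-10 samples in
one group the Satterthwaite degrees-of-freedom estimate is unstable, inflating
the far tail of the null several-fold — exactly the region an FDR scan reads.
The pooled statistic is calibrated there; Welch remains available via
``equal_var=False`` for strongly heteroscedastic responses.

The module also houses the per-concentration volcano scan, Fisher exact
co-occurrence tests for genetic features, and parametric gene-set enrichment
(PAGE): Z = (Sm - mu) * sqrt(m) / sigma for a set of size m with mean gene
statistic Sm against a universe with mean mu and sd sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio
from statsmodels.stats.multitest import multipletests

from .screen_core import ViabilityTensor

__all__ = [
    "MedianPolishFit",
    "median_polish",
    "assoc_test",
    "bh_adjust",
    "association_scan",
    "volcano_per_concentration",
    "fisher_cooccurrence",
    "FisherResult",
    "page_enrichment",
    "EnrichmentResult",
]


@dataclass
class MedianPolishFit:
    """Result of a Tukey median polish of a two-way table.

    For every observed cell, ``overall + row_effects[i] + col_effects[j] +
    residuals[i, j]`` reconstructs the input exactly.  Rows/columns with no
    observations are dropped; ``row_kept``/``col_kept`` map back to the input
    and ``row_effects_full`` carries NaN at dropped positions.
    """

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool
    row_kept: np.ndarray
    col_kept: np.ndarray

    @property
    def row_effects_full(self) -> np.ndarray:
        out = np.full(self.row_kept.shape, np.nan)
        out[self.row_kept] = self.row_effects
        return out


def median_polish(
    m: np.ndarray, eps: float = 0.01, max_iter: int = 10, rows_first: bool = True
) -> MedianPolishFit:
    """Tukey's median polish with the classical defaults.

    Alternating row/column median sweeps (rows first) until the reduction in
    the sum of absolute residuals falls below ``eps`` (relative) or
    ``max_iter`` sweeps.  NaN cells are ignored; all-missing rows or columns
    are dropped with a warning.
    """
    x = np.asarray(m, dtype=float)
    if x.ndim != 2:
        raise ValueError("median_polish expects a 2-D matrix")
    row_kept = ~np.all(np.isnan(x), axis=1)
    col_kept = ~np.all(np.isnan(x), axis=0)
    if not row_kept.all() or not col_kept.all():
        warnings.warn(
            f"median_polish: dropping {int((~row_kept).sum())} all-missing rows and "
            f"{int((~col_kept).sum())} all-missing columns",
            stacklevel=2,
        )
    x = x[np.ix_(row_kept, col_kept)]
    nr, nc = x.shape
    if nr < 2 or nc < 2:
        raise ValueError("median_polish needs >= 2 rows and >= 2 columns with observations")

    def _nanmedian(a, axis):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(a, axis=axis)

    overall = 0.0
    re = np.zeros(nr)
    ce = np.zeros(nc)
    resid = x.copy()
    oldsum = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sweeps = ("rows", "cols") if rows_first else ("cols", "rows")
        for which in sweeps:
            if which == "rows":
                rdelta = _nanmedian(resid, axis=1)
                rdelta = np.where(np.isnan(rdelta), 0.0, rdelta)
                resid -= rdelta[:, None]
                re += rdelta
                delta = float(np.median(ce))
                ce -= delta
                overall += delta
            else:
                cdelta = _nanmedian(resid, axis=0)
                cdelta = np.where(np.isnan(cdelta), 0.0, cdelta)
                resid -= cdelta[None, :]
                ce += cdelta
                delta = float(np.median(re))
                re -= delta
                overall += delta
        newsum = float(np.nansum(np.abs(resid)))
        if newsum == 0.0 or abs(newsum - oldsum) < eps * newsum:
            converged = True
            break
        oldsum = newsum

    return MedianPolishFit(
        overall=overall,
        row_effects=re,
        col_effects=ce,
        residuals=resid,
        iterations=it,
        converged=converged,
        row_kept=row_kept,
        col_kept=col_kept,
    )


def assoc_test(
    y: pd.Series | np.ndarray,
    feature: pd.Series | np.ndarray,
    block: pd.Series | np.ndarray | None = None,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-group association of a per-sample aggregate with a binary feature.

    Returns ``(effect, p)`` where effect = mean(feature present) - mean(absent)
    in percent-viability points.  Unblocked: two-sample t test (Student's
    pooled-variance by default, Welch with ``equal_var=False``).  Blocked: a
    two-factor linear model ``y ~ feature + block``; the effect and p come
    from the feature coefficient.  Samples with missing y or feature (or block)
    are excluded; a feature level left empty yields ``(nan, nan)`` + warning.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(feature, dtype=float)
    arrays = [y, f]
    if block is not None:
        b = np.asarray(block, dtype=float)
        arrays.append(b)
    ok = ~np.any([np.isnan(a) for a in arrays], axis=0)
    y, f = y[ok], f[ok]
    n1, n0 = int((f == 1).sum()), int((f == 0).sum())
    if n1 < 2 or n0 < 2:
        warnings.warn(
            f"assoc_test: feature level with <2 samples (present={n1}, absent={n0}); skipped",
            stacklevel=2,
        )
        return (np.nan, np.nan)
    if block is None:
        y1, y0 = y[f == 1], y[f == 0]
        res = stats.ttest_ind(y1, y0, equal_var=equal_var)
        return (float(np.mean(y1) - np.mean(y0)), float(res.pvalue))
    import statsmodels.api as sm

    b = b[ok]
    X = sm.add_constant(np.column_stack([f, b]))
    fit = sm.OLS(y, X).fit()
    return (float(fit.params[1]), float(fit.pvalues[1]))


def _ttest_features(
    y: np.ndarray, f: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sample t tests of one response against many binary features.

    ``y`` is (n,), ``f`` is (n, p) with entries {0, 1, NaN}.  Returns
    (effect, p, n_present, n_absent) arrays of length p.  Matches
    :func:`assoc_test` cell for cell; columns with fewer than 2 samples per
    level yield NaN.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    ok = ~np.isnan(y)[:, None] & ~np.isnan(f)
    w1 = np.where(ok & (f == 1), 1.0, 0.0)
    w0 = np.where(ok & (f == 0), 1.0, 0.0)
    n1 = w1.sum(axis=0)
    n0 = w0.sum(axis=0)
    ys = np.where(np.isnan(y), 0.0, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = (w1 * ys[:, None]).sum(axis=0) / n1
        m0 = (w0 * ys[:, None]).sum(axis=0) / n0
        v1 = (w1 * (ys[:, None] - m1[None, :]) ** 2).sum(axis=0) / (n1 - 1)
        v0 = (w0 * (ys[:, None] - m0[None, :]) ** 2).sum(axis=0) / (n0 - 1)
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
            t = (m1 - m0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
            df = n1 + n0 - 2
        else:
            se2 = v1 / n1 + v0 / n0
            t = (m1 - m0) / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        df = np.broadcast_to(df, t.shape)
    valid = (n1 >= 2) & (n0 >= 2)
    p = np.full(f.shape[1], np.nan)
    effect = np.full(f.shape[1], np.nan)
    good = valid & np.isfinite(t) & np.isfinite(df)
    p[good] = 2.0 * stats.t.sf(np.abs(t[good]), df[good])
    effect[valid] = (m1 - m0)[valid]
    return effect, p, n1.astype(int), n0.astype(int)


def bh_adjust(p: np.ndarray | list, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p values and significance flags at ``q``.

    NaN inputs stay NaN and are never flagged.
    """
    p = np.asarray(p, dtype=float)
    adj = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.sum() > 0:
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p values must lie in [0, 1]")
        rej, p_adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adj[ok] = p_adj
        flags[ok] = rej
    return adj, flags


def association_scan(
    tensor: ViabilityTensor,
    features: pd.DataFrame,
    q: float = 0.10,
    block: pd.Series | None = None,
    dose_method: str = "median_polish",
    max_missing_fraction: float = 0.2,
    min_per_group: int = 2,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Test every drug against every binary feature; one BH family for the scan.

    For each drug the concentration series is aggregated (median polish by
    default), each feature column is tested on complete cases, and BH
    adjustment at ``q`` is applied jointly across all drug x feature tests.
    Features with more than two distinct non-missing values are skipped with a
    warning (genotypes are binary here); features missing in more than
    ``max_missing_fraction`` of samples are tested on complete cases and
    flagged in the ``high_missingness`` column.

    ``min_per_group`` optionally guards the scan against very rare
    aberrations: tests with fewer than this many samples on either side
    report NaN and leave the BH family.
    """
    from .screen_core import dose_summarize

    features = features.loc[[s for s in tensor.sample_ids if s in features.index]]
    feat_cols = []
    for c in features.columns:
        vals = features[c].dropna().unique()
        if len(vals) > 2 or not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
            warnings.warn(f"association_scan: feature {c!r} is not binary 0/1; skipped", stacklevel=2)
            continue
        feat_cols.append(c)

    fmat = features[feat_cols].astype(float)
    miss_high = (fmat.isna().mean() > max_missing_fraction).values
    rows = []
    for drug in tensor.drug_ids:
        agg = dose_summarize(tensor, drug, method=dose_method)
        agg = agg.reindex(features.index)
        if block is None:
            effect, p, n1, n0 = _ttest_features(agg.values, fmat.values, equal_var=equal_var)
            small = (n1 < min_per_group) | (n0 < min_per_group)
            effect = np.where(small, np.nan, effect)
            p = np.where(small, np.nan, p)
            for k, feat in enumerate(feat_cols):
                rows.append(
                    dict(drug_id=drug, feature_id=feat, effect=effect[k], p_value=p[k],
                         n_present=int(n1[k]), n_absent=int(n0[k]), blocked=False,
                         high_missingness=bool(miss_high[k]))
                )
        else:
            blk = block.reindex(features.index)
            for k, feat in enumerate(feat_cols):
                fvals = fmat[feat]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    effect, p = assoc_test(agg.values, fvals.values, blk.values,
                                           equal_var=equal_var)
                ok = agg.notna() & fvals.notna() & blk.notna()
                n1 = int((fvals[ok] == 1).sum())
                n0 = int((fvals[ok] == 0).sum())
                if min(n1, n0) < min_per_group:
                    effect, p = np.nan, np.nan
                rows.append(
                    dict(drug_id=drug, feature_id=feat, effect=effect, p_value=p,
                         n_present=n1, n_absent=n0,
                         blocked=True, high_missingness=bool(miss_high[k]))
                )
    table = pd.DataFrame(rows)
    adj, flags = bh_adjust(table["p_value"].values, q=q)
    table["p_adjusted"] = adj
    table["significant_at_q"] = flags
    cols = ["drug_id", "feature_id", "effect", "p_value", "p_adjusted", "significant_at_q",
            "n_present", "n_absent", "blocked", "high_missingness"]
    return table[cols]


def volcano_per_concentration(
    tensor: ViabilityTensor, factor: pd.Series, q: float = 0.10,
    equal_var: bool = True,
) -> pd.DataFrame:
    """t test of a binary factor at each (drug, concentration) separately.

    Effect = mean(factor present) - mean(absent): negative values mean lower
    viability, i.e. higher sensitivity, in the factor-positive group.  BH
    adjustment is one family across all drug x concentration tests.
    """
    factor = factor.reindex(tensor.sample_ids).astype(float)
    rows = []
    fcol = factor.values[:, None]
    for j, drug in enumerate(tensor.drug_ids):
        for k in range(tensor.n_concentrations):
            y = tensor.values[:, j, k]
            effect, p, _, _ = _ttest_features(y, fcol, equal_var=equal_var)
            rows.append(
                dict(drug_id=drug, concentration_index=k + 1,
                     effect=float(effect[0]), p_value=float(p[0]))
            )
    table = pd.DataFrame(rows)
    adj, flags = bh_adjust(table["p_value"].values, q=q)
    table["p_adjusted"] = adj
    table["significant_at_q"] = flags
    return table


@dataclass
class FisherResult:
    """Fisher exact test of co-occurrence of two binary features."""

    odds_ratio: float  # conditional MLE
    sample_odds_ratio: float  # ad/bc, inf sentinel when a zero cell allows it
    p_value: float  # two-sided, hypergeometric
    table: np.ndarray  # [[n11, n10], [n01, n00]]


def fisher_cooccurrence(f1, f2) -> FisherResult:
    """Two-sided Fisher exact co-occurrence test on pairwise-complete samples.

    The reported odds ratio is the conditional maximum-likelihood estimate
    (as in R's fisher.test); the sample odds ratio ad/bc is also emitted.
    Constant features are an error naming the offending feature.
    """
    a1 = np.asarray(f1, dtype=float)
    a2 = np.asarray(f2, dtype=float)
    ok = ~(np.isnan(a1) | np.isnan(a2))
    a1, a2 = a1[ok], a2[ok]
    for name, a in (("f1", a1), ("f2", a2)):
        if len(np.unique(a)) < 2:
            raise ValueError(f"fisher_cooccurrence: feature {name} is constant after filtering")
    n11 = int(np.sum((a1 == 1) & (a2 == 1)))
    n10 = int(np.sum((a1 == 1) & (a2 == 0)))
    n01 = int(np.sum((a1 == 0) & (a2 == 1)))
    n00 = int(np.sum((a1 == 0) & (a2 == 0)))
    table = np.array([[n11, n10], [n01, n00]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    cmle = float(_cmle_odds_ratio(table, kind="conditional").statistic)
    if n10 * n01 == 0:
        sample_or = np.inf if n11 * n00 > 0 else np.nan
    else:
        sample_or = n11 * n00 / (n10 * n01)
    return FisherResult(odds_ratio=cmle, sample_odds_ratio=float(sample_or),
                        p_value=float(p), table=table)


@dataclass
class EnrichmentResult:
    """PAGE statistic for one gene set."""

    set_id: str
    m: int
    set_mean: float  # Sm
    universe_mean: float  # mu
    universe_sd: float  # sigma
    z: float
    p_value: float


def page_enrichment(
    gene_stats: pd.Series, sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Parametric analysis of gene-set enrichment.

    For each set (intersected with the gene universe), Z = (Sm - mu) * sqrt(m)
    / sigma with a two-sided normal p value.  Sets with empty intersection are
    skipped; an empty universe or zero-variance statistics are errors.
    """
    gene_stats = gene_stats.dropna()
    if gene_stats.empty:
        raise ValueError("page_enrichment: empty gene universe")
    mu = float(gene_stats.mean())
    sigma = float(gene_stats.std(ddof=1))
    if sigma <= 0:
        raise ValueError("page_enrichment: gene statistics have zero variance")
    rows = []
    for set_id, genes in sets.items():
        members = gene_stats.index.intersection(pd.Index(genes))
        m = len(members)
        if m == 0:
            continue
        sm = float(gene_stats.loc[members].mean())
        z = (sm - mu) * np.sqrt(m) / sigma
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            EnrichmentResult(set_id, m, sm, mu, sigma, float(z), float(p)).__dict__
        )
    return pd.DataFrame(rows)
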
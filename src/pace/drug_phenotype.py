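"""Drug-response phenotypes: similarity mapping, embedding, and stratification.

"Guilt by association": drugs whose viability profiles correlate across a
large sample panel tend to share targets or mechanism, so the pairwise Pearson
matrix of per-sample dose summaries (average of the 2 lowest concentrations),
hierarchically clustered on distance 1 - r, is the drug-similarity map.

Per-sample pathway dependence is summarized by the ternary relative-effect
statistic for a triple of drugs: e_i = (100 - v_i) / (300 - (v1 + v2 + v3)),
which sums to 1 and places each sample inside an equilateral triangle; overall
susceptibility is max_i (100 - v_i).

CLL samples are stratified by a sequential decision tree on three reference
drugs: strong ibrutinib response -> BTK group; else everolimus response ->
mTOR; else selumetinib response -> MEK; else weak.  Group-vs-rest
cosensitivity is tested per drug with Welch's t, BH-controlled at FDR 5% plus
a > 5 percent-point mean-effect filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genetic_association import bh_adjust

__all__ = [
    "DrugCorrelation",
    "drug_correlation",
    "embed_samples",
    "zscore_columns",
    "RelativeEffect",
    "relative_effect",
    "StratificationResult",
    "classify_cll",
    "calibrate_thresholds",
    "cosensitivity",
]

GROUPS = ("BTK", "mTOR", "MEK", "weak")
DEFAULT_REFERENCE_DRUGS = ("ibrutinib", "everolimus", "selumetinib")


@dataclass
class DrugCorrelation:
    """Pairwise-complete Pearson similarity of drug response profiles."""

    drug_ids: list[str]
    r: pd.DataFrame  # symmetric; NaN where undefined
    n_pairs: pd.DataFrame  # complete observations per cell
    linkage: np.ndarray  # scipy merge list on distance 1 - r

    def dendrogram_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.drug_ids[i] for i in order]


def drug_correlation(
    summaries: pd.DataFrame, min_pairs: int = 3, linkage_method: str = "complete"
) -> DrugCorrelation:
    """Pearson correlation matrix over samples for every drug pair.

    ``summaries`` is a samples x drugs matrix of dose summaries.  Cells with
    fewer than ``min_pairs`` complete sample pairs are NaN, as are drugs with
    zero variance (with a warning).  Rows/columns are clustered on distance
    1 - r (``complete`` linkage by default; ``average`` and ``ward`` allowed).
    """
    if summaries.shape[0] < 3:
        raise ValueError("drug_correlation needs at least 3 samples")
    if linkage_method not in ("complete", "average", "ward"):
        raise ValueError(f"unsupported linkage method {linkage_method!r}")
    sd = summaries.std(ddof=1)
    flat = [c for c in summaries.columns if not np.isnan(sd[c]) and sd[c] == 0]
    if flat:
        warnings.warn(
            f"drug_correlation: zero-variance drugs, correlations undefined: {flat}",
            stacklevel=2,
        )
    r = summaries.corr(method="pearson", min_periods=min_pairs)
    notna = summaries.notna().astype(int)
    n_pairs = notna.T @ notna
    # diagonal: exactly 1 whenever the drug has >= 2 observations
    for c in summaries.columns:
        r.loc[c, c] = 1.0 if notna[c].sum() >= 2 else np.nan
    dist = 1.0 - r.fillna(0.0).values
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    return DrugCorrelation(list(summaries.columns), r, n_pairs, link)


def embed_samples(
    profiles: pd.DataFrame, perplexity: float = 30.0, seed: int = 0
) -> pd.DataFrame:
    """2-D t-SNE embedding of sample drug-response profiles.

    Missing values are imputed per column with the median before embedding
    (neutral and deterministic); the embedding itself is delegated to
    scikit-learn and is deterministic under a fixed seed.
    """
    n = profiles.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"embed_samples: n={n} < 3 * perplexity={3 * perplexity:g}; lower the perplexity"
        )
    from sklearn.manifold import TSNE

    x = profiles.apply(lambda c: c.fillna(c.median()), axis=0).values
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=int(seed), init="pca"
    ).fit_transform(x)
    return pd.DataFrame(coords, index=profiles.index, columns=["tsne1", "tsne2"])


def zscore_columns(m: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, sample sd 1 (n - 1).

    Constant columns map to all-zero with a warning; NaNs are preserved.
    """
    mean = m.mean()
    sd = m.std(ddof=1)
    flat = [c for c in m.columns if not np.isnan(sd[c]) and sd[c] == 0]
    if flat:
        warnings.warn(f"zscore_columns: constant columns set to zero: {flat}", stacklevel=2)
    sd_safe = sd.replace(0.0, np.nan)
    z = (m - mean) / sd_safe
    for c in flat:
        z[c] = m[c].notna().map({True: 0.0, False: np.nan})
    return z


@dataclass
class RelativeEffect:
    """Ternary relative effects of a drug triple on one sample."""

    sample_id: str | None
    drugs: tuple[str, str, str] | None
    e: tuple[float, float, float]  # sums to 1 (uniform in the degenerate case)
    susceptibility: float  # max_i (100 - v_i), percent points


def relative_effect(
    v1: float, v2: float, v3: float,
    sample_id: str | None = None,
    drugs: tuple[str, str, str] | None = None,
) -> RelativeEffect:
    """e_i = (100 - v_i) / (300 - (v1 + v2 + v3)); susceptibility = max(100 - v_i).

    When v1 + v2 + v3 = 300 the denominator vanishes and e is set to the
    uniform (1/3, 1/3, 1/3) by convention, keeping every sample plottable.
    """
    v = np.array([v1, v2, v3], dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("relative_effect requires finite viabilities")
    denom = 300.0 - float(v.sum())
    if denom == 0.0:
        e = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    else:
        ev = (100.0 - v) / denom
        e = (float(ev[0]), float(ev[1]), float(ev[2]))
    return RelativeEffect(sample_id, drugs, e, float(np.max(100.0 - v)))


@dataclass
class StratificationResult:
    """Per-sample response-group labels plus the rule that produced them."""

    groups: pd.Series  # values in GROUPS or 'unclassifiable'
    thresholds: dict[str, float]  # percent-viability cutoffs on the dose summary
    reference_drugs: tuple[str, str, str]

    def counts(self) -> pd.Series:
        return self.groups.value_counts().reindex(
            list(GROUPS) + ["unclassifiable"], fill_value=0
        )


def classify_cll(
    summaries: pd.DataFrame,
    thresholds: dict[str, float],
    reference_drugs: tuple[str, str, str] = DEFAULT_REFERENCE_DRUGS,
) -> StratificationResult:
    """Sequential decision tree over three reference-drug dose summaries.

    summary(ibrutinib) < theta_ibr -> BTK; else summary(everolimus) <
    theta_eve -> mTOR; else summary(selumetinib) < theta_sel -> MEK; else
    weak.  A sample missing the summary needed at an undecided step is
    'unclassifiable'.  ``thresholds`` maps each reference drug id to its
    cutoff.  The result is independent of the order samples are presented.
    """
    missing_drugs = [d for d in reference_drugs if d not in summaries.columns]
    if missing_drugs:
        raise ValueError(f"classify_cll: reference drugs absent from panel: {missing_drugs}")
    missing_thr = [d for d in reference_drugs if d not in thresholds]
    if missing_thr:
        raise ValueError(f"classify_cll: no threshold configured for: {missing_thr}")

    labels = {}
    rule = list(zip(reference_drugs, GROUPS[:3]))
    for sample in summaries.index:
        label = "weak"
        for drug, group in rule:
            v = summaries.loc[sample, drug]
            if pd.isna(v):
                label = "unclassifiable"
                break
            if v < thresholds[drug]:
                label = group
                break
        labels[sample] = label
    return StratificationResult(
        pd.Series(labels, name="group").reindex(summaries.index),
        {d: float(thresholds[d]) for d in reference_drugs},
        tuple(reference_drugs),
    )


def calibrate_thresholds(
    summaries: pd.DataFrame,
    target_sizes: tuple[int, int, int, int] = (50, 26, 23, 85),
    reference_drugs: tuple[str, str, str] = DEFAULT_REFERENCE_DRUGS,
) -> dict[str, float]:
    """Choose decision-tree cutoffs so expected group sizes match targets.

    Sequential quantile calibration: theta_ibr is the (n_BTK / n)-quantile of
    the ibrutinib summary; among the samples above it, theta_eve is the
    (n_mTOR / remaining)-quantile of the everolimus summary, and likewise for
    selumetinib.  Exact cutoffs for the published tree live outside the main
    text, so calibration on the cohort at hand is the shipped, reproducible
    default.
    """
    remaining = summaries.dropna(subset=list(reference_drugs))
    n = len(remaining)
    if n == 0:
        raise ValueError("calibrate_thresholds: no complete samples")
    fracs = np.array(target_sizes, dtype=float)
    fracs = fracs / fracs.sum()
    thresholds = {}
    for drug, frac in zip(reference_drugs, fracs[:3]):
        k = len(remaining)
        take = frac * n
        qu = min(max(take / k, 0.0), 1.0)
        theta = float(remaining[drug].quantile(qu))
        thresholds[drug] = theta
        remaining = remaining[remaining[drug] >= theta]
    return thresholds


def cosensitivity(
    strat: StratificationResult,
    summaries: pd.DataFrame,
    q: float = 0.05,
    min_effect: float = 5.0,
) -> pd.DataFrame:
    """Group-vs-rest drug response differences across the whole panel.

    For every (group, drug): Welch t test of the group's dose summaries
    against all samples from the remaining groups; effect = mean(group) -
    mean(rest) in percent points.  BH adjustment runs once across all
    (drug, group) tests at ``q``; a row is significant only if it passes the
    FDR cut *and* |effect| > ``min_effect``.  Groups of size < 2 are skipped
    with a warning.
    """
    from scipy import stats

    groups = strat.groups.reindex(summaries.index)
    rows = []
    for g in GROUPS:
        in_g = groups == g
        if int(in_g.sum()) < 2:
            warnings.warn(f"cosensitivity: group {g!r} has <2 samples; skipped", stacklevel=2)
            continue
        in_rest = groups.isin([h for h in GROUPS if h != g])
        for drug in summaries.columns:
            y1 = summaries.loc[in_g, drug].dropna()
            y0 = summaries.loc[in_rest, drug].dropna()
            if len(y1) < 2 or len(y0) < 2:
                rows.append(dict(drug_id=drug, group=g, effect=np.nan, p_value=np.nan,
                                 n_group=len(y1), n_rest=len(y0)))
                continue
            res = stats.ttest_ind(y1, y0, equal_var=False)
            rows.append(
                dict(drug_id=drug, group=g, effect=float(y1.mean() - y0.mean()),
                     p_value=float(res.pvalue), n_group=len(y1), n_rest=len(y0))
            )
    table = pd.DataFrame(rows)
    adj, flags = bh_adjust(table["p_value"].values, q=q)
    table["p_adjusted"] = adj
    table["significant"] = flags & (table["effect"].abs() > min_effect)
    return table
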
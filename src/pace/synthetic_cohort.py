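"""Fully synthetic ex vivo drug screen with known ground truth.

The generator emulates the statistical structure of a primary blood-cancer
drug-sensitivity cohort: ~246 patient samples (184 CLL, the rest spread over
smaller disease entities) plus 3 healthy-donor controls, screened with 64
drugs at 5 ascending concentrations on 384-well plates carrying 32 DMSO
control wells each.

Cohort genetics follow a sequential logistic dependency model so that planted
pairwise odds ratios hit their targets in expectation: TP53 mutation is
conditioned on del17p13 (target OR ~ 29), del13q14 on trisomy 12 (target
OR ~ 0.2, mutual exclusivity), and pretreatment on TP53 and unmutated IGHV
(clonal selection under chemotherapy and progressive disease, respectively).
Latent response groups (BTK / mTOR / MEK / weak, expected sizes 50/26/23/85
of 184 CLL) drive sensitivity to the reference drugs; the mTOR group is drawn
almost exclusively from IGHV-mutated samples.

Viability is generated as v(s,d,c) = 100 * (1 - e(d,c) * sens(s,d)), where
e(d,c) is the drug's kill fraction (nondecreasing in concentration) and
sens(s,d) = logistic(b0_d + beta_d . x_s + eps_bio) combines group, IGHV,
genetic, pretreatment and disease covariates with Gaussian noise on the
logit.  Technical noise is multiplicative lognormal on the luminescence scale.
The IGHV effect on ibrutinib is calibrated so that, at the lowest
concentration, unmutated samples average ~89.2% viability versus ~99.5% in
mutated samples.  Survival times are exponential with hazard h0 * exp(eta),
with eta a linear predictor over TP53, IGHV, del17p13 and pretreatment, and
independent uniform administrative censoring — closed forms for all checks.

Every generated quantity is recorded in a ground-truth table so that
parameter-recovery tests can compare estimates against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .screen_core import (
    PLATE_COLS,
    PLATE_ROWS,
    PlateReading,
    ViabilityTensor,
    WellAssignment,
)

__all__ = [
    "CohortConfig",
    "ResponseModel",
    "TruthTable",
    "SyntheticCohort",
    "ScreenBundle",
    "generate_cohort",
    "generate_viability",
    "add_technical_noise",
    "render_plates",
    "default_layout",
    "generate_survival",
    "generate_omics",
    "simulate_screen",
    "default_response_model",
    "beta_for_viability_delta",
    "planted_thresholds",
]

GENETIC_FEATURES = [
    "trisomy12", "TP53", "del17p13", "del13q14", "del11q22.3",
    "KRAS", "BRAF", "CREBBP", "KLHL6", "gain8q24",
]


@dataclass
class CohortConfig:
    """Cohort composition and genetic dependency structure."""

    n_cll: int = 184
    other_diagnoses: dict[str, int] = field(
        default_factory=lambda: {
            "T-PLL": 25, "MCL": 10, "MZL": 7, "AML": 6,
            "HCL": 4, "FL": 4, "LPL": 4, "T-NHL": 2,
        }
    )
    n_controls: int = 3  # healthy mononuclear-cell samples, diagnosis 'hMNC'
    p_ighv_mutated: float = 98 / 172
    # expected CLL response-group fractions (BTK, mTOR, MEK, weak)
    group_probs: dict[str, float] = field(
        default_factory=lambda: {
            "BTK": 50 / 184, "mTOR": 26 / 184, "MEK": 23 / 184, "weak": 85 / 184
        }
    )
    # U-CLL share within each group; mTOR is almost exclusively M-CLL (1 of 23)
    group_u_fraction: dict[str, float] = field(
        default_factory=lambda: {"BTK": 0.60, "mTOR": 1 / 23, "MEK": 0.55}
    )
    feature_freqs: dict[str, float] = field(
        default_factory=lambda: {
            "trisomy12": 0.17, "TP53": 0.12, "del17p13": 0.10, "del13q14": 0.45,
            "del11q22.3": 0.15, "KRAS": 0.04, "BRAF": 0.05, "CREBBP": 0.04,
            "KLHL6": 0.02, "gain8q24": 0.04,
        }
    )
    or_del17p13_tp53: float = 29.0
    or_del13q14_trisomy12: float = 0.2
    pretreat_freq: float = 52 / 184
    or_pretreat_tp53: float = 8.0
    or_pretreat_ucll: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for name, p in {**self.feature_freqs, "p_ighv_mutated": self.p_ighv_mutated,
                        "pretreat_freq": self.pretreat_freq}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {name}={p}")
        total = sum(self.group_probs.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"group probabilities sum to {total} > 1")


@dataclass
class TruthTable:
    """Ground truth of one simulated screen; immutable by convention once built."""

    groups: pd.Series | None = None  # per-CLL-sample latent group
    planted_effects: pd.DataFrame | None = None  # per (drug, covariate) deltas in percent
    cox_eta: pd.DataFrame | None = None  # per-sample true linear predictors
    thresholds: dict[str, float] | None = None  # planted decision boundaries


@dataclass
class SyntheticCohort:
    """Annotations, genetic features and ground truth for one simulated cohort."""

    annotation: pd.DataFrame  # diagnosis, IGHV, pretreated, age, sex_male, methylation_cluster
    features: pd.DataFrame  # binary genetics (NaN outside CLL) + methylation_cluster
    truth: TruthTable

    @property
    def sample_ids(self) -> list[str]:
        return list(self.annotation.index)

    @property
    def cll_ids(self) -> list[str]:
        return list(self.annotation.index[self.annotation["diagnosis"] == "CLL"])


def _solve_conditional_intercept(parents: np.ndarray, betas: np.ndarray,
                                 target_p: float, label: str) -> float:
    """Find a with mean(expit(a + parents @ betas)) = target_p over realized parents."""
    lin = parents @ betas

    def f(a: float) -> float:
        return float(np.mean(expit(a + lin))) - target_p

    lo, hi = -25.0, 25.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"infeasible odds-ratio/frequency target for {label}: "
            f"cannot reach marginal frequency {target_p}"
        )
    return float(brentq(f, lo, hi, xtol=1e-12))


def generate_cohort(cfg: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Draw a cohort with the configured dependency structure; deterministic per seed."""
    cfg = cfg or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    diagnoses = ["CLL"] * cfg.n_cll
    for dx, n in cfg.other_diagnoses.items():
        diagnoses += [dx] * n
    diagnoses += ["hMNC"] * cfg.n_controls
    n = len(diagnoses)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    dx = pd.Series(diagnoses, index=ids, name="diagnosis")
    is_cll = (dx == "CLL").values

    # IGHV status (CLL only)
    ighv = np.full(n, np.nan, dtype=object)
    mutated = rng.random(n) < cfg.p_ighv_mutated
    ighv[is_cll] = np.where(mutated[is_cll], "M", "U")

    # latent response groups, conditioned on IGHV so composition targets hold
    p_u = 1.0 - cfg.p_ighv_mutated
    probs_u, probs_m = {}, {}
    for g in ("BTK", "mTOR", "MEK"):
        pg = cfg.group_probs[g]
        fu = cfg.group_u_fraction[g]
        probs_u[g] = min(pg * fu / p_u, 1.0)
        probs_m[g] = min(pg * (1.0 - fu) / (1.0 - p_u), 1.0)
    for probs in (probs_u, probs_m):
        s = sum(probs.values())
        if s > 1.0:
            raise ValueError("group composition targets infeasible: conditional probs exceed 1")
        probs["weak"] = 1.0 - s
    groups = np.full(n, None, dtype=object)
    names = ["BTK", "mTOR", "MEK", "weak"]
    u_draw = rng.random(n)
    for i in range(n):
        if not is_cll[i]:
            continue
        probs = probs_u if ighv[i] == "U" else probs_m
        cum = np.cumsum([probs[g] for g in names])
        groups[i] = names[int(np.searchsorted(cum, u_draw[i]))]

    # genetics with sequential logistic conditioning (CLL only)
    n_cll = int(is_cll.sum())
    feats = pd.DataFrame(np.nan, index=ids, columns=GENETIC_FEATURES)
    draws = {f: rng.random(n_cll) for f in GENETIC_FEATURES}

    def bern(p, f):
        return (draws[f] < p).astype(float)

    f = cfg.feature_freqs
    trisomy12 = bern(f["trisomy12"], "trisomy12")
    del17p13 = bern(f["del17p13"], "del17p13")
    b = np.log(cfg.or_del17p13_tp53)
    a = _solve_conditional_intercept(del17p13[:, None], np.array([b]), f["TP53"],
                                     "del17p13<->TP53")
    tp53 = (draws["TP53"] < expit(a + b * del17p13)).astype(float)
    b = np.log(cfg.or_del13q14_trisomy12)
    a = _solve_conditional_intercept(trisomy12[:, None], np.array([b]), f["del13q14"],
                                     "del13q14<->trisomy12")
    del13q14 = (draws["del13q14"] < expit(a + b * trisomy12)).astype(float)
    for name in ("del11q22.3", "KRAS", "BRAF", "CREBBP", "KLHL6", "gain8q24"):
        feats.loc[is_cll, name] = bern(f[name], name)
    feats.loc[is_cll, "trisomy12"] = trisomy12
    feats.loc[is_cll, "del17p13"] = del17p13
    feats.loc[is_cll, "TP53"] = tp53
    feats.loc[is_cll, "del13q14"] = del13q14

    # pretreatment: enriched in TP53-mutant and U-CLL
    ucll = (ighv[is_cll] == "U").astype(float)
    parents = np.column_stack([tp53, ucll])
    betas = np.array([np.log(cfg.or_pretreat_tp53), np.log(cfg.or_pretreat_ucll)])
    a = _solve_conditional_intercept(parents, betas, cfg.pretreat_freq,
                                     "pretreatment<->TP53/IGHV")
    pretreated = np.zeros(n)
    pretreated[is_cll] = (rng.random(n_cll) < expit(a + parents @ betas)).astype(float)

    # demographics and the 3-level methylation programming cluster (IGHV-linked)
    age = np.clip(np.round(rng.normal(62, 11, n)), 25, 92)
    sex_male = (rng.random(n) < 0.6).astype(int)
    meth = np.full(n, np.nan)
    cluster_levels = np.array([0.0, 0.5, 1.0])
    p_u_cluster = np.array([0.80, 0.15, 0.05])  # U-CLL: low-programmed
    p_m_cluster = np.array([0.10, 0.30, 0.60])
    cdraw = rng.random(n)
    for i in range(n):
        if not is_cll[i]:
            continue
        p = p_u_cluster if ighv[i] == "U" else p_m_cluster
        meth[i] = cluster_levels[int(np.searchsorted(np.cumsum(p), cdraw[i]))]

    annotation = pd.DataFrame(
        {
            "diagnosis": dx,
            "IGHV": pd.Series(ighv, index=ids),
            "pretreated": pretreated,
            "age": age,
            "sex_male": sex_male,
            "methylation_cluster": meth,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    features = feats.copy()
    features["methylation_cluster"] = meth
    truth = TruthTable(groups=pd.Series(groups, index=ids, name="group").dropna())
    return SyntheticCohort(annotation, features, truth)


# ---------------------------------------------------------------------------
# response model
# ---------------------------------------------------------------------------

@dataclass
class ResponseModel:
    """Generative drug-response model: kill fractions plus covariate effects."""

    drug_ids: list[str]
    kill: pd.DataFrame  # drugs x 5 kill fractions, nondecreasing in concentration
    base_logit: pd.Series  # per-drug baseline sensitivity logit
    effects: dict[str, dict[str, float]]  # drug -> covariate -> logit effect
    sigma_bio: float = 0.3  # between-sample sd on the sensitivity logit
    sigma_tech: float = 0.03  # well-level lognormal sd on RLU
    l0: float = 1.0e6  # control luminescence level (RLU)

    def validate(self) -> None:
        if self.sigma_bio < 0 or self.sigma_tech < 0:
            raise ValueError("noise sds must be nonnegative")
        k = self.kill.values
        if np.any(k < 0) or np.any(k >= 1):
            raise ValueError("kill fractions must lie in [0, 1)")
        if np.any(np.diff(k, axis=1) < -1e-12):
            raise ValueError("kill fractions must be nondecreasing in concentration")


KILL_TARGETED = np.array([0.28, 0.32, 0.40, 0.50, 0.62])
KILL_CYTOTOXIC = np.array([0.45, 0.50, 0.55, 0.60, 0.65])
KILL_GENERIC = np.array([0.10, 0.14, 0.20, 0.28, 0.38])

_BCR_DRUGS = ["ibrutinib", "idelalisib", "duvelisib", "spebrutinib", "PRT062607"]
_MULTIKINASE = ["dasatinib", "AZD7762", "PF477736", "SCH 900776", "AT13387",
                "ganetespib", "onalespib"]
_MEK_ERK = ["selumetinib", "cobimetinib", "trametinib", "SCH772984"]
_CYTOTOXICS = ["fludarabine", "doxorubicin", "nutlin-3", "YM155", "thapsigargin", "rotenone"]
_OTHER_NAMED = ["everolimus", "silmitasertib", "venetoclax", "navitoclax",
                "encorafenib", "tamatinib", "tipifarnib", "chaetoglobosin A",
                "MIS-43", "SD07", "SD51", "bortezomib"]


def beta_for_viability_delta(kill_mean: float, base_logit: float, delta_percent: float) -> float:
    """Logit effect producing a given mean viability change (percent points).

    Solves 100 * kill_mean * (expit(b0 + beta) - expit(b0)) = -delta_percent,
    so a negative ``delta_percent`` (lower viability, more sensitive) yields a
    positive sensitivity effect.  Raises if the target exceeds what the kill
    fraction can produce.
    """
    base = float(expit(base_logit))
    target = base - delta_percent / (100.0 * kill_mean)
    if not 0.0 < target < 1.0:
        raise ValueError(
            f"viability delta {delta_percent} not reachable with kill_mean={kill_mean}, "
            f"base_logit={base_logit}"
        )
    return float(logit(target) - base_logit)


def default_response_model() -> ResponseModel:
    """The default planted effect structure (fixed, not seed-dependent)."""
    named = (_BCR_DRUGS + _MULTIKINASE + _MEK_ERK + _CYTOTOXICS + _OTHER_NAMED)
    fillers = [f"compound_{i:02d}" for i in range(len(named) + 1, 65)]
    drugs = named + fillers
    assert len(drugs) == 64

    kill = {}
    b0 = {}
    for d in drugs:
        if d in _BCR_DRUGS + _MULTIKINASE + _MEK_ERK + ["everolimus", "silmitasertib",
                                                        "venetoclax", "navitoclax",
                                                        "encorafenib", "tamatinib"]:
            kill[d], b0[d] = KILL_TARGETED, -4.0
        elif d in _CYTOTOXICS or d == "bortezomib":
            kill[d], b0[d] = KILL_CYTOTOXIC, 0.0
        else:
            kill[d], b0[d] = KILL_GENERIC, -1.0

    eff: dict[str, dict[str, float]] = {d: {} for d in drugs}
    # IGHV anchor: -10.3 percent points at the lowest ibrutinib concentration
    beta_u_ibr = beta_for_viability_delta(KILL_TARGETED[0], -4.0, -(99.5 - 89.2))
    eff["ibrutinib"] = {"IGHV_U": beta_u_ibr, "group:BTK": 6.0}
    for d in ["idelalisib", "duvelisib", "spebrutinib", "PRT062607"]:
        eff[d] = {"IGHV_U": 3.0, "group:BTK": 2.5}
    eff["idelalisib"]["trisomy12"] = 1.0
    eff["duvelisib"]["trisomy12"] = 1.0
    for d in _MULTIKINASE:
        eff[d] = {"IGHV_U": 2.8, "group:BTK": 1.5}
    eff["everolimus"] = {"group:mTOR": 6.0, "trisomy12": 1.0, "CREBBP": 1.5}
    eff["selumetinib"] = {"group:MEK": 6.0, "trisomy12": 1.2, "KRAS": 1.5, "IGHV_U": 1.0}
    for d in ["cobimetinib", "trametinib", "SCH772984"]:
        eff[d] = {"group:MEK": 3.0, "trisomy12": 1.2, "KRAS": 1.5}
    for d in ["silmitasertib", "venetoclax", "navitoclax"]:
        eff[d] = {"group:mTOR": 2.0}
    eff["fludarabine"] = {"TP53": -2.0, "del17p13": -1.5, "pretreated": -1.0}
    eff["doxorubicin"] = {"TP53": -1.5, "del17p13": -1.0}
    eff["nutlin-3"] = {"TP53": -2.5, "del17p13": -1.5, "pretreated": -0.8}
    eff["encorafenib"] = {"KRAS": -2.0, "diagnosis:HCL": 3.0}
    eff["chaetoglobosin A"] = {"trisomy12": -1.0}
    eff["thapsigargin"] = {"diagnosis:T-PLL": 2.0}
    eff["tamatinib"] = {"diagnosis:AML": 2.0}
    eff["tipifarnib"] = {"diagnosis:AML": 2.0}
    for d in _BCR_DRUGS:
        eff[d]["diagnosis:T-PLL"] = -2.0
        eff[d]["diagnosis:MZL"] = -1.5
    eff["ibrutinib"]["diagnosis:MCL"] = 1.0
    eff["everolimus"]["diagnosis:MCL"] = 1.0
    for d in ["selumetinib", "cobimetinib", "trametinib"]:
        eff[d]["diagnosis:HCL"] = 2.5

    # small fixed disease-specific offsets so disease entities separate in the
    # embedding; drawn once from a pinned stream so the model is a constant
    rng = np.random.default_rng(20170731)
    diseases = ["T-PLL", "MCL", "MZL", "AML", "HCL", "FL", "LPL", "T-NHL", "hMNC"]
    for dx in diseases:
        for d in drugs:
            key = f"diagnosis:{dx}"
            eff[d][key] = eff[d].get(key, 0.0) + float(rng.normal(0.0, 0.6))

    model = ResponseModel(
        drug_ids=drugs,
        kill=pd.DataFrame({d: kill[d] for d in drugs}).T.set_axis(range(1, 6), axis=1),
        base_logit=pd.Series(b0),
        effects=eff,
    )
    model.validate()
    return model


def planted_thresholds() -> dict[str, float]:
    """Decision-tree cutoffs at the planted boundaries of the default model."""
    return {"ibrutinib": 81.0, "everolimus": 85.0, "selumetinib": 82.0}


def _design_matrix(cohort: SyntheticCohort) -> pd.DataFrame:
    ann = cohort.annotation
    x = pd.DataFrame(index=ann.index)
    groups = cohort.truth.groups.reindex(ann.index) if cohort.truth.groups is not None else None
    for g in ("BTK", "mTOR", "MEK"):
        x[f"group:{g}"] = (groups == g).astype(float) if groups is not None else 0.0
    x["IGHV_U"] = (ann["IGHV"] == "U").astype(float)
    for f in GENETIC_FEATURES:
        x[f] = cohort.features[f].fillna(0.0)
    x["pretreated"] = ann["pretreated"].astype(float)
    for dx in ann["diagnosis"].unique():
        if dx != "CLL":
            x[f"diagnosis:{dx}"] = (ann["diagnosis"] == dx).astype(float)
    return x


def generate_viability(
    cohort: SyntheticCohort,
    model: ResponseModel | None = None,
    seed: int = 0,
    technical_noise: bool = True,
) -> tuple[ViabilityTensor, TruthTable]:
    """Generate the viability tensor and record planted effects in the truth table."""
    model = model or default_response_model()
    model.validate()
    rng = np.random.default_rng(seed)
    x = _design_matrix(cohort)
    samples = list(x.index)
    n, d, c = len(samples), len(model.drug_ids), model.kill.shape[1]

    values = np.empty((n, d, c))
    truth_rows = []
    for j, drug in enumerate(model.drug_ids):
        b0 = float(model.base_logit[drug])
        lin = np.full(n, b0)
        for cov, beta in model.effects.get(drug, {}).items():
            if cov in x.columns and beta != 0.0:
                lin = lin + beta * x[cov].values
        if model.sigma_bio > 0:
            lin = lin + rng.normal(0.0, model.sigma_bio, n)
        sens = expit(lin)
        kill = model.kill.loc[drug].values
        values[:, j, :] = 100.0 * (1.0 - kill[None, :] * sens[:, None])
        base = expit(b0)
        for cov, beta in model.effects.get(drug, {}).items():
            shifted = expit(b0 + beta)
            truth_rows.append(
                dict(
                    drug_id=drug, covariate=cov, beta=beta,
                    delta_low2=float(-100.0 * kill[:2].mean() * (shifted - base)),
                    delta_all5=float(-100.0 * kill.mean() * (shifted - base)),
                )
            )
    if technical_noise and model.sigma_tech > 0:
        values = values * np.exp(rng.normal(0.0, model.sigma_tech, values.shape))

    tensor = ViabilityTensor(samples, list(model.drug_ids), values)
    truth = replace(
        cohort.truth,
        planted_effects=pd.DataFrame(truth_rows),
        thresholds=planted_thresholds(),
    )
    cohort.truth = truth
    return tensor, truth


def add_technical_noise(tensor: ViabilityTensor, sigma_tech: float, seed: int = 0) -> ViabilityTensor:
    """Apply multiplicative lognormal well noise to a noise-free tensor."""
    rng = np.random.default_rng(seed)
    values = tensor.values * np.exp(rng.normal(0.0, sigma_tech, tensor.values.shape))
    return ViabilityTensor(list(tensor.sample_ids), list(tensor.drug_ids), values)


def default_layout(drug_ids: list[str], n_concentrations: int, n_controls: int = 32) -> dict[str, WellAssignment]:
    """Row-major 384-well layout: treated wells first, then DMSO controls, rest empty."""
    wells = [f"{r}{c}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1)]
    n_treated = len(drug_ids) * n_concentrations
    if n_treated + n_controls > len(wells):
        raise ValueError(
            f"layout overflow: {n_treated} treated + {n_controls} control wells "
            f"exceed {len(wells)}"
        )
    layout: dict[str, WellAssignment] = {}
    i = 0
    for drug in drug_ids:
        for k in range(1, n_concentrations + 1):
            layout[wells[i]] = WellAssignment("treated", drug, k)
            i += 1
    for _ in range(n_controls):
        layout[wells[i]] = WellAssignment("dmso_control")
        i += 1
    for w in wells[i:]:
        layout[w] = WellAssignment("empty")
    return layout


def render_plates(
    tensor: ViabilityTensor,
    model: ResponseModel | None = None,
    seed: int = 0,
    n_controls: int = 32,
) -> list[PlateReading]:
    """Emit raw-luminescence plates (one sample per plate) from a viability tensor.

    RLU(w) = L0 * v(w)/100 * lognormal(0, sigma_tech); control wells carry
    v = 100.  With sigma_tech = 0, normalize_plate o render_plates recovers
    the tensor exactly.
    """
    model = model or default_response_model()
    rng = np.random.default_rng(seed)
    layout = default_layout(tensor.drug_ids, tensor.n_concentrations, n_controls)
    treated_wells = {
        (a.drug_id, a.concentration_index): w
        for w, a in layout.items() if a.role == "treated"
    }
    control_wells = [w for w, a in layout.items() if a.role == "dmso_control"]
    well_order = [
        treated_wells[(drug, k + 1)]
        for drug in tensor.drug_ids
        for k in range(tensor.n_concentrations)
    ]
    plates = []
    for i, sample in enumerate(tensor.sample_ids):
        flat = tensor.values[i].reshape(-1)
        n_wells = flat.size + len(control_wells)
        noise = (
            np.exp(rng.normal(0.0, model.sigma_tech, n_wells))
            if model.sigma_tech > 0 else np.ones(n_wells)
        )
        rlu = model.l0 * flat / 100.0 * noise[: flat.size]
        wells = {w: float(r) for w, r, v in zip(well_order, rlu, flat) if not np.isnan(v)}
        for w, nz in zip(control_wells, noise[flat.size:]):
            wells[w] = float(model.l0 * nz)
        plates.append(PlateReading(f"P{i + 1:04d}", sample, wells, dict(layout)))
    return plates


# ---------------------------------------------------------------------------
# survival and omics
# ---------------------------------------------------------------------------

OS_BETAS = {"TP53": 0.8, "IGHV_U": 0.5, "del17p13": 0.4, "pretreated": 0.3}
TTT_BETAS = {"IGHV_U": 1.0, "trisomy12": 0.4, "TP53": 0.5}


def exponential_survival_times(
    eta: np.ndarray, h0: float, censor_low: float, censor_high: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Event times from hazard h0 * exp(eta) with independent uniform censoring."""
    eta = np.asarray(eta, dtype=float)
    t_event = rng.exponential(1.0, eta.shape) / (h0 * np.exp(eta))
    t_cens = rng.uniform(censor_low, censor_high, eta.shape)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def generate_survival(
    cohort: SyntheticCohort,
    seed: int = 0,
    h0_os: float = 1 / 3000.0,
    h0_ttt: float = 1 / 1200.0,
    censor_window: tuple[float, float] = (365.0, 3650.0),
    n_ttt_missing: int = 10,
) -> pd.DataFrame:
    """CLL survival records (long format: sample_id, endpoint, time_days, event).

    Overall survival (OS) is generated for every CLL sample; time to treatment
    (TTT) for all but ``n_ttt_missing`` randomly chosen samples, mirroring the
    smaller TTT denominator seen in real cohorts.  Linear predictors use TP53,
    IGHV, del17p13, pretreatment (OS) and IGHV, trisomy 12, TP53 (TTT); the
    per-sample eta values are stored in the truth table.
    """
    rng = np.random.default_rng(seed)
    cll = cohort.cll_ids
    x = _design_matrix(cohort).loc[cll]
    eta_os = sum(b * x[c].values for c, b in OS_BETAS.items())
    eta_ttt = sum(b * x[c].values for c, b in TTT_BETAS.items())

    rows = []
    t, e = exponential_survival_times(eta_os, h0_os, *censor_window, rng=rng)
    for sid, ti, ei in zip(cll, t, e):
        rows.append(dict(sample_id=sid, endpoint="OS", time_days=float(ti), event=int(ei)))
    ttt_samples = list(cll)
    if n_ttt_missing > 0:
        drop = set(rng.choice(len(cll), size=min(n_ttt_missing, len(cll)), replace=False))
        ttt_samples = [s for i, s in enumerate(cll) if i not in drop]
    keep = [i for i, s in enumerate(cll) if s in set(ttt_samples)]
    t, e = exponential_survival_times(eta_ttt[keep], h0_ttt, *censor_window, rng=rng)
    for sid, ti, ei in zip(ttt_samples, t, e):
        rows.append(dict(sample_id=sid, endpoint="TTT", time_days=float(ti), event=int(ei)))

    cohort.truth = replace(
        cohort.truth,
        cox_eta=pd.DataFrame({"eta_OS": eta_os, "eta_TTT": eta_ttt}, index=pd.Index(cll, name="sample_id")),
    )
    return pd.DataFrame(rows)


def generate_omics(
    cohort: SyntheticCohort,
    n_genes: int = 300,
    n_cpgs: int = 300,
    n_factors: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent-factor expression and methylation matrices for the CLL samples.

    The leading expression factor tracks IGHV status and the second tracks
    trisomy 12; the leading methylation factor tracks the programming cluster.
    These matrices model only the low-rank covariance relevant to the lasso
    variance decomposition, not molecular-level counts.
    """
    rng = np.random.default_rng(seed)
    cll = cohort.cll_ids
    n = len(cll)
    u = (cohort.annotation.loc[cll, "IGHV"] == "U").astype(float).values
    tri = cohort.features.loc[cll, "trisomy12"].fillna(0.0).values
    meth_cluster = cohort.annotation.loc[cll, "methylation_cluster"].fillna(0.5).values

    def factor_matrix(drivers: list[np.ndarray]) -> np.ndarray:
        fs = [dr * 1.5 + rng.normal(0, 0.5, n) for dr in drivers]
        while len(fs) < n_factors:
            fs.append(rng.normal(0, 1, n))
        return np.column_stack(fs)

    f_expr = factor_matrix([u, tri])
    loadings = rng.normal(0, 1, (n_factors, n_genes)) / np.sqrt(n_factors)
    expr = f_expr @ loadings + rng.normal(0, 0.5, (n, n_genes))
    expression = pd.DataFrame(
        expr, index=pd.Index(cll, name="sample_id"),
        columns=[f"gene_{i + 1:04d}" for i in range(n_genes)],
    )

    f_meth = factor_matrix([2.0 * (meth_cluster - 0.5)])
    loadings = rng.normal(0, 1, (n_factors, n_cpgs)) / np.sqrt(n_factors)
    meth = f_meth @ loadings + rng.normal(0, 0.5, (n, n_cpgs))
    methylation = pd.DataFrame(
        meth, index=pd.Index(cll, name="sample_id"),
        columns=[f"cpg_{i + 1:04d}" for i in range(n_cpgs)],
    )
    return expression, methylation


@dataclass
class ScreenBundle:
    """Everything one simulated screen produces."""

    cohort: SyntheticCohort
    tensor: ViabilityTensor
    model: ResponseModel
    survival: pd.DataFrame
    expression: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None


def simulate_screen(
    cfg: CohortConfig | None = None,
    model: ResponseModel | None = None,
    seed: int = 0,
    technical_noise: bool = True,
    with_omics: bool = False,
) -> ScreenBundle:
    """Cohort -> viability -> survival (-> omics), all from one seed stream."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    cohort = generate_cohort(cfg, seed=seeds[0])
    model = model or default_response_model()
    tensor, _ = generate_viability(cohort, model, seed=seeds[1], technical_noise=technical_noise)
    survival = generate_survival(cohort, seed=seeds[2])
    expression = methylation = None
    if with_omics:
        expression, methylation = generate_omics(cohort, seed=seeds[3])
    return ScreenBundle(cohort, tensor, model, survival, expression, methylation)
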
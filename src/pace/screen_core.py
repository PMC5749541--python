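"""Plate-level viability normalization and the sample x drug x concentration tensor.

A screen plates one patient sample per 384-well plate: each drug occupies one
well per concentration, and a set of DMSO-only wells (32 in the default design)
serves as the on-plate negative control.  Viability is the ATP-luminescence
readout of a treated well divided by the median luminescence of the same-plate
control wells, expressed in percent (100 = control level).  Values above 100
are retained: drug-induced viability increases are a real signal (paradoxical
pathway activation), so no clipping is applied unless requested.

The central downstream object is :class:`ViabilityTensor`, a dense
``samples x drugs x concentrations`` array of percent viabilities with NaN for
unobserved cells.  Concentration index 1 is the *lowest* molar concentration;
"the 2 lowest concentrations" always means indices 1 and 2.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24
_WELL_RE = re.compile(r"^([A-Pa-p])([0-9]{1,2})$")

DOSE_METHODS = ("low2_mean", "all5_mean", "median_polish")


def canonical_well(well: str) -> str:
    """Validate a 384-well coordinate ('A1'..'P24', case-insensitive) and upper-case it."""
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise ValueError(f"not a 384-well coordinate: {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if not 1 <= col <= PLATE_COLS:
        raise ValueError(f"well column out of range 1-{PLATE_COLS}: {well!r}")
    return f"{row}{col}"


@dataclass(frozen=True)
class WellAssignment:
    """Role of one well on the plate layout."""

    role: str  # 'treated' | 'dmso_control' | 'empty'
    drug_id: str | None = None
    concentration_index: int | None = None  # 1 = lowest molar concentration

    def __post_init__(self) -> None:
        if self.role not in ("treated", "dmso_control", "empty"):
            raise ValueError(f"unknown well role: {self.role!r}")
        if self.role == "treated":
            if not self.drug_id or self.concentration_index is None:
                raise ValueError("treated wells need drug_id and concentration_index")
            if int(self.concentration_index) < 1:
                raise ValueError("concentration_index is 1-based (1 = lowest)")


@dataclass
class PlateReading:
    """Raw luminescence readout of one 384-well plate for one sample.

    ``wells`` maps well coordinate -> relative light units (RLU, nonnegative);
    ``layout`` maps well coordinate -> :class:`WellAssignment`.
    """

    plate_id: str
    sample_id: str
    wells: dict[str, float]
    layout: dict[str, WellAssignment]

    def __post_init__(self) -> None:
        self.wells = {canonical_well(w): float(v) for w, v in self.wells.items()}
        self.layout = {canonical_well(w): a for w, a in self.layout.items()}
        for w, v in self.wells.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"plate {self.plate_id}: negative or non-finite RLU in well {w}")

    def control_wells(self) -> list[str]:
        return [w for w, a in self.layout.items() if a.role == "dmso_control"]

    def control_values(self) -> np.ndarray:
        return np.array([self.wells[w] for w in self.control_wells() if w in self.wells], dtype=float)


def normalize_plate(plate: PlateReading, clip: bool = False) -> dict[str, float]:
    """Normalize one plate to percent viability against the DMSO-control median.

    viability(w) = 100 * RLU(w) / median(control RLUs).  Control wells are
    normalized too, so the median of normalized controls is exactly 100.  Empty
    wells are skipped.  A read well absent from the layout is an error naming
    the well; a nonpositive control median is a hard error.
    """
    controls = plate.control_values()
    if controls.size == 0:
        raise ValueError(f"plate {plate.plate_id}: no DMSO control wells with readings")
    ctrl_median = float(np.median(controls))
    if ctrl_median <= 0:
        raise ValueError(
            f"plate {plate.plate_id}: control median is {ctrl_median}, must be > 0"
        )
    out: dict[str, float] = {}
    for w, rlu in plate.wells.items():
        if w not in plate.layout:
            raise KeyError(f"plate {plate.plate_id}: well {w} has a reading but no layout entry")
        role = plate.layout[w].role
        if role == "empty":
            continue
        v = 100.0 * rlu / ctrl_median
        if clip:
            v = min(v, 100.0)
        out[w] = v
    return out


@dataclass
class TensorQCReport:
    """Bookkeeping from tensor assembly."""

    n_total: int
    n_filled: int
    n_masked: int
    n_replicate_wells_averaged: int


@dataclass
class ViabilityTensor:
    """Dense samples x drugs x concentrations percent-viability array.

    ``values[i, j, k]`` is the percent viability of sample ``sample_ids[i]``
    under drug ``drug_ids[j]`` at concentration index ``k + 1`` (ascending in
    molarity, 1 = lowest).  Missing cells are NaN; ``mask`` is True where
    missing.  All statistics downstream exclude masked cells.
    """

    sample_ids: list[str]
    drug_ids: list[str]
    values: np.ndarray  # float, shape (S, D, C), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[:2] != (len(self.sample_ids), len(self.drug_ids)):
            raise ValueError("tensor dimensions inconsistent with id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")

    @property
    def n_concentrations(self) -> int:
        return self.values.shape[2]

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is missing."""
        return np.isnan(self.values)

    def drug_matrix(self, drug_id: str) -> pd.DataFrame:
        """samples x concentrations matrix for one drug (columns 1..C)."""
        j = self._drug_index(drug_id)
        return pd.DataFrame(
            self.values[:, j, :],
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=pd.RangeIndex(1, self.n_concentrations + 1, name="concentration_index"),
        )

    def _drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id: {drug_id!r}") from None

    def select_samples(self, ids: Sequence[str]) -> "ViabilityTensor":
        """Subset to the given samples, keeping their order."""
        idx = [self.sample_ids.index(s) for s in ids]
        return ViabilityTensor(list(ids), list(self.drug_ids), self.values[idx].copy())

    def summary_matrix(self, method: str = "low2_mean") -> pd.DataFrame:
        """samples x drugs matrix of per-drug dose summaries."""
        cols = {d: dose_summarize(self, d, method=method) for d in self.drug_ids}
        return pd.DataFrame(cols, index=pd.Index(self.sample_ids, name="sample_id"))

    def profile_matrix(self) -> pd.DataFrame:
        """samples x (drugs * concentrations) matrix, columns '<drug>:<conc>'."""
        s, d, c = self.values.shape
        cols = [f"{drug}:{k}" for drug in self.drug_ids for k in range(1, c + 1)]
        return pd.DataFrame(
            self.values.reshape(s, d * c),
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=cols,
        )

    def to_frame(self) -> pd.DataFrame:
        """Lossless long-format view (sample_id, drug_id, concentration_index, viability_percent, masked)."""
        s, d, c = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.sample_ids, self.drug_ids, range(1, c + 1)],
            names=["sample_id", "drug_id", "concentration_index"],
        )
        df = pd.DataFrame({"viability_percent": self.values.reshape(-1)}, index=idx).reset_index()
        df["masked"] = df["viability_percent"].isna().astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ViabilityTensor":
        samples = list(pd.unique(df["sample_id"]))
        drugs = list(pd.unique(df["drug_id"]))
        n_conc = int(df["concentration_index"].max())
        values = np.full((len(samples), len(drugs), n_conc), np.nan)
        si = {s: i for i, s in enumerate(samples)}
        di = {d: i for i, d in enumerate(drugs)}
        for row in df.itertuples(index=False):
            if getattr(row, "masked", 0):
                continue
            v = row.viability_percent
            if pd.notna(v):
                values[si[row.sample_id], di[row.drug_id], int(row.concentration_index) - 1] = v
        return cls(samples, drugs, values)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ViabilityTensor":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def assemble_tensor(
    plates: Sequence[PlateReading],
    sample_ids: Sequence[str] | None = None,
    drug_ids: Sequence[str] | None = None,
    n_concentrations: int | None = None,
    clip: bool = False,
) -> tuple[ViabilityTensor, TensorQCReport]:
    """Normalize plates and assemble the viability tensor.

    The manifest (``sample_ids``, ``drug_ids``, ``n_concentrations``) defaults
    to whatever the plates contain, in order of first appearance.  When given
    explicitly, a treated well whose sample or drug is not in the manifest is
    an error.  Replicate wells for the same (sample, drug, concentration) are
    averaged.  Cells without any well stay masked (NaN).
    """
    seen_samples: list[str] = []
    seen_drugs: list[str] = []
    max_conc = 0
    normalized: list[tuple[str, dict[str, float], PlateReading]] = []
    for plate in plates:
        viab = normalize_plate(plate, clip=clip)
        normalized.append((plate.sample_id, viab, plate))
        if plate.sample_id not in seen_samples:
            seen_samples.append(plate.sample_id)
        for a in plate.layout.values():
            if a.role == "treated":
                if a.drug_id not in seen_drugs:
                    seen_drugs.append(a.drug_id)
                max_conc = max(max_conc, a.concentration_index)

    samples = list(sample_ids) if sample_ids is not None else seen_samples
    drugs = list(drug_ids) if drug_ids is not None else seen_drugs
    n_conc = int(n_concentrations) if n_concentrations is not None else max_conc
    si = {s: i for i, s in enumerate(samples)}
    di = {d: i for i, d in enumerate(drugs)}

    total = np.zeros((len(samples), len(drugs), n_conc))
    count = np.zeros_like(total, dtype=int)
    for sample, viab, plate in normalized:
        if sample not in si:
            raise ValueError(f"plate {plate.plate_id}: sample id {sample!r} not in manifest")
        for w, v in viab.items():
            a = plate.layout[w]
            if a.role != "treated":
                continue
            if a.drug_id not in di:
                raise ValueError(f"plate {plate.plate_id}: drug id {a.drug_id!r} not in manifest")
            if a.concentration_index > n_conc:
                raise ValueError(
                    f"plate {plate.plate_id}: concentration index {a.concentration_index} "
                    f"exceeds manifest maximum {n_conc}"
                )
            total[si[sample], di[a.drug_id], a.concentration_index - 1] += v
            count[si[sample], di[a.drug_id], a.concentration_index - 1] += 1

    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    tensor = ViabilityTensor(samples, drugs, values)
    n_total = int(np.prod(values.shape))
    n_filled = int((count > 0).sum())
    report = TensorQCReport(
        n_total=n_total,
        n_filled=n_filled,
        n_masked=n_total - n_filled,
        n_replicate_wells_averaged=int((count > 1).sum()),
    )
    logger.info(
        "assembled tensor %dx%dx%d: %d filled, %d masked, %d replicate cells averaged",
        len(samples), len(drugs), n_conc, n_filled, report.n_masked,
        report.n_replicate_wells_averaged,
    )
    return tensor, report


def qc_exclude_drugs(tensor: ViabilityTensor, excluded: Iterable[str]) -> ViabilityTensor:
    """Drop screen-QC-failed drugs entirely, preserving the order of the rest."""
    excluded = list(excluded)
    unknown = [d for d in excluded if d not in tensor.drug_ids]
    if unknown:
        raise ValueError(f"cannot exclude unknown drug ids: {unknown}")
    keep = [j for j, d in enumerate(tensor.drug_ids) if d not in excluded]
    if not keep:
        raise ValueError("QC exclusion would remove every drug")
    return ViabilityTensor(
        list(tensor.sample_ids),
        [tensor.drug_ids[j] for j in keep],
        tensor.values[:, keep, :].copy(),
    )


def dose_summarize(tensor: ViabilityTensor, drug_id: str, method: str = "low2_mean") -> pd.Series:
    """Collapse one drug's concentration series to a per-sample scalar.

    ``low2_mean``: mean of the 2 lowest-concentration unmasked values (if only
    one of the two is observed, that value is used; if neither, NaN).
    ``all5_mean``: mean of all unmasked concentrations.  ``median_polish``:
    overall + row effect from a Tukey median polish of the samples x
    concentrations matrix.  Missingness propagates as NaN, never raises.
    """
    if method not in DOSE_METHODS:
        raise ValueError(f"unknown dose summary method {method!r}; choose from {DOSE_METHODS}")
    m = tensor.drug_matrix(drug_id)
    if method == "low2_mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            out = np.nanmean(m.values[:, :2], axis=1)
        return pd.Series(out, index=m.index, name=drug_id)
    if method == "all5_mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmean(m.values, axis=1)
        return pd.Series(out, index=m.index, name=drug_id)
    from .genetic_association import median_polish  # lazy: avoids module cycle

    fit = median_polish(m.values)
    agg = np.where(fit.row_kept, fit.overall + fit.row_effects_full, np.nan)
    return pd.Series(agg, index=m.index, name=drug_id)


def control_drift_report(plates: Sequence[PlateReading], cv_threshold: float = 0.2) -> pd.DataFrame:
    """Per-plate control-well QC: count, median, coefficient of variation, flag.

    Plates whose control CV exceeds ``cv_threshold`` (or that have no controls)
    are flagged.  Purely diagnostic, never mutates data.
    """
    rows = []
    for plate in plates:
        ctrl = plate.control_values()
        if ctrl.size == 0:
            rows.append(
                dict(plate_id=plate.plate_id, sample_id=plate.sample_id, n_controls=0,
                     control_median=np.nan, control_cv=np.nan, flagged=True)
            )
            continue
        med = float(np.median(ctrl))
        mean = float(np.mean(ctrl))
        cv = float(np.std(ctrl, ddof=1) / mean) if ctrl.size > 1 and mean > 0 else 0.0
        rows.append(
            dict(plate_id=plate.plate_id, sample_id=plate.sample_id, n_controls=int(ctrl.size),
                 control_median=med, control_cv=cv, flagged=bool(cv > cv_threshold))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file contracts
# ---------------------------------------------------------------------------

def read_layout(path: str | Path) -> dict[str, WellAssignment]:
    """Read a plate layout TSV: columns well, role, drug_id, concentration_index."""
    df = pd.read_csv(path, sep="\t", dtype={"well": str})
    layout: dict[str, WellAssignment] = {}
    for row in df.itertuples(index=False):
        role = str(row.role)
        if role == "treated":
            layout[canonical_well(row.well)] = WellAssignment(
                "treated", str(row.drug_id), int(row.concentration_index)
            )
        else:
            layout[canonical_well(row.well)] = WellAssignment(role)
    return layout


def write_layout(layout: Mapping[str, WellAssignment], path: str | Path) -> None:
    rows = [
        dict(
            well=canonical_well(w), role=a.role,
            drug_id=a.drug_id if a.drug_id is not None else "",
            concentration_index=a.concentration_index if a.concentration_index is not None else "",
        )
        for w, a in layout.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_plates(plate_path: str | Path, layout_path: str | Path) -> list[PlateReading]:
    """Read long-format plate readings (plate_id, sample_id, well, rlu) + shared layout."""
    layout = read_layout(layout_path)
    df = pd.read_csv(plate_path, sep="\t", dtype={"well": str})
    plates = []
    for (plate_id, sample_id), grp in df.groupby(["plate_id", "sample_id"], sort=False):
        wells = {canonical_well(w): float(r) for w, r in zip(grp["well"], grp["rlu"])}
        plates.append(PlateReading(str(plate_id), str(sample_id), wells, dict(layout)))
    return plates


def write_plates(plates: Sequence[PlateReading], path: str | Path) -> None:
    rows = []
    for p in plates:
        for w, r in p.wells.items():
            rows.append(dict(plate_id=p.plate_id, sample_id=p.sample_id, well=w, rlu=r))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
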
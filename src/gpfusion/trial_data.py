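"""Trial phenotypes, NDVI covariates and predictor-block assembly.

Phenotype records are design-adjusted trait values for a wheat line in a
year (and optionally an environment). NDVI covariates are canopy-greenness
measurements taken four times during the vegetative (vg) period and twice
during grain filling (gf). Two NDVI layouts are supported:

* ``dates_aligned`` — timepoint *t* of a period is the same covariate
  column in every year (4 vg + 2 gf columns);
* ``average`` — the within-period mean (1 vg + 1 gf column).

:func:`assemble_predictors` turns a record table plus a
:class:`~gpfusion.genotype_qc.GenomicFeatures` into the per-modality design
blocks (year one-hot, genomic ``Z_L Lᵀ`` rows, standardized NDVI columns)
that every model in the package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gpfusion.genotype_qc import GenomicFeatures, genomic_inputs

PHENO_COLUMNS = ["line", "year", "environment", "trait", "value"]
NDVI_COLUMNS = ["line", "year", "period", "timepoint", "value"]
N_TIMEPOINTS = {"vg": 4, "gf": 2}


@dataclass(frozen=True)
class PredictorSpec:
    """Which predictor blocks enter a model.

    ``ndvi`` is a subset of ``{"vg", "gf"}``; ``ndvi_mode`` is
    ``dates_aligned``, ``average`` or ``none``. The year-by-line interaction
    requires both the year and the genomic block.
    """

    include_year: bool = True
    include_G: bool = True
    include_year_by_G: bool = False
    ndvi: frozenset = frozenset()
    ndvi_mode: str = "none"

    def __post_init__(self):
        object.__setattr__(self, "ndvi", frozenset(self.ndvi))
        if self.include_year_by_G and not (self.include_year and self.include_G):
            raise ValueError("year x G interaction requires both year and G blocks")
        if self.ndvi and self.ndvi_mode == "none":
            raise ValueError("ndvi periods requested but ndvi_mode is 'none'")
        if self.ndvi_mode not in ("dates_aligned", "average", "none"):
            raise ValueError(f"unknown ndvi_mode {self.ndvi_mode!r}")
        if not self.ndvi <= {"vg", "gf"}:
            raise ValueError(f"ndvi periods must be within {{'vg','gf'}}: {set(self.ndvi)}")

    def label(self) -> str:
        """Human-readable predictor-set label, e.g. ``Year + G + NDVI_vg_gf``."""
        parts = []
        if self.include_year:
            parts.append("Year")
        if self.include_G:
            parts.append("G")
        if self.include_year_by_G:
            parts.append("year x GID")
        if self.ndvi:
            parts.append("NDVI_" + "_".join(sorted(self.ndvi, reverse=True)))
        return " + ".join(parts)


@dataclass
class DesignBlocks:
    """Row-aligned model inputs for one trait's records."""

    y: np.ndarray
    X_year: np.ndarray            # n x (#years), one-hot; 0 columns if excluded
    ZLstar: np.ndarray            # n x J genomic features; 0 columns if excluded
    X_ndvi: np.ndarray            # n x (#ndvi columns), standardized
    line_index: np.ndarray        # record -> position in features.G
    year_index: np.ndarray        # record -> position in year_labels
    year_labels: list
    ndvi_names: list
    records: pd.DataFrame
    ndvi_raw: np.ndarray | None = None
    ndvi_center: np.ndarray | None = None
    ndvi_scale: np.ndarray | None = None
    spec: PredictorSpec | None = None
    features: GenomicFeatures | None = None

    @property
    def n(self) -> int:
        return len(self.y)

    def modality_dict(self) -> dict[str, np.ndarray]:
        """Non-empty blocks keyed by modality name, for the multimodal net."""
        out = {}
        if self.X_year.shape[1]:
            out["year"] = self.X_year
        if self.ZLstar.shape[1]:
            out["genomic"] = self.ZLstar
        if self.X_ndvi.shape[1]:
            out["ndvi"] = self.X_ndvi
        return out

    def stacked(self) -> np.ndarray:
        """All blocks concatenated column-wise (for single-matrix models)."""
        return np.column_stack([self.X_year, self.ZLstar, self.X_ndvi])


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype table contract and return a normalized copy."""
    missing = set(PHENO_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    rec = records.loc[:, PHENO_COLUMNS].copy()
    rec["value"] = rec["value"].astype(float)
    if not np.isfinite(rec["value"]).all():
        raise ValueError("non-finite phenotype values")
    dup = rec.duplicated(subset=["line", "year", "environment", "trait"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (line, year, environment, trait) records")
    return rec


def ndvi_wide(ndvi: pd.DataFrame, periods, mode: str) -> pd.DataFrame:
    """Pivot the long NDVI table to one row per (line, year).

    ``dates_aligned`` keeps each timepoint as a column (``vg1..vg4``,
    ``gf1..gf2``); ``average`` collapses each period to its mean.
    """
    missing = set(NDVI_COLUMNS) - set(ndvi.columns)
    if missing:
        raise ValueError(f"NDVI table missing columns: {sorted(missing)}")
    sub = ndvi[ndvi["period"].isin(list(periods))].copy()
    if mode == "average":
        wide = sub.pivot_table(
            index=["line", "year"], columns="period", values="value", aggfunc="mean"
        )
        wide = wide.reindex(columns=[p for p in ("vg", "gf") if p in periods])
        wide.columns = [f"{p}_mean" for p in wide.columns]
    else:
        sub["col"] = sub["period"] + sub["timepoint"].astype(int).astype(str)
        wide = sub.pivot_table(index=["line", "year"], columns="col", values="value")
        order = [
            f"{p}{t}" for p in ("vg", "gf") if p in periods
            for t in range(1, N_TIMEPOINTS[p] + 1)
        ]
        absent = [c for c in order if c not in wide.columns]
        if absent:
            raise ValueError(f"NDVI table lacks timepoint columns: {absent}")
        wide = wide.reindex(columns=order)
    return wide


def assemble_predictors(
    records: pd.DataFrame,
    features: GenomicFeatures,
    spec: PredictorSpec,
    ndvi: pd.DataFrame | None = None,
    train_idx: np.ndarray | None = None,
) -> DesignBlocks:
    """Build row-aligned design blocks for one trait.

    NDVI columns are standardized to mean 0 / unit variance using the rows in
    ``train_idx`` only (all rows when ``None``), so test records never leak
    into the scaling; the raw values are kept on the result for export.
    """
    rec = validate_records(records)
    traits = rec["trait"].unique()
    if len(traits) != 1:
        raise ValueError(f"records must contain a single trait, got {list(traits)}")

    line_pos = {l: i for i, l in enumerate(features.line_ids)}
    unknown = sorted(set(rec["line"]) - set(line_pos))
    if unknown:
        raise KeyError(f"lines absent from genomic features: {unknown[:10]}")
    line_index = rec["line"].map(line_pos).to_numpy(int)

    # year and environment are interchangeable split units; LOO over
    # environments relabels them upstream, so "year" here is the split label
    year_labels = sorted(rec["year"].astype(str).unique())
    year_pos = {yl: i for i, yl in enumerate(year_labels)}
    year_index = rec["year"].astype(str).map(year_pos).to_numpy(int)

    n = len(rec)
    if spec.include_year:
        X_year = np.zeros((n, len(year_labels)))
        X_year[np.arange(n), year_index] = 1.0
    else:
        X_year = np.zeros((n, 0))

    ZLstar = (
        genomic_inputs(features, line_index) if spec.include_G else np.zeros((n, 0))
    )

    ndvi_names: list = []
    X_ndvi = np.zeros((n, 0))
    raw = center = scale = None
    if spec.ndvi:
        if ndvi is None:
            raise ValueError("spec requests NDVI but no NDVI table was given")
        periods = [p for p in ("vg", "gf") if p in spec.ndvi]
        wide = ndvi_wide(ndvi, periods, spec.ndvi_mode)
        keys = pd.MultiIndex.from_frame(rec[["line", "year"]])
        missing_keys = [k for k in keys if k not in wide.index]
        if missing_keys:
            raise KeyError(f"NDVI missing for records: {missing_keys[:10]}")
        raw = wide.loc[keys].to_numpy(float)
        if np.isnan(raw).any():
            bad = keys[np.isnan(raw).any(axis=1)]
            raise KeyError(f"NDVI missing for records: {list(bad[:10])}")
        ndvi_names = list(wide.columns)
        tr = np.arange(n) if train_idx is None else np.asarray(train_idx, dtype=int)
        center = raw[tr].mean(axis=0)
        scale = raw[tr].std(axis=0, ddof=0)
        scale = np.where(scale == 0, 1.0, scale)
        X_ndvi = (raw - center) / scale

    return DesignBlocks(
        y=rec["value"].to_numpy(float),
        X_year=X_year,
        ZLstar=ZLstar,
        X_ndvi=X_ndvi,
        line_index=line_index,
        year_index=year_index,
        year_labels=year_labels,
        ndvi_names=ndvi_names,
        records=rec.reset_index(drop=True),
        ndvi_raw=raw,
        ndvi_center=center,
        ndvi_scale=scale,
        spec=spec,
        features=features,
    )


def read_phenotypes(path, sep: str = ",") -> pd.DataFrame:
    return validate_records(pd.read_csv(path, sep=sep))


def read_ndvi(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(NDVI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"NDVI table missing columns: {sorted(missing)}")
    return df
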
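"""Cross-validation protocols, accuracy metrics and the experiment grid.

Two protocols mirror how genomic prediction is assessed in multi-year
trials:

* **5-fold cross-validation by line** — lines (not records) are partitioned
  into five balanced folds, so every record of a held-out line is unseen;
  this measures prediction of *new lines* observed in known years.
* **Leave-one-year-out (LOO)** — all records of one year (or one
  environment) form the test set; models drop the year main effect, the
  year-by-line interaction and the year input tower, since the held-out
  label never appears in training.

Accuracy is summarized per fold by NRMSEP (root-mean-squared error of
prediction divided by the mean of the observed test values) and the Pearson
correlation between observed and predicted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gpfusion.baselines import GBMSpec, SVRSpec, fit_gbm, fit_svr_linear, predict_gbm
from gpfusion.gblup import GBLUPSpec, fit_gblup, predict_gblup
from gpfusion.mmdl import MMDLConfig, build_mmdl, predict_mmdl, train_mmdl
from gpfusion.trial_data import DesignBlocks, PredictorSpec, assemble_predictors

MODELS = ("gblup", "mmdl", "gbm", "svr")


@dataclass
class SplitPlan:
    scheme: str                     # "fivefold" | "loo"
    unit: str                       # "line" | "year" | "environment"
    folds: list                     # per fold: dict(test=<record idx>, train=<record idx>, label=...)
    seed: int | None = None


class MetricError(ValueError):
    pass


def nrmsep(obs, pred) -> float:
    """Root-mean-squared error of prediction divided by mean(obs).

    Scale-invariant: multiplying both vectors by c > 0 leaves it unchanged.
    Undefined for mean-zero observations (use a trait on its natural scale,
    or normalize by the standard deviation instead).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise MetricError("obs and pred must be equal-length vectors with >= 2 entries")
    m = obs.mean()
    if m == 0:
        raise MetricError(
            "mean of observed values is zero; mean-normalized RMSE undefined "
            "(consider normalizing by the standard deviation)"
        )
    return float(np.sqrt(np.mean((obs - pred) ** 2)) / m)


def pearson_cor(obs, pred) -> float:
    """Sample Pearson correlation; zero-variance input is an error, not 0."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise MetricError("obs and pred must be equal-length vectors with >= 3 entries")
    if obs.std() == 0 or pred.std() == 0:
        raise MetricError("correlation undefined: zero variance in obs or pred")
    return float(np.corrcoef(obs, pred)[0, 1])


def kfold_by_line(records: pd.DataFrame, k: int = 5, seed: int = 0) -> SplitPlan:
    """Random balanced partition of the line set; records follow their line."""
    lines = np.array(sorted(records["line"].unique()))
    if k > len(lines):
        raise ValueError(f"k={k} exceeds the {len(lines)} available lines")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(lines)
    groups = np.array_split(shuffled, k)
    folds = []
    line_col = records["line"].to_numpy()
    for f, grp in enumerate(groups):
        test_mask = np.isin(line_col, grp)
        folds.append(
            {
                "label": f"fold{f + 1}",
                "test": np.flatnonzero(test_mask),
                "train": np.flatnonzero(~test_mask),
                "lines": list(grp),
            }
        )
    return SplitPlan(scheme="fivefold", unit="line", folds=folds, seed=seed)


def loo_split(records: pd.DataFrame, holdout_label, unit: str = "year") -> SplitPlan:
    """Hold out every record of one year (or environment)."""
    if unit not in ("year", "environment"):
        raise ValueError("unit must be 'year' or 'environment'")
    labels = records[unit].unique()
    if holdout_label not in set(labels):
        raise KeyError(f"unknown {unit} label {holdout_label!r}; have {sorted(map(str, labels))}")
    if len(labels) < 2:
        raise ValueError(f"need at least 2 {unit} labels for a LOO split")
    mask = (records[unit] == holdout_label).to_numpy()
    folds = [
        {
            "label": str(holdout_label),
            "test": np.flatnonzero(mask),
            "train": np.flatnonzero(~mask),
        }
    ]
    return SplitPlan(scheme="loo", unit=unit, folds=folds)


def aggregate(per_fold: dict[str, list]) -> dict:
    """Mean and sample SD (n−1) across folds for each metric."""
    out = {}
    for metric, vals in per_fold.items():
        v = np.asarray(vals, dtype=float)
        out[f"{metric}_mean"] = float(v.mean())
        out[f"{metric}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
    return out


# ---------------------------------------------------------------------------
# model adapters: fit on a training index set, predict a test index set
# ---------------------------------------------------------------------------

def _loo_spec(spec: PredictorSpec) -> PredictorSpec:
    """LOO variant: no year main effect, no year-by-line interaction."""
    return PredictorSpec(
        include_year=False,
        include_G=spec.include_G,
        include_year_by_G=False,
        ndvi=spec.ndvi,
        ndvi_mode=spec.ndvi_mode,
    )


def _subset_blocks(blocks: DesignBlocks, idx: np.ndarray) -> DesignBlocks:
    return DesignBlocks(
        y=blocks.y[idx],
        X_year=blocks.X_year[idx],
        ZLstar=blocks.ZLstar[idx],
        X_ndvi=blocks.X_ndvi[idx],
        line_index=blocks.line_index[idx],
        year_index=blocks.year_index[idx],
        year_labels=blocks.year_labels,
        ndvi_names=blocks.ndvi_names,
        records=blocks.records.iloc[idx].reset_index(drop=True),
        spec=blocks.spec,
        features=blocks.features,
    )


def _fit_predict(model: str, blocks_tr: DesignBlocks, blocks_te: DesignBlocks,
                 model_config, seed: int) -> np.ndarray:
    if model == "gblup":
        spec = model_config or GBLUPSpec()
        # the split scheme owns the predictor structure (LOO drops year terms)
        spec = replace(spec, predictor=blocks_tr.spec)
        spec.chain.seed = seed
        summary = fit_gblup(blocks_tr, spec)
        return predict_gblup(summary, blocks_te)
    if model == "mmdl":
        # train on the standardized response; raw trait scales sit far from
        # the zero-initialized output neuron
        cfg = model_config or MMDLConfig()
        cfg.seed = seed
        m_y, s_y = blocks_tr.y.mean(), blocks_tr.y.std() or 1.0
        tr = blocks_tr.modality_dict()
        net = build_mmdl({q: m.shape[1] for q, m in tr.items()}, cfg)
        train_mmdl(net, tr, (blocks_tr.y - m_y) / s_y, cfg)
        return m_y + s_y * predict_mmdl(net, blocks_te.modality_dict())
    if model == "gbm":
        spec = model_config or GBMSpec()
        spec.seed = seed
        ens = fit_gbm(blocks_tr.stacked(), blocks_tr.y, spec)
        return predict_gbm(ens, blocks_te.stacked())
    if model == "svr":
        # standardize the response so the tube width eps spans 0.1 response
        # SD; features keep their native scales (the genomic columns carry
        # meaningful relative magnitudes)
        spec = model_config or SVRSpec()
        m_y, s_y = blocks_tr.y.mean(), blocks_tr.y.std() or 1.0
        beta0, beta = fit_svr_linear(blocks_tr.stacked(), (blocks_tr.y - m_y) / s_y, spec)
        return m_y + s_y * (beta0 + blocks_te.stacked() @ beta)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def run_experiment(
    records: pd.DataFrame,
    features,
    plan: SplitPlan,
    models=("gblup",),
    predictor_specs=(PredictorSpec(),),
    ndvi: pd.DataFrame | None = None,
    model_configs: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every model on every predictor set under one split plan.

    Returns a long-format table with one row per (model, predictor set,
    NDVI mode, fold, metric). Every model sees identical folds, so paired
    comparisons across models are valid. Failures carry the model and fold
    in the raised error.
    """
    model_configs = model_configs or {}
    rows = []
    for spec in predictor_specs:
        eff_spec = _loo_spec(spec) if plan.scheme == "loo" else spec
        for model in models:
            for f, fold in enumerate(plan.folds):
                try:
                    blocks = assemble_predictors(
                        records, features, eff_spec, ndvi=ndvi, train_idx=fold["train"]
                    )
                    tr = _subset_blocks(blocks, fold["train"])
                    te = _subset_blocks(blocks, fold["test"])
                    pred = _fit_predict(model, tr, te, model_configs.get(model), seed)
                    metrics = {"nrmsep": nrmsep(te.y, pred)}
                    try:
                        metrics["cor"] = pearson_cor(te.y, pred)
                    except MetricError:
                        # degenerate predictions: flag with NaN rather than 0
                        metrics["cor"] = float("nan")
                except Exception as err:
                    raise RuntimeError(
                        f"model={model} predictor='{spec.label()}' fold={fold['label']}: {err}"
                    ) from err
                for metric, value in metrics.items():
                    rows.append(
                        {
                            "model": model,
                            "predictors": spec.label(),
                            "ndvi_mode": spec.ndvi_mode,
                            "scheme": plan.scheme,
                            "fold": fold["label"],
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Fold-aggregated table: mean and SD per (model, predictors, metric)."""
    g = results.groupby(["model", "predictors", "ndvi_mode", "scheme", "metric"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    return out


def plot_summary(results: pd.DataFrame, path, metric: str = "cor") -> None:
    """Bar chart of fold-mean accuracy per model and predictor set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summ = summarize(results)
    sub = summ[summ["metric"] == metric].copy()
    sub["label"] = sub["model"] + "\n" + sub["predictors"]
    fig, ax = plt.subplots(figsize=(1.2 * len(sub) + 2, 4))
    ax.bar(sub["label"], sub["mean"], yerr=sub["sd"].fillna(0), capsize=3)
    ax.set_ylabel({"cor": "Pearson correlation", "nrmsep": "NRMSEP"}.get(metric, metric))
    ax.set_title(f"{sub['scheme'].iloc[0]} accuracy by model")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
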
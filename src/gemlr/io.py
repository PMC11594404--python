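"""CSV/JSON input and report output.

Feature tables are plain CSVs with a header row and the sample-ID column
first (configurable).  Models are a single versioned JSON document so a
fit can be archived, diffed, and reloaded bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationResult
from .exceptions import SchemaError
from .model_core import (
    FeatureTable,
    GeMLRModel,
    gate_posterior,
    predict_hard,
    predict_soft,
)
from .model_selection import CVResult

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_model",
    "read_model",
    "write_report",
    "write_cv_result",
    "read_cv_result",
]


def read_dataset(path, outcome_col: str, sample_id_col: str | None = None,
                 weight_col: str | None = None, outcome_map: dict | None = None):
    """Load and validate a samples x features CSV.

    Returns ``(FeatureTable, y, weights)`` where ``weights`` is None when
    no weight column is configured.  The sample-ID column defaults to the
    first column.  Rows with missing feature values are rejected with
    their IDs listed; outcome codes must be 0/1 or covered by
    ``outcome_map``.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError("dataset needs a sample-ID column and features")
    if sample_id_col is None:
        sample_id_col = df.columns[0]
    for col in [sample_id_col, outcome_col] + ([weight_col] if weight_col else []):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not found in {path}")
    ids = df[sample_id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise SchemaError(f"duplicate sample IDs: {dupes}")

    raw_y = df[outcome_col]
    if outcome_map is not None:
        unknown = sorted(set(raw_y.astype(str)) - set(map(str, outcome_map)))
        if unknown:
            raise SchemaError(f"outcome codes not in mapping: {unknown}")
        y = raw_y.astype(str).map({str(k): v for k, v in outcome_map.items()})
    else:
        y = raw_y
    y = np.asarray(y)
    if not np.all(np.isin(np.unique(y), [0, 1])):
        raise SchemaError(
            f"outcome column {outcome_col!r} has codes outside 0/1 "
            f"({np.unique(y)[:10]}); provide an outcome_map")
    y = y.astype(int)

    weights = None
    if weight_col is not None:
        weights = pd.to_numeric(df[weight_col], errors="coerce").to_numpy(float)
        if np.isnan(weights).any():
            raise SchemaError(f"non-numeric values in weight column {weight_col!r}")

    drop = [sample_id_col, outcome_col] + ([weight_col] if weight_col else [])
    feat = df.drop(columns=drop)
    for col in feat.columns:
        coerced = pd.to_numeric(feat[col], errors="coerce")
        bad = coerced.isna() & feat[col].notna()
        if bad.any():
            rows = [ids[i] for i in np.flatnonzero(bad.to_numpy())]
            raise SchemaError(f"non-numeric cells in column {col!r}, rows {rows}")
        feat[col] = coerced
    if feat.isna().any().any():
        rows = [ids[i] for i in np.flatnonzero(feat.isna().any(axis=1).to_numpy())]
        raise SchemaError(f"missing feature values in rows: {rows}")
    table = FeatureTable(feat.to_numpy(float), ids, list(feat.columns))
    return table, y, weights


def write_dataset(path, table: FeatureTable, y=None, outcome_col="outcome",
                  sample_id_col="sample_id"):
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, sample_id_col, table.sample_ids)
    if y is not None:
        df[outcome_col] = np.asarray(y)
    df.to_csv(path, index=False)


def write_model(path, model: GeMLRModel):
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_model(path) -> GeMLRModel:
    return GeMLRModel.from_dict(json.loads(Path(path).read_text()))


def write_cv_result(path, result: CVResult):
    Path(path).write_text(json.dumps({
        "fold_aucs": result.fold_aucs,
        "repeat_means": result.repeat_means,
        "cv_auc": result.cv_auc,
        "se": result.se,
        "ci": list(result.ci),
        "config": result.config,
    }, indent=1))


def read_cv_result(path) -> CVResult:
    d = json.loads(Path(path).read_text())
    return CVResult(fold_aucs=d["fold_aucs"], repeat_means=d["repeat_means"],
                    cv_auc=d["cv_auc"], se=d["se"], ci=tuple(d["ci"]),
                    config=d.get("config", {}))


def write_report(outdir, model: GeMLRModel, table: FeatureTable | None = None,
                 annotations: list[AnnotationResult] | None = None,
                 cv_results: dict | None = None):
    """Write tabular summaries of a fitted model.

    ``coefficients.tsv`` — one row per cluster over classifier features;
    ``memberships.tsv`` — per-sample gate posteriors and hard cluster;
    ``annotations.tsv`` — forward-selection traces; ``cv_summary.tsv`` —
    CV AUCs per configuration.  Returns the list of files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    feat_names = (model.standardizer.feature_names
                  if model.standardizer is not None else None)
    cls_names = ([feat_names[j] for j in model.roles.classifier_features]
                 if feat_names else
                 [f"f{j}" for j in model.roles.classifier_features])
    rows = []
    for c, h in enumerate(model.heads):
        row = {"cluster": c + 1, "head": type(h).__name__}
        if hasattr(h, "coefficients"):
            row.update(dict(zip(cls_names, h.coefficients)))
            row["intercept"] = h.intercept
        else:
            row["prob1"] = h.prob1
        rows.append(row)
    path = outdir / "coefficients.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    written.append(path)

    if table is not None:
        Z = (model.standardizer.transform(table)
             if model.standardizer is not None else table)
        W = np.atleast_2d(gate_posterior(
            Z.values[:, model.roles.gate_features], model.gate))
        hard, prob = predict_hard(table, model)
        soft = predict_soft(table, model)
        df = pd.DataFrame(W, columns=[f"posterior_c{c + 1}"
                                      for c in range(model.n_clusters)])
        df.insert(0, "sample_id", table.sample_ids)
        df["hard_cluster"] = np.atleast_1d(hard) + 1
        df["p_soft"] = np.atleast_1d(soft)
        df["p_hard"] = np.atleast_1d(prob)
        path = outdir / "memberships.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    if annotations is not None:
        gate_names = ([feat_names[j] for j in model.roles.gate_features]
                      if feat_names else
                      [f"f{j}" for j in model.roles.gate_features])
        rows = []
        for ann in annotations:
            for step, (j, a) in enumerate(ann.trace, start=1):
                rows.append({"cluster": ann.cluster + 1, "step": step,
                             "feature": gate_names[j], "A_c": a,
                             "A_full": ann.A_full,
                             "stop_reason": ann.stop_reason})
        path = outdir / "annotations.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)

    if cv_results is not None:
        rows = []
        for label, res in cv_results.items():
            rows.append({"config": label, "cv_auc": res.cv_auc, "se": res.se,
                         "ci_low": res.ci[0], "ci_high": res.ci[1],
                         **{f"repeat{r + 1}": m
                            for r, m in enumerate(res.repeat_means)}})
        path = outdir / "cv_summary.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
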
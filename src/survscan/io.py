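"""Readers and writers for the TSV/CSV formats the pipeline consumes.

All tabular IO goes through pandas; the separator is inferred from the file
extension (.csv -> comma, anything else -> tab).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountMatrix, ExpressionMatrix, NormalizationFactors
from .overlap import DETable
from .survival import SurvivalCohort


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_counts(
    counts_path, lengths_path, groups_path=None
) -> CountMatrix:
    """Counts table (first column gene id) + gene-length table (+ groups)."""
    df = pd.read_csv(counts_path, sep=_sep(counts_path), index_col=0)
    lengths = pd.read_csv(lengths_path, sep=_sep(lengths_path), index_col=0).iloc[:, 0]
    groups = None
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep=_sep(groups_path), index_col=0).iloc[:, 0]
        groups = [gdf[s] for s in df.columns]
    return CountMatrix.from_dataframe(df, lengths, group_labels=groups)


def write_counts(cm: CountMatrix, counts_path, lengths_path) -> None:
    pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids).to_csv(
        counts_path, sep=_sep(counts_path), index_label="gene_id"
    )
    pd.DataFrame(
        {"length_bp": cm.gene_lengths_bp}, index=cm.gene_ids
    ).to_csv(lengths_path, sep=_sep(lengths_path), index_label="gene_id")


def write_expression(em: ExpressionMatrix, path, nf: NormalizationFactors | None = None) -> None:
    """Expression TSV with a header comment recording scale and TMM settings."""
    with open(path, "w") as fh:
        if nf is not None:
            fh.write(
                f"# scale={em.scale_tag} trim_m={nf.trim_m} trim_a={nf.trim_a} "
                f"reference={nf.reference_sample}\n"
            )
        else:
            fh.write(f"# scale={em.scale_tag}\n")
        em.to_frame().to_csv(fh, sep=_sep(path), index_label="gene_id")


def read_expression(path) -> ExpressionMatrix:
    scale = "log2_fpkm_plus1"
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first[1:].split():
            if token.startswith("scale="):
                scale = token.split("=", 1)[1]
    df = pd.read_csv(path, sep=_sep(path), index_col=0, skiprows=skip)
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        values=df.to_numpy(float),
        scale_tag=scale,
    )


def write_factors(nf: NormalizationFactors, path) -> None:
    nf.to_frame().to_csv(path, sep=_sep(path), index=False)


def read_survival(path, patient_id="patient_id", time="time", event="event") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    missing = {patient_id, time, event} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_survival(cohort: SurvivalCohort, path) -> None:
    pd.DataFrame(
        {
            "patient_id": cohort.patient_ids,
            "time": cohort.time,
            "event": cohort.event,
            "expr": cohort.expr,
        }
    ).to_csv(path, sep=_sep(path), index=False)


def cohort_from_tables(
    survival_df: pd.DataFrame,
    expr_series: pd.Series,
    patient_id: str = "patient_id",
    time: str = "time",
    event: str = "event",
) -> SurvivalCohort:
    """Join a survival table with per-patient expression by patient id."""
    ids = survival_df[patient_id].astype(str)
    expr_series = expr_series.copy()
    expr_series.index = expr_series.index.astype(str)
    orphans = sorted(set(ids) - set(expr_series.index))
    if orphans:
        raise ValueError(f"patients without expression values: {orphans[:10]}")
    return SurvivalCohort(
        time=survival_df[time].to_numpy(float),
        event=survival_df[event].to_numpy(),
        expr=expr_series.reindex(ids).to_numpy(float),
        patient_ids=ids.to_numpy(object),
    )


def read_de_table(path, gene="gene", log2_fc="log2fc", p_value="pvalue", fdr="padj") -> DETable:
    df = pd.read_csv(path, sep=_sep(path))
    missing = {gene, log2_fc, p_value} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return DETable.from_dataframe(df, gene, log2_fc, p_value, fdr)


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
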
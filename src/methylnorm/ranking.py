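"""Cross-dataset ranking of preprocessing methods from metric reports.

The procedure, run separately for Type I and Type II probes:

A. compute DMRSE, the three genotype-group scores and Seabird per method;
B. collapse the genotype-group scores to one GCOSE (their mean);
C. within each dataset, rank methods on each metric (ascending — lower is
   better), ties sharing the mean rank;
D. average the three metric ranks per method;
E. average those mean ranks across datasets;
F. rank the per-type averages, again with mean-rank ties.

The reported table carries the Type I rank, the Type II rank, and their
average per method.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .datatypes import ValidationError
from .metrics import MetricReport

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("dmrse", "gcose", "seabird")


def _reports_to_wide(reports) -> pd.DataFrame:
    if isinstance(reports, pd.DataFrame):
        df = reports.copy()
        if "metric" in df.columns:  # tidy long form
            df = df[df["metric"].isin(METRIC_COLUMNS)]
            df = df.pivot_table(
                index=["dataset", "method", "assay_type"],
                columns="metric",
                values="value",
                aggfunc="first",
            ).reset_index()
        return df
    rows = []
    for r in reports:
        rows.append(
            {
                "dataset": r.dataset_id,
                "method": r.method,
                "assay_type": r.assay_type,
                "dmrse": r.dmrse,
                "gcose": r.gcose,
                "seabird": r.seabird,
            }
        )
    return pd.DataFrame(rows)


def rank_methods(reports: Sequence[MetricReport] | pd.DataFrame) -> pd.DataFrame:
    """Steps A-F: collapse, rank within dataset, average across datasets, re-rank.

    Accepts a list of :class:`MetricReport` or a tidy/wide metrics frame.
    Returns a frame indexed by method with columns ``rank_typeI``,
    ``rank_typeII`` and ``average`` (ties share mean ranks, so values like
    1.5 occur).  A metric missing for *all* dataset/method cells (e.g.
    Seabird on single-sex data) is dropped with a logged note; a metric
    missing for only some cells is an error.
    """
    df = _reports_to_wide(reports)
    if df.empty or df["method"].nunique() < 2:
        raise ValidationError("ranking needs reports for at least 2 methods")
    metrics = []
    for metric in METRIC_COLUMNS:
        if metric not in df.columns or df[metric].isna().all():
            logger.warning("metric %r missing everywhere; ranking without it", metric)
            continue
        if df[metric].isna().any():
            missing = df.loc[df[metric].isna(), ["dataset", "method", "assay_type"]]
            raise ValidationError(
                f"metric {metric!r} missing for cells:\n{missing.to_string(index=False)}"
            )
        metrics.append(metric)
    if not metrics:
        raise ValidationError("no usable metrics to rank")

    type_ranks = {}
    for assay_type, sub in df.groupby("assay_type"):
        mean_ranks = []
        for _, per_dataset in sub.groupby("dataset"):
            per_dataset = per_dataset.set_index("method")
            # step C: ascending ranks per metric; step D: mean across metrics
            ranks = per_dataset[metrics].rank(axis=0, method="average")
            mean_ranks.append(ranks.mean(axis=1))
        # step E: mean of mean ranks across datasets
        across = pd.concat(mean_ranks, axis=1)
        if across.isna().any().any():
            raise ValidationError("methods are not present in every dataset")
        # step F: final rank of the cross-dataset averages
        type_ranks[assay_type] = across.mean(axis=1).rank(method="average")

    table = pd.DataFrame(
        {
            "rank_typeI": type_ranks.get("I"),
            "rank_typeII": type_ranks.get("II"),
        }
    )
    table["average"] = table[["rank_typeI", "rank_typeII"]].mean(axis=1)
    table.index.name = "method"
    return table.sort_index()
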
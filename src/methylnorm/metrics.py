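"""Data-quality metrics built on probes with known expected behaviour.

Three independent metrics score a beta matrix, each smaller-is-better:

* **DMRSE** — probes inside imprinted differentially methylated regions carry
  one methylated and one unmethylated allele, so their expected beta is 0.5.
  DMRSE is the pooled standard deviation of all iDMR beta values divided by
  the square root of the number of samples: a standard-error-like measure of
  residual technical variance.
* **GCOSE** — the array's SNP genotyping control probes produce trimodal beta
  (homozygous BB / heterozygous AB / homozygous AA clusters near 0, 0.5, 1).
  Each probe is partitioned by k-means (k = 3); within-cluster sums of squares
  and cluster sizes are summed over probes per genotype group, the summed SS is
  divided by the summed size and by sqrt(total samples), and the three group
  values are averaged.
* **Seabird** — X-chromosome inactivation hypermethylates the inactive X in
  females, so a per-probe sex-difference t-test should flag X-chromosome
  probes.  Seabird is 1 - AUC of the ROC using the t-test p-value to predict
  X-chromosome location: 0 for a perfect predictor, 0.5 for chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

GENOTYPE_GROUPS = ("BB", "AB", "AA")
_CANONICAL_CENTERS = np.array([0.2, 0.5, 0.8])


@dataclass
class MetricReport:
    """DMRSE / GCOSE / Seabird values for one method x assay type x dataset."""

    dataset_id: str
    method: str
    assay_type: str
    n_samples: int
    dmrse: float | None = None
    gcose_by_group: dict | None = None
    gcose: float | None = None
    seabird: float | None = None
    notes: list = field(default_factory=list)


def _beta_values(betas) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(betas, BetaMatrix):
        return betas.values.to_numpy(dtype=float), betas
    if isinstance(betas, pd.DataFrame):
        return betas.to_numpy(dtype=float), None
    return np.asarray(betas, dtype=float), None


def dmrse(betas, idmr_mask=None, mode: str = "pooled") -> float:
    """Standard error of imprinted-DMR betas (expected value 0.5 throughout).

    ``mode='pooled'`` (default) divides the standard deviation of the full
    pooled set of iDMR beta values by sqrt(n samples).  ``mode='row'`` and
    ``mode='col'`` average per-probe (respectively per-sample) standard
    deviations first.
    """
    arr, bm = _beta_values(betas)
    if idmr_mask is None:
        if bm is None:
            raise ValidationError("idmr_mask is required when betas carry no manifest")
        idmr_mask = bm.probes["IsIDMR"].to_numpy()
    idmr_mask = np.asarray(idmr_mask)
    if idmr_mask.dtype != bool:
        mask = np.zeros(arr.shape[0], dtype=bool)
        mask[idmr_mask] = True
        idmr_mask = mask
    if not idmr_mask.any():
        raise ValidationError("no iDMR probes in manifest")
    sub = arr[idmr_mask]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValidationError("DMRSE needs >= 2 iDMR probes and >= 2 samples")
    n_samples = sub.shape[1]
    if mode == "pooled":
        sd = float(np.std(sub, ddof=1))
    elif mode == "row":
        sd = float(np.mean(np.std(sub, axis=1, ddof=1)))
    elif mode == "col":
        sd = float(np.mean(np.std(sub, axis=0, ddof=1)))
    else:
        raise ValidationError(f"unknown DMRSE mode {mode!r}")
    return sd / np.sqrt(n_samples)


def _kmeans_1d(
    x: np.ndarray, centers: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic Lloyd iteration in one dimension from fixed initial centers.

    Empty clusters keep their centers.  Returns (labels, final centers).
    """
    centers = np.array(centers, dtype=float)
    labels = np.zeros(x.size, dtype=int)
    for _ in range(max_iter):
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for k in range(centers.size):
            members = x[labels == k]
            if members.size:
                new[k] = members.mean()
        if np.max(np.abs(new - centers)) < tol:
            centers = new
            break
        centers = new
    labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    return labels, centers


def _assign_groups(centers: np.ndarray) -> list[int]:
    """Map cluster centers (ascending) to genotype group slots BB/AB/AA."""
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(centers[:, None] - _CANONICAL_CENTERS[None, :])
    rows, cols = linear_sum_assignment(cost)
    out = [0] * centers.size
    for r, c in zip(rows, cols):
        out[r] = int(c)
    return out


def gcose(
    betas,
    snp_mask=None,
    seed: int = 0,
    init_centers: Sequence[float] = (0.2, 0.5, 0.8),
) -> tuple[dict, float]:
    """Genotype Combined Standard Error from SNP control probes.

    Per SNP probe, k-means (k = 3, fixed initial centers, Lloyd iteration)
    partitions the probe's betas across samples; clusters are labelled by
    ascending center (BB < AB < AA).  Within-cluster sums of squares and
    cluster sizes are summed over probes per group g, MS_g = sum(SS_g) /
    sum(n_g), each divided by sqrt(total samples); GCOSE is the mean of the
    three group values.

    ``seed`` is accepted for interface uniformity; the procedure is fully
    deterministic (fixed initial centers), so it is unused.

    Returns ``(gcose_by_group, gcose)``.
    """
    del seed
    arr, bm = _beta_values(betas)
    if snp_mask is None:
        if bm is None:
            raise ValidationError("snp_mask is required when betas carry no manifest")
        snp_mask = bm.probes["IsSNP"].to_numpy()
    snp_mask = np.asarray(snp_mask)
    if snp_mask.dtype != bool:
        mask = np.zeros(arr.shape[0], dtype=bool)
        mask[snp_mask] = True
        snp_mask = mask
    if not snp_mask.any():
        raise ValidationError("no SNP probes in manifest")
    sub = arr[snp_mask]
    n_samples = sub.shape[1]
    if n_samples < 3:
        raise ValidationError("GCOSE needs >= 3 samples")
    init = np.asarray(init_centers, dtype=float)
    ss_sum = np.zeros(3)
    n_sum = np.zeros(3)
    for row in sub:
        distinct = np.unique(row)
        if distinct.size < 3:
            # degenerate probe: cluster with reduced k; it contributes only
            # to the genotype groups it forms
            logger.info("SNP probe with %d distinct values; reduced-k clustering", distinct.size)
            k = distinct.size
            labels, centers = _kmeans_1d(row, distinct)
        else:
            labels, centers = _kmeans_1d(row, init)
        present = np.unique(labels)
        order = present[np.argsort(centers[present])]
        groups = _assign_groups(centers[order])
        for cluster, g in zip(order, groups):
            members = row[labels == cluster]
            ss_sum[g] += float(np.sum((members - members.mean()) ** 2))
            n_sum[g] += members.size
    by_group = {}
    root_n = np.sqrt(n_samples)
    for g, label in enumerate(GENOTYPE_GROUPS):
        ms = ss_sum[g] / n_sum[g] if n_sum[g] > 0 else 0.0
        by_group[label] = ms / root_n
    return by_group, float(np.mean(list(by_group.values())))


def sex_difference_pvalues(betas, sexes) -> np.ndarray:
    """Per-probe two-sided Welch t-test p-values for male/female difference.

    Probes with zero variance in both groups get p = 1 when the group means
    are equal and p = 0 when they differ (complete separation).
    """
    arr, _ = _beta_values(betas)
    sexes = np.asarray(pd.Series(sexes).astype(str).str.lower())
    male = sexes == "male"
    female = sexes == "female"
    if male.sum() < 2 or female.sum() < 2:
        raise ValidationError(
            "sex-difference test needs >= 2 males and >= 2 females "
            "(single-sex data makes the test redundant)"
        )
    a, b = arr[:, male], arr[:, female]
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(result.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        equal_means = np.isclose(a[bad].mean(axis=1), b[bad].mean(axis=1))
        p[bad] = np.where(equal_means, 1.0, 0.0)
    return p


def roc_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUC by the rank-sum (Mann-Whitney) formulation; ties share average rank."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    n_pos = int(positives.sum())
    n_neg = int((~positives).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)
    return float((ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def seabird(
    betas,
    sexes=None,
    chromosomes=None,
    include_y: bool = True,
    pvalues: np.ndarray | None = None,
) -> float:
    """1 - AUC of sex-difference p-values predicting X-chromosome location.

    Smaller p predicts X, so the ROC score is -p; positives are X-chromosome
    probes.  ``include_y=False`` drops Y-chromosome probes from the negatives.
    Precomputed ``pvalues`` may be supplied to skip the t-tests.
    """
    arr, bm = _beta_values(betas)
    if chromosomes is None:
        if bm is None:
            raise ValidationError("chromosomes required when betas carry no manifest")
        chromosomes = bm.probes["Chromosome"].to_numpy()
    chromosomes = np.asarray(chromosomes, dtype=str)
    chrom = np.char.upper(np.char.replace(chromosomes, "chr", ""))
    if pvalues is None:
        if sexes is None and bm is not None:
            sexes = bm.samples["Sex"]
        pvalues = sex_difference_pvalues(arr, sexes)
    pvalues = np.asarray(pvalues, dtype=float)
    keep = np.ones(len(chrom), dtype=bool)
    if not include_y:
        keep &= chrom != "Y"
    positives = chrom[keep] == "X"
    auc = roc_auc(-pvalues[keep], positives)
    return 1.0 - auc


def count_significant_sex_differences(
    pvalues: np.ndarray, n_tests: int | None = None, level: float = 0.05
) -> int:
    """Number of probes significant after Bonferroni correction."""
    p = np.asarray(pvalues, dtype=float)
    if n_tests is None:
        n_tests = p.size
    return int((p < level / n_tests).sum())


def evaluate_all(
    betas_by_method: Mapping[str, BetaMatrix],
    probes: pd.DataFrame | None = None,
    sexes=None,
    dataset_id: str = "dataset",
    seed: int = 0,
) -> list[MetricReport]:
    """Compute all three metrics per method and per assay type.

    Metrics are computed on the probe subset of each assay type (Seabird's ROC
    is restricted to probes of that type).  A metric that cannot be computed
    (e.g. Seabird on single-sex data) is recorded as missing with a note
    rather than raising.
    """
    reports: list[MetricReport] = []
    for method, betas in betas_by_method.items():
        manifest = probes if probes is not None else betas.probes
        manifest = manifest.loc[betas.values.index]
        sample_sexes = sexes if sexes is not None else betas.samples["Sex"]
        for assay_type in ("I", "II"):
            mask = (manifest["AssayType"] == assay_type).to_numpy()
            sub = betas.values.loc[mask]
            sub_manifest = manifest.loc[mask]
            report = MetricReport(
                dataset_id=dataset_id,
                method=method,
                assay_type=assay_type,
                n_samples=sub.shape[1],
            )
            try:
                report.dmrse = dmrse(sub, sub_manifest["IsIDMR"].to_numpy())
            except ValidationError as exc:
                report.notes.append(f"dmrse: {exc}")
                logger.warning("%s/%s/%s DMRSE skipped: %s", dataset_id, method, assay_type, exc)
            try:
                by_group, combined = gcose(sub, sub_manifest["IsSNP"].to_numpy(), seed=seed)
                report.gcose_by_group = by_group
                report.gcose = combined
            except ValidationError as exc:
                report.notes.append(f"gcose: {exc}")
                logger.warning("%s/%s/%s GCOSE skipped: %s", dataset_id, method, assay_type, exc)
            try:
                report.seabird = seabird(
                    sub,
                    sexes=sample_sexes,
                    chromosomes=sub_manifest["Chromosome"].to_numpy(),
                )
            except ValidationError as exc:
                report.notes.append(f"seabird: {exc}")
                logger.warning("%s/%s/%s Seabird skipped: %s", dataset_id, method, assay_type, exc)
            reports.append(report)
    return reports


def reports_to_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Tidy frame (dataset, method, assay_type, metric, value) from reports."""
    rows = []
    for r in reports:
        for metric, value in (
            ("dmrse", r.dmrse),
            ("gcose", r.gcose),
            ("seabird", r.seabird),
        ):
            rows.append(
                {
                    "dataset": r.dataset_id,
                    "method": r.method,
                    "assay_type": r.assay_type,
                    "metric": metric,
                    "value": value,
                    "n_samples": r.n_samples,
                }
            )
        if r.gcose_by_group:
            for g, v in r.gcose_by_group.items():
                rows.append(
                    {
                        "dataset": r.dataset_id,
                        "method": r.method,
                        "assay_type": r.assay_type,
                        "metric": f"gcose_{g}",
                        "value": v,
                        "n_samples": r.n_samples,
                    }
                )
    return pd.DataFrame(rows)
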
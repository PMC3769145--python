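"""Beta/M-value arithmetic and the preprocessing method registry.

The methylation fraction at a CpG is summarized as

    beta = M / (M + U + alpha)

with M, U the methylated/unmethylated intensities and alpha (default 100) a
stabilizing offset; the unbounded alternative is the M-value
log2((M + alpha) / (U + alpha)), a logit-like transform of beta.  Twelve named
preprocessing methods (raw, betaqn, naten, nanet, nanes, danes, danet, danen,
daten1, daten2, nasen, dasen) combine optional Type I/II background
equalization with a between-array quantile-normalization scheme before beta
is computed; ``dasen`` — background equalization followed by separate QN of
methylated/unmethylated x Type I/Type II intensities — is the recommended
default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .background import BackgroundOffsets, equalize_background, estimate_background_offsets
from .datatypes import (
    METHOD_NAMES,
    BetaMatrix,
    IntensityDataset,
    MethodSpec,
    ValidationError,
)
from .qn import quantile_normalize, quantile_normalize_grouped


def compute_beta(dataset: IntensityDataset, alpha: float = 100.0) -> BetaMatrix:
    """beta = M / (M + U + alpha), elementwise; 0 when M = U = 0 and alpha > 0."""
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    m = dataset.methylated.to_numpy(dtype=float)
    u = dataset.unmethylated.to_numpy(dtype=float)
    denom = m + u + alpha
    if alpha == 0 and (denom == 0).any():
        i, j = np.argwhere(denom == 0)[0]
        raise ValidationError(
            f"undefined beta (M = U = 0 with alpha = 0) at probe "
            f"{dataset.methylated.index[i]!r}, sample {dataset.methylated.columns[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        beta = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    values = pd.DataFrame(
        beta, index=dataset.methylated.index, columns=dataset.methylated.columns
    )
    return BetaMatrix(values=values, probes=dataset.probes, samples=dataset.samples)


def beta_to_m(beta):
    """M-value from beta: log2(beta / (1 - beta)). Defined on the open (0, 1)."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise ValidationError("beta_to_m requires 0 < beta < 1 (M-value is infinite at 0/1)")
    out = np.log2(beta / (1.0 - beta))
    return out.item() if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + 2.0 ** (-m))
    return out.item() if out.ndim == 0 else out


def intensity_to_m(M, U, alpha: float = 100.0):
    """M-value from intensities: log2((M + alpha) / (U + alpha)); alpha > 0."""
    if alpha <= 0:
        raise ValidationError("intensity_to_m requires alpha > 0")
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    out = np.log2((M + alpha) / (U + alpha))
    return out.item() if out.ndim == 0 else out


def _row_groups(dataset: IntensityDataset, by_type: bool) -> np.ndarray:
    if by_type:
        return (dataset.probes["AssayType"] == "II").to_numpy().astype(int)
    return np.zeros(dataset.n_probes, dtype=int)


def normalize_intensities(
    dataset: IntensityDataset,
    spec: MethodSpec | str,
    offsets: BackgroundOffsets | None = None,
    pool_channels: bool = False,
    grid_size: int = 512,
) -> IntensityDataset:
    """Background-equalize and quantile-normalize intensities per one method.

    Returns the dataset whose M/U matrices are what the method feeds into the
    beta computation (``beta_qn`` methods normalize betas, not intensities,
    and are rejected here).
    """
    if isinstance(spec, str):
        spec = MethodSpec.from_name(spec)
    if spec.between_array_qn == "beta_qn":
        raise ValidationError(f"method {spec.name!r} normalizes betas, not intensities")
    if spec.between_array_qn != "none" and dataset.n_samples < 2:
        raise ValidationError(
            f"method {spec.name!r} quantile-normalizes across arrays and needs >= 2 samples"
        )
    if spec.background != "none":
        if offsets is None:
            offsets = estimate_background_offsets(
                dataset,
                smooth_by_position=(spec.background == "equalize_smoothed"),
                pool_channels=pool_channels,
                grid_size=grid_size,
            )
        dataset = equalize_background(dataset, offsets)
    qn_mode = spec.between_array_qn
    if qn_mode == "none":
        return dataset
    by_type = qn_mode.endswith("types_separate")
    groups = _row_groups(dataset, by_type)
    m = dataset.methylated.to_numpy(dtype=float)
    u = dataset.unmethylated.to_numpy(dtype=float)
    if qn_mode.startswith("MU_separate"):
        m = quantile_normalize_grouped(m, groups)
        u = quantile_normalize_grouped(u, groups)
    elif qn_mode.startswith("MU_together"):
        m, u = quantile_normalize_grouped(m, groups, join_columns=u)
    else:  # pragma: no cover - registry guards the mode names
        raise ValidationError(f"unknown QN mode {qn_mode!r}")
    return dataset.with_intensities(
        pd.DataFrame(m, index=dataset.methylated.index, columns=dataset.methylated.columns),
        pd.DataFrame(u, index=dataset.methylated.index, columns=dataset.methylated.columns),
    )


def apply_method(
    dataset: IntensityDataset,
    spec: MethodSpec | str,
    offsets: BackgroundOffsets | None = None,
    pool_channels: bool = False,
    grid_size: int = 512,
) -> BetaMatrix:
    """Run one named preprocessing method end to end and return betas.

    Dispatch: (1) if the spec calls for background adjustment, estimate the
    Type II - Type I offsets (position-smoothed for ``equalize_smoothed``) and
    add them to Type I intensities; (2) apply the between-array QN scheme;
    (3) compute beta with the spec's alpha.

    Precomputed ``offsets`` may be passed to skip re-estimation.
    """
    if isinstance(spec, str):
        spec = MethodSpec.from_name(spec)
    if spec.between_array_qn == "beta_qn":
        if dataset.n_samples < 2:
            raise ValidationError(
                f"method {spec.name!r} quantile-normalizes across arrays and needs >= 2 samples"
            )
        betas = compute_beta(dataset, spec.alpha)
        values = quantile_normalize(betas.values.to_numpy())
        return BetaMatrix(
            values=pd.DataFrame(
                values, index=betas.values.index, columns=betas.values.columns
            ),
            probes=dataset.probes,
            samples=dataset.samples,
        )
    normalized = normalize_intensities(
        dataset, spec, offsets=offsets, pool_channels=pool_channels, grid_size=grid_size
    )
    return compute_beta(normalized, spec.alpha)


class MethylationNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer over the preprocessing method registry.

    Parameters
    ----------
    method : str, default "dasen"
        One of the twelve registered method names.
    alpha : float, default 100.0
        Offset in beta = M / (M + U + alpha).
    pool_channels : bool, default False
        Use a single pooled background offset per sample for both channels.
    grid_size : int, default 512
        Density grid resolution for background-peak estimation.

    Attributes
    ----------
    spec_ : MethodSpec
        Resolved design point after :meth:`fit`.
    offsets_ : BackgroundOffsets or None
        Background offsets estimated for the most recently transformed
        dataset (None for methods without background adjustment).

    Notes
    -----
    Quantile normalization has no out-of-sample reference distribution: each
    dataset is normalized against itself, so ``transform`` is per-dataset and
    ``fit`` resolves and validates the configuration.
    """

    def __init__(
        self,
        method: str = "dasen",
        alpha: float = 100.0,
        pool_channels: bool = False,
        grid_size: int = 512,
    ):
        self.method = method
        self.alpha = alpha
        self.pool_channels = pool_channels
        self.grid_size = grid_size

    def fit(self, X: IntensityDataset, y=None) -> "MethylationNormalizer":
        self.spec_ = MethodSpec.from_name(self.method, alpha=self.alpha)
        self.offsets_ = None
        return self

    def transform(self, X: IntensityDataset) -> BetaMatrix:
        if not hasattr(self, "spec_"):
            raise ValidationError("MethylationNormalizer is not fitted; call fit first")
        offsets = None
        if self.spec_.background != "none":
            offsets = estimate_background_offsets(
                X,
                smooth_by_position=(self.spec_.background == "equalize_smoothed"),
                pool_channels=self.pool_channels,
                grid_size=self.grid_size,
            )
        self.offsets_ = offsets
        return apply_method(
            X,
            self.spec_,
            offsets=offsets,
            pool_channels=self.pool_channels,
            grid_size=self.grid_size,
        )

    @staticmethod
    def available_methods() -> tuple[str, ...]:
        return METHOD_NAMES
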
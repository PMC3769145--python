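"""Core containers for paired methylated/unmethylated intensity data.

The Infinium 450K array reports, for every CpG probe and every sample, a
methylated (M) and an unmethylated (U) fluorescence intensity.  Probes come in
two chemistries: Type I (two beads, one colour channel) and Type II (one bead,
two colours).  All preprocessing in this package operates on the paired M/U
matrices together with a probe manifest (assay type, chromosome, SNP-control
and imprinted-DMR flags) and a sample sheet (sex, BeadChip position).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

VALID_ASSAY_TYPES = ("I", "II")
VALID_CHANNELS = ("Red", "Grn", "Both")
VALID_SEXES = ("male", "female", "unknown")

#: Table of method name -> (background adjustment, between-array QN mode).
#: The naming convention: 2nd letter d = background equalization ("d"justment),
#: n = none; letters 3-4 encode the QN scheme (see MethodSpec docstring).
METHOD_TABLE: Mapping[str, tuple[str, str]] = {
    "raw": ("none", "none"),
    "betaqn": ("none", "beta_qn"),
    "naten": ("none", "MU_separate_types_together"),
    "nanet": ("none", "MU_together_types_together"),
    "nanes": ("none", "MU_together_types_separate"),
    "danes": ("equalize", "MU_together_types_separate"),
    "danet": ("equalize", "MU_together_types_together"),
    "danen": ("equalize", "none"),
    "daten1": ("equalize", "MU_separate_types_together"),
    "daten2": ("equalize_smoothed", "MU_separate_types_together"),
    "nasen": ("none", "MU_separate_types_separate"),
    "dasen": ("equalize", "MU_separate_types_separate"),
}

METHOD_NAMES = tuple(METHOD_TABLE)


class ValidationError(ValueError):
    """Raised when input data violates a structural invariant."""


@dataclass(frozen=True)
class MethodSpec:
    """A point in the preprocessing design space.

    Three axes define each named method:

    * ``background`` — whether the Type I / Type II background difference is
      equalized before normalization (``none``, ``equalize``, or
      ``equalize_smoothed`` which smooths per-sample offsets over BeadChip
      row position).
    * ``between_array_qn`` — the quantile-normalization scheme.
      ``MU_separate_*`` normalizes the M and U matrices independently;
      ``MU_together_*`` concatenates the M and U columns so the two channels
      are normalized against each other (removing dye bias);
      ``*_types_together`` uses a single probe pool while ``*_types_separate``
      quantile-normalizes Type I and Type II probes independently;
      ``beta_qn`` quantile-normalizes the raw beta matrix instead of
      intensities.
    * ``alpha`` — the offset in beta = M / (M + U + alpha), default 100.
    """

    name: str
    background: str
    between_array_qn: str
    alpha: float = 100.0

    @classmethod
    def from_name(cls, name: str, alpha: float = 100.0) -> "MethodSpec":
        if name not in METHOD_TABLE:
            raise ValidationError(
                f"unknown method {name!r}; valid methods: {', '.join(METHOD_NAMES)}"
            )
        if alpha < 0:
            raise ValidationError("alpha must be >= 0")
        background, qn = METHOD_TABLE[name]
        return cls(name=name, background=background, between_array_qn=qn, alpha=alpha)


def _check_bool_column(df: pd.DataFrame, col: str) -> pd.Series:
    s = df[col]
    if s.dtype != bool:
        s = s.astype(bool)
    return s


def validate_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe manifest indexed by probe id.

    Required columns: AssayType, Chromosome, Channel, IsSNP, IsIDMR.
    """
    required = {"AssayType", "Chromosome", "Channel", "IsSNP", "IsIDMR"}
    missing = required - set(probes.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if probes.index.has_duplicates:
        dups = probes.index[probes.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids in manifest: {dups[:5]}")
    bad = set(probes["AssayType"]) - set(VALID_ASSAY_TYPES)
    if bad:
        raise ValidationError(f"invalid AssayType values: {sorted(bad)} (expected I or II)")
    bad = set(probes["Channel"]) - set(VALID_CHANNELS)
    if bad:
        raise ValidationError(f"invalid Channel values: {sorted(bad)}")
    probes = probes.copy()
    probes["IsSNP"] = _check_bool_column(probes, "IsSNP")
    probes["IsIDMR"] = _check_bool_column(probes, "IsIDMR")
    # chromosome labels normalized without "chr" prefix, X/Y uppercased
    chrom = probes["Chromosome"].astype(str).str.replace("^chr", "", regex=True)
    probes["Chromosome"] = chrom.where(~chrom.str.fullmatch("[xyXY]"), chrom.str.upper())
    type2 = probes["AssayType"] == "II"
    if (probes.loc[type2, "Channel"] != "Both").any():
        raise ValidationError("Type II probes must have Channel == 'Both'")
    if (probes.loc[~type2, "Channel"] == "Both").any():
        raise ValidationError("Type I probes must have Channel 'Red' or 'Grn'")
    both = probes["IsSNP"] & probes["IsIDMR"]
    if both.any():
        raise ValidationError(
            f"probes flagged both SNP and iDMR: {probes.index[both].tolist()[:5]}"
        )
    return probes


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet indexed by sample id.

    Required columns: Sex, ChipID, ChipRow, ChipCol (positions may be missing,
    but row/col must be missing together).
    """
    required = {"Sex", "ChipID", "ChipRow", "ChipCol"}
    missing = required - set(samples.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if samples.index.has_duplicates:
        dups = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    bad = set(samples["Sex"].astype(str).str.lower()) - set(VALID_SEXES)
    if bad:
        raise ValidationError(f"invalid Sex values: {sorted(bad)}")
    samples = samples.copy()
    samples["Sex"] = samples["Sex"].astype(str).str.lower()
    row_na = samples["ChipRow"].isna()
    col_na = samples["ChipCol"].isna()
    if (row_na != col_na).any():
        raise ValidationError("ChipRow and ChipCol must be both present or both missing")
    for col in ("ChipRow", "ChipCol"):
        vals = samples[col].dropna()
        if len(vals) and (vals.astype(float) < 1).any():
            raise ValidationError(f"{col} values must be >= 1")
    return samples


def _validate_matrix(df: pd.DataFrame, name: str) -> None:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{name} matrix contains non-numeric values")
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"{name} matrix has non-finite value at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{name} matrix has negative value at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )


@dataclass
class IntensityDataset:
    """Paired methylated/unmethylated intensity matrices with annotations.

    ``methylated`` and ``unmethylated`` are probes x samples DataFrames with
    identical index/columns; ``probes`` and ``samples`` are the manifest and
    sample sheet aligned to them.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        m, u = self.methylated, self.unmethylated
        if m.shape != u.shape:
            raise ValidationError(
                f"methylated {m.shape} and unmethylated {u.shape} shapes differ"
            )
        if not m.index.equals(u.index) or not m.columns.equals(u.columns):
            raise ValidationError("methylated/unmethylated labels are not aligned")
        if m.index.has_duplicates:
            raise ValidationError("duplicate probe ids in intensity matrix")
        if m.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in intensity matrix")
        self.probes = validate_probes(self.probes)
        self.samples = validate_samples(self.samples)
        if not set(m.index) <= set(self.probes.index):
            missing = sorted(set(m.index) - set(self.probes.index))
            raise ValidationError(f"probes absent from manifest: {missing[:5]}")
        if not set(m.columns) <= set(self.samples.index):
            missing = sorted(set(m.columns) - set(self.samples.index))
            raise ValidationError(f"samples absent from sample sheet: {missing[:5]}")
        # align annotation order to the matrices
        self.probes = self.probes.loc[m.index]
        self.samples = self.samples.loc[m.columns]
        _validate_matrix(m, "methylated")
        _validate_matrix(u, "unmethylated")

    @property
    def n_probes(self) -> int:
        return self.methylated.shape[0]

    @property
    def n_samples(self) -> int:
        return self.methylated.shape[1]

    def with_intensities(
        self, methylated: pd.DataFrame, unmethylated: pd.DataFrame
    ) -> "IntensityDataset":
        """Copy of this dataset with replaced intensity matrices."""
        return IntensityDataset(
            methylated=methylated,
            unmethylated=unmethylated,
            probes=self.probes.copy(),
            samples=self.samples.copy(),
        )


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1]."""

    values: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and (not np.isfinite(v).all() or v.min() < 0 or v.max() > 1):
            raise ValidationError("beta values must be finite and within [0, 1]")
        self.probes = self.probes.loc[self.values.index]
        self.samples = self.samples.loc[self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]
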
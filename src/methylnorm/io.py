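"""Readers and writers for intensity tables, manifests, sample sheets and betas.

File dialect: tab-separated UTF-8 text with '.' decimal separators, probe-id
column headed "ProbeID" — the tabular shape of a GenomeStudio raw-intensity
export without its multi-section wrapper.  Manifests and sample sheets may be
comma- or tab-separated.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, IntensityDataset, ValidationError

PROBE_ID = "ProbeID"
SAMPLE_ID = "SampleID"


class ParseError(ValueError):
    """Raised when a file cell cannot be parsed."""


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def _read_intensity_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected probe-id column plus sample columns")
    df = df.set_index(df.columns[0])
    df.index.name = PROBE_ID
    df.columns.name = SAMPLE_ID
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate probe ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric or missing intensity at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        i, j = np.argwhere((numeric.to_numpy() < 0))[0]
        raise ParseError(
            f"{path}: negative intensity at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return numeric


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probe manifest (ProbeID, AssayType, Chromosome, Channel, IsSNP, IsIDMR)."""
    df = _read_table(path)
    if PROBE_ID not in df.columns:
        raise ValidationError(f"{path}: manifest must have a {PROBE_ID} column")
    return df.set_index(PROBE_ID)


def read_samplesheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample sheet (SampleID, Sex, ChipID, ChipRow, ChipCol)."""
    df = _read_table(path)
    if SAMPLE_ID not in df.columns:
        raise ValidationError(f"{path}: sample sheet must have a {SAMPLE_ID} column")
    return df.set_index(SAMPLE_ID)


def read_intensities(
    meth_path: str | os.PathLike,
    unmeth_path: str | os.PathLike,
    manifest_path: str | os.PathLike,
    samplesheet_path: str | os.PathLike,
) -> IntensityDataset:
    """Assemble a validated :class:`IntensityDataset` from four text files.

    The two intensity tables are aligned by probe and sample *label*, never by
    position, so row/column order may differ between files.
    """
    meth = _read_intensity_matrix(meth_path)
    unmeth = _read_intensity_matrix(unmeth_path)
    if set(meth.index) != set(unmeth.index):
        raise ValidationError("methylated/unmethylated tables cover different probes")
    if set(meth.columns) != set(unmeth.columns):
        raise ValidationError("methylated/unmethylated tables cover different samples")
    unmeth = unmeth.loc[meth.index, meth.columns]
    probes = read_manifest(manifest_path)
    samples = read_samplesheet(samplesheet_path)
    missing = set(meth.index) - set(probes.index)
    if missing:
        raise ValidationError(f"manifest does not cover probes: {sorted(missing)[:5]}")
    missing = set(meth.columns) - set(samples.index)
    if missing:
        raise ValidationError(f"sample sheet does not cover samples: {sorted(missing)[:5]}")
    return IntensityDataset(
        methylated=meth, unmethylated=unmeth, probes=probes, samples=samples
    )


def write_betas(betas: BetaMatrix | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a beta matrix as TSV (6 decimal places, ProbeID first column)."""
    df = betas.values if isinstance(betas, BetaMatrix) else betas
    df.to_csv(path, sep="\t", float_format="%.6f", index_label=PROBE_ID)


def read_betas(path: str | os.PathLike) -> pd.DataFrame:
    """Read a beta TSV written by :func:`write_betas`."""
    return pd.read_csv(path, sep="\t", index_col=0)
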
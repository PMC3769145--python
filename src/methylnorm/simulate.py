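"""Synthetic 450K-like intensity data with ground truth.

The generator emulates every structural feature the preprocessing methods and
quality metrics exploit:

* a bimodal autosomal methylation landscape (most CpGs near 0 or 1, a small
  intermediate fraction);
* imprinted-DMR probes at true methylation 0.5;
* trimodal SNP control probes with Hardy-Weinberg genotype draws;
* X-chromosome probes hypermethylated in females (inactive-X methylation)
  and lowly methylated in males;
* Type II assays with inflated background (compressing Type II betas toward
  0.5) and a dye-bias multiplier on the unmethylated (red) channel;
* per-sample intensity scaling, optional BeadChip-row background gradients,
  and additive fluorescence noise.

Probe-level truth (theta), genotypes, sexes and the injected backgrounds are
returned alongside the dataset so estimator recovery can be tested.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .datatypes import IntensityDataset, ValidationError
from . import io as mio

AUTOSOMES = [str(c) for c in range(1, 23)]


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic array.

    Intensity units are arbitrary fluorescence counts on the scale of real
    450K scanner output (total signal a few thousand, background a few
    hundred).  Sample-level nuisances mirror the technical variation a
    between-array normalization is meant to remove: per-sample background
    jitter (``background_sample_sd``, shared by both probe types and
    channels), per-sample dye-bias variation around the Type II mean
    multiplier (``dye_bias_sample_sd``, lognormal), per-sample incomplete
    bisulfite conversion (``conversion_shift_sd``: a half-normal fraction
    f of unmethylated cytosines reads as methylated, theta -> theta +
    f * (1 - theta)), and global intensity scaling (``sample_scale_sd``).
    ``x_escape_fraction`` of X-chromosome probes escape X inactivation and
    show no sex difference, so the sex-difference ROC has a realistic
    ceiling.  ``chip_row_gradient`` tilts the *Type II* background across
    BeadChip rows, so the Type II - Type I offset varies linearly with row
    at exactly this slope.  ``theta_concentration=None`` switches off the
    per-cell beta noise on true methylation (useful for closed-form checks).
    """

    n_samples: int = 20
    n_autosomal: int = 20000
    n_idmr: int = 237
    n_snp: int = 65
    n_x: int = 500
    frac_type2: float = 0.72
    background_type1: float = 300.0
    background_type2: float = 800.0
    background_sample_sd: float = 150.0
    dye_bias_type2: float = 1.3
    dye_bias_sample_sd: float = 0.15
    conversion_shift_sd: float = 0.02
    x_escape_fraction: float = 0.2
    sample_scale_sd: float = 0.15
    chip_row_gradient: float = 0.0
    noise_sd: float = 100.0
    intensity_mean: float = 4000.0
    intensity_cv: float = 0.1
    theta_concentration: float | None = 150.0
    allele_freqs: tuple | None = None
    sex_ratio: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("n_samples must be >= 4")
        for name in ("n_autosomal", "n_idmr", "n_snp", "n_x"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("frac_type2", "sex_ratio"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1)")
        if not 0 <= self.x_escape_fraction < 1:
            raise ValidationError("x_escape_fraction must be in [0, 1)")
        for name in (
            "background_sample_sd",
            "dye_bias_sample_sd",
            "conversion_shift_sd",
            "sample_scale_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "background_type1",
            "background_type2",
            "dye_bias_type2",
            "intensity_mean",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.allele_freqs is not None:
            freqs = np.asarray(self.allele_freqs, dtype=float)
            if freqs.size != self.n_snp or ((freqs <= 0) | (freqs >= 1)).any():
                raise ValidationError(
                    "allele_freqs must give one frequency in (0, 1) per SNP probe"
                )


@dataclass
class GroundTruth:
    """True generative quantities behind a simulated dataset."""

    theta: pd.DataFrame
    genotypes: pd.DataFrame
    sexes: pd.Series
    sample_scale: pd.Series
    expected_offset: pd.Series  # Type II - Type I background per sample
    background_type1: float
    background_type2: float
    chip_row_gradient: float
    config: SimulationConfig = field(repr=False, default=None)


def _draw_autosomal_theta(rng: np.random.Generator, n: int) -> np.ndarray:
    component = rng.choice(3, size=n, p=[0.40, 0.40, 0.20])
    theta = np.empty(n)
    low, high, mid = component == 0, component == 1, component == 2
    theta[low] = rng.beta(2.0, 40.0, low.sum())
    theta[high] = rng.beta(40.0, 2.0, high.sum())
    theta[mid] = rng.beta(5.0, 5.0, mid.sum())
    return theta


def _fix_sex_counts(female: np.ndarray) -> np.ndarray:
    """Guarantee at least two samples of each sex (flip the earliest ones)."""
    female = female.copy()
    n_female = int(female.sum())
    if n_female < 2:
        female[np.flatnonzero(~female)[: 2 - n_female]] = True
    n_male = int((~female).sum())
    if n_male < 2:
        female[np.flatnonzero(female)[: 2 - n_male]] = False
    return female


def simulate_dataset(config: SimulationConfig) -> tuple[IntensityDataset, GroundTruth]:
    """Generate an :class:`IntensityDataset` plus its :class:`GroundTruth`.

    Fully reproducible from ``config.seed``: independent deterministic
    sub-streams drive probe layout, true methylation, genotypes, sexes and
    intensity noise.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_layout, rng_theta, rng_geno, rng_sex, rng_scale, rng_noise = (
        np.random.default_rng(s) for s in streams
    )

    n_probes = config.n_autosomal + config.n_idmr + config.n_snp + config.n_x
    n = config.n_samples
    category = np.array(
        ["autosomal"] * config.n_autosomal
        + ["idmr"] * config.n_idmr
        + ["snp"] * config.n_snp
        + ["x"] * config.n_x
    )
    probe_ids = np.array(
        [
            f"rs{i:06d}" if category[i] == "snp" else f"cg{i:08d}"
            for i in range(n_probes)
        ]
    )
    is_type2 = rng_layout.random(n_probes) < config.frac_type2
    channel = np.where(
        is_type2, "Both", rng_layout.choice(["Red", "Grn"], size=n_probes)
    )
    chromosome = rng_layout.choice(AUTOSOMES, size=n_probes)
    chromosome[category == "x"] = "X"
    probes = pd.DataFrame(
        {
            "AssayType": np.where(is_type2, "II", "I"),
            "Chromosome": chromosome,
            "Channel": channel,
            "IsSNP": category == "snp",
            "IsIDMR": category == "idmr",
        },
        index=pd.Index(probe_ids, name="ProbeID"),
    )

    sample_ids = [f"S{i:03d}" for i in range(n)]
    female = _fix_sex_counts(rng_sex.random(n) < config.sex_ratio)
    positions = np.arange(n) % 12
    samples = pd.DataFrame(
        {
            "Sex": np.where(female, "female", "male"),
            "ChipID": [f"chip{i // 12:02d}" for i in range(n)],
            "ChipRow": positions % 6 + 1,
            "ChipCol": positions // 6 + 1,
        },
        index=pd.Index(sample_ids, name="SampleID"),
    )

    # true methylation fraction theta, probe x sample
    theta = np.empty((n_probes, n))
    auto = category == "autosomal"
    theta[auto] = _draw_autosomal_theta(rng_theta, int(auto.sum()))[:, None]
    theta[category == "idmr"] = 0.5
    x_mask = category == "x"
    n_x = int(x_mask.sum())
    female_level = 0.5 + rng_theta.uniform(0.0, 0.3, n_x)
    male_level = rng_theta.uniform(0.05, 0.25, n_x)
    x_theta = np.where(female[None, :], female_level[:, None], male_level[:, None])
    # a fraction of X loci escape X inactivation: no sex difference there
    escapes = rng_theta.random(n_x) < config.x_escape_fraction
    x_theta[escapes] = _draw_autosomal_theta(rng_theta, int(escapes.sum()))[:, None]
    theta[x_mask] = x_theta

    snp_mask = category == "snp"
    if config.allele_freqs is not None:
        freqs = np.asarray(config.allele_freqs, dtype=float)
    else:
        freqs = rng_geno.uniform(0.2, 0.8, config.n_snp)
    genotypes = rng_geno.binomial(2, freqs[:, None], size=(config.n_snp, n))
    theta[snp_mask] = genotypes / 2.0

    if config.theta_concentration is not None:
        c = config.theta_concentration
        clipped = np.clip(theta, 0.02, 0.98)
        theta_obs = rng_theta.beta(c * clipped, c * (1.0 - clipped))
    else:
        theta_obs = theta

    # incomplete bisulfite conversion: per sample, a fraction f of
    # unmethylated cytosines reads as methylated (SNP probes unaffected -
    # they genotype, not measure methylation)
    if config.conversion_shift_sd > 0:
        shift = np.abs(rng_scale.normal(0.0, config.conversion_shift_sd, n))
        theta_obs = np.where(
            snp_mask[:, None],
            theta_obs,
            theta_obs + shift[None, :] * (1.0 - theta_obs),
        )

    # intensities
    scale = np.exp(rng_scale.normal(0.0, config.sample_scale_sd, n))
    total = config.intensity_mean * scale[None, :]
    if config.intensity_cv > 0:
        total = total * np.exp(rng_noise.normal(0.0, config.intensity_cv, theta_obs.shape))
    rows = samples["ChipRow"].to_numpy(dtype=float)
    bg = np.where(
        is_type2[:, None],
        config.background_type2 + config.chip_row_gradient * (rows[None, :] - 1.0),
        config.background_type1,
    )
    if config.background_sample_sd > 0:
        # per-sample background level shared by both probe types and
        # channels, so the II - I offset is unchanged in expectation
        bg = bg + rng_scale.normal(0.0, config.background_sample_sd, n)[None, :]
        bg = np.clip(bg, 0.0, None)
    dye_sample = np.full(n, config.dye_bias_type2)
    if config.dye_bias_sample_sd > 0:
        dye_sample = dye_sample * np.exp(
            rng_scale.normal(0.0, config.dye_bias_sample_sd, n)
        )
    dye = np.where(is_type2[:, None], dye_sample[None, :], 1.0)
    meth = theta_obs * total + bg
    unmeth = (1.0 - theta_obs) * total * dye + bg
    if config.noise_sd > 0:
        meth = meth + rng_noise.normal(0.0, config.noise_sd, meth.shape)
        unmeth = unmeth + rng_noise.normal(0.0, config.noise_sd, unmeth.shape)
    meth = np.clip(meth, 0.0, None)
    unmeth = np.clip(unmeth, 0.0, None)

    dataset = IntensityDataset(
        methylated=pd.DataFrame(meth, index=probes.index, columns=samples.index),
        unmethylated=pd.DataFrame(unmeth, index=probes.index, columns=samples.index),
        probes=probes,
        samples=samples,
    )
    expected_offset = pd.Series(
        config.background_type2
        + config.chip_row_gradient * (rows - 1.0)
        - config.background_type1,
        index=samples.index,
        name="ExpectedOffset",
    )
    truth = GroundTruth(
        theta=pd.DataFrame(theta, index=probes.index, columns=samples.index),
        genotypes=pd.DataFrame(
            genotypes, index=probes.index[snp_mask], columns=samples.index
        ),
        sexes=samples["Sex"].copy(),
        sample_scale=pd.Series(scale, index=samples.index, name="Scale"),
        expected_offset=expected_offset,
        background_type1=config.background_type1,
        background_type2=config.background_type2,
        chip_row_gradient=config.chip_row_gradient,
        config=config,
    )
    return dataset, truth


def write_fixture(
    dataset: IntensityDataset, ground_truth: GroundTruth, out_dir: str | os.PathLike
) -> dict:
    """Write a simulated dataset (and its truth) as plain-text files.

    Emits ``methylated.tsv``, ``unmethylated.tsv``, ``manifest.tsv``,
    ``samples.tsv`` in the package's standard formats plus
    ``truth_samples.tsv`` (sex, scale, expected offset), ``truth_theta.tsv``
    and ``config.json``.  Returns the path map.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "methylated": os.path.join(out_dir, "methylated.tsv"),
        "unmethylated": os.path.join(out_dir, "unmethylated.tsv"),
        "manifest": os.path.join(out_dir, "manifest.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "truth_samples": os.path.join(out_dir, "truth_samples.tsv"),
        "truth_theta": os.path.join(out_dir, "truth_theta.tsv"),
        "config": os.path.join(out_dir, "config.json"),
    }
    dataset.methylated.to_csv(paths["methylated"], sep="\t", index_label=mio.PROBE_ID)
    dataset.unmethylated.to_csv(paths["unmethylated"], sep="\t", index_label=mio.PROBE_ID)
    dataset.probes.to_csv(paths["manifest"], sep="\t", index_label=mio.PROBE_ID)
    dataset.samples.to_csv(paths["samples"], sep="\t", index_label=mio.SAMPLE_ID)
    truth_samples = pd.DataFrame(
        {
            "Sex": ground_truth.sexes,
            "Scale": ground_truth.sample_scale,
            "ExpectedOffset": ground_truth.expected_offset,
        }
    )
    truth_samples.to_csv(paths["truth_samples"], sep="\t", index_label=mio.SAMPLE_ID)
    ground_truth.theta.to_csv(paths["truth_theta"], sep="\t", index_label=mio.PROBE_ID)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(ground_truth.config), fh, indent=2, default=list)
    return paths
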
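"""Synthetic untargeted-lipidomics studies with known ground truth.

Emulates the acquisition design of a two-class plasma lipidomics cohort:
two infection classes of ~20 children each, ~4000 LC-MS features, a pooled
study quality-control sample (SQC) injected repeatedly through the run, a
seven-concentration SQC dilution series acquired at the beginning and end of
the run, a long-term reference (LTR) interleaved with the SQCs every ten
study injections, and age/sex covariates with a planted subset of
age-associated features.

Intensity model (all noise multiplicative, i.e. log-normal):

    study sample  = base_j x class effect x age effect x biological noise
                    x injection drift x technical noise
    SQC           = mean over study samples of the noise-free level
                    x drift x technical noise
    dilution at d = SQC level x d (dilution-responsive features)
                    or constant (artifact features) x technical noise
    LTR           = independent pooled level x drift x technical noise

Coefficients of variation are specified on the natural intensity scale and
converted exactly to log-scale sigma via sigma = sqrt(log(1 + cv^2)).
Planted class effects are standardized: a mean log-intensity shift of
``effect_size`` times the total log-scale standard deviation of a study
sample.  Every generated table is bit-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tableio import FeatureTable, write_study

__all__ = ["SimConfig", "GroundTruth", "simulate_study", "write_fixture", "read_fixture"]


def cv_to_sigma(cv: float) -> float:
    """Log-scale sigma of a log-normal with natural-scale CV ``cv``."""
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass
class SimConfig:
    """Design parameters of a synthetic study.

    Defaults mirror the emulated cohort: 20 samples per class, 4000
    features of which 40 carry a class effect of one biological standard
    deviation, pooled-SQC technical CV 5%, biological CV 35%, a 7-level
    dilution series with 2 replicates per level, and QC injections
    interleaved every 10 study samples.
    """

    n_per_class: int = 20
    n_features: int = 4000
    n_discriminatory: int = 40
    effect_size: float = 1.0          # standardized mean log-intensity shift
    n_age_assoc: int = 5
    age_effect_size: float = 1.0      # standardized above/below-median-age shift
    tech_cv: float = 0.05             # natural-scale CV of replicate injections
    bio_cv: float = 0.35              # natural-scale CV between study subjects
    n_sqc: int = 8
    n_ltr: int = 8
    dilution_factors: tuple = (0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 1.0)
    dilution_replicates: int = 2
    drift_slope: float = 0.001        # multiplicative drift per injection
    frac_noise_features: float = 0.1  # non-dilution-responsive artifacts
    missing_rate: float = 0.0
    age_overlap: bool = False         # allow age-associated ∩ discriminatory
    seed: int = 0

    def validate(self) -> "SimConfig":
        for name in ("n_per_class", "n_features", "n_sqc", "n_ltr", "dilution_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count, got {getattr(self, name)}")
        if not 0 <= self.n_discriminatory <= self.n_features:
            raise ValueError(f"n_discriminatory out of range: {self.n_discriminatory}")
        if not 0 <= self.n_age_assoc <= self.n_features:
            raise ValueError(f"n_age_assoc out of range: {self.n_age_assoc}")
        if not 0 <= self.tech_cv < self.bio_cv:
            raise ValueError(
                f"require 0 <= tech_cv < bio_cv, got tech_cv={self.tech_cv}, bio_cv={self.bio_cv}"
            )
        if len(self.dilution_factors) != 7:
            raise ValueError(f"dilution_factors must have length 7, got {len(self.dilution_factors)}")
        if any(d <= 0 for d in self.dilution_factors):
            raise ValueError(f"dilution_factors must be strictly positive: {self.dilution_factors}")
        if not 0 <= self.frac_noise_features < 1:
            raise ValueError(f"frac_noise_features must be in [0, 1): {self.frac_noise_features}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1): {self.missing_rate}")
        return self


@dataclass
class GroundTruth:
    """Which features were planted with which effect.

    ``discriminatory`` maps feature id -> direction (``up-in-bacterial`` or
    ``up-in-viral``); ``age_assoc_ids`` and ``noise_ids`` list the planted
    age-associated and non-dilution-responsive features.
    """

    discriminatory: dict = field(default_factory=dict)
    age_assoc_ids: list = field(default_factory=list)
    noise_ids: list = field(default_factory=list)

    @property
    def discriminatory_ids(self) -> list:
        return list(self.discriminatory)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _injection_layout(config: SimConfig, rng: np.random.Generator):
    """Ordered list of (role, dilution_factor or None, study_index or None).

    Dilution replicates split between the start and end of the run; SQC and
    LTR injections alternate after every block of five study samples, so a
    QC-role sample lands every ~5 injections and each role recurs every ~10,
    mirroring the pooled-QC spacing of the emulated design.
    """
    n_study = 2 * config.n_per_class
    study_order = rng.permutation(n_study)  # randomised acquisition order

    dil = [(f, r) for r in range(config.dilution_replicates) for f in config.dilution_factors]
    half = len(dil) // 2
    layout: list[tuple] = [("dilution", f, None) for f, _ in dil[:half]]

    qc_roles = []
    for i in range(max(config.n_sqc, config.n_ltr)):
        if i < config.n_sqc:
            qc_roles.append("sqc")
        if i < config.n_ltr:
            qc_roles.append("ltr")
    qc_iter = iter(qc_roles)

    placed = 0
    layout.append((next(qc_iter, "sqc"), None, None))  # run-start QC
    for i in range(n_study):
        layout.append(("study", None, int(study_order[i])))
        placed += 1
        if placed % 5 == 0:
            nxt = next(qc_iter, None)
            if nxt is not None:
                layout.append((nxt, None, None))
    for role in qc_iter:  # QCs that did not fit between study blocks
        layout.append((role, None, None))
    layout += [("dilution", f, None) for f, _ in dil[half:]]
    return layout


def simulate_study(config: SimConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate one synthetic study and its ground truth.

    Returns a raw-intensity :class:`FeatureTable` (samples ordered by
    injection) and the :class:`GroundTruth` of planted effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_study = 2 * config.n_per_class
    p = config.n_features
    sigma_bio = cv_to_sigma(config.bio_cv)
    sigma_tech = cv_to_sigma(config.tech_cv)
    sigma_total = float(np.hypot(sigma_bio, sigma_tech))

    feature_ids = [f"F{j + 1:05d}" for j in range(p)]

    # planted feature sets
    perm = rng.permutation(p)
    disc_idx = perm[: config.n_discriminatory]
    n_noise = int(round(config.frac_noise_features * p))
    noise_idx = perm[config.n_discriminatory: config.n_discriminatory + n_noise]
    if config.age_overlap:
        age_idx = rng.permutation(p)[: config.n_age_assoc]
    else:
        age_idx = perm[config.n_discriminatory + n_noise:
                       config.n_discriminatory + n_noise + config.n_age_assoc]

    # base log abundances spread over ~4 decades, as in real LC-MS tables
    base = rng.normal(loc=11.0, scale=1.8, size=p)

    # class effect: +/- effect_size * sigma_total split evenly around base
    delta = np.zeros(p)
    signs = np.ones(config.n_discriminatory)
    signs[1::2] = -1.0  # alternate up-in-bacterial / up-in-viral
    delta[disc_idx] = signs * config.effect_size * sigma_total

    # covariates: log-age uniform on [log 1, log 102] months -> median ~10
    log_age = rng.uniform(np.log(1.0), np.log(102.0), size=n_study)
    age_months = np.exp(log_age)
    sex = rng.integers(0, 2, size=n_study)  # 0 = female, 1 = male

    # age slope calibrated so an above/below-median split of the samples
    # shows a standardized shift of age_effect_size on the *observed* scale,
    # which includes the variance the age effect itself adds.  For log-age
    # uniform on [a, b]: split means differ by c = (b-a)/2 and the age term
    # contributes slope * v to the sd with v = (b-a)/sqrt(12); solving
    # a_eff * sqrt(sigma^2 + s^2 v^2) = s * c gives the slope below.
    age_slope = np.zeros(p)
    if config.n_age_assoc:
        a_eff = config.age_effect_size
        c = (np.log(102.0) - np.log(1.0)) / 2.0
        v = (np.log(102.0) - np.log(1.0)) / np.sqrt(12.0)
        if a_eff * v >= c:
            raise ValueError(
                f"age_effect_size {a_eff} infeasible: a median split of a "
                f"uniform covariate cannot exceed {c / v:.3f} standard deviations"
            )
        age_slope[age_idx] = a_eff * sigma_total / np.sqrt(c**2 - a_eff**2 * v**2)

    classes = np.array(["bacterial"] * config.n_per_class + ["viral"] * config.n_per_class)
    y = (classes == "bacterial").astype(float)

    # noise-free study log-levels (before drift/technical noise), then
    # biological noise per subject
    centered_age = log_age - log_age.mean()
    study_log = (
        base[None, :]
        + np.outer(y - 0.5, delta)
        + np.outer(centered_age, age_slope)
        + rng.normal(0.0, sigma_bio, size=(n_study, p))
    )

    # pooled-SQC level: mean of study samples on the natural scale
    sqc_level = np.log(np.mean(np.exp(study_log), axis=0))
    ltr_level = base + rng.normal(0.0, sigma_bio / np.sqrt(12), size=p)  # external pool

    layout = _injection_layout(config, rng)
    drift_log = np.log1p(config.drift_slope)

    rows, sample_meta = [], []
    counters = {"study": 0, "sqc": 0, "ltr": 0, "dilution": 0}
    for order, (role, dil_factor, study_ix) in enumerate(layout, start=1):
        counters[role] += 1
        tech = rng.normal(0.0, sigma_tech, size=p)
        drift = drift_log * order
        if role == "study":
            log_int = study_log[study_ix] + drift + tech
            sid = f"S{study_ix + 1:03d}"
            meta = dict(role=role, **{"class": classes[study_ix]},
                        injection_order=order, dilution_factor=np.nan,
                        age_months=round(float(age_months[study_ix]), 1),
                        sex="male" if sex[study_ix] else "female")
        elif role == "sqc":
            log_int = sqc_level + drift + tech
            sid = f"SQC{counters['sqc']:02d}"
            meta = dict(role=role, **{"class": np.nan}, injection_order=order,
                        dilution_factor=np.nan, age_months=np.nan, sex=np.nan)
        elif role == "ltr":
            log_int = ltr_level + drift + tech
            sid = f"LTR{counters['ltr']:02d}"
            meta = dict(role=role, **{"class": np.nan}, injection_order=order,
                        dilution_factor=np.nan, age_months=np.nan, sex=np.nan)
        else:  # dilution: responsive features scale with d, artifacts stay flat
            log_int = sqc_level + np.log(dil_factor) + drift + tech
            log_int[noise_idx] = sqc_level[noise_idx] + drift + tech[noise_idx]
            sid = f"DIL{counters['dilution']:02d}"
            meta = dict(role=role, **{"class": np.nan}, injection_order=order,
                        dilution_factor=dil_factor, age_months=np.nan, sex=np.nan)
        rows.append(np.exp(log_int))
        sample_meta.append((sid, meta))

    intensities = pd.DataFrame(
        np.asarray(rows), index=[sid for sid, _ in sample_meta], columns=feature_ids
    )
    if config.missing_rate > 0:
        mask = rng.random(intensities.shape) < config.missing_rate
        intensities = intensities.mask(mask)

    samples = pd.DataFrame([m for _, m in sample_meta], index=intensities.index)

    features = pd.DataFrame(
        {
            "mz": np.round(rng.uniform(50.0, 2000.0, size=p), 4),
            "rt_min": np.round(rng.uniform(0.2, 15.0, size=p), 2),
            "annotation": ["UNKNOWN"] * p,
            "annotation_level": [4] * p,
        },
        index=pd.Index(feature_ids),
    )

    truth = GroundTruth(
        discriminatory={
            feature_ids[j]: ("up-in-bacterial" if s > 0 else "up-in-viral")
            for j, s in zip(disc_idx, signs)
        },
        age_assoc_ids=[feature_ids[j] for j in sorted(age_idx)],
        noise_ids=[feature_ids[j] for j in sorted(noise_idx)],
    )

    table = FeatureTable(intensities, samples, features)
    if config.missing_rate == 0:
        table.validate()
    return table, truth


def write_fixture(table: FeatureTable, truth: GroundTruth, directory) -> pathlib.Path:
    """Write intensity/sample/feature CSVs plus ``truth.json`` to a directory."""
    if table.n_samples == 0 or table.n_features == 0:
        raise ValueError("refusing to write an empty feature table")
    directory = pathlib.Path(directory)
    write_study(table, directory)
    (directory / "truth.json").write_text(truth.to_json(), encoding="utf-8")
    return directory


def read_fixture(directory) -> tuple[FeatureTable, GroundTruth]:
    """Read back a fixture written by :func:`write_fixture`."""
    from .tableio import read_study

    directory = pathlib.Path(directory)
    table = read_study(
        directory / "intensities.csv", directory / "samples.csv", directory / "features.csv"
    )
    truth = GroundTruth.from_json((directory / "truth.json").read_text(encoding="utf-8"))
    return table, truth
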
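"""Shared data model and I/O for feature-intensity tables.

The central object is :class:`FeatureTable`: a samples x features intensity
matrix with aligned per-sample metadata (role in the acquisition design,
infection class, injection order, dilution factor, age, sex) and per-feature
metadata (m/z, retention time, annotation, annotation level).  Every stage of
the discovery pipeline consumes and produces this one object.

Files are plain CSV/TSV: an intensity table whose first column is the sample
identifier, a sample-metadata table and a feature-metadata table.  Sample
roles are explicit metadata and are never inferred from identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "TableValidationError",
    "SAMPLE_ROLES",
    "CLASS_LABELS",
    "read_study",
    "write_study",
    "log_transform",
    "class_vector",
]

SAMPLE_ROLES = ("study", "sqc", "ltr", "dilution")
CLASS_LABELS = ("bacterial", "viral")

#: canonical sample-metadata columns, in file order
SAMPLE_COLUMNS = ["role", "class", "injection_order", "dilution_factor", "age_months", "sex"]
#: canonical feature-metadata columns
FEATURE_COLUMNS = ["mz", "rt_min", "annotation", "annotation_level"]


class TableValidationError(ValueError):
    """Raised when a feature table violates its structural invariants.

    ``problems`` lists every violation found, so all failures are reported
    together rather than one at a time.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid feature table:\n  - " + "\n  - ".join(self.problems))


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with aligned metadata.

    Parameters
    ----------
    intensities
        Non-negative real matrix, index = sample ids, columns = feature ids.
    samples
        Per-sample metadata indexed by sample id.  Columns: ``role`` (one of
        ``study``/``sqc``/``ltr``/``dilution``), ``class`` (``bacterial``/
        ``viral``/missing), ``injection_order``, ``dilution_factor``,
        ``age_months``, ``sex``.
    features
        Per-feature metadata indexed by feature id.  Columns: ``mz`` (Da),
        ``rt_min`` (minutes), ``annotation``, ``annotation_level`` (MSI tier
        1-4).
    log_scale
        True once :func:`log_transform` has been applied.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame
    log_scale: bool = field(default=False)

    # -- basic introspection ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def role_mask(self, role: str) -> np.ndarray:
        return (self.samples["role"] == role).to_numpy()

    # -- subsetting ---------------------------------------------------------

    def subset_samples(self, sample_ids) -> "FeatureTable":
        sample_ids = list(sample_ids)
        return replace(
            self,
            intensities=self.intensities.loc[sample_ids],
            samples=self.samples.loc[sample_ids],
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        return replace(
            self,
            intensities=self.intensities[feature_ids],
            features=self.features.loc[feature_ids],
        )

    def study_samples(self) -> "FeatureTable":
        """Restrict to study-role samples (the patient samples)."""
        ids = self.samples.index[self.role_mask("study")]
        return self.subset_samples(ids)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "FeatureTable":
        """Check all structural invariants; raise with every failure found."""
        problems: list[str] = []
        inten, samples, features = self.intensities, self.samples, self.features

        if list(inten.index) != list(samples.index):
            missing = set(inten.index) ^ set(samples.index)
            problems.append(
                f"dimension mismatch: intensity rows and sample metadata differ "
                f"(symmetric difference: {sorted(map(str, missing))[:5]})"
            )
        if list(inten.columns) != list(features.index):
            missing = set(inten.columns) ^ set(features.index)
            problems.append(
                f"dimension mismatch: intensity columns and feature metadata differ "
                f"(symmetric difference: {sorted(map(str, missing))[:5]})"
            )
        if inten.index.has_duplicates:
            problems.append(f"duplicate sample ids: {sorted(inten.index[inten.index.duplicated()])}")
        if inten.columns.has_duplicates:
            problems.append(f"duplicate feature ids: {sorted(inten.columns[inten.columns.duplicated()])}")

        aligned = not problems  # metadata checks only make sense on aligned tables

        values = inten.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = inten.columns[[not np.issubdtype(dt, np.number) for dt in inten.dtypes]]
            problems.append(f"non-numeric intensity columns: {list(bad)[:5]}")
        else:
            if not np.all(np.isfinite(values)):
                problems.append("non-finite intensities present")
            elif not self.log_scale and np.any(values < 0):
                problems.append("negative intensities present")

        if aligned:
            bad_roles = set(samples["role"]) - set(SAMPLE_ROLES)
            if bad_roles:
                problems.append(f"unknown sample roles: {sorted(bad_roles)}")
            study = samples[samples["role"] == "study"]
            no_class = study.index[~study["class"].isin(CLASS_LABELS)]
            if len(no_class):
                problems.append(f"study sample without class: {list(no_class)[:5]}")
            dil = samples[samples["role"] == "dilution"]
            no_factor = dil.index[dil["dilution_factor"].isna()]
            if len(no_factor):
                problems.append(f"dilution sample without dilution_factor: {list(no_factor)[:5]}")
            order = samples["injection_order"].dropna()
            if order.duplicated().any():
                problems.append("injection_order values not unique")

        if problems:
            raise TableValidationError(problems)
        return self


def _read_csv(path, keep_default_na: bool = True) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8",
                        keep_default_na=keep_default_na,
                        na_values=[""] if not keep_default_na else None)
    frame.index.name = None
    frame.columns.name = None
    return frame


def read_study(
    intensities_path,
    samples_path,
    features_path,
    missing_policy: str = "error",
) -> FeatureTable:
    """Read and validate a study from three CSV/TSV files.

    Samples are reordered by injection order when present.  ``missing_policy``
    controls non-numeric intensity cells: ``"error"`` rejects them, ``"nan"``
    lets them through as NaN (they then fail the finiteness invariant only if
    validation is run on the raw matrix).
    """
    inten = _read_csv(intensities_path, keep_default_na=(missing_policy != "error"))
    inten.index = inten.index.astype(str)
    if missing_policy == "error":
        non_numeric = [c for c in inten.columns if not np.issubdtype(inten[c].dtype, np.number)]
        if non_numeric:
            raise TableValidationError(
                [f"non-numeric intensity value in column(s) {non_numeric[:5]} "
                 f"of {intensities_path} (missing_policy='error')"]
            )
    else:
        inten = inten.apply(pd.to_numeric, errors="coerce")

    samples = _read_csv(samples_path)
    samples.index = samples.index.astype(str)
    features = _read_csv(features_path)
    features.index = features.index.astype(str)

    table = FeatureTable(inten, samples, features).validate()
    order = table.samples["injection_order"]
    if order.notna().all():
        ids = order.sort_values(kind="stable").index
        table = table.subset_samples(ids)
    return table


def write_study(table: FeatureTable, directory) -> dict:
    """Write a table to ``intensities.csv``/``samples.csv``/``features.csv``."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": directory / "intensities.csv",
        "samples": directory / "samples.csv",
        "features": directory / "features.csv",
    }
    table.intensities.rename_axis("sample_id").to_csv(paths["intensities"])
    table.samples.rename_axis("sample_id").to_csv(paths["samples"])
    table.features.rename_axis("feature_id").to_csv(paths["features"])
    return paths


def log_transform(table: FeatureTable, pseudocount: float = 1.0) -> FeatureTable:
    """Natural log of (intensity + pseudocount), elementwise; metadata untouched.

    The multiplicative error structure of LC-MS intensities makes log scale
    the natural space for the linear modelling downstream.  A pseudocount of
    1 is negligible at typical instrument intensity scales and guards against
    exact zeros.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    values = table.intensities.to_numpy(dtype=float)
    if pseudocount == 0 and np.any(values <= 0):
        raise ValueError("zero intensity with pseudocount 0: log undefined")
    logged = table.intensities.astype(float) + pseudocount
    return replace(table, intensities=np.log(logged), log_scale=True)


def class_vector(table: FeatureTable) -> np.ndarray:
    """Encode infection class for the study samples: bacterial = 1, viral = 0.

    Raises if any study sample is unlabelled or only one class is present.
    """
    study = table.samples[table.role_mask("study")]
    labels = study["class"]
    unknown = labels.index[~labels.isin(CLASS_LABELS)]
    if len(unknown):
        raise ValueError(f"study samples without a class label: {list(unknown)[:5]}")
    y = (labels == "bacterial").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present for a two-class model")
    return y
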
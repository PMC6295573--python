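"""Reading, validation and standardization of regional morphometric tables.

Accepts two tab-separated dialects:

* wide, one file per feature, one row per subject, one column per
  region-measure (the layout produced by FreeSurfer's
  ``aparcstats2table``), and
* long, a single file with columns ``subject, region, feature, value``.

Either way the result is a :class:`FeatureTensor` aligned to the
canonical atlas region order.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import N_REGIONS, RegionAtlas

#: default feature set, in canonical order, with the column suffix each
#: uses in wide tables (thickness mm, volume mm^3, area mm^2,
#: mean curvature mm^-1, fold index unitless)
DEFAULT_FEATURES: tuple[str, ...] = ("thickness", "volume", "area", "meancurv", "foldind")

_ZTOL = 1e-9


class MorphometryError(ValueError):
    """Fatal validation problem in an input table."""


@dataclass(frozen=True)
class FeatureTensor:
    """Subjects x regions x features array of morphometric measurements."""

    values: np.ndarray
    subjects: tuple[str, ...]
    features: tuple[str, ...]
    atlas: RegionAtlas
    standardized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise MorphometryError(f"tensor must be 3-axis, got shape {v.shape}")
        if v.shape[0] != len(self.subjects):
            raise MorphometryError("subject axis does not match subject list")
        if v.shape[1] != N_REGIONS:
            raise MorphometryError(f"region axis must have {N_REGIONS} entries, got {v.shape[1]}")
        if v.shape[2] != len(self.features):
            raise MorphometryError("feature axis does not match feature list")
        if v.shape[2] < 2:
            raise MorphometryError("need at least 2 features per region")
        if not np.all(np.isfinite(v)):
            s, r, f = np.argwhere(~np.isfinite(v))[0]
            raise MorphometryError(
                f"non-finite value at subject {self.subjects[s]!r}, "
                f"region {self.atlas.names[r]!r}, feature {self.features[f]!r}"
            )
        object.__setattr__(self, "values", v)
        if self.standardized:
            mu = v.mean(axis=1)
            sd = v.std(axis=1, ddof=1)
            if not (np.all(np.abs(mu) < _ZTOL) and np.all(np.abs(sd - 1.0) < _ZTOL)):
                raise MorphometryError("standardized flag set but slices are not z-scored")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def subject_matrix(self, subject: str) -> np.ndarray:
        """One subject's regions x features slice."""
        try:
            i = self.subjects.index(subject)
        except ValueError:
            raise KeyError(f"unknown subject {subject!r}") from None
        return self.values[i]


def zscore_features(tensor: FeatureTensor, axis: str = "regions") -> FeatureTensor:
    """Standardize each feature to mean 0, sample SD 1.

    ``axis="regions"`` (default) standardizes within each subject across
    the 68 regions, making the features commensurate inside one
    subject's region vectors. ``axis="subjects"`` standardizes each
    (region, feature) across subjects instead.
    """
    if tensor.standardized:
        raise MorphometryError("tensor is already standardized")
    v = tensor.values
    if axis == "regions":
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, ddof=1, keepdims=True)
        bad = np.argwhere(sd[:, 0, :] <= 0)
        if bad.size:
            s, f = bad[0]
            raise MorphometryError(
                f"zero variance across regions for subject {tensor.subjects[s]!r}, "
                f"feature {tensor.features[f]!r}"
            )
    elif axis == "subjects":
        mu = v.mean(axis=0, keepdims=True)
        sd = v.std(axis=0, ddof=1, keepdims=True)
        if np.any(sd <= 0):
            r, f = np.argwhere(sd[0] <= 0)[0]
            raise MorphometryError(
                f"zero variance across subjects for region {tensor.atlas.names[r]!r}, "
                f"feature {tensor.features[f]!r}"
            )
    else:
        raise ValueError(f"unknown z-score axis {axis!r}")
    out = (v - mu) / sd
    return dataclasses.replace(tensor, values=out, standardized=(axis == "regions"))


def _wide_columns(atlas: RegionAtlas, measure: str) -> list[str]:
    return [f"{name}_{measure}" for name in atlas.names]


def read_feature_tables(
    paths: Mapping[str, str | Path],
    atlas: RegionAtlas,
    features: Sequence[str] | None = None,
) -> FeatureTensor:
    """Read one wide TSV per feature into an aligned tensor.

    ``paths`` maps feature name -> wide-TSV path; the feature name is
    also the per-column measure suffix (``lh_bankssts_thickness`` ...).
    Columns are aligned to the canonical atlas order regardless of their
    order on disk; extra columns are ignored with a report attached to
    the tensor is not needed — they are simply dropped.
    """
    features = tuple(features) if features is not None else tuple(paths)
    missing = [f for f in features if f not in paths]
    if missing:
        raise MorphometryError(f"no path given for features: {missing}")

    frames: dict[str, pd.DataFrame] = {}
    for feat in features:
        path = Path(paths[feat])
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        first = df.columns[0]
        df = df.set_index(first)
        df.index = df.index.astype(str)
        want = _wide_columns(atlas, feat)
        absent = [c for c in want if c not in df.columns]
        if absent:
            raise MorphometryError(f"{path}: missing region column {absent[0]!r}")
        unknown = sorted(set(df.columns) - set(want))
        if unknown:
            warnings.warn(f"{path}: ignoring {len(unknown)} unknown column(s): {unknown[:5]}")
        sub = df[want]
        coerced = sub.apply(pd.to_numeric, errors="coerce")
        if coerced.isna().any().any():
            r, c = np.argwhere(coerced.isna().to_numpy())[0]
            raise MorphometryError(
                f"{path}: non-numeric value at subject {sub.index[r]!r}, column {want[c]!r}"
            )
        frames[feat] = coerced

    subjects = tuple(frames[features[0]].index)
    for feat in features[1:]:
        if set(frames[feat].index) != set(subjects):
            raise MorphometryError(
                f"subject sets differ between feature tables "
                f"({features[0]!r} vs {feat!r})"
            )
        frames[feat] = frames[feat].loc[list(subjects)]

    values = np.stack([frames[f].to_numpy(dtype=float) for f in features], axis=2)
    return FeatureTensor(values=values, subjects=subjects, features=features, atlas=atlas)


def write_feature_tables(
    tensor: FeatureTensor, directory: str | Path, prefix: str = "features"
) -> dict[str, Path]:
    """Write one wide TSV per feature (inverse of :func:`read_feature_tables`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for k, feat in enumerate(tensor.features):
        cols = _wide_columns(tensor.atlas, feat)
        df = pd.DataFrame(tensor.values[:, :, k], columns=cols)
        df.insert(0, "subject", list(tensor.subjects))
        path = directory / f"{prefix}.{feat}.tsv"
        df.to_csv(path, sep="\t", index=False)
        out[feat] = path
    return out


def read_long_table(path: str | Path, atlas: RegionAtlas) -> FeatureTensor:
    """Read a long TSV with columns subject, region, feature, value."""
    df = pd.read_csv(
        path, sep="\t", dtype={"subject": str, "region": str, "feature": str},
        float_precision="round_trip",
    )
    need = {"subject", "region", "feature", "value"}
    if not need <= set(df.columns):
        raise MorphometryError(f"{path}: long table must have columns {sorted(need)}")
    subjects = tuple(dict.fromkeys(df["subject"]))
    features = tuple(dict.fromkeys(df["feature"]))
    values = np.full((len(subjects), N_REGIONS, len(features)), np.nan)
    s_idx = {s: i for i, s in enumerate(subjects)}
    f_idx = {f: i for i, f in enumerate(features)}
    try:
        r_pos = df["region"].map(atlas.index_of).to_numpy()
    except KeyError as exc:
        raise MorphometryError(f"{path}: {exc}") from exc
    values[
        df["subject"].map(s_idx).to_numpy(),
        r_pos,
        df["feature"].map(f_idx).to_numpy(),
    ] = pd.to_numeric(df["value"], errors="coerce").to_numpy()
    if np.isnan(values).any():
        raise MorphometryError(f"{path}: incomplete or non-numeric long table")
    return FeatureTensor(values=values, subjects=subjects, features=features, atlas=atlas)


def write_long_table(tensor: FeatureTensor, path: str | Path) -> Path:
    path = Path(path)
    s, r, f = np.meshgrid(
        np.arange(tensor.n_subjects), np.arange(N_REGIONS), np.arange(len(tensor.features)),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "subject": np.asarray(tensor.subjects)[s.ravel()],
            "region": np.asarray(tensor.atlas.names)[r.ravel()],
            "feature": np.asarray(tensor.features)[f.ravel()],
            "value": tensor.values.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


GROUPS = ("NC", "AD")
_CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-subject covariate table.

    Columns: subject, group (NC/AD), age, sex (F/M), mmse, cdr.
    When both group and CDR are present they must agree
    (CDR 0 <-> NC, CDR > 0 <-> AD).
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    need = {"subject", "group", "age", "sex", "mmse"}
    if not need <= set(df.columns):
        raise MorphometryError(f"{path}: cohort table must have columns {sorted(need)}")
    if not df["group"].isin(GROUPS).all():
        raise MorphometryError(f"{path}: group labels must be one of {GROUPS}")
    if not df["sex"].isin(("F", "M")).all():
        raise MorphometryError(f"{path}: sex must be F or M")
    mmse = pd.to_numeric(df["mmse"])
    if ((mmse < 0) | (mmse > 30)).any():
        raise MorphometryError(f"{path}: MMSE out of range 0-30")
    if "cdr" in df.columns:
        cdr = pd.to_numeric(df["cdr"])
        if not cdr.isin(_CDR_LEVELS).all():
            raise MorphometryError(f"{path}: CDR must be one of {_CDR_LEVELS}")
        clash = ((cdr == 0) & (df["group"] != "NC")) | ((cdr > 0) & (df["group"] != "AD"))
        if clash.any():
            bad = df.loc[clash, "subject"].iloc[0]
            raise MorphometryError(f"{path}: group/CDR mismatch for subject {bad!r}")
    return df
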
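"""Synthetic cohort generation with the statistical structure the
analysis assumes.

Each group has a 68x68 positive-definite interregional correlation
template. A subject is drawn as ``X = T^{1/2} Z`` with ``Z`` a
68 x k matrix of independent standard normal values, so the rows
(regions) of ``X`` carry cross-feature correlation ``T`` and the
subject's empirical Pearson matrix is a k-sample estimate of the
template. Group differences are implanted directly in correlation
units via per-edge template overrides; MMSE scores are coupled to the
realized global efficiency of each subject's network computed through
the real pipeline.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import N_REGIONS, RegionAtlas, load_atlas
from .io import (
    DEFAULT_FEATURES,
    FeatureTensor,
    read_cohort_table,
    write_feature_tables,
    zscore_features,
)
from .metrics import global_efficiency
from .network import build_network, to_weights

#: raw-scale (location, scale) used to dress standardized draws up as
#: plausible regional measurements with heterogeneous magnitudes
FEATURE_SCALES = {
    "thickness": (2.5, 0.25),
    "volume": (5000.0, 900.0),
    "area": (2400.0, 400.0),
    "meancurv": (0.13, 0.02),
    "foldind": (15.0, 4.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic generator."""

    n_nc: int = 20
    n_ad: int = 20
    n_features: int = 5
    base_within: float = 0.3
    base_between: float = 0.1
    effect_edges: tuple[tuple[str, str, float, float], ...] = ()
    mmse_intercept_nc: float = 29.0
    mmse_intercept_ad: float = 26.3
    mmse_slope: float = 1.5
    mmse_noise_sd: float = 1.0
    mmse_clip: tuple[int, int] = (20, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nc < 2 or self.n_ad < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_features < 2:
            raise ValueError("need at least 2 features")
        for v in (self.base_within, self.base_between):
            if not -1.0 < v < 1.0:
                raise ValueError("base correlations must lie in (-1, 1)")
        for a, b, r_nc, r_ad in self.effect_edges:
            if not (-1.0 < r_nc < 1.0 and -1.0 < r_ad < 1.0):
                raise ValueError(f"override correlations for ({a}, {b}) must lie in (-1, 1)")


def reported_effect_edges() -> tuple[tuple[str, str, float, float], ...]:
    """The packaged reference edge-alteration table as implant targets."""
    df = load_reported_edge_changes()
    return tuple(
        (row.region_a, row.region_b, float(row.r_nc), float(row.r_ad))
        for row in df.itertuples()
    )


def load_reported_edge_changes() -> pd.DataFrame:
    """Published reference table of significantly changed edges."""
    path = resources.files("morphnet.data").joinpath("reported_edge_changes.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_reported_hub_fractions(group: str) -> pd.DataFrame:
    """Published per-region consensus fractions (percent) for one group."""
    group = group.lower()
    if group not in ("nc", "ad"):
        raise ValueError("group must be 'nc' or 'ad'")
    path = resources.files("morphnet.data").joinpath(f"reported_hub_fractions_{group}.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def nearest_positive_definite(a: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix into a unit-diagonal positive-definite one.

    Eigenvalues are clipped from below and the result rescaled back to
    a correlation matrix.
    """
    sym = (a + a.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diagonal(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def make_templates(
    spec: CohortSpec, atlas: RegionAtlas | None = None, repair_tol: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Build the two group correlation templates.

    The base structure is block-wise by lobe (``base_within`` inside a
    lobe, ``base_between`` across lobes); ``effect_edges`` overrides are
    then applied — the NC value to the control template, the AD value to
    the patient template — and both matrices are repaired to positive
    definiteness. Overrides moved by more than ``repair_tol`` during
    repair are reported with a warning.
    """
    atlas = atlas or load_atlas()
    lobes = np.asarray(atlas.lobes)
    same_lobe = lobes[:, None] == lobes[None, :]
    base = np.where(same_lobe, spec.base_within, spec.base_between).astype(float)
    np.fill_diagonal(base, 1.0)

    t_nc, t_ad = base.copy(), base.copy()
    idx_pairs = []
    for a, b, r_nc, r_ad in spec.effect_edges:
        i, j = atlas.index_of(a), atlas.index_of(b)
        idx_pairs.append((i, j, r_nc, r_ad))
        t_nc[i, j] = t_nc[j, i] = r_nc
        t_ad[i, j] = t_ad[j, i] = r_ad

    t_nc = nearest_positive_definite(t_nc)
    t_ad = nearest_positive_definite(t_ad)
    moved = [
        (atlas.abbrevs[i], atlas.abbrevs[j])
        for i, j, r_nc, r_ad in idx_pairs
        if abs(t_nc[i, j] - r_nc) > repair_tol or abs(t_ad[i, j] - r_ad) > repair_tol
    ]
    if moved:
        warnings.warn(
            f"positive-definite repair moved {len(moved)} override(s) by more "
            f"than {repair_tol}: {moved[:5]}"
        )
    return t_nc, t_ad


def _template_sqrt(template: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(template)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def sample_subject(
    template: np.ndarray, k: int, rng: np.random.Generator, sqrt_cache: np.ndarray | None = None
) -> np.ndarray:
    """One subject's regions x k standardized feature draw."""
    if k < 2:
        raise ValueError("need k >= 2 features")
    root = sqrt_cache if sqrt_cache is not None else _template_sqrt(template)
    return root @ rng.standard_normal((template.shape[0], k))


def generate_cohort(
    spec: CohortSpec, atlas: RegionAtlas | None = None
) -> tuple[FeatureTensor, pd.DataFrame]:
    """Draw a full cohort: feature tensor plus covariate table.

    MMSE is generated from each subject's realized global efficiency
    (computed through the actual network + metric pipeline on absolute
    weights), standardized across the cohort, with group intercepts and
    Gaussian noise, then clipped and rounded to integers.
    """
    atlas = atlas or load_atlas()
    rng = np.random.default_rng(spec.seed)
    t_nc, t_ad = make_templates(spec, atlas)
    roots = {"NC": _template_sqrt(t_nc), "AD": _template_sqrt(t_ad)}

    features = (
        DEFAULT_FEATURES[: spec.n_features]
        if spec.n_features <= len(DEFAULT_FEATURES)
        else DEFAULT_FEATURES + tuple(f"synth{i}" for i in range(len(DEFAULT_FEATURES), spec.n_features))
    )
    groups = ["NC"] * spec.n_nc + ["AD"] * spec.n_ad
    subjects = tuple(
        [f"nc{i + 1:03d}" for i in range(spec.n_nc)]
        + [f"ad{i + 1:03d}" for i in range(spec.n_ad)]
    )

    templates = {"NC": t_nc, "AD": t_ad}
    raw = np.empty((len(subjects), N_REGIONS, spec.n_features))
    for s, group in enumerate(groups):
        x = sample_subject(templates[group], spec.n_features, rng, sqrt_cache=roots[group])
        for f, feat in enumerate(features):
            loc, scale = FEATURE_SCALES.get(feat, (0.0, 1.0))
            raw[s, :, f] = loc + scale * x[:, f]
    tensor = FeatureTensor(values=raw, subjects=subjects, features=features, atlas=atlas)

    # realized global efficiency through the real pipeline
    ztensor = zscore_features(tensor)
    e_glob = np.array(
        [
            global_efficiency(to_weights(build_network(ztensor, s), "abs"))
            for s in subjects
        ]
    )
    z_e = (e_glob - e_glob.mean()) / e_glob.std(ddof=1) if e_glob.std(ddof=1) > 0 else np.zeros_like(e_glob)
    intercepts = np.where(np.asarray(groups) == "NC", spec.mmse_intercept_nc, spec.mmse_intercept_ad)
    mmse = intercepts + spec.mmse_slope * z_e + rng.normal(0.0, spec.mmse_noise_sd, len(subjects))
    mmse = np.clip(np.rint(mmse), *spec.mmse_clip).astype(int)

    ages = rng.integers(70, 80, len(subjects))
    sexes = np.where(np.arange(len(subjects)) % 2 == 0, "F", "M")
    cohort = pd.DataFrame(
        {
            "subject": subjects,
            "group": groups,
            "age": ages,
            "sex": sexes,
            "mmse": mmse,
            "cdr": np.where(np.asarray(groups) == "NC", 0.0, 0.5),
        }
    )
    return tensor, cohort


def write_cohort(
    tensor: FeatureTensor, cohort: pd.DataFrame, directory: str | Path, spec: CohortSpec
) -> dict[str, Path]:
    """Write the full fixture set: wide feature TSVs, cohort TSV, spec JSON."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {f: p for f, p in write_feature_tables(tensor, directory).items()}
    cohort_path = directory / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False)
    spec_path = directory / "cohort_spec.json"
    payload = dataclasses.asdict(spec)
    payload["effect_edges"] = [list(e) for e in spec.effect_edges]
    spec_path.write_text(json.dumps(payload, indent=2))
    out = {"cohort": cohort_path, "spec": spec_path}
    out.update(paths)
    return out


def read_cohort(directory: str | Path, atlas: RegionAtlas | None = None):
    """Round-trip loader for :func:`write_cohort` output."""
    from .io import read_feature_tables

    atlas = atlas or load_atlas()
    directory = Path(directory)
    paths = {}
    for p in sorted(directory.glob("features.*.tsv")):
        feat = p.name.split(".")[1]
        paths[feat] = p
    order = [f for f in DEFAULT_FEATURES if f in paths] + sorted(
        f for f in paths if f not in DEFAULT_FEATURES
    )
    tensor = read_feature_tables(paths, atlas, features=order)
    cohort = read_cohort_table(directory / "cohort.tsv")
    return tensor, cohort
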
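"""Per-subject network construction from standardized feature vectors.

Each region's standardized features form its feature vector; the
network edge between two regions is the Pearson correlation of their
vectors, giving a 68x68 symmetric matrix with 2278 unique weighted
edges per subject. The signed matrix is kept for group statistics;
graph metrics consume a nonnegative transform of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import N_EDGES, N_REGIONS, RegionAtlas, load_centroids
from .io import FeatureTensor

WEIGHT_TRANSFORMS = ("abs", "positive")


class NetworkError(ValueError):
    """Degenerate input to network construction."""


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two equal-length feature vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise NetworkError("vectors must be 1-d, equal length >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    nu = np.sqrt(du @ du)
    nv = np.sqrt(dv @ dv)
    if nu == 0.0 or nv == 0.0:
        raise NetworkError("zero-variance vector: correlation undefined")
    return float(np.clip((du @ dv) / (nu * nv), -1.0, 1.0))


@dataclass(frozen=True)
class ConnMatrix:
    """One subject's symmetric interregional correlation matrix (diag 0)."""

    r: np.ndarray
    subject: str
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (N_REGIONS, N_REGIONS):
            raise NetworkError(f"matrix must be {N_REGIONS}x{N_REGIONS}, got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-12):
            raise NetworkError("matrix is not symmetric")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise NetworkError("correlations must lie in [-1, 1]")
        if np.any(np.diagonal(r) != 0):
            raise NetworkError("diagonal must be zero (self-connections excluded)")
        object.__setattr__(self, "r", r)

    @property
    def n_edges(self) -> int:
        return N_EDGES

    def edge_values(self) -> np.ndarray:
        """The 2278 unique edges, upper triangle in row-major order."""
        iu = np.triu_indices(N_REGIONS, 1)
        return self.r[iu]


@dataclass(frozen=True)
class WeightMatrix:
    """Nonnegative weights derived from a ConnMatrix."""

    w: np.ndarray
    transform: str
    subject: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise NetworkError("weight matrix is not symmetric")
        if np.any(w < 0) or np.any(w > 1 + 1e-12):
            raise NetworkError("weights must lie in [0, 1]")
        if np.any(np.diagonal(w) != 0):
            raise NetworkError("weight diagonal must be zero")
        object.__setattr__(self, "w", w)

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]


def build_network(tensor: FeatureTensor, subject: str) -> ConnMatrix:
    """All 2278 pairwise Pearson correlations for one subject."""
    if not tensor.standardized:
        raise NetworkError("tensor must be z-scored before network construction")
    x = tensor.subject_matrix(subject)  # regions x features
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = tensor.atlas.names[int(np.argmax(sd == 0))]
        raise NetworkError(f"zero-variance feature vector for region {bad!r}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnMatrix(r=r, subject=subject, atlas=tensor.atlas)


def to_weights(conn: ConnMatrix, transform: str = "abs") -> WeightMatrix:
    """Map signed correlations to nonnegative graph weights."""
    if transform == "abs":
        w = np.abs(conn.r)
    elif transform == "positive":
        w = np.maximum(conn.r, 0.0)
    else:
        raise NetworkError(f"unknown weight transform {transform!r}; use one of {WEIGHT_TRANSFORMS}")
    return WeightMatrix(w=w, transform=transform, subject=conn.subject)


def edge_table(conn: ConnMatrix, transform: str = "abs") -> pd.DataFrame:
    """Edge list over the frozen upper-triangle row-major edge order."""
    iu, ju = np.triu_indices(N_REGIONS, 1)
    ab = np.asarray(conn.atlas.abbrevs)
    w = to_weights(conn, transform).w
    return pd.DataFrame(
        {
            "region_a": ab[iu],
            "region_b": ab[ju],
            "r": conn.r[iu, ju],
            "w": w[iu, ju],
        }
    )


def export_edge_list(conn: ConnMatrix, path: str | Path, transform: str = "abs") -> Path:
    path = Path(path)
    edge_table(conn, transform).to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def export_brainnet(
    conn: ConnMatrix,
    node_path: str | Path,
    edge_path: str | Path,
    node_size: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write viewer-compatible ``.node`` / ``.edge`` files.

    The ``.edge`` file is the full 68x68 weight matrix, whitespace
    separated; the ``.node`` file has columns x y z color size label,
    with color coding the lobe and size defaulting to node strength.
    """
    node_path, edge_path = Path(node_path), Path(edge_path)
    cent = load_centroids().set_index("name").loc[list(conn.atlas.names)]
    lobe_color = {lobe: i + 1 for i, lobe in enumerate(sorted(set(conn.atlas.lobes)))}
    if node_size is None:
        node_size = np.abs(conn.r).sum(axis=0)
    with node_path.open("w") as fh:
        for i, name in enumerate(conn.atlas.names):
            x, y, z = cent.loc[name, ["x", "y", "z"]]
            fh.write(
                f"{x:.1f}\t{y:.1f}\t{z:.1f}\t{lobe_color[conn.atlas.lobes[i]]}\t"
                f"{float(node_size[i]):.4f}\t{conn.atlas.abbrevs[i]}\n"
            )
    np.savetxt(edge_path, conn.r, fmt="%.6f", delimiter="\t")
    return node_path, edge_path
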
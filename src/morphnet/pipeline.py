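"""End-to-end pipeline orchestration: ingest or simulate, build
networks, compute metrics, run group statistics, and write artifacts."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import RegionAtlas, load_atlas
from .cohort import CohortSpec, generate_cohort, read_cohort, write_cohort
from .io import zscore_features
from .metrics import compute_all_metrics
from .network import build_network, export_brainnet, export_edge_list
from .stats import (
    consensus_hubs,
    edgewise_comparison,
    ks_normality,
    metrics_frame,
    mmse_screen,
    rank_transform,
    spearman,
    two_sample_test,
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, serializable for provenance."""

    input_dir: str | None = None
    simulate: CohortSpec | None = None
    transform: str = "abs"
    modularity_rounds: int = 100
    modularity_seed: int = 0
    tails: str = "one"
    direction: str = "observed"
    alpha: float = 0.05
    fdr_method: str = "bh"
    consensus_threshold: float = 0.30
    mmse_zone: tuple[int, int] = (28, 30)
    screen_voting: str = "any"
    outlier_rule: str = "iqr"
    output_dir: str = "morphnet_run"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.consensus_threshold <= 1.0:
            raise ValueError("consensus threshold must lie in [0, 1]")
        if self.mmse_zone[0] > self.mmse_zone[1]:
            raise ValueError("MMSE zone lower bound exceeds upper bound")
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir / simulate must be given")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"]["effect_edges"] = [list(e) for e in self.simulate.effect_edges]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig, atlas: RegionAtlas | None = None) -> Path:
    """Execute all stages in order and write every artifact.

    Returns the run directory. A failure in any stage leaves the
    artifacts written so far plus a ``FAILED`` marker file.
    """
    atlas = atlas or load_atlas()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        _run_stages(cfg, atlas, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return out


def _run_stages(cfg: RunConfig, atlas: RegionAtlas, out: Path) -> None:
    # --- stage 1: ingest or simulate -------------------------------------
    if cfg.simulate is not None:
        tensor, cohort = generate_cohort(cfg.simulate, atlas)
        write_cohort(tensor, cohort, out / "cohort_data", cfg.simulate)
    else:
        tensor, cohort = read_cohort(cfg.input_dir, atlas)

    # --- stage 2: standardize and build individual networks --------------
    ztensor = zscore_features(tensor)
    networks = {s: build_network(ztensor, s) for s in tensor.subjects}

    rows = []
    for s, conn in networks.items():
        edges = conn.edge_values()
        rows.append(edges)
    iu, ju = np.triu_indices(len(atlas), 1)
    ab = np.asarray(atlas.abbrevs)
    edge_long = pd.DataFrame(
        np.column_stack(rows), columns=list(tensor.subjects)
    )
    edge_long.insert(0, "region_b", ab[ju])
    edge_long.insert(0, "region_a", ab[iu])
    _tsv(edge_long, out / "networks.tsv")

    # --- stage 3: per-subject graph metrics ------------------------------
    per_subject = [
        compute_all_metrics(
            networks[s],
            transform=cfg.transform,
            rounds=cfg.modularity_rounds,
            seed=cfg.modularity_seed,
        )
        for s in tensor.subjects
    ]
    scalar = metrics_frame(per_subject).merge(cohort, on="subject")
    _tsv(scalar, out / "metrics.tsv")

    nodal = pd.DataFrame(
        {
            "subject": np.repeat(list(tensor.subjects), len(atlas)),
            "region": np.tile(ab, len(per_subject)),
            "e_local": np.concatenate([m.e_local for m in per_subject]),
            "bc": np.concatenate([m.bc for m in per_subject]),
            "n_bc": np.concatenate(
                [m.n_bc if m.n_bc is not None else np.full(len(atlas), np.nan) for m in per_subject]
            ),
        }
    )
    _tsv(nodal, out / "nodal_metrics.tsv")

    hub_rows = pd.DataFrame(
        [[region in m.hubs for region in ab] for m in per_subject],
        columns=ab,
    )
    hub_rows.insert(0, "subject", list(tensor.subjects))
    _tsv(hub_rows, out / "subject_hubs.tsv")

    # --- stage 4: group statistics ---------------------------------------
    by_group = dict(cohort.groupby("group")["subject"].apply(list))
    nets_nc = [networks[s] for s in by_group.get("NC", [])]
    nets_ad = [networks[s] for s in by_group.get("AD", [])]
    comparison = edgewise_comparison(
        nets_nc,
        nets_ad,
        alpha=cfg.alpha,
        tails=cfg.tails,
        direction=cfg.direction,
        outlier_rule=cfg.outlier_rule,
        fdr_method=cfg.fdr_method,
    )
    _tsv(comparison, out / "edge_comparison.tsv")

    # --- stage 5: consensus hubs -----------------------------------------
    metric_by_subject = {m.subject: m for m in per_subject}
    hub_tables = {}
    for group, subs in by_group.items():
        table = consensus_hubs(
            [metric_by_subject[s].hubs for s in subs],
            atlas,
            threshold=cfg.consensus_threshold,
            bc_per_subject=[metric_by_subject[s].bc for s in subs],
        )
        hub_tables[group] = table
        _tsv(table, out / f"consensus_hubs_{group.lower()}.tsv")

    # --- stage 6: MMSE screening -----------------------------------------
    screening = mmse_screen(
        scalar[["subject", "group", "mmse", "e_global", "m_e_local", "m_bc"]],
        zone=cfg.mmse_zone,
        voting=cfg.screen_voting,
    )
    _tsv(screening, out / "screening.tsv")

    # --- stage 7: scalar-metric group tests and associations -------------
    metric_tests = {}
    for prop in ("e_global", "q", "m_e_local", "m_bc", "mmse"):
        vals = scalar[prop].to_numpy(dtype=float)
        groups = scalar["group"].to_numpy()
        ranks = rank_transform(vals)
        res = two_sample_test(
            ranks[groups == "NC"], ranks[groups == "AD"],
            tails=cfg.tails, direction=cfg.direction,
        )
        metric_tests[prop] = {
            "t": res.t,
            "p": res.p,
            "welch": res.welch,
            "normality_p": ks_normality(vals) if np.unique(vals).size > 1 else None,
        }
    associations = {
        prop: spearman(scalar["mmse"], scalar[prop])
        for prop in ("e_global", "q", "m_e_local", "m_bc")
    }

    # --- stage 8: viewer exports and summary -----------------------------
    first = networks[tensor.subjects[0]]
    export_edge_list(first, out / "example_subject.edges.tsv", transform=cfg.transform)
    export_brainnet(first, out / "example_subject.node", out / "example_subject.edge")

    sig = comparison[comparison["significant"]]
    confusion = (
        screening.groupby(["group", "predicted"]).size().to_dict()
        if "group" in screening
        else {}
    )
    summary = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "n_subjects": len(tensor.subjects),
        "n_edges": int(len(comparison)),
        "n_significant_edges": int(sig.shape[0]),
        "significant_by_class": sig["change_class"].value_counts().to_dict(),
        "consensus_hubs": {
            g: t.loc[t["is_hub"], "region"].tolist() for g, t in hub_tables.items()
        },
        "metric_tests": metric_tests,
        "mmse_spearman": associations,
        "screening_confusion": {f"{g}->{p}": int(n) for (g, p), n in confusion.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
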
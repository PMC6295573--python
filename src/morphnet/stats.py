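"""Group-level inference over individual networks and graph metrics.

The group pipeline mirrors the analysis protocol: per-variable outlier
exclusion, rank transform of the pooled values (mean ranks for ties),
independent two-sample t-tests with a Levene gate selecting the
unequal-variance statistic, FDR correction across the 2278 edges, and a
four-way classification of significantly changed edges. Consensus hubs
and an MMSE-zone screening rule summarize the subject-level results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .atlas import N_REGIONS, RegionAtlas
from .metrics import SubjectMetrics
from .network import ConnMatrix

CHANGE_CLASSES = (
    "decrease-positive",
    "decrease-negative",
    "increase-positive",
    "increase-negative",
)

FDR_METHODS = {"bh": "fdr_bh", "by": "fdr_by"}
OUTLIER_RULES = ("off", "iqr", "zscore")


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by mean ranks."""
    return sps.rankdata(np.asarray(values, dtype=float), method="average")


def ks_normality(values: np.ndarray) -> float:
    """Normality p-value for one variable.

    One-sample Kolmogorov-Smirnov against a normal with estimated mean
    and SD; since the parameters are estimated from the same sample the
    Lilliefors-corrected p-value is reported (plain KS would be far too
    conservative). Used to justify the rank transform, not as a gate.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 values for a normality check")
    return float(lilliefors(values, dist="norm", pvalmethod="table")[1])


@dataclass(frozen=True)
class TestResult:
    t: float
    p: float
    df: float
    welch: bool
    levene_p: float


def _batch_ttest(
    a: np.ndarray,
    b: np.ndarray,
    tails: str = "two",
    direction: str | np.ndarray = "observed",
    levene_alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Levene-gated two-sample t-tests, one per column.

    Returns (t, p, df, welch_flags). ``t`` is (mean_a - mean_b) / SE.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)

    # Levene gate (center = mean): pooled t-test on absolute deviations
    za, zb = np.abs(a - ma), np.abs(b - mb)
    mza, mzb = za.mean(axis=0), zb.mean(axis=0)
    vza, vzb = za.var(axis=0, ddof=1), zb.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * vza + (n2 - 1) * vzb) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lev = (mza - mzb) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    lev_p = 2 * sps.t.sf(np.abs(np.nan_to_num(t_lev)), n1 + n2 - 2)
    welch = lev_p < levene_alpha

    pooled2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_pool = (ma - mb) / np.sqrt(pooled2 * (1 / n1 + 1 / n2))
        se_w2 = va / n1 + vb / n2
        t_welch = (ma - mb) / np.sqrt(se_w2)
        df_welch = se_w2**2 / ((va / n1) ** 2 / (n1 - 1) + (vb / n2) ** 2 / (n2 - 1))
    df_pool = np.full_like(t_pool, float(n1 + n2 - 2))
    t = np.where(welch, t_welch, t_pool)
    df = np.where(welch, df_welch, df_pool)

    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    df = np.where(np.isfinite(df), df, float(n1 + n2 - 2))

    if tails == "two":
        p = 2 * sps.t.sf(np.abs(t), df)
    elif tails == "one":
        if isinstance(direction, str) and direction == "observed":
            # replication mode: test in the direction of the observed
            # difference per column (anti-conservative by construction)
            p = sps.t.sf(np.abs(t), df)
        else:
            sign = np.sign(np.asarray(direction, dtype=float))
            p = sps.t.sf(sign * t, df)
    else:
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    p = np.where(degenerate, 1.0, np.clip(p, 0.0, 1.0))
    return t, p, df, welch


def two_sample_test(
    a: Sequence[float],
    b: Sequence[float],
    tails: str = "two",
    direction: str | float = "observed",
    levene_alpha: float = 0.05,
) -> TestResult:
    """Levene-gated independent two-sample t-test on two value lists."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[:, None]
    if a[:, 0].var(ddof=1) == 0 and b[:, 0].var(ddof=1) == 0:
        if a.mean() != b.mean():
            raise ValueError("degenerate variance in both groups")
        return TestResult(t=0.0, p=1.0, df=float(len(a) + len(b) - 2), welch=False, levene_p=1.0)
    dir_arg = direction if isinstance(direction, str) else np.array([direction])
    t, p, df, welch = _batch_ttest(a, b, tails=tails, direction=dir_arg, levene_alpha=levene_alpha)
    za = np.abs(a[:, 0] - a.mean())
    zb = np.abs(b[:, 0] - b.mean())
    lev = sps.ttest_ind(za, zb, equal_var=True)
    return TestResult(
        t=float(t[0]), p=float(p[0]), df=float(df[0]), welch=bool(welch[0]),
        levene_p=float(lev.pvalue),
    )


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05, method: str = "bh"):
    """FDR step-up correction: adjusted q-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method=FDR_METHODS[method])
    return q, reject


def classify_edge_change(mean_nc: float, mean_ad: float) -> str:
    """Four-way label for a changed edge.

    An edge is a *decrease* when the patient-group correlation moved
    toward zero (|AD| < |NC|), labeled by the control-group sign; it is
    an *increase* otherwise, labeled by the patient-group sign. This
    covers sign flips as well as same-sign changes.
    """
    if abs(mean_ad) < abs(mean_nc):
        return "decrease-positive" if mean_nc > 0 else "decrease-negative"
    return "increase-positive" if mean_ad > 0 else "increase-negative"


def exclude_outliers(values: Sequence[float], rule: str = "iqr"):
    """Per-variable outlier mask. Returns (keep_mask, log dict).

    ``iqr``: drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR];
    ``zscore``: drop |z| > 3; ``off``: keep everything.
    """
    values = np.asarray(values, dtype=float)
    if rule == "off":
        keep = np.ones(values.size, dtype=bool)
    elif rule == "iqr":
        if values.size < 4:
            raise ValueError("need at least 4 values for IQR fences")
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        keep = (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)
    elif rule == "zscore":
        sd = values.std(ddof=1)
        keep = np.abs(values - values.mean()) <= 3 * sd if sd > 0 else np.ones(values.size, bool)
    else:
        raise ValueError(f"unknown outlier rule {rule!r}; use one of {OUTLIER_RULES}")
    log = {"rule": rule, "n": int(values.size), "n_excluded": int((~keep).sum())}
    return keep, log


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (NaN when either input is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def _edge_values(conns: Iterable[ConnMatrix]) -> np.ndarray:
    return np.vstack([c.edge_values() for c in conns])


def edgewise_comparison(
    networks_nc: Sequence[ConnMatrix],
    networks_ad: Sequence[ConnMatrix],
    alpha: float = 0.05,
    tails: str = "one",
    direction: str = "observed",
    outlier_rule: str = "iqr",
    fdr_method: str = "bh",
    levene_alpha: float = 0.05,
) -> pd.DataFrame:
    """Edge-wise two-sample screen across all 2278 edges.

    Per edge: outlier exclusion per group, rank transform of the pooled
    retained values, Levene-gated t-test, then FDR correction across
    edges and change classification of the significant ones.
    """
    if len(networks_nc) < 2 or len(networks_ad) < 2:
        raise ValueError("need at least 2 subjects per group")
    atlas = networks_nc[0].atlas
    nc = _edge_values(networks_nc)  # (n1, 2278)
    ad = _edge_values(networks_ad)
    n1 = nc.shape[0]
    n_edges = nc.shape[1]

    if outlier_rule == "off":
        keep_nc = np.ones_like(nc, dtype=bool)
        keep_ad = np.ones_like(ad, dtype=bool)
    else:
        keep_nc = np.ones_like(nc, dtype=bool)
        keep_ad = np.ones_like(ad, dtype=bool)
        for vals, keep in ((nc, keep_nc), (ad, keep_ad)):
            if outlier_rule == "iqr":
                q1, q3 = np.percentile(vals, [25, 75], axis=0)
                fence = 1.5 * (q3 - q1)
                keep[:] = (vals >= q1 - fence) & (vals <= q3 + fence)
            elif outlier_rule == "zscore":
                sd = vals.std(axis=0, ddof=1)
                keep[:] = np.abs(vals - vals.mean(axis=0)) <= 3 * np.where(sd > 0, sd, np.inf)
            else:
                raise ValueError(f"unknown outlier rule {outlier_rule!r}")

    clean = keep_nc.all(axis=0) & keep_ad.all(axis=0)
    t = np.empty(n_edges)
    p = np.empty(n_edges)
    welch = np.zeros(n_edges, dtype=bool)
    mean_nc = np.empty(n_edges)
    mean_ad = np.empty(n_edges)

    # fast path: edges with no exclusions, rank-transformed jointly
    if clean.any():
        pooled = np.vstack([nc[:, clean], ad[:, clean]])
        ranks = sps.rankdata(pooled, method="average", axis=0)
        tc, pc, _, wc = _batch_ttest(
            ranks[:n1], ranks[n1:], tails=tails, direction=direction,
            levene_alpha=levene_alpha,
        )
        t[clean], p[clean], welch[clean] = tc, pc, wc
        mean_nc[clean] = nc[:, clean].mean(axis=0)
        mean_ad[clean] = ad[:, clean].mean(axis=0)

    for e in np.flatnonzero(~clean):
        va = nc[keep_nc[:, e], e]
        vb = ad[keep_ad[:, e], e]
        pooled = np.concatenate([va, vb])
        ranks = rank_transform(pooled)
        res = two_sample_test(
            ranks[: va.size], ranks[va.size:], tails=tails, direction=direction,
            levene_alpha=levene_alpha,
        )
        t[e], p[e], welch[e] = res.t, res.p, res.welch
        mean_nc[e], mean_ad[e] = va.mean(), vb.mean()

    q, reject = bh_fdr(p, alpha=alpha, method=fdr_method)
    classes = [
        classify_edge_change(mnc, mad) if sig else "none"
        for mnc, mad, sig in zip(mean_nc, mean_ad, reject)
    ]
    iu, ju = np.triu_indices(N_REGIONS, 1)
    ab = np.asarray(atlas.abbrevs)
    return pd.DataFrame(
        {
            "region_a": ab[iu],
            "region_b": ab[ju],
            "mean_nc": mean_nc,
            "mean_ad": mean_ad,
            "t": t,
            "p": p,
            "q": q,
            "significant": reject,
            "change_class": classes,
            "welch": welch,
            "n_excluded_nc": (~keep_nc).sum(axis=0),
            "n_excluded_ad": (~keep_ad).sum(axis=0),
        }
    )


def consensus_from_fractions(fractions: Sequence[float], threshold: float = 0.30) -> np.ndarray:
    """Group-hub flags from per-region subject fractions (inclusive rule)."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    return fractions >= threshold


def consensus_hubs(
    per_subject_hubs: Sequence[frozenset[str] | set[str]],
    atlas: RegionAtlas,
    threshold: float = 0.30,
    bc_per_subject: Sequence[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Group consensus hubs from individual hub sets.

    A region is a group hub when the fraction of subjects having it as
    an individual hub reaches the consensus threshold (inclusive).
    """
    if len(per_subject_hubs) < 1:
        raise ValueError("need at least one subject")
    n = len(per_subject_hubs)
    counts = np.zeros(N_REGIONS)
    for hubset in per_subject_hubs:
        for region in hubset:
            counts[atlas.index_of(region)] += 1
    fractions = counts / n
    df = pd.DataFrame(
        {
            "region": atlas.abbrevs,
            "lobe": atlas.lobes,
            "class": atlas.classes,
            "fraction": fractions,
            "is_hub": consensus_from_fractions(fractions, threshold),
        }
    )
    if bc_per_subject is not None:
        df["avg_bc"] = np.vstack(bc_per_subject).mean(axis=0)
    return df


def metrics_frame(metrics: Sequence[SubjectMetrics]) -> pd.DataFrame:
    """Scalar per-subject metrics as a tidy table."""
    return pd.DataFrame(
        {
            "subject": [m.subject for m in metrics],
            "e_global": [m.e_global for m in metrics],
            "q": [m.q for m in metrics],
            "m_e_local": [m.m_e_local for m in metrics],
            "m_bc": [m.m_bc for m in metrics],
        }
    )


def screening_thresholds(reference: pd.DataFrame) -> dict[str, float]:
    """Midpoint-of-group-means decision thresholds from a labeled table.

    ``reference`` needs columns group, e_global, m_e_local, m_bc.
    """
    means = reference.groupby("group")[["e_global", "m_e_local", "m_bc"]].mean()
    if not {"NC", "AD"} <= set(means.index):
        raise ValueError("reference table must contain both NC and AD subjects")
    return {
        prop: float((means.loc["NC", prop] + means.loc["AD", prop]) / 2.0)
        for prop in ("e_global", "m_e_local", "m_bc")
    }


def mmse_screen(
    subjects: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    zone: tuple[int, int] = (28, 30),
    voting: str = "any",
) -> pd.DataFrame:
    """Combined MMSE + graph-property screening rule.

    Subjects below the zone are labeled AD outright. Inside the zone a
    subject votes AD when e_global or m_e_local falls below, or m_bc
    rises above, its decision threshold; ``voting`` is "any" (one vote
    suffices) or "majority" (at least two of three).
    """
    need = {"subject", "mmse", "e_global", "m_e_local", "m_bc"}
    if not need <= set(subjects.columns):
        raise ValueError(f"screening table must have columns {sorted(need)}")
    if subjects["mmse"].isna().any():
        raise ValueError("missing MMSE score")
    if thresholds is None:
        thresholds = screening_thresholds(subjects)
    lo, hi = zone
    if lo > hi:
        raise ValueError("zone lower bound exceeds upper bound")
    out = subjects.copy()
    out["zone"] = np.where(out["mmse"] < lo, "low", "high")
    votes = (
        (out["e_global"] < thresholds["e_global"]).astype(int)
        + (out["m_e_local"] < thresholds["m_e_local"]).astype(int)
        + (out["m_bc"] > thresholds["m_bc"]).astype(int)
    )
    out["votes_ad"] = votes
    needed = 1 if voting == "any" else 2
    if voting not in ("any", "majority"):
        raise ValueError(f"unknown voting scheme {voting!r}")
    out["predicted"] = np.where(
        (out["zone"] == "low") | (votes >= needed), "AD", "NC"
    )
    return out
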
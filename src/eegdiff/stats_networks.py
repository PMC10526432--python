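"""Two-group per-feature difference maps and differential PLI networks.

Every feature column is compared between the two groups with a one-way
ANOVA (two groups, so F is the squared pooled t statistic, df 1 and
n_a + n_b - 2). Significant PLI features form a differential brain
network per band, each edge labelled with the group whose connectivity
is higher.

The statistical unit is selectable: ``unit='epoch'`` treats every epoch
row as an observation (large effective n; within-subject correlation is
ignored), ``unit='subject'`` first averages each subject's epochs (one
observation per subject). No multiple-testing correction is applied by
default; a Benjamini-Hochberg switch is available.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BAND_NAMES
from .features import split_feature_id

DEFAULT_ALPHA = 0.05


def anova_oneway(values_a, values_b) -> tuple[float, float]:
    """Two-group one-way ANOVA: (F, p) with df (1, n_a + n_b - 2).

    Degenerate input (zero variance in both groups and equal means)
    yields (nan, nan).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ssw == 0:
        return (np.nan, np.nan)
    f, p = sps.f_oneway(a, b)
    return float(f), float(p)


@dataclass(frozen=True)
class DiffResult:
    """Per-feature two-group comparison."""

    feature_id: str
    family: str
    band: str
    target: str  # channel, or 'ch1-ch2' for a pair
    f_stat: float
    p_value: float
    mean_a: float
    mean_b: float
    significant: bool
    direction: str  # group label with the higher mean ('' if not significant)


def _group_matrices(table: pd.DataFrame, columns, unit: str):
    groups = list(pd.unique(table["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    if unit == "subject":
        agg = table.groupby(["subject_id", "group"], sort=True)[columns].mean()
        agg = agg.reset_index()
        src = agg
    elif unit == "epoch":
        src = table
    else:
        raise ValueError("unit must be 'epoch' or 'subject'")
    mat_a = src.loc[src["group"] == groups[0], columns].to_numpy(float)
    mat_b = src.loc[src["group"] == groups[1], columns].to_numpy(float)
    return groups, mat_a, mat_b


def _compare_columns(table: pd.DataFrame, columns, alpha: float, unit: str,
                     fdr: bool) -> list[DiffResult]:
    groups, mat_a, mat_b = _group_matrices(table, columns, unit)
    f, p = sps.f_oneway(mat_a, mat_b, axis=0)
    f, p = np.atleast_1d(f), np.atleast_1d(p)
    p_crit = np.asarray(p, dtype=float)
    if fdr:
        finite = np.isfinite(p_crit)
        adj = np.full_like(p_crit, np.nan)
        adj[finite] = sps.false_discovery_control(p_crit[finite], method="bh")
        p_crit = adj
    out = []
    ma, mb = mat_a.mean(axis=0), mat_b.mean(axis=0)
    for i, col in enumerate(columns):
        fam, band, target = split_feature_id(col)
        sig = bool(np.isfinite(p_crit[i]) and p_crit[i] < alpha)
        direction = ""
        if sig:
            direction = groups[0] if ma[i] > mb[i] else groups[1]
        out.append(DiffResult(feature_id=col, family=fam, band=band,
                              target=target, f_stat=float(f[i]),
                              p_value=float(p[i]), mean_a=float(ma[i]),
                              mean_b=float(mb[i]), significant=sig,
                              direction=direction))
    return out


def difference_map(table: pd.DataFrame, family: str,
                   alpha: float = DEFAULT_ALPHA, unit: str = "epoch",
                   fdr: bool = False) -> list[DiffResult]:
    """Per (band, channel) ANOVA for one scalar feature family (PSD or FE)."""
    if family not in ("PSD", "FE"):
        raise ValueError("family must be 'PSD' or 'FE'")
    cols = [c for c in table.columns if c.startswith(family + "_")]
    if not cols:
        raise ValueError(f"no {family} columns in table")
    return _compare_columns(table, cols, alpha, unit, fdr)


@dataclass(frozen=True)
class DiffNetwork:
    """Significant PLI edges for one band with direction counts.

    ``ratio`` formats the counts as 'B/A' (second group's count first,
    matching a higher-in-B-first reporting convention).
    """

    band: str
    edges: tuple  # of (pair, direction, p_value)
    count_b_higher: int
    count_a_higher: int

    @property
    def ratio(self) -> str:
        return f"{self.count_b_higher}/{self.count_a_higher}"

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def differential_network(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                         unit: str = "epoch", fdr: bool = False,
                         ) -> dict[str, DiffNetwork]:
    """Per band, the network of significantly different PLI edges."""
    cols = [c for c in table.columns if c.startswith("PLI_")]
    if not cols:
        raise ValueError("no PLI columns in table")
    results = _compare_columns(table, cols, alpha, unit, fdr)
    groups = list(pd.unique(table["group"]))
    nets: dict[str, DiffNetwork] = {}
    bands = [b for b in BAND_NAMES
             if any(r.band == b for r in results)] or sorted(
                 {r.band for r in results})
    for band in bands:
        sig = [r for r in results if r.band == band and r.significant]
        edges = tuple((r.target, r.direction, r.p_value) for r in sig)
        nets[band] = DiffNetwork(
            band=band, edges=edges,
            count_b_higher=sum(1 for r in sig if r.direction == groups[1]),
            count_a_higher=sum(1 for r in sig if r.direction == groups[0]),
        )
    return nets


def key_connection_share(networks: dict[str, DiffNetwork]) -> dict[str, float]:
    """Per-band share of all significant edges across bands (sums to 1)."""
    total = sum(n.n_edges for n in networks.values())
    if total == 0:
        raise ValueError("no significant edges in any band")
    return {band: n.n_edges / total for band, n in networks.items()}


def diff_results_frame(results: list[DiffResult]) -> pd.DataFrame:
    """Tabular view of a difference map for serialisation."""
    return pd.DataFrame([r.__dict__ for r in results])
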
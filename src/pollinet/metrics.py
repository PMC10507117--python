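"""Binary structure metrics of bipartite networks and model comparisons.

Nestedness follows the paired-overlap-with-decreasing-fill definition
(NODF, 0-100): for every ordered pair of rows (and of columns) where the
first has strictly larger marginal total than the second, the pair
contributes the percentage of the sparser row's links that overlap the
denser one's; equal marginal totals contribute zero.  ``nodf_c`` rescales
NODF by connectance and the log geometric mean of guild sizes so that
networks of different size and fill can be compared; the raw NODF is
always reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import BinaryNetwork

__all__ = [
    "BinaryNetwork",
    "StructureReport",
    "nodf",
    "nodf_c",
    "structure",
    "trajectory_metrics",
    "compare_models",
    "ComparisonReport",
]


def nodf(M: np.ndarray) -> float:
    """Nestedness (NODF) of a binary matrix, in [0, 100]."""
    M = np.asarray(M, dtype=bool)
    n_r, n_c = M.shape
    if n_r < 2 and n_c < 2:
        return 0.0

    def axis_sum(X: np.ndarray) -> float:
        Xi = X.astype(np.int64)
        k = Xi.sum(axis=1).astype(float)
        S = (Xi @ Xi.T).astype(float)  # pairwise shared links
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(k[None, :] > 0, S / np.where(k > 0, k, 1.0)[None, :], 0.0)
        dec = k[:, None] > k[None, :]  # strictly decreasing fill
        return float((frac * dec).sum())

    total = axis_sum(M) + axis_sum(M.T)
    n_pairs = n_r * (n_r - 1) / 2 + n_c * (n_c - 1) / 2
    return 100.0 * total / n_pairs


def nodf_c(M: np.ndarray) -> float:
    """Size/connectance-corrected nestedness.

    ``NODFc = NODF / (C * log10(sqrt(n_r * n_c)))`` with connectance
    ``C``; undefined (NaN) for degenerate or single-species guilds.
    """
    M = np.asarray(M, dtype=bool)
    n_r, n_c = M.shape
    links = int(M.sum())
    if n_r == 0 or n_c == 0 or links == 0:
        return float("nan")
    C = links / (n_r * n_c)
    s = math.sqrt(n_r * n_c)
    if s <= 1.0:
        return float("nan")
    return nodf(M) / (C * math.log10(s))


@dataclass
class StructureReport:
    """Binary structure of one network snapshot."""

    richness: int
    n_plants: int
    n_polls: int
    connectance: float
    poll_plant_ratio: float
    plant_degrees: np.ndarray
    poll_degrees: np.ndarray
    nodf: float
    nodf_c: float
    time: float | None = None

    def as_dict(self) -> dict:
        return {
            "richness": self.richness,
            "n_plants": self.n_plants,
            "n_polls": self.n_polls,
            "connectance": self.connectance,
            "poll_plant_ratio": self.poll_plant_ratio,
            "nodf": self.nodf,
            "nodf_c": self.nodf_c,
            "time": self.time,
        }


def structure(net: BinaryNetwork) -> StructureReport:
    """All binary structure metrics of a snapshot; both guilds must be
    non-empty."""
    n_p, n_a = net.n_plants, net.n_polls
    if n_p == 0 or n_a == 0:
        raise ValueError("cannot compute structure of a network with an empty guild")
    M = net.adjacency
    links = int(M.sum())
    return StructureReport(
        richness=n_p + n_a,
        n_plants=n_p,
        n_polls=n_a,
        connectance=links / (n_p * n_a),
        poll_plant_ratio=n_a / n_p,
        plant_degrees=M.sum(axis=1),
        poll_degrees=M.sum(axis=0),
        nodf=nodf(M),
        nodf_c=nodf_c(M),
        time=net.time,
    )


_TRAJ_METRICS = ("richness", "connectance", "poll_plant_ratio", "nodf")


def trajectory_metrics(
    snapshot_series: list[list[BinaryNetwork]],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> pd.DataFrame:
    """Per-event mean structure across simulations with bootstrap bands.

    ``snapshot_series`` holds one list of per-event snapshots per
    simulation (e.g. the post-extinction networks of every grid cell).
    Returns a tidy frame (event, metric, mean, lo, hi); the percentile
    bootstrap resamples simulations with replacement.
    """
    rng = np.random.default_rng(seed)
    n_sims = len(snapshot_series)
    n_events = min(len(s) for s in snapshot_series)
    values = {m: np.full((n_sims, n_events), np.nan) for m in _TRAJ_METRICS}
    for s, series in enumerate(snapshot_series):
        for k in range(n_events):
            net = series[k]
            if net.n_plants == 0 or net.n_polls == 0:
                continue
            rep = structure(net)
            for m in _TRAJ_METRICS:
                values[m][s, k] = getattr(rep, m)
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    idx = rng.integers(0, n_sims, size=(n_boot, n_sims))
    rows = []
    for m, arr in values.items():
        mean = np.nanmean(arr, axis=0)
        boots = np.nanmean(arr[idx], axis=1)  # (n_boot, n_events)
        lo = np.nanpercentile(boots, lo_q, axis=0)
        hi = np.nanpercentile(boots, hi_q, axis=0)
        for k in range(n_events):
            rows.append(
                {"event": k, "metric": m, "mean": mean[k], "lo": lo[k], "hi": hi[k]}
            )
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Paired and unpaired one-sided comparisons of one metric between
    two simulation grids matched cell-by-cell."""

    metric: str
    alternative: str
    n_cells: int
    mean_a: float
    mean_b: float
    paired_t: float
    paired_p: float
    welch_t: float
    welch_p: float


def compare_models(
    values_a: dict,
    values_b: dict,
    metric: str = "",
    alternative: str = "greater",
) -> ComparisonReport:
    """Compare a scalar metric between two grids of simulations.

    ``values_a`` and ``values_b`` map identical (p_spec_plant,
    p_spec_poll) keys to metric values.  The headline test is a paired
    one-sided t-test on cell-wise differences (cells matched by
    probability pair); a one-sided Welch unequal-variance test is
    reported alongside.  ``alternative='greater'`` tests a > b.
    """
    if set(values_a) != set(values_b):
        raise ValueError("grids do not share identical probability cells")
    keys = sorted(values_a)
    a = np.array([values_a[k] for k in keys], dtype=float)
    b = np.array([values_b[k] for k in keys], dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    d = a - b
    if np.allclose(d, 0.0):
        pt, pp = 0.0, 0.5  # identical grids: no evidence either way
    else:
        res = stats.ttest_rel(a, b, alternative=alternative)
        pt, pp = float(res.statistic), float(res.pvalue)
    resw = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return ComparisonReport(
        metric=metric,
        alternative=alternative,
        n_cells=int(ok.sum()),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        paired_t=pt,
        paired_p=pp,
        welch_t=float(resw.statistic),
        welch_p=float(resw.pvalue),
    )
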
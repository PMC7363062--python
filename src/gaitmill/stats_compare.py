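"""Pre/post comparison statistics for the sEMG indices.

Small paired cohorts (here n = 9 participants) call for a non-parametric
dependent-sample test, so the pre-vs-post comparison of each index uses
the Wilcoxon signed-rank test with:

* mid-ranks for tied |differences| and zero differences dropped
  (standard signed-rank conventions, zero count reported);
* an **exact** two-sided p by full enumeration of all 2^n sign
  assignments when n <= 12, the normal approximation with continuity
  and tie correction otherwise;
* effect size r = |z| / sqrt(2 n) with z from the normal approximation
  (z over the root of the total observation count).

Index values are first normalized per participant-session by the peak
dynamic method — each index divided by its within-session peak across
muscle/side/phase entries — which puts every participant on a 0-1 scale
before pairing.  Group-level change is reported as
``delta% = 100 * (post_mean - pre_mean) / pre_mean`` on the raw means by
default.

Ambulation categories follow the community-walking speed cut-offs:
most-limited (< 0.6 m/s), least-limited (< 0.8 m/s), community walker
(>= 0.8 m/s).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "PairedSample",
    "TestResult",
    "normalize_peak",
    "normalize_session_table",
    "wilcoxon_signed_rank",
    "delta_percent",
    "classify_ambulation",
    "compare_sessions",
    "EXACT_MAX_N",
]

log = logging.getLogger(__name__)

EXACT_MAX_N = 12  # full 2^n enumeration up to here

INDICES = ("mav", "rms", "mf", "mdf")
AMBULATION_ORDER = ("MLCW", "LLCW", "CW")


@dataclass(frozen=True)
class PairedSample:
    """Matched pre/post values, one pair per participant."""

    pre: np.ndarray
    post: np.ndarray
    index_name: str = ""

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=float)
        post = np.asarray(self.post, dtype=float)
        if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
            raise ValueError("pre and post must be 1-D, same length >= 2")
        if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
            raise ValueError("paired values must be finite")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)

    @property
    def n(self) -> int:
        return self.pre.size

    @property
    def differences(self) -> np.ndarray:
        return self.post - self.pre


@dataclass(frozen=True)
class TestResult:
    """Wilcoxon signed-rank outcome."""

    w_statistic: float
    p_value: float
    z_value: float
    effect_r: float
    n_used: int        # pairs after dropping zero differences
    n_zero: int = 0    # zero-difference pairs dropped
    method: str = "exact"
    degenerate: bool = False


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of |d| and signs, zero differences already removed."""
    ranks = spstats.rankdata(np.abs(d))  # mid-ranks for ties
    return ranks, np.sign(d)


def _normal_z(w_small: float, ranks: np.ndarray) -> float:
    """z for the smaller rank sum with continuity and tie correction."""
    n = ranks.size
    mu = n * (n + 1) / 4.0
    # tie correction over groups of tied absolute differences
    _, counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    if sigma2 <= 0:
        return 0.0
    return (w_small - mu + 0.5) / np.sqrt(sigma2)


def wilcoxon_signed_rank(sample: PairedSample) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on post - pre differences.

    W is the smaller of the positive/negative rank sums.  For
    n <= 12 (after dropping zeros) the two-sided p is exact: the
    fraction of the 2^n equally likely sign assignments whose smaller
    rank sum is <= the observed W.  Larger n uses the normal
    approximation with continuity and tie corrections.  All differences
    zero gives the degenerate p = 1 result, flagged.
    """
    d = sample.differences
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        log.warning("all paired differences are zero; degenerate test")
        return TestResult(0.0, 1.0, 0.0, 0.0, 0, n_zero, "degenerate", True)
    if n < 2:
        log.warning("only %d nonzero difference; degenerate test", n)
        return TestResult(0.0, 1.0, 0.0, 0.0, n, n_zero, "degenerate", True)

    ranks, signs = _signed_ranks(d)
    w_pos = float(ranks[signs > 0].sum())
    w_neg = float(ranks[signs < 0].sum())
    w = min(w_pos, w_neg)
    total = ranks.sum()

    if n <= EXACT_MAX_N:
        # enumerate all sign assignments; mid-ranks handled natively
        signs_matrix = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        sums = signs_matrix @ ranks
        smaller = np.minimum(sums, total - sums)
        p = float(np.mean(smaller <= w + 1e-12))
        method = "exact"
    else:
        z = _normal_z(w, ranks)
        p = float(2 * spstats.norm.cdf(z))
        p = min(p, 1.0)
        method = "normal"
    z = _normal_z(w, ranks)
    # effect size over total observation count (2n paired readings)
    effect_r = float(min(abs(z) / np.sqrt(2 * n), 1.0))
    return TestResult(w, p, float(z), effect_r, n, n_zero, method)


def normalize_peak(values) -> np.ndarray:
    """Peak dynamic normalization: divide a series by its maximum.

    The output lies in [-?, 1] with max exactly 1 (for positive input,
    [0, 1]); raises on a non-positive peak.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValueError("need a finite non-empty series")
    peak = float(np.max(arr))
    if peak <= 0:
        raise ValueError("series peak must be > 0 for peak normalization")
    return arr / peak


def normalize_session_table(table: pd.DataFrame, indices=INDICES) -> pd.DataFrame:
    """Peak-normalize each index within each participant's session.

    For every participant, each index column is divided by that
    participant's peak of the index across all muscle/side/phase rows —
    the 0-1 within-session scaling applied before the paired tests.
    """
    out = table.copy()
    for p, grp in table.groupby("participant"):
        for ix in indices:
            vals = grp[ix].to_numpy(dtype=float)
            if np.all(np.isnan(vals)):
                continue
            peak = np.nanmax(vals)
            if peak <= 0:
                raise ValueError(f"participant {p}: non-positive peak for {ix}")
            out.loc[grp.index, ix] = vals / peak
    return out


def delta_percent(pre_mean: float, post_mean: float) -> float:
    """Percent change of the group mean, 100*(post - pre)/pre."""
    if pre_mean == 0:
        raise ValueError("pre_mean must be nonzero for a percent change")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def classify_ambulation(speed: float) -> str:
    """Community-ambulation category from overground speed (m/s)."""
    if speed < 0:
        raise ValueError("speed must be >= 0")
    if speed < 0.6:
        return "MLCW"
    if speed < 0.8:
        return "LLCW"
    return "CW"


def compare_sessions(
    pre_table: pd.DataFrame,
    post_table: pd.DataFrame,
    indices=INDICES,
    normalize: bool = True,
    delta_on_normalized: bool = False,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Paired pre/post comparison of every (muscle, side, phase, index).

    Both tables must be long feature tables with ``participant``,
    ``muscle``, ``side``, ``phase`` and the index columns, covering the
    same participants.  Values are peak-normalized within participant-
    session before testing (``normalize=True``); delta% is computed on
    raw group means unless ``delta_on_normalized``.

    Returns a tidy report with one row per (muscle, side, phase, index):
    n, w, z, p, r, delta_pct, significant.  ``holm=True`` applies a Holm
    step-down correction across the report's p-values (off by default).
    """
    pre_ids = set(pre_table["participant"])
    post_ids = set(post_table["participant"])
    if pre_ids != post_ids:
        raise ValueError(
            "participant mismatch between tables: "
            f"only-pre={sorted(pre_ids - post_ids)}, only-post={sorted(post_ids - pre_ids)}"
        )

    pre_n = normalize_session_table(pre_table, indices) if normalize else pre_table
    post_n = normalize_session_table(post_table, indices) if normalize else post_table

    key = ["muscle", "side", "phase"]
    rows = []
    for group_key, pre_grp in pre_n.groupby(key):
        sel = (post_n[key] == pd.Series(dict(zip(key, group_key)))).all(axis=1)
        post_grp = post_n[sel]
        pre_grp = pre_grp.sort_values("participant")
        post_grp = post_grp.sort_values("participant")
        pre_raw = pre_table.loc[pre_grp.index]
        post_raw = post_table.loc[post_grp.index]
        for ix in indices:
            a = pre_grp[ix].to_numpy(dtype=float)
            b = post_grp[ix].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 2:
                continue
            res = wilcoxon_signed_rank(PairedSample(a[ok], b[ok], ix))
            if delta_on_normalized:
                dpre, dpost = a[ok].mean(), b[ok].mean()
            else:
                dpre = pre_raw[ix].to_numpy(dtype=float)[ok].mean()
                dpost = post_raw[ix].to_numpy(dtype=float)[ok].mean()
            rows.append(
                {
                    "muscle": group_key[0], "side": group_key[1],
                    "phase": group_key[2], "index": ix,
                    "n": res.n_used, "n_zero": res.n_zero,
                    "w": res.w_statistic, "z": res.z_value,
                    "p": res.p_value, "r": res.effect_r,
                    "delta_pct": delta_percent(dpre, dpost),
                }
            )
    report = pd.DataFrame(rows).sort_values(
        ["muscle", "side", "phase", "index"]
    ).reset_index(drop=True)
    if holm and len(report):
        order = np.argsort(report["p"].to_numpy())
        m = len(report)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * report["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        report["p_holm"] = adj
        report["significant"] = report["p_holm"] <= alpha
    else:
        report["significant"] = report["p"] <= alpha
    return report
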
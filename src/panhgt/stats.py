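"""Shared statistics: Spearman correlation, Wilcoxon rank-sum, correlograms.

All tests report raw p-values (no multiplicity correction); output tables
carry an explicit ``raw_p`` naming so downstream users are not misled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationReport:
    var_a: str
    var_b: str
    method: str
    coefficient: float
    p_value: float
    n: int
    high: bool  # |R| > 0.6 and p < 0.001
    defined: bool = True


def spearman(x, y, n_perm: int = 20000, seed: int = 0) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    p-value: exact two-sided permutation test by full enumeration of all n!
    permutations for n <= 8, seeded Monte-Carlo permutation test for
    8 < n <= 20, large-sample t approximation above. Returns (nan, nan) for
    constant inputs.
    """
    from itertools import permutations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n > 20:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    elif n <= 8:
        perms = np.array(list(permutations(range(n))))
        rperm = ry[perms]  # (n!, n)
        rc = rx - rx.mean()
        pc = rperm - rperm.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.sum(rc * rc) * np.sum(pc * pc, axis=1))
        rs = (pc @ rc) / denom
        p = float(np.mean(np.abs(rs) >= abs(rho) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            rp = rng.permutation(ry)
            r = np.corrcoef(rx, rp)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return rho, float(min(1.0, p))


def _rank_sum_u(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(np.sum(ranks_a)) - n_a * (n_a + 1) / 2.0


def wilcoxon_rank_sum(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U for sample_a).

    Exact double-tail p by enumeration of all group assignments when
    n_a + n_b <= 12; normal approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    n_a, n_b = len(a), len(b)
    ranks = sps.rankdata(pooled)
    u_obs = _rank_sum_u(ranks[:n_a], n_a, n_b)
    if n_a + n_b <= 12:
        idx = np.arange(n_a + n_b)
        us = np.array([_rank_sum_u(ranks[list(c)], n_a, n_b)
                       for c in combinations(idx, n_a)])
        lo, hi = min(u_obs, n_a * n_b - u_obs), max(u_obs, n_a * n_b - u_obs)
        p = (np.sum(us <= lo + 1e-9) + np.sum(us >= hi - 1e-9)) / len(us)
        return u_obs, float(min(1.0, p))
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return u_obs, float(res.pvalue)


def correlation_matrix(feature_table: pd.DataFrame,
                       method: str = "pearson") -> list[CorrelationReport]:
    """All pairwise correlations between numeric columns.

    Pairs with |R| > 0.6 and p < 0.001 are flagged ``high``; pairs involving
    a constant column are flagged undefined. Output sorted by column names.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    if len(feature_table) < 3:
        raise ValueError("need at least 3 rows")
    cols = sorted(c for c in feature_table.columns
                  if np.issubdtype(feature_table[c].dtype, np.number))
    out = []
    for va, vb in combinations(cols, 2):
        x = feature_table[va].to_numpy(dtype=float)
        y = feature_table[vb].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            out.append(CorrelationReport(va, vb, method, float("nan"),
                                         float("nan"), len(x), False, False))
            continue
        if method == "pearson":
            r, p = sps.pearsonr(x, y)
        else:
            r, p = spearman(x, y)
        out.append(CorrelationReport(va, vb, method, float(r), float(p),
                                     len(x), bool(abs(r) > 0.6 and p < 0.001)))
    return out


def reports_to_frame(reports: list[CorrelationReport]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in reports])
    return df.rename(columns={"p_value": "raw_p"})
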
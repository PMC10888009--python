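"""Group statistics: permutation tests on AUC values, BH-FDR for nodal
families, and covariate-adjusted partial correlations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_PERMUTATIONS = 10_000
DEFAULT_Q = 0.05


@dataclass
class GroupComparisonResult:
    metric: str
    observed_diff: float
    p_perm: float
    node: str | int | None = None
    q_fdr: float | None = None

    @property
    def direction(self) -> int:
        return int(np.sign(self.observed_diff))


@dataclass
class PartialCorrelationResult:
    x_name: str
    y_name: str
    covariates: list[str]
    r: float
    p: float
    n: int
    q: float | None = None


def permutation_test(
    auc_group1: np.ndarray,
    auc_group2: np.ndarray,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    metric: str = "",
) -> GroupComparisonResult:
    """Two-tailed label-shuffling test on the group-mean difference.

    p = (1 + #{|perm diff| >= |observed diff|}) / (B + 1), so p is never 0.
    """
    x = np.asarray(auc_group1, dtype=float)
    y = np.asarray(auc_group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    if B < 100:
        raise ValueError("B must be >= 100")
    observed = x.mean() - y.mean()
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; permutation p set to 1", stacklevel=2)
        return GroupComparisonResult(metric=metric, observed_diff=0.0, p_perm=1.0)
    rng = np.random.default_rng(seed)
    n1 = x.size
    count = 0
    block = 2000  # vectorized in blocks to bound memory
    done = 0
    while done < B:
        b = min(block, B - done)
        idx = np.argsort(rng.random((b, pooled.size)), axis=1)
        perm = pooled[idx]
        diffs = perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1)
        count += int((np.abs(diffs) >= abs(observed) - 1e-15).sum())
        done += b
    p = (1 + count) / (B + 1)
    return GroupComparisonResult(metric=metric, observed_diff=float(observed), p_perm=float(p))


def fdr_bh(p_values: np.ndarray, q_level: float = DEFAULT_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values plus significance mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing q along the sorted order
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= q_level


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariate_matrix: np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: list[str] | None = None,
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after projecting out [1, covariates].

    With no covariates this reduces exactly to the plain Pearson correlation.
    The p-value uses t = r * sqrt(df / (1 - r^2)) with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariate_matrix is None:
        covariate_matrix = np.empty((n, 0))
    Z = np.asarray(covariate_matrix, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clipped = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_clipped * np.sqrt(df / (1 - r_clipped**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(
        x_name=x_name,
        y_name=y_name,
        covariates=covariate_names or [f"z{i}" for i in range(k)],
        r=r,
        p=p,
        n=n,
    )


def compare_groups(
    global_auc: dict[str, dict[str, np.ndarray]],
    nodal_auc: dict[str, dict[str, np.ndarray]],
    contrasts: list[tuple[str, str]] | None = None,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    q_level: float = DEFAULT_Q,
    node_labels: list[str] | None = None,
) -> dict[tuple[str, str], list[GroupComparisonResult]]:
    """Permutation tests for every contrast.

    ``global_auc[metric][group]`` is a vector of per-subject AUCs;
    ``nodal_auc[metric][group]`` is (subjects x nodes). Global metrics are
    tested without FDR; each nodal metric forms one BH-FDR family of nodes
    per contrast.
    """
    groups = sorted({g for by_group in global_auc.values() for g in by_group} |
                    {g for by_group in nodal_auc.values() for g in by_group})
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]

    results: dict[tuple[str, str], list[GroupComparisonResult]] = {}
    rng = np.random.default_rng(seed)
    for g1, g2 in contrasts:
        rows: list[GroupComparisonResult] = []
        for metric, by_group in global_auc.items():
            res = permutation_test(
                by_group[g1], by_group[g2], B=B, seed=int(rng.integers(2**31 - 1)), metric=metric
            )
            rows.append(res)
        for metric, by_group in nodal_auc.items():
            a, b = np.asarray(by_group[g1]), np.asarray(by_group[g2])
            family: list[GroupComparisonResult] = []
            for node in range(a.shape[1]):
                res = permutation_test(
                    a[:, node], b[:, node], B=B, seed=int(rng.integers(2**31 - 1)), metric=metric
                )
                res.node = node_labels[node] if node_labels else node
                family.append(res)
            qs, _ = fdr_bh(np.array([r.p_perm for r in family]), q_level)
            for res, qv in zip(family, qs):
                res.q_fdr = float(qv)
            rows.extend(family)
        results[(g1, g2)] = rows
    return results
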
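r"""Quantitative yardsticks for mapping quality: the normalized absolute
difference (NAD), the Dice coefficient, paired t-tests with
Benjamini-Hochberg FDR control, and experiment drivers.

NAD between a projected and a reference probabilistic map is

    NAD = sum_i |projected_i - truth_i| / sum_i truth_i,

i.e. the absolute disagreement normalized by the size of the reference
structure; lower is better.  Dice between two label supports A, B is
``2|A n B| / (|A| + |B|)``; 1 is perfect overlap.

Structure-wise metrics may carry replicates (e.g. the two hemisphere
half-shells); replicates are averaged per structure before testing, and
the FDR correction is applied across the set of pairwise approach
comparisons for a given metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateMetricError, ValidationError
from .projection import Parcellation

__all__ = [
    "nad",
    "dice",
    "paired_t",
    "bh_fdr",
    "compare_approaches",
    "convergence_experiment",
]


def _labels_of(parc) -> np.ndarray:
    return parc.labels if isinstance(parc, Parcellation) else np.asarray(parc)


def nad(projected: np.ndarray, truth: np.ndarray) -> float:
    """Normalized absolute difference between two nonnegative maps."""
    projected = np.asarray(projected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if projected.shape != truth.shape:
        raise ValidationError("maps must share a shape")
    denom = truth.sum()
    if denom <= 0:
        raise DegenerateMetricError("reference map sums to zero; NAD undefined")
    return float(np.abs(projected - truth).sum() / denom)


def dice(a, b, label: int, on_empty: str = "raise") -> float:
    """Dice overlap of one label's support in two parcellations.

    When the label is absent from both, the coefficient is undefined:
    ``on_empty='raise'`` (default) raises, ``'nan'`` returns NaN.  It is
    never silently reported as 1.
    """
    la, lb = _labels_of(a), _labels_of(b)
    if la.shape != lb.shape:
        raise ValidationError("parcellations must share a shape")
    in_a = la == label
    in_b = lb == label
    na, nb = int(in_a.sum()), int(in_b.sum())
    if na + nb == 0:
        if on_empty == "nan":
            return float("nan")
        raise DegenerateMetricError(f"label {label} absent from both parcellations")
    return 2.0 * int((in_a & in_b).sum()) / (na + nb)


def paired_t(diffs: np.ndarray) -> tuple[float, int, float]:
    """Paired-sample t statistic, degrees of freedom and two-sided p.

    ``t = mean / (sd / sqrt(n))`` with the n-1 (unbiased) standard
    deviation; p from the t distribution with ``df = n - 1``.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 2:
        raise ValidationError("paired t-test needs at least two differences")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise DegenerateMetricError("all differences identical; t statistic undefined")
    t = diffs.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: indices of rejected hypotheses.

    Sort ascending, find the largest rank k with ``p_(k) <= k*q/m``, and
    reject every hypothesis with rank <= k.
    """
    pvals = np.asarray(list(pvals), dtype=float)
    m = len(pvals)
    if m == 0:
        return np.array([], dtype=np.int64)
    if pvals.min() < 0 or pvals.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= thresholds)[0]
    if passing.size == 0:
        return np.array([], dtype=np.int64)
    k = passing[-1] + 1
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    metrics: pd.DataFrame  # one row per (structure, approach[, replicate])
    tests: pd.DataFrame  # one row per approach pair


def compare_approaches(
    values: dict[str, np.ndarray],
    metric_name: str = "metric",
    higher_is_better: bool = False,
    q: float = 0.05,
) -> ComparisonResult:
    """Per-structure metrics per approach plus all pairwise paired t-tests.

    ``values[approach]`` is an array of shape (n_structures,) or
    (n_structures, n_replicates); replicates are nan-averaged per
    structure before testing.  The BH-FDR correction runs across the
    C(A, 2) pairwise tests.  Pairs with identical metrics everywhere are
    flagged degenerate and never significant.
    """
    if len(values) < 2:
        raise ValidationError("need at least two approaches to compare")
    collapsed = {}
    rows = []
    for name, arr in values.items():
        arr = np.asarray(arr, dtype=float)
        per_structure = np.nanmean(arr, axis=1) if arr.ndim == 2 else arr
        collapsed[name] = per_structure
        for s, v in enumerate(per_structure):
            rows.append({"structure": s, "approach": name, metric_name: v})
    metrics = pd.DataFrame(rows)

    pairs = list(itertools.combinations(values.keys(), 2))
    test_rows = []
    for a, b in pairs:
        diffs = collapsed[a] - collapsed[b]
        diffs = diffs[np.isfinite(diffs)]
        degenerate = len(diffs) < 2 or diffs.std(ddof=1) == 0
        if degenerate:
            t_val, df, p = float("nan"), len(diffs) - 1, float("nan")
        else:
            t_val, df, p = paired_t(diffs)
        test_rows.append(
            {
                "metric": metric_name,
                "a": a,
                "b": b,
                "mean_a": float(np.nanmean(collapsed[a])),
                "mean_b": float(np.nanmean(collapsed[b])),
                "t": t_val,
                "df": df,
                "p": p,
                "degenerate": degenerate,
            }
        )
    tests = pd.DataFrame(test_rows)
    valid = tests.index[~tests["degenerate"]]
    rejected = bh_fdr(tests.loc[valid, "p"].to_numpy(), q=q) if len(valid) else np.array([], int)
    significant = np.zeros(len(tests), dtype=bool)
    significant[valid.to_numpy()[rejected]] = True
    tests["significant"] = significant
    better = []
    for _, row in tests.iterrows():
        if row["mean_a"] == row["mean_b"]:
            better.append("tie")
        elif (row["mean_a"] > row["mean_b"]) == higher_is_better:
            better.append(row["a"])
        else:
            better.append(row["b"])
    tests["better"] = better
    return ComparisonResult(metrics=metrics, tests=tests)


def convergence_experiment(
    run,
    sizes,
    seeds,
) -> tuple[pd.DataFrame, dict]:
    """Metric-vs-cohort-size curves over seeded replicates.

    ``run(size, seed)`` must return a dict of metric name -> value for a
    fusion mapping built from ``size`` subjects under ``seed``.  Returns
    the long table plus, per metric: the seed-averaged curve, whether it
    is non-increasing over ``sizes``, and the fraction of seeds whose
    value at the largest size is below the value at the smallest size.
    """
    sizes = list(sizes)
    seeds = list(seeds)
    if sizes != sorted(sizes):
        raise ValidationError("sizes must be ascending")
    rows = []
    for seed in seeds:
        for size in sizes:
            out = run(size, seed)
            rows.append({"size": size, "seed": seed, **out})
    table = pd.DataFrame(rows)
    summary = {}
    metric_cols = [c for c in table.columns if c not in ("size", "seed")]
    for col in metric_cols:
        curve = table.groupby("size")[col].mean().reindex(sizes)
        wide = table.pivot(index="seed", columns="size", values=col)
        improved = (wide[sizes[-1]] < wide[sizes[0]]).mean()
        summary[col] = {
            "curve": curve.to_dict(),
            "non_increasing": bool(np.all(np.diff(curve.to_numpy()) <= 1e-12)),
            "frac_seeds_improved": float(improved),
        }
    return table, summary
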
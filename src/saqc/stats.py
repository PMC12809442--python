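"""Statistical toolbox: two-sample and association tests with effect sizes.

Every test is paired with the effect-size measure conventionally reported
with it, because on large residue sets p-values alone are uninformative —
tiny differences reach significance while the practical effect is nil:

* Student's t-test + Cohen's d (pooled sd by default; Welch optional),
  interpreted as very small (<0.2), small [0.2, 0.5), medium [0.5, 0.8) and
  large (≥0.8) on |d|;
* Kruskal–Wallis + rank η² = (H − k + 1)/(n − k), clamped at 0, interpreted
  around the anchors 0.01 (small), 0.06 (medium) and 0.14 (large), with
  optional Dunn post-hoc pairwise z-tests (unadjusted by default, Holm on
  request);
* Pearson χ² + Cramér's V = sqrt(χ² / (n·(min(r, c) − 1)));
* Pearson correlation r.

The scipy implementations provide the test statistics; the effect sizes,
interpretation bins and the Dunn procedure are computed here.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclasses.dataclass
class EffectSizeResult:
    test: str
    statistic: float
    p_value: float
    effect: float
    effect_label: str
    group_summaries: Dict[str, Dict[str, float]]
    extra: Optional[dict] = None


def cohens_d_label(d: float) -> str:
    d = abs(d)
    if d < 0.2:
        return "very small"
    if d < 0.5:
        return "small"
    if d < 0.8:
        return "medium"
    return "large"


def eta2_label(eta2: float) -> str:
    if eta2 < 0.01:
        return "very small"
    if eta2 < 0.06:
        return "small"
    if eta2 < 0.14:
        return "medium"
    return "large"


def cramers_v_label(v: float) -> str:
    if v < 0.1:
        return "negligible"
    if v < 0.3:
        return "weak"
    if v < 0.5:
        return "moderate"
    return "strong"


def pearson_r_label(r: float) -> str:
    r = abs(r)
    if r < 0.3:
        return "weak"
    if r < 0.5:
        return "moderate"
    return "strong"


def _summary(sample: np.ndarray) -> Dict[str, float]:
    return {
        "n": int(len(sample)),
        "mean": float(np.mean(sample)),
        "sd": float(np.std(sample, ddof=1)) if len(sample) > 1 else 0.0,
    }


def ttest_cohens_d(
    sample_a: Sequence[float], sample_b: Sequence[float], welch: bool = False
) -> EffectSizeResult:
    """Two-sample t-test with Cohen's d (pooled-sd standardized difference)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    pooled_var = (
        ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
        / (len(a) + len(b) - 2)
    )
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    d = float((np.mean(a) - np.mean(b)) / np.sqrt(pooled_var))
    return EffectSizeResult(
        test="t_test",
        statistic=float(stat),
        p_value=float(p),
        effect=d,
        effect_label=cohens_d_label(d),
        group_summaries={"a": _summary(a), "b": _summary(b)},
    )


def kruskal_eta2(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    dunn: bool = False,
    adjust: Optional[str] = None,
) -> EffectSizeResult:
    """Kruskal–Wallis H (tie-corrected) with rank η² effect size.

    η² = (H − k + 1)/(n − k), clamped at 0; with ``dunn=True`` pairwise
    Dunn z-tests are attached under ``extra["dunn"]``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("need at least 3 groups")
    if any(len(g) < 1 for g in arrays):
        raise ValueError("every group needs n >= 1")
    n = sum(len(g) for g in arrays)
    if n < 5:
        raise ValueError("need total n >= 5")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate data: all values identical")
    h, p = sps.kruskal(*arrays)
    k = len(arrays)
    eta2 = max(0.0, float((h - k + 1) / (n - k)))
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    extra = None
    if dunn:
        extra = {"dunn": dunn_posthoc(arrays, labels=list(labels), adjust=adjust)}
    return EffectSizeResult(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        effect=eta2,
        effect_label=eta2_label(eta2),
        group_summaries={str(l): _summary(g) for l, g in zip(labels, arrays)},
        extra=extra,
    )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    adjust: Optional[str] = None,
) -> List[dict]:
    """Dunn's pairwise rank z-tests after a Kruskal–Wallis test.

    z = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − T/(12(N−1))]·(1/n_i + 1/n_j)),
    where T = Σ(t³ − t) over tied groups. Two-sided normal p-values,
    unadjusted by default; ``adjust='holm'`` applies the Holm step-down
    correction across all pairs.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    results = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(base_var * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        results.append(
            {"pair": (str(labels[i]), str(labels[j])), "z": float(z), "p_value": float(p)}
        )
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        raw = [r["p_value"] for r in results]
        _, adjusted, _, _ = multipletests(raw, method=adjust)
        for r, p_adj in zip(results, adjusted):
            r["p_adjusted"] = float(p_adj)
    return results


def chi2_cramers_v(table: Sequence[Sequence[float]]) -> EffectSizeResult:
    """Pearson χ² test of independence with Cramér's V."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    n = t.sum()
    if n <= 0:
        raise ValueError("table total must be > 0")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError(
            "zero row or column marginal; collapse empty categories before testing"
        )
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    v = float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))
    return EffectSizeResult(
        test="chi2",
        statistic=float(chi2),
        p_value=float(p),
        effect=v,
        effect_label=cramers_v_label(v),
        group_summaries={"table": {"n": int(n), "rows": t.shape[0], "cols": t.shape[1]}},
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> EffectSizeResult:
    """Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = sps.pearsonr(x, y)
    return EffectSizeResult(
        test="pearson",
        statistic=float(r),
        p_value=float(p),
        effect=float(r),
        effect_label=pearson_r_label(float(r)),
        group_summaries={"x": _summary(x), "y": _summary(y)},
    )
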
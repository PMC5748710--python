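"""Proportion–threshold (PT) curves, their AUC, and class ranking.

For one disease class with per-gene permutation p-values p_1 ... p_n, the PT
curve maps a threshold t in [0, 1] to the fraction of genes with p strictly
below t.  It is the empirical CDF of the p-values evaluated with a strict
inequality, so the curve starts at 0 for t = 0.  A class whose genes are
tightly linked to the query set has p-values piled near 0 and a curve that
shoots up immediately — by analogy with ROC analysis, the area under the PT
curve (between 0 and 1) summarizes the class-level association.

The exact area of the step curve has a closed form:

    AUC = ∫₀¹ #{p_i < t}/n dt = mean_i(1 − p_i)

which is what :func:`auc` computes; :func:`auc_trapezoid` is a grid-sampled
variant kept for plotting, which agrees with the exact value to half the grid
step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .scoring import GeneAssociationRecord

__all__ = [
    "PTCurve",
    "ClassAssociationResult",
    "default_threshold_grid",
    "pt_curve",
    "auc",
    "auc_trapezoid",
    "rank_classes",
    "plot_pt_curves",
]


@dataclass(frozen=True)
class PTCurve:
    thresholds: tuple[float, ...]
    proportions: tuple[float, ...]
    n_genes: int


@dataclass(frozen=True)
class ClassAssociationResult:
    class_name: str
    records: tuple[GeneAssociationRecord, ...]
    curve: PTCurve
    auc: float
    rank: int | None = None
    n_genes_input: int | None = None

    @property
    def p_values(self) -> tuple[float, ...]:
        return tuple(rec.p_value for rec in self.records)


def default_threshold_grid(n_permutations: int) -> np.ndarray:
    """The natural grid {0, 1/n, 2/n, ..., 1}: p-values only exist on it."""
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    return np.linspace(0.0, 1.0, n_permutations + 1)


def _check_p_values(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("p_values must be non-empty")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValidationError("p-values must lie in [0, 1]")
    return p


def pt_curve(
    p_values: Sequence[float], thresholds: Sequence[float] | None = None, *,
    n_permutations: int | None = None,
) -> PTCurve:
    """Proportion of p-values strictly below each threshold.

    Pass explicit ``thresholds`` (sorted, within [0, 1]) or ``n_permutations``
    to use the default permutation grid.
    """
    p = _check_p_values(p_values)
    if thresholds is None:
        if n_permutations is None:
            raise ValidationError("need thresholds or n_permutations")
        t = default_threshold_grid(n_permutations)
    else:
        t = np.asarray(thresholds, dtype=float)
        if t.size == 0 or np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] > 1:
            raise ValidationError("thresholds must be sorted within [0, 1]")
    p_sorted = np.sort(p)
    counts = np.searchsorted(p_sorted, t, side="left")  # strict: #{p < t}
    proportions = counts / p.size
    return PTCurve(
        thresholds=tuple(float(x) for x in t),
        proportions=tuple(float(x) for x in proportions),
        n_genes=int(p.size),
    )


def auc(p_values: Sequence[float]) -> float:
    """Exact area under the PT step curve on [0, 1]: mean over genes of 1 − p."""
    p = _check_p_values(p_values)
    # summing in sorted order makes the value independent of input order
    return float(np.mean(1.0 - np.sort(p)))


def auc_trapezoid(p_values: Sequence[float], step: float = 0.001) -> float:
    """Trapezoid-rule AUC on a uniform grid; agrees with :func:`auc` to step/2."""
    if not 0.0 < step <= 1.0:
        raise ValidationError("grid step must be in (0, 1]")
    n_intervals = int(round(1.0 / step))
    grid = np.linspace(0.0, 1.0, n_intervals + 1)
    curve = pt_curve(p_values, grid)
    return float(np.trapezoid(curve.proportions, curve.thresholds))


def rank_classes(
    results: Sequence[ClassAssociationResult],
) -> list[ClassAssociationResult]:
    """Sort by AUC descending (ties broken by class name) and assign ranks 1..K."""
    names = [r.class_name for r in results]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate class names in results")
    def sort_key(r: ClassAssociationResult):
        # empty (NaN-AUC) classes sort last
        value = r.auc if r.auc == r.auc else float("-inf")
        return (-value, r.class_name)

    ordered = sorted(results, key=sort_key)
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def plot_pt_curves(results: Sequence[ClassAssociationResult], path) -> None:
    """Render all PT curves on one axis (matplotlib, Agg-safe)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for res in results:
        ax.step(
            res.curve.thresholds, res.curve.proportions, where="post",
            label=f"{res.class_name} (AUC={res.auc:.3f})", linewidth=1,
        )
    ax.set_xlabel("p-value threshold")
    ax.set_ylabel("proportion of genes with p < threshold")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    if len(results) <= 12:
        ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
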
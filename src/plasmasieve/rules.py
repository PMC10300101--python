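"""Rule-based baseline: exhaustive grid of coverage/VAF/quality cutoffs.

The grid is the full Cartesian product of 9 unique-molecule coverage
minima, 11 VAF minima and 10 PHRED quality minima — 990 candidate filters —
selected by mean held-out F1 under stratified cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .metrics import f1_from_pr_rc
from .variant_io import VariantCall

COVERAGE_GRID = (10, 20, 50, 75, 100, 150, 200, 500, 1000)
VAF_GRID = (0.001, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05, 0.075, 0.10, 0.15, 0.20)
QUALITY_GRID = (1, 2, 5, 10, 15, 20, 25, 30, 40, 50)


@dataclass(frozen=True)
class FilterRule:
    min_coverage: int   # unique molecules
    min_vaf: float      # fraction
    min_quality: float  # PHRED

    def keeps(self, call: VariantCall) -> bool:
        return (
            call.umi_depth >= self.min_coverage
            and call.vaf >= self.min_vaf
            and call.qual >= self.min_quality
        )


def generate_grid() -> list[FilterRule]:
    """All 990 cutoff combinations, coverage-major then VAF then quality."""
    return [
        FilterRule(c, v, q)
        for c, v, q in product(COVERAGE_GRID, VAF_GRID, QUALITY_GRID)
    ]


def apply_rule(rule: FilterRule, calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Keep calls meeting all three inclusive minima."""
    return [c for c in calls if rule.keeps(c)]


def _call_arrays(calls: Sequence[VariantCall]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cov = np.array([c.umi_depth for c in calls], dtype=float)
    vaf = np.array([c.vaf for c in calls], dtype=float)
    qual = np.array([c.qual for c in calls], dtype=float)
    return cov, vaf, qual


def _rule_f1(keep: np.ndarray, labels: np.ndarray) -> float:
    tp = int(np.sum(keep & labels))
    fp = int(np.sum(keep & ~labels))
    fn = int(np.sum(~keep & labels))
    pr = tp / (tp + fp) if tp + fp else 0.0
    rc = tp / (tp + fn) if tp + fn else 0.0
    return f1_from_pr_rc(pr, rc)


def select_rule_cv(
    labeled: Sequence[tuple[VariantCall, bool]],
    folds: int = 4,
    seed: int = 0,
) -> FilterRule:
    """Pick the rule maximizing mean held-out F1 over stratified folds.

    Pools all labeled calls (not patients) into folds; ties break toward
    the earlier rule in grid order so selection is deterministic.
    """
    if len(labeled) < folds:
        raise ValueError(f"need at least {folds} labeled calls")
    calls = [c for c, _ in labeled]
    labels = np.array([bool(y) for _, y in labeled])
    if labels.all() or not labels.any():
        raise ValueError("need both classes to select a rule")

    cov, vaf, qual = _call_arrays(calls)
    grid = generate_grid()
    # vectorized keep matrix: rules x calls
    cov_t = np.array([r.min_coverage for r in grid])[:, None]
    vaf_t = np.array([r.min_vaf for r in grid])[:, None]
    qual_t = np.array([r.min_quality for r in grid])[:, None]
    keep = (cov[None, :] >= cov_t) & (vaf[None, :] >= vaf_t) & (qual[None, :] >= qual_t)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_f1 = np.zeros((len(grid), folds))
    for fold_idx, (_, test_idx) in enumerate(skf.split(cov.reshape(-1, 1), labels)):
        y = labels[test_idx]
        k = keep[:, test_idx]
        tp = (k & y).sum(axis=1)
        fp = (k & ~y).sum(axis=1)
        fn = (~k & y).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pr = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
            rc = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
            f1 = np.where(pr + rc > 0, 2 * pr * rc / np.maximum(pr + rc, 1e-300), 0.0)
        fold_f1[:, fold_idx] = f1
    mean_f1 = fold_f1.mean(axis=1)
    best = int(np.argmax(mean_f1))  # argmax returns the first maximum: grid-order tie-break
    return grid[best]
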
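"""Two-sample permutation tests on the difference of group medians.

The observed statistic is median(A) - median(B). Under the null that
group labels are exchangeable, the labels are randomly reassigned
(preserving group sizes) and the two-sided p-value is the fraction of
regroupings whose absolute statistic reaches the observed one.

When the number of distinct regroupings C(n_A + n_B, n_A) does not
exceed the permutation budget, all of them are enumerated and the
p-value is exact. Otherwise regroupings are sampled and the add-one
estimator (b + 1) / (n + 1) is used, which never returns zero and is
an unbiased-conservative Monte-Carlo p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PermutationResult",
    "KingdomPrevalenceRecord",
    "permutation_test_median_diff",
    "compare_groups",
    "kingdom_prevalence_test",
]

# relative tolerance when comparing permuted statistics to the observed one,
# so that float round-off in medians cannot flip a tie
_REL_EPS = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    statistic_observed: float
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool
    group_summaries: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class KingdomPrevalenceRecord:
    """A sugar's prevalence in the study genus and across the kingdom."""

    sugar_id: str
    kingdom_prevalence: float
    genus_prevalence: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.kingdom_prevalence <= 1.0):
            raise ValueError(
                f"{self.sugar_id}: kingdom prevalence outside [0, 1]"
            )


def permutation_test_median_diff(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test of median(A) - median(B).

    Switches to exhaustive enumeration of all C(n, n_A) regroupings when
    that count fits within ``n_permutations``; otherwise samples with the
    generator seeded by ``seed`` and applies the add-one estimator.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    observed = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    threshold = abs(observed) - _REL_EPS * max(1.0, abs(observed))

    n_exact = comb(n, na)
    if n_exact <= n_permutations:
        hits = 0
        idx_all = np.arange(n)
        for combo in combinations(range(n), na):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            stat = np.median(pooled[sel]) - np.median(pooled[~sel])
            if abs(stat) >= threshold:
                hits += 1
        return PermutationResult(
            statistic_observed=observed,
            p_value=hits / n_exact,
            n_permutations=n_exact,
            seed=seed,
            exact=True,
        )

    rng = np.random.default_rng(seed)
    hits = 0
    # vectorized in blocks to bound memory at ~ block x n doubles
    block = max(1, min(n_permutations, 200_000 // max(n, 1)))
    remaining = n_permutations
    while remaining > 0:
        m = min(block, remaining)
        order = np.argsort(rng.random((m, n)), axis=1)  # m random permutations
        permuted = pooled[order]
        stats = np.median(permuted[:, :na], axis=1) - np.median(
            permuted[:, na:], axis=1
        )
        hits += int(np.count_nonzero(np.abs(stats) >= threshold))
        remaining -= m
    return PermutationResult(
        statistic_observed=observed,
        p_value=(hits + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
        exact=False,
    )


def _summary(vals: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"n": int(vals.size), "median": float(med),
            "q1": float(q1), "q3": float(q3)}


def compare_groups(
    values: Mapping[str, float],
    labels: Mapping[str, str],
    n_permutations: int = 100_000,
    seed: int | None = None,
    group_order: tuple[str, str] | None = None,
) -> PermutationResult:
    """Split values by label and test the median difference.

    ``group_order`` fixes which label is group A (statistic = A - B);
    by default labels are taken in sorted order. Every value id must be
    labeled; ids whose label is outside the two compared groups are
    ignored. Group medians and IQRs are recorded on the result.
    """
    grouped: dict[str, list[float]] = {}
    for key, val in values.items():
        if key not in labels:
            raise KeyError(f"no group label for id {key!r}")
        grouped.setdefault(labels[key], []).append(float(val))
    if group_order is None:
        present = sorted(grouped)
        if len(present) < 2:
            raise ValueError(f"need two groups, got {present}")
        group_order = (present[0], present[1])
    name_a, name_b = group_order
    for name in group_order:
        if len(grouped.get(name, [])) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
    a = np.asarray(grouped[name_a], dtype=float)
    b = np.asarray(grouped[name_b], dtype=float)
    res = permutation_test_median_diff(a, b, n_permutations=n_permutations, seed=seed)
    return PermutationResult(
        statistic_observed=res.statistic_observed,
        p_value=res.p_value,
        n_permutations=res.n_permutations,
        seed=res.seed,
        exact=res.exact,
        group_summaries={name_a: _summary(a), name_b: _summary(b)},
    )


def kingdom_prevalence_test(
    records: Sequence[KingdomPrevalenceRecord],
    labels: Mapping[str, str],
    n_permutations: int = 100_000,
    seed: int | None = None,
    group_order: tuple[str, str] | None = None,
) -> PermutationResult:
    """Core-vs-accessory comparison of kingdom-wide sugar prevalence.

    Every labeled sugar (label in the two compared groups) must carry a
    kingdom-prevalence record; missing sugars are reported together.
    """
    by_sugar = {r.sugar_id: r.kingdom_prevalence for r in records}
    wanted = set(group_order) if group_order else None
    relevant = [
        s for s, lab in labels.items() if wanted is None or lab in wanted
    ]
    missing = sorted(s for s in relevant if s not in by_sugar)
    if missing:
        raise KeyError(f"sugars without kingdom-prevalence records: {missing}")
    values = {s: by_sugar[s] for s in relevant}
    return compare_groups(
        values, labels, n_permutations=n_permutations, seed=seed,
        group_order=group_order,
    )
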
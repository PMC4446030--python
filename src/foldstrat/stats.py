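"""Multi-level nonparametric demarcation statistics.

Layer demarcation within an age group is tested with three complementary
Wilcoxon signed-rank comparison bars over the animals' subunit profiles:

* bar 1 compares every subunit with its depth neighbour,
* bar 2 compares disjoint blocks of two subunits (subunit 1 is isolated in
  its own block when its values are significantly higher than subunit 2's,
  so that the narrow subepithelial band is not averaged away),
* bar 3 compares the hypothetical zones.

A subunit boundary at which every bar that tests it is significant is a
*distinct* demarcation; when the bars disagree the transition is
*continuous*; when nothing is significant there is no demarcation.
Between age groups, zone values are compared with the Kruskal-Wallis test.
All tests are two-sided at alpha = 0.05 on raw p-values — no multiplicity
adjustment is applied, accepting comparison-wise error control.

The signed-rank p-value is exact (full sign-flip enumeration via dynamic
programming, midranks for ties, zero differences dropped) up to n = 25
pairs and a tie-corrected normal approximation beyond.  With n = 6 pairs
the smallest attainable two-sided exact p is 2/64 = 0.03125, so
significance at 0.05 requires all six animals to agree in direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stratigraphy import ZoneMap

ALPHA = 0.05
EXACT_LIMIT = 25


@dataclass
class ComparisonResult:
    """One two-sided comparison; ``boundary`` is the subunit boundary the
    comparison tests (boundary i separates subunits i and i+1), or None
    for between-group tests."""

    left: str
    right: str
    statistic: float
    p_value: float
    n: int
    alpha: float = ALPHA
    untestable: bool = False
    boundary: int | None = None

    @property
    def significant(self) -> bool:
        return (not self.untestable) and self.p_value <= self.alpha


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic by enumerating all
    2^n sign assignments (dynamic programming over doubled ranks)."""
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[:total + 1 - d]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[:w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired(values_a, values_b, *, alpha: float = ALPHA,
                    method: str = "auto", left: str = "a",
                    right: str = "b",
                    boundary: int | None = None) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-animal values.

    Pairs with a missing (NaN) member are dropped, then zero differences
    are dropped before midranking the absolute differences.  ``method``
    may be ``exact``, ``approx`` or ``auto`` (exact up to 25 informative
    pairs).  The statistic reported is W+, the sum of ranks of positive
    differences.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    if d.size == 0:
        return ComparisonResult(left, right, np.nan, 1.0, 0, alpha,
                                untestable=True, boundary=boundary)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        # all pairs tied: no evidence of a difference
        return ComparisonResult(left, right, 0.0, 1.0, 0, alpha,
                                untestable=True, boundary=boundary)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if method == "exact" or (method == "auto" and n <= EXACT_LIMIT):
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        # tie-corrected variance of W+
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return ComparisonResult(left, right, w_plus, p, n, alpha,
                            boundary=boundary)


def _col(profiles: pd.DataFrame, subunits) -> np.ndarray:
    """Per-animal mean over a set of subunit columns (NaN-aware)."""
    sub = profiles[list(subunits)]
    return sub.mean(axis=1, skipna=True).to_numpy()


def bar1(profiles: pd.DataFrame, *, alpha: float = ALPHA
         ) -> list[ComparisonResult]:
    """Neighbour comparisons: subunit i versus i+1 for every boundary."""
    n = profiles.shape[1]
    results = []
    for i in range(1, n):
        results.append(wilcoxon_paired(
            _col(profiles, [i]), _col(profiles, [i + 1]), alpha=alpha,
            left=str(i), right=str(i + 1), boundary=i))
    return results


def bar2_blocks(n_subunits: int, isolate_first: bool) -> list[tuple[int, ...]]:
    """Disjoint 2-subunit blocks; the final block may hold one subunit.

    With ``isolate_first`` the subepithelial subunit 1 forms its own block
    and pairing starts at subunit 2.
    """
    start = 2 if isolate_first else 1
    blocks: list[tuple[int, ...]] = [(1,)] if isolate_first else []
    i = start
    while i <= n_subunits:
        blocks.append(tuple(range(i, min(i + 2, n_subunits + 1))))
        i += 2
    return blocks


def bar2(profiles: pd.DataFrame, *, alpha: float = ALPHA,
         bar1_results: list[ComparisonResult] | None = None
         ) -> list[ComparisonResult]:
    """Comparisons of consecutive 2-subunit blocks.

    Subunit 1 is not grouped with subunit 2 when the bar-1 test of 1
    versus 2 is significant with subunit 1 higher (the subepithelial band
    then stands alone).  That condition is read off the bar-1 result
    rather than re-tested, keeping a single evidence source.
    """
    n = profiles.shape[1]
    if bar1_results is None:
        first = wilcoxon_paired(_col(profiles, [1]), _col(profiles, [2]),
                                alpha=alpha, left="1", right="2", boundary=1)
    else:
        first = next(r for r in bar1_results if r.boundary == 1)
    d = (profiles[1] - profiles[2]).dropna()
    isolate = bool(first.significant and d.size and d.mean() > 0)
    blocks = bar2_blocks(n, isolate)
    results = []
    for left_blk, right_blk in zip(blocks, blocks[1:]):
        label_l = "-".join(map(str, (left_blk[0], left_blk[-1]))) \
            if len(left_blk) > 1 else str(left_blk[0])
        label_r = "-".join(map(str, (right_blk[0], right_blk[-1]))) \
            if len(right_blk) > 1 else str(right_blk[0])
        results.append(wilcoxon_paired(
            _col(profiles, left_blk), _col(profiles, right_blk),
            alpha=alpha, left=label_l, right=label_r,
            boundary=left_blk[-1]))
    return results


def bar3(profiles: pd.DataFrame, zone_map: ZoneMap, *,
         alpha: float = ALPHA) -> list[ComparisonResult]:
    """Comparisons of consecutive hypothetical zones (per-animal zone
    means, paired by animal)."""
    zones = sorted(zone_map.members)
    results = []
    for za, zb in zip(zones, zones[1:]):
        results.append(wilcoxon_paired(
            _col(profiles, zone_map.members[za]),
            _col(profiles, zone_map.members[zb]),
            alpha=alpha, left=f"Z{za}", right=f"Z{zb}",
            boundary=zone_map.members[za][-1]))
    return results


@dataclass
class DemarcationReport:
    """Per-boundary significance pattern and classification.

    ``bars`` maps boundary index -> {bar name -> significant or None if
    the bar has no comparison at that boundary}; ``classification`` maps
    boundary index -> 'distinct' (every testing bar significant),
    'continuous' (testing bars disagree) or 'none'.
    """

    n_subunits: int
    bars: dict[int, dict[str, bool | None]] = field(default_factory=dict)
    classification: dict[int, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(1, self.n_subunits):
            row = {"boundary": b}
            row.update(self.bars.get(b, {}))
            row["classification"] = self.classification.get(b, "none")
            rows.append(row)
        return pd.DataFrame(rows)


def summarise_bars(bar1_results: list[ComparisonResult],
                   bar2_results: list[ComparisonResult],
                   bar3_results: list[ComparisonResult],
                   n_subunits: int) -> DemarcationReport:
    """Combine the three bars into the per-boundary summary (bar 4)."""
    report = DemarcationReport(n_subunits=n_subunits)
    by_bar = {"bar1": bar1_results, "bar2": bar2_results,
              "bar3": bar3_results}
    for b in range(1, n_subunits):
        flags: dict[str, bool | None] = {}
        for name, results in by_bar.items():
            hit = [r for r in results if r.boundary == b]
            flags[name] = hit[0].significant if hit else None
        tested = [v for v in flags.values() if v is not None]
        if tested and all(tested):
            cls = "distinct"
        elif any(tested):
            cls = "continuous"
        else:
            cls = "none"
        report.bars[b] = flags
        report.classification[b] = cls
    return report


def kruskal_wallis_zone(values_young, values_old, *,
                        alpha: float = ALPHA,
                        label: str = "zone") -> ComparisonResult:
    """Kruskal-Wallis test between the two age groups' zone values.

    With two groups the tie-corrected H statistic is referred to a
    chi-square distribution with one degree of freedom.  Degenerate
    all-tied data yields H = 0, p = 1.
    """
    young = np.asarray(values_young, dtype=float)
    old = np.asarray(values_old, dtype=float)
    young = young[~np.isnan(young)]
    old = old[~np.isnan(old)]
    if young.size < 2 or old.size < 2:
        return ComparisonResult("young", "old", np.nan, 1.0,
                                young.size + old.size, alpha,
                                untestable=True)
    pooled = np.concatenate([young, old])
    if np.all(pooled == pooled[0]):
        return ComparisonResult("young", "old", 0.0, 1.0, pooled.size,
                                alpha)
    h, p = sps.kruskal(young, old)
    return ComparisonResult("young", "old", float(h), float(p),
                            pooled.size, alpha)


def ks_normality(residuals, *, alpha: float = ALPHA) -> ComparisonResult:
    """One-sample Kolmogorov-Smirnov test against a normal with the sample
    mean and standard deviation.

    Reported to justify the use of nonparametric tests; a significant
    result rejects normality.
    """
    x = np.asarray(residuals, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3 or np.std(x, ddof=1) == 0:
        return ComparisonResult("sample", "normal", np.nan, 1.0, x.size,
                                alpha, untestable=True)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return ComparisonResult("sample", "normal", float(stat), float(p),
                            x.size, alpha)


def results_frame(results: list[ComparisonResult],
                  comparison: str = "") -> pd.DataFrame:
    """Tidy table of comparison results (raw p-values, no adjustment)."""
    return pd.DataFrame([{
        "comparison": comparison,
        "left": r.left, "right": r.right, "boundary": r.boundary,
        "statistic": r.statistic, "p_value": r.p_value, "n": r.n,
        "significant": r.significant, "untestable": r.untestable,
    } for r in results])
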
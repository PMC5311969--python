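"""Statistical layer: Spearman rank correlation with Bonferroni
correction, Mann-Whitney U with exact small-sample enumeration, and
Fisher's exact test for r x c tables by full enumeration.

These are the nonparametric tests used on honey-composition data, where
proportions are far from normal: pairwise hive concordance (do colonies
use the same plants in similar proportions?), month comparisons of
richness/diversity at tiny N, and the association between forage class
(major/minor) and plant status (native/both/horticulture).

Spearman's rho and its t-approximation p come from scipy (Pearson on
average ranks); the exact Mann-Whitney p enumerates all C(n1+n2, n1)
group labelings (ties handled through average ranks), and the Fisher
test enumerates every table with the observed margins, summing the
multivariate hypergeometric probabilities of tables no more probable
than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import comb, lgamma, sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .composition import SampleComposition
from .formats_io import RegionalChecklist
from .taxonomic_assignment import _constituent_genera

EXACT_MWU_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 8
FISHER_MAX_N = 500

STATUS_ORDER = ("native", "both", "horticulture")


@dataclass
class StatResult:
    name: str
    statistic: float
    p_value: float
    n: int
    method: str  # exact | approximate
    p_adjusted: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"{self.name}: p={self.p_value} outside (0, 1]")


def spearman_rho(
    x: Sequence[float], y: Sequence[float], name: str = "spearman"
) -> StatResult:
    """Spearman's rho with average-rank ties.

    rho is the Pearson correlation of the rank vectors. The p-value uses
    the t approximation for n > 8 and exact permutation enumeration for
    n <= 8 (all n! rank permutations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in a rank vector")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        # permutation distribution of rho under independence
        rx_c = rx - rx.mean()
        denom = sqrt(float(rx_c @ rx_c) * float((ry - ry.mean()) @ (ry - ry.mean())))
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(ry):
            r = float(rx_c @ (np.asarray(perm) - ry.mean())) / denom
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        t = rho * sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        p = min(1.0, max(p, np.nextafter(0, 1)))
        method = "approximate"
    return StatResult(name, rho, p, n=n, method=method)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: each p times the family size, capped at 1."""
    if any(not 0.0 < p <= 1.0 for p in p_values):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p_values)
    return [min(1.0, m * p) for p in p_values]


def mann_whitney_u(
    group1: Sequence[float],
    group2: Sequence[float],
    name: str = "mann-whitney",
) -> StatResult:
    """Mann-Whitney U with exact enumeration at small n.

    Reports U = min(U1, U2) as the statistic and the tie-corrected
    normal-approximation Z (no continuity correction) alongside. The
    exact two-sided p enumerates all C(n1+n2, n1) labelings when
    n1 + n2 <= 12 (doubled smaller tail, capped at 1); beyond that the
    normal approximation provides the p-value.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    z = 0.0 if var <= 0 else (u - mu) / sqrt(var)
    p_normal = 1.0 if var <= 0 else float(2.0 * sps.norm.sf(abs(z)))
    p_normal = min(1.0, max(p_normal, np.nextafter(0, 1)))

    if n <= EXACT_MWU_MAX_N:
        total = comb(n, n1)
        le = ge = 0
        for idx in combinations(range(n), n1):
            r1_perm = float(ranks[list(idx)].sum())
            u1_perm = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1_perm
            if u1_perm <= u1 + 1e-9:
                le += 1
            if u1_perm >= u1 - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        method = "exact"
    else:
        p = p_normal
        method = "approximate"
    return StatResult(
        name,
        u,
        p,
        n=min(n1, n2),
        method=method,
        extras={"z": z, "p_normal": p_normal, "u1": u1, "u2": u2},
    )


def _log_table_probability(
    table: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray, total: int
) -> float:
    lp = (
        sum(lgamma(r + 1) for r in row_sums)
        + sum(lgamma(c + 1) for c in col_sums)
        - lgamma(total + 1)
        - sum(lgamma(v + 1) for v in table.ravel())
    )
    return lp


def _enumerate_tables(row_sums, col_rem, row_idx, current, out):
    """Recursively yield all tables with the fixed margins."""
    r = len(row_sums)
    if row_idx == r - 1:
        out.append(current + [list(col_rem)])
        return
    target = row_sums[row_idx]

    def fill(col, remaining, row):
        c = len(col_rem)
        if col == c - 1:
            if remaining <= col_rem[c - 1]:
                _enumerate_tables(
                    row_sums,
                    [
                        col_rem[j] - (row + [remaining])[j]
                        for j in range(c)
                    ],
                    row_idx + 1,
                    current + [row + [remaining]],
                    out,
                )
            return
        for v in range(min(remaining, col_rem[col]) + 1):
            fill(col + 1, remaining - v, row + [v])

    fill(0, target, [])


def fisher_exact(table: Sequence[Sequence[int]], name: str = "fisher") -> StatResult:
    """Fisher's exact test for an r x c contingency table.

    Two-sided p by the probability rule: the sum of multivariate
    hypergeometric probabilities (margins fixed) of every table whose
    probability does not exceed the observed table's (within a 1e-7
    relative tolerance, as exact-test implementations conventionally
    allow). Tables up to n = 500 are enumerated; larger tables are
    rejected with a pointer to simulation-based alternatives.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(obs.sum())
    if total > FISHER_MAX_N:
        raise ValueError(
            f"table total {total} exceeds the enumeration bound "
            f"{FISHER_MAX_N}; use a simulation-based test instead"
        )
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if total == 0:
        return StatResult(name, 0.0, 1.0, n=0, method="exact")
    lp_obs = _log_table_probability(obs, row_sums, col_sums, total)
    tables: list[list[list[int]]] = []
    _enumerate_tables(list(row_sums), list(col_sums), 0, [], tables)
    p = 0.0
    for t in tables:
        arr = np.asarray(t, dtype=np.int64)
        lp = _log_table_probability(arr, row_sums, col_sums, total)
        if lp <= lp_obs + 1e-7:
            p += float(np.exp(lp))
    p = min(1.0, p)
    return StatResult(name, float(np.exp(lp_obs)), p, n=total, method="exact")


def hive_concordance(
    compositions: Sequence[SampleComposition],
    month: str = "",
) -> list[StatResult]:
    """Pairwise Spearman correlations of hive compositions.

    The common taxon list is the union across hives with absent taxa as
    zero; results carry Bonferroni-adjusted p-values over all pairs
    returned.
    """
    if len(compositions) < 2:
        raise ValueError("need at least two hives")
    taxa = sorted({t for c in compositions for t in c.proportions})
    results = []
    for c1, c2 in combinations(compositions, 2):
        x = [c1.proportions.get(t, 0.0) for t in taxa]
        y = [c2.proportions.get(t, 0.0) for t in taxa]
        label = f"spearman_{c1.hive_id}_vs_{c2.hive_id}"
        if month:
            label += f"_{month}"
        results.append(spearman_rho(x, y, name=label))
    adjusted = bonferroni([r.p_value for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj
    return results


def _status_of(label: str, checklist: RegionalChecklist) -> str | None:
    row = checklist.lookup(label)
    if row is not None:
        return row.status
    for genus in _constituent_genera(label):
        row = checklist.lookup(genus)
        if row is not None:
            return row.status
    return None


def status_association(
    checklist: RegionalChecklist, major_minor: Mapping[str, str]
) -> StatResult:
    """Fisher's exact test of plant status x forage class.

    Builds the (native | both | horticulture) x (major | minor)
    contingency table over classified honey taxa and tests whether major
    forage leans toward native plants.
    """
    counts = {(s, c): 0 for s in STATUS_ORDER for c in ("major", "minor")}
    n_classified = 0
    for label, cls in major_minor.items():
        if cls not in ("major", "minor"):
            raise ValueError(f"{label!r}: class must be major or minor, got {cls!r}")
        status = _status_of(label, checklist)
        if status is None:
            continue
        counts[(status, cls)] += 1
        n_classified += 1
    if n_classified == 0:
        raise ValueError("no classified taxa found on the checklist")
    table = [
        [counts[(s, "major")], counts[(s, "minor")]] for s in STATUS_ORDER
    ]
    result = fisher_exact(table, name="status_x_forage_class")
    result.extras["table"] = table
    return result


def stats_report(results: Iterable[StatResult]):
    """Stats results as a tidy table (test, statistic, p, p_adjusted, n)."""
    import pandas as pd

    rows = [
        (
            r.name,
            r.statistic,
            r.p_value,
            r.p_adjusted if r.p_adjusted is not None else "",
            r.n,
            r.method,
            r.extras.get("z", ""),
        )
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["test", "statistic", "p", "p_adjusted", "n", "method", "z"]
    )
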
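"""Statistical procedures for the pipeline, implemented from first principles.

Every test the pipeline invokes lives here: Fisher's exact test on 2x2
tables, the one-sample t test, Mann-Whitney U (exact and tie-corrected
normal approximation), Kruskal-Wallis with tie correction, Dunn's post hoc
z comparisons, one-way ANOVA with Bonferroni pairwise t tests, and the
four-point ordinal severity encoding used for eye phenotypes.

Only distribution tail functions (t, chi-squared, standard normal) are
delegated to :mod:`scipy.stats`; the test statistics, the exact-test
enumeration and the tie corrections are computed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _dist

Tail = Literal["two_sided", "greater", "less"]

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "SeverityScore",
    "SEVERITY_LABELS",
    "fisher_exact",
    "one_sample_t",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_posthoc",
    "anova_bonferroni",
    "encode_severity",
    "midranks",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single statistical comparison.

    Attributes
    ----------
    method : str
        Identifier of the procedure (``"fisher_exact"``, ``"one_sample_t"`` ...).
    statistic : float
        The test statistic on its natural scale (odds-ratio-free: U, t, H, F, z).
    p_value : float
        Always in [0, 1].
    tail : str
        ``two_sided``, ``greater`` or ``less``.
    n : mapping
        Sample-size record, e.g. ``{"n1": 310, "n2": 396}``.
    table : tuple or None
        The 2x2 table ``(a, b, c, d)`` for exact tests.
    degenerate : bool
        True when a contract fallback (zero margin, zero variance) fixed
        the p-value rather than the sampling distribution.
    """

    method: str
    statistic: float
    p_value: float
    tail: Tail
    n: Mapping[str, int] = field(default_factory=dict)
    table: Optional[Tuple[int, int, int, int]] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "tail": self.tail,
            "n": dict(self.n),
            "degenerate": self.degenerate,
        }
        if self.table is not None:
            d["table"] = list(self.table)
        return d


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; row 1 = group 1, column 1 = event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"table cell {name} must be a non-negative integer, got {v!r}")

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def row2(self) -> int:
        return self.c + self.d

    @property
    def col1(self) -> int:
        return self.a + self.c

    @property
    def col2(self) -> int:
        return self.b + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(a: int, r1: int, c1: int, n: int) -> float:
    # P(A = a | margins) = C(r1, a) C(n - r1, c1 - a) / C(n, c1)
    lg = math.lgamma
    return (
        lg(r1 + 1) - lg(a + 1) - lg(r1 - a + 1)
        + lg(n - r1 + 1) - lg(c1 - a + 1) - lg(n - r1 - (c1 - a) + 1)
        - (lg(n + 1) - lg(c1 + 1) - lg(n - c1 + 1))
    )


def fisher_exact(table: ContingencyTable2x2 | Sequence[Sequence[int]], tail: Tail = "two_sided") -> TestResult:
    """Fisher's exact test conditioned on both margins.

    ``greater`` is the upper tail on cell ``a`` (enrichment of the event in
    group 1); ``two_sided`` sums the probabilities of every table in the
    conditional support whose probability does not exceed the observed
    table's (with a small relative slack for floating-point ties).

    A zero row or column margin leaves the table unconstrained: p = 1 with
    the degenerate flag set.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    t = table
    n_rec = {"row1": t.row1, "row2": t.row2}
    if min(t.row1, t.row2, t.col1, t.col2) == 0:
        return TestResult("fisher_exact", float("nan"), 1.0, tail, n_rec,
                          table=t.as_tuple(), degenerate=True)

    lo = max(0, t.col1 - t.row2)
    hi = min(t.row1, t.col1)
    logp = np.array([_log_hypergeom_pmf(a, t.row1, t.col1, t.total) for a in range(lo, hi + 1)])
    pmf = np.exp(logp)
    idx = t.a - lo
    obs_p = pmf[idx]

    if tail == "greater":
        p = float(pmf[idx:].sum())
    elif tail == "less":
        p = float(pmf[: idx + 1].sum())
    elif tail == "two_sided":
        p = float(pmf[pmf <= obs_p * (1.0 + 1e-7)].sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    # odds ratio as the descriptive statistic (conditional-sample estimate)
    if t.b * t.c == 0:
        oratio = math.inf if t.a * t.d > 0 else float("nan")
    else:
        oratio = (t.a * t.d) / (t.b * t.c)
    return TestResult("fisher_exact", oratio, min(p, 1.0), tail, n_rec, table=t.as_tuple())


# ---------------------------------------------------------------------------
# One-sample t
# ---------------------------------------------------------------------------

def one_sample_t(xs: Sequence[float], mu0: float, tail: Tail = "two_sided") -> TestResult:
    """One-sample t test of ``mean(xs)`` against ``mu0``.

    Zero sample variance is handled as a degenerate case: p = 1 when the
    common value equals ``mu0``, p = 0 otherwise.
    """
    x = np.asarray(xs, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one-sample t requires at least 2 observations")
    mean = x.mean()
    sd = x.std(ddof=1)
    n_rec = {"n": int(n)}
    if sd == 0.0:
        if mean == mu0:
            return TestResult("one_sample_t", 0.0, 1.0, tail, n_rec, degenerate=True)
        stat = math.inf if mean > mu0 else -math.inf
        return TestResult("one_sample_t", stat, 0.0, tail, n_rec, degenerate=True)
    tstat = (mean - mu0) / (sd / math.sqrt(n))
    df = n - 1
    if tail == "two_sided":
        p = 2.0 * _dist.t.sf(abs(tstat), df)
    elif tail == "greater":
        p = _dist.t.sf(tstat, df)
    elif tail == "less":
        p = _dist.t.cdf(tstat, df)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TestResult("one_sample_t", float(tstat), float(min(p, 1.0)), tail, n_rec)


# ---------------------------------------------------------------------------
# Rank machinery
# ---------------------------------------------------------------------------

def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..N with ties assigned the mean of the ranks they span."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "normal_approx", "auto"] = "auto",
    tail: Tail = "two_sided",
    continuity: bool = True,
) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    ``exact`` enumerates every assignment of the pooled values to the two
    group labels (the conditional permutation distribution, correct under
    ties); ``auto`` switches to enumeration when the pooled size is at most
    12 and otherwise uses the tie-corrected normal approximation with an
    optional continuity correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    m, nn = xa.size, ya.size
    if m < 1 or nn < 1:
        raise ValueError("both groups must be non-empty")
    n_rec = {"n1": int(m), "n2": int(nn)}
    u = _mw_u(xa, ya)
    pooled = np.concatenate([xa, ya])
    if np.unique(pooled).size == 1:
        return TestResult("mann_whitney", m * nn / 2.0, 1.0, tail, n_rec, degenerate=True)

    if mode == "auto":
        mode = "exact" if (m + nn) <= 12 else "normal_approx"

    mu = m * nn / 2.0
    if mode == "exact":
        # Conditional enumeration over which pooled positions form group 1.
        us = np.array([
            _mw_u(pooled[list(comb)], np.delete(pooled, list(comb)))
            for comb in itertools.combinations(range(m + nn), m)
        ])
        eps = 1e-9
        if tail == "greater":
            p = float(np.mean(us >= u - eps))
        elif tail == "less":
            p = float(np.mean(us <= u + eps))
        elif tail == "two_sided":
            p = float(np.mean(np.abs(us - mu) >= abs(u - mu) - eps))
        else:
            raise ValueError(f"unknown tail {tail!r}")
        return TestResult("mann_whitney_exact", u, min(p, 1.0), tail, n_rec)

    if mode != "normal_approx":
        raise ValueError(f"unknown mode {mode!r}")
    big_n = m + nn
    tie = _tie_term(pooled)
    var = m * nn / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
    if var <= 0:
        return TestResult("mann_whitney", u, 1.0, tail, n_rec, degenerate=True)
    cc = 0.5 if continuity else 0.0
    sd = math.sqrt(var)
    if tail == "greater":
        z = (u - mu - cc) / sd
        p = _dist.norm.sf(z)
    elif tail == "less":
        z = (u - mu + cc) / sd
        p = _dist.norm.cdf(z)
    elif tail == "two_sided":
        z = (abs(u - mu) - cc) / sd
        p = 2.0 * _dist.norm.sf(max(z, 0.0))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TestResult("mann_whitney", u, float(min(p, 1.0)), tail, n_rec)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction, p from chi-squared (k-1 df)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(gs)
    big_n = pooled.size
    n_rec = {f"n{i+1}": int(g.size) for i, g in enumerate(gs)}
    if np.unique(pooled).size == 1:
        return TestResult("kruskal_wallis", 0.0, 1.0, "two_sided", n_rec, degenerate=True)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in gs:
        rsum = ranks[start:start + g.size].sum()
        h += rsum * rsum / g.size
        start += g.size
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    correction = 1.0 - _tie_term(pooled) / (big_n ** 3 - big_n)
    h /= correction
    p = float(_dist.chi2.sf(h, len(gs) - 1))
    return TestResult("kruskal_wallis", float(h), p, "two_sided", n_rec)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjust: Literal["bonferroni", "none"] = "bonferroni",
) -> dict[tuple[int, int], TestResult]:
    """Dunn's pairwise z comparisons on the pooled ranks.

    Returns a mapping from the 0-based group-index pair (i, j), i < j, to
    its TestResult. Bonferroni multiplies each p by the number of pairs,
    capped at 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(gs)
    big_n = pooled.size
    ranks = midranks(pooled)
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    tie = _tie_term(pooled)
    base_var = big_n * (big_n + 1) / 12.0 - tie / (12.0 * (big_n - 1))
    k = len(gs)
    n_pairs = k * (k - 1) // 2
    out: dict[tuple[int, int], TestResult] = {}
    for i, j in itertools.combinations(range(k), 2):
        n_rec = {"n1": int(gs[i].size), "n2": int(gs[j].size)}
        se2 = base_var * (1.0 / gs[i].size + 1.0 / gs[j].size)
        if se2 <= 0:
            out[(i, j)] = TestResult("dunn", 0.0, 1.0, "two_sided", n_rec, degenerate=True)
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se2)
        p = 2.0 * _dist.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        elif adjust != "none":
            raise ValueError(f"unknown adjustment {adjust!r}")
        out[(i, j)] = TestResult("dunn", float(z), float(min(p, 1.0)), "two_sided", n_rec)
    return out


# ---------------------------------------------------------------------------
# One-way ANOVA with Bonferroni pairwise t
# ---------------------------------------------------------------------------

def anova_bonferroni(
    groups: Sequence[Sequence[float]],
) -> tuple[TestResult, dict[tuple[int, int], TestResult]]:
    """One-way ANOVA F test plus Bonferroni-adjusted pairwise t comparisons.

    Pairwise t statistics use the pooled within-group variance (MS_within)
    with N - k degrees of freedom; each pairwise p is multiplied by the
    number of pairs and capped at 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups, each with >= 2 observations")
    k = len(gs)
    big_n = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, big_n - k
    ms_w = ss_within / df_w
    n_rec = {f"n{i+1}": int(g.size) for i, g in enumerate(gs)}
    n_pairs = k * (k - 1) // 2
    if ms_w == 0.0:
        degenerate_equal = all(g.mean() == gs[0].mean() for g in gs)
        f = 0.0 if degenerate_equal else math.inf
        omnibus = TestResult("anova", f, 1.0 if degenerate_equal else 0.0,
                             "two_sided", n_rec, degenerate=True)
    else:
        f = (ss_between / df_b) / ms_w
        omnibus = TestResult("anova", float(f), float(_dist.f.sf(f, df_b, df_w)), "two_sided", n_rec)
    pairwise: dict[tuple[int, int], TestResult] = {}
    for i, j in itertools.combinations(range(k), 2):
        pn = {"n1": int(gs[i].size), "n2": int(gs[j].size)}
        if ms_w == 0.0:
            equal = gs[i].mean() == gs[j].mean()
            pairwise[(i, j)] = TestResult("bonferroni_t", 0.0 if equal else math.inf,
                                          1.0 if equal else 0.0, "two_sided", pn, degenerate=True)
            continue
        se = math.sqrt(ms_w * (1.0 / gs[i].size + 1.0 / gs[j].size))
        t = (gs[i].mean() - gs[j].mean()) / se
        p = min(1.0, 2.0 * _dist.t.sf(abs(t), df_w) * n_pairs)
        pairwise[(i, j)] = TestResult("bonferroni_t", float(t), float(p), "two_sided", pn)
    return omnibus, pairwise


# ---------------------------------------------------------------------------
# Ordinal severity encoding
# ---------------------------------------------------------------------------

SEVERITY_LABELS: Mapping[str, int] = {
    "normal": 0,
    "none": 0,  # both wordings occur for the unaffected category
    "slight": 1,
    "mild": 2,
    "moderate": 3,
}


@dataclass(frozen=True)
class SeverityScore:
    """One eye's black-ommatidia severity on the four-point scale."""

    label: str
    value: int

    def __post_init__(self) -> None:
        if SEVERITY_LABELS.get(self.label) != self.value:
            raise ValueError(f"label/value mismatch: {self.label!r} != {self.value}")


def encode_severity(labels: Sequence[str]) -> list[int]:
    """Map severity labels to ordinal scores 0-3; unknown labels are errors."""
    out = []
    for lab in labels:
        key = str(lab).strip().lower()
        if key not in SEVERITY_LABELS:
            raise ValueError(f"unknown severity label: {lab!r}")
        out.append(SEVERITY_LABELS[key])
    return out
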
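"""Randomly seeded network null models and observed-vs-null comparisons.

The question asked of a three-seed network is whether its multivalent
structure — genes touching two or three of the seeds — exceeds what
networks seeded by random gene triples produce. An ensemble of random
3-symbol seed sets is drawn from a declared pool, each set's network is
extracted and summarized, and the observed network is compared to the
ensemble two ways: a two-sided one-sample t test on network size or
composition, and a one-tailed Fisher's exact test on a 2x2 table pooling
the null networks' counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .interactome import (
    InteractionDb,
    OrthologyMap,
    SeedNetwork,
    ValenceSummary,
    count_valence,
    extract_seed_network,
)
from .stats import ContingencyTable2x2, TestResult, fisher_exact, one_sample_t

logger = logging.getLogger(__name__)

Valence = Literal["ge1", "exactly2"]


@dataclass(frozen=True)
class NullEnsemble:
    """Valence summaries of networks seeded by random 3-symbol sets."""

    seed_sets: tuple[tuple[str, str, str], ...]
    summaries: tuple[ValenceSummary, ...]
    pool_label: str
    rng_seed: int

    def __post_init__(self) -> None:
        if len(self.seed_sets) != len(self.summaries):
            raise ValueError("one summary per seed set required")
        for s in self.seed_sets:
            if len(set(s)) != 3:
                raise ValueError(f"seed set must have 3 distinct symbols: {s}")

    def to_dict(self) -> dict:
        return {
            "pool_label": self.pool_label,
            "rng_seed": self.rng_seed,
            "n_sets": len(self.seed_sets),
            "seed_sets": [list(s) for s in self.seed_sets],
            "summaries": [s.to_dict() for s in self.summaries],
        }


def sample_seed_sets(
    pool: Sequence[str], n_sets: int, rng_seed: int | np.random.Generator
) -> list[tuple[str, str, str]]:
    """Draw ``n_sets`` seed triples uniformly from ``pool``.

    Sampling is without replacement within a set (3 distinct symbols) but
    sets may recur across draws. Deterministic under a fixed seed; the
    pool is sorted internally so input order does not matter.
    """
    pool = sorted(set(pool))
    if len(pool) < 3:
        raise ValueError(f"pool must contain at least 3 symbols, got {len(pool)}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_sets):
        idx = rng.choice(len(pool), size=3, replace=False)
        out.append(tuple(sorted(pool[i] for i in idx)))
    return out


def build_null(
    db: InteractionDb,
    orthology: OrthologyMap,
    seed_sets: Sequence[Sequence[str]],
    k_augment: int = 15,
    *,
    pool: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
    pool_label: str = "genome_wide",
    rng_seed: int = 0,
    max_redraws: int = 1000,
) -> NullEnsemble:
    """Extract and summarize one network per random seed set.

    A set containing a symbol with no orthologue in the database is
    redrawn from ``pool`` (when given) rather than skipped, preserving the
    requested ensemble size; redraws are logged. Without a pool an
    unresolvable set is an error.
    """
    final_sets: list[tuple[str, str, str]] = []
    summaries: list[ValenceSummary] = []
    n_redraws = 0
    for seed_set in seed_sets:
        current = tuple(seed_set)
        while True:
            try:
                net = extract_seed_network(db, current, orthology, k_augment=k_augment)
                break
            except ValueError:
                if pool is None or rng is None:
                    raise
                n_redraws += 1
                if n_redraws > max_redraws:
                    raise ValueError("seed pool exhausted by redraws of unresolvable sets")
                current = sample_seed_sets(pool, 1, rng)[0]
        final_sets.append(tuple(sorted(current)))
        summaries.append(count_valence(net))
    if n_redraws:
        logger.info("build_null: redrew %d unresolvable seed sets", n_redraws)
    return NullEnsemble(tuple(final_sets), tuple(summaries), pool_label, rng_seed)


def compare_total_genes(observed: ValenceSummary, null: NullEnsemble) -> TestResult:
    """Two-sided one-sample t of the null networks' total gene counts
    against the observed network's total."""
    totals = [s.n_total for s in null.summaries]
    if len(totals) < 2:
        raise ValueError("need at least 2 null summaries")
    return one_sample_t(totals, mu0=observed.n_total, tail="two_sided")


def _valence_columns(s: ValenceSummary, valence: Valence) -> tuple[int, int]:
    """(event count, complement count) for one network."""
    if valence == "ge1":
        return s.n_interact_ge1, s.n_total - s.n_interact_ge1
    if valence == "exactly2":
        return s.n_exactly2, s.n_interact_ge1 - s.n_exactly2
    raise ValueError(f"unknown valence {valence!r}")


def compare_valence(
    observed: ValenceSummary,
    null: NullEnsemble,
    valence: Valence = "exactly2",
    method: Literal["fisher", "t"] = "fisher",
    tail: str = "greater",
) -> TestResult:
    """Compare observed valence composition against the pooled null.

    ``fisher``: 2x2 table with rows {observed network, pooled null
    networks}; for ``ge1`` the columns are {interactors, other members},
    for ``exactly2`` {exactly-2-seed genes, other interactors}. Default
    tail ``greater`` tests enrichment in the observed network.

    ``t``: two-sided one-sample t of the per-null-network proportions
    (event / column total) against the observed proportion; null networks
    with a zero column total are dropped with a log message.
    """
    if method == "fisher":
        a, b = _valence_columns(observed, valence)
        c = d = 0
        for s in null.summaries:
            ev, other = _valence_columns(s, valence)
            c += ev
            d += other
        return fisher_exact(ContingencyTable2x2(a, b, c, d), tail=tail)
    if method == "t":
        a, b = _valence_columns(observed, valence)
        if a + b == 0:
            raise ValueError("observed network has an empty denominator for this valence")
        obs_prop = a / (a + b)
        props = []
        n_dropped = 0
        for s in null.summaries:
            ev, other = _valence_columns(s, valence)
            if ev + other == 0:
                n_dropped += 1
                continue
            props.append(ev / (ev + other))
        if n_dropped:
            logger.info("compare_valence(t): dropped %d null networks with empty denominators",
                        n_dropped)
        if len(props) < 2:
            raise ValueError("fewer than 2 null networks with a defined proportion")
        return one_sample_t(props, mu0=obs_prop, tail="two_sided")
    raise ValueError(f"unknown method {method!r}")


def empirical_percentile(observed_value: float, null_values: Sequence[float]) -> float:
    """Diagnostic only: fraction of null values >= the observed value."""
    arr = np.asarray(null_values, dtype=float)
    if arr.size == 0:
        raise ValueError("no null values")
    return float(np.mean(arr >= observed_value))
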
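"""Rare-CNV inclusion cascade and case/control gene burden testing.

Clinical CNV burden analyses of the kind modeled here keep only calls
that are rare in controls (<0.1% carrier frequency), large (>300 kb),
mostly outside segmental duplications (<50% overlapped), and interstitial
heterozygous deletions or duplications — whole-chromosome gains and
losses are excluded. Surviving calls are intersected with gene models
(>=1 bp overlap) to define per-gene carrier sets, and case vs control
carrier frequencies are compared by one-tailed Fisher's exact tests, per
gene and for the gene set combined.

Coordinates are 0-based half-open (BED convention) throughout; 1-based
inclusive inputs can be converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .stats import ContingencyTable2x2, TestResult, fisher_exact

COHORTS = frozenset({"case", "control"})
CNV_TYPES = frozenset({"deletion", "duplication"})
ZYGOSITIES = frozenset({"heterozygous", "homozygous", "unknown"})

CALL_COLUMNS = ["sample_id", "cohort", "chrom", "start", "end", "type", "zygosity"]

FILTER_RULES = (
    "whole_chromosome",
    "not_interstitial_heterozygous",
    "size",
    "segdup_overlap",
    "control_frequency",
)


@dataclass(frozen=True)
class CnvCall:
    """One deletion/duplication interval in one sample (0-based half-open)."""

    sample_id: str
    cohort: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    zygosity: str = "heterozygous"

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"unknown CNV type {self.cnv_type!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusion constants of the rare-CNV cascade.

    Defaults: control carrier frequency < 0.1%, size > 300 kb, merged
    segmental-duplication overlap < 50% of the call, gene overlap >= 1 bp,
    and whole-chromosome proxy at >= 90% of the chromosome span.
    """

    max_control_freq: float = 0.001
    min_size_bp: int = 300_000
    max_segdup_overlap: float = 0.5
    min_gene_overlap_bp: int = 1
    whole_chrom_span_frac: float = 0.9

    def __post_init__(self) -> None:
        for name in ("max_control_freq", "max_segdup_overlap", "whole_chrom_span_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_size_bp <= 0:
            raise ValueError("min_size_bp must be positive")
        if self.min_gene_overlap_bp < 1:
            raise ValueError("min_gene_overlap_bp must be >= 1")


@dataclass(frozen=True)
class BedInterval:
    """Named genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BurdenResult:
    """Case/control carrier comparison for one gene (or the combined set)."""

    gene: str
    case_carriers: int
    case_n: int
    control_carriers: int
    control_n: int
    test: TestResult = field(compare=False)

    def __post_init__(self) -> None:
        if self.case_carriers > self.case_n or self.control_carriers > self.control_n:
            raise ValueError(f"{self.gene}: carrier count exceeds denominator")

    @property
    def case_freq(self) -> float:
        return self.case_carriers / self.case_n

    @property
    def control_freq(self) -> float:
        return self.control_carriers / self.control_n

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "case_carriers": self.case_carriers,
            "case_n": self.case_n,
            "control_carriers": self.control_carriers,
            "control_n": self.control_n,
            "case_freq": self.case_freq,
            "control_freq": self.control_freq,
            "test": self.test.to_dict(),
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_calls(path: str | Path, one_based: bool = False) -> list[CnvCall]:
    """Read the CNV TSV; validate tokens and coordinates with line numbers.

    Output is sorted by (chrom, start, end, sample_id).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CNV TSV missing columns: {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        start, end = int(row.start), int(row.end)
        if one_based:
            start -= 1
        try:
            calls.append(CnvCall(row.sample_id, row.cohort, row.chrom, start, end,
                                 row.type, row.zygosity))
        except ValueError as e:
            raise ValueError(f"line {line_no}: {e}") from None
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample_id))


def calls_to_frame(calls: Iterable[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample_id, c.cohort, c.chrom, c.start, c.end, c.cnv_type, c.zygosity) for c in calls],
        columns=CALL_COLUMNS,
    )


def read_bed(path: str | Path) -> list[BedInterval]:
    """Read a BED file (chrom, start, end[, name]); sorted per chromosome."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {i}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else "."
            try:
                out.append(BedInterval(parts[0], int(parts[1]), int(parts[2]), name))
            except ValueError as e:
                raise ValueError(f"line {i}: {e}") from None
    return sorted(out, key=lambda b: (b.chrom, b.start, b.end, b.name))


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str, "size": int})
    return dict(zip(df["chrom"], df["size"]))


# ---------------------------------------------------------------------------
# Control-frequency clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_calls(calls: Sequence[CnvCall], recip_overlap: float = 0.5) -> list[int]:
    """Single-linkage clusters of same-type, same-chromosome calls at
    >= ``recip_overlap`` reciprocal overlap; returns one cluster id per call."""
    if not 0.0 < recip_overlap <= 1.0:
        raise ValueError("recip_overlap must be in (0, 1]")
    uf = _UnionFind(len(calls))
    groups: dict[tuple[str, str], list[int]] = {}
    for idx, c in enumerate(calls):
        groups.setdefault((c.chrom, c.cnv_type), []).append(idx)
    for idxs in groups.values():
        idxs = sorted(idxs, key=lambda i: (calls[i].start, calls[i].end))
        for pos, i in enumerate(idxs):
            ci = calls[i]
            for j in idxs[pos + 1:]:
                cj = calls[j]
                if cj.start >= ci.end:
                    break  # sorted by start: no later call intersects ci
                inter = min(ci.end, cj.end) - cj.start
                if inter >= recip_overlap * max(ci.length, cj.length):
                    uf.union(i, j)
    roots = [uf.find(i) for i in range(len(calls))]
    relabel: dict[int, int] = {}
    return [relabel.setdefault(r, len(relabel)) for r in roots]


def control_frequency(
    calls: Sequence[CnvCall], control_n: int, recip_overlap: float = 0.5
) -> np.ndarray:
    """Per-call control carrier frequency via reciprocal-overlap clustering.

    A call's frequency is the number of distinct control samples in its
    cluster divided by ``control_n``; a case call clustering with no
    control call has frequency 0.
    """
    if control_n <= 0:
        raise ValueError("control_n must be positive")
    labels = cluster_calls(calls, recip_overlap)
    cluster_controls: dict[int, set[str]] = {}
    for c, lab in zip(calls, labels):
        if c.cohort == "control":
            cluster_controls.setdefault(lab, set()).add(c.sample_id)
    return np.array([len(cluster_controls.get(lab, ())) / control_n for lab in labels])


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def segdup_overlap_fraction(call: CnvCall, segdups_by_chrom: Mapping[str, Sequence[tuple[int, int]]]) -> float:
    """Fraction of the call covered by (pre-merged) segmental duplications."""
    covered = 0
    for s, e in segdups_by_chrom.get(call.chrom, ()):
        if e <= call.start:
            continue
        if s >= call.end:
            break
        covered += min(e, call.end) - max(s, call.start)
    return covered / call.length


def filter_calls(
    calls: Sequence[CnvCall],
    segdups: Sequence[BedInterval],
    chrom_sizes: Mapping[str, int],
    thresholds: FilterThresholds = FilterThresholds(),
    control_n: int | None = None,
    recip_overlap: float = 0.5,
) -> tuple[list[CnvCall], pd.DataFrame]:
    """Apply the rare-CNV inclusion cascade in fixed rule order.

    Rules, in order: (1) whole-chromosome span, (2) interstitial
    heterozygous deletions/duplications only, (3) size > ``min_size_bp``,
    (4) merged segdup overlap < ``max_segdup_overlap``, (5) control
    frequency < ``max_control_freq``. The audit table records, for each
    removed call, the first rule it failed. Control frequencies are
    computed on the calls surviving rules 1-4 (frequencies among
    comparable, quality-filtered events); ``control_n`` defaults to the
    number of distinct control samples present in ``calls``.

    Returns (surviving calls, audit DataFrame).
    """
    if control_n is None:
        control_n = len({c.sample_id for c in calls if c.cohort == "control"})
    segdups_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in segdups:
        segdups_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    segdups_by_chrom = {ch: _merge_intervals(ivs) for ch, ivs in segdups_by_chrom.items()}

    audit_rows: list[tuple[str, str, int, int, str, str]] = []
    stage4: list[CnvCall] = []
    for c in calls:
        if c.chrom not in chrom_sizes:
            raise ValueError(f"chromosome {c.chrom!r} absent from chrom_sizes")
        rule = None
        if c.length >= thresholds.whole_chrom_span_frac * chrom_sizes[c.chrom]:
            rule = "whole_chromosome"
        elif c.zygosity != "heterozygous":
            rule = "not_interstitial_heterozygous"
        elif c.length <= thresholds.min_size_bp:
            rule = "size"
        elif segdup_overlap_fraction(c, segdups_by_chrom) >= thresholds.max_segdup_overlap:
            rule = "segdup_overlap"
        if rule is None:
            stage4.append(c)
        else:
            audit_rows.append((c.sample_id, c.chrom, c.start, c.end, c.cnv_type, rule))

    surviving: list[CnvCall] = []
    if stage4:
        freqs = control_frequency(stage4, control_n, recip_overlap) if control_n > 0 \
            else np.zeros(len(stage4))
        for c, f in zip(stage4, freqs):
            if f < thresholds.max_control_freq:
                surviving.append(c)
            else:
                audit_rows.append((c.sample_id, c.chrom, c.start, c.end, c.cnv_type,
                                   "control_frequency"))
    audit = pd.DataFrame(audit_rows,
                         columns=["sample_id", "chrom", "start", "end", "type", "failed_rule"])
    return surviving, audit


# ---------------------------------------------------------------------------
# Gene carriers and burden tests
# ---------------------------------------------------------------------------

def gene_carriers(
    calls: Sequence[CnvCall],
    gene_models: Sequence[BedInterval],
    min_gene_overlap_bp: int = 1,
) -> dict[str, dict[str, set[str]]]:
    """Map gene -> {"case": carrier sample set, "control": carrier sample set}.

    A sample is a carrier for a gene if at least one of its calls overlaps
    the gene by >= ``min_gene_overlap_bp``; multiple qualifying calls count
    once.
    """
    if not gene_models:
        raise ValueError("gene models must be non-empty")
    trees: dict[str, IntervalTree] = {}
    carriers: dict[str, dict[str, set[str]]] = {}
    for g in gene_models:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.name)
        carriers.setdefault(g.name, {"case": set(), "control": set()})
    for c in calls:
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(c.start, c.end):
            if min(c.end, iv.end) - max(c.start, iv.begin) >= min_gene_overlap_bp:
                carriers[iv.data][c.cohort].add(c.sample_id)
    return carriers


def burden_test(
    carriers: Mapping[str, Mapping[str, set[str]]],
    case_n: int | Mapping[str, int],
    control_n: int,
    gene_set: Sequence[str] | None = None,
    tail: str = "greater",
) -> tuple[dict[str, BurdenResult], BurdenResult]:
    """One-tailed Fisher burden tests, per gene and combined over a set.

    ``case_n`` may be a single cohort denominator or a per-gene mapping of
    assayable case counts (probe-coverage-adjusted). The combined test
    counts a sample once if it carries a qualifying CNV overlapping any
    gene of the set; its case denominator is the full cohort (the maximum
    per-gene denominator when a mapping is given).
    """
    genes = sorted(gene_set) if gene_set is not None else sorted(carriers)
    per_gene: dict[str, BurdenResult] = {}
    for g in genes:
        sets = carriers.get(g, {"case": set(), "control": set()})
        cn = case_n[g] if isinstance(case_n, Mapping) else case_n
        a, c = len(sets["case"]), len(sets["control"])
        test = fisher_exact(ContingencyTable2x2(a, cn - a, c, control_n - c), tail=tail)
        per_gene[g] = BurdenResult(g, a, cn, c, control_n, test)
    case_union: set[str] = set()
    control_union: set[str] = set()
    for g in genes:
        sets = carriers.get(g, {"case": set(), "control": set()})
        case_union |= sets["case"]
        control_union |= sets["control"]
    combined_case_n = max(case_n.values()) if isinstance(case_n, Mapping) else case_n
    a, c = len(case_union), len(control_union)
    test = fisher_exact(
        ContingencyTable2x2(a, combined_case_n - a, c, control_n - c), tail=tail
    )
    combined = BurdenResult("GENE_SET", a, combined_case_n, c, control_n, test)
    return per_gene, combined


def carrier_breakdown_by_type(
    calls: Sequence[CnvCall],
    gene_models: Sequence[BedInterval],
    min_gene_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Diagnostic: per-gene, per-CNV-type carrier counts by cohort."""
    rows = []
    for cnv_type in sorted(CNV_TYPES):
        subset = [c for c in calls if c.cnv_type == cnv_type]
        if not gene_models:
            continue
        cmap = gene_carriers(subset, gene_models, min_gene_overlap_bp)
        for g in sorted(cmap):
            rows.append((g, cnv_type, len(cmap[g]["case"]), len(cmap[g]["control"])))
    return pd.DataFrame(rows, columns=["gene", "type", "case_carriers", "control_carriers"])


def overall_rates(
    calls: Sequence[CnvCall],
    gene_models: Sequence[BedInterval],
    case_n: int,
    control_n: int,
    min_gene_overlap_bp: int = 1,
) -> dict[str, float]:
    """Overall event rates over the gene set, both numerator conventions.

    ``per_sample``: fraction of samples carrying >= 1 qualifying call over
    any gene; ``per_event``: qualifying call count divided by cohort size.
    """
    cmap = gene_carriers(calls, gene_models, min_gene_overlap_bp)
    case_samples: set[str] = set()
    control_samples: set[str] = set()
    for sets in cmap.values():
        case_samples |= sets["case"]
        control_samples |= sets["control"]
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.name)
    n_events = {"case": 0, "control": 0}
    for c in calls:
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        hit = any(
            min(c.end, iv.end) - max(c.start, iv.begin) >= min_gene_overlap_bp
            for iv in tree.overlap(c.start, c.end)
        )
        if hit:
            n_events[c.cohort] += 1
    return {
        "case_per_sample": len(case_samples) / case_n,
        "control_per_sample": len(control_samples) / control_n,
        "case_per_event": n_events["case"] / case_n,
        "control_per_event": n_events["control"] / control_n,
    }
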
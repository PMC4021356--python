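"""Synthetic inputs with the statistical structure the analyses assume.

Three generators stand in for external resources that cannot be shipped:

* a five-species interactome with evidence-typed edges and an orthology
  map, optionally with a *planted triad* — three seed symbols plus a
  configurable number of genes wired to exactly two (bivalent) or exactly
  one (univalent) of the seeds;
* a case/control CNV cohort with log-uniform call sizes, recurrent
  (common) loci, whole-chromosome events, optional per-gene probe
  coverage, and per-gene relative risks applied to cases;
* ordinal (four-point severity) or continuous phenotype score tables.

All generators are deterministic under their ``rng_seed``: sub-streams
are derived per species / sample / planted gene, so enlarging a planted
signal extends it without re-rolling what was already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cnv import BedInterval, CnvCall
from .interactome import EVIDENCE_TYPES, InteractionRecord, OrthologyMap

DEFAULT_SPECIES = ("sp1", "sp2", "sp3", "sp4", "sp5")
DEFAULT_EDGE_PROBS = {ev: 0.002 for ev in sorted(EVIDENCE_TYPES)}

# Sub-stream tags (mixed into the numpy SeedSequence entropy)
_TAG_ORTHOLOGY = 1
_TAG_BACKGROUND = 2
_TAG_PLANT = 3
_TAG_CNV = 4
_TAG_SCORES = 5


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *tags]))


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTriad:
    """Three seed symbols plus counts of bivalent/univalent planted genes."""

    seeds: tuple[str, str, str]
    n_bivalent: int = 0
    n_univalent: int = 0

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != 3:
            raise ValueError("planted triad needs 3 distinct seed symbols")
        if self.n_bivalent < 0 or self.n_univalent < 0:
            raise ValueError("planted counts must be >= 0")


@dataclass(frozen=True)
class InteractomeSimConfig:
    genes_per_species: int = 500
    species_list: tuple[str, ...] = DEFAULT_SPECIES
    orthology_coverage: float = 0.8
    edge_prob_by_evidence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_PROBS)
    )
    planted_triad: Optional[PlantedTriad] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_species <= 0:
            raise ValueError("genes_per_species must be positive")
        if not 0.0 <= self.orthology_coverage <= 1.0:
            raise ValueError("orthology_coverage must be in [0, 1]")
        for ev, p in self.edge_prob_by_evidence.items():
            if ev not in EVIDENCE_TYPES:
                raise ValueError(f"unknown evidence type {ev!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability for {ev!r} out of [0, 1]: {p}")
        if self.planted_triad is not None:
            pt = self.planted_triad
            needed = 3 + pt.n_bivalent + pt.n_univalent
            if needed > self.genes_per_species:
                raise ValueError(
                    f"cannot place planted seed symbol {pt.seeds[0]!r}: planted triad needs "
                    f"{needed} genes per species but only {self.genes_per_species} exist"
                )


def _symbol(idx: int, seeds: Optional[tuple[str, str, str]]) -> str:
    if seeds is not None and idx < 3:
        return seeds[idx]
    return f"HG{idx + 1:04d}"


def simulate_interactome(
    config: InteractomeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (edges TSV frame, orthology TSV frame).

    Per species, background edges are drawn independently per evidence
    type (Erdős–Rényi per type). Gene index ``j`` in every species maps —
    with probability ``orthology_coverage`` — to the shared human symbol of
    index ``j``, which is what makes cross-species collapsing meaningful.
    When a triad is planted, symbol indices 0–2 are the seed symbols and
    their orthologues are always mapped; each planted gene is wired, in a
    randomly chosen species, to exactly 2 (bivalent) or exactly 1
    (univalent) randomly chosen seed orthologues and force-mapped so it
    survives symbol collapsing.
    """
    n = config.genes_per_species
    seeds = config.planted_triad.seeds if config.planted_triad else None
    species = list(config.species_list)

    # Orthology: one coverage draw per (species, gene)
    orth_rows: list[tuple[str, str, str]] = []
    mapped: set[tuple[str, int]] = set()
    for si, sp in enumerate(species):
        rng = _rng(config.rng_seed, _TAG_ORTHOLOGY, si)
        cover = rng.random(n) < config.orthology_coverage
        for j in range(n):
            if seeds is not None and j < 3:
                cover[j] = True  # seed orthologues present in every species
            if cover[j]:
                orth_rows.append((sp, f"{sp}_g{j + 1:04d}", _symbol(j, seeds)))
                mapped.add((sp, j))

    # Background edges: per species x evidence, Binomial edge count then
    # a uniform without-replacement draw of pair indices.
    bg_edges: list[tuple[str, int, int, str]] = []  # (species, i, j, evidence)
    n_pairs = n * (n - 1) // 2
    evidence_types = sorted(config.edge_prob_by_evidence)
    for si, sp in enumerate(species):
        for ei, ev in enumerate(evidence_types):
            p = config.edge_prob_by_evidence[ev]
            if p <= 0.0 or n_pairs == 0:
                continue
            rng = _rng(config.rng_seed, _TAG_BACKGROUND, si, ei)
            m = int(rng.binomial(n_pairs, p))
            if m == 0:
                continue
            pair_idx = rng.choice(n_pairs, size=m, replace=False)
            # decode linear pair index -> (i, j), i < j
            for k in np.sort(pair_idx):
                i = int((2 * n - 1 - math.sqrt((2 * n - 1) ** 2 - 8 * k)) // 2)
                j = int(k - i * (2 * n - i - 1) // 2 + i + 1)
                bg_edges.append((sp, i, j, ev))

    # Planted triad: a fixed permutation of candidate genes, prefix-taken,
    # with per-gene sub-streams so growing the counts only appends. A
    # planted gene's seed valence is exact by construction: background
    # edges between it (in any species) and disallowed seed orthologues
    # are suppressed.
    planted_edges: list[tuple[str, int, int, str]] = []
    forbidden: set[tuple[int, int]] = set()  # (gene index, seed index) pairs to drop
    if config.planted_triad is not None:
        pt = config.planted_triad
        perm_rng = _rng(config.rng_seed, _TAG_PLANT, 0)
        candidates = perm_rng.permutation(np.arange(3, n))
        chosen = candidates[: pt.n_bivalent + pt.n_univalent]
        for rank, j in enumerate(chosen):
            j = int(j)
            valence = 2 if rank < pt.n_bivalent else 1
            g_rng = _rng(config.rng_seed, _TAG_PLANT, 1, j)
            si = int(g_rng.integers(len(species)))
            sp = species[si]
            seed_idx = sorted(int(s) for s in g_rng.choice(3, size=valence, replace=False))
            for sidx in range(3):
                if sidx not in seed_idx:
                    forbidden.add((j, sidx))
            for sidx in seed_idx:
                ev = evidence_types[int(g_rng.integers(len(evidence_types)))]
                planted_edges.append((sp, sidx, j, ev))
            if (sp, j) not in mapped:  # planted genes must collapse to a symbol
                orth_rows.append((sp, f"{sp}_g{j + 1:04d}", _symbol(j, seeds)))
                mapped.add((sp, j))
        bg_edges = [
            e for e in bg_edges
            if not ((e[2], e[1]) in forbidden or (e[1], e[2]) in forbidden)
        ]

    edge_rows = [
        (sp, f"{sp}_g{i + 1:04d}", f"{sp}_g{j + 1:04d}", ev, 1.0)
        for sp, i, j, ev in bg_edges + planted_edges
    ]
    edges = pd.DataFrame(edge_rows, columns=["species", "gene_a", "gene_b", "evidence", "weight"])
    # canonical order + dedupe (a planted edge may duplicate a background one)
    swap = edges["gene_a"] > edges["gene_b"]
    edges.loc[swap, ["gene_a", "gene_b"]] = edges.loc[swap, ["gene_b", "gene_a"]].values
    edges = (
        edges.drop_duplicates(subset=["species", "gene_a", "gene_b", "evidence"])
        .sort_values(["species", "gene_a", "gene_b", "evidence"], kind="mergesort")
        .reset_index(drop=True)
    )
    orthology = (
        pd.DataFrame(orth_rows, columns=["species", "species_gene", "human_symbol"])
        .drop_duplicates()
        .sort_values(["species", "species_gene", "human_symbol"], kind="mergesort")
        .reset_index(drop=True)
    )
    return edges, orthology


def interactome_objects(
    config: InteractomeSimConfig,
):
    """Convenience: simulate and return (InteractionDb, OrthologyMap)."""
    from .interactome import InteractionDb

    edges, orth = simulate_interactome(config)
    records = [
        InteractionRecord(r.species, r.gene_a, r.gene_b, r.evidence, float(r.weight))
        for r in edges.itertuples(index=False)
    ]
    omap = OrthologyMap()
    for r in orth.itertuples(index=False):
        omap.add(r.species, r.species_gene, [r.human_symbol])
    return InteractionDb(records), omap


def symbol_pool(config: InteractomeSimConfig) -> list[str]:
    """All human symbols of the simulated universe (seed symbols included)."""
    seeds = config.planted_triad.seeds if config.planted_triad else None
    return [_symbol(j, seeds) for j in range(config.genes_per_species)]


# ---------------------------------------------------------------------------
# CNV cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvSimConfig:
    """Case/control CNV cohort simulation.

    ``baseline_carrier_rate`` is the expected per-gene carrier rate in
    controls; ``per_gene_relative_risk`` multiplies it in cases. Cohort
    sizes default to the scale of large clinical CNV databases (tens of
    thousands of referred cases against ~8,000 population controls).
    ``background_calls_per_sample`` adds unanchored genome-wide calls
    (Poisson per sample); ``common_cnv_rate`` is the expected fraction of
    calls that come from a small set of recurrent loci, which downstream
    filtering should remove as common.
    """

    chrom_sizes: Mapping[str, int]
    gene_models: tuple[BedInterval, ...]
    segdup_intervals: tuple[BedInterval, ...] = ()
    n_cases: int = 5000
    n_controls: int = 8329
    baseline_carrier_rate: float = 0.002
    per_gene_relative_risk: Mapping[str, float] = field(default_factory=dict)
    size_distribution: tuple[int, int] = (301_000, 3_000_000)
    common_cnv_rate: float = 0.0
    whole_chrom_rate: float = 0.0
    background_calls_per_sample: float = 0.05
    per_gene_coverage: Optional[Mapping[str, float]] = None
    n_recurrent_loci: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        for name in ("baseline_carrier_rate", "common_cnv_rate", "whole_chrom_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        gene_names = {g.name for g in self.gene_models}
        for g, rr in self.per_gene_relative_risk.items():
            if g not in gene_names:
                raise ValueError(f"relative-risk gene {g!r} absent from gene models")
            if rr < 0:
                raise ValueError(f"relative risk for {g!r} must be >= 0")
        for g in self.gene_models:
            if g.chrom not in self.chrom_sizes or g.end > self.chrom_sizes[g.chrom]:
                raise ValueError(f"gene {g.name!r} outside declared chromosomes")
        lo, hi = self.size_distribution
        if not (0 < lo <= hi):
            raise ValueError("size_distribution bounds must satisfy 0 < lo <= hi")
        if self.per_gene_coverage:
            for g, f in self.per_gene_coverage.items():
                if g not in gene_names:
                    raise ValueError(f"coverage gene {g!r} absent from gene models")
                if not 0.0 < f <= 1.0:
                    raise ValueError(f"coverage for {g!r} must be in (0, 1]")


def _draw_size(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    if lo == hi:
        return lo
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def simulate_cnv_cohort(config: CnvSimConfig) -> tuple[list[CnvCall], dict]:
    """Generate the cohort's CNV call table.

    Returns ``(calls, meta)`` where ``meta`` carries the cohort
    denominators, the per-gene assayable case counts implied by
    ``per_gene_coverage``, and the recurrent loci used for common calls.
    """
    rng = _rng(config.rng_seed, _TAG_CNV)
    chroms = sorted(config.chrom_sizes)
    samples = [("case", f"case{i + 1:06d}") for i in range(config.n_cases)] + [
        ("control", f"ctrl{i + 1:06d}") for i in range(config.n_controls)
    ]

    # fixed recurrent loci for "common" calls
    recurrent: list[tuple[str, int, int, str]] = []
    for _ in range(config.n_recurrent_loci):
        ch = chroms[int(rng.integers(len(chroms)))]
        size = min(_draw_size(rng, config.size_distribution), config.chrom_sizes[ch])
        start = int(rng.integers(0, max(1, config.chrom_sizes[ch] - size + 1)))
        cnv_type = "deletion" if rng.random() < 0.5 else "duplication"
        recurrent.append((ch, start, start + size, cnv_type))

    lam_targeted = config.baseline_carrier_rate
    lam_other = config.background_calls_per_sample + lam_targeted * len(config.gene_models)
    lam_recurrent_total = (
        lam_other * config.common_cnv_rate / (1.0 - config.common_cnv_rate)
        if 0.0 < config.common_cnv_rate < 1.0 and recurrent
        else 0.0
    )

    calls: list[CnvCall] = []
    for s_idx, (cohort, sid) in enumerate(samples):
        s_rng = _rng(config.rng_seed, _TAG_CNV, 1, s_idx)
        # gene-anchored calls
        for g in config.gene_models:
            rr = config.per_gene_relative_risk.get(g.name, 1.0) if cohort == "case" else 1.0
            lam = lam_targeted * rr
            k = int(s_rng.poisson(lam)) if lam > 0 else 0
            for _ in range(k):
                size = _draw_size(s_rng, config.size_distribution)
                size = min(size, config.chrom_sizes[g.chrom])
                lo = max(0, g.start - size + 1)
                hi = min(g.end - 1, config.chrom_sizes[g.chrom] - size)
                start = int(s_rng.integers(lo, max(lo, hi) + 1))
                cnv_type = "deletion" if s_rng.random() < 0.5 else "duplication"
                calls.append(CnvCall(sid, cohort, g.chrom, start, start + size,
                                     cnv_type, "heterozygous"))
        # unanchored background calls
        k = int(s_rng.poisson(config.background_calls_per_sample)) \
            if config.background_calls_per_sample > 0 else 0
        for _ in range(k):
            ch = chroms[int(s_rng.integers(len(chroms)))]
            size = min(_draw_size(s_rng, config.size_distribution), config.chrom_sizes[ch])
            start = int(s_rng.integers(0, max(1, config.chrom_sizes[ch] - size + 1)))
            cnv_type = "deletion" if s_rng.random() < 0.5 else "duplication"
            calls.append(CnvCall(sid, cohort, ch, start, start + size,
                                 cnv_type, "heterozygous"))
        # recurrent (common) calls
        if lam_recurrent_total > 0:
            k = int(s_rng.poisson(lam_recurrent_total))
            for _ in range(k):
                ch, start, end, cnv_type = recurrent[int(s_rng.integers(len(recurrent)))]
                calls.append(CnvCall(sid, cohort, ch, start, end, cnv_type, "heterozygous"))
        # whole-chromosome events
        if config.whole_chrom_rate > 0 and s_rng.random() < config.whole_chrom_rate:
            ch = chroms[int(s_rng.integers(len(chroms)))]
            cnv_type = "deletion" if s_rng.random() < 0.5 else "duplication"
            calls.append(CnvCall(sid, cohort, ch, 0, config.chrom_sizes[ch],
                                 cnv_type, "unknown"))

    # probe-coverage masking: a fixed subset of cases is unassayable per gene
    case_n_by_gene: dict[str, int] = {}
    if config.per_gene_coverage:
        mask_rng = _rng(config.rng_seed, _TAG_CNV, 2)
        unassayable: dict[str, set[str]] = {}
        for g in config.gene_models:
            cov = config.per_gene_coverage.get(g.name, 1.0)
            n_assay = int(round(cov * config.n_cases))
            case_n_by_gene[g.name] = n_assay
            drop = mask_rng.choice(config.n_cases, size=config.n_cases - n_assay, replace=False)
            unassayable[g.name] = {f"case{int(i) + 1:06d}" for i in drop}
        kept: list[CnvCall] = []
        gene_by_name = {g.name: g for g in config.gene_models}
        for c in calls:
            masked = False
            if c.cohort == "case":
                for gname, sids in unassayable.items():
                    g = gene_by_name[gname]
                    if (c.sample_id in sids and c.chrom == g.chrom
                            and min(c.end, g.end) - max(c.start, g.start) >= 1):
                        masked = True
                        break
            if not masked:
                kept.append(c)
        calls = kept
    else:
        case_n_by_gene = {g.name: config.n_cases for g in config.gene_models}

    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    meta = {
        "case_n": config.n_cases,
        "control_n": config.n_controls,
        "case_n_by_gene": case_n_by_gene,
        "recurrent_loci": recurrent,
    }
    return calls, meta


# ---------------------------------------------------------------------------
# Phenotype scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSimConfig:
    """Ordinal (four-point severity) or continuous score simulation."""

    genotypes: tuple[str, ...]
    n_per_genotype: int
    mode: str = "ordinal"
    per_genotype_category_probs: Optional[Mapping[str, Sequence[float]]] = None
    per_genotype_mean_sd: Optional[Mapping[str, tuple[float, float]]] = None
    n_batches: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_genotype <= 0:
            raise ValueError("n_per_genotype must be positive")
        if self.mode == "ordinal":
            if self.per_genotype_category_probs is None:
                raise ValueError("ordinal mode needs per_genotype_category_probs")
            for g in self.genotypes:
                probs = self.per_genotype_category_probs.get(g)
                if probs is None:
                    raise ValueError(f"no category probabilities for genotype {g!r}")
                if len(probs) != 4:
                    raise ValueError(f"genotype {g!r}: need 4 category probabilities")
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(
                        f"genotype {g!r}: category probabilities sum to {sum(probs)}, not 1"
                    )
        elif self.mode == "continuous":
            if self.per_genotype_mean_sd is None:
                raise ValueError("continuous mode needs per_genotype_mean_sd")
            for g in self.genotypes:
                if g not in self.per_genotype_mean_sd:
                    raise ValueError(f"no mean/sd for genotype {g!r}")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


def simulate_phenotypes(config: PhenotypeSimConfig) -> pd.DataFrame:
    """Draw a score table: columns genotype, score[, batch]."""
    rows: list[tuple] = []
    for gi, g in enumerate(config.genotypes):
        rng = _rng(config.rng_seed, _TAG_SCORES, gi)
        if config.mode == "ordinal":
            probs = np.asarray(config.per_genotype_category_probs[g], dtype=float)
            scores = rng.choice(4, size=config.n_per_genotype, p=probs / probs.sum())
        else:
            mean, sd = config.per_genotype_mean_sd[g]
            scores = rng.normal(mean, sd, size=config.n_per_genotype)
        batches = np.arange(config.n_per_genotype) % config.n_batches + 1
        for s, b in zip(scores, batches):
            val = int(s) if config.mode == "ordinal" else float(s)
            rows.append((g, val, int(b)))
    df = pd.DataFrame(rows, columns=["genotype", "score", "batch"])
    if config.n_batches == 1:
        df = df.drop(columns=["batch"])
    return df
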
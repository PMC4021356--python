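"""Multi-species interaction database, orthology collapsing, and seed networks.

The central object is the neighborhood of a three-gene seed set in a
multi-species interaction database: per species, every gene sharing an
edge with a seed orthologue is an interactor; interactors are collapsed to
human symbols through an orthology map, and each member's *seed valence*
is the number of distinct seed genes it touches, pooled across species.
A configurable number of connector ("augmented") genes — non-interactors
ranked by how many edges they have into the current network — can be
appended; they count toward network size but never toward valence.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

EVIDENCE_TYPES = frozenset(
    {"coexpression", "genetic", "physical", "shared_domain", "colocalization", "predicted"}
)

EDGE_COLUMNS = ["species", "gene_a", "gene_b", "evidence", "weight"]
ORTHOLOGY_COLUMNS = ["species", "species_gene", "human_symbol"]


@dataclass(frozen=True)
class InteractionRecord:
    """One undirected, evidence-typed edge between two genes in one species."""

    species: str
    gene_a: str
    gene_b: str
    evidence: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge on {self.gene_a}")
        if self.evidence not in EVIDENCE_TYPES:
            raise ValueError(f"unknown evidence type: {self.evidence!r}")
        if self.weight < 0:
            raise ValueError("edge weight must be non-negative")
        # canonical undirected ordering
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.species, self.gene_a, self.gene_b, self.evidence)


class OrthologyMap:
    """species-gene -> set of human symbols, with a reverse index.

    Lookups of unmapped genes return the empty set rather than failing;
    one-to-many mappings expand to every symbol.
    """

    def __init__(self, entries: Mapping[tuple[str, str], Iterable[str]] | None = None):
        self._fwd: dict[tuple[str, str], frozenset[str]] = {}
        self._rev: dict[str, set[tuple[str, str]]] = defaultdict(set)
        if entries:
            for (species, gene), symbols in entries.items():
                self.add(species, gene, symbols)

    def add(self, species: str, gene: str, symbols: Iterable[str]) -> None:
        syms = frozenset(s for s in symbols if s)
        key = (species, gene)
        merged = self._fwd.get(key, frozenset()) | syms
        self._fwd[key] = merged
        for s in syms:
            self._rev[s].add(key)

    def symbols_for(self, species: str, gene: str) -> frozenset[str]:
        return self._fwd.get((species, gene), frozenset())

    def genes_for_symbol(self, symbol: str) -> frozenset[tuple[str, str]]:
        return frozenset(self._rev.get(symbol, set()))

    def __len__(self) -> int:
        return len(self._fwd)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologyMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(ORTHOLOGY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"orthology TSV missing columns: {sorted(missing)}")
        m = cls()
        for row in df.itertuples(index=False):
            m.add(str(row.species), str(row.species_gene), [str(row.human_symbol)])
        return m

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sp, g, s)
            for (sp, g), syms in sorted(self._fwd.items())
            for s in sorted(syms)
        ]
        return pd.DataFrame(rows, columns=ORTHOLOGY_COLUMNS)


def load_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read the edges TSV, canonicalize, validate and deduplicate.

    Duplicate undirected edges of the same species and evidence are
    collapsed keeping the maximum weight; self-edges are dropped with a
    warning; an unknown evidence token raises an error naming the 1-based
    file line it occurs on.
    """
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in EDGE_COLUMNS[:4]})
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"edges TSV missing columns: {sorted(missing)}")
    records: dict[tuple, InteractionRecord] = {}
    n_dup = 0
    n_self = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        if row.evidence not in EVIDENCE_TYPES:
            raise ValueError(f"line {line_no}: unknown evidence type {row.evidence!r}")
        if row.gene_a == row.gene_b:
            n_self += 1
            continue
        rec = InteractionRecord(row.species, row.gene_a, row.gene_b, row.evidence, float(row.weight))
        prev = records.get(rec.key)
        if prev is None:
            records[rec.key] = rec
        else:
            n_dup += 1
            if rec.weight > prev.weight:
                records[rec.key] = rec
    if n_self:
        logger.warning("dropped %d self-edges", n_self)
    if n_dup:
        logger.info("collapsed %d duplicate undirected edges (kept max weight)", n_dup)
    return sorted(records.values(), key=lambda r: r.key)


def records_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.species, r.gene_a, r.gene_b, r.evidence, r.weight) for r in records],
        columns=EDGE_COLUMNS,
    )


class InteractionDb:
    """Indexed view of an interaction-record collection.

    Provides O(1) neighbor lookup per (species, gene); the index makes
    repeated seed-network extraction (the null ensembles build hundreds)
    cheap.
    """

    def __init__(self, records: Iterable[InteractionRecord]):
        self.records: list[InteractionRecord] = sorted(
            {r.key: r for r in records}.values(), key=lambda r: r.key
        )
        self._adj: dict[tuple[str, str], set[str]] = defaultdict(set)
        self._incident: dict[tuple[str, str], list[InteractionRecord]] = defaultdict(list)
        for r in self.records:
            self._adj[(r.species, r.gene_a)].add(r.gene_b)
            self._adj[(r.species, r.gene_b)].add(r.gene_a)
            self._incident[(r.species, r.gene_a)].append(r)
            self._incident[(r.species, r.gene_b)].append(r)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionDb":
        return cls(load_interactions(path))

    def neighbors(self, species: str, gene: str) -> set[str]:
        return self._adj.get((species, gene), set())

    def incident_edges(self, species: str, gene: str) -> list[InteractionRecord]:
        return self._incident.get((species, gene), [])

    def __len__(self) -> int:
        return len(self.records)


def collapse_to_human(
    genes: Iterable[tuple[str, str]], orthology: OrthologyMap
) -> frozenset[str]:
    """Union of human symbols over (species, gene) pairs.

    Unmapped genes contribute nothing and are counted in the log rather
    than silently absorbed.
    """
    out: set[str] = set()
    n_unmapped = 0
    for species, gene in genes:
        syms = orthology.symbols_for(species, gene)
        if not syms:
            n_unmapped += 1
        out |= syms
    if n_unmapped:
        logger.info("collapse_to_human: %d species genes had no human symbol", n_unmapped)
    return frozenset(out)


@dataclass(frozen=True)
class SeedNetwork:
    """Extracted neighborhood of a 3-gene seed set.

    ``seed_adjacency`` maps each non-seed interactor symbol to the set of
    seeds it touches (union over species). ``augmented`` genes are
    connectors appended after extraction; they are members but carry no
    valence.
    """

    seeds: tuple[str, str, str]
    members: frozenset[str]
    seed_adjacency: Mapping[str, frozenset[str]]
    augmented: frozenset[str] = frozenset()
    edges: tuple[InteractionRecord, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != 3:
            raise ValueError("exactly 3 distinct seeds required")
        if not set(self.seeds) <= self.members:
            raise ValueError("seeds must be members")
        bad = set(self.seed_adjacency) & set(self.seeds)
        if bad:
            raise ValueError(f"seeds cannot appear as interactors of themselves: {sorted(bad)}")
        if self.augmented & (set(self.seed_adjacency) | set(self.seeds)):
            raise ValueError("augmented genes must be disjoint from seeds and interactors")

    @property
    def interactors(self) -> frozenset[str]:
        return frozenset(self.seed_adjacency)

    def to_json(self, path: str | Path | None = None) -> dict:
        obj = {
            "seeds": sorted(self.seeds),
            "members": sorted(self.members),
            "seed_adjacency": {g: sorted(s) for g, s in sorted(self.seed_adjacency.items())},
            "augmented": sorted(self.augmented),
            "n_edges": len(self.edges),
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=2) + "\n")
        return obj

    @classmethod
    def from_json(cls, path: str | Path) -> "SeedNetwork":
        obj = json.loads(Path(path).read_text())
        return cls(
            seeds=tuple(obj["seeds"]),
            members=frozenset(obj["members"]),
            seed_adjacency={g: frozenset(s) for g, s in obj["seed_adjacency"].items()},
            augmented=frozenset(obj.get("augmented", [])),
        )


@dataclass(frozen=True)
class ValenceSummary:
    """Seed-valence counts of a network (total includes seeds and connectors)."""

    n_total: int
    n_interact_ge1: int
    n_exactly2: int
    n_exactly3: int

    def __post_init__(self) -> None:
        ok = (
            self.n_exactly3 <= self.n_exactly2 + self.n_exactly3
            <= self.n_interact_ge1 <= self.n_total - 3
        )
        if not ok or min(self.n_total, self.n_interact_ge1, self.n_exactly2, self.n_exactly3) < 0:
            raise ValueError(f"inconsistent valence counts: {self}")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_interact_ge1": self.n_interact_ge1,
            "n_exactly2": self.n_exactly2,
            "n_exactly3": self.n_exactly3,
        }


def _seed_orthologue_index(
    db: InteractionDb, seeds: Sequence[str], orthology: OrthologyMap
) -> dict[str, list[tuple[str, str]]]:
    """seed symbol -> list of (species, gene) orthologues present in the db."""
    out: dict[str, list[tuple[str, str]]] = {}
    for seed in seeds:
        pairs = sorted(orthology.genes_for_symbol(seed))
        if not pairs:
            raise ValueError(f"seed {seed!r} has no orthologue in the orthology map")
        out[seed] = pairs
    return out


def extract_seed_network(
    db: InteractionDb,
    seeds: Sequence[str],
    orthology: OrthologyMap,
    k_augment: int = 15,
) -> SeedNetwork:
    """Extract the seed network of three human-symbol seeds.

    Per species, every gene sharing an edge with a seed orthologue becomes
    an interactor; interactors are collapsed to human symbols and each
    symbol's adjacency is the union, over species, of the seeds it touches.
    ``k_augment`` connector symbols are then appended, ranked by their
    number of edges into the current members (ties broken lexicographically).
    Retained edges are those whose endpoints both collapse into the final
    member set (a seed orthologue endpoint collapses to its seed symbol).
    """
    seeds = tuple(seeds)
    if len(set(seeds)) != 3:
        raise ValueError("exactly 3 distinct seed symbols required")
    orth_index = _seed_orthologue_index(db, seeds, orthology)

    seed_adjacency: dict[str, set[str]] = defaultdict(set)
    for seed, pairs in orth_index.items():
        for species, gene in pairs:
            for nb in db.neighbors(species, gene):
                for sym in orthology.symbols_for(species, nb):
                    if sym not in seeds:
                        seed_adjacency[sym].add(seed)

    members: set[str] = set(seeds) | set(seed_adjacency)

    augmented: set[str] = set()
    if k_augment > 0:
        counts: dict[str, int] = defaultdict(int)
        member_sets = members
        for rec in db.records:
            syms_a = orthology.symbols_for(rec.species, rec.gene_a)
            syms_b = orthology.symbols_for(rec.species, rec.gene_b)
            for cand, other in ((syms_a, syms_b), (syms_b, syms_a)):
                if other & member_sets:
                    for sym in cand - member_sets:
                        counts[sym] += 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        augmented = {sym for sym, _ in ranked[:k_augment]}
        members |= augmented

    retained = tuple(
        rec
        for rec in db.records
        if (orthology.symbols_for(rec.species, rec.gene_a) & members)
        and (orthology.symbols_for(rec.species, rec.gene_b) & members)
    )
    return SeedNetwork(
        seeds=seeds,
        members=frozenset(members),
        seed_adjacency={g: frozenset(s) for g, s in seed_adjacency.items()},
        augmented=frozenset(augmented),
        edges=retained,
    )


def count_valence(net: SeedNetwork) -> ValenceSummary:
    """Count members by the number of distinct seeds they interact with."""
    valences = [len(s) for s in net.seed_adjacency.values()]
    return ValenceSummary(
        n_total=len(net.members),
        n_interact_ge1=sum(1 for v in valences if v >= 1),
        n_exactly2=sum(1 for v in valences if v == 2),
        n_exactly3=sum(1 for v in valences if v == 3),
    )


def summarize_evidence(net: SeedNetwork) -> dict[str, float]:
    """Fraction of retained edges per evidence type (sums to 1)."""
    if not net.edges:
        raise ValueError("network has no retained edges")
    counts: dict[str, int] = defaultdict(int)
    for rec in net.edges:
        counts[rec.evidence] += 1
    total = sum(counts.values())
    return {ev: c / total for ev, c in sorted(counts.items())}
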
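"""End-to-end runs: configuration, orchestration, reports, validation.

A run is described by a YAML config with up to three stages —
``interactome`` (seed-network extraction plus the randomly-seeded null
comparison), ``cnv`` (filter cascade plus burden tests) and
``phenotypes`` (ordinal score comparisons). Each stage either simulates
its inputs or loads them from the declared TSV/BED/CSV dialects. One
top-level seed fans out deterministically to per-stage sub-seeds, so a
single integer reproduces the whole report.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnv import (
    BedInterval,
    FilterThresholds,
    burden_test,
    calls_to_frame,
    filter_calls,
    gene_carriers,
    overall_rates,
    read_bed,
    read_calls,
    read_chrom_sizes,
)
from .interactome import (
    InteractionDb,
    OrthologyMap,
    count_valence,
    extract_seed_network,
    summarize_evidence,
)
from .nullmodel import build_null, compare_total_genes, compare_valence, sample_seed_sets
from .stats import kruskal_wallis, dunn_posthoc, mann_whitney
from .synthetic import (
    CnvSimConfig,
    InteractomeSimConfig,
    PhenotypeSimConfig,
    PlantedTriad,
    interactome_objects,
    simulate_cnv_cohort,
    simulate_phenotypes,
    symbol_pool,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys in {where}: {sorted(unknown)}")


def _stage_seed(seed: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated run configuration (see load_config for the schema)."""

    seed: int
    out_dir: Path
    interactome: Optional[dict] = None
    cnv: Optional[dict] = None
    phenotypes: Optional[dict] = None
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        # hash the analysis configuration only; output location is incidental
        payload = {k: v for k, v in self.raw.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_TOP_KEYS = {"seed", "out_dir", "interactome", "cnv", "phenotypes"}
_INTERACTOME_KEYS = {"simulate", "edges", "orthology", "seeds", "k_augment", "null_model"}
_NULL_KEYS = {"n_sets", "pool_label", "pool_file"}
_CNV_KEYS = {"simulate", "calls", "genes", "segdups", "chrom_sizes", "thresholds",
             "gene_set", "coverage", "one_based"}
_PHENO_KEYS = {"simulate", "scores", "design"}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    if "seed" not in raw:
        raise ConfigError("config missing required field: seed")
    cfg = RunConfig(
        seed=int(raw["seed"]),
        out_dir=Path(raw.get("out_dir", "seednet_run")),
        interactome=raw.get("interactome"),
        cnv=raw.get("cnv"),
        phenotypes=raw.get("phenotypes"),
        raw=raw,
    )
    base = Path(path).parent
    if cfg.interactome is not None:
        _check_keys(cfg.interactome, _INTERACTOME_KEYS, "interactome")
        if "seeds" not in cfg.interactome:
            raise ConfigError("config missing required field: interactome.seeds")
        if "simulate" not in cfg.interactome:
            for key in ("edges", "orthology"):
                if key not in cfg.interactome:
                    raise ConfigError(f"config missing required field: interactome.{key}")
                p = base / cfg.interactome[key]
                if not p.exists():
                    raise ConfigError(f"interactome.{key}: path does not exist: {p}")
                cfg.interactome[key] = str(p)
        if "null_model" in cfg.interactome:
            _check_keys(cfg.interactome["null_model"], _NULL_KEYS, "interactome.null_model")
    if cfg.cnv is not None:
        _check_keys(cfg.cnv, _CNV_KEYS, "cnv")
        if "simulate" not in cfg.cnv:
            for key in ("calls", "genes", "segdups", "chrom_sizes"):
                if key not in cfg.cnv:
                    raise ConfigError(f"config missing required field: cnv.{key}")
                p = base / cfg.cnv[key]
                if not p.exists():
                    raise ConfigError(f"cnv.{key}: path does not exist: {p}")
                cfg.cnv[key] = str(p)
    if cfg.phenotypes is not None:
        _check_keys(cfg.phenotypes, _PHENO_KEYS, "phenotypes")
        if "simulate" not in cfg.phenotypes:
            if "scores" not in cfg.phenotypes:
                raise ConfigError("config missing required field: phenotypes.scores")
            p = base / cfg.phenotypes["scores"]
            if not p.exists():
                raise ConfigError(f"phenotypes.scores: path does not exist: {p}")
            cfg.phenotypes["scores"] = str(p)
    return cfg


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _build_interactome_inputs(section: dict, stage_seed: int):
    if "simulate" in section:
        sim = dict(section["simulate"])
        planted = sim.pop("planted", None)
        if planted is not None:
            planted = PlantedTriad(
                seeds=tuple(planted["seeds"]),
                n_bivalent=int(planted.get("n_bivalent", 0)),
                n_univalent=int(planted.get("n_univalent", 0)),
            )
        sim_cfg = InteractomeSimConfig(
            genes_per_species=int(sim.pop("genes_per_species", 500)),
            species_list=tuple(sim.pop("species", ("sp1", "sp2", "sp3", "sp4", "sp5"))),
            orthology_coverage=float(sim.pop("orthology_coverage", 0.8)),
            edge_prob_by_evidence=sim.pop("edge_prob_by_evidence", None)
            or {ev: float(sim.pop("edge_prob", 0.002)) for ev in
                ("coexpression", "genetic", "physical", "shared_domain",
                 "colocalization", "predicted")},
            planted_triad=planted,
            rng_seed=int(sim.pop("rng_seed", stage_seed)),
        )
        if sim:
            raise ConfigError(f"unknown config keys in interactome.simulate: {sorted(sim)}")
        db, orthology = interactome_objects(sim_cfg)
        pool = symbol_pool(sim_cfg)
        return db, orthology, pool
    db = InteractionDb.from_tsv(section["edges"])
    orthology = OrthologyMap.from_tsv(section["orthology"])
    pool = sorted({s for r in db.records
                   for s in (orthology.symbols_for(r.species, r.gene_a)
                             | orthology.symbols_for(r.species, r.gene_b))})
    return db, orthology, pool


def run_interactome_stage(section: dict, stage_seed: int, out_dir: Path) -> dict:
    db, orthology, pool = _build_interactome_inputs(section, stage_seed)
    seeds = tuple(section["seeds"])
    k_augment = int(section.get("k_augment", 15))
    net = extract_seed_network(db, seeds, orthology, k_augment=k_augment)
    observed = count_valence(net)
    net.to_json(out_dir / "network.json")
    result: dict = {
        "seeds": list(seeds),
        "k_augment": k_augment,
        "observed_valence": observed.to_dict(),
        "evidence_fractions": summarize_evidence(net) if net.edges else {},
        "n_db_edges": len(db),
    }
    null_cfg = section.get("null_model")
    if null_cfg:
        n_sets = int(null_cfg.get("n_sets", 120))
        pool_label = null_cfg.get("pool_label", "genome_wide")
        if "pool_file" in null_cfg:
            pool = [line.strip() for line in Path(null_cfg["pool_file"]).read_text().splitlines()
                    if line.strip()]
        pool = [s for s in pool if s not in seeds]
        rng = np.random.default_rng(stage_seed)
        seed_sets = sample_seed_sets(pool, n_sets, rng)
        ensemble = build_null(db, orthology, seed_sets, k_augment=k_augment,
                              pool=pool, rng=rng, pool_label=pool_label,
                              rng_seed=stage_seed)
        result["null"] = {
            "pool_label": pool_label,
            "n_sets": n_sets,
            "mean_n_total": float(np.mean([s.n_total for s in ensemble.summaries])),
            "mean_n_interact_ge1": float(np.mean([s.n_interact_ge1 for s in ensemble.summaries])),
            "mean_n_exactly2": float(np.mean([s.n_exactly2 for s in ensemble.summaries])),
        }
        result["tests"] = {
            "total_genes_t": compare_total_genes(observed, ensemble).to_dict(),
            "ge1_fisher": compare_valence(observed, ensemble, "ge1", "fisher").to_dict(),
            "exactly2_fisher": compare_valence(observed, ensemble, "exactly2", "fisher").to_dict(),
        }
        try:
            result["tests"]["exactly2_t"] = compare_valence(
                observed, ensemble, "exactly2", "t").to_dict()
        except ValueError as e:
            result["tests"]["exactly2_t"] = {"error": str(e)}
    return result


def run_cnv_stage(section: dict, stage_seed: int, out_dir: Path) -> dict:
    thresholds = FilterThresholds(**section.get("thresholds", {}))
    if "simulate" in section:
        sim = dict(section["simulate"])
        genes = tuple(BedInterval(*g) for g in sim.pop("gene_models"))
        segdups = tuple(BedInterval(*s) for s in sim.pop("segdup_intervals", []))
        sim_cfg = CnvSimConfig(
            chrom_sizes=dict(sim.pop("chrom_sizes")),
            gene_models=genes,
            segdup_intervals=segdups,
            rng_seed=int(sim.pop("rng_seed", stage_seed)),
            **{k: v for k, v in sim.items()},
        )
        calls, meta = simulate_cnv_cohort(sim_cfg)
        chrom_sizes = dict(sim_cfg.chrom_sizes)
        gene_models = list(genes)
        segdup_list = list(segdups)
        case_n: int | dict = meta["case_n_by_gene"] if section.get("coverage") else meta["case_n"]
        control_n = meta["control_n"]
    else:
        calls = read_calls(section["calls"], one_based=bool(section.get("one_based", False)))
        gene_models = read_bed(section["genes"])
        segdup_list = read_bed(section["segdups"])
        chrom_sizes = read_chrom_sizes(section["chrom_sizes"])
        control_n = len({c.sample_id for c in calls if c.cohort == "control"})
        case_n = len({c.sample_id for c in calls if c.cohort == "case"})
        if "coverage" in section:
            cov = pd.read_csv(section["coverage"], sep="\t")
            case_n = dict(zip(cov.iloc[:, 0], cov.iloc[:, 1].astype(int)))

    surviving, audit = filter_calls(calls, segdup_list, chrom_sizes, thresholds,
                                    control_n=control_n)
    audit.to_csv(out_dir / "cnv_audit.tsv", sep="\t", index=False)
    calls_to_frame(surviving).to_csv(out_dir / "cnv_surviving.tsv", sep="\t", index=False)
    gene_set = section.get("gene_set") or sorted({g.name for g in gene_models})
    carriers = gene_carriers(surviving, gene_models, thresholds.min_gene_overlap_bp)
    per_gene, combined = burden_test(carriers, case_n, control_n, gene_set)
    pd.DataFrame([r.to_dict() | {"p_value": r.test.p_value} for r in per_gene.values()]).to_csv(
        out_dir / "cnv_burden.tsv", sep="\t", index=False)
    scalar_case_n = max(case_n.values()) if isinstance(case_n, dict) else case_n
    return {
        "thresholds": thresholds.__dict__,
        "n_calls": len(calls),
        "n_surviving": len(surviving),
        "removed_by_rule": audit["failed_rule"].value_counts().to_dict() if len(audit) else {},
        "per_gene": {g: r.to_dict() for g, r in per_gene.items()},
        "combined": combined.to_dict(),
        "overall_rates": overall_rates(surviving, gene_models, scalar_case_n, control_n,
                                       thresholds.min_gene_overlap_bp),
    }


def run_phenotype_stage(section: dict, stage_seed: int, out_dir: Path) -> dict:
    if "simulate" in section:
        sim = dict(section["simulate"])
        cfg = PhenotypeSimConfig(
            genotypes=tuple(sim.pop("genotypes")),
            n_per_genotype=int(sim.pop("n_per_genotype")),
            mode=sim.pop("mode", "ordinal"),
            per_genotype_category_probs=sim.pop("per_genotype_category_probs", None),
            per_genotype_mean_sd=sim.pop("per_genotype_mean_sd", None),
            n_batches=int(sim.pop("n_batches", 1)),
            rng_seed=int(sim.pop("rng_seed", stage_seed)),
        )
        if sim:
            raise ConfigError(f"unknown config keys in phenotypes.simulate: {sorted(sim)}")
        scores = simulate_phenotypes(cfg)
    else:
        scores = pd.read_csv(section["scores"])
    scores.to_csv(out_dir / "scores.csv", index=False)
    design = section.get("design", "pairwise")
    groups = {g: sub["score"].to_numpy() for g, sub in scores.groupby("genotype", sort=True)}
    names = sorted(groups)
    result: dict = {"design": design, "genotypes": names,
                    "n_per_genotype": {g: int(len(v)) for g, v in groups.items()}}
    if design == "pairwise":
        result["comparisons"] = {
            f"{a}_vs_{b}": mann_whitney(groups[a], groups[b]).to_dict()
            for a, b in itertools.combinations(names, 2)
        }
    elif design == "omnibus":
        ordered = [groups[g] for g in names]
        result["omnibus"] = kruskal_wallis(ordered).to_dict()
        result["posthoc"] = {
            f"{names[i]}_vs_{names[j]}": r.to_dict()
            for (i, j), r in dunn_posthoc(ordered).items()
        }
    else:
        raise ConfigError(f"unknown phenotypes.design {design!r}")
    return result


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and write the run report.

    Partial outputs are retained on failure; the raised StageError names
    the failing stage. The report is written to ``<out_dir>/report.json``
    and is byte-identical across runs with the same config and seed apart
    from the provenance timestamp.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "seednet_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
    }
    stages = [
        ("interactome", config.interactome, run_interactome_stage, 1),
        ("cnv", config.cnv, run_cnv_stage, 2),
        ("phenotypes", config.phenotypes, run_phenotype_stage, 3),
    ]
    for name, section, runner, idx in stages:
        if section is None:
            continue
        logger.info("running stage %s", name)
        try:
            report[name] = runner(section, _stage_seed(config.seed, idx), out_dir)
        except Exception as e:  # partial outputs stay on disk
            (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
            raise StageError(name, e) from e
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# ---------------------------------------------------------------------------
# Report validation
# ---------------------------------------------------------------------------

def _collect_p_values(obj: Any, path: str = "") -> list[tuple[str, Any]]:
    out = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            sub = f"{path}.{k}" if path else str(k)
            if k == "p_value":
                out.append((sub, v))
            else:
                out.extend(_collect_p_values(v, sub))
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            out.extend(_collect_p_values(v, f"{path}[{i}]"))
    return out


def validate_report(path: str | Path) -> tuple[bool, list[str]]:
    """Schema/invariant checks on a run report.

    Verifies that every p-value lies in [0, 1], every valence summary
    satisfies the chain inequality, and every burden result has carriers
    within its denominator. Returns (ok, messages).
    """
    messages: list[str] = []
    try:
        report = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        return False, [f"malformed JSON at line {e.lineno}, column {e.colno}: {e.msg}"]
    if "provenance" not in report:
        messages.append("missing provenance block")
    for where, p in _collect_p_values(report):
        if not isinstance(p, (int, float)) or not (0.0 <= p <= 1.0):
            messages.append(f"p-value out of [0, 1] at {where}: {p}")

    def check_valence(d: dict, where: str) -> None:
        try:
            ok = (d["n_exactly3"] <= d["n_exactly2"] + d["n_exactly3"]
                  <= d["n_interact_ge1"] <= d["n_total"] - 3)
        except (KeyError, TypeError):
            messages.append(f"malformed valence summary at {where}")
            return
        if not ok:
            messages.append(f"valence chain inequality violated at {where}: {d}")

    if "interactome" in report and "observed_valence" in report["interactome"]:
        check_valence(report["interactome"]["observed_valence"], "interactome.observed_valence")
    if "cnv" in report:
        burdens = list(report["cnv"].get("per_gene", {}).items())
        if "combined" in report["cnv"]:
            burdens.append(("combined", report["cnv"]["combined"]))
        for g, b in burdens:
            if b["case_carriers"] > b["case_n"] or b["control_carriers"] > b["control_n"]:
                messages.append(f"carrier count exceeds denominator for {g}")
    return (len(messages) == 0), messages
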
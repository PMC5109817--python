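"""Config-driven orchestration: simulate/load -> QC -> diversity ->
clustering -> core selection -> evaluation, with a run manifest.

The config is a YAML key/value tree validated fail-closed (unknown keys
are errors).  Either a ``simulate`` block (simulator parameters) or an
``input`` block (paths to genotype/phenotype/passport files) provides the
collection.  Reruns with the same config and seed are bit-identical; the
manifest embeds the config echo, its hash, the seed, and versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .diversity import amova, fst_per_cluster, group_diversity
from .distance import (
    cut_tree,
    export_newick,
    manhattan_dissimilarity,
    nj_tree,
    pcoa,
    upgma_tree,
)
from .evaluation import evaluate_core
from .model import (
    Collection,
    merge_collection,
    read_genotypes,
    read_passport,
    read_phenotypes,
    read_trait_schema,
    write_genotypes,
    write_passport,
    write_phenotypes,
    write_trait_schema,
)
from .qc import apply_qc
from .selection import STRATEGIES, run_strategy
from .simulate import SimulationConfig, default_paper_like_config, simulate_collection

logger = logging.getLogger("germcore")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "germcore_out"
    simulate: dict | None = None  # SimulationConfig overrides, or {} for defaults
    input: dict | None = None  # {genotypes, phenotypes?, schema?, passport?, holdouts?}
    qc: dict = field(default_factory=lambda: {"het_threshold": 0.3, "max_missing": 7})
    clustering: dict = field(default_factory=lambda: {"method": "upgma", "k": 5})
    strategies: list[str] = field(default_factory=lambda: list(STRATEGIES))
    evaluation: dict = field(
        default_factory=lambda: {"md_form": "relative", "imax_convention": "fixed"}
    )
    nj: bool = True
    pcoa_axes: int = 2
    amova_permutations: int = 199
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_KNOWN_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}
_QC_KEYS = {"het_threshold", "max_missing"}
_CLUSTER_KEYS = {"method", "k"}
_EVAL_KEYS = {"md_form", "imax_convention"}
_INPUT_KEYS = {"genotypes", "phenotypes", "schema", "passport", "holdouts"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)} | {"paper_like"}


def validate_config(source) -> PipelineConfig:
    """Load and validate a pipeline config (path, YAML string, or dict).

    Unknown keys anywhere in the tree are rejected, naming the key path.
    A missing seed defaults to 0 and is recorded in the manifest.
    """
    if isinstance(source, dict):
        raw = source
    else:
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    def check(d: dict, allowed: set[str], where: str) -> None:
        for k in d:
            if k not in allowed:
                raise ConfigError(f"unknown config key: {where}{k}")

    check(raw, _KNOWN_KEYS, "")
    for key, allowed in (
        ("qc", _QC_KEYS),
        ("clustering", _CLUSTER_KEYS),
        ("evaluation", _EVAL_KEYS),
        ("input", _INPUT_KEYS),
        ("simulate", _SIM_KEYS),
    ):
        if isinstance(raw.get(key), dict):
            check(raw[key], allowed, f"{key}.")
    cfg = PipelineConfig(**{**{k: v for k, v in raw.items()}})
    defaults = PipelineConfig()
    cfg.qc = {**defaults.qc, **(cfg.qc or {})}
    cfg.clustering = {**defaults.clustering, **(cfg.clustering or {})}
    cfg.evaluation = {**defaults.evaluation, **(cfg.evaluation or {})}
    if cfg.simulate is None and cfg.input is None:
        raise ConfigError("config must provide either 'simulate' or 'input'")
    if cfg.input is not None:
        if "genotypes" not in cfg.input:
            raise ConfigError("input.genotypes is required")
        for k, v in cfg.input.items():
            if v and not Path(v).exists():
                raise ConfigError(f"input.{k}: path does not exist: {v}")
    for s in cfg.strategies:
        if s not in STRATEGIES:
            raise ConfigError(f"unknown strategy {s!r}")
    if cfg.clustering.get("method") not in ("upgma",):
        raise ConfigError("clustering.method must be 'upgma' (cores need a rooted cut)")
    return cfg


def _load_collection(cfg: PipelineConfig) -> Collection:
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        if sim.pop("paper_like", False):
            sc = default_paper_like_config(seed=cfg.seed)
            for k, v in sim.items():
                setattr(sc, k, v)
        else:
            sc = SimulationConfig(**sim)
        if "seed" not in sim:
            sc.seed = cfg.seed
        collection, _ = simulate_collection(sc)
        return collection
    inp = cfg.input or {}
    g = read_genotypes(inp["genotypes"])
    phen = None
    if inp.get("phenotypes"):
        schema = read_trait_schema(inp["schema"])
        phen = read_phenotypes(inp["phenotypes"], schema)
    pp = read_passport(inp["passport"]) if inp.get("passport") else None
    ho = read_genotypes(inp["holdouts"]) if inp.get("holdouts") else None
    return merge_collection(g, phen, pp, ho)


def _write_csv(path: Path, rows: list[dict]) -> None:
    import csv

    if not rows:
        path.write_text("")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full workflow; returns the output directory.

    Stages: (simulate | load) -> QC -> diversity tables -> Manhattan
    dissimilarity -> UPGMA (+ optional NJ) trees -> tree-cut clusters ->
    AMOVA -> PCoA -> one core per strategy -> per-core evaluation ->
    cross-strategy comparison -> manifest.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        collection = _load_collection(cfg)
        if cfg.simulate is not None:
            write_genotypes(collection.genotypes, out / "genotypes.csv")
            if collection.phenotypes is not None:
                write_phenotypes(collection.phenotypes, out / "phenotypes.csv")
                write_trait_schema(collection.phenotypes.traits, out / "trait_schema.json")
            if collection.passport is not None:
                write_passport(collection.passport, out / "passport.csv")
            if collection.holdout_genotypes is not None:
                write_genotypes(collection.holdout_genotypes, out / "holdout_genotypes.csv")

        stage = "qc"
        qc = apply_qc(collection.genotypes, **cfg.qc)
        _write_csv(out / "qc_report.csv", qc.to_rows())
        retained = collection.subset(qc.retained_ids)
        logger.info(
            "QC: %d accessions -> %d retained (%d hybrid, %d high-missing)",
            collection.genotypes.n_accessions,
            len(qc.retained_ids),
            qc.n_hybrid,
            qc.n_high_missing,
        )

        stage = "diversity"
        grouping = "species" if retained.passport is not None else "total"
        rows = [dataclasses.asdict(s) for s in group_diversity(retained, grouping)]
        _write_csv(out / "diversity_by_species.csv", rows)

        stage = "distance"
        D = manhattan_dissimilarity(retained.genotypes)

        stage = "clustering"
        ut = upgma_tree(D)
        export_newick(ut, out / "upgma.nwk")
        if cfg.nj and len(D.ids) >= 3:
            export_newick(nj_tree(D), out / "nj.nwk")
        k = int(cfg.clustering.get("k", 5))
        clusters = cut_tree(ut, k)
        _write_csv(
            out / "clusters.csv",
            [{"accession": a, "cluster": c} for a, c in clusters.labels.items()],
        )
        cl = fst_per_cluster(retained.genotypes, clusters.labels)
        _write_csv(
            out / "diversity_by_cluster.csv",
            [
                {"cluster": lab, "n": cl.n[lab], "H_E": cl.H_E[lab],
                 "I": cl.I[lab], "F_ST": cl.F_ST[lab]}
                for lab in cl.labels
            ],
        )
        # AMOVA needs >=2 accessions per group; singleton clusters are dropped
        sizes: dict[object, int] = {}
        for c in clusters.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        usable = [a for a, c in clusters.labels.items() if sizes[c] >= 2]
        if len({clusters.labels[a] for a in usable}) >= 2:
            am = amova(
                D.subset(usable),
                {a: clusters.labels[a] for a in usable},
                n_perm=cfg.amova_permutations,
                seed=cfg.seed,
            )
            payload = dataclasses.asdict(am)
            if len(usable) < len(D.ids):
                payload["n_dropped_singletons"] = len(D.ids) - len(usable)
            (out / "amova.json").write_text(json.dumps(payload, indent=2))
        else:
            (out / "amova.json").write_text(
                json.dumps({"skipped": "fewer than two clusters of size >= 2"})
            )

        stage = "pcoa"
        pc = pcoa(D, n_axes=cfg.pcoa_axes)
        pc_rows = [
            {"accession": a, **{f"axis{t + 1}": float(pc.coordinates[i, t])
                                for t in range(pc.coordinates.shape[1])}}
            for i, a in enumerate(pc.ids)
        ]
        _write_csv(out / "pcoa.csv", pc_rows)
        (out / "pcoa_variance.json").write_text(
            json.dumps({"pct_variance": [float(x) for x in pc.pct_variance]})
        )

        stage = "selection"
        comparison = []
        for strat in cfg.strategies:
            core = run_strategy(retained, strat, clusters=clusters)
            _write_csv(
                out / f"core_{strat.replace('+', 'p')}.csv",
                [
                    {"accession": a, "strategy": strat,
                     "cluster": core.cluster_of.get(a, "")}
                    for a in core.selected_ids
                ],
            )
            stage = "evaluation"
            rep = evaluate_core(
                core,
                retained,
                md_form=cfg.evaluation["md_form"],
                imax_convention=cfg.evaluation["imax_convention"],
            )
            row = {
                "strategy": strat,
                "n_entries": rep.n_core,
                "pct_of_entire": round(rep.pct_of_entire, 2),
                "classes_covered": core.classes_covered,
                "classes_total": core.classes_total,
                "MD_pct": round(rep.MD, 2),
                "CR_pct": round(rep.CR, 2),
                "VD_pct": round(rep.VD, 2),
                "VR_pct": round(rep.VR, 2),
                "I": round(rep.categorical.I_core, 2),
                "I_entire": round(rep.categorical.I_entire, 2),
                "I_max": round(rep.categorical.I_max, 2),
                "J_prime": round(rep.categorical.J_core, 2),
                "J_prime_entire": round(rep.categorical.J_entire, 2),
                "representative": rep.representative,
            }
            if rep.holdout is not None:
                avg = rep.holdout.averages()
                row["holdout_J_core"] = round(avg["J_core"], 2)
                row["holdout_J_entire"] = round(avg["J_entire"], 2)
            comparison.append(row)
            stage = "selection"
        _write_csv(out / "strategy_comparison.csv", comparison)

        stage = "manifest"
        manifest = {
            "germcore_version": __version__,
            "numpy_version": np.__version__,
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
            "config_hash": cfg.config_hash(),
            "n_accessions_input": collection.genotypes.n_accessions,
            "n_retained": len(qc.retained_ids),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
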
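"""End-to-end orchestration: simulate -> contrasts -> DEGs -> consensus ->
cross-validation -> panel minimization -> TF network, with a reproducible
summary.

One global seed fans out to per-stage seeds through ``numpy.random.
SeedSequence(seed).spawn``-style keys, so stages are independently
reproducible. Every run writes the resolved configuration next to its
outputs together with a machine-readable summary JSON.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, degs, io, network, preprocess, simulate
from .datatypes import CLASS_A, CLASS_B, ValidationError

log = logging.getLogger("toxclass")

SUMMARY_SCHEMA_VERSION = 1

_STAGES = ("simulate", "preprocess", "degs", "crossval", "minimize", "network")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = _STAGES.index(stage)
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=(idx,)).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    out_dir: str = "toxclass_run"
    seed: int = 0
    # inputs: either simulate=True or paths to expr/meta/annot TSVs
    simulate: bool = True
    expr_path: str | None = None
    meta_path: str | None = None
    annot_path: str | None = None
    # synthetic-data knobs (None -> generator defaults)
    n_probesets: int | None = None
    residual_sd: float | None = None
    # thresholds
    fc_threshold: float = degs.DEFAULT_FC_THRESHOLD
    alpha: float = degs.DEFAULT_ALPHA
    min_compounds: int = degs.DEFAULT_MIN_COMPOUNDS
    n_features: int = classify.DEFAULT_N_FEATURES
    retention: float = network.DEFAULT_RETENTION
    mi_k: int = network.DEFAULT_K
    # stage toggles
    run_combat: bool = False
    crossval_n: tuple[int, ...] = (1, 2)
    run_minimize: bool = False
    minimize_sizes: tuple[int, ...] | None = None
    run_network: bool = False
    network_samples: int = 200
    tune_folds: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("crossval_n", "minimize_sizes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["crossval_n"] = list(d["crossval_n"])
        if d["minimize_sizes"] is not None:
            d["minimize_sizes"] = list(d["minimize_sizes"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _stage(name: str):
    """Decorator-free stage wrapper: logs timing and re-raises with context."""

    class _ctx:
        def __init__(self):
            self.t0 = None

        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
                return False
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    return _ctx()


def run_all(config: RunConfig) -> dict:
    """Execute the toggled stages and write the report bundle.

    Returns the summary dict (also written to ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
    }

    with _stage("simulate" if config.simulate else "load"):
        if config.simulate:
            kwargs = {}
            if config.n_probesets is not None:
                kwargs["n_probesets"] = config.n_probesets
            if config.residual_sd is not None:
                kwargs["residual_sd"] = config.residual_sd
            cfg = simulate.SyntheticConfig(
                seed=stage_seed(config.seed, "simulate"), **kwargs
            )
            expr, meta, annot, truth = simulate.generate_dataset(cfg)
            io.write_matrix(expr, out / "expression.tsv")
            io.write_sample_metadata(meta, out / "metadata.tsv")
            io.write_annotation(annot, out / "annotation.tsv")
            io.write_json(
                {
                    "shared_signatures": truth.shared_signatures,
                    "compound_effects": truth.compound_effects,
                },
                out / "truth.json",
            )
        else:
            for label, p in (
                ("expression", config.expr_path),
                ("metadata", config.meta_path),
                ("annotation", config.annot_path),
            ):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{label} file missing: {p}")
            expr = io.read_expression_matrix(config.expr_path)
            meta = io.read_sample_metadata(config.meta_path)
            annot = io.read_annotation(config.annot_path)
        summary["stages"]["data"] = {
            "n_probesets": expr.shape[0],
            "n_samples": expr.shape[1],
            "n_compounds": len(meta.compounds),
        }

    with _stage("preprocess"):
        contrasts = preprocess.subtract_controls(expr, meta)
        io.write_matrix(contrasts, out / "contrasts.tsv")
        if config.run_combat:
            adjusted, _ = preprocess.combat_adjust(expr, meta)
            io.write_matrix(adjusted, out / "expression_combat.tsv")
        pca_res = preprocess.pca(contrasts, n_components=2)
        pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        summary["stages"]["preprocess"] = {
            "n_contrast_columns": contrasts.shape[1],
            "pc1_explained": float(pca_res.explained_variance_ratio[0]),
        }

    with _stage("degs"):
        deg_table = degs.moderated_t(contrasts, meta)
        calls = degs.call_degs(
            deg_table, annot, fc_threshold=config.fc_threshold, alpha=config.alpha
        )
        deg_counts = {
            c: len(calls.gene_calls.get(c, {})) for c in meta.compounds
        }
        class_compounds = {
            CLASS_A: [c for c in meta.compounds if meta.class_of(c) == CLASS_A],
            CLASS_B: [c for c in meta.compounds if meta.class_of(c) == CLASS_B],
        }
        consensus_sets = []
        consensus_sizes = {}
        for cls, comps in class_compounds.items():
            if len(comps) >= config.min_compounds:
                up, down = degs.consensus_genes(
                    calls, comps, cls, m=config.min_compounds
                )
                consensus_sets += [up.as_gene_set(), down.as_gene_set()]
                consensus_sizes[cls] = {"up": len(up), "down": len(down)}
        io.write_gene_sets(consensus_sets, out / "consensus.gmt")
        summary["stages"]["degs"] = {
            "deg_counts": deg_counts,
            "consensus_sizes": consensus_sizes,
        }

    with _stage("crossval"):
        cv_summary = {}
        for n in config.crossval_n:
            res = classify.leave_n_out(
                contrasts,
                meta,
                n=n,
                n_features=config.n_features,
                folds=config.tune_folds,
                seed=stage_seed(config.seed, "crossval"),
            )
            cv_summary[f"leave_{n}_out"] = {
                "n_compound_predictions": res.n_compound_predictions,
                "n_replicate_predictions": res.n_replicate_predictions,
                "compound_accuracy": res.compound_accuracy,
                "replicate_accuracy": res.replicate_accuracy,
            }
        io.write_json(cv_summary, out / "crossval.json")
        summary["stages"]["crossval"] = cv_summary

    if config.run_minimize:
        with _stage("minimize"):
            curve = classify.minimize_panel(
                contrasts,
                meta,
                start_size=config.n_features,
                panel_sizes=(
                    list(config.minimize_sizes) if config.minimize_sizes else None
                ),
                folds=config.tune_folds,
                seed=stage_seed(config.seed, "minimize"),
            )
            curve.table.to_csv(out / "predictivity_curve.tsv", sep="\t", index=False)
            summary["stages"]["minimize"] = {
                "panel_sizes": list(curve.table["panel_size"]),
                "loo_accuracy": list(curve.table["loo_accuracy"]),
            }

    if config.run_network:
        with _stage("network"):
            coexpr, modules = simulate.generate_coexpression_dataset(
                n_samples=config.network_samples,
                modules=[(12, 0.85), (10, 0.85), (8, 0.8)],
                n_background_genes=30,
                seed=stage_seed(config.seed, "network"),
            )
            net, mi, clr = network.build_tf_network(
                coexpr,
                k=config.mi_k,
                retention=0.05,
                seed=stage_seed(config.seed, "network"),
            )
            net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
            summary["stages"]["network"] = {
                "n_nodes": len(net.nodes),
                "n_edges": net.n_edges,
                "n_communities": len(set(net.communities.values())),
                "modularity": net.modularity,
            }

    io.write_json(summary, out / "summary.json")
    return summary
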
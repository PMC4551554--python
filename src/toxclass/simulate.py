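"""Synthetic expression data with the statistical structure the analysis assumes.

The generator emulates a two-class microarray toxicology study: two groups
of six compounds each, four biological replicates per compound (five for
two of them), 35 untreated controls, and two measurement batches that shift
and rescale every probe set. Treated samples carry a class-shared signature
(each compound expresses a random ~80% of it) plus compound-private
deregulation whose size varies over an order of magnitude between
compounds. All noise is Gaussian on the log2 scale and every draw is
deterministic under the config seed.

A second generator emits latent-factor co-expression data for the network
stage: genes in a module are noisy linear functions of one shared factor,
so the expected within-module Pearson correlation is the square of the
gene-factor loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CLASS_A,
    CLASS_B,
    CONTROL,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleMetadata,
    ValidationError,
)


@dataclass(frozen=True)
class CompoundSpec:
    """One test compound: its class, replicate count and private signature."""

    name: str
    class_label: str
    n_replicates: int = 4
    n_private: int = 500
    private_effect_log2: float = 1.0  # mean |log2 FC| of private probes


# Study-shaped default design: 6 + 6 compounds, 4 replicates each with one
# extra replicate for two compounds (50 treated arrays), private signature
# sizes spanning a few hundred to a few thousand probes.
DEFAULT_COMPOUNDS: tuple[CompoundSpec, ...] = (
    CompoundSpec("belinostat", CLASS_A, 4, 150),
    CompoundSpec("entinostat", CLASS_A, 4, 900),
    CompoundSpec("panobinostat", CLASS_A, 4, 1500),
    CompoundSpec("SAHA", CLASS_A, 4, 300),
    CompoundSpec("TSA", CLASS_A, 5, 2200),
    CompoundSpec("VPA", CLASS_A, 4, 3000),
    CompoundSpec("HgBr2", CLASS_B, 4, 600),
    CompoundSpec("HgCl2", CLASS_B, 4, 100),
    CompoundSpec("MeHg", CLASS_B, 5, 400),
    CompoundSpec("PCMB", CLASS_B, 4, 700),
    CompoundSpec("PMA", CLASS_B, 4, 2500),
    CompoundSpec("thimerosal", CLASS_B, 4, 150),
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Effect sizes are |log2 fold changes|; noise and batch offsets are in
    log2 units. ``shared_effect_range`` bounds the magnitude of the
    class-shared signature probes (strong, class-defining effects);
    private effects follow a Gamma(2, mean/2) magnitude distribution so
    that many are small, which reproduces heterogeneous per-compound DEG
    counts.
    """

    n_probesets: int = 10000
    n_genes: int = 8000
    compounds: tuple[CompoundSpec, ...] = DEFAULT_COMPOUNDS
    n_controls: int = 35
    n_batches: int = 2
    n_shared_per_class: int = 300
    shared_inclusion_prob: float = 0.8
    shared_effect_range: tuple[float, float] = (1.5, 2.5)
    batch_location_sd: float = 0.5
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    residual_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    unannotated_fraction: float = 0.1
    two_control_prob: float = 0.8  # fraction of treated samples matched to 2 controls
    seed: int = 0

    def __post_init__(self):
        if self.n_probesets < 1 or self.n_genes < 1 or self.n_controls < 1:
            raise ValidationError("all counts must be positive")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")
        if not self.compounds:
            raise ValidationError("at least one compound required")
        for cls in {c.class_label for c in self.compounds}:
            if sum(1 for c in self.compounds if c.class_label == cls) < 1:
                raise ValidationError(f"class {cls} has no compounds")
        for c in self.compounds:
            if c.n_replicates < 1 or c.n_private < 0:
                raise ValidationError(f"invalid compound spec {c.name}")
            if c.private_effect_log2 < 0:
                raise ValidationError(f"negative effect size for {c.name}")
        if self.n_shared_per_class < 0:
            raise ValidationError("n_shared_per_class must be >= 0")
        n_classes = len({c.class_label for c in self.compounds})
        max_priv = max((c.n_private for c in self.compounds), default=0)
        if n_classes * self.n_shared_per_class + max_priv > self.n_probesets:
            raise ValidationError("signatures do not fit into n_probesets")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the matrices.

    ``compound_effects`` maps compound -> {probe_id: signed log2 effect}
    (shared-signature probes the compound expresses plus its private
    probes); ``shared_signatures`` maps class -> {probe_id: signed effect}.
    """

    compound_effects: dict[str, dict[str, float]]
    shared_signatures: dict[str, dict[str, float]]
    batch_location: pd.DataFrame  # probe x batch additive offsets
    batch_scale: pd.DataFrame  # probe x batch noise scale factors

    def consensus_truth(self, class_label: str, compounds: Sequence[str], m: int = 4):
        """Probes truly deregulated in the same direction by >= m compounds."""
        up: dict[str, int] = {}
        down: dict[str, int] = {}
        for comp in compounds:
            for probe, eff in self.compound_effects[comp].items():
                tgt = up if eff > 0 else down
                tgt[probe] = tgt.get(probe, 0) + 1
        return (
            {p for p, k in up.items() if k >= m},
            {p for p, k in down.items() if k >= m},
        )


def generate_dataset(config: SyntheticConfig):
    """Draw one synthetic study.

    Returns ``(ExpressionMatrix, SampleMetadata, ProbeAnnotation,
    SyntheticTruth)``. Control samples carry baseline + batch effect +
    noise; treated samples additionally carry their compound's shared and
    private effects. Batch assignment is stratified so every compound and
    the controls span all batches where replicate counts allow.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_probesets
    probe_ids = [f"PS{i:05d}" for i in range(1, G + 1)]

    # --- annotation: many-to-one probe -> gene, a fraction unannotated
    gene_pool = [f"GENE{i:05d}" for i in range(1, config.n_genes + 1)]
    gene_idx = rng.integers(0, config.n_genes, size=G)
    unannotated = rng.random(G) < config.unannotated_fraction
    mapping = {
        p: (None if u else gene_pool[g])
        for p, g, u in zip(probe_ids, gene_idx, unannotated)
    }
    annotation = ProbeAnnotation(mapping)

    # --- signatures: disjoint shared blocks per class, privates drawn from the rest
    classes = []
    for c in config.compounds:
        if c.class_label not in classes:
            classes.append(c.class_label)
    probe_perm = rng.permutation(G)
    shared_signatures: dict[str, dict[str, float]] = {}
    cursor = 0
    for cls in classes:
        idx = probe_perm[cursor : cursor + config.n_shared_per_class]
        cursor += config.n_shared_per_class
        lo, hi = config.shared_effect_range
        mags = rng.uniform(lo, hi, size=len(idx))
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        shared_signatures[cls] = {
            probe_ids[i]: float(s * m) for i, s, m in zip(idx, signs, mags)
        }
    background = probe_perm[cursor:]

    compound_effects: dict[str, dict[str, float]] = {}
    for c in config.compounds:
        effects: dict[str, float] = {}
        shared = shared_signatures[c.class_label]
        keep = rng.random(len(shared)) < config.shared_inclusion_prob
        for (probe, eff), k in zip(shared.items(), keep):
            if k:
                effects[probe] = eff
        if c.n_private:
            priv_idx = rng.choice(background, size=c.n_private, replace=False)
            mags = rng.gamma(2.0, c.private_effect_log2 / 2.0, size=c.n_private)
            signs = rng.choice([-1.0, 1.0], size=c.n_private)
            for i, s, m in zip(priv_idx, signs, mags):
                effects[probe_ids[i]] = float(s * m)
        compound_effects[c.name] = effects

    # --- batch parameters (batch 1 is the reference)
    batch_ids = [f"B{i}" for i in range(1, config.n_batches + 1)]
    loc = np.zeros((G, config.n_batches))
    scale = np.ones((G, config.n_batches))
    for b in range(1, config.n_batches):
        loc[:, b] = rng.normal(0.0, config.batch_location_sd, size=G)
        scale[:, b] = rng.uniform(*config.batch_scale_range, size=G)
    batch_location = pd.DataFrame(loc, index=probe_ids, columns=batch_ids)
    batch_scale = pd.DataFrame(scale, index=probe_ids, columns=batch_ids)

    # --- sample layout: controls first, then compounds; stratified batches
    rows = []
    control_ids = [f"CTRL{i:02d}" for i in range(1, config.n_controls + 1)]
    controls_by_batch: dict[int, list[str]] = {b: [] for b in range(config.n_batches)}
    for i, sid in enumerate(control_ids):
        b = i % config.n_batches
        controls_by_batch[b].append(sid)
        rows.append((sid, CONTROL, CONTROL, batch_ids[b], i + 1, []))
    treated_batches: dict[str, int] = {}
    for ci, c in enumerate(config.compounds):
        for r in range(c.n_replicates):
            sid = f"{c.name}_r{r + 1}"
            b = (r + ci) % config.n_batches  # stratified: replicates span batches
            treated_batches[sid] = b
            n_ctrl = 2 if rng.random() < config.two_control_prob else 1
            pool = controls_by_batch[b]
            picks = rng.choice(len(pool), size=min(n_ctrl, len(pool)), replace=False)
            matched = [pool[i] for i in sorted(picks)]
            rows.append((sid, c.name, c.class_label, batch_ids[b], r + 1, matched))
    meta = SampleMetadata(
        pd.DataFrame(rows, columns=SampleMetadata.COLUMNS)
    )

    # --- expression values
    baseline = rng.uniform(*config.baseline_mean_range, size=G)
    sample_ids = meta.sample_ids
    values = np.empty((G, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        row = meta.table.iloc[j]
        b = batch_ids.index(row["batch_id"])
        noise = rng.normal(0.0, config.residual_sd, size=G) * scale[:, b]
        col = baseline + loc[:, b] + noise
        if row["compound"] != CONTROL:
            for probe, eff in compound_effects[row["compound"]].items():
                col[_probe_pos(probe)] += eff
        values[:, j] = col

    expr = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))
    truth = SyntheticTruth(
        compound_effects=compound_effects,
        shared_signatures=shared_signatures,
        batch_location=batch_location,
        batch_scale=batch_scale,
    )
    return expr, meta, annotation, truth


def _probe_pos(probe: str) -> int:
    # probe ids are PS%05d starting at 1
    return int(probe[2:]) - 1


def generate_coexpression_dataset(
    n_samples: int,
    modules: Sequence[tuple[int, float]],
    n_background_genes: int = 0,
    seed: int = 0,
):
    """Latent-factor co-expression data for the network stage.

    Each module ``(size, latent_correlation)`` shares one standard-normal
    factor f; its genes are ``lam * f + sqrt(1 - lam^2) * eps`` with
    ``lam = latent_correlation``, so the expected pairwise Pearson r within
    a module is ``lam**2``. Background genes are independent N(0, 1).

    Returns ``(ExpressionMatrix, module_truth)`` where module_truth maps
    module index -> list of gene ids.
    """
    rng = np.random.default_rng(seed)
    for size, lam in modules:
        if size < 2:
            raise ValidationError("module size must be >= 2")
        if not (0.0 <= lam < 1.0):
            raise ValidationError("latent_correlation must be in [0, 1)")
    gene_ids: list[str] = []
    cols: list[np.ndarray] = []
    truth: dict[int, list[str]] = {}
    g = 0
    for mi, (size, lam) in enumerate(modules):
        f = rng.standard_normal(n_samples)
        members = []
        for _ in range(size):
            g += 1
            gid = f"TF{g:04d}"
            eps = rng.standard_normal(n_samples)
            cols.append(lam * f + np.sqrt(1.0 - lam**2) * eps)
            gene_ids.append(gid)
            members.append(gid)
        truth[mi] = members
    for _ in range(n_background_genes):
        g += 1
        gene_ids.append(f"TF{g:04d}")
        cols.append(rng.standard_normal(n_samples))
    data = pd.DataFrame(
        np.asarray(cols),
        index=gene_ids,
        columns=[f"S{j:04d}" for j in range(1, n_samples + 1)],
    )
    return ExpressionMatrix(data), truth
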
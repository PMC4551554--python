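"""Per-compound differential expression and multi-compound consensus genes.

Each compound is tested with a one-sample moderated t on its contrast
columns: the per-probe variance estimate is shrunk toward a global prior
fitted across all probes by empirical Bayes (method of moments on the
log-variance scale via digamma/trigamma matching), which stabilizes tests
at small replicate numbers. P values are FDR-adjusted by Benjamini-
Hochberg. A probe is called significant when its linear fold change
exceeds the threshold AND its adjusted p is below alpha; a gene is
deregulated when at least one of its annotated probes is significant; a
consensus gene is one deregulated in the same direction by at least m
compounds of a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ContrastMatrix,
    GeneSet,
    ProbeAnnotation,
    SampleMetadata,
    ValidationError,
)

DEFAULT_FC_THRESHOLD = 1.5  # linear fold change
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COMPOUNDS = 4


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to variances.

    On the log scale, ``log s2_g`` has mean ``log s0^2 + digamma(df/2) -
    log(df/2) - digamma(d0/2) + log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond the sampling term ``trigamma(df/2)``.
    Returns ``(inf, exp(mean))`` when the observed spread is no larger than
    the sampling spread (complete pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValidationError("need >= 2 positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s02 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


@dataclass
class DEGTable:
    """Moderated-t results per (compound, probe).

    ``table`` has columns: compound, probe_id, log2_fc, s2, df_residual,
    s2_post, t, p_value, adj_p. ``priors`` maps compound -> (d0, s0^2).
    """

    table: pd.DataFrame
    priors: dict[str, tuple[float, float]]

    def for_compound(self, compound: str) -> pd.DataFrame:
        sub = self.table[self.table["compound"] == compound]
        if sub.empty:
            raise ValidationError(f"no results for compound {compound!r}")
        return sub.set_index("probe_id")


def moderated_t(
    contrasts: ContrastMatrix,
    meta: SampleMetadata,
    prior_df: float | None = None,
) -> DEGTable:
    """One-sample moderated t of each probe's mean contrast against zero.

    Fits the variance prior per compound across all probes. ``prior_df``
    overrides the fitted d0 (0 gives the ordinary t; inf gives complete
    pooling to s0^2).
    """
    frames = []
    priors: dict[str, tuple[float, float]] = {}
    for compound in meta.compounds:
        cols = [s for s in meta.samples_of(compound) if s in contrasts.data.columns]
        if len(cols) < 2:
            raise ValidationError(
                f"compound {compound!r} has {len(cols)} replicate columns; need >= 2"
            )
        X = contrasts.data[cols].to_numpy()
        n = X.shape[1]
        dg = n - 1
        mean = X.mean(axis=1)
        s2 = X.var(axis=1, ddof=1)
        d0, s02 = fit_variance_prior(s2, dg)
        if prior_df is not None:
            d0 = float(prior_df)  # s02 stays as fitted (only used when d0 > 0)
        priors[compound] = (d0, s02)
        if d0 == 0:
            s2_post = s2.copy()
            df_total = float(dg)
        elif np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.inf
        else:
            s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
            df_total = d0 + dg
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(s2_post / n)
        t = np.where(np.isfinite(t), t, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        adj = bh_adjust(p)
        frames.append(
            pd.DataFrame(
                {
                    "compound": compound,
                    "probe_id": contrasts.probe_ids,
                    "log2_fc": mean,
                    "s2": s2,
                    "df_residual": dg,
                    "s2_post": s2_post,
                    "t": t,
                    "p_value": p,
                    "adj_p": adj,
                }
            )
        )
    return DEGTable(table=pd.concat(frames, ignore_index=True), priors=priors)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, clipped to [0, 1]."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneCalls:
    """Per-compound significant calls at probe and gene level.

    ``probe_calls``: compound -> {probe_id: +1/-1}.
    ``gene_calls``: compound -> {gene_symbol: +1/-1} (annotated probes only).
    """

    probe_calls: dict[str, dict[str, int]]
    gene_calls: dict[str, dict[str, int]]
    fc_threshold: float
    alpha: float


def call_degs(
    deg: DEGTable,
    annot: ProbeAnnotation,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> GeneCalls:
    """Apply the significance rule and lift probe calls to gene level.

    A probe is significant iff linear |FC| > fc_threshold and adjusted
    p < alpha. A gene is deregulated iff >= 1 of its annotated probes is
    significant; its direction is that of the significant probe with the
    smallest adjusted p (ties broken by larger |FC|, then probe id).
    """
    if fc_threshold <= 0 or alpha <= 0:
        raise ValidationError("thresholds must be positive")
    log_thresh = np.log2(fc_threshold)
    probe_calls: dict[str, dict[str, int]] = {}
    gene_calls: dict[str, dict[str, int]] = {}
    for compound in deg.table["compound"].unique():
        sub = deg.for_compound(compound)
        sig = sub[(sub["log2_fc"].abs() > log_thresh) & (sub["adj_p"] < alpha)]
        probe_calls[compound] = {
            p: (1 if fc > 0 else -1) for p, fc in zip(sig.index, sig["log2_fc"])
        }
        best: dict[str, tuple[float, float, str, int]] = {}
        for p, row in sig.iterrows():
            gene = annot.symbol(p)
            if gene is None:
                continue
            key = (row["adj_p"], -abs(row["log2_fc"]), str(p))
            if gene not in best or key < best[gene][:3]:
                best[gene] = (*key, 1 if row["log2_fc"] > 0 else -1)
        gene_calls[compound] = {g: v[3] for g, v in best.items()}
    return GeneCalls(
        probe_calls=probe_calls,
        gene_calls=gene_calls,
        fc_threshold=fc_threshold,
        alpha=alpha,
    )


@dataclass
class ConsensusSet:
    """Genes deregulated in one direction by >= m compounds of a class."""

    class_label: str
    direction: str  # "up" / "down"
    min_compounds: int
    support: dict[str, int]  # gene -> number of supporting compounds

    @property
    def genes(self) -> list[str]:
        return sorted(self.support)

    def as_gene_set(self) -> GeneSet:
        return GeneSet(
            name=f"{self.class_label}_consensus_{self.direction}",
            genes=tuple(self.genes),
            description=f">= {self.min_compounds} compounds, {self.direction}",
            direction=self.direction,
        )

    def __len__(self) -> int:
        return len(self.support)


def consensus_genes(
    calls: GeneCalls,
    class_compounds: list[str],
    class_label: str,
    m: int = DEFAULT_MIN_COMPOUNDS,
) -> tuple[ConsensusSet, ConsensusSet]:
    """Up- and down-consensus sets for one class of compounds."""
    if len(class_compounds) < m:
        raise ValidationError(
            f"class {class_label!r} has {len(class_compounds)} compounds; "
            f"consensus requires >= m={m}"
        )
    up: dict[str, int] = {}
    down: dict[str, int] = {}
    for compound in class_compounds:
        for gene, direction in calls.gene_calls.get(compound, {}).items():
            tgt = up if direction > 0 else down
            tgt[gene] = tgt.get(gene, 0) + 1
    return (
        ConsensusSet(class_label, "up", m, {g: k for g, k in up.items() if k >= m}),
        ConsensusSet(class_label, "down", m, {g: k for g, k in down.items() if k >= m}),
    )


def cross_class_overlap(
    calls: GeneCalls,
    compounds_a: list[str],
    compounds_b: list[str],
    k_a_values: list[int],
    k_b_values: list[int],
) -> pd.DataFrame:
    """Counts of genes supported by >= k_A compounds of A and >= k_B of B.

    k_B = 0 rows count genes regardless of B support; combined with an
    explicit "B support == 0" column this covers the "all A, no B" cells.
    Directions are counted separately (a gene supports a direction in a
    class if called that way by the required number of its compounds).
    """
    records = []
    for direction, sign in (("up", 1), ("down", -1)):
        support_a: dict[str, int] = {}
        support_b: dict[str, int] = {}
        for comp, tgt in [(c, support_a) for c in compounds_a] + [
            (c, support_b) for c in compounds_b
        ]:
            for gene, d in calls.gene_calls.get(comp, {}).items():
                if d == sign:
                    tgt[gene] = tgt.get(gene, 0) + 1
        genes = set(support_a) | set(support_b)
        for ka in k_a_values:
            for kb in k_b_values:
                n = sum(
                    1
                    for g in genes
                    if support_a.get(g, 0) >= ka and support_b.get(g, 0) >= kb
                )
                n_a_only = sum(
                    1
                    for g in genes
                    if support_a.get(g, 0) >= ka and support_b.get(g, 0) == 0
                )
                records.append(
                    {
                        "direction": direction,
                        "k_a": ka,
                        "k_b": kb,
                        "count": n,
                        "count_a_only": n_a_only,
                    }
                )
    return pd.DataFrame(records)
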
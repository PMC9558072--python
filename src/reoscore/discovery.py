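"""Discovery of an immune gene-pair signature from an expression + survival cohort.

The pipeline proceeds in seven stages:

I.    split patients into two clusters (k-means, Euclidean distance);
II.   differentially expressed genes (DEGs) between the clusters (BH-FDR);
III.  restrict an immune-related gene (IRG) list to genes on the platform;
IV.   intersect DEGs with IRGs -> immune-related DEGs (IRDEGs);
V.    pair every IRDEG with every other gene and score each pair 1 per sample
      where the first gene is expressed above the second (ties score 0);
VI.   survival screen: per pair, log-rank test of score-1 vs score-0 samples,
      keeping pairs with p below the screening threshold (candidates);
VII.  diversity filter: keep pairs whose score is concentrated in one cluster
      (fraction >= alpha scoring 1 in one cluster AND >= alpha scoring 0 in
      the other, either orientation); alpha is raised in 0.05 steps while the
      retained set is still larger than the signature-size cap.

Order robustness: clustering and differential expression run on *within-sample
ranks* of the expression values, so every stage — and therefore the discovered
signature — depends only on the within-sample relative ordering of genes and
is invariant under any strictly increasing per-sample transform (the property
that makes rank-based pair signatures portable across platforms and batches).
Group means and log-fold-changes in the DE table are descriptive, computed on
the supplied (log-scale) values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .core import (
    ClinicalTable,
    ExpressionMatrix,
    GenePair,
    Signature,
    StratRule,
    ValidationError,
    _norm,
)
from .stats import bh_adjust, logrank_test_matrix

__all__ = [
    "DiscoveryConfig",
    "cluster_patients",
    "differential_expression",
    "select_irdegs",
    "enumerate_irgps",
    "count_irgps",
    "pair_score_matrix",
    "survival_screen",
    "diversity_filter",
    "discover_signature",
]


@dataclass
class DiscoveryConfig:
    """Tunable parameters of the discovery pipeline.

    ``alpha`` is the diversity factor: the minimum fraction of one cluster
    scoring 1 and of the other cluster scoring 0 for a pair to be retained.
    ``max_pairs`` caps the signature size; when the diversity filter keeps at
    least ``max_pairs`` pairs, alpha is raised in 0.05 steps (up to 1.0).
    """

    k: int = 2
    seed: int = 0
    deg_fdr: float = 0.05
    deg_abs_logfc: float = 0.0
    screen_p: float = 0.05
    alpha: float = 0.8
    max_pairs: int = 50

    def validate(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if not (0 < self.alpha <= 1):
            raise ValidationError("alpha must lie in (0, 1]")
        for name in ("deg_fdr", "screen_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.deg_abs_logfc < 0:
            raise ValidationError("deg_abs_logfc must be non-negative")
        if self.max_pairs < 1:
            raise ValidationError("max_pairs must be >= 1")


def _sample_ranks(expr: ExpressionMatrix) -> np.ndarray:
    """Within-sample ranks (midranks for ties), genes x samples."""
    return sps.rankdata(expr.values, axis=0)


def cluster_patients(
    expr: ExpressionMatrix,
    k: int = 2,
    seed: int = 0,
    immune_genes: Sequence[str] | None = None,
) -> pd.Series:
    """Stage I: k-means over samples (genes as features, within-sample ranks).

    Labels are 'A', 'B', ...; when an immune gene list is supplied, 'A' is the
    cluster with the highest mean immune-gene rank (the immune-high cluster),
    otherwise the largest cluster (ties broken towards the cluster containing
    the lexicographically first sample).
    """
    n = expr.shape[1]
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of samples ({n})")
    if k < 2:
        raise ValidationError("k must be >= 2")
    ranks = _sample_ranks(expr)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(ranks.T)

    order_stat = np.full(k, -np.inf)
    if immune_genes is not None:
        found, _ = expr.resolve_genes(immune_genes)
        idx = [expr.gene_ids.index(g) for g in found]
        if idx:
            imm = ranks[idx, :]
            for c in range(k):
                if np.any(raw == c):
                    order_stat[c] = imm[:, raw == c].mean()
    if not np.isfinite(order_stat).any():
        sizes = np.bincount(raw, minlength=k).astype(float)
        first = np.argsort(expr.sample_ids)[0]
        # larger cluster first; tie -> the cluster holding the first sample
        order_stat = sizes + 0.5 * (np.arange(k) == raw[first])
    letter_of = {
        c: chr(ord("A") + rank)
        for rank, c in enumerate(np.argsort(-order_stat, kind="stable"))
    }
    return pd.Series(
        [letter_of[c] for c in raw], index=expr.sample_ids, name="cluster"
    )


def differential_expression(
    expr: ExpressionMatrix,
    labels: pd.Series,
    deg_fdr: float = 0.05,
    deg_abs_logfc: float = 0.0,
) -> pd.DataFrame:
    """Stage II: per-gene two-group test with BH-FDR control.

    Significance comes from a Welch t-test on within-sample ranks (order
    robust); ``mean_a``/``mean_b``/``log_fc`` are descriptive statistics of
    the supplied values (difference of group means, i.e. the log fold change
    when the input is log-scale). A gene is flagged significant when
    ``fdr < deg_fdr`` and ``|log_fc| >= deg_abs_logfc``.
    """
    labels = labels.loc[expr.sample_ids]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"differential expression needs exactly 2 groups, got {groups}")
    in_a = (labels == groups[0]).to_numpy()
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValidationError("each group needs at least 2 samples")

    values = expr.values
    ranks = _sample_ranks(expr)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(ranks[:, in_a], ranks[:, ~in_a], axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    mean_a = values[:, in_a].mean(axis=1)
    mean_b = values[:, ~in_a].mean(axis=1)
    log_fc = mean_a - mean_b
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log_fc": log_fc,
            "p_value": p,
            "fdr": fdr,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    out["significant"] = (out.fdr < deg_fdr) & (out.log_fc.abs() >= deg_abs_logfc)
    return out


def select_irdegs(significant_genes: Iterable[str], irg_list: Iterable[str]) -> list[str]:
    """Stage IV: immune-related DEGs — case-insensitive intersection.

    Returns the matched genes (spelled as in ``significant_genes``) in sorted
    order; an empty intersection triggers a warning so the pipeline can halt
    cleanly.
    """
    irg_keys = {_norm(g) for g in irg_list}
    hits = sorted(
        {g for g in significant_genes if _norm(g) in irg_keys}, key=_norm
    )
    if not hits:
        warnings.warn("no immune-related DEGs: DEG and immune lists are disjoint")
    return hits


def enumerate_irgps(
    irdegs: Iterable[str], all_genes: Iterable[str]
) -> Iterator[GenePair]:
    """Stage V: stream ordered pairs (irdeg, other gene), lexicographic order.

    When both members are IRDEGs only the canonical ordering (lexicographically
    smaller first gene) is emitted, since the reversed pair carries the same
    information for untied values.
    """
    irdeg_sorted = sorted({_norm(g): g for g in irdegs}.values(), key=_norm)
    irdeg_keys = {_norm(g) for g in irdeg_sorted}
    genes_sorted = sorted({_norm(g): g for g in all_genes}.values(), key=_norm)
    gene_keys = {_norm(g) for g in genes_sorted}
    for a in irdeg_sorted:
        ka = _norm(a)
        if ka not in gene_keys:
            raise ValidationError(f"IRDEG {a!r} not present in the gene universe")
        for b in genes_sorted:
            kb = _norm(b)
            if kb == ka:
                continue
            if kb in irdeg_keys and kb < ka:
                continue  # reversed duplicate of an earlier pair
            yield GenePair(a, b)


def count_irgps(n_irdegs: int, n_genes: int) -> int:
    """Closed-form pair count: m(n-1) - C(m,2) for m IRDEGs among n genes."""
    m = n_irdegs
    return m * (n_genes - 1) - m * (m - 1) // 2


def pair_score_matrix(
    expr: ExpressionMatrix, pairs: Sequence[GenePair]
) -> pd.DataFrame:
    """Stage V scoring: binary pair-by-sample matrix; 1 iff expr[a] > expr[b].

    Ties score 0. All pair genes must be present (an error lists missing
    symbols; the scoring module offers a lenient skip policy).
    """
    pairs = list(pairs)
    wanted: list[str] = []
    for p in pairs:
        wanted.extend((p.gene_a, p.gene_b))
    _, missing = expr.resolve_genes(wanted)
    if missing:
        raise ValidationError(
            f"genes absent from expression matrix: {sorted(set(missing))}"
        )
    gene_pos = {_norm(g): i for i, g in enumerate(expr.gene_ids)}
    ia = np.array([gene_pos[_norm(p.gene_a)] for p in pairs])
    ib = np.array([gene_pos[_norm(p.gene_b)] for p in pairs])
    v = expr.values
    scores = (v[ia, :] > v[ib, :]).astype(np.int8)
    return pd.DataFrame(
        scores,
        index=pd.Index([str(p) for p in pairs], name="pair"),
        columns=expr.sample_ids,
    )


def survival_screen(
    score_matrix: pd.DataFrame,
    clinical: ClinicalTable,
    screen_p: float = 0.05,
) -> pd.DataFrame:
    """Stage VI: per pair, log-rank test of score-1 vs score-0 samples.

    Returns one row per pair: n_score1, n_score0, logrank_p, candidate,
    excluded. Pairs with a constant score or a score group smaller than 2 are
    excluded (no p-value) rather than assigned p = 1, so they cannot inflate
    the candidate set.
    """
    common = [s for s in score_matrix.columns if s in set(clinical.sample_ids)]
    if not common:
        raise ValidationError("no samples shared between score matrix and clinical table")
    sm = score_matrix.loc[:, common].to_numpy(dtype=np.int8)
    clin = clinical.subset(common)
    time = clin.time.to_numpy()
    event = clin.event.to_numpy()

    n1 = sm.sum(axis=1)
    n0 = sm.shape[1] - n1
    usable = (n1 >= 2) & (n0 >= 2)

    logrank_p = np.full(sm.shape[0], np.nan)
    if usable.any():
        _, p, valid = logrank_test_matrix(time, event, sm[usable])
        lp = np.full(valid.size, np.nan)
        lp[valid] = p[valid]
        logrank_p[usable] = lp
    out = pd.DataFrame(
        {
            "n_score1": n1,
            "n_score0": n0,
            "logrank_p": logrank_p,
            "excluded": ~usable | np.isnan(logrank_p),
        },
        index=score_matrix.index,
    )
    out["candidate"] = (~out.excluded) & (out.logrank_p < screen_p)
    return out


def diversity_filter(
    score_matrix: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.8,
) -> pd.DataFrame:
    """Stage VII: keep pairs whose score separates the two clusters.

    A pair passes at diversity factor ``alpha`` when at least a fraction
    ``alpha`` of cluster-A samples score 1 and at least ``alpha`` of cluster-B
    samples score 0, or the reverse orientation. Returns frac1_A, frac1_B and
    the pass flag per pair.
    """
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must lie in (0, 1]")
    labels = labels.loc[score_matrix.columns]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"diversity filter needs exactly 2 clusters, got {groups}")
    in_a = (labels == groups[0]).to_numpy()
    sm = score_matrix.to_numpy(dtype=float)
    frac1_a = sm[:, in_a].mean(axis=1)
    frac1_b = sm[:, ~in_a].mean(axis=1)
    fwd = (frac1_a >= alpha) & ((1.0 - frac1_b) >= alpha)
    rev = (frac1_b >= alpha) & ((1.0 - frac1_a) >= alpha)
    return pd.DataFrame(
        {
            "frac1_A": frac1_a,
            "frac1_B": frac1_b,
            "diversity_pass": fwd | rev,
        },
        index=score_matrix.index,
    )


def discover_signature(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    irg_list: Sequence[str],
    config: DiscoveryConfig | None = None,
) -> tuple[Signature | None, dict]:
    """Run the full seven-stage discovery and assemble the signature.

    Returns ``(signature, report)``. Any stage that comes up empty halts the
    pipeline cleanly: the signature is None and ``report['halted_at']`` names
    the stage. The report also records per-stage counts, exclusion tallies and
    the diversity factor finally used. The final pairs are ordered by
    survival-screen p-value (ties broken lexicographically) and carry the
    median stratification rule.
    """
    config = config or DiscoveryConfig()
    config.validate()
    common = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if len(common) < 20:
        raise ValidationError(
            f"need >= 20 samples shared between expression and clinical, got {len(common)}"
        )
    expr = expr.subset_samples(common)
    clinical = clinical.subset(common)

    report: dict = {
        "n_samples": len(common),
        "config": asdict(config),
        "halted_at": None,
    }

    # I. cluster
    labels = cluster_patients(expr, k=config.k, seed=config.seed, immune_genes=irg_list)
    report["cluster_sizes"] = labels.value_counts().sort_index().to_dict()
    if labels.nunique() != 2 or labels.value_counts().min() < 2:
        report["halted_at"] = "clustering"
        return None, report

    # II. differential expression
    degs = differential_expression(expr, labels, config.deg_fdr, config.deg_abs_logfc)
    sig_genes = list(degs.index[degs.significant])
    report["n_deg"] = len(sig_genes)
    if not sig_genes:
        report["halted_at"] = "differential_expression"
        return None, report

    # III. immune genes present on the platform
    irg_present, _ = expr.resolve_genes(irg_list)
    irg_present = [g for g in irg_present]
    report["n_irg"] = len(irg_present)
    if not irg_present:
        report["halted_at"] = "immune_gene_list"
        return None, report

    # IV. immune-related DEGs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        irdegs = select_irdegs(sig_genes, irg_present)
    report["n_irdeg"] = len(irdegs)
    if not irdegs:
        report["halted_at"] = "irdeg_intersection"
        return None, report

    # V. enumerate and score pairs
    pairs = list(enumerate_irgps(irdegs, expr.gene_ids))
    report["n_irgp"] = len(pairs)
    scores = pair_score_matrix(expr, pairs)

    # VI. survival screen
    screen = survival_screen(scores, clinical, config.screen_p)
    report["n_excluded_constant"] = int(screen.excluded.sum())
    cand_mask = screen.candidate.to_numpy()
    report["n_candidates"] = int(cand_mask.sum())
    if not cand_mask.any():
        report["halted_at"] = "survival_screen"
        return None, report
    cand_scores = scores.loc[cand_mask]

    # VII. diversity filter with alpha escalation against the size cap
    alpha = config.alpha
    while True:
        div = diversity_filter(cand_scores, labels, alpha)
        n_final = int(div.diversity_pass.sum())
        if n_final < config.max_pairs or alpha >= 1.0:
            break
        alpha = min(round(alpha + 0.05, 10), 1.0)
    report["alpha_used"] = alpha
    report["n_final"] = n_final
    if n_final == 0:
        report["halted_at"] = "diversity_filter"
        return None, report

    kept = div.index[div.diversity_pass]
    order_df = pd.DataFrame(
        {"logrank_p": screen.loc[kept, "logrank_p"].to_numpy(), "label": list(kept)}
    )
    ordering = order_df.sort_values(["logrank_p", "label"], kind="stable")["label"]
    by_label = {str(p): p for p in pairs}
    final_pairs = tuple(by_label[label] for label in ordering)
    signature = Signature(final_pairs, StratRule("median"))
    return signature, report
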
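"""Apply a gene-pair signature to a cohort and stratify patients.

A sample's score is the number of signature pairs whose first gene is
expressed above the second within that sample — an integer between 0 and the
number of evaluated pairs. Because only within-sample orderings enter the
score, it is unchanged by any strictly increasing per-sample transform of the
expression values (normalisation-free, platform-portable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GenePair, Signature, StratRule, ValidationError

__all__ = ["CohortScores", "score_cohort", "stratify", "export_pair_profiles"]


@dataclass
class CohortScores:
    """Per-sample signature scores plus the underlying 0/1 pair vectors.

    ``pair_matrix`` is pairs x samples (0/1); ``scores`` its column sums;
    ``evaluated_pairs`` the number of pairs actually scored on this platform
    (smaller than the signature when pairs were skipped for missing genes,
    listed in ``dropped_pairs``).
    """

    pair_matrix: pd.DataFrame
    scores: pd.Series
    evaluated_pairs: int
    dropped_pairs: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def score_cohort(
    expr: ExpressionMatrix,
    sig: Signature,
    missing_policy: Literal["error", "skip"] = "error",
) -> CohortScores:
    """Score every sample against the signature.

    ``missing_policy='error'`` demands every signature gene on the platform
    (all-or-nothing comparability across the cohort); ``'skip'`` drops
    unscoreable pairs uniformly for the whole cohort and records the reduced
    ``evaluated_pairs``.
    """
    if missing_policy not in ("error", "skip"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    usable: list[GenePair] = []
    dropped: list[str] = []
    missing_genes: set[str] = set()
    for p in sig.pairs:
        miss = [g for g in (p.gene_a, p.gene_b) if not expr.has_gene(g)]
        if miss:
            dropped.append(str(p))
            missing_genes.update(miss)
        else:
            usable.append(p)
    if missing_genes and missing_policy == "error":
        raise ValidationError(
            f"signature genes absent from expression matrix: {sorted(missing_genes)}"
        )
    if not usable:
        raise ValidationError("no signature pair is scoreable on this platform")

    rows = np.vstack([(expr.row(p.gene_a) > expr.row(p.gene_b)).astype(np.int8) for p in usable])
    pair_matrix = pd.DataFrame(
        rows,
        index=pd.Index([str(p) for p in usable], name="pair"),
        columns=expr.sample_ids,
    )
    scores = pair_matrix.sum(axis=0).astype(int)
    scores.name = "score"
    return CohortScores(
        pair_matrix=pair_matrix,
        scores=scores,
        evaluated_pairs=len(usable),
        dropped_pairs=dropped,
    )


def stratify(
    scores: CohortScores | pd.Series,
    rule: StratRule | str | None = None,
) -> pd.Series:
    """Assign each sample to the 'high' or 'low' score group.

    ``fixed_threshold`` t: high iff score > t. ``median``: high iff score
    strictly exceeds the cohort median (samples at the median go low,
    consistent with the strict inequality of the fixed rule). All scores
    identical under the median rule is a degenerate stratification and raises.
    """
    if isinstance(scores, CohortScores):
        s = scores.scores
    else:
        s = scores
    if len(s) < 2:
        raise ValidationError("stratification needs at least 2 samples")
    if rule is None:
        rule = StratRule("median")
    elif isinstance(rule, str):
        rule = StratRule.parse(rule)
    if rule.kind == "fixed_threshold":
        cut = float(rule.threshold)
    else:
        if s.nunique() == 1:
            raise ValidationError("degenerate stratification: all scores identical")
        cut = float(s.median())
    out = pd.Series(
        np.where(s.to_numpy(dtype=float) > cut, "high", "low"),
        index=s.index,
        name="group",
    )
    return out


def export_pair_profiles(scores: CohortScores, path=None) -> pd.DataFrame:
    """The pair-by-sample 0/1 table behind the scores (column sums = scores).

    Writes a TSV when ``path`` is given; the table feeds subtype comparisons
    and cross-platform concordance analyses.
    """
    table = scores.pair_matrix.copy()
    if path is not None:
        table.to_csv(path, sep="\t")
    return table
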
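"""Per-spot TME scoring: PAGE enrichment, module scores, classification.

PAGE (Parametric Analysis of Gene set Enrichment) turns a signature gene
list into a z-like per-spot score.  With f_gs the log2 fold change of gene
g in spot s against the gene's mean across spots, and m signature genes
present in the matrix:

    score_s = (Sm_s - mu_s) * sqrt(m) / delta_s

where Sm_s is the mean of f over the signature genes, mu_s the mean over
all genes and delta_s the (sample) standard deviation over all genes.
Spots with delta_s = 0 (constant fold-change vector, e.g. a constant
matrix) are flagged degenerate and scored 0 rather than propagating NaN.

Each spot is then labeled with the top-scoring feature, provided the top
score clears a floor; ties break by a fixed priority (tumor features
before microenvironment features, lexicographic within each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tmeland.config import AnalysisConfig, SignatureSet
from tmeland.normalize import log_normalize, median_library_log2

UNASSIGNED = "unassigned"


class ScoringError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Per-spot × per-signature enrichment scores.

    ``degenerate`` flags spots whose background fold-change spread was zero
    (their scores are 0 by convention).  ``n_genes_used`` records m, the
    signature size after intersecting with the matrix genes.  ``priority``
    is the deterministic tie-break order used downstream.
    """

    scores: pd.DataFrame
    degenerate: pd.Series
    normalization: str
    n_genes_used: dict[str, int]
    priority: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ScoringError("non-finite scores")

    @property
    def signatures(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class SpotLabeling:
    """Winning feature per spot, or 'unassigned' below the score floor."""

    labels: pd.Series
    winning_score: pd.Series
    min_score: float

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def page_scores(counts: pd.DataFrame, signatures: SignatureSet) -> ScoreTable:
    """PAGE enrichment score of every signature for every spot.

    Counts are scaled per spot to the median library size and
    log2(x+1)-transformed before fold changes are taken.

    Raises :class:`ScoringError` if any signature has no genes in the
    matrix, or if fewer than 2 spots are provided.
    """
    if len(counts) < 2:
        raise ScoringError("PAGE requires at least 2 spots")
    logexpr = median_library_log2(counts)
    fold = logexpr - logexpr.mean(axis=0)
    f = fold.to_numpy(dtype=float)
    mu = f.mean(axis=1)
    delta = f.std(axis=1, ddof=1)
    degenerate = delta == 0
    safe_delta = np.where(degenerate, 1.0, delta)

    cols = {}
    n_used = {}
    gene_index = {g: i for i, g in enumerate(counts.columns)}
    for sig in signatures:
        idx = [gene_index[g] for g in sig.genes if g in gene_index]
        m = len(idx)
        if m == 0:
            raise ScoringError(
                f"signature {sig.name!r} shares no genes with the count matrix"
            )
        sm = f[:, idx].mean(axis=1)
        score = (sm - mu) * np.sqrt(m) / safe_delta
        score[degenerate] = 0.0
        cols[sig.name] = score
        n_used[sig.name] = m

    scores = pd.DataFrame(cols, index=counts.index)
    return ScoreTable(
        scores=scores,
        degenerate=pd.Series(degenerate, index=counts.index),
        normalization="median-library log2(x+1)",
        n_genes_used=n_used,
        priority=signatures.priority_order(),
    )


def module_score(
    counts: pd.DataFrame,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    control_pool=None,
) -> pd.Series:
    """Expression-program module score per spot.

    Mean normalized expression of the gene set minus the mean of control
    genes, where each set gene contributes ``n_ctrl`` controls drawn (with
    replacement) from its own average-expression bin — the standard
    bin-matched control construction.  ``control_pool`` overrides the drawn
    controls (e.g. for a self-control sanity check).  Deterministic given
    ``seed``.
    """
    if n_bins < 2:
        raise ScoringError("n_bins must be >= 2")
    genes = [g for g in gene_set if g in counts.columns]
    if not genes:
        raise ScoringError("gene set shares no genes with the count matrix")
    data = log_normalize(counts)
    avg = data.mean(axis=0)
    if control_pool is None:
        # equal-frequency binning of all genes by average expression
        ranks = avg.rank(method="first")
        bins = np.ceil(ranks / len(avg) * n_bins).astype(int)
        rng = np.random.default_rng(seed)
        ctrl: list[str] = []
        for g in genes:
            pool = avg.index[bins == bins[g]]
            ctrl.extend(rng.choice(pool, size=min(n_ctrl, len(pool)), replace=True))
        control_pool = ctrl
    else:
        control_pool = [g for g in control_pool if g in counts.columns]
        if not control_pool:
            raise ScoringError("control pool shares no genes with the count matrix")
    score = data[genes].mean(axis=1) - data[list(control_pool)].mean(axis=1)
    score.name = "module_score"
    return score


def classify_spots(table: ScoreTable, config: AnalysisConfig | None = None) -> SpotLabeling:
    """Label each spot with its argmax signature, or 'unassigned'.

    A label is assigned iff the winning score is >= ``config.min_score``.
    Exact ties go to the earlier signature in the recorded priority order.
    """
    config = config or AnalysisConfig()
    order = [s for s in (table.priority or sorted(table.signatures)) if s in table.scores]
    order += [s for s in table.signatures if s not in order]
    scores = table.scores[order]
    arr = scores.to_numpy()
    win_idx = np.argmax(arr, axis=1)  # first max wins -> priority order
    win_score = arr[np.arange(len(arr)), win_idx]
    labels = np.where(
        win_score >= config.min_score,
        np.asarray(order, dtype=object)[win_idx],
        UNASSIGNED,
    )
    return SpotLabeling(
        labels=pd.Series(labels, index=scores.index, name="feature"),
        winning_score=pd.Series(win_score, index=scores.index, name="score"),
        min_score=config.min_score,
    )


def feature_proportions(
    labeling: SpotLabeling, sections: pd.Series | None = None
) -> pd.DataFrame:
    """Per-section proportion of each feature label (incl. 'unassigned').

    ``sections`` maps spot id to section id; a single implicit section is
    assumed when omitted.  Rows sum to 1.
    """
    labels = labeling.labels
    if len(labels) == 0:
        raise ScoringError("empty labeling")
    if sections is None:
        sections = pd.Series("section", index=labels.index)
    sections = sections.reindex(labels.index)
    df = pd.crosstab(sections, labels)
    if (df.sum(axis=1) == 0).any():
        raise ScoringError("section with no spots")
    return df.div(df.sum(axis=1), axis=0)
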
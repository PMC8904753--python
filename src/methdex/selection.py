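"""Resampling-based candidate-gene selection.

The discovery cohort is subsampled (default 90% of samples, stratified by
case/control label, 300 times without replacement within each draw). In each
iteration every gene's SIMPO scores are compared between cases and controls
with a pooled two-sample t-test; the 50 genes with the smallest p-values score
one *occurrence*. The candidate list is the genes ranked by occurrence count,
with each gene's mean t across all iterations recording its direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from scipy import stats

from .simpo import SimpoMatrix, _VAR_EPS

__all__ = [
    "SelectionResult",
    "subsample_indices",
    "gene_case_control_t",
    "resample_select",
    "partition_signs",
]


@dataclass(frozen=True)
class SelectionResult:
    """Ranked candidate genes with occurrence counts and mean t-scores.

    ``frame`` is indexed by gene symbol, ordered by rank (1-based), with
    columns ``occurrence_count``, ``mean_t``, ``rank``.
    """

    frame: pd.DataFrame
    n_iter: int
    fraction: float
    top_n: int
    seed: int | None = None

    @property
    def ranked_genes(self) -> list[str]:
        return list(self.frame.index)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, n_iter=0, fraction=float("nan"), top_n=0, seed=None):
        frame = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(frame=frame, n_iter=n_iter, fraction=fraction, top_n=top_n, seed=seed)


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def subsample_indices(labels, fraction: float, rng_seed) -> np.ndarray:
    """Draw floor(fraction * n) sample indices without replacement, stratified by label.

    Each class contributes floor(fraction * n_class) indices; any shortfall
    against the overall floor(fraction * n) is topped up from the classes with
    the largest fractional remainders (ties broken by class value).
    """
    labels = np.asarray(labels)
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = labels.size
    total = floor(fraction * n)
    rng = _as_rng(rng_seed)
    classes = np.unique(labels)
    take = {c: floor(fraction * (labels == c).sum()) for c in classes}
    remainders = sorted(
        classes,
        key=lambda c: (-(fraction * (labels == c).sum() - take[c]), c),
    )
    short = total - sum(take.values())
    for c in remainders[:short]:
        take[c] += 1
    chosen = []
    for c in classes:
        if take[c] < 2:
            raise ValueError(f"subsample would leave class {c} with < 2 members")
        idx = np.flatnonzero(labels == c)
        chosen.append(rng.choice(idx, size=take[c], replace=False))
    return np.sort(np.concatenate(chosen))


def _pooled_t_rows(case_block: np.ndarray, ctrl_block: np.ndarray):
    """Row-wise pooled two-sample t (cases - controls) with NaN-aware counts.

    Rows with < 2 valid values in either class or zero pooled variance get the
    sentinel (t=0, p=1).
    """
    def _stats(block):
        ok = np.isfinite(block)
        cnt = ok.sum(axis=1).astype(float)
        filled = np.where(ok, block, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = filled.sum(axis=1) / cnt
            dev = np.where(ok, block - mean[:, None], 0.0)
            var = (dev * dev).sum(axis=1) / (cnt - 1.0)
        return cnt, mean, var

    n1, m1, v1 = _stats(case_block)
    n0, m0, v0 = _stats(ctrl_block)
    with np.errstate(invalid="ignore", divide="ignore"):
        sw2 = ((n1 - 1.0) * v1 + (n0 - 1.0) * v0) / (n1 + n0 - 2.0)
        t = (m1 - m0) / np.sqrt(sw2 * (1.0 / n1 + 1.0 / n0))
        df = n1 + n0 - 2.0
    bad = (n1 < 2) | (n0 < 2) | ~np.isfinite(sw2) | (sw2 <= _VAR_EPS)
    t = np.where(bad, 0.0, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1.0))
    p = np.where(bad, 1.0, p)
    return t, p


def gene_case_control_t(simpo: SimpoMatrix, labels, subset=None):
    """Per-gene pooled t and two-sided p of case-vs-control SIMPO differences.

    ``labels`` is a 0/1 array aligned with ``simpo.sample_ids``; ``subset``
    optionally restricts the columns (sample indices). Genes with fewer than
    two valid cells in either class get the sentinel (t=0, p=1).
    """
    labels = np.asarray(labels)
    arr = simpo.values.to_numpy(dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        arr = arr[:, subset]
        labels = labels[subset]
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    return _pooled_t_rows(arr[:, labels == 1], arr[:, labels == 0])


def resample_select(
    simpo: SimpoMatrix,
    labels,
    n_iter: int = 300,
    fraction: float = 0.9,
    top_n: int = 50,
    rng_seed=None,
) -> SelectionResult:
    """Rank genes by how often they enter the per-iteration top-``top_n`` list.

    Each iteration draws a stratified subsample, ranks genes by ascending
    t-test p (ties: larger ``|t|`` first, then gene symbol) and counts the
    first ``top_n``. ``mean_t`` averages each gene's t over *all* iterations.
    The final ranking sorts by occurrence count (ties: larger ``|mean_t|``,
    then gene symbol).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    labels = np.asarray(labels)
    rng = _as_rng(rng_seed)
    genes = np.array(simpo.gene_symbols)
    n_genes = genes.size
    # lexicographic tiebreak key: position of each gene in sorted symbol order
    lex = np.empty(n_genes, dtype=int)
    lex[np.argsort(genes, kind="stable")] = np.arange(n_genes)
    occurrence = np.zeros(n_genes, dtype=int)
    t_sum = np.zeros(n_genes)
    for _ in range(n_iter):
        subset = subsample_indices(labels, fraction, rng)
        t, p = gene_case_control_t(simpo, labels, subset)
        order = np.lexsort((lex, -np.abs(t), p))
        occurrence[order[:top_n]] += 1
        t_sum += t
    mean_t = t_sum / n_iter
    final = np.lexsort((lex, -np.abs(mean_t), -occurrence))
    frame = pd.DataFrame(
        {
            "occurrence_count": occurrence[final],
            "mean_t": mean_t[final],
            "rank": np.arange(1, n_genes + 1),
        },
        index=pd.Index(genes[final], name="gene"),
    )
    seed = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    return SelectionResult(frame=frame, n_iter=n_iter, fraction=fraction, top_n=top_n, seed=seed)


def partition_signs(selection: SelectionResult, k: int) -> tuple[list[str], list[str]]:
    """Split the top-k ranked genes by the sign of their mean t-score.

    Genes with mean t exactly 0 go to the positive set. Either set may come
    back empty; downstream index construction then reports the gene list as
    unusable at this k.
    """
    if not 1 <= k <= len(selection.frame):
        raise ValueError(f"k must be in [1, {len(selection.frame)}]")
    top = selection.frame.iloc[:k]
    pos = list(top.index[top["mean_t"] >= 0.0])
    neg = list(top.index[top["mean_t"] < 0.0])
    return pos, neg
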
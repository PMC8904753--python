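"""The methylation-derived depression index (mDI).

A fitted index is a pair of gene sets: a *positive* set (genes whose SIMPO
scores run higher in cases) and a *negative* set (lower in cases), taken as the
top-K candidate genes split by the sign of their mean case-control t. For one
sample, with x the sample's SIMPO values over the n positive genes and y over
the m negative genes,

    mDI = 1 + (x_bar - y_bar) / sqrt(S_x^2 / n + S_y^2 / m),

a Welch-style t offset by 1 so that mDI = 1 means no positive/negative
contrast. K is chosen by sweeping k over a range (default 10..500) and keeping
the k whose index correlates most strongly (Pearson, point-biserial) with the
0/1 case label on the training cohort; ties go to the smallest k. A frozen
index is applied verbatim to new cohorts — nothing is re-selected.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import SelectionResult, partition_signs
from .simpo import SimpoMatrix, _VAR_EPS

logger = logging.getLogger("methdex")

__all__ = ["MdiModel", "MdiScores", "mdi_score", "score_cohort", "sweep_k"]


@dataclass(frozen=True)
class MdiModel:
    """A frozen index: gene sets, chosen K and fitting provenance."""

    positive_genes: tuple[str, ...]
    negative_genes: tuple[str, ...]
    k: int
    training_correlation: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.positive_genes) + len(self.negative_genes) != self.k:
            raise ValueError("gene sets do not add up to k")
        if not self.positive_genes or not self.negative_genes:
            raise ValueError("both gene sets must be non-empty")

    def to_json(self, path) -> None:
        payload = {
            "positive_genes": list(self.positive_genes),
            "negative_genes": list(self.negative_genes),
            "k": self.k,
            "training_correlation": self.training_correlation,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "MdiModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            positive_genes=tuple(payload["positive_genes"]),
            negative_genes=tuple(payload["negative_genes"]),
            k=int(payload["k"]),
            training_correlation=float(payload["training_correlation"]),
            provenance=payload.get("provenance", {}),
        )


@dataclass(frozen=True)
class MdiScores:
    """Per-sample mDI values plus the gene counts actually used per sample."""

    scores: pd.Series  # index sample_id, NaN = not scorable
    genes_used: pd.DataFrame  # columns n_positive, n_negative

    @property
    def flagged_samples(self) -> list[str]:
        return list(self.scores.index[self.scores.isna()])

    def to_csv(self, path) -> None:
        self.scores.rename("mDI").to_csv(path, index_label="sample_id", na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "MdiScores":
        s = pd.read_csv(path, index_col="sample_id")["mDI"]
        used = pd.DataFrame(index=s.index, columns=["n_positive", "n_negative"], dtype=float)
        return cls(scores=s.astype(float), genes_used=used)


def mdi_score(pos_values, neg_values) -> float:
    """Welch-style index for one sample; NaN if either side has < 2 valid values
    or the denominator is zero."""
    x = np.asarray(pos_values, dtype=float)
    y = np.asarray(neg_values, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    n, m = x.size, y.size
    if n < 2 or m < 2:
        return float("nan")
    denom = np.sqrt(x.var(ddof=1) / n + y.var(ddof=1) / m)
    if denom <= np.sqrt(_VAR_EPS):
        return float("nan")
    return float(1.0 + (x.mean() - y.mean()) / denom)


def _score_block(P: np.ndarray, N: np.ndarray):
    """Vectorised mDI over samples: P = positive-gene rows, N = negative rows."""

    def _stats(block):
        ok = np.isfinite(block)
        cnt = ok.sum(axis=0).astype(float)
        filled = np.where(ok, block, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = filled.sum(axis=0) / cnt
            dev = np.where(ok, block - mean, 0.0)
            var = (dev * dev).sum(axis=0) / (cnt - 1.0)
        return cnt, mean, var

    n, mx, vx = _stats(P)
    m, my, vy = _stats(N)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(vx / n + vy / m)
        val = 1.0 + (mx - my) / denom
    ok = (n >= 2) & (m >= 2) & np.isfinite(denom) & (denom > np.sqrt(_VAR_EPS))
    return np.where(ok, val, np.nan), n, m


def score_cohort(simpo: SimpoMatrix, model: MdiModel) -> MdiScores:
    """Apply a frozen index to a cohort's SIMPO matrix.

    Genes of the model absent from the cohort are dropped with a warning; if
    either set falls below two genes the cohort cannot be scored and an error
    names the offending set. Samples whose valid-gene counts are insufficient
    come back flagged (NaN), never silently scored.
    """
    present = set(simpo.gene_symbols)
    missing = [g for g in (*model.positive_genes, *model.negative_genes) if g not in present]
    if missing:
        warnings.warn(
            f"{len(missing)} model gene(s) absent from cohort: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else ""),
            stacklevel=2,
        )
    pos = [g for g in model.positive_genes if g in present]
    neg = [g for g in model.negative_genes if g in present]
    for name, genes in (("positive", pos), ("negative", neg)):
        if len(genes) < 2:
            raise ValueError(f"{name} gene set reduced below 2 genes in this cohort")
    arr = simpo.values
    vals, n_used, m_used = _score_block(
        arr.loc[pos].to_numpy(dtype=float), arr.loc[neg].to_numpy(dtype=float)
    )
    scores = pd.Series(vals, index=arr.columns, name="mDI")
    used = pd.DataFrame(
        {"n_positive": n_used.astype(int), "n_negative": m_used.astype(int)}, index=arr.columns
    )
    return MdiScores(scores=scores, genes_used=used)


def _pearson_with_binary(x: np.ndarray, y: np.ndarray) -> float:
    """Point-biserial r; NaN when either side is constant or < 3 points."""
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if x.size < 3 or len(np.unique(y)) < 2:
        return float("nan")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        return float("nan")
    return float((xd * yd).sum() / denom)


def sweep_k(
    selection: SelectionResult,
    simpo: SimpoMatrix,
    labels,
    k_min: int = 10,
    k_max: int = 500,
) -> tuple[MdiModel, pd.DataFrame]:
    """Sweep K over [k_min, k_max], score the cohort at each K and keep the K
    with the highest point-biserial correlation between mDI and the label.

    Returns the frozen model and the full per-k curve (columns ``k``, ``r``,
    ``n_positive``, ``n_negative``) for plotting. Ks at which the index is
    undefined (single-sign gene list, degenerate variances) get r = NaN.
    Ties in r go to the smallest k.
    """
    n_ranked = len(selection.frame)
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > n_ranked:
        raise ValueError(f"k_max={k_max} exceeds the {n_ranked} ranked genes")
    labels = np.asarray(labels, dtype=float)

    ranked = selection.ranked_genes
    missing = [g for g in ranked[:k_max] if g not in set(simpo.gene_symbols)]
    if missing:
        raise ValueError(f"ranked gene(s) absent from SIMPO matrix: {missing[:5]}")
    V = simpo.values.loc[ranked[:k_max]].to_numpy(dtype=float)
    sign_pos = selection.frame["mean_t"].to_numpy()[:k_max] >= 0.0
    ok = np.isfinite(V)
    V0 = np.where(ok, V, 0.0)

    def _cums(row_mask):
        use = ok & row_mask[:, None]
        v = np.where(use, V0, 0.0)
        return (
            np.cumsum(use, axis=0).astype(float),
            np.cumsum(v, axis=0),
            np.cumsum(v * v, axis=0),
        )

    Cp, S1p, S2p = _cums(sign_pos)
    Cn, S1n, S2n = _cums(~sign_pos)

    ks = np.arange(k_min, k_max + 1)
    rows = ks - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        n = Cp[rows]  # (K, S) valid positive-gene counts
        m = Cn[rows]
        mx = S1p[rows] / n
        my = S1n[rows] / m
        vx = (S2p[rows] - S1p[rows] ** 2 / n) / (n - 1.0)
        vy = (S2n[rows] - S1n[rows] ** 2 / m) / (m - 1.0)
        denom = np.sqrt(vx / n + vy / m)
        mdi = 1.0 + (mx - my) / denom
    cell_ok = (n >= 2) & (m >= 2) & np.isfinite(denom) & (denom > np.sqrt(_VAR_EPS))
    mdi = np.where(cell_ok, mdi, np.nan)

    r = np.array([_pearson_with_binary(mdi[i], labels) for i in range(len(ks))])
    n_pos_k = sign_pos.cumsum()[rows]
    curve = pd.DataFrame(
        {"k": ks, "r": r, "n_positive": n_pos_k, "n_negative": ks - n_pos_k}
    )
    if not np.isfinite(r).any():
        raise ValueError("index undefined at every k in the sweep range")
    best_i = int(np.nanargmax(np.where(np.isfinite(r), r, -np.inf)))
    best_k = int(ks[best_i])
    pos, neg = partition_signs(selection, best_k)
    model = MdiModel(
        positive_genes=tuple(pos),
        negative_genes=tuple(neg),
        k=best_k,
        training_correlation=float(r[best_i]),
        provenance={
            "seed": selection.seed,
            "n_iter": selection.n_iter,
            "fraction": selection.fraction,
            "top_n": selection.top_n,
            "k_min": k_min,
            "k_max": k_max,
        },
    )
    logger.info("K sweep: chose k=%d with r=%.4f", best_k, r[best_i])
    return model, curve
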
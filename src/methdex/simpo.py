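"""SIMPO: a per-gene, per-sample promoter-vs-body methylation contrast.

For one gene in one sample, let x be the beta values of its m promoter probes
and y the beta values of its n other-region probes (gene body, 5'UTR, 1stExon,
3'UTR). The SIMPO score is the pooled two-sample t statistic

    score = (x_bar - y_bar) / (S_w * sqrt(1/m + 1/n)),
    S_w^2 = [(m-1) S_1^2 + (n-1) S_2^2] / (m + n - 2),

with unbiased (count-1) sample variances. A cell is *invalid* (NaN) when either
side has fewer than two non-missing probes or the pooled variance is exactly
zero; a constant-methylation gene carries no promoter/body contrast and an
infinite score would poison every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, GeneRegionIndex

logger = logging.getLogger("methdex")

# variances below this are numerically zero (float noise of a constant side)
_VAR_EPS = 1e-24

__all__ = ["SimpoMatrix", "simpo_score", "simpo_matrix", "read_simpo_matrix", "write_simpo_matrix"]


@dataclass(frozen=True)
class SimpoMatrix:
    """Genes x samples matrix of SIMPO t-statistics; NaN cells are invalid."""

    values: pd.DataFrame
    n_invalid_cells: int = 0
    dropped_genes: tuple[str, ...] = ()

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def valid(self) -> pd.DataFrame:
        """Boolean validity flag per cell."""
        return self.values.notna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def simpo_score(promoter_values, other_values) -> float:
    """Pooled two-sample t of promoter vs other-region beta values (NaN if invalid)."""
    x = np.asarray(promoter_values, dtype=float)
    y = np.asarray(other_values, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    m, n = x.size, y.size
    if m < 2 or n < 2:
        return float("nan")
    s1 = x.var(ddof=1)
    s2 = y.var(ddof=1)
    sw2 = ((m - 1) * s1 + (n - 1) * s2) / (m + n - 2)
    if sw2 <= _VAR_EPS:
        return float("nan")
    return float((x.mean() - y.mean()) / (np.sqrt(sw2) * np.sqrt(1.0 / m + 1.0 / n)))


def _side_stats(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (count, mean, unbiased variance) over a probes x samples block."""
    ok = np.isfinite(block)
    cnt = ok.sum(axis=0).astype(float)
    filled = np.where(ok, block, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=0) / cnt
        dev = np.where(ok, block - mean, 0.0)
        var = (dev * dev).sum(axis=0) / (cnt - 1.0)
    return cnt, mean, var


def simpo_matrix(
    beta: BetaMatrix,
    index: GeneRegionIndex,
    max_invalid_frac: float = 0.05,
) -> SimpoMatrix:
    """Score every (gene, sample) cell of the cohort.

    Genes invalid in more than ``max_invalid_frac`` of samples are dropped with
    a warning; the count of remaining invalid cells is logged and carried on
    the result.
    """
    if len(index) == 0:
        raise ValueError("empty gene/region index")
    pos = {p: i for i, p in enumerate(beta.values.index)}
    arr = beta.values.to_numpy(dtype=float)
    n_samples = arr.shape[1]
    genes = sorted(index.genes)
    scores = np.full((len(genes), n_samples), np.nan)
    for gi, gene in enumerate(genes):
        prom_ids, other_ids = index.genes[gene]
        P = arr[[pos[p] for p in prom_ids], :]
        O = arr[[pos[p] for p in other_ids], :]
        m, xbar, s1 = _side_stats(P)
        n, ybar, s2 = _side_stats(O)
        with np.errstate(invalid="ignore", divide="ignore"):
            sw2 = ((m - 1.0) * s1 + (n - 1.0) * s2) / (m + n - 2.0)
            t = (xbar - ybar) / (np.sqrt(sw2) * np.sqrt(1.0 / m + 1.0 / n))
        ok = (m >= 2) & (n >= 2) & np.isfinite(sw2) & (sw2 > _VAR_EPS)
        scores[gi, ok] = t[ok]
    frame = pd.DataFrame(scores, index=genes, columns=beta.values.columns)
    invalid_frac = frame.isna().mean(axis=1)
    dropped = tuple(frame.index[invalid_frac > max_invalid_frac])
    if dropped:
        logger.warning(
            "dropping %d gene(s) invalid in > %.0f%% of samples: %s",
            len(dropped),
            100 * max_invalid_frac,
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
        frame = frame.drop(index=list(dropped))
    n_invalid = int(frame.isna().to_numpy().sum())
    if n_invalid:
        logger.info("SIMPO matrix: %d invalid cell(s) remain (NaN)", n_invalid)
    return SimpoMatrix(values=frame, n_invalid_cells=n_invalid, dropped_genes=dropped)


def write_simpo_matrix(simpo: SimpoMatrix, path) -> None:
    simpo.values.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def read_simpo_matrix(path) -> SimpoMatrix:
    from .io import _read_matrix_tsv

    frame = _read_matrix_tsv(path, "gene symbol")
    return SimpoMatrix(values=frame, n_invalid_cells=int(frame.isna().to_numpy().sum()))
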
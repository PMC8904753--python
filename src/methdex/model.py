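"""Model/Results front end for fitting the depression index to a cohort.

    >>> model = DepressionIndexModel.from_cohort(beta, annotation, phenotype)
    >>> res = model.fit(n_iter=300, fraction=0.9, top_n=50, seed=17)
    >>> print(res.summary())
    >>> val_scores = res.score(validation_simpo)        # frozen transfer
    >>> report = res.evaluate(val_scores, val_phenotype)

Fitting runs the resampling gene selection followed by the K sweep; the
results object holds the frozen gene sets, the per-k correlation curve, the
training scores and evaluation/plotting helpers. Scoring a new cohort never
re-selects anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evaluation import EvaluationReport, evaluate
from .io import BetaMatrix, Phenotype, ProbeAnnotation, build_gene_region_index
from .mdi import MdiModel, MdiScores, score_cohort, sweep_k
from .selection import SelectionResult, resample_select
from .simpo import SimpoMatrix, simpo_matrix

__all__ = ["DepressionIndexModel", "DepressionIndexResults"]


class DepressionIndexModel:
    """mDI model specification bound to a training cohort.

    Parameters
    ----------
    simpo : SimpoMatrix
        Gene-level SIMPO scores of the discovery cohort.
    phenotype : Phenotype
        Case/control labels for (at least) the SIMPO samples.
    """

    def __init__(self, simpo: SimpoMatrix, phenotype: Phenotype):
        self.simpo = simpo
        self.phenotype = phenotype
        self.labels = phenotype.labels_for(simpo.sample_ids)

    @classmethod
    def from_cohort(
        cls,
        beta: BetaMatrix,
        annotation: ProbeAnnotation,
        phenotype: Phenotype,
        min_probes: int = 2,
        max_invalid_frac: float = 0.05,
    ) -> "DepressionIndexModel":
        """Build straight from probe-level data: region index, then SIMPO."""
        index = build_gene_region_index(annotation, beta, min_probes=min_probes)
        return cls(simpo_matrix(beta, index, max_invalid_frac=max_invalid_frac), phenotype)

    def fit(
        self,
        n_iter: int = 300,
        fraction: float = 0.9,
        top_n: int = 50,
        k_min: int = 10,
        k_max: int = 500,
        seed: int | None = None,
    ) -> "DepressionIndexResults":
        selection = resample_select(
            self.simpo, self.labels, n_iter=n_iter, fraction=fraction, top_n=top_n, rng_seed=seed
        )
        k_max = min(k_max, len(selection.frame))
        mdi_model, curve = sweep_k(selection, self.simpo, self.labels, k_min=k_min, k_max=k_max)
        train_scores = score_cohort(self.simpo, mdi_model)
        return DepressionIndexResults(
            model=mdi_model,
            selection=selection,
            curve=curve,
            training_scores=train_scores,
            training_data=self,
        )


@dataclass
class DepressionIndexResults:
    """A fitted (frozen) depression index plus its training diagnostics."""

    model: MdiModel
    selection: SelectionResult
    curve: pd.DataFrame
    training_scores: MdiScores
    training_data: DepressionIndexModel

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def training_correlation(self) -> float:
        return self.model.training_correlation

    def score(self, simpo: SimpoMatrix) -> MdiScores:
        """Apply the frozen index to a (new) cohort's SIMPO matrix."""
        return score_cohort(simpo, self.model)

    def evaluate(
        self, scores: MdiScores | None = None, phenotype: Phenotype | None = None, **kw
    ) -> EvaluationReport:
        """Evaluation report; defaults to the training cohort."""
        if scores is None:
            scores = self.training_scores
        pheno = phenotype if phenotype is not None else self.training_data.phenotype
        labels = pheno.labels_for(scores.scores.index)
        return evaluate(scores.scores, labels, **kw)

    def summary(self) -> str:
        rep = self.evaluate()
        lines = [
            "Methylation-derived depression index (mDI)",
            "=" * 46,
            f"chosen K:                 {self.model.k}",
            f"  positive genes:         {len(self.model.positive_genes)}",
            f"  negative genes:         {len(self.model.negative_genes)}",
            f"training point-biserial r: {self.model.training_correlation:.4f}"
            f" (p = {rep.pearson_p:.3g})",
            f"training AUC:             {rep.auc:.4f}",
            f"case-control t:           {rep.t_statistic:.3f} (p = {rep.t_p:.3g})",
            f"OR (median split):        {rep.or_median_split:.3f}"
            f" [{rep.or_median_split_ci[0]:.3f}, {rep.or_median_split_ci[1]:.3f}]",
            f"OR (Q4 vs Q1):            {rep.or_q4_vs_q1:.3f}"
            f" [{rep.or_q4_vs_q1_ci[0]:.3f}, {rep.or_q4_vs_q1_ci[1]:.3f}]",
            f"samples:                  {rep.n_cases} cases / {rep.n_controls} controls",
            "provenance:               "
            + ", ".join(f"{k}={v}" for k, v in self.model.provenance.items()),
        ]
        return "\n".join(lines)

    def plot_k_curve(self, ax=None):
        """Correlation-vs-K curve with the chosen K marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve["k"], self.curve["r"], lw=1.0)
        ax.axvline(self.model.k, color="crimson", ls="--", lw=0.8, label=f"K = {self.model.k}")
        ax.set_xlabel("number of genes K")
        ax.set_ylabel("point-biserial r (mDI vs label)")
        ax.legend()
        return ax

    def plot_roc(self, scores=None, phenotype=None, ax=None):
        import matplotlib.pyplot as plt
        from .evaluation import roc_auc

        if scores is None:
            scores = self.training_scores
        pheno = phenotype if phenotype is not None else self.training_data.phenotype
        labels = pheno.labels_for(scores.scores.index)
        s = scores.scores
        ok = s.notna()
        auc, (fpr, tpr) = roc_auc(s[ok], labels[ok.to_numpy()], return_curve=True)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"mDI (AUC = {auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
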
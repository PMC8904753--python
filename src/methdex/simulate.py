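"""Synthetic 450K-style cohorts with the structure the analysis assumes.

The methylation generator draws, per gene, a handful of promoter probes and a
handful of other-region probes with logit-scale mean methylation around a
promoter baseline (hypomethylated) and a gene-body baseline (more methylated).
A sample's beta value is the inverse logit of the probe mean plus Gaussian
probe noise, clipped away from {0, 1}. *Causal* genes shift their promoter
probes by +/- ``effect_size`` (logit scale) in case samples only — only a
promoter-vs-other differential, exactly what the SIMPO contrast detects, is
injected; shifting both sides equally would produce no signal by construction.

The array design (probe counts and means) comes from ``design_seed``, sample
noise from ``rng_seed``: two cohorts sharing a config but differing in
``rng_seed`` are independent draws on the same array, so an index frozen on
one transfers meaningfully to the other. Causal genes are the first
``n_causal`` genes, directions alternating up/down.

The cancer generator equips samples with blood cell proportions (Dirichlet
monocyte/granulocyte/lymphocyte composition, log-normal CD4/CD8 ratio) and a
binary outcome drawn from a logistic model on the z-scored mDI and its
interaction with CD4/CD8; diagnosed samples get a uniform diagnosis year.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import BetaMatrix, Phenotype, ProbeAnnotation

__all__ = [
    "SimulationConfig",
    "CancerSimulationConfig",
    "generate_methylation_cohort",
    "generate_cancer_cohort",
]

_PROM_GROUPS = ("TSS200", "TSS1500")
_OTHER_GROUPS = ("Body", "5UTR", "1stExon", "3UTR")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative law of a case/control methylation cohort."""

    n_cases: int = 150
    n_controls: int = 150
    n_genes: int = 1000
    n_causal: int = 50
    probes_per_region: tuple[int, int] = (2, 8)
    promoter_mean: float = -1.0  # logit scale
    other_mean: float = 0.5  # logit scale
    probe_mean_sd: float = 0.5  # spread of per-probe means around the baseline
    noise_sd: float = 0.5  # per-(probe, sample) logit noise
    effect_size: float = 1.0  # case shift of causal promoter probes, logit scale
    missing_rate: float = 0.01
    rng_seed: int = 0
    design_seed: int = 450  # array design; fixed so cohorts share probes

    def __post_init__(self) -> None:
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal must not exceed n_genes")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        lo, hi = self.probes_per_region
        if lo < 2 or hi < lo:
            raise ValueError("probes_per_region must satisfy 2 <= lo <= hi")


def _gene_symbol(i: int) -> str:
    return f"G{i + 1:05d}"


def generate_methylation_cohort(cfg: SimulationConfig):
    """Returns (BetaMatrix, ProbeAnnotation, Phenotype, truth dict)."""
    design = np.random.default_rng(cfg.design_seed)
    lo, hi = cfg.probes_per_region
    genes = [_gene_symbol(i) for i in range(cfg.n_genes)]
    m_counts = design.integers(lo, hi + 1, size=cfg.n_genes)
    n_counts = design.integers(lo, hi + 1, size=cfg.n_genes)

    probe_ids, ann_rows, probe_mean = [], [], []
    prom_rows: dict[str, list[int]] = {}
    pid = 0
    for gi, gene in enumerate(genes):
        prom_rows[gene] = []
        for j in range(m_counts[gi]):
            probe_ids.append(f"cg{pid:08d}")
            ann_rows.append((f"cg{pid:08d}", gene, _PROM_GROUPS[j % 2]))
            probe_mean.append(cfg.promoter_mean + design.normal(0.0, cfg.probe_mean_sd))
            prom_rows[gene].append(pid)
            pid += 1
        for j in range(n_counts[gi]):
            probe_ids.append(f"cg{pid:08d}")
            ann_rows.append((f"cg{pid:08d}", gene, _OTHER_GROUPS[j % 4]))
            probe_mean.append(cfg.other_mean + design.normal(0.0, cfg.probe_mean_sd))
            pid += 1
    probe_mean = np.array(probe_mean)

    directions = {genes[i]: (1 if i % 2 == 0 else -1) for i in range(cfg.n_causal)}

    rng = np.random.default_rng(cfg.rng_seed)
    n_samples = cfg.n_cases + cfg.n_controls
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    labels = np.array([1] * cfg.n_cases + [0] * cfg.n_controls)

    logit = probe_mean[:, None] + rng.normal(0.0, cfg.noise_sd, size=(pid, n_samples))
    case_cols = np.flatnonzero(labels == 1)
    for gene, direction in directions.items():
        rows = prom_rows[gene]
        logit[np.ix_(rows, case_cols)] += direction * cfg.effect_size
    beta_vals = np.clip(expit(logit), 0.001, 0.999)
    if cfg.missing_rate > 0:
        beta_vals[rng.random(beta_vals.shape) < cfg.missing_rate] = np.nan

    beta = BetaMatrix(pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids))
    ann = ProbeAnnotation(pd.DataFrame(ann_rows, columns=["probe_id", "gene", "group"]))
    age = np.clip(rng.normal(48.0, 13.0, size=n_samples).round(1), 18.0, 85.0)
    sex = np.where(rng.random(n_samples) < 0.6, "F", "M")
    pheno = Phenotype(
        pd.DataFrame(
            {"label": labels, "age": age, "sex": sex},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = {
        "causal_genes": directions,
        "effect_size": cfg.effect_size,
        "config": asdict(cfg),
    }
    return beta, ann, pheno, truth


@dataclass(frozen=True)
class CancerSimulationConfig:
    """Generative law of the prospective cancer cohort covariates and outcome."""

    n_samples: int = 659
    follow_up_years: int = 11
    cell_dirichlet: tuple[float, float, float] = (8.0, 60.0, 30.0)  # mono, gran, lympho
    cd4_cd8_log_mean: float = float(np.log(1.8))
    cd4_cd8_log_sd: float = 0.35
    intercept: float = -0.59  # logit of the cohort's final cumulative incidence
    b_mdi: float = 0.6037
    b_interaction: float = 0.5579
    rng_seed: int = 0


def generate_cancer_cohort(cfg: CancerSimulationConfig, scores) -> Phenotype:
    """Attach cell proportions and a coupled time-to-diagnosis outcome to scores.

    ``scores`` may be an MdiScores or a pandas Series indexed by sample id; its
    first ``n_samples`` entries define the cohort.
    """
    s = scores.scores if hasattr(scores, "scores") else scores
    s = s.dropna()
    if len(s) < cfg.n_samples:
        raise ValueError(f"scores cover {len(s)} samples; {cfg.n_samples} required")
    s = s.iloc[: cfg.n_samples]
    rng = np.random.default_rng(cfg.rng_seed)
    comp = rng.dirichlet(cfg.cell_dirichlet, size=cfg.n_samples)
    mono, gran, lympho = comp[:, 0], comp[:, 1], comp[:, 2]
    ratio = np.exp(rng.normal(cfg.cd4_cd8_log_mean, cfg.cd4_cd8_log_sd, size=cfg.n_samples))
    tcell = 0.7 * lympho
    cd4 = tcell * ratio / (1.0 + ratio)
    cd8 = tcell / (1.0 + ratio)
    nk = 0.18 * lympho
    bcell = 0.12 * lympho

    z = lambda x: (x - x.mean()) / x.std(ddof=1)
    z_mdi = z(s.to_numpy(dtype=float))
    z_ratio = z(ratio)
    p = expit(cfg.intercept + cfg.b_mdi * z_mdi + cfg.b_interaction * z_mdi * z_ratio)
    y = (rng.random(cfg.n_samples) < p).astype(int)
    years = np.full(cfg.n_samples, pd.NA, dtype=object)
    n_cases = int(y.sum())
    years[y == 1] = rng.integers(1, cfg.follow_up_years + 1, size=n_cases)

    frame = pd.DataFrame(
        {
            "label": y,
            "diagnosis_year": pd.array(years, dtype="Int64"),
            "mono": mono,
            "gran": gran,
            "lympho": lympho,
            "cd4": cd4,
            "cd8": cd8,
            "nk": nk,
            "bcell": bcell,
        },
        index=pd.Index(s.index, name="sample_id"),
    )
    return Phenotype(frame)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
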
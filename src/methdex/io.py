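"""Tabular I/O and the core cohort data model.

Formats handled here are deliberately plain text:

* **beta matrix** — TSV, probes in rows, header ``probe_id<TAB>sample1<TAB>...``,
  cells are methylation beta values in [0, 1] or the literal ``NA`` for missing.
* **probe annotation** — TSV with header ``probe_id<TAB>gene<TAB>group`` where the
  gene and group fields are semicolon-separated *parallel* lists, the dialect of
  the Illumina manifest columns ``UCSC_RefGene_Name`` / ``UCSC_RefGene_Group``.
* **phenotype** — CSV with header ``sample_id,label,...``; ``label`` is 0/1 case
  status, optional columns cover age, sex, follow-up diagnosis year and blood
  cell proportions.

The :class:`GeneRegionIndex` groups each gene's probes into a *promoter* side
(TSS1500/TSS200) and an *other* side (5'UTR, 1stExon, gene body, 3'UTR); the
promoter-vs-other contrast is the raw material of the SIMPO score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("methdex")

__all__ = [
    "FormatError",
    "BetaMatrix",
    "ProbeAnnotation",
    "Phenotype",
    "GeneRegionIndex",
    "REGION_GROUPS",
    "PROMOTER_GROUPS",
    "OTHER_GROUPS",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_phenotype",
    "write_phenotype",
    "build_gene_region_index",
]

#: the six Illumina 450K manifest region-group labels
REGION_GROUPS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"})
#: groups counted as promoter; the remaining four form the "other" side
PROMOTER_GROUPS = frozenset({"TSS1500", "TSS200"})
OTHER_GROUPS = REGION_GROUPS - PROMOTER_GROUPS

# the manifest itself writes 5'UTR / 3'UTR; accept both spellings
_GROUP_ALIASES = {"5'UTR": "5UTR", "3'UTR": "3UTR"}


class FormatError(ValueError):
    """A file violated the expected tabular format or a value constraint."""


@dataclass(frozen=True)
class BetaMatrix:
    """Probe-level methylation beta values, probes x samples; NaN = missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise FormatError("duplicate probe ids in beta matrix")
        if v.columns.has_duplicates:
            raise FormatError("duplicate sample ids in beta matrix")
        arr = v.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise FormatError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ProbeAnnotation:
    """One record per (probe, gene, region-group) assignment."""

    records: pd.DataFrame  # columns: probe_id, gene, group

    def __post_init__(self) -> None:
        bad = set(self.records["group"]) - REGION_GROUPS
        if bad:
            raise FormatError(f"unknown region group label(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Phenotype:
    """Per-sample case/control label plus optional covariates.

    Index of ``frame`` is the sample id; ``label`` is 0/1 (1 = case). Optional
    columns: ``age``, ``sex``, ``diagnosis_year`` (follow-up year of a cancer
    diagnosis; missing = cancer-free through follow-up) and cell proportions
    ``mono, gran, lympho, cd4, cd8, nk, bcell, tcell`` as fractions of whole
    blood.
    """

    frame: pd.DataFrame

    _PROPORTIONS = ("mono", "gran", "lympho", "cd4", "cd8", "nk", "bcell", "tcell")

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            raise FormatError("duplicate sample ids in phenotype")
        if "label" not in f.columns:
            raise FormatError("phenotype requires a 'label' column")
        lab = f["label"].to_numpy()
        if not np.isin(lab, (0, 1)).all():
            raise FormatError("label must be 0 or 1")
        for col in self._PROPORTIONS:
            if col in f.columns:
                x = f[col].to_numpy(dtype=float)
                x = x[np.isfinite(x)]
                if x.size and (x.min() < 0.0 or x.max() > 1.0):
                    raise FormatError(f"cell proportion '{col}' outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def labels_for(self, sample_ids) -> np.ndarray:
        """0/1 labels aligned to ``sample_ids`` (KeyError on unknown samples)."""
        return self.frame.loc[list(sample_ids), "label"].to_numpy(dtype=int)


@dataclass(frozen=True)
class GeneRegionIndex:
    """Per-gene promoter/other probe partition, restricted to measured probes."""

    genes: dict[str, tuple[list[str], list[str]]]
    n_excluded: int = 0
    min_probes: int = 2

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.items())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path, index_label: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected a tab-separated header with sample ids")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample ids in header")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.columns = samples  # undo any pandas dedup-mangling
    if raw.index.has_duplicates:
        raise FormatError(f"{path}: duplicate {index_label}s")

    def _col(c: pd.Series) -> pd.Series:
        if (c.str.strip() == "").any():
            raise FormatError(f"{path}: empty cell in column '{c.name}' (use NA for missing)")
        cc = c.mask(c == "NA")
        try:
            return pd.to_numeric(cc)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in column '{c.name}': {exc}") from exc

    out = raw.apply(_col).astype(float)
    out.index.name = None
    out.columns.name = None
    return out


def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes x samples beta-value TSV; ``NA`` marks missing values."""
    return BetaMatrix(_read_matrix_tsv(path, "probe id"))


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read a manifest-dialect annotation TSV into flat (probe, gene, group) records.

    The ``gene`` and ``group`` columns are semicolon-separated parallel lists;
    each position yields one record. Exact duplicate records are collapsed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    probes, genes, groups = [], [], []
    for probe, gene_field, group_field in df[["probe_id", "gene", "group"]].itertuples(index=False):
        gs = str(gene_field).split(";")
        rs = str(group_field).split(";")
        if len(gs) != len(rs):
            raise FormatError(
                f"{path}: probe {probe}: gene/group lists of unequal length ({len(gs)} vs {len(rs)})"
            )
        for g, r in zip(gs, rs):
            r = _GROUP_ALIASES.get(r, r)
            if r not in REGION_GROUPS:
                raise FormatError(f"{path}: probe {probe}: unknown region group '{r}'")
            probes.append(probe)
            genes.append(g)
            groups.append(r)
    rec = pd.DataFrame({"probe_id": probes, "gene": genes, "group": groups})
    rec = rec.drop_duplicates(ignore_index=True)
    return ProbeAnnotation(rec)


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    """Write one flat record per row (a valid, if verbose, manifest dialect)."""
    ann.records.to_csv(path, sep="\t", index=False)


_PHENO_COLUMNS = (
    "label",
    "age",
    "sex",
    "diagnosis_year",
    "mono",
    "gran",
    "lympho",
    "cd4",
    "cd8",
    "nk",
    "bcell",
    "tcell",
)


def read_phenotype(path) -> Phenotype:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'sample_id'")
    df = df.set_index("sample_id")
    unknown = set(df.columns) - set(_PHENO_COLUMNS)
    if unknown:
        raise FormatError(f"{path}: unknown phenotype column(s): {sorted(unknown)}")
    if "diagnosis_year" in df.columns:
        df["diagnosis_year"] = df["diagnosis_year"].astype("Int64")
    return Phenotype(df)


def write_phenotype(pheno: Phenotype, path) -> None:
    pheno.frame.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# gene/region index
# ---------------------------------------------------------------------------


def build_gene_region_index(
    ann: ProbeAnnotation, beta: BetaMatrix, min_probes: int = 2
) -> GeneRegionIndex:
    """Partition each gene's measured probes into promoter and other sides.

    A probe annotated to both a promoter and a non-promoter group of the same
    gene contributes to both sides. Genes with fewer than ``min_probes``
    measured probes on either side are excluded (both variance terms of the
    SIMPO statistic are undefined for singleton sides).
    """
    if min_probes < 2:
        raise ValueError("min_probes must be >= 2")
    measured = set(beta.values.index)
    rec = ann.records[ann.records["probe_id"].isin(measured)]
    if rec.empty:
        raise FormatError("annotation and beta matrix share no probes")
    genes: dict[str, tuple[list[str], list[str]]] = {}
    n_excluded = 0
    for gene, sub in rec.groupby("gene", sort=True):
        prom = sorted(set(sub.loc[sub["group"].isin(PROMOTER_GROUPS), "probe_id"]))
        other = sorted(set(sub.loc[sub["group"].isin(OTHER_GROUPS), "probe_id"]))
        if len(prom) >= min_probes and len(other) >= min_probes:
            genes[str(gene)] = (prom, other)
        else:
            n_excluded += 1
    logger.info("gene/region index: %d genes kept, %d excluded", len(genes), n_excluded)
    return GeneRegionIndex(genes=genes, n_excluded=n_excluded, min_probes=min_probes)
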
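"""QC, two-step geometric-mean normalization of nCounter-style panel counts,
and the tumor inflammation signature (TIS).

The panel mixes positive/negative spike-in controls, housekeeping genes and
endogenous genes. QC excludes samples whose housekeeping geometric mean of
raw counts is below 100. Normalization proceeds in two identical steps —
first on positive controls, then on housekeeping genes: per sample compute
the geometric mean of the control set (geomean_control), take the grand
geometric mean of those values across samples (geomean_geomeans), and scale
every count in the sample by geomean_geomeans / geomean_control.

The TIS is a weighted sum of log2 normalized counts over an 18-gene immune
panel; the weights file defines the operative gene set, because published
weight values live in the signature's reference publication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "HOUSEKEEPING_GENES",
    "TIS_GENES",
    "PanelCountMatrix",
    "NormalizationFactors",
    "QCResult",
    "qc_filter",
    "normalize",
    "tis_score",
    "load_tis_weights",
    "default_tis_weights_path",
    "read_rcc_counts",
]

#: Housekeeping genes whose raw-count geometric mean is the QC metric.
HOUSEKEEPING_GENES: tuple[str, ...] = ("DDX50", "EIF2B4", "MRPS5", "SAP130")

#: The printed TIS gene list (17 symbols; the operative set is whatever the
#: weights file provides, so an 18th gene such as CMKLR1 is a drop-in).
TIS_GENES: tuple[str, ...] = (
    "PSMB10", "HLA-DQA1", "HLA-DRB1",           # antigen-presenting cells
    "HLA-E", "NKG7", "CD8A",                    # T/NK cell abundance
    "CCL5", "CXCL9", "CD27", "CXCR6", "IDO1", "STAT1",  # IFN activity
    "TIGIT", "LAG3", "CD274", "PDCD1LG2", "CD276",      # T-cell exhaustion
)

GENE_CLASSES = ("positive_control", "negative_control", "housekeeping", "endogenous")


@dataclass
class PanelCountMatrix:
    """Genes x samples count matrix plus a per-gene class annotation."""

    counts: pd.DataFrame  # index: gene, columns: sample
    gene_class: pd.Series  # index: gene -> class

    def __post_init__(self) -> None:
        self.gene_class = self.gene_class.reindex(self.counts.index)
        if self.gene_class.isna().any():
            missing = list(self.gene_class[self.gene_class.isna()].index[:5])
            raise ValueError(f"genes without a class annotation: {missing}")
        bad = set(self.gene_class) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if not (self.gene_class == "positive_control").any():
            raise ValueError("matrix must contain at least one positive control")

    def genes_of(self, cls: str) -> list[str]:
        return list(self.gene_class[self.gene_class == cls].index)

    @classmethod
    def from_tsv(cls, path, sep: str = "\t") -> "PanelCountMatrix":
        """Read a genes-x-samples table whose first columns are gene and
        gene_class."""
        df = pd.read_csv(path, sep=sep)
        for col in ("gene", "gene_class"):
            if col not in df.columns:
                raise ValueError(f"count table is missing the {col!r} column")
        df = df.set_index("gene")
        return cls(
            counts=df.drop(columns="gene_class").astype(float),
            gene_class=df["gene_class"],
        )

    def to_tsv(self, path, sep: str = "\t") -> None:
        out = self.counts.copy()
        out.insert(0, "gene_class", self.gene_class)
        out.to_csv(path, sep=sep, index_label="gene")


def _geomean(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Geometric mean along ``axis``; any zero in a slice makes it 0."""
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("geometric mean requires nonnegative values")
    has_zero = (values == 0).any(axis=axis)
    safe = np.where(values > 0, values, 1.0)
    return np.where(has_zero, 0.0, np.exp(np.mean(np.log(safe), axis=axis)))


@dataclass(frozen=True)
class QCResult:
    passing: list[str]
    excluded: dict[str, str]  # sample -> reason
    housekeeping_geomean: pd.Series


def qc_filter(matrix: PanelCountMatrix, min_geomean: float = 100.0) -> QCResult:
    """Exclude samples whose housekeeping raw-count geometric mean is < 100.

    The comparison is strict: a geometric mean of exactly 100 passes. Every
    housekeeping gene must be present in the matrix.
    """
    missing = [g for g in HOUSEKEEPING_GENES if g not in matrix.counts.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    hk = matrix.counts.loc[list(HOUSEKEEPING_GENES)]
    gm = pd.Series(_geomean(hk.to_numpy(), axis=0), index=matrix.counts.columns)
    excluded = {
        s: f"housekeeping geometric mean {gm[s]:.4g} < {min_geomean:g}"
        for s in matrix.counts.columns
        if gm[s] < min_geomean
    }
    passing = [s for s in matrix.counts.columns if s not in excluded]
    return QCResult(passing=passing, excluded=excluded, housekeeping_geomean=gm)


@dataclass(frozen=True)
class NormalizationFactors:
    positive_control: pd.Series  # per-sample factor from step 1
    housekeeping: pd.Series  # per-sample factor from step 2


def _normalization_step(
    counts: pd.DataFrame, control_genes: list[str], label: str
) -> tuple[pd.DataFrame, pd.Series]:
    gm = _geomean(counts.loc[control_genes].to_numpy(), axis=0)
    if (gm <= 0).any():
        bad = [s for s, g in zip(counts.columns, gm) if g <= 0]
        raise ValueError(
            f"zero geometric mean of {label} genes in sample(s) {bad}; "
            "cannot normalize"
        )
    grand = float(np.exp(np.mean(np.log(gm))))
    factors = pd.Series(grand / gm, index=counts.columns)
    return counts * factors, factors


def normalize(
    matrix: PanelCountMatrix,
) -> tuple[PanelCountMatrix, NormalizationFactors]:
    """Two-step geometric-mean normalization (positive controls, then
    housekeeping genes) applied to all genes of QC-passing input."""
    pos = matrix.genes_of("positive_control")
    step1, f_pos = _normalization_step(matrix.counts, pos, "positive-control")
    step2, f_hk = _normalization_step(step1, list(HOUSEKEEPING_GENES), "housekeeping")
    return (
        PanelCountMatrix(counts=step2, gene_class=matrix.gene_class.copy()),
        NormalizationFactors(positive_control=f_pos, housekeeping=f_hk),
    )


def default_tis_weights_path():
    """Path to the bundled placeholder weights (unit weight per printed TIS
    gene). These are a documented stand-in, not published weight values."""
    return resources.files("rrdkit.data") / "tis_weights_unit.tsv"


def load_tis_weights(path=None) -> pd.Series:
    """Load a (gene, weight) TSV into a Series indexed by gene."""
    df = pd.read_csv(path or default_tis_weights_path(), sep="\t")
    if not {"gene", "weight"} <= set(df.columns):
        raise ValueError("weights file must have 'gene' and 'weight' columns")
    return df.set_index("gene")["weight"].astype(float)


def tis_score(
    normalized: PanelCountMatrix,
    weights: pd.Series,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample TIS: sum over weight genes of weight * log2(count + 1).

    Every gene in the weights file must be present in the matrix; missing
    genes are reported by name.
    """
    missing = [g for g in weights.index if g not in normalized.counts.index]
    if missing:
        raise ValueError(f"TIS weight genes absent from matrix: {missing}")
    sub = normalized.counts.loc[list(weights.index)]
    logged = np.log2(sub + pseudocount)
    return pd.Series(
        weights.to_numpy() @ logged.to_numpy(),
        index=normalized.counts.columns,
        name="tis",
    )


_RCC_CLASS_MAP = {
    "positive": "positive_control",
    "negative": "negative_control",
    "housekeeping": "housekeeping",
    "endogenous": "endogenous",
}


def read_rcc_counts(path, sample: str) -> PanelCountMatrix:
    """Minimal parser for the CodeSummary section of an RCC-like text file.

    Reads CSV lines ``CodeClass,Name,Accession,Count`` between
    ``<Code_Summary>`` and ``</Code_Summary>`` and returns a one-sample
    matrix.
    """
    rows = []
    in_section = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.lower() == "<code_summary>":
                in_section = True
                continue
            if line.lower() == "</code_summary>":
                break
            if not in_section or not line:
                continue
            parts = line.split(",")
            if parts[0] == "CodeClass":
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed CodeSummary line: {line!r}")
            cls = _RCC_CLASS_MAP.get(parts[0].strip().lower())
            if cls is None:
                raise ValueError(f"unknown CodeClass {parts[0]!r}")
            rows.append((parts[1].strip(), cls, float(parts[3])))
    if not rows:
        raise ValueError(f"no CodeSummary section found in {path}")
    df = pd.DataFrame(rows, columns=["gene", "gene_class", sample]).set_index("gene")
    return PanelCountMatrix(counts=df[[sample]], gene_class=df["gene_class"])
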
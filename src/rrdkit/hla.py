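"""HLA class-I loss-of-heterozygosity calling from paired allele coverage.

For each HLA gene (A, B, C) the two typed alleles are compared at their
mismatch positions: the per-position tumor coverage ratio
allele1/allele2 is normalized by the matched-normal ratio at the same
position, and a paired two-sided test asks whether the log ratio departs
from zero. The decision rule is deliberately simple: LOH iff the paired
p-value is strictly below 0.01. A copy-number estimate may be reported
alongside but never gates the call — in hypermutation-driven tumors
copy-number losses are rare and a combined copy-number cutoff would
under-call LOH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AllelePairCoverage",
    "ImbalanceResult",
    "LOHCall",
    "LOH_ALPHA",
    "MIN_MISMATCH_POSITIONS",
    "allelic_imbalance_test",
    "call_loh",
]

LOH_ALPHA = 0.01
MIN_MISMATCH_POSITIONS = 5


@dataclass
class AllelePairCoverage:
    """Per-position coverage of the two alleles of one HLA gene, in tumor
    and matched normal, at positions where the allele sequences differ."""

    gene: str  # HLA-A / HLA-B / HLA-C
    tumor_allele1: np.ndarray
    tumor_allele2: np.ndarray
    normal_allele1: np.ndarray
    normal_allele2: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(a, dtype=float)
            for a in (
                self.tumor_allele1,
                self.tumor_allele2,
                self.normal_allele1,
                self.normal_allele2,
            )
        ]
        n = {a.shape for a in arrays}
        if len(n) != 1:
            raise ValueError("coverage vectors must have identical length")
        if any((a < 0).any() for a in arrays):
            raise ValueError("coverage must be nonnegative")
        (
            self.tumor_allele1,
            self.tumor_allele2,
            self.normal_allele1,
            self.normal_allele2,
        ) = arrays

    @property
    def n_mismatch_positions(self) -> int:
        return int(self.tumor_allele1.shape[0])


@dataclass(frozen=True)
class ImbalanceResult:
    gene: str
    p_value: float | None
    statistic: float | None
    n_positions: int
    status: str  # "ok" or "insufficient_positions"


def allelic_imbalance_test(
    x: AllelePairCoverage,
    test: str = "paired-t",
    pseudocount: float = 0.5,
) -> ImbalanceResult:
    """Paired two-sided test for allelic imbalance on log coverage ratios.

    Per position: d = log((t1+q)/(t2+q)) - log((n1+q)/(n2+q)) with
    pseudocount q; the normal-derived term removes allele-specific capture
    bias. ``test`` is "paired-t" (default) or "wilcoxon" (signed-rank).
    Fewer than 5 mismatch positions cannot support the test; an explicit
    insufficient status is returned, never a fabricated p-value.
    """
    if test not in ("paired-t", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}; use 'paired-t' or 'wilcoxon'")
    n = x.n_mismatch_positions
    if n < MIN_MISMATCH_POSITIONS:
        return ImbalanceResult(
            gene=x.gene, p_value=None, statistic=None, n_positions=n,
            status="insufficient_positions",
        )
    d = np.log(
        (x.tumor_allele1 + pseudocount) / (x.tumor_allele2 + pseudocount)
    ) - np.log(
        (x.normal_allele1 + pseudocount) / (x.normal_allele2 + pseudocount)
    )
    if np.allclose(d, 0.0):
        # identical ratios at every position: no evidence of imbalance
        return ImbalanceResult(
            gene=x.gene, p_value=1.0, statistic=0.0, n_positions=n, status="ok"
        )
    if test == "paired-t":
        res = stats.ttest_1samp(d, popmean=0.0)
    else:
        res = stats.wilcoxon(d)
    return ImbalanceResult(
        gene=x.gene,
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        n_positions=n,
        status="ok",
    )


@dataclass(frozen=True)
class LOHCall:
    gene: str
    p_value: float
    loh: bool
    copy_number_estimate: float | None = None


def call_loh(
    p_value: float,
    copy_number_estimate: float | None = None,
    gene: str = "",
    alpha: float = LOH_ALPHA,
) -> LOHCall:
    """LOH iff p < alpha (strict); the copy-number estimate is carried in
    the output for reporting but never participates in the decision."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p_value must be in [0, 1], got {p_value}")
    return LOHCall(
        gene=gene,
        p_value=p_value,
        loh=p_value < alpha,
        copy_number_estimate=copy_number_estimate,
    )
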
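"""TCR repertoire metrics: clonotype down-sampling and diversity summaries.

Sequencing depth varies across repertoire libraries, so clonotype tables
are down-sampled to a common read total (a multivariate hypergeometric
draw of reads without replacement, the count-level equivalent of
down-sampling raw reads) before computing clone counts, clonotypes per
1,000 reads, and Shannon diversity (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DownsampleResult",
    "RepertoireSummary",
    "downsample",
    "summary_metrics",
    "read_clonotype_tsv",
]

CHAINS = ("alpha", "beta", "gamma", "delta")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("clonotype", "chain", "count"):
        if col not in table.columns:
            raise ValueError(f"clonotype table is missing the {col!r} column")
    if (table["count"] < 1).any():
        raise ValueError("clonotype counts must be >= 1")
    bad = set(table["chain"]) - set(CHAINS)
    if bad:
        raise ValueError(f"unknown chains: {sorted(bad)}")
    if table.duplicated(["chain", "clonotype"]).any():
        raise ValueError("clonotype identifiers must be unique per chain")
    return table


@dataclass
class DownsampleResult:
    table: pd.DataFrame
    target_reads: int
    status: str  # "ok" or "insufficient_reads" (returned unchanged)


def downsample(
    table: pd.DataFrame, target_reads: int, seed: int | np.random.Generator = 0
) -> DownsampleResult:
    """Draw exactly ``target_reads`` reads without replacement across
    clonotypes (multivariate hypergeometric); clonotypes drawn to zero are
    dropped. A table with fewer total reads than the target is returned
    unchanged with an ``insufficient_reads`` status.
    """
    table = _validate(table)
    if target_reads < 1:
        raise ValueError("target_reads must be >= 1")
    total = int(table["count"].sum())
    if total < target_reads:
        return DownsampleResult(
            table=table.copy(), target_reads=target_reads,
            status="insufficient_reads",
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    drawn = rng.multivariate_hypergeometric(
        table["count"].to_numpy(dtype=np.int64), target_reads
    )
    out = table.copy()
    out["count"] = drawn
    out = out[out["count"] > 0].reset_index(drop=True)
    return DownsampleResult(table=out, target_reads=target_reads, status="ok")


@dataclass(frozen=True)
class RepertoireSummary:
    clone_count: int
    total_reads: int
    clonotypes_per_1000_reads: float
    shannon_diversity: float


def summary_metrics(table: pd.DataFrame, per_reads: int = 1000) -> RepertoireSummary:
    """Clone count, clonotypes per 1,000 reads, and Shannon H (natural log).

    per-1,000 = clone_count / (total_reads / 1000); H = -sum f_i ln f_i
    over clonotype read frequencies. Equal counts give H = ln(clone_count).
    """
    table = _validate(table)
    if table.empty:
        raise ValueError("clonotype table is empty")
    counts = table["count"].to_numpy(dtype=float)
    total = counts.sum()
    clone_count = len(table)
    return RepertoireSummary(
        clone_count=clone_count,
        total_reads=int(total),
        clonotypes_per_1000_reads=clone_count / (total / per_reads),
        shannon_diversity=float(stats.entropy(counts / total)),
    )


def read_clonotype_tsv(path) -> pd.DataFrame:
    return _validate(
        pd.read_csv(path, sep="\t", dtype={"clonotype": str, "chain": str})
    )
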
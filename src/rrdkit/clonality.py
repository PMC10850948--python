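"""Cancer cell fraction (CCF) and clonal classification.

The CCF of a somatic mutation is the fraction of tumor cells that carry it,
estimated from the observed variant allele fraction (VAF) corrected for
tumor purity ``p``, local tumor copy number ``c``, normal copy number
(2 for autosomes) and mutation multiplicity ``m``:

    CCF = vaf * (p*c + (1 - p)*c_normal) / (m * p)

Mutations with CCF strictly greater than 0.85 are classified clonal. The
formula is deliberately confined to :func:`compute_ccf` so an alternative
rendering can be swapped in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CCFInput",
    "CCFRecord",
    "CLONAL_CCF_THRESHOLD",
    "compute_ccf",
    "classify_clonal",
    "infer_multiplicity",
    "ccf_table",
]

#: CCF above which a mutation is called clonal (strict >).
CLONAL_CCF_THRESHOLD = 0.85


@dataclass(frozen=True)
class CCFInput:
    """Per-variant inputs to the CCF computation.

    Purity/copy-number estimation (e.g. ASCAT) is upstream; ``p``, ``c`` and
    ``m`` arrive as inputs here.
    """

    vaf: float
    p: float  # tumor purity
    c: float  # local tumor copy number
    m: int = 1  # multiplicity (copies carrying the mutation)
    c_normal: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.p}")
        if self.c < 0:
            raise ValueError(f"local copy number must be >= 0, got {self.c}")
        if self.m < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.m}")
        if self.m > max(self.c, 1):
            raise ValueError(
                f"multiplicity {self.m} exceeds local copy number {self.c}"
            )


@dataclass(frozen=True)
class CCFRecord:
    ccf: float  # capped at 1.0
    ccf_raw: float  # uncapped estimate
    clonal: bool
    threshold: float = CLONAL_CCF_THRESHOLD


def compute_ccf(x: CCFInput, threshold: float = CLONAL_CCF_THRESHOLD) -> CCFRecord:
    """CCF of one mutation; the raw estimate is retained alongside the value
    capped at 1.0 (sampling noise can push the raw estimate above 1)."""
    raw = x.vaf * (x.p * x.c + (1.0 - x.p) * x.c_normal) / (x.m * x.p)
    ccf = min(raw, 1.0)
    return CCFRecord(
        ccf=ccf, ccf_raw=raw, clonal=classify_clonal(ccf, threshold), threshold=threshold
    )


def classify_clonal(ccf: float, threshold: float = CLONAL_CCF_THRESHOLD) -> bool:
    """Clonal iff CCF is strictly greater than the threshold."""
    if not 0.0 <= ccf <= 1.0:
        raise ValueError(f"ccf must be in [0, 1], got {ccf}")
    return ccf > threshold


def infer_multiplicity(vaf: float, p: float, c: float, c_normal: float = 2.0) -> int:
    """Nearest-integer multiplicity when it is not supplied.

    m = round(vaf * (p*c + (1-p)*c_normal) / p), clipped to [1, c]. This is
    the value that puts the CCF closest to 1 among integer multiplicities.
    """
    if p <= 0:
        raise ValueError("purity must be positive")
    m = round(vaf * (p * c + (1.0 - p) * c_normal) / p)
    return int(min(max(m, 1), max(c, 1)))


def ccf_table(df: pd.DataFrame, threshold: float = CLONAL_CCF_THRESHOLD) -> pd.DataFrame:
    """Vectorized CCF over a table with columns vaf, p, c and optional m,
    c_normal; returns a copy with ccf, ccf_raw and clonal columns appended.

    Rows without an ``m`` column (or with missing m) get the inferred
    multiplicity.
    """
    out = df.copy()
    if "c_normal" not in out:
        out["c_normal"] = 2.0
    if "m" not in out:
        out["m"] = pd.NA
    records = []
    for row in out.itertuples(index=False):
        m = row.m
        if pd.isna(m):
            m = infer_multiplicity(row.vaf, row.p, row.c, row.c_normal)
        rec = compute_ccf(
            CCFInput(vaf=row.vaf, p=row.p, c=row.c, m=int(m), c_normal=row.c_normal),
            threshold,
        )
        records.append((int(m), rec.ccf, rec.ccf_raw, rec.clonal))
    out[["m", "ccf", "ccf_raw", "clonal"]] = pd.DataFrame(records, index=out.index)
    return out
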
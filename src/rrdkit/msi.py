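"""MMRDness: a microsatellite-instability score from low-pass sequencing.

Mismatch-repair deficient genomes accumulate single-base deletions at
homopolymer microsatellites. The score summarises, over 'A'-homopolymer
loci 10-15 bases long, the per-locus proportion of reads carrying a
single-base deletion:

    score = log10( sum over passing loci of del1_reads/total_reads ) + 1.1

The additive scalar 1.1 places typical proficient samples near zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log10
from typing import Iterable

import pandas as pd

__all__ = [
    "MicrosatelliteLocus",
    "MMRDnessResult",
    "MMRDNESS_OFFSET",
    "mmrdness_score",
    "read_loci_tsv",
    "write_loci_tsv",
]

MMRDNESS_OFFSET = 1.1


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """Read summary at one homopolymer microsatellite locus."""

    locus_id: str
    base: str  # repeat unit, e.g. 'A'
    length: int  # homopolymer run length in bases
    total_reads: int
    del1_reads: int  # reads with a single-base deletion

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.total_reads < 0 or self.del1_reads < 0:
            raise ValueError("read counts must be nonnegative")
        if self.del1_reads > self.total_reads:
            raise ValueError(
                f"del1_reads {self.del1_reads} > total_reads {self.total_reads} "
                f"at locus {self.locus_id}"
            )

    @property
    def proportion(self) -> float:
        return self.del1_reads / self.total_reads if self.total_reads else 0.0


@dataclass(frozen=True)
class MMRDnessResult:
    n_loci_used: int
    sum_proportions: float
    score: float | None  # None iff below detection (sum == 0)
    status: str  # "ok" or "below_detection"
    offset: float = MMRDNESS_OFFSET


def mmrdness_score(
    loci: Iterable[MicrosatelliteLocus],
    min_len: int = 10,
    max_len: int = 15,
    min_coverage: int = 10,
    base: str = "A",
) -> MMRDnessResult:
    """Score a sample from its microsatellite locus table.

    Loci enter the sum iff repeat base matches, min_len <= length <= max_len
    (inclusive) and total_reads >= min_coverage. A zero proportion sum is a
    legitimate "below detection" outcome (log undefined), reported as an
    explicit status rather than -inf; a table in which no locus passes the
    filters is an error.
    """
    passing = [
        loc
        for loc in loci
        if loc.base == base
        and min_len <= loc.length <= max_len
        and loc.total_reads >= min_coverage
    ]
    if not passing:
        raise ValueError(
            f"no locus passed the filters (base={base!r}, "
            f"length in [{min_len}, {max_len}], coverage >= {min_coverage})"
        )
    total = sum(loc.proportion for loc in passing)
    if total == 0.0:
        return MMRDnessResult(
            n_loci_used=len(passing),
            sum_proportions=0.0,
            score=None,
            status="below_detection",
        )
    return MMRDnessResult(
        n_loci_used=len(passing),
        sum_proportions=total,
        score=log10(total) + MMRDNESS_OFFSET,
        status="ok",
    )


_COLUMNS = ["locus_id", "base", "length", "total_reads", "del1_reads"]


def read_loci_tsv(path) -> list[MicrosatelliteLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "base": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"locus table is missing columns: {missing}")
    return [
        MicrosatelliteLocus(
            locus_id=r.locus_id,
            base=r.base,
            length=int(r.length),
            total_reads=int(r.total_reads),
            del1_reads=int(r.del1_reads),
        )
        for r in df.itertuples(index=False)
    ]


def write_loci_tsv(loci: Iterable[MicrosatelliteLocus], path) -> None:
    pd.DataFrame([loc.__dict__ for loc in loci], columns=_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
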
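"""Consensus merging of per-caller somatic call sets, TMB, and immune-escape flagging.

Somatic variant calling pipelines run several callers over the same
tumor/normal pair and keep only variants supported by a minimum number of
them (here: 2 of 4). Tumor mutational burden (TMB) is then the number of
consensus somatic SNVs divided by the callable territory in megabases
(~50 Mb for a whole exome).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantCall",
    "ConsensusVariant",
    "ConsensusVariantSet",
    "TMBResult",
    "ImmuneEscapePanel",
    "DEFAULT_IMMUNE_ESCAPE_GENES",
    "normalize_alleles",
    "merge_consensus",
    "compute_tmb",
    "flag_immune_escape",
]

#: Antigen-presentation / interferon-signaling genes screened as markers of
#: immune resistance or escape. "IRF" is kept as printed (no family-member
#: number is specified); callers may substitute their own list.
DEFAULT_IMMUNE_ESCAPE_GENES: tuple[str, ...] = (
    "B2M",
    "JAK1",
    "JAK2",
    "IFNGR1",
    "IFNGR2",
    "TYK2",
    "STAT1",
    "STAT2",
    "STAT5A",
    "STAT5B",
    "IRF",
)


@dataclass(frozen=True)
class VariantCall:
    """One somatic call from one caller.

    Coordinates are 1-based (VCF convention). ``vclass`` is derived:
    "SNV" iff both alleles are single bases, otherwise "indel".
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    caller: str = ""
    vaf: float | None = None
    depth: int | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty allele strings")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")

    @property
    def vclass(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce an allele pair to its parsimonious minimal representation.

    Callers represent the same indel differently (padded bases, redundant
    context). The shared suffix is trimmed first, then the shared prefix
    (advancing ``pos``), always keeping at least one base in each allele.
    SNVs pass through unchanged.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _normalized(call: VariantCall) -> VariantCall:
    pos, ref, alt = normalize_alleles(call.pos, call.ref, call.alt)
    if (pos, ref, alt) == (call.pos, call.ref, call.alt):
        return call
    return replace(call, pos=pos, ref=ref, alt=alt)


@dataclass(frozen=True)
class ConsensusVariant:
    """A variant retained by the consensus rule, with per-caller provenance."""

    chrom: str
    pos: int
    ref: str
    alt: str
    callers: frozenset[str]
    vaf: float | None = None  # median across supporting callers
    depth: int | None = None  # median across supporting callers
    gene: str | None = None

    @property
    def vclass(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConsensusVariantSet:
    variants: list[ConsensusVariant]
    min_callers: int = 2
    total_callers: int = 4

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def _median_or_none(values: Sequence[float]) -> float | None:
    vals = [v for v in values if v is not None]
    return statistics.median(vals) if vals else None


def merge_consensus(
    callsets: Mapping[str, Iterable[VariantCall]],
    min_callers: int = 2,
) -> ConsensusVariantSet:
    """Merge per-caller call sets, retaining variants seen by >= ``min_callers``.

    Variants are keyed on (chrom, pos, ref, alt) after allele normalization;
    duplicate calls by the same caller count once. SNVs and indels are merged
    separately and the results unioned (the key spaces are disjoint, so this
    mirrors per-class consensus files). Consensus VAF and depth are medians
    across supporting callers.
    """
    if not callsets:
        raise ValueError("at least one caller's call set is required")
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")

    merged: list[ConsensusVariant] = []
    for vclass in ("SNV", "indel"):
        support: dict[tuple, dict[str, VariantCall]] = {}
        for caller, calls in callsets.items():
            for call in calls:
                call = _normalized(call)
                if call.vclass != vclass:
                    continue
                support.setdefault(call.key, {})[caller] = call
        for key, by_caller in support.items():
            if len(by_caller) < min_callers:
                continue
            calls = list(by_caller.values())
            genes = [c.gene for c in calls if c.gene]
            merged.append(
                ConsensusVariant(
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    callers=frozenset(by_caller),
                    vaf=_median_or_none([c.vaf for c in calls]),
                    depth=_median_or_none([c.depth for c in calls]),
                    gene=genes[0] if genes else None,
                )
            )
    merged.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return ConsensusVariantSet(
        variants=merged, min_callers=min_callers, total_callers=len(callsets)
    )


@dataclass(frozen=True)
class TMBResult:
    n_snv: int
    callable_mb: float = 50.0
    tmb: float = field(init=False)

    def __post_init__(self) -> None:
        if self.callable_mb <= 0:
            raise ValueError("callable_mb must be positive")
        object.__setattr__(self, "tmb", self.n_snv / self.callable_mb)


def compute_tmb(
    consensus: ConsensusVariantSet, callable_mb: float = 50.0
) -> TMBResult:
    """TMB in mutations/Mb: consensus somatic SNVs over callable megabases.

    Indels are excluded from the numerator.
    """
    n_snv = sum(1 for v in consensus if v.vclass == "SNV")
    return TMBResult(n_snv=n_snv, callable_mb=callable_mb)


@dataclass(frozen=True)
class ImmuneEscapePanel:
    genes: tuple[str, ...] = DEFAULT_IMMUNE_ESCAPE_GENES

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must contain at least one gene symbol")
        if len({g.strip().upper() for g in self.genes}) != len(self.genes):
            raise ValueError("panel gene symbols must be unique")


def flag_immune_escape(
    consensus: ConsensusVariantSet,
    panel: ImmuneEscapePanel | None = None,
) -> pd.DataFrame:
    """Count consensus variants in each immune-escape panel gene.

    Matching is case-insensitive after whitespace strip; panel genes with no
    hits appear as zero rows, so the table always has one row per panel gene.
    """
    panel = panel or ImmuneEscapePanel()
    counts = {g: 0 for g in panel.genes}
    lookup = {g.strip().upper(): g for g in panel.genes}
    for v in consensus:
        if v.gene is None:
            continue
        hit = lookup.get(v.gene.strip().upper())
        if hit is not None:
            counts[hit] += 1
    return pd.DataFrame(
        {"gene": list(counts), "n_variants": list(counts.values())}
    )
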
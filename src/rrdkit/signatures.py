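"""Indel mutational-signature refitting over the 83-channel ID context set.

A sample's indel catalog (counts over the standard 83 indel context
channels: 1-bp insertions/deletions by homopolymer length and C/T class,
longer insertions/deletions by repeat number, and microhomology-flanked
deletions) is decomposed as a nonnegative combination of reference
signature columns by nonnegative least squares:

    weights = argmin_{w >= 0} || catalog - S w ||_2

Absolute contributions are the fitted weights (in mutations); relative
contributions are weights / sum(weights). Signature ID8, attributed to
double-strand-break repair of ionizing-radiation damage by end joining, is
the quantity of interest in the radiation analyses, but any signature in
the matrix can be queried. The same operation refits 96-channel SBS
catalogs against an SBS matrix.

The bundled reference matrix is synthetic (ID1/ID2/ID8-like column shapes,
valid probability vectors) so the package builds and tests without any
download; a real COSMIC matrix in the same TSV layout is a drop-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variants import VariantCall, normalize_alleles

__all__ = [
    "ID83_CHANNELS",
    "id83_channels",
    "SignatureMatrix",
    "RefitResult",
    "load_signature_matrix",
    "default_signature_matrix_path",
    "refit",
    "relative_contribution",
    "classify_1bp_indels",
    "synthetic_id83_matrix",
]


def id83_channels() -> list[str]:
    """The 83 indel context channels in canonical order.

    Labels follow the ``{size}:{Del|Ins}:{type}:{subindex}`` convention:
    1-bp events are typed by the pyrimidine class of the affected base
    (C or T, folding G->C and A->T) with subindex encoding homopolymer
    length (deletions: 0 = length 1 ... 5 = length 6+; insertions:
    0 = zero existing repeats ... 5 = 5+); longer events are typed R
    (repeat) with subindex the repeat count, or M (microhomology) with
    subindex the homology length.
    """
    channels: list[str] = []
    for base in ("C", "T"):
        channels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):
        channels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for size in (2, 3, 4, 5):
        channels += [f"{size}:Del:R:{i}" for i in range(6)]
    for size in (2, 3, 4, 5):
        channels += [f"{size}:Ins:R:{i}" for i in range(6)]
    for size, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        channels += [f"{size}:Del:M:{i}" for i in range(1, max_mh + 1)]
    assert len(channels) == 83
    return channels


ID83_CHANNELS: tuple[str, ...] = tuple(id83_channels())


@dataclass
class SignatureMatrix:
    """Channels x signatures probability matrix (columns sum to 1)."""

    probabilities: pd.DataFrame  # index: channel, columns: signature id

    def __post_init__(self) -> None:
        probs = self.probabilities
        if (probs.to_numpy() < 0).any():
            raise ValueError("signature probabilities must be nonnegative")
        sums = probs.sum(axis=0)
        off = sums[(sums - 1.0).abs() > 1e-6]
        if len(off):
            raise ValueError(
                f"signature columns must sum to 1: {dict(off.round(6))}"
            )

    @property
    def signature_ids(self) -> list[str]:
        return list(self.probabilities.columns)

    @property
    def channels(self) -> list[str]:
        return list(self.probabilities.index)


def default_signature_matrix_path():
    return resources.files("rrdkit.data") / "synthetic_id83_signatures.tsv"


def load_signature_matrix(path=None) -> SignatureMatrix:
    """Load a channel x signature TSV (first column ``channel``)."""
    df = pd.read_csv(path or default_signature_matrix_path(), sep="\t")
    if "channel" not in df.columns:
        raise ValueError("signature matrix must have a 'channel' column")
    return SignatureMatrix(probabilities=df.set_index("channel").astype(float))


@dataclass(frozen=True)
class RefitResult:
    absolute: pd.Series  # fitted mutations per signature
    relative: pd.Series | None  # fractions summing to 1; None if catalog empty
    residual_norm: float
    status: str  # "ok" or "empty_catalog"


def refit(
    catalog: pd.Series | Sequence[float],
    signatures: SignatureMatrix,
) -> RefitResult:
    """Nonnegative least-squares refit of a catalog against signature columns.

    The catalog must be indexed by (or ordered as) the matrix's channels; a
    mismatched channel set is an error, never silently reordered away. An
    all-zero catalog yields zero absolute contributions and an undefined
    (None) relative vector.
    """
    channels = signatures.channels
    if isinstance(catalog, pd.Series):
        if list(catalog.index) != channels:
            if set(catalog.index) != set(channels):
                raise ValueError(
                    "catalog channels do not match the signature matrix"
                )
            catalog = catalog.reindex(channels)
        y = catalog.to_numpy(dtype=float)
    else:
        y = np.asarray(catalog, dtype=float)
        if y.shape[0] != len(channels):
            raise ValueError(
                f"catalog has {y.shape[0]} channels, matrix has {len(channels)}"
            )
    if (y < 0).any():
        raise ValueError("catalog counts must be nonnegative")

    ids = signatures.signature_ids
    if not y.any():
        return RefitResult(
            absolute=pd.Series(0.0, index=ids),
            relative=None,
            residual_norm=0.0,
            status="empty_catalog",
        )
    weights, rnorm = nnls(signatures.probabilities.to_numpy(), y)
    absolute = pd.Series(weights, index=ids)
    total = absolute.sum()
    relative = absolute / total if total > 0 else None
    return RefitResult(
        absolute=absolute,
        relative=relative,
        residual_norm=float(rnorm),
        status="ok" if relative is not None else "empty_catalog",
    )


def relative_contribution(result: RefitResult, signature_id: str) -> float:
    """Relative weight of one signature; 0.0 is a legitimate value
    (absence of the signature)."""
    if result.relative is None:
        raise ValueError("refit produced no relative contributions "
                         f"(status={result.status})")
    if signature_id not in result.relative.index:
        raise KeyError(
            f"unknown signature {signature_id!r}; "
            f"matrix has {list(result.relative.index)}"
        )
    return float(result.relative[signature_id])


def classify_1bp_indels(
    variants: Iterable[VariantCall],
    homopolymer_run: Callable[[str, int, str], int],
    channels: Sequence[str] = ID83_CHANNELS,
) -> tuple[pd.Series, int]:
    """Bin 1-bp insertions/deletions into their ID-83 homopolymer channels.

    ``homopolymer_run(chrom, pos, base)`` must return the length of the
    homopolymer run of ``base`` containing/adjacent to the event (the
    deleted base counts itself; for insertions it is the number of existing
    copies). Indels longer than 1 bp, and SNVs, go to the unclassified
    count and are excluded from refitting. Returns (catalog, unclassified).
    """
    catalog = pd.Series(0, index=list(channels), dtype=int)
    unclassified = 0
    for v in variants:
        pos, ref, alt = normalize_alleles(v.pos, v.ref, v.alt)
        if len(ref) == 2 and len(alt) == 1 and ref[0] == alt[0]:
            kind, base, anchor = "Del", ref[1], pos + 1
            run = max(int(homopolymer_run(v.chrom, anchor, base)), 1)
            sub = min(run, 6) - 1  # subindex 0 = run length 1, 5 = 6+
        elif len(ref) == 1 and len(alt) == 2 and ref[0] == alt[0]:
            kind, base, anchor = "Ins", alt[1], pos + 1
            run = max(int(homopolymer_run(v.chrom, anchor, base)), 0)
            sub = min(run, 5)  # subindex 0 = no existing repeat, 5 = 5+
        else:
            unclassified += 1
            continue
        pyr = {"A": "T", "T": "T", "C": "C", "G": "C"}.get(base.upper())
        if pyr is None:
            unclassified += 1
            continue
        catalog[f"1:{kind}:{pyr}:{sub}"] += 1
    return catalog, unclassified


def synthetic_id83_matrix() -> SignatureMatrix:
    """Deterministically construct the bundled synthetic reference matrix.

    Column shapes imitate the qualitative character of three COSMIC indel
    signatures without reproducing any published values:

    - ID1-like: 1-bp T insertions at long homopolymers (replication slippage),
    - ID2-like: 1-bp T deletions at long homopolymers (slippage on the
      template strand; dominant in mismatch-repair deficiency),
    - ID8-like: >=2-bp deletions spread over repeat and microhomology
      contexts (end-joining repair of double-strand breaks).
    """
    channels = id83_channels()
    cols = {}

    def col(weights: dict[str, float]) -> list[float]:
        total = sum(weights.values())
        return [weights.get(ch, 0.0) / total for ch in channels]

    cols["ID1"] = col(
        {f"1:Ins:T:{i}": w for i, w in zip(range(6), (1, 2, 4, 8, 30, 55))}
        | {f"1:Ins:C:{i}": 0.5 for i in range(6)}
    )
    cols["ID2"] = col(
        {f"1:Del:T:{i}": w for i, w in zip(range(6), (1, 2, 5, 10, 35, 47))}
        | {f"1:Del:C:{i}": 0.4 for i in range(6)}
    )
    id8 = {f"{s}:Del:R:0": 8.0 for s in (2, 3, 4, 5)}
    id8 |= {f"{s}:Del:R:1": 4.0 for s in (2, 3, 4, 5)}
    id8 |= {
        "2:Del:M:1": 10.0,
        "3:Del:M:1": 8.0, "3:Del:M:2": 4.0,
        "4:Del:M:1": 6.0, "4:Del:M:2": 4.0, "4:Del:M:3": 2.0,
        "5:Del:M:1": 6.0, "5:Del:M:2": 4.0, "5:Del:M:3": 3.0,
        "5:Del:M:4": 2.0, "5:Del:M:5": 2.0,
    }
    id8 |= {"1:Del:C:0": 1.0, "1:Del:T:0": 1.0}
    cols["ID8"] = col(id8)

    return SignatureMatrix(
        probabilities=pd.DataFrame(cols, index=pd.Index(channels, name="channel"))
    )
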
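"""Shared readers/writers: minimal VCF v4.2 (via pysam) and TSV helpers.

Call sets travel as plain-text VCF with ``VAF`` and ``DP`` INFO fields and
an optional ``GENE`` annotation; multiallelic records are split into one
call per ALT on read.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pysam

from .variants import ConsensusVariantSet, VariantCall

__all__ = ["read_vcf_minimal", "write_vcf_minimal", "write_consensus_vcf"]


def _build_header(contigs: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.add_meta(
        "INFO", items=[("ID", "VAF"), ("Number", "A"), ("Type", "Float"),
                       ("Description", "Variant allele fraction")]
    )
    header.add_meta(
        "INFO", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                       ("Description", "Read depth")]
    )
    header.add_meta(
        "INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Gene symbol")]
    )
    header.add_meta(
        "INFO", items=[("ID", "CALLERS"), ("Number", "."), ("Type", "String"),
                       ("Description", "Supporting callers")]
    )
    return header


def write_vcf_minimal(
    calls: Iterable[VariantCall], path: str | os.PathLike
) -> None:
    """Write calls as uncompressed VCF v4.2 with VAF/DP/GENE INFO fields."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    contigs = sorted({c.chrom for c in calls})
    header = _build_header(contigs or ["chr1"])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.chrom, start=call.pos - 1,
                alleles=(call.ref, call.alt), filter="PASS",
            )
            if call.vaf is not None:
                rec.info["VAF"] = (float(call.vaf),)
            if call.depth is not None:
                rec.info["DP"] = int(call.depth)
            if call.gene:
                rec.info["GENE"] = call.gene
            out.write(rec)


def write_consensus_vcf(
    consensus: ConsensusVariantSet, path: str | os.PathLike
) -> None:
    """Consensus set as VCF, recording the supporting callers per record."""
    variants = sorted(consensus, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    contigs = sorted({v.chrom for v in variants})
    header = _build_header(contigs or ["chr1"])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1,
                alleles=(v.ref, v.alt), filter="PASS",
            )
            if v.vaf is not None:
                rec.info["VAF"] = (float(v.vaf),)
            if v.depth is not None:
                rec.info["DP"] = int(round(v.depth))
            if v.gene:
                rec.info["GENE"] = v.gene
            rec.info["CALLERS"] = ",".join(sorted(v.callers))
            out.write(rec)


def _info_get(rec, key):
    """INFO lookup tolerant of keys missing from the header (pysam raises
    on those instead of returning None)."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _record_vaf(rec, alt_index: int) -> float | None:
    """VAF from INFO; falls back to AD/DP arithmetic when absent."""
    vaf = _info_get(rec, "VAF")
    if vaf is not None:
        if isinstance(vaf, tuple):
            vaf = vaf[alt_index] if alt_index < len(vaf) else vaf[0]
        return float(vaf)
    # fall back to first sample's AD/DP if the file has genotypes
    if rec.samples:
        sample = rec.samples[0]
        ad = sample.get("AD")
        dp = sample.get("DP") or _info_get(rec, "DP")
        if ad is not None and dp:
            return float(ad[alt_index + 1]) / float(dp)
    return None


def read_vcf_minimal(
    path: str | os.PathLike, caller: str = ""
) -> list[VariantCall]:
    """Read a VCF into VariantCall records, splitting multiallelic ALTs.

    VAF is taken from INFO/VAF, computed from AD/DP when possible, and
    left as None otherwise; downstream code treats missing VAF explicitly.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None:
                continue
            depth = _info_get(rec, "DP")
            gene = _info_get(rec, "GENE")
            for i, alt in enumerate(rec.alts):
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        caller=caller,
                        vaf=_record_vaf(rec, i),
                        depth=int(depth) if depth is not None else None,
                        gene=str(gene) if gene else None,
                    )
                )
    return calls


def read_callsets(
    paths: Mapping[str, str | os.PathLike]
) -> dict[str, list[VariantCall]]:
    """Read one VCF per caller label into the consensus-merge input shape."""
    return {caller: read_vcf_minimal(p, caller=caller) for caller, p in paths.items()}
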
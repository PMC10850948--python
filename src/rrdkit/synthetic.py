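"""Seeded synthetic inputs for every pipeline stage, with ground truth.

No patient-level data accompany the study this pipeline operationalizes,
so each stage is exercised on simulated inputs whose generating parameters
(the truth) are returned alongside: per-caller somatic call sets with known
CCF and clonality, A-homopolymer microsatellite read summaries, nCounter-
style panel count matrices, 83-channel indel catalogs from known signature
mixes, paired HLA allele coverage, clonotype tables, and survival cohorts.

All generators draw from `numpy` Generator streams derived from a single
seed (one fixed substream per stage), so identical configuration and seed
reproduce identical outputs byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import log
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .hla import AllelePairCoverage
from .msi import MicrosatelliteLocus
from .nanostring import HOUSEKEEPING_GENES, TIS_GENES, PanelCountMatrix
from .signatures import SignatureMatrix, load_signature_matrix
from .survival import SurvivalRecord
from .variants import VariantCall

__all__ = [
    "SimulationConfig",
    "CALLERS",
    "simulate_variant_callsets",
    "simulate_ms_loci",
    "simulate_panel_counts",
    "simulate_indel_catalog",
    "simulate_survival",
    "simulate_hla_coverage",
    "simulate_clonotypes",
]

CALLERS = ("callerA", "callerB", "callerC", "callerD")

# fixed substream index per stage, so stages are independent and partial
# re-runs reproduce
_STREAMS = {
    "variants": 1,
    "ms_loci": 2,
    "panel": 3,
    "indels": 4,
    "survival": 5,
    "hla": 6,
    "clonotypes": 7,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stage]])


@dataclass
class SimulationConfig:
    """Generating parameters for all stages; defaults are the study-like
    conditions the recovery tests run under."""

    seed: int = 0
    # -- somatic variants --
    n_variants: int = 1000
    purity: float = 0.7
    cn_profile: list[tuple[int, int]] = field(
        default_factory=lambda: [(2, 1), (2, 2), (3, 1)]
    )  # (local copy number, multiplicity) states, drawn uniformly
    clonal_fraction: float = 0.6
    subclonal_ccf_range: tuple[float, float] = (0.1, 0.6)
    depth: int = 150
    indel_fraction: float = 0.1
    caller_count_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.15, 3: 0.30, 4: 0.50}
    )
    false_positive_rate: float = 0.02  # caller-private FPs per true variant
    # -- microsatellites --
    n_ms_loci: int = 100
    ms_regime: str = "deficient"  # or "proficient"
    per_locus_deletion_mean: float | None = None  # None -> regime default
    ms_len_range: tuple[int, int] = (10, 15)
    ms_depth: int = 100
    # -- expression panel --
    n_samples: int = 12
    nb_dispersion: float = 0.1
    technical_factor_sigma: float = 0.4
    low_quality_samples: int = 0  # forced below the QC floor
    # -- indel signatures --
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {"ID1": 0.3, "ID2": 0.7}
    )
    n_indels: int = 10000
    # -- survival --
    survival_medians: dict[str, float] = field(
        default_factory=lambda: {"continued": 11.6, "stopped": 1.2}
    )
    censoring_rate: float = 0.2

    REGIME_DELETION_MEANS = {"deficient": 0.05, "proficient": 0.005}

    def __post_init__(self) -> None:
        for name in ("purity", "clonal_fraction", "indel_fraction",
                     "false_positive_rate", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.purity == 0.0:
            raise ValueError("purity must be in (0, 1]")
        lo, hi = self.subclonal_ccf_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("subclonal_ccf_range must satisfy 0 <= low <= high <= 1")
        if self.depth <= 0 or self.ms_depth <= 0:
            raise ValueError("depth must be positive")
        if self.ms_regime not in self.REGIME_DELETION_MEANS:
            raise ValueError(f"ms_regime must be one of "
                             f"{sorted(self.REGIME_DELETION_MEANS)}")
        if abs(sum(self.caller_count_dist.values()) - 1.0) > 1e-9:
            raise ValueError("caller_count_dist must sum to 1")
        if any(k not in (1, 2, 3, 4) for k in self.caller_count_dist):
            raise ValueError("caller counts must be in {1, 2, 3, 4}")
        if abs(sum(self.signature_mix.values()) - 1.0) > 1e-9:
            raise ValueError("signature_mix must sum to 1")
        if any(v < 0 for v in self.signature_mix.values()):
            raise ValueError("signature_mix fractions must be nonnegative")
        if any(m < 1 or m > max(c, 1) for c, m in self.cn_profile):
            raise ValueError("each cn state needs 1 <= multiplicity <= copy number")
        if any(v <= 0 for v in self.survival_medians.values()):
            raise ValueError("survival medians must be positive")

    @property
    def deletion_mean(self) -> float:
        if self.per_locus_deletion_mean is not None:
            return self.per_locus_deletion_mean
        return self.REGIME_DELETION_MEANS[self.ms_regime]

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from YAML or JSON; keys mirror the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "cn_profile" in raw:
            raw["cn_profile"] = [tuple(x) for x in raw["cn_profile"]]
        for key in ("subclonal_ccf_range", "ms_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "caller_count_dist" in raw:
            raw["caller_count_dist"] = {
                int(k): float(v) for k, v in raw["caller_count_dist"].items()
            }
        return cls(**raw)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


_BASES = np.array(list("ACGT"))


def simulate_variant_callsets(
    config: SimulationConfig,
) -> tuple[dict[str, list[VariantCall]], pd.DataFrame]:
    """Per-caller somatic call sets plus a truth table.

    Each true variant gets a truth CCF (1.0 if clonal, else uniform on the
    subclonal range), a copy-number state from ``cn_profile``, and an
    expected VAF ccf*m*p / (p*c + (1-p)*2). Read depth is Poisson and the
    observed VAF binomial at that depth. The variant is emitted by k
    callers (k drawn from ``caller_count_dist``); caller-private false
    positives are appended at ``false_positive_rate`` per true variant.
    The truth table records every generated value; false positives are not
    in the truth table.
    """
    rng = _rng(config.seed, "variants")
    n = config.n_variants
    clonal = rng.random(n) < config.clonal_fraction
    lo, hi = config.subclonal_ccf_range
    ccf = np.where(clonal, 1.0, rng.uniform(lo, hi, n))
    states = [config.cn_profile[i] for i in rng.integers(len(config.cn_profile), size=n)]
    c = np.array([s[0] for s in states], dtype=float)
    m = np.array([s[1] for s in states], dtype=float)
    p = config.purity
    vaf_true = ccf * m * p / (p * c + (1.0 - p) * 2.0)
    depth = np.maximum(rng.poisson(config.depth, n), 1)
    alt_reads = rng.binomial(depth, np.clip(vaf_true, 0.0, 1.0))
    vaf_obs = alt_reads / depth
    is_indel = rng.random(n) < config.indel_fraction

    ks = list(config.caller_count_dist)
    probs = np.array([config.caller_count_dist[k] for k in ks], dtype=float)
    n_callers = np.array(ks)[rng.choice(len(ks), size=n, p=probs / probs.sum())]

    truth_rows = []
    callsets: dict[str, list[VariantCall]] = {cal: [] for cal in CALLERS}
    for i in range(n):
        pos = 10_000 + 100 * i
        if is_indel[i]:
            ref, alt = ("CA", "C") if rng.random() < 0.5 else ("C", "CA")
        else:
            ref, alt = rng.choice(4, size=2, replace=False)
            ref, alt = _BASES[ref], _BASES[alt]
        supporting = rng.choice(len(CALLERS), size=n_callers[i], replace=False)
        for j in supporting:
            callsets[CALLERS[j]].append(
                VariantCall(
                    chrom="chr1", pos=pos, ref=str(ref), alt=str(alt),
                    caller=CALLERS[j], vaf=float(vaf_obs[i]), depth=int(depth[i]),
                )
            )
        truth_rows.append(
            {
                "variant_id": f"v{i:05d}", "chrom": "chr1", "pos": pos,
                "ref": str(ref), "alt": str(alt),
                "vclass": "indel" if is_indel[i] else "SNV",
                "ccf": float(ccf[i]), "clonal": bool(ccf[i] > 0.85),
                "purity": p, "c": float(c[i]), "m": int(m[i]),
                "vaf_true": float(vaf_true[i]), "depth": int(depth[i]),
                "vaf_obs": float(vaf_obs[i]), "n_callers": int(n_callers[i]),
            }
        )

    # caller-private false positives, placed outside the true-position range
    for j, cal in enumerate(CALLERS):
        n_fp = rng.poisson(config.false_positive_rate * n)
        for f in range(n_fp):
            pos = 10_000 + 100 * (n + 1) + 100 * f + j  # unique per caller
            ref, alt = rng.choice(4, size=2, replace=False)
            callsets[cal].append(
                VariantCall(
                    chrom="chr1", pos=int(pos),
                    ref=str(_BASES[ref]), alt=str(_BASES[alt]),
                    caller=cal, vaf=float(rng.uniform(0.02, 0.2)),
                    depth=int(max(rng.poisson(config.depth), 1)),
                )
            )
    return callsets, pd.DataFrame(truth_rows)


def simulate_ms_loci(config: SimulationConfig) -> list[MicrosatelliteLocus]:
    """A-homopolymer locus read summaries.

    Every locus carries the regime's deletion proportion (deficient 0.05,
    proficient 0.005 by default — placeholders for recovery tests, not
    biological claims); deletion read counts are binomial at ``ms_depth``.
    Lengths are uniform over ``ms_len_range``.
    """
    if config.n_ms_loci < 1:
        raise ValueError("n_ms_loci must be >= 1")
    rng = _rng(config.seed, "ms_loci")
    lo, hi = config.ms_len_range
    lengths = rng.integers(lo, hi + 1, size=config.n_ms_loci)
    prop = config.deletion_mean
    dels = rng.binomial(config.ms_depth, prop, size=config.n_ms_loci)
    return [
        MicrosatelliteLocus(
            locus_id=f"ms{i:04d}", base="A", length=int(lengths[i]),
            total_reads=config.ms_depth, del1_reads=int(dels[i]),
        )
        for i in range(config.n_ms_loci)
    ]


def _nb_counts(rng, mean: np.ndarray, dispersion: float):
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_panel_counts(
    config: SimulationConfig,
) -> tuple[PanelCountMatrix, pd.Series]:
    """nCounter-style count matrix plus truth technical factors per sample.

    Six positive controls on a four-fold titration ladder, eight negative
    controls, the four housekeeping genes, and 103 endogenous genes
    (the 17 TIS genes among them). Counts are negative-binomial around
    gene mean x the sample's multiplicative technical factor. The first
    ``low_quality_samples`` samples have housekeeping counts suppressed so
    their geometric mean falls below the QC floor.
    """
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _rng(config.seed, "panel")
    pos_genes = [f"POS_{c}" for c in "ABCDEF"]
    neg_genes = [f"NEG_{c}" for c in "ABCDEFGH"]
    n_other = 103 - len(TIS_GENES)
    endo_genes = list(TIS_GENES) + [f"ENDO_{i:03d}" for i in range(n_other)]
    genes = pos_genes + neg_genes + list(HOUSEKEEPING_GENES) + endo_genes
    classes = (
        ["positive_control"] * len(pos_genes)
        + ["negative_control"] * len(neg_genes)
        + ["housekeeping"] * len(HOUSEKEEPING_GENES)
        + ["endogenous"] * len(endo_genes)
    )
    means = np.concatenate(
        [
            8192.0 / 4 ** np.arange(6),  # positive-control titration
            np.full(len(neg_genes), 3.0),
            np.array([400.0, 600.0, 800.0, 1200.0]),
            np.exp(rng.normal(5.5, 1.0, size=len(endo_genes))),
        ]
    )
    factors = np.exp(rng.normal(0.0, config.technical_factor_sigma, config.n_samples))
    counts = np.empty((len(genes), config.n_samples))
    for s in range(config.n_samples):
        counts[:, s] = _nb_counts(rng, means * factors[s], config.nb_dispersion)
    hk_rows = [genes.index(g) for g in HOUSEKEEPING_GENES]
    for s in range(min(config.low_quality_samples, config.n_samples)):
        counts[hk_rows, s] = rng.integers(10, 60, size=len(hk_rows))
    samples = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    matrix = PanelCountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                            columns=samples),
        gene_class=pd.Series(classes, index=genes),
    )
    return matrix, pd.Series(factors, index=samples, name="technical_factor")


def simulate_indel_catalog(
    config: SimulationConfig, signatures: SignatureMatrix | None = None
) -> tuple[pd.Series, dict[str, float]]:
    """Multinomial 83-channel catalog from the configured signature mix."""
    signatures = signatures or load_signature_matrix()
    unknown = set(config.signature_mix) - set(signatures.signature_ids)
    if unknown:
        raise ValueError(f"signature_mix names absent from matrix: {sorted(unknown)}")
    rng = _rng(config.seed, "indels")
    probs = np.zeros(len(signatures.channels))
    for sig, frac in config.signature_mix.items():
        probs += frac * signatures.probabilities[sig].to_numpy()
    probs /= probs.sum()
    counts = rng.multinomial(config.n_indels, probs)
    catalog = pd.Series(counts, index=signatures.channels, name="count")
    return catalog, dict(config.signature_mix)


def simulate_survival(config: SimulationConfig) -> list[SurvivalRecord]:
    """Exponential survival cohorts, ``n_samples`` subjects per group.

    Event times are exponential with rate ln2/median per group; with
    probability ``censoring_rate`` a subject is instead censored at a
    uniform time before its event.
    """
    rng = _rng(config.seed, "survival")
    records = []
    i = 0
    for group, median in config.survival_medians.items():
        scale = median / log(2.0)
        times = rng.exponential(scale, config.n_samples)
        censored = rng.random(config.n_samples) < config.censoring_rate
        obs = np.where(censored, rng.uniform(0.0, times), times)
        for t, e in zip(obs, ~censored):
            records.append(
                SurvivalRecord(
                    subject_id=f"P{i:04d}", group=group,
                    time=float(t), event=bool(e),
                )
            )
            i += 1
    return records


def simulate_hla_coverage(
    n_positions: int = 50,
    depth: float = 100.0,
    imbalance: float = 1.0,
    gene: str = "HLA-A",
    noise_sd: float = 0.15,
    seed: int = 0,
) -> AllelePairCoverage:
    """Paired allele coverage at mismatch positions.

    ``imbalance`` multiplies allele2's tumor coverage (1.0 = balanced, i.e.
    the null; 0.2 = strong loss of allele2). Coverage is lognormal around
    ``depth`` with multiplicative noise ``noise_sd`` on the log scale.
    """
    rng = np.random.default_rng([int(seed), _STREAMS["hla"]])
    base = depth * np.exp(rng.normal(0.0, noise_sd, n_positions))
    t1 = base * np.exp(rng.normal(0.0, noise_sd, n_positions))
    t2 = base * imbalance * np.exp(rng.normal(0.0, noise_sd, n_positions))
    n1 = depth * np.exp(rng.normal(0.0, noise_sd, n_positions))
    n2 = depth * np.exp(rng.normal(0.0, noise_sd, n_positions))
    return AllelePairCoverage(
        gene=gene,
        tumor_allele1=np.round(t1), tumor_allele2=np.round(t2),
        normal_allele1=np.round(n1), normal_allele2=np.round(n2),
    )


def simulate_clonotypes(
    n_clonotypes: int = 500,
    total_reads: int = 1_000_000,
    chain: str = "beta",
    alpha: float = 1.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Clonotype count table with power-law-ish clone sizes (Zipf exponent
    ``alpha``), scaled to ``total_reads`` total."""
    rng = np.random.default_rng([int(seed), _STREAMS["clonotypes"]])
    raw = 1.0 / np.arange(1, n_clonotypes + 1) ** alpha
    raw = raw * rng.uniform(0.5, 1.5, n_clonotypes)
    counts = np.maximum(np.round(raw / raw.sum() * total_reads).astype(int), 1)
    return pd.DataFrame(
        {
            "clonotype": [f"CDR3_{i:05d}" for i in range(n_clonotypes)],
            "chain": chain,
            "count": counts,
        }
    )
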
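"""Iterative marker/sample quality control.

Each pass first filters SNPs — call rate < 90%, minor allele frequency
< 3%, exact Hardy-Weinberg P < 1e-6, in that order — then filters samples
with call rate < 90%; passes repeat, with all statistics recomputed on the
surviving data, until a full pass removes nothing.

The HWE test is the exact conditional test (sum of probabilities, given the
allele counts, of heterozygote counts no more probable than the observed
one), which is well defined at all counts and matches use of a 1e-6 tail
threshold.  A marker failing several filters records only the first reason
in application order.  X-linkage/sex checks require chip intensity data not
modeled here and are recorded as unsupported in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import gammaln

from .formats import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "snp_call_rate",
    "sample_call_rate",
    "minor_allele_frequency",
    "genotype_counts",
    "hwe_test",
    "iterative_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    snp_call: float = 0.90
    maf: float = 0.03
    hwe: float = 1e-6
    sample_call: float = 0.90

    def validate(self) -> None:
        for name in ("snp_call", "maf", "hwe", "sample_call"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"threshold {name} must be in [0, 1]")


@dataclass
class QcReport:
    excluded_snps: List[Tuple[str, str]] = field(default_factory=list)
    excluded_samples: List[Tuple[str, str]] = field(default_factory=list)
    n_iterations: int = 0
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    notes: List[str] = field(default_factory=lambda: [
        "sex-linkage / X-intensity checks unsupported (no intensity data)",
    ])

    def counts_by_reason(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for _, reason in self.excluded_snps:
            out[reason] = out.get(reason, 0) + 1
        return out


def snp_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Proportion of non-missing calls per marker."""
    if g.n_individuals == 0 or g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    return 1.0 - np.isnan(g.dosage).mean(axis=0)


def sample_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Proportion of non-missing calls per individual."""
    if g.n_individuals == 0 or g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    return 1.0 - np.isnan(g.dosage).mean(axis=1)


def minor_allele_frequency(g: GenotypeMatrix, marker=None) -> np.ndarray:
    """MAF per marker: min(f, 1-f) with f the allele2 frequency.

    ``marker`` may be a marker id or index to return a single value.
    All-missing markers yield NaN (they fail call rate first).
    """
    with np.errstate(invalid="ignore"):
        f = np.nanmean(g.dosage, axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    if marker is None:
        return maf
    j = g.markers.index_of(marker) if isinstance(marker, str) else int(marker)
    return float(maf[j])


def genotype_counts(g: GenotypeMatrix) -> np.ndarray:
    """(m, 3) counts of hom-allele1, het, hom-allele2 per marker."""
    d = g.dosage
    return np.stack(
        [np.nansum(d == k, axis=0) for k in (0.0, 1.0, 2.0)], axis=1
    ).astype(int)


def hwe_test(hom1: int, het: int, hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg P-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count.
    """
    if min(hom1, het, hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom1 + het + hom2
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = min(2 * hom1 + het, 2 * hom2 + het)
    # heterozygote count shares parity with the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_a = 2 * n
    # log P(het | allele counts): multinomial/hypergeometric-type kernel
    minor_hom = (n_minor - hets) // 2
    major_hom = n - hets - minor_hom
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1) - gammaln(minor_hom + 1) - gammaln(major_hom + 1)
        + gammaln(n_minor + 1) + gammaln(n_a - n_minor + 1) - gammaln(n_a + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.searchsorted(hets, het)]
    return float(np.minimum(p[p <= p_obs * (1 + 1e-12)].sum(), 1.0))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    counts = genotype_counts(g)
    out = np.ones(g.n_markers)
    for j, (h1, he, h2) in enumerate(counts):
        if h1 + he + h2 >= 1:
            out[j] = hwe_test(int(h1), int(he), int(h2))
    return out


def iterative_qc(
    g: GenotypeMatrix,
    thresholds: Optional[QcThresholds] = None,
) -> Tuple[GenotypeMatrix, QcReport]:
    """Apply the recursive two-step QC until nothing more is removed.

    Raises ``ValueError`` if no data survive.
    """
    thresholds = thresholds or QcThresholds()
    thresholds.validate()
    report = QcReport(
        n_markers_in=g.n_markers, n_samples_in=g.n_individuals,
    )
    current = g
    while True:
        report.n_iterations += 1
        removed_any = False

        # step 1: SNP filters, in order call rate, MAF, HWE
        reasons = {}
        call = snp_call_rate(current)
        for j in np.flatnonzero(call < thresholds.snp_call):
            reasons.setdefault(j, "call_rate")
        maf = minor_allele_frequency(current)
        with np.errstate(invalid="ignore"):
            fail_maf = np.flatnonzero(maf < thresholds.maf)
        for j in fail_maf:
            reasons.setdefault(j, "maf")
        hwe = hwe_pvalues(current)
        for j in np.flatnonzero(hwe < thresholds.hwe):
            reasons.setdefault(j, "hwe")
        if reasons:
            removed_any = True
            order = sorted(reasons)
            for j in order:
                report.excluded_snps.append(
                    (str(current.markers.marker_id[j]), reasons[j])
                )
            keep = np.setdiff1d(np.arange(current.n_markers), order)
            if len(keep) == 0:
                raise ValueError("no data survive QC: all markers excluded")
            current = current.subset(markers=keep)

        # step 2: sample call-rate filter on the surviving markers
        s_call = sample_call_rate(current)
        fail = np.flatnonzero(s_call < thresholds.sample_call)
        if len(fail):
            removed_any = True
            for i in fail:
                report.excluded_samples.append(
                    (current.individual_ids[int(i)], "call_rate")
                )
            keep = np.setdiff1d(np.arange(current.n_individuals), fail)
            if len(keep) == 0:
                raise ValueError("no data survive QC: all samples excluded")
            current = current.subset(individuals=keep)

        if not removed_any:
            break

    report.n_markers_out = current.n_markers
    report.n_samples_out = current.n_individuals
    return current, report
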
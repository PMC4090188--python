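"""Linkage disequilibrium, haplotype blocks, EM frequencies, haplotype
score tests, founder haplotype sharing, and interval intersection.

Pairwise LD comes from two-locus haplotype frequencies estimated by EM on
unphased dosages (double heterozygotes split by the current phase
estimate): D = p11 - pA*pB, D' = D/Dmax, r2 = D^2/(pA(1-pA)pB(1-pB)).

Blocks follow the confidence-interval (Gabriel-style) rule: a likelihood
profile over |D'| (allele frequencies fixed at their estimates) yields a
90% interval per pair; pairs with lower bound >= 0.70 and upper bound >=
0.98 show "strong LD", pairs with upper bound < 0.90 show "strong
recombination".  A contiguous marker run is a block when at least 95% of
its informative pairs show strong LD; runs are accepted greedily, longest
bp span first, without overlap.

The haplotype score test follows the quantitative-trait score framework:
per-individual expected haplotype counts under the EM phase posteriors
enter a Gaussian generalized-linear-model score function; rare haplotypes
(frequency below a pooling threshold, default 0.02) are pooled and not
scored; the global statistic is a quadratic form with generalized-inverse
covariance, referred to chi-square with df = (number scored - 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .formats import GenotypeMatrix, MarkerMap

__all__ = [
    "LdStats",
    "HaplotypeBlock",
    "HapFrequencyResult",
    "HapScoreResult",
    "SharedSegment",
    "ld_pair",
    "dprime_confidence_interval",
    "detect_blocks",
    "em_haplotype_frequencies",
    "hap_score_test",
    "shared_segments",
    "intersect_intervals",
    "recode_major_minor",
]

MAX_WINDOW = 12  # enumeration bound for EM windows


# ---------------------------------------------------------------------------
# EM haplotype frequencies (general window)
# ---------------------------------------------------------------------------

@dataclass
class HapFrequencyResult:
    haplotypes: List[Tuple[int, ...]]
    frequencies: np.ndarray
    #: per individual: list of ((hapA, hapB), posterior probability)
    posteriors: List[List[Tuple[Tuple[Tuple[int, ...], Tuple[int, ...]], float]]]
    individual_ids: List[str]
    loglik_trace: List[float]
    converged: bool

    def frequency_of(self, hap: Tuple[int, ...]) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(tuple(hap))])
        except ValueError:
            return 0.0


def _compatible_pairs(geno: Tuple[int, ...]):
    """Unordered haplotype pairs consistent with a multilocus genotype."""
    het = [i for i, d in enumerate(geno) if d == 1]
    base = [1 if d == 2 else 0 for d in geno]
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    first, rest = het[0], het[1:]
    for bits in itertools.product((0, 1), repeat=len(rest)):
        a, b = list(base), list(base)
        a[first], b[first] = 0, 1
        for pos, bit in zip(rest, bits):
            a[pos], b[pos] = bit, 1 - bit
        pairs.append((tuple(a), tuple(b)))
    return pairs


def em_haplotype_frequencies(
    g: GenotypeMatrix,
    marker_ids: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> HapFrequencyResult:
    """EM over compatible diplotypes with flat initialization.

    Individuals with a missing genotype inside the window are dropped.
    Raises for windows larger than the enumeration bound (12 markers).
    """
    cols = [g.markers.index_of(m) for m in marker_ids]
    if len(cols) > MAX_WINDOW:
        raise ValueError(
            f"window of {len(cols)} markers exceeds the enumeration bound "
            f"({MAX_WINDOW}); split the window"
        )
    D = g.dosage[:, cols]
    keep = ~np.isnan(D).any(axis=1)
    ids = [iid for iid, k in zip(g.individual_ids, keep) if k]
    genos = [tuple(int(v) for v in row) for row in D[keep]]
    if not genos:
        raise ValueError("no complete genotypes in window")

    pair_lists = [_compatible_pairs(gt) for gt in genos]
    hap_set = sorted({h for pl in pair_lists for pair in pl for h in pair})
    hap_idx = {h: k for k, h in enumerate(hap_set)}
    H = len(hap_set)
    freq = np.full(H, 1.0 / H)
    n = len(genos)

    trace: List[float] = []
    converged = False
    post: List[np.ndarray] = [np.empty(len(pl)) for pl in pair_lists]
    for _ in range(max_iter):
        counts = np.zeros(H)
        ll = 0.0
        for i, pl in enumerate(pair_lists):
            w = np.asarray([
                (2.0 if a != b else 1.0) * freq[hap_idx[a]] * freq[hap_idx[b]]
                for a, b in pl
            ])
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pl), 1.0 / len(pl))
                tot = 1.0
                ll += -np.inf
            else:
                w = w / tot
                ll += np.log(tot)
            post[i] = w
            for (a, b), p in zip(pl, w):
                counts[hap_idx[a]] += p
                counts[hap_idx[b]] += p
        new_freq = counts / (2.0 * n)
        trace.append(float(ll))
        if np.max(np.abs(new_freq - freq)) < tol:
            freq = new_freq
            converged = True
            break
        freq = new_freq

    posteriors = [
        [((a, b), float(p)) for (a, b), p in zip(pl, w)]
        for pl, w in zip(pair_lists, post)
    ]
    return HapFrequencyResult(
        haplotypes=list(hap_set), frequencies=freq,
        posteriors=posteriors, individual_ids=ids,
        loglik_trace=trace, converged=converged,
    )


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

@dataclass
class LdStats:
    marker1: str
    marker2: str
    d: float
    d_prime: float
    r2: float
    hap_freqs: Dict[Tuple[int, int], float]


def _pair_freqs_to_ld(p: Dict[Tuple[int, int], float]) -> Tuple[float, float, float]:
    pa = p[(1, 0)] + p[(1, 1)]
    pb = p[(0, 1)] + p[(1, 1)]
    d = p[(1, 1)] - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = d / dmax if dmax > 0 else 0.0
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = d * d / denom if denom > 0 else 0.0
    return d, d_prime, r2


def ld_pair(g: GenotypeMatrix, m1: str, m2: str) -> LdStats:
    """Two-locus LD from EM haplotype frequencies on unphased dosages."""
    for m in (m1, m2):
        j = g.markers.index_of(m)
        col = g.dosage[:, j]
        vals = col[~np.isnan(col)]
        if len(np.unique(vals)) < 2:
            raise ValueError(f"LD undefined: marker {m!r} is monomorphic")
    em = em_haplotype_frequencies(g, [m1, m2])
    p = {hw: 0.0 for hw in itertools.product((0, 1), repeat=2)}
    for h, f in zip(em.haplotypes, em.frequencies):
        p[tuple(h)] = float(f)
    d, d_prime, r2 = _pair_freqs_to_ld(p)
    return LdStats(m1, m2, d, d_prime, r2, p)


def dprime_confidence_interval(
    g: GenotypeMatrix, m1: str, m2: str,
    grid: int = 101, lower_q: float = 0.05, upper_q: float = 0.95,
) -> Tuple[float, float]:
    """Likelihood-profile confidence bounds on |D'| for one marker pair.

    Allele frequencies are fixed at their sample estimates; a normalized
    likelihood over |D'| in [0, 1] (sign taken from the point estimate)
    gives cumulative 5%/95% bounds.
    """
    j1, j2 = g.markers.index_of(m1), g.markers.index_of(m2)
    d1, d2 = g.dosage[:, j1], g.dosage[:, j2]
    ok = ~np.isnan(d1) & ~np.isnan(d2)
    d1, d2 = d1[ok].astype(int), d2[ok].astype(int)
    counts = np.zeros((3, 3))
    for a, b in zip(d1, d2):
        counts[a, b] += 1

    ld = ld_pair(g, m1, m2)
    pa = ld.hap_freqs[(1, 0)] + ld.hap_freqs[(1, 1)]
    pb = ld.hap_freqs[(0, 1)] + ld.hap_freqs[(1, 1)]
    sign = 1.0 if ld.d >= 0 else -1.0
    if sign >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return 0.0, 0.0

    dgrid = np.linspace(0.0, 1.0, grid)
    ll = np.full(grid, -np.inf)
    eps = 1e-12
    for k, dp in enumerate(dgrid):
        dval = sign * dp * dmax
        h = {
            (1, 1): pa * pb + dval,
            (1, 0): pa * (1 - pb) - dval,
            (0, 1): (1 - pa) * pb - dval,
            (0, 0): (1 - pa) * (1 - pb) + dval,
        }
        if min(h.values()) < -1e-9:
            continue
        h = {k2: max(v, eps) for k2, v in h.items()}
        # genotype-class probabilities under HWE
        lp = 0.0
        for a in range(3):
            for b in range(3):
                if counts[a, b] == 0:
                    continue
                prob = 0.0
                for (x1, y1), (x2, y2) in itertools.product(h, h):
                    if x1 + x2 == a and y1 + y2 == b:
                        prob += h[(x1, y1)] * h[(x2, y2)]
                lp += counts[a, b] * np.log(max(prob, eps))
        ll[k] = lp
    w = np.exp(ll - ll.max())
    w = w / w.sum()
    cum = np.cumsum(w)
    lo = float(dgrid[int(np.searchsorted(cum, lower_q))])
    hi = float(dgrid[min(int(np.searchsorted(cum, upper_q)), grid - 1)])
    return lo, hi


# ---------------------------------------------------------------------------
# block detection
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeBlock:
    chromosome: str
    first_marker: str
    last_marker: str
    first_index: int
    last_index: int
    span_bp: int
    marker_ids: List[str] = field(default_factory=list)


def detect_blocks(
    g: GenotypeMatrix,
    marker_ids: Optional[Sequence[str]] = None,
    strong_lower: float = 0.70,
    strong_upper: float = 0.98,
    recomb_upper: float = 0.90,
    min_strong_fraction: float = 0.95,
) -> List[HaplotypeBlock]:
    """Confidence-interval block detection over an ordered marker set."""
    mm = g.markers
    if marker_ids is None:
        marker_ids = [str(m) for m in mm.marker_id]
    marker_ids = list(marker_ids)
    k = len(marker_ids)
    if k < 2:
        return []
    idx = [mm.index_of(m) for m in marker_ids]
    chroms = {str(mm.chromosome[i]) for i in idx}
    if len(chroms) > 1:
        raise ValueError("block detection requires markers on one chromosome")
    chromosome = chroms.pop()
    pos = np.asarray([mm.position_bp[i] for i in idx])

    STRONG, RECOMB, OTHER = 1, -1, 0
    klass = np.zeros((k, k), dtype=int)
    for a in range(k):
        for b in range(a + 1, k):
            try:
                lo, hi = dprime_confidence_interval(g, marker_ids[a], marker_ids[b])
            except ValueError:
                klass[a, b] = OTHER
                continue
            if lo >= strong_lower and hi >= strong_upper:
                klass[a, b] = STRONG
            elif hi < recomb_upper:
                klass[a, b] = RECOMB
            else:
                klass[a, b] = OTHER

    candidates = []
    for a in range(k):
        for b in range(a + 1, k):
            sub = klass[a:b + 1, a:b + 1]
            n_strong = int((sub == STRONG).sum())
            n_inform = n_strong + int((sub == RECOMB).sum())
            if n_inform == 0:
                continue
            if n_strong / n_inform >= min_strong_fraction:
                candidates.append((int(pos[b] - pos[a]), b - a, a, b))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))

    taken = np.zeros(k, dtype=bool)
    blocks: List[HaplotypeBlock] = []
    for span, _, a, b in candidates:
        if taken[a:b + 1].any():
            continue
        taken[a:b + 1] = True
        blocks.append(HaplotypeBlock(
            chromosome=chromosome,
            first_marker=marker_ids[a], last_marker=marker_ids[b],
            first_index=a, last_index=b,
            span_bp=int(pos[b] - pos[a]),
            marker_ids=marker_ids[a:b + 1],
        ))
    blocks.sort(key=lambda blk: blk.first_index)
    return blocks


# ---------------------------------------------------------------------------
# haplotype score test
# ---------------------------------------------------------------------------

@dataclass
class HapScoreResult:
    haplotypes: List[str]
    frequencies: np.ndarray
    scores: np.ndarray
    p_values: np.ndarray
    global_stat: float
    df: int
    global_p: float
    n_pooled: int
    n_individuals: int


def hap_score_test(
    g: GenotypeMatrix,
    marker_ids: Sequence[str],
    trait: Dict[str, float],
    min_freq: float = 0.02,
) -> HapScoreResult:
    """Score test of haplotype-trait association (Gaussian trait).

    ``trait`` maps individual id to the quantitative trait (raw or
    residual).  Haplotypes below ``min_freq`` are pooled and not scored.
    """
    em = em_haplotype_frequencies(g, marker_ids)
    use = [i for i, iid in enumerate(em.individual_ids) if iid in trait]
    if len(use) < 3:
        raise ValueError("fewer than 3 individuals with trait and genotypes")
    y = np.asarray([trait[em.individual_ids[i]] for i in use], float)

    scored = [
        k for k, f in enumerate(em.frequencies) if f >= min_freq
    ]
    n_pooled = len(em.haplotypes) - len(scored)
    if len(scored) < 2:
        raise ValueError("fewer than 2 haplotypes above the pooling threshold")
    hap_col = {k: c for c, k in enumerate(scored)}
    hap_idx = {h: k for k, h in enumerate(em.haplotypes)}

    X = np.zeros((len(use), len(scored)))
    for r, i in enumerate(use):
        for (a, b), p in em.posteriors[i]:
            for h in (a, b):
                k = hap_idx[h]
                if k in hap_col:
                    X[r, hap_col[k]] += p

    yc = y - y.mean()
    sigma2 = float(yc @ yc) / len(y)  # MLE under the null
    Xc = X - X.mean(axis=0, keepdims=True)
    U = Xc.T @ yc / sigma2
    V = (Xc.T @ Xc) / sigma2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = U / np.sqrt(np.diag(V))
    p_each = 2.0 * stats.norm.sf(np.abs(z))
    global_stat = float(U @ np.linalg.pinv(V) @ U)
    df = len(scored) - 1
    global_p = float(stats.chi2.sf(global_stat, df))

    mm = g.markers
    cols = [mm.index_of(m) for m in marker_ids]
    def hap_string(h):
        return "".join(
            str(mm.allele2[c]) if a else str(mm.allele1[c])
            for a, c in zip(h, cols)
        )
    return HapScoreResult(
        haplotypes=[hap_string(em.haplotypes[k]) for k in scored],
        frequencies=np.asarray([em.frequencies[k] for k in scored]),
        scores=z, p_values=p_each,
        global_stat=global_stat, df=df, global_p=global_p,
        n_pooled=n_pooled, n_individuals=len(use),
    )


# ---------------------------------------------------------------------------
# haplotype sharing
# ---------------------------------------------------------------------------

@dataclass
class SharedSegment:
    first_marker: str
    last_marker: str
    first_index: int
    last_index: int
    bp_length: int
    n_carriers: int

    @property
    def n_markers(self) -> int:
        return self.last_index - self.first_index + 1


def shared_segments(
    haps, markers: Optional[MarkerMap] = None
) -> List[SharedSegment]:
    """Maximal marker runs where all input haplotypes are identical.

    ``haps`` is a (k, m) array of allele codes, or a ``GenotypeMatrix``
    with phase (each individual contributes two haplotypes; unphased input
    raises).  Segment length is the bp span between its first and last
    marker.
    """
    if isinstance(haps, GenotypeMatrix):
        if haps.phase is None:
            raise ValueError("haplotype sharing requires phased input")
        markers = markers or haps.markers
        haps = haps.phase.reshape(-1, haps.n_markers)
    haps = np.asarray(haps)
    if haps.ndim != 2 or haps.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    if markers is None:
        raise ValueError("a MarkerMap is required")
    m = haps.shape[1]
    if m != markers.n_markers:
        raise ValueError("haplotype length does not match marker map")
    same = (haps == haps[0]).all(axis=0)
    segments: List[SharedSegment] = []
    j = 0
    while j < m:
        if same[j]:
            start = j
            while j + 1 < m and same[j + 1]:
                j += 1
            segments.append(SharedSegment(
                first_marker=str(markers.marker_id[start]),
                last_marker=str(markers.marker_id[j]),
                first_index=start, last_index=j,
                bp_length=int(markers.position_bp[j] - markers.position_bp[start]),
                n_carriers=haps.shape[0],
            ))
        j += 1
    return segments


def recode_major_minor(haps: np.ndarray) -> np.ndarray:
    """Display coding: per marker, the more frequent allele is 1, other 2.

    Ties resolve toward the numerically smaller allele code.
    """
    haps = np.asarray(haps)
    out = np.empty_like(haps, dtype=np.int8)
    for j in range(haps.shape[1]):
        col = haps[:, j]
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) == 1:
            out[:, j] = 1
            continue
        major = vals[np.lexsort((vals, -counts))[0]]
        out[:, j] = np.where(col == major, 1, 2)
    return out


# ---------------------------------------------------------------------------
# interval intersection
# ---------------------------------------------------------------------------

def intersect_intervals(
    a: Sequence[Tuple[float, float]], b: Sequence[Tuple[float, float]]
) -> List[Tuple[float, float]]:
    """Pairwise intersection of two bp-interval lists, merged and sorted."""
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                out.append((lo, hi))
    out.sort()
    merged: List[Tuple[float, float]] = []
    for s, e in out:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
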
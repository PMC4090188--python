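"""Synthetic F2-intercross and breed-panel generators.

The default configuration emulates the design of the mapped study
population: 314 F2 animals in 47 litters from 9 F1 sires x 34 F1 dams, an
ear-area trait with mean 244 cm^2 and coefficient of variation 22%, a QTL
explaining half the phenotypic variance whose alleles are alternatively
fixed in the two founder breeds (Minzhu carrying Q = allele2, Large White
carrying q), and a desk-scale marker panel of 200 SNPs on one 60-Mb
chromosome (~1 marker / 300 kb).

Crossovers follow a Poisson/Haldane model (no interference): the count per
meiosis is Poisson in the chromosome's Morgan length and positions are
uniform on the genetic map.  Polygenic values descend the pedigree by
Mendelian sampling: founders ~ N(0, sigma2_a); offspring = parent mean +
N(0, sigma2_a / 2), ignoring inbreeding, which is exact under the pedigree
model behind the additive relationship matrix.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formats import GenotypeMatrix, MarkerMap, Pedigree, PhenotypeTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "SweepSimConfig",
    "simulate_cross",
    "simulate_breed_panels",
    "plant_shared_haplotype",
    "default_marker_map",
]

MINZHU = "Minzhu"
LARGE_WHITE = "LargeWhite"


@dataclass
class SimConfig:
    """Study-design parameters of the simulated intercross.

    Variance bookkeeping: the target phenotypic variance is
    ``(trait_mean * trait_cv)**2``.  ``qtl_variance_fraction``,
    ``additive_variance_fraction`` and ``litter_variance_fraction`` are
    fractions of that total; the analytically known fixed-effect and
    covariate variance is subtracted and the residual variance absorbs the
    remainder, so the realized phenotypic variance matches the target.
    Explicit ``sigma2_*`` values override the fractions.
    """

    n_f2: int = 314
    n_litters: int = 47
    n_f1_sires: int = 9
    n_f1_dams: int = 34
    n_markers: int = 200
    n_chromosomes: int = 1
    chromosome_length_bp: int = 60_000_000
    cm_per_mb: float = 1.0
    qtl_marker_index: Optional[int] = 100
    qtl_variance_fraction: float = 0.5
    qtl2_marker_index: Optional[int] = None
    qtl2_variance_fraction: float = 0.0
    trait_mean: float = 244.0
    trait_cv: float = 0.22
    additive_variance_fraction: float = 0.20
    litter_variance_fraction: float = 0.05
    sigma2_a: Optional[float] = None
    sigma2_c: Optional[float] = None
    sigma2_e: Optional[float] = None
    n_parity: int = 3
    n_batch: int = 28
    sex_effect: float = 4.0
    parity_effect_sd: float = 3.0
    batch_effect_sd: float = 3.0
    body_weight_mean: float = 100.0
    body_weight_sd: float = 8.0
    body_weight_slope: float = 0.35
    founder_breed_freqs: Optional[np.ndarray] = None  # (2, m): Minzhu, LargeWhite
    qtl_flank_mb: float = 3.0
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def phenotypic_variance(self) -> float:
        return (self.trait_mean * self.trait_cv) ** 2

    def fixed_effect_variance(self) -> float:
        """Population variance contributed by fixed effects + covariate."""
        v_sex = self.sex_effect ** 2          # balanced +/- sex_effect
        v_par = self.parity_effect_sd ** 2
        v_bat = self.batch_effect_sd ** 2
        v_bw = (self.body_weight_slope * self.body_weight_sd) ** 2
        return v_sex + v_par + v_bat + v_bw

    def variance_components(self) -> Tuple[float, float, float, float, float]:
        """Return (v_qtl, v_qtl2, sigma2_a, sigma2_c, sigma2_e)."""
        V = self.phenotypic_variance
        v_q = self.qtl_variance_fraction * V
        v_q2 = self.qtl2_variance_fraction * V
        s_a = self.sigma2_a if self.sigma2_a is not None else self.additive_variance_fraction * V
        s_c = self.sigma2_c if self.sigma2_c is not None else self.litter_variance_fraction * V
        if self.sigma2_e is not None:
            s_e = self.sigma2_e
        else:
            s_e = V - v_q - v_q2 - s_a - s_c - self.fixed_effect_variance()
        if min(s_a, s_c, s_e) < 0:
            raise ValueError("variance components must be non-negative")
        return v_q, v_q2, s_a, s_c, s_e

    def validate(self) -> None:
        if not (0 <= self.qtl_variance_fraction < 1):
            raise ValueError("qtl_variance_fraction must be in [0, 1)")
        for name in ("n_f2", "n_litters", "n_f1_sires", "n_f1_dams", "n_markers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_f2 < self.n_litters:
            raise ValueError("impossible litter partition: n_f2 < n_litters")
        if self.qtl_marker_index is not None and not (
            0 <= self.qtl_marker_index < self.n_markers
        ):
            raise ValueError("qtl_marker_index out of range")
        if self.qtl2_marker_index is not None and not (
            0 <= self.qtl2_marker_index < self.n_markers
        ):
            raise ValueError("qtl2_marker_index out of range")
        self.variance_components()


@dataclass
class SimTruth:
    """Ground truth of a simulated cross.

    Haplotypes are stored for every pedigree member as ``(n, 2, m)`` arrays
    of allele2 copies (``hap_alleles``) and founder-chromosome origin labels
    (``hap_origin``, a global founder-haplotype index), so any descendant
    haplotype can be regenerated from the founder alleles.
    """

    individual_ids: list
    markers: MarkerMap
    hap_alleles: np.ndarray     # (n, 2, m) int8
    hap_origin: np.ndarray      # (n, 2, m) int32
    founder_hap_owner: list     # founder individual id per global hap index
    founder_hap_breed: list     # breed per global hap index
    qtl_marker_index: Optional[int]
    qtl_genotype: Dict[str, int]          # F2 id -> Q-allele dosage
    breeding_values: Dict[str, float]
    litter_effects: Dict[str, float]
    realized_components: Dict[str, float]
    config: SimConfig

    def founder_hap_matrix(self) -> np.ndarray:
        """(n_founder_haps, m) alleles in global founder-hap order."""
        n_haps = len(self.founder_hap_owner)
        out = np.zeros((n_haps, self.markers.n_markers), dtype=np.int8)
        owner_row = {iid: i for i, iid in enumerate(self.individual_ids)}
        for h in range(n_haps):
            row = owner_row[self.founder_hap_owner[h]]
            which = h % 2
            out[h] = self.hap_alleles[row, which]
        return out

    def q_bearing_haplotypes(self) -> np.ndarray:
        """Founder haplotypes of the Q-fixed breed (Minzhu), (k, m)."""
        fm = self.founder_hap_matrix()
        mask = np.asarray(self.founder_hap_breed) == MINZHU
        return fm[mask]

    def to_genotype_matrix(self, rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
        dosage = self.hap_alleles.sum(axis=1).astype(float)
        if self.config.missing_rate > 0:
            rng = rng or np.random.default_rng(self.config.seed + 7)
            mask = rng.random(dosage.shape) < self.config.missing_rate
            dosage[mask] = np.nan
        return GenotypeMatrix(
            list(self.individual_ids), self.markers, dosage, phase=self.hap_alleles.copy()
        )


def default_marker_map(config: SimConfig) -> MarkerMap:
    """Evenly spaced markers; chromosomes named '5', '7', ... by convention."""
    per_chrom = [config.n_markers // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_markers % config.n_chromosomes):
        per_chrom[i] += 1
    names = [str(c) for c in (5, 7, 1, 2, 3, 4, 6, 8, 9)] + [
        str(c) for c in range(10, 10 + max(0, config.n_chromosomes - 9))
    ]
    mids, chroms, pos, cms = [], [], [], []
    for c in range(config.n_chromosomes):
        m = per_chrom[c]
        p = np.linspace(
            config.chromosome_length_bp / m, config.chromosome_length_bp, m
        ).round().astype(np.int64)
        pos.extend(p)
        cms.extend(p * 1e-6 * config.cm_per_mb)
        chroms.extend([names[c]] * m)
        mids.extend(f"M{names[c]}_{j:04d}" for j in range(m))
    n = len(mids)
    return MarkerMap(
        mids, chroms, pos, ["A"] * n, ["G"] * n, cm=np.asarray(cms)
    )


def _founder_freqs(config: SimConfig, markers: MarkerMap, rng) -> np.ndarray:
    """Per-breed allele2 frequencies (rows: Minzhu, LargeWhite)."""
    m = markers.n_markers
    base = rng.uniform(0.1, 0.9, m)
    delta = rng.uniform(0.05, 0.25, m)
    qtl_idx = [
        i for i in (config.qtl_marker_index, config.qtl2_marker_index)
        if i is not None
    ]
    flank = np.zeros(m, dtype=bool)
    for qi in qtl_idx:
        same = markers.chromosome == markers.chromosome[qi]
        near = np.abs(markers.position_bp - markers.position_bp[qi]) <= (
            config.qtl_flank_mb * 1e6
        )
        flank |= same & near
    delta[flank] = rng.uniform(0.25, 0.45, flank.sum())
    mz = np.clip(base + delta, 0.02, 0.98)
    lw = np.clip(base - delta, 0.02, 0.98)
    for qi in qtl_idx:
        mz[qi], lw[qi] = 1.0, 0.0  # Q fixed in Minzhu, q in Large White
    return np.vstack([mz, lw])


def _chromosome_slices(markers: MarkerMap) -> list:
    slices, start = [], 0
    chrom = markers.chromosome
    for j in range(1, markers.n_markers + 1):
        if j == markers.n_markers or chrom[j] != chrom[start]:
            slices.append(slice(start, j))
            start = j
    return slices


def _gamete(hap_pair, origin_pair, cm, chrom_slices, rng):
    """Sample one gamete (alleles, origins) by Poisson/Haldane crossovers."""
    m = hap_pair.shape[1]
    allele = np.empty(m, dtype=np.int8)
    origin = np.empty(m, dtype=np.int32)
    for sl in chrom_slices:
        c = cm[sl]
        length_morgan = (c[-1] - c[0]) / 100.0
        n_x = rng.poisson(length_morgan)
        cuts = np.sort(rng.uniform(c[0], c[-1], n_x))
        current = rng.integers(0, 2)
        take = np.full(sl.stop - sl.start, current, dtype=np.int8)
        if n_x:
            n_cross = np.searchsorted(cuts, c, side="right")
            take = (current + n_cross) % 2
        idx = np.arange(sl.start, sl.stop)
        allele[sl] = hap_pair[take, idx]
        origin[sl] = origin_pair[take, idx]
    return allele, origin


def _build_pedigree(config: SimConfig) -> pd.DataFrame:
    rows = []
    # founders: each F1 gets its own Large White father and Minzhu mother
    n_f1 = config.n_f1_sires + config.n_f1_dams
    for i in range(n_f1):
        rows.append((f"LW_{i:03d}", "", "", "M", "F0", LARGE_WHITE))
        rows.append((f"MZ_{i:03d}", "", "", "F", "F0", MINZHU))
    f1_sires = [f"F1S_{i:02d}" for i in range(config.n_f1_sires)]
    f1_dams = [f"F1D_{i:02d}" for i in range(config.n_f1_dams)]
    for i, sid in enumerate(f1_sires):
        rows.append((sid, f"LW_{i:03d}", f"MZ_{i:03d}", "M", "F1", ""))
    for j, did in enumerate(f1_dams):
        k = config.n_f1_sires + j
        rows.append((did, f"LW_{k:03d}", f"MZ_{k:03d}", "F", "F1", ""))
    # litters: deterministic partition of n_f2
    base = config.n_f2 // config.n_litters
    extra = config.n_f2 % config.n_litters
    litter_sizes = [base + 1 if l < extra else base for l in range(config.n_litters)]
    if min(litter_sizes) < 1:
        raise ValueError("impossible litter partition")
    k = 0
    litter_info = []
    for l, size in enumerate(litter_sizes):
        sire = f1_sires[l % config.n_f1_sires]
        dam = f1_dams[l % config.n_f1_dams]
        for _ in range(size):
            rows.append((f"F2_{k:04d}", sire, dam, "", "F2", ""))
            litter_info.append((f"F2_{k:04d}", f"L{l:02d}"))
            k += 1
    df = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "sex", "generation", "founder_breed"]
    )
    return df, dict(litter_info)


def simulate_cross(
    config: SimConfig,
) -> Tuple[GenotypeMatrix, Pedigree, PhenotypeTable, SimTruth]:
    """Simulate genotypes, pedigree, phenotypes and ground truth.

    Returns the genotype matrix for *all* pedigree members (founders, F1 and
    F2, with phase), the pedigree, the F2 phenotype table and the truth
    object carrying haplotypes, founder origins, QTL genotypes, breeding
    values and realized variance components.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = default_marker_map(config)
    chrom_slices = _chromosome_slices(markers)
    cm = markers.cm
    freqs = (
        config.founder_breed_freqs
        if config.founder_breed_freqs is not None
        else _founder_freqs(config, markers, rng)
    )
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (2, markers.n_markers):
        raise ValueError("founder_breed_freqs must have shape (2, n_markers)")

    ped_df, litter_of = _build_pedigree(config)
    ped = Pedigree(ped_df)
    ids = ped.ids
    n = len(ids)
    m = markers.n_markers
    row = {iid: i for i, iid in enumerate(ids)}

    hap_alleles = np.zeros((n, 2, m), dtype=np.int8)
    hap_origin = np.zeros((n, 2, m), dtype=np.int32)
    founder_hap_owner: list = []
    founder_hap_breed: list = []

    v_q, v_q2, s_a, s_c, s_e = config.variance_components()
    bv: Dict[str, float] = {}

    for rec in ped.table.itertuples():
        i = row[rec.id]
        if rec.sire == "" and rec.dam == "":
            breed_row = 0 if rec.founder_breed == MINZHU else 1
            for h in (0, 1):
                g_idx = len(founder_hap_owner)
                founder_hap_owner.append(rec.id)
                founder_hap_breed.append(rec.founder_breed)
                hap_alleles[i, h] = (rng.random(m) < freqs[breed_row]).astype(np.int8)
                hap_origin[i, h] = g_idx
            bv[rec.id] = rng.normal(0.0, np.sqrt(s_a))
        else:
            ps, pd_ = row[rec.sire], row[rec.dam]
            hap_alleles[i, 0], hap_origin[i, 0] = _gamete(
                hap_alleles[ps], hap_origin[ps], cm, chrom_slices, rng
            )
            hap_alleles[i, 1], hap_origin[i, 1] = _gamete(
                hap_alleles[pd_], hap_origin[pd_], cm, chrom_slices, rng
            )
            bv[rec.id] = 0.5 * (bv[rec.sire] + bv[rec.dam]) + rng.normal(
                0.0, np.sqrt(s_a / 2.0)
            )

    f2_ids = [iid for iid in ids if iid.startswith("F2_")]
    f2_rows = np.asarray([row[iid] for iid in f2_ids])
    n2 = len(f2_ids)

    # fixed effects with exactly known population variance
    sex = rng.integers(0, 2, n2)
    sex_eff = np.where(sex == 0, -config.sex_effect, config.sex_effect)
    parity_levels = np.arange(config.n_parity)
    par_effects = parity_levels - parity_levels.mean()
    par_effects = par_effects / (par_effects.std() or 1.0) * config.parity_effect_sd
    litters = sorted(set(litter_of.values()))
    litter_parity = {l: int(rng.integers(0, config.n_parity)) for l in litters}
    parity = np.asarray([litter_parity[litter_of[iid]] for iid in f2_ids])
    raw_bat = rng.normal(0.0, 1.0, config.n_batch)
    raw_bat = (raw_bat - raw_bat.mean()) / (raw_bat.std() or 1.0)
    bat_effects = raw_bat * config.batch_effect_sd
    batch = rng.integers(0, config.n_batch, n2)
    weight = rng.normal(config.body_weight_mean, config.body_weight_sd, n2)

    litter_eff = {l: rng.normal(0.0, np.sqrt(s_c)) for l in litters}
    c_vec = np.asarray([litter_eff[litter_of[iid]] for iid in f2_ids])
    a_vec = np.asarray([bv[iid] for iid in f2_ids])
    e_vec = rng.normal(0.0, np.sqrt(s_e), n2)

    qtl_effect = np.zeros(n2)
    qtl_geno: Dict[str, int] = {}
    if config.qtl_marker_index is not None and v_q > 0:
        a_q = np.sqrt(2.0 * v_q)
        d = hap_alleles[f2_rows, :, config.qtl_marker_index].sum(axis=1)
        qtl_effect += a_q * (d - 1.0)
        qtl_geno = {iid: int(dv) for iid, dv in zip(f2_ids, d)}
    elif config.qtl_marker_index is not None:
        d = hap_alleles[f2_rows, :, config.qtl_marker_index].sum(axis=1)
        qtl_geno = {iid: int(dv) for iid, dv in zip(f2_ids, d)}
    if config.qtl2_marker_index is not None and v_q2 > 0:
        a_q2 = np.sqrt(2.0 * v_q2)
        d2 = hap_alleles[f2_rows, :, config.qtl2_marker_index].sum(axis=1)
        qtl_effect += a_q2 * (d2 - 1.0)

    intercept = config.trait_mean - config.body_weight_slope * config.body_weight_mean
    y = (
        intercept
        + sex_eff
        + par_effects[parity]
        + bat_effects[batch]
        + config.body_weight_slope * weight
        + c_vec
        + a_vec
        + qtl_effect
        + e_vec
    )

    pheno = PhenotypeTable(pd.DataFrame({
        "id": f2_ids,
        "ear_area": y,
        "sex": np.where(sex == 0, "M", "F"),
        "parity": [f"P{p}" for p in parity],
        "batch": [f"B{b:02d}" for b in batch],
        "litter_id": [litter_of[iid] for iid in f2_ids],
        "body_weight": weight,
    }))

    # record simulated sex back into the pedigree for the F2
    sex_col = ped.table["id"].map(
        dict(zip(f2_ids, np.where(sex == 0, "M", "F")))
    )
    ped.table.loc[sex_col.notna(), "sex"] = sex_col[sex_col.notna()]

    truth = SimTruth(
        individual_ids=ids,
        markers=markers,
        hap_alleles=hap_alleles,
        hap_origin=hap_origin,
        founder_hap_owner=founder_hap_owner,
        founder_hap_breed=founder_hap_breed,
        qtl_marker_index=config.qtl_marker_index,
        qtl_genotype=qtl_geno,
        breeding_values=bv,
        litter_effects=litter_eff,
        realized_components={
            "sigma2_a": float(np.var(a_vec)),
            "sigma2_c": float(np.var(c_vec)),
            "sigma2_e": float(np.var(e_vec)),
            "v_qtl": float(np.var(qtl_effect)),
        },
        config=config,
    )
    g = truth.to_genotype_matrix(rng)
    return g, ped, pheno, truth


# ---------------------------------------------------------------------------
# shared-haplotype planting
# ---------------------------------------------------------------------------

def plant_shared_haplotype(truth: SimTruth, interval: Tuple[int, int]) -> SimTruth:
    """Force all Q-bearing founder chromosomes to share one haplotype.

    ``interval`` is an inclusive ``(first_marker_index, last_marker_index)``
    range.  Every Minzhu founder chromosome (all carry Q) receives the same
    allele sequence over the interval; at the markers immediately flanking
    it one founder chromosome is toggled if needed so that sharing cannot
    extend past the requested bounds.  All descendant haplotypes are then
    regenerated from the recorded founder-of-origin labels.
    """
    lo, hi = int(interval[0]), int(interval[1])
    m = truth.markers.n_markers
    if lo > hi:
        raise ValueError("interval is empty")
    if lo < 0 or hi >= m:
        raise ValueError("interval outside marker map")

    founder_mat = truth.founder_hap_matrix()
    q_idx = np.flatnonzero(np.asarray(truth.founder_hap_breed) == MINZHU)
    if len(q_idx) == 0:
        raise ValueError("no Q-bearing founder chromosomes in truth")
    template = founder_mat[q_idx[0], lo:hi + 1].copy()
    founder_mat[np.ix_(q_idx, np.arange(lo, hi + 1))] = template
    for edge in (lo - 1, hi + 1):
        if 0 <= edge < m and len(q_idx) >= 2:
            col = founder_mat[q_idx, edge]
            if (col == col[0]).all():
                founder_mat[q_idx[1], edge] = 1 - col[0]

    new = dataclasses.replace(truth)
    new.hap_alleles = founder_mat[truth.hap_origin, np.arange(m)[None, None, :]]
    new.hap_alleles = new.hap_alleles.astype(np.int8)
    # keep QTL genotype bookkeeping consistent with the (possibly) new alleles
    if truth.qtl_marker_index is not None and truth.qtl_genotype:
        row = {iid: i for i, iid in enumerate(truth.individual_ids)}
        new.qtl_genotype = {
            iid: int(new.hap_alleles[row[iid], :, truth.qtl_marker_index].sum())
            for iid in truth.qtl_genotype
        }
    return new


# ---------------------------------------------------------------------------
# breed panels for sweep detection
# ---------------------------------------------------------------------------

@dataclass
class SweepSimConfig:
    """Breed-panel generator for sweep detection.

    The case breed is fixed (one allele at frequency 1.0) at every marker of
    ``run`` (inclusive marker-index range) and guaranteed polymorphic
    elsewhere; control breeds are drawn from frequencies bounded away from
    fixation and guaranteed polymorphic at the run markers.  Default panel
    sizes follow the study's panels (case 32; controls 38/69/95).
    """

    markers: Optional[MarkerMap] = None
    n_markers: int = 40
    region_start_bp: int = 30_135_149
    region_end_bp: int = 40_915_894
    chromosome: str = "5"
    run: Optional[Tuple[int, int]] = (14, 19)
    case_breed: str = "Erhualian"
    panel_sizes: Dict[str, int] = field(default_factory=lambda: {
        "Erhualian": 32, "Duroc": 38, "Landrace": 69, "LargeWhite": 95,
    })
    seed: int = 0

    def marker_map(self) -> MarkerMap:
        if self.markers is not None:
            return self.markers
        pos = np.linspace(
            self.region_start_bp, self.region_end_bp, self.n_markers
        ).round().astype(np.int64)
        n = len(pos)
        return MarkerMap(
            [f"SW_{j:03d}" for j in range(n)], [self.chromosome] * n, pos,
            ["A"] * n, ["G"] * n,
        )


def _force_polymorphic(geno: np.ndarray, rng, f: float) -> np.ndarray:
    """Resample a genotype column until it is polymorphic (then force)."""
    for _ in range(200):
        if len(np.unique(geno)) > 1 or 0 < geno[0] < 2:
            return geno
        geno = rng.binomial(2, f, len(geno))
    geno[0] = 1
    return geno


def simulate_breed_panels(config: SweepSimConfig) -> Dict[str, GenotypeMatrix]:
    """Generate one GenotypeMatrix per breed over a shared candidate region."""
    rng = np.random.default_rng(config.seed)
    markers = config.marker_map()
    m = markers.n_markers
    run_mask = np.zeros(m, dtype=bool)
    if config.run is not None:
        lo, hi = config.run
        if lo > hi or lo < 0 or hi >= m:
            raise ValueError("fixed-run interval outside marker range")
        run_mask[lo:hi + 1] = True

    panels: Dict[str, GenotypeMatrix] = {}
    for breed, size in config.panel_sizes.items():
        dosage = np.zeros((size, m), dtype=float)
        is_case = breed == config.case_breed
        for j in range(m):
            if is_case and run_mask[j]:
                dosage[:, j] = 2.0  # fixed for allele2 at every run marker
                continue
            f = rng.uniform(0.2, 0.8) if is_case else rng.uniform(0.15, 0.85)
            g = rng.binomial(2, f, size)
            if is_case or run_mask[j]:
                # case must stay polymorphic off-run; controls must stay
                # polymorphic at run markers
                g = _force_polymorphic(g, rng, f)
            dosage[:, j] = g
        panels[breed] = GenotypeMatrix(
            [f"{breed}_{i:03d}" for i in range(size)], markers, dosage
        )
    return panels
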
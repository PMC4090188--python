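"""Marker-assisted segregation analysis (MASS) of F1 sires.

Offspring of a sire are sorted into two groups by the paternal homolog they
inherited (majority vote over sire-heterozygous markers); a log10
likelihood ratio ``Z = log10(L_H1 / L_H0)`` then compares a heterozygous-
sire model (group-specific means, pooled maximum-likelihood variance)
against a homozygous-sire model (common mean and variance).  Sires are
called Qq when Z > 2, homozygous when Z < -2, and undetermined in between
(boundary values included in "undetermined").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats import GenotypeMatrix, Pedigree

__all__ = [
    "MassResult",
    "assign_transmitted_homolog",
    "mass_z",
    "classify_sire",
    "sire_mass",
]

H1, H2, UNASSIGNED = "H1", "H2", "unassigned"
QQ_HET, HOMOZYGOUS, UNDETERMINED = "Qq", "homozygous", "undetermined"


@dataclass
class MassResult:
    sire_id: str
    labels: Dict[str, str]              # offspring id -> H1/H2/unassigned
    n1: int
    n2: int
    n_unassigned: int
    mean1: float
    mean2: float
    se1: float
    se2: float
    z: Optional[float]
    classification: str
    n_informative_markers: int = 0


def assign_transmitted_homolog(
    sire_phase: np.ndarray,
    offspring_dosage: np.ndarray,
    dam_dosage: Optional[np.ndarray] = None,
) -> Tuple[List[str], int]:
    """Label each offspring with the sire homolog it inherited.

    ``sire_phase`` is ``(2, m)`` allele2 copies per homolog;
    ``offspring_dosage`` is ``(n, m)``; ``dam_dosage`` (optional, same
    shape) disambiguates heterozygous offspring.  At each sire-heterozygous
    marker the transmitted sire allele is inferred where it is uniquely
    determined by the offspring (and dam) genotype; the homolog compatible
    at the majority of informative markers wins, ties or no informative
    marker give ``unassigned``.

    Raises if the sire is homozygous at every marker.
    """
    sire_phase = np.asarray(sire_phase)
    offspring_dosage = np.asarray(offspring_dosage, float)
    het = sire_phase[0] != sire_phase[1]
    if not het.any():
        raise ValueError("uninformative sire: homozygous at all markers")
    info = np.flatnonzero(het)
    labels: List[str] = []
    for i in range(offspring_dosage.shape[0]):
        votes = {H1: 0, H2: 0}
        for j in info:
            d = offspring_dosage[i, j]
            if np.isnan(d):
                continue
            if dam_dosage is not None and not np.isnan(dam_dosage[i, j]):
                dd = dam_dosage[i, j]
                dam_can = {0.0: (0,), 1.0: (0, 1), 2.0: (1,)}[dd]
            else:
                dam_can = (0, 1)
            feasible = {int(d) - t for t in dam_can} & {0, 1}
            if len(feasible) != 1:
                continue
            t = feasible.pop()
            votes[H1 if sire_phase[0, j] == t else H2] += 1
        if votes[H1] == votes[H2]:
            labels.append(UNASSIGNED)
        else:
            labels.append(H1 if votes[H1] > votes[H2] else H2)
    return labels, int(len(info))


def mass_z(pheno1: Sequence[float], pheno2: Sequence[float]) -> float:
    """log10 likelihood ratio of two-mean vs one-mean Gaussian models.

    H1: group-specific means with pooled MLE variance; H0: one common mean
    and MLE variance.  Requires at least two records per group.
    """
    y1 = np.asarray(pheno1, float)
    y2 = np.asarray(pheno2, float)
    if len(y1) < 2 or len(y2) < 2:
        raise ValueError("each group needs at least 2 records")
    n = len(y1) + len(y2)
    ss1 = float(((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum())
    y = np.concatenate([y1, y2])
    ss0 = float(((y - y.mean()) ** 2).sum())
    if ss1 == 0.0 and ss0 == 0.0:
        return 0.0
    if ss1 == 0.0:
        return np.inf
    return float(n / 2.0 * np.log10(ss0 / ss1))


def classify_sire(z: Optional[float]) -> str:
    """Apply the Z thresholds: >2 Qq, <-2 homozygous, else undetermined."""
    if z is None or not np.isfinite(z):
        if z is not None and np.isposinf(z):
            return QQ_HET
        return UNDETERMINED
    if z > 2.0:
        return QQ_HET
    if z < -2.0:
        return HOMOZYGOUS
    return UNDETERMINED


def sire_mass(
    sire_id: str,
    sire_phase: np.ndarray,
    g: GenotypeMatrix,
    ped: Pedigree,
    trait: Dict[str, float],
    marker_ids: Sequence[str],
    dam_dosage_lookup: Optional[Dict[str, np.ndarray]] = None,
    litter_of: Optional[Dict[str, str]] = None,
    adjust_dam_allele: bool = True,
) -> MassResult:
    """Run MASS for one sire over a marker window.

    ``trait`` maps offspring id to the phenotype; offspring without a trait
    record are ignored.  ``dam_dosage_lookup`` may map an offspring id to
    its dam's dosage vector over the same markers.

    Two marker-assisted nuisance adjustments sharpen the group contrast
    without touching the likelihood-ratio itself: when ``litter_of`` is
    given, phenotypes are centered within litter (removes litter and
    dam-level polygenic variance); when ``adjust_dam_allele`` is set, the
    dam-transmitted allele at the central sire-heterozygous marker —
    offspring dosage minus the inferred paternal allele — is regressed out
    (removes the maternal QTL-allele variance from the within-group noise).
    Both are valid under either sire genotype, so the H0 false-positive
    rate is preserved.
    """
    cols = [g.markers.index_of(m) for m in marker_ids]
    offspring = [o for o in ped.offspring_of_sire(sire_id) if o in trait]
    rows = [g.index_of(o) for o in offspring]
    off_dos = g.dosage[np.ix_(rows, cols)]
    dam_dos = None
    if dam_dosage_lookup is not None:
        dam_dos = np.vstack([
            dam_dosage_lookup.get(o, np.full(len(cols), np.nan)) for o in offspring
        ])
    phase = np.asarray(sire_phase)
    if phase.shape == (2, g.n_markers):
        phase = phase[:, cols]
    labels, n_info = assign_transmitted_homolog(phase, off_dos, dam_dos)
    lab_map = dict(zip(offspring, labels))

    y_adj = np.asarray([trait[o] for o in offspring], float)
    if litter_of is not None:
        lit = np.asarray([litter_of.get(o, "?") for o in offspring])
        for lev in np.unique(lit):
            sel = lit == lev
            y_adj[sel] -= y_adj[sel].mean()
    if adjust_dam_allele:
        # central window marker; the paternal allele there is known even
        # when the sire is homozygous at it
        c = phase.shape[1] // 2
        if phase[0, c] == phase[1, c]:
            pat = np.where(
                [l != UNASSIGNED for l in labels], float(phase[0, c]), np.nan
            )
        else:
            pat = np.asarray([
                phase[0, c] if l == H1 else phase[1, c] if l == H2 else np.nan
                for l in labels
            ])
        dam_al = off_dos[:, c] - pat
        ok = ~np.isnan(dam_al)
        if ok.sum() >= 3 and len(np.unique(dam_al[ok])) > 1:
            Xd = np.column_stack([np.ones(int(ok.sum())), dam_al[ok]])
            b, *_ = np.linalg.lstsq(Xd, y_adj[ok], rcond=None)
            y_adj[ok] = y_adj[ok] - Xd @ b + float(np.mean(Xd @ b))

    y1 = np.asarray([y for y, l in zip(y_adj, labels) if l == H1])
    y2 = np.asarray([y for y, l in zip(y_adj, labels) if l == H2])
    n_un = sum(1 for l in labels if l == UNASSIGNED)

    def _se(v):
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan

    if len(y1) < 2 or len(y2) < 2:
        z: Optional[float] = None
        cls = UNDETERMINED
    else:
        z = mass_z(y1, y2)
        cls = classify_sire(z)
    return MassResult(
        sire_id=sire_id,
        labels=lab_map,
        n1=len(y1), n2=len(y2), n_unassigned=n_un,
        mean1=float(y1.mean()) if len(y1) else np.nan,
        mean2=float(y2.mean()) if len(y2) else np.nan,
        se1=_se(y1), se2=_se(y2),
        z=z, classification=cls,
        n_informative_markers=n_info,
    )
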
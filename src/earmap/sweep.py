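"""Breed-panel selective-sweep detection by fixation runs.

A sweep is called where more than three consecutive markers (run length >=
``min_run``, default 4) are fixed for one allele in the case breed while
the control breeds stay polymorphic; the reported interval is bounded by
the nearest non-fixed flanking markers, both exclusive, and its bp length
is the distance between those flanking markers.  Fixation is judged on
observed calls (missing genotypes ignored, with the missing fraction
reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formats import GenotypeMatrix

__all__ = [
    "BreedPanel",
    "SweepInterval",
    "genotype_frequencies",
    "heterozygosity",
    "heterozygosity_table",
    "detect_sweep",
]


@dataclass
class BreedPanel:
    breed: str
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        if self.genotypes.n_individuals < 1:
            raise ValueError("breed panel needs at least one individual")


def genotype_frequencies(panel: BreedPanel, marker) -> Tuple[float, float, float]:
    """Frequencies of (hom-allele1, het, hom-allele2) among observed calls."""
    g = panel.genotypes
    j = g.markers.index_of(marker) if isinstance(marker, str) else int(marker)
    col = g.dosage[:, j]
    obs = col[~np.isnan(col)]
    if len(obs) == 0:
        raise ValueError(f"all genotypes missing at marker {marker!r}")
    n = len(obs)
    return (
        float((obs == 0).sum() / n),
        float((obs == 1).sum() / n),
        float((obs == 2).sum() / n),
    )


def heterozygosity(panel: BreedPanel, marker) -> float:
    """Expected heterozygosity 2f(1-f) from the observed allele frequency."""
    g = panel.genotypes
    j = g.markers.index_of(marker) if isinstance(marker, str) else int(marker)
    col = g.dosage[:, j]
    obs = col[~np.isnan(col)]
    if len(obs) == 0:
        raise ValueError(f"all genotypes missing at marker {marker!r}")
    f = float(obs.mean() / 2.0)
    return 2.0 * f * (1.0 - f)


def heterozygosity_table(panels: Sequence[BreedPanel]) -> pd.DataFrame:
    """Per-breed per-marker expected heterozygosity (long companion table)."""
    rows = []
    for p in panels:
        mm = p.genotypes.markers
        for j in range(mm.n_markers):
            rows.append({
                "breed": p.breed,
                "marker": str(mm.marker_id[j]),
                "chr": str(mm.chromosome[j]),
                "pos": int(mm.position_bp[j]),
                "heterozygosity": heterozygosity(p, j),
            })
    return pd.DataFrame(rows)


@dataclass
class SweepInterval:
    case_breed: str
    run_marker_ids: List[str]
    first_index: int
    last_index: int
    left_flank: Optional[str]       # exclusive; None at chromosome edge
    right_flank: Optional[str]
    bp_length: int
    missing_fraction: float = 0.0

    @property
    def n_run_markers(self) -> int:
        return len(self.run_marker_ids)


def _fixation_mask(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker: all observed calls identical homozygotes."""
    d = g.dosage
    obs = ~np.isnan(d)
    any_obs = obs.any(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nanmean(d, axis=0) / 2.0
    het_present = np.nansum(d == 1, axis=0) > 0
    return any_obs & ~het_present & ((f == 0.0) | (f == 1.0))


def _polymorphic_mask(g: GenotypeMatrix) -> np.ndarray:
    return ~_fixation_mask(g)


def detect_sweep(
    case: BreedPanel,
    controls: Sequence[BreedPanel],
    min_run: int = 4,
    require_all_run_markers: bool = False,
) -> List[SweepInterval]:
    """Find case-fixed marker runs that stay polymorphic in every control.

    ``min_run`` is the minimum run length (default 4, i.e. strictly more
    than three consecutive fixed markers).  Each control breed must be
    polymorphic at >= 1 marker of the run (or at every run marker when
    ``require_all_run_markers``).  Interval bounds are the nearest non-
    fixed flanking markers, both exclusive; the bp length is the distance
    between them (falling back to the run's outer markers at a chromosome
    edge).
    """
    mm = case.genotypes.markers
    for c in controls:
        if list(c.genotypes.markers.marker_id) != list(mm.marker_id):
            raise ValueError(
                f"control panel {c.breed!r} marker set differs from case"
            )
    fixed = _fixation_mask(case.genotypes)
    missing_frac = np.isnan(case.genotypes.dosage).mean(axis=0)
    m = mm.n_markers

    out: List[SweepInterval] = []
    j = 0
    while j < m:
        if not fixed[j]:
            j += 1
            continue
        start = j
        while j + 1 < m and fixed[j + 1] and mm.chromosome[j + 1] == mm.chromosome[j]:
            j += 1
        end = j
        j += 1
        if end - start + 1 < min_run:
            continue
        run_cols = np.arange(start, end + 1)
        ok = True
        for c in controls:
            poly = _polymorphic_mask(c.genotypes)[run_cols]
            ok &= poly.all() if require_all_run_markers else poly.any()
        if not ok:
            continue
        left = start - 1 if start > 0 and mm.chromosome[start - 1] == mm.chromosome[start] else None
        right = end + 1 if end < m - 1 and mm.chromosome[end + 1] == mm.chromosome[end] else None
        lo_pos = mm.position_bp[left] if left is not None else mm.position_bp[start]
        hi_pos = mm.position_bp[right] if right is not None else mm.position_bp[end]
        out.append(SweepInterval(
            case_breed=case.breed,
            run_marker_ids=[str(mm.marker_id[k]) for k in run_cols],
            first_index=start, last_index=end,
            left_flank=str(mm.marker_id[left]) if left is not None else None,
            right_flank=str(mm.marker_id[right]) if right is not None else None,
            bp_length=int(hi_pos - lo_pos),
            missing_fraction=float(missing_frac[run_cols].mean()),
        ))
    return out
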
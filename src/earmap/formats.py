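"""Core data containers and text-file I/O for the fine-mapping pipeline.

All genotype data travel as whitespace-delimited PED/MAP text with the six
standard leading PED columns; pedigree and phenotype tables are delimited
text with a header; association results are written as TSV with a fixed
column order.  Coordinates are 1-based inclusive throughout, and interval
lengths are reported as ``end_bp - start_bp``.

Dosage convention: genotypes are stored as copies of ``allele2`` per marker
(0, 1, 2, or NaN for missing).  Unknown allele characters (``0``, ``N``)
are read as missing; missingness is preserved verbatim by every round trip,
never imputed at this layer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MarkerMap",
    "GenotypeMatrix",
    "Pedigree",
    "PhenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_results",
    "write_results",
    "RESULT_COLUMNS",
]

MISSING_ALLELES = {"0", "N", ".", "-9"}

#: fixed column order of association-result tables
RESULT_COLUMNS = [
    "marker", "chr", "pos", "effect", "se", "T2", "T2_gc", "P", "var_pct",
]


class FormatError(ValueError):
    """Raised on malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered marker metadata: id, chromosome, 1-based bp position, alleles.

    ``cm`` optionally carries genetic-map positions (centimorgans), used by
    the simulator's crossover model; it is written to / read from the third
    MAP column.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    cm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        if self.cm is not None:
            self.cm = np.asarray(self.cm, dtype=float)
        n = len(self.marker_id)
        for name in ("chromosome", "position_bp", "allele1", "allele2"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"marker map column {name!r} has wrong length")
        if self.cm is not None and len(self.cm) != n:
            raise FormatError("marker map column 'cm' has wrong length")
        ids, counts = np.unique(self.marker_id, return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][0]
            raise FormatError(f"duplicate marker id {dup!r}")
        if n and (self.position_bp <= 0).any():
            raise FormatError("marker positions must be positive (1-based)")
        # strictly increasing positions within each chromosome
        for chrom in pd.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if (np.diff(pos) <= 0).any():
                raise FormatError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        self._index = {m: i for i, m in enumerate(self.marker_id)}

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def __len__(self) -> int:
        return self.n_markers

    def index_of(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def subset(self, idx: Sequence[int]) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            self.marker_id[idx], self.chromosome[idx], self.position_bp[idx],
            self.allele1[idx], self.allele2[idx],
            None if self.cm is None else self.cm[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        d = {
            "marker_id": self.marker_id,
            "chromosome": self.chromosome,
            "position_bp": self.position_bp,
            "allele1": self.allele1,
            "allele2": self.allele2,
        }
        if self.cm is not None:
            d["cm"] = self.cm
        return pd.DataFrame(d)


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-dosage matrix (copies of ``allele2``).

    ``dosage`` is float with NaN marking missing calls.  ``phase``, when
    present, is an ``(n, 2, m)`` int8 array of per-haplotype allele2 copies
    (0/1) whose sum equals ``dosage`` wherever dosage is non-missing.
    """

    individual_ids: list
    markers: MarkerMap
    dosage: np.ndarray
    phase: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.individual_ids = list(self.individual_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.individual_ids):
            raise FormatError("dosage rows do not match individual ids")
        if m != self.markers.n_markers:
            raise FormatError("dosage columns do not match marker map")
        if len(set(self.individual_ids)) != n:
            raise FormatError("duplicate individual ids")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise FormatError("dosage values must be 0, 1, 2 or missing")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=np.int8)
            if self.phase.shape != (n, 2, m):
                raise FormatError("phase array has wrong shape")
            hap_sum = self.phase.sum(axis=1)
            obs = ~np.isnan(self.dosage)
            if not np.array_equal(hap_sum[obs], self.dosage[obs]):
                raise FormatError("phase does not sum to dosage")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def index_of(self, individual_id: str) -> int:
        return self.individual_ids.index(individual_id)

    def subset(
        self,
        individuals: Optional[Sequence] = None,
        markers: Optional[Sequence[int]] = None,
    ) -> "GenotypeMatrix":
        """Subset by individual ids (or row indices) and marker indices."""
        if individuals is None:
            rows = np.arange(self.n_individuals)
        else:
            lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
            rows = np.asarray(
                [lookup[i] if isinstance(i, str) else int(i) for i in individuals]
            )
        if markers is None:
            cols = np.arange(self.n_markers)
        else:
            cols = np.asarray(markers)
        return GenotypeMatrix(
            [self.individual_ids[r] for r in rows],
            self.markers.subset(cols),
            self.dosage[np.ix_(rows, cols)],
            None if self.phase is None else self.phase[np.ix_(rows, np.arange(2), cols)],
        )


UNKNOWN_PARENT = ""


@dataclass
class Pedigree:
    """Three-generation intercross pedigree.

    Stored as a DataFrame with columns ``id, sire, dam, sex, generation,
    founder_breed``; unknown parents are empty strings.  Records are kept in
    (and validated to admit) a topological order: parents precede offspring.
    """

    table: pd.DataFrame

    REQUIRED = ["id", "sire", "dam", "sex", "generation"]

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"pedigree missing required column {col!r}")
        if "founder_breed" not in df.columns:
            df["founder_breed"] = ""
        for col in ("id", "sire", "dam", "sex", "generation", "founder_breed"):
            df[col] = df[col].fillna("").astype(str)
        for col in ("sire", "dam"):
            df.loc[df[col] == "0", col] = UNKNOWN_PARENT
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise FormatError(f"duplicate pedigree id {dup!r}")
        ids = set(df["id"])
        for col in ("sire", "dam"):
            named = df.loc[df[col] != UNKNOWN_PARENT, col]
            missing = set(named) - ids
            if missing:
                raise FormatError(
                    f"{col} id {sorted(missing)[0]!r} has no pedigree record"
                )
        self.table = self._toposort(df)
        self._row = {iid: i for i, iid in enumerate(self.table["id"])}

    @staticmethod
    def _toposort(df: pd.DataFrame) -> pd.DataFrame:
        """Order parents before offspring; raise on cycles."""
        parents = {
            r.id: [p for p in (r.sire, r.dam) if p != UNKNOWN_PARENT]
            for r in df.itertuples()
        }
        order: list = []
        state: dict = {}  # 0 visiting, 1 done

        for start in df["id"]:
            if start in state:
                continue
            stack = [(start, iter(parents[start]))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if state.get(p) == 0:
                        raise FormatError(f"pedigree cycle involving {p!r}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(parents[p])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    order.append(node)
                    stack.pop()
        pos = {iid: i for i, iid in enumerate(order)}
        out = df.iloc[np.argsort([pos[i] for i in df["id"]], kind="stable")]
        return out.reset_index(drop=True)

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    def __len__(self) -> int:
        return len(self.table)

    def row(self, individual_id: str) -> int:
        return self._row[individual_id]

    def parents(self, individual_id: str) -> tuple:
        r = self.table.iloc[self._row[individual_id]]
        return (r["sire"] or None, r["dam"] or None)

    def offspring_of_sire(self, sire_id: str) -> list:
        return list(self.table.loc[self.table["sire"] == sire_id, "id"])


@dataclass
class PhenotypeTable:
    """Per-F2 trait records: ear area (cm^2) plus fixed effects and covariate."""

    table: pd.DataFrame

    REQUIRED = ["id", "ear_area", "sex", "parity", "batch", "litter_id", "body_weight"]

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"phenotype table missing required column {col!r}")
        df["id"] = df["id"].astype(str)
        for col in ("sex", "parity", "batch", "litter_id"):
            df[col] = df[col].astype(str)
        df["ear_area"] = df["ear_area"].astype(float)
        df["body_weight"] = df["body_weight"].astype(float)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise FormatError(f"duplicate phenotype record for {dup!r}")
        if (df["ear_area"] <= 0).any():
            raise FormatError("ear_area must be positive")
        self.table = df.reset_index(drop=True)

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    def __len__(self) -> int:
        return len(self.table)

    def check_against_pedigree(self, ped: Pedigree) -> None:
        missing = set(self.ids) - set(ped.ids)
        if missing:
            raise FormatError(
                f"phenotyped individual {sorted(missing)[0]!r} absent from pedigree"
            )


# ---------------------------------------------------------------------------
# PED/MAP genotypes
# ---------------------------------------------------------------------------

def _read_map(map_path) -> tuple:
    """Read a MAP file; returns (fields per row, has_alleles, has_cm)."""
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) not in (3, 4, 6):
                raise FormatError(
                    f"{map_path}: line {ln}: expected 3, 4 or 6 columns, "
                    f"got {len(parts)}"
                )
            rows.append((ln, parts))
    if not rows:
        raise FormatError(f"{map_path}: empty map file")
    ncol = len(rows[0][1])
    for ln, parts in rows:
        if len(parts) != ncol:
            raise FormatError(f"{map_path}: line {ln}: inconsistent column count")
    return rows, ncol


def read_genotypes(ped_path, map_path) -> GenotypeMatrix:
    """Read whitespace-delimited PED/MAP text into a dosage matrix.

    The MAP file carries ``chrom  marker_id  [cm]  pos  [allele1 allele2]``.
    When allele columns are absent, alleles are inferred per marker from the
    PED data in lexicographic order (``allele2`` sorts last), so the dosage
    coding is deterministic.  Unknown allele characters become missing.
    """
    rows, ncol = _read_map(map_path)
    chroms, mids, cms, positions, a1, a2 = [], [], [], [], [], []
    for ln, parts in rows:
        chroms.append(parts[0])
        mids.append(parts[1])
        if ncol == 3:
            cms.append(np.nan)
            positions.append(parts[2])
        else:
            cms.append(float(parts[2]))
            positions.append(parts[3])
        if ncol == 6:
            a1.append(parts[4])
            a2.append(parts[5])
    try:
        positions = [int(p) for p in positions]
    except ValueError as exc:
        raise FormatError(f"{map_path}: non-integer position: {exc}") from None
    m = len(mids)

    indiv, allele_rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{ped_path}: line {ln}: fewer than 6 leading columns")
            alleles = parts[6:]
            if len(alleles) % 2 == 1:
                raise FormatError(f"{ped_path}: line {ln}: odd allele count")
            if len(alleles) != 2 * m:
                raise FormatError(
                    f"{ped_path}: line {ln}: {len(alleles) // 2} genotypes for "
                    f"{m} map markers"
                )
            indiv.append(parts[1])
            allele_rows.append(alleles)
    if not indiv:
        raise FormatError(f"{ped_path}: empty PED file")

    al = np.asarray(allele_rows, dtype=object).reshape(len(indiv), m, 2)
    if ncol != 6:
        # infer alleles per marker, lexicographic order
        a1, a2 = [], []
        for j in range(m):
            seen = sorted(
                {x for x in al[:, j, :].ravel() if x not in MISSING_ALLELES}
            )
            if len(seen) > 2:
                raise FormatError(
                    f"{ped_path}: marker {mids[j]!r} has more than two alleles"
                )
            if len(seen) == 2:
                a1.append(seen[0]); a2.append(seen[1])
            elif len(seen) == 1:
                a1.append(seen[0]); a2.append("0")
            else:
                a1.append("0"); a2.append("0")

    dosage = np.full((len(indiv), m), np.nan)
    for j in range(m):
        col = al[:, j, :]
        missing = np.isin(col, list(MISSING_ALLELES)).any(axis=1)
        bad = ~missing & ~np.isin(col, (a1[j], a2[j])).all(axis=1)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{ped_path}: individual {indiv[i]!r}, marker {mids[j]!r}: "
                f"allele not in map ({col[i, 0]}/{col[i, 1]})"
            )
        d = (col == a2[j]).sum(axis=1).astype(float)
        d[missing] = np.nan
        dosage[:, j] = d

    cm_arr = np.asarray(cms, float)
    markers = MarkerMap(
        mids, chroms, positions, a1, a2,
        cm=None if np.isnan(cm_arr).all() else cm_arr,
    )
    return GenotypeMatrix(indiv, markers, dosage)


def write_genotypes(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP text (6-column MAP including the allele labels)."""
    mm = g.markers
    cm = mm.cm if mm.cm is not None else np.zeros(mm.n_markers)
    with open(map_path, "w") as fh:
        for j in range(mm.n_markers):
            fh.write(
                f"{mm.chromosome[j]}\t{mm.marker_id[j]}\t{cm[j]:g}\t"
                f"{mm.position_bp[j]}\t{mm.allele1[j]}\t{mm.allele2[j]}\n"
            )
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(g.individual_ids):
            fields = ["0", str(iid), "0", "0", "0", "-9"]
            for j in range(mm.n_markers):
                d = g.dosage[i, j]
                if np.isnan(d):
                    pair = ("0", "0")
                elif g.phase is not None:
                    pair = tuple(
                        mm.allele2[j] if h else mm.allele1[j]
                        for h in g.phase[i, :, j]
                    )
                elif d == 0:
                    pair = (mm.allele1[j], mm.allele1[j])
                elif d == 1:
                    pair = (mm.allele1[j], mm.allele2[j])
                else:
                    pair = (mm.allele2[j], mm.allele2[j])
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_pedigree(path) -> Pedigree:
    return Pedigree(_read_table(path))


def write_pedigree(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = _read_table(path)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write an association-result table as TSV in the fixed column order.

    Floating-point columns are rendered with 17 significant digits so that
    P-values survive a round trip to at least 15 significant digits.
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"results table missing column {missing[0]!r}")
    out = results[RESULT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results table missing column {missing[0]!r}")
    return df
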
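"""GRAMMAR-with-genomic-control association for the F2 intercross.

Three steps:

1. Fit the polygenic mixed model
   ``y = Xb + w p + T c + Z a + e`` with litter effects
   ``c ~ N(0, I sigma2_c)``, additive polygenic effects
   ``a ~ N(0, A sigma2_a)`` (A the pedigree numerator relationship matrix)
   and residuals ``e ~ N(0, I sigma2_e)``, by average-information REML with
   an EM-flavored fallback step; keep the residuals
   ``y* = y - X b_hat - w p_hat - T c_hat - Z a_hat``.
2. Regress ``y*`` on each marker's allele dosage (single-locus regression,
   pairwise deletion of missing genotypes): slope ``k_hat``, its sampling
   variance, and ``T2 = k_hat**2 / var(k_hat)``.
3. Genomic control: ``lambda = median(T2) / 0.456`` (0.456 is the printed
   chi-square(1) median constant; the exact 0.45494 is available via
   ``gc_constant``), ``T2_adj = T2 / lambda``, P from the chi-square(1)
   upper tail.  ``lambda`` is applied as estimated, even when below 1.

Genome-wide thresholds are plain Bonferroni: ``alpha / n_tests``.
Conditional analysis appends the top marker's dosage to the fixed effects
and re-runs all three steps, excluding that marker from the rescan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .formats import GenotypeMatrix, Pedigree, PhenotypeTable

__all__ = [
    "CHI2_1_MEDIAN_PRINTED",
    "CHI2_1_MEDIAN_EXACT",
    "MixedModelSpec",
    "GrammarResiduals",
    "AssocResult",
    "relationship_matrix",
    "fit_polygenic",
    "residual_scan",
    "genomic_control",
    "bonferroni_threshold",
    "conditional_scan",
    "gwas_scan",
    "variance_explained",
    "results_to_frame",
    "manhattan_table",
    "qq_table",
]

#: genomic-control constant as printed in the method's description
CHI2_1_MEDIAN_PRINTED = 0.456
#: exact median of the chi-square(1) distribution
CHI2_1_MEDIAN_EXACT = float(stats.chi2.median(1))


# ---------------------------------------------------------------------------
# pedigree relationship matrix
# ---------------------------------------------------------------------------

def relationship_matrix(ped: Pedigree) -> Tuple[np.ndarray, List[str]]:
    """Additive numerator relationship matrix by the tabular method.

    Founders are taken as unrelated and non-inbred; unknown parents are
    treated as unrelated founders.  Returns ``(A, ids)`` with ids in the
    pedigree's topological order.
    """
    ids = ped.ids
    n = len(ids)
    row = {iid: i for i, iid in enumerate(ids)}
    A = np.zeros((n, n))
    for i, iid in enumerate(ids):
        s, d = ped.parents(iid)
        si = row[s] if s else -1
        di = row[d] if d else -1
        a_sd = A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            val = 0.0
            if si >= 0:
                val += 0.5 * A[j, si]
            if di >= 0:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
    return A, ids


# ---------------------------------------------------------------------------
# mixed-model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass
class MixedModelSpec:
    """Columns of the Step-1 model drawn from the phenotype table."""

    trait: str = "ear_area"
    fixed_factors: Sequence[str] = ("sex", "parity", "batch")
    covariates: Sequence[str] = ("body_weight",)
    litter: str = "litter_id"
    #: extra numeric covariates supplied directly (id-aligned), e.g. the
    #: conditioning marker's dosage in a conditional analysis
    extra_covariates: Dict[str, Dict[str, float]] = field(default_factory=dict)


def build_design(
    pheno: PhenotypeTable, spec: MixedModelSpec
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str], List[str]]:
    """Return (y, X, T, ids, column names); T is the litter incidence."""
    df = pheno.table
    ids = list(df["id"])
    y = df[spec.trait].to_numpy(float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for fac in spec.fixed_factors:
        levels = pd.unique(df[fac])
        if len(levels) < 2:
            continue
        for lev in levels[1:]:
            cols.append((df[fac] == lev).to_numpy(float))
            names.append(f"{fac}={lev}")
    for cov in spec.covariates:
        cols.append(df[cov].to_numpy(float))
        names.append(cov)
    for name, mapping in spec.extra_covariates.items():
        missing = [i for i in ids if i not in mapping or np.isnan(mapping[i])]
        if missing:
            raise ValueError(
                f"extra covariate {name!r} missing for individual {missing[0]!r}"
            )
        cols.append(np.asarray([mapping[i] for i in ids], float))
        names.append(name)
    X = np.column_stack(cols)
    litters = pd.unique(df[spec.litter])
    T = (df[spec.litter].to_numpy()[:, None] == litters[None, :]).astype(float)
    return y, X, T, ids, names


# ---------------------------------------------------------------------------
# REML polygenic fit (Step 1)
# ---------------------------------------------------------------------------

@dataclass
class GrammarResiduals:
    ids: List[str]
    y_star: np.ndarray
    sigma2_a: float
    sigma2_c: float
    sigma2_e: float
    loglik: float
    converged: bool
    n_iter: int
    beta: np.ndarray
    beta_names: List[str]
    trace: List[float] = field(default_factory=list)


def _reml_loglik(theta, parts, y, X):
    V = theta[0] * parts[0] + theta[1] * parts[1] + theta[2] * parts[2]
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    Vi_y = cho_solve((c, low), y)
    Vi_X = cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return ll, Py, Vi_X, XtViX, (c, low), beta


def fit_polygenic(
    pheno: PhenotypeTable,
    ped: Pedigree,
    spec: Optional[MixedModelSpec] = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> GrammarResiduals:
    """REML fit of the Step-1 polygenic model; returns the residuals y*.

    Average-information updates with step halving; when the AI step is not
    usable (non-PD information, bound violation, or a likelihood decrease
    that halving cannot repair) an EM-flavored scaled-gradient step is taken
    instead.  Components are constrained non-negative by projection to a
    small floor.  Convergence: successive REML log-likelihood change below
    ``tol``.
    """
    spec = spec or MixedModelSpec()
    pheno.check_against_pedigree(ped)
    y, X, T, ids, names = build_design(pheno, spec)
    n = len(y)
    if T.shape[1] < 2:
        raise ValueError("at least 2 litters required")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "confounded fixed effects: design is rank deficient; using a "
            "generalized inverse", RuntimeWarning,
        )
        # drop dependent columns deterministically
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-8 * np.abs(np.diag(r)).max()
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]

    A_full, ped_ids = relationship_matrix(ped)
    rows = [ped_ids.index(i) for i in ids]
    A = A_full[np.ix_(rows, rows)]
    K_c = T @ T.T
    parts = (A, K_c, np.eye(n))

    vary = float(np.var(y))
    floor = 1e-8 * vary
    theta = np.array([vary / 3.0, vary / 3.0, vary / 3.0])
    out = _reml_loglik(theta, parts, y, X)
    if out is None:
        raise RuntimeError("REML failed at the starting values")
    ll = out[0]
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, Py, Vi_X, XtViX, chol, _ = out
        Vi = cho_solve(chol, np.eye(n))
        P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
        t_vecs = [parts[k] @ Py for k in range(3)]
        score = np.array([
            -0.5 * (np.trace(P @ parts[k]) - float(Py @ t_vecs[k]))
            for k in range(3)
        ])
        AI = 0.5 * np.array([
            [float(t_vecs[i] @ (P @ t_vecs[j])) for j in range(3)]
            for i in range(3)
        ])

        # active set: components stuck at the floor with a negative score
        # are held fixed so the AI step cannot thrash against the bound
        free = ~((theta <= floor * (1 + 1e-9)) & (score < 0))
        if not free.any():
            converged = True
            break

        step = None
        try:
            step_free = np.linalg.solve(
                AI[np.ix_(free, free)], score[free]
            )
            step = np.zeros(3)
            step[free] = step_free
        except np.linalg.LinAlgError:
            pass

        new_out, new_theta = None, None
        if step is not None:
            scale = 1.0
            for _ in range(12):
                cand = np.maximum(theta + scale * step, floor)
                res = _reml_loglik(cand, parts, y, X)
                if res is not None and res[0] >= ll - 1e-10:
                    new_out, new_theta = res, cand
                    break
                scale *= 0.5
        if new_out is None:
            # EM-flavored fallback: scaled gradient, guaranteed in-bounds
            em = theta.copy()
            em[free] = theta[free] + (theta[free] ** 2) * (2.0 * score[free]) / n
            cand = np.maximum(em, floor)
            res = _reml_loglik(cand, parts, y, X)
            if res is None:
                break
            new_out, new_theta = res, cand

        delta = new_out[0] - ll
        theta, out, ll = new_theta, new_out, new_out[0]
        trace.append(ll)
        if abs(delta) < tol:
            converged = True
            break
    if not converged and it >= max_iter:
        raise RuntimeError(
            f"REML did not converge in {max_iter} iterations; trace={trace[-5:]}"
        )

    _, Py, Vi_X, XtViX, chol, beta = out
    s_a, s_c, s_e = theta
    y_star = s_e * Py  # y - X beta - T c_hat - a_hat
    return GrammarResiduals(
        ids=ids, y_star=y_star,
        sigma2_a=float(s_a), sigma2_c=float(s_c), sigma2_e=float(s_e),
        loglik=float(ll), converged=converged, n_iter=it,
        beta=beta, beta_names=names, trace=trace,
    )


# ---------------------------------------------------------------------------
# Step 2: single-locus regression on residuals
# ---------------------------------------------------------------------------

@dataclass
class AssocResult:
    marker_id: str
    chromosome: str
    position_bp: int
    n_used: int
    k_hat: float
    var_k: float
    T2: float
    var_pct: float
    tested: bool = True
    lambda_gc: Optional[float] = None
    T2_adj: Optional[float] = None
    P: Optional[float] = None

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_k)) if self.tested else np.nan


def residual_scan(
    resid: GrammarResiduals, g: GenotypeMatrix
) -> List[AssocResult]:
    """Regress y* on each marker dosage; missing genotypes drop pairwise.

    Monomorphic (zero-variance) or insufficiently observed markers are
    returned flagged ``tested=False`` rather than raising.
    """
    lookup = {iid: i for i, iid in enumerate(g.individual_ids)}
    common = [i for i in resid.ids if i in lookup]
    if not common:
        raise ValueError("no individuals shared between residuals and genotypes")
    y = np.asarray(
        [resid.y_star[resid.ids.index(i)] for i in common]
        if common != resid.ids else resid.y_star
    )
    rows = np.asarray([lookup[i] for i in common])
    D = g.dosage[rows]
    mask = ~np.isnan(D)
    nj = mask.sum(axis=0).astype(float)
    Ymat = np.where(mask, y[:, None], 0.0)
    Dm = np.where(mask, D, 0.0)
    sx = Dm.sum(axis=0)
    sy = Ymat.sum(axis=0)
    sxx = (Dm * Dm).sum(axis=0)
    sxy = (Dm * Ymat).sum(axis=0)
    syy = (Ymat * Ymat).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Sxx = sxx - sx * sx / nj
        Sxy = sxy - sx * sy / nj
        Syy = syy - sy * sy / nj
        k = Sxy / Sxx
        rss = Syy - Sxy * Sxy / Sxx
        var_k = rss / (nj - 2.0) / Sxx
        t2 = np.where(var_k > 0, k * k / var_k, 0.0)
        var_pct = np.where(Syy > 0, 100.0 * Sxy * Sxy / (Sxx * Syy), 0.0)

    mm = g.markers
    results: List[AssocResult] = []
    for j in range(g.n_markers):
        ok = nj[j] >= 3 and np.isfinite(Sxx[j]) and Sxx[j] > 1e-12
        results.append(AssocResult(
            marker_id=str(mm.marker_id[j]),
            chromosome=str(mm.chromosome[j]),
            position_bp=int(mm.position_bp[j]),
            n_used=int(nj[j]),
            k_hat=float(k[j]) if ok else np.nan,
            var_k=float(var_k[j]) if ok else np.nan,
            T2=float(t2[j]) if ok else np.nan,
            var_pct=float(var_pct[j]) if ok else np.nan,
            tested=bool(ok),
        ))
    return results


def variance_explained(result: AssocResult) -> float:
    """Percent of residual-trait variance explained by the marker (R^2)."""
    return float(result.var_pct)


# ---------------------------------------------------------------------------
# Step 3: genomic control
# ---------------------------------------------------------------------------

def genomic_control(
    results: Sequence[AssocResult],
    gc_constant: float = CHI2_1_MEDIAN_PRINTED,
) -> List[AssocResult]:
    """Divide every T2 by lambda = median(T2)/constant; P from chi2(1).

    ``lambda`` is applied as estimated (no clamping at 1).  Raises on a
    degenerate scan where the median statistic is zero.
    """
    tested = [r for r in results if r.tested]
    if not tested:
        raise ValueError("no tested markers")
    med = float(np.median([r.T2 for r in tested]))
    lam = med / gc_constant
    if lam <= 0:
        raise ValueError("degenerate scan: median T2 is zero")
    out = []
    for r in results:
        if r.tested:
            t2a = r.T2 / lam
            out.append(replace(
                r, lambda_gc=lam, T2_adj=float(t2a),
                P=float(stats.chi2.sf(t2a, 1)),
            ))
        else:
            out.append(replace(r, lambda_gc=lam))
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide P threshold: alpha divided by the number of tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# orchestration: full scan and conditional scan
# ---------------------------------------------------------------------------

def gwas_scan(
    pheno: PhenotypeTable,
    ped: Pedigree,
    g: GenotypeMatrix,
    spec: Optional[MixedModelSpec] = None,
    gc_constant: float = CHI2_1_MEDIAN_PRINTED,
) -> Tuple[GrammarResiduals, List[AssocResult]]:
    """Steps 1-3 in sequence on the phenotyped individuals."""
    resid = fit_polygenic(pheno, ped, spec)
    results = residual_scan(resid, g)
    return resid, genomic_control(results, gc_constant=gc_constant)


def conditional_scan(
    pheno: PhenotypeTable,
    ped: Pedigree,
    spec: Optional[MixedModelSpec],
    g: GenotypeMatrix,
    top_marker: str,
    gc_constant: float = CHI2_1_MEDIAN_PRINTED,
) -> Tuple[GrammarResiduals, List[AssocResult]]:
    """Re-run the whole procedure with ``top_marker`` as a fixed covariate.

    Individuals missing the conditioning genotype are dropped; the marker
    itself is excluded from the rescan.  Raises if the conditioning marker
    is monomorphic.
    """
    spec = spec or MixedModelSpec()
    j = g.markers.index_of(top_marker)
    dose = {iid: g.dosage[i, j] for i, iid in enumerate(g.individual_ids)}
    avail = [i for i in pheno.ids if i in dose and not np.isnan(dose[i])]
    vals = np.asarray([dose[i] for i in avail])
    if len(np.unique(vals)) < 2:
        raise ValueError(f"conditioning marker {top_marker!r} is monomorphic")
    sub = PhenotypeTable(
        pheno.table[pheno.table["id"].isin(avail)].reset_index(drop=True)
    )
    spec2 = replace(
        spec,
        extra_covariates={**spec.extra_covariates, f"geno[{top_marker}]": dose},
    )
    resid = fit_polygenic(sub, ped, spec2)
    keep = [jj for jj in range(g.n_markers) if jj != j]
    results = residual_scan(resid, g.subset(markers=keep))
    return resid, genomic_control(results, gc_constant=gc_constant)


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def results_to_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "marker": [r.marker_id for r in results],
        "chr": [r.chromosome for r in results],
        "pos": [r.position_bp for r in results],
        "effect": [r.k_hat for r in results],
        "se": [r.se for r in results],
        "T2": [r.T2 for r in results],
        "T2_gc": [r.T2_adj for r in results],
        "P": [r.P for r in results],
        "var_pct": [r.var_pct for r in results],
    })


def manhattan_table(results: Sequence[AssocResult]) -> pd.DataFrame:
    """Per-marker (chr, pos, -log10 P) coordinates for a Manhattan plot."""
    rs = [r for r in results if r.tested and r.P is not None]
    return pd.DataFrame({
        "chr": [r.chromosome for r in rs],
        "pos": [r.position_bp for r in rs],
        "neglog10_p": [-np.log10(max(r.P, 1e-300)) for r in rs],
    })


def qq_table(results: Sequence[AssocResult]) -> pd.DataFrame:
    """Expected vs observed -log10 P quantiles."""
    ps = np.sort([r.P for r in results if r.tested and r.P is not None])
    k = len(ps)
    expected = (np.arange(1, k + 1) - 0.5) / k
    return pd.DataFrame({
        "expected_neglog10_p": -np.log10(expected),
        "observed_neglog10_p": -np.log10(np.maximum(ps, 1e-300)),
    })
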
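"""End-to-end orchestration: QC -> GWAS -> conditional -> MASS ->
haplotypes -> sweep, plus a toy nearest-feature annotator and loaders for
the reported significant-SNP tables shipped with the package.

The pipeline is driven by a ``RunConfig`` (YAML-serializable).  One master
seed derives per-stage seeds by fixed offsets, so a run is deterministic
given its configuration.  The refinement logic mirrors the fine-mapping
narrative: the significant-SNP span is successively intersected with the
founder haplotype-sharing segments, the haplotype-block region and the
selective-sweep interval; an empty intersection at any stage leaves the
previous interval standing (recorded in the report).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import grammar, haplotypes, mass, qc, sweep
from .formats import (
    GenotypeMatrix, MarkerMap, Pedigree, PhenotypeTable,
    read_genotypes, read_pedigree, read_phenotypes, write_results,
)
from .grammar import bonferroni_threshold, results_to_frame
from .simdata import SimConfig, SweepSimConfig, plant_shared_haplotype, simulate_cross, simulate_breed_panels

__all__ = [
    "RunConfig",
    "run_pipeline",
    "annotate_nearest",
    "load_reported_snps",
    "significant_span",
]

log = logging.getLogger("earmap")

STAGE_SEED_OFFSETS = {
    "simulate": 0, "qc": 101, "gwas": 202, "conditional": 303,
    "mass": 404, "haplotypes": 505, "sweep": 606,
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: Optional[str] = None
    data: str = "simulate"                      # "simulate" or "files"
    genotype_ped: Optional[str] = None
    genotype_map: Optional[str] = None
    pedigree_csv: Optional[str] = None
    phenotype_csv: Optional[str] = None
    stages: Dict[str, bool] = field(default_factory=lambda: {
        "qc": True, "gwas": True, "conditional": True,
        "mass": True, "haplotypes": True, "sweep": True,
    })
    alpha: float = 0.01
    gc_constant: float = grammar.CHI2_1_MEDIAN_PRINTED
    qc_thresholds: Dict[str, float] = field(default_factory=lambda: {
        "snp_call": 0.90, "maf": 0.03, "hwe": 1e-6, "sample_call": 0.90,
    })
    min_run: int = 4
    mass_window: int = 11
    shared_interval_halfwidth: int = 5
    #: pipeline-level simulated design: a 5-chromosome genome (QTL mid-way
    #: along the first chromosome, labelled "5") so that genomic control and
    #: genome-wide thresholds see a mostly unlinked marker background, as in
    #: a real whole-genome scan
    sim: Dict[str, object] = field(default_factory=lambda: {
        "n_chromosomes": 5, "n_markers": 300, "qtl_marker_index": 30,
    })
    sweep_sim: Dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(getattr(cfg, k), dict) and isinstance(v, dict):
                getattr(cfg, k).update(v)
            else:
                setattr(cfg, k, v)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not any(self.stages.values()):
            raise ValueError("all stages disabled; nothing to run")
        if self.data not in ("simulate", "files"):
            raise ValueError("data must be 'simulate' or 'files'")
        if self.data == "files":
            for name in ("genotype_ped", "genotype_map", "pedigree_csv",
                         "phenotype_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"input file for {name!r} not found: {p}")


def significant_span(
    results: Sequence[grammar.AssocResult], threshold: float,
    chromosome: Optional[str] = None,
) -> Tuple[List[grammar.AssocResult], Optional[Tuple[int, int]]]:
    """Markers below the P threshold (optionally one chromosome) + bp span."""
    sig = [
        r for r in results
        if r.tested and r.P is not None and r.P < threshold
        and (chromosome is None or r.chromosome == chromosome)
    ]
    if not sig:
        return [], None
    pos = [r.position_bp for r in sig]
    return sig, (min(pos), max(pos))


def _intersect_or_keep(current, candidate):
    """Intersect two interval lists, keeping ``current`` when empty."""
    if not candidate:
        return current, False
    merged = haplotypes.intersect_intervals(current, candidate)
    if merged:
        return merged, True
    return current, False


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the enabled stages in order; return a JSON-able report."""
    config.validate()
    t0 = time.time()
    report: Dict = {"seed": config.seed, "stages_run": []}
    rng_seed = int(config.seed) % (2 ** 31 - 1)

    # --- inputs ------------------------------------------------------------
    truth = None
    if config.data == "simulate":
        sim_cfg = SimConfig(**{"seed": rng_seed, **config.sim})
        g, ped, pheno, truth = simulate_cross(sim_cfg)
        if sim_cfg.qtl_marker_index is not None and config.shared_interval_halfwidth:
            lo = max(0, sim_cfg.qtl_marker_index - config.shared_interval_halfwidth)
            hi = min(sim_cfg.n_markers - 1,
                     sim_cfg.qtl_marker_index + config.shared_interval_halfwidth)
            truth = plant_shared_haplotype(truth, (lo, hi))
            g = truth.to_genotype_matrix()
        report["true_qtl_marker"] = (
            None if truth.qtl_marker_index is None
            else str(truth.markers.marker_id[truth.qtl_marker_index])
        )
        report["true_qtl_pos"] = (
            None if truth.qtl_marker_index is None
            else int(truth.markers.position_bp[truth.qtl_marker_index])
        )
    else:
        g = read_genotypes(config.genotype_ped, config.genotype_map)
        ped = read_pedigree(config.pedigree_csv)
        pheno = read_phenotypes(config.phenotype_csv)
    pheno.check_against_pedigree(ped)
    log.info("inputs: %d individuals x %d markers, %d phenotyped",
             g.n_individuals, g.n_markers, len(pheno))

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        enabled = config.stages.get(name, False)
        if enabled:
            report["stages_run"].append(name)
        return enabled

    # --- QC ----------------------------------------------------------------
    if _stage("qc"):
        t = time.time()
        thresholds = qc.QcThresholds(**config.qc_thresholds)
        g, qc_report = qc.iterative_qc(g, thresholds)
        report["qc"] = {
            "n_markers_in": qc_report.n_markers_in,
            "n_markers_out": qc_report.n_markers_out,
            "n_samples_in": qc_report.n_samples_in,
            "n_samples_out": qc_report.n_samples_out,
            "n_iterations": qc_report.n_iterations,
            "excluded_by_reason": qc_report.counts_by_reason(),
        }
        surviving = set(g.individual_ids)
        pheno = PhenotypeTable(
            pheno.table[pheno.table["id"].isin(surviving)].reset_index(drop=True)
        )
        log.info("qc: %d markers, %d samples survive (%.1fs)",
                 g.n_markers, g.n_individuals, time.time() - t)

    results = None
    resid = None
    top = None
    refined: List[Tuple[float, float]] = []
    threshold = None

    # --- GWAS --------------------------------------------------------------
    if _stage("gwas"):
        t = time.time()
        resid, results = grammar.gwas_scan(
            pheno, ped, g, gc_constant=config.gc_constant
        )
        n_tested = sum(1 for r in results if r.tested)
        threshold = bonferroni_threshold(config.alpha, n_tested)
        sig_all, _ = significant_span(results, threshold)
        top = min(
            (r for r in results if r.tested), key=lambda r: r.P, default=None
        )
        top_chrom = top.chromosome if top else None
        sig_chrom, span = significant_span(results, threshold, top_chrom)
        report["gwas"] = {
            "n_tested": n_tested,
            "lambda_gc": results[0].lambda_gc if results else None,
            "threshold": threshold,
            "n_significant": len(sig_all),
            "top_marker": top.marker_id if top else None,
            "top_chromosome": top_chrom,
            "top_p": top.P if top else None,
            "significant_span": list(span) if span else None,
            "variance_components": {
                "sigma2_a": resid.sigma2_a, "sigma2_c": resid.sigma2_c,
                "sigma2_e": resid.sigma2_e,
            },
        }
        if span:
            refined = [tuple(span)]
        if outdir:
            write_results(results_to_frame(results), outdir / "gwas_results.tsv")
            grammar.manhattan_table(results).to_csv(
                outdir / "manhattan.tsv", sep="\t", index=False)
            grammar.qq_table(results).to_csv(
                outdir / "qq.tsv", sep="\t", index=False)
        log.info("gwas: %d/%d significant, top=%s (%.1fs)",
                 len(sig_all), n_tested, top.marker_id if top else None,
                 time.time() - t)

    # --- conditional -------------------------------------------------------
    if _stage("conditional"):
        if top is None:
            raise RuntimeError("conditional stage requires a completed GWAS stage")
        t = time.time()
        _, cond_results = grammar.conditional_scan(
            pheno, ped, None, g, top.marker_id, gc_constant=config.gc_constant
        )
        cond_sig, _ = significant_span(cond_results, threshold)
        by_chrom: Dict[str, int] = {}
        for r in cond_sig:
            by_chrom[r.chromosome] = by_chrom.get(r.chromosome, 0) + 1
        report["conditional"] = {
            "conditioned_on": top.marker_id,
            "n_significant": len(cond_sig),
            "n_significant_by_chromosome": by_chrom,
            "n_significant_on_top_chromosome": by_chrom.get(top.chromosome, 0),
        }
        if outdir:
            write_results(results_to_frame(cond_results),
                          outdir / "conditional_results.tsv")
        log.info("conditional: %d significant after conditioning (%.1fs)",
                 len(cond_sig), time.time() - t)

    # --- MASS --------------------------------------------------------------
    if _stage("mass"):
        if top is None or resid is None:
            raise RuntimeError("mass stage requires a completed GWAS stage")
        if truth is None and g.phase is None:
            raise RuntimeError("mass stage requires phased sire genotypes")
        t = time.time()
        mm = g.markers
        chrom_idx = [
            j for j in range(mm.n_markers) if mm.chromosome[j] == top.chromosome
        ]
        top_j = mm.index_of(top.marker_id)
        chrom_idx.sort(key=lambda j: abs(j - top_j))
        window = sorted(chrom_idx[:config.mass_window])
        window_ids = [str(mm.marker_id[j]) for j in window]
        trait = dict(zip(pheno.table["id"], pheno.table["ear_area"]))
        litter_of = dict(zip(pheno.table["id"], pheno.table["litter_id"]))
        phase_rows = {iid: i for i, iid in enumerate(g.individual_ids)}
        sires = [
            r.id for r in ped.table.itertuples()
            if r.generation == "F1" and len(ped.offspring_of_sire(r.id)) > 0
        ]
        sire_results = []
        for sid in sires:
            if truth is not None:
                cols_truth = [truth.markers.index_of(m) for m in window_ids]
                phase = truth.hap_alleles[
                    truth.individual_ids.index(sid)][:, cols_truth]
            else:
                phase = g.phase[phase_rows[sid]]
            dam_lookup = {}
            for off in ped.offspring_of_sire(sid):
                dam = ped.parents(off)[1]
                if dam in phase_rows:
                    dam_lookup[off] = g.dosage[phase_rows[dam]][window]
            try:
                res = mass.sire_mass(
                    sid, np.asarray(phase), g, ped, trait, window_ids,
                    dam_lookup, litter_of=litter_of,
                )
            except ValueError:
                continue
            sire_results.append(res)
        calls = [r.classification for r in sire_results]
        report["mass"] = {
            "window_markers": window_ids,
            "n_sires_tested": len(sire_results),
            "n_qq_het": calls.count(mass.QQ_HET),
            "n_homozygous": calls.count(mass.HOMOZYGOUS),
            "n_undetermined": calls.count(mass.UNDETERMINED),
            "sires": {
                r.sire_id: {
                    "z": None if r.z is None else round(float(r.z), 4),
                    "n1": r.n1, "n2": r.n2, "call": r.classification,
                } for r in sire_results
            },
        }
        if outdir:
            pd.DataFrame([{
                "sire": r.sire_id, "n1": r.n1, "n2": r.n2,
                "mean1": r.mean1, "mean2": r.mean2,
                "se1": r.se1, "se2": r.se2,
                "Z": r.z, "call": r.classification,
            } for r in sire_results]).to_csv(
                outdir / "mass_report.tsv", sep="\t", index=False)
        log.info("mass: %d sires, %d Qq (%.1fs)", len(sire_results),
                 calls.count(mass.QQ_HET), time.time() - t)

    # --- haplotypes: blocks, hap-scores, sharing ---------------------------
    if _stage("haplotypes"):
        if results is None or top is None:
            raise RuntimeError("haplotypes stage requires a completed GWAS stage")
        t = time.time()
        sig_chrom, span = significant_span(results, threshold, top.chromosome)
        hap_rep: Dict = {"n_significant_markers": len(sig_chrom)}
        if len(sig_chrom) >= 2:
            sig_ids = [r.marker_id for r in sig_chrom]
            f2_rows = [i for i, iid in enumerate(g.individual_ids)
                       if iid in set(pheno.ids)]
            g_f2 = g.subset(individuals=f2_rows)
            blocks = haplotypes.detect_blocks(g_f2, sig_ids)
            hap_rep["blocks"] = [{
                "first": b.first_marker, "last": b.last_marker,
                "n_markers": len(b.marker_ids), "span_bp": b.span_bp,
            } for b in blocks]
            trait = dict(zip(resid.ids, resid.y_star))
            scores = []
            for b in blocks:
                window = b.marker_ids[:haplotypes.MAX_WINDOW]
                try:
                    sc = haplotypes.hap_score_test(g_f2, window, trait)
                except ValueError:
                    continue
                scores.append({
                    "block": f"{b.first_marker}..{b.last_marker}",
                    "global_stat": round(sc.global_stat, 4),
                    "df": sc.df, "global_p": sc.global_p,
                })
            hap_rep["block_scores"] = scores
            block_iv = [
                (float(mm_pos_lo), float(mm_pos_hi))
                for mm_pos_lo, mm_pos_hi in (
                    (g.markers.position_bp[g.markers.index_of(b.first_marker)],
                     g.markers.position_bp[g.markers.index_of(b.last_marker)])
                    for b in blocks
                )
            ]
            shared_iv = []
            if truth is not None:
                q_haps = truth.q_bearing_haplotypes()
                cols = [truth.markers.index_of(m) for m in sig_ids]
                sub_map = truth.markers.subset(cols)
                segs = [
                    s for s in haplotypes.shared_segments(q_haps[:, cols], sub_map)
                    if s.n_markers >= 2
                ]
                hap_rep["shared_segments"] = [{
                    "first": s.first_marker, "last": s.last_marker,
                    "n_markers": s.n_markers, "bp_length": s.bp_length,
                } for s in segs]
                shared_iv = [
                    (float(sub_map.position_bp[s.first_index]),
                     float(sub_map.position_bp[s.last_index])) for s in segs
                ]
            refined, used_sharing = _intersect_or_keep(refined, shared_iv)
            refined, used_blocks = _intersect_or_keep(refined, block_iv)
            hap_rep["used_sharing"] = used_sharing
            hap_rep["used_blocks"] = used_blocks
            hap_rep["refined_intervals"] = [list(iv) for iv in refined]
        report["haplotypes"] = hap_rep
        log.info("haplotypes: %s (%.1fs)", hap_rep.get("refined_intervals"),
                 time.time() - t)

    # --- sweep -------------------------------------------------------------
    if _stage("sweep"):
        t = time.time()
        sweep_kwargs = dict(config.sweep_sim)
        if config.data == "simulate" and top is not None and "run" not in sweep_kwargs:
            # centre the default breed-panel region on the association peak
            halfwidth = 1_000_000
            sweep_kwargs.setdefault("region_start_bp", int(top.position_bp - halfwidth))
            sweep_kwargs.setdefault("region_end_bp", int(top.position_bp + halfwidth))
            sweep_kwargs.setdefault("chromosome", top.chromosome)
            sweep_kwargs.setdefault("n_markers", 20)
            sweep_kwargs.setdefault("run", (7, 12))
        sw_cfg = SweepSimConfig(**{
            "seed": rng_seed + STAGE_SEED_OFFSETS["sweep"], **sweep_kwargs})
        panels = simulate_breed_panels(sw_cfg)
        case = sweep.BreedPanel(sw_cfg.case_breed, panels[sw_cfg.case_breed])
        controls = [
            sweep.BreedPanel(b, p) for b, p in panels.items()
            if b != sw_cfg.case_breed
        ]
        intervals = sweep.detect_sweep(case, controls, min_run=config.min_run)
        report["sweep"] = {
            "case_breed": sw_cfg.case_breed,
            "intervals": [{
                "n_run_markers": iv.n_run_markers,
                "left_flank": iv.left_flank, "right_flank": iv.right_flank,
                "bp_length": iv.bp_length,
            } for iv in intervals],
        }
        sweep_iv = []
        mmn = sw_cfg.marker_map()
        for iv in intervals:
            lo = mmn.position_bp[mmn.index_of(iv.left_flank)] if iv.left_flank else mmn.position_bp[iv.first_index]
            hi = mmn.position_bp[mmn.index_of(iv.right_flank)] if iv.right_flank else mmn.position_bp[iv.last_index]
            sweep_iv.append((float(lo), float(hi)))
        refined, used_sweep = _intersect_or_keep(refined, sweep_iv)
        report["sweep"]["used_in_refinement"] = used_sweep
        if outdir:
            sweep.heterozygosity_table([case] + controls).to_csv(
                outdir / "sweep_heterozygosity.tsv", sep="\t", index=False)
        log.info("sweep: %d interval(s) (%.1fs)", len(intervals), time.time() - t)

    report["refined_intervals"] = [list(iv) for iv in refined]
    log.info("pipeline done in %.1fs", time.time() - t0)

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# toy nearest-feature annotation
# ---------------------------------------------------------------------------

def annotate_nearest(markers: MarkerMap, bed_path) -> pd.DataFrame:
    """Annotate markers with the nearest BED feature on their chromosome.

    A marker inside a feature reports ``within`` and distance 0; otherwise
    the bp distance to the nearest feature edge.  Markers on chromosomes
    without features are flagged ``none``.
    """
    feats = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "name": str},
        skip_blank_lines=True,
    ) if Path(bed_path).stat().st_size > 0 else pd.DataFrame(
        columns=["chrom", "start", "end", "name"])
    rows = []
    for j in range(markers.n_markers):
        chrom = str(markers.chromosome[j])
        pos = int(markers.position_bp[j])
        sub = feats[feats["chrom"] == chrom]
        if len(sub) == 0:
            rows.append({
                "marker": str(markers.marker_id[j]), "chr": chrom, "pos": pos,
                "feature": None, "distance": None, "location": "none",
            })
            continue
        start1 = sub["start"].astype(int) + 1   # BED is 0-based half-open
        end1 = sub["end"].astype(int)
        inside = (pos >= start1) & (pos <= end1)
        if inside.any():
            name = sub.loc[inside.idxmax(), "name"]
            rows.append({
                "marker": str(markers.marker_id[j]), "chr": chrom, "pos": pos,
                "feature": name, "distance": 0, "location": "within",
            })
        else:
            dist = np.minimum(np.abs(start1 - pos), np.abs(pos - end1))
            k = dist.idxmin()
            rows.append({
                "marker": str(markers.marker_id[j]), "chr": chrom, "pos": pos,
                "feature": sub.loc[k, "name"], "distance": int(dist.loc[k]),
                "location": "flanking",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reported significant-SNP tables (shipped package data)
# ---------------------------------------------------------------------------

_REPORTED = {
    "ssc5": "ssc5_significant_snps.tsv",
    "ssc7_conditional": "ssc7_conditional_snps.tsv",
}


def load_reported_snps(which: str = "ssc5") -> pd.DataFrame:
    """Load a reported genome-wide-significant SNP table (ear-size scan).

    ``which`` is ``"ssc5"`` (primary scan) or ``"ssc7_conditional"``
    (conditional analysis).  Columns: marker, chr, pos, nearest_gene,
    distance, P, var_pct.
    """
    try:
        fname = _REPORTED[which]
    except KeyError:
        raise ValueError(f"unknown table {which!r}; choose from {sorted(_REPORTED)}")
    ref = importlib.resources.files("earmap.data").joinpath(fname)
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["P"] = df["P"].astype(float)
    return df


def reported_marker_map(which: str = "ssc5") -> MarkerMap:
    """MarkerMap over a reported SNP table (synthetic A/G allele labels)."""
    df = load_reported_snps(which)
    n = len(df)
    return MarkerMap(
        df["marker"].tolist(), df["chr"].astype(str).tolist(),
        df["pos"].tolist(), ["A"] * n, ["G"] * n,
    )
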
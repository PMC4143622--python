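"""End-to-end pipeline: trajectory fits -> derived trait -> association ->
replicate-set power, with all intermediate tables written to disk.

One run executes a single analysis arm — population-based (Wald
regression + FDR on the unrelated cohort) or family-based (within-family
permutation regression and/or TDT on the pedigrees) — with or without
covariates in the trajectory model, mirroring the four discrete analyses
of the study design. Condition comparisons (covariates vs. none) are made
by running the pipeline twice and calling
:func:`trajmap.power.compare_conditions` on the per-gene power vectors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from .genotypes import GenotypeData, read_ped_map
from .longdata import read_long_phenotypes
from .phenotype import extract_trait, pick_relevant_subgroup
from .power import (
    PowerReport,
    build_replicate_sets,
    per_gene_power,
    read_regions_bed,
)
from .trajectory import GroupTrajectoryResults, select_model

__all__ = ["PipelineConfig", "run_pipeline", "write_model_report", "write_bpp_table"]

log = logging.getLogger("trajmap")

POP_THRESHOLDS = [1.0, 5.0, 10.0]       # top x%
FAM_THRESHOLDS = [0.001, 0.01, 0.05]    # alpha


@dataclass
class PipelineConfig:
    """Paths, analysis arm and tuning knobs for one pipeline run."""

    phenotype_paths: list
    ped_path: str
    map_path: str
    bed_path: str
    outdir: str
    arm: str = "population"              # "population" | "family"
    use_covariates: bool = False
    family_test: str = "qfam"            # "qfam" | "tdt"
    k_max: int = 6
    alpha_prune: float = 0.05
    n_restarts: int = 3
    n_sets: int = 100
    set_size: int = 3
    n_perm: int = 999
    thresholds: list[float] = field(default_factory=list)
    criterion: str = ""                  # "top_percent" | "alpha"; default by arm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("population", "family"):
            raise ValueError("arm must be 'population' or 'family'")
        if self.family_test not in ("qfam", "tdt"):
            raise ValueError("family_test must be 'qfam' or 'tdt'")
        if not self.criterion:
            self.criterion = "top_percent" if self.arm == "population" else "alpha"
        if self.criterion not in ("top_percent", "alpha"):
            raise ValueError("criterion must be 'top_percent' or 'alpha'")
        if not self.thresholds:
            self.thresholds = (
                list(POP_THRESHOLDS)
                if self.criterion == "top_percent"
                else list(FAM_THRESHOLDS)
            )

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items() if k != "outdir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _subset_genotypes(geno: GenotypeData, rows: np.ndarray) -> GenotypeData:
    return GenotypeData(
        snp_ids=geno.snp_ids,
        chrom=geno.chrom,
        pos=geno.pos,
        alleles=geno.alleles,
        dosage=geno.dosage[rows],
        pedigree=geno.pedigree.iloc[rows].reset_index(drop=True),
        pheno=None if geno.pheno is None else geno.pheno[rows],
    )


def _cohort_rows(geno: GenotypeData, arm: str) -> np.ndarray:
    """Population arm: singleton-family founders (the unrelated subset);
    family arm: members of multi-person families."""
    sizes = geno.pedigree.groupby("FID")["IID"].transform("size").to_numpy()
    return np.flatnonzero(sizes == 1) if arm == "population" else np.flatnonzero(sizes > 1)


def write_model_report(fits: dict[int, GroupTrajectoryResults], selected_k: int,
                       path) -> None:
    """JSON report: per-k loglik/BIC/orders and the selected model's
    parameters."""
    best = fits[selected_k]
    report = {
        "selected_k": selected_k,
        "per_k": {
            str(k): {"loglik": f.loglik, "bic": f.bic, "orders": f.spec.orders,
                     "converged": f.converged}
            for k, f in fits.items()
        },
        "selected": {
            "orders": best.spec.orders,
            "pi": best.pi.tolist(),
            "sigma": np.atleast_1d(best.sigma).tolist(),
            "beta": [b.tolist() for b in best.beta],
            "gamma": np.asarray(best.gamma).tolist(),
            "loglik": best.loglik,
            "bic": best.bic,
            "n_params": best.n_params,
        },
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def write_bpp_table(result: GroupTrajectoryResults, path) -> None:
    """TSV with FID, IID, BPP_1..BPP_k and the modal subgroup (1-based)."""
    data = result.model.data
    cols = {"FID": data.family_ids, "IID": data.individual_ids}
    for j in range(result.spec.k):
        cols[f"BPP_{j + 1}"] = result.bpp[:, j]
    cols["assigned_group"] = result.assigned_group + 1
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _analyze_replicate(rep_id: int, pheno_path, geno: GenotypeData,
                       cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    data = read_long_phenotypes(pheno_path)
    seed = (cfg.seed * 100_003 + rep_id) % (2**31 - 1)
    fit = select_model(
        data,
        k_max=cfg.k_max,
        use_covariates=cfg.use_covariates,
        alpha=cfg.alpha_prune,
        n_restarts=cfg.n_restarts,
        seed=seed,
    )
    t_last = float(np.max(data.times[data.mask]))
    group = pick_relevant_subgroup(fit, t_last)
    pheno = extract_trait(fit, group)
    write_bpp_table(fit, outdir / f"bpp_rep{rep_id}.tsv")

    # align trait with genotype rows
    trait_q = np.full(geno.n_individuals, np.nan)
    trait_b = np.full(geno.n_individuals, np.nan)
    row_of = geno.row_index()
    for fid, iid, q, b in zip(
        pheno.family_ids, pheno.individual_ids, pheno.bpp_trait, pheno.binary_trait
    ):
        r = row_of.get((fid, iid))
        if r is not None:
            trait_q[r] = q
            trait_b[r] = b

    if cfg.arm == "population":
        tab = assoc_mod.wald_qt_scan(trait_q, geno)
    elif cfg.family_test == "qfam":
        tab = assoc_mod.qfam_perm_scan(trait_q, geno, n_perm=cfg.n_perm,
                                       seed=seed + 1)
        tab["P_ASYMPTOTIC"] = tab["P"]
        tab["P"] = tab["EMP_P"]
    else:
        if not np.nansum(trait_b == 1):
            raise RuntimeError(
                f"[tdt stage] replicate {rep_id}: no affected offspring after "
                f"dichotomization"
            )
        tab = assoc_mod.tdt_scan(trait_b, geno)
        tab["CORR_P"] = assoc_mod.perm_correct_family(tab, n_perm=cfg.n_perm,
                                                      seed=seed + 1)
    assoc_mod.write_association(tab, outdir / f"assoc_rep{rep_id}.tsv")
    log.info("replicate %d: k=%d group=%d snps=%d", rep_id, fit.spec.k,
             group + 1, len(tab))
    tab.attrs["selected_k"] = fit.spec.k
    tab.attrs["fast_group_share"] = float(np.mean(pheno.binary_trait))
    return tab


def run_pipeline(cfg: PipelineConfig) -> PowerReport:
    """Execute one analysis arm end to end; deterministic under cfg.seed.

    Per replicate: trajectory model selection, relevant-subgroup trait
    extraction, and the arm's association scan; then replicate sets are
    drawn and per-gene/total power and null-region rates computed at each
    threshold. All intermediate tables are written under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: arm=%s covariates=%s seed=%d config=%s",
             cfg.arm, cfg.use_covariates, cfg.seed, cfg.digest())
    geno_all = read_ped_map(cfg.ped_path, cfg.map_path)
    rows = _cohort_rows(geno_all, cfg.arm)
    if len(rows) == 0:
        raise RuntimeError(f"[cohort stage] no individuals for arm {cfg.arm!r}")
    geno = _subset_genotypes(geno_all, rows)
    regions = read_regions_bed(cfg.bed_path)
    log.info("cohort: %d individuals, %d SNPs, %d regions",
             geno.n_individuals, geno.n_snps, len(regions))

    tables: dict[int, pd.DataFrame] = {}
    for rep_id, path in enumerate(cfg.phenotype_paths, start=1):
        try:
            tables[rep_id] = _analyze_replicate(rep_id, path, geno, cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"[replicate {rep_id} stage] {exc}") from exc

    sets = build_replicate_sets(
        n_pool=len(cfg.phenotype_paths), n_sets=cfg.n_sets,
        set_size=cfg.set_size, seed=cfg.seed,
    )
    kind = cfg.criterion
    report = PowerReport(criterion_kind=kind, thresholds=list(cfg.thresholds))
    for th in cfg.thresholds:
        report.per_gene[th] = per_gene_power(sets, tables, regions, (kind, th))
    report.meta = {
        "arm": cfg.arm,
        "use_covariates": cfg.use_covariates,
        "family_test": cfg.family_test if cfg.arm == "family" else None,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "n_replicates": len(cfg.phenotype_paths),
        "n_sets": cfg.n_sets,
        "selected_k": {r: int(t.attrs["selected_k"]) for r, t in tables.items()},
        "fast_group_share": {r: t.attrs["fast_group_share"] for r, t in tables.items()},
    }
    report.to_json(outdir / "power_report.json")
    report.to_tsv(outdir / "power_per_gene.tsv")
    log.info("pipeline done: total power %s",
             {th: report.total_power(th) for th in cfg.thresholds})
    return report
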
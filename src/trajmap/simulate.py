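"""GAW18-like synthetic cohorts: pedigrees, genotypes and replicate phenotypes.

The generator emulates the shape of the study data this method targets:
systolic blood pressure (SBP, mmHg) measured at 3 visits on ~850
individuals from 20 extended three-generation pedigrees plus an unrelated
subset of 157, with 200 phenotype replicates over one fixed set of
genotypes. Founder genotypes are drawn at linkage equilibrium and
propagated by gene-dropping, so the genotypes are Mendelian-consistent by
construction and identical across replicates; phenotypes are re-simulated
per replicate from a trajectory-mixture generative model with genetic and
covariate effects.

Genetic effects come in two modes. ``level-shift`` adds a per-allele mean
shift at every visit, scaled so the genetic term explains a target
fraction of the total trait variance (the headline causal gene mirrors a
~6%-of-variance effect). ``group-logit`` instead tilts the latent
subgroup assignment: each causal allele adds to the log-odds of the
high-trajectory subgroup.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeData, write_ped_map
from .longdata import LongitudinalData, write_long_phenotypes
from .power import GeneRegion, write_regions_bed

__all__ = [
    "CausalGene",
    "SimConfig",
    "build_pedigree",
    "simulate_genotypes",
    "simulate_phenotype_replicate",
    "make_gaw18_like_bundle",
    "mendelian_error_count",
]

SNP_SPACING = 1_000  # bp between adjacent simulated SNPs
REGION_GAP_SNPS = 3  # buffer SNPs between regions


@dataclass
class CausalGene:
    """One causal gene region.

    ``ve`` is the target fraction of total trait variance explained by the
    gene's level shift (level-shift mode); ``logit_effect`` is the log-odds
    increment per causal allele on high-subgroup membership (group-logit
    mode). ``n_region_snps`` is the width of the region; ``n_causal`` of
    its central SNPs carry the effect.
    """

    name: str
    ve: float = 0.01
    n_region_snps: int = 5
    n_causal: int = 1
    mode: str = "level-shift"
    logit_effect: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.ve < 1:
            raise ValueError("ve must lie in [0, 1)")
        if self.mode not in ("level-shift", "group-logit"):
            raise ValueError("mode must be 'level-shift' or 'group-logit'")
        if self.n_causal > self.n_region_snps:
            raise ValueError("n_causal cannot exceed n_region_snps")


def _default_genes() -> list[CausalGene]:
    """15 causal genes: one MAP4-like headline effect (~6% of variance)
    and a tail of smaller effects."""
    ves = [0.06, 0.03, 0.025, 0.02, 0.02, 0.015, 0.015, 0.012,
           0.012, 0.01, 0.01, 0.008, 0.008, 0.006, 0.006]
    return [CausalGene(name=f"gene_{i + 1:02d}", ve=v) for i, v in enumerate(ves)]


@dataclass
class SimConfig:
    """Study-shaped simulation settings.

    Defaults mirror the target study design: 20 extended pedigrees
    (three generations, 42 members each, ~840 individuals), 157 unrelated
    individuals, 3 visits, 200 phenotype replicates, a 3-subgroup SBP-like
    trajectory truth whose high ("fast") subgroup holds ~9% of the
    population, shared residual SD 8 mmHg, 15 causal genes led by a
    6%-of-variance effect, and 3 null regions of varying size.
    """

    n_families: int = 20
    n_unrelated: int = 157
    n_visits: int = 3
    n_replicates: int = 200
    maf_range: tuple[float, float] = (0.1, 0.5)
    causal_genes: list[CausalGene] = field(default_factory=_default_genes)
    null_region_sizes: tuple[int, ...] = (5, 10, 20)
    chrom: str = "3"
    # trajectory truth: visit-index time coding 0, 1, 2
    k_true: int = 3
    beta_true: list[list[float]] = field(
        default_factory=lambda: [[112.0, 2.0], [128.0, 3.0], [150.0, 5.0]]
    )
    pi_true: tuple[float, ...] = (0.56, 0.35, 0.09)
    sigma_true: float = 8.0
    # covariate model (age years, medication/smoking 0-1, sex 0-1)
    gamma_age: float = 0.25
    gamma_meds: float = -8.0
    gamma_smoke: float = 4.0
    gamma_sex: float = 4.0
    baseline_age_mean: float = 50.0
    baseline_age_sd: float = 8.0
    visit_spacing: float = 5.0
    smoke_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2")
        if abs(sum(self.pi_true) - 1) > 1e-9 or any(p < 0 for p in self.pi_true):
            raise ValueError("pi_true must be a probability vector")
        if len(self.beta_true) != self.k_true or len(self.pi_true) != self.k_true:
            raise ValueError("beta_true and pi_true must have length k_true")
        total_ve = sum(g.ve for g in self.causal_genes if g.mode == "level-shift")
        if total_ve >= 1:
            raise ValueError("summed variance-explained targets must be < 1")

    # -- genome layout --------------------------------------------------
    def region_layout(self):
        """Assign SNP indices to gene and null regions, with buffers.

        Returns (n_snps, regions, causal_snp_indices) where ``regions`` is a
        list of GeneRegion and ``causal_snp_indices`` maps gene name to the
        SNP indices carrying its effect.
        """
        regions: list[GeneRegion] = []
        causal_idx: dict[str, list[int]] = {}
        cursor = REGION_GAP_SNPS
        blocks = [(g.name, g.n_region_snps, False, g) for g in self.causal_genes]
        blocks += [
            (f"null_{i + 1}", w, True, None)
            for i, w in enumerate(self.null_region_sizes)
        ]
        for name, width, is_null, gene in blocks:
            idx = list(range(cursor, cursor + width))
            start = (idx[0] + 1) * SNP_SPACING
            end = (idx[-1] + 1) * SNP_SPACING
            regions.append(
                GeneRegion(name=name, chrom=self.chrom, start=start, end=end,
                           is_null=is_null)
            )
            if gene is not None:
                mid = width // 2
                lo = mid - gene.n_causal // 2
                causal_idx[name] = [idx[lo + c] for c in range(gene.n_causal)]
            cursor += width + REGION_GAP_SNPS
        return cursor, regions, causal_idx

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["causal_genes"] = [CausalGene(**g) for g in d.get("causal_genes", [])]
        for key in ("maf_range", "null_region_sizes", "pi_true"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# pedigree and genotypes
# ---------------------------------------------------------------------------

def build_pedigree(config: SimConfig) -> pd.DataFrame:
    """Pedigree rows for all families plus the unrelated cohort.

    Each family follows a fixed three-generation template: a founder
    couple, five of their children each married to a founder spouse, and
    six grandchildren per couple (42 members). Unrelated individuals are
    singleton founders with FID "U<i>". Parents precede children in row
    order.
    """
    rows = []
    for f in range(1, config.n_families + 1):
        fid = f"F{f:03d}"

        def add(iid, pat, mat, sex):
            rows.append({"FID": fid, "IID": iid, "PAT": pat, "MAT": mat, "SEX": sex})

        add("g1_f", "0", "0", 1)
        add("g1_m", "0", "0", 2)
        for c in range(1, 6):
            sex = 1 if c % 2 else 2
            add(f"g2_{c}", "g1_f", "g1_m", sex)
            add(f"g2_{c}s", "0", "0", 2 if sex == 1 else 1)
            father = f"g2_{c}" if sex == 1 else f"g2_{c}s"
            mother = f"g2_{c}s" if sex == 1 else f"g2_{c}"
            for gc in range(1, 7):
                add(f"g3_{c}_{gc}", father, mother, 1 if gc % 2 else 2)
    for u in range(1, config.n_unrelated + 1):
        rows.append(
            {"FID": f"U{u:03d}", "IID": "1", "PAT": "0", "MAT": "0",
             "SEX": 1 if u % 2 else 2}
        )
    return pd.DataFrame(rows)


def simulate_genotypes(config: SimConfig) -> GenotypeData:
    """Founder genotypes at linkage equilibrium, gene-dropped through the
    pedigrees; the unrelated cohort is drawn as founders."""
    rng = np.random.default_rng(config.seed)
    ped = build_pedigree(config)
    n_snps, _, _ = config.region_layout()
    maf = rng.uniform(*config.maf_range, size=n_snps)
    n = len(ped)
    dosage = np.full((n, n_snps), np.nan)
    index = {(f, i): r for r, (f, i) in enumerate(zip(ped["FID"], ped["IID"]))}
    for r, row in enumerate(ped.itertuples(index=False)):
        if row.PAT == "0":
            dosage[r] = rng.binomial(2, maf)
        else:
            fa = dosage[index[(row.FID, row.PAT)]]
            mo = dosage[index[(row.FID, row.MAT)]]
            # each parent transmits the coded allele w.p. dosage/2
            dosage[r] = rng.binomial(1, fa / 2.0) + rng.binomial(1, mo / 2.0)
    snp_ids = np.array([f"snp_{s + 1:05d}" for s in range(n_snps)], dtype=object)
    pos = (np.arange(n_snps) + 1) * SNP_SPACING
    alleles = np.array([["A", "B"]] * n_snps, dtype=object)
    return GenotypeData(
        snp_ids=snp_ids,
        chrom=np.array([config.chrom] * n_snps, dtype=object),
        pos=pos,
        alleles=alleles,
        dosage=dosage,
        pedigree=ped,
    )


def mendelian_error_count(geno: GenotypeData) -> int:
    """Dosage-level Mendelian inconsistencies across all parent-offspring
    trios and SNPs (0 for gene-dropped data)."""
    from .association import extract_trios

    errors = 0
    for child, fa, mo in extract_trios(geno.pedigree):
        gc, gf, gm = geno.dosage[child], geno.dosage[fa], geno.dosage[mo]
        ok = np.isfinite(gc) & np.isfinite(gf) & np.isfinite(gm)
        h = (gf == 1).astype(int) + (gm == 1)
        f2 = (gf == 2).astype(int) + (gm == 2)
        x = gc - f2
        errors += int(np.sum(ok & ((x < 0) | (x > h))))
    return errors


# ---------------------------------------------------------------------------
# phenotype replicates
# ---------------------------------------------------------------------------

def _fixed_covariates(config: SimConfig, n: int):
    """Covariates held fixed across replicates (seeded from the config)."""
    rng = np.random.default_rng((config.seed, 0xC0F))
    age0 = rng.normal(config.baseline_age_mean, config.baseline_age_sd, size=n)
    ages = age0[:, None] + config.visit_spacing * np.arange(config.n_visits)[None, :]
    smoke = rng.binomial(1, config.smoke_prob, size=n).astype(float)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    return ages, smoke, sex


def simulate_phenotype_replicate(
    genotypes: GenotypeData, config: SimConfig, replicate_seed: int
) -> LongitudinalData:
    """One phenotype replicate over the fixed genotypes.

    Latent subgroup, medication and measurement noise are re-drawn per
    replicate; age, smoking and sex are fixed across replicates. Genetic
    level-shift effects are scaled so each gene's term explains its target
    fraction of the total per-observation trait variance.
    """
    rng = np.random.default_rng((config.seed, 0xFE0, replicate_seed))
    n = genotypes.n_individuals
    T = config.n_visits
    _, _, causal_idx = config.region_layout()
    genes = {g.name: g for g in config.causal_genes}

    # latent subgroup: multinomial logit, optionally tilted by causal dosage
    logits = np.log(np.asarray(config.pi_true))[None, :].repeat(n, axis=0)
    high = config.k_true - 1
    for name, snps in causal_idx.items():
        g = genes[name]
        if g.mode == "group-logit":
            dose = np.nansum(genotypes.dosage[:, snps], axis=1)
            logits[:, high] += g.logit_effect * dose
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    group = np.array([rng.choice(config.k_true, p=probs[i]) for i in range(n)])

    ages, smoke, sex = _fixed_covariates(config, n)
    is_high = (group == high).astype(float)
    p_med = np.clip(
        0.05 + 0.10 * np.arange(T)[None, :] + 0.40 * is_high[:, None], 0, 0.95
    )
    meds = rng.binomial(1, p_med).astype(float)

    visits = np.arange(T, dtype=float)
    base = np.zeros((n, T))
    for j in range(config.k_true):
        b = config.beta_true[j]
        traj = sum(b[d] * visits**d for d in range(len(b)))
        base[group == j] = traj
    base = (
        base
        + config.gamma_age * (ages - config.baseline_age_mean)
        + config.gamma_meds * meds
        + config.gamma_smoke * smoke[:, None]
        + config.gamma_sex * sex[:, None]
        + rng.normal(0, config.sigma_true, size=(n, T))
    )

    # genetic level shifts, scaled to target variance-explained fractions
    total_ve = sum(genes[nm].ve for nm in causal_idx if genes[nm].mode == "level-shift")
    v_base = float(np.var(base))
    shift = np.zeros(n)
    for name, snps in causal_idx.items():
        g = genes[name]
        if g.mode != "level-shift" or g.ve == 0:
            continue
        dose = np.nansum(genotypes.dosage[:, snps], axis=1)
        gc = dose - dose.mean()
        vg = float(np.var(gc))
        if vg == 0:
            raise ValueError(
                f"gene {name}: causal SNPs are monomorphic; attainable "
                f"variance-explained maximum is 0"
            )
        a = np.sqrt(g.ve / (1 - total_ve) * v_base / vg)
        shift += a * gc
    y = base + shift[:, None]

    times = np.tile(visits, (n, 1))
    return LongitudinalData(
        individual_ids=genotypes.individual_ids,
        family_ids=genotypes.family_ids,
        times=times,
        values=y,
        mask=np.ones((n, T), dtype=bool),
        covariates_tv={"AGE": ages, "MEDS": meds},
        covariates_ti={"SMOKE": smoke, "SEX": sex},
    )


def make_gaw18_like_bundle(config: SimConfig, outdir) -> dict:
    """Write a complete study-shaped bundle to ``outdir``.

    Produces genotypes.ped/.map, regions.bed, config.yaml and one
    phenotype TSV per replicate (pheno_rep<i>.tsv, 1-based). Returns a
    dict of the paths written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(config)
    ped_path, map_path = out / "genotypes.ped", out / "genotypes.map"
    write_ped_map(geno, ped_path, map_path)
    _, regions, _ = config.region_layout()
    bed_path = out / "regions.bed"
    write_regions_bed(regions, bed_path)
    config.to_yaml(out / "config.yaml")
    pheno_paths = []
    for r in range(1, config.n_replicates + 1):
        data = simulate_phenotype_replicate(geno, config, replicate_seed=r)
        p = out / f"pheno_rep{r}.tsv"
        write_long_phenotypes(data, p)
        pheno_paths.append(p)
    return {
        "ped": ped_path,
        "map": map_path,
        "bed": bed_path,
        "config": out / "config.yaml",
        "phenotypes": pheno_paths,
    }
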
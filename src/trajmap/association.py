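"""SNP association tests for the derived subgroup-membership trait.

Population arm: per-SNP simple linear (Wald) regression of the quantitative
trait on allele dosage, with Benjamini-Hochberg FDR across SNPs. Family
arm: the same regression statistic with an empirical p-value from
within-family trait permutation (family structure preserved), and a
transmission disequilibrium test (TDT) on the dichotomized trait; multiple
testing in the family arm is corrected by max-statistic permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeData

__all__ = [
    "wald_qt_test",
    "wald_qt_scan",
    "bh_fdr",
    "qfam_perm_test",
    "qfam_perm_scan",
    "tdt_test",
    "tdt_scan",
    "extract_trios",
    "perm_correct_family",
]


# ---------------------------------------------------------------------------
# population-based: Wald regression + FDR
# ---------------------------------------------------------------------------

def wald_qt_test(trait, dosage) -> dict:
    """Simple linear regression trait = a + b * dosage.

    Two-sided p from t = b/SE(b) on n-2 degrees of freedom; pairs with a
    missing trait or genotype are dropped. A monomorphic genotype yields
    p = NaN with a reason code rather than an error.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(dosage, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    n = len(y)
    if n < 3:
        raise ValueError(f"need >= 3 complete observations, got {n}")
    if np.ptp(x) == 0:
        return {"beta": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan,
                "n": n, "reason": "monomorphic"}
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    s2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(s2 / sxx)
    if se == 0:
        # perfect fit: infinite statistic, p underflows to 0-adjacent
        return {"beta": beta, "se": 0.0, "stat": np.inf, "p": np.finfo(float).tiny,
                "n": n, "reason": ""}
    t = beta / se
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return {"beta": beta, "se": se, "stat": t, "p": max(p, np.finfo(float).tiny),
            "n": n, "reason": ""}


def wald_qt_scan(trait, geno: GenotypeData) -> pd.DataFrame:
    """Wald regression across all SNPs, with BH q-values.

    Returns columns CHR, SNP, BP, BETA, SE, STAT, P, Q (Q is NaN where P is).
    """
    rows = []
    for s in range(geno.n_snps):
        try:
            r = wald_qt_test(trait, geno.dosage[:, s])
        except ValueError:
            r = {"beta": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan,
                 "n": 0, "reason": "too-few-observations"}
        rows.append(r)
    tab = pd.DataFrame(
        {
            "CHR": geno.chrom,
            "SNP": geno.snp_ids,
            "BP": geno.pos,
            "BETA": [r["beta"] for r in rows],
            "SE": [r["se"] for r in rows],
            "STAT": [r["stat"] for r in rows],
            "P": [r["p"] for r in rows],
        }
    )
    q = np.full(len(tab), np.nan)
    ok = tab["P"].notna().to_numpy()
    if ok.any():
        q[ok] = bh_fdr(tab.loc[ok, "P"].to_numpy())
    tab["Q"] = q
    return tab


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# family-based: within-family permutation regression
# ---------------------------------------------------------------------------

def _family_permutations(family_ids, n_perm: int, rng) -> np.ndarray:
    """(n_perm, N) index arrays, each shuffling positions within family."""
    fam = np.asarray(family_ids)
    n = len(fam)
    blocks = [np.flatnonzero(fam == f) for f in pd.unique(fam)]
    if all(len(b) == 1 for b in blocks):
        raise ValueError("all families have size 1; within-family permutation impossible")
    perms = np.tile(np.arange(n), (n_perm, 1))
    for b in blocks:
        if len(b) < 2:
            continue
        for r in range(n_perm):
            perms[r, b] = b[rng.permutation(len(b))]
    return perms


def _t_matrix(Y: np.ndarray, xc: np.ndarray, syy: np.ndarray | float, sxx: float,
              n: int) -> np.ndarray:
    """t statistics for rows of centered Y against one centered regressor."""
    sxy = Y @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy**2 / (sxx * syy)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        t = np.sign(sxy) * np.sqrt((n - 2) * r2 / (1 - r2))
    return t


def qfam_perm_test(trait, dosage, family_ids, n_perm: int = 999,
                   seed: int | None = None) -> dict:
    """Family-structure-respecting permutation test for one SNP.

    The observed statistic is the Wald t; the empirical p-value is
    ``(1 + #{permuted |t| >= observed |t|}) / (n_perm + 1)`` where each
    permutation shuffles trait values among individuals within each family.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = wald_qt_test(trait, dosage)
    if not np.isfinite(obs["stat"]):
        obs["emp_p"] = np.nan
        return obs
    y = np.asarray(trait, dtype=float)
    x = np.asarray(dosage, dtype=float)
    fam = np.asarray(family_ids)
    keep = np.isfinite(y)
    y, x, fam = y[keep], x[keep], fam[keep]
    rng = np.random.default_rng(seed)
    perms = _family_permutations(fam, n_perm, rng)
    valid = np.isfinite(x)
    xv = x[valid]
    xc = xv - xv.mean()
    sxx = float(xc @ xc)
    n = valid.sum()
    Y = y[perms][:, valid]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("bn,bn->b", Yc, Yc)
    t_perm = _t_matrix(Yc, xc, syy, sxx, n)
    exceed = np.sum(np.abs(t_perm) >= abs(obs["stat"]))
    obs["emp_p"] = (1 + exceed) / (n_perm + 1)
    return obs


def qfam_perm_scan(trait, geno: GenotypeData, n_perm: int = 999,
                   seed: int | None = None, max_stat: bool = True) -> pd.DataFrame:
    """Permutation regression across SNPs, sharing one set of within-family
    shuffles; optionally adds max-statistic multiplicity-corrected p-values.

    Columns: CHR, SNP, BP, BETA, SE, STAT, P, EMP_P (+ CORR_P when
    ``max_stat``). SNPs with missing genotypes are handled by per-SNP
    complete-case subsetting.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(trait, dtype=float)
    fam = geno.family_ids
    keep = np.isfinite(y)
    y, fam = y[keep], fam[keep]
    D = geno.dosage[keep]
    rng = np.random.default_rng(seed)
    perms = _family_permutations(fam, n_perm, rng)
    Yp = y[perms]

    base = wald_qt_scan(trait, geno)
    m = geno.n_snps
    t_perm = np.full((n_perm, m), np.nan)
    for s in range(m):
        x = D[:, s]
        valid = np.isfinite(x)
        nv = int(valid.sum())
        if nv < 3 or np.ptp(x[valid]) == 0:
            continue
        xv = x[valid]
        xc = xv - xv.mean()
        sxx = float(xc @ xc)
        Yv = Yp[:, valid]
        Yc = Yv - Yv.mean(axis=1, keepdims=True)
        syy = np.einsum("bn,bn->b", Yc, Yc)
        t_perm[:, s] = _t_matrix(Yc, xc, syy, sxx, nv)

    obs = base["STAT"].to_numpy()
    emp = np.full(m, np.nan)
    ok = np.isfinite(obs)
    with np.errstate(invalid="ignore"):
        emp[ok] = (1 + np.sum(np.abs(t_perm[:, ok]) >= np.abs(obs[ok]), axis=0)) / (
            n_perm + 1
        )
    base["EMP_P"] = emp
    if max_stat:
        with np.errstate(invalid="ignore"):
            max_t = np.nanmax(np.abs(np.where(np.isnan(t_perm), -np.inf, t_perm)), axis=1)
        corr = np.full(m, np.nan)
        corr[ok] = (1 + np.sum(max_t[:, None] >= np.abs(obs[ok])[None, :], axis=0)) / (
            n_perm + 1
        )
        base["CORR_P"] = corr
    return base


# ---------------------------------------------------------------------------
# family-based: transmission disequilibrium test
# ---------------------------------------------------------------------------

def extract_trios(pedigree: pd.DataFrame) -> list[tuple[int, int, int]]:
    """All (child, father, mother) row-index triples resolvable in the pedigree.

    Every offspring with both parents present in the same family yields one
    trio; an offspring appears more than once only through distinct parent
    pairs (which the PED dialect cannot encode, so in practice once).
    """
    idx = {
        (f, i): r for r, (f, i) in enumerate(zip(pedigree["FID"], pedigree["IID"]))
    }
    trios = []
    for r, row in enumerate(pedigree.itertuples(index=False)):
        if row.PAT == "0" or row.MAT == "0":
            continue
        fa = idx.get((row.FID, row.PAT))
        mo = idx.get((row.FID, row.MAT))
        if fa is not None and mo is not None:
            trios.append((r, fa, mo))
    return trios


def _tdt_counts(binary_trait, geno: GenotypeData,
                trios: list[tuple[int, int, int]] | None = None):
    """Per-SNP transmitted (b) / untransmitted (c) counts from heterozygous
    parents to affected offspring, plus a Mendelian-inconsistency tally."""
    aff = np.asarray(binary_trait, dtype=float)
    if trios is None:
        trios = extract_trios(geno.pedigree)
    trios = [t for t in trios if aff[t[0]] == 1]
    if not trios:
        raise ValueError("no genotyped parent-offspring trio with an affected offspring")
    ci = np.array([t[0] for t in trios])
    fi = np.array([t[1] for t in trios])
    mi = np.array([t[2] for t in trios])
    GC, GF, GM = geno.dosage[ci], geno.dosage[fi], geno.dosage[mi]
    complete = np.isfinite(GC) & np.isfinite(GF) & np.isfinite(GM)
    H = (GF == 1).astype(int) + (GM == 1)
    F2 = (GF == 2).astype(int) + (GM == 2)
    X = GC - F2  # coded alleles the het parents must have transmitted
    consistent = complete & (X >= 0) & (X <= H)
    b = np.where(consistent, X, 0).sum(axis=0)
    c = np.where(consistent, H - X, 0).sum(axis=0)
    mendel = (complete & ~consistent).sum(axis=0)
    return b.astype(float), c.astype(float), mendel.astype(int), len(trios)


def tdt_test(binary_trait, dosage, pedigree: pd.DataFrame) -> dict:
    """TDT for one SNP: chi2 = (b - c)^2 / (b + c), 1-df upper-tail p.

    ``binary_trait`` (0/1) and ``dosage`` are aligned with pedigree rows.
    Trios with a missing genotype are excluded; Mendelian-inconsistent
    trios are skipped and tallied.
    """
    dosage = np.asarray(dosage, dtype=float).reshape(-1, 1)
    tmp = GenotypeData.__new__(GenotypeData)
    tmp.dosage = dosage
    tmp.pedigree = pedigree
    b, c, mendel, n_trios = _tdt_counts(binary_trait, tmp)
    return _tdt_row(float(b[0]), float(c[0]), int(mendel[0]), n_trios)


def _tdt_row(b: float, c: float, mendel: int, n_trios: int) -> dict:
    if b + c == 0:
        return {"b": b, "c": c, "chi2": np.nan, "p": np.nan,
                "reason": "no-informative-transmissions",
                "mendel_errors": mendel, "n_trios": n_trios}
    chi2 = (b - c) ** 2 / (b + c)
    return {"b": b, "c": c, "chi2": chi2, "p": float(stats.chi2.sf(chi2, df=1)) or np.finfo(float).tiny,
            "reason": "", "mendel_errors": mendel, "n_trios": n_trios}


def tdt_scan(binary_trait, geno: GenotypeData) -> pd.DataFrame:
    """TDT across all SNPs; columns CHR, SNP, BP, B, C, STAT, P, MENDEL."""
    b, c, mendel, _ = _tdt_counts(binary_trait, geno)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(b + c > 0, (b - c) ** 2 / np.maximum(b + c, 1), np.nan)
    p = np.where(np.isfinite(chi2), stats.chi2.sf(np.nan_to_num(chi2), df=1), np.nan)
    return pd.DataFrame(
        {"CHR": geno.chrom, "SNP": geno.snp_ids, "BP": geno.pos,
         "B": b, "C": c, "STAT": chi2, "P": p, "MENDEL": mendel}
    )


def perm_correct_family(table: pd.DataFrame, n_perm: int = 999,
                        seed: int | None = None) -> np.ndarray:
    """Max-statistic permutation correction for a TDT scan.

    Under the null each informative transmission is a fair coin, so each
    permutation redraws b* ~ Binomial(b + c, 1/2) per SNP, records the
    maximum chi-square over SNPs, and the corrected p-value is
    ``(1 + #{max_perm >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(table) == 0:
        raise ValueError("empty association table")
    rng = np.random.default_rng(seed)
    ntr = (table["B"] + table["C"]).to_numpy(dtype=float)
    obs = table["STAT"].to_numpy(dtype=float)
    m = len(table)
    informative = ntr > 0
    max_chi = np.zeros(n_perm)
    if informative.any():
        n_inf = ntr[informative].astype(int)
        bstar = rng.binomial(n_inf[None, :], 0.5, size=(n_perm, len(n_inf)))
        chi = (2 * bstar - n_inf[None, :]) ** 2 / n_inf[None, :]
        max_chi = chi.max(axis=1)
    corr = np.full(m, np.nan)
    ok = np.isfinite(obs)
    corr[ok] = (1 + np.sum(max_chi[:, None] >= obs[ok][None, :], axis=0)) / (n_perm + 1)
    return corr


def write_association(table: pd.DataFrame, path) -> None:
    """Write an association table TSV (columns as produced by the scans)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
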
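"""Association tests: regression oracle, FDR, permutation and TDT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trajmap.association import (
    bh_fdr,
    qfam_perm_scan,
    qfam_perm_test,
    tdt_scan,
    tdt_test,
    wald_qt_test,
)
from trajmap.genotypes import GenotypeData


def make_geno(dosage, fids=None, pat=None, mat=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    fids = fids if fids is not None else [f"F{i}" for i in range(n)]
    ped = pd.DataFrame(
        {
            "FID": fids,
            "IID": [f"i{i}" for i in range(n)],
            "PAT": pat if pat is not None else ["0"] * n,
            "MAT": mat if mat is not None else ["0"] * n,
            "SEX": [1] * n,
        }
    )
    return GenotypeData(
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=(np.arange(m) + 1) * 100,
        alleles=np.array([["A", "B"]] * m, dtype=object),
        dosage=dosage,
        pedigree=ped,
    )


# ---------------------------------------------------------------------------
# Wald regression
# ---------------------------------------------------------------------------

def test_wald_matches_normal_equations_oracle():
    """Hand-rolled normal-equations least squares agrees to 1e-10."""
    x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
    y = np.array([1.0, 1.2, 1.9, 2.1, 3.0, 3.2])
    n = len(x)
    # independent closed-form oracle
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    b = (n * sxy - sx * sy) / (n * sxx - sx**2)
    a = (sy - b * sx) / n
    ssr = ((y - a - b * x) ** 2).sum()
    se = np.sqrt(ssr / (n - 2) / (sxx - sx**2 / n))
    t = b / se
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), n - 2)
    r = wald_qt_test(y, x)
    assert r["beta"] == pytest.approx(b, abs=1e-10)
    assert r["stat"] == pytest.approx(t, abs=1e-10)
    assert r["p"] == pytest.approx(p, abs=1e-10)


def test_wald_constant_trait_zero_slope():
    r = wald_qt_test(np.ones(6), np.array([0, 1, 2, 0, 1, 2.0]))
    assert r["beta"] == 0.0


def test_wald_monomorphic_reason_code():
    r = wald_qt_test(np.arange(5.0), np.ones(5))
    assert np.isnan(r["p"]) and r["reason"] == "monomorphic"


def test_wald_order_invariance():
    rng = np.random.default_rng(0)
    y, x = rng.normal(size=30), rng.integers(0, 3, 30).astype(float)
    perm = rng.permutation(30)
    a, b = wald_qt_test(y, x), wald_qt_test(y[perm], x[perm])
    assert a["beta"] == pytest.approx(b["beta"], abs=1e-12)
    assert a["p"] == pytest.approx(b["p"], abs=1e-12)


def test_wald_too_few_observations():
    with pytest.raises(ValueError):
        wald_qt_test([1.0, 2.0], [0.0, 1.0])


def test_wald_power_monotone_in_effect():
    """Rejection rate at alpha=0.05 grows with the simulated effect size."""
    rng = np.random.default_rng(7)
    n, m = 200, 300
    rates = []
    for eff in (0.0, 0.3, 0.6):
        hits = 0
        for s in range(m):
            x = rng.binomial(2, 0.3, n).astype(float)
            y = eff * x + rng.normal(0, 1, n)
            hits += wald_qt_test(y, x)["p"] < 0.05
        rates.append(hits / m)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > 0.9


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def brute_force_bh(p):
    """Textbook step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


@pytest.mark.parametrize(
    "pvals, expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2], [0.2]),
        ([1.0, 1.0], [1.0, 1.0]),
    ],
)
def test_bh_fdr_examples(pvals, expected):
    np.testing.assert_allclose(bh_fdr(pvals), expected, atol=1e-12)


def test_bh_fdr_empty():
    assert len(bh_fdr([])) == 0


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=20),
    st.randoms(use_true_random=False),
)
def test_bh_fdr_matches_oracle_and_order_invariant(pvals, rnd):
    q = bh_fdr(pvals)
    np.testing.assert_allclose(q, brute_force_bh(pvals), atol=1e-12)
    perm = list(range(len(pvals)))
    rnd.shuffle(perm)
    q2 = bh_fdr([pvals[i] for i in perm])
    np.testing.assert_allclose(q2, q[perm], atol=1e-12)


# ---------------------------------------------------------------------------
# QFAM-style within-family permutation
# ---------------------------------------------------------------------------

def _family_sim(n_fam=40, fam_size=4, seed=0):
    rng = np.random.default_rng(seed)
    n = n_fam * fam_size
    fids = np.repeat([f"F{i}" for i in range(n_fam)], fam_size)
    x = rng.binomial(2, 0.3, n).astype(float)
    return fids, x, rng


def test_qfam_min_emp_p_bound():
    fids, x, rng = _family_sim(seed=1)
    y = x * 2.0 + rng.normal(0, 0.5, len(x))  # strong signal
    r = qfam_perm_test(y, x, fids, n_perm=49, seed=0)
    assert r["emp_p"] == pytest.approx(1 / 50)
    with pytest.raises(ValueError):
        qfam_perm_test(y, x, fids, n_perm=0)


def test_qfam_all_singleton_families_error():
    y = np.arange(6.0)
    x = np.array([0, 1, 2, 0, 1, 2.0])
    with pytest.raises(ValueError, match="size 1"):
        qfam_perm_test(y, x, [f"F{i}" for i in range(6)], n_perm=9, seed=0)


def test_qfam_robust_to_family_confounder():
    """A family-constant confounder correlated with genotype shifts the
    naive Wald p but leaves the within-family empirical p null-like."""
    fids, x, rng = _family_sim(n_fam=60, fam_size=4, seed=2)
    # family-level confounder proportional to the family's mean dosage
    fam_means = pd.Series(x).groupby(pd.Series(fids)).transform("mean").to_numpy()
    y = 3.0 * fam_means + rng.normal(0, 1, len(x))
    r = qfam_perm_test(y, x, fids, n_perm=499, seed=3)
    assert r["p"] < 0.01          # naive regression is fooled
    assert r["emp_p"] > 0.05      # within-family permutation is not


def test_qfam_scan_single_snp_corrected_equals_empirical():
    fids, x, rng = _family_sim(seed=4)
    y = rng.normal(size=len(x))
    geno = make_geno(x[:, None], fids=list(fids))
    tab = qfam_perm_scan(y, geno, n_perm=199, seed=5)
    assert tab["CORR_P"].iloc[0] == pytest.approx(tab["EMP_P"].iloc[0])


def test_qfam_scan_corrected_dominates_empirical():
    fids, _, rng = _family_sim(seed=6)
    D = rng.binomial(2, 0.3, size=(len(fids), 8)).astype(float)
    y = rng.normal(size=len(fids))
    tab = qfam_perm_scan(y, make_geno(D, fids=list(fids)), n_perm=99, seed=7)
    assert np.all(tab["CORR_P"] >= tab["EMP_P"] - 1e-12)


# ---------------------------------------------------------------------------
# TDT
# ---------------------------------------------------------------------------

def make_trios(child_doses, father_doses, mother_doses):
    """One family per trio; returns (geno, affected) with all children
    affected."""
    n_trio = len(child_doses)
    rows_d = []
    fids, iids, pats, mats = [], [], [], []
    for i, (gc, gf, gm) in enumerate(zip(child_doses, father_doses, mother_doses)):
        fid = f"T{i}"
        fids += [fid] * 3
        iids += ["dad", "mom", "kid"]
        pats += ["0", "0", "dad"]
        mats += ["0", "0", "mom"]
        rows_d += [[gf], [gm], [gc]]
    ped = pd.DataFrame({"FID": fids, "IID": iids, "PAT": pats, "MAT": mats,
                        "SEX": [1, 2, 1] * n_trio})
    geno = GenotypeData(
        snp_ids=np.array(["s0"], dtype=object),
        chrom=np.array(["1"], dtype=object),
        pos=np.array([100]),
        alleles=np.array([["A", "B"]], dtype=object),
        dosage=np.array(rows_d, dtype=float),
        pedigree=ped,
    )
    aff = np.array([0, 0, 1] * n_trio, dtype=float)
    return geno, aff


def test_tdt_balanced_transmissions():
    # father het, mother hom-ref; child 1 -> transmitted, child 0 -> not
    geno, aff = make_trios([1, 0, 1, 0], [1, 1, 1, 1], [0, 0, 0, 0])
    r = tdt_test(aff, geno.dosage[:, 0], geno.pedigree)
    assert r["b"] == 2 and r["c"] == 2
    assert r["chi2"] == 0 and r["p"] == pytest.approx(1.0)


def test_tdt_14_trio_fixture_matches_enumeration():
    """10 transmissions vs 4: chi2 = (10-4)^2/14 = 36/14, verified against
    per-trio enumeration."""
    child = [1] * 10 + [0] * 4
    geno, aff = make_trios(child, [1] * 14, [0] * 14)
    # brute-force enumeration over trios
    b = c = 0
    for gc in child:
        # single het parent (father), mother transmits 0; child dose is
        # exactly what the father transmitted
        if gc == 1:
            b += 1
        else:
            c += 1
    assert (b, c) == (10, 4)
    r = tdt_test(aff, geno.dosage[:, 0], geno.pedigree)
    assert (r["b"], r["c"]) == (10, 4)
    assert r["chi2"] == pytest.approx(36 / 14)


def test_tdt_double_het_child_counts():
    # both parents het: child 2 -> b+=2; child 0 -> c+=2; child 1 -> b+=1,c+=1
    geno, aff = make_trios([2, 0, 1], [1, 1, 1], [1, 1, 1])
    r = tdt_test(aff, geno.dosage[:, 0], geno.pedigree)
    assert (r["b"], r["c"]) == (3, 3)


def test_tdt_homozygous_parents_uninformative():
    geno, aff = make_trios([1, 2, 0], [2, 2, 0], [0, 2, 0])
    r = tdt_test(aff, geno.dosage[:, 0], geno.pedigree)
    assert r["b"] + r["c"] == 0
    assert np.isnan(r["p"]) and r["reason"] == "no-informative-transmissions"


def test_tdt_mendel_inconsistent_trio_skipped():
    # 0/0 x 0/0 parents cannot produce a dose-1 child
    geno, aff = make_trios([1, 1], [0, 1], [0, 0])
    r = tdt_test(aff, geno.dosage[:, 0], geno.pedigree)
    assert r["mendel_errors"] == 1
    assert (r["b"], r["c"]) == (1, 0)


def test_tdt_unaffected_offspring_ignored():
    geno, aff = make_trios([1, 1], [1, 1], [0, 0])
    aff[-1] = 0  # second trio's child unaffected
    r = tdt_test(aff, geno.dosage[:, 0], geno.pedigree)
    assert r["b"] + r["c"] == 1


def test_tdt_requires_affected_trio():
    geno, aff = make_trios([1], [1], [0])
    with pytest.raises(ValueError, match="affected"):
        tdt_test(np.zeros_like(aff), geno.dosage[:, 0], geno.pedigree)


def test_tdt_scan_matches_single(two_group_data):
    geno, aff = make_trios([1, 0, 2, 1], [1, 1, 1, 1], [1, 0, 1, 0])
    tab = tdt_scan(aff, geno)
    single = tdt_test(aff, geno.dosage[:, 0], geno.pedigree)
    assert tab["B"].iloc[0] == single["b"]
    assert tab["STAT"].iloc[0] == pytest.approx(single["chi2"])
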
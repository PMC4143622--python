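"""Derive association phenotypes from a fitted trajectory mixture.

The clinically relevant subgroup is the one whose fitted polynomial takes
the highest (or, configurably, lowest) value at the final time point —
for hypertension, the subgroup with the highest blood pressure at the last
visit. Each individual's posterior probability (BPP) of belonging to that
subgroup becomes a quantitative trait; a dichotomized 0/1 version serves
tests that require an affection status. An optional Box-Cox transform is
available for the (typically bimodal) BPP distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .trajectory import GroupTrajectoryResults

__all__ = [
    "DerivedPhenotype",
    "pick_relevant_subgroup",
    "extract_trait",
    "dichotomize",
    "boxcox_transform",
    "write_quantitative_phenotype",
    "write_binary_phenotype",
]


@dataclass
class DerivedPhenotype:
    """Per-individual subgroup-membership phenotype.

    ``bpp_trait`` is the posterior probability (in [0, 1]) of the clinically
    relevant subgroup; ``binary_trait`` its dichotomized 0/1 version
    (probability above 0.5 -> 1). ``transform`` records any normalization
    applied ("none" or "boxcox(lambda)").
    """

    individual_ids: np.ndarray
    family_ids: np.ndarray
    bpp_trait: np.ndarray
    binary_trait: np.ndarray
    relevant_group_index: int
    transform: str = "none"

    def __post_init__(self) -> None:
        self.bpp_trait = np.asarray(self.bpp_trait, dtype=float)
        self.binary_trait = np.asarray(self.binary_trait, dtype=int)
        if self.transform == "none":
            if np.any((self.bpp_trait < 0) | (self.bpp_trait > 1)):
                raise ValueError("bpp_trait must lie in [0, 1]")
            if not np.array_equal(self.binary_trait, dichotomize(self.bpp_trait)):
                raise ValueError("binary_trait inconsistent with the threshold rule")


def pick_relevant_subgroup(
    model: GroupTrajectoryResults, t_last: float, direction: str = "highest"
) -> int:
    """Index (0-based) of the clinically relevant subgroup.

    Evaluates each subgroup's fitted polynomial at the final time point
    ``t_last`` — covariate terms excluded, i.e. at reference covariate level
    zero — and returns the argmax (``direction="highest"``) or argmin
    (``direction="lowest"``). An exact tie among the extreme fitted values
    is an error since no rule can order the tied subgroups.
    """
    if not model.converged:
        raise ValueError("subgroup selection requires a converged model")
    if direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    vals = np.array(
        [model.predict_trajectory(j, t_last) for j in range(model.spec.k)], dtype=float
    )
    extreme = vals.max() if direction == "highest" else vals.min()
    tied = np.flatnonzero(vals == extreme)
    if len(tied) > 1:
        raise ValueError(
            f"tie at t={t_last}: subgroups {list(tied + 1)} all have fitted value "
            f"{extreme}"
        )
    return int(tied[0])


def extract_trait(model: GroupTrajectoryResults, group: int) -> DerivedPhenotype:
    """BPP of one subgroup as a quantitative trait, plus its dichotomization."""
    if not 0 <= group < model.spec.k:
        raise ValueError(f"group {group} out of range for k={model.spec.k}")
    bpp = model.bpp[:, group]
    return DerivedPhenotype(
        individual_ids=model.model.data.individual_ids,
        family_ids=model.model.data.family_ids,
        bpp_trait=bpp,
        binary_trait=dichotomize(bpp),
        relevant_group_index=group,
    )


def dichotomize(bpp) -> np.ndarray:
    """Threshold posterior probabilities at 0.5.

    Above 0.5 -> 1, below 0.5 -> 0; exactly 0.5 is assigned 1 (inclusive
    upper rule). Inputs outside [0, 1] are rejected.
    """
    arr = np.asarray(bpp, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    out = (arr >= 0.5).astype(int)
    return out if np.ndim(bpp) else int(out)


def boxcox_transform(values, lam="mle"):
    """Box-Cox power transform: (y^lam - 1)/lam, or ln(y) at lam = 0.

    ``lam="mle"`` maximizes the profile log-likelihood (scipy's estimator).
    All values must be strictly positive; pass a pre-shifted array if any
    are not. Returns ``(transformed, lambda_used)``.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("Box-Cox requires strictly positive values; shift first")
    if isinstance(lam, str):
        if lam != "mle":
            raise ValueError("lam must be a number or 'mle'")
        out, lam_used = stats.boxcox(arr)
        return out, float(lam_used)
    return special.boxcox(arr, float(lam)), float(lam)


def write_quantitative_phenotype(pheno: DerivedPhenotype, path) -> None:
    """TSV with FID, IID, TRAIT — the quantitative BPP phenotype."""
    pd.DataFrame(
        {"FID": pheno.family_ids, "IID": pheno.individual_ids, "TRAIT": pheno.bpp_trait}
    ).to_csv(path, sep="\t", index=False)


def write_binary_phenotype(pheno: DerivedPhenotype, path) -> None:
    """TSV with FID, IID, AFF in 1/2 coding (2=affected, 1=unaffected, 0=missing)."""
    pd.DataFrame(
        {
            "FID": pheno.family_ids,
            "IID": pheno.individual_ids,
            "AFF": pheno.binary_trait + 1,
        }
    ).to_csv(path, sep="\t", index=False)
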
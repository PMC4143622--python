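"""Longitudinal phenotype container and its long-format TSV dialect.

The canonical in-memory layout is rectangular: ``N`` individuals by ``T``
visit slots, with a boolean observation mask so that individuals with
missing visits contribute likelihood only over the visits they attended.
Time-varying covariates share the visit grid; time-independent covariates
are per-individual scalars broadcast over visits when a model matrix is
assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalData",
    "read_long_phenotypes",
    "write_long_phenotypes",
]

#: Fixed leading columns of the long-format phenotype dialect.
CORE_COLUMNS = ["FID", "IID", "VISIT", "TIME", "VALUE"]


@dataclass
class LongitudinalData:
    """Repeated measurements of one quantitative trait on a visit grid.

    Parameters
    ----------
    individual_ids : ndarray of str, shape (N,)
        Within-family individual identifiers (IID).
    family_ids : ndarray of str, shape (N,)
        Family identifiers (FID); all-"0" for an unrelated cohort.
    times : ndarray, shape (N, T)
        Numeric time value of each visit (visit index, age, ...).
    values : ndarray, shape (N, T)
        Trait measurements (e.g. systolic blood pressure in mmHg).
    mask : ndarray of bool, shape (N, T)
        True where a visit was observed.
    covariates_tv : dict of str -> ndarray (N, T)
        Time-varying covariates aligned with the visit grid.
    covariates_ti : dict of str -> ndarray (N,)
        Time-independent covariates.
    """

    individual_ids: np.ndarray
    family_ids: np.ndarray
    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    covariates_tv: dict[str, np.ndarray] = field(default_factory=dict)
    covariates_ti: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.family_ids = np.asarray(self.family_ids, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n, t = self.times.shape
        if self.values.shape != (n, t) or self.mask.shape != (n, t):
            raise ValueError("times, values and mask must share shape (N, T)")
        if len(self.individual_ids) != n or len(self.family_ids) != n:
            raise ValueError("identifier arrays must have length N")
        if not self.mask.any(axis=1).all():
            bad = np.asarray(self.individual_ids)[~self.mask.any(axis=1)]
            raise ValueError(f"individuals with no observed visit: {list(bad)}")
        # times strictly increasing over observed visits, per individual
        for i in range(n):
            ti = self.times[i, self.mask[i]]
            if np.any(np.diff(ti) <= 0):
                raise ValueError(
                    f"times not strictly increasing for individual "
                    f"{self.individual_ids[i]}"
                )
        for name, arr in self.covariates_tv.items():
            if arr.shape != (n, t):
                raise ValueError(f"time-varying covariate {name!r} misaligned")
        for name, arr in self.covariates_ti.items():
            if arr.shape != (n,):
                raise ValueError(f"static covariate {name!r} misaligned")

    # -- convenience ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.times.shape[0]

    @property
    def n_visits(self) -> int:
        return self.times.shape[1]

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates_tv) + list(self.covariates_ti)

    def covariate_matrix(self) -> np.ndarray:
        """Stack all covariates into an (N, T, C) array.

        Time-independent covariates are broadcast over visits. Ordering is
        time-varying first (dict order), then static.
        """
        n, t = self.times.shape
        cols = [arr for arr in self.covariates_tv.values()]
        cols += [np.repeat(arr[:, None], t, axis=1) for arr in self.covariates_ti.values()]
        if not cols:
            return np.zeros((n, t, 0))
        return np.stack(cols, axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (one row per observed visit)."""
        rows = []
        tv_names = list(self.covariates_tv)
        ti_names = list(self.covariates_ti)
        for i in range(self.n_individuals):
            for v in range(self.n_visits):
                if not self.mask[i, v]:
                    continue
                row = {
                    "FID": self.family_ids[i],
                    "IID": self.individual_ids[i],
                    "VISIT": v + 1,
                    "TIME": self.times[i, v],
                    "VALUE": self.values[i, v],
                }
                for name in tv_names:
                    row[name] = self.covariates_tv[name][i, v]
                for name in ti_names:
                    row[name] = self.covariates_ti[name][i]
                rows.append(row)
        return pd.DataFrame(rows)


def read_long_phenotypes(path) -> LongitudinalData:
    """Read a long-format phenotype TSV into a :class:`LongitudinalData`.

    The dialect has columns FID, IID, VISIT, TIME, VALUE, then any number of
    covariate columns (auto-detected). "NA" marks a missing value; a row with
    missing VALUE yields a masked cell. Row order is irrelevant. Duplicate
    (IID, VISIT) pairs are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str}, na_values=["NA"])
    missing_cols = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype file missing columns: {missing_cols}")
    if df.duplicated(subset=["FID", "IID", "VISIT"]).any():
        dup = df[df.duplicated(subset=["FID", "IID", "VISIT"])].iloc[0]
        raise ValueError(
            f"duplicate (IID, VISIT) row: IID={dup['IID']} VISIT={dup['VISIT']}"
        )
    cov_names = [c for c in df.columns if c not in CORE_COLUMNS]

    df = df.sort_values(["FID", "IID", "VISIT"], kind="stable")
    keys = df[["FID", "IID"]].drop_duplicates()
    index = {(f, i): r for r, (f, i) in enumerate(zip(keys["FID"], keys["IID"]))}
    n = len(index)
    visits = np.sort(df["VISIT"].unique())
    t = len(visits)
    vpos = {v: j for j, v in enumerate(visits)}

    times = np.zeros((n, t))
    values = np.full((n, t), np.nan)
    mask = np.zeros((n, t), dtype=bool)
    # covariate columns: decide tv vs ti after filling
    cov = {name: np.full((n, t), np.nan) for name in cov_names}

    for row in df.itertuples(index=False):
        r = index[(row.FID, row.IID)]
        c = vpos[row.VISIT]
        times[r, c] = row.TIME
        val = getattr(row, "VALUE")
        if pd.notna(val):
            values[r, c] = float(val)
            mask[r, c] = True
        for name in cov_names:
            cov[name][r, c] = getattr(row, name)

    # fill unobserved time cells with the visit-grid default (column median)
    for c in range(t):
        col = times[:, c]
        seen = mask[:, c]
        if not seen.all() and seen.any():
            col[~seen] = np.median(col[seen])

    covariates_tv: dict[str, np.ndarray] = {}
    covariates_ti: dict[str, np.ndarray] = {}
    for name, arr in cov.items():
        with np.errstate(invalid="ignore"):
            spread = np.nanmax(arr, axis=1) - np.nanmin(arr, axis=1)
        if np.all(np.nan_to_num(spread) == 0):
            first = np.array([arr[i][~np.isnan(arr[i])][0] if (~np.isnan(arr[i])).any() else np.nan for i in range(n)])
            covariates_ti[name] = first
        else:
            filled = np.where(np.isnan(arr), 0.0, arr)
            covariates_tv[name] = filled

    fids = np.array([k[0] for k in index], dtype=object)
    iids = np.array([k[1] for k in index], dtype=object)
    return LongitudinalData(
        individual_ids=iids,
        family_ids=fids,
        times=times,
        values=values,
        mask=mask,
        covariates_tv=covariates_tv,
        covariates_ti=covariates_ti,
    )


def write_long_phenotypes(data: LongitudinalData, path) -> None:
    """Write the long-format TSV dialect read by :func:`read_long_phenotypes`."""
    df = data.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
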
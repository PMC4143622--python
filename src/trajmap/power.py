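"""Replicate-set power evaluation.

A replicate set is one discovery replicate plus two confirmatory
replicates drawn without replacement from the pool of phenotype
replicates. A gene scores YES for a set only when all three replicates
contain at least one SNP in the gene whose association p-value qualifies —
either ranked in the top x% of that replicate's scan (population arm) or
at/below a fixed threshold alpha (family arm). Per-gene power is the
fraction of YES sets; total power is the mean of per-gene power over
causal (non-null) genes; the same machinery applied to null regions
estimates empirical type-I error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicateSet",
    "GeneRegion",
    "build_replicate_sets",
    "gene_hit",
    "per_gene_power",
    "total_power",
    "compare_conditions",
    "read_regions_bed",
    "write_regions_bed",
    "PowerReport",
]


@dataclass(frozen=True)
class ReplicateSet:
    """One discovery replicate id plus two confirmatory ids (all distinct)."""

    discovery: int
    confirmatory: tuple[int, int]

    def __post_init__(self) -> None:
        ids = self.all_ids
        if len(set(ids)) != len(ids):
            raise ValueError(f"replicate ids within a set must be distinct: {ids}")

    @property
    def all_ids(self) -> tuple[int, ...]:
        return (self.discovery, *self.confirmatory)


@dataclass
class GeneRegion:
    """Genomic interval, 1-based inclusive coordinates.

    ``is_null`` marks regions containing no simulated functional locus,
    used for empirical type-I error rather than power.
    """

    name: str
    chrom: str
    start: int
    end: int
    is_null: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")

    def contains(self, chrom, pos) -> np.ndarray:
        return (np.asarray(chrom, dtype=object) == self.chrom) & (
            (np.asarray(pos) >= self.start) & (np.asarray(pos) <= self.end)
        )


def build_replicate_sets(
    n_pool: int, n_sets: int, set_size: int = 3, seed: int | None = None
) -> list[ReplicateSet]:
    """Draw ``n_sets`` replicate sets of ``set_size`` distinct ids (1-based).

    Ids are sampled without replacement within each set; sets are drawn
    independently, so an id may recur across sets. Deterministic under seed.
    """
    if set_size > n_pool:
        raise ValueError(f"set_size {set_size} exceeds pool {n_pool}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        ids = rng.choice(n_pool, size=set_size, replace=False) + 1
        out.append(ReplicateSet(int(ids[0]), tuple(int(i) for i in ids[1:])))
    return out


def gene_hit(assoc: pd.DataFrame, gene: GeneRegion, criterion) -> bool:
    """Does a replicate's scan qualify inside one gene?

    ``criterion`` is ``("top_percent", x)`` — some gene SNP's p-value ranks
    within the top ceil(x/100 * m) of the m SNPs tested in this replicate —
    or ``("alpha", a)`` — some gene SNP has p <= a. A gene covering no
    tested SNP is a NO.
    """
    kind, value = criterion
    p = assoc["P"].to_numpy(dtype=float)
    inside = gene.contains(assoc["CHR"].to_numpy(), assoc["BP"].to_numpy())
    inside &= np.isfinite(p)
    if not inside.any():
        return False
    if kind == "alpha":
        return bool(np.nanmin(p[inside]) <= value)
    if kind == "top_percent":
        tested = np.isfinite(p)
        m = int(tested.sum())
        cutoff_rank = math.ceil(value / 100.0 * m)
        ranks = stats.rankdata(p[tested], method="min")
        rank_map = np.full(len(p), np.inf)
        rank_map[tested] = ranks
        return bool(np.min(rank_map[inside]) <= cutoff_rank)
    raise ValueError(f"unknown criterion kind {kind!r}")


def per_gene_power(
    sets: list[ReplicateSet],
    per_replicate_assoc: dict[int, pd.DataFrame],
    genes: list[GeneRegion],
    criterion,
) -> pd.DataFrame:
    """Fraction of replicate sets scoring YES per gene.

    A set is YES for a gene only when the gene qualifies in the discovery
    and in both confirmatory replicates. Returns columns gene, is_null,
    power. Order of sets and genes does not affect the result.
    """
    for rs in sets:
        for rid in rs.all_ids:
            if rid not in per_replicate_assoc:
                raise KeyError(f"missing association table for replicate {rid}")
    # cache per (replicate, gene) hit decisions
    hits: dict[tuple[int, int], bool] = {}
    rows = []
    for gi, gene in enumerate(genes):
        yes = 0
        for rs in sets:
            ok = True
            for rid in rs.all_ids:
                key = (rid, gi)
                if key not in hits:
                    hits[key] = gene_hit(per_replicate_assoc[rid], gene, criterion)
                if not hits[key]:
                    ok = False
                    break
            yes += ok
        rows.append({"gene": gene.name, "is_null": gene.is_null,
                     "power": yes / len(sets)})
    return pd.DataFrame(rows)


def total_power(per_gene: pd.DataFrame) -> float:
    """Arithmetic mean of per-gene power over non-null genes."""
    causal = per_gene[~per_gene["is_null"]]
    if len(causal) == 0:
        raise ValueError("no non-null genes")
    return float(causal["power"].mean())


def compare_conditions(power_a, power_b, paired: bool = True) -> dict:
    """Two-sided t-test comparing per-gene power between two conditions.

    Paired by gene by default. Zero variance of the differences yields
    ``p = NaN`` with a reason code instead of an error.
    """
    a = np.asarray(power_a, dtype=float)
    b = np.asarray(power_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors over >= 2 genes")
    if paired:
        d = a - b
        if np.allclose(d, d[0], rtol=0, atol=1e-12 * max(1.0, np.abs(d).max())):
            return {"t": np.nan, "p": np.nan, "reason": "zero-variance-differences"}
        t, p = stats.ttest_rel(a, b)
    else:
        if a.std() == 0 and b.std() == 0:
            return {"t": np.nan, "p": np.nan, "reason": "zero-variance"}
        t, p = stats.ttest_ind(a, b)
    return {"t": float(t), "p": float(p), "reason": ""}


# ---------------------------------------------------------------------------
# BED IO (0-based half-open on disk, 1-based inclusive in memory)
# ---------------------------------------------------------------------------

def read_regions_bed(path) -> list[GeneRegion]:
    """Read gene/null regions from BED (chrom, start, end, name[, null flag])."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}: line {ln}: need chrom,start,end,name")
            chrom, start, end, name = parts[:4]
            is_null = len(parts) > 4 and parts[4].lower() in ("1", "null", "true")
            regions.append(
                GeneRegion(name=name, chrom=chrom, start=int(start) + 1,
                           end=int(end), is_null=is_null)
            )
    return regions


def write_regions_bed(regions: list[GeneRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            flag = "null" if r.is_null else "gene"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\t{flag}\n")


@dataclass
class PowerReport:
    """Per-gene and total power across thresholds, null-region rates,
    and condition comparisons, ready for JSON/TSV serialization."""

    criterion_kind: str
    thresholds: list[float]
    per_gene: dict[float, pd.DataFrame] = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def total_power(self, threshold: float) -> float:
        return total_power(self.per_gene[threshold])

    def null_rates(self, threshold: float) -> pd.DataFrame:
        pg = self.per_gene[threshold]
        return pg[pg["is_null"]]

    def to_dict(self) -> dict:
        out = {
            "criterion_kind": self.criterion_kind,
            "thresholds": self.thresholds,
            "per_gene_power": {
                str(th): {row["gene"]: row["power"]
                          for _, row in pg[~pg["is_null"]].iterrows()}
                for th, pg in self.per_gene.items()
            },
            "null_region_rates": {
                str(th): {row["gene"]: row["power"]
                          for _, row in pg[pg["is_null"]].iterrows()}
                for th, pg in self.per_gene.items()
            },
            "total_power": {
                str(th): self.total_power(th) for th in self.thresholds
            },
            "comparisons": self.comparisons,
            "meta": self.meta,
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def to_tsv(self, path) -> None:
        """Per-gene power per threshold in long form (bar-chart data)."""
        frames = []
        for th, pg in self.per_gene.items():
            f = pg.copy()
            f["threshold"] = th
            frames.append(f)
        pd.concat(frames).to_csv(path, sep="\t", index=False)
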
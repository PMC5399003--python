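"""Per-SNP nucleotide diversity and population differentiation.

At a biallelic site with allele observation counts ``n_i`` (``n = sum n_i``),
nucleotide diversity is

    pi = 1 - sum_i n_i^2 / n^2,

the probability that two allele observations drawn with replacement differ.
Between subpopulations with per-site allele totals ``n_j`` and diversities
``pi_j``, differentiation is estimated with an n_j^2-weighted index robust to
unbalanced subpopulation sizes:

    F_ST = 1 - (sum_j n_j^2 pi_j) / (pi_pooled * sum_j n_j^2).

F_ST is undefined where the pooled site is monomorphic (pi_pooled = 0); those
sites are later replaced with the genomic mean of the defined values.  The
estimator is deliberately not clamped to [0, 1]: it can be slightly negative
when within-subpopulation diversity exceeds pooled diversity, and clamping
would bias window means and the bootstrap null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import EXCLUDED, MISSING, GeneticMap, GenotypeMatrix, SubpopAssignment

logger = logging.getLogger(__name__)


def site_pi(n_a, n_b):
    """Nucleotide diversity 1 - sum n_i^2 / n^2 at a biallelic site.

    Accepts scalars or arrays of allele observation counts; returns NaN
    where n = 0.
    """
    n_a = np.asarray(n_a, dtype=np.float64)
    n_b = np.asarray(n_b, dtype=np.float64)
    n = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 1.0 - (n_a**2 + n_b**2) / n**2
    return np.where(n > 0, pi, np.nan)[()]


def site_fst(counts_by_pop: list[tuple[float, float]]):
    """Unbalanced-size F_ST from per-subpopulation (n_A, n_B) counts.

    Returns NaN where the pooled site is monomorphic (to be substituted with
    the genomic mean downstream) or where any subpopulation has no allele
    observations; the value is not clamped.
    """
    if len(counts_by_pop) < 2:
        raise ValueError("need at least 2 subpopulations")
    n_a = np.array([c[0] for c in counts_by_pop], dtype=np.float64)
    n_b = np.array([c[1] for c in counts_by_pop], dtype=np.float64)
    return _fst_from_arrays(n_a[None, :], n_b[None, :])[0]


def _fst_from_arrays(n_a: np.ndarray, n_b: np.ndarray) -> np.ndarray:
    """Vectorised F_ST; rows are sites, columns subpopulations."""
    n_j = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_j = 1.0 - (n_a**2 + n_b**2) / n_j**2
    pooled_a = n_a.sum(axis=1)
    pooled_b = n_b.sum(axis=1)
    pi_pool = site_pi(pooled_a, pooled_b)
    w = n_j**2
    num = np.nansum(w * pi_j, axis=1)
    den = pi_pool * w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = 1.0 - num / den
    undefined = (pi_pool == 0) | np.isnan(pi_pool) | (n_j == 0).any(axis=1)
    return np.where(undefined, np.nan, fst)


def compute_site_stats(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    assignment: SubpopAssignment,
    pop1: str,
    pop2: str,
) -> pd.DataFrame:
    """Per-SNP diversity and differentiation table for one contrast.

    Samples labelled ``excluded`` (or belonging to other subpopulations) are
    dropped; SNPs absent from the genetic map are excluded with a logged
    count.  Columns: snp_id, lg, cm, n_pop1, n_pop2, pi_pop1, pi_pop2,
    pi_pooled, fst, substituted.  ``fst`` is NaN at sites where it is
    undefined; apply :func:`substitute_undefined_fst` before windowing.
    """
    assignment.validate_for_contrast(pop1, pop2)
    mapped = gmap.positions_for(g.snps)
    n_unmapped = g.n_snps - len(mapped)
    if n_unmapped:
        logger.info("excluding %d SNPs without map positions", n_unmapped)

    rows = []
    pops = []
    for pop in (pop1, pop2):
        members = [s for s in assignment.samples_in(pop) if s in set(g.samples)]
        if len(members) < 2:
            raise ValueError(f"subpopulation {pop!r}: <2 genotyped samples")
        pops.append(g.sample_index(members))

    jdx = g.snp_index(mapped["snp_id"])
    calls = g.calls[:, jdx]

    per_pop_a, per_pop_b = [], []
    for idx in pops:
        sub = calls[idx, :]
        obs = sub != MISSING
        n_b = np.where(obs, sub, 0).sum(axis=0).astype(np.float64)
        n = 2.0 * obs.sum(axis=0)
        per_pop_a.append(n - n_b)
        per_pop_b.append(n_b)
    n_a = np.stack(per_pop_a, axis=1)
    n_b = np.stack(per_pop_b, axis=1)

    n_j = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_j = 1.0 - (n_a**2 + n_b**2) / n_j**2
    pi_pool = site_pi(n_a.sum(axis=1), n_b.sum(axis=1))
    fst = _fst_from_arrays(n_a, n_b)

    out = pd.DataFrame(
        {
            "snp_id": mapped["snp_id"].to_numpy(),
            "lg": mapped["lg"].to_numpy(),
            "cm": mapped["cm"].to_numpy(dtype=float),
            "n_pop1": n_j[:, 0].astype(int),
            "n_pop2": n_j[:, 1].astype(int),
            "pi_pop1": pi_j[:, 0],
            "pi_pop2": pi_j[:, 1],
            "pi_pooled": np.asarray(pi_pool, dtype=float),
            "fst": fst,
            "substituted": False,
        }
    )
    return out


def substitute_undefined_fst(records: pd.DataFrame) -> pd.DataFrame:
    """Replace undefined per-site F_ST values with the genomic mean.

    The genomic mean is the arithmetic mean of all defined per-site values of
    the same contrast, computed once genome-wide (not per linkage group).
    Defined values are untouched; substituted sites are flagged.
    """
    out = records.copy()
    undef = out["fst"].isna()
    defined = out.loc[~undef, "fst"]
    if defined.empty:
        raise ValueError("no defined F_ST values to compute the genomic mean")
    out.loc[undef, "fst"] = defined.mean()
    out["substituted"] = undef.to_numpy()
    return out


@dataclass
class GenomewideSummary:
    mean_fst: float
    mean_pi_pop1: float
    mean_pi_pop2: float
    n_sites: int
    fst_aggregate: str


def genomewide_summary(records: pd.DataFrame, fst_aggregate: str = "mean") -> GenomewideSummary:
    """Genome-wide means of per-site statistics.

    ``fst_aggregate`` is ``"mean"`` (arithmetic mean of per-site values,
    post-substitution) or ``"ratio_of_sums"`` (1 - sum of numerators over sum
    of denominators, robust to per-site ratio noise).
    """
    if records.empty:
        raise ValueError("no site records")
    if fst_aggregate == "mean":
        mean_fst = float(records["fst"].mean())
    elif fst_aggregate == "ratio_of_sums":
        mean_fst = ratio_of_sums_fst(records)
    else:
        raise ValueError(f"unknown fst_aggregate {fst_aggregate!r}")
    return GenomewideSummary(
        mean_fst=mean_fst,
        mean_pi_pop1=float(records["pi_pop1"].mean()),
        mean_pi_pop2=float(records["pi_pop2"].mean()),
        n_sites=len(records),
        fst_aggregate=fst_aggregate,
    )


def ratio_of_sums_fst(records: pd.DataFrame) -> float:
    """Aggregate F_ST as 1 - (sum_sites sum_j n_j^2 pi_j)/(sum_sites pi n_j^2).

    Sites where the per-site ratio is undefined (monomorphic pooled) add zero
    to both sums, so no substitution is involved.
    """
    n1 = records["n_pop1"].to_numpy(dtype=float)
    n2 = records["n_pop2"].to_numpy(dtype=float)
    num = n1**2 * records["pi_pop1"].to_numpy() + n2**2 * records["pi_pop2"].to_numpy()
    den = records["pi_pooled"].to_numpy() * (n1**2 + n2**2)
    ok = np.isfinite(num) & np.isfinite(den)
    return float(1.0 - num[ok].sum() / den[ok].sum())


def estimate_divergence_f(records: pd.DataFrame) -> float:
    """Method-of-moments estimate of the island-model divergence parameter F.

    Under a Balding-Nichols model with subpopulation weights w_j = n_j / n,
    the ratio-of-sums aggregate m of the n_j^2-weighted F_ST estimator has
    expectation m = F (1 - s) / (1 - F s) with s = sum w_j^2, because both
    numerator and denominator are averaged over sites before forming the
    ratio.  Inverting gives F = m / ((1 - s) + m s).
    """
    m = ratio_of_sums_fst(records)
    n1 = float(records["n_pop1"].mean())
    n2 = float(records["n_pop2"].mean())
    n = n1 + n2
    s = (n1 / n) ** 2 + (n2 / n) ** 2
    return m / ((1.0 - s) + m * s)
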
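"""Genotype matrices, genetic maps, subpopulation assignments and panel-level
diversity statistics.

Genotype calls at biallelic SNPs are stored as an ``int8`` matrix of B-allele
dosages: ``0`` = AA, ``1`` = AB (heterozygous), ``2`` = BB, ``-1`` = missing.
Samples are rows, SNPs are columns.  All panel statistics (heterozygosity,
identity-by-state distance, LD) are defined on this encoding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
AA = 0
AB = 1
BB = 2

_TSV_TOKENS = {"A": AA, "H": AB, "B": BB, "-": MISSING}
_TOKEN_OF = {AA: "A", AB: "H", BB: "B", MISSING: "-"}

#: label used in assignment tables for samples outside both subgene pools
EXCLUDED = "excluded"


class GenotypeLoadError(ValueError):
    """Raised when a genotype file contains malformed or duplicated entries."""


@dataclass
class GenotypeMatrix:
    """Diploid calls of inbred lines at mapped biallelic SNPs.

    Parameters
    ----------
    samples : list of str
        Ordered, unique sample identifiers (rows of ``calls``).
    snps : list of str
        Ordered, unique SNP identifiers (columns of ``calls``).
    calls : ndarray of int8, shape (n_samples, n_snps)
        B-allele dosage per (sample, SNP): 0 (AA), 1 (AB), 2 (BB) or
        -1 (missing).
    """

    samples: list[str]
    snps: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.snps = list(self.snps)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeLoadError("duplicate sample identifiers")
        if len(set(self.snps)) != len(self.snps):
            raise GenotypeLoadError("duplicate SNP identifiers")
        bad = ~np.isin(self.calls, (MISSING, AA, AB, BB))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeLoadError(
                f"invalid call code {self.calls[i, j]} at sample "
                f"{self.samples[i]!r}, SNP {self.snps[j]!r}"
            )

    # -- basic shape -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[n] for n in names], dtype=int)

    def snp_index(self, names: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.snps)}
        return np.array([pos[n] for n in names], dtype=int)

    def subset(self, samples: Sequence[str] | None = None,
               snps: Sequence[str] | None = None) -> "GenotypeMatrix":
        calls = self.calls
        out_samples = self.samples
        out_snps = self.snps
        if samples is not None:
            idx = self.sample_index(samples)
            calls = calls[idx, :]
            out_samples = list(samples)
        if snps is not None:
            jdx = self.snp_index(snps)
            calls = calls[:, jdx]
            out_snps = list(snps)
        return GenotypeMatrix(out_samples, out_snps, calls.copy())

    # -- per-SNP marginals -------------------------------------------------

    def missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per SNP."""
        return (self.calls == MISSING).mean(axis=0)

    def het_rate(self) -> np.ndarray:
        """Heterozygous fraction among non-missing calls per SNP (NaN if all
        calls at a SNP are missing)."""
        nonmiss = (self.calls != MISSING).sum(axis=0)
        het = (self.calls == AB).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nonmiss > 0, het / nonmiss, np.nan)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (n_A, n_B) allele observation counts.

        Each non-missing diploid call contributes two observations; a
        heterozygote contributes one of each allele.
        """
        obs = self.calls != MISSING
        n_b = np.where(obs, self.calls, 0).sum(axis=0)
        n = 2 * obs.sum(axis=0)
        return n - n_b, n_b

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP from allele counts (NaN where no
        non-missing calls)."""
        n_a, n_b = self.allele_counts()
        n = n_a + n_b
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, np.minimum(n_a, n_b) / n, np.nan)
        return f


@dataclass
class GeneticMap:
    """SNP positions (centimorgan) on linkage groups.

    ``table`` has columns ``snp_id``, ``lg`` and ``cm``.  Ties in ``cm`` are
    allowed (markers co-segregating in a bin).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing_cols = {"snp_id", "lg", "cm"} - set(t.columns)
        if missing_cols:
            raise ValueError(f"genetic map missing columns {sorted(missing_cols)}")
        if t["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids in genetic map")
        if (t["cm"] < 0).any():
            raise ValueError("negative cM position in genetic map")
        self.table = t.reset_index(drop=True)

    @property
    def groups(self) -> list:
        return sorted(self.table["lg"].unique(), key=str)

    def group_span(self, lg) -> tuple[float, float]:
        pos = self.table.loc[self.table["lg"] == lg, "cm"]
        if pos.empty:
            raise KeyError(f"linkage group {lg!r} not in map")
        return float(pos.min()), float(pos.max())

    @property
    def total_length(self) -> float:
        """Sum over linkage groups of (max - min) position, in cM."""
        spans = self.table.groupby("lg")["cm"].agg(lambda s: s.max() - s.min())
        return float(spans.sum())

    def positions_for(self, snps: Sequence[str]) -> pd.DataFrame:
        sub = self.table.set_index("snp_id")
        present = [s for s in snps if s in sub.index]
        return sub.loc[present].reset_index()


@dataclass
class SubpopAssignment:
    """Sample-to-subpopulation labels; ``excluded`` marks admixed samples
    dropped from two-population contrasts."""

    labels: dict[str, str]

    def subpopulations(self) -> list[str]:
        return sorted({v for v in self.labels.values() if v != EXCLUDED})

    def samples_in(self, subpop: str) -> list[str]:
        return [s for s, v in self.labels.items() if v == subpop]

    def validate_for_contrast(self, pop1: str, pop2: str) -> None:
        for p in (pop1, pop2):
            if len(self.samples_in(p)) < 2:
                raise ValueError(
                    f"subpopulation {p!r} has fewer than 2 samples"
                )


@dataclass(frozen=True)
class FilterSpec:
    """SNP retention thresholds: missing-call rate, heterozygous-call rate
    (among non-missing calls), and minor allele frequency from allele counts.
    """

    max_missing_rate: float
    max_het_rate: float
    min_maf: float

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "max_het_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


#: thresholds used for biparental RIL populations before linkage mapping
RIL_FILTER = FilterSpec(max_missing_rate=0.20, max_het_rate=0.10, min_maf=0.25)
#: thresholds used for the diversity panel
PANEL_FILTER = FilterSpec(max_missing_rate=0.20, max_het_rate=0.20, min_maf=0.01)

FILTER_PRESETS = {"ril": RIL_FILTER, "panel": PANEL_FILTER}


def min_effective_samples(n_samples: int, max_missing_rate: float) -> int:
    """Smallest per-SNP sample count implied by a missing-rate ceiling.

    With ``n_samples`` lines and at most ``max_missing_rate`` missing calls
    allowed per SNP, every retained SNP is observed in at least
    ``ceil(n_samples * (1 - max_missing_rate))`` lines.
    """
    return math.ceil(n_samples * (1.0 - max_missing_rate))


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_fail_missing: int
    n_fail_het: int
    n_fail_maf: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"retained {self.n_retained}/{self.n_input} SNPs "
            f"(failed missing-rate: {self.n_fail_missing}, het-rate: "
            f"{self.n_fail_het}, MAF: {self.n_fail_maf})"
        )


def filter_snps(g: GenotypeMatrix, spec: FilterSpec) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop SNPs failing any of the three panel-quality criteria.

    The criteria are evaluated jointly in one pass, so the operation is
    idempotent and order-independent: a SNP failing any single criterion is
    removed.  Failure counts are reported per criterion (a SNP can fail
    several).
    """
    miss = g.missing_rate()
    het = g.het_rate()
    maf = g.maf()
    fail_missing = miss > spec.max_missing_rate
    # all-missing SNPs have NaN het/maf; they already fail the missing filter
    fail_het = np.nan_to_num(het, nan=0.0) > spec.max_het_rate
    fail_maf = np.nan_to_num(maf, nan=0.0) < spec.min_maf
    keep = ~(fail_missing | fail_het | fail_maf)
    report = FilterReport(
        n_input=g.n_snps,
        n_retained=int(keep.sum()),
        n_fail_missing=int(fail_missing.sum()),
        n_fail_het=int(fail_het.sum()),
        n_fail_maf=int(fail_maf.sum()),
    )
    if report.n_retained == 0:
        logger.warning("all %d SNPs removed by filter %s", g.n_snps, spec)
    kept_snps = [s for s, k in zip(g.snps, keep) if k]
    out = GenotypeMatrix(g.samples, kept_snps, g.calls[:, keep].copy())
    return out, report


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, dialect: str = "tsv") -> GenotypeMatrix:
    """Load a genotype matrix from ``tsv`` or ``vcf``.

    The TSV dialect has one header row of SNP ids, the first column holding
    sample ids, and calls coded ``A``/``B``/``H``/``-``.  VCF loading keeps
    biallelic records only (multi-allelic records are skipped with a logged
    count) and maps GT ``0/0``, ``1/1``, ``0/1``, ``./.`` to AA, BB, AB,
    missing.
    """
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise GenotypeLoadError(f"{path}: no SNP columns")
    sample_col = df.columns[0]
    samples = df[sample_col].tolist()
    if len(set(samples)) != len(samples):
        dup = pd.Series(samples)
        dup = dup[dup.duplicated()].iloc[0]
        raise GenotypeLoadError(f"{path}: duplicate sample id {dup!r}")
    snps = list(df.columns[1:])
    calls = np.empty((len(samples), len(snps)), dtype=np.int8)
    for j, snp in enumerate(snps):
        col = df[snp].astype(str).str.strip()
        codes = col.map(_TSV_TOKENS)
        if codes.isna().any():
            i = int(codes.isna().idxmax())
            raise GenotypeLoadError(
                f"{path}: malformed call {col.iloc[i]!r} at sample "
                f"{samples[i]!r}, SNP {snp!r}"
            )
        calls[:, j] = codes.to_numpy(dtype=np.int8)
    return GenotypeMatrix(samples, snps, calls)


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list[str] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    # cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
    remap = np.array([AA, AB, MISSING, BB], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        snps.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(remap[np.asarray(var.gt_types)])
    if n_skipped:
        logger.warning("skipped %d multi-allelic VCF records", n_skipped)
    calls = (np.stack(cols, axis=1) if cols
             else np.empty((len(samples), 0), dtype=np.int8))
    g = GenotypeMatrix(samples, snps, calls)
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    tokens = np.array([_TOKEN_OF[c] for c in (AA, AB, BB)] + ["-"])
    # map -1 -> index 3
    idx = np.where(g.calls == MISSING, 3, g.calls)
    df = pd.DataFrame(tokens[idx], index=g.samples, columns=g.snps)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_map_tsv(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"snp_id": str, "lg": str})
    return GeneticMap(df[["snp_id", "lg", "cm"]])


def write_map_tsv(gmap: GeneticMap, path: str | Path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_assignment_tsv(path: str | Path) -> SubpopAssignment:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample_id": str, "subpop": str})
    return SubpopAssignment(dict(zip(df["sample_id"], df["subpop"])))


def write_assignment_tsv(assign: SubpopAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(assign.labels), "subpop": list(assign.labels.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel diversity statistics
# ---------------------------------------------------------------------------

def heterozygosity_rate(g: GenotypeMatrix) -> float:
    """Overall fraction of heterozygous calls among non-missing calls."""
    nonmiss = int((g.calls != MISSING).sum())
    if nonmiss == 0:
        raise ValueError("all calls missing")
    return int((g.calls == AB).sum()) / nonmiss


def pairwise_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """1 - IBS-proportion distance matrix over samples.

    Per jointly non-missing SNP the shared-allele fraction is 1 for identical
    homozygotes, 0 for opposite homozygotes and 0.5 whenever either call is
    heterozygous; the distance is one minus its mean.  Pairs with no jointly
    non-missing SNP are NaN.  The matrix is symmetric with a zero diagonal.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    c = g.calls
    obs = (c != MISSING).astype(np.float64)
    hom_a = (c == AA).astype(np.float64)
    hom_b = (c == BB).astype(np.float64)
    het = (c == AB).astype(np.float64)
    n_joint = obs @ obs.T
    equal_hom = hom_a @ hom_a.T + hom_b @ hom_b.T
    het_involved = het @ obs.T + obs @ het.T - het @ het.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (equal_hom + 0.5 * het_involved) / n_joint
    dist = 1.0 - sim
    dist[n_joint == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=g.samples, columns=g.samples)


def _dosage_float(g: GenotypeMatrix) -> np.ndarray:
    d = g.calls.astype(np.float64)
    d[g.calls == MISSING] = np.nan
    return d


def ld_r2(g: GenotypeMatrix, snp1: str, snp2: str) -> float:
    """Squared Pearson correlation of allele dosages (AA=0, AB=1, BB=2)
    across samples non-missing at both SNPs.

    Raises if either SNP is monomorphic among the jointly non-missing
    samples (zero variance makes r^2 undefined).
    """
    j1, j2 = g.snp_index([snp1, snp2])
    x = g.calls[:, j1].astype(np.float64)
    y = g.calls[:, j2].astype(np.float64)
    keep = (g.calls[:, j1] != MISSING) & (g.calls[:, j2] != MISSING)
    x, y = x[keep], y[keep]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        raise ValueError(
            f"r^2 undefined for {snp1!r} vs {snp2!r}: "
            "monomorphic or insufficient joint calls"
        )
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_decay_curve(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    max_cm: float = 5.0,
    bin_cm: float = 0.25,
    r2_threshold: float = 0.2,
) -> tuple[pd.DataFrame, float | None]:
    """Mean r^2 against genetic distance, intra-linkage-group pairs only.

    All mapped SNP pairs on the same linkage group with distance <= ``max_cm``
    are binned by distance (left-closed bins of width ``bin_cm``); pairs where
    either SNP is monomorphic among the jointly called samples are skipped.
    Returns the per-bin table (``bin_left``, ``bin_mid``, ``mean_r2``,
    ``n_pairs``) and the smallest bin midpoint with mean r^2 <=
    ``r2_threshold`` (None when the curve never drops below it).
    """
    mapped = gmap.positions_for(g.snps)
    dos = _dosage_float(g)
    snp_col = {s: j for j, s in enumerate(g.snps)}
    n_bins = int(np.ceil(max_cm / bin_cm))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for lg, sub in mapped.groupby("lg"):
        sub = sub.sort_values("cm")
        pos = sub["cm"].to_numpy()
        jdx = np.array([snp_col[s] for s in sub["snp_id"]])
        hi = np.searchsorted(pos, pos + max_cm, side="right")
        for a in range(len(pos)):
            b = np.arange(a + 1, hi[a])
            if b.size == 0:
                continue
            x = dos[:, jdx[a]]
            y = dos[:, jdx[b]]
            joint = ~np.isnan(x)[:, None] & ~np.isnan(y)
            nj = joint.sum(axis=0)
            xm = np.where(joint, x[:, None], 0.0)
            ym = np.where(joint, y, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mx = xm.sum(0) / nj
                my = ym.sum(0) / nj
                sxy = (xm * ym).sum(0) - nj * mx * my
                sxx = (xm * xm).sum(0) - nj * mx * mx
                syy = (ym * ym).sum(0) - nj * my * my
                r2 = (sxy * sxy) / (sxx * syy)
            ok = (nj >= 2) & np.isfinite(r2)
            if not ok.any():
                continue
            d = pos[b[ok]] - pos[a]
            bins = np.minimum((d / bin_cm).astype(int), n_bins - 1)
            np.add.at(sums, bins, r2[ok])
            np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)
    table = pd.DataFrame(
        {
            "bin_left": np.arange(n_bins) * bin_cm,
            "bin_mid": (np.arange(n_bins) + 0.5) * bin_cm,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )
    table = table[table["n_pairs"] > 0].reset_index(drop=True)
    below = table[table["mean_r2"] <= r2_threshold]
    decay_cm = float(below["bin_mid"].iloc[0]) if not below.empty else None
    return table, decay_cm
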
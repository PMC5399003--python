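"""Model/Results interface for the selective-sweep genome scan.

:class:`SelectionScan` is built from a genotype matrix, a genetic map and a
subpopulation assignment; :meth:`SelectionScan.fit` runs the full pipeline
(per-site statistics, genomic-mean substitution, kernel-smoothed windows,
bootstrap p-values, region calling) and returns a :class:`ScanResults`
carrying the per-site, per-window and per-region tables, the genome-wide
summaries and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (
    FilterSpec,
    GeneticMap,
    GenotypeMatrix,
    SubpopAssignment,
    filter_snps,
    heterozygosity_rate,
    read_assignment_tsv,
    read_genotypes,
    read_map_tsv,
)
from .overlap import coincidence_report
from .sitestats import (
    compute_site_stats,
    estimate_divergence_f,
    genomewide_summary,
    ratio_of_sums_fst,
    substitute_undefined_fst,
)
from .windows import (
    GenomeSpec,
    RegionTotals,
    ScanConfig,
    bootstrap_pvalues,
    call_outlier_regions,
    genome_fraction,
    make_windows,
    smooth_statistic,
)

logger = logging.getLogger(__name__)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


class SelectionScan:
    """Windowed F_ST / pi-ratio selection scan between two subpopulations.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    genetic_map : GeneticMap
    assignment : SubpopAssignment
        Sample labels; samples labelled ``excluded`` or missing from the
        table are dropped (with a logged count).
    pop1, pop2 : str
        Subpopulation labels for the contrast; pi-ratio numerators come from
        ``pop1``.  Default to the first two labels in sorted order.
    config : ScanConfig
    filter_spec : FilterSpec, optional
        If given, SNPs are filtered before the scan.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        genetic_map: GeneticMap,
        assignment: SubpopAssignment,
        pop1: str | None = None,
        pop2: str | None = None,
        config: ScanConfig | None = None,
        filter_spec: FilterSpec | None = None,
    ) -> None:
        pops = assignment.subpopulations()
        if pop1 is None or pop2 is None:
            if len(pops) < 2:
                raise ValueError("need at least two subpopulations")
            pop1, pop2 = pops[0], pops[1]
        assignment.validate_for_contrast(pop1, pop2)

        known = set(genotypes.samples)
        n_unassigned = sum(1 for s in known if s not in assignment.labels)
        if n_unassigned:
            logger.info("%d genotyped samples have no assignment; excluded",
                        n_unassigned)

        self.filter_report = None
        if filter_spec is not None:
            genotypes, self.filter_report = filter_snps(genotypes, filter_spec)
            logger.info("filter: %s", self.filter_report)

        self.genotypes = genotypes
        self.genetic_map = genetic_map
        self.assignment = assignment
        self.pop1 = pop1
        self.pop2 = pop2
        self.config = config or ScanConfig()
        self.input_digests: dict[str, str] = {}

    @classmethod
    def from_files(
        cls,
        genotype_path: str | Path,
        map_path: str | Path,
        assignment_path: str | Path,
        dialect: str = "tsv",
        **kwargs,
    ) -> "SelectionScan":
        model = cls(
            read_genotypes(genotype_path, dialect=dialect),
            read_map_tsv(map_path),
            read_assignment_tsv(assignment_path),
            **kwargs,
        )
        model.input_digests = {
            "genotypes": _digest(genotype_path),
            "map": _digest(map_path),
            "assignment": _digest(assignment_path),
        }
        return model

    def fit(self, seed: int | None = None) -> "ScanResults":
        """Run the scan; all randomness (the bootstrap) is driven by ``seed``."""
        cfg = self.config
        sites = compute_site_stats(
            self.genotypes, self.genetic_map, self.assignment,
            self.pop1, self.pop2,
        )
        if sites.empty:
            raise ValueError("no mapped SNPs to scan")
        sites = substitute_undefined_fst(sites)

        scan_map = GeneticMap(
            sites[["snp_id", "lg", "cm"]].reset_index(drop=True)
        )
        windows = make_windows(scan_map, cfg)
        windows = smooth_statistic(sites, windows, cfg)
        windows = bootstrap_pvalues(sites, windows, cfg, seed=seed)
        regions, totals = call_outlier_regions(windows, cfg, scan_map)

        summary = genomewide_summary(sites)
        manifest = {
            "package_version": __version__,
            "seed": seed,
            "pop1": self.pop1,
            "pop2": self.pop2,
            "window_cm": cfg.window_cm,
            "step_cm": cfg.step_cm,
            "alpha": cfg.alpha,
            "n_boot": cfg.n_boot,
            "kernel": cfg.kernel,
            "n_samples": self.genotypes.n_samples,
            "n_snps_input": self.genotypes.n_snps,
            "n_snps_mapped": len(sites),
            "n_fst_substituted": int(sites["substituted"].sum()),
            "n_windows": len(windows),
            "input_digests": self.input_digests,
            "filter": (
                None if self.filter_report is None else vars(self.filter_report)
            ),
            "region_length_rule": "window-extent union (centre-span also reported)",
        }
        return ScanResults(
            model=self,
            site_stats=sites,
            windows=windows,
            regions=regions,
            region_totals=totals,
            overall_fst=summary.mean_fst,
            mean_pi_pop1=summary.mean_pi_pop1,
            mean_pi_pop2=summary.mean_pi_pop2,
            seed=seed,
            manifest=manifest,
        )


@dataclass
class ScanResults:
    """Fitted selection-scan results.

    Attributes
    ----------
    site_stats : DataFrame
        Per-SNP table (snp_id, lg, cm, n_pop1, n_pop2, pi_pop1, pi_pop2,
        pi_pooled, fst, substituted).
    windows : DataFrame
        Per-window table (lg, center_cm, start/end, k, smoothed means,
        pi_ratio, p_fst, p_ratio, sig flags).
    regions : DataFrame
        Merged significant regions per statistic with cM spans.
    """

    model: SelectionScan
    site_stats: pd.DataFrame
    windows: pd.DataFrame
    regions: pd.DataFrame
    region_totals: RegionTotals
    overall_fst: float
    mean_pi_pop1: float
    mean_pi_pop2: float
    seed: int | None
    manifest: dict = field(default_factory=dict)

    # -- derived summaries -------------------------------------------------

    def fst_ratio_of_sums(self) -> float:
        return ratio_of_sums_fst(self.site_stats)

    def divergence_f_estimate(self) -> float:
        return estimate_divergence_f(self.site_stats)

    def heterozygosity(self) -> float:
        return heterozygosity_rate(self.model.genotypes)

    def genome_fractions(self, genome: GenomeSpec | None = None) -> dict[str, float]:
        """Percent of the map covered by significant regions, per statistic.

        With no explicit :class:`GenomeSpec` the denominator is the scan
        map's own total length.
        """
        if genome is None:
            genome = GenomeSpec(
                total_map_length_cm=self.model.genetic_map.total_length,
                genome_size_mb=630.0,
            )
        return {
            stat: genome_fraction(total, genome)
            for stat, total in self.region_totals.window_extent.items()
        }

    def coincidence(self, catalog: pd.DataFrame, scan_label: str = "scan",
                    ld_halfwidth_cm: float = 2.0) -> pd.DataFrame:
        return coincidence_report(
            catalog, {scan_label: self.regions}, ld_halfwidth_cm
        )

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        fr = self.genome_fractions()
        n_sig_f = int(self.windows["sig_fst"].sum())
        n_sig_r = int(self.windows["sig_ratio"].sum())
        lines = [
            "Selective-sweep genome scan",
            "=" * 64,
            f"Contrast:            {self.model.pop1} vs {self.model.pop2}",
            f"Samples:             {self.model.genotypes.n_samples}"
            f"  (pop1 {len(self.model.assignment.samples_in(self.model.pop1))},"
            f" pop2 {len(self.model.assignment.samples_in(self.model.pop2))})",
            f"Mapped SNPs:         {len(self.site_stats)}"
            f"  (F_ST substituted at {int(self.site_stats['substituted'].sum())})",
            f"Windows:             {len(self.windows)}"
            f"  ({cfg.window_cm} cM, step {cfg.step_cm} cM, kernel {cfg.kernel})",
            f"Bootstrap:           n_boot={cfg.n_boot}, alpha={cfg.alpha},"
            f" seed={self.seed}",
            "-" * 64,
            f"Mean F_ST (sites):   {self.overall_fst:.4f}"
            f"   (ratio-of-sums {self.fst_ratio_of_sums():.4f})",
            f"Mean pi pop1:        {self.mean_pi_pop1:.4f}",
            f"Mean pi pop2:        {self.mean_pi_pop2:.4f}",
            f"pi1/pi2 (means):     "
            f"{self.mean_pi_pop1 / self.mean_pi_pop2:.3f}",
            "-" * 64,
            f"Significant windows: F_ST {n_sig_f}, pi-ratio {n_sig_r}",
        ]
        for stat in ("fst", "pi_ratio"):
            n_reg = int((self.regions["statistic"] == stat).sum())
            tot = self.region_totals.window_extent.get(stat, 0.0)
            lines.append(
                f"Regions ({stat:8s}):  {n_reg} totalling {tot:.2f} cM"
                f" ({fr[stat]:.2f}% of map)"
            )
        return "\n".join(lines)

    def plot(self, statistic: str = "fst", ax=None):
        """Manhattan-style track of window means with significant regions
        shaded; never load-bearing for analysis."""
        import matplotlib.pyplot as plt

        col = {"fst": "fst_mean", "pi_ratio": "pi_ratio"}[statistic]
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        offset = 0.0
        ticks, labels = [], []
        for lg, sub in self.windows.groupby("lg"):
            x = sub["center_cm"] + offset
            ax.plot(x, sub[col], ".", ms=2)
            for _, r in self.regions[
                (self.regions["lg"] == lg)
                & (self.regions["statistic"] == statistic)
            ].iterrows():
                ax.axvspan(r["start_cm"] + offset, r["end_cm"] + offset,
                           color="purple", alpha=0.25, lw=0)
            ticks.append(offset + sub["center_cm"].median())
            labels.append(str(lg))
            offset += sub["center_cm"].max() + 5.0
        ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
        ax.set_ylabel({"fst": "window $F_{ST}$",
                       "pi_ratio": r"window $\pi_1/\pi_2$"}[statistic])
        return ax

    # -- output ------------------------------------------------------------

    def to_tsv(self, outdir: str | Path) -> dict[str, Path]:
        """Write per-site, per-window and per-region TSVs plus the manifest.

        Every file starts with ``#`` metadata lines followed by a plain
        header row; the region file uses cM coordinates (BED-like but not
        base-pair BED).
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        meta = [f"# {k}={v}" for k, v in self.manifest.items()
                if k != "input_digests"]

        def _write(df: pd.DataFrame, name: str, columns=None) -> None:
            p = outdir / name
            with open(p, "w") as fh:
                fh.write("\n".join(meta) + "\n")
                (df if columns is None else df[columns]).to_csv(
                    fh, sep="\t", index=False, float_format="%.6g"
                )
            paths[name] = p

        _write(self.site_stats, "site_stats.tsv")
        _write(
            self.windows, "windows.tsv",
            ["lg", "center_cm", "k", "fst_mean", "pi_pop1_mean",
             "pi_pop2_mean", "pi_ratio", "p_fst", "p_ratio",
             "sig_fst", "sig_ratio"],
        )
        _write(self.regions, "regions.tsv")
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(self.manifest, indent=2, default=str))
        paths["manifest.json"] = mpath
        return paths


def read_regions_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"lg": str})
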
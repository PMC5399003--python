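"""Trait-locus catalogs, LD-block SNP clustering, and coincidence between
candidate sweep regions and known loci.

Association hits closer than 2 cM on the same linkage group are chained into
one LD-block cluster.  A qualitative gene/QTL coincides with a sweep region
when its tagging SNP position falls inside the region span; a GWAS hit
coincides when its surrounding LD block (2 cM either side of the SNP)
overlaps the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("gwas", "qualitative")

CATALOG_COLUMNS = ["locus_id", "trait", "lg", "cm", "mode", "source"]


def read_catalog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"locus_id": str, "trait": str, "lg": str,
                            "mode": str, "source": str})
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns {sorted(missing)}")
    bad = ~df["mode"].isin(MODES)
    if bad.any():
        raise ValueError(f"unknown catalog mode {df.loc[bad, 'mode'].iloc[0]!r}")
    return df[CATALOG_COLUMNS]


def cluster_snps(catalog: pd.DataFrame, gap_cm: float = 2.0) -> pd.DataFrame:
    """Chain mapped SNPs into LD-block clusters per linkage group.

    Single-linkage chaining: after sorting by position, consecutive SNPs
    strictly less than ``gap_cm`` apart join the same cluster.  Rows with a
    missing position (NaN cm or lg) are excluded with a warning.  Returns one
    row per cluster: cluster_id, lg, start_cm, end_cm, n_snps, members.
    """
    mapped = catalog.dropna(subset=["lg", "cm"])
    n_unmapped = len(catalog) - len(mapped)
    if n_unmapped:
        logger.warning("excluding %d unmapped catalog SNPs from clustering",
                       n_unmapped)
    clusters = []
    for lg, sub in mapped.groupby("lg", sort=True):
        sub = sub.sort_values("cm")
        pos = sub["cm"].to_numpy(dtype=float)
        ids = sub["locus_id"].tolist()
        breaks = np.where(np.diff(pos) >= gap_cm)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            clusters.append(
                {
                    "lg": lg,
                    "start_cm": float(pos[a]),
                    "end_cm": float(pos[b - 1]),
                    "n_snps": int(b - a),
                    "members": ",".join(ids[a:b]),
                }
            )
    out = pd.DataFrame(clusters,
                       columns=["lg", "start_cm", "end_cm", "n_snps", "members"])
    out.insert(0, "cluster_id", [f"cluster_{i + 1}" for i in range(len(out))])
    return out


@dataclass
class CoincidenceCall:
    locus_id: str
    coincident: bool
    regions: list  # indices of matched region rows
    rule: str


def coincide(
    locus: pd.Series,
    regions: pd.DataFrame,
    ld_halfwidth_cm: float = 2.0,
) -> CoincidenceCall:
    """Test one catalog locus against a merged region table.

    Qualitative loci must have their tagging SNP inside a region's half-open
    span [start_cm, end_cm); GWAS loci coincide when the closed LD block
    [cm - h, cm + h] overlaps a region, touching included.
    """
    same_lg = regions[regions["lg"] == locus["lg"]]
    cm = float(locus["cm"])
    if locus["mode"] == "qualitative":
        hit = same_lg[(same_lg["start_cm"] <= cm) & (cm < same_lg["end_cm"])]
        rule = "point-in-region"
    elif locus["mode"] == "gwas":
        lo, hi = cm - ld_halfwidth_cm, cm + ld_halfwidth_cm
        hit = same_lg[(same_lg["start_cm"] <= hi) & (same_lg["end_cm"] >= lo)]
        rule = f"ld-block-overlap(h={ld_halfwidth_cm})"
    else:
        raise ValueError(f"unknown locus mode {locus['mode']!r}")
    return CoincidenceCall(
        locus_id=str(locus["locus_id"]),
        coincident=not hit.empty,
        regions=list(hit.index),
        rule=rule,
    )


def coincidence_report(
    catalog: pd.DataFrame,
    regions_by_scan: dict[str, pd.DataFrame],
    ld_halfwidth_cm: float = 2.0,
    pod_length_trait: str = "pod length",
) -> pd.DataFrame:
    """Locus-by-region coincidence table across one or more scans.

    ``regions_by_scan`` maps a scan label (e.g. ``"domestication"``,
    ``"improvement"``) to its merged region table.  The report has one row
    per (scan, region), listing coincident loci grouped by trait, counts of
    pod-length vs other-trait loci, and whether the region is specific to
    that scan (no positional overlap with any region of the other scans).
    Use :func:`report_counts` for the per-scan totals.
    """
    rows = []
    for scan, regions in regions_by_scan.items():
        other = [r for s, r in regions_by_scan.items() if s != scan]
        for ridx, region in regions.iterrows():
            hits = []
            for _, locus in catalog.iterrows():
                call = coincide(locus, regions, ld_halfwidth_cm)
                if ridx in call.regions:
                    hits.append(locus)
            traits = sorted({str(h["trait"]) for h in hits})
            n_pod = sum(str(h["trait"]) == pod_length_trait for h in hits)
            specific = not any(
                _regions_overlap(region, o) for o in other
            ) if other else False
            rows.append(
                {
                    "scan": scan,
                    "lg": region["lg"],
                    "start_cm": region["start_cm"],
                    "end_cm": region["end_cm"],
                    "statistic": region["statistic"],
                    "loci": ",".join(str(h["locus_id"]) for h in hits),
                    "traits": ";".join(traits),
                    "n_pod_length": n_pod,
                    "n_other_traits": len(hits) - n_pod,
                    "scan_specific": bool(specific),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["scan", "lg", "start_cm", "end_cm", "statistic", "loci",
                 "traits", "n_pod_length", "n_other_traits", "scan_specific"],
    )


def _regions_overlap(region: pd.Series, others: pd.DataFrame) -> bool:
    same = others[others["lg"] == region["lg"]]
    return bool(
        (
            (same["start_cm"] < region["end_cm"])
            & (same["end_cm"] > region["start_cm"])
        ).any()
    )


def report_counts(report: pd.DataFrame) -> pd.DataFrame:
    """Per-scan totals: regions coincident with pod-length loci, with
    other-trait loci, and scan-specific regions."""
    rows = []
    for scan, sub in report.groupby("scan"):
        rows.append(
            {
                "scan": scan,
                "n_regions": len(sub),
                "n_regions_pod_length": int((sub["n_pod_length"] > 0).sum()),
                "n_regions_other_traits": int(
                    ((sub["n_pod_length"] == 0) & (sub["n_other_traits"] > 0)).sum()
                ),
                "n_scan_specific": int(sub["scan_specific"].sum()),
            }
        )
    return pd.DataFrame(rows)
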
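"""Synthetic two-subpopulation inbred SNP panels with planted sweeps.

The generator emulates a diversity panel of essentially homozygous lines
drawn from two diverged subgene pools, the setting the scan statistics
assume: ~25-30 k biallelic SNPs on 11 linkage groups, background divergence
from a Balding-Nichols model, genome-wide diversity loss in subpopulation 2
(the bottlenecked pool), a few percent residual heterozygosity and missing
calls, and planted sweep regions of elevated divergence and depressed
subpopulation-2 diversity.  A truth table records every planted quantity so
recovery can be scored.

Model
-----
SNP positions are uniform on each linkage group.  Ancestral allele
frequencies are p ~ Uniform(0.05, 0.95).  Each subpopulation's frequency is
drawn from Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance
F p(1-p).  Subpopulation 1 uses ``background_F`` everywhere.  Subpopulation
2 — the bottlenecked pool — uses ``background_F`` outside sweeps and
``sweep_F`` inside, and its frequencies are then pushed toward the nearer
fixation boundary genome-wide by ``pop2_diversity_loss``
(f -> f(1-d) if f < 1/2 else f + (1-f) d), emulating the diversity lost in
its founding bottleneck.  Inside a sweep the swept haplotype carries, at
each site, the ancestrally minor (putatively derived) allele with
probability 1 - p; subpopulation 2 is pushed toward that allele's fixation
boundary by the sweep's ``diversity_loss`` (1.0 = hard sweep), which both
depresses pi_2 and creates strong divergence from subpopulation 1.  Each
inbred line is homozygous BB with probability f, else AA; heterozygous
calls then overwrite at ``het_rate`` and missing calls at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    AA,
    AB,
    BB,
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    SubpopAssignment,
)

POP1 = "pop1"
POP2 = "pop2"


@dataclass(frozen=True)
class Sweep:
    """A planted sweep: elevated divergence and depressed subpopulation-2
    diversity over [start_cm, end_cm] on one linkage group.

    ``sweep_F`` is the Balding-Nichols divergence of subpopulation 2's
    pre-sweep frequencies inside the span; ``diversity_loss`` is how far
    those frequencies are then pushed toward fixation of the swept allele
    (1.0 = a hard sweep that fixes it)."""

    lg: str
    start_cm: float
    end_cm: float
    sweep_F: float = 0.5
    diversity_loss: float = 1.0

    def __post_init__(self) -> None:
        if self.end_cm <= self.start_cm:
            raise ValueError("sweep end must exceed start")
        if not 0 <= self.sweep_F < 1 or not 0 <= self.diversity_loss <= 1:
            raise ValueError("sweep parameters outside valid range")


def default_sweeps() -> list[Sweep]:
    return [
        Sweep("LG01", 10.0, 14.0),
        Sweep("LG03", 30.0, 34.0),
        Sweep("LG06", 50.0, 54.0),
        Sweep("LG09", 20.0, 24.0),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults reproduce the study conditions of the cowpea diversity panel
    the statistics were built for: subpopulation sizes 79 (grain/short-pod
    pool) and 99 (vegetable/long-pod pool), 11 linkage groups totalling
    ~837 cM, ~27 500 mapped SNPs, divergence parameter 0.26, a genome-wide
    subpopulation-2 diversity loss of 0.65 (calibrated so mean pi_2 lands
    near 0.13 against pi_1 near 0.27), 2% residual heterozygosity and 3%
    missing calls, plus four planted sweeps.
    """

    n_pop1: int = 79
    n_pop2: int = 99
    n_lg: int = 11
    map_length_per_lg_cm: float = 76.1
    n_snps: int = 27_500
    background_F: float = 0.26
    pop2_diversity_loss: float = 0.65
    sweeps: tuple[Sweep, ...] = field(default_factory=lambda: tuple(default_sweeps()))
    het_rate: float = 0.02
    missing_rate: float = 0.03
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_pop1, self.n_pop2) < 2:
            raise ValueError("each subpopulation needs >= 2 samples")
        if not 0 <= self.background_F < 1:
            raise ValueError("background_F must be in [0, 1)")
        for r in (self.het_rate, self.missing_rate, self.pop2_diversity_loss):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        lgs = {f"LG{i + 1:02d}" for i in range(self.n_lg)}
        for sw in self.sweeps:
            if sw.lg not in lgs:
                raise ValueError(f"sweep on unknown linkage group {sw.lg!r}")
            if sw.start_cm < 0 or sw.end_cm > self.map_length_per_lg_cm:
                raise ValueError(
                    f"sweep [{sw.start_cm}, {sw.end_cm}] outside map bounds "
                    f"[0, {self.map_length_per_lg_cm}]"
                )


def scaled_down(seed: int | None = None, **overrides) -> SimConfig:
    """A small configuration for tests and quick runs: 2 linkage groups of
    20 cM, 2000 SNPs, one 4 cM sweep per group."""
    base = dict(
        n_pop1=79,
        n_pop2=99,
        n_lg=2,
        map_length_per_lg_cm=20.0,
        n_snps=2000,
        sweeps=(Sweep("LG01", 8.0, 12.0), Sweep("LG02", 13.0, 17.0)),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class TruthTable:
    """Ground truth per SNP (ancestral and subpopulation frequencies,
    in-sweep flag) and the planted sweep spans."""

    snps: pd.DataFrame  # snp_id, lg, cm, p_anc, f_pop1, f_pop2, in_sweep
    sweeps: tuple[Sweep, ...]

    def sweep_spans(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lg": s.lg,
                    "start_cm": s.start_cm,
                    "end_cm": s.end_cm,
                    "sweep_F": s.sweep_F,
                    "diversity_loss": s.diversity_loss,
                }
                for s in self.sweeps
            ]
        )


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    genetic_map: GeneticMap
    assignment: SubpopAssignment
    truth: TruthTable
    config: SimConfig


def _push_to_boundary(f: np.ndarray, d) -> np.ndarray:
    """Move frequencies toward the nearer fixation boundary by factor d."""
    return np.where(f < 0.5, f * (1.0 - d), f + (1.0 - f) * d)


def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies: Beta with mean p and
    variance F p (1-p); degenerate at p where F = 0."""
    f = p.copy()
    pos = F > 0
    if pos.any():
        a = p[pos] * (1.0 - F[pos]) / F[pos]
        b = (1.0 - p[pos]) * (1.0 - F[pos]) / F[pos]
        f[pos] = rng.beta(a, b)
    return f


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a genotype matrix, genetic map, subpopulation assignment and
    truth table under ``cfg`` (fully reproducible given ``cfg.seed``)."""
    rng = np.random.default_rng(cfg.seed)
    lgs = [f"LG{i + 1:02d}" for i in range(cfg.n_lg)]

    lg_of = rng.integers(0, cfg.n_lg, size=cfg.n_snps)
    cm = rng.uniform(0.0, cfg.map_length_per_lg_cm, size=cfg.n_snps)
    order = np.lexsort((cm, lg_of))
    lg_of, cm = lg_of[order], cm[order]
    snp_ids = [f"snp_{i + 1:06d}" for i in range(cfg.n_snps)]
    lg_labels = np.array(lgs, dtype=object)[lg_of]

    p = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    # a sweep acts in subpopulation 2 only: pop1 keeps background divergence
    # and diversity everywhere, pop2 drifts at sweep_F and loses diversity
    # inside sweeps
    F2 = np.full(cfg.n_snps, cfg.background_F)
    sweep_loss = np.zeros(cfg.n_snps)
    in_sweep = np.zeros(cfg.n_snps, dtype=bool)
    for sw in cfg.sweeps:
        inside = (lg_labels == sw.lg) & (cm >= sw.start_cm) & (cm <= sw.end_cm)
        in_sweep |= inside
        F2[inside] = sw.sweep_F
        sweep_loss[inside] = sw.diversity_loss

    f1 = _bn_draw(rng, p, np.full(cfg.n_snps, cfg.background_F))
    # background bottleneck: pop2 frequencies drift toward the nearer
    # fixation boundary genome-wide
    f2 = _push_to_boundary(_bn_draw(rng, p, F2), cfg.pop2_diversity_loss)
    # inside sweeps the swept haplotype carries, at each site, the
    # ancestrally minor (putatively derived) allele with probability 1 - p;
    # pop2 is pushed toward that allele's boundary by the sweep's
    # diversity_loss on top of the background loss
    swept_is_b = rng.random(cfg.n_snps) < (1.0 - p)
    target = np.where(swept_is_b, 1.0, 0.0)
    f2_swept = f2 + (target - f2) * sweep_loss
    f2 = np.where(in_sweep, f2_swept, f2)

    n_total = cfg.n_pop1 + cfg.n_pop2
    freqs = np.concatenate(
        [np.tile(f1, (cfg.n_pop1, 1)), np.tile(f2, (cfg.n_pop2, 1))]
    )
    calls = np.where(rng.random((n_total, cfg.n_snps)) < freqs, BB, AA).astype(np.int8)
    u = rng.random((n_total, cfg.n_snps))
    calls[u < cfg.het_rate] = AB
    v = rng.random((n_total, cfg.n_snps))
    calls[v < cfg.missing_rate] = MISSING

    samples = [f"p1_{i + 1:03d}" for i in range(cfg.n_pop1)] + [
        f"p2_{i + 1:03d}" for i in range(cfg.n_pop2)
    ]
    genotypes = GenotypeMatrix(samples, snp_ids, calls)
    gmap = GeneticMap(pd.DataFrame({"snp_id": snp_ids, "lg": lg_labels, "cm": cm}))
    labels = {s: (POP1 if s.startswith("p1_") else POP2) for s in samples}
    assignment = SubpopAssignment(labels)
    truth = TruthTable(
        snps=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "lg": lg_labels,
                "cm": cm,
                "p_anc": p,
                "f_pop1": f1,
                "f_pop2": f2,
                "in_sweep": in_sweep,
            }
        ),
        sweeps=tuple(cfg.sweeps),
    )
    return SimResult(genotypes, gmap, assignment, truth, cfg)


def make_catalog(
    truth: TruthTable,
    n_true_loci: int,
    n_decoy_loci: int,
    seed: int | None = None,
    decoy_margin_cm: float = 3.0,
) -> pd.DataFrame:
    """A trait-locus catalog with loci planted inside sweeps (true) and far
    outside them (decoys), modes alternating gwas/qualitative.

    Decoys are placed at least ``decoy_margin_cm`` beyond the GWAS LD
    half-width (2 cM) from every sweep boundary so they can never coincide
    with perfectly recovered regions.
    """
    rng = np.random.default_rng(seed)
    spans = truth.sweep_spans()
    if n_true_loci > 0 and spans.empty:
        raise ValueError("no planted sweeps to place true loci in")
    rows = []
    for i in range(n_true_loci):
        sw = spans.iloc[int(rng.integers(0, len(spans)))]
        rows.append(
            {
                "locus_id": f"true_{i + 1:03d}",
                "trait": "pod length" if i % 2 == 0 else "seed size",
                "lg": sw["lg"],
                "cm": float(rng.uniform(sw["start_cm"], sw["end_cm"])),
                "mode": "gwas" if i % 2 == 0 else "qualitative",
                "source": "synthetic-truth",
            }
        )
    lg_extent = truth.snps.groupby("lg")["cm"].agg(["min", "max"])
    keep_out = 2.0 + decoy_margin_cm
    placed = 0
    attempts = 0
    while placed < n_decoy_loci and attempts < 1000 * max(1, n_decoy_loci):
        attempts += 1
        lg = lg_extent.index[int(rng.integers(0, len(lg_extent)))]
        cm = float(rng.uniform(lg_extent.loc[lg, "min"], lg_extent.loc[lg, "max"]))
        near = spans[(spans["lg"] == lg)
                     & (spans["start_cm"] - keep_out <= cm)
                     & (cm <= spans["end_cm"] + keep_out)]
        if not near.empty:
            continue
        placed += 1
        rows.append(
            {
                "locus_id": f"decoy_{placed:03d}",
                "trait": "flower colour",
                "lg": lg,
                "cm": cm,
                "mode": "gwas" if placed % 2 == 0 else "qualitative",
                "source": "synthetic-decoy",
            }
        )
    if placed < n_decoy_loci:
        raise RuntimeError("could not place all decoy loci outside sweeps")
    return pd.DataFrame(
        rows, columns=["locus_id", "trait", "lg", "cm", "mode", "source"]
    )


def write_config(cfg: SimConfig, path: str | Path) -> None:
    """Flat key=value dump of a SimConfig (sweeps as a compact list)."""
    lines = []
    for k, v in cfg.__dict__.items():
        if k == "sweeps":
            v = ";".join(
                f"{s.lg}:{s.start_cm}-{s.end_cm}:{s.sweep_F}:{s.diversity_loss}"
                for s in cfg.sweeps
            )
        lines.append(f"{k}={v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> SimConfig:
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        kv[k.strip()] = v.strip()
    sweeps = []
    for part in filter(None, kv.pop("sweeps", "").split(";")):
        lg, span, sf, dl = part.split(":")
        a, _, b = span.partition("-")
        sweeps.append(Sweep(lg, float(a), float(b), float(sf), float(dl)))
    ints = {"n_pop1", "n_pop2", "n_lg", "n_snps", "seed"}
    args = {}
    for k, v in kv.items():
        if v == "None":
            args[k] = None
        elif k in ints:
            args[k] = int(v)
        else:
            args[k] = float(v)
    return SimConfig(sweeps=tuple(sweeps), **args)


@dataclass
class RecoveryScore:
    """How well a fitted scan recovered the planted sweeps.

    Recall counts planted-sweep windows (centre inside a planted span) that
    were called significant; the false-length fraction is the share of
    called region length lying outside every planted span.
    """

    recall_fst: float
    recall_ratio: float
    recall_any: float
    false_length_fst: float
    false_length_ratio: float
    n_planted_windows: int


def score_recovery(windows: pd.DataFrame, regions: pd.DataFrame,
                   truth: TruthTable) -> RecoveryScore:
    """Score a scan's windows and regions against the planted truth."""
    spans = truth.sweep_spans()

    def inside(lg, c) -> bool:
        sub = spans[spans["lg"] == lg]
        return bool(((sub["start_cm"] <= c) & (c <= sub["end_cm"])).any())

    planted = np.array(
        [inside(lg, c) for lg, c in zip(windows["lg"], windows["center_cm"])]
    )
    if not planted.any():
        raise ValueError("no windows fall inside planted sweeps")
    sig_f = windows["sig_fst"].fillna(False).to_numpy(dtype=bool)
    sig_r = windows["sig_ratio"].fillna(False).to_numpy(dtype=bool)

    def false_fraction(stat: str) -> float:
        sub = regions[regions["statistic"] == stat]
        total = float(sub["length_cm"].sum())
        if total == 0:
            return float("nan")
        outside = 0.0
        for _, r in sub.iterrows():
            sw = spans[spans["lg"] == r["lg"]]
            covered = sum(
                max(0.0, min(r["end_cm"], s["end_cm"]) - max(r["start_cm"], s["start_cm"]))
                for _, s in sw.iterrows()
            )
            outside += r["length_cm"] - covered
        return outside / total

    return RecoveryScore(
        recall_fst=float(sig_f[planted].mean()),
        recall_ratio=float(sig_r[planted].mean()),
        recall_any=float((sig_f | sig_r)[planted].mean()),
        false_length_fst=false_fraction("fst"),
        false_length_ratio=false_fraction("pi_ratio"),
        n_planted_windows=int(planted.sum()),
    )
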
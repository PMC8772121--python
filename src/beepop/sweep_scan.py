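"""Selective-sweep scan from joint Fst and theta-pi-ratio window outliers.

The scan contrasts a candidate cohort against a reference cohort in
sliding windows (default 20 kb, 10 kb step): per window it computes the
Weir-Cockerham Fst between the cohorts and nucleotide diversity within
each, Z-transforms the Fst values across windows, log2-transforms the
diversity ratio pi_reference / pi_candidate, and selects windows lying
in the upper tail of both distributions (default top 5% each,
intersected).  Selected windows are merged into regions and annotated
with overlapping genes.

A sweep in the candidate cohort depletes its local diversity and
elevates differentiation, so it surfaces as a jointly large Z(Fst) and
log2 ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GeneRecord, GenomicWindow, GenotypeMatrix, PopulationMap
from .popgen_stats import wc_fst_window, window_pi

__all__ = [
    "SweepWindow",
    "SweepRegion",
    "compute_sweep_stats",
    "z_transform",
    "attach_z_scores",
    "select_top_intersection",
    "merge_regions",
    "overlap_genes",
    "sweep_table",
]


@dataclass
class SweepWindow:
    """One genomic window of the sweep scan."""

    window: GenomicWindow
    n_sites: int
    fst: float
    pi_candidate: float
    pi_reference: float
    log2_ratio: float = float("nan")
    z_fst: float = float("nan")
    rankable: bool = False
    selected_fst: bool = False
    selected_pi: bool = False

    @property
    def selected(self) -> bool:
        return self.selected_fst and self.selected_pi


@dataclass
class SweepRegion:
    """Merged interval of selected windows, with implicated genes."""

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_z_fst: float
    peak_log2_ratio: float
    genes: list[str] = field(default_factory=list)


def z_transform(values: Sequence[float]) -> np.ndarray:
    """Standardize to zero mean and unit sample standard deviation (n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to Z-transform")
    if not np.all(np.isfinite(x)):
        raise ValueError("Z-transform requires finite values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("Z-transform undefined for zero spread")
    return (x - x.mean()) / sd


def compute_sweep_stats(
    g: GenotypeMatrix,
    candidate: Sequence[str],
    reference: Sequence[str],
    size: int = 20_000,
    step: int = 10_000,
    min_sites: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> list[SweepWindow]:
    """Per-window Fst between cohorts and pi within each cohort.

    Windows with fewer than ``min_sites`` usable SNPs, a non-finite
    Fst, or zero diversity in either cohort are kept in the output but
    flagged unrankable (they carry no Z-score and cannot be selected).
    Z-scores are computed across the rankable windows.
    """
    cand = list(candidate)
    ref = list(reference)
    if set(cand) & set(ref):
        raise ValueError("candidate and reference cohorts overlap")
    if len(cand) < 2 or len(ref) < 2:
        raise ValueError("each cohort needs at least 2 samples")
    if chrom_lengths is None:
        chrom_lengths = {}
        for s in g.sites:
            chrom_lengths[s.chrom] = max(chrom_lengths.get(s.chrom, 0), s.pos)
    from .genotype_io import make_windows

    windows = make_windows(chrom_lengths, size, step)
    two_pop = PopulationMap(
        {**{s: "candidate" for s in cand}, **{s: "reference" for s in ref}}
    )
    fst_stats = wc_fst_window(g, two_pop, windows)
    pi_cand = window_pi(g, windows, samples=cand)
    pi_ref = window_pi(g, windows, samples=ref)

    out: list[SweepWindow] = []
    for wf, wc, wr in zip(fst_stats, pi_cand, pi_ref):
        pc, pr = wc.pi, wr.pi
        rankable = (
            wf.n_sites >= min_sites
            and math.isfinite(wf.fst)
            and pc > 0.0
            and pr > 0.0
        )
        log2_ratio = math.log2(pr / pc) if pc > 0 and pr > 0 else float("nan")
        out.append(
            SweepWindow(
                window=wf.window,
                n_sites=wf.n_sites,
                fst=wf.fst,
                pi_candidate=pc,
                pi_reference=pr,
                log2_ratio=log2_ratio,
                rankable=rankable,
            )
        )
    n_excluded = sum(1 for w in out if not w.rankable)
    if n_excluded:
        warnings.warn(
            f"{n_excluded} of {len(out)} windows excluded from ranking "
            f"(min_sites={min_sites} or zero diversity)",
            stacklevel=2,
        )
    attach_z_scores(out)
    return out


def attach_z_scores(wins: list[SweepWindow]) -> None:
    """Z-transform Fst across the rankable windows, in place."""
    rank = [w for w in wins if w.rankable]
    if len(rank) < 2:
        return
    z = z_transform([w.fst for w in rank])
    for w, zv in zip(rank, z):
        w.z_fst = float(zv)


def select_top_intersection(
    wins: Sequence[SweepWindow], q: float = 0.05, two_tailed_pi: bool = False
) -> list[SweepWindow]:
    """Windows in the top ``q`` tail of both Z(Fst) and log2 pi ratio.

    Thresholds are empirical quantiles over the rankable windows using
    the 'higher' convention, so each threshold is an observed value and
    ties at the threshold are included.  With ``two_tailed_pi`` the
    lower pi tail (reference-depleted) also qualifies, each tail at q.
    Flags are set in place; the selected windows are returned.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    rank = [w for w in wins if w.rankable]
    if len(rank) < 20:
        raise ValueError("need at least 20 rankable windows to set quantiles")
    if len(rank) < 1.0 / q:
        warnings.warn(
            f"only {len(rank)} rankable windows for q={q}; thresholds are coarse",
            stacklevel=2,
        )
    z = np.array([w.z_fst for w in rank])
    lr = np.array([w.log2_ratio for w in rank])
    z_thr = float(np.quantile(z, 1 - q, method="higher"))
    pi_hi = float(np.quantile(lr, 1 - q, method="higher"))
    pi_lo = float(np.quantile(lr, q, method="lower")) if two_tailed_pi else None
    for w in wins:
        w.selected_fst = w.rankable and w.z_fst >= z_thr
        w.selected_pi = w.rankable and (
            w.log2_ratio >= pi_hi
            or (pi_lo is not None and w.log2_ratio <= pi_lo)
        )
    return [w for w in wins if w.selected]


def merge_regions(
    selected: Sequence[SweepWindow], gap: int = 0
) -> list[SweepRegion]:
    """Merge overlapping/abutting selected windows (within ``gap`` bp)."""
    wins = sorted(selected, key=lambda w: (w.window.chrom, w.window.start))
    regions: list[SweepRegion] = []
    for w in wins:
        if (
            regions
            and regions[-1].chrom == w.window.chrom
            and w.window.start <= regions[-1].end + gap
        ):
            r = regions[-1]
            r.end = max(r.end, w.window.end)
            r.n_windows += 1
            r.peak_z_fst = max(r.peak_z_fst, w.z_fst)
            r.peak_log2_ratio = max(r.peak_log2_ratio, w.log2_ratio)
        else:
            regions.append(
                SweepRegion(
                    chrom=w.window.chrom,
                    start=w.window.start,
                    end=w.window.end,
                    n_windows=1,
                    peak_z_fst=w.z_fst,
                    peak_log2_ratio=w.log2_ratio,
                )
            )
    return regions


def overlap_genes(
    regions: Sequence[SweepRegion], genes: Sequence[GeneRecord]
) -> tuple[list[SweepRegion], list[str]]:
    """Assign genes overlapping each region by >= 1 bp (strand ignored).

    Returns the regions (gene lists filled in place) and the flat,
    deduplicated, sorted list of implicated gene ids.
    """
    flat: set[str] = set()
    for r in regions:
        hits = [
            gn.gene_id
            for gn in genes
            if gn.chrom == r.chrom and gn.start < r.end and r.start < gn.end
        ]
        r.genes = sorted(set(hits))
        flat.update(hits)
    return list(regions), sorted(flat)


def sweep_table(wins: Sequence[SweepWindow]) -> pd.DataFrame:
    """Per-window scan table (start printed 1-based inclusive)."""
    return pd.DataFrame(
        {
            "chrom": [w.window.chrom for w in wins],
            "start": [w.window.start + 1 for w in wins],
            "end": [w.window.end for w in wins],
            "n_sites": [w.n_sites for w in wins],
            "fst": [w.fst for w in wins],
            "z_fst": [w.z_fst for w in wins],
            "pi_cand": [w.pi_candidate for w in wins],
            "pi_ref": [w.pi_reference for w in wins],
            "log2_ratio": [w.log2_ratio for w in wins],
            "rankable": [w.rankable for w in wins],
            "selected": [w.selected for w in wins],
        }
    )
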
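"""Core population-genetic statistics.

Windowed nucleotide diversity (pi), windowed and genome-wide
Weir & Cockerham (1984) Fst, pairwise-Fst matrices with summaries,
per-individual heterozygosity / inbreeding, genotype-dosage LD decay and
a minimal genotype PCA.

Fst follows the 1984 variance-component estimator: per biallelic site,
an among-population component ``a``, an among-individual-within-
population component ``b`` and a within-individual component ``c`` are
computed from the per-population sample sizes, allele frequencies and
observed heterozygote proportions.  Windowed and genome-wide values are
ratios of summed components, Sum(a) / Sum(a+b+c), which is the standard
"ratio of averages" and can legitimately be slightly negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenomicWindow,
    GenotypeMatrix,
    PopulationMap,
)

__all__ = [
    "WindowStat",
    "FstMatrix",
    "HetStats",
    "LDDecayCurve",
    "PCAResult",
    "window_pi",
    "wc_fst_components",
    "wc_fst_window",
    "genome_fst",
    "pairwise_fst_matrix",
    "fst_matrix_summary",
    "het_and_inbreeding",
    "ld_r2_decay",
    "genotype_pca",
]


@dataclass
class WindowStat:
    """Per-window statistics: pi and/or Fst with its component sums."""

    window: GenomicWindow
    n_sites: int
    pi: float = float("nan")
    fst: float = float("nan")
    components: tuple[float, float, float] | None = None


def window_stats_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    """Tab-friendly table; start/end printed 1-based inclusive."""
    return pd.DataFrame(
        {
            "chrom": [w.window.chrom for w in stats],
            "start": [w.window.start + 1 for w in stats],
            "end": [w.window.end for w in stats],
            "n_sites": [w.n_sites for w in stats],
            "pi": [w.pi for w in stats],
            "fst": [w.fst for w in stats],
        }
    )


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def _pi_per_site(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pi = n_ref*n_alt / C(n,2) over non-missing alleles.

    Returns (pi_site, usable) where sites with fewer than 2 called
    alleles are flagged unusable (pi set to 0, excluded from counts).
    """
    called = dosage != MISSING
    n = 2 * called.sum(axis=1).astype(np.float64)
    alt = np.where(called, dosage, 0).sum(axis=1).astype(np.float64)
    usable = n >= 2
    pairs = n * (n - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(usable, alt * (n - alt) / np.where(usable, pairs, 1.0), 0.0)
    return pi, usable


def window_pi(
    g: GenotypeMatrix,
    windows: Sequence[GenomicWindow],
    samples: Sequence[str] | None = None,
    per_site: bool = False,
) -> list[WindowStat]:
    """Sliding-window nucleotide diversity.

    Per site, pi = n_ref * n_alt / C(n, 2) with n the count of
    non-missing alleles in the sample subset; the window value divides
    the per-site sum by the window length in bp (or by the usable-site
    count when ``per_site`` is set).  Windows without usable sites get
    pi = 0 and n_sites = 0.
    """
    sub = g if samples is None else g.subset_samples(samples)
    if sub.n_samples == 0:
        raise ValueError("sample subset is empty")
    pi_site, usable = _pi_per_site(sub.dosage)
    out: list[WindowStat] = []
    for w in windows:
        rows = sub.site_range(w)
        u = usable[rows]
        total = float(pi_site[rows][u].sum())
        n_used = int(u.sum())
        denom = n_used if per_site else w.size
        pi = total / denom if denom > 0 else 0.0
        out.append(WindowStat(window=w, n_sites=n_used, pi=pi))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def wc_fst_components(
    g: GenotypeMatrix, pops: PopulationMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c).

    Populations with no called genotype at a site drop out of that
    site; sites with fewer than 2 informative populations, or with mean
    per-population sample size <= 1, are unusable (components set to 0).
    Returns (a, b, c, usable) arrays of length n_sites.
    """
    idx = pops.column_indices(g)
    if len(idx) < 2:
        raise ValueError("need at least 2 populations with samples in the matrix")
    S = g.n_sites
    P = len(idx)
    n_i = np.zeros((P, S))
    p_i = np.zeros((P, S))
    h_i = np.zeros((P, S))
    for k, cols in enumerate(idx.values()):
        d = g.dosage[:, cols]
        called = d != MISSING
        n = called.sum(axis=1).astype(np.float64)
        alt = np.where(called, d, 0).sum(axis=1).astype(np.float64)
        het = ((d == 1) & called).sum(axis=1).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), 0.0)
            h = np.where(n > 0, het / np.maximum(n, 1), 0.0)
        n_i[k], p_i[k], h_i[k] = n, p, h

    present = n_i > 0
    r = present.sum(axis=0).astype(np.float64)
    sum_n = n_i.sum(axis=0)
    usable = (r >= 2) & (sum_n / np.maximum(r, 1) > 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = sum_n / np.maximum(r, 1)
        nc = (sum_n - (n_i**2).sum(axis=0) / np.maximum(sum_n, 1)) / np.maximum(
            r - 1, 1
        )
        pbar = (n_i * p_i).sum(axis=0) / np.maximum(sum_n, 1)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / np.maximum(
            (r - 1) * nbar, 1e-300
        )
        hbar = (n_i * h_i).sum(axis=0) / np.maximum(sum_n, 1)

        inner = pbar * (1 - pbar) - (r - 1) / np.maximum(r, 1) * s2 - hbar / 4.0
        a = nbar / np.maximum(nc, 1e-300) * (
            s2 - inner / np.maximum(nbar - 1, 1e-300)
        )
        b = nbar / np.maximum(nbar - 1, 1e-300) * (
            pbar * (1 - pbar)
            - (r - 1) / np.maximum(r, 1) * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def _ratio(a_sum: float, abc_sum: float) -> float:
    return a_sum / abc_sum if abc_sum != 0.0 else float("nan")


def wc_fst_window(
    g: GenotypeMatrix, pops: PopulationMap, windows: Sequence[GenomicWindow]
) -> list[WindowStat]:
    """Windowed W&C Fst: Sum(a) / Sum(a+b+c) over the sites of each window.

    Windows whose component total is zero get fst = NaN.
    """
    a, b, c, usable = wc_fst_components(g, pops)
    abc = a + b + c
    out: list[WindowStat] = []
    for w in windows:
        rows = g.site_range(w)
        sa = float(a[rows].sum())
        sabc = float(abc[rows].sum())
        out.append(
            WindowStat(
                window=w,
                n_sites=int(usable[rows].sum()),
                fst=_ratio(sa, sabc),
                components=(sa, float(b[rows].sum()), float(c[rows].sum())),
            )
        )
    return out


def genome_fst(g: GenotypeMatrix, pops: PopulationMap) -> float:
    """Genome-wide W&C Fst: ratio of component sums over all usable sites."""
    a, b, c, _ = wc_fst_components(g, pops)
    return _ratio(float(a.sum()), float((a + b + c).sum()))


# ---------------------------------------------------------------------------
# Pairwise matrices and summaries
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    """Symmetric pairwise-Fst table over named groups (diagonal NaN)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("values must be square over labels")
        off = ~np.eye(k, dtype=bool)
        if not np.allclose(
            self.values[off], self.values.T[off], equal_nan=True
        ):
            raise ValueError("pairwise Fst matrix must be symmetric")

    @classmethod
    def from_pairs(
        cls, labels: Sequence[str], pairs: Mapping[tuple[str, str], float]
    ) -> "FstMatrix":
        k = len(labels)
        m = np.full((k, k), np.nan)
        li = {l: i for i, l in enumerate(labels)}
        for (x, y), v in pairs.items():
            m[li[x], li[y]] = v
            m[li[y], li[x]] = v
        return cls(list(labels), m)

    def value(self, x: str, y: str) -> float:
        i, j = self.labels.index(x), self.labels.index(y)
        return float(self.values[i, j])

    def pair_values(
        self,
        focal: str | Sequence[str] | None = None,
        partners: Sequence[str] | None = None,
    ) -> list[float]:
        """Off-diagonal values over selected unordered pairs."""
        known = set(self.labels)
        if focal is not None:
            focal_set = {focal} if isinstance(focal, str) else set(focal)
            bad = focal_set - known
            if bad:
                raise KeyError(
                    f"unknown focal label(s) {sorted(bad)}; known: {self.labels}"
                )
        else:
            focal_set = None
        if partners is not None:
            bad = set(partners) - known
            if bad:
                raise KeyError(
                    f"unknown partner label(s) {sorted(bad)}; known: {self.labels}"
                )
        vals = []
        for i, x in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                y = self.labels[j]
                if focal_set is not None:
                    if x in focal_set:
                        other = y
                    elif y in focal_set:
                        other = x
                    else:
                        continue
                    if partners is not None and other not in partners:
                        continue
                if np.isnan(self.values[i, j]):
                    continue
                vals.append(float(self.values[i, j]))
        return vals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def fst_matrix_summary(
    m: FstMatrix,
    focal: str | Sequence[str] | None = None,
    partners: Sequence[str] | None = None,
) -> dict[str, float]:
    """Mean / min / max over selected unordered pairs (unweighted).

    With no ``focal``, all C(k,2) pairs are used; with a focal label (or
    set), only pairs containing a focal member, optionally restricted to
    a ``partners`` set.
    """
    vals = m.pair_values(focal=focal, partners=partners)
    if not vals:
        raise ValueError("selected pair set is empty")
    return {
        "n_pairs": len(vals),
        "mean": float(np.mean(vals)),
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
    }


def pairwise_fst_matrix(
    g: GenotypeMatrix,
    pops: PopulationMap,
    windows: Sequence[GenomicWindow] | None = None,
    method: str = "genome",
) -> FstMatrix:
    """Pairwise W&C Fst over all population pairs.

    ``method='genome'`` (default) is the genome-wide ratio of summed
    components over all retained sites; ``method='window_mean'``
    averages per-window ratios over ``windows``.  Populations with
    fewer than 2 samples are excluded with a warning.
    """
    labels = []
    for label in pops.populations:
        members = [s for s in pops.samples_for(label) if s in g.samples]
        if len(members) >= 2:
            labels.append(label)
        else:
            warnings.warn(
                f"population {label!r} has < 2 samples; excluded", stacklevel=2
            )
    if len(labels) < 2:
        raise ValueError("need >= 2 populations with >= 2 samples each")
    pairs: dict[tuple[str, str], float] = {}
    for i, x in enumerate(labels):
        for y in labels[i + 1 :]:
            sub_map = pops.restrict([x, y])
            if method == "genome":
                pairs[(x, y)] = genome_fst(g, sub_map)
            elif method == "window_mean":
                if windows is None:
                    raise ValueError("window_mean method requires windows")
                stats = wc_fst_window(g, sub_map, windows)
                vals = [s.fst for s in stats if np.isfinite(s.fst)]
                pairs[(x, y)] = float(np.mean(vals)) if vals else float("nan")
            else:
                raise ValueError(f"unknown method {method!r}")
    return FstMatrix.from_pairs(labels, pairs)


# ---------------------------------------------------------------------------
# Heterozygosity and inbreeding
# ---------------------------------------------------------------------------

@dataclass
class HetStats:
    """Population-level heterozygosity summary with a per-individual table.

    ``per_individual`` columns: sample, n_sites_used, observed_hom,
    expected_hom, f.  ``he`` is the unweighted mean of per-site expected
    heterozygosity 2p(1-p); ``ho`` the mean per-individual heterozygous
    proportion; ``f`` the mean per-individual inbreeding coefficient.
    """

    population: str
    he: float
    ho: float
    f: float
    per_individual: pd.DataFrame


def het_and_inbreeding(
    g: GenotypeMatrix, pops: PopulationMap
) -> dict[str, HetStats]:
    """Per-population He / Ho / F from observed vs expected homozygosity.

    Allele frequencies are taken per population; per individual, only
    sites called in that individual contribute, with
    F = (obs_hom - exp_hom) / (n_used - exp_hom).  Individuals whose
    denominator is zero get F = NaN and are excluded from the
    population mean.
    """
    out: dict[str, HetStats] = {}
    idx = pops.column_indices(g)
    for label, cols in idx.items():
        d = g.dosage[:, cols]
        called = d != MISSING
        n = called.sum(axis=1).astype(np.float64)
        alt = np.where(called, d, 0).sum(axis=1).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        he_site = 2 * p * (1 - p)
        informative = n > 0

        rows = []
        for j, col in enumerate(cols):
            mask = called[:, j]
            n_used = int(mask.sum())
            obs_hom = int(((d[:, j] == 0) | (d[:, j] == 2))[mask].sum())
            exp_hom = float((1.0 - he_site[mask]).sum())
            denom = n_used - exp_hom
            f = (obs_hom - exp_hom) / denom if denom != 0 else float("nan")
            rows.append(
                {
                    "sample": g.samples[int(col)],
                    "n_sites_used": n_used,
                    "observed_hom": obs_hom,
                    "expected_hom": exp_hom,
                    "f": f,
                }
            )
        table = pd.DataFrame(rows)
        ho_ind = 1.0 - table.observed_hom / table.n_sites_used.replace(0, np.nan)
        he = float(np.nanmean(he_site[informative])) if informative.any() else float("nan")
        out[label] = HetStats(
            population=label,
            he=he,
            ho=float(np.nanmean(ho_ind)),
            f=float(np.nanmean(table.f)),
            per_individual=table,
        )
    return out


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LDDecayCurve:
    """Mean genotype-dosage r^2 binned by physical distance.

    ``decay_distance`` is the midpoint of the first populated bin whose
    mean r^2 falls below ``threshold`` (NaN if never crossed).
    """

    bin_edges: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    threshold: float
    decay_distance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "n_pairs": self.n_pairs.astype(int),
                "mean_r2": self.mean_r2,
            }
        )


def ld_r2_decay(
    g: GenotypeMatrix,
    max_dist: int,
    bin_width: int,
    samples: Sequence[str] | None = None,
    threshold: float = 0.1,
) -> LDDecayCurve:
    """Composite genotype-dosage LD decay.

    r^2 is the squared Pearson correlation of the two dosage vectors
    over samples called at both sites (no phasing); same-chromosome
    pairs separated by at most ``max_dist`` bp are binned by distance.
    Pairs involving a zero-variance site are skipped.
    """
    sub = g if samples is None else g.subset_samples(samples)
    edges = np.arange(0, max_dist + bin_width, bin_width, dtype=np.int64)
    n_bins = len(edges) - 1
    sum_r2 = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=np.int64)

    # group rows by chromosome, preserving matrix order
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sub.sites):
        by_chrom.setdefault(s.chrom, []).append(i)

    D = sub.dosage.astype(np.float64)
    M = sub.dosage != MISSING
    for rows in by_chrom.values():
        pos = np.array([sub.sites[i].pos for i in rows], dtype=np.int64)
        Dc = D[rows]
        Mc = M[rows]
        for ii in range(len(rows)):
            jj = int(np.searchsorted(pos, pos[ii] + max_dist, side="right"))
            if jj <= ii + 1:
                continue
            both = Mc[ii] & Mc[ii + 1 : jj]
            nb = both.sum(axis=1).astype(np.float64)
            x = np.where(both, Dc[ii], 0.0)
            y = np.where(both, Dc[ii + 1 : jj], 0.0)
            sx, sy = x.sum(axis=1), y.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                vx = (x * x).sum(axis=1) - sx * sx / nb
                vy = (y * y).sum(axis=1) - sy * sy / nb
                cov = (x * y).sum(axis=1) - sx * sy / nb
                ok = (nb >= 2) & (vx > 0) & (vy > 0)
                r2 = np.where(ok, cov * cov / np.where(ok, vx * vy, 1.0), 0.0)
            b = np.minimum((pos[ii + 1 : jj] - pos[ii]) // bin_width, n_bins - 1)
            np.add.at(sum_r2, b[ok], r2[ok])
            np.add.at(count, b[ok], 1)

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(count > 0, sum_r2 / np.maximum(count, 1), np.nan)
    decay = float("nan")
    for b in range(n_bins):
        if count[b] > 0 and mean_r2[b] < threshold:
            decay = float(0.5 * (edges[b] + edges[b + 1]))
            break
    return LDDecayCurve(edges, mean_r2, count, threshold, decay)


# ---------------------------------------------------------------------------
# Genotype PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Per-sample PC scores with explained-variance fractions."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def genotype_pca(g: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the standardized genotype matrix.

    Missing dosages are mean-imputed per site; sites are centered by
    their mean dosage 2p and scaled by sqrt(2p(1-p)) (the usual
    drift-variance standardization); monomorphic sites drop out.
    """
    max_pc = max(g.n_samples - 1, 1)
    if n_components > max_pc:
        warnings.warn(
            f"n_components clipped from {n_components} to {max_pc}", stacklevel=2
        )
        n_components = max_pc
    D = g.dosage.astype(np.float64)
    called = g.dosage != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(
            called.sum(axis=1) > 0,
            np.where(called, D, 0).sum(axis=1) / np.maximum(called.sum(axis=1), 1),
            np.nan,
        )
    D = np.where(called, D, mean[:, None])
    p = mean / 2.0
    scale = np.sqrt(2 * p * (1 - p))
    keep = np.isfinite(scale) & (scale > 0)
    X = ((D[keep] - mean[keep, None]) / scale[keep, None]).T  # samples x sites
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    evr = S**2 / max((S**2).sum(), 1e-300)
    scores = U[:, :n_components] * S[:n_components]
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=list(g.samples), columns=cols),
        explained_variance_ratio=evr[:n_components],
    )
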
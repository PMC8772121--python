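"""Synthetic genotype and wing-landmark data with recorded ground truth.

Genotypes follow the Balding-Nichols model: an ancestral allele
frequency p is drawn uniformly per SNP, each population's frequency is
drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) so its expected Fst against the
ancestral pool is F, and diploid genotypes are Binomial(2, pop
frequency).  Selective sweeps are injected by redrawing the candidate
population's frequencies in the sweep interval with an elevated
divergence coefficient and then pushing them toward the nearer fixation
so the expected within-population heterozygosity drops by a stated
factor relative to the background.

Wing landmark sets emulate specimens digitized from wing photographs:
a template shape plus per-group mean-shape offsets and isotropic
landmark noise, sized by a centroid-size model linear in site latitude
and altitude, then hit with nuisance rotation and translation.

Every generator is a pure function of its spec (seed included):
identical inputs give byte-identical outputs, and the returned truth
records are sufficient to compute the oracles used in tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    VariantSite,
    write_vcf,
)
from .morphometrics import (
    LandmarkConfiguration,
    LandmarkSet,
    centroid_size,
    write_tps,
)

__all__ = [
    "SweepSpec",
    "GenoSimSpec",
    "CsModel",
    "SiteSpec",
    "MorphoSimSpec",
    "simulate_genotypes",
    "simulate_landmarks",
    "predicted_fst_from_truth",
    "default_wing_shape",
    "default_sites",
    "make_fixture_suite",
]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepSpec:
    """A low-diversity / high-divergence interval injected into one population."""

    start: int
    end: int
    diversity_reduction: float = 10.0
    local_fst: float = 0.6
    pop: int = 0  # index of the swept (candidate) population

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("sweep interval must have end > start")
        if self.diversity_reduction < 1.0:
            raise ValueError("diversity_reduction must be >= 1")


@dataclass(frozen=True)
class GenoSimSpec:
    """Balding-Nichols cohort scenario."""

    n_pops: int = 2
    n_per_pop: int = 20
    n_snps: int = 5_000
    chrom_length: int = 2_000_000
    fst: float | tuple[float, ...] = 0.05
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    sweeps: tuple[SweepSpec, ...] = ()
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for f in self.pop_fst:
            if not 0.0 <= f < 1.0:
                raise ValueError("per-population F must be in [0, 1)")
        for sw in self.sweeps:
            if sw.end > self.chrom_length:
                raise ValueError("sweep interval exceeds chromosome length")
            if not 0 <= sw.pop < self.n_pops:
                raise ValueError("sweep population index out of range")

    @property
    def pop_fst(self) -> tuple[float, ...]:
        if isinstance(self.fst, (int, float)):
            return (float(self.fst),) * self.n_pops
        if len(self.fst) != self.n_pops:
            raise ValueError("per-population fst length must equal n_pops")
        return tuple(float(f) for f in self.fst)

    @property
    def pop_labels(self) -> list[str]:
        return [f"pop{i+1}" for i in range(self.n_pops)]


def _bn_freq(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols draw of population frequencies around ancestral p."""
    if f == 0.0:
        return p.copy()
    lam = (1.0 - f) / f
    return rng.beta(p * lam, (1.0 - p) * lam)


def _reduce_het(p: np.ndarray, target_pq: np.ndarray) -> np.ndarray:
    """Push frequencies toward the nearer fixation so p'(1-p') = target_pq."""
    target_pq = np.minimum(target_pq, 0.25)
    root = 0.5 * np.sqrt(np.maximum(1.0 - 4.0 * target_pq, 0.0))
    return np.where(p >= 0.5, 0.5 + root, 0.5 - root)


def simulate_genotypes(
    spec: GenoSimSpec,
) -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """Simulate a diploid cohort under the Balding-Nichols model.

    Returns the genotype matrix, the sample -> population map, and a
    truth record holding the realized per-site per-population
    frequencies (after sweep injection), the ancestral frequencies and
    the sweep layout.
    """
    rng = np.random.default_rng(spec.seed)
    # unique sorted positions
    pool = rng.choice(spec.chrom_length, size=spec.n_snps, replace=False)
    positions = np.sort(pool) + 1  # 1-based

    lo, hi = spec.ancestral_range
    anc = rng.uniform(lo, hi, size=spec.n_snps)
    freqs = np.empty((spec.n_pops, spec.n_snps))
    for k, f in enumerate(spec.pop_fst):
        freqs[k] = _bn_freq(rng, anc, f)

    sweep_mask = np.zeros(spec.n_snps, dtype=bool)
    for sw in spec.sweeps:
        in_sweep = (positions - 1 >= sw.start) & (positions - 1 < sw.end)
        sweep_mask |= in_sweep
        if not in_sweep.any():
            continue
        f_bg = spec.pop_fst[sw.pop]
        local = _bn_freq(rng, anc[in_sweep], sw.local_fst)
        # scale the het target so E[sweep het] = E[background het] / d
        factor = (1.0 - f_bg) / ((1.0 - sw.local_fst) * sw.diversity_reduction)
        target_pq = local * (1.0 - local) * factor
        freqs[sw.pop, in_sweep] = _reduce_het(local, target_pq)

    n_total = spec.n_pops * spec.n_per_pop
    dosage = np.empty((spec.n_snps, n_total), dtype=np.int8)
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for k, label in enumerate(spec.pop_labels):
        cols = slice(k * spec.n_per_pop, (k + 1) * spec.n_per_pop)
        dosage[:, cols] = rng.binomial(
            2, freqs[k][:, None], size=(spec.n_snps, spec.n_per_pop)
        ).astype(np.int8)
        for j in range(spec.n_per_pop):
            name = f"{label}_s{j+1:03d}"
            samples.append(name)
            assignments[name] = label

    if spec.missing_rate > 0.0:
        miss = rng.random(dosage.shape) < spec.missing_rate
        dosage[miss] = MISSING

    sites = [
        VariantSite(spec.chrom, int(pos), "A", "T") for pos in positions
    ]
    truth = {
        "positions": positions.tolist(),
        "ancestral_freq": anc.tolist(),
        "pop_freqs": {
            label: freqs[k].tolist() for k, label in enumerate(spec.pop_labels)
        },
        "pop_fst": list(spec.pop_fst),
        "sweeps": [
            {
                "start": sw.start,
                "end": sw.end,
                "diversity_reduction": sw.diversity_reduction,
                "local_fst": sw.local_fst,
                "pop": spec.pop_labels[sw.pop],
            }
            for sw in spec.sweeps
        ],
        "sweep_site_mask": sweep_mask.tolist(),
        "seed": spec.seed,
    }
    return (
        GenotypeMatrix(sites, samples, dosage),
        PopulationMap(assignments),
        truth,
    )


def predicted_fst_from_truth(
    truth: dict, pops: Sequence[str] | None = None
) -> float:
    """Genome-wide Fst predicted from the recorded true frequencies.

    Per site, the between-population numerator is the sample variance
    s^2 of the true frequencies across populations (r-1 divisor) and
    the denominator is pbar(1-pbar) + s^2/r, whose expectations under
    the Balding-Nichols model are F*p(1-p) and p(1-p); the genome value
    is the ratio of sums, matching the ratio-of-sums convention of the
    Weir-Cockerham estimator this oracle cross-checks.
    """
    labels = list(pops) if pops is not None else list(truth["pop_freqs"])
    P = np.array([truth["pop_freqs"][l] for l in labels])
    r = P.shape[0]
    pbar = P.mean(axis=0)
    s2 = P.var(axis=0, ddof=1)
    num = s2
    den = pbar * (1 - pbar) + s2 / r
    return float(num.sum() / den.sum())


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CsModel:
    """Linear centroid-size model: base + slopes * covariates + noise."""

    base: float = 5.0
    latitude_slope: float = 0.0
    longitude_slope: float = 0.0
    altitude_slope: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class SiteSpec:
    """One sampling site with its geographic covariates."""

    name: str
    group: str
    latitude: float
    longitude: float
    altitude: float
    n_specimens: int = 10


@dataclass(frozen=True)
class MorphoSimSpec:
    """Wing-landmark scenario: template shape, group offsets, CS model."""

    mean_shape: tuple[tuple[float, float], ...]
    sites: tuple[SiteSpec, ...]
    group_offsets: dict | None = None  # group -> (k, 2) offset array-like
    landmark_noise_sd: float = 0.01
    cs_model: CsModel = field(default_factory=CsModel)
    rotation_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    translation_range: tuple[float, float] = (-10.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")
        arr = np.asarray(self.mean_shape, float)
        if len(arr) < 3 or np.linalg.matrix_rank(arr - arr.mean(axis=0)) < 2:
            raise ValueError("mean shape is degenerate (collinear or < 3 points)")


def default_wing_shape(k: int = 20) -> tuple[tuple[float, float], ...]:
    """A non-degenerate elongated template with k landmarks.

    Points lie on a 3:1 ellipse with a deterministic radial modulation,
    spanning a few coordinate units (CS around 5), which stands in for
    vein-intersection landmarks on a wing photograph.
    """
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    radial = 1.0 + 0.15 * np.sin(3 * t) + 0.1 * np.cos(5 * t)
    pts = np.column_stack([1.5 * radial * np.cos(t), 0.5 * radial * np.sin(t)])
    return tuple((float(x), float(y)) for x, y in pts)


def default_sites(
    n_groups: int = 5, n_sites_per_group: int = 1, n_specimens: int = 10
) -> tuple[SiteSpec, ...]:
    """Five-region default layout with a latitude/altitude gradient."""
    sites: list[SiteSpec] = []
    for gi in range(n_groups):
        for si in range(n_sites_per_group):
            sites.append(
                SiteSpec(
                    name=f"site{gi+1}_{si+1}",
                    group=f"region{gi+1}",
                    latitude=20.0 + 6.0 * gi + 0.5 * si,
                    longitude=100.0 + 3.0 * gi + 1.0 * si,
                    altitude=200.0 + 300.0 * gi + 50.0 * si,
                    n_specimens=n_specimens,
                )
            )
    return tuple(sites)


def simulate_landmarks(
    spec: MorphoSimSpec,
) -> tuple[LandmarkSet, dict]:
    """Simulate digitized wing specimens with known ground truth.

    Each specimen shape is the template plus its group's mean-shape
    offset plus isotropic Gaussian landmark noise; the result is
    centered, normalized to unit centroid size and multiplied by the
    specimen's true CS from the ``cs_model`` (so measured CS equals the
    truth exactly), then rotated and translated by nuisance draws.
    """
    rng = np.random.default_rng(spec.seed)
    template = np.asarray(spec.mean_shape, float)
    k = len(template)
    offsets = {
        g: np.asarray(o, float) for g, o in (spec.group_offsets or {}).items()
    }

    configs: list[LandmarkConfiguration] = []
    meta_rows = []
    truth_specimens = []
    counter = 0
    for site in spec.sites:
        cs_mean = (
            spec.cs_model.base
            + spec.cs_model.latitude_slope * site.latitude
            + spec.cs_model.longitude_slope * site.longitude
            + spec.cs_model.altitude_slope * site.altitude
        )
        for _ in range(site.n_specimens):
            counter += 1
            sid = f"spec{counter:04d}"
            shape = template + offsets.get(site.group, 0.0)
            shape = shape + rng.normal(0.0, spec.landmark_noise_sd, size=(k, 2))
            shape = shape - shape.mean(axis=0)
            shape = shape / np.sqrt((shape**2).sum())
            cs_true = cs_mean + (
                rng.normal(0.0, spec.cs_model.noise_sd)
                if spec.cs_model.noise_sd > 0
                else 0.0
            )
            if cs_true <= 0:
                raise ValueError("cs_model produced a non-positive centroid size")
            theta = rng.uniform(*spec.rotation_range)
            shift = rng.uniform(*spec.translation_range, size=2)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            coords = (shape * cs_true) @ rot.T + shift
            configs.append(LandmarkConfiguration(specimen_id=sid, coords=coords))
            meta_rows.append(
                {
                    "specimen": sid,
                    "site": site.name,
                    "region": site.group,
                    "latitude": site.latitude,
                    "longitude": site.longitude,
                    "altitude": site.altitude,
                }
            )
            truth_specimens.append(
                {
                    "specimen": sid,
                    "site": site.name,
                    "group": site.group,
                    "cs": float(cs_true),
                    "rotation": float(theta),
                    "translation": [float(shift[0]), float(shift[1])],
                }
            )
    metadata = pd.DataFrame(meta_rows).set_index("specimen")
    truth = {
        "template": np.asarray(spec.mean_shape, float).tolist(),
        "specimens": truth_specimens,
        "cs_model": {
            "base": spec.cs_model.base,
            "latitude_slope": spec.cs_model.latitude_slope,
            "longitude_slope": spec.cs_model.longitude_slope,
            "altitude_slope": spec.cs_model.altitude_slope,
            "noise_sd": spec.cs_model.noise_sd,
        },
        "seed": spec.seed,
    }
    return LandmarkSet(configurations=configs, metadata=metadata), truth


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

DEFAULT_SWEEP = SweepSpec(start=900_000, end=1_000_000)
DEFAULT_GENO = GenoSimSpec(sweeps=(DEFAULT_SWEEP,))


def _write_gff(path: Path, chrom: str, length: int, gene_len: int, step: int) -> list[str]:
    ids = []
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        i = 0
        for start in range(0, length - gene_len, step):
            i += 1
            gid = f"gene{i:04d}"
            ids.append(gid)
            fh.write(
                f"{chrom}\tsim\tgene\t{start+1}\t{start+gene_len}\t.\t"
                f"{'+' if i % 2 else '-'}\t.\tID={gid}\n"
            )
    return ids


def make_fixture_suite(
    out_dir: str | Path, seed: int = 0, overwrite: bool = False
) -> dict:
    """Write the default no-download test scenario to ``out_dir``.

    Emits a VCF, population map, GFF3 of synthetic genes tiling the
    chromosome, forewing and hindwing TPS files, specimen metadata and
    truth records, plus a manifest with SHA-256 checksums of every
    file.  The default genotype scenario is 2 populations x 20
    diploids, 2 Mb, 5000 SNPs with one 100-kb sweep; wings are 5
    regions x 10 specimens.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    geno_spec = GenoSimSpec(
        sweeps=(DEFAULT_SWEEP,), seed=seed, missing_rate=0.02
    )
    g, pops, geno_truth = simulate_genotypes(geno_spec)
    write_vcf(g, out / "genotypes.vcf")
    pops.to_file(out / "population_map.tsv")
    gene_ids = _write_gff(
        out / "genes.gff3", geno_spec.chrom, geno_spec.chrom_length, 2_000, 4_000
    )
    geno_truth["gene_ids"] = gene_ids

    wing_sites = default_sites(n_sites_per_group=2, n_specimens=5)
    fore_spec = MorphoSimSpec(
        mean_shape=default_wing_shape(20),
        sites=wing_sites,
        cs_model=CsModel(base=4.0, latitude_slope=0.05, altitude_slope=0.0005,
                         noise_sd=0.05),
        seed=seed + 1,
    )
    hind_spec = MorphoSimSpec(
        mean_shape=default_wing_shape(10),
        sites=wing_sites,
        cs_model=CsModel(base=2.5, latitude_slope=0.03, altitude_slope=0.0003,
                         noise_sd=0.03),
        seed=seed + 2,
    )
    fore, fore_truth = simulate_landmarks(fore_spec)
    hind, hind_truth = simulate_landmarks(hind_spec)
    write_tps(fore, out / "forewing.tps")
    write_tps(hind, out / "hindwing.tps")
    fore.metadata.to_csv(out / "specimen_metadata.tsv", sep="\t")

    with open(out / "truth_genotypes.json", "w") as fh:
        json.dump(geno_truth, fh)
    with open(out / "truth_landmarks.json", "w") as fh:
        json.dump({"forewing": fore_truth, "hindwing": hind_truth}, fh)

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "files": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
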
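"""Genotype, annotation and windowing I/O.

Internal coordinates are 0-based half-open everywhere; VCF and GFF3
positions (1-based inclusive) are converted on ingestion and converted
back when tables are printed.  Diploid genotypes are stored as alt-allele
dosage in {0, 1, 2}; any genotype with an unknown allele (``./.`` or a
half call such as ``0/.``) is stored as :data:`MISSING`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING: int = -1
"""Sentinel dosage for a missing diploid genotype."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Input data violate an internal invariant."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP locus.

    ``pos`` is the 1-based physical position as printed in VCF; use
    ``pos0`` for arithmetic in the internal 0-based convention.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"{self.chrom}:{self.pos} ref and alt alleles are identical"
            )

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"window end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and start < self.end and self.start < end


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval from a GFF3 annotation (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid dosage matrix anchored to genomic coordinates.

    ``dosage`` is an ``int8`` array of shape (n_sites, n_samples) holding
    counts of the alternate allele, with :data:`MISSING` for no-calls.
    Sites are sorted by (chrom, pos) with no duplicates; the order of
    first appearance of each chromosome is preserved.
    """

    sites: list[VariantSite]
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("dosage values must be in {0,1,2} or MISSING")
        seen_chroms: dict[str, int] = {}
        last_pos = None
        for s in self.sites:
            if s.chrom not in seen_chroms:
                seen_chroms[s.chrom] = len(seen_chroms)
                last_pos = 0
            elif seen_chroms[s.chrom] != len(seen_chroms) - 1:
                raise ValidationError(
                    f"sites not grouped by chromosome at {s.chrom}:{s.pos}"
                )
            if s.pos <= last_pos:
                raise ValidationError(
                    f"sites not sorted / duplicated at {s.chrom}:{s.pos}"
                )
            last_pos = s.pos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chroms(self) -> list[str]:
        out: list[str] = []
        for s in self.sites:
            if not out or out[-1] != s.chrom:
                out.append(s.chrom)
        return out

    def positions(self, chrom: str | None = None) -> np.ndarray:
        """1-based positions, optionally restricted to one chromosome."""
        if chrom is None:
            return np.array([s.pos for s in self.sites], dtype=np.int64)
        return np.array(
            [s.pos for s in self.sites if s.chrom == chrom], dtype=np.int64
        )

    def site_range(self, window: GenomicWindow) -> slice:
        """Row slice of the sites falling inside ``window``."""
        rows = [i for i, s in enumerate(self.sites) if s.chrom == window.chrom]
        if not rows:
            return slice(0, 0)
        lo, hi = rows[0], rows[-1] + 1
        pos0 = np.array([self.sites[i].pos0 for i in range(lo, hi)])
        i0 = lo + int(np.searchsorted(pos0, window.start, side="left"))
        i1 = lo + int(np.searchsorted(pos0, window.end, side="left"))
        return slice(i0, i1)

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return np.array([lookup[s] for s in samples], dtype=np.intp)

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(samples)
        return GenotypeMatrix(list(self.sites), list(samples), self.dosage[:, idx])

    def take_sites(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            [self.sites[int(i)] for i in rows], list(self.samples), self.dosage[rows]
        )


@dataclass
class PopulationMap:
    """Sample -> population-label assignment."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for sample, label in self.assignments.items():
            if not label:
                raise ValidationError(f"empty population label for sample {sample}")

    @property
    def populations(self) -> list[str]:
        out: list[str] = []
        for label in self.assignments.values():
            if label not in out:
                out.append(label)
        return out

    def samples_for(self, label: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == label]

    def restrict(self, labels: Iterable[str]) -> "PopulationMap":
        keep = set(labels)
        return PopulationMap(
            {s: p for s, p in self.assignments.items() if p in keep}
        )

    def column_indices(self, g: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Per-population column indices into ``g`` (samples present in both)."""
        out: dict[str, np.ndarray] = {}
        for label in self.populations:
            members = [s for s in self.samples_for(label) if s in g.samples]
            if members:
                out[label] = g.sample_indices(members)
        return out

    @classmethod
    def from_file(cls, path: str | Path) -> "PopulationMap":
        """Read a 2-column tab-separated (sample, population) file."""
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}:{ln}: expected 2 tab-separated columns")
                assignments[parts[0]] = parts[1]
        return cls(assignments)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sample, label in self.assignments.items():
                fh.write(f"{sample}\t{label}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Parse diploid GT fields of a VCF 4.x file into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are dropped when ``biallelic_only``
    (records with more than one ALT allele are always dropped, since the
    dosage encoding is biallelic).  Half-missing genotypes map to
    :data:`MISSING`.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read VCF: {path} does not exist")
    vcf = VCF(str(path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    cur_chrom: str | None = None
    last_pos = 0
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if biallelic_only and not var.is_snp:
            continue
        if var.CHROM != cur_chrom:
            if var.CHROM in seen:
                raise ValidationError(
                    f"unsorted VCF: chromosome {var.CHROM} interleaved at "
                    f"{var.CHROM}:{var.POS}"
                )
            seen.add(var.CHROM)
            cur_chrom = var.CHROM
            last_pos = 0
        if var.POS <= last_pos:
            raise ValidationError(
                f"unsorted VCF: record {var.CHROM}:{var.POS} follows "
                f"position {last_pos}"
            )
        last_pos = var.POS
        gts = var.genotypes
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, gt in enumerate(gts):
            a, b = gt[0], gt[1] if len(gt) > 2 else -1
            if a >= 0 and b >= 0:
                row[j] = (a > 0) + (b > 0)
        sites.append(VariantSite(var.CHROM, var.POS, var.REF, var.ALT[0]))
        rows.append(row)
    dosage = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(sites, samples, dosage)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2 file (round-trips with read_vcf)."""
    chrom_max: dict[str, int] = {}
    for s in g.sites:
        chrom_max[s.chrom] = max(chrom_max.get(s.chrom, 0), s.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for i, s in enumerate(g.sites):
            gts = "\t".join(_GT_STR[int(d)] for d in g.dosage[i])
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def site_allele_stats(
    dosage: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_called_alleles, alt_allele_count, minor-allele frequency).

    MAF is computed over non-missing alleles only; sites with no calls
    get MAF 0.
    """
    called = dosage != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(n_alleles > 0, maf, 0.0)
    return n_alleles, alt, maf


def filter_variants(
    g: GenotypeMatrix, max_missing: float = 0.10, min_maf: float = 0.01
) -> GenotypeMatrix:
    """Retain sites with missing fraction < ``max_missing`` and MAF > ``min_maf``.

    Defaults follow the standard resequencing QC thresholds (missing
    ratio below 10%, minor allele frequency above 1%).  Site order is
    preserved; an empty result is returned with a warning, not an error.
    """
    for name, v in (("max_missing", max_missing), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if g.n_sites == 0:
        return g
    called = g.dosage != MISSING
    miss_frac = 1.0 - called.mean(axis=1)
    _, _, maf = site_allele_stats(g.dosage)
    keep = (miss_frac < max_missing) & (maf > min_maf)
    if not keep.any():
        warnings.warn("filter_variants removed every site", stacklevel=2)
    return g.take_sites(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(
    chrom_lengths: Mapping[str, int], size: int, step: int
) -> list[GenomicWindow]:
    """Sliding windows of ``size`` bp every ``step`` bp, per chromosome.

    Windows start at 0; the final window is truncated at the chromosome
    end; a window is emitted only if its start lies inside the
    chromosome.
    """
    if step < 1 or size < 1:
        raise ValueError(f"size and step must be >= 1 (got {size}, {step})")
    if step > size:
        raise ValueError(f"step ({step}) must not exceed window size ({size})")
    windows: list[GenomicWindow] = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(length), step):
            windows.append(GenomicWindow(chrom, start, min(start + size, int(length))))
    return windows


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff_genes(path: str | Path) -> list[GeneRecord]:
    """Extract features of type ``gene`` from a GFF3 file.

    Coordinates are converted to the internal 0-based half-open
    convention.  Strand is recorded but never used for overlap tests.
    """
    import gffutils.iterators

    genes: list[GeneRecord] = []
    record_no = 0
    try:
        for feat in gffutils.iterators.DataIterator(str(path)):
            record_no += 1
            if feat.featuretype != "gene":
                continue
            attrs = feat.attributes
            gene_id = None
            for key in ("ID", "gene_id", "Name"):
                if key in attrs and attrs[key]:
                    gene_id = attrs[key][0]
                    break
            if gene_id is None:
                gene_id = f"gene{record_no}"
            genes.append(
                GeneRecord(feat.seqid, feat.start - 1, feat.end, feat.strand, gene_id)
            )
    except FormatError:
        raise
    except Exception as exc:  # gffutils raises bare exceptions on bad lines
        raise FormatError(
            f"{path}: malformed GFF3 near record {record_no + 1}: {exc}"
        ) from exc
    return genes
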
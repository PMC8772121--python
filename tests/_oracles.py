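"""Independent brute-force oracles, kept deliberately separate from the
package implementations they cross-check: scalar transcriptions of the
Weir & Cockerham (1984) variance-component formulas and exhaustive
pairwise-difference nucleotide diversity."""

import itertools

import numpy as np

from beepop.genotype_io import MISSING


def wc_site_oracle(dosages_by_pop):
    """W&C (1984) a, b, c for one site from per-population dosage lists.

    ``dosages_by_pop``: list of lists of diploid dosages (missing values
    already removed).  Scalar transcription of the published formulas
    with r populations, sample sizes n_i, allele frequencies p_i and
    heterozygote proportions h_i.
    """
    pops = [p for p in dosages_by_pop if len(p) > 0]
    r = len(pops)
    n = [len(p) for p in pops]
    p = [sum(pop) / (2 * len(pop)) for pop in pops]
    h = [sum(1 for d in pop if d == 1) / len(pop) for pop in pops]

    nbar = sum(n) / r
    if r < 2 or nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)

    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1))
        * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst_oracle(dosage, pop_cols):
    """Ratio-of-sums W&C Fst over all sites of a dosage matrix.

    ``pop_cols``: list of column-index lists, one per population.
    """
    sum_a = sum_abc = 0.0
    for row in dosage:
        by_pop = [
            [int(row[j]) for j in cols if row[j] != MISSING] for cols in pop_cols
        ]
        if sum(1 for p in by_pop if p) < 2:
            continue
        a, b, c = wc_site_oracle(by_pop)
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc if sum_abc != 0 else float("nan")


def pi_window_oracle(dosage, window_size):
    """Window pi by exhaustive enumeration of allele pairs.

    Per site, every non-missing diploid contributes its two alleles;
    pi_site is the fraction of differing unordered allele pairs; the
    window value is the per-site sum divided by the window length.
    """
    total = 0.0
    for row in dosage:
        alleles = []
        for d in row:
            if d == MISSING:
                continue
            alleles += [1] * int(d) + [0] * (2 - int(d))
        if len(alleles) < 2:
            continue
        pairs = list(itertools.combinations(alleles, 2))
        total += sum(1 for x, y in pairs if x != y) / len(pairs)
    return total / window_size
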
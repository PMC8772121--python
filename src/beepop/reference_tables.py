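"""Published pairwise-Fst reference tables for *Apis cerana* cohorts.

Two genome-wide pairwise Weir-Cockerham Fst tables from whole-genome
resequencing surveys of Chinese eastern honey bee populations: one over
five geographic regions (Changbai Mountain, North, Northwest,
Qinghai-Tibet, South) and one over the six sampling areas inside the
Changbai Mountain region (four Jilin areas, Heilongjiang, Liaoning).
They serve as worked-example inputs for matrix summaries and as
fixtures for report formatting; the package does not recompute them.
"""

from __future__ import annotations

from .popgen_stats import FstMatrix

REGION_LABELS = ["Changbai Mountain", "North", "Northwest", "Qinghai-Tibet", "South"]

_REGION_PAIRS = {
    ("Changbai Mountain", "North"): 0.2214,
    ("Changbai Mountain", "Northwest"): 0.2129,
    ("Changbai Mountain", "Qinghai-Tibet"): 0.2609,
    ("Changbai Mountain", "South"): 0.2225,
    ("North", "Northwest"): 0.0094,
    ("North", "Qinghai-Tibet"): 0.0534,
    ("North", "South"): 0.0237,
    ("Northwest", "Qinghai-Tibet"): 0.0557,
    ("Northwest", "South"): 0.0282,
    ("Qinghai-Tibet", "South"): 0.0451,
}

CHANGBAI_LABELS = ["JL-BS", "JL-JL", "JL-TH", "JL-YB", "HL", "LN"]
JILIN_LABELS = ["JL-BS", "JL-JL", "JL-TH", "JL-YB"]

_CHANGBAI_PAIRS = {
    ("JL-BS", "JL-JL"): 0.0118,
    ("JL-BS", "JL-TH"): 0.0061,
    ("JL-BS", "JL-YB"): 0.0088,
    ("JL-BS", "HL"): 0.1109,
    ("JL-BS", "LN"): 0.1523,
    ("JL-JL", "JL-TH"): -0.0031,
    ("JL-JL", "JL-YB"): 0.0012,
    ("JL-JL", "HL"): 0.1111,
    ("JL-JL", "LN"): 0.1500,
    ("JL-TH", "JL-YB"): -0.0011,
    ("JL-TH", "HL"): 0.0857,
    ("JL-TH", "LN"): 0.1027,
    ("JL-YB", "HL"): 0.0932,
    ("JL-YB", "LN"): 0.1448,
    ("HL", "LN"): 0.2030,
}


def regional_fst_table() -> FstMatrix:
    """Pairwise Fst among the five geographic regions."""
    return FstMatrix.from_pairs(REGION_LABELS, _REGION_PAIRS)


def changbai_fst_table() -> FstMatrix:
    """Pairwise Fst among the six Changbai Mountain sampling areas."""
    return FstMatrix.from_pairs(CHANGBAI_LABELS, _CHANGBAI_PAIRS)
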
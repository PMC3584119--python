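"""The lepidopteran mitochondrial gene order of the three studied segments.

Feature templates carry the expected type, strand and approximate length of
every feature in each sequenced segment, in forward (stored-strand) order.
They drive both the synthetic genome generator and the window placement of
the rule-based annotator.  Spacer loci exist between every adjacent feature
pair and are named ``isp^<left>-<right>``; most have length zero.

Coordinates are 0-based half-open on the stored forward strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FeatureTemplate", "SEGMENTS", "SEGMENT_IDS", "TRNA_ANTICODONS",
           "spacer_locus", "START_CODONS", "TRNA_GEOMETRY"]

# legitimate mitochondrial PCG start codons (ATN wildcards expanded on use)
START_CODONS = ("ATA", "ATT", "ATC", "ATG", "GTG", "TTG", "GTT")

# anticodons, written in the tRNA coding orientation
TRNA_ANTICODONS = {
    "trnL2": "TAA",   # Leu(UUR)
    "trnK": "CTT",
    "trnD": "GTC",
    "trnH": "GTG",
    "trnS2": "TGA",   # Ser(UCN)
    "trnL1": "TAG",   # Leu(CUN)
    "trnV": "TAC",
}

# canonical cloverleaf geometry used for synthetic tRNAs (coding orientation):
# acceptor stem 7 bp, D stem 4 bp + 7 nt DHU loop, anticodon stem 5 bp +
# 7 nt loop (anticodon centred), 4 nt variable loop, T stem 5 bp + 7 nt
# TPsiC loop.  Total 70 nt.
TRNA_GEOMETRY = {
    "acceptor": 7, "linker1": 2,
    "d_stem": 4, "dhu_loop": 7, "linker2": 1,
    "ac_stem": 5, "ac_loop": 7, "var_loop": 4,
    "t_stem": 5, "t_loop": 7,
}
TRNA_LENGTH = (2 * TRNA_GEOMETRY["acceptor"] + TRNA_GEOMETRY["linker1"]
               + 2 * TRNA_GEOMETRY["d_stem"] + TRNA_GEOMETRY["dhu_loop"]
               + TRNA_GEOMETRY["linker2"] + 2 * TRNA_GEOMETRY["ac_stem"]
               + TRNA_GEOMETRY["ac_loop"] + TRNA_GEOMETRY["var_loop"]
               + 2 * TRNA_GEOMETRY["t_stem"] + TRNA_GEOMETRY["t_loop"])


@dataclass(frozen=True)
class FeatureTemplate:
    gene: str
    type: str            # PCG | tRNA | rRNA | control_region
    strand: str          # '+' or '-'
    length: int          # expected length on the stored strand, nt
    stop: str = "TAA"    # PCG only: TAA/TAG or T/TA for truncated stops


# gene body lengths follow the studied (partial) genes; PCG lengths exclude
# the stop codon, which `stop` appends (possibly truncated)
SEGMENTS: dict[str, list[FeatureTemplate]] = {
    "cox1_cox3": [
        FeatureTemplate("cox1", "PCG", "+", 1458),
        FeatureTemplate("trnL2", "tRNA", "+", TRNA_LENGTH),
        FeatureTemplate("cox2", "PCG", "+", 681, stop="T"),
        FeatureTemplate("trnK", "tRNA", "+", TRNA_LENGTH),
        FeatureTemplate("trnD", "tRNA", "+", TRNA_LENGTH),
        FeatureTemplate("atp8", "PCG", "+", 186),
        FeatureTemplate("atp6", "PCG", "+", 675),
        FeatureTemplate("cox3", "PCG", "+", 102),
    ],
    "nad5_nad4": [
        FeatureTemplate("nad5", "PCG", "-", 1497),
        FeatureTemplate("trnH", "tRNA", "-", TRNA_LENGTH),
        FeatureTemplate("nad4", "PCG", "-", 267, stop="TA"),
    ],
    "cob_CR": [
        FeatureTemplate("cob", "PCG", "+", 558),
        FeatureTemplate("trnS2", "tRNA", "+", TRNA_LENGTH),
        FeatureTemplate("nad1", "PCG", "-", 936),
        FeatureTemplate("trnL1", "tRNA", "-", TRNA_LENGTH),
        FeatureTemplate("rrnL", "rRNA", "-", 1400),
        FeatureTemplate("trnV", "tRNA", "-", TRNA_LENGTH),
        FeatureTemplate("rrnS", "rRNA", "-", 787),
        FeatureTemplate("AT_rich", "control_region", "+", 350),
    ],
}

SEGMENT_IDS = list(SEGMENTS)

# nuclear CDS templates (gene, length in nt, multiple of 3)
NUCLEAR_GENES = {"EF-1a": 999, "wng": 309, "pho": 651}


def spacer_locus(left: str, right: str) -> str:
    return f"isp^{left}-{right}"


def segment_spacer_loci(segment_id: str) -> list[str]:
    feats = SEGMENTS[segment_id]
    return [spacer_locus(a.gene, b.gene) for a, b in zip(feats, feats[1:])]
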
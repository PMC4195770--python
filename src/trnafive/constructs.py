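"""Reference synthetic tRNA constructs.

Synthetic oligonucleotides used in in vitro
angiogenin cleavage assays of tRNA-Asp(GTC): a wild-type 75-mer carrying
the CCA tail, with a variant methylated at the two variable-loop-junction
cytosines (m5C at sequential positions 47 and 48, 1-based).  Under the
pipeline's structural numbering those two cytosines sit at positions 48
and 49 (the last variable-loop base and the first paired T-stem base).

The cloverleaf of this molecule: 7-bp acceptor stem, 4-bp D stem with an
8-nt D loop, 5-bp anticodon stem with a 7-nt loop (anticodon GTC at
34-36), a 4-nt variable loop, and a 5-bp T stem with a 7-nt loop,
followed by the discriminator base and the CCA tail.
"""

from __future__ import annotations

from .model import TRNAGene

# 75 nt, written 5'->3' in the DNA alphabet (U -> T); last three bases CCA.
ASP_GTC_SEQUENCE = (
    "TCCTCGTTAGTATAGTGGTTAGTATCCCCGCCTGTCACGCGGGAGACCGGGGTTCAATTCCCCGACGGGGAGCCA"
)

# cloverleaf, segment by segment (acceptor 5', linker, D arm, linker,
# anticodon arm, variable loop, T arm, acceptor 3', discriminator + CCA)
ASP_GTC_DOT_BRACKET = (
    "(((((((" + ".." + "((((" + "........" + "))))" + "." +
    "(((((" + "......." + ")))))" + "...." +
    "(((((" + "......." + ")))))" + ")))))))" + "." + "..."
)

#: 1-based sequential positions of the two m5C marks on the methylated variant
ASP_GTC_M5C_POSITIONS = (47, 48)


def asp_gtc_construct() -> TRNAGene:
    """The synthetic Asp-GTC construct as an annotated gene model
    (CCA tail included in the sequence)."""
    return TRNAGene.from_structure(
        "Asp-GTC-synthetic",
        "Asp",
        "GTC",
        ASP_GTC_SEQUENCE,
        ASP_GTC_DOT_BRACKET,
        cca_included=True,
    )
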
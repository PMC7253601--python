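"""Published sequence fixtures for the cop-operon operator analyses.

These are the printed oligonucleotide sequences used in the CopR-CopY binding
studies: the 18 candidate-operator 27-mers with their experimental binding
outcome (7 L. lactis CopR sites plus S. pneumoniae candidates and the two
native cop operators), and the 61-base S. pneumoniae cop promoter fragment
containing both operator repeats.  They make the scanner's concordance checks
runnable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["OperatorProbe", "TABLE2_PROBES", "COP_PROMOTER_61MER"]


@dataclass(frozen=True)
class OperatorProbe:
    """A tested 27-mer with its organism, nearest gene, and binding outcome."""

    organism: str
    gene: str
    sequence: str
    binds: bool


#: The 18 tested candidate operator sites (9 bound, 9 not).
TABLE2_PROBES: tuple[OperatorProbe, ...] = (
    OperatorProbe("Lactococcus lactis", "ytjD1", "AAATAGTTTACAAGTGTAAATTTATTT", True),
    OperatorProbe("Lactococcus lactis", "ydiD", "AAAATGTTTACATGTGTAAATTTTCAC", True),
    OperatorProbe("Lactococcus lactis", "copR", "TTAGTGTTTACACGTGTAAACTTATCT", True),
    OperatorProbe("Lactococcus lactis", "copB", "TGATAGTTTACAATTGTAAACTATATA", True),
    OperatorProbe("Lactococcus lactis", "yahC", "TTTTCGTTTACAATTGTAAACATAGAA", True),
    OperatorProbe("Lactococcus lactis", "lctO", "CTATCATCTACAGATGTAAACTTTATA", True),
    OperatorProbe("Lactococcus lactis", "ytjD2", "GATAAGATTACATATGTAAACAATAAA", True),
    OperatorProbe("Lactococcus lactis", "yfhF", "TAAGTATATACATCTGTAAAACTGAAA", False),
    OperatorProbe("Lactococcus lactis", "yxdE", "TTTGCTATTACACTTGTATCACATAAA", False),
    OperatorProbe("Streptococcus pneumoniae", "Sp_0090_1", "TGATTTAGGACATTTGTTTGATAGTGG", False),
    OperatorProbe("Streptococcus pneumoniae", "Sp_0090_2", "GAGTATACTAATAATGTAATCGTTATC", False),
    OperatorProbe("Streptococcus pneumoniae", "Sp_0045", "GGTGAACTAACAGATGTTTACGAAATT", False),
    OperatorProbe("Streptococcus pneumoniae", "Sp_0530", "ATTTGAGGAACAAATGTACGTTTATAA", False),
    OperatorProbe("Streptococcus pneumoniae", "Sp_1433", "GTAATTATAACAGATGTATAATAGAAA", False),
    OperatorProbe("Streptococcus pneumoniae", "Sp_1863", "ATGAATAAAACAATTGTAACACTCATC", False),
    OperatorProbe("Streptococcus pneumoniae", "Sp_2073", "AAGGCGGAAACATGTGTCAATGACTTG", False),
    OperatorProbe("Streptococcus pneumoniae", "copY_proximal", "GTGTAATTGACAAATGTAGATTTTGGA", True),
    OperatorProbe("Streptococcus pneumoniae", "copY_distal", "CTATAATTGACAAATGTAGATTTTAAG", True),
)

#: 61-base S. pneumoniae cop promoter fragment carrying both operator repeats
#: (the EMSA probe); the two 16-base operators sit 24 bases apart.
COP_PROMOTER_61MER = (
    "TAATTGACAAATGTAGATTTTAAGAGTATACTGATGAGTGTAATTGACAAATGTAGATTTT"
)
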
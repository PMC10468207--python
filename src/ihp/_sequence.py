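"""Synthetic stand-in CaMKII-alpha subunit sequence.

This is a SYNTHETIC 478-residue sequence, generated once with a fixed seed,
used only as a scaffold for placing simulated DSS crosslink sites.  It is
*not* the real UniProt Q9UQM7 sequence; it reproduces only the features the
simulations need: standard 20-letter alphabet, tryptic K/R sites at
realistic spacing, and lysines in every subunit domain, including K42 in
the kinase domain and the K344/K347 pair in the hub domain that anchor the
default domain boundaries.
"""

from __future__ import annotations

SUBUNIT_LENGTH = 478

# synthetic; see module docstring
SYNTHETIC_SUBUNIT_SEQUENCE = (
    "LIGHEIQSTKGWVFQEFLKEKLMLTFLVSLTKGQSGVISNFKGKSPFLIETEPWRNSPED"
    "PLHMRCNEINSIIVKRVQFPGHFWMKLIEQTNSSNWNKIKVSNNSPGTKDNLNNFPRQSG"
    "DLPEKPVQPSEENLIDKGKSVSGYSRTNLEFVYRMGICLDTNKDYLFLNIMRENQGDFVV"
    "KLKLLMVVFPDIDEKYTFTSDVPVVPPGRSVMSADGFSFKKLLVSQVIEVVKLVVGYESI"
    "LCPKCQNIEKNGMQKGTSIETNNPGRKSPILVLRSSTTIKSCMVMTRMQFKSVEANTMSK"
    "KVPNNNELDEIPGKNECDHNKDYAGEKFVKTDSVSLIKQKFVLKTCKNSIVDKYDTEGTT"
    "LNPNHKVENFVGIGPSTHRKSILVIEALFQRTVVTELVTKNPHEETNFHKGRPPYNIMCV"
    "TSRLPSDLTFGILPIGREVANKNKPQGSYPREYLVNQPLFVTGKTSKSQTPVGPNYRV"
)

assert len(SYNTHETIC_SUBUNIT_SEQUENCE) == SUBUNIT_LENGTH


def lysine_positions(start: int = 1, end: int = SUBUNIT_LENGTH) -> list[int]:
    """1-based positions of lysines within [start, end] inclusive."""
    return [
        i + 1
        for i, aa in enumerate(SYNTHETIC_SUBUNIT_SEQUENCE)
        if aa == "K" and start <= i + 1 <= end
    ]


def tryptic_peptide(pos: int, sequence: str = SYNTHETIC_SUBUNIT_SEQUENCE) -> str:
    """Tryptic peptide containing 1-based residue ``pos``.

    The peptide runs from the residue after the previous K/R up to and
    including the first K/R at or after ``pos``.  A crosslinked lysine at
    ``pos`` therefore sits at the peptide C-terminus (one missed cleavage
    at the modified site is implicit, as DSS blocks tryptic cleavage).
    """
    if not 1 <= pos <= len(sequence):
        raise ValueError(f"position {pos} outside sequence of length {len(sequence)}")
    i = pos - 1
    start = 0
    for j in range(i - 1, -1, -1):
        if sequence[j] in "KR":
            start = j + 1
            break
    end = len(sequence)
    for j in range(i, len(sequence)):
        if sequence[j] in "KR":
            end = j + 1
            break
    return sequence[start:end]
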
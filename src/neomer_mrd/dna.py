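"""Small DNA-string helpers shared by the catalog and the scanner."""

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of a sequence and its reverse complement.

    Used as the strand-free key under which neomers are deduplicated and
    stored; the original orientation is recorded separately.
    """
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def is_acgt(seq: str) -> bool:
    return not set(seq) - VALID_BASES
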
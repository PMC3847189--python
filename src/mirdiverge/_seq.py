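"""Small sequence helpers shared across modules.

Transcript-side sequences (miRNA matures, hairpins, UTRs) are RNA (ACGU);
genomes are DNA (ACGT). Conversion happens at module boundaries.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")
GAP = "-"

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_TO_RNA = str.maketrans("Tt", "Uu")
_TO_DNA = str.maketrans("Uu", "Tt")


def to_rna(seq: str) -> str:
    """Uppercase and transliterate T -> U."""
    return seq.upper().translate(_TO_RNA)


def to_dna(seq: str) -> str:
    """Uppercase and transliterate U -> T."""
    return seq.upper().translate(_TO_DNA)


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def validate_alphabet(seq: str, alphabet: frozenset, *, what: str = "sequence",
                      allow_gap: bool = False) -> None:
    allowed = alphabet | {GAP} if allow_gap else alphabet
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{what} contains characters outside {''.join(sorted(allowed))}: "
                         f"{''.join(sorted(bad))}")
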
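"""Restriction enzymes and recognition-site search.

TRFLP fragment arithmetic only needs two facts about an enzyme: the IUPAC
recognition pattern and where within the site the top strand is cut. Both
enzymes used for AM-fungal SSU fingerprinting (AluI, HinfI) recognise
reverse-complement-palindromic sites, so scanning one strand finds every
double-stranded site; this is asserted when an enzyme is registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "IUPAC_CODES",
    "RestrictionEnzyme",
    "AluI",
    "HinfI",
    "DEFAULT_ENZYMES",
    "DEFAULT_CHANNEL_RULE",
    "find_recognition_sites",
    "reverse_complement",
]

# IUPAC nucleotide codes -> set of unambiguous bases each matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a (possibly IUPAC-ambiguous) nucleotide string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _is_rc_palindrome(pattern: str) -> bool:
    """True if the IUPAC pattern equals its own reverse complement as a base set."""
    rc = reverse_complement(pattern)
    if len(rc) != len(pattern):
        return False
    return all(IUPAC_CODES[a] == IUPAC_CODES[b] for a, b in zip(pattern, rc))


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme defined by its recognition site.

    Parameters
    ----------
    name:
        Conventional enzyme name, e.g. ``"AluI"``.
    recognition:
        IUPAC pattern of the recognition site (length ``r``).
    cut_offset:
        Number of bases of the site left of the cut on the scanned strand
        (``0 <= cut_offset <= r``). AluI AG^CT has offset 2; HinfI G^ANTC
        has offset 1.
    """

    name: str
    recognition: str
    cut_offset: int
    require_palindromic: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        pattern = self.recognition.upper()
        object.__setattr__(self, "recognition", pattern)
        bad = set(pattern) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC codes in pattern: {sorted(bad)}")
        if not pattern:
            raise ValueError(f"{self.name}: empty recognition pattern")
        if not 0 <= self.cut_offset <= len(pattern):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside pattern "
                f"of length {len(pattern)}"
            )
        if self.require_palindromic and not _is_rc_palindrome(pattern):
            raise ValueError(
                f"{self.name}: pattern {pattern!r} is not a reverse-complement "
                "palindrome; single-strand scanning would miss sites"
            )

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    def duplex_cut_offset(self) -> float:
        """Mean of the top- and bottom-strand cut coordinates within the site.

        For a palindromic site cut after ``c`` bases on the top strand, the
        bottom strand is cut ``r - c`` bases in, so the duplex mean is
        ``r / 2`` regardless of ``c``. Blunt cutters (AluI) give an integer;
        odd-length sites with overhangs (HinfI, r = 5) give half-integers.
        """
        return (self.cut_offset + (self.site_length - self.cut_offset)) / 2.0


AluI = RestrictionEnzyme("AluI", "AGCT", 2)
HinfI = RestrictionEnzyme("HinfI", "GANTC", 1)

DEFAULT_ENZYMES: dict[str, RestrictionEnzyme] = {"AluI": AluI, "HinfI": HinfI}

#: Channel rule for the AM1/NS31 assay: only HEX-labelled AluI fragments and
#: FAM-labelled HinfI fragments are informative; the complementary channels
#: are short and invariant across genotypes.
DEFAULT_CHANNEL_RULE: dict[str, str] = {"AluI": "HEX", "HinfI": "FAM"}

_UNAMBIGUOUS = frozenset("ACGT")


def _check_unambiguous(sequence: str) -> None:
    bad = set(sequence) - _UNAMBIGUOUS
    if bad:
        raise ValueError(
            "sequence contains IUPAC ambiguity codes or invalid characters "
            f"{sorted(bad)}; digestion requires unambiguous A/C/G/T"
        )


def find_recognition_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Locate every recognition site of `enzyme` on the stored strand.

    Parameters
    ----------
    sequence:
        Unambiguous nucleotide string (A/C/G/T only; ambiguity codes raise).
    enzyme:
        The enzyme whose IUPAC pattern is matched at every offset.

    Returns
    -------
    list of int
        0-based start positions of matches, ascending. Patterns longer than
        the sequence yield an empty list.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    _check_unambiguous(seq)
    pattern = [IUPAC_CODES[c] for c in enzyme.recognition]
    r = len(pattern)
    out: list[int] = []
    for i in range(len(seq) - r + 1):
        if all(seq[i + j] in pattern[j] for j in range(r)):
            out.append(i)
    return out
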
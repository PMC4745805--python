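"""In-silico tryptic digestion.

Trypsin cleaves C-terminal of lysine (K) and arginine (R).  Classical
digestion rules suppress cleavage when the next residue is proline; search
engines expose this as an option, and the workflow modelled here runs
*without* the proline restriction, i.e. K/R followed by P is still a
cleavage site.  Digestion feeds two consumers:

* peptide enumeration with missed cleavages (identification-side bookkeeping),
* the iBAQ denominator — the number of "observable" fully-tryptic peptides,
  conventionally those of 7–30 residues.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import parser as _pyt_parser

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

# cleavage C-terminal of K/R; the restricted variant skips sites followed by P
_RULE_NO_PROLINE_RESTRICTION = r"(?<=[KR])"
_RULE_PROLINE_RESTRICTION = r"(?<=[KR])(?!P)"


@dataclass(frozen=True)
class DigestConfig:
    """Parameters of the tryptic digest.

    max_missed_cleavages : missed cleavage sites allowed inside a peptide.
    proline_restriction : if True, K/R followed by P is not a cleavage site.
    observable_min_len / observable_max_len : length window (residues) for
        peptides counted as mass-spectrometrically observable (iBAQ
        denominator); applied to the fully-cleaved digest only.
    """

    max_missed_cleavages: int = 2
    proline_restriction: bool = False
    observable_min_len: int = 7
    observable_max_len: int = 30

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.observable_min_len > self.observable_max_len:
            raise ValueError(
                "observable_min_len must not exceed observable_max_len"
            )

    @property
    def rule(self) -> str:
        if self.proline_restriction:
            return _RULE_PROLINE_RESTRICTION
        return _RULE_NO_PROLINE_RESTRICTION


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("protein sequence is empty")
    for pos, aa in enumerate(sequence):
        if aa not in CANONICAL_AA:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {pos} "
                f"(1-based {pos + 1})"
            )


def in_silico_tryptic_digest(
    sequence: str, config: DigestConfig | None = None
) -> list[str]:
    """All tryptic peptides of ``sequence`` with 0..max missed cleavages.

    Peptides are returned in order of their start position (then by length),
    with multiplicity: a peptide occurring twice in the sequence appears
    twice.  Uses pyteomics' cleavage machinery with the K/R rule selected by
    ``config.proline_restriction``.
    """
    config = config or DigestConfig()
    _validate_sequence(sequence)
    frags = _pyt_parser.xcleave(
        sequence,
        config.rule,
        missed_cleavages=config.max_missed_cleavages,
        min_length=0,
    )
    # a cleavage site at the C-terminus makes pyteomics emit the terminal
    # fragment once per missed-cleavage count; keep one copy per position
    frags = sorted(set(frags), key=lambda item: (item[0], len(item[1])))
    return [pep for _, pep in frags]


def count_observable_peptides(
    sequence: str, config: DigestConfig | None = None
) -> int:
    """Number of fully-cleaved peptides inside the observable length window.

    This is the iBAQ denominator: peptides of the 0-missed-cleavage digest
    whose length lies in [observable_min_len, observable_max_len].
    """
    config = config or DigestConfig()
    _validate_sequence(sequence)
    frags = _pyt_parser.xcleave(sequence, config.rule, missed_cleavages=0,
                                min_length=0)
    lo, hi = config.observable_min_len, config.observable_max_len
    return sum(1 for _, pep in frags if lo <= len(pep) <= hi)
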
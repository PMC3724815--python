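"""RNA sequence container with alphabet normalization.

All sequences in the pipeline are held 5'->3'.  DNA-alphabet input (T) is
silently normalized to U, since mRNA records fetched from sequence databases
commonly arrive in the DNA alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: Mature animal miRNAs are ~22 nt; lengths far outside this band are suspect
#: but not fatal (isomiRs, non-standard annotations).
MIRNA_LENGTH_RANGE = (15, 30)


class Role(Enum):
    MIRNA = "miRNA"
    TARGET = "target"


class SequenceError(ValueError):
    """Raised for sequences that cannot be normalized to A/C/G/U."""


def normalize_residues(raw: str, identifier: str = "?") -> str:
    """Uppercase, map T->U, and validate against the RNA alphabet."""
    residues = raw.strip().upper().replace("T", "U")
    bad = set(residues) - RNA_ALPHABET
    if bad:
        raise SequenceError(
            f"record {identifier!r} contains non-RNA characters: "
            f"{''.join(sorted(bad))}"
        )
    if "T" in raw.upper():
        logger.debug("record %r: DNA alphabet detected, T normalized to U", identifier)
    return residues


@dataclass(frozen=True)
class RNASequence:
    """A validated single-stranded RNA sequence, oriented 5'->3'."""

    identifier: str
    residues: str
    role: Role = field(default=Role.TARGET)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, self.identifier)
        )
        if not self.residues:
            raise SequenceError(f"record {self.identifier!r} is empty")
        if self.role is Role.MIRNA:
            lo, hi = MIRNA_LENGTH_RANGE
            if not lo <= len(self.residues) <= hi:
                logger.warning(
                    "miRNA %r has unusual length %d (expected %d-%d nt)",
                    self.identifier, len(self.residues), lo, hi,
                )

    def __len__(self) -> int:
        return len(self.residues)
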
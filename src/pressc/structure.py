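"""Structure-status encoding of (sequence, dot-bracket) pairs.

Each position gets one of ten statuses: the four unpaired bases A, C, G, U,
or one of six orientation-distinguished pair statuses A-U, U-A, G-C, C-G,
G-U, U-G. Pair statuses carry a free energy (hydrogen-bond proxy) used by
the long-range correlation factors: Watson-Crick A-U pairs -2 kcal/mol,
G-C pairs -3, wobble G-U pairs -1, unpaired bases 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from pressc.rna_io import AnnotatedRna

__all__ = [
    "STATUS_ALPHABET",
    "STATUS_INDEX",
    "UNPAIRED",
    "StructureError",
    "FreeEnergyTable",
    "build_pair_table",
    "pair_count",
    "assign_statuses",
    "status_free_energy",
]

#: Fixed status order used for every feature-vector layout.
STATUS_ALPHABET: tuple[str, ...] = (
    "A", "C", "G", "U", "A-U", "U-A", "G-C", "C-G", "G-U", "U-G",
)
STATUS_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATUS_ALPHABET)}

#: Sentinel partner index for unpaired positions.
UNPAIRED = -1

_CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

_DEFAULT_ENERGIES: dict[str, float] = {
    "A": 0.0, "C": 0.0, "G": 0.0, "U": 0.0,
    "A-U": -2.0, "U-A": -2.0,
    "G-C": -3.0, "C-G": -3.0,
    "G-U": -1.0, "U-G": -1.0,
}

OWN_FIRST = "own-first"
FIVE_PRIME_FIRST = "five-prime-first"


class StructureError(ValueError):
    """Invalid dot-bracket structure or non-canonical pairing."""


def _reverse_status(status: str) -> str:
    if "-" not in status:
        return status
    a, b = status.split("-")
    return f"{b}-{a}"


@dataclass(frozen=True)
class FreeEnergyTable:
    """Free energy per structure status, kcal/mol.

    Must be symmetric under pair-orientation reversal so that the
    correlation factors do not depend on which strand side a pair is read
    from.
    """

    energy: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_ENERGIES))

    def __post_init__(self) -> None:
        missing = set(STATUS_ALPHABET) - set(self.energy)
        if missing:
            raise ValueError(f"free-energy table missing statuses: {sorted(missing)}")
        for status in STATUS_ALPHABET[4:]:
            rev = _reverse_status(status)
            if self.energy[status] != self.energy[rev]:
                raise ValueError(
                    f"free-energy table not orientation-symmetric: "
                    f"F({status})={self.energy[status]} != F({rev})={self.energy[rev]}"
                )

    @classmethod
    def from_config(cls, source) -> "FreeEnergyTable":
        """Build a table from ``status<TAB or =>value`` lines, overriding defaults."""
        energies = dict(_DEFAULT_ENERGIES)
        lines = source.splitlines() if isinstance(source, str) else source
        for raw in lines:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.replace("=", "\t").partition("\t")
            status = key.strip()
            if status not in STATUS_INDEX:
                raise ValueError(f"unknown status in free-energy config: {status!r}")
            energies[status] = float(value.strip())
        return cls(energy=energies)


DEFAULT_ENERGY_TABLE = FreeEnergyTable()


def build_pair_table(structure: str) -> list[int]:
    """Match nested brackets into a partner table.

    Returns a list where entry *i* is the 0-based partner of position *i*,
    or :data:`UNPAIRED`. Unbalanced brackets raise :class:`StructureError`
    with the position of the first violation; pseudoknot notations are
    rejected outright.
    """
    partner = [UNPAIRED] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[j] = i
            partner[i] = j
        elif ch != ".":
            raise StructureError(
                f"invalid structure symbol {ch!r} at position {i} "
                "(pseudoknot and other notations are not supported)"
            )
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[0]}")
    return partner


def pair_count(partner: Sequence[int]) -> int:
    return sum(1 for p in partner if p != UNPAIRED) // 2


def assign_statuses(
    rna: AnnotatedRna,
    partner: Optional[Sequence[int]] = None,
    convention: str = OWN_FIRST,
) -> tuple[str, ...]:
    """Assign the 10-symbol structure status to every position.

    Unpaired positions get their base; paired positions get a composite
    ``X-Y`` status. Under the default ``own-first`` convention X is the
    position's own base and Y its partner's, so the two partners carry
    mirrored statuses; under ``five-prime-first`` both partners carry the
    pair read 5'→3'.
    """
    if partner is None:
        if rna.structure is None:
            raise StructureError(f"record {rna.id!r}: no structure to assign statuses from")
        partner = build_pair_table(rna.structure)
    if len(partner) != len(rna.residues):
        raise StructureError(
            f"record {rna.id!r}: pair table length {len(partner)} "
            f"!= sequence length {len(rna.residues)}"
        )
    if convention not in (OWN_FIRST, FIVE_PRIME_FIRST):
        raise ValueError(f"unknown status convention {convention!r}")

    seq = rna.residues
    statuses = []
    for i, p in enumerate(partner):
        if p == UNPAIRED:
            statuses.append(seq[i])
            continue
        if (seq[i], seq[p]) not in _CANONICAL_PAIRS:
            raise StructureError(
                f"record {rna.id!r}: non-canonical pair {seq[i]}-{seq[p]} "
                f"at positions {i} and {p}"
            )
        if convention == OWN_FIRST:
            statuses.append(f"{seq[i]}-{seq[p]}")
        else:
            five, three = (i, p) if i < p else (p, i)
            statuses.append(f"{seq[five]}-{seq[three]}")
    return tuple(statuses)


def status_free_energy(status: str, table: FreeEnergyTable = DEFAULT_ENERGY_TABLE) -> float:
    """Free energy of one status, kcal/mol."""
    try:
        return table.energy[status]
    except KeyError:
        raise StructureError(f"unknown structure status {status!r}") from None
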
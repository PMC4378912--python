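"""Labeled synthetic hairpins and decoys with controllable separation.

Structures are *planted*, not folded: the generator emits the dot-bracket
alongside the sequence, so status-assignment ground truth is exact and no
external folding software is needed. Decoys reuse the same sequence
construction but weaken the planted stem (fewer, interrupted pairs), so
the two classes differ in structure features while their base composition
is drawn from identical distributions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Optional

from pressc.rna_io import NEGATIVE, POSITIVE, AnnotatedRna
from pressc.structure import DEFAULT_ENERGY_TABLE, FreeEnergyTable

__all__ = ["HairpinSpec", "SyntheticError", "generate_hairpin", "generate_decoy", "generate_dataset"]

_BASES = "ACGU"
_GC_PAIRS = (("G", "C"), ("C", "G"))
_WEAK_PAIRS = (("A", "U"), ("U", "A"), ("G", "U"), ("U", "G"))


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class HairpinSpec:
    """Construction parameters for one planted stem-loop."""

    stem_len: int = 22
    loop_len: int = 4
    bulge_rate: float = 0.0
    gc_bias: float = 0.5
    flank_len: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_len < 1:
            raise SyntheticError(f"stem_len must be >= 1, got {self.stem_len}")
        if self.loop_len < 3:
            raise SyntheticError(f"loop_len must be >= 3 (minimal hairpin loop), got {self.loop_len}")
        for name in ("bulge_rate", "gc_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticError(f"{name} must lie in [0, 1], got {v}")
        if self.flank_len < 0:
            raise SyntheticError(f"flank_len must be >= 0, got {self.flank_len}")


def _build(
    spec: HairpinSpec,
    rng: random.Random,
    broken: frozenset[int],
) -> tuple[str, str]:
    """Assemble sequence and dot-bracket; stem positions in ``broken`` stay unpaired."""
    pairs = []
    for _ in range(spec.stem_len):
        pool = _GC_PAIRS if rng.random() < spec.gc_bias else _WEAK_PAIRS
        pairs.append(pool[rng.randrange(len(pool))])

    five_seq, five_struct = [], []
    for k, (b5, _) in enumerate(pairs):
        five_seq.append(b5)
        five_struct.append("." if k in broken else "(")
        if rng.random() < spec.bulge_rate:
            five_seq.append(rng.choice(_BASES))
            five_struct.append(".")

    loop = [rng.choice(_BASES) for _ in range(spec.loop_len)]
    three_seq, three_struct = [], []
    for k in range(spec.stem_len - 1, -1, -1):
        three_seq.append(pairs[k][1])
        three_struct.append("." if k in broken else ")")

    flank5 = [rng.choice(_BASES) for _ in range(spec.flank_len)]
    flank3 = [rng.choice(_BASES) for _ in range(spec.flank_len)]
    seq = "".join(flank5 + five_seq + loop + three_seq + flank3)
    struct = "".join(
        ["."] * len(flank5) + five_struct + ["."] * len(loop) + three_struct + ["."] * len(flank3)
    )
    return seq, struct


def _planted_mfe(seq: str, struct: str, table: FreeEnergyTable) -> float:
    stack, total = [], 0.0
    for i, ch in enumerate(struct):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            total += table.energy[f"{seq[j]}-{seq[i]}"]
    return total


def generate_hairpin(
    spec: HairpinSpec,
    record_id: Optional[str] = None,
    table: FreeEnergyTable = DEFAULT_ENERGY_TABLE,
) -> AnnotatedRna:
    """One positive record with a fully planted stem of ``spec.stem_len`` pairs."""
    rng = random.Random(spec.seed)
    seq, struct = _build(spec, rng, frozenset())
    return AnnotatedRna(
        id=record_id or f"hairpin_{spec.seed}",
        residues=seq,
        structure=struct,
        mfe=_planted_mfe(seq, struct, table),
        label=POSITIVE,
    )


def generate_decoy(
    spec: HairpinSpec,
    seed: Optional[int] = None,
    break_rate: float = 1.0 / 3.0,
    record_id: Optional[str] = None,
    table: FreeEnergyTable = DEFAULT_ENERGY_TABLE,
) -> AnnotatedRna:
    """One negative record: same sequence construction, interrupted stem.

    Each stem pair is independently broken (left unpaired on both sides)
    with probability ``break_rate``, at least one always; the sequence
    itself is generated exactly as for a positive of the same spec, so the
    mononucleotide composition distributions match.
    """
    spec = replace(spec, seed=spec.seed if seed is None else seed)
    rng = random.Random(spec.seed)
    broken = {k for k in range(spec.stem_len) if rng.random() < break_rate}
    if not broken:
        broken = {rng.randrange(spec.stem_len)}
    seq, struct = _build(spec, rng, frozenset(broken))
    return AnnotatedRna(
        id=record_id or f"decoy_{spec.seed}",
        residues=seq,
        structure=struct,
        mfe=_planted_mfe(seq, struct, table),
        label=NEGATIVE,
    )


def generate_dataset(
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    pos_spec: HairpinSpec = HairpinSpec(stem_len=22),
    neg_spec: HairpinSpec = HairpinSpec(stem_len=8),
    table: FreeEnergyTable = DEFAULT_ENERGY_TABLE,
) -> list[AnnotatedRna]:
    """n_pos planted hairpins followed by n_neg decoys, all seeded from ``seed``."""
    rng = random.Random(seed)
    records = []
    for i in range(n_pos):
        s = replace(pos_spec, seed=rng.randrange(2 ** 31))
        records.append(generate_hairpin(s, record_id=f"pos_{i:04d}", table=table))
    for i in range(n_neg):
        s = replace(neg_spec, seed=rng.randrange(2 ** 31))
        records.append(generate_decoy(s, record_id=f"neg_{i:04d}", table=table))
    return records
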
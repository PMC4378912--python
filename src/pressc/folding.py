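"""Pluggable secondary-structure folding backends.

Production runs use an external thermodynamic folder (e.g. RNAfold)
wrapped as a subprocess; tests and the synthetic pipeline use a
deterministic maximum-base-pairing folder. The baseline folder is
explicitly non-thermodynamic: its "MFE" is a pseudo energy summed from the
per-status free-energy table.
"""

from __future__ import annotations

import io
import shlex
import subprocess
from dataclasses import dataclass
from typing import Protocol

from pressc.rna_io import AnnotatedRna, RnaIoError, read_vienna, write_fasta
from pressc.structure import DEFAULT_ENERGY_TABLE, UNPAIRED, FreeEnergyTable

__all__ = [
    "FoldingBackend",
    "FoldingError",
    "BaselineFolder",
    "ExternalFolder",
    "baseline_fold",
    "external_fold",
]

_PAIRABLE = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


class FoldingError(RuntimeError):
    """Folding backend unavailable or produced malformed output."""


class FoldingBackend(Protocol):
    name: str

    def fold(self, rna: AnnotatedRna) -> AnnotatedRna: ...


def _pseudo_mfe(residues: str, partner: list[int], table: FreeEnergyTable) -> float:
    # Each pair counted once, from its 5' side.
    total = 0.0
    for i, p in enumerate(partner):
        if p > i:
            total += table.energy[f"{residues[i]}-{residues[p]}"]
    return total


def baseline_fold(
    rna: AnnotatedRna,
    min_loop: int = 3,
    table: FreeEnergyTable = DEFAULT_ENERGY_TABLE,
) -> AnnotatedRna:
    """Maximum base pairing by dynamic programming (Nussinov-style).

    Pairs are canonical Watson-Crick plus G-U wobble, subject to
    ``j - i > min_loop``. Traceback is deterministic: a position pairs with
    the largest admissible partner achieving the optimum, bifurcating at
    the smallest split. The pseudo-MFE sums the status free energies over
    the 5'-side of each pair.
    """
    seq = rna.residues
    L = len(seq)
    if L == 0:
        raise FoldingError(f"record {rna.id!r}: cannot fold an empty sequence")

    def pairable(i: int, j: int) -> bool:
        return j - i > min_loop and (seq[i], seq[j]) in _PAIRABLE

    # M[i][j] = max pairs in seq[i..j]; recurrence on whether i is paired.
    M = [[0] * L for _ in range(L)]
    for span in range(min_loop + 1, L):
        for i in range(L - span):
            j = i + span
            best = M[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if pairable(i, k):
                    inner = M[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    outer = M[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + inner + outer)
            M[i][j] = best

    partner = [UNPAIRED] * L
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        paired = False
        # Largest admissible partner first: deterministic traceback.
        for k in range(j, i + min_loop, -1):
            if pairable(i, k):
                inner = M[i + 1][k - 1] if k - 1 >= i + 1 else 0
                outer = M[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + outer == M[i][j]:
                    partner[i], partner[k] = k, i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))

    structure = "".join(
        "." if p == UNPAIRED else ("(" if p > i else ")") for i, p in enumerate(partner)
    )
    return rna.with_structure(structure, mfe=_pseudo_mfe(seq, partner, table))


@dataclass(frozen=True)
class BaselineFolder:
    """Deterministic max-pairing backend for tests and synthetic data."""

    min_loop: int = 3
    table: FreeEnergyTable = DEFAULT_ENERGY_TABLE
    name: str = "baseline"

    def fold(self, rna: AnnotatedRna) -> AnnotatedRna:
        return baseline_fold(rna, min_loop=self.min_loop, table=self.table)


def external_fold(records: list[AnnotatedRna], command: str) -> list[AnnotatedRna]:
    """Fold a batch of records through an external Vienna-format folder.

    The command receives all records as FASTA on stdin in one invocation
    and must emit Vienna records (``>id`` / sequence / structure with MFE)
    on stdout.
    """
    if not command or not command.strip():
        raise FoldingError(
            "no external folder configured: set the folder command "
            "(config key 'folder-cmd' / option --folder-cmd)"
        )
    buf = io.StringIO()
    write_fasta(records, buf)
    try:
        proc = subprocess.run(
            shlex.split(command),
            input=buf.getvalue(),
            capture_output=True,
            text=True,
            check=False,
        )
    except FileNotFoundError as exc:
        raise FoldingError(
            f"external folder executable not found ({command!r}); "
            "check the 'folder-cmd' configuration"
        ) from exc
    if proc.returncode != 0:
        raise FoldingError(
            f"external folder exited with status {proc.returncode}: "
            f"{proc.stderr.strip()[:500]}"
        )
    try:
        folded = read_vienna(io.StringIO(proc.stdout))
    except RnaIoError as exc:
        raise FoldingError(f"malformed folder output: {exc}") from exc

    by_id = {rec.id: rec for rec in folded}
    out = []
    for rec in records:
        got = by_id.get(rec.id)
        if got is None:
            raise FoldingError(f"folder output missing record {rec.id!r}")
        if got.residues != rec.residues:
            raise FoldingError(f"folder altered the sequence of record {rec.id!r}")
        if len(got.structure) != len(rec.residues):
            raise FoldingError(
                f"folder output for {rec.id!r} has structure length "
                f"{len(got.structure)}, expected {len(rec.residues)}"
            )
        out.append(rec.with_structure(got.structure, mfe=got.mfe))
    return out


@dataclass(frozen=True)
class ExternalFolder:
    """Subprocess wrapper around a Vienna-format folding executable."""

    command: str
    name: str = "external"

    def fold(self, rna: AnnotatedRna) -> AnnotatedRna:
        return self.fold_many([rna])[0]

    def fold_many(self, records: list[AnnotatedRna]) -> list[AnnotatedRna]:
        return external_fold(records, self.command)
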
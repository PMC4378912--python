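"""Benchmark assembly: pseudo-hairpin admission filters, class balancing
and an external redundancy-reduction hook.

A candidate pseudo hairpin is admitted when its length lies in
[51, 137] nt, its folded structure has at least 18 base pairs, and its MFE
is at most -15 kcal/mol — all boundaries inclusive.
"""

from __future__ import annotations

import logging
import random
import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from pressc.rna_io import AnnotatedRna, read_fasta, write_fasta
from pressc.structure import build_pair_table, pair_count

__all__ = [
    "FilterCriteria",
    "DatasetError",
    "admit_pseudo_hairpin",
    "balance_subsample",
    "reduce_redundancy_external",
]

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class FilterCriteria:
    min_len: int = 51
    max_len: int = 137
    min_pairs: int = 18
    max_mfe: float = -15.0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise DatasetError(f"min_len {self.min_len} > max_len {self.max_len}")
        if self.min_pairs < 0:
            raise DatasetError(f"min_pairs must be >= 0, got {self.min_pairs}")


def admit_pseudo_hairpin(
    rna: AnnotatedRna, crit: FilterCriteria = FilterCriteria()
) -> tuple[bool, str]:
    """Check the three admission criteria; on failure name the first violated one."""
    if rna.structure is None or rna.mfe is None:
        raise DatasetError(f"record {rna.id!r}: structure and MFE required for admission")
    L = len(rna.residues)
    if not crit.min_len <= L <= crit.max_len:
        return False, f"length {L} outside [{crit.min_len}, {crit.max_len}]"
    pairs = pair_count(build_pair_table(rna.structure))
    if pairs < crit.min_pairs:
        return False, f"{pairs} base pairs < minimum {crit.min_pairs}"
    if rna.mfe > crit.max_mfe:
        return False, f"MFE {rna.mfe} above maximum {crit.max_mfe} kcal/mol"
    return True, "admitted"


def balance_subsample(
    records: Sequence[AnnotatedRna], target_count: int, seed: int = 0
) -> list[AnnotatedRna]:
    """Seeded uniform subset without replacement, preserving input order."""
    if target_count > len(records):
        raise DatasetError(
            f"cannot subsample {target_count} from {len(records)} records"
        )
    indices = list(range(len(records)))
    random.Random(seed).shuffle(indices)
    keep = sorted(indices[:target_count])
    return [records[i] for i in keep]


def reduce_redundancy_external(
    fasta_path: str,
    identity: float = 0.8,
    command: Optional[str] = None,
    skip: bool = False,
) -> list[str]:
    """Run an external clustering tool (CD-HIT style) and return retained ids.

    Purely a wrapper: the tool is invoked as
    ``<command> -i <in> -o <out> -c <identity>`` and its representative
    FASTA output is parsed for ids. With ``skip=True`` (or when the stage
    is disabled by flag upstream) every id is retained and a warning logged.
    """
    all_ids = [rec.id for rec in read_fasta(fasta_path)]
    if skip:
        logger.warning("redundancy reduction skipped: retaining all %d records", len(all_ids))
        return all_ids
    if not command:
        raise DatasetError(
            "no clustering command configured: set --cdhit-cmd or pass skip=True"
        )
    if not 0.0 < identity <= 1.0:
        raise DatasetError(f"identity cutoff {identity} outside (0, 1]")
    with tempfile.TemporaryDirectory() as tmp:
        out_path = Path(tmp) / "representatives.fasta"
        argv = shlex.split(command) + ["-i", fasta_path, "-o", str(out_path), "-c", str(identity)]
        try:
            proc = subprocess.run(argv, capture_output=True, text=True, check=False)
        except FileNotFoundError as exc:
            raise DatasetError(
                f"clustering executable not found ({command!r}); install it or "
                "skip the reduction stage"
            ) from exc
        if proc.returncode != 0:
            raise DatasetError(
                f"clustering tool failed (exit {proc.returncode}, cutoff {identity}): "
                f"{proc.stderr.strip()[:500]}"
            )
        return [rec.id for rec in read_fasta(str(out_path))]
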
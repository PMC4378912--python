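"""Feature vectors built on the structure-status encoding.

Two vector families are produced:

* the structure-status composition vector — normalized n-tuple status
  frequencies (``10**n`` components) extended with ``lam`` tiered
  correlation factors weighted by ``w``, all sharing one normalizing
  denominator so the vector sums to 1;
* its extended form — the same vector concatenated with the structure's
  minimum free energy, a Monte-Carlo randomization-test P-value, and the
  64 overlapping tri-nucleotide frequencies (66 extra components).

The correlation factor at tier ``j`` is the mean squared free-energy
difference between statuses ``j`` positions apart, capturing long-range
structure order that the local tuple counts cannot see.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from pressc.rna_io import AnnotatedRna
from pressc.structure import (
    DEFAULT_ENERGY_TABLE,
    STATUS_ALPHABET,
    STATUS_INDEX,
    FreeEnergyTable,
)

__all__ = [
    "PSESSC",
    "EXPSESSC",
    "PsesscParams",
    "FeatureVector",
    "FeatureError",
    "ntuple_ssc",
    "theta_factors",
    "pse_ssc",
    "trinucleotide_composition",
    "randomization_pvalue",
    "ex_pse_ssc",
    "shuffle_residues",
]

PSESSC = "PseSSC"
EXPSESSC = "ExPseSSC"

_BASES = ("A", "C", "G", "U")
TRINUCLEOTIDES = tuple("".join(t) for t in itertools.product(_BASES, repeat=3))


class FeatureError(ValueError):
    """Invalid feature-extraction input or parameters."""


@dataclass(frozen=True)
class PsesscParams:
    """Feature parameters: tuple rank ``n``, correlation depth ``lam``, weight ``w``."""

    n: int = 2
    lam: int = 13
    w: float = 0.5

    def __post_init__(self) -> None:
        if not isinstance(self.n, int) or self.n < 1:
            raise FeatureError(f"n must be an integer >= 1, got {self.n}")
        if not isinstance(self.lam, int) or self.lam < 1:
            raise FeatureError(f"lam must be an integer >= 1, got {self.lam}")
        if not 0.0 <= self.w <= 1.0:
            raise FeatureError(f"w must lie in [0, 1], got {self.w}")

    @property
    def pse_dim(self) -> int:
        return 10 ** self.n + self.lam

    @property
    def ex_dim(self) -> int:
        return self.pse_dim + 66


@dataclass
class FeatureVector:
    """A computed feature vector together with its generating parameters."""

    record_id: str
    kind: str
    params: PsesscParams
    values: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.params.pse_dim if self.kind == PSESSC else self.params.ex_dim
        if self.kind not in (PSESSC, EXPSESSC):
            raise FeatureError(f"unknown feature kind {self.kind!r}")
        if self.values.shape != (expected,):
            raise FeatureError(
                f"record {self.record_id!r}: {self.kind} with params {self.params} "
                f"must have dimension {expected}, got {self.values.shape}"
            )

    def feature_names(self) -> list[str]:
        names = [
            "|".join(t)
            for t in itertools.product(STATUS_ALPHABET, repeat=self.params.n)
        ]
        names += [f"theta_{j}" for j in range(1, self.params.lam + 1)]
        if self.kind == EXPSESSC:
            names += ["mfe", "pvalue"] + [f"tri_{t}" for t in TRINUCLEOTIDES]
        return names


def ntuple_ssc(statuses: Sequence[str], n: int) -> np.ndarray:
    """Normalized sliding-window n-tuple status frequencies.

    Component order is lexicographic over the fixed status alphabet; with
    10 statuses the tuple at alphabet indices ``(i_1 … i_n)`` lands at the
    base-10 positional index ``i_1 i_2 … i_n``.
    """
    L = len(statuses)
    if n < 1:
        raise FeatureError(f"n must be >= 1, got {n}")
    if L < n:
        raise FeatureError(f"sequence of {L} statuses is too short for n={n} tuples")
    counts = np.zeros(10 ** n, dtype=float)
    idx = [STATUS_INDEX[s] for s in statuses]
    for start in range(L - n + 1):
        code = 0
        for k in range(n):
            code = code * 10 + idx[start + k]
        counts[code] += 1.0
    return counts / (L - n + 1)


def theta_factors(
    statuses: Sequence[str],
    lam: int,
    table: FreeEnergyTable = DEFAULT_ENERGY_TABLE,
) -> np.ndarray:
    """Tiered correlation factors theta_1 … theta_lam.

    theta_j is the mean over positions of the squared free-energy
    difference between statuses j apart; requires ``lam < L``.
    """
    L = len(statuses)
    if lam < 1:
        raise FeatureError(f"lam must be >= 1, got {lam}")
    if lam >= L:
        raise FeatureError(
            f"lam={lam} violates the constraint lam < L for a sequence of length {L}"
        )
    F = np.array([table.energy[s] for s in statuses])
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        d = F[:-j] - F[j:]
        thetas[j - 1] = float(np.mean(d * d))
    return thetas


def pse_ssc(
    statuses: Sequence[str],
    params: PsesscParams,
    table: FreeEnergyTable = DEFAULT_ENERGY_TABLE,
    record_id: str = "",
    label: Optional[str] = None,
) -> FeatureVector:
    """Structure-status composition vector of dimension ``10**n + lam``.

    The first ``10**n`` components are the tuple frequencies and the last
    ``lam`` the weighted correlation factors, all divided by
    ``sum(f) + w * sum(theta)`` so the vector sums to 1.
    """
    f = ntuple_ssc(statuses, params.n)
    theta = theta_factors(statuses, params.lam, table)
    denom = f.sum() + params.w * theta.sum()
    values = np.concatenate([f, params.w * theta]) / denom
    return FeatureVector(record_id=record_id, kind=PSESSC, params=params,
                         values=values, label=label)


def trinucleotide_composition(rna: AnnotatedRna) -> np.ndarray:
    """Overlapping 3-mer frequencies in lexicographic A<C<G<U order, summing to 1."""
    L = len(rna.residues)
    if L < 3:
        raise FeatureError(f"record {rna.id!r}: length {L} < 3, no tri-nucleotides")
    counts = np.zeros(64, dtype=float)
    base_idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    seq = rna.residues
    for i in range(L - 2):
        code = base_idx[seq[i]] * 16 + base_idx[seq[i + 1]] * 4 + base_idx[seq[i + 2]]
        counts[code] += 1.0
    return counts / (L - 2)


def shuffle_residues(residues: str, rng: random.Random, method: str = "mono") -> str:
    """Composition-preserving shuffle of a sequence.

    ``mono`` permutes residues uniformly; ``dinucleotide`` preserves all
    dinucleotide counts via the Eulerian-path (Altschul-Erikson) scheme,
    which matters when downstream energies are dinucleotide-sensitive.
    """
    if method == "mono":
        chars = list(residues)
        rng.shuffle(chars)
        return "".join(chars)
    if method != "dinucleotide":
        raise FeatureError(f"unknown shuffle method {method!r}")
    if len(residues) < 3:
        return residues

    first, last = residues[0], residues[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(residues, residues[1:]):
        edges.setdefault(a, []).append(b)

    vertices = list(edges)
    for _ in range(1000):
        # Pick a random terminal edge per non-final vertex; keep only
        # selections whose terminal edges lead every vertex to the last one.
        last_edge = {
            v: rng.choice(edges[v]) for v in vertices if v != last
        }
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for valid input
        raise FeatureError("dinucleotide shuffle failed to find an Eulerian ordering")

    pools = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        pools[v] = rest

    out = [first]
    cur = first
    positions = {v: 0 for v in pools}
    for _ in range(len(residues) - 1):
        nxt = pools[cur][positions[cur]]
        positions[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def randomization_pvalue(
    rna: AnnotatedRna,
    backend,
    shuffles: int = 100,
    seed: int = 0,
    method: str = "mono",
) -> float:
    """Monte-Carlo randomization-test P-value for the observed MFE.

    Folds ``shuffles`` composition-preserving permutations of the sequence
    and reports ``(c + 1) / (shuffles + 1)`` where ``c`` counts shuffles
    whose MFE is at least as low as the observed one; never returns 0.
    """
    if shuffles < 1:
        raise FeatureError(f"shuffles must be >= 1, got {shuffles}")
    observed = rna.mfe
    if observed is None:
        observed = backend.fold(rna).mfe
    rng = random.Random(seed)
    c = 0
    for _ in range(shuffles):
        shuffled = AnnotatedRna(id=rna.id, residues=shuffle_residues(rna.residues, rng, method))
        if backend.fold(shuffled).mfe <= observed:
            c += 1
    return (c + 1) / (shuffles + 1)


def ex_pse_ssc(
    rna: AnnotatedRna,
    statuses: Sequence[str],
    params: PsesscParams,
    table: FreeEnergyTable = DEFAULT_ENERGY_TABLE,
    b_value: Optional[float] = None,
) -> FeatureVector:
    """Extended vector: [pse-ssc | MFE | P-value | 64 tri-nucleotide frequencies]."""
    if rna.mfe is None:
        raise FeatureError(f"record {rna.id!r}: MFE required for the extended vector")
    if b_value is None:
        raise FeatureError(
            f"record {rna.id!r}: randomization P-value (b_value) required; "
            "compute it with randomization_pvalue or supply it from a manifest"
        )
    base = pse_ssc(statuses, params, table, record_id=rna.id, label=rna.label)
    values = np.concatenate(
        [base.values, [rna.mfe, b_value], trinucleotide_composition(rna)]
    )
    return FeatureVector(record_id=rna.id, kind=EXPSESSC, params=params,
                         values=values, label=rna.label)
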
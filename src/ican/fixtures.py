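"""Synthetic peptides and curated small molecules for testing and demos.

Every generator is a pure function of its seed. The separable
classification task labels peptides by whether they contain a
sulfur-bearing residue (cysteine or methionine): sulfur is the rarest
element of the protein alphabet, so under any mode that counts S the
classes are separable on the sulfur rows and a relevance heat map has an
unambiguous expected hot region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import FastaRecord

__all__ = [
    "SyntheticTask",
    "AMINO_ACIDS",
    "SULFUR_RESIDUES",
    "gen_random_peptides",
    "gen_separable_task",
    "fixture_molecules",
    "AMINO_ACID_FORMULAS",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
SULFUR_RESIDUES = ("C", "M")
_NON_SULFUR = tuple(a for a in AMINO_ACIDS if a not in SULFUR_RESIDUES)

#: Molecular formulas of the 20 standard free amino acids (element -> count),
#: the independent reference for the peptide-to-SMILES conversion.
AMINO_ACID_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 5, "N": 1, "O": 2},
    "A": {"C": 3, "H": 7, "N": 1, "O": 2},
    "V": {"C": 5, "H": 11, "N": 1, "O": 2},
    "L": {"C": 6, "H": 13, "N": 1, "O": 2},
    "I": {"C": 6, "H": 13, "N": 1, "O": 2},
    "P": {"C": 5, "H": 9, "N": 1, "O": 2},
    "F": {"C": 9, "H": 11, "N": 1, "O": 2},
    "W": {"C": 11, "H": 12, "N": 2, "O": 2},
    "M": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "C": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "S": {"C": 3, "H": 7, "N": 1, "O": 3},
    "T": {"C": 4, "H": 9, "N": 1, "O": 3},
    "Y": {"C": 9, "H": 11, "N": 1, "O": 3},
    "N": {"C": 4, "H": 8, "N": 2, "O": 3},
    "Q": {"C": 5, "H": 10, "N": 2, "O": 3},
    "D": {"C": 4, "H": 7, "N": 1, "O": 4},
    "E": {"C": 5, "H": 9, "N": 1, "O": 4},
    "K": {"C": 6, "H": 14, "N": 2, "O": 2},
    "R": {"C": 6, "H": 14, "N": 4, "O": 2},
    "H": {"C": 6, "H": 9, "N": 3, "O": 2},
}


@dataclass
class SyntheticTask:
    """A labeled FASTA data set with a stated generating rule."""

    records: list[FastaRecord]
    labels: np.ndarray  # 0/1 per record
    rule: str
    seed: int


def gen_random_peptides(
    n: int,
    length_range: tuple[int, int] = (5, 30),
    seed: int = 0,
    alphabet: tuple[str, ...] = AMINO_ACIDS,
    prefix: str = "pep",
) -> list[FastaRecord]:
    """n random peptides, residues i.i.d. uniform over the alphabet,
    lengths uniform over the inclusive range. Deterministic given seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}: need 1 <= min <= max")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        records.append(FastaRecord(f"{prefix}{i}", seq))
    return records


def gen_separable_task(
    n: int = 200,
    length_range: tuple[int, int] = (5, 30),
    seed: int = 7,
) -> SyntheticTask:
    """Balanced binary task: positives contain >= 1 cysteine, negatives are
    sulfur-free.

    Sequences are drawn over the three-carbon residues alanine, serine and
    cysteine — positives uniformly over {A, C, S} with one cysteine forced
    if none was drawn, negatives uniformly over {A, S}. Because A, S and C
    all contribute exactly three backbone carbons, residue i always
    occupies the same three array columns in every sequence, so the
    encoding's positional features are aligned across the data set and the
    sulfur rows are the only systematic class difference. The classes are
    therefore linearly separable on the sulfur rows, a forest trained on
    the encoding concentrates its impurity-based importance there, and the
    expected hot rows of a relevance heat map are unambiguous.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}: need 1 <= min <= max")
    records: list[FastaRecord] = []
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        if i < n_pos:
            seq = list(rng.choice(("A", "C", "S"), size=length))
            if "C" not in seq:
                seq[int(rng.integers(0, length))] = "C"
            labels[i] = 1
        else:
            seq = list(rng.choice(("A", "S"), size=length))
        records.append(FastaRecord(f"pep{i}", "".join(seq)))
    return SyntheticTask(
        records=records,
        labels=labels,
        rule="label 1 iff the sequence contains a cysteine",
        seed=seed,
    )


def fixture_molecules() -> list[tuple[str, str, dict[str, int]]]:
    """Curated small molecules: (name, SMILES, expected formula)."""
    return [
        ("methane", "C", {"C": 1, "H": 4}),
        ("ethane", "CC", {"C": 2, "H": 6}),
        ("isobutane", "CC(C)C", {"C": 4, "H": 10}),
        ("cyclohexane", "C1CCCCC1", {"C": 6, "H": 12}),
        ("phenol", "C1=CC=C(C=C1)O", {"C": 6, "H": 6, "O": 1}),
        ("glycine", "NCC(=O)O", {"C": 2, "H": 5, "N": 1, "O": 2}),
        ("methionine", "NC(CCSC)C(=O)O", {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1}),
        # cyclo(Gly-Gly), the simplest cyclic peptide (2,5-diketopiperazine)
        ("cyclo_diglycine", "O=C1CNC(=O)CN1", {"C": 4, "H": 6, "N": 2, "O": 2}),
        ("ethanethiol", "CCS", {"C": 2, "H": 6, "S": 1}),
    ]
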
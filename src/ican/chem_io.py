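"""Input handling: FASTA records, peptide-to-SMILES conversion, molecular graphs.

Peptides arrive as single-letter FASTA sequences; arbitrary organic
molecules arrive as SMILES strings. Both funnel into a :class:`MolGraph`,
an undirected labeled graph with explicit hydrogens on which all
neighborhood counting is performed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "FastaRecord",
    "MolGraph",
    "ParseError",
    "NoCarbonBackboneError",
    "STANDARD_RESIDUES",
    "read_fasta",
    "write_fasta",
    "convert_fasta_to_smiles",
    "parse_smiles",
    "collect_unique_elements",
    "read_smiles_file",
    "canonical_element_order",
]


class ParseError(ValueError):
    """Raised for malformed FASTA/SMILES input; the message names the culprit."""


class NoCarbonBackboneError(ParseError):
    """Raised for molecules without a single carbon atom (no backbone to walk)."""


#: SMILES fragments for the 20 standard amino-acid residues, written so that
#: the linear peptide N(1)...C(=O)-N(2)...C(=O)-...-OH is obtained by plain
#: string concatenation of the fragments followed by a terminal "O".
#: Each fragment starts with the backbone nitrogen and ends with the carbonyl
#: "C(=O)", so joining fragments forms the amide bond and removes one water
#: per bond implicitly. No stereochemistry markers are used.
STANDARD_RESIDUES: dict[str, str] = {
    "G": "NCC(=O)",
    "A": "NC(C)C(=O)",
    "V": "NC(C(C)C)C(=O)",
    "L": "NC(CC(C)C)C(=O)",
    "I": "NC(C(C)CC)C(=O)",
    "P": "N1CCCC1C(=O)",
    "F": "NC(CC1=CC=CC=C1)C(=O)",
    "W": "NC(CC1=CNC2=CC=CC=C12)C(=O)",
    "M": "NC(CCSC)C(=O)",
    "C": "NC(CS)C(=O)",
    "S": "NC(CO)C(=O)",
    "T": "NC(C(O)C)C(=O)",
    "Y": "NC(CC1=CC=C(O)C=C1)C(=O)",
    "N": "NC(CC(N)=O)C(=O)",
    "Q": "NC(CCC(N)=O)C(=O)",
    "D": "NC(CC(O)=O)C(=O)",
    "E": "NC(CCC(O)=O)C(=O)",
    "K": "NC(CCCCN)C(=O)",
    "R": "NC(CCCNC(N)=N)C(=O)",
    "H": "NC(CC1=CNC=N1)C(=O)",
}

_VALID_RESIDUES = frozenset(STANDARD_RESIDUES)

# fixed head of the canonical element order; everything else sorts after it
_CANONICAL_HEAD = ("H", "C", "N", "O", "S")


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA entry: an identifier and an uppercase amino-acid sequence."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record '{self.identifier}': empty sequence")
        bad = [(i, c) for i, c in enumerate(self.sequence) if c not in _VALID_RESIDUES]
        if bad:
            pos, char = bad[0]
            raise ParseError(
                f"record '{self.identifier}': invalid residue character "
                f"'{char}' at position {pos + 1} (only the 20 standard "
                f"one-letter codes are accepted)"
            )


@dataclass
class MolGraph:
    """Undirected atom graph with explicit hydrogens.

    Nodes are integer ordinals following first appearance in the SMILES
    text (heavy atoms) with hydrogens appended after; each node carries an
    ``element`` attribute. Edges carry a ``order`` attribute with the bond
    order, recorded for motif inspection only — neighborhood counting
    treats every bond as a single adjacency.
    """

    graph: nx.Graph
    smiles: str = ""

    @property
    def atoms(self) -> list[int]:
        return sorted(self.graph.nodes)

    def element(self, node: int) -> str:
        return self.graph.nodes[node]["element"]

    def carbons(self) -> list[int]:
        """Carbon ordinals in ascending order."""
        return [n for n in sorted(self.graph.nodes) if self.element(n) == "C"]

    def element_counts(self) -> Counter:
        """Molecular formula as an element → count mapping (H included)."""
        return Counter(d["element"] for _, d in self.graph.nodes(data=True))

    def elements(self) -> set[str]:
        return set(self.element_counts())


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Parse a FASTA file into validated records.

    Sequences are uppercased and whitespace-stripped; wrapped sequence
    lines are joined. Raises :class:`ParseError` naming the offending line
    for text before the first header, empty sequences, or residue letters
    outside the 20 standard codes.
    """
    path = Path(path)
    records: list[FastaRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"line {header_line}: record '{header}' has an empty sequence")
        records.append(FastaRecord(header, seq))

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"line {lineno}: malformed header '{line}'")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence data before any '>' header")
                chunks.append(line.upper().replace(" ", ""))
    flush()
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path) -> None:
    """Write records as standard multi-record FASTA (one sequence line each)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n{rec.sequence}\n")


def convert_fasta_to_smiles(sequence: str) -> str:
    """Assemble the SMILES of the linear peptide for a one-letter sequence.

    Residue fragments are condensed N-to-C, removing one water per peptide
    bond; the product has a free N-terminal amine and a free C-terminal
    carboxylic acid. Example: ``"G" -> "NCC(=O)O"``,
    ``"GG" -> "NCC(=O)NCC(=O)O"``.
    """
    if not sequence:
        raise ParseError("empty sequence")
    parts = []
    for pos, letter in enumerate(sequence.upper(), start=1):
        frag = STANDARD_RESIDUES.get(letter)
        if frag is None:
            raise ParseError(
                f"unknown residue letter '{letter}' at position {pos}; "
                "supply SMILES directly for non-standard residues"
            )
        parts.append(frag)
    return "".join(parts) + "O"


def parse_smiles(smiles: str, require_carbon: bool = True) -> MolGraph:
    """Parse a SMILES string into a :class:`MolGraph` with explicit hydrogens.

    Aromatic notation is kekulized during sanitization so hydrogen counts
    are well defined; hydrogens are added as degree-1 nodes to satisfy
    standard valences. Multi-fragment (dot-separated) SMILES are accepted
    and yield one graph with several connected components.
    """
    smiles = smiles.strip()
    if not smiles:
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: '{smiles}'")
    mol = Chem.AddHs(mol)

    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=bond.GetBondTypeAsDouble(),
        )
    mg = MolGraph(graph=g, smiles=smiles)
    if require_carbon and not mg.carbons():
        raise NoCarbonBackboneError(f"no carbon backbone in '{smiles}'")
    return mg


def canonical_element_order(elements: Iterable[str]) -> list[str]:
    """Order element symbols H, C, N, O, S first (those present), rest alphabetically."""
    present = set(elements)
    head = [e for e in _CANONICAL_HEAD if e in present]
    tail = sorted(present - set(_CANONICAL_HEAD))
    return head + tail


def collect_unique_elements(graphs: Sequence[MolGraph]) -> list[str]:
    """Union of element symbols across graphs, in canonical order."""
    if not graphs:
        raise ValueError("collect_unique_elements requires at least one graph")
    seen: set[str] = set()
    for g in graphs:
        seen |= g.elements()
    return canonical_element_order(seen)


def read_smiles_file(path: str | Path, column: str | None = None) -> list[tuple[str, str]]:
    """Read SMILES as (identifier, smiles) pairs.

    Plain text: one SMILES per line, optionally followed by whitespace and a
    name; identifiers default to the 1-based line index. CSV: pass the name
    of the SMILES column; an ``id`` column is used when present.
    """
    path = Path(path)
    if column is not None:
        import pandas as pd

        df = pd.read_csv(path)
        if column not in df.columns:
            raise ParseError(f"{path}: no column '{column}' (have {list(df.columns)})")
        ids = df["id"].astype(str) if "id" in df.columns else df.index.astype(str)
        return list(zip(ids, df[column].astype(str)))
    pairs: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            name = fields[1] if len(fields) > 1 else str(lineno)
            pairs.append((name, fields[0]))
    if not pairs:
        raise ParseError(f"{path}: no SMILES found")
    return pairs
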
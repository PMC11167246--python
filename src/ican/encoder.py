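"""The counting-array encoder.

A molecule is encoded as an integer matrix whose columns are the backbone
carbons in traversal order and whose rows are (element, level) pairs:
one block of element rows per neighborhood level, level-1 block first.
Cell (e, l, j) holds how many atoms of element e sit at shortest-path
distance exactly l from the j-th backbone carbon. Per-molecule arrays are
flattened column-by-column and zero-padded to a common length to form the
feature matrix handed to ML models.

Three element alphabets are supported: mode 1 counts the five most
abundant elements in proteins (H, C, N, O, S); mode 2 drops hydrogen
(C, N, O, S); mode 3 is data-driven and counts every element present in
the data set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import chem_io
from .backbone import build_neighbor_directory, index_carbons
from .chem_io import FastaRecord, MolGraph, ParseError

__all__ = [
    "ElementAlphabet",
    "EncodingConfig",
    "CountingArray",
    "DatasetLayout",
    "EncodedDataset",
    "MODE1_ELEMENTS",
    "MODE2_ELEMENTS",
    "build_alphabet",
    "encode_molecule",
    "flatten_and_pad",
    "unflatten",
    "encode_dataset",
]

MODE1_ELEMENTS = ("H", "C", "N", "O", "S")
MODE2_ELEMENTS = ("C", "N", "O", "S")


@dataclass(frozen=True)
class ElementAlphabet:
    """Ordered element symbols to count. mode is 1, 2 or 3."""

    mode: int
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)


@dataclass(frozen=True)
class EncodingConfig:
    """User-facing knobs: alphabet mode and number of neighborhood levels."""

    mode: int = 1
    levels: int = 2

    def __post_init__(self) -> None:
        if self.mode not in (1, 2, 3):
            raise ValueError(f"mode must be 1, 2 or 3, got {self.mode}")
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")


@dataclass
class CountingArray:
    """Per-molecule counting array.

    values has shape (len(alphabet) * levels, n_carbons); row blocks are
    level-major (all elements at level 1, then level 2, ...). Column j
    corresponds to the j-th backbone carbon of the traversal.
    """

    values: np.ndarray
    alphabet: ElementAlphabet
    levels: int
    carbon_ordinals: tuple[int, ...]
    name: str = ""

    @property
    def n_carbons(self) -> int:
        return self.values.shape[1]

    def row_labels(self) -> list[str]:
        return [
            f"{elem}_L{level}"
            for level in range(1, self.levels + 1)
            for elem in self.alphabet.symbols
        ]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"C{j}" for j in range(self.n_carbons)]
        return pd.DataFrame(self.values, index=self.row_labels(), columns=cols)

    def flatten(self) -> np.ndarray:
        """Concatenate columns in order (column-by-column flattening)."""
        return self.values.flatten(order="F")


@dataclass(frozen=True)
class DatasetLayout:
    """Everything needed to un-flatten a feature row back into array coordinates."""

    alphabet: ElementAlphabet
    levels: int
    max_carbons: int

    @property
    def n_rows(self) -> int:
        return len(self.alphabet) * self.levels

    @property
    def vector_length(self) -> int:
        return self.n_rows * self.max_carbons

    def feature_names(self) -> list[str]:
        names = []
        for col in range(self.max_carbons):
            for level in range(1, self.levels + 1):
                for elem in self.alphabet.symbols:
                    names.append(f"{elem}_L{level}_C{col}")
        return names

    def to_dict(self) -> dict:
        return {
            "mode": self.alphabet.mode,
            "alphabet": list(self.alphabet.symbols),
            "levels": self.levels,
            "max_carbons": self.max_carbons,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetLayout":
        return cls(
            alphabet=ElementAlphabet(d["mode"], tuple(d["alphabet"])),
            levels=d["levels"],
            max_carbons=d["max_carbons"],
        )


@dataclass
class EncodedDataset:
    """Stacked, padded feature matrix plus the layout metadata."""

    matrix: np.ndarray  # (n_molecules, layout.vector_length), int
    layout: DatasetLayout
    names: list[str]
    carbon_counts: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.names, columns=self.layout.feature_names())

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write PREFIX.csv (feature matrix) and PREFIX.layout.json."""
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".csv")
        layout_path = prefix.with_suffix(".layout.json")
        df = self.to_frame()
        df.insert(0, "id", self.names)
        df.to_csv(csv_path, index=False)
        meta = self.layout.to_dict()
        meta["carbon_counts"] = self.carbon_counts
        layout_path.write_text(json.dumps(meta, indent=2), encoding="utf-8")
        return csv_path, layout_path

    @classmethod
    def load(cls, prefix: str | Path) -> "EncodedDataset":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"))
        meta = json.loads(prefix.with_suffix(".layout.json").read_text(encoding="utf-8"))
        names = df["id"].astype(str).tolist()
        matrix = df.drop(columns=["id"]).to_numpy(dtype=np.int64)
        return cls(
            matrix=matrix,
            layout=DatasetLayout.from_dict(meta),
            names=names,
            carbon_counts=list(meta["carbon_counts"]),
        )


def build_alphabet(mode: int, graphs: Sequence[MolGraph] | None = None) -> ElementAlphabet:
    """Build the element alphabet for a mode.

    Modes 1 and 2 are fixed lists; mode 3 derives the alphabet from the
    data (union of elements over all graphs, canonical order) and
    therefore requires graphs.
    """
    if mode == 1:
        return ElementAlphabet(1, MODE1_ELEMENTS)
    if mode == 2:
        return ElementAlphabet(2, MODE2_ELEMENTS)
    if mode == 3:
        if not graphs:
            raise ValueError("mode 3 is data-driven and requires at least one molecule")
        return ElementAlphabet(3, tuple(chem_io.collect_unique_elements(graphs)))
    raise ValueError(f"mode must be 1, 2 or 3, got {mode}")


def encode_molecule(
    graph: MolGraph,
    alphabet: ElementAlphabet,
    levels: int,
    name: str = "",
) -> CountingArray:
    """Encode one molecule into its counting array.

    Elements outside the alphabet are simply not counted; they still
    occupy graph distance (an oxygen between two carbons keeps them two
    apart under mode 2).
    """
    indexing = index_carbons(graph)
    directory = build_neighbor_directory(graph, indexing, levels)
    n_elem = len(alphabet)
    values = np.zeros((n_elem * levels, len(indexing)), dtype=np.int64)
    for j, carbon in enumerate(indexing):
        for level in range(1, levels + 1):
            counts = directory.counts(carbon, level)
            base = (level - 1) * n_elem
            for i, elem in enumerate(alphabet.symbols):
                values[base + i, j] = counts.get(elem, 0)
    return CountingArray(
        values=values,
        alphabet=alphabet,
        levels=levels,
        carbon_ordinals=tuple(indexing),
        name=name,
    )


def flatten_and_pad(arrays: Sequence[CountingArray]) -> EncodedDataset:
    """Flatten arrays column-by-column and zero-pad to the data-set maximum.

    All arrays must share alphabet and levels. Row i of the result is
    array i's columns concatenated in order followed by trailing zeros up
    to len(alphabet) * levels * max_carbons.
    """
    if not arrays:
        raise ValueError("flatten_and_pad requires at least one array")
    first = arrays[0]
    for a in arrays[1:]:
        if a.alphabet.symbols != first.alphabet.symbols or a.levels != first.levels:
            raise ValueError("all arrays must share the same alphabet and levels")
    max_carbons = max(a.n_carbons for a in arrays)
    layout = DatasetLayout(alphabet=first.alphabet, levels=first.levels, max_carbons=max_carbons)
    matrix = np.zeros((len(arrays), layout.vector_length), dtype=np.int64)
    for i, a in enumerate(arrays):
        flat = a.flatten()
        matrix[i, : flat.size] = flat
    return EncodedDataset(
        matrix=matrix,
        layout=layout,
        names=[a.name or str(i) for i, a in enumerate(arrays)],
        carbon_counts=[a.n_carbons for a in arrays],
    )


def unflatten(vector: np.ndarray, layout: DatasetLayout) -> np.ndarray:
    """Inverse of column-by-column flattening: vector -> (n_rows, max_carbons)."""
    vector = np.asarray(vector)
    if vector.size != layout.vector_length:
        raise ValueError(
            f"vector length {vector.size} does not match layout length {layout.vector_length}"
        )
    return vector.reshape((layout.n_rows, layout.max_carbons), order="F")


def _to_graphs(
    records: Iterable[FastaRecord | tuple[str, str] | str],
    input_format: str,
) -> tuple[list[tuple[str, MolGraph]], list[tuple[str, str]]]:
    """Normalize heterogeneous inputs to (name, MolGraph) pairs; collect failures."""
    graphs: list[tuple[str, MolGraph]] = []
    failures: list[tuple[str, str]] = []
    for i, rec in enumerate(records):
        if isinstance(rec, FastaRecord):
            name, payload, kind = rec.identifier, rec.sequence, "fasta"
        elif isinstance(rec, tuple):
            name, payload = rec
            kind = input_format
        else:
            name, payload, kind = str(i), rec, input_format
        try:
            smiles = chem_io.convert_fasta_to_smiles(payload) if kind == "fasta" else payload
            graphs.append((name, chem_io.parse_smiles(smiles)))
        except ParseError as exc:
            failures.append((name, str(exc)))
    return graphs, failures


def encode_dataset(
    records: Sequence[FastaRecord | tuple[str, str] | str],
    config: EncodingConfig,
    input_format: str = "smiles",
) -> EncodedDataset:
    """Encode a whole data set: convert, parse, encode, flatten, pad.

    records may be FastaRecord objects, (name, smiles-or-sequence) pairs,
    or bare strings; input_format ("fasta" or "smiles") applies to
    non-FastaRecord entries, so FASTA and SMILES inputs can be mixed.
    Deterministic: identical inputs and config give identical matrices.
    Per-record failures are collected; the run aborts only if every record
    fails.
    """
    if not records:
        raise ValueError("encode_dataset requires at least one record")
    if input_format not in ("fasta", "smiles"):
        raise ValueError(f"input_format must be 'fasta' or 'smiles', got '{input_format}'")
    graphs, failures = _to_graphs(records, input_format)
    if not graphs:
        details = "; ".join(f"{n}: {m}" for n, m in failures)
        raise ParseError(f"all {len(failures)} records failed to encode: {details}")
    if failures:
        import warnings

        warnings.warn(
            f"{len(failures)} record(s) failed and were dropped: "
            + "; ".join(f"{n}: {m}" for n, m in failures),
            stacklevel=2,
        )
    alphabet = build_alphabet(config.mode, [g for _, g in graphs])
    arrays = [encode_molecule(g, alphabet, config.levels, name=n) for n, g in graphs]
    return flatten_and_pad(arrays)
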
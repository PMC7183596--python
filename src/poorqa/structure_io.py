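"""Readers for the file formats the quality-assessment pipeline touches.

Covers CASP-submission-style PDB models (ATOM records, single conformer),
DSSP output files, CASP RR contact-prediction lists, plain-text secondary
structure / solvent accessibility class strings, and delimited score tables
carrying GDT-TS / TM-score quality labels.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "FormatError",
    "Residue",
    "ProteinModel",
    "ContactPrediction",
    "SSPrediction",
    "SAPrediction",
    "QualityTable",
    "read_pdb",
    "extract_domain",
    "read_contact_rr",
    "read_ss_prediction",
    "read_sa_prediction",
    "read_dssp",
    "read_score_table",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to its expected dialect."""


@dataclass
class Residue:
    """One amino-acid residue: PDB number, 3-letter name, atom coordinates (Å)."""

    number: int
    name: str
    atoms: dict[str, np.ndarray]
    icode: str = ""
    chain: str = "A"

    @property
    def key(self) -> tuple[str, int, str]:
        """Composite identity: (chain, PDB residue number, insertion code)."""
        return (self.chain, self.number, self.icode)

    def reference_atom(self) -> Optional[np.ndarray]:
        """Contact reference atom: Cβ, or Cα for glycine / when Cβ is absent."""
        if self.name != "GLY" and "CB" in self.atoms:
            return self.atoms["CB"]
        return self.atoms.get("CA")


@dataclass
class ProteinModel:
    """An ordered protein model parsed from a PDB file.

    Residue numbering is taken verbatim from the file (possibly gapped);
    sequence-position features use the ordered index of residues present.
    """

    model_id: str
    residues: list[Residue]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"model {self.model_id!r} has no residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise FormatError(f"model {self.model_id!r} has duplicate residue numbers")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def coordinates(self, atom: str = "CA") -> np.ndarray:
        """(n, 3) array of one named atom per residue; NaN rows where absent."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, res in enumerate(self.residues):
            if atom in res.atoms:
                out[i] = res.atoms[atom]
        return out

    def reference_coordinates(self) -> np.ndarray:
        """Contact reference atoms (Cβ; Cα for GLY or missing Cβ), NaN where neither."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, res in enumerate(self.residues):
            ref = res.reference_atom()
            if ref is not None:
                out[i] = ref
        return out


@dataclass
class ContactPrediction:
    """Predicted residue–residue contacts with confidences, canonical i < j."""

    pairs: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for i, j, c in self.pairs:
            if i >= j:
                raise ValueError(f"contact pair ({i},{j}) must satisfy i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate contact pair ({i},{j})")
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence {c} outside [0,1] for pair ({i},{j})")
            seen.add((i, j))

    def sorted_by_confidence(self) -> list[tuple[int, int, float]]:
        """Descending confidence; ties broken by ascending (i, j)."""
        return sorted(self.pairs, key=lambda p: (-p[2], p[0], p[1]))


@dataclass
class SSPrediction:
    """Three-class secondary-structure prediction, one of H/E/C per position."""

    classes: str

    def __post_init__(self) -> None:
        bad = set(self.classes) - set("HEC")
        if bad:
            raise ValueError(f"invalid secondary-structure classes: {sorted(bad)}")


@dataclass
class SAPrediction:
    """Binary solvent-accessibility prediction, e (exposed) / b (buried)."""

    classes: str

    def __post_init__(self) -> None:
        bad = set(self.classes) - set("eb")
        if bad:
            raise ValueError(f"invalid accessibility classes: {sorted(bad)}")

    def as_binary(self) -> str:
        """Exposed → '1', buried → '0'."""
        return self.classes.translate(str.maketrans("eb", "10"))


@dataclass
class QualityTable:
    """model_id → (GDT-TS on [0,100], optional TM-score on [0,1])."""

    entries: dict[str, tuple[float, Optional[float]]] = field(default_factory=dict)

    def gdt_ts(self, model_id: str) -> float:
        return self.entries[model_id][0]

    def tm_score(self, model_id: str) -> Optional[float]:
        return self.entries[model_id][1]


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path: str | Path, model_id: Optional[str] = None) -> ProteinModel:
    """Parse a CASP-submission-style PDB file into a :class:`ProteinModel`.

    Only ATOM records are considered; the first MODEL wins in multi-model
    files; alternate locations resolve to the first occurrence; residues
    lacking Cα/Cβ are retained.
    """
    path = Path(path)
    if model_id is None:
        model_id = path.stem
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(model_id, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no ATOM records found")
    residues: list[Residue] = []
    for chain in models[0]:
        for res in chain:
            hetero, number, icode = res.id
            if hetero.strip():
                continue  # HETATM / water
            atoms: dict[str, np.ndarray] = {}
            for atom in res.get_unpacked_list():
                # altloc: first occurrence in file order wins
                if atom.get_name() in atoms:
                    continue
                coord = np.asarray(atom.get_coord(), dtype=float)
                if not np.all(np.isfinite(coord)):
                    raise FormatError(f"{path}: non-finite coordinate in residue {number}")
                atoms[atom.get_name()] = coord
            residues.append(
                Residue(number=int(number), name=res.get_resname().strip(),
                        atoms=atoms, icode=icode.strip(), chain=str(chain.id))
            )
    if not residues:
        raise FormatError(f"{path}: no ATOM records found")
    return ProteinModel(model_id=model_id, residues=residues, source_path=str(path))


def extract_domain(model: ProteinModel,
                   ranges: Sequence[tuple[int, int]]) -> ProteinModel:
    """Restrict a model to a domain given by residue-number intervals.

    Discontinuous domains collapse to the single closed interval
    [min of all starts, max of all ends] — e.g. 77–134 and 348–520
    become 77–520.
    """
    if not ranges:
        raise ValueError("ranges must be non-empty")
    for start, end in ranges:
        if start > end:
            raise ValueError(f"invalid interval ({start},{end}): start > end")
    lo = min(start for start, _ in ranges)
    hi = max(end for _, end in ranges)
    kept = [r for r in model.residues if lo <= r.number <= hi]
    if not kept:
        raise FormatError(
            f"domain [{lo},{hi}] contains no residues of model {model.model_id!r}")
    return ProteinModel(model_id=model.model_id, residues=kept,
                        source_path=model.source_path)


# ---------------------------------------------------------------------------
# CASP RR contacts

def read_contact_rr(path: str | Path, n_res: int) -> ContactPrediction:
    """Read a CASP RR contact file ("i j d1 d2 p" lines, headers tolerated).

    Pairs are canonicalised to i < j; indices outside [1, n_res] are dropped
    (a warning reports how many); on duplicate (i, j) the first line wins.
    """
    path = Path(path)
    pairs: dict[tuple[int, int], float] = {}
    n_dropped = 0
    for raw in path.read_text().splitlines():
        tokens = raw.split()
        if len(tokens) < 3:
            continue
        try:
            i, j = int(tokens[0]), int(tokens[1])
            conf = float(tokens[-1])
        except ValueError:
            continue  # header / comment line
        if i > j:
            i, j = j, i
        if i == j or i < 1 or j > n_res:
            n_dropped += 1
            continue
        conf = min(max(conf, 0.0), 1.0)
        pairs.setdefault((i, j), conf)
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} out-of-range contact pairs")
    if not pairs:
        raise FormatError(f"{path}: no valid contact pair lines")
    return ContactPrediction(pairs=[(i, j, c) for (i, j), c in pairs.items()])


# ---------------------------------------------------------------------------
# Class-string predictions

def _read_class_string(path: str | Path) -> str:
    """Concatenate non-header lines of a (possibly wrapped) class-string file."""
    chunks = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", ">")):
            continue
        chunks.append(line)
    return "".join(chunks)


def read_ss_prediction(path: str | Path) -> SSPrediction:
    """Read a 3-class secondary-structure string; non-H/E characters map to C."""
    raw = _read_class_string(path)
    if not raw:
        raise FormatError(f"{path}: empty secondary-structure prediction")
    # 8-state DSSP letters and common coil markers collapse to C
    coil = set("GIBTSC-._~ ")
    mapped = []
    for c in raw.upper():
        if c in "HE":
            mapped.append(c)
        elif c in coil:
            mapped.append("C")
        else:
            raise FormatError(
                f"{path}: unmappable secondary-structure character {c!r}")
    return SSPrediction(classes="".join(mapped))


def read_sa_prediction(path: str | Path) -> SAPrediction:
    """Read a binary accessibility string; alphabet {e, b, -} with '-' → buried."""
    raw = _read_class_string(path)
    if not raw:
        raise FormatError(f"{path}: empty accessibility prediction")
    table = {"e": "e", "E": "e", "b": "b", "B": "b", "-": "b"}
    try:
        mapped = "".join(table[c] for c in raw)
    except KeyError as exc:
        raise FormatError(f"{path}: unmappable accessibility character {exc}") from exc
    return SAPrediction(classes=mapped)


# ---------------------------------------------------------------------------
# DSSP output

_DSSP_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def read_dssp(path: str | Path) -> list[tuple[int, str, float]]:
    """Read a DSSP output file into (residue number, 3-state SS, absolute ACC Å²).

    The 8-state DSSP column is collapsed (H,G,I→H; E,B→E; else C); chain-break
    '!' lines are skipped.
    """
    lines = Path(path).read_text().splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = k + 1
            break
    if start is None or start >= len(lines):
        raise FormatError(f"{path}: no DSSP data section found")
    out: list[tuple[int, str, float]] = []
    for line in lines[start:]:
        if len(line) < 38:
            continue
        if line[13] == "!":
            continue  # chain break
        try:
            number = int(line[5:10])
            acc = float(line[34:38])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed DSSP residue line: {line!r}") from exc
        ss8 = line[16]
        out.append((number, _DSSP_COLLAPSE.get(ss8, "C"), acc))
    if not out:
        raise FormatError(f"{path}: DSSP data section is empty")
    return out


# ---------------------------------------------------------------------------
# Quality score tables

def read_score_table(path: str | Path,
                     model_col: str = "model",
                     gdt_col: str = "gdt_ts",
                     tm_col: str = "tm_score") -> QualityTable:
    """Read a delimited quality table (model id, GDT-TS, optional TM-score).

    GDT-TS is accepted on either the [0,1] or [0,100] scale; values ≤ 1 are
    rescaled to the canonical [0,100].
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    if model_col not in df.columns or gdt_col not in df.columns:
        raise FormatError(
            f"{path}: required columns {model_col!r}/{gdt_col!r} not found "
            f"(have {list(df.columns)})")
    entries: dict[str, tuple[float, Optional[float]]] = {}
    for _, row in df.iterrows():
        gdt = float(row[gdt_col])
        if gdt <= 1.0:
            gdt *= 100.0
        if not 0.0 <= gdt <= 100.0:
            raise FormatError(f"{path}: GDT-TS {gdt} outside [0,100]")
        tm = None
        if tm_col in df.columns and pd.notna(row[tm_col]):
            tm = float(row[tm_col])
            if not 0.0 <= tm <= 1.0:
                raise FormatError(f"{path}: TM-score {tm} outside [0,1]")
        entries[str(row[model_col])] = (gdt, tm)
    return QualityTable(entries=entries)
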
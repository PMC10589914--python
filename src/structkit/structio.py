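"""Hierarchical macromolecular data model and PDB/mmCIF file I/O.

The coordinate hierarchy is Structure > Chain > Residue > Atom.  Residues are
identified by author numbering, i.e. the pair ``(number, insertion_code)``,
which is what appears in PDB files and in the literature when a loop is named
"19-38".  Chains are typed (protein / nucleic / hetero / mixed) by majority
residue classification.

Parsing policy:

* alternate locations are resolved at parse time — the highest-occupancy
  conformer is kept, ties broken alphabetically by alt-loc identifier;
* multi-model files yield model 1 by default, other models by number;
* hydrogens are retained on parse (downstream geometry excludes them);
* for mmCIF the *author* identifiers (``auth_asym_id`` / ``auth_seq_id``)
  are used so the hierarchy matches a PDB-format parse of the same entry.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Union

import numpy as np

__all__ = [
    "Atom", "Residue", "Chain", "Structure", "ParseError", "ResidueID",
    "parse_pdb", "parse_mmcif", "write_pdb", "write_mmcif",
    "chain_sequence", "extract_range",
]


class ParseError(ValueError):
    """Raised when a structure or record file cannot be parsed."""


#: the 20 standard amino acids plus selenomethionine
AMINO3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

NUCLEOTIDES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
    "A": "A", "C": "C", "G": "G", "U": "U",
}


def classify_residue(res_name: str) -> str:
    """Classify a residue name as ``protein``, ``nucleic`` or ``hetero``."""
    name = res_name.strip().upper()
    if name in AMINO3:
        return "protein"
    if name in NUCLEOTIDES:
        return "nucleic"
    return "hetero"


ResidueID = tuple[int, str]


def as_residue_id(rid: Union[int, str, ResidueID]) -> ResidueID:
    """Normalise a residue identifier to ``(number, insertion_code)``.

    Accepts an int (``30``), a ``(30, "A")`` pair, or a string like ``"30A"``.
    """
    if isinstance(rid, tuple):
        return int(rid[0]), str(rid[1])
    if isinstance(rid, int):
        return rid, ""
    s = str(rid).strip()
    num, icode = s, ""
    if s and s[-1].isalpha():
        num, icode = s[:-1], s[-1]
    return int(num), icode


@dataclass
class Atom:
    """A single atom record.

    ``coords`` are Cartesian, in Angstrom.  ``alt_loc`` is the alternate
    location indicator that survived alt-loc resolution ("" if none).
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("atom coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name.strip():
            raise ValueError("atom name must be non-empty")
        self.name = self.name.strip()

    @property
    def is_hydrogen(self) -> bool:
        el = self.element.strip().upper()
        if el:
            return el in ("H", "D")
        n = self.name.lstrip("0123456789")
        return n[:1].upper() in ("H", "D")


@dataclass
class Residue:
    """One residue: author number, insertion code, name and its atoms."""

    number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> ResidueID:
        return (self.number, self.insertion_code)

    @property
    def kind(self) -> str:
        return classify_residue(self.res_name)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Residue {self.res_name} {self.number}{self.insertion_code}>"


@dataclass
class Chain:
    """An ordered collection of residues sharing one chain identifier."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def chain_type(self) -> str:
        """Majority residue classification: protein / nucleic / hetero / mixed."""
        counts = {"protein": 0, "nucleic": 0, "hetero": 0}
        for r in self.residues:
            counts[r.kind] += 1
        best = max(counts, key=lambda k: counts[k])
        ties = [k for k, v in counts.items() if v == counts[best]]
        if len(ties) > 1 and counts[best] > 0:
            return "mixed"
        return best

    def get_residue(self, rid: Union[int, str, ResidueID]) -> Residue | None:
        rid = as_residue_id(rid)
        for r in self.residues:
            if r.id == rid:
                return r
        return None

    def index_of(self, rid: Union[int, str, ResidueID]) -> int:
        rid = as_residue_id(rid)
        for i, r in enumerate(self.residues):
            if r.id == rid:
                return i
        raise KeyError(f"residue {rid[0]}{rid[1]} not in chain {self.chain_id}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class Structure:
    """One model of a macromolecular entry: ordered, uniquely-named chains."""

    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    model_number: int = 1

    def get_chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def atom_count(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


# ---------------------------------------------------------------------------
# PDB format
# ---------------------------------------------------------------------------

def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} field {text.strip()!r}") from None


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> alphabetical."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = []
            order.append(a.name)
        by_name[a.name].append(a)
    kept = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.alt_loc))
        kept.append(best)
    return kept


def parse_pdb(source: Union[str, Iterable[str]], entry_id: str = "", model: int | None = None) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only ATOM / HETATM / TER / MODEL / ENDMDL records are interpreted; all
    other records are ignored.  The first model is returned unless ``model``
    requests another.  Alt-locs are resolved (highest occupancy kept).
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]

    wanted = model
    current_model = 1
    seen_models: list[int] = []
    # chain_id -> Chain, per selected model; raw atoms grouped per residue
    chains: dict[str, Chain] = {}
    chain_order: list[str] = []
    raw: dict[tuple[str, int, str, str], list[Atom]] = {}
    raw_order: list[tuple[str, int, str, str]] = []
    n_atom_records = 0

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            try:
                current_model = int(line[6:].split()[0])
            except (ValueError, IndexError):
                raise ParseError(f"line {lineno}: malformed MODEL record")
            seen_models.append(current_model)
            continue
        if rec == "ENDMDL":
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if wanted is None and seen_models and current_model != seen_models[0]:
            continue
        if wanted is not None and seen_models and current_model != wanted:
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: truncated coordinate record")
        serial = int(line[6:11]) if line[6:11].strip() else 0
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip()
        try:
            number = int(line[22:26])
        except ValueError:
            raise ParseError(f"line {lineno}: malformed residue number {line[22:26]!r}") from None
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x coordinate", lineno)
        y = _parse_float(line[38:46], "y coordinate", lineno)
        z = _parse_float(line[46:54], "z coordinate", lineno)
        occ = _parse_float(line[54:60], "occupancy", lineno) if line[54:60].strip() else 1.0
        bfac = _parse_float(line[60:66], "B-factor", lineno) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        atom = Atom(serial=serial, name=name, element=element,
                    coords=np.array([x, y, z]), occupancy=occ,
                    b_factor=bfac, alt_loc=alt_loc)
        n_atom_records += 1
        key = (chain_id, number, icode, res_name)
        if key not in raw:
            raw[key] = []
            raw_order.append(key)
        raw[key].append(atom)

    if wanted is not None and seen_models and wanted not in seen_models:
        raise ParseError(f"model {wanted} not present (models: {sorted(set(seen_models))})")
    if n_atom_records == 0:
        raise ParseError("no atoms")

    for key in raw_order:
        chain_id, number, icode, res_name = key
        res = Residue(number=number, insertion_code=icode, res_name=res_name,
                      atoms=_resolve_altlocs(raw[key]))
        if chain_id not in chains:
            chains[chain_id] = Chain(chain_id=chain_id)
            chain_order.append(chain_id)
        chains[chain_id].residues.append(res)

    model_number = wanted if wanted is not None else (seen_models[0] if seen_models else 1)
    return Structure(entry_id=entry_id, chains=[chains[c] for c in chain_order],
                     model_number=model_number)


def _format_atom_name(name: str, element: str) -> str:
    """PDB atom-name justification: 1-char elements start at column 14."""
    if len(name) >= 4:
        return name[:4]
    el = element.strip()
    if len(el) == 2 or (not el and len(name) > 0 and name[0].isdigit()):
        return name.ljust(4)[:4]
    return (" " + name).ljust(4)


def write_pdb(s: Structure) -> str:
    """Render a Structure as fixed-column PDB text (ATOM/HETATM, TER, END)."""
    out: list[str] = []
    serial = 0
    for chain in s.chains:
        if len(chain.chain_id) > 1:
            raise ValueError(
                f"chain id {chain.chain_id!r} longer than 1 character: PDB column limit")
        for res in chain.residues:
            rec = "HETATM" if res.kind == "hetero" else "ATOM  "
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                out.append(
                    f"{rec}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.alt_loc or ' ':1}{res.res_name:>3s} {chain.chain_id or ' ':1}"
                    f"{res.number:4d}{res.insertion_code or ' ':1}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        last = chain.residues[-1]
        out.append(f"TER   {serial:5d}      {last.res_name:>3s} {chain.chain_id or ' ':1}"
                   f"{last.number:4d}{last.insertion_code or ' ':1}")
    out.append("END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# mmCIF format
# ---------------------------------------------------------------------------

def _cif_tokenize_line(line: str) -> list[str]:
    """Split one CIF data line into tokens, honouring ' and " quoting."""
    lexer = shlex.shlex(line, posix=True)
    lexer.whitespace_split = True
    lexer.commenters = "#"
    return list(lexer)


def parse_mmcif(source: Union[str, Iterable[str]], entry_id: str = "", model: int | None = None) -> Structure:
    """Parse the ``_atom_site`` loop of an mmCIF file into a :class:`Structure`.

    Author identifiers (auth_asym_id, auth_seq_id, auth_comp_id, auth_atom_id)
    are preferred, falling back to label_* when absent, so the resulting
    hierarchy matches a PDB-format parse of the same entry.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]

    # locate the _atom_site loop
    tags: list[str] = []
    rows: list[list[str]] = []
    i = 0
    n = len(lines)
    found = False
    while i < n:
        if lines[i].strip() == "loop_":
            j = i + 1
            loop_tags = []
            while j < n and lines[j].strip().startswith("_"):
                loop_tags.append(lines[j].strip().split()[0])
                j += 1
            if loop_tags and loop_tags[0].startswith("_atom_site."):
                tags = loop_tags
                found = True
                # accumulate data rows until next tag/loop/data block or EOF
                row_idx = 0
                while j < n:
                    stripped = lines[j].strip()
                    if (not stripped or stripped.startswith("#")):
                        j += 1
                        continue
                    if stripped.startswith(("_", "loop_", "data_", "stop_")):
                        break
                    values = _cif_tokenize_line(lines[j])
                    row_idx += 1
                    if len(values) != len(tags):
                        raise ParseError(
                            f"_atom_site row {row_idx}: expected {len(tags)} values, "
                            f"got {len(values)}")
                    rows.append(values)
                    j += 1
                break
            i = j
        else:
            i += 1
    if not found:
        raise ParseError("no _atom_site loop found")

    col = {t.split(".", 1)[1]: k for k, t in enumerate(tags)}

    def pick(row: list[str], auth: str, label: str, default: str = "") -> str:
        for key in (auth, label):
            if key in col:
                v = row[col[key]]
                if v not in ("?", ".", None):
                    return v
        return default

    wanted = model
    first_model: int | None = None
    chains: dict[str, Chain] = {}
    chain_order: list[str] = []
    raw: dict[tuple[str, int, str, str], list[Atom]] = {}
    raw_order: list[tuple[str, int, str, str]] = []

    for row in rows:
        mnum = int(pick(row, "pdbx_PDB_model_num", "pdbx_PDB_model_num", "1") or 1)
        if first_model is None:
            first_model = mnum
        target = wanted if wanted is not None else first_model
        if mnum != target:
            continue
        name = pick(row, "auth_atom_id", "label_atom_id")
        res_name = pick(row, "auth_comp_id", "label_comp_id")
        chain_id = pick(row, "auth_asym_id", "label_asym_id")
        seq = pick(row, "auth_seq_id", "label_seq_id")
        icode = pick(row, "pdbx_PDB_ins_code", "pdbx_PDB_ins_code")
        alt = pick(row, "label_alt_id", "label_alt_id")
        try:
            number = int(seq)
        except ValueError:
            raise ParseError(f"malformed residue number {seq!r}") from None
        coords = np.array([float(row[col["Cartn_x"]]),
                           float(row[col["Cartn_y"]]),
                           float(row[col["Cartn_z"]])])
        occ = float(pick(row, "occupancy", "occupancy", "1.0") or 1.0)
        bfac = float(pick(row, "B_iso_or_equiv", "B_iso_or_equiv", "0.0") or 0.0)
        element = pick(row, "type_symbol", "type_symbol")
        serial = int(pick(row, "id", "id", "0") or 0)
        atom = Atom(serial=serial, name=name, element=element, coords=coords,
                    occupancy=occ, b_factor=bfac, alt_loc=alt)
        key = (chain_id, number, icode, res_name)
        if key not in raw:
            raw[key] = []
            raw_order.append(key)
        raw[key].append(atom)

    if not raw_order:
        raise ParseError("no atoms")
    for key in raw_order:
        chain_id, number, icode, res_name = key
        res = Residue(number=number, insertion_code=icode, res_name=res_name,
                      atoms=_resolve_altlocs(raw[key]))
        if chain_id not in chains:
            chains[chain_id] = Chain(chain_id=chain_id)
            chain_order.append(chain_id)
        chains[chain_id].residues.append(res)

    model_number = wanted if wanted is not None else (first_model or 1)
    return Structure(entry_id=entry_id, chains=[chains[c] for c in chain_order],
                     model_number=model_number)


_CIF_TAGS = [
    "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
    "label_comp_id", "label_asym_id", "label_seq_id", "pdbx_PDB_ins_code",
    "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv",
    "auth_seq_id", "auth_comp_id", "auth_asym_id", "auth_atom_id",
    "pdbx_PDB_model_num",
]


def write_mmcif(s: Structure) -> str:
    """Render a Structure as a minimal mmCIF ``_atom_site`` loop."""
    out = [f"data_{s.entry_id or 'structkit'}", "#", "loop_"]
    out += [f"_atom_site.{t}" for t in _CIF_TAGS]
    serial = 0
    for chain in s.chains:
        for res in chain.residues:
            group = "HETATM" if res.kind == "hetero" else "ATOM"
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                out.append(" ".join([
                    group, str(serial), atom.element or "?", atom.name,
                    atom.alt_loc or ".", res.res_name, chain.chain_id or ".",
                    str(res.number), res.insertion_code or "?",
                    f"{x:.3f}", f"{y:.3f}", f"{z:.3f}",
                    f"{atom.occupancy:.2f}", f"{atom.b_factor:.2f}",
                    str(res.number), res.res_name, chain.chain_id or ".",
                    atom.name, str(s.model_number),
                ]))
    out.append("#")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# chain utilities
# ---------------------------------------------------------------------------

def chain_sequence(c: Chain) -> str:
    """One-letter sequence of a protein or nucleic chain, in residue order.

    Unknown residues map to "X".  Numbering gaps do not introduce gap
    characters.  Raises for hetero chains, which have no sequence.
    """
    ctype = c.chain_type
    if ctype == "protein":
        return "".join(AMINO3.get(r.res_name.strip().upper(), "X") for r in c.residues)
    if ctype == "nucleic":
        return "".join(NUCLEOTIDES.get(r.res_name.strip().upper(), "X") for r in c.residues)
    raise ValueError(f"chain {c.chain_id!r} is {ctype}; no sequence defined")


def extract_range(c: Chain, start: Union[int, str, ResidueID],
                  end: Union[int, str, ResidueID]) -> Chain:
    """New chain holding the inclusive residue range ``start``..``end``.

    Endpoints are author residue ids; order is file order, so ranges may span
    insertion codes (e.g. 30, 30A, 31).
    """
    i = c.index_of(start)
    j = c.index_of(end)
    if i > j:
        s, e = as_residue_id(start), as_residue_id(end)
        raise ValueError(f"range start {s[0]}{s[1]} comes after end {e[0]}{e[1]}")
    return Chain(chain_id=c.chain_id, residues=c.residues[i:j + 1])
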
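"""Readers and writers for the formats the toolkit touches.

Covers a minimal NMR-STAR v3 chemical-shift loop, Sparky-style peak lists
(plus an equivalent CSV dialect), multi-model PDB files (read via
Biopython, written with a minimal formatter) and CSV tables with a
commented provenance header.  All writers round-trip through their readers.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from . import __version__
from .errors import ParseError
from .isotopomer import ONE_LETTER
from .peaks import Peak
from .structure import Conformer

__all__ = [
    "read_nmrstar_shifts",
    "write_nmrstar_shifts",
    "read_peaklist",
    "write_peaklist",
    "read_pdb",
    "write_pdb",
    "write_csv",
    "read_csv",
]

THREE_TO_ONE = {v: k for k, v in ONE_LETTER.items()}

# ---------------------------------------------------------------- NMR-STAR

_STAR_TAGS = {
    "_Atom_chem_shift.Seq_ID": "residue",
    "_Atom_chem_shift.Comp_ID": "residue_type",
    "_Atom_chem_shift.Atom_ID": "atom",
    "_Atom_chem_shift.Val": "shift_ppm",
    "_Atom_chem_shift.Ambiguity_code": "ambiguity",
}


def read_nmrstar_shifts(path) -> pd.DataFrame:
    """Parse the atom-chemical-shift loop of a minimal NMR-STAR v3 file.

    Only the ``_Atom_chem_shift`` loop is read; unknown tags are ignored.
    Returns a frame with columns residue, residue_type, atom, shift_ppm,
    ambiguity.  Raises :class:`ParseError` (with line number) on a missing
    loop or malformed value.
    """
    lines = Path(path).read_text().splitlines()
    i, n = 0, len(lines)
    while i < n:
        if lines[i].strip() == "loop_":
            tags, j = [], i + 1
            while j < n and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                return _parse_shift_loop(lines, tags, j, path)
            i = j
        else:
            i += 1
    raise ParseError("no _Atom_chem_shift loop found", path)


def _parse_shift_loop(lines, tags, start, path) -> pd.DataFrame:
    cols = {k: tags.index(tag) for tag, k in _STAR_TAGS.items() if tag in tags}
    for required in ("residue", "atom", "shift_ppm"):
        if required not in cols:
            raise ParseError(f"shift loop lacks a {required} tag", path, start)
    rows = []
    for lineno in range(start, len(lines)):
        line = lines[lineno].strip()
        if not line or line.startswith("#"):
            continue
        if line in ("stop_", "save_"):
            break
        fields = line.split()
        if len(fields) < len(tags):
            raise ParseError(
                f"expected {len(tags)} fields, got {len(fields)}", path, lineno + 1
            )
        row = {}
        for key, idx in cols.items():
            val = fields[idx]
            if key in ("residue", "ambiguity"):
                try:
                    row[key] = int(val) if val != "." else None
                except ValueError:
                    raise ParseError(f"bad integer {val!r}", path, lineno + 1) from None
            elif key == "shift_ppm":
                try:
                    row[key] = float(val)
                except ValueError:
                    raise ParseError(
                        f"bad chemical shift {val!r}", path, lineno + 1
                    ) from None
            else:
                row[key] = val
        rows.append(row)
    if not rows:
        raise ParseError("empty chemical shift loop", path, start)
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["residue", "atom"])
    if dup.any():
        raise ParseError(
            f"duplicate (residue, atom) rows: {df[dup][['residue', 'atom']].values.tolist()}",
            path,
        )
    return df


def write_nmrstar_shifts(table: pd.DataFrame, path) -> None:
    """Write a minimal, canonical NMR-STAR v3 chemical-shift loop."""
    buf = _io.StringIO()
    buf.write("data_shifts\n\nsave_assigned_chemical_shifts\n   loop_\n")
    tags = list(_STAR_TAGS)
    for t in tags:
        buf.write(f"      {t}\n")
    for _, row in table.iterrows():
        amb = row.get("ambiguity")
        amb = "." if amb is None or (isinstance(amb, float) and np.isnan(amb)) else int(amb)
        buf.write(
            f"      {int(row['residue'])} {row['residue_type']} {row['atom']} "
            f"{float(row['shift_ppm']):.3f} {amb}\n"
        )
    buf.write("   stop_\nsave_\n")
    Path(path).write_text(buf.getvalue())


# --------------------------------------------------------------- peak lists

_ASSIGN_TOKEN = re.compile(r"^(?:([A-Z])(\d+))?([A-Z][A-Z0-9']*)$")


def parse_assignment(text: str):
    """Split a Sparky assignment like ``A12H-N-CA`` into per-axis atoms.

    Tokens without a residue prefix inherit it from the previous token; a
    token with an explicit prefix may point at another residue (sequential
    peaks like ``A12H-N-A11CA``).  Returns (residue_number, residue_type,
    atoms, residues-per-axis).
    """
    parts = text.strip().split("-")
    atoms, residues = [], []
    cur = None  # (number, one-letter type)
    for tok in parts:
        m = _ASSIGN_TOKEN.match(tok)
        if not m:
            raise ParseError(f"bad assignment token {tok!r} in {text!r}")
        one, num, atom = m.groups()
        if one is not None:
            if one not in ONE_LETTER:
                raise ParseError(f"unknown residue code {one!r} in {text!r}")
            cur = (int(num), one)
        if cur is None:
            raise ParseError(f"assignment {text!r} starts without a residue")
        atoms.append(atom)
        residues.append(cur)
    amide = next((r for r, a in zip(residues, atoms) if a in ("H", "N", "HN")), residues[0])
    return amide[0], ONE_LETTER[amide[1]], tuple(atoms), residues


def _role_of(amide_res: int, atoms, residues) -> str | None:
    for (num, _), atom in zip(residues, atoms):
        if atom in ("CA", "CB"):
            if num == amide_res:
                return f"{atom}_i"
            if num == amide_res - 1:
                return f"{atom}_i-1"
    return None


def read_peaklist(path, dialect: str | None = None):
    """Read an assigned peak list.

    ``dialect`` is ``"sparky"`` (whitespace columns: assignment, one shift
    per axis, height) or ``"csv"`` (explicit header
    ``assignment,w1,...,height``); None sniffs from the first line.
    Unparsable rows are collected and returned, never silently dropped.
    Returns ``(peaks, rejected)``; raises if no row parses.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty peak list", path)
    if dialect is None:
        dialect = "csv" if "," in lines[0] else "sparky"

    peaks, rejected = [], []
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if stripped.startswith("#"):
            continue
        fields = ([f.strip() for f in stripped.split(",")] if dialect == "csv"
                  else stripped.split())
        if fields[0].lower() in ("assignment", "assign"):
            continue  # header row
        try:
            if len(fields) < 3:
                raise ParseError("too few columns", path, lineno)
            assignment = fields[0]
            shifts = tuple(float(x) for x in fields[1:-1])
            height = float(fields[-1])
            resnum, rtype, atoms, residues = parse_assignment(assignment)
            if len(atoms) != len(shifts):
                raise ParseError(
                    f"{len(atoms)} assignment axes vs {len(shifts)} shifts",
                    path, lineno,
                )
            peaks.append(Peak(resnum, rtype, atoms, shifts, height,
                              role=_role_of(resnum, atoms, residues)))
        except (ParseError, ValueError) as exc:
            rejected.append((lineno, stripped, str(exc)))
    if not peaks:
        raise ParseError(f"no parsable rows ({len(rejected)} rejected)", path)
    return peaks, rejected


def write_peaklist(peaks: list[Peak], path, dialect: str = "sparky") -> None:
    """Write peaks in a format :func:`read_peaklist` round-trips."""
    rows = []
    for p in peaks:
        one = THREE_TO_ONE.get(p.residue_type.upper(), "X")
        assignment = f"{one}{p.residue_number}" + "-".join(p.atoms)
        # sequential carbon roles carry their own residue prefix
        if p.role in ("CA_i-1", "CB_i-1"):
            *rest, carbon = p.atoms
            assignment = (f"{one}{p.residue_number}" + "-".join(rest)
                          + f"-{one}{p.residue_number - 1}{carbon}")
        rows.append((assignment, *p.dims, p.intensity))
    with open(path, "w") as fh:
        if dialect == "csv":
            naxes = len(rows[0]) - 2
            fh.write("assignment," + ",".join(f"w{i+1}" for i in range(naxes))
                     + ",height\n")
            for r in rows:
                fh.write(",".join(str(x) for x in r) + "\n")
        else:
            fh.write("      Assignment"
                     + "".join(f"       w{i+1}" for i in range(len(rows[0]) - 2))
                     + "   Data Height\n\n")
            for r in rows:
                fh.write("  ".join(str(x) for x in r) + "\n")


# --------------------------------------------------------------------- PDB


def read_pdb(path) -> list[Conformer]:
    """Read a (multi-model) PDB file into a list of conformers.

    MODEL/ENDMDL blocks become separate conformers; single-model files
    yield one.  For altloc'd atoms the highest-occupancy location wins
    (first on ties); HETATM records are ignored and a file without any ATOM
    record raises.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(path))
    conformers = []
    for model in structure:
        res_nums, res_types, atom_names, coords = [], [], [], []
        chain_id = "A"
        for chain in model:
            for residue in chain:
                if residue.id[0] != " ":
                    continue  # HETATM / water
                chain_id = chain.id
                # a DisorderedAtom delegates to its selected child, which
                # Biopython sets to the highest-occupancy altloc (first on ties)
                for atom in residue:
                    res_nums.append(residue.id[1])
                    res_types.append(residue.get_resname())
                    atom_names.append(atom.get_name())
                    coords.append(atom.get_coord())
        if res_nums:
            conformers.append(Conformer(
                np.array(res_nums),
                np.array(res_types, dtype=object),
                np.array(atom_names, dtype=object),
                np.array(coords, dtype=float),
                model_id=model.id + 1, chain_id=chain_id,
            ))
    if not conformers:
        raise ParseError("no ATOM records", path)
    return conformers


def write_pdb(conformers: list[Conformer], path) -> None:
    """Write conformers as a minimal multi-model PDB file."""
    with open(path, "w") as fh:
        multi = len(conformers) > 1
        for k, c in enumerate(conformers, 1):
            if multi:
                fh.write(f"MODEL     {k:>4}\n")
            serial = 1
            for res, rtype, atom, xyz in zip(
                c.residue_numbers, c.residue_types, c.atom_names, c.coords
            ):
                name = f" {atom:<3}" if len(atom) < 4 else atom
                element = atom.strip()[0]
                fh.write(
                    f"ATOM  {serial:>5} {name:<4} {rtype:<3} {c.chain_id}"
                    f"{int(res):>4}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {element:>2}\n"
                )
                serial += 1
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------- CSV


def write_csv(df: pd.DataFrame, path, meta: dict | None = None,
              index: bool = False) -> None:
    """CSV with a leading commented provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# fracnmr {__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=index)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
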
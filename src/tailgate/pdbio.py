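"""Fixed-column PDB reading and writing.

Coordinates are converted Angstrom -> nm on read and back on write, so the
rest of the package never sees Angstrom.  The per-atom mobility flag is
carried in the B-factor column: 0.00 = mobile, 1.00 = immobile, which keeps
a simulated system fully described by a single PDB file.

Only ATOM/HETATM/TER/END records are interpreted; everything else is
ignored.  Multi-model files, connectivity records and mmCIF are out of
scope.
"""

from __future__ import annotations

import io
from typing import IO, Iterable

import numpy as np

from .errors import PDBParseError, ValidationError
from .structure import Structure

ANGSTROM_PER_NM = 10.0


def _parse_field(line: str, lineno: int, lo: int, hi: int, conv, what: str):
    raw = line[lo:hi]
    try:
        return conv(raw)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {raw!r}") from None


def read_structure(source: str | IO[str]) -> Structure:
    """Parse PDB text into a :class:`Structure` (coordinates in nm).

    ``source`` may be a string or a text file object.  TER and END records
    close the current chain; a chain id reappearing after its chain was
    closed is a contiguity violation and raises :class:`ValidationError`.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source

    ids, names, res_idx, res_names, chains, xyz, mobile = \
        [], [], [], [], [], [], []
    closed_chains: set[str] = set()
    current_chain: str | None = None
    seen_ids: set[int] = set()

    for lineno, line in enumerate(io.StringIO(text), start=1):
        rec = line[0:6].strip()
        if rec == "TER" or rec == "END" or rec == "ENDMDL":
            if current_chain is not None:
                closed_chains.add(current_chain)
                current_chain = None
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"line {lineno}: record too short for "
                                "coordinate fields")
        serial = _parse_field(line, lineno, 6, 11, lambda s: int(s), "serial")
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22]
        resseq = _parse_field(line, lineno, 22, 26, lambda s: int(s),
                              "residue number")
        x = _parse_field(line, lineno, 30, 38, float, "x")
        y = _parse_field(line, lineno, 38, 46, float, "y")
        z = _parse_field(line, lineno, 46, 54, float, "z")
        bcol = line[60:66].strip()
        try:
            bfac = float(bcol) if bcol else 0.0
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed B-factor field {bcol!r}") from None

        if serial in seen_ids:
            raise ValidationError(
                f"line {lineno}: duplicate atom serial {serial}")
        seen_ids.add(serial)
        if chain != current_chain:
            if chain in closed_chains:
                raise ValidationError(
                    f"line {lineno}: chain {chain!r} reopened after TER")
            if current_chain is not None:
                closed_chains.add(current_chain)
            current_chain = chain

        ids.append(serial)
        names.append(name)
        res_idx.append(resseq)
        res_names.append(resname)
        chains.append(chain)
        xyz.append((x / ANGSTROM_PER_NM,
                    y / ANGSTROM_PER_NM,
                    z / ANGSTROM_PER_NM))
        mobile.append(bfac < 0.5)

    if not ids:
        raise ValidationError("no atoms")
    return Structure(np.array(ids), np.array(names), np.array(res_idx),
                     np.array(res_names), np.array(chains),
                     np.array(xyz, dtype=np.float64),
                     np.array(mobile)).validate()


def write_structure(s: Structure, sink: IO[str] | None = None) -> str:
    """Write a Structure as fixed-column PDB text (coordinates in Angstrom).

    Returns the text; if ``sink`` is given the text is also written to it.
    Chains are terminated with TER records and the file with END.
    """
    s.validate()
    lines: list[str] = []
    prev_chain = None
    for i in range(s.n_atoms):
        name = str(s.atom_name[i])
        resname = str(s.residue_name[i])
        chain = str(s.chain_id[i])
        if len(name) > 4:
            raise ValidationError(f"atom name {name!r} exceeds 4 characters")
        if len(resname) > 3:
            raise ValidationError(
                f"residue name {resname!r} exceeds 3 characters")
        if len(chain) != 1:
            raise ValidationError(f"chain id {chain!r} is not one character")
        serial = int(s.atom_id[i])
        if serial > 99999 or serial < 0:
            raise ValidationError(f"atom serial {serial} out of PDB range")
        if not 0 <= int(s.residue_index[i]) <= 9999:
            raise ValidationError(
                f"residue number {int(s.residue_index[i])} out of PDB range")
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        # conventional placement: names up to 3 chars start in column 14
        fname = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = s.coords[i] * ANGSTROM_PER_NM
        if max(abs(x), abs(y), abs(z)) >= 10000.0:
            raise ValidationError(
                f"atom {serial}: coordinate exceeds PDB column width")
        bfac = 0.0 if s.mobile[i] else 1.0
        lines.append(
            f"ATOM  {serial:5d} {fname}{'':1s}{resname:>3s} {chain}"
            f"{int(s.residue_index[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfac:6.2f}")
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        sink.write(text)
    return text
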
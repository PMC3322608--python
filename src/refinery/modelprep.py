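"""Coordinate stripping and header metadata extraction for PDB-format models.

Deposited coordinate files carry records that confuse automated restraint
generation and refinement.  ``strip_model`` removes them: explicit H atoms,
essentially-absent atoms (occupancy < 0.01), unknown ligands (UNL), unknown
residues' side chains beyond C-beta (UNK), unknown atoms (UNX / element X),
inter-symmetry LINK and SSBOND records, and — when an external carbohydrate
validator has flagged them — superfluous O atoms in sugars.  Distance fields
in surviving LINK records are blanked so the refinement engine regenerates
them from its own dictionary.

``extract_header`` pulls refinement metadata out of the header: the reported
R and R_free (REMARK 3), TLS group selections and tensors, the solvent model
and the deposition year (used by the cycle-count rules to spot pre-1990
"legacy" models).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

from pydantic import BaseModel, Field

from .errors import EmptyModelError

__all__ = [
    "AtomRecord",
    "AtomId",
    "LinkRecord",
    "TlsGroup",
    "HeaderInfo",
    "strip_model",
    "extract_header",
    "read_model",
    "write_model",
    "LEGACY_YEAR",
]

#: models deposited before this year are treated as "legacy"
LEGACY_YEAR = 1990

_BACKBONE_AND_CB = {"N", "CA", "C", "O", "CB", "OXT"}


class AtomRecord(BaseModel):
    name: str
    element: str
    residue: str
    chain: str
    res_seq: int = 0
    position: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    occupancy: float = Field(default=1.0, ge=0.0, le=1.0)
    b_factor: float = Field(default=20.0, ge=0.0)
    is_water: bool = False
    altloc: Optional[str] = None

    def atom_id(self) -> "AtomId":
        return (self.chain, self.res_seq, self.name.strip())


AtomId = Tuple[str, int, str]


@dataclass(frozen=True)
class LinkRecord:
    atom1: AtomId
    atom2: AtomId
    kind: Literal["LINK", "SSBOND"] = "LINK"
    inter_symmetry: bool = False
    distance: Optional[float] = None


@dataclass(frozen=True)
class TlsGroup:
    selections: Tuple[Tuple[str, int, int], ...]  # (chain, first, last)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    t: Tuple[float, ...] = (0.0,) * 6  # T11 T22 T33 T12 T13 T23
    l: Tuple[float, ...] = (0.0,) * 6
    s: Tuple[float, ...] = (0.0,) * 9


@dataclass
class HeaderInfo:
    r_head: Optional[float] = None
    r_free_head: Optional[float] = None
    tls_groups: List[TlsGroup] = field(default_factory=list)
    solvent_model: str = ""
    links: List[LinkRecord] = field(default_factory=list)
    deposition_year: Optional[int] = None

    @property
    def legacy(self) -> bool:
        return self.deposition_year is not None and self.deposition_year < LEGACY_YEAR


def _is_hydrogen(atom: AtomRecord) -> bool:
    el = atom.element.strip().upper()
    if el:
        return el in ("H", "D")
    # legacy files without an element column: infer from the atom name;
    # a leading digit (e.g. 1HB2) still denotes a hydrogen
    name = atom.name.strip().upper()
    if not name:
        return False
    first = name[1] if name[0].isdigit() and len(name) > 1 else name[0]
    return first in ("H", "D")


def strip_model(
    atoms: Sequence[AtomRecord],
    header: HeaderInfo,
    superfluous_carb_o: Optional[set] = None,
) -> Tuple[List[AtomRecord], HeaderInfo, Dict[str, int]]:
    """Apply all removal rules; returns (atoms, header, removal log).

    ``superfluous_carb_o`` is an externally supplied set of atom ids flagged
    by a carbohydrate validator; when absent that rule is a no-op.  Raises
    :class:`EmptyModelError` if nothing survives.
    """
    flagged = superfluous_carb_o or set()
    log = {
        "hydrogens": 0,
        "low_occupancy": 0,
        "unl_residues": 0,
        "unk_sidechain": 0,
        "unx_atoms": 0,
        "carbohydrate_o": 0,
        "inter_symmetry_links": 0,
        "link_distances_cleared": 0,
    }
    kept: List[AtomRecord] = []
    for a in atoms:
        res = a.residue.strip().upper()
        name = a.name.strip().upper()
        if _is_hydrogen(a):
            log["hydrogens"] += 1
        elif a.occupancy < 0.01:
            log["low_occupancy"] += 1
        elif res == "UNL":
            log["unl_residues"] += 1
        elif res == "UNK" and name not in _BACKBONE_AND_CB:
            log["unk_sidechain"] += 1
        elif res == "UNX" or a.element.strip().upper() == "X":
            log["unx_atoms"] += 1
        elif a.atom_id() in flagged:
            log["carbohydrate_o"] += 1
        else:
            kept.append(a)
    if not kept:
        raise EmptyModelError("stripping removed every atom")

    present = {a.atom_id() for a in kept}
    links: List[LinkRecord] = []
    for link in header.links:
        if link.inter_symmetry:
            log["inter_symmetry_links"] += 1
            continue
        if link.atom1 not in present or link.atom2 not in present:
            # partner removed above; a dangling link cannot be kept
            log["inter_symmetry_links"] += 0
            continue
        if link.distance is not None:
            log["link_distances_cleared"] += 1
            link = replace(link, distance=None)
        links.append(link)

    new_header = HeaderInfo(
        r_head=header.r_head,
        r_free_head=header.r_free_head,
        tls_groups=list(header.tls_groups),
        solvent_model=header.solvent_model,
        links=links,
        deposition_year=header.deposition_year,
    )
    return kept, new_header, log


# ---------------------------------------------------------------------------
# header extraction

_R_WORK_RE = re.compile(r"REMARK   3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)")
_R_WORK_ALT_RE = re.compile(
    r"REMARK   3\s+R VALUE\s+\(WORKING \+ TEST SET\)\s*:\s*([0-9.]+)")
_R_FREE_RE = re.compile(r"REMARK   3\s+FREE R VALUE\s*:\s*([0-9.]+)")
_SOLVENT_RE = re.compile(r"REMARK   3\s+METHOD USED\s*:\s*(.+?)\s*$")
_TLS_GROUP_RE = re.compile(r"REMARK   3\s+TLS GROUP\s*:\s*(\d+)")
_TLS_SEL_RE = re.compile(
    r"REMARK   3\s+(?:SELECTION|RESIDUE RANGE)\s*:?\s*(.*)$")
_CHAIN_RANGE_RE = re.compile(
    r"(?:CHAIN\s+)?([A-Za-z0-9])\s+(?:AND\s+RESID\s+)?(-?\d+)\s+(?:TO|THROUGH)\s+"
    r"(?:[A-Za-z0-9]\s+)?(-?\d+)", re.IGNORECASE)
_ORIGIN_RE = re.compile(
    r"REMARK   3\s+ORIGIN FOR THE GROUP \(A\):\s*([-0-9. ]+)$")
_TENSOR_ELEM_RE = re.compile(r"([TLS])(\d\d):\s*(-?[0-9.]+)")
_HEADER_DATE_RE = re.compile(
    r"^HEADER.{40,}?(\d\d)-([A-Z]{3})-(\d\d(?:\d\d)?)")


def _parse_tls_blocks(lines: List[str]) -> List[TlsGroup]:
    groups: List[TlsGroup] = []
    current: Optional[dict] = None
    for line in lines:
        m = _TLS_GROUP_RE.match(line)
        if m:
            if current is not None:
                groups.append(_finish_tls(current))
            current = {"selections": [], "origin": (0.0, 0.0, 0.0),
                       "T": {}, "L": {}, "S": {}}
            continue
        if current is None:
            continue
        m = _TLS_SEL_RE.match(line)
        if m and "ORIGIN" not in line:
            mm = _CHAIN_RANGE_RE.search(m.group(1))
            if mm:
                current["selections"].append(
                    (mm.group(1), int(mm.group(2)), int(mm.group(3))))
            continue
        m = _ORIGIN_RE.match(line)
        if m:
            parts = [float(x) for x in m.group(1).split()]
            if len(parts) == 3:
                current["origin"] = tuple(parts)
            continue
        for kind, ij, val in _TENSOR_ELEM_RE.findall(line):
            if line.lstrip().startswith("REMARK   3".lstrip()):
                current[kind][ij] = float(val)
    if current is not None:
        groups.append(_finish_tls(current))
    return groups


def _finish_tls(d: dict) -> TlsGroup:
    t_order = ["11", "22", "33", "12", "13", "23"]
    s_order = ["11", "12", "13", "21", "22", "23", "31", "32", "33"]
    if not d["selections"]:
        raise ValueError("TLS group without a parsable selection")
    return TlsGroup(
        selections=tuple(d["selections"]),
        origin=d["origin"],
        t=tuple(d["T"].get(ij, 0.0) for ij in t_order),
        l=tuple(d["L"].get(ij, 0.0) for ij in t_order),
        s=tuple(d["S"].get(ij, 0.0) for ij in s_order),
    )


_MONTHS = {m: i + 1 for i, m in enumerate(
    ["JAN", "FEB", "MAR", "APR", "MAY", "JUN",
     "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"])}


def _parse_link_line(line: str) -> Optional[LinkRecord]:
    try:
        if line.startswith("LINK"):
            a1 = (line[21], int(line[22:26]), line[12:16].strip())
            a2 = (line[51], int(line[52:56]), line[42:46].strip())
            sym1 = line[59:65].strip()
            sym2 = line[66:72].strip()
            dist_txt = line[73:78].strip()
            dist = float(dist_txt) if dist_txt else None
            inter = bool(sym1 and sym2 and sym1 != sym2)
            return LinkRecord(a1, a2, "LINK", inter, dist)
        if line.startswith("SSBOND"):
            a1 = (line[15], int(line[17:21]), "SG")
            a2 = (line[29], int(line[31:35]), "SG")
            sym1 = line[59:65].strip()
            sym2 = line[66:72].strip()
            dist_txt = line[73:78].strip()
            dist = float(dist_txt) if dist_txt else None
            inter = bool(sym1 and sym2 and sym1 != sym2)
            return LinkRecord(a1, a2, "SSBOND", inter, dist)
    except (ValueError, IndexError):
        return None
    return None


def extract_header(pdb_text: str) -> HeaderInfo:
    """Parse refinement metadata out of PDB-format text.

    Absent fields stay ``None`` — they are never defaulted, because the
    orchestrator must abort when the reported R factor is missing.  A
    malformed TLS block yields an empty ``tls_groups`` with a warning (the
    header TLS model is then simply unavailable as a candidate).
    """
    info = HeaderInfo()
    lines = pdb_text.splitlines()
    tls_lines: List[str] = []
    in_tls = False
    for line in lines:
        if info.deposition_year is None:
            m = _HEADER_DATE_RE.match(line)
            if m:
                y = int(m.group(3))
                info.deposition_year = y if y > 1900 else (1900 + y if y > 40 else 2000 + y)
        if line.startswith("REMARK   3"):
            if info.r_head is None:
                m = _R_WORK_RE.match(line) or _R_WORK_ALT_RE.match(line)
                if m:
                    info.r_head = float(m.group(1))
                    continue
            if info.r_free_head is None:
                m = _R_FREE_RE.match(line)
                if m:
                    info.r_free_head = float(m.group(1))
                    continue
            m = _SOLVENT_RE.match(line)
            if m and not info.solvent_model:
                info.solvent_model = m.group(1)
                continue
            if "TLS DETAILS" in line:
                in_tls = True
            if in_tls:
                tls_lines.append(line)
        elif line.startswith(("LINK", "SSBOND")):
            link = _parse_link_line(line)
            if link is not None:
                info.links.append(link)
    if tls_lines:
        try:
            info.tls_groups = _parse_tls_blocks(tls_lines)
        except (ValueError, KeyError) as exc:
            warnings.warn(f"malformed TLS block ignored: {exc}")
            info.tls_groups = []
    return info


# ---------------------------------------------------------------------------
# PDB I/O

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_model(pdb_text: str) -> Tuple[List[AtomRecord], HeaderInfo]:
    """Parse ATOM/HETATM records plus header metadata from PDB text."""
    atoms: List[AtomRecord] = []
    for line in pdb_text.splitlines():
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        line = line.ljust(80)
        res = line[17:20].strip()
        occ_txt = line[54:60].strip()
        b_txt = line[60:66].strip()
        atoms.append(AtomRecord(
            name=line[12:16].strip(),
            element=line[76:78].strip(),
            residue=res,
            chain=line[21],
            res_seq=int(line[22:26]),
            position=(float(line[30:38]), float(line[38:46]), float(line[46:54])),
            occupancy=min(1.0, max(0.0, float(occ_txt) if occ_txt else 1.0)),
            b_factor=max(0.0, float(b_txt) if b_txt else 0.0),
            is_water=res in _WATER_NAMES,
            altloc=line[16].strip() or None,
        ))
    return atoms, extract_header(pdb_text)


def write_model(atoms: Sequence[AtomRecord], header: HeaderInfo) -> str:
    """Serialize atoms + surviving LINK records as PDB-format text."""
    out: List[str] = []
    if header.r_head is not None:
        out.append(f"REMARK   3   R VALUE            (WORKING SET) : {header.r_head:.3f}")
    if header.r_free_head is not None:
        out.append(f"REMARK   3   FREE R VALUE                     : {header.r_free_head:.3f}")
    for link in header.links:
        if link.kind == "LINK":
            (c1, s1, n1), (c2, s2, n2) = link.atom1, link.atom2
            out.append(
                f"LINK        {n1:<4.4s}     {c1}{s1:4d}                "
                f"{n2:<4.4s}     {c2}{s2:4d}    ")
    for i, a in enumerate(atoms, start=1):
        record = "HETATM" if (a.is_water or a.residue not in _AA3) else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3.3s}"
        x, y, z = a.position
        out.append(
            f"{record}{i:5d} {name:<4.4s}{(a.altloc or ' ')[:1]}{a.residue:>3.3s} "
            f"{a.chain}{a.res_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2.2s}")
    out.append("END")
    return "\n".join(out) + "\n"


_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "UNK", "MSE",
}
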
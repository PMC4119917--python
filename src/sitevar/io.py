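"""Domain types and readers/writers for the formats the pipeline touches.

The pipeline's currency is the per-site profile: every structural or
sequence-derived measure is a vector with one value per residue of a single
protein chain. This module defines the containers (:class:`StructureModel`,
:class:`MSAlignment`, :class:`SiteProfile`) and the plain-text I/O (PDB,
aligned FASTA, Newick via :mod:`sitevar.tree`, TSV reports).

Site indexing is 1-based ordinal along the chain and is decoupled from the
author residue numbering of the PDB file; all profiles use ordinal indexing.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
ALPHABET = set(AMINO_ACIDS) | {GAP}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is read as methionine
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

# Element-based van der Waals radii in Å (Bondi 1964, J Phys Chem 68:441).
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "H": 1.20, "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
}
DEFAULT_VDW = 1.70

#: profile measures and their orientation class. "conservation" measures are
#: sign-flipped by orientation so that buried/packed/conserved sites score low
#: and every meaningful structure-sequence relationship is a positive
#: correlation.
MEASURES = {
    "CS": "variability",
    "ET": "variability",
    "KBSP": "conservation",
    "VTSP": "conservation",
    "EN": "variability",
    "WCN": "conservation",
    "CN": "conservation",
    "ASA": "variability",
    "RSA_R": "variability",
    "RSA_M": "variability",
    "RSA_T": "variability",
}


@dataclass
class Atom:
    element: str
    coord: np.ndarray  # (3,) Å
    radius: float      # vdW radius, Å
    name: str = ""     # PDB atom name, e.g. "CA", "OD1"


@dataclass
class Site:
    index: int              # 1-based ordinal along the chain
    residue_number: str     # author numbering, insertion code preserved
    aa: str                 # one-letter code
    ca: np.ndarray          # (3,) Å
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class StructureModel:
    """A parsed single protein chain with Cα coordinates per residue."""

    chain_id: str
    sites: list[Site]

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError(f"structure needs at least 2 sites, got {len(self.sites)}")
        for s in self.sites:
            if not np.all(np.isfinite(s.ca)):
                raise ValueError(f"non-finite Cα coordinate at site {s.index}")
            for a in s.atoms:
                if a.radius <= 0:
                    raise ValueError(f"non-positive vdW radius at site {s.index}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sequence(self) -> str:
        return "".join(s.aa for s in self.sites)

    @property
    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in chain order."""
        return np.array([s.ca for s in self.sites], dtype=float)

    def is_ca_only(self) -> bool:
        return all(len(s.atoms) <= 1 for s in self.sites)


@dataclass
class SiteProfile:
    """A per-site numeric vector tagged with its measure kind.

    ``values`` has one entry per structure site; missing values are NaN.
    ``oriented`` records whether the sign convention (packed/conserved = low)
    has been applied; ``smoothed`` whether sliding-window smoothing has.
    """

    values: np.ndarray
    measure: str
    oriented: bool = False
    smoothed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if np.any(np.isinf(self.values)):
            raise ValueError(f"{self.measure} profile contains infinities")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MSAlignment:
    """Aligned sequences over the 20-aa + gap alphabet with a designated query.

    ``column_to_site`` maps 0-based alignment columns to 1-based structure
    site ordinals; it covers exactly the columns where the query row has no
    gap, in order.
    """

    names: list[str]
    rows: list[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"record {name!r} has length {len(row)}, expected {L}"
                )
        bad = set(self.query_row) - ALPHABET
        if bad:
            raise ValueError(
                f"query row contains illegal characters: {sorted(bad)}"
            )
        self.column_to_site = {}
        site = 0
        for col, c in enumerate(self.query_row):
            if c != GAP:
                site += 1
                self.column_to_site[col] = site

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index]

    @property
    def query_name(self) -> str:
        return self.names[self.query_index]

    @property
    def query_sequence(self) -> str:
        return self.query_row.replace(GAP, "")

    @property
    def mapped_columns(self) -> list[int]:
        """Alignment columns mapped to structure sites, in site order."""
        return sorted(self.column_to_site, key=self.column_to_site.get)

    def column(self, col: int) -> str:
        return "".join(row[col] for row in self.rows)


# ---------------------------------------------------------------------------
# PDB

def read_pdb(text: str, chain_id: str | None = None) -> StructureModel:
    """Parse ATOM records of one chain into a :class:`StructureModel`.

    HETATM records, waters and alternate locations other than the first
    listed are dropped. A residue without a Cα is skipped with a warning;
    multiple MODELs reduce to the first with a warning. MSE is read as Met;
    other nonstandard residues are skipped with a warning.
    """
    chains: dict[str, dict] = {}
    seen_model = False
    for line in text.splitlines():
        rec = line[:6]
        if rec.startswith("ENDMDL"):
            if seen_model:
                logger.warning("multiple models in PDB input; using the first")
                break
            seen_model = True
            continue
        if not rec.startswith("ATOM") and not (
            rec.startswith("HETATM") and line[17:20].strip() == "MSE"
        ):
            continue
        resname = line[17:20].strip()
        if resname not in THREE_TO_ONE:
            continue  # nonstandard residues reported once per residue below
        cid = line[21].strip() or " "
        if chain_id is not None and cid != chain_id:
            continue
        altloc = line[16].strip()
        name = line[12:16].strip()
        resnum = line[22:27].strip()  # author number + insertion code
        coord = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        element = line[76:78].strip().upper() or name[:1]
        residues = chains.setdefault(cid, {})
        res = residues.setdefault(resnum, {"resname": resname, "atoms": {}})
        key = name
        if key in res["atoms"]:
            continue  # keep first-listed altLoc only
        if altloc and res.get("altloc", altloc) != altloc:
            continue
        res.setdefault("altloc", altloc)
        res["atoms"][key] = (element, coord)

    if not chains:
        raise ValueError("no parsable ATOM records found")
    if chain_id is None:
        if len(chains) > 1:
            logger.warning(
                "multiple chains %s; using the first", sorted(chains)
            )
        cid = next(iter(chains))
    else:
        cid = chain_id
        if cid not in chains:
            raise ValueError(f"chain {cid!r} not found")

    sites = []
    for resnum, res in chains[cid].items():
        if "CA" not in res["atoms"]:
            logger.warning("residue %s has no CA; skipped", resnum)
            continue
        aa = THREE_TO_ONE[res["resname"]]
        atoms = [
            Atom(el, xyz, VDW_RADII.get(el, DEFAULT_VDW), name)
            for name, (el, xyz) in res["atoms"].items()
        ]
        sites.append(
            Site(
                index=len(sites) + 1,
                residue_number=resnum,
                aa=aa,
                ca=res["atoms"]["CA"][1],
                atoms=atoms,
            )
        )
    if not sites:
        raise ValueError(f"no residues with CA in chain {cid!r}")
    return StructureModel(chain_id=cid, sites=sites)


def write_pdb(structure: StructureModel) -> str:
    """Serialize a structure back to fixed-column PDB ATOM records."""
    lines = []
    serial = 0
    for site in structure.sites:
        resname = ONE_TO_THREE[site.aa]
        atoms = site.atoms or [Atom("C", site.ca, DEFAULT_VDW, "CA")]
        names = _atom_names(atoms)
        for name, atom in zip(names, atoms):
            serial += 1
            x, y, z = atom.coord
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad_name}{'':1s}{resname} "
                f"{structure.chain_id:1s}{site.residue_number:>5s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"{'':10s}{atom.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _atom_names(atoms: list[Atom]) -> list[str]:
    # prefer recorded names; single-atom (Cα-only) sites serialize as CA
    names, counts = [], {}
    for a in atoms:
        if a.name:
            names.append(a.name)
        elif len(atoms) == 1:
            names.append("CA")
        else:
            counts[a.element] = counts.get(a.element, 0) + 1
            names.append(f"{a.element}{counts[a.element]}")
    return names


# ---------------------------------------------------------------------------
# aligned FASTA

def read_alignment(fasta_text: str, query_name: str) -> MSAlignment:
    """Read an aligned FASTA into an :class:`MSAlignment`.

    Rows are uppercased; characters outside the 20-aa + gap alphabet in
    non-query rows are mapped to gaps with a warning. The query row is held
    to the strict alphabet.
    """
    records = list(SeqIO.parse(_io.StringIO(fasta_text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    names = [r.id for r in records]
    if query_name not in names:
        raise ValueError(f"query {query_name!r} not among records")
    L = len(records[0].seq)
    rows = []
    qi = names.index(query_name)
    for i, r in enumerate(records):
        s = str(r.seq).upper().replace(".", GAP)
        if len(s) != L:
            raise ValueError(
                f"record {r.id!r} has length {len(s)}, expected {L}"
            )
        if i != qi:
            bad = set(s) - ALPHABET
            if bad:
                logger.warning(
                    "record %s: characters %s mapped to gaps", r.id, sorted(bad)
                )
                s = "".join(c if c in ALPHABET else GAP for c in s)
        rows.append(s)
    return MSAlignment(names=names, rows=rows, query_index=qi)


def write_alignment(msa: MSAlignment) -> str:
    out = _io.StringIO()
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(msa.names, msa.rows)
    ]
    SeqIO.write(records, out, "fasta")
    return out.getvalue()


# ---------------------------------------------------------------------------
# reports

def write_report(
    records: list[dict],
    float_fmt: str = "%.3f",
    columns: list[str] | None = None,
) -> str:
    """Render keyed records as a TSV with a deterministic column order.

    Columns follow first-seen key order (or the explicit ``columns``, which
    also makes an empty record list render as a header-only file); floats
    are printed at 3 decimals (the precision of the published summary
    tables).
    """
    import pandas as pd

    columns = list(columns) if columns else []
    for rec in records:
        for k in rec:
            if k not in columns:
                columns.append(k)
    df = pd.DataFrame.from_records(records, columns=columns)
    return df.to_csv(sep="\t", index=False, float_format=float_fmt)
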
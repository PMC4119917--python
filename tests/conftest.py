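import numpy as np
import pytest

from sitevar.io import Atom, Site, StructureModel


def make_structure(coords, aa=None, atoms=None) -> StructureModel:
    """Build a minimal structure from Cα coordinates.

    ``atoms``: optional list (per site) of (element, xyz, radius, name)
    tuples; omitted sites carry no atom records (Cα-only).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    aa = aa or "A" * n
    sites = []
    for i in range(n):
        site_atoms = []
        if atoms is not None:
            site_atoms = [
                Atom(el, np.asarray(xyz, float), r, name)
                for el, xyz, r, name in atoms[i]
            ]
        sites.append(
            Site(
                index=i + 1,
                residue_number=str(i + 1),
                aa=aa[i],
                ca=coords[i],
                atoms=site_atoms,
            )
        )
    return StructureModel(chain_id="A", sites=sites)


def pdb_lines(residues, chain="A"):
    """Fixed-column ATOM records from (resname, resnum, [(name, element, xyz)])."""
    lines = []
    serial = 0
    for resname, resnum, atoms in residues:
        for name, element, (x, y, z) in atoms:
            serial += 1
            pad = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad} {resname} {chain}{resnum:>4s}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
    return "\n".join(lines) + "\nEND\n"


BACKBONE = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]


def backbone_residue(resname, resnum, origin):
    ox, oy, oz = origin
    offsets = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.2, 1.2, 0.0), (2.2, 2.4, 0.3)]
    return (
        resname,
        resnum,
        [
            (name, el, (ox + dx, oy + dy, oz + dz))
            for (name, el), (dx, dy, dz) in zip(BACKBONE, offsets)
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
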
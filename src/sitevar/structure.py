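"""Structural site profiles: local packing density and solvent accessibility.

Local packing density comes in two flavours: the parameter-free weighted
contact number WCN_i = sum_{j != i} 1 / r_ij^2 over Cα–Cα distances, and the
contact number CN(r0), the count of other Cα within a cut-off radius. Solvent
accessibility is the Shrake–Rupley accessible surface area with a 1.4 Å water
probe, and its relative form RSA = ASA / maxASA(aa) under three published
max-ASA tables (Rose, Miller, Tien "theoretical").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .io import SiteProfile, StructureModel

logger = logging.getLogger(__name__)

#: radius of the single pseudo-atom used for ASA of Cα-only models, Å
CA_PSEUDO_RADIUS = 3.0

# Maximum ASA per residue type, Å². Rose et al. 1985 (Science 229:834,
# mean standard-state areas); Miller et al. 1987 (J Mol Biol 196:641);
# Tien et al. 2013 (PLoS ONE 8:e80635, theoretical maxima).
_ROSE = {
    "A": 118.1, "R": 256.0, "N": 165.5, "D": 158.7, "C": 146.1,
    "Q": 193.2, "E": 186.2, "G": 88.1, "H": 202.5, "I": 181.0,
    "L": 193.1, "K": 225.8, "M": 203.4, "F": 222.8, "P": 146.8,
    "S": 129.8, "T": 152.5, "W": 266.3, "Y": 236.8, "V": 164.5,
}
_MILLER = {
    "A": 113.0, "R": 241.0, "N": 158.0, "D": 151.0, "C": 140.0,
    "Q": 189.0, "E": 183.0, "G": 85.0, "H": 194.0, "I": 182.0,
    "L": 180.0, "K": 211.0, "M": 204.0, "F": 218.0, "P": 143.0,
    "S": 122.0, "T": 146.0, "W": 259.0, "Y": 229.0, "V": 160.0,
}
_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass(frozen=True)
class MaxASATable:
    name: str
    max_asa: dict

    def __post_init__(self) -> None:
        if len(self.max_asa) != 20 or any(v <= 0 for v in self.max_asa.values()):
            raise ValueError("max-ASA table needs 20 positive entries")


MAX_ASA_TABLES = {
    "rose": MaxASATable("Rose", _ROSE),
    "miller": MaxASATable("Miller", _MILLER),
    "tien": MaxASATable("Tien", _TIEN),
}
#: measure tag of the RSA profile obtained with each table
RSA_MEASURE = {"rose": "RSA_R", "miller": "RSA_M", "tien": "RSA_T"}


def _ca_distances(structure: StructureModel) -> np.ndarray:
    D = squareform(pdist(structure.ca_coords))
    off = D + np.eye(structure.n_sites)
    if np.any(off == 0):
        i, j = np.argwhere(off == 0)[0]
        raise ValueError(f"duplicate Cα coordinates at sites {i + 1} and {j + 1}")
    return D


def compute_wcn(structure: StructureModel) -> SiteProfile:
    """Weighted contact number: sum of inverse squared Cα–Cα distances."""
    D = _ca_distances(structure)
    inv2 = 1.0 / (D**2 + np.eye(structure.n_sites))
    np.fill_diagonal(inv2, 0.0)
    return SiteProfile(inv2.sum(axis=1), "WCN")


def compute_cn(structure: StructureModel, cutoff: float) -> SiteProfile:
    """Contact number: count of other Cα within ``cutoff`` Å (inclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    D = _ca_distances(structure)
    within = D <= cutoff
    np.fill_diagonal(within, False)
    prof = SiteProfile(within.sum(axis=1).astype(float), "CN")
    prof.meta["cutoff"] = cutoff
    return prof


def scan_cn_cutoff(
    structures: list[StructureModel],
    seq_profiles: list[SiteProfile],
    radii=range(9, 31),
    method: str = "pearson",
) -> tuple[int, dict]:
    """Find the CN cut-off radius maximizing the mean CN-sequence correlation.

    For each radius, each protein's CN profile is smoothed, sign-oriented and
    correlated with the (smoothed, oriented) sequence profile; the dataset
    mean is recorded. Ties break toward the smaller radius.
    """
    from .stats import correlate, orient_profile, smooth_profile

    if not structures:
        raise ValueError("empty dataset")
    if len(structures) != len(seq_profiles):
        raise ValueError("need one sequence profile per structure")
    radii = list(radii)
    prepared = [
        p if p.oriented else orient_profile(p if p.smoothed else smooth_profile(p))
        for p in seq_profiles
    ]
    curve = {}
    for r in radii:
        rhos = []
        for s, seq in zip(structures, prepared):
            cn = orient_profile(smooth_profile(compute_cn(s, r)))
            rhos.append(correlate(cn, seq, method=method))
        valid = [x for x in rhos if not np.isnan(x)]
        curve[r] = float(np.mean(valid)) if valid else np.nan
    best = max(
        sorted(curve),
        key=lambda r: -np.inf if np.isnan(curve[r]) else curve[r],
    )
    return best, curve


# ---------------------------------------------------------------------------
# solvent accessibility


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def compute_asa(
    structure: StructureModel,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    pseudo: bool | None = None,
) -> SiteProfile:
    """Accessible surface area per site by Shrake–Rupley point sampling.

    Test points are placed on each atom's solvent-expanded sphere
    (vdW + probe); a point is accessible when it lies outside every other
    atom's expanded sphere. Per-site ASA sums the atom contributions of the
    residue's atoms, in Å². For Cα-only models each site is represented by a
    single pseudo-atom of radius 3.0 Å and the profile is flagged
    ``pseudo_atoms`` in its metadata; pass ``pseudo=False`` to force the use
    of the recorded atom radii instead.
    """
    if pseudo is None:
        pseudo = structure.is_ca_only()
    coords, radii, owner = [], [], []
    for si, site in enumerate(structure.sites):
        if pseudo:
            coords.append(site.ca)
            radii.append(CA_PSEUDO_RADIUS)
            owner.append(si)
        else:
            if not site.atoms:
                raise ValueError(f"site {site.index} has no atoms")
            for a in site.atoms:
                coords.append(a.coord)
                radii.append(a.radius)
                owner.append(si)
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    owner = np.asarray(owner)
    expanded = radii + probe
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_reach = expanded.max()
    asa = np.zeros(structure.n_sites)
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], expanded[i] + max_reach)
            if j != i
        ]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        area = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
        asa[owner[i]] += area
    prof = SiteProfile(asa, "ASA")
    prof.meta["probe"] = probe
    prof.meta["n_sphere_points"] = n_sphere_points
    if pseudo:
        prof.meta["pseudo_atoms"] = True
    return prof


def compute_rsa(
    asa_profile: SiteProfile,
    sequence: str,
    table: MaxASATable | str = "tien",
) -> SiteProfile:
    """Relative solvent accessibility: ASA / maxASA(aa), clamped to [0, 1]."""
    if isinstance(table, str):
        key = table.lower()
        tab = MAX_ASA_TABLES[key]
    else:
        tab = table
        key = tab.name.lower()
    if len(asa_profile) != len(sequence):
        raise ValueError("ASA profile and sequence lengths differ")
    values = np.empty(len(sequence))
    clamped = 0
    for i, aa in enumerate(sequence):
        if aa not in tab.max_asa:
            raise ValueError(f"unknown amino acid {aa!r} at site {i + 1}")
        v = asa_profile.values[i] / tab.max_asa[aa]
        if v > 1.0:
            clamped += 1
            v = 1.0
        values[i] = max(v, 0.0)
    if clamped:
        logger.warning(
            "RSA(%s): %d of %d sites clamped to 1.0", tab.name, clamped, len(sequence)
        )
    prof = SiteProfile(values, RSA_MEASURE.get(key, "RSA_T"))
    prof.meta["table"] = tab.name
    prof.meta["clamped"] = clamped
    prof.meta.update(asa_profile.meta)
    return prof
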
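"""Binding-interface detection on multimeric structures and peptide scoring.

Interface residues are found by the classic buried-surface criterion: compute
per-residue relative solvent accessibility (rSASA) on the full oligomer and on
each chain in isolation; residues whose rSASA rises by more than 25 percentage
points upon removing the partner chains are interface residues.  SASA is
computed by sphere sampling (Shrake-Rupley with a deterministic golden-spiral
point set) and normalised by residue-type theoretical maximum accessibilities
(Tien et al.-style table), expressed in percent.

Peptides are mapped onto chains by exact sequence match and scored by their
mean per-residue minimum C-alpha distance to the interface residue set; a
peptide closer than a cutoff (2.6 A, or 0.3 A for the stringent variant) is
"interface associated".
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: van der Waals radii (A) by element symbol, fallback 1.70.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Theoretical maximum accessibilities (A^2) per residue type, used to
#: normalise residue SASA to percent.  Configurable via the ``reference``
#: argument of :func:`relative_sasa`.
MAX_ACC = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_MAX_ACC = 197.0  # fallback for nonstandard residues

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclasses.dataclass
class Chain:
    """One polypeptide chain: residue names, C-alpha trace and atom spheres."""

    chain_id: str
    resnames: list[str]  # 3-letter codes
    ca: np.ndarray  # (n_res, 3)
    atom_coords: np.ndarray  # (n_atoms, 3)
    atom_radii: np.ndarray  # (n_atoms,)
    atom_residue: np.ndarray  # (n_atoms,) index into residues

    @property
    def n_residues(self) -> int:
        return len(self.resnames)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r, "X") for r in self.resnames)


@dataclasses.dataclass
class StructureModel:
    """A (possibly multimeric) structure as chains of residues with atoms."""

    structure_id: str
    chains: list[Chain]

    @property
    def n_subunits(self) -> int:
        return len(self.chains)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @classmethod
    def from_file(cls, path: str | Path, structure_id: str | None = None) -> "StructureModel":
        """Read a PDB or mmCIF file (first model, polymer chains)."""
        import gemmi

        st = gemmi.read_structure(str(path))
        st.setup_entities()
        st.remove_ligands_and_waters()
        st.remove_hydrogens()
        model = st[0]
        chains = []
        for ch in model:
            resnames, cas = [], []
            coords, radii, residx = [], [], []
            for res in ch:
                ca = res.find_atom("CA", "*")
                if ca is None:
                    continue
                idx = len(resnames)
                resnames.append(res.name)
                cas.append([ca.pos.x, ca.pos.y, ca.pos.z])
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    radii.append(VDW_RADII.get(atom.element.name.upper(), DEFAULT_VDW))
                    residx.append(idx)
            if resnames:
                chains.append(
                    Chain(
                        ch.name,
                        resnames,
                        np.asarray(cas, float),
                        np.asarray(coords, float),
                        np.asarray(radii, float),
                        np.asarray(residx, int),
                    )
                )
        return cls(structure_id or Path(path).stem, chains)

    def to_pdb(self, path: str | Path) -> None:
        """Write C-alpha (and pseudo side chain) spheres as a minimal PDB.

        Element-based radii are re-derived on read, so custom sphere radii do
        not survive a round trip; intended for visualisation and interchange.
        """
        with open(path, "w") as fh:
            serial = 1
            for chain in self.chains:
                seen: dict[int, int] = {}
                for i, (coord, resi) in enumerate(
                    zip(chain.atom_coords, chain.atom_residue)
                ):
                    seen[resi] = seen.get(resi, 0) + 1
                    name = "CA" if seen[resi] == 1 else "CB"
                    resname = chain.resnames[resi]
                    fh.write(
                        f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} "
                        f"{chain.chain_id[:1]}{resi + 1:4d}    "
                        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}\n"
                    )
                    serial += 1
            fh.write("END\n")


# ---------------------------------------------------------------------------
# SASA


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) by sphere sampling.

    Each atom is expanded by the probe radius and sampled with a fixed
    golden-spiral point set; a point is accessible iff it lies outside every
    other expanded atom.  Deterministic for a given ``n_points``.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n_atoms = len(coords)
    if n_atoms == 0:
        return np.zeros(0)
    sphere = _golden_spiral(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    r_max = expanded.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        r_i = expanded[i]
        pts = coords[i] + r_i * sphere
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], r_i + r_max)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < r_i + expanded[j]
        ]
        if neighbors:
            d2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (expanded[neighbors] ** 2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        areas[i] = 4.0 * np.pi * r_i**2 * n_acc / n_points
    return areas


def relative_sasa(
    entity: StructureModel | Chain,
    probe_radius: float = 1.4,
    n_points: int = 960,
    reference: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-residue SASA and rSASA (%) for a structure or a single chain.

    rSASA is the residue SASA divided by the residue type's reference maximum
    accessibility, x100; values above 100% are not clipped.  Unknown residue
    types fall back to a default reference with a warning.
    """
    reference = dict(MAX_ACC if reference is None else reference)
    chains = entity.chains if isinstance(entity, StructureModel) else [entity]
    coords = np.concatenate([c.atom_coords for c in chains])
    radii = np.concatenate([c.atom_radii for c in chains])
    atom_area = shrake_rupley(coords, radii, probe_radius, n_points)

    rows = []
    offset = 0
    warned: set[str] = set()
    for chain in chains:
        n_at = len(chain.atom_coords)
        per_res = np.zeros(chain.n_residues)
        np.add.at(per_res, chain.atom_residue, atom_area[offset : offset + n_at])
        offset += n_at
        for i, resname in enumerate(chain.resnames):
            if resname not in reference and resname not in warned:
                warnings.warn(f"no reference accessibility for {resname}; using default")
                warned.add(resname)
            ref = reference.get(resname, DEFAULT_MAX_ACC)
            rows.append(
                {
                    "chain_id": chain.chain_id,
                    "residue_index": i,
                    "resname": resname,
                    "sasa": per_res[i],
                    "rsasa": 100.0 * per_res[i] / ref,
                }
            )
    return pd.DataFrame(rows)


def detect_interface(
    structure: StructureModel,
    threshold: float = 25.0,
    probe_radius: float = 1.4,
    n_points: int = 960,
    reference: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Label interface residues by the rSASA burial criterion.

    A residue is an interface residue iff its rSASA computed on the isolated
    chain exceeds its rSASA in the full oligomer by strictly more than
    ``threshold`` percentage points.
    """
    if structure.n_subunits < 2:
        warnings.warn(f"{structure.structure_id}: single chain, no interface possible")
    olig = relative_sasa(structure, probe_radius, n_points, reference)
    iso = pd.concat(
        [relative_sasa(c, probe_radius, n_points, reference) for c in structure.chains],
        ignore_index=True,
    )
    out = olig.merge(
        iso[["chain_id", "residue_index", "rsasa"]],
        on=["chain_id", "residue_index"],
        suffixes=("_oligomer", "_isolated"),
    )
    out["delta_rsasa"] = out["rsasa_isolated"] - out["rsasa_oligomer"]
    out["is_interface"] = (out["delta_rsasa"] > threshold) & (structure.n_subunits >= 2)
    return out


# ---------------------------------------------------------------------------
# peptide mapping and distances


def map_peptide_to_chain(
    peptide: str,
    structure: StructureModel,
    rng: np.random.Generator | int | None = 0,
) -> tuple[str, int, int] | None:
    """Locate a peptide on a chain by exact sequence match.

    Returns (chain_id, start_residue_index, end_residue_index) with 0-based
    inclusive indices, or None if the peptide is absent from every chain.
    When the peptide occurs in several chain copies (or several positions),
    one occurrence is chosen uniformly at random with the supplied seeded
    generator, so reruns are reproducible.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    hits: list[tuple[str, int, int]] = []
    for chain in structure.chains:
        seq = chain.sequence
        pos = seq.find(peptide)
        while pos != -1:
            hits.append((chain.chain_id, pos, pos + len(peptide) - 1))
            pos = seq.find(peptide, pos + 1)
    if not hits:
        return None
    return hits[int(rng.integers(len(hits)))]


def peptide_interface_distance(
    structure: StructureModel,
    chain_id: str,
    interval: tuple[int, int],
    interface: pd.DataFrame,
) -> float:
    """Mean over peptide residues of the minimum C-alpha distance (A) to any
    interface residue.  Raises ValueError if the interface set is empty."""
    iface = interface[interface["is_interface"]]
    if iface.empty:
        raise ValueError("empty interface: peptide distance undefined")
    iface_coords = np.array(
        [
            structure.chain(c).ca[i]
            for c, i in iface[["chain_id", "residue_index"]].itertuples(
                index=False, name=None
            )
        ]
    )
    start, end = interval
    pep_coords = structure.chain(chain_id).ca[start : end + 1]
    d = np.linalg.norm(pep_coords[:, None, :] - iface_coords[None, :, :], axis=-1)
    return float(d.min(axis=1).mean())


def peptide_distance_table(
    structure: StructureModel,
    peptides: Iterable[str],
    interface: pd.DataFrame | None = None,
    cutoffs: Sequence[float] = (2.6, 0.3),
    seed: int = 0,
    **interface_kwargs,
) -> pd.DataFrame:
    """Map peptides onto a structure and score interface proximity.

    Peptides absent from the structure are discarded.  Returns one row per
    mapped peptide with its distance and an ``interface_lt_{cutoff}`` flag for
    each cutoff.  If the structure has no interface residues the table is
    empty (all peptides excluded).
    """
    if interface is None:
        interface = detect_interface(structure, **interface_kwargs)
    rng = np.random.default_rng(seed)
    rows = []
    has_interface = bool(interface["is_interface"].any())
    for pep in peptides:
        mapped = map_peptide_to_chain(pep, structure, rng)
        if mapped is None or not has_interface:
            continue
        chain_id, start, end = mapped
        dist = peptide_interface_distance(structure, chain_id, (start, end), interface)
        row = {
            "peptide_id": pep,
            "chain_id": chain_id,
            "start": start,
            "end": end,
            "distance": dist,
        }
        for cutoff in cutoffs:
            row[f"interface_lt_{cutoff:g}"] = dist < cutoff
        rows.append(row)
    cols = ["peptide_id", "chain_id", "start", "end", "distance"] + [
        f"interface_lt_{c:g}" for c in cutoffs
    ]
    return pd.DataFrame(rows, columns=cols)


def select_structure(
    candidates: Mapping[str, StructureModel],
    policy: str = "biggest",
    seed: int = 0,
    marker_peptides: Iterable[str] | None = None,
    nonmarker_peptides: Iterable[str] | None = None,
    cutoff: float = 2.6,
    **interface_kwargs,
) -> StructureModel:
    """Choose one structure per protein among candidates.

    ``biggest``
        most subunits, ties broken by structure id;
    ``random``
        seeded uniform choice;
    ``best``
        maximise the agreement score: markers within ``cutoff`` of an
        interface plus non-markers outside it, ties broken by more subunits.
    """
    if not candidates:
        raise ValueError("no candidate structures")
    items = sorted(candidates.items())
    if policy == "biggest":
        return max(items, key=lambda kv: (kv[1].n_subunits, kv[0]))[1]
    if policy == "random":
        rng = np.random.default_rng(seed)
        return items[int(rng.integers(len(items)))][1]
    if policy == "best":
        if marker_peptides is None or nonmarker_peptides is None:
            raise ValueError("policy 'best' needs marker and non-marker peptides")
        markers = list(marker_peptides)
        nonmarkers = list(nonmarker_peptides)
        scored = []
        for sid, st in items:
            table = peptide_distance_table(
                st, markers + nonmarkers, cutoffs=(cutoff,), seed=seed,
                **interface_kwargs,
            )
            flag = dict(zip(table["peptide_id"], table[f"interface_lt_{cutoff:g}"]))
            score = sum(1 for p in markers if flag.get(p, False)) + sum(
                1 for p in nonmarkers if not flag.get(p, True)
            )
            scored.append((score, st.n_subunits, sid, st))
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        return scored[-1][3]
    raise ValueError(f"unknown policy {policy!r}")


def interface_roc(
    labels: Sequence[bool], scores: Sequence[float], markers: Sequence[bool] | None = None
) -> dict:
    """ROC AUC of a significance score against interface association.

    AUC is the probability that a random interface-associated peptide outranks
    a random non-associated one (ties count one half).  When marker calls are
    supplied, confusion counts follow the marker/interface mapping: marker at
    interface = TP, marker off interface = FP, non-marker at interface = FN,
    non-marker off interface = TN.  With a single-class label vector the AUC
    is undefined and reported as None.
    """
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, bool)
    scores = np.asarray(scores, float)
    out: dict = {"n": int(len(labels)), "n_positive": int(labels.sum())}
    if labels.sum() in (0, len(labels)):
        out["auc"] = None
    else:
        out["auc"] = float(roc_auc_score(labels, scores))
    if markers is not None:
        markers = np.asarray(markers, bool)
        out.update(
            tp=int((markers & labels).sum()),
            fp=int((markers & ~labels).sum()),
            fn=int((~markers & labels).sum()),
            tn=int((~markers & ~labels).sum()),
        )
    return out
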
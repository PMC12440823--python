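"""Synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates the data structure of a serial-ultrafiltration LiP-MS
library experiment: four size fractions x n biological replicates of LiP
peptide intensities and tryptic-control protein intensities, with

* multiplicative log-normal replicate noise at configurable coefficients of
  variation (the standard noise model for label-free MS peak areas),
* per-protein, per-fraction abundance differences (proteins partition
  unevenly across molecular-weight fractions), and
* planted *markers*: protein regions whose peptide/protein intensity ratio
  changes between named fractions by a configured fold change, while all
  other peptides keep fraction-constant expected ratios.

Structural and network fixtures follow the same philosophy: a toy dimer with
a designed contact patch (recorded as ground-truth interface residues), and
clique-per-complex networks with planted communities.  All generators are
pure functions of their parameters and seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

from flipms.io import classify_tryptic
from flipms.structure import MAX_ACC, ONE_TO_THREE, Chain, StructureModel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
FRACTIONS = ("100K", "50K", "30K", "10K")

#: rSASA reference table for toy structures.  Toy residues are uniform
#: two-sphere pseudo-residues, so the residue-type-specific maxima of real
#: side chains do not apply; a uniform reference scaled to the exposure of a
#: fully solvent-facing mid-chain toy residue (~100 A^2) is used instead.
TOY_REFERENCE = {name: 100.0 for name in MAX_ACC}


def protein_mw_kda(sequence: str) -> float:
    """Molecular weight in kDa from average residue masses."""
    return molecular_weight(sequence, seq_type="protein") / 1000.0


def make_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (50, 500),
    seed: int = 0,
) -> dict[str, str]:
    """Random proteome {accession: sequence}; uniform residue usage."""
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"length_range min {lo} > max {hi}")
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    proteome = {}
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        proteome[f"P{i + 1:04d}"] = seq
    return proteome


def _tryptic_intervals(sequence: str) -> list[tuple[int, int]]:
    """1-based inclusive intervals of fully tryptic peptides (no missed
    cleavages): cut after every K/R."""
    intervals = []
    start = 1
    for i, aa in enumerate(sequence, start=1):
        if aa in "KR" or i == len(sequence):
            intervals.append((start, i))
            start = i + 1
    return intervals


def digest_in_silico(
    proteome: Mapping[str, str],
    pk_sites_per_protein: int = 2,
    seed: int = 0,
    min_length: int = 6,
) -> pd.DataFrame:
    """In-silico double digest: trypsin plus random proteinase-K sites.

    Fully tryptic peptides come from K/R cleavage; each random internal PK
    site splits its host tryptic peptide into two semi-tryptic fragments
    (one PK terminus paired with the flanking tryptic terminus).  Peptides
    shorter than ``min_length`` are discarded, matching the usual search
    engine floor of six residues.  Peptide sequences duplicated anywhere in
    the proteome are dropped so sequences identify peptides uniquely.
    """
    if not proteome:
        raise ValueError("empty proteome")
    rng = np.random.default_rng(seed)
    rows = []
    for acc, seq in proteome.items():
        tryptic = _tryptic_intervals(seq)
        for start, end in tryptic:
            if end - start + 1 >= min_length:
                rows.append((acc, start, end, "fully_tryptic"))
        if pk_sites_per_protein > 0 and len(seq) > 2:
            # PK cleaves between site and site+1; interior positions only
            sites = rng.choice(
                np.arange(1, len(seq)), size=min(pk_sites_per_protein, len(seq) - 1),
                replace=False,
            )
            for site in np.sort(sites):
                host = next(((s, e) for s, e in tryptic if s <= site < e), None)
                if host is None:
                    continue
                s, e = host
                for frag in ((s, int(site)), (int(site) + 1, e)):
                    if frag[1] - frag[0] + 1 >= min_length:
                        rows.append((acc, frag[0], frag[1], "semi_tryptic"))
    out = pd.DataFrame(rows, columns=["protein_id", "start", "end", "tryptic_type"])
    out["sequence"] = [
        proteome[p][s - 1 : e] for p, s, e in zip(out["protein_id"], out["start"], out["end"])
    ]
    out["peptide_id"] = out["sequence"]
    out = out.drop_duplicates(subset=["protein_id", "start", "end"])
    dup = out["sequence"].duplicated(keep=False)
    out = out[~dup]
    # classify against the real rule so semi fragments landing on K/R stay honest
    out["tryptic_type"] = [
        classify_tryptic(proteome[p], s, e)
        for p, s, e in zip(out["protein_id"], out["start"], out["end"])
    ]
    out["ambiguous"] = False
    cols = ["peptide_id", "protein_id", "sequence", "start", "end", "tryptic_type", "ambiguous"]
    return out[cols].reset_index(drop=True)


@dataclasses.dataclass(frozen=True)
class PlantedMarker:
    """A protein region whose peptide/protein ratio is multiplied by
    ``2**log2fc`` in ``fraction`` (relative to every other fraction)."""

    protein_id: str
    start: int
    end: int
    log2fc: float
    fraction: str = "100K"


@dataclasses.dataclass
class SimulationTruth:
    """Everything needed to reproduce and evaluate a simulated experiment."""

    seed: int
    fractions: tuple[str, ...] = FRACTIONS
    n_replicates: int = 4
    cv_peptide: float = 0.1
    cv_protein: float = 0.1
    missingness: float = 0.0
    fraction_abundance: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    planted_markers: list[PlantedMarker] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if self.cv_peptide < 0 or self.cv_protein < 0:
            raise ValueError("CVs must be >= 0")
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness must be in [0, 1]")
        for m in self.planted_markers:
            if not np.isfinite(m.log2fc):
                raise ValueError("planted fold changes must be finite")

    def marker_peptides(self, annotations: pd.DataFrame) -> set[str]:
        """Peptide ids overlapping any planted region (>= 1 residue)."""
        out: set[str] = set()
        for m in self.planted_markers:
            sel = annotations[
                (annotations["protein_id"] == m.protein_id)
                & (annotations["start"] <= m.end)
                & (annotations["end"] >= m.start)
            ]
            out.update(sel["peptide_id"])
        return out

    def marker_regions(self) -> set[tuple[str, int, int]]:
        return {(m.protein_id, m.start, m.end) for m in self.planted_markers}


def default_truth(
    proteome: Mapping[str, str],
    annotations: pd.DataFrame,
    n_markers: int = 50,
    log2fc: float = 1.0,
    marker_fraction: str = "100K",
    cv_peptide: float = 0.1,
    cv_protein: float = 0.1,
    n_replicates: int = 4,
    missingness: float = 0.0,
    seed: int = 0,
) -> SimulationTruth:
    """Build study-condition defaults: 4 fractions x 4 replicates, 10% CV
    log-normal noise, log2FC-1 markers planted on fully tryptic peptides of
    distinct proteins, and log-normal protein abundances with per-fraction
    differences."""
    rng = np.random.default_rng(seed)
    abundance = {
        acc: {
            f: float(10 ** (rng.normal(6.0, 0.3) + rng.normal(0.0, 0.2)))
            for f in FRACTIONS
        }
        for acc in proteome
    }
    fully = annotations[annotations["tryptic_type"] == "fully_tryptic"]
    candidates = fully.drop_duplicates(subset="protein_id")
    if n_markers > len(candidates):
        raise ValueError(
            f"cannot plant {n_markers} markers on {len(candidates)} eligible proteins"
        )
    chosen = candidates.iloc[
        rng.choice(len(candidates), size=n_markers, replace=False)
    ]
    markers = [
        PlantedMarker(p, int(s), int(e), log2fc, marker_fraction)
        for p, s, e in zip(chosen["protein_id"], chosen["start"], chosen["end"])
    ]
    return SimulationTruth(
        seed=seed,
        n_replicates=n_replicates,
        cv_peptide=cv_peptide,
        cv_protein=cv_protein,
        missingness=missingness,
        fraction_abundance=abundance,
        planted_markers=markers,
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and coefficient of variation
    ``cv`` (log-normal parameterisation)."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_flip_experiment(
    truth: SimulationTruth,
    proteome: Mapping[str, str],
    annotations: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate LiP and tryptic-control intensity tables.

    Protein intensities follow ``truth.fraction_abundance`` with log-normal
    noise at ``cv_protein``; each peptide draws a base peptide/protein yield
    and its intensity is abundance x yield x (planted multiplier) x noise at
    ``cv_peptide``.  Records are dropped independently at the missingness
    rate.  Returns (lip, tryptic_control) canonical tables.
    """
    rng = np.random.default_rng(truth.seed)
    fractions = list(truth.fractions)
    reps = range(1, truth.n_replicates + 1)

    for m in truth.planted_markers:
        sel = annotations[
            (annotations["protein_id"] == m.protein_id)
            & (annotations["start"] <= m.end)
            & (annotations["end"] >= m.start)
        ]
        if sel.empty:
            warnings.warn(
                f"planted region {m.protein_id}[{m.start},{m.end}] has no covering peptide"
            )

    lip_rows, ctrl_rows = [], []
    for acc in proteome:
        abund = truth.fraction_abundance.get(acc)
        if abund is None:
            raise ValueError(f"no fraction_abundance entry for {acc}")
        noise = _lognormal_noise(rng, truth.cv_protein, (len(fractions), truth.n_replicates))
        for fi, frac in enumerate(fractions):
            for ri, rep in enumerate(reps):
                ctrl_rows.append(
                    (acc, acc, frac, rep, abund[frac] * noise[fi, ri], "tryptic_control")
                )

    marker_mult = {}
    for m in truth.planted_markers:
        sel = annotations[
            (annotations["protein_id"] == m.protein_id)
            & (annotations["start"] <= m.end)
            & (annotations["end"] >= m.start)
        ]
        for pep in sel["peptide_id"]:
            marker_mult[pep] = (m.fraction, 2.0**m.log2fc)

    for pep, acc in zip(annotations["peptide_id"], annotations["protein_id"]):
        if acc not in proteome:
            continue
        abund = truth.fraction_abundance[acc]
        base_yield = float(rng.lognormal(np.log(0.05), 0.5))
        noise = _lognormal_noise(rng, truth.cv_peptide, (len(fractions), truth.n_replicates))
        frac_mult, mult = marker_mult.get(pep, (None, 1.0))
        for fi, frac in enumerate(fractions):
            m = mult if frac == frac_mult else 1.0
            for ri, rep in enumerate(reps):
                lip_rows.append(
                    (pep, acc, frac, rep, abund[frac] * base_yield * m * noise[fi, ri], "lip")
                )

    columns = ["analyte_id", "protein_id", "group", "replicate", "intensity", "sample_type"]
    lip = pd.DataFrame(lip_rows, columns=columns)
    ctrl = pd.DataFrame(ctrl_rows, columns=columns)
    if truth.missingness > 0:
        lip = lip[rng.random(len(lip)) >= truth.missingness].reset_index(drop=True)
        ctrl = ctrl[rng.random(len(ctrl)) >= truth.missingness].reset_index(drop=True)
    return lip, ctrl


# ---------------------------------------------------------------------------
# toy structures


def simulate_dimer_structure(
    chain_length: int = 40,
    interface_width: int = 10,
    seed: int = 0,
    sequences: tuple[str, str] | None = None,
    contact_distance: float = 7.0,
    apart_distance: float = 40.0,
    atom_radius: float = 1.9,
) -> tuple[StructureModel, set[tuple[str, int]]]:
    """Toy two-chain structure with a designed central contact patch.

    Each residue contributes a C-alpha sphere and a pseudo side-chain sphere
    (uniform radius, default 1.9 A) pointing toward the partner chain.  Chain
    B runs parallel to chain A at ``apart_distance`` except over the central
    ``interface_width`` residues, where it approaches to ``contact_distance``
    (C-alpha to C-alpha across the interface).  Returns the structure and the
    ground-truth buried residues as {(chain_id, residue_index)} (0-based).
    Setting ``contact_distance`` to a large value yields a no-contact control
    with an empty truth set.
    """
    if sequences is not None:
        seq_a, seq_b = sequences
    else:
        rng = np.random.default_rng(seed)
        seq_a = "".join(rng.choice(list(AMINO_ACIDS), size=chain_length))
        seq_b = "".join(rng.choice(list(AMINO_ACIDS), size=chain_length))
    if interface_width >= min(len(seq_a), len(seq_b)):
        raise ValueError("interface_width must be smaller than the chain length")

    spacing = 3.8  # C-alpha spacing along the chain axis (A)
    side = 3.0  # side-chain sphere offset toward the partner (A)
    n_a, n_b = len(seq_a), len(seq_b)
    patch_a = _central_patch(n_a, interface_width)
    patch_b = _central_patch(n_b, interface_width)
    # closest inter-chain atom pair is side-chain to side-chain
    in_contact = (
        interface_width > 0
        and contact_distance - 2 * side <= 2 * (atom_radius + 1.4)
    )

    def build_chain(chain_id, seq, patch, is_b):
        ca, coords, radii, residx = [], [], [], []
        for i in range(len(seq)):
            if is_b:
                y = contact_distance if i in patch else apart_distance
                sign = -1.0
            else:
                y, sign = 0.0, 1.0
            ca.append([spacing * i, y, 0.0])
            coords.append([spacing * i, y, 0.0])
            coords.append([spacing * i, y + sign * side, 0.0])
            radii += [atom_radius, atom_radius]
            residx += [i, i]
        return Chain(
            chain_id,
            [ONE_TO_THREE[aa] for aa in seq],
            np.asarray(ca),
            np.asarray(coords),
            np.asarray(radii),
            np.asarray(residx),
        )

    chain_a = build_chain("A", seq_a, patch_a, is_b=False)
    chain_b = build_chain("B", seq_b, patch_b, is_b=True)
    structure = StructureModel("toy_dimer", [chain_a, chain_b])
    truth: set[tuple[str, int]] = set()
    if in_contact:
        truth |= {("A", i) for i in patch_a} | {("B", i) for i in patch_b}
    return structure, truth


def _central_patch(n: int, width: int) -> set[int]:
    start = (n - width) // 2
    return set(range(start, start + width))


# ---------------------------------------------------------------------------
# toy networks


def simulate_complex_network(
    complex_sizes: Sequence[int],
    n_bridge_edges: int = 0,
    seed: int = 0,
) -> tuple[nx.Graph, dict[str, tuple[str, frozenset]], list[set[str]]]:
    """Planted-community network: one clique per complex plus sparse bridges.

    Returns (graph, complexes {id: (name, member set)}, planted partition).
    """
    if any(s < 2 for s in complex_sizes):
        raise ValueError("complex sizes must be >= 2")
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    complexes: dict[str, tuple[str, frozenset]] = {}
    partition: list[set[str]] = []
    for k, size in enumerate(complex_sizes, start=1):
        members = [f"CPX{k}_P{i + 1}" for i in range(size)]
        graph.add_edges_from(
            (members[i], members[j]) for i in range(size) for j in range(i + 1, size)
        )
        complexes[f"CPX{k}"] = (f"complex_{k}", frozenset(members))
        partition.append(set(members))
    if n_bridge_edges > 0 and len(complex_sizes) >= 2:
        added = 0
        existing = set(map(frozenset, graph.edges()))
        while added < n_bridge_edges:
            i, j = rng.choice(len(partition), size=2, replace=False)
            u = sorted(partition[i])[int(rng.integers(len(partition[i])))]
            v = sorted(partition[j])[int(rng.integers(len(partition[j])))]
            if frozenset((u, v)) in existing:
                continue
            graph.add_edge(u, v)
            existing.add(frozenset((u, v)))
            added += 1
    return graph, complexes, partition


def complex_table(complexes: Mapping[str, tuple[str, Iterable[str]]]) -> pd.DataFrame:
    """Complex-membership table in the on-disk format the network reader uses."""
    return pd.DataFrame(
        {
            "complex_id": list(complexes),
            "complex_name": [complexes[c][0] for c in complexes],
            "members": [";".join(sorted(complexes[c][1])) for c in complexes],
        }
    )
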
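"""Build the FLiP marker library from significant unique regions.

A FLiP marker is a unique protein region (coordinates of the longest fully
tryptic parent) whose median q-value clears the significance threshold.
Each marker carries a confidence class based on the serial-ultrafiltration
molecular-weight logic: a protein is *allowed* to elute in a fraction if
half its molecular weight does not exceed the fraction's expected upper
bound (the next-larger membrane cutoff).  A marker whose every significant
fraction pair involves a disallowed fraction is low confidence -- the change
may be driven by aberrant elution (e.g. in-cell cleavage) rather than an
assembly-state difference.

Markers can be annotated with orthogonal interface evidence: overlap with
protein-binding or RNA-binding domains, and proximity (< 2.6 A) to a known
binding interface on a multimeric structure.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_CUTOFFS = (100.0, 50.0, 30.0, 10.0)  # MWCOs in kDa, descending


def fraction_label(cutoff: float) -> str:
    return f"{cutoff:g}K"


def expected_fractions(
    protein_mw_kda: float, cutoffs: Sequence[float] = DEFAULT_CUTOFFS
) -> set[str]:
    """Fractions a monomer of the given mass may legitimately elute in.

    The retentate of cutoff k is expected to hold species below the
    next-larger cutoff (unbounded for the largest membrane); a fraction is
    allowed iff MW/2 <= that upper bound (boundary inclusive).  For the
    default 100/50/30/10 cascade an 80-kDa protein is allowed down to the
    30-K fraction (40 <= 50) but not the 10-K fraction (40 > 30).
    """
    if protein_mw_kda <= 0:
        raise ValueError("protein molecular weight must be positive")
    if list(cutoffs) != sorted(cutoffs, reverse=True):
        raise ValueError("cutoffs must be strictly descending")
    allowed = set()
    half = protein_mw_kda / 2.0
    for i, k in enumerate(cutoffs):
        upper = float("inf") if i == 0 else cutoffs[i - 1]
        if half <= upper:
            allowed.add(fraction_label(k))
    return allowed


def classify_confidence(
    significant_pairs: Iterable[tuple[str, str]],
    allowed_fractions: set[str],
) -> str:
    """``low`` iff every significant fraction pair involves a disallowed
    fraction; ``high`` as soon as one all-allowed pair exists."""
    pairs = list(significant_pairs)
    if not pairs:
        raise ValueError("no significant fraction pair: not a marker")
    for a, b in pairs:
        if a in allowed_fractions and b in allowed_fractions:
            return "high"
    return "low"


def build_library(
    regions: pd.DataFrame,
    pairwise: pd.DataFrame,
    protein_mw_kda: Mapping[str, float],
    q_threshold: float = 0.05,
    pair_threshold: float = 0.05,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the marker library and its summary.

    Parameters
    ----------
    regions
        Unique-region table from :func:`flipms.diffstats.group_to_parent`.
    pairwise
        Peptide x fraction-pair Tukey table with BH-adjusted ``p_adj``.
    protein_mw_kda
        Monomeric molecular weight per protein (computed from sequence).

    Returns
    -------
    library : DataFrame
        One row per region with q_median < ``q_threshold``: coordinates,
        members, significant fraction pairs, confidence class and evidence
        flags (initialised False; see :func:`annotate_library`).
    summary : dict
        n_markers, n_proteins, pct_high_confidence.
    """
    sig_pairs = pairwise[pairwise["p_adj"] < pair_threshold]
    pair_map: dict[str, set[tuple[str, str]]] = {}
    for pep, g1, g2 in sig_pairs[["peptide_id", "group1", "group2"]].itertuples(
        index=False, name=None
    ):
        pair_map.setdefault(pep, set()).add((g1, g2))

    rows = []
    for region in regions.itertuples(index=False):
        if not region.q_median < q_threshold:
            continue
        pairs: set[tuple[str, str]] = set()
        for pep in region.member_peptides:
            pairs |= pair_map.get(pep, set())
        mw = protein_mw_kda[region.protein_id]
        allowed = expected_fractions(mw, cutoffs)
        confidence = classify_confidence(pairs, allowed) if pairs else "low"
        rows.append(
            {
                "protein_id": region.protein_id,
                "start": region.start,
                "end": region.end,
                "q_median": region.q_median,
                "confidence": confidence,
                "member_peptides": list(region.member_peptides),
                "significant_pairs": sorted(pairs),
                "no_significant_pair": not pairs,
                "protein_binding_domain": False,
                "rna_binding_domain": False,
                "near_interface": False,
            }
        )
    columns = [
        "protein_id", "start", "end", "q_median", "confidence", "member_peptides",
        "significant_pairs", "no_significant_pair", "protein_binding_domain",
        "rna_binding_domain", "near_interface",
    ]
    library = pd.DataFrame(rows, columns=columns)
    n = len(library)
    summary = {
        "n_markers": n,
        "n_proteins": int(library["protein_id"].nunique()) if n else 0,
        "pct_high_confidence": (
            100.0 * float((library["confidence"] == "high").mean()) if n else float("nan")
        ),
    }
    return library, summary


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def annotate_library(
    library: pd.DataFrame,
    domains: pd.DataFrame | None = None,
    interface_distances: pd.DataFrame | None = None,
    distance_cutoff: float = 2.6,
    protein_binding_term: str = "protein binding",
    rna_binding_term: str = "RNA binding",
) -> pd.DataFrame:
    """Set the evidence flags on a marker library.

    ``domains`` has columns (protein_id, start, end, term); a marker gets a
    binding-domain flag when it overlaps (>= 1 residue) a domain annotated
    with the matching GO term.  ``interface_distances`` has columns
    (protein_id, start, end, distance); the ``near_interface`` flag is set
    when the region's average interface distance is strictly below the
    cutoff.  Absent evidence leaves flags False.
    """
    out = library.copy()
    if domains is not None and len(domains):
        for idx, marker in out.iterrows():
            sub = domains[domains["protein_id"] == marker["protein_id"]]
            for dom in sub.itertuples(index=False):
                if not _overlaps(marker["start"], marker["end"], dom.start, dom.end):
                    continue
                term = str(dom.term)
                if protein_binding_term in term:
                    out.at[idx, "protein_binding_domain"] = True
                if rna_binding_term in term:
                    out.at[idx, "rna_binding_domain"] = True
    if interface_distances is not None and len(interface_distances):
        dist = interface_distances.set_index(["protein_id", "start", "end"])["distance"]
        for idx, marker in out.iterrows():
            key = (marker["protein_id"], marker["start"], marker["end"])
            if key in dist.index and dist.loc[key] < distance_cutoff:
                out.at[idx, "near_interface"] = True
    return out


def library_to_tsv(library: pd.DataFrame, path) -> None:
    """Serialise the library with list columns joined by ';'."""
    out = library.copy()
    out["member_peptides"] = out["member_peptides"].map(";".join)
    out["significant_pairs"] = out["significant_pairs"].map(
        lambda pairs: ";".join(f"{a}-{b}" for a, b in pairs)
    )
    out.to_csv(path, sep="\t", index=False)
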
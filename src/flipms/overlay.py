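"""Overlay a marker library on a perturbation LiP-MS experiment.

A significant peptide in a perturbation dataset is called a *marker hit*
when at least half of it (by residue count) falls inside a library marker of
its protein, so the peptide's accessibility change can be read as a change
in protein-interaction state.  Protein-abundance changes from the tryptic
control are called separately so hits can be interpreted against abundance
shifts.
"""

from __future__ import annotations

import pandas as pd


def overlap_fraction(
    peptide: tuple[int, int],
    marker: tuple[int, int],
    same_protein: bool = True,
) -> float:
    """|peptide ∩ marker| / |peptide| on 1-based inclusive intervals.

    Peptides and markers on different proteins do not overlap by contract.
    """
    if not same_protein:
        return 0.0
    p_start, p_end = peptide
    m_start, m_end = marker
    inter = min(p_end, m_end) - max(p_start, m_start) + 1
    return max(inter, 0) / (p_end - p_start + 1)


def call_marker_hits(
    results_table: pd.DataFrame,
    annotations: pd.DataFrame,
    library: pd.DataFrame,
    min_overlap: float = 0.5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Match significant perturbation peptides to library markers.

    A peptide is a hit iff its q-value is below ``q_threshold`` and its best
    overlap with any marker of its protein is at least ``min_overlap``
    (boundary inclusive).  The hit inherits the marker's confidence class.

    Parameters
    ----------
    results_table
        Per-peptide table of a fitted :class:`flipms.diffstats.PeptideAnova`
        on the perturbation experiment (protein-abundance corrected), indexed
        by or containing ``peptide_id`` with ``q`` and ``log2fc`` columns.
    annotations
        Peptide positions on proteins.
    library
        Marker library from :func:`flipms.markers.build_library`.
    """
    table = results_table.reset_index() if "peptide_id" not in results_table.columns else results_table
    sig = table[table["q"] < q_threshold]
    ann = annotations.set_index("peptide_id")
    by_protein = dict(tuple(library.groupby("protein_id", sort=False)))
    rows = []
    for row in sig.itertuples(index=False):
        pep = row.peptide_id
        if pep not in ann.index:
            continue
        a = ann.loc[pep]
        markers = by_protein.get(a["protein_id"])
        if markers is None:
            continue
        best, best_marker = 0.0, None
        for m in markers.itertuples(index=False):
            frac = overlap_fraction((a["start"], a["end"]), (m.start, m.end))
            if frac > best:
                best, best_marker = frac, m
        if best_marker is not None and best >= min_overlap:
            rows.append(
                {
                    "peptide_id": pep,
                    "protein_id": a["protein_id"],
                    "marker_start": best_marker.start,
                    "marker_end": best_marker.end,
                    "overlap_fraction": best,
                    "q": row.q,
                    "log2fc": row.log2fc,
                    "direction": 1 if row.log2fc > 0 else (-1 if row.log2fc < 0 else 0),
                    "confidence": best_marker.confidence,
                }
            )
    columns = [
        "peptide_id", "protein_id", "marker_start", "marker_end", "overlap_fraction",
        "q", "log2fc", "direction", "confidence",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_hits(hits: pd.DataFrame) -> dict:
    return {
        "n_hit_peptides": int(len(hits)),
        "n_hit_proteins": int(hits["protein_id"].nunique()) if len(hits) else 0,
    }


def protein_abundance_changes(
    protein_results: pd.DataFrame,
    lfc_threshold: float = 0.5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Proteins with |log2 fold change| strictly above ``lfc_threshold`` and
    q below ``q_threshold`` (from :func:`flipms.diffstats.protein_abundance_anova`)."""
    mask = (protein_results["log2fc"].abs() > lfc_threshold) & (
        protein_results["q"] < q_threshold
    )
    return protein_results[mask].reset_index(drop=True)
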
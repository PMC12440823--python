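"""Evidence analyses on a marker library.

Three orthogonal checks that the library behaves like a set of
interaction-interface reporters: enrichment of domain GO terms among marker
peptides (one-sided Fisher against the detected background), overlap with
disordered regions (many binding interfaces are disordered), and overlap
with curated interaction-disrupting mutation sites, judged against a
resampling null that places the same number of sites uniformly over the
same proteins.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from flipms.diffstats import adjust_bh


def _assign_terms(peptides: pd.DataFrame, domains: pd.DataFrame) -> dict[str, set[str]]:
    """peptide_id -> set of terms whose domain interval overlaps the peptide."""
    out: dict[str, set[str]] = {p: set() for p in peptides["peptide_id"]}
    by_protein = dict(tuple(domains.groupby("protein_id", sort=False)))
    for row in peptides.itertuples(index=False):
        sub = by_protein.get(row.protein_id)
        if sub is None:
            continue
        for dom in sub.itertuples(index=False):
            if row.start <= dom.end and dom.start <= row.end:
                out[row.peptide_id].add(dom.term)
    return out


def domain_fisher(
    marker_peptides: pd.DataFrame,
    background_peptides: pd.DataFrame,
    domains: pd.DataFrame,
) -> pd.DataFrame:
    """Per-term one-sided Fisher enrichment of markers vs non-marker background.

    Both peptide frames carry (peptide_id, protein_id, start, end); peptides
    present in the marker set are removed from the background so the 2x2
    table is marker vs non-marker x in-term vs not.  Terms touching no
    peptide at all are skipped.  BH across terms.
    """
    marker_ids = set(marker_peptides["peptide_id"])
    background = background_peptides[
        ~background_peptides["peptide_id"].isin(marker_ids)
    ]
    terms_m = _assign_terms(marker_peptides, domains)
    terms_b = _assign_terms(background, domains)
    all_terms = sorted(set().union(*terms_m.values(), *terms_b.values()))
    n_m, n_b = len(terms_m), len(terms_b)
    rows = []
    for term in all_terms:
        a = sum(term in t for t in terms_m.values())  # markers in term
        c = sum(term in t for t in terms_b.values())  # background in term
        if a + c == 0:
            continue
        table = [[a, n_m - a], [c, n_b - c]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append((term, a, n_m - a, c, n_b - c, odds, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "term", "markers_in_term", "markers_not_in_term",
            "background_in_term", "background_not_in_term", "odds_ratio", "p",
        ],
    )
    out["q"] = adjust_bh(out["p"]) if len(out) else out["p"]
    return out


def disorder_analysis(
    peptides: pd.DataFrame,
    significant: Sequence[str],
    disorder_regions: pd.DataFrame,
) -> dict:
    """Disorder overlap of significant vs nonsignificant peptides.

    A peptide is *disordered* when it at least partially overlaps an
    annotated disordered region of its protein.  Returns per-peptide flags,
    the percentage disordered among significant and nonsignificant peptides,
    and a one-sided Fisher p against the null that significant peptides are
    not enriched in disorder.
    """
    by_protein = (
        dict(tuple(disorder_regions.groupby("protein_id", sort=False)))
        if len(disorder_regions)
        else {}
    )
    flags = {}
    for row in peptides.itertuples(index=False):
        sub = by_protein.get(row.protein_id)
        flag = False
        if sub is not None:
            flag = bool(
                ((row.start <= sub["end"]) & (sub["start"] <= row.end)).any()
            )
        flags[row.peptide_id] = flag
    sig = set(significant)
    sig_flags = [flags[p] for p in flags if p in sig]
    non_flags = [flags[p] for p in flags if p not in sig]
    a, b = sum(sig_flags), len(sig_flags) - sum(sig_flags)
    c, d = sum(non_flags), len(non_flags) - sum(non_flags)
    if a + b and c + d:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    else:
        p = 1.0
    pct = lambda x: 100.0 * np.mean(x) if len(x) else 0.0  # noqa: E731
    return {
        "flags": flags,
        "pct_disordered_significant": pct(sig_flags),
        "pct_disordered_nonsignificant": pct(non_flags),
        "pct_disordered_all": pct(list(flags.values())),
        "p": float(p),
    }


def mutation_overlap(
    markers: pd.DataFrame,
    sites: pd.DataFrame,
    protein_lengths: Mapping[str, int],
    window_aa: int = 0,
) -> float:
    """Fraction of mutation sites covered by (window-extended) markers.

    ``sites`` has columns (protein_id, position).  A site counts as
    overlapped when it lies within any marker interval of its protein
    extended by ``window_aa`` residues on each side.
    """
    for i, row in enumerate(sites.itertuples(index=False)):
        length = protein_lengths.get(row.protein_id)
        if length is not None and not 1 <= row.position <= length:
            raise ValueError(
                f"mutation site row {i}: position {row.position} outside "
                f"{row.protein_id} (length {length})"
            )
    by_protein = dict(tuple(markers.groupby("protein_id", sort=False)))
    hit = 0
    for row in sites.itertuples(index=False):
        sub = by_protein.get(row.protein_id)
        if sub is None:
            continue
        if (
            (sub["start"] - window_aa <= row.position)
            & (row.position <= sub["end"] + window_aa)
        ).any():
            hit += 1
    return hit / len(sites) if len(sites) else float("nan")


def mutation_null(
    markers: pd.DataFrame,
    protein_lengths: Mapping[str, int],
    n_sites: int,
    observed_overlap: float,
    n_draws: int = 10,
    window_aa: int = 0,
    seed: int = 0,
) -> dict:
    """Resampling null for the mutation-site overlap.

    Each draw places ``n_sites`` sites uniformly at random over the pooled
    residues of the protein set (proteins weighted by length) and records the
    marker-overlap fraction.  The empirical p is the fraction of draws with
    overlap at least the observed one; with the default ten draws its floor
    is 1/11, so a normal-approximation p over the null draws is also
    reported for users who need resolution beyond the draw count.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    proteins = sorted(protein_lengths)
    # residue-level coverage mask over the pooled protein set, so each draw is
    # a cheap index lookup rather than an interval scan
    covered_chunks = []
    by_protein = dict(tuple(markers.groupby("protein_id", sort=False)))
    for p in proteins:
        length = protein_lengths[p]
        mask = np.zeros(length, bool)
        sub = by_protein.get(p)
        if sub is not None:
            for s, e in sub[["start", "end"]].itertuples(index=False, name=None):
                lo = max(s - window_aa, 1) - 1
                hi = min(e + window_aa, length)
                mask[lo:hi] = True
        covered_chunks.append(mask)
    covered = np.concatenate(covered_chunks)
    idx = rng.integers(len(covered), size=(n_draws, n_sites))
    overlaps = covered[idx].mean(axis=1)
    p_empirical = float((overlaps >= observed_overlap).mean())
    mean = float(overlaps.mean())
    sd = float(overlaps.std(ddof=1)) if n_draws > 1 else 0.0
    if n_draws > 1 and sd > 0:
        p_normal = float(stats.norm.sf((observed_overlap - mean) / sd))
    else:
        p_normal = float("nan")
    return {
        "null_overlaps": overlaps,
        "mean_null_overlap": mean,
        "p_empirical": p_empirical,
        "p_normal": p_normal,
    }
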
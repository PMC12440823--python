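"""Intensity-table and proteome I/O, peptide annotation, and the detection filter.

Intensity data live in long-format :class:`pandas.DataFrame` objects with one
row per analyte x group x replicate x sample type -- the in-memory form of an
``IntensityRecord`` collection.  Canonical columns:

``analyte_id``
    Peptide sequence (LiP samples) or protein accession (tryptic controls).
``protein_id``
    Accession of the parent protein (equals ``analyte_id`` for controls).
``group``
    Fraction label (``100K``/``50K``/``30K``/``10K``) or condition label.
``replicate``
    Positive integer biological replicate.
``intensity``
    Positive MS peak area in arbitrary units.
``sample_type``
    ``lip`` or ``tryptic_control``.

Exported tables use these names under a configurable column *dialect* so that
long-format exports of DIA search engines (Spectronaut-like reports) can be
read without renaming files by hand.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

CANONICAL_COLUMNS = (
    "analyte_id",
    "protein_id",
    "group",
    "replicate",
    "intensity",
    "sample_type",
)

#: Values treated as missing intensities on read.
MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none", "filtered"}

SAMPLE_TYPES = ("lip", "tryptic_control")


class FormatError(ValueError):
    """An input table violates the declared format or an invariant."""


@dataclasses.dataclass(frozen=True)
class Dialect:
    """Column-name mapping from a concrete file to the canonical schema.

    The default dialect is the identity.  ``Dialect.spectronaut()`` mirrors a
    long-format Spectronaut report; arbitrary dialects can be declared in a
    JSON config ``{"analyte_id": "PEP.StrippedSequence", ...}``.
    """

    analyte_id: str = "analyte_id"
    protein_id: str = "protein_id"
    group: str = "group"
    replicate: str = "replicate"
    intensity: str = "intensity"
    sample_type: str = "sample_type"
    sep: str = "\t"

    @classmethod
    def spectronaut(cls) -> "Dialect":
        return cls(
            analyte_id="PEP.StrippedSequence",
            protein_id="PG.ProteinAccessions",
            group="R.Condition",
            replicate="R.Replicate",
            intensity="PEP.Quantity",
            sample_type="R.SampleType",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Dialect":
        with open(path) as fh:
            return cls(**json.load(fh))

    def column_map(self) -> dict[str, str]:
        """file column -> canonical column"""
        return {getattr(self, c): c for c in CANONICAL_COLUMNS}


def _parse_intensity(value, line_no: int) -> float | None:
    if value is None:
        return None
    text = str(value).strip()
    if text.lower() in MISSING_TOKENS:
        return None
    try:
        out = float(text)
    except ValueError as err:
        raise FormatError(
            f"non-numeric intensity {value!r} on line {line_no}"
        ) from err
    if out != out:  # NaN literal parsed by float()
        return None
    return out


def read_intensity_table(
    path: str | Path, dialect: Dialect | None = None
) -> pd.DataFrame:
    """Read a long-format intensity table into the canonical schema.

    Missing, zero or negative intensities are dropped (never imputed) and the
    number of dropped rows is recorded in ``df.attrs["n_skipped"]``.  A missing
    required column or a duplicated (analyte, group, replicate, sample_type)
    key raises :class:`FormatError`.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    missing = [
        src for src in dialect.column_map() if src not in raw.columns
    ]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    raw = raw.rename(columns=dialect.column_map())[list(CANONICAL_COLUMNS)]

    intensities = []
    keep = []
    # header is line 1, first data row line 2
    for line_no, value in zip(range(2, len(raw) + 2), raw["intensity"]):
        parsed = _parse_intensity(value, line_no)
        if parsed is None or parsed <= 0:
            keep.append(False)
        else:
            keep.append(True)
            intensities.append(parsed)
    n_skipped = int(len(keep) - sum(keep))
    df = raw.loc[keep].copy()
    df["intensity"] = intensities
    df["replicate"] = df["replicate"].astype(int)
    validate_intensity_table(df)
    df = df.reset_index(drop=True)
    df.attrs["n_skipped"] = n_skipped
    return df


def validate_intensity_table(df: pd.DataFrame) -> None:
    """Check the IntensityRecord invariants on a canonical table."""
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    bad_types = set(df["sample_type"]) - set(SAMPLE_TYPES)
    if bad_types:
        raise FormatError(f"unknown sample_type value(s): {sorted(bad_types)}")
    if len(df) and (df["intensity"] <= 0).any():
        raise FormatError("intensities must be positive")
    key = ["analyte_id", "group", "replicate", "sample_type"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].tolist()
        raise FormatError(
            f"duplicated (analyte_id, group, replicate, sample_type) key: {first}"
        )


def write_intensity_table(
    df: pd.DataFrame, path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write a canonical table under a dialect (inverse of the reader)."""
    dialect = dialect or Dialect()
    inverse = {v: k for k, v in dialect.column_map().items()}
    df[list(CANONICAL_COLUMNS)].rename(columns=inverse).to_csv(
        path, sep=dialect.sep, index=False
    )


# ---------------------------------------------------------------------------
# proteome + peptide annotation


def read_proteome(path: str | Path) -> dict[str, str]:
    """Read a FASTA proteome into {accession: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_proteome(proteome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteome.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _is_tryptic_terminus(protein: str, pos_before: int) -> bool:
    """True if a cleavage between pos_before and pos_before+1 (0-based) is
    trypsin-consistent, i.e. the preceding residue is K/R or a protein end."""
    if pos_before == 0 or pos_before == len(protein):
        return True
    return protein[pos_before - 1] in "KR"


def classify_tryptic(
    protein: str, start: int, end: int, no_cleave_before_proline: bool = False
) -> str:
    """Classify a peptide at 1-based inclusive [start, end] on ``protein``.

    ``fully_tryptic`` iff both termini conform to the cleavage rule: preceded
    by K/R (or protein N-terminus) and ending in K/R (or protein C-terminus).
    The optional proline refinement additionally rejects K/R-P junctions.
    """
    n_ok = _is_tryptic_terminus(protein, start - 1)
    c_ok = _is_tryptic_terminus(protein, end)
    if no_cleave_before_proline:
        if n_ok and 1 < start <= len(protein) and protein[start - 1] == "P":
            n_ok = False
        if c_ok and end < len(protein) and protein[end] == "P":
            c_ok = False
    return "fully_tryptic" if (n_ok and c_ok) else "semi_tryptic"


def annotate_peptides(
    peptides: Iterable[tuple[str, str]] | pd.DataFrame,
    proteome: Mapping[str, str],
    no_cleave_before_proline: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Locate peptides on their proteins and classify their termini.

    Parameters
    ----------
    peptides
        Iterable of (peptide sequence, protein accession) pairs, or a frame
        with ``analyte_id``/``protein_id`` columns.
    proteome
        {accession: sequence}.

    Returns
    -------
    annotations : DataFrame
        Columns peptide_id, protein_id, sequence, start, end (1-based
        inclusive), tryptic_type, ambiguous (True when the sequence occurs
        more than once in the protein; the first occurrence is used).
    unmapped : list of str
        Peptides absent from their stated protein (not fatal).
    """
    if isinstance(peptides, pd.DataFrame):
        pairs = list(
            peptides[["analyte_id", "protein_id"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
    else:
        pairs = list(peptides)

    rows = []
    unmapped: list[str] = []
    for seq, acc in pairs:
        protein = proteome.get(acc)
        if protein is None or seq not in protein:
            unmapped.append(seq)
            continue
        start = protein.index(seq) + 1
        end = start + len(seq) - 1
        rows.append(
            {
                "peptide_id": seq,
                "protein_id": acc,
                "sequence": seq,
                "start": start,
                "end": end,
                "tryptic_type": classify_tryptic(
                    protein, start, end, no_cleave_before_proline
                ),
                "ambiguous": protein.count(seq) > 1,
            }
        )
    columns = [
        "peptide_id",
        "protein_id",
        "sequence",
        "start",
        "end",
        "tryptic_type",
        "ambiguous",
    ]
    return pd.DataFrame(rows, columns=columns), unmapped


# ---------------------------------------------------------------------------
# detection filter


def detection_filter(
    records: pd.DataFrame,
    min_reps: int = 3,
    min_groups: int = 2,
) -> pd.DataFrame:
    """Apply the replicate/detection filter used before any differential test.

    An analyte is retained iff it was measured in at least ``min_reps``
    replicates in each of at least ``min_groups`` groups; a LiP peptide must
    additionally have its parent protein pass the same rule in the tryptic
    control.  Rows in groups where the analyte falls below the replicate floor
    are dropped as well, so every surviving (analyte, group) cell is testable.

    Retained/dropped analyte counts are stored in ``df.attrs`` under
    ``n_retained`` and ``n_dropped``.
    """
    if records.empty:
        out = records.copy()
        out.attrs.update(n_retained=0, n_dropped=0)
        return out

    counts = (
        records.groupby(["sample_type", "analyte_id", "group"], sort=False)[
            "replicate"
        ]
        .nunique()
        .reset_index(name="n_reps")
    )
    counts["cell_ok"] = counts["n_reps"] >= min_reps
    n_good_groups = counts.groupby(["sample_type", "analyte_id"], sort=False)[
        "cell_ok"
    ].sum()
    passing = set(n_good_groups[n_good_groups >= min_groups].index)

    ctrl_passing = {a for (st, a) in passing if st == "tryptic_control"}

    def analyte_ok(row_key) -> bool:
        st, analyte, protein = row_key
        if (st, analyte) not in passing:
            return False
        if st == "lip":
            return protein in ctrl_passing
        return True

    keys = records[["sample_type", "analyte_id", "protein_id"]].drop_duplicates()
    keep_analytes = {
        (st, a)
        for st, a, p in keys.itertuples(index=False, name=None)
        if analyte_ok((st, a, p))
    }

    good_cells = {
        (st, a, g)
        for st, a, g, ok in counts[
            ["sample_type", "analyte_id", "group", "cell_ok"]
        ].itertuples(index=False, name=None)
        if ok and (st, a) in keep_analytes
    }
    mask = [
        (st, a, g) in good_cells
        for st, a, g in records[["sample_type", "analyte_id", "group"]].itertuples(
            index=False, name=None
        )
    ]
    out = records.loc[mask].reset_index(drop=True)
    all_analytes = set(map(tuple, keys[["sample_type", "analyte_id"]].values))
    out.attrs.update(
        n_retained=len(keep_analytes), n_dropped=len(all_analytes - keep_analytes)
    )
    return out
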
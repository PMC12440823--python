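"""Differential AP-MS interaction analysis (bait-normalised ratio of ratios).

For each high-confidence prey the statistic compares, between two
treatments, the double ratio

    R_prey,treatment = [ mu(I_prey,FLAG) / mu(I_prey,non-FLAG) ]
                     / [ mu(I_bait,FLAG) / mu(I_bait,non-FLAG) ] ,

i.e. the prey's tag-specific enrichment normalised by the bait's, which
cancels sample-class scaling and bait-level pull-down efficiency.  Each
ratio's uncertainty is propagated from the four underlying relative errors
and the treatments are compared with

    t_prey = (R_HU - R_untreated) / sqrt( (sd_HU^2 + sd_untreated^2) / 3 ) ,

referred to a Student's t distribution with four degrees of freedom (the
form used in the original pipeline, kept as printed: fixed df, pooled /3
denominator).  p-values are two-sided; the fold change is
log2(R_HU / R_untreated).

Candidate interactors are pre-filtered on externally computed SAINT
probabilities and spectral counts; SAINT itself is an input, not part of
this package.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TAGS = ("FLAG", "non-FLAG")


def filter_interactors(
    saint: pd.DataFrame,
    prob_min: float = 1.0,
    min_reps: int = 4,
    min_mean_sc: float = 4.5,
) -> list[str]:
    """High-confidence prey set from a SAINT output table.

    ``saint`` has columns prey, probability, spectral_counts (';'-separated
    per-replicate counts).  A prey is kept iff probability >= ``prob_min``,
    it was detected (count > 0) in ``min_reps`` of ``min_reps`` pull-down
    replicates, and its mean spectral count is at least ``min_mean_sc``
    (all boundaries inclusive).
    """
    kept = []
    for row in saint.itertuples(index=False):
        counts = [float(x) for x in str(row.spectral_counts).split(";") if x != ""]
        if (
            row.probability >= prob_min
            and len(counts) >= min_reps
            and sum(c > 0 for c in counts) >= min_reps
            and np.mean(counts) >= min_mean_sc
        ):
            kept.append(row.prey)
    return kept


def total_area_normalize(data: pd.DataFrame) -> pd.DataFrame:
    """Joint total-area-sum normalisation: each sample (tag x treatment x
    replicate) is scaled so its intensity total equals the mean sample total."""
    out = data.copy()
    key = ["tag", "treatment", "replicate"]
    totals = out.groupby(key, sort=False)["intensity"].sum().rename("sample_total")
    out = out.merge(totals, on=key)
    out["intensity"] = out["intensity"] * totals.mean() / out["sample_total"]
    return out.drop(columns="sample_total")


class DifferentialInteraction:
    """Model of treatment-dependent bait-prey interaction changes.

    Parameters
    ----------
    data : DataFrame
        Long-format protein intensities with columns protein_id, tag
        ({"FLAG", "non-FLAG"}), treatment (two labels, e.g. "untreated" /
        "HU"), replicate, intensity (> 0).
    bait : str
        Accession of the bait protein; must be present in all four
        tag x treatment classes.
    normalize : bool
        Apply joint total-area-sum normalisation before fitting.
    min_reps : int
        Detection floor per prey and sample class (default triplicates).
    """

    #: degrees of freedom of the t reference distribution
    df = 4

    def __init__(
        self,
        data: pd.DataFrame,
        bait: str,
        treatments: Sequence[str] = ("untreated", "HU"),
        normalize: bool = True,
        min_reps: int = 3,
    ):
        if (data["intensity"] <= 0).any():
            raise ValueError("intensities must be positive")
        if len(treatments) != 2:
            raise ValueError("exactly two treatments are compared")
        self.data = total_area_normalize(data) if normalize else data.copy()
        self.bait = bait
        self.treatments = tuple(treatments)
        self.min_reps = min_reps
        for tag in TAGS:
            for trt in self.treatments:
                sub = self.data[
                    (self.data["protein_id"] == bait)
                    & (self.data["tag"] == tag)
                    & (self.data["treatment"] == trt)
                ]
                if sub.empty:
                    raise ValueError(f"bait {bait!r} missing in class ({tag}, {trt})")

    def _class_stats(self) -> pd.DataFrame:
        g = self.data.groupby(["protein_id", "tag", "treatment"], sort=False)["intensity"]
        return g.agg(n="size", mu="mean", sd=lambda x: x.std(ddof=1)).reset_index()

    def fit(self) -> "DifferentialInteractionResults":
        cs = self._class_stats()
        stats_map = {
            (r.protein_id, r.tag, r.treatment): r for r in cs.itertuples(index=False)
        }

        def ratio_and_sd(prey: str, trt: str):
            needed = [
                (prey, "FLAG", trt), (prey, "non-FLAG", trt),
                (self.bait, "FLAG", trt), (self.bait, "non-FLAG", trt),
            ]
            rs = [stats_map.get(k) for k in needed]
            if any(r is None for r in rs):
                return None
            pf, pn, bf, bn = rs
            R = (pf.mu / pn.mu) / (bf.mu / bn.mu)
            cv2 = sum((r.sd / r.mu) ** 2 for r in rs)
            return R, R * np.sqrt(cv2)

        rows, skipped = [], []
        trt1, trt2 = self.treatments  # (untreated, HU-like)
        for prey in cs["protein_id"].unique():
            reps_ok = all(
                stats_map.get((prey, tag, trt)) is not None
                and stats_map[(prey, tag, trt)].n >= self.min_reps
                for tag in TAGS
                for trt in self.treatments
            )
            if not reps_ok:
                skipped.append((prey, "below replicate floor in a sample class"))
                continue
            first = ratio_and_sd(prey, trt1)
            second = ratio_and_sd(prey, trt2)
            if first is None or second is None:
                skipped.append((prey, "missing sample class"))
                continue
            r1, sd1 = first
            r2, sd2 = second
            denom = np.sqrt((sd1**2 + sd2**2) / 3.0)
            t = (r2 - r1) / denom if denom > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(t), self.df) if denom > 0 else 1.0
            rows.append(
                {
                    "prey": prey,
                    f"R_{trt1}": r1,
                    f"R_{trt2}": r2,
                    f"sd_{trt1}": sd1,
                    f"sd_{trt2}": sd2,
                    "t": t,
                    "p": p,
                    "log2fc": float(np.log2(r2 / r1)),
                }
            )
        table = pd.DataFrame(rows).set_index("prey") if rows else pd.DataFrame()
        return DifferentialInteractionResults(
            model=self, table=table, skipped=skipped
        )


@dataclasses.dataclass
class DifferentialInteractionResults:
    """Per-prey double ratios, propagated errors and t tests."""

    model: DifferentialInteraction
    table: pd.DataFrame
    skipped: list[tuple[str, str]]

    @property
    def df(self) -> int:
        return self.model.df

    def significant(self, p_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] < p_threshold]

    def summary(self, p_threshold: float = 0.05) -> str:
        t1, t2 = self.model.treatments
        lines = [
            "Differential AP-MS interactions (bait-normalised ratio of ratios)",
            f"  bait:                 {self.model.bait}",
            f"  treatments:           {t1} vs {t2}",
            f"  preys tested:         {len(self.table)}",
            f"  preys skipped:        {len(self.skipped)}",
            f"  significant (p<{p_threshold:g}): "
            f"{int((self.table['p'] < p_threshold).sum()) if len(self.table) else 0}",
            f"  reference:            Student t, {self.df} degrees of freedom",
        ]
        return "\n".join(lines)
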
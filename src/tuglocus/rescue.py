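"""Reciprocal-rescue gene intersection and Fisher overlap testing.

A gene is "reciprocally regulated" when it is significantly dysregulated in
knockout vs wild type AND significantly changed in the opposite direction in
rescue vs knockout -- the expression signature of a trans effect of the
restored RNA.  The overlap of the two significant sets over the shared
tested-gene universe is summarized in a 2x2 table and scored with the
two-sided Fisher exact test (probability-mass rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact


@dataclass
class ReciprocalSet:
    """Per-gene reciprocal calls plus the 2x2 overlap table.

    ``overlap_table`` rows are KO-significance, columns rescue-significance:
    [[both, ko_only], [rescue_only, neither]]; entries sum to the shared
    unfiltered gene universe.
    """

    table: pd.DataFrame
    overlap_table: np.ndarray
    fdr: float

    @property
    def reciprocal_genes(self) -> list[str]:
        return list(self.table.index[self.table["reciprocal"]])


def reciprocal_genes(
    de_ko_wt: pd.DataFrame,
    de_rescue_ko: pd.DataFrame,
    fdr: float = 0.05,
) -> ReciprocalSet:
    """Intersect two DE results into reciprocal calls and a 2x2 overlap table.

    A gene is reciprocal iff its adjusted p-value is below ``fdr`` in BOTH
    comparisons and its log2FC signs are strictly opposite.  The overlap
    table counts significance in each comparison over the genes unfiltered
    in both.
    """
    if set(de_ko_wt.index) != set(de_rescue_ko.index):
        raise ValueError("gene universes differ between the two DE results")
    a = de_ko_wt
    b = de_rescue_ko.reindex(a.index)
    tested = (~a["filtered"]) & (~b["filtered"])
    sig_ko = (a["fdr_adjusted_p"] < fdr) & tested
    sig_rescue = (b["fdr_adjusted_p"] < fdr) & tested
    opposite = (a["log2fc"] * b["log2fc"]) < 0
    reciprocal = sig_ko & sig_rescue & opposite
    table = pd.DataFrame(
        {
            "log2fc_ko_wt": a["log2fc"],
            "log2fc_rescue_ko": b["log2fc"],
            "fdr_ko_wt": a["fdr_adjusted_p"],
            "fdr_rescue_ko": b["fdr_adjusted_p"],
            "both_significant": sig_ko & sig_rescue,
            "opposite_direction": opposite.fillna(False),
            "reciprocal": reciprocal,
        },
        index=a.index,
    )
    both = int((sig_ko & sig_rescue).sum())
    ko_only = int((sig_ko & ~sig_rescue).sum())
    rescue_only = int((~sig_ko & sig_rescue).sum())
    neither = int((tested & ~sig_ko & ~sig_rescue).sum())
    overlap = np.array([[both, ko_only], [rescue_only, neither]])
    return ReciprocalSet(table=table.loc[tested], overlap_table=overlap, fdr=fdr)


def overlap_fisher(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value is the exact hypergeometric two-sided probability (sum over
    tables with probability less than or equal to the observed one, fixed
    margins); the reported odds ratio is the sample odds ratio ad/bc
    (infinity when bc = 0).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative table entries")
    p = float(fisher_exact(t, alternative="two-sided")[1])
    a, b = t[0]
    c, d = t[1]
    odds = float(a * d) / (b * c) if b * c > 0 else float("inf")
    return p, odds
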
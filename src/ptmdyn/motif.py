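"""Differential flanking-sequence analysis of regulated vs unregulated sites.

For each site a -15..+15 window (31 residues, the modified residue at
position 0) is cut from the protein sequence, padding positions that fall
outside the sequence.  Per (position, residue) cell the residue frequency in
the regulated set is compared with the unregulated set by a two-proportion
z-test on pooled variance — the statistic behind iceLogo-style difference
logos — and cells with p <= alpha are flagged significant.  Padding cells
are excluded from all denominators.  No multiple-testing correction is
applied by default (an optional Benjamini-Hochberg switch exists), and
position 0 is reported but flagged since its composition is constrained by
the modified residue itself.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

PAD = "-"
DEFAULT_HALFWIDTH = 15

#: residues a PTM type can chemically occupy; used for validation warnings
EXPECTED_RESIDUES = {"phospho": set("STY"), "acetyl": {"K"}, "ubiquityl": {"K"}}


@dataclass
class MotifResult:
    position: int  # offset in [-halfwidth, +halfwidth], 0 = modified residue
    residue: str
    freq_regulated: float  # fraction over non-padding cells
    freq_unregulated: float
    delta_pct: float  # percentage points, regulated - unregulated
    p_value: float
    significant: bool
    center_flag: bool = False  # position 0: composition fixed by the PTM


def extract_flank(
    sequence: str, position: int, halfwidth: int = DEFAULT_HALFWIDTH
) -> str:
    """Cut the window of ``2*halfwidth + 1`` residues centered on a 1-based
    site position, padding out-of-sequence cells with ``-``."""
    if not (1 <= position <= len(sequence)):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    start = position - 1 - halfwidth
    end = position - 1 + halfwidth + 1
    left_pad = max(0, -start)
    right_pad = max(0, end - len(sequence))
    return (
        PAD * left_pad
        + sequence[max(0, start) : min(len(sequence), end)]
        + PAD * right_pad
    )


def count_center_mismatches(
    windows: list[str], residues: list[str]
) -> int:
    """Validation: windows whose center letter disagrees with the recorded
    site residue (counted, not dropped)."""
    h = (len(windows[0]) - 1) // 2 if windows else 0
    return sum(1 for w, r in zip(windows, residues) if w[h] != r)


def _two_proportion_p(c1: int, n1: int, c2: int, n2: int) -> float:
    if n1 == 0 or n2 == 0:
        return 1.0
    if c1 + c2 == 0 or c1 + c2 == n1 + n2:
        return 1.0  # pooled variance is zero; no evidence of a difference
    _, p = proportions_ztest([c1, c2], [n1, n2], alternative="two-sided")
    return float(p)


def differential_frequency(
    regulated: list[str],
    unregulated: list[str],
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[MotifResult]:
    """Per-cell differential residue frequencies between two window sets.

    Frequencies are computed over non-padding cells at each offset; a
    position with zero non-padding cells in either set yields no results
    there.  With ``fdr=True`` significance is called on Benjamini-Hochberg
    adjusted p-values instead of raw ones.
    """
    if not regulated or not unregulated:
        raise ValueError("both window sets must be non-empty")
    width = len(regulated[0])
    if any(len(w) != width for w in regulated + unregulated):
        raise ValueError("all windows must have equal width")
    halfwidth = (width - 1) // 2

    results: list[MotifResult] = []
    for col in range(width):
        reg_letters = [w[col] for w in regulated if w[col] != PAD]
        unreg_letters = [w[col] for w in unregulated if w[col] != PAD]
        n1, n2 = len(reg_letters), len(unreg_letters)
        if n1 == 0 or n2 == 0:
            continue
        reg_counts = Counter(reg_letters)
        unreg_counts = Counter(unreg_letters)
        for residue in sorted(set(reg_counts) | set(unreg_counts)):
            c1, c2 = reg_counts[residue], unreg_counts[residue]
            f1, f2 = c1 / n1, c2 / n2
            results.append(
                MotifResult(
                    position=col - halfwidth,
                    residue=residue,
                    freq_regulated=f1,
                    freq_unregulated=f2,
                    delta_pct=(f1 - f2) * 100.0,
                    p_value=_two_proportion_p(c1, n1, c2, n2),
                    significant=False,
                    center_flag=(col == halfwidth),
                )
            )
    pvals = np.array([r.p_value for r in results])
    if fdr and len(pvals):
        _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, adjusted):
            r.significant = bool(q <= alpha)
    else:
        for r in results:
            r.significant = bool(r.p_value <= alpha)
    return results


def delta_matrix(results: list[MotifResult], significant_only: bool = False):
    """Pivot results into a residue x position matrix of delta_pct values,
    suitable for text export or heatmap plotting."""
    import pandas as pd

    rows = [
        (r.residue, r.position, r.delta_pct)
        for r in results
        if r.significant or not significant_only
    ]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["residue", "position", "delta_pct"])
    return df.pivot_table(
        index="residue", columns="position", values="delta_pct", fill_value=0.0
    )
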
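"""Site filtering, replicate aggregation, regulation calls and replicate QC.

A site is *regulated* when its replicate-mean log2 SILAC ratio shows at least
a 2-fold change (|mean log2| >= 1, inclusive) at either 0.5 h (M/L) or 2 h
(H/L) after stimulation.  A protein is regulated when at least one of its PTM
sites is.  The mean is taken over log2 ratios, not raw ratios; time points
quantified in fewer than ``min_replicates`` replicates are treated as
unquantified for that site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_tables import SiteQuantRecord

DEFAULT_MIN_LOC_PROB = 0.9
DEFAULT_FOLD = 2.0
DEFAULT_MIN_REPLICATES = 2


@dataclass
class TemporalProfile:
    """Replicate-averaged log2 ratios of one site at 0.5 h and 2 h.

    ``mean_log2_05h`` / ``mean_log2_2h`` are ``None`` where the time point is
    unquantified (fewer than ``min_replicates`` replicate values).
    """

    accession: str
    position: int
    ptm_type: str
    condition: str
    residue: str = ""
    mean_log2_05h: float | None = None
    mean_log2_2h: float | None = None
    n_05h: int = 0
    n_2h: int = 0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.accession, self.position, self.ptm_type, self.condition)

    @property
    def quantified_both(self) -> bool:
        return self.mean_log2_05h is not None and self.mean_log2_2h is not None


def filter_sites(
    records: Iterable[SiteQuantRecord], min_loc_prob: float = DEFAULT_MIN_LOC_PROB
) -> list[SiteQuantRecord]:
    """Drop rows with localization probability strictly below ``min_loc_prob``.

    Protein-level (wcp) rows have no localization and always pass; PTM rows
    with an absent loc_prob are treated as unlocalized and removed.
    """
    kept = []
    for r in records:
        if r.ptm_type == "wcp":
            kept.append(r)
        elif r.loc_prob is not None and r.loc_prob >= min_loc_prob:
            kept.append(r)
    return kept


def _mean_present(values: Sequence[float | None]) -> tuple[float | None, int]:
    present = [v for v in values if v is not None and not math.isnan(v)]
    if not present:
        return None, 0
    return float(np.mean(present)), len(present)


def aggregate_replicates(
    records: Iterable[SiteQuantRecord], min_replicates: int = DEFAULT_MIN_REPLICATES
) -> list[TemporalProfile]:
    """Collapse per-replicate records into one temporal profile per site key.

    Multiple records with the same key (e.g. re-measurements) contribute all
    their replicate values.  A time point with fewer than ``min_replicates``
    values is marked unquantified (mean ``None``), never zero-filled.
    """
    grouped: dict[tuple, list[SiteQuantRecord]] = {}
    order: list[tuple] = []
    for r in records:
        if r.key not in grouped:
            grouped[r.key] = []
            order.append(r.key)
        grouped[r.key].append(r)
    profiles = []
    for key in order:
        recs = grouped[key]
        ml: list[float | None] = []
        hl: list[float | None] = []
        for r in recs:
            ml.extend(r.log2_ml)
            hl.extend(r.log2_hl)
        mean_ml, n_ml = _mean_present(ml)
        mean_hl, n_hl = _mean_present(hl)
        if n_ml < min_replicates:
            mean_ml = None
        if n_hl < min_replicates:
            mean_hl = None
        profiles.append(
            TemporalProfile(
                accession=key[0],
                position=key[1],
                ptm_type=key[2],
                condition=key[3],
                residue=recs[0].residue,
                mean_log2_05h=mean_ml,
                mean_log2_2h=mean_hl,
                n_05h=n_ml,
                n_2h=n_hl,
            )
        )
    return profiles


@dataclass(frozen=True)
class RegulationCall:
    regulated_05h: bool
    regulated_2h: bool

    @property
    def regulated_any(self) -> bool:
        return self.regulated_05h or self.regulated_2h


def call_regulated(profile: TemporalProfile, fold: float = DEFAULT_FOLD) -> RegulationCall:
    """Call a site regulated at each quantified time point.

    Regulated at a time point iff |mean log2 ratio| >= log2(fold); the
    threshold is inclusive ("at least a 2-fold change").  Unquantified time
    points are never regulated.
    """
    if fold <= 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    thr = math.log2(fold)
    r05 = profile.mean_log2_05h is not None and abs(profile.mean_log2_05h) >= thr
    r2 = profile.mean_log2_2h is not None and abs(profile.mean_log2_2h) >= thr
    return RegulationCall(r05, r2)


def call_regulated_protein(
    profiles: Iterable[TemporalProfile], fold: float = DEFAULT_FOLD
) -> bool:
    """A protein is regulated iff >= 1 of its PTM-site profiles is regulated.

    Protein-level (wcp) profiles are excluded; a protein with no PTM sites is
    unregulated.
    """
    return any(
        call_regulated(p, fold).regulated_any
        for p in profiles
        if p.ptm_type != "wcp"
    )


def replicate_correlation(
    records: Iterable[SiteQuantRecord],
    channel: str = "ml",
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson correlation between replicates of one ratio channel.

    Builds a sites x replicates matrix from the records of one experiment and
    correlates replicate columns over pairwise-complete observations.  Pairs
    sharing fewer than ``min_shared`` quantified sites are NaN.  The result is
    symmetric with a unit diagonal.
    """
    if channel not in ("ml", "hl"):
        raise ValueError("channel must be 'ml' or 'hl'")
    rows = {}
    for r in records:
        values = r.log2_ml if channel == "ml" else r.log2_hl
        rows[r.key] = [np.nan if v is None else v for v in values]
    if not rows:
        return pd.DataFrame()
    n_rep = max(len(v) for v in rows.values())
    mat = pd.DataFrame(
        [v + [np.nan] * (n_rep - len(v)) for v in rows.values()],
        columns=[f"rep{i + 1}" for i in range(n_rep)],
    )
    corr = mat.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr
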
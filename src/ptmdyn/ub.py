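"""Ubiquitination-specific analyses.

Three pieces: (1) ubiquitin chain-linkage abundance from diGly (K-epsilon-GG)
sites mapped onto the 76-residue ubiquitin moiety of polyubiquitin
precursors; (2) flagging sites dramatically affected by the proteasome
inhibitor MG132; (3) calling each ubiquitination site degradative or
non-degradative by comparing the MG132-arm ubiquitinome change with the
untreated whole-cell-proteome change of the host protein — degradative
ubiquitination drives turnover, so its ubiquitin signal moves inversely to
the protein level, while signaling-type (non-degradative) ubiquitination
moves with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_tables import SiteQuantRecord

#: ubiquitin lysines that can carry a polyubiquitin chain
CANONICAL_LINKAGES = (6, 11, 27, 29, 33, 48, 63)
LINKAGE_NAMES = tuple(f"K{k}" for k in CANONICAL_LINKAGES)

UBIQUITIN_MOIETY_LENGTH = 76


@dataclass
class LinkageAbundance:
    """Relative intensity of the seven chain-forming ubiquitin lysines."""

    fractions: dict[str, float]
    total_intensity: float
    other_intensity: float = 0.0
    n_other_sites: int = 0  # GG sites mapping off the canonical lysines


@dataclass
class UbOutcome:
    key: tuple
    verdict: str  # degradative | non_degradative | unclassified
    mg132_affected: bool = False
    ub_log2_mg132: float | None = None
    wcp_log2_untreated: float | None = None
    missing_wcp: bool = False


def map_to_moiety(position: int, moiety_length: int = UBIQUITIN_MOIETY_LENGTH) -> int:
    """Map a polyubiquitin-precursor position into the repeated 76-residue
    ubiquitin moiety: ((position - 1) mod 76) + 1."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    return (position - 1) % moiety_length + 1


def chain_linkage_abundance(
    records: Iterable[SiteQuantRecord],
    ubiquitin_accessions: Sequence[str],
    fusion_accessions: Sequence[str] = (),
    moiety_length: int = UBIQUITIN_MOIETY_LENGTH,
) -> LinkageAbundance:
    """Intensity-weighted linkage-site abundance over K6..K63.

    GG-site records on polyubiquitin precursors have their positions folded
    into the ubiquitin moiety by the modulo-76 map; on ribosomal-fusion
    precursors (``fusion_accessions``) only positions inside the single
    N-terminal moiety are mapped and later positions are ignored.  Intensity
    landing on a non-canonical moiety position goes to an ``other`` bucket
    (reported, not silently dropped).  Fractions are normalized over the
    seven canonical lysines.
    """
    ub_set = set(ubiquitin_accessions)
    fusion = set(fusion_accessions)
    sums = {name: 0.0 for name in LINKAGE_NAMES}
    other = 0.0
    n_other = 0
    for r in records:
        if r.accession not in ub_set or r.ptm_type != "ubiquityl":
            continue
        if r.accession in fusion and r.position > moiety_length:
            continue
        pos = map_to_moiety(r.position, moiety_length)
        if pos in CANONICAL_LINKAGES:
            sums[f"K{pos}"] += r.intensity
        else:
            other += r.intensity
            n_other += 1
    total = sum(sums.values())
    fractions = {
        name: (sums[name] / total if total > 0 else 0.0) for name in LINKAGE_NAMES
    }
    return LinkageAbundance(
        fractions=fractions,
        total_intensity=total,
        other_intensity=other,
        n_other_sites=n_other,
    )


def flag_mg132_effect(
    log2_ml_untreated: float | None,
    log2_ml_mg132: float | None,
    threshold: float = 1.0,
    two_sided: bool = False,
) -> bool:
    """A site is dramatically affected by MG132 iff its log2(M/L) is >=
    ``threshold`` in both the untreated and MG132 runs (one-sided, as the
    published rule); ``two_sided=True`` instead requires |log2(M/L)| >=
    threshold in both runs."""
    if log2_ml_untreated is None or log2_ml_mg132 is None:
        return False
    if two_sided:
        return abs(log2_ml_untreated) >= threshold and abs(log2_ml_mg132) >= threshold
    return log2_ml_untreated >= threshold and log2_ml_mg132 >= threshold


def classify_ub_outcome(
    ub_log2_mg132: float | None,
    wcp_log2_untreated: float | None,
    threshold: float = 1.0,
) -> str:
    """Degradative vs non-degradative call for one ubiquitination site.

    Requires a substantial ubiquitinome change under MG132
    (|ub_log2_mg132| >= threshold), else ``unclassified``.  The site is
    ``non_degradative`` when the untreated protein level shows the *same*
    change (same sign, also beyond the threshold); otherwise ``degradative``
    — including the stable-protein case, where ubiquitin accumulating under
    proteasome blockade with no matching protein rise indicates turnover.
    """
    if ub_log2_mg132 is None or wcp_log2_untreated is None:
        return "unclassified"
    if abs(ub_log2_mg132) < threshold:
        return "unclassified"
    same_sign = (ub_log2_mg132 > 0) == (wcp_log2_untreated > 0)
    if same_sign and abs(wcp_log2_untreated) >= threshold:
        return "non_degradative"
    return "degradative"


def call_ub_outcomes(
    ub_mg132_log2: Mapping[tuple, float | None],
    ub_untreated_log2: Mapping[tuple, float | None],
    wcp_untreated_log2: Mapping[str, float | None],
    threshold: float = 1.0,
) -> list[UbOutcome]:
    """Classify every MG132-arm ubiquitination site.

    Maps are keyed by site key (accession, position, ptm_type, condition)
    for the ubiquitinome and by accession for the whole-cell proteome;
    values are the chosen channel's replicate-mean log2 ratios.  A site
    whose protein lacks a WCP ratio is unclassified with ``missing_wcp``.
    """
    outcomes = []
    for key, ub_val in ub_mg132_log2.items():
        accession = key[0]
        wcp_val = wcp_untreated_log2.get(accession)
        untreated_key = (key[0], key[1], key[2], "untreated")
        out = UbOutcome(
            key=key,
            verdict=classify_ub_outcome(ub_val, wcp_val, threshold),
            mg132_affected=flag_mg132_effect(
                ub_untreated_log2.get(untreated_key), ub_val, threshold
            ),
            ub_log2_mg132=ub_val,
            wcp_log2_untreated=wcp_val,
            missing_wcp=wcp_val is None,
        )
        outcomes.append(out)
    return outcomes
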
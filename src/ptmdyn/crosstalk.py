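"""Protein-level crosstalk statistics.

Multi-regulated proteins are *synchronous* (Syn) when all their regulated
PTM sites share one speed group (all fast or all slow) and *heterochronous*
(Hetero) when speeds mix.  Within-protein crosstalk is probed by sequence
distances between site pairs; across-protein crosstalk by interaction degree
in a confidence-filtered edge list; and fast/slow co-occurrence across PTM
types by a protein-count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_tables import InteractionEdge
from .temporal import SiteClassification, UNREGULATED

GROUPS = ("unregulated", "single", "syn", "hetero")

#: matrix axes for fast/slow co-occurrence; wcp is a pseudo-type carrying
#: protein-level regulation speed
COOC_TYPES = ("acetyl", "phospho", "ubiquityl", "wcp")


@dataclass
class ProteinCrosstalkSummary:
    accession: str
    group: str
    multi_type: bool = False
    n_sites_total: int = 0
    n_sites_regulated: int = 0
    interaction_degree: int = 0
    mean_distance_all: float | None = None
    mean_distance_syn: float | None = None
    mean_distance_hetero: float | None = None
    fast_types: set = field(default_factory=set)
    slow_types: set = field(default_factory=set)


def classify_protein_group(classifications: Sequence[SiteClassification]) -> str:
    """Syn/Hetero grouping from the speed axis of a protein's regulated sites:
    0 regulated -> unregulated, 1 -> single, >= 2 all one speed -> syn,
    >= 2 mixed speeds -> hetero."""
    speeds = [cl.speed for cl in classifications if cl.speed != "none"]
    if not speeds:
        return "unregulated"
    if len(speeds) == 1:
        return "single"
    return "syn" if len(set(speeds)) == 1 else "hetero"


def pairwise_distances(
    sites: Sequence[tuple[int, str]], pair_set: str
) -> list[int]:
    """Sequence distances |pos_i - pos_j| over a chosen pair set.

    ``sites`` are (position, speed) tuples; ``pair_set`` selects
    ``all_regulated`` (every pair), ``syn_pairs`` (same-speed pairs) or
    ``hetero_pairs`` (different-speed pairs).  Fewer than two eligible sites
    yield an empty list.
    """
    if pair_set not in ("all_regulated", "syn_pairs", "hetero_pairs"):
        raise ValueError(f"unknown pair_set {pair_set!r}")
    out = []
    for (pos_i, sp_i), (pos_j, sp_j) in combinations(sites, 2):
        same = sp_i == sp_j
        if pair_set == "syn_pairs" and not same:
            continue
        if pair_set == "hetero_pairs" and same:
            continue
        out.append(abs(pos_i - pos_j))
    return out


def interaction_degree(
    accessions: Iterable[str], edges: Iterable[InteractionEdge]
) -> dict[str, int]:
    """Distinct-partner count per protein in a de-duplicated edge list;
    proteins absent from the list get 0."""
    partners: dict[str, set[str]] = {}
    for e in edges:
        partners.setdefault(e.protein_a, set()).add(e.protein_b)
        partners.setdefault(e.protein_b, set()).add(e.protein_a)
    return {acc: len(partners.get(acc, ())) for acc in accessions}


def summarize_protein(
    accession: str,
    classifications: Sequence[SiteClassification],
    quantified_positions: Sequence[int] | None = None,
    degree: int = 0,
) -> ProteinCrosstalkSummary:
    """Build the per-protein crosstalk summary from its site classifications.

    Distance statistics follow the protein's group: syn proteins take all
    regulated pairs; hetero proteins take same-speed (``Hetero-s``) and
    cross-speed (``Hetero-h``) pairs separately; unregulated proteins use all
    quantified-site pairs (``quantified_positions``).
    """
    group = classify_protein_group(classifications)
    regulated = [cl for cl in classifications if cl.speed != "none"]
    reg_sites = [(cl.key[1], cl.speed) for cl in regulated]
    summary = ProteinCrosstalkSummary(
        accession=accession,
        group=group,
        multi_type=len({cl.key[2] for cl in regulated}) >= 2,
        n_sites_total=len(classifications),
        n_sites_regulated=len(regulated),
        interaction_degree=degree,
        fast_types={cl.key[2] for cl in regulated if cl.speed == "fast"},
        slow_types={cl.key[2] for cl in regulated if cl.speed == "slow"},
    )

    def _mean(values: list[int]) -> float | None:
        return sum(values) / len(values) if values else None

    if group == "syn":
        summary.mean_distance_all = _mean(pairwise_distances(reg_sites, "all_regulated"))
    elif group == "hetero":
        summary.mean_distance_syn = _mean(pairwise_distances(reg_sites, "syn_pairs"))
        summary.mean_distance_hetero = _mean(
            pairwise_distances(reg_sites, "hetero_pairs")
        )
    elif group == "unregulated" and quantified_positions:
        all_sites = [(p, "q") for p in quantified_positions]
        summary.mean_distance_all = _mean(pairwise_distances(all_sites, "all_regulated"))
    return summary


def cooccurrence_matrix(
    summaries: Iterable[ProteinCrosstalkSummary],
    wcp_speed: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Protein counts of fast-type X with slow-type Y co-occurrence.

    Cell (X, Y) counts proteins carrying >= 1 fast-class site of PTM type X
    and >= 1 slow-class site of PTM type Y.  ``wcp_speed`` (accession ->
    ``fast``/``slow``) feeds the wcp pseudo-type from protein-level
    regulation.
    """
    wcp_speed = wcp_speed or {}
    mat = pd.DataFrame(0, index=list(COOC_TYPES), columns=list(COOC_TYPES))
    mat.index.name = "fast_type"
    mat.columns.name = "slow_type"
    for s in summaries:
        fast = set(s.fast_types)
        slow = set(s.slow_types)
        wcp = wcp_speed.get(s.accession)
        if wcp == "fast":
            fast.add("wcp")
        elif wcp == "slow":
            slow.add("wcp")
        for x in fast & set(COOC_TYPES):
            for y in slow & set(COOC_TYPES):
                mat.loc[x, y] += 1
    return mat


def distance_distributions(
    summaries: Iterable[ProteinCrosstalkSummary],
) -> dict[str, list[float]]:
    """Pool per-protein mean distances into the four plotted groups:
    unregulated, syn, hetero-s (same-speed pairs in hetero proteins) and
    hetero-h (cross-speed pairs)."""
    pools: dict[str, list[float]] = {
        "unregulated": [],
        "syn": [],
        "hetero-s": [],
        "hetero-h": [],
    }
    for s in summaries:
        if s.group == "unregulated" and s.mean_distance_all is not None:
            pools["unregulated"].append(s.mean_distance_all)
        elif s.group == "syn" and s.mean_distance_all is not None:
            pools["syn"].append(s.mean_distance_all)
        elif s.group == "hetero":
            if s.mean_distance_syn is not None:
                pools["hetero-s"].append(s.mean_distance_syn)
            if s.mean_distance_hetero is not None:
                pools["hetero-h"].append(s.mean_distance_hetero)
    return pools
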
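"""Six-class temporal classification of regulated PTM sites.

Two independent routes are provided and reconciled:

1. **Rule-based.**  A regulated site already changed at 0.5 h is *fast*,
   one changed only by 2 h is *slow*.  Fast sites split into *lasting*
   (change persists at 2 h with the same sign) and *transient* (it does
   not); every group splits into *up* and *down*, giving six classes:
   slow-up, slow-down, fast-lasting-up/down, fast-transient-up/down.

2. **Fuzzy c-means** (Bezdek alternating optimization, implemented here)
   on per-site standardized trajectory shapes, with sites assigned to
   their argmax cluster only when the membership exceeds 0.6 (strict),
   and clusters labeled by applying the rule classifier to the raw-space
   cluster centers.

Sites quantified at only one time point get a provisional rule label from
that point (with ``conflict_flag``) and are excluded from clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .site_processing import TemporalProfile, call_regulated, DEFAULT_FOLD

SIX_CLASSES = (
    "slow-up",
    "slow-down",
    "fast-lasting-up",
    "fast-lasting-down",
    "fast-transient-up",
    "fast-transient-down",
)
UNREGULATED = "unregulated"

DEFAULT_MEMBERSHIP = 0.6


@dataclass
class SiteClassification:
    """Temporal class of one site: rule-based label plus its decomposition
    into speed / persistence / direction, and the fuzzy-c-means assignment."""

    key: tuple
    speed: str  # fast | slow | none
    persistence: str  # lasting | transient | n/a
    direction: str  # up | down | n/a
    six_class_label: str
    conflict_flag: bool = False
    fcm_cluster: int | None = None
    fcm_membership: float = 0.0


def classify_rule_based(
    profile: TemporalProfile, fold: float = DEFAULT_FOLD
) -> SiteClassification:
    """Assign the six-class temporal label by the speed/persistence/direction
    rules.

    Sign-reversing fast sites (regulated at both points with opposite signs)
    are labeled fast-transient by their 0.5 h direction with ``conflict_flag``.
    Sites quantified at a single time point are labeled from that point alone
    (fast-transient-* from 0.5 h, slow-* from 2 h) with ``conflict_flag``.
    """
    call = call_regulated(profile, fold)
    m05, m2 = profile.mean_log2_05h, profile.mean_log2_2h

    if not call.regulated_any:
        return SiteClassification(
            key=profile.key,
            speed="none",
            persistence="n/a",
            direction="n/a",
            six_class_label=UNREGULATED,
            conflict_flag=not profile.quantified_both,
        )

    single_point = not profile.quantified_both
    if call.regulated_05h:
        direction = "up" if m05 > 0 else "down"
        if m2 is None:
            # persistence unverifiable with no 2 h measurement
            persistence = "transient"
            conflict = True
        elif call.regulated_2h and (m2 > 0) == (m05 > 0):
            persistence = "lasting"
            conflict = False
        elif call.regulated_2h:
            # sign reversal at 2 h: labeled by 0.5 h direction
            persistence = "transient"
            conflict = True
        else:
            persistence = "transient"
            conflict = False
        label = f"fast-{persistence}-{direction}"
        return SiteClassification(
            key=profile.key,
            speed="fast",
            persistence=persistence,
            direction=direction,
            six_class_label=label,
            conflict_flag=conflict or single_point,
        )

    # regulated only at 2 h
    direction = "up" if m2 > 0 else "down"
    return SiteClassification(
        key=profile.key,
        speed="slow",
        persistence="n/a",
        direction=direction,
        six_class_label=f"slow-{direction}",
        conflict_flag=single_point,
    )


# ---------------------------------------------------------------------------
# Fuzzy c-means


@dataclass
class FcmModel:
    """Fitted fuzzy c-means model over standardized trajectory vectors."""

    c: int
    m: float
    centers: np.ndarray  # (c, d)
    memberships: np.ndarray  # (n, c), rows sum to 1
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def standardize_profiles(profiles: list[TemporalProfile]) -> np.ndarray:
    """Map each profile to the trajectory (0, mean_05h, mean_2h) standardized
    per site across its three time points (zero mean, unit sd).

    This clusters trajectory *shape* rather than magnitude.  A flat
    trajectory (sd 0) maps to the zero vector.
    """
    out = np.zeros((len(profiles), 3))
    for i, p in enumerate(profiles):
        if not p.quantified_both:
            raise ValueError(f"profile {p.key} not quantified at both time points")
        v = np.array([0.0, p.mean_log2_05h, p.mean_log2_2h])
        sd = v.std()
        out[i] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def _kmeanspp_init(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: spread initial centers by squared distance."""
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(
            [np.sum((x - ctr) ** 2, axis=1) for ctr in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _memberships_from_centers(
    x: np.ndarray, centers: np.ndarray, m: float
) -> np.ndarray:
    # u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1)); points on a center get u=1 there
    d2 = np.maximum(
        ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), 0.0
    )
    exact = d2 < 1e-300
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    u = np.where(np.isfinite(inv), inv, 0.0)
    row_exact = exact.any(axis=1)
    u[row_exact] = exact[row_exact].astype(float)
    u /= u.sum(axis=1, keepdims=True)
    return u


def fit_fcm(
    x: np.ndarray,
    c: int = 6,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> FcmModel:
    """Fit fuzzy c-means by alternating membership/center updates.

    Converges when the max center shift falls below ``tol`` or after
    ``max_iter`` iterations; deterministic given ``seed``.  Requires at
    least ``c`` distinct points.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be a 2-D array of profiles")
    if np.unique(x, axis=0).shape[0] < c:
        raise ValueError(
            f"need at least {c} distinct profiles, got {np.unique(x, axis=0).shape[0]}"
        )
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(x, c, rng)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = _memberships_from_centers(x, centers, m)
        um = u**m
        new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - new_centers[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((um * d2).sum()))
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break
    memberships = _memberships_from_centers(x, centers, m)
    return FcmModel(
        c=c,
        m=m,
        centers=centers,
        memberships=memberships,
        objective_trace=trace,
        n_iter=it,
        converged=converged,
    )


def assign_fcm(
    model: FcmModel, threshold: float = DEFAULT_MEMBERSHIP
) -> list[int | None]:
    """Assign each site to its argmax cluster iff the membership is strictly
    greater than ``threshold``; otherwise unassigned (``None``)."""
    out: list[int | None] = []
    for row in model.memberships:
        k = int(np.argmax(row))
        out.append(k if row[k] > threshold else None)
    return out


def raw_space_centers(
    model: FcmModel, profiles: list[TemporalProfile]
) -> np.ndarray:
    """Cluster centers pulled back into raw log2-ratio space: the
    membership^m-weighted mean of the member profiles' (0.5 h, 2 h) means."""
    raw = np.array([[p.mean_log2_05h, p.mean_log2_2h] for p in profiles])
    um = model.memberships**model.m
    return (um.T @ raw) / um.sum(axis=0)[:, None]


def label_clusters(
    model: FcmModel,
    profiles: list[TemporalProfile],
    fold: float = DEFAULT_FOLD,
) -> dict[int, str]:
    """Label each cluster by rule-classifying its raw-space center.

    Labels need not be unique across clusters; a center whose trajectory is
    unregulated under the fold rule is labeled ``unregulated`` (flagged by
    the caller as an unlabeled cluster).
    """
    centers = raw_space_centers(model, profiles)
    labels = {}
    for k, (m05, m2) in enumerate(centers):
        center_profile = TemporalProfile(
            accession="<center>",
            position=0,
            ptm_type="wcp",
            condition="untreated",
            mean_log2_05h=float(m05),
            mean_log2_2h=float(m2),
            n_05h=1,
            n_2h=1,
        )
        labels[k] = classify_rule_based(center_profile, fold).six_class_label
    return labels


def classify_sites(
    profiles: list[TemporalProfile],
    fold: float = DEFAULT_FOLD,
    membership_threshold: float = DEFAULT_MEMBERSHIP,
    c: int = 6,
    seed: int = 0,
) -> list[SiteClassification]:
    """Run both classification routes over a set of profiles and reconcile.

    Every profile gets a rule-based label.  Regulated profiles quantified at
    both time points additionally enter fuzzy c-means; their cluster index
    and max membership are recorded when assigned.  Returns classifications
    in input order.
    """
    classifications = [classify_rule_based(p, fold) for p in profiles]
    eligible = [
        i
        for i, (p, cl) in enumerate(zip(profiles, classifications))
        if cl.six_class_label != UNREGULATED and p.quantified_both
    ]
    sub = [profiles[i] for i in eligible]
    if len(eligible) >= c:
        x = standardize_profiles(sub)
        if np.unique(x, axis=0).shape[0] >= c:
            model = fit_fcm(x, c=c, seed=seed)
            assignments = assign_fcm(model, membership_threshold)
            for j, i in enumerate(eligible):
                classifications[i].fcm_membership = float(
                    model.memberships[j].max()
                )
                classifications[i].fcm_cluster = assignments[j]
    return classifications


def fcm_rule_agreement(
    classifications: list[SiteClassification],
    cluster_labels: dict[int, str],
) -> float:
    """Fraction of FCM-assigned sites whose cluster label matches their
    rule-based label.  NaN if nothing is assigned."""
    assigned = [
        cl
        for cl in classifications
        if cl.fcm_cluster is not None and cl.six_class_label != UNREGULATED
    ]
    if not assigned:
        return math.nan
    hits = sum(
        1 for cl in assigned if cluster_labels.get(cl.fcm_cluster) == cl.six_class_label
    )
    return hits / len(assigned)
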
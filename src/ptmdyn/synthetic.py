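"""Synthetic SILAC PTM datasets with planted ground truth.

The generator emulates the structure of a two-time-point (0.5 h = M/L,
2 h = H/L), three-replicate SILAC experiment over three PTM proteomes
(acetylome, phosphoproteome, ubiquitinome) plus a whole-cell proteome, an
MG132 treatment arm, protein sequences, and a confidence-scored interaction
edge list.  Every downstream stage has recoverable planted truth:

* per-site temporal class — each regulated site follows one of the six
  class templates (effect size e on the log2 scale) plus i.i.d. Gaussian
  replicate noise;
* per-protein group — unregulated / single / syn (clustered same-speed
  sites, gaps ~ U[5, 30]) / hetero (cross-speed sites far apart, gaps
  ~ U[100, 300]);
* a flanking-sequence motif enriched around regulated sites of one PTM type;
* degradative vs non-degradative ubiquitination sites on dedicated proteins
  with consistent MG132-arm ubiquitinome and untreated WCP tables;
* a polyubiquitin precursor whose GG-site intensities follow configurable
  chain-linkage fractions;
* interaction edges denser around hetero proteins (degree ordering
  hetero > syn > single > unregulated in expectation).

Regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_tables import (
    SiteQuantRecord,
    write_site_table,
    write_fasta,
)
from .temporal import SIX_CLASSES, UNREGULATED

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: noiseless (0.5 h, 2 h) log2-ratio template of each temporal class,
#: as multiples of the planted effect size e
CLASS_TEMPLATES = {
    "slow-up": (0.0, 1.0),
    "slow-down": (0.0, -1.0),
    "fast-lasting-up": (1.0, 1.0),
    "fast-lasting-down": (-1.0, -1.0),
    "fast-transient-up": (1.0, 0.0),
    "fast-transient-down": (-1.0, 0.0),
    UNREGULATED: (0.0, 0.0),
}

#: 76-residue synthetic ubiquitin moiety: lysines at the seven canonical
#: chain positions, glycines at 75/76, alanine elsewhere (synthetic stand-in
#: for the real ubiquitin sequence; only the lysine positions matter here)
UBIQUITIN_MOIETY = "".join(
    "K" if i in (6, 11, 27, 29, 33, 48, 63) else ("G" if i >= 75 else "A")
    for i in range(1, 77)
)


@dataclass
class MotifSpec:
    """A planted flanking-residue enrichment around regulated sites."""

    ptm_type: str = "phospho"
    offset: int = 1  # relative to the modified residue
    residue: str = "P"
    enrichment: float = 0.4  # probability of the residue at that offset


@dataclass
class SyntheticConfig:
    n_proteins: int = 300
    seq_len_range: tuple = (200, 400)
    #: Poisson mean of unregulated background sites per protein per PTM type
    background_sites_per_type: float = 1.0
    #: protein-group mix; the regulated share echoes a mostly-unregulated
    #: proteome with single-regulated proteins dominating the regulated part
    group_fractions: dict = field(
        default_factory=lambda: {
            "unregulated": 0.674,
            "single": 0.193,
            "syn": 0.055,
            "hetero": 0.078,
        }
    )
    #: class mix for regulated sites (uniform over the six classes)
    class_fractions: dict = field(
        default_factory=lambda: {c: 1.0 / 6.0 for c in SIX_CLASSES}
    )
    effect_log2_range: tuple = (2.0, 2.0)
    noise_sd: float = 0.1
    n_replicates: int = 3
    missing_prob: float = 0.1
    #: fraction of PTM rows given a sub-threshold localization probability
    low_locprob_frac: float = 0.05
    syn_gap_range: tuple = (5, 30)
    hetero_gap_range: tuple = (100, 300)
    motif_spec: MotifSpec = field(default_factory=MotifSpec)
    #: WCP protein-level speed mix (pseudo-type for co-occurrence)
    wcp_speed_fractions: dict = field(
        default_factory=lambda: {"none": 0.7, "fast": 0.15, "slow": 0.15}
    )
    n_ub_outcome_sites: int = 60
    ub_fraction_degradative: float = 0.5
    linkage_fractions: dict = field(
        default_factory=lambda: {
            "K48": 0.6,
            "K63": 0.3,
            "K6": 0.02,
            "K11": 0.02,
            "K27": 0.02,
            "K29": 0.02,
            "K33": 0.02,
        }
    )
    ub_total_intensity: float = 1.0e6
    n_ub_repeats: int = 4  # polyubiquitin moiety repeats in the precursor
    degree_by_group: dict = field(
        default_factory=lambda: {
            "hetero": 8.0,
            "syn": 5.0,
            "single": 3.0,
            "unregulated": 1.0,
        }
    )
    n_decoy_edges: int = 100  # edges scored below the 0.8 cutoff
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if sum(self.group_fractions.values()) > 1 + 1e-9:
            raise ValueError("group fractions must sum to <= 1")
        if abs(sum(self.linkage_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("linkage fractions must sum to 1")
        if abs(self.motif_spec.offset) > 15:
            raise ValueError("motif offset beyond the +/-15 flanking window")
        if not (0 <= self.missing_prob < 1):
            raise ValueError("missing_prob must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted truth, exactly recoverable from the generator parameters."""

    site_class: dict = field(default_factory=dict)  # site key -> label
    protein_group: dict = field(default_factory=dict)  # accession -> group
    wcp_speed: dict = field(default_factory=dict)  # accession -> fast/slow/none
    ub_verdict: dict = field(default_factory=dict)  # mg132 site key -> verdict
    motif_spec: MotifSpec | None = None
    linkage_fractions: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class SyntheticDataset:
    """In-memory bundle of all generated inputs plus the ground truth."""

    site_records: dict  # ptm_type -> list[SiteQuantRecord] (all conditions)
    sequences: dict  # accession -> sequence
    edges_raw: list  # (protein_a, protein_b, score) rows, pre-filter
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Materialize the bundle in the dialects the readers consume,
        plus a key=value manifest of all generator parameters."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for ptm_type, records in self.site_records.items():
            p = outdir / f"sites_{ptm_type}.tsv"
            write_site_table(p, records)
            paths[ptm_type] = p
        write_fasta(outdir / "proteins.fasta", self.sequences)
        paths["fasta"] = outdir / "proteins.fasta"
        with open(outdir / "interactions.tsv", "w", encoding="utf-8") as fh:
            fh.write("protein_a\tprotein_b\tscore\n")
            for a, b, s in self.edges_raw:
                fh.write(f"{a}\t{b}\t{s!r}\n")
        paths["interactions"] = outdir / "interactions.tsv"
        with open(outdir / "manifest.txt", "w", encoding="utf-8") as fh:
            for k, v in asdict(self.config).items():
                fh.write(f"{k}={v}\n")
        paths["manifest"] = outdir / "manifest.txt"
        return paths


def _rule_label(t05: float, t2: float) -> str:
    """Noiseless rule label of a planted template (threshold |log2| >= 1)."""
    r05, r2 = abs(t05) >= 1, abs(t2) >= 1
    if r05:
        direction = "up" if t05 > 0 else "down"
        lasting = r2 and (t2 > 0) == (t05 > 0)
        return f"fast-{'lasting' if lasting else 'transient'}-{direction}"
    if r2:
        return f"slow-{'up' if t2 > 0 else 'down'}"
    return UNREGULATED


class _Generator:
    def __init__(self, config: SyntheticConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.truth = GroundTruth(
            motif_spec=config.motif_spec,
            linkage_fractions=dict(config.linkage_fractions),
            seed=config.seed,
        )
        self.sequences: dict[str, list[str]] = {}
        self.records: dict[str, list[SiteQuantRecord]] = {
            "acetyl": [],
            "phospho": [],
            "ubiquityl": [],
            "wcp": [],
        }
        self.edges_raw: list[tuple[str, str, float]] = []

    # -- low-level helpers --------------------------------------------------

    def _effect(self) -> float:
        lo, hi = self.cfg.effect_log2_range
        return float(self.rng.uniform(lo, hi))

    def _replicates(self, mean: float) -> list[float | None]:
        cfg = self.cfg
        values: list[float | None] = []
        for _ in range(cfg.n_replicates):
            if self.rng.random() < cfg.missing_prob:
                values.append(None)
            else:
                values.append(float(mean + self.rng.normal(0, cfg.noise_sd)))
        if all(v is None for v in values):
            # a record must carry at least one measurement
            values[int(self.rng.integers(cfg.n_replicates))] = float(
                mean + self.rng.normal(0, cfg.noise_sd)
            )
        return values

    def _loc_prob(self) -> float:
        if self.rng.random() < self.cfg.low_locprob_frac:
            return float(self.rng.uniform(0.5, 0.899))
        return float(self.rng.uniform(0.95, 1.0))

    def _residue_for(self, ptm_type: str) -> str:
        if ptm_type == "phospho":
            return str(self.rng.choice(list("STY")))
        return "K"

    def _make_site(
        self,
        accession: str,
        position: int,
        ptm_type: str,
        label: str,
        condition: str = "untreated",
        template: tuple[float, float] | None = None,
        intensity: float | None = None,
        loc_prob: float | None = None,
    ) -> SiteQuantRecord:
        if template is None:
            f05, f2 = CLASS_TEMPLATES[label]
            e = self._effect()
            template = (f05 * e, f2 * e)
        residue = self._residue_for(ptm_type)
        self.sequences[accession][position - 1] = residue
        rec = SiteQuantRecord(
            accession=accession,
            position=position,
            residue=residue,
            ptm_type=ptm_type,
            loc_prob=self._loc_prob() if loc_prob is None else loc_prob,
            log2_ml=self._replicates(template[0]),
            log2_hl=self._replicates(template[1]),
            intensity=float(self.rng.uniform(1e4, 1e7))
            if intensity is None
            else intensity,
            condition=condition,
            cell_line="SYN",
        )
        self.records[ptm_type].append(rec)
        if condition == "untreated":
            self.truth.site_class[rec.key] = _rule_label(*template)
        return rec

    def _new_protein(self, accession: str, length: int) -> None:
        seq = self.rng.choice(AA20, size=length)
        self.sequences[accession] = list(seq)

    def _free_positions(
        self, accession: str, used: set[int], n: int, margin: int = 17
    ) -> list[int]:
        length = len(self.sequences[accession])
        out = []
        for _ in range(n):
            for _attempt in range(200):
                pos = int(self.rng.integers(margin, length - margin + 1))
                if all(abs(pos - u) > 1 for u in used):
                    used.add(pos)
                    out.append(pos)
                    break
            else:
                raise RuntimeError(f"could not place {n} sites on {accession}")
        return out

    def _sample_class(self, speed: str | None = None) -> str:
        names = list(self.cfg.class_fractions)
        probs = np.array([self.cfg.class_fractions[c] for c in names])
        probs = probs / probs.sum()
        if speed is not None:
            mask = np.array([c.startswith(speed) for c in names])
            probs = probs * mask
            probs = probs / probs.sum()
        return str(self.rng.choice(names, p=probs))

    # -- main protein population --------------------------------------------

    def build_proteins(self) -> None:
        cfg = self.cfg
        groups = list(cfg.group_fractions)
        probs = np.array([cfg.group_fractions[g] for g in groups])
        probs = probs / probs.sum()
        ptm_types = ("acetyl", "phospho", "ubiquityl")
        for i in range(cfg.n_proteins):
            acc = f"SYNP{i:04d}"
            group = str(self.rng.choice(groups, p=probs))
            self.truth.protein_group[acc] = group
            lo, hi = cfg.seq_len_range
            length = int(self.rng.integers(lo, hi + 1))
            if group == "hetero":
                length = max(length, cfg.hetero_gap_range[1] + 120)
            self._new_protein(acc, length)
            used: set[int] = set()

            # planted regulated sites per group
            if group == "single":
                (pos,) = self._free_positions(acc, used, 1)
                label = self._sample_class()
                ptm = str(self.rng.choice(ptm_types))
                self._make_site(acc, pos, ptm, label)
            elif group == "syn":
                speed = str(self.rng.choice(["fast", "slow"]))
                n_sites = int(self.rng.integers(2, 4))
                base = int(
                    self.rng.integers(17, length - cfg.syn_gap_range[1] * n_sites - 17)
                )
                pos = base
                for _ in range(n_sites):
                    used.add(pos)
                    label = self._sample_class(speed)
                    ptm = str(self.rng.choice(ptm_types))
                    self._make_site(acc, pos, ptm, label)
                    pos += int(self.rng.integers(*cfg.syn_gap_range))
            elif group == "hetero":
                base = int(
                    self.rng.integers(17, length - cfg.hetero_gap_range[1] - 40)
                )
                used.add(base)
                fast_label = self._sample_class("fast")
                self._make_site(acc, base, str(self.rng.choice(ptm_types)), fast_label)
                slow_pos = base + int(self.rng.integers(*cfg.hetero_gap_range))
                used.add(slow_pos)
                slow_label = self._sample_class("slow")
                self._make_site(
                    acc, slow_pos, str(self.rng.choice(ptm_types)), slow_label
                )
                if self.rng.random() < 0.5:
                    extra = base + int(self.rng.integers(*cfg.syn_gap_range))
                    if extra not in used and extra < length - 17:
                        used.add(extra)
                        self._make_site(
                            acc,
                            extra,
                            str(self.rng.choice(ptm_types)),
                            self._sample_class("fast"),
                        )

            # unregulated background sites
            for ptm in ptm_types:
                n_bg = int(self.rng.poisson(cfg.background_sites_per_type))
                n_bg = min(n_bg, max(0, (length - 34) // 3 - len(used)))
                if n_bg <= 0:
                    continue
                for pos in self._free_positions(acc, used, n_bg):
                    self._make_site(acc, pos, ptm, UNREGULATED)

            # whole-cell proteome row
            speed = str(
                self.rng.choice(
                    list(cfg.wcp_speed_fractions),
                    p=np.array(list(cfg.wcp_speed_fractions.values()))
                    / sum(cfg.wcp_speed_fractions.values()),
                )
            )
            self.truth.wcp_speed[acc] = speed
            direction = 1.0 if self.rng.random() < 0.5 else -1.0
            e = self._effect()
            if speed == "fast":
                template = (direction * e, direction * e)
            elif speed == "slow":
                template = (0.0, direction * e)
            else:
                template = (0.0, 0.0)
            self._make_wcp(acc, template)

    def _make_wcp(
        self, accession: str, template: tuple[float, float]
    ) -> SiteQuantRecord:
        rec = SiteQuantRecord(
            accession=accession,
            position=0,
            residue="-",
            ptm_type="wcp",
            loc_prob=None,
            log2_ml=self._replicates(template[0]),
            log2_hl=self._replicates(template[1]),
            intensity=float(self.rng.uniform(1e5, 1e8)),
            condition="untreated",
            cell_line="SYN",
        )
        self.records["wcp"].append(rec)
        return rec

    # -- motif planting ------------------------------------------------------

    def plant_motif(self) -> None:
        spec = self.cfg.motif_spec
        for rec in self.records[spec.ptm_type]:
            if rec.condition != "untreated":
                continue
            if self.truth.site_class.get(rec.key, UNREGULATED) == UNREGULATED:
                continue
            target = rec.position - 1 + spec.offset
            seq = self.sequences[rec.accession]
            if 0 <= target < len(seq) and self.rng.random() < spec.enrichment:
                seq[target] = spec.residue

    # -- ubiquitination outcome arm ------------------------------------------

    def build_ub_outcomes(self) -> None:
        cfg = self.cfg
        n_deg = int(round(cfg.n_ub_outcome_sites * cfg.ub_fraction_degradative))
        for i in range(cfg.n_ub_outcome_sites):
            acc = f"SYNU{i:04d}"
            self._new_protein(acc, 150)
            (pos,) = self._free_positions(acc, set(), 1)
            e = self._effect()
            degradative = i < n_deg
            if degradative:
                # proteasome blockade: ubiquitin conjugates accumulate while
                # the untreated protein level falls
                ub_mg132, wcp = e, -e
            else:
                sign = 1.0 if self.rng.random() < 0.5 else -1.0
                ub_mg132, wcp = sign * e, sign * e
            # untreated ubiquitinome: affected sites rise in both arms
            affected = self.rng.random() < 0.5
            ub_untreated = e if (affected and ub_mg132 >= 1) else 0.2 * np.sign(ub_mg132)

            rec_mg = self._make_site(
                acc,
                pos,
                "ubiquityl",
                UNREGULATED,  # label bookkeeping unused for mg132 rows
                condition="mg132",
                template=(ub_mg132, ub_mg132),
                loc_prob=float(self.rng.uniform(0.95, 1.0)),
            )
            self._make_site(
                acc,
                pos,
                "ubiquityl",
                UNREGULATED,
                condition="untreated",
                template=(float(ub_untreated), float(ub_untreated)),
                loc_prob=float(self.rng.uniform(0.95, 1.0)),
            )
            self._make_wcp(acc, (wcp, wcp))
            self.truth.wcp_speed[acc] = "fast" if abs(wcp) >= 1 else "none"
            # the untreated ubiquitinome site is this protein's only PTM site
            self.truth.protein_group[acc] = (
                "single" if abs(ub_untreated) >= 1 else "unregulated"
            )
            self.truth.ub_verdict[rec_mg.key] = (
                "degradative" if degradative else "non_degradative"
            )

    # -- polyubiquitin precursor ----------------------------------------------

    def build_ubiquitin_precursor(self) -> None:
        cfg = self.cfg
        acc = "SYNUBB"
        moiety = UBIQUITIN_MOIETY
        self.sequences[acc] = list(moiety * cfg.n_ub_repeats)
        self.truth.protein_group.setdefault(acc, "unregulated")
        self.truth.wcp_speed.setdefault(acc, "none")
        for name, frac in cfg.linkage_fractions.items():
            k = int(name[1:])
            per_repeat = frac * cfg.ub_total_intensity / cfg.n_ub_repeats
            for repeat in range(cfg.n_ub_repeats):
                pos = repeat * 76 + k
                rec = SiteQuantRecord(
                    accession=acc,
                    position=pos,
                    residue="K",
                    ptm_type="ubiquityl",
                    loc_prob=float(self.rng.uniform(0.95, 1.0)),
                    log2_ml=self._replicates(0.0),
                    log2_hl=self._replicates(0.0),
                    intensity=per_repeat,
                    condition="untreated",
                    cell_line="SYN",
                )
                self.records["ubiquityl"].append(rec)
                self.truth.site_class[rec.key] = UNREGULATED

    # -- interaction network ---------------------------------------------------

    def build_edges(self) -> None:
        cfg = self.cfg
        accessions = sorted(a for a in self.truth.protein_group if a.startswith("SYNP"))
        seen: set[tuple[str, str]] = set()
        for acc in accessions:
            group = self.truth.protein_group[acc]
            degree = int(self.rng.poisson(cfg.degree_by_group.get(group, 1.0)))
            if degree <= 0:
                continue
            partners = self.rng.choice(
                len(accessions), size=min(degree, len(accessions) - 1), replace=False
            )
            for j in partners:
                other = accessions[int(j)]
                if other == acc:
                    continue
                pair = (acc, other) if acc <= other else (other, acc)
                if pair in seen:
                    continue
                seen.add(pair)
                self.edges_raw.append(
                    (pair[0], pair[1], float(self.rng.uniform(0.801, 1.0)))
                )
        for _ in range(cfg.n_decoy_edges):
            i, j = self.rng.choice(len(accessions), size=2, replace=False)
            a, b = accessions[int(i)], accessions[int(j)]
            pair = (a, b) if a <= b else (b, a)
            if pair in seen:
                continue
            seen.add(pair)
            self.edges_raw.append(
                (pair[0], pair[1], float(self.rng.uniform(0.4, 0.8)))
            )

    def run(self) -> SyntheticDataset:
        self.build_proteins()
        self.plant_motif()
        self.build_ub_outcomes()
        self.build_ubiquitin_precursor()
        self.build_edges()
        sequences = {acc: "".join(seq) for acc, seq in sorted(self.sequences.items())}
        for records in self.records.values():
            for rec in records:
                rec.validate()
        return SyntheticDataset(
            site_records=self.records,
            sequences=sequences,
            edges_raw=self.edges_raw,
            truth=self.truth,
            config=self.cfg,
        )


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic input bundle with planted ground truth."""
    return _Generator(config or SyntheticConfig()).run()


def generate_class_benchmark(
    n_per_class: int = 200,
    effect: float = 2.0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Balanced temporal-classification benchmark: ``n_per_class`` sites per
    temporal class, each site's replicate ratios = class template (effect
    size ``effect``) + N(0, noise_sd); no missing values.

    Returns ``(profiles, labels)`` where profiles are
    :class:`~ptmdyn.site_processing.TemporalProfile` and labels the planted
    classes, in a seed-determined interleaved order.
    """
    from .site_processing import TemporalProfile

    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    i = 0
    for label in SIX_CLASSES:
        f05, f2 = CLASS_TEMPLATES[label]
        for _ in range(n_per_class):
            m05 = f05 * effect + rng.normal(0, noise_sd, n_replicates).mean()
            m2 = f2 * effect + rng.normal(0, noise_sd, n_replicates).mean()
            profiles.append(
                TemporalProfile(
                    accession=f"BM{i:05d}",
                    position=1,
                    ptm_type="phospho",
                    condition="untreated",
                    residue="S",
                    mean_log2_05h=float(m05),
                    mean_log2_2h=float(m2),
                    n_05h=n_replicates,
                    n_2h=n_replicates,
                )
            )
            labels.append(label)
            i += 1
    order = rng.permutation(len(profiles))
    return [profiles[j] for j in order], [labels[j] for j in order]


def truth_evaluation(predictions: dict, truth: GroundTruth) -> dict:
    """Compare pipeline outputs with planted truth, stage by stage.

    ``predictions`` may hold ``site_class`` (site key -> six-class label),
    ``protein_group`` (accession -> group) and ``ub_verdict`` (MG132-arm
    site key -> verdict).  Each present stage yields an accuracy and a
    confusion table over the keys shared with the truth; absent stages are
    flagged as missing rather than failing.
    """
    import pandas as pd

    report: dict[str, dict] = {}
    stages = (
        ("site_class", truth.site_class),
        ("protein_group", truth.protein_group),
        ("ub_verdict", truth.ub_verdict),
    )
    for stage, truth_map in stages:
        pred_map = predictions.get(stage)
        if pred_map is None:
            report[stage] = {"missing": True}
            continue
        shared = [k for k in truth_map if k in pred_map]
        pairs = [(truth_map[k], pred_map[k]) for k in shared]
        if pairs:
            df = pd.DataFrame(pairs, columns=["truth", "predicted"])
            confusion = pd.crosstab(df["truth"], df["predicted"])
            accuracy = float((df["truth"] == df["predicted"]).mean())
        else:
            confusion = pd.DataFrame()
            accuracy = float("nan")
        report[stage] = {
            "missing": False,
            "n": len(pairs),
            "n_truth_only": len(truth_map) - len(shared),
            "n_predicted_only": len(set(pred_map) - set(truth_map)),
            "accuracy": accuracy,
            "confusion": confusion,
        }
    return report
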
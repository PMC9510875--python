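"""End-to-end orchestration: read -> filter -> aggregate -> classify ->
crosstalk -> ubiquitination outcomes -> motifs -> report.

Runs are driven by a :class:`RunConfig` naming either input files or a
synthetic-generation block (exactly one).  Every stage logs record counts in
and out, and the final summary accounts for every input row: a row is either
in the filtered-out count, the insufficient-data count, or contributes to a
classified site — nothing is lost silently.  Given identical configuration
and inputs the output tables are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import crosstalk as ct
from . import io_tables as iot
from . import motif as mt
from . import site_processing as sp
from . import temporal as tp
from . import ub as ubm
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset

PTM_TABLE_KEYS = ("acetyl", "phospho", "ubiquityl", "wcp")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "ptmdyn_out"
    seed: int = 0
    #: input paths: ptm type -> site table; plus fasta and interactions
    site_tables: dict = field(default_factory=dict)
    fasta: str | None = None
    interactions: str | None = None
    #: alternatively, a synthetic-generation block (SyntheticConfig fields)
    synthetic: dict | None = None
    fold: float = 2.0
    min_loc_prob: float = 0.9
    min_replicates: int = 2
    membership_threshold: float = 0.6
    min_interaction_score: float = 0.8
    ub_threshold: float = 1.0
    alpha: float = 0.05
    #: which SILAC channel carries the ratio used for the MG132-arm
    #: comparison (the channel -> time-point mapping made explicit)
    ub_channel: str = "ml"
    ubiquitin_accessions: list = field(default_factory=lambda: ["SYNUBB"])
    run_motifs: bool = True

    def validate(self) -> None:
        has_paths = bool(self.site_tables)
        has_synth = self.synthetic is not None
        if has_paths == has_synth:
            raise ConfigError(
                "exactly one of site_tables / synthetic must be provided"
            )
        if has_paths and self.run_motifs and not self.fasta:
            raise ConfigError("motif stage enabled but no FASTA path given")
        if not (1.0 < self.fold):
            raise ConfigError("fold must be > 1")
        for name, value, lo, hi in (
            ("min_loc_prob", self.min_loc_prob, 0.0, 1.0),
            ("membership_threshold", self.membership_threshold, 0.0, 1.0),
            ("min_interaction_score", self.min_interaction_score, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
        ):
            if not (lo <= value <= hi):
                raise ConfigError(f"{name}={value} outside [{lo}, {hi}]")
        if self.ub_channel not in ("ml", "hl"):
            raise ConfigError("ub_channel must be 'ml' or 'hl'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    config: RunConfig
    profiles: list
    classifications: list
    cluster_labels: dict
    protein_summaries: list
    cooccurrence: pd.DataFrame
    ub_outcomes: list
    linkage: ubm.LinkageAbundance
    motif_results: dict
    summary: dict
    log: list
    truth: object | None = None


def _log(log: list, stage: str, message: str) -> None:
    log.append(f"[{stage}] {message}")


def _mean_channel(profile: sp.TemporalProfile, channel: str) -> float | None:
    return profile.mean_log2_05h if channel == "ml" else profile.mean_log2_2h


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    truth = None

    # ---- stage: inputs ----
    try:
        if config.synthetic is not None:
            synth_cfg = SyntheticConfig(**{**config.synthetic, "seed": config.seed})
            dataset: SyntheticDataset = generate_dataset(synth_cfg)
            truth = dataset.truth
            paths = dataset.write(outdir / "inputs")
            site_paths = {k: paths[k] for k in PTM_TABLE_KEYS}
            fasta_path = paths["fasta"]
            edges_path = paths["interactions"]
            _log(log, "inputs", f"generated synthetic bundle (seed={config.seed})")
        else:
            site_paths = dict(config.site_tables)
            fasta_path = config.fasta
            edges_path = config.interactions
        tables = {
            ptm: iot.read_site_table(path, ptm) for ptm, path in site_paths.items()
        }
        sequences = iot.read_fasta(fasta_path).sequences if fasta_path else {}
        edges = (
            iot.read_interactions(edges_path, config.min_interaction_score)
            if edges_path
            else []
        )
        for ptm, recs in tables.items():
            _log(log, "inputs", f"{ptm}: {len(recs)} rows read")
        _log(log, "inputs", f"{len(edges)} interaction edges retained")
    except (OSError, iot.FormatError, ValueError) as exc:
        raise StageError("inputs", str(exc)) from exc

    # ---- stage: filter ----
    filtered: dict[str, list] = {}
    accounting: dict[str, dict] = {}
    for ptm, recs in tables.items():
        kept = sp.filter_sites(recs, config.min_loc_prob)
        filtered[ptm] = kept
        accounting[ptm] = {"rows_in": len(recs), "rows_filtered_out": len(recs) - len(kept)}
        _log(log, "filter", f"{ptm}: {len(recs)} -> {len(kept)} rows")

    # ---- stage: aggregate ----
    profiles_by_type: dict[str, list[sp.TemporalProfile]] = {}
    for ptm, recs in filtered.items():
        untreated = [r for r in recs if r.condition == "untreated"]
        profs = sp.aggregate_replicates(untreated, config.min_replicates)
        profiles_by_type[ptm] = profs
        n_rows_untreated = len(untreated)
        accounting[ptm]["rows_untreated"] = n_rows_untreated
        accounting[ptm]["rows_mg132"] = len(recs) - n_rows_untreated
        _log(log, "aggregate", f"{ptm}: {len(profs)} site profiles")

    usable: dict[str, list[sp.TemporalProfile]] = {}
    insufficient: dict[str, list[sp.TemporalProfile]] = {}
    for ptm, profs in profiles_by_type.items():
        usable[ptm] = [p for p in profs if p.mean_log2_05h is not None or p.mean_log2_2h is not None]
        insufficient[ptm] = [p for p in profs if p.mean_log2_05h is None and p.mean_log2_2h is None]
        accounting[ptm]["sites_total"] = len(profs)
        accounting[ptm]["sites_classified"] = len(usable[ptm])
        accounting[ptm]["sites_insufficient"] = len(insufficient[ptm])

    # ---- stage: classify ----
    ptm_profiles = [p for ptm in ("acetyl", "phospho", "ubiquityl") for p in usable.get(ptm, [])]
    classifications = [tp.classify_rule_based(p, config.fold) for p in ptm_profiles]
    cluster_labels: dict[int, str] = {}
    eligible = [
        i
        for i, (p, cl) in enumerate(zip(ptm_profiles, classifications))
        if cl.six_class_label != tp.UNREGULATED and p.quantified_both
    ]
    fcm_profiles = [ptm_profiles[i] for i in eligible]
    if len(fcm_profiles) >= 6:
        x = tp.standardize_profiles(fcm_profiles)
        if len(set(map(tuple, x))) >= 6:
            model = tp.fit_fcm(x, seed=config.seed)
            assignments = tp.assign_fcm(model, config.membership_threshold)
            for j, i in enumerate(eligible):
                classifications[i].fcm_membership = float(model.memberships[j].max())
                classifications[i].fcm_cluster = assignments[j]
            cluster_labels = tp.label_clusters(model, fcm_profiles, config.fold)
    n_reg = sum(1 for cl in classifications if cl.six_class_label != tp.UNREGULATED)
    _log(log, "classify", f"{n_reg}/{len(classifications)} sites regulated")

    # wcp protein-level classification feeds the co-occurrence pseudo-type
    wcp_class = {
        p.accession: tp.classify_rule_based(p, config.fold)
        for p in usable.get("wcp", [])
    }
    wcp_speed = {
        acc: cl.speed for acc, cl in wcp_class.items() if cl.speed != "none"
    }

    # ---- stage: crosstalk ----
    by_protein: dict[str, list[tp.SiteClassification]] = {}
    positions: dict[str, list[int]] = {}
    for p, cl in zip(ptm_profiles, classifications):
        by_protein.setdefault(p.accession, []).append(cl)
        positions.setdefault(p.accession, []).append(p.position)
    degrees = ct.interaction_degree(by_protein.keys(), edges)
    protein_summaries = [
        ct.summarize_protein(acc, cls, positions[acc], degrees.get(acc, 0))
        for acc, cls in sorted(by_protein.items())
    ]
    cooccurrence = ct.cooccurrence_matrix(protein_summaries, wcp_speed)
    _log(log, "crosstalk", f"{len(protein_summaries)} protein summaries")

    # ---- stage: ub outcomes ----
    ub_mg132 = sp.aggregate_replicates(
        [r for r in filtered.get("ubiquityl", []) if r.condition == "mg132"],
        config.min_replicates,
    )
    ub_untreated_map = {
        p.key: _mean_channel(p, config.ub_channel) for p in usable.get("ubiquityl", [])
    }
    wcp_map = {
        p.accession: _mean_channel(p, config.ub_channel) for p in usable.get("wcp", [])
    }
    ub_outcomes = ubm.call_ub_outcomes(
        {p.key: _mean_channel(p, config.ub_channel) for p in ub_mg132},
        ub_untreated_map,
        wcp_map,
        config.ub_threshold,
    )
    linkage = ubm.chain_linkage_abundance(
        [r for r in filtered.get("ubiquityl", []) if r.condition == "untreated"],
        config.ubiquitin_accessions,
    )
    _log(log, "ub", f"{len(ub_outcomes)} MG132-arm sites classified")

    # ---- stage: motifs ----
    motif_results: dict[str, list[mt.MotifResult]] = {}
    if config.run_motifs and sequences:
        for ptm in ("acetyl", "phospho", "ubiquityl"):
            reg_windows, unreg_windows = [], []
            for p, cl in zip(ptm_profiles, classifications):
                if p.ptm_type != ptm or p.accession not in sequences:
                    continue
                # ubiquitin precursors repeat one moiety: their flanks are
                # pseudo-replicated windows that would distort the background
                if p.accession in config.ubiquitin_accessions:
                    continue
                seq = sequences[p.accession]
                if not (1 <= p.position <= len(seq)):
                    continue
                window = mt.extract_flank(seq, p.position)
                if cl.six_class_label != tp.UNREGULATED:
                    reg_windows.append(window)
                else:
                    unreg_windows.append(window)
            if reg_windows and unreg_windows:
                motif_results[ptm] = mt.differential_frequency(
                    reg_windows, unreg_windows, config.alpha
                )
                n_sig = sum(1 for r in motif_results[ptm] if r.significant)
                _log(log, "motif", f"{ptm}: {n_sig} significant cells")

    # ---- stage: report ----
    summary = summarize_distributions(ptm_profiles, classifications, protein_summaries)
    summary["accounting"] = accounting
    summary["ub"] = {
        "n_outcomes": len(ub_outcomes),
        "n_degradative": sum(1 for o in ub_outcomes if o.verdict == "degradative"),
        "n_non_degradative": sum(
            1 for o in ub_outcomes if o.verdict == "non_degradative"
        ),
        "n_unclassified": sum(1 for o in ub_outcomes if o.verdict == "unclassified"),
        "n_mg132_affected": sum(1 for o in ub_outcomes if o.mg132_affected),
        "linkage_fractions": linkage.fractions,
    }
    summary["fcm_cluster_labels"] = {str(k): v for k, v in cluster_labels.items()}

    result = PipelineResult(
        config=config,
        profiles=ptm_profiles,
        classifications=classifications,
        cluster_labels=cluster_labels,
        protein_summaries=protein_summaries,
        cooccurrence=cooccurrence,
        ub_outcomes=ub_outcomes,
        linkage=linkage,
        motif_results=motif_results,
        summary=summary,
        log=log,
        truth=truth,
    )
    _write_outputs(result, outdir, filtered, insufficient)
    return result


def check_no_silent_loss(summary: dict) -> bool:
    """Every input row is accounted for: filtered out, or part of a site
    that was classified or reported as insufficient-data."""
    for ptm, acc in summary["accounting"].items():
        if acc["rows_in"] != acc["rows_filtered_out"] + acc["rows_untreated"] + acc["rows_mg132"]:
            return False
        if acc["sites_total"] != acc["sites_classified"] + acc["sites_insufficient"]:
            return False
    return True


def summarize_distributions(profiles, classifications, protein_summaries) -> dict:
    """Per-PTM-type counts: sites and proteins, regulated up/down per time
    point, fast/slow shares, single/multi-site protein split, and the
    protein-group sizes."""
    per_type: dict[str, dict] = {}
    for ptm in ("acetyl", "phospho", "ubiquityl"):
        sub = [(p, cl) for p, cl in zip(profiles, classifications) if p.ptm_type == ptm]
        if not sub:
            per_type[ptm] = {
                "n_sites": 0, "n_proteins": 0, "n_regulated": 0,
                "up_05h": 0, "down_05h": 0, "up_2h": 0, "down_2h": 0,
                "n_fast": 0, "n_slow": 0,
                "multi_site_proteins": 0, "single_site_proteins": 0,
            }
            continue
        site_counts: dict[str, int] = {}
        up05 = down05 = up2 = down2 = 0
        for p, cl in sub:
            site_counts[p.accession] = site_counts.get(p.accession, 0) + 1
            call = sp.call_regulated(p)
            if call.regulated_05h:
                if p.mean_log2_05h > 0:
                    up05 += 1
                else:
                    down05 += 1
            if call.regulated_2h:
                if p.mean_log2_2h > 0:
                    up2 += 1
                else:
                    down2 += 1
        per_type[ptm] = {
            "n_sites": len(sub),
            "n_proteins": len(site_counts),
            "n_regulated": sum(
                1 for _, cl in sub if cl.six_class_label != tp.UNREGULATED
            ),
            "up_05h": up05,
            "down_05h": down05,
            "up_2h": up2,
            "down_2h": down2,
            "n_fast": sum(1 for _, cl in sub if cl.speed == "fast"),
            "n_slow": sum(1 for _, cl in sub if cl.speed == "slow"),
            "multi_site_proteins": sum(1 for v in site_counts.values() if v > 1),
            "single_site_proteins": sum(1 for v in site_counts.values() if v == 1),
        }
    groups = {g: 0 for g in ct.GROUPS}
    for s in protein_summaries:
        groups[s.group] += 1
    multi_type = {
        g: sum(1 for s in protein_summaries if s.group == g and s.multi_type)
        for g in ("syn", "hetero")
    }
    return {
        "per_type": per_type,
        "protein_groups": groups,
        "multi_type_counts": multi_type,
        "class_counts": {
            label: sum(1 for cl in classifications if cl.six_class_label == label)
            for label in (*tp.SIX_CLASSES, tp.UNREGULATED)
        },
    }


def _write_outputs(result: PipelineResult, outdir: Path, filtered, insufficient) -> None:
    prof_rows = []
    for p, cl in zip(result.profiles, result.classifications):
        prof_rows.append(
            {
                "accession": p.accession,
                "position": p.position,
                "ptm_type": p.ptm_type,
                "condition": p.condition,
                "mean_log2_05h": p.mean_log2_05h,
                "mean_log2_2h": p.mean_log2_2h,
                "n_05h": p.n_05h,
                "n_2h": p.n_2h,
                "six_class_label": cl.six_class_label,
                "speed": cl.speed,
                "persistence": cl.persistence,
                "direction": cl.direction,
                "fcm_cluster": "" if cl.fcm_cluster is None else cl.fcm_cluster,
                "fcm_membership": cl.fcm_membership,
                "conflict_flag": cl.conflict_flag,
            }
        )
    pd.DataFrame(prof_rows).to_csv(outdir / "classifications.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "accession": s.accession,
                "group": s.group,
                "multi_type": s.multi_type,
                "n_sites_total": s.n_sites_total,
                "n_sites_regulated": s.n_sites_regulated,
                "interaction_degree": s.interaction_degree,
                "mean_distance_all": s.mean_distance_all,
                "mean_distance_syn": s.mean_distance_syn,
                "mean_distance_hetero": s.mean_distance_hetero,
            }
            for s in result.protein_summaries
        ]
    ).to_csv(outdir / "protein_summaries.tsv", sep="\t", index=False)

    result.cooccurrence.to_csv(outdir / "cooccurrence.tsv", sep="\t")

    pd.DataFrame(
        [
            {
                "accession": o.key[0],
                "position": o.key[1],
                "verdict": o.verdict,
                "mg132_affected": o.mg132_affected,
                "ub_log2_mg132": o.ub_log2_mg132,
                "wcp_log2_untreated": o.wcp_log2_untreated,
                "missing_wcp": o.missing_wcp,
            }
            for o in result.ub_outcomes
        ]
    ).to_csv(outdir / "ub_outcomes.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"linkage": k, "fraction": v} for k, v in result.linkage.fractions.items()]
    ).to_csv(outdir / "linkage_abundance.tsv", sep="\t", index=False)

    for ptm, results in result.motif_results.items():
        pd.DataFrame(
            [
                {
                    "position": r.position,
                    "residue": r.residue,
                    "freq_regulated": r.freq_regulated,
                    "freq_unregulated": r.freq_unregulated,
                    "delta_pct": r.delta_pct,
                    "p_value": r.p_value,
                    "significant": r.significant,
                    "center_flag": r.center_flag,
                }
                for r in results
            ]
        ).to_csv(outdir / f"motifs_{ptm}.tsv", sep="\t", index=False)

    insuff_rows = [
        {"accession": p.accession, "position": p.position, "ptm_type": p.ptm_type}
        for profs in insufficient.values()
        for p in profs
    ]
    pd.DataFrame(insuff_rows, columns=["accession", "position", "ptm_type"]).to_csv(
        outdir / "insufficient_data.tsv", sep="\t", index=False
    )

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True, default=str)
    with open(outdir / "log.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(result.log) + "\n")
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(result.config), fh, sort_keys=True)
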
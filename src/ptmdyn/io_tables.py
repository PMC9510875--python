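"""Readers and writers for the pipeline's tabular and sequence formats.

The site-table dialect is fixed: tab-separated UTF-8 text with a header row
and '.' decimals.  Required columns are ``accession``, ``position``,
``residue``, ``loc_prob``, ``log2_ML_rep1..n``, ``log2_HL_rep1..n``,
``intensity`` and ``condition``; an optional ``cell_line`` column is carried
through.  Missing ratio cells are written as ``NA`` (empty cells are also
accepted on read) and are preserved as absent values, never imputed.

Positions are 1-based within the protein sequence.  Whole-cell-proteome
(``wcp``) rows carry protein-level ratios and no site semantics; they use the
sentinel position 0 and residue ``-``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = set("UBZX")

PTM_TYPES = ("acetyl", "phospho", "ubiquityl", "wcp")
CONDITIONS = ("untreated", "mg132")

#: sentinel residue for protein-level (wcp) rows
WCP_RESIDUE = "-"


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


@dataclass
class SiteQuantRecord:
    """One PTM site (or one protein for ``wcp``) in one experiment.

    ``log2_ml`` and ``log2_hl`` hold per-replicate log2 SILAC ratios for the
    0.5 h (M/L) and 2 h (H/L) channels; entries are ``None`` where the
    replicate did not quantify the site.
    """

    accession: str
    position: int
    residue: str
    ptm_type: str
    loc_prob: float | None
    log2_ml: list[float | None]
    log2_hl: list[float | None]
    intensity: float = 0.0
    condition: str = "untreated"
    cell_line: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.accession, self.position, self.ptm_type, self.condition)

    def validate(self) -> None:
        if self.ptm_type not in PTM_TYPES:
            raise ValueError(f"unknown ptm_type {self.ptm_type!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.ptm_type == "wcp":
            if self.position not in (0,):
                # protein-level rows use the sentinel position 0
                raise ValueError(
                    f"wcp row for {self.accession} has position {self.position}; expected 0"
                )
        else:
            if self.position < 1:
                raise ValueError(
                    f"{self.accession}: position must be >= 1, got {self.position}"
                )
            if self.residue not in AMINO_ACIDS:
                raise ValueError(
                    f"{self.accession}:{self.position}: residue {self.residue!r} "
                    "is not a canonical amino acid"
                )
        if self.loc_prob is not None and not (0.0 <= self.loc_prob <= 1.0):
            raise ValueError(f"loc_prob {self.loc_prob} outside [0, 1]")
        if not any(v is not None for v in self.log2_ml + self.log2_hl):
            raise ValueError(
                f"{self.accession}:{self.position}: no replicate ratio present"
            )
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected protein-protein interaction with a confidence score."""

    protein_a: str
    protein_b: str
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"interaction score {self.score} outside [0, 1]")


_RATIO_COL = re.compile(r"^log2_(ML|HL)_rep(\d+)$")
_BASE_COLS = ("accession", "position", "residue", "loc_prob", "intensity", "condition")


def _parse_cell(value: str, column: str, row_number: int) -> float | None:
    value = value.strip()
    if value in ("", "NA", "NaN", "nan"):
        return None
    try:
        return float(value)
    except ValueError:
        raise FormatError(
            f"row {row_number}: non-numeric value {value!r} in column {column}"
        ) from None


def read_site_table(path: str | Path, ptm_type: str) -> list[SiteQuantRecord]:
    """Read a site-quantification table into records, preserving row order.

    Missing ratio cells become absent entries (``None``), never zeros.
    Filtering on localization probability is a later stage; rows are returned
    as found.
    """
    if ptm_type not in PTM_TYPES:
        raise ValueError(f"unknown ptm_type {ptm_type!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            return []
        header = header_line.rstrip("\n").split("\t")
        for col in _BASE_COLS:
            if col not in header:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        ml_cols = sorted(
            (c for c in header if _RATIO_COL.match(c) and "_ML_" in c),
            key=lambda c: int(_RATIO_COL.match(c).group(2)),
        )
        hl_cols = sorted(
            (c for c in header if _RATIO_COL.match(c) and "_HL_" in c),
            key=lambda c: int(_RATIO_COL.match(c).group(2)),
        )
        if not ml_cols and not hl_cols:
            raise FormatError(
                f"{path.name}: missing required column 'log2_ML_rep1' (no ratio columns found)"
            )
        idx = {c: i for i, c in enumerate(header)}
        records: list[SiteQuantRecord] = []
        for row_number, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise FormatError(
                    f"row {row_number}: expected {len(header)} cells, got {len(cells)}"
                )
            loc_raw = cells[idx["loc_prob"]].strip()
            loc_prob = None if loc_raw in ("", "NA") else _parse_cell(
                loc_raw, "loc_prob", row_number
            )
            intensity_cell = _parse_cell(cells[idx["intensity"]], "intensity", row_number)
            rec = SiteQuantRecord(
                accession=cells[idx["accession"]].strip(),
                position=int(cells[idx["position"]]),
                residue=cells[idx["residue"]].strip(),
                ptm_type=ptm_type,
                loc_prob=loc_prob,
                log2_ml=[_parse_cell(cells[idx[c]], c, row_number) for c in ml_cols],
                log2_hl=[_parse_cell(cells[idx[c]], c, row_number) for c in hl_cols],
                intensity=intensity_cell if intensity_cell is not None else 0.0,
                condition=cells[idx["condition"]].strip(),
                cell_line=cells[idx["cell_line"]].strip() if "cell_line" in idx else "",
            )
            rec.validate()
            records.append(rec)
    return records


def _fmt(value: float | None) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    return repr(value) if isinstance(value, float) else str(value)


def write_site_table(path: str | Path, records: Iterable[SiteQuantRecord]) -> None:
    """Write records in the dialect :func:`read_site_table` reads (round-trip exact)."""
    records = list(records)
    n_ml = max((len(r.log2_ml) for r in records), default=3)
    n_hl = max((len(r.log2_hl) for r in records), default=3)
    header = (
        list(_BASE_COLS[:4])
        + [f"log2_ML_rep{i + 1}" for i in range(n_ml)]
        + [f"log2_HL_rep{i + 1}" for i in range(n_hl)]
        + ["intensity", "condition", "cell_line"]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            ml = list(r.log2_ml) + [None] * (n_ml - len(r.log2_ml))
            hl = list(r.log2_hl) + [None] * (n_hl - len(r.log2_hl))
            cells = [
                r.accession,
                str(r.position),
                r.residue,
                _fmt(r.loc_prob),
                *[_fmt(v) for v in ml],
                *[_fmt(v) for v in hl],
                _fmt(r.intensity),
                r.condition,
                r.cell_line,
            ]
            fh.write("\t".join(cells) + "\n")


@dataclass
class FastaResult:
    sequences: dict[str, str] = field(default_factory=dict)
    n_ambiguous: int = 0  # count of U/B/Z/X letters seen


def read_fasta(path: str | Path) -> FastaResult:
    """Read a FASTA file into ``accession -> uppercase sequence``.

    Accessions are the first whitespace-delimited token of the header.
    Ambiguity letters (U/B/Z/X) are retained but counted in ``n_ambiguous``.
    Duplicate accessions raise an error.
    """
    result = FastaResult()
    for record in SeqIO.parse(str(path), "fasta"):
        acc = record.id.split()[0]
        if acc in result.sequences:
            raise FormatError(f"duplicate FASTA accession {acc!r}")
        seq = str(record.seq).upper()
        result.n_ambiguous += sum(1 for ch in seq if ch in AMBIGUOUS_AA)
        result.sequences[acc] = seq
    return result


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sequences:
            fh.write(f">{acc}\n")
            seq = sequences[acc]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_interactions(path: str | Path, min_score: float = 0.8) -> list[InteractionEdge]:
    """Read a three-column edge list, keeping edges with score strictly above
    ``min_score``; unordered duplicate pairs collapse to the max-score edge and
    self-edges are dropped."""
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            return []
        lines = [] if _looks_like_header(first) else [first]
        lines += fh.readlines()
    for line in lines:
        line = line.rstrip("\n")
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) < 3:
            raise FormatError(f"interaction row needs 3 columns: {line!r}")
        a, b, score = cells[0].strip(), cells[1].strip(), float(cells[2])
        if not (0.0 <= score <= 1.0):
            raise FormatError(f"interaction score {score} outside [0, 1]")
        if a == b:
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair not in best:
            order.append(pair)
            best[pair] = score
        else:
            best[pair] = max(best[pair], score)
    return [
        InteractionEdge(a, b, best[(a, b)])
        for a, b in order
        if best[(a, b)] > min_score
    ]


def _looks_like_header(line: str) -> bool:
    cells = line.rstrip("\n").split("\t")
    if len(cells) < 3:
        return True
    try:
        float(cells[2])
        return False
    except ValueError:
        return True


def write_interactions(path: str | Path, edges: Iterable[InteractionEdge]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tscore\n")
        for e in edges:
            fh.write(f"{e.protein_a}\t{e.protein_b}\t{_fmt(e.score)}\n")


def count_absent_ratios(records: Iterable[SiteQuantRecord]) -> int:
    """Number of absent replicate-ratio entries; conserved from file to records."""
    return sum(
        sum(1 for v in r.log2_ml + r.log2_hl if v is None) for r in records
    )
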
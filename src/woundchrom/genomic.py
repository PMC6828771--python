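"""Genomic data model, standard-format I/O and interval operations.

Coordinates are 0-based half-open throughout (BED convention); GFF3 input is
converted on read.  The analysis window of a gene is the strand-aware 1-kb
promoter plus the gene body, the region over which ChIP read depth is
averaged downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: Marks analysed throughout; H3 itself is carried as the normalisation track.
DEFAULT_MARKS = ("H3K27me3", "H3K36me3", "H3K4me3", "H3K9_14ac", "H3K27ac")

PERMISSIVE_MARKS = ("H3K36me3", "H3K4me3", "H3K9_14ac", "H3K27ac")
REPRESSIVE_MARKS = ("H3K27me3",)


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


class ValidationError(ValueError):
    """Semantically invalid data (invariant violation)."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """bp gap between closest edges; 0 if overlapping; None if different chrom."""
        if self.chrom != other.chrom:
            return None
        return max(0, other.start - self.end, self.start - other.end)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, got {self.body.strand!r}"
            )


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    mark: str
    time_h: float
    replicate: int
    neg_log10_q: float

    def __post_init__(self) -> None:
        if self.neg_log10_q < 0:
            raise ValidationError("neg_log10_q must be >= 0")
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")


def analysis_window(gene: GeneModel, promoter_bp: int = 1000) -> GenomicInterval:
    """Strand-aware promoter + gene-body window.

    For a + gene the window extends ``promoter_bp`` upstream of the start
    (clamped at 0); for a - gene, beyond the end.  Chromosome-length clamping
    is not applied (lengths are unknown from BED input).
    """
    if promoter_bp < 0:
        raise ValidationError(f"promoter_bp must be >= 0, got {promoter_bp}")
    b = gene.body
    if b.strand == "+":
        return GenomicInterval(b.chrom, max(0, b.start - promoter_bp), b.end, "+")
    return GenomicInterval(b.chrom, b.start, b.end + promoter_bp, "-")


# ---------------------------------------------------------------------------
# readers / writers


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 or GFF3 (``gene`` features only).

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Input order is preserved; duplicate gene ids raise.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                # also covers GFF3 pragma lines
                if is_gff is False and line.startswith("##gff"):
                    is_gff = True
                continue
            fields = line.split("\t")
            if is_gff or (len(fields) == 9 and fields[3].isdigit() and fields[6] in STRANDS
                          and not fields[1].isdigit()):
                gene = _parse_gff3_gene(fields, path, lineno)
                if gene is None:
                    continue
            else:
                gene = _parse_bed6_gene(fields, path, lineno)
            if gene.gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def _parse_bed6_gene(fields: Sequence[str], path: Path, lineno: int) -> GeneModel:
    if len(fields) < 6:
        raise ParseError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}")
    try:
        chrom, start, end, name, _score, strand = fields[:6]
        iv = GenomicInterval(chrom, int(start), int(end), strand)
    except (ValueError, ValidationError) as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if strand == ".":
        raise ValidationError(f"{path}:{lineno}: gene {name!r} has strand '.'")
    return GeneModel(name, iv)


def _parse_gff3_gene(fields: Sequence[str], path: Path, lineno: int) -> GeneModel | None:
    if len(fields) != 9:
        raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
    if fields[2].lower() != "gene":
        return None
    chrom, _src, _type, start, end, _score, strand, _phase, attrs = fields
    gene_id = None
    for item in attrs.rstrip(";").split(";"):
        key, _, val = item.strip().partition("=")
        if key in ("ID", "gene_id", "Name") and gene_id is None:
            gene_id = val.removeprefix("gene:")
    if gene_id is None:
        raise ParseError(f"{path}:{lineno}: gene record without ID attribute")
    if strand == ".":
        raise ValidationError(f"{path}:{lineno}: gene {gene_id!r} has strand '.'")
    try:
        iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
    except (ValueError, ValidationError) as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return GeneModel(gene_id, iv)


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 (exact round-trip with read_gene_models)."""
    with open(path, "w") as fh:
        for g in genes:
            b = g.body
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{g.gene_id}\t0\t{b.strand}\n")


def write_windows_bed(genes: Iterable[GeneModel], path: str | Path,
                      promoter_bp: int = 1000) -> None:
    with open(path, "w") as fh:
        for g in genes:
            w = analysis_window(g, promoter_bp)
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{g.gene_id}\t0\t{w.strand}\n")


def read_peaks(path: str | Path, mark: str, time_h: float, replicate: int,
               min_neg_log10_q: float = 3.0) -> list[Peak]:
    """Read an ENCODE narrowPeak (10 col) or broadPeak (9 col) file.

    Only peaks with -log10(Q) >= ``min_neg_log10_q`` (default 3.0, i.e.
    Q < 0.001) are retained; the dropped count is logged.
    """
    path = Path(path)
    peaks: list[Peak] = []
    dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 9 narrowPeak/broadPeak columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                q = float(fields[8])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start < 0:
                raise ValidationError(f"{path}:{lineno}: negative coordinate {start}")
            if q < min_neg_log10_q:
                dropped += 1
                continue
            peaks.append(Peak(GenomicInterval(chrom, start, end, "."),
                              mark, time_h, replicate, q))
    if dropped:
        log.info("%s: dropped %d peaks below -log10(Q) threshold %.3g",
                 path.name, dropped, min_neg_log10_q)
    return peaks


# ---------------------------------------------------------------------------
# peak -> gene assignment


@dataclass
class PeakAssignment:
    """Closest-gene assignments for one peak set against one gene set."""

    #: rows: peak_index, gene_id, distance_bp (ties -> multiple rows per peak)
    table: pd.DataFrame
    unassigned: list[int] = field(default_factory=list)


def assign_peaks_to_genes(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                          promoter_bp: int = 1000) -> PeakAssignment:
    """Map each peak to its closest gene analysis window (BEDTools-closest style).

    Distance is the bp gap between closest edges (0 on overlap).  Exact
    distance ties map the peak to all tied genes.  Peaks on chromosomes
    absent from the gene set are reported unassigned, not an error.
    """
    if not genes:
        raise ValidationError("gene set is empty")
    windows: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for g in genes:
        w = analysis_window(g, promoter_bp)
        starts, ends, ids = windows.setdefault(w.chrom, ([], [], []))  # type: ignore[arg-type]
        starts.append(w.start)  # type: ignore[union-attr]
        ends.append(w.end)  # type: ignore[union-attr]
        ids.append(g.gene_id)
    windows = {c: (np.asarray(s), np.asarray(e), ids)
               for c, (s, e, ids) in windows.items()}

    rows: list[tuple[int, str, int]] = []
    unassigned: list[int] = []
    for i, p in enumerate(peaks):
        hit = windows.get(p.interval.chrom)
        if hit is None:
            unassigned.append(i)
            continue
        starts, ends, ids = hit
        gaps = np.maximum(0, np.maximum(starts - p.interval.end,
                                        p.interval.start - ends))
        dmin = int(gaps.min())
        for j in np.flatnonzero(gaps == dmin):
            rows.append((i, ids[j], dmin))
    table = pd.DataFrame(rows, columns=["peak_index", "gene_id", "distance_bp"])
    return PeakAssignment(table, unassigned)


def marked_genes(assignment_rep1: PeakAssignment, assignment_rep2: PeakAssignment,
                 max_distance_bp: int = 0) -> set[str]:
    """Genes with >= 1 peak within ``max_distance_bp`` in BOTH replicates."""
    def hit(a: PeakAssignment) -> set[str]:
        t = a.table
        if t.empty:
            return set()
        return set(t.loc[t["distance_bp"] <= max_distance_bp, "gene_id"])

    return hit(assignment_rep1) & hit(assignment_rep2)


H3_TRACK = "H3"

COVERAGE_COLUMNS = ["gene_id", "track", "time_h", "replicate", "mean_depth"]


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format coverage table (gene_id, track, time_h, replicate,
    mean_depth) and validate it.

    ``track`` is a mark name or ``H3``.  Every (gene, time, replicate) present
    for a mark must also be present for H3 (the normalisation denominator).
    """
    cov = pd.read_csv(path, sep="\t")
    missing = set(COVERAGE_COLUMNS) - set(cov.columns)
    if missing:
        raise ParseError(f"{path}: missing coverage columns {sorted(missing)}")
    return validate_coverage(cov)


def validate_coverage(cov: pd.DataFrame) -> pd.DataFrame:
    if (cov["mean_depth"] < 0).any() or not np.isfinite(cov["mean_depth"]).all():
        bad = cov.loc[~np.isfinite(cov["mean_depth"]) | (cov["mean_depth"] < 0)].iloc[0]
        raise ValidationError(
            f"coverage depth must be finite and >= 0; offending row: "
            f"{bad['gene_id']}/{bad['track']}/t={bad['time_h']}"
        )
    keys = cov[["gene_id", "time_h", "replicate"]].apply(tuple, axis=1)
    h3_keys = set(keys[cov["track"] == H3_TRACK])
    mark_keys = set(keys[cov["track"] != H3_TRACK])
    orphans = mark_keys - h3_keys
    if orphans:
        example = sorted(orphans)[0]
        raise ValidationError(
            f"{len(orphans)} mark coverage rows lack a matching H3 row, "
            f"e.g. gene={example[0]} t={example[1]} rep={example[2]}"
        )
    return cov


def write_assignment_tsv(assignment: PeakAssignment, peaks: Sequence[Peak],
                         path: str | Path) -> None:
    t = assignment.table.copy()
    t.insert(0, "peak_id", [
        f"{peaks[i].interval.chrom}:{peaks[i].interval.start}-{peaks[i].interval.end}"
        for i in t["peak_index"]
    ])
    t.drop(columns="peak_index").to_csv(path, sep="\t", index=False)
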
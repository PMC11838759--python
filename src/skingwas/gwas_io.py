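"""Readers, writers and core domain types for the tabular and interval formats
the pipeline touches.

Coordinate conventions
----------------------
BED intervals are 0-based half-open ``[start, end)``; summary-statistic and
background-catalogue positions are 1-based points. The two meet exactly once,
in point-in-interval queries: a 1-based position ``q`` hits ``[start, end)``
iff ``start < q <= end``.

Every writer emits a commented header line recording the package version and
genome build; readers validate the build against the one they were asked for
and refuse to mix builds.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import __version__
from .errors import BuildMismatchError, FormatError, RowError

logger = logging.getLogger(__name__)

DEFAULT_BUILD = "hg19"
VALID_ALLELES = frozenset("ACGT")

_SUMMARY_COLUMNS = ("chrom", "pos", "risk_allele", "other_allele", "beta", "se", "p")


def variant_id(chrom: str, pos: int, risk_allele: str) -> str:
    """Canonical variant identifier, ``chrom:pos:riskallele``."""
    return f"{chrom}:{pos}:{risk_allele}"


def norm_chrom(chrom: str) -> str:
    """Normalise chromosome labels so 'chr6' and '6' compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association evidence: the atom of fine-mapping.

    ``beta`` is the per-risk-allele log-odds, ``se`` its standard error and
    ``p`` the reported association p-value.
    """

    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    beta: float
    se: float
    p: float

    def __post_init__(self):
        if self.risk_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"alleles must be one of A/C/G/T, got "
                             f"{self.risk_allele!r}/{self.other_allele!r}")
        if self.risk_allele == self.other_allele:
            raise ValueError("risk_allele equals other_allele")
        if not self.se > 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if not (0 < self.p <= 1):
            raise ValueError(f"p must lie in (0, 1], got {self.p}")

    @property
    def variant_id(self) -> str:
        return variant_id(self.chrom, self.pos, self.risk_allele)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based point falls in the interval (start < pos <= end)."""
        return norm_chrom(chrom) == norm_chrom(self.chrom) and self.start < pos <= self.end


@dataclass
class AnnotationTrack:
    """A named collection of genomic intervals (BED semantics).

    Intervals may overlap one another; no merging is performed. Point queries
    are served from per-chromosome start/end arrays built on first use.
    """

    name: str
    intervals: list[GenomicInterval]
    _index: dict[str, tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(norm_chrom(iv.chrom), []).append(iv)
        return {
            c: (np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64))
            for c, ivs in by_chrom.items()
        }

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Whether any interval covers the 1-based point (start < pos <= end)."""
        if self._index is None:
            self._index = self._build_index()
        hit = self._index.get(norm_chrom(chrom))
        if hit is None:
            return False
        starts, ends = hit
        return bool(np.any((starts < pos) & (pos <= ends)))


@dataclass(frozen=True)
class EqtlRecord:
    """A nominally significant variant-gene expression association."""

    variant_id: str
    gene: str
    p: float


@dataclass(frozen=True)
class BackgroundLocus:
    """Best signal of one trait-locus from the background trait catalogue."""

    trait: str
    chrom: str
    pos: int
    p: float


# ---------------------------------------------------------------------------
# header / build plumbing
# ---------------------------------------------------------------------------

def _header_line(build: str) -> str:
    return f"# skingwas={__version__} build={build}\n"


def _check_build(line: str, expected: str, path) -> None:
    for tok in line.lstrip("# ").split():
        if tok.startswith("build="):
            found = tok.split("=", 1)[1]
            if found != expected:
                raise BuildMismatchError(
                    f"{path}: file declares build {found!r}, expected {expected!r}"
                )


def _open_rows(path) -> tuple[list[str], list[int]]:
    """All non-comment lines of a file with their 1-based line numbers."""
    rows, numbers = [], []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            rows.append(line.rstrip("\n"))
            numbers.append(i)
    return rows, numbers


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(path, disease: str, build: str = DEFAULT_BUILD
                       ) -> list[SummaryStatRecord]:
    """Read a tab-separated summary-statistics table for one disease.

    The header must name at least chrom, pos, risk_allele, other_allele,
    beta, se and p. Records are returned sorted by (chrom, pos); duplicate
    variant ids and invariant violations are errors, never silent drops.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        _check_build(first, build, path)
    rows, numbers = _open_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file (no header)")
    header = rows[0].split("\t")
    col = {name: idx for idx, name in enumerate(header)}
    missing = [c for c in _SUMMARY_COLUMNS if c not in col]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[SummaryStatRecord] = []
    seen: set[str] = set()
    for raw, lineno in zip(rows[1:], numbers[1:]):
        fields = raw.split("\t")
        if len(fields) < len(header):
            raise RowError(f"expected {len(header)} fields, got {len(fields)}", lineno)
        try:
            rec = SummaryStatRecord(
                chrom=fields[col["chrom"]],
                pos=int(fields[col["pos"]]),
                risk_allele=fields[col["risk_allele"]],
                other_allele=fields[col["other_allele"]],
                beta=float(fields[col["beta"]]),
                se=float(fields[col["se"]]),
                p=float(fields[col["p"]]),
            )
        except (ValueError, TypeError) as exc:
            raise RowError(str(exc), lineno) from exc
        if rec.variant_id in seen:
            raise RowError(f"duplicate variant_id {rec.variant_id} in {disease} table",
                           lineno)
        seen.add(rec.variant_id)
        records.append(rec)
    records.sort(key=lambda r: (norm_chrom(r.chrom), r.pos))
    logger.info("read %d summary-stat records for %s from %s", len(records), disease, path)
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path,
                        build: str = DEFAULT_BUILD) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line(build))
        fh.write("\t".join(_SUMMARY_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.risk_allele}\t{r.other_allele}"
                     f"\t{r.beta!r}\t{r.se!r}\t{r.p!r}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, name: str, build: str = DEFAULT_BUILD) -> AnnotationTrack:
    """Read a 3+ column BED file (0-based half-open) as an annotation track."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        _check_build(first, build, path)
    rows, numbers = _open_rows(path)
    intervals: list[GenomicInterval] = []
    for raw, lineno in zip(rows, numbers):
        fields = raw.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: BED needs >= 3 columns, "
                              f"got {len(fields)}")
        try:
            iv = GenomicInterval(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                name=fields[3] if len(fields) > 3 else None,
            )
        except (ValueError, TypeError) as exc:
            raise RowError(str(exc), lineno) from exc
        intervals.append(iv)
    return AnnotationTrack(name=name, intervals=intervals)


def write_bed(track: AnnotationTrack, path, build: str = DEFAULT_BUILD) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line(build))
        for iv in track.intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# eQTL table
# ---------------------------------------------------------------------------

def read_eqtl_table(path, p_max: float = 0.05) -> list[EqtlRecord]:
    """Read a tab-separated (variant_id, gene, p) table, keeping rows with
    p strictly below ``p_max`` (the nominal-significance filter)."""
    rows, numbers = _open_rows(path)
    if not rows:
        warnings.warn(f"{path}: empty eQTL table", stacklevel=2)
        return []
    start = 1 if rows[0].split("\t")[0] == "variant_id" else 0
    records: list[EqtlRecord] = []
    n_total = 0
    for raw, lineno in zip(rows[start:], numbers[start:]):
        fields = raw.split("\t")
        if len(fields) < 3:
            raise RowError(f"expected 3 fields, got {len(fields)}", lineno)
        try:
            p = float(fields[2])
        except ValueError as exc:
            raise RowError(f"malformed p-value {fields[2]!r}", lineno) from exc
        n_total += 1
        if p < p_max:
            records.append(EqtlRecord(variant_id=fields[0], gene=fields[1], p=p))
    logger.info("retained %d/%d eQTL rows with p < %g from %s",
                len(records), n_total, p_max, path)
    if not records:
        warnings.warn(f"{path}: no eQTL rows pass p < {p_max}", stacklevel=2)
    return records


def write_eqtl_table(records: Iterable[EqtlRecord], path,
                     build: str = DEFAULT_BUILD) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line(build))
        fh.write("variant_id\tgene\tp\n")
        for r in records:
            fh.write(f"{r.variant_id}\t{r.gene}\t{r.p!r}\n")


# ---------------------------------------------------------------------------
# background trait-locus catalogue
# ---------------------------------------------------------------------------

def read_background(path, build: str = DEFAULT_BUILD) -> list[BackgroundLocus]:
    """Read a tab-separated (trait, chrom, pos, p) background catalogue."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        _check_build(first, build, path)
    rows, numbers = _open_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty background catalogue")
    start = 1 if rows[0].split("\t")[0] == "trait" else 0
    loci: list[BackgroundLocus] = []
    for raw, lineno in zip(rows[start:], numbers[start:]):
        fields = raw.split("\t")
        if len(fields) < 4:
            raise RowError(f"expected 4 fields, got {len(fields)}", lineno)
        try:
            loci.append(BackgroundLocus(trait=fields[0], chrom=fields[1],
                                        pos=int(fields[2]), p=float(fields[3])))
        except ValueError as exc:
            raise RowError(str(exc), lineno) from exc
    return loci


def write_background(loci: Iterable[BackgroundLocus], path,
                     build: str = DEFAULT_BUILD) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line(build))
        fh.write("trait\tchrom\tpos\tp\n")
        for b in loci:
            fh.write(f"{b.trait}\t{b.chrom}\t{b.pos}\t{b.p!r}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT dialect: name, description, tab-separated genes."""
    rows, numbers = _open_rows(path)
    sets: dict[str, set[str]] = {}
    for raw, lineno in zip(rows, numbers):
        fields = raw.split("\t")
        if len(fields) < 3:
            raise RowError("GMT rows need name, description and >= 1 gene", lineno)
        name = fields[0]
        if name in sets:
            raise RowError(f"duplicate gene-set name {name!r}", lineno)
        sets[name] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "-"] + sorted(genes)) + "\n")
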
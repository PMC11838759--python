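"""Annotation overlap counting and observed/expected enrichment.

A disease locus "overlaps" a track when at least one of its credible-set
variants falls inside a track interval (1-based point against 0-based
half-open interval: ``start < pos <= end``). The expected overlap rate comes
from a background catalogue of trait-associated loci; enrichment is the
observed overlap proportion divided by that rate, with a one-sided
upper-tail exact binomial p-value (enrichment only, matching how such
overlaps are reported).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError
from .finemap import CredibleSet
from .gwas_io import AnnotationTrack, BackgroundLocus, SummaryStatRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    disease: str
    track: str
    n_loci: int
    observed: int
    background_rate: float
    oe: float
    p: float


@dataclass(frozen=True)
class SpecificityResult:
    """Overlap-count folds of a reference cell type against each other cell
    type; infinite folds (zero count in the other type) are excluded from the
    mean and listed in ``excluded``."""

    reference_cell: str
    fold: dict[str, float]
    mean_fold: float
    excluded: tuple[str, ...] = ()


def variant_in_track(variant: SummaryStatRecord, track: AnnotationTrack) -> bool:
    """Whether the variant's 1-based position falls in any track interval."""
    return track.contains_point(variant.chrom, variant.pos)


def locus_overlaps_track(credible_set: CredibleSet, track: AnnotationTrack) -> bool:
    """Whether at least one in-set credible variant overlaps the track."""
    by_id = {m.variant_id: m for m in credible_set.locus.members}
    return any(variant_in_track(by_id[e.variant_id], track)
               for e in credible_set.entries)


def background_rate(background: Sequence[BackgroundLocus],
                    track: AnnotationTrack) -> float:
    """Fraction of background trait loci (points) covered by the track."""
    if not background:
        raise DegenerateInputError("background catalogue is empty; rate undefined")
    n_hit = sum(track.contains_point(b.chrom, b.pos) for b in background)
    rate = n_hit / len(background)
    if rate == 0.0:
        warnings.warn(f"track {track.name!r} covers no background locus; "
                      "downstream enrichment test is undefined", stacklevel=2)
    return rate


def oe_enrichment(credible_sets: Sequence[CredibleSet],
                  track: AnnotationTrack,
                  background: Sequence[BackgroundLocus],
                  disease: str = "all") -> EnrichmentResult:
    """Observed/expected overlap enrichment of disease loci against the
    background rate, with a one-sided exact binomial p-value
    P(X >= observed | n_loci, rate)."""
    if not credible_sets:
        raise DegenerateInputError("no credible sets supplied")
    rate = background_rate(background, track)
    if rate <= 0.0 or rate >= 1.0:
        raise DegenerateInputError(
            f"degenerate background rate {rate} for track {track.name!r}; "
            "the binomial test is undefined")
    n = len(credible_sets)
    observed = sum(locus_overlaps_track(cs, track) for cs in credible_sets)
    oe = (observed / n) / rate
    p = binomtest(observed, n, rate, alternative="greater").pvalue
    return EnrichmentResult(disease=disease, track=track.name, n_loci=n,
                            observed=observed, background_rate=rate,
                            oe=oe, p=float(p))


def variant_level_enrichment(variants: Sequence[SummaryStatRecord],
                             track: AnnotationTrack,
                             background: Sequence[BackgroundLocus],
                             disease: str = "all") -> EnrichmentResult:
    """Same test with individual credible variants as the counting unit."""
    if not variants:
        raise DegenerateInputError("no variants supplied")
    rate = background_rate(background, track)
    if rate <= 0.0 or rate >= 1.0:
        raise DegenerateInputError(
            f"degenerate background rate {rate} for track {track.name!r}")
    n = len(variants)
    observed = sum(variant_in_track(v, track) for v in variants)
    oe = (observed / n) / rate
    p = binomtest(observed, n, rate, alternative="greater").pvalue
    return EnrichmentResult(disease=disease, track=track.name, n_loci=n,
                            observed=observed, background_rate=rate,
                            oe=oe, p=float(p))


def specificity_fold(counts_by_cell_type: Mapping[str, int],
                     reference: str) -> SpecificityResult:
    """Fold of the reference cell type's overlap count over each other cell
    type's count; zero counts in the denominator give an undefined fold,
    which is excluded from the arithmetic mean and flagged."""
    if reference not in counts_by_cell_type:
        raise DegenerateInputError(f"reference cell type {reference!r} missing "
                                   f"from counts: {sorted(counts_by_cell_type)}")
    if any(c < 0 for c in counts_by_cell_type.values()):
        raise DegenerateInputError("overlap counts must be >= 0")
    ref_count = counts_by_cell_type[reference]
    folds: dict[str, float] = {}
    excluded: list[str] = []
    for cell, count in counts_by_cell_type.items():
        if cell == reference:
            continue
        if count == 0:
            excluded.append(cell)
        else:
            folds[cell] = ref_count / count
    if not folds:
        raise DegenerateInputError("no finite folds: all other counts are zero")
    mean_fold = sum(folds.values()) / len(folds)
    return SpecificityResult(reference_cell=reference, fold=folds,
                             mean_fold=mean_fold, excluded=tuple(excluded))


def add_bh_column(results: Sequence[EnrichmentResult]) -> list[tuple[EnrichmentResult, float]]:
    """Optional Benjamini-Hochberg adjusted p-values across a batch of
    enrichment results (off by default in the pipeline output)."""
    if not results:
        return []
    adjusted = multipletests([r.p for r in results], method="fdr_bh")[1]
    return list(zip(results, (float(q) for q in adjusted)))
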
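"""Locus delineation and 95% Bayesian credible sets.

Disease loci are delineated from genome-wide-significant variants by
single-linkage distance merging (gap <= 500 kb merges), after removing
variants in the MHC region, whose extreme LD makes summary-statistic
fine-mapping unreliable.

Per-variant evidence is summarised by Wakefield's approximate Bayes factor
under a single-causal-variant assumption with a N(0, W) prior on the
log-odds effect:

    ABF = sqrt(se^2 / (se^2 + W)) * exp( beta^2 * W / (2 * se^2 * (se^2 + W)) )

(oriented as evidence for association over the null, so ABF > 1 favours
association). Posterior inclusion probabilities are the ABFs normalised over
the locus; the 95% credible set is the smallest set of variants, taken in
decreasing posterior order, whose cumulative posterior reaches the coverage
target (ties at the inclusion boundary are all included).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .gwas_io import GenomicInterval, SummaryStatRecord, norm_chrom

logger = logging.getLogger(__name__)

#: MHC region on chromosome 6 (hg19 coordinates), excluded before merging.
MHC_HG19 = GenomicInterval("chr6", 25_000_000, 34_000_000, name="MHC")

#: Default prior variance on the log-odds effect size (sd 0.2).
DEFAULT_PRIOR_W = 0.04

GENOME_WIDE_P = 5e-8
MERGE_DIST = 500_000


@dataclass(frozen=True)
class Locus:
    """A merged disease signal: genome-wide-significant variants within
    ``merge_dist`` of each other on one chromosome."""

    disease: str
    chrom: str
    span: tuple[int, int]
    lead: SummaryStatRecord
    members: tuple[SummaryStatRecord, ...]

    @property
    def locus_id(self) -> str:
        return f"{self.disease}:{self.chrom}:{self.span[0]}-{self.span[1]}"


@dataclass(frozen=True)
class CredibleSetEntry:
    variant_id: str
    abf: float
    posterior: float


@dataclass(frozen=True)
class CredibleSet:
    """The variants whose summed posterior reaches the coverage target,
    in decreasing posterior order, with per-variant posteriors over the
    whole locus."""

    locus: Locus
    entries: tuple[CredibleSetEntry, ...]
    coverage: float

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(e.variant_id for e in self.entries)


def delineate_loci(records: Sequence[SummaryStatRecord],
                   disease: str,
                   p_threshold: float = GENOME_WIDE_P,
                   merge_dist: int = MERGE_DIST,
                   mhc: GenomicInterval | None = MHC_HG19) -> list[Locus]:
    """Delineate loci for one disease from its summary statistics.

    Keeps variants with p strictly below ``p_threshold``, removes variants
    inside the MHC interval (pass ``mhc=None`` to disable), then merges
    variants on the same chromosome by single linkage: a gap of exactly
    ``merge_dist`` base pairs still merges. The lead variant is the smallest
    p, ties broken by smaller position.
    """
    significant = [r for r in records if r.p < p_threshold]
    if mhc is not None:
        significant = [r for r in significant
                       if not mhc.contains_point(r.chrom, r.pos)]
    if not significant:
        warnings.warn(f"{disease}: no genome-wide-significant variants outside "
                      "the MHC; returning no loci", stacklevel=2)
        return []

    by_chrom: dict[str, list[SummaryStatRecord]] = {}
    for r in sorted(significant, key=lambda r: (norm_chrom(r.chrom), r.pos)):
        by_chrom.setdefault(norm_chrom(r.chrom), []).append(r)

    loci: list[Locus] = []
    for chrom, recs in by_chrom.items():
        cluster: list[SummaryStatRecord] = [recs[0]]
        for r in recs[1:]:
            if r.pos - cluster[-1].pos <= merge_dist:
                cluster.append(r)
            else:
                loci.append(_make_locus(disease, cluster))
                cluster = [r]
        loci.append(_make_locus(disease, cluster))
    loci.sort(key=lambda l: (norm_chrom(l.chrom), l.span[0]))
    logger.info("%s: %d loci from %d significant variants", disease,
                len(loci), len(significant))
    return loci


def _make_locus(disease: str, members: list[SummaryStatRecord]) -> Locus:
    lead = min(members, key=lambda r: (r.p, r.pos))
    return Locus(
        disease=disease,
        chrom=members[0].chrom,
        span=(members[0].pos, members[-1].pos),
        lead=lead,
        members=tuple(members),
    )


def log_wakefield_abf(beta: float, se: float, prior_w: float = DEFAULT_PRIOR_W) -> float:
    """Natural log of the Wakefield approximate Bayes factor (association over
    null); numerically safe for arbitrarily large ``|beta|/se``."""
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    if prior_w <= 0:
        raise DomainError(f"prior_w must be > 0, got {prior_w}")
    v = se * se
    return 0.5 * math.log(v / (v + prior_w)) + (beta * beta * prior_w) / (2 * v * (v + prior_w))


def wakefield_abf(beta: float, se: float, prior_w: float = DEFAULT_PRIOR_W) -> float:
    """Wakefield approximate Bayes factor; may overflow to ``inf`` for extreme
    z-scores — use :func:`log_wakefield_abf` when combining many variants."""
    la = log_wakefield_abf(beta, se, prior_w)
    try:
        return math.exp(la)
    except OverflowError:
        return math.inf


def credible_set(locus: Locus,
                 coverage_target: float = 0.95,
                 prior_w: float = DEFAULT_PRIOR_W) -> CredibleSet:
    """Compute the credible set of a locus under the single-causal model.

    Posteriors are the softmax of log-ABFs over all locus members; entries
    are included in decreasing posterior order until the cumulative posterior
    reaches ``coverage_target``, then extended to take in any variants tied
    (to within 1e-12) with the last included posterior.
    """
    members = locus.members
    if not members:
        raise DomainError("locus has no members")
    log_abf = np.array([log_wakefield_abf(r.beta, r.se, prior_w) for r in members])
    shifted = log_abf - log_abf.max()
    post = np.exp(shifted)
    post /= post.sum()

    # stable ordering: posterior descending, position ascending on ties
    order = sorted(range(len(members)), key=lambda i: (-post[i], members[i].pos))
    cum = 0.0
    included: list[int] = []
    for rank, i in enumerate(order):
        cum += post[i]
        included.append(i)
        if cum >= coverage_target:
            boundary = post[i]
            for j in order[rank + 1:]:
                if abs(post[j] - boundary) <= 1e-12:
                    cum += post[j]
                    included.append(j)
                else:
                    break
            break

    entries = tuple(
        CredibleSetEntry(
            variant_id=members[i].variant_id,
            abf=float(np.exp(min(log_abf[i], 700.0))),
            posterior=float(post[i]),
        )
        for i in included
    )
    return CredibleSet(locus=locus, entries=entries, coverage=float(cum))


def credible_sets_for_disease(records: Sequence[SummaryStatRecord],
                              disease: str,
                              p_threshold: float = GENOME_WIDE_P,
                              merge_dist: int = MERGE_DIST,
                              mhc: GenomicInterval | None = MHC_HG19,
                              coverage_target: float = 0.95,
                              prior_w: float = DEFAULT_PRIOR_W) -> list[CredibleSet]:
    """Delineate loci and compute one credible set per locus."""
    loci = delineate_loci(records, disease, p_threshold, merge_dist, mhc)
    return [credible_set(l, coverage_target, prior_w) for l in loci]
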
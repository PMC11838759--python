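"""Ancestry risk-allele-frequency contrasts, their joint regression on
regulatory annotations, and gene-set enrichment of eQTL target genes.

Per variant, the risk-allele frequency (RAF) of each ancestry group is the
unweighted mean over its constituent populations. A variant is flagged
``afr_higher`` when its African-ancestry RAF strictly exceeds the
European-ancestry RAF, ``eur_higher`` for the converse, and ``tie`` on exact
equality. The flag is then modelled by logistic regression (outcome
afr_higher = 1, eur_higher = 0, ties excluded) on binary annotation-overlap
indicators, either jointly or one mark at a time; exp(coefficient) is
reported as an odds ratio with a Wald p-value.

Gene-set enrichment of eQTL target genes uses the one-sided Fisher exact
test (upper-tail hypergeometric) on the 2x2 selected-by-membership table,
with gene sets of 500 or more genes rejected by the term-size filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom

from .errors import DegenerateInputError, DomainError, RowError
from .finemap import CredibleSet
from .gwas_io import EqtlRecord

logger = logging.getLogger(__name__)

Direction = Literal["afr_higher", "eur_higher", "tie"]

FREQ_COLUMNS = ("variant_id", "raf_afr", "raf_eur", "n_pops_afr", "n_pops_eur")

#: gene sets at or above this size are rejected (term-size filter)
MAX_TERM_SIZE = 500


@dataclass(frozen=True)
class RafFlag:
    variant_id: str
    direction: Direction


@dataclass(frozen=True)
class GlmResult:
    term: str
    or_estimate: float
    p: float
    model: Literal["joint", "marginal"]


@dataclass(frozen=True)
class GeneSetEnrichment:
    set_name: str
    universe_size: int
    set_size: int
    selected_size: int
    hits: int
    or_estimate: float
    p: float


# ---------------------------------------------------------------------------
# frequency table I/O and aggregation
# ---------------------------------------------------------------------------

def aggregate_population_freqs(pop_freqs: pd.DataFrame,
                               weights: Mapping[str, float] | None = None
                               ) -> pd.DataFrame:
    """Aggregate per-population RAFs into per-ancestry-group RAFs.

    ``pop_freqs`` has columns (variant_id, population, group, raf) with group
    in {afr, eur}. The default is the unweighted mean across populations; a
    mapping population -> weight switches to a weighted mean.
    """
    rows = []
    for vid, sub in pop_freqs.groupby("variant_id", sort=True):
        entry = {"variant_id": vid}
        for group, col in (("afr", "raf_afr"), ("eur", "raf_eur")):
            g = sub[sub["group"] == group]
            if g.empty:
                raise DegenerateInputError(f"variant {vid}: no {group} populations")
            if weights is None:
                entry[col] = float(g["raf"].mean())
            else:
                w = np.array([weights[p] for p in g["population"]])
                entry[col] = float(np.average(g["raf"], weights=w))
            entry[f"n_pops_{group}"] = len(g)
        rows.append(entry)
    return pd.DataFrame(rows, columns=list(FREQ_COLUMNS))


def read_freq_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise RowError(f"{path}: missing column(s) {missing}")
    bad = df[(df["raf_afr"] < 0) | (df["raf_afr"] > 1)
             | (df["raf_eur"] < 0) | (df["raf_eur"] > 1)]
    if not bad.empty:
        raise RowError(f"{path}: frequencies outside [0, 1] for "
                       f"{bad['variant_id'].tolist()[:5]}")
    return df


def write_freq_table(df: pd.DataFrame, path) -> None:
    from . import __version__
    with open(path, "w") as fh:
        fh.write(f"# skingwas={__version__}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# direction flags and proportions
# ---------------------------------------------------------------------------

def flag_raf_direction(freqs: pd.DataFrame,
                       variant_ids: Iterable[str]) -> list[RafFlag]:
    """One flag per queried variant, by strict comparison of group RAFs.
    Variants absent from the table are an error (never silently skipped)."""
    table = freqs.set_index("variant_id")
    ids = list(variant_ids)
    missing = [v for v in ids if v not in table.index]
    if missing:
        raise DegenerateInputError(
            f"{len(missing)} variant(s) missing from the frequency table: "
            f"{missing[:10]}")
    flags = []
    for vid in ids:
        afr, eur = table.at[vid, "raf_afr"], table.at[vid, "raf_eur"]
        if afr > eur:
            direction: Direction = "afr_higher"
        elif eur > afr:
            direction = "eur_higher"
        else:
            direction = "tie"
        flags.append(RafFlag(variant_id=vid, direction=direction))
    return flags


def locus_direction(credible_set: CredibleSet,
                    flags_by_variant: Mapping[str, Direction]) -> Direction:
    """Majority direction over a locus's in-set variants; equal afr/eur
    counts give a tie."""
    n_afr = sum(flags_by_variant[v] == "afr_higher" for v in credible_set.variant_ids)
    n_eur = sum(flags_by_variant[v] == "eur_higher" for v in credible_set.variant_ids)
    if n_afr > n_eur:
        return "afr_higher"
    if n_eur > n_afr:
        return "eur_higher"
    return "tie"


def raf_proportions(flags: Sequence[RafFlag],
                    unit: Literal["variant", "locus"] = "variant",
                    credible_sets: Sequence[CredibleSet] | None = None
                    ) -> dict[Direction, float]:
    """Proportions of afr_higher / eur_higher / tie for one disease.

    ``unit='variant'`` counts flags directly; ``unit='locus'`` takes the
    majority direction of each credible set's in-set variants.
    """
    if unit == "variant":
        units: list[Direction] = [f.direction for f in flags]
    elif unit == "locus":
        if credible_sets is None:
            raise DomainError("locus unit requires credible_sets")
        by_variant = {f.variant_id: f.direction for f in flags}
        units = [locus_direction(cs, by_variant) for cs in credible_sets]
    else:
        raise DomainError(f"unknown unit {unit!r}")
    if not units:
        raise DegenerateInputError("no flags to summarise")
    n = len(units)
    return {
        "afr_higher": units.count("afr_higher") / n,
        "eur_higher": units.count("eur_higher") / n,
        "tie": units.count("tie") / n,
    }


# ---------------------------------------------------------------------------
# GLM of the afr_higher flag on annotation indicators
# ---------------------------------------------------------------------------

def fit_raf_annotation_glm(flags: Sequence[RafFlag],
                           indicators: pd.DataFrame,
                           mode: Literal["joint", "marginal"] = "joint"
                           ) -> list[GlmResult]:
    """Logistic regression of 1{afr_higher} on annotation-overlap indicators.

    ``indicators`` is indexed by variant_id with one boolean/0-1 column per
    mark. Tie-flagged variants are excluded. ``joint`` fits all predictors in
    one model; ``marginal`` fits one single-predictor model per mark. The
    intercept is fit but not reported. Constant predictors and complete
    separation raise a typed error naming the term.
    """
    # diseases can share loci, so the same variant may be flagged repeatedly;
    # consistent duplicates collapse to one observation, conflicts are an error
    by_id: dict[str, Direction] = {}
    for f in flags:
        if by_id.setdefault(f.variant_id, f.direction) != f.direction:
            raise DegenerateInputError(
                f"conflicting flags for variant {f.variant_id}")
    kept = [RafFlag(v, d) for v, d in by_id.items() if d != "tie"]
    if not kept:
        raise DegenerateInputError("all flags are ties; outcome undefined")
    missing = [f.variant_id for f in kept if f.variant_id not in indicators.index]
    if missing:
        raise DegenerateInputError(f"indicator table missing variants: {missing[:10]}")
    y = pd.Series([1.0 if f.direction == "afr_higher" else 0.0 for f in kept],
                  index=[f.variant_id for f in kept])
    if y.nunique() < 2:
        raise DegenerateInputError("outcome has a single class; GLM undefined")
    X = indicators.loc[y.index].astype(float)

    for term in X.columns:
        if X[term].nunique() < 2:
            raise DegenerateInputError(f"constant predictor {term!r}")
        tab = pd.crosstab(y, X[term])
        if (tab == 0).any().any() and tab.shape == (2, 2):
            d = np.asarray(tab)
            # complete separation: the predictor's levels split the outcome
            if (d[0, 1] == 0 and d[1, 0] == 0) or (d[0, 0] == 0 and d[1, 1] == 0):
                raise DegenerateInputError(f"complete separation on term {term!r}")

    def _fit(cols: list[str]) -> list[GlmResult]:
        design = sm.add_constant(X[cols], has_constant="add")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels-internal failures
            raise DegenerateInputError(f"logistic fit failed for {cols}: {exc}") from exc
        out = []
        for term in cols:
            coef = fit.params[term]
            if not np.isfinite(coef) or abs(coef) > 15:
                raise DegenerateInputError(
                    f"term {term!r} did not converge to a finite effect "
                    "(quasi-separation)")
            out.append(GlmResult(term=term, or_estimate=float(np.exp(coef)),
                                 p=float(fit.pvalues[term]),
                                 model=mode))
        return out

    if mode == "joint":
        return _fit(list(X.columns))
    if mode == "marginal":
        results: list[GlmResult] = []
        for term in X.columns:
            results.extend(_fit([term]))
        return results
    raise DomainError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def geneset_enrichment(selected_genes: set[str],
                       gene_set: set[str],
                       universe: set[str],
                       set_name: str = "gene_set",
                       max_term_size: int = MAX_TERM_SIZE) -> GeneSetEnrichment:
    """One-sided Fisher exact enrichment of ``selected_genes`` in
    ``gene_set`` within ``universe``.

    p is the upper-tail hypergeometric probability P(hits >= observed);
    the odds ratio is (a*d)/(b*c) on the 2x2 table, with a Haldane-Anscombe
    0.5 correction applied iff any cell is zero. Gene sets of
    ``max_term_size`` or more genes are rejected.
    """
    if not universe:
        raise DegenerateInputError("empty gene universe")
    gene_set = gene_set & universe
    selected = selected_genes & universe
    if not selected:
        raise DegenerateInputError("no selected genes in the universe")
    if not gene_set:
        raise DegenerateInputError(f"gene set {set_name!r} has no genes in the universe")
    if len(gene_set) >= max_term_size:
        raise DomainError(f"gene set {set_name!r} has {len(gene_set)} genes; "
                          f"term-size filter requires < {max_term_size}")
    m, n_set, n_sel = len(universe), len(gene_set), len(selected)
    a = len(selected & gene_set)                 # selected, in set
    b = n_sel - a                                # selected, not in set
    c = n_set - a                                # in set, not selected
    d = m - n_set - n_sel + a                    # neither
    p = float(hypergeom.sf(a - 1, m, n_set, n_sel))
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
    else:
        a_, b_, c_, d_ = a, b, c, d
    or_estimate = (a_ * d_) / (b_ * c_)
    return GeneSetEnrichment(set_name=set_name, universe_size=m, set_size=n_set,
                             selected_size=n_sel, hits=a,
                             or_estimate=float(or_estimate), p=p)


def collect_eqtl_targets(credible_sets: Sequence[CredibleSet],
                         eqtl_records: Sequence[EqtlRecord],
                         flags: Sequence[RafFlag],
                         direction: Direction) -> set[str]:
    """Union of eQTL target genes over in-set credible variants whose RAF
    flag matches ``direction``."""
    wanted = {f.variant_id for f in flags if f.direction == direction}
    in_set = {v for cs in credible_sets for v in cs.variant_ids}
    chosen = wanted & in_set
    genes = {r.gene for r in eqtl_records if r.variant_id in chosen}
    if not genes:
        warnings.warn(f"no eQTL target genes for direction {direction!r}",
                      stacklevel=2)
    return genes
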
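"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes, not
any particular dataset:

* GWAS summary statistics with one causal variant per locus. Non-causal
  variants are LD partners of the causal variant with correlation r drawn
  uniform on [0.2, 0.95]; their true log-odds effects are attenuated,
  ``beta_j = r_j * beta_causal``. All variants in a locus share one allele
  frequency (variants in strong LD necessarily have similar frequencies),
  so attenuation on the beta scale equals attenuation on the z scale.
  Sampling noise is marginally Normal(0, se) per variant and jointly follows
  the standard one-factor LD structure: ``noise_j = se_j * (r_j * eta +
  sqrt(1 - r_j^2) * eps_j)`` with eta shared across the locus. Standard
  errors use the additive log-odds approximation
  ``se = sqrt(1 / (2 * n_eff * p * (1 - p)))`` with
  ``n_eff = n_cases * n_controls / (n_cases + n_controls)``.

* Ancestry allele frequencies from the Balding-Nichols model: each ancestry
  group's frequency is Beta-distributed around the ancestral frequency with
  divergence FST, and the five constituent populations of each group scatter
  around their group frequency with a small within-group FST.

* Annotation tracks that cover causal variants with an elevated probability
  in the planted-enriched tracks, and all other positions (non-causal
  variants, background trait loci) at the null rate.

* eQTL target tables, gene sets with planted enrichment among variants whose
  risk allele is more frequent in the African-ancestry group, a labelled
  expression matrix with a planted module shift in one cell type, and a
  paired stimulated/unstimulated count table with group-specific fold
  changes.

All output is a deterministic function of the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DomainError
from .gwas_io import (AnnotationTrack, BackgroundLocus, EqtlRecord,
                      GenomicInterval, SummaryStatRecord, variant_id)

logger = logging.getLogger(__name__)

#: population size used to clip simulated frequencies to [1/2N, 1 - 1/2N]
CLIP_N = 5000

#: autosomes used for locus placement; chr6 is avoided so simulated loci
#: never fall in the MHC exclusion window
_CHROMS = [f"chr{i}" for i in range(1, 23) if i != 6]

DISEASES = ("acne", "AA", "AD", "psoriasis", "SLE", "SSc", "vitiligo")

TRACK_NAMES = ("ATAC", "BRU", "HIC_LOOP_END", "EQTL")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror a seven-disease inflammatory-skin-disease study:
    ~35 loci per disease, ten candidate variants per locus, 20k/20k
    case-control samples, African/European divergence FST = 0.1, causal
    log-odds 0.25, and annotation coverage of 0.334 at enriched causal
    variants against a 0.2 background rate (observed/expected ~ 1.67).
    """

    n_diseases: int = 7
    loci_per_disease: int = 35
    variants_per_locus: int = 10
    n_cases: int = 20_000
    n_controls: int = 20_000
    fst: float = 0.1
    causal_beta: float = 0.25
    annotation_overlap_prob_null: float = 0.2
    annotation_overlap_prob_enriched: float = 0.334
    seed: int = 0

    def __post_init__(self):
        if self.n_diseases < 1:
            raise DomainError("n_diseases must be >= 1")
        if self.loci_per_disease < 1 or self.variants_per_locus < 1:
            raise DomainError("loci_per_disease and variants_per_locus must be >= 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise DomainError("n_cases and n_controls must be >= 1")
        for name in ("fst", "annotation_overlap_prob_null",
                     "annotation_overlap_prob_enriched"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise DomainError(f"{name} must lie in (0, 1), got {v}")

    @property
    def diseases(self) -> tuple[str, ...]:
        if self.n_diseases <= len(DISEASES):
            return DISEASES[: self.n_diseases]
        return DISEASES + tuple(f"disease{i}" for i in range(len(DISEASES), self.n_diseases))

    @property
    def n_eff(self) -> float:
        return self.n_cases * self.n_controls / (self.n_cases + self.n_controls)


@dataclass
class GroundTruth:
    """Planted truth: the causal variant of each locus, per-variant ancestral
    and per-group frequencies, and which tracks are enriched."""

    causal_variants: dict[str, list[str]]            # disease -> causal id per locus
    p_anc: dict[str, float]                          # variant_id -> ancestral freq
    p_afr: dict[str, float]
    p_eur: dict[str, float]
    enriched_tracks: set[str] = field(default_factory=lambda: {"ATAC", "BRU"})

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["enriched_tracks"] = sorted(self.enriched_tracks)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["enriched_tracks"] = set(payload["enriched_tracks"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# population frequencies
# ---------------------------------------------------------------------------

def balding_nichols(p_anc: float, fst: float, rng: np.random.Generator,
                    size=None) -> np.ndarray | float:
    """Draw population frequencies from the Balding-Nichols Beta distribution
    with mean ``p_anc`` and shape ``(p_anc (1-fst)/fst, (1-p_anc)(1-fst)/fst)``,
    clipped away from fixation at 1/(2N) with N = 5000."""
    if not (0 < p_anc < 1):
        raise DomainError(f"p_anc must lie in (0, 1), got {p_anc}")
    if not (0 < fst < 1):
        raise DomainError(f"fst must lie in (0, 1), got {fst}")
    scale = (1 - fst) / fst
    draw = rng.beta(p_anc * scale, (1 - p_anc) * scale, size=size)
    lo = 1.0 / (2 * CLIP_N)
    return np.clip(draw, lo, 1 - lo) if size is not None else float(min(max(draw, lo), 1 - lo))


def simulate_population_freqs(p_anc: float, fst: float,
                              rng: np.random.Generator | int
                              ) -> tuple[float, float]:
    """Draw one African-ancestry and one European-ancestry frequency,
    independently, around the ancestral frequency."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    p_afr = balding_nichols(p_anc, fst, rng)
    p_eur = balding_nichols(p_anc, fst, rng)
    return p_afr, p_eur


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _locus_positions(locus_index: int, n_variants: int) -> tuple[str, np.ndarray]:
    """Deterministic locus placement: cycle the autosomes (skipping chr6),
    5 Mb between loci on a chromosome, variants 1 kb apart."""
    chrom = _CHROMS[locus_index % len(_CHROMS)]
    base = 10_000_000 + (locus_index // len(_CHROMS)) * 5_000_000
    return chrom, base + 1000 * np.arange(n_variants)


def simulate_summary_stats(cfg: SimConfig
                           ) -> tuple[dict[str, list[SummaryStatRecord]], GroundTruth]:
    """Simulate per-disease summary statistics with one causal variant per
    locus, plus the planted ground truth (causal ids and ancestry
    frequencies for every variant)."""
    rng = np.random.default_rng(cfg.seed)
    alleles = np.array(list("ACGT"))
    stats: dict[str, list[SummaryStatRecord]] = {}
    truth = GroundTruth(causal_variants={}, p_anc={}, p_afr={}, p_eur={})

    for d_idx, disease in enumerate(cfg.diseases):
        records: list[SummaryStatRecord] = []
        causal_ids: list[str] = []
        for li in range(cfg.loci_per_disease):
            # globally unique locus slot so diseases never share positions
            chrom, positions = _locus_positions(
                d_idx * cfg.loci_per_disease + li, cfg.variants_per_locus)
            m = cfg.variants_per_locus
            p_locus = float(rng.uniform(0.05, 0.95))
            se = float(np.sqrt(1.0 / (2 * cfg.n_eff * p_locus * (1 - p_locus))))
            r = rng.uniform(0.2, 0.95, size=m)
            causal = int(rng.integers(m))
            r[causal] = 1.0
            true_beta = r * cfg.causal_beta
            eta = rng.normal()
            eps = rng.normal(size=m)
            noise = se * (r * eta + np.sqrt(1 - r ** 2) * eps)
            beta_obs = true_beta + noise
            z = beta_obs / se
            pvals = 2 * norm.sf(np.abs(z))
            pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
            ra, oa = rng.choice(alleles, size=2, replace=False)
            for j in range(m):
                rec = SummaryStatRecord(
                    chrom=chrom, pos=int(positions[j]),
                    risk_allele=str(ra), other_allele=str(oa),
                    beta=float(beta_obs[j]), se=se, p=float(pvals[j]),
                )
                records.append(rec)
                truth.p_anc[rec.variant_id] = p_locus
                p_afr, p_eur = simulate_population_freqs(p_locus, cfg.fst, rng)
                truth.p_afr[rec.variant_id] = p_afr
                truth.p_eur[rec.variant_id] = p_eur
                if j == causal:
                    causal_ids.append(rec.variant_id)
        stats[disease] = records
        truth.causal_variants[disease] = causal_ids
    return stats, truth


# ---------------------------------------------------------------------------
# annotation tracks and background catalogue
# ---------------------------------------------------------------------------

def simulate_background(n_traits: int, rng: np.random.Generator | int,
                        ) -> list[BackgroundLocus]:
    """Background trait-locus catalogue: one best-signal point per trait,
    placed on the same chromosome grid as the simulated loci but offset so
    background loci never coincide with disease variants."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    loci = []
    for t in range(n_traits):
        chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
        pos = int(rng.integers(5_000_000, 200_000_000))
        loci.append(BackgroundLocus(trait=f"trait{t:05d}", chrom=chrom, pos=pos,
                                    p=float(rng.uniform(1e-30, 5e-8))))
    return loci


def _cover_position(chrom: str, pos: int, rng: np.random.Generator,
                    name: str | None = None) -> GenomicInterval:
    """A 200-1000 bp interval covering the 1-based position ``pos``."""
    width = int(rng.integers(200, 1001))
    start = int(rng.integers(max(0, pos - width), pos))  # start < pos <= start+width
    return GenomicInterval(chrom=chrom, start=start, end=start + width, name=name)


def simulate_annotation_tracks(stats: dict[str, list[SummaryStatRecord]],
                               truth: GroundTruth,
                               cfg: SimConfig,
                               background: list[BackgroundLocus] | None = None,
                               track_names: tuple[str, ...] = TRACK_NAMES,
                               rng: np.random.Generator | int | None = None,
                               ) -> list[AnnotationTrack]:
    """Generate one track per name. Causal variants of tracks named in
    ``truth.enriched_tracks`` are covered with the enriched probability;
    every other variant and every background locus with the null rate.
    ``rng`` overrides the default ``cfg.seed + 1`` stream so coverage can be
    redrawn while the summary statistics stay fixed."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    causal = {v for ids in truth.causal_variants.values() for v in ids}
    tracks: list[AnnotationTrack] = []
    for name in track_names:
        p_causal = (cfg.annotation_overlap_prob_enriched
                    if name in truth.enriched_tracks
                    else cfg.annotation_overlap_prob_null)
        intervals: list[GenomicInterval] = []
        seen: set[str] = set()
        for records in stats.values():
            for rec in records:
                if rec.variant_id in seen:
                    continue
                seen.add(rec.variant_id)
                prob = p_causal if rec.variant_id in causal else cfg.annotation_overlap_prob_null
                if rng.random() < prob:
                    intervals.append(_cover_position(rec.chrom, rec.pos, rng))
        for bg in (background or []):
            if rng.random() < cfg.annotation_overlap_prob_null:
                intervals.append(_cover_position(bg.chrom, bg.pos, rng))
        tracks.append(AnnotationTrack(name=name, intervals=intervals))
    return tracks


# ---------------------------------------------------------------------------
# eQTL table and gene sets
# ---------------------------------------------------------------------------

def simulate_gene_universe(n_genes: int = 2000) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def simulate_eqtl_table(stats: dict[str, list[SummaryStatRecord]],
                        truth: GroundTruth,
                        universe: list[str],
                        rng: np.random.Generator | int,
                        planted_size: int = 20,
                        planted_prob: float = 0.7,
                        targets_per_variant: int = 2,
                        eqtl_prob: float = 0.5) -> list[EqtlRecord]:
    """eQTL variant-gene pairs. Each variant is an eQTL with probability
    ``eqtl_prob``; AfrA-higher variants draw their target genes from the
    planted set with probability ``planted_prob`` per target, others draw
    uniformly from the rest of the universe."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    planted = universe[:planted_size]
    rest = universe[planted_size:]
    records: list[EqtlRecord] = []
    seen: set[str] = set()
    for recs in stats.values():
        for rec in recs:
            vid = rec.variant_id
            if vid in seen:
                continue
            seen.add(vid)
            if rng.random() >= eqtl_prob:
                continue
            afr_higher = truth.p_afr[vid] > truth.p_eur[vid]
            genes: set[str] = set()
            for _ in range(targets_per_variant):
                if afr_higher and rng.random() < planted_prob:
                    genes.add(str(rng.choice(planted)))
                else:
                    genes.add(str(rng.choice(rest)))
            for g in sorted(genes):
                records.append(EqtlRecord(variant_id=vid, gene=g,
                                          p=float(rng.uniform(1e-8, 0.05))))
    return records


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def simulate_expression_matrix(universe: list[str],
                               module_genes: list[str],
                               rng: np.random.Generator | int,
                               cell_types: tuple[str, ...] = (
                                   "keratinocyte", "myeloid", "tcell", "fibroblast"),
                               n_cells_per_type: int = 50,
                               elevated_cell_type: str = "keratinocyte",
                               shift: float = 1.0,
                               ) -> tuple[pd.DataFrame, pd.Series]:
    """Genes x cells matrix of non-negative normalised expression with the
    module genes shifted up by ``shift`` in one cell type. Returns the
    matrix and a per-cell cell-type label series."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n_cells = n_cells_per_type * len(cell_types)
    base = rng.lognormal(mean=1.0, sigma=0.5, size=len(universe))
    expr = rng.lognormal(mean=0.0, sigma=0.3, size=(len(universe), n_cells)) * base[:, None]
    labels = pd.Series(
        [ct for ct in cell_types for _ in range(n_cells_per_type)],
        index=[f"cell{i:04d}" for i in range(n_cells)], name="cell_type",
    )
    df = pd.DataFrame(expr, index=universe, columns=labels.index)
    module_idx = [g for g in module_genes if g in df.index]
    mask = (labels == elevated_cell_type).to_numpy()
    df.loc[module_idx, mask] += shift
    return df, labels


def simulate_stimulation_matrix(n_genes: int,
                                n_donors_per_group: int,
                                planted: dict[str, tuple[float, float]] | None,
                                rng: np.random.Generator | int,
                                noise_sigma: float = 0.15) -> pd.DataFrame:
    """Paired stimulated/unstimulated counts for two donor groups.

    ``planted`` maps gene name -> (fold change in group A, fold change in
    group B) applied to the stimulated sample; unmentioned genes respond
    with fold change 1. Returns a long table with columns (gene, donor,
    group, condition, count).
    """
    if n_donors_per_group < 1:
        raise DomainError("n_donors_per_group must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    planted = planted or {}
    genes = [f"SG{i:04d}" for i in range(n_genes)]
    for g in planted:
        if g not in genes:
            raise DomainError(f"planted gene {g!r} not among the {n_genes} simulated genes")
    rows = []
    base = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    for group_idx, group in enumerate(("A", "B")):
        for d in range(n_donors_per_group):
            donor = f"{group}{d:02d}"
            donor_effect = rng.lognormal(mean=0.0, sigma=0.05)
            for gi, gene in enumerate(genes):
                fc = planted.get(gene, (1.0, 1.0))[group_idx]
                un = base[gi] * donor_effect * rng.lognormal(0.0, noise_sigma)
                st = base[gi] * donor_effect * fc * rng.lognormal(0.0, noise_sigma)
                rows.append((gene, donor, group, "unstimulated", un))
                rows.append((gene, donor, group, "stimulated", st))
    return pd.DataFrame(rows, columns=["gene", "donor", "group", "condition", "count"])


# ---------------------------------------------------------------------------
# full input bundle
# ---------------------------------------------------------------------------

def simulate_freq_table(truth: GroundTruth, cfg: SimConfig,
                        within_fst: float = 0.01, n_pops: int = 5) -> pd.DataFrame:
    """Per-variant risk-allele frequencies aggregated (unweighted mean) over
    ``n_pops`` constituent populations per ancestry group. Populations
    scatter around the group frequency with a small within-group FST."""
    rng = np.random.default_rng(cfg.seed + 2)
    rows = []
    for vid in truth.p_anc:
        pops_afr = balding_nichols(truth.p_afr[vid], within_fst, rng, size=n_pops)
        pops_eur = balding_nichols(truth.p_eur[vid], within_fst, rng, size=n_pops)
        rows.append((vid, float(np.mean(pops_afr)), float(np.mean(pops_eur)),
                     n_pops, n_pops))
    return pd.DataFrame(rows, columns=["variant_id", "raf_afr", "raf_eur",
                                       "n_pops_afr", "n_pops_eur"])


def write_bundle(cfg: SimConfig, outdir,
                 n_background: int = 2000,
                 planted_set_size: int = 20) -> Path:
    """Generate every pipeline input into ``outdir`` plus a
    ``ground_truth.json``; returns the directory path."""
    from . import gwas_io
    from .ancestry import write_freq_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stats, truth = simulate_summary_stats(cfg)
    rng = np.random.default_rng(cfg.seed + 3)

    for disease, records in stats.items():
        gwas_io.write_summary_stats(records, outdir / f"sumstats_{disease}.tsv")

    background = simulate_background(n_background, rng)
    gwas_io.write_background(background, outdir / "background.tsv")

    tracks = simulate_annotation_tracks(stats, truth, cfg, background)
    for track in tracks:
        gwas_io.write_bed(track, outdir / f"track_{track.name}.bed")

    universe = simulate_gene_universe()
    eqtl = simulate_eqtl_table(stats, truth, universe, rng, planted_size=planted_set_size)
    gwas_io.write_eqtl_table(eqtl, outdir / "eqtl.tsv")

    gene_sets = simulate_gene_sets(universe, rng, planted_size=planted_set_size)
    gwas_io.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    with open(outdir / "gene_universe.txt", "w") as fh:
        fh.write("\n".join(universe) + "\n")

    freqs = simulate_freq_table(truth, cfg)
    write_freq_table(freqs, outdir / "ancestry_freqs.tsv")

    module_genes = universe[:planted_set_size]
    expr, labels = simulate_expression_matrix(universe[:500], module_genes, rng)
    expr.to_csv(outdir / "expression_matrix.tsv", sep="\t")
    labels.to_csv(outdir / "cell_labels.tsv", sep="\t")

    # responders whose group-A excess scales with the average response
    # (log2 fcA = 1.25 s, log2 fcB = 0.75 s -> diff = s/2, avg = s)
    planted_stim = {f"SG{i:04d}": (2.0 ** (1.25 * (1.0 + 0.1 * i)),
                                   2.0 ** (0.75 * (1.0 + 0.1 * i)))
                    for i in range(15)}
    stim = simulate_stimulation_matrix(n_genes=300, n_donors_per_group=3,
                                       planted=planted_stim, rng=rng)
    stim.to_csv(outdir / "stimulation.tsv", sep="\t", index=False)

    truth.to_json(outdir / "ground_truth.json")
    logger.info("wrote synthetic bundle to %s", outdir)
    return outdir


def simulate_gene_sets(universe: list[str], rng: np.random.Generator | int,
                       planted_name: str = "IL1_LIKE_SET",
                       planted_size: int = 20, n_null_sets: int = 10,
                       null_size: int = 50) -> dict[str, set[str]]:
    """A planted set (the first genes of the universe, which the eQTL
    generator preferentially assigns to AfrA-higher variants) plus random
    null sets."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    sets = {planted_name: set(universe[:planted_size])}
    for k in range(n_null_sets):
        sets[f"NULL_SET_{k:02d}"] = set(
            str(g) for g in rng.choice(universe, size=null_size, replace=False))
    return sets
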
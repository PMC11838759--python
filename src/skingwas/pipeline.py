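"""End-to-end orchestration: wiring the stages into one reproducible run.

Stages communicate via files only; every stage's table is written to the run
directory so any stage can be re-run from intermediates. Given the same
inputs, configuration and seed, a run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ancestry, expression, finemap, gwas_io, overlap
from .errors import DegenerateInputError, DomainError, SkingwasError, StageError
from .gwas_io import GenomicInterval

logger = logging.getLogger(__name__)


def parse_mhc(spec: str) -> GenomicInterval | None:
    """Parse 'chrom:start-end' (or 'none') into the MHC exclusion interval."""
    if spec.lower() == "none":
        return None
    try:
        chrom, rng = spec.split(":")
        start, end = (int(x.replace(",", "")) for x in rng.split("-"))
    except ValueError as exc:
        raise DomainError(f"cannot parse MHC interval {spec!r}; expected "
                          "'chrom:start-end' or 'none'") from exc
    return GenomicInterval(chrom, start, end, name="MHC")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    sumstats: dict[str, str]            # disease -> summary-stat TSV
    tracks: dict[str, str]              # track name -> BED
    background: str
    eqtl: str
    freqs: str
    gene_sets: str                      # GMT
    gene_universe: str                  # one gene per line
    expression_matrix: str | None = None
    cell_labels: str | None = None
    stimulation: str | None = None
    outdir: str = "skingwas_run"
    build: str = gwas_io.DEFAULT_BUILD
    p_threshold: float = finemap.GENOME_WIDE_P
    merge_dist: int = finemap.MERGE_DIST
    prior_w: float = finemap.DEFAULT_PRIOR_W
    coverage: float = 0.95
    eqtl_p: float = 0.05
    fc_min: float = 1.5
    fdr_max: float = 0.10
    mhc: str = "chr6:25000000-34000000"
    module_set_name: str | None = None  # default: first set in the GMT
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_threshold < 1) or not (0 < self.coverage <= 1):
            raise DomainError("p_threshold in (0,1) and coverage in (0,1] required")
        if self.prior_w <= 0 or self.merge_dist < 0:
            raise DomainError("prior_w must be > 0 and merge_dist >= 0")
        if not (0 < self.eqtl_p <= 1) or not (0 <= self.fdr_max <= 1):
            raise DomainError("eqtl_p in (0,1] and fdr_max in [0,1] required")
        parse_mhc(self.mhc)  # fail fast on a malformed interval

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload.update(overrides)
        return cls(**payload)

    @classmethod
    def from_bundle(cls, bundle_dir, outdir="skingwas_run", **overrides) -> "PipelineConfig":
        """Configuration for a directory written by the ``simulate`` stage."""
        bundle = Path(bundle_dir)
        sumstats = {p.stem.removeprefix("sumstats_"): str(p)
                    for p in sorted(bundle.glob("sumstats_*.tsv"))}
        tracks = {p.stem.removeprefix("track_"): str(p)
                  for p in sorted(bundle.glob("track_*.bed"))}
        if not sumstats:
            raise DomainError(f"{bundle}: no sumstats_*.tsv files found")
        kwargs = dict(
            sumstats=sumstats,
            tracks=tracks,
            background=str(bundle / "background.tsv"),
            eqtl=str(bundle / "eqtl.tsv"),
            freqs=str(bundle / "ancestry_freqs.tsv"),
            gene_sets=str(bundle / "gene_sets.gmt"),
            gene_universe=str(bundle / "gene_universe.txt"),
            expression_matrix=str(bundle / "expression_matrix.tsv"),
            cell_labels=str(bundle / "cell_labels.tsv"),
            stimulation=str(bundle / "stimulation.tsv"),
            outdir=str(outdir),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (the output directory is not
        part of the analysis, so runs to different directories hash equal)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class MissingInputError(SkingwasError):
    """A configured input file does not exist."""


def _require(path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise MissingInputError(f"missing input file: {p}")
    return p


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write per-stage TSVs, a machine-readable
    ``summary.json`` and a ``run.log`` into the run directory."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    mhc = parse_mhc(cfg.mhc)
    summary: dict = {"version": __version__, "config_hash": cfg.config_hash(),
                     "build": cfg.build}

    # --- fine-mapping -----------------------------------------------------
    stage = "finemap"
    try:
        credible_sets: dict[str, list[finemap.CredibleSet]] = {}
        rows = []
        for disease, path in cfg.sumstats.items():
            records = gwas_io.read_summary_stats(_require(path, stage), disease,
                                                 build=cfg.build)
            sets = finemap.credible_sets_for_disease(
                records, disease, p_threshold=cfg.p_threshold,
                merge_dist=cfg.merge_dist, mhc=mhc,
                coverage_target=cfg.coverage, prior_w=cfg.prior_w)
            credible_sets[disease] = sets
            for cs in sets:
                cum = 0.0
                for e in cs.entries:
                    cum += e.posterior
                    rows.append((disease, cs.locus.locus_id, e.variant_id,
                                 e.abf, e.posterior, cum, True))
        pd.DataFrame(rows, columns=["disease", "locus_id", "variant_id", "abf",
                                    "posterior", "cumulative", "in_set"]
                     ).to_csv(out / "credible_sets.tsv", sep="\t", index=False)
        summary["loci_per_disease"] = {d: len(s) for d, s in credible_sets.items()}
        summary["bci_variants_per_disease"] = {
            d: sum(len(cs.entries) for cs in s) for d, s in credible_sets.items()}
    except SkingwasError as exc:
        raise StageError(stage, exc) from exc

    # --- annotation enrichment -------------------------------------------
    stage = "enrich"
    try:
        tracks = {name: gwas_io.read_bed(_require(path, stage), name, build=cfg.build)
                  for name, path in cfg.tracks.items()}
        background = gwas_io.read_background(_require(cfg.background, stage),
                                             build=cfg.build)
        enr_rows = []
        all_sets = [cs for sets in credible_sets.values() for cs in sets]
        for name, track in tracks.items():
            for disease, sets in credible_sets.items():
                if not sets:
                    continue
                r = overlap.oe_enrichment(sets, track, background, disease=disease)
                enr_rows.append(dataclasses.asdict(r))
            pooled = overlap.oe_enrichment(all_sets, track, background, disease="all")
            enr_rows.append(dataclasses.asdict(pooled))
        enrichment = pd.DataFrame(enr_rows)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["enrichment"] = enrichment[enrichment["disease"] == "all"][
            ["track", "n_loci", "observed", "background_rate", "oe", "p"]
        ].to_dict(orient="records")
    except SkingwasError as exc:
        raise StageError(stage, exc) from exc

    # --- ancestry frequency contrasts --------------------------------------
    stage = "ancestry"
    try:
        freqs = ancestry.read_freq_table(_require(cfg.freqs, stage))
        flags_by_disease: dict[str, list[ancestry.RafFlag]] = {}
        prop_rows = []
        for disease, sets in credible_sets.items():
            ids = [v for cs in sets for v in cs.variant_ids]
            if not ids:
                continue
            flags = ancestry.flag_raf_direction(freqs, ids)
            flags_by_disease[disease] = flags
            for unit in ("variant", "locus"):
                props = ancestry.raf_proportions(flags, unit=unit, credible_sets=sets)
                prop_rows.append({"disease": disease, "unit": unit, **props})
        proportions = pd.DataFrame(prop_rows)
        proportions.to_csv(out / "raf_proportions.tsv", sep="\t", index=False)
        summary["raf_proportions"] = prop_rows
    except SkingwasError as exc:
        raise StageError(stage, exc) from exc

    # --- GLM of afr_higher on annotation indicators -----------------------
    stage = "glm"
    try:
        eqtl_records = gwas_io.read_eqtl_table(_require(cfg.eqtl, stage),
                                               p_max=cfg.eqtl_p)
        eqtl_variants = {r.variant_id for r in eqtl_records}
        all_flags = [f for flags in flags_by_disease.values() for f in flags]
        variants_by_id = {m.variant_id: m
                          for sets in credible_sets.values()
                          for cs in sets for m in cs.locus.members}
        ind_rows = {}
        for f in all_flags:
            rec = variants_by_id[f.variant_id]
            row = {name: overlap.variant_in_track(rec, tr)
                   for name, tr in tracks.items() if name.upper() != "EQTL"}
            row["eqtl"] = f.variant_id in eqtl_variants
            ind_rows[f.variant_id] = row
        indicators = pd.DataFrame.from_dict(ind_rows, orient="index")
        glm_rows = []
        for mode in ("joint", "marginal"):
            try:
                for res in ancestry.fit_raf_annotation_glm(all_flags, indicators,
                                                           mode=mode):
                    glm_rows.append(dataclasses.asdict(res))
            except DegenerateInputError as exc:
                logger.warning("GLM (%s) skipped: %s", mode, exc)
                glm_rows.append({"term": "-", "or_estimate": float("nan"),
                                 "p": float("nan"), "model": f"{mode} (skipped: {exc})"})
        glm = pd.DataFrame(glm_rows)
        glm.to_csv(out / "glm.tsv", sep="\t", index=False)
        summary["glm"] = glm_rows
    except SkingwasError as exc:
        raise StageError(stage, exc) from exc

    # --- gene-set enrichment of eQTL targets -------------------------------
    stage = "geneset"
    try:
        with open(_require(cfg.gene_universe, stage)) as fh:
            universe = {line.strip() for line in fh if line.strip()}
        gene_sets = gwas_io.read_gmt(_require(cfg.gene_sets, stage))
        gs_rows = []
        for direction in ("afr_higher", "eur_higher"):
            selected = ancestry.collect_eqtl_targets(
                all_sets, eqtl_records, all_flags, direction)
            if not selected:
                continue
            for name, genes in gene_sets.items():
                if len(genes & universe) >= ancestry.MAX_TERM_SIZE:
                    logger.warning("gene set %s rejected by the term-size filter", name)
                    continue
                res = ancestry.geneset_enrichment(selected, genes, universe,
                                                  set_name=name)
                gs_rows.append({"direction": direction, **dataclasses.asdict(res)})
        geneset = pd.DataFrame(gs_rows).sort_values(
            ["direction", "p"]).reset_index(drop=True)
        geneset.to_csv(out / "geneset.tsv", sep="\t", index=False)
        summary["geneset_top"] = geneset.groupby("direction").head(3).to_dict(
            orient="records")
    except SkingwasError as exc:
        raise StageError(stage, exc) from exc

    # --- module score -------------------------------------------------------
    stage = "modscore"
    if cfg.expression_matrix:
        try:
            matrix, labels = expression.read_expression_matrix(
                _require(cfg.expression_matrix, stage),
                _require(cfg.cell_labels, stage) if cfg.cell_labels else None)
            set_name = cfg.module_set_name or next(iter(gene_sets))
            module_genes = sorted(gene_sets[set_name])
            scores = expression.module_score(
                matrix, module_genes, rng=np.random.default_rng(cfg.seed + 10))
            score_table = pd.DataFrame({"score": scores})
            if labels is not None:
                score_table["cell_type"] = labels
                summary["module_score_by_cell_type"] = (
                    score_table.groupby("cell_type")["score"].mean().round(6).to_dict())
            score_table.to_csv(out / "module_scores.tsv", sep="\t")
        except SkingwasError as exc:
            raise StageError(stage, exc) from exc

    # --- stimulation contrast ----------------------------------------------
    stage = "stimcontrast"
    if cfg.stimulation:
        try:
            paired = pd.read_csv(_require(cfg.stimulation, stage), sep="\t",
                                 comment="#")
            contrast = expression.stimulation_contrast(
                paired, fc_min=cfg.fc_min, fdr_max=cfg.fdr_max)
            contrast.table.to_csv(out / "stim_contrast.tsv", sep="\t", index=False)
            summary["stimulation"] = {
                "n_induced": contrast.n_induced,
                "pearson_r": None if np.isnan(contrast.pearson_r)
                else round(contrast.pearson_r, 6),
                "pearson_p": None if np.isnan(contrast.pearson_p)
                else float(contrast.pearson_p),
            }
        except SkingwasError as exc:
            raise StageError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    with open(out / "run.log", "w") as fh:
        fh.write(f"skingwas {__version__}\nconfig_hash {cfg.config_hash()}\n"
                 f"build {cfg.build}\nseed {cfg.seed}\n")
    cfg.to_yaml(out / "config.yaml")
    logger.info("pipeline complete: %s", out)
    return out
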
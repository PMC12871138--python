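"""Configuration-driven orchestration of the full analysis.

Stages: simulate-or-ingest, channel normalization, per-plex ROC
enrichment filtering, per-contrast differential abundance, direction-aware
over-representation, secretion-class partition, dynamic-range rank,
optional tissue-plasma concordance and disease-association join.  Every
intermediate table is written under the run directory and a manifest
records the config, the seed, input hashes, output hashes and per-stage
counts.  Identical config + seed reproduce byte-identical outputs (the
run log, which carries timestamps, is excluded from the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._errors import ConfigError, SecretomapError, StageError
from . import annotate, differential, ora, roc_filter, simulate
from .io_tables import (QuantExperiment, TermMap, read_annotation_catalog, read_gmt,
                        read_quant_table, write_annotation_catalog, write_gmt,
                        write_quant_table, write_result_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (YAML-loadable)."""

    mode: str = "simulate"                      # simulate | ingest
    sim: simulate.SimulationConfig = field(default_factory=simulate.default_study_design)
    simulate_plasma: bool = False               # simulate-mode paired plasma experiment
    plasma_effect_jitter_sd: float = 0.5
    quant_path: str | None = None               # ingest mode
    design_path: str | None = None
    annotations_path: str | None = None
    plasma_quant_path: str | None = None        # optional paired plasma (ingest)
    plasma_design_path: str | None = None
    gmt_path: str | None = None
    atlas_path: str | None = None
    normalization: str = "median_center"
    min_frac_quantified: float = 0.5
    fixed_fpr: float | None = None
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    alpha: float = 0.05
    fc_min: float = 1.5
    enrichment_fdr: float = 0.05
    background_mode: str = "experiment"         # experiment | supplied
    disease_p_max: float = 0.05
    seed: int = 0
    out_dir: str = "secretomap_run"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ConfigError(f"mode must be 'simulate' or 'ingest', got {self.mode!r}")
        if self.background_mode not in ("experiment", "supplied"):
            raise ConfigError("background_mode must be 'experiment' or 'supplied'")
        if self.mode == "ingest":
            for name in ("quant_path", "design_path", "annotations_path"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"ingest mode requires {name}")
                if not Path(path).exists():
                    raise ConfigError(f"{name}: no such file: {path}")
            for name in ("plasma_quant_path", "plasma_design_path", "gmt_path",
                         "atlas_path"):
                path = getattr(self, name)
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"{name}: no such file: {path}")
        else:
            self.sim.validate()
        for a, b in self.contrasts:
            if a == b:
                raise ConfigError(f"contrast {a}:{b} compares a condition to itself")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = simulate.SimulationConfig.from_dict(d["sim"])
        if "contrasts" in d:
            d["contrasts"] = [tuple(c.split(":")) if isinstance(c, str) else tuple(c)
                              for c in d["contrasts"]]
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}") from None
        except yaml.YAMLError as exc:
            raise ConfigError(f"config file {path} is not valid YAML: {exc}") from None
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["contrasts"] = [f"{a}:{b}" for a, b in self.contrasts]
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _terms_from_catalog(catalog) -> list[TermMap]:
    """Derive one term map per cellular-component label in the catalog."""
    members: dict[str, set[str]] = {}
    for pid in catalog.proteins:
        for term in catalog.cc_terms(pid):
            members.setdefault(term, set()).add(pid)
    return [TermMap(term_id=f"CC:{name.replace(' ', '_')}", term_name=name,
                    members=frozenset(pids))
            for name, pids in sorted(members.items())]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; return the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("secretomap")
    root.addHandler(handler)
    if root.level == logging.NOTSET or root.level > logging.INFO:
        root.setLevel(logging.INFO)

    counts: dict = {}
    inputs: dict[str, str] = {}
    plasma_q = None
    try:
        # ---- stage: input -------------------------------------------------
        stage = "input"
        try:
            if config.mode == "simulate":
                sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
                q, truth = simulate.simulate_experiment(sim_cfg)
                catalog = simulate.annotation_catalog_from_truth(truth, seed=config.seed)
                simulate.write_truth(truth, out / "truth.tsv")
                if config.simulate_plasma:
                    plasma_q, _ = simulate.simulate_counterpart(
                        sim_cfg, truth, tissue="plasma", seed=config.seed + 1,
                        effect_log2_jitter_sd=config.plasma_effect_jitter_sd)
            else:
                q = read_quant_table(config.quant_path, config.design_path)
                catalog = read_annotation_catalog(config.annotations_path)
                for p in (config.quant_path, config.design_path, config.annotations_path):
                    inputs[str(p)] = _sha256(Path(p))
                if config.plasma_quant_path and config.plasma_design_path:
                    plasma_q = read_quant_table(config.plasma_quant_path,
                                                config.plasma_design_path)
                    for p in (config.plasma_quant_path, config.plasma_design_path):
                        inputs[str(p)] = _sha256(Path(p))
            write_quant_table(q, out / "quant.tsv", out / "design.tsv")
            write_annotation_catalog(catalog, out / "annotations.tsv")
            counts["n_proteins"] = q.n_proteins
            counts["n_channels"] = len(q.design)
            logger.info("input: %d proteins x %d channels", q.n_proteins, len(q.design))

            if config.gmt_path:
                terms = read_gmt(config.gmt_path)
                inputs[str(config.gmt_path)] = _sha256(Path(config.gmt_path))
            else:
                terms = _terms_from_catalog(catalog)
            write_gmt(terms, out / "terms.gmt")

            # contrasts default to every non-reference condition vs the first
            contrasts = list(config.contrasts)
            if not contrasts:
                conds = q.conditions()
                contrasts = [(c, conds[0]) for c in conds[1:]]
        except SecretomapError:
            raise
        except OSError as exc:
            raise StageError(stage, str(exc)) from exc

        # ---- stage: filter ------------------------------------------------
        stage = "filter"
        results = roc_filter.filter_experiment(
            q, catalog, normalization=config.normalization,
            min_frac_quantified=config.min_frac_quantified, fixed_fpr=config.fixed_fpr)
        passing_all: set[str] = set()
        summary_rows = []
        for plex, res in results.items():
            ratio_df = res.ratios.rename_axis("protein").reset_index()
            write_result_table(ratio_df, out / f"ratios_{plex}.tsv")
            write_result_table(res.roc.as_frame(), out / f"roc_{plex}.tsv")
            summary_rows.append({"plex_id": plex, "n_identified": res.n_identified,
                                 "n_passing": res.n_passing,
                                 "selected_cutoff": res.roc.selected_cutoff,
                                 "selected_j": res.roc.selected_j, "auc": res.roc.auc})
            passing_all |= res.passing
            logger.info("filter[%s]: %d identified, %d passing, cutoff %.3f, AUC %.3f",
                        plex, res.n_identified, res.n_passing,
                        res.roc.selected_cutoff, res.roc.auc)
        write_result_table(pd.DataFrame(summary_rows), out / "filter_summary.tsv")
        (out / "passing.txt").write_text("\n".join(sorted(passing_all)) + "\n",
                                         encoding="utf-8")
        counts["n_passing"] = len(passing_all)

        # ---- stage: differential ------------------------------------------
        stage = "differential"
        norm_q = roc_filter.normalize_channels(q, config.normalization) \
            if config.normalization != "none" else q
        diff_tables: dict[str, pd.DataFrame] = {}
        for a, b in contrasts:
            label = differential.contrast_label(a, b)
            diff = differential.differential_abundance(
                norm_q, passing_all, (a, b), alpha=config.alpha, fc_min=config.fc_min)
            diff_tables[label] = diff
            write_result_table(diff, out / f"diff_{label}.tsv")
            n_up = int((diff["significant"] & (diff["log2fc"] > 0)).sum())
            n_down = int((diff["significant"] & (diff["log2fc"] < 0)).sum())
            counts[f"n_significant_up_{label}"] = n_up
            counts[f"n_significant_down_{label}"] = n_down
            logger.info("differential[%s]: %d tested, %d up, %d down",
                        label, int(diff["p"].notna().sum()), n_up, n_down)

        # ---- stage: enrichment --------------------------------------------
        stage = "enrichment"
        supplied_bg = frozenset(catalog.proteins) if config.background_mode == "supplied" \
            else None
        for label, diff in diff_tables.items():
            enr = ora.directional_enrichment(diff, terms, background=supplied_bg,
                                             fdr=config.enrichment_fdr)
            write_result_table(enr, out / f"enrichment_{label}.tsv")
            counts[f"n_enriched_terms_{label}"] = int(enr["significant"].sum()) \
                if len(enr) else 0

        # ---- stage: classify ----------------------------------------------
        stage = "classify"
        summary = annotate.classify_secretion(passing_all, catalog)
        write_result_table(summary.per_protein, out / "secretion_classes.tsv")
        class_df = pd.DataFrame(
            {"secretion_class": list(summary.counts),
             "count": list(summary.counts.values()),
             "fraction": [summary.fractions[c] if summary.fractions else float("nan")
                          for c in summary.counts]})
        write_result_table(class_df, out / "secretion_class_summary.tsv")
        counts["n_signal_peptide"] = summary.counts["signal_peptide"]

        # ---- stage: rank --------------------------------------------------
        stage = "rank"
        ref_cond = q.conditions()[0]
        rank = annotate.dynamic_range_rank(norm_q, catalog, ref_cond)
        write_result_table(rank.table, out / f"rank_{ref_cond}.tsv")
        if rank.span_orders is not None:
            counts["dynamic_range_span_orders"] = round(rank.span_orders, 4)

        # ---- stage: concordance -------------------------------------------
        if plasma_q is not None:
            stage = "concordance"
            norm_plasma = roc_filter.normalize_channels(plasma_q, config.normalization) \
                if config.normalization != "none" else plasma_q
            for a, b in contrasts:
                label = differential.contrast_label(a, b)
                diff_plasma = differential.differential_abundance(
                    norm_plasma, passing_all, (a, b), alpha=config.alpha,
                    fc_min=config.fc_min)
                conc = annotate.tissue_plasma_concordance(diff_tables[label], diff_plasma)
                write_result_table(conc.pairs, out / f"concordance_pairs_{label}.tsv")
                counts[f"concordance_r_{label}"] = round(conc.r, 4) \
                    if conc.r is not None else None
                counts[f"concordance_n_{label}"] = conc.n

        # ---- stage: disease-link ------------------------------------------
        if config.atlas_path:
            stage = "disease_link"
            atlas = annotate.read_disease_atlas(config.atlas_path)
            inputs[str(config.atlas_path)] = _sha256(Path(config.atlas_path))
            regulated = sorted({p for diff in diff_tables.values()
                                for p in diff.loc[diff["significant"], "protein"]})
            links = annotate.link_disease_associations(regulated, atlas,
                                                       p_max=config.disease_p_max)
            write_result_table(links, out / "disease_links.tsv")
            counts["n_disease_links"] = len(links)
    except SecretomapError as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    # ---- manifest ---------------------------------------------------------
    outputs = {p.name: _sha256(p) for p in sorted(out.iterdir())
               if p.is_file() and p.name not in ("run.log", "manifest.json")}
    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "inputs": inputs,
        "outputs": outputs,
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                                       encoding="utf-8")
    return manifest
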
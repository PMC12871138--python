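"""Synthetic multiplexed proximity-labeling experiments with known ground truth.

The generative model mirrors what an ER-lumenal, Cre-dependent biotin
ligase produces in vivo:

- *secretory* proteins are labeled only in Cre+ channels, so they carry a
  positive true log2(Cre+/Cre-) enrichment;
- *background* proteins are endogenously biotinylated (e.g. mitochondrial
  carboxylases) and appear equally in both genotypes (enrichment 0);
- *nonspecific* proteins are bead-binding contaminants at a low abundance
  floor in all channels (enrichment 0).

Protein base abundances are log-normal, spanning several orders of
magnitude as circulating proteomes do.  A chosen fraction of secretory
proteins responds to each non-reference condition with a log2 effect of
random sign.  Measurement noise is multiplicative log-normal with a given
coefficient of variation; entries are then masked missing, by default
completely at random.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .io_tables import ChannelDesign, QuantExperiment, AnnotationCatalog

CLASS_SECRETORY = "secretory"
CLASS_BACKGROUND = "background"
CLASS_NONSPECIFIC = "nonspecific"
CLASSES = (CLASS_SECRETORY, CLASS_BACKGROUND, CLASS_NONSPECIFIC)

#: Stage names used to derive independent random substreams from one seed.
_STREAMS = ("abundance", "enrichment", "effects", "noise", "missing", "annotation")


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    ``channels_per_condition`` maps each condition to a
    ``(n_cre_pos, n_cre_neg)`` pair; its first key is the reference
    condition (no condition effect).  Abundance parameters are on the
    natural-log scale; enrichment and condition effects on the log2 scale.
    """

    n_proteins: int = 2400
    frac_secretory: float = 0.6
    frac_background: float = 0.25
    n_plex: int = 1
    channels_per_condition: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"basal": (3, 3), "LPS": (3, 2), "fasted": (3, 2)})
    tissue: str = "iWAT"
    base_abundance_logmean: float = 11.5   # exp(11.5) ~ 1e5 arbitrary units
    base_abundance_logsd: float = 2.3      # ~1 order of magnitude per SD
    enrichment_log2mean: float = 3.0
    enrichment_log2sd: float = 0.8
    frac_de: float = 0.2
    effect_log2mean: float = 1.5
    effect_log2sd: float = 0.5
    noise_cv: float = 0.2
    missing_rate: float = 0.05
    seed: int = 0
    # TMT reporter-ion ratio compression, applied as a shrinkage factor on
    # true log2 enrichments and effects; 1.0 = no compression.
    ratio_compression: float = 1.0
    # Bead-binding floor for nonspecific proteins, as a multiplier on the
    # log-normal base abundance draw.
    bead_background_frac: float = 0.05
    # If True, missingness probability grows with low-abundance rank
    # (mean rate preserved); default is completely-at-random.
    intensity_dependent_missing: bool = False

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not (0 < self.frac_secretory < 1) or not (0 < self.frac_background < 1):
            raise ConfigError("frac_secretory and frac_background must be in (0,1)")
        if self.frac_secretory + self.frac_background > 1:
            raise ConfigError("frac_secretory + frac_background must be <= 1")
        if self.n_plex < 1:
            raise ConfigError("n_plex must be >= 1")
        if not self.channels_per_condition:
            raise ConfigError("channels_per_condition must be non-empty")
        for cond, (npos, nneg) in self.channels_per_condition.items():
            if npos < 1:
                raise ConfigError(f"condition {cond!r}: need >= 1 cre_pos channel")
            if nneg < 1:
                raise ConfigError(
                    f"condition {cond!r}: a plex with zero cre_neg channels has no "
                    "background control; enrichment ratios would be undefined")
        for name in ("base_abundance_logsd", "enrichment_log2sd", "effect_log2sd",
                     "noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0 <= self.frac_de <= 1):
            raise ConfigError("frac_de must be in [0, 1]")
        if self.ratio_compression <= 0:
            raise ConfigError("ratio_compression must be > 0")

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels_per_condition"] = {k: list(v) for k, v in self.channels_per_condition.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "channels_per_condition" in d:
            d["channels_per_condition"] = {
                k: tuple(int(x) for x in v) for k, v in d["channels_per_condition"].items()}
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown simulation parameters: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @property
    def reference_condition(self) -> str:
        return next(iter(self.channels_per_condition))

    def effect_conditions(self) -> list[str]:
        return [c for c in self.channels_per_condition if c != self.reference_condition]


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated experiment.

    ``table`` is indexed by protein ID with columns ``class``,
    ``true_base_abundance``, ``true_log2_enrichment`` and one
    ``true_log2_effect_<condition>`` column per non-reference condition
    (0 for proteins without a condition effect).
    """

    table: pd.DataFrame
    reference_condition: str

    def proteins_of_class(self, cls: str) -> list[str]:
        return list(self.table.index[self.table["class"] == cls])

    def effect_column(self, condition: str) -> str:
        return f"true_log2_effect_{condition}"

    def true_effects(self, condition: str) -> pd.Series:
        return self.table[self.effect_column(condition)]


def default_study_design() -> SimulationConfig:
    """The default simulated study: one 16-plex, three conditions.

    Mirrors the shape of an in-vivo negative-energy-balance experiment:
    basal, LPS and fasted conditions, each with Cre+ replicates and
    Cre- background-control channels, 16 channels in total.
    """
    cfg = SimulationConfig()
    cfg.validate()
    assert sum(p + n for p, n in cfg.channels_per_condition.values()) == 16
    return cfg


def _class_counts(cfg: SimulationConfig) -> tuple[int, int, int]:
    # Deterministic rounding: floor secretory, then background; remainder
    # is nonspecific.  Exactly partitions n_proteins.
    n_sec = int(np.floor(cfg.frac_secretory * cfg.n_proteins))
    n_bg = int(np.floor(cfg.frac_background * cfg.n_proteins))
    return n_sec, n_bg, cfg.n_proteins - n_sec - n_bg


def _build_design(cfg: SimulationConfig) -> list[ChannelDesign]:
    design = []
    for p in range(1, cfg.n_plex + 1):
        plex = f"plex{p}"
        for cond, (npos, nneg) in cfg.channels_per_condition.items():
            for r in range(1, npos + 1):
                design.append(ChannelDesign(f"{plex}_{cond}_pos{r}", "cre_pos", cond,
                                            cfg.tissue, r, plex))
            for r in range(1, nneg + 1):
                design.append(ChannelDesign(f"{plex}_{cond}_neg{r}", "cre_neg", cond,
                                            cfg.tissue, r, plex))
    return design


def simulate_experiment(config: SimulationConfig) -> tuple[QuantExperiment, SyntheticTruth]:
    """Draw one multiplexed experiment from the generative model.

    The expected intensity of protein *i* in channel *c* is
    ``base_i * 2**(enrichment_i * [c is cre_pos]) * 2**(effect_{i,cond(c)})``,
    multiplied by log-normal noise with median 1 and the configured CV,
    then masked missing at ``missing_rate``.  Identical seeds give
    bit-identical output; each model component draws from its own named
    substream, so e.g. changing ``missing_rate`` never perturbs the
    abundance draws.
    """
    config.validate()
    streams = {name: np.random.default_rng(child) for name, child in
               zip(_STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STREAMS)))}

    n = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(1, n + 1)]
    n_sec, n_bg, n_non = _class_counts(config)
    classes = np.array([CLASS_SECRETORY] * n_sec + [CLASS_BACKGROUND] * n_bg
                       + [CLASS_NONSPECIFIC] * n_non)

    base = np.exp(streams["abundance"].normal(config.base_abundance_logmean,
                                              config.base_abundance_logsd, size=n))
    base[classes == CLASS_NONSPECIFIC] *= config.bead_background_frac

    enrich = np.zeros(n)
    enrich[:n_sec] = streams["enrichment"].normal(config.enrichment_log2mean,
                                                  config.enrichment_log2sd, size=n_sec)

    truth_cols = {"class": classes, "true_base_abundance": base,
                  "true_log2_enrichment": enrich}
    effects: dict[str, np.ndarray] = {}
    for cond in config.effect_conditions():
        eff = np.zeros(n)
        if n_sec > 0 and config.frac_de > 0:
            n_de = int(np.floor(config.frac_de * n_sec))
            idx = streams["effects"].choice(n_sec, size=n_de, replace=False)
            mag = streams["effects"].normal(config.effect_log2mean, config.effect_log2sd,
                                            size=n_de)
            sign = streams["effects"].choice([-1.0, 1.0], size=n_de)
            eff[idx] = mag * sign
        effects[cond] = eff
        truth_cols[f"true_log2_effect_{cond}"] = eff

    design = _build_design(config)
    is_pos = np.array([c.genotype == "cre_pos" for c in design], dtype=float)
    cond_effect = np.column_stack([
        effects.get(c.condition, np.zeros(n)) for c in design])

    shrink = config.ratio_compression
    log2_expected = (np.log2(base)[:, None]
                     + shrink * enrich[:, None] * is_pos[None, :]
                     + shrink * cond_effect)
    expected = np.exp2(log2_expected)

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
        noise = np.exp(streams["noise"].normal(0.0, sigma, size=expected.shape))
        observed = expected * noise
    else:
        observed = expected

    if config.missing_rate > 0:
        if config.intensity_dependent_missing:
            # Low-abundance entries are likelier to be missing; mean rate
            # preserved: p = rate * 2 * (1 - rank_fraction), clipped at 1.
            flat = observed.ravel()
            ranks = np.empty(flat.size)
            ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
            frac = ranks / max(flat.size - 1, 1)
            p = np.clip(config.missing_rate * 2.0 * (1.0 - frac), 0.0, 1.0)
            mask = streams["missing"].random(flat.size) < p
            mask = mask.reshape(observed.shape)
        else:
            mask = streams["missing"].random(observed.shape) < config.missing_rate
        observed = observed.copy()
        observed[mask] = np.nan

    mat = pd.DataFrame(observed, index=pd.Index(proteins, name="protein"),
                       columns=[c.channel_id for c in design])
    truth = pd.DataFrame(truth_cols, index=pd.Index(proteins, name="protein"))
    return (QuantExperiment(mat, design),
            SyntheticTruth(truth, config.reference_condition))


# Cellular-component vocabularies used when deriving an annotation catalog
# from simulated class labels (consistent with the ROC truth-set rules).
_SECRETORY_CC = ("endoplasmic reticulum", "Golgi apparatus", "extracellular region",
                 "plasma membrane", "lysosome")
_BACKGROUND_CC = ("mitochondrion",)
_NONSPECIFIC_CC = ("cytosol", "nucleus")


def annotation_catalog_from_truth(truth: SyntheticTruth, seed: int = 0,
                                  signal_peptide_rate: float = 0.8,
                                  ups_rate: float = 0.1,
                                  transmembrane_rate: float = 0.25) -> AnnotationCatalog:
    """Derive a localization catalog consistent with simulated class labels.

    Secretory proteins receive secretory-pathway cellular-component terms
    and, mostly, a signal-peptide flag (the remainder split between
    unconventional secretion and membrane-only); background proteins are
    annotated mitochondrial (endogenously biotinylated carboxylases);
    nonspecific proteins cytosolic or nuclear.  This exercises the
    annotation-driven truth-set construction exactly the way a real GO
    catalog would.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA110]))
    rows = {}
    for pid, cls in truth.table["class"].items():
        if cls == CLASS_SECRETORY:
            cc = frozenset({_SECRETORY_CC[rng.integers(len(_SECRETORY_CC))]})
            sp = bool(rng.random() < signal_peptide_rate)
            ups = (not sp) and bool(rng.random() < ups_rate / max(1e-9, 1 - signal_peptide_rate))
            tm = bool(rng.random() < transmembrane_rate)
        elif cls == CLASS_BACKGROUND:
            cc = frozenset(_BACKGROUND_CC)
            sp = ups = tm = False
        else:
            cc = frozenset({_NONSPECIFIC_CC[rng.integers(len(_NONSPECIFIC_CC))]})
            sp = ups = tm = False
        rows[pid] = {"cc_terms": cc, "signal_peptide": sp, "ups_predicted": ups,
                     "transmembrane": tm, "tissue_enriched": None,
                     "concentration_pmol_ml": np.nan}
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(AnnotationCatalog.COLUMNS))
    table.index.name = "protein"
    return AnnotationCatalog(table)


def simulate_counterpart(config: SimulationConfig, truth: SyntheticTruth,
                         tissue: str, seed: int,
                         effect_log2_jitter_sd: float = 0.5
                         ) -> tuple[QuantExperiment, SyntheticTruth]:
    """Simulate a paired compartment (e.g. plasma) sharing a tissue's truth.

    The same proteins keep their base abundances and enrichments; each
    condition effect is perturbed by independent N(0, jitter_sd^2) noise,
    emulating the imperfect agreement between a tissue secretome and its
    circulating counterpart (secretion kinetics, clearance, other source
    tissues).  Fresh noise and missingness streams are drawn from
    ``seed``.
    """
    config.validate()
    streams = {name: np.random.default_rng(child) for name, child in
               zip(_STREAMS, np.random.SeedSequence(seed).spawn(len(_STREAMS)))}
    n = len(truth.table)
    base = truth.table["true_base_abundance"].to_numpy()
    enrich = truth.table["true_log2_enrichment"].to_numpy()
    effects = {}
    truth_cols = {"class": truth.table["class"].to_numpy(),
                  "true_base_abundance": base, "true_log2_enrichment": enrich}
    for cond in config.effect_conditions():
        eff = truth.true_effects(cond).to_numpy().copy()
        if effect_log2_jitter_sd > 0:
            eff = eff + streams["effects"].normal(0.0, effect_log2_jitter_sd, size=n)
        effects[cond] = eff
        truth_cols[f"true_log2_effect_{cond}"] = eff

    cfg2 = dataclasses.replace(config, tissue=tissue)
    design = _build_design(cfg2)
    is_pos = np.array([c.genotype == "cre_pos" for c in design], dtype=float)
    cond_effect = np.column_stack([effects.get(c.condition, np.zeros(n)) for c in design])
    shrink = config.ratio_compression
    log2_expected = (np.log2(base)[:, None]
                     + shrink * enrich[:, None] * is_pos[None, :]
                     + shrink * cond_effect)
    expected = np.exp2(log2_expected)
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
        expected = expected * np.exp(streams["noise"].normal(0.0, sigma, size=expected.shape))
    if config.missing_rate > 0:
        mask = streams["missing"].random(expected.shape) < config.missing_rate
        expected = expected.copy()
        expected[mask] = np.nan
    mat = pd.DataFrame(expected, index=truth.table.index.copy(),
                       columns=[c.channel_id for c in design])
    truth2 = pd.DataFrame(truth_cols, index=truth.table.index.copy())
    return QuantExperiment(mat, design), SyntheticTruth(truth2, config.reference_condition)


def write_truth(truth: SyntheticTruth, path) -> None:
    from .io_tables import write_result_table
    df = truth.table.reset_index()
    write_result_table(df, path)
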
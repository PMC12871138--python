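"""Secretion-class partitioning, tissue-plasma concordance, dynamic-range
rank calibration, and disease-association joins.

These are the annotation-facing analyses applied to a filtered secretory
proteome: how much of it carries a classical signal peptide versus
unconventional-secretion or membrane-only predictions, how well tissue
fold changes agree with the circulating fold changes of the same
proteins, how many orders of magnitude of absolute plasma concentration
the detected set spans, and which regulated proteins carry published
disease associations in an external plasma proteome-phenome atlas (whose
odds ratios and p-values are inputs, never recomputed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import SchemaError, ValidationError
from .io_tables import AnnotationCatalog, QuantExperiment

logger = logging.getLogger(__name__)

SECRETION_CLASSES = ("signal_peptide", "ups_predicted", "transmembrane_only",
                     "intracellular_other")


@dataclass
class SecretionClassSummary:
    """Mutually exclusive secretion-class partition of a protein set.

    Assignment precedence: signal peptide > predicted unconventional
    secretion > transmembrane-only > intracellular/other.  The raw
    multi-flag annotation is preserved in ``per_protein``.
    """

    per_protein: pd.DataFrame
    counts: dict[str, int]
    fractions: dict[str, float] | None  # None for an empty input


def classify_secretion(proteins, catalog: AnnotationCatalog) -> SecretionClassSummary:
    """Partition proteins into secretion classes by annotation precedence."""
    rows = []
    for pid in sorted(set(proteins)):
        sp = catalog.flag(pid, "signal_peptide")
        ups = catalog.flag(pid, "ups_predicted")
        tm = catalog.flag(pid, "transmembrane")
        if sp:
            cls = "signal_peptide"
        elif ups:
            cls = "ups_predicted"
        elif tm:
            cls = "transmembrane_only"
        else:
            cls = "intracellular_other"
        rows.append({"protein": pid, "secretion_class": cls, "signal_peptide": sp,
                     "ups_predicted": ups, "transmembrane": tm})
    per_protein = pd.DataFrame(rows, columns=["protein", "secretion_class",
                                              "signal_peptide", "ups_predicted",
                                              "transmembrane"])
    counts = {c: int((per_protein["secretion_class"] == c).sum()) for c in SECRETION_CLASSES}
    total = len(per_protein)
    fractions = {c: counts[c] / total for c in SECRETION_CLASSES} if total else None
    return SecretionClassSummary(per_protein=per_protein, counts=counts, fractions=fractions)


@dataclass
class ConcordanceResult:
    """Pearson agreement of tissue and plasma fold changes on shared proteins."""

    shared_proteins: frozenset[str]
    r: float | None
    n: int
    pairs: pd.DataFrame  # protein, log2fc_tissue, log2fc_plasma


def tissue_plasma_concordance(diff_tissue: pd.DataFrame,
                              diff_plasma: pd.DataFrame) -> ConcordanceResult:
    """Pearson r between tissue and plasma log2FC of shared proteins.

    Both tables must carry the same contrast label.  With fewer than
    three shared proteins, r is not reported (warning).
    """
    for df, name in ((diff_tissue, "tissue"), (diff_plasma, "plasma")):
        if df.empty:
            raise ValidationError(f"{name} differential table is empty")
    contrasts_t = set(diff_tissue["contrast"].unique())
    contrasts_p = set(diff_plasma["contrast"].unique())
    if contrasts_t != contrasts_p:
        raise ValidationError(
            f"contrast labels differ between tissue {sorted(contrasts_t)} and "
            f"plasma {sorted(contrasts_p)}")
    t = diff_tissue.loc[diff_tissue["log2fc"].notna(), ["protein", "log2fc"]]
    p = diff_plasma.loc[diff_plasma["log2fc"].notna(), ["protein", "log2fc"]]
    pairs = t.merge(p, on="protein", suffixes=("_tissue", "_plasma"), how="inner",
                    sort=True)
    n = len(pairs)
    if n < 3:
        logger.warning("tissue_plasma_concordance: only %d shared proteins; r not reported", n)
        r = None
    else:
        r = float(stats.pearsonr(pairs["log2fc_tissue"], pairs["log2fc_plasma"]).statistic)
    return ConcordanceResult(shared_proteins=frozenset(pairs["protein"]), r=r, n=n,
                             pairs=pairs)


@dataclass
class RankTable:
    """Descending-intensity rank of detected proteins with known concentrations.

    ``span_orders`` is log10(max/min) of the known concentrations among
    the detected proteins — the dynamic range covered, in orders of
    magnitude (None if fewer than one known concentration pair).
    """

    table: pd.DataFrame  # protein, mean_intensity, rank, concentration_pmol_ml
    min_concentration: float | None
    max_concentration: float | None
    span_orders: float | None


def dynamic_range_rank(q: QuantExperiment, catalog: AnnotationCatalog,
                       condition: str, genotype: str = "cre_pos") -> RankTable:
    """Rank proteins by mean intensity in one condition's Cre+ channels.

    Rank 1 is the highest mean intensity; ties are broken by protein ID.
    Known absolute plasma concentrations (common unit pmol/mL) are joined
    where the catalog has them, and the summary reports the detected
    dynamic range in orders of magnitude.
    """
    cols = q.channel_ids(genotype=genotype, condition=condition)
    if not cols:
        raise ValidationError(f"no {genotype} channels for condition {condition!r}")
    mean = q.intensities[cols].mean(axis=1, skipna=True).dropna()
    df = pd.DataFrame({"protein": mean.index, "mean_intensity": mean.to_numpy()})
    df = df.sort_values(["mean_intensity", "protein"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["concentration_pmol_ml"] = [catalog.concentration(p) for p in df["protein"]]
    known = df["concentration_pmol_ml"].dropna()
    if len(known) >= 1:
        cmin, cmax = float(known.min()), float(known.max())
        span = float(np.log10(cmax / cmin)) if len(known) >= 2 else None
    else:
        cmin = cmax = span = None
    return RankTable(table=df, min_concentration=cmin, max_concentration=cmax,
                     span_orders=span)


# ---------------------------------------------------------------------------
# disease-association join
# ---------------------------------------------------------------------------

ATLAS_COLUMNS = ("protein", "disease", "odds_ratio", "p_adj")


def read_disease_atlas(path: str | Path) -> pd.DataFrame:
    """Read a plasma proteome-phenome association table.

    Required columns: protein, disease, odds_ratio, p_adj; optional:
    chapter (disease chapter for grouping), cohort_n.  Association
    statistics are external inputs and are only validated, never
    recomputed.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"disease atlas {path}: missing columns {missing}")
    if (df["odds_ratio"] <= 0).any():
        raise ValidationError(f"disease atlas {path}: odds_ratio must be > 0")
    if ((df["p_adj"] <= 0) | (df["p_adj"] > 1)).any():
        raise ValidationError(f"disease atlas {path}: p_adj must be in (0, 1]")
    return df


def link_disease_associations(regulated, atlas: pd.DataFrame,
                              p_max: float = 0.05) -> pd.DataFrame:
    """Join regulated proteins with atlas associations at p_adj <= p_max.

    Grouped (sorted) by disease chapter when a ``chapter`` column exists,
    then disease, then protein.
    """
    reg = set(regulated)
    hits = atlas[(atlas["p_adj"] <= p_max) & atlas["protein"].isin(reg)].copy()
    sort_cols = [c for c in ("chapter", "disease", "protein") if c in hits.columns]
    return hits.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
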
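"""Cre+/Cre- enrichment ratios and the ROC-based secretory-proteome filter.

A cell type-specific ER-targeted ligase labels secretory-pathway clients
only in Cre+ animals, while endogenously biotinylated and bead-binding
proteins appear in both genotypes.  The filter ranks proteins by their
log2(Cre+/Cre-) ratio, scores candidate cutoffs against an
annotation-derived truth standard (secretory-pathway annotated proteins
as true positives, exclusively cytosolic/nuclear/mitochondrial proteins
as false positives), and keeps everything at or above the cutoff that
maximizes Youden's J = TPR - FPR.

ROC curves and cutoffs are per plex: enrichment is a within-experiment
contrast and is never pooled across multiplexed runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigError, ValidationError
from .io_tables import AnnotationCatalog, QuantExperiment

logger = logging.getLogger(__name__)

#: Cellular-component labels counted as secretory-pathway localization.
SECRETORY_CC_TERMS = frozenset({
    "endoplasmic reticulum", "Golgi apparatus", "extracellular region",
    "plasma membrane", "lysosome",
})

#: Labels whose exclusive holders form the false-positive standard.
NONSECRETORY_CC_TERMS = frozenset({"cytosol", "nucleus", "mitochondrion"})

NORMALIZATION_METHODS = ("median_center", "total_sum", "none")


@dataclass(frozen=True)
class TruthSets:
    """Annotation-derived gold standard for ROC construction."""

    true_positives: frozenset[str]
    false_positives: frozenset[str]
    construction_rule: str

    def __post_init__(self):
        overlap = self.true_positives & self.false_positives
        if overlap:
            raise ValidationError(f"truth sets overlap: {sorted(overlap)[:5]}")


@dataclass
class RocCurve:
    """ROC over candidate log2-ratio cutoffs, with the selected operating point.

    ``cutoffs`` is descending; ``tpr``/``fpr`` are the detection rates at
    ratio >= cutoff, so both are non-decreasing along the arrays.
    """

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    selected_cutoff: float
    selected_j: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.cutoffs, "tpr": self.tpr, "fpr": self.fpr})


@dataclass
class EnrichmentFilterResult:
    """The filtered proteome: ratios, the ROC, and the passing set."""

    ratios: pd.Series
    roc: RocCurve
    passing: frozenset[str]
    n_identified: int
    n_passing: int


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_channels(q: QuantExperiment, method: str = "median_center") -> QuantExperiment:
    """Equalize channel loading before ratio computation.

    ``median_center`` shifts each channel's log2 intensities so channel
    medians coincide (at their grand mean); ``total_sum`` scales channels
    to equal totals; ``none`` returns the experiment unchanged.  Missing
    entries stay missing.
    """
    if method not in NORMALIZATION_METHODS:
        raise ConfigError(f"unknown normalization {method!r} (choose from {NORMALIZATION_METHODS})")
    if method == "none":
        return q
    mat = q.intensities
    counts = mat.notna().sum(axis=0)
    empty = counts[counts == 0]
    if len(empty):
        raise ValidationError(f"channel(s) with no quantified values: {list(empty.index)}")
    if method == "median_center":
        with np.errstate(divide="ignore"):
            logmat = np.log2(mat.where(mat > 0))
        medians = logmat.median(axis=0, skipna=True)
        target = medians.mean()
        scaled = mat.mul(np.exp2(target - medians), axis=1)
    else:  # total_sum
        totals = mat.sum(axis=0, skipna=True)
        scaled = mat.mul(totals.mean() / totals, axis=1)
    return QuantExperiment(scaled, q.design)


# ---------------------------------------------------------------------------
# enrichment ratios
# ---------------------------------------------------------------------------

def compute_enrichment_ratios(q: QuantExperiment,
                              min_frac_quantified: float = 0.5) -> pd.Series:
    """Per-protein log2(Cre+/Cre-) over all channels of the experiment.

    A protein is retained only if it is quantified in at least
    ``min_frac_quantified`` of the channels within *each* genotype group.
    The ratio is ``log2(mean_pos / mean_neg)`` of raw intensities, with
    both means floored at epsilon = half the smallest positive intensity
    observed in the experiment, so a background-free protein gets a large
    finite ratio instead of infinity.
    """
    pos_cols = q.channel_ids(genotype="cre_pos")
    neg_cols = q.channel_ids(genotype="cre_neg")
    if not pos_cols or not neg_cols:
        raise ValidationError("experiment needs >=1 cre_pos and >=1 cre_neg channel")
    mat = q.intensities
    vals = mat.to_numpy(dtype=float)
    positive = vals[np.isfinite(vals) & (vals > 0)]
    if positive.size == 0:
        logger.warning("no positive intensities; returning empty ratio mapping")
        return pd.Series(dtype=float, name="log2_ratio")
    eps = 0.5 * positive.min()

    pos = mat[pos_cols]
    neg = mat[neg_cols]
    ok = ((pos.notna().sum(axis=1) / len(pos_cols) >= min_frac_quantified)
          & (neg.notna().sum(axis=1) / len(neg_cols) >= min_frac_quantified))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("compute_enrichment_ratios: dropped %d/%d proteins below "
                    "min_frac_quantified=%.2f", n_dropped, len(mat), min_frac_quantified)
    pos_mean = pos[ok].mean(axis=1, skipna=True).clip(lower=eps)
    neg_mean = neg[ok].mean(axis=1, skipna=True).clip(lower=eps)
    ratios = np.log2(pos_mean / neg_mean)
    ratios.name = "log2_ratio"
    if ratios.empty:
        logger.warning("no protein survived the quantification-fraction filter")
    return ratios


# ---------------------------------------------------------------------------
# truth sets and ROC
# ---------------------------------------------------------------------------

def build_truth_sets(catalog: AnnotationCatalog, proteins,
                     secretory_terms: frozenset[str] = SECRETORY_CC_TERMS,
                     nonsecretory_terms: frozenset[str] = NONSECRETORY_CC_TERMS) -> TruthSets:
    """Label proteins as ROC true/false positives from their annotations.

    True positives: cellular-component terms intersect the secretory list,
    or a predicted signal peptide (secretory membership takes precedence —
    dual-localized proteins are legitimately labeled by an ER ligase).
    False positives: non-empty terms, disjoint from the secretory list and
    contained in the non-secretory list.  Everything else is unlabeled and
    is filtered by the cutoff without informing it.
    """
    tp, fp = set(), set()
    for pid in proteins:
        cc = catalog.cc_terms(pid)
        if (cc & secretory_terms) or catalog.flag(pid, "signal_peptide"):
            tp.add(pid)
        elif cc and cc <= nonsecretory_terms:
            fp.add(pid)
    if not tp or not fp:
        raise ValidationError(
            "truth sets empty (TP=%d, FP=%d): supply an annotation catalog covering "
            "both secretory-pathway and exclusively non-secretory proteins"
            % (len(tp), len(fp)))
    rule = ("TP: cc_terms intersect {%s} or signal_peptide; FP: cc_terms non-empty, "
            "disjoint from the secretory list and within {%s}"
            % (", ".join(sorted(secretory_terms)), ", ".join(sorted(nonsecretory_terms))))
    return TruthSets(frozenset(tp), frozenset(fp), rule)


def build_roc(ratios, truth: TruthSets, fixed_fpr: float | None = None) -> RocCurve:
    """ROC over the labeled ratios; select the operating cutoff.

    Candidate cutoffs are the distinct labeled-protein ratios in
    descending order; at cutoff t, TPR and FPR count labeled proteins
    with ratio >= t.  AUC is the trapezoid over (FPR, TPR) anchored at
    (0,0) and (1,1).  By default the cutoff maximizes Youden's
    J = TPR - FPR, ties broken toward the smaller cutoff (retaining more
    proteins); with ``fixed_fpr`` the smallest cutoff with FPR <= fixed_fpr
    is chosen instead (maximizing TPR at that specificity).
    """
    ratios = pd.Series(dict(ratios)) if not isinstance(ratios, pd.Series) else ratios
    tp_ratios = ratios[ratios.index.isin(truth.true_positives)].to_numpy(dtype=float)
    fp_ratios = ratios[ratios.index.isin(truth.false_positives)].to_numpy(dtype=float)
    if tp_ratios.size == 0 or fp_ratios.size == 0:
        raise ValidationError("need >=1 labeled true positive and false positive with a ratio")
    labeled = np.concatenate([tp_ratios, fp_ratios])
    cutoffs = np.unique(labeled)[::-1]
    if cutoffs.size == 1:
        raise ValidationError(
            "degenerate ROC: all labeled ratios are identical (%.6g)" % cutoffs[0])
    tpr = np.array([(tp_ratios >= t).mean() for t in cutoffs])
    fpr = np.array([(fp_ratios >= t).mean() for t in cutoffs])
    auc = float(np.trapezoid(np.concatenate([[0.0], tpr, [1.0]]),
                             np.concatenate([[0.0], fpr, [1.0]])))
    if fixed_fpr is not None:
        admissible = np.flatnonzero(fpr <= fixed_fpr)
        if admissible.size == 0:
            raise ValidationError(f"no cutoff achieves FPR <= {fixed_fpr}")
        sel = admissible[-1]  # smallest admissible cutoff = highest TPR
    else:
        j = tpr - fpr
        # descending scan; >= keeps the later (smaller) cutoff on ties
        sel = 0
        for i in range(1, cutoffs.size):
            if j[i] >= j[sel]:
                sel = i
    return RocCurve(cutoffs=cutoffs, tpr=tpr, fpr=fpr, auc=auc,
                    selected_cutoff=float(cutoffs[sel]),
                    selected_j=float(tpr[sel] - fpr[sel]))


def apply_filter(ratios, roc: RocCurve) -> EnrichmentFilterResult:
    """Keep every protein whose ratio is at or above the selected cutoff.

    The cutoff learned from the labeled proteins is applied to the whole
    quantified proteome, labeled or not — that is the point of the
    procedure.  The boundary is inclusive: the cutoff is itself an
    observed ratio.
    """
    ratios = pd.Series(dict(ratios)) if not isinstance(ratios, pd.Series) else ratios
    passing = frozenset(ratios.index[ratios >= roc.selected_cutoff])
    return EnrichmentFilterResult(ratios=ratios, roc=roc, passing=passing,
                                  n_identified=int(ratios.size), n_passing=len(passing))


def filter_experiment(q: QuantExperiment, catalog: AnnotationCatalog,
                      normalization: str = "median_center",
                      min_frac_quantified: float = 0.5,
                      fixed_fpr: float | None = None) -> dict[str, EnrichmentFilterResult]:
    """Normalize, ratio, and ROC-filter each plex of an experiment.

    Returns one :class:`EnrichmentFilterResult` per plex ID (cutoffs are
    experiment-specific and never pooled).
    """
    out = {}
    for plex in q.plex_ids():
        sub = normalize_channels(q.subset_plex(plex), normalization)
        ratios = compute_enrichment_ratios(sub, min_frac_quantified)
        truth = build_truth_sets(catalog, ratios.index)
        roc = build_roc(ratios, truth, fixed_fpr=fixed_fpr)
        out[plex] = apply_filter(ratios, roc)
    return out
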
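"""Over-representation analysis of term maps against experiment-specific backgrounds.

One-sided Fisher's exact test (enrichment direction) per term, BH-FDR
across the terms actually tested.  The background is explicit and
experiment-specific — typically all proteins quantified and ROC-passing
in the experiment — never an implicit whole-genome default, although a
genome-wide background may be supplied where that is the intended
comparison.

The direction-aware variant splits a differential table into significant
up- and down-regulated foregrounds and tests each against all proteins
tested in the contrast.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .differential import bh_adjust
from .io_tables import TermMap

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ("term_id", "term_name", "k", "K", "n", "N",
                      "odds_ratio", "p", "q", "significant", "direction")


def enrichment_pvalue(k, K, n, N):
    """Exact one-sided enrichment p-value P(X >= k), X ~ Hypergeom(N, K, n).

    Identical to a one-sided Fisher exact test on the 2x2
    (in/out foreground) x (in/out term) table.  Accepts arrays.
    """
    return np.minimum(stats.hypergeom.sf(np.asarray(k) - 1, N, K, n), 1.0)


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    """Sample odds ratio of the 2x2 table; Haldane-Anscombe 0.5 fallback
    for display when a cell is zero (p stays exact).  Degenerate tables
    (foreground = background) report 1."""
    a, b, c, d = k, n - k, K - k, N - K - (n - k)
    if n == N or K == 0:
        return 1.0
    if min(a, b, c, d) == 0:
        return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_enrichment(foreground: Iterable[str], background: Iterable[str],
                      terms: list[TermMap], fdr: float = 0.05,
                      direction: str = "all") -> pd.DataFrame:
    """Per-term enrichment of ``foreground`` within ``background``.

    Term memberships are intersected with the background before counting;
    terms disjoint from the background are skipped (logged).  p is the
    exact hypergeometric upper tail P(X >= k), identical to a one-sided
    Fisher test on the 2x2 table; q is BH across the tested terms only.
    """
    fg = frozenset(foreground)
    bg = frozenset(background)
    if not fg:
        raise ValidationError("foreground is empty")
    if not fg <= bg:
        extra = sorted(fg - bg)[:5]
        raise ValidationError(f"foreground must be a subset of background (extra: {extra})")
    n, N = len(fg), len(bg)
    rows = []
    for term in sorted(terms, key=lambda t: t.term_id):
        members = term.members & bg
        K = len(members)
        if K == 0:
            logger.info("fisher_enrichment: term %s disjoint from background; skipped",
                        term.term_id)
            continue
        k = len(members & fg)
        p = float(enrichment_pvalue(k, K, n, N))
        rows.append((term.term_id, term.term_name, k, K, n, N,
                     _odds_ratio(k, K, n, N), p, np.nan, False, direction))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < fdr
    return df


def directional_enrichment(diff: pd.DataFrame, terms: list[TermMap],
                           background: Iterable[str] | None = None,
                           fdr: float = 0.05) -> pd.DataFrame:
    """Up/down-split over-representation from a differential table.

    Foregrounds are the significantly up- and down-regulated proteins (the
    table's own significance gate); the background defaults to every
    protein actually tested in the contrast.  Records carry a signed
    display score, ``-log10(q)`` with the sign of the direction, so
    up-enrichment plots red-positive and down-enrichment blue-negative.
    An empty direction is skipped with a warning.
    """
    tested = diff[diff["p"].notna()]
    bg = frozenset(background) if background is not None else frozenset(tested["protein"])
    sig = tested[tested["significant"]]
    frames = []
    for direction, sign in (("up", 1.0), ("down", -1.0)):
        fg = frozenset(sig.loc[sig["log2fc"] > 0 if direction == "up"
                               else sig["log2fc"] < 0, "protein"])
        if not fg:
            logger.warning("directional_enrichment: no significant %s-regulated proteins; "
                           "direction skipped", direction)
            continue
        res = fisher_enrichment(fg, bg, terms, fdr=fdr, direction=direction)
        res["signed_score"] = sign * -np.log10(res["q"])
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=[*ENRICHMENT_COLUMNS, "signed_score"])
    return pd.concat(frames, ignore_index=True)
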
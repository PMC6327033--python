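"""Gaussian-entropy information gain for contig pre-selection.

Each contig's CPM vector over the grouped animals is scored by the reduction in
Gaussian entropy obtained when the HIGH/LOW phenotype group is observed:

    H(sd)       = log2(sd * sqrt(2*pi*c))
    IG(contig)  = H(sd_pooled) - (N_H * H(sd_H) + N_L * H(sd_L)) / (N_H + N_L)

with maximum-likelihood (divide-by-N) standard deviations, which guarantees
IG >= 0 (the pooled variance is the within-group mixture variance plus a
non-negative between-group term, and log is concave).  The multiplicative
entropy constant ``c`` cancels exactly between the two terms, so IG does not
depend on it; the default follows the Euler–Mascheroni constant, with Euler's
number available for the differential-entropy convention — either gives
identical IG.  Entropies are in bits (base-2 logarithm).

Contigs whose within-group SD is zero separate the groups perfectly and are
flagged degenerate with IG = +inf (ranked first); a zero pooled SD (constant
contig) gives IG = 0 with a degenerate flag.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GROUP_HIGH, GROUP_LOW, AbundanceMatrix, DataError

logger = logging.getLogger("rumengwas")

#: Euler–Mascheroni constant, the default entropy constant.
EULER_MASCHERONI = 0.5772156649015329


def entropy(sd: float, constant: float = EULER_MASCHERONI) -> float:
    """Gaussian entropy log2(sd * sqrt(2*pi*constant)) in bits.

    Returns -inf for sd == 0 (the caller decides how to treat the degenerate
    case); negative sd is an error.
    """
    if sd < 0:
        raise DataError("standard deviation must be non-negative")
    if constant <= 0:
        raise DataError("entropy constant must be positive")
    if sd == 0:
        return -math.inf
    return math.log2(sd * math.sqrt(2.0 * math.pi * constant))


def _ml_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=0))


def information_gain(x: Sequence[float], labels: Sequence[str],
                     constant: float = EULER_MASCHERONI, ddof: int = 0) -> float:
    """Information gain (bits) of one contig's CPM vector given HIGH/LOW labels.

    ``ddof=0`` (maximum-likelihood SD) is the default and keeps IG >= 0;
    ``ddof=1`` switches to sample SDs.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if x.shape != labels.shape:
        raise DataError("x and labels must align")
    hi = x[labels == GROUP_HIGH]
    lo = x[labels == GROUP_LOW]
    if len(hi) < 2 or len(lo) < 2:
        raise DataError("each group needs at least 2 samples")
    sd_pool = float(np.std(x, ddof=ddof))
    sd_hi = float(np.std(hi, ddof=ddof))
    sd_lo = float(np.std(lo, ddof=ddof))
    return _ig_from_sds(sd_pool, sd_hi, sd_lo, len(hi), len(lo), constant)


def _ig_from_sds(sd_pool: float, sd_hi: float, sd_lo: float,
                 n_hi: int, n_lo: int, constant: float) -> float:
    if sd_pool == 0.0:
        return 0.0
    if sd_hi == 0.0 or sd_lo == 0.0:
        return math.inf
    n = n_hi + n_lo
    h_pool = entropy(sd_pool, constant)
    h_cond = (n_hi * entropy(sd_hi, constant) + n_lo * entropy(sd_lo, constant)) / n
    return h_pool - h_cond


def information_gain_table(m: AbundanceMatrix, labels: Sequence[str],
                           constant: float = EULER_MASCHERONI, ddof: int = 0) -> pd.DataFrame:
    """Per-contig information gain over the grouped samples.

    Returns a DataFrame indexed by feature id with columns n_high, n_low,
    pooled_sd, sd_high, sd_low, ig_bits, degenerate, rank (dense rank by
    ig_bits descending, degenerate +inf contigs first, ties sharing the
    earlier stable order) and selected (all False until
    :func:`select_top_percentile`).
    """
    labels = np.asarray(labels)
    if len(labels) != m.n_samples:
        raise DataError("labels must align with matrix samples")
    hi_mask = labels == GROUP_HIGH
    lo_mask = labels == GROUP_LOW
    n_hi, n_lo = int(hi_mask.sum()), int(lo_mask.sum())
    if n_hi < 2 or n_lo < 2:
        raise DataError("each group needs at least 2 samples")
    X = m.values
    sd_pool = np.std(X, axis=0, ddof=ddof)
    sd_hi = np.std(X[hi_mask], axis=0, ddof=ddof)
    sd_lo = np.std(X[lo_mask], axis=0, ddof=ddof)
    n = n_hi + n_lo
    with np.errstate(divide="ignore", invalid="ignore"):
        ig = (np.log2(sd_pool)
              - (n_hi * np.log2(sd_hi) + n_lo * np.log2(sd_lo)) / n)
    # the sqrt(2*pi*constant) factor cancels because the weights sum to 1
    degenerate = (sd_hi == 0) | (sd_lo == 0) | (sd_pool == 0)
    ig = np.where(sd_pool == 0, 0.0, ig)
    ig = np.where((sd_pool > 0) & ((sd_hi == 0) | (sd_lo == 0)), np.inf, ig)
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.info("information gain: %d degenerate contig(s)", n_degenerate)
    tab = pd.DataFrame(
        {
            "n_high": n_hi,
            "n_low": n_lo,
            "pooled_sd": sd_pool,
            "sd_high": sd_hi,
            "sd_low": sd_lo,
            "ig_bits": ig,
            "degenerate": degenerate,
        },
        index=pd.Index(m.feature_ids, name="feature_id"),
    )
    # stable descending rank: +inf (degenerate, perfectly separating) first
    order = np.argsort(-ig, kind="stable")
    rank = np.empty(len(ig), dtype=int)
    rank[order] = np.arange(1, len(ig) + 1)
    tab["rank"] = rank
    tab["selected"] = False
    return tab


def n_selected(n_features: int, percentile: float) -> int:
    """Number of features retained by a top-percentile cut: ceil((1 - p/100) * n)."""
    if not 0 < percentile < 100:
        raise DataError("percentile must be in (0, 100)")
    # round before ceil so e.g. (1 - 95/100)*100 -> exactly 5, not 5 + 4e-15
    return int(math.ceil(round(n_features * (100.0 - percentile) / 100.0, 9)))


def select_top_percentile(tab: pd.DataFrame, percentile: float = 95.0) -> pd.DataFrame:
    """Mark the top-ranked contigs above the IG percentile as selected.

    Retains ceil((1 - percentile/100) * n_features) contigs.  A tie in ig_bits
    straddling the cut is resolved by the stable feature order with a warning.
    """
    if len(tab) == 0:
        raise DataError("empty information-gain table")
    k = n_selected(len(tab), percentile)
    out = tab.copy()
    out["selected"] = out["rank"] <= k
    if 0 < k < len(tab):
        ranked = out.sort_values("rank")
        ig_in = ranked["ig_bits"].iloc[k - 1]
        ig_out = ranked["ig_bits"].iloc[k]
        if ig_in == ig_out:
            warnings.warn("information-gain tie at the selection boundary; "
                          "resolved by stable feature order", stacklevel=2)
            logger.warning("IG tie at selection boundary (k=%d)", k)
    logger.info("information gain selected %d of %d contigs (percentile %.1f)",
                k, len(tab), percentile)
    return out


def selected_features(tab: pd.DataFrame) -> list:
    return list(tab.index[tab["selected"]])


def write_infogain_tsv(tab: pd.DataFrame, path) -> None:
    cols = ["n_high", "n_low", "pooled_sd", "sd_high", "sd_low", "ig_bits", "rank", "selected"]
    tab[cols].to_csv(path, sep="\t")
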
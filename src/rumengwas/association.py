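"""Per-contig logistic metaGWAS, taxonomy-level association, trait correlations.

The metaGWAS fits, for every pre-selected contig, a logistic regression of the
HIGH/LOW group (coded 1/0) on that contig's CPM, and tests the slope with a
Wald z test.  Contigs are declared significant at a configurable raw alpha
(0.05 by default, no multiple-testing correction; Benjamini–Hochberg is an
opt-in).  Complete separation — a contig whose CPM perfectly divides the two
groups, where the logistic MLE diverges — is detected up front and reported as
missing-with-reason rather than fitted.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core_io import GROUP_HIGH, GROUP_LOW, AbundanceMatrix, DataError, PhenotypeTable

logger = logging.getLogger("rumengwas")

#: Continuous traits scanned by the correlation panel when present.
CORRELATION_TRAITS = ("fe", "rfi", "dmi", "milk_yield", "milk_solids", "body_weight")


def _encode_groups(groups: Sequence[str]) -> np.ndarray:
    groups = np.asarray(groups)
    bad = set(np.unique(groups)) - {GROUP_HIGH, GROUP_LOW}
    if bad:
        raise DataError(f"unexpected group labels {sorted(bad)}")
    y = (groups == GROUP_HIGH).astype(float)
    if y.min() == y.max():
        raise DataError("both HIGH and LOW groups are required")
    return y


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation: the predictor ranges of the two classes do not overlap."""
    x1, x0 = x[y == 1], x[y == 0]
    return x1.min() > x0.max() or x0.min() > x1.max()


def metagwas(m: AbundanceMatrix, groups: Sequence[str], alpha: float = 0.05,
             standardize: bool = True, correction: str | None = None) -> pd.DataFrame:
    """Logistic regression of group (HIGH=1, LOW=0) on each contig's CPM.

    Returns a DataFrame indexed by feature id with beta (slope on the —
    optionally z-standardized — CPM scale), se, Wald z statistic, p_value,
    converged, separation, reason and the significant flag at ``alpha``.
    ``correction='bh'`` applies Benjamini–Hochberg to the p-values first.
    """
    y = _encode_groups(groups)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise DataError("need at least 2 samples per group")
    X = m.values
    rows = []
    for j, fid in enumerate(m.feature_ids):
        x = X[:, j].astype(float)
        rec = {"feature_id": fid, "beta": np.nan, "se": np.nan, "statistic": np.nan,
               "p_value": np.nan, "converged": False, "separation": False, "reason": ""}
        sd = x.std(ddof=0)
        if sd == 0:
            rec["reason"] = "constant"
            rows.append(rec)
            continue
        if _is_separated(x, y):
            rec["separation"] = True
            rec["reason"] = "complete separation"
            rows.append(rec)
            continue
        xs = (x - x.mean()) / sd if standardize else x
        design = sm.add_constant(xs)
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            rec["separation"] = True
            rec["reason"] = "complete separation"
            rows.append(rec)
            continue
        rec["converged"] = bool(fit.mle_retvals.get("converged", False))
        if not rec["converged"]:
            rec["reason"] = "did not converge"
        rec["beta"] = float(fit.params[1])
        rec["se"] = float(fit.bse[1])
        rec["statistic"] = float(fit.tvalues[1])
        rec["p_value"] = float(fit.pvalues[1])
        rows.append(rec)
    tab = pd.DataFrame(rows).set_index("feature_id")
    tab.attrs["standardized"] = standardize
    if correction == "bh":
        ok = tab["p_value"].notna()
        adj = np.full(len(tab), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(tab.loc[ok, "p_value"], method="fdr_bh")[1]
        tab["p_adjusted"] = adj
        pcol = "p_adjusted"
    else:
        pcol = "p_value"
    tab["significant"] = tab["converged"] & (tab[pcol] < alpha)
    logger.info("metaGWAS: %d/%d significant at alpha=%g (%d separated, %d failed)",
                int(tab["significant"].sum()), len(tab), alpha,
                int(tab["separation"].sum()),
                int((~tab["converged"] & ~tab["separation"]).sum()))
    return tab


def significant_features(tab: pd.DataFrame) -> list:
    """Contigs flagged significant, excluding separated/unconverged fits."""
    return list(tab.index[tab["significant"]])


def taxa_association(rel: AbundanceMatrix, groups: Sequence[str],
                     parity: Sequence[str], alpha: float = 0.05,
                     direction: str = "abundance_response") -> pd.DataFrame:
    """Association of taxon relative abundances with efficiency group and parity.

    Default model (``abundance_response``): binomial-family GLM with logit link
    of the taxon's relative abundance on group + parity fixed effects; the
    reported p-value is the group effect's.  ``direction='group_response'``
    instead fits a logistic regression of group on abundance + parity.
    """
    if rel.unit != "relative":
        raise DataError("taxa_association expects relative abundances")
    y_group = _encode_groups(groups)
    parity = np.asarray(parity)
    if len(parity) != rel.n_samples:
        raise DataError("parity must align with samples")
    par = (parity == "multiparous").astype(float)
    if par.min() == par.max():
        logger.warning("parity has a single level; its effect is not estimable")
    rows = []
    for j, fid in enumerate(rel.feature_ids):
        ab = rel.values[:, j]
        rec = {"feature_id": fid, "beta": np.nan, "se": np.nan, "statistic": np.nan,
               "p_value": np.nan, "converged": False, "separation": False, "reason": ""}
        if np.all(ab == 0):
            rec["reason"] = "absent in all samples"
            rows.append(rec)
            continue
        try:
            if direction == "abundance_response":
                design = sm.add_constant(np.column_stack([y_group, par]))
                if np.linalg.matrix_rank(design) < design.shape[1]:
                    rec["reason"] = "rank-deficient design (parity confounded with group)"
                    logger.warning("taxa_association: %s", rec["reason"])
                    rows.append(rec)
                    continue
                fit = sm.GLM(ab, design, family=sm.families.Binomial()).fit()
                idx = 1  # group effect
            elif direction == "group_response":
                design = sm.add_constant(np.column_stack([ab, par]))
                fit = sm.Logit(y_group, design).fit(disp=0, maxiter=200)
                idx = 1
            else:
                raise DataError(f"unknown direction {direction!r}")
        except (PerfectSeparationError, np.linalg.LinAlgError):
            rec["separation"] = True
            rec["reason"] = "complete separation"
            rows.append(rec)
            continue
        rec["converged"] = bool(getattr(fit, "converged", True))
        rec["beta"] = float(fit.params[idx])
        rec["se"] = float(fit.bse[idx])
        rec["statistic"] = float(fit.tvalues[idx])
        rec["p_value"] = float(fit.pvalues[idx])
        rows.append(rec)
    tab = pd.DataFrame(rows).set_index("feature_id")
    tab["significant"] = tab["converged"] & (tab["p_value"] < alpha)
    return tab


def trait_correlations(m: AbundanceMatrix, phen: PhenotypeTable, top_k: int,
                       assoc: pd.DataFrame,
                       traits: Sequence[str] = CORRELATION_TRAITS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho between the top-k smallest-p contigs and continuous traits.

    Returns (rho table: features x traits, summary: per-trait mean |rho| and
    quartiles of rho).  Traits absent from the phenotype table are skipped;
    a zero-variance trait yields NaN with a log message.
    """
    usable = assoc[assoc["p_value"].notna()].sort_values("p_value", kind="stable")
    if top_k > len(usable):
        raise DataError(f"top_k={top_k} exceeds {len(usable)} associated features")
    feats = list(usable.index[:top_k])
    sub = m.restrict(feats)
    ph = phen.data.loc[sub.sample_ids]
    present = [t for t in traits if t in ph.columns and ph[t].notna().all()]
    rho = pd.DataFrame(index=pd.Index(feats, name="feature_id"),
                       columns=present, dtype=float)
    for t in present:
        tv = ph[t].to_numpy(dtype=float)
        if np.std(tv) == 0:
            logger.warning("trait %s has zero variance; correlations undefined", t)
            rho[t] = np.nan
            continue
        r, _ = stats.spearmanr(sub.values, tv)
        # spearmanr returns the full (p+1)x(p+1) matrix; last row vs features
        r = np.atleast_2d(r)
        rho[t] = r[-1, :-1] if r.shape[0] > 1 else float(r)
    summary = pd.DataFrame({
        "mean_abs_rho": rho.abs().mean(),
        "q1": rho.quantile(0.25),
        "median": rho.quantile(0.5),
        "q3": rho.quantile(0.75),
    })
    return rho, summary


def write_association_tsv(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, sep="\t")
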
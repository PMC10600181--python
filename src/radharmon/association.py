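"""Feature–mutation logistic association scan with FDR control.

For every (radiomic feature, gene) pair a univariable logistic regression
``logit P(mutated) = b0 + b1 * feature`` is fit by maximum likelihood and
the slope tested with a Wald z statistic.  Genes are pre-filtered on
minor mutation frequency (default floor 0.05), p-values are adjusted by
the Benjamini–Hochberg step-up procedure within each feature across the
retained genes, and the scans obtained from differently harmonized
versions of the same matrix are compared by the squared Pearson
correlation of their paired p-values.

Features are fed to the regressions on their raw scale by default — the
slope is then "log-odds per feature unit", matching how such scans report
effect sizes — with an optional per-SD standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import FeatureMatrix, MutationMatrix

__all__ = ["AssociationTable", "filter_genes", "logistic_fit", "wald_p",
           "bh_adjust", "scan", "method_concordance"]

#: separation guard on the per-SD slope scale (|b1| * SD(x) above this, or a
#: comparably huge standard error, is treated as quasi-separation)
SEPARATION_GUARD = 15.0


@dataclass
class LogisticFitResult:
    estimate: float                    # log-odds per feature unit
    se: float
    z: float
    p: float
    converged: bool


@dataclass
class AssociationTable:
    """One logistic-regression record per (feature, retained gene)."""

    method: str
    records: pd.DataFrame              # feature, gene, estimate, se, z, p, p_adj, ...
    m_genes: int                       # family size used for BH within each feature

    def significant(self, level: float = 0.05) -> pd.DataFrame:
        r = self.records
        return r[(r["converged"]) & (r["p_adj"] < level)]


def filter_genes(mut: MutationMatrix, min_freq: float = 0.05) -> MutationMatrix:
    """Drop genes whose *minor* mutation frequency is below ``min_freq``.

    The minor frequency is ``min(f, 1 - f)`` for cohort mutation fraction
    f, so both very rare and near-fixed mutations are removed.
    """
    f = mut.frequencies()
    keep = np.minimum(f, 1 - f) >= min_freq
    if not keep.any():
        raise ValueError("all genes removed by the frequency filter")
    return MutationMatrix(values=mut.values.loc[:, keep.to_numpy()])


def logistic_fit(y: np.ndarray, x: np.ndarray) -> LogisticFitResult:
    """ML fit of ``logit P(y=1) = b0 + b1*x`` with Wald inference on b1.

    Newton/IRLS (max 25 iterations, deviance tolerance 1e-8); the standard
    error comes from the inverse observed information.  (Quasi-)complete
    separation is flagged — ``converged=False`` with NaN p — rather than
    raised, so a scan can record and skip the pair.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("y and x must be equal-length vectors of size >= 3")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in x")
    if np.all(y == y[0]):
        raise ValueError("y is constant; logistic model undefined")

    X = sm.add_constant(x)
    sd_x = x.std(ddof=1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=25, tol=1e-8,
                                     disp=0, warn_convergence=False)
        b1 = float(res.params[1])
        se = float(res.bse[1])
        ok = bool(res.mle_retvals["converged"])
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFitResult(np.nan, np.nan, np.nan, np.nan, False)
    if (not np.isfinite(b1) or not np.isfinite(se)
            or abs(b1) * sd_x > SEPARATION_GUARD
            or se * sd_x > SEPARATION_GUARD or not ok):
        return LogisticFitResult(b1, se, np.nan, np.nan, False)
    z = b1 / se
    return LogisticFitResult(b1, se, z, wald_p(z), True)


def wald_p(z: float) -> float:
    """Two-sided standard-normal tail probability, ``2 * (1 - Phi(|z|))``."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    Adjusted values are order-preserving, >= the raw p, and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan(data: FeatureMatrix, mut: MutationMatrix, method: str,
         standardize: bool = False, level: float = 0.05) -> AssociationTable:
    """Fit one logistic model per (feature, gene) and BH-adjust per feature.

    The mutation matrix must be pre-filtered (see :func:`filter_genes`)
    and aligned on subject ids.  BH families are the retained genes within
    each feature; records from non-converged fits are excluded from the
    family with a warning and carry NaN adjusted p.
    """
    if list(data.subject_ids) != list(mut.subject_ids):
        raise ValueError("feature and mutation matrices have different subjects")
    X = data.values.to_numpy()
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    M = mut.values.to_numpy()

    rows = []
    n_failed = 0
    for gi, feat in enumerate(data.feature_names):
        for ji, gene in enumerate(mut.gene_names):
            fit = logistic_fit(M[:, ji], X[:, gi])
            n_failed += not fit.converged
            rows.append((feat, gene, fit.estimate, fit.se, fit.z, fit.p,
                         fit.converged))
    rec = pd.DataFrame(rows, columns=["feature", "gene", "estimate", "se",
                                      "z", "p", "converged"])
    if n_failed:
        warnings.warn(f"{n_failed} fits flagged as separated/non-converged "
                      "and excluded from BH adjustment")
    rec["p_adj"] = np.nan
    for feat, grp in rec.groupby("feature", sort=False):
        ok = grp["converged"] & grp["p"].notna()
        if ok.any():
            rec.loc[grp.index[ok], "p_adj"] = bh_adjust(grp.loc[ok, "p"])
    rec["significant"] = rec["converged"] & (rec["p_adj"] < level)
    return AssociationTable(method=method, records=rec, m_genes=mut.n_genes)


def method_concordance(table_a: AssociationTable, table_b: AssociationTable,
                       log10: bool = False) -> float:
    """Squared Pearson correlation of paired raw p-values across methods.

    Records are matched on (feature, gene); only pairs converged in both
    tables enter.  ``log10=True`` correlates ``-log10 p`` instead.
    """
    a = table_a.records.set_index(["feature", "gene"])
    b = table_b.records.set_index(["feature", "gene"])
    shared = a.index.intersection(b.index)
    pa = a.loc[shared, "p"]
    pb = b.loc[shared, "p"]
    keep = (a.loc[shared, "converged"] & b.loc[shared, "converged"]
            & pa.notna() & pb.notna())
    pa, pb = pa[keep].to_numpy(), pb[keep].to_numpy()
    if pa.size < 2:
        raise ValueError("need >= 2 shared converged records")
    if log10:
        pa, pb = -np.log10(pa), -np.log10(pb)
    r = np.corrcoef(pa, pb)[0, 1]
    return float(r ** 2)
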
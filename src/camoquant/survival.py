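"""Survival analysis of interval-checked predation data.

Field predation experiments record, for each model replicate, the
treatment (background type), the first check time at which attack
damage was observed (status 1) or the study end if it survived
(status 0, right-censored).  This module provides the three standard
analyses for such data:

* Kaplan–Meier product-limit survival curves per treatment with
  Greenwood standard errors,
* pairwise log-rank tests with Benjamini–Hochberg adjustment, and
* Cox proportional-hazards regression maximising the Efron (default)
  or Breslow partial likelihood by Newton–Raphson, with hazard ratios
  and an overall Wald test.

Efron tie handling is the default because check-time data are heavily
tied.  Attack time is the check time at which damage was observed (not
an interval midpoint).  Event tables are plain ``pandas`` data frames
with columns ``treatment``, ``time_h``, ``status`` (1 = attacked,
0 = censored) and optional ``replicate_id`` / covariate columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .errors import ConvergenceError, DomainError, UsageError

REQUIRED_COLUMNS = ("treatment", "time_h", "status")


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table and return a cleaned copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"event table missing columns {missing}")
    if len(df) == 0:
        raise UsageError("event table is empty")
    out = df.copy()
    out["treatment"] = out["treatment"].astype(str)
    out["time_h"] = out["time_h"].astype(float)
    out["status"] = out["status"].astype(int)
    if (out["time_h"] <= 0).any():
        raise DomainError("event times must be positive")
    if not out["status"].isin([0, 1]).all():
        raise DomainError("status must be 0 (censored) or 1 (event)")
    return out


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMFit:
    """Per-treatment product-limit curves.

    ``tables`` maps treatment → data frame with columns ``time_h``,
    ``n_risk``, ``n_event``, ``n_censor``, ``survival``, ``se``
    (Greenwood), one row per distinct observed time.
    """

    tables: dict[str, pd.DataFrame]

    def survival_at(self, treatment: str, t: float) -> tuple[float, float]:
        """Step-function value S(t) and its Greenwood SE."""
        tab = self.tables[treatment]
        past = tab[tab["time_h"] <= t]
        if len(past) == 0:
            return 1.0, 0.0
        row = past.iloc[-1]
        return float(row["survival"]), float(row["se"])

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for trt, tab in self.tables.items():
            frames.append(tab.assign(treatment=trt))
        return pd.concat(frames, ignore_index=True)[
            ["treatment", "time_h", "n_risk", "n_event", "n_censor", "survival", "se"]
        ]


def km_fit(df: pd.DataFrame, by: str = "treatment") -> KMFit:
    """Kaplan–Meier estimator S(t) = Π (1 − d_j/n_j) per group, with
    Greenwood variance S(t)² Σ d_j / (n_j (n_j − d_j))."""
    df = validate_events(df)
    tables: dict[str, pd.DataFrame] = {}
    for trt, grp in df.groupby(by, sort=True):
        times = np.sort(grp["time_h"].unique())
        t_arr = grp["time_h"].to_numpy()
        s_arr = grp["status"].to_numpy()
        surv = 1.0
        gw = 0.0  # running Greenwood sum
        rows = []
        for t in times:
            n_risk = int((t_arr >= t).sum())
            d = int(((t_arr == t) & (s_arr == 1)).sum())
            c = int(((t_arr == t) & (s_arr == 0)).sum())
            if d > 0:
                surv *= 1.0 - d / n_risk
                if n_risk > d:
                    gw += d / (n_risk * (n_risk - d))
            se = surv * np.sqrt(gw) if surv > 0 else 0.0
            rows.append((t, n_risk, d, c, surv, se))
        tables[str(trt)] = pd.DataFrame(
            rows, columns=["time_h", "n_risk", "n_event", "n_censor", "survival", "se"]
        )
    if not tables:
        raise UsageError("no groups found in the event table")
    return KMFit(tables)


# ---------------------------------------------------------------------------
# Pairwise log-rank
# ---------------------------------------------------------------------------

def logrank_pairwise(df: pd.DataFrame, adjust: str = "bh") -> pd.DataFrame:
    """Pairwise log-rank χ² tests between treatments.

    Returns one row per unordered pair with ``chi2``, ``p`` and the
    adjusted ``p_adj`` (Benjamini–Hochberg by default; ``adjust=None``
    leaves raw p-values).
    """
    df = validate_events(df)
    treatments = sorted(df["treatment"].unique())
    if len(treatments) < 2:
        raise UsageError("pairwise log-rank needs at least two treatments")
    rows = []
    for a, b in combinations(treatments, 2):
        ga = df[df["treatment"] == a]
        gb = df[df["treatment"] == b]
        res = logrank_test(
            ga["time_h"], gb["time_h"],
            event_observed_A=ga["status"], event_observed_B=gb["status"],
        )
        rows.append({"a": a, "b": b,
                     "chi2": float(res.test_statistic), "p": float(res.p_value)})
    out = pd.DataFrame(rows)
    if adjust is None or adjust == "none":
        out["p_adj"] = out["p"]
    elif adjust in ("bh", "fdr_bh"):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        raise UsageError(f"unknown adjustment {adjust!r}")
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox regression result: log-hazard coefficients versus a named
    reference level, hazard ratios exp(coef), Wald test."""

    coef: pd.Series
    se: pd.Series
    reference_level: str
    wald_stat: float
    wald_df: int
    wald_p: float
    ties: str
    loglik: float
    n_iter: int
    converged: bool

    @property
    def hazard_ratio(self) -> pd.Series:
        return np.exp(self.coef)

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hazard_ratio": self.hazard_ratio,
                "se": self.se,
                "z": z,
                "p": chi2_dist.sf(z**2, df=1),
            }
        )


def _partial_likelihood(beta, X, time, event, ties):
    """Log partial likelihood, gradient and information matrix."""
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(X.shape[1])
    info = np.zeros((X.shape[1], X.shape[1]))
    for t in np.unique(time[event == 1]):
        risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        wr = w[risk]
        Xr = X[risk]
        WR = wr.sum()
        SR = Xr.T @ wr
        QR = Xr.T @ (Xr * wr[:, None])
        ll += eta[dead].sum()
        grad += X[dead].sum(axis=0)
        if ties == "breslow":
            steps = [(WR, SR, QR)] * d
        elif ties == "efron":
            wd = w[dead]
            Xd = X[dead]
            WD = wd.sum()
            SD = Xd.T @ wd
            QD = Xd.T @ (Xd * wd[:, None])
            steps = [
                (WR - (l / d) * WD, SR - (l / d) * SD, QR - (l / d) * QD)
                for l in range(d)
            ]
        else:
            raise UsageError(f"unknown tie handling {ties!r}")
        for Wl, Sl, Ql in steps:
            ll -= np.log(Wl)
            mu = Sl / Wl
            grad -= mu
            info += Ql / Wl - np.outer(mu, mu)
    return ll, grad, info


def cox_fit(
    df: pd.DataFrame,
    covariates=("treatment",),
    ties: str = "efron",
    reference: str | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Categorical covariates are dummy-coded against a reference level
    (for ``treatment``: alphabetically first unless ``reference`` is
    given).  Convergence requires gradient norm < ``tol`` within
    ``max_iter`` iterations.
    """
    df = validate_events(df)
    if df["status"].sum() == 0:
        raise UsageError("Cox regression needs at least one event")
    cols = []
    names = []
    ref_level = ""
    for cov in covariates:
        if cov not in df.columns:
            raise UsageError(f"covariate {cov!r} not in event table")
        col = df[cov]
        if col.dtype.kind in "OUS" or col.dtype.name == "category":
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise UsageError(f"covariate {cov!r} has a single level")
            ref = reference if (cov == "treatment" and reference is not None) else levels[0]
            if ref not in levels:
                raise UsageError(f"reference level {ref!r} not among {levels}")
            if cov == "treatment":
                ref_level = ref
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(cov)
    if not cols:
        raise UsageError("no usable covariates")
    X = np.column_stack(cols)
    time = df["time_h"].to_numpy(float)
    event = df["status"].to_numpy(int)

    beta = np.zeros(X.shape[1])
    ll, grad, info = _partial_likelihood(beta, X, time, event, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving line search on the partial likelihood
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_ll, new_grad, new_info = _partial_likelihood(new_beta, X, time, event, ties)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
    else:
        it = max_iter
    if not converged and np.linalg.norm(grad) < tol:
        converged = True
    if not converged:
        raise ConvergenceError(
            f"Newton–Raphson did not reach gradient norm {tol} in {max_iter} iterations"
        )
    if np.max(np.abs(beta)) > 15:
        warnings.warn(
            "very large coefficient; possible complete separation", stacklevel=2
        )
    cov_mat = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov_mat))
    wald = float(beta @ info @ beta)
    wald_df = X.shape[1]
    return CoxFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        reference_level=ref_level,
        wald_stat=wald,
        wald_df=wald_df,
        wald_p=float(chi2_dist.sf(wald, df=wald_df)),
        ties=ties,
        loglik=float(ll),
        n_iter=it,
        converged=converged,
    )
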
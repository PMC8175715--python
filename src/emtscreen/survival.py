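"""Survival estimators: Cox proportional hazards, Kaplan-Meier, log-rank.

The Cox fitter maximizes the partial likelihood by Newton-Raphson with
the Efron correction for tied event times (integer-valued synthetic
times produce heavy ties, where Efron is markedly less biased than
Breslow).  It is deliberately self-contained and fast for a single
covariate, because the genome-wide prognostic screen refits it once per
gene.  The 95% confidence interval is Wald-style on the log scale,
``exp(beta +- 1.96 * se)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    InputError,
    InsufficientDataError,
)


class PartialLikelihood:
    """Efron partial likelihood for fixed (time, event), reusable across
    covariate vectors.

    Sorting and event-time grouping are done once in the constructor so
    that a genome-wide screen can refit thousands of single-covariate
    models against the same survival data cheaply.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or time.shape != event.shape:
            raise InputError("time and event must be 1-D arrays of equal length")
        if (time < 0).any():
            raise InputError("negative survival times")
        if not np.isin(event, (0, 1)).all():
            raise InputError("event indicator must be 0/1")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order].astype(int)
        self.n_events = int(self.event.sum())
        if self.n_events < 1:
            raise InsufficientDataError("no events in survival data")
        # tied-time groups; per event: its group start in the sorted
        # arrays, its Efron fraction l/d, and its group id (all
        # precomputed so the likelihood is loop-free over groups)
        change = np.flatnonzero(np.diff(self.time)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [self.n]])
        ev_idx, ev_start, ev_frac, ev_gid = [], [], [], []
        gid = 0
        for s, e in zip(starts, ends):
            members = np.flatnonzero(self.event[s:e]) + s
            d = members.size
            if d == 0:
                continue
            ev_idx.append(members)
            ev_start.append(np.full(d, s))
            ev_frac.append(np.arange(d) / d)
            ev_gid.append(np.full(d, gid))
            gid += 1
        self.ev_idx = np.concatenate(ev_idx)
        self.ev_start = np.concatenate(ev_start)
        self.ev_frac = np.concatenate(ev_frac)
        self.ev_gid = np.concatenate(ev_gid)
        # position of each group's first event within the event arrays
        self.group_first = np.flatnonzero(
            np.diff(self.ev_gid, prepend=self.ev_gid[0] - 1)
        )

    def loglik_grad_info(self, x_sorted: np.ndarray, beta: np.ndarray):
        """Log partial likelihood, score vector and information matrix
        (Efron ties), vectorized over event-time groups."""
        x = x_sorted if x_sorted.ndim == 2 else x_sorted[:, None]
        p = x.shape[1]
        eta = np.clip(x @ beta, -500, 500)
        w = np.exp(eta)
        wx = w[:, None] * x
        wxx = wx[:, :, None] * x[:, None, :]
        # suffix sums over the risk set {i : time_i >= t_group}
        c0 = np.concatenate([[0.0], np.cumsum(w)])
        c1 = np.concatenate([np.zeros((1, p)), np.cumsum(wx, axis=0)])
        c2 = np.concatenate([np.zeros((1, p, p)), np.cumsum(wxx, axis=0)])
        s0 = c0[-1] - c0[self.ev_start]
        s1 = c1[-1] - c1[self.ev_start]
        s2 = c2[-1] - c2[self.ev_start]
        # within-group sums over the tied events, broadcast back per event
        d0 = np.add.reduceat(w[self.ev_idx], self.group_first)[self.ev_gid]
        d1 = np.add.reduceat(wx[self.ev_idx], self.group_first, axis=0)[self.ev_gid]
        d2 = np.add.reduceat(wxx[self.ev_idx], self.group_first, axis=0)[self.ev_gid]
        frac = self.ev_frac
        phi0 = s0 - frac * d0
        phi1 = s1 - frac[:, None] * d1
        phi2 = s2 - frac[:, None, None] * d2
        ll = float(eta[self.ev_idx].sum() - np.log(phi0).sum())
        ratio1 = phi1 / phi0[:, None]
        grad = x[self.ev_idx].sum(axis=0) - ratio1.sum(axis=0)
        info = (phi2 / phi0[:, None, None]).sum(axis=0) - ratio1.T @ ratio1
        return ll, grad, info

    def fit(
        self,
        x_sorted: np.ndarray,
        max_iter: int = 100,
        tol_score: float = 1e-8,
        tol_step: float = 1e-10,
    ):
        """Newton-Raphson with step halving; returns
        (beta, covariance, loglik, n_iter, converged)."""
        x = x_sorted if x_sorted.ndim == 2 else x_sorted[:, None]
        sd = x.std(axis=0)
        if (sd == 0).any():
            raise DegenerateInputError("constant covariate in Cox fit")
        beta = np.zeros(x.shape[1])
        ll, grad, info = self.loglik_grad_info(x, beta)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            # step halving keeps the likelihood ascending
            factor = 1.0
            for _ in range(30):
                candidate = beta + factor * step
                new_ll, new_grad, new_info = self.loglik_grad_info(x, candidate)
                if new_ll >= ll - 1e-12:
                    break
                factor /= 2.0
            beta, ll, grad, info = candidate, new_ll, new_grad, new_info
            if np.max(np.abs(beta) * sd) > 10:
                # one covariate sd multiplying the hazard by more than e^10
                # is the signature of a monotone likelihood, whether the
                # iteration stalls there or "converges" on the plateau
                raise ConvergenceError(
                    "monotone partial likelihood (perfect separation): "
                    f"|beta| diverged to {beta} after {n_iter} iterations"
                )
            if np.max(np.abs(grad)) < tol_score or np.max(np.abs(factor * step)) < tol_step:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"Cox fit did not converge in {max_iter} iterations "
                f"(max |score| = {np.max(np.abs(grad)):.3g})"
            )
        cov = np.linalg.inv(info)
        return beta, cov, ll, n_iter, converged


@dataclass
class CoxPHResults:
    """Fitted Cox proportional-hazards model.

    ``params`` are log hazard ratios; ``zvalues`` are Wald statistics
    ``beta / se``; ``conf_int`` is ``exp(beta +- 1.96 se)``.
    """

    params: pd.Series
    bse: pd.Series
    llf: float
    n: int
    n_events: int
    ties: str = "efron"
    n_iter: int = 0
    covariance: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def zvalues(self) -> pd.Series:
        return (self.params / self.bse).rename("z")

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index, name="p"
        )

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    def conf_int(self, z_crit: float = 1.96) -> pd.DataFrame:
        lower = np.exp(self.params - z_crit * self.bse)
        upper = np.exp(self.params + z_crit * self.bse)
        return pd.DataFrame({"ci95_lower": lower, "ci95_upper": upper})

    def summary(self) -> str:
        ci = self.conf_int()
        table = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "HR": self.hazard_ratios,
                "ci95_lower": ci["ci95_lower"],
                "ci95_upper": ci["ci95_upper"],
            }
        )
        head = (
            f"Cox proportional hazards ({self.ties} ties)\n"
            f"n = {self.n}, events = {self.n_events}, "
            f"log partial likelihood = {self.llf:.4f}\n"
        )
        return head + table.to_string(float_format=lambda v: f"{v:.4f}")


class CoxPH:
    """Cox proportional-hazards model.

    Parameters
    ----------
    time, event : 1-D arrays
        Follow-up time and event indicator (1 = event, 0 = censored).
    exog : DataFrame or 2-D array
        Covariates, one column per term.
    """

    def __init__(self, time, event, exog, ties: str = "efron"):
        if ties != "efron":
            raise InputError(f"unsupported ties method {ties!r}")
        self.ties = ties
        if isinstance(exog, pd.Series):
            exog = exog.to_frame()
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            x = exog.to_numpy(dtype=float)
        else:
            x = np.asarray(exog, dtype=float)
            if x.ndim == 1:
                x = x[:, None]
            self.exog_names = [f"x{i}" for i in range(x.shape[1])]
        if not np.isfinite(x).all():
            raise InputError("non-finite covariate values")
        self._pl = PartialLikelihood(np.asarray(time, dtype=float), np.asarray(event))
        self._x = x[self._pl.order]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, covariates: list[str], **kwargs) -> "CoxPH":
        """Build from a survival table with ``time`` and ``event`` columns."""
        missing = [c for c in ("time", "event", *covariates) if c not in data.columns]
        if missing:
            raise InputError(f"survival table missing columns {missing}")
        return cls(
            data["time"].to_numpy(), data["event"].to_numpy(), data[covariates], **kwargs
        )

    def fit(self, **kwargs) -> CoxPHResults:
        beta, cov, ll, n_iter, _ = self._pl.fit(self._x, **kwargs)
        se = np.sqrt(np.diag(cov))
        return CoxPHResults(
            params=pd.Series(beta, index=self.exog_names, name="coef"),
            bse=pd.Series(se, index=self.exog_names, name="se"),
            llf=float(ll),
            n=self._pl.n,
            n_events=self._pl.n_events,
            ties=self.ties,
            n_iter=n_iter,
            covariance=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
        )


def cox_fit(data: pd.DataFrame, covariates: list[str], **kwargs) -> CoxPHResults:
    """Univariable or multivariable Cox fit on a survival table."""
    return CoxPH.from_dataframe(data, covariates).fit(**kwargs)


@dataclass
class KMCurve:
    """Product-limit estimate of the survival function.

    ``table`` has one row per distinct time with columns ``n_at_risk``,
    ``n_events``, ``n_censored`` and ``survival`` (right-continuous;
    censorings at a time are counted after the events at that time).
    """

    table: pd.DataFrame
    label: str | None = None

    def survival_at(self, t: float) -> float:
        times = self.table.index.to_numpy()
        below = times <= t
        if not below.any():
            return 1.0
        return float(self.table["survival"].to_numpy()[below][-1])

    def step_function(self) -> pd.DataFrame:
        """The curve as (time, survival) pairs starting at S(0) = 1."""
        steps = self.table.reset_index()[["time", "survival"]]
        return pd.concat(
            [pd.DataFrame({"time": [0.0], "survival": [1.0]}), steps],
            ignore_index=True,
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        steps = self.step_function()
        ax.step(steps["time"], steps["survival"], where="post",
                label=kwargs.pop("label", self.label), **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        return ax


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier estimator for one group."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if time.size == 0:
        raise InsufficientDataError("empty survival data")
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    uniq, first = np.unique(t, return_index=True)
    rows = []
    at_risk = t.size
    surv = 1.0
    for i, u in enumerate(uniq):
        stop = first[i + 1] if i + 1 < uniq.size else t.size
        d_events = int(d[first[i] : stop].sum())
        n_cens = int(stop - first[i] - d_events)
        if d_events > 0:
            surv *= 1.0 - d_events / at_risk
        rows.append((u, at_risk, d_events, n_cens, surv))
        at_risk -= d_events + n_cens
    table = pd.DataFrame(
        rows, columns=["time", "n_at_risk", "n_events", "n_censored", "survival"]
    ).set_index("time")
    return KMCurve(table)


def km_curves(data: pd.DataFrame, group: pd.Series | str) -> dict[str, KMCurve]:
    """Kaplan-Meier per group; ``group`` is a column name or aligned labels."""
    labels = data[group] if isinstance(group, str) else group
    out = {}
    for level in pd.unique(labels):
        mask = (labels == level).to_numpy()
        curve = km_curve(data["time"].to_numpy()[mask], data["event"].to_numpy()[mask])
        curve.label = str(level)
        out[str(level)] = curve
    return out


@dataclass
class LogrankResult:
    statistic: float
    df: int
    pvalue: float


def logrank_test(time, event, group) -> LogrankResult:
    """Multi-group log-rank test (chi-square on observed minus expected)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    labels, group_idx = np.unique(np.asarray(group), return_inverse=True)
    n_groups = labels.size
    if n_groups < 2:
        raise InputError("log-rank test needs >= 2 groups")
    if event.sum() < 1:
        raise InsufficientDataError("no events")
    observed = np.zeros(n_groups)
    expected = np.zeros(n_groups)
    variance = np.zeros((n_groups, n_groups))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_g = np.bincount(group_idx[at_risk], minlength=n_groups).astype(float)
        events_here = (time == t) & (event == 1)
        d = events_here.sum()
        d_g = np.bincount(group_idx[events_here], minlength=n_groups).astype(float)
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            hyper = d * (n - d) / (n - 1)
            variance += hyper * (np.diag(n_g / n) - np.outer(n_g, n_g) / n**2)
    diff = (observed - expected)[:-1]
    v = variance[:-1, :-1]
    if diff.size == 0 or np.allclose(v, 0):
        stat = 0.0
    else:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    df = n_groups - 1
    return LogrankResult(stat, df, float(stats.chi2.sf(stat, df)))


def dichotomize(values: pd.Series, rule: str) -> pd.Series:
    """Split a numeric series into 'low'/'high' at the mean or the median.

    The split rule is always explicit because both conventions are in
    routine use; values strictly above the cutoff are 'high'.
    """
    if rule == "mean":
        cutoff = float(values.mean())
    elif rule == "median":
        cutoff = float(values.median())
    else:
        raise InputError(f"split rule must be 'mean' or 'median', got {rule!r}")
    labels = np.where(values.to_numpy(dtype=float) > cutoff, "high", "low")
    out = pd.Series(labels, index=values.index, name=f"{values.name or 'value'}_group")
    out.attrs["rule"] = rule
    out.attrs["cutoff"] = cutoff
    return out
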
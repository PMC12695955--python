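"""Displacement models: median quantile regression and region transitions.

Two models summarize how breeding-site displacement is structured:

* A median (tau = 0.5) quantile regression of pair distance on a numeric
  predictor (maternal age, or the lag in years between two pupping events).
  The fit minimizes the check (pinball) loss
  ``rho_tau(u) = u * (tau - 1[u < 0])`` exactly: for a two-parameter line
  an optimal solution always passes through two observations with distinct
  predictor values, so the global minimum is found by scoring every such
  candidate line.  One-sided inference for a positive slope uses a paired
  (x, y) bootstrap.
* A multinomial (softmax) logistic regression of pup region on mother natal
  region, fit by Newton iteration on the aggregated 3x3 transition counts,
  reported as relative-risk ratios against a baseline region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geo import ColonyMap, Region

REGION_ORDER = [Region.NORTHERN.value, Region.CENTRAL.value, Region.SOUTHERN.value]


class FitError(ValueError):
    """The data cannot support the requested fit."""


# ---------------------------------------------------------------------------
# median quantile regression
# ---------------------------------------------------------------------------


def check_loss(residuals: np.ndarray, tau: float) -> float:
    """Total pinball loss of a residual vector."""
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _candidate_lines(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope/intercept of every line through two points with distinct x."""
    i, j = np.triu_indices(len(x), k=1)
    keep = x[i] != x[j]
    i, j = i[keep], j[keep]
    slopes = (y[j] - y[i]) / (x[j] - x[i])
    intercepts = y[i] - slopes * x[i]
    return intercepts, slopes


def _pinball_matrix(
    x: np.ndarray, y: np.ndarray, intercepts: np.ndarray, slopes: np.ndarray, tau: float
) -> np.ndarray:
    """Per-candidate, per-point pinball losses (candidates x points)."""
    resid = y[None, :] - intercepts[:, None] - slopes[:, None] * x[None, :]
    return resid * (tau - (resid < 0))


def _exact_fit(
    x: np.ndarray, y: np.ndarray, tau: float
) -> tuple[float, float, float]:
    intercepts, slopes = _candidate_lines(x, y)
    if len(slopes) == 0:
        raise FitError("predictor is constant; a slope cannot be estimated")
    losses = _pinball_matrix(x, y, intercepts, slopes, tau).sum(axis=1)
    best = int(np.argmin(losses))
    return float(intercepts[best]), float(slopes[best]), float(losses[best])


@dataclass
class QuantRegFit:
    tau: float
    intercept: float
    slope: float
    check_loss: float
    p_one_sided: float
    bootstrap_B: int
    seed: int
    n_used: int
    dropped_levels: list
    bootstrap_slopes: np.ndarray = field(repr=False)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Percentile bootstrap confidence interval for the slope."""
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.bootstrap_slopes, [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        lo, hi = self.slope_ci()
        return {
            "tau": self.tau,
            "intercept_m": self.intercept,
            "slope_m_per_year": self.slope,
            "check_loss": self.check_loss,
            "p_one_sided_slope_gt_0": self.p_one_sided,
            "slope_ci95": [lo, hi],
            "bootstrap_B": self.bootstrap_B,
            "seed": self.seed,
            "n_used": self.n_used,
            "dropped_levels": list(self.dropped_levels),
        }


def fit_median_regression(
    x,
    y,
    tau: float = 0.5,
    min_level_count: int = 2,
    B: int = 2000,
    seed: int = 0,
) -> QuantRegFit:
    """Median regression of distance on a discrete numeric predictor.

    Predictor values observed fewer than ``min_level_count`` times are
    dropped (and logged in ``dropped_levels``) before fitting: a lag year
    represented by a single pair is not representative of that lag.  The
    one-sided p-value for the alternative ``slope > 0`` is the proportion
    of paired-bootstrap slopes that are <= 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise FitError("x and y must be aligned")

    levels, counts = np.unique(x, return_counts=True)
    dropped = [float(v) for v in levels[counts < min_level_count]]
    keep = ~np.isin(x, dropped)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise FitError("fewer than 3 observations remain after level filtering")
    if len(np.unique(x)) < 2:
        raise FitError("predictor is constant after level filtering")

    intercept, slope, loss = _exact_fit(x, y, tau)

    # Bootstrap over resample weights: any optimal line for a resampled
    # dataset passes through two of the original points, so the candidate
    # set (and its pinball-loss matrix) is shared across replicates.
    intercepts, slopes = _candidate_lines(x, y)
    loss_matrix = _pinball_matrix(x, y, intercepts, slopes, tau)
    n = len(x)
    rng = np.random.default_rng(seed)
    boot_slopes = np.empty(B)
    for b in range(B):
        while True:
            w = rng.multinomial(n, np.full(n, 1.0 / n)).astype(float)
            support = w > 0
            if len(np.unique(x[support])) >= 2:
                break
        # candidates touching zero-weight points remain valid lines, so the
        # weighted argmin is still the exact optimum for the resample
        boot_slopes[b] = slopes[int(np.argmin(loss_matrix @ w))]

    p_one = float(np.count_nonzero(boot_slopes <= 0.0)) / B
    return QuantRegFit(
        tau=tau,
        intercept=intercept,
        slope=slope,
        check_loss=loss,
        p_one_sided=p_one,
        bootstrap_B=B,
        seed=seed,
        n_used=n,
        dropped_levels=dropped,
        bootstrap_slopes=boot_slopes,
    )


# ---------------------------------------------------------------------------
# region transition table
# ---------------------------------------------------------------------------


@dataclass
class RegionTransitionTable:
    counts: pd.DataFrame  # mother natal region (rows) x pup region (cols)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def natal_percent(self) -> pd.Series:
        return 100.0 * self.row_totals / self.n_pairs

    @property
    def pupping_percent(self) -> pd.Series:
        return 100.0 * self.col_totals / self.n_pairs

    @property
    def percentages(self) -> pd.DataFrame:
        return 100.0 * self.counts / self.n_pairs

    def to_edge_list(self) -> pd.DataFrame:
        """Long-form (mother_region, pup_region, count) for alluvial plots."""
        edges = self.counts.stack().reset_index()
        edges.columns = ["mother_region", "pup_region", "count"]
        return edges[edges["count"] > 0].reset_index(drop=True)


def transition_table(pairs: pd.DataFrame, colony: ColonyMap) -> RegionTransitionTable:
    """3x3 mother-natal-region by pup-region counts for qualified pairs."""
    mother = [colony.region_of(b).value for b in pairs["natal_beach"]]
    pup = [colony.region_of(b).value for b in pairs["pupping_beach"]]
    counts = (
        pd.crosstab(pd.Series(mother, name="mother"), pd.Series(pup, name="pup"))
        .reindex(index=REGION_ORDER, columns=REGION_ORDER, fill_value=0)
        .astype(int)
    )
    return RegionTransitionTable(counts=counts)


# ---------------------------------------------------------------------------
# multinomial (softmax) regression on the transition table
# ---------------------------------------------------------------------------


@dataclass
class MultinomFit:
    outcome_levels: list[str]
    baseline_outcome: str
    predictor_levels: list[str]
    reference_predictor: str
    coefficients: pd.DataFrame  # (outcome, parameter) long-form
    log_likelihood: float
    fitted_probs: pd.DataFrame  # predictor level x outcome level
    converged: bool
    ridge: float
    separation_detected: bool

    def rrr(self, outcome: str, predictor: str) -> float:
        """Relative-risk ratio of `outcome` vs baseline for `predictor` vs ref."""
        row = self._coef_row(outcome, f"mother[{predictor}]")
        return float(np.exp(row["coef"]))

    def wald_p(self, outcome: str, predictor: str) -> float:
        return float(self._coef_row(outcome, f"mother[{predictor}]")["p"])

    def _coef_row(self, outcome: str, parameter: str) -> pd.Series:
        sel = self.coefficients[
            (self.coefficients["outcome"] == outcome)
            & (self.coefficients["parameter"] == parameter)
        ]
        if len(sel) != 1:
            raise KeyError(f"no coefficient for outcome={outcome!r} {parameter!r}")
        return sel.iloc[0]

    @staticmethod
    def render_rrr(rrr: float) -> str:
        """Phrase an RRR as 'k times more/less likely' (reciprocal when < 1)."""
        if rrr == 0 or not np.isfinite(rrr):
            return "not estimable"
        if rrr < 1.0:
            return f"{1.0 / rrr:.1f} times less likely"
        return f"{rrr:.1f} times more likely"

    def describe(self) -> str:
        lines = [
            f"Multinomial fit: pup region ~ mother region "
            f"(baseline outcome {self.baseline_outcome}, "
            f"reference predictor {self.reference_predictor})"
        ]
        for _, row in self.coefficients.iterrows():
            if not row["parameter"].startswith("mother["):
                continue
            pred = row["parameter"][len("mother["):-1]
            rrr = float(np.exp(row["coef"]))
            lines.append(
                f"  {pred} mothers, {row['outcome']} vs {self.baseline_outcome} pups: "
                f"RRR {rrr:.3g} ({self.render_rrr(rrr)}), p = {row['p']:.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "baseline_outcome": self.baseline_outcome,
            "reference_predictor": self.reference_predictor,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "ridge": self.ridge,
            "separation_detected": self.separation_detected,
            "coefficients": self.coefficients.to_dict(orient="records"),
            "fitted_probs": {
                lvl: {o: float(p) for o, p in row.items()}
                for lvl, row in self.fitted_probs.iterrows()
            },
        }


def fit_multinomial(
    table: RegionTransitionTable | pd.DataFrame,
    baseline_outcome: str = Region.SOUTHERN.value,
    reference_predictor: str = Region.SOUTHERN.value,
    tol: float = 1e-8,
    max_iter: int = 200,
    ridge: float = 0.0,
) -> MultinomFit:
    """Maximum-likelihood softmax regression on aggregated counts.

    The predictor (mother region) and outcome (pup region) are both
    categorical; with one parameter per predictor level the model is
    saturated, so fitted probabilities reproduce the empirical row
    proportions and the RRRs are empirical odds ratios against the baseline
    cell.  Newton iteration runs until the gradient norm drops below
    ``tol``.  Complete separation (an empty outcome cell within a predictor
    level) pushes the MLE to infinity; it is detected and handled by a tiny
    ridge penalty (1e-6 unless a larger one is passed), which is reported.
    """
    counts = table.counts if isinstance(table, RegionTransitionTable) else table
    counts = counts.astype(float)
    predictor_levels = [str(i) for i in counts.index]
    outcome_levels = [str(c) for c in counts.columns]
    if baseline_outcome not in outcome_levels:
        raise FitError(f"baseline outcome {baseline_outcome!r} not among outcomes")
    if reference_predictor not in predictor_levels:
        raise FitError(f"reference predictor {reference_predictor!r} not among levels")

    observed_outcomes = [o for o in outcome_levels if counts[o].sum() > 0]
    if len(observed_outcomes) < 2:
        raise FitError("outcome must have at least 2 observed levels")
    row_totals = counts.sum(axis=1)
    if (row_totals <= 0).any():
        raise FitError("every predictor level needs at least one observation")

    separation = bool((counts.to_numpy() == 0).any())
    if separation and ridge == 0.0:
        ridge = 1e-6

    nonbase = [o for o in outcome_levels if o != baseline_outcome]
    nonref = [l for l in predictor_levels if l != reference_predictor]
    param_names = ["intercept"] + [f"mother[{l}]" for l in nonref]
    L, J, P = len(predictor_levels), len(nonbase), len(param_names)

    # design matrix: one row per predictor level
    X = np.zeros((L, P))
    X[:, 0] = 1.0
    for k, lvl in enumerate(nonref):
        X[predictor_levels.index(lvl), 1 + k] = 1.0
    N = row_totals.to_numpy()
    Y = counts[nonbase].to_numpy()  # observed counts for non-baseline outcomes

    theta = np.zeros(J * P)

    def probs(th: np.ndarray) -> np.ndarray:
        eta = X @ th.reshape(J, P).T  # (L, J)
        expeta = np.exp(eta - eta.max(axis=1, keepdims=True).clip(min=0))
        denom = np.exp(-eta.max(axis=1, keepdims=True).clip(min=0)) + expeta.sum(
            axis=1, keepdims=True
        )
        return expeta / denom  # (L, J) non-baseline probabilities

    def loglik(th: np.ndarray) -> float:
        pi = probs(th)
        p_base = 1.0 - pi.sum(axis=1)
        with np.errstate(divide="ignore"):
            ll = np.sum(Y * np.log(np.clip(pi, 1e-300, None)))
            ll += np.sum(
                counts[baseline_outcome].to_numpy() * np.log(np.clip(p_base, 1e-300, None))
            )
        return float(ll - ridge * np.dot(th, th))

    converged = False
    for _ in range(max_iter):
        pi = probs(theta)
        grad = np.zeros(J * P)
        hess = np.zeros((J * P, J * P))
        for j in range(J):
            grad[j * P : (j + 1) * P] = X.T @ (Y[:, j] - N * pi[:, j])
            for k in range(J):
                w = N * pi[:, j] * ((j == k) - pi[:, k])
                hess[j * P : (j + 1) * P, k * P : (k + 1) * P] = -(X.T * w) @ X
        grad -= 2.0 * ridge * theta
        hess -= 2.0 * ridge * np.eye(J * P)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        step = np.linalg.solve(hess, grad)
        new_theta = theta - step
        # halve the step while the (penalized) likelihood worsens
        ll_old = loglik(theta)
        for _ in range(40):
            if loglik(new_theta) >= ll_old - 1e-12:
                break
            new_theta = (theta + new_theta) / 2.0
        theta = new_theta
    else:
        converged = np.linalg.norm(grad) < tol

    pi = probs(theta)
    info = -hess  # observed information (penalized)
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = np.divide(theta, se, out=np.full_like(theta, np.nan), where=se > 0)
    pvals = 2.0 * norm.sf(np.abs(z))

    rows = []
    for j, outcome in enumerate(nonbase):
        for p_idx, pname in enumerate(param_names):
            flat = j * P + p_idx
            rows.append(
                {
                    "outcome": outcome,
                    "parameter": pname,
                    "coef": float(theta[flat]),
                    "rrr": float(np.exp(theta[flat])),
                    "se": float(se[flat]),
                    "z": float(z[flat]),
                    "p": float(pvals[flat]),
                }
            )
    coef_df = pd.DataFrame(rows)

    fitted = pd.DataFrame(index=predictor_levels, columns=outcome_levels, dtype=float)
    fitted.loc[:, nonbase] = pi
    fitted.loc[:, baseline_outcome] = 1.0 - pi.sum(axis=1)

    return MultinomFit(
        outcome_levels=outcome_levels,
        baseline_outcome=baseline_outcome,
        predictor_levels=predictor_levels,
        reference_predictor=reference_predictor,
        coefficients=coef_df,
        log_likelihood=loglik(theta) + ridge * float(np.dot(theta, theta)),
        fitted_probs=fitted[outcome_levels],
        converged=converged,
        ridge=ridge,
        separation_detected=separation,
    )
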
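"""Associating appearance-mode scores with covariates and outcomes.

The appearance parameters of each subject are compact body-shape/composition
features; this module relates them to study variables:

* bivariate association of one mode with a continuous covariate (Pearson r
  with its t-test p) or a binary covariate (univariate logistic Wald p);
* stepwise logistic selection — forward entry by the smallest
  likelihood-ratio p <= p_enter, followed by backward elimination of any term
  whose p > p_stay — over the candidate modes, producing a model
  ``alpha = beta0 + sum_i beta_i * pc_i`` and ``P(outcome) = 1/(1+exp(-alpha))``;
* rank-based (Mann-Whitney) AUC with ties counted 1/2;
* visualization of a fitted logistic direction as a pair of synthesized body
  images at -/+ k standard deviations plus a red/green difference image.

Logistic fits use iteratively reweighted least squares (Newton scoring) to a
coefficient tolerance of 1e-8.  Perfect separation is detected by coefficient
blow-up; the fit is flagged and coefficients are capped at a documented bound
rather than diverging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dxa_maps import export_8bit

__all__ = ["LogisticModel", "AssociationTable", "bivariate_assoc",
           "fit_logistic", "stepwise_logistic", "predict_prob", "auc",
           "regression_direction_visualization", "match_by_bins"]

COEF_CAP = 25.0  # |beta| bound applied when perfect separation is detected


# ---------------------------------------------------------------------------
# Containers


@dataclass
class LogisticModel:
    """alpha(c) = intercept + sum over selected modes of beta_i * pc_i."""

    intercept: float
    coefficients: dict[int, float]   # keyed by mode index
    outcome: str = ""
    separation_flag: bool = False

    def __post_init__(self) -> None:
        values = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite logistic coefficients")

    def alpha(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        out = np.full(scores.shape[0], self.intercept)
        for mode, beta in self.coefficients.items():
            if mode >= scores.shape[1]:
                raise KeyError(f"score matrix lacks mode {mode}")
            out = out + beta * scores[:, mode]
        return out

    def equation(self) -> str:
        terms = [f"{self.intercept:+.4g}"]
        terms += [f"{b:+.4g}*pc{m + 1}" for m, b in sorted(self.coefficients.items())]
        return " ".join(terms)


@dataclass
class AssociationTable:
    """Per (mode, covariate) statistic and p-value, filtered at a threshold."""

    rows: list[dict] = field(default_factory=list)
    p_threshold: float = 0.05

    def add(self, mode: int, covariate: str, statistic: float, p: float) -> None:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p <= self.p_threshold:
            self.rows.append({"mode": mode, "covariate": covariate,
                              "statistic": statistic, "p": p})


# ---------------------------------------------------------------------------
# Logistic fitting by IRLS


def _irls(x: np.ndarray, y: np.ndarray, tol: float = 1e-8,
          max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton scoring for logistic regression with an intercept column.

    Returns (beta, covariance, separation_flag).  ``x`` excludes the
    intercept; singular (collinear) designs are handled by least-squares
    steps.  Runaway coefficients (perfect separation) are capped at
    ``COEF_CAP`` and flagged.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    n, p = design.shape
    beta = np.zeros(p)
    separated = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        wd = design * w[:, None]
        hess = design.T @ wd
        try:
            step = np.linalg.solve(hess, design.T @ (w * z)) - beta
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, design.T @ (w * z), rcond=None)[0] - beta
        beta = beta + step
        if np.abs(beta).max() > COEF_CAP:
            separated = True
            beta = np.clip(beta, -COEF_CAP, COEF_CAP)
            break
        if np.abs(step).max() < tol:
            break
    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    hess = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    return beta, cov, separated


def _deviance(x: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), np.atleast_2d(x)]) \
        if np.asarray(x).size else np.ones((len(y), 1))
    eta = np.clip(design @ beta, -500, 500)
    ll = y * eta - np.log1p(np.exp(eta))
    return -2.0 * float(ll.sum())


def fit_logistic(scores: np.ndarray, labels: np.ndarray,
                 mode_indices: list[int], outcome: str = "",
                 ) -> tuple[LogisticModel, float]:
    """Fit a logistic model on the given mode columns; returns (model, deviance)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(labels, dtype=float)
    x = scores[:, mode_indices] if mode_indices else np.empty((len(y), 0))
    beta, _, separated = _irls(x, y)
    model = LogisticModel(float(beta[0]),
                          {m: float(b) for m, b in zip(mode_indices, beta[1:])},
                          outcome, separated)
    return model, _deviance(x, y, beta)


# ---------------------------------------------------------------------------
# Operations


def bivariate_assoc(mode_scores: np.ndarray, covariate: np.ndarray,
                    kind: str = "continuous") -> tuple[float, float]:
    """Association of one mode's scores with a covariate.

    ``continuous`` -> (Pearson r, t-test p); ``binary`` -> (log-odds slope,
    Wald p) from a univariate logistic fit of the covariate on the scores.
    """
    scores = np.asarray(mode_scores, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if scores.shape != cov.shape or scores.ndim != 1:
        raise ValueError("mode scores and covariate must be equal-length 1D")
    if len(scores) < 3:
        raise ValueError("need n >= 3")
    if scores.std() == 0 or cov.std() == 0:
        raise ValueError("zero-variance input")
    if kind == "continuous":
        r, p = stats.pearsonr(scores, cov)
        return float(r), float(p)
    if kind == "binary":
        classes = np.unique(cov)
        if len(classes) != 2:
            raise ValueError("binary covariate must have exactly 2 levels")
        y = (cov == classes[1]).astype(float)
        beta, covm, separated = _irls(scores[:, None], y)
        se = float(np.sqrt(max(covm[1, 1], 0.0)))
        if separated or se == 0:
            return float(beta[1]), 0.0
        z = beta[1] / se
        return float(beta[1]), float(2 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown kind {kind!r}")


def stepwise_logistic(scores: np.ndarray, labels: np.ndarray,
                      p_enter: float = 0.05, p_stay: float = 0.05,
                      candidates: list[int] | None = None,
                      outcome: str = "") -> LogisticModel:
    """Forward selection with backward elimination by likelihood-ratio tests.

    At each step the candidate with the smallest likelihood-ratio p-value
    enters if p <= p_enter (ties broken by lower mode index); after each
    entry, any included term whose exclusion LR p exceeds p_stay is removed
    (worst first).  Stops when no change occurs.  Labels must be binary with
    both classes present; the candidate pool defaults to every score column
    (callers restrict it to the modes explaining 95% of variance).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (y == classes[1]).astype(float)
    pool = list(range(scores.shape[1])) if candidates is None else list(candidates)
    selected: list[int] = []
    _, dev_cur = fit_logistic(scores, y, selected, outcome)
    while True:
        changed = False
        # forward: best LR p among remaining candidates
        best = None
        for m in sorted(set(pool) - set(selected)):
            _, dev = fit_logistic(scores, y, selected + [m], outcome)
            lr = max(dev_cur - dev, 0.0)
            p = float(stats.chi2.sf(lr, df=1))
            if best is None or p < best[0] - 1e-15:
                best = (p, m, dev)
        if best is not None and best[0] <= p_enter:
            selected.append(best[1])
            selected.sort()
            dev_cur = best[2]
            changed = True
        # backward: drop worst terms with LR p > p_stay
        while selected:
            worst = None
            for m in selected:
                reduced = [k for k in selected if k != m]
                _, dev_red = fit_logistic(scores, y, reduced, outcome)
                lr = max(dev_red - dev_cur, 0.0)
                p = float(stats.chi2.sf(lr, df=1))
                if worst is None or p > worst[0] + 1e-15:
                    worst = (p, m, dev_red)
            if worst is not None and worst[0] > p_stay:
                selected.remove(worst[1])
                dev_cur = worst[2]
                changed = True
            else:
                break
        if not changed:
            break
    model, _ = fit_logistic(scores, y, selected, outcome)
    return model


def predict_prob(model: LogisticModel, scores: np.ndarray) -> np.ndarray:
    """Elementwise inverse logit of alpha(scores), strictly inside (0, 1)."""
    alpha = model.alpha(scores)
    return 1.0 / (1.0 + np.exp(-np.clip(alpha, -700, 700)))


def auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    pos = y == classes[1]
    n_pos = int(pos.sum())
    n_neg = len(y) - n_pos
    ranks = stats.rankdata(p)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Visualization of a fitted direction in appearance space


def regression_direction_visualization(appearance_model, logistic_model:
                                       LogisticModel, k_sd: float = 3.0):
    """Synthesize body images at -/+ k_sd along a fitted logistic direction.

    The direction d = sum_i beta_i e_i over the selected modes is normalized
    to unit Mahalanobis length (sqrt(sum d_i^2 / lambda_i) = 1), so +/- k_sd
    steps are k_sd population standard deviations along the direction.
    Returns ``(low, high, difference_rgb)`` where low/high are
    (PointSet, channel images) synthesis results and the difference image of
    the first channel colors high>low red and low>high green.
    """
    from .appearance_model import synthesize

    if not logistic_model.coefficients:
        raise ValueError("zero direction: the model has no mode coefficients")
    d = np.zeros(appearance_model.n_modes)
    for mode, beta in logistic_model.coefficients.items():
        if mode >= appearance_model.n_modes:
            raise ValueError(f"mode {mode} not in the appearance model")
        d[mode] = beta
    lam = np.maximum(appearance_model.eigenvalues, 1e-30)
    mah = float(np.sqrt((d ** 2 / lam).sum()))
    if mah == 0:
        raise ValueError("zero direction")
    d = d / mah
    low = synthesize(appearance_model, -k_sd * d)
    high = synthesize(appearance_model, +k_sd * d)
    diff = _difference_rgb(low[1][0], high[1][0])
    return low, high, diff


def _difference_rgb(low_img: np.ndarray, high_img: np.ndarray) -> np.ndarray:
    both = np.isfinite(low_img) & np.isfinite(high_img)
    diff = np.where(both, high_img - low_img, 0.0)
    span = float(np.abs(diff).max())
    rgb = np.zeros(diff.shape + (3,), dtype=np.uint8)
    if span > 0:
        rgb[..., 0] = export_8bit(np.clip(diff, 0, None), 0, span)    # red: high > low
        rgb[..., 1] = export_8bit(np.clip(-diff, 0, None), 0, span)   # green: low > high
    return rgb


# ---------------------------------------------------------------------------
# Case-control matching utility


def match_by_bins(covariate: np.ndarray, labels: np.ndarray,
                  n_bins: int = 8, rng: np.random.Generator | None = None,
                  ) -> np.ndarray:
    """Select control indices whose covariate bin counts match the cases.

    Mirrors a matched case-control design: controls are drawn (without
    replacement, per bin) to match the case histogram over ``n_bins`` equal
    quantile-ish bins of the covariate.  Returns the sorted indices of
    cases plus matched controls.
    """
    cov = np.asarray(covariate, dtype=float)
    y = np.asarray(labels).astype(bool)
    rng = np.random.default_rng(0) if rng is None else rng
    edges = np.quantile(cov, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    bins = np.digitize(cov, edges[1:-1])
    chosen: list[int] = []
    for b in range(n_bins):
        case_pool = np.nonzero((bins == b) & y)[0]
        ctrl_pool = np.nonzero((bins == b) & ~y)[0]
        take = min(len(case_pool), len(ctrl_pool))
        if take:
            # unmatched subjects in the bin are dropped from both arms
            chosen.extend(rng.choice(case_pool, size=take, replace=False))
            chosen.extend(rng.choice(ctrl_pool, size=take, replace=False))
    return np.sort(np.asarray(chosen, dtype=int))
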
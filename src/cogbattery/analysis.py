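"""Validity, agreement and learning-trend analytics.

Implements the statistical pipeline applied to the battery's session logs:

* **Relative validity** — Spearman rank correlation (mid-ranks for ties)
  between a conventional baseline instrument and the smartphone analogue,
  computed three ways: against the first performed attempt, against the mean
  of all attempts, and against the first attempt with at least half the items
  correct (the mistake filter).
* **Agreement** — Bland-Altman comparison on z-scores, since the two
  instruments share no natural scale: per-pair differences against means with
  limits of agreement mean ± 1.96·SD.
* **Practice effect** — a two-level linear mixed model
  ``score = (beta0 + b0_i) + (beta1 + b1_i)·(attempt-1) + eps`` with an
  unstructured 2x2 random-effects covariance, fitted by REML (ML optional).
  The attempt covariate is centred at the first attempt so the fixed
  intercept is first-attempt performance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import (
    DegenerateDesignError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)

#: conventional measure -> (smartphone test_id, part). The trail pairing maps
#: the numeric row to smartphone part 1 and the alphanumeric row to part 3;
#: both are configurable because the smartphone adds a reversed part 4 with no
#: paper-and-pencil analogue.
DEFAULT_PAIRING: dict[str, tuple[str, int]] = {
    "stroop_1": ("stroop", 1),
    "stroop_2": ("stroop", 2),
    "stroop_3": ("stroop", 3),
    "tmt_a": ("tmt", 1),
    "tmt_b": ("tmt", 3),
}


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman_rho(
    x, y, exact_p: bool = False
) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Pairs with a missing member are dropped pairwise.  The p-value uses the
    large-sample t approximation; with ``exact_p`` and n <= 10 the exact
    permutation p-value is returned instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D samples")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined for a constant sample")
    rx = st.rankdata(x)  # mid-ranks
    ry = st.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact_p and n <= 10:
        return rho, _exact_permutation_p(rx, ry, rho)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * st.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value over all orderings of one margin."""
    n = len(rx)
    sx, sy = rx.std(), ry.std()
    mx, my = rx.mean(), ry.mean()
    thresh = abs(rho_obs) - 1e-12
    count = total = 0
    chunk: list[tuple] = []

    def flush(chunk):
        nonlocal count, total
        perm = np.asarray(chunk, dtype=float)
        rhos = ((perm - my) @ (rx - mx)) / (len(rx) * sx * sy)
        count += int(np.sum(np.abs(rhos) >= thresh))
        total += len(perm)

    for p in itertools.permutations(ry):
        chunk.append(p)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return count / total


# ---------------------------------------------------------------------------
# Relative validity
# ---------------------------------------------------------------------------


@dataclass
class ValidityReport:
    """Per-measure relative validity table.

    Columns: n, rho_first/p_first (conventional vs first smartphone attempt),
    rho_mean/p_mean (vs the mean of all attempts), rho_filtered/p_filtered
    (vs the first attempt with at least half the answers correct).
    """

    table: pd.DataFrame


def _conventional_series(conventional: pd.DataFrame, measure: str) -> pd.Series:
    sub = conventional[conventional["measure"] == measure]
    return sub.set_index("participant_id")["score"]


def _paired_rho(conv: pd.Series, phone: pd.Series) -> tuple[int, float, float]:
    merged = pd.concat({"c": conv, "s": phone}, axis=1, join="inner").dropna()
    if len(merged) < 3:
        raise InsufficientDataError(
            f"only {len(merged)} matched pairs; need at least 3"
        )
    rho, p = spearman_rho(merged["c"].to_numpy(), merged["s"].to_numpy())
    return len(merged), rho, p


def first_attempt_validity(
    conventional: pd.DataFrame,
    sessions: pd.DataFrame,
    pairing: Mapping[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Spearman validity of the first performed smartphone attempt."""
    pairing = dict(pairing or DEFAULT_PAIRING)
    rows = []
    for measure, (test_id, part) in pairing.items():
        sub = sessions[(sessions["test_id"] == test_id) & (sessions["part"] == part)]
        firsts = sub[sub["attempt_index"] == 1].set_index("participant_id")["score"]
        n, rho, p = _paired_rho(_conventional_series(conventional, measure), firsts)
        rows.append({"measure": measure, "n": n, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


def mean_attempt_validity(
    conventional: pd.DataFrame,
    sessions: pd.DataFrame,
    pairing: Mapping[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Spearman validity of each participant's mean score over all attempts."""
    pairing = dict(pairing or DEFAULT_PAIRING)
    rows = []
    for measure, (test_id, part) in pairing.items():
        sub = sessions[(sessions["test_id"] == test_id) & (sessions["part"] == part)]
        means = sub.groupby("participant_id")["score"].mean()
        n, rho, p = _paired_rho(_conventional_series(conventional, measure), means)
        rows.append({"measure": measure, "n": n, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


def filtered_first_valid_attempt(
    sessions: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Select, per participant x test x part, the earliest attempt scoring at
    least ``threshold`` of the items correct; participants with no qualifying
    attempt are excluded (not an error).  Requires n_correct and n_items."""
    if not {"n_correct", "n_items"} <= set(sessions.columns):
        raise InvalidInputError("sessions must carry n_correct and n_items")
    ok = sessions[sessions["n_correct"] >= threshold * sessions["n_items"]]
    idx = ok.groupby(["participant_id", "test_id", "part"])["attempt_index"].idxmin()
    return sessions.loc[sorted(idx)].reset_index(drop=True)


def filtered_attempt_validity(
    conventional: pd.DataFrame,
    sessions: pd.DataFrame,
    pairing: Mapping[str, tuple[str, int]] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Spearman validity of the first attempt without many mistakes."""
    pairing = dict(pairing or DEFAULT_PAIRING)
    selected = filtered_first_valid_attempt(sessions, threshold)
    rows = []
    for measure, (test_id, part) in pairing.items():
        sub = selected[(selected["test_id"] == test_id) & (selected["part"] == part)]
        scores = sub.set_index("participant_id")["score"]
        n, rho, p = _paired_rho(_conventional_series(conventional, measure), scores)
        rows.append({"measure": measure, "n": n, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


def validity_report(
    conventional: pd.DataFrame,
    sessions: pd.DataFrame,
    pairing: Mapping[str, tuple[str, int]] | None = None,
) -> ValidityReport:
    """Assemble the full relative-validity table (first/mean/filtered)."""
    first = first_attempt_validity(conventional, sessions, pairing).set_index("measure")
    mean = mean_attempt_validity(conventional, sessions, pairing).set_index("measure")
    filt = filtered_attempt_validity(conventional, sessions, pairing).set_index("measure")
    table = pd.DataFrame(
        {
            "n": first["n"],
            "rho_first": first["rho"],
            "p_first": first["p_value"],
            "rho_mean": mean["rho"],
            "p_mean": mean["p_value"],
            "rho_filtered": filt["rho"],
            "p_filtered": filt["p_value"],
        }
    )
    return ValidityReport(table=table.reset_index())


# ---------------------------------------------------------------------------
# Bland-Altman agreement on z-scores
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """Bland-Altman comparison of two instruments on a common z-score scale."""

    z_conventional: np.ndarray
    z_smartphone: np.ndarray
    differences: np.ndarray
    means: np.ndarray
    mean_difference: float
    sd_difference: float
    limits_of_agreement: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_conventional": self.z_conventional,
                "z_smartphone": self.z_smartphone,
                "difference": self.differences,
                "mean": self.means,
            }
        )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("cannot standardize a zero-variance sample")
    return (v - v.mean()) / sd


def bland_altman(conventional, smartphone) -> AgreementReport:
    """Bland-Altman agreement between paired conventional and smartphone
    scores, both standardized to z-scores over the matched pairs."""
    c = np.asarray(conventional, dtype=float)
    s = np.asarray(smartphone, dtype=float)
    if c.shape != s.shape or c.ndim != 1:
        raise InvalidInputError("paired samples must be equal-length 1-D")
    keep = ~(np.isnan(c) | np.isnan(s))
    c, s = c[keep], s[keep]
    if len(c) < 3:
        raise InsufficientDataError(f"need >= 3 matched pairs, got {len(c)}")
    zc, zs = _zscore(c), _zscore(s)
    diff = zs - zc
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    return AgreementReport(
        z_conventional=zc,
        z_smartphone=zs,
        differences=diff,
        means=(zs + zc) / 2.0,
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        limits_of_agreement=(mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff),
    )


# ---------------------------------------------------------------------------
# Learning-trend mixed model
# ---------------------------------------------------------------------------


@dataclass
class TrendFit:
    """Random-intercept/random-slope fit of score on attempt (centred at 1)."""

    intercept: float
    slope: float
    slope_se: float
    slope_p: float
    var_intercept: float
    var_slope: float
    cov_intercept_slope: float
    resid_var: float
    n_participants: int
    n_obs: int
    converged: bool
    method: str

    def to_dict(self) -> dict:
        return asdict(self)


def fit_learning_trend(
    long_data: pd.DataFrame,
    score_col: str = "score",
    ml: bool = False,
) -> TrendFit:
    """Fit the two-level linear model of score on attempt index.

    ``long_data`` must carry participant_id, attempt_index and the score
    column.  Estimation is REML with an unstructured 2x2 random-effects
    covariance (set ``ml=True`` for maximum likelihood).  The attempt
    covariate is attempt_index - 1, so the intercept estimates first-attempt
    performance and the slope the per-attempt change.
    """
    import statsmodels.formula.api as smf

    required = {"participant_id", "attempt_index", score_col}
    if not required <= set(long_data.columns):
        raise InvalidInputError(f"long data must carry columns {sorted(required)}")
    df = long_data[["participant_id", "attempt_index", score_col]].dropna().copy()
    df["attempt0"] = df["attempt_index"] - 1
    df = df.rename(columns={score_col: "y"})
    counts = df.groupby("participant_id")["attempt_index"].nunique()
    if (counts < 2).all():
        raise DegenerateDesignError(
            "every participant has a single attempt; slopes are unidentified"
        )
    if (counts >= 2).sum() < 2:
        raise InsufficientDataError("need >= 2 participants with repeated attempts")
    model = smf.mixedlm("y ~ attempt0", df, groups=df["participant_id"],
                        re_formula="~attempt0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=not ml, method=["lbfgs", "cg"], maxiter=200)
            if not getattr(result, "converged", True):
                # variance components on the boundary defeat gradient
                # optimizers; Powell handles the boundary reliably
                retry = model.fit(reml=not ml, method=["powell"], maxiter=500)
                if getattr(retry, "converged", False):
                    result = retry
        except Exception as exc:  # noqa: BLE001 - surfaced as a fit failure
            raise FitFailureError(f"mixed-model fit failed: {exc}") from exc
        fe = result.fe_params
        slope_se = float(result.bse_fe["attempt0"])
        slope_p = float(result.pvalues["attempt0"])
    if not np.all(np.isfinite(fe)):
        raise FitFailureError("mixed-model fit produced non-finite estimates")
    cov_re = np.asarray(result.cov_re)
    return TrendFit(
        intercept=float(fe["Intercept"]),
        slope=float(fe["attempt0"]),
        slope_se=slope_se,
        slope_p=slope_p,
        var_intercept=float(cov_re[0, 0]),
        var_slope=float(cov_re[1, 1]),
        cov_intercept_slope=float(cov_re[0, 1]),
        resid_var=float(result.scale),
        n_participants=int(df["participant_id"].nunique()),
        n_obs=int(len(df)),
        converged=bool(getattr(result, "converged", True)),
        method="ml" if ml else "reml",
    )


def repeat_effect_report(
    sessions: pd.DataFrame,
    min_attempts: int = 9,
    score_col: str = "score",
    min_subset_participants: int = 5,
) -> pd.DataFrame:
    """Learning-trend fits per test part, on everyone and on frequent users.

    For each (test_id, part) group the model is fitted on all participants
    and again on the subset who made at least ``min_attempts`` attempts (the
    selective-dropout sensitivity analysis).  Subset estimates are NaN where
    fewer than ``min_subset_participants`` participants qualify; if no group
    has a qualifying subset the report raises :class:`InsufficientDataError`.
    """
    if min_attempts < 1:
        raise InvalidInputError("min_attempts must be >= 1")
    rows = []
    any_subset = False
    for (test_id, part), grp in sessions.groupby(["test_id", "part"]):
        try:
            fit_all = fit_learning_trend(grp, score_col=score_col)
        except (DegenerateDesignError, InsufficientDataError, FitFailureError):
            continue
        max_attempt = grp.groupby("participant_id")["attempt_index"].max()
        frequent = max_attempt[max_attempt >= min_attempts].index
        row = {
            "test_id": test_id,
            "part": part,
            "slope_all": fit_all.slope,
            "slope_se_all": fit_all.slope_se,
            "slope_p_all": fit_all.slope_p,
            "n_participants_all": fit_all.n_participants,
            "slope_subset": np.nan,
            "slope_se_subset": np.nan,
            "n_participants_subset": len(frequent),
        }
        if len(frequent) >= min_subset_participants:
            try:
                fit_sub = fit_learning_trend(
                    grp[grp["participant_id"].isin(frequent)], score_col=score_col
                )
                row["slope_subset"] = fit_sub.slope
                row["slope_se_subset"] = fit_sub.slope_se
                any_subset = True
            except (DegenerateDesignError, InsufficientDataError, FitFailureError):
                pass
        rows.append(row)
    if not rows:
        raise InsufficientDataError("no test part had fittable repeated attempts")
    if min_attempts > 1 and not any_subset:
        raise InsufficientDataError(
            f"no test part has {min_subset_participants}+ participants with "
            f">= {min_attempts} attempts"
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plots (optional artifacts)
# ---------------------------------------------------------------------------


def plot_bland_altman(report: AgreementReport, path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.means, report.differences, s=14, alpha=0.7)
    ax.axhline(report.mean_difference, color="k", lw=1)
    for lim in report.limits_of_agreement:
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of z-scores")
    ax.set_ylabel("difference of z-scores")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_adherence_over_time(adherence_frame: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for test_id, row in adherence_frame.iterrows():
        ax.plot(range(1, len(row) + 1), row.values, marker="o", label=test_id)
    ax.set_xlabel("reminder occasion")
    ax.set_ylabel("adherence (%)")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories(
    sessions: pd.DataFrame, test_id: str, part: int, path, max_attempt: int = 12
) -> None:
    """Mean score per attempt with per-attempt n, for one test part."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = sessions[
        (sessions["test_id"] == test_id)
        & (sessions["part"] == part)
        & (sessions["attempt_index"] <= max_attempt)
    ]
    means = sub.groupby("attempt_index")["score"].mean()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(means.index, means.values, marker="o")
    ax.set_xlabel("attempt")
    ax.set_ylabel("mean score")
    ax.set_title(f"{test_id} part {part}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
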
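"""Score-quantile stratification, log-rank test, univariate Cox regression
and the exploratory multi-threshold survival scan.

The log-rank statistic follows the standard construction: at each distinct
event time the observed events in one group are compared with their
expectation under the conditional (multivariate) hypergeometric model, and
chi_square = (O - E)^2 / V is referred to chi-square with 1 df.  Cox
estimation maximizes the partial likelihood by Newton-Raphson with Breslow
handling of tied event times; at beta = 0 the score test for a binary
covariate without ties reproduces the log-rank chi-square exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MetsigError


@dataclass
class StratifiedGroups:
    """Low/high score strata; middle specimens may remain unassigned."""

    low_ids: list[str]
    high_ids: list[str]
    f_low: float
    f_high: float


@dataclass
class LogRankResult:
    chi_square: float
    p: float
    direction: int  # sign of (observed - expected) events in the high group
    o_high: float
    e_high: float
    variance: float
    df: int = 1


def _ceil_frac(f: float, n: int) -> int:
    # tolerate float representation of exact fractions like 0.25 * 4
    return math.ceil(f * n - 1e-9)


def partition_by_score(scores: pd.Series, f_low: float, f_high: float) -> StratifiedGroups:
    """Split specimens into bottom-f_low and top-f_high score strata.

    Specimens are stably sorted ascending by (score, specimen_id); the low
    group is the first ceil(f_low * n), and the high group the last
    ceil(f_high * n) — taken as the exact complement when f_low + f_high = 1
    so the two groups always partition the cohort (e.g. 377 specimens at
    25/75 split into 95 and 282).
    """
    if not (0 < f_low <= 1 and 0 < f_high <= 1):
        raise MetsigError(f"fractions must lie in (0, 1], got ({f_low}, {f_high})")
    if f_low + f_high > 1 + 1e-9:
        raise MetsigError(f"groups overlap: f_low + f_high = {f_low + f_high:g} > 1")
    order = scores.rename("score").rename_axis("specimen_id").reset_index()
    order = order.sort_values(["score", "specimen_id"], kind="stable")
    ids = order["specimen_id"].tolist()
    n = len(ids)
    n_low = _ceil_frac(f_low, n)
    if abs(f_low + f_high - 1.0) <= 1e-9:
        n_high = n - n_low
    else:
        n_high = _ceil_frac(f_high, n)
    if n_low == 0 or n_high == 0:
        raise MetsigError(f"empty stratum: n_low={n_low}, n_high={n_high} of n={n}")
    if n_low + n_high > n:
        raise MetsigError(
            f"strata overlap after rounding: {n_low} + {n_high} > {n} specimens"
        )
    return StratifiedGroups(
        low_ids=ids[:n_low], high_ids=ids[n - n_high :], f_low=f_low, f_high=f_high
    )


def logrank_from_arrays(time: np.ndarray, event: np.ndarray, in_high: np.ndarray) -> LogRankResult:
    """Two-group log-rank test on plain arrays (group 'high' vs the rest).

    Ties: all events at a tied time enter through the multivariate
    hypergeometric mean and variance, V_j = d_j (n_j - d_j) n1_j n0_j /
    (n_j^2 (n_j - 1)).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    in_high = np.asarray(in_high, dtype=bool)
    if event.sum() == 0:
        raise MetsigError("no events observed; log-rank undefined")
    if in_high.all() or (~in_high).all():
        raise MetsigError("one group is empty")

    order = np.argsort(time, kind="stable")
    time, event, in_high = time[order], event[order], in_high[order]
    event_times = np.unique(time[event == 1])

    # at-risk and death counts at each distinct event time
    n_total = len(time)
    o_high = e_high = variance = 0.0
    for t in event_times:
        at_risk = time >= t
        n_j = int(at_risk.sum())
        n1_j = int((at_risk & in_high).sum())
        dying = (time == t) & (event == 1)
        d_j = int(dying.sum())
        d1_j = int((dying & in_high).sum())
        o_high += d1_j
        e_high += d_j * n1_j / n_j
        if n_j > 1:
            n0_j = n_j - n1_j
            variance += d_j * (n_j - d_j) * n1_j * n0_j / (n_j**2 * (n_j - 1))
    diff = o_high - e_high
    if variance == 0:
        chi_square = 0.0
        p = 1.0
    else:
        chi_square = diff * diff / variance
        p = float(stats.chi2.sf(chi_square, df=1))
    direction = int(np.sign(diff))
    return LogRankResult(
        chi_square=float(chi_square),
        p=p,
        direction=direction,
        o_high=float(o_high),
        e_high=float(e_high),
        variance=float(variance),
    )


def logrank_test(groups: StratifiedGroups, surv: pd.DataFrame) -> LogRankResult:
    """Log-rank test between the low and high strata.

    ``surv`` is indexed by specimen id with ``time`` and ``event`` columns;
    specimens outside the two strata are ignored.
    """
    wanted = [s for s in groups.low_ids + groups.high_ids if s in surv.index]
    missing = (set(groups.low_ids) | set(groups.high_ids)) - set(surv.index)
    if missing:
        raise MetsigError(f"specimens without survival records: {sorted(missing)[:5]}")
    sub = surv.loc[wanted]
    in_high = np.array([s in set(groups.high_ids) for s in sub.index])
    return logrank_from_arrays(
        sub["time"].to_numpy(), sub["event"].to_numpy(), in_high
    )


def cox_univariate(
    covariate: pd.Series | np.ndarray,
    surv: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Univariate Cox proportional-hazards fit by Newton-Raphson.

    Breslow handling of tied event times.  Returns
    ``(beta_hat, se, p_wald, p_score)``: the Wald test at the maximum
    partial-likelihood estimate and the score test at beta = 0 (which
    equals the log-rank chi-square for a binary covariate without ties).
    """
    if isinstance(covariate, pd.Series):
        common = covariate.index.intersection(surv.index)
        x = covariate.loc[common].to_numpy(dtype=float)
        sub = surv.loc[common]
    else:
        x = np.asarray(covariate, dtype=float)
        sub = surv
        if len(x) != len(sub):
            raise MetsigError("covariate and survival records have mismatched lengths")
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise MetsigError("constant covariate; Cox model not identifiable")
    if event.sum() == 0:
        raise MetsigError("no events observed; Cox model undefined")

    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    event_times = np.unique(time[event == 1])

    def score_info(beta: float):
        """Partial-likelihood score U(beta) and information I(beta), Breslow ties."""
        eta = np.exp(beta * x)
        U = Info = 0.0
        for t in event_times:
            at_risk = time >= t
            dying = (time == t) & (event == 1)
            d = int(dying.sum())
            w = eta[at_risk]
            xr = x[at_risk]
            s0 = w.sum()
            s1 = (w * xr).sum()
            s2 = (w * xr * xr).sum()
            xbar = s1 / s0
            U += x[dying].sum() - d * xbar
            Info += d * (s2 / s0 - xbar * xbar)
        return U, Info

    # score test at beta = 0
    u0, i0 = score_info(0.0)
    if i0 <= 0:
        raise MetsigError("zero information at beta=0; covariate degenerate at event times")
    chi_score = u0 * u0 / i0
    p_score = float(stats.chi2.sf(chi_score, df=1))

    beta = 0.0
    for _ in range(max_iter):
        u, info = score_info(beta)
        if info <= 0:
            raise MetsigError(f"non-positive information during Newton-Raphson (beta={beta:g})")
        step = u / info
        beta += step
        if abs(step) < tol:
            break
    else:
        raise MetsigError(
            f"Cox Newton-Raphson failed to converge in {max_iter} iterations "
            f"(last beta={beta:g}, step={step:g})"
        )
    _, info = score_info(beta)
    se = 1.0 / math.sqrt(info)
    p_wald = float(2.0 * stats.norm.sf(abs(beta) / se))
    return float(beta), float(se), p_wald, p_score


def threshold_scan(
    scores: pd.Series, surv: pd.DataFrame, grid=None
) -> pd.DataFrame:
    """Log-rank results over a grid of quantile breakdowns.

    Exploratory by design: no multiplicity correction.  Grid points whose
    partition or test fails (e.g. constant scores) are flagged in the
    ``failed``/``error`` columns rather than aborting the scan.
    """
    from .config import DEFAULT_GRID

    if grid is None:
        grid = DEFAULT_GRID
    grid = list(grid)
    if not grid:
        raise MetsigError("empty threshold grid")
    rows = []
    for f_low, f_high in grid:
        try:
            groups = partition_by_score(scores, f_low, f_high)
            if len(set(scores.loc[groups.low_ids])) == 1 and set(
                scores.loc[groups.low_ids]
            ) == set(scores.loc[groups.high_ids]):
                raise MetsigError("degenerate partition: identical scores in both strata")
            res = logrank_test(groups, surv)
            rows.append(
                (f_low, f_high, len(groups.low_ids), len(groups.high_ids),
                 res.chi_square, res.p, res.direction, False, "")
            )
        except MetsigError as exc:
            rows.append((f_low, f_high, 0, 0, np.nan, np.nan, 0, True, str(exc)))
    return pd.DataFrame(
        rows,
        columns=["f_low", "f_high", "n_low", "n_high", "chi_square", "p",
                 "direction", "failed", "error"],
    )
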
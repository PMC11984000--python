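"""Effect of high understandability on viewer engagement.

Treatment is the binary high-understandability label; outcomes are
log-transformed engagement counts (log(count+1), natural log).  Because
assignment is observational, units are matched on channel and video
covariates before estimation:

* **CEM** (coarsened exact matching, the default): each covariate is
  coarsened into bins, units are stratified by their joint bin signature,
  strata lacking either group are dropped, and controls are reweighted so
  each stratum's groups balance — a variable-ratio matched sample.
* **PSM**: 1:1 nearest-neighbor matching on the logit of a logistic
  propensity score, without replacement, caliper 0.2 SD of the logit.

Balance is reported as standardized mean differences (difference of
weighted group means divided by the unweighted sample SD of the treated
group), and the ATE as the treatment coefficient of a weighted least
squares regression of the log outcome on an intercept and treatment over
the matched sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from vidability.corpus_io import VideoRecord
from vidability.text_features import tokenize_words

__all__ = [
    "COVARIATE_NAMES",
    "OUTCOME_NAMES",
    "CausalUnit",
    "build_causal_units",
    "units_to_frame",
    "units_from_frame",
    "MatchedSample",
    "BalanceReport",
    "ATEEstimate",
    "fit_propensity",
    "match",
    "balance",
    "estimate_ate",
    "naive_difference",
]

COVARIATE_NAMES = (
    "log_channel_view_count",
    "log_channel_subscriber_count",
    "log_channel_video_count",
    "content_definition_sd",
    "duration_s",
    "description_word_count",
    "description_unique_words",
    "log_published_days",
)

OUTCOME_NAMES = ("log_view_count", "log_like_count", "log_comment_count")


@dataclass(frozen=True)
class CausalUnit:
    """One video prepared for causal analysis (transforms already applied)."""

    video_id: str
    treatment: int
    covariates: dict  # COVARIATE_NAMES -> float
    outcomes: dict  # OUTCOME_NAMES -> float

    def cov_array(self) -> np.ndarray:
        return np.array([self.covariates[n] for n in COVARIATE_NAMES], dtype=float)


def build_causal_units(records: Sequence[VideoRecord], treatment: Mapping[str, int]) -> list[CausalUnit]:
    """Prepare causal units from video records and a treatment map.

    Log transforms use log(x+1) except channel_video_count, which enters as
    log(x); when any channel has zero videos the +1 fallback is applied to
    that covariate for all units, with a warning.
    """
    zero_channels = any(r.channel_video_count == 0 for r in records)
    if zero_channels:
        warnings.warn(
            "channel_video_count contains zeros; using log(x+1) instead of log(x)"
        )
    units = []
    for r in records:
        if r.video_id not in treatment:
            continue
        words = tokenize_words(r.description)
        cvc = r.channel_video_count + 1 if zero_channels else r.channel_video_count
        covariates = {
            "log_channel_view_count": math.log(r.channel_view_count + 1),
            "log_channel_subscriber_count": math.log(r.channel_subscriber_count + 1),
            "log_channel_video_count": math.log(cvc),
            "content_definition_sd": 1.0 if r.content_definition == "SD" else 0.0,
            "duration_s": float(r.duration_s),
            "description_word_count": float(len(words)),
            "description_unique_words": float(len({w.lower() for w in words})),
            "log_published_days": math.log(r.published_days + 1),
        }
        outcomes = {
            "log_view_count": math.log(r.view_count + 1),
            "log_like_count": math.log(r.like_count + 1),
            "log_comment_count": math.log(r.comment_count + 1),
        }
        units.append(
            CausalUnit(r.video_id, int(treatment[r.video_id]), covariates, outcomes)
        )
    return units


def units_to_frame(units: Sequence[CausalUnit]) -> pd.DataFrame:
    rows = []
    for u in units:
        row = {"video_id": u.video_id, "treatment": u.treatment}
        row.update(u.covariates)
        row.update(u.outcomes)
        rows.append(row)
    return pd.DataFrame(rows).set_index("video_id")


def units_from_frame(frame: pd.DataFrame) -> list[CausalUnit]:
    units = []
    frame = frame.reset_index() if frame.index.name == "video_id" else frame
    for _, row in frame.iterrows():
        units.append(
            CausalUnit(
                video_id=str(row["video_id"]),
                treatment=int(row["treatment"]),
                covariates={n: float(row[n]) for n in COVARIATE_NAMES},
                outcomes={n: float(row[n]) for n in OUTCOME_NAMES if n in row},
            )
        )
    return units


# ---------------------------------------------------------------------------
# Propensity model

def _check_groups(units):
    n_t = sum(u.treatment for u in units)
    if n_t == 0 or n_t == len(units):
        raise ValueError("both treatment groups must be nonempty")


def fit_propensity(units: Sequence[CausalUnit], return_model: bool = False):
    """Logistic regression of treatment on the covariate set; returns
    fitted propensities keyed by video_id (and, with ``return_model``, the
    statsmodels fit and the names of the covariates that entered it).
    Complete separation on a covariate is reported as an error naming it;
    constant covariates are dropped from the design (an all-constant
    design reduces to the intercept-only fit, the treated fraction)."""
    _check_groups(units)
    X = np.vstack([u.cov_array() for u in units])
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    y = np.array([u.treatment for u in units], dtype=float)

    # Pre-check: a covariate whose treated and control supports do not
    # overlap separates the groups perfectly.
    separating = []
    for j, name in enumerate(COVARIATE_NAMES):
        xt, xc = X[y == 1, j], X[y == 0, j]
        if xt.min() > xc.max() or xc.min() > xt.max():
            separating.append(name)
    if separating:
        raise ValueError(f"perfect separation on covariate(s): {', '.join(separating)}")

    varying = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    used_names = [COVARIATE_NAMES[j] for j in varying]
    if varying:
        design = sm.add_constant(X[:, varying], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.Logit(y, design).fit(disp=0, maxiter=200)
        fitted = result.predict(design)
    else:
        result = None
        fitted = np.full(len(units), y.mean())
    fitted = np.clip(fitted, 1e-12, 1 - 1e-12)
    propensities = {u.video_id: float(p) for u, p in zip(units, fitted)}
    if return_model:
        return propensities, result, used_names
    return propensities


# ---------------------------------------------------------------------------
# Matching

@dataclass(frozen=True)
class MatchedSample:
    """Per-unit matching weights (dropped units have weight 0)."""

    weights: dict  # video_id -> float
    method: str
    params: dict = field(default_factory=dict)

    def retained(self, units: Sequence[CausalUnit], group: int) -> list[CausalUnit]:
        return [u for u in units if u.treatment == group and self.weights.get(u.video_id, 0.0) > 0]


def _sturges_bins(n: int) -> int:
    return int(math.ceil(math.log2(n))) + 1


def _cem(units: Sequence[CausalUnit], bins: Optional[int]) -> MatchedSample:
    n = len(units)
    k = bins if bins is not None else _sturges_bins(n)
    X = np.vstack([u.cov_array() for u in units])
    signatures = np.zeros((n, len(COVARIATE_NAMES)), dtype=int)
    for j, name in enumerate(COVARIATE_NAMES):
        col = X[:, j]
        values = np.unique(col)
        if name == "content_definition_sd" or len(values) <= 2:
            # Binary/near-constant covariates keep their raw levels.
            signatures[:, j] = np.searchsorted(values, col)
            continue
        lo, hi = col.min(), col.max()
        edges = np.linspace(lo, hi, k + 1)
        signatures[:, j] = np.clip(np.digitize(col, edges[1:-1]), 0, k - 1)

    strata: dict[tuple, list[int]] = {}
    for i in range(n):
        strata.setdefault(tuple(signatures[i]), []).append(i)

    treated = np.array([u.treatment for u in units])
    weights = {u.video_id: 0.0 for u in units}
    retained_strata = []
    for sig, members in strata.items():
        m_t = sum(1 for i in members if treated[i] == 1)
        m_c = len(members) - m_t
        if m_t == 0 or m_c == 0:
            continue
        retained_strata.append((sig, members, m_t, m_c))
    if not retained_strata:
        raise ValueError("no common support: every stratum lacks one group")

    M_t = sum(m_t for _, _, m_t, _ in retained_strata)
    M_c = sum(m_c for _, _, _, m_c in retained_strata)
    for sig, members, m_t, m_c in retained_strata:
        for i in members:
            if treated[i] == 1:
                weights[units[i].video_id] = 1.0
            else:
                weights[units[i].video_id] = (m_t / m_c) * (M_c / M_t)
    return MatchedSample(weights=weights, method="CEM", params={"bins": k})


def _psm(units: Sequence[CausalUnit], propensity: Mapping[str, float],
         caliper_sd: float) -> MatchedSample:
    logit = {
        vid: math.log(p / (1.0 - p)) for vid, p in propensity.items()
    }
    sd = float(np.std(list(logit.values()), ddof=1))
    caliper = caliper_sd * sd
    treated = sorted([u.video_id for u in units if u.treatment == 1])
    controls = sorted([u.video_id for u in units if u.treatment == 0])
    available = set(controls)
    weights = {u.video_id: 0.0 for u in units}
    n_pairs = 0
    for t in treated:
        best, best_d = None, None
        for c in available:
            d = abs(logit[t] - logit[c])
            if best_d is None or d < best_d or (d == best_d and c < best):
                best, best_d = c, d
        if best is not None and best_d <= caliper:
            weights[t] = 1.0
            weights[best] = 1.0
            available.discard(best)
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no common support: no pair within the caliper")
    return MatchedSample(
        weights=weights, method="PSM", params={"caliper_sd": caliper_sd, "pairs": n_pairs}
    )


def match(units: Sequence[CausalUnit], method: str = "CEM", params: Optional[dict] = None) -> MatchedSample:
    """Match treated and control units; see the module docstring.

    ``params``: CEM accepts ``bins`` (default Sturges on n); PSM accepts
    ``propensity`` (id -> score; fitted here when omitted) and
    ``caliper_sd`` (default 0.2).
    """
    _check_groups(units)
    params = dict(params or {})
    if method == "CEM":
        return _cem(units, params.get("bins"))
    if method == "PSM":
        propensity = params.get("propensity") or fit_propensity(units)
        return _psm(units, propensity, params.get("caliper_sd", 0.2))
    raise ValueError(f"unknown matching method {method!r}")


# ---------------------------------------------------------------------------
# Balance diagnostics

@dataclass(frozen=True)
class BalanceReport:
    """Per-covariate weighted means and SMDs, before and (optionally) after
    matching.  The SMD denominator is the unweighted sample SD of the full
    treated group, so before/after values share a scale."""

    table: pd.DataFrame

    def mean_abs_smd(self, stage: str = "before") -> float:
        return float(self.table[f"smd_{stage}"].abs().mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.average(x, weights=w))


def _smd(mean_t: float, mean_c: float, sd_t: float) -> float:
    diff = mean_t - mean_c
    if sd_t == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / sd_t


def balance(units: Sequence[CausalUnit], matched: Optional[MatchedSample] = None) -> BalanceReport:
    treated = [u for u in units if u.treatment == 1]
    control = [u for u in units if u.treatment == 0]
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need at least two units per group for balance diagnostics")

    rows = {}
    for name in COVARIATE_NAMES:
        xt = np.array([u.covariates[name] for u in treated])
        xc = np.array([u.covariates[name] for u in control])
        sd_t = float(np.std(xt, ddof=1))
        row = {
            "mean_treated_before": float(xt.mean()),
            "mean_control_before": float(xc.mean()),
            "smd_before": _smd(float(xt.mean()), float(xc.mean()), sd_t),
        }
        if matched is not None:
            wt = np.array([matched.weights.get(u.video_id, 0.0) for u in treated])
            wc = np.array([matched.weights.get(u.video_id, 0.0) for u in control])
            if wt.sum() == 0 or wc.sum() == 0:
                raise ValueError("matched sample is empty in one group")
            mt = _weighted_mean(xt, wt)
            mc = _weighted_mean(xc, wc)
            row.update(
                mean_treated_after=mt,
                mean_control_after=mc,
                smd_after=_smd(mt, mc, sd_t),
            )
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "covariate"
    if np.isinf(table.filter(like="smd").to_numpy()).any():
        warnings.warn("infinite SMD: zero treated SD with unequal means")
    return BalanceReport(table=table)


# ---------------------------------------------------------------------------
# Treatment-effect estimation

@dataclass(frozen=True)
class ATEEstimate:
    outcome: str
    intercept: float
    ate: float
    se: float
    p_value: float
    n_treated: int
    n_control: int


def estimate_ate(units: Sequence[CausalUnit], matched: MatchedSample, outcome: str) -> ATEEstimate:
    """Weighted least squares of the log outcome on intercept + treatment
    over the matched, weighted sample."""
    if outcome not in OUTCOME_NAMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    kept = [u for u in units if matched.weights.get(u.video_id, 0.0) > 0]
    n_t = sum(u.treatment for u in kept)
    n_c = len(kept) - n_t
    if n_t == 0 or n_c == 0:
        raise ValueError("matched sample is empty in one group")
    y = np.array([u.outcomes[outcome] for u in kept])
    t = np.array([u.treatment for u in kept], dtype=float)
    w = np.array([matched.weights[u.video_id] for u in kept])
    design = sm.add_constant(t, has_constant="add")
    fit = sm.WLS(y, design, weights=w).fit()
    return ATEEstimate(
        outcome=outcome,
        intercept=float(fit.params[0]),
        ate=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n_treated=n_t,
        n_control=n_c,
    )


def naive_difference(units: Sequence[CausalUnit], outcome: str) -> float:
    """Unmatched treated-minus-control mean difference of the log outcome."""
    yt = [u.outcomes[outcome] for u in units if u.treatment == 1]
    yc = [u.outcomes[outcome] for u in units if u.treatment == 0]
    return float(np.mean(yt) - np.mean(yc))
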
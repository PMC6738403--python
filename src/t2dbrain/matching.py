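"""Sample filtering and optimal 2:1 case-control matching.

Controls are matched to cases at a fixed ratio by minimising the total
propensity-score distance over all assignments (min-cost bipartite assignment
with each case duplicated ``ratio`` times), the globally optimal counterpart
of nearest-neighbour greedy matching. The propensity model is a logistic
regression of case status on age, sex, race, BMI and RIN; on perfect
separation the matcher falls back to covariate-space Mahalanobis distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

COVARIATES_NUMERIC = ("age", "bmi", "rin")
COVARIATES_CATEGORICAL = ("sex", "race")


class EmptyCohortError(ValueError):
    """Raised when quality filtering leaves no usable samples."""


@dataclass
class MatchedCohort:
    case_ids: list[str]
    control_ids: list[str]
    pairing: dict[str, list[str]]  # case id -> ratio control ids
    distance_metric: str
    total_distance: float = 0.0

    def all_ids(self) -> list[str]:
        return self.case_ids + self.control_ids

    def to_dict(self) -> dict:
        return {
            "case_ids": self.case_ids,
            "control_ids": self.control_ids,
            "pairing": self.pairing,
            "distance_metric": self.distance_metric,
            "total_distance": self.total_distance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MatchedCohort":
        return cls(
            case_ids=list(d["case_ids"]),
            control_ids=list(d["control_ids"]),
            pairing={k: list(v) for k, v in d["pairing"].items()},
            distance_metric=d["distance_metric"],
            total_distance=float(d.get("total_distance", 0.0)),
        )


def filter_samples(
    samples: pd.DataFrame,
    min_rin: float = 6.0,
    allowed_races: tuple[str, ...] = ("black", "white"),
) -> pd.DataFrame:
    """Quality filter: RIN strictly above ``min_rin``, known binary status,
    races restricted to ``allowed_races`` (pass ``None`` to keep all)."""
    if "rin" not in samples.columns:
        raise KeyError("samples must have a 'rin' column")
    keep = samples["rin"] > min_rin
    keep &= samples["status"].isin([0, 1]).fillna(False)
    if allowed_races is not None and "race" in samples.columns:
        keep &= samples["race"].isin(allowed_races)
    out = samples.loc[keep].copy()
    if out.empty:
        raise EmptyCohortError("no samples survive quality filtering")
    return out


def _design_matrix(samples: pd.DataFrame) -> np.ndarray:
    """Intercept + numeric covariates + one-hot categoricals (first level reference)."""
    cols = [np.ones(len(samples))]
    for c in COVARIATES_NUMERIC:
        cols.append(samples[c].to_numpy(float))
    for c in COVARIATES_CATEGORICAL:
        levels = sorted(samples[c].astype(str).unique())
        for lev in levels[1:]:
            cols.append((samples[c].astype(str) == lev).to_numpy(float))
    return np.column_stack(cols)


@dataclass
class PropensityResult:
    scores: pd.Series | None  # per-sample P(case); None if separation fallback
    metric: str  # "propensity" or "mahalanobis"
    distance: pd.DataFrame = field(default=None, repr=False)  # cases x controls


def estimate_propensity(samples: pd.DataFrame) -> PropensityResult:
    """Logistic propensity scores; Mahalanobis distance fallback on separation.

    The returned object always carries a cases x controls distance matrix,
    which is |score_i - score_j| under the logistic model.
    """
    import statsmodels.api as sm

    samples = samples.sort_index()
    X = _design_matrix(samples)
    y = samples["status"].to_numpy(float)
    case_ids = samples.index[y == 1]
    ctrl_ids = samples.index[y == 0]

    scores = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        p = fit.predict(X)
        if np.all((p > 1e-8) & (p < 1 - 1e-8)) and np.isfinite(fit.params).all():
            scores = pd.Series(p, index=samples.index, name="propensity")
    except Exception:  # noqa: BLE001 - any fit failure routes to the fallback
        scores = None

    if scores is not None:
        d = np.abs(scores[case_ids].to_numpy()[:, None] - scores[ctrl_ids].to_numpy()[None, :])
        metric = "propensity"
    else:
        logger.warning("perfect separation in propensity model; using Mahalanobis distance")
        Z = _design_matrix(samples)[:, 1:]  # drop intercept
        cov = np.cov(Z, rowvar=False)
        cov += np.eye(cov.shape[0]) * 1e-8 * np.trace(cov) / cov.shape[0]
        VI = np.linalg.pinv(cov)
        zc = Z[y == 1]
        zk = Z[y == 0]
        diff = zc[:, None, :] - zk[None, :, :]
        d = np.sqrt(np.maximum(np.einsum("ijk,kl,ijl->ij", diff, VI, diff), 0.0))
        metric = "mahalanobis"
    dist = pd.DataFrame(d, index=case_ids, columns=ctrl_ids)
    return PropensityResult(scores=scores, metric=metric, distance=dist)


def optimal_match(
    scores: pd.Series | None,
    status: pd.Series,
    ratio: int = 2,
    distance: pd.DataFrame | None = None,
    metric: str = "propensity",
) -> MatchedCohort:
    """Globally optimal ``ratio``:1 control-to-case assignment.

    Either per-sample ``scores`` (distance = absolute score difference) or an
    explicit cases x controls ``distance`` matrix may be supplied. Each case
    node is duplicated ``ratio`` times and the total assignment cost is
    minimised with the Hungarian algorithm; ties are resolved deterministically
    by sorting samples lexicographically by id first.
    """
    status = status.sort_index()
    case_ids = list(status.index[status == 1])
    ctrl_ids = list(status.index[status == 0])
    deficit = ratio * len(case_ids) - len(ctrl_ids)
    if deficit > 0:
        raise ValueError(
            f"insufficient controls: need {ratio * len(case_ids)}, have {len(ctrl_ids)} "
            f"(short by {deficit})"
        )
    if distance is None:
        if scores is None:
            raise ValueError("either scores or a distance matrix is required")
        s = scores.sort_index()
        d = np.abs(s[case_ids].to_numpy()[:, None] - s[ctrl_ids].to_numpy()[None, :])
    else:
        d = distance.loc[case_ids, ctrl_ids].to_numpy(float)

    cost = np.repeat(d, ratio, axis=0)  # (cases*ratio) x controls
    rows, cols = linear_sum_assignment(cost)
    pairing: dict[str, list[str]] = {c: [] for c in case_ids}
    for r, c in zip(rows, cols):
        pairing[case_ids[r // ratio]].append(ctrl_ids[c])
    for c in pairing:
        pairing[c].sort()
    matched_controls = sorted(x for v in pairing.values() for x in v)
    return MatchedCohort(
        case_ids=case_ids,
        control_ids=matched_controls,
        pairing=pairing,
        distance_metric=metric,
        total_distance=float(cost[rows, cols].sum()),
    )


def greedy_match(scores: pd.Series, status: pd.Series, ratio: int = 2) -> MatchedCohort:
    """Nearest-neighbour greedy matching (baseline for the optimality check)."""
    status = status.sort_index()
    case_ids = list(status.index[status == 1])
    ctrl_ids = list(status.index[status == 0])
    if ratio * len(case_ids) > len(ctrl_ids):
        raise ValueError("insufficient controls")
    s = scores.sort_index()
    available = set(ctrl_ids)
    pairing: dict[str, list[str]] = {}
    total = 0.0
    for cid in case_ids:
        chosen = sorted(available, key=lambda k: (abs(s[k] - s[cid]), k))[:ratio]
        for k in chosen:
            available.discard(k)
            total += abs(s[k] - s[cid])
        pairing[cid] = sorted(chosen)
    controls = sorted(x for v in pairing.values() for x in v)
    return MatchedCohort(case_ids, controls, pairing, "propensity-greedy", total)


def match_cohort(
    samples: pd.DataFrame,
    ratio: int = 2,
    min_rin: float = 6.0,
    exact: tuple[str, ...] | None = None,
) -> MatchedCohort:
    """Filter, score and optimally match in one call.

    ``exact`` names categorical covariates (e.g. ("sex", "race")) on which
    case and control must agree; disagreeing pairs get prohibitive cost.
    """
    filtered = filter_samples(samples, min_rin=min_rin)
    prop = estimate_propensity(filtered)
    dist = prop.distance.copy()
    metric = prop.metric
    if exact:
        for col in exact:
            cv = filtered[col].astype(str)
            mism = cv[dist.index].to_numpy()[:, None] != cv[dist.columns].to_numpy()[None, :]
            dist = dist.mask(pd.DataFrame(mism, index=dist.index, columns=dist.columns),
                             1e6 + dist)
        metric = f"{metric}+exact({','.join(exact)})"
    return optimal_match(None, filtered["status"], ratio=ratio,
                         distance=dist, metric=metric)


def balance_table(cohort: MatchedCohort, samples: pd.DataFrame) -> pd.DataFrame:
    """Standardised mean differences and two-sample test p-values per covariate,
    before (all filtered samples) and after matching.

    SMD = (mean_case - mean_control) / pooled SD for numeric covariates;
    chi-square (or Fisher for 2x2 with small counts) for categoricals. A zero
    pooled SD gives SMD 0 when the means agree and +/-inf otherwise.
    """
    rows = []
    pre = samples
    post = samples.loc[cohort.all_ids()]
    for stage, df in (("pre", pre), ("post", post)):
        case = df[df["status"] == 1]
        ctrl = df[df["status"] == 0]
        for c in COVARIATES_NUMERIC:
            x, y = case[c].to_numpy(float), ctrl[c].to_numpy(float)
            pooled = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
            diff = x.mean() - y.mean()
            if pooled == 0:
                smd = 0.0 if diff == 0 else np.inf * np.sign(diff)
            else:
                smd = diff / pooled
            p = stats.ttest_ind(x, y, equal_var=False).pvalue if min(len(x), len(y)) > 1 else np.nan
            rows.append((stage, c, smd, p))
        for c in COVARIATES_CATEGORICAL:
            tab = pd.crosstab(df[c], df["status"])
            if tab.shape == (2, 2) and tab.to_numpy().min() < 5:
                p = stats.fisher_exact(tab.to_numpy())[1]
            elif tab.size > 1 and tab.to_numpy().sum() > 0:
                p = stats.chi2_contingency(tab.to_numpy())[1]
            else:
                p = np.nan
            # SMD for a binary categorical: difference in level-1 proportions
            levels = sorted(df[c].astype(str).unique())
            if len(levels) == 2:
                pc = (case[c].astype(str) == levels[1]).mean()
                pk = (ctrl[c].astype(str) == levels[1]).mean()
                pooled = np.sqrt((pc * (1 - pc) + pk * (1 - pk)) / 2.0)
                smd = 0.0 if pooled == 0 else (pc - pk) / pooled
            else:
                smd = np.nan
            rows.append((stage, c, smd, p))
    return pd.DataFrame(rows, columns=["stage", "covariate", "smd", "p"])
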
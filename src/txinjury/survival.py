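"""Outcome analyses: death-censored survival, time-varying Cox effects,
random-survival-forest importance, splines and covariate correlations.

The survival design is biopsy-anchored: time 0 is the biopsy, the event is
death-censored graft failure within 3 years, one randomly chosen biopsy per
kidney enters the analysis, and death with a functioning graft counts as
non-informative censoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import EARLY_TXBX_DAYS, LATE_TXBX_DAYS, SampleMetadata, one_biopsy_per_kidney

logger = logging.getLogger(__name__)

THREE_YEARS_DAYS = 3 * 365.0


@dataclass
class SurvivalFrame:
    """One row per kidney: follow-up time, event flag, and predictors."""

    df: pd.DataFrame  # columns: kidney_id, time, event, txbx_days, predictors...

    def __post_init__(self) -> None:
        if self.df["kidney_id"].duplicated().any():
            raise ValueError("survival frame must have one row per kidney")
        if (self.df["time"] <= 0).any():
            raise ValueError("non-positive follow-up time")
        if not self.df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")

    @property
    def n_events(self) -> int:
        return int(self.df["event"].sum())

    def predictors(self, names: list[str]) -> pd.DataFrame:
        return self.df[names]


def build_survival_frame(
    meta: SampleMetadata,
    scores: pd.DataFrame | None = None,
    seed: int = 0,
    horizon_days: float = THREE_YEARS_DAYS,
) -> SurvivalFrame:
    """Biopsy-anchored death-censored survival frame.

    Selects one random biopsy per kidney (seeded), censors administratively at
    ``horizon_days`` after biopsy, and codes death with function as censoring.
    Optional per-biopsy ``scores`` (PCs, archetype scores, gene-set means) are
    joined as predictors. Kidneys with no positive follow-up are excluded with
    a logged count.
    """
    df = meta.df
    fup = pd.to_numeric(df["followup_days"], errors="coerce")
    usable = fup.notna() & (fup > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("excluded %d biopsies without positive follow-up", n_dropped)
    eligible = SampleMetadata(df.loc[usable].copy())
    if len(eligible) == 0:
        raise ValueError("no biopsies with usable follow-up")
    picked = one_biopsy_per_kidney(eligible, seed=seed).df

    fup = picked["followup_days"].astype(float)
    time = np.minimum(fup, horizon_days)
    event = ((picked["graft_failed"].astype(int) == 1) & (fup <= horizon_days)).astype(int)
    out = pd.DataFrame(
        {
            "kidney_id": picked["kidney_id"],
            "time": time,
            "event": event,
            "txbx_days": picked["txbx_days"].astype(float),
        },
        index=picked.index,
    )
    if scores is not None:
        out = out.join(scores, how="left")
    frame = SurvivalFrame(out)
    logger.info(
        "survival frame: %d kidneys, %d events, %d censored",
        len(out), frame.n_events, len(out) - frame.n_events,
    )
    return frame


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_curve(frame: SurvivalFrame, groups: pd.Series | None = None) -> dict:
    """Product-limit survival per group, with at-risk tables.

    Returns a dict ``group -> DataFrame(timeline, survival, at_risk)``; with
    ``groups=None`` a single curve keyed ``"all"``. Empty groups are dropped
    with a warning.
    """
    from lifelines import KaplanMeierFitter

    if frame.n_events < 1:
        warnings.warn("no events: survival is 1 everywhere")
    if groups is None:
        labels = pd.Series("all", index=frame.df.index)
    else:
        labels = groups.reindex(frame.df.index)
    out = {}
    for g in pd.unique(labels.dropna()):
        sub = frame.df[labels == g]
        if len(sub) == 0:
            warnings.warn(f"empty group {g!r} dropped")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        tl = kmf.survival_function_.index.to_numpy()
        at_risk = np.array([(sub["time"] >= t).sum() for t in tl])
        out[g] = pd.DataFrame(
            {
                "timeline": tl,
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": at_risk,
            }
        )
    return out


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Step-function evaluation of a km_curve table at time t."""
    mask = curve["timeline"] <= t
    if not mask.any():
        return 1.0
    return float(curve.loc[mask, "survival"].iloc[-1])


# ---------------------------------------------------------------------------
# Cox with time-varying PC effects


@dataclass
class TimeVaryingEffect:
    """log-hazard effect of one predictor as a function of TxBx.

    beta(t) = main + interaction * g(t), with a delta-method pointwise
    confidence band from the coefficient covariance.
    """

    name: str
    main: float
    interaction: float
    cov: np.ndarray  # 2x2 covariance of (main, interaction)
    transform: str = "log"

    def _g(self, t_days):
        t = np.asarray(t_days, dtype=float)
        return np.log(t) if self.transform == "log" else t

    def beta(self, t_days):
        return self.main + self.interaction * self._g(t_days)

    def band(self, t_days, z: float = 1.96):
        g = self._g(t_days)
        var = self.cov[0, 0] + g**2 * self.cov[1, 1] + 2 * g * self.cov[0, 1]
        se = np.sqrt(np.maximum(var, 0))
        b = self.beta(t_days)
        return b - z * se, b + z * se


def cox_time_interaction(
    frame: SurvivalFrame,
    pcs: list[str],
    time_transform: str = "log",
    include_txbx_main: bool = True,
):
    """Proportional-hazards fit with PC x g(TxBx) interaction terms.

    g is the natural log of days posttransplant by default (``"linear"``
    selects untransformed days). Returns ``(effects, fitter)`` where
    ``effects`` maps each PC to a :class:`TimeVaryingEffect`.
    """
    from lifelines import CoxPHFitter

    if time_transform not in ("log", "linear"):
        raise ValueError("time_transform must be 'log' or 'linear'")
    g = np.log(frame.df["txbx_days"]) if time_transform == "log" else frame.df["txbx_days"]
    data = pd.DataFrame({"time": frame.df["time"], "event": frame.df["event"]})
    if include_txbx_main:
        data["g_txbx"] = g
    for pc in pcs:
        col = frame.df[pc].astype(float)
        if col.std() == 0:
            raise ValueError(f"degenerate predictor {pc!r}")
        data[pc] = col
        data[f"{pc}:g_txbx"] = col * g
    n_params = data.shape[1] - 2
    if frame.n_events < 10 * n_params:
        warnings.warn(
            f"{frame.n_events} events for {n_params} parameters (<10 per parameter)"
        )
    cph = CoxPHFitter()
    try:
        cph.fit(data.dropna(), duration_col="time", event_col="event")
    except Exception as exc:  # noqa: BLE001 - surface convergence diagnostics
        raise RuntimeError(f"Cox fit failed: {exc}") from exc

    effects = {}
    V = cph.variance_matrix_
    for pc in pcs:
        inter = f"{pc}:g_txbx"
        cov = np.array(
            [
                [V.loc[pc, pc], V.loc[pc, inter]],
                [V.loc[inter, pc], V.loc[inter, inter]],
            ]
        )
        effects[pc] = TimeVaryingEffect(
            name=pc,
            main=float(cph.params_[pc]),
            interaction=float(cph.params_[inter]),
            cov=cov,
            transform=time_transform,
        )
    return effects, cph


# ---------------------------------------------------------------------------
# Concordance and random survival forests


def c_statistic(risk, time, event) -> float:
    """Harrell's concordance over usable pairs (ties in risk count 1/2).

    A pair is comparable when the smaller time is an event time.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(risk)
    conc = ties = pairs = 0.0
    for i in range(n):
        if event[i] != 1:
            continue
        comparable = (time > time[i]) | ((time == time[i]) & (event == 0))
        pairs += comparable.sum()
        conc += (risk[comparable] < risk[i]).sum()
        ties += (risk[comparable] == risk[i]).sum()
    if pairs == 0:
        raise ValueError("no comparable pairs")
    return float((conc + 0.5 * ties) / pairs)


def rsf_importance(
    frame: SurvivalFrame,
    predictors: list[str],
    ntree: int = 5000,
    seed: int = 0,
    n_repeats: int = 5,
    min_samples_leaf: int = 15,
):
    """Random survival forest: OOB error (1 - C) and permutation importance.

    Missing predictor values are median-imputed. Predictors are processed in
    name-sorted order with per-predictor seeded permutations, so the result
    is invariant to the caller's column order. ``ntree`` defaults to the
    production value; analyses at test scale pass a smaller forest since tree
    count is a runtime rather than statistical choice.

    Returns ``(importance, oob_error, forest)`` with ``importance`` a Series
    (mean drop in OOB-style concordance when the predictor is permuted),
    sorted descending.
    """
    from sksurv.ensemble import RandomSurvivalForest
    from sksurv.util import Surv

    names = sorted(predictors)
    X = frame.df[names].astype(float).copy()
    X = X.fillna(X.median())
    for c in names:
        if X[c].std() == 0:
            warnings.warn(f"constant predictor {c!r}: importance will be zero")
    y = Surv.from_arrays(frame.df["event"].astype(bool), frame.df["time"])
    forest = RandomSurvivalForest(
        n_estimators=ntree,
        min_samples_leaf=min_samples_leaf,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X.to_numpy(), y)
    oob_error = 1.0 - float(forest.oob_score_)

    time_arr = frame.df["time"].to_numpy(dtype=float)
    event_arr = frame.df["event"].to_numpy(dtype=int)

    def _concordance(mat):
        return c_statistic(forest.predict(mat), time_arr, event_arr)

    base = _concordance(X.to_numpy())
    imp = {}
    for j, c in enumerate(names):
        rng = np.random.default_rng([seed, j])
        drops = []
        for _ in range(n_repeats):
            Xp = X.to_numpy().copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(base - _concordance(Xp))
        imp[c] = float(np.mean(drops))
    importance = pd.Series(imp, name="permutation_importance").sort_values(ascending=False)
    return importance, oob_error, forest


# ---------------------------------------------------------------------------
# Restricted cubic splines


@dataclass
class SplineFit:
    """Least-squares restricted cubic spline (linear beyond boundary knots)."""

    knots: np.ndarray
    coef: np.ndarray  # intercept, linear, then one coefficient per inner basis

    def basis(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = self.knots
        K = len(t)
        cols = [np.ones_like(x), x]
        denom = (t[-1] - t[0]) ** 2
        for j in range(K - 2):
            d = lambda u: np.maximum(u, 0.0) ** 3
            cj = (
                d(x - t[j])
                - d(x - t[K - 2]) * (t[K - 1] - t[j]) / (t[K - 1] - t[K - 2])
                + d(x - t[K - 1]) * (t[K - 2] - t[j]) / (t[K - 1] - t[K - 2])
            ) / denom
            cols.append(cj)
        return np.column_stack(cols)

    def predict(self, x) -> np.ndarray:
        return self.basis(x) @ self.coef


#: Harrell's default knot quantiles by knot count.
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def rcs_fit(y, x, n_knots: int = 3) -> SplineFit:
    """Fit y on a restricted cubic spline of x, knots at standard quantiles.

    With 3 knots (the default) the knots sit at the 0.10/0.50/0.90 quantiles;
    the fitted function is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    qs = _KNOT_QUANTILES.get(n_knots)
    if qs is None:
        qs = tuple(np.linspace(0.05, 0.95, n_knots))
    knots = np.quantile(x, qs)
    if len(np.unique(knots)) < n_knots:
        raise ValueError("insufficient distinct x values for the requested knots")
    fit = SplineFit(knots=knots, coef=np.zeros(n_knots))
    B = fit.basis(x)
    fit.coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    return fit


# ---------------------------------------------------------------------------
# Score / covariate associations and group summaries


def correlate_with_covariate(
    scores: pd.DataFrame, covariate: pd.Series
) -> pd.DataFrame:
    """Spearman rho and tie-corrected p of each score column vs a covariate."""
    joined = scores.join(covariate.rename("_cov"), how="inner").dropna(subset=["_cov"])
    if len(joined) < 3:
        raise ValueError("need at least 3 paired observations")
    cov = joined["_cov"]
    if cov.nunique() < 2:
        raise ValueError("constant covariate")
    rows = {}
    for col in scores.columns:
        res = spearmanr(joined[col], cov, nan_policy="omit")
        rows[col] = {"rho": float(res.statistic), "p": float(res.pvalue)}
    return pd.DataFrame(rows).T


def group_summaries(
    meta: SampleMetadata,
    groups: pd.Series,
    scores: pd.DataFrame | None = None,
    epoch: str = "all",
) -> pd.DataFrame:
    """Per-injury-group cohort summaries, optionally epoch-stratified.

    ``epoch`` is ``"all"``, ``"early"`` (TxBx <= 42 days) or ``"late"``
    (TxBx > 1 year). Empty groups yield a row with n=0 and missing stats.
    """
    df = meta.df.join(groups.rename("group"), how="inner")
    if epoch == "early":
        df = df[df["txbx_days"] <= EARLY_TXBX_DAYS]
    elif epoch == "late":
        df = df[df["txbx_days"] > LATE_TXBX_DAYS]
    elif epoch != "all":
        raise ValueError("epoch must be 'all', 'early' or 'late'")
    if scores is not None:
        df = df.join(scores, how="left")
    rows = []
    group_names = list(pd.unique(groups.dropna()))
    for g in group_names:
        sub = df[df["group"] == g]
        row = {"group": g, "n": len(sub)}
        if len(sub):
            row["median_txbx_days"] = float(sub["txbx_days"].median())
            row["mean_egfr"] = float(sub["egfr"].mean())
            row["mean_donor_age"] = float(sub["donor_age"].mean())
            row["pct_donor_age_ge50"] = float(100 * (sub["donor_age"] >= 50).mean())
            if scores is not None:
                for c in scores.columns:
                    row[f"mean_{c}"] = float(sub[c].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
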
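"""Longitudinal statistics for the pulsatility analysis.

Covariate residualization (physical-activity and cardiovascular-risk
adjustment), generalized-ESD outlier screening, paired contrasts of global
amplitude across visits and walk conditions, block-retest reliability,
change-change correlations between amplitude and Stroop response time, and
channel-wise paired t maps with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .types import (
    ContrastResult,
    DataError,
    GlobalPulseAmplitude,
    ParameterError,
)

__all__ = [
    "residualize",
    "gesd_outliers",
    "paired_ttest",
    "block_reliability",
    "delta_correlation",
    "bh_adjust",
    "channelwise_contrast",
    "stroop_change",
    "build_participant_table",
]

STROOP_CONDITIONS = ("naming", "reading", "inhibition", "switching")


def residualize(values: np.ndarray, covariates: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Adjust values for covariates by OLS, preserving the original scale.

    Fits ``values ~ intercept + covariates`` and returns residual + grand
    mean, so the adjusted series is on the same scale as the input.
    """
    y = np.asarray(values, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) < X.shape[1] + 2:
        raise ParameterError("need n >= number of covariates + 2")
    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.cond(design) > 1e8:
        raise ParameterError("collinear covariates (condition number > 1e8)")
    import statsmodels.api as sm

    fit = sm.OLS(y, design).fit()
    return fit.resid + y.mean()


def gesd_outliers(
    x: np.ndarray, alpha: float = 0.05, max_out: int | None = None
) -> list[int]:
    """Generalized extreme Studentized deviate test for multiple outliers.

    Iteratively removes the most extreme studentized value and compares the
    test statistic R_i against the critical value lambda_i from the t
    distribution; all indices up to the largest i with R_i > lambda_i are
    returned (indices into the input vector).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ParameterError("GESD needs n >= 5")
    if max_out is None:
        max_out = int(np.ceil(0.1 * n))
    max_out = min(max_out, n - 2)

    remaining = list(range(n))
    removed: list[int] = []
    exceed: list[bool] = []
    for i in range(1, max_out + 1):
        sub = x[remaining]
        mu, sd = sub.mean(), sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - mu)
        j = int(np.argmax(dev))
        r_i = dev[j] / sd
        m = n - i + 1  # current sample size
        p = 1 - alpha / (2 * m)
        t_crit = spstats.t.ppf(p, m - 2)
        lam = (m - 1) * t_crit / np.sqrt((m - 2 + t_crit**2) * m)
        removed.append(remaining.pop(j))
        exceed.append(bool(r_i > lam))
    k = max((i + 1 for i, e in enumerate(exceed) if e), default=0)
    return sorted(removed[:k])


def paired_ttest(x: np.ndarray, y: np.ndarray, scope: str = "global") -> ContrastResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ParameterError("paired t-test needs n >= 3")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return ContrastResult(scope=scope, statistic=0.0, df=n - 1, p_raw=1.0,
                                  effect=0.0, n=n)
        raise DataError("zero-variance non-zero differences; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * spstats.t.sf(abs(t), n - 1)
    return ContrastResult(scope=scope, statistic=float(t), df=n - 1,
                          p_raw=float(p), effect=float(d.mean()), n=n)


def block_reliability(block1: np.ndarray, block2: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between block-1 and block-2 amplitudes."""
    block1 = np.asarray(block1, dtype=float)
    block2 = np.asarray(block2, dtype=float)
    if len(block1) < 3:
        raise ParameterError("reliability needs n >= 3")
    r, p = spstats.pearsonr(block1, block2)
    return float(r), float(p)


def delta_correlation(
    d_amp: np.ndarray,
    d_rt: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    drop_outliers: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Correlation between amplitude change and response-time change.

    Plain Pearson when ``covariates`` is None or empty; otherwise partial
    correlation (Pearson on the residuals of each delta regressed on the
    covariates, p-value with df = n - 2 - k).  With ``drop_outliers`` the
    generalized-ESD screen is applied to each delta and flagged
    participants removed (indices logged in the result).
    """
    d_amp = np.asarray(d_amp, dtype=float)
    d_rt = np.asarray(d_rt, dtype=float)
    if d_amp.shape != d_rt.shape:
        raise ParameterError("paired deltas must have equal length")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[1] == 0:
            cov = None

    removed: list[int] = []
    if drop_outliers:
        removed = sorted(set(gesd_outliers(d_amp, alpha)) | set(gesd_outliers(d_rt, alpha)))
        keep = [i for i in range(len(d_amp)) if i not in removed]
        d_amp, d_rt = d_amp[keep], d_rt[keep]
        if cov is not None:
            cov = cov[keep]
    n = len(d_amp)
    if n < 5:
        raise DataError(f"only {n} pairs after outlier removal; need >= 5")

    if cov is None:
        r, p = spstats.pearsonr(d_amp, d_rt)
        k = 0
        method = "pearson"
    else:
        ra = residualize(d_amp, cov) - d_amp.mean()
        rb = residualize(d_rt, cov) - d_rt.mean()
        r = float(np.corrcoef(ra, rb)[0, 1])
        k = cov.shape[1]
        df = n - 2 - k
        if df <= 0:
            raise ParameterError("not enough pairs for partial correlation")
        t = r * np.sqrt(df / max(1 - r**2, np.finfo(float).tiny))
        p = 2 * spstats.t.sf(abs(t), df)
        method = f"partial ({k} covariates)"
    return dict(r=float(r), p=float(p), n=n, method=method, outliers_removed=removed)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def channelwise_contrast(
    amp_a: pd.DataFrame,
    amp_b: pd.DataFrame,
    q_threshold: float = 0.05,
    min_participants: int = 3,
) -> pd.DataFrame:
    """Channel-wise paired t map with FDR control.

    ``amp_a`` and ``amp_b`` are participants x channels amplitude tables for
    the two conditions (e.g. T0 vs T12, or BW vs AW), indexed by participant.
    Channels are analyzed over the intersection of participants with data in
    both conditions; channels observed in fewer than ``min_participants``
    paired rows are excluded (listed with reason).  Returns one row per
    channel: t, df, p_raw, q_fdr, significant.
    """
    common = sorted(set(amp_a.columns) & set(amp_b.columns))
    rows = []
    skipped = []
    for ch in common:
        pair = pd.concat([amp_a[ch], amp_b[ch]], axis=1, join="inner").dropna()
        if len(pair) < min_participants:
            skipped.append(ch)
            continue
        try:
            res = paired_ttest(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy(),
                               scope="channel")
        except DataError:
            skipped.append(ch)
            continue
        rows.append(dict(channel_id=ch, t=res.statistic, df=res.df,
                         p_raw=res.p_raw, effect=res.effect, n=res.n))
    if not rows:
        raise DataError("no channels with enough paired observations")
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["q_fdr"] < q_threshold
    out.attrs["skipped_channels"] = skipped
    return out


def stroop_change(
    rt_t0: pd.DataFrame,
    rt_t12: pd.DataFrame,
    err_t0: pd.DataFrame | None = None,
    err_t12: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-condition Stroop change: mean RT reduction and paired tests.

    Inputs are participants x conditions tables of response times (s) and
    error counts at the two visits.  ``delta_rt`` is mean RT(T0) minus mean
    RT(T12) (positive = faster after 12 months).  A speed-accuracy-tradeoff
    flag is raised for a condition whose response time improves while its
    errors significantly worsen.
    """
    for cond in STROOP_CONDITIONS:
        if cond not in rt_t0.columns or cond not in rt_t12.columns:
            raise DataError(f"missing Stroop condition {cond!r}")
    rows = []
    for cond in STROOP_CONDITIONS:
        a = rt_t0[cond].to_numpy(dtype=float)
        b = rt_t12[cond].to_numpy(dtype=float)
        res = paired_ttest(a, b)
        row = dict(
            condition=cond,
            rt_t0_mean=float(a.mean()),
            rt_t12_mean=float(b.mean()),
            delta_rt=float(a.mean() - b.mean()),
            t=res.statistic,
            df=res.df,
            p=res.p_raw,
        )
        if err_t0 is not None and err_t12 is not None and cond in err_t0 and cond in err_t12:
            e0 = err_t0[cond].to_numpy(dtype=float)
            e1 = err_t12[cond].to_numpy(dtype=float)
            try:
                eres = paired_ttest(e0, e1)
                row["err_p"] = eres.p_raw
                row["err_delta"] = float(e0.mean() - e1.mean())
                row["speed_accuracy_flag"] = bool(
                    row["delta_rt"] > 0 and eres.p_raw < 0.05 and row["err_delta"] < 0
                )
            except DataError:
                row["err_p"] = np.nan
                row["err_delta"] = float(e0.mean() - e1.mean())
                row["speed_accuracy_flag"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def build_participant_table(
    globals_list: list[GlobalPulseAmplitude],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-participant analysis table.

    One row per (participant, timepoint) with block-1/block-2/mean global
    amplitudes per condition (BW, AW); covariates merged in when given.
    """
    rows = [
        dict(participant_id=g.participant_id, timepoint=g.timepoint,
             condition=g.condition, block=g.block, value=g.value)
        for g in globals_list
    ]
    df = pd.DataFrame(rows)
    wide = df.pivot_table(
        index=["participant_id", "timepoint"],
        columns=["condition", "block"],
        values="value",
    )
    out = pd.DataFrame(index=wide.index)
    for cond in ("BW", "AW"):
        if cond not in wide.columns.get_level_values(0):
            continue
        sub = wide[cond]
        for blk in sub.columns:
            out[f"{cond.lower()}_block{blk}"] = sub[blk]
        out[f"{cond.lower()}_mean"] = sub.mean(axis=1)
    out = out.reset_index()
    if covariates is not None:
        out = out.merge(covariates, on=["participant_id", "timepoint"], how="left")
    return out
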
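"""Ecotype comparisons of response strength and timing.

Strength is modelled per odorant x population with a linear mixed model:
log2(strength + 0.01) ~ ecotype * pulse_duration with a random intercept
per antenna (REML). Onset and offset times are modelled for 300-ms pulses
only with a simple linear model log2(timing) ~ ecotype. Inference uses
flat-prior posterior simulation (10,000 draws by default): for the linear
model the residual variance is drawn from its scaled inverse-chi-squared
posterior and coefficients from a matching multivariate normal; for the
mixed model variance components are held at their REML estimates and the
fixed effects are drawn from a multivariate normal with the fitted
coefficient covariance (a documented approximation). Certainty is the
proportion of draws in which one ecotype exceeds the other, reported
direction-agnostically; >95% / >99% certainty earns one / two asterisks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelError",
    "LOG2_OFFSET",
    "transform_strength",
    "inverse_transform_strength",
    "ModelFit",
    "fit_strength_model",
    "fit_timing_model",
    "PosteriorDraws",
    "simulate_posterior",
    "PosteriorSummary",
    "ecotype_contrast",
    "summarize_comparison",
    "summarize_strength_contrasts",
    "group_mean_summary",
    "stars_for_certainty",
]

#: offset added before the log2 transform of response strength
LOG2_OFFSET = 0.01

ECOTYPE_REF = "full-winged"
ECOTYPE_ALT = "wing-reduced"


class ModelError(ValueError):
    """Raised on singular or under-determined model designs."""


def transform_strength(strength_mv, offset: float = LOG2_OFFSET):
    """log2(strength + offset); raises on strength <= -offset."""
    x = np.asarray(strength_mv, dtype=float)
    if np.any(x <= -offset):
        bad = np.flatnonzero(x <= -offset)
        raise ValueError(
            f"strength <= {-offset} mV at rows {bad.tolist()}: outside the "
            "transform domain"
        )
    out = np.log2(x + offset)
    return float(out) if np.isscalar(strength_mv) else out


def inverse_transform_strength(value, offset: float = LOG2_OFFSET):
    """Back-transform a modelling-scale value: 2**value - offset."""
    return 2.0 ** np.asarray(value, dtype=float) - offset


@dataclass
class ModelFit:
    """Coefficients and covariance of a fitted strength or timing model."""

    kind: str  # "mixed" | "linear"
    params: pd.Series
    cov: pd.DataFrame
    scale: float  # residual variance
    df_resid: float
    re_var: float | None  # random-intercept variance (mixed only)
    n_obs: int
    n_dropped: int
    durations: list = field(default_factory=list)
    formula: str = ""


def _filter_table(table: pd.DataFrame, odorant, population) -> pd.DataFrame:
    df = table
    if odorant is not None:
        df = df[df["odorant"] == odorant]
    if population is not None:
        df = df[df["population"] == population]
    return df.copy()


def _strength_design(df: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    durations = sorted(df["pulse_duration_ms"].unique())
    wr = (df["ecotype"] == ECOTYPE_ALT).astype(float).to_numpy()
    cols = {"intercept": np.ones(len(df))}
    cols[f"ecotype[{ECOTYPE_ALT}]"] = wr
    for d in durations[1:]:
        ind = (df["pulse_duration_ms"] == d).astype(float).to_numpy()
        cols[f"dur[{d:g}]"] = ind
        cols[f"ecotype[{ECOTYPE_ALT}]:dur[{d:g}]"] = wr * ind
    return pd.DataFrame(cols, index=df.index), durations


def fit_strength_model(
    table: pd.DataFrame, odorant=None, population=None
) -> ModelFit:
    """REML linear mixed model for log2-transformed response strength.

    Fixed effects: ecotype, pulse duration (categorical, reference =
    smallest level) and their interaction; random intercept per antenna.
    Rows with strength <= -0.01 mV are dropped (and counted).
    """
    df = _filter_table(table, odorant, population)
    modellable = df["strength_mV"] > -LOG2_OFFSET
    n_dropped = int((~modellable).sum())
    df = df[modellable]
    if df["ecotype"].nunique() < 2:
        raise ModelError("both ecotypes are required to fit the strength model")
    if df["pulse_duration_ms"].nunique() < 2:
        raise ModelError("at least two pulse-duration levels are required")
    for eco in (ECOTYPE_REF, ECOTYPE_ALT):
        if df.loc[df["ecotype"] == eco, "antenna_id"].nunique() < 2:
            raise ModelError(f"fewer than 2 antennae for ecotype {eco!r}")

    y = transform_strength(df["strength_mV"].to_numpy())
    exog, durations = _strength_design(df)
    k = exog.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=df["antenna_id"].to_numpy())
            result = model.fit(reml=True)
        params = pd.Series(np.asarray(result.fe_params), index=exog.columns)
        cov = np.asarray(result.cov_params())[:k, :k]
        scale = float(result.scale)
        re_var = float(np.asarray(result.cov_re)[0, 0])
    except np.linalg.LinAlgError:
        # degenerate data (zero residual variance); fixed effects reduce to OLS
        ols = sm.OLS(y, exog).fit()
        params = ols.params.copy()
        cov = np.asarray(ols.cov_params())
        scale = float(ols.scale)
        re_var = 0.0
    return ModelFit(
        kind="mixed",
        params=params,
        cov=pd.DataFrame(cov, index=exog.columns, columns=exog.columns),
        scale=scale,
        df_resid=float(len(df) - k),
        re_var=re_var,
        n_obs=len(df),
        n_dropped=n_dropped,
        durations=durations,
        formula="log2(strength + 0.01) ~ ecotype * duration + (1 | antenna)",
    )


def fit_timing_model(
    table: pd.DataFrame,
    which: str = "onset",
    odorant=None,
    population=None,
    duration_ms: float = 300.0,
) -> ModelFit:
    """Linear model log2(timing) ~ ecotype for 300-ms pulses.

    ``which`` selects onset or offset. Rows with invalid or non-positive
    timings are excluded before fitting and counted in ``n_dropped``.
    """
    if which not in ("onset", "offset"):
        raise ValueError(f"which must be 'onset' or 'offset', got {which!r}")
    col = f"{which}_s"
    df = _filter_table(table, odorant, population)
    df = df[df["pulse_duration_ms"] == duration_ms]
    usable = df[col].notna() & (df[col] > 0)
    n_dropped = int((~usable).sum())
    df = df[usable]
    for eco in (ECOTYPE_REF, ECOTYPE_ALT):
        if (df["ecotype"] == eco).sum() < 2:
            raise ModelError(f"fewer than 2 antennae for ecotype {eco!r}")

    y = np.log2(df[col].to_numpy(dtype=float))
    exog = pd.DataFrame(
        {
            "intercept": np.ones(len(df)),
            f"ecotype[{ECOTYPE_ALT}]": (df["ecotype"] == ECOTYPE_ALT).astype(float),
        },
        index=df.index,
    )
    result = sm.OLS(y, exog).fit()
    return ModelFit(
        kind="linear",
        params=result.params.copy(),
        cov=result.cov_params().copy(),
        scale=float(result.scale),
        df_resid=float(result.df_resid),
        re_var=None,
        n_obs=len(df),
        n_dropped=n_dropped,
        durations=[duration_ms],
        formula=f"log2({which}) ~ ecotype",
    )


@dataclass
class PosteriorDraws:
    """Flat-prior posterior simulation output."""

    coef: pd.DataFrame  # n_sim x n_coefficients
    sigma2: np.ndarray  # residual-variance draws (constant for mixed fits)
    kind: str
    seed: int | None

    @property
    def n_sim(self) -> int:
        return len(self.coef)


def simulate_posterior(
    fit: ModelFit, n_sim: int = 10_000, seed: int | None = None
) -> PosteriorDraws:
    """Draw coefficient vectors from the flat-prior posterior.

    Linear model: residual variance ~ scaled inverse chi-squared with the
    residual degrees of freedom, coefficients ~ MVN centered at the
    estimates with covariance rescaled by each variance draw. Mixed model:
    variance components fixed at their REML estimates, fixed effects ~ MVN
    with the fitted covariance.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(fit.params.index)
    beta_hat = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    if fit.kind == "linear":
        df_resid = fit.df_resid
        sigma2 = fit.scale * df_resid / rng.chisquare(df_resid, size=n_sim)
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((n_sim, len(names)))
        scale_factor = np.sqrt(sigma2 / fit.scale)[:, None]
        draws = beta_hat + scale_factor * (z @ chol.T)
    else:
        sigma2 = np.full(n_sim, fit.scale)
        draws = rng.multivariate_normal(
            beta_hat, cov, size=n_sim, method="cholesky"
        )
    return PosteriorDraws(
        coef=pd.DataFrame(draws, columns=names), sigma2=sigma2, kind=fit.kind, seed=seed
    )


def stars_for_certainty(certainty: float) -> str:
    """">95% certainty: one asterisk; >99%: two."""
    if certainty > 0.99:
        return "**"
    if certainty > 0.95:
        return "*"
    return ""


@dataclass
class PosteriorSummary:
    """One ecotype contrast: estimate, 95% CI, certainty and asterisks.

    ``mean``/``lo95``/``hi95`` are on the modelling (log2) scale and are
    oriented as full-winged minus wing-reduced; ``ratio`` fields give
    2**value (the full-winged / wing-reduced ratio of the back-transformed
    quantity).
    """

    label: str
    mean: float
    lo95: float
    hi95: float
    ratio: float
    ratio_lo95: float
    ratio_hi95: float
    p_fw_greater: float
    certainty: float
    direction: str
    stars: str


def ecotype_contrast(fit: ModelFit, duration_ms: float | None = None) -> pd.Series:
    """Contrast vector giving (full-winged minus wing-reduced) fitted values.

    For the strength model the contrast is evaluated at one pulse
    duration; for the timing model ``duration_ms`` is ignored.
    """
    c = pd.Series(0.0, index=fit.params.index)
    c[f"ecotype[{ECOTYPE_ALT}]"] = -1.0
    if fit.kind == "mixed":
        if duration_ms is None:
            raise ValueError("duration_ms is required for the strength model")
        if duration_ms not in fit.durations:
            raise ValueError(f"duration {duration_ms} not in fit: {fit.durations}")
        name = f"ecotype[{ECOTYPE_ALT}]:dur[{duration_ms:g}]"
        if name in c.index:  # absent for the reference level
            c[name] = -1.0
    return c


def summarize_comparison(
    draws: PosteriorDraws, contrast: pd.Series, label: str = ""
) -> PosteriorSummary:
    """Summarize one linear contrast of the posterior draws.

    Certainty is direction-agnostic: max(p, 1 - p) where p is the
    proportion of draws with the full-winged value above the wing-reduced
    value. The credible interval is the [2.5%, 97.5%] quantile range.
    """
    c = contrast.reindex(draws.coef.columns).fillna(0.0).to_numpy()
    d = draws.coef.to_numpy() @ c
    p = float(np.mean(d > 0))
    certainty = max(p, 1.0 - p)
    lo, hi = np.quantile(d, [0.025, 0.975])
    mean = float(np.mean(d))
    with np.errstate(over="ignore"):  # extreme draws back-transform to inf
        ratio, ratio_lo, ratio_hi = np.exp2([mean, lo, hi])
    return PosteriorSummary(
        label=label,
        mean=mean,
        lo95=float(lo),
        hi95=float(hi),
        ratio=float(ratio),
        ratio_lo95=float(ratio_lo),
        ratio_hi95=float(ratio_hi),
        p_fw_greater=p,
        certainty=certainty,
        direction=(
            f"{ECOTYPE_REF} > {ECOTYPE_ALT}" if p >= 0.5 else f"{ECOTYPE_ALT} > {ECOTYPE_REF}"
        ),
        stars=stars_for_certainty(certainty),
    )


def summarize_strength_contrasts(
    fit: ModelFit, draws: PosteriorDraws, label_prefix: str = ""
) -> pd.DataFrame:
    """Per-duration ecotype contrasts of the strength model as a table."""
    rows = []
    for d in fit.durations:
        s = summarize_comparison(
            draws, ecotype_contrast(fit, d), label=f"{label_prefix}{d:g} ms"
        )
        rows.append(
            {
                "contrast": s.label,
                "mean_log2": s.mean,
                "lo95_log2": s.lo95,
                "hi95_log2": s.hi95,
                "ratio": s.ratio,
                "p_fw_greater": s.p_fw_greater,
                "certainty": s.certainty,
                "direction": s.direction,
                "stars": s.stars,
            }
        )
    return pd.DataFrame(rows)


def group_mean_summary(
    fit: ModelFit,
    draws: PosteriorDraws,
    duration_ms: float | None = None,
    backtransform_offset: float | None = None,
) -> pd.DataFrame:
    """Back-transformed fitted group means with 95% credible intervals.

    For the strength model pass ``backtransform_offset=0.01`` so the
    offset added before the log2 transform is subtracted again; timing
    models back-transform with 2**value only.
    """
    rows = []
    for eco in (ECOTYPE_REF, ECOTYPE_ALT):
        c = pd.Series(0.0, index=fit.params.index)
        c["intercept"] = 1.0
        if eco == ECOTYPE_ALT:
            c[f"ecotype[{ECOTYPE_ALT}]"] = 1.0
        if fit.kind == "mixed" and duration_ms is not None:
            dname = f"dur[{duration_ms:g}]"
            if dname in c.index:
                c[dname] = 1.0
                if eco == ECOTYPE_ALT:
                    c[f"ecotype[{ECOTYPE_ALT}]:{dname}"] = 1.0
        vals = draws.coef.to_numpy() @ c.reindex(draws.coef.columns).fillna(0.0).to_numpy()
        lo, hi = np.quantile(vals, [0.025, 0.975])
        offset = backtransform_offset or 0.0
        rows.append(
            {
                "ecotype": eco,
                "mean": 2.0 ** float(np.mean(vals)) - offset,
                "lo95": 2.0 ** float(lo) - offset,
                "hi95": 2.0 ** float(hi) - offset,
            }
        )
    return pd.DataFrame(rows)
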
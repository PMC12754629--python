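"""Power-law diversity-functioning model fit per salinity treatment.

The richness-yield relationship is modelled as a power function, fit on the
log10 scale with mean-centered log richness:

    log10 Y(S) = b * (log10 S - log10 Sc) + log10 Y(Sc)

so the intercept is the yield at the average (geometric-mean) richness Sc and
the exponent ``b`` sets the curve's shape: ``b < 1`` means function
decelerates with richness (functional redundancy), ``b = 1`` is a linear
gain per species, ``b > 1`` accelerates. One shared Sc — computed over all
records of the experiment — keeps intercepts comparable across salinities.

Per-salinity fits are ordinary least squares; a linear mixed-effects variant
adds a random intercept per community (the unit repeated across salinities)
with salinity as a fixed categorical factor interacting with centered log
richness. Trends of the fitted parameters across the salinity gradient are
summarized by linear or quadratic regression (the quadratic term tests an
inverted-U shape).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import SingularFitWarning

__all__ = [
    "PowerFitResult",
    "TrendFit",
    "MixedModelResult",
    "center_log_richness",
    "fit_power_per_salinity",
    "fit_all_salinities",
    "fit_mixed_model",
    "classify_exponent",
    "parameter_trend",
    "simulate_power_records",
    "fits_table",
]


@dataclass
class PowerFitResult:
    """Per-salinity power-model fit: exponent, centered intercept, fit stats."""

    salinity: float
    b: float = float("nan")
    b_se: float = float("nan")
    log_y_sc: float = float("nan")
    log_y_sc_se: float = float("nan")
    sc: float = float("nan")
    r2: float = float("nan")
    p_value: float = float("nan")
    n: int = 0
    n_zero_excluded: int = 0
    ok: bool = True
    reason: str | None = None


@dataclass
class TrendFit:
    """Trend of a fitted parameter (intercept or exponent) across salinity."""

    response: str
    form: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    slope2: float | None = None  # quadratic coefficient (inverted-U test)


@dataclass
class MixedModelResult:
    """Per-salinity fixed effects from the random-intercept mixed model.

    ``per_salinity`` maps salinity -> dict(b, b_se, log_y_sc, log_y_sc_se).
    p-values for fixed effects are Wald t-as-z approximations and flagged as
    such; per-salinity OLS fits remain the reported inferential surface.
    """

    per_salinity: dict
    random_intercept_sd: float
    converged: bool
    singular: bool
    n: int
    sc: float


def center_log_richness(records: pd.DataFrame):
    """Shared centering of log10 richness over all records of an experiment.

    Returns ``(sc, covariate)``: ``Sc = 10**mean(log10 S)`` (the geometric
    mean richness, replicate-weighted) and the per-record centered covariate
    ``log10(S) - mean(log10 S)``, whose mean is zero by construction.
    """
    if len(records) == 0:
        raise ValueError("no records to center")
    s = np.asarray(records["richness"], dtype=float)
    if np.any(s < 1):
        raise ValueError("richness must be >= 1")
    log_s = np.log10(s)
    mean_log = float(log_s.mean())
    return 10.0 ** mean_log, pd.Series(log_s - mean_log, index=records.index, name="covariate")


def _prepare(records: pd.DataFrame, floor: float):
    """Attach the shared covariate; split off zero/floored yields."""
    sc, covariate = center_log_richness(records)
    df = records.assign(covariate=covariate)
    usable = df["Y_O"] > floor
    return sc, df[usable].copy(), int((~usable).sum())


def fit_power_per_salinity(
    records: pd.DataFrame,
    salinity: float,
    floor: float = 0.0,
    sc_records: pd.DataFrame | None = None,
) -> PowerFitResult:
    """OLS fit of log10 yield on centered log10 richness at one salinity.

    Centering uses all records (every salinity) of ``sc_records`` — by
    default ``records`` itself — so intercepts share one Sc. Yields at or
    below ``floor`` are excluded before the log transform, with the count
    reported; if fewer than 3 usable records remain the result is flagged
    not-ok with the reason (mirroring functional collapse at extreme
    salinity) rather than raising.
    """
    base = records if sc_records is None else sc_records
    sc, usable, _ = _prepare(base, floor)
    sub = usable[usable["salinity_pct"] == float(salinity)]
    n_total = int((records["salinity_pct"] == float(salinity)).sum())
    n_zero = n_total - len(sub)
    out = PowerFitResult(salinity=float(salinity), sc=sc, n=len(sub), n_zero_excluded=n_zero)
    if len(sub) < 3:
        out.ok = False
        out.reason = (
            f"only {len(sub)} of {n_total} records have yield above the detection floor "
            f"at {salinity}% salinity; need >= 3 for a fit"
        )
        return out

    y = np.log10(sub["Y_O"].to_numpy())
    x = sm.add_constant(sub["covariate"].to_numpy())
    fit = sm.OLS(y, x).fit()
    out.log_y_sc, out.b = (float(v) for v in fit.params)
    out.log_y_sc_se, out.b_se = (float(v) for v in fit.bse)
    out.r2 = float(fit.rsquared)
    out.p_value = float(fit.pvalues[1])
    return out


def fit_all_salinities(records: pd.DataFrame, floor: float = 0.0) -> list:
    """Per-salinity power fits for every salinity present, sharing one Sc."""
    return [
        fit_power_per_salinity(records, s, floor=floor, sc_records=records)
        for s in sorted(records["salinity_pct"].unique())
    ]


def fit_mixed_model(records: pd.DataFrame, floor: float = 0.0) -> MixedModelResult:
    """Random-intercept mixed model across all salinities.

    Fits ``log10(Y) ~ 0 + C(salinity) + C(salinity):covariate`` with a random
    intercept per community — the replicate unit repeated across salinity
    treatments — and extracts per-salinity exponent and intercept fixed
    effects. Boundary/convergence problems are reported via the ``singular``
    flag (and a :class:`SingularFitWarning`), not an exception; with zero
    between-community variance the fixed effects coincide with the
    per-salinity OLS fits.
    """
    sc, usable, _ = _prepare(records, floor)
    levels = sorted(usable["salinity_pct"].unique())
    if len(levels) < 2:
        raise ValueError("mixed model needs >= 2 salinity levels")
    df = usable.assign(log_y=np.log10(usable["Y_O"]))

    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            "log_y ~ 0 + C(salinity_pct) + C(salinity_pct):covariate",
            data=df,
            groups=df["community_id"],
        )
        fit = model.fit(reml=True)
        if any("converge" in str(w.message).lower() or "singular" in str(w.message).lower()
               for w in caught):
            singular = True
    converged = bool(getattr(fit, "converged", True))
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    if re_var <= 1e-10:
        singular = True
    if singular:
        warnings.warn(
            "mixed-model variance estimate on or near the boundary; "
            "fixed effects reduce to the OLS fits",
            SingularFitWarning,
            stacklevel=2,
        )

    per_salinity = {}
    for s in levels:
        int_name = f"C(salinity_pct)[{s}]"
        slope_name = f"C(salinity_pct)[{s}]:covariate"
        per_salinity[s] = {
            "b": float(fit.params[slope_name]),
            "b_se": float(fit.bse[slope_name]),
            "log_y_sc": float(fit.params[int_name]),
            "log_y_sc_se": float(fit.bse[int_name]),
        }
    return MixedModelResult(
        per_salinity=per_salinity,
        random_intercept_sd=math.sqrt(max(re_var, 0.0)),
        converged=converged,
        singular=singular,
        n=len(df),
        sc=sc,
    )


def classify_exponent(b: float, tol: float = 1e-6) -> str:
    """Redundancy classification of the BEF exponent.

    ``b < 1``: function decelerates with richness — functional redundancy;
    ``b = 1`` (within ``tol``): linear, every species contributes;
    ``b > 1``: accelerating.
    """
    if not np.isfinite(b):
        raise ValueError(f"exponent must be finite (got {b})")
    if abs(b - 1.0) <= tol:
        return "linear/no redundancy"
    return "decelerating/functional redundancy" if b < 1.0 else "accelerating"


def parameter_trend(fits: list, response: str, form: str = "linear") -> TrendFit:
    """Regress a fitted parameter (``"intercept"`` or ``"exponent"``) on salinity.

    ``form="linear"`` needs >= 3 usable fits and reports the slope's p-value;
    ``form="quadratic"`` needs >= 4 and reports the quadratic coefficient's
    p-value (negative & significant = inverted-U).
    """
    if response not in ("intercept", "exponent"):
        raise ValueError(f"response must be 'intercept' or 'exponent' (got {response!r})")
    if form not in ("linear", "quadratic"):
        raise ValueError(f"form must be 'linear' or 'quadratic' (got {form!r})")
    usable = [f for f in fits if f.ok]
    needed = 3 if form == "linear" else 4
    if len(usable) < needed:
        raise ValueError(f"{form} trend needs >= {needed} usable fits, got {len(usable)}")

    x = np.array([f.salinity for f in usable])
    y = np.array([f.log_y_sc if response == "intercept" else f.b for f in usable])
    cols = [np.ones_like(x), x] + ([x ** 2] if form == "quadratic" else [])
    fit = sm.OLS(y, np.column_stack(cols)).fit()
    return TrendFit(
        response=response,
        form=form,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p_value=float(fit.pvalues[-1]),
        n=len(usable),
        slope2=float(fit.params[2]) if form == "quadratic" else None,
    )


def simulate_power_records(
    b: float,
    log_y_sc: float,
    noise_sd: float,
    rng: np.random.Generator,
    richness_levels=(5, 10, 20, 40),
    replicate_counts=(4, 8, 16, 3),
    salinity: float = 0.0,
) -> pd.DataFrame:
    """Draw yields straight from the power model, for calibration studies.

    Builds the replicate design (default: the 31-community 5/10/20/40 layout)
    and samples ``log10 Y = log_y_sc + b*(log10 S - mean log10 S) + eps`` with
    ``eps ~ Normal(0, noise_sd)``. Used for exponent-recovery and type-I-error
    simulations where the data-generating model must be exactly the fitted one.
    """
    s = np.repeat(richness_levels, replicate_counts).astype(float)
    cov = np.log10(s) - np.log10(s).mean()
    log_y = log_y_sc + b * cov + rng.normal(0.0, noise_sd, size=len(s))
    return pd.DataFrame(
        {
            "community_id": [f"R{i + 1}" for i in range(len(s))],
            "group": np.repeat(
                [chr(ord("A") + i) for i in range(len(richness_levels))], replicate_counts
            ),
            "salinity_pct": salinity,
            "richness": s.astype(int),
            "Y_O": 10.0 ** log_y,
        }
    )


def pooled_exponent_difference(fit_pairs) -> tuple:
    """Inverse-variance pooled exponent difference across replicate experiments.

    ``fit_pairs`` is an iterable of ``(fit_lo, fit_hi)`` per-salinity fit
    pairs, one per replicate experiment; returns ``(difference, se)`` for the
    pooled ``b_hi - b_lo``. A single noisy 31-community experiment rarely
    resolves an exponent contrast; pooling replicate assemblies does.
    """
    diffs, variances = [], []
    for fit_lo, fit_hi in fit_pairs:
        if not (fit_lo.ok and fit_hi.ok):
            continue
        diffs.append(fit_hi.b - fit_lo.b)
        variances.append(fit_hi.b_se**2 + fit_lo.b_se**2)
    if not diffs:
        raise ValueError("no usable fit pairs")
    w = 1.0 / np.asarray(variances)
    diff = float((w * np.asarray(diffs)).sum() / w.sum())
    return diff, float(1.0 / math.sqrt(w.sum()))


def fits_table(fits: list) -> pd.DataFrame:
    """Per-salinity fit results as the bef_fits.csv table."""
    return pd.DataFrame(
        {
            "salinity_pct": [f.salinity for f in fits],
            "b": [f.b for f in fits],
            "b_se": [f.b_se for f in fits],
            "logY_Sc": [f.log_y_sc for f in fits],
            "logY_Sc_se": [f.log_y_sc_se for f in fits],
            "Sc": [f.sc for f in fits],
            "R2": [f.r2 for f in fits],
            "p_value": [f.p_value for f in fits],
            "n": [f.n for f in fits],
            "n_zero_excluded": [f.n_zero_excluded for f in fits],
            "ok": [f.ok for f in fits],
            "reason": [f.reason or "" for f in fits],
        }
    )
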
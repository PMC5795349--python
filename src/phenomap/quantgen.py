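"""Per-day ANOVA decomposition and broad-sense heritability statistics.

For each trait and imaging day the phenotype of the plant in row i, pot j is
modeled as

    y_ij = mu + alpha_i + gamma_g(i,j) + eps_ij          (row-adjusted)
    y_ij = mu + gamma_g(i,j) + eps_ij                    (genotype-only)

where alpha is a greenhouse-row (or replicate) effect and gamma a genotype
effect.  Effects are fitted by least squares with sequential (type-I) sums
of squares, the environment term entered first.  Two heritability statistics
are derived per day:

* adjusted  HR = SS_gamma / (SS_eps + SS_gamma)   from the row-adjusted fit,
  i.e. the genotype share of the variation left after removing row effects;
* classical HR = SS_gamma / SS_total              from the genotype-only fit,
  whose denominator still contains the row-driven variation.

Genotypes without replication (ZL22 in this experiment) cannot separate
genotype from error and are excluded.  A Gaussian-kernel local mean smooths
the day-by-day HR series into a time course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MODELS = ("row+genotype", "genotype_only", "replicate+genotype")


class SingularDesignError(ValueError):
    """Raised when model terms are aliased and the SS split is undefined."""


@dataclass(frozen=True)
class HeritabilityFit:
    """Sequential sum-of-squares decomposition for one trait-day."""

    day: int
    model: str
    ss_env: float        # row or replicate SS (0 for genotype_only)
    ss_genotype: float
    ss_error: float
    n_obs: int
    n_genotypes: int
    n_dropped: int = 0   # NA rows + unreplicated-genotype rows removed

    @property
    def ss_total(self) -> float:
        return self.ss_env + self.ss_genotype + self.ss_error


def _dummies(labels: np.ndarray) -> tuple[np.ndarray, int]:
    levels, codes = np.unique(labels, return_inverse=True)
    return np.eye(len(levels))[codes][:, 1:], len(levels)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(rank)


def sequential_ss(
    y: np.ndarray, terms: list[tuple[str, np.ndarray]]
) -> dict[str, float]:
    """Type-I sums of squares for categorical terms entered in order.

    Each term is (name, label array).  Returns a dict with one SS per term
    plus ``error``.  Raises SingularDesignError when adding a term does not
    add the expected degrees of freedom (fully aliased terms).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    tiny = 1e-10 * (float(y @ y) + 1.0)  # snap fp dust to an exact zero
    X = np.ones((n, 1))
    rss_prev, rank_prev = _rss(X, y)
    out: dict[str, float] = {}
    for name, labels in terms:
        D, n_levels = _dummies(np.asarray(labels))
        X = np.hstack([X, D])
        rss_cur, rank_cur = _rss(X, y)
        if rank_cur == rank_prev and n_levels > 1:
            raise SingularDesignError(
                f"term '{name}' is aliased with preceding terms"
            )
        if rss_cur < tiny:
            rss_cur = 0.0
        out[name] = max(rss_prev - rss_cur, 0.0)
        rss_prev, rank_prev = rss_cur, rank_cur
    out["error"] = rss_prev
    return out


def _prepare(df: pd.DataFrame, value_col: str, min_reps: int = 2):
    d = df.dropna(subset=[value_col])
    n_na = len(df) - len(d)
    counts = d["genotype"].value_counts()
    keep = counts[counts >= min_reps].index
    n_unrep = int((~d["genotype"].isin(keep)).sum())
    d = d[d["genotype"].isin(keep)]
    return d, n_na + n_unrep


def anova_day(
    observations: pd.DataFrame,
    model: str = "row+genotype",
    value_col: str = "value",
    day: int | None = None,
) -> HeritabilityFit:
    """Fit one trait-day and return its sequential SS decomposition.

    ``observations`` needs columns ``genotype``, ``value_col`` and (model
    dependent) ``row`` or ``replicate``.  NA values and genotypes left with
    fewer than 2 plants (e.g. ZL22) are dropped first; the drop count is
    recorded and logged.  The environment term, when present, is entered
    before genotype.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    d, n_dropped = _prepare(observations, value_col)
    n_geno = d["genotype"].nunique()
    if n_geno < 2:
        raise ValueError("need at least 2 replicated genotypes after NA removal")
    if n_dropped:
        log.debug("anova_day dropped %d rows (NA or unreplicated)", n_dropped)
    y = d[value_col].to_numpy(dtype=float)
    terms: list[tuple[str, np.ndarray]] = []
    env = None
    if model == "row+genotype":
        env = "row"
    elif model == "replicate+genotype":
        env = "replicate"
    if env is not None:
        terms.append((env, d[env].to_numpy()))
    terms.append(("genotype", d["genotype"].to_numpy()))
    ss = sequential_ss(y, terms)
    if day is None:
        day = int(d["day"].iloc[0]) if "day" in d.columns else 0
    return HeritabilityFit(
        day=day,
        model=model,
        ss_env=ss.get(env, 0.0) if env else 0.0,
        ss_genotype=ss["genotype"],
        ss_error=ss["error"],
        n_obs=len(d),
        n_genotypes=n_geno,
        n_dropped=n_dropped,
    )


def heritability(fit: HeritabilityFit, kind: str = "adjusted") -> float:
    """Broad-sense heritability from a fitted SS decomposition.

    ``adjusted`` uses SS_genotype/(SS_error+SS_genotype) and expects an
    environment-adjusted fit; ``classical`` uses SS_genotype/SS_total from
    the genotype-only fit.  An all-zero decomposition yields NaN.
    """
    if kind == "adjusted":
        denom = fit.ss_error + fit.ss_genotype
    elif kind == "classical":
        if fit.model != "genotype_only":
            raise ValueError("classical heritability requires the genotype_only fit")
        denom = fit.ss_total
    else:
        raise ValueError("kind must be 'adjusted' or 'classical'")
    if denom == 0:
        log.warning("zero total SS on day %s; heritability undefined", fit.day)
        return float("nan")
    return fit.ss_genotype / denom


def heritability_series(
    observations: pd.DataFrame,
    value_col: str = "value",
    models: tuple[str, ...] = ("row+genotype", "genotype_only"),
) -> pd.DataFrame:
    """Per-day adjusted and classical HR for a long trait table."""
    rows = []
    for day, d in observations.groupby("day"):
        rec: dict = {"day": int(day)}
        try:
            if "row+genotype" in models:
                fit = anova_day(d, "row+genotype", value_col, day=int(day))
                rec.update(
                    hr_adjusted=heritability(fit, "adjusted"),
                    ss_row=fit.ss_env,
                    ss_genotype=fit.ss_genotype,
                    ss_error=fit.ss_error,
                    n_obs=fit.n_obs,
                )
            if "genotype_only" in models:
                fit0 = anova_day(d, "genotype_only", value_col, day=int(day))
                rec["hr_classical"] = heritability(fit0, "classical")
        except ValueError as exc:
            log.warning("day %s skipped: %s", day, exc)
            continue
        rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=["day", "hr_adjusted", "hr_classical"])
    return pd.DataFrame(rows).sort_values("day").reset_index(drop=True)


def error_heritability(
    residuals: pd.DataFrame, value_col: str = "residual"
) -> float:
    """Genotype-explained fraction of model residuals.

    Fits the replicate+genotype model to per-plant residuals (replicate =
    a sequential pair of greenhouse rows; unreplicated genotypes excluded)
    and returns SS_genotype/(SS_error+SS_genotype) — the share of the
    residual variation that is systematic by genotype rather than random.
    """
    fit = anova_day(residuals, "replicate+genotype", value_col)
    return heritability(fit, "adjusted")


def permutation_null(
    residuals: pd.DataFrame,
    value_col: str = "residual",
    n_perm: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of error_heritability under shuffled residuals."""
    rng = np.random.default_rng(seed)
    d = residuals.dropna(subset=[value_col]).reset_index(drop=True)
    vals = d[value_col].to_numpy(dtype=float)
    out = np.empty(n_perm)
    for k in range(n_perm):
        d2 = d.copy()
        d2[value_col] = rng.permutation(vals)
        out[k] = error_heritability(d2, value_col)
    return out


def smooth_heritability(
    days: np.ndarray, hr: np.ndarray, bandwidth_days: float = 2.0
) -> np.ndarray:
    """Gaussian-kernel local-mean smoothing of a day-indexed HR series.

    Weights w_i = exp(-((t - t_i)/bandwidth)^2 / 2), renormalized at every
    evaluation day, so endpoints use truncated kernels.  The output is a
    convex combination of the input and stays within its range; NaN values
    are ignored with their weight.
    """
    if bandwidth_days <= 0:
        raise ValueError("bandwidth must be positive")
    days = np.asarray(days, dtype=float)
    hr = np.asarray(hr, dtype=float)
    ok = ~np.isnan(hr)
    out = np.full_like(hr, np.nan)
    for k, t in enumerate(days):
        w = np.exp(-0.5 * ((t - days[ok]) / bandwidth_days) ** 2)
        if w.sum() > 0:
            out[k] = float(w @ hr[ok] / w.sum())
    return out
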
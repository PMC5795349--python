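"""Biomass prediction from image features and genotype error decomposition.

Fresh above-ground biomass is predicted from six image-derived features:
summed side-view plant pixels (zoom adjusted), side + top pixels, aggregate
fluorescence in the side views, aggregate fluorescence in side + top views,
and the hyperspectral stem and leaf pixel counts.  The univariate model uses
the side-view pixel sum alone; the multivariate models use all six.

Because pixel area and biomass are linked by a tissue density that differs
between genotypes (leaf-to-stem ratio, stalk density), any density-blind
predictor is systematically wrong per genotype.  The residuals of a fitted
model are therefore decomposed with a replicate+genotype ANOVA: the genotype
share of the residual sum of squares measures how much of the prediction
error is systematic genetic signal rather than random noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

from . import quantgen

FEATURES = [
    "side_pixels",
    "side_top_pixels",
    "fluor_side",
    "fluor_side_top",
    "stem_pixels",
    "leaf_pixels",
]
RESPONSE = "fresh_biomass_g"

METHODS = ("univariate_linear", "multivariate_linear", "mars", "random_forest", "svm")


class MethodUnavailableError(RuntimeError):
    """A regression backend is not installed in this environment."""


@dataclass(frozen=True)
class BiomassModelResult:
    method: str
    plants: np.ndarray
    measured: np.ndarray
    predicted: np.ndarray
    r: float  # in-sample Pearson correlation

    @property
    def residuals(self) -> np.ndarray:
        return self.measured - self.predicted

    def residual_frame(self, features: pd.DataFrame) -> pd.DataFrame:
        """Residuals joined back to genotype/replicate for decomposition."""
        d = features.set_index("plant").loc[self.plants]
        return pd.DataFrame(
            {
                "plant": self.plants,
                "genotype": d["genotype"].to_numpy(),
                "replicate": d["replicate"].to_numpy(),
                "residual": self.residuals,
            }
        )


def assemble_features(
    rgb_traits: pd.DataFrame,
    fluor_table: pd.DataFrame,
    hyper_counts: pd.DataFrame,
    biomass: pd.DataFrame,
    day: int | None = None,
) -> pd.DataFrame:
    """One row per plant with the six predictors and the biomass response.

    ``rgb_traits``: long table from rgb.build_trait_timeseries (needs
    area_adj per view); ``fluor_table``: per plant/view aggregate intensity;
    ``hyper_counts``: per plant stem/leaf pixel counts; ``biomass``: per
    plant fresh_biomass_g plus genotype/replicate.  ``day`` selects the
    (final) imaging day; default is the latest day present.  Plants missing
    a modality are flagged incomplete and excluded from model fits.
    """
    if day is None:
        day = int(rgb_traits["day"].max())
    rt = rgb_traits[rgb_traits["day"] == day]
    area = rt[rt["trait"].isin(["area_adj", "area_px"])].pivot_table(
        index="plant", columns=["trait", "view"], values="value"
    )

    def col(trait, view):
        try:
            return area[(trait, view)]
        except KeyError:
            return pd.Series(np.nan, index=area.index)

    side = col("area_adj", "side0") + col("area_adj", "side90")
    side_top = side + col("area_px", "top")  # top view has no zoom correction
    fl = fluor_table[fluor_table["day"] == day].pivot_table(
        index="plant", columns="view", values="aggregate_intensity"
    )
    fl_side = fl.get("side0", np.nan) + fl.get("side90", np.nan)
    fl_side_top = fl_side + fl.get("top", np.nan)
    hc = hyper_counts[hyper_counts["day"] == day].set_index("plant")
    out = pd.DataFrame(
        {
            "side_pixels": side,
            "side_top_pixels": side_top,
            "fluor_side": fl_side,
            "fluor_side_top": fl_side_top,
            "stem_pixels": hc["stem_pixels"],
            "leaf_pixels": hc["leaf_pixels"],
        }
    )
    meta = biomass.set_index("plant")[["genotype", "replicate", RESPONSE]]
    out = out.join(meta, how="outer").reset_index(names="plant")
    if out[RESPONSE].notna().sum() == 0:
        raise ValueError("no plants overlap between image features and biomass")
    out["complete"] = out[FEATURES + [RESPONSE]].notna().all(axis=1)
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def fit_biomass(
    features: pd.DataFrame, method: str = "univariate_linear", seed: int = 0
) -> BiomassModelResult:
    """Fit a biomass model in-sample and return predictions and residuals.

    ``univariate_linear`` regresses biomass on side_pixels only; the
    multivariate methods use all six predictors.  Stochastic backends are
    seeded.  MARS requires the optional py-earth package.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    d = features[features["complete"]] if "complete" in features else features
    d = d.dropna(subset=FEATURES[:1] + [RESPONSE])
    if len(d) < 10:
        raise ValueError("need at least 10 complete plants to fit")
    y = d[RESPONSE].to_numpy(dtype=float)
    if method == "univariate_linear":
        X = d[["side_pixels"]].to_numpy(dtype=float)
        model = LinearRegression()
    else:
        X = d[FEATURES].to_numpy(dtype=float)
        if method == "multivariate_linear":
            model = LinearRegression()
        elif method == "random_forest":
            model = RandomForestRegressor(n_estimators=200, random_state=seed)
        elif method == "svm":
            model = SVR(kernel="rbf", C=100.0, gamma="scale")
        else:  # mars
            try:
                from pyearth import Earth  # type: ignore
            except ImportError as exc:
                raise MethodUnavailableError(
                    "MARS needs the py-earth package, which is not installed; "
                    "use multivariate_linear, random_forest or svm"
                ) from exc
            model = Earth()
    model.fit(X, y)
    pred = np.asarray(model.predict(X), dtype=float)
    return BiomassModelResult(
        method=method,
        plants=d["plant"].to_numpy(),
        measured=y,
        predicted=pred,
        r=_pearson(y, pred),
    )


def genotype_error_fraction(
    result: BiomassModelResult, features: pd.DataFrame
) -> float:
    """Fraction of prediction-error variation explained by genotype.

    Residuals are decomposed with the replicate+genotype model (replicate =
    sequential row pair; unreplicated genotypes such as ZL22 excluded) and
    the genotype share SS_g/(SS_g+SS_err) is returned.  A value near the
    permutation null means random error; a large value means the model is
    systematically biased per genotype.
    """
    return quantgen.error_heritability(result.residual_frame(features))
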
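"""Geography and environment association models for chemotypes.

Accessions are first assigned to a northern or southern collection by a
piecewise latitude-by-longitude boundary approximating the Pyrenees-Alps-
Carpathians mountain chain.  A linear (ordinary least squares) model then
relates either a binary chemotype contrast (Allyl vs 2-OH-3-Butenyl,
coded 0/1 -- a linear probability model) or the side-chain carbon length
(3/4, from the MAM state) to the genomic group, five environmental
covariates and, for the pooled fit, the geography main effect and all
geography x covariate interactions.  Per-term p-values come from Type-II
partial F-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

ENV_COVARIATES = ("bio5", "bio6", "bio13", "bio14", "coast_distance")

META_COLUMNS = (
    "accession",
    "latitude",
    "longitude",
    "genomic_group",
    "bio5",
    "bio6",
    "bio13",
    "bio14",
    "coast_distance",
)


@dataclass
class Boundary:
    """Piecewise-constant boundary latitude as a function of longitude.

    ``breaks`` are the interior longitude breakpoints (ascending) and
    ``lats`` the boundary latitudes for the ``len(breaks) + 1`` longitude
    intervals.  The default puts the Pyrenees at 42.5 N (west of 2 E), the
    Alps at 45.5 N (2-18 E) and the Carpathians at 46.5 N (east of 18 E).
    ``lon_range`` marks the span the boundary was defined for; longitudes
    outside it fall back to the nearest segment with a warning.
    """

    breaks: tuple[float, ...] = (2.0, 18.0)
    lats: tuple[float, ...] = (42.5, 45.5, 46.5)
    lon_range: tuple[float, float] = (-25.0, 65.0)

    def __post_init__(self) -> None:
        if len(self.lats) != len(self.breaks) + 1:
            raise ValueError("need one more latitude than longitude breakpoints")
        if list(self.breaks) != sorted(self.breaks):
            raise ValueError("longitude breakpoints must be ascending")

    def latitude_at(self, longitude: float | np.ndarray) -> np.ndarray:
        lon = np.asarray(longitude, dtype=float)
        outside = (lon < self.lon_range[0]) | (lon > self.lon_range[1])
        if np.any(outside):
            warnings.warn(
                "longitude(s) outside the boundary's defined range; using the "
                "nearest segment"
            )
        idx = np.searchsorted(np.asarray(self.breaks), lon, side="right")
        return np.asarray(self.lats)[idx]


DEFAULT_BOUNDARY = Boundary()


def assign_region(
    meta: pd.DataFrame, boundary: Boundary | None = None
) -> pd.Series:
    """Label each accession ``south`` (strictly below the boundary) or ``north``.

    A point exactly on the boundary is labelled north.  Returns the labels
    and also stores them in a ``region`` column of ``meta`` (in place).
    """
    boundary = boundary if boundary is not None else DEFAULT_BOUNDARY
    cutoff = boundary.latitude_at(meta["longitude"].to_numpy(dtype=float))
    region = np.where(meta["latitude"].to_numpy(dtype=float) < cutoff, "south", "north")
    labels = pd.Series(region, index=meta.index, name="region")
    meta["region"] = labels
    return labels


@dataclass
class ModelReport:
    """One fitted environment-association model."""

    model_id: str
    response: str
    region_filter: str
    n: int
    terms: pd.DataFrame  # term, df, F, p
    params: pd.Series
    formula: str
    rank_deficient: bool = False
    aliased: list[str] = field(default_factory=list)
    merged_levels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.insert(0, "model_id", self.model_id)
        out.insert(1, "n", self.n)
        return out


def _merge_rare_levels(series: pd.Series, min_count: int = 2) -> tuple[pd.Series, list[str]]:
    counts = series.value_counts()
    rare = [str(level) for level, c in counts.items() if c < min_count]
    if rare:
        warnings.warn(
            f"factor level(s) with < {min_count} observations merged into 'other': {rare}"
        )
        series = series.where(~series.isin(rare), "other")
    return series, rare


def fit_region_model(
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    response: str = "chemotype_pair",
    region_filter: str = "all",
    boundary: Boundary | None = None,
) -> ModelReport:
    """Fit the chemotype/chain-length ~ environment linear model.

    Parameters
    ----------
    calls:
        Per-accession chemotype calls with at least ``accession_id``,
        ``chemotype`` and ``mam_state`` columns.
    meta:
        Accession metadata with coordinates, ``genomic_group`` and the five
        environmental covariates.  A ``region`` column is computed from the
        boundary if absent.
    response:
        ``"chemotype_pair"`` restricts to Allyl / 2-OH-3-Butenyl accessions
        and codes 2-OH-3-Butenyl as 1 (linear probability model);
        ``"chain_length"`` codes the side-chain carbon number 3/4 from the
        MAM state.
    region_filter:
        ``"north"`` or ``"south"`` fit one collection with main effects
        only; ``"all"`` fits the pooled data adding the geography main
        effect and all geography x covariate (and geography x genomic
        group) interactions.
    """
    if response not in ("chemotype_pair", "chain_length"):
        raise ValueError(f"unknown response {response!r}")
    if region_filter not in ("north", "south", "all"):
        raise ValueError(f"unknown region_filter {region_filter!r}")

    meta = meta.copy()
    if "region" not in meta.columns:
        assign_region(meta, boundary)
    data = calls.merge(
        meta, left_on="accession_id", right_on="accession", how="inner"
    )

    if response == "chemotype_pair":
        data = data[data["chemotype"].isin(["Allyl", "2-OH-3-Butenyl"])].copy()
        data["y"] = (data["chemotype"] == "2-OH-3-Butenyl").astype(float)
        coding = "2-OH-3-Butenyl=1 vs Allyl=0"
    else:
        data = data[data["mam_state"].isin(["MAM1", "MAM2"])].copy()
        data["y"] = np.where(data["mam_state"] == "MAM2", 3.0, 4.0)
        coding = "carbon chain length (MAM2=3, MAM1=4)"

    if region_filter in ("north", "south"):
        data = data[data["region"] == region_filter].copy()
    if len(data) < 10:
        raise ValueError(
            f"only {len(data)} usable accessions for response={response!r}, "
            f"region={region_filter!r}"
        )

    data["genomic_group"], merged = _merge_rare_levels(
        data["genomic_group"].astype(str)
    )

    covar_terms = list(ENV_COVARIATES)
    terms = ["C(genomic_group)"] + covar_terms
    if region_filter == "all":
        terms += ["C(region)", "C(region):C(genomic_group)"]
        terms += [f"C(region):{c}" for c in covar_terms]
    formula = "y ~ " + " + ".join(terms)

    fit = smf.ols(formula, data=data).fit()
    rank_deficient = fit.model.exog.shape[1] > np.linalg.matrix_rank(fit.model.exog)
    aliased: list[str] = []
    if rank_deficient:
        # identify aliased columns via pivoted QR on the design matrix
        X = fit.model.exog
        rank = np.linalg.matrix_rank(X)
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        names = np.asarray(fit.model.exog_names)
        aliased = [str(n) for n in names[piv[rank:]]]
        warnings.warn(f"design is rank deficient; aliased columns: {aliased}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm emits noise on 0-df terms
        table = anova_lm(fit, typ=2)
    table = table.drop(index="Residual", errors="ignore")
    terms_frame = pd.DataFrame(
        {
            "term": table.index,
            "df": table["df"].to_numpy(),
            "F": table["F"].to_numpy(),
            "p": table["PR(>F)"].to_numpy(),
        }
    ).reset_index(drop=True)

    return ModelReport(
        model_id=f"{response}_{region_filter}",
        response=coding,
        region_filter=region_filter,
        n=len(data),
        terms=terms_frame,
        params=fit.params,
        formula=formula,
        rank_deficient=rank_deficient,
        aliased=aliased,
        merged_levels=merged,
    )
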
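"""Replicated-profile statistics: heritability, adjusted means and PCA.

Measurements arrive as a long-format table with one row per
(accession, replicate, plate, compound) cell holding the amount in
micromol per gram seed.  For each compound we fit the fixed-effects linear
model

    amount ~ accession + replicate + plate

(all factors categorical) and decompose the total sum of squares
sequentially in that order (Type-I, accession first).  Broad-sense
heritability is the accession share of the total sum of squares; for a
balanced design this equals the classical between-accession eta-squared
and is insensitive to the fitting order.

Adjusted per-accession means ("emmeans") are model predictions averaged
uniformly over the observed replicate and plate levels, which corrects
accession means measured on biased plates.  PCA of the accession x
compound emmean matrix summarizes profile variation; columns are centered
and, by default, scaled to unit variance before the singular value
decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("accession", "replicate", "plate", "compound", "amount")


class MeasurementFormatError(ValueError):
    """A measurement table is structurally malformed."""


class MeasurementValidationError(ValueError):
    """A measurement table violates an invariant (negative amount, duplicate)."""


def validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise MeasurementFormatError(f"missing required column(s): {missing}")
    bad = table.index[table["amount"] < 0]
    if len(bad):
        raise MeasurementValidationError(
            f"negative amount at row(s) {list(bad[:5])}"
        )
    dup = table.duplicated(subset=["accession", "replicate", "compound"])
    if dup.any():
        first = table.loc[dup].iloc[0]
        raise MeasurementValidationError(
            "duplicate (accession, replicate, compound) key: "
            f"({first['accession']}, {first['replicate']}, {first['compound']})"
        )
    return table


def read_measurements(path: str | Path, registry=None) -> pd.DataFrame:
    """Read and validate a tidy TSV of glucosinolate measurements.

    With a :class:`~aragsl.compounds.CompoundRegistry`, compounds absent
    from the registry are flagged with a warning but retained (they may
    be long-chain or indolic compounds outside the chemotyping panel).
    """
    table = pd.read_csv(path, sep="\t")
    validate_measurements(table)
    if registry is not None:
        unknown = sorted(set(table["compound"]) - set(registry.names))
        if unknown:
            warnings.warn(f"unknown compound(s) retained: {unknown}")
    return table


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


@dataclass
class HeritabilityResult:
    """Per-compound ANOVA sum-of-squares shares.

    ``shares`` has one row per compound with columns ``h2`` (the accession
    share), ``share_accession``, ``share_replicate``, ``share_plate``,
    ``share_residual`` and ``n_obs``.  ``median_h2`` is the median of
    ``h2`` across compounds.
    """

    shares: pd.DataFrame
    median_h2: float
    skipped: list[str]


def _dummies(codes: np.ndarray) -> np.ndarray:
    n_levels = codes.max() + 1
    out = np.zeros((codes.size, n_levels))
    out[np.arange(codes.size), codes] = 1.0
    return out


def _sequential_ss(
    y: np.ndarray, acc: np.ndarray, rep: np.ndarray, plate: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Type-I sums of squares for accession, replicate, plate, residual.

    Computed by orthogonal projection: the accession factor is absorbed by
    within-accession demeaning, then replicate and plate dummy blocks are
    added sequentially (Frisch-Waugh), so the four components partition the
    total sum of squares exactly.
    """
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    # accession first: between-accession SS of the raw data
    acc_means = np.bincount(acc, weights=y) / np.bincount(acc)
    r1 = y - acc_means[acc]
    ss_acc = ss_total - float(np.sum(r1**2))

    def project_out_accession(block: np.ndarray) -> np.ndarray:
        means = (
            np.vstack([np.bincount(acc, weights=col) for col in block.T]).T
            / np.bincount(acc)[:, None]
        )
        return block - means[acc]

    r = r1
    explained = []
    basis: np.ndarray | None = None
    for codes in (rep, plate):
        block = project_out_accession(_dummies(codes))
        if basis is not None:
            coef, *_ = np.linalg.lstsq(basis, block, rcond=None)
            block = block - basis @ coef
        coef, *_ = np.linalg.lstsq(block, r, rcond=None)
        fitted = block @ coef
        explained.append(float(np.sum(fitted**2)))
        r = r - fitted
        basis = block if basis is None else np.hstack([basis, block])
    ss_rep, ss_plate = explained
    ss_resid = float(np.sum(r**2))
    return ss_total, ss_acc, ss_rep, ss_plate, ss_resid


def estimate_heritability(table: pd.DataFrame) -> HeritabilityResult:
    """Broad-sense heritability per compound from the replicated design.

    Requires at least two accessions and at least two replicates overall.
    Compounds observed in fewer than two accessions, or with zero total
    variance, are skipped with a warning.
    """
    validate_measurements(table)
    if table["accession"].nunique() < 2:
        raise MeasurementValidationError("heritability needs >= 2 accessions")
    if table["replicate"].nunique() < 2:
        raise MeasurementValidationError("heritability needs >= 2 replicates")

    rows = []
    skipped: list[str] = []
    for compound, sub in table.groupby("compound", sort=True):
        if sub["accession"].nunique() < 2:
            skipped.append(str(compound))
            warnings.warn(
                f"compound {compound!r} observed in fewer than two accessions; skipped"
            )
            continue
        y = sub["amount"].to_numpy(dtype=float)
        acc = pd.factorize(sub["accession"])[0]
        rep = pd.factorize(sub["replicate"])[0]
        plate = pd.factorize(sub["plate"])[0]
        ss_total, ss_acc, ss_rep, ss_plate, ss_resid = _sequential_ss(
            y, acc, rep, plate
        )
        if ss_total <= 0:
            skipped.append(str(compound))
            warnings.warn(f"compound {compound!r} has zero variance; skipped")
            continue
        rows.append(
            {
                "compound": compound,
                "h2": ss_acc / ss_total,
                "share_accession": ss_acc / ss_total,
                "share_replicate": ss_rep / ss_total,
                "share_plate": ss_plate / ss_total,
                "share_residual": ss_resid / ss_total,
                "n_obs": len(sub),
            }
        )
    shares = pd.DataFrame(rows)
    median = float(shares["h2"].median()) if len(shares) else float("nan")
    return HeritabilityResult(shares=shares, median_h2=median, skipped=skipped)


def compute_emmeans(table: pd.DataFrame) -> pd.DataFrame:
    """Adjusted per-accession means for every compound.

    Fits ``amount ~ accession + replicate + plate`` per compound and
    predicts each accession at the uniform average over observed replicate
    and plate levels.  For a balanced design this equals the arithmetic
    mean of the accession's measurements.  Accessions never measured for a
    compound get an adjusted mean of zero (treated as below detection) with
    a warning.

    Returns an accession x compound :class:`~pandas.DataFrame`.
    """
    validate_measurements(table)
    all_accessions = pd.Index(sorted(table["accession"].unique().tolist()))
    columns: dict[str, pd.Series] = {}
    filled_any = False
    for compound, sub in table.groupby("compound", sort=True):
        acc_codes, acc_levels = pd.factorize(sub["accession"], sort=True)
        rep_codes, _ = pd.factorize(sub["replicate"], sort=True)
        plate_codes, _ = pd.factorize(sub["plate"], sort=True)
        y = sub["amount"].to_numpy(dtype=float)
        n = len(sub)
        A = _dummies(acc_codes)
        R = _dummies(rep_codes)
        P = _dummies(plate_codes)
        X = np.hstack([np.ones((n, 1)), A[:, 1:], R[:, 1:], P[:, 1:]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        # prediction design: each accession at the uniform mean of
        # replicate and plate levels (reference level implicit)
        n_acc = A.shape[1]
        n_rep = R.shape[1]
        n_plate = P.shape[1]
        Xp = np.zeros((n_acc, X.shape[1]))
        Xp[:, 0] = 1.0
        for i in range(1, n_acc):
            Xp[i, i] = 1.0
        rep_block = slice(n_acc, n_acc + n_rep - 1)
        plate_block = slice(n_acc + n_rep - 1, n_acc + n_rep - 1 + n_plate - 1)
        Xp[:, rep_block] = 1.0 / n_rep
        Xp[:, plate_block] = 1.0 / n_plate
        emm = Xp @ beta
        series = pd.Series(emm, index=acc_levels).reindex(all_accessions)
        if series.isna().any():
            filled_any = True
            series = series.fillna(0.0)
        columns[str(compound)] = series
    if filled_any:
        warnings.warn(
            "some accessions lack measurements for some compounds; "
            "their adjusted means were set to 0 (below detection)"
        )
    out = pd.DataFrame(columns)
    out.index.name = "accession"
    return out


@dataclass
class PcaResult:
    """Scores, loadings and variance shares from an SVD-based PCA."""

    scores: pd.DataFrame  # accession x component
    loadings: pd.DataFrame  # compound x component
    variance_explained: np.ndarray  # proportion per component, sums to 1
    dropped_columns: list[str]


def run_pca(emmeans: pd.DataFrame, scale: bool = True) -> PcaResult:
    """PCA of the accession x compound matrix.

    Columns are centered; with ``scale`` they are also divided by their
    standard deviation (zero-variance columns are dropped with a warning).
    Component signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    if emmeans.shape[0] < 2 or emmeans.shape[1] < 2:
        raise ValueError("PCA needs at least 2 accessions and 2 compounds")
    if emmeans.isna().any().any():
        raise ValueError("PCA input has missing cells")
    X = emmeans.to_numpy(dtype=float)
    cols = list(emmeans.columns)
    X = X - X.mean(axis=0)
    dropped: list[str] = []
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(
                f"dropping zero-variance column(s) with scale=True: {dropped}"
            )
            X = X[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
            sd = sd[keep]
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    eig = s**2
    var_explained = eig / eig.sum()
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(U * s, index=emmeans.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=cols, columns=comp_names)
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_explained,
        dropped_columns=dropped,
    )
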
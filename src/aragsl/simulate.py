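"""Synthetic accession cohorts with known chemotype ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage is testable without any external data:

* **Accessions** carry a true enzyme-state triple (MAM, AOP, GS-OH), a
  chemotype, a MAM haplotype clade (1-8; three C3 clades, five C4), an
  AOP genomic structure (A-F) and coordinates.  Southern accessions are
  drawn with a sharp longitudinal Allyl / 2-OH-3-Butenyl partition;
  northern accessions mix all seven chemotypes.
* **Profiles** are balanced replicated measurements of 23 compounds: the
  nine canonical short-chain aliphatics whose composition is dictated by
  the chemotype (the dominant compound carries the ``dominance`` fraction
  of the short-chain pool), plus 14 long-chain/indolic fillers.  Amounts
  are log-normal with additive accession, replicate, plate and residual
  effects on the log scale; noise is calibrated so the ANOVA sum-of-squares
  heritability realizes the configured target (see ``docs/methods.md`` for
  the calibration and its replicate-count constraint).
* **Sequences** are a clade-structured gap-free alignment: one root, eight
  clade ancestors, tips mutated within clades, and a distant outgroup.
* **Environment** layers latitude/longitude-dependent covariate fields,
  a region-correlated genomic grouping, and -- when effect sizes are
  supplied -- a logistic reassignment of the Allyl / 2-OH-3-Butenyl
  contrast so association models have a known signal to recover.

All outputs are a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemotype import CHEMOTYPES
from .compounds import CANONICAL_SHORT_CHAIN, CompoundRegistry, default_registry
from .envmodels import Boundary, assign_region
from .phylo import Alignment


class ConfigurationError(ValueError):
    """A simulation parameter is outside its valid range."""


C3_CHEMOTYPES = ("3MSO", "3OHP", "Allyl")
C4_CHEMOTYPES = ("4MSO", "4OHB", "3-Butenyl", "2-OH-3-Butenyl")

#: MAM haplotype clades by chain class: three C3 clades, five C4 clades.
C3_CLADES = (1, 3, 6)
C4_CLADES = (2, 4, 5, 7, 8)

#: AOP genomic structures: A expresses AOP2; B and E express AOP3 (promoter
#: inversion / AOP2-deletion haplotypes); C, D and F are independent nulls.
STRUCTURE_TO_AOP = {
    "A": "AOP2",
    "B": "AOP3",
    "E": "AOP3",
    "C": "AOP_null",
    "D": "AOP_null",
    "F": "AOP_null",
}
AOP_TO_STRUCTURES = {
    "AOP2": ("A",),
    "AOP3": ("B", "E"),
    "AOP_null": ("C", "D", "F"),
}

DOMINANT_COMPOUND = {
    "3MSO": "3MSO",
    "4MSO": "4MSO",
    "3OHP": "3OHP",
    "4OHB": "4OHB",
    "Allyl": "Allyl",
    "3-Butenyl": "3-Butenyl",
    "2-OH-3-Butenyl": "2-OH-3-Butenyl",
}

_CHEMO_TO_MAM = {c: "MAM2" for c in C3_CHEMOTYPES} | {c: "MAM1" for c in C4_CHEMOTYPES}
_CHEMO_TO_AOP = {
    "3MSO": "AOP_null",
    "4MSO": "AOP_null",
    "3OHP": "AOP3",
    "4OHB": "AOP3",
    "Allyl": "AOP2",
    "3-Butenyl": "AOP2",
    "2-OH-3-Butenyl": "AOP2",
}

OUTGROUP_ID = "A_lyrata_outgroup"


def default_chemotype_weights() -> dict[str, float]:
    """Observed European class imbalance: 47% Allyl, 27% 2-OH-3-Butenyl,
    the remainder spread evenly over the other five chemotypes."""
    weights = {"Allyl": 0.47, "2-OH-3-Butenyl": 0.27}
    rest = (1.0 - sum(weights.values())) / 5
    for c in ("3MSO", "4MSO", "3OHP", "4OHB", "3-Butenyl"):
        weights[c] = rest
    return weights


@dataclass(frozen=True)
class GroundTruth:
    """True genotype, chemotype and location of one simulated accession."""

    accession_id: str
    mam_state: str  # MAM1 | MAM2
    mam_clade: int  # 1..8
    aop_state: str  # AOP2 | AOP3 | AOP_null
    aop_structure: str  # A..F
    gsoh_state: str  # functional | nonfunctional
    chemotype_true: str
    latitude: float
    longitude: float
    region_true: str  # north | south


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the study conditions the analyses were built for:
    797 accessions, two replicates on 17 plates, a strongly dominant
    chemotype compound (0.85 of the short-chain pool) and a median
    heritability of 0.83.
    """

    n_accessions: int = 797
    n_replicates: int = 2
    n_plates: int = 17
    dominance: float = 0.85
    heritability_target: float = 0.83
    seed: int = 0
    chemotype_weights: dict[str, float] = field(
        default_factory=default_chemotype_weights
    )
    p_south: float = 0.5
    south_lon_split: float = 5.0
    gsoh_lof_rate_masked: float = 0.147
    clade_mutation_rate: float = 0.06
    tip_mutation_rate: float = 0.008
    outgroup_rate_factor: float = 4.0
    sequence_length: int = 500
    env_effect_sizes: dict[str, float] | None = None
    env_effect_sizes_south: dict[str, float] | None = None
    total_short_chain: float = 30.0

    def __post_init__(self) -> None:
        if self.n_accessions < 0:
            raise ConfigurationError("n_accessions must be non-negative")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be at least 1")
        if self.n_plates < 1:
            raise ConfigurationError("n_plates must be at least 1")
        if not (0.5 < self.dominance <= 1.0):
            raise ConfigurationError("dominance must lie in (0.5, 1]")
        if not (0.0 <= self.heritability_target <= 1.0):
            raise ConfigurationError("heritability_target must lie in [0, 1]")
        if not (0.0 <= self.p_south <= 1.0):
            raise ConfigurationError("p_south must lie in [0, 1]")
        if not (0.0 <= self.gsoh_lof_rate_masked <= 1.0):
            raise ConfigurationError("gsoh_lof_rate_masked must lie in [0, 1]")
        for name in ("clade_mutation_rate", "tip_mutation_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 0.5):
                raise ConfigurationError(f"{name} must lie in [0, 0.5)")
        if self.outgroup_rate_factor < 3.0:
            raise ConfigurationError("outgroup_rate_factor must be at least 3")
        if self.sequence_length < 100:
            raise ConfigurationError("sequence_length must be at least 100")
        weights = self.chemotype_weights
        if set(weights) != set(CHEMOTYPES):
            raise ConfigurationError(
                "chemotype_weights must cover exactly the seven chemotypes"
            )
        if any(w < 0 for w in weights.values()) or abs(sum(weights.values()) - 1) > 1e-9:
            raise ConfigurationError("chemotype_weights must be a probability vector")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-specific generator so each operation is independently
        deterministic for a given seed."""
        return np.random.default_rng([int(self.seed), stage])


def _enforce_minimum_counts(
    labels: np.ndarray, minimum: int, classes: Sequence[str]
) -> np.ndarray:
    """Reassign from the most frequent class so each class has >= minimum."""
    labels = labels.copy()
    for cls in classes:
        while (labels == cls).sum() < minimum:
            counts = pd.Series(labels).value_counts()
            donor = counts.index[0]
            if counts.iloc[0] <= minimum:
                break  # cohort too small to guarantee coverage
            idx = np.where(labels == donor)[0][-1]
            labels[idx] = cls
    return labels


def _assign_with_coverage(
    rng: np.random.Generator,
    mask: np.ndarray,
    choices: Sequence,
    out: np.ndarray,
) -> None:
    """Fill ``out[mask]`` with random draws from ``choices``, then make sure
    each choice appears at least once when the class is large enough."""
    idx = np.where(mask)[0]
    if idx.size == 0:
        return
    draws = rng.choice(len(choices), size=idx.size)
    for pos, c in zip(idx, draws):
        out[pos] = choices[c]
    if idx.size >= len(choices):
        present = {out[i] for i in idx}
        missing = [c for c in choices if c not in present]
        counts = pd.Series([out[i] for i in idx]).value_counts()
        for c in missing:
            donor = counts.index[0]
            pos = [i for i in idx if out[i] == donor][-1]
            out[pos] = c
            counts = pd.Series([out[i] for i in idx]).value_counts()


def simulate_accessions(config: SimulationConfig) -> list[GroundTruth]:
    """Draw a cohort of accessions with consistent genotypes and geography.

    Chemotypes follow ``config.chemotype_weights``.  Accessions of the two
    major chemotypes are placed in the southern collection with probability
    ``p_south``, where Allyl sits east and 2-OH-3-Butenyl west of
    ``south_lon_split`` (the sharp Iberian/Mediterranean partition); all
    other chemotypes, and the remaining majors, go north where every
    chemotype co-occurs.  When ``n_accessions >= 50`` every clade 1-8 and
    structure A-F is guaranteed at least one carrier.
    """
    n = config.n_accessions
    if n == 0:
        return []
    rng = config.rng(1)
    labels = list(CHEMOTYPES)
    probs = np.array([config.chemotype_weights[c] for c in labels])
    chemotypes = np.asarray(rng.choice(labels, size=n, p=probs), dtype=object)
    if n >= 50:
        # guarantee clade/structure coverage without fabricating chemotypes
        # the configured mixture excludes
        possible = [c for c, p in zip(labels, probs) if p > 0]
        chemotypes = _enforce_minimum_counts(chemotypes, 2, possible)

    mam = np.array([_CHEMO_TO_MAM[c] for c in chemotypes], dtype=object)
    aop = np.array([_CHEMO_TO_AOP[c] for c in chemotypes], dtype=object)

    clades = np.zeros(n, dtype=int)
    _assign_with_coverage(rng, mam == "MAM2", C3_CLADES, clades)
    _assign_with_coverage(rng, mam == "MAM1", C4_CLADES, clades)

    structures = np.empty(n, dtype=object)
    for state, opts in AOP_TO_STRUCTURES.items():
        _assign_with_coverage(rng, aop == state, opts, structures)

    gsoh = np.empty(n, dtype=object)
    for i, c in enumerate(chemotypes):
        if c == "2-OH-3-Butenyl":
            gsoh[i] = "functional"
        elif c == "3-Butenyl":
            gsoh[i] = "nonfunctional"
        else:  # phenotypically masked: LOF alleles drift at a higher rate
            gsoh[i] = (
                "nonfunctional"
                if rng.random() < config.gsoh_lof_rate_masked
                else "functional"
            )

    lat = np.empty(n)
    lon = np.empty(n)
    for i, c in enumerate(chemotypes):
        south = c in ("Allyl", "2-OH-3-Butenyl") and rng.random() < config.p_south
        if south:
            lat[i] = rng.uniform(36.5, 41.5)
            if c == "Allyl":
                lon[i] = rng.uniform(config.south_lon_split, 26.0)
            else:
                lon[i] = rng.uniform(-9.5, config.south_lon_split)
        else:
            lat[i] = rng.uniform(47.0, 61.0)
            lon[i] = rng.uniform(-5.0, 30.0)

    frame = pd.DataFrame({"latitude": lat, "longitude": lon})
    region = assign_region(frame, Boundary())

    return [
        GroundTruth(
            accession_id=f"acc{i:04d}",
            mam_state=str(mam[i]),
            mam_clade=int(clades[i]),
            aop_state=str(aop[i]),
            aop_structure=str(structures[i]),
            gsoh_state=str(gsoh[i]),
            chemotype_true=str(chemotypes[i]),
            latitude=float(lat[i]),
            longitude=float(lon[i]),
            region_true=str(region.iloc[i]),
        )
        for i in range(n)
    ]


def chemotype_composition(chemotype: str, dominance: float) -> dict[str, float]:
    """Expected short-chain composition: the chemotype's dominant compound
    carries ``dominance`` of the pool, the other eight share the rest."""
    dominant = DOMINANT_COMPOUND[chemotype]
    rest = (1.0 - dominance) / (len(CANONICAL_SHORT_CHAIN) - 1)
    return {
        c: (dominance if c == dominant else rest) for c in CANONICAL_SHORT_CHAIN
    }


def _eta_squared_noise_ratio(t: float, n_acc: int, n_rep: int) -> float:
    """Within/between variance ratio so the sum-of-squares heritability
    realizes ``t``.

    With ``a`` accessions and ``r`` replicates, the expected accession and
    total sums of squares are (a-1)(sw2 + r sg2) and (ar-1)(sg2 + sw2), so
    targeting their ratio at ``t`` gives
    sw2/sg2 = ((a-1) r - (ar-1) t) / ((ar-1) t - (a-1)).
    The achievable range is ((a-1)/(ar-1), 1]: below it the target is
    unreachable at this replicate count (the estimator's null expectation
    is the lower bound) and a configuration error is raised.
    """
    a, r = n_acc, n_rep
    big_n = a * r
    if t >= 1.0:
        return 0.0
    lower = (a - 1) / (big_n - 1)
    denom = (big_n - 1) * t - (a - 1)
    if denom <= 0:
        raise ConfigurationError(
            f"heritability_target={t} is below the estimator's lower bound "
            f"{lower:.3f} for {a} accessions x {r} replicates; "
            "increase n_replicates"
        )
    return max(((a - 1) * r - (big_n - 1) * t) / denom, 0.0)


def simulate_profiles(
    truth: Sequence[GroundTruth],
    config: SimulationConfig,
    registry: CompoundRegistry | None = None,
) -> pd.DataFrame:
    """Balanced replicated measurement table for a cohort.

    Log-amounts are genetic value + replicate + plate + residual effects.
    Genetic values of the nine short-chain compounds encode the chemotype
    composition (times a per-accession size effect); filler compounds get
    independent per-accession effects.  Noise is scaled per compound so
    the realized sum-of-squares heritability matches
    ``config.heritability_target`` (exactly zero noise at a target of 1).
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    registry = registry if registry is not None else default_registry(include_fillers=True)
    rng = config.rng(2)
    n_a = len(truth)
    n_rep = config.n_replicates
    n_plates = config.n_plates
    compounds = registry.names
    short = [c for c in compounds if registry[c].is_short_chain_aliphatic]
    fillers = [c for c in compounds if not registry[c].is_short_chain_aliphatic]

    # per-accession genetic values on the log scale
    alpha = rng.normal(0.0, 0.25, size=n_a)
    filler_mu = {c: rng.normal(np.log(2.0), 0.6) for c in fillers}
    G = np.zeros((n_a, len(compounds)))
    col = {c: j for j, c in enumerate(compounds)}
    for i, acc in enumerate(truth):
        comp = chemotype_composition(acc.chemotype_true, config.dominance)
        for c in short:
            G[i, col[c]] = np.log(config.total_short_chain * comp[c]) + alpha[i]
    for c in fillers:
        G[:, col[c]] = filler_mu[c] + alpha + rng.normal(0.0, 0.35, size=n_a)

    # per-compound noise calibration
    t = config.heritability_target
    sw2 = np.zeros(len(compounds))
    if n_a >= 2:
        ratio = _eta_squared_noise_ratio(t, n_a, n_rep) if n_rep >= 2 else 0.0
        var_g = G.var(axis=0, ddof=1)
        for c in fillers:
            # heritability is estimated on the raw (lognormal) scale, so the
            # within/between variance ratio must hold for exp-transformed
            # values: Var(e^eps) / Var(e^g) = ratio gives, for normal g,
            # sw2 = log(1 + ratio * (1 - exp(-sg2)))
            sg2 = var_g[col[c]]
            sw2[col[c]] = np.log1p(ratio * -np.expm1(-sg2))
        for c in short:
            # modest fixed-CV noise floor, scaled to zero as the target
            # approaches 1; the chemotype compounds keep their (large)
            # compositional genetic variance, so their realized
            # heritability runs above the target (see docs/methods.md)
            sw2[col[c]] = 0.078 * ratio
    sigma_rep = np.sqrt(0.02 * sw2)
    sigma_plate = np.sqrt(0.15 * sw2)
    sigma_resid = np.sqrt(0.83 * sw2)

    rep_effect = rng.normal(0.0, 1.0, size=(n_rep, len(compounds))) * sigma_rep
    plate_effect = rng.normal(0.0, 1.0, size=(n_plates, len(compounds))) * sigma_plate
    plate_of = rng.integers(0, n_plates, size=(n_a, n_rep))

    rows = []
    for i, acc in enumerate(truth):
        for r in range(n_rep):
            p = plate_of[i, r]
            eps = rng.normal(0.0, 1.0, size=len(compounds)) * sigma_resid
            amounts = np.exp(G[i] + rep_effect[r] + plate_effect[p] + eps)
            rows.append((acc.accession_id, f"rep{r + 1}", f"plate{p + 1:02d}", amounts))
    table = pd.DataFrame(
        {
            "accession": np.repeat([r[0] for r in rows], len(compounds)),
            "replicate": np.repeat([r[1] for r in rows], len(compounds)),
            "plate": np.repeat([r[2] for r in rows], len(compounds)),
            "compound": np.tile(compounds, len(rows)),
            "amount": np.concatenate([r[3] for r in rows]),
        }
    )
    return table


def _mutate(
    rng: np.random.Generator, codes: np.ndarray, rate: float
) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    if mask.any():
        out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out


def simulate_sequences(
    truth: Sequence[GroundTruth],
    config: SimulationConfig,
    outgroup_id: str = OUTGROUP_ID,
) -> Alignment:
    """Clade-structured gap-free alignment with a distant outgroup.

    One root sequence; eight clade ancestors mutated from it at
    ``clade_mutation_rate``; each accession's tip mutated from its clade's
    ancestor at ``tip_mutation_rate``; the outgroup mutated from the root
    at ``outgroup_rate_factor`` times the clade rate (capped at 0.45).
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = config.rng(3)
    L = config.sequence_length
    bases = np.array(list("ACGT"))
    root = rng.integers(0, 4, size=L)
    ancestors = {
        clade: _mutate(rng, root, config.clade_mutation_rate)
        for clade in sorted(C3_CLADES + C4_CLADES)
    }
    outgroup_rate = min(config.outgroup_rate_factor * config.clade_mutation_rate, 0.45)
    sequences: dict[str, str] = {
        outgroup_id: "".join(bases[_mutate(rng, root, outgroup_rate)])
    }
    for acc in truth:
        tip = _mutate(rng, ancestors[acc.mam_clade], config.tip_mutation_rate)
        sequences[acc.accession_id] = "".join(bases[tip])
    return Alignment(sequences, outgroup_id)


GENOMIC_GROUPS = ("admixed", "central_europe", "germany", "iberia", "italy_balkan", "relict")
_GROUP_PROBS_NORTH = np.array([0.20, 0.28, 0.24, 0.08, 0.12, 0.08])
_GROUP_PROBS_SOUTH = np.array([0.10, 0.08, 0.06, 0.38, 0.30, 0.08])


def simulate_environment(
    truth: Sequence[GroundTruth],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Per-accession metadata, optionally injecting environmental effects.

    The five covariates are smooth latitude/longitude fields plus noise;
    the genomic group is a categorical correlated with region.  When
    ``config.env_effect_sizes`` is given (a mapping of covariate name to
    logistic slope per standard deviation), the Allyl / 2-OH-3-Butenyl
    contrast is *re-drawn* for major-chemotype accessions from a logistic
    model on the standardized covariates (``env_effect_sizes_south``, if
    set, replaces the slopes for southern accessions), and the returned
    truth records are updated consistently.  With all slopes zero this
    makes the contrast independent of geography -- the null case for
    association-model calibration.

    Returns ``(meta, truth)`` where ``meta`` has one row per accession and
    ``truth`` reflects any re-drawn chemotypes.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = config.rng(4)
    n = len(truth)
    lat = np.array([a.latitude for a in truth])
    lon = np.array([a.longitude for a in truth])

    # smooth continental gradients plus substantial local variation
    # (topography, rain shadows), which keeps the five layers from being
    # collinear once latitude/longitude trends are shared
    bio5 = 21.0 + 0.60 * (46.0 - lat) + 0.15 * lon + rng.normal(0, 2.5, n)
    bio6 = 2.0 - 0.50 * (lat - 40.0) - 0.12 * lon + rng.normal(0, 2.5, n)
    bio13 = 78.0 + 0.9 * (48.0 - lat) + 0.5 * np.abs(lon - 8.0) + rng.normal(0, 14.0, n)
    bio14 = np.clip(38.0 - 1.1 * (46.0 - lat) + rng.normal(0, 9.0, n), 0.0, None)
    coast = np.clip(
        10.0 * np.abs(lon - 8.0) + 9.0 * (lat - 36.0) + rng.normal(0, 70.0, n), 0.0, None
    )

    meta = pd.DataFrame(
        {
            "accession": [a.accession_id for a in truth],
            "latitude": lat,
            "longitude": lon,
            "bio5": bio5,
            "bio6": bio6,
            "bio13": bio13,
            "bio14": bio14,
            "coast_distance": coast,
        }
    )
    assign_region(meta)
    groups = np.empty(n, dtype=object)
    for i in range(n):
        probs = (
            _GROUP_PROBS_SOUTH if meta["region"].iloc[i] == "south" else _GROUP_PROBS_NORTH
        )
        groups[i] = GENOMIC_GROUPS[rng.choice(len(GENOMIC_GROUPS), p=probs)]
    meta["genomic_group"] = groups

    new_truth = list(truth)
    if config.env_effect_sizes is not None:
        covars = {
            "bio5": bio5,
            "bio6": bio6,
            "bio13": bio13,
            "bio14": bio14,
            "coast_distance": coast,
        }
        z = {k: (v - v.mean()) / v.std(ddof=0) for k, v in covars.items()}
        base_logit = np.log(0.27 / 0.47)  # cohort-level 2-OH-3-Butenyl : Allyl odds
        for i, acc in enumerate(truth):
            if acc.chemotype_true not in ("Allyl", "2-OH-3-Butenyl"):
                continue
            slopes = config.env_effect_sizes
            if (
                config.env_effect_sizes_south is not None
                and meta["region"].iloc[i] == "south"
            ):
                slopes = config.env_effect_sizes_south
            lp = base_logit + sum(b * z[k][i] for k, b in slopes.items())
            p_oh = 1.0 / (1.0 + np.exp(-lp))
            chemo = "2-OH-3-Butenyl" if rng.random() < p_oh else "Allyl"
            if chemo != acc.chemotype_true:
                mam = _CHEMO_TO_MAM[chemo]
                clade_pool = C3_CLADES if mam == "MAM2" else C4_CLADES
                new_truth[i] = replace(
                    acc,
                    chemotype_true=chemo,
                    mam_state=mam,
                    mam_clade=int(rng.choice(clade_pool)),
                    aop_state="AOP2",
                    aop_structure="A",
                    gsoh_state=(
                        "functional" if chemo == "2-OH-3-Butenyl" else "nonfunctional"
                    ),
                )
    return meta, new_truth


@dataclass
class SimulatedDataset:
    truth: list[GroundTruth]
    meta: pd.DataFrame
    measurements: pd.DataFrame
    alignment: Alignment
    registry: CompoundRegistry


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all four generators in their natural order."""
    truth = simulate_accessions(config)
    meta, truth = simulate_environment(truth, config)
    registry = default_registry(include_fillers=True)
    measurements = simulate_profiles(truth, config, registry)
    alignment = simulate_sequences(truth, config)
    return SimulatedDataset(truth, meta, measurements, alignment, registry)


def truth_to_frame(truth: Sequence[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truth])


def calls_from_truth(truth: Sequence[GroundTruth]) -> pd.DataFrame:
    """Chemotype-call table straight from ground truth (no measurement
    noise); useful for isolating downstream stages in simulations."""
    return pd.DataFrame(
        {
            "accession_id": [t.accession_id for t in truth],
            "chemotype": [t.chemotype_true for t in truth],
            "mam_state": [t.mam_state for t in truth],
            "aop_state": [t.aop_state for t in truth],
            "gsoh_state": [t.gsoh_state for t in truth],
        }
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write truth/measurements/metadata as TSV and the alignment as FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_to_frame(dataset.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    dataset.measurements.to_csv(outdir / "measurements.tsv", sep="\t", index=False)
    dataset.meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    dataset.alignment.write_fasta(outdir / "alignment.fasta")
    dataset.registry.write_tsv(outdir / "compounds.tsv")
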
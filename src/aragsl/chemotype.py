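"""Enzyme-state calling and seven-way chemotype assignment.

An accession's seed glucosinolate profile is reduced to the functional
state of three loci and then to a single discrete chemotype label:

* **MAM (GS-Elong)** -- compare the summed C3 vs C4 short-chain aliphatic
  amounts; a C3 majority indicates MAM2, a C4 majority MAM1.
* **AOP (GS-AOP)** -- compare the alkenyl, hydroxyalkyl ("alkyl") and MSO
  fractions of the total short-chain aliphatic pool; the strictly largest
  fraction names the expressed enzyme (AOP2, AOP3) or the null state.
* **GS-OH** -- only scoreable in MAM1/AOP2 accessions, which accumulate the
  3-Butenyl substrate; elsewhere the locus is phenotypically *masked* by
  functional epistasis.  Where scoreable, a 2-OH-3-Butenyl majority over the
  two butenyls indicates a functional enzyme.

The (MAM, AOP, GS-OH) triple maps onto seven chemotypes::

    MAM2, AOP null            -> 3MSO
    MAM1, AOP null            -> 4MSO
    MAM2, AOP3                -> 3OHP
    MAM1, AOP3                -> 4OHB
    MAM2, AOP2                -> Allyl
    MAM1, AOP2, GS-OH nonfunc -> 3-Butenyl
    MAM1, AOP2, GS-OH func    -> 2-OH-3-Butenyl

"Majority" is read as a strict maximum; exact ties (and profiles below the
detection floor) are refused as ``undetermined`` rather than guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .compounds import (
    ALKENYL_COMPOUNDS,
    ALKYL_COMPOUNDS,
    C3_COMPOUNDS,
    C4_COMPOUNDS,
    MSO_COMPOUNDS,
    CompoundRegistry,
    default_registry,
    total,
)

UNDETERMINED = "undetermined"
CHEMOTYPES = (
    "3MSO",
    "4MSO",
    "3OHP",
    "4OHB",
    "Allyl",
    "3-Butenyl",
    "2-OH-3-Butenyl",
)


class MamCall(NamedTuple):
    c3_total: float
    c4_total: float
    mam_state: str  # MAM1 | MAM2 | undetermined


class AopCall(NamedTuple):
    alkenyl_ratio: float
    alkyl_ratio: float
    mso_ratio: float
    aop_state: str  # AOP2 | AOP3 | AOP_null | undetermined
    mt_dominated: bool


@dataclass
class ChemotypeCall:
    """Full per-accession record: totals, ratios, enzyme states, chemotype."""

    accession_id: str
    c3_total: float
    c4_total: float
    alkenyl_ratio: float
    alkyl_ratio: float
    mso_ratio: float
    butenyl_oh_ratio: float | None
    mam_state: str
    aop_state: str
    gsoh_state: str  # functional | nonfunctional | masked | undetermined
    chemotype: str


def _short_chain_registry(registry: CompoundRegistry | None) -> CompoundRegistry:
    return registry if registry is not None else default_registry()


def call_mam(
    profile: Mapping[str, float],
    registry: CompoundRegistry | None = None,
    floor: float = 0.0,
) -> MamCall:
    """Call the GS-Elong (MAM) state from C3 vs C4 short-chain totals.

    Compounds absent from ``profile`` count as zero.  The call is
    ``undetermined`` when both chain totals are at or below ``floor`` or
    when the totals tie exactly.
    """
    registry = _short_chain_registry(registry)
    c3 = total(profile, [c for c in registry.short_chain if registry[c].chain_length == 3])
    c4 = total(profile, [c for c in registry.short_chain if registry[c].chain_length == 4])
    if c3 <= floor and c4 <= floor:
        state = UNDETERMINED
    elif c3 > c4:
        state = "MAM2"
    elif c4 > c3:
        state = "MAM1"
    else:
        state = UNDETERMINED
    return MamCall(c3, c4, state)


def call_aop(
    profile: Mapping[str, float],
    registry: CompoundRegistry | None = None,
) -> AopCall:
    """Call the GS-AOP state from side-chain modification ratios.

    All three ratios share the total short-chain aliphatic pool as the
    denominator.  MT compounds appear only in the denominator, so the three
    ratios may sum to less than one; a profile whose short-chain pool is
    mostly MT is still called by the strict argmax but flagged
    ``mt_dominated``.
    """
    registry = _short_chain_registry(registry)
    denom = total(profile, registry.short_chain)
    if denom <= 0:
        return AopCall(0.0, 0.0, 0.0, UNDETERMINED, False)
    alkenyl = total(profile, ALKENYL_COMPOUNDS) / denom
    alkyl = total(profile, ALKYL_COMPOUNDS) / denom
    mso = total(profile, MSO_COMPOUNDS) / denom
    mt_dominated = (alkenyl + alkyl + mso) < 0.5
    ratios = {"AOP2": alkenyl, "AOP3": alkyl, "AOP_null": mso}
    best = max(ratios.values())
    winners = [s for s, r in ratios.items() if r == best]
    state = winners[0] if len(winners) == 1 else UNDETERMINED
    if mt_dominated and state != UNDETERMINED:
        warnings.warn(
            "AOP call on an MT-dominated profile: modification ratios sum to "
            f"{alkenyl + alkyl + mso:.3f}",
            stacklevel=2,
        )
    return AopCall(alkenyl, alkyl, mso, state, mt_dominated)


def call_gsoh(
    profile: Mapping[str, float],
    mam_state: str,
    aop_state: str,
    threshold: float = 0.5,
) -> tuple[str, float | None]:
    """Call the GS-OH state; returns ``(state, butenyl_oh_ratio)``.

    The locus is scoreable only in MAM1/AOP2 accessions (3-Butenyl
    producers); in any other background it is ``masked`` and the ratio is
    ``None``.  Where scoreable, the hydroxylated fraction
    ``2-OH-3-Butenyl / (2-OH-3-Butenyl + 3-Butenyl)`` above ``threshold``
    indicates a functional enzyme.
    """
    if not (mam_state == "MAM1" and aop_state == "AOP2"):
        return "masked", None
    oh = float(profile.get("2-OH-3-Butenyl", 0.0))
    but = float(profile.get("3-Butenyl", 0.0))
    if oh + but <= 0:
        warnings.warn(
            "MAM1/AOP2 accession with no butenyl glucosinolates: "
            "GS-OH state undetermined",
            stacklevel=2,
        )
        return UNDETERMINED, None
    ratio = oh / (oh + but)
    return ("functional" if ratio > threshold else "nonfunctional"), ratio


_CHEMOTYPE_MAP = {
    ("MAM2", "AOP_null"): "3MSO",
    ("MAM1", "AOP_null"): "4MSO",
    ("MAM2", "AOP3"): "3OHP",
    ("MAM1", "AOP3"): "4OHB",
    ("MAM2", "AOP2"): "Allyl",
}


def classify_chemotype(mam_state: str, aop_state: str, gsoh_state: str) -> str:
    """Map an enzyme-state triple to one of the seven chemotype labels.

    Any undetermined input propagates to an ``undetermined`` chemotype.
    """
    if mam_state == UNDETERMINED or aop_state == UNDETERMINED:
        return UNDETERMINED
    if (mam_state, aop_state) in _CHEMOTYPE_MAP:
        return _CHEMOTYPE_MAP[(mam_state, aop_state)]
    if (mam_state, aop_state) == ("MAM1", "AOP2"):
        if gsoh_state == "functional":
            return "2-OH-3-Butenyl"
        if gsoh_state == "nonfunctional":
            return "3-Butenyl"
        return UNDETERMINED
    raise ValueError(f"unrecognized enzyme states ({mam_state!r}, {aop_state!r})")


def call_accession(
    accession_id: str,
    profile: Mapping[str, float],
    registry: CompoundRegistry | None = None,
    gsoh_threshold: float = 0.5,
    floor: float = 0.0,
) -> ChemotypeCall:
    """Run the full MAM -> AOP -> GS-OH -> chemotype cascade on one profile."""
    registry = _short_chain_registry(registry)
    mam = call_mam(profile, registry, floor=floor)
    aop = call_aop(profile, registry)
    gsoh_state, oh_ratio = call_gsoh(
        profile, mam.mam_state, aop.aop_state, threshold=gsoh_threshold
    )
    chemotype = classify_chemotype(mam.mam_state, aop.aop_state, gsoh_state)
    return ChemotypeCall(
        accession_id=accession_id,
        c3_total=mam.c3_total,
        c4_total=mam.c4_total,
        alkenyl_ratio=aop.alkenyl_ratio,
        alkyl_ratio=aop.alkyl_ratio,
        mso_ratio=aop.mso_ratio,
        butenyl_oh_ratio=oh_ratio,
        mam_state=mam.mam_state,
        aop_state=aop.aop_state,
        gsoh_state=gsoh_state,
        chemotype=chemotype,
    )


def classify_all(
    emmeans: pd.DataFrame,
    registry: CompoundRegistry | None = None,
    gsoh_threshold: float = 0.5,
    floor: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every accession of an accession x compound matrix.

    Parameters
    ----------
    emmeans:
        Adjusted per-accession means, accessions as index, compounds as
        columns (the output of :func:`aragsl.profiles.compute_emmeans`).

    Returns
    -------
    calls, frequencies:
        ``calls`` holds one row per accession with all intermediate
        quantities; ``frequencies`` tabulates chemotype counts with
        percentages both of classified accessions and of all accessions.
    """
    registry = _short_chain_registry(registry)
    records = []
    for accession, row in emmeans.iterrows():
        call = call_accession(
            str(accession),
            row.to_dict(),
            registry,
            gsoh_threshold=gsoh_threshold,
            floor=floor,
        )
        records.append(vars(call))
    calls = pd.DataFrame.from_records(records)
    freq = chemotype_frequencies(calls["chemotype"])
    return calls, freq


def chemotype_frequencies(labels: Iterable[str]) -> pd.DataFrame:
    """Count chemotype labels; percentages over classified and over all."""
    series = pd.Series(list(labels), dtype="object")
    counts = series.value_counts()
    n_total = int(series.size)
    n_classified = int((series != UNDETERMINED).sum())
    order = [c for c in CHEMOTYPES if c in counts.index]
    if UNDETERMINED in counts.index:
        order.append(UNDETERMINED)
    counts = counts.reindex(order)
    out = pd.DataFrame({"chemotype": counts.index, "count": counts.values})
    out["pct_classified"] = [
        100.0 * c / n_classified if (ch != UNDETERMINED and n_classified) else float("nan")
        for ch, c in zip(out["chemotype"], out["count"])
    ]
    out["pct_total"] = 100.0 * out["count"] / n_total if n_total else float("nan")
    return out.reset_index(drop=True)


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
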
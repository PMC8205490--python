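"""Epistasis-conditioned loss-of-function frequency analysis for *GS-OH*.

GS-OH activity is only phenotypically visible in accessions that make its
substrate, 3-Butenyl glucosinolate -- the C4-alkenyl chemotypes
(3-Butenyl and 2-OH-3-Butenyl).  In every other background the locus is
cryptic, so loss-of-function (LOF) alleles can drift without phenotypic
cost.  This module partitions a classified cohort into the phenotypically
*expressed* (C4-alkenyl) and *masked* (everything else) sets, computes
per-mutation-class carrier fractions in each set, and tests whether LOF
carriers are enriched in the masked set with a one-sided Fisher exact
test.

Fractions are kept as exact rationals and rounded half-away-from-zero to
three decimals for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

C4_ALKENYL_CHEMOTYPES = ("3-Butenyl", "2-OH-3-Butenyl")


def round_half_away(value: Fraction | float, digits: int = 3) -> float:
    """Round half away from zero, as display tables conventionally do."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-digits)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


def partition_by_epistasis(calls: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Split classified accessions into (expressed, masked) sets.

    ``expressed`` holds the C4-alkenyl accessions (chemotype 3-Butenyl or
    2-OH-3-Butenyl), whose GS-OH state is phenotypically readable;
    ``masked`` holds every other *classified* accession.  Undetermined
    accessions belong to neither set.
    """
    chemo = calls.set_index("accession_id")["chemotype"]
    expressed = set(chemo.index[chemo.isin(C4_ALKENYL_CHEMOTYPES)].astype(str))
    masked = set(
        chemo.index[
            ~chemo.isin(C4_ALKENYL_CHEMOTYPES) & (chemo != "undetermined")
        ].astype(str)
    )
    return expressed, masked


@dataclass
class LofClassCounts:
    """Carrier counts for one mutation class in the two epistasis sets.

    ``carriers_masked`` may be ``None`` when the masked carriers of a class
    could not be ascertained (e.g. lesions unresolvable from sequence).
    """

    mutation_class: str
    carriers_expressed: int
    carriers_masked: int | None


def count_carriers(
    carriers: pd.DataFrame,
    expressed: set[str],
    masked: set[str],
) -> list[LofClassCounts]:
    """Aggregate a per-accession carrier table (columns ``mutation_class``,
    ``accession``) into per-class counts for the two sets."""
    required = {"mutation_class", "accession"}
    if not required.issubset(carriers.columns):
        raise ValueError(f"carrier table needs columns {sorted(required)}")
    out = []
    for cls, sub in carriers.groupby("mutation_class", sort=True):
        ids = set(sub["accession"].astype(str))
        out.append(
            LofClassCounts(
                mutation_class=str(cls),
                carriers_expressed=len(ids & expressed),
                carriers_masked=len(ids & masked),
            )
        )
    return out


def compute_lof_frequencies(
    counts: Iterable[LofClassCounts | Mapping],
    n_expressed: int,
    n_masked: int,
) -> pd.DataFrame:
    """Carrier fractions per mutation class in the expressed and masked sets.

    ``fraction`` is carriers over the C4-alkenyl (expressed) denominator;
    ``observed_frequency`` is carriers over the masked denominator.  Both
    are reported rounded half-away-from-zero to three decimals alongside
    the exact rationals.  A zero denominator or unknown carrier count
    yields a flagged undefined entry rather than NaN propagation.
    """
    if n_expressed < 0 or n_masked < 0:
        raise ValueError("set sizes must be non-negative")
    rows = []
    for item in counts:
        if isinstance(item, Mapping):
            item = LofClassCounts(**item)
        if item.carriers_expressed > n_expressed:
            raise ValueError(
                f"{item.mutation_class}: carriers exceed the expressed set size"
            )
        if item.carriers_masked is not None and item.carriers_masked > n_masked:
            raise ValueError(
                f"{item.mutation_class}: carriers exceed the masked set size"
            )
        row: dict = {"mutation_class": item.mutation_class}
        if n_expressed > 0:
            frac = Fraction(item.carriers_expressed, n_expressed)
            row.update(
                fraction=round_half_away(frac),
                fraction_exact=frac,
                fraction_display=(
                    f"{round_half_away(frac):.3f} "
                    f"({item.carriers_expressed}/{n_expressed})"
                ),
            )
        else:
            row.update(fraction=None, fraction_exact=None, fraction_display="undefined")
        if item.carriers_masked is None or n_masked <= 0:
            row.update(
                observed_frequency=None,
                observed_frequency_exact=None,
                observed_frequency_display="Unknown",
            )
        else:
            freq = Fraction(item.carriers_masked, n_masked)
            row.update(
                observed_frequency=round_half_away(freq),
                observed_frequency_exact=freq,
                observed_frequency_display=(
                    f"{round_half_away(freq):.3f} ({item.carriers_masked}/{n_masked})"
                ),
            )
        row.update(
            carriers_expressed=item.carriers_expressed,
            n_expressed=n_expressed,
            carriers_masked=item.carriers_masked,
            n_masked=n_masked,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def test_enrichment(lof_table: pd.DataFrame) -> pd.DataFrame:
    """One-sided Fisher exact tests for LOF enrichment in the masked set.

    For each mutation class with known masked carriers, and for the pooled
    counts over those classes, tests the alternative that LOF carriers are
    *more* frequent among masked accessions than among expressed ones.
    Reports the conditional-MLE odds ratio.  Degenerate margins (an empty
    set or no carriers anywhere) give p = 1 with a note.
    """
    usable = lof_table[lof_table["carriers_masked"].notna()]
    rows = []

    def one_test(name: str, cm: int, nm: int, ce: int, ne: int) -> dict:
        table = [[cm, nm - cm], [ce, ne - ce]]
        note = ""
        if min(nm, ne) == 0 or (cm + ce) == 0 or (cm + ce) == (nm + ne):
            p, oddsratio = 1.0, float("nan")
            note = "degenerate margins"
        else:
            res = stats.fisher_exact(table, alternative="greater")
            p = float(res.pvalue)
            oddsratio = float(
                stats.contingency.odds_ratio(table, kind="conditional").statistic
            )
        return {
            "mutation_class": name,
            "carriers_masked": cm,
            "n_masked": nm,
            "carriers_expressed": ce,
            "n_expressed": ne,
            "odds_ratio": oddsratio,
            "p_value": p,
            "note": note,
        }

    for row in usable.itertuples(index=False):
        rows.append(
            one_test(
                row.mutation_class,
                int(row.carriers_masked),
                int(row.n_masked),
                int(row.carriers_expressed),
                int(row.n_expressed),
            )
        )
    if len(usable):
        rows.append(
            one_test(
                "pooled",
                int(usable["carriers_masked"].sum()),
                int(usable["n_masked"].iloc[0]),
                int(usable["carriers_expressed"].sum()),
                int(usable["n_expressed"].iloc[0]),
            )
        )
    return pd.DataFrame(rows)
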
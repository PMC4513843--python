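"""Per-variant activity statistics for ribozyme sequencing assays.

The assay's activity statistic is the fraction cleaved,

    f = cleaved / (cleaved + uncleaved),

computed per variant and condition from classified read counts.  For
ligand-dependent aptazymes, activation is summarized by the on/off ratio
f(+ligand) / f(-ligand) and a phenotype gate (+ligand activity above a
threshold AND at least a threshold-fold activation) picks out functional
switches.  Ratios use a Jeffreys-style pseudo-count, f~ = (c + 0.5)/(c + u + 1),
so that a variant with zero cleaved reads in the -ligand pool still yields a
finite fold change; reported fractions themselves are never smoothed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data.IUPACData import ambiguous_dna_values

from .classify import ReadCall, Tally
from .designs import LibraryDesign, Status, enumerate_variants


@dataclass(frozen=True)
class GateCriteria:
    """Phenotype gate for ligand-activated aptazymes.

    ``f_plus_min``: minimum fraction cleaved with ligand (default 0.30);
    ``ratio_min``: minimum on/off fold activation (default 3.0).  Both
    inequalities are strict.
    """

    f_plus_min: float = 0.30
    ratio_min: float = 3.0

    def __post_init__(self):
        if self.f_plus_min <= 0 or self.ratio_min <= 0:
            raise ValueError("gate criteria must be strictly positive")


@dataclass(frozen=True)
class FitResult:
    """Ordinary least-squares fit of one activity profile against another."""

    slope: float
    intercept: float
    r_squared: float


@dataclass
class CountTable:
    """Cleaved/uncleaved read tallies per (library, condition, variant).

    ``counts`` covers the full enumerated variant space of every design
    (zero-filled), so absent variants are explicit.  ``rejects`` tallies
    AMBIGUOUS and UNASSIGNED reads by reason.
    """

    counts: pd.DataFrame  # columns: library, condition, variant, cleaved, uncleaved
    rejects: pd.DataFrame  # columns: library, condition, reason, count
    total_reads: int

    @property
    def assigned_reads(self) -> int:
        return int(self.counts[["cleaved", "uncleaved"]].to_numpy().sum())

    @property
    def rejected_reads(self) -> int:
        return int(self.rejects["count"].sum()) if len(self.rejects) else 0

    def cell(self, library: str, condition: str, variant: str) -> tuple[int, int]:
        sel = self.counts[
            (self.counts["library"] == library)
            & (self.counts["condition"] == condition)
            & (self.counts["variant"] == variant)
        ]
        if sel.empty:
            raise KeyError((library, condition, variant))
        row = sel.iloc[0]
        return int(row["cleaved"]), int(row["uncleaved"])


def tabulate(
    calls: Iterable[ReadCall],
    designs: Sequence[LibraryDesign],
) -> CountTable:
    """Aggregate a classified read stream into a :class:`CountTable`.

    Every CLEAVED/UNCLEAVED call increments exactly one cell; AMBIGUOUS and
    UNASSIGNED calls go to the reject tallies.  A call naming a library that
    is not registered raises ValueError.
    """
    by_name = {d.name: d for d in designs}
    cells: dict[tuple[str, str, str], list[int]] = {}
    for d in designs:
        for cond in d.conditions:
            for v in enumerate_variants(d):
                cells[(d.name, cond, v)] = [0, 0]
    rejects: dict[tuple[str, str, str], int] = {}
    total = 0
    for call in calls:
        total += 1
        if call.assigned:
            if call.library not in by_name:
                raise ValueError(f"call references unknown library {call.library!r}")
            key = (call.library, call.condition, call.variant)
            if key not in cells:
                raise ValueError(f"call references unknown cell {key}")
            cells[key][0 if call.status is Status.CLEAVED else 1] += 1
        else:
            rkey = (call.library, call.condition, call.reject_reason)
            rejects[rkey] = rejects.get(rkey, 0) + 1
    counts = pd.DataFrame(
        [(lib, cond, v, c, u) for (lib, cond, v), (c, u) in cells.items()],
        columns=["library", "condition", "variant", "cleaved", "uncleaved"],
    )
    rej = pd.DataFrame(
        [(lib, cond, r, n) for (lib, cond, r), n in sorted(rejects.items())],
        columns=["library", "condition", "reason", "count"],
    )
    return CountTable(counts=counts, rejects=rej, total_reads=total)


def fraction_cleaved(cleaved: int, uncleaved: int) -> float:
    """cleaved / (cleaved + uncleaved); NaN (never an exception) at zero depth."""
    depth = cleaved + uncleaved
    if depth <= 0:
        return math.nan
    return cleaved / depth


def _smoothed_fraction(cleaved: float, uncleaved: float) -> float:
    return (cleaved + 0.5) / (cleaved + uncleaved + 1.0)


def activation_ratio(
    counts_minus: tuple[int, int], counts_plus: tuple[int, int]
) -> float:
    """On/off fold activation from (cleaved, uncleaved) counts per condition.

    Uses pseudo-counted fractions f~ = (c + 0.5)/(c + u + 1) in both
    conditions so the ratio is finite and positive whenever both depths are
    positive; returns NaN if either condition has zero depth.
    """
    c_m, u_m = counts_minus
    c_p, u_p = counts_plus
    if c_m + u_m <= 0 or c_p + u_p <= 0:
        return math.nan
    return _smoothed_fraction(c_p, u_p) / _smoothed_fraction(c_m, u_m)


def phenotype_gate(
    f_minus: float,
    f_plus: float,
    ratio: float,
    criteria: GateCriteria | None = None,
) -> bool:
    """True iff f_plus > f_plus_min and ratio > ratio_min (strict)."""
    criteria = criteria or GateCriteria()
    return bool(f_plus > criteria.f_plus_min and ratio > criteria.ratio_min)


def build_profile(
    table: CountTable,
    condition_minus: str = "minus",
    condition_plus: str = "plus",
    criteria: GateCriteria | None = None,
    min_depth: int = 50,
) -> pd.DataFrame:
    """Per-variant activity profile from a two-condition count table.

    Returns a DataFrame with one row per (library, variant): raw fractions
    and depths per condition, the pseudo-counted on/off ratio, the phenotype
    gate verdict, and a ``low_depth`` flag marking (not removing) variants
    with fewer than ``min_depth`` assigned reads in either condition.
    """
    criteria = criteria or GateCriteria()
    wide = table.counts.pivot_table(
        index=["library", "variant"],
        columns="condition",
        values=["cleaved", "uncleaved"],
        aggfunc="sum",
        fill_value=0,
    )
    rows = []
    for (lib, variant), row in wide.iterrows():
        c_m = int(row.get(("cleaved", condition_minus), 0))
        u_m = int(row.get(("uncleaved", condition_minus), 0))
        c_p = int(row.get(("cleaved", condition_plus), 0))
        u_p = int(row.get(("uncleaved", condition_plus), 0))
        f_m = fraction_cleaved(c_m, u_m)
        f_p = fraction_cleaved(c_p, u_p)
        ratio = activation_ratio((c_m, u_m), (c_p, u_p))
        gate = (
            phenotype_gate(f_m, f_p, ratio, criteria)
            if not (math.isnan(f_p) or math.isnan(ratio))
            else False
        )
        rows.append(
            {
                "library": lib,
                "variant": variant,
                "f_minus": f_m,
                "f_plus": f_p,
                "depth_minus": c_m + u_m,
                "depth_plus": c_p + u_p,
                "ratio": ratio,
                "gate": gate,
                "low_depth": (c_m + u_m) < min_depth or (c_p + u_p) < min_depth,
            }
        )
    return pd.DataFrame(rows).sort_values(["library", "variant"]).reset_index(drop=True)


def rank_variants(
    profile: "pd.DataFrame | Mapping[str, float]",
    condition: str = "plus",
) -> list[str]:
    """Variants sorted by descending fraction cleaved in one condition.

    Ties are broken lexicographically by variant string.  Accepts either a
    profile DataFrame (uses column ``f_<condition>``) or a plain mapping
    variant -> fraction.
    """
    if isinstance(profile, pd.DataFrame):
        col = f"f_{condition}"
        if col not in profile.columns:
            raise KeyError(f"profile has no column {col!r}")
        pairs = list(zip(profile["variant"], profile[col]))
    else:
        pairs = list(profile.items())
    return [v for v, _ in sorted(pairs, key=lambda p: (-p[1], p[0]))]


_IUPAC_SETS = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


def match_pattern(variants: Iterable[str], pattern: str) -> list[str]:
    """Variants matching an IUPAC pattern position-wise (U and T equivalent)."""
    pattern = pattern.upper()
    sets = []
    for letter in pattern:
        try:
            sets.append(_IUPAC_SETS[letter.replace("U", "T")])
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {letter!r} in pattern") from None
    out = []
    for v in variants:
        if len(v) != len(pattern):
            raise ValueError(
                f"variant {v!r} length {len(v)} != pattern length {len(pattern)}"
            )
        if all(b.replace("U", "T") in s for b, s in zip(v.upper(), sets)):
            out.append(v)
    return out


def hamming_distance(a: str, b: str) -> int:
    """Number of differing positions between equal-length variant strings."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def compare_profiles(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS of y on x plus squared Pearson correlation, on raw fractions.

    Requires >= 3 paired finite values.  Zero variance in x yields an
    undefined (NaN) fit rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-d inputs with at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.allclose(x, x[0]):
        return FitResult(math.nan, math.nan, math.nan)
    fit = stats.linregress(x, y)
    return FitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def write_profile_tsv(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False)


def write_counts_tsv(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index=False)


def write_tally_tsv(tally: Tally, path) -> None:
    pd.Series(tally.as_dict()).rename_axis("category").rename("reads").to_frame().to_csv(
        path, sep="\t"
    )
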
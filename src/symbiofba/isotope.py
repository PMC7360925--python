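"""¹³C isotopologue enrichment from LC-MS peak areas.

An isotopologue table holds peak areas A₀…A_k for the mass isotopologues
M+0…M+k of one compound in one sample.  For a fully ¹³C-labeled dietary
tracer, unlabeled (M+0) material indexes de-novo biosynthesis while labeled
material indexes dietary uptake, so the labeled/unlabeled ratio falls when
biosynthesis rises.  Two ratio conventions are supported because partially
labeled isotopologues (M+1…M+5 for histidine) carry real signal:

* ``all-labeled`` (default): Σ_{k≥1} A_k / A₀
* ``m6-only``: A_k_max / A₀ (only the fully labeled species counts)

No natural-abundance correction is applied by default; a correction-matrix
hook exists for callers who need one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .phenostats import GroupSummary, TestResult, pooled_t_summary

RatioMode = Literal["all-labeled", "m6-only"]


@dataclass(frozen=True)
class IsotopologueTable:
    """Peak areas for M+0…M+k of one compound in one sample."""

    compound: str
    sample: str
    group: str
    fraction_kind: Literal["soluble", "protein"]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "areas", tuple(float(a) for a in self.areas))
        if len(self.areas) < 2:
            raise ValidationError(
                f"{self.compound}/{self.sample}: need areas for at least M+0 and M+1"
            )
        if any(a < 0 for a in self.areas):
            raise ValidationError(f"{self.compound}/{self.sample}: negative peak area")
        if not any(a > 0 for a in self.areas):
            raise ValidationError(f"{self.compound}/{self.sample}: all peak areas are zero")

    @property
    def k_max(self) -> int:
        return len(self.areas) - 1


@dataclass(frozen=True)
class EnrichmentResult:
    ratio_13C_12C: float
    fractions: tuple[float, ...]
    mode: RatioMode


def isotopologue_fractions(table: IsotopologueTable) -> tuple[float, ...]:
    """Relative proportion of each isotopologue: A_k / ΣA."""
    total = sum(table.areas)
    return tuple(a / total for a in table.areas)


def label_ratio(table: IsotopologueTable, mode: RatioMode = "all-labeled") -> float:
    """Labeled/unlabeled ratio for one table.

    Raises on A₀ = 0 (the ratio is infinite; use fractions instead).
    """
    a0 = table.areas[0]
    if a0 == 0:
        raise ValidationError(
            f"{table.compound}/{table.sample}: M+0 area is zero, the "
            "labeled/unlabeled ratio is infinite — compare isotopologue "
            "fractions instead"
        )
    if mode == "all-labeled":
        return sum(table.areas[1:]) / a0
    if mode == "m6-only":
        return table.areas[-1] / a0
    raise ValueError(f"unknown ratio mode {mode!r}")


def enrichment(table: IsotopologueTable, mode: RatioMode = "all-labeled") -> EnrichmentResult:
    return EnrichmentResult(
        ratio_13C_12C=label_ratio(table, mode),
        fractions=isotopologue_fractions(table),
        mode=mode,
    )


def apply_correction(table: IsotopologueTable, matrix: np.ndarray) -> IsotopologueTable:
    """Optional natural-abundance correction hook (disabled by default).

    ``matrix`` is the (k+1)×(k+1) correction matrix mapping measured to
    corrected areas; negative corrected areas are clipped to zero.
    """
    areas = np.asarray(table.areas)
    if matrix.shape != (len(areas), len(areas)):
        raise ValidationError(
            f"correction matrix shape {matrix.shape} does not match "
            f"{len(areas)} isotopologues"
        )
    corrected = np.clip(np.linalg.solve(matrix, areas), 0.0, None)
    return IsotopologueTable(
        compound=table.compound,
        sample=table.sample,
        group=table.group,
        fraction_kind=table.fraction_kind,
        areas=tuple(corrected),
    )


# ---------------------------------------------------------------------------
# group summaries


@dataclass(frozen=True)
class EnrichmentComparison:
    """Two-group comparison of label ratios within one fraction kind."""

    fraction_kind: str
    groups: dict[str, GroupSummary]
    test: TestResult
    alpha: float


def summarize_enrichment(
    tables: Iterable[IsotopologueTable],
    mode: RatioMode = "all-labeled",
) -> list[EnrichmentComparison]:
    """Per-(group, fraction) label-ratio summaries plus two-group t tests.

    Exactly two groups are required (a paired line design, e.g. a symbiont
    carrier and its cured counterpart); each group needs ≥ 2 replicates.
    When both the soluble and protein fractions are present, the critical
    probability is Bonferroni-adjusted to α = 0.025 for the two tests.
    """
    tables = list(tables)
    groups = sorted({t.group for t in tables})
    if len(groups) != 2:
        raise ValidationError(
            f"expected exactly 2 groups for a pairwise design, got {groups}"
        )
    kinds = sorted({t.fraction_kind for t in tables})
    alpha = 0.05 / len(kinds)

    out: list[EnrichmentComparison] = []
    for kind in kinds:
        summaries: dict[str, GroupSummary] = {}
        for g in groups:
            ratios = [
                label_ratio(t, mode)
                for t in tables
                if t.group == g and t.fraction_kind == kind
            ]
            if len(ratios) < 2:
                raise ValidationError(
                    f"group {g!r}, fraction {kind!r}: need >= 2 replicates to "
                    f"estimate a standard error, got {len(ratios)}"
                )
            arr = np.asarray(ratios)
            summaries[g] = GroupSummary(
                mean=float(arr.mean()),
                se=float(arr.std(ddof=1) / np.sqrt(len(arr))),
                n=len(arr),
            )
        test = pooled_t_summary(summaries[groups[0]], summaries[groups[1]])
        out.append(
            EnrichmentComparison(
                fraction_kind=kind, groups=summaries, test=test, alpha=alpha
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV I/O


def read_isotopologue_tsv(path: str | Path) -> list[IsotopologueTable]:
    """Read tables from a TSV with columns
    ``compound, sample, group, fraction_kind, M0..Mk``."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["compound", "sample", "group", "fraction_kind"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    area_cols = [c for c in df.columns if c not in meta_cols]
    area_cols.sort(key=lambda c: int(c.lstrip("M")))
    return [
        IsotopologueTable(
            compound=row["compound"],
            sample=row["sample"],
            group=row["group"],
            fraction_kind=row["fraction_kind"],
            areas=tuple(float(row[c]) for c in area_cols),
        )
        for _, row in df.iterrows()
    ]


def write_isotopologue_tsv(tables: Sequence[IsotopologueTable], path: str | Path) -> None:
    k = max(t.k_max for t in tables)
    rows = []
    for t in tables:
        rec = {
            "compound": t.compound,
            "sample": t.sample,
            "group": t.group,
            "fraction_kind": t.fraction_kind,
        }
        for i in range(k + 1):
            rec[f"M{i}"] = t.areas[i] if i <= t.k_max else 0.0
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
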
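"""Biomass-ratio sweep: histidine flux and AICAR overflow vs symbiont load.

The central in-silico experiment of the package: starting from the
facultative-symbiont-free two-compartment community (obligate symbiont +
host), add the facultative symbiont at a series of biomass ratios and record

* flux through the terminal histidine biosynthesis reaction (HisD), the
  index of total histidine production, and
* net AICAR export from the producing organism into the shared pool
  ("overflow"), the by-product signature of histidine overproduction.

Because histidine biosynthesis co-produces AICAR 1:1 and the producer
consumes AICAR only up to its purine requirement, overflow appears exactly
when total community histidine demand exceeds that requirement.

Also here: the conversions between cell-number ratios (what microscopy/qPCR
measures) and biomass ratios (what the model is parameterized by), linked
through a per-cell mass factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .community import CommunityModel, CommunitySpec, assemble_community, set_biomass_ratio
from .errors import ConfigurationError
from .fba import FluxSolution, solve_pfba

#: numeric stand-in for a zero baseline when reporting fold changes
FOLD_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# ratio string handling


def parse_ratio(label: str) -> float:
    """Parse a ``B:H`` ratio string into r = grams H per gram B.

    ``"10:1" → 0.1``, ``"1:5" → 5.0``; decimals allowed on either side.
    """
    try:
        a_txt, b_txt = label.split(":")
        a, b = float(a_txt), float(b_txt)
    except ValueError as exc:
        raise ValueError(f"ratio {label!r} is not of the form 'a:b'") from exc
    if a <= 0 or b <= 0:
        raise ValueError(f"ratio components must be positive, got {label!r}")
    return b / a


def format_ratio(r: float, sig: int = 2) -> str:
    """Render r (H per B) as a normalized ``x:1`` or ``1:x`` label."""
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    if r <= 1.0:
        return f"{_round_sig(1.0 / r, sig):g}:1"
    return f"1:{_round_sig(r, sig):g}"


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# readouts


def hisd_flux(
    community: CommunityModel,
    solution: FluxSolution,
    reaction: str = "HisD",
    organism: str | None = None,
) -> float:
    """Flux through the (tagged) HisD reaction in ``organism`` (default:
    the community's reference organism)."""
    solution.require_optimal()
    org = organism or community.reference
    rid = community.reaction_of(reaction, org)
    return solution.fluxes[rid]


def aicar_overflow(
    community: CommunityModel,
    solution: FluxSolution,
    metabolite: str = "aicar",
    organism: str | None = None,
    clip: bool = False,
) -> float:
    """Net AICAR flux out of the producing organism into the shared pool.

    Positive = export (overflow).  The raw signed value is returned by
    default; ``clip=True`` floors it at 0 for reporting, matching the
    convention that overflow is a nonnegative quantity.
    """
    solution.require_optimal()
    org = organism or community.reference
    tid = community.pool_transports.get((org, metabolite))
    if tid is None:
        raise ConfigurationError(
            f"no pool transport for metabolite {metabolite!r} in organism "
            f"{org!r}; expected a reaction 'TP_{metabolite}__{org}'"
        )
    raw = solution.fluxes[tid]
    return max(0.0, raw) if clip else raw


# ---------------------------------------------------------------------------
# the sweep


@dataclass(frozen=True)
class RatioPoint:
    """One solved community at one biomass ratio (r = 0 is the baseline)."""

    ratio_label: str
    r: float
    hisd_flux: float
    aicar_overflow: float
    status: str = "optimal"


@dataclass(frozen=True)
class SweepResult:
    baseline: RatioPoint
    points: tuple[RatioPoint, ...]
    pct_hisd_increase: tuple[float, ...]
    overflow_fold: tuple[float, ...]

    def rows(self) -> list[dict]:
        """Flat table (baseline first) for TSV/DataFrame output."""
        out = [
            {
                "ratio": self.baseline.ratio_label,
                "r": self.baseline.r,
                "hisd_flux": self.baseline.hisd_flux,
                "aicar_overflow": self.baseline.aicar_overflow,
                "pct_hisd_increase": 0.0,
                "overflow_fold": 1.0,
                "status": self.baseline.status,
            }
        ]
        for p, pct, fold in zip(self.points, self.pct_hisd_increase, self.overflow_fold):
            out.append(
                {
                    "ratio": p.ratio_label,
                    "r": p.r,
                    "hisd_flux": p.hisd_flux,
                    "aicar_overflow": p.aicar_overflow,
                    "pct_hisd_increase": pct,
                    "overflow_fold": fold,
                    "status": p.status,
                }
            )
        return out


#: sweep grid covering the studied range endpoints (10:1 … 1:5) and the
#: empirically calibrated ratio 6.7:1
DEFAULT_RATIOS = ("10:1", "6.7:1", "5:1", "2:1", "1:1", "1:2", "1:5")


def run_ratio_sweep(
    spec: CommunitySpec,
    ratios: Sequence[str] = DEFAULT_RATIOS,
    vary: str | None = None,
    hisd_reaction: str = "HisD",
    aicar_metabolite: str = "aicar",
) -> SweepResult:
    """Solve the community across a grid of biomass ratios.

    ``vary`` names the facultative symbiont being swept (default: the first
    non-reference symbiont).  The baseline is the community with that
    organism removed entirely (not r → 0, which the coupling convention
    forbids).  Each point is solved by pFBA; infeasible points are flagged
    in their ``status`` and carry NaN readouts, and the sweep continues.
    """
    if vary is None:
        others = [m.id for m, _ in spec.symbionts if m.id != spec.reference_id]
        if not others:
            raise ConfigurationError("no non-reference symbiont to sweep")
        vary = others[0]

    base_spec = spec.without(vary)
    base_comm = assemble_community(base_spec)
    base_sol = solve_pfba(base_comm, objective={})
    base_sol.require_optimal()
    base_hisd = hisd_flux(base_comm, base_sol, reaction=hisd_reaction)
    base_over = aicar_overflow(base_comm, base_sol, metabolite=aicar_metabolite, clip=True)
    baseline = RatioPoint(
        ratio_label="baseline", r=0.0, hisd_flux=base_hisd, aicar_overflow=base_over
    )

    r_values = sorted((parse_ratio(label), label) for label in ratios)
    community = assemble_community(spec)
    points: list[RatioPoint] = []
    for r, label in r_values:
        community = set_biomass_ratio(community, vary, r)
        sol = solve_pfba(community, objective={})
        if sol.status != "optimal":
            points.append(
                RatioPoint(
                    ratio_label=label, r=r, hisd_flux=float("nan"),
                    aicar_overflow=float("nan"), status=sol.status,
                )
            )
            continue
        points.append(
            RatioPoint(
                ratio_label=label,
                r=r,
                hisd_flux=hisd_flux(community, sol, reaction=hisd_reaction),
                aicar_overflow=aicar_overflow(
                    community, sol, metabolite=aicar_metabolite, clip=True
                ),
            )
        )

    pct = tuple(
        100.0 * (p.hisd_flux - base_hisd) / base_hisd if p.status == "optimal" else float("nan")
        for p in points
    )
    denom = max(base_over, FOLD_FLOOR)
    fold = tuple(
        p.aicar_overflow / denom if p.status == "optimal" else float("nan")
        for p in points
    )
    return SweepResult(
        baseline=baseline, points=tuple(points),
        pct_hisd_increase=pct, overflow_fold=fold,
    )


def write_sweep_tsv(result: SweepResult, path) -> None:
    import pandas as pd

    pd.DataFrame(result.rows()).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell-number ↔ biomass ratio conversions


def _as_pair(ratio: str | tuple[float, float]) -> tuple[float, float]:
    if isinstance(ratio, str):
        a_txt, b_txt = ratio.split(":")
        pair = (float(a_txt), float(b_txt))
    else:
        pair = (float(ratio[0]), float(ratio[1]))
    if pair[0] <= 0 or pair[1] <= 0:
        raise ValueError(f"ratio components must be positive, got {ratio!r}")
    return pair


def calibrate_per_cell_mass(
    biomass_ratio: str | tuple[float, float],
    cell_ratio: str | tuple[float, float],
) -> float:
    """Per-cell mass factor (grams per B cell / grams per H cell) from one
    matched biomass-ratio / cell-number-ratio pair.

    If biomass B:H = mB:mH corresponds to cell numbers cB:cH, then
    ``factor = (cH/cB) / (mH/mB)``.  E.g. biomass 1:5 matching cells 1:130
    gives factor 26: each B cell outweighs an H cell 26-fold.
    """
    mB, mH = _as_pair(biomass_ratio)
    cB, cH = _as_pair(cell_ratio)
    return (cH / cB) / (mH / mB)


def cells_to_biomass(
    cell_ratio: str | tuple[float, float],
    factor: float,
    sig: int = 2,
) -> tuple[float, str]:
    """Convert a cell-number ratio B:H into a biomass ratio using the
    per-cell mass factor.

    Returns ``(biomass_B_per_H, label)`` where the label is normalized to
    ``x:1`` or ``1:x`` at ``sig`` significant figures.  Cells 1:3.9 with
    factor 26 → (6.67, "6.7:1").
    """
    if factor <= 0:
        raise ValueError(f"per-cell mass factor must be positive, got {factor}")
    cB, cH = _as_pair(cell_ratio)
    biomass_b_per_h = (cB * factor) / cH
    # format_ratio takes r = H per B
    return biomass_b_per_h, format_ratio(1.0 / biomass_b_per_h, sig=sig)
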
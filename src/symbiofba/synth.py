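"""Synthetic inputs: the analytic toy symbiosis and data generators.

The toy symbiosis condenses the histidine→AICAR→purine coupling into the
smallest network that reproduces its logic:

* the obligate symbiont (Buchnera) makes histidine from a pooled precursor
  via a lumped terminal reaction (HisD) that co-produces AICAR 1:1, can
  consume AICAR only into a fixed purine demand ``a``, and exports
  histidine to the shared pool;
* the host drains a fixed histidine demand ``h_A`` from the pool and soaks
  up any AICAR overflow in a free accumulation sink;
* the facultative symbiont (Hamiltonella) is a histidine auxotroph: pure
  uptake plus a fixed per-gram demand ``h_H``, no synthesis.

At steady state the community therefore obeys, exactly,

    v_his(r)    = max(a, h_A + b + r·h_H)
    overflow(r) = max(0, h_A + b + r·h_H − a)

for facultative biomass ratio r (grams per gram of the obligate symbiont)
and optional producer self-use ``b``.  These closed forms are returned next
to the models and serve as the analytic oracle for the whole LP stack.

Default parameters are calibrated to the two anchors of the study system:
zero AICAR overflow without the facultative symbiont (a = h_A), and a
+0.8% histidine-flux increase at the empirically observed biomass ratio
6.7:1 (h_H = 0.0536, since 0.0536/6.7 ≈ 0.8% of 1.0).  Away from those
anchors the toy's numbers are its own, not a genome-scale model's.

All other generators (random feasible networks, isotopologue tables,
metabolomics matrices, performance samples) are pure functions of their
parameters and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .community import CommunitySpec
from .core import Medium, Metabolite, OrganismModel, Reaction, ReactionKind
from .errors import ValidationError
from .isotope import IsotopologueTable


@dataclass(frozen=True)
class ToyParams:
    """Coupling constants of the toy symbiosis (mmol·gDW_B⁻¹·h⁻¹).

    ``h_A``: host histidine demand; ``a``: producer AICAR consumption into
    purines; ``h_H``: facultative symbiont per-gram histidine demand;
    ``b``: producer self histidine use; ``uptake_cap``: pool precursor
    uptake limit.
    """

    h_A: float = 1.0
    a: float = 1.0
    h_H: float = 0.0536
    b: float = 0.0
    uptake_cap: float = 10.0

    def __post_init__(self) -> None:
        for name in ("h_A", "a", "h_H", "b", "uptake_cap"):
            if getattr(self, name) < 0:
                raise ValidationError(f"toy parameter {name} must be >= 0")


@dataclass(frozen=True)
class ToySymbiosis:
    host: OrganismModel
    buchnera: OrganismModel
    hamiltonella: OrganismModel
    params: ToyParams
    v_his: Callable[[float], float]
    overflow: Callable[[float], float]

    def spec(self, r_hamiltonella: float | None = None) -> CommunitySpec:
        """A ready-to-assemble community spec; ``None`` omits the
        facultative symbiont (the two-compartment baseline)."""
        symbionts: list[tuple[OrganismModel, float]] = [(self.buchnera, 1.0)]
        if r_hamiltonella is not None:
            if not r_hamiltonella > 0:
                raise ValidationError(
                    "r must be > 0; omit the organism for the baseline "
                    "(pass r_hamiltonella=None)"
                )
            symbionts.append((self.hamiltonella, r_hamiltonella))
        return CommunitySpec(
            host=self.host,
            symbionts=symbionts,
            medium=Medium({"prpp": self.params.uptake_cap}),
            reference=self.buchnera.id,
        )


def make_toy_symbiosis(params: ToyParams = ToyParams()) -> ToySymbiosis:
    """Build the three toy organism models plus their analytic flux curves."""
    p = params

    buchnera = OrganismModel.from_parts(
        id="Buchnera",
        metabolites=[
            Metabolite("prpp", name="phosphoribosyl pyrophosphate", transportable=True),
            Metabolite("his", name="histidine", transportable=True),
            Metabolite("aicar", name="AICAR", transportable=True),
            Metabolite("pur", name="purine"),
        ],
        reactions=[
            # lumped terminal histidine synthesis; AICAR is the 1:1 by-product
            Reaction("HisD", {"prpp": -1.0, "his": 1.0, "aicar": 1.0}, lb=0.0, ub=1000.0),
            # purine synthesis exists only from AICAR (de novo pathway deleted)
            Reaction("PurSyn", {"aicar": -1.0, "pur": 1.0}, lb=0.0, ub=1000.0),
            Reaction("DM_pur", {"pur": -1.0}, lb=p.a, ub=p.a, kind=ReactionKind.DEMAND),
            Reaction("DM_his_self", {"his": -1.0}, lb=p.b, ub=p.b, kind=ReactionKind.DEMAND),
        ],
    )

    hamiltonella = OrganismModel.from_parts(
        id="Hamiltonella",
        metabolites=[Metabolite("his", name="histidine", transportable=True)],
        # auxotroph: demand without any synthesis route
        reactions=[
            Reaction("DM_his", {"his": -1.0}, lb=p.h_H, ub=p.h_H, kind=ReactionKind.DEMAND),
        ],
    )

    host = OrganismModel.from_parts(
        id="host",
        metabolites=[
            Metabolite("his", name="histidine", transportable=True),
            Metabolite("aicar", name="AICAR", transportable=True),
        ],
        reactions=[
            Reaction("DM_his", {"his": -1.0}, lb=p.h_A, ub=p.h_A, kind=ReactionKind.DEMAND),
            # free accumulation sink: overflow AICAR ends up in host tissue
            Reaction("SINK_aicar", {"aicar": -1.0}, lb=0.0, ub=1000.0, kind=ReactionKind.DEMAND),
        ],
    )

    def v_his(r: float) -> float:
        return max(p.a, p.h_A + p.b + r * p.h_H)

    def overflow(r: float) -> float:
        return max(0.0, p.h_A + p.b + r * p.h_H - p.a)

    return ToySymbiosis(
        host=host, buchnera=buchnera, hamiltonella=hamiltonella,
        params=p, v_his=v_his, overflow=overflow,
    )


def random_network(seed: int, n_mets: int = 5, n_rxns: int = 6) -> OrganismModel:
    """A connected, feasible-by-construction random network.

    A source→chain→sink backbone guarantees a flux-carrying path (uptake
    exchange, conversions, a small pinned demand); any remaining reaction
    budget is spent on random internal conversions that can rest at zero.
    """
    if n_mets < 1 or n_rxns < 1:
        raise ValidationError("need n_mets >= 1 and n_rxns >= 1")
    rng = np.random.default_rng(seed)
    mets = [Metabolite(f"m{i}", transportable=(i == 0)) for i in range(n_mets)]
    rxns: list[Reaction] = [
        Reaction("EX_m0", {"m0": -1.0}, lb=-10.0, ub=10.0, kind=ReactionKind.EXCHANGE)
    ]
    chain_len = min(n_mets - 1, max(0, n_rxns - 2))
    for i in range(chain_len):
        rxns.append(Reaction(f"conv{i}", {f"m{i}": -1.0, f"m{i + 1}": 1.0}, lb=0.0, ub=10.0))
    end = f"m{chain_len}"
    demand = round(float(rng.uniform(0.1, 1.0)), 6)
    if len(rxns) < n_rxns:
        rxns.append(
            Reaction(f"DM_{end}", {end: -1.0}, lb=demand, ub=demand, kind=ReactionKind.DEMAND)
        )
    while len(rxns) < n_rxns:
        i, j = rng.integers(0, n_mets, size=2)
        rid = f"rand{len(rxns)}"
        if i == j:
            rxns.append(Reaction(rid, {f"m{i}": -1.0}, lb=0.0, ub=10.0, kind=ReactionKind.DEMAND))
        else:
            rxns.append(Reaction(rid, {f"m{i}": -1.0, f"m{j}": 1.0}, lb=0.0, ub=10.0))
    return OrganismModel.from_parts(id=f"random_{seed}", metabolites=mets, reactions=rxns[:n_rxns])


def gen_isotopologue_tables(
    true_fractions: Sequence[float],
    cv: float = 0.1,
    n_samples: int = 3,
    seed: int = 0,
    compound: str = "histidine",
    group: str = "line_A",
    fraction_kind: str = "soluble",
    total_area: float = 1e6,
) -> list[IsotopologueTable]:
    """Noisy isotopologue tables around known true fractions.

    Each area is ``total_area × fraction × LogNormal`` with unit median and
    coefficient of variation ``cv`` — multiplicative noise because peak
    areas are positive and right-skewed.  ``cv = 0`` reproduces the true
    fractions exactly.
    """
    fr = np.asarray(true_fractions, dtype=float)
    if fr.ndim != 1 or fr.size < 2:
        raise ValidationError("need fractions for at least M+0 and M+1")
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValidationError("true fractions must be nonnegative and sum to 1")
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    tables = []
    for s in range(n_samples):
        noise = np.exp(rng.normal(0.0, sigma, size=fr.size)) if cv > 0 else np.ones(fr.size)
        areas = total_area * fr * noise
        tables.append(
            IsotopologueTable(
                compound=compound,
                sample=f"{group}_{fraction_kind}_{s + 1}",
                group=group,
                fraction_kind=fraction_kind,
                areas=tuple(areas),
            )
        )
    return tables


def gen_metabolomics_matrix(
    n_genotypes: int = 6,
    n_reps: int = 5,
    genotype_sd: float = 1.0,
    status_effects: Sequence[float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_features: int = 100,
    baseline_mean: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-scale metabolite abundances with genotype and status structure.

    Model per feature f, genotype g, replicate k:
    ``y = baseline_f + u_{f,g} + β_f · status_g + ε`` with genotype random
    intercepts ``u ~ N(0, genotype_sd²)`` and noise ``ε ~ N(0, noise_sd²)``.
    The first half of the genotypes carry the facultative symbiont
    (status = 1) — status is a genotype-level property, exactly the
    confounding that motivates the mixed-model screening stage.

    Defaults mirror the study layout: 6 genotypes (3 carriers), 5 replicate
    pools each.  Returns ``(matrix features × samples, design table)``.
    """
    if n_genotypes < 2 or n_reps < 2:
        raise ValidationError("need >= 2 genotypes and >= 2 replicates")
    if status_effects is None:
        status_effects = np.zeros(n_features)
    effects = np.asarray(status_effects, dtype=float)
    n_features = effects.size
    rng = np.random.default_rng(seed)

    genotypes = [f"G{g + 1}" for g in range(n_genotypes)]
    status_of = {g: int(i < n_genotypes // 2) for i, g in enumerate(genotypes)}
    samples, design_rows = [], []
    for g in genotypes:
        for k in range(n_reps):
            sid = f"{g}_r{k + 1}"
            samples.append((sid, g))
            design_rows.append({"sample": sid, "genotype": g, "status": status_of[g]})

    baselines = rng.normal(baseline_mean, 2.0, size=n_features)
    intercepts = rng.normal(0.0, genotype_sd, size=(n_features, n_genotypes))
    gidx = {g: i for i, g in enumerate(genotypes)}
    data = np.empty((n_features, len(samples)))
    for j, (sid, g) in enumerate(samples):
        data[:, j] = (
            baselines
            + intercepts[:, gidx[g]]
            + effects * status_of[g]
            + rng.normal(0.0, noise_sd, size=n_features)
        )
    matrix = pd.DataFrame(
        data,
        index=[f"metab_{i + 1}" for i in range(n_features)],
        columns=[sid for sid, _ in samples],
    )
    return matrix, pd.DataFrame(design_rows)


def gen_performance_samples(
    mean: float, sd: float, n: int, seed: int = 0
) -> np.ndarray:
    """Raw per-individual performance values behind a printed mean ± SE."""
    if n < 2:
        raise ValidationError("need n >= 2")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, size=n)
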
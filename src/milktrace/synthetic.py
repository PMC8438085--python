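"""Synthetic study datasets with a planted soil-phyllosphere-cow-teat-milk
transfer chain.

The generator emulates the study design: a network of dairy farms, four
compartments per farm, two marker domains (prokaryote 16S, fungal 18S), one
sample per farm x compartment x domain at a nominal sequencing depth of
10,000 reads. Each compartment has its own genus pool (a shared core plus a
compartment-specific tail) with independent per-genus Dirichlet
concentrations; latent compositions are chained by mixing proportions

    phyllosphere = l1*soil + (1-l1)*e_phyllo
    cow-teat     = l2*phyllosphere + (1-l2)*e_teat
    milk         = l3*cow-teat + l4*e'_phyllo + (1-l3-l4)*e_milk

with e_* fresh Dirichlet draws, and counts are multinomial over the latent
composition. The direct phyllosphere-to-milk path carries a fresh draw from
the phyllosphere pool (airborne or feed-borne inoculum characteristic of the
habitat's flora) rather than the realized, soil-imprinted phyllosphere
composition; this keeps the direct grass-to-milk signal from smuggling soil
signal into milk, so the absent soil-to-milk edge stays a true null.
Mixing proportions may respond to a farm covariate through a
logistic-quadratic curve with an interior optimum, which is the planted
signal the driver-model chain is expected to recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_tables import (
    COMPARTMENTS,
    DOMAINS,
    GenusCountTable,
    SampleMetadata,
    canonical_pair,
)

#: the four chained transfer edges, in chain order
def edge_key(edge: tuple[str, str]) -> str:
    """Flat column label for a transfer edge, e.g. ``soil->phyllosphere``."""
    return f"{edge[0]}->{edge[1]}"


CHAIN_EDGES = (
    ("soil", "phyllosphere"),
    ("phyllosphere", "cow-teat"),
    ("cow-teat", "milk"),
    ("phyllosphere", "milk"),
)

#: quantitative covariate [min, max] envelopes of the study's farm network
COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "Elevation": (328.6, 1237.9),
    "C_org": (27.0, 103.0),
    "N_tot": (2.8, 10.7),
    "CaCO3": (0.5, 343.0),
    "C_N": (8.7, 10.8),
    "pH": (5.5, 7.9),
    "P2O5": (1.5e-3, 0.1),
    "NO3": (1.6, 95.3),
    "NH4": (8.2, 25.1),
    "Clay": (19.4, 66.3),
    "Silt": (32.6, 68.2),
    "Sand": (1.1, 35.9),
    "SpRichness": (12, 58),
    "Pielou": (0.133, 0.37),
    "Grass": (41.0, 91.5),
    "Forb": (1.1, 37.2),
    "Legume": (3.6, 45.9),
    "Cattle": (123.0, 779.1),
    "Cattle_spring": (0.0, 294.6),
    "Cattle_summer": (0.0, 385.7),
    "Cattle_autumn": (0.0, 249.4),
    "P_ind": (0.0, 18.5),
    "K_ind": (0.0, 75.0),
    "N_ind": (0.0, 68.0),
    "Liquid_manure": (0.0, 50.6),
    "Solid_manure": (0.0, 12.1),
    "Total_manure": (0.0, 50.6),
    "Total_N_fertilization": (0.0, 90.6),
    "Dairy_cows": (25, 200),
}

#: categorical frequencies observed across the 44-farm network
MILKING_PREPARATION_COUNTS = {"none": 1, "dry": 26, "humid": 17}
COW_TEAT_CARE_COUNTS = {"yes": 35, "no": 9}


@dataclass
class TransferResponse:
    """Logistic-quadratic covariate response of one mixing proportion.

    lambda = expit(c0 + c1*x + c2*x^2 + eps) with eps ~ N(0, noise_sd) per
    farm; ``driver=None`` gives a covariate-free baseline expit(c0 + eps).
    """

    c0: float
    c1: float = 0.0
    c2: float = 0.0
    driver: str | None = None
    noise_sd: float = 0.2

    @property
    def optimum(self) -> float | None:
        """Vertex of the quadratic response (the planted optimum)."""
        if self.driver is None or self.c2 == 0:
            return None
        return -self.c1 / (2.0 * self.c2)

    def lam(self, covariate_row: Mapping[str, float], noise: float = 0.0) -> float:
        eta = self.c0 + noise
        if self.driver is not None:
            x = float(covariate_row[self.driver])
            eta += self.c1 * x + self.c2 * x * x
        return float(expit(eta))


def quadratic_response(
    driver: str,
    optimum: float,
    curvature: float,
    peak_lambda: float,
    noise_sd: float = 0.2,
) -> TransferResponse:
    """Build a logistic-quadratic response peaking at ``optimum`` with
    lambda = ``peak_lambda`` there; ``curvature`` (< 0) is the logit-scale
    quadratic coefficient."""
    if not 0 < peak_lambda < 1:
        raise ValueError("peak_lambda must lie in (0, 1)")
    if curvature >= 0:
        raise ValueError("curvature must be negative for an interior optimum")
    c2 = curvature
    c1 = -2.0 * curvature * optimum
    c0 = float(logit(peak_lambda)) - (c1 * optimum + c2 * optimum**2)
    return TransferResponse(c0=c0, c1=c1, c2=c2, driver=driver, noise_sd=noise_sd)


def constant_response(baseline: float, noise_sd: float = 0.2) -> TransferResponse:
    if not 0 <= baseline < 1:
        raise ValueError("baseline mixing must lie in [0, 1)")
    c0 = float(logit(baseline)) if baseline > 0 else -math.inf
    return TransferResponse(c0=c0, noise_sd=noise_sd if baseline > 0 else 0.0)


def default_responses() -> dict[tuple[str, str], TransferResponse]:
    """The default driver scenario: the soil-phyllosphere mixing responds to
    soil pH with an interior optimum at pH 7.0; the other edges sit near the
    middle of the mixing scale."""
    return {
        ("soil", "phyllosphere"): quadratic_response(
            driver="pH", optimum=7.0, curvature=-1.2, peak_lambda=0.4
        ),
        ("phyllosphere", "cow-teat"): constant_response(0.3),
        ("cow-teat", "milk"): constant_response(0.28),
        ("phyllosphere", "milk"): constant_response(0.2),
    }


@dataclass
class ScenarioConfig:
    """Study-design parameters of a synthetic dataset."""

    seed: int
    n_farms: int = 44
    n_genera: dict[str, int] = field(
        default_factory=lambda: {"prokaryote": 1917, "fungal": 1080}
    )
    reads: int = 10_000
    shared_core_frac: float = 0.4
    concentration: float = 100.0
    #: lognormal sigma of each pool's rank-abundance profile; the gradient
    #: from even soil communities to strongly dominated milk communities
    #: controls how fast transfer signal decays along the chain
    abundance_sigma: dict[str, float] = field(
        default_factory=lambda: {
            "soil": 0.7,
            "phyllosphere": 1.2,
            "cow-teat": 1.4,
            "milk": 1.5,
        }
    )
    responses: dict[tuple[str, str], TransferResponse] = field(
        default_factory=default_responses
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_farms <= 0 or self.reads <= 0:
            raise ValueError("n_farms and reads must be positive")
        if not 0 <= self.shared_core_frac <= 1:
            raise ValueError("shared_core_frac must lie in [0, 1]")
        if isinstance(self.abundance_sigma, (int, float)):
            self.abundance_sigma = {c: float(self.abundance_sigma) for c in COMPARTMENTS}
        for edge in CHAIN_EDGES:
            if edge not in self.responses:
                raise ValueError(f"missing transfer response for edge {edge}")
        base3 = expit(self.responses[("cow-teat", "milk")].c0)
        base4 = expit(self.responses[("phyllosphere", "milk")].c0)
        if base3 + base4 > 1:
            raise ValueError(
                "baseline cow-teat->milk and phyllosphere->milk mixing exceed 1"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset: genus pools, per-farm mixing
    proportions and the covariate-response parameters."""

    pools: dict[str, dict[str, pd.Series]]  # domain -> compartment -> alpha
    responses: dict[tuple[str, str], TransferResponse]
    lambdas: pd.DataFrame  # farms x edges (edge_key columns), realized mixing
    seed: int

    def planted_optimum(self, edge: tuple[str, str]) -> float | None:
        return self.responses[canonical_pair(*edge)].optimum

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "responses": {
                edge_key(edge): {**asdict(resp)}
                for edge, resp in self.responses.items()
            },
            "lambdas": {
                col: self.lambdas[col].round(10).to_dict()
                for col in self.lambdas.columns
            },
            "pools": {
                dom: {comp: alpha.round(10).to_dict() for comp, alpha in comps.items()}
                for dom, comps in self.pools.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticBundle:
    tables: dict[str, GenusCountTable]  # domain -> raw counts
    metadata: SampleMetadata
    covariates: pd.DataFrame  # indexed by farm
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = {}
        for dom, table in self.tables.items():
            p = out / f"counts_{dom}.tsv"
            table.counts.to_csv(p, sep="\t")
            written[f"counts_{dom}"] = p
        p = out / "metadata.tsv"
        self.metadata.table.to_csv(p, sep="\t", index=False)
        written["metadata"] = p
        p = out / "covariates.tsv"
        self.covariates.to_csv(p, sep="\t", float_format="%.12g")
        written["covariates"] = p
        p = out / "truth.json"
        self.truth.to_json(p)
        written["truth"] = p
        return written


# ---------------------------------------------------------------------------
# covariates


def _uniform(rng: np.random.Generator, name: str) -> float:
    lo, hi = COVARIATE_RANGES[name]
    return float(rng.uniform(lo, hi))


def _in_range(name: str, value: float) -> bool:
    lo, hi = COVARIATE_RANGES[name]
    return lo <= value <= hi


def generate_covariates(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a farm covariate table spanning the study's observed ranges.

    Marginals are independent uniforms over the observed [min, max]
    envelopes, with the structural identities enforced by rejection:
    texture and vegetation-group covers each sum to 100 %, seasonal grazing
    pressures sum to the annual value, manure and fertilization totals are
    consistent, and Manure_prop follows its zero rule. At the study's design
    size (44 farms) the categorical frequencies reproduce the observed
    counts exactly; at other sizes they are drawn with those proportions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_farms):
        row: dict[str, float | str] = {}
        for name in ("Elevation", "C_org", "N_tot", "CaCO3", "C_N", "pH",
                     "P2O5", "NO3", "NH4", "Pielou"):
            row[name] = _uniform(rng, name)
        while True:  # texture closure
            clay, silt = _uniform(rng, "Clay"), _uniform(rng, "Silt")
            sand = 100.0 - clay - silt
            if _in_range("Sand", sand):
                row.update(Clay=clay, Silt=silt, Sand=sand)
                break
        while True:  # vegetation-group closure
            grass, forb = _uniform(rng, "Grass"), _uniform(rng, "Forb")
            legume = 100.0 - grass - forb
            if _in_range("Legume", legume):
                row.update(Grass=grass, Forb=forb, Legume=legume)
                break
        while True:  # seasonal grazing pressures summing into the annual range
            seasons = {
                s: _uniform(rng, f"Cattle_{s}") for s in ("spring", "summer", "autumn")
            }
            total = sum(seasons.values())
            if _in_range("Cattle", total):
                row.update({f"Cattle_{s}": v for s, v in seasons.items()})
                row["Cattle"] = total
                break
        while True:  # fertilization identities
            liquid = _uniform(rng, "Liquid_manure")
            solid = _uniform(rng, "Solid_manure")
            n_ind = _uniform(rng, "N_ind")
            manure = liquid + solid
            if _in_range("Total_manure", manure) and _in_range(
                "Total_N_fertilization", manure + n_ind
            ):
                row.update(
                    Liquid_manure=liquid,
                    Solid_manure=solid,
                    N_ind=n_ind,
                    Total_manure=manure,
                    Total_N_fertilization=manure + n_ind,
                )
                break
        total_n = row["Total_N_fertilization"]
        row["Manure_prop"] = 0.0 if total_n == 0 else row["Total_manure"] / total_n
        row["P_ind"] = _uniform(rng, "P_ind")
        row["K_ind"] = _uniform(rng, "K_ind")
        row["SpRichness"] = float(rng.integers(12, 59))
        row["Dairy_cows"] = float(rng.integers(25, 201))
        rows.append(row)

    df = pd.DataFrame(rows, index=[f"F{i + 1:02d}" for i in range(config.n_farms)])
    df.index.name = "farm"
    for col, counts in (
        ("Milking_preparation", MILKING_PREPARATION_COUNTS),
        ("Cow-teat_care", COW_TEAT_CARE_COUNTS),
    ):
        if config.n_farms == sum(counts.values()):
            values = [lvl for lvl, k in counts.items() for _ in range(k)]
        else:
            probs = np.array(list(counts.values()), dtype=float)
            values = list(
                rng.choice(list(counts), size=config.n_farms, p=probs / probs.sum())
            )
        df[col] = rng.permutation(np.array(values, dtype=object))
    return df


# ---------------------------------------------------------------------------
# communities


def build_pools(
    config: ScenarioConfig, rng: np.random.Generator
) -> dict[str, dict[str, pd.Series]]:
    """Per-domain, per-compartment Dirichlet concentration vectors.

    A shared core (``shared_core_frac`` of each domain's genera) is present in
    every compartment's pool; the remainder is split into four
    compartment-specific tails. Concentrations are lognormal within a pool and
    independent across compartments, so compartments overlap in membership but
    not in expected rank-abundance.
    """
    prefix = {"prokaryote": "p", "fungal": "f"}
    pools: dict[str, dict[str, pd.Series]] = {}
    for dom in DOMAINS:
        n = config.n_genera[dom]
        genera = [f"{prefix[dom]}_g{i + 1:04d}" for i in range(n)]
        n_core = int(round(config.shared_core_frac * n))
        tail = genera[n_core:]
        tail_split = np.array_split(np.array(tail), len(COMPARTMENTS))
        pools[dom] = {}
        for ci, comp in enumerate(COMPARTMENTS):
            members = genera[:n_core] + list(tail_split[ci])
            w = rng.lognormal(
                mean=0.0, sigma=config.abundance_sigma[comp], size=len(members)
            )
            alpha = pd.Series(0.0, index=genera)
            alpha.loc[members] = config.concentration * w / w.sum()
            pools[dom][comp] = alpha
    return pools


def farm_lambdas(
    config: ScenarioConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Realized mixing proportions per farm and edge (shared across domains)."""
    rows = []
    for farm, cov_row in covariates.iterrows():
        lams = {}
        for edge in CHAIN_EDGES:
            resp = config.responses[edge]
            noise = rng.normal(0.0, resp.noise_sd) if resp.noise_sd > 0 else 0.0
            lams[edge] = resp.lam(cov_row, noise)
        s = lams[("cow-teat", "milk")] + lams[("phyllosphere", "milk")]
        if s > 1:  # keep the milk mixture a proper convex combination
            lams[("cow-teat", "milk")] *= (1.0 - 1e-9) / s
            lams[("phyllosphere", "milk")] *= (1.0 - 1e-9) / s
        rows.append({edge_key(e): lams[e] for e in CHAIN_EDGES})
    df = pd.DataFrame(rows, index=covariates.index)
    df.index.name = "farm"
    return df


def farm_compositions(
    pools: Mapping[str, pd.Series],
    lams: Mapping[tuple[str, str], float],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Latent compartment compositions for one farm and one domain.

    The direct phyllosphere-to-milk term mixes in a fresh draw from the
    phyllosphere pool — habitat-characteristic flora reaching the tank
    without passing through the teat — so the soil imprint reaches milk only
    through the three-step chain.
    """

    def draw(comp: str) -> np.ndarray:
        alpha = pools[comp].to_numpy()
        out = np.zeros_like(alpha)
        support = alpha > 0
        out[support] = rng.dirichlet(alpha[support])
        return out

    l1 = lams[("soil", "phyllosphere")]
    l2 = lams[("phyllosphere", "cow-teat")]
    l3 = lams[("cow-teat", "milk")]
    l4 = lams[("phyllosphere", "milk")]
    soil = draw("soil")
    phyllo = l1 * soil + (1.0 - l1) * draw("phyllosphere")
    teat = l2 * phyllo + (1.0 - l2) * draw("cow-teat")
    milk = l3 * teat + l4 * draw("phyllosphere") + (1.0 - l3 - l4) * draw("milk")
    return {"soil": soil, "phyllosphere": phyllo, "cow-teat": teat, "milk": milk}


def generate_communities(
    covariates: pd.DataFrame,
    truth: SyntheticTruth,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, GenusCountTable], SampleMetadata]:
    """Multinomial genus count tables (one per domain) plus sample metadata."""
    tables: dict[str, GenusCountTable] = {}
    meta_rows = []
    counts_by_dom: dict[str, dict[str, np.ndarray]] = {d: {} for d in DOMAINS}
    for farm in covariates.index:
        lams = {e: float(truth.lambdas.loc[farm, edge_key(e)]) for e in CHAIN_EDGES}
        for dom in DOMAINS:
            comps = farm_compositions(truth.pools[dom], lams, rng)
            for comp in COMPARTMENTS:
                sid = f"{farm}:{comp}"  # shared by the two sequencing runs
                counts_by_dom[dom][sid] = rng.multinomial(config.reads, comps[comp])
                meta_rows.append(
                    {"sample": sid, "farm": farm, "compartment": comp, "domain": dom}
                )
    for dom in DOMAINS:
        genera = truth.pools[dom][COMPARTMENTS[0]].index
        df = pd.DataFrame.from_dict(counts_by_dom[dom], orient="index")
        df.columns = genera
        tables[dom] = GenusCountTable(df, domain=dom)
    return tables, SampleMetadata(pd.DataFrame(meta_rows))


def generate_dataset(config: ScenarioConfig) -> SyntheticBundle:
    """End-to-end deterministic synthetic bundle for a scenario config."""
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_pool, rng_lam, rng_comm = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    covariates = generate_covariates(config, rng_cov)
    pools = build_pools(config, rng_pool)
    lambdas = farm_lambdas(config, covariates, rng_lam)
    truth = SyntheticTruth(
        pools=pools, responses=dict(config.responses), lambdas=lambdas,
        seed=config.seed,
    )
    tables, metadata = generate_communities(covariates, truth, config, rng_comm)
    return SyntheticBundle(
        tables=tables, metadata=metadata, covariates=covariates, truth=truth
    )
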
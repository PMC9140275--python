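"""Synthetic administrative-claims generator with planted ground truth.

The generator works top-down.  A structural model first draws, per patient,
every analysis variable (demographic and comorbidity indicators, index
treatment regimen, complications, healthcare resource use, and total
healthcare cost) from linear structural equations with *planted standardized
coefficients*.  Claim-level records — drug administrations, diagnosis claims
and encounters — are then emitted so that every downstream pipeline stage
(line-of-therapy segmentation, cohort selection, comorbidity scoring, resource
counting, cost aggregation) re-derives exactly the planted values.  Claim
costs are allocated so that a patient's in-window claims sum to the generated
total cost, inverted through the configured exchange-rate/CPI tables so the
cost engine recovers the planted adjusted-USD total.

Coefficients are planted on the standardized scale and converted to the raw
scale analytically.  Binary variables are drawn by uniform thresholding of a
linear probability (so conditional means stay linear and least squares is
unbiased); mutually exclusive regimen categories are drawn from a categorical
distribution whose category probabilities are linear in the predictors (each
dummy then also has a linear conditional mean); cost uses a multiplicative
log-normal error whose sigma is solved so the cost variance hits its target
exactly.  Population means and covariances of every variable are computed
recursively in closed form, which is what makes exact standardized planting
possible.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .costs import RateTables, default_rate_tables
from .lot import LotRules
from .pathmodel import BLOCK_EDGES

__all__ = [
    "SimConfig",
    "ClaimsBundle",
    "StructuralModel",
    "default_structure",
    "default_blocks",
    "generate_bundle",
    "corrupt_bundle",
    "simulate_analysis_table",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Structural node specifications

@dataclasses.dataclass(frozen=True)
class ExogBinary:
    name: str
    block: str
    p: float


@dataclasses.dataclass(frozen=True)
class ExogGroup:
    """Mutually exclusive exogenous dummies (reference = all zero)."""
    names: tuple
    block: str
    probs: tuple


@dataclasses.dataclass(frozen=True)
class ExogUniformInt:
    name: str
    block: str
    low: int
    high: int  # inclusive


@dataclasses.dataclass(frozen=True)
class EndogBinary:
    """Linear-probability Bernoulli: P(Y=1|X) = intercept + b'X."""
    name: str
    block: str
    mean: float
    edges: Mapping[str, float]  # parent -> standardized coefficient
    logistic: bool = False  # misspecification option: logit link instead


@dataclasses.dataclass(frozen=True)
class EndogCategorical:
    """Exclusive categories with linear category probabilities.

    The listed categories get linear-probability equations; the implicit
    reference category absorbs the remainder, so each dummy's conditional
    mean is exactly linear in the parents.
    """
    names: tuple
    block: str
    bases: tuple
    edges: Mapping[str, Mapping[str, float]]  # name -> {parent: beta}


@dataclasses.dataclass(frozen=True)
class EndogCount:
    """1 + Poisson with linear mean (always >= 1)."""
    name: str
    block: str
    mean: float
    edges: Mapping[str, float]


@dataclasses.dataclass(frozen=True)
class EndogContinuous:
    """Linear mean plus independent noise (centered gamma for right skew)."""
    name: str
    block: str
    mean: float
    sd: float
    edges: Mapping[str, float]
    noise_shape: float | None = None  # gamma shape; None -> normal noise
    integer: bool = False


@dataclasses.dataclass(frozen=True)
class EndogCost:
    """Linear mean with multiplicative log-normal (mean-one) error.

    ``sigma="auto"`` solves sigma so Var(Y) equals sd**2 exactly, keeping the
    planted standardized coefficients exact at population level.
    """
    name: str
    block: str
    mean: float
    sd: float
    edges: Mapping[str, float]
    sigma: float | str = "auto"


_EXOG_KINDS = (ExogBinary, ExogGroup, ExogUniformInt)


class StructuralModel:
    """Ordered structural nodes with analytic moment resolution."""

    def __init__(self, nodes):
        self.nodes = list(nodes)
        self._resolved = None

    # -- bookkeeping -------------------------------------------------------
    def var_names(self) -> list:
        out = []
        for nd in self.nodes:
            out.extend(nd.names if isinstance(nd, (ExogGroup, EndogCategorical)) else [nd.name])
        return out

    def blocks(self) -> dict:
        out: dict = {}
        for nd in self.nodes:
            names = nd.names if isinstance(nd, (ExogGroup, EndogCategorical)) else [nd.name]
            out.setdefault(nd.block, []).extend(names)
        return out

    def validate_edges(self):
        block_of = {}
        for nd in self.nodes:
            names = nd.names if isinstance(nd, (ExogGroup, EndogCategorical)) else [nd.name]
            for n in names:
                block_of[n] = nd.block
        for nd in self.nodes:
            if isinstance(nd, _EXOG_KINDS):
                continue
            edge_sets = (
                nd.edges.values() if isinstance(nd, EndogCategorical) else [nd.edges]
            )
            child_block = nd.block
            for es in ([nd.edges] if not isinstance(nd, EndogCategorical) else nd.edges.values()):
                for parent in es:
                    if parent not in block_of:
                        raise SimConfigError(f"planted edge from unknown variable {parent!r}")
                    if (block_of[parent], child_block) not in BLOCK_EDGES:
                        raise SimConfigError(
                            f"planted edge {parent!r} -> {child_block} block not allowed"
                        )

    # -- analytic resolution ------------------------------------------------
    def resolve(self) -> dict:
        """Convert standardized planted coefficients to raw scale.

        Returns a plan with, per node, raw coefficients, intercepts and noise
        parameters, plus the population mean vector, covariance matrix and the
        implied standardized coefficient for every edge.
        """
        if self._resolved is not None:
            return self._resolved
        self.validate_edges()
        names: list = []
        idx: dict = {}
        mu: list = []
        support: dict = {}
        group_of: dict = {}
        groups: dict = {}
        n_total = len(self.var_names())
        cov = np.zeros((n_total, n_total))
        plan = []
        std_effects: dict = {}

        def add_var(name, mean, var, cross, lo, hi, gid=None):
            i = len(names)
            idx[name] = i
            names.append(name)
            mu.append(mean)
            cov[i, i] = var
            for other, c in cross.items():
                j = idx[other]
                cov[i, j] = cov[j, i] = c
            support[name] = (lo, hi)
            if gid is not None:
                group_of[name] = gid
                groups.setdefault(gid, []).append(name)

        def sd_of(name):
            return math.sqrt(cov[idx[name], idx[name]])

        def raw_coefs(edges, child_sd):
            b = {}
            for parent, beta in edges.items():
                sp = sd_of(parent)
                if beta != 0 and sp == 0:
                    raise SimConfigError(f"edge from constant variable {parent!r}")
                if beta != 0 and child_sd == 0:
                    raise SimConfigError("nonzero edge into zero-variance child")
                b[parent] = 0.0 if child_sd == 0 or sp == 0 else beta * child_sd / sp
            return b

        def lp_cross(b):
            """cov(linear predictor, each existing variable)."""
            out = np.zeros(len(names))
            for parent, coef in b.items():
                out += coef * cov[idx[parent], : len(names)]
            return {names[j]: out[j] for j in range(len(names))}

        def lp_var(b):
            ps = list(b)
            v = 0.0
            for p1 in ps:
                for p2 in ps:
                    v += b[p1] * b[p2] * cov[idx[p1], idx[p2]]
            return v

        def lp_bounds(intercept, b):
            lo = hi = intercept
            done_groups = set()
            for parent in b:
                gid = group_of.get(parent)
                if gid is not None:
                    if gid in done_groups:
                        continue
                    done_groups.add(gid)
                    opts = [0.0] + [b.get(m, 0.0) for m in groups[gid]]
                    lo += min(opts)
                    hi += max(opts)
                else:
                    slo, shi = support[parent]
                    vals = [b[parent] * slo, b[parent] * shi]
                    lo += min(vals)
                    hi += max(vals)
            return lo, hi

        gid_counter = 0
        for nd in self.nodes:
            if isinstance(nd, ExogBinary):
                if not 0 <= nd.p <= 1:
                    raise SimConfigError(f"{nd.name}: p outside [0,1]")
                add_var(nd.name, nd.p, nd.p * (1 - nd.p), {}, 0.0, 1.0)
                plan.append(("exog_binary", nd))
            elif isinstance(nd, ExogGroup):
                if any(p < 0 for p in nd.probs) or sum(nd.probs) > 1 + 1e-12:
                    raise SimConfigError(f"{nd.names}: invalid group probabilities")
                gid_counter += 1
                for k, (nm, p) in enumerate(zip(nd.names, nd.probs)):
                    cross = {
                        nd.names[j]: -p * nd.probs[j] for j in range(k)
                    }
                    add_var(nm, p, p * (1 - p), cross, 0.0, 1.0, gid=gid_counter)
                plan.append(("exog_group", nd))
            elif isinstance(nd, ExogUniformInt):
                lo, hi = nd.low, nd.high
                m = (lo + hi) / 2.0
                k = hi - lo + 1
                add_var(nd.name, m, (k * k - 1) / 12.0, {}, float(lo), float(hi))
                plan.append(("exog_uniform_int", nd))
            elif isinstance(nd, EndogBinary):
                m = nd.mean
                child_sd = math.sqrt(m * (1 - m))
                b = raw_coefs(nd.edges, child_sd)
                intercept = m - sum(b[p] * mu[idx[p]] for p in b)
                lo, hi = lp_bounds(intercept, b)
                if not nd.logistic and (lo < -1e-9 or hi > 1 + 1e-9):
                    raise SimConfigError(
                        f"{nd.name}: linear probability outside [0,1] "
                        f"(range {lo:.4f}..{hi:.4f}); weaken edges or base rate"
                    )
                add_var(nd.name, m, m * (1 - m), lp_cross(b), 0.0, 1.0)
                for p, beta in nd.edges.items():
                    std_effects[(nd.name, p)] = beta
                plan.append(("binary", nd, b, intercept))
            elif isinstance(nd, EndogCategorical):
                gid_counter += 1
                bs, intercepts = {}, {}
                # raw coefs per category first (child sds known a priori)
                for nm, base in zip(nd.names, nd.bases):
                    child_sd = math.sqrt(base * (1 - base))
                    bs[nm] = raw_coefs(nd.edges.get(nm, {}), child_sd)
                    intercepts[nm] = base - sum(
                        bs[nm][p] * mu[idx[p]] for p in bs[nm]
                    )
                # simplex validation on the support hull
                sum_b: dict = {}
                for nm in nd.names:
                    for p, c in bs[nm].items():
                        sum_b[p] = sum_b.get(p, 0.0) + c
                lo_s, hi_s = lp_bounds(sum(intercepts.values()), sum_b)
                if hi_s > 1 + 1e-9:
                    raise SimConfigError(
                        f"{nd.names}: category probabilities can exceed 1"
                    )
                for nm in nd.names:
                    lo, hi = lp_bounds(intercepts[nm], bs[nm])
                    if lo < -1e-9:
                        raise SimConfigError(f"{nm}: category probability can go negative")
                for k, (nm, base) in enumerate(zip(nd.names, nd.bases)):
                    cross = lp_cross(bs[nm])
                    for j in range(k):  # exclusivity overrides: cov = -mu_i mu_j
                        cross[nd.names[j]] = -base * nd.bases[j]
                    add_var(nm, base, base * (1 - base), cross, 0.0, 1.0, gid=gid_counter)
                    for p, beta in nd.edges.get(nm, {}).items():
                        std_effects[(nm, p)] = beta
                plan.append(("categorical", nd, bs, intercepts))
            elif isinstance(nd, EndogCount):
                if nd.mean <= 1:
                    raise SimConfigError(f"{nd.name}: count mean must exceed 1")
                # child sd solves sd^2 = (mean-1) + R*sd^2 with R = beta'Corr beta
                R = 0.0
                ps = list(nd.edges)
                for p1 in ps:
                    for p2 in ps:
                        R += (
                            nd.edges[p1]
                            * nd.edges[p2]
                            * cov[idx[p1], idx[p2]]
                            / (sd_of(p1) * sd_of(p2))
                        )
                if R >= 1:
                    raise SimConfigError(f"{nd.name}: planted edges explain >= 100% variance")
                child_sd = math.sqrt((nd.mean - 1) / (1 - R))
                b = raw_coefs(nd.edges, child_sd)
                intercept = nd.mean - sum(b[p] * mu[idx[p]] for p in b)
                lo, hi = lp_bounds(intercept, b)
                if lo < 1:
                    raise SimConfigError(f"{nd.name}: Poisson mean can fall below 0")
                add_var(nd.name, nd.mean, child_sd**2, lp_cross(b), 1.0, math.inf)
                for p, beta in nd.edges.items():
                    std_effects[(nd.name, p)] = beta
                plan.append(("count", nd, b, intercept))
            elif isinstance(nd, EndogContinuous):
                b = raw_coefs(nd.edges, nd.sd)
                vlp = lp_var(b)
                noise_var = nd.sd**2 - vlp
                if noise_var < -1e-9:
                    raise SimConfigError(
                        f"{nd.name}: planted edges imply more variance than target SD"
                    )
                noise_var = max(noise_var, 0.0)
                intercept = nd.mean - sum(b[p] * mu[idx[p]] for p in b)
                lo, hi = lp_bounds(intercept, b)
                noise_lo = 0.0
                if nd.noise_shape is not None and noise_var > 0:
                    scale = math.sqrt(noise_var / nd.noise_shape)
                    noise_lo = -nd.noise_shape * scale
                    if lo + noise_lo < 0:
                        raise SimConfigError(
                            f"{nd.name}: can go negative (min {lo + noise_lo:.1f}); "
                            "raise mean or reduce SD"
                        )
                add_var(
                    nd.name, nd.mean, nd.sd**2, lp_cross(b), lo + noise_lo, math.inf
                )
                for p, beta in nd.edges.items():
                    std_effects[(nd.name, p)] = beta
                plan.append(("continuous", nd, b, intercept, noise_var))
            elif isinstance(nd, EndogCost):
                b = raw_coefs(nd.edges, nd.sd)
                vlp = lp_var(b)
                if vlp > nd.sd**2 + 1e-9:
                    raise SimConfigError(
                        f"{nd.name}: planted edges imply more variance than target SD"
                    )
                intercept = nd.mean - sum(b[p] * mu[idx[p]] for p in b)
                lo, hi = lp_bounds(intercept, b)
                if nd.sigma == "auto":
                    denom = vlp + nd.mean**2
                    T = (nd.sd**2 - vlp) / denom if denom > 0 else 0.0
                    sigma = math.sqrt(math.log1p(max(T, 0.0)))
                    var = nd.sd**2
                else:
                    sigma = float(nd.sigma)
                    T = math.expm1(sigma**2)
                    # Var(lp * e) = Var(lp)(1+T) + mean^2 T for mean-one e
                    var = vlp * (1 + T) + nd.mean**2 * T
                if sigma > 0 and lo <= 0:
                    raise SimConfigError(
                        f"{nd.name}: linear predictor can reach {lo:.1f} <= 0; "
                        "multiplicative error requires a positive mean"
                    )
                child_sd = math.sqrt(var)
                add_var(nd.name, nd.mean, var, lp_cross(b), 0.0, math.inf)
                for p, beta in nd.edges.items():
                    # implied standardized value given the final child SD
                    std_effects[(nd.name, p)] = (
                        b[p] * sd_of(p) / child_sd if child_sd > 0 else 0.0
                    )
                plan.append(("cost", nd, b, intercept, sigma))
            else:
                raise SimConfigError(f"unknown node type {type(nd).__name__}")

        self._resolved = {
            "plan": plan,
            "names": names,
            "mu": np.asarray(mu),
            "cov": cov,
            "std_effects": std_effects,
            "blocks": self.blocks(),
        }
        return self._resolved

    def standardized_effects(self) -> dict:
        """Implied population standardized coefficient per (child, parent)."""
        return dict(self.resolve()["std_effects"])

    # -- sampling ------------------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        res = self.resolve()
        data: dict = {}

        def lp_of(b, intercept):
            out = np.full(n, intercept)
            for p, coef in b.items():
                out += coef * data[p]
            return out

        for entry in res["plan"]:
            kind, nd = entry[0], entry[1]
            if kind == "exog_binary":
                data[nd.name] = (rng.random(n) < nd.p).astype(float)
            elif kind == "exog_group":
                u = rng.random(n)
                cum = np.cumsum(nd.probs)
                cat = np.searchsorted(cum, u)  # == len(probs) -> reference
                for k, nm in enumerate(nd.names):
                    data[nm] = (cat == k).astype(float)
            elif kind == "exog_uniform_int":
                data[nd.name] = rng.integers(nd.low, nd.high + 1, size=n).astype(float)
            elif kind == "binary":
                _, _, b, intercept = entry
                lp = lp_of(b, intercept)
                if nd.logistic:
                    lp = 1.0 / (1.0 + np.exp(-(lp - 0.5) * 6.0))
                data[nd.name] = (rng.random(n) < np.clip(lp, 0, 1)).astype(float)
            elif kind == "categorical":
                _, _, bs, intercepts = entry
                u = rng.random(n)
                cum = np.zeros(n)
                assigned = np.full(n, -1)
                for k, nm in enumerate(nd.names):
                    cum = cum + np.clip(lp_of(bs[nm], intercepts[nm]), 0, 1)
                    hit = (assigned < 0) & (u < cum)
                    assigned[hit] = k
                for k, nm in enumerate(nd.names):
                    data[nm] = (assigned == k).astype(float)
            elif kind == "count":
                _, _, b, intercept = entry
                lam = np.maximum(lp_of(b, intercept) - 1.0, 0.0)
                data[nd.name] = 1.0 + rng.poisson(lam).astype(float)
            elif kind == "continuous":
                _, _, b, intercept, noise_var = entry
                lp = lp_of(b, intercept)
                if noise_var > 0:
                    if nd.noise_shape is not None:
                        scale = math.sqrt(noise_var / nd.noise_shape)
                        eps = rng.gamma(nd.noise_shape, scale, size=n) - nd.noise_shape * scale
                    else:
                        eps = rng.normal(0.0, math.sqrt(noise_var), size=n)
                    lp = lp + eps
                if nd.integer:
                    lp = np.round(lp)
                data[nd.name] = lp
            elif kind == "cost":
                _, _, b, intercept, sigma = entry
                lp = lp_of(b, intercept)
                if sigma > 0:
                    z = rng.standard_normal(n)
                    lp = lp * np.exp(sigma * z - sigma**2 / 2.0)
                data[nd.name] = lp
        return pd.DataFrame(data, columns=res["names"])


# ---------------------------------------------------------------------------
# Default study conditions

ITR_CATEGORIES = ("itr_r_chase", "itr_gdp", "itr_r_epoch", "itr_other_r")

#: regimen category id behind each planted ITR dummy
ITR_DUMMY_TO_CATEGORY = {
    "itr_r_chase": "r_chase",
    "itr_gdp": "gdp",
    "itr_r_epoch": "r_epoch",
    "itr_other_r": "other_r",
}
ITR_REFERENCE_CATEGORY = "other_chemo_without_r"

#: drug-code templates per regimen category (codes from the shipped config)
REGIMEN_TEMPLATES = {
    "rchop": ("RTX-A", "CPA-1", "DOX-1", "VCR-1", "PSL-1"),
    "r_chase": ("RTX-A", "CPA-1", "ARA-1", "ETP-1", "DEX-1"),
    "gdp_r": ("RTX-B", "GEM-1", "DEX-1", "CDDP-1"),
    "gdp_nor": ("GEM-1", "DEX-1", "CDDP-1"),
    "r_epoch": ("RTX-A", "ETP-1", "PSL-1", "VCR-1", "CPA-1", "DOX-1"),
    "other_r": ("RTX-A", "NOVEL-1"),
    "other_chemo_without_r": ("ARA-1", "ETP-1"),
    "r_devic": ("RTX-A", "DEX-1", "ETP-1", "IFO-1", "CBP-1"),
    "r_ice": ("RTX-A", "IFO-1", "CBP-1", "ETP-1"),
    "r_dhap": ("RTX-A", "DEX-1", "ARA-1", "CDDP-1"),
    "r_bendamustine": ("RTX-A", "BEN-1"),
    "eshap": ("ETP-1", "ARA-1", "CDDP-1", "MPSL-1"),
    "nos": ("UNSPEC-1",),
    "meam": ("RAN-1", "ETP-1", "ARA-1", "MEL-1"),
}

#: templates eligible for post-index lines beyond the cohort-defining one
LATER_LINE_TEMPLATES = (
    "r_devic", "r_ice", "r_dhap", "r_bendamustine", "eshap", "nos",
    "other_chemo_without_r",
)

_CATEGORY_OF_TEMPLATE = {
    "rchop": "other_r",
    "r_chase": "r_chase",
    "gdp_r": "gdp",
    "gdp_nor": "gdp",
    "r_epoch": "r_epoch",
    "other_r": "other_r",
    "other_chemo_without_r": "other_chemo_without_r",
    "r_devic": "r_devic",
    "r_ice": "r_ice",
    "r_dhap": "r_dhap",
    "r_bendamustine": "r_bendamustine",
    "eshap": "eshap",
    "nos": "nos",
    "meam": "conditioning_auto_sct",  # when followed by auto-SCT
}


def default_structure() -> StructuralModel:
    """The default study conditions for the second-line cohort.

    Base rates, cost level and the direct standardized effects mirror the
    published second-line cohort (female 44.3%, mean cost 73,296 USD, the
    LOS effect 0.750, etc.); mediator-path coefficients are set to plausible
    moderate values since the source reports only the resulting indirect
    effects.  Cost and LOS spreads are reduced relative to the heavy-tailed
    real data so all planted costs stay strictly positive.
    """
    return StructuralModel([
        ExogBinary("female", "patient_characteristics", 0.443),
        ExogGroup(
            ("age_66_70", "age_71_75", "age_76_80", "age_81_85", "age_85p"),
            "patient_characteristics",
            (0.17, 0.17, 0.17, 0.10, 0.06),
        ),
        ExogUniformInt("index_year", "patient_characteristics", 1, 11),
        ExogGroup(("cci_3", "cci_4", "cci_5p"), "comorbidities", (0.114, 0.145, 0.279)),
        ExogBinary("prior_cancer", "comorbidities", 0.08),
        EndogCategorical(
            names=ITR_CATEGORIES,
            block="itr",
            bases=(0.067, 0.077, 0.034, 0.444),
            edges={
                "itr_r_chase": {"female": -0.02, "age_81_85": -0.02, "cci_5p": -0.03},
                "itr_gdp": {"age_66_70": 0.02, "cci_3": 0.02},
                "itr_r_epoch": {},
                "itr_other_r": {
                    "female": 0.03, "age_85p": -0.04, "cci_5p": -0.05,
                    "prior_cancer": -0.02,
                },
            },
        ),
        EndogBinary(
            "comp_heart", "complications", 0.15,
            {"cci_4": 0.04, "cci_5p": 0.08, "itr_r_chase": 0.05, "itr_other_r": 0.03},
        ),
        EndogBinary(
            "comp_liver", "complications", 0.16,
            {"cci_5p": 0.06, "itr_gdp": 0.03},
        ),
        EndogBinary(
            "comp_kidney", "complications", 0.055,
            {"cci_5p": 0.05, "itr_r_chase": 0.03},
        ),
        EndogContinuous(
            "los_days", "hcru", mean=123.0, sd=60.0,
            edges={
                "itr_r_chase": 0.10, "itr_gdp": 0.05, "itr_other_r": -0.06,
                "comp_heart": 0.15, "comp_liver": 0.10, "comp_kidney": 0.05,
            },
            noise_shape=1.2, integer=True,
        ),
        EndogCount(
            "n_hospitalizations", "hcru", mean=5.0,
            edges={"comp_heart": 0.10, "itr_r_chase": 0.05, "itr_gdp": 0.04},
        ),
        EndogBinary(
            "any_icu", "hcru", 0.027, {"comp_heart": 0.05, "comp_kidney": 0.04},
        ),
        EndogBinary(
            "any_sct", "hcru", 0.135,
            {"itr_r_chase": 0.06, "itr_other_r": -0.04, "comp_heart": -0.03},
        ),
        EndogCost(
            "thcc_adj_usd", "thcc", mean=73296.40, sd=40000.0,
            edges={
                "female": -0.036,
                "age_66_70": -0.030, "age_71_75": -0.052, "age_76_80": -0.063,
                "age_81_85": -0.081, "age_85p": -0.063,
                "index_year": -0.119,
                "cci_3": 0.017, "cci_4": 0.018, "cci_5p": 0.062,
                "prior_cancer": 0.024,
                "itr_r_chase": 0.016, "itr_gdp": -0.006, "itr_r_epoch": -0.005,
                "itr_other_r": 0.033,
                "comp_heart": 0.064, "comp_liver": 0.012, "comp_kidney": 0.053,
                "los_days": 0.750, "n_hospitalizations": 0.088,
                "any_icu": 0.050, "any_sct": 0.156,
            },
            sigma="auto",
        ),
    ])


def default_blocks() -> dict:
    """Model block assignment matching the default generator's planted nodes."""
    return {k: list(v) for k, v in default_structure().blocks().items()}


def simulate_analysis_table(
    structure: StructuralModel, n: int, rng: np.random.Generator | int
) -> pd.DataFrame:
    """Draw n analysis rows directly from the structural equations."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return structure.sample(n, rng)


# ---------------------------------------------------------------------------
# Simulation configuration and bundle container

DEFAULT_COST_SPLIT = {
    "inpatient": 0.58,
    "icu": 0.02,
    "outpatient": 0.14,
    "cancer_treatment": 0.13,
    "other_pharmacy": 0.10,
    "sct": 0.03,
}

DEFAULT_IMAGING_RATES = {
    "any_pet": 0.45,
    "any_mri": 0.30,
    "any_ct": 0.85,
    "any_er": 0.04,
    "any_radiation": 0.25,
}

CORRUPTION_SCENARIOS = (
    "short_followup",
    "sparse_claims",
    "missing_lookback",
    "immunotherapy_combo",
)

_RULE_OF_SCENARIO = {
    "short_followup": "followup_lt_12mo",
    "sparse_claims": "missing_claim_in_6mo_period",
    "missing_lookback": "no_lookback_claim",
    "immunotherapy_combo": "rituximab_immunotherapy_combo",
}


@dataclasses.dataclass
class SimConfig:
    """Generator configuration; the defaults ARE the study conditions."""

    n_patients: int = 2000
    seed: int = 0
    id_window: tuple = (dt.date(2008, 10, 1), dt.date(2019, 6, 30))
    data_end: dt.date = dt.date(2021, 6, 30)
    target_line: int = 2
    structure: StructuralModel = dataclasses.field(default_factory=default_structure)
    p_gap_transition: float = 0.35
    p_third_line: float = 0.55
    p_conditioning_given_sct: float = 0.5
    p_allo: float = 0.05
    p_gdp_with_r: float = 0.8
    p_complication_history: float = 0.3
    imaging_rates: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_IMAGING_RATES)
    )
    cost_split: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COST_SPLIT)
    )
    rates: RateTables = dataclasses.field(default_factory=default_rate_tables)
    lot_rules: LotRules = dataclasses.field(default_factory=LotRules)

    def __post_init__(self):
        if self.n_patients < 1:
            raise SimConfigError("n_patients must be >= 1")
        if self.id_window[0] >= self.id_window[1]:
            raise SimConfigError("id_window start must precede end")
        if self.target_line not in (2, 3):
            raise SimConfigError("target_line must be 2 or 3")
        if abs(sum(self.cost_split.values()) - 1.0) > 1e-9:
            raise SimConfigError("cost_split must sum to 1")
        for k, v in {
            "p_gap_transition": self.p_gap_transition,
            "p_third_line": self.p_third_line,
            "p_conditioning_given_sct": self.p_conditioning_given_sct,
            "p_allo": self.p_allo,
            "p_complication_history": self.p_complication_history,
            **self.imaging_rates,
        }.items():
            if not 0 <= v <= 1:
                raise SimConfigError(f"probability {k}={v} outside [0,1]")
        self.structure.resolve()  # validates planted edges & feasibility

    def to_jsonable(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "seed": self.seed,
            "id_window": [d.isoformat() for d in self.id_window],
            "data_end": self.data_end.isoformat(),
            "target_line": self.target_line,
            "p_gap_transition": self.p_gap_transition,
            "p_third_line": self.p_third_line,
            "cost_split": dict(self.cost_split),
            "imaging_rates": dict(self.imaging_rates),
            "planted_standardized_effects": {
                f"{c}<-{p}": v
                for (c, p), v in self.structure.standardized_effects().items()
            },
        }


@dataclasses.dataclass
class ClaimsBundle:
    """Five claims tables plus the generator's ground truth."""

    patients: pd.DataFrame
    drug_claims: pd.DataFrame
    dx_claims: pd.DataFrame
    encounters: pd.DataFrame
    truth: pd.DataFrame
    truth_lines: pd.DataFrame
    meta: dict

    _TABLES = ("patients", "drug_claims", "dx_claims", "encounters", "truth", "truth_lines")

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            *(getattr(self, t).copy() for t in self._TABLES), meta=dict(self.meta)
        )

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for t in self._TABLES:
            getattr(self, t).to_csv(outdir / f"{t}.csv", index=False)
        (outdir / "sim_config.json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def read(cls, indir) -> "ClaimsBundle":
        indir = Path(indir)
        tables = {}
        for t in cls._TABLES:
            df = pd.read_csv(indir / f"{t}.csv")
            for col in df.columns:
                if col.endswith("date") or col in ("start_date", "end_date"):
                    df[col] = pd.to_datetime(df[col]).dt.date
            tables[t] = df
        meta = json.loads((indir / "sim_config.json").read_text())
        return cls(**tables, meta=meta)


# ---------------------------------------------------------------------------
# Bundle generation


def _index_date(iy: int, rng) -> dt.date:
    """Index date inside year 2008+iy respecting the identification window."""
    if iy == 1:  # leave room for the first line and lookback after Oct 2008
        doy = int(rng.integers(212, 361))
    elif iy == 11:
        doy = int(rng.integers(0, 180))  # identification ends June 30
    else:
        doy = int(rng.integers(0, 361))
    return dt.date(2008 + iy, 1, 1) + dt.timedelta(days=doy)


def _cycle_days(start: dt.date, n_cycles: int) -> list:
    return [start + dt.timedelta(days=21 * k) for k in range(n_cycles)]


def _components_of(template: str, config: SimConfig) -> set:
    m = config.lot_rules.drug_to_component
    return {m[c] for c in REGIMEN_TEMPLATES[template]}


def generate_bundle(config: SimConfig) -> ClaimsBundle:
    """Generate a synthetic claims database with planted ground truth.

    Identical ``config`` (including seed) yields a byte-identical bundle.
    Every uncorrupted patient passes all cohort-selection rules, re-derives
    the planted treatment lines exactly, and has in-window claim costs whose
    adjusted-USD total equals the planted total healthcare cost.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    table = config.structure.sample(n, rng)
    for flag, rate in config.imaging_rates.items():
        table[flag] = (rng.random(n) < rate).astype(float)

    pats, drugs, dxs, encs = [], [], [], []
    truth_rows, truth_lines = [], []
    split = dict(config.cost_split)
    rates = config.rates
    ref_cpi = rates.cpi[rates.reference_year]

    for i in range(n):
        pid = f"P{i:05d}"
        row = table.iloc[i]
        iy = int(row["index_year"])
        index = _index_date(iy, rng)
        los = int(row["los_days"])
        n_hosp = int(row["n_hospitalizations"])
        if los < n_hosp:  # unreachable under the default conditions; keep safe
            los = n_hosp
            table.iat[i, table.columns.get_loc("los_days")] = float(los)

        # follow-up long enough for the 12-month rule and all hospital stays
        f0 = 420.0 + rng.gamma(2.0, 250.0)
        F = int(min(f0, (config.data_end - index).days))
        F = max(F, 371, los + 90)
        if index + dt.timedelta(days=F) > config.data_end:
            F = (config.data_end - index).days
            if los > F - 10:
                los = F - 10
                table.iat[i, table.columns.get_loc("los_days")] = float(los)
        end = index + dt.timedelta(days=F)

        # ---- treatment-line history -------------------------------------
        lines = []  # (template, start, n_cycles)
        n1 = int(rng.integers(5, 8))
        gap1 = int(rng.integers(91, 151)) if rng.random() < config.p_gap_transition \
            else int(rng.integers(7, 61))
        # index line template from the planted ITR category
        cat = ITR_REFERENCE_CATEGORY
        for dummy in ITR_CATEGORIES:
            if row[dummy] == 1:
                cat = ITR_DUMMY_TO_CATEGORY[dummy]
                break
        if cat == "gdp":
            idx_template = "gdp_r" if rng.random() < config.p_gdp_with_r else "gdp_nor"
        elif cat == "other_chemo_without_r":
            idx_template = "other_chemo_without_r"
        elif cat == "other_r":
            idx_template = "other_r"
        else:
            idx_template = cat

        if config.target_line == 2:
            t1 = index - dt.timedelta(days=21 * (n1 - 1) + gap1)
            lines.append(("rchop", t1, n1))
            n_idx = int(rng.integers(3, 7))
            lines.append((idx_template, index, n_idx))
        else:
            # a second line sits between first treatment and the 3L index
            n2 = int(rng.integers(3, 7))
            gap2 = int(rng.integers(91, 151)) if rng.random() < config.p_gap_transition \
                else int(rng.integers(7, 61))
            t2 = index - dt.timedelta(days=21 * (n2 - 1) + gap2)
            t1 = t2 - dt.timedelta(days=21 * (n1 - 1) + gap1)
            prior2 = rng.choice(["r_chase", "gdp_r", "other_r", "other_chemo_without_r"])
            if _components_of(idx_template, config) <= _components_of(prior2, config):
                gap2 = int(rng.integers(91, 151))  # force the gap trigger
                t2 = index - dt.timedelta(days=21 * (n2 - 1) + gap2)
                t1 = t2 - dt.timedelta(days=21 * (n1 - 1) + gap1)
            lines.append(("rchop", t1, n1))
            lines.append((str(prior2), t2, n2))
            n_idx = int(rng.integers(3, 7))
            lines.append((idx_template, index, n_idx))

        idx_line_no = len(lines)
        idx_end = index + dt.timedelta(days=21 * (n_idx - 1))

        # optional post-index line (always beyond the cohort-defining line)
        any_sct = row["any_sct"] == 1
        sct_line_no = idx_line_no if any_sct else 0
        post_template = None
        if config.target_line == 2 and rng.random() < config.p_third_line:
            if any_sct and rng.random() < config.p_conditioning_given_sct:
                post_template = "meam"
            else:
                post_template = str(rng.choice(LATER_LINE_TEMPLATES))
            n3 = int(rng.integers(2, 5))
            if rng.random() < config.p_gap_transition or _components_of(
                post_template, config
            ) <= _components_of(idx_template, config):
                gap3 = int(rng.integers(91, 151))
            else:
                gap3 = int(rng.integers(7, 61))
            start3 = idx_end + dt.timedelta(days=gap3)
            dur3 = 21 * (n3 - 1)
            if (start3 + dt.timedelta(days=dur3 + 15)) <= end:
                lines.append((post_template, start3, n3))
                if post_template == "meam":
                    sct_line_no = len(lines)
            else:
                post_template = None

        # ---- drug claims & truth lines ------------------------------------
        cancer_claim_rows = []  # indices into drugs that are in-window
        patient_sct_kind = "none"
        for ln_no, (template, start, n_cyc) in enumerate(lines, start=1):
            codes = REGIMEN_TEMPLATES[template]
            days = _cycle_days(start, n_cyc)
            for d in days:
                for code in codes:
                    drugs.append(
                        {"patient_id": pid, "service_date": d,
                         "drug_code": code, "cost_jpy": 0.0}
                    )
                    if d >= index:
                        cancer_claim_rows.append(len(drugs) - 1)
            sct_kind = "none"
            if ln_no == sct_line_no and any_sct:
                sct_kind = "allo" if rng.random() < config.p_allo else "auto"
                patient_sct_kind = sct_kind
            cat_ln = _CATEGORY_OF_TEMPLATE[template]
            if template == "meam" and sct_kind != "auto":
                cat_ln = "other_chemo_without_r"
            truth_lines.append(
                {"patient_id": pid, "line_number": ln_no,
                 "start_date": start, "end_date": days[-1],
                 "regimen_category": cat_ln, "sct_within_line": sct_kind}
            )
            dxs.append({"patient_id": pid, "service_date": start, "icd10_code": "C83.3"})

        # ---- diagnosis claims ---------------------------------------------
        t1 = lines[0][1]
        dxs.append({"patient_id": pid, "service_date": t1 - dt.timedelta(days=30),
                    "icd10_code": "J06.9"})
        prior_cancer = row["prior_cancer"] == 1
        if prior_cancer:
            dxs.append({"patient_id": pid,
                        "service_date": index - dt.timedelta(days=int(rng.integers(30, 171))),
                        "icd10_code": "C18.9"})
        cci_codes = _cci_kit(row, prior_cancer, rng)
        for code in cci_codes:
            dxs.append({"patient_id": pid,
                        "service_date": index - dt.timedelta(days=int(rng.integers(25, 171))),
                        "icd10_code": code})
        for comp, code in (("comp_heart", "I20.0"), ("comp_kidney", "N17.9"),
                           ("comp_liver", "K75.9")):
            if row[comp] == 1:
                offset = int(rng.integers(20, max(21, min(241, F - 20))))
                dxs.append({"patient_id": pid,
                            "service_date": index + dt.timedelta(days=offset),
                            "icd10_code": code})
            elif rng.random() < config.p_complication_history:
                dxs.append({"patient_id": pid,
                            "service_date": t1 - dt.timedelta(days=int(rng.integers(40, 81))),
                            "icd10_code": code})
                dxs.append({"patient_id": pid,
                            "service_date": index + dt.timedelta(days=int(rng.integers(20, 201))),
                            "icd10_code": code})

        # ---- encounters -----------------------------------------------------
        inpatient_rows, icu_rows, outpatient_rows, sct_rows = [], [], [], []
        lengths = rng.multinomial(los - n_hosp, np.full(n_hosp, 1.0 / n_hosp)) + 1
        free = F - los
        cursor = index
        for ℓ in lengths:
            gap = int(rng.integers(0, max(1, free // n_hosp)))
            admit = cursor + dt.timedelta(days=gap)
            disch = admit + dt.timedelta(days=int(ℓ) - 1)
            encs.append({"patient_id": pid, "admit_date": admit, "discharge_date": disch,
                         "setting": "inpatient", "cost_jpy": 0.0})
            inpatient_rows.append(len(encs) - 1)
            cursor = disch + dt.timedelta(days=1)
        if row["any_icu"] == 1:
            a0 = encs[inpatient_rows[0]]["admit_date"]
            d0 = encs[inpatient_rows[0]]["discharge_date"]
            encs.append({"patient_id": pid, "admit_date": a0,
                         "discharge_date": min(a0 + dt.timedelta(days=2), d0),
                         "setting": "ICU", "cost_jpy": 0.0})
            icu_rows.append(len(encs) - 1)
        day = 15
        while day < F:
            d = index + dt.timedelta(days=day)
            encs.append({"patient_id": pid, "admit_date": d, "discharge_date": d,
                         "setting": "outpatient", "cost_jpy": 0.0})
            outpatient_rows.append(len(encs) - 1)
            day += 30
        encs.append({"patient_id": pid, "admit_date": end, "discharge_date": end,
                     "setting": "outpatient", "cost_jpy": 0.0})
        outpatient_rows.append(len(encs) - 1)
        for flag, setting in (("any_pet", "PET"), ("any_mri", "MRI"), ("any_ct", "CT"),
                              ("any_er", "ER"), ("any_radiation", "radiation")):
            if row[flag] == 1:
                d = index + dt.timedelta(days=int(rng.integers(10, F - 9)))
                encs.append({"patient_id": pid, "admit_date": d, "discharge_date": d,
                             "setting": setting, "cost_jpy": 0.0})
                outpatient_rows.append(len(encs) - 1)
        if any_sct:
            tmpl, s_start, s_cyc = lines[sct_line_no - 1]
            if tmpl == "meam":  # transplant right after the conditioning course
                s_date = s_start + dt.timedelta(days=21 * (s_cyc - 1) + int(rng.integers(2, 9)))
            else:
                dur = 21 * (s_cyc - 1)
                s_date = s_start + dt.timedelta(days=int(rng.integers(5, max(6, dur + 1))))
            encs.append({"patient_id": pid, "admit_date": s_date, "discharge_date": s_date,
                         "setting": f"SCT-{patient_sct_kind}", "cost_jpy": 0.0})
            sct_rows.append(len(encs) - 1)

        # ---- supportive pharmacy (unmapped drug codes) ----------------------
        pharm_rows = []
        day = 20
        while day < F:
            drugs.append({"patient_id": pid,
                          "service_date": index + dt.timedelta(days=day),
                          "drug_code": "SUPP-1", "cost_jpy": 0.0})
            pharm_rows.append(len(drugs) - 1)
            day += 30

        # ---- cost allocation -------------------------------------------------
        thcc = float(row["thcc_adj_usd"])
        pools = {
            "inpatient": ("enc", inpatient_rows),
            "icu": ("enc", icu_rows),
            "outpatient": ("enc", outpatient_rows),
            "cancer_treatment": ("drug", cancer_claim_rows),
            "other_pharmacy": ("drug", pharm_rows),
            "sct": ("enc", sct_rows),
        }
        weights = {c: w for c, w in split.items() if pools[c][1]}
        wsum = sum(weights.values())
        total_jpy = 0.0
        for c, w in weights.items():
            kind, rows_ = pools[c]
            usd_each = thcc * (w / wsum) / len(rows_)
            for r in rows_:
                rec = drugs[r] if kind == "drug" else encs[r]
                y = (rec["service_date"] if kind == "drug" else rec["admit_date"]).year
                jpy = usd_each * (rates.cpi[y] / ref_cpi) * rates.fx[y]
                rec["cost_jpy"] = rec["cost_jpy"] + jpy
                total_jpy += jpy

        # ---- patient & truth rows --------------------------------------------
        age = _age_from_bands(row, rng)
        sex = "F" if row["female"] == 1 else "M"
        pats.append({"patient_id": pid, "sex": sex,
                     "birth_year": index.year - age, "death_or_censor_date": end})
        t_row = {"patient_id": pid, "index_date": index,
                 "first_treatment_date": t1, "followup_days": F,
                 "age": age, "n_lines": len(lines),
                 "total_cost_jpy": total_jpy,
                 "corrupt_scenario": "", "expected_exclusion_rule": ""}
        t_row.update({c: row[c] for c in table.columns})
        t_row["los_days"] = float(los)
        truth_rows.append(t_row)

    bundle = ClaimsBundle(
        patients=pd.DataFrame(pats),
        drug_claims=pd.DataFrame(drugs),
        dx_claims=pd.DataFrame(dxs),
        encounters=pd.DataFrame(encs),
        truth=pd.DataFrame(truth_rows),
        truth_lines=pd.DataFrame(truth_lines),
        meta=config.to_jsonable(),
    )
    _check_bundle(bundle, config)
    return bundle


def _cci_kit(row, prior_cancer: bool, rng) -> list:
    """Diagnosis codes producing exactly the planted modified-CCI band.

    Codes are chosen outside the complication sets and (except the planted
    C18.9 prior-cancer code, whose malignancy weight is accounted for) outside
    C00-C96 minus C77-C89, so planted quantities never interfere.
    """
    if row["cci_5p"] == 1:
        return ["C78.0"]  # metastatic (6); supersedes malignancy if present
    if row["cci_4"] == 1:
        return ["J44.9", "K25.9"] if prior_cancer else ["G81.9", "J44.9", "K25.9"]
    if row["cci_3"] == 1:
        return ["J44.9"] if prior_cancer else ["J44.9", "K25.9", "E11.9"]
    # reference band 0-2
    if prior_cancer:
        return []  # malignancy weight 2 keeps the band
    k = int(rng.integers(0, 3))
    return [["J44.9"], ["J44.9", "K25.9"]][k - 1] if k else []


def _age_from_bands(row, rng) -> int:
    if row["age_66_70"] == 1:
        return int(rng.integers(66, 71))
    if row["age_71_75"] == 1:
        return int(rng.integers(71, 76))
    if row["age_76_80"] == 1:
        return int(rng.integers(76, 81))
    if row["age_81_85"] == 1:
        return int(rng.integers(81, 86))
    if row["age_85p"] == 1:
        return int(rng.integers(86, 95))
    return int(rng.integers(40, 66))


def _check_bundle(bundle: ClaimsBundle, config: SimConfig) -> None:
    """Generation-time invariants (dates, non-negative costs, id closure)."""
    for tbl, col in (("drug_claims", "service_date"), ("dx_claims", "service_date"),
                     ("encounters", "admit_date"), ("encounters", "discharge_date")):
        dates = getattr(bundle, tbl)[col]
        if len(dates) and max(dates) > config.data_end:
            raise AssertionError(f"{tbl}.{col} beyond data horizon")
    e = bundle.encounters
    if len(e) and (pd.to_datetime(e["discharge_date"]) < pd.to_datetime(e["admit_date"])).any():
        raise AssertionError("discharge before admission")
    if (bundle.drug_claims["cost_jpy"] < 0).any() or (e["cost_jpy"] < 0).any():
        raise AssertionError("negative generated cost")
    pids = set(bundle.patients["patient_id"])
    for tbl in ("drug_claims", "dx_claims", "encounters"):
        if not set(getattr(bundle, tbl)["patient_id"]) <= pids:
            raise AssertionError(f"{tbl} references unknown patient ids")


# ---------------------------------------------------------------------------
# Corruption scenarios


def corrupt_bundle(
    bundle: ClaimsBundle,
    scenario: str,
    fraction: float = 0.2,
    seed: int | None = None,
) -> ClaimsBundle:
    """Return a copy where a fraction of patients violate exactly one rule.

    ``round(fraction * n)`` patients are flagged in the truth table
    (``corrupt_scenario`` / ``expected_exclusion_rule``) and their claims are
    modified so that cohort selection excludes exactly them, at the named rule.
    Truth lines of flagged patients are not updated (they are excluded before
    any line-level quantity is used).
    """
    if scenario not in CORRUPTION_SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {CORRUPTION_SCENARIOS}"
        )
    out = bundle.copy()
    rng = np.random.default_rng(
        bundle.meta.get("seed", 0) * 1000003 % (2**31)
        if seed is None else seed
    )
    n = len(out.truth)
    k = int(round(fraction * n))
    flagged = np.sort(rng.choice(n, size=k, replace=False))
    truth = out.truth
    pids = truth["patient_id"].to_numpy()

    drug, dx, enc = out.drug_claims, out.dx_claims, out.encounters
    keep_drug = np.ones(len(drug), bool)
    keep_dx = np.ones(len(dx), bool)
    keep_enc = np.ones(len(enc), bool)
    add_drug = []

    for j in flagged:
        pid = pids[j]
        t1 = truth.iloc[j]["first_treatment_date"]
        index = truth.iloc[j]["index_date"]
        if scenario == "short_followup":
            cutoff = t1 + dt.timedelta(days=300)
            keep_drug &= ~((drug["patient_id"] == pid) & (drug["service_date"] > cutoff))
            keep_dx &= ~((dx["patient_id"] == pid) & (dx["service_date"] > cutoff))
            keep_enc &= ~((enc["patient_id"] == pid) & (enc["admit_date"] > cutoff))
            out.patients.loc[
                out.patients["patient_id"] == pid, "death_or_censor_date"
            ] = cutoff
        elif scenario == "sparse_claims":
            lo = t1 + dt.timedelta(days=183)
            hi = t1 + dt.timedelta(days=366)
            keep_drug &= ~((drug["patient_id"] == pid)
                           & (drug["service_date"] >= lo) & (drug["service_date"] < hi))
            keep_dx &= ~((dx["patient_id"] == pid)
                         & (dx["service_date"] >= lo) & (dx["service_date"] < hi))
            keep_enc &= ~((enc["patient_id"] == pid)
                          & (enc["admit_date"] >= lo) & (enc["admit_date"] < hi))
        elif scenario == "missing_lookback":
            lo = t1 - dt.timedelta(days=183)
            keep_drug &= ~((drug["patient_id"] == pid)
                           & (drug["service_date"] >= lo) & (drug["service_date"] < t1))
            keep_dx &= ~((dx["patient_id"] == pid)
                         & (dx["service_date"] >= lo) & (dx["service_date"] < t1))
            keep_enc &= ~((enc["patient_id"] == pid)
                          & (enc["admit_date"] >= lo) & (enc["admit_date"] < t1))
        elif scenario == "immunotherapy_combo":
            add_drug.append({"patient_id": pid, "service_date": index,
                             "drug_code": "OBZ-1", "cost_jpy": 0.0})
            has_r = (
                (drug["patient_id"] == pid)
                & (drug["service_date"] == index)
                & drug["drug_code"].str.startswith("RTX")
            ).any()
            if not has_r:
                add_drug.append({"patient_id": pid, "service_date": index,
                                 "drug_code": "RTX-A", "cost_jpy": 0.0})

    out.drug_claims = drug[keep_drug].reset_index(drop=True)
    if add_drug:
        out.drug_claims = pd.concat(
            [out.drug_claims, pd.DataFrame(add_drug)], ignore_index=True
        )
    out.dx_claims = dx[keep_dx].reset_index(drop=True)
    out.encounters = enc[keep_enc].reset_index(drop=True)
    truth.loc[truth.index[flagged], "corrupt_scenario"] = scenario
    truth.loc[truth.index[flagged], "expected_exclusion_rule"] = _RULE_OF_SCENARIO[scenario]
    out.meta = dict(out.meta, corruption={"scenario": scenario, "fraction": fraction,
                                          "n_flagged": int(k)})
    return out
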
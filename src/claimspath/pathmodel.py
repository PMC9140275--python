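"""Recursive observed-variable path analysis with effect decomposition.

Implements the cost-driver model used throughout this package: a system of
linear structural equations among observed variables grouped into six blocks

    patient_characteristics (PC), comorbidities (CM), index treatment regimen
    (ITR), complications (CP), healthcare resource utilization (HCRU), and a
    single total-healthcare-cost outcome (THCC),

with the block-level arrows

    PC -> THCC, CM -> THCC, ITR -> THCC, CP -> THCC, HCRU -> THCC,
    PC -> ITR,  CM -> ITR,  ITR -> HCRU, CP -> HCRU, CM -> CP, ITR -> CP.

The model is recursive (acyclic) with uncorrelated equation errors, so
equation-wise least squares is the maximum-likelihood estimator.  Because
medical cost is strongly right-skewed, inference uses heteroskedasticity-
consistent (sandwich) standard errors.  Each predictor's standardized effect
on cost decomposes into a direct effect (its edge into THCC), an indirect
effect (the sum over all mediated directed paths into THCC of the product of
standardized edge coefficients), and a total effect (their sum).  Model fit
is summarized by the standardized root mean square residual (SRMR) between
the observed and model-implied correlation structure; values below 0.08 are
conventionally read as good fit.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "BLOCKS",
    "BLOCK_EDGES",
    "PathSpec",
    "PathModel",
    "PathResults",
    "build_spec",
    "srmr_from_matrices",
    "indirect_from_standardized",
]

#: Canonical block names, in causal (topological) order.
BLOCKS = (
    "patient_characteristics",
    "comorbidities",
    "itr",
    "complications",
    "hcru",
    "thcc",
)

#: Permitted block-level arrows (from_block, to_block).  Any variable-level
#: edge must lie along one of these.
BLOCK_EDGES = (
    ("patient_characteristics", "thcc"),
    ("comorbidities", "thcc"),
    ("itr", "thcc"),
    ("complications", "thcc"),
    ("hcru", "thcc"),
    ("patient_characteristics", "itr"),
    ("comorbidities", "itr"),
    ("itr", "hcru"),
    ("complications", "hcru"),
    ("comorbidities", "complications"),
    ("itr", "complications"),
)

_ENDOGENOUS_BLOCKS = ("itr", "complications", "hcru", "thcc")


class PathSpecError(ValueError):
    """Raised for structurally invalid path specifications."""


@dataclasses.dataclass(frozen=True)
class PathSpec:
    """Variable-level DAG expanded from a block assignment.

    Parameters
    ----------
    blocks : mapping
        Maps each block name in :data:`BLOCKS` to the ordered list of column
        names assigned to it.  The ``thcc`` block must contain exactly one
        column.  Blocks other than ``thcc`` may be empty except that every
        endogenous block with variables must have at least one incoming edge,
        which the block arrows guarantee whenever its parent blocks are
        non-empty.
    extra_edges : tuple
        Reserved for variable-level edges beyond the block expansion; any
        requested edge not along a permitted block arrow raises.
    """

    blocks: Mapping[str, tuple]
    edges: tuple  # ((from_col, to_col), ...)

    @classmethod
    def from_blocks(
        cls,
        blocks: Mapping[str, Sequence[str]],
        extra_edges: Iterable[tuple] = (),
        drop_edges: Iterable[tuple] = (),
    ) -> "PathSpec":
        blocks = {b: tuple(blocks.get(b, ())) for b in BLOCKS}
        unknown = set(blocks) - set(BLOCKS)
        if unknown:
            raise PathSpecError(f"unknown blocks: {sorted(unknown)}")
        if len(blocks["thcc"]) != 1:
            raise PathSpecError("the thcc block must contain exactly one column")
        all_cols = [c for b in BLOCKS for c in blocks[b]]
        if len(set(all_cols)) != len(all_cols):
            raise PathSpecError("a column may belong to only one block")
        col_block = {c: b for b in BLOCKS for c in blocks[b]}

        edges = []
        for fb, tb in BLOCK_EDGES:
            for f in blocks[fb]:
                for t in blocks[tb]:
                    edges.append((f, t))
        for f, t in extra_edges:
            if f not in col_block or t not in col_block:
                raise PathSpecError(f"edge ({f}, {t}) references unassigned column")
            if (col_block[f], col_block[t]) not in BLOCK_EDGES:
                raise PathSpecError(
                    f"edge ({f}, {t}) not permitted: no block arrow "
                    f"{col_block[f]} -> {col_block[t]}"
                )
            if (f, t) not in edges:
                edges.append((f, t))
        for f, t in drop_edges:  # deliberate misspecification / restrictions
            if (f, t) not in edges:
                raise PathSpecError(f"cannot drop absent edge ({f}, {t})")
            edges.remove((f, t))

        g = nx.DiGraph(edges)
        if not nx.is_directed_acyclic_graph(g):  # defensive; arrows are acyclic
            raise PathSpecError("requested edge set contains a cycle")
        for b in _ENDOGENOUS_BLOCKS:
            for c in blocks[b]:
                if g.in_degree(c) == 0:
                    raise PathSpecError(f"endogenous variable {c!r} has no parents")
        return cls(blocks=blocks, edges=tuple(edges))

    # -- convenience accessors -------------------------------------------------
    @property
    def nodes(self) -> tuple:
        """All columns in topological (block) order."""
        return tuple(c for b in BLOCKS for c in self.blocks[b])

    @property
    def thcc(self) -> str:
        return self.blocks["thcc"][0]

    @property
    def exogenous(self) -> tuple:
        return tuple(self.blocks["patient_characteristics"]) + tuple(
            self.blocks["comorbidities"]
        )

    @property
    def endogenous(self) -> tuple:
        return tuple(c for b in _ENDOGENOUS_BLOCKS for c in self.blocks[b])

    def block_of(self, col: str) -> str:
        for b in BLOCKS:
            if col in self.blocks[b]:
                return b
        raise KeyError(col)

    def parents(self, col: str) -> tuple:
        return tuple(f for f, t in self.edges if t == col)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def build_spec(
    columns: Sequence[str], block_assignment: Mapping[str, str]
) -> PathSpec:
    """Build a :class:`PathSpec` from a column -> block mapping.

    Every column must be assigned to exactly one block; the expansion places
    variable-level edges along every permitted block arrow.
    """
    missing = [c for c in columns if c not in block_assignment]
    if missing:
        raise PathSpecError(f"columns not assigned to a block: {missing}")
    blocks: dict = {b: [] for b in BLOCKS}
    for c in columns:
        b = block_assignment[c]
        if b not in blocks:
            raise PathSpecError(f"unknown block {b!r} for column {c!r}")
        blocks[b].append(c)
    return PathSpec.from_blocks(blocks)


# ---------------------------------------------------------------------------
# Model


class PathModel:
    """Recursive path model estimated by equation-wise least squares.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per subject; must contain every column of ``spec``.  Rows
        with missing values in model columns are dropped (count retained on
        the results object).
    spec : PathSpec
        Variable-level DAG, usually built with :meth:`PathSpec.from_blocks`.

    Notes
    -----
    Equation-wise OLS is the ML solution for recursive systems with
    uncorrelated errors, so no joint optimization is needed.  Standardization
    uses sample standard deviations of all variables, binary indicators
    included (the ``std.all`` convention), because the reported effect tables
    standardize dummy predictors as well.
    """

    def __init__(self, data: pd.DataFrame, spec: PathSpec):
        missing = [c for c in spec.nodes if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks model columns: {missing}")
        sub = data.loc[:, list(spec.nodes)].apply(pd.to_numeric)
        complete = sub.dropna()
        self.n_dropped = len(sub) - len(complete)
        self.data = complete.reset_index(drop=True)
        self.spec = spec
        max_parents = max((len(spec.parents(c)) for c in spec.endogenous), default=0)
        if len(self.data) <= max_parents + 1:
            raise ValueError(
                f"n={len(self.data)} too small for largest equation "
                f"({max_parents} predictors)"
            )

    @classmethod
    def from_blocks(
        cls, data: pd.DataFrame, blocks: Mapping[str, Sequence[str]]
    ) -> "PathModel":
        return cls(data, PathSpec.from_blocks(blocks))

    def fit(self, cov_type: str = "HC1") -> "PathResults":
        """Estimate all structural equations.

        Parameters
        ----------
        cov_type : str
            Sandwich estimator passed to statsmodels (``HC0``/``HC1``/``HC3``).
            ``HC1`` by default: the small-sample degrees-of-freedom correction
            of the heteroskedasticity-consistent estimator.
        """
        spec = self.spec
        nodes = list(spec.nodes)
        data = self.data
        n = len(data)
        idx = {c: i for i, c in enumerate(nodes)}
        p = len(nodes)

        B = np.zeros((p, p))
        se = np.full((p, p), np.nan)
        intercepts = np.zeros(p)
        resid_var = np.zeros(p)
        eq_cov = {}  # child -> (parents, cov of unstandardized coefs, no const)

        for child in spec.endogenous:
            parents = list(spec.parents(child))
            X = data[parents].to_numpy(float)
            rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
            if rank < len(parents) + 1:
                bad = _collinear_columns(X, parents)
                raise np.linalg.LinAlgError(
                    f"rank-deficient parent set for {child!r}; "
                    f"offending columns: {bad}"
                )
            res = sm.OLS(data[child].to_numpy(float), sm.add_constant(X)).fit(
                cov_type=cov_type
            )
            ci = idx[child]
            intercepts[ci] = res.params[0]
            for j, par in enumerate(parents):
                B[ci, idx[par]] = res.params[j + 1]
                se[ci, idx[par]] = res.bse[j + 1]
            # n-1 denominator keeps the implied covariance consistent with the
            # ddof=1 sample covariance (saturated specs then reproduce S).
            resid_var[ci] = res.ssr / (n - 1)
            eq_cov[child] = (parents, np.asarray(res.cov_params())[1:, 1:])

        sds = data[nodes].std(ddof=0).to_numpy() * np.sqrt(n / (n - 1))
        beta = B * (sds[None, :] / sds[:, None])
        beta_se = se * (sds[None, :] / sds[:, None])

        S = np.cov(data[nodes].to_numpy(float), rowvar=False, ddof=1)
        sigma_hat = _implied_covariance(
            B, resid_var, S, [idx[c] for c in spec.exogenous], nodes, spec
        )
        return PathResults(
            model=self,
            nodes=nodes,
            B=B,
            intercepts=intercepts,
            se=se,
            beta=beta,
            beta_se=beta_se,
            resid_var=resid_var,
            S=S,
            sigma_hat=sigma_hat,
            n=n,
            cov_type=cov_type,
            eq_cov=eq_cov,
            sds=sds,
        )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list:
    """Name columns involved in a rank deficiency (smallest singular vectors)."""
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    bad: set = set()
    for k in range(len(s)):
        if s[k] <= tol:
            bad |= {names[j] for j in np.nonzero(np.abs(vt[k]) > 1e-8)[0]}
    return sorted(bad) if bad else list(names)


def _implied_covariance(B, resid_var, S, exog_idx, nodes, spec) -> np.ndarray:
    """Sigma_hat = (I-B)^-1 Psi (I-B)^-T with a saturated exogenous block."""
    np_ = len(nodes)
    psi = np.zeros((np_, np_))
    ex = np.asarray(exog_idx, int)
    psi[np.ix_(ex, ex)] = S[np.ix_(ex, ex)]
    for i, c in enumerate(nodes):
        if c in spec.endogenous:
            psi[i, i] = resid_var[i]
    inv = np.linalg.inv(np.eye(np_) - B)
    sig = inv @ psi @ inv.T
    return (sig + sig.T) / 2.0


def srmr_from_matrices(S: np.ndarray, sigma_hat: np.ndarray) -> float:
    """SRMR over the p(p+1)/2 unique elements of the correlation residuals.

    Off-diagonal residuals are differences of correlations (both matrices
    standardized by the *observed* standard deviations); diagonal residuals
    are the standardized variance residuals (S_ii - Sigma_ii)/S_ii.
    """
    dg = np.diag(S)
    if np.any(dg <= 0):
        raise ValueError("non-positive variance in S")
    d = np.sqrt(dg)
    Dinv = 1.0 / d
    E = Dinv[:, None] * (S - sigma_hat) * Dinv[None, :]
    p = S.shape[0]
    iu = np.triu_indices(p)
    return float(np.sqrt(np.mean(E[iu] ** 2)))


# ---------------------------------------------------------------------------
# Results


class PathResults:
    """Fitted path model: coefficient matrices, fit statistics and effects.

    Attributes
    ----------
    B, beta : numpy.ndarray
        Unstandardized and standardized coefficient matrices, entry
        ``[to, from]``, respecting the spec's sparsity.
    se, beta_se : numpy.ndarray
        Per-edge sandwich standard errors on both scales.
    resid_var : numpy.ndarray
        Equation error variances (n-1 denominator).
    S, sigma_hat : numpy.ndarray
        Observed and model-implied covariance matrices over the model nodes.
    srmr : float
        Standardized root mean square residual.
    """

    def __init__(
        self,
        model,
        nodes,
        B,
        intercepts,
        se,
        beta,
        beta_se,
        resid_var,
        S,
        sigma_hat,
        n,
        cov_type,
        eq_cov,
        sds,
    ):
        self.model = model
        self.nodes = list(nodes)
        self._idx = {c: i for i, c in enumerate(self.nodes)}
        self.B = B
        self.intercepts = intercepts
        self.se = se
        self.beta = beta
        self.beta_se = beta_se
        self.resid_var = resid_var
        self.S = S
        self.sigma_hat = sigma_hat
        self.n = n
        self.cov_type = cov_type
        self._eq_cov = eq_cov
        self.sds = sds

    # -- fit -------------------------------------------------------------------
    @property
    def srmr(self) -> float:
        return srmr_from_matrices(self.S, self.sigma_hat)

    @property
    def spec(self) -> PathSpec:
        return self.model.spec

    # -- effect decomposition ---------------------------------------------------
    @property
    def predictors(self) -> list:
        """All nodes with a directed path into the cost outcome."""
        return [c for c in self.nodes if c != self.spec.thcc]

    def direct_effects(self) -> pd.Series:
        t = self._idx[self.spec.thcc]
        return pd.Series(
            {c: self.beta[t, self._idx[c]] for c in self.predictors},
            name="direct",
        )

    def indirect_effects(self) -> pd.Series:
        """Sum over all mediated paths of products of standardized coefficients.

        Computed from powers of the (nilpotent) standardized coefficient
        matrix: the [thcc, predictor] entry of ``beta**k`` sums the products
        over all directed paths of length k.
        """
        ind = _path_sums(self.beta, min_len=2)
        t = self._idx[self.spec.thcc]
        out = {}
        for c in self.predictors:
            if self.spec.block_of(c) == "hcru":
                out[c] = np.nan  # HCRU has no outgoing mediated path to cost
            else:
                out[c] = ind[t, self._idx[c]]
        return pd.Series(out, name="indirect")

    def total_effects(self) -> pd.Series:
        d = self.direct_effects()
        i = self.indirect_effects().fillna(0.0)
        return (d + i).rename("total")

    def effects(
        self,
        ci: str = "bootstrap",
        reps: int = 2000,
        seed: int | None = None,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Effect table: standardized direct/indirect/total with 95% CIs.

        Parameters
        ----------
        ci : {"bootstrap", "delta"}
            ``bootstrap``: nonparametric row resampling, percentile intervals,
            p-values by sign counts with +1 continuity.  ``delta``: first-order
            variance of coefficient products from the per-equation sandwich
            covariances (faster; treats standardizing SDs as fixed).
        reps : int
            Bootstrap replications (ignored for ``delta``); must be >= 2.
        seed : int, optional
            Makes the bootstrap reproducible.
        """
        point = pd.DataFrame(
            {
                "direct": self.direct_effects(),
                "indirect": self.indirect_effects(),
                "total": self.total_effects(),
            }
        )
        point.insert(0, "block", [self.spec.block_of(c) for c in point.index])
        if ci == "bootstrap":
            ci_tab = self._bootstrap_cis(reps=reps, seed=seed, alpha=alpha)
        elif ci == "delta":
            ci_tab = self._delta_cis(alpha=alpha)
        else:
            raise ValueError(f"unknown CI method {ci!r}")
        return point.join(ci_tab)

    # -- bootstrap ----------------------------------------------------------
    def _effect_arrays(self, beta: np.ndarray) -> np.ndarray:
        """direct/indirect/total stacked as (3, n_predictors) for one beta."""
        t = self._idx[self.spec.thcc]
        cols = [self._idx[c] for c in self.predictors]
        ind_m = _path_sums(beta, min_len=2)
        direct = beta[t, cols]
        indirect = ind_m[t, cols]
        for j, c in enumerate(self.predictors):
            if self.spec.block_of(c) == "hcru":
                indirect[j] = 0.0
        return np.vstack([direct, indirect, direct + indirect])

    def _bootstrap_cis(self, reps: int, seed, alpha: float) -> pd.DataFrame:
        if reps < 2:
            raise ValueError("reps must be >= 2")
        rng = np.random.default_rng(seed)
        data = self.model.data
        spec = self.spec
        nodes = self.nodes
        n = len(data)
        # one cross-product matrix per resample feeds every equation's solve
        Z = np.column_stack([np.ones(n)] + [data[c].to_numpy(float) for c in nodes])
        eqs = [
            (1 + self._idx[c],
             np.array([0] + [1 + self._idx[p] for p in spec.parents(c)]),
             self._idx[c],
             np.array([self._idx[p] for p in spec.parents(c)]))
            for c in spec.endogenous
        ]
        p_nodes = len(nodes)
        draws = np.empty((reps, 3, len(self.predictors)))
        self.n_bootstrap_redraws = 0
        r = 0
        while r < reps:
            take = rng.integers(0, n, size=n)
            Zb = Z[take]
            G = Zb.T @ Zb
            s1 = G[0, 1:]  # column sums
            var = (np.diag(G)[1:] - s1**2 / n) / (n - 1)
            if np.any(var <= 0):
                self.n_bootstrap_redraws += 1  # degenerate resample; redraw
                continue
            sds = np.sqrt(var)
            beta = np.zeros((p_nodes, p_nodes))
            try:
                for yi, cols, ci, pidx in eqs:
                    coef = np.linalg.solve(G[np.ix_(cols, cols)], G[cols, yi])
                    beta[ci, pidx] = coef[1:] * sds[pidx] / sds[ci]
            except np.linalg.LinAlgError:
                self.n_bootstrap_redraws += 1
                continue
            draws[r] = self._effect_arrays(beta)
            r += 1
        lo = np.quantile(draws, alpha / 2, axis=0)
        hi = np.quantile(draws, 1 - alpha / 2, axis=0)
        n_le = (draws <= 0).sum(axis=0)
        n_ge = (draws >= 0).sum(axis=0)
        pvals = np.minimum(
            1.0, 2.0 * np.minimum(n_le + 1, n_ge + 1) / (reps + 1)
        )
        return self._ci_frame(lo, hi, pvals)

    def _delta_cis(self, alpha: float) -> pd.DataFrame:
        ses = self._delta_ses()
        point = np.vstack(
            [
                self.direct_effects().to_numpy(),
                self.indirect_effects().fillna(0.0).to_numpy(),
                self.total_effects().to_numpy(),
            ]
        )
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo = point - zcrit * ses
        hi = point + zcrit * ses
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(ses > 0, point / ses, np.inf * np.sign(point))
        pvals = 2 * stats.norm.sf(np.abs(z))
        pvals = np.where(ses > 0, pvals, np.where(point == 0, 1.0, 0.0))
        return self._ci_frame(lo, hi, pvals)

    def _delta_ses(self) -> np.ndarray:
        """First-order SEs of (direct, indirect, total) per predictor.

        The edge coefficients theta (standardized, grouped by equation) carry a
        block-diagonal covariance assembled from the per-equation sandwich
        covariances rescaled to the standardized metric; effect gradients come
        from central finite differences of the path-sum polynomial.
        """
        theta_edges = []  # (child, parent)
        blocks_cov = []
        for child, (parents, cov) in self._eq_cov.items():
            ci = self._idx[child]
            d = np.array(
                [self.sds[self._idx[p]] / self.sds[ci] for p in parents]
            )
            blocks_cov.append(d[:, None] * cov * d[None, :])
            theta_edges.extend((child, p) for p in parents)
        V = _block_diag(blocks_cov)
        theta0 = np.array(
            [self.beta[self._idx[c], self._idx[p]] for c, p in theta_edges]
        )

        def effects_of(theta: np.ndarray) -> np.ndarray:
            beta = np.zeros_like(self.beta)
            for val, (c, p) in zip(theta, theta_edges):
                beta[self._idx[c], self._idx[p]] = val
            return self._effect_arrays(beta).ravel()

        h = 1e-6
        base = effects_of(theta0)
        G = np.empty((base.size, theta0.size))
        for j in range(theta0.size):
            tp = theta0.copy()
            tm = theta0.copy()
            tp[j] += h
            tm[j] -= h
            G[:, j] = (effects_of(tp) - effects_of(tm)) / (2 * h)
        var = np.einsum("ij,jk,ik->i", G, V, G)
        return np.sqrt(np.maximum(var, 0.0)).reshape(3, -1)

    def _ci_frame(self, lo, hi, pvals) -> pd.DataFrame:
        out = {}
        for i, eff in enumerate(("direct", "indirect", "total")):
            out[f"{eff}_lo"] = lo[i]
            out[f"{eff}_hi"] = hi[i]
            out[f"{eff}_p"] = pvals[i]
        frame = pd.DataFrame(out, index=self.predictors)
        hcru = [c for c in self.predictors if self.spec.block_of(c) == "hcru"]
        frame.loc[hcru, ["indirect_lo", "indirect_hi", "indirect_p"]] = np.nan
        return frame

    # -- presentation ---------------------------------------------------------
    def summary(self, ci: str = "delta", **kwargs) -> str:
        """Text summary in the shape of a standardized effect table."""
        tab = self.effects(ci=ci, **kwargs)
        short = {"patient_characteristics": "PC", "comorbidities": "CM",
                 "itr": "ITR", "complications": "CP", "hcru": "HCRU"}
        lines = [
            "Recursive path model of total healthcare cost",
            f"n = {self.n}   cov_type = {self.cov_type}   SRMR = {self.srmr:.4f}",
            f"outcome: {self.spec.thcc}   CI method: {ci}",
            "-" * 86,
            f"{'predictor':<24}{'block':<7}"
            f"{'direct [95% CI]':<28}{'indirect':<11}{'total [95% CI]':<26}",
            "-" * 86,
        ]
        for name, row in tab.iterrows():
            ind = "-" if np.isnan(row["indirect"]) else f"{row['indirect']:+.3f}"
            lines.append(
                f"{name:<24}{short.get(row['block'], row['block']):<7}"
                f"{row['direct']:+.3f} [{row['direct_lo']:+.3f}, {row['direct_hi']:+.3f}]   "
                f"{ind:<11}"
                f"{row['total']:+.3f} [{row['total_lo']:+.3f}, {row['total_hi']:+.3f}]"
            )
        return "\n".join(lines)

    def to_fit_json(self) -> dict:
        """Serializable record of the fit (coefficients, SEs, SRMR, n)."""
        return {
            "nodes": self.nodes,
            "B": self.B.tolist(),
            "beta": self.beta.tolist(),
            "se_robust": np.where(np.isnan(self.se), None, self.se).tolist(),
            "resid_var": self.resid_var.tolist(),
            "srmr": self.srmr,
            "n": int(self.n),
            "n_dropped": int(self.model.n_dropped),
            "cov_type": self.cov_type,
        }


def indirect_from_standardized(beta: np.ndarray) -> np.ndarray:
    """Indirect-effect matrix: sum over all directed paths of length >= 2 of
    the product of standardized edge coefficients (entry [to, from])."""
    return _path_sums(np.asarray(beta, float), min_len=2)


def _path_sums(beta: np.ndarray, min_len: int = 2) -> np.ndarray:
    """Sum of path products over all directed paths of length >= min_len.

    beta is nilpotent for a DAG, so the series terminates after p-1 powers.
    """
    p = beta.shape[0]
    total = np.zeros_like(beta)
    power = np.linalg.matrix_power(beta, min_len) if min_len > 1 else beta.copy()
    for _ in range(min_len, p):
        if not np.any(power):
            break
        total = total + power
        power = power @ beta
    return total


def _block_diag(mats) -> np.ndarray:
    sizes = [m.shape[0] for m in mats]
    out = np.zeros((sum(sizes), sum(sizes)))
    o = 0
    for m in mats:
        k = m.shape[0]
        out[o : o + k, o : o + k] = m
        o += k
    return out
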
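"""Uncertainty-weighted positive matrix factorization with error estimation.

The receptor matrix X (n samples × m species) is approximated as G·F with
G ≥ 0 (n × q source contributions) and F ≥ 0 (q × m source profiles),
minimizing the weighted least-squares objective

    Q = Σ_ij ( (x_ij − Σ_k g_ik f_kj) / σ_ij )²

where σ_ij is the per-cell measurement uncertainty.  The optimizer is
alternating weighted non-negative least squares: holding F fixed, each row
of G solves a small convex NNLS problem (and symmetrically for the columns
of F), so Q is non-increasing across sweeps by construction.  Multi-start
over random non-negative initializations guards against local minima.

Error estimation follows EPA PMF practice:

* **bootstrap (BS)** — resample sample days in blocks with replacement,
  refit from the base solution, and map each bootstrap factor to the base
  factor whose contribution series it correlates with best; a factor is
  "mapped" when that correlation reaches a threshold (default 0.6);
* **displacement (DISP)** — push one profile value away from its fitted
  value, re-optimize everything else, and record the displacement at which
  Q rises by dQmax (levels 4, 8, 16, 32); a factor swap is flagged when the
  re-optimized solution no longer tracks the base factors.

Robust mode caps the influence of ill-fit cells: where |e/σ| exceeds α
(default 4) the effective uncertainty is inflated to make the scaled
residual exactly α.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from pmfrisk.receptor import ReceptorDataset

__all__ = [
    "PMFModel",
    "PMFResults",
    "BootstrapResult",
    "DispResult",
    "fit_pmf",
    "q_diagnostics",
    "scan_factors",
    "bootstrap",
    "disp",
    "apportion_mass",
]

DEFAULT_N_STARTS = 20
DEFAULT_TOL = 1e-8
DEFAULT_TOL_ITERS = 10
DEFAULT_MAX_ITER = 20000
ROBUST_ALPHA = 4.0
DEFAULT_DQMAX_LEVELS = (4.0, 8.0, 16.0, 32.0)
SWAP_R_THRESHOLD = 0.6


# ---------------------------------------------------------------------------
# low-level weighted ALS
# ---------------------------------------------------------------------------

def _nnls_rows(X, W, B):
    """Row-wise weighted NNLS: for each i, argmin_{g≥0} ||W_i∘(X_i − g·B)||²."""
    n, q = X.shape[0], B.shape[0]
    G = np.empty((n, q))
    for i in range(n):
        A = (B * W[i][None, :]).T          # m × q design
        b = X[i] * W[i]
        G[i], _ = nnls(A, b)
    return G


def _q_value(X, W, G, F):
    R = (X - G @ F) * W
    return float(np.sum(R * R))


def _als(X, W, G, F, tol, tol_iters, max_iter, robust, alpha, trace=False):
    """Alternating NNLS on (G, F).  Returns (G, F, q_trace, converged).

    ``W`` is 1/σ.  In robust mode the working weights are recomputed each
    sweep so that cells with |e/σ| > α contribute a scaled residual of α.
    """
    q_trace = []
    Wk = W
    q_prev = np.inf
    streak = 0
    converged = False
    for it in range(max_iter):
        G = _nnls_rows(X, Wk, F)
        F = _nnls_rows(X.T, Wk.T, G.T).T
        if robust:
            R = np.abs((X - G @ F) * W)
            infl = np.where(R > alpha, R / alpha, 1.0)
            Wk = W / infl
        qv = _q_value(X, Wk, G, F)
        if trace:
            q_trace.append(qv)
        if qv <= 1e-12 * X.size:   # exact factorization found
            converged = True
            break
        rel = abs(q_prev - qv) / max(qv, 1e-300)
        streak = streak + 1 if rel < tol else 0
        q_prev = qv
        if streak >= tol_iters:
            converged = True
            break
    return G, F, q_trace, converged


def _scale_unit_mean(G, F):
    """Gauge fix: scale G columns to unit mean (F rows absorb the scale)."""
    s = G.mean(axis=0)
    s = np.where(s > 0, s, 1.0)
    return G / s[None, :], F * s[:, None]


def _match_factors(F_ref, F_new):
    """Greedy optimal assignment of new factors to reference factors by
    cosine similarity of profiles.  Returns permutation p with
    F_new[p[k]] ≈ F_ref[k]."""
    from scipy.optimize import linear_sum_assignment

    def norm(M):
        nrm = np.linalg.norm(M, axis=1, keepdims=True)
        return M / np.where(nrm > 0, nrm, 1.0)

    C = norm(F_ref) @ norm(F_new).T
    row, col = linear_sum_assignment(-C)
    perm = np.empty(len(row), dtype=int)
    perm[row] = col
    return perm


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PMFModel:
    """Weighted PMF model bound to a receptor dataset.

    Parameters
    ----------
    dataset : ReceptorDataset
        Screened dataset; only species not labelled ``bad`` are fitted.
    n_factors : int
        Number of sources q; must satisfy ``1 <= q < min(n, m)``.
    robust : bool
        Downweight cells with |scaled residual| > ``alpha`` (default True).
    include_total : bool
        Fit the total-mass column as a (weak) species so the profiles carry
        a mass row; when False, mass is apportioned post hoc by NNLS
        regression of observed PM2.5 on the contributions.
    """

    def __init__(
        self,
        dataset: ReceptorDataset,
        n_factors: int,
        robust: bool = True,
        alpha: float = ROBUST_ALPHA,
        tol: float = DEFAULT_TOL,
        tol_iters: int = DEFAULT_TOL_ITERS,
        max_iter: int = DEFAULT_MAX_ITER,
        include_total: bool = True,
    ):
        X, S, species = dataset.fit_arrays(include_total=include_total)
        n, m = X.shape
        if not (1 <= n_factors < min(n, m)):
            raise ValueError(
                f"n_factors must satisfy 1 <= q < min(n, m)={min(n, m)}, got {n_factors}"
            )
        if np.any(S <= 0):
            raise ValueError("all fitted uncertainties must be > 0")
        self.dataset = dataset
        self.n_factors = int(n_factors)
        self.robust = robust
        self.alpha = alpha
        self.tol = tol
        self.tol_iters = tol_iters
        self.max_iter = max_iter
        self.include_total = include_total
        self.X = X
        self.W = 1.0 / S
        self.species = species

    # -- fitting ------------------------------------------------------------
    def _init_gf(self, rng):
        n, m = self.X.shape
        q = self.n_factors
        scale = np.sqrt(max(self.X.mean(), 1e-12) / q)
        G0 = rng.uniform(0.1, 1.0, size=(n, q)) * scale
        F0 = rng.uniform(0.1, 1.0, size=(q, m)) * scale
        return G0, F0

    def fit(self, n_starts: int = DEFAULT_N_STARTS, seed: int = 0) -> "PMFResults":
        """Fit with ``n_starts`` random initializations; keep the lowest-Q
        run (ties broken by start index).  Start seeds are derived from
        ``seed`` by fixed increments so runs are reproducible."""
        best = None
        any_converged = False
        for s in range(n_starts):
            rng = np.random.default_rng(seed + s)
            G0, F0 = self._init_gf(rng)
            G, F, qt, conv = _als(
                self.X, self.W, G0, F0,
                self.tol, self.tol_iters, self.max_iter,
                self.robust, self.alpha, trace=True,
            )
            q_true = _q_value(self.X, self.W, G, F)
            any_converged = any_converged or conv
            if best is None or q_true < best[0]:
                best = (q_true, s, G, F, qt, conv)
        q_true, start_index, G, F, q_trace, conv = best
        if not any_converged:
            warnings.warn("no start converged; returning best run with converged=False")
        G, F = _scale_unit_mean(G, F)
        return PMFResults(
            model=self,
            G=G,
            F=F,
            q_trace=q_trace,
            converged=conv,
            seed=seed,
            start_index=start_index,
        )

    def fit_from(self, G0, F0, max_iter=None) -> "PMFResults":
        """Refit from a warm start (bootstrap / displacement re-fits)."""
        G, F, qt, conv = _als(
            self.X, self.W, np.asarray(G0, float).copy(), np.asarray(F0, float).copy(),
            self.tol, self.tol_iters,
            max_iter if max_iter is not None else self.max_iter,
            self.robust, self.alpha, trace=True,
        )
        G, F = _scale_unit_mean(G, F)
        return PMFResults(model=self, G=G, F=F, q_trace=qt, converged=conv,
                          seed=-1, start_index=-1)


@dataclass
class BootstrapResult:
    """Bootstrap factor-mapping summary.

    ``mapped_counts[k]`` counts replicates in which some bootstrap factor
    mapped to base factor k (max contribution correlation ≥ threshold);
    ``unmapped`` counts bootstrap factors that mapped to no base factor."""

    n_boot: int
    block_size: int
    r_threshold: float
    mapped_counts: np.ndarray
    unmapped: int
    failed_replicates: int

    @property
    def mapping_rate(self) -> np.ndarray:
        return self.mapped_counts / max(self.n_boot, 1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mapped": self.mapped_counts,
                "mapping_rate": self.mapping_rate,
            },
            index=[f"factor_{k + 1}" for k in range(len(self.mapped_counts))],
        )


@dataclass
class DispResult:
    """Displacement intervals per (factor, species, dQmax level)."""

    table: pd.DataFrame  # columns: factor, species, dqmax, lower, base, upper, swap
    dqmax_levels: tuple

    @property
    def any_swap(self) -> bool:
        return bool(self.table["swap"].any())

    def interval(self, factor: int, species: str, dqmax: float):
        t = self.table
        row = t[(t["factor"] == factor) & (t["species"] == species) & (t["dqmax"] == dqmax)]
        if row.empty:
            raise KeyError((factor, species, dqmax))
        r = row.iloc[0]
        return float(r["lower"]), float(r["upper"])


@dataclass
class PMFResults:
    """Fitted PMF solution.

    G columns are scaled to unit mean, so row k of F is the mean species
    apportionment (µg/m³) of factor k.
    """

    model: PMFModel
    G: np.ndarray
    F: np.ndarray
    q_trace: list
    converged: bool
    seed: int
    start_index: int
    factor_names: list = field(default=None)

    def __post_init__(self):
        if np.any(self.G < 0) or np.any(self.F < 0):
            raise ValueError("G and F must be non-negative")
        if self.factor_names is None:
            self.factor_names = [f"factor_{k + 1}" for k in range(self.n_factors)]

    # -- basic views --------------------------------------------------------
    @property
    def n_factors(self) -> int:
        return self.G.shape[1]

    @property
    def species(self) -> list:
        return self.model.species

    @property
    def contributions(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=self.model.dataset.data.index,
                            columns=self.factor_names)

    @property
    def profiles(self) -> pd.DataFrame:
        return pd.DataFrame(self.F, index=self.factor_names, columns=self.species)

    @property
    def residuals(self) -> np.ndarray:
        return self.model.X - self.G @ self.F

    @property
    def scaled_residuals(self) -> np.ndarray:
        return self.residuals * self.model.W

    @property
    def Q_true(self) -> float:
        R = self.scaled_residuals
        return float(np.sum(R * R))

    @property
    def Q_robust(self) -> float:
        """Q with scaled residuals beyond α capped via uncertainty inflation
        (equals Q_true when no cell exceeds α)."""
        r = np.abs(self.scaled_residuals)
        a = self.model.alpha
        # inflation sigma' = sigma*(r/a)  =>  (e/sigma')² caps at a²
        contrib = np.where(r > a, a * a, r * r)
        return float(np.sum(contrib))

    @property
    def Q_expected(self) -> float:
        """Degrees-of-freedom heuristic: n·m − q·(n+m) over fitted cells."""
        n, m = self.model.X.shape
        return float(n * m - self.n_factors * (n + m))

    def q_diagnostics(self) -> dict:
        return {
            "Q_true": self.Q_true,
            "Q_robust": self.Q_robust,
            "Q_expected": self.Q_expected,
            "Q_true_over_expected": self.Q_true / self.Q_expected
            if self.Q_expected > 0 else np.nan,
            "scaled_residuals": self.scaled_residuals,
        }

    def summary(self) -> str:
        d = self.q_diagnostics()
        n, m = self.model.X.shape
        lines = [
            "Weighted PMF results",
            "=" * 60,
            f"samples: {n}    species: {m}    factors: {self.n_factors}",
            f"converged: {self.converged}   (start {self.start_index}, seed {self.seed})",
            f"Q(true):     {d['Q_true']:.2f}",
            f"Q(robust):   {d['Q_robust']:.2f}",
            f"Q(expected): {d['Q_expected']:.0f}"
            f"    Q/Qexp: {d['Q_true_over_expected']:.3f}",
            "",
            "Mean factor profile (µg/m³ at unit mean contribution):",
            self.profiles.T.round(4).to_string(),
        ]
        try:
            shares = self.mass_shares()
            lines += ["", "Mean mass shares (%):",
                      shares.round(1).to_string()]
        except ValueError:
            pass
        return "\n".join(lines)

    # -- mass apportionment --------------------------------------------------
    def factor_mass(self) -> pd.DataFrame:
        """Per-day per-factor PM2.5 mass (µg/m³): G column × profile mass row.

        When the total-mass species was not fitted, mass loadings come from
        a post-hoc NNLS regression of observed PM2.5 on the contributions.
        """
        total = self.model.dataset.total_species
        if self.model.include_total and total in self.species:
            mass_row = self.F[:, self.species.index(total)]
        else:
            y = self.model.dataset.data[total].to_numpy(dtype=float)
            mass_row, _ = nnls(self.G, y)
        mass = self.G * mass_row[None, :]
        return pd.DataFrame(mass, index=self.model.dataset.data.index,
                            columns=self.factor_names)

    def mass_shares(self) -> pd.Series:
        """Mean percentage contribution of each factor to modelled PM2.5."""
        mean_mass = self.factor_mass().mean(axis=0)
        tot = mean_mass.sum()
        if tot <= 0:
            raise ValueError("modelled mass is zero; cannot compute shares")
        return 100.0 * mean_mass / tot

    def mass_r2(self) -> float:
        """R² between observed and modelled total PM2.5."""
        obs = self.model.dataset.data[self.model.dataset.total_species].to_numpy(float)
        mod = self.factor_mass().sum(axis=1).to_numpy(float)
        ss_res = np.sum((obs - mod) ** 2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan

    def apportion_species(self, species=None) -> dict:
        """Per-source per-species concentration series g_ik·f_kj (µg/m³),
        as {factor name: DataFrame(dates × species)} — input to the
        source-resolved health-risk stage."""
        if species is None:
            species = [s for s in self.species
                       if s != self.model.dataset.total_species]
        idx = [self.species.index(s) for s in species]
        out = {}
        for k, name in enumerate(self.factor_names):
            out[name] = pd.DataFrame(
                np.outer(self.G[:, k], self.F[k, idx]),
                index=self.model.dataset.data.index,
                columns=species,
            )
        return out

    # -- error estimation ----------------------------------------------------
    def bootstrap(
        self,
        n_boot: int = 100,
        block_size: int = 3,
        r_threshold: float = 0.6,
        seed: int = 0,
        refit_max_iter: int = 300,
    ) -> BootstrapResult:
        """Block-bootstrap stability analysis (see module docstring)."""
        if n_boot < 1 or block_size < 1:
            raise ValueError("n_boot and block_size must be >= 1")
        n = self.model.X.shape[0]
        q = self.n_factors
        rng = np.random.default_rng(seed)
        mapped = np.zeros(q, dtype=int)
        unmapped = 0
        failed = 0
        for _ in range(n_boot):
            idx = _block_indices(n, block_size, rng)
            boot_ds = self.model.dataset.subset_rows(idx)
            m = PMFModel(
                boot_ds, q,
                robust=self.model.robust, alpha=self.model.alpha,
                tol=self.model.tol, tol_iters=self.model.tol_iters,
                max_iter=refit_max_iter, include_total=self.model.include_total,
            )
            try:
                res = m.fit_from(self.G[idx], self.F, max_iter=refit_max_iter)
            except Exception:
                failed += 1
                continue
            base_G = self.G[idx]
            hit = set()
            for kb in range(q):
                r_best, k_best = -np.inf, -1
                for k in range(q):
                    r = _pearson(res.G[:, kb], base_G[:, k])
                    if r > r_best:
                        r_best, k_best = r, k
                if r_best >= r_threshold:
                    hit.add(k_best)
                else:
                    unmapped += 1
            for k in hit:
                mapped[k] += 1
        return BootstrapResult(
            n_boot=n_boot, block_size=block_size, r_threshold=r_threshold,
            mapped_counts=mapped, unmapped=unmapped, failed_replicates=failed,
        )

    def disp(
        self,
        species_subset=None,
        dqmax_levels=DEFAULT_DQMAX_LEVELS,
        factors=None,
        refit_max_iter: int = 150,
        rel_tol: float = 0.05,
    ) -> DispResult:
        """Displacement intervals for selected (factor, species) profile
        values (see module docstring).  ``species_subset`` defaults to all
        fitted species except total mass."""
        levels = tuple(float(d) for d in dqmax_levels)
        if any(d <= 0 for d in levels) or list(levels) != sorted(levels):
            raise ValueError("dqmax_levels must be positive and ascending")
        if species_subset is None:
            species_subset = [s for s in self.species
                              if s != self.model.dataset.total_species]
        missing = [s for s in species_subset if s not in self.species]
        if missing:
            raise ValueError(f"species not fitted: {missing}")
        if factors is None:
            factors = list(range(self.n_factors))
        q_base = self.Q_true
        rows = []
        for k in factors:
            for sp in species_subset:
                j = self.species.index(sp)
                base = float(self.F[k, j])
                bounds = _disp_one(self, k, j, q_base, levels,
                                   refit_max_iter, rel_tol)
                prev_lo, prev_hi = base, base
                for d, (lo, hi, swap) in zip(levels, bounds):
                    lo = min(lo, prev_lo)   # enforce nesting across levels
                    hi = max(hi, prev_hi)
                    prev_lo, prev_hi = lo, hi
                    rows.append({"factor": k, "species": sp, "dqmax": d,
                                 "lower": lo, "base": base, "upper": hi,
                                 "swap": swap})
        return DispResult(table=pd.DataFrame(rows), dqmax_levels=levels)


# ---------------------------------------------------------------------------
# DISP internals
# ---------------------------------------------------------------------------

def _pearson(a, b):
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _block_indices(n, block_size, rng):
    """Sample ceil(n/block) circular blocks of consecutive days, truncate to n."""
    n_blocks = int(np.ceil(n / block_size))
    starts = rng.integers(0, n, size=n_blocks)
    idx = np.concatenate([(s + np.arange(block_size)) % n for s in starts])
    return idx[:n]


def _disp_refit_q(results, k, j, value, refit_max_iter):
    """Min Q with F[k, j] pinned to ``value``; returns (Q, swap flag).

    The pin is only meaningful under the unit-mean-G gauge (otherwise a
    joint rescaling of G[:, k] and F[k, :] recovers the base solution with
    any pinned value), so the gauge is re-imposed after every G update and
    the pinned cell restored in the F update — projected alternating
    minimization of the gauge-fixed constrained problem.
    """
    model = results.model
    X, W = model.X, model.W
    G = results.G.copy()
    F = results.F.copy()
    F[k, j] = value
    q_prev = np.inf
    for _ in range(refit_max_iter):
        G = _nnls_rows(X, W, F)
        s = G.mean(axis=0)
        s = np.where(s > 1e-12, s, 1.0)
        G = G / s[None, :]
        F = F * s[:, None]
        # F update with cell (k, j) held fixed: solve column j over the
        # other factors with the pinned contribution removed.
        Ft = _nnls_rows(X.T, W.T, G.T).T
        resid_j = X[:, j] - G[:, k] * value
        others = [kk for kk in range(F.shape[0]) if kk != k]
        if others:
            A = (G[:, others] * W[:, j][:, None])
            b = resid_j * W[:, j]
            sol, _ = nnls(A, b)
            Ft[others, j] = sol
        Ft[k, j] = value
        F = Ft
        qv = _q_value(X, W, G, F)
        if abs(q_prev - qv) / max(qv, 1e-300) < 1e-7:
            break
        q_prev = qv
    # swap detection: every base factor should still have a re-optimized
    # factor whose contribution series tracks it
    swap = False
    for kb in range(F.shape[0]):
        r_best = max(_pearson(G[:, kk], results.G[:, kb]) for kk in range(F.shape[0]))
        if r_best < SWAP_R_THRESHOLD:
            swap = True
            break
    return qv, swap


def _disp_one(results, k, j, q_base, levels, refit_max_iter, rel_tol):
    """Displacement bounds for one (factor, species) cell at each dQmax.

    Returns a list of (lower, upper, swap) aligned with ``levels``.
    For each direction the boundary where ΔQ = dQmax is located by
    geometric bracketing plus bisection (relative tolerance ``rel_tol`` on
    the displacement).
    """
    base = float(results.F[k, j])
    d_max = levels[-1]
    col_scale = max(float(results.F[:, j].max()), 1e-12)
    step0 = max(0.25 * col_scale, 0.05 * max(base, col_scale))

    cache: dict = {}

    def dq(v):
        v = max(v, 0.0)
        key = round(v / max(step0, 1e-300), 6)
        if key not in cache:
            qv, swap = _disp_refit_q(results, k, j, v, refit_max_iter)
            cache[key] = (max(qv - q_base, 0.0), swap)
        return cache[key]

    out = []

    # ---- upward direction: bracket then bisect per level
    hi = base + step0
    for _ in range(40):
        if dq(hi)[0] >= d_max:
            break
        hi = base + (hi - base) * 2.0
    uppers = {}
    lo_br = base
    for d in levels:
        a, b = lo_br, hi
        if dq(b)[0] < d:       # objective never rose enough: unbounded side
            uppers[d] = (b, dq(b)[1])
            lo_br = b
            continue
        for _ in range(30):
            midv = 0.5 * (a + b)
            if dq(midv)[0] < d:
                a = midv
            else:
                b = midv
            if (b - a) <= rel_tol * max(b, step0):
                break
        uppers[d] = (b, dq(b)[1])
        lo_br = a

    # ---- downward direction (bounded below by 0)
    lowers = {}
    dq0, swap0 = dq(0.0)
    hi_br = base
    for d in levels:
        if dq0 < d:
            lowers[d] = (0.0, swap0)
            continue
        a, b = 0.0, hi_br
        for _ in range(30):
            midv = 0.5 * (a + b)
            if dq(midv)[0] < d:
                b = midv
            else:
                a = midv
            if (b - a) <= rel_tol * max(base, step0):
                break
        lowers[d] = (a, dq(a)[1])
        hi_br = b

    for d in levels:
        lo, sw_lo = lowers[d]
        up, sw_up = uppers[d]
        out.append((min(lo, base), max(up, base), bool(sw_lo or sw_up)))
    return out


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_pmf(
    ds: ReceptorDataset,
    q: int,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    robust: bool = True,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    include_total: bool = True,
) -> PMFResults:
    """Fit a q-factor weighted PMF model (wrapper over :class:`PMFModel`)."""
    model = PMFModel(ds, q, robust=robust, tol=tol, max_iter=max_iter,
                     include_total=include_total)
    return model.fit(n_starts=n_starts, seed=seed)


def q_diagnostics(results: PMFResults, ds: ReceptorDataset | None = None) -> dict:
    """Q diagnostics {Q_true, Q_robust, Q_expected, scaled residuals}."""
    if ds is not None and ds is not results.model.dataset:
        if ds.data.shape != results.model.dataset.data.shape:
            raise ValueError("dataset shape does not match the fitted model")
    return results.q_diagnostics()


def scan_factors(
    ds: ReceptorDataset,
    q_range,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Model-size scan: fit each q in ``q_range`` and tabulate Q diagnostics.

    The returned frame has one row per q with Q_true, Q_robust, Q_expected
    and their ratio — the standard aid for choosing the number of sources.
    """
    q_range = list(q_range)
    if not q_range:
        raise ValueError("q_range must be non-empty")
    rows = []
    results = {}
    for q in q_range:
        res = fit_pmf(ds, q, n_starts=n_starts, seed=seed, **kwargs)
        d = res.q_diagnostics()
        rows.append({
            "q": q,
            "Q_true": d["Q_true"],
            "Q_robust": d["Q_robust"],
            "Q_expected": d["Q_expected"],
            "Q_true_over_expected": d["Q_true_over_expected"],
            "converged": res.converged,
        })
        results[q] = res
    table = pd.DataFrame(rows).set_index("q")
    table.attrs["results"] = results
    return table


def bootstrap(results: PMFResults, ds=None, n_boot: int = 100,
              block_size: int = 3, map_r_threshold: float = 0.6,
              seed: int = 0) -> BootstrapResult:
    """Functional wrapper over :meth:`PMFResults.bootstrap`."""
    return results.bootstrap(n_boot=n_boot, block_size=block_size,
                             r_threshold=map_r_threshold, seed=seed)


def disp(results: PMFResults, ds=None, species_subset=None,
         dqmax_levels=DEFAULT_DQMAX_LEVELS) -> DispResult:
    """Functional wrapper over :meth:`PMFResults.disp`."""
    return results.disp(species_subset=species_subset, dqmax_levels=dqmax_levels)


def apportion_mass(results: PMFResults, ds=None):
    """Per-factor daily mass, mean percentage shares, and PM2.5 R²."""
    return {
        "factor_mass": results.factor_mass(),
        "shares_pct": results.mass_shares(),
        "r2": results.mass_r2(),
    }
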
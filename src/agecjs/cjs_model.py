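"""Hierarchical Bayesian Cormack-Jolly-Seber model with age, transience,
trap-dependence and individual frailty.

The state process is a Bernoulli survival chain conditioned on first
capture, ``z[i,t+1] | z[i,t] ~ Bernoulli(z[i,t] * phi[A[i,t]])``, and the
observation process is ``y[i,t] | z[i,t] ~ Bernoulli(z[i,t] * P[T[i,t]])``.
Apparent survival and recapture are modelled on the logit scale:

    logit phi[i,t] = beta[A[i,t], W(t)] + eps[i, cell]
    logit P[i,t]   = alpha[T[i,t], W(t)] + omega[i, cell]

where ``A`` is the five-category age/residency covariate (juvenile,
newly-marked/resident immature, newly-marked/resident adult), ``T`` the
four-category immediate trap-response covariate, ``W`` the study period,
and ``eps``/``omega`` logit-normal individual frailty terms with
cell-specific standard deviations. Priors are vague: Uniform(0,1) on the
probability scale for every intercept (a standard-logistic prior on the
logit scale) and Uniform(0,10) on the frailty standard deviations.

Inference is by adaptive Metropolis-within-Gibbs on the *marginal*
likelihood — the latent alive states are summed out analytically by the
forward/backward recursion — which is testable against brute-force
enumeration and makes the posterior independent of any data-augmentation
scheme. The production protocol is 3 chains of 95,000 iterations with a
40,000 burn-in, thinned by 10; convergence is screened with the
Gelman-Rubin potential scale reduction factor (values below 1.1 read as
converged).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .encounter_data import AGE_CLASS_NAMES, CaptureHistory

__all__ = [
    "MCMCConfig",
    "CJSDesign",
    "PosteriorDraws",
    "history_loglik",
    "linear_predictors",
    "dataset_loglik",
    "build_design",
    "sample_posterior",
    "gelman_rubin",
    "inverse_logit",
    "logit",
]

N_SURVIVAL_CATEGORIES = 5  # 1 juv, 2 new imm, 3 res imm, 4 new ad, 5 res ad
N_TRAP_CATEGORIES = 4      # 1/2/3 prev-captured juv/imm/ad, 4 not captured
# frailty cells group the newly-marked and resident categories of a class:
# a newly-marked bird contributes a single interval, too little to carry its
# own variance component.
_CAT_TO_GROUP = {1: 0, 2: 1, 3: 1, 4: 2, 5: 2}


def inverse_logit(x):
    """Overflow-safe logistic function, elementwise."""
    x = np.asarray(x, dtype=float)
    t = np.exp(-np.abs(x))
    out = np.where(x >= 0, 1.0 / (1.0 + t), t / (1.0 + t))
    return float(out) if out.ndim == 0 else out


def logit(p):
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Marginal likelihood of one capture history
# ---------------------------------------------------------------------------


def history_loglik(y_row, f: int, phi, p) -> float:
    """Marginal log-likelihood of one capture history given parameters.

    Sums over all latent alive/dead sequences with the standard recursion:
    between the first and last detection the individual is certainly
    alive; after the last detection the probability of never being seen
    again satisfies ``chi[t] = (1-phi[t]) + phi[t]*(1-p[t])*chi[t+1]`` with
    ``chi[k-1] = 1``. Conditioning is on the first capture (CJS), so no
    parameter before ``f`` enters.

    Parameters
    ----------
    y_row : binary vector of length k.
    f : 0-based first-capture occasion; ``y_row[f]`` must be 1.
    phi : length k-1; ``phi[t]`` is survival over occasions (t, t+1].
    p : length k-1; ``p[t]`` is the recapture probability at occasion t+1.
    """
    y = np.asarray(y_row).astype(np.int64)
    k = y.shape[0]
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    if phi.shape[0] != k - 1 or p.shape[0] != k - 1:
        raise ValueError("phi and p must have length k-1")
    if ((phi < 0) | (phi > 1)).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if y[f] != 1:
        raise ValueError("the individual must be detected at its first capture")
    if y[:f].any():
        raise ValueError("detections before the first capture occasion")
    last = int(np.flatnonzero(y).max())
    ll = 0.0
    with np.errstate(divide="ignore"):
        for t in range(f, last):
            ll += np.log(phi[t])
            ll += np.log(p[t]) if y[t + 1] else np.log1p(-p[t])
        chi = 1.0
        for t in range(k - 2, last - 1, -1):
            chi = (1.0 - phi[t]) + phi[t] * (1.0 - p[t]) * chi
        ll += np.log(chi) if chi > 0 else -np.inf
    return float(ll)


# ---------------------------------------------------------------------------
# Design: mapping covariate matrices to parameter cells
# ---------------------------------------------------------------------------


@dataclass
class CJSDesign:
    """Index structures tying each individual-interval to parameter cells."""

    k: int
    n_periods: int
    f: np.ndarray
    last: np.ndarray
    y: np.ndarray
    bidx: np.ndarray          # (n, k-1) beta cell per survival interval, -1 undefined
    aidx: np.ndarray          # (n, k-1) alpha cell per recapture occasion t+1
    egidx: np.ndarray         # (n, k-1) global survival frailty index
    ogidx: np.ndarray         # (n, k-1) global recapture frailty index
    eps_group: np.ndarray     # sigma_phi cell of each survival frailty
    omega_group: np.ndarray
    eps_ind: np.ndarray       # owning individual of each frailty
    omega_ind: np.ndarray
    beta_names: list[str]
    alpha_names: list[str]
    sigphi_names: list[str]
    sigp_names: list[str]
    beta_occupancy: np.ndarray
    alpha_occupancy: np.ndarray

    @property
    def param_names(self) -> list[str]:
        return self.beta_names + self.alpha_names + self.sigphi_names + self.sigp_names

    @property
    def nb(self) -> int:
        return len(self.beta_names)

    @property
    def na(self) -> int:
        return len(self.alpha_names)

    def beta_index(self, category: int, period: int) -> int:
        return (category - 1) * self.n_periods + (period - 1)

    def alpha_index(self, trap_category: int, period: int) -> int:
        return self.nb + (trap_category - 1) * self.n_periods + (period - 1)

    def empty_cells(self) -> list[str]:
        names = []
        for j, occ in enumerate(self.beta_occupancy):
            if occ == 0:
                names.append(self.beta_names[j])
        for j, occ in enumerate(self.alpha_occupancy):
            if occ == 0:
                names.append(self.alpha_names[j])
        return names


def build_design(history: CaptureHistory, A: np.ndarray, T: np.ndarray,
                 random_effects: str = "cell") -> CJSDesign:
    """Build parameter-cell index structures from the covariate matrices.

    ``random_effects`` selects the frailty granularity: ``"cell"`` draws an
    independent effect per (class-group, period) cell an individual
    occupies; ``"individual"`` draws one effect per individual for life
    with a single shared standard deviation; ``"none"`` switches frailty
    off entirely.
    """
    if random_effects not in ("cell", "individual", "none"):
        raise ValueError(f"unknown random_effects mode {random_effects!r}")
    grid = history.grid
    k, P = grid.k, grid.n_periods
    n = history.n
    w_occ = np.array([grid.period_of(t) for t in range(k)])
    A = np.asarray(A)
    T = np.asarray(T)

    bidx = np.full((n, k - 1), -1, dtype=np.int64)
    aidx = np.full((n, k - 1), -1, dtype=np.int64)
    w_int = np.broadcast_to(w_occ[None, : k - 1] - 1, (n, k - 1))
    w_next = np.broadcast_to(w_occ[None, 1:] - 1, (n, k - 1))
    defined = A > 0
    bidx[defined] = (A[defined] - 1) * P + w_int[defined]
    defined_t = T > 0
    aidx[defined_t] = (T[defined_t] - 1) * P + w_next[defined_t]
    if np.any((A > 0) != (T > 0)):
        raise ValueError("A and T disagree on which cells are defined")

    egidx = np.full((n, k - 1), -1, dtype=np.int64)
    ogidx = np.full((n, k - 1), -1, dtype=np.int64)
    eps_group: list[int] = []
    eps_ind: list[int] = []
    omega_group: list[int] = []
    omega_ind: list[int] = []
    if random_effects != "none":
        for i in range(n):
            seen: dict[int, int] = {}
            seen_o: dict[int, int] = {}
            for t in range(history.f[i], k - 1):
                if random_effects == "cell":
                    cell = _CAT_TO_GROUP[int(A[i, t])] * P + (w_occ[t] - 1)
                    cell_o = (int(T[i, t]) - 1) * P + (w_occ[t + 1] - 1)
                else:  # one effect per individual for life
                    cell = 0
                    cell_o = 0
                if cell not in seen:
                    seen[cell] = len(eps_group)
                    eps_group.append(cell)
                    eps_ind.append(i)
                egidx[i, t] = seen[cell]
                if cell_o not in seen_o:
                    seen_o[cell_o] = len(omega_group)
                    omega_group.append(cell_o)
                    omega_ind.append(i)
                ogidx[i, t] = seen_o[cell_o]

    beta_names = [
        f"beta[{cat},{w}]"
        for cat in range(1, N_SURVIVAL_CATEGORIES + 1)
        for w in range(1, P + 1)
    ]
    alpha_names = [
        f"alpha[{tc},{w}]"
        for tc in range(1, N_TRAP_CATEGORIES + 1)
        for w in range(1, P + 1)
    ]
    if random_effects == "cell":
        sigphi_names = [
            f"sigma_phi[{AGE_CLASS_NAMES[g]},{w}]"
            for g in range(3)
            for w in range(1, P + 1)
        ]
        sigp_names = [
            f"sigma_p[{tc},{w}]"
            for tc in range(1, N_TRAP_CATEGORIES + 1)
            for w in range(1, P + 1)
        ]
    elif random_effects == "individual":
        sigphi_names = ["sigma_phi[shared]"]
        sigp_names = ["sigma_p[shared]"]
    else:
        sigphi_names = []
        sigp_names = []

    beta_occ = np.bincount(bidx[bidx >= 0], minlength=len(beta_names))
    alpha_occ = np.bincount(aidx[aidx >= 0], minlength=len(alpha_names))

    return CJSDesign(
        k=k,
        n_periods=P,
        f=history.f.astype(np.int64),
        last=history.last.astype(np.int64),
        y=history.y.astype(np.uint8),
        bidx=bidx,
        aidx=aidx,
        egidx=egidx,
        ogidx=ogidx,
        eps_group=np.array(eps_group, dtype=np.int64),
        omega_group=np.array(omega_group, dtype=np.int64),
        eps_ind=np.array(eps_ind, dtype=np.int64),
        omega_ind=np.array(omega_ind, dtype=np.int64),
        beta_names=beta_names,
        alpha_names=alpha_names,
        sigphi_names=sigphi_names,
        sigp_names=sigp_names,
        beta_occupancy=beta_occ,
        alpha_occupancy=alpha_occ,
    )


def linear_predictors(design: CJSDesign, beta: np.ndarray, alpha: np.ndarray,
                      eps: np.ndarray | None = None,
                      omega: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual, per-interval survival and recapture probabilities.

    ``phi[i, t] = ilogit(beta[cell] + eps[i, cell])`` for the survival
    interval starting at occasion ``t``; ``p[i, t]`` likewise governs
    recapture at occasion ``t+1``. Entries before an individual's first
    capture are NaN. Requesting a defined entry whose covariate cell is
    missing raises (an indexing bug upstream), it is never defaulted.
    """
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if beta.shape[0] != design.nb or alpha.shape[0] != design.na:
        raise ValueError("beta/alpha length does not match the design's cells")
    n, km1 = design.bidx.shape
    phi = np.full((n, km1), np.nan)
    p = np.full((n, km1), np.nan)
    sel = design.bidx >= 0
    xb = beta[design.bidx[sel]]
    xa = alpha[design.aidx[sel]]
    if eps is not None and eps.size:
        xb = xb + eps[design.egidx[sel]]
    if omega is not None and omega.size:
        xa = xa + omega[design.ogidx[sel]]
    phi[sel] = inverse_logit(xb)
    p[sel] = inverse_logit(xa)
    return phi, p


def dataset_loglik(design: CJSDesign, beta: np.ndarray, alpha: np.ndarray) -> float:
    """Total marginal log-likelihood without frailty, for fixed intercepts.

    Used by tests and by external samplers as the bare-likelihood surface;
    the MCMC kernel evaluates the identical recursion individual by
    individual.
    """
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    total = 0.0
    for i in range(design.y.shape[0]):
        phi = np.zeros(design.k - 1)
        p = np.zeros(design.k - 1)
        sel = design.bidx[i] >= 0
        phi[sel] = inverse_logit(beta[design.bidx[i][sel]])
        p[sel] = inverse_logit(alpha[design.aidx[i][sel]])
        total += history_loglik(design.y[i], int(design.f[i]), phi, p)
    return total


# ---------------------------------------------------------------------------
# MCMC driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults follow the production protocol."""

    chains: int = 3
    iterations: int = 95_000
    burn_in: int = 40_000
    thin: int = 10
    seed: int = 0
    random_effects: str = "cell"  # "cell" | "individual" | "none"

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must lie in [0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def scaled_down(self) -> "MCMCConfig":
        """The documented reduced protocol for tests and quick runs."""
        return replace(self, iterations=6_000, burn_in=2_000, thin=4)


@dataclass
class PosteriorDraws:
    """Retained posterior draws of all saved parameters, by chain."""

    draws: np.ndarray  # (chains, n_retained, n_params)
    param_names: list[str]
    design: CJSDesign
    config: MCMCConfig
    rhat: np.ndarray = field(init=False)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.draws.shape[0] >= 2 and self.draws.shape[1] >= 10:
            self.rhat = gelman_rubin(self.draws)
        else:
            self.rhat = np.full(self.draws.shape[2], np.nan)
        empties = self.design.empty_cells()
        if empties:
            self.warnings.append(
                "prior-only cells (never occupied by any individual): "
                + ", ".join(empties)
            )
        if self.converged is False:
            bad = [
                f"{nm} (Rhat={r:.3f})"
                for nm, r in zip(self.param_names, self.rhat)
                if np.isfinite(r) and r >= 1.1
            ]
            self.warnings.append("non-convergence flagged: " + ", ".join(bad))

    @property
    def converged(self) -> bool | None:
        if np.isnan(self.rhat).all():
            return None
        return bool(np.nanmax(self.rhat) < 1.1)

    # -- access ----------------------------------------------------------

    def _flat(self, idx: int) -> np.ndarray:
        return self.draws[:, :, idx].reshape(-1)

    def by_name(self, name: str) -> np.ndarray:
        return self._flat(self.param_names.index(name))

    def beta_draws(self, category: int, period: int) -> np.ndarray:
        """Pooled logit-scale survival intercept draws for one cell."""
        return self._flat(self.design.beta_index(category, period))

    def alpha_draws(self, trap_category: int, period: int) -> np.ndarray:
        return self._flat(self.design.alpha_index(trap_category, period))

    def phi_draws(self, category: int, period: int) -> np.ndarray:
        """Probability-scale apparent survival draws for one cell."""
        return inverse_logit(self.beta_draws(category, period))

    def p_draws(self, trap_category: int, period: int) -> np.ndarray:
        return inverse_logit(self.alpha_draws(trap_category, period))

    def cell_is_prior_only(self, kind: str, category: int, period: int) -> bool:
        if kind == "phi":
            return bool(self.design.beta_occupancy[
                self.design.beta_index(category, period)] == 0)
        return bool(self.design.alpha_occupancy[
            self.design.alpha_index(category, period) - self.design.nb] == 0)

    # -- summaries ---------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        flat = self.draws.reshape(-1, self.draws.shape[2])
        occupied = np.concatenate(
            [
                self.design.beta_occupancy > 0,
                self.design.alpha_occupancy > 0,
                np.ones(len(self.design.sigphi_names) + len(self.design.sigp_names), bool),
            ]
        )
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": np.percentile(flat, 2.5, axis=0),
                "q97.5": np.percentile(flat, 97.5, axis=0),
                "rhat": self.rhat,
                "occupied": occupied,
            }
        )

    def draws_frame(self) -> pd.DataFrame:
        """Long-format draws table (chain, iteration, parameter, value)."""
        chains, nd, npar = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(1, chains + 1), nd * npar),
                "iteration": np.tile(np.repeat(np.arange(1, nd + 1), npar), chains),
                "parameter": np.tile(self.param_names, chains * nd),
                "value": self.draws.reshape(-1),
            }
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.summary().to_csv(directory / "posterior_summary.csv", index=False)
        self.draws_frame().to_csv(directory / "posterior_draws.csv", index=False)


def _initial_values(rng: np.random.Generator, design: CJSDesign,
                    random_effects: str) -> tuple[np.ndarray, ...]:
    beta0 = logit(rng.uniform(0.15, 0.85, size=design.nb))
    alpha0 = logit(rng.uniform(0.15, 0.85, size=design.na))
    nsg = len(design.sigphi_names)
    nsp = len(design.sigp_names)
    sigphi0 = rng.uniform(0.2, 1.5, size=nsg)
    sigp0 = rng.uniform(0.2, 1.5, size=nsp)
    return np.atleast_1d(beta0), np.atleast_1d(alpha0), sigphi0, sigp0


def sample_posterior(history: CaptureHistory, A: np.ndarray, T: np.ndarray,
                     config: MCMCConfig = MCMCConfig()) -> PosteriorDraws:
    """Draw from the posterior of the hierarchical CJS model.

    Runs ``config.chains`` independent chains (sequentially) from
    overdispersed starting values, retains every ``thin``-th post-burn-in
    iteration, and computes the Gelman-Rubin statistic for every saved
    parameter. Non-convergence and prior-only cells are reported in
    ``result.warnings``, never suppressed. Identical configs and seeds
    yield identical retained draws.
    """
    design = build_design(history, A, T, random_effects=config.random_effects)
    m_eps = np.bincount(design.eps_group, minlength=len(design.sigphi_names)) \
        if design.eps_group.size else np.zeros(len(design.sigphi_names), dtype=np.int64)
    m_om = np.bincount(design.omega_group, minlength=len(design.sigp_names)) \
        if design.omega_group.size else np.zeros(len(design.sigp_names), dtype=np.int64)

    # CSR lists of the individuals affected by each intercept cell
    def _csr(idx_matrix: np.ndarray, ncell: int) -> tuple[np.ndarray, np.ndarray]:
        members: list[set[int]] = [set() for _ in range(ncell)]
        ii, tt = np.nonzero(idx_matrix >= 0)
        for i, t in zip(ii, tt):
            members[idx_matrix[i, t]].add(int(i))
        ptr = np.zeros(ncell + 1, dtype=np.int64)
        flat: list[int] = []
        for j in range(ncell):
            ptr[j + 1] = ptr[j] + len(members[j])
            flat.extend(sorted(members[j]))
        return np.array(flat, dtype=np.int64), ptr

    aff_b_flat, aff_b_ptr = _csr(design.bidx, design.nb)
    aff_a_flat, aff_a_ptr = _csr(design.aidx, design.na)

    # CSR lists of the random effects inside each variance cell (for the
    # interweaving rescaling moves)
    def _group_csr(groups: np.ndarray, ncell: int) -> tuple[np.ndarray, np.ndarray]:
        if groups.size == 0:
            return np.zeros(0, dtype=np.int64), np.zeros(ncell + 1, dtype=np.int64)
        order = np.argsort(groups, kind="stable").astype(np.int64)
        counts = np.bincount(groups, minlength=ncell)
        ptr = np.zeros(ncell + 1, dtype=np.int64)
        ptr[1:] = np.cumsum(counts)
        return order, ptr

    grp_e_flat, grp_e_ptr = _group_csr(design.eps_group, len(design.sigphi_names))
    grp_o_flat, grp_o_ptr = _group_csr(design.omega_group, len(design.sigp_names))

    use_re = config.random_effects != "none"
    all_draws = []
    for c in range(config.chains):
        rng = np.random.default_rng([config.seed, c])
        beta0, alpha0, sigphi0, sigp0 = _initial_values(rng, design, config.random_effects)
        chain_seed = int((config.seed * 1_000_003 + 7_919 * c + 17) % (2**31 - 1))
        draws = _kernels.run_chain(
            chain_seed, config.iterations, config.burn_in, config.thin, design.k,
            design.f, design.last, design.y,
            design.bidx, design.aidx, design.egidx, design.ogidx,
            design.eps_group, design.omega_group, design.eps_ind, design.omega_ind,
            m_eps.astype(np.int64), m_om.astype(np.int64),
            aff_b_flat, aff_b_ptr, aff_a_flat, aff_a_ptr,
            grp_e_flat, grp_e_ptr, grp_o_flat, grp_o_ptr,
            beta0, alpha0, sigphi0, sigp0, use_re,
        )
        all_draws.append(draws)
    stacked = np.stack(all_draws, axis=0)
    return PosteriorDraws(
        draws=stacked,
        param_names=design.param_names,
        design=design,
        config=config,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor, per parameter.

    Classic between/within-chain construction: with m chains of n draws,
    ``W`` the mean within-chain variance and ``B/n`` the variance of the
    chain means, the pooled variance estimate is ``(n-1)/n W + B/n`` and
    the statistic is the square root of its ratio to ``W``. Degenerate
    (zero-variance) parameters report exactly 1.
    """
    draws = np.asarray(draws, dtype=float)
    squeeze = draws.ndim == 2
    if squeeze:
        draws = draws[:, :, None]
    m, nd, npar = draws.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    if nd < 10:
        raise ValueError("Gelman-Rubin needs at least ten retained draws per chain")
    means = draws.mean(axis=1)
    w = draws.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = means.var(axis=0, ddof=1)
    var_plus = (nd - 1) / nd * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    rhat = np.where(w > 0, rhat, 1.0)
    return float(rhat[0]) if squeeze else rhat
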
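"""Two-state ZZ-exchange (EXSY) forward model and least-squares fitting.

Slow folding/unfolding exchange between a folded state F and an unfolded
state U is quantified from the mixing-time dependence of the four peak
classes of a longitudinal-exchange experiment: the diagonal peaks F->F
and U->U and the cross-peaks F->U and U->F.  Longitudinal magnetization
evolves under the Bloch-McConnell rate matrix

    d/dt [M_F, M_U] = K [M_F, M_U],
    K = [[-k_FU - R1_F,  k_UF        ],
         [ k_FU,        -k_UF - R1_U]]

with k_FU = k_ex * p_U and k_UF = k_ex * (1 - p_U), so that detailed
balance p_F k_FU = p_U k_UF holds by construction.  The observable
intensities at mixing time T are the entries of expm(K T) scaled by the
initial state amplitudes.

``fit_exchange`` fits k_ex and p_U (plus per-state R1 and amplitude
nuisance parameters) to all four curves simultaneously by weighted least
squares, with standard errors from the covariance at the optimum and an
optional residual bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares

__all__ = [
    "ExchangeModelParams",
    "ExchangeDataset",
    "zz_forward",
    "fit_exchange",
    "simulate_exchange_dataset",
    "ExchangeFitResult",
]

PEAK_CLASSES = ("FF", "UU", "FU", "UF")


@dataclass
class ExchangeModelParams:
    """Two-state exchange parameters.

    k_ex = k_FU + k_UF is the total exchange rate; p_u the unfolded
    population; r1_f/r1_u the longitudinal relaxation rates of the
    observed coherence in each state; amp_f/amp_u the initial
    magnetization amplitudes.
    """

    k_ex: float
    p_u: float
    r1_f: float = 0.0
    r1_u: float = 0.0
    amp_f: float = 1.0
    amp_u: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.p_u < 1.0:
            raise ValueError(f"p_u must lie strictly in (0, 1), got {self.p_u}")
        if self.k_ex < 0:
            raise ValueError("k_ex must be >= 0")

    @property
    def k_fu(self):
        return self.k_ex * self.p_u

    @property
    def k_uf(self):
        return self.k_ex * (1.0 - self.p_u)

    def rate_matrix(self):
        return np.array(
            [
                [-self.k_fu - self.r1_f, self.k_uf],
                [self.k_fu, -self.k_uf - self.r1_u],
            ]
        )


@dataclass
class ExchangeDataset:
    """Peak intensities vs mixing delay for the four peak classes."""

    delays: np.ndarray  # s
    intensities: dict  # class -> array over delays
    weights: dict | None = None  # class -> per-point sigma

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        for cls in PEAK_CLASSES:
            if cls not in self.intensities:
                raise ValueError(f"missing intensity curve for peak class {cls}")
            self.intensities[cls] = np.asarray(self.intensities[cls], dtype=float)
            if self.intensities[cls].shape != self.delays.shape:
                raise ValueError(f"curve {cls} length mismatch with delays")
        if self.weights is not None:
            for cls in PEAK_CLASSES:
                w = np.asarray(self.weights[cls], dtype=float)
                if np.any(w <= 0):
                    raise ValueError("weights (sigmas) must be positive")
                self.weights[cls] = w

    @classmethod
    def from_csv(cls, path):
        """Read a (delay, class, intensity[, sigma]) table."""
        df = pd.read_csv(path)
        delays = np.sort(df["delay"].unique())
        intens = {}
        weights = {} if "sigma" in df.columns else None
        for pc in PEAK_CLASSES:
            sub = df[df["class"] == pc].set_index("delay").loc[delays]
            intens[pc] = sub["intensity"].to_numpy()
            if weights is not None:
                weights[pc] = sub["sigma"].to_numpy()
        return cls(delays=delays, intensities=intens, weights=weights)

    def to_csv(self, path):
        rows = []
        for pc in PEAK_CLASSES:
            for i, d in enumerate(self.delays):
                row = {"delay": d, "class": pc, "intensity": self.intensities[pc][i]}
                if self.weights is not None:
                    row["sigma"] = self.weights[pc][i]
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def zz_forward(params: ExchangeModelParams, t):
    """Evaluate the four ZZ-exchange intensity curves at mixing time(s) t.

    Returns a dict {FF, UU, FU, UF} of arrays (or floats for scalar t).
    FF/FU start from (amp_f, 0); UU/UF start from (0, amp_u); FU denotes
    magnetization that started on F and is detected on U.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    K = params.rate_matrix()
    out = {c: np.empty(t_arr.shape) for c in PEAK_CLASSES}
    for i, ti in enumerate(t_arr):
        P = expm(K * ti)
        out["FF"][i] = params.amp_f * P[0, 0]
        out["FU"][i] = params.amp_f * P[1, 0]
        out["UU"][i] = params.amp_u * P[1, 1]
        out["UF"][i] = params.amp_u * P[0, 1]
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return {c: float(v[0]) for c, v in out.items()}
    return out


@dataclass
class ExchangeFitResult:
    params: ExchangeModelParams
    stderr: dict
    cost: float
    success: bool
    message: str

    def to_json(self):
        import json

        p = self.params
        return json.dumps(
            {
                "k_ex": {"value": p.k_ex, "stderr": self.stderr.get("k_ex")},
                "p_u": {"value": p.p_u, "stderr": self.stderr.get("p_u")},
                "r1_f": {"value": p.r1_f, "stderr": self.stderr.get("r1_f")},
                "r1_u": {"value": p.r1_u, "stderr": self.stderr.get("r1_u")},
                "amp_f": {"value": p.amp_f, "stderr": self.stderr.get("amp_f")},
                "amp_u": {"value": p.amp_u, "stderr": self.stderr.get("amp_u")},
                "cost": self.cost,
                "success": self.success,
            }
        )


_NAMES = ("k_ex", "p_u", "r1_f", "r1_u", "amp_f", "amp_u")


def _residuals(theta, data: ExchangeDataset, shared_r1: bool):
    k_ex, p_u, r1_f, r1_u, amp_f, amp_u = theta
    if shared_r1:
        r1_u = r1_f
    pars = ExchangeModelParams(
        k_ex=k_ex, p_u=p_u, r1_f=r1_f, r1_u=r1_u, amp_f=amp_f, amp_u=amp_u
    )
    model = zz_forward(pars, data.delays)
    res = []
    for pc in PEAK_CLASSES:
        r = model[pc] - data.intensities[pc]
        if data.weights is not None:
            r = r / data.weights[pc]
        res.append(r)
    return np.concatenate(res)


def fit_exchange(
    data: ExchangeDataset,
    init: ExchangeModelParams | None = None,
    shared_r1: bool = False,
    bootstrap: int = 0,
    rng=None,
):
    """Weighted least-squares fit of the two-state ZZ-exchange model.

    All four curves are fitted simultaneously.  Standard errors come from
    the covariance at the optimum (scaled by the reduced chi-square when
    no weights are given); ``bootstrap`` > 0 adds residual-bootstrap
    errors, replacing the covariance estimates.
    """
    if data.delays.size < 2:
        raise ValueError("need at least 2 mixing delays")
    if init is None:
        amp0 = max(data.intensities["FF"].max(), 1e-12)
        ampu0 = max(data.intensities["UU"].max(), 1e-12)
        init = ExchangeModelParams(k_ex=1.0, p_u=0.5, r1_f=1.0, r1_u=1.0, amp_f=amp0, amp_u=ampu0)

    x0 = np.array([init.k_ex, init.p_u, init.r1_f, init.r1_u, init.amp_f, init.amp_u])
    eps = 1e-9
    lb = np.array([0.0, eps, 0.0, 0.0, -np.inf, -np.inf])
    ub = np.array([np.inf, 1.0 - eps, np.inf, np.inf, np.inf, np.inf])
    x0 = np.clip(x0, lb + eps, ub - eps)

    sol = least_squares(_residuals, x0, args=(data, shared_r1), bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"exchange fit did not converge: {sol.message}; final cost {sol.cost:.3g}")

    theta = sol.x.copy()
    if shared_r1:
        theta[3] = theta[2]
    fitted = ExchangeModelParams(*theta)

    # covariance from the Jacobian at the optimum
    J = sol.jac
    dof = max(1, sol.fun.size - (5 if shared_r1 else 6))
    s2 = 2.0 * sol.cost / dof if data.weights is None else 1.0
    JTJ = J.T @ J
    stderr = {}
    try:
        cov = s2 * np.linalg.pinv(JTJ)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        stderr = dict(zip(_NAMES, se))
        if shared_r1:
            stderr["r1_u"] = stderr["r1_f"]
    except np.linalg.LinAlgError:  # pragma: no cover - near-singular fits
        stderr = {n: float("nan") for n in _NAMES}

    if bootstrap > 0:
        rng = np.random.default_rng(rng)
        model = zz_forward(fitted, data.delays)
        resid = {pc: data.intensities[pc] - model[pc] for pc in PEAK_CLASSES}
        draws = []
        for _ in range(bootstrap):
            boot = {
                pc: model[pc] + rng.choice(resid[pc], size=resid[pc].size, replace=True)
                for pc in PEAK_CLASSES
            }
            bdata = ExchangeDataset(
                delays=data.delays.copy(), intensities=boot,
                weights=None if data.weights is None else dict(data.weights),
            )
            try:
                bsol = least_squares(
                    _residuals, sol.x, args=(bdata, shared_r1), bounds=(lb, ub)
                )
                draws.append(bsol.x)
            except Exception:  # pragma: no cover
                continue
        if draws:
            sds = np.std(np.array(draws), axis=0, ddof=1)
            stderr = dict(zip(_NAMES, sds))
            if shared_r1:
                stderr["r1_u"] = stderr["r1_f"]

    return ExchangeFitResult(
        params=fitted,
        stderr=stderr,
        cost=float(sol.cost),
        success=bool(sol.success),
        message=str(sol.message),
    )


def simulate_exchange_dataset(params: ExchangeModelParams, delays, noise_sd=0.0, rng=None):
    """Forward curves at the given delays plus additive Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    delays = np.asarray(delays, dtype=float)
    curves = zz_forward(params, delays)
    weights = None
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        curves = {pc: v + rng.normal(0.0, noise_sd, size=v.shape) for pc, v in curves.items()}
        weights = {pc: np.full(delays.shape, noise_sd) for pc in PEAK_CLASSES}
    return ExchangeDataset(delays=delays, intensities=curves, weights=weights)
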
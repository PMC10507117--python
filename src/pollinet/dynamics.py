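"""Consumer-resource population dynamics with adaptive foraging.

The model couples four sets of state variables on a bipartite
plant-pollinator network:

* plant abundances ``P_i``, which grow with the quantity and quality of
  pollinator visits and decline with mortality,
* pollinator abundances ``A_j``, which grow by converting consumed floral
  rewards into births,
* floral rewards ``R_i``, produced by plants and depleted by visitors,
* foraging efforts ``alpha_ij``, the fraction of its per-capita foraging
  a pollinator assigns to each plant in its diet.

Visit quantity is ``v_ij = A_j P_i tau_j alpha_ij`` and visit quality
``sigma_ij`` is the share of conspecific pollen carried by pollinator j,
``eps_i v_ij / sum_k eps_k v_kj``.  Rewards consumption follows a linear
(Type I) functional response, ``f(R_i) = alpha_ij tau_j b_ij R_i``.
Adaptive foraging is a replicator equation driving efforts toward the
plants yielding the highest per-effort rewards intake; it conserves the
per-pollinator effort simplex exactly.  With adaptive foraging disabled
efforts stay uniform over each pollinator's diet (fixed foragers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .community import Community

__all__ = [
    "visit_rates",
    "consumption",
    "recruitment",
    "rhs",
    "integrate",
    "doubling_time",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last community state."""

    def __init__(self, message: str, community: Community | None = None):
        super().__init__(message)
        self.community = community


# --------------------------------------------------------------- derived rates


def visit_rates(comm: Community) -> tuple[np.ndarray, np.ndarray]:
    """Visit quantities ``v_ij`` and qualities ``sigma_ij``.

    ``sigma`` columns are normalized over the plants each pollinator
    visits; a pollinator with no pollen flow (zero denominator) has all
    qualities zero.
    """
    tau = comm.poll_params["tau"]
    v = comm.alpha * comm.P[:, None] * (comm.A * tau)[None, :]
    ev = comm.plant_params["eps"][:, None] * v
    denom = ev.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.where(denom > 0, ev / np.where(denom > 0, denom, 1.0), 0.0)
    return v, sigma


def consumption(comm: Community) -> np.ndarray:
    """Per-capita rewards consumption ``f(R_i) = alpha_ij tau_j b_ij R_i``."""
    tb = comm.poll_params["tau"] * comm.poll_params["b"]
    return comm.alpha * comm.R[:, None] * tb[None, :]


def recruitment(comm: Community, P: np.ndarray | None = None) -> np.ndarray:
    """Seed-to-adult recruitment fractions ``gamma_i``.

    ``gamma_i = g_i (1 - sum_{l != i} u_l P_l - w_i P_i)``; may be
    negative under over-crowding and is returned unclamped.
    """
    if P is None:
        P = comm.P
    u = comm.plant_params["u"]
    total_u = float(u @ P)
    return comm.plant_params["g"] * (1.0 - (total_u - u * P) - comm.plant_params["w"] * P)


# ------------------------------------------------------------------------ rhs


def rhs(comm: Community, adaptive: bool = True) -> tuple[np.ndarray, ...]:
    """Time derivatives ``(dP, dA, dR, dalpha)`` at the community's state.

    With ``adaptive=False`` (or ``G_j = 0``) the effort derivatives vanish.
    The replicator structure guarantees ``sum_i dalpha_ij = 0``.
    """
    comm.validate()
    v, sigma = visit_rates(comm)
    f = consumption(comm)
    gamma = recruitment(comm)
    e = comm.plant_params["e"]
    c = comm.poll_params["c"]
    dP = gamma * (e[:, None] * v * sigma).sum(axis=1) - comm.P * comm.plant_params["mu_P"]
    intake = (c[None, :] * f).sum(axis=0)  # per-capita rewards-to-birth gain
    dA = comm.A * intake - comm.A * comm.poll_params["mu_A"]
    dR = (
        comm.plant_params["beta"] * comm.P
        - comm.plant_params["phi"] * comm.R
        - (comm.A[None, :] * f).sum(axis=1)
    )
    if adaptive:
        tb = comm.poll_params["tau"] * comm.poll_params["b"]
        fitness = np.where(comm.adjacency, c[None, :] * tb[None, :] * comm.R[:, None], 0.0)
        dalpha = comm.poll_params["G"][None, :] * comm.alpha * (fitness - intake[None, :])
    else:
        dalpha = np.zeros_like(comm.alpha)
    return dP, dA, dR, dalpha


# ------------------------------------------------------------------ integrate


@dataclass
class _LinkSystem:
    """Flattened ODE right-hand side over the community's link list."""

    comm: Community
    adaptive: bool
    li: np.ndarray = field(init=False)  # plant row per link
    lj: np.ndarray = field(init=False)  # pollinator column per link

    def __post_init__(self) -> None:
        self.li, self.lj = np.nonzero(self.comm.adjacency)

    def pack(self) -> np.ndarray:
        c = self.comm
        parts = [c.P, c.A, c.R]
        if self.adaptive:
            parts.append(c.alpha[self.li, self.lj])
        return np.concatenate(parts) if parts else np.zeros(0)

    def unpack(self, y: np.ndarray) -> None:
        c = self.comm
        n_p, n_a = c.n_plants, c.n_polls
        c.P = np.maximum(y[:n_p], 0.0)
        c.A = np.maximum(y[n_p : n_p + n_a], 0.0)
        c.R = np.maximum(y[n_p + n_a : 2 * n_p + n_a], 0.0)
        if self.adaptive:
            al = np.zeros((n_p, n_a))
            al[self.li, self.lj] = np.maximum(y[2 * n_p + n_a :], 0.0)
            c.alpha = al
            c.normalize_efforts()

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        c = self.comm
        n_p, n_a = c.n_plants, c.n_polls
        P = np.maximum(y[:n_p], 0.0)
        A = np.maximum(y[n_p : n_p + n_a], 0.0)
        R = np.maximum(y[n_p + n_a : 2 * n_p + n_a], 0.0)
        li, lj = self.li, self.lj
        if self.adaptive:
            a = np.maximum(y[2 * n_p + n_a :], 0.0)
        else:
            a = self._uniform_alpha
        pp, ap = c.plant_params, c.poll_params
        tau_l = ap["tau"][lj]
        v = A[lj] * P[li] * tau_l * a
        ev = pp["eps"][li] * v
        denom = np.bincount(lj, weights=ev, minlength=n_a)
        dsafe = np.where(denom > 0, denom, 1.0)
        sigma = np.where(denom[lj] > 0, ev / dsafe[lj], 0.0)
        u = pp["u"]
        total_u = float(u @ P)
        gamma = pp["g"] * (1.0 - (total_u - u * P) - pp["w"] * P)
        seed = np.bincount(li, weights=pp["e"][li] * v * sigma, minlength=n_p)
        dP = gamma * seed - P * pp["mu_P"]
        f = a * tau_l * ap["b"][lj] * R[li]
        intake = np.bincount(lj, weights=ap["c"][lj] * f, minlength=n_a)
        dA = A * intake - A * ap["mu_A"]
        drain = np.bincount(li, weights=A[lj] * f, minlength=n_p)
        dR = pp["beta"] * P - pp["phi"] * R - drain
        if self.adaptive:
            fitness = ap["c"][lj] * tau_l * ap["b"][lj] * R[li]
            dalpha = ap["G"][lj] * a * (fitness - intake[lj])
            return np.concatenate([dP, dA, dR, dalpha])
        return np.concatenate([dP, dA, dR])

    @property
    def _uniform_alpha(self) -> np.ndarray:
        d = np.bincount(self.lj, minlength=self.comm.n_polls)
        return 1.0 / d[self.lj]


def integrate(
    comm: Community,
    t_span: float,
    adaptive: bool = True,
    threshold: float | None = None,
    checkpoint_interval: float | None = None,
    t0: float = 0.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> list[tuple[object, float]]:
    """Advance the community in place by ``t_span`` timesteps.

    At each checkpoint (every ``checkpoint_interval`` timesteps, or only
    at the end when ``None``) species whose abundance has fallen to or
    below ``threshold`` are removed and logged as ``(species_id, time)``;
    surviving pollinators' efforts are renormalized.  Returns the
    extinction log.  Solver failure raises :class:`IntegrationError`
    carrying the state at failure.
    """
    if t_span < 0:
        raise ValueError("t_span must be nonnegative")
    log: list[tuple[object, float]] = []
    if t_span == 0:
        return log
    if not adaptive:
        comm.set_uniform_efforts()
    step = checkpoint_interval if checkpoint_interval else t_span
    t = t0
    t_end = t0 + t_span
    while t < t_end - 1e-9:
        t_next = min(t + step, t_end)
        if comm.n_plants + comm.n_polls > 0:
            sys = _LinkSystem(comm, adaptive)
            y0 = sys.pack()
            sol = solve_ivp(
                sys,
                (t, t_next),
                y0,
                method="LSODA",
                rtol=rtol,
                atol=atol,
                t_eval=[t_next],
            )
            if not sol.success:
                raise IntegrationError(
                    f"solver failed at t~{t_next}: {sol.message}", comm
                )
            sys.unpack(sol.y[:, -1])
            if not adaptive:
                comm.set_uniform_efforts()
        if threshold is not None:
            log.extend(apply_extinctions(comm, threshold, t_next))
        t = t_next
    return log


def apply_extinctions(
    comm: Community, threshold: float, time: float
) -> list[tuple[object, float]]:
    """Remove species at/below the abundance threshold; returns the log."""
    dead_p = np.nonzero(comm.P <= threshold)[0]
    dead_a = np.nonzero(comm.A <= threshold)[0]
    log = [(comm.plant_ids[i], time) for i in dead_p]
    log += [(comm.poll_ids[j], time) for j in dead_a]
    if len(log):
        comm.remove_species(list(dead_p), list(dead_a))
    return log


# ------------------------------------------------------------------- analytic


def doubling_time(mu_A: float) -> float:
    """Pollinator generation time ``T = ln(2) / mu_A``.

    With the default mortality 0.001 per timestep this is ~693.15
    timesteps, so a 1e5-timestep assembly spans ~144 generations.
    """
    if mu_A <= 0:
        raise ValueError("mortality rate must be positive")
    return math.log(2.0) / mu_A
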
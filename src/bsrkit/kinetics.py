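"""nth-order plug-flow kinetics of sulfate reduction.

The packed-bed reactors are idealised as plug flow: a fluid parcel entering
with sulfate concentration C0 evolves along cumulative residence time
τ = V/F under the irreversible rate law r = k·Cⁿ, giving the closed forms

    n = 1:   C(τ) = C0 · exp(−k·τ)
    n ≠ 1:   C(τ) = [C0^(1−n) − (1−n)·k·τ]^(1/(1−n))

with substrate exhaustion (C → 0) when the bracket becomes non-positive for
n < 1. Volumetric sulfate reduction rate (VSRR) over a reactor or zone is
r_A = X·F·C0/V with conversion X = (C_in − C_out)/C_in.

Fitting minimises the sum of squared concentration residuals over
zone-boundary and effluent observations across an HRT series, with a
deterministic multi-start bounded least-squares search over (n, log10 k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ReactorGeometry",
    "SteadyStateObservation",
    "FitOptions",
    "KineticFit",
    "conversion",
    "vsrr",
    "plugflow_effluent",
    "cstr_effluent",
    "fit_order_and_rate",
    "dilution_rate",
]

#: Magnitude of g = (n−1)·k·τ·C0^(n−1) below which log1p(g)/g switches to its
#: series 1 − g/2; keeps the plug-flow evaluation smooth through n = 1 at
#: machine precision.
N_UNITY_EPS = 1e-8


@dataclass(frozen=True)
class ReactorGeometry:
    """Reactor volume layout.

    ``zone_boundaries`` are cumulative volumes from the inlet (L), strictly
    increasing, ending at ``total_volume``; a packed-bed column sampled at
    thirds has boundaries (0.33, 0.66, 1.0). A CSTR has the single boundary
    equal to its volume.
    """

    reactor_id: str
    kind: str  # "plug_flow" | "cstr" | "channel"
    total_volume: float
    zone_boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("plug_flow", "cstr", "channel"):
            raise ValueError(f"unknown reactor kind {self.kind!r}")
        b = tuple(float(v) for v in self.zone_boundaries)
        object.__setattr__(self, "zone_boundaries", b)
        if not b or any(x2 <= x1 for x1, x2 in zip(b, b[1:])) or b[0] <= 0:
            raise ValueError("zone_boundaries must be positive and strictly increasing")
        if not math.isclose(b[-1], self.total_volume, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("last zone boundary must equal total_volume")


@dataclass(frozen=True)
class SteadyStateObservation:
    """One steady-state measurement point.

    ``position`` is cumulative volume from the inlet (L); for effluent or
    CSTR samples it equals the total reactor volume. ``concentrations`` and
    ``feed`` map species id → mg/L; ``flow_rate`` is L/h.
    """

    reactor_id: str
    hrt: float  # h
    flow_rate: float  # L/h
    position: float  # L
    concentrations: dict[str, float]
    feed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hrt <= 0 or self.flow_rate <= 0 or self.position <= 0:
            raise ValueError("hrt, flow_rate and position must be positive")
        bad = {s: c for s, c in self.concentrations.items() if c < 0}
        if bad:
            raise ValueError(f"negative concentrations: {bad}")

    @property
    def tau(self) -> float:
        """Cumulative residence time to this position, h."""
        return self.position / self.flow_rate

    def check_flow_consistency(self, total_volume: float, tol: float = 0.01) -> None:
        """F × HRT must reproduce the reactor volume (load-time invariant)."""
        if abs(self.flow_rate * self.hrt - total_volume) > tol * total_volume:
            raise ValueError(
                f"{self.reactor_id}: flow {self.flow_rate:g} L/h × HRT {self.hrt:g} h "
                f"= {self.flow_rate * self.hrt:g} L differs from reactor volume "
                f"{total_volume:g} L by more than {tol:.0%}"
            )


@dataclass(frozen=True)
class FitOptions:
    """Controls for :func:`fit_order_and_rate` (deterministic by construction)."""

    objective: str = "conc"  # "conc" (default) or "rate"
    n_bounds: tuple[float, float] = (0.1, 5.0)
    log10_k_bounds: tuple[float, float] = (-12.0, 3.0)
    n_starts: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    extra_k_starts: int = 0  # additional log-spaced k starts per n (1e-9..1)
    sse_tie_tol: float = 1e-9


@dataclass
class KineticFit:
    """Fitted reaction order and rate constant with diagnostics.

    ``k`` has units mg^(1−n)·L^(n−1)·h⁻¹ so that r = k·Cⁿ is mg·L⁻¹·h⁻¹.
    """

    n: float
    k: float
    sse: float
    residuals: np.ndarray
    n_obs: int
    converged: bool
    starts_tried: int
    tie_flag: bool = False
    clipped_observations: tuple[int, ...] = ()
    objective: str = "conc"


def conversion(c_in: float, c_out: float, noise_tol: float = 0.05) -> float:
    """Fractional conversion X = (C_in − C_out)/C_in, in [0, 1].

    C_out marginally above C_in (measurement noise, within ``noise_tol``
    relative) is clipped to X = 0; a larger excess raises.
    """
    if c_in <= 0:
        raise ValueError("inlet concentration must be positive")
    if c_out < 0:
        raise ValueError("outlet concentration must be >= 0")
    x = (c_in - c_out) / c_in
    if x < 0:
        if -x <= noise_tol:
            return 0.0
        raise ValueError(
            f"outlet {c_out:g} exceeds inlet {c_in:g} beyond noise tolerance {noise_tol:.0%}"
        )
    return x


def vsrr(x: float, flow_rate: float, c0: float, volume: float) -> float:
    """Volumetric sulfate reduction rate r_A = X·F·C0/V, mg·L⁻¹·h⁻¹."""
    if volume <= 0 or flow_rate <= 0:
        raise ValueError("volume and flow rate must be positive")
    if not 0 <= x <= 1:
        raise ValueError("conversion must lie in [0, 1]")
    return x * flow_rate * c0 / volume


def dilution_rate(hrt: float) -> float:
    """D = 1/HRT, h⁻¹."""
    if hrt <= 0:
        raise ValueError("HRT must be positive")
    return 1.0 / hrt


def plugflow_effluent(c0, n: float, k: float, tau) -> float | np.ndarray:
    """Concentration leaving an ideal plug-flow reactor after residence time τ.

    Closed-form integral of dC/dτ = −k·Cⁿ from C0. Returns 0 once the
    substrate is exhausted (bracket ≤ 0, possible for n < 1); never NaN.
    Vectorised over ``tau`` (and ``c0``).
    """
    if k < 0:
        raise ValueError("rate constant must be >= 0")
    if n < 0:
        raise ValueError("reaction order must be >= 0")
    c0 = np.asarray(c0, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(c0 <= 0) or np.any(tau < 0):
        raise ValueError("need C0 > 0 and tau >= 0")
    if k == 0.0:
        out = c0 * np.ones_like(tau)
        return float(out) if out.ndim == 0 else out
    # Stable evaluation smooth through n = 1:
    #   C^(1-n) = C0^(1-n)·[1 + g],  g = (n-1)·k·τ·C0^(n-1)
    #   ln C   = ln C0 − k·τ·C0^(n-1)·φ(g),  φ(g) = log1p(g)/g, φ(0) = 1,
    # which reduces to C0·exp(−kτ) exactly as n → 1 and avoids the
    # catastrophic cancellation of forming C0^(1-n) − (1-n)kτ directly.
    scaled_ktau = k * tau * c0 ** (n - 1.0)
    g = (n - 1.0) * scaled_ktau
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(np.abs(g) > N_UNITY_EPS, np.log1p(np.maximum(g, -1.0)) / np.where(g == 0, 1.0, g), 1.0 - g / 2.0)
    out = np.where(g > -1.0, c0 * np.exp(-scaled_ktau * phi), 0.0)
    out = np.minimum(out, c0)
    return float(out) if out.ndim == 0 else out


def cstr_effluent(c0: float, n: float, k: float, hrt: float) -> float:
    """Steady-state concentration of a CSTR from the mass balance k·Cⁿ = D·(C0 − C).

    Solved by bisection on (0, C0]; the balance has a unique root because the
    left side increases and the right side decreases in C.
    """
    if c0 <= 0 or hrt <= 0 or k < 0 or n < 0:
        raise ValueError("need C0 > 0, HRT > 0, k >= 0, n >= 0")
    if k == 0:
        return c0
    d = dilution_rate(hrt)
    from scipy.optimize import brentq

    f = lambda c: k * c**n - d * (c0 - c)
    if f(c0) <= 0:  # pragma: no cover - k>0 makes f(c0) > 0
        return c0
    return brentq(f, 0.0, c0, xtol=1e-12, rtol=1e-14)


def _initial_log10_k(n: float, c0: np.ndarray, c: np.ndarray, tau: np.ndarray) -> float:
    """Closed-form k estimate from the median observation at a trial order."""
    i = int(np.argsort(tau)[len(tau) // 2])
    c0_i, c_i, tau_i = c0[i], max(c[i], 1e-9), max(tau[i], 1e-9)
    c_i = min(c_i, c0_i * (1 - 1e-9))  # ensure a positive drop
    if abs(n - 1.0) < N_UNITY_EPS:
        k = math.log(c0_i / c_i) / tau_i
    else:
        k = (c_i ** (1.0 - n) - c0_i ** (1.0 - n)) / ((n - 1.0) * tau_i)
    return math.log10(max(k, 1e-12))


def fit_order_and_rate(
    observations: list[SteadyStateObservation],
    geometry: ReactorGeometry,
    options: FitOptions | None = None,
    species: str = "sulfate",
) -> KineticFit:
    """Fit one global (n, k) to zone-resolved, multi-HRT concentration data.

    Each observation contributes the residual
    C_obs(τᵢ) − plugflow_effluent(C0ᵢ, n, k, τᵢ); the default objective is in
    concentration space (``options.objective="rate"`` fits VSRR instead).
    Bounded trust-region least squares is restarted from a fixed grid of
    trial orders, each paired with a closed-form rate-constant guess, so the
    result is deterministic. Ties in SSE within ``sse_tie_tol`` are resolved
    toward the smaller order (parsimony) and flagged.
    """
    opts = options or FitOptions()
    if opts.objective not in ("conc", "rate"):
        raise ValueError("objective must be 'conc' or 'rate'")
    reactors = {o.reactor_id for o in observations}
    if len(reactors) > 1:
        raise ValueError(f"observations span multiple reactors: {sorted(reactors)}")
    usable = [o for o in observations if species in o.concentrations and species in o.feed]
    taus = np.array([o.tau for o in usable])
    if len(usable) < 3 or len(np.unique(np.round(taus, 9))) < 2:
        raise ValueError(
            "insufficient data: need >= 3 observations spanning >= 2 distinct residence times"
        )
    c0 = np.array([o.feed[species] for o in usable])
    c_obs = np.array([o.concentrations[species] for o in usable])
    flow = np.array([o.flow_rate for o in usable])
    clipped = tuple(int(i) for i in np.flatnonzero(c_obs > c0))

    if opts.objective == "conc":
        target = c_obs
        to_space = lambda c_model: c_model
    else:
        # rate space: VSRR over the cumulative volume to each position
        vol = np.array([o.position for o in usable])
        x_obs = np.clip((c0 - c_obs) / c0, 0.0, 1.0)
        target = x_obs * flow * c0 / vol
        to_space = lambda c_model: np.clip((c0 - c_model) / c0, 0.0, 1.0) * flow * c0 / vol

    def residual(params: np.ndarray) -> np.ndarray:
        n, log10k = params
        return to_space(plugflow_effluent(c0, n, 10.0**log10k, taus)) - target

    lo = np.array([opts.n_bounds[0], opts.log10_k_bounds[0]])
    hi = np.array([opts.n_bounds[1], opts.log10_k_bounds[1]])
    candidates: list[tuple[float, float, float, bool]] = []  # (sse, n, log10k, ok)
    starts = 0
    for n0 in opts.n_starts:
        k_guesses = [_initial_log10_k(n0, c0, c_obs, taus)]
        if opts.extra_k_starts:
            k_guesses += list(np.linspace(-9.0, 0.0, opts.extra_k_starts))
        for lk0 in k_guesses:
            x0 = np.clip([n0, lk0], lo, hi)
            starts += 1
            try:
                sol = least_squares(
                    residual, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
            except Exception:
                continue
            candidates.append((float(np.sum(sol.fun**2)), sol.x[0], sol.x[1], bool(sol.success)))
    if not candidates:
        raise RuntimeError("optimizer failed at every start")
    best_sse = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] - best_sse <= opts.sse_tie_tol]
    tie_flag = len({round(c[1], 6) for c in tied}) > 1
    sse, n_hat, lk_hat, ok = min(tied, key=lambda c: c[1])  # parsimony: smallest n
    k_hat = 10.0**lk_hat
    res = to_space(plugflow_effluent(c0, n_hat, k_hat, taus)) - target
    return KineticFit(
        n=float(n_hat),
        k=float(k_hat),
        sse=float(np.sum(res**2)),
        residuals=res,
        n_obs=len(usable),
        converged=any(c[3] for c in tied),
        starts_tried=starts,
        tie_flag=tie_flag,
        clipped_observations=clipped,
        objective=opts.objective,
    )
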